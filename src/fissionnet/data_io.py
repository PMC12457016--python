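"""Tabular schemas, validation and CSV round-trip for behavioral observation data.

The on-disk format is a directory of UTF-8 CSV files with headers and
ISO-8601 dates:

    individuals.csv          id, sex, birth_date, mother_id, adult_from
    focal_scans.csv          focal_id, date, minute_index, activity,
                             partner_id, proximity_partner_ids
    agonistic.csv            date, winner_id, loser_id, group_id
    census.csv               date, group_id, present_ids
    births.csv               mother_id, infant_id, birth_date, death_date
    fissions.csv             event_id, parent_group_id, subgrouping_onset,
                             fission_date, resident_male_daughter
    fission_assignments.csv  event_id, individual_id, daughter

Unknown values are empty fields.  ``present_ids`` and
``proximity_partner_ids`` are semicolon-joined id lists.  Dates are
day-resolution.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from pathlib import Path
from typing import Iterable

import pandas as pd

ACTIVITIES = ("feed", "move", "social_groom", "rest")
SEXES = ("female", "male")
DAUGHTERS = ("A", "B")

#: aliases accepted (case-insensitively) as "unknown" on read, beyond the empty field
DEFAULT_NA_ALIASES: tuple[str, ...] = ()

FILE_SCHEMAS: dict[str, list[str]] = {
    "individuals": ["id", "sex", "birth_date", "mother_id", "adult_from"],
    "focal_scans": [
        "focal_id",
        "date",
        "minute_index",
        "activity",
        "partner_id",
        "proximity_partner_ids",
    ],
    "agonistic": ["date", "winner_id", "loser_id", "group_id"],
    "census": ["date", "group_id", "present_ids"],
    "births": ["mother_id", "infant_id", "birth_date", "death_date"],
    "fissions": [
        "event_id",
        "parent_group_id",
        "subgrouping_onset",
        "fission_date",
        "resident_male_daughter",
    ],
    "fission_assignments": ["event_id", "individual_id", "daughter"],
}


class DataValidationError(ValueError):
    """A record violates a schema invariant.

    The message names the offending table, the (0-based) row within it and
    the invariant that failed.
    """


@dataclasses.dataclass
class FissionEvent:
    """One permanent group fission: a parent group splitting into daughters A/B."""

    event_id: str
    parent_group_id: str
    subgrouping_onset: dt.date
    fission_date: dt.date
    daughter_assignments: dict[str, str]
    resident_male_daughter: str

    def daughter_members(self, daughter: str) -> set[str]:
        return {i for i, d in self.daughter_assignments.items() if d == daughter}


@dataclasses.dataclass
class BehaviorDataset:
    """Validated collection of observation records for one study population.

    Tables are pandas DataFrames with the columns listed in
    :data:`FILE_SCHEMAS`; date columns hold ``datetime.date`` objects and
    unknown values are ``None``.
    """

    individuals: pd.DataFrame
    focal_scans: pd.DataFrame
    agonistic: pd.DataFrame
    census: pd.DataFrame
    births: pd.DataFrame
    fissions: list[FissionEvent]

    def fission(self, event_id: str) -> FissionEvent:
        for f in self.fissions:
            if f.event_id == event_id:
                return f
        raise KeyError(f"unknown fission event {event_id!r}")

    def sex_of(self, ind_id: str) -> str:
        row = self.individuals.loc[self.individuals["id"] == ind_id]
        if row.empty:
            raise KeyError(f"unknown individual {ind_id!r}")
        return row["sex"].iloc[0]

    def group_ids(self) -> set[str]:
        return set(self.census["group_id"].unique())


def _parse_date(value, table: str, row: int, col: str, na_aliases) -> dt.date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, dt.date) and not isinstance(value, dt.datetime):
        return value
    if isinstance(value, dt.datetime):
        return value.date()
    s = str(value).strip()
    if s == "" or s.lower() in na_aliases:
        return None
    try:
        return dt.date.fromisoformat(s)
    except ValueError as exc:
        raise DataValidationError(
            f"{table}.csv row {row}: column {col!r}: not an ISO-8601 date: {s!r}"
        ) from exc


def _parse_id_set(value) -> frozenset[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return frozenset()
    if isinstance(value, (set, frozenset)):
        return frozenset(value)
    s = str(value).strip()
    if not s:
        return frozenset()
    return frozenset(p for p in s.split(";") if p)


def _clean_str(value, na_aliases) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s == "" or s.lower() in na_aliases:
        return None
    return s


def validate_dataset(ds: BehaviorDataset) -> None:
    """Check every documented invariant; raise :class:`DataValidationError` on the first failure."""
    ind = ds.individuals
    ids = list(ind["id"])
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DataValidationError(f"individuals.csv: duplicate ids {dupes}")
    known = set(ids)
    for row, rec in ind.iterrows():
        if rec["sex"] not in SEXES:
            raise DataValidationError(
                f"individuals.csv row {row}: sex must be one of {SEXES}, got {rec['sex']!r}"
            )
        if (
            rec["birth_date"] is not None
            and rec["adult_from"] is not None
            and rec["birth_date"] > rec["adult_from"]
        ):
            raise DataValidationError(
                f"individuals.csv row {row}: birth_date after adult_from"
            )
        if rec["mother_id"] is not None and rec["mother_id"] not in known:
            raise DataValidationError(
                f"individuals.csv row {row}: unresolved mother_id {rec['mother_id']!r}"
            )

    for row, rec in ds.focal_scans.iterrows():
        if rec["focal_id"] not in known:
            raise DataValidationError(
                f"focal_scans.csv row {row}: unresolved focal_id {rec['focal_id']!r}"
            )
        if rec["activity"] not in ACTIVITIES:
            raise DataValidationError(
                f"focal_scans.csv row {row}: activity must be one of {ACTIVITIES}"
            )
        if rec["minute_index"] < 0:
            raise DataValidationError(
                f"focal_scans.csv row {row}: negative minute_index"
            )
        if rec["partner_id"] is not None and rec["activity"] != "social_groom":
            raise DataValidationError(
                f"focal_scans.csv row {row}: partner_id set but activity is "
                f"{rec['activity']!r}, not social_groom"
            )
        if rec["activity"] == "move" and rec["proximity_partner_ids"]:
            raise DataValidationError(
                f"focal_scans.csv row {row}: proximity partners recorded while moving"
            )
        unresolved = (set(rec["proximity_partner_ids"]) | (
            {rec["partner_id"]} if rec["partner_id"] is not None else set()
        )) - known
        if unresolved:
            raise DataValidationError(
                f"focal_scans.csv row {row}: unresolved partner ids {sorted(unresolved)}"
            )

    for row, rec in ds.agonistic.iterrows():
        if rec["winner_id"] == rec["loser_id"]:
            raise DataValidationError(
                f"agonistic.csv row {row}: winner_id equals loser_id"
            )
        for col in ("winner_id", "loser_id"):
            if rec[col] not in known:
                raise DataValidationError(
                    f"agonistic.csv row {row}: unresolved {col} {rec[col]!r}"
                )

    seen: set[tuple] = set()
    for row, rec in ds.census.iterrows():
        key = (rec["group_id"], rec["date"])
        if key in seen:
            raise DataValidationError(
                f"census.csv row {row}: duplicate date {rec['date']} for group {rec['group_id']!r}"
            )
        seen.add(key)
        unresolved = set(rec["present_ids"]) - known
        if unresolved:
            raise DataValidationError(
                f"census.csv row {row}: unresolved present ids {sorted(unresolved)}"
            )

    for row, rec in ds.births.iterrows():
        if rec["death_date"] is not None and rec["death_date"] < rec["birth_date"]:
            raise DataValidationError(
                f"births.csv row {row}: death_date before birth_date"
            )
        if rec["mother_id"] not in known:
            raise DataValidationError(
                f"births.csv row {row}: unresolved mother_id {rec['mother_id']!r}"
            )

    census_by_group: dict[str, set[str]] = {}
    for _, rec in ds.census.iterrows():
        census_by_group.setdefault(rec["group_id"], set()).update(rec["present_ids"])
    eids = [f.event_id for f in ds.fissions]
    if len(eids) != len(set(eids)):
        raise DataValidationError("fissions.csv: duplicate event_ids")
    for f in ds.fissions:
        if f.fission_date < f.subgrouping_onset:
            raise DataValidationError(
                f"fissions.csv event {f.event_id}: fission_date before subgrouping_onset"
            )
        if f.resident_male_daughter not in DAUGHTERS:
            raise DataValidationError(
                f"fissions.csv event {f.event_id}: resident_male_daughter must be A or B"
            )
        parent_members = census_by_group.get(f.parent_group_id, set())
        for ind_id, daughter in f.daughter_assignments.items():
            if daughter not in DAUGHTERS:
                raise DataValidationError(
                    f"fission_assignments.csv event {f.event_id}: daughter must be A or B"
                )
            if ind_id not in parent_members:
                raise DataValidationError(
                    f"fission_assignments.csv event {f.event_id}: {ind_id!r} never "
                    f"appears in census of parent group {f.parent_group_id!r}"
                )


def read_dataset(
    directory: str | Path, na_aliases: Iterable[str] = DEFAULT_NA_ALIASES
) -> BehaviorDataset:
    """Read and validate a dataset directory written by :func:`write_dataset`."""
    directory = Path(directory)
    na = {a.lower() for a in na_aliases}
    raw: dict[str, pd.DataFrame] = {}
    for name, cols in FILE_SCHEMAS.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise DataValidationError(f"missing input file {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise DataValidationError(f"{name}.csv: missing columns {missing}")
        raw[name] = df

    def col_dates(name, col):
        return [
            _parse_date(v, name, i, col, na)
            for i, v in enumerate(raw[name][col])
        ]

    def col_str(name, col):
        return [_clean_str(v, na) for v in raw[name][col]]

    individuals = pd.DataFrame(
        {
            "id": col_str("individuals", "id"),
            "sex": col_str("individuals", "sex"),
            "birth_date": col_dates("individuals", "birth_date"),
            "mother_id": col_str("individuals", "mother_id"),
            "adult_from": col_dates("individuals", "adult_from"),
        }
    )
    minute_raw = col_str("focal_scans", "minute_index")
    try:
        minutes = [int(v) for v in minute_raw]
    except (TypeError, ValueError) as exc:
        raise DataValidationError(f"focal_scans.csv: non-integer minute_index") from exc
    focal_scans = pd.DataFrame(
        {
            "focal_id": col_str("focal_scans", "focal_id"),
            "date": col_dates("focal_scans", "date"),
            "minute_index": minutes,
            "activity": col_str("focal_scans", "activity"),
            "partner_id": col_str("focal_scans", "partner_id"),
            "proximity_partner_ids": [
                _parse_id_set(v) for v in raw["focal_scans"]["proximity_partner_ids"]
            ],
        }
    )
    agonistic = pd.DataFrame(
        {
            "date": col_dates("agonistic", "date"),
            "winner_id": col_str("agonistic", "winner_id"),
            "loser_id": col_str("agonistic", "loser_id"),
            "group_id": col_str("agonistic", "group_id"),
        }
    )
    census = pd.DataFrame(
        {
            "date": col_dates("census", "date"),
            "group_id": col_str("census", "group_id"),
            "present_ids": [_parse_id_set(v) for v in raw["census"]["present_ids"]],
        }
    )
    births = pd.DataFrame(
        {
            "mother_id": col_str("births", "mother_id"),
            "infant_id": col_str("births", "infant_id"),
            "birth_date": col_dates("births", "birth_date"),
            "death_date": col_dates("births", "death_date"),
        }
    )
    assignments: dict[str, dict[str, str]] = {}
    for i, rec in raw["fission_assignments"].iterrows():
        eid = _clean_str(rec["event_id"], na)
        assignments.setdefault(eid, {})[_clean_str(rec["individual_id"], na)] = (
            _clean_str(rec["daughter"], na)
        )
    fissions = []
    for i, rec in raw["fissions"].iterrows():
        eid = _clean_str(rec["event_id"], na)
        fissions.append(
            FissionEvent(
                event_id=eid,
                parent_group_id=_clean_str(rec["parent_group_id"], na),
                subgrouping_onset=_parse_date(
                    rec["subgrouping_onset"], "fissions", i, "subgrouping_onset", na
                ),
                fission_date=_parse_date(
                    rec["fission_date"], "fissions", i, "fission_date", na
                ),
                daughter_assignments=assignments.get(eid, {}),
                resident_male_daughter=_clean_str(rec["resident_male_daughter"], na),
            )
        )

    ds = BehaviorDataset(
        individuals=individuals,
        focal_scans=focal_scans,
        agonistic=agonistic,
        census=census,
        births=births,
        fissions=fissions,
    )
    validate_dataset(ds)
    return ds


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, (set, frozenset)):
        return ";".join(sorted(value))
    return str(value)


def write_dataset(ds: BehaviorDataset, directory: str | Path) -> list[Path]:
    """Write a dataset to a directory of CSVs readable by :func:`read_dataset`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    tables = {
        "individuals": ds.individuals,
        "focal_scans": ds.focal_scans,
        "agonistic": ds.agonistic,
        "census": ds.census,
        "births": ds.births,
        "fissions": pd.DataFrame(
            [
                {
                    "event_id": f.event_id,
                    "parent_group_id": f.parent_group_id,
                    "subgrouping_onset": f.subgrouping_onset,
                    "fission_date": f.fission_date,
                    "resident_male_daughter": f.resident_male_daughter,
                }
                for f in ds.fissions
            ],
            columns=FILE_SCHEMAS["fissions"],
        ),
        "fission_assignments": pd.DataFrame(
            [
                {"event_id": f.event_id, "individual_id": i, "daughter": d}
                for f in ds.fissions
                for i, d in sorted(f.daughter_assignments.items())
            ],
            columns=FILE_SCHEMAS["fission_assignments"],
        ),
    }
    for name, df in tables.items():
        path = directory / f"{name}.csv"
        out = df.copy()
        for col in FILE_SCHEMAS[name]:
            if col in out.columns:
                out[col] = [_fmt(v) for v in out[col]]
        out = out[FILE_SCHEMAS[name]] if len(out) else pd.DataFrame(
            columns=FILE_SCHEMAS[name]
        )
        out.to_csv(path, index=False)
        written.append(path)
    return written


def observation_days(
    ds: BehaviorDataset, group_id: str, window: tuple[dt.date, dt.date]
) -> list[dt.date]:
    """Census dates for a group within a closed date window, ascending.

    Observation days are days on which the group was censused, not calendar
    days; gaps in monitoring simply do not appear.
    """
    if group_id not in ds.group_ids():
        raise KeyError(f"unknown group {group_id!r}")
    lo, hi = window
    days = [
        d
        for d, g in zip(ds.census["date"], ds.census["group_id"])
        if g == group_id and lo <= d <= hi
    ]
    return sorted(days)
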