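"""Maternal relatedness, reproductive state and resident-male tenure.

Relatedness is read off the recorded maternal pedigree only (paternity
unknown) and binned coarsely: mother-offspring 0.5; sisters and
grandmother-granddaughter 0.25; aunt-niece 0.125; first cousins 0.0625;
any more distant detectable maternal-line relationship 0.03125; unrelated
or unknown 0.

A female is pregnant at a date if she gives birth within the following
gestation length (176 days), lactating if she has a living infant younger
than one year, and "at risk of infanticide" if either holds.

A male gains resident status by being the sole male in a group for seven
consecutive observation days (status backdated to the first of them) and
loses it after seven consecutive observation days of complete absence.
Observation days are days with a census record, not calendar days.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import pandas as pd

from .data_io import BehaviorDataset

GESTATION_DAYS = 176
INFANT_DEPENDENCY_DAYS = 365
RESIDENCY_DAYS = 7

RELATEDNESS_BINS = {1: 0.5, 2: 0.25, 3: 0.125, 4: 0.0625}
DISTANT_RELATEDNESS = 0.03125


class Pedigree:
    """Maternal-line pedigree: each individual maps to a known mother or nothing."""

    def __init__(self, mother_of: dict[str, str | None]):
        self.mother_of = {k: v for k, v in mother_of.items() if v is not None}
        # cycle check
        for start in self.mother_of:
            seen = {start}
            cur = start
            while cur in self.mother_of:
                cur = self.mother_of[cur]
                if cur in seen:
                    raise ValueError(f"pedigree contains a cycle through {start!r}")
                seen.add(cur)

    @classmethod
    def from_dataset(cls, ds: BehaviorDataset) -> "Pedigree":
        return cls(dict(zip(ds.individuals["id"], ds.individuals["mother_id"])))

    def maternal_ancestors(self, ind: str) -> dict[str, int]:
        """All recorded maternal ancestors of ``ind`` with their depth (mother = 1)."""
        out: dict[str, int] = {}
        cur, depth = ind, 0
        while cur in self.mother_of:
            cur = self.mother_of[cur]
            depth += 1
            out[cur] = depth
        return out


def relatedness(p: Pedigree, i: str, j: str) -> float:
    """Binned maternal relatedness of a dyad; closest detectable path wins.

    The bin is keyed on the summed depths to the closest common maternal
    ancestor: 1 step (mother-offspring) = 0.5, 2 (sisters, grandmother) =
    0.25, 3 (aunt-niece) = 0.125, 4 (first cousins) = 0.0625, any longer
    detectable path = 0.03125.  Dyads with no recorded common ancestor —
    including those with unknown pedigrees — score 0.
    """
    if i == j:
        raise ValueError("relatedness is defined for two distinct individuals")
    anc_i = p.maternal_ancestors(i)
    anc_i[i] = 0
    anc_j = p.maternal_ancestors(j)
    anc_j[j] = 0
    common = set(anc_i) & set(anc_j)
    if not common:
        return 0.0
    steps = min(anc_i[a] + anc_j[a] for a in common)
    if steps == 0:
        raise ValueError("identical individuals in a dyad")
    return RELATEDNESS_BINS.get(steps, DISTANT_RELATEDNESS)


@dataclasses.dataclass
class FemaleState:
    female_id: str
    at_date: dt.date
    pregnant: bool
    lactating: bool

    @property
    def at_risk(self) -> bool:
        return self.pregnant or self.lactating


def reproductive_state(
    ds: BehaviorDataset,
    female: str,
    date: dt.date,
    gestation_days: int = GESTATION_DAYS,
    infant_dependency_days: int = INFANT_DEPENDENCY_DAYS,
) -> FemaleState:
    """Pregnancy/lactation status of a female on a given date, from birth records.

    Pregnant iff a birth falls within the gestation window strictly after
    the date; lactating iff an infant born on or before the date is younger
    than the dependency period and still alive that day.  An infant's death
    ends lactation immediately.
    """
    pregnant = False
    lactating = False
    for _, rec in ds.births.iterrows():
        if rec["mother_id"] != female:
            continue
        b = rec["birth_date"]
        if date < b <= date + dt.timedelta(days=gestation_days):
            pregnant = True
        age = (date - b).days
        if 0 <= age < infant_dependency_days:
            death = rec["death_date"]
            if death is None or death > date:
                lactating = True
    return FemaleState(female_id=female, at_date=date, pregnant=pregnant, lactating=lactating)


@dataclasses.dataclass
class ResidencyInterval:
    male_id: str
    start_date: dt.date  # first day of the qualifying sole-male run
    end_date: dt.date | None  # last observation day present; None if still resident


@dataclasses.dataclass
class ResidencyTimeline:
    group_id: str
    intervals: list[ResidencyInterval]

    def resident_on(self, date: dt.date) -> str | None:
        for iv in self.intervals:
            if iv.start_date <= date and (iv.end_date is None or date <= iv.end_date):
                return iv.male_id
        return None


def residency_timeline(
    ds: BehaviorDataset, group_id: str, residency_days: int = RESIDENCY_DAYS
) -> ResidencyTimeline:
    """Reconstruct the group's resident-male tenure from daily census records.

    Status is gained on completing ``residency_days`` consecutive
    observation days as the sole male (backdated to the first of those
    days) and lost once the male has been absent for that many consecutive
    observation days; the interval then closes on his last day present.
    """
    males = {
        rec["id"]
        for _, rec in ds.individuals.iterrows()
        if rec["sex"] == "male"
    }
    days = sorted(
        (d, ids)
        for d, g, ids in zip(
            ds.census["date"], ds.census["group_id"], ds.census["present_ids"]
        )
        if g == group_id
    )
    intervals: list[ResidencyInterval] = []
    sole_run: dict[str, dt.date] = {}  # male -> first day of current sole run
    sole_count: dict[str, int] = {}
    resident: str | None = None
    res_start: dt.date | None = None
    last_present: dt.date | None = None
    absent_count = 0

    for date, present in days:
        males_here = males & set(present)
        # residency loss
        if resident is not None:
            if resident in males_here:
                last_present = date
                absent_count = 0
            else:
                absent_count += 1
                if absent_count >= residency_days:
                    intervals.append(
                        ResidencyInterval(resident, res_start, last_present)
                    )
                    resident, res_start, last_present = None, None, None
                    absent_count = 0
        # residency gain
        if len(males_here) == 1:
            (m,) = males_here
            if m not in sole_run:
                sole_run, sole_count = {m: date}, {m: 0}
            sole_count[m] += 1
            if sole_count[m] >= residency_days and resident != m:
                if resident is not None:
                    intervals.append(
                        ResidencyInterval(resident, res_start, last_present)
                    )
                resident, res_start = m, sole_run[m]
                last_present, absent_count = date, 0
        else:
            sole_run, sole_count = {}, {}
    if resident is not None:
        # still resident when the records end
        intervals.append(ResidencyInterval(resident, res_start, None))
    return ResidencyTimeline(group_id=group_id, intervals=intervals)


def female_state_table(
    ds: BehaviorDataset,
    females: list[str],
    at_date: dt.date,
    fission_id: str = "",
    gestation_days: int = GESTATION_DAYS,
    infant_dependency_days: int = INFANT_DEPENDENCY_DAYS,
) -> pd.DataFrame:
    rows = []
    for f in females:
        st = reproductive_state(
            ds, f, at_date, gestation_days, infant_dependency_days
        )
        rows.append(
            {
                "female_id": f,
                "fission_id": fission_id,
                "pregnant": int(st.pregnant),
                "lactating": int(st.lactating),
                "at_risk": int(st.at_risk),
            }
        )
    return pd.DataFrame(
        rows, columns=["female_id", "fission_id", "pregnant", "lactating", "at_risk"]
    )
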