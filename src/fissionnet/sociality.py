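"""Dyadic sociality indices (DSI) and tie-consistency classification.

The DSI is a composite affiliative-tie strength for a female pair,
combining grooming and resting-within-1-m rates normalized by the medians
of all dyads in the same group and annual window:

    DSI = 1/2 * (G_ij / G_med) + 1/4 * (R_ij / R_med) + 1/4 * (R_ji / R_med)

where G_ij is the dyad's grooming rate over the pair's combined focal
observation time, and R_ij (R_ji) is the rate at which i (j) was recorded
resting within 1 m of the other during her own focal time.  The two
proximity terms are kept separate because they are not symmetrical
measures.  When only one member of the dyad contributed focal data, the
single available proximity term gets weight 1/2 instead of 1/4.  A DSI > 1
means the dyad affiliated more than the median dyad of its group.

Ties are classified over the two annual windows before the onset of
subgrouping: consistently strong (> threshold both years), consistently
weak, or inconsistent (the reference class in downstream models).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from itertools import combinations

import numpy as np
import pandas as pd

from .data_io import BehaviorDataset, FissionEvent

DateWindow = tuple[dt.date, dt.date]

DSI_THRESHOLD = 1.0
WINDOW_DAYS = 365


class ZeroMedianError(ValueError):
    """A group-window median rate is zero, so the DSI ratio is undefined."""


class UnobservedDyadError(ValueError):
    """Neither member of the dyad has focal observation time in the window."""


def year_windows(onset: dt.date) -> tuple[DateWindow, DateWindow]:
    """The two closed 365-day annual windows preceding the subgrouping onset.

    Window 1 ends the day before onset; window 2 is the year before that
    (days 366-730 before onset).
    """
    y1 = (onset - dt.timedelta(days=WINDOW_DAYS), onset - dt.timedelta(days=1))
    y2 = (
        onset - dt.timedelta(days=2 * WINDOW_DAYS),
        onset - dt.timedelta(days=WINDOW_DAYS + 1),
    )
    return y1, y2


@dataclasses.dataclass
class DyadRates:
    """Raw interaction rates for one dyad in one window (all rates per focal minute)."""

    i_id: str
    j_id: str
    G_ij: float
    R_ij: float | None
    R_ji: float | None
    focal_minutes_i: float
    focal_minutes_j: float

    @property
    def single_focal(self) -> bool:
        return (self.focal_minutes_i == 0) != (self.focal_minutes_j == 0)


@dataclasses.dataclass
class GroupMedians:
    group_id: str
    window: DateWindow
    G_med: float
    R_med: float


@dataclasses.dataclass
class WindowCounts:
    """Aggregated focal-scan counts for one window (shared by all dyads)."""

    focal_minutes: dict[str, int]
    groom_minutes: dict[frozenset, int]  # unordered pair -> minutes, either focal
    rest_prox: dict[tuple[str, str], int]  # (focal, partner) -> scan count

    def minutes(self, ind: str) -> int:
        return self.focal_minutes.get(ind, 0)


def aggregate_window(ds: BehaviorDataset, window: DateWindow) -> WindowCounts:
    """One pass over the focal scans in a window, producing all per-dyad counts."""
    lo, hi = window
    scans = ds.focal_scans
    dates = scans["date"].to_numpy()
    mask = np.array([(lo <= d <= hi) for d in dates], dtype=bool)
    sub = scans.loc[mask]

    focal_minutes: dict[str, int] = {}
    groom: dict[frozenset, int] = {}
    rest: dict[tuple[str, str], int] = {}
    for focal, activity, partner, prox in zip(
        sub["focal_id"], sub["activity"], sub["partner_id"], sub["proximity_partner_ids"]
    ):
        focal_minutes[focal] = focal_minutes.get(focal, 0) + 1
        if activity == "social_groom" and partner is not None:
            key = frozenset((focal, partner))
            groom[key] = groom.get(key, 0) + 1
        elif activity == "rest":
            # only resting-within-1-m proximity feeds the DSI
            for p in prox:
                rest[(focal, p)] = rest.get((focal, p), 0) + 1
    return WindowCounts(focal_minutes=focal_minutes, groom_minutes=groom, rest_prox=rest)


def dyad_rates_from_counts(counts: WindowCounts, i: str, j: str) -> DyadRates:
    mi = counts.minutes(i)
    mj = counts.minutes(j)
    if mi == 0 and mj == 0:
        raise UnobservedDyadError(
            f"dyad ({i}, {j}): neither member has focal minutes in the window"
        )
    g = counts.groom_minutes.get(frozenset((i, j)), 0)
    return DyadRates(
        i_id=i,
        j_id=j,
        G_ij=g / (mi + mj),
        R_ij=(counts.rest_prox.get((i, j), 0) / mi) if mi > 0 else None,
        R_ji=(counts.rest_prox.get((j, i), 0) / mj) if mj > 0 else None,
        focal_minutes_i=mi,
        focal_minutes_j=mj,
    )


def dyad_rates(ds: BehaviorDataset, i: str, j: str, window: DateWindow) -> DyadRates:
    """Grooming and proximity rates for one dyad in one annual window.

    The grooming denominator is the pair's combined focal minutes; each
    proximity rate uses its own member's focal minutes.  When one member has
    no focal data the dyad is single-focal and only the observed member's
    rates are defined.
    """
    if i == j:
        raise ValueError("a dyad needs two distinct individuals")
    return dyad_rates_from_counts(aggregate_window(ds, window), i, j)


def group_medians(
    rates: list[DyadRates], group_id: str = "", window: DateWindow | None = None
) -> GroupMedians:
    """Median grooming and (pooled directed) proximity rates over the included dyads."""
    g = [r.G_ij for r in rates]
    pooled_r = [x for r in rates for x in (r.R_ij, r.R_ji) if x is not None]
    return GroupMedians(
        group_id=group_id,
        window=window,
        G_med=float(np.median(g)) if g else 0.0,
        R_med=float(np.median(pooled_r)) if pooled_r else 0.0,
    )


def compute_dsi(
    rates: DyadRates, med: GroupMedians, zero_median_fallback: bool = False
) -> float:
    """The dyadic sociality index for one dyad given its group-window medians.

    By default a zero median is a hard error (the ratio is undefined); with
    ``zero_median_fallback`` the undefined term is dropped and the remaining
    weights renormalized to sum to 1.
    """
    single = rates.single_focal
    g_w = 0.5
    if single:
        r_terms = [r for r in (rates.R_ij, rates.R_ji) if r is not None]
        r_weights = [0.5]
    else:
        r_terms = [rates.R_ij, rates.R_ji]
        r_weights = [0.25, 0.25]

    terms: list[tuple[float, float]] = []  # (weight, ratio)
    if med.G_med > 0:
        terms.append((g_w, rates.G_ij / med.G_med))
    elif not zero_median_fallback:
        raise ZeroMedianError(
            f"group {med.group_id!r}: median grooming rate is zero"
        )
    if med.R_med > 0:
        terms.extend((w, r / med.R_med) for w, r in zip(r_weights, r_terms))
    elif not zero_median_fallback:
        raise ZeroMedianError(
            f"group {med.group_id!r}: median proximity rate is zero"
        )
    if not terms:
        raise ZeroMedianError(
            f"group {med.group_id!r}: both medians are zero; DSI undefined"
        )
    wsum = sum(w for w, _ in terms)
    return sum(w * r for w, r in terms) / wsum


def classify_consistency(
    dsi_y1: float, dsi_y2: float, threshold: float = DSI_THRESHOLD
) -> tuple[str, int, int]:
    """Tie-consistency class over the two annual windows, plus model dummies.

    Strong requires DSI strictly above the threshold in both years;
    exactly one year above is inconsistent; everything else (including
    exact ties at the threshold) is weak.  Returns
    ``(label, dummy_strong, dummy_weak)``; inconsistent is the reference
    class with both dummies 0.
    """
    hi1, hi2 = dsi_y1 > threshold, dsi_y2 > threshold
    if hi1 and hi2:
        return "consistently_strong", 1, 0
    if hi1 != hi2:
        return "inconsistent", 0, 0
    return "consistently_weak", 0, 1


def _adult_coverage(adult_from: dt.date | None, window: DateWindow) -> float:
    if adult_from is None:
        return 0.0
    lo, hi = window
    start = max(adult_from, lo)
    if start > hi:
        return 0.0
    return ((hi - start).days + 1) / ((hi - lo).days + 1)


def eligible_females(
    ds: BehaviorDataset,
    fission: FissionEvent,
    window: DateWindow | None = None,
) -> set[str]:
    """Parous females of the parent group followable for at least half the window.

    A female qualifies if she appears in the parent group's census during
    the window and her adult (parous, hence followable) tenure covers at
    least 50% of it — exclusion applies only when she was followed for
    strictly less than half of the year.
    """
    if window is None:
        window = year_windows(fission.subgrouping_onset)[0]
    lo, hi = window
    present: set[str] = set()
    for d, g, ids in zip(
        ds.census["date"], ds.census["group_id"], ds.census["present_ids"]
    ):
        if g == fission.parent_group_id and lo <= d <= hi:
            present.update(ids)
    out = set()
    for _, rec in ds.individuals.iterrows():
        if rec["sex"] != "female" or rec["id"] not in present:
            continue
        if _adult_coverage(rec["adult_from"], window) >= 0.5:
            out.add(rec["id"])
    return out


def sociality_table(
    ds: BehaviorDataset,
    fission: FissionEvent,
    threshold: float = DSI_THRESHOLD,
    zero_median_fallback: bool = False,
) -> pd.DataFrame:
    """Per-dyad DSI values for both pre-fission years plus consistency class.

    Eligibility is decided on the year immediately before subgrouping onset;
    the same dyads are then indexed in the previous year under relaxed
    rules, so a female with no focal data that year contributes through her
    partners' follows (single-focal variant).
    """
    y1, y2 = year_windows(fission.subgrouping_onset)
    females = sorted(eligible_females(ds, fission, y1))
    dyads = list(combinations(females, 2))

    rows = []
    per_year: dict[str, dict] = {}
    for label, window in (("y1", y1), ("y2", y2)):
        counts = aggregate_window(ds, window)
        rates = {d: dyad_rates_from_counts(counts, *d) for d in dyads}
        med = group_medians(
            list(rates.values()), group_id=fission.parent_group_id, window=window
        )
        per_year[label] = {
            d: compute_dsi(r, med, zero_median_fallback=zero_median_fallback)
            for d, r in rates.items()
        }
    for i, j in dyads:
        d1 = per_year["y1"][(i, j)]
        d2 = per_year["y2"][(i, j)]
        label, s, w = classify_consistency(d1, d2, threshold)
        rows.append(
            {
                "i_id": i,
                "j_id": j,
                "fission_id": fission.event_id,
                "dsi_y1": d1,
                "dsi_y2": d2,
                "consistency": label,
                "dummy_strong": s,
                "dummy_weak": w,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "i_id",
            "j_id",
            "fission_id",
            "dsi_y1",
            "dsi_y2",
            "consistency",
            "dummy_strong",
            "dummy_weak",
        ],
    )


def compute_male_dsi(
    rates: DyadRates, med: GroupMedians, zero_median_fallback: bool = False
) -> float:
    """Female-male DSI: grooming and resting in proximity weighted equally.

    Males are not focal subjects, so the dyad is indexed from the female's
    follows alone and the grooming and proximity terms each carry weight
    1/2; medians must come from all female-resident-male dyads of the
    group-window (see :func:`male_dsi_table`).
    """
    terms: list[tuple[float, float]] = []
    if med.G_med > 0:
        terms.append((0.5, rates.G_ij / med.G_med))
    elif not zero_median_fallback:
        raise ZeroMedianError(
            f"group {med.group_id!r}: median female-male grooming rate is zero"
        )
    r = rates.R_ij if rates.R_ij is not None else rates.R_ji
    if med.R_med > 0:
        terms.append((0.5, r / med.R_med))
    elif not zero_median_fallback:
        raise ZeroMedianError(
            f"group {med.group_id!r}: median female-male proximity rate is zero"
        )
    if not terms:
        raise ZeroMedianError(
            f"group {med.group_id!r}: both female-male medians are zero"
        )
    wsum = sum(w for w, _ in terms)
    return sum(w * r_ for w, r_ in terms) / wsum


def male_dsi_table(
    ds: BehaviorDataset,
    fission: FissionEvent,
    resident_male: str,
    females: list[str] | None = None,
    zero_median_fallback: bool = False,
) -> pd.DataFrame:
    """Each eligible female's DSI with the resident male in the pre-fission year.

    The female-male grooming rate uses the female's focal minutes as
    denominator (the male contributes no follows), and medians are taken
    across all female-resident-male dyads of the pre-fission group.
    """
    y1, _ = year_windows(fission.subgrouping_onset)
    if females is None:
        females = sorted(eligible_females(ds, fission, y1))
    counts = aggregate_window(ds, y1)
    rates = {}
    for f in females:
        mf = counts.minutes(f)
        if mf == 0:
            raise UnobservedDyadError(
                f"female {f!r} has no focal minutes in the pre-fission year"
            )
        rates[f] = DyadRates(
            i_id=f,
            j_id=resident_male,
            G_ij=counts.groom_minutes.get(frozenset((f, resident_male)), 0) / mf,
            R_ij=counts.rest_prox.get((f, resident_male), 0) / mf,
            R_ji=None,
            focal_minutes_i=mf,
            focal_minutes_j=0,
        )
    g_med = float(np.median([r.G_ij for r in rates.values()])) if rates else 0.0
    r_med = float(np.median([r.R_ij for r in rates.values()])) if rates else 0.0
    med = GroupMedians(
        group_id=fission.parent_group_id, window=y1, G_med=g_med, R_med=r_med
    )
    rows = [
        {
            "female_id": f,
            "fission_id": fission.event_id,
            "dsi_with_resident": compute_male_dsi(
                r, med, zero_median_fallback=zero_median_fallback
            ),
        }
        for f, r in rates.items()
    ]
    return pd.DataFrame(
        rows, columns=["female_id", "fission_id", "dsi_with_resident"]
    )
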