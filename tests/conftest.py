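"""Shared fixtures: a hand-computable 4-female dataset and small simulations.

The toy dataset is built so that every downstream quantity is exact by
hand: one strongly bonded dyad (A, B) and five near-median dyads, a
perfectly transitive dominance order A > B > C > D, one pregnant and one
lactating female (both assigned to the resident male's daughter group),
and a mother-daughter pair for the pedigree.
"""

import datetime as dt

import pandas as pd
import pytest

from fissionnet.data_io import BehaviorDataset, FissionEvent

ONSET = dt.date(2020, 3, 1)
FISSION_DATE = dt.date(2020, 5, 1)
Y1 = (dt.date(2019, 3, 2), dt.date(2020, 2, 29))
Y2 = (dt.date(2018, 3, 2), dt.date(2019, 3, 1))

FEMALES = ["A", "B", "C", "D"]
MALE = "M"

# per-window scan budget is exactly 100 minutes per female
GROOM = {  # focal -> partner -> scans per window
    "A": {"B": 10, "C": 1, "D": 1, MALE: 4},
    "B": {"A": 10, "C": 1, "D": 1, MALE: 2},
    "C": {"A": 1, "B": 1, "D": 1, MALE: 2},
    "D": {"A": 1, "B": 1, "C": 1, MALE: 1},
}
PROX = {  # focal -> partner -> resting-within-1-m scans per window
    "A": {"B": 5, "C": 2, "D": 2, MALE: 4},
    "B": {"A": 5, "C": 2, "D": 2, MALE: 2},
    "C": {"A": 2, "B": 2, "D": 2, MALE: 2},
    "D": {"A": 2, "B": 2, "C": 2, MALE: 1},
}
FOCAL_MINUTES = 100

# hand-computed expectations (see test modules)
TOY_EXPECT = {
    "G_AB": 20 / 200,
    "R_AB": 5 / 100,
    "G_med": 0.01,
    "R_med": 0.02,
    "dsi_AB": 6.25,  # 0.5*(0.1/0.01) + 0.25*2.5 + 0.25*2.5
    "dsi_other": 1.0,
    "male_dsi": {"A": 2.0, "B": 1.0, "C": 1.0, "D": 0.5},
    "order": ["A", "B", "C", "D"],
    "persistence_rate": 2 / 6,
}


def _scan_rows():
    rows = []
    for lo, _hi in (Y1, Y2):
        for focal in FEMALES:
            events = []
            for partner, k in GROOM[focal].items():
                events.extend(("social_groom", partner, frozenset()) for _ in range(k))
            for partner, k in PROX[focal].items():
                events.extend(("rest", None, frozenset((partner,))) for _ in range(k))
            while len(events) < FOCAL_MINUTES:
                events.append(("rest", None, frozenset()))
            for day, (act, partner, prox) in enumerate(events):
                rows.append(
                    {
                        "focal_id": focal,
                        "date": lo + dt.timedelta(days=day * 3),
                        "minute_index": 0,
                        "activity": act,
                        "partner_id": partner,
                        "proximity_partner_ids": prox,
                    }
                )
    return rows


def make_toy_dataset() -> BehaviorDataset:
    individuals = [
        {"id": "A", "sex": "female", "birth_date": dt.date(2008, 1, 1),
         "mother_id": None, "adult_from": dt.date(2015, 1, 1)},
        {"id": "B", "sex": "female", "birth_date": dt.date(2010, 1, 1),
         "mother_id": "A", "adult_from": dt.date(2017, 1, 1)},
        {"id": "C", "sex": "female", "birth_date": dt.date(2009, 1, 1),
         "mother_id": None, "adult_from": dt.date(2016, 1, 1)},
        {"id": "D", "sex": "female", "birth_date": dt.date(2009, 6, 1),
         "mother_id": None, "adult_from": dt.date(2016, 6, 1)},
        {"id": MALE, "sex": "male", "birth_date": None, "mother_id": None,
         "adult_from": None},
        {"id": "Ainf", "sex": "female", "birth_date": dt.date(2020, 8, 1),
         "mother_id": "A", "adult_from": None},
        {"id": "Binf", "sex": "male", "birth_date": dt.date(2020, 1, 1),
         "mother_id": "B", "adult_from": None},
        {"id": "Cinf", "sex": "female", "birth_date": dt.date(2020, 2, 1),
         "mother_id": "C", "adult_from": None},
        {"id": "Dinf", "sex": "male", "birth_date": dt.date(2018, 1, 1),
         "mother_id": "D", "adult_from": None},
    ]
    births = [
        # A: pregnant at fission (birth 92 days later)
        {"mother_id": "A", "infant_id": "Ainf", "birth_date": dt.date(2020, 8, 1),
         "death_date": None},
        # B: dependent infant, alive
        {"mother_id": "B", "infant_id": "Binf", "birth_date": dt.date(2020, 1, 1),
         "death_date": None},
        # C: infant died before the fission -> not lactating
        {"mother_id": "C", "infant_id": "Cinf", "birth_date": dt.date(2020, 2, 1),
         "death_date": dt.date(2020, 4, 1)},
        # D: old independent infant
        {"mother_id": "D", "infant_id": "Dinf", "birth_date": dt.date(2018, 1, 1),
         "death_date": None},
    ]
    census = []
    day = dt.date(2018, 3, 1)
    while day <= dt.date(2020, 6, 1):
        census.append(
            {"date": day, "group_id": "G",
             "present_ids": frozenset(FEMALES + [MALE])}
        )
        day += dt.timedelta(days=1)
    agonistic = []

    def fight(w, l, n, date):
        for _ in range(n):
            agonistic.append(
                {"date": date, "winner_id": w, "loser_id": l, "group_id": "G"}
            )

    fight("A", "B", 2, dt.date(2020, 1, 15))
    fight("B", "C", 2, dt.date(2020, 2, 15))
    fight("C", "D", 2, dt.date(2020, 3, 15))
    fight("A", "C", 1, dt.date(2020, 4, 1))
    fight("A", "D", 1, dt.date(2020, 4, 2))
    fight("B", "D", 1, dt.date(2020, 4, 3))
    # excluded: after fission completion, and from an earlier calendar year
    fight("D", "A", 3, dt.date(2020, 5, 15))
    fight("D", "A", 3, dt.date(2019, 6, 1))

    fission = FissionEvent(
        event_id="F1",
        parent_group_id="G",
        subgrouping_onset=ONSET,
        fission_date=FISSION_DATE,
        daughter_assignments={"A": "A", "B": "A", "C": "B", "D": "B", MALE: "A"},
        resident_male_daughter="A",
    )
    return BehaviorDataset(
        individuals=pd.DataFrame(individuals),
        focal_scans=pd.DataFrame(_scan_rows()),
        agonistic=pd.DataFrame(agonistic),
        census=pd.DataFrame(census),
        births=pd.DataFrame(births),
        fissions=[fission],
    )


@pytest.fixture(scope="session")
def toy_dataset() -> BehaviorDataset:
    return make_toy_dataset()


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured simulated population with fission outcomes."""
    from fissionnet.synthetic_data import SimConfig, simulate_fission, simulate_population

    cfg = SimConfig(
        seed=11, n_groups=3, females_per_group=10, focal_minutes_per_female_year=1000
    )
    ds, truth = simulate_population(cfg)
    ds.fissions = simulate_fission(cfg, truth)
    return cfg, ds, truth
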