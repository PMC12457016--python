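"""Maternal relatedness bins, reproductive state and resident-male tenure."""

import datetime as dt
from itertools import combinations

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fissionnet.attributes import (
    Pedigree,
    relatedness,
    reproductive_state,
    residency_timeline,
)
from fissionnet.data_io import BehaviorDataset

from conftest import FISSION_DATE, make_toy_dataset

# A three-generation matriline:
#   gma -> (mo, aunt); mo -> (ego, sis); aunt -> cousin; cousin -> cousins_kid
PED = Pedigree(
    {
        "mo": "gma",
        "aunt": "gma",
        "ego": "mo",
        "sis": "mo",
        "cousin": "aunt",
        "cousins_kid": "cousin",
        "stranger": None,
    }
)


class TestRelatedness:
    @pytest.mark.parametrize(
        "i, j, expected",
        [
            ("ego", "mo", 0.5),
            ("ego", "sis", 0.25),
            ("ego", "gma", 0.25),
            ("ego", "aunt", 0.125),
            ("ego", "cousin", 0.0625),
            ("ego", "cousins_kid", 0.03125),  # more distant, still detectable
            ("ego", "stranger", 0.0),
        ],
    )
    def test_binned_coefficients(self, i, j, expected):
        assert relatedness(PED, i, j) == expected

    def test_unknown_pedigrees_score_zero(self):
        p = Pedigree({"x": None, "y": None})
        assert relatedness(p, "x", "y") == 0.0

    def test_symmetry_over_all_dyads(self):
        members = ["gma", "mo", "aunt", "ego", "sis", "cousin", "cousins_kid"]
        for i, j in combinations(members, 2):
            assert relatedness(PED, i, j) == relatedness(PED, j, i)

    def test_values_come_from_the_finite_bin_set(self):
        allowed = {0.0, 0.03125, 0.0625, 0.125, 0.25, 0.5}
        members = ["gma", "mo", "aunt", "ego", "sis", "cousin", "cousins_kid",
                   "stranger"]
        for i, j in combinations(members, 2):
            assert relatedness(PED, i, j) in allowed

    def test_closest_path_wins(self):
        # a and b are sisters AND b is also a's recorded daughter is
        # impossible; instead: c relates to a both as grandchild (0.25 via
        # chain) and more distantly through another line — recorded links
        # only allow one chain each, so check min-steps explicitly
        p = Pedigree({"b": "a", "c": "b"})
        assert relatedness(p, "a", "c") == 0.25

    def test_cycle_detection(self):
        with pytest.raises(ValueError, match="cycle"):
            Pedigree({"a": "b", "b": "a"})

    def test_self_dyad_rejected(self):
        with pytest.raises(ValueError):
            relatedness(PED, "ego", "ego")


class TestReproductiveState:
    def test_birth_within_gestation_window_means_pregnant(self, toy_dataset):
        st_ = reproductive_state(toy_dataset, "A", FISSION_DATE)
        assert st_.pregnant and not st_.lactating and st_.at_risk

    def test_dependent_living_infant_means_lactating(self, toy_dataset):
        st_ = reproductive_state(toy_dataset, "B", FISSION_DATE)
        assert st_.lactating and not st_.pregnant and st_.at_risk

    def test_infant_death_ends_lactation(self, toy_dataset):
        st_ = reproductive_state(toy_dataset, "C", FISSION_DATE)
        assert not st_.lactating and not st_.at_risk

    def test_infant_older_than_a_year_not_dependent(self, toy_dataset):
        st_ = reproductive_state(toy_dataset, "D", FISSION_DATE)
        assert not st_.lactating and not st_.at_risk

    def test_birth_on_the_fission_date_counts_as_lactating_not_pregnant(self):
        ds = make_toy_dataset()
        ds.births.loc[ds.births["mother_id"] == "A", "birth_date"] = FISSION_DATE
        st_ = reproductive_state(ds, "A", FISSION_DATE)
        assert st_.lactating and not st_.pregnant

    def test_birth_just_past_gestation_horizon_not_pregnant(self):
        ds = make_toy_dataset()
        ds.births.loc[ds.births["mother_id"] == "A", "birth_date"] = (
            FISSION_DATE + dt.timedelta(days=177)
        )
        assert not reproductive_state(ds, "A", FISSION_DATE).pregnant

    @given(offset=st.integers(-400, 400))
    @settings(max_examples=40, deadline=None)
    def test_at_risk_is_pregnant_or_lactating(self, offset):
        ds = make_toy_dataset()
        ds.births.loc[ds.births["mother_id"] == "A", "birth_date"] = (
            FISSION_DATE + dt.timedelta(days=offset)
        )
        st_ = reproductive_state(ds, "A", FISSION_DATE)
        assert st_.at_risk == (st_.pregnant or st_.lactating)


def _census_dataset(days):
    """A minimal dataset whose census is the given (date, present set) list."""
    ids = sorted({i for _, present in days for i in present})
    individuals = pd.DataFrame(
        [
            {"id": i, "sex": "male" if i.startswith("m") else "female",
             "birth_date": None, "mother_id": None, "adult_from": None}
            for i in ids
        ]
    )
    census = pd.DataFrame(
        [{"date": d, "group_id": "G", "present_ids": frozenset(p)} for d, p in days]
    )
    empty_scans = pd.DataFrame(
        columns=["focal_id", "date", "minute_index", "activity", "partner_id",
                 "proximity_partner_ids"]
    )
    return BehaviorDataset(
        individuals=individuals,
        focal_scans=empty_scans,
        agonistic=pd.DataFrame(columns=["date", "winner_id", "loser_id", "group_id"]),
        census=census,
        births=pd.DataFrame(columns=["mother_id", "infant_id", "birth_date",
                                     "death_date"]),
        fissions=[],
    )


def _days(spec):
    """spec: list of male-presence sets; observation days are every 2nd calendar day."""
    base = dt.date(2020, 1, 1)
    return [
        (base + dt.timedelta(days=2 * k), {"f"} | males)
        for k, males in enumerate(spec)
    ]


class TestResidency:
    def test_seven_sole_observation_days_grant_backdated_residency(self):
        ds = _census_dataset(_days([{"m1"}] * 7 + [{"m1"}] * 3))
        tl = residency_timeline(ds, "G")
        assert len(tl.intervals) == 1
        iv = tl.intervals[0]
        assert iv.male_id == "m1"
        assert iv.start_date == dt.date(2020, 1, 1)  # backdated to run start
        assert iv.end_date is None

    def test_six_sole_days_then_second_male_never_resident(self):
        ds = _census_dataset(_days([{"m1"}] * 6 + [{"m1", "m2"}] + [{"m1"}] * 3))
        tl = residency_timeline(ds, "G")
        assert tl.intervals == []

    def test_seven_absent_observation_days_close_the_interval(self):
        spec = [{"m1"}] * 10 + [set()] * 7 + [{"m1"}] * 2
        ds = _census_dataset(_days(spec))
        tl = residency_timeline(ds, "G")
        assert len(tl.intervals) == 1
        iv = tl.intervals[0]
        assert iv.end_date == dt.date(2020, 1, 1) + dt.timedelta(days=2 * 9)
        # after losing status he is no longer resident
        assert tl.resident_on(dt.date(2020, 3, 1)) is None

    def test_observation_days_not_calendar_days(self):
        # 7 sole observation days spread over 13 calendar days still qualify
        ds = _census_dataset(_days([{"m1"}] * 7))
        tl = residency_timeline(ds, "G")
        assert len(tl.intervals) == 1
        assert (
            tl.resident_on(dt.date(2020, 1, 13)) == "m1"
        )  # 7th observation day

    def test_succession_yields_non_overlapping_intervals(self):
        spec = [{"m1"}] * 10 + [set()] * 3 + [{"m2"}] * 10
        ds = _census_dataset(_days(spec))
        tl = residency_timeline(ds, "G")
        assert [iv.male_id for iv in tl.intervals] == ["m1", "m2"]
        a, b = tl.intervals
        assert a.end_date < b.start_date

    def test_toy_dataset_male_is_resident_throughout(self, toy_dataset):
        tl = residency_timeline(toy_dataset, "G")
        assert tl.resident_on(FISSION_DATE) == "M"
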