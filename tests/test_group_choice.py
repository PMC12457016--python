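"""Conditional logit of daughter-group choice: closed forms and invariances."""

import numpy as np
import pandas as pd
import pytest

from fissionnet.attributes import female_state_table
from fissionnet.group_choice import (
    ModelFitError,
    build_choice_datasets,
    conditional_logit_loglik,
    fit_conditional_logit,
    predicted_choice_probability,
)
from fissionnet.sociality import male_dsi_table

from conftest import FISSION_DATE


def paired_binary_choices(k, n):
    """n choosers between a binary-attribute alternative and a bare one; k pick it."""
    rows = []
    for c in range(n):
        chosen_a = c < k
        rows.append({"choice_id": f"c{c}", "chosen": int(chosen_a), "x": 1.0})
        rows.append({"choice_id": f"c{c}", "chosen": int(not chosen_a), "x": 0.0})
    return pd.DataFrame(rows)


class TestClosedForm:
    @pytest.mark.parametrize("k, n", [(3, 10), (7, 10), (25, 40), (1, 5)])
    def test_mle_odds_ratio_is_k_over_n_minus_k(self, k, n):
        fit = fit_conditional_logit(paired_binary_choices(k, n), terms=("x",))
        assert np.exp(fit.coef("x")) == pytest.approx(k / (n - k), rel=1e-8)

    def test_even_split_gives_zero_coefficient(self):
        fit = fit_conditional_logit(paired_binary_choices(10, 20), terms=("x",))
        assert fit.coef("x") == pytest.approx(0.0, abs=1e-10)
        assert np.exp(fit.coef("x")) == pytest.approx(1.0)

    def test_all_one_way_is_separation(self):
        with pytest.raises(ModelFitError):
            fit_conditional_logit(paired_binary_choices(10, 10), terms=("x",))


class TestLikelihoodProperties:
    def _sim(self, rng, n=200, beta=(1.0, -0.5)):
        rows = []
        for c in range(n):
            x = rng.normal(size=(2, 2))
            eta = x @ np.array(beta)
            p = np.exp(eta - eta.max())
            p /= p.sum()
            ch = rng.choice(2, p=p)
            for a in range(2):
                rows.append(
                    {"choice_id": f"c{c:03d}", "chosen": int(a == ch),
                     "u": x[a, 0], "v": x[a, 1]}
                )
        return pd.DataFrame(rows)

    def test_gradient_vanishes_at_reported_maximum(self):
        rng = np.random.default_rng(1)
        df = self._sim(rng)
        fit = fit_conditional_logit(df, terms=("u", "v"))
        b = fit.table["coef"].to_numpy()
        eps = 1e-5
        ll0 = conditional_logit_loglik(b, df, terms=("u", "v"))
        for k in range(2):
            d = np.zeros(2)
            d[k] = eps
            assert conditional_logit_loglik(b + d, df, terms=("u", "v")) <= ll0 + 1e-9
            assert conditional_logit_loglik(b - d, df, terms=("u", "v")) <= ll0 + 1e-9

    def test_alternative_invariant_covariate_is_degenerate(self):
        rng = np.random.default_rng(2)
        df = self._sim(rng)
        df["const_within"] = np.repeat(
            rng.normal(size=len(df) // 2), 2
        )  # same value in both rows of each choice
        with pytest.raises(ModelFitError, match="alternative-invariant|singular"):
            fit_conditional_logit(df, terms=("u", "const_within"))

    def test_matches_grid_oracle_on_small_fixture(self):
        rng = np.random.default_rng(3)
        df = self._sim(rng, n=12)
        fit = fit_conditional_logit(df, terms=("u", "v"))
        # dense iteratively refined grid over the same likelihood, evaluated
        # directly from its definition (softmax over each pair of rows)
        X = df[["u", "v"]].to_numpy().reshape(12, 2, 2)
        chosen = df["chosen"].to_numpy().reshape(12, 2).argmax(axis=1)

        def ll(b):
            eta = X @ b
            return float(
                (eta[np.arange(12), chosen] - np.logaddexp(eta[:, 0], eta[:, 1])).sum()
            )

        center = np.zeros(2)
        width = 4.0
        for _ in range(7):
            axes = [np.linspace(c - width, c + width, 41) for c in center]
            U, V = np.meshgrid(*axes, indexing="ij")
            B = np.column_stack([U.ravel(), V.ravel()])
            lls = np.array([ll(b) for b in B])
            center = B[np.argmax(lls)]
            width = width * 2.2 / 40
        assert np.allclose(fit.table["coef"].to_numpy(), center, atol=1e-3)


class TestPrediction:
    def test_zero_coefficients_give_even_odds(self):
        fit = fit_conditional_logit(paired_binary_choices(10, 20), terms=("x",))
        p = predicted_choice_probability(fit, [[1.0], [0.0]])
        assert np.allclose(p, [0.5, 0.5], atol=1e-8)

    def test_log3_coefficient_gives_three_quarters(self):
        fit = fit_conditional_logit(paired_binary_choices(15, 20), terms=("x",))
        # fitted OR is exactly 3 here: 15/5
        p = predicted_choice_probability(fit, [[1.0], [0.0]])
        assert p[0] == pytest.approx(0.75, rel=1e-6)

    def test_probabilities_sum_to_one(self):
        fit = fit_conditional_logit(paired_binary_choices(5, 20), terms=("x",))
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = predicted_choice_probability(fit, rng.normal(size=(2, 1)))
            assert p.sum() == pytest.approx(1.0)
            assert (p >= 0).all()


class TestDatasetConstruction:
    def test_two_rows_per_female_split_by_risk(self, toy_dataset):
        fission = toy_dataset.fissions[0]
        females = ["A", "B", "C", "D"]
        states = female_state_table(
            toy_dataset, females, FISSION_DATE, fission_id=fission.event_id
        )
        md = male_dsi_table(toy_dataset, fission, "M", females)
        at_risk, not_at_risk = build_choice_datasets(states, md, [fission])
        assert len(at_risk) == 4  # A and B, two rows each
        assert len(not_at_risk) == 4  # C and D
        for df in (at_risk, not_at_risk):
            counts = df.groupby("choice_id")["chosen"].agg(["size", "sum"])
            assert (counts["size"] == 2).all()
            assert (counts["sum"] == 1).all()
            # the resident male is in exactly one alternative per choice
            assert (df.groupby("choice_id")["resident_present"].sum() == 1).all()

    def test_dsi_constant_within_female_interaction_varies(self, toy_dataset):
        fission = toy_dataset.fissions[0]
        females = ["A", "B", "C", "D"]
        states = female_state_table(
            toy_dataset, females, FISSION_DATE, fission_id=fission.event_id
        )
        md = male_dsi_table(toy_dataset, fission, "M", females)
        at_risk, _ = build_choice_datasets(states, md, [fission])
        a_rows = at_risk[at_risk["female_id"] == "A"]
        assert a_rows["dsi_with_resident"].nunique() == 1
        assert set(a_rows["resident_x_dsi"]) == {0.0, 2.0}

    def test_missing_assignment_is_an_error(self, toy_dataset):
        fission = toy_dataset.fissions[0]
        states = female_state_table(
            toy_dataset, ["A", "B", "C", "D"], FISSION_DATE,
            fission_id=fission.event_id,
        )
        extra = pd.concat(
            [states, pd.DataFrame([{"female_id": "Z", "fission_id": "F1",
                                    "pregnant": 0, "lactating": 0, "at_risk": 0}])],
            ignore_index=True,
        )
        md = male_dsi_table(toy_dataset, fission, "M", ["A", "B", "C", "D"])
        with pytest.raises(KeyError, match="Z"):
            build_choice_datasets(extra, md, [fission])


def test_parameter_recovery_against_simulated_choices():
    """Simulated choices at a known coefficient are recovered without bias."""
    from fissionnet.synthetic_data import simulate_choice_table

    gamma = (np.log(3.0), 0.0)
    ests, ses = [], []
    for r in range(40):
        rng = np.random.default_rng(900 + r)
        df = simulate_choice_table(300, gamma, rng)
        fit = fit_conditional_logit(df)
        ests.append(fit.coef("resident_present"))
        ses.append(fit.se("resident_present"))
    ests = np.array(ests)
    mcse = ests.std(ddof=1) / np.sqrt(len(ests))
    assert abs(ests.mean() - gamma[0]) < 3 * mcse
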