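"""Conditional logit models of post-fission group choice.

Each female choosing between the two daughter groups contributes one
"choice set" of two alternatives, exactly one of which is chosen.  Choice
probabilities depend only on attributes of the alternatives,

    P(female c picks alternative a) = exp(x_ca . beta) / sum_b exp(x_cb . beta),

so alternative-invariant attributes (anything about the female herself)
cancel from the likelihood and can enter only through interactions with an
alternative-varying covariate.  There is no intercept.  The model is fit
by Newton iteration on the exact conditional-logit log-likelihood with
analytic gradient and Hessian; Wald standard errors come from the observed
information.

Datasets are built separately for females at risk of infanticide
(pregnant or with a dependent infant at fission) and females not at risk.
The covariates are whether the original group's resident male is present
in the alternative, and its interaction with the female's DSI with that
male (the DSI enters uncentered, so the resident-present main effect is
the effect at DSI = 0).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import FissionEvent
from .persistence_model import ModelFitError

CHOICE_TERMS = ("resident_present", "resident_x_dsi")

DATA_COLUMNS = [
    "choice_id",
    "fission_id",
    "female_id",
    "alternative",
    "chosen",
    "resident_present",
    "dsi_with_resident",
    "resident_x_dsi",
]


@dataclasses.dataclass
class ChoiceFit:
    """Fitted conditional logit: coefficient table and fit statistics."""

    table: pd.DataFrame
    loglik: float
    n_choices: int
    terms: tuple[str, ...]

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "coef"])

    def se(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "se"])


def build_choice_datasets(
    states: pd.DataFrame,
    male_dsi: pd.DataFrame,
    fissions: list[FissionEvent],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format choice tables (two rows per female-fission), split by risk.

    Returns ``(at_risk, not_at_risk)``.  A female present in two fissions
    contributes an independent choice to each, classified by her risk state
    at that fission.
    """
    st = states.set_index(["fission_id", "female_id"])
    md = male_dsi.set_index(["fission_id", "female_id"])
    rows = []
    for f in fissions:
        fid = f.event_id
        females = sorted(e_i[1] for e_i in st.index if e_i[0] == fid)
        for fem in females:
            if fem not in f.daughter_assignments:
                raise KeyError(
                    f"female {fem!r} has no daughter-group assignment in fission {fid!r}"
                )
            chosen_daughter = f.daughter_assignments[fem]
            try:
                dsi = float(md.loc[(fid, fem), "dsi_with_resident"])
            except KeyError as exc:
                raise KeyError(
                    f"no resident-male DSI for female {fem!r} in fission {fid!r}"
                ) from exc
            at_risk = int(st.loc[(fid, fem), "at_risk"])
            for alt in ("A", "B"):
                res = int(alt == f.resident_male_daughter)
                rows.append(
                    {
                        "choice_id": f"{fid}:{fem}",
                        "fission_id": fid,
                        "female_id": fem,
                        "alternative": alt,
                        "chosen": int(alt == chosen_daughter),
                        "resident_present": res,
                        "dsi_with_resident": dsi,
                        "resident_x_dsi": res * dsi,
                        "at_risk": at_risk,
                    }
                )
    df = pd.DataFrame(rows, columns=DATA_COLUMNS + ["at_risk"])
    at_risk = df[df["at_risk"] == 1][DATA_COLUMNS].reset_index(drop=True)
    not_at_risk = df[df["at_risk"] == 0][DATA_COLUMNS].reset_index(drop=True)
    return at_risk, not_at_risk


def _loglik_parts(beta: np.ndarray, X: list[np.ndarray], chosen: list[int]):
    """Log-likelihood, gradient and Hessian of the conditional logit."""
    k = len(beta)
    ll = 0.0
    grad = np.zeros(k)
    hess = np.zeros((k, k))
    for Xc, ch in zip(X, chosen):
        eta = Xc @ beta
        m = eta.max()
        w = np.exp(eta - m)
        denom = w.sum()
        p = w / denom
        ll += eta[ch] - (m + np.log(denom))
        xbar = p @ Xc
        grad += Xc[ch] - xbar
        hess -= (Xc * p[:, None]).T @ Xc - np.outer(xbar, xbar)
    return ll, grad, hess


def conditional_logit_loglik(
    beta, data: pd.DataFrame, terms: tuple[str, ...] = CHOICE_TERMS
) -> float:
    """The exact conditional-logit log-likelihood (used by oracles and fits alike)."""
    X, chosen = _design(data, terms)
    return _loglik_parts(np.asarray(beta, dtype=float), X, chosen)[0]


def _design(data: pd.DataFrame, terms):
    X = []
    chosen = []
    for _, grp in data.groupby("choice_id", sort=True):
        if len(grp) < 2:
            raise ModelFitError(
                f"choice set {grp['choice_id'].iloc[0]!r} has fewer than 2 alternatives"
            )
        if int(grp["chosen"].sum()) != 1:
            raise ModelFitError(
                f"choice set {grp['choice_id'].iloc[0]!r} must have exactly one chosen alternative"
            )
        X.append(grp[list(terms)].to_numpy(dtype=float))
        chosen.append(int(np.flatnonzero(grp["chosen"].to_numpy())[0]))
    return X, chosen


def fit_conditional_logit(
    data: pd.DataFrame,
    terms: tuple[str, ...] = CHOICE_TERMS,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ChoiceFit:
    """Maximize the conditional-logit likelihood by Newton iteration.

    Raises :class:`ModelFitError` on separation (diverging coefficients),
    non-convergence, or a degenerate design (a term constant within every
    choice set carries no information and makes the Hessian singular).
    """
    if len(data) == 0:
        raise ModelFitError("empty choice dataset")
    X, chosen = _design(data, terms)
    for k_, term in enumerate(terms):
        if all(np.ptp(Xc[:, k_]) == 0 for Xc in X):
            raise ModelFitError(
                f"term {term!r} is alternative-invariant (constant within every "
                "choice set); it cancels from the likelihood and cannot be "
                "estimated except through an interaction"
            )
    k = len(terms)
    beta = np.zeros(k)
    ll, grad, hess = _loglik_parts(beta, X, chosen)
    for it in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ModelFitError(
                f"singular information matrix at iteration {it}: a term may be "
                "alternative-invariant or collinear"
            ) from exc
        # damped Newton: halve until the likelihood does not decrease
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new = _loglik_parts(cand, X, chosen)[0]
            if ll_new >= ll - 1e-12:
                break
            scale /= 2
        beta = beta + scale * step
        ll_prev = ll
        ll, grad, hess = _loglik_parts(beta, X, chosen)
        if np.max(np.abs(grad)) < tol or abs(ll - ll_prev) < tol:
            break
    else:
        raise ModelFitError(
            f"conditional logit did not converge in {max_iter} iterations "
            f"(|grad| = {np.max(np.abs(grad)):.2e})"
        )
    if np.any(np.abs(beta) > 15):
        raise ModelFitError(
            "coefficient diverged (|beta| > 15): choices are likely separated; "
            f"estimates: {dict(zip(terms, beta))}"
        )
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "term": list(terms),
            "coef": beta,
            "se": se,
            "odds_ratio": np.exp(beta),
            "z": z,
            "p": p,
        }
    )
    return ChoiceFit(table=table, loglik=float(ll), n_choices=len(X), terms=tuple(terms))


def predicted_choice_probability(
    fit: ChoiceFit, covariates: np.ndarray
) -> np.ndarray:
    """Choice probabilities for one choice set (rows = alternatives).

    ``covariates`` has one row per alternative with columns in the fitted
    term order; returns the softmax of the linear predictors, which sums
    to 1.
    """
    Xc = np.asarray(covariates, dtype=float)
    beta = fit.table["coef"].to_numpy()
    eta = Xc @ beta
    w = np.exp(eta - eta.max())
    return w / w.sum()
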