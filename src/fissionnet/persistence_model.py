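"""Dyadic edge-persistence model across group fissions.

A pre-fission tie is taken to persist when both females join the same
daughter group.  With only dyad-independent terms (edge covariates,
attribute homophily and their interactions) and a block-diagonal
constraint restricting dyads to the same parent group, the persistence
component of a separable temporal exponential random graph model
factorizes into independent Bernoulli terms

    logL = sum_dyads [ y * eta - log(1 + exp(eta)) ],   eta = X beta

so it is fit here exactly, by Newton iteration on that likelihood, rather
than by network MCMC.  The intercept is the baseline edge persistence;
coefficients are reported with observed-information Wald standard errors
on the log-odds scale alongside odds ratios.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .attributes import Pedigree, relatedness
from .data_io import BehaviorDataset, FissionEvent
from .dominance import Hierarchy, rank_distance, standardize

#: covariates of the full persistence model, in reporting order
FULL_TERMS = (
    "dummy_strong",
    "dummy_weak",
    "relatedness",
    "risk_match",
    "relatedness_x_riskmatch",
    "rankdist_z",
)

DATA_COLUMNS = [
    "fission_id",
    "i_id",
    "j_id",
    "persisted",
    "dummy_strong",
    "dummy_weak",
    "relatedness",
    "risk_match",
    "relatedness_x_riskmatch",
    "rankdist_z",
]


class ModelFitError(RuntimeError):
    """The likelihood could not be maximized (separation or rank deficiency)."""


@dataclasses.dataclass
class PersistenceFit:
    """Fitted persistence model: coefficient table and fit statistics.

    ``table`` columns: term, coef (log-odds), se (log-odds scale),
    odds_ratio, se_or (odds-ratio scale, by the delta method), z, p.
    """

    table: pd.DataFrame
    loglik: float
    aic: float
    n_dyads: int
    terms: tuple[str, ...]

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "coef"])

    def se(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "se"])


def build_persistence_dataset(
    sociality: pd.DataFrame,
    hierarchies: dict[str, Hierarchy],
    states: pd.DataFrame,
    pedigree: Pedigree,
    fissions: list[FissionEvent],
) -> pd.DataFrame:
    """Join per-dyad covariates with the persistence outcome, across fissions.

    The pre-fission network is the complete graph on eligible females
    within each parent group (block-diagonal constraint: no between-group
    dyads exist).  ``persisted`` is 1 iff the two females share a daughter
    group.  Rank distance is Z-scored over the pooled dyad set because the
    model is fit jointly across fissions.
    """
    soc = sociality.set_index(["fission_id", "i_id", "j_id"])
    st = states.set_index(["fission_id", "female_id"])
    rows = []
    for f in fissions:
        fid = f.event_id
        females = sorted(
            {i for i in f.daughter_assignments}
            & {i for (e, i) in st.index if e == fid}
        )
        h = hierarchies.get(fid)
        if h is None:
            raise KeyError(f"no hierarchy computed for fission {fid!r}")
        for i, j in combinations(females, 2):
            try:
                soc_row = soc.loc[(fid, i, j)]
            except KeyError:
                try:
                    soc_row = soc.loc[(fid, j, i)]
                except KeyError:
                    raise KeyError(
                        f"dyad ({i}, {j}) of fission {fid!r} missing from the sociality table"
                    ) from None
            try:
                risk_i = int(st.loc[(fid, i), "at_risk"])
                risk_j = int(st.loc[(fid, j), "at_risk"])
            except KeyError as exc:
                raise KeyError(
                    f"female state missing for dyad ({i}, {j}) of fission {fid!r}"
                ) from exc
            rel = relatedness(pedigree, i, j)
            risk_match = int(risk_i == risk_j)
            rows.append(
                {
                    "fission_id": fid,
                    "i_id": i,
                    "j_id": j,
                    "persisted": int(
                        f.daughter_assignments[i] == f.daughter_assignments[j]
                    ),
                    "dummy_strong": int(soc_row["dummy_strong"]),
                    "dummy_weak": int(soc_row["dummy_weak"]),
                    "relatedness": rel,
                    "risk_match": risk_match,
                    "relatedness_x_riskmatch": rel * risk_match,
                    "rank_distance": rank_distance(h, i, j),
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["rankdist_z"] = standardize(df["rank_distance"].to_numpy())
    else:
        df["rankdist_z"] = []
    return df[DATA_COLUMNS + ["rank_distance"]]


def fit_persistence(
    data: pd.DataFrame, terms: tuple[str, ...] = FULL_TERMS
) -> PersistenceFit:
    """Maximize the Bernoulli persistence likelihood by Newton iteration.

    ``terms`` selects covariate columns; an intercept (baseline edge
    persistence) is always included.  Raises :class:`ModelFitError` on
    rank-deficient designs (naming the collinear columns) and on
    non-convergence or separation (with the iteration diagnostics).
    """
    if len(data) == 0:
        raise ModelFitError("empty persistence dataset")
    y = data["persisted"].to_numpy(dtype=float)
    names = ["baseline_edge_persistence"] + list(terms)
    X = np.column_stack(
        [np.ones(len(data))] + [data[t].to_numpy(dtype=float) for t in terms]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns that add no rank
        bad = []
        kept = X[:, :1]
        for k in range(1, X.shape[1]):
            cand = np.column_stack([kept, X[:, k]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(names[k])
            else:
                kept = cand
        raise ModelFitError(f"design matrix is rank deficient; collinear terms: {bad}")
    try:
        res = sm.Logit(y, X).fit(method="newton", maxiter=100, disp=False)
    except Exception as exc:  # pragma: no cover - statsmodels wraps several errors
        raise ModelFitError(f"persistence likelihood maximization failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ModelFitError(
            "Newton iteration did not converge (possible separation); "
            f"trace: {res.mle_retvals}"
        )
    if np.any(np.abs(res.params) > 15):
        raise ModelFitError(
            "coefficient diverged (|beta| > 15): data are likely separated; "
            f"estimates: {dict(zip(names, res.params))}"
        )
    coefs = res.params
    ses = res.bse
    z = coefs / ses
    p = 2 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "term": names,
            "coef": coefs,
            "se": ses,
            "odds_ratio": np.exp(coefs),
            "se_or": np.exp(coefs) * ses,  # delta method on the OR scale
            "z": z,
            "p": p,
        }
    )
    k = X.shape[1]
    return PersistenceFit(
        table=table,
        loglik=float(res.llf),
        aic=float(2 * k - 2 * res.llf),
        n_dyads=len(data),
        terms=tuple(terms),
    )


def persistence_rate(data: pd.DataFrame) -> float:
    """Empirical probability that a pre-fission edge persisted."""
    if len(data) == 0:
        raise ValueError("empty persistence dataset")
    return float(np.mean(data["persisted"]))


def compare_models(fits: dict[str, PersistenceFit]) -> pd.DataFrame:
    """AIC comparison table over models fit to the identical dataset."""
    ns = {f.n_dyads for f in fits.values()}
    if len(ns) > 1:
        raise ValueError(f"models were fit to different row counts: {ns}")
    rows = [
        {
            "model": name,
            "n_terms": len(f.terms) + 1,
            "loglik": f.loglik,
            "aic": f.aic,
        }
        for name, f in fits.items()
    ]
    out = pd.DataFrame(rows)
    out["delta_aic"] = out["aic"] - out["aic"].min()
    out["selected"] = out["delta_aic"] == 0
    return out.sort_values("aic", kind="stable").reset_index(drop=True)
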