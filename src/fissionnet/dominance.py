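"""Dominance hierarchies from winner:loser matrices via the I&SI criterion.

The I&SI method seeks the ordinal ranking that minimizes, lexicographically,
first the number of inconsistencies I (dyads in which the lower-ranked
individual won the majority of interactions) and then their total strength
SI (the summed rank distances of the inconsistent dyads).  The search here
is a two-phase heuristic: a David's-score initial order followed by
pairwise-swap hill climbing under seeded random restarts.  On small
matrices the result is pinned to the exhaustive optimum by the test suite.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import warnings
from itertools import combinations, permutations

import numpy as np
import pandas as pd

from .data_io import BehaviorDataset


@dataclasses.dataclass
class ContestMatrix:
    """Directed win counts: wins[a, b] = interactions individual a won against b."""

    ids: list[str]
    wins: np.ndarray
    group_id: str = ""
    year: int | None = None

    def __post_init__(self):
        self.wins = np.asarray(self.wins, dtype=int)
        n = len(self.ids)
        if self.wins.shape != (n, n):
            raise ValueError("wins matrix shape does not match ids")
        if np.any(np.diag(self.wins) != 0):
            raise ValueError("diagonal of wins matrix must be zero")
        if np.any(self.wins < 0):
            raise ValueError("win counts must be nonnegative")


@dataclasses.dataclass
class Hierarchy:
    """An ordinal ranking (rank 1 = top) with its inconsistency diagnostics."""

    order: list[str]
    I: int
    SI: int
    converged: bool
    seed: int
    n_optima_found: int = 1

    def rank(self, ind: str) -> int:
        try:
            return self.order.index(ind) + 1
        except ValueError:
            raise KeyError(f"{ind!r} is not ranked in this hierarchy") from None


def build_contest_matrix(
    ds: BehaviorDataset, group_id: str, year: int, until: dt.date
) -> ContestMatrix:
    """Aggregate decided agonistic interactions of a group for one calendar year.

    Only interactions dated up to ``until`` (the completion of the fission)
    are counted; undecided interactions never enter the dataset by schema.
    """
    recs = [
        (w, l)
        for d, w, l, g in zip(
            ds.agonistic["date"],
            ds.agonistic["winner_id"],
            ds.agonistic["loser_id"],
            ds.agonistic["group_id"],
        )
        if g == group_id and d.year == year and d <= until
    ]
    ids = sorted({i for pair in recs for i in pair})
    if not ids:
        warnings.warn(
            f"group {group_id!r}, year {year}: no decided agonistic "
            "interactions; the hierarchy is undefined",
            stacklevel=2,
        )
    idx = {i: k for k, i in enumerate(ids)}
    wins = np.zeros((len(ids), len(ids)), dtype=int)
    for w, l in recs:
        wins[idx[w], idx[l]] += 1
    return ContestMatrix(ids=ids, wins=wins, group_id=group_id, year=year)


def inconsistencies(wins: np.ndarray, order: np.ndarray) -> tuple[int, int]:
    """(I, SI) of an ordering given as an index permutation into ``wins``.

    A dyad is inconsistent iff the lower-ranked member won strictly more
    interactions; its strength is the pair's rank distance.  Tied records
    and unknown relationships are not inconsistencies.
    """
    sub = wins[np.ix_(order, order)]
    upset = sub.T > sub  # below-diagonal winner beat above-diagonal one
    iu = np.triu_indices(len(order), k=1)
    mask = upset[iu]
    I = int(mask.sum())
    SI = int((iu[1][mask] - iu[0][mask]).sum())
    return I, SI


def davids_scores(wins: np.ndarray) -> np.ndarray:
    """David's scores (Pij-based, with the dyadic correction) for the initial order."""
    n = wins.shape[0]
    total = wins + wins.T
    with np.errstate(divide="ignore", invalid="ignore"):
        # dyadic proportion corrected for interaction count
        pij = np.where(total > 0, (wins / np.maximum(total, 1)), 0.0)
        dij = np.where(
            total > 0, pij - ((pij - 0.5) / (total + 1)), 0.0
        )
    np.fill_diagonal(dij, 0.0)
    w = dij.sum(axis=1)
    w2 = dij @ w
    l = dij.T.sum(axis=1)
    l2 = dij.T @ l
    return w + w2 - l - l2


def _hill_climb(wins: np.ndarray, order: np.ndarray) -> tuple[np.ndarray, int, int]:
    """Greedy improvement by pairwise swaps until (I, SI) is locally minimal."""
    n = len(order)
    best = inconsistencies(wins, order)
    improved = True
    while improved and best[0] + best[1] > 0:
        improved = False
        for a in range(n - 1):
            for b in range(a + 1, n):
                order[a], order[b] = order[b], order[a]
                cand = inconsistencies(wins, order)
                if cand < best:
                    best = cand
                    improved = True
                else:
                    order[a], order[b] = order[b], order[a]
    return order, best[0], best[1]


def isi_order(
    m: ContestMatrix, seed: int = 0, max_iter: int = 50
) -> Hierarchy:
    """Find an ordering minimizing (I, SI) lexicographically.

    ``max_iter`` seeded random restarts perturb the David's-score initial
    order; the best local optimum is returned.  Among equally optimal
    orders the first found under the seeded restart sequence wins, so the
    result is deterministic given (matrix, seed).  ``converged`` is False
    only when restarts were exhausted while the last restart still found an
    improvement (the search may not have stabilized).
    """
    n = len(m.ids)
    if n < 2:
        raise ValueError("a hierarchy needs at least 2 individuals")
    rng = np.random.default_rng(seed)
    ds = davids_scores(m.wins)
    init = np.argsort(-ds, kind="stable")

    best_order, bi, bsi = _hill_climb(m.wins, init.copy())
    best = (bi, bsi)
    n_optima = 1
    last_improving_restart = 0
    for it in range(1, max_iter + 1):
        start = best_order.copy()
        # perturb: a few random swaps of the incumbent
        for _ in range(max(1, n // 3)):
            a, b = rng.integers(0, n, size=2)
            start[a], start[b] = start[b], start[a]
        cand_order, ci, csi = _hill_climb(m.wins, start)
        if (ci, csi) < best:
            best, best_order = (ci, csi), cand_order
            n_optima = 1
            last_improving_restart = it
        elif (ci, csi) == best and not np.array_equal(cand_order, best_order):
            n_optima += 1
        if best == (0, 0):
            break
    converged = best == (0, 0) or last_improving_restart < max_iter
    return Hierarchy(
        order=[m.ids[k] for k in best_order],
        I=best[0],
        SI=best[1],
        converged=converged,
        seed=seed,
        n_optima_found=n_optima,
    )


def exhaustive_isi(m: ContestMatrix) -> Hierarchy:
    """Exact (I, SI) optimum by enumerating all orderings (small n only)."""
    n = len(m.ids)
    if n > 9:
        raise ValueError("exhaustive search is limited to n <= 9")
    best = None
    best_perm = None
    for perm in permutations(range(n)):
        val = inconsistencies(m.wins, np.array(perm))
        if best is None or val < best:
            best, best_perm = val, perm
    return Hierarchy(
        order=[m.ids[k] for k in best_perm],
        I=best[0],
        SI=best[1],
        converged=True,
        seed=-1,
    )


def rank_distance(h: Hierarchy, i: str, j: str) -> int:
    """Number of ordinal rank steps between two ranked individuals."""
    return abs(h.rank(i) - h.rank(j))


def standardize(distances) -> np.ndarray:
    """Z-scores of rank distances over the pooled dyad set entering a model."""
    d = np.asarray(distances, dtype=float)
    sd = d.std(ddof=0)
    if sd == 0:
        return np.zeros_like(d)
    return (d - d.mean()) / sd


def rank_table(h: Hierarchy, group_id: str, fission_id: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fission_id": fission_id,
            "group_id": group_id,
            "individual_id": h.order,
            "rank": np.arange(1, len(h.order) + 1),
        }
    )


def rank_distance_table(h: Hierarchy, fission_id: str = "") -> pd.DataFrame:
    rows = [
        {
            "fission_id": fission_id,
            "i_id": i,
            "j_id": j,
            "rank_distance": rank_distance(h, i, j),
        }
        for i, j in combinations(h.order, 2)
    ]
    return pd.DataFrame(rows, columns=["fission_id", "i_id", "j_id", "rank_distance"])
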