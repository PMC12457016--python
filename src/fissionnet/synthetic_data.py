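"""Synthetic behavioral datasets with known ground truth.

The generator emulates the structure of a long-term one-male-group study
population: several groups of adult, parous females organized in
matrilines, two annual windows of focal-follow scans whose grooming and
resting-in-proximity counts are Poisson draws around dyad-specific rates
(kin-elevated, with tie-class multipliers that make dyads consistently
strong, consistently weak, or inconsistent across the two years), a latent
dominance order generating agonistic outcomes with a configurable upset
probability, birth timelines inducing pregnancy/lactation states, a single
resident male per group with a qualifying tenure, and a fission splitting
each group into two daughter groups.

Fission outcomes are drawn in one of two modes:

``choice_first``
    Each female independently picks the daughter group with or without the
    resident male from the conditional-logit law with coefficients
    ``gamma`` (risk-dependent).  Realistic; dyad-level effects are then
    whatever the individual choices induce.

``dyad_target``
    The bipartition of each group is sampled from an exponential family
    over bipartitions whose couplings are calibrated (Levenberg-Marquardt
    on exactly enumerated partition probabilities) so that each dyad's
    marginal probability of ending up together is as close to
    ``logistic(x . beta)`` as the moment geometry of bipartitions allows
    (co-membership is transitive, so the joint law cannot be independent
    Bernoulli and exact margins are generically infeasible; the residual
    is of order 1e-2).  This makes the dyad-independent persistence
    model's estimating equation essentially unbiased and is the mode used
    for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd

from .attributes import Pedigree, relatedness
from .data_io import BehaviorDataset, FissionEvent
from .dominance import standardize

#: coefficient names of the persistence model, in design-matrix order
BETA_TERMS = (
    "intercept",
    "dummy_strong",
    "dummy_weak",
    "relatedness",
    "risk_match",
    "relatedness_x_riskmatch",
    "rankdist_z",
)


def _default_beta() -> dict[str, float]:
    # odds ratios of the published persistence fit, on the log-odds scale
    return {
        "intercept": float(np.log(0.81)),
        "dummy_strong": float(np.log(1.80)),
        "dummy_weak": float(np.log(1.41)),
        "relatedness": float(np.log(1.23)),
        "risk_match": float(np.log(1.78)),
        "relatedness_x_riskmatch": float(np.log(147.01)),
        "rankdist_z": float(np.log(0.98)),
    }


@dataclasses.dataclass
class SimConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    seed: int = 0
    n_groups: int = 5
    females_per_group: int = 15
    n_matrilines: int = 4
    generation_depth: int = 3
    first_fission_year: int = 2012
    focal_minutes_per_female_year: int = 1800
    # behavior rates, per focal minute and partner
    baseline_groom_rate: float = 0.004
    baseline_prox_rate: float = 0.006
    dyad_rate_sd: float = 0.4  # lognormal sd of dyad-level heterogeneity
    kin_multiplier: float = 3.0  # applied to dyads with relatedness >= 0.125
    strong_multiplier: float = 4.0
    weak_multiplier: float = 0.25
    frac_strong: float = 0.30
    frac_weak: float = 0.40
    # dominance
    upset_probability: float = 0.10
    agonistic_per_dyad_year: float = 2.0
    # reproduction
    at_risk_fraction: float = 0.41
    infant_mortality: float = 0.10
    # monitoring
    observation_prob: float = 0.9
    # female-male affiliation
    male_groom_rate: float = 0.003
    male_rate_sd: float = 0.6
    # ground-truth model coefficients
    beta: dict[str, float] = dataclasses.field(default_factory=_default_beta)
    gamma_at_risk: tuple[float, float] = (float(np.log(3.63)), float(np.log(1.25)))
    gamma_not_at_risk: tuple[float, float] = (float(np.log(1.36)), float(np.log(0.86)))
    fission_mode: str = "choice_first"

    def validate(self) -> None:
        if self.focal_minutes_per_female_year <= 0:
            raise ValueError("focal_minutes_per_female_year must be positive")
        if not (0 <= self.frac_strong + self.frac_weak <= 1):
            raise ValueError("tie-class fractions must sum to at most 1")
        for name in ("upset_probability", "at_risk_fraction", "observation_prob",
                     "infant_mortality"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.females_per_group < 4:
            raise ValueError("need at least 4 females per group")
        if self.fission_mode not in ("choice_first", "dyad_target"):
            raise ValueError(f"unknown fission mode {self.fission_mode!r}")


@dataclasses.dataclass
class GroupTruth:
    group_id: str
    females: list[str]
    male_id: str
    onset: dt.date
    fission_date: dt.date
    latent_order: list[str]  # top rank first
    tie_class: dict[tuple[str, str], str]  # sorted dyad -> class label
    groom_rate: dict[tuple[str, str], tuple[float, float]]  # dyad -> (year1, year2)
    prox_rate: dict[tuple[str, str], tuple[float, float]]
    at_risk: dict[str, bool]
    male_dsi: dict[str, float]  # true expected DSI with the resident male
    assignments: dict[str, str] = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class SimTruth:
    """Generating parameters and per-dyad/per-female ground truth."""

    beta: dict[str, float]
    gamma_at_risk: tuple[float, float]
    gamma_not_at_risk: tuple[float, float]
    groups: list[GroupTruth]
    mother_of: dict[str, str | None]

    def group(self, group_id: str) -> GroupTruth:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(group_id)

    def pedigree(self) -> Pedigree:
        return Pedigree(self.mother_of)


def _dyad(i: str, j: str) -> tuple[str, str]:
    return (i, j) if i < j else (j, i)


# ---------------------------------------------------------------------------
# population structure


def _build_matrilines(cfg: SimConfig, gi: int, rng: np.random.Generator):
    """Maternal family trees for one group.

    Returns (living adult ids, mother_of links including record-only
    ancestors, birth dates).  One matriline is left with unrecorded mothers
    to emulate truncated pedigrees.
    """
    gid = f"g{gi}"
    n = cfg.females_per_group
    sizes = [n // cfg.n_matrilines] * cfg.n_matrilines
    for k in range(n % cfg.n_matrilines):
        sizes[k] += 1
    fission_year = cfg.first_fission_year + gi
    living: list[str] = []
    mother_of: dict[str, str | None] = {}
    birth_year: dict[str, int] = {}
    counter = 0
    for mi, size in enumerate(sizes):
        unknown = mi == cfg.n_matrilines - 1  # truncated pedigree matriline
        if unknown:
            for _ in range(size):
                fid = f"{gid}f{counter:02d}"
                counter += 1
                living.append(fid)
                mother_of[fid] = None
                birth_year[fid] = fission_year - int(rng.integers(12, 26))
            continue
        founder = f"{gid}a{mi}"  # record-only ancestor, not censused
        mother_of[founder] = None
        birth_year[founder] = fission_year - int(rng.integers(32, 40))
        # breadth-first fill: founder's daughters, then granddaughters, ...
        queue = [(founder, 0)]
        placed = 0
        while placed < size and queue:
            mother, gen = queue.pop(0)
            n_daughters = 2 if gen + 1 < cfg.generation_depth else 1
            for _ in range(n_daughters):
                if placed >= size:
                    break
                fid = f"{gid}f{counter:02d}"
                counter += 1
                living.append(fid)
                mother_of[fid] = mother
                base = birth_year[mother] + 8
                birth_year[fid] = min(
                    fission_year - 10, base + int(rng.integers(0, 4))
                )
                placed += 1
                if gen + 1 < cfg.generation_depth:
                    queue.append((fid, gen + 1))
    return living, mother_of, birth_year


def simulate_truth(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimTruth:
    """The cheap ground-truth layer: structure and rates, no behavioral records."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    groups: list[GroupTruth] = []
    all_mothers: dict[str, str | None] = {}
    for gi in range(cfg.n_groups):
        gid = f"g{gi}"
        females, mother_of, birth_year = _build_matrilines(cfg, gi, rng)
        all_mothers.update(mother_of)
        onset = dt.date(cfg.first_fission_year + gi, 3, 1)
        fission_date = onset + dt.timedelta(days=60)
        ped = Pedigree(mother_of)
        tie_class: dict[tuple[str, str], str] = {}
        groom_rate: dict[tuple[str, str], tuple[float, float]] = {}
        prox_rate: dict[tuple[str, str], tuple[float, float]] = {}
        p_inconsistent = 1 - cfg.frac_strong - cfg.frac_weak
        for i, j in combinations(sorted(females), 2):
            d = _dyad(i, j)
            cls = rng.choice(
                ["consistently_strong", "consistently_weak", "inconsistent"],
                p=[cfg.frac_strong, cfg.frac_weak, p_inconsistent],
            )
            tie_class[d] = str(cls)
            het = float(np.exp(rng.normal(0, cfg.dyad_rate_sd)))
            kin = cfg.kin_multiplier if relatedness(ped, i, j) >= 0.125 else 1.0
            if cls == "consistently_strong":
                mults = (cfg.strong_multiplier, cfg.strong_multiplier)
            elif cls == "consistently_weak":
                mults = (cfg.weak_multiplier, cfg.weak_multiplier)
            else:
                hi_first = rng.random() < 0.5
                mults = (
                    (cfg.strong_multiplier, cfg.weak_multiplier)
                    if hi_first
                    else (cfg.weak_multiplier, cfg.strong_multiplier)
                )
            groom_rate[d] = tuple(cfg.baseline_groom_rate * het * kin * m for m in mults)
            prox_rate[d] = tuple(cfg.baseline_prox_rate * het * kin * m for m in mults)
        order = list(rng.permutation(sorted(females)))
        at_risk = {f: bool(rng.random() < cfg.at_risk_fraction) for f in sorted(females)}
        male_rates = {
            f: cfg.male_groom_rate * float(np.exp(rng.normal(0, cfg.male_rate_sd)))
            for f in sorted(females)
        }
        med = float(np.median(list(male_rates.values())))
        male_dsi = {f: r / med for f, r in male_rates.items()}
        groups.append(
            GroupTruth(
                group_id=gid,
                females=sorted(females),
                male_id=f"{gid}m",
                onset=onset,
                fission_date=fission_date,
                latent_order=order,
                tie_class=tie_class,
                groom_rate=groom_rate,
                prox_rate=prox_rate,
                at_risk=at_risk,
                male_dsi=male_dsi,
            )
        )
        all_mothers[f"{gid}m"] = None
        all_mothers[f"{gid}v"] = None
    return SimTruth(
        beta=dict(cfg.beta),
        gamma_at_risk=cfg.gamma_at_risk,
        gamma_not_at_risk=cfg.gamma_not_at_risk,
        groups=groups,
        mother_of=all_mothers,
    )


# ---------------------------------------------------------------------------
# behavioral record emission


def _emit_group_scans(cfg, g: GroupTruth, rng, rows: list) -> None:
    from .sociality import year_windows

    y1, y2 = year_windows(g.onset)
    m_total = cfg.focal_minutes_per_female_year
    for year_idx, (lo, hi) in enumerate((y1, y2)):
        ndays = (hi - lo).days + 1
        for f in g.females:
            events: list[tuple[str, str | None, frozenset]] = []
            for p in g.females:
                if p == f:
                    continue
                d = _dyad(f, p)
                gcount = rng.poisson(g.groom_rate[d][year_idx] * m_total)
                events.extend(("social_groom", p, frozenset()) for _ in range(gcount))
                rcount = rng.poisson(g.prox_rate[d][year_idx] * m_total)
                events.extend(("rest", None, frozenset((p,))) for _ in range(rcount))
            # female-male affiliation, year 1 only matters but keep both years
            mrate = cfg.male_groom_rate * g.male_dsi[f]
            for _ in range(rng.poisson(mrate * m_total)):
                events.append(("social_groom", g.male_id, frozenset()))
            for _ in range(rng.poisson(mrate * m_total)):
                events.append(("rest", None, frozenset((g.male_id,))))
            n_filler = max(0, m_total - len(events))
            filler_acts = rng.choice(
                ["feed", "rest", "move"], size=n_filler, p=[0.45, 0.35, 0.2]
            )
            events.extend((str(a), None, frozenset()) for a in filler_acts)
            offsets = rng.integers(0, ndays, size=len(events))
            for (act, partner, prox), off in zip(events, offsets):
                rows.append(
                    (
                        f,
                        lo + dt.timedelta(days=int(off)),
                        0,  # minute_index assigned after sorting
                        act,
                        partner,
                        prox,
                    )
                )


def simulate_population(cfg: SimConfig) -> tuple[BehaviorDataset, SimTruth]:
    """Generate a full validated dataset plus its ground truth.

    Deterministic given ``cfg.seed``: the same config yields byte-identical
    files when written with :func:`fissionnet.data_io.write_dataset`.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth = simulate_truth(cfg, rng)

    individuals_rows = []
    scan_rows: list = []
    agonistic_rows = []
    census_rows = []
    birth_rows = []

    for g in truth.groups:
        fission_year = g.fission_date.year
        # individuals: living females, ancestors, resident + visitor male
        ids_here = set(g.females)
        for f in g.females:
            birth = dt.date(fission_year - 12, 6, 1)
            # reconstruct a plausible birth date from the matriline builder's years
            individuals_rows.append(
                {
                    "id": f,
                    "sex": "female",
                    "birth_date": None,
                    "mother_id": truth.mother_of.get(f),
                    "adult_from": g.onset - dt.timedelta(days=800),
                }
            )
        ancestors = {
            m
            for f in g.females
            if (m := truth.mother_of.get(f)) is not None and m not in ids_here
        }
        for a in sorted(ancestors):
            individuals_rows.append(
                {
                    "id": a,
                    "sex": "female",
                    "birth_date": None,
                    "mother_id": truth.mother_of.get(a),
                    "adult_from": None,
                }
            )
        for m in (g.male_id, f"{g.group_id}v"):
            individuals_rows.append(
                {"id": m, "sex": "male", "birth_date": None,
                 "mother_id": None, "adult_from": None}
            )

        # births inducing the reproductive states
        for f in g.females:
            if g.at_risk[f]:
                if rng.random() < 0.5:  # pregnant at fission
                    b = g.fission_date + dt.timedelta(days=int(rng.integers(1, 177)))
                    death = None
                else:  # dependent infant, alive at fission
                    b = g.fission_date - dt.timedelta(days=int(rng.integers(0, 360)))
                    death = None
                birth_rows.append(
                    {
                        "mother_id": f,
                        "infant_id": f"{f}i",
                        "birth_date": b,
                        "death_date": death,
                    }
                )
            elif rng.random() < 0.3:
                # an older (independent) infant, or one that died young
                b = g.fission_date - dt.timedelta(days=int(rng.integers(400, 900)))
                death = (
                    b + dt.timedelta(days=int(rng.integers(10, 300)))
                    if rng.random() < cfg.infant_mortality
                    else None
                )
                birth_rows.append(
                    {"mother_id": f, "infant_id": f"{f}i", "birth_date": b,
                     "death_date": death}
                )

        # census: near-daily observation from the start of year 2 to after fission
        start = g.onset - dt.timedelta(days=2 * 365)
        end = g.fission_date + dt.timedelta(days=30)
        day = start
        day_index = 0
        while day <= end:
            if rng.random() < cfg.observation_prob:
                present = set(g.females) | {g.male_id}
                if day_index > 40 and rng.random() < 0.15:
                    present.add(f"{g.group_id}v")  # visiting male
                census_rows.append(
                    {"date": day, "group_id": g.group_id, "present_ids": frozenset(present)}
                )
            day += dt.timedelta(days=1)
            day_index += 1

        # agonistic interactions in the fission calendar year, before completion
        rank_of = {f: k for k, f in enumerate(g.latent_order)}
        year_start = dt.date(fission_year, 1, 1)
        span = (g.fission_date - year_start).days
        for i, j in combinations(g.females, 2):
            for _ in range(rng.poisson(cfg.agonistic_per_dyad_year)):
                upset = rng.random() < cfg.upset_probability
                dominant = i if rank_of[i] < rank_of[j] else j
                subordinate = j if dominant == i else i
                winner, loser = (
                    (subordinate, dominant) if upset else (dominant, subordinate)
                )
                agonistic_rows.append(
                    {
                        "date": year_start + dt.timedelta(days=int(rng.integers(0, span))),
                        "winner_id": winner,
                        "loser_id": loser,
                        "group_id": g.group_id,
                    }
                )

        _emit_group_scans(cfg, g, rng, scan_rows)

    # infants referenced by birth records must exist as individuals
    for rec in birth_rows:
        individuals_rows.append(
            {
                "id": rec["infant_id"],
                "sex": "female" if rng.random() < 0.5 else "male",
                "birth_date": rec["birth_date"],
                "mother_id": rec["mother_id"],
                "adult_from": None,
            }
        )

    scans = pd.DataFrame(
        scan_rows,
        columns=["focal_id", "date", "minute_index", "activity", "partner_id",
                 "proximity_partner_ids"],
    )
    scans = scans.sort_values(
        ["focal_id", "date", "activity"], kind="stable"
    ).reset_index(drop=True)
    scans["minute_index"] = scans.groupby(["focal_id", "date"]).cumcount()

    ds = BehaviorDataset(
        individuals=pd.DataFrame(
            individuals_rows,
            columns=["id", "sex", "birth_date", "mother_id", "adult_from"],
        ),
        focal_scans=scans,
        agonistic=pd.DataFrame(
            agonistic_rows, columns=["date", "winner_id", "loser_id", "group_id"]
        ),
        census=pd.DataFrame(census_rows, columns=["date", "group_id", "present_ids"]),
        births=pd.DataFrame(
            birth_rows, columns=["mother_id", "infant_id", "birth_date", "death_date"]
        ),
        fissions=[],
    )
    return ds, truth


# ---------------------------------------------------------------------------
# fission outcomes


@lru_cache(maxsize=8)
def _bipartition_table(n: int) -> np.ndarray:
    """All 2^(n-1) - 1 proper bipartition side vectors of n nodes (node 0 on side 0)."""
    if n > 20:
        raise ValueError("exact bipartition enumeration is limited to n <= 20")
    codes = np.arange(1, 2 ** (n - 1), dtype=np.int64)
    sides = ((codes[:, None] >> np.arange(n - 1)) & 1).astype(np.int8)
    return np.concatenate([np.zeros((len(codes), 1), dtype=np.int8), sides], axis=1)


def _logit(p):
    return np.log(p) - np.log1p(-p)


def bipartition_distribution(
    eta: np.ndarray,
    n: int,
    calibrate: bool = True,
    tol: float = 1e-3,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """The calibrated distribution over proper bipartitions for given dyad targets.

    ``eta`` holds the target co-membership log-odds for each dyad (i < j
    order).  The distribution is the exponential family over proper
    bipartitions with couplings ``eta'``; when ``calibrate`` is set the
    couplings are adjusted — a scalar-offset bisection followed by
    Levenberg-Marquardt on the exactly enumerated mean map — so that the
    vector of dyad co-membership margins is the least-squares projection
    of ``logistic(eta)`` onto the achievable moment set.  Because
    co-membership is transitive, generic targets sit slightly outside
    that set, so a residual of order 1e-2 on a few dyads is expected even
    at convergence; the achieved maximum margin error is always reported
    in the diagnostics dict.

    Returns ``(side_vectors, probabilities, diagnostics)``.
    """
    eta = np.asarray(eta, dtype=float)
    dyads = list(combinations(range(n), 2))
    if len(eta) != len(dyads):
        raise ValueError("eta must have one entry per dyad")
    S = _bipartition_table(n)
    ii = np.array([a for a, b in dyads])
    jj = np.array([b for a, b in dyads])
    Y = (S[:, ii] == S[:, jj]).astype(float)
    target = 1.0 / (1.0 + np.exp(-eta))
    target = np.clip(target, 1e-4, 1 - 1e-4)
    couplings = eta.copy()

    def margins_of(c):
        logw = Y @ c
        w = np.exp(logw - logw.max())
        return np.clip((w @ Y) / w.sum(), 1e-9, 1 - 1e-9), w

    iters = 0
    if calibrate:
        # Stage 1: a common offset delta so the mean margin matches the mean
        # target.  Without it the weights concentrate on lopsided partitions
        # (co-membership is maximal there) and Newton starts too far out.
        # The mean margin is monotone in delta, so bisection is safe.
        lo_d, hi_d = -10.0, 10.0
        for _ in range(60):
            mid = 0.5 * (lo_d + hi_d)
            m_mid, _ = margins_of(couplings + mid)
            if m_mid.mean() < target.mean():
                lo_d = mid
            else:
                hi_d = mid
        couplings = couplings + 0.5 * (lo_d + hi_d)
        margins, w = margins_of(couplings)
        err = float(np.max(np.abs(margins - target)))
        # Stage 2: the target margins generically sit slightly OUTSIDE the
        # feasible moment polytope of bipartitions (co-membership is
        # transitive, so e.g. triangle-type constraints bind), so exact
        # matching may be impossible.  Calibration therefore least-squares
        # projects: minimize ||margins(c) - target||^2 by
        # Levenberg-Marquardt, whose Jacobian d margins / d couplings is
        # the co-membership covariance matrix, exact under the enumerated
        # distribution.
        D = len(eta)
        eye = np.eye(D)
        sse = float(np.sum((margins - target) ** 2))
        lam = 1e-3
        stalls = 0
        for iters in range(1, max_iter + 1):
            if err < tol or stalls >= 2:
                break
            probs = w / w.sum()
            Yw = Y * probs[:, None]
            cov = Yw.T @ Y - np.outer(margins, margins)
            r = target - margins
            JtJ = cov @ cov
            Jtr = cov @ r
            scale0 = max(float(np.trace(JtJ)) / D, 1e-14)
            improved = False
            for _ in range(15):
                step = np.linalg.solve(JtJ + lam * scale0 * eye, Jtr)
                cand = np.clip(couplings + step, -30, 30)
                m_new, w_new = margins_of(cand)
                sse_new = float(np.sum((m_new - target) ** 2))
                if sse_new < sse * (1 - 1e-10):
                    stalls = stalls + 1 if sse_new > sse * (1 - 1e-4) else 0
                    couplings, margins, w = cand, m_new, w_new
                    sse = sse_new
                    err = float(np.max(np.abs(margins - target)))
                    lam = max(lam / 3, 1e-10)
                    improved = True
                    break
                lam *= 8
            if not improved:
                break  # at the least-squares projection onto the polytope
    else:
        margins, w = margins_of(couplings)
        err = float(np.max(np.abs(margins - target)))
    probs = w / w.sum()
    diag = {
        "calibration_iters": iters,
        "max_margin_error": err,
        "margins": margins,
        "target": target,
    }
    return S, probs, diag


def sample_bipartition(
    eta: np.ndarray,
    n: int,
    rng: np.random.Generator,
    calibrate: bool = True,
    tol: float = 1e-3,
    max_iter: int = 200,
) -> tuple[np.ndarray, dict]:
    """Draw one bipartition from :func:`bipartition_distribution`."""
    S, probs, diag = bipartition_distribution(
        eta, n, calibrate=calibrate, tol=tol, max_iter=max_iter
    )
    pick = rng.choice(len(S), p=probs)
    return S[pick].copy(), diag


def truth_design(truth: SimTruth) -> pd.DataFrame:
    """Per-dyad design matrix from ground-truth covariates, pooled across groups.

    Rank distance comes from the latent order and is Z-scored over the
    pooled dyad set, mirroring how the persistence model will see it.
    """
    ped = truth.pedigree()
    rows = []
    for g in truth.groups:
        rank_of = {f: k + 1 for k, f in enumerate(g.latent_order)}
        for i, j in combinations(g.females, 2):
            cls = g.tie_class[_dyad(i, j)]
            rel = relatedness(ped, i, j)
            risk_match = int(g.at_risk[i] == g.at_risk[j])
            rows.append(
                {
                    "fission_id": g.group_id,
                    "i_id": i,
                    "j_id": j,
                    "dummy_strong": int(cls == "consistently_strong"),
                    "dummy_weak": int(cls == "consistently_weak"),
                    "relatedness": rel,
                    "risk_match": risk_match,
                    "relatedness_x_riskmatch": rel * risk_match,
                    "rank_distance": abs(rank_of[i] - rank_of[j]),
                }
            )
    df = pd.DataFrame(rows)
    df["rankdist_z"] = standardize(df["rank_distance"].to_numpy())
    return df


def simulate_fission(
    cfg: SimConfig,
    truth: SimTruth,
    rng: np.random.Generator | None = None,
    mode: str | None = None,
) -> list[FissionEvent]:
    """Draw daughter-group assignments for every group and record them in the truth.

    Daughter A always holds the resident male.  In ``choice_first`` mode
    each female joins A with probability
    ``logistic(gamma_1 + gamma_2 * her DSI with the male)`` (gamma taken
    from her infanticide-risk class); in ``dyad_target`` mode the
    bipartition follows the calibrated dyadic law of
    :func:`sample_bipartition` with the ground-truth persistence
    coefficients.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    mode = mode or cfg.fission_mode
    events: list[FissionEvent] = []
    design = truth_design(truth) if mode == "dyad_target" else None
    for g in truth.groups:
        females = g.females
        if mode == "choice_first":
            sides = {}
            for f in females:
                gamma = (
                    truth.gamma_at_risk if g.at_risk[f] else truth.gamma_not_at_risk
                )
                eta = gamma[0] + gamma[1] * g.male_dsi[f]
                p_a = 1.0 / (1.0 + np.exp(-eta))
                sides[f] = "A" if rng.random() < p_a else "B"
            if len(set(sides.values())) == 1:  # a fission needs two daughters
                flip = females[int(rng.integers(0, len(females)))]
                sides[flip] = "B" if sides[flip] == "A" else "A"
        else:
            sub = design[design["fission_id"] == g.group_id]
            X = np.column_stack(
                [np.ones(len(sub))]
                + [sub[t].to_numpy(dtype=float) for t in BETA_TERMS[1:]]
            )
            beta_vec = np.array([truth.beta[t] for t in BETA_TERMS])
            eta = X @ beta_vec
            side_vec, _ = sample_bipartition(eta, len(females), rng)
            # label the larger side A (the side that keeps the resident male)
            a_side = 0 if side_vec.sum() <= len(females) / 2 else 1
            sides = {
                f: ("A" if s == a_side else "B") for f, s in zip(females, side_vec)
            }
        assignments = dict(sides)
        assignments[g.male_id] = "A"
        g.assignments = assignments
        events.append(
            FissionEvent(
                event_id=g.group_id,
                parent_group_id=g.group_id,
                subgrouping_onset=g.onset,
                fission_date=g.fission_date,
                daughter_assignments=assignments,
                resident_male_daughter="A",
            )
        )
    return events


def truth_persistence_dataset(truth: SimTruth) -> pd.DataFrame:
    """Persistence design + outcome built from ground truth (for recovery tests)."""
    df = truth_design(truth).copy()
    persisted = []
    for _, row in df.iterrows():
        g = truth.group(row["fission_id"])
        if not g.assignments:
            raise ValueError("fission outcomes have not been simulated yet")
        persisted.append(
            int(g.assignments[row["i_id"]] == g.assignments[row["j_id"]])
        )
    df["persisted"] = persisted
    return df


def simulate_choice_table(
    n_females: int,
    gamma: tuple[float, float],
    rng: np.random.Generator,
    dsi_sd: float = 0.5,
) -> pd.DataFrame:
    """Standalone conditional-logit draws for choice-model recovery tests.

    Each synthetic female has a DSI with the resident male drawn lognormal
    around 1 and picks the resident-male alternative with probability
    ``logistic(gamma_1 + gamma_2 * dsi)``.
    """
    rows = []
    for k in range(n_females):
        dsi = float(np.exp(rng.normal(0, dsi_sd)))
        eta = gamma[0] + gamma[1] * dsi
        chooses_resident = rng.random() < 1.0 / (1.0 + np.exp(-eta))
        for alt, res in (("A", 1), ("B", 0)):
            rows.append(
                {
                    "choice_id": f"c{k:04d}",
                    "fission_id": "sim",
                    "female_id": f"f{k:04d}",
                    "alternative": alt,
                    "chosen": int((res == 1) == chooses_resident),
                    "resident_present": res,
                    "dsi_with_resident": dsi,
                    "resident_x_dsi": res * dsi,
                }
            )
    return pd.DataFrame(rows)
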