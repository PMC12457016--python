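# Methods

This note documents the modeling choices, the synthetic-data generator,
the numerical decisions, and the limits of what the test suite
establishes.

## Models and assumptions

**Sociality index.** The dyadic sociality index combines a symmetric
grooming rate with two directed resting-within-1-m proximity rates, each
normalized by its group-window median. Design choices where the index
definition leaves room:

- The grooming denominator is the *sum* of both members' focal minutes
  ("total observation time" of the pair). This keeps the term symmetric
  and damps sampling imbalance between members.
- Proximity uses only resting-within-1-m partner records. Grooming-time
  proximity co-occurs with grooming and would double-count; feeding
  proximity (7 m) is retained in the data model but unused by the index.
- One pooled proximity median: the median of the combined set
  {R_ij, R_ji} over included dyads, since the formula uses a single
  median symbol for both directed terms.
- A DSI exactly equal to the threshold (1) in a year is binned with the
  weak side, so the classification is total: strong requires strictly > 1
  in both years, inconsistent requires strictly > 1 in exactly one year,
  weak is everything else. Exact ties are measure-zero in real rate data
  but common in small constructed examples.
- A zero group median makes the index undefined; the default is a hard
  error naming the offending median. An explicit fallback drops the
  undefined term and renormalizes the remaining weights to sum to 1 —
  silent division is worse than failure.
- Eligibility ("followed for at least half the year") is evaluated as
  adult-tenure coverage of the 365-day window with an inclusive boundary
  (coverage ≥ 0.5). Windows are closed 365-day intervals: the first ends
  the day before subgrouping onset, the second covers days 366–730 before
  onset. In the second window eligibility is *not* re-applied: the same
  dyads are indexed under relaxed rules, with females lacking focal data
  contributing through their partners' follows (single-focal variant).

**Dominance.** The I&SI criterion is combinatorial; the paper-trail
implementations are heuristic searches. Here: David's-score
initialization, pairwise-swap hill climbing accepting lexicographic
(I, SI) improvements, and seeded random restarts (default 50) perturbing
the incumbent. A dyad is inconsistent iff the lower-ranked member won
strictly more decided interactions; ties and unobserved dyads are not
inconsistencies. Determinism: the same matrix and seed always return the
same order; among equally optimal orders the first found under the seeded
restart sequence wins, and the number of distinct optima encountered is
reported. The test suite pins the search to the exhaustive optimum on
random matrices with n ≤ 7; for larger n only local optimality is
guaranteed. Rank distance is Z-scored over the pooled dyad set entering
the joint model (not per fission), since the model is fit jointly.

**Relatedness.** Binned by the summed depths to the closest recorded
common maternal ancestor: 1 → 0.5, 2 → 0.25, 3 → 0.125, 4 → 0.0625,
≥ 5 → 0.03125, none → 0. The closest relationship wins when multiple
paths exist. Only recorded links count: a relationship through an
unrecorded intermediate female is invisible and scores 0, mirroring
truncated field pedigrees.

**Reproductive state.** Pregnant at date *d* iff a birth falls in
(d, d + 176]; lactating iff an infant born on or before *d* is younger
than 365 days and alive past *d* (a death on or before *d* ends
lactation); at risk of infanticide = pregnant or lactating. A birth on
the fission date itself counts as lactating, not pregnant.

**Residency.** A male gains resident status on completing 7 consecutive
*observation* days (days with a census record, not calendar days) as the
sole male, backdated to the first day of the run — backdating makes
tenure-length checks like "resident > 176 days at fission" conservative
and deterministic, where the alternative (status from the 7th day) is
equally defensible. Status is lost after 7 consecutive observation days
of complete absence, the interval closing on the last day present.

**Persistence model.** With only dyad-independent terms and the
block-diagonal constraint, the persistence component of the temporal
exponential random graph family *is* an independent-Bernoulli logistic
likelihood, so it is fit exactly by Newton iteration (via the standard
logistic fitter) rather than by network MCMC — exact, fast, and testable
against a grid-search oracle. No formation model exists because no new
within-group ties can form at the fission itself. Standard errors are
observed-information Wald on the log-odds scale; the coefficient table
reports both the log-odds-scale SE and a delta-method SE on the
odds-ratio scale, since published tables are often ambiguous about which
scale they print. Raw Wald p-values, no multiple-testing adjustment.
Separation and rank deficiency raise errors naming the offending terms
instead of returning garbage (a coefficient beyond ±15 on the log-odds
scale is treated as divergence).

**Conditional logit.** Written for general J alternatives, validated for
J = 2 (all observed fissions produced two daughter groups). The female's
DSI with the resident male enters *uncentered*, so the resident-present
main effect is the effect at DSI = 0; centering would change the main
effect's meaning and magnitude. Females present in two fissions
contribute independent choices.

## The synthetic generator

`SimConfig` defaults are the study conditions: 5 groups × 15 adult
females, at-risk fraction 0.41, gestation 176 days, dependency 365 days,
residency rule 7 observation days, ground-truth persistence coefficients
at the published odds ratios (0.81 baseline, 1.80 strong, 1.41 weak, 1.23
relatedness, 1.78 risk homophily, 147.01 interaction, 0.98 rank distance,
on the log-odds scale) and choice coefficients 3.63/1.25 (at risk) and
1.36/0.86 (not at risk). Where the emulated study does not state a value,
the default was set once to a field-realistic magnitude and documented
here: 1800 focal minutes per female-year (≈ 30 h, a plausible yearly
focal load per female); grooming 0.4% and resting-proximity 0.6% of scans
per partner at baseline; tie-class mix 0.30 strong / 0.40 weak / 0.30
inconsistent; tie-class rate multipliers ×4 (strong years) and ×0.25
(weak years) with lognormal dyad heterogeneity (sd 0.4 on the log scale);
kin multiplier ×3 for relatedness ≥ 0.125; agonistic rate 2 decided
contests per dyad-year with 10% upsets; census coverage 90% of days.
Behavioral counts are exposure-weighted Poisson draws; matrilines are
breadth-first family trees with one deliberately pedigree-less matriline
per group (~20% of females, emulating truncated records).

Fission outcomes come in two modes, drawn independently because they
answer different questions:

- **choice-first** (default): each female joins the resident male's
  daughter group with probability `logistic(g1 + g2·DSI_male)` using her
  risk class's coefficients. Individually realistic; any dyad-level
  persistence structure is then only what individual choices induce, so
  the persistence model fit to this mode correctly shows near-null dyadic
  effects.
- **dyad-target**: the bipartition of each group is sampled from an
  exponential family over proper bipartitions (both daughters non-empty),
  enumerated exactly for n ≤ 20 (2^(n−1) − 1 configurations). Couplings
  are calibrated so each dyad's co-membership margin matches
  `logistic(x'β)`: a scalar-offset bisection matches the mean margin,
  then Levenberg–Marquardt least-squares-projects the margin vector onto
  the achievable set, using the exact Jacobian (the co-membership
  covariance matrix under the enumerated distribution).

A point worth stating plainly: *exact* margin matching is generically
impossible. Co-membership indicators are transitive, so the moment
polytope of bipartitions excludes most target vectors (the corresponding
maximum-likelihood calibration problem is unbounded). The least-squares
projection leaves residuals of order 10⁻² on the worst dyads (median
~2×10⁻³), which is the closest any partition-valued generator can come to
"dyad persistence follows the logistic law".

## What the recovery experiments show — and what they cannot

The headline experiment (200 replicates, 5 fissions × 15 females,
dyad-target mode, β_strong = log 1.8, β_riskmatch = log 1.78, intercept
log 0.81, other coefficients 0; choice model at n = 500 females,
γ_resident = log 3.63) establishes:

- **Mean recovery**: every persistence coefficient and both choice
  coefficients are recovered within 3 Monte-Carlo standard errors of
  truth. The estimating equation is unbiased because the margins match
  (up to the projection residual).
- **Interval calibration is term-dependent.** 95% Wald CI coverage is
  nominal (0.92–0.98 across 200 replicates) for the dyad-local terms —
  tie-consistency dummies, relatedness, the relatedness × risk
  interaction, rank distance — and for both choice-model coefficients.
  It is *not* nominal for the intercept (≈ 0.68) and the risk-homophily
  term (≈ 0.50).

The undercoverage is not a bug and cannot be removed by a better
generator: a fission contributes a single partition, i.e. one draw of the
group's bulk configuration (split sizes, and how the at-risk class splits
across daughters). Global statistics such as the baseline persistence
and the homophily count are dominated by that configuration, so their
effective sample size is the number of fissions (5), not the number of
dyads (525); their replicate-to-replicate standard deviation exceeds the
independence-based Wald SE by a factor of ≈ 2–2.6. Dyad-local covariates
vary within a partition and are essentially unaffected. The practical
reading for users of the dyad-independent persistence model on real
fission data: trust the point estimates; trust Wald intervals for edge
covariates; treat intervals for the baseline and for nodematch-style
homophily terms as optimistic unless the number of fission events is
large.

Passing tests on the generator also do not certify behavior on real
data in other respects: the generator draws scan counts as independent
Poisson (no autocorrelation within follows, no observer effects), makes
reproductive states exactly observable, and keeps group membership fixed
between windows except at the fission itself. Pipeline-measured
covariates (DSI classes from finite focal samples) attenuate fitted
effects relative to truth-covariate fits — visible in the worked example,
where the weak-tie dummy shrinks toward zero; the recovery experiments
therefore feed the models truth covariates, isolating estimator bias from
measurement error by design.

## Problem sizes and tolerances

Test-suite problem sizes were chosen so the full suite is a
coffee-break run: recovery uses 200 replicates (the partition sampler
costs ~0.4 s per group of 15: enumeration is 16 383 partitions × 105
dyads, and each calibration iteration is one matvec plus one 105² GEMM);
oracle checks use exhaustive search at n ≤ 7 (≤ 5 040 orderings) and
iteratively refined grids (relative precision ~10⁻⁵ against fitter
tolerances of 10⁻³). The likelihood fitters converge to |grad| < 10⁻¹⁰;
fit determinism is exact, and pipeline reports hash-identically under a
fixed config and seed.

## Known limitations

- The I&SI search guarantees global optimality only where exhaustively
  verified (n ≤ 7); published heuristics differ in tie-breaking, so
  orders on larger matrices are reproducible (seeded) but not canonical.
- The bipartition sampler's exact enumeration caps at n = 20 females per
  group; larger groups would need the (not implemented) MCMC path.
- Relatedness ignores paternity entirely, as maternal pedigrees are the
  only input.
- The conditional logit has no random effects; repeated females across
  fissions are treated as independent choices.
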