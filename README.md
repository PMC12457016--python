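# fissionnet

Analysis pipeline for **post-fission group choice in wild primates**: given
long-term behavioral observation records from social groups that permanently
split ("fission") into two daughter groups, which social ties do individuals
preserve, and what predicts their choice of group?

The package was built around the study system of blue monkeys
(*Cercopithecus mitis*): matrilocal groups of philopatric adult females with
a single resident male, monitored by near-daily census, focal follows,
ad libitum agonistic records and birth records. It is aimed at behavioral
ecologists who have (or can emulate) that kind of field data and want a
tested, reusable implementation of the full chain from raw records to
fitted models — plus a synthetic-data generator with known ground truth, so
every stage can be validated without any field data.

## The statistical chain

**Dyadic sociality index (DSI).** For females *i, j* in one group and one
annual window,

    DSI_ij = 1/2 (G_ij / G_med) + 1/4 (R_ij / R_med) + 1/4 (R_ji / R_med)

where `G_ij` is the pair's grooming rate over their combined focal time and
`R_ij` (`R_ji`) the rate at which *i* (*j*) rested within 1 m of the other
during her own focal time; medians are over all included dyads of the same
group-window. DSI > 1 means above-median affiliation. If only one member
contributed focal data, the single proximity term gets weight 1/2. Ties are
"consistently strong" (DSI > 1 in both pre-fission years), "consistently
weak", or "inconsistent" (the reference class).

**I&SI dominance hierarchy.** From each group-year winner:loser matrix, the
ordinal ranking minimizing lexicographically the number *I*, then the summed
rank distance *SI*, of inconsistent dyads (lower-ranked won the majority).
Two-phase search: David's-score initialization, then pairwise-swap hill
climbing with seeded restarts; pinned to the exhaustive optimum at small *n*
by the test suite. Dyadic rank distance is Z-scored before modeling.

**Maternal relatedness.** From recorded mother links only: mother–offspring
0.5; sisters and grandmother–granddaughter 0.25; aunt–niece 0.125; first
cousins 0.0625; more distant detectable maternal kin 0.03125; unknown or
unrelated 0.

**Edge persistence (temporal network model).** A pre-fission tie persists
when both females join the same daughter group. With dyad-independent edge
covariates and a block-diagonal constraint (dyads only within parent
groups), the persistence component of a separable temporal exponential
random graph model factorizes into independent Bernoulli terms,

    log L = sum_dyads [ y_ij x_ij'b − log(1 + exp(x_ij'b)) ]

fit exactly by Newton iteration, with odds ratios, observed-information
Wald standard errors and AIC model comparison. Covariates: tie-consistency
dummies, relatedness, infanticide-risk homophily (both females pregnant or
lactating, or both not), relatedness × risk homophily, standardized rank
distance.

**Conditional logit of group choice.** Each female chooses between the two
daughter groups; choice probabilities depend only on attributes of the
alternatives, `P(a) = exp(x_a'g) / sum_b exp(x_b'g)` (no intercept;
female-level attributes cancel and enter only via interactions). Fitted by
Newton iteration on the exact likelihood, separately for females at risk of
infanticide and not at risk, with resident-male presence and its
interaction with the female's DSI with that male as predictors.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (script 01 writes the raw records under `scratch/`, everything else
writes small tables under `results/`):

```bash
python analysis/01_simulate.py       # population + two independent fission draws
python analysis/02_sociality.py      # DSI per dyad and year + male DSI
python analysis/03_dominance.py      # I&SI hierarchies
python analysis/04_attributes.py     # reproductive states, residency
python analysis/05_persistence.py    # edge-persistence model + AIC
python analysis/06_group_choice.py   # conditional logit by risk class
python analysis/07_report.py         # full pipeline in one pass
```

Script 02 prints, for the default configuration (5 groups × 15 females):

```
525 dyads across 5 fissions
DSI > 1 in the pre-fission year: 50%
consistency
consistently_weak      0.35
consistently_strong    0.34
inconsistent           0.31
```

— half of all dyads sit above their group median by construction of the
index, and the recovered consistency-class mix is close to the generating
mix (0.40/0.30/0.30), the gap being honest measurement noise in dyads near
the median. Script 06 prints (choice-first draw, at-risk females):

```
at_risk: 27 females, 23 joined the resident male's group
            term   coef   se  odds_ratio      z    p
resident_present  2.056 0.88       7.814  2.335 0.02
```

— at-risk females prefer the daughter group holding their original
resident male (the generating odds ratio at DSI = 0 is 3.63; a single draw
of 27 females estimates it with wide error), while the same fit for
not-at-risk females shows no such preference. Script 05 fits the
persistence model on the dyad-target draw and selects the full model over
the null by AIC (610 vs 702 for this seed).

The same stages are available as a CLI (`fissionnet simulate|dsi|ranks|
attributes|fit-persistence|fit-choice|run|report`) for use on your own
CSV records.

## Input schemas

`read_dataset(dir)` expects UTF-8 CSVs with ISO-8601 dates; unknown values
are empty fields; id-set fields are semicolon-joined. One example row each:

| file | columns | example |
| --- | --- | --- |
| individuals.csv | id, sex, birth_date, mother_id, adult_from | `f01,female,2008-01-01,f00,2015-01-01` |
| focal_scans.csv | focal_id, date, minute_index, activity, partner_id, proximity_partner_ids | `f01,2019-05-02,12,social_groom,f02,` |
| agonistic.csv | date, winner_id, loser_id, group_id | `2020-01-15,f01,f02,G` |
| census.csv | date, group_id, present_ids | `2020-01-15,G,f01;f02;m01` |
| births.csv | mother_id, infant_id, birth_date, death_date | `f01,f01i,2020-08-01,` |
| fissions.csv | event_id, parent_group_id, subgrouping_onset, fission_date, resident_male_daughter | `F1,G,2020-03-01,2020-05-01,A` |
| fission_assignments.csv | event_id, individual_id, daughter | `F1,f01,A` |

Activities are `feed / move / social_groom / rest`; `partner_id` only with
grooming; proximity partners never while moving (only resting-within-1-m
proximity feeds the DSI).

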