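"""Generate the synthetic study population used by the downstream analyses.

Five one-male groups of 15 adult females (two annual windows of focal
data each), with kin-structured affiliative rates, a latent dominance
hierarchy, birth timelines and a resident male per group; each group then
fissions into two daughter groups.

Fission outcomes are drawn twice, independently, as the two generator
modes serve different analyses: a dyad-target draw (partition calibrated
to the dyadic persistence law) drives the edge-persistence chain
(scripts 02-05, 07), and a choice-first draw (each female follows the
conditional-logit law for the resident male's group) drives the
group-choice analysis (script 06).  Raw records are large and go to
scratch/.
"""

import copy
import json
from pathlib import Path

from fissionnet.data_io import write_dataset
from fissionnet.synthetic_data import SimConfig, simulate_fission, simulate_population

import numpy as np

DATA_DIR = Path("scratch/synthetic_data")
DATA_DIR_CHOICE = Path("scratch/synthetic_data_choice")


def main() -> None:
    cfg = SimConfig(seed=2025)
    ds, truth = simulate_population(cfg)

    ds.fissions = simulate_fission(
        cfg, truth, rng=np.random.default_rng(cfg.seed + 1), mode="dyad_target"
    )
    write_dataset(ds, DATA_DIR)
    truth_out = {
        "beta": truth.beta,
        "gamma_at_risk": list(truth.gamma_at_risk),
        "gamma_not_at_risk": list(truth.gamma_not_at_risk),
        "groups": {
            g.group_id: {
                "latent_order": g.latent_order,
                "at_risk": {k: bool(v) for k, v in g.at_risk.items()},
                "assignments": g.assignments,
            }
            for g in truth.groups
        },
    }
    (DATA_DIR / "truth.json").write_text(json.dumps(truth_out, indent=2, sort_keys=True))

    ds_choice = copy.copy(ds)
    ds_choice.fissions = simulate_fission(
        cfg, truth, rng=np.random.default_rng(cfg.seed + 2), mode="choice_first"
    )
    write_dataset(ds_choice, DATA_DIR_CHOICE)

    n_f = sum(len(g.females) for g in truth.groups)
    print(f"simulated {cfg.n_groups} groups, {n_f} adult females")
    print(f"{len(ds.focal_scans)} focal-scan minutes, {len(ds.agonistic)} agonistic records")
    print(f"wrote dyad-target fissions to {DATA_DIR}/ (persistence chain)")
    print(f"wrote choice-first fissions to {DATA_DIR_CHOICE}/ (group-choice analysis)")


if __name__ == "__main__":
    main()
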