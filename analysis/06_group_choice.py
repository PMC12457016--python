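"""Conditional logit of daughter-group choice, by infanticide-risk class.

Each female chooses between the daughter group holding her original
group's resident male and the one without him; the model asks whether
male presence (and its interaction with her DSI with that male) predicts
the choice, separately for females at risk of infanticide and females
not at risk.  Writes results/choices_{at_risk,not_at_risk}.csv and
results/choice_fits.md.
"""

from pathlib import Path

import pandas as pd

from fissionnet.attributes import female_state_table, residency_timeline
from fissionnet.data_io import read_dataset
from fissionnet.group_choice import build_choice_datasets, fit_conditional_logit
from fissionnet.persistence_model import ModelFitError
from fissionnet.sociality import male_dsi_table, sociality_table

DATA_DIR = Path("scratch/synthetic_data_choice")
RESULTS = Path("results")


def main() -> None:
    ds = read_dataset(DATA_DIR)
    RESULTS.mkdir(exist_ok=True)
    states, male = [], []
    for fission in ds.fissions:
        soc = sociality_table(ds, fission)
        females = sorted(set(soc["i_id"]) | set(soc["j_id"]))
        states.append(
            female_state_table(ds, females, fission.fission_date,
                               fission_id=fission.event_id)
        )
        resident = residency_timeline(ds, fission.parent_group_id).resident_on(
            fission.fission_date
        )
        male.append(male_dsi_table(ds, fission, resident, females))
    at_risk, not_at_risk = build_choice_datasets(
        pd.concat(states, ignore_index=True), pd.concat(male, ignore_index=True),
        ds.fissions,
    )
    lines = ["# Post-fission group choice", ""]
    for name, table in (("at_risk", at_risk), ("not_at_risk", not_at_risk)):
        table.to_csv(RESULTS / f"choices_{name}.csv", index=False)
        n = len(table) // 2
        with_male = table[(table["resident_present"] == 1) & (table["chosen"] == 1)]
        print(f"{name}: {n} females, {len(with_male)} joined the resident male's group")
        lines += [f"## {name.replace('_', ' ')} females (n = {n})", ""]
        try:
            fit = fit_conditional_logit(table)
            print(fit.table.round(3).to_string(index=False))
            for rec in fit.table.round(4).to_dict(orient="records"):
                lines.append(
                    f"- {rec['term']}: OR {rec['odds_ratio']}, z {rec['z']}, p {rec['p']}"
                )
        except ModelFitError as exc:
            print(f"{name}: not estimable ({exc})")
            lines.append(f"not estimable: {exc}")
        lines.append("")
    (RESULTS / "choice_fits.md").write_text("\n".join(lines))
    print(f"wrote choice tables and {RESULTS}/choice_fits.md")


if __name__ == "__main__":
    main()
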