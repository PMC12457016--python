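"""Edge-persistence model: which female-female ties survive the fission?

Joins the dyad covariates (tie consistency, maternal relatedness, risk
homophily, standardized rank distance) with the persistence outcome and
fits the Bernoulli persistence likelihood, comparing the full model with
a null (intercept-only) model by AIC.  Writes results/persistence.csv and
results/persistence_fit.md.
"""

from pathlib import Path

import pandas as pd

from fissionnet.attributes import Pedigree, female_state_table
from fissionnet.data_io import read_dataset
from fissionnet.dominance import build_contest_matrix, isi_order
from fissionnet.persistence_model import (
    build_persistence_dataset,
    compare_models,
    fit_persistence,
    persistence_rate,
)
from fissionnet.sociality import sociality_table

DATA_DIR = Path("scratch/synthetic_data")
RESULTS = Path("results")


def main() -> None:
    ds = read_dataset(DATA_DIR)
    RESULTS.mkdir(exist_ok=True)
    soc, states, hier = [], [], {}
    for fission in ds.fissions:
        t = sociality_table(ds, fission)
        soc.append(t)
        females = sorted(set(t["i_id"]) | set(t["j_id"]))
        states.append(
            female_state_table(ds, females, fission.fission_date,
                               fission_id=fission.event_id)
        )
        m = build_contest_matrix(ds, fission.parent_group_id,
                                 fission.fission_date.year,
                                 until=fission.fission_date)
        hier[fission.event_id] = isi_order(m, seed=0)
    data = build_persistence_dataset(
        pd.concat(soc, ignore_index=True), hier,
        pd.concat(states, ignore_index=True),
        Pedigree.from_dataset(ds), ds.fissions,
    )
    data.to_csv(RESULTS / "persistence.csv", index=False)

    fits = {"null": fit_persistence(data, terms=()),
            "full": fit_persistence(data)}
    aic = compare_models(fits)
    print(f"{len(data)} dyads; persistence rate {persistence_rate(data):.2f}")
    print(fits["full"].table.round(3).to_string(index=False))
    print(aic.round(1).to_string(index=False))

    def md_table(df):
        cols = list(df.columns)
        head = "| " + " | ".join(cols) + " |"
        sep = "| " + " | ".join("---" for _ in cols) + " |"
        body = ["| " + " | ".join(str(v) for v in row) + " |"
                for row in df.itertuples(index=False)]
        return "\n".join([head, sep, *body])

    lines = ["# Edge persistence fit", "",
             f"{len(data)} dyads, persistence rate "
             f"{persistence_rate(data):.3f}", "",
             md_table(fits["full"].table.round(4)), "",
             "## AIC comparison", "", md_table(aic.round(2)), ""]
    (RESULTS / "persistence_fit.md").write_text("\n".join(lines))
    print(f"wrote {RESULTS}/persistence.csv and {RESULTS}/persistence_fit.md")


if __name__ == "__main__":
    main()
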