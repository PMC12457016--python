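"""End-to-end orchestration: raw records -> indices -> models -> report.

The run configuration names every biological constant used downstream
(annual window length, gestation length, infant dependency period,
residency rule, DSI threshold) so a reuser can change them without
touching code.  A run is deterministic given its config and inputs; the
report carries a provenance block (config hash, seed, package version)
and every number in it is recomputable from the inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .attributes import (
    GESTATION_DAYS,
    INFANT_DEPENDENCY_DAYS,
    RESIDENCY_DAYS,
    Pedigree,
    female_state_table,
    residency_timeline,
)
from .data_io import BehaviorDataset, read_dataset
from .dominance import build_contest_matrix, isi_order, rank_distance_table, rank_table
from .group_choice import (
    CHOICE_TERMS,
    ChoiceFit,
    build_choice_datasets,
    fit_conditional_logit,
)
from .persistence_model import (
    FULL_TERMS,
    ModelFitError,
    PersistenceFit,
    build_persistence_dataset,
    compare_models,
    fit_persistence,
    persistence_rate,
)
from .sociality import DSI_THRESHOLD, WINDOW_DAYS, male_dsi_table, sociality_table

log = logging.getLogger("fissionnet")


@dataclasses.dataclass
class RunConfig:
    """Inputs, constants and term lists for one full pipeline run.

    The defaults are the field study's rule constants: 365-day annual
    windows, 176-day gestation, 365-day infant dependency, the 7-observation-
    day residency rule and a DSI consistency threshold of 1.
    """

    input_dir: str = "."
    output_dir: str = "results"
    window_days: int = WINDOW_DAYS
    gestation_days: int = GESTATION_DAYS
    dependency_days: int = INFANT_DEPENDENCY_DAYS
    residency_days: int = RESIDENCY_DAYS
    dsi_threshold: float = DSI_THRESHOLD
    persistence_terms: tuple[str, ...] = FULL_TERMS
    choice_terms: tuple[str, ...] = CHOICE_TERMS
    seed: int = 0
    zero_median_fallback: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("persistence_terms", "choice_terms"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def hash(self) -> str:
        """Hash of the scientific configuration (locator paths excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("input_dir")
        payload.pop("output_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _fit_to_dict(fit: PersistenceFit | ChoiceFit) -> dict:
    out = {
        "table": fit.table.to_dict(orient="records"),
        "loglik": fit.loglik,
    }
    if isinstance(fit, PersistenceFit):
        out["aic"] = fit.aic
        out["n_dyads"] = fit.n_dyads
    else:
        out["n_choices"] = fit.n_choices
    return out


def run_pipeline(
    cfg: RunConfig, ds: BehaviorDataset | None = None
) -> dict:
    """Execute every stage and return the run report as a plain dict.

    Stages: data_io -> sociality -> dominance -> attributes ->
    persistence model (with AIC comparison against the null) -> group
    choice.  Intermediate tables are written under ``cfg.output_dir``.
    A choice model that cannot be estimated (no females in a risk class,
    or separated choices) is reported as not estimable rather than
    aborting the run.
    """
    if ds is None:
        ds = read_dataset(cfg.input_dir)
    if not ds.fissions:
        raise ValueError("dataset contains no fission events")
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    soc_tables, male_tables, state_tables, hier = [], [], [], {}
    rank_rows, rankdist_rows = [], []
    per_fission = {}
    for fission in ds.fissions:
        soc = sociality_table(
            ds,
            fission,
            threshold=cfg.dsi_threshold,
            zero_median_fallback=cfg.zero_median_fallback,
        )
        soc_tables.append(soc)
        timeline = residency_timeline(
            ds, fission.parent_group_id, residency_days=cfg.residency_days
        )
        resident = timeline.resident_on(fission.fission_date) or timeline.resident_on(
            fission.subgrouping_onset
        )
        if resident is None:
            raise ValueError(
                f"fission {fission.event_id}: no resident male on the fission date"
            )
        females = sorted(set(soc["i_id"]) | set(soc["j_id"]))
        male_tables.append(
            male_dsi_table(
                ds,
                fission,
                resident,
                females,
                zero_median_fallback=cfg.zero_median_fallback,
            )
        )
        states = female_state_table(
            ds,
            females,
            fission.fission_date,
            fission_id=fission.event_id,
            gestation_days=cfg.gestation_days,
            infant_dependency_days=cfg.dependency_days,
        )
        state_tables.append(states)
        matrix = build_contest_matrix(
            ds,
            fission.parent_group_id,
            fission.fission_date.year,
            until=fission.fission_date,
        )
        h = isi_order(matrix, seed=cfg.seed)
        hier[fission.event_id] = h
        rank_rows.append(rank_table(h, fission.parent_group_id, fission.event_id))
        rankdist_rows.append(rank_distance_table(h, fission.event_id))
        per_fission[fission.event_id] = {
            "n_eligible_females": len(females),
            "n_dyads": len(soc),
            "resident_male": resident,
            "hierarchy_I": h.I,
            "hierarchy_SI": h.SI,
            "n_at_risk": int(states["at_risk"].sum()),
        }
        log.info(
            "fission %s: %d eligible females, %d dyads, resident %s",
            fission.event_id,
            len(females),
            len(soc),
            resident,
        )

    sociality = pd.concat(soc_tables, ignore_index=True)
    male_dsi = pd.concat(male_tables, ignore_index=True)
    states = pd.concat(state_tables, ignore_index=True)
    ranks = pd.concat(rank_rows, ignore_index=True)
    pedigree = Pedigree.from_dataset(ds)

    persistence = build_persistence_dataset(
        sociality, hier, states, pedigree, ds.fissions
    )
    fits = {
        "null": fit_persistence(persistence, terms=()),
        "full": fit_persistence(persistence, terms=cfg.persistence_terms),
    }
    aic_table = compare_models(fits)

    at_risk, not_at_risk = build_choice_datasets(states, male_dsi, ds.fissions)
    choice_fits = {}
    for name, table in (("at_risk", at_risk), ("not_at_risk", not_at_risk)):
        try:
            choice_fits[name] = _fit_to_dict(
                fit_conditional_logit(table, terms=cfg.choice_terms)
            )
        except ModelFitError as exc:
            choice_fits[name] = {"not_estimable": str(exc)}

    sociality.to_csv(outdir / "dyads.csv", index=False)
    male_dsi.to_csv(outdir / "male_dsi.csv", index=False)
    states.to_csv(outdir / "female_states.csv", index=False)
    ranks.to_csv(outdir / "ranks.csv", index=False)
    pd.concat(rankdist_rows, ignore_index=True).to_csv(
        outdir / "dyad_rankdist.csv", index=False
    )
    persistence.to_csv(outdir / "persistence.csv", index=False)
    at_risk.to_csv(outdir / "choices_at_risk.csv", index=False)
    not_at_risk.to_csv(outdir / "choices_not_at_risk.csv", index=False)

    report = {
        "per_fission": per_fission,
        "n_dyads_total": int(len(persistence)),
        "persistence_rate": persistence_rate(persistence),
        "persistence_fits": {k: _fit_to_dict(v) for k, v in fits.items()},
        "aic_comparison": aic_table.to_dict(orient="records"),
        "choice_fits": choice_fits,
        "n_females_choice": {
            "at_risk": int(len(at_risk) // 2),
            "not_at_risk": int(len(not_at_risk) // 2),
        },
        "provenance": {
            "config_hash": cfg.hash(),
            "seed": cfg.seed,
            "version": __version__,
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _coef_markdown(records: list[dict]) -> list[str]:
    lines = ["| predictor | odds ratio | s.e. | p |", "| --- | --- | --- | --- |"]
    for r in records:
        lines.append(
            f"| {r['term']} | {r['odds_ratio']:.2f} | {r['se']:.2f} | {r['p']:.3g} |"
        )
    return lines


def render_report(report: dict, fmt: str = "markdown") -> str:
    """Render a run report as markdown (coefficient tables in odds ratio | s.e. | p
    order) or as round-trippable JSON."""
    if fmt == "json":
        return json.dumps(report, indent=2, sort_keys=True)
    if fmt != "markdown":
        raise ValueError(f"unknown report format {fmt!r}")
    lines = ["# Fission analysis report", ""]
    lines.append(
        f"Provenance: config `{report['provenance']['config_hash']}`, "
        f"seed {report['provenance']['seed']}, version {report['provenance']['version']}"
    )
    lines.append("")
    lines.append("## Fissions")
    lines.append("")
    lines.append("| fission | eligible females | dyads | at risk | resident male | I | SI |")
    lines.append("| --- | --- | --- | --- | --- | --- | --- |")
    for fid, info in report["per_fission"].items():
        lines.append(
            f"| {fid} | {info['n_eligible_females']} | {info['n_dyads']} | "
            f"{info['n_at_risk']} | {info['resident_male']} | "
            f"{info['hierarchy_I']} | {info['hierarchy_SI']} |"
        )
    lines.append("")
    lines.append("## Edge persistence")
    lines.append("")
    lines.append(
        f"{report['n_dyads_total']} dyads; empirical persistence rate "
        f"{report['persistence_rate']:.3f}"
    )
    lines.append("")
    lines.extend(_coef_markdown(report["persistence_fits"]["full"]["table"]))
    lines.append("")
    lines.append("AIC comparison:")
    lines.append("")
    lines.append("| model | AIC | dAIC |")
    lines.append("| --- | --- | --- |")
    for rec in report["aic_comparison"]:
        lines.append(f"| {rec['model']} | {rec['aic']:.1f} | {rec['delta_aic']:.1f} |")
    lines.append("")
    lines.append("## Post-fission group choice")
    for name in ("at_risk", "not_at_risk"):
        fit = report["choice_fits"][name]
        n = report["n_females_choice"][name]
        lines.append("")
        lines.append(f"### {name.replace('_', ' ')} females (n = {n})")
        lines.append("")
        if "not_estimable" in fit:
            lines.append(f"not estimable: {fit['not_estimable']}")
        else:
            lines.extend(_coef_markdown(fit["table"]))
    lines.append("")
    return "\n".join(lines)
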