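"""End-to-end pipeline: simulate -> score -> fit -> select -> assign ->
associate -> ebayes, with CSV interchange and JSON provenance records.

Every stage writes its output table(s) plus a provenance JSON (config
hash, seed, row counts in/out) and can be re-run from the intermediates
on disk.  CSVs use UTF-8 with empty fields for missing values.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import selection as msel
from . import simulate as sim
from .associations import association_table, fit_binary_outcome, fit_continuous_outcome
from .basis import FPBasis
from .ebayes import (
    fit_analyte_models,
    lod_filter,
    planned_contrasts,
    select_metabolomic_features,
)
from .smfq import fitting_sample, score_table
from .trajectory import TrajectoryModel

logger = logging.getLogger(__name__)

STAGES = ("simulate", "score", "fit", "select", "assign", "associate", "ebayes")


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml``)."""

    outdir: Path
    seed: int = 0
    generator: dict = field(default_factory=dict)
    outcomes: list = field(default_factory=list)
    model_grid: dict = field(default_factory=dict)
    gates: dict = field(default_factory=dict)
    association: dict = field(default_factory=dict)
    fdr_q: float = 0.1
    min_measurements: int = 3

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "outdir" not in raw:
            raise PipelineConfigError("config must set 'outdir'")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        raw["outdir"] = Path(raw["outdir"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = {k: v for k, v in vars(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_provenance(outdir: Path, stage: str, cfg: PipelineConfig, seed, counts):
    rec = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": seed,
        "row_counts": counts,
    }
    (outdir / f"provenance_{stage}.json").write_text(json.dumps(rec, indent=2))


def _csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, na_rep="")


def _read_required(path: Path, columns=None) -> pd.DataFrame:
    if not path.exists():
        raise PipelineConfigError(f"required intermediate {path} is missing")
    df = pd.read_csv(path)
    if columns:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise PipelineConfigError(f"{path.name} lacks column(s) {missing}")
    return df


def stage_simulate(cfg: PipelineConfig) -> dict:
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    gen_kwargs = dict(cfg.generator)
    gen_kwargs.setdefault("seed", cfg.seed)
    gcfg = sim.GeneratorConfig(**gen_kwargs)
    cohort = sim.generate_cohort(gcfg)
    _csv(cohort.occasions, outdir / "occasions.csv")
    _csv(cohort.covariates, outdir / "covariates.csv")

    outcome_cfgs = []
    for spec in cfg.outcomes:
        spec = dict(spec)
        kind = spec.pop("kind", "binary")
        if kind == "binary":
            spec.setdefault("covariate_effects", dict(sim.DEFAULT_COVARIATE_EFFECTS))
            spec["class_risk_ratios"] = {
                int(k): float(v) for k, v in spec.get("class_risk_ratios", {}).items()
            }
            outcome_cfgs.append(sim.OutcomeEffectConfig(**spec))
        else:
            spec["class_shifts"] = {
                int(k): float(v) for k, v in spec.get("class_shifts", {}).items()
            }
            outcome_cfgs.append(sim.ContinuousOutcomeConfig(**spec))
    if not outcome_cfgs:
        outcome_cfgs = [sim.DEFAULT_DEPRESSION_OUTCOME]
    outcomes = sim.generate_outcomes(cohort, outcome_cfgs, seed=cfg.seed + 1)
    _csv(outcomes, outdir / "outcomes.csv")

    panel = sim.generate_biomarker_panel(
        cohort, sim.default_protein_panel_spec(), seed=cfg.seed + 2
    )
    values = panel.values.reset_index()
    _csv(values, outdir / "biomarkers.csv")
    _csv(panel.metadata, outdir / "biomarker_meta.csv")
    counts = {
        "subjects": cohort.n_subjects,
        "occasions": len(cohort.occasions),
        "outcomes": len(outcomes),
        "analytes": len(panel.metadata),
    }
    _write_provenance(outdir, "simulate", cfg, cfg.seed, counts)
    return counts


def stage_score(cfg: PipelineConfig) -> dict:
    outdir = cfg.outdir
    occ = _read_required(outdir / "occasions.csv")
    scores = score_table(occ)
    _csv(scores, outdir / "scores.csv")
    counts = {"occasions_in": len(occ), "scores_out": int(scores["score"].notna().sum())}
    _write_provenance(outdir, "score", cfg, None, counts)
    return counts


def _grid_from_config(cfg: PipelineConfig):
    grid = cfg.model_grid
    g_range = grid.get("n_classes", [1, 2, 3, 4, 5, 6])
    if isinstance(g_range, dict):
        g_range = list(range(g_range.get("min", 1), g_range.get("max", 6) + 1))
    structures = tuple(grid.get("structures", ["none"]))
    bases = [
        FPBasis(powers=tuple(p)) for p in grid.get("fp_powers", [[1.0, 2.0]])
    ]
    multistart = grid.get("multistart", {})
    return g_range, structures, bases, multistart


def stage_fit(cfg: PipelineConfig) -> dict:
    outdir = cfg.outdir
    scores = _read_required(outdir / "scores.csv", ["subject_id", "age", "score"])
    fit_df = fitting_sample(scores, cfg.min_measurements)
    g_range, structures, bases, multistart = _grid_from_config(cfg)
    candidates = msel.fit_candidate_grid(
        fit_df,
        n_classes_range=g_range,
        structures=structures,
        bases=bases,
        seed=cfg.seed,
        n_starts=multistart.get("n_starts", 50),
        burn_iters=multistart.get("burn_iters", 10),
        final_iters=multistart.get("final_iters", 500),
    )
    for c in candidates:
        (outdir / f"model_{c.label.replace('|', '_')}.json").write_text(
            c.model.to_json()
        )
    _csv(pd.DataFrame([c.to_record() for c in candidates]), outdir / "fit_indices.csv")
    counts = {
        "fit_subjects": int(fit_df["subject_id"].nunique()),
        "candidates": len(candidates),
    }
    _write_provenance(outdir, "fit", cfg, cfg.seed, counts)
    return counts


def stage_select(cfg: PipelineConfig) -> dict:
    outdir = cfg.outdir
    scores = _read_required(outdir / "scores.csv", ["subject_id", "age", "score"])
    fit_df = fitting_sample(scores, cfg.min_measurements)
    idx = _read_required(outdir / "fit_indices.csv")
    candidates = []
    for _, row in idx.iterrows():
        model = TrajectoryModel.from_json(
            (outdir / f"model_{row['label'].replace('|', '_')}.json").read_text()
        )
        candidates.append(msel.summarise_candidate(model, fit_df))
    gates = msel.SelectionGates(**cfg.gates) if cfg.gates else msel.SelectionGates()
    report = msel.select_model(candidates, gates)
    (outdir / "selection.json").write_text(report.to_json())
    if report.chosen is not None:
        curves = msel.class_curve_table(report.chosen.model, fit_df)
        _csv(curves, outdir / "class_curves.csv")
        (outdir / "model_chosen.json").write_text(report.chosen.model.to_json())
        try:
            plot_trajectories(curves, outdir / "trajectories.svg")
        except Exception as exc:  # plotting is best-effort
            logger.warning("trajectory plot failed: %s", exc)
    counts = {"candidates": len(candidates), "chosen": report.chosen.label if report.chosen else None}
    _write_provenance(outdir, "select", cfg, None, counts)
    return counts


def stage_assign(cfg: PipelineConfig) -> dict:
    outdir = cfg.outdir
    scores = _read_required(outdir / "scores.csv", ["subject_id", "age", "score"])
    model = TrajectoryModel.from_json((outdir / "model_chosen.json").read_text())
    post = model.predict_proba(scores)
    df = post.to_frame()
    _csv(df, outdir / "posteriors.csv")
    fit_n = fitting_sample(scores, cfg.min_measurements)["subject_id"].nunique()
    counts = {
        "subjects_total": len(df),
        "fit_subsample": int(fit_n),
        "predicted_remainder": int(len(df) - fit_n),
    }
    _write_provenance(outdir, "assign", cfg, None, counts)
    return counts


def stage_associate(cfg: PipelineConfig) -> dict:
    outdir = cfg.outdir
    cov = _read_required(outdir / "covariates.csv", ["subject_id"])
    outcomes = _read_required(outdir / "outcomes.csv", ["subject_id"])
    post = _read_required(outdir / "posteriors.csv", ["subject_id", "modal_class"])
    df = cov.merge(outcomes, on="subject_id").merge(
        post[["subject_id", "modal_class"]], on="subject_id"
    )
    df = df.rename(columns={"modal_class": "trajectory_class"})
    assoc_cfg = cfg.association
    binary = assoc_cfg.get("binary_outcomes")
    continuous = assoc_cfg.get("continuous_outcomes", [])
    if binary is None:
        binary = [c for c in outcomes.columns if c != "subject_id"]
    model = assoc_cfg.get("model", "adjusted")
    results = []
    for outcome in binary:
        results += fit_binary_outcome(df, outcome, model=model)
    for outcome in continuous:
        results += fit_continuous_outcome(df, outcome, model=model)
    table = association_table(results, q=cfg.fdr_q)
    _csv(table, outdir / "associations.csv")
    counts = {"models": len(results), "rows": len(table)}
    _write_provenance(outdir, "associate", cfg, None, counts)
    return counts


def stage_ebayes(cfg: PipelineConfig) -> dict:
    outdir = cfg.outdir
    cov = _read_required(outdir / "covariates.csv", ["subject_id"])
    post = _read_required(outdir / "posteriors.csv", ["subject_id", "modal_class"])
    values = _read_required(outdir / "biomarkers.csv").set_index("subject_id")
    meta = _read_required(outdir / "biomarker_meta.csv", ["analyte", "family"])
    panel = sim.BiomarkerPanel(
        values=values,
        censored=pd.DataFrame(False, index=values.index, columns=values.columns),
        metadata=meta,
    )
    filtered = lod_filter(panel)
    filtered = select_metabolomic_features(filtered)
    sample = cov.merge(post[["subject_id", "modal_class"]], on="subject_id")
    sample = sample.rename(columns={"modal_class": "trajectory_class"})
    fits = fit_analyte_models(
        filtered.values, sample, model=cfg.association.get("model", "adjusted")
    )
    eb = planned_contrasts(fits, q=cfg.fdr_q)
    _csv(eb.table, outdir / "ebayes_results.csv")
    try:
        plot_volcano(eb.table, outdir / "volcano.svg")
    except Exception as exc:  # plotting is best-effort
        logger.warning("volcano plot failed: %s", exc)
    counts = {
        "analytes_in": len(panel.metadata),
        "analytes_retained": len(filtered.metadata),
        "tests": len(eb.table),
    }
    _write_provenance(outdir, "ebayes", cfg, None, counts)
    return counts


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "score": stage_score,
    "fit": stage_fit,
    "select": stage_select,
    "assign": stage_assign,
    "associate": stage_associate,
    "ebayes": stage_ebayes,
}


def run_pipeline(cfg: PipelineConfig, stages=STAGES) -> dict:
    """Run the requested stages in order; halts on the failing stage."""
    summary = {}
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise PipelineConfigError(f"unknown stage {stage!r}")
        try:
            summary[stage] = _STAGE_FUNCS[stage](cfg)
            logger.info("stage %s: %s", stage, summary[stage])
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return summary


def plot_trajectories(curves: pd.DataFrame, path) -> None:
    """Class mean trajectories with 95% bands (vector output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for cls, grp in curves.groupby("class"):
        ax.plot(grp["age"], grp["mean"], label=f"class {cls}")
        if {"ci_low", "ci_high"} <= set(grp.columns):
            ax.fill_between(grp["age"], grp["ci_low"], grp["ci_high"], alpha=0.2)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("predicted mean symptom score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_volcano(table: pd.DataFrame, path) -> None:
    """Volcano plot of moderated contrast results."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    contrasts = table["contrast"].unique()
    fig, axes = plt.subplots(1, len(contrasts), figsize=(4 * len(contrasts), 4),
                             squeeze=False)
    for ax, contrast in zip(axes[0], contrasts):
        sub = table[table["contrast"] == contrast]
        colors = np.where(sub["fdr_significant"], "tab:red", "tab:gray")
        ax.scatter(sub["estimate"], sub["neg_log10_p"], s=12, c=colors)
        ax.set_title(contrast)
        ax.set_xlabel("estimate (log scale)")
        ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
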