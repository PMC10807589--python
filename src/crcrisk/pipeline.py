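"""End-to-end orchestration with a single structured config file.

Two modes mirror how the score is used in practice:

* ``discover`` — screen a labeled cohort, reduce the panel by iterative
  subtraction, derive ROC cutoffs and metrics (in-cohort construction);
* ``apply`` — score any cohort with a frozen panel + cutoff (external
  validation); no screening stage is executed.

Every run writes its tables plus a manifest of input checksums, parameters
and the stages executed, so a reproduction attempt is auditable. Identical
config + seed produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .cohort import VariantDialect, build_cohort, read_clinical_table, read_variant_table
from .immune import ExpressionProfile, compare_groups_fdr, normalize_expression, ssgsea_scores, tls_score, bundled_immune_sets, read_gmt
from .scoring import DEFAULT_GENE_SET, DEFAULT_PENALTY_POINTS, G8Model, ScoreModel
from .survival import fit_survival

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]

_ALLOWED_KEYS = {
    "mode",
    "variants",
    "clinical",
    "expression",
    "gene_sets_gmt",
    "dialect",
    "region_size_mb",
    "tmb_threshold",
    "top_k",
    "gene_set",
    "penalty_points",
    "cutoff",
    "seed",
    "outdir",
}


@dataclass
class PipelineConfig:
    """Validated run configuration (unknown keys are rejected)."""

    variants: str
    clinical: str
    outdir: str
    mode: str = "discover"
    expression: str | None = None
    gene_sets_gmt: str | None = None
    dialect: Mapping[str, str] | None = None
    region_size_mb: float = 38.0
    tmb_threshold: float = 10.0
    top_k: int = 30
    gene_set: list[str] = field(default_factory=lambda: list(DEFAULT_GENE_SET))
    penalty_points: int = DEFAULT_PENALTY_POINTS
    cutoff: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("discover", "apply"):
            raise ValueError(f"mode must be 'discover' or 'apply', got {self.mode!r}")
        if self.mode == "apply" and self.cutoff is None:
            raise ValueError("apply mode requires a frozen cutoff")


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict[str, Any]
    results: Any  # G8Results in discover mode, scores frame in apply mode


def _write_tsv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kwargs)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the configured stages; abort names the failing stage."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": {
            k: v for k, v in dataclasses.asdict(config).items()
        },
        "inputs": {},
        "stages": [],
    }
    for key in ("variants", "clinical", "expression", "gene_sets_gmt"):
        p = getattr(config, key)
        if p:
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}

    stage = "load"
    try:
        dialect = VariantDialect(**config.dialect) if config.dialect else None
        variants, errors = read_variant_table(config.variants, dialect=dialect)
        if errors:
            raise ValueError(f"{len(errors)} malformed variant rows, e.g. {errors[:3]}")
        clinical = read_clinical_table(config.clinical)
        gene_universe = None
        if config.mode == "apply":
            # guarantee panel columns exist even if unmutated in this cohort
            observed = sorted({v.gene for v in variants})
            gene_universe = sorted(set(observed) | set(config.gene_set))
        cohort = build_cohort(
            variants,
            clinical,
            region_size_mb=config.region_size_mb,
            tmb_threshold=config.tmb_threshold,
            gene_universe=gene_universe,
        )
        manifest["stages"].append(stage)

        results: Any
        if config.mode == "discover":
            stage = "screen+subtract+score"
            model = G8Model(
                cohort.labeled_subset(),
                top_k=config.top_k,
                penalty_points=config.penalty_points,
            )
            res = model.fit()
            _write_tsv(res.screen, outdir / "screen.tsv")
            _write_tsv(res.trace.to_frame(), outdir / "trace.tsv", index=False)
            _write_tsv(res.scores_frame(), outdir / "scores.tsv", index_label="sample")
            metrics = pd.DataFrame(
                {
                    "g8": res.metrics_g8.to_dict(),
                    "g8plus": res.metrics_g8plus.to_dict(),
                }
            )
            metrics.loc["auc"] = [res.roc_g8.auc, res.roc_g8plus.auc]
            metrics.loc["cutoff"] = [
                res.roc_g8.chosen_cutoff,
                res.roc_g8plus.chosen_cutoff,
            ]
            metrics.loc["tmb_auc"] = [res.tmb_roc.auc, res.tmb_roc.auc]
            _write_tsv(metrics, outdir / "metrics.tsv", index_label="quantity", na_rep="NA")
            (outdir / "summary.txt").write_text(res.summary() + "\n")
            results = res
            score_series = res.g8plus
            score_cohort = model.cohort
        else:
            stage = "apply_frozen_model"
            frozen = ScoreModel(
                gene_set=tuple(config.gene_set),
                penalty_points=config.penalty_points,
                cutoff=config.cutoff,
            )
            scores = frozen.score(cohort).rename("g8plus").to_frame()
            scores["predicted_recurrence"] = frozen.predict(cohort)
            _write_tsv(scores, outdir / "scores.tsv", index_label="sample")
            results = scores
            score_series = scores["g8plus"]
            score_cohort = cohort
        manifest["stages"].append(stage)

        rfs = pd.DataFrame(
            {
                "rfs_time": [c.rfs_time for c in score_cohort.clinical],
                "rfs_event": [c.rfs_event for c in score_cohort.clinical],
            },
            index=score_cohort.sample_ids,
        ).dropna()
        if len(rfs) >= 4:
            stage = "survival"
            cutoff = (
                config.cutoff
                if config.mode == "apply"
                else results.roc_g8plus.chosen_cutoff
            )
            strata = pd.Series(
                ["high" if s >= cutoff else "low" for s in score_series.loc[rfs.index]],
                index=rfs.index,
            )
            if strata.nunique() == 2:
                fit = fit_survival(rfs["rfs_time"], rfs["rfs_event"].astype(int), strata)
                km_frames = []
                for grp, tbl in fit.km.items():
                    t = tbl.copy()
                    t.insert(0, "stratum", grp)
                    km_frames.append(t)
                _write_tsv(pd.concat(km_frames), outdir / "km.tsv", index=False)
                (outdir / "logrank.json").write_text(
                    json.dumps(
                        {"chi2": fit.logrank_chi2, "p": fit.logrank_p}, indent=2
                    )
                )
                manifest["stages"].append(stage)

        if config.expression:
            stage = "immune"
            expr = pd.read_csv(config.expression, sep="\t", index_col=0)
            profile = normalize_expression(ExpressionProfile(expr))
            sets = (
                read_gmt(config.gene_sets_gmt)
                if config.gene_sets_gmt
                else bundled_immune_sets()
            )
            scores_ic = ssgsea_scores(profile, sets)
            tls = tls_score(profile)
            cutoff = (
                config.cutoff
                if config.mode == "apply"
                else results.roc_g8plus.chosen_cutoff
            )
            grouping = pd.Series(
                ["high" if score_series.get(s, 0) >= cutoff else "low" for s in expr.columns],
                index=expr.columns,
            )
            _write_tsv(scores_ic, outdir / "ssgsea.tsv", index_label="set")
            _write_tsv(tls.to_frame(), outdir / "tls.tsv", index_label="sample")
            if grouping.nunique() == 2 and (grouping == "high").sum() >= 3 and (grouping == "low").sum() >= 3:
                comp = compare_groups_fdr(
                    pd.concat([scores_ic, tls.to_frame().T]), grouping
                )
                _write_tsv(comp, outdir / "immune_comparison.tsv")
            manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return PipelineResult(outdir=outdir, manifest=manifest, results=results)
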