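"""One-command orchestration of the full analysis.

``run_full_pipeline`` chains the stages: simulate (or load) the data, score
idea texts (Tf-idf and communication burden), compute rating medians and
area ratios, run the quantile-group comparisons, the beta regression of the
area ratio on knowledge, the AIC-selected LASSO of each novelty metric on
the area ratio plus covariates, and the mediation path models.  All numeric
outputs are written as JSON/CSV plus a human-readable markdown report, and
a manifest records the config hash, seeds, package versions and a content
hash of every output file, so a re-run with the same config reproduces the
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arearatio import read_boxes_csv, read_mask_png, score_masks
from .compare import bootstrap_compare, compare_groups, correlation_matrix
from .exceptions import AttnovError, ConfigurationError
from .mediation import PathModel
from .regression import (
    BetaRegression,
    LassoAIC,
    default_lambda_grid,
)
from .synthetic import SimulationConfig, generate_dataset, write_dataset
from .textnovelty import (
    novelty_to_individuals,
    read_corpus_jsonl,
    read_reference_corpus,
    score_corpus,
)

__all__ = ["PipelineConfig", "PipelineError", "run_full_pipeline"]

USAGE_COVARIATES = ["n_speakers", "usage_frequency", "particularity", "self_knowledge"]
NOVELTY_METRICS = ["novelty_individuals", "tfidf", "cb"]


class PipelineError(AttnovError):
    """A stage failed; carries the stage name and the underlying error."""

    def __init__(self, stage: str, error: Exception):
        self.stage = stage
        self.error = error
        super().__init__(f"stage {stage!r} failed: {error}")

    def record(self) -> dict:
        return {"stage": self.stage, "error_type": type(self.error).__name__, "message": str(self.error)}


@dataclass
class PipelineConfig:
    """Paths and options for one end-to-end run."""

    outdir: str = "attnov_output"
    simulation: SimulationConfig | None = None
    # input paths (ignored when a simulation block is present)
    participants_csv: str | None = None
    ideas_jsonl: str | None = None
    reference_path: str | None = None
    masks_dir: str | None = None
    boxes_csv: str | None = None
    ratings_csv: str | None = None
    # analysis options
    tokenizer: str = "simple"
    log_base: float | None = None
    smoothing: str = "addone"
    t_variant: str = "student"
    quantile: float = 0.25
    bootstrap_B: int = 10_000
    seed: int = 0
    lambda_grid: tuple[float, ...] = field(default_factory=lambda: default_lambda_grid())
    knowledge_col: str = "test_score"
    transform: str = "arcsine_x2"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        config = cls(**raw)
        if sim is not None:
            if "age_range" in sim:
                sim["age_range"] = tuple(sim["age_range"])
            config.simulation = SimulationConfig(**sim)
        return config

    def as_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if self.simulation is not None:
            out["simulation"] = self.simulation.as_dict()
        out["lambda_grid"] = [float(l) for l in self.lambda_grid]
        return out


def _round_floats(obj, sig: int = 12):
    """Round all floats to `sig` significant digits for byte-stable JSON."""
    if isinstance(obj, float):
        if obj == 0 or not math.isfinite(obj):
            return obj
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), sig)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _write_json(path: Path, obj) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_round_floats(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise ConfigurationError(f"no {what} path configured and no simulation block")
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"{what} path does not exist: {p}")
    return p


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        dataset = generate_dataset(config.simulation)
        return (
            dataset.participants,
            dataset.idea_corpus,
            dataset.reference_corpus,
            dataset.masks,
            dataset.ratings,
            dataset,
        )
    participants = pd.read_csv(_require(config.participants_csv, "participants CSV"))
    corpus = read_corpus_jsonl(_require(config.ideas_jsonl, "idea corpus JSONL"), config.tokenizer)
    reference = read_reference_corpus(_require(config.reference_path, "reference corpus"), config.tokenizer)
    masks = None
    if config.masks_dir is not None:
        mask_dir = _require(config.masks_dir, "mask directory")
        masks = [read_mask_png(p) for p in sorted(mask_dir.glob("*.png"))]
    elif config.boxes_csv is not None:
        masks = read_boxes_csv(_require(config.boxes_csv, "box CSV"))
    ratings = None
    if config.ratings_csv is not None:
        ratings = pd.read_csv(_require(config.ratings_csv, "ratings CSV"))
    return participants, corpus, reference, masks, ratings, None


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the report bundle (also written to outdir)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config.as_dict()}
    outputs: list[Path] = []

    stage = "load"
    try:
        participants, corpus, reference, masks, ratings, dataset = _load_inputs(config)
        if dataset is not None:
            write_dataset(dataset, outdir / "synthetic_data")

        stage = "score_text"
        scores = score_corpus(corpus, reference, smoothing=config.smoothing, log_base=config.log_base)
        scores_path = outdir / "text_scores.csv"
        scores.to_csv(scores_path, index=False, float_format="%.12g")
        outputs.append(scores_path)

        stage = "assemble"
        table = participants.merge(
            scores.rename(columns={"id": "participant_id"}), on="participant_id", how="left"
        )
        if masks is not None and len(masks) > 0:
            ratio = score_masks(masks).rename(
                columns={"image_id": "participant_id", "area_ratio": "area_ratio_mask"}
            )
            table = table.merge(ratio, on="participant_id", how="left")
            if "area_ratio" not in table.columns:
                table["area_ratio"] = table["area_ratio_mask"]
        if ratings is not None:
            rater_cols = [c for c in ratings.columns if c.startswith("rater_")]
            med = ratings[rater_cols].apply(novelty_to_individuals, axis=1)
            table = table.merge(
                pd.DataFrame(
                    {"participant_id": ratings["participant_id"], "novelty_individuals": med}
                ),
                on="participant_id",
                how="left",
            )
        table_path = outdir / "participants_scored.csv"
        table.to_csv(table_path, index=False, float_format="%.12g")
        outputs.append(table_path)
        bundle["n_participants"] = int(len(table))

        metrics = [m for m in NOVELTY_METRICS if m in table.columns]

        stage = "compare_groups"
        comparisons: dict = {}
        comparisons["area_ratio_by_knowledge"] = compare_groups(
            table,
            split_by=config.knowledge_col,
            metric="area_ratio",
            quantile=config.quantile,
            transform=config.transform,
            variant=config.t_variant,
            id_col="participant_id",
        ).as_dict()
        for metric in metrics:
            comparisons[f"{metric}_by_area_ratio"] = compare_groups(
                table,
                split_by="area_ratio",
                metric=metric,
                quantile=config.quantile,
                transform=None,
                variant=config.t_variant,
                id_col="participant_id",
            ).as_dict()
        if "novelty_individuals" in metrics:
            from .compare import quartile_split

            split = quartile_split(
                table[["participant_id", "area_ratio"]], quantile=config.quantile
            )
            idx = table.set_index("participant_id")["novelty_individuals"]
            comparisons["novelty_individuals_bootstrap"] = bootstrap_compare(
                idx.loc[list(split.top_ids)].to_numpy(),
                idx.loc[list(split.bottom_ids)].to_numpy(),
                B=config.bootstrap_B,
                seed=config.seed,
            )
        comp_path = outdir / "comparisons.json"
        _write_json(comp_path, comparisons)
        outputs.append(comp_path)
        bundle["comparisons"] = comparisons

        stage = "correlations"
        if len(metrics) >= 2:
            corr, pvals = correlation_matrix(table[metrics])
            correlations = {
                "metrics": metrics,
                "pearson": corr.to_numpy().tolist(),
                "p_values": pvals.to_numpy().tolist(),
            }
            corr_path = outdir / "metric_correlations.json"
            _write_json(corr_path, correlations)
            outputs.append(corr_path)
            bundle["correlations"] = correlations

        stage = "beta_regression"
        beta_results = {}
        model1 = BetaRegression.from_dataframe(
            table, "area_ratio", [config.knowledge_col, "gender", "age"]
        ).fit()
        beta_results["model1"] = model1.as_dict()
        if all(c in table.columns for c in USAGE_COVARIATES):
            model2 = BetaRegression.from_dataframe(
                table,
                "area_ratio",
                [config.knowledge_col, "gender", "age", *USAGE_COVARIATES],
            ).fit()
            beta_results["model2"] = model2.as_dict()
        beta_path = outdir / "beta_regression.json"
        _write_json(beta_path, beta_results)
        outputs.append(beta_path)
        bundle["beta_regression"] = beta_results

        stage = "lasso"
        predictors = ["area_ratio", config.knowledge_col, "gender", "age"] + [
            c for c in USAGE_COVARIATES if c in table.columns
        ]
        lasso_results = {}
        for metric in metrics:
            best = LassoAIC.from_dataframe(table, metric, predictors).fit(config.lambda_grid)
            lasso_results[metric] = best.as_dict()
        lasso_path = outdir / "lasso.json"
        _write_json(lasso_path, lasso_results)
        outputs.append(lasso_path)
        bundle["lasso"] = lasso_results

        stage = "path_analysis"
        path_results = {}
        for metric in metrics:
            res = PathModel.from_dataframe(
                table, config.knowledge_col, "area_ratio", metric
            ).fit(ci="delta")
            path_results[metric] = res.as_dict()
        path_path = outdir / "path_analysis.json"
        _write_json(path_path, path_results)
        outputs.append(path_path)
        bundle["path_analysis"] = path_results

        stage = "report"
        report_path = outdir / "report.md"
        report_path.write_text(_render_report(bundle), encoding="utf-8")
        outputs.append(report_path)

        stage = "manifest"
        manifest = {
            "config": _round_floats(config.as_dict()),
            "config_sha256": hashlib.sha256(
                json.dumps(_round_floats(config.as_dict()), sort_keys=True).encode()
            ).hexdigest(),
            "package_version": __version__,
            "seed": config.seed,
            "n_participants": bundle["n_participants"],
            "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
        }
        _write_json(outdir / "manifest.json", manifest)
        bundle["manifest"] = manifest
    except AttnovError as exc:
        err = exc if isinstance(exc, PipelineError) else PipelineError(stage, exc)
        _write_json(outdir / "error.json", err.record())
        raise err from exc
    return bundle


def _render_report(bundle: dict) -> str:
    lines = ["# Analysis report", ""]
    lines.append(f"Participants: {bundle['n_participants']}")
    lines.append("")
    lines.append("## Group comparisons (top vs bottom quantile)")
    for name, comp in bundle.get("comparisons", {}).items():
        if "t" in comp:
            lines.append(
                f"- {name}: mean(top) = {comp['mean_top']:.3f}, "
                f"mean(bottom) = {comp['mean_bottom']:.3f}, "
                f"t = {comp['t']:.2f}, p = {comp['p_value']:.3g}, r = {comp['effect_r']:.2f}"
            )
        else:
            lines.append(
                f"- {name} (bootstrap): mean(top) = {comp['mean_a']:.3f}, "
                f"mean(bottom) = {comp['mean_b']:.3f}, p = {comp['p_value']:.3g}"
            )
    lines.append("")
    lines.append("## Beta regression of area ratio")
    for name, fit in bundle.get("beta_regression", {}).items():
        coef = fit["coefficients"]
        lines.append(
            f"- {name}: knowledge coefficient = {coef.get('test_score', float('nan')):.4f} "
            f"(phi = {fit['phi']:.2f}, pseudo-R2 = {fit['pseudo_r2']:.3f})"
        )
    lines.append("")
    lines.append("## LASSO (AIC-selected lambda)")
    for metric, fit in bundle.get("lasso", {}).items():
        coef = fit["coefficients"]
        lines.append(
            f"- {metric}: area-ratio coefficient = {coef.get('area_ratio', 0.0):.3f} "
            f"(lambda = {fit['lambda']:.3g})"
        )
    lines.append("")
    lines.append("## Path analysis (knowledge -> area ratio -> novelty)")
    for metric, fit in bundle.get("path_analysis", {}).items():
        lines.append(
            f"- {metric}: a = {fit['a']:.4f}, b = {fit['b']:.3f}, "
            f"indirect = {fit['indirect']:.4f} (p = {fit['p_values']['indirect']:.3g}), "
            f"direct = {fit['c_prime']:.4f} (p = {fit['p_values']['c_prime']:.3g})"
        )
    lines.append("")
    return "\n".join(lines)
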