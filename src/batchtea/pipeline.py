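"""End-to-end pipeline: generate -> train -> analyze.

Each stage writes its artifacts under the configured output directory with a
provenance block (seed, config hash, package version); a single global seed
is fanned out to the stages by fixed offsets so stages are individually
reproducible.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .config import PipelineConfig, config_hash
from .scenarios import (FEATURE_COLUMNS, SamplingBounds, ScenarioDataset,
                        generate_dataset)
from .surrogate import (SearchSpace, SplitPlan,
                        cross_validate_models, evaluate, learning_curve,
                        make_model, select_features, split_train_test,
                        train_models, tune_best)
from .uncertainty import (feasible_mpsp_range, interpolate_heatmap,
                          kde_marginals, shap_summary, spearman_table)
from . import plots

__all__ = ["stage_generate", "stage_train", "stage_analyze", "reproduce"]

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets
_GENERATE, _TRAIN, _TUNE, _ANALYZE = 101, 202, 303, 404


def _provenance(config: PipelineConfig, stage: str) -> dict:
    return {"stage": stage, "seed": config.seed,
            "config_hash": config_hash(config), "version": __version__}


def _write_json(payload: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, default=float))


def stage_generate(config: PipelineConfig, out_dir: Path) -> ScenarioDataset:
    bounds = SamplingBounds(variables=config.variables(),
                            target_irr_range=config.irr_range)
    dataset = generate_dataset(bounds, n=config.n, seed=config.seed + _GENERATE)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset.to_csv(out_dir / "dataset.csv")
    _write_json({**_provenance(config, "generate"), "n": dataset.n},
                out_dir / "dataset_provenance.json")
    logger.info("generated %d scenarios -> %s", dataset.n, out_dir / "dataset.csv")
    return dataset


def stage_train(config: PipelineConfig, dataset: ScenarioDataset,
                out_dir: Path) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    plan = SplitPlan(train_fraction=config.train_fraction,
                     cv_folds=config.cv_folds, seed=config.seed + _TRAIN)
    train, test = split_train_test(dataset, plan)

    selection = select_features(train, seed=plan.seed)
    (out_dir / "selected_features.txt").write_text(
        "\n".join(selection.selected) + "\n")

    cv_selected = cross_validate_models(train, selection.selected,
                                        seed=plan.seed, folds=plan.cv_folds)
    cv_full = cross_validate_models(
        train, FEATURE_COLUMNS, seed=plan.seed, folds=plan.cv_folds,
        models={"xgboost": make_model("xgboost", seed=plan.seed)})

    space = SearchSpace(iterations=config.search_iterations,
                        folds=config.cv_folds)
    tuned, search_table = tune_best(train, selection.selected, space,
                                    seed=config.seed + _TUNE)
    search_table.to_csv(out_dir / "search_results.csv", index=False)

    curve = learning_curve(tuned, train, selection.selected,
                           seed=plan.seed, folds=plan.cv_folds)
    curve.to_csv(out_dir / "learning_curve.csv", index=False)
    plots.plot_learning_curve(curve, out_dir / "learning_curve.png")

    models = train_models(train, selection.selected, seed=plan.seed)
    holdout = evaluate(models, test, selection.selected)
    holdout_tuned = evaluate({"xgboost_tuned": tuned}, test, selection.selected)

    report = {
        **_provenance(config, "train"),
        "selected_features": list(selection.selected),
        "lasso_alpha": selection.alpha,
        "cv_selected_features": cv_selected.per_target,
        "cv_full_features_xgboost": cv_full.per_target,
        "holdout_default_models": holdout.per_target,
        "holdout_tuned_xgboost": holdout_tuned.per_target,
        "tuned_params": {k.split("__")[-1]: v for k, v in
                         tuned.get_params().items()
                         if k.startswith("model__estimator__") and
                         k.split("__")[-1] in ("n_estimators", "max_depth",
                                               "learning_rate", "subsample",
                                               "colsample_bytree")},
    }
    _write_json(report, out_dir / "metrics.json")
    return {"train": train, "test": test, "selection": selection,
            "models": models, "tuned": tuned, "report": report}


def stage_analyze(config: PipelineConfig, dataset: ScenarioDataset,
                  trained: dict, out_dir: Path) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed + _ANALYZE
    corr = spearman_table(dataset)
    corr.table.to_csv(out_dir / "spearman.csv")

    selection = trained["selection"]
    curves = kde_marginals(dataset, selection.selected)
    plots.plot_kde_marginals(curves, out_dir / "kde_marginals.png")

    tuned = trained["tuned"]
    for target in ("mpsp", "upc"):
        summary = shap_summary(tuned, trained["test"], target,
                               selection.selected, seed=seed,
                               n_samples=50, n_background=30,
                               n_permutations=16)
        plots.plot_attribution_summary(summary,
                                       out_dir / f"shap_{target}.png")
        summary.ranking().to_csv(out_dir / f"shap_ranking_{target}.csv",
                                 header=["mean_abs_attribution"])

    grid = interpolate_heatmap(dataset, resolution=config.heatmap_resolution)
    plots.plot_heatmap(grid, out_dir / "mpsp_heatmap.png", marr=config.marr)
    lo, hi = feasible_mpsp_range(grid, config.marr, config.upc_window)
    feasibility = {
        **_provenance(config, "analyze"),
        "marr": config.marr, "upc_window": list(config.upc_window),
        "mpsp_min": lo, "mpsp_max": hi,
    }
    _write_json(feasibility, out_dir / "feasibility.json")
    return {"spearman": corr, "feasibility": feasibility, "heatmap": grid}


def reproduce(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns the stage summaries."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    dataset = stage_generate(config, out_dir)
    results["dataset"] = dataset
    trained = stage_train(config, dataset, out_dir)
    results["train"] = trained["report"]
    analysis = stage_analyze(config, dataset, trained, out_dir)
    results["analysis"] = analysis["feasibility"]
    return results
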