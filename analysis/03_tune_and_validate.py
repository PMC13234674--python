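#!/usr/bin/env python
"""Stage 3 — randomized search, learning curve and hold-out validation.

Tunes the boosted ensemble over the printed hyperparameter space (30
sampled configurations, 5-fold CV), draws its learning curve, evaluates the
tuned model on the untouched 20% hold-out, and reports the RMSE of min-max
normalized targets against the normalized target standard deviations.
"""

import argparse
import json
from pathlib import Path

from batchtea.plots import plot_learning_curve
from batchtea.scenarios import ScenarioDataset
from batchtea.surrogate import (SearchSpace, SplitPlan, evaluate,
                                learning_curve, normalized_target_report,
                                select_features, split_train_test, tune_best)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=42)
parser.add_argument("--data", type=Path, default=Path("results/dataset.csv"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

dataset = ScenarioDataset.from_csv(args.data)
train, test = split_train_test(dataset, SplitPlan(seed=args.seed))
selection = select_features(train, seed=args.seed)
print(f"tuning on {len(selection.selected)} selected features ...")

space = SearchSpace()
tuned, search = tune_best(train, selection.selected, space, seed=args.seed)
search.to_csv(args.out / "search_results.csv", index=False)
best = search.iloc[0]
print("best configuration (CV R^2 = %.3f):" % best.cv_r2)
for key in ("n_estimators", "max_depth", "learning_rate", "subsample",
            "colsample_bytree"):
    print(f"  {key:<18s} {best[key]}")

curve = learning_curve(tuned, train, selection.selected, seed=args.seed)
curve.to_csv(args.out / "learning_curve.csv", index=False)
plot_learning_curve(curve, args.out / "learning_curve.png")
print("\nlearning curve (validation R^2 by training size):")
print(curve[["n_train", "train_r2", "validation_r2"]].round(3).to_string(index=False))

holdout = evaluate({"xgboost_tuned": tuned}, test, selection.selected)
print("\nhold-out metrics:")
print(holdout.averaged().round(3).to_string())
for target in ("upc", "mpsp"):
    print(f"  {target}: " + ", ".join(
        f"{k}={v:.3f}" for k, v in holdout.per_target["xgboost_tuned"][target].items()
        if k != "mape_excluded"))

norm = normalized_target_report(tuned, train, test, selection.selected)
print("\nnormalized-target comparison (hold-out):")
print(norm.round(4).to_string())
payload = {
    "best_params": {k: (float(best[k]) if k != "n_estimators" else int(best[k]))
                    for k in ("n_estimators", "max_depth", "learning_rate",
                              "subsample", "colsample_bytree")},
    "holdout": holdout.per_target,
    "normalized": norm.to_dict(),
}
(args.out / "holdout_metrics.json").write_text(json.dumps(payload, indent=2,
                                                          default=float))
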