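#!/usr/bin/env python
"""Stage 2 — feature selection and screening of the six regressors.

Splits the dataset 80/20, selects a joint sparse feature set with multitask
LASSO, and cross-validates the six default-hyperparameter regressors on the
selected features (plus the boosted ensemble on all 35 features for the
full-variable baseline).  Writes the CV metric tables under results/.
"""

import argparse
from pathlib import Path

from batchtea.scenarios import FEATURE_COLUMNS, ScenarioDataset
from batchtea.surrogate import (SplitPlan, cross_validate_models, make_model,
                                select_features, split_train_test)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=42)
parser.add_argument("--data", type=Path, default=Path("results/dataset.csv"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

dataset = ScenarioDataset.from_csv(args.data)
train, test = split_train_test(dataset, SplitPlan(seed=args.seed))

selection = select_features(train, seed=args.seed)
print(f"multitask LASSO (alpha={selection.alpha:.4f}) selected "
      f"{len(selection.selected)} of {len(FEATURE_COLUMNS)} features:")
for name in selection.selected:
    print(f"  {name:<28s} |coef| = {selection.coefficients[name]:.4f}")
(args.out / "selected_features.txt").write_text("\n".join(selection.selected) + "\n")

print("\n5-fold CV, selected features, uniform average over UPC and MPSP:")
report = cross_validate_models(train, selection.selected, seed=args.seed)
print(report.averaged().round(3).to_string())
report.averaged().to_csv(args.out / "cv_metrics_selected.csv")
for target in ("upc", "mpsp"):
    table = report.for_target(target)
    table.to_csv(args.out / f"cv_metrics_{target}.csv")
    print(f"\nper-target metrics for {target.upper()}:")
    print(table.round(3).to_string())

print("\nfull-variable baseline (boosted ensemble, 35 features):")
full = cross_validate_models(train, FEATURE_COLUMNS, seed=args.seed,
                             models={"xgboost": make_model("xgboost",
                                                           seed=args.seed)})
print(full.averaged().round(3).to_string())
full.averaged().to_csv(args.out / "cv_metrics_full_xgboost.csv")
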