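#!/usr/bin/env python
"""Stage 4 — uncertainty and feasibility analyses.

Computes the Spearman correlation table (the dominant UPC and MPSP
drivers), KDE marginals of the selected features, Shapley attributions of
the tuned surrogate's predictions, the cubic-interpolated MPSP(IRR, UPC)
heatmap, and the feasible MPSP range under the 30% minimum attractive rate
of return with UPC restricted to 140-240 USD/kg.
"""

import argparse
import json
from pathlib import Path

from batchtea.plots import (plot_attribution_summary, plot_heatmap,
                            plot_kde_marginals)
from batchtea.scenarios import ScenarioDataset
from batchtea.surrogate import (SplitPlan, make_model, select_features,
                                split_train_test)
from batchtea.uncertainty import (feasible_mpsp_range, interpolate_heatmap,
                                  kde_marginals, shap_summary, spearman_table)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=42)
parser.add_argument("--data", type=Path, default=Path("results/dataset.csv"))
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--marr", type=float, default=0.30)
args = parser.parse_args()

dataset = ScenarioDataset.from_csv(args.data)
corr = spearman_table(dataset)
corr.table.to_csv(args.out / "spearman.csv")
print("top-5 Spearman correlations per target:")
for target in ("upc", "mpsp"):
    print(f"  {target.upper()}:")
    for name, rho in corr.top(target).items():
        print(f"    {name:<28s} {rho:+.2f}")

train, test = split_train_test(dataset, SplitPlan(seed=args.seed))
selection = select_features(train, seed=args.seed)
curves = kde_marginals(dataset, selection.selected)
plot_kde_marginals(curves, args.out / "kde_marginals.png")
print(f"\nKDE marginals for {len(curves)} selected features -> kde_marginals.png")

model = make_model("xgboost", seed=args.seed)
model.fit(train[list(selection.selected)], train[["upc", "mpsp"]])
for target in ("mpsp", "upc"):
    summary = shap_summary(model, test, target, selection.selected,
                           n_samples=60, n_background=40, seed=args.seed)
    plot_attribution_summary(summary, args.out / f"shap_{target}.png")
    ranking = summary.ranking()
    ranking.to_csv(args.out / f"shap_ranking_{target}.csv",
                   header=["mean_abs_attribution"])
    print(f"\nShapley ranking for {target.upper()} (top 5):")
    print(ranking.head(5).round(2).to_string())

grid = interpolate_heatmap(dataset, resolution=100)
plot_heatmap(grid, args.out / "mpsp_heatmap.png", marr=args.marr)
lo, hi = feasible_mpsp_range(grid, args.marr, (140.0, 240.0))
print(f"\nfeasible MPSP at IRR >= {args.marr:.0%}, UPC in [140, 240] USD/kg: "
      f"{lo:.0f} - {hi:.0f} USD/kg")
(args.out / "feasibility.json").write_text(json.dumps(
    {"marr": args.marr, "upc_window": [140.0, 240.0],
     "mpsp_min": lo, "mpsp_max": hi}, indent=2))
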