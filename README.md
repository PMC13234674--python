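# batchtea

Stochastic techno-economic assessment (TEA) of batch active-pharmaceutical-
ingredient (API) manufacturing, with machine-learning surrogates for the
economic targets.

The package is built around the SynPharm-style batch process that makes a
small-molecule API by condensing quinaldine and hydroquinone (134
batches/yr, 33,000 kg/yr). It answers two questions a process economist
asks of such a plant:

* **What does a kilogram cost?** The unit production cost,
  `UPC = OPEX / P_annual`, from a calibrated five-category operating-cost
  model (raw materials, facility-dependent, labor-dependent, lab/QC/QA,
  waste treatment).
* **What must a kilogram sell for?** The minimum product selling price
  (MPSP): the price at which the project's net present value,
  `NPV = Σ CF_t/(1+r)^t`, is zero at a target internal rate of return,
  solved by bisection over a full discounted-cash-flow schedule
  (construction, startup, inflation, depreciation, debt service, income
  tax).

Input uncertainty — 34 prices, rates and operating parameters, each with
published uniform bounds — is propagated by Monte Carlo: 5,000 scenarios,
each solved exactly, yield a 37-column dataset (34 inputs + target IRR +
UPC + MPSP). Six multi-output regressors (linear, k-NN, random forest,
polynomial ridge, SVR, gradient boosting) are screened as surrogates with
5-fold cross-validation after multitask-LASSO feature selection; the
boosted ensemble is tuned by randomized search. Uncertainty analyses cover
Spearman rank correlations, kernel-density marginals, exact Shapley
attributions of the surrogate, and a cubic-interpolated MPSP(IRR, UPC)
heatmap from which the feasible price range under a 30% minimum attractive
rate of return is extracted.

See `docs/methods.md` for the model conventions and calibrations.

## Worked example

```python
from batchtea import run_baseline, generate_dataset, spearman_table

opex, out = run_baseline()          # all inputs at their baselines
print(f"OPEX  {opex.total:,.0f} USD/yr")
print(f"UPC   {out.upc:.2f} USD/kg")
print(f"MPSP  {out.mpsp:.2f} USD/kg at a {out.irr:.0%} target IRR")

ds = generate_dataset(n=5000, seed=42)
rho = spearman_table(ds).table
print(f"rho(labor rate, UPC) = {rho.loc['labor_rate', 'upc']:.2f}")
```

prints

```
OPEX  5,776,000 USD/yr
UPC   175.03 USD/kg
MPSP  319.94 USD/kg at a 30% target IRR
rho(labor rate, UPC) = 0.72
```

The baseline year reproduces the published cost sheet (5.78 M USD/yr, 175
USD/kg); selling at 320 USD/kg would return 30% on the investment under the
baseline financing assumptions; and across the Monte Carlo study the labor
rate is the strongest driver of production cost.

## The analysis, step by step

The numbered drivers under `analysis/` run the full study and write their
tables and figures to `results/`:

```sh
python analysis/01_generate_dataset.py   # baseline + 5,000-scenario dataset
python analysis/02_screen_models.py      # feature selection + six-model CV
python analysis/03_tune_and_validate.py  # randomized search, learning curve, hold-out
python analysis/04_uncertainty.py        # Spearman, KDE, Shapley, heatmap, feasibility
```

The same pipeline is available as a CLI (`batchtea generate|train|analyze|
heatmap|reproduce`) and as one call, `batchtea.reproduce(PipelineConfig())`.

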