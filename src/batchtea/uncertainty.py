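"""Uncertainty and sensitivity analyses over the scenario dataset.

* Spearman rank correlations between every input and each target,
* kernel-density marginals of the sampled features,
* per-sample Shapley attributions of the surrogate's predictions (exact
  coalition enumeration against a marginal background expectation; additive
  by construction),
* a cubic-interpolated MPSP(IRR, UPC) surface, and
* extraction of the feasible MPSP range under a minimum-return constraint.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import griddata
from scipy.stats import gaussian_kde, rankdata

from .scenarios import FEATURE_COLUMNS, TARGET_COLUMNS, ScenarioDataset

__all__ = [
    "SpearmanResult",
    "AttributionSummary",
    "HeatmapGrid",
    "spearman",
    "spearman_table",
    "kde_marginals",
    "shap_summary",
    "interpolate_heatmap",
    "feasible_mpsp_range",
]


# ---------------------------------------------------------------------------
# Spearman rank correlation

@dataclass(frozen=True)
class SpearmanResult:
    """Rank correlations of every feature against each target."""

    table: pd.DataFrame  # index: feature, columns: targets

    def top(self, target: str, k: int = 5) -> pd.Series:
        col = self.table[target].dropna()
        return col.reindex(col.abs().sort_values(ascending=False).index).head(k)


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation, average ranks for ties.

    With distinct ranks this reduces to ``1 - 6 sum(d_i^2) / (n(n^2-1))``
    where ``d_i`` are rank differences; with ties it is the Pearson
    correlation of the average ranks (the standard generalization).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx ** 2) * np.sum(ry ** 2)))


def spearman_table(dataset: ScenarioDataset | pd.DataFrame,
                   feature_columns: tuple[str, ...] = FEATURE_COLUMNS,
                   target_columns: tuple[str, ...] = TARGET_COLUMNS,
                   ) -> SpearmanResult:
    """Rank correlation of every feature with every target.

    Constant columns yield NaN (undefined correlation)."""
    frame = dataset.frame if isinstance(dataset, ScenarioDataset) else dataset
    if len(frame) < 3:
        raise ValueError("need at least 3 rows")
    out = {}
    for t in target_columns:
        out[t] = {f: spearman(frame[f].to_numpy(), frame[t].to_numpy())
                  for f in feature_columns}
    return SpearmanResult(table=pd.DataFrame(out))


# ---------------------------------------------------------------------------
# KDE marginals

def kde_marginals(dataset: ScenarioDataset | pd.DataFrame,
                  features: tuple[str, ...] | list[str],
                  grid_points: int = 256,
                  bw_method: str | float = "scott",
                  ) -> dict[str, pd.DataFrame]:
    """Gaussian kernel density estimate of each feature's marginal.

    Returns, per feature, a table of grid values and densities over a grid
    padded by one bandwidth beyond the observed range.  Each density
    integrates to ~1 over its grid.
    """
    frame = dataset.frame if isinstance(dataset, ScenarioDataset) else dataset
    if len(frame) < 30:
        raise ValueError("need at least 30 rows for a density estimate")
    curves = {}
    for name in features:
        x = frame[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"feature {name!r} is constant; degenerate density",
                          RuntimeWarning, stacklevel=2)
            continue
        kde = gaussian_kde(x, bw_method=bw_method)
        bw = math.sqrt(float(kde.covariance[0, 0]))
        # pad by three bandwidths so the Gaussian tails are captured and the
        # density integrates to ~1 on the grid
        grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, grid_points)
        curves[name] = pd.DataFrame({"value": grid, "density": kde(grid)})
    return curves


# ---------------------------------------------------------------------------
# Shapley attributions

@dataclass(frozen=True)
class AttributionSummary:
    """Per-sample additive feature attributions for one target.

    ``base_value + attributions.sum(axis=1)`` reconstructs each prediction.
    """

    attributions: pd.DataFrame  # rows: samples, columns: features
    base_value: float
    feature_values: pd.DataFrame
    target: str

    def ranking(self) -> pd.Series:
        """Features ordered by mean absolute attribution."""
        return self.attributions.abs().mean(axis=0).sort_values(ascending=False)


def _coalition_masks(d: int) -> np.ndarray:
    """All 2^d coalitions as a boolean matrix (coalition x feature)."""
    idx = np.arange(2 ** d)
    return (idx[:, None] >> np.arange(d)) & 1 > 0


def _shapley_exact(predict, x_row: np.ndarray, background: np.ndarray,
                   masks: np.ndarray) -> np.ndarray:
    """Exact Shapley values for one sample against a marginal background.

    The value of a coalition S is the mean prediction with the features in S
    taken from the sample and the rest from the background rows.  All
    coalition evaluations are batched into a single model call; use only for
    modest d (2^d coalitions).
    """
    d = len(x_row)
    n_bg = len(background)
    n_coal = len(masks)
    # (coalition, background, feature) -> stacked prediction batch
    mixed = np.broadcast_to(background, (n_coal, n_bg, d)).copy()
    for i in range(d):
        mixed[masks[:, i], :, i] = x_row[i]
    values = predict(mixed.reshape(n_coal * n_bg, d)).reshape(n_coal, n_bg).mean(axis=1)

    sizes = masks.sum(axis=1)
    fact = [math.factorial(k) for k in range(d + 1)]
    phi = np.zeros(d)
    bit = 1 << np.arange(d)
    coal_idx = np.arange(n_coal)
    for i in range(d):
        without = coal_idx[(coal_idx & bit[i]) == 0]
        with_i = without | bit[i]
        s = sizes[without]
        w = np.array([fact[k] * fact[d - k - 1] / fact[d] for k in s])
        phi[i] = float(np.sum(w * (values[with_i] - values[without])))
    return phi


def _shapley_sampled(predict, x_row: np.ndarray, background: np.ndarray,
                     n_permutations: int, rng: np.random.Generator) -> np.ndarray:
    """Permutation-sampling Shapley estimate for larger feature counts.

    Each permutation contributes one marginal-contribution telescope; all of
    a permutation's coalition evaluations are batched into one model call.
    """
    d = len(x_row)
    n_bg = len(background)
    phi = np.zeros(d)
    base = float(np.mean(predict(background)))
    for _ in range(n_permutations):
        order = rng.permutation(d)
        batch = np.empty((d, n_bg, d))
        mixed = background.copy()
        for step, i in enumerate(order):
            mixed[:, i] = x_row[i]
            batch[step] = mixed
        values = predict(batch.reshape(d * n_bg, d)).reshape(d, n_bg).mean(axis=1)
        prev = base
        for step, i in enumerate(order):
            phi[i] += values[step] - prev
            prev = values[step]
    return phi / n_permutations


def shap_summary(model, data: pd.DataFrame, target: str,
                 features: tuple[str, ...] | list[str],
                 target_columns: tuple[str, ...] = TARGET_COLUMNS,
                 n_samples: int = 100, n_background: int = 50,
                 max_exact_features: int = 12, n_permutations: int = 64,
                 seed: int = 0) -> AttributionSummary:
    """Shapley attribution of the surrogate's predictions for one target.

    Up to ``max_exact_features`` features the values are exact (coalition
    enumeration); beyond that a permutation-sampling estimator is used with
    a warning.  The background distribution is a random subset of ``data``;
    attributions explain the difference between each prediction and the mean
    background prediction and sum to it exactly in the exact regime.
    """
    features = tuple(features)
    if target not in target_columns:
        raise ValueError(f"unknown target {target!r}")
    t_idx = target_columns.index(target)
    rng = np.random.default_rng(seed)
    x_all = data[list(features)].to_numpy(dtype=float)
    n_samples = min(n_samples, len(x_all))
    n_background = min(n_background, len(x_all))
    sample_idx = rng.choice(len(x_all), size=n_samples, replace=False)
    bg_idx = rng.choice(len(x_all), size=n_background, replace=False)
    background = x_all[bg_idx]

    def predict(matrix: np.ndarray) -> np.ndarray:
        frame = pd.DataFrame(matrix, columns=features)
        pred = np.asarray(model.predict(frame), dtype=float)
        return pred[:, t_idx] if pred.ndim > 1 else pred

    exact = len(features) <= max_exact_features
    if not exact:
        warnings.warn(
            f"{len(features)} features exceed the exact enumeration limit "
            f"({max_exact_features}); falling back to permutation sampling",
            RuntimeWarning, stacklevel=2)

    base_value = float(np.mean(predict(background)))
    masks = _coalition_masks(len(features)) if exact else None
    rows = []
    for i in sample_idx:
        if exact:
            phi = _shapley_exact(predict, x_all[i], background, masks)
        else:
            phi = _shapley_sampled(predict, x_all[i], background,
                                   n_permutations, rng)
        rows.append(phi)
    attributions = pd.DataFrame(np.array(rows), columns=features)
    feature_values = data.iloc[sample_idx][list(features)].reset_index(drop=True)
    return AttributionSummary(attributions=attributions, base_value=base_value,
                              feature_values=feature_values, target=target)


# ---------------------------------------------------------------------------
# MPSP(IRR, UPC) surface

@dataclass(frozen=True)
class HeatmapGrid:
    """Regular MPSP surface over (IRR, UPC); NaN outside the convex hull of
    the support points."""

    irr_axis: np.ndarray
    upc_axis: np.ndarray
    mpsp: np.ndarray  # shape (len(upc_axis), len(irr_axis))


def _aggregate_support(irr: np.ndarray, upc: np.ndarray, mpsp: np.ndarray,
                       bins: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Condense scattered scenarios into per-bin centroids and mean MPSP.

    MPSP is multi-valued over the (IRR, UPC) plane — scenarios with the same
    return target and production cost still differ in tax, loan and
    inflation terms.  Interpolating the raw scatter therefore chases noise
    (near-coincident points with very different values produce unbounded
    cubic overshoot); the surface of interest is the conditional mean.
    """
    irr_edges = np.linspace(irr.min(), irr.max(), bins + 1)
    upc_edges = np.linspace(upc.min(), upc.max(), bins + 1)
    ii = np.clip(np.digitize(irr, irr_edges) - 1, 0, bins - 1)
    jj = np.clip(np.digitize(upc, upc_edges) - 1, 0, bins - 1)
    flat = ii * bins + jj
    order = np.argsort(flat)
    flat_sorted = flat[order]
    starts = np.searchsorted(flat_sorted, np.unique(flat_sorted))
    groups = np.split(order, starts[1:])
    agg_irr = np.array([irr[g].mean() for g in groups])
    agg_upc = np.array([upc[g].mean() for g in groups])
    agg_mpsp = np.array([mpsp[g].mean() for g in groups])
    return agg_irr, agg_upc, agg_mpsp


def interpolate_heatmap(points: pd.DataFrame | ScenarioDataset,
                        irr_grid: np.ndarray | None = None,
                        upc_grid: np.ndarray | None = None,
                        resolution: int = 100,
                        method: str = "cubic",
                        aggregate_bins: int | None = 30) -> HeatmapGrid:
    """Cubic interpolation of MPSP over scattered (IRR, UPC) support points.

    ``points`` needs columns ``irr``, ``upc`` and ``mpsp`` (scenario rows or
    surrogate predictions).  Grid cells outside the convex hull of the
    support are NaN (masked, never extrapolated).  The two axes live on very
    different scales (fractions vs hundreds of USD/kg), so the triangulation
    is built on range-normalized coordinates; otherwise sliver triangles
    produce large cubic overshoots.

    With ``aggregate_bins`` set (the default), the scatter is first reduced
    to per-bin centroids carrying the local mean MPSP, and the surface
    interpolates those; pass ``None`` to interpolate the raw points exactly
    (only sensible when the support is single-valued).
    """
    frame = points.frame if isinstance(points, ScenarioDataset) else points
    if len(frame) < 16:
        raise ValueError("need at least 16 support points")
    irr = frame["irr"].to_numpy(dtype=float)
    upc = frame["upc"].to_numpy(dtype=float)
    mpsp = frame["mpsp"].to_numpy(dtype=float)
    if aggregate_bins is not None:
        irr, upc, mpsp = _aggregate_support(irr, upc, mpsp, aggregate_bins)
    if irr_grid is None:
        irr_grid = np.linspace(irr.min(), irr.max(), resolution)
    if upc_grid is None:
        upc_grid = np.linspace(upc.min(), upc.max(), resolution)
    irr_span = max(np.ptp(irr), 1e-12)
    upc_span = max(np.ptp(upc), 1e-12)
    gi, gu = np.meshgrid((np.asarray(irr_grid) - irr.min()) / irr_span,
                         (np.asarray(upc_grid) - upc.min()) / upc_span)
    surface = griddata(((irr - irr.min()) / irr_span,
                        (upc - upc.min()) / upc_span),
                       mpsp, (gi, gu), method=method)
    return HeatmapGrid(irr_axis=np.asarray(irr_grid),
                       upc_axis=np.asarray(upc_grid), mpsp=surface)


def feasible_mpsp_range(grid: HeatmapGrid, irr_min: float,
                        upc_window: tuple[float, float]) -> tuple[float, float]:
    """(min, max) of the MPSP surface over cells with IRR >= ``irr_min`` and
    UPC inside ``upc_window``."""
    lo, hi = upc_window
    irr_mask = grid.irr_axis >= irr_min
    upc_mask = (grid.upc_axis >= lo) & (grid.upc_axis <= hi)
    cells = grid.mpsp[np.ix_(upc_mask, irr_mask)]
    cells = cells[np.isfinite(cells)]
    if cells.size == 0:
        raise ValueError("no feasible cells")
    return float(cells.min()), float(cells.max())
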