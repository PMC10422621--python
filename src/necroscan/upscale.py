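"""Regional application of the calibrated necromass model.

The plot-calibrated regression is applied pixelwise to smoothed pre/post
F-Cover rasters inside a mangrove-extent mask; negative predictions are
clamped to zero for mapping (an unclamped diagnostic layer is kept for
audit).  Total aboveground mass is mapped from canopy height with the
regional height allometry B = 10.0 * H (Mg/ha per meter of canopy
height), and AGN/AGTM ratios and masked regional summaries (totals,
means, histograms) are derived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GridSpec, MetricRaster, smooth_window
from .model import AGNModel

#: Mg/ha of aboveground mass per meter of canopy height
HEIGHT_TO_MASS = 10.0


@dataclass
class RegionMask:
    """Grid-aligned boolean raster; True marks mangrove extent."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, bool)
        if self.values.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError("mask shape does not match grid")


@dataclass
class RegionalSummary:
    total_agn_mg: float
    mean_agn_mg_ha: float
    n_pixels: int
    histogram: list[tuple[float, float, int]]  # (bin low, bin high, count)

    def to_dict(self) -> dict:
        return {
            "total_agn_mg": self.total_agn_mg,
            "mean_agn_mg_ha": self.mean_agn_mg_ha,
            "n_pixels": self.n_pixels,
            "histogram": [
                {"low": lo, "high": hi, "count": n} for lo, hi, n in self.histogram
            ],
        }


def _check_same_grid(*rasters) -> GridSpec:
    grids = {r.grid for r in rasters}
    if len(grids) != 1:
        raise ValueError("rasters/mask must share one GridSpec")
    return rasters[0].grid


def predict_raster(
    model: AGNModel,
    fcover_before: MetricRaster,
    fcover_after: MetricRaster,
    mask: RegionMask | None = None,
    smooth: int = 3,
    clamp: bool = True,
) -> MetricRaster:
    """Map predicted AGN (Mg/ha) from paired F-Cover rasters.

    Both epochs are smoothed identically (``smooth`` x ``smooth`` moving
    average, default 3) before differencing; the fractional change feeds
    the fitted regression.  Pixels outside the mask, with no-data in
    either epoch, or with zero pre-storm cover become no-data.  With
    ``clamp`` (the default) negative predictions are set to 0; pass
    ``clamp=False`` for the unclamped diagnostic layer.
    """
    rasters = [fcover_before, fcover_after] + ([mask] if mask is not None else [])
    grid = _check_same_grid(*rasters)
    if smooth > 1:
        fcover_before = smooth_window(fcover_before, smooth)
        fcover_after = smooth_window(fcover_after, smooth)
    before = fcover_before.values
    after = fcover_after.values
    valid = np.isfinite(before) & np.isfinite(after) & (before != 0)
    if mask is not None:
        valid &= mask.values
    with np.errstate(invalid="ignore", divide="ignore"):
        dpfc = (after - before) / before
        agn = model.a1 + model.a2 * dpfc
    if clamp:
        agn = np.maximum(agn, 0.0)
    agn = np.where(valid, agn, np.nan)
    name = "AGN" if clamp else "AGN_unclamped"
    return MetricRaster(grid, name, agn)


def agtm_from_height(chm: MetricRaster) -> MetricRaster:
    """Total aboveground mass (Mg/ha) from canopy height: B = 10.0 * H."""
    h = chm.values
    if np.nanmin(h) < 0:
        raise ValueError("canopy heights must be non-negative")
    return MetricRaster(chm.grid, "AGTM", HEIGHT_TO_MASS * h)


def necromass_fraction(agn, agtm):
    """Ratio AGN/AGTM (dimensionless; multiply by 100 for percent).

    Accepts scalars, arrays, or MetricRasters.  Undefined (NaN) where
    AGTM is zero or missing.  The mean ratio over a plot set is the
    arithmetic mean of per-plot ratios, not the ratio of means.
    """
    if isinstance(agn, MetricRaster):
        grid = _check_same_grid(agn, agtm)
        a, t = agn.values, agtm.values
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where((t > 0) & np.isfinite(a), a / t, np.nan)
        return MetricRaster(grid, "AGN_fraction", ratio)
    a = np.asarray(agn, float)
    t = np.asarray(agtm, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(t > 0, a / t, np.nan)
    return float(ratio) if ratio.ndim == 0 else ratio


def regional_summary(
    agn_raster: MetricRaster, bin_width: float = 10.0
) -> RegionalSummary:
    """Masked-region totals, mean, and AGN histogram.

    Total (Mg) sums value x pixel-area (ha) over non-missing pixels; the
    mean (Mg/ha) averages over the same pixels.  Histogram bins are
    half-open ``[k*w, (k+1)*w)`` with the last bin closed so the counts
    partition the pixels.
    """
    vals = agn_raster.values[np.isfinite(agn_raster.values)]
    if vals.size == 0:
        raise ValueError("no valid pixels to summarize")
    area_ha = agn_raster.grid.cell_area_ha
    total = float(vals.sum() * area_ha)
    mean = float(vals.mean())
    lo_edge = np.floor(vals.min() / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((vals.max() - lo_edge) / bin_width - 1e-12)))
    edges = lo_edge + bin_width * np.arange(n_bins + 1)
    counts, edges = np.histogram(vals, bins=edges)
    histogram = [
        (float(lo), float(hi), int(n))
        for lo, hi, n in zip(edges[:-1], edges[1:], counts)
    ]
    return RegionalSummary(total, mean, int(vals.size), histogram)


def treemean_vs_agn(
    treemean_before, modeled_agn
) -> tuple[float, float, float]:
    """OLS of modeled AGN on pre-storm Tree Mean: (slope, intercept, r)."""
    import statsmodels.api as sm
    from scipy import stats

    x = np.asarray(treemean_before, float)
    y = np.asarray(modeled_agn, float)
    if len(x) < 3:
        raise ValueError("need at least 3 plots")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate design: constant tree heights")
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    r, _ = stats.pearsonr(x, y)
    return float(ols.params[1]), float(ols.params[0]), float(r)


def rasterize_mask_fraction(
    coverage_fraction: np.ndarray, grid: GridSpec, threshold: float = 0.5
) -> RegionMask:
    """Mask from a per-cell coverage-fraction grid (cells >= threshold kept)."""
    frac = np.asarray(coverage_fraction, float)
    return RegionMask(grid, frac >= threshold)
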