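"""Point-cloud handling: reading, clipping, height normalization, metrics.

A survey is a table of discrete-return lidar records (x, y, z,
return_number, n_returns, optional ground classification).  Heights above
ground are derived either from vendor ground classification or from a
per-cell minimum-z surface, and returns are stratified at the 1.37 m
breast-height threshold into ground / shrub / tree.  The five gridded
metrics (F-Cover, Tree Mean, Shrub Mean, Pulse Density, CHM) are computed
per grid cell from the stratified returns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .grids import GridSpec, MetricRaster

#: breast height (m); returns above it are "tree", at/below it "shrub"
TREE_HEIGHT_THRESHOLD = 1.37

#: LAS classification code for ground returns
GROUND_CLASS = 2

_COLUMNS = ["x", "y", "z", "return_number", "n_returns"]


class EmptyCloudError(ValueError):
    """Raised when an operation requires a non-empty point cloud."""


@dataclass
class PointCloud:
    """A lidar survey epoch.

    ``points`` holds one row per return with columns x, y, z,
    return_number, n_returns, optionally ``ground`` (bool) and, after
    :func:`normalize_heights`, ``height`` (m above ground, >= 0).
    """

    points: pd.DataFrame = field(repr=False)
    epoch_label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.points.columns]
        if missing:
            raise ValueError(f"point table missing columns: {missing}")
        bad = self.points["return_number"] > self.points["n_returns"]
        if bad.any():
            rows = self.points.index[bad][:5].tolist()
            raise ValueError(
                f"return_number exceeds n_returns at rows {rows}"
            )
        if ((self.points["return_number"] < 1) | (self.points["n_returns"] < 1)).any():
            raise ValueError("return_number and n_returns must be positive")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the returns."""
        if len(self.points) == 0:
            raise EmptyCloudError("empty cloud has no extent")
        p = self.points
        return (p["x"].min(), p["y"].min(), p["x"].max(), p["y"].max())

    @property
    def has_heights(self) -> bool:
        return "height" in self.points.columns

    @property
    def first_returns(self) -> pd.DataFrame:
        return self.points[self.points["return_number"] == 1]


def read_point_cloud(path: str | Path, epoch_label: str = "") -> PointCloud:
    """Read a whitespace-delimited xyz return table.

    Columns: ``x y z return_number n_returns [class]`` where class 2 marks
    ground returns.  Lines starting with ``#`` are ignored.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep=r"\s+", comment="#", header=None,
            names=_COLUMNS + ["classification"],
            usecols=range(6), engine="python",
        )
    except pd.errors.EmptyDataError:
        raise EmptyCloudError(f"{path} contains no returns") from None
    except ValueError:
        # fewer than 6 columns: retry without classification
        df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                         names=_COLUMNS, engine="python")
    if len(df) == 0:
        raise EmptyCloudError(f"{path} contains no returns")
    for col in ("x", "y", "z"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if not np.isfinite(vals).all():
            bad = int(np.flatnonzero(~np.isfinite(vals))[0]) + 1
            raise ValueError(f"{path}: non-finite {col} at record {bad}")
        df[col] = vals
    for col in ("return_number", "n_returns"):
        df[col] = pd.to_numeric(df[col], errors="raise", downcast="integer")
    bad = df["return_number"] > df["n_returns"]
    if bad.any():
        rec = int(df.index[bad][0]) + 1
        raise ValueError(f"{path}: return_number > n_returns at record {rec}")
    if "classification" in df.columns and df["classification"].notna().any():
        df["ground"] = df["classification"].fillna(0).astype(int) == GROUND_CLASS
    df = df.drop(columns=[c for c in ("classification",) if c in df.columns])
    return PointCloud(df.reset_index(drop=True), epoch_label=epoch_label)


def write_point_cloud(cloud: PointCloud, path: str | Path) -> None:
    """Write the xyz table dialect that :func:`read_point_cloud` reads."""
    df = cloud.points
    cols = [df["x"], df["y"], df["z"], df["return_number"], df["n_returns"]]
    fmt = ["%.6f", "%.6f", "%.6f", "%d", "%d"]
    if "ground" in df.columns:
        cols.append(np.where(df["ground"], GROUND_CLASS, 1))
        fmt.append("%d")
    arr = np.column_stack(cols)
    np.savetxt(Path(path), arr, fmt=fmt,
               header="x y z return_number n_returns class" if len(fmt) == 6
               else "x y z return_number n_returns")


def clip_rectangle(
    cloud: PointCloud, center: tuple[float, float], side: float, buffer: float = 0.0
) -> PointCloud:
    """Keep returns inside a closed square window around ``center``.

    The window half-width is ``side/2 + buffer``; bounds are inclusive so
    returns exactly on the edge are kept.
    """
    if side <= 0:
        raise ValueError("side must be positive")
    if buffer < 0:
        raise ValueError("buffer must be non-negative")
    half = side / 2.0 + buffer
    p = cloud.points
    keep = (np.abs(p["x"] - center[0]) <= half) & (np.abs(p["y"] - center[1]) <= half)
    out = PointCloud(p[keep].reset_index(drop=True), epoch_label=cloud.epoch_label)
    return out


def _ground_surface_from_minima(
    points: pd.DataFrame, grid_resolution: float
) -> RegularGridInterpolator:
    """Bilinear surface through per-cell minimum z."""
    x, y, z = points["x"].to_numpy(), points["y"].to_numpy(), points["z"].to_numpy()
    grid = GridSpec.from_extent(x.min(), y.min(), x.max(), y.max(), grid_resolution)
    row, col = grid.cell_index(x, y)
    row = np.clip(row, 0, grid.n_rows - 1)
    col = np.clip(col, 0, grid.n_cols - 1)
    zmin = np.full((grid.n_rows, grid.n_cols), np.inf)
    np.minimum.at(zmin, (row, col), z)
    # fill cells with no returns from neighbors via nearest finite value
    if np.isinf(zmin).any():
        finite = np.isfinite(zmin)
        rr, cc = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij")
        from scipy.interpolate import NearestNDInterpolator

        nn = NearestNDInterpolator(
            np.column_stack([rr[finite], cc[finite]]), zmin[finite]
        )
        zmin[~finite] = nn(np.column_stack([rr[~finite], cc[~finite]]))
    centers_y = grid.origin[1] + (np.arange(grid.n_rows) + 0.5) * grid.cell_size
    centers_x = grid.origin[0] + (np.arange(grid.n_cols) + 0.5) * grid.cell_size
    return RegularGridInterpolator(
        (centers_y, centers_x), zmin, method="linear", bounds_error=False, fill_value=None
    )


def normalize_heights(
    cloud: PointCloud,
    ground: str = "auto",
    grid_resolution: float = 5.0,
) -> PointCloud:
    """Attach height above ground to every return.

    ``ground`` selects the ground model:

    * ``"classified_returns"`` — bilinear surface through returns flagged
      as ground by the vendor classification;
    * ``"lowest_point_surface"`` — bilinear surface through the per-cell
      minimum z on a ``grid_resolution`` m grid (for clouds without
      classification);
    * ``"auto"`` — classified returns when present, else lowest-point.

    Heights are clamped at zero: returns below the interpolated ground
    (sensor and interpolation noise) get height 0.
    """
    if len(cloud) == 0:
        raise EmptyCloudError("cannot normalize an empty cloud")
    p = cloud.points
    has_flags = "ground" in p.columns and bool(p["ground"].any())
    if ground == "auto":
        ground = "classified_returns" if has_flags else "lowest_point_surface"
    if ground == "classified_returns":
        if not has_flags:
            raise ValueError("no ground-classified returns available")
        surf = _ground_surface_from_minima(p[p["ground"]], grid_resolution)
    elif ground == "lowest_point_surface":
        if grid_resolution <= 0:
            raise ValueError("grid_resolution must be positive")
        surf = _ground_surface_from_minima(p, grid_resolution)
    else:
        raise ValueError(f"unknown ground mode: {ground!r}")
    ground_z = surf(np.column_stack([p["y"], p["x"]]))
    out = p.copy()
    out["height"] = np.maximum(p["z"].to_numpy() - ground_z, 0.0)
    return PointCloud(out, epoch_label=cloud.epoch_label)


def stratify_return(height_above_ground: float) -> str:
    """Assign a normalized return to ground / shrub / tree.

    Exactly 0 is ground; heights up to and including 1.37 m are shrub;
    strictly above 1.37 m is tree.
    """
    h = float(height_above_ground)
    if h < 0:
        raise ValueError(f"negative height {h}; normalize_heights clamps at 0")
    if h == 0:
        return "ground"
    if h <= TREE_HEIGHT_THRESHOLD:
        return "shrub"
    return "tree"


def _strata(height: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ground = height == 0
    shrub = (height > 0) & (height <= TREE_HEIGHT_THRESHOLD)
    tree = height > TREE_HEIGHT_THRESHOLD
    return ground, shrub, tree


def compute_grid_metrics(cloud: PointCloud, grid: GridSpec) -> dict[str, MetricRaster]:
    """Grid the cloud into the five canopy metrics.

    Per cell: F-Cover is the fraction of first returns in the tree
    stratum; Shrub Mean / Tree Mean are mean heights of the respective
    strata over all returns (no-data when the stratum is empty); Pulse
    Density is first returns per m²; CHM is the maximum tree-stratum
    height (0 where no tree returns).  F-Cover and Pulse Density are
    no-data in cells with zero first returns.
    """
    if len(cloud) == 0:
        raise EmptyCloudError("cannot compute metrics for an empty cloud")
    if not cloud.has_heights:
        raise ValueError("heights not normalized; call normalize_heights first")
    p = cloud.points
    h = p["height"].to_numpy()
    if (h < 0).any():
        raise ValueError("negative heights present")
    row, col = grid.cell_index(p["x"].to_numpy(), p["y"].to_numpy())
    inside = (row >= 0) & (row < grid.n_rows) & (col >= 0) & (col < grid.n_cols)
    row, col, h = row[inside], col[inside], h[inside]
    first = p["return_number"].to_numpy()[inside] == 1
    _, shrub, tree = _strata(h)
    shape = (grid.n_rows, grid.n_cols)
    flat = row * grid.n_cols + col
    size = shape[0] * shape[1]

    def _count(mask: np.ndarray) -> np.ndarray:
        return np.bincount(flat[mask], minlength=size).reshape(shape).astype(float)

    def _sum(mask: np.ndarray) -> np.ndarray:
        return np.bincount(flat[mask], weights=h[mask], minlength=size).reshape(shape)

    n_first = _count(first)
    n_first_tree = _count(first & tree)
    with np.errstate(invalid="ignore", divide="ignore"):
        fcover = np.where(n_first > 0, n_first_tree / n_first, np.nan)
        pulse_density = np.where(n_first > 0, n_first / grid.cell_area_m2, np.nan)
        n_shrub, n_tree = _count(shrub), _count(tree)
        shrub_mean = np.where(n_shrub > 0, _sum(shrub) / n_shrub, np.nan)
        tree_mean = np.where(n_tree > 0, _sum(tree) / n_tree, np.nan)
    chm = np.zeros(size)
    np.maximum.at(chm, flat[tree], h[tree])
    chm = chm.reshape(shape)
    return {
        "FCover": MetricRaster(grid, "FCover", fcover),
        "TreeMean": MetricRaster(grid, "TreeMean", tree_mean),
        "ShrubMean": MetricRaster(grid, "ShrubMean", shrub_mean),
        "PulseDensity": MetricRaster(grid, "PulseDensity", pulse_density),
        "CHM": MetricRaster(grid, "CHM", chm),
    }


def vertical_profile(cloud: PointCloud, bin_height: float = 1.0) -> pd.DataFrame:
    """Histogram of normalized return heights.

    Bins are ``[k*bin_height, (k+1)*bin_height)``; counts over all bins
    sum to the number of returns.  Empty interior bins are reported as 0.
    """
    if bin_height <= 0:
        raise ValueError("bin_height must be positive")
    if not cloud.has_heights:
        raise ValueError("heights not normalized; call normalize_heights first")
    h = cloud.points["height"].to_numpy()
    if len(h) == 0:
        return pd.DataFrame({"bin_low": [], "bin_high": [], "count": []})
    idx = np.floor(h / bin_height).astype(int)
    n_bins = idx.max() + 1
    counts = np.bincount(idx, minlength=n_bins)
    lows = np.arange(n_bins) * bin_height
    return pd.DataFrame({"bin_low": lows, "bin_high": lows + bin_height, "count": counts})


def pulse_count_change(
    pre: PointCloud, post: PointCloud, first_returns_only: bool = False
) -> tuple[int, int, int]:
    """Total return counts for two epochs and their difference (post − pre)."""
    if first_returns_only:
        n_pre, n_post = len(pre.first_returns), len(post.first_returns)
    else:
        n_pre, n_post = len(pre), len(post)
    return n_pre, n_post, n_post - n_pre


def plot_metric_value(
    metrics: dict[str, MetricRaster] | MetricRaster,
    center: tuple[float, float],
    window: int = 3,
):
    """Averaged metric value(s) at a plot center.

    Averages the ``window`` x ``window`` neighborhood of 13 m cells around
    the cell containing ``center`` — a 39 x 39 m footprint by default,
    which absorbs hand-held-GPS positioning error of the field plots.
    """
    single = isinstance(metrics, MetricRaster)
    rasters = {"value": metrics} if single else metrics
    out: dict[str, float] = {}
    for name, raster in rasters.items():
        g = raster.grid
        row, col = g.cell_index(np.array([center[0]]), np.array([center[1]]))
        r, c = int(row[0]), int(col[0])
        half = window // 2
        block = raster.values[
            max(0, r - half): r + half + 1, max(0, c - half): c + half + 1
        ]
        finite = np.isfinite(block)
        out[name] = float(block[finite].mean()) if finite.any() else float("nan")
    return out["value"] if single else out
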