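"""Gridded canopy-metric rasters.

Metrics are produced on a regular grid in a projected CRS in meters
(13 m cells by default, matching common airborne-lidar gridded products).
No-data is represented as NaN in memory and as an explicit ``nodata_value``
on disk.  The on-disk format is the ESRI ASCII grid (``.asc``), a plain-text
header followed by the value matrix, readable by every mainstream GIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

DEFAULT_CELL_SIZE = 13.0

METRIC_NAMES = ("FCover", "TreeMean", "ShrubMean", "PulseDensity", "CHM")


@dataclass(frozen=True)
class GridSpec:
    """Regular row-major grid; pixel (0, 0) has its corner at ``origin``.

    ``origin`` is the lower-left corner in projected coordinates (m).
    Rows index northing upward: row ``i`` spans
    ``origin_y + i*cell`` .. ``origin_y + (i+1)*cell``.
    """

    origin: tuple[float, float]
    cell_size: float = DEFAULT_CELL_SIZE
    n_rows: int = 1
    n_cols: int = 1

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size ** 2

    @property
    def cell_area_ha(self) -> float:
        return self.cell_area_m2 / 1e4

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col).

        Cells are half-open ``[edge, edge + cell)`` except the final
        row/column, which is closed so points on the outer boundary land
        in exactly one cell.
        """
        col = np.floor((np.asarray(x, float) - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y, float) - self.origin[1]) / self.cell_size).astype(int)
        # points exactly on the top/right boundary belong to the last cell
        col = np.where(
            (col == self.n_cols)
            & np.isclose(x, self.origin[0] + self.n_cols * self.cell_size),
            self.n_cols - 1,
            col,
        )
        row = np.where(
            (row == self.n_rows)
            & np.isclose(y, self.origin[1] + self.n_rows * self.cell_size),
            self.n_rows - 1,
            row,
        )
        return row, col

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.cell_index(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    @classmethod
    def from_extent(
        cls,
        xmin: float,
        ymin: float,
        xmax: float,
        ymax: float,
        cell_size: float = DEFAULT_CELL_SIZE,
    ) -> "GridSpec":
        """Grid snapped to the lower-left of the extent, covering it fully."""
        n_cols = max(1, int(np.ceil((xmax - xmin) / cell_size - 1e-9)))
        n_rows = max(1, int(np.ceil((ymax - ymin) / cell_size - 1e-9)))
        return cls(origin=(xmin, ymin), cell_size=cell_size, n_rows=n_rows, n_cols=n_cols)


@dataclass
class MetricRaster:
    """One gridded metric layer; NaN marks no-data."""

    grid: GridSpec
    metric_name: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.n_rows}, {self.grid.n_cols})"
            )

    def copy_with(self, values: np.ndarray, metric_name: str | None = None) -> "MetricRaster":
        return MetricRaster(self.grid, metric_name or self.metric_name, np.array(values, float))

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


def smooth_window(raster: MetricRaster, window: int = 3) -> MetricRaster:
    """Spatial moving average ignoring no-data cells.

    Each cell becomes the mean of the finite values inside the
    ``window`` x ``window`` neighborhood.  At the raster edge the window
    shrinks (truncates) rather than padding with no-data, so cells near
    the boundary stay defined.  A neighborhood with no finite value
    stays no-data.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    v = raster.values
    finite = np.isfinite(v)
    filled = np.where(finite, v, 0.0)
    half = window // 2
    total = np.zeros_like(v)
    count = np.zeros_like(v)
    nr, nc = v.shape
    for dr in range(-half, half + 1):
        for dc in range(-half, half + 1):
            r0, r1 = max(0, dr), min(nr, nr + dr)
            s0, s1 = max(0, -dr), min(nr, nr - dr)
            c0, c1 = max(0, dc), min(nc, nc + dc)
            t0, t1 = max(0, -dc), min(nc, nc - dc)
            total[s0:s1, t0:t1] += filled[r0:r1, c0:c1]
            count[s0:s1, t0:t1] += finite[r0:r1, c0:c1]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(count > 0, total / count, np.nan)
    return raster.copy_with(out)


def write_ascii_grid(raster: MetricRaster, path: str | Path, nodata_value: float = -9999.0) -> None:
    """Write an ESRI ASCII grid (text). Row order on disk is north-to-south."""
    path = Path(path)
    g = raster.grid
    vals = np.where(np.isfinite(raster.values), raster.values, nodata_value)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.origin[0]:.6f}\n"
        f"yllcorner {g.origin[1]:.6f}\n"
        f"cellsize {g.cell_size:.6f}\n"
        f"NODATA_value {nodata_value}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, vals[::-1], fmt="%.6f")


def read_ascii_grid(path: str | Path, metric_name: str = "metric") -> MetricRaster:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1]
    nodata = header.get("nodata_value", -9999.0)
    data = np.where(np.isclose(data, nodata), np.nan, data)
    grid = GridSpec(
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
    )
    return MetricRaster(grid, metric_name, data)
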