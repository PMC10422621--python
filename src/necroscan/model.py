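"""Necromass regression: canopy-cover change as a predictor of standing dead mass.

The calibration model is a simple linear regression of field-measured
aboveground necromass (AGN, Mg/ha) on the fractional change in lidar
F-Cover between the pre- and post-storm surveys,

    AGN = a1 + a2 * dPFc,

where dPFc = (F_after - F_before) / F_before is dimensionless (a 36% cover
loss enters as -0.36, not -36).  Prediction uncertainty is quantified by
leave-one-out cross-validation: each plot is predicted from a model fitted
to the remaining plots and the root mean square of the held-out errors is
reported.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlotCalibrationPoint:
    """One plot's pairing of fractional F-Cover change and field AGN."""

    plot_id: str
    dpfc: float  # fractional change, negative = canopy loss
    agn_field: float  # Mg/ha; NaN when the plot lacks a field estimate

    def __post_init__(self) -> None:
        if self.dpfc < -1:
            raise ValueError(f"{self.plot_id}: fractional change {self.dpfc} < -1")
        if np.isfinite(self.agn_field) and self.agn_field < 0:
            raise ValueError(f"{self.plot_id}: negative field AGN")


@dataclass
class AGNModel:
    """Fitted AGN-vs-cover-change regression with diagnostics."""

    a1: float  # intercept, Mg/ha
    a2: float  # slope, Mg/ha per unit fractional cover change
    n: int
    r: float
    r2: float
    p_value: float
    rmse_loocv: float = float("nan")
    residuals: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AGNModel":
        return cls(**json.loads(Path(path).read_text()))


def percent_change(before: float, after: float) -> float:
    """Fractional change (after - before) / before.

    Returned as a fraction; multiply by 100 only for display.
    """
    if before == 0:
        raise ZeroDivisionError("percent change undefined for before == 0")
    return (after - before) / before


def _complete_points(
    points: Sequence[PlotCalibrationPoint],
) -> list[PlotCalibrationPoint]:
    complete = [p for p in points if np.isfinite(p.agn_field)]
    dropped = [p.plot_id for p in points if not np.isfinite(p.agn_field)]
    if dropped:
        logger.info("excluding plots without field AGN: %s", ", ".join(dropped))
    return complete


def fit_agn_regression(points: Sequence[PlotCalibrationPoint]) -> AGNModel:
    """Ordinary least squares of field AGN on fractional F-Cover change.

    Points with missing (NaN) field AGN are excluded with a logged note.
    Reports the intercept a1, slope a2, Pearson r between AGN and dPFc,
    r^2, and the two-sided t-test p-value on the slope.
    """
    pts = _complete_points(points)
    if len(pts) < 3:
        raise ValueError(f"need at least 3 complete calibration points, got {len(pts)}")
    x = np.array([p.dpfc for p in pts])
    y = np.array([p.agn_field for p in pts])
    if np.allclose(x, x[0]):
        raise ValueError("degenerate design: all cover changes identical")
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    a1, a2 = ols.params
    r, _ = stats.pearsonr(x, y)
    fitted = a1 + a2 * x
    model = AGNModel(
        a1=float(a1),
        a2=float(a2),
        n=len(pts),
        r=float(r),
        r2=float(r) ** 2,
        p_value=float(ols.pvalues[1]),
        residuals={p.plot_id: float(res) for p, res in zip(pts, y - fitted)},
    )
    model.rmse_loocv = loocv_rmse(pts) if len(pts) >= 4 else float("nan")
    return model


def loocv_rmse(points: Sequence[PlotCalibrationPoint]) -> float:
    """Leave-one-out cross-validated RMSE (Mg/ha) of the regression.

    Each point is predicted from an OLS fit to the other n-1 points;
    the explicit refit loop is kept deliberately simple (n is small).
    """
    pts = _complete_points(points)
    if len(pts) < 4:
        raise ValueError(f"LOOCV needs at least 4 points, got {len(pts)}")
    x = np.array([p.dpfc for p in pts])
    y = np.array([p.agn_field for p in pts])
    errors = np.empty(len(pts))
    for i in range(len(pts)):
        keep = np.ones(len(pts), bool)
        keep[i] = False
        xk, yk = x[keep], y[keep]
        res = sm.OLS(yk, sm.add_constant(xk)).fit()
        errors[i] = y[i] - (res.params[0] + res.params[1] * x[i])
    return float(np.sqrt(np.mean(errors ** 2)))


def predict_agn(model: AGNModel, dpfc: float | np.ndarray) -> float | np.ndarray:
    """Evaluate a1 + a2 * dPFc (unclamped; clamping happens at raster stage)."""
    out = model.a1 + model.a2 * np.asarray(dpfc, float)
    return float(out) if out.ndim == 0 else out


def validate_modeled_vs_field(
    field_agn: Sequence[float], modeled_agn: Sequence[float]
) -> tuple[float, float, float]:
    """Pearson r, r^2, and slope p-value of modeled AGN regressed on field AGN."""
    f = np.asarray(field_agn, float)
    m = np.asarray(modeled_agn, float)
    if f.shape != m.shape:
        raise ValueError(f"length mismatch: {f.shape} vs {m.shape}")
    if len(f) < 3:
        raise ValueError("need at least 3 pairs")
    r, _ = stats.pearsonr(f, m)
    ols = sm.OLS(m, sm.add_constant(f)).fit()
    return float(r), float(r) ** 2, float(ols.pvalues[1])


def calibration_points_from_table(table: pd.DataFrame) -> list[PlotCalibrationPoint]:
    """Build calibration points from a table with columns
    plot_id, fcover_before, fcover_after, agn_field_mg_ha.

    Fractional cover change is always recomputed from the before/after
    columns, never taken from a pre-computed percent column.
    """
    required = {"plot_id", "fcover_before", "fcover_after", "agn_field_mg_ha"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"calibration table missing columns {missing}")
    points = []
    for _, row in table.iterrows():
        points.append(
            PlotCalibrationPoint(
                plot_id=str(row["plot_id"]),
                dpfc=percent_change(float(row["fcover_before"]), float(row["fcover_after"])),
                agn_field=float(row["agn_field_mg_ha"]),
            )
        )
    return points
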