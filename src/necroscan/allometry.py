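"""Field-plot mass estimation: allometry and line-intercept woody debris.

Standing live and dead stems are converted to aboveground mass with
species-specific allometric equations for Everglades mangroves.  Each
species carries four constants (a, b, c, d): total mass and leaf mass are
log10-linear in DBH, and the woody aboveground mass is their difference,

    mass_kg = 10^(a*log10(DBH) + b) - 10^(c*log10(DBH) + d)

with DBH in cm at 1.3 m.  The same equation is applied to standing dead
trees (necromass); no decay-class deduction is made.  Downed wood is
estimated with the line-intercept method: the volume per unit area
contributed by pieces crossing a transect of length L is
pi^2 * sum(d_i^2) / (8 * L).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: minimum censused stem diameter (cm)
DBH_CENSUS_MIN = 5.0

#: coarse/fine woody-debris diameter cut (cm)
WD_COARSE_MIN = 7.5

#: wood specific gravity defaults (g/cm^3 == Mg/m^3) by debris size class.
#: Configurable package defaults, not literature constants.
WD_SPECIFIC_GRAVITY = {"coarse": 0.8, "fine": 0.6}

SPECIES = ("red", "white", "black")

#: per-species (a, b, c, d) of the total-minus-leaf allometry
ALLOMETRY_COEFFICIENTS: dict[str, tuple[float, float, float, float]] = {
    "black": (1.934, -0.395, 0.985, -0.855),
    "white": (1.930, -0.441, 1.160, -1.043),
    "red": (1.731, -0.112, 1.337, -0.843),
}


@dataclass(frozen=True)
class TreeRecord:
    species: str
    dbh: float  # cm at breast height
    status: str  # "live" | "dead"

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(
                f"unsupported species {self.species!r}; expected one of {SPECIES}"
            )
        if self.dbh < DBH_CENSUS_MIN:
            raise ValueError(
                f"dbh {self.dbh} cm below census threshold {DBH_CENSUS_MIN} cm"
            )
        if self.status not in ("live", "dead"):
            raise ValueError(f"status must be 'live' or 'dead', got {self.status!r}")


@dataclass
class WDTransect:
    """Line-intercept transect: intersected piece diameters (cm)."""

    diameters_cm: list[float]
    length_m: float = 10.0

    def __post_init__(self) -> None:
        if self.length_m <= 0:
            raise ValueError("transect length must be positive")
        if any(d <= 0 for d in self.diameters_cm):
            raise ValueError("piece diameters must be positive")


@dataclass
class PlotRecord:
    id: str
    trees: list[TreeRecord] = field(default_factory=list)
    wd_transects: list[WDTransect] = field(default_factory=list)
    center: tuple[float, float] = (0.0, 0.0)
    side: float = 10.0

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError("plot side must be positive")

    @property
    def area_m2(self) -> float:
        return self.side ** 2


@dataclass(frozen=True)
class PlotMasses:
    """Per-plot mass densities, Mg/ha. agtm == agb + agn by construction."""

    plot_id: str
    agb: float
    agn: float
    agtm: float
    wd: float = float("nan")


def tree_mass(species: str, dbh: float,
              coefficients: dict | None = None) -> float:
    """Aboveground woody mass (kg) of one stem from species and DBH (cm)."""
    coefficients = coefficients or ALLOMETRY_COEFFICIENTS
    if species not in coefficients:
        raise ValueError(f"no allometric coefficients for species {species!r}")
    if dbh < DBH_CENSUS_MIN:
        raise ValueError(f"dbh {dbh} cm below census threshold {DBH_CENSUS_MIN} cm")
    a, b, c, d = coefficients[species]
    log_dbh = np.log10(dbh)
    mass = 10.0 ** (a * log_dbh + b) - 10.0 ** (c * log_dbh + d)
    if mass <= 0:
        raise ValueError(
            f"non-positive mass for species={species} dbh={dbh}; check coefficients"
        )
    return float(mass)


def aggregate_plot_mass(plot: PlotRecord,
                        coefficients: dict | None = None) -> PlotMasses:
    """Sum live (AGB) and dead (AGN) stem masses and scale to Mg/ha."""
    kg_to_mg_per_ha = 1e4 / plot.area_m2 / 1e3  # kg on the plot -> Mg/ha
    agb_kg = sum(tree_mass(t.species, t.dbh, coefficients)
                 for t in plot.trees if t.status == "live")
    agn_kg = sum(tree_mass(t.species, t.dbh, coefficients)
                 for t in plot.trees if t.status == "dead")
    agb = agb_kg * kg_to_mg_per_ha
    agn = agn_kg * kg_to_mg_per_ha
    wd = wd_line_intercept(plot.wd_transects)[1] if plot.wd_transects else float("nan")
    return PlotMasses(plot.id, agb=agb, agn=agn, agtm=agb + agn, wd=wd)


def _transect_volume_m3_per_ha(diameters_cm: Iterable[float], length_m: float) -> float:
    d_m = np.asarray(list(diameters_cm), float) / 100.0
    return float(np.pi ** 2 * np.sum(d_m ** 2) / (8.0 * length_m) * 1e4)


def wd_line_intercept(
    transects: list[WDTransect],
    specific_gravity: dict[str, float] | None = None,
) -> tuple[float, float, dict[str, dict[str, float]]]:
    """Downed-wood volume and mass from replicate line-intercept transects.

    Per transect and size class (coarse >= 7.5 cm diameter, fine below),
    volume per area is pi^2 * sum(d^2) / (8L) scaled to m^3/ha; replicate
    transects are averaged after conversion to per-transect totals; mass
    uses the class-specific wood specific gravity (Mg/m^3).  Size class is
    recomputed from the diameter, never trusted from input.

    Returns (volume m^3/ha, mass Mg/ha, per-class breakdown).
    """
    if not transects:
        raise ValueError("at least one transect required")
    sg = specific_gravity or WD_SPECIFIC_GRAVITY
    per_class = {cls: {"volume_m3_ha": 0.0, "mass_mg_ha": 0.0} for cls in ("coarse", "fine")}
    for cls in per_class:
        if cls == "coarse":
            vols = [
                _transect_volume_m3_per_ha(
                    [d for d in t.diameters_cm if d >= WD_COARSE_MIN], t.length_m
                )
                for t in transects
            ]
        else:
            vols = [
                _transect_volume_m3_per_ha(
                    [d for d in t.diameters_cm if d < WD_COARSE_MIN], t.length_m
                )
                for t in transects
            ]
        vol = float(np.mean(vols))
        per_class[cls]["volume_m3_ha"] = vol
        per_class[cls]["mass_mg_ha"] = vol * sg[cls]
    volume = sum(v["volume_m3_ha"] for v in per_class.values())
    mass = sum(v["mass_mg_ha"] for v in per_class.values())
    return volume, mass, per_class


class PlotTableError(ValueError):
    """Validation failure in a plot census table; carries row numbers."""


def load_plot_table(
    trees_path: str | Path, wd_path: str | Path | None = None
) -> list[PlotRecord]:
    """Load plot census (and optionally woody-debris) CSV tables.

    Census columns: plot_id, species, dbh_cm, status.
    Debris columns: plot_id, transect_id, diameter_cm [, length_m].
    Rows violating the census invariants are reported with their row
    numbers (1-based, excluding the header).
    """
    trees = pd.read_csv(trees_path)
    required = {"plot_id", "species", "dbh_cm", "status"}
    if not required.issubset(trees.columns):
        raise PlotTableError(f"{trees_path}: missing columns {required - set(trees.columns)}")
    errors = []
    records: dict[str, PlotRecord] = {}
    for i, row in trees.iterrows():
        try:
            tree = TreeRecord(str(row["species"]).strip(),
                              float(row["dbh_cm"]), str(row["status"]).strip())
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i + 1}: {exc}")
            continue
        pid = str(row["plot_id"])
        records.setdefault(pid, PlotRecord(pid)).trees.append(tree)
    if errors:
        raise PlotTableError(f"{trees_path}: " + "; ".join(errors))
    if wd_path is not None:
        wd = pd.read_csv(wd_path)
        for (pid, _tid), group in wd.groupby(["plot_id", "transect_id"]):
            length = float(group["length_m"].iloc[0]) if "length_m" in group else 10.0
            diam = [d for d in group["diameter_cm"].astype(float) if d > 0]
            records.setdefault(str(pid), PlotRecord(str(pid))).wd_transects.append(
                WDTransect(diam, length)
            )
    return list(records.values())
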