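"""Bundled field-campaign and lidar-summary tables for the Everglades study.

These are the published plot-level values from the January 2018
post-hurricane field campaign along the Shark and Harney Rivers and the
paired March/December 2017 airborne-lidar acquisitions: per-plot pulse
return counts, field mass densities (woody debris, necromass, biomass,
total mass), F-Cover before/after the storm, and modeled necromass/total
mass.  They are carried verbatim as printed, including one internally
inconsistent percent-change cell (plot WSC-9-100, printed as −287.7%
where its own before/after columns give −27.7%); a corrected column
recomputed from the before/after values is provided alongside.

Values are used for calibration, regression reproduction, and as test
oracles; NaN marks cells published as N/A.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

NA = float("nan")

# per-plot total pulse returns, before / after the hurricane
_PULSE_RETURNS = [
    # river, site, plot, before, after
    ("Shark", "SRS-5", "SRS-5-50", 4850, 3196),
    ("Shark", "SRS-5", "SRS-5-100", 4009, 2678),
    ("Shark", "SRS-6", "SRS-6-50", 4792, 4088),
    ("Shark", "SRS-6", "SRS-6-100", 4637, 4159),
    ("Shark", "SRS-6", "SRS-6-100-P2", 4954, 4102),
    ("Shark", "SRS-6", "SRS-6-350", 2577, 3200),
    ("Harney", "WSC-8", "WSC-8-50", 3043, 3290),
    ("Harney", "WSC-8", "WSC-8-100", 1743, 1789),
    ("Harney", "WSC-9", "WSC-9-50", 2840, 1139),
    ("Harney", "WSC-9", "WSC-9-100", 3064, 2695),
    ("Harney", "WSC-9", "WSC-9-350", 2943, 2514),
    ("Harney", "WSC-10", "WSC-10-50", 1693, 1938),
    ("Harney", "WSC-10", "WSC-10-100", 1605, 1638),
    ("Harney", "WSC-10", "WSC-10-350", 2438, 2290),
]

# field mass densities (Mg/ha): WD, AGN, AGB, AGTM
_FIELD_MASSES = [
    ("Shark", "SRS-5", "SRS-5-50", 30.7, 16.4, 140.7, 157.0),
    ("Shark", "SRS-5", "SRS-5-100", 21.8, 24.7, 87.4, 112.1),
    ("Shark", "SRS-6", "SRS-6-50", 2.6, 52.3, 119.6, 172.0),
    ("Shark", "SRS-6", "SRS-6-100", NA, 87.3, NA, NA),
    ("Shark", "SRS-6", "SRS-6-100-P2", 40.9, NA, 60.6, 60.57),
    ("Shark", "SRS-6", "SRS-6-350", 52.3, 4.00, 141.1, 145.1),
    ("Harney", "WSC-8", "WSC-8-50", 3.0, 63.5, 59.3, 122.8),
    ("Harney", "WSC-8", "WSC-8-100", 9.8, 40.5, 65.3, 105.7),
    ("Harney", "WSC-9", "WSC-9-50", 7.4, 35.7, 107.7, 143.3),
    ("Harney", "WSC-9", "WSC-9-100", 157.6, 52.1, 99.63, 151.8),
    ("Harney", "WSC-9", "WSC-9-350", 22.7, 9.4, 136.3, 145.7),
    ("Harney", "WSC-10", "WSC-10-50", 23.7, 57.6, 99.6, 157.2),
    ("Harney", "WSC-10", "WSC-10-100", 84.3, 35.8, 56.8, 92.60),
    ("Harney", "WSC-10", "WSC-10-350", 19.7, 113.1, 74.2, 187.3),
]

# F-Cover percent before / after, printed change and printed percent change
_FCOVER = [
    ("Shark", "SRS-5", "SRS-5-50", 96.7, 79.6, -17.1, -17.7),
    ("Shark", "SRS-5", "SRS-5-100", 96.1, 83.8, -12.3, -12.8),
    ("Shark", "SRS-6", "SRS-6-50", 93.8, 60.0, -33.8, -36.0),
    ("Shark", "SRS-6", "SRS-6-100", 96.4, 65.7, -30.7, -31.8),
    ("Shark", "SRS-6", "SRS-6-100-P2", 96.4, 65.7, -30.7, -31.8),
    ("Shark", "SRS-6", "SRS-6-350", 96.1, 72.6, -23.5, -24.5),
    ("Harney", "WSC-8", "WSC-8-50", 96.7, 61.5, -35.2, -36.4),
    ("Harney", "WSC-8", "WSC-8-100", 94.9, 72.2, -22.7, -23.9),
    ("Harney", "WSC-9", "WSC-9-50", 96.9, 76.7, -20.2, -20.8),
    ("Harney", "WSC-9", "WSC-9-100", 98.2, 71.0, -27.2, -287.7),  # typo as printed
    ("Harney", "WSC-9", "WSC-9-350", 97.8, 75.7, -22.1, -22.6),
    ("Harney", "WSC-10", "WSC-10-50", 94.7, 69.6, -25.1, -26.5),
    ("Harney", "WSC-10", "WSC-10-100", 95.0, 70.3, -24.7, -26.0),
    ("Harney", "WSC-10", "WSC-10-350", 98.2, 64.9, -33.2, -33.9),
]

# field and modeled AGN / AGTM with their ratios (%)
_AGN_AGTM = [
    ("Shark", "SRS-5", "SRS-5-50", 16.4, 157.0, 10.5, 19.7, 141.3, 13.9),
    ("Shark", "SRS-5", "SRS-5-100", 24.7, 112.1, 22.0, 4.8, 118.3, 4.1),
    ("Shark", "SRS-6", "SRS-6-50", 52.3, 172.0, 30.4, 75.2, 202.2, 37.2),
    ("Shark", "SRS-6", "SRS-6-100", 87.3, NA, NA, 62.6, 224.4, 27.9),
    ("Shark", "SRS-6", "SRS-6-100-P2", NA, 60.57, NA, 62.6, 224.4, 27.9),
    ("Shark", "SRS-6", "SRS-6-350", 4.00, 145.1, 2.8, 40.3, 138.9, 29.0),
    ("Harney", "WSC-8", "WSC-8-50", 63.5, 122.8, 51.7, 76.6, 149.8, 51.1),
    ("Harney", "WSC-8", "WSC-8-100", 40.5, 105.7, 38.3, 38.8, 78.5, 49.4),
    ("Harney", "WSC-9", "WSC-9-50", 35.7, 143.3, 24.9, 29.1, 124.1, 23.4),
    ("Harney", "WSC-9", "WSC-9-100", 52.1, 151.8, 34.3, 50.1, 174.0, 28.8),
    ("Harney", "WSC-9", "WSC-9-350", 9.4, 145.7, 6.5, 34.4, 161.38, 21.3),
    ("Harney", "WSC-10", "WSC-10-50", 57.6, 157.2, 36.6, 46.5, 164.7, 28.2),
    ("Harney", "WSC-10", "WSC-10-100", 35.8, 92.60, 38.7, 44.8, 141.6, 31.6),
    ("Harney", "WSC-10", "WSC-10-350", 113.1, 187.3, 60.4, 67.0, 164.2, 40.8),
]


def pulse_returns() -> pd.DataFrame:
    """Per-plot total pulse return counts before/after the storm."""
    df = pd.DataFrame(
        _PULSE_RETURNS, columns=["river", "site", "plot_id", "before", "after"]
    )
    df["difference"] = df["after"] - df["before"]
    return df


def field_masses() -> pd.DataFrame:
    """Per-plot field mass densities (Mg/ha)."""
    return pd.DataFrame(
        _FIELD_MASSES,
        columns=["river", "site", "plot_id", "wd", "agn", "agb", "agtm"],
    )


def fcover_change() -> pd.DataFrame:
    """Per-plot F-Cover (%) before/after with printed and corrected changes.

    ``percent_change_printed`` carries the published cells verbatim,
    including the WSC-9-100 typo; ``percent_change_corrected`` is
    recomputed from the before/after columns and is what calibration uses.
    """
    df = pd.DataFrame(
        _FCOVER,
        columns=[
            "river", "site", "plot_id", "fcover_before", "fcover_after",
            "change_printed", "percent_change_printed",
        ],
    )
    df["percent_change_corrected"] = (
        (df["fcover_after"] - df["fcover_before"]) / df["fcover_before"] * 100.0
    )
    return df


def agn_agtm_ratios() -> pd.DataFrame:
    """Per-plot field and modeled AGN, AGTM, and their ratios (%)."""
    return pd.DataFrame(
        _AGN_AGTM,
        columns=[
            "river", "site", "plot_id",
            "agn_field", "agtm_field", "ratio_field_pct",
            "agn_modeled", "agtm_modeled", "ratio_modeled_pct",
        ],
    )


def calibration_table() -> pd.DataFrame:
    """Plots with both a field AGN estimate and F-Cover change (n = 13).

    Joins the field necromass table with the cover-change table and drops
    plots published without a field AGN value (the second SRS-6-100 plot).
    """
    fc = fcover_change()[["plot_id", "fcover_before", "fcover_after"]]
    fm = field_masses()[["plot_id", "agn"]].rename(columns={"agn": "agn_field_mg_ha"})
    merged = fc.merge(fm, on="plot_id")
    return merged[np.isfinite(merged["agn_field_mg_ha"])].reset_index(drop=True)


def study_tables() -> dict[str, pd.DataFrame]:
    """All bundled study tables keyed by content."""
    return {
        "pulse_returns": pulse_returns(),
        "field_masses": field_masses(),
        "fcover_change": fcover_change(),
        "agn_agtm_ratios": agn_agtm_ratios(),
        "calibration": calibration_table(),
    }
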