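"""Bundled reference dataset: published group statistics from a two-year
willow (Salix miyabeana 'SX67') fertigation experiment.

Three irrigation treatments — UI (unirrigated control), PW (potable water)
and WWD (primary wastewater) — each with 12 replicate trees.  The tables
hold treatment means and standard errors for the xylem/vessel traits, the
vessel diameter-class decomposition (classes are half-open ``[a, b)`` µm)
and the wood composition assay (% of oven-dry mass).  They serve as worked
inputs for the arithmetic layers of this package and as calibration anchors
for the synthetic generator defaults.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_willow_fertigation"]

TREATMENTS = ("UI", "PW", "WWD")
CLASS_LABELS = ("[10-20)", "[20-30)", "[30-40)", "[40-50)", "[50-60)", "[60-70)")

# smallest / largest vessel lumen areas observed across all samples (µm²)
VESSEL_AREA_EXTREMES_UM2 = (250.015, 2999.9)


def _t(columns: dict) -> pd.DataFrame:
    df = pd.DataFrame(columns, index=list(TREATMENTS))
    df.index.name = "treatment"
    return df


def load_willow_fertigation() -> dict[str, pd.DataFrame]:
    """Return the reference tables as a dict of DataFrames.

    Keys: ``traits`` (per-treatment xylem trait means/SE), ``class_frequency``
    and ``ks_contribution`` (per diameter class, % mean/SE), ``composition``
    (mass fractions, % mean/SE).  n = 12 per treatment throughout.
    """
    traits = _t(
        {
            "wood_density_mean": [0.37, 0.39, 0.32],
            "wood_density_se": [0.01, 0.01, 0.01],
            "fiber_ray_density_mean": [5695, 5756, 6243],
            "fiber_ray_density_se": [90, 109, 70],
            "fiber_ray_pct_mean": [81, 81, 84],
            "tension_wood_pct_mean": [27.6, 34.1, 39.8],
            "tension_wood_pct_se": [2.4, 3.0, 2.0],
            "mean_vessel_area_um2_mean": [1112, 1083, 1064],
            "mean_vessel_area_um2_se": [16, 15, 18],
            "mean_vessel_diameter_um_mean": [36.2, 36.0, 35.5],
            "mean_vessel_diameter_um_se": [0.2, 0.2, 0.3],
            "vessel_density_per_mm2_mean": [172, 173, 152],
            "vessel_density_per_mm2_se": [4, 3, 4],
            "ks_mean": [10.79, 9.99, 8.85],
            "ks_se": [0.2, 0.3, 0.4],
            "xylem_pct_mean": [92.4, 94.6, 95.8],
            "vessel_pct_mean": [19, 19, 16],
            "vessel_fiber_density_ratio_pct_mean": [3.0, 3.0, 2.4],
            "vessel_fiber_area_ratio_pct_mean": [24, 23, 19],
            "n": [12, 12, 12],
        }
    )

    freq = pd.DataFrame(
        {
            "[10-20)": [6.1, 5.1, 5.8],
            "[20-30)": [22.8, 21.4, 25.0],
            "[30-40)": [34.7, 39.4, 37.6],
            "[40-50)": [26.5, 27.5, 22.7],
            "[50-60)": [9.5, 6.3, 8.4],
            "[60-70)": [0.5, 0.2, 0.4],
        },
        index=list(TREATMENTS),
    )
    freq.index.name = "treatment"
    freq_se = pd.DataFrame(
        {
            "[10-20)": [0.5, 0.2, 0.4],
            "[20-30)": [0.6, 0.8, 1.3],
            "[30-40)": [0.9, 0.7, 0.9],
            "[40-50)": [1.2, 0.7, 1.5],
            "[50-60)": [1.1, 0.6, 0.6],
            "[60-70)": [0.1, 0.0, 0.1],
        },
        index=list(TREATMENTS),
    )
    freq_se.index.name = "treatment"

    ks_contrib = pd.DataFrame(
        {
            "[10-20)": [0.3, 0.3, 0.3],
            "[20-30)": [3.9, 4.1, 4.9],
            "[30-40)": [22.0, 27.6, 24.8],
            "[40-50)": [41.2, 45.1, 38.1],
            "[50-60)": [30.2, 21.7, 29.6],
            "[60-70)": [2.3, 1.2, 2.3],
        },
        index=list(TREATMENTS),
    )
    ks_contrib.index.name = "treatment"
    ks_contrib_se = pd.DataFrame(
        {
            "[10-20)": [0.02, 0.01, 0.02],
            "[20-30)": [0.2, 0.2, 0.4],
            "[30-40)": [1.2, 1.1, 1.0],
            "[40-50)": [2.3, 0.8, 2.1],
            "[50-60)": [2.8, 1.6, 2.0],
            "[60-70)": [0.5, 0.2, 0.4],
        },
        index=list(TREATMENTS),
    )
    ks_contrib_se.index.name = "treatment"

    composition = _t(
        {
            "glucan_mean": [33.9, 36.2, 39.5],
            "glucan_se": [1.2, 0.7, 1.1],
            "xylan_mean": [11.9, 12.6, 13.3],
            "xylan_se": [0.5, 0.2, 0.5],
            "galactan_mean": [1.3, 1.4, 1.3],
            "galactan_se": [0.06, 0.03, 0.05],
            "arabinan_mean": [1.2, 1.3, 1.0],
            "arabinan_se": [0.1, 0.1, 0.1],
            "mannan_mean": [1.7, 2.0, 2.0],
            "mannan_se": [0.1, 0.1, 0.1],
            "hemicellulose_mean": [16.1, 17.3, 17.7],
            "hemicellulose_se": [0.6, 0.3, 0.6],
            "total_sugars_mean": [50.0, 53.6, 57.2],
            "total_sugars_se": [1.8, 1.0, 1.6],
            "asl_mean": [5.2, 5.1, 5.3],
            "asl_se": [0.05, 0.07, 0.06],
            "ail_mean": [22.5, 22.1, 22.8],
            "ail_se": [0.3, 0.3, 0.3],
            "total_lignin_mean": [27.7, 27.1, 28.1],
            "total_lignin_se": [0.3, 0.3, 0.3],
            "extractives_mean": [10.5, 10.7, 6.8],
            "extractives_se": [0.1, 0.3, 0.2],
            "mass_closure_mean": [88.2, 91.4, 92.1],
            "mass_closure_se": [1.7, 1.0, 1.5],
        }
    )

    return {
        "traits": traits,
        "class_frequency": freq,
        "class_frequency_se": freq_se,
        "ks_contribution": ks_contrib,
        "ks_contribution_se": ks_contrib_se,
        "composition": composition,
    }
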