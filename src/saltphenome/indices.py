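"""Scalar salinity-tolerance indices from harvest, ion and senescence data.

All normalisations are ratios of group means (the convention for
screening tables), not means of per-plant ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "salinity_tolerance",
    "normalize_to_control",
    "na_k_ratio",
    "tissue_water_concentration",
    "relative_senescence",
    "tolerance_table",
]


def salinity_tolerance(sdw_salt: float, sdw_control: float) -> float:
    """Salinity tolerance ST = 100 * mean SDW under salt / mean SDW control.

    Conventionally computed at 80 mM NaCl, but any salt level's mean may
    be supplied.  Scale-invariant in the SDW units.
    """
    if not sdw_control > 0:
        raise ValueError(f"control mean SDW must be > 0, got {sdw_control}")
    return 100.0 * sdw_salt / sdw_control


def normalize_to_control(values_salt, values_control) -> float:
    """Ratio of the salt-group mean to the control-group mean.

    Used for chlorophyll and biomass normalisation; a value of 0.66
    reads as a 34% reduction relative to non-salinised plants.
    """
    salt = np.asarray(values_salt, dtype=float)
    control = np.asarray(values_control, dtype=float)
    if salt.size == 0 or control.size == 0:
        raise ValueError("empty group")
    cm = control.mean()
    if not cm > 0:
        raise ValueError(f"control mean must be > 0, got {cm}")
    return float(salt.mean() / cm)


def na_k_ratio(na: float, k: float) -> float:
    """Shoot Na+/K+ ratio (both in umol g^-1 DW)."""
    if not k > 0:
        raise ValueError(f"K+ concentration must be > 0, got {k}")
    return na / k


def tissue_water_concentration(conc_dw: float, fw_dw_ratio: float,
                               *, rounded: bool = False) -> float:
    """Re-express a dry-weight ion concentration per gram of tissue water.

    A gram of dry matter in tissue with fresh/dry ratio R carries
    (R - 1) grams of water, so c_tw = c_dw / (R - 1).  For example
    114 umol g^-1 DW at R = 3.6 is 43.85 — 44 when rounded — umol per
    gram of tissue water.
    """
    if not fw_dw_ratio > 1:
        raise ValueError(
            f"FW/DW ratio must exceed 1 (no tissue water otherwise), got {fw_dw_ratio}")
    c = conc_dw / (fw_dw_ratio - 1.0)
    return float(round(c)) if rounded else float(c)


def relative_senescence(sen_salt, sen_control) -> float:
    """Percent increase of mean senescence under salt relative to control."""
    salt = np.asarray(sen_salt, dtype=float)
    control = np.asarray(sen_control, dtype=float)
    if salt.size == 0 or control.size == 0:
        raise ValueError("empty group")
    cm = control.mean()
    if not cm > 0:
        raise ValueError(f"control mean senescence must be > 0, got {cm}")
    return float(100.0 * (salt.mean() - cm) / cm)


def tolerance_table(
    harvest: pd.DataFrame,
    ion: pd.DataFrame,
    metadata: pd.DataFrame,
    salt_level: str = "80mM",
    control_level: str = "0mM",
) -> pd.DataFrame:
    """Genotype-level tolerance indices at one salt level vs control.

    Joins the harvest and ion tables through the design metadata and
    returns one row per genotype: ST (percent), mean Na+/K+, chlorophyll
    and biomass normalised to control, relative senescence (percent),
    and mean ion concentrations under salt.
    """
    joined = harvest.merge(ion, on="plant").merge(
        metadata[["plant", "genotype", "treatment"]], on="plant")
    rows = []
    for genotype, g in joined.groupby("genotype", sort=True):
        salt = g[g["treatment"] == salt_level]
        control = g[g["treatment"] == control_level]
        if salt.empty or control.empty:
            raise ValueError(
                f"genotype {genotype!r}: missing {salt_level} or {control_level} group")
        na_mean = salt["na_umol_gdw"].mean()
        k_mean = salt["k_umol_gdw"].mean()
        rows.append({
            "genotype": genotype,
            "treatment": salt_level,
            "st_pct": salinity_tolerance(salt["sdw_g"].mean(),
                                         control["sdw_g"].mean()),
            "na_k": na_k_ratio(na_mean, k_mean),
            "na_umol_gdw": na_mean,
            "k_umol_gdw": k_mean,
            "norm_chlorophyll": normalize_to_control(salt["chlorophyll_mg_g"],
                                                     control["chlorophyll_mg_g"]),
            "norm_biomass": normalize_to_control(salt["sdw_g"], control["sdw_g"]),
            "rel_senescence_pct": relative_senescence(salt["senescence"],
                                                      control["senescence"]),
            "mean_ses": salt["ses"].mean(),
            "n_salt": len(salt),
            "n_control": len(control),
        })
    return pd.DataFrame(rows)
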