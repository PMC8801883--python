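"""Plot-level yield components and efficiency traits.

Covers the derived quantities of a maize shading or stand-density trial:
individual kernel weight from a 400-kernel sample (reported at
145 g kg^-1 moisture), kernel number per plant back-calculated from yield,
relative yield paired to the unshaded control within genotype and block,
barrenness (< 10 kernels per plant), biomass partitioning efficiency,
seed-set efficiency, and the cross-experiment response summaries linking
shading susceptibility to stand-density behaviour.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "STANDARD_MOISTURE",
    "kernel_weight",
    "knp_from_yield",
    "relative_yield",
    "add_relative_yield",
    "barrenness",
    "partition_efficiency",
    "seed_set_efficiency",
    "response_summaries",
]

#: Reporting moisture content for yield and kernel weight (g water / g).
STANDARD_MOISTURE = 0.145

#: Kernels weighed per plot sample.
SAMPLE_KERNELS = 400

#: Plants with fewer than this many kernels count as barren.
BARREN_THRESHOLD = 10


def kernel_weight(sample_weight: float, sample_moisture: float = STANDARD_MOISTURE,
                  n_kernels: int = SAMPLE_KERNELS) -> float:
    """Individual kernel weight (mg) at 145 g kg^-1 moisture.

    ``sample_weight`` is the mass (g) of ``n_kernels`` kernels at
    ``sample_moisture`` (g water per g fresh weight; pass 0 for oven-dry
    samples).  The reported weight is dry matter / (1 - 0.145).
    """
    if sample_weight <= 0:
        raise ValueError("sample weight must be > 0")
    if not 0.0 <= sample_moisture < 1.0:
        raise ValueError("moisture must lie in [0, 1)")
    dry_mg = sample_weight * (1.0 - sample_moisture) * 1000.0 / n_kernels
    return dry_mg / (1.0 - STANDARD_MOISTURE)


def knp_from_yield(yield_mg_ha: float, kw_mg: float, density: float) -> float:
    """Kernel number per plant from plot yield, KW and stand density.

    yield in Mg ha^-1 (1 Mg ha^-1 = 100 g m^-2), kw in mg kernel^-1,
    density in plants m^-2.
    """
    if kw_mg <= 0 or density <= 0:
        raise ValueError("kernel weight and density must be > 0")
    if yield_mg_ha < 0:
        raise ValueError("yield must be >= 0")
    return (yield_mg_ha * 100.0) / (kw_mg / 1000.0) / density


def relative_yield(treatment_yield: float, control_yield: float) -> float:
    """Treatment yield as % of the paired control (same genotype x block)."""
    if control_yield <= 0:
        raise ValueError("control yield must be > 0")
    # parenthesised so a plot divided by itself is exactly 100.0
    return 100.0 * (treatment_yield / control_yield)


def add_relative_yield(plots: pd.DataFrame, control: str = "T0",
                       keys: tuple[str, ...] = ("env", "hybrid", "block"),
                       yield_col: str = "yield_mg_ha") -> pd.DataFrame:
    """Return ``plots`` with a ``relative_yield_pct`` column.

    Pairing is strict: each plot is divided by the control plot of the
    same (env, hybrid, block); a missing control raises ``ValueError``.
    """
    keys = list(keys)
    ctrl = plots.loc[plots["treatment"] == control, keys + [yield_col]]
    if ctrl.empty:
        raise ValueError(f"no control treatment {control!r} in table")
    dup = ctrl.duplicated(subset=keys)
    if dup.any():
        raise ValueError("multiple control plots for one genotype x block")
    merged = plots.merge(ctrl.rename(columns={yield_col: "_ctrl_yield"}),
                         on=keys, how="left", validate="many_to_one")
    if merged["_ctrl_yield"].isna().any():
        missing = merged.loc[merged["_ctrl_yield"].isna(), keys].drop_duplicates()
        raise ValueError(f"missing control for: {missing.to_dict('records')}")
    if (merged["_ctrl_yield"] <= 0).any():
        raise ValueError("control yield must be > 0 for relative yield")
    merged["relative_yield_pct"] = (
        100.0 * (merged[yield_col] / merged["_ctrl_yield"]))
    return merged.drop(columns="_ctrl_yield")


def barrenness(kernel_counts) -> float:
    """Percentage of plants with fewer than 10 kernels at maturity.

    Exactly 10 kernels is not barren (the threshold is strict).
    """
    counts = np.asarray(kernel_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("need at least one plant")
    return float(100.0 * np.mean(counts < BARREN_THRESHOLD))


def partition_efficiency(eb: float, total_biomass: float) -> float:
    """Ear biomass over total shoot biomass 15 d after anthesis (g g^-1)."""
    if total_biomass <= 0:
        raise ValueError("total biomass must be > 0")
    if eb > total_biomass:
        raise ValueError("ear biomass cannot exceed total biomass")
    if eb < 0:
        raise ValueError("ear biomass must be >= 0")
    return eb / total_biomass


def seed_set_efficiency(knp: float, eb: float) -> float:
    """Kernels set per gram of accumulated ear biomass."""
    if eb <= 0:
        raise ValueError("ear biomass must be > 0")
    if knp < 0:
        raise ValueError("kernel number must be >= 0")
    return knp / eb


def response_summaries(shading_plots: pd.DataFrame,
                       density_plots: pd.DataFrame,
                       s0_label: str = "S0", control: str = "T0"
                       ) -> tuple[pd.DataFrame, dict]:
    """Per-hybrid shading susceptibility vs stand-density response.

    shading_susceptibility = 100 - mean relative yield of the shading
    window ending at anthesis; optimum_density is the tested density with
    maximum mean yield; supraoptimal_decline is the % yield drop from the
    optimum to the highest tested density.  Returns the per-hybrid table
    and Spearman rank correlations of susceptibility with
    (-optimum_density) and with supraoptimal_decline.
    """
    if "relative_yield_pct" not in shading_plots.columns:
        shading_plots = add_relative_yield(shading_plots, control=control)
    s0 = shading_plots[shading_plots["treatment"] == s0_label]
    if s0.empty:
        raise ValueError(f"no {s0_label!r} treatment in shading table")
    suscept = 100.0 - s0.groupby("hybrid")["relative_yield_pct"].mean()

    dens_means = (density_plots
                  .groupby(["hybrid", "density_pl_m2"])["yield_mg_ha"]
                  .mean().reset_index())
    d_max = density_plots["density_pl_m2"].max()
    rows = []
    for hyb, grp in dens_means.groupby("hybrid"):
        opt_row = grp.loc[grp["yield_mg_ha"].idxmax()]
        y_at_max = grp.loc[grp["density_pl_m2"] == d_max,
                           "yield_mg_ha"].iloc[0]
        decline = 100.0 * (opt_row["yield_mg_ha"] - y_at_max) \
            / opt_row["yield_mg_ha"]
        rows.append({"hybrid": hyb,
                     "optimum_density": float(opt_row["density_pl_m2"]),
                     "supraoptimal_decline_pct": float(decline)})
    dens_tbl = pd.DataFrame(rows).set_index("hybrid")

    common = suscept.index.intersection(dens_tbl.index)
    if len(common) < 3:
        raise ValueError("need at least 3 hybrids common to both experiments")
    table = dens_tbl.loc[common].copy()
    table.insert(0, "shading_susceptibility_pct", suscept.loc[common])
    rho_opt, p_opt = spearmanr(table["shading_susceptibility_pct"],
                               -table["optimum_density"])
    rho_dec, p_dec = spearmanr(table["shading_susceptibility_pct"],
                               table["supraoptimal_decline_pct"])
    corr = {"rho_optimum_density": float(rho_opt), "p_optimum_density": float(p_opt),
            "rho_supraoptimal_decline": float(rho_dec),
            "p_supraoptimal_decline": float(p_dec)}
    return table.reset_index(), corr
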