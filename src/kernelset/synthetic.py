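"""Synthetic maize trial generator.

Emulates the data structure of two kinds of field experiments on
commercial maize hybrids:

* **shading trials** — an RCBD in which whole plots are shaded for 7-day
  windows around anthesis (80% reduction of incident PAR), with an
  unshaded control, and ~15 tagged plants per plot phenotyped for growth
  and kernel number;
* **stand-density trials** — the same hybrids grown at 5, 7, 9 and
  11 plants m^-2 in an RCBD across sowing-date environments.

Each plant carries a latent potential growth rate around flowering
(lognormal between plants).  Shading multiplies instantaneous growth
during the window's overlap with the +/-15 d flowering interval by
``1 - (1 - transmission) * sensitivity * window_weight``; crowding scales
mean growth as ``density^-gamma`` with an exponent steepened by the same
genotype sensitivity (crowding tolerance = 1 - sensitivity).  Ear biomass
and kernel number then follow the genotype's piecewise hyperbolic
responses with multiplicative observation noise, and morphometrics
(height, stem diameter, ear diameter) are generated so the allometric
calibration regressions hold up to that noise.

Every plot holds its own independently drawn plants, as in a real trial
where the control is a physically distinct plot; with all noise sources
at zero (``obs_noise_cv = 0`` and ``pgr_cv = 0``) and zero sensitivity,
every relative yield is exactly 100%.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (GenotypeCoefficients, REFERENCE_HYBRIDS,
                    ear_biomass_forward, kernel_number_forward)

__all__ = [
    "SimConfig",
    "SimOutput",
    "default_shading_config",
    "default_density_config",
    "simulate_shading_experiment",
    "simulate_density_trial",
    "generate_recovery_dataset",
]

CONTROL_LABEL = "T0"

#: Shading windows in days relative to anthesis (start, end).
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "S-14": (-21.0, -14.0),
    "S-7": (-14.0, -7.0),
    "S0": (-7.0, 0.0),
    "S+7": (0.0, 7.0),
    "S+14": (7.0, 14.0),
}

#: Triangular proximity-to-anthesis weights, peaking at the window ending
#: at anthesis (S0) and decaying outward.
DEFAULT_WINDOW_WEIGHTS: dict[str, float] = {
    "S-14": 0.2, "S-7": 0.6, "S0": 1.0, "S+7": 0.6, "S+14": 0.2,
}

#: Shading sensitivity in [0, 1] per hybrid; H2 and H3 are the susceptible
#: genotypes, H1 and H4 the tolerant ones.
DEFAULT_SENSITIVITY = {"H1": 0.2, "H2": 0.9, "H3": 0.7, "H4": 0.1}

#: Mean plant growth rate around flowering (g plant^-1 d^-1) per hybrid.
DEFAULT_PGR_MEAN = {"H1": 3.93, "H2": 3.78, "H3": 2.88, "H4": 3.48}

#: Mean individual kernel weight (mg, at 145 g kg^-1 moisture) per hybrid.
DEFAULT_KW_MEAN = {"H1": 317.0, "H2": 329.0, "H3": 320.0, "H4": 342.0}

# Generating truth for the allometric relations (see methods note).
_PRE_INTERCEPT = 5.0      # g; shoot biomass ~ stem volume
_PRE_SLOPE = 0.12         # g cm^-3
_EAR_K = 1.6              # g cm^-2; ear biomass ~ diameter^2
_BASELINE_SHOOT_G = 20.0  # g shoot biomass independent of growth rate
_PREFLOWER_DAYS = 15.0    # d of growth embodied in the preflowering sample
_MORPH_NOISE_FRACTION = 0.2   # morphometric noise CV as fraction of obs CV
_KW_NOISE_FRACTION = 0.3       # kernel-weight noise CV as fraction of obs CV


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment.

    genotypes are (label, GenotypeCoefficients, shading_sensitivity)
    triples with sensitivity in [0, 1].  ``windows`` (shading) or
    ``densities`` (plants m^-2, strictly increasing) define the treatment
    design; both default to the study layouts.  ``pgr_cv`` and
    ``obs_noise_cv`` are percentages.
    """

    genotypes: list[tuple[str, GenotypeCoefficients, float]] = field(
        default_factory=lambda: [
            (h, REFERENCE_HYBRIDS[h], DEFAULT_SENSITIVITY[h])
            for h in ("H1", "H2", "H3", "H4")])
    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS))
    window_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WINDOW_WEIGHTS))
    densities: tuple[float, ...] = (5.0, 7.0, 9.0, 11.0)
    environments: tuple[str, ...] = ("Env1", "Env2")
    restricted_windows: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"S-14": ("Env1",)})
    n_blocks: int = 3
    n_tagged_plants: int = 15
    pgr_mean_per_genotype: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PGR_MEAN))
    pgr_cv: float = 30.0
    shade_transmission: float = 0.2
    obs_noise_cv: float = 10.0
    kw_mean: dict[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_KW_MEAN))
    stand_density: float = 8.0         # plants m^-2 in shading trials
    density_ref: float = 5.0           # density at which pgr_mean applies
    density_exponent: float = 0.5      # gamma of the resource-share rule
    flowering_interval_days: float = 30.0
    anthesis_interval: tuple[float, float] = (-15.0, 15.0)
    block_cv: float = 3.0              # % multiplicative block effect
    env_decline: float = 0.06          # per-environment growth decline
    area_m2: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.shade_transmission <= 1.0:
            raise ValueError("shade_transmission must lie in [0, 1]")
        if self.n_blocks < 2:
            raise ValueError("n_blocks must be >= 2")
        if self.pgr_cv < 0 or self.obs_noise_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.n_tagged_plants <= 0:
            raise ValueError("n_tagged_plants must be positive")
        for label, _, s in self.genotypes:
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"sensitivity of {label} must lie in [0, 1]")

    def kw_for(self, hybrid: str) -> float:
        if isinstance(self.kw_mean, dict):
            return float(self.kw_mean[hybrid])
        return float(self.kw_mean)


@dataclass
class SimOutput:
    """Tables produced by one simulation run.

    ``truth`` carries the generating coefficients and per-cohort latent
    mean growth rates for recovery testing only; analysis stages never
    read it.  ``calibration`` holds destructive border-plant samples for
    the allometric regressions.
    """

    plants: pd.DataFrame
    plots: pd.DataFrame
    daily_temperature: pd.Series
    truth: dict
    calibration: pd.DataFrame

    def write(self, outdir: str | Path, header: str | None = None) -> None:
        """Write plants.csv, plots.csv, calibration.csv, temperature.csv
        and truth.json; an optional comment header is prepended to CSVs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in (("plants", self.plants), ("plots", self.plots),
                         ("calibration", self.calibration)):
            path = outdir / f"{name}.csv"
            with open(path, "w") as fh:
                if header:
                    fh.write(f"# {header}\n")
                df.to_csv(fh, index=False)
        temps = self.daily_temperature.rename("tmean_c")
        temps.index.name = "day"
        with open(outdir / "temperature.csv", "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            temps.to_csv(fh)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2)


def default_shading_config(seed: int = 0, **overrides) -> SimConfig:
    """The shading study conditions with an optional field override."""
    return replace(SimConfig(seed=seed), **overrides) if overrides \
        else SimConfig(seed=seed)


def default_density_config(seed: int = 0, **overrides) -> SimConfig:
    """The stand-density study conditions (three sowing-date environments)."""
    cfg = SimConfig(seed=seed, environments=("Env3", "Env4", "Env5"))
    return replace(cfg, **overrides) if overrides else cfg


def _overlap_days(window: tuple[float, float],
                  interval: tuple[float, float]) -> float:
    return max(0.0, min(window[1], interval[1]) - max(window[0], interval[0]))


def _lognormal_factors(rng: np.random.Generator, cv_pct: float,
                       size: int) -> np.ndarray:
    """Mean-1 lognormal multipliers with the given CV (in %)."""
    cv = cv_pct / 100.0
    if cv == 0.0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2),
                         size=size)


def _mult_noise(rng: np.random.Generator, cv_pct: float,
                size: int) -> np.ndarray:
    """Multiplicative Gaussian noise factors max(0, 1 + cv*z)."""
    cv = cv_pct / 100.0
    if cv == 0.0:
        return np.ones(size)
    return np.maximum(0.0, 1.0 + cv * rng.standard_normal(size))


def _daily_temperature(rng: np.random.Generator, n_days: int) -> pd.Series:
    days = np.arange(-n_days // 2, n_days - n_days // 2)
    temps = 24.0 + 2.5 * np.sin(2 * np.pi * days / n_days) \
        + 1.5 * rng.standard_normal(n_days)
    return pd.Series(temps, index=days, name="tmean_c")


def _morphometrics(rng: np.random.Generator, potential: np.ndarray,
                   eb: np.ndarray, obs_cv: float):
    """Height, stem diameter and ear diameter consistent with the
    allometric generating truth, plus preflowering shoot biomass."""
    n = len(potential)
    b_pre = _BASELINE_SHOOT_G + _PREFLOWER_DAYS * potential
    volume = (b_pre - _PRE_INTERCEPT) / _PRE_SLOPE
    height = 180.0 + 10.0 * potential + 5.0 * rng.standard_normal(n)
    height = np.maximum(height, 50.0)
    diam = np.sqrt(4.0 * volume / (math.pi * height))
    ear_d = np.sqrt(eb / _EAR_K)
    m_cv = obs_cv * _MORPH_NOISE_FRACTION
    return (b_pre,
            height * _mult_noise(rng, m_cv, n),
            diam * _mult_noise(rng, m_cv, n),
            ear_d * _mult_noise(rng, m_cv, n))


def _calibration_samples(rng: np.random.Generator, hybrid: str,
                         coefs: GenotypeCoefficients, mean_pgr: float,
                         cfg: SimConfig, n: int = 27) -> pd.DataFrame:
    """Destructive border-plant samples for the calibration regressions."""
    pot = mean_pgr * _lognormal_factors(rng, cfg.pgr_cv, n)
    eb = ear_biomass_forward(pot, coefs) * _mult_noise(rng, cfg.obs_noise_cv, n)
    b_pre, height, diam, ear_d = _morphometrics(rng, pot, eb, cfg.obs_noise_cv)
    b_post = b_pre + cfg.flowering_interval_days * pot
    noise = _mult_noise(rng, cfg.obs_noise_cv, 3 * n).reshape(3, n)
    return pd.DataFrame({
        "hybrid": hybrid,
        "height_cm": height,
        "stem_diam_cm": diam,
        "ear_diam_cm": ear_d,
        "biomass_pre_g": b_pre * noise[0],
        "biomass_post_g": b_post * noise[1],
        "ear_biomass_g": eb * noise[2],
    })


def simulate_shading_experiment(cfg: SimConfig) -> SimOutput:
    """Simulate the RCBD shading trial.

    Raises ``ValueError`` when the configuration is invalid (no control is
    possible only by construction here, so the guard checks windows and
    plant counts).
    """
    if cfg.n_tagged_plants <= 0:
        raise ValueError("n_tagged_plants must be positive")
    rng = np.random.default_rng(cfg.seed)
    temps = _daily_temperature(rng, int(cfg.flowering_interval_days))

    interval = cfg.anthesis_interval
    span = interval[1] - interval[0]
    treatments: list[tuple[str, float]] = [(CONTROL_LABEL, 0.0)]
    for label, window in cfg.windows.items():
        w = cfg.window_weights.get(label, 0.0)
        frac = _overlap_days(window, interval) / span
        treatments.append((label, frac * w))
    if len(treatments) < 2:
        raise ValueError("no shading treatment besides the control")

    env_factor = {e: 1.0 - cfg.env_decline * i
                  for i, e in enumerate(cfg.environments)}
    block_eff = {(e, b): f for e in cfg.environments
                 for b, f in zip(range(1, cfg.n_blocks + 1),
                                 _lognormal_factors(rng, cfg.block_cv,
                                                    cfg.n_blocks))}

    rows: list[pd.DataFrame] = []
    latent: list[dict] = []
    plot_id = 0
    n = cfg.n_tagged_plants
    for env in cfg.environments:
        for hyb, coefs, sens in cfg.genotypes:
            base_pgr = cfg.pgr_mean_per_genotype[hyb] * env_factor[env]
            for blk in range(1, cfg.n_blocks + 1):
                cohort_mean = base_pgr * block_eff[(env, blk)]
                latent.append({"env": env, "hybrid": hyb, "block": blk,
                               "latent_mean_pgr": cohort_mean})
                for label, weight in treatments:
                    allowed = cfg.restricted_windows.get(label)
                    if allowed is not None and env not in allowed:
                        continue
                    potential = cohort_mean * _lognormal_factors(
                        rng, cfg.pgr_cv, n)
                    stress = 1.0 - (1.0 - cfg.shade_transmission) * sens * weight
                    pgr = potential * stress
                    eb = ear_biomass_forward(pgr, coefs) * _mult_noise(
                        rng, cfg.obs_noise_cv, n)
                    knp = kernel_number_forward(eb, coefs) * _mult_noise(
                        rng, cfg.obs_noise_cv, n)
                    b_pre, height, diam, ear_d = _morphometrics(
                        rng, potential, eb, cfg.obs_noise_cv)
                    plot_id += 1
                    rows.append(pd.DataFrame({
                        "plot_id": plot_id, "env": env, "hybrid": hyb,
                        "treatment": label, "block": blk,
                        "density_pl_m2": cfg.stand_density,
                        "plant_id": np.arange(1, n + 1),
                        "height_cm": height, "stem_diam_cm": diam,
                        "ear_diam_cm": ear_d,
                        "biomass_pre_g": b_pre,
                        "biomass_post_g": b_pre
                        + cfg.flowering_interval_days * pgr,
                        "pgr_true": pgr, "eb_g": eb, "knp": knp,
                    }))
    plants = pd.concat(rows, ignore_index=True)
    plants, plots = _finalise_plots(cfg, rng, plants)
    calib = pd.concat(
        [_calibration_samples(rng, hyb, coefs,
                              cfg.pgr_mean_per_genotype[hyb], cfg)
         for hyb, coefs, _ in cfg.genotypes], ignore_index=True)
    truth = {
        "seed": cfg.seed,
        "coefficients": {h: c.to_dict() for h, c, _ in cfg.genotypes},
        "sensitivity": {h: s for h, _, s in cfg.genotypes},
        "latent_mean_pgr": latent,
    }
    return SimOutput(plants=plants, plots=plots, daily_temperature=temps,
                     truth=truth, calibration=calib)


def simulate_density_trial(cfg: SimConfig) -> SimOutput:
    """Simulate the RCBD stand-density trial.

    Mean growth per plant declines with density as
    ``(d / density_ref) ** -(gamma * (2 - tolerance))`` where the crowding
    tolerance is ``1 - shading_sensitivity``; plot yield is
    density x kernel number x kernel weight.
    """
    dens = tuple(float(d) for d in cfg.densities)
    if len(dens) < 2:
        raise ValueError("need at least two density levels")
    if any(b <= a for a, b in zip(dens, dens[1:])):
        raise ValueError("density levels must be strictly increasing")
    rng = np.random.default_rng(cfg.seed)
    temps = _daily_temperature(rng, int(cfg.flowering_interval_days))

    env_factor = {e: 1.0 - cfg.env_decline * i
                  for i, e in enumerate(cfg.environments)}
    block_eff = {(e, b): f for e in cfg.environments
                 for b, f in zip(range(1, cfg.n_blocks + 1),
                                 _lognormal_factors(rng, cfg.block_cv,
                                                    cfg.n_blocks))}

    rows: list[pd.DataFrame] = []
    latent: list[dict] = []
    plot_id = 0
    n = cfg.n_tagged_plants
    gamma = cfg.density_exponent
    for env in cfg.environments:
        for hyb, coefs, sens in cfg.genotypes:
            base_pgr = cfg.pgr_mean_per_genotype[hyb] * env_factor[env]
            tol = 1.0 - sens
            for blk in range(1, cfg.n_blocks + 1):
                cohort_mean = base_pgr * block_eff[(env, blk)]
                for d in dens:
                    crowd = (d / cfg.density_ref) ** (-gamma * (2.0 - tol))
                    pgr = cohort_mean * crowd * _lognormal_factors(
                        rng, cfg.pgr_cv, n)
                    latent.append({"env": env, "hybrid": hyb, "block": blk,
                                   "density": d,
                                   "latent_mean_pgr": cohort_mean * crowd})
                    eb = ear_biomass_forward(pgr, coefs) * _mult_noise(
                        rng, cfg.obs_noise_cv, n)
                    knp = kernel_number_forward(eb, coefs) * _mult_noise(
                        rng, cfg.obs_noise_cv, n)
                    b_pre, height, diam, ear_d = _morphometrics(
                        rng, pgr, eb, cfg.obs_noise_cv)
                    plot_id += 1
                    rows.append(pd.DataFrame({
                        "plot_id": plot_id, "env": env, "hybrid": hyb,
                        "treatment": f"D{d:g}", "block": blk,
                        "density_pl_m2": d,
                        "plant_id": np.arange(1, n + 1),
                        "height_cm": height, "stem_diam_cm": diam,
                        "ear_diam_cm": ear_d,
                        "biomass_pre_g": b_pre,
                        "biomass_post_g": b_pre
                        + cfg.flowering_interval_days * pgr,
                        "pgr_true": pgr, "eb_g": eb, "knp": knp,
                    }))
    plants = pd.concat(rows, ignore_index=True)
    plants, plots = _finalise_plots(cfg, rng, plants)
    calib = pd.concat(
        [_calibration_samples(rng, hyb, coefs,
                              cfg.pgr_mean_per_genotype[hyb], cfg)
         for hyb, coefs, _ in cfg.genotypes], ignore_index=True)
    truth = {
        "seed": cfg.seed,
        "coefficients": {h: c.to_dict() for h, c, _ in cfg.genotypes},
        "sensitivity": {h: s for h, _, s in cfg.genotypes},
        "latent_mean_pgr": latent,
    }
    return SimOutput(plants=plants, plots=plots, daily_temperature=temps,
                     truth=truth, calibration=calib)


def _finalise_plots(cfg: SimConfig, rng: np.random.Generator,
                    plants: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate plants into plot records (yield, KW, barrenness)."""
    keys = ["plot_id", "env", "hybrid", "treatment", "block", "density_pl_m2"]
    agg = plants.groupby(keys, sort=False).agg(
        knp=("knp", "mean"),
        barren_pct=("knp", lambda k: 100.0 * float((k < 10).mean())),
    ).reset_index()
    kw_noise = _mult_noise(rng, cfg.obs_noise_cv * _KW_NOISE_FRACTION,
                           len(agg))
    agg["kw_mg"] = np.array([cfg.kw_for(h) for h in agg["hybrid"]]) * kw_noise
    # plot yield (Mg ha^-1 at standard moisture): density x KNP x KW
    agg["yield_mg_ha"] = (agg["density_pl_m2"] * agg["knp"]
                          * agg["kw_mg"] / 1000.0) / 100.0
    cols = ["plot_id", "env", "hybrid", "treatment", "block",
            "density_pl_m2", "yield_mg_ha", "kw_mg", "knp", "barren_pct"]
    return plants, agg[cols]


def generate_recovery_dataset(coefs: GenotypeCoefficients, n: int,
                              noise_cv: float, rng: np.random.Generator,
                              pgr_range: tuple[float, float] = (0.5, 6.0)):
    """Per-plant (pgr, eb, knp) triples for parameter-recovery studies.

    PGR is uniform on ``pgr_range``; EB is the hyperbolic response with
    multiplicative Gaussian noise of CV ``noise_cv`` (%); KNP is the
    hyperbolic response to the *realised* EB with its own multiplicative
    noise, so each stage's curve holds between observed quantities.
    """
    pgr = rng.uniform(pgr_range[0], pgr_range[1], size=n)
    eb = ear_biomass_forward(pgr, coefs) * _mult_noise(rng, noise_cv, n)
    knp = kernel_number_forward(eb, coefs) * _mult_noise(rng, noise_cv, n)
    return pgr, eb, knp
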