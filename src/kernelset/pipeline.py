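"""End-to-end reproducible runs: simulate -> allometry -> growth -> model
fit -> traits -> ANOVA -> shading/density response correlation.

A run is driven by a :class:`RunConfig` (YAML/JSON-friendly), writes every
stage's table as CSV into one output directory with a header comment
carrying the seed and config hash, and finishes with a JSON manifest
(package and library versions, seed, config hash, file digests).  The
same config and seed give a bit-identical run.  The master seed fans out
to per-stage child seeds through a hash of the stage name, so toggling
one stage never perturbs another stage's random stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allometry import (fit_ear_model, fit_postflowering, fit_preflowering,
                        predict_biomass, stem_volume)
from .growth import cv_pgr, thermal_time
from .inference import fit_rcbd, tukey_hsd
from .model import GenotypeCoefficients, fit_kernelset
from .synthetic import (SimConfig, default_density_config,
                        default_shading_config, simulate_density_trial,
                        simulate_shading_experiment)
from .traits import add_relative_yield, response_summaries

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

STAGES = ("simulate", "allometry", "growth", "fit", "traits", "anova",
          "correlate")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic child seed (< 2^31) for one pipeline stage."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``shading`` and ``density`` override fields of the default study
    conditions (see :class:`~kernelset.synthetic.SimConfig`); ``stages``
    selects which stages run (dependencies are checked, not inferred).
    """

    seed: int = 0
    outdir: str = "runs/demo"
    stages: tuple[str, ...] = STAGES
    shading: dict = field(default_factory=dict)
    density: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def canonical_json(self) -> str:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV, skipping the seed/config header comment."""
    return pd.read_csv(path, comment="#")


def _fit_allometry(calib: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-hybrid calibration regressions; returns a tidy coefficient
    table and the fitted model objects."""
    rows, models = [], {}
    for hyb, grp in calib.groupby("hybrid"):
        vol = stem_volume(grp["height_cm"].to_numpy(),
                          grp["stem_diam_cm"].to_numpy())
        pre = fit_preflowering(np.column_stack(
            [vol, grp["biomass_pre_g"]]))
        post = fit_postflowering(np.column_stack(
            [vol, grp["ear_diam_cm"], grp["biomass_post_g"]]))
        ear = fit_ear_model(np.column_stack(
            [grp["ear_diam_cm"], grp["ear_biomass_g"]]))
        models[hyb] = {"preflowering": pre, "postflowering": post, "ear": ear}
        for m in (pre, post, ear):
            rows.append({"hybrid": hyb, "kind": m.kind,
                         "r_squared": m.r_squared,
                         "n_calibration": m.n_calibration,
                         **{f"b{i}": c for i, c in enumerate(m.coefficients)}})
    return pd.DataFrame(rows), models


def _apply_allometry(plants: pd.DataFrame, models: dict) -> pd.DataFrame:
    plants = plants.copy()
    for col in ("biomass_pre_est_g", "biomass_post_est_g", "eb_est_g"):
        plants[col] = np.nan
    for hyb, mods in models.items():
        mask = plants["hybrid"] == hyb
        vol = stem_volume(plants.loc[mask, "height_cm"].to_numpy(),
                          plants.loc[mask, "stem_diam_cm"].to_numpy())
        ear_d = plants.loc[mask, "ear_diam_cm"].to_numpy()
        plants.loc[mask, "biomass_pre_est_g"] = predict_biomass(
            mods["preflowering"], vol)
        plants.loc[mask, "biomass_post_est_g"] = predict_biomass(
            mods["postflowering"], np.column_stack([vol, ear_d]))
        plants.loc[mask, "eb_est_g"] = predict_biomass(mods["ear"], ear_d)
    return plants


def _fit_stage(plants: pd.DataFrame) -> pd.DataFrame:
    """Kernel-set model fits per genotype x replicate, pooling treatments."""
    rows = []
    for (env, hyb, blk), grp in plants.groupby(["env", "hybrid", "block"]):
        try:
            res = fit_kernelset(grp["pgr_true"], grp["eb_g"], grp["knp"])
        except ValueError as exc:
            logger.warning("fit skipped for %s/%s/block %s: %s",
                           env, hyb, blk, exc)
            continue
        rows.append({"env": env, "hybrid": hyb, "block": blk,
                     "replicate": f"{env}-B{blk}",
                     **res.coefficients.to_dict(),
                     "r_squared_eb": res.r_squared_eb,
                     "r_squared_kn": res.r_squared_kn,
                     "n_points": res.n_points, "converged": res.converged,
                     "residual_ss": res.residual_ss})
    return pd.DataFrame(rows)


def _traits_stage(plants: pd.DataFrame, plots: pd.DataFrame,
                  with_relative: bool) -> pd.DataFrame:
    per_plot = plants.groupby("plot_id").agg(
        eb_mean_g=("eb_g", "mean"),
        biomass_post_mean_g=("biomass_post_g", "mean"),
        pgr_mean=("pgr_true", "mean"),
        cv_pgr_pct=("pgr_true", lambda p: cv_pgr(p)),
    ).reset_index()
    out = plots.merge(per_plot, on="plot_id", how="left")
    out["pef"] = out["eb_mean_g"] / out["biomass_post_mean_g"]
    out["ssef"] = np.where(out["eb_mean_g"] > 0,
                           out["knp"] / out["eb_mean_g"], np.nan)
    if with_relative:
        out = add_relative_yield(out)
    return out


def _anova_stage(traits_tbl: pd.DataFrame, outdir: Path, tag: str,
                 header: str) -> None:
    factors = ["env", "hybrid", "treatment"]
    single_env = traits_tbl["env"].nunique() == 1
    if single_env:
        factors = ["hybrid", "treatment"]
    res = fit_rcbd(traits_tbl, "yield_mg_ha", factors,
                   interactions=[("hybrid", "treatment")],
                   nest_block_in=None if single_env else "env")
    _write_csv(res.terms, outdir / f"anova_yield_{tag}.csv", header)
    mm = []
    for f in factors:
        tab = res.marginal_means[f].rename(columns={f: "level"})
        tab.insert(0, "factor", f)
        mm.append(tab)
    _write_csv(pd.concat(mm, ignore_index=True),
               outdir / f"marginal_means_{tag}.csv", header)
    pairs, hsd = tukey_hsd(res, "treatment")
    pairs.insert(0, "factor", "treatment")
    pairs["hsd"] = hsd
    _write_csv(pairs, outdir / f"tukey_treatment_{tag}.csv", header)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Raises ``ValueError`` if a stage runs without its inputs (stage order
    is simulate -> allometry -> growth -> fit -> traits -> anova ->
    correlate).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(),
                                      logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"seed={config.seed} config={config.config_hash()}"
    stages = set(config.stages)
    needed = [s for s in STAGES if s in stages]
    for s, dep in (("allometry", "simulate"), ("growth", "simulate"),
                   ("fit", "simulate"), ("traits", "simulate"),
                   ("anova", "traits"), ("correlate", "traits")):
        if s in stages and dep not in stages and not (
                outdir / "plants_shading.csv").exists():
            raise ValueError(f"stage {s!r} needs outputs of {dep!r}")

    sims = {}
    if "simulate" in stages:
        sh_cfg = default_shading_config(
            seed=stage_seed(config.seed, "simulate-shading"), **config.shading)
        de_cfg = default_density_config(
            seed=stage_seed(config.seed, "simulate-density"), **config.density)
        sims["shading"] = simulate_shading_experiment(sh_cfg)
        sims["density"] = simulate_density_trial(de_cfg)
        for tag, sim in sims.items():
            _write_csv(sim.plants, outdir / f"plants_{tag}.csv", header)
            _write_csv(sim.plots, outdir / f"plots_{tag}.csv", header)
            _write_csv(sim.calibration, outdir / f"calibration_{tag}.csv",
                       header)
            temps = sim.daily_temperature.rename("tmean_c")
            temps.index.name = "day"
            temps = temps.reset_index()
            _write_csv(temps, outdir / f"temperature_{tag}.csv", header)
            with open(outdir / f"truth_{tag}.json", "w") as fh:
                json.dump(sim.truth, fh, indent=2)

    def load(name: str) -> pd.DataFrame:
        return read_csv(outdir / name)

    models = {}
    if "allometry" in stages:
        for tag in ("shading", "density"):
            calib = load(f"calibration_{tag}.csv")
            table, mods = _fit_allometry(calib)
            models[tag] = mods
            _write_csv(table, outdir / f"allometry_{tag}.csv", header)
            plants = _apply_allometry(load(f"plants_{tag}.csv"), mods)
            _write_csv(plants, outdir / f"plants_{tag}.csv", header)

    if "growth" in stages:
        for tag in ("shading", "density"):
            plants = load(f"plants_{tag}.csv")
            temps = load(f"temperature_{tag}.csv")
            tt = thermal_time(temps["tmean_c"].to_numpy())
            days = len(temps)
            plants["pgr_gpd"] = (plants["biomass_post_g"]
                                 - plants["biomass_pre_g"]) / days
            plants["pgr_mg_cd"] = (plants["biomass_post_g"]
                                   - plants["biomass_pre_g"]) * 1000.0 / tt
            _write_csv(plants, outdir / f"plants_{tag}.csv", header)

    if "fit" in stages:
        coefs = _fit_stage(load("plants_shading.csv"))
        _write_csv(coefs, outdir / "coefficients.csv", header)
        if coefs["hybrid"].nunique() > 1 and len(coefs) > coefs["hybrid"].nunique():
            rows = []
            for c in GenotypeCoefficients.__dataclass_fields__:
                res = fit_rcbd(coefs, c, ["hybrid"], block="replicate",
                               nest_block_in=None)
                t = res.terms
                t.insert(0, "coefficient", c)
                rows.append(t)
            _write_csv(pd.concat(rows, ignore_index=True),
                       outdir / "coefficient_anova.csv", header)

    if "traits" in stages:
        for tag, rel in (("shading", True), ("density", False)):
            tbl = _traits_stage(load(f"plants_{tag}.csv"),
                                load(f"plots_{tag}.csv"), with_relative=rel)
            _write_csv(tbl, outdir / f"traits_{tag}.csv", header)

    if "anova" in stages:
        for tag in ("shading", "density"):
            _anova_stage(load(f"traits_{tag}.csv"), outdir, tag, header)

    if "correlate" in stages:
        summary, corr = response_summaries(load("traits_shading.csv"),
                                           load(f"traits_density.csv"))
        for k, v in corr.items():
            summary[k] = v
        _write_csv(summary, outdir / "response_summary.csv", header)

    import scipy
    import statsmodels
    manifest = {
        "package": "kernelset",
        "version": __version__,
        "libraries": {"numpy": np.__version__, "pandas": pd.__version__,
                      "scipy": scipy.__version__,
                      "statsmodels": statsmodels.__version__},
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": json.loads(config.canonical_json()),
        "files": {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                  for p in sorted(outdir.glob("*.csv"))},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("run complete: %s", outdir)
    return outdir
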