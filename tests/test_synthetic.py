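"""Synthetic trial generator: determinism, closure and stress structure."""

import numpy as np
import pandas as pd
import pytest

from kernelset import (REFERENCE_HYBRIDS, add_relative_yield,
                       default_density_config, default_shading_config,
                       ear_biomass_forward, generate_recovery_dataset,
                       kernel_number_forward, simulate_density_trial,
                       simulate_shading_experiment)


def zero_noise_config(seed=0, sens=0.0, **kw):
    genos = [(h, REFERENCE_HYBRIDS[h], sens) for h in ("H1", "H2", "H3", "H4")]
    return default_shading_config(seed=seed, obs_noise_cv=0.0, pgr_cv=0.0,
                                  genotypes=genos, **kw)


class TestDeterminism:
    def test_shading_repeatable(self, small_shading_sim):
        again = simulate_shading_experiment(default_shading_config(seed=11))
        pd.testing.assert_frame_equal(small_shading_sim.plants, again.plants)
        pd.testing.assert_frame_equal(small_shading_sim.plots, again.plots)

    def test_density_repeatable(self):
        a = simulate_density_trial(default_density_config(seed=3))
        b = simulate_density_trial(default_density_config(seed=3))
        pd.testing.assert_frame_equal(a.plants, b.plants)
        pd.testing.assert_frame_equal(a.plots, b.plots)

    def test_seed_changes_output(self, small_shading_sim):
        other = simulate_shading_experiment(default_shading_config(seed=12))
        assert not small_shading_sim.plants["knp"].equals(other.plants["knp"])


class TestZeroNoiseClosure:
    def test_plants_lie_on_generating_curves(self):
        sim = simulate_shading_experiment(zero_noise_config(sens=0.4))
        for hyb, grp in sim.plants.groupby("hybrid"):
            c = REFERENCE_HYBRIDS[hyb]
            np.testing.assert_allclose(
                grp["eb_g"], ear_biomass_forward(grp["pgr_true"].to_numpy(), c),
                rtol=1e-12)
            np.testing.assert_allclose(
                grp["knp"], kernel_number_forward(grp["eb_g"].to_numpy(), c),
                rtol=1e-12)

    def test_no_stress_no_noise_relative_yield_is_100(self):
        sim = simulate_shading_experiment(zero_noise_config())
        ry = add_relative_yield(sim.plots)["relative_yield_pct"]
        assert (ry == 100.0).all()


class TestShadingStructure:
    def test_truth_carried_for_recovery_only(self, small_shading_sim):
        truth = small_shading_sim.truth
        assert set(truth["coefficients"]) == {"H1", "H2", "H3", "H4"}
        assert "latent_mean_pgr" in truth

    def test_s14_restricted_to_first_environment(self, small_shading_sim):
        plots = small_shading_sim.plots
        envs = plots.loc[plots["treatment"] == "S-14", "env"].unique()
        assert list(envs) == ["Env1"]

    def test_every_plant_belongs_to_one_plot(self, small_shading_sim):
        plants, plots = small_shading_sim.plants, small_shading_sim.plots
        assert set(plants["plot_id"]) == set(plots["plot_id"])
        key = plants.groupby("plot_id")[["env", "hybrid", "treatment",
                                         "block"]].nunique()
        assert (key == 1).all().all()

    def test_stress_monotone_in_shading_intensity(self):
        """More PAR removed (lower transmission) never raises EB or KNP."""
        heavy = simulate_shading_experiment(
            zero_noise_config(seed=5, sens=0.6, shade_transmission=0.1))
        light = simulate_shading_experiment(
            zero_noise_config(seed=5, sens=0.6, shade_transmission=0.6))
        for col in ("eb_g", "knp"):
            h = heavy.plants.groupby("treatment")[col].mean()
            l = light.plants.groupby("treatment")[col].mean()
            assert (h <= l + 1e-9).all()

    def test_s0_most_damaging_window(self):
        sim = simulate_shading_experiment(zero_noise_config(sens=0.8))
        knp = sim.plants.groupby("treatment")["knp"].mean()
        shaded = knp.drop("T0")
        assert shaded.idxmin() == "S0"

    def test_susceptible_hybrids_fall_most_at_s0(self):
        """Across 10 seeds, the high-sensitivity genotypes (H2, H3) lose
        more relative yield under the anthesis-ending window than the
        tolerant ones (H1, H4)."""
        ry_means = []
        for seed in range(10):
            sim = simulate_shading_experiment(default_shading_config(seed=seed))
            ry = add_relative_yield(sim.plots)
            m = ry[ry["treatment"] == "S0"].groupby("hybrid")[
                "relative_yield_pct"].mean()
            ry_means.append(m)
        m = pd.concat(ry_means, axis=1).mean(axis=1)
        assert m[["H2", "H3"]].mean() < m[["H1", "H4"]].mean()

    def test_barrenness_emerges_below_base_pgr(self):
        cfg = default_shading_config(
            seed=2, pgr_mean_per_genotype={h: 0.3 for h in
                                           ("H1", "H2", "H3", "H4")})
        sim = simulate_shading_experiment(cfg)
        assert sim.plots["barren_pct"].mean() > 95.0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            default_shading_config(n_blocks=1)
        with pytest.raises(ValueError):
            default_shading_config(shade_transmission=1.4)
        with pytest.raises(ValueError):
            default_shading_config(n_tagged_plants=0)
        with pytest.raises(ValueError):
            default_shading_config(genotypes=[
                ("H1", REFERENCE_HYBRIDS["H1"], 1.7)])


class TestDensityTrial:
    def test_yield_proportional_to_density_without_competition(self):
        cfg = default_density_config(seed=4, density_exponent=0.0,
                                     obs_noise_cv=0.0, pgr_cv=0.0,
                                     block_cv=0.0)
        sim = simulate_density_trial(cfg)
        per_plant = sim.plots["yield_mg_ha"] / sim.plots["density_pl_m2"]
        for _, grp in sim.plots.assign(pp=per_plant).groupby(["env", "hybrid"]):
            np.testing.assert_allclose(grp["pp"], grp["pp"].iloc[0], rtol=1e-9)

    def test_mean_pgr_declines_with_density(self):
        sim = simulate_density_trial(default_density_config(seed=8))
        m = sim.plants.groupby("density_pl_m2")["pgr_true"].mean()
        assert m.loc[11.0] < m.loc[5.0]
        assert m.is_monotonic_decreasing

    def test_tolerant_genotype_has_higher_optimum_density(self):
        """Two genotypes identical except for sensitivity: the tolerant one
        peaks at an equal or higher density (mean yields over 10 seeds)."""
        genos = [("tol", REFERENCE_HYBRIDS["H4"], 0.1),
                 ("sus", REFERENCE_HYBRIDS["H4"], 0.8)]
        pgr = {"tol": 3.48, "sus": 3.48}
        kw = {"tol": 330.0, "sus": 330.0}
        acc = []
        for seed in range(10):
            cfg = default_density_config(seed=seed, genotypes=genos,
                                         pgr_mean_per_genotype=pgr,
                                         kw_mean=kw)
            sim = simulate_density_trial(cfg)
            acc.append(sim.plots.groupby(["hybrid", "density_pl_m2"])
                       ["yield_mg_ha"].mean())
        mean = pd.concat(acc, axis=1).mean(axis=1)
        opt = mean.groupby("hybrid").idxmax().map(lambda t: t[1])
        assert opt["tol"] >= opt["sus"]

    def test_density_level_validation(self):
        with pytest.raises(ValueError):
            simulate_density_trial(default_density_config(densities=(7.0,)))
        with pytest.raises(ValueError):
            simulate_density_trial(
                default_density_config(densities=(7.0, 5.0, 9.0)))


class TestRecoveryDataset:
    def test_shapes_and_zero_noise_exactness(self, rng):
        c = REFERENCE_HYBRIDS["H2"]
        pgr, eb, knp = generate_recovery_dataset(c, 50, 0.0, rng)
        assert len(pgr) == len(eb) == len(knp) == 50
        np.testing.assert_allclose(eb, ear_biomass_forward(pgr, c))
        np.testing.assert_allclose(knp, kernel_number_forward(eb, c))
        assert (knp[eb <= c.eb_b] == 0).all()
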