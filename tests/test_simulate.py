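"""Synthetic-data generator: structure, determinism, noise model."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thermogrowth import StrainParams, default_config, simulate_dataset, standardize_rates
from thermogrowth.model import growth_rate, log_growth_rate
from thermogrowth.simulate import GroupSpec, biokinetic_grid, draw_strain


class TestDrawStrain:
    spec = GroupSpec(name="mesophile", dH_act_mean=75300.0, dCp_mean=59.9,
                     n_mean=422.0)

    def test_zero_sd_returns_the_means(self):
        spec = GroupSpec(name="m", dH_act_mean=75300.0, dCp_mean=59.9,
                         n_mean=422.0, dH_act_sd=0.0, dCp_sd=0.0, n_sd=0.0)
        s = draw_strain(spec, np.random.default_rng(0))
        assert (s.dH_act, s.dCp, s.n) == (75300.0, 59.9, 422.0)

    def test_sample_means_match_generating_means(self):
        """10,000 draws recover the generating means within 3 standard
        errors (Monte-Carlo check of the truncated-Gaussian sampler)."""
        rng = np.random.default_rng(123)
        draws = [draw_strain(self.spec, rng) for _ in range(10_000)]
        for attr, mean, sd in (("dH_act", 75300.0, self.spec.dH_act_sd),
                               ("dCp", 59.9, self.spec.dCp_sd),
                               ("n", 422.0, self.spec.n_sd)):
            xs = np.array([getattr(d, attr) for d in draws])
            assert abs(xs.mean() - mean) < 3 * sd / np.sqrt(len(xs))

    def test_all_draws_strictly_positive(self):
        spec = GroupSpec(name="x", dH_act_mean=500.0, dCp_mean=25.0,
                         n_mean=60.0, dH_act_sd=2000.0, dCp_sd=30.0, n_sd=80.0)
        rng = np.random.default_rng(5)
        for _ in range(500):
            s = draw_strain(spec, rng)
            assert s.dH_act > 0 and s.dCp > 0 and s.n > 0


class TestBiokineticGrid:
    def test_grid_shape_and_coverage(self, u_ref, meso):
        grid = biokinetic_grid(meso, u_ref, 14)
        assert len(grid) == 14
        assert np.all(np.diff(grid) > 0)
        assert grid[0] >= 271.0 and grid[-1] <= 396.0
        from thermogrowth import optimal_temperature
        t_opt, _ = optimal_temperature(u_ref, meso)
        assert np.min(np.abs(grid - t_opt)) < 1.0

    def test_cold_endpoint_is_low_rate(self, u_ref, meso):
        grid = biokinetic_grid(meso, u_ref, 14)
        r = growth_rate(grid, u_ref, meso)
        assert r[0] <= 0.055 * r.max()

    def test_requires_at_least_three_points(self, u_ref, meso):
        with pytest.raises(ValueError):
            biokinetic_grid(meso, u_ref, 2)


class TestSimulateDataset:
    def test_default_config_record_count(self):
        records, truth = simulate_dataset(default_config(seed=0))
        assert len(records) == 14 * 14 == 196
        assert records["strain_id"].nunique() == 14
        assert set(truth["strains"]) == set(records["strain_id"])

    def test_same_seed_identical_output(self):
        a, _ = simulate_dataset(default_config(seed=42))
        b, _ = simulate_dataset(default_config(seed=42))
        sa, sb = io.StringIO(), io.StringIO()
        a.to_csv(sa), b.to_csv(sb)
        assert sa.getvalue() == sb.getvalue()

    def test_different_seed_different_output(self):
        a, _ = simulate_dataset(default_config(seed=1))
        b, _ = simulate_dataset(default_config(seed=2))
        assert not a["rate_obs"].equals(b["rate_obs"])

    def test_record_invariants(self):
        records, _ = simulate_dataset(default_config(seed=3))
        assert (records["rate_obs"] >= 0).all()
        assert records["temperature_K"].between(250.0, 420.0).all()
        per_strain_max = records.groupby("strain_id")["rate_std"].max()
        assert np.allclose(per_strain_max, 1.0)

    def test_zero_noise_reproduces_model_exactly(self, u_ref):
        cfg = default_config(seed=9, noise_sd=0.0, points_per_strain=6,
                             strains_per_group={"psychrophile": 0,
                                                "mesophile": 2,
                                                "ascomycota": 0,
                                                "thermophile": 0,
                                                "hyperthermophile": 0})
        records, truth = simulate_dataset(cfg)
        for sid, grp in records.groupby("strain_id"):
            t = truth["strains"][sid]
            s = StrainParams(c=t["c"], dH_act=t["dH_act"], dCp=t["dCp"],
                             n=t["n"])
            r_model = growth_rate(grp["temperature_K"].to_numpy(), u_ref, s)
            assert np.allclose(np.sqrt(grp["rate_obs"]), np.sqrt(r_model),
                               atol=1e-12)

    def test_sqrt_scale_residuals_are_gaussian(self, u_ref):
        """At noise_sd = 0.05 and ~10,000 records the sqrt-scale residuals
        pass an omnibus normality test."""
        cfg = default_config(seed=21, noise_sd=0.05, points_per_strain=800,
                             strains_per_group={"psychrophile": 0,
                                                "mesophile": 6,
                                                "ascomycota": 0,
                                                "thermophile": 6,
                                                "hyperthermophile": 0})
        records, truth = simulate_dataset(cfg)
        resid = []
        for sid, grp in records.groupby("strain_id"):
            t = truth["strains"][sid]
            s = StrainParams(c=t["c"], dH_act=t["dH_act"], dCp=t["dCp"], n=t["n"])
            mu = np.exp(0.5 * log_growth_rate(grp["temperature_K"].to_numpy(),
                                              u_ref, s))
            r = np.sqrt(grp["rate_obs"].to_numpy()) - mu
            # drop points where flooring at zero could truncate the noise
            resid.append(r[mu > 4 * 0.05])
        resid = np.concatenate(resid)
        assert len(resid) > 5000
        assert stats.normaltest(resid).pvalue > 1e-3
        assert np.std(resid) == pytest.approx(0.05, rel=0.05)


class TestStandardize:
    def test_simple_example(self):
        df = pd.DataFrame({"strain_id": ["a"] * 3,
                           "temperature_K": [280.0, 290.0, 300.0],
                           "rate_obs": [2.0, 4.0, 8.0]})
        out = standardize_rates(df)
        assert list(out["rate_std"]) == [0.25, 0.5, 1.0]

    def test_idempotent(self):
        df = pd.DataFrame({"strain_id": ["a", "a", "b", "b"],
                           "temperature_K": [280.0, 290.0, 280.0, 290.0],
                           "rate_obs": [1.0, 3.0, 0.5, 2.0]})
        once = standardize_rates(df)
        twice = standardize_rates(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_preserves_within_strain_ordering(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"strain_id": ["s"] * 20,
                           "temperature_K": np.arange(20.0) + 280.0,
                           "rate_obs": rng.uniform(0.1, 5.0, 20)})
        out = standardize_rates(df)
        assert (out["rate_obs"].rank() == out["rate_std"].rank()).all()

    def test_all_zero_strain_raises_with_name(self):
        df = pd.DataFrame({"strain_id": ["ok", "ok", "dead", "dead"],
                           "temperature_K": [280.0, 290.0, 280.0, 290.0],
                           "rate_obs": [1.0, 2.0, 0.0, 0.0]})
        with pytest.raises(ValueError, match="dead"):
            standardize_rates(df)
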