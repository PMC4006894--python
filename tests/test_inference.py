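"""Hierarchical inference: likelihood/prior oracles, engine consistency,
determinism, single-strain fits and the two-stage standardisation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gamma as gamma_dist, norm

from thermogrowth import (PriorSpec, StrainParams, UniversalParams,
                          fit_single_strain, log_likelihood, log_prior,
                          run_mcmc, simulate_dataset, default_config)
from thermogrowth.inference import GrowthSampler, two_stage_fit
from thermogrowth.model import log_growth_rate
from thermogrowth.priors import HIER_PARAMS
from thermogrowth.structures import ModelStructure


def _structure_and_params(records, truth):
    labels = (records.drop_duplicates("strain_id")
              .set_index("strain_id")["group"].to_dict())
    structure = ModelStructure.from_labels(labels)
    strain_params = {sid: StrainParams(c=t["c"], dH_act=t["dH_act"],
                                       dCp=t["dCp"], n=t["n"], group=t["group"])
                     for sid, t in truth["strains"].items()}
    return structure, strain_params


class TestLogLikelihood:
    def test_perfect_fit_closed_form(self, u_ref):
        """Zero residuals leave only the Gaussian normalisation:
        N (log(tau)/2 - log(2 pi)/2)."""
        records, truth = simulate_dataset(default_config(
            seed=5, noise_sd=0.0, points_per_strain=6,
            strains_per_group={"psychrophile": 0, "mesophile": 2,
                               "ascomycota": 0, "thermophile": 0,
                               "hyperthermophile": 0}))
        _, sp = _structure_and_params(records, truth)
        tau = 400.0
        ll = log_likelihood(records, u_ref, sp, tau)
        n = len(records)
        assert ll == pytest.approx(
            n * (0.5 * np.log(tau) - 0.5 * np.log(2 * np.pi)), rel=1e-10)

    def test_matches_per_record_loop_oracle(self, u_ref, small_dataset):
        records, truth = small_dataset
        _, sp = _structure_and_params(records, truth)
        tau = 900.0
        ll = log_likelihood(records, u_ref, sp, tau)
        oracle = 0.0
        for _, row in records.iterrows():
            s = sp[row["strain_id"]]
            mu = np.exp(0.5 * log_growth_rate(row["temperature_K"], u_ref, s))
            oracle += norm.logpdf(np.sqrt(row["rate_std"]), mu,
                                  1.0 / np.sqrt(tau))
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_duplicating_records_doubles_loglik(self, u_ref, small_dataset):
        records, truth = small_dataset
        _, sp = _structure_and_params(records, truth)
        ll1 = log_likelihood(records, u_ref, sp, 500.0)
        ll2 = log_likelihood(pd.concat([records, records]), u_ref, sp, 500.0)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)


class TestLogPrior:
    prior = PriorSpec()

    def _setup(self, small_dataset):
        records, truth = small_dataset
        structure, sp = _structure_and_params(records, truth)
        group_means = {g: dict(truth["group_means"][g]) for g in structure.groups}
        tau_theta = {"dH_act": 1e-6, "dCp": 1.0, "n": 1e-3}
        return structure, sp, group_means, tau_theta

    def test_out_of_bounds_universal_is_minus_inf(self, small_dataset):
        structure, sp, gm, tt = self._setup(small_dataset)
        bad = UniversalParams(5900.0, 17.0, 375.5, 390.9)  # above dH* box
        assert log_prior(bad, gm, sp, tt, 100.0, self.prior, structure) == -np.inf

    def test_strain_at_group_mean_maximises_its_term(self, u_ref, small_dataset):
        structure, sp, gm, tt = self._setup(small_dataset)
        sid = next(iter(sp))
        g = structure.assignment[sid]
        at_mean = dict(sp)
        at_mean[sid] = StrainParams(c=sp[sid].c, dH_act=gm[g]["dH_act"],
                                    dCp=gm[g]["dCp"], n=gm[g]["n"])
        off = dict(sp)
        off[sid] = StrainParams(c=sp[sid].c, dH_act=gm[g]["dH_act"] + 3000.0,
                                dCp=gm[g]["dCp"], n=gm[g]["n"])
        lp_mean = log_prior(u_ref, gm, at_mean, tt, 100.0, self.prior, structure)
        lp_off = log_prior(u_ref, gm, off, tt, 100.0, self.prior, structure)
        assert lp_mean > lp_off

    def test_matches_independent_term_by_term_oracle(self, u_ref, small_dataset):
        structure, sp, gm, tt = self._setup(small_dataset)
        tau_obs = 321.0
        lp = log_prior(u_ref, gm, sp, tt, tau_obs, self.prior, structure)

        oracle = 0.0
        for name, x in zip(("dH_star", "dS_star", "T_H", "T_S"),
                           u_ref.as_array()):
            lo, hi = self.prior.universal_bounds[name]
            oracle += -np.log(hi - lo)
        for g in structure.groups:
            for p in HIER_PARAMS:
                lo, hi = self.prior.group_bounds[p]
                oracle += -np.log(hi - lo)
        for p in HIER_PARAMS:
            lo, hi = self.prior.tau_theta_bounds[p]
            oracle += -np.log(hi - lo)
        lo, hi = self.prior.log_c_bounds
        for sid, s in sp.items():
            oracle += -np.log(hi - lo)
            g = structure.assignment[sid]
            for p in HIER_PARAMS:
                oracle += norm.logpdf(getattr(s, p), gm[g][p],
                                      1.0 / np.sqrt(tt[p]))
        a, b = self.prior.gamma_obs
        oracle += gamma_dist.logpdf(tau_obs, a, scale=1.0 / b)
        assert lp == pytest.approx(oracle, abs=1e-10)


class TestEngineConsistency:
    def test_engine_density_matches_functional_oracles(self, small_dataset):
        """The engine's cached log-likelihood and prior at its own state
        agree with the standalone implementations (dual-route check)."""
        records, truth = small_dataset
        structure, _ = _structure_and_params(records, truth)
        eng = GrowthSampler(records, structure, seed=4)
        for _ in range(30):
            eng.sweep()
        u = UniversalParams.from_array(eng.u)
        sp = {sid: StrainParams(c=float(np.exp(eng.P[i, 0])),
                                dH_act=eng.P[i, 1], dCp=eng.P[i, 2],
                                n=eng.P[i, 3])
              for i, sid in enumerate(eng.strain_ids)}
        ll = log_likelihood(records, u, sp, eng.tau_obs)
        assert eng.loglik() == pytest.approx(ll, abs=1e-8)

        gm = {g: {p: eng.M[j, k] for k, p in enumerate(HIER_PARAMS)}
              for j, g in enumerate(eng.groups)}
        tt = {p: float(np.exp(eng.log_tau[k]))
              for k, p in enumerate(HIER_PARAMS)}
        lp = log_prior(u, gm, sp, tt, eng.tau_obs, eng.prior, structure)
        # the engine works in log coordinates for the precisions: its state
        # density adds the Jacobians log(tau) for each precision
        jac = float(np.sum(eng.log_tau)) + np.log(eng.tau_obs)
        assert eng._log_prior_state() == pytest.approx(lp + jac, abs=1e-8)

    def test_flat_state_roundtrip(self, small_dataset):
        records, truth = small_dataset
        structure, _ = _structure_and_params(records, truth)
        eng = GrowthSampler(records, structure, seed=4)
        v = eng.state()
        lt = eng.log_target()
        eng.set_state(v + 0.0)
        assert eng.log_target() == pytest.approx(lt, rel=1e-12)
        assert eng.log_target(v) == pytest.approx(lt, rel=1e-12)


class TestRunMCMC:
    def test_same_seed_identical_chains(self, small_dataset):
        records, truth = small_dataset
        structure, _ = _structure_and_params(records, truth)
        a = run_mcmc(records, structure, iterations=120, seed=8)
        b = run_mcmc(records, structure, iterations=120, seed=8)
        for name in a.chains:
            assert np.array_equal(a.chains[name], b.chains[name])

    def test_record_order_does_not_matter(self, small_dataset):
        """Shuffling the rows of the input table changes nothing: strains
        use their own seeded streams keyed by label."""
        records, truth = small_dataset
        structure, _ = _structure_and_params(records, truth)
        shuffled = records.sample(frac=1.0, random_state=99)
        a = run_mcmc(records, structure, iterations=80, seed=8)
        b = run_mcmc(shuffled, structure, iterations=80, seed=8)
        for name in a.chains:
            assert np.array_equal(a.chains[name], b.chains[name])

    def test_prior_only_run_reproduces_uniform_moments(self, small_dataset):
        """With the likelihood switched off the universal parameters sample
        their uniform boxes: means near midpoints, SDs near width/sqrt(12)."""
        records, truth = small_dataset
        structure, _ = _structure_and_params(records, truth)
        prior = PriorSpec()
        res = run_mcmc(records, structure, prior, iterations=4000, seed=13,
                       beta=0.0)
        for name in ("dH_star", "dS_star", "T_H", "T_S"):
            lo, hi = prior.universal_bounds[name]
            mid, width = (lo + hi) / 2, hi - lo
            tol = 0.15 if name not in ("T_H", "T_S") else 0.25
            assert abs(res.posterior_mean(name) - mid) < tol * width
            assert res.posterior_sd(name) == pytest.approx(
                width / np.sqrt(12), rel=0.5)

    def test_summaries_use_only_retained_samples(self, small_dataset):
        records, truth = small_dataset
        structure, _ = _structure_and_params(records, truth)
        res = run_mcmc(records, structure, iterations=200, seed=8, burn_in=0.5)
        name = "dH_star"
        assert res.posterior_mean(name) == pytest.approx(
            float(np.mean(res.chains[name][100:])), rel=1e-12)
        lo, hi = res.hpdi(name)
        assert lo <= res.posterior_mean(name) <= hi


class TestSingleStrainFit:
    def _strain_records(self, noise=0.0, seed=31, k=14):
        cfg = default_config(seed=seed, noise_sd=noise, points_per_strain=k,
                             strains_per_group={"psychrophile": 0,
                                                "mesophile": 1,
                                                "ascomycota": 0,
                                                "thermophile": 0,
                                                "hyperthermophile": 0})
        records, truth = simulate_dataset(cfg)
        sid = records["strain_id"].iloc[0]
        return records, truth["strains"][sid]

    def test_zero_noise_recovery_with_classical_fixing_scheme(self):
        """Freezing dS*, T_H and T_S (as in single-curve fits) recovers the
        generating enzyme parameters of a noiseless strain to 1%."""
        records, t = self._strain_records(noise=0.0)
        fit = fit_single_strain(records)
        assert fit.params["dH_act"] == pytest.approx(t["dH_act"], rel=0.01)
        assert fit.params["dCp"] == pytest.approx(t["dCp"], rel=0.01)
        assert fit.params["n"] == pytest.approx(t["n"], rel=0.01)

    def test_only_c_free_matches_linear_least_squares(self, u_ref):
        """With every parameter but c frozen the problem is linear in
        sqrt(c); the optimiser must match the closed form."""
        records, t = self._strain_records(noise=0.02, seed=35)
        fixed = {"dH_act": t["dH_act"], "dCp": t["dCp"], "n": t["n"],
                 "dH_star": 4874.0, "dS_star": 17.0, "T_H": 375.5,
                 "T_S": 390.9}
        fit = fit_single_strain(records, fixed=fixed)
        s1 = StrainParams(c=1.0, dH_act=t["dH_act"], dCp=t["dCp"], n=t["n"])
        T = records["temperature_K"].to_numpy()
        y = np.sqrt(records["rate_std"].to_numpy())
        r1 = np.exp(0.5 * log_growth_rate(T, u_ref, s1))
        c_closed = float((y @ r1) / (r1 @ r1)) ** 2
        assert fit.params["c"] == pytest.approx(c_closed, rel=1e-6)

    def test_estimates_equivariant_to_rate_units(self):
        """Multiplying all rates by a constant only rescales c."""
        records, _ = self._strain_records(noise=0.01, seed=37)
        scaled = records.copy()
        scaled["rate_std"] = scaled["rate_std"] * 250.0
        a = fit_single_strain(records)
        b = fit_single_strain(scaled)
        for p in ("dH_act", "dCp", "n", "dH_star"):
            assert b.params[p] == pytest.approx(a.params[p], rel=1e-4)
        assert b.params["c"] == pytest.approx(250.0 * a.params["c"], rel=1e-3)

    def test_too_few_records_rejected(self):
        records, _ = self._strain_records(k=4)
        with pytest.raises(ValueError):
            fit_single_strain(records.head(4))


class TestTwoStage:
    def test_stage_two_fitted_maxima_near_one(self):
        """On near-noiseless data the second-stage rescaling is a no-op:
        the fitted maximum rate of every strain stays at one."""
        from thermogrowth.derived import optimal_temperature
        from thermogrowth.model import growth_rate

        cfg = default_config(seed=19, noise_sd=0.0, points_per_strain=10,
                             strains_per_group={"psychrophile": 0,
                                                "mesophile": 2,
                                                "ascomycota": 0,
                                                "thermophile": 2,
                                                "hyperthermophile": 0})
        records, truth = simulate_dataset(cfg)
        structure, _ = _structure_and_params(records, truth)
        res = two_stage_fit(records, structure, iterations=3000, seed=2,
                            rhat_abort=None)
        u = res.universal_params()
        for sid, s in res.strain_params().items():
            t_opt, _ = optimal_temperature(u, s)
            # posterior-mean curves at a short desk-scale run: a few percent
            assert growth_rate(t_opt, u, s) == pytest.approx(1.0, abs=0.05)
        assert hasattr(res, "stage1")
        # rescaled observations keep per-strain maxima near one
        for sid, s1 in res.stage1.strain_params().items():
            t_opt, _ = optimal_temperature(res.stage1.universal_params(), s1)
            assert 0.8 < growth_rate(t_opt, res.stage1.universal_params(), s1) < 1.2
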