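"""Closed-form growth model: free energy, native-state probability, rate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermogrowth import (StrainParams, UniversalParams, growth_rate,
                          native_state_probability, unfolding_free_energy)
from thermogrowth.constants import R
from thermogrowth.model import log_growth_rate

# values frozen from a high-precision symbolic evaluation (sympy/mpmath)
DG_310_MESO = -13.680022788171402
P_NATIVE_AT_TSTAR = 0.868124570989820
T_STAR_MESO = 294.313471494387


def universal(dH_star=4874.0, dS_star=17.0, T_H=375.5, T_S=390.9):
    return UniversalParams(dH_star, dS_star, T_H, T_S)


class TestUnfoldingFreeEnergy:
    def test_collapses_to_line_without_heat_capacity(self, u_ref):
        """dCp = 0 removes all curvature: dG = dH* - T dS*, with a single
        zero at dH*/dS*."""
        T0 = 4874.0 / 17.0
        assert unfolding_free_energy(T0, u_ref, 0.0) == pytest.approx(0.0, abs=1e-9)
        for T in (250.0, 300.0, 380.0):
            assert unfolding_free_energy(T, u_ref, 0.0) == pytest.approx(
                4874.0 - T * 17.0, rel=1e-12)

    def test_value_at_310K(self, u_ref):
        assert unfolding_free_energy(310.0, u_ref, 59.9) == pytest.approx(
            DG_310_MESO, abs=1e-6)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(dCp=st.floats(20.0, 120.0), T=st.floats(255.0, 420.0))
    def test_concave_in_temperature(self, u_ref, dCp, T):
        """Second derivative is -dCp/T < 0 everywhere."""
        h = 0.01
        d2 = (unfolding_free_energy(T + h, u_ref, dCp)
              - 2 * unfolding_free_energy(T, u_ref, dCp)
              + unfolding_free_energy(T - h, u_ref, dCp)) / h**2
        assert d2 == pytest.approx(-dCp / T, rel=5e-3)

    def test_rejects_nonpositive_temperature_and_negative_dCp(self, u_ref):
        with pytest.raises(ValueError):
            unfolding_free_energy(-5.0, u_ref, 59.9)
        with pytest.raises(ValueError):
            unfolding_free_energy(300.0, u_ref, -1.0)


class TestUniversalParamsValidation:
    def test_convergence_temperature_ordering_enforced(self):
        with pytest.raises(ValueError):
            UniversalParams(4874.0, 17.0, 392.0, 390.9)

    def test_positive_fields_enforced(self):
        with pytest.raises(ValueError):
            UniversalParams(-1.0, 17.0, 375.5, 390.9)

    def test_temperature_window(self):
        with pytest.raises(ValueError):
            UniversalParams(4874.0, 17.0, 100.0, 390.9)


class TestNativeStateProbability:
    def test_half_when_free_energy_zero(self, u_ref):
        """Logistic midpoint: dG = 0 gives exactly P = 0.5, regardless of n."""
        T0 = 4874.0 / 17.0  # zero of the dCp = 0 line
        # dCp -> 0 limit not allowed here (dCp > 0 in the two-state model),
        # so use a root of the curved dG instead
        from thermogrowth import half_denaturation_bounds
        t_l, t_u = half_denaturation_bounds(u_ref, 59.9)
        for T in (t_l, t_u):
            for n in (10.0, 422.0, 5000.0):
                assert native_state_probability(T, u_ref, 59.9, n) == \
                    pytest.approx(0.5, abs=1e-7)

    def test_value_at_stability_temperature(self, u_ref):
        assert native_state_probability(T_STAR_MESO, u_ref, 59.9, 422.0) == \
            pytest.approx(P_NATIVE_AT_TSTAR, abs=1e-9)

    def test_saturates_without_overflow(self, u_ref):
        P_cold = native_state_probability(255.0, u_ref, 59.9, 1e7)
        P_mid = native_state_probability(T_STAR_MESO, u_ref, 59.9, 1e7)
        assert P_cold == 0.0 and P_mid == 1.0
        assert not np.isnan([P_cold, P_mid]).any()

    def test_limit_of_vanishing_protein_size(self, u_ref):
        T = np.linspace(260.0, 400.0, 20)
        assert np.allclose(native_state_probability(T, u_ref, 59.9, 0.0), 0.5)


class TestGrowthRate:
    def test_degenerate_arrhenius_limit(self, u_ref):
        """With no activation enthalpy and no protein, r = c T / 2."""
        s = StrainParams(c=2.5, dH_act=0.0, dCp=59.9, n=0.0)
        T = np.array([270.0, 300.0, 350.0])
        assert np.allclose(growth_rate(T, u_ref, s), 2.5 * T / 2.0, rtol=1e-12)

    def test_invariant_under_unit_rescaling(self, u_ref, meso):
        """Rescaling the rate units and c together changes nothing."""
        T = np.linspace(275.0, 310.0, 50)
        r1 = growth_rate(T, u_ref, meso)
        r2 = growth_rate(T, u_ref, meso.with_c(meso.c * 3600.0)) / 3600.0
        assert np.allclose(r1, r2, rtol=1e-12)

    def test_matches_extended_precision_oracle(self, u_ref, meso):
        """Vectorised evaluation equals a term-by-term mpmath computation
        to relative tolerance 1e-10 on a 1000-point grid."""
        import mpmath as mp

        grid = np.linspace(272.0, 320.0, 1000)
        ours = growth_rate(grid, u_ref, meso)
        mp.mp.dps = 40
        for T, r in zip(grid[::97], ours[::97]):
            t = mp.mpf(float(T))
            dG = (mp.mpf(4874) + mp.mpf('59.9') * (t - mp.mpf('375.5'))
                  - t * (mp.mpf(17) + mp.mpf('59.9') * mp.log(t / mp.mpf('390.9'))))
            rate = (mp.mpf(meso.c) * t * mp.exp(-mp.mpf(75300) / (mp.mpf('8.314') * t))
                    / (1 + mp.exp(-mp.mpf(422) * dG / (mp.mpf('8.314') * t))))
            assert abs(float(rate) - r) <= 1e-10 * abs(float(rate))

    def test_positive_and_finite_everywhere(self, u_ref, meso):
        T = np.linspace(201.0, 449.0, 500)
        r = growth_rate(T, u_ref, meso)
        assert np.all(np.isfinite(r)) and np.all(r >= 0.0)

    def test_increasing_activation_enthalpy_slows_rate(self, u_ref, meso):
        import dataclasses
        faster = growth_rate(300.0, u_ref, meso)
        slower = growth_rate(
            300.0, u_ref, dataclasses.replace(meso, dH_act=meso.dH_act + 5e3))
        assert slower < faster

    def test_log_rate_consistent_with_rate(self, u_ref, meso):
        T = np.linspace(275.0, 310.0, 20)
        assert np.allclose(np.exp(log_growth_rate(T, u_ref, meso)),
                           growth_rate(T, u_ref, meso), rtol=1e-12)


class TestStrainParamsValidation:
    def test_rejects_nonpositive_scaling_and_heat_capacity(self):
        with pytest.raises(ValueError):
            StrainParams(c=0.0, dH_act=1.0, dCp=1.0, n=1.0)
        with pytest.raises(ValueError):
            StrainParams(c=1.0, dH_act=1.0, dCp=0.0, n=1.0)

    def test_rejects_negative_but_allows_zero_limits(self):
        StrainParams(c=1.0, dH_act=0.0, dCp=1.0, n=0.0)
        with pytest.raises(ValueError):
            StrainParams(c=1.0, dH_act=-1.0, dCp=1.0, n=1.0)
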