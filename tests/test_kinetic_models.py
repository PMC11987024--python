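"""Closed-form kinetics against the brute-force moment-ODE oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from amykit.kinetic_models import (
    ConfigurationError,
    KineticCurve,
    KineticParameters,
    MacroscopicRates,
    half_time,
    macroscopic_rates,
    moment_ode_oracle,
    normalized_rates,
    oosawa_curve,
    params_from_macroscopic,
    rg_curve,
    theta_from_order,
)


def make_params(**kw):
    base = dict(m0=10.0, nc=2.0, kn=1e-4, kplus=0.1,
                mechanism="secondary_single", k2=1e-3, n2=2.0)
    base.update(kw)
    return KineticParameters(**base)


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(mechanism="fragmentation", kf=None),
            dict(mechanism="secondary_single", k2=None),
            dict(mechanism="secondary_single", n2=None),
            dict(mechanism="secondary_multistep", K2=None),
        ],
    )
    def test_missing_mechanism_constant_names_field(self, kw):
        with pytest.raises(ConfigurationError):
            make_params(**kw)

    def test_invalid_scalars_rejected(self):
        with pytest.raises(ConfigurationError):
            make_params(m0=0.0)
        with pytest.raises(ConfigurationError):
            make_params(nc=0.5)
        with pytest.raises(ConfigurationError):
            make_params(kn=-1.0)


class TestNormalizedRates:
    def test_zero_nucleation_constant_gives_zero_rate(self):
        nu = normalized_rates(make_params(kn=0.0, nc=3.0, m0=50.0))
        assert nu.nu_n == 0.0

    def test_multistep_converges_to_single_step_at_large_K2(self):
        single = normalized_rates(make_params())
        multi = normalized_rates(
            make_params(mechanism="secondary_multistep", K2=1e9)
        )
        assert multi.nu_2 == pytest.approx(single.nu_2, rel=1e-7)

    def test_single_step_nu2_scales_with_m0_power(self):
        # doubling m0**n2 doubles nu_2: with n2=2, m0 -> m0*sqrt(2)
        lo = normalized_rates(make_params(m0=10.0))
        hi = normalized_rates(make_params(m0=10.0 * np.sqrt(2.0)))
        assert hi.nu_2 == pytest.approx(2.0 * lo.nu_2, rel=1e-12)


class TestMacroscopicRates:
    def test_zero_rate_constants_give_zero_macroscopic_rates(self):
        assert macroscopic_rates(make_params(kn=0.0)).lam == 0.0
        frag = make_params(mechanism="fragmentation", kf=0.0)
        assert macroscopic_rates(frag).kappa == 0.0
        assert macroscopic_rates(make_params(mechanism="oosawa")).kappa == 0.0

    def test_square_root_dependence_on_kn_and_k2(self):
        base = macroscopic_rates(make_params())
        lam4 = macroscopic_rates(make_params(kn=4e-4))
        kap4 = macroscopic_rates(make_params(k2=4e-3))
        assert lam4.lam == pytest.approx(2.0 * base.lam, rel=1e-12)
        assert kap4.kappa == pytest.approx(2.0 * base.kappa, rel=1e-12)

    def test_macroscopic_roundtrip_through_params(self):
        rates = MacroscopicRates(lam=0.05, kappa=0.8, theta=0.4)
        p = params_from_macroscopic(rates, m0=10.0, n2=2.0)
        back = macroscopic_rates(p)
        assert back.lam == pytest.approx(rates.lam, rel=1e-12)
        assert back.kappa == pytest.approx(rates.kappa, rel=1e-12)


class TestOosawaCurve:
    def test_boundary_and_degenerate_cases(self, hour_grid):
        rates = MacroscopicRates(lam=0.5, kappa=0.0)
        curve = oosawa_curve(rates, 2.0, hour_grid)
        assert curve.fraction_fibrillar[0] == 0.0
        zero = oosawa_curve(MacroscopicRates(0.0, 0.0), 2.0, hour_grid)
        assert np.all(zero.fraction_fibrillar == 0.0)
        with pytest.raises(ValueError):
            oosawa_curve(rates, 2.0, np.array([-1.0, 0.0]))

    @pytest.mark.parametrize("nc", [1.5, 2.0, 3.0])
    @pytest.mark.parametrize("lam_tmax", [1.0, 4.0, 10.0])
    def test_matches_moment_ode_within_one_percent(self, nc, lam_tmax):
        lam = 0.5
        t = np.linspace(0.0, lam_tmax / lam, 120)
        rates = MacroscopicRates(lam=lam, kappa=0.0)
        p = params_from_macroscopic(rates, m0=10.0, nc=nc, mechanism="oosawa")
        closed = oosawa_curve(rates, nc, t).fraction_fibrillar
        oracle = moment_ode_oracle(p, t).fraction_fibrillar
        assert np.max(np.abs(closed - oracle)) < 0.01

    def test_nondecreasing_and_bounded(self, hour_grid):
        curve = oosawa_curve(MacroscopicRates(0.3, 0.0), 2.0, hour_grid)
        y = curve.fraction_fibrillar
        assert np.all(np.diff(y) >= 0)
        assert y[0] == 0.0 and y[-1] <= 1.0


class TestRgCurve:
    def test_boundary_cases(self, hour_grid, default_rates):
        curve = rg_curve(default_rates, hour_grid)
        assert curve.fraction_fibrillar[0] == 0.0
        zero = rg_curve(MacroscopicRates(0.0, 0.0, 0.3), hour_grid)
        assert np.all(zero.fraction_fibrillar == 0.0)

    def test_numerically_stable_at_extreme_kappa_t(self):
        t = np.array([0.0, 1e3, 1e6])
        y = rg_curve(MacroscopicRates(1e-3, 50.0, 0.323), t).fraction_fibrillar
        assert np.all(np.isfinite(y))
        assert y[-1] == pytest.approx(1.0)

    def test_half_time_matches_oracle_at_study_theta(self):
        # theta = 0.323 corresponds to secondary order n2 with
        # theta = sqrt(2/(n2(n2+1)))
        theta = 0.323
        n2 = (-1.0 + np.sqrt(1.0 + 8.0 / theta ** 2)) / 2.0
        rates = MacroscopicRates(lam=0.02, kappa=1.0, theta=theta)
        t = np.linspace(0.0, 24.0, 2000)
        p = params_from_macroscopic(rates, m0=10.0, nc=2.0, n2=n2)
        t50_closed = half_time(rg_curve(rates, t))
        t50_oracle = half_time(moment_ode_oracle(p, t))
        assert abs(t50_closed - t50_oracle) / t50_oracle < 0.05

    @pytest.mark.parametrize("ratio", [5.0, 20.0, 100.0, 500.0])
    def test_half_time_matches_oracle_secondary_dominated(self, ratio):
        n2 = 2.0
        theta = theta_from_order(n2)
        kap = 1.0
        rates = MacroscopicRates(lam=kap / ratio, kappa=kap, theta=theta)
        t_max = (np.log(2.0 * ratio ** 2) + 10.0) / kap
        t = np.linspace(0.0, t_max, 2000)
        p = params_from_macroscopic(rates, m0=10.0, n2=n2)
        t50_closed = half_time(rg_curve(rates, t))
        t50_oracle = half_time(moment_ode_oracle(p, t))
        assert abs(t50_closed - t50_oracle) / t50_oracle < 0.05

    def test_nondecreasing_bounded(self, hour_grid, default_rates):
        y = rg_curve(default_rates, hour_grid).fraction_fibrillar
        assert np.all(np.diff(y) >= 0)
        assert np.all((0.0 <= y) & (y <= 1.0))


class TestMomentOdeOracle:
    def test_no_nucleation_no_seeds_stays_zero(self, hour_grid):
        p = make_params(kn=0.0, k2=0.0)
        y = moment_ode_oracle(p, hour_grid).fraction_fibrillar
        assert np.max(np.abs(y)) < 1e-12

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        lam=st.floats(0.01, 0.5),
        ratio=st.floats(1.0, 100.0),
        n2=st.floats(1.0, 3.0),
        nc=st.floats(1.0, 3.0),
    )
    def test_mass_conservation(self, lam, ratio, n2, nc):
        rates = MacroscopicRates(lam=lam, kappa=lam * ratio, theta=0.4)
        p = params_from_macroscopic(rates, m0=10.0, nc=nc, n2=n2)
        t = np.linspace(0.0, 30.0, 60)
        _, violation = moment_ode_oracle(p, t, return_conservation=True)
        assert violation < 1e-6 * p.m0

    def test_sigmoidal_with_unit_plateau_when_secondary_dominates(self):
        rates = MacroscopicRates(lam=0.02, kappa=1.0, theta=theta_from_order(2.0))
        p = params_from_macroscopic(rates, m0=10.0, n2=2.0)
        t = np.linspace(0.0, 45.0, 450)
        y = moment_ode_oracle(p, t, rtol=1e-10).fraction_fibrillar
        assert y[-1] == pytest.approx(1.0, abs=1e-6)
        # sigmoid: maximal slope strictly inside the window
        i = np.argmax(np.diff(y))
        assert 0 < i < y.size - 2


class TestHalfTime:
    def test_exact_grid_crossing(self):
        curve = KineticCurve(np.array([0.0, 1.0, 2.0]), np.array([0.0, 0.5, 1.0]))
        assert half_time(curve) == pytest.approx(1.0)

    def test_amplitude_scale_invariance(self, hour_grid, default_rates):
        y = rg_curve(default_rates, hour_grid).fraction_fibrillar
        t50 = half_time(KineticCurve(hour_grid, y))
        t50_scaled = half_time(KineticCurve(hour_grid, 0.7 * y))
        assert t50_scaled == pytest.approx(t50, rel=1e-12)

    def test_no_half_time_is_none_not_a_number(self, hour_grid):
        flat = KineticCurve(hour_grid, np.zeros_like(hour_grid))
        assert half_time(flat) is None
        # rises only at the very end: never reaches half the final-window mean
        y = np.zeros_like(hour_grid)
        y[-1] = 1.0
        assert half_time(KineticCurve(hour_grid, y)) is not None  # crosses at end

    def test_matches_bisection_root_of_oosawa_form(self):
        lam, nc = 0.5, 2.0
        t = np.linspace(0.0, 24.0, 2000)
        rates = MacroscopicRates(lam=lam, kappa=0.0)
        t50 = half_time(oosawa_curve(rates, nc, t))

        def f(tt):
            return 1.0 - np.cosh(np.sqrt(nc / 2.0) * lam * tt) ** (-2.0 / nc) - 0.5

        root = brentq(f, 1e-6, 24.0)
        grid_err = t[1] - t[0]
        assert abs(t50 - root) <= grid_err

    def test_half_time_decreases_with_lambda(self):
        t = np.linspace(0.0, 48.0, 2000)
        t50s = []
        for lam in [0.01, 0.02, 0.05, 0.1]:
            rates = MacroscopicRates(lam=lam, kappa=1.0, theta=0.323)
            t50s.append(half_time(rg_curve(rates, t)))
        assert all(a > b for a, b in zip(t50s, t50s[1:]))
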