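"""Taylor dispersion, SPR, NMR CSP, copelleting and composition rules."""

import numpy as np
import pandas as pd
import pytest

from amykit.biophysics import (
    Sensorgram,
    Taylorgram,
    buffer_capacity,
    copelleting_fraction,
    csp,
    extinction_coefficient_280,
    fit_spr_1to1,
    fit_spr_biexponential,
    fit_taylorgram,
    stokes_einstein,
    taylor_peak,
)
from amykit.synthetic_data import (
    gen_spr_series,
    gen_spr_trace,
    gen_taylorgram,
)


class TestTaylorgram:
    def test_noise_free_recovery(self):
        tg, truth = gen_taylorgram(seed=0, noise_sigma=0.0)
        fit = fit_taylorgram(tg)
        assert fit.A == pytest.approx(truth["A"], rel=1e-3)
        assert fit.t_R == pytest.approx(truth["t_R"], rel=1e-3)
        assert fit.D == pytest.approx(truth["D"], rel=1e-3)

    def test_noisy_diffusion_within_two_percent(self):
        tg, truth = gen_taylorgram(seed=4, noise_sigma=0.01)
        fit = fit_taylorgram(tg)
        assert fit.D == pytest.approx(truth["D"], rel=0.02)

    def test_time_shift_moves_peak_center_only(self):
        tg, truth = gen_taylorgram(seed=0, noise_sigma=0.0)
        # same peak, observed 30 s later
        shifted = Taylorgram(tg.times, taylor_peak(tg.times, truth["A"],
                                                   truth["t_R"] + 30.0,
                                                   truth["D"], tg.a), a=tg.a)
        fit0 = fit_taylorgram(tg)
        fit1 = fit_taylorgram(shifted)
        assert fit1.t_R - fit0.t_R == pytest.approx(30.0, abs=0.5)
        # dispersion accrues with residence time: D agrees closely
        assert fit1.D == pytest.approx(fit0.D, rel=0.01)

    def test_fit_reproduces_generator_hydrodynamic_radius(self):
        tg, truth = gen_taylorgram(seed=0, noise_sigma=0.0)
        fit = fit_taylorgram(tg)
        assert fit.R_h == pytest.approx(stokes_einstein(truth["D"]), rel=1e-3)


class TestStokesEinstein:
    def test_hand_value(self):
        # D = 4e-10 m²/s, T = 303 K, eta = 0.797 mPa·s -> about 0.696 nm
        assert stokes_einstein(4.0e-10) == pytest.approx(0.696e-9, rel=1e-3)

    def test_inverse_proportionality(self):
        assert stokes_einstein(2e-10) == pytest.approx(2 * stokes_einstein(4e-10))
        assert stokes_einstein(4e-10) * 4e-10 == pytest.approx(
            stokes_einstein(1e-10) * 1e-10
        )

    def test_nonpositive_d_rejected(self):
        with pytest.raises(ValueError):
            stokes_einstein(0.0)


class TestSprBiexponential:
    def test_noise_free_recovery(self):
        sg, truth = gen_spr_trace(seed=0, kind="biexp", noise_sigma=0.0)
        fit = fit_spr_biexponential(sg)
        assert fit.k1 == pytest.approx(truth["k1"], rel=5e-3)
        assert fit.k2 == pytest.approx(truth["k2"], rel=5e-3)
        assert fit.plateau == pytest.approx(truth["plateau"], rel=5e-3)

    def test_zero_amplitudes_zero_plateau(self):
        t = np.linspace(0.0, 120.0, 241)
        sg = Sensorgram(t, np.zeros_like(t), concentration=10.0, tau=60.0)
        fit = fit_spr_biexponential(sg)
        assert fit.plateau == pytest.approx(0.0, abs=1e-6)

    def test_plateau_invariant_under_phase_label_swap(self):
        sg, _ = gen_spr_trace(seed=2, kind="biexp", noise_sigma=0.5,
                              A1=20.0, A2=30.0, k1=0.05, k2=0.5)
        fit = fit_spr_biexponential(sg)
        # canonical ordering: fast phase first, plateau unchanged
        assert fit.k1 >= fit.k2
        assert fit.plateau == pytest.approx(50.0, rel=0.05)


class TestSprLangmuir:
    def test_recovery_when_kd_in_range(self):
        truth_kd = 50.0  # uM, inside the tested concentration range
        sgs, truth = gen_spr_series(seed=6, concentrations=(10.0, 50.0, 150.0),
                                    b_max=100.0, k_on=1e-3, k_off=0.05,
                                    noise_sigma=1.0)
        fit = fit_spr_1to1(sgs)
        assert truth["K_D"] == pytest.approx(truth_kd)
        assert fit.K_D == pytest.approx(truth["K_D"], rel=0.05)
        assert fit.B_max == pytest.approx(truth["b_max"], rel=0.05)
        assert fit.status == "ok"

    def test_weak_binding_flagged_unidentifiable(self):
        # K_D = 25 mM >> 150 uM: plateau linear in concentration
        sgs, _ = gen_spr_series(seed=7, concentrations=(10.0, 50.0, 150.0),
                                b_max=1e4, k_on=2e-6, k_off=0.05,
                                noise_sigma=0.2)
        fit = fit_spr_1to1(sgs, b_max=1e4)
        assert fit.status == "KD >> max [A]"
        assert fit.K_D > 1500.0

    def test_zero_concentration_trace_is_flat(self):
        sgs, _ = gen_spr_series(seed=8, concentrations=(0.0, 50.0),
                                noise_sigma=0.0)
        assert np.allclose(sgs[0].response, 0.0)


def peak_table(rows):
    return pd.DataFrame(rows, columns=["residue", "dH", "dN", "intensity"])


class TestCsp:
    def test_zero_shift_zero_csp(self):
        ref = peak_table([(1, 8.0, 120.0, 100.0)])
        out = csp(ref, ref.copy())
        assert out["csp"].iloc[0] == 0.0
        assert out["intensity_ratio"].iloc[0] == 1.0

    def test_sign_flip_symmetry(self):
        ref = peak_table([(1, 8.0, 120.0, 100.0)])
        plus = peak_table([(1, 8.1, 120.5, 80.0)])
        minus = peak_table([(1, 7.9, 119.5, 80.0)])
        assert csp(ref, plus)["csp"].iloc[0] == pytest.approx(
            csp(ref, minus)["csp"].iloc[0], rel=1e-12
        )

    def test_hand_evaluated_weighting(self):
        # CSP = sqrt((dH^2 + (0.14*dN)^2)/2) at dH=0.03, dN=0.5
        ref = peak_table([(7, 8.00, 120.0, 100.0)])
        lig = peak_table([(7, 8.03, 120.5, 60.0)])
        expected = np.sqrt((0.03 ** 2 + (0.14 * 0.5) ** 2) / 2.0)
        out = csp(ref, lig)
        assert out["csp"].iloc[0] == pytest.approx(expected, abs=1e-6)
        assert out["intensity_ratio"].iloc[0] == pytest.approx(0.6)

    def test_unmatched_residue_excluded(self):
        ref = peak_table([(1, 8.0, 120.0, 100.0), (2, 8.2, 118.0, 90.0)])
        lig = peak_table([(1, 8.0, 120.0, 50.0)])
        out = csp(ref, lig)
        assert out["residue"].tolist() == [1]


def spectrum(wavelengths, values):
    return pd.DataFrame({"wavelength": wavelengths, "absorbance": values})


class TestCopelleting:
    wl = np.arange(240.0, 401.0, 2.0)

    def _gauss(self, peak, center=291.0, width=15.0, offset=0.0):
        return offset + peak * np.exp(-((self.wl - center) ** 2) / (2 * width ** 2))

    def test_unchanged_spectrum_is_fully_free(self):
        s = spectrum(self.wl, self._gauss(0.5))
        ref = spectrum(self.wl, np.zeros_like(self.wl))
        out = copelleting_fraction(s, s, ref, ref, lambda_max=291.0)
        assert out["percent_free"] == pytest.approx(100.0)
        assert out["percent_copelleted"] == pytest.approx(0.0)

    def test_halved_peak_is_half_free(self):
        before = spectrum(self.wl, self._gauss(0.5))
        after = spectrum(self.wl, self._gauss(0.25))
        ref = spectrum(self.wl, np.zeros_like(self.wl))
        out = copelleting_fraction(before, after, ref, ref, lambda_max=291.0)
        assert out["percent_free"] == pytest.approx(50.0, abs=1e-9)

    def test_reference_and_baseline_corrections(self):
        # reference offset 0.05 and 400-nm drift 0.02 must both cancel
        ref_val = 0.05
        drift = 0.02
        before = spectrum(self.wl, self._gauss(0.5, offset=ref_val + drift))
        after = spectrum(self.wl, self._gauss(0.2, offset=ref_val + drift))
        ref = spectrum(self.wl, np.full_like(self.wl, ref_val))
        # corrected peak heights: (gauss + drift - drift) -> 0.5 and 0.2 at peak,
        # minus the gaussian tail at 400 nm (same for both, ~0)
        out = copelleting_fraction(before, after, ref, ref, lambda_max=291.0)
        tail = np.exp(-((400.0 - 291.0) ** 2) / (2 * 15.0 ** 2))
        expected = 100.0 * (0.2 - 0.2 * tail) / (0.5 - 0.5 * tail)
        assert out["percent_free"] == pytest.approx(expected, abs=1e-6)

    def test_gain_invariance(self):
        before = spectrum(self.wl, self._gauss(0.5))
        after = spectrum(self.wl, self._gauss(0.3))
        ref = spectrum(self.wl, np.full_like(self.wl, 0.01))
        a = copelleting_fraction(before, after, ref, ref, lambda_max=291.0)
        before2 = spectrum(self.wl, 3.0 * self._gauss(0.5))
        after2 = spectrum(self.wl, 3.0 * self._gauss(0.3))
        ref2 = spectrum(self.wl, 3.0 * np.full_like(self.wl, 0.01))
        b = copelleting_fraction(before2, after2, ref2, ref2, lambda_max=291.0)
        assert a["percent_free"] == pytest.approx(b["percent_free"], rel=1e-12)

    def test_nonpositive_before_value_rejected(self):
        flat = spectrum(self.wl, np.zeros_like(self.wl))
        with pytest.raises(ValueError):
            copelleting_fraction(flat, flat, flat, flat, lambda_max=291.0)


class TestExtinctionCoefficient:
    def test_composition_rule(self):
        assert extinction_coefficient_280(0, 0, 0) == 0.0
        assert extinction_coefficient_280(0, 1, 1) == 1615.0

    def test_additivity(self):
        a, b = (1, 2, 0), (0, 3, 1)
        total = tuple(x + y for x, y in zip(a, b))
        assert extinction_coefficient_280(*total) == (
            extinction_coefficient_280(*a) + extinction_coefficient_280(*b)
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            extinction_coefficient_280(-1, 0, 0)


class TestBufferCapacity:
    def test_hand_evaluated_van_slyke(self):
        # 160 mM, pKa 9.1, pH 7.4, 30 C -> about 7.07 mM
        beta = buffer_capacity(160.0, [9.1], 7.4, temperature_c=30.0)
        assert beta == pytest.approx(7.07, abs=0.02)

    def test_far_from_pka_only_water_terms_remain(self):
        beta = buffer_capacity(1.0, [13.0], 7.0, temperature_c=25.0)
        water = np.log(10.0) * (10 ** (-13.996 + 7.0) + 10 ** -7.0) * 1e3
        assert beta == pytest.approx(water, rel=0.01)

    def test_maximal_at_ph_equal_pka(self):
        grid = np.linspace(6.0, 12.0, 61)
        betas = [buffer_capacity(100.0, [9.0], ph) for ph in grid]
        assert grid[int(np.argmax(betas))] == pytest.approx(9.0, abs=0.11)
        peak = np.log(10.0) * 0.1 / 4.0 * 1e3
        assert max(betas) == pytest.approx(peak, rel=0.01)

    def test_empty_pka_list_rejected(self):
        with pytest.raises(ValueError):
            buffer_capacity(100.0, [], 7.0)
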