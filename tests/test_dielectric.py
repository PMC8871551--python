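"""Local-porosity-theory mixing law: forward solver and three-parameter fit."""

import numpy as np
import pytest

from porodiff import dielectric_lpt as dl
from porodiff import synthetic_data as sd

from conftest import brute_force_eps_root


class TestWaterEps:
    def test_zero_conductivity_is_real(self):
        p = dl.LPTParams(sigma_w=0.0)
        eps = dl.water_eps(1e6, p)
        assert eps.imag == 0.0
        assert eps.real == p.eps_w

    def test_loss_at_1mhz(self):
        p = dl.LPTParams(eps_w=78.5, sigma_w=0.1)
        eps = dl.water_eps(1e6, p)
        # sigma/(eps0 * 2 pi f)
        assert -eps.imag == pytest.approx(0.1 / (dl.EPS0 * 2 * np.pi * 1e6),
                                          rel=1e-12)
        assert -eps.imag == pytest.approx(1797.5, abs=0.1)

    def test_loss_vanishes_at_high_frequency(self):
        p = dl.LPTParams(sigma_w=0.1)
        assert abs(dl.water_eps(1e15, p).imag) < 1e-4

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            dl.water_eps(0.0, dl.LPTParams())


class TestEffectiveComponents:
    @pytest.mark.parametrize("phi,which,expected", [
        (1.0, 0, "water"), (1.0, 1, "water"),
        (0.0, 0, "polymer"), (0.0, 1, "polymer"),
    ])
    def test_pure_phase_limits(self, lpt_default, phi, which, expected):
        freq = 1e6
        pair = dl.effective_component_eps(phi, freq, lpt_default)
        ref = (dl.water_eps(freq, lpt_default) if expected == "water"
               else complex(lpt_default.eps_p))
        assert pair[which] == pytest.approx(ref, rel=1e-12)

    def test_exact_rational_oracle_at_half_porosity(self):
        # lossless components eps_w = 80, eps_p = 3, phi = 1/2: evaluating
        # the mixing formulas in exact rational arithmetic gives
        # eps_we = 13760/403 and eps_pe = 978/95
        p = dl.LPTParams(eps_w=80.0, sigma_w=0.0, eps_p=3.0)
        ewe, epe = dl.effective_component_eps(0.5, 1e6, p)
        assert ewe.real == pytest.approx(13760 / 403, rel=1e-12)
        assert epe.real == pytest.approx(978 / 95, rel=1e-12)
        assert ewe.imag == epe.imag == 0.0

    def test_out_of_range_porosity_rejected(self, lpt_default):
        with pytest.raises(ValueError):
            dl.effective_component_eps(1.5, 1e6, lpt_default)


class TestMixingResidual:
    def test_pure_water_fixed_point(self):
        p = dl.LPTParams(Gamma=0.0, phi0=0.9999, var=0.0)
        f = 1e6
        r = dl.mixing_residual(dl.water_eps(f, p), f, p)
        assert abs(r) < 1e-3

    def test_pure_polymer_fixed_point(self):
        # Gamma large -> lambda ~ 0 everywhere below phi = 1
        p = dl.LPTParams(Gamma=500.0, phi0=0.0001, var=0.0, sigma_w=0.0)
        r = dl.mixing_residual(complex(p.eps_p), 1e6, p)
        assert abs(r) < 1e-3

    def test_residual_vanishes_at_solved_root(self, lpt_default):
        for f in (1e3, 1e6, 2e9):
            eps = dl.solve_effective_eps(f, lpt_default)
            assert abs(dl.mixing_residual(eps, f, lpt_default)) < 1e-10

    def test_nonpositive_trial_rejected(self, lpt_default):
        with pytest.raises(ValueError):
            dl.mixing_residual(-1.0 + 0j, 1e6, lpt_default)


class TestSolver:
    def test_matches_brute_force_oracle(self):
        # independent complex-plane grid refinement vs the Newton solver
        cases = [
            dl.LPTParams(Gamma=0.5, phi0=0.6, var=0.02),
            dl.LPTParams(Gamma=2.0, phi0=0.8, var=0.01),
            dl.LPTParams(Gamma=5.0, phi0=0.4, var=0.03, sigma_w=0.05),
        ]
        for p in cases:
            for f in (1e3, 1e6, 1e9):
                newton = dl.solve_effective_eps(f, p)
                brute = brute_force_eps_root(f, p)
                assert abs(newton - brute) / abs(newton) < 1e-6

    def test_all_water_degenerate_spectrum(self):
        p = dl.LPTParams(Gamma=0.0, phi0=0.999999, var=0.0)
        freqs = np.logspace(3, 9, 8)
        spec = dl.forward_spectrum(p, freqs)
        ref = dl.water_eps(freqs, p)
        np.testing.assert_allclose(spec.eps_complex, ref, rtol=1e-5)

    def test_all_polymer_degenerate(self):
        # a delta distribution at phi0 -> 0 with lambda = 0 everywhere:
        # the root is the blocked-cell permittivity at phi0 (-> eps_p)
        p = dl.LPTParams(Gamma=500.0, phi0=0.000001, var=0.0, sigma_w=0.0)
        eps = dl.solve_effective_eps(1e6, p)
        expected = dl.effective_component_eps(p.phi0, 1e6, p)[1]
        assert eps == pytest.approx(expected, rel=1e-9)
        assert eps == pytest.approx(complex(p.eps_p), rel=1e-5)

    def test_lossy_branch(self, lpt_default):
        for f in (1e3, 1e6, 1e9):
            eps = dl.solve_effective_eps(f, lpt_default)
            assert eps.real > 0
            assert eps.imag <= 1e-12

    def test_quadrature_doubling_stable(self, lpt_default):
        for f in (1e4, 1e8):
            e1 = dl.solve_effective_eps(f, lpt_default, n_nodes=dl.N_QUAD)
            e2 = dl.solve_effective_eps(f, lpt_default, n_nodes=2 * dl.N_QUAD)
            assert abs(e1 - e2) / abs(e1) < 1e-8


class TestForwardSpectrum:
    def test_interfacial_dispersion_lowers_high_freq_eps(self, lpt_default):
        spec = dl.forward_spectrum(lpt_default, dl.default_frequency_grid(30))
        assert spec.eps_real[-1] < spec.eps_real[0]
        assert np.all(spec.eps_loss >= 0)

    def test_continuity_along_grid(self, lpt_default):
        # on a dense grid the continuation path must have no branch jumps;
        # even the conduction-dominated 1/ω loss changes < 10% per step
        spec = dl.forward_spectrum(lpt_default, dl.default_frequency_grid(300))
        rel_jump = np.abs(np.diff(spec.eps_complex)) / np.abs(spec.eps_complex[:-1])
        assert np.all(rel_jump < 0.10)

    def test_effective_medium_bracketing(self, lpt_default):
        # the real part stays between the component permittivities
        spec = dl.forward_spectrum(lpt_default, dl.default_frequency_grid(20))
        assert np.all(spec.eps_real >= lpt_default.eps_p - 1e-9)
        assert np.all(spec.eps_real <= lpt_default.eps_w + 1e-9)

    def test_higher_gamma_reduces_low_frequency_loss(self):
        # fewer percolating cells -> less conduction loss at low frequency
        freqs = np.array([1e3, 1e4])
        losses = []
        for gamma in (0.5, 2.0, 8.0):
            p = dl.LPTParams(Gamma=gamma, phi0=0.7, var=0.02)
            losses.append(dl.forward_spectrum(p, freqs).eps_loss[0])
        assert losses[0] > losses[1] > losses[2]


class TestBulkPorosity:
    def test_delta_limit(self):
        p = dl.LPTParams(phi0=0.37, var=0.0)
        assert dl.bulk_porosity(p) == pytest.approx(0.37, rel=1e-12)

    def test_symmetric_truncation(self):
        p = dl.LPTParams(phi0=0.5, var=0.02)
        assert dl.bulk_porosity(p) == pytest.approx(0.5, rel=1e-10)

    def test_against_fine_trapezoid_oracle(self):
        from scipy import stats
        p = dl.LPTParams(phi0=0.9, var=0.04)
        sd_ = np.sqrt(p.var)
        a, b = -p.phi0 / sd_, (1 - p.phi0) / sd_
        x = np.linspace(0, 1, 400_001)
        pdf = stats.truncnorm.pdf(x, a, b, loc=p.phi0, scale=sd_)
        oracle = np.trapezoid(x * pdf, x) / np.trapezoid(pdf, x)
        assert dl.bulk_porosity(p) == pytest.approx(oracle, abs=1e-8)


class TestInversion:
    def test_noiseless_round_trip(self, lpt_default):
        freqs = dl.default_frequency_grid(50)
        spec = dl.forward_spectrum(lpt_default, freqs)
        fit, diag = dl.fit_lpt(spec, known=lpt_default, seed=0)
        assert fit.Gamma == pytest.approx(lpt_default.Gamma, rel=0.01)
        assert fit.phi0 == pytest.approx(lpt_default.phi0, rel=0.01)
        assert fit.var == pytest.approx(lpt_default.var, rel=0.01)

    def test_fully_percolating_boundary(self):
        truth = dl.LPTParams(Gamma=0.0, phi0=0.8, var=0.01)
        spec = dl.forward_spectrum(truth, dl.default_frequency_grid(30))
        fit, _ = dl.fit_lpt(spec, known=truth, n_starts=3, seed=1)
        assert fit.Gamma <= 0.05

    def test_narrow_spectrum_rejected(self, lpt_default):
        freqs = np.logspace(6, 7, 12)
        spec = dl.forward_spectrum(lpt_default, freqs)
        with pytest.raises(ValueError, match="decade"):
            dl.fit_lpt(spec, known=lpt_default)
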