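"""TRES assembly, center of gravity, FWHM, and relaxation fitting."""

import numpy as np
import pytest

from trfit.core_model import RelaxationModel, relaxation_curve
from trfit.decay_fitting import DecayFitResult
from trfit.synthetic import simulate_tres_dataset
from trfit.tres import (
    Spectrum,
    analyze_tres,
    build_tres,
    center_of_gravity,
    fit_relaxation,
    relaxation_time_ratio,
    spectral_fwhm,
)

from test_synthetic import _homog_scenario


def _fit_stub(model, lam, converged=True):
    return DecayFitResult(
        model=model, irf_shift=0.0, background=0.0, scale=1.0,
        reduced_chi2=1.0, residuals=np.zeros(1), converged=converged,
        window=(0.0, 50.0), meta={"wavelength_nm": lam},
    )


class TestCenterOfGravity:
    def test_single_point(self):
        s = Spectrum(np.array([310.0, 320.0, 330.0]),
                     np.array([0.0, 1.0, 0.0]), 0.0)
        # only the 320-nm point carries weight: nu = 1e7/320
        assert center_of_gravity(s) == pytest.approx(31250.0)

    def test_two_point_mean(self):
        s = Spectrum(np.array([300.0, 400.0]), np.array([1.0, 1.0]), 0.0)
        assert center_of_gravity(s) == pytest.approx(29166.67, abs=0.5)

    def test_weighted_mean(self):
        s = Spectrum(np.array([300.0, 350.0]), np.array([1.0, 3.0]), 0.0)
        assert center_of_gravity(s) == pytest.approx(29761.9, abs=0.5)

    def test_scale_and_zero_padding_invariance(self, rng):
        lams = np.linspace(300.0, 380.0, 20)
        inten = np.exp(-0.5 * ((lams - 340.0) / 15.0) ** 2)
        ref = center_of_gravity(Spectrum(lams, inten, 0.0))
        assert center_of_gravity(Spectrum(lams, 7.3 * inten, 0.0)) == pytest.approx(ref)
        padded_lams = np.concatenate([[280.0, 290.0], lams, [400.0]])
        padded = np.concatenate([[0.0, 0.0], inten, [0.0]])
        assert center_of_gravity(Spectrum(padded_lams, padded, 0.0)) == pytest.approx(ref)


class TestFWHM:
    def test_gaussian_closed_form(self):
        """A Gaussian band in wavenumber (sigma 800 cm^-1) sampled on a 2-nm
        grid has FWHM 2 sqrt(2 ln 2) * 800 within 1%."""
        lams = np.arange(300.0, 391.0, 2.0)
        nu = 1.0e7 / lams
        inten = np.exp(-0.5 * ((nu - 29400.0) / 800.0) ** 2)
        got = spectral_fwhm(Spectrum(lams, inten, 0.0))
        expected = 2.0 * np.sqrt(2.0 * np.log(2.0)) * 800.0
        assert got == pytest.approx(expected, rel=0.01)

    def test_scale_invariance(self):
        lams = np.arange(300.0, 391.0, 2.0)
        nu = 1.0e7 / lams
        inten = np.exp(-0.5 * ((nu - 29400.0) / 900.0) ** 2)
        a = spectral_fwhm(Spectrum(lams, inten, 0.0))
        b = spectral_fwhm(Spectrum(lams, 2.0 * inten, 0.0))
        assert a == pytest.approx(b)

    def test_monotone_spectrum_rejected(self):
        lams = np.linspace(300.0, 390.0, 20)
        with pytest.raises(ValueError, match="interior maximum"):
            spectral_fwhm(Spectrum(lams, np.linspace(0.1, 1.0, 20), 0.0))

    def test_truncated_flank_named(self):
        lams = np.linspace(300.0, 390.0, 31)
        nu = 1.0e7 / lams
        inten = np.exp(-0.5 * ((nu - 32500.0) / 900.0) ** 2)  # blue edge cut
        with pytest.raises(ValueError, match="flank"):
            spectral_fwhm(Spectrum(lams, inten, 0.0))


class TestBuildTres:
    lams = np.linspace(300.0, 390.0, 10)

    def test_identical_decays_give_flat_spectra(self, triexp):
        fits = [_fit_stub(triexp, lam) for lam in self.lams]
        spectra = build_tres(fits, np.array([0.0, 1.0, 5.0]))
        for s in spectra:
            np.testing.assert_allclose(s.intensities, 1.0)

    def test_too_few_wavelengths(self, triexp):
        fits = [_fit_stub(triexp, lam) for lam in self.lams[:3]]
        with pytest.raises(ValueError, match="8"):
            build_tres(fits, np.array([0.0]))

    def test_duplicate_wavelengths(self, triexp):
        fits = [_fit_stub(triexp, 340.0) for _ in self.lams]
        with pytest.raises(ValueError, match="duplicate"):
            build_tres(fits, np.array([0.0]))

    def test_unconverged_named(self, triexp):
        fits = [_fit_stub(triexp, lam) for lam in self.lams[:-1]]
        fits.append(_fit_stub(triexp, 390.0, converged=False))
        with pytest.raises(ValueError, match="390"):
            build_tres(fits, np.array([0.0]))


class TestFitRelaxation:
    def test_exact_recovery(self):
        truth = RelaxationModel(C=700.0, t_relax=1.5, nu_inf=28900.0)
        t = np.linspace(0.0, 10.0, 40)
        fit = fit_relaxation(t, relaxation_curve(truth, t))
        assert fit.model.C == pytest.approx(700.0, rel=1e-6)
        assert fit.model.t_relax == pytest.approx(1.5, rel=1e-6)
        assert fit.model.nu_inf == pytest.approx(28900.0, rel=1e-9)
        assert not fit.rising_trend

    def test_window_excludes_late_rise(self):
        """With a rise after 2 ns the fit restricted to [0, 2] ns sees only
        the initial decay."""
        truth = RelaxationModel(C=700.0, t_relax=0.8, nu_inf=28900.0)
        t = np.linspace(0.0, 6.0, 61)
        nu = relaxation_curve(truth, t).copy()
        nu[t > 2.0] += 400.0 * (t[t > 2.0] - 2.0)  # artificial late rise
        fit = fit_relaxation(t, nu, window=(0.0, 2.0))
        assert fit.model.t_relax == pytest.approx(0.8, rel=1e-6)
        assert fit.window == (0.0, 2.0)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_relaxation(np.arange(4.0), np.ones(4) * 29000.0)

    def test_rising_trend_flagged(self):
        t = np.linspace(0.0, 10.0, 30)
        nu = 29000.0 - 300.0 * np.exp(-t / 2.0)
        with pytest.warns(UserWarning, match="non-decreasing"):
            fit = fit_relaxation(t, nu)
        assert fit.rising_trend


class TestRatio:
    def test_identity(self):
        m = RelaxationModel(C=500.0, t_relax=1.0, nu_inf=29000.0)
        r, se = relaxation_time_ratio(m, m)
        assert r == 1.0 and se == 0.0

    @pytest.mark.parametrize("td,th,expected", [(1.53, 1.0, 1.53), (1.2, 1.0, 1.2)])
    def test_direct_division(self, td, th, expected):
        d = RelaxationModel(C=500.0, t_relax=td, nu_inf=29000.0)
        h = RelaxationModel(C=500.0, t_relax=th, nu_inf=29000.0)
        assert relaxation_time_ratio(d, h)[0] == pytest.approx(expected)

    def test_error_propagation(self):
        from trfit.tres import RelaxationFit

        d = RelaxationFit(RelaxationModel(500.0, 2.0, 29000.0),
                          {"t_relax": 0.2}, False, (0.0, 10.0))
        h = RelaxationFit(RelaxationModel(500.0, 1.0, 29000.0),
                          {"t_relax": 0.1}, False, (0.0, 10.0))
        r, se = relaxation_time_ratio(d, h)
        assert r == pytest.approx(2.0)
        assert se == pytest.approx(2.0 * np.sqrt(0.1**2 + 0.1**2))


class TestPipeline:
    def test_homogeneous_recovery(self, grid, irf):
        """Full chain recovers the generating relaxation time within 10%
        and the limiting level within 30 cm^-1 (replicate mean)."""
        scen = _homog_scenario(t_relax=1.5, nu_inf=28900.0, C=700.0)
        lams = np.linspace(294.0, 390.0, 16)
        times = np.concatenate([np.arange(0.0, 3.0, 0.1), np.arange(3.0, 25.0, 1.0)])
        trs, nus = [], []
        for seed in range(3):
            hists = simulate_tres_dataset(scen, lams, 20000, seed=seed,
                                          grid=grid, irf=irf)
            res = analyze_tres(hists, irf, times)
            trs.append(res.relax_fit.model.t_relax)
            nus.append(res.relax_fit.model.nu_inf)
        assert np.mean(trs) == pytest.approx(1.5, rel=0.10)
        assert abs(np.mean(nus) - 28900.0) < 30.0

    def test_nu_t_monotone_noise_free(self, grid, irf):
        from trfit.core_model import convolve_with_irf
        from trfit.synthetic import DecayHistogram, tres_surface

        scen = _homog_scenario(t_relax=2.0)
        lams = np.linspace(294.0, 390.0, 16)
        surf = tres_surface(scen, lams, grid.times)
        conv = np.stack([convolve_with_irf(surf[i], irf) for i in range(len(lams))])
        conv *= 20000 / conv.max()
        hists = [DecayHistogram(grid, np.round(conv[i]).astype(np.int64),
                                {"wavelength_nm": float(l)})
                 for i, l in enumerate(lams)]
        res = analyze_tres(hists, irf, np.linspace(0.0, 20.0, 41))
        # monotone non-increasing up to the tri-exponential approximation
        # error of the empirical per-wavelength fits (< 1 cm^-1)
        assert np.all(np.diff(res.nu_t) <= 0.5)
        assert res.nu_t[0] - res.nu_t[-1] > 600.0  # full shift resolved

    def test_fwhm_transient_maximum_location(self):
        """Two-fraction pipeline FWHM peaks where the analytic mixture
        surface says it should (within 1 ns)."""
        from trfit.synthetic import ScenarioParams, tres_surface

        base = _homog_scenario(t_relax=1.0, nu_inf=29590.0, C=1200.0)
        scen = ScenarioParams(
            **{**{f: getattr(base, f) for f in (
                "peptide_id", "decay", "aniso_aq", "aniso_m", "relax_aq",
                "relax_m", "Kd", "kq", "t_relax_slow",
                "spectral_width_sigma", "provenance")},
               "hetero_fraction": 0.5}
        )
        lams = np.arange(288.0, 403.0, 2.0)
        times = np.linspace(0.0, 30.0, 121)
        surf = tres_surface(scen, lams, times)
        widths = np.array([
            spectral_fwhm(Spectrum(lams, surf[:, j], t))
            for j, t in enumerate(times)
        ])
        # numeric argmax of the analytic mixture in wavenumber space
        nu_dense = np.linspace(24000.0, 36000.0, 4000)
        sig = scen.spectral_width_sigma
        arg_analytic = None
        best = -1.0
        for j, t in enumerate(times):
            c1 = 1200.0 * np.exp(-t / 1.0) + 29590.0
            c2 = 1200.0 * np.exp(-t / scen.t_relax_slow) + 29590.0
            mix = 0.5 * np.exp(-0.5 * ((nu_dense - c1) / sig) ** 2) + \
                  0.5 * np.exp(-0.5 * ((nu_dense - c2) / sig) ** 2)
            half = mix.max() / 2.0
            above = nu_dense[mix >= half]
            w = above[-1] - above[0]
            if w > best:
                best, arg_analytic = w, t
        assert abs(times[np.argmax(widths)] - arg_analytic) < 1.0
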