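"""Synthetic-experiment generators: determinism, anchored defaults, and
analytic oracles for the emission surface."""

import numpy as np
import pytest

from trfit.core_model import RelaxationModel, relaxation_curve
from trfit.synthetic import (
    DecayHistogram,
    ScenarioParams,
    make_gaussian_irf,
    polarized_expectation_set,
    scenario_from_table,
    simulate_calcein_sample,
    simulate_decay,
    simulate_partition_titration,
    simulate_polarized_set,
    simulate_quench_series,
    simulate_tres_dataset,
    tres_surface,
)
from trfit.tres import Spectrum, center_of_gravity, spectral_fwhm


class TestScenarioTable:
    def test_v4w_row(self):
        s = scenario_from_table("V4W")
        assert s.Kd == 23.0
        assert s.aniso_aq.r_inf == 0.005
        assert s.aniso_m.r_inf == 0.080
        assert s.relax_aq.nu_inf == 28700.0
        assert s.relax_m.nu_inf == 29590.0

    def test_l5w_row(self):
        s = scenario_from_table("L5W")
        assert s.Kd == 17.0
        assert s.aniso_m.r_inf == 0.070
        assert s.relax_m.nu_inf == 28900.0

    def test_unknown_peptide(self):
        with pytest.raises(KeyError):
            scenario_from_table("X9W")

    def test_provenance_flags(self):
        s = scenario_from_table("L1W")
        assert s.provenance["Kd"] == "table"
        assert s.provenance["r_inf_m"] == "table"
        assert s.provenance["lifetimes"] == "invented"
        assert s.provenance["kq"] == "invented"


class TestGaussianIRF:
    def test_delta_limit(self, grid):
        irf = make_gaussian_irf(grid.dt / 20.0, 1.0, grid)
        assert np.count_nonzero(irf.counts) == 1

    def test_peak_at_center_and_width(self, grid):
        irf = make_gaussian_irf(0.2, 2.0, grid)
        t = grid.times
        assert abs(t[np.argmax(irf.counts)] - 2.0) <= grid.dt
        assert irf.counts.sum() == pytest.approx(1.0)
        # empirical FWHM of the sampled curve within one bin of requested
        above = t[irf.counts >= irf.counts.max() / 2.0]
        assert abs((above[-1] - above[0]) - 0.2) <= grid.dt

    def test_invalid_inputs(self, grid):
        with pytest.raises(ValueError):
            make_gaussian_irf(-1.0, 1.0, grid)
        with pytest.raises(ValueError):
            make_gaussian_irf(0.2, 100.0, grid)


class TestSimulateDecay:
    def test_deterministic(self, grid):
        curve = np.exp(-grid.times / 2.0)
        a = simulate_decay(curve, grid, 10000, seed=7)
        b = simulate_decay(curve, grid, 10000, seed=7)
        assert np.array_equal(a.counts, b.counts)
        c = simulate_decay(curve, grid, 10000, seed=8)
        assert not np.array_equal(a.counts, c.counts)

    def test_zero_curve(self, grid):
        h = simulate_decay(np.zeros(grid.n_bins), grid, 100, seed=0)
        assert h.counts.sum() == 0

    def test_poisson_moments(self, grid):
        """Standardized residuals against the known expectation average to
        ~0 over replicates (Poisson moment oracle)."""
        curve = np.exp(-grid.times / 5.0)
        expectation = curve * 10000.0 / curve.max()
        mask = expectation > 20
        zs = []
        for seed in range(100):
            h = simulate_decay(curve, grid, 10000, seed=seed)
            z = (h.counts[mask] - expectation[mask]) / np.sqrt(expectation[mask])
            zs.append(z.mean())
        assert abs(np.mean(zs)) < 0.01

    def test_invalid(self, grid):
        with pytest.raises(ValueError):
            simulate_decay(np.ones(grid.n_bins), grid, 0)
        with pytest.raises(ValueError):
            simulate_decay(np.ones(grid.n_bins), grid, 100, background=-1.0)

    def test_histogram_invariants(self, grid):
        with pytest.raises(ValueError):
            DecayHistogram(grid, -np.ones(grid.n_bins, dtype=np.int64))
        with pytest.raises(ValueError):
            DecayHistogram(grid, np.zeros(grid.n_bins, dtype=np.int64),
                           meta={"bogus_key": 1})


class TestPolarizedSet:
    def test_empty_thetas(self, grid, irf):
        scen = scenario_from_table("V4W")
        with pytest.raises(ValueError):
            simulate_polarized_set(scen, [], 1.1, 1000, grid=grid, irf=irf)

    def test_metadata_and_determinism(self, grid, irf):
        scen = scenario_from_table("V4W")
        a = simulate_polarized_set(scen, [0.0, 90.0], 1.1, 5000, seed=3,
                                   grid=grid, irf=irf)
        b = simulate_polarized_set(scen, [0.0, 90.0], 1.1, 5000, seed=3,
                                   grid=grid, irf=irf)
        assert a[0].meta["polarizer_deg"] == 0.0
        assert a[1].meta["g_factor"] == 1.1
        assert all(np.array_equal(x.counts, y.counts) for x, y in zip(a, b))

    def test_noise_free_construction_identity(self, grid):
        """VV/VH expectation curves with a delta IRF reproduce r(t)."""
        from trfit.core_model import InstrumentResponse

        delta = np.zeros(grid.n_bins)
        delta[0] = 1.0
        dirf = InstrumentResponse(grid, delta)
        scen = scenario_from_table("L7W")
        G = 1.2
        vv, vh = polarized_expectation_set(scen, [0.0, 90.0], G, grid, dirf, "m")
        r = (vv - G * vh) / (vv + 2.0 * G * vh)
        aniso = scen.aniso_m
        truth = aniso.B * np.exp(-grid.times / aniso.phi) + aniso.r_inf
        np.testing.assert_allclose(r, truth, atol=1e-9)


def _homog_scenario(t_relax=2.0, nu_inf=29000.0, C=800.0, sigma=1400.0):
    base = scenario_from_table("L1W")
    return ScenarioParams(
        peptide_id="L1W",
        decay=base.decay,
        aniso_aq=base.aniso_aq,
        aniso_m=base.aniso_m,
        relax_aq=base.relax_aq,
        relax_m=RelaxationModel(C=C, t_relax=t_relax, nu_inf=nu_inf),
        Kd=base.Kd,
        kq=base.kq,
        hetero_fraction=0.0,
        t_relax_slow=10.0,
        spectral_width_sigma=sigma,
        provenance={},
    )


class TestTRESSurface:
    # 2-nm grid spanning the emission band with >3 sigma margin on both
    # flanks, so the discrete center of gravity is truncation-free
    wavelengths = np.arange(288.0, 403.0, 2.0)

    def test_cog_tracks_generating_center(self):
        """Discrete center of gravity of the analytic surface matches the
        generating band center within the wavelength-grid discretization."""
        scen = _homog_scenario()
        times = np.array([0.0, 0.5, 1.0, 2.0, 5.0, 10.0])
        surf = tres_surface(scen, self.wavelengths, times)
        truth = relaxation_curve(scen.relax_m, times)
        for j, t in enumerate(times):
            cog = center_of_gravity(Spectrum(self.wavelengths, surf[:, j], t))
            assert abs(cog - truth[j]) < 10.0

    def test_homogeneous_fwhm_constant(self):
        scen = _homog_scenario()
        times = np.linspace(0.0, 20.0, 15)
        surf = tres_surface(scen, self.wavelengths, times)
        widths = [
            spectral_fwhm(Spectrum(self.wavelengths, surf[:, j], t))
            for j, t in enumerate(times)
        ]
        widths = np.asarray(widths)
        assert np.ptp(widths) / widths.mean() < 0.02

    def test_heterogeneous_fwhm_transient_maximum(self):
        """A slow-relaxing subpopulation separates the bands transiently,
        producing an interior FWHM maximum."""
        base = _homog_scenario(t_relax=1.0, nu_inf=29590.0, C=1200.0)
        scen = ScenarioParams(
            **{**{f: getattr(base, f) for f in (
                "peptide_id", "decay", "aniso_aq", "aniso_m", "relax_aq",
                "relax_m", "Kd", "kq", "t_relax_slow",
                "spectral_width_sigma", "provenance")},
               "hetero_fraction": 0.5}
        )
        times = np.linspace(0.0, 40.0, 81)
        surf = tres_surface(scen, self.wavelengths, times)
        widths = np.array([
            spectral_fwhm(Spectrum(self.wavelengths, surf[:, j], t))
            for j, t in enumerate(times)
        ])
        k = int(np.argmax(widths))
        assert 0 < k < widths.size - 1
        assert widths[k] > widths[0] and widths[k] > widths[-1]

    def test_steady_state_cog_between_limits(self):
        scen = _homog_scenario()
        times = np.linspace(0.0, 40.0, 400)
        surf = tres_surface(scen, self.wavelengths, times)
        steady = surf.sum(axis=1)
        cog = center_of_gravity(Spectrum(self.wavelengths, steady, 0.0))
        nu0 = relaxation_curve(scen.relax_m, 0.0)
        assert scen.relax_m.nu_inf < cog < nu0

    def test_bad_wavelengths(self, grid, irf):
        scen = _homog_scenario()
        with pytest.raises(ValueError):
            tres_surface(scen, np.array([350.0, 340.0]), np.array([0.0]))
        with pytest.raises(ValueError):
            simulate_tres_dataset(scen, np.array([300.0, 310.0]), 1000,
                                  grid=grid, irf=irf)

    def test_dataset_deterministic(self, grid, irf):
        scen = _homog_scenario()
        lams = np.arange(300.0, 391.0, 12.0)
        a = simulate_tres_dataset(scen, lams, 5000, seed=5, grid=grid, irf=irf)
        b = simulate_tres_dataset(scen, lams, 5000, seed=5, grid=grid, irf=irf)
        assert all(np.array_equal(x.counts, y.counts) for x, y in zip(a, b))
        assert a[0].meta["wavelength_nm"] == 300.0


class TestQuenchSeries:
    def test_zero_q_matches_reference_law(self, grid, irf):
        scen = scenario_from_table("L5W")
        hists = simulate_quench_series(scen, [0.0, 0.2, 0.4], 100000, seed=2,
                                       grid=grid, irf=irf)
        assert hists[0].meta["quencher_M"] == 0.0
        # effective decay slows down monotonically with [Q] removed -> the
        # quenched histograms decay strictly faster than the reference
        assert hists[1].counts[400:600].sum() < hists[0].counts[400:600].sum()

    def test_preconditions(self, grid, irf):
        scen = scenario_from_table("L5W")
        with pytest.raises(ValueError):
            simulate_quench_series(scen, [0.1, 0.2], 1000, grid=grid, irf=irf)
        with pytest.raises(ValueError):
            simulate_quench_series(scen, [0.0, -0.1], 1000, grid=grid, irf=irf)


class TestCalcein:
    def test_amplitude_construction(self, fine_grid, fine_irf):
        s = simulate_calcein_sample(0.5, 0.0, 1.2, 1000, grid=fine_grid,
                                    irf=fine_irf)
        assert s.B_F / s.B_E == pytest.approx(1.2)
        full = simulate_calcein_sample(1.0, 0.0, 1.2, 1000, grid=fine_grid,
                                       irf=fine_irf)
        assert full.B_E == 0.0
        none = simulate_calcein_sample(0.0, 0.1, 1.2, 1000, grid=fine_grid,
                                       irf=fine_irf)
        assert none.B_F == pytest.approx(0.1)

    def test_invalid_fractions(self, fine_grid, fine_irf):
        with pytest.raises(ValueError):
            simulate_calcein_sample(1.5, 0.0, 1.2, 1000, grid=fine_grid,
                                    irf=fine_irf)
        with pytest.raises(ValueError):
            simulate_calcein_sample(0.5, 0.0, -1.0, 1000, grid=fine_grid,
                                    irf=fine_irf)


class TestPartitionTitration:
    endpoints = {330.0: (1000.0, 1500.0), 340.0: (900.0, 1600.0)}

    def test_noise_free_law(self):
        tbl = simulate_partition_titration(20.0, [0.0, 200.0], self.endpoints,
                                           noise_cv=0.0)
        at0 = tbl[(tbl.lipid_uM == 0.0) & (tbl.wavelength_nm == 330.0)]
        assert at0.intensity.iloc[0] == pytest.approx(1000.0)
        at10kd = tbl[(tbl.lipid_uM == 200.0) & (tbl.wavelength_nm == 330.0)]
        assert at10kd.intensity.iloc[0] == pytest.approx(
            (10.0 / 11.0) * 1500.0 + (1.0 / 11.0) * 1000.0
        )

    def test_preconditions(self):
        with pytest.raises(ValueError):
            simulate_partition_titration(-1.0, [0.0, 30.0], self.endpoints)
        with pytest.raises(ValueError):
            simulate_partition_titration(20.0, [15.0, 30.0], self.endpoints)
        with pytest.raises(ValueError):
            simulate_partition_titration(20.0, [0.0, 30.0], {330.0: (1.0, 2.0)})

    def test_deterministic(self):
        a = simulate_partition_titration(20.0, [0.0, 30.0], self.endpoints,
                                         noise_cv=0.05, seed=9)
        b = simulate_partition_titration(20.0, [0.0, 30.0], self.endpoints,
                                         noise_cv=0.05, seed=9)
        assert a.equals(b)
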