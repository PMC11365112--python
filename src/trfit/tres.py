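"""Time-resolved emission spectra: assembly, center of gravity, FWHM, and
the dipolar-relaxation fit.

Spectra at fixed delays after excitation are assembled from per-wavelength
reconvolution fits (noise-free reconstructed decays, mirroring the two-step
empirical-fit-then-analyze structure of the quenching analysis). The center
of gravity nu(t) — the intensity-weighted mean of 1/lambda — is fitted
monoexponentially to C exp(-t/t_relax) + nu_inf to extract the dipolar
relaxation time and limiting relaxation level. A paired H2O/D2O comparison
yields the heavy-water relaxation-time ratio R_D/H.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .core_model import InstrumentResponse, RelaxationModel, multiexp_intensity
from .decay_fitting import DecayFitResult, fit_multiexp_reconvolution

__all__ = [
    "Spectrum",
    "TRESResult",
    "RelaxationFit",
    "build_tres",
    "center_of_gravity",
    "spectral_fwhm",
    "fit_relaxation",
    "relaxation_time_ratio",
    "analyze_tres",
]


@dataclass(frozen=True)
class Spectrum:
    """Peak-normalized emission spectrum at one delay after excitation."""

    wavelengths: np.ndarray = field(repr=False)  # nm, strictly increasing
    intensities: np.ndarray = field(repr=False)  # relative, max = 1
    time_stamp: float  # ns

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if lam.ndim != 1 or lam.size < 2 or np.any(np.diff(lam) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if inten.shape != lam.shape:
            raise ValueError("intensities must match wavelengths in shape")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        peak = inten.max()
        if peak <= 0:
            raise ValueError("spectrum has no positive intensity")
        object.__setattr__(self, "wavelengths", lam)
        object.__setattr__(self, "intensities", inten / peak)


@dataclass(frozen=True)
class RelaxationFit:
    """Relaxation-law fit with standard errors and a rising-trend flag."""

    model: RelaxationModel
    stderr: dict  # keys: C, t_relax, nu_inf
    rising_trend: bool
    window: tuple[float, float]


@dataclass(frozen=True)
class TRESResult:
    """Assembled TRES analysis: spectra, nu(t), FWHM(t), relaxation fit."""

    spectra: list
    times: np.ndarray = field(repr=False)
    nu_t: np.ndarray = field(repr=False)  # cm^-1
    fwhm_t: np.ndarray = field(repr=False)  # cm^-1; NaN where undefined
    relax_fit: RelaxationFit | None
    fit_window: tuple[float, float] | None


def build_tres(
    per_wavelength_fits: list[DecayFitResult],
    times: np.ndarray,
) -> list[Spectrum]:
    """Assemble peak-normalized spectra at the requested delays.

    Each fit must carry ``wavelength_nm`` metadata and be converged; the
    reconstructed (noise-free, IRF-free) decay law — signed pre-exponentials
    included, so red-edge rise components survive — is evaluated at each
    delay and the intensities across wavelengths form one spectrum per
    delay. Small negative excursions of the reconstructed law are clipped
    to zero.
    """
    if len(per_wavelength_fits) < 8:
        raise ValueError("at least 8 wavelengths are required for TRES assembly")
    lams, fits = [], []
    for fit in per_wavelength_fits:
        lam = fit.meta.get("wavelength_nm")
        if lam is None:
            raise ValueError("every fit needs wavelength_nm metadata")
        if not fit.converged:
            raise ValueError(f"fit at {lam} nm did not converge; refusing assembly")
        lams.append(float(lam))
        fits.append(fit)
    lams = np.asarray(lams)
    if np.unique(lams).size != lams.size:
        raise ValueError("duplicate wavelengths in TRES input")
    order = np.argsort(lams)
    lams = lams[order]
    fits = [fits[i] for i in order]
    times = np.asarray(times, dtype=float)

    def _eval(fit: DecayFitResult) -> np.ndarray:
        if fit.signed_amplitudes is not None:
            amps = np.asarray(fit.signed_amplitudes)
            taus = np.asarray(fit.model.lifetimes)
            return np.sum(amps[:, None] * np.exp(-times[None, :] / taus[:, None]), axis=0)
        return np.asarray(multiexp_intensity(fit.model, times))

    surface = np.clip(np.stack([_eval(f) for f in fits]), 0.0, None)
    return [
        Spectrum(wavelengths=lams, intensities=surface[:, j], time_stamp=times[j])
        for j in range(times.size)
    ]


def center_of_gravity(spectrum: Spectrum) -> float:
    """Spectral center of gravity in cm^-1.

    The intensity-weighted mean of the reciprocal wavelength, computed
    directly on the wavelength grid: nu = sum_l I_l / lambda_l / sum_l I_l
    with lambda in cm. Invariant to uniform intensity rescaling and to
    appending zero-intensity wavelengths.
    """
    inten = spectrum.intensities
    total = inten.sum()
    if total <= 0:
        raise ValueError("center of gravity undefined for an all-zero spectrum")
    nu = 1.0e7 / spectrum.wavelengths  # nm -> cm^-1
    return float((inten * nu).sum() / total)


def spectral_fwhm(spectrum: Spectrum) -> float:
    """Full width at half maximum on the wavenumber axis (cm^-1).

    The spectrum is mapped to nu = 1/lambda (increasing), half-maximum
    crossings are located by linear interpolation on each flank, and with
    multiple crossings per flank the outermost is taken (robust to noisy
    shoulders). Raises if the maximum sits on a grid edge (no interior
    maximum) or if a flank never crosses half maximum (truncated spectrum).
    """
    nu = (1.0e7 / spectrum.wavelengths)[::-1]
    inten = spectrum.intensities[::-1]
    i_max = int(np.argmax(inten))
    if i_max == 0 or i_max == inten.size - 1:
        raise ValueError("spectrum has no interior maximum; FWHM undefined")
    half = inten.max() / 2.0

    def _outermost(lo_slice: slice, search_from_outside: bool) -> float:
        vals = inten[lo_slice]
        nus = nu[lo_slice]
        above = vals >= half
        cross = np.nonzero(above[1:] != above[:-1])[0]
        if cross.size == 0:
            side = "low-wavenumber" if search_from_outside else "high-wavenumber"
            raise ValueError(
                f"spectrum truncated: the {side} flank never crosses half maximum"
            )
        i = cross[0] if search_from_outside else cross[-1]
        f = (half - vals[i]) / (vals[i + 1] - vals[i])
        return float(nus[i] + f * (nus[i + 1] - nus[i]))

    low = _outermost(slice(0, i_max + 1), True)
    high = _outermost(slice(i_max, None), False)
    return high - low


def fit_relaxation(
    times: np.ndarray,
    nu_values: np.ndarray,
    window: tuple[float, float] | None = None,
) -> RelaxationFit:
    """Monoexponential fit nu(t) = C exp(-t/t_relax) + nu_inf.

    The fit can be restricted to a window (t_lo, t_hi) — used when nu(t)
    rises again at late times and only the initial decay is meaningful. A
    fitted C < 0 (non-decreasing trend) is flagged and returned with a
    warning, not rejected. Unweighted least squares; standard errors from
    the covariance of the fit.
    """
    times = np.asarray(times, dtype=float)
    nu_values = np.asarray(nu_values, dtype=float)
    ok = np.isfinite(nu_values)
    times, nu_values = times[ok], nu_values[ok]
    if window is not None:
        m = (times >= window[0]) & (times <= window[1])
        times, nu_values = times[m], nu_values[m]
        win = (float(window[0]), float(window[1]))
    else:
        win = (float(times.min()), float(times.max()))
    if times.size < 5:
        raise ValueError("at least 5 points inside the window are required")

    def law(t, C, t_relax, nu_inf):
        return C * np.exp(-t / t_relax) + nu_inf

    c0 = nu_values[0] - nu_values[-1]
    span = max(times.max() - times.min(), 1e-6)
    p0 = (c0 if abs(c0) > 1e-9 else 1.0, span / 3.0, nu_values[-1])
    popt, pcov = curve_fit(
        law, times, nu_values, p0=p0,
        bounds=([-np.inf, 1e-6, 0.0], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    rising = popt[0] < -max(1e-6, 1e-3 * abs(nu_values).max())
    if rising:
        warnings.warn(
            "fitted relaxation amplitude C is negative: nu(t) trend is "
            "non-decreasing in the fit window",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # C < 0 already warned above
        model = RelaxationModel(C=float(popt[0]), t_relax=float(popt[1]),
                                nu_inf=float(popt[2]))
    return RelaxationFit(
        model=model,
        stderr={"C": float(perr[0]), "t_relax": float(perr[1]),
                "nu_inf": float(perr[2])},
        rising_trend=bool(rising),
        window=win,
    )


def relaxation_time_ratio(
    fit_D2O: RelaxationFit | RelaxationModel,
    fit_H2O: RelaxationFit | RelaxationModel,
) -> tuple[float, float]:
    """Heavy-water relaxation-time ratio R_D/H = t_relax(D2O) / t_relax(H2O).

    Returns (ratio, standard error) with the error propagated to first order
    from the two fits' t_relax standard errors (zero when plain models are
    passed).
    """

    def _unpack(x) -> tuple[float, float]:
        if isinstance(x, RelaxationFit):
            return x.model.t_relax, x.stderr.get("t_relax", 0.0)
        return x.t_relax, 0.0

    td, sd = _unpack(fit_D2O)
    th, sh = _unpack(fit_H2O)
    ratio = td / th
    se = abs(ratio) * np.sqrt((sd / td) ** 2 + (sh / th) ** 2)
    return float(ratio), float(se)


def analyze_tres(
    histograms: list,
    irf: InstrumentResponse,
    times: np.ndarray,
    n_components: int = 3,
    fit_window: tuple[float, float] | None = None,
    relax_window: tuple[float, float] | None = None,
    delay_floor: float = 1e-3,
) -> TRESResult:
    """Full TRES chain: per-wavelength reconvolution fits -> spectra ->
    nu(t), FWHM(t) -> relaxation fit.

    Wavelength decays are fitted in order with each fit warm-starting the
    next (the decay shape varies smoothly across the band). Requested delays
    at which the total reconstructed intensity has fallen below
    ``delay_floor`` of its initial value are dropped: past that point the
    fluorescence has decayed below the photon noise and the reconstructed
    decays are extrapolation, not measurement. FWHM is NaN at delays where
    the spectrum is truncated or has no interior maximum; the relaxation fit
    ignores non-finite nu(t) entries.
    """
    times = np.asarray(times, dtype=float)
    hists = sorted(histograms, key=lambda h: h.meta.get("wavelength_nm", 0.0))
    grid = hists[0].grid
    tau_cap = grid.span / 4.0  # lifetimes beyond this are tail extrapolation
    fits: list[DecayFitResult] = []
    init = None
    for h in hists:
        fit = fit_multiexp_reconvolution(
            h, irf, n_components=n_components, init=init, window=fit_window,
            nonneg=False,
            lifetime_bounds=[(2.0 * grid.dt, tau_cap)] * n_components,
        )
        if fit.converged and fit.model.n_components == n_components:
            init = fit.model.lifetimes
        else:
            init = None
        fits.append(fit)
    if delay_floor is not None:
        total = np.zeros(times.size)
        for f in fits:
            amps = np.asarray(
                f.signed_amplitudes
                if f.signed_amplitudes is not None
                else f.model.amplitudes
            )
            taus = np.asarray(f.model.lifetimes)
            total += np.clip(
                np.sum(amps[:, None] * np.exp(-times[None, :] / taus[:, None]), axis=0),
                0.0,
                None,
            )
        keep = total >= delay_floor * total[0]
        if keep.sum() >= 5:
            times = times[keep]
    spectra = build_tres(fits, times)
    nu_t = np.array([center_of_gravity(s) for s in spectra])
    fwhm_t = np.empty(times.size)
    for j, s in enumerate(spectra):
        try:
            fwhm_t[j] = spectral_fwhm(s)
        except ValueError:
            fwhm_t[j] = np.nan
    relax = fit_relaxation(times, nu_t, window=relax_window)
    return TRESResult(
        spectra=spectra,
        times=times,
        nu_t=nu_t,
        fwhm_t=fwhm_t,
        relax_fit=relax,
        fit_window=relax.window,
    )
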