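"""Global fit of polarized fluorescence decays.

All polarizer-angle curves are fitted simultaneously in counts space by
reconvolution with the single-exponential-plus-offset anisotropy law

    I(theta, t) = k(theta)/3 * sum_i A_i e^{-t/tau_i}
                  * [1 + (3 cos^2 theta - 1)(B e^{-t/phi} + r_inf)],

sharing B, phi and r_inf across curves. Lifetimes are fixed inputs
(pre-fitted from a magic-angle curve or TRES analysis); the shared
amplitudes and optional per-curve intensity scales enter linearly and are
solved in closed form at each objective evaluation. G is a measured
instrument property, never fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls
from scipy.signal import fftconvolve

from .core_model import (
    AnisotropyModel,
    InstrumentResponse,
    MultiExpModel,
    polarizer_factor,
)
from .synthetic import DecayHistogram

__all__ = ["AnisotropyFitResult", "fit_anisotropy_global", "anisotropy_construction"]

_MAGIC_GEOM_TOL = 1e-3  # |3cos^2(theta)-1| below this carries no r(t) information


@dataclass(frozen=True)
class AnisotropyFitResult:
    """Globally fitted anisotropy parameters with fixed input lifetimes."""

    aniso: AnisotropyModel
    lifetimes_used: MultiExpModel
    per_curve_scale: tuple[float, ...]
    reduced_chi2: float
    amplitudes: tuple[float, ...]
    phi_unconstrained: bool = False
    residuals: np.ndarray = field(default=None, repr=False)


def anisotropy_construction(
    i_vv: np.ndarray, i_vh: np.ndarray, G: float
) -> np.ndarray:
    """Brute-force anisotropy curve r(t) = (I_VV - G I_VH)/(I_VV + 2 G I_VH).

    The construction oracle: applied to noise-free polarized curves it
    recovers B e^{-t/phi} + r_inf exactly at every grid point.
    """
    i_vv = np.asarray(i_vv, dtype=float)
    i_vh = np.asarray(i_vh, dtype=float)
    denom = i_vv + 2.0 * G * i_vh
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom != 0, (i_vv - G * i_vh) / denom, np.nan)


def fit_anisotropy_global(
    decays: list[DecayHistogram],
    irf: InstrumentResponse,
    lifetimes: MultiExpModel,
    G: float,
    fit_scales: bool = False,
    window: tuple[float, float] | None = None,
) -> AnisotropyFitResult:
    """Simultaneous reconvolution fit of polarized decays for B, phi, r_inf.

    Parameters
    ----------
    decays
        Histograms with ``polarizer_deg`` metadata, at least two distinct
        angles including vertical (0 deg) and at least one angle away from
        the magic angle on each information side.
    lifetimes
        Fixed fluorophore decay model (not altered by the fit).
    G
        Instrument polarization correction factor.
    fit_scales
        When False (default) a single common acquisition scale is shared by
        all curves, enforcing the strict intensity ratios of the polarized
        law — the measured G factor is what carries the channel-throughput
        correction. Fitting one scale per curve instead (True) opens a
        near-degeneracy between the VH/VV scale ratio and the limiting
        anisotropy and is intended only for diagnosing G-factor problems.
    """
    if G <= 0:
        raise ValueError(f"G must be > 0, got {G}")
    thetas = []
    for d in decays:
        th = d.meta.get("polarizer_deg")
        if th is None:
            raise ValueError("every decay needs polarizer_deg metadata")
        thetas.append(float(th))
    distinct = sorted(set(round(t, 6) for t in thetas))
    if len(distinct) < 2 or not any(abs(t) < 1e-6 for t in distinct):
        raise ValueError(
            "at least 2 distinct polarizer angles including 0 deg are required"
        )
    geoms = np.array([3.0 * np.cos(np.radians(t)) ** 2 - 1.0 for t in thetas])
    if np.all(np.abs(geoms) < _MAGIC_GEOM_TOL):
        raise ValueError(
            "anisotropy parameters are unidentifiable from magic-angle data only"
        )

    grid = decays[0].grid
    for d in decays:
        if d.grid != grid or irf.grid != grid:
            raise ValueError("all decays and the IRF must share one time grid")
    t = grid.times - grid.t_start
    n = grid.n_bins
    kernel = irf.normalized
    times = grid.times
    if window is None:
        t_lo = times[int(np.argmax(irf.counts))] - 0.5
        t_hi = times[-1]
    else:
        t_lo, t_hi = window
    mask = (times >= t_lo) & (times <= t_hi)
    if not mask.any():
        raise ValueError("fit window does not overlap the grid")

    taus = np.asarray(lifetimes.lifetimes)
    rel_amps = np.asarray(lifetimes.amplitudes)
    rel_amps = rel_amps / rel_amps.sum()
    ys = [d.counts.astype(float)[mask] for d in decays]
    ws = [1.0 / np.sqrt(np.maximum(y, 1.0)) for y in ys]
    k3s = [polarizer_factor(th, G) for th in thetas]

    def curve_bases(B: float, phi: float, r_inf: float) -> list[np.ndarray]:
        """Per-curve design matrices of IRF-convolved component bases."""
        exp_tau = np.exp(-t[None, :] / taus[:, None])  # (n_comp, n)
        out = []
        for geom, k3 in zip(geoms, k3s):
            bracket = 1.0 + geom * (B * np.exp(-t / phi) + r_inf)
            ideal = exp_tau * bracket[None, :] * k3
            conv = fftconvolve(ideal, kernel[None, :], axes=1)[:, :n]
            out.append(np.clip(conv.T[mask], 0.0, None))  # (n_win, n_comp)
        return out

    def solve_linear(bases: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        """Shared amplitudes + per-curve scales by alternating closed forms."""
        amps = rel_amps.copy()
        scales = np.ones(len(bases))
        for _ in range(60):
            prev = (amps.copy(), scales.copy())
            if fit_scales:
                for j, D in enumerate(bases):
                    m = D @ amps
                    wm = ws[j] * m
                    denom = wm @ wm
                    scales[j] = (wm @ (ws[j] * ys[j])) / denom if denom > 0 else 1.0
            else:
                # one common scale, absorbed into the amplitudes
                scales[:] = 1.0
            A_rows = np.vstack(
                [s * (ws[j][:, None] * D) for j, (D, s) in enumerate(zip(bases, scales))]
            )
            y_rows = np.concatenate([w * y for w, y in zip(ws, ys)])
            amps, _ = nnls(A_rows, y_rows)
            if amps.sum() <= 0:
                amps = rel_amps.copy()
                break
            if fit_scales:
                # fix the gauge: first curve's scale is 1
                g = scales[0] if scales[0] > 0 else 1.0
                scales /= g
                amps *= g
            if (
                np.allclose(amps, prev[0], rtol=1e-12, atol=1e-15)
                and np.allclose(scales, prev[1], rtol=1e-12, atol=1e-15)
            ):
                break
        return amps, scales

    def residual_fun(x: np.ndarray) -> np.ndarray:
        B, logphi, r_inf = x
        bases = curve_bases(B, np.exp(logphi), r_inf)
        amps, scales = solve_linear(bases)
        res = [
            (y - s * (D @ amps)) * w
            for y, w, D, s in zip(ys, ws, bases, scales)
        ]
        return np.concatenate(res)

    bounds = (
        np.array([-0.1, np.log(grid.dt / 2.0), -0.2]),
        np.array([0.45, np.log(grid.span * 2.0), 0.4]),
    )
    best = None
    for phi0 in (0.3, 1.0, 3.0):
        x0 = np.array([0.15, np.log(phi0), 0.05])
        res = least_squares(
            residual_fun, x0, bounds=bounds, method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        if best is None or res.cost < best.cost:
            best = res

    B, phi, r_inf = best.x[0], float(np.exp(best.x[1])), best.x[2]
    bases = curve_bases(B, phi, r_inf)
    amps, scales = solve_linear(bases)
    resid = residual_fun(best.x)
    n_free = 3 + len(taus) + (len(decays) - 1 if fit_scales else 0)
    dof = max(resid.size - n_free, 1)
    phi_unconstrained = abs(B) < 0.005
    if phi_unconstrained:
        warnings.warn(
            "anisotropy decay amplitude B ~ 0: phi is unconstrained",
            stacklevel=2,
        )
    aniso = AnisotropyModel(B=float(B), phi=phi, r_inf=float(r_inf), G=G)
    return AnisotropyFitResult(
        aniso=aniso,
        lifetimes_used=lifetimes,
        per_curve_scale=tuple(float(s) for s in scales),
        reduced_chi2=float(resid @ resid) / dof,
        amplitudes=tuple(float(a) for a in amps),
        phi_unconstrained=phi_unconstrained,
        residuals=resid,
    )
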