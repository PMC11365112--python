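"""Iterative-reconvolution fitting of TCSPC photon-count histograms.

The empirical stage behind every downstream analysis: a 1-3 exponential decay
law is convolved with the measured IRF (allowing a small temporal shift) and
matched to the counts by Neyman-weighted least squares. Amplitudes and the
constant background enter linearly and are solved by non-negative least
squares at every objective evaluation (variable projection); only the
lifetimes and the IRF shift are handled by the nonlinear optimizer, which
makes the fits fast and insensitive to amplitude initialization.

Also provides noise-free decay reconstruction from a fit and the generic
support-plane (NSSR) confidence procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares, nnls
from scipy.signal import fftconvolve

from .core_model import InstrumentResponse, MultiExpModel, TimeGrid, multiexp_intensity
from .synthetic import DecayHistogram

__all__ = [
    "DecayFitResult",
    "NSSRProfile",
    "fit_multiexp_reconvolution",
    "reconstruct_decay",
    "support_plane_nssr",
]

_SHIFT_BOUND_BINS = 5.0  # IRF temporal alignment freedom, +/- bins
_MERGE_REL_TOL = 0.05  # components closer than 5% in lifetime are merged


@dataclass(frozen=True)
class DecayFitResult:
    """Result of one reconvolution fit.

    ``signed_amplitudes`` is set only for fits run without the
    non-negativity constraint (per-wavelength TRES fits, where red-edge rise
    components carry negative pre-exponentials); it is aligned with
    ``model.lifetimes`` and is what reconstruction uses when present. The
    ``model`` field always satisfies the non-negative total-intensity
    invariants (negative parts clipped to zero).
    """

    model: MultiExpModel
    irf_shift: float  # ns
    background: float  # counts per bin
    scale: float
    reduced_chi2: float
    residuals: np.ndarray = field(repr=False)  # weighted, over the fit window
    converged: bool
    window: tuple[float, float]  # ns
    meta: dict = field(default_factory=dict)
    signed_amplitudes: tuple[float, ...] | None = None


@dataclass(frozen=True)
class NSSRProfile:
    """Support-plane profile of normalized SSR over one scanned parameter."""

    parameter: str
    grid: np.ndarray = field(repr=False)
    nssr: np.ndarray = field(repr=False)
    cutoff: float
    interval: tuple[float, float]
    open_low: bool = False
    open_high: bool = False


def _shifted_kernel(irf: InstrumentResponse, shift_bins: float) -> np.ndarray:
    """Unit-sum IRF kernel displaced by a (fractional) number of bins."""
    k = irf.normalized
    if shift_bins == 0.0:
        return k
    idx = np.arange(k.size, dtype=float)
    return np.interp(idx - shift_bins, idx, k, left=0.0, right=0.0)


def _exp_bases(taus: np.ndarray, t: np.ndarray, kernel: np.ndarray, n: int) -> np.ndarray:
    """IRF-convolved unit-amplitude exponential bases, shape (n_bins, n_comp)."""
    bases = np.exp(-t[None, :] / taus[:, None])
    conv = fftconvolve(bases, kernel[None, :], axes=1)[:, :n]
    return np.clip(conv.T, 0.0, None)


def _resolve_window(
    decay: DecayHistogram, irf: InstrumentResponse, window: tuple[float, float] | None
) -> tuple[np.ndarray, tuple[float, float]]:
    times = decay.grid.times
    if window is None:
        t_lo = times[int(np.argmax(irf.counts))] - 0.5
        t_hi = times[-1]
    else:
        t_lo, t_hi = float(window[0]), float(window[1])
    mask = (times >= t_lo) & (times <= t_hi)
    if not mask.any():
        raise ValueError(f"fit window [{t_lo}, {t_hi}] ns does not overlap the grid")
    return mask, (t_lo, t_hi)


def _merge_close_components(amps: np.ndarray, taus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(taus)
    amps, taus = amps[order], taus[order]
    out_a, out_t = [amps[0]], [taus[0]]
    for a, tau in zip(amps[1:], taus[1:]):
        if (tau - out_t[-1]) / tau < _MERGE_REL_TOL:
            total = out_a[-1] + a
            if total > 0:
                out_t[-1] = (out_a[-1] * out_t[-1] + a * tau) / total
            out_a[-1] = total
        else:
            out_a.append(a)
            out_t.append(tau)
    return np.asarray(out_a), np.asarray(out_t)


def fit_multiexp_reconvolution(
    decay: DecayHistogram,
    irf: InstrumentResponse,
    n_components: int,
    init: Sequence[float] | None = None,
    fixed: dict | None = None,
    window: tuple[float, float] | None = None,
    n_starts: int = 5,
    lifetime_bounds: Sequence[tuple[float, float] | None] | None = None,
    mle: bool = False,
    nonneg: bool = True,
) -> DecayFitResult:
    """Fit a 1-3 exponential decay by iterative reconvolution.

    Parameters
    ----------
    decay, irf
        Histogram and IRF sharing one time grid.
    n_components
        Number of exponential components (1-3; the empirical analyses cap at
        a tri-exponential law).
    init
        Optional lifetime initialization (ns). When given, a single start is
        used; otherwise ``n_starts`` deterministic log-spaced lifetime sets
        are tried and the best objective kept.
    fixed
        Optional pins: ``{"lifetimes": (0.4, None)}`` pins individual
        lifetimes (None = free); ``{"background": 0.0}`` pins the constant
        background.
    window
        Fit window (t_lo, t_hi) in ns. Default: from 0.5 ns before the IRF
        maximum to the end of the grid.
    lifetime_bounds
        Optional per-component (lo, hi) bounds in ns for the free lifetimes.
    mle
        Use Poisson-deviance residuals instead of the default Neyman
        weighting (sigma^2 = max(counts, 1)).
    nonneg
        Constrain amplitudes (and background) to be non-negative (default,
        appropriate for total-intensity decays). Per-wavelength spectral
        fits pass False: decays on the red edge of a relaxing band rise
        before they fall, which needs negative pre-exponentials.

    Notes
    -----
    Amplitudes and background are solved by non-negative linear least squares
    within every objective evaluation; the IRF temporal shift is a free
    parameter bounded to +/-5 bins. Lifetimes within 5% of each other are
    merged in the reported model. Non-convergence is flagged on the result,
    not raised.
    """
    if n_components not in (1, 2, 3):
        raise ValueError(f"n_components must be 1, 2 or 3, got {n_components}")
    if decay.grid != irf.grid:
        raise ValueError("decay and IRF must share one time grid")
    fixed = dict(fixed or {})
    grid = decay.grid
    t = grid.times - grid.t_start
    n = grid.n_bins
    counts = decay.counts.astype(float)
    mask, window_ns = _resolve_window(decay, irf, window)
    y = counts[mask]
    w = 1.0 / np.sqrt(np.maximum(y, 1.0))

    pins = list(fixed.get("lifetimes", (None,) * n_components))
    if len(pins) != n_components:
        raise ValueError("fixed lifetimes must have length n_components")
    free_idx = [i for i, p in enumerate(pins) if p is None]
    bg_fixed = fixed.get("background", None)

    tau_lo = max(2.0 * grid.dt, 1e-3)
    tau_hi = grid.span
    if lifetime_bounds is None:
        lifetime_bounds = [None] * n_components
    lo_b = np.array(
        [lifetime_bounds[i][0] if lifetime_bounds[i] else tau_lo for i in free_idx]
    )
    hi_b = np.array(
        [lifetime_bounds[i][1] if lifetime_bounds[i] else tau_hi for i in free_idx]
    )

    def assemble_taus(x_free: np.ndarray) -> np.ndarray:
        taus = np.empty(n_components)
        for i, p in enumerate(pins):
            taus[i] = p if p is not None else np.nan
        taus[free_idx] = np.exp(x_free)
        return taus

    def design(taus: np.ndarray, shift: float) -> np.ndarray:
        kernel = _shifted_kernel(irf, shift)
        D = _exp_bases(taus, t, kernel, n)[mask]
        if bg_fixed is None:
            D = np.column_stack([D, np.ones(D.shape[0])])
        return D

    def solve_linear(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        target = y if bg_fixed is None else y - bg_fixed
        if nonneg:
            coef, _ = nnls(D * w[:, None], target * w)
        else:
            # truncated SVD: near-degenerate lifetime pairs otherwise yield
            # huge cancelling amplitudes whose extrapolation is unstable
            coef, *_ = np.linalg.lstsq(D * w[:, None], target * w, rcond=1e-8)
        fit = D @ coef + (bg_fixed or 0.0)
        return coef, fit

    def residual_fun(x: np.ndarray) -> np.ndarray:
        taus = assemble_taus(x[:-1])
        D = design(taus, x[-1])
        _, fit = solve_linear(D)
        if mle:
            m = np.maximum(fit, 1e-12)
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(y > 0, y * np.log(y / m), 0.0)
            dev = 2.0 * (m - y + term)
            return np.sign(y - m) * np.sqrt(np.maximum(dev, 0.0))
        return (y - fit) * w

    if init is not None:
        starts = [np.asarray(init, dtype=float)[free_idx]]
    else:
        base_lo = np.maximum(lo_b, max(2.0 * grid.dt, 0.05))
        base_hi = np.minimum(hi_b, tau_hi / 3.0)
        base_hi = np.maximum(base_hi, base_lo * 1.5)
        factors = np.geomspace(0.5, 2.0, max(n_starts, 1))
        starts = []
        for fct in factors:
            s = np.geomspace(base_lo.min(), base_hi.max(), max(len(free_idx), 1)) * fct
            starts.append(np.clip(s, lo_b, hi_b))

    best = None
    x_bounds = (
        np.concatenate([np.log(lo_b), [-_SHIFT_BOUND_BINS]]),
        np.concatenate([np.log(hi_b), [_SHIFT_BOUND_BINS]]),
    )
    for s0 in starts:
        x0 = np.concatenate([np.log(np.clip(s0, lo_b, hi_b)), [0.0]])
        x0 = np.clip(x0, x_bounds[0] + 1e-9, x_bounds[1] - 1e-9)
        try:
            res = least_squares(
                residual_fun, x0, bounds=x_bounds, method="trf",
                xtol=1e-10, ftol=1e-10, gtol=1e-10,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        raise RuntimeError("all optimization starts failed")

    taus = assemble_taus(best.x[:-1])
    shift = float(best.x[-1])
    D = design(taus, shift)
    coef, fit = solve_linear(D)
    if bg_fixed is None:
        amps, background = coef[:-1], float(coef[-1])
    else:
        amps, background = coef, float(bg_fixed)
    signed: tuple[float, ...] | None = None
    if nonneg:
        if not np.any(amps > 0):  # pathological all-zero NNLS solution
            amps = np.full_like(amps, 1e-12)
        amps_m, taus_m = _merge_close_components(amps, taus)
        keep = amps_m > 0
        if not keep.any():
            keep = np.ones_like(amps_m, dtype=bool)
            amps_m = np.maximum(amps_m, 1e-12)
        model = MultiExpModel(tuple(amps_m[keep]), tuple(taus_m[keep]))
    else:
        # keep signed components intact (no merging); the model field holds
        # the non-negative projection for invariant-safe reporting
        order = np.argsort(taus)
        amps, taus = amps[order], taus[order]
        signed = tuple(float(a) for a in amps)
        pos = np.clip(amps, 0.0, None)
        if not np.any(pos > 0):
            pos = np.abs(amps)
        model = MultiExpModel(tuple(np.maximum(pos, 0.0)), tuple(taus))

    n_free = (
        len(amps)
        + len(free_idx)
        + 1  # shift
        + (1 if bg_fixed is None else 0)
    )
    resid = (y - fit) * w
    dof = max(y.size - n_free, 1)
    red_chi2 = float(resid @ resid) / dof
    return DecayFitResult(
        model=model,
        irf_shift=shift * grid.dt,
        background=background,
        scale=1.0,
        reduced_chi2=red_chi2,
        residuals=resid,
        converged=bool(best.status > 0),
        window=window_ns,
        meta=dict(decay.meta),
        signed_amplitudes=signed,
    )


def reconstruct_decay(result: DecayFitResult, grid: TimeGrid) -> np.ndarray:
    """Evaluate the fitted decay law on a grid — no IRF, no background.

    This is the "deconvoluted" noise-free F(t) used by the TRES and quenching
    stages. Refuses unconverged fits: their parameters are not meaningful.
    """
    if not result.converged:
        raise ValueError(
            "refusing to reconstruct from an unconverged fit; re-fit with "
            "different initialization or a wider window"
        )
    t = grid.times - grid.t_start
    if result.signed_amplitudes is not None:
        amps = np.asarray(result.signed_amplitudes)
        taus = np.asarray(result.model.lifetimes)
        return np.sum(amps[:, None] * np.exp(-t[None, :] / taus[:, None]), axis=0)
    return np.asarray(multiexp_intensity(result.model, t))


def support_plane_nssr(
    objective: Callable[[float], float],
    best_sse: float,
    grid: np.ndarray,
    cutoff: float = 1.5,
    parameter: str = "parameter",
) -> NSSRProfile:
    """Support-plane confidence profile for one parameter.

    ``objective(trial)`` must return the SSR with the scanned parameter
    pinned at ``trial`` and all other parameters re-optimized. The profile is
    the ratio SSR(trial)/best_sse; the confidence interval collects trials
    with NSSR <= cutoff (default 1.5), with endpoints located by linear
    interpolation between the grid points straddling the cutoff. A side on
    which the cutoff is never crossed is reported at the grid bound with an
    open-interval flag.
    """
    if cutoff <= 1.0:
        raise ValueError("cutoff must exceed 1")
    if best_sse <= 0:
        raise ValueError("best_sse must be positive")
    grid = np.asarray(grid, dtype=float)
    nssr = np.array([objective(v) for v in grid]) / best_sse
    i0 = int(np.argmin(nssr))
    if nssr[i0] > 1.0 + 1e-6:
        warnings.warn(
            "NSSR minimum on the scan grid exceeds 1; the grid may not span "
            "the best-fit value",
            stacklevel=2,
        )

    def _cross(i_from: int, step: int) -> tuple[float, bool]:
        i = i0
        while 0 <= i + step < grid.size:
            j = i + step
            if nssr[j] > cutoff:
                # linear interpolation between (grid[i], nssr[i]) and j
                frac = (cutoff - nssr[i]) / (nssr[j] - nssr[i])
                return float(grid[i] + frac * (grid[j] - grid[i])), False
            i = j
        return float(grid[0 if step < 0 else -1]), True

    lo, open_low = _cross(i0, -1)
    hi, open_high = _cross(i0, +1)
    return NSSRProfile(
        parameter=parameter,
        grid=grid,
        nssr=nssr,
        cutoff=cutoff,
        interval=(lo, hi),
        open_low=open_low,
        open_high=open_high,
    )
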