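"""Two-step global Stern-Volmer analysis of collisional quenching.

Step 1: every decay of an acrylamide titration is fitted empirically by
tri-exponential reconvolution. Step 2: the reconstructed ("deconvoluted")
noise-free decays are fitted globally to F_q(t) = F0(t) exp(-t kq [Q]) with
F0(t) — the reconstructed zero-quencher decay — held fixed and only the
apparent quenching rate constant kq adjusted. kq is apparent because bulk
quencher concentrations are used: a shielded fluorophore sees a lower local
[Q] and yields a lower kq.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .core_model import InstrumentResponse, MultiExpModel, TimeGrid
from .decay_fitting import DecayFitResult, fit_multiexp_reconvolution, reconstruct_decay
from .synthetic import DecayHistogram

__all__ = ["QuenchFitResult", "fit_quench_series", "quench_relaxation_scatter"]


@dataclass(frozen=True)
class QuenchFitResult:
    """Globally fitted apparent quenching rate constant."""

    kq: float  # ns^-1 M^-1 (apparent)
    F0_model: MultiExpModel
    per_Q_sse: dict
    Q_list: tuple[float, ...]
    step1_fits: tuple[DecayFitResult, ...] = field(repr=False)


def fit_quench_series(
    decays: list[DecayHistogram],
    irf: InstrumentResponse,
    n_components: int = 3,
    window: tuple[float, float] | None = None,
    kq_upper: float = 100.0,
) -> QuenchFitResult:
    """Fit an acrylamide titration for the apparent quenching constant kq.

    Requires at least three concentrations including exactly one [Q] = 0.
    The step-2 objective is unweighted least squares on the reconstructed
    noise-free curves over [0, 5 max(tau)] — the reconstruction step exists
    precisely to escape per-photon weighting. kq is constrained non-negative;
    an unconstrained optimum below zero raises a data-quality warning.
    """
    qs = []
    for d in decays:
        q = d.meta.get("quencher_M")
        if q is None:
            raise ValueError("every decay needs quencher_M metadata")
        qs.append(float(q))
    if len(qs) != len(set(qs)):
        raise ValueError("duplicate quencher concentrations")
    if qs.count(0.0) != 1:
        raise ValueError("the series must contain exactly one [Q] = 0 decay")
    if len(qs) < 3:
        raise ValueError("at least 3 quencher concentrations are required")

    order = np.argsort(qs)
    decays = [decays[i] for i in order]
    qs = [qs[i] for i in order]

    fits: list[DecayFitResult] = []
    init = None
    for d in decays:
        fit = fit_multiexp_reconvolution(
            d, irf, n_components=n_components, init=init, window=window
        )
        if fit.converged and fit.model.n_components == n_components:
            init = fit.model.lifetimes
        fits.append(fit)

    f0_model = fits[0].model
    tau_max = max(f0_model.lifetimes)
    grid = decays[0].grid
    t = np.arange(0.0, 5.0 * tau_max + grid.dt, grid.dt)
    eval_grid = TimeGrid(t_start=0.0, dt=grid.dt, n_bins=t.size)
    f0 = reconstruct_decay(fits[0], eval_grid)
    recon = {
        q: reconstruct_decay(fit, eval_grid)
        for q, fit in zip(qs[1:], fits[1:])
    }

    def sse(kq: float) -> float:
        total = 0.0
        for q, fq in recon.items():
            model = f0 * np.exp(-t * kq * q)
            r = fq - model
            total += float(r @ r)
        return total

    # data-quality check: if SSE is increasing at kq = 0 the unconstrained
    # optimum is negative
    eps = 1e-6
    if sse(eps) > sse(0.0):
        warnings.warn(
            "unconstrained quenching optimum is negative; kq clamped to 0 "
            "(check data quality)",
            stacklevel=2,
        )
        kq_best = 0.0
    else:
        res = minimize_scalar(sse, bounds=(0.0, kq_upper), method="bounded",
                              options={"xatol": 1e-10})
        kq_best = float(res.x)

    per_q = {q: float(np.sum((fq - f0 * np.exp(-t * kq_best * q)) ** 2))
             for q, fq in recon.items()}
    return QuenchFitResult(
        kq=kq_best,
        F0_model=f0_model,
        per_Q_sse=per_q,
        Q_list=tuple(qs),
        step1_fits=tuple(fits),
    )


def quench_relaxation_scatter(
    points: list[tuple[float, float]]
) -> tuple[float, float, float]:
    """Ordinary least-squares line through (x, y) condition points.

    Used for the exposure-vs-relaxation correlation (apparent kq against the
    limiting relaxation level nu_inf across peptides/conditions). Returns
    (slope, intercept, R^2).
    """
    if len(points) < 3:
        raise ValueError("at least 3 points are required")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("slope undefined: all x values identical")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    ss_res = float(np.sum((y - slope * x - intercept) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, intercept, r2
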