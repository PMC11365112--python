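"""Membrane partitioning and calcein-leakage analysis.

Covers the endpoint leakage quantification from two-lifetime calcein decays,
the global steady-state partition-titration fit with support-plane (NSSR)
confidence intervals on Kd, the bound fraction / bound peptide-to-lipid mole
ratio, and the partition-weighted decomposition of any observable (r_inf,
nu_inf, tau_av, phi, t_relax) into its aqueous and membrane-bound endpoint
values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .core_model import InstrumentResponse, MultiExpModel
from .decay_fitting import DecayFitResult, NSSRProfile, fit_multiexp_reconvolution, support_plane_nssr
from .synthetic import DecayHistogram

__all__ = [
    "CalceinFit",
    "PartitionFit",
    "PartitionWeightedFit",
    "leakage",
    "leakage_band",
    "fit_calcein_decay",
    "bound_fraction",
    "bound_mole_ratio",
    "fit_partition_titration",
    "fit_partition_weighted",
]

logger = logging.getLogger(__name__)

#: Default empirical static-quenching correction factor (+/- 0.2).
Q_STAT_DEFAULT = 1.2
#: Default support-plane cutoff on the normalized sum of squared residuals.
NSSR_CUTOFF_DEFAULT = 1.5

OBSERVABLE_NAMES = ("r_inf", "nu_inf", "tau_av", "phi", "t_relax")


@dataclass(frozen=True)
class CalceinFit:
    """Two-component calcein decay amplitudes and the derived leakage."""

    B_F: float
    B_E: float
    B_F0: float
    Q_stat: float
    L: float
    fit: DecayFitResult = field(repr=False)


@dataclass(frozen=True)
class PartitionFit:
    """Global partition-titration fit: shared K, per-wavelength endpoints."""

    K: float  # uM^-1
    Kd: float  # uM, = 1/K exactly
    endpoints: dict  # wavelength -> (I_W0, I_W100)
    nssr: NSSRProfile
    wavelengths: tuple[float, ...]
    sse: float


@dataclass(frozen=True)
class PartitionWeightedFit:
    """Aqueous/membrane endpoint decomposition of one observable."""

    observable: str
    p_aq: float
    p_m: float
    Kd_fixed: float
    residuals: np.ndarray = field(repr=False)
    stderr: tuple[float, float] = (np.nan, np.nan)


def leakage(
    B_F: float, B_F0: float, B_E: float, Q_stat: float = Q_STAT_DEFAULT
) -> float:
    """Calcein leakage fraction L = (B_F - B_F0) / ((B_F - B_F0) + QStat B_E).

    B_F and B_E are the free and entrapped decay amplitudes; B_F0 the free
    baseline from the no-peptide control; Q_stat corrects for static
    quenching of the entrapped amplitude. The result is clamped to [0, 1]
    (a logged event) — noise can push the raw ratio out of range.
    """
    if min(B_F, B_F0, B_E) < 0:
        raise ValueError("amplitudes must be non-negative")
    if Q_stat <= 0:
        raise ValueError("Q_stat must be > 0")
    num = B_F - B_F0
    denom = num + Q_stat * B_E
    if num == 0 and B_E == 0:
        raise ValueError("leakage undefined: no released and no entrapped signal")
    if denom == 0:
        # num < 0 exactly cancelling the entrapped term
        logger.warning("leakage denominator zero; clamping L to 0")
        return 0.0
    raw = num / denom
    if raw < 0.0 or raw > 1.0:
        logger.warning("leakage %.4f outside [0, 1]; clamped", raw)
    return float(np.clip(raw, 0.0, 1.0))


def leakage_band(
    B_F: float,
    B_F0: float,
    B_E: float,
    Q_stat: float = Q_STAT_DEFAULT,
    Q_stat_err: float = 0.2,
) -> tuple[float, float, float]:
    """Leakage with its Q_stat uncertainty band (L is monotone in Q_stat).

    Returns (L_low, L, L_high) evaluated at Q_stat + err, Q_stat, and
    Q_stat - err.
    """
    lo = leakage(B_F, B_F0, B_E, Q_stat + Q_stat_err)
    mid = leakage(B_F, B_F0, B_E, Q_stat)
    hi = leakage(B_F, B_F0, B_E, max(Q_stat - Q_stat_err, 1e-9))
    return lo, mid, hi


def fit_calcein_decay(
    decay: DecayHistogram,
    irf: InstrumentResponse,
    tau_entrapped_bounds: tuple[float, float] = (0.2, 0.8),
    tau_free_bounds: tuple[float, float] = (3.0, 5.0),
    window: tuple[float, float] | None = None,
) -> tuple[float, float, MultiExpModel]:
    """Two-component reconvolution fit of a calcein decay.

    The entrapped (self-quenched) component is sought near 0.4 ns and the
    free component near 4 ns; amplitudes are mapped by lifetime ordering
    (long = free). Raises if the fitted lifetimes collapse onto each other
    (ratio < 1.5), i.e. the two populations are unresolved.

    Returns (B_F, B_E, fitted model).
    """
    init = (
        float(np.sqrt(tau_entrapped_bounds[0] * tau_entrapped_bounds[1])),
        float(np.sqrt(tau_free_bounds[0] * tau_free_bounds[1])),
    )
    fit = fit_multiexp_reconvolution(
        decay,
        irf,
        n_components=2,
        init=init,
        lifetime_bounds=[tau_entrapped_bounds, tau_free_bounds],
        window=window,
    )
    model = fit.model
    if model.n_components == 2:
        if model.lifetimes[1] / model.lifetimes[0] < 1.5:
            raise ValueError(
                "calcein components unresolved: fitted lifetimes "
                f"{model.lifetimes} differ by less than a factor 1.5"
            )
        B_E, B_F = model.amplitudes
    else:
        # one amplitude fell to zero: the sample is all-free or all-entrapped
        tau = model.lifetimes[0]
        if tau >= tau_free_bounds[0]:
            B_E, B_F = 0.0, model.amplitudes[0]
        else:
            B_E, B_F = model.amplitudes[0], 0.0
    return float(B_F), float(B_E), model


def bound_fraction(c_L: float, Kd: float) -> float:
    """Membrane-bound peptide fraction X = (cL/Kd) / (1 + cL/Kd).

    Strictly increasing in the lipid concentration c_L; 0 at c_L = 0 and
    half-saturated at c_L = Kd.
    """
    if Kd <= 0:
        raise ValueError("Kd must be > 0")
    if c_L < 0:
        raise ValueError("c_L must be non-negative")
    x = c_L / Kd
    return x / (1.0 + x)


def bound_mole_ratio(c_P: float, c_L: float, Kd: float) -> float:
    """Bound peptide-to-lipid mole ratio Rb = X(c_L, Kd) * c_P / c_L.

    The local peptide density within the membrane: total peptide c_P scaled
    by its bound fraction, per lipid.
    """
    if c_L == 0:
        raise ZeroDivisionError(
            "Rb undefined at c_L = 0; the bound fraction alone "
            "(bound_fraction) is 0 there"
        )
    if c_P < 0:
        raise ValueError("c_P must be non-negative")
    return bound_fraction(c_L, Kd) * c_P / c_L


def _partition_sse_for_K(
    K: float, cL: np.ndarray, table: dict[float, np.ndarray]
) -> tuple[float, dict]:
    """SSR at fixed K with per-wavelength endpoints re-optimized (linear)."""
    x = K * cL / (1.0 + K * cL)
    design = np.column_stack([1.0 - x, x])  # columns: I_W0, I_W100
    sse = 0.0
    endpoints = {}
    for lam, values in table.items():
        coef, res, _, _ = np.linalg.lstsq(design, values, rcond=None)
        fit = design @ coef
        sse += float(np.sum((values - fit) ** 2))
        endpoints[lam] = (float(coef[0]), float(coef[1]))
    return sse, endpoints


def fit_partition_titration(
    intensity_table,
    nssr_cutoff: float = NSSR_CUTOFF_DEFAULT,
    nssr_points: int = 81,
) -> PartitionFit:
    """Global fit of a steady-state intensity titration for K (and Kd = 1/K).

    ``intensity_table`` is a long DataFrame with columns wavelength_nm,
    lipid_uM, intensity: corrected intensities I'_W per wavelength and lipid
    concentration. K is shared globally across wavelengths; each wavelength
    keeps free endpoints (intensity at zero and complete binding). The
    support-plane NSSR profile over Kd (81 log-spaced trials spanning a
    factor 10 either side of the optimum, cutoff 1.5) is attached.
    """
    df = intensity_table
    lams = np.sort(df["wavelength_nm"].unique())
    cLs = np.sort(df["lipid_uM"].unique())
    if lams.size < 2:
        raise ValueError("at least 2 wavelengths are required for a global fit")
    if cLs.size < 4 or 0.0 not in cLs:
        raise ValueError(
            "at least 4 lipid concentrations including 0 are required"
        )
    table = {}
    for lam in lams:
        sub = df[df["wavelength_nm"] == lam].sort_values("lipid_uM")
        if not np.array_equal(sub["lipid_uM"].to_numpy(), cLs):
            raise ValueError(f"wavelength {lam} nm misses some lipid concentrations")
        table[float(lam)] = sub["intensity"].to_numpy(dtype=float)
    all_values = np.concatenate(list(table.values()))
    if np.allclose(all_values, all_values[0]):
        raise ValueError("all intensities identical: K is unidentifiable")

    def sse_logK(logK: float) -> float:
        return _partition_sse_for_K(10.0 ** logK, cLs, table)[0]

    res = minimize_scalar(sse_logK, bounds=(-5.0, 2.0), method="bounded",
                          options={"xatol": 1e-10})
    K = float(10.0 ** res.x)
    sse_best, endpoints = _partition_sse_for_K(K, cLs, table)
    Kd = 1.0 / K

    def sse_for_Kd(kd_trial: float) -> float:
        return _partition_sse_for_K(1.0 / kd_trial, cLs, table)[0]

    nssr_grid = np.geomspace(Kd / 10.0, Kd * 10.0, nssr_points)
    profile = support_plane_nssr(
        sse_for_Kd, sse_best, nssr_grid, cutoff=nssr_cutoff, parameter="Kd"
    )
    return PartitionFit(
        K=K,
        Kd=Kd,
        endpoints=endpoints,
        nssr=profile,
        wavelengths=tuple(float(l) for l in lams),
        sse=sse_best,
    )


def fit_partition_weighted(
    values: np.ndarray,
    c_L: np.ndarray,
    Kd_fixed: float,
    sems: np.ndarray | None = None,
    observable: str = "r_inf",
) -> PartitionWeightedFit:
    """Decompose an observable into aqueous and membrane endpoints.

    Fits p_obs(c_L) = X p_m + (1 - X) p_aq with the bound fraction X
    computed from the fixed Kd (taken from the steady-state titration — it
    is never co-fitted, avoiding the K/endpoint degeneracy). Weighted by
    1/sem^2 when per-point standard errors are supplied. The c_L = 0 point
    anchors the aqueous endpoint.
    """
    if Kd_fixed <= 0:
        raise ValueError("Kd_fixed must be > 0")
    if observable not in OBSERVABLE_NAMES:
        raise ValueError(f"observable must be one of {OBSERVABLE_NAMES}")
    c_L = np.asarray(c_L, dtype=float)
    values = np.asarray(values, dtype=float)
    if c_L.size < 3 or 0.0 not in c_L:
        raise ValueError("at least 3 lipid concentrations including 0 are required")
    x = np.array([bound_fraction(c, Kd_fixed) for c in c_L])
    design = np.column_stack([1.0 - x, x])  # columns: p_aq, p_m
    if sems is not None:
        w = 1.0 / np.asarray(sems, dtype=float)
        design_w = design * w[:, None]
        values_w = values * w
    else:
        design_w, values_w = design, values
    coef, _, _, _ = np.linalg.lstsq(design_w, values_w, rcond=None)
    resid = values - design @ coef
    dof = max(c_L.size - 2, 1)
    cov = np.linalg.pinv(design_w.T @ design_w) * float(resid @ resid) / dof
    stderr = tuple(float(s) for s in np.sqrt(np.clip(np.diag(cov), 0.0, None)))
    return PartitionWeightedFit(
        observable=observable,
        p_aq=float(coef[0]),
        p_m=float(coef[1]),
        Kd_fixed=float(Kd_fixed),
        residuals=resid,
        stderr=stderr,
    )
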