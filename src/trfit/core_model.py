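"""Closed-form photophysical forward models for TCSPC analysis.

Everything in this module is deterministic and noise-free: multi-exponential
fluorescence decay laws, the polarized-detection intensity law with its
polarizer matching factor, the monoexponential dipolar-relaxation law for the
spectral center of gravity, and causal discrete convolution with an
instrument response function (IRF).

Units convention: times in ns, angles in degrees, wavenumbers in cm^-1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MAGIC_ANGLE_DEG",
    "TimeGrid",
    "MultiExpModel",
    "AnisotropyModel",
    "RelaxationModel",
    "InstrumentResponse",
    "multiexp_intensity",
    "amplitude_avg_lifetime",
    "polarizer_factor",
    "polarized_intensity",
    "relaxation_curve",
    "convolve_with_irf",
]

#: Magic angle arccos(1/sqrt(3)) in degrees; at this emission-polarizer angle
#: the detected decay is independent of rotational dynamics.
MAGIC_ANGLE_DEG: float = math.degrees(math.acos(1.0 / math.sqrt(3.0)))


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time axis for decay histograms and IRFs.

    Parameters
    ----------
    t_start : float
        Time of the first bin edge (ns).
    dt : float
        Bin width (ns), strictly positive.
    n_bins : int
        Number of bins, at least 2.
    """

    t_start: float
    dt: float
    n_bins: int

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")

    @property
    def times(self) -> np.ndarray:
        """Bin times (ns), uniform by construction."""
        return self.t_start + self.dt * np.arange(self.n_bins)

    @property
    def span(self) -> float:
        return self.dt * (self.n_bins - 1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeGrid):
            return NotImplemented
        return (
            math.isclose(self.t_start, other.t_start, abs_tol=1e-12)
            and math.isclose(self.dt, other.dt, rel_tol=1e-12)
            and self.n_bins == other.n_bins
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass(frozen=True)
class MultiExpModel:
    """Multi-exponential fluorescence decay law F(t) = sum_i A_i exp(-t/tau_i).

    At most three components; lifetimes are stored sorted ascending with the
    amplitudes permuted accordingly.
    """

    amplitudes: tuple[float, ...]
    lifetimes: tuple[float, ...]

    def __post_init__(self) -> None:
        amps = tuple(float(a) for a in self.amplitudes)
        taus = tuple(float(t) for t in self.lifetimes)
        if len(amps) != len(taus):
            raise ValueError("amplitudes and lifetimes must have equal length")
        if not 1 <= len(taus) <= 3:
            raise ValueError("between 1 and 3 components are supported")
        if any(t <= 0 for t in taus):
            raise ValueError("all lifetimes must be > 0")
        if any(a < 0 for a in amps):
            raise ValueError("amplitudes must be non-negative")
        if all(a == 0 for a in amps):
            raise ValueError("at least one amplitude must be positive")
        order = np.argsort(taus)
        object.__setattr__(self, "lifetimes", tuple(taus[i] for i in order))
        object.__setattr__(self, "amplitudes", tuple(amps[i] for i in order))

    @property
    def n_components(self) -> int:
        return len(self.lifetimes)

    @property
    def total_amplitude(self) -> float:
        return float(sum(self.amplitudes))


@dataclass(frozen=True)
class AnisotropyModel:
    """Single-exponential anisotropy decay r(t) = B exp(-t/phi) + r_inf.

    ``G`` is the instrument polarization correction factor entering the
    polarizer matching factor. The fundamental one-photon limit r0 <= 0.4 is
    enforced as a warning only: fit excursions above the physical limit must
    stay visible.
    """

    B: float
    phi: float
    r_inf: float
    G: float = 1.0

    def __post_init__(self) -> None:
        if self.phi <= 0:
            raise ValueError(f"phi must be > 0, got {self.phi}")
        if self.G <= 0:
            raise ValueError(f"G must be > 0, got {self.G}")
        if not -0.2 <= self.r_inf <= 0.4:
            raise ValueError(f"r_inf must lie in [-0.2, 0.4], got {self.r_inf}")
        if self.B + self.r_inf > 0.4:
            warnings.warn(
                f"r0 = B + r_inf = {self.B + self.r_inf:.3f} exceeds the "
                "one-photon fundamental limit 0.4",
                stacklevel=2,
            )

    @property
    def r0(self) -> float:
        """Initial anisotropy B + r_inf (derived, not a fit parameter)."""
        return self.B + self.r_inf


@dataclass(frozen=True)
class RelaxationModel:
    """Dipolar-relaxation law nu(t) = C exp(-t/t_relax) + nu_inf (cm^-1).

    C is the detectable part of the total spectral shift; nu_inf is the
    limiting relaxation level. Fitted C may excurse below zero on data with a
    rising nu(t) trend; this is warned about, not rejected.
    """

    C: float
    t_relax: float
    nu_inf: float

    def __post_init__(self) -> None:
        if self.t_relax <= 0:
            raise ValueError(f"t_relax must be > 0, got {self.t_relax}")
        if self.nu_inf <= 0:
            raise ValueError(f"nu_inf must be > 0, got {self.nu_inf}")
        if self.C < 0:
            warnings.warn(
                f"relaxation amplitude C = {self.C:.1f} cm^-1 is negative "
                "(rising nu(t) trend)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class InstrumentResponse:
    """Measured instrument response function on a uniform time grid."""

    grid: TimeGrid
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (self.grid.n_bins,):
            raise ValueError(
                f"IRF counts shape {counts.shape} does not match grid "
                f"({self.grid.n_bins} bins)"
            )
        if np.any(counts < 0):
            raise ValueError("IRF counts must be non-negative")
        if counts.sum() <= 0:
            raise ValueError("IRF total counts must be positive")
        object.__setattr__(self, "counts", counts)

    @property
    def normalized(self) -> np.ndarray:
        """IRF scaled to unit sum (the convolution kernel)."""
        return self.counts / self.counts.sum()


def multiexp_intensity(model: MultiExpModel, t: float | np.ndarray) -> float | np.ndarray:
    """Evaluate F(t) = sum_i A_i exp(-t/tau_i).

    Strictly decreasing in t; F(0) equals the total amplitude.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    A = np.asarray(model.amplitudes)
    tau = np.asarray(model.lifetimes)
    out = np.sum(A[:, None] * np.exp(-t_arr.ravel()[None, :] / tau[:, None]), axis=0)
    out = out.reshape(t_arr.shape)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def amplitude_avg_lifetime(model: MultiExpModel) -> float:
    """Amplitude-averaged lifetime tau_av = sum A_i tau_i / sum A_i (ns)."""
    total = model.total_amplitude
    if total == 0:
        raise ValueError("invalid model: all amplitudes are zero")
    return float(
        sum(a * t for a, t in zip(model.amplitudes, model.lifetimes)) / total
    )


def polarizer_factor(theta: float, G: float) -> float:
    """Polarized-detection matching factor k(theta)/3 = cos^2(theta) + sin^2(theta)/G.

    Equals 1 at theta = 0 for any G, 1/G at theta = 90 deg, and (2+G)/(3G) at
    the magic angle. ``theta`` in degrees.
    """
    if G <= 0:
        raise ValueError(f"G must be > 0, got {G}")
    rad = math.radians(theta)
    return math.cos(rad) ** 2 + math.sin(rad) ** 2 / G


def polarized_intensity(
    model: MultiExpModel,
    aniso: AnisotropyModel,
    theta: float,
    t: float | np.ndarray,
) -> float | np.ndarray:
    """Polarized fluorescence decay at emission-polarizer angle theta (degrees).

    I(theta, t) = k(theta)/3 * F(t) * [1 + (3 cos^2 theta - 1)(B e^{-t/phi} + r_inf)].
    At the magic angle the bracket is exactly 1 for any anisotropy parameters.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    k3 = polarizer_factor(theta, aniso.G)
    rad = math.radians(theta)
    geom = 3.0 * math.cos(rad) ** 2 - 1.0
    r_t = aniso.B * np.exp(-t_arr / aniso.phi) + aniso.r_inf
    out = k3 * np.asarray(multiexp_intensity(model, t_arr)) * (1.0 + geom * r_t)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def relaxation_curve(model: RelaxationModel, t: float | np.ndarray) -> float | np.ndarray:
    """Center-of-gravity time course nu(t) = C exp(-t/t_relax) + nu_inf (cm^-1)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    out = model.C * np.exp(-t_arr / model.t_relax) + model.nu_inf
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def convolve_with_irf(curve: np.ndarray, irf: InstrumentResponse) -> np.ndarray:
    """Causal discrete convolution of an intensity curve with the IRF.

    The IRF is normalized to unit sum before convolving, so the output total
    equals the input total whenever the full convolution support fits inside
    the grid. Linear convolution with zero padding — no FFT wraparound, so
    decay tails cannot alias into the t ~ 0 region. A delta IRF at bin k
    returns the curve delayed by k bins, zero-padded at the front.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.shape != (irf.grid.n_bins,):
        raise ValueError(
            f"curve shape {curve.shape} does not match the IRF grid "
            f"({irf.grid.n_bins} bins)"
        )
    full = np.convolve(curve, irf.normalized)
    return full[: irf.grid.n_bins]
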