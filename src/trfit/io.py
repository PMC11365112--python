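"""Plain-text file formats and run configuration.

Decay histograms travel in a two-column TSV dialect with ``# key=value``
header lines for acquisition metadata; IRFs use the same layout with float
counts. TRES wavelength series use a long CSV (wavelength_nm, time_ns,
counts); titrations a long CSV (wavelength_nm, lipid_uM, intensity).
Run configurations are YAML with unknown keys rejected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_model import InstrumentResponse, TimeGrid
from .synthetic import META_KEYS, DecayHistogram

__all__ = [
    "read_decay",
    "write_decay",
    "read_irf",
    "write_irf",
    "read_tres_csv",
    "write_tres_csv",
    "read_titration_csv",
    "write_titration_csv",
    "RunConfig",
    "load_config",
]

logger = logging.getLogger(__name__)

_GRID_KEYS = ("dt_ns", "t_start_ns")
_FLOAT_META = {
    "wavelength_nm", "polarizer_deg", "g_factor", "quencher_M", "lipid_uM",
    "background",
}


def _format_header(meta: dict, grid: TimeGrid) -> list[str]:
    lines = [f"# dt_ns={grid.dt!r}", f"# t_start_ns={grid.t_start!r}"]
    for key in sorted(meta):
        lines.append(f"# {key}={meta[key]}")
    return lines


def write_decay(decay: DecayHistogram, path: str | Path) -> None:
    """Write a decay histogram in the TSV dialect (lossless round trip)."""
    path = Path(path)
    lines = _format_header(decay.meta, decay.grid)
    times = decay.grid.times
    for t, c in zip(times, decay.counts):
        lines.append(f"{t:.9f}\t{int(c)}")
    path.write_text("\n".join(lines) + "\n")


def _parse_headers_and_body(
    path: Path, counts_type: str
) -> tuple[dict, np.ndarray, np.ndarray]:
    headers: dict[str, str] = {}
    times, counts = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" not in body:
                raise ValueError(f"{path}:{lineno}: malformed header {line!r}")
            key, _, value = body.partition("=")
            headers[key.strip()] = value.strip()
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected two tab-separated columns"
            )
        try:
            t = float(parts[0])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric time {parts[0]!r}")
        if counts_type == "int":
            try:
                c = int(parts[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: counts must be integers, got {parts[1]!r}"
                )
            if c < 0:
                raise ValueError(f"{path}:{lineno}: negative count {c}")
        else:
            c = float(parts[1])
            if c < 0:
                raise ValueError(f"{path}:{lineno}: negative value {c}")
        times.append(t)
        counts.append(c)
    if len(times) < 2:
        raise ValueError(f"{path}: fewer than 2 data rows")
    return headers, np.asarray(times), np.asarray(counts)


def _grid_from(headers: dict, times: np.ndarray, path: Path) -> TimeGrid:
    diffs = np.diff(times)
    dt_col = float(np.median(diffs))
    if "dt_ns" in headers:
        dt = float(headers["dt_ns"])
    else:
        dt = dt_col
        warnings.warn(
            f"{path}: dt_ns metadata missing; inferred dt = {dt:.6g} ns from "
            "the time column",
            stacklevel=3,
        )
    if np.any(np.abs(diffs - dt) > 1e-6 * dt):
        bad = int(np.argmax(np.abs(diffs - dt))) + 2
        raise ValueError(f"{path}: non-uniform time column near data row {bad}")
    t_start = float(headers.get("t_start_ns", times[0]))
    return TimeGrid(t_start=t_start, dt=dt, n_bins=times.size)


def _meta_from(headers: dict) -> dict:
    meta = {}
    for key, value in headers.items():
        if key in _GRID_KEYS:
            continue
        if key not in META_KEYS:
            raise ValueError(f"unknown metadata key {key!r}")
        meta[key] = float(value) if key in _FLOAT_META else value
    return meta


def read_decay(path: str | Path) -> DecayHistogram:
    """Read a decay histogram from the TSV dialect.

    Malformed lines are reported with their line number; a missing dt_ns
    header is inferred from the (required-uniform) time column with a
    warning.
    """
    path = Path(path)
    headers, times, counts = _parse_headers_and_body(path, "int")
    grid = _grid_from(headers, times, path)
    return DecayHistogram(grid=grid, counts=counts.astype(np.int64),
                          meta=_meta_from(headers))


def write_irf(irf: InstrumentResponse, path: str | Path) -> None:
    """Write an IRF in the TSV dialect (float counts)."""
    path = Path(path)
    lines = _format_header({}, irf.grid)
    for t, c in zip(irf.grid.times, irf.counts):
        lines.append(f"{t:.9f}\t{float(c)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_irf(path: str | Path) -> InstrumentResponse:
    """Read an IRF from the TSV dialect."""
    path = Path(path)
    headers, times, counts = _parse_headers_and_body(path, "float")
    grid = _grid_from(headers, times, path)
    return InstrumentResponse(grid=grid, counts=counts)


def write_tres_csv(histograms: list[DecayHistogram], path: str | Path) -> None:
    """Write a wavelength series as long CSV (wavelength_nm, time_ns, counts)."""
    rows = []
    for h in histograms:
        lam = h.meta.get("wavelength_nm")
        if lam is None:
            raise ValueError("every histogram needs wavelength_nm metadata")
        times = h.grid.times
        rows.append(pd.DataFrame(
            {"wavelength_nm": lam, "time_ns": times, "counts": h.counts}
        ))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_tres_csv(path: str | Path) -> list[DecayHistogram]:
    """Read a long TRES CSV back into per-wavelength decay histograms."""
    df = pd.read_csv(path)
    required = {"wavelength_nm", "time_ns", "counts"}
    if not required.issubset(df.columns):
        raise ValueError(f"TRES CSV must have columns {sorted(required)}")
    out = []
    for lam, sub in df.groupby("wavelength_nm", sort=True):
        sub = sub.sort_values("time_ns")
        times = sub["time_ns"].to_numpy(dtype=float)
        diffs = np.diff(times)
        dt = float(np.median(diffs))
        if np.any(np.abs(diffs - dt) > 1e-6 * dt):
            raise ValueError(f"non-uniform time column at wavelength {lam} nm")
        grid = TimeGrid(t_start=float(times[0]), dt=dt, n_bins=times.size)
        out.append(DecayHistogram(
            grid=grid,
            counts=sub["counts"].to_numpy(dtype=np.int64),
            meta={"wavelength_nm": float(lam)},
        ))
    return out


def write_titration_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a titration table (wavelength_nm, lipid_uM, intensity) as CSV."""
    table.to_csv(path, index=False)


def read_titration_csv(path: str | Path) -> pd.DataFrame:
    """Read a titration CSV, checking the column contract."""
    df = pd.read_csv(path)
    required = {"wavelength_nm", "lipid_uM", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"titration CSV must have columns {sorted(required)}")
    return df


_CONFIG_KEYS = {
    "peptide_id", "seed", "outdir", "environment",
    "grid_span_ns", "grid_bins", "irf_fwhm_ns",
    "peak_counts", "wavelengths_nm", "tres_times_ns",
    "thetas_deg", "g_factor", "quencher_M", "lipid_uM_list",
    "nssr_cutoff", "q_stat", "leak_fraction", "bf0_fraction",
    "noise_cv", "peptide_uM",
    "stages",
}
_STAGE_NAMES = ("decay", "tres", "anisotropy", "quench", "leakage",
                "partition", "decompose")


@dataclass
class RunConfig:
    """Validated configuration of a full synthetic-analysis pipeline run."""

    peptide_id: str = "V4W"
    seed: int | None = None
    outdir: str = "trfit_run"
    environment: str = "m"
    grid_span_ns: float = 50.0
    grid_bins: int = 1024
    irf_fwhm_ns: float = 0.25
    peak_counts: int = 20000
    wavelengths_nm: list = field(default_factory=lambda: list(np.arange(300.0, 391.0, 6.0)))
    tres_times_ns: list = field(default_factory=list)
    thetas_deg: list = field(default_factory=lambda: [0.0, 90.0])
    g_factor: float = 1.1
    quencher_M: list = field(default_factory=lambda: [0.0, 0.1, 0.2, 0.3, 0.4])
    lipid_uM_list: list = field(default_factory=lambda: [0.0, 15.0, 30.0, 60.0, 90.0])
    nssr_cutoff: float = 1.5
    q_stat: float = 1.2
    leak_fraction: float = 0.5
    bf0_fraction: float = 0.05
    noise_cv: float = 0.02
    peptide_uM: float = 6.6
    stages: list = field(default_factory=lambda: list(_STAGE_NAMES))

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config must set an explicit seed")
        unknown = set(self.stages) - set(_STAGE_NAMES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
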