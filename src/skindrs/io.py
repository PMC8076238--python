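"""Spectrum file I/O, band-coverage validation, and provenance stamping.

On-disk convention: two-column delimited text (wavelength_nm, value) with
``#``-prefixed header lines carrying ``key: value`` metadata (at least
``kind`` and ``units``).  Wavelengths are nm everywhere on disk; optical
coefficients are mm^-1.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Spectrum",
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "BandCoverage",
    "validate_band_coverage",
    "ProvenanceStamp",
]

#: wavelength beyond which the NIR spectrometer signal is too noisy to use
NOISY_WAVELENGTH_LIMIT_NM = 1380.0


class SpectrumParseError(ValueError):
    """Raised when a spectrum file violates the two-column text contract."""


@dataclass
class Spectrum:
    """A sampled spectrum: strictly increasing wavelength grid plus values.

    Parameters
    ----------
    wavelength_nm : array of float
        Strictly increasing wavelengths in nanometres.
    values : array of float
        One value per wavelength (reflectance, mu_a in mm^-1, or
        mu_s' in mm^-1 depending on ``kind``).
    kind : str
        Tag identifying the physical quantity, e.g. ``"absorption"``,
        ``"reflectance"``, ``"reduced_scattering"``.
    units : str
        Unit string for the values column.
    """

    wavelength_nm: np.ndarray
    values: np.ndarray
    kind: str = "unknown"
    units: str = ""

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelength_nm.ndim != 1 or self.values.ndim != 1:
            raise ValueError("wavelength and values must be 1-D")
        if self.wavelength_nm.size != self.values.size:
            raise ValueError(
                f"length mismatch: {self.wavelength_nm.size} wavelengths "
                f"vs {self.values.size} values"
            )
        if self.wavelength_nm.size >= 2:
            dw = np.diff(self.wavelength_nm)
            if np.any(dw == 0):
                dup = self.wavelength_nm[:-1][dw == 0][0]
                raise ValueError(f"duplicate wavelength {dup} nm")
            if np.any(dw < 0):
                warnings.warn("wavelengths not sorted; sorting", stacklevel=2)
                order = np.argsort(self.wavelength_nm)
                self.wavelength_nm = self.wavelength_nm[order]
                self.values = self.values[order]

    def __len__(self) -> int:
        return self.wavelength_nm.size

    def interp(self, wavelength_nm: np.ndarray) -> np.ndarray:
        """Linear interpolation of the values onto a new grid (edges held)."""
        return np.interp(np.asarray(wavelength_nm, dtype=float),
                         self.wavelength_nm, self.values)

    def slice_band(self, lo_nm: float, hi_nm: float) -> "Spectrum":
        """Return the sub-spectrum with lo <= wavelength <= hi."""
        m = (self.wavelength_nm >= lo_nm) & (self.wavelength_nm <= hi_nm)
        return Spectrum(self.wavelength_nm[m], self.values[m],
                        kind=self.kind, units=self.units)


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column delimited-text spectrum.

    ``#`` lines are header metadata (``# key: value``).  Non-numeric data
    rows and duplicate wavelengths raise :class:`SpectrumParseError` naming
    the offending line number (1-based).  Unsorted wavelengths are sorted
    with a warning.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    wl: list[float] = []
    vals: list[float] = []
    seen: dict[float, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip().lower()] = val.strip()
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise SpectrumParseError(
                    f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                w = float(parts[0])
                v = float(parts[1])
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric row {line!r}") from exc
            if w in seen:
                raise SpectrumParseError(
                    f"{path}:{lineno}: duplicate wavelength {w} nm "
                    f"(first seen at line {seen[w]})")
            seen[w] = lineno
            wl.append(w)
            vals.append(v)
    if not wl:
        raise SpectrumParseError(f"{path}: no data rows")
    return Spectrum(np.array(wl), np.array(vals),
                    kind=meta.get("kind", "unknown"),
                    units=meta.get("units", ""))


def write_spectrum(spectrum: Spectrum, path: str | Path,
                   extra_header: dict[str, str] | None = None) -> None:
    """Write a spectrum in the two-column text format (full float precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# kind: {spectrum.kind}\n")
        fh.write(f"# units: {spectrum.units}\n")
        for k, v in (extra_header or {}).items():
            fh.write(f"# {k}: {v}\n")
        for w, v in zip(spectrum.wavelength_nm, spectrum.values):
            fh.write(f"{float(w)!r}\t{float(v)!r}\n")


@dataclass
class BandCoverage:
    """Report of how well a spectrum covers an analysis band."""

    band_name: str
    band_lo_nm: float
    band_hi_nm: float
    n_in_band: int
    full_coverage: bool
    gaps: list[tuple[float, float]] = field(default_factory=list)
    beyond_noisy_limit: bool = False


def validate_band_coverage(spectrum: Spectrum, band,
                           max_gap_nm: float = 10.0) -> BandCoverage:
    """Report in-band point count, sampling gaps wider than ``max_gap_nm``,
    and whether the spectrum extends past the noisy >1380 nm region.
    """
    lo, hi = band.lo_nm, band.hi_nm
    wl = spectrum.wavelength_nm
    in_band = wl[(wl >= lo) & (wl <= hi)]
    gaps: list[tuple[float, float]] = []
    if in_band.size == 0:
        gaps.append((lo, hi))
        full = False
    else:
        edges = np.concatenate(([lo], in_band, [hi]))
        for a, b in zip(edges[:-1], edges[1:]):
            if b - a > max_gap_nm:
                gaps.append((float(a), float(b)))
        full = wl.min() <= lo and wl.max() >= hi and not gaps
    return BandCoverage(
        band_name=band.name,
        band_lo_nm=lo,
        band_hi_nm=hi,
        n_in_band=int(in_band.size),
        full_coverage=bool(full),
        gaps=gaps,
        beyond_noisy_limit=bool(wl.max() > NOISY_WAVELENGTH_LIMIT_NM),
    )


def _hash_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()[:16]


def hash_file(path: str | Path) -> str:
    return _hash_bytes(Path(path).read_bytes())


def hash_config(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    return _hash_bytes(json.dumps(obj, sort_keys=True, default=str).encode())


@dataclass
class ProvenanceStamp:
    """Provenance carried by every serialized output."""

    tool_version: str
    config_hash: str
    input_hashes: dict[str, str]
    seeds: dict[str, int]
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")

    def to_dict(self) -> dict:
        return {
            "tool_version": self.tool_version,
            "config_hash": self.config_hash,
            "input_hashes": dict(self.input_hashes),
            "seeds": dict(self.seeds),
            "timestamp": self.timestamp,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "ProvenanceStamp":
        d = json.loads(Path(path).read_text())
        return cls(tool_version=d["tool_version"], config_hash=d["config_hash"],
                   input_hashes=d["input_hashes"], seeds=d["seeds"],
                   timestamp=d.get("timestamp", ""))


def make_stamp(config_obj, inputs: dict[str, str | Path] | None = None,
               seeds: dict[str, int] | None = None) -> ProvenanceStamp:
    from . import __version__
    return ProvenanceStamp(
        tool_version=__version__,
        config_hash=hash_config(config_obj),
        input_hashes={k: hash_file(v) for k, v in (inputs or {}).items()},
        seeds=dict(seeds or {}),
    )
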