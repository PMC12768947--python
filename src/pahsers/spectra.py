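"""Spectrum containers, CSV I/O and the preprocessing chain.

Every spectrum in the package lives on a fixed uniform wavenumber grid
(default 400-2000 cm^-1, 660 points). Preprocessing mirrors common SERS
practice: Savitzky-Golay smoothing, Savitzky-Golay baseline subtraction,
then max-normalization (the scale the neural networks operate on; the raw
maximum is kept as metadata because quantification needs it back).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "WavenumberGrid",
    "Spectrum",
    "SpectrumSet",
    "DEFAULT_GRID",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "sg_smooth",
    "subtract_baseline",
    "max_normalize",
    "preprocess",
    "default_baseline_window",
]


class SpectrumError(ValueError):
    """Raised for malformed spectra, files or degenerate inputs."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform wavenumber axis in cm^-1.

    The default spectral length w = 660 points is the width every model
    input, reference and simulated mixture share.
    """

    start: float = 400.0
    end: float = 2000.0
    n_points: int = 660

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise SpectrumError(f"grid start {self.start} must be < end {self.end}")
        if self.n_points < 2:
            raise SpectrumError("grid needs at least 2 points")

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.start, self.end, self.n_points)

    @property
    def spacing(self) -> float:
        return (self.end - self.start) / (self.n_points - 1)

    def index_of(self, wavenumber: float) -> int:
        """Index of the grid point nearest to *wavenumber*."""
        return int(round((wavenumber - self.start) / self.spacing))

    def contains(self, wavenumber: float) -> bool:
        return self.start <= wavenumber <= self.end


DEFAULT_GRID = WavenumberGrid()


@dataclass
class Spectrum:
    """Intensities (arbitrary units) on a :class:`WavenumberGrid`."""

    grid: WavenumberGrid
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or len(self.intensities) != self.grid.n_points:
            raise SpectrumError(
                f"intensity vector length {self.intensities.shape} does not match "
                f"grid with {self.grid.n_points} points"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise SpectrumError(f"spectrum {self.label!r} contains non-finite values")

    def with_intensities(self, values: np.ndarray, label: str | None = None) -> "Spectrum":
        return Spectrum(self.grid, values, self.label if label is None else label)

    @property
    def max(self) -> float:
        return float(self.intensities.max())


@dataclass
class SpectrumSet:
    """Ordered collection of spectra sharing one grid."""

    spectra: list[Spectrum]
    role: str = "reference"

    def __post_init__(self) -> None:
        if self.spectra:
            grid = self.spectra[0].grid
            for s in self.spectra:
                if s.grid != grid:
                    raise SpectrumError("all spectra in a set must share one grid")

    @property
    def grid(self) -> WavenumberGrid:
        if not self.spectra:
            raise SpectrumError("empty spectrum set has no grid")
        return self.spectra[0].grid

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.spectra]

    def by_label(self, label: str) -> Spectrum:
        for s in self.spectra:
            if s.label == label:
                return s
        raise KeyError(f"no spectrum labelled {label!r}")

    def matrix(self, labels: Sequence[str] | None = None) -> np.ndarray:
        """Stack intensities into an (n, w) matrix, optionally in label order."""
        members = self.spectra if labels is None else [self.by_label(l) for l in labels]
        return np.stack([s.intensities for s in members])

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def save(self, directory: str | Path) -> None:
        """Write one CSV per spectrum plus a JSON manifest of labels/role."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"role": self.role, "spectra": []}
        for i, s in enumerate(self.spectra):
            fname = f"spectrum_{i:04d}.csv"
            write_spectrum_csv(s, directory / fname)
            manifest["spectra"].append({"file": fname, "label": s.label})
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path, grid: WavenumberGrid | None = None) -> "SpectrumSet":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        spectra = []
        for entry in manifest["spectra"]:
            policy = "strict" if grid is None else "resample"
            s = read_spectrum_csv(directory / entry["file"], grid_policy=policy, grid=grid)
            s.label = entry["label"]
            spectra.append(s)
        return cls(spectra, role=manifest.get("role", "reference"))


def read_spectrum_csv(
    path: str | Path,
    grid_policy: str = "strict",
    grid: WavenumberGrid | None = None,
    label: str = "",
) -> Spectrum:
    """Read a two-column (wavenumber, intensity) CSV.

    ``grid_policy='strict'`` keeps the file's own (uniform) grid;
    ``'resample'`` linearly interpolates onto *grid*. A header row is
    tolerated. Non-numeric data rows raise a parse error naming the line.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - I/O failure path
        raise SpectrumError(f"cannot read {path}: {exc}") from exc
    if raw.shape[1] < 2:
        raise SpectrumError(f"{path}: expected two columns (wavenumber, intensity)")
    data = raw.iloc[:, :2].apply(pd.to_numeric, errors="coerce")
    bad = data.isna().any(axis=1)
    # a non-numeric first row is treated as a header, anything later is an error
    start = 1 if bad.iloc[0] else 0
    bad_rows = np.flatnonzero(bad.values[start:])
    if bad_rows.size:
        line = bad_rows[0] + start + 1
        raise SpectrumError(f"{path}: non-numeric value on line {line}")
    values = data.values[start:]
    order = np.argsort(values[:, 0], kind="stable")
    wn, inten = values[order, 0], values[order, 1]
    if np.any(np.diff(wn) <= 0):
        raise SpectrumError(f"{path}: duplicate or non-increasing wavenumbers")

    if grid_policy == "strict":
        file_grid = WavenumberGrid(float(wn[0]), float(wn[-1]), len(wn))
        if not np.allclose(file_grid.values, wn, atol=1e-6 * max(1.0, abs(wn[-1]))):
            raise SpectrumError(f"{path}: wavenumber axis is not uniform; use grid_policy='resample'")
        return Spectrum(file_grid, inten, label=label or path.stem)
    if grid_policy == "resample":
        if grid is None:
            raise SpectrumError("grid_policy='resample' requires a target grid")
        resampled = np.interp(grid.values, wn, inten)
        return Spectrum(grid, resampled, label=label or path.stem)
    raise SpectrumError(f"unknown grid_policy {grid_policy!r}")


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as full-precision two-column CSV."""
    path = Path(path)
    try:
        df = pd.DataFrame(
            {"wavenumber": spectrum.grid.values, "intensity": spectrum.intensities}
        )
        df.to_csv(path, index=False, float_format="%.12g")
    except OSError as exc:
        raise SpectrumError(f"cannot write {path}: {exc}") from exc


def _check_sg_params(window: int, degree: int, n_points: int) -> None:
    if window % 2 == 0:
        raise SpectrumError(f"Savitzky-Golay window must be odd, got {window}")
    if window <= degree:
        raise SpectrumError(f"window ({window}) must exceed polynomial degree ({degree})")
    if window > n_points:
        raise SpectrumError(f"window ({window}) exceeds spectrum length ({n_points})")


def sg_smooth(spectrum: Spectrum, window: int = 5, degree: int = 3) -> Spectrum:
    """Savitzky-Golay smoothing (default span 5, degree 3).

    Edges are handled by fitting the end windows and evaluating the fitted
    polynomial (no padding or wraparound).
    """
    _check_sg_params(window, degree, spectrum.grid.n_points)
    smoothed = savgol_filter(spectrum.intensities, window, degree, mode="interp")
    return spectrum.with_intensities(smoothed)


def default_baseline_window(n_points: int) -> int:
    """Default baseline span: about a third of the spectrum, forced odd."""
    w = max(5, n_points // 3)
    return w + 1 if w % 2 == 0 else w


def subtract_baseline(
    spectrum: Spectrum, window: int | None = None, degree: int = 1
) -> Spectrum:
    """Subtract a degree-1 Savitzky-Golay baseline estimate.

    The window defaults to ~n/3 of the spectrum: wide enough to follow the
    broad background while leaving narrow Raman bands mostly intact.
    """
    if window is None:
        window = default_baseline_window(spectrum.grid.n_points)
    _check_sg_params(window, degree, spectrum.grid.n_points)
    baseline = savgol_filter(spectrum.intensities, window, degree, mode="interp")
    return spectrum.with_intensities(spectrum.intensities - baseline)


def max_normalize(spectrum: Spectrum) -> tuple[Spectrum, float]:
    """Scale to unit maximum; returns (normalized spectrum, original max).

    The original maximum is the metadata quantification later multiplies
    back in. All-nonpositive spectra are rejected rather than divided.
    """
    max_height = spectrum.max
    if max_height <= 0:
        raise SpectrumError(
            f"cannot max-normalize spectrum {spectrum.label!r}: no positive intensity"
        )
    return spectrum.with_intensities(spectrum.intensities / max_height), max_height


def preprocess(
    spectrum: Spectrum,
    smooth_window: int = 5,
    smooth_degree: int = 3,
    baseline_window: int | None = None,
    normalize: bool = True,
) -> tuple[Spectrum, float]:
    """Full chain: smooth, baseline-subtract, max-normalize.

    Returns the processed spectrum and the pre-normalization maximum
    (1.0 when ``normalize=False``).
    """
    s = sg_smooth(spectrum, smooth_window, smooth_degree)
    s = subtract_baseline(s, baseline_window)
    if normalize:
        return max_normalize(s)
    return s, 1.0
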