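"""Synthetic reference library, blanks and "measured" mixture spectra.

No experimental SERS library ships with the package, so this module builds
one with the documented qualitative structure of the five PAH targets:

* PY (pyrene) — dominant ring C=C stretching band at 1241 cm^-1;
* ANT (anthracene) — only three resolvable bands and the weakest response;
* BAP (benzo[a]pyrene) — the richest spectrum, eight bands;
* NP (nitro-pyrene) — no unique bands: every NP band sits within one FWHM
  of a band of some other target;
* PY, NP and ANT all share structure near 1240 and 1400 cm^-1, which is
  what makes the mixtures genuinely overlapped.

Bands are Lorentzian (the usual Raman line shape), FWHM 12 cm^-1 by
default. The concentration response of each target is a Hill/Langmuir
saturation curve h(c) = h_max * c / (K + c): monotone, invertible and a
reasonable stand-in for an adsorption-limited SERS response over the
10 nM - 1 uM calibration range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectra import Spectrum, SpectrumSet, SpectrumError, WavenumberGrid

__all__ = [
    "TARGETS",
    "PeakSpec",
    "ReferenceDefinition",
    "ResponseModel",
    "NoiseConfig",
    "DEFAULT_REFERENCE_DEFINITIONS",
    "DEFAULT_RESPONSE_MODELS",
    "lorentzian",
    "make_reference",
    "default_reference_library",
    "make_blank",
    "simulate_measured_spectrum",
    "ratio_to_concentrations",
]

#: Canonical target order used for every 5-vector in the package.
TARGETS = ("PY", "TP", "NP", "BAP", "ANT")

DEFAULT_FWHM = 12.0  # cm^-1, typical SERS band width


@dataclass(frozen=True)
class PeakSpec:
    """One Lorentzian band: center (cm^-1), FWHM (cm^-1), height relative to the reference max."""

    center: float
    fwhm: float = DEFAULT_FWHM
    rel_height: float = 1.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise SpectrumError(f"peak FWHM must be positive, got {self.fwhm}")
        if not 0 < self.rel_height <= 1:
            raise SpectrumError(f"rel_height must be in (0, 1], got {self.rel_height}")


@dataclass(frozen=True)
class ReferenceDefinition:
    """Peak table for one target's reference spectrum."""

    target: str
    peaks: tuple[PeakSpec, ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise SpectrumError(f"{self.target}: a reference needs at least one peak")
        if sum(1 for p in self.peaks if p.rel_height == 1.0) != 1:
            raise SpectrumError(f"{self.target}: exactly one peak must have rel_height 1")


@dataclass(frozen=True)
class ResponseModel:
    """Hill/Langmuir peak-height response h(c) = h_max * c / (K + c).

    h_max is the saturation height (arbitrary units, the scale the unit-max
    reference is multiplied by); K is the concentration (uM) at half
    saturation.
    """

    target: str
    h_max: float
    K: float

    def __post_init__(self) -> None:
        if self.h_max <= 0 or self.K <= 0:
            raise SpectrumError(f"{self.target}: h_max and K must be positive")

    def height(self, conc: float | np.ndarray) -> float | np.ndarray:
        c = np.asarray(conc, dtype=float)
        if np.any(c < 0):
            raise SpectrumError("concentration must be nonnegative")
        out = self.h_max * c / (self.K + c)
        return float(out) if out.ndim == 0 else out

    def inverse(self, h: float) -> float:
        """Concentration producing height h (h must be below h_max)."""
        if h <= 0:
            return 0.0
        if h >= self.h_max:
            raise SpectrumError(f"height {h} at or above saturation {self.h_max}")
        return self.K * h / (self.h_max - h)


@dataclass(frozen=True)
class NoiseConfig:
    """Stochastic measurement model: additive Gaussian noise (sd as a
    fraction of the spectrum maximum), integer grid shifts, and the broad
    water background amplitude (fraction of unit signal scale)."""

    noise_sd: float = 0.01
    max_shift: int = 2
    background_scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.max_shift < 0 or self.background_scale < 0:
            raise SpectrumError("noise parameters must be nonnegative")

    def silent(self) -> "NoiseConfig":
        """Copy with all stochastic components off (for oracles/round-trips)."""
        return replace(self, noise_sd=0.0, max_shift=0)


# Peak tables for the five targets. Centers other than PY's 1241 cm^-1
# are conventions chosen to satisfy the qualitative constraints above,
# not literature assignments.
DEFAULT_REFERENCE_DEFINITIONS: dict[str, ReferenceDefinition] = {
    "PY": ReferenceDefinition(
        "PY",
        (
            PeakSpec(1241.0, rel_height=1.0),   # dominant ring C=C stretch
            PeakSpec(1404.0, rel_height=0.55),
            PeakSpec(1065.0, rel_height=0.40),
            PeakSpec(1620.0, rel_height=0.35),
            PeakSpec(592.0, rel_height=0.30),
        ),
    ),
    "TP": ReferenceDefinition(
        "TP",
        (
            PeakSpec(1340.0, rel_height=1.0),
            PeakSpec(1060.0, rel_height=0.60),
            PeakSpec(698.0, rel_height=0.50),
            PeakSpec(1600.0, rel_height=0.45),
        ),
    ),
    # every NP band lies within one FWHM of a PY or ANT band (no unique peaks)
    "NP": ReferenceDefinition(
        "NP",
        (
            PeakSpec(1234.0, rel_height=1.0),   # overlaps PY 1241
            PeakSpec(1394.0, rel_height=0.70),  # overlaps ANT 1400 / PY 1404
            PeakSpec(1614.0, rel_height=0.50),  # overlaps PY 1620
            PeakSpec(1072.0, rel_height=0.45),  # overlaps PY 1065 / TP 1060
            PeakSpec(747.0, rel_height=0.30),   # overlaps ANT 755
        ),
    ),
    "BAP": ReferenceDefinition(
        "BAP",
        (
            PeakSpec(1355.0, rel_height=1.0),
            PeakSpec(1138.0, rel_height=0.55),
            PeakSpec(766.0, rel_height=0.50),
            PeakSpec(1518.0, rel_height=0.45),
            PeakSpec(905.0, rel_height=0.40),
            PeakSpec(612.0, rel_height=0.35),
            PeakSpec(1583.0, rel_height=0.35),
            PeakSpec(1310.0, rel_height=0.30),
        ),
    ),
    "ANT": ReferenceDefinition(
        "ANT",
        (
            PeakSpec(1400.0, rel_height=1.0),
            PeakSpec(1244.0, rel_height=0.60),
            PeakSpec(755.0, rel_height=0.45),
        ),
    ),
}

# ANT carries the weakest response (lowest intensities at equal concentration).
# K values put the 10 nM - 1 uM calibration range at roughly 3-75% of saturation.
DEFAULT_RESPONSE_MODELS: dict[str, ResponseModel] = {
    "PY": ResponseModel("PY", h_max=1.00, K=0.30),
    "TP": ResponseModel("TP", h_max=0.90, K=0.35),
    "NP": ResponseModel("NP", h_max=0.85, K=0.30),
    "BAP": ResponseModel("BAP", h_max=0.95, K=0.32),
    "ANT": ResponseModel("ANT", h_max=0.45, K=0.28),
}


def lorentzian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-height Lorentzian profile."""
    hw = fwhm / 2.0
    return hw**2 / ((x - center) ** 2 + hw**2)


def make_reference(defn: ReferenceDefinition, grid: WavenumberGrid) -> Spectrum:
    """Render a peak table into a unit-max reference spectrum."""
    for p in defn.peaks:
        if not grid.contains(p.center):
            raise SpectrumError(
                f"{defn.target}: peak at {p.center} cm^-1 outside grid "
                f"[{grid.start}, {grid.end}]"
            )
    x = grid.values
    y = np.zeros(grid.n_points)
    for p in defn.peaks:
        y += p.rel_height * lorentzian(x, p.center, p.fwhm)
    return Spectrum(grid, y / y.max(), label=defn.target)


def default_reference_library(
    grid: WavenumberGrid | None = None,
    background_scale: float = NoiseConfig().background_scale,
) -> SpectrumSet:
    """The five default unit-max references plus a noiseless drinking-water blank."""
    grid = grid or WavenumberGrid()
    spectra = [make_reference(DEFAULT_REFERENCE_DEFINITIONS[t], grid) for t in TARGETS]
    blank_cfg = NoiseConfig(noise_sd=0.0, max_shift=0, background_scale=background_scale)
    spectra.append(make_blank(grid, blank_cfg))
    return SpectrumSet(spectra, role="reference")


def _background_shape(grid: WavenumberGrid, preset: str) -> np.ndarray:
    """Broad low-order polynomial hump: the water/substrate background."""
    t = (grid.values - grid.start) / (grid.end - grid.start)
    if preset == "drinking":
        shape = 0.5 + 0.8 * t * (1.0 - t) * 4.0 * 0.5 - 0.2 * t
    elif preset == "river":
        # broader and stronger, tilted toward low wavenumbers
        shape = 0.8 + 1.2 * (1.0 - t) * t * (2.0 - t) - 0.1 * t
    else:
        raise SpectrumError(f"unknown background preset {preset!r}")
    return shape / shape.max()


def make_blank(
    grid: WavenumberGrid, cfg: NoiseConfig, preset: str = "drinking"
) -> Spectrum:
    """Water blank: smooth broad background plus Gaussian noise.

    Deterministic for a fixed ``cfg.seed``. The river preset is broader and
    roughly twice as strong as the drinking-water one.
    """
    amplitude = cfg.background_scale * (2.0 if preset == "river" else 1.0)
    y = amplitude * _background_shape(grid, preset)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        y = y + rng.normal(0.0, cfg.noise_sd, grid.n_points)
    return Spectrum(grid, y, label="blank" if preset == "drinking" else f"blank-{preset}")


def simulate_measured_spectrum(
    concs: dict[str, float],
    responses: dict[str, ResponseModel],
    refs: SpectrumSet,
    cfg: NoiseConfig,
    preset: str = "drinking",
    rng: np.random.Generator | None = None,
    label: str = "sample",
) -> Spectrum:
    """Simulate one measured mixture at known concentrations (uM).

    Each target contributes ``responses[t].height(conc) * reference`` on the
    raw (unnormalized) scale; the water background and Gaussian noise are
    added on top.
    """
    grid = refs.grid
    for t, c in concs.items():
        if c < 0:
            raise SpectrumError(f"negative concentration for {t}: {c}")
    y = np.zeros(grid.n_points)
    for t, c in concs.items():
        if c > 0:
            y = y + responses[t].height(c) * refs.by_label(t).intensities
    blank = make_blank(grid, cfg.silent(), preset=preset)
    y = y + blank.intensities
    if cfg.noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        scale = y.max() if y.max() > 0 else 1.0
        y = y + rng.normal(0.0, cfg.noise_sd * scale, grid.n_points)
    return Spectrum(grid, y, label=label)


def ratio_to_concentrations(total: float, ratio) -> np.ndarray:
    """Split a total concentration (uM) among the five targets by ratio.

    ``ratio_to_concentrations(1.0, (5, 2, 1, 1, 1))`` gives
    (0.5, 0.2, 0.1, 0.1, 0.1) uM in the canonical PY, TP, NP, BAP, ANT order.
    """
    ratio = np.asarray(ratio, dtype=float)
    if total < 0:
        raise SpectrumError(f"total concentration must be nonnegative, got {total}")
    if np.any(ratio < 0):
        raise SpectrumError("ratio weights must be nonnegative")
    s = ratio.sum()
    if s <= 0:
        raise SpectrumError("ratio must contain at least one positive weight")
    return total * ratio / s
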