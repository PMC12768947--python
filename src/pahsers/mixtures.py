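"""Labeled training-set fabrication by scaled addition of reference spectra.

Each sample is built as

    M = sum_i a_i * R_i + blank (+ shift, + noise),   a_i = l_i * S

where the references R_i are unit-max, the contributions l_i are fractions
summing to 1 over the present targets, and S is an overall signal scale
drawn log-uniformly. The network consumes the max-normalized spectrum
M / max(M); labels carry the contributions l, the presence pattern, and the
normalization factor z = max(M) / S. The factor z is what lets absolute
peak heights be recovered from normalized-scale predictions:
(l_i / z) * max(M) = a_i exactly when noise is off.

Per-target contributions are zeroed with 20% probability and every
surviving contribution is floored at 1% of the total signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .references import TARGETS, NoiseConfig, make_blank
from .spectra import Spectrum, SpectrumSet, SpectrumError, WavenumberGrid

__all__ = [
    "MixtureLabels",
    "TrainingSample",
    "SimDataset",
    "DEFAULT_SCALE_RANGE",
    "DATASET_SIZES",
    "sample_contributions",
    "apply_random_shift",
    "compose_mixture",
    "generate_dataset",
]

#: Overall signal scale S is drawn log-uniformly over two decades.
DEFAULT_SCALE_RANGE = (0.1, 10.0)

#: Default dataset sizes by role.
DATASET_SIZES = {"train": 10_000, "validation": 2_000, "optimization": 6_000}


@dataclass
class MixtureLabels:
    """Presence pattern, fractional contributions and normalization factor z."""

    presence: np.ndarray      # binary 5-vector
    contributions: np.ndarray  # fractions, sum 1 when any target present
    norm_factor: float         # z = max(M) / S

    @property
    def regression_target(self) -> np.ndarray:
        """The 6-number continuous label (l_1..l_5, z)."""
        return np.append(self.contributions, self.norm_factor)


@dataclass
class TrainingSample:
    spectrum: Spectrum  # unit-max
    labels: MixtureLabels
    raw_max: float


@dataclass
class SimDataset:
    """Array-backed dataset of simulated samples (one role, one seed)."""

    X: np.ndarray              # (n, w) unit-max spectra
    contributions: np.ndarray  # (n, 5)
    presence: np.ndarray       # (n, 5) binary
    norm_factors: np.ndarray   # (n,)
    raw_max: np.ndarray        # (n,)
    grid: WavenumberGrid
    role: str
    seed: int
    config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def regression_targets(self) -> np.ndarray:
        return np.column_stack([self.contributions, self.norm_factors])

    def sample(self, i: int) -> TrainingSample:
        spec = Spectrum(self.grid, self.X[i], label=f"{self.role}-{i}")
        labels = MixtureLabels(self.presence[i], self.contributions[i], float(self.norm_factors[i]))
        return TrainingSample(spec, labels, float(self.raw_max[i]))

    def save(self, path: str | Path) -> None:
        """Persist as .npz (spectra matrix) + CSV label table + JSON config."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            path.with_suffix(".npz"),
            X=self.X,
            grid=np.array([self.grid.start, self.grid.end, self.grid.n_points]),
        )
        labels = pd.DataFrame(self.contributions, columns=[f"contrib_{t}" for t in TARGETS])
        for j, t in enumerate(TARGETS):
            labels[f"present_{t}"] = self.presence[:, j]
        labels["norm_factor"] = self.norm_factors
        labels["raw_max"] = self.raw_max
        labels.to_csv(path.with_suffix(".labels.csv"), index=False)
        meta = {"role": self.role, "seed": self.seed, "config": self.config}
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SimDataset":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        g = arrays["grid"]
        grid = WavenumberGrid(float(g[0]), float(g[1]), int(g[2]))
        labels = pd.read_csv(path.with_suffix(".labels.csv"))
        meta = json.loads(path.with_suffix(".meta.json").read_text())
        return cls(
            X=arrays["X"],
            contributions=labels[[f"contrib_{t}" for t in TARGETS]].values,
            presence=labels[[f"present_{t}" for t in TARGETS]].values.astype(int),
            norm_factors=labels["norm_factor"].values,
            raw_max=labels["raw_max"].values,
            grid=grid,
            role=meta["role"],
            seed=meta["seed"],
            config=meta.get("config", {}),
        )


def sample_contributions(
    rng: np.random.Generator, zero_prob: float = 0.2, min_frac: float = 0.01
) -> np.ndarray:
    """Draw one 5-vector of fractional contributions.

    Each target is independently zeroed with probability *zero_prob*;
    survivors get a Dirichlet draw mapped onto the simplex slice where
    every entry is at least *min_frac*, so contributions sum to 1 with a
    hard 1%-of-total floor. If all five are zeroed the sample is a blank
    (all-zero vector).
    """
    if not 0 <= zero_prob <= 1:
        raise SpectrumError(f"zero_prob must be in [0, 1], got {zero_prob}")
    if not 0 < min_frac < 0.2:
        raise SpectrumError(f"min_frac must be in (0, 1/5), got {min_frac}")
    alive = rng.random(len(TARGETS)) >= zero_prob
    k = int(alive.sum())
    out = np.zeros(len(TARGETS))
    if k == 0:
        return out
    u = rng.dirichlet(np.ones(k))
    out[alive] = min_frac + (1.0 - k * min_frac) * u
    return out


def apply_random_shift(
    spectrum: Spectrum, rng: np.random.Generator, max_shift: int
) -> Spectrum:
    """Translate intensities by a uniform integer offset in [-max_shift, +max_shift].

    Vacated edge points repeat the edge value; the grid itself is unchanged
    (this emulates small instrument wavenumber drift).
    """
    if max_shift < 0:
        raise SpectrumError("max_shift must be nonnegative")
    if max_shift == 0:
        return spectrum
    offset = int(rng.integers(-max_shift, max_shift + 1))
    if offset == 0:
        return spectrum
    y = spectrum.intensities
    shifted = np.empty_like(y)
    if offset > 0:
        shifted[offset:] = y[:-offset]
        shifted[:offset] = y[0]
    else:
        shifted[:offset] = y[-offset:]
        shifted[offset:] = y[-1]
    return spectrum.with_intensities(shifted)


def compose_mixture(
    contributions: np.ndarray,
    refs: SpectrumSet,
    blank: Spectrum,
    cfg: NoiseConfig,
    rng: np.random.Generator,
    scale_range: tuple[float, float] = DEFAULT_SCALE_RANGE,
) -> TrainingSample:
    """Build one labeled sample by scaled addition of references.

    Noiseless reconstruction identity: with the returned labels,
    (l_i / z) * max(M) equals the absolute scale a_i applied to reference i.
    """
    contributions = np.asarray(contributions, dtype=float)
    grid = refs.grid
    lo, hi = scale_range
    S = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    a = contributions * S
    y = blank.intensities.copy()
    for j, t in enumerate(TARGETS):
        if a[j] > 0:
            y = y + a[j] * refs.by_label(t).intensities
    raw = Spectrum(grid, y)
    raw = apply_random_shift(raw, rng, cfg.max_shift)
    if cfg.noise_sd > 0:
        scale = raw.max if raw.max > 0 else 1.0
        raw = raw.with_intensities(
            raw.intensities + rng.normal(0.0, cfg.noise_sd * scale, grid.n_points)
        )
    raw_max = raw.max
    if raw_max <= 0:
        raise SpectrumError("degenerate sample: no signal and no background to normalize")
    labels = MixtureLabels(
        presence=(contributions > 0).astype(int),
        contributions=contributions,
        norm_factor=raw_max / S,
    )
    return TrainingSample(raw.with_intensities(raw.intensities / raw_max), labels, raw_max)


def generate_dataset(
    n: int,
    role: str,
    refs: SpectrumSet,
    cfg: NoiseConfig,
    seed: int,
    zero_prob: float = 0.2,
    min_frac: float = 0.01,
    scale_range: tuple[float, float] = DEFAULT_SCALE_RANGE,
    background_preset: str = "drinking",
) -> SimDataset:
    """Generate *n* independent labeled samples; bit-reproducible from *seed*."""
    if n < 1:
        raise SpectrumError("dataset size must be at least 1")
    if min_frac * len(TARGETS) >= 1:
        raise SpectrumError(f"min_frac {min_frac} infeasible: 5 * min_frac must be < 1")
    grid = refs.grid
    rng = np.random.default_rng(seed)
    blank = make_blank(grid, cfg.silent(), preset=background_preset)
    X = np.empty((n, grid.n_points))
    contribs = np.empty((n, len(TARGETS)))
    z = np.empty(n)
    raw_max = np.empty(n)
    for i in range(n):
        c = sample_contributions(rng, zero_prob, min_frac)
        sample = compose_mixture(c, refs, blank, cfg, rng, scale_range)
        X[i] = sample.spectrum.intensities
        contribs[i] = sample.labels.contributions
        z[i] = sample.labels.norm_factor
        raw_max[i] = sample.raw_max
    config = {
        "zero_prob": zero_prob,
        "min_frac": min_frac,
        "scale_range": list(scale_range),
        "noise_sd": cfg.noise_sd,
        "max_shift": cfg.max_shift,
        "background_scale": cfg.background_scale,
        "background_preset": background_preset,
    }
    return SimDataset(
        X=X,
        contributions=contribs,
        presence=(contribs > 0).astype(int),
        norm_factors=z,
        raw_max=raw_max,
        grid=grid,
        role=role,
        seed=seed,
        config=config,
    )
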