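"""Decisions and concentrations from raw model outputs.

Classification scores become binary calls through per-target thresholds
chosen to maximize the geometric mean sqrt(sensitivity * specificity) on
validation data. Regression outputs (contributions l and normalization
factor z) become concentrations through

    height_i = max(l_i, 0) / z * raw_max
    conc_i   = calibration_curve_i.inverse(height_i)

with a hard floor of 0 uM (negative contributions and sub-blank heights
report zero), mirroring standard practice of never reporting negative
concentrations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq, curve_fit

from .references import TARGETS

__all__ = [
    "QuantError",
    "ThresholdSet",
    "CalibrationCurve",
    "QuantResult",
    "choose_threshold",
    "classify",
    "fit_calibration_curve",
    "estimate_lod",
    "contributions_to_concentrations",
]

#: Factor above the calibrated maximum at which extrapolated concentrations are capped.
EXTRAPOLATION_CAP = 10.0


class QuantError(ValueError):
    """Degenerate labels, unfittable calibrations and the like."""


def choose_threshold(scores: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """Pick the score cutoff maximizing sqrt(sensitivity * specificity).

    Candidates are midpoints between adjacent sorted unique scores, plus
    boundary candidates below the minimum (everything called positive) and
    above the maximum (everything negative); a score equal to the threshold
    is called positive. Ties break toward the lowest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if scores.shape != truth.shape:
        raise QuantError("scores and truth must have equal length")
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise QuantError("threshold selection needs both classes in the truth vector")
    u = np.unique(scores)
    candidates = np.concatenate([[u[0] / 2.0], (u[:-1] + u[1:]) / 2.0, [(u[-1] + 1.0) / 2.0]])
    # call = score >= t ; vectorized confusion counts per candidate
    calls = scores[None, :] >= candidates[:, None]
    tp = (calls & truth[None, :]).sum(axis=1)
    fp = (calls & ~truth[None, :]).sum(axis=1)
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    gm = np.sqrt(sens * spec)
    best = int(np.argmax(gm))  # argmax returns the first (lowest-threshold) maximum
    return float(candidates[best]), float(gm[best])


@dataclass
class ThresholdSet:
    """Per-target decision thresholds plus the geometric mean each achieved."""

    thresholds: np.ndarray
    geometric_means: np.ndarray

    @classmethod
    def fit(cls, scores: np.ndarray, truth: np.ndarray) -> "ThresholdSet":
        """Fit one threshold per column of an (n, 5) score matrix."""
        scores = np.asarray(scores, dtype=float)
        truth = np.asarray(truth)
        ts, gms = [], []
        for j in range(scores.shape[1]):
            t, g = choose_threshold(scores[:, j], truth[:, j])
            ts.append(t)
            gms.append(g)
        return cls(np.array(ts), np.array(gms))

    def save(self, path: str | Path) -> None:
        payload = {
            "targets": list(TARGETS),
            "thresholds": self.thresholds.tolist(),
            "geometric_means": self.geometric_means.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ThresholdSet":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["thresholds"]), np.array(d["geometric_means"]))


def classify(scores: np.ndarray, thresholds: ThresholdSet) -> np.ndarray:
    """Binary calls: positive iff score >= per-target threshold."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    return (scores >= thresholds.thresholds[None, :]).astype(int)


def _hill(c, h_max, K):
    return h_max * c / (K + c)


@dataclass
class CalibrationCurve:
    """Monotone concentration -> peak-height map, invertible in range.

    ``form='hill'`` fits h = h_max*c/(K+c); ``form='poly_log'`` fits a
    quadratic in log10(c), checked for monotonicity over the data range.
    """

    target: str
    form: str
    params: np.ndarray
    conc_range: tuple[float, float]

    def predict(self, conc) -> np.ndarray | float:
        c = np.asarray(conc, dtype=float)
        if self.form == "hill":
            out = _hill(c, *self.params)
        else:
            logc = np.log10(np.maximum(c, 1e-12))
            out = np.polyval(self.params, logc)
        return float(out) if out.ndim == 0 else out

    def inverse(self, height: float) -> tuple[float, bool]:
        """Concentration for a height; returns (conc, extrapolated_flag).

        Heights at or below the blank-equivalent level (the curve at 0)
        report 0 uM. Heights above the calibrated maximum are extrapolated
        up to EXTRAPOLATION_CAP * c_max and flagged.
        """
        c_min, c_max = self.conc_range
        if height <= max(self.predict(0.0) if self.form == "hill" else 0.0, 0.0):
            return 0.0, False
        h_top = float(self.predict(c_max))
        if height >= h_top:
            cap = EXTRAPOLATION_CAP * c_max
            if self.form == "hill":
                h_max, K = self.params
                conc = K * height / (h_max - height) if height < h_max else cap
            else:
                conc = cap
            return min(float(conc), cap), True
        if self.form == "hill":
            h_max, K = self.params
            return float(K * height / (h_max - height)), False
        # poly_log: monotone only over the calibrated range; below it fall back
        # to a linear segment through the origin
        h_lo = float(self.predict(c_min))
        if height <= h_lo:
            return float(c_min * height / h_lo), False
        f = lambda c: float(self.predict(c)) - height
        return float(brentq(f, c_min, c_max)), False

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "form": self.form,
            "params": self.params.tolist(),
            "conc_range": list(self.conc_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(d["target"], d["form"], np.array(d["params"]), tuple(d["conc_range"]))


def fit_calibration_curve(
    concs: np.ndarray, heights: np.ndarray, form: str = "hill", target: str = ""
) -> CalibrationCurve:
    """Fit a monotone calibration curve from (concentration, peak height) pairs."""
    concs = np.asarray(concs, dtype=float)
    heights = np.asarray(heights, dtype=float)
    if len(np.unique(concs)) < 4:
        raise QuantError("calibration needs at least 4 distinct concentrations")
    if np.any(heights <= 0):
        raise QuantError("calibration heights must be positive")
    order = np.argsort(concs)
    concs, heights = concs[order], heights[order]
    if form == "hill":
        p0 = (heights.max() * 1.5, np.median(concs))
        params, _ = curve_fit(
            _hill, concs, heights, p0=p0,
            bounds=([heights.max() * 0.999, 1e-9], [np.inf, np.inf]), maxfev=20_000,
        )
        curve = CalibrationCurve(target, "hill", np.asarray(params), (concs[0], concs[-1]))
    elif form == "poly_log":
        logc = np.log10(concs)
        params = np.polyfit(logc, heights, 2)
        curve = CalibrationCurve(target, "poly_log", params, (concs[0], concs[-1]))
        probe = np.logspace(logc[0], logc[-1], 200)
        vals = curve.predict(probe)
        if np.any(np.diff(vals) <= 0):
            raise QuantError(
                f"poly_log fit for {target or 'target'} is non-monotone over the data "
                f"range (min slope at c≈{probe[np.argmin(np.diff(vals))]:.3g} uM)"
            )
    else:
        raise QuantError(f"unknown calibration form {form!r}")
    # round-trip contract: inverse(fit(c)) == c within the calibrated range
    for c in np.geomspace(concs[0], concs[-1], 5)[1:-1]:
        rt, _ = curve.inverse(float(curve.predict(c)))
        if abs(rt - c) > 1e-6 * max(c, 1e-9) + 1e-9:
            raise QuantError(f"calibration round-trip failed at {c} uM (got {rt})")
    return curve


def estimate_lod(curve: CalibrationCurve, blank_sd: float, snr: float = 3.5) -> float:
    """Limit of detection: smallest concentration with height >= snr * blank_sd."""
    if blank_sd <= 0:
        raise QuantError("blank_sd must be positive")
    if snr < 0:
        raise QuantError("snr must be nonnegative")
    target_h = snr * blank_sd
    if target_h <= 0:
        return 0.0
    c_min, c_max = curve.conc_range
    top = float(curve.predict(EXTRAPOLATION_CAP * c_max))
    if target_h > top:
        raise QuantError(
            f"required height {target_h:.3g} exceeds curve maximum {top:.3g}: not detectable"
        )
    conc, _ = curve.inverse(target_h)
    return conc


@dataclass
class QuantResult:
    """Per-target concentrations (uM) plus extrapolation flags."""

    concentrations: np.ndarray
    extrapolated: np.ndarray

    def as_dict(self) -> dict:
        return {t: float(c) for t, c in zip(TARGETS, self.concentrations)}


def contributions_to_concentrations(
    pred: np.ndarray,
    raw_max: float,
    curves: dict[str, CalibrationCurve],
    z_floor: float = 1e-6,
) -> QuantResult:
    """Convert a predicted 6-vector (l_1..l_5, z) into concentrations.

    Each contribution is divided by the predicted normalization factor,
    scaled by the unnormalized test-spectrum maximum, and inverted through
    that target's calibration curve; the lowest reportable value is 0.
    """
    pred = np.asarray(pred, dtype=float)
    if pred.shape != (6,):
        raise QuantError(f"expected a 6-vector (5 contributions + z), got shape {pred.shape}")
    if raw_max <= 0:
        raise QuantError("raw_max must be positive")
    z = pred[5]
    if z <= z_floor:
        raise QuantError(f"degenerate normalization factor z={z} (floor {z_floor})")
    heights = np.maximum(pred[:5], 0.0) / z * raw_max
    concs = np.zeros(5)
    flags = np.zeros(5, dtype=bool)
    for j, t in enumerate(TARGETS):
        concs[j], flags[j] = curves[t].inverse(float(heights[j]))
    return QuantResult(np.maximum(concs, 0.0), flags)
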