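"""Evaluation artifacts: confusion matrices, classification metrics,
ROC-AUC, and the two RMSE figures of merit.

RMSE_spectrum = sqrt( (1/(n*w)) * sum_i sum_k (yhat_{i,k} - y_{i,k})^2 )
compares predicted and actual spectra on the max-normalized scale the
networks operate on (w spectral points per sample).

RMSE_conc = sqrt( (1/(n*m)) * sum_i sum_j (chat_{i,j} - c_{i,j})^2 )
compares predicted and actual concentration matrices in uM (m = 5 targets).

Metrics with zero denominators are reported as None ("undefined") rather
than coerced to 0 or 1, so macro averages are never silently inflated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_curve

from .references import TARGETS
from .spectra import Spectrum, SpectrumSet, SpectrumError

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "ROCResult",
    "confusion",
    "class_metrics",
    "micro_macro",
    "roc",
    "roc_micro_macro",
    "rmse_spectrum",
    "rmse_conc",
    "reconstruct_predicted_spectrum",
    "subset_accuracy",
    "per_call_accuracy",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass(frozen=True)
class ClassMetrics:
    """Precision, sensitivity (recall), specificity, NPV and f1.

    ``None`` marks an undefined metric (zero denominator)."""

    precision: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    npv: Optional[float]
    f1: Optional[float]

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "npv": self.npv,
            "f1": self.f1,
        }


def confusion(pred: Sequence[int], truth: Sequence[int]) -> ConfusionMatrix:
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise SpectrumError("prediction and truth vectors must have equal length")
    return ConfusionMatrix(
        tp=int((pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        tn=int((~pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    sensitivity = _ratio(cm.tp, cm.tp + cm.fn)
    specificity = _ratio(cm.tn, cm.tn + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    if precision is None or sensitivity is None or precision + sensitivity == 0:
        f1 = None
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return ClassMetrics(precision, sensitivity, specificity, npv, f1)


def micro_macro(
    per_target: Sequence[ConfusionMatrix],
) -> tuple[ClassMetrics, ClassMetrics, list[str]]:
    """Micro (summed-matrix) and macro (mean of per-target) averages.

    Returns (micro, macro, warnings); targets with undefined entries are
    excluded from the corresponding macro mean and reported in warnings.
    """
    if not per_target:
        raise SpectrumError("micro_macro needs at least one confusion matrix")
    pooled = ConfusionMatrix()
    for cm in per_target:
        pooled = pooled + cm
    micro = class_metrics(pooled)
    per = [class_metrics(cm) for cm in per_target]
    warnings: list[str] = []
    macro_vals = {}
    for name in ("precision", "sensitivity", "specificity", "npv", "f1"):
        vals = [getattr(m, name) for m in per]
        defined = [v for v in vals if v is not None]
        if len(defined) < len(vals):
            warnings.append(
                f"{name}: undefined for {len(vals) - len(defined)} target(s); macro "
                f"averages the remaining {len(defined)}"
            )
        macro_vals[name] = float(np.mean(defined)) if defined else None
    return micro, ClassMetrics(**macro_vals), warnings


@dataclass(frozen=True)
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc(scores: Sequence[float], truth: Sequence[int]) -> ROCResult:
    """ROC by threshold sweep (positive call at score >= threshold), trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    if truth.min() == truth.max():
        raise SpectrumError("ROC needs both classes in the truth vector")
    fpr, tpr, _ = roc_curve(truth, scores, drop_intermediate=False)
    return ROCResult(fpr, tpr, float(np.trapezoid(tpr, fpr)))


def roc_micro_macro(
    scores: np.ndarray, truth: np.ndarray
) -> tuple[ROCResult, float, list[ROCResult]]:
    """Per-target ROC plus micro (pooled pairs) and macro (mean AUC) averages."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    per = [roc(scores[:, j], truth[:, j]) for j in range(scores.shape[1])]
    micro = roc(scores.ravel(), truth.ravel())
    macro_auc = float(np.mean([r.auc for r in per]))
    return micro, macro_auc, per


def _stack(spectra) -> np.ndarray:
    if isinstance(spectra, SpectrumSet):
        return spectra.matrix()
    if isinstance(spectra, (list, tuple)) and spectra and isinstance(spectra[0], Spectrum):
        grids = {s.grid for s in spectra}
        if len(grids) > 1:
            raise SpectrumError("spectra must share one grid")
        return np.stack([s.intensities for s in spectra])
    return np.atleast_2d(np.asarray(spectra, dtype=float))


def rmse_spectrum(pred_spectra, actual_spectra) -> float:
    """Root mean squared error over all n*w spectral points."""
    P, A = _stack(pred_spectra), _stack(actual_spectra)
    if P.shape != A.shape:
        raise SpectrumError(f"spectrum sets differ in shape: {P.shape} vs {A.shape}")
    return float(np.sqrt(np.mean((P - A) ** 2)))


def rmse_conc(pred: np.ndarray, actual: np.ndarray) -> float:
    """Root mean squared error over all n*m concentration entries (uM)."""
    P = np.atleast_2d(np.asarray(pred, dtype=float))
    A = np.atleast_2d(np.asarray(actual, dtype=float))
    if P.shape != A.shape:
        raise SpectrumError(f"concentration matrices differ in shape: {P.shape} vs {A.shape}")
    return float(np.sqrt(np.mean((P - A) ** 2)))


def reconstruct_predicted_spectrum(
    pred_labels: np.ndarray,
    refs: SpectrumSet,
    raw_max: float,
    normalize: bool = True,
) -> Spectrum:
    """Scaled addition of references from a predicted 6-vector.

    Absolute scale is sum_i (l_i / z) * raw_max * R_i; with
    ``normalize=True`` the result is divided by raw_max, putting it on the
    max-normalized scale rmse_spectrum compares on.
    """
    pred = np.asarray(pred_labels, dtype=float)
    if pred.shape != (6,):
        raise SpectrumError(f"expected 6 predicted labels, got shape {pred.shape}")
    z = pred[5]
    if abs(z) <= 1e-9:
        raise SpectrumError(f"degenerate normalization factor z={z}")
    grid = refs.grid
    y = np.zeros(grid.n_points)
    for j, t in enumerate(TARGETS):
        contrib = max(pred[j], 0.0)
        if contrib > 0:
            y = y + (contrib / z) * raw_max * refs.by_label(t).intensities
    if normalize:
        y = y / raw_max
    return Spectrum(grid, y, label="reconstruction")


def subset_accuracy(calls: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of samples whose full 5-call pattern is exactly right."""
    calls = np.atleast_2d(calls)
    truth = np.atleast_2d(truth)
    return float(np.mean(np.all(calls == truth, axis=1)))


def per_call_accuracy(calls: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of individual target calls (n*5 of them) that are right."""
    return float(np.mean(np.asarray(calls) == np.asarray(truth)))
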