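"""Accuracy metrics for vegetation masks.

Three metrics score an index-derived vegetation mask against reference
data: overall accuracy OA = (TP+TN)/N and the chance-corrected kappa
coefficient, both computed from a confusion matrix over reference ROI
pixels; and the relative error of FVC,

    RE = (V_sup - V_vi) / V_sup,

where V_sup is the reference FVC (supervised classification) and V_vi the
index-pipeline FVC.  RE is signed; grade-level aggregation uses |RE| so
over- and under-estimates cannot cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "AccuracyResult",
    "confusion_from_rois",
    "overall_accuracy",
    "kappa",
    "kappa_from_matrix",
    "relative_error",
    "evaluate_mask",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts over reference pixels (vegetation = positive)."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def matrix(self) -> np.ndarray:
        """2x2 matrix, rows = reference class, columns = predicted class."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]], dtype=np.int64)


@dataclass(frozen=True)
class AccuracyResult:
    oa: float          # fraction in [0, 1]
    kappa: float
    re: float          # signed
    abs_re: float

    @property
    def oa_percent(self) -> float:
        return 100.0 * self.oa


def confusion_from_rois(mask: np.ndarray, roi_labels: np.ndarray) -> ConfusionCounts:
    """Tally confusion counts over labelled reference pixels.

    ``roi_labels`` is an array of the mask's shape with 0 = unassigned,
    1 = reference vegetation, 2 = reference non-vegetation; counts are taken
    over labelled pixels only.
    """
    m = np.asarray(mask)
    labels = np.asarray(roi_labels)
    if m.shape != labels.shape:
        raise ValueError("mask and ROI label shapes differ")
    if not np.isin(labels, (0, 1, 2)).all():
        raise ValueError("ROI labels must be 0 (unassigned), 1 (vegetation) or 2")
    veg_ref = labels == 1
    soil_ref = labels == 2
    if not veg_ref.any() or not soil_ref.any():
        raise ValueError("both reference classes must be represented in the ROIs")
    pred_veg = m.astype(bool)
    return ConfusionCounts(
        tp=int((veg_ref & pred_veg).sum()),
        fn=int((veg_ref & ~pred_veg).sum()),
        fp=int((soil_ref & pred_veg).sum()),
        tn=int((soil_ref & ~pred_veg).sum()),
    )


def overall_accuracy(c: ConfusionCounts) -> float:
    """OA = (TP + TN) / N."""
    if c.n == 0:
        raise ValueError("empty confusion matrix: OA undefined")
    return (c.tp + c.tn) / c.n


def kappa_from_matrix(matrix: np.ndarray) -> float:
    """Kappa coefficient of a general r x r confusion matrix.

    kappa = (N * sum_i x_ii - sum_i x_i+ x_+i) / (N^2 - sum_i x_i+ x_+i).
    """
    x = np.asarray(matrix, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] != x.shape[1] or x.shape[0] < 2:
        raise ValueError("confusion matrix must be square, r >= 2")
    if (x < 0).any():
        raise ValueError("confusion counts must be non-negative")
    n = x.sum()
    if n == 0:
        raise ValueError("empty confusion matrix: kappa undefined")
    diag = np.trace(x)
    chance = float(x.sum(axis=1) @ x.sum(axis=0))
    denom = n * n - chance
    if denom == 0:
        raise ValueError("kappa undefined: all pixels fall in one reference/predicted cell")
    return float((n * diag - chance) / denom)


def kappa(c: ConfusionCounts) -> float:
    """Kappa of binary confusion counts (general-form formula on the 2x2 matrix)."""
    return kappa_from_matrix(c.matrix())


def relative_error(v_sup: float, v_vi: float) -> tuple[float, float]:
    """Signed and absolute relative error of an FVC estimate.

    ``v_sup`` is the reference FVC (percent), ``v_vi`` the estimate.
    """
    if v_sup <= 0:
        raise ValueError("reference FVC zero: RE undefined")
    re = (v_sup - v_vi) / v_sup
    return re, abs(re)


def evaluate_mask(
    mask: np.ndarray,
    roi_labels: np.ndarray,
    v_sup: float,
    v_vi: float,
) -> AccuracyResult:
    """OA, kappa and RE of one candidate mask in a single call."""
    c = confusion_from_rois(mask, roi_labels)
    re, abs_re = relative_error(v_sup, v_vi)
    return AccuracyResult(oa=overall_accuracy(c), kappa=kappa(c), re=re, abs_re=abs_re)
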