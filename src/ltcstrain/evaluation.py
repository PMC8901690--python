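"""Error analysis and ROC classification protocol.

Measurement error against ground truth is summarized as normalized mean
absolute error (MAE) and root-mean-square error (RMSE) binned by
contrast-to-noise ratio (0.5 dB bins over 1-8 dB), together with an
ordinary least-squares agreement regression.  Classification of disease
versus control on the scalar strain metrics uses empirical ROC curves with
AUC, percentile-bootstrap confidence bands over subjects (resampling
repeated measurements jointly), the Youden index and the
distance-to-corner at the optimal threshold.  Lower metric values indicate
the positive (disease) class: impaired ventricles shorten less.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

logger = logging.getLogger(__name__)

__all__ = [
    "ErrorReport",
    "RocCurve",
    "agreement_regression",
    "error_by_cnr",
    "roc_analysis",
    "youden_index",
    "distance_to_corner",
]

CNR_BIN_EDGES = np.arange(1.0, 8.01, 0.5)


@dataclass
class ErrorReport:
    """Normalized error statistics per CNR bin."""

    bins: np.ndarray  # bin centers (dB)
    mae: np.ndarray
    rmse: np.ndarray
    spread: np.ndarray  # std of normalized |error| per bin
    n_per_bin: np.ndarray
    normalizer: float

    def as_dict(self) -> dict:
        return {
            "bins": self.bins.tolist(),
            "mae": self.mae.tolist(),
            "rmse": self.rmse.tolist(),
            "spread": self.spread.tolist(),
            "n_per_bin": self.n_per_bin.tolist(),
            "normalizer": self.normalizer,
        }


@dataclass
class RocCurve:
    """Empirical ROC curve with bootstrap confidence band."""

    fpr: np.ndarray  # 1 - specificity, nondecreasing
    tpr: np.ndarray  # sensitivity, nondecreasing
    auc: float
    fpr_grid: np.ndarray | None = None
    tpr_lo: np.ndarray | None = None  # 2.5th percentile band
    tpr_hi: np.ndarray | None = None  # 97.5th percentile band
    auc_ci: tuple[float, float] | None = None
    yi: float = 0.0
    corner_distance: float = 0.0

    @property
    def points(self) -> np.ndarray:
        """(sensitivity, 1-specificity) pairs."""
        return np.column_stack([self.tpr, self.fpr])


def agreement_regression(measured: np.ndarray, truth: np.ndarray) -> tuple[float, float, float]:
    """OLS fit of measured on truth: returns (slope, bias, R^2)."""
    measured = np.asarray(measured, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if measured.shape != truth.shape or len(measured) < 3:
        raise ValueError("need equal-length series of at least 3 points")
    if np.var(truth) == 0:
        raise ValueError("zero-variance truth; regression undefined")
    res = stats.linregress(truth, measured)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def error_by_cnr(
    abs_errors: np.ndarray,
    cnrs: np.ndarray,
    normalizer: float,
) -> ErrorReport:
    """Bin normalized errors by CNR (0.5 dB bins over [1, 8] dB).

    Bins are left-closed/right-open except the last, which includes the
    8 dB edge; values outside [1, 8] dB are dropped with a logged count.
    MAE and RMSE are normalized by ``normalizer`` (the peak |GLS| or
    |GLSr| of the dataset).
    """
    e = np.abs(np.asarray(abs_errors, dtype=float))
    c = np.asarray(cnrs, dtype=float)
    if e.shape != c.shape:
        raise ValueError("errors and cnrs must have equal length")
    if normalizer <= 0:
        raise ValueError("normalizer must be positive")
    edges = CNR_BIN_EDGES
    inside = (c >= edges[0]) & (c <= edges[-1])
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.info("error_by_cnr: dropped %d measurements outside [1, 8] dB", n_dropped)
    e, c = e[inside], c[inside]
    if len(e) == 0:
        raise ValueError("no measurements inside the CNR binning range")
    idx = np.clip(np.digitize(c, edges) - 1, 0, len(edges) - 2)
    centers, mae, rmse, spread, counts = [], [], [], [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        if not sel.any():
            continue
        eb = e[sel] / normalizer
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        mae.append(eb.mean())
        rmse.append(np.sqrt((eb**2).mean()))
        spread.append(eb.std())
        counts.append(int(sel.sum()))
    return ErrorReport(
        bins=np.array(centers), mae=np.array(mae), rmse=np.array(rmse),
        spread=np.array(spread), n_per_bin=np.array(counts), normalizer=float(normalizer),
    )


def youden_index(sensitivity: float, specificity: float) -> float:
    """Informedness YI = sensitivity + specificity - 1, clamped to [0, 1]."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return float(np.clip(sensitivity + specificity - 1.0, 0.0, 1.0))


def distance_to_corner(points: np.ndarray) -> float:
    """Distance of the best ROC point from perfect prediction.

    ``points`` holds (sensitivity, 1-specificity) rows; returns the minimum
    Euclidean distance to the (1, 0) corner.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("no ROC points")
    return float(np.min(np.hypot(1.0 - pts[:, 0], pts[:, 1])))


def _normalize_group(group) -> list[np.ndarray]:
    """Coerce a group into per-subject measurement arrays."""
    subjects = []
    for entry in group:
        arr = np.atleast_1d(np.asarray(entry, dtype=float))
        if arr.size == 0:
            raise ValueError("a subject has no measurements")
        subjects.append(arr)
    if not subjects:
        raise ValueError("empty group")
    return subjects


def _roc_points(pos_scores: np.ndarray, neg_scores: np.ndarray):
    y = np.concatenate([np.ones_like(pos_scores), np.zeros_like(neg_scores)])
    # lower metric values indicate disease: negate so higher score = positive
    s = -np.concatenate([pos_scores, neg_scores])
    fpr, tpr, _ = _roc_curve(y, s)
    return fpr, tpr


def roc_analysis(
    group_pos,
    group_neg,
    n_resamples: int = 1000,
    seed: int = 0,
) -> RocCurve:
    """ROC analysis of a scalar strain metric for disease classification.

    ``group_pos`` (disease) and ``group_neg`` (control) are sequences of
    per-subject metric values; a subject entry may itself be a sequence of
    repeated measurements, which are averaged for the point estimate and
    resampled jointly with their subject in the bootstrap.  Lower metric
    values indicate disease.  Returns the empirical ROC with trapezoidal
    AUC, a percentile-bootstrap 95% band on sensitivity over a fixed
    1-specificity grid, an AUC confidence interval, the Youden index and
    the distance to corner.
    """
    pos = _normalize_group(group_pos)
    neg = _normalize_group(group_neg)
    pos_means = np.array([s.mean() for s in pos])
    neg_means = np.array([s.mean() for s in neg])
    fpr, tpr = _roc_points(pos_means, neg_means)
    auc_val = float(_auc(fpr, tpr))
    yi = float(np.max(tpr - fpr))
    cd = distance_to_corner(np.column_stack([tpr, fpr]))

    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, 101)
    tpr_samples = np.empty((n_resamples, len(grid)))
    auc_samples = np.empty(n_resamples)
    for r in range(n_resamples):
        bp = _resample_subjects(pos, rng)
        bn = _resample_subjects(neg, rng)
        f, t = _roc_points(bp, bn)
        auc_samples[r] = _auc(f, t)
        tpr_samples[r] = np.interp(grid, f, t)
    tpr_lo, tpr_hi = np.percentile(tpr_samples, [2.5, 97.5], axis=0)
    auc_ci = tuple(np.percentile(auc_samples, [2.5, 97.5]))
    return RocCurve(
        fpr=fpr, tpr=tpr, auc=auc_val,
        fpr_grid=grid, tpr_lo=tpr_lo, tpr_hi=tpr_hi,
        auc_ci=(float(auc_ci[0]), float(auc_ci[1])),
        yi=max(yi, 0.0), corner_distance=cd,
    )


def _resample_subjects(subjects: list[np.ndarray], rng: np.random.Generator) -> np.ndarray:
    """Bootstrap: resample subjects with replacement, and each chosen
    subject's repeated measurements with replacement."""
    picks = rng.integers(0, len(subjects), len(subjects))
    out = np.empty(len(subjects))
    for i, p in enumerate(picks):
        meas = subjects[p]
        out[i] = meas[rng.integers(0, len(meas), len(meas))].mean() if len(meas) > 1 else meas[0]
    return out
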