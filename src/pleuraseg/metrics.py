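"""Segmentation and classification evaluation metrics.

Overlap metrics (IoU, DSC) follow the convention that two empty masks agree
perfectly (score 1), which rewards correct negatives on lesion-free crops.
The Hausdorff distance is the full symmetric textbook definition in pixel
units, computed with an exact Euclidean distance transform; when exactly one
mask is empty it returns the grid's maximal pixel-to-pixel distance (the
diagonal), and 0 when both are empty.

Confidence intervals use the percentile bootstrap of the mean; AUROC is the
Mann–Whitney probability with ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .errors import ShapeMismatchError, UndefinedRateError

__all__ = [
    "MetricReport",
    "ConfusionCounts",
    "iou",
    "dsc",
    "hausdorff",
    "bootstrap_mean_ci",
    "auroc",
    "rates",
    "Rates",
]


@dataclass(frozen=True)
class MetricReport:
    metric: str
    point_estimate: float
    ci_low: float
    ci_high: float
    n_samples: int
    n_boot: int
    seed: int

    def __str__(self) -> str:
        return f"{self.metric}: {self.point_estimate:.3f} ({self.ci_low:.3f}-{self.ci_high:.3f})"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class Rates:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def _as_binary_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union; both-empty ⇒ 1.0."""
    a, b = _as_binary_pair(a, b)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|a∩b| / (|a|+|b|); both-empty ⇒ 1.0."""
    a, b = _as_binary_pair(a, b)
    total = np.count_nonzero(a) + np.count_nonzero(b)
    if total == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / total


def hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance in pixels (exact Euclidean)."""
    a, b = _as_binary_pair(a, b)
    ea, eb = not a.any(), not b.any()
    if ea and eb:
        return 0.0
    if ea or eb:
        return float(np.hypot(a.shape[0] - 1, a.shape[1] - 1))
    # distance of every pixel to the nearest foreground pixel of the other mask
    dist_to_b = ndimage.distance_transform_edt(~b)
    dist_to_a = ndimage.distance_transform_edt(~a)
    return float(max(dist_to_b[a].max(), dist_to_a[b].max()))


def bootstrap_mean_ci(
    values,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    metric: str = "mean",
) -> MetricReport:
    """Percentile bootstrap interval of the mean; deterministic in ``seed``."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("bootstrap requires a non-empty value list")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return MetricReport(
        metric=metric,
        point_estimate=float(values.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_samples=int(values.size),
        n_boot=int(n_boot),
        seed=int(seed),
    )


def auroc(scores, labels) -> float:
    """Mann–Whitney AUROC (ties counted 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC requires both classes present")
    ranks = rankdata(scores)
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def rates(counts: ConfusionCounts) -> Rates:
    """Sensitivity, specificity, PPV, NPV; zero denominators raise."""
    pairs = {
        "sensitivity": (counts.tp, counts.tp + counts.fn),
        "specificity": (counts.tn, counts.tn + counts.fp),
        "ppv": (counts.tp, counts.tp + counts.fp),
        "npv": (counts.tn, counts.tn + counts.fn),
    }
    out = {}
    for name, (num, den) in pairs.items():
        if den == 0:
            raise UndefinedRateError(name)
        out[name] = num / den
    return Rates(**out)


def rates_or_nan(counts: ConfusionCounts) -> Rates:
    """Like :func:`rates` but NaN instead of raising on zero denominators."""
    vals = {}
    for name, (num, den) in {
        "sensitivity": (counts.tp, counts.tp + counts.fn),
        "specificity": (counts.tn, counts.tn + counts.fp),
        "ppv": (counts.tp, counts.tp + counts.fp),
        "npv": (counts.tn, counts.tn + counts.fn),
    }.items():
        vals[name] = num / den if den else float("nan")
    return Rates(**vals)
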