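"""Constraint-reliability discrimination.

A transferred lung+space constraint is only useful if it actually contains
the lesion. Each training/validation sample is scored by its coverage rate

    R = |C ∩ S| / |S|

(the fraction of ground-truth lesion pixels inside the constraint) and
labelled reliable (B = 1) iff R ≥ τ (default τ = 0.99). A small convolutional
classifier is then trained with cross-entropy on channel-fused inputs
(image, constraint, image⊙constraint) to predict reliability, a score cutoff
is chosen as the smallest grid point whose validation specificity reaches a
target, and the final constraint set keeps the refined constraint for samples
scoring at or above the cutoff while rejected samples fall back to the
all-ones mask (which nullifies the training penalty for them).

Only training and validation samples ever enter this phase; the test split is
not passed in, so no information can leak from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError, ShapeMismatchError, TrainingError
from .metrics import ConfusionCounts, Rates, rates_or_nan
from .nn import TinyConvClassifier, sigmoid
from .training import TrainConfig, fit_loop

__all__ = [
    "DiscriminatorConfig",
    "CoverageRecord",
    "coverage_rate",
    "label",
    "fuse_input",
    "train_discriminator",
    "select_cutoff",
    "CutoffResult",
    "assemble_constraints",
    "degrade_constraints",
    "records_frame",
]


@dataclass(frozen=True)
class DiscriminatorConfig:
    tau: float = 0.99
    specificity_targets: tuple[float, ...] = (0.80, 0.85, 0.90, 0.95)
    cutoff_step: float = 0.01
    assembly_specificity: float = 0.90
    classifier_base: int = 8
    classifier_depth: int = 2
    train: TrainConfig = field(default_factory=lambda: TrainConfig(max_epochs=30))

    def __post_init__(self):
        if not 0 < self.tau <= 1:
            raise ParameterError("tau", "must lie in (0, 1]")
        if any(not 0 < t < 1 for t in self.specificity_targets):
            raise ParameterError("specificity_targets", "must lie in (0, 1)")
        if not 0 < self.cutoff_step <= 1:
            raise ParameterError("cutoff_step", "must lie in (0, 1]")


@dataclass
class CoverageRecord:
    sample_id: str
    R: float
    B: int
    score: float = float("nan")
    kept: bool = False


def coverage_rate(constraint: np.ndarray, lesion: np.ndarray) -> float:
    """Fraction of lesion pixels inside the constraint, R = |C∩S| / |S|."""
    constraint = np.asarray(constraint).astype(bool)
    lesion = np.asarray(lesion).astype(bool)
    if constraint.shape != lesion.shape:
        raise ShapeMismatchError(f"{constraint.shape} vs {lesion.shape}")
    total = np.count_nonzero(lesion)
    if total == 0:
        raise ParameterError("lesion", "coverage rate undefined for an empty lesion")
    return np.count_nonzero(constraint & lesion) / total


def label(R: float, tau: float) -> int:
    """Reliability label: 1 iff R ≥ τ."""
    if not (0 <= R <= 1 and 0 <= tau <= 1):
        raise ParameterError("R/tau", "must lie in [0, 1]")
    return int(R >= tau)


def fuse_input(image: np.ndarray, constraint: np.ndarray) -> np.ndarray:
    """Channel fusion (image, constraint, image⊙constraint) → (3, H, W)."""
    image = np.asarray(image, dtype=np.float64)
    constraint = np.asarray(constraint, dtype=np.float64)
    if image.shape != constraint.shape:
        raise ShapeMismatchError(f"{image.shape} vs {constraint.shape}")
    return np.stack([image, constraint, image * constraint])


def _bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    grad = (sigmoid(z) - y) / len(y)
    return loss, grad


def train_discriminator(
    train_inputs: np.ndarray,
    train_labels: np.ndarray,
    valid_inputs: np.ndarray,
    valid_labels: np.ndarray,
    config: DiscriminatorConfig = DiscriminatorConfig(),
) -> tuple[TinyConvClassifier, np.ndarray, pd.DataFrame]:
    """Fit the reliability classifier; returns (model, valid scores, history)."""
    train_labels = np.asarray(train_labels, dtype=float)
    valid_labels = np.asarray(valid_labels, dtype=float)
    if len(np.unique(train_labels)) < 2:
        raise TrainingError(
            "discriminator training needs both reliable and unreliable constraints "
            "(single-class labels; consider lesion_outside or constraint corruption)"
        )
    tc = config.train
    net = TinyConvClassifier(
        in_ch=3, base=config.classifier_base, depth=config.classifier_depth, seed=tc.seed
    )

    def run_batch(idx, lr):
        z = net.forward_logits(train_inputs[idx])
        loss, gz = _bce_with_logits(z, train_labels[idx])
        net.zero_grads()
        net.backward(gz)
        net.sgd_step(lr)
        return loss

    def evaluate():
        zs = np.concatenate(
            [
                net.forward_logits(valid_inputs[i : i + tc.batch_size])
                for i in range(0, len(valid_inputs), tc.batch_size)
            ]
        )
        loss, _ = _bce_with_logits(zs, valid_labels)
        return loss, -loss

    history = fit_loop(net, len(train_inputs), tc, run_batch, evaluate)
    scores = np.concatenate(
        [
            net.forward(valid_inputs[i : i + tc.batch_size])
            for i in range(0, len(valid_inputs), tc.batch_size)
        ]
    )
    return net, scores, history


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    rates: Rates
    target: float
    attained: bool


def select_cutoff(
    scores,
    labels,
    specificity_target: float,
    step: float = 0.01,
) -> CutoffResult:
    """Smallest grid cutoff whose validation specificity reaches the target.

    The grid is {0, step, 2·step, …, 1}; a sample is kept (predicted
    positive) when score ≥ cutoff. Specificity is the fraction of unreliable
    (label-0) constraints correctly rejected. If no grid point attains the
    target the topmost grid point is returned with ``attained=False``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise TrainingError("cutoff selection requires both classes in validation labels")
    n_grid = int(round(1.0 / step))
    grid = np.round(np.arange(n_grid + 1) * step, 10)
    chosen = None
    for cutoff in grid:
        pred = scores >= cutoff
        tn = int(np.sum(~pred & (labels == 0)))
        fp = int(np.sum(pred & (labels == 0)))
        spec = tn / (tn + fp)
        if spec >= specificity_target:
            chosen = float(cutoff)
            break
    attained = chosen is not None
    if not attained:
        chosen = float(grid[-1])
    pred = scores >= chosen
    counts = ConfusionCounts(
        tp=int(np.sum(pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        tn=int(np.sum(~pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
    )
    return CutoffResult(
        cutoff=chosen, rates=rates_or_nan(counts), target=specificity_target, attained=attained
    )


def assemble_constraints(
    constraints: list[np.ndarray] | np.ndarray,
    scores,
    cutoff: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Final constraint set: keep where score ≥ cutoff, else all-ones fallback.

    Returns (stacked constraints, kept flags).
    """
    constraints = np.asarray([np.asarray(c).astype(bool) for c in constraints])
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(constraints):
        raise ParameterError("scores", "must align with constraints")
    kept = scores >= cutoff
    out = np.where(kept[:, None, None], constraints, True)
    return out, kept


def degrade_constraints(
    constraints: list[np.ndarray],
    fraction: float,
    seed: int,
    erosion_radius: tuple[int, int] = (8, 12),
    shift_px: tuple[int, int] = (20, 28),
) -> tuple[list[np.ndarray], np.ndarray]:
    """Heavily erode and shift a random fraction of constraints.

    Emulates transfer failures severe enough that the lesion is no longer
    covered; used to stress-test the discriminator and in the benchmark
    harness. Returns (constraints, corrupted flags).
    """
    rng = np.random.default_rng(seed)
    n = len(constraints)
    n_bad = int(round(fraction * n))
    bad = np.zeros(n, dtype=bool)
    bad[rng.choice(n, size=n_bad, replace=False)] = True
    out = []
    for i, c in enumerate(constraints):
        c = np.asarray(c).astype(bool)
        if bad[i]:
            r = int(rng.integers(erosion_radius[0], erosion_radius[1] + 1))
            yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
            disk = yy * yy + xx * xx <= r * r
            c = ndimage.binary_erosion(c, structure=disk, border_value=0)
            d = int(rng.integers(shift_px[0], shift_px[1] + 1))
            angle = rng.uniform(0, 2 * np.pi)
            dy, dx = int(round(d * np.sin(angle))), int(round(d * np.cos(angle)))
            c = ndimage.shift(c.astype(float), (dy, dx), order=0, cval=0.0, prefilter=False) > 0.5
        out.append(c)
    return out, bad


def records_frame(records: list[CoverageRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"sample_id": r.sample_id, "R": r.R, "B": r.B, "score": r.score, "kept": r.kept}
            for r in records
        ]
    )
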