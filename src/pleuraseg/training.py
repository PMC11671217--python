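"""Network-agnostic training: SGD with plateau learning-rate decay, early
stopping with best-weights restore, baseline vs constrained segmentation
losses, and λ grid selection.

Schedule (shared by the segmenter and the constraint classifier): learning
rate starts at 0.01 and is multiplied by 0.9 after 5 epochs without
validation improvement; training stops after ``early_stop_patience`` epochs
without improvement or at ``max_epochs``, whichever comes first, and the
best-validation parameters are restored. "Improvement" is a strict increase
of the monitored validation score by more than ``min_delta``.

The segmenter monitors mean validation DSC of the binarized prediction; the
classifier monitors negative validation cross-entropy. Both are deterministic
given the config seed (pure-numpy arithmetic, seeded shuffling): constrained
training in which every constraint is all-ones is bit-identical to baseline
training because the penalty short-circuits to exactly zero loss and zero
gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
import json

import numpy as np
import pandas as pd

from . import losses
from .errors import ParameterError, TrainingError
from .metrics import dsc

__all__ = ["TrainConfig", "SegBatch", "train", "select_lambda", "fit_loop",
           "predict_probs", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class TrainConfig:
    lr0: float = 0.01
    plateau_factor: float = 0.9
    plateau_patience: int = 5
    early_stop_patience: int = 15
    max_epochs: int = 50
    lambda_penalty: float = 0.6
    lambda_grid: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)
    batch_size: int = 4
    min_delta: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ParameterError("lr0", "must be positive")
        if not 0 < self.plateau_factor < 1:
            raise ParameterError("plateau_factor", "must lie in (0, 1)")
        if self.lambda_penalty < 0:
            raise ParameterError("lambda_penalty", "must be non-negative")


@dataclass
class SegBatch:
    """Aligned arrays for segmenter training.

    images: (N, 3, H, W) float32 — grayscale replicated over three channels;
    targets: (N, H, W) binary lesion (or lung) masks;
    constraints: (N, H, W) binary admissible-region masks, or None (treated
    as all-ones, i.e. unconstrained).
    """

    images: np.ndarray
    targets: np.ndarray
    constraints: np.ndarray | None = None

    def __post_init__(self):
        if self.images.ndim != 4 or self.images.shape[1] != 3:
            raise ParameterError("images", "must have shape (N, 3, H, W)")
        if self.targets.shape != (
            self.images.shape[0],
            self.images.shape[2],
            self.images.shape[3],
        ):
            raise ParameterError("targets", "must align with images")
        if self.constraints is not None:
            if self.constraints.shape != self.targets.shape:
                raise ParameterError("constraints", "must align with targets")
            vals = np.unique(self.constraints)
            if not np.all(np.isin(vals, (0, 1))):
                raise ParameterError("constraints", "must be binary")

    def __len__(self) -> int:
        return self.images.shape[0]


def to_batch(samples, target_attr: str = "lesion_mask", constraints=None) -> SegBatch:
    """Stack phantom samples into a SegBatch (3-channel replication)."""
    images = np.stack([np.repeat(s.image[None], 3, axis=0) for s in samples]).astype(np.float32)
    targets = np.stack([getattr(s, target_attr) for s in samples]).astype(np.float64)
    cons = None
    if constraints is not None:
        cons = np.stack(constraints).astype(np.float64)
    return SegBatch(images=images, targets=targets, constraints=cons)


def fit_loop(net, n_train: int, config: TrainConfig, run_batch, evaluate) -> pd.DataFrame:
    """Generic epoch loop: shuffled minibatches, plateau decay, early stop.

    ``run_batch(indices, lr) -> float`` performs one SGD step and returns the
    batch loss; ``evaluate() -> (val_loss, val_score)`` scores the validation
    split (score is maximised). Restores the best-scoring parameters.
    """
    rng = np.random.default_rng(config.seed)
    lr = config.lr0
    best_score = -np.inf
    best_params = net.get_params()
    rows = []
    no_improve = 0
    plateau = 0
    for epoch in range(config.max_epochs):
        perm = rng.permutation(n_train)
        total, seen = 0.0, 0
        for start in range(0, n_train, config.batch_size):
            idx = perm[start : start + config.batch_size]
            loss = run_batch(idx, lr)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            total += loss * len(idx)
            seen += len(idx)
        train_loss = total / seen
        val_loss, val_score = evaluate()
        if not np.isfinite(val_loss):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        improved = val_score > best_score + config.min_delta
        if improved:
            best_score = val_score
            best_params = net.get_params()
            no_improve = 0
            plateau = 0
        else:
            no_improve += 1
            plateau += 1
        rows.append(
            {
                "epoch": epoch,
                "train_loss": train_loss,
                "val_loss": val_loss,
                "val_score": val_score,
                "lr": lr,
                "improved": improved,
            }
        )
        if plateau >= config.plateau_patience:
            lr *= config.plateau_factor
            plateau = 0
        if no_improve >= config.early_stop_patience:
            break
    net.set_params(best_params)
    return pd.DataFrame(rows)


def predict_probs(net, images: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Forward a stack of (N, 3, H, W) images in chunks; returns (N, H, W)."""
    outs = [
        net.forward(images[i : i + batch_size]) for i in range(0, images.shape[0], batch_size)
    ]
    return np.concatenate(outs, axis=0)


def train(
    net,
    train_batch: SegBatch,
    valid_batch: SegBatch,
    config: TrainConfig,
    mode: str = "baseline",
) -> tuple[object, pd.DataFrame]:
    """Train a segmenter; mode 'baseline' (Dice) or 'constrained' (Dice + λ·penalty)."""
    if mode not in ("baseline", "constrained"):
        raise ParameterError("mode", "must be 'baseline' or 'constrained'")
    if len(train_batch) == 0 or len(valid_batch) == 0:
        raise TrainingError("empty training or validation split")
    if mode == "constrained" and train_batch.constraints is None:
        raise TrainingError("constrained mode requires constraints in the batch")
    lam = config.lambda_penalty if mode == "constrained" else 0.0
    cons = train_batch.constraints if mode == "constrained" else None

    def run_batch(idx, lr):
        preds = net.forward(train_batch.images[idx])
        loss, gpred = losses.constrained_loss_grad(
            preds,
            train_batch.targets[idx],
            None if cons is None else cons[idx],
            lam,
        )
        net.zero_grads()
        net.backward(gpred)
        net.sgd_step(lr)
        return loss

    def evaluate():
        preds = predict_probs(net, valid_batch.images)
        val_loss = losses.constrained_loss(preds, valid_batch.targets, None, 0.0)
        masks = preds >= 0.5
        val_dsc = float(
            np.mean([dsc(masks[i], valid_batch.targets[i]) for i in range(len(valid_batch))])
        )
        return val_loss, val_dsc

    history = fit_loop(net, len(train_batch), config, run_batch, evaluate)
    return net, history


def select_lambda(
    network_factory,
    train_batch: SegBatch,
    valid_batch: SegBatch,
    config: TrainConfig,
    _train_fn=None,
) -> tuple[float, pd.DataFrame]:
    """Grid-search λ by validation mean DSC; ties resolve to the smaller λ.

    ``network_factory(seed) -> network`` builds a fresh seed-derived model per
    grid point so each λ starts from the same initialisation.
    """
    if not config.lambda_grid:
        raise ParameterError("lambda_grid", "must be non-empty")
    train_fn = _train_fn or train
    rows = []
    best_lam, best_dsc = None, -np.inf
    for lam in config.lambda_grid:
        cfg = TrainConfig(**{**asdict(config), "lambda_penalty": float(lam)})
        net = network_factory(config.seed)
        net, history = train_fn(net, train_batch, valid_batch, cfg, mode="constrained")
        val_dsc = float(history["val_score"].max())
        rows.append({"lambda": float(lam), "val_dsc": val_dsc})
        if val_dsc > best_dsc:  # strict: ties keep the earlier (smaller) λ
            best_dsc = val_dsc
            best_lam = float(lam)
    return best_lam, pd.DataFrame(rows)


def save_checkpoint(net, config: TrainConfig, path: str | Path, extra: dict | None = None) -> None:
    """Persist network parameters plus config as an .npz archive."""
    params = net.get_params()
    meta = {"config": asdict(config), "n_params": len(params), **(extra or {})}
    np.savez(
        path,
        *params,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_checkpoint(path: str | Path, network_factory):
    """Rebuild a network from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        params = [data[f"arr_{i}"] for i in range(meta["n_params"])]
    config = TrainConfig(**{k: tuple(v) if isinstance(v, list) else v
                            for k, v in meta["config"].items()})
    net = network_factory(config.seed)
    net.set_params(params)
    return net, config, meta
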