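"""End-to-end orchestration of the four training phases on phantom data.

Phase 1 trains an auxiliary lung segmenter on clean phantoms (standing in for
external lung-segmentation datasets). Phase 2 deploys it on the shifted
target domain and refines the predicted lungs into lung+space constraint
candidates. Phase 3 labels candidates by lesion coverage, trains the
reliability discriminator and assembles the final constraint set (all-ones
fallback for rejected candidates). Phase 4 trains the lesion segmenter with
the constrained loss and compares it against the unconstrained baseline on
the held-out test split.

Every stochastic component derives its seed deterministically from one global
seed, so a full pipeline re-run with the same configuration yields
byte-identical report CSVs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import discriminator as disc_mod
from . import losses, metrics, morphology, phantom, training
from .errors import ParameterError, TrainingError
from .nn import TinyUNet

__all__ = [
    "ExperimentConfig",
    "AblationVariant",
    "derive_seed",
    "run_phase1",
    "run_phase2",
    "run_phase3",
    "run_phase4",
    "run_comparison",
    "run_ablation",
    "run_robustness",
    "run_all",
    "improvement_pct",
    "config_to_yaml",
    "config_from_yaml",
    "config_hash",
]

ABLATION_VARIANTS = (
    "baseline",
    "raw_lung_constraints",
    "refined_constraints",
    "refined_plus_discriminator",
)


@dataclass(frozen=True)
class AblationVariant:
    name: str

    def __post_init__(self):
        if self.name not in ABLATION_VARIANTS:
            raise ParameterError("variant", f"must be one of {ABLATION_VARIANTS}")


@dataclass(frozen=True)
class ExperimentConfig:
    """Full experiment description; serializable to a single YAML file."""

    phantom: phantom.PhantomConfig = field(default_factory=phantom.PhantomConfig)
    target_shift: phantom.DomainShiftConfig = field(
        default_factory=lambda: phantom.DomainShiftConfig(
            gamma_range=(0.7, 1.4), noise_sigma=0.05, affine_max_shift_px=2,
            affine_max_rotate_deg=4.0,
        )
    )
    n_aux: int = 60
    aux_split: tuple[float, float, float] = (0.7, 0.15, 0.15)
    n_target: int = 180
    target_split: tuple[float, float, float] = (2 / 3, 1 / 9, 2 / 9)
    morph: morphology.MorphConfig = field(default_factory=morphology.MorphConfig)
    disc: disc_mod.DiscriminatorConfig = field(default_factory=disc_mod.DiscriminatorConfig)
    seg_train: training.TrainConfig = field(default_factory=training.TrainConfig)
    net_base: int = 8
    net_depth: int = 2
    corrupt_fraction: float = 0.3
    seeds: tuple[int, ...] = (0, 1, 2)


def derive_seed(global_seed: int, tag: str) -> int:
    """Stable sub-seed from (global seed, component tag)."""
    digest = hashlib.sha256(f"{global_seed}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def config_hash(cfg: ExperimentConfig) -> str:
    return hashlib.sha256(config_to_yaml(cfg).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# YAML round trip


def config_to_yaml(cfg: ExperimentConfig) -> str:
    return yaml.safe_dump(asdict(cfg), sort_keys=True)


def _shift_from(d: dict) -> phantom.DomainShiftConfig:
    return phantom.DomainShiftConfig(
        gamma_range=tuple(d["gamma_range"]),
        noise_sigma=d["noise_sigma"],
        affine_max_shift_px=d["affine_max_shift_px"],
        affine_max_rotate_deg=d["affine_max_rotate_deg"],
    )


def config_from_yaml(text: str) -> ExperimentConfig:
    d = yaml.safe_load(text)
    ph = dict(d["phantom"])
    ph["lung_axes_range"] = tuple(tuple(v) for v in ph["lung_axes_range"])
    ph["lesion_area_range"] = tuple(ph["lesion_area_range"])
    ph["distractor_count_range"] = tuple(ph["distractor_count_range"])
    ph["shift"] = _shift_from(ph["shift"])
    disc_d = dict(d["disc"])
    disc_d["specificity_targets"] = tuple(disc_d["specificity_targets"])
    disc_d["train"] = training.TrainConfig(
        **{k: tuple(v) if isinstance(v, list) else v for k, v in disc_d["train"].items()}
    )
    return ExperimentConfig(
        phantom=phantom.PhantomConfig(**ph),
        target_shift=_shift_from(d["target_shift"]),
        n_aux=d["n_aux"],
        aux_split=tuple(d["aux_split"]),
        n_target=d["n_target"],
        target_split=tuple(d["target_split"]),
        morph=morphology.MorphConfig(**d["morph"]),
        disc=disc_mod.DiscriminatorConfig(**disc_d),
        seg_train=training.TrainConfig(
            **{k: tuple(v) if isinstance(v, list) else v for k, v in d["seg_train"].items()}
        ),
        net_base=d["net_base"],
        net_depth=d["net_depth"],
        corrupt_fraction=d["corrupt_fraction"],
        seeds=tuple(d["seeds"]),
    )


# ---------------------------------------------------------------------------
# Phase results


@dataclass
class Phase1Result:
    network: TinyUNet
    reports: dict[str, metrics.MetricReport]
    history: pd.DataFrame


@dataclass
class Phase3Result:
    records: pd.DataFrame
    constraints: np.ndarray
    kept: np.ndarray
    classifier: object
    report: pd.DataFrame
    auroc: float
    valid_scores: np.ndarray


@dataclass
class Phase4Result:
    network: TinyUNet
    reports: dict[str, metrics.MetricReport]
    history: pd.DataFrame


# ---------------------------------------------------------------------------
# Phases


def run_phase1(cfg: ExperimentConfig, seed: int) -> Phase1Result:
    """Train the auxiliary lung segmenter on clean phantoms and evaluate it."""
    aux_cfg = replace(cfg.phantom, seed=derive_seed(seed, "aux_data"))
    tr, va, te = phantom.generate_dataset(aux_cfg, cfg.n_aux, cfg.aux_split)
    net = TinyUNet(base=cfg.net_base, depth=cfg.net_depth, seed=derive_seed(seed, "phase1_init"))
    tc = replace(cfg.seg_train, seed=derive_seed(seed, "phase1_train"))
    net, history = training.train(
        net,
        training.to_batch(tr, target_attr="lung_mask"),
        training.to_batch(va, target_attr="lung_mask"),
        tc,
        mode="baseline",
    )
    # evaluation targets are the lung masks, not lesions
    batch = training.to_batch(te, target_attr="lung_mask")
    preds = losses.binarize(training.predict_probs(net, batch.images))
    per = {
        "iou": [metrics.iou(preds[i], batch.targets[i]) for i in range(len(te))],
        "dsc": [metrics.dsc(preds[i], batch.targets[i]) for i in range(len(te))],
        "hd": [metrics.hausdorff(preds[i], batch.targets[i]) for i in range(len(te))],
    }
    reports = {
        f"lung_{name}": metrics.bootstrap_mean_ci(
            vals, seed=derive_seed(seed, f"phase1_boot_{name}"), metric=f"lung_{name}"
        )
        for name, vals in per.items()
    }
    return Phase1Result(network=net, reports=reports, history=history)


def run_phase2(
    net: TinyUNet,
    samples: list[phantom.PhantomSample],
    morph: morphology.MorphConfig = morphology.MorphConfig(),
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Predict lung masks on target images and refine into constraint candidates.

    Returns (candidates, raw predicted lung masks).
    """
    batch = training.to_batch(samples)
    probs = training.predict_probs(net, batch.images)
    raw = [np.asarray(m) for m in losses.binarize(probs)]
    candidates = [morphology.refine(m, morph) for m in raw]
    return candidates, raw


def run_phase3(
    candidates: list[np.ndarray],
    train_samples: list[phantom.PhantomSample],
    valid_samples: list[phantom.PhantomSample],
    cfg: disc_mod.DiscriminatorConfig,
    seed: int,
) -> Phase3Result:
    """Label candidates by coverage, train the discriminator, assemble constraints.

    ``candidates`` must align with train_samples + valid_samples. The test
    split is never passed here.
    """
    samples = list(train_samples) + list(valid_samples)
    if len(candidates) != len(samples):
        raise ParameterError("candidates", "must align with train+valid samples")
    n_train = len(train_samples)
    R = np.array(
        [disc_mod.coverage_rate(c, s.lesion_mask) for c, s in zip(candidates, samples)]
    )
    B = np.array([disc_mod.label(r, cfg.tau) for r in R])
    if len(np.unique(B[:n_train])) < 2 or len(np.unique(B[n_train:])) < 2:
        raise TrainingError(
            "constraints fall in a single reliability class on the training "
            "or validation split; the discriminator cannot be trained or "
            "calibrated (add lesion_outside or heavier constraint corruption)"
        )
    fused = np.stack(
        [disc_mod.fuse_input(s.image, c) for s, c in zip(samples, candidates)]
    ).astype(np.float32)
    tc = replace(cfg.train, seed=derive_seed(seed, "disc_train"))
    clf, valid_scores, _ = disc_mod.train_discriminator(
        fused[:n_train], B[:n_train], fused[n_train:], B[n_train:],
        replace(cfg, train=tc),
    )
    auc = metrics.auroc(valid_scores, B[n_train:])

    rows = []
    cut_by_target = {}
    for target in cfg.specificity_targets:
        res = disc_mod.select_cutoff(valid_scores, B[n_train:], target, cfg.cutoff_step)
        cut_by_target[target] = res
        rows.append(
            {
                "specificity_target": target,
                "cutoff": res.cutoff,
                "auroc": auc,
                "specificity": res.rates.specificity,
                "sensitivity": res.rates.sensitivity,
                "ppv": res.rates.ppv,
                "npv": res.rates.npv,
                "attained": res.attained,
            }
        )
    report = pd.DataFrame(rows)

    assembly = cut_by_target.get(
        cfg.assembly_specificity,
        disc_mod.select_cutoff(
            valid_scores, B[n_train:], cfg.assembly_specificity, cfg.cutoff_step
        ),
    )
    all_scores = np.concatenate(
        [
            clf.forward(fused[i : i + tc.batch_size])
            for i in range(0, len(fused), tc.batch_size)
        ]
    )
    constraints, kept = disc_mod.assemble_constraints(candidates, all_scores, assembly.cutoff)
    records = disc_mod.records_frame(
        [
            disc_mod.CoverageRecord(
                sample_id=f"s{samples[i].meta.get('index', i):05d}",
                R=float(R[i]),
                B=int(B[i]),
                score=float(all_scores[i]),
                kept=bool(kept[i]),
            )
            for i in range(len(samples))
        ]
    )
    return Phase3Result(
        records=records,
        constraints=constraints,
        kept=kept,
        classifier=clf,
        report=report,
        auroc=auc,
        valid_scores=valid_scores,
    )


def run_phase4(
    train_samples,
    valid_samples,
    test_samples,
    cfg: ExperimentConfig,
    seed: int,
    mode: str = "baseline",
    constraints: np.ndarray | None = None,
) -> Phase4Result:
    """Train the lesion segmenter (baseline or constrained) and evaluate it."""
    n_train = len(train_samples)
    cons_train = cons_valid = None
    if mode == "constrained":
        if constraints is None or len(constraints) != n_train + len(valid_samples):
            raise ParameterError("constraints", "must cover every train+valid sample")
        cons_train = constraints[:n_train]
        cons_valid = constraints[n_train:]
    net = TinyUNet(base=cfg.net_base, depth=cfg.net_depth, seed=derive_seed(seed, "phase4_init"))
    tc = replace(cfg.seg_train, seed=derive_seed(seed, "phase4_train"))
    net, history = training.train(
        net,
        training.to_batch(train_samples, constraints=cons_train),
        training.to_batch(valid_samples, constraints=cons_valid),
        tc,
        mode=mode,
    )
    reports = {}
    batch = training.to_batch(test_samples)
    preds = losses.binarize(training.predict_probs(net, batch.images))
    per = {
        "iou": [metrics.iou(preds[i], batch.targets[i]) for i in range(len(test_samples))],
        "dsc": [metrics.dsc(preds[i], batch.targets[i]) for i in range(len(test_samples))],
        "hd": [metrics.hausdorff(preds[i], batch.targets[i]) for i in range(len(test_samples))],
    }
    for name, vals in per.items():
        reports[name] = metrics.bootstrap_mean_ci(
            vals, seed=derive_seed(seed, f"phase4_boot_{name}"), metric=name
        )
    return Phase4Result(network=net, reports=reports, history=history)


def improvement_pct(baseline: float, ours: float, metric: str) -> float:
    """Relative improvement in percent; HD counts decreases as improvements."""
    if metric.lower() in ("hd", "hausdorff"):
        return 100.0 * (baseline - ours) / baseline
    return 100.0 * (ours - baseline) / baseline


# ---------------------------------------------------------------------------
# Target-domain preparation shared by the harnesses


def _prepare_target(cfg: ExperimentConfig, seed: int):
    tgt_cfg = replace(cfg.phantom, seed=derive_seed(seed, "target_data"))
    tr, va, te = phantom.generate_dataset(tgt_cfg, cfg.n_target, cfg.target_split)
    shift_seed = derive_seed(seed, "target_shift")
    tr = [phantom.corrupt(s, cfg.target_shift, shift_seed) for s in tr]
    va = [phantom.corrupt(s, cfg.target_shift, shift_seed) for s in va]
    te = [phantom.corrupt(s, cfg.target_shift, shift_seed) for s in te]
    return tr, va, te


def _constraint_sets(cfg: ExperimentConfig, seed: int, phase1_net, train_s, valid_s):
    """Raw, refined, and discriminator-filtered constraint sets for train+valid."""
    _, raw = run_phase2(phase1_net, list(train_s) + list(valid_s), cfg.morph)
    raw_deg, corrupted = disc_mod.degrade_constraints(
        raw, cfg.corrupt_fraction, derive_seed(seed, "constraint_corruption")
    )
    candidates = [morphology.refine(m, cfg.morph) for m in raw_deg]
    return {"raw": raw_deg, "refined": candidates, "corrupted_flags": corrupted}


# ---------------------------------------------------------------------------
# Harnesses


def run_comparison(cfg: ExperimentConfig, seed: int) -> pd.DataFrame:
    """Baseline vs discriminator-constrained training at one seed."""
    p1 = run_phase1(cfg, seed)
    tr, va, te = _prepare_target(cfg, seed)
    sets = _constraint_sets(cfg, seed, p1.network, tr, va)
    p3 = run_phase3(sets["refined"], tr, va, cfg.disc, seed)
    base = run_phase4(tr, va, te, cfg, seed, mode="baseline")
    ours = run_phase4(tr, va, te, cfg, seed, mode="constrained", constraints=p3.constraints)
    rows = []
    for m in ("iou", "dsc", "hd"):
        b, o = base.reports[m], ours.reports[m]
        rows.append(
            {
                "metric": m,
                "baseline": b.point_estimate,
                "baseline_ci_low": b.ci_low,
                "baseline_ci_high": b.ci_high,
                "ours": o.point_estimate,
                "ours_ci_low": o.ci_low,
                "ours_ci_high": o.ci_high,
                "improvement_pct": improvement_pct(b.point_estimate, o.point_estimate, m),
            }
        )
    return pd.DataFrame(rows)


def _variant_result(cfg, seed, variant, tr, va, te, sets, p3_cache) -> dict:
    if variant == "baseline":
        res = run_phase4(tr, va, te, cfg, seed, mode="baseline")
    elif variant == "raw_lung_constraints":
        cons = np.asarray([c.astype(bool) for c in sets["raw"]])
        res = run_phase4(tr, va, te, cfg, seed, mode="constrained", constraints=cons)
    elif variant == "refined_constraints":
        cons = np.asarray([c.astype(bool) for c in sets["refined"]])
        res = run_phase4(tr, va, te, cfg, seed, mode="constrained", constraints=cons)
    elif variant == "refined_plus_discriminator":
        if p3_cache.get("result") is None:
            p3_cache["result"] = run_phase3(sets["refined"], tr, va, cfg.disc, seed)
        res = run_phase4(
            tr, va, te, cfg, seed, mode="constrained", constraints=p3_cache["result"].constraints
        )
    else:
        raise ParameterError("variant", f"unknown variant {variant}")
    return {m: res.reports[m].point_estimate for m in ("iou", "dsc", "hd")}


def run_ablation(
    cfg: ExperimentConfig,
    seed: int,
    variants: tuple[str, ...] = ABLATION_VARIANTS,
) -> pd.DataFrame:
    """One full pipeline run per variant per seed; consolidated report."""
    rows = []
    for s in cfg.seeds:
        run_seed = derive_seed(seed, f"ablation_seed_{s}")
        p1 = run_phase1(cfg, run_seed)
        tr, va, te = _prepare_target(cfg, run_seed)
        sets = _constraint_sets(cfg, run_seed, p1.network, tr, va)
        p3_cache: dict = {}
        for variant in variants:
            AblationVariant(variant)
            point = _variant_result(cfg, run_seed, variant, tr, va, te, sets, p3_cache)
            rows.append({"variant": variant, "seed": s, **point})
    frame = pd.DataFrame(rows)
    means = (
        frame.groupby("variant", sort=False)[["iou", "dsc", "hd"]]
        .mean()
        .reset_index()
        .assign(seed="mean")
    )
    return pd.concat([frame, means], ignore_index=True)


def run_robustness(
    cfg: ExperimentConfig,
    seed: int,
    closing_grid: tuple[int, ...] = (15, 19, 25),
    dilation_grid: tuple[int, ...] = (11, 15, 21),
    tau_grid: tuple[float, ...] = (0.80, 0.90, 0.99),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sweeps over morphological element sizes and coverage rates.

    Element-size grid points recompute the refinement (Phase 2 onwards);
    coverage-rate points reuse the default candidates and re-run Phase 3
    onwards. One seed (the first of cfg.seeds) per grid point.
    """
    run_seed = derive_seed(seed, f"robust_seed_{cfg.seeds[0]}")
    p1 = run_phase1(cfg, run_seed)
    tr, va, te = _prepare_target(cfg, run_seed)
    _, raw = run_phase2(p1.network, list(tr) + list(va), cfg.morph)
    raw_deg, _ = disc_mod.degrade_constraints(
        raw, cfg.corrupt_fraction, derive_seed(run_seed, "constraint_corruption")
    )
    base = run_phase4(tr, va, te, cfg, run_seed, mode="baseline")

    elem_rows = []
    for c_size in closing_grid:
        for d_size in dilation_grid:
            morph = replace(cfg.morph, closing_size=c_size, dilation_size=d_size)
            candidates = [morphology.refine(m, morph) for m in raw_deg]
            p3 = run_phase3(candidates, tr, va, cfg.disc, run_seed)
            res = run_phase4(
                tr, va, te, cfg, run_seed, mode="constrained", constraints=p3.constraints
            )
            elem_rows.append(
                {
                    "closing_size": c_size,
                    "dilation_size": d_size,
                    **{m: res.reports[m].point_estimate for m in ("iou", "dsc", "hd")},
                }
            )

    default_candidates = [morphology.refine(m, cfg.morph) for m in raw_deg]
    tau_rows = []
    for tau in tau_grid:
        disc_cfg = replace(cfg.disc, tau=tau)
        p3 = run_phase3(default_candidates, tr, va, disc_cfg, run_seed)
        res = run_phase4(
            tr, va, te, cfg, run_seed, mode="constrained", constraints=p3.constraints
        )
        tau_rows.append(
            {"tau": tau, **{m: res.reports[m].point_estimate for m in ("iou", "dsc", "hd")}}
        )
    for rows in (elem_rows, tau_rows):
        rows.insert(
            0,
            {
                **{k: "baseline" for k in rows[0] if k not in ("iou", "dsc", "hd")},
                **{m: base.reports[m].point_estimate for m in ("iou", "dsc", "hd")},
            },
        )
    return pd.DataFrame(elem_rows), pd.DataFrame(tau_rows)


def save_overlay(sample: phantom.PhantomSample, pred_mask: np.ndarray, path: str | Path) -> None:
    """Overlay panel: image, ground-truth lesion contour, predicted mask."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    for ax in axes:
        ax.axis("off")
    axes[0].imshow(sample.image, cmap="gray", vmin=0, vmax=1)
    axes[0].set_title("image")
    axes[1].imshow(sample.image, cmap="gray", vmin=0, vmax=1)
    axes[1].contour(sample.lesion_mask, levels=[0.5], colors="lime")
    axes[1].contour(sample.lungspace_mask, levels=[0.5], colors="cyan", linewidths=0.7)
    axes[1].set_title("truth + lung+space")
    axes[2].imshow(sample.image, cmap="gray", vmin=0, vmax=1)
    axes[2].contour(pred_mask, levels=[0.5], colors="red")
    axes[2].set_title("prediction")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_all(cfg: ExperimentConfig, seed: int, outdir: str | Path) -> dict[str, Path]:
    """Full pipeline; writes config, reports, ledgers and figures to outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    (outdir / "config.yaml").write_text(config_to_yaml(cfg))

    p1 = run_phase1(cfg, seed)
    aux = pd.DataFrame(
        [
            {
                "metric": r.metric,
                "mean": r.point_estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n": r.n_samples,
                "config_hash": chash,
            }
            for r in p1.reports.values()
        ]
    )

    tr, va, te = _prepare_target(cfg, seed)
    sets = _constraint_sets(cfg, seed, p1.network, tr, va)
    p3 = run_phase3(sets["refined"], tr, va, cfg.disc, seed)
    base = run_phase4(tr, va, te, cfg, seed, mode="baseline")
    ours = run_phase4(tr, va, te, cfg, seed, mode="constrained", constraints=p3.constraints)
    comparison = pd.DataFrame(
        [
            {
                "metric": m,
                "baseline": base.reports[m].point_estimate,
                "ours": ours.reports[m].point_estimate,
                "improvement_pct": improvement_pct(
                    base.reports[m].point_estimate, ours.reports[m].point_estimate, m
                ),
                "config_hash": chash,
            }
            for m in ("iou", "dsc", "hd")
        ]
    )

    paths = {}
    for name, frame in (
        ("aux_metrics", aux),
        ("coverage_records", p3.records.assign(config_hash=chash)),
        ("discriminator_report", p3.report.assign(config_hash=chash)),
        ("phase4_comparison", comparison),
    ):
        p = outdir / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = p

    batch = training.to_batch(te[:3])
    preds = losses.binarize(training.predict_probs(ours.network, batch.images))
    for i in range(len(te[:3])):
        save_overlay(te[i], preds[i], outdir / f"overlay_{i}.png")
    return paths
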