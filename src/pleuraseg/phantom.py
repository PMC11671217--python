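"""Synthetic chest-radiograph phantoms with paired anatomical masks.

Each phantom renders a square "radiograph": a bright thorax ellipse on a dark
background, two darker elliptical lung fields, and a lucent (brighter than
lung, texture-suppressed) lesion emulating a pneumothorax. Alongside the image
the generator emits three binary ground-truth masks:

* ``lung_mask`` — the two lung fields;
* ``lungspace_mask`` — the lungs expanded by a pleural rim: the admissible
  region for a pneumothorax (lungs + pleural space);
* ``lesion_mask`` — the lesion, placed inside the lung+space band (crescents
  hugging the pleural margin, the typical pneumothorax geometry) unless a
  deliberate violation is sampled for discriminator stress-testing.

A :class:`DomainShiftConfig` describes acquisition-style corruption (gamma,
additive noise, small affine warps applied jointly to image and masks) used to
emulate the distribution shift between an auxiliary lung-segmentation domain
and the pneumothorax target domain, which is what makes transferred
constraints realistically unreliable.

Determinism contract: the sample stream is a pure function of
``(config, index)`` — two generators with equal configs produce bit-identical
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError
from . import io as psio

__all__ = [
    "DomainShiftConfig",
    "PhantomConfig",
    "PhantomSample",
    "generate_phantom",
    "generate_dataset",
    "corrupt",
    "largest_remainder_sizes",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class DomainShiftConfig:
    """Acquisition-shift corruption magnitudes (all zero ⇒ identity)."""

    gamma_range: tuple[float, float] = (1.0, 1.0)
    noise_sigma: float = 0.0
    affine_max_shift_px: int = 0
    affine_max_rotate_deg: float = 0.0

    def __post_init__(self):
        lo, hi = self.gamma_range
        if lo <= 0 or hi < lo:
            raise ParameterError("gamma_range", "requires 0 < lo <= hi")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma", "must be non-negative")
        if self.affine_max_shift_px < 0:
            raise ParameterError("affine_max_shift_px", "must be non-negative")
        if self.affine_max_rotate_deg < 0:
            raise ParameterError("affine_max_rotate_deg", "must be non-negative")

    @property
    def is_identity(self) -> bool:
        return (
            self.gamma_range == (1.0, 1.0)
            and self.noise_sigma == 0
            and self.affine_max_shift_px == 0
            and self.affine_max_rotate_deg == 0
        )


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and sampling parameters of the phantom generator.

    ``lung_axes_range`` gives (horizontal, vertical) semi-axis intervals as
    fractions of the image side. ``lesion_area_range`` is the lesion area as a
    fraction of the lung+space area. Defaults target a 64×64 test scale; 224
    is supported for realism-scale runs.
    """

    image_size: int = 64
    lung_axes_range: tuple[tuple[float, float], tuple[float, float]] = (
        (0.13, 0.18),
        (0.26, 0.34),
    )
    pleural_rim_px: int = 2
    lesion_area_range: tuple[float, float] = (0.03, 0.10)
    lesion_outside_prob: float = 0.0
    crescent_prob: float = 0.7
    distractor_count_range: tuple[int, int] = (2, 4)
    shift: DomainShiftConfig = field(default_factory=DomainShiftConfig)
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ParameterError("image_size", "must be >= 32")
        lo, hi = self.lesion_area_range
        if not (0 < lo <= hi <= 0.5):
            raise ParameterError("lesion_area_range", "must be within (0, 0.5]")
        if not 0 <= self.lesion_outside_prob <= 1:
            raise ParameterError("lesion_outside_prob", "must lie in [0, 1]")
        if self.pleural_rim_px < 0:
            raise ParameterError("pleural_rim_px", "must be non-negative")
        lo_d, hi_d = self.distractor_count_range
        if lo_d < 0 or hi_d < lo_d:
            raise ParameterError("distractor_count_range", "requires 0 <= lo <= hi")
        if self.seed < 0:
            raise ParameterError("seed", "must be non-negative")


@dataclass
class PhantomSample:
    """One phantom: intensity image plus lung / lung+space / lesion masks."""

    image: np.ndarray
    lung_mask: np.ndarray
    lungspace_mask: np.ndarray
    lesion_mask: np.ndarray
    meta: dict

    def validate(self) -> None:
        shapes = {
            self.image.shape,
            self.lung_mask.shape,
            self.lungspace_mask.shape,
            self.lesion_mask.shape,
        }
        if len(shapes) != 1:
            raise ParameterError("sample", "grids must share one shape")
        if np.any(self.lung_mask & ~self.lungspace_mask):
            raise ParameterError("sample", "lung_mask must be within lungspace_mask")
        if not self.meta.get("violates", False):
            if np.any(self.lesion_mask & ~self.lungspace_mask):
                raise ParameterError("sample", "lesion must lie inside lung+space")
            if not self.lesion_mask.any():
                raise ParameterError("sample", "lesion_mask must be non-empty")


def _disk(radius: int) -> np.ndarray:
    if radius == 0:
        return np.ones((1, 1), dtype=bool)
    r = np.arange(-radius, radius + 1)
    yy, xx = np.meshgrid(r, r, indexing="ij")
    return yy * yy + xx * xx <= radius * radius


def _ellipse_mask(size: int, cy: float, cx: float, ay: float, ax: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _grow_region(allowed: np.ndarray, seed_yx: tuple[int, int], area: int) -> np.ndarray:
    """Pick the `area` allowed pixels closest (Euclidean) to the seed pixel."""
    ys, xs = np.nonzero(allowed)
    d = (ys - seed_yx[0]) ** 2 + (xs - seed_yx[1]) ** 2
    order = np.lexsort((xs, ys, d))  # deterministic tie-break: distance, then raster
    take = order[: min(area, len(order))]
    out = np.zeros_like(allowed)
    out[ys[take], xs[take]] = True
    return out


def generate_phantom(config: PhantomConfig, index: int) -> PhantomSample:
    """Render phantom ``index`` of the stream defined by ``config``."""
    if index < 0:
        raise ParameterError("index", "must be >= 0")
    rng = np.random.default_rng([config.seed, index])
    s = config.image_size

    # --- anatomy -----------------------------------------------------------
    (ax_lo, ax_hi), (ay_lo, ay_hi) = config.lung_axes_range
    cy = s * (0.5 + rng.uniform(-0.02, 0.02))
    lung = np.zeros((s, s), dtype=bool)
    for side in (-1.0, 1.0):
        a = s * rng.uniform(ax_lo, ax_hi)
        b = s * rng.uniform(ay_lo, ay_hi)
        cx = s * (0.5 + side * (0.22 + rng.uniform(-0.015, 0.015)))
        lung |= _ellipse_mask(s, cy + s * rng.uniform(-0.02, 0.02), cx, b, a)
    thorax = _ellipse_mask(s, s * 0.52, s * 0.5, s * 0.46, s * 0.44)
    lung &= thorax

    if config.pleural_rim_px > 0:
        lungspace = ndimage.binary_dilation(lung, structure=_disk(config.pleural_rim_px))
    else:
        lungspace = lung.copy()

    # --- lesion ------------------------------------------------------------
    frac = rng.uniform(*config.lesion_area_range)
    area = int(round(frac * lungspace.sum()))
    if area < 1:
        raise ParameterError(
            "lesion_area_range", "lesion cannot fit inside lung+space (area < 1 px)"
        )
    violates = bool(rng.random() < config.lesion_outside_prob)
    crescent = bool(rng.random() < config.crescent_prob)

    if violates:
        # place the lesion outside the admissible region, near its border
        outside = ~ndimage.binary_dilation(lungspace, structure=_disk(1))
        near = outside & ndimage.binary_dilation(lungspace, structure=_disk(8))
        allowed = near if near.any() else outside
    elif crescent:
        band_w = max(2, config.pleural_rim_px + 2)
        core = ndimage.binary_erosion(lungspace, structure=_disk(band_w), border_value=1)
        allowed = lungspace & ~core
        if allowed.sum() < area:
            allowed = lungspace
    else:
        allowed = lungspace
    ys, xs = np.nonzero(allowed)
    if len(ys) == 0:
        raise ParameterError("lesion_area_range", "no admissible pixels for the lesion")
    j = int(rng.integers(len(ys)))
    lesion = _grow_region(allowed, (int(ys[j]), int(xs[j])), area)

    # --- distractors -------------------------------------------------------
    # lesion-like lucencies OUTSIDE the lung+space (skin folds, bowel gas):
    # they share the lesion's intensity signature, so location is the only
    # cue that separates them from true pneumothorax
    lo_d, hi_d = config.distractor_count_range
    n_distract = int(rng.integers(lo_d, hi_d + 1)) if hi_d > 0 else 0
    distractors = np.zeros((s, s), dtype=bool)  # lucent cores
    halos = np.zeros((s, s), dtype=bool)  # lung-like dark surround
    allowed_d = thorax & ~ndimage.binary_dilation(lungspace, structure=_disk(6)) & ~lesion
    # mimics sit near — but clearly outside — the pleural boundary (as skin
    # folds and bowel gas do): inside a ring 6-16 px from the lung+space, so
    # they stay outside the admissible region even after its morphological
    # dilation, and only the anatomical prior can rule them out
    near_boundary = allowed_d & ndimage.binary_dilation(lungspace, structure=_disk(16))
    for _ in range(n_distract):
        free = allowed_d & ~halos
        seed_pool = near_boundary & ~halos
        if not seed_pool.any():
            seed_pool = free
        dys, dxs = np.nonzero(seed_pool)
        if len(dys) == 0:
            break
        jd = int(rng.integers(len(dys)))
        d_area = max(1, int(round(area * rng.uniform(0.5, 1.0))))
        seed_yx = (int(dys[jd]), int(dxs[jd]))
        # halo ~3x the core area: locally the distractor looks exactly like
        # a lesion inside lung tissue; only its anatomical position differs
        halo = _grow_region(free, seed_yx, 3 * d_area)
        core = _grow_region(halo, seed_yx, d_area)
        halos |= halo
        distractors |= core

    # --- rendering ---------------------------------------------------------
    image = np.full((s, s), 0.12)
    image[thorax] = 0.75
    image[lung] = 0.35
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (s, s)), 1.2)
    image[lung] += 0.06 * texture[lung]
    image[halos] = 0.35 + 0.06 * texture[halos]
    image[lesion] = 0.55 + 0.01 * texture[lesion]  # lucent, texture-suppressed
    image[distractors] = 0.55 + 0.01 * texture[distractors]
    image = np.clip(ndimage.gaussian_filter(image, 0.6), 0.0, 1.0)

    sample = PhantomSample(
        image=image,
        lung_mask=lung,
        lungspace_mask=lungspace,
        lesion_mask=lesion,
        meta={
            "seed": config.seed,
            "index": index,
            "violates": violates,
            "crescent": crescent,
            "lesion_area": int(lesion.sum()),
            "n_distractors": n_distract,
            "corrupted": False,
        },
    )
    sample.validate()
    return sample


def largest_remainder_sizes(n: int, ratios: tuple[float, ...]) -> list[int]:
    """Apportion n into len(ratios) parts by the largest-remainder rule."""
    raw = [n * r for r in ratios]
    sizes = [int(np.floor(x)) for x in raw]
    rem = n - sum(sizes)
    order = sorted(range(len(ratios)), key=lambda i: (-(raw[i] - sizes[i]), i))
    for i in order[:rem]:
        sizes[i] += 1
    return sizes


def generate_dataset(
    config: PhantomConfig,
    n: int,
    split: tuple[float, float, float] = (0.7, 0.1, 0.2),
) -> tuple[list[PhantomSample], list[PhantomSample], list[PhantomSample]]:
    """Generate n phantoms and partition them into train/validation/test."""
    if n < 3:
        raise ParameterError("n", "must be >= 3")
    if any(r <= 0 for r in split):
        raise ParameterError("split", "ratios must be positive")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ParameterError("split", "ratios must sum to 1")
    sizes = largest_remainder_sizes(n, tuple(split))
    samples = [generate_phantom(config, i) for i in range(n)]
    n1, n2, _ = sizes
    return samples[:n1], samples[n1 : n1 + n2], samples[n1 + n2 :]


def _warp(arr: np.ndarray, angle_deg: float, dy: int, dx: int, order: int) -> np.ndarray:
    """Rotate about the image centre then translate; background-padded."""
    if angle_deg == 0.0:
        return ndimage.shift(arr.astype(float), (dy, dx), order=order, cval=0.0, prefilter=False)
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    centre = (np.array(arr.shape) - 1) / 2.0
    # forward map q -> R(q - c) + c + t; affine_transform needs the inverse:
    # input coordinate = R.T @ output + (c - R.T @ (c + t))
    offset = centre - rot.T @ (centre + np.array([dy, dx]))
    return ndimage.affine_transform(
        arr.astype(float), rot.T, offset=offset, order=order, cval=0.0, prefilter=False
    )


def corrupt(sample: PhantomSample, shift: DomainShiftConfig, seed: int) -> PhantomSample:
    """Apply domain-shift corruption; masks are warped jointly with the image."""
    if shift.is_identity:
        out = PhantomSample(
            image=sample.image.copy(),
            lung_mask=sample.lung_mask.copy(),
            lungspace_mask=sample.lungspace_mask.copy(),
            lesion_mask=sample.lesion_mask.copy(),
            meta={**sample.meta, "shift": "identity"},
        )
        return out
    rng = np.random.default_rng([max(seed, 0), sample.meta.get("index", 0)])
    image = sample.image.astype(float)

    gamma = float(rng.uniform(*shift.gamma_range))
    if gamma != 1.0:
        image = np.clip(image, 0.0, 1.0) ** gamma
    if shift.noise_sigma > 0:
        image = image + rng.normal(0.0, shift.noise_sigma, image.shape)
    image = np.clip(image, 0.0, 1.0)

    dy = dx = 0
    angle = 0.0
    if shift.affine_max_shift_px > 0:
        m = shift.affine_max_shift_px
        dy, dx = (int(v) for v in rng.integers(-m, m + 1, size=2))
    if shift.affine_max_rotate_deg > 0:
        angle = float(rng.uniform(-shift.affine_max_rotate_deg, shift.affine_max_rotate_deg))
    if dy or dx or angle:
        image = np.clip(_warp(image, angle, dy, dx, order=1), 0.0, 1.0)
        masks = [
            _warp(m.astype(float), angle, dy, dx, order=0) > 0.5
            for m in (sample.lung_mask, sample.lungspace_mask, sample.lesion_mask)
        ]
    else:
        masks = [sample.lung_mask.copy(), sample.lungspace_mask.copy(), sample.lesion_mask.copy()]

    return PhantomSample(
        image=image,
        lung_mask=masks[0],
        lungspace_mask=masks[1],
        lesion_mask=masks[2],
        meta={**sample.meta, "shift": {"gamma": gamma, "dy": dy, "dx": dx, "angle": angle}},
    )


def write_dataset(
    splits: dict[str, list[PhantomSample]], outdir: str | Path
) -> pd.DataFrame:
    """Write per-sample PNGs plus a manifest CSV; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for split_name, samples in splits.items():
        for sample in samples:
            sid = f"{split_name}_{sample.meta['index']:05d}"
            paths = {}
            for kind, arr in (
                ("image", sample.image),
                ("lung", sample.lung_mask),
                ("lungspace", sample.lungspace_mask),
                ("lesion", sample.lesion_mask),
            ):
                p = outdir / f"{sid}_{kind}.png"
                if kind == "image":
                    psio.save_image(arr, p)
                else:
                    psio.save_mask(arr, p)
                paths[kind] = p.name
            rows.append(
                {
                    "sample_id": sid,
                    "split": split_name,
                    "violates": bool(sample.meta.get("violates", False)),
                    **{f"{k}_path": v for k, v in paths.items()},
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def read_dataset(outdir: str | Path) -> dict[str, list[PhantomSample]]:
    """Read a dataset written by :func:`write_dataset`."""
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    splits: dict[str, list[PhantomSample]] = {}
    for _, row in manifest.iterrows():
        sample = PhantomSample(
            image=psio.load_image(outdir / row["image_path"]),
            lung_mask=psio.load_mask(outdir / row["lung_path"]),
            lungspace_mask=psio.load_mask(outdir / row["lungspace_path"]),
            lesion_mask=psio.load_mask(outdir / row["lesion_path"]),
            meta={"index": int(row["sample_id"].rsplit("_", 1)[1]), "violates": bool(row["violates"])},
        )
        splits.setdefault(row["split"], []).append(sample)
    return splits
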