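"""Refining a predicted lung mask into a lung+space constraint.

The refinement is three morphological stages in fixed order:

1. **top-2 connected-component cutoff** — removes speckle islands, keeping the
   two frontal lung fields;
2. **closing with a 19×19 ellipse element** — fills holes inside the lungs;
3. **dilation with a 15×15 ellipse element** — expands the lung fields to
   cover the pleural space between lung boundary and chest wall.

Border convention: the grid is conceptually padded with background for
dilation; erosion (inside closing) is the dual of that dilation, i.e. pads
with foreground, which keeps closing extensive (close(m) ⊇ m) everywhere
including at the frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError

__all__ = [
    "MorphConfig",
    "ellipse_element",
    "top_k_components",
    "dilate",
    "erode",
    "close",
    "refine",
]

_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class MorphConfig:
    keep_components: int = 2
    closing_size: int = 19
    dilation_size: int = 15
    connectivity: int = 8

    def __post_init__(self):
        if self.keep_components < 1:
            raise ParameterError("keep_components", "must be >= 1")
        for name in ("closing_size", "dilation_size"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ParameterError(name, "must be an odd positive integer")
        if self.connectivity not in (4, 8):
            raise ParameterError("connectivity", "must be 4 or 8")


def ellipse_element(size: int) -> np.ndarray:
    """Discrete filled ellipse (here: disk) inscribed in a size×size square.

    Cell (r, c) is foreground iff ((r-m)/m)² + ((c-m)/m)² ≤ 1 with
    m = (size-1)/2; size 1 gives a single pixel.
    """
    if size < 1 or size % 2 == 0:
        raise ParameterError("size", "must be an odd positive integer")
    if size == 1:
        return np.ones((1, 1), dtype=bool)
    m = (size - 1) / 2.0
    r = (np.arange(size) - m) / m
    yy, xx = np.meshgrid(r, r, indexing="ij")
    return yy * yy + xx * xx <= 1.0


def top_k_components(mask: np.ndarray, k: int, connectivity: int = 8) -> np.ndarray:
    """Union of the k largest connected foreground components.

    Size ties are broken in favour of the component whose first pixel comes
    earliest in raster-scan order.
    """
    if k < 1:
        raise ParameterError("k", "must be >= 1")
    mask = np.asarray(mask).astype(bool)
    structure = _STRUCTURE_8 if connectivity == 8 else _STRUCTURE_4
    labels, n = ndimage.label(mask, structure=structure)
    if n <= k:
        return mask.copy()
    flat = labels.ravel()
    sizes = np.bincount(flat, minlength=n + 1)
    firsts = np.full(n + 1, flat.size, dtype=np.int64)
    np.minimum.at(firsts, flat, np.arange(flat.size))
    order = sorted(range(1, n + 1), key=lambda lab: (-sizes[lab], firsts[lab]))
    keep = np.zeros(n + 1, dtype=bool)
    keep[order[:k]] = True
    return keep[labels]


def dilate(mask: np.ndarray, element: np.ndarray) -> np.ndarray:
    """Binary dilation; outside the grid counts as background."""
    return ndimage.binary_dilation(np.asarray(mask).astype(bool), structure=element, border_value=0)


def erode(mask: np.ndarray, element: np.ndarray) -> np.ndarray:
    """Binary erosion as the dual of background-padded dilation
    (outside the grid counts as foreground)."""
    return ndimage.binary_erosion(np.asarray(mask).astype(bool), structure=element, border_value=1)


def close(mask: np.ndarray, element: np.ndarray) -> np.ndarray:
    """Morphological closing: dilation followed by the dual erosion."""
    return erode(dilate(mask, element), element)


def refine(lung_pred: np.ndarray, config: MorphConfig = MorphConfig()) -> np.ndarray:
    """Predicted lung mask → lung+space constraint (cutoff → close → dilate)."""
    out = top_k_components(lung_pred, config.keep_components, config.connectivity)
    out = close(out, ellipse_element(config.closing_size))
    out = dilate(out, ellipse_element(config.dilation_size))
    return out
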