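"""Image and mask I/O: PNG grayscale images, 0/255 PNG masks, and the
run-length-encoded (RLE) mask dialect used by the SIIM-ACR pneumothorax
competition — space-separated (start, run) pairs, **column-major** flattening
with **1-based** starts, and the literal string ``-1`` for an empty mask.

Resizing helpers use bilinear interpolation for intensity images and
nearest-neighbour for masks, so binarity is preserved.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

from .errors import FormatError

__all__ = [
    "decode_rle",
    "encode_rle",
    "rle_to_string",
    "string_to_rle",
    "read_rle_csv",
    "write_rle_csv",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "resize_image",
    "resize_mask",
]


def decode_rle(pairs: list[tuple[int, int]], height: int, width: int) -> np.ndarray:
    """Decode (start, run) pairs into a binary (height, width) grid.

    Starts are 1-based offsets into the column-major flattening of the grid.
    An empty list decodes to an all-zero grid.
    """
    flat = np.zeros(height * width, dtype=bool)
    prev_start = 0
    for i, (start, run) in enumerate(pairs):
        if start < 1 or run < 1 or start - 1 + run > height * width:
            raise FormatError(f"RLE pair {i} ({start}, {run}) exceeds {height}x{width} grid")
        if start <= prev_start:
            raise FormatError(f"RLE pair {i}: starts must be strictly increasing")
        prev_start = start
        flat[start - 1 : start - 1 + run] = True
    return flat.reshape((height, width), order="F")


def encode_rle(mask: np.ndarray) -> list[tuple[int, int]]:
    """Encode a binary grid as maximal (start, run) pairs (column-major, 1-based)."""
    arr = np.asarray(mask)
    if not np.all(np.isin(np.unique(arr), (0, 1))):
        raise TypeError("mask must be binary")
    flat = arr.astype(bool).flatten(order="F")
    padded = np.concatenate([[False], flat, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]  # 0-based
    ends = np.nonzero(diff == -1)[0]
    return [(int(s) + 1, int(e - s)) for s, e in zip(starts, ends)]


def rle_to_string(pairs: list[tuple[int, int]]) -> str:
    if not pairs:
        return "-1"
    return " ".join(f"{s} {r}" for s, r in pairs)


def string_to_rle(text: str) -> list[tuple[int, int]]:
    text = text.strip()
    if text in ("-1", ""):
        return []
    tokens = text.split()
    if len(tokens) % 2:
        raise FormatError("RLE string must contain an even number of tokens")
    vals = [int(t) for t in tokens]
    return list(zip(vals[::2], vals[1::2]))


def write_rle_csv(masks: dict[str, np.ndarray], path: str | Path) -> pd.DataFrame:
    """Write masks as a CSV with columns (image_id, rle_string)."""
    rows = [
        {"image_id": image_id, "rle_string": rle_to_string(encode_rle(mask))}
        for image_id, mask in masks.items()
    ]
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame


def read_rle_csv(path: str | Path, height: int, width: int) -> dict[str, np.ndarray]:
    frame = pd.read_csv(path, dtype={"image_id": str, "rle_string": str})
    return {
        row["image_id"]: decode_rle(string_to_rle(str(row["rle_string"])), height, width)
        for _, row in frame.iterrows()
    }


def load_image(path: str | Path) -> np.ndarray:
    """Load an 8/16-bit grayscale PNG, normalised by bit depth into [0, 1]."""
    try:
        img = Image.open(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if img.mode in ("I;16", "I;16B", "I"):
        arr = np.asarray(img, dtype=np.float64) / 65535.0
    elif img.mode == "L":
        arr = np.asarray(img, dtype=np.float64) / 255.0
    elif img.mode in ("RGB", "RGBA", "LA", "P"):
        arr = np.asarray(img.convert("L"), dtype=np.float64) / 255.0
    else:
        raise IOError(f"unsupported image mode {img.mode!r} in {path}")
    if arr.ndim != 2:
        raise IOError(f"image {path} is not 2D")
    return np.clip(arr, 0.0, 1.0)


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Save a [0, 1] intensity grid as an 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray(np.round(arr * 255.0).astype(np.uint8), mode="L").save(path)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Save a binary grid as a 0/255 8-bit PNG."""
    arr = np.asarray(mask).astype(bool)
    Image.fromarray(np.where(arr, 255, 0).astype(np.uint8), mode="L").save(path)


def load_mask(path: str | Path) -> np.ndarray:
    """Load a PNG mask, thresholding at half of full scale."""
    return load_image(path) >= 0.5


def resize_image(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of an intensity grid to ``shape``."""
    return _sk_resize(
        np.asarray(image, dtype=float), shape, order=1, anti_aliasing=False, preserve_range=True
    )


def resize_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize of a binary mask; output remains binary."""
    out = _sk_resize(
        np.asarray(mask).astype(float), shape, order=0, anti_aliasing=False, preserve_range=True
    )
    return out >= 0.5
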