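"""Compact numpy neural networks with hand-written backpropagation.

Two models are provided:

* :class:`TinyUNet` — a small encoder–decoder segmenter with skip connections
  (configurable depth and base width) mapping a 3-channel image batch
  (N, 3, H, W) to a probability map batch (N, H, W) through a sigmoid head.
* :class:`TinyConvClassifier` — the same convolutional trunk followed by
  global average pooling and a linear head, mapping (N, 3, H, W) to a scalar
  probability per sample.

Both expose ``get_params`` / ``set_params`` (flat list of arrays),
``zero_grads`` and ``sgd_step(lr)``, which is all the training loop needs.
Convolutions use sliding-window views + einsum (same padding, odd kernels);
downsampling is 2×2 average pooling, upsampling nearest-neighbour. Everything
is float32 and fully deterministic given the construction seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "TinyUNet", "TinyConvClassifier", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Conv2d:
    """Same-padding 2D convolution (odd kernel), He-initialised."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int, rng: np.random.Generator):
        if ksize % 2 == 0:
            raise ValueError("kernel size must be odd")
        fan_in = in_ch * ksize * ksize
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, ksize, ksize)).astype(
            np.float32
        )
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.k = ksize
        self._win: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        out = np.einsum("nchwij,ocij->nohw", self._win, self.W, optimize=True)
        return out + self.b[None, :, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        p = self.k // 2
        self.gb += g.sum(axis=(0, 2, 3))
        self.gW += np.einsum("nohw,nchwij->ocij", g, self._win, optimize=True)
        gp = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p)))
        gwin = sliding_window_view(gp, (self.k, self.k), axis=(2, 3))
        # input gradient = correlation of upstream gradient with 180°-rotated kernels
        return np.einsum("nohwij,ocij->nchw", gwin, self.W[:, :, ::-1, ::-1], optimize=True)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]


def _relu_forward(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mask = x > 0
    return x * mask, mask


def _avgpool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _avgpool2_backward(g: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * np.float32(0.25)


def _upsample2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _upsample2_backward(g: np.ndarray) -> np.ndarray:
    n, c, h, w = g.shape
    return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class _Network:
    """Parameter-list plumbing shared by both models."""

    _layers: list[Conv2d]

    def get_params(self) -> list[np.ndarray]:
        return [p.copy() for layer in self._layers for p in layer.params()]

    def set_params(self, params: list[np.ndarray]) -> None:
        flat = [p for layer in self._layers for p in layer.params()]
        if len(flat) != len(params):
            raise ValueError("parameter list length mismatch")
        for dst, src in zip(flat, params):
            dst[...] = src

    def zero_grads(self) -> None:
        for layer in self._layers:
            for g in layer.grads():
                g[...] = 0.0

    def sgd_step(self, lr: float, momentum: float = 0.9) -> None:
        if not hasattr(self, "_velocity"):
            self._velocity = [
                np.zeros_like(p) for layer in self._layers for p in layer.params()
            ]
        i = 0
        for layer in self._layers:
            for p, g in zip(layer.params(), layer.grads()):
                v = self._velocity[i]
                v *= np.float32(momentum)
                v -= np.float32(lr) * g
                p += v
                i += 1


class TinyUNet(_Network):
    """Minimal encoder–decoder segmenter with skip connections.

    depth = number of 2× downsamplings; base = channels at the first level.
    Input spatial dims must be divisible by 2**depth.
    """

    def __init__(
        self,
        in_ch: int = 3,
        base: int = 8,
        depth: int = 2,
        seed: int = 0,
        head_bias: float = 0.0,
    ):
        rng = np.random.default_rng(seed)
        widths = [base * 2**i for i in range(depth + 1)]
        self.depth = depth
        self.head_bias = head_bias
        self.enc: list[Conv2d] = []
        ch = in_ch
        for w in widths[:-1]:
            self.enc.append(Conv2d(ch, w, 3, rng))
            ch = w
        self.bott = Conv2d(ch, widths[-1], 3, rng)
        self.dec: list[Conv2d] = []
        ch = widths[-1]
        for w in reversed(widths[:-1]):
            self.dec.append(Conv2d(ch + w, w, 3, rng))
            ch = w
        self.head = Conv2d(ch, 1, 1, rng)
        # optional class-prior head-bias initialisation (logit of the expected
        # foreground fraction); 0 works well for both lung and lesion tasks
        self.head.b[...] = np.float32(head_bias)
        self._layers = [*self.enc, self.bott, *self.dec, self.head]

    def forward(self, x: np.ndarray) -> np.ndarray:
        # inputs are [0, 1] intensities; centre to [-1, 1] so first-layer
        # gradients decouple (all-positive inputs stall feature learning)
        x = np.ascontiguousarray(x * 2.0 - 1.0, dtype=np.float32)
        if x.shape[2] % 2**self.depth or x.shape[3] % 2**self.depth:
            raise ValueError(f"spatial dims must be divisible by {2 ** self.depth}")
        self._cache: dict = {"skips": [], "relu_masks": [], "splits": []}
        for conv in self.enc:
            x, m = _relu_forward(conv.forward(x))
            self._cache["relu_masks"].append(m)
            self._cache["skips"].append(x)
            x = _avgpool2(x)
        x, m = _relu_forward(self.bott.forward(x))
        self._cache["relu_masks"].append(m)
        for conv, skip in zip(self.dec, reversed(self._cache["skips"])):
            x = _upsample2(x)
            self._cache["splits"].append(x.shape[1])
            x = np.concatenate([x, skip], axis=1)
            x, m = _relu_forward(conv.forward(x))
            self._cache["relu_masks"].append(m)
        z = self.head.forward(x)[:, 0]
        self._prob = sigmoid(z.astype(np.float64))
        return self._prob

    def backward(self, gprob: np.ndarray) -> None:
        """Accumulate parameter gradients from d loss / d probability map."""
        gz = (gprob * self._prob * (1.0 - self._prob)).astype(np.float32)
        g = self.head.backward(gz[:, None])
        masks = self._cache["relu_masks"]
        mi = len(masks) - 1
        skip_grads: list[np.ndarray] = []
        for conv in reversed(self.dec):
            g = conv.backward(g * masks[mi])
            mi -= 1
            split = self._cache["splits"].pop()
            g, gskip = g[:, :split], g[:, split:]
            skip_grads.append(gskip)
            g = _upsample2_backward(g)
        g = self.bott.backward(g * masks[mi])
        mi -= 1
        for conv in reversed(self.enc):
            # pool-path gradient plus the skip-connection gradient for this level
            g = _avgpool2_backward(g) + skip_grads.pop()
            g = conv.backward(g * masks[mi])
            mi -= 1

    def clone_init(self, seed: int) -> "TinyUNet":
        base = self.enc[0].W.shape[0]
        return TinyUNet(in_ch=3, base=base, depth=self.depth, seed=seed,
                        head_bias=self.head_bias)


class TinyConvClassifier(_Network):
    """Conv trunk + global average pooling + linear head → scalar probability."""

    def __init__(self, in_ch: int = 3, base: int = 8, depth: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.convs: list[Conv2d] = []
        ch = in_ch
        for i in range(depth + 1):
            w = base * 2**i
            self.convs.append(Conv2d(ch, w, 3, rng))
            ch = w
        self.head = Conv2d(ch, 1, 1, rng)  # 1x1 conv acts as the linear head
        self._layers = [*self.convs, self.head]

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x * 2.0 - 1.0, dtype=np.float32)
        self._masks = []
        for i, conv in enumerate(self.convs):
            x, m = _relu_forward(conv.forward(x))
            self._masks.append(m)
            if i < len(self.convs) - 1:
                x = _avgpool2(x)
        self._pre_gap_shape = x.shape
        gap = x.mean(axis=(2, 3), keepdims=True)
        z = self.head.forward(gap)[:, 0, 0, 0]
        return z.astype(np.float64)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward_logits(x))

    def backward(self, glogit: np.ndarray) -> None:
        g = self.head.backward(glogit.astype(np.float32)[:, None, None, None])
        n, c, h, w = self._pre_gap_shape
        g = np.broadcast_to(g / np.float32(h * w), self._pre_gap_shape).copy()
        for i, conv in enumerate(reversed(self.convs)):
            if i > 0:
                g = _avgpool2_backward(g)
            g = conv.backward(g * self._masks[len(self.convs) - 1 - i])

    def clone_init(self, seed: int) -> "TinyConvClassifier":
        base = self.convs[0].W.shape[0]
        return TinyConvClassifier(in_ch=3, base=base, depth=self.depth, seed=seed)
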