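"""A 3D encoder-decoder segmentation network in pure numpy.

The architecture follows the standard U-Net pattern: ``depth`` resolution
levels whose filter counts double per level starting from ``base_filters``;
two 3x3x3 convolution blocks per level, each Conv -> ReLU -> BatchNorm (the
normalisation is applied after the non-linear activation); 2x2x2 max-pool
downsampling; nearest-neighbour upsampling with skip concatenation; and a
final 1x1x1 convolution to a single pre-sigmoid output channel. Training
minimises the soft-Dice loss (overlap-based, no distance term) with Adam,
one volume per step.

Forward and backward passes are hand-derived. Convolutions run as im2col
matrix products; the gradient with respect to the input is the correlation
of the upstream gradient with the spatially flipped, channel-transposed
kernels. Batch statistics are per-channel over the spatial grid (batch size
one); inference uses frozen running statistics, so prediction is a
deterministic function of the trained state.

This backend is meant for small grids and small channel counts; the cheap
voxel-feature backend covers larger experiment sweeps.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..types import Case, Volume
from .voxel import _soft_dice_grad

_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-8
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


def _correlate(x: np.ndarray, kernels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Same-padding cross-correlation of (Cin, D, H, W) with (Cout, Cin, k, k, k).

    Returns the output (Cout, D, H, W) and the im2col matrix (N, Cin*k^3)
    for reuse in the backward pass.
    """
    cout, cin, k, _, _ = kernels.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))  # (Cin, D, H, W, k,k,k)
    d, h, w = x.shape[1:]
    cols = win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(d * h * w, cin * k**3)
    out = cols @ kernels.reshape(cout, cin * k**3).T  # (N, Cout)
    return out.T.reshape(cout, d, h, w), cols


class _Conv:
    """3D convolution, stride 1, same padding."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / (cin * k**3))  # He initialisation
        self.W = rng.normal(0.0, scale, size=(cout, cin, k, k, k))
        self.b = np.zeros(cout)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        out, cols = _correlate(x, self.W)
        self._cols, self._xshape = cols, x.shape
        return out + self.b[:, None, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cout = dout.shape[0]
        dflat = dout.reshape(cout, -1)          # (Cout, N)
        self.grads[0][...] = (dflat @ self._cols).reshape(self.W.shape)
        self.grads[1][...] = dflat.sum(axis=1)
        # gradient wrt input: correlate dout with flipped, transposed kernels
        Wt = self.W.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
        dx, _ = _correlate(dout, np.ascontiguousarray(Wt))
        self._cols = None
        return dx


class _ReLU:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class _BatchNorm:
    """Per-channel normalisation over the spatial grid."""

    def __init__(self, channels: int) -> None:
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:
        c = x.shape[0]
        flat = x.reshape(c, -1)
        if self.training:
            mean = flat.mean(axis=1)
            var = flat.var(axis=1)
            self.running_mean = _BN_MOMENTUM * self.running_mean + (1 - _BN_MOMENTUM) * mean
            self.running_var = _BN_MOMENTUM * self.running_var + (1 - _BN_MOMENTUM) * var
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + _BN_EPS)
        xn = (flat - mean[:, None]) * ivar[:, None]
        self._cache = (xn, ivar, flat.shape[1])
        out = self.gamma[:, None] * xn + self.beta[:, None]
        return out.reshape(x.shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c = dout.shape[0]
        dflat = dout.reshape(c, -1)
        xn, ivar, n = self._cache
        self.grads[0][...] = (dflat * xn).sum(axis=1)
        self.grads[1][...] = dflat.sum(axis=1)
        dxn = dflat * self.gamma[:, None]
        dx = (ivar[:, None] / n) * (
            n * dxn - dxn.sum(axis=1, keepdims=True)
            - xn * (dxn * xn).sum(axis=1, keepdims=True))
        return dx.reshape(dout.shape)


class _MaxPool2:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial dims {x.shape[1:]} not divisible by 2 for pooling")
        blocks = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        blocks = blocks.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, d // 2, h // 2, w // 2, 8)
        self._arg = blocks.argmax(axis=-1)
        self._shape = x.shape
        return blocks.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, d2, h2, w2 = dout.shape
        dblocks = np.zeros((c, d2, h2, w2, 8))
        np.put_along_axis(dblocks, self._arg[..., None], dout[..., None], axis=-1)
        dx = dblocks.reshape(c, d2, h2, w2, 2, 2, 2).transpose(0, 1, 4, 2, 5, 3, 6)
        return dx.reshape(self._shape)


class _Upsample2:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, d, h, w = dout.shape
        return (dout.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
                    .sum(axis=(2, 4, 6)))


class _ConvBlock:
    """Two Conv -> ReLU -> BatchNorm units."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator) -> None:
        self.layers = [
            _Conv(cin, cout, k, rng), _ReLU(), _BatchNorm(cout),
            _Conv(cout, cout, k, rng), _ReLU(), _BatchNorm(cout),
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class UNet3D:
    def __init__(self, depth: int = 3, base_filters: int = 8, kernel: int = 3,
                 learning_rate: float = 1e-3, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.lr = learning_rate
        filters = [base_filters * 2**i for i in range(depth)]
        self.enc = []
        cin = 1
        for f in filters:
            self.enc.append(_ConvBlock(cin, f, kernel, rng))
            cin = f
        self.pools = [_MaxPool2() for _ in range(depth - 1)]
        self.ups = [_Upsample2() for _ in range(depth - 1)]
        self.dec = []
        for i in reversed(range(depth - 1)):
            self.dec.append(_ConvBlock(filters[i] + filters[i + 1], filters[i], kernel, rng))
        self.final = _Conv(filters[0], 1, 1, rng)
        self._modules = self.enc + self.dec + [self.final]
        self._bn_layers = [l for block in (self.enc + self.dec)
                           for l in block.layers if isinstance(l, _BatchNorm)]
        self._params = [p for m in self._modules
                        for l in (m.layers if isinstance(m, _ConvBlock) else [m])
                        for p in l.params]
        self._grads = [g for m in self._modules
                       for l in (m.layers if isinstance(m, _ConvBlock) else [m])
                       for g in l.grads]
        self._adam_m = [np.zeros_like(p) for p in self._params]
        self._adam_v = [np.zeros_like(p) for p in self._params]
        self._adam_t = 0
        self._norm_mean: float | None = None
        self._norm_std: float | None = None

    # ---- plumbing --------------------------------------------------------
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self._params))

    def _set_training(self, flag: bool) -> None:
        for bn in self._bn_layers:
            bn.training = flag

    def _check_shape(self, shape: tuple[int, ...]) -> None:
        stride = 2 ** (self.depth - 1)
        if any(s < stride or s % stride for s in shape):
            raise ValueError(
                f"input shape {shape} must be divisible by 2^(depth-1) = {stride}")

    def _forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        for i in range(self.depth - 1):
            x = self.enc[i].forward(x)
            skips.append(x)
            x = self.pools[i].forward(x)
        x = self.enc[-1].forward(x)
        self._concat_channels = []
        for j, i in enumerate(reversed(range(self.depth - 1))):
            x = self.ups[j].forward(x)
            self._concat_channels.append(skips[i].shape[0])
            x = np.concatenate([skips[i], x], axis=0)
            x = self.dec[j].forward(x)
        return self.final.forward(x)

    def _backward(self, dlogits: np.ndarray) -> None:
        d = self.final.backward(dlogits)
        dskips: dict[int, np.ndarray] = {}
        # walk the decoder in reverse of the forward order
        for j in reversed(range(self.depth - 1)):
            i = self.depth - 2 - j
            d = self.dec[j].backward(d)
            c_skip = self._concat_channels[j]
            dskips[i] = d[:c_skip]
            d = self.ups[j].backward(d[c_skip:])
        d = self.enc[-1].backward(d)
        for i in reversed(range(self.depth - 1)):
            d = self.pools[i].backward(d)
            d = d + dskips[i]
            d = self.enc[i].backward(d)

    def _adam_step(self) -> None:
        self._adam_t += 1
        b1c = 1 - _ADAM_B1**self._adam_t
        b2c = 1 - _ADAM_B2**self._adam_t
        for p, g, m, v in zip(self._params, self._grads, self._adam_m, self._adam_v):
            m *= _ADAM_B1
            m += (1 - _ADAM_B1) * g
            v *= _ADAM_B2
            v += (1 - _ADAM_B2) * g**2
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + _ADAM_EPS)

    def _normalise(self, img: np.ndarray) -> np.ndarray:
        if self._norm_mean is None:
            return img
        return (img - self._norm_mean) / self._norm_std

    # ---- public ----------------------------------------------------------
    def loss_and_step(self, volume_voxels: np.ndarray, target: np.ndarray) -> float:
        """One training step on a single volume; returns the soft-Dice loss."""
        self._check_shape(volume_voxels.shape)
        x = self._normalise(np.asarray(volume_voxels, dtype=float))[None]
        z = self._forward(x)
        loss, dz = _soft_dice_grad(z.reshape(-1), target.reshape(-1).astype(float))
        self._backward(dz.reshape(z.shape))
        self._adam_step()
        return float(loss)

    def train_epochs(self, cases: Sequence[Case], epochs: int, seed: int) -> None:
        rng = np.random.default_rng(seed)
        if self._norm_mean is None:
            all_vals = np.concatenate([np.asarray(c.volume.voxels, dtype=float).ravel()
                                       for c in cases])
            self._norm_mean = float(all_vals.mean())
            self._norm_std = float(all_vals.std() + 1e-8)
        self._set_training(True)
        order = np.arange(len(cases))
        for _epoch in range(epochs):
            rng.shuffle(order)
            for i in order:
                case = cases[i]
                self.loss_and_step(case.volume.voxels, case.mask.voxels)
        self._set_training(False)

    def logits(self, volume: Volume) -> np.ndarray:
        self._check_shape(volume.shape)
        self._set_training(False)
        x = self._normalise(np.asarray(volume.voxels, dtype=float))[None]
        return self._forward(x)[0]
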