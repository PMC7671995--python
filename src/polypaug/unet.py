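"""A numpy U-Net for binary segmentation, with manual backpropagation.

The encoder applies ``levels`` blocks of two 3x3 convolutions (each followed
by batch normalization and ReLU), with 2x2 max-pooling between blocks and
channel widths doubling from ``base_width``; the default configuration turns
a 256x256x3 input into a 16x16x1024 bottleneck.  The decoder mirrors it with
``levels - 1`` blocks of 2x2 nearest up-sampling, a 3x3 convolution, skip
concatenation with the matching encoder feature map, and two further 3x3
convolutions.  Zero padding preserves spatial size everywhere; a final 1x1
convolution and sigmoid produce the per-pixel polyp probability map.

All tensors are NCHW float32.  Every layer implements ``forward``/``backward``
so the network trains with plain numpy; weights are He-initialized from a
seeded generator, which makes training bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["UNetConfig", "UNet", "build_unet"]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters.

    Defaults are the full-scale network (256x256 input, five blocks reaching
    a 16x16x1024 bottleneck, dropout 0.5, batch norm on).  Smaller configs
    (e.g. 3 levels, base width 8, 64x64 input) keep the same topology at CPU
    scale.
    """

    input_height: int = 256
    input_width: int = 256
    levels: int = 5
    base_width: int = 64
    dropout_rate: float = 0.5
    batch_norm: bool = True

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        div = 2 ** (self.levels - 1)
        if self.input_height % div or self.input_width % div:
            raise ValueError(
                f"input dims must be divisible by 2^(levels-1) = {div}"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def bottleneck_shape(self) -> tuple[int, int, int]:
        div = 2 ** (self.levels - 1)
        return (
            self.input_height // div,
            self.input_width // div,
            self.base_width * div,
        )


# ---------------------------------------------------------------- layers --

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (n, c, k, k, h, w), (s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return np.ascontiguousarray(cols).reshape(n, c * k * k, h * w)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int], k: int, pad: int) -> np.ndarray:
    n, c, h, w = shape
    dcols = dcols.reshape(n, c, k, k, h, w)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + h, j:j + w] += dcols[:, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w] if pad else dxp


class Conv2D:
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * k * k))
        self.W = (rng.standard_normal((cout, cin * k * k)) * std).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k = k
        self.pad = k // 2
        self._cols = None
        self._xshape = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.k, self.pad)
        if train:
            self._cols, self._xshape = cols, x.shape
        out = np.matmul(self.W[None], cols) + self.b[None, :, None]
        return out.reshape(n, -1, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, h, w = dout.shape
        dflat = dout.reshape(n, f, h * w)
        self.dW[...] = np.einsum("nfp,ncp->fc", dflat, self._cols)
        self.db[...] = dflat.sum(axis=(0, 2))
        dcols = np.matmul(self.W.T[None], dflat)
        dx = _col2im(dcols, self._xshape, self.k, self.pad)
        self._cols = None
        return dx


class BatchNorm2D:
    def __init__(self, c: int, momentum: float = 0.99, eps: float = 1e-3):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.dgamma[...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        self._cache = None
        return dx.astype(np.float32)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2:
    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        if train:
            mask = xr == out[:, :, :, None, :, None]
            # split gradient equally among tied maxima to keep backward exact
            mask = mask / mask.sum(axis=(3, 5), keepdims=True)
            self._cache = (mask, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask, shape = self._cache
        dx = mask * dout[:, :, :, None, :, None]
        self._cache = None
        return dx.reshape(shape).astype(np.float32)


class Upsample2:
    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Dropout:
    def __init__(self, rate: float):
        self.rate = rate
        self._mask = None

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None = None) -> np.ndarray:
        if not train or self.rate == 0.0:
            return x
        assert rng is not None, "dropout in training mode needs an rng"
        self._mask = (rng.uniform(size=x.shape) >= self.rate).astype(np.float32) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        dx = dout * self._mask
        self._mask = None
        return dx


class _Identity:
    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x, train):
        return x

    def backward(self, dout):
        return dout


class ConvBlock:
    """(conv3x3 -> BN -> ReLU) x 2."""

    def __init__(self, cin: int, cout: int, batch_norm: bool, rng: np.random.Generator):
        self.layers = []
        for c_in in (cin, cout):
            self.layers.append(Conv2D(c_in, cout, 3, rng))
            self.layers.append(BatchNorm2D(cout) if batch_norm else _Identity())
            self.layers.append(ReLU())

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


# ------------------------------------------------------------------ U-Net --

class UNet:
    """Binary segmentation network; see the module docstring for topology."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        L, B = config.levels, config.base_width
        bn = config.batch_norm
        widths = [B * 2 ** i for i in range(L)]

        self.enc = []
        cin = 3
        for wdt in widths:
            self.enc.append(ConvBlock(cin, wdt, bn, rng))
            cin = wdt
        self.pools = [MaxPool2() for _ in range(L - 1)]
        # dropout regularizes the two deepest encoder blocks
        self.enc_dropout = [
            Dropout(config.dropout_rate if i >= L - 2 else 0.0) for i in range(L)
        ]

        self.up = []        # per decoder stage: (Upsample2, conv3x3, ConvBlock)
        for i in reversed(range(L - 1)):
            wdt = widths[i]
            self.up.append(
                (Upsample2(), Conv2D(widths[i + 1], wdt, 3, rng), ConvBlock(2 * wdt, wdt, bn, rng))
            )
        self.head = Conv2D(B, 1, 1, rng)
        self._cache = None

    # -- parameter plumbing -------------------------------------------------
    def _modules(self):
        mods = list(self.enc)
        for upsample, conv, block in self.up:
            mods.extend([conv, block])
        mods.append(self.head)
        return mods

    def params(self):
        return [p for m in self._modules() for p in m.params()]

    def grads(self):
        return [g for m in self._modules() for g in m.grads()]

    def batchnorms(self) -> list[BatchNorm2D]:
        out = []
        for m in self._modules():
            for layer in getattr(m, "layers", []):
                if isinstance(layer, BatchNorm2D):
                    out.append(layer)
        return out

    def _clear_caches(self) -> None:
        self._cache = None
        for m in self._modules():
            for layer in getattr(m, "layers", [m]):
                for attr in ("_cols", "_cache", "_mask"):
                    if hasattr(layer, attr):
                        setattr(layer, attr, None)

    def calibrate_batchnorm(self, batches) -> None:
        """Precise batch-norm calibration.

        Replaces the momentum-tracked running statistics with the exact
        average of the batch statistics over ``batches`` (an iterable of
        (N, 3, H, W) float arrays).  Exponential running averages can lag
        badly after short trainings; evaluating with calibrated statistics
        makes eval-mode behavior match what the network actually learned.
        Dropout is disabled during calibration (inference-time statistics).
        """
        bns = self.batchnorms()
        if not bns:
            return
        saved_momentum = [bn.momentum for bn in bns]
        saved_rates = [d.rate for d in self.enc_dropout]
        for d in self.enc_dropout:
            d.rate = 0.0
        try:
            for i, x in enumerate(batches):
                for bn in bns:
                    bn.momentum = i / (i + 1.0)  # cumulative average
                self.forward(np.asarray(x, dtype=np.float32), train=True)
        finally:
            for bn, m0 in zip(bns, saved_momentum):
                bn.momentum = m0
            for d, r in zip(self.enc_dropout, saved_rates):
                d.rate = r
            self._clear_caches()

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """x: (N, 3, H, W) float32 in [0, 1] -> (N, 1, H, W) probabilities."""
        x = np.asarray(x, dtype=np.float32)
        skips = []
        L = self.config.levels
        for i in range(L):
            x = self.enc[i].forward(x, train)
            x = self.enc_dropout[i].forward(x, train, rng)
            if i < L - 1:
                skips.append(x)
                x = self.pools[i].forward(x, train)
        for stage, (upsample, conv, block) in enumerate(self.up):
            skip = skips[L - 2 - stage]
            x = upsample.forward(x, train)
            x = conv.forward(x, train)
            x = np.concatenate([skip, x], axis=1)
            x = block.forward(x, train)
        z = self.head.forward(x, train)
        p = 1.0 / (1.0 + np.exp(-z))
        if train:
            self._cache = p
        return p

    def backward(self, dprob: np.ndarray) -> None:
        """Backpropagate dL/dprob through the whole network."""
        p = self._cache
        d = (dprob * p * (1.0 - p)).astype(np.float32)
        d = self.head.backward(d)
        L = self.config.levels
        dskips = [None] * (L - 1)
        for stage in reversed(range(len(self.up))):
            upsample, conv, block = self.up[stage]
            d = block.backward(d)
            c_skip = d.shape[1] // 2
            dskips[L - 2 - stage] = d[:, :c_skip]
            d = conv.backward(d[:, c_skip:])
            d = upsample.backward(d)
        for i in reversed(range(L)):
            if i < L - 1:
                d = self.pools[i].backward(d)
                d = d + dskips[i]
            d = self.enc_dropout[i].backward(d)
            d = self.enc[i].backward(d)
        self._cache = None

    # -- inference helpers ----------------------------------------------------
    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """uint8 (N, H, W, 3) images -> (N, H, W) probability maps."""
        x = np.transpose(images.astype(np.float32) / 255.0, (0, 3, 1, 2))
        return self.forward(x, train=False)[:, 0]


def build_unet(config: UNetConfig, seed: int = 0) -> UNet:
    """Construct a seeded, He-initialized network from a config."""
    return UNet(config, seed=seed)
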