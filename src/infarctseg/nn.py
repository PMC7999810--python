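"""Minimal 3D neural-network layers with explicit forward/backward passes.

Pure-NumPy building blocks for the volumetric U-Net: 3D convolution (via
shift-and-matmul, so the inner loop is 27 BLAS GEMMs rather than a Python
loop over voxels), batch normalization, 2x2x2 max pooling, strided transposed
convolution, dropout, and an Adam optimizer. Tensors are (batch, channels,
D, H, W) float32. Every layer caches what its backward pass needs; call
``forward`` before ``backward``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "MaxPool3d",
    "ConvTranspose3d",
    "Dropout",
    "Adam",
]

DTYPE = np.float32


class Layer:
    """Base: trainable ``params`` with matching ``grads``; ``buffers`` are state
    that is saved/loaded but not optimized (e.g. batch-norm running stats)."""

    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []
        self.buffers: list[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self):
        for g in self.grads:
            g[...] = 0


class Conv3d(Layer):
    """3D convolution, kernel k with "same" zero padding (k odd).

    Implemented as im2col + one GEMM per pass: the padded input is unfolded
    into a (k^3 * c_in, n_voxels) matrix so the whole convolution is a single
    BLAS matrix product. The unfolded matrix is rebuilt (not cached) in the
    backward pass to keep peak memory proportional to the activations.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = c_in * kernel ** 3
        # He initialization (ReLU nonlinearity follows every conv here)
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel, kernel))
        self.w = w.astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def _offsets(self):
        k = self.k
        return [(i, j, l) for i in range(k) for j in range(k) for l in range(k)]

    def _w_matrix(self) -> np.ndarray:
        # (c_out, k^3 * c_in) with the offset index varying slowest, matching _unfold
        return np.ascontiguousarray(
            self.w.transpose(0, 2, 3, 4, 1).reshape(self.c_out, -1)
        )

    def _unfold(self, xp, D, H, W) -> np.ndarray:
        B = xp.shape[0]
        n = D * H * W
        cols = np.empty((B, self.k ** 3 * self.c_in, n), dtype=DTYPE)
        for o, (i, j, l) in enumerate(self._offsets()):
            cols[:, o * self.c_in : (o + 1) * self.c_in] = xp[
                :, :, i : i + D, j : j + H, l : l + W
            ].reshape(B, self.c_in, n)
        return cols

    def forward(self, x, training):
        pad = self.k // 2
        B, _, D, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad))) if pad else x
        self._xp, self._shape = xp, (B, D, H, W)
        cols = self._unfold(xp, D, H, W)
        out = self._w_matrix() @ cols
        out += self.b[None, :, None]
        return out.reshape(B, self.c_out, D, H, W)

    def backward(self, g):
        pad = self.k // 2
        B, D, H, W = self._shape
        n = D * H * W
        gf = g.reshape(B, self.c_out, n)
        cols = self._unfold(self._xp, D, H, W)
        dw_mat = np.einsum("bon,bkn->ok", gf, cols, optimize=True)
        self.grads[0] += (
            dw_mat.reshape(self.c_out, self.k, self.k, self.k, self.c_in).transpose(0, 4, 1, 2, 3)
        )
        self.grads[1] += gf.sum(axis=(0, 2))
        dcols = self._w_matrix().T @ gf
        dxp = np.zeros_like(self._xp)
        for o, (i, j, l) in enumerate(self._offsets()):
            dxp[:, :, i : i + D, j : j + H, l : l + W] += dcols[
                :, o * self.c_in : (o + 1) * self.c_in
            ].reshape(B, self.c_in, D, H, W)
        self._xp = None
        if pad:
            return dxp[:, :, pad:-pad, pad:-pad, pad:-pad]
        return dxp


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, g):
        out = np.where(self._mask, g, 0)
        self._mask = None
        return out


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (batch, spatial); running stats at eval."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.buffers = [self.running_mean, self.running_var]

    def forward(self, x, training):
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * invstd[None, :, None, None, None]
        if training:
            self._cache = (xhat, invstd, x.shape)
        else:
            self._cache = None
            self._eval_invstd = invstd
        out = self.gamma[None, :, None, None, None] * xhat + self.beta[None, :, None, None, None]
        return out.astype(DTYPE)

    def backward(self, g):
        axes = (0, 2, 3, 4)
        if self._cache is None:  # eval-mode backward (not used in training loop)
            return g * (self.gamma * self._eval_invstd)[None, :, None, None, None]
        xhat, invstd, shape = self._cache
        m = shape[0] * shape[2] * shape[3] * shape[4]
        dgamma = (g * xhat).sum(axis=axes)
        dbeta = g.sum(axis=axes)
        self.grads[0] += dgamma
        self.grads[1] += dbeta
        gx = self.gamma[None, :, None, None, None] * g
        dx = (
            invstd[None, :, None, None, None]
            / m
            * (m * gx - gx.sum(axis=axes)[None, :, None, None, None] - xhat * (gx * xhat).sum(axis=axes)[None, :, None, None, None])
        )
        self._cache = None
        return dx.astype(DTYPE)


class MaxPool3d(Layer):
    """2x2x2 max pooling (even spatial dims required)."""

    def forward(self, x, training):
        B, C, D, H, W = x.shape
        xr = x.reshape(B, C, D // 2, 2, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(3, 5, 7))
        mask = xr == out[:, :, :, None, :, None, :, None]
        # split gradient evenly among ties
        self._mask = mask
        self._count = mask.sum(axis=(3, 5, 7))
        self._in_shape = x.shape
        return out

    def backward(self, g):
        B, C, D, H, W = self._in_shape
        gr = (g / self._count)[:, :, :, None, :, None, :, None] * self._mask
        self._mask = self._count = None
        return gr.reshape(B, C, D, H, W)


class ConvTranspose3d(Layer):
    """2x2x2 transposed convolution with stride 2 (spatial upsampling x2)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * 8
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_in, c_out, 2, 2, 2))
        self.w = w.astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training):
        B, _, D, H, W = x.shape
        self._x = x
        n = D * H * W
        xf = x.reshape(B, self.c_in, n)
        out = np.empty((B, self.c_out, 2 * D, 2 * H, 2 * W), dtype=DTYPE)
        for i in range(2):
            for j in range(2):
                for l in range(2):
                    block = (self.w[:, :, i, j, l].T @ xf).reshape(B, self.c_out, D, H, W)
                    out[:, :, i::2, j::2, l::2] = block
        out += self.b[None, :, None, None, None]
        return out

    def backward(self, g):
        x = self._x
        B, _, D, H, W = x.shape
        n = D * H * W
        xf = x.reshape(B, self.c_in, n)
        dx = np.zeros((B, self.c_in, n), dtype=DTYPE)
        for i in range(2):
            for j in range(2):
                for l in range(2):
                    gf = g[:, :, i::2, j::2, l::2].reshape(B, self.c_out, n)
                    self.grads[0][:, :, i, j, l] += np.einsum("bcn,bon->co", xf, gf, optimize=True)
                    dx += self.w[:, :, i, j, l] @ gf
        self.grads[1] += g.sum(axis=(0, 2, 3, 4))
        self._x = None
        return dx.reshape(x.shape)


class Dropout(Layer):
    """Inverted dropout; a no-op at rate 0 or in eval mode. The mask generator
    is shared across the network so one seed reproduces a whole run."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, g):
        if self._mask is None:
            return g
        out = g * self._mask
        self._mask = None
        return out


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
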