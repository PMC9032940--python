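"""NumPy layers with explicit forward/backward passes.

The canonical activation layout is ``(batch, maps, space, time)``: EEG input
enters as one map over (electrodes x samples), the depthwise spatial stage
collapses the electrode axis to 1, and everything downstream is per-map time
series. Temporal convolutions are cross-correlations with same padding
(pad_left = (K-1)//2), evaluated by FFT; their gradients are convolutions of
the same kind, so both directions share the FFT helper. Every backward pass
here is validated against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft
from scipy.signal import fftconvolve

from .functional import elu, elu_grad, sigmoid

__all__ = [
    "Layer",
    "TemporalConv",
    "DepthwiseSpatialConv",
    "SeparableTemporalConv",
    "BatchNorm",
    "ELU",
    "AvgPoolTime",
    "Dropout",
    "SEBlock",
    "Dense",
]


class Layer:
    """Base class: trainable ``params`` and matching ``grads`` dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def apply_constraints(self) -> None:
        """Projection applied after each optimizer step (default: none)."""


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _corr_same_slices(kernel_length: int):
    """Left/right slice offsets for same-padded cross-correlation."""
    pad_left = (kernel_length - 1) // 2
    pad_right = kernel_length - 1 - pad_left
    return pad_left, pad_right


class TemporalConv(Layer):
    """Bank of shared-weight temporal filters: (B,1,C,T) -> (B,F,C,T).

    Each of the F filters is a length-K kernel slid along time with same
    padding, applied identically on every electrode row — the frequency-
    filter stage. Bias-free by default.
    """

    def __init__(self, n_filters: int, kernel_length: int, *,
                 bias: bool = False, rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        super().__init__()
        if n_filters < 1 or kernel_length < 1:
            raise ValueError("n_filters and kernel_length must be positive")
        rng = rng or np.random.default_rng()
        self.kernel_length = kernel_length
        self.params["W"] = _glorot(rng, (n_filters, kernel_length),
                                   kernel_length, kernel_length * n_filters, dtype)
        if bias:
            self.params["b"] = np.zeros(n_filters, dtype=dtype)
        self._pl, self._pr = _corr_same_slices(kernel_length)

    def forward(self, x, training=False, rng=None):
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (B,1,C,T), got {x.shape}")
        T = x.shape[3]
        K = self.kernel_length
        if K > T:
            raise ValueError(
                f"kernel_length {K} exceeds {T} time samples"
            )
        W = self.params["W"]
        # Linear correlation by FFT; the input spectrum is cached for the
        # backward pass, where all reductions happen in the frequency domain
        # so only small inverse transforms remain.
        nfft = sfft.next_fast_len(T + K - 1, real=True)
        Xf = sfft.rfft(x, nfft, axis=3)
        Wf = sfft.rfft(W[:, ::-1], nfft, axis=1)
        full = sfft.irfft(Xf * Wf[None, :, None, :], nfft, axis=3)
        y = full[..., self._pr:self._pr + T]
        if "b" in self.params:
            y = y + self.params["b"][None, :, None, None]
        self._Xf, self._T, self._nfft = Xf, T, nfft
        self._dtype = x.dtype
        return np.ascontiguousarray(y, dtype=x.dtype)

    def backward(self, dy):
        W = self.params["W"]
        T, K, pl, nfft = self._T, self.kernel_length, self._pl, self._nfft
        DYf = sfft.rfft(dy, nfft, axis=3)
        # dW[f,k] = sum_{b,c,t} dy[b,f,c,t] * x[b,c,t+k-pl]: circular
        # cross-correlation is alias-free at lags |k-pl| <= K-1 because the
        # transform length covers T+K-1.
        S = np.einsum("bfcn,bxcn->fn", np.conj(DYf), self._Xf, optimize=True)
        corr = sfft.irfft(S, nfft, axis=1)
        lags = (np.arange(K) - pl) % nfft
        self.grads["W"] = corr[:, lags].astype(W.dtype)
        if "b" in self.params:
            self.grads["b"] = dy.sum(axis=(0, 2, 3)).astype(W.dtype)
        # dx[tau] = sum_f (W_f convolved with dy_f)[tau+pl]; the sum over
        # filters is taken on spectra so only one map is inverse-transformed.
        WfT = sfft.rfft(W, nfft, axis=1)
        G = np.einsum("bfcn,fn->bcn", DYf, WfT, optimize=True)[:, None, :, :]
        dx = sfft.irfft(G, nfft, axis=3)[..., pl:pl + T]
        return np.ascontiguousarray(dx, dtype=self._dtype)


class DepthwiseSpatialConv(Layer):
    """Per-map spatial filters spanning all electrodes: (B,F,C,T) -> (B,F*D,1,T).

    Learns ``depth_multiplier`` spatial patterns per temporal filter (valid
    padding across the electrode axis, which therefore collapses to 1).
    Kernel max-norm constrained to 1 across electrodes.
    """

    MAX_NORM = 1.0

    def __init__(self, n_in_maps: int, depth_multiplier: int, n_channels: int,
                 *, bias: bool = False, rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.n_channels = n_channels
        self.depth_multiplier = depth_multiplier
        self.params["W"] = _glorot(rng, (n_in_maps, depth_multiplier, n_channels),
                                   n_channels, depth_multiplier, dtype)
        if bias:
            self.params["b"] = np.zeros(n_in_maps * depth_multiplier, dtype=dtype)

    def forward(self, x, training=False, rng=None):
        if x.shape[2] != self.n_channels:
            raise ValueError(
                f"spatial extent {x.shape[2]} != configured {self.n_channels} channels"
            )
        W = self.params["W"]
        B, F, C, T = x.shape
        y = np.einsum("bfct,fdc->bfdt", x, W, optimize=True)
        y = y.reshape(B, F * self.depth_multiplier, 1, T)
        if "b" in self.params:
            y = y + self.params["b"][None, :, None, None]
        self._x = x
        return y

    def backward(self, dy):
        x, W = self._x, self.params["W"]
        B, F, C, T = x.shape
        if "b" in self.params:
            self.grads["b"] = dy.sum(axis=(0, 2, 3)).astype(W.dtype)
        d = dy.reshape(B, F, self.depth_multiplier, T)
        self.grads["W"] = np.einsum("bfct,bfdt->fdc", x, d, optimize=True).astype(W.dtype)
        return np.einsum("bfdt,fdc->bfct", d, W, optimize=True).astype(x.dtype)

    def apply_constraints(self):
        W = self.params["W"]
        norms = np.sqrt((W ** 2).sum(axis=2, keepdims=True))
        np.multiply(W, np.minimum(1.0, self.MAX_NORM / np.maximum(norms, 1e-12)),
                    out=W)


class SeparableTemporalConv(Layer):
    """Depthwise temporal pass + 1x1 pointwise mixing: (B,F,1,T) -> (B,F,1,T).

    Each map gets its own length-K temporal summary kernel (same padding),
    then a pointwise matrix remixes the F maps.
    """

    def __init__(self, n_maps: int, kernel_length: int, *, bias: bool = False,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.kernel_length = kernel_length
        self.params["W_depth"] = _glorot(rng, (n_maps, kernel_length),
                                         kernel_length, 1, dtype)
        self.params["W_point"] = _glorot(rng, (n_maps, n_maps), n_maps, n_maps, dtype)
        if bias:
            self.params["b"] = np.zeros(n_maps, dtype=dtype)
        self._pl, self._pr = _corr_same_slices(kernel_length)

    def forward(self, x, training=False, rng=None):
        if x.shape[1] != self.params["W_depth"].shape[0]:
            raise ValueError(
                f"{x.shape[1]} input maps != {self.params['W_depth'].shape[0]} kernels"
            )
        T = x.shape[3]
        Wd = self.params["W_depth"]
        full = fftconvolve(x, Wd[None, :, None, ::-1], axes=3)
        z = full[..., self._pr:self._pr + T]
        y = np.einsum("nm,bmst->bnst", self.params["W_point"], z, optimize=True)
        if "b" in self.params:
            y = y + self.params["b"][None, :, None, None]
        self._x, self._z = x, z
        return y.astype(x.dtype, copy=False)

    def backward(self, dy):
        x, z = self._x, self._z
        Wd, Wp = self.params["W_depth"], self.params["W_point"]
        T, K, pl = x.shape[3], self.kernel_length, self._pl
        if "b" in self.params:
            self.grads["b"] = dy.sum(axis=(0, 2, 3)).astype(Wd.dtype)
        self.grads["W_point"] = np.einsum("bnst,bmst->nm", dy, z,
                                          optimize=True).astype(Wp.dtype)
        dz = np.einsum("nm,bnst->bmst", Wp, dy, optimize=True)
        e = fftconvolve(x[..., ::-1], dz, axes=3)
        self.grads["W_depth"] = (
            e[..., T + pl - K:T + pl][..., ::-1].sum(axis=(0, 2)).astype(Wd.dtype)
        )
        g = fftconvolve(dz, Wd[None, :, None, :], axes=3)
        return g[..., pl:pl + T].astype(x.dtype)


class BatchNorm(Layer):
    """Per-map batch normalization over (batch, space, time).

    Trainable scale/shift (2 parameters per map); running statistics are
    buffers, updated with Keras-style momentum, and used in evaluation mode.
    """

    def __init__(self, n_maps: int, *, eps: float = 1e-3, momentum: float = 0.99,
                 dtype=np.float32) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(n_maps, dtype=dtype)
        self.params["beta"] = np.zeros(n_maps, dtype=dtype)
        self.running_mean = np.zeros(n_maps, dtype=np.float64)
        self.running_var = np.ones(n_maps, dtype=np.float64)

    def forward(self, x, training=False, rng=None):
        gamma = self.params["gamma"].astype(np.float64)
        beta = self.params["beta"].astype(np.float64)
        if training:
            x = np.ascontiguousarray(x)
            B, F, S, T = x.shape
            n = B * S * T
            xr = x.reshape(B, F, S * T)
            s1 = xr.sum(axis=(0, 2), dtype=np.float64)
            # per-(b,f) self dot maps to BLAS; accumulate rows in float64
            s2 = np.einsum("bfk,bfk->bf", xr, xr, optimize=True)\
                .sum(axis=0, dtype=np.float64)
            mu = s1 / n
            var = np.maximum(s2 / n - mu ** 2, 0.0)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu
            self.running_var = m * self.running_var + (1 - m) * var
            inv_std = 1.0 / np.sqrt(var + self.eps)
            self._x, self._mu, self._inv_std, self._n = x, mu, inv_std, n
            # single fused affine pass: y = a*x + c
            a = (gamma * inv_std).astype(x.dtype)[None, :, None, None]
            c = (beta - gamma * mu * inv_std).astype(x.dtype)[None, :, None, None]
            return a * x + c
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        a = (gamma * inv).astype(x.dtype)[None, :, None, None]
        c = (beta - gamma * self.running_mean * inv).astype(x.dtype)[None, :, None, None]
        return a * x + c

    def backward(self, dy):
        x, mu, inv_std, n = self._x, self._mu, self._inv_std, self._n
        gamma = self.params["gamma"]
        B, F, S, T = x.shape
        dyr = np.ascontiguousarray(dy).reshape(B, F, S * T)
        # dgamma = sum(dy*xhat) expressed through raw-x sums so that xhat is
        # never materialized: sum(dy*xhat) = inv*(sum(dy*x) - mu*sum(dy))
        sxy = np.einsum("bfk,bfk->bf", dyr, x.reshape(B, F, S * T),
                        optimize=True).sum(axis=0, dtype=np.float64)
        dbeta = dyr.sum(axis=(0, 2), dtype=np.float64)
        dgamma = inv_std * (sxy - mu * dbeta)
        self.grads["gamma"] = dgamma.astype(gamma.dtype)
        self.grads["beta"] = dbeta.astype(gamma.dtype)
        # dx = coeff*(n*dy - dbeta - xhat*dgamma) rearranged as a per-map
        # affine combination of dy and x (two fused passes over the volume)
        coeff = gamma.astype(np.float64) * inv_std / n
        a = (coeff * n).astype(dy.dtype)[None, :, None, None]
        c = (-coeff * dgamma * inv_std).astype(dy.dtype)[None, :, None, None]
        d = (coeff * (dgamma * inv_std * mu - dbeta)).astype(dy.dtype)
        dx = a * dy
        dx += c * x
        dx += d[None, :, None, None]
        return dx


class ELU(Layer):
    def __init__(self, alpha: float = 1.0) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training=False, rng=None):
        y = elu(x, self.alpha)
        self._x, self._y = x, y
        return y.astype(x.dtype, copy=False)

    def backward(self, dy):
        return dy * elu_grad(self._x, self._y, self.alpha)


class AvgPoolTime(Layer):
    """Average pooling along time with stride = width; remainder truncated."""

    def __init__(self, width: int) -> None:
        super().__init__()
        if width < 1:
            raise ValueError("pool width must be positive")
        self.width = width

    def forward(self, x, training=False, rng=None):
        B, F, S, T = x.shape
        p = self.width
        T2 = T // p
        if T2 < 1:
            raise ValueError(f"time extent {T} shorter than pool width {p}")
        self._in_T = T
        return x[..., :T2 * p].reshape(B, F, S, T2, p).mean(axis=-1)

    def backward(self, dy):
        p = self.width
        dx = np.zeros(dy.shape[:3] + (self._in_T,), dtype=dy.dtype)
        dx[..., :dy.shape[3] * p] = np.repeat(dy / p, p, axis=3)
        return dx


class Dropout(Layer):
    """Inverted per-element dropout; identity in evaluation mode."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class SEBlock(Layer):
    """Squeeze-and-excitation channel attention on (B,F,S,T) volumes.

    Squeeze: global average per map. Excitation: FC to F/r with ReLU, FC back
    to F with sigmoid. Scale: per-map multiplication by the resulting gate,
    which lies strictly in (0,1), so the rescaling is contractive.
    """

    def __init__(self, n_maps: int, reduction_ratio: int, *, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        if reduction_ratio < 1 or n_maps % reduction_ratio != 0:
            raise ValueError(
                f"reduction ratio {reduction_ratio} must divide {n_maps} maps"
            )
        rng = rng or np.random.default_rng()
        hidden = n_maps // reduction_ratio
        self.params["W1"] = _glorot(rng, (hidden, n_maps), n_maps, hidden, dtype)
        self.params["W2"] = _glorot(rng, (n_maps, hidden), hidden, n_maps, dtype)
        if bias:
            self.params["b1"] = np.zeros(hidden, dtype=dtype)
            self.params["b2"] = np.zeros(n_maps, dtype=dtype)

    def gate(self, x: np.ndarray) -> np.ndarray:
        """Compute the (B, F) gate vector for a volume without scaling it."""
        s = x.mean(axis=(2, 3))
        h_pre = s @ self.params["W1"].T
        if "b1" in self.params:
            h_pre = h_pre + self.params["b1"]
        h = np.maximum(h_pre, 0.0)
        g_pre = h @ self.params["W2"].T
        if "b2" in self.params:
            g_pre = g_pre + self.params["b2"]
        g = sigmoid(g_pre)
        self._s, self._h_pre, self._h, self._g = s, h_pre, h, g
        return g

    def forward(self, x, training=False, rng=None):
        g = self.gate(x)
        self._x = x
        return x * g[:, :, None, None]

    def backward(self, dy):
        x = self._x
        s, h_pre, h, g = self._s, self._h_pre, self._h, self._g
        W1, W2 = self.params["W1"], self.params["W2"]
        dx = dy * g[:, :, None, None]
        dg = (dy * x).sum(axis=(2, 3))
        dg_pre = dg * g * (1.0 - g)
        self.grads["W2"] = (dg_pre.T @ h).astype(W2.dtype)
        if "b2" in self.params:
            self.grads["b2"] = dg_pre.sum(axis=0).astype(W2.dtype)
        dh = dg_pre @ W2
        dh_pre = dh * (h_pre > 0)
        self.grads["W1"] = (dh_pre.T @ s).astype(W1.dtype)
        if "b1" in self.params:
            self.grads["b1"] = dh_pre.sum(axis=0).astype(W1.dtype)
        ds = dh_pre @ W1
        dx = dx + ds[:, :, None, None] / (x.shape[2] * x.shape[3])
        return dx.astype(x.dtype, copy=False)


class Dense(Layer):
    """Fully connected (B, n_in) -> (B, n_out); kernel max-norm 0.25."""

    MAX_NORM = 0.25

    def __init__(self, n_in: int, n_out: int, *, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["W"] = _glorot(rng, (n_out, n_in), n_in, n_out, dtype)
        if bias:
            self.params["b"] = np.zeros(n_out, dtype=dtype)

    def forward(self, x, training=False, rng=None):
        self._x = x
        y = x @ self.params["W"].T
        if "b" in self.params:
            y = y + self.params["b"]
        return y

    def backward(self, dy):
        W = self.params["W"]
        self.grads["W"] = (dy.T @ self._x).astype(W.dtype)
        if "b" in self.params:
            self.grads["b"] = dy.sum(axis=0).astype(W.dtype)
        return (dy @ W).astype(self._x.dtype)

    def apply_constraints(self):
        W = self.params["W"]
        norms = np.sqrt((W ** 2).sum(axis=1, keepdims=True))
        np.multiply(W, np.minimum(1.0, self.MAX_NORM / np.maximum(norms, 1e-12)),
                    out=W)
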