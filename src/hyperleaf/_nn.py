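"""Minimal CPU neural-network engine (numpy) used by the lcnet module.

Implements exactly the layer vocabulary the architectures need: N-d
convolution (dense and depthwise) via im2col/GEMM with a transposed-conv
backward pass, batch normalization, ReLU, max/average pooling, channel
shuffle/split/concat (ShuffleNetV2 units), dropout, linear, softmax
cross-entropy, and Adam.  Everything is float32 and fully seeded; there is
no autograd — each layer carries its own analytic backward.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter", "Layer", "Sequential", "Conv", "BatchNorm", "ReLU",
    "MaxPool", "AdaptiveAvgPoolDepth", "FoldDepth", "GlobalAvgPool",
    "Dropout", "Linear", "ChannelShuffle", "ShuffleBasicUnit",
    "ShuffleDownUnit", "softmax_cross_entropy", "Adam",
    "shuffle_permutation",
]


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    name: str = ""

    def params(self) -> list[Parameter]:
        return []

    def buffers(self) -> list[np.ndarray]:
        return []

    def atomic(self) -> list["Layer"]:
        return [self]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# convolution plumbing
# ---------------------------------------------------------------------------

def conv_out_len(L: int, kernel: int = 3, stride: int = 1, padding: int = 1) -> int:
    """Output length of a strided convolution: floor((L + 2p - k)/s) + 1."""
    if L < 1:
        raise ValueError("input length must be >= 1")
    out = (L + 2 * padding - kernel) // stride + 1
    if out < 1:
        raise ValueError(
            f"convolution output length {out} < 1 for L={L}, k={kernel}, "
            f"s={stride}, p={padding}"
        )
    return out


try:  # JIT-compiled im2col/col2im data movement; numpy fallback below
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a standard dependency
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco


@_njit(fastmath=True)
def _pack3(xp, cols, s0, s1, s2, od, oh, ow, k0, k1, k2):
    B, C = xp.shape[0], xp.shape[1]
    for b in range(B):
        for z in range(od):
            for y in range(oh):
                for x in range(ow):
                    row = ((b * od + z) * oh + y) * ow + x
                    col = 0
                    for c in range(C):
                        for kz in range(k0):
                            for ky in range(k1):
                                for kx in range(k2):
                                    cols[row, col] = xp[
                                        b, c, z * s0 + kz, y * s1 + ky, x * s2 + kx
                                    ]
                                    col += 1


@_njit(fastmath=True)
def _pack2(xp, cols, s0, s1, oh, ow, k0, k1):
    B, C = xp.shape[0], xp.shape[1]
    for b in range(B):
        for y in range(oh):
            for x in range(ow):
                row = (b * oh + y) * ow + x
                col = 0
                for c in range(C):
                    for ky in range(k0):
                        for kx in range(k1):
                            cols[row, col] = xp[b, c, y * s0 + ky, x * s1 + kx]
                            col += 1


@_njit(fastmath=True)
def _scatter3(dcols, dxp, s0, s1, s2, od, oh, ow, k0, k1, k2):
    B, C = dxp.shape[0], dxp.shape[1]
    for b in range(B):
        for z in range(od):
            for y in range(oh):
                for x in range(ow):
                    row = ((b * od + z) * oh + y) * ow + x
                    col = 0
                    for c in range(C):
                        for kz in range(k0):
                            for ky in range(k1):
                                for kx in range(k2):
                                    dxp[
                                        b, c, z * s0 + kz, y * s1 + ky, x * s2 + kx
                                    ] += dcols[row, col]
                                    col += 1


@_njit(fastmath=True)
def _scatter2(dcols, dxp, s0, s1, oh, ow, k0, k1):
    B, C = dxp.shape[0], dxp.shape[1]
    for b in range(B):
        for y in range(oh):
            for x in range(ow):
                row = (b * oh + y) * ow + x
                col = 0
                for c in range(C):
                    for ky in range(k0):
                        for kx in range(k1):
                            dxp[b, c, y * s0 + ky, x * s1 + kx] += dcols[row, col]
                            col += 1


@_njit(fastmath=True)
def _dw3_fwd(xp, W, y, s0, s1, s2):
    B, C, od, oh, ow = y.shape
    k0, k1, k2 = W.shape[1], W.shape[2], W.shape[3]
    for b in range(B):
        for c in range(C):
            for z in range(od):
                for yy in range(oh):
                    for xx in range(ow):
                        acc = 0.0
                        for kz in range(k0):
                            for ky in range(k1):
                                for kx in range(k2):
                                    acc += W[c, kz, ky, kx] * xp[
                                        b, c, z * s0 + kz, yy * s1 + ky, xx * s2 + kx
                                    ]
                        y[b, c, z, yy, xx] = acc


@_njit(fastmath=True)
def _dw3_bwd(xp, W, dy, dW, dxp, s0, s1, s2, with_dx):
    B, C, od, oh, ow = dy.shape
    k0, k1, k2 = W.shape[1], W.shape[2], W.shape[3]
    for b in range(B):
        for c in range(C):
            for z in range(od):
                for yy in range(oh):
                    for xx in range(ow):
                        g = dy[b, c, z, yy, xx]
                        for kz in range(k0):
                            for ky in range(k1):
                                for kx in range(k2):
                                    dW[c, kz, ky, kx] += g * xp[
                                        b, c, z * s0 + kz, yy * s1 + ky, xx * s2 + kx
                                    ]
                                    if with_dx:
                                        dxp[
                                            b, c, z * s0 + kz, yy * s1 + ky,
                                            xx * s2 + kx
                                        ] += g * W[c, kz, ky, kx]


@_njit(fastmath=True)
def _dw2_fwd(xp, W, y, s0, s1):
    B, C, oh, ow = y.shape
    k0, k1 = W.shape[1], W.shape[2]
    for b in range(B):
        for c in range(C):
            for yy in range(oh):
                for xx in range(ow):
                    acc = 0.0
                    for ky in range(k0):
                        for kx in range(k1):
                            acc += W[c, ky, kx] * xp[b, c, yy * s0 + ky, xx * s1 + kx]
                    y[b, c, yy, xx] = acc


@_njit(fastmath=True)
def _dw2_bwd(xp, W, dy, dW, dxp, s0, s1, with_dx):
    B, C, oh, ow = dy.shape
    k0, k1 = W.shape[1], W.shape[2]
    for b in range(B):
        for c in range(C):
            for yy in range(oh):
                for xx in range(ow):
                    g = dy[b, c, yy, xx]
                    for ky in range(k0):
                        for kx in range(k1):
                            dW[c, ky, kx] += g * xp[b, c, yy * s0 + ky, xx * s1 + kx]
                            if with_dx:
                                dxp[b, c, yy * s0 + ky, xx * s1 + kx] += g * W[c, ky, kx]


@_njit(fastmath=True)
def _bn_moments(x3, s1, s2):
    # x3: (B, C, S) contiguous; accumulates per-channel sum and sum-of-squares
    B, C, S = x3.shape
    for b in range(B):
        for c in range(C):
            a1 = 0.0
            a2 = 0.0
            for s in range(S):
                v = x3[b, c, s]
                a1 += v
                a2 += v * v
            s1[c] += a1
            s2[c] += a2


@_njit(fastmath=True)
def _bn_dx(dy3, x3, av, bv, cv, dx3):
    # dx = a[c]*dy + b[c]*x + c[c], one fused pass
    B, C, S = dy3.shape
    for b in range(B):
        for c in range(C):
            a_, b_, c_ = av[c], bv[c], cv[c]
            for s in range(S):
                dx3[b, c, s] = a_ * dy3[b, c, s] + b_ * x3[b, c, s] + c_


@_njit(fastmath=True)
def _bn_relu_grads(dy3, y3, x3, s_dy, s_dy_x):
    # reductions of the ReLU-masked upstream gradient (mask = y > 0)
    B, C, S = dy3.shape
    for b in range(B):
        for c in range(C):
            a1 = 0.0
            a2 = 0.0
            for s in range(S):
                if y3[b, c, s] > 0:
                    g = dy3[b, c, s]
                    a1 += g
                    a2 += g * x3[b, c, s]
            s_dy[c] += a1
            s_dy_x[c] += a2


@_njit(fastmath=True)
def _bn_relu_dx(dy3, y3, x3, av, bv, cv, dx3):
    # dx = a[c]*(masked dy) + b[c]*x + c[c]
    B, C, S = dy3.shape
    for b in range(B):
        for c in range(C):
            a_, b_, c_ = av[c], bv[c], cv[c]
            for s in range(S):
                g = dy3[b, c, s] if y3[b, c, s] > 0 else 0.0
                dx3[b, c, s] = a_ * g + b_ * x3[b, c, s] + c_


@_njit(fastmath=True)
def _bn_grads(dy3, x3, s_dy, s_dy_x):
    B, C, S = dy3.shape
    for b in range(B):
        for c in range(C):
            a1 = 0.0
            a2 = 0.0
            for s in range(S):
                g = dy3[b, c, s]
                a1 += g
                a2 += g * x3[b, c, s]
            s_dy[c] += a1
            s_dy_x[c] += a2


def _pad_spatial(x, padding, value=0.0):
    if all(p == 0 for p in padding):
        return x
    pads = [(0, 0), (0, 0)] + [(p, p) for p in padding]
    return np.pad(x, pads, constant_values=value)


def _windows(xp, kernel, stride):
    """Strided sliding windows over the spatial axes of (B, C, *S)."""
    d = len(kernel)
    win = np.lib.stride_tricks.sliding_window_view(
        xp, window_shape=kernel, axis=tuple(range(2, 2 + d))
    )
    sl = (slice(None), slice(None)) + tuple(slice(None, None, s) for s in stride)
    return win[sl]  # (B, C, *So, *K)


def _dense_conv(xp, W, stride):
    """Valid dense convolution of pre-padded input; returns (y, cols, out_sp)."""
    d = W.ndim - 2
    kernel = W.shape[2:]
    B, C = xp.shape[:2]
    out_sp = tuple(
        (L - k) // s + 1 for L, k, s in zip(xp.shape[2:], kernel, stride)
    )
    P = int(np.prod(out_sp))
    if _HAVE_NUMBA:
        xp = np.ascontiguousarray(xp, dtype=np.float32)
        cols = np.empty((B * P, C * int(np.prod(kernel))), dtype=np.float32)
        if d == 3:
            _pack3(xp, cols, *stride, *out_sp, *kernel)
        else:
            _pack2(xp, cols, *stride, *out_sp, *kernel)
    else:
        win = _windows(xp, kernel, stride)
        cols = np.moveaxis(win, 1, 1 + d).reshape(B * P, -1)
    y = cols @ W.reshape(W.shape[0], -1).T
    y = np.moveaxis(y.reshape((B,) + out_sp + (W.shape[0],)), -1, 1)
    return np.ascontiguousarray(y), cols, out_sp


def _depthwise_conv(xp, W, stride):
    """Valid depthwise convolution; W is (C, *K)."""
    d = W.ndim - 1
    win = _windows(xp, W.shape[1:], stride)
    B, C = win.shape[:2]
    out_sp = win.shape[2:2 + d]
    winr = win.reshape(B, C, int(np.prod(out_sp)), -1)
    y = np.einsum("bcpk,ck->bcp", winr, W.reshape(C, -1))
    return np.ascontiguousarray(y.reshape((B, C) + out_sp)), winr, out_sp


def _col2im(dcols, xp_shape, out_sp, kernel, stride):
    """Scatter-add per-window gradients back onto the padded input.

    ``dcols`` is (B, *out_sp, C, *K); iterates over the kernel offsets (a few
    dozen vectorized slice-adds) instead of building a stride-1 im2col, which
    keeps memory flat."""
    B = dcols.shape[0]
    d = len(kernel)
    C = dcols.shape[1 + d]
    dxp = np.zeros((B, C) + tuple(xp_shape[2:]), dtype=np.float32)
    for koff in np.ndindex(*kernel):
        sl = (slice(None), slice(None)) + tuple(
            slice(k, k + s * L, s) for k, s, L in zip(koff, stride, out_sp)
        )
        patch = dcols[(slice(None),) + (slice(None),) * d + (slice(None),) + koff]
        dxp[sl] += np.moveaxis(patch, -1, 1)
    return dxp


class Conv(Layer):
    """N-d convolution (2 or 3 spatial dims), dense or depthwise, bias-free by
    default (always followed by BN in these architectures)."""

    def __init__(self, in_ch, out_ch, kernel, stride=None, padding=None,
                 depthwise=False, bias=False, rng=None, name="",
                 needs_input_grad=True):
        kernel = tuple(kernel)
        d = len(kernel)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel = kernel
        self.stride = tuple(stride) if stride is not None else (1,) * d
        self.padding = tuple(padding) if padding is not None else tuple(k // 2 for k in kernel)
        self.depthwise = depthwise
        self.needs_input_grad = needs_input_grad
        self.name = name
        rng = rng or np.random.default_rng(0)
        if depthwise:
            if in_ch != out_ch:
                raise ValueError("depthwise conv needs in_ch == out_ch")
            fan_in = int(np.prod(kernel))
            shape = (in_ch,) + kernel
        else:
            fan_in = in_ch * int(np.prod(kernel))
            shape = (out_ch, in_ch) + kernel
        self.W = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), shape))
        self.b = Parameter(np.zeros(out_ch)) if bias else None
        self._cache = None
        self.last_out_spatial = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def param_count_formula(self) -> int:
        """Closed-form parameter count: k-volume x C_in x C_out (/C for
        depthwise), plus C_out if biased."""
        kv = int(np.prod(self.kernel))
        n = kv * self.out_ch if self.depthwise else kv * self.in_ch * self.out_ch
        return n + (self.out_ch if self.b is not None else 0)

    def macs(self, out_spatial) -> int:
        kv = int(np.prod(self.kernel))
        per_pos = kv * self.out_ch if self.depthwise else kv * self.in_ch * self.out_ch
        return per_pos * int(np.prod(out_spatial))

    def forward(self, x, training):
        xp = _pad_spatial(x.astype(np.float32, copy=False), self.padding)
        if self.depthwise:
            if _HAVE_NUMBA:
                xp = np.ascontiguousarray(xp)
                out_sp = tuple(
                    (L - k) // s + 1
                    for L, k, s in zip(xp.shape[2:], self.kernel, self.stride)
                )
                y = np.empty(xp.shape[:2] + out_sp, dtype=np.float32)
                if len(self.kernel) == 3:
                    _dw3_fwd(xp, self.W.value, y, *self.stride)
                else:
                    _dw2_fwd(xp, self.W.value, y, *self.stride)
                self._cache = ("dw_nb", xp, x.shape, xp.shape)
            else:
                y, winr, out_sp = _depthwise_conv(xp, self.W.value, self.stride)
                self._cache = ("dw", winr, x.shape, xp.shape)
        else:
            y, cols, out_sp = _dense_conv(xp, self.W.value, self.stride)
            self._cache = ("dense", cols, x.shape, xp.shape)
        if self.b is not None:
            y += self.b.value.reshape((1, -1) + (1,) * len(out_sp))
        self.last_out_spatial = out_sp
        return y

    def backward(self, dy):
        kind, cache, x_shape, xp_shape = self._cache
        d = len(self.kernel)
        B = dy.shape[0]
        out_sp = dy.shape[2:]
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0,) + tuple(range(2, 2 + d)))
        # weight gradient and per-window gradients from the stored im2col
        if kind == "dense":
            dymat = np.moveaxis(dy, 1, 1 + d).reshape(B * int(np.prod(out_sp)), -1)
            self.W.grad += (dymat.T @ cache).reshape(self.W.value.shape)
            if not self.needs_input_grad:
                self._cache = None
                return None
            dcols_flat = dymat @ self.W.value.reshape(self.W.value.shape[0], -1)
            if _HAVE_NUMBA:
                dxp = np.zeros((B, self.in_ch) + tuple(xp_shape[2:]), dtype=np.float32)
                if d == 3:
                    _scatter3(dcols_flat, dxp, *self.stride, *out_sp, *self.kernel)
                else:
                    _scatter2(dcols_flat, dxp, *self.stride, *out_sp, *self.kernel)
                crop = (slice(None), slice(None)) + tuple(
                    slice(p, p + L) for p, L in zip(self.padding, x_shape[2:])
                )
                self._cache = None
                return np.ascontiguousarray(dxp[crop])
            dcols = dcols_flat.reshape(
                (B,) + tuple(out_sp) + (self.in_ch,) + self.kernel
            )
        elif kind == "dw_nb":
            xp = cache
            dy = np.ascontiguousarray(dy, dtype=np.float32)
            dW = np.zeros_like(self.W.value)
            dxp = (
                np.zeros(xp.shape, dtype=np.float32)
                if self.needs_input_grad else np.zeros((1,) * xp.ndim, np.float32)
            )
            if d == 3:
                _dw3_bwd(xp, self.W.value, dy, dW, dxp, *self.stride,
                         self.needs_input_grad)
            else:
                _dw2_bwd(xp, self.W.value, dy, dW, dxp, *self.stride,
                         self.needs_input_grad)
            self.W.grad += dW
            self._cache = None
            if not self.needs_input_grad:
                return None
            crop = (slice(None), slice(None)) + tuple(
                slice(p, p + L) for p, L in zip(self.padding, x_shape[2:])
            )
            return np.ascontiguousarray(dxp[crop])
        else:
            dyr = dy.reshape(B, self.in_ch, -1)
            self.W.grad += np.einsum("bcpk,bcp->ck", cache, dyr).reshape(
                self.W.value.shape
            )
            if not self.needs_input_grad:
                self._cache = None
                return None
            # (B, C, P, Kf) per-window grads; re-layout to (B, *out, C, *K)
            dwin = dyr[..., None] * self.W.value.reshape(1, self.in_ch, 1, -1)
            dcols = np.moveaxis(
                dwin.reshape((B, self.in_ch) + tuple(out_sp) + self.kernel), 1, 1 + d
            )
        dxp = _col2im(dcols, xp_shape, out_sp, self.kernel, self.stride)
        crop = (slice(None), slice(None)) + tuple(
            slice(p, p + L) for p, L in zip(self.padding, x_shape[2:])
        )
        self._cache = None
        return np.ascontiguousarray(dxp[crop])


def _chan_dot(a, b):
    """Per-channel dot product sum_{all but axis 1} a*b, without copies."""
    sub = "bc" + "xyz"[: a.ndim - 2]
    return np.einsum(f"{sub},{sub}->c", a, b)


class BatchNorm(Layer):
    """Batch normalization, optionally with a fused trailing ReLU
    (numerically identical to BN followed by ReLU; saves a tensor pass)."""

    def __init__(self, C, eps=1e-5, momentum=0.1, relu=False, name=""):
        self.C = C
        self.eps = eps
        self.momentum = momentum
        self.relu = relu
        self.gamma = Parameter(np.ones(C))
        self.beta = Parameter(np.zeros(C))
        self.running_mean = np.zeros(C, dtype=np.float32)
        self.running_var = np.ones(C, dtype=np.float32)
        self.name = name
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def param_count_formula(self):
        return 2 * self.C

    def _shape(self, x):
        return (1, self.C) + (1,) * (x.ndim - 2)

    def forward(self, x, training):
        axes = (0,) + tuple(range(2, x.ndim))
        if training:
            # single-pass moments: E[x], E[x^2]
            n = x.size // self.C
            if _HAVE_NUMBA and x.flags.c_contiguous:
                s1 = np.zeros(self.C, dtype=np.float64)
                s2 = np.zeros(self.C, dtype=np.float64)
                _bn_moments(x.reshape(x.shape[0], self.C, -1), s1, s2)
            else:
                s1 = x.sum(axis=axes)
                s2 = _chan_dot(x, x)
            mean = (s1 / n).astype(np.float32)
            var = (s2 / n - (s1 / n) ** 2).astype(np.float32)
            np.maximum(var, 0.0, out=var)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        sh = self._shape(x)
        inv = 1.0 / np.sqrt(var + self.eps)
        # fused y = x * (gamma*inv) + (beta - gamma*inv*mean)
        a = (self.gamma.value * inv).astype(np.float32)
        b = (self.beta.value - a * mean).astype(np.float32)
        y = x * a.reshape(sh) + b.reshape(sh)
        y = y.astype(np.float32, copy=False)
        if self.relu:
            np.maximum(y, 0.0, out=y)
        if training:
            self._cache = (x, mean, inv, axes, y if self.relu else None)
        else:
            self._cache = None
        return y

    def backward(self, dy):
        x, mean, inv, axes, y_relu = self._cache
        n = dy.size // self.C
        fused = (
            _HAVE_NUMBA and dy.flags.c_contiguous and x.flags.c_contiguous
            and (y_relu is None or y_relu.flags.c_contiguous)
        )
        if fused:
            B = dy.shape[0]
            dy3 = dy.reshape(B, self.C, -1)
            x3 = x.reshape(B, self.C, -1)
            sum_dy = np.zeros(self.C, dtype=np.float64)
            sum_dy_x = np.zeros(self.C, dtype=np.float64)
            if self.relu:
                y3 = y_relu.reshape(B, self.C, -1)
                _bn_relu_grads(dy3, y3, x3, sum_dy, sum_dy_x)
            else:
                _bn_grads(dy3, x3, sum_dy, sum_dy_x)
        else:
            if self.relu:
                dy = dy * (y_relu > 0)
            sum_dy = dy.sum(axis=axes)
            sum_dy_x = _chan_dot(dy, x)
        sum_dy_xhat = (sum_dy_x - mean * sum_dy) * inv
        self.gamma.grad += sum_dy_xhat.astype(np.float32)
        self.beta.grad += sum_dy.astype(np.float32)
        g = self.gamma.value * inv
        # dx = g*dy - (g/n)*sum_dy - (g/n)*xhat*sum_dy_xhat, fused as a*dy + b*x + c
        a = np.asarray(g, dtype=np.float32)
        b = np.asarray(-(g * inv * sum_dy_xhat) / n, dtype=np.float32)
        c = np.asarray(-(g * sum_dy) / n - (-(g * inv * sum_dy_xhat) / n) * mean,
                       dtype=np.float32)
        self._cache = None
        if fused:
            dx3 = np.empty_like(dy3)
            if self.relu:
                _bn_relu_dx(dy3, y3, x3, a, b, c, dx3)
            else:
                _bn_dx(dy3, x3, a, b, c, dx3)
            return dx3.reshape(dy.shape)
        sh = self._shape(dy)
        dx = dy * a.reshape(sh) + x * b.reshape(sh) + c.reshape(sh)
        return dx.astype(np.float32, copy=False)


class ReLU(Layer):
    def forward(self, x, training):
        y = np.maximum(x, 0.0)
        self._y = y
        return y

    def backward(self, dy):
        return dy * (self._y > 0)


class MaxPool(Layer):
    """k x k (x k) max pooling with -inf padding (ShuffleNetV2 stems)."""

    def __init__(self, kernel, stride, padding, name=""):
        self.kernel = tuple(kernel)
        self.stride = tuple(stride)
        self.padding = tuple(padding)
        self.name = name

    def forward(self, x, training):
        xp = _pad_spatial(x, self.padding, value=-np.inf)
        win = _windows(xp, self.kernel, self.stride)
        d = len(self.kernel)
        B, C = win.shape[:2]
        out_sp = win.shape[2:2 + d]
        winr = win.reshape(B, C, int(np.prod(out_sp)), -1)
        self._arg = winr.argmax(axis=-1)
        y = np.take_along_axis(winr, self._arg[..., None], axis=-1)[..., 0]
        self._geom = (x.shape, xp.shape, out_sp)
        return np.ascontiguousarray(y.reshape((B, C) + out_sp))

    def backward(self, dy):
        x_shape, xp_shape, out_sp = self._geom
        d = len(self.kernel)
        B, C = dy.shape[:2]
        P = int(np.prod(out_sp))
        dxp = np.zeros((B, C) + xp_shape[2:], dtype=np.float32)
        # unravel window argmax into padded-input coordinates
        karg = np.array(np.unravel_index(self._arg.reshape(B, C, P), self.kernel))
        pos = np.array(np.unravel_index(np.arange(P), out_sp))  # (d, P)
        idx = [
            karg[a] + (pos[a] * self.stride[a])[None, None, :] for a in range(d)
        ]
        bb = np.arange(B)[:, None, None]
        cc = np.arange(C)[None, :, None]
        np.add.at(dxp, (bb, cc, *idx), dy.reshape(B, C, P))
        crop = (slice(None), slice(None)) + tuple(
            slice(p, p + L) for p, L in zip(self.padding, x_shape[2:])
        )
        return np.ascontiguousarray(dxp[crop])


class AdaptiveAvgPoolDepth(Layer):
    """Adaptive average pooling over the spectral (depth) axis only:
    (B, C, D, H, W) -> (B, C, out, H, W)."""

    def __init__(self, out: int = 2, name=""):
        self.out = out
        self.name = name

    def forward(self, x, training):
        B, C, D, H, W = x.shape
        self._in_depth = D
        bins = [(int(np.floor(i * D / self.out)), int(np.ceil((i + 1) * D / self.out)))
                for i in range(self.out)]
        self._bins = bins
        y = np.stack([x[:, :, a:b].mean(axis=2) for a, b in bins], axis=2)
        return np.ascontiguousarray(y.astype(np.float32))

    def backward(self, dy):
        B, C, _, H, W = dy.shape
        dx = np.zeros((B, C, self._in_depth, H, W), dtype=np.float32)
        for i, (a, b) in enumerate(self._bins):
            dx[:, :, a:b] += dy[:, :, i:i + 1] / (b - a)
        return dx


class FoldDepth(Layer):
    """Fold the depth axis into channels: (B, C, D, H, W) -> (B, C*D, H, W)
    (or -> (B, C*D, 1, H, W) when `keep_3d`), the hybrid's 3D-to-2D bridge."""

    def __init__(self, keep_3d: bool = False, name=""):
        self.keep_3d = keep_3d
        self.name = name

    def forward(self, x, training):
        B, C, D, H, W = x.shape
        self._shape = x.shape
        y = x.reshape(B, C * D, H, W)
        if self.keep_3d:
            y = y.reshape(B, C * D, 1, H, W)
        return y

    def backward(self, dy):
        return dy.reshape(self._shape)


class GlobalAvgPool(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, dy):
        sp = self._shape[2:]
        P = int(np.prod(sp))
        return np.broadcast_to(
            dy.reshape(dy.shape + (1,) * len(sp)), self._shape
        ).astype(np.float32) / P


class Dropout(Layer):
    def __init__(self, p=0.2, name=""):
        self.p = p
        self.rng = np.random.default_rng(0)
        self.name = name

    def forward(self, x, training):
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return (x * self._mask).astype(np.float32)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(np.float32)


class Linear(Layer):
    def __init__(self, in_f, out_f, rng=None, name=""):
        rng = rng or np.random.default_rng(0)
        self.in_f, self.out_f = in_f, out_f
        self.W = Parameter(rng.normal(0.0, np.sqrt(2.0 / in_f), (out_f, in_f)))
        self.b = Parameter(np.zeros(out_f))
        self.name = name

    def params(self):
        return [self.W, self.b]

    def param_count_formula(self):
        return self.in_f * self.out_f + self.out_f

    def macs(self, _=None):
        return self.in_f * self.out_f

    def forward(self, x, training):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy):
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value


def shuffle_permutation(C: int, groups: int) -> np.ndarray:
    """Channel-shuffle permutation: reshape (groups, C/groups), transpose,
    flatten.  A fixed bijection on channel indices."""
    if C % groups:
        raise ValueError(f"channels {C} not divisible by groups {groups}")
    return np.arange(C).reshape(groups, C // groups).T.ravel()


class ChannelShuffle(Layer):
    def __init__(self, C, groups=2, name=""):
        self.perm = shuffle_permutation(C, groups)
        self.inv = np.argsort(self.perm)
        self.name = name

    def forward(self, x, training):
        return np.ascontiguousarray(x[:, self.perm])

    def backward(self, dy):
        return np.ascontiguousarray(dy[:, self.inv])


class Sequential(Layer):
    def __init__(self, layers, name=""):
        self.layers = list(layers)
        self.name = name

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def buffers(self):
        return [b for l in self.layers for b in l.buffers()]

    def atomic(self):
        return [a for l in self.layers for a in l.atomic()]

    def forward(self, x, training):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def _branch(in_ch, out_ch, d, stride_tuple, rng, with_first_pw=True):
    """ShuffleNetV2 right branch: 1x1 BN ReLU, 3x3 depthwise BN, 1x1 BN ReLU."""
    one = (1,) * d
    k = (3,) * d
    layers = []
    if with_first_pw:
        layers += [Conv(in_ch, out_ch, one, one, (0,) * d, rng=rng),
                   BatchNorm(out_ch, relu=True)]
        dw_ch = out_ch
    else:
        dw_ch = in_ch
    layers += [
        Conv(dw_ch, dw_ch, k, stride_tuple, (1,) * d, depthwise=True, rng=rng),
        BatchNorm(dw_ch),
        Conv(dw_ch, out_ch, one, one, (0,) * d, rng=rng),
        BatchNorm(out_ch, relu=True),
    ]
    return Sequential(layers)


class ShuffleBasicUnit(Layer):
    """ShuffleNetV2 basic unit: channel split (half/half), one branch passes
    through, the other runs 1x1 -> depthwise 3x3 -> 1x1 (BN/ReLU as usual),
    concat, channel shuffle (groups = 2)."""

    def __init__(self, C, d=2, rng=None, name=""):
        if C % 2:
            raise ValueError("basic unit needs even channels")
        self.C = C
        self.half = C // 2
        self.branch = _branch(self.half, self.half, d, (1,) * d, rng)
        self.shuffle = ChannelShuffle(C, 2)
        self.name = name

    def params(self):
        return self.branch.params()

    def buffers(self):
        return self.branch.buffers()

    def atomic(self):
        return self.branch.atomic() + [self.shuffle]

    def forward(self, x, training):
        x1, x2 = x[:, : self.half], x[:, self.half:]
        y2 = self.branch.forward(np.ascontiguousarray(x2), training)
        y = np.concatenate([x1, y2], axis=1)
        return self.shuffle.forward(y, training)

    def backward(self, dy):
        dy = self.shuffle.backward(dy)
        d1, d2 = dy[:, : self.half], dy[:, self.half:]
        dx2 = self.branch.backward(np.ascontiguousarray(d2))
        return np.concatenate([d1, dx2], axis=1)


class ShuffleDownUnit(Layer):
    """ShuffleNetV2 downsampling unit: both branches see the full input and
    stride; concat doubles (or re-targets) the channel count, then shuffle."""

    def __init__(self, in_ch, out_ch, d=2, stride=None, rng=None, name=""):
        half = out_ch // 2
        self.in_ch, self.out_ch = in_ch, out_ch
        st = tuple(stride) if stride is not None else (2,) * d
        one = (1,) * d
        # left branch: depthwise (strided) BN, then 1x1 BN ReLU
        self.branch1 = Sequential([
            Conv(in_ch, in_ch, (3,) * d, st, (1,) * d, depthwise=True, rng=rng),
            BatchNorm(in_ch),
            Conv(in_ch, half, one, one, (0,) * d, rng=rng),
            BatchNorm(half, relu=True),
        ])
        self.branch2 = _branch(in_ch, half, d, st, rng)
        self.shuffle = ChannelShuffle(out_ch, 2)
        self.half = half
        self.name = name

    def params(self):
        return self.branch1.params() + self.branch2.params()

    def buffers(self):
        return self.branch1.buffers() + self.branch2.buffers()

    def atomic(self):
        return self.branch1.atomic() + self.branch2.atomic() + [self.shuffle]

    def forward(self, x, training):
        y1 = self.branch1.forward(x, training)
        y2 = self.branch2.forward(x, training)
        y = np.concatenate([y1, y2], axis=1)
        return self.shuffle.forward(y, training)

    def backward(self, dy):
        dy = self.shuffle.backward(dy)
        d1, d2 = dy[:, : self.half], dy[:, self.half:]
        dx1 = self.branch1.backward(np.ascontiguousarray(d1))
        dx2 = self.branch2.backward(np.ascontiguousarray(d2))
        return dx1 + dx2


# ---------------------------------------------------------------------------
# loss and optimizer
# ---------------------------------------------------------------------------

def softmax_cross_entropy(logits: np.ndarray, labels0: np.ndarray):
    """Mean cross-entropy over the batch; labels are 0-based ints.
    Returns (loss, dlogits)."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -float(np.log(np.maximum(p[np.arange(n), labels0], 1e-12)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels0] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


class Adam:
    """Adam with the standard defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.beta1) * (p.grad - m)
            v += (1 - self.beta2) * (p.grad ** 2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
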