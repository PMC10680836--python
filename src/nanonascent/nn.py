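"""Minimal neural-network engine for variable-length 1-D signals.

A small, self-contained layer library (1-D convolution, time-axis batch norm,
ReLU, bidirectional GRU, pooling head, dense layers) with hand-written
backpropagation and an AdamW optimizer.  Everything operates on a single
sequence at a time in time-major layout ``(T, channels)`` — there is no
padding and no batching, matching the classifier's batch-size-1 training
regime.  The GRU recurrence loops are JIT-compiled with numba when available
(a pure-numpy fallback gives identical results).

All gradients are *accumulated* into each layer's ``grads`` arrays; callers
zero them explicitly (this is what makes gradient accumulation over a window
of sequences trivial).  Correctness of every backward pass is pinned by
numerical-gradient tests.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class Layer:
    """Base class: parameters, accumulated gradients, optional buffers."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def add_param(self, name: str, value: np.ndarray) -> np.ndarray:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)
        return value

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def forward(self, x, train: bool = False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv1d(Layer):
    """Strided 1-D convolution, valid padding, time-major (T, C_in) -> (T_out, C_out)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        fan_in = kernel_size * in_channels
        self.add_param("W", rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, out_channels)))
        self.add_param("b", np.zeros(out_channels))

    def out_length(self, T: int) -> int:
        return (T - self.kernel_size) // self.stride + 1

    def forward(self, x, train: bool = False):
        T = x.shape[0]
        T_out = self.out_length(T)
        if T_out < 1:
            raise ValueError(f"input of length {T} too short for kernel {self.kernel_size}")
        # im2col: (T_out, kernel, C_in) -> (T_out, kernel*C_in)
        windows = np.lib.stride_tricks.sliding_window_view(x, self.kernel_size, axis=0)
        cols = windows[:: self.stride].transpose(0, 2, 1).reshape(T_out, -1)
        self._cols = cols
        self._T_in = T
        return cols @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        W = self.params["W"]
        self.grads["W"] += self._cols.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        dcols = (dy @ W.T).reshape(dy.shape[0], self.kernel_size, self.in_channels)
        dx = np.zeros((self._T_in, self.in_channels))
        T_out = dy.shape[0]
        for j in range(self.kernel_size):
            dx[j : j + self.stride * T_out : self.stride] += dcols[:, j, :]
        return dx


class BatchNorm1d(Layer):
    """Per-channel normalisation over the time axis of a single sequence.

    With batch size 1, statistics across examples are undefined; training mode
    therefore normalises each channel over the sequence's own time dimension
    and maintains running statistics (momentum 0.1) for evaluation.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.add_param("gamma", np.ones(channels))
        self.add_param("beta", np.zeros(channels))
        self.buffers["running_mean"] = np.zeros(channels)
        self.buffers["running_var"] = np.ones(channels)

    def forward(self, x, train: bool = False):
        self._train = train
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            m = self.momentum
            self.buffers["running_mean"] *= 1 - m
            self.buffers["running_mean"] += m * mu
            self.buffers["running_var"] *= 1 - m
            self.buffers["running_var"] += m * var
        else:
            mu = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._invstd
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        xhat = self._xhat
        self.grads["gamma"] += (dy * xhat).sum(axis=0)
        self.grads["beta"] += dy.sum(axis=0)
        dxhat = dy * self.params["gamma"]
        if not self._train:
            return dxhat * self._invstd
        N = dy.shape[0]
        return (
            self._invstd
            / N
            * (N * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        )


class ReLU(Layer):
    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


@njit(cache=True)
def _gru_forward_loop(xp, Whh, bhh, h0):  # pragma: no cover - jitted
    T = xp.shape[0]
    H = h0.shape[0]
    hs = np.empty((T, H))
    rs = np.empty((T, H))
    zs = np.empty((T, H))
    ns = np.empty((T, H))
    hpn = np.empty((T, H))
    h = h0.copy()
    for t in range(T):
        hp = h @ Whh
        for i in range(H):
            r = 1.0 / (1.0 + np.exp(-(xp[t, i] + hp[i] + bhh[i])))
            z = 1.0 / (1.0 + np.exp(-(xp[t, H + i] + hp[H + i] + bhh[H + i])))
            hp_n = hp[2 * H + i] + bhh[2 * H + i]
            n = np.tanh(xp[t, 2 * H + i] + r * hp_n)
            rs[t, i] = r
            zs[t, i] = z
            ns[t, i] = n
            hpn[t, i] = hp_n
            hs[t, i] = (1.0 - z) * n + z * h[i]
        h = hs[t].copy()
    return hs, rs, zs, ns, hpn


@njit(cache=True)
def _gru_backward_loop(dY, hs, rs, zs, ns, hpn, Whh, h0):  # pragma: no cover - jitted
    """Sequential part of BPTT: per-step pre-activation gradients.

    Returns dxp (grad wrt the input projection, also the rows whose GEMM with
    the inputs gives dW_ih) and dhp (rows whose GEMM with the previous hidden
    states gives dW_hh); the large matrix products are done by the caller in
    one BLAS call each.
    """
    T, H = dY.shape
    dxp = np.empty((T, 3 * H))
    dhp_all = np.empty((T, 3 * H))
    dh = np.zeros(H)
    for t in range(T - 1, -1, -1):
        h_prev = hs[t - 1] if t > 0 else h0
        r = rs[t]
        z = zs[t]
        n = ns[t]
        hp = hpn[t]
        for i in range(H):
            dhi = dh[i] + dY[t, i]
            dn = dhi * (1.0 - z[i])
            da_n = dn * (1.0 - n[i] * n[i])
            da_r = da_n * hp[i] * r[i] * (1.0 - r[i])
            da_z = dhi * (h_prev[i] - n[i]) * z[i] * (1.0 - z[i])
            dxp[t, i] = da_r
            dxp[t, H + i] = da_z
            dxp[t, 2 * H + i] = da_n
            dhp_all[t, i] = da_r
            dhp_all[t, H + i] = da_z
            dhp_all[t, 2 * H + i] = da_n * r[i]
            dh[i] = dhi * z[i]
        dh += Whh @ dhp_all[t]
    return dxp, dhp_all, dh


class GRU(Layer):
    """(Optionally bidirectional) GRU over a (T, I) sequence -> (T, D*H).

    Gate order in the stacked weight matrices is reset, update, candidate;
    separate input and recurrent biases are used (the two-bias convention).
    The output row at time t holds the forward hidden state after step t and,
    when bidirectional, the backward hidden state after processing t..T-1 —
    so the final forward state is ``y[-1, :H]`` and the final backward state
    is ``y[0, H:]``.
    """

    def __init__(self, input_size: int, hidden_size: int, bidirectional: bool,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.bidirectional = bidirectional
        bound = 1.0 / np.sqrt(hidden_size)
        for d in ("fwd", "bwd")[: 2 if bidirectional else 1]:
            self.add_param(f"W_ih_{d}", rng.uniform(-bound, bound, (input_size, 3 * hidden_size)))
            self.add_param(f"W_hh_{d}", rng.uniform(-bound, bound, (hidden_size, 3 * hidden_size)))
            self.add_param(f"b_ih_{d}", rng.uniform(-bound, bound, 3 * hidden_size))
            self.add_param(f"b_hh_{d}", rng.uniform(-bound, bound, 3 * hidden_size))
        self._h0 = np.zeros(hidden_size)

    def _run_direction(self, x, d: str):
        xp = x @ self.params[f"W_ih_{d}"] + self.params[f"b_ih_{d}"]
        return _gru_forward_loop(
            np.ascontiguousarray(xp), self.params[f"W_hh_{d}"], self.params[f"b_hh_{d}"], self._h0
        )

    def forward(self, x, train: bool = False):
        self._x = x
        self._state = {}
        self._state["fwd"] = self._run_direction(x, "fwd")
        if not self.bidirectional:
            return self._state["fwd"][0]
        self._x_rev = np.ascontiguousarray(x[::-1])
        self._state["bwd"] = self._run_direction(self._x_rev, "bwd")
        return np.concatenate(
            [self._state["fwd"][0], self._state["bwd"][0][::-1]], axis=1
        )

    def _backward_direction(self, dY, x, d: str):
        hs, rs, zs, ns, hpn = self._state[d]
        dxp, dhp, _ = _gru_backward_loop(
            np.ascontiguousarray(dY), hs, rs, zs, ns, hpn, self.params[f"W_hh_{d}"], self._h0
        )
        h_prev = np.vstack((self._h0[None, :], hs[:-1]))
        self.grads[f"W_hh_{d}"] += h_prev.T @ dhp
        self.grads[f"b_hh_{d}"] += dhp.sum(axis=0)
        self.grads[f"W_ih_{d}"] += x.T @ dxp
        self.grads[f"b_ih_{d}"] += dxp.sum(axis=0)
        return dxp @ self.params[f"W_ih_{d}"].T

    def backward(self, dy):
        H = self.hidden_size
        dx = self._backward_direction(dy[:, :H] if self.bidirectional else dy, self._x, "fwd")
        if self.bidirectional:
            dx = dx + self._backward_direction(dy[:, H:][::-1], self._x_rev, "bwd")[::-1]
        return dx


class PoolConcat(Layer):
    """Fixed-size read embedding from a variable-length GRU output.

    Concatenates max-pool over time, mean-pool over time, the final forward
    hidden state and (when bidirectional) the final backward hidden state:
    (T, D*H) -> (2*D*H + D*H,), i.e. 288 features for a bidirectional GRU
    with 48 hidden units.
    """

    def __init__(self, hidden_size: int, bidirectional: bool) -> None:
        super().__init__()
        self.hidden_size = hidden_size
        self.bidirectional = bidirectional

    @property
    def out_features(self) -> int:
        width = self.hidden_size * (2 if self.bidirectional else 1)
        return 2 * width + width

    def forward(self, y, train: bool = False):
        self._shape = y.shape
        self._argmax = y.argmax(axis=0)
        parts = [y.max(axis=0), y.mean(axis=0)]
        H = self.hidden_size
        if self.bidirectional:
            parts.append(y[-1, :H])  # final forward state
            parts.append(y[0, H:])  # final backward state
        else:
            parts.append(y[-1, :])
        return np.concatenate(parts)

    def backward(self, df):
        T, W = self._shape
        H = self.hidden_size
        dy = np.zeros((T, W))
        dy[self._argmax, np.arange(W)] += df[:W]
        dy += df[W : 2 * W] / T
        if self.bidirectional:
            dy[-1, :H] += df[2 * W : 2 * W + H]
            dy[0, H:] += df[2 * W + H :]
        else:
            dy[-1, :] += df[2 * W :]
        return dy


class Dense(Layer):
    """Fully connected layer on a flat feature vector."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        limit = np.sqrt(6.0 / (in_features + out_features))
        self.add_param("W", rng.uniform(-limit, limit, (in_features, out_features)))
        self.add_param("b", np.zeros(out_features))

    def forward(self, x, train: bool = False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] += np.outer(self._x, dy)
        self.grads["b"] += dy
        return self.params["W"] @ dy


class AdamW:
    """AdamW: Adam with decoupled weight decay (``theta -= lr*wd*theta``)."""

    def __init__(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
                 lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0) -> None:
        self.params = params
        self.grads = grads
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            g = self.grads[k]
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            if self.weight_decay:
                p -= lr * self.weight_decay * p
            p -= lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0
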