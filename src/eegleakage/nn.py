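"""Minimal numpy neural-network engine for the segment classifier.

Implements exactly the layers the architecture needs — time-axis 2-D
convolutions (kernels of shape 1 x k, so channels act as image height and
are never mixed by the convolution), ELU, batch normalisation, average
pooling along time, fully connected layers — plus Adam with L2 weight
decay, a warm-up/linear-decay learning-rate schedule, and binary
cross-entropy on logits.

Activations use a channels-last layout ``(n, C, time, features)`` so that
every convolution is a single large GEMM (with preallocated outputs;
measured throughput is within ~10% of square-matrix BLAS speed) and no
transposes are needed between layers. All computation is float32 and fully
deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ConvNet", "Adam", "bce_with_logits", "lr_at_step"]

F32 = np.float32


def _uniform_init(rng, shape, fan_in):
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(F32)


class _Buffers:
    """Per-layer scratch-buffer cache.

    Batch shapes are constant during training, so the large conv/activation
    temporaries are allocated once and reused every step instead of paying
    page-fault and memset costs on fresh ~100 MB allocations per batch.
    Buffers are keyed by name and reallocated whenever the requested shape
    changes (e.g. the final short batch or evaluation passes).
    """

    def __init__(self):
        self._store = {}

    def get(self, name, shape, zero=False):
        key = (name, shape)
        buf = self._store.get(key)
        if buf is None:
            buf = np.empty(shape, F32)
            self._store[key] = buf
        if zero:
            buf.fill(0.0)
        return buf


# ---------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------


class ConvTime:
    """Convolution along the time axis: (n, C, T, Fin) -> (n, C, T', Fout).

    'same' padding preserves T (zero-padded both sides); 'valid' gives
    T' = T - k + 1. Channels C are image height and are never mixed.

    Two GEMM strategies, chosen by the cheaper intermediate:

    * **im2col** (few input features, e.g. the first convolution with
      Fin=1): gather k-tap windows into a (m, k*Fin) matrix and multiply
      by the (k*Fin, Fout) weight matrix.
    * **tap-stack** (few output features, e.g. the second convolution with
      Fout=10): multiply the raw (m, Fin) activations by the weights
      reshaped to (Fin, k*Fout), producing every (tap, filter) partial
      product at every padded time position, then sum k shifted slices.

    Both run as single large GEMMs with preallocated outputs.
    """

    def __init__(self, fin, fout, kernel, padding, rng):
        self.fin, self.fout, self.k = fin, fout, kernel
        self.padding = padding
        fan_in = fin * kernel
        self.W = _uniform_init(rng, (kernel, fin, fout), fan_in)
        self.b = _uniform_init(rng, (fout,), fan_in)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.strategy = "im2col" if fin <= fout else "tapstack"
        self._bufs = _Buffers()

    def out_time(self, T):
        if self.padding == "same":
            return T
        return T - self.k + 1

    def _pad(self, x):
        n, C, T, fin = x.shape
        k = self.k
        if self.padding == "same":
            pl = (k - 1) // 2
            xp = self._bufs.get("xp", (n, C, T + k - 1, fin), zero=True)
            xp[:, :, pl : pl + T] = x
            return xp, T
        Tout = T - k + 1
        if Tout < 1:
            raise ValueError(
                f"time extent {T} too small for kernel {k} under valid "
                f"padding (minimum {k})"
            )
        return x, Tout

    def forward(self, x, train):
        n, C, _, fin = x.shape
        k, fout = self.k, self.fout
        xp, Tout = self._pad(x)
        if self.strategy == "im2col":
            cols = self._bufs.get("cols", (n, C, Tout, k, fin))
            for kk in range(k):
                cols[:, :, :, kk, :] = xp[:, :, kk : kk + Tout, :]
            flat = cols.reshape(n * C * Tout, k * fin)
            out = self._bufs.get("out", (flat.shape[0], fout))
            np.matmul(flat, self.W.reshape(k * fin, fout), out=out)
            out += self.b
            if train:
                self._flat, self._xpshape = flat, xp.shape
            return out.reshape(n, C, Tout, fout)
        # tap-stack; the GEMM runs over the unpadded rows only (padding is
        # zero, so its partial products vanish) and the shifted-tap sum
        # clips each tap's slice at the boundaries instead
        T = x.shape[2]
        flat = x.reshape(n * C * T, fin)
        Wr = np.ascontiguousarray(
            self.W.transpose(1, 0, 2).reshape(fin, k * fout)
        )
        Z = self._bufs.get("Z", (flat.shape[0], k * fout))
        np.matmul(flat, Wr, out=Z)
        Zv = Z.reshape(n, C, T, k, fout)
        pl = (k - 1) // 2 if self.padding == "same" else 0
        out = self._bufs.get("out", (n, C, Tout, fout), zero=True)
        for kk in range(k):
            # out[t] += Z[t + kk - pl, kk]; keep both indices in range
            lo = max(0, pl - kk)
            hi = min(Tout, T + pl - kk)
            if lo < hi:
                out[:, :, lo:hi] += Zv[:, :, lo + kk - pl : hi + kk - pl, kk, :]
        out += self.b
        if train:
            self._flat, self._xpshape = flat, xp.shape
        return out

    def backward(self, dy):
        n, C, Tout, fout = dy.shape
        k, fin = self.k, self.fin
        self.db[...] = dy.sum(axis=(0, 1, 2))
        if self.strategy == "im2col":
            dyf = dy.reshape(n * C * Tout, fout)
            self.dW[...] = (self._flat.T @ dyf).reshape(self.W.shape)
            dcols = self._bufs.get("dcols", (dyf.shape[0], k * fin))
            np.matmul(dyf, self.W.reshape(k * fin, fout).T, out=dcols)
            dcv = dcols.reshape(n, C, Tout, k, fin)
            dxp = self._bufs.get("dxp", self._xpshape, zero=True)
            for kk in range(k):
                dxp[:, :, kk : kk + Tout, :] += dcv[:, :, :, kk, :]
        else:
            # gather dy windows instead of scattering into padded space:
            # G[u, kk, o] = dy[u - kk, o] (zero outside), so that
            # dxp[u, i] = sum_{kk,o} G[u, kk, o] W[kk, i, o]   and
            # dW[kk, i, o] = sum_u xp[u, i] G[u, kk, o]
            # mirror of the forward trick: gather dy windows over the
            # unpadded time extent T only; G[u, kk, o] = dy[u + pl - kk, o]
            T = self._xpshape[2] - (k - 1 if self.padding == "same" else 0)
            pl = (k - 1) // 2 if self.padding == "same" else 0
            dyp = self._bufs.get("dyp", (n, C, T + k - 1, fout), zero=True)
            dyp[:, :, k - 1 - pl : k - 1 - pl + Tout] = dy
            G = self._bufs.get("G", (n, C, T, k, fout))
            for kk in range(k):
                G[:, :, :, kk, :] = dyp[:, :, k - 1 - kk : k - 1 - kk + T]
            Gf = G.reshape(n * C * T, k * fout)
            dWmat = self._flat.T @ Gf  # (fin, k*fout)
            self.dW[...] = dWmat.reshape(fin, k, fout).transpose(1, 0, 2)
            Wmat = np.ascontiguousarray(
                self.W.transpose(0, 2, 1).reshape(k * fout, fin)
            )
            dflat = self._bufs.get("dflat", (Gf.shape[0], fin))
            np.matmul(Gf, Wmat, out=dflat)
            dx = dflat.reshape(n, C, T, fin)
            self._flat = None
            return dx
        if self.padding == "same":
            pl = (k - 1) // 2
            T = Tout
            dx = dxp[:, :, pl : pl + T]
        else:
            dx = dxp
        self._flat = None
        return dx

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ELU:
    """ELU computed as max(x, 0) + alpha * (exp(min(x, 0)) - 1).

    The clipped-exponential form runs through numpy's SIMD exp kernel and
    avoids branching over the (large) first-block activation tensor; the
    backward pass reuses the stored output (derivative is out + alpha on
    the negative side, 1 elsewhere).
    """

    def __init__(self, alpha=1.0):
        self.alpha = alpha
        self._bufs = _Buffers()

    def forward(self, x, train):
        neg = self._bufs.get("neg", x.shape)
        out = self._bufs.get("out", x.shape)
        np.minimum(x, 0.0, out=neg)
        np.maximum(x, 0.0, out=out)
        np.exp(neg, out=neg)
        neg -= 1.0
        if self.alpha != 1.0:
            neg *= self.alpha
        out += neg
        if train:
            self._out = out
        return out

    def backward(self, dy):
        out = self._out
        self._out = None
        grad = self._bufs.get("neg", out.shape)  # reuse; fwd value dead here
        if self.alpha == 1.0:
            np.minimum(out, 0.0, out=grad)
            grad += 1.0
        else:
            np.where(out > 0, F32(1.0), out + F32(self.alpha), out=grad)
        grad *= dy
        return grad

    def params(self):
        return []


class ReLU:
    def forward(self, x, train):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx

    def params(self):
        return []


class BatchNorm:
    """Batch normalisation over the trailing feature axis.

    Works for both the 4-D (n, C, T, F) and 2-D (n, F) layouts: statistics
    are taken over every axis except the last. Running statistics follow
    the usual exponential update ``running = (1 - m) * running + m * batch``
    and are used in evaluation mode. Forward and backward are written as
    fused per-feature affine passes so the large first-block activation is
    touched a minimal number of times.
    """

    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        self.eps = eps
        self.momentum = momentum
        self.gamma = np.ones(num_features, F32)
        self.beta = np.zeros(num_features, F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(num_features, F32)
        self.running_var = np.ones(num_features, F32)
        self._bufs = _Buffers()

    def forward(self, x, train):
        nfeat = x.shape[-1]
        x2d = x.reshape(-1, nfeat)
        if not train:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            a = (self.gamma * inv).astype(F32)
            b = (self.beta - self.running_mean * self.gamma * inv).astype(F32)
            out = self._bufs.get("out", x2d.shape)
            np.multiply(x2d, a, out=out)
            out += b
            return out.reshape(x.shape)
        m = x2d.shape[0]
        ones = self._bufs.get("ones", (m,))
        ones.fill(1.0)
        s1 = (ones @ x2d).astype(np.float64)
        s2 = np.einsum("ij,ij->j", x2d, x2d).astype(np.float64)
        mean = s1 / m
        var = np.maximum(s2 / m - mean * mean, 0.0)
        mom = self.momentum
        unbiased = var * (m / max(m - 1, 1))
        self.running_mean = ((1 - mom) * self.running_mean + mom * mean).astype(F32)
        self.running_var = ((1 - mom) * self.running_var + mom * unbiased).astype(F32)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = self._bufs.get("xhat", x2d.shape)
        np.multiply(x2d, inv.astype(F32), out=xhat)
        xhat -= (mean * inv).astype(F32)
        out = self._bufs.get("out", x2d.shape)
        np.multiply(xhat, self.gamma, out=out)
        out += self.beta
        self._cache = (xhat, inv)
        return out.reshape(x.shape)

    def backward(self, dy):
        xhat, inv = self._cache
        self._cache = None
        nfeat = dy.shape[-1]
        dy2d = dy.reshape(-1, nfeat)
        m = dy2d.shape[0]
        ones = self._bufs.get("ones", (m,))
        ones.fill(1.0)
        s1 = (ones @ dy2d).astype(np.float64)  # = dbeta
        s2 = np.einsum("ij,ij->j", dy2d, xhat).astype(np.float64)  # = dgamma
        self.dbeta[...] = s1
        self.dgamma[...] = s2
        a = (self.gamma * inv).astype(F32)  # coefficient of dy
        b = (a * s2 / m).astype(F32)  # coefficient of xhat
        c = (a * s1 / m).astype(F32)  # constant shift
        dx = self._bufs.get("dx", dy2d.shape)
        np.multiply(dy2d, a, out=dx)
        xhat *= b  # xhat buffer no longer needed; reuse in place
        dx -= xhat
        dx -= c
        return dx.reshape(dy.shape)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class AvgPoolTime:
    """Average pooling along the time axis with stride == kernel.

    A trailing remainder shorter than the kernel is dropped.
    """

    def __init__(self, k):
        self.k = k
        self._bufs = _Buffers()

    def out_time(self, T):
        return T // self.k

    def forward(self, x, train):
        n, C, T, f = x.shape
        To = T // self.k
        self._in_time = T
        xv = x[:, :, : To * self.k].reshape(n, C, To, self.k, f)
        out = self._bufs.get("out", (n, C, To, f))
        return xv.mean(axis=3, out=out)

    def backward(self, dy):
        n, C, To, f = dy.shape
        T = self._in_time
        remainder = T - To * self.k
        dx = self._bufs.get("dx", (n, C, T, f), zero=remainder > 0)
        dx[:, :, : To * self.k].reshape(n, C, To, self.k, f)[...] = (
            dy / self.k
        )[:, :, :, None, :]
        return dx

    def params(self):
        return []


class Flatten:
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def params(self):
        return []


class Linear:
    def __init__(self, fin, fout, rng):
        self.W = _uniform_init(rng, (fin, fout), fin)
        self.b = _uniform_init(rng, (fout,), fin)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        dx = dy @ self.W.T
        self._x = None
        return dx

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


# ---------------------------------------------------------------------
# network
# ---------------------------------------------------------------------


class ConvNet:
    """The two-block convolutional segment classifier.

    Layer sequence: Conv(512 filters, 1x65) - ELU - BatchNorm -
    AvgPool(1x2) - Conv(10, 1x33) - ELU - BatchNorm - AvgPool(1x4) -
    Flatten - Linear(160) - BatchNorm - ReLU - Linear(1). Convolutions and
    pools act along time only; the input is one segment of shape (C, L)
    and the output one logit.
    """

    def __init__(
        self,
        C,
        L,
        rng,
        *,
        conv1_filters=512,
        conv1_kernel=65,
        conv2_filters=10,
        conv2_kernel=33,
        pool1=2,
        pool2=4,
        hidden_units=160,
        elu_alpha=1.0,
        bn_epsilon=1e-5,
        bn_momentum=0.1,
        padding_mode="same",
    ):
        if padding_mode not in ("same", "valid"):
            raise ValueError("padding_mode must be 'same' or 'valid'")
        self.C, self.L = C, L
        conv1 = ConvTime(1, conv1_filters, conv1_kernel, padding_mode, rng)
        t = conv1.out_time(L)
        if t < 1:
            raise ValueError(
                f"L={L} too small for kernel {conv1_kernel} under "
                f"{padding_mode} padding (minimum L={conv1_kernel})"
            )
        pool_a = AvgPoolTime(pool1)
        t = pool_a.out_time(t)
        conv2 = ConvTime(
            conv1_filters, conv2_filters, conv2_kernel, padding_mode, rng
        )
        t = conv2.out_time(t)
        if t < 1:
            min_l = (
                conv1_kernel + pool1 * (conv2_kernel - 1 + 1) - 1
                if padding_mode == "valid"
                else pool1 * pool2
            )
            raise ValueError(
                f"L={L} too small for the configured kernels/pools under "
                f"{padding_mode} padding (minimum L~{min_l})"
            )
        pool_b = AvgPoolTime(pool2)
        t = pool_b.out_time(t)
        if t < 1:
            raise ValueError(
                f"L={L} leaves no time samples after pooling "
                f"({pool1}x then {pool2}x); minimum L={pool1 * pool2} under "
                "same padding"
            )
        self.flat_width = conv2_filters * C * t
        self.layers = [
            conv1,
            ELU(elu_alpha),
            BatchNorm(conv1_filters, bn_epsilon, bn_momentum),
            pool_a,
            conv2,
            ELU(elu_alpha),
            BatchNorm(conv2_filters, bn_epsilon, bn_momentum),
            pool_b,
            Flatten(),
            Linear(self.flat_width, hidden_units, rng),
            BatchNorm(hidden_units, bn_epsilon, bn_momentum),
            ReLU(),
            Linear(hidden_units, 1, rng),
        ]

    def forward(self, X, train=False):
        """X: (n, C, L) float32 -> logits (n,)."""
        h = np.ascontiguousarray(X, dtype=F32)[..., None]  # (n, C, L, 1)
        for layer in self.layers:
            h = layer.forward(h, train)
        return h[:, 0]

    def backward(self, dlogits):
        g = dlogits[:, None].astype(F32)
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_parameters(self):
        return sum(p.size for p, _ in self.params())

    def get_state(self):
        state = [p.copy() for p, _ in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def set_state(self, state):
        it = iter(state)
        for p, _ in self.params():
            p[...] = next(it)
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = next(it)
                layer.running_var[...] = next(it)

    def predict_logits(self, X, batch_size=256):
        out = np.empty(len(X), F32)
        for i in range(0, len(X), batch_size):
            out[i : i + batch_size] = self.forward(X[i : i + batch_size])
        return out


# ---------------------------------------------------------------------
# loss, schedule, optimiser
# ---------------------------------------------------------------------


def bce_with_logits(logits, y):
    """Mean binary cross-entropy on logits and its gradient.

    Uses the stable formulation max(z, 0) - z*y + log(1 + exp(-|z|)).
    """
    z = logits.astype(np.float64)
    y = y.astype(np.float64)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    p = 1.0 / (1.0 + np.exp(-z))
    grad = (p - y) / len(z)
    return float(loss.mean()), grad.astype(F32)


def lr_at_step(step, total_steps, base_lr, warmup_frac=0.1):
    """Linear warm-up over the first fraction of steps, then linear decay
    to zero at the final step."""
    warmup_steps = max(1, int(round(warmup_frac * total_steps)))
    if step < warmup_steps:
        return base_lr * (step + 1) / warmup_steps
    remaining = max(total_steps - warmup_steps, 1)
    return base_lr * max(0.0, (total_steps - step) / remaining)


class Adam:
    """Adam with (coupled) L2 weight decay added to the gradient."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8,
                 weight_decay=0.0):
        self.params = params  # list of (value, grad) pairs
        self.lr = lr
        self.beta1, self.beta2 = beta1, beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self, lr=None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            grad = g if self.weight_decay == 0 else g + self.weight_decay * p
            m *= b1
            m += (1 - b1) * grad
            v *= b2
            v += (1 - b2) * grad * grad
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
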