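"""Minimal CNN engine (NumPy + BLAS) used by the positioning models.

Implements exactly the layer set the positioning networks need — 3x3
convolutions (GEMM via im2col), batch normalisation, ReLU, 2x2 max
pooling, dense layers, dropout, and softmax/cross-entropy and
sigmoid/mean-squared-error heads — with reverse-mode gradients and a
momentum SGD optimiser.  Everything is float32 and seeded; on a single
thread the computation is bit-reproducible.

Tensors are NHWC (channels last): with narrow early layers this keeps the
im2col patch copies contiguous and the GEMMs in BLAS-friendly shapes on a
single CPU core.  The engine is deliberately small: no autograd graph,
just a list of layers each exposing ``forward(x, train)`` /
``backward(dy)`` and its ``(param, grad)`` pairs.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

F = np.float32


class TrainingError(RuntimeError):
    """Raised when optimisation diverges (non-finite loss)."""


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> List[Tuple[np.ndarray, np.ndarray]]:
        return []


class Conv3x3(Layer):
    """Same-padding 3x3 convolution, He-initialised.

    The kernel is stored as a (9*c_in, c_out) GEMM matrix (``w`` exposes
    the (3, 3, c_in, c_out) view).  Work buffers (padded input, im2col
    patch matrix, gradients) persist across steps to avoid re-faulting
    hundreds of MB per batch.  ``is_input`` marks the first layer of a
    network, where the gradient with respect to the input is not needed.
    """

    kernel_size = (3, 3)

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 is_input: bool = False):
        self.c_in, self.c_out, self.is_input = c_in, c_out, is_input
        scale = np.sqrt(2.0 / (c_in * 9))
        self.wm = (rng.standard_normal((9 * c_in, c_out)) * scale).astype(F)
        self.b = np.zeros(c_out, dtype=F)
        self.dwm = np.zeros_like(self.wm)
        self.db = np.zeros_like(self.b)
        self._bufs: dict = {}

    @property
    def w(self) -> np.ndarray:
        """Kernel tensor view, shape (3, 3, c_in, c_out)."""
        return self.wm.reshape(3, 3, self.c_in, self.c_out)

    def _buffers(self, N: int, H: int, W: int) -> dict:
        key = (N, H, W)
        buf = self._bufs.get(key)
        if buf is None:
            # "cols" holds the input patches for the forward GEMM and is
            # reused (after dW is computed) for the dY patches of the
            # input-gradient GEMM, so it is sized for the wider of the two
            c_max = self.c_in if self.is_input else max(self.c_in, self.c_out)
            buf = {
                "xp": np.zeros((N, H + 2, W + 2, self.c_in), dtype=F),
                "colsbuf": np.empty(N * H * W * 9 * c_max, dtype=F),
                "y": np.empty((N * H * W, self.c_out), dtype=F),
                "tmp": np.empty((N * H * W, max(self.c_in, self.c_out)), dtype=F),
            }
            if not self.is_input:
                buf["dyp"] = np.zeros((N, H + 2, W + 2, self.c_out), dtype=F)
                buf["dx"] = np.empty((N * H * W, self.c_in), dtype=F)
            # keep a few geometries (train batch, train tail, eval tail)
            if len(self._bufs) >= 3:
                del self._bufs[next(iter(self._bufs))]
            self._bufs[key] = buf
        return buf

    def release_buffers(self) -> None:
        self._bufs = {}

    @staticmethod
    def _im2col(xp: np.ndarray, colsbuf: np.ndarray, H: int, W: int) -> np.ndarray:
        """Padded NHWC tensor -> (3, N*H*W, 3*C) patch blocks in ``colsbuf``.

        Width-direction patches are contiguous in NHWC, so a strided view
        covers the three dj kernel columns at once; the three di row
        shifts become contiguous block copies.  Block ``di`` pairs with
        the kernel-matrix row slice ``[di*3C:(di+1)*3C]``.
        """
        N, _, _, C = xp.shape
        s0, s1, s2, s3 = xp.strides
        v = np.lib.stride_tricks.as_strided(
            xp, shape=(N, H + 2, W, 3 * C), strides=(s0, s1, s2, s3),
            writeable=False,
        )
        cols = colsbuf[: 3 * N * H * W * 3 * C].reshape(3, N, H, W, 3 * C)
        for di in range(3):
            cols[di] = v[:, di:di + H]
        return cols.reshape(3, N * H * W, 3 * C)

    def _matmul_blocks(self, cols, wmat, out, tmp):
        """out = sum_di cols[di] @ wmat[di-block] with one temp buffer."""
        k = cols.shape[2]
        np.matmul(cols[0], wmat[:k], out=out)
        for di in (1, 2):
            np.matmul(cols[di], wmat[di * k:(di + 1) * k], out=tmp)
            out += tmp
        return out

    def forward(self, x, train):
        N, H, W, C = x.shape
        buf = self._buffers(N, H, W)
        xp = buf["xp"]
        xp[:, 1:-1, 1:-1, :] = x
        cols = self._im2col(xp, buf["colsbuf"], H, W)
        tmp = buf["tmp"][:, : self.c_out]
        y = self._matmul_blocks(cols, self.wm, buf["y"], tmp)
        y += self.b
        if train:
            self._shape = (N, H, W, C)
        return y.reshape(N, H, W, self.c_out)

    def backward(self, dy):
        N, H, W, C = self._shape
        buf = self._bufs[(N, H, W)]
        cols = buf["colsbuf"][: 3 * N * H * W * 3 * C].reshape(
            3, N * H * W, 3 * C)
        dym = dy.reshape(N * H * W, self.c_out)
        for di in range(3):
            np.matmul(cols[di].T, dym,
                      out=self.dwm[di * 3 * C:(di + 1) * 3 * C])
        self.db[...] = dym.sum(axis=0)
        if self.is_input:
            return None
        # dX is itself a 3x3 convolution of dY with the spatially flipped,
        # channel-transposed kernel — BLAS-friendlier than scatter-adds;
        # the cols buffer is free again now that dW is done
        wback = np.ascontiguousarray(
            self.w[::-1, ::-1].transpose(0, 1, 3, 2)
        ).reshape(9 * self.c_out, C)
        dyp = buf["dyp"]
        dyp[:, 1:-1, 1:-1, :] = dy.reshape(N, H, W, self.c_out)
        dycols = self._im2col(dyp, buf["colsbuf"], H, W)
        tmp = buf["tmp"][:, : self.c_in]
        dx = self._matmul_blocks(dycols, wback, buf["dx"], tmp)
        return dx.reshape(N, H, W, C)

    def params(self):
        return [(self.wm, self.dwm), (self.b, self.db)]


class BatchNorm2d(Layer):
    """Per-channel batch normalisation with learned affine parameters."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=F)
        self.beta = np.zeros(c, dtype=F)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(c, dtype=F)
        self.run_var = np.ones(c, dtype=F)
        self.momentum, self.eps = momentum, eps
        self._ybufs: dict = {}

    def release_buffers(self) -> None:
        self._ybufs = {}

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 1, 2), dtype=np.float32)
            var = x.var(axis=(0, 1, 2), dtype=np.float32)
            self.run_mean = (self.momentum * self.run_mean
                             + (1 - self.momentum) * mean).astype(F)
            self.run_var = (self.momentum * self.run_var
                            + (1 - self.momentum) * var).astype(F)
        else:
            mean, var = self.run_mean, self.run_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(F)
        # fused affine: y = x * a + c  (ReLU may overwrite y in place;
        # backward recomputes xhat from the cached input x)
        a = self.gamma * inv
        c = self.beta - mean * a
        key = x.shape
        y = self._ybufs.get(key)
        if y is None:
            y = np.empty_like(x)
            # keep a few geometries (train batch, train tail, eval tail)
            if len(self._ybufs) >= 3:
                del self._ybufs[next(iter(self._ybufs))]
            self._ybufs[key] = y
        np.multiply(x, a, out=y)
        y += c
        if train:
            self._x, self._mean, self._inv = x, mean.astype(F), inv
        return y

    def backward(self, dy):
        # all in place: xhat overwrites the cached input buffer and dx
        # overwrites dy (both are upstream work buffers, expendable here)
        xhat = self._x
        xhat -= self._mean
        xhat *= self._inv
        n = dy.shape[0] * dy.shape[1] * dy.shape[2]
        self.dgamma[...] = np.einsum("nhwc,nhwc->c", dy, xhat)
        self.dbeta[...] = dy.sum(axis=(0, 1, 2))
        g = self.gamma * self._inv / n
        xhat *= self.dgamma
        xhat += self.dbeta
        dy *= F(n)
        dy -= xhat
        dy *= g
        self._x = None
        return dy

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class ReLU(Layer):
    """Rectifier applied in place (its input is always a fresh buffer)."""

    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0, out=x)

    def backward(self, dy):
        dy *= self._mask
        self._mask = None
        return dy


class MaxPool2x2(Layer):
    def __init__(self):
        self._dxbuf: Optional[np.ndarray] = None

    def release_buffers(self) -> None:
        self._dxbuf = None

    def forward(self, x, train):
        N, H, W, C = x.shape
        xr = x.reshape(N, H // 2, 2, W // 2, 2, C)
        y = xr.max(axis=(2, 4))
        if train:
            self._xr, self._y = xr, y
        return y

    def backward(self, dy):
        xr, y = self._xr, self._y
        mask = xr == y[:, :, None, :, None, :]
        cnt = mask.sum(axis=(2, 4), dtype=np.int32)
        scaled = (dy / cnt).astype(F, copy=False)[:, :, None, :, None, :]
        if self._dxbuf is None or self._dxbuf.shape != xr.shape:
            self._dxbuf = np.empty(xr.shape, dtype=F)
        dx = np.multiply(mask, scaled, out=self._dxbuf)
        N, Hh, _, Wh, _, C = xr.shape
        self._xr = self._y = None
        return dx.reshape(N, Hh * 2, Wh * 2, C)


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(F)
        self.b = np.zeros(n_out, dtype=F)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        dx = dy @ self.w.T
        self._x = None
        return dx

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p, self.rng = p, rng

    def forward(self, x, train):
        if not train or self.p == 0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(F) / F(1 - self.p)
        return x * self._mask

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


# ----------------------------------------------------------------------
# heads
# ----------------------------------------------------------------------

class SoftmaxCrossEntropy:
    """Softmax output with (optionally class-weighted) cross-entropy."""

    name = "softmax_cross_entropy"

    def probabilities(self, z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def loss_grad(self, z, y, sample_weight=None):
        p = self.probabilities(z)
        n = len(y)
        w = np.ones(n, dtype=F) if sample_weight is None else np.asarray(
            sample_weight, dtype=F)
        logp = -np.log(np.clip(p[np.arange(n), y], 1e-12, None))
        loss = float((w * logp).sum() / w.sum())
        grad = p.astype(F)
        grad[np.arange(n), y] -= 1.0
        grad *= (w / w.sum())[:, None]
        return loss, grad


class SigmoidMSE:
    """Sigmoid output with mean-squared-error loss (targets in [0, 1])."""

    name = "sigmoid_mse"

    def probabilities(self, z: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-z))

    def loss_grad(self, z, t, sample_weight=None):
        s = self.probabilities(z)
        d = s - t
        loss = float((d ** 2).mean())
        grad = (2.0 * d * s * (1 - s) / d.size).astype(F)
        return loss, grad


# ----------------------------------------------------------------------
# network + optimiser
# ----------------------------------------------------------------------

class Network:
    """A plain layer stack with one loss head.

    ``forward``/``predict`` expect NHWC input (N, H, W, C); convenience
    reshaping from (N, H, W) is done by the callers.
    """

    def __init__(self, layers: Sequence[Layer], head):
        self.layers = list(layers)
        self.head = head

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = np.ascontiguousarray(x, dtype=F)
        for layer in self.layers:
            h = layer.forward(h, train)
        return h

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = []
        for i in range(0, len(x), batch_size):
            z = self.forward(x[i:i + batch_size], train=False)
            outs.append(self.head.probabilities(z))
        return np.concatenate(outs, axis=0)

    def train_step(self, x, y, opt, sample_weight=None) -> float:
        z = self.forward(x, train=True)
        loss, dz = self.head.loss_grad(z, y, sample_weight)
        if not np.isfinite(loss):
            raise TrainingError("non-finite loss")
        d = dz
        for layer in reversed(self.layers):
            d = layer.backward(d)
        opt.step(self.parameters())
        return loss

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def release_buffers(self) -> None:
        """Free per-layer work buffers (weights are untouched)."""
        for layer in self.layers:
            release = getattr(layer, "release_buffers", None)
            if release is not None:
                release()

    def get_weights(self) -> List[np.ndarray]:
        ws = [p.copy() for p, _ in self.parameters()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm2d):
                ws.extend([layer.run_mean.copy(), layer.run_var.copy()])
        return ws

    def set_weights(self, ws: List[np.ndarray]) -> None:
        params = self.parameters()
        for (p, _), w in zip(params, ws[: len(params)]):
            p[...] = w
        rest = iter(ws[len(params):])
        for layer in self.layers:
            if isinstance(layer, BatchNorm2d):
                layer.run_mean = next(rest).copy()
                layer.run_var = next(rest).copy()


class SGD:
    """Stochastic gradient descent with (optional) classical momentum."""

    def __init__(self, lr: float, momentum: float = 0.0):
        self.lr, self.momentum = lr, momentum
        self._vel: dict = {}

    def step(self, params):
        for p, g in params:
            if self.momentum:
                v = self._vel.setdefault(id(p), np.zeros_like(p))
                v *= self.momentum
                v -= self.lr * g
                p += v
            else:
                p -= self.lr * g
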