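"""Numpy neural-network layers with hand-written backpropagation.

Every layer owns :class:`Param` objects (value + accumulated gradient).
``forward`` returns the output together with an explicit cache object, and
``backward`` consumes that cache — layers such as the character CNN run once
per word within a sentence, so caches cannot live on the layer itself.
Gradients accumulate (+=) across the sentences of a mini-batch and are
consumed by the optimizer, which then zeroes them.  Shapes follow the
sentence convention ``(n_tokens, features)``.

Randomly initialized embedding rows are drawn uniformly from
``[-sqrt(3/dim), +sqrt(3/dim)]`` (exactly 0.1 at dim 300); weight matrices
use the same uniform scheme with dim = fan-in.  PAD rows (index 0) of
embedding tables are frozen at zero.
"""

from __future__ import annotations

import numpy as np


def uniform_bound(dim: int) -> float:
    return float(np.sqrt(3.0 / dim))


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


def _uniform(rng: np.random.Generator, shape: tuple, dim: int) -> np.ndarray:
    b = uniform_bound(dim)
    return rng.uniform(-b, b, size=shape)


def sigmoid(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    def params(self) -> dict[str, Param]:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.params().values():
            p.grad[...] = 0.0


class Embedding(Layer):
    """Lookup table with uniform init; row 0 (PAD) is frozen at zero.

    ``pretrained`` marks rows loaded from an external vector file; they are
    fine-tuned like every other row, the flag is bookkeeping only.
    """

    def __init__(self, n_symbols: int, dim: int, rng: np.random.Generator,
                 name: str = "emb"):
        self.name = name
        self.dim = dim
        self.W = Param(_uniform(rng, (n_symbols, dim), dim))
        self.W.value[0] = 0.0
        self.pretrained = np.zeros(n_symbols, dtype=bool)

    def load_pretrained(self, vectors: dict[str, np.ndarray],
                        symbol_to_index: dict[str, int]) -> int:
        """Overwrite rows present in ``vectors``; return how many were set."""
        n = 0
        for symbol, vec in vectors.items():
            i = symbol_to_index.get(symbol)
            if i is None or i == 0:
                continue
            if len(vec) != self.dim:
                raise ValueError(
                    f"pretrained vector for {symbol!r} has dim {len(vec)}, "
                    f"table has dim {self.dim}"
                )
            self.W.value[i] = np.asarray(vec, dtype=np.float64)
            self.pretrained[i] = True
            n += 1
        return n

    def forward(self, idx: np.ndarray) -> np.ndarray:
        return self.W.value[np.asarray(idx)]

    def backward(self, idx: np.ndarray, dout: np.ndarray) -> None:
        np.add.at(self.W.grad, np.asarray(idx), dout)
        self.W.grad[0] = 0.0  # PAD stays frozen

    def params(self) -> dict[str, Param]:
        return {f"{self.name}.W": self.W}


class Dense(Layer):
    """Affine map ``y = x W + b`` over rows."""

    def __init__(self, din: int, dout: int, rng: np.random.Generator,
                 name: str = "dense"):
        self.name = name
        self.W = Param(_uniform(rng, (din, dout), din))
        self.b = Param(np.zeros(dout))

    def forward(self, x: np.ndarray):
        return x @ self.W.value + self.b.value, x

    def backward(self, dout: np.ndarray, cache) -> np.ndarray:
        x = cache
        self.W.grad += x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T

    def params(self) -> dict[str, Param]:
        return {f"{self.name}.W": self.W, f"{self.name}.b": self.b}


class CharCnn(Layer):
    """Character CNN: one convolution + max-pool per kernel width.

    Kernel widths default to (2, 3, 4) characters; each width has its own
    filter bank.  For one word the char embedding matrix (L, dc) with L >= 4
    is convolved per width, passed through tanh, max-pooled over positions,
    and the pooled vectors are concatenated (output dim = 3 x n_filters).
    """

    def __init__(self, char_dim: int, n_filters: int, rng: np.random.Generator,
                 widths: tuple[int, ...] = (2, 3, 4), name: str = "cnn"):
        self.name = name
        self.widths = tuple(widths)
        self.char_dim = char_dim
        self.n_filters = n_filters
        self.W = {
            k: Param(_uniform(rng, (k * char_dim, n_filters), k * char_dim))
            for k in self.widths
        }
        self.b = {k: Param(np.zeros(n_filters)) for k in self.widths}

    @property
    def out_dim(self) -> int:
        return len(self.widths) * self.n_filters

    def forward(self, C: np.ndarray):
        """C: (L, dc) with L >= max(widths); returns ((out_dim,), cache)."""
        L = C.shape[0]
        if L < max(self.widths):
            raise ValueError(f"word must be padded to length {max(self.widths)}")
        pooled = []
        cache = {}
        for k in self.widths:
            n_pos = L - k + 1
            win = np.lib.stride_tricks.sliding_window_view(C, k, axis=0)
            win = win.transpose(0, 2, 1).reshape(n_pos, k * self.char_dim)
            A = np.tanh(win @ self.W[k].value + self.b[k].value)  # (n_pos, nf)
            arg = A.argmax(axis=0)
            pooled.append(A[arg, np.arange(self.n_filters)])
            cache[k] = (win, A, arg)
        return np.concatenate(pooled), (C.shape, cache)

    def backward(self, dout: np.ndarray, cache) -> np.ndarray:
        (L, dc), per_width = cache
        dC = np.zeros((L, dc))
        nf = self.n_filters
        for j, k in enumerate(self.widths):
            win, A, arg = per_width[k]
            d = dout[j * nf : (j + 1) * nf]
            dA = np.zeros_like(A)
            dA[arg, np.arange(nf)] = d
            dS = (1.0 - A * A) * dA
            self.W[k].grad += win.T @ dS
            self.b[k].grad += dS.sum(axis=0)
            dwin = (dS @ self.W[k].value.T).reshape(-1, k, dc)
            for off in range(k):
                dC[off : off + dwin.shape[0]] += dwin[:, off, :]
        return dC

    def params(self) -> dict[str, Param]:
        out = {}
        for k in self.widths:
            out[f"{self.name}.W{k}"] = self.W[k]
            out[f"{self.name}.b{k}"] = self.b[k]
        return out


class Gate(Layer):
    """Gated interpolation of word and character vectors.

    ``z = sigmoid(U tanh(W x + V c + b))`` and ``out = z*x + (1-z)*c``,
    elementwise over a shared dimension ``dx``.  With ``scalar_gate`` the
    gate collapses to one shared value per token.
    """

    def __init__(self, dx: int, hidden: int, rng: np.random.Generator,
                 scalar_gate: bool = False, name: str = "gate"):
        self.name = name
        self.scalar = scalar_gate
        zdim = 1 if scalar_gate else dx
        self.W = Param(_uniform(rng, (dx, hidden), dx))
        self.V = Param(_uniform(rng, (dx, hidden), dx))
        self.b = Param(np.zeros(hidden))
        self.U = Param(_uniform(rng, (hidden, zdim), hidden))

    def forward(self, X: np.ndarray, C: np.ndarray):
        if X.shape != C.shape:
            raise ValueError(
                f"word and char representations differ: {X.shape} vs {C.shape}"
            )
        A = X @ self.W.value + C @ self.V.value + self.b.value
        T = np.tanh(A)
        Z = sigmoid(T @ self.U.value)  # (n, dx) or (n, 1)
        out = Z * X + (1.0 - Z) * C
        return out, (X, C, T, Z)

    def backward(self, dout: np.ndarray, cache):
        X, C, T, Z = cache
        dX = Z * dout
        dC = (1.0 - Z) * dout
        dZ = (X - C) * dout
        if self.scalar:
            dZ = dZ.sum(axis=1, keepdims=True)
        dS = Z * (1.0 - Z) * dZ
        self.U.grad += T.T @ dS
        dT = dS @ self.U.value.T
        dA = (1.0 - T * T) * dT
        self.W.grad += X.T @ dA
        self.V.grad += C.T @ dA
        self.b.grad += dA.sum(axis=0)
        dX += dA @ self.W.value.T
        dC += dA @ self.V.value.T
        return dX, dC

    def params(self) -> dict[str, Param]:
        return {
            f"{self.name}.W": self.W,
            f"{self.name}.V": self.V,
            f"{self.name}.b": self.b,
            f"{self.name}.U": self.U,
        }


class Lstm(Layer):
    """Single-direction LSTM over a sequence; forget-gate bias starts at 1."""

    def __init__(self, din: int, hidden: int, rng: np.random.Generator,
                 name: str = "lstm"):
        self.name = name
        self.din = din
        self.h = hidden
        self.Wx = Param(_uniform(rng, (din, 4 * hidden), din))
        self.Wh = Param(_uniform(rng, (hidden, 4 * hidden), hidden))
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget gate open at init
        self.b = Param(b)

    def forward(self, X: np.ndarray):
        n = X.shape[0]
        h = self.h
        I = np.zeros((n, h)); F = np.zeros((n, h))
        G = np.zeros((n, h)); O = np.zeros((n, h))
        Cc = np.zeros((n, h)); H = np.zeros((n, h))
        h_prev = np.zeros(h)
        c_prev = np.zeros(h)
        Wx, Wh, b = self.Wx.value, self.Wh.value, self.b.value
        XW = X @ Wx  # hoist the input projection out of the loop
        for t in range(n):
            pre = XW[t] + h_prev @ Wh + b
            I[t] = sigmoid(pre[:h])
            F[t] = sigmoid(pre[h : 2 * h])
            G[t] = np.tanh(pre[2 * h : 3 * h])
            O[t] = sigmoid(pre[3 * h :])
            Cc[t] = F[t] * c_prev + I[t] * G[t]
            H[t] = O[t] * np.tanh(Cc[t])
            h_prev, c_prev = H[t], Cc[t]
        return H, (X, I, F, G, O, Cc, H)

    def backward(self, dH: np.ndarray, cache) -> np.ndarray:
        X, I, F, G, O, Cc, H = cache
        n, h = H.shape
        dpre_all = np.zeros((n, 4 * h))
        dh_next = np.zeros(h)
        dc_next = np.zeros(h)
        WhT = self.Wh.value.T
        for t in range(n - 1, -1, -1):
            dh = dH[t] + dh_next
            tc = np.tanh(Cc[t])
            dO = dh * tc
            dc = dh * O[t] * (1.0 - tc * tc) + dc_next
            c_prev = Cc[t - 1] if t > 0 else np.zeros(h)
            dF = dc * c_prev
            dI = dc * G[t]
            dG = dc * I[t]
            dc_next = dc * F[t]
            dpre = dpre_all[t]
            dpre[:h] = dI * I[t] * (1.0 - I[t])
            dpre[h : 2 * h] = dF * F[t] * (1.0 - F[t])
            dpre[2 * h : 3 * h] = dG * (1.0 - G[t] * G[t])
            dpre[3 * h :] = dO * O[t] * (1.0 - O[t])
            dh_next = dpre @ WhT
        self.Wx.grad += X.T @ dpre_all
        H_prev = np.vstack([np.zeros(h), H[:-1]])
        self.Wh.grad += H_prev.T @ dpre_all
        self.b.grad += dpre_all.sum(axis=0)
        return dpre_all @ self.Wx.value.T

    def params(self) -> dict[str, Param]:
        return {
            f"{self.name}.Wx": self.Wx,
            f"{self.name}.Wh": self.Wh,
            f"{self.name}.b": self.b,
        }


class BiLstm(Layer):
    """Forward and backward LSTM; per-token outputs concatenated."""

    def __init__(self, din: int, hidden: int, rng: np.random.Generator,
                 name: str = "bilstm"):
        self.fwd = Lstm(din, hidden, rng, name=f"{name}.fwd")
        self.bwd = Lstm(din, hidden, rng, name=f"{name}.bwd")
        self.h = hidden

    def forward(self, X: np.ndarray):
        Hf, cf = self.fwd.forward(X)
        Hb_rev, cb = self.bwd.forward(X[::-1])
        return np.concatenate([Hf, Hb_rev[::-1]], axis=1), (cf, cb)

    def backward(self, dH: np.ndarray, cache) -> np.ndarray:
        cf, cb = cache
        h = self.h
        dX = self.fwd.backward(dH[:, :h], cf)
        dX = dX + self.bwd.backward(dH[::-1, h:], cb)[::-1]
        return dX

    def params(self) -> dict[str, Param]:
        return {**self.fwd.params(), **self.bwd.params()}


class Dropout:
    """Inverted dropout; identity when rate is 0 or in eval mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, X: np.ndarray, train: bool,
                rng: np.random.Generator | None):
        if not train or self.rate == 0.0:
            return X, None
        mask = (rng.random(X.shape) >= self.rate) / (1.0 - self.rate)
        return X * mask, mask

    def backward(self, dout: np.ndarray, mask) -> np.ndarray:
        if mask is None:
            return dout
        return dout * mask


class BatchNorm(Layer):
    """Per-feature normalization over the token axis with learned scale/shift.

    Statistics are taken over the tokens currently flowing through the layer
    during training, with running averages used at prediction time.
    """

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5,
                 name: str = "bn"):
        self.name = name
        self.gamma = Param(np.ones(dim))
        self.beta = Param(np.zeros(dim))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def forward(self, X: np.ndarray, train: bool):
        use_batch = train and X.shape[0] > 1
        if use_batch:
            mean = X.mean(axis=0)
            var = X.var(axis=0)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        Xhat = (X - mean) * inv
        return self.gamma.value * Xhat + self.beta.value, (Xhat, inv, use_batch)

    def backward(self, dout: np.ndarray, cache) -> np.ndarray:
        Xhat, inv, used_batch_stats = cache
        self.gamma.grad += (dout * Xhat).sum(axis=0)
        self.beta.grad += dout.sum(axis=0)
        dXhat = dout * self.gamma.value
        if not used_batch_stats:
            return dXhat * inv
        n = Xhat.shape[0]
        return (inv / n) * (
            n * dXhat - dXhat.sum(axis=0) - Xhat * (dXhat * Xhat).sum(axis=0)
        )

    def params(self) -> dict[str, Param]:
        return {f"{self.name}.gamma": self.gamma, f"{self.name}.beta": self.beta}
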