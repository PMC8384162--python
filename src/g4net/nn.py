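"""Minimal NumPy implementation of the active-G4 convolutional network.

The architecture is small and fixed — one-hot DNA (L x 4) -> 1-D valid
convolution (F kernels of width k, ReLU) -> non-overlapping local average
pooling -> global max pooling over positions -> optional concatenation of a
scalar accessibility input -> dropout -> dense ReLU -> dense sigmoid — so
the forward and backward passes are written directly against BLAS matmuls
(im2col) instead of pulling in a deep-learning framework. All randomness
(weight initialisation, shuffling, dropout) flows from a single seed, which
makes training bit-reproducible on a given platform.
"""

from __future__ import annotations

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def binary_cross_entropy(p: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def im2col(X: np.ndarray, kernel_size: int) -> np.ndarray:
    """(B, L, 4) -> (B, L - k + 1, k * 4) sliding windows (a view)."""
    windows = np.lib.stride_tricks.sliding_window_view(X, kernel_size, axis=1)
    # windows: (B, T, 4, k) -> (B, T, k, 4) so the flat layout is position-major
    return windows.transpose(0, 1, 3, 2).reshape(X.shape[0], -1, kernel_size * 4)


class RMSProp:
    """Root-mean-square propagation with Keras-default settings."""

    def __init__(self, params: dict, lr: float = 1e-3, rho: float = 0.9,
                 eps: float = 1e-7):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.cache = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        for k, g in grads.items():
            c = self.cache[k]
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            params[k] -= self.lr * g / (np.sqrt(c) + self.eps)


class ConvNet:
    """The fixed-topology network; see module docstring for the layer order."""

    def __init__(
        self,
        n_kernels: int = 900,
        kernel_size: int = 20,
        pool_size: int = 12,
        dropout_rate: float = 0.0,
        dense_units: int = 100,
        input_length: int = 201,
        use_accessibility: bool = True,
        seed: int = 0,
    ):
        if n_kernels < 1:
            raise ValueError("need at least one kernel")
        if kernel_size > input_length:
            raise ValueError("kernel wider than the input sequence")
        conv_len = input_length - kernel_size + 1
        if pool_size > conv_len:
            raise ValueError("pool size exceeds the convolution output length")
        if not 0.0 <= dropout_rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.n_kernels = n_kernels
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.dropout_rate = dropout_rate
        self.dense_units = dense_units
        self.input_length = input_length
        self.use_accessibility = use_accessibility
        self.conv_len = conv_len
        self.pooled_len = conv_len // pool_size
        self.feature_len = n_kernels + (1 if use_accessibility else 0)
        rng = np.random.default_rng(seed)
        self.params = {
            "Wc": _glorot(rng, (kernel_size * 4, n_kernels), kernel_size * 4, n_kernels),
            "bc": np.zeros(n_kernels, dtype=np.float32),
            "W1": _glorot(rng, (self.feature_len, dense_units), self.feature_len, dense_units),
            "b1": np.zeros(dense_units, dtype=np.float32),
            "W2": _glorot(rng, (dense_units, 1), dense_units, 1),
            "b2": np.zeros(1, dtype=np.float32),
        }

    # -- forward pieces ----------------------------------------------------

    def conv_activations(self, X: np.ndarray) -> np.ndarray:
        """Post-ReLU convolution outputs, shape (B, conv_len, n_kernels)."""
        P = im2col(np.ascontiguousarray(X, dtype=np.float32), self.kernel_size)
        z = P.reshape(-1, P.shape[-1]) @ self.params["Wc"] + self.params["bc"]
        return np.maximum(z, 0.0).reshape(X.shape[0], self.conv_len, self.n_kernels)

    def _forward(self, X, acc, train=False, rng=None):
        B = X.shape[0]
        P = im2col(np.ascontiguousarray(X, dtype=np.float32), self.kernel_size)
        Pf = P.reshape(B * self.conv_len, -1)
        z1 = (Pf @ self.params["Wc"] + self.params["bc"]).reshape(
            B, self.conv_len, self.n_kernels
        )
        a1 = np.maximum(z1, 0.0)
        Tp, w = self.pooled_len, self.pool_size
        pooled = a1[:, : Tp * w].reshape(B, Tp, w, self.n_kernels).mean(axis=2)
        gidx = pooled.argmax(axis=1)                      # (B, F)
        g = np.take_along_axis(pooled, gidx[:, None, :], axis=1)[:, 0, :]
        if self.use_accessibility:
            h = np.concatenate([g, np.asarray(acc, dtype=np.float32)[:, None]], axis=1)
        else:
            h = g
        if train and self.dropout_rate > 0.0:
            keep = 1.0 - self.dropout_rate
            mask = (rng.random(h.shape) < keep).astype(np.float32) / keep
            h = h * mask
        else:
            mask = None
        z2 = h @ self.params["W1"] + self.params["b1"]
        a2 = np.maximum(z2, 0.0)
        z3 = a2 @ self.params["W2"] + self.params["b2"]
        p = sigmoid(z3[:, 0])
        return {
            "Pf": Pf, "z1": z1, "gidx": gidx, "h": h, "mask": mask,
            "z2": z2, "a2": a2, "p": p,
        }

    def predict_proba(self, X, acc=None, batch_size: int = 256) -> np.ndarray:
        if acc is None:
            acc = np.zeros(X.shape[0], dtype=np.float32)
        out = np.empty(X.shape[0], dtype=np.float64)
        for i in range(0, X.shape[0], batch_size):
            sl = slice(i, i + batch_size)
            out[sl] = self._forward(X[sl], acc[sl])["p"]
        return out

    # -- backward ----------------------------------------------------------

    def _backward(self, cache, y):
        B = y.shape[0]
        F, Tp, w = self.n_kernels, self.pooled_len, self.pool_size
        dz3 = ((cache["p"] - y) / B).astype(np.float32)[:, None]
        grads = {
            "W2": cache["a2"].T @ dz3,
            "b2": dz3.sum(axis=0),
        }
        da2 = dz3 @ self.params["W2"].T
        dz2 = da2 * (cache["z2"] > 0)
        grads["W1"] = cache["h"].T @ dz2
        grads["b1"] = dz2.sum(axis=0)
        dh = dz2 @ self.params["W1"].T
        if cache["mask"] is not None:
            dh = dh * cache["mask"]
        dg = dh[:, :F]
        dpooled = np.zeros((B, Tp, F), dtype=np.float32)
        np.put_along_axis(dpooled, cache["gidx"][:, None, :], dg[:, None, :], axis=1)
        da1 = np.zeros((B, self.conv_len, F), dtype=np.float32)
        da1[:, : Tp * w] = np.repeat(dpooled / w, w, axis=1)
        dz1 = da1 * (cache["z1"] > 0)
        grads["Wc"] = cache["Pf"].T @ dz1.reshape(B * self.conv_len, F)
        grads["bc"] = dz1.sum(axis=(0, 1))
        return grads

    # -- training ----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        acc: np.ndarray,
        y: np.ndarray,
        epochs: int = 20,
        batch_size: int = 128,
        seed: int = 0,
        validation: tuple | None = None,
        learning_rate: float = 1e-3,
        verbose: bool = False,
    ) -> list[dict]:
        """Minimise binary cross-entropy with RMSprop; returns per-epoch history."""
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data must contain both classes")
        rng = np.random.default_rng(seed)
        opt = RMSProp(self.params, lr=learning_rate)
        X = np.ascontiguousarray(X, dtype=np.float32)
        acc = np.asarray(acc, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        history = []
        for epoch in range(epochs):
            order = rng.permutation(X.shape[0])
            losses = []
            for i in range(0, X.shape[0], batch_size):
                idx = order[i : i + batch_size]
                cache = self._forward(X[idx], acc[idx], train=True, rng=rng)
                loss = binary_cross_entropy(cache["p"], y[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}, batch {i // batch_size}"
                    )
                grads = self._backward(cache, y[idx])
                opt.step(self.params, grads)
                losses.append(loss)
            record = {"epoch": epoch, "loss": float(np.mean(losses))}
            if validation is not None:
                Xv, av, yv = validation
                pv = self.predict_proba(Xv, av)
                record["val_loss"] = binary_cross_entropy(pv, yv)
                record["val_acc"] = float(np.mean((pv >= 0.5) == (yv >= 0.5)))
            history.append(record)
            if verbose:
                print(f"epoch {epoch + 1}/{epochs}: " +
                      " ".join(f"{k}={v:.4f}" for k, v in record.items() if k != "epoch"))
        return history


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)
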