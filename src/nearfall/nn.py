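"""A compact sequence network: 1-D convolutions -> LSTM -> softmax head.

Implements exactly the network family used for activity recognition here
(temporal convolutions for local feature extraction, an LSTM for longer
range dynamics, a fully connected softmax output), with explicit
reverse-mode gradients and an Adam optimizer.  Everything is plain
numpy: given a fixed seed, initialization, data shuffling and therefore
the trained weights are fully reproducible.

Shapes: inputs are ``(batch, time, channels)``; convolutions are
"valid" along time; each conv block is followed by temporal max pooling;
the classifier reads the LSTM's final hidden state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConvLSTMNet"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, T, C) -> (B, T-k+1, k*C) sliding windows along time."""
    win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (B, T', C, k)
    b, tp, c, _ = win.shape
    return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(b, tp, k * c)


@dataclass
class ConvLSTMNet:
    """Conv1d stack -> LSTM -> dense softmax classifier.

    Parameters
    ----------
    n_channels : input channels per time step
    n_classes : output classes
    conv_filters : filters per conv block (default (16, 32))
    kernel : temporal kernel size of every conv block
    pool : max-pool width after every conv block
    hidden : LSTM state size
    lr : Adam learning rate
    seed : master seed for initialization and shuffling
    """

    n_channels: int
    n_classes: int
    conv_filters: tuple[int, ...] = (16, 32)
    kernel: int = 5
    pool: int = 4
    hidden: int = 64
    lr: float = 3e-3
    grad_clip: float = 5.0
    seed: int = 0
    params: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        p = self.params
        c_in = self.n_channels
        for i, f in enumerate(self.conv_filters):
            fan = self.kernel * c_in
            p[f"Wc{i}"] = rng.normal(0, np.sqrt(2.0 / fan), (fan, f))
            p[f"bc{i}"] = np.zeros(f)
            c_in = f
        h = self.hidden
        for name, fan in (("Wx", c_in), ("Wh", h)):
            p[name] = rng.normal(0, 1.0 / np.sqrt(fan), (fan, 4 * h))
        p["bh"] = np.zeros(4 * h)
        p["bh"][h:2 * h] = 1.0  # forget-gate bias
        p["Wo"] = rng.normal(0, 1.0 / np.sqrt(h), (h, self.n_classes))
        p["bo"] = np.zeros(self.n_classes)
        self._adam_m = {k: np.zeros_like(v) for k, v in p.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in p.items()}
        self._adam_t = 0
        self._rng = rng

    # ------------------------------------------------------------------ fwd
    def _forward(self, x: np.ndarray, cache: bool = False):
        p = self.params
        caches: list = []
        for i in range(len(self.conv_filters)):
            xc = _im2col(x, self.kernel)
            z = xc @ p[f"Wc{i}"] + p[f"bc{i}"]
            a = np.maximum(z, 0.0)
            # temporal max pool
            b, tp, f = a.shape
            t2 = tp // self.pool
            ar = a[:, : t2 * self.pool, :].reshape(b, t2, self.pool, f)
            amax = np.argmax(ar, axis=2)
            pooled = np.take_along_axis(ar, amax[:, :, None, :], axis=2)[:, :, 0, :]
            if cache:
                caches.append((x.shape, xc, z, ar.shape, amax))
            x = pooled

        # LSTM over the pooled sequence
        b, t, _ = x.shape
        h = self.hidden
        hs = np.zeros((b, h))
        cs = np.zeros((b, h))
        steps = []
        for k in range(t):
            zt = x[:, k, :] @ p["Wx"] + hs @ p["Wh"] + p["bh"]
            i_g = _sigmoid(zt[:, :h])
            f_g = _sigmoid(zt[:, h:2 * h])
            o_g = _sigmoid(zt[:, 2 * h:3 * h])
            g_g = np.tanh(zt[:, 3 * h:])
            c_new = f_g * cs + i_g * g_g
            tc = np.tanh(c_new)
            h_new = o_g * tc
            if cache:
                steps.append((x[:, k, :], hs, cs, i_g, f_g, o_g, g_g, c_new, tc))
            hs, cs = h_new, c_new

        logits = hs @ p["Wo"] + p["bo"]
        if cache:
            return logits, (caches, x, steps, hs)
        return logits

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Softmax class probabilities, rows summing to 1."""
        outs = []
        for i in range(0, len(x), batch_size):
            logits = self._forward(x[i:i + batch_size])
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            outs.append(e / e.sum(axis=1, keepdims=True))
        return np.vstack(outs) if outs else np.empty((0, self.n_classes))

    # ------------------------------------------------------------------ bwd
    def _loss_and_grads(self, x: np.ndarray, y: np.ndarray, sample_w: np.ndarray):
        p = self.params
        logits, (conv_caches, lstm_in, steps, h_final) = self._forward(x, cache=True)
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        proba = e / e.sum(axis=1, keepdims=True)
        n = len(y)
        wsum = sample_w.sum()
        loss = float(-(sample_w * np.log(proba[np.arange(n), y] + 1e-12)).sum() / wsum)

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlogits = proba.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits *= (sample_w / wsum)[:, None]

        grads["Wo"] = h_final.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dh = dlogits @ p["Wo"].T
        dc = np.zeros_like(dh)
        h = self.hidden
        dx_seq = np.zeros_like(lstm_in)
        for k in range(len(steps) - 1, -1, -1):
            x_t, h_prev, c_prev, i_g, f_g, o_g, g_g, c_new, tc = steps[k]
            do = dh * tc
            dtc = dh * o_g * (1.0 - tc * tc) + dc
            df = dtc * c_prev
            di = dtc * g_g
            dg = dtc * i_g
            dc = dtc * f_g
            dz = np.concatenate(
                [di * i_g * (1 - i_g), df * f_g * (1 - f_g),
                 do * o_g * (1 - o_g), dg * (1 - g_g * g_g)], axis=1)
            grads["Wx"] += x_t.T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["bh"] += dz.sum(axis=0)
            dx_seq[:, k, :] = dz @ p["Wx"].T
            dh = dz @ p["Wh"].T
        dpooled = dx_seq

        for i in range(len(self.conv_filters) - 1, -1, -1):
            x_shape, xc, z, ar_shape, amax = conv_caches[i]
            b, t2, pool, f = ar_shape
            # un-pool: route gradient to argmax positions
            dar = np.zeros(ar_shape)
            np.put_along_axis(dar, amax[:, :, None, :], dpooled[:, :, None, :], axis=2)
            da = np.zeros((b, z.shape[1], f))
            da[:, : t2 * pool, :] = dar.reshape(b, t2 * pool, f)
            dz = da * (z > 0)
            bsz, tp, _ = dz.shape
            grads[f"Wc{i}"] = xc.reshape(bsz * tp, -1).T @ dz.reshape(bsz * tp, -1)
            grads[f"bc{i}"] = dz.sum(axis=(0, 1))
            dxc = dz @ self.params[f"Wc{i}"].T  # (B, T', k*C)
            c_in = x_shape[2]
            dxc = dxc.reshape(bsz, tp, self.kernel, c_in)
            dx = np.zeros(x_shape)
            for j in range(self.kernel):
                dx[:, j:j + tp, :] += dxc[:, :, j, :]
            dpooled = dx
        return loss, grads

    def _adam_step(self, grads: dict) -> None:
        gn = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
        scale = min(1.0, self.grad_clip / (gn + 1e-12))
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            g = g * scale
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = self._adam_m[k] / (1 - b1 ** self._adam_t)
            vhat = self._adam_v[k] / (1 - b2 ** self._adam_t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)

    # ------------------------------------------------------------------ fit
    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        class_weights: np.ndarray | None = None,
        epochs: int = 30,
        batch_size: int = 128,
        val_fraction: float = 0.2,
        patience: int = 5,
        verbose: bool = False,
    ) -> list[float]:
        """Train with weighted cross-entropy, early stopping on a held-out split.

        Returns the per-epoch validation-loss history.  The best-epoch
        weights (lowest validation loss) are restored at the end.
        """
        n = len(x)
        if class_weights is None:
            class_weights = np.ones(self.n_classes)
        sample_w = class_weights[y]

        idx = self._rng.permutation(n)
        n_val = max(1, int(round(val_fraction * n))) if n >= 10 else 0
        val_idx, tr_idx = idx[:n_val], idx[n_val:]
        if len(tr_idx) == 0:
            tr_idx = idx
            val_idx = idx

        best_loss = np.inf
        best_params: dict | None = None
        history: list[float] = []
        stall = 0
        for epoch in range(epochs):
            order = self._rng.permutation(len(tr_idx))
            for i in range(0, len(order), batch_size):
                b = tr_idx[order[i:i + batch_size]]
                _, grads = self._loss_and_grads(x[b], y[b], sample_w[b])
                self._adam_step(grads)
            # validation loss (weighted CE)
            proba = self.predict_proba(x[val_idx])
            vw = sample_w[val_idx]
            vl = float(-(vw * np.log(proba[np.arange(len(val_idx)), y[val_idx]] + 1e-12)).sum() / vw.sum())
            history.append(vl)
            if verbose:
                print(f"epoch {epoch + 1}: val loss {vl:.4f}")
            if vl < best_loss - 1e-4:
                best_loss = vl
                best_params = {k: v.copy() for k, v in self.params.items()}
                stall = 0
            else:
                stall += 1
                if stall >= patience:
                    break
        if best_params is not None:
            self.params = best_params
        return history
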