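"""A small LSTM binary sequence classifier in pure numpy.

One embedding layer, one LSTM layer (gates computed jointly), and a sigmoid
readout from the final hidden state, trained by backpropagation through time
with Adam on the binary cross-entropy.  Everything is seeded and runs on
integer-state numpy generators, so training is bit-reproducible for a fixed
(seed, data) pair.  Sized for name-length sequences and corpora of a few
thousand to a few hundred thousand strings on one CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["TinyLSTM"]


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class TinyLSTM:
    """LSTM over token-id sequences with a single-probability output."""

    def __init__(self, vocab_size: int, embedding_dim: int = 32, hidden_dim: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        v, d, h = vocab_size, embedding_dim, hidden_dim
        k = 1.0 / np.sqrt(h)
        self.params = {
            "E": rng.normal(0.0, 0.1, size=(v, d)),
            "W": rng.uniform(-k, k, size=(d + h, 4 * h)),
            "b": np.zeros(4 * h),
            "w_out": rng.uniform(-k, k, size=h),
            "b_out": np.zeros(1),
        }
        self.params["b"][h : 2 * h] = 1.0  # forget-gate bias: remember by default
        self.vocab_size = v
        self.embedding_dim = d
        self.hidden_dim = h

    # -- forward / backward ------------------------------------------------
    def _forward(self, ids: np.ndarray, mask: np.ndarray, want_cache: bool):
        p = self.params
        b_sz, t_len = ids.shape
        h_dim = self.hidden_dim
        h = np.zeros((b_sz, h_dim))
        c = np.zeros((b_sz, h_dim))
        cache = []
        for t in range(t_len):
            x = p["E"][ids[:, t]]
            z = np.concatenate([x, h], axis=1)
            gates = z @ p["W"] + p["b"]
            i = _sigmoid(gates[:, :h_dim])
            f = _sigmoid(gates[:, h_dim : 2 * h_dim])
            o = _sigmoid(gates[:, 2 * h_dim : 3 * h_dim])
            g = np.tanh(gates[:, 3 * h_dim :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            m = mask[:, t : t + 1]
            if want_cache:
                cache.append((ids[:, t], z, i, f, o, g, c, tc, m))
            c = m * c_new + (1.0 - m) * c
            h = m * h_new + (1.0 - m) * h
        logits = h @ p["w_out"] + p["b_out"][0]
        return logits, h, cache

    def _backward(self, dlogits: np.ndarray, h_final: np.ndarray, cache) -> dict:
        p = self.params
        h_dim = self.hidden_dim
        d_dim = self.embedding_dim
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["w_out"] = h_final.T @ dlogits
        grads["b_out"] = np.array([dlogits.sum()])
        dh = dlogits[:, None] * p["w_out"][None, :]
        dc = np.zeros_like(dh)
        for ids_t, z, i, f, o, g, c_prev, tc, m in reversed(cache):
            dh_new = dh * m
            dc_new = dc * m + dh_new * o * (1.0 - tc**2)
            do = dh_new * tc
            df = dc_new * c_prev
            di = dc_new * g
            dg = dc_new * i
            dgates = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    do * o * (1.0 - o),
                    dg * (1.0 - g**2),
                ],
                axis=1,
            )
            grads["W"] += z.T @ dgates
            grads["b"] += dgates.sum(axis=0)
            dz = dgates @ p["W"].T
            np.add.at(grads["E"], ids_t, dz[:, :d_dim])
            dh = dh * (1.0 - m) + dz[:, d_dim:]
            dc = dc * (1.0 - m) + dc_new * f
        return grads

    @staticmethod
    def _pad(seqs) -> tuple[np.ndarray, np.ndarray]:
        t_max = max((len(s) for s in seqs), default=1)
        t_max = max(t_max, 1)
        ids = np.zeros((len(seqs), t_max), dtype=np.int64)
        mask = np.zeros((len(seqs), t_max))
        for r, s in enumerate(seqs):
            ids[r, : len(s)] = s
            mask[r, : len(s)] = 1.0
        return ids, mask

    def loss_and_grads(self, seqs, y, sample_weight=None):
        """Mean weighted BCE over a batch plus parameter gradients."""
        ids, mask = self._pad(seqs)
        y = np.asarray(y, dtype=float)
        sw = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, float)
        logits, h, cache = self._forward(ids, mask, want_cache=True)
        # stable BCE from logits
        losses = np.maximum(logits, 0.0) - logits * y + np.log1p(np.exp(-np.abs(logits)))
        total_w = sw.sum()
        loss = float((sw * losses).sum() / total_w)
        dlogits = sw * (_sigmoid(logits) - y) / total_w
        grads = self._backward(dlogits, h, cache)
        return loss, grads

    # -- training ----------------------------------------------------------
    def fit(
        self,
        seqs,
        y,
        epochs: int = 10,
        batch_size: int = 256,
        lr: float = 0.01,
        class_weight=None,
        seed: int = 0,
        clip_norm: float = 5.0,
    ) -> list[float]:
        """Adam training; returns the per-epoch mean loss trace.

        ``class_weight`` may be None or a {0: w0, 1: w1} map (e.g. inverse
        class frequencies for imbalanced training sets).
        """
        y = np.asarray(y, dtype=float)
        n = len(seqs)
        sw = np.ones(n)
        if class_weight is not None:
            sw = np.where(y > 0.5, class_weight.get(1, 1.0), class_weight.get(0, 1.0))
        rng = np.random.default_rng(seed)
        m_t = {k: np.zeros_like(v) for k, v in self.params.items()}
        v_t = {k: np.zeros_like(v) for k, v in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        trace = []
        for epoch in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                batch = [seqs[i] for i in idx]
                loss, grads = self.loss_and_grads(batch, y[idx], sw[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch {n_batches} "
                        f"(lr={lr}, batch_size={len(batch)}); try a smaller "
                        "learning rate"
                    )
                gnorm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
                if gnorm > clip_norm:
                    for g in grads.values():
                        g *= clip_norm / gnorm
                step += 1
                for k in self.params:
                    m_t[k] = beta1 * m_t[k] + (1 - beta1) * grads[k]
                    v_t[k] = beta2 * v_t[k] + (1 - beta2) * grads[k] ** 2
                    m_hat = m_t[k] / (1 - beta1**step)
                    v_hat = v_t[k] / (1 - beta2**step)
                    self.params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)
                epoch_loss += loss
                n_batches += 1
            trace.append(epoch_loss / max(n_batches, 1))
        return trace

    def predict_proba(self, seqs, batch_size: int = 1024) -> np.ndarray:
        """P(label = 1) for each sequence; deterministic given the weights."""
        out = np.empty(len(seqs))
        for start in range(0, len(seqs), batch_size):
            batch = seqs[start : start + batch_size]
            ids, mask = self._pad(batch)
            logits, _, _ = self._forward(ids, mask, want_cache=False)
            out[start : start + len(batch)] = _sigmoid(logits)
        return out

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=float).copy()
        self.vocab_size, self.embedding_dim = self.params["E"].shape
        self.hidden_dim = self.params["w_out"].size
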