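"""A small NumPy conv/attention network for token-sequence classification.

Architecture: trainable embedding → three 1-D convolutions (valid
padding, ReLU) → single-head scaled-dot-product self-attention with a
residual connection → global max pooling over positions → linear
softmax head.  Trained with Adam on cross-entropy.  Everything is
plain NumPy with hand-written backpropagation, seeded and fully
deterministic on one machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_F32 = np.float32


@dataclass(frozen=True)
class ConvAttentionConfig:
    embedding_dim: int = 64
    conv_filters: int = 64
    kernel_widths: tuple[int, int, int] = (3, 5, 7)
    attention: bool = True
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.kernel_widths) != 3:
            raise ValueError("exactly three convolutional layers are required")

    @property
    def receptive_shrink(self) -> int:
        return sum(w - 1 for w in self.kernel_widths)


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, width: int):
    """Valid 1-D convolution via im2col.  x: (B, L, Cin), w: (width*Cin, F)."""
    B, L, Cin = x.shape
    Lout = L - width + 1
    patches = np.concatenate([x[:, i : i + Lout, :] for i in range(width)], axis=2)
    y = patches @ w + b
    return y, patches


def _conv_backward(dy, patches, w, width, x_shape):
    B, L, Cin = x_shape
    Lout = L - width + 1
    dw = patches.reshape(-1, patches.shape[2]).T @ dy.reshape(-1, dy.shape[2])
    db = dy.sum(axis=(0, 1))
    dpatches = dy @ w.T
    dx = np.zeros(x_shape, dtype=dy.dtype)
    for i in range(width):
        dx[:, i : i + Lout, :] += dpatches[:, :, i * Cin : (i + 1) * Cin]
    return dx, dw, db


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class ConvAttentionNet:
    """The trainable network; ``vocab_size`` excludes the pad index."""

    def __init__(self, vocab_size: int, n_classes: int, config: ConvAttentionConfig):
        self.config = config
        self.n_classes = n_classes
        self.vocab_size = vocab_size
        rng = np.random.default_rng(config.seed)
        d, F = config.embedding_dim, config.conv_filters
        p: dict[str, np.ndarray] = {}
        p["E"] = (rng.standard_normal((vocab_size + 1, d)) * 0.1).astype(_F32)
        cin = d
        for li, w in enumerate(config.kernel_widths):
            fan_in = w * cin
            p[f"W{li}"] = (
                rng.standard_normal((fan_in, F)) * np.sqrt(2.0 / fan_in)
            ).astype(_F32)
            p[f"b{li}"] = np.zeros(F, dtype=_F32)
            cin = F
        if config.attention:
            for name in ("Wq", "Wk", "Wv"):
                p[name] = (rng.standard_normal((F, F)) * np.sqrt(1.0 / F)).astype(_F32)
        p["Wo"] = (rng.standard_normal((F, n_classes)) * np.sqrt(1.0 / F)).astype(_F32)
        p["bo"] = np.zeros(n_classes, dtype=_F32)
        self.params = p
        self._adam_m = {k: np.zeros_like(v) for k, v in p.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in p.items()}
        self._adam_t = 0

    # ---------------------------------------------------------------- forward

    def _forward(self, tokens: np.ndarray, want_cache: bool):
        cfg, p = self.config, self.params
        x = p["E"][tokens]  # (B, L, d)
        cache = {"tokens": tokens} if want_cache else None
        h = x
        acts = []
        for li, w in enumerate(cfg.kernel_widths):
            if h.shape[1] < w:
                raise ValueError(
                    f"padded length {tokens.shape[1]} too short for the "
                    f"convolution stack (needs ≥ {cfg.receptive_shrink + 1})"
                )
            z, patches = _conv_forward(h, p[f"W{li}"], p[f"b{li}"], w)
            a = np.maximum(z, 0)
            acts.append((h.shape, patches, z > 0))
            h = a
        if cfg.attention:
            q, k, v = h @ p["Wq"], h @ p["Wk"], h @ p["Wv"]
            scale = _F32(1.0 / np.sqrt(cfg.conv_filters))
            attn = _softmax(q @ k.transpose(0, 2, 1) * scale)
            att_out = attn @ v
            r = h + att_out
        else:
            q = k = v = attn = None
            r = h
        pool_idx = r.argmax(axis=1)  # (B, F)
        pooled = np.take_along_axis(r, pool_idx[:, None, :], axis=1)[:, 0, :]
        logits = pooled @ p["Wo"] + p["bo"]
        if want_cache:
            cache.update(
                acts=acts, h=h, q=q, k=k, v=v, attn=attn,
                pool_idx=pool_idx, pooled=pooled, r_shape=r.shape,
            )
        return logits, cache

    def predict_logits(self, tokens: np.ndarray) -> np.ndarray:
        if tokens.shape[0] == 0:
            return np.zeros((0, self.n_classes))
        logits, _ = self._forward(tokens, want_cache=False)
        return logits.astype(np.float64)

    def predict_proba(self, tokens: np.ndarray) -> np.ndarray:
        return _softmax(self.predict_logits(tokens))

    # --------------------------------------------------------------- backward

    def _backward(self, cache, dlogits):
        cfg, p = self.config, self.params
        grads: dict[str, np.ndarray] = {}
        grads["Wo"] = cache["pooled"].T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dpooled = (dlogits @ p["Wo"].T).astype(_F32)
        dr = np.zeros(cache["r_shape"], dtype=_F32)
        np.put_along_axis(dr, cache["pool_idx"][:, None, :], dpooled[:, None, :], axis=1)
        h = cache["h"]
        if cfg.attention:
            attn, q, k, v = cache["attn"], cache["q"], cache["k"], cache["v"]
            datt = dr  # residual: dh gets dr as well, added below
            dv = attn.transpose(0, 2, 1) @ datt
            dattn = datt @ v.transpose(0, 2, 1)
            dscores = attn * (dattn - (dattn * attn).sum(axis=2, keepdims=True))
            dscores *= _F32(1.0 / np.sqrt(cfg.conv_filters))
            dq = dscores @ k
            dk = dscores.transpose(0, 2, 1) @ q
            F = cfg.conv_filters
            h2 = h.reshape(-1, F)
            grads["Wq"] = h2.T @ dq.reshape(-1, F)
            grads["Wk"] = h2.T @ dk.reshape(-1, F)
            grads["Wv"] = h2.T @ dv.reshape(-1, F)
            dh = dr + dq @ p["Wq"].T + dk @ p["Wk"].T + dv @ p["Wv"].T
        else:
            dh = dr
        for li in reversed(range(3)):
            x_shape, patches, relu_mask = cache["acts"][li]
            dz = dh * relu_mask
            dh, dw, db = _conv_backward(
                dz, patches, p[f"W{li}"], cfg.kernel_widths[li], x_shape
            )
            grads[f"W{li}"] = dw
            grads[f"b{li}"] = db
        dE = np.zeros_like(p["E"])
        np.add.at(dE, cache["tokens"].ravel(), dh.reshape(-1, dh.shape[2]))
        grads["E"] = dE
        return grads

    def _adam_step(self, grads):
        lr, b1, b2, eps = self.config.learning_rate, 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for key, g in grads.items():
            g = g.astype(_F32)
            m = self._adam_m[key]
            v = self._adam_v[key]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            self.params[key] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(_F32)

    # ------------------------------------------------------------------- fit

    def fit(self, tokens: np.ndarray, labels: np.ndarray) -> list[float]:
        """Train; returns the mean cross-entropy per epoch."""
        cfg = self.config
        n = tokens.shape[0]
        rng = np.random.default_rng(cfg.seed + 1)
        onehot = np.eye(self.n_classes, dtype=np.float64)[labels]
        history: list[float] = []
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                logits, cache = self._forward(tokens[idx], want_cache=True)
                probs = _softmax(logits.astype(np.float64))
                batch_loss = -np.mean(
                    np.log(np.clip(probs[np.arange(len(idx)), labels[idx]], 1e-12, None))
                )
                total += batch_loss * len(idx)
                dlogits = ((probs - onehot[idx]) / len(idx)).astype(_F32)
                grads = self._backward(cache, dlogits)
                self._adam_step(grads)
            history.append(total / n)
        return history

    # ----------------------------------------------------------- persistence

    def state_arrays(self) -> dict[str, np.ndarray]:
        return dict(self.params)

    @classmethod
    def from_state(
        cls,
        vocab_size: int,
        n_classes: int,
        config: ConvAttentionConfig,
        arrays: dict[str, np.ndarray],
    ) -> "ConvAttentionNet":
        net = cls(vocab_size, n_classes, config)
        for key in net.params:
            net.params[key] = arrays[key].astype(_F32)
        return net
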