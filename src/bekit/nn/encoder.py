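"""Attention-based sequence encoder for short fixed-length DNA inputs.

A standard pre-norm transformer encoder: learned token + position embeddings,
``n_layers`` blocks of multi-head self-attention and a two-layer feed-forward
net with residual connections, a final layer norm and mean pooling over
positions.  Sized for CPU training on 20-34 token sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Tensor, dropout, embedding, layer_norm, parameter


@dataclass
class EncoderConfig:
    vocab_size: int = 5          # A C G T + pad
    max_len: int = 34
    d_model: int = 64
    n_heads: int = 4
    n_layers: int = 2
    d_ff: int = 128
    dropout: float = 0.1

    def to_dict(self):
        return asdict(self)


def _init(rng: np.random.Generator, *shape, scale: float | None = None):
    scale = scale if scale is not None else 1.0 / np.sqrt(shape[0])
    return parameter(rng.normal(0.0, scale, size=shape))


class TransformerEncoder:
    """Self-attention encoder mapping token ids (B, T) to pooled vectors (B, d)."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        c = self.config = config
        if c.d_model % c.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        p = self.params = {}
        p["tok_emb"] = _init(rng, c.vocab_size, c.d_model, scale=0.1)
        p["pos_emb"] = _init(rng, c.max_len, c.d_model, scale=0.1)
        for l in range(c.n_layers):
            for name in ("wq", "wk", "wv", "wo"):
                p[f"l{l}.{name}"] = _init(rng, c.d_model, c.d_model)
            p[f"l{l}.bo"] = parameter(np.zeros(c.d_model))
            p[f"l{l}.ln1_g"] = parameter(np.ones(c.d_model))
            p[f"l{l}.ln1_b"] = parameter(np.zeros(c.d_model))
            p[f"l{l}.w1"] = _init(rng, c.d_model, c.d_ff)
            p[f"l{l}.b1"] = parameter(np.zeros(c.d_ff))
            p[f"l{l}.w2"] = _init(rng, c.d_ff, c.d_model)
            p[f"l{l}.b2"] = parameter(np.zeros(c.d_model))
            p[f"l{l}.ln2_g"] = parameter(np.ones(c.d_model))
            p[f"l{l}.ln2_b"] = parameter(np.zeros(c.d_model))
        p["ln_f_g"] = parameter(np.ones(c.d_model))
        p["ln_f_b"] = parameter(np.zeros(c.d_model))

    def __call__(self, ids: np.ndarray, rng: np.random.Generator | None = None,
                 train: bool = False) -> Tensor:
        c, p = self.config, self.params
        ids = np.asarray(ids)
        B, T = ids.shape
        x = embedding(p["tok_emb"], ids) + embedding(
            p["pos_emb"], np.broadcast_to(np.arange(T), (B, T))
        )
        dh = c.d_model // c.n_heads
        for l in range(c.n_layers):
            h = layer_norm(x, p[f"l{l}.ln1_g"], p[f"l{l}.ln1_b"])
            q = (h @ p[f"l{l}.wq"]).reshape(B, T, c.n_heads, dh).transpose(0, 2, 1, 3)
            k = (h @ p[f"l{l}.wk"]).reshape(B, T, c.n_heads, dh).transpose(0, 2, 1, 3)
            v = (h @ p[f"l{l}.wv"]).reshape(B, T, c.n_heads, dh).transpose(0, 2, 1, 3)
            att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
            att = att.softmax(axis=-1)
            att = dropout(att, c.dropout, rng, train)
            ctx = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, c.d_model)
            x = x + dropout(ctx @ p[f"l{l}.wo"] + p[f"l{l}.bo"], c.dropout, rng, train)
            h = layer_norm(x, p[f"l{l}.ln2_g"], p[f"l{l}.ln2_b"])
            ff = (h @ p[f"l{l}.w1"] + p[f"l{l}.b1"]).relu() @ p[f"l{l}.w2"] + p[f"l{l}.b2"]
            x = x + dropout(ff, c.dropout, rng, train)
        x = layer_norm(x, p["ln_f_g"], p["ln_f_b"])
        return x.mean(axis=1)

    # -- checkpoint plumbing --------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = np.array(state[k], dtype=p.data.dtype)


class MLPHead:
    """Linear (optionally one hidden layer) scalar head."""

    def __init__(self, d_in: int, rng: np.random.Generator, d_hidden: int = 0):
        self.params = {}
        if d_hidden:
            self.params["w1"] = _init(rng, d_in, d_hidden)
            self.params["b1"] = parameter(np.zeros(d_hidden))
            self.params["w2"] = _init(rng, d_hidden, 1)
            self.params["b2"] = parameter(np.zeros(1))
        else:
            self.params["w"] = _init(rng, d_in, 1)
            self.params["b"] = parameter(np.zeros(1))
        self.d_hidden = d_hidden

    def __call__(self, x: Tensor) -> Tensor:
        p = self.params
        if self.d_hidden:
            return ((x @ p["w1"] + p["b1"]).relu() @ p["w2"] + p["b2"]).reshape(-1)
        return (x @ p["w"] + p["b"]).reshape(-1)

    def state_dict(self):
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state):
        for k, p in self.params.items():
            p.data = np.array(state[k], dtype=p.data.dtype)
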