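"""Encoder-only transformer with rotary positions and pre-layer norm.

The architecture family is the ESM-2 style encoder: token embedding (no
learned positional embedding; rotary applied to queries/keys), N pre-LN
blocks of multi-head self-attention + GELU MLP, a final layer norm, and an
MLM head (dense + GELU + LN + decoder tied to the embedding). Dropout is
omitted (the training runs here are short and heavily seeded).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor

__all__ = ["ModelConfig", "Encoder", "ClassifierHead"]


@dataclass(frozen=True)
class ModelConfig:
    n_layers: int
    n_heads: int
    hidden_size: int
    intermediate_size: int
    vocab_size: int = 26
    max_len: int = 320
    rotary: bool = True
    pre_layer_norm: bool = True
    preset: str = "custom"

    def __post_init__(self):
        if self.hidden_size % self.n_heads:
            raise ValueError("hidden_size must be divisible by n_heads")

    @classmethod
    def paper_350m(cls) -> "ModelConfig":
        return cls(32, 20, 960, 3840, 26, 320, preset="paper_350m")

    @classmethod
    def tiny(cls) -> "ModelConfig":
        return cls(2, 4, 64, 256, 26, 320, preset="tiny")


def parameter_shapes(config: ModelConfig) -> list:
    """Every trainable tensor's (name, shape); the analytic census."""
    h, i, v = config.hidden_size, config.intermediate_size, config.vocab_size
    shapes = [("embed.weight", (v, h))]
    for l in range(config.n_layers):
        p = f"layer{l}."
        shapes += [
            (p + "ln1.gamma", (h,)), (p + "ln1.beta", (h,)),
            (p + "attn.q.weight", (h, h)), (p + "attn.q.bias", (h,)),
            (p + "attn.k.weight", (h, h)), (p + "attn.k.bias", (h,)),
            (p + "attn.v.weight", (h, h)), (p + "attn.v.bias", (h,)),
            (p + "attn.o.weight", (h, h)), (p + "attn.o.bias", (h,)),
            (p + "ln2.gamma", (h,)), (p + "ln2.beta", (h,)),
            (p + "mlp.fc1.weight", (h, i)), (p + "mlp.fc1.bias", (i,)),
            (p + "mlp.fc2.weight", (i, h)), (p + "mlp.fc2.bias", (h,)),
        ]
    shapes += [
        ("final_ln.gamma", (h,)), ("final_ln.beta", (h,)),
        ("lm_head.dense.weight", (h, h)), ("lm_head.dense.bias", (h,)),
        ("lm_head.ln.gamma", (h,)), ("lm_head.ln.beta", (h,)),
        ("lm_head.bias", (v,)),  # decoder weight is tied to embed.weight
    ]
    return shapes


def _rotary_tables(max_len: int, dh: int) -> tuple:
    half = dh // 2
    inv_freq = 1.0 / (10000.0 ** (np.arange(half) / half))
    angles = np.outer(np.arange(max_len), inv_freq)  # (L, dh/2)
    cos = np.concatenate([np.cos(angles)] * 2, axis=-1).astype(np.float32)
    sin = np.concatenate([np.sin(angles)] * 2, axis=-1).astype(np.float32)
    return cos, sin


class Encoder:
    """The MLM encoder. Parameters live in ``self.params`` (name -> Tensor)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}
        for name, shape in parameter_shapes(config):
            if name.endswith(("gamma",)):
                data = np.ones(shape, dtype=np.float32)
            elif name.endswith(("beta", "bias")):
                data = np.zeros(shape, dtype=np.float32)
            else:
                data = rng.normal(0.0, 0.02, size=shape).astype(np.float32)
            self.params[name] = Tensor(data, name=name)
        self._cos, self._sin = _rotary_tables(
            config.max_len, config.hidden_size // config.n_heads
        )

    # ------------------------------------------------------------- plumbing
    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=np.float32)

    def checksum(self) -> str:
        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k].data).tobytes())
        return h.hexdigest()

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    @classmethod
    def from_file(cls, path, config: ModelConfig) -> "Encoder":
        model = cls(config, seed=0)
        with np.load(path) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model

    # -------------------------------------------------------------- forward
    def _linear(self, x: Tensor, prefix: str) -> Tensor:
        return x @ self.params[prefix + ".weight"] + self.params[prefix + ".bias"]

    def forward(self, ids: np.ndarray, flags: np.ndarray, capture: bool = False):
        """Hidden states after the final layer norm; optionally capture
        per-layer hidden-state tensors and attention weight arrays."""
        cfg = self.config
        B, L = ids.shape
        nh, dh = cfg.n_heads, cfg.hidden_size // cfg.n_heads
        bias = ((1.0 - flags.astype(np.float32)) * -1e9)[:, None, None, :]
        cos, sin = self._cos[:L], self._sin[:L]
        h = Tensor.embedding(self.params["embed.weight"], ids)
        captured = {"hidden": [], "attention": []} if capture else None
        for l in range(cfg.n_layers):
            p = f"layer{l}."
            x = h.layer_norm(self.params[p + "ln1.gamma"], self.params[p + "ln1.beta"])
            q = self._linear(x, p + "attn.q").reshape(B, L, nh, dh).swapaxes(1, 2)
            k = self._linear(x, p + "attn.k").reshape(B, L, nh, dh).swapaxes(1, 2)
            v = self._linear(x, p + "attn.v").reshape(B, L, nh, dh).swapaxes(1, 2)
            if cfg.rotary:
                q, k = q.rotary(cos, sin), k.rotary(cos, sin)
            q = q * float(1.0 / np.sqrt(dh))  # scale q, not the L x L scores
            probs = (q @ k.swapaxes(-1, -2)).add_const(bias).softmax_last()
            ctx = (probs @ v).swapaxes(1, 2).reshape(B, L, cfg.hidden_size)
            h = h + self._linear(ctx, p + "attn.o")
            x = h.layer_norm(self.params[p + "ln2.gamma"], self.params[p + "ln2.beta"])
            h = h + self._mlp(x, p)
            if capture:
                captured["hidden"].append(h)
                captured["attention"].append(probs.data)
        h = h.layer_norm(self.params["final_ln.gamma"], self.params["final_ln.beta"])
        if capture:
            return h, captured
        return h

    def _mlp(self, x: Tensor, prefix: str) -> Tensor:
        y = self._linear(x, prefix + "mlp.fc1").gelu()
        return self._linear(y, prefix + "mlp.fc2")

    def mlm_logits(self, hidden: Tensor) -> Tensor:
        """Per-position vocabulary logits (decoder tied to the embedding)."""
        x = self._linear(hidden, "lm_head.dense").gelu()
        x = x.layer_norm(self.params["lm_head.ln.gamma"], self.params["lm_head.ln.beta"])
        return x @ self.params["embed.weight"].swapaxes(0, 1) + self.params["lm_head.bias"]


class ClassifierHead:
    """Single affine map from a pooled representation to two class logits."""

    def __init__(self, hidden_size: int, n_classes: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.weight = Tensor(
            rng.normal(0.0, 0.02, size=(hidden_size, n_classes)).astype(np.float32),
            name="head.weight",
        )
        self.bias = Tensor(np.zeros(n_classes, dtype=np.float32), name="head.bias")

    @property
    def params(self) -> dict:
        return {"head.weight": self.weight, "head.bias": self.bias}

    def logits(self, pooled: Tensor) -> Tensor:
        return pooled @ self.weight + self.bias
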