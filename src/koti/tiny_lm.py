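"""A tiny trainable masked language model, implemented in NumPy.

This model exists so the prompt-based fine-tuning loop — cross-entropy on
the verbalizer's class distribution, AdamW with decoupled weight decay
excluding biases and normalization parameters — can be exercised end to
end on synthetic data at desk scale. It is a deliberately small cloze
scorer, not a transformer: token embeddings are pooled with fixed
proximity weights around the scoring position (tokens near the mask count
more, mirroring the locality premise the insertion methods rely on),
normalized with a LayerNorm, passed through one tanh hidden layer, and
projected back onto the vocabulary.

Architecture (``V`` = vocab size, ``d`` = embedding dim):

    c_i     = softmax_i(-|i - mask_pos| / tau)          fixed weights
    h       = sum_i c_i * E[t_i]                        (d,)
    z       = LayerNorm(h; gain, bias)
    u       = tanh(W1 z + b1)
    logits  = W2 u + b2                                 (V,)

Everything is float64 and deterministic given the seed, so training runs
are exactly reproducible.
"""

from __future__ import annotations

import copy
from typing import Callable, Mapping

import numpy as np

from .insertion import PromptInput

_EPS = 1e-5
_UNK_ID = 1


class TinyMaskedLM:
    """Trainable cloze scorer over a closed whitespace vocabulary."""

    kind = "masked"
    trainable = True

    def __init__(self, vocab_size: int, dim: int = 64, tau: float = 16.0,
                 seed: int = 0, max_input: int = 512) -> None:
        if max_input < 16:
            raise ValueError("max_input must be >= 16")
        rng = np.random.default_rng(seed)
        self.vocab_size = vocab_size
        self.dim = dim
        self.tau = float(tau)
        self.max_input = max_input
        scale = 0.02
        self.params: dict[str, np.ndarray] = {
            "embed.weight": rng.normal(0.0, scale, (vocab_size, dim)),
            "norm.gain": np.ones(dim),
            "norm.bias": np.zeros(dim),
            "fc1.weight": rng.normal(0.0, scale, (dim, dim)),
            "fc1.bias": np.zeros(dim),
            "out.weight": rng.normal(0.0, scale, (vocab_size, dim)),
            "out.bias": np.zeros(vocab_size),
        }

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def clone(self) -> "TinyMaskedLM":
        return copy.deepcopy(self)

    # -- forward / backward ------------------------------------------------

    def _pool_weights(self, n: int, pos: int) -> np.ndarray:
        dist = np.abs(np.arange(n) - pos) / self.tau
        w = np.exp(-dist)
        return w / w.sum()

    def forward(self, tokens: np.ndarray, pos: int):
        """Vocabulary logits at ``pos`` plus a cache for backprop."""
        p = self.params
        t = np.asarray(tokens, dtype=int)
        t = np.where(t < self.vocab_size, t, _UNK_ID)
        c = self._pool_weights(len(t), pos)
        h = c @ p["embed.weight"][t]
        mu = h.mean()
        xc = h - mu
        var = (xc * xc).mean()
        inv = 1.0 / np.sqrt(var + _EPS)
        xh = xc * inv
        z = p["norm.gain"] * xh + p["norm.bias"]
        a = p["fc1.weight"] @ z + p["fc1.bias"]
        u = np.tanh(a)
        logits = p["out.weight"] @ u + p["out.bias"]
        cache = {"t": t, "c": c, "xh": xh, "inv": inv, "z": z, "u": u}
        return logits, cache

    def backward(self, cache: Mapping, dlogits: np.ndarray
                 ) -> dict[str, np.ndarray]:
        p = self.params
        t, c, xh, inv, z, u = (cache["t"], cache["c"], cache["xh"],
                               cache["inv"], cache["z"], cache["u"])
        grads = {name: np.zeros_like(arr) for name, arr in p.items()}
        grads["out.weight"] = np.outer(dlogits, u)
        grads["out.bias"] = dlogits.copy()
        du = p["out.weight"].T @ dlogits
        da = du * (1.0 - u * u)
        grads["fc1.weight"] = np.outer(da, z)
        grads["fc1.bias"] = da
        dz = p["fc1.weight"].T @ da
        grads["norm.gain"] = dz * xh
        grads["norm.bias"] = dz
        dxh = dz * p["norm.gain"]
        dh = inv * (dxh - dxh.mean() - xh * (dxh * xh).mean())
        np.add.at(grads["embed.weight"], t, np.outer(c, dh))
        return grads

    # -- backend contract --------------------------------------------------

    def score(self, pinput: PromptInput) -> np.ndarray:
        """Logits at the mask position of an encoder-layout input."""
        if pinput.mask_index is None:
            raise ValueError("masked model requires an input with a mask")
        if pinput.total_tokens > self.max_input:
            raise ValueError(
                f"input of {pinput.total_tokens} tokens exceeds "
                f"max_input {self.max_input}")
        logits, _ = self.forward(np.array(pinput.tokens), pinput.mask_index)
        return logits


class AdamW:
    """AdamW with decoupled weight decay and per-name decay exclusion.

    Decay is applied to every parameter except those matched by
    ``exclude`` — by default biases and normalization parameters, which by
    convention are left unregularized.
    """

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 weight_decay: float = 0.01,
                 exclude: Callable[[str], bool] | None = None,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.exclude = exclude if exclude is not None else (lambda n: False)
        self.betas = betas
        self.eps = eps
        self.step_count = 0
        self._m = {n: np.zeros_like(v) for n, v in params.items()}
        self._v = {n: np.zeros_like(v) for n, v in params.items()}

    @property
    def decayed_param_names(self) -> list[str]:
        """Names of parameters that receive weight decay (audit hook)."""
        return [n for n in self.params if not self.exclude(n)]

    def step(self, grads: Mapping[str, np.ndarray]) -> None:
        self.step_count += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.step_count
        bc2 = 1.0 - b2 ** self.step_count
        for name, p in self.params.items():
            g = grads[name]
            m = self._m[name]
            v = self._v[name]
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and not self.exclude(name):
                update = update + self.weight_decay * p
            p -= self.lr * update
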