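"""Manual verbalizer: label words -> token ids -> class probabilities.

Each class is represented by one single-token label word. Class
probabilities are a softmax restricted to the label-word logits taken from
the model's vocabulary distribution at the mask (encoder) or next-token
(decoder) position; no corpus-prior calibration is applied. Multi-token
label words are a hard error rather than being pooled, to avoid silently
scoring a different word than intended.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .insertion import TokenizerContract
from .task_config import TaskSpec


class VerbalizerError(ValueError):
    """A label word does not map to exactly one token."""


@dataclass(frozen=True)
class Verbalizer:
    """Class-ordered mapping from class name to label-word token id."""

    class_order: tuple[str, ...]
    class_token: Mapping[str, int]

    def __post_init__(self) -> None:
        ids = [self.class_token[c] for c in self.class_order]
        if len(set(ids)) != len(ids):
            raise VerbalizerError(f"label-word token ids collide: {ids}")

    @property
    def token_ids(self) -> np.ndarray:
        return np.array([self.class_token[c] for c in self.class_order])


@dataclass(frozen=True)
class ClassDistribution:
    """Normalized class probabilities, keyed in class order."""

    probs: Mapping[str, float]

    def __post_init__(self) -> None:
        total = float(sum(self.probs.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")


def build_verbalizer(spec: TaskSpec,
                     tokenizer: TokenizerContract) -> Verbalizer:
    """Map each label word to its (single) token id under ``tokenizer``."""
    class_token: dict[str, int] = {}
    for cls in spec.classes:
        word = spec.label_words[cls]
        ids = tokenizer.encode(word)
        if len(ids) != 1:
            raise VerbalizerError(
                f"label word {word!r} for class {cls!r} tokenizes to "
                f"{len(ids)} tokens; verbalizer words must be single tokens")
        class_token[cls] = ids[0]
    return Verbalizer(class_order=tuple(spec.classes),
                      class_token=class_token)


def verbalize(vocab_logits: np.ndarray, v: Verbalizer) -> ClassDistribution:
    """Softmax over the label-word logits only.

    Shift-invariant and numerically stable; logits for all other
    vocabulary entries are ignored.
    """
    logits = np.asarray(vocab_logits, dtype=float)[v.token_ids]
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError(
            f"non-finite logits at label-word positions: {logits}")
    shifted = logits - logits.max()
    expd = np.exp(shifted)
    probs = expd / expd.sum()
    return ClassDistribution(
        probs={c: float(p) for c, p in zip(v.class_order, probs)})


def predict_class(dist: ClassDistribution) -> str:
    """Argmax class; exact ties resolve to the earliest class in order."""
    best_cls, best_p = None, -1.0
    for cls, p in dist.probs.items():  # insertion order == class order
        if p > best_p:
            best_cls, best_p = cls, p
    assert best_cls is not None
    return best_cls
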