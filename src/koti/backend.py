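"""Model backends: tokenizer, deterministic mock, fine-tuning, registry.

Two kinds of backend are distinguished. *Masked* backends score the
vocabulary at the mask position of an encoder-layout input; *causal*
backends score the next token at the end of a decoder-layout input.

The centerpiece for testing is a deterministic mock backend that
operationalizes the premise the insertion methods rest on: the class
signal a model can extract decays with the token distance between the
scoring position (the template) and the class-revealing cue in the text.
Each class has a disjoint cue lexicon; the logit assigned to a class's
label word is ``base - decay * d`` where ``d`` is the distance to the
nearest visible cue token, and zero (no signal) when no cue lies within
the visibility ``window`` or the cue was truncated away. Distances and
budgets are therefore exactly countable in tests.

:func:`finetune` implements the prompt-based fine-tuning contract:
cross-entropy between the verbalizer's class distribution and the gold
class, AdamW with weight decay 0.01 on all parameters except biases and
normalization layers. The mock backend is not trainable (fine-tuning it is
a warned no-op); the :class:`~koti.tiny_lm.TinyMaskedLM` is.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .insertion import PromptInput
from .task_config import TaskSpec
from .tiny_lm import AdamW, TinyMaskedLM
from .verbalizer import Verbalizer, build_verbalizer


class BackendError(RuntimeError):
    """Layout/kind mismatch, over-budget input, or training failure."""


class WhitespaceTokenizer:
    """Deterministic whitespace tokenizer with a growable closed vocabulary.

    Ids 0 and 1 are reserved for ``[MASK]`` and ``[UNK]``. New words are
    assigned ids in first-seen order; after :meth:`freeze` unseen words map
    to ``[UNK]`` instead of growing the vocabulary (needed once a model
    with a fixed embedding table has been built). One special token is
    budgeted per input, as a stand-in for a [CLS]/BOS marker.
    """

    mask_token = "[MASK]"
    unk_token = "[UNK]"
    num_special_tokens = 1

    def __init__(self, lexicon: Sequence[str] = ()) -> None:
        self._vocab: dict[str, int] = {self.mask_token: 0, self.unk_token: 1}
        self._words: list[str] = [self.mask_token, self.unk_token]
        self._frozen = False
        for word in lexicon:
            self.token_to_id(word)

    @property
    def mask_token_id(self) -> int:
        return 0

    @property
    def vocab_size(self) -> int:
        return len(self._words)

    def freeze(self) -> None:
        self._frozen = True

    def token_to_id(self, word: str) -> int:
        idx = self._vocab.get(word)
        if idx is None:
            if self._frozen:
                return 1
            idx = len(self._words)
            self._vocab[word] = idx
            self._words.append(word)
        return idx

    def encode(self, text: str) -> list[int]:
        return [self.token_to_id(w) for w in text.split()]

    def decode(self, ids: Sequence[int]) -> str:
        return " ".join(self._words[i] if 0 <= i < len(self._words)
                        else self.unk_token for i in ids)


@dataclass(frozen=True)
class MockBackendConfig:
    """Parameters of the keyword-proximity mock backend.

    ``cue_lexicon`` maps each class name to the tokens that reveal it;
    lexicons must be disjoint across classes. ``base`` is the logit granted
    at distance zero, eroded by ``decay`` per token of distance (never
    below zero); beyond ``window`` tokens the cue is invisible and
    contributes nothing.

    ``noise_sd`` optionally adds a reproducible per-(note, class) logit
    perturbation drawn from N(0, noise_sd) and seeded by ``seed``: scoring
    the same note twice is still bit-identical, but across notes the
    perturbation acts as noise, which turns the argmax accuracy into a
    smooth function of the signal margin instead of a hard threshold. The
    default of 0 keeps the mock fully noiseless.
    """

    cue_lexicon: Mapping[str, tuple[str, ...]]
    decay: float = 0.02
    window: int = 150
    base: float = 4.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cue_lexicon",
                           {c: tuple(v) for c, v in self.cue_lexicon.items()})
        for value in (self.decay, self.base, float(self.window),
                      self.noise_sd):
            if not math.isfinite(value):
                raise ValueError("decay, window, base and noise_sd must "
                                 "be finite")
        if self.decay < 0 or self.window < 0 or self.noise_sd < 0:
            raise ValueError("decay, window and noise_sd must be "
                             "non-negative")
        seen: set[str] = set()
        for cls, cues in self.cue_lexicon.items():
            overlap = seen & set(cues)
            if overlap:
                raise ValueError(
                    f"cue lexicons must be disjoint; {sorted(overlap)} "
                    f"reused by class {cls!r}")
            seen |= set(cues)


class MockBackend:
    """Deterministic proximity-scoring test double.

    Stateless and therefore trivially reproducible: the same input always
    yields bit-identical logits.
    """

    trainable = False

    def __init__(self, cfg: MockBackendConfig,
                 tokenizer: WhitespaceTokenizer,
                 class_token: Mapping[str, int],
                 kind: str = "masked", max_input: int = 512) -> None:
        if kind not in ("masked", "causal"):
            raise ValueError(f"kind must be masked|causal, got {kind!r}")
        if max_input < 16:
            raise ValueError("max_input must be >= 16")
        self.cfg = cfg
        self.kind = kind
        self.max_input = max_input
        self.tokenizer = tokenizer
        self.class_token = dict(class_token)
        if cfg.cue_lexicon and not set(cfg.cue_lexicon) & set(class_token):
            # classic pitfall: YAML parses unquoted yes/no keys as booleans
            raise BackendError(
                f"cue lexicon classes {sorted(map(repr, cfg.cue_lexicon))} "
                f"share nothing with task classes "
                f"{sorted(map(repr, class_token))}; if the config is YAML, "
                "quote keys like 'yes'/'no'")
        self._cue_ids = {
            cls: {tokenizer.token_to_id(w) for w in cues}
            for cls, cues in cfg.cue_lexicon.items()
        }

    def clone(self) -> "MockBackend":
        return self

    def score(self, pinput: PromptInput) -> np.ndarray:
        if pinput.total_tokens > self.max_input:
            raise BackendError(
                f"input of {pinput.total_tokens} tokens exceeds "
                f"max_input {self.max_input}")
        if self.kind == "masked":
            if pinput.mask_index is None:
                raise BackendError(
                    "masked backend requires an encoder layout with a mask")
            pos = pinput.mask_index
        else:
            if pinput.mask_index is not None:
                raise BackendError(
                    "causal backend requires a decoder layout (no mask)")
            pos = len(pinput.tokens) - 1
        tokens = pinput.tokens
        logits = np.zeros(self.tokenizer.vocab_size)
        for class_index, (cls, target) in enumerate(
                sorted(self.class_token.items())):
            cue_ids = self._cue_ids.get(cls, set())
            dist = min((abs(i - pos) for i, t in enumerate(tokens)
                        if t in cue_ids), default=None)
            if dist is not None and dist <= self.cfg.window:
                logits[target] = max(
                    0.0, self.cfg.base - self.cfg.decay * dist)
            if self.cfg.noise_sd > 0:
                rng = np.random.default_rng(np.random.SeedSequence(
                    [self.cfg.seed, zlib.crc32(pinput.note_id.encode()),
                     class_index]))
                logits[target] += rng.normal(0.0, self.cfg.noise_sd)
        return logits


def make_mock_backend(spec: TaskSpec, tokenizer: WhitespaceTokenizer,
                      cfg: MockBackendConfig, kind: str = "masked",
                      max_input: int = 512) -> MockBackend:
    """Wire a mock backend to a task's verbalizer token ids."""
    verb = build_verbalizer(spec, tokenizer)
    return MockBackend(cfg, tokenizer, verb.class_token, kind=kind,
                       max_input=max_input)


# -- fine-tuning -----------------------------------------------------------


def default_decay_exclusion(name: str) -> bool:
    """True for parameters conventionally exempt from weight decay."""
    return "bias" in name or "norm" in name


@dataclass(frozen=True)
class FinetuneConfig:
    """Prompt-based fine-tuning hyper-parameters.

    Weight decay defaults to 0.01 and is withheld from biases and
    normalization parameters via ``decay_exclusions``. Learning rate,
    batch size and epoch count are left to hyper-parameter search.
    """

    learning_rate: float = 0.002
    batch_size: int = 8
    epochs: int = 10
    weight_decay: float = 0.01
    decay_exclusions: object = field(default=default_decay_exclusion)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


def finetune(backend, examples: Sequence[tuple[PromptInput, str]],
             cfg: FinetuneConfig, verbalizer: Verbalizer,
             return_optimizer: bool = False):
    """Fine-tune a trainable backend on (input, gold class) pairs.

    Minimizes the cross-entropy between the verbalizer's restricted
    softmax and the gold class. Returns ``(backend, epoch_losses)`` — the
    per-epoch mean training losses — or, with ``return_optimizer=True``,
    ``(backend, epoch_losses, optimizer)`` for weight-decay audits.
    With ``epochs=0`` the backend is returned unchanged.
    """
    if not getattr(backend, "trainable", False):
        warnings.warn(f"{type(backend).__name__} is not trainable; "
                      "fine-tuning is a no-op", stacklevel=2)
        return (backend, [], None) if return_optimizer else (backend, [])
    if cfg.epochs == 0:
        return (backend, [], None) if return_optimizer else (backend, [])
    if not examples:
        raise BackendError("cannot fine-tune on an empty training set")

    class_ids = verbalizer.token_ids
    class_index = {c: i for i, c in enumerate(verbalizer.class_order)}
    optimizer = AdamW(backend.params, lr=cfg.learning_rate,
                      weight_decay=cfg.weight_decay,
                      exclude=cfg.decay_exclusions)
    rng = np.random.default_rng(cfg.seed)
    epoch_losses: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(len(examples))
        losses: list[float] = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            grads_sum: dict[str, np.ndarray] | None = None
            for idx in batch:
                pinput, gold = examples[idx]
                logits, cache = backend.forward(np.array(pinput.tokens),
                                                pinput.mask_index)
                restricted = logits[class_ids]
                shifted = restricted - restricted.max()
                probs = np.exp(shifted)
                probs /= probs.sum()
                target = class_index[gold]
                loss = -float(np.log(probs[target] + 1e-300))
                if not math.isfinite(loss):
                    raise BackendError(f"non-finite training loss {loss}; "
                                       f"probs={probs}")
                losses.append(loss)
                dlogits = np.zeros_like(logits)
                dlogits[class_ids] = probs
                dlogits[class_ids[target]] -= 1.0
                grads = backend.backward(cache, dlogits)
                if grads_sum is None:
                    grads_sum = grads
                else:
                    for name in grads_sum:
                        grads_sum[name] += grads[name]
            assert grads_sum is not None
            for name in grads_sum:
                grads_sum[name] /= len(batch)
            optimizer.step(grads_sum)
        epoch_losses.append(float(np.mean(losses)))
    if return_optimizer:
        return backend, epoch_losses, optimizer
    return backend, epoch_losses


# -- registry --------------------------------------------------------------


def get_backend(name: str, spec: TaskSpec, tokenizer: WhitespaceTokenizer,
                mock_config: MockBackendConfig | None = None,
                model_max: int = 512, seed: int = 0):
    """Instantiate a backend by registry name.

    Supported names: ``mock`` (masked proximity mock), ``mock-causal``
    (same, scored at the sequence end), ``tiny`` (trainable NumPy masked
    LM), and ``hf-masked:<model>`` / ``hf-causal:<model>`` adapters for
    pretrained checkpoints, which require the optional ``transformers``
    dependency.
    """
    if name in ("mock", "mock-causal"):
        if mock_config is None:
            raise BackendError("the mock backend requires a MockBackendConfig")
        kind = "causal" if name == "mock-causal" else "masked"
        return make_mock_backend(spec, tokenizer, mock_config, kind=kind,
                                 max_input=model_max)
    if name == "tiny":
        return TinyMaskedLM(vocab_size=tokenizer.vocab_size + 256,
                            seed=seed, max_input=model_max)
    if name.startswith(("hf-masked:", "hf-causal:")):
        from . import hf

        kind, _, model_name = name.partition(":")
        return hf.HFBackend(model_name, kind=kind.removeprefix("hf-"),
                            max_input=model_max)
    raise BackendError(f"unknown backend {name!r}")
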