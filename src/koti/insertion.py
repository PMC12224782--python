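"""Token-budget-aware truncation and model-input assembly.

Five input layouts are supported:

* ``KOTI`` — keyword-optimized template insertion: the note is split at the
  end of the first keyword-bearing sentence, the template goes between the
  two chunks, and both flanks are truncated proportionally to their length
  (head truncation of the left chunk, tail truncation of the right) so the
  final input stays centered on the salient sentence while fitting the
  model's token limit.
* ``STI_K`` — the same two trimmed chunks concatenated, template appended
  at the end: identical token content, different template position.
* ``STI_S`` — naive baseline: the full note tail-truncated to the budget,
  template appended at the end.
* ``DECODER_KOTI`` — left-to-right models cannot take a mid-sequence cloze,
  so the trailing chunk is prepended: ``<text_b> <text_a> <template>``, and
  the class is read from the next-token logits at the end of the sequence.
* ``KOTI_OFFSET`` — KOTI with the split point moved a signed number of
  sentences away from the first flagged sentence (clamped to the note),
  used to probe how template distance from the evidence degrades
  performance.

Notes without any keyword match fall back to the ``STI_S`` layout in every
method, with ``fallback=True`` recorded on the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Protocol, Sequence

from .note_processing import SegmentedNote, SplitNote, split_at_sentence
from .task_config import MASK_PLACEHOLDER, TaskSpec, TemplateError


class Method(str, Enum):
    KOTI = "koti"
    STI_K = "sti-k"
    STI_S = "sti-s"
    DECODER_KOTI = "decoder-koti"
    KOTI_OFFSET = "koti-offset"


class InsertionError(ValueError):
    """Invalid method/offset combination or malformed assembly request."""


class BudgetError(InsertionError):
    """The token budget leaves no room for note text."""


class TokenizerContract(Protocol):
    """Minimal text<->token mapping a backend must provide."""

    mask_token: str
    mask_token_id: int
    num_special_tokens: int

    def encode(self, text: str) -> list[int]: ...

    def decode(self, ids: Sequence[int]) -> str: ...


@dataclass(frozen=True)
class TokenBudget:
    """Token accounting for one model/template combination.

    ``available`` is what remains for note text once the template and the
    backend's special tokens are reserved out of the model's input limit,
    so an assembled input can never exceed ``model_max``.
    """

    model_max: int
    template_tokens: int
    special_tokens: int

    def __post_init__(self) -> None:
        if min(self.model_max, self.template_tokens,
               self.special_tokens) < 0:
            raise BudgetError("token counts must be non-negative")
        if self.available < 1:
            raise BudgetError(
                f"no room for note text: model_max={self.model_max}, "
                f"template={self.template_tokens}, "
                f"special={self.special_tokens}")

    @property
    def available(self) -> int:
        return self.model_max - self.template_tokens - self.special_tokens


@dataclass(frozen=True)
class Segment:
    role: str  # chunk_a | template | chunk_b
    tokens: tuple[int, ...]


@dataclass(frozen=True)
class PromptInput:
    """An assembled, budget-respecting model input.

    ``mask_index`` is the position of the mask token in the flattened
    sequence for encoder layouts; decoder layouts carry no mask and are
    scored at the final position. ``total_tokens`` includes the backend's
    special tokens.
    """

    note_id: str
    method: Method
    segments: tuple[Segment, ...]
    mask_index: int | None
    fallback: bool
    total_tokens: int
    offset: int = 0
    effective_offset: int = 0

    @property
    def tokens(self) -> tuple[int, ...]:
        return tuple(t for seg in self.segments for t in seg.tokens)

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(seg.role for seg in self.segments)

    def to_debug_dict(self, tokenizer: TokenizerContract) -> dict:
        return {
            "note_id": self.note_id,
            "method": self.method.value,
            "offset": self.offset,
            "effective_offset": self.effective_offset,
            "fallback": self.fallback,
            "mask_index": self.mask_index,
            "total_tokens": self.total_tokens,
            "segments": [
                {"role": seg.role, "n_tokens": len(seg.tokens),
                 "text": tokenizer.decode(seg.tokens)}
                for seg in self.segments
            ],
        }


def proportional_truncate(tokens_a: Sequence[int], tokens_b: Sequence[int],
                          available: int) -> tuple[list[int], list[int]]:
    """Trim two chunks to a shared budget, proportionally to their lengths.

    The left chunk is head-truncated (tokens dropped from the front) and
    the right chunk tail-truncated (dropped from the end), keeping the text
    adjacent to the split point. The number removed from each chunk is its
    proportional share of the excess, rounded half-up for the left chunk
    with the remainder taken from the right, capped at each chunk's length.
    """
    if available < 1:
        raise BudgetError(f"available budget must be >= 1, got {available}")
    len_a, len_b = len(tokens_a), len(tokens_b)
    total = len_a + len_b
    excess = total - available
    if excess <= 0:
        return list(tokens_a), list(tokens_b)
    remove_a = math.floor(excess * len_a / total + 0.5)  # round half-up
    remove_a = min(remove_a, len_a)
    remove_b = excess - remove_a
    if remove_b > len_b:  # re-cap: push the overflow back onto a
        remove_a += remove_b - len_b
        remove_b = len_b
    return list(tokens_a[remove_a:]), list(tokens_b[:len_b - remove_b])


def template_tokens(spec: TaskSpec, tokenizer: TokenizerContract,
                    with_mask: bool = True) -> list[int]:
    """Tokenize the task template.

    For encoder layouts the ``[MASK]`` placeholder is replaced by the
    tokenizer's mask token and must surface as exactly one mask token id.
    For decoder layouts (``with_mask=False``) the placeholder is dropped:
    the model predicts the class word as the next token after the template.
    """
    if with_mask:
        text = spec.template_text.replace(MASK_PLACEHOLDER,
                                          tokenizer.mask_token)
        ids = tokenizer.encode(text)
        if ids.count(tokenizer.mask_token_id) != 1:
            raise TemplateError(
                f"template {spec.template_text!r} did not tokenize to "
                "exactly one mask token; keep the placeholder "
                "whitespace-separated")
        return ids
    text = spec.template_text.replace(MASK_PLACEHOLDER, " ").strip()
    return tokenizer.encode(text)


def make_budget(spec: TaskSpec, tokenizer: TokenizerContract,
                model_max: int = 512,
                method: Method = Method.KOTI) -> TokenBudget:
    """Budget for a task/tokenizer/method combination."""
    with_mask = method is not Method.DECODER_KOTI
    n_template = len(template_tokens(spec, tokenizer, with_mask=with_mask))
    return TokenBudget(model_max=model_max, template_tokens=n_template,
                       special_tokens=tokenizer.num_special_tokens)


def _assemble(note_id: str, method: Method, segments: list[Segment],
              budget: TokenBudget, mask_id: int | None, fallback: bool,
              offset: int = 0, effective_offset: int = 0) -> PromptInput:
    flat = [t for seg in segments for t in seg.tokens]
    total = len(flat) + budget.special_tokens
    if total > budget.model_max:  # pragma: no cover - guarded by truncation
        raise BudgetError(f"assembled input has {total} tokens "
                          f"> model_max {budget.model_max}")
    mask_index = flat.index(mask_id) if mask_id is not None else None
    return PromptInput(note_id=note_id, method=method,
                       segments=tuple(segments), mask_index=mask_index,
                       fallback=fallback, total_tokens=total,
                       offset=offset, effective_offset=effective_offset)


def build_prompt_input(split: SplitNote, spec: TaskSpec, method: Method,
                       tokenizer: TokenizerContract, budget: TokenBudget,
                       offset: int = 0,
                       segmented: SegmentedNote | None = None) -> PromptInput:
    """Assemble the model input for one note under one insertion method.

    ``segmented`` (the flagged sentence decomposition the split came from)
    is required for ``KOTI_OFFSET`` so the split point can be moved; the
    requested offset is clamped to the note and the effective offset
    recorded.
    """
    method = Method(method)
    if offset != 0 and method is not Method.KOTI_OFFSET:
        raise InsertionError(
            f"offset={offset} is only valid with KOTI_OFFSET, not {method}")

    decoder = method is Method.DECODER_KOTI
    tmpl = template_tokens(spec, tokenizer, with_mask=not decoder)
    mask_id = None if decoder else tokenizer.mask_token_id
    effective_offset = 0

    if method is Method.KOTI_OFFSET:
        if segmented is None:
            raise InsertionError("KOTI_OFFSET requires the segmented note")
        if segmented.flags:
            target = min(max(segmented.flags[0] + offset, 0),
                         len(segmented.sentences) - 1)
            effective_offset = target - segmented.flags[0]
            split = split_at_sentence(segmented, target, matched=True)
        else:
            split = SplitNote(note_id=split.note_id, text_a=split.text,
                              text_b="", matched=False)

    fallback = not split.matched and method is not Method.STI_S

    if method is Method.STI_S or fallback:
        # naive layout: full text, tail truncation, template appended
        kept = tokenizer.encode(split.text)[:budget.available]
        segments = [Segment("chunk_a", tuple(kept)),
                    Segment("template", tuple(tmpl))]
        return _assemble(split.note_id, method, segments, budget, mask_id,
                         fallback=fallback, offset=offset,
                         effective_offset=effective_offset)

    tokens_a = tokenizer.encode(split.text_a)
    tokens_b = tokenizer.encode(split.text_b)
    trim_a, trim_b = proportional_truncate(tokens_a, tokens_b,
                                           budget.available)
    seg_a = Segment("chunk_a", tuple(trim_a))
    seg_b = Segment("chunk_b", tuple(trim_b))
    seg_t = Segment("template", tuple(tmpl))

    if method in (Method.KOTI, Method.KOTI_OFFSET):
        segments = [seg_a, seg_t, seg_b]
    elif method is Method.STI_K:
        segments = [seg_a, seg_b, seg_t]
    elif method is Method.DECODER_KOTI:
        segments = [seg_b, seg_a, seg_t]
    else:  # pragma: no cover - exhaustive enum
        raise InsertionError(f"unknown method {method!r}")
    return _assemble(split.note_id, method, segments, budget, mask_id,
                     fallback=False, offset=offset,
                     effective_offset=effective_offset)


def prepare_input(text: str, spec: TaskSpec, method: Method,
                  tokenizer: TokenizerContract, budget: TokenBudget,
                  offset: int = 0, note_id: str = "") -> PromptInput:
    """Full pipeline for one note: segment, flag, split, assemble."""
    from .note_processing import flag_keyword_sentences, segment_sentences, \
        split_at_first_flag

    seg = flag_keyword_sentences(segment_sentences(text, note_id=note_id),
                                 spec.keywords)
    split = split_at_first_flag(seg)
    return build_prompt_input(split, spec, method, tokenizer, budget,
                              offset=offset, segmented=seg)
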