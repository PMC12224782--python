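"""Synthetic clinical-note corpora with controllable evidence placement.

Real discharge summaries are long, line-structured, and mostly
administrative: the sentence that decides a classification label is buried
somewhere among filler about vitals, billing and follow-up plans, and the
note as a whole frequently exceeds a model's input limit. The generator
reproduces exactly that sparsity structure, nothing more: each non-unknown
note contains exactly one *evidence sentence* embedding one class cue
token (e.g. ``"endorses"`` / ``"denies"``) together with one task keyword,
at a controllable relative position; everything else is filler drawn from
an administrative lexicon. At a configurable per-note rate, one filler
sentence contains a task keyword *without* any cue (a distractor), which
exercises the first-flagged-sentence rule against false anchors while
keeping keyword matches predominantly informative, as they are when
keywords are chosen to describe the task. Notes of the designated unknown
class contain no keywords at all.

Cue, keyword and filler vocabularies are disjoint by validation, so
ground truth is unambiguous by construction and an oracle can re-derive
every label from the text alone. Token counts use whitespace tokens (the
mock tokenizer's unit); the fraction of notes exceeding a stated token
budget is controlled per note by construction, so the realized fraction
matches the target closely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .backend import MockBackendConfig
from .note_processing import Note
from .task_config import TaskSpec

_FILLER = (
    "patient", "seen", "clinic", "today", "routine", "followup", "visit",
    "history", "reviewed", "medications", "continued", "plan", "discussed",
    "stable", "exam", "unremarkable", "labs", "ordered", "will", "return",
    "as", "needed", "section", "header", "admin", "billing", "insurance",
    "form", "vitals", "recorded", "tolerating", "diet", "ambulating",
    "without", "assistance", "scheduled", "counseled", "advised",
)


class SynthConfigError(ValueError):
    """Inconsistent generator configuration."""


class IntegrityError(RuntimeError):
    """A note's text disagrees with its stored provenance."""


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic corpus.

    Defaults emulate a gynecological-encounter corpus for a three-way
    symptom task (``unknown`` / ``yes`` / ``no``): 300 notes, evidence
    position uniform over the note, 70% of notes over a 512-token budget,
    and a 10% chance per note of one false-anchor distractor sentence.
    ``unknown`` is listed first so
    that a no-signal verbalizer tie resolves to the no-evidence class,
    matching the clinical semantics of an unmentioned finding.
    """

    n_notes: int = 300
    classes: tuple[str, ...] = ("unknown", "yes", "no")
    prevalence: tuple[float, ...] = (0.2, 0.4, 0.4)
    sentences_per_note: tuple[int, int] = (25, 50)
    tokens_per_sentence: tuple[int, int] = (10, 18)
    evidence_position: tuple = ("uniform",)
    over_budget_fraction: float = 0.7
    budget_tokens: int = 512
    distractor_rate: float = 0.1
    filler_lexicon: tuple[str, ...] = _FILLER
    cue_lexicon: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {"yes": ("endorses",), "no": ("denies",)})
    task_keywords: tuple[str, ...] = ("cramps", "menstrual pain")
    unknown_class_name: str | None = "unknown"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        object.__setattr__(self, "prevalence", tuple(self.prevalence))
        object.__setattr__(self, "cue_lexicon",
                           {c: tuple(v) for c, v in self.cue_lexicon.items()})
        if len(self.prevalence) != len(self.classes):
            raise SynthConfigError("one prevalence per class required")
        if abs(sum(self.prevalence) - 1.0) > 1e-9:
            raise SynthConfigError(
                f"prevalences must sum to 1, got {sum(self.prevalence)}")
        for lo, hi in (self.sentences_per_note, self.tokens_per_sentence):
            if lo < 1 or hi < lo:
                raise SynthConfigError(f"empty range ({lo}, {hi})")
        if not 0.0 <= self.over_budget_fraction <= 1.0:
            raise SynthConfigError("over_budget_fraction must be in [0, 1]")
        if not 0.0 <= self.distractor_rate <= 1.0:
            raise SynthConfigError("distractor_rate must be in [0, 1]")
        evidence_classes = [c for c in self.classes
                           if c != self.unknown_class_name]
        missing = [c for c in evidence_classes if c not in self.cue_lexicon]
        if missing:
            raise SynthConfigError(f"no cue tokens for classes {missing}")
        cues = {w for v in self.cue_lexicon.values() for w in v}
        filler = set(self.filler_lexicon)
        if cues & filler:
            raise SynthConfigError(
                f"cue and filler lexicons overlap: {sorted(cues & filler)}")
        for kw in self.task_keywords:
            hits = [w for w in filler | cues if kw.lower() in w.lower()]
            if hits:
                raise SynthConfigError(
                    f"keyword {kw!r} collides with lexicon words {hits}")

    def mock_backend_config(self, **overrides) -> MockBackendConfig:
        """Mock backend wired to this corpus's cue lexicon."""
        return MockBackendConfig(cue_lexicon=dict(self.cue_lexicon),
                                 seed=self.seed, **overrides)


@dataclass(frozen=True)
class SynthNote:
    """A generated note plus its ground-truth provenance."""

    id: str
    text: str
    label: str
    evidence_index: int | None
    token_count: int

    def to_note(self) -> Note:
        return Note(id=self.id, text=self.text, label=self.label)


def synth_task_spec(cfg: SynthConfig,
                    name: str = "synthetic-symptom") -> TaskSpec:
    """Task spec matched to a synthetic corpus (identity label words)."""
    return TaskSpec(
        name=name,
        template_text="symptom reported: [MASK]",
        classes=cfg.classes,
        label_words={c: c for c in cfg.classes},
        keywords=cfg.task_keywords,
        positive_class=("yes" if "yes" in cfg.classes else cfg.classes[0]),
    )


def _draw_position(rng: np.random.Generator, dist: tuple) -> float:
    kind = dist[0]
    if kind == "uniform":
        return float(rng.uniform())
    if kind == "beta":
        return float(rng.beta(dist[1], dist[2]))
    raise SynthConfigError(f"unknown evidence position distribution {dist!r}")


def _sentence_lengths(rng: np.random.Generator, cfg: SynthConfig,
                      over_budget: bool) -> list[int]:
    """Plan per-sentence token counts meeting the over/under-budget target.

    The sentence-count range is a soft prior: sentences are appended (for
    over-budget notes) or dropped (for under-budget notes) until the note's
    whitespace token count lands on the requested side of the budget.
    Over-budget notes aim at 1.2-3x the budget, the regime of real
    discharge summaries, where most of a note cannot fit the model input.
    """
    lo_s, hi_s = cfg.sentences_per_note
    lo_t, hi_t = cfg.tokens_per_sentence
    counts = list(rng.integers(lo_t, hi_t + 1,
                               size=int(rng.integers(lo_s, hi_s + 1))))
    if over_budget:
        target = cfg.budget_tokens * rng.uniform(1.2, 3.0)
        while sum(counts) < target:
            counts.append(int(rng.integers(lo_t, hi_t + 1)))
    else:
        while sum(counts) > cfg.budget_tokens and len(counts) > 2:
            counts.pop()
        if sum(counts) > cfg.budget_tokens:
            raise SynthConfigError(
                "cannot build an under-budget note: two sentences already "
                "exceed budget_tokens")
    return [int(c) for c in counts]


def _filler_sentence(rng: np.random.Generator, cfg: SynthConfig,
                     n_tokens: int, keyword: str | None) -> str:
    words = list(rng.choice(cfg.filler_lexicon, size=n_tokens))
    if keyword is not None:
        kw_words = keyword.split()
        pos = 1 if n_tokens > len(kw_words) else 0
        words[pos:pos + len(kw_words)] = kw_words
        words = words[:n_tokens]
    return " ".join(words) + "."


def _evidence_sentence(rng: np.random.Generator, cfg: SynthConfig,
                       cue: str, keyword: str, n_tokens: int) -> str:
    kw_words = keyword.split()
    words = ["patient", cue, *kw_words]
    while len(words) < n_tokens:
        words.append(str(rng.choice(cfg.filler_lexicon)))
    return " ".join(words[:max(n_tokens, len(words))]) + "."


def generate_corpus(cfg: SynthConfig) -> list[SynthNote]:
    """Generate a corpus; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    notes: list[SynthNote] = []
    for i in range(cfg.n_notes):
        label = str(rng.choice(cfg.classes, p=cfg.prevalence))
        over = bool(rng.uniform() < cfg.over_budget_fraction)
        counts = _sentence_lengths(rng, cfg, over)
        n_sent = len(counts)
        is_unknown = label == cfg.unknown_class_name
        distractor_index = None
        if is_unknown:
            evidence_index = None
        else:
            u = _draw_position(rng, cfg.evidence_position)
            evidence_index = int(round(u * (n_sent - 1)))
            if n_sent > 1 and rng.uniform() < cfg.distractor_rate:
                others = [j for j in range(n_sent) if j != evidence_index]
                distractor_index = int(rng.choice(others))
        sentences: list[str] = []
        for j, n_tokens in enumerate(counts):
            if j == evidence_index:
                cue = str(rng.choice(cfg.cue_lexicon[label]))
                keyword = str(rng.choice(cfg.task_keywords))
                sentences.append(
                    _evidence_sentence(rng, cfg, cue, keyword, n_tokens))
            else:
                keyword = (str(rng.choice(cfg.task_keywords))
                           if j == distractor_index else None)
                sentences.append(
                    _filler_sentence(rng, cfg, n_tokens, keyword))
        text = " ".join(sentences)
        notes.append(SynthNote(id=f"synth-{i:05d}", text=text, label=label,
                               evidence_index=evidence_index,
                               token_count=len(text.split())))
    return notes


def oracle_label(note: SynthNote, cfg: SynthConfig) -> str:
    """Re-derive a note's class from its text and check provenance.

    The class is the one whose cue token occurs in the note (cues only
    ever appear in the evidence sentence); with no cue the note belongs to
    the unknown class. A mismatch with the stored label means the note was
    tampered with.
    """
    tokens = {w.rstrip(".!?") for w in note.text.split()}
    found = [cls for cls, cues in cfg.cue_lexicon.items()
             if tokens & set(cues)]
    if len(found) > 1:
        raise IntegrityError(f"note {note.id}: cues of several classes "
                             f"present: {found}")
    if found:
        derived = found[0]
    elif cfg.unknown_class_name is not None:
        derived = cfg.unknown_class_name
    else:
        raise IntegrityError(f"note {note.id}: no cue found and no "
                             "unknown class configured")
    if derived != note.label:
        raise IntegrityError(
            f"note {note.id}: text implies {derived!r} but provenance "
            f"says {note.label!r}")
    return derived


def write_corpus(corpus: Sequence[SynthNote], path: str | Path) -> None:
    """Write ``notes.jsonl`` plus a ``.provenance.jsonl`` sidecar.

    The sidecar (evidence position, token count) is never read by the
    classification pipeline; it exists for tests and audits.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for note in corpus:
            fh.write(json.dumps({"id": note.id, "text": note.text,
                                 "label": note.label}) + "\n")
    sidecar = path.with_suffix(".provenance.jsonl")
    with open(sidecar, "w", encoding="utf-8") as fh:
        for note in corpus:
            fh.write(json.dumps({
                "id": note.id, "label": note.label,
                "evidence_index": note.evidence_index,
                "token_count": note.token_count}) + "\n")
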