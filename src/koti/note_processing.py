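"""Sentence segmentation, keyword flagging, and note splitting.

Clinical notes are line-structured documents: section headers, medication
lists and narrative fragments separated by newlines, with conventional
sentence terminators inside narrative passages. The splitter here is a
deterministic rule: a sentence ends at ``. ! ?`` followed by whitespace, or
at a newline. Abbreviations are not special-cased — determinism and exact
reconstruction matter more than linguistic precision for template
placement, and the splitter is pluggable for anyone who disagrees.

Keyword matching is case-insensitive plain-substring matching with no word
boundaries: anchor lists routinely contain sub-words (``"osteo"`` must hit
``"osteoarthritis"``).
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .task_config import SchemaError, TaskSpec

# sentence boundary: terminator followed by horizontal whitespace, or newline
_BOUNDARY = re.compile(r"(?<=[.!?])[ \t]+|\n")


@dataclass(frozen=True)
class Note:
    """A clinical note: unique id, raw text, optional gold label."""

    id: str
    text: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("note id must be non-empty")


@dataclass(frozen=True)
class SegmentedNote:
    """Sentence decomposition of a note as character spans.

    ``sentences`` are 0-based half-open ``(start, end)`` spans over ``text``,
    sorted and non-overlapping; characters between spans are whitespace
    gaps, so spans plus gaps reconstruct the text exactly. ``flags`` lists
    the indices of sentences containing at least one keyword, ascending.
    """

    note_id: str
    text: str
    sentences: tuple[tuple[int, int], ...]
    flags: tuple[int, ...] = ()

    def sentence_text(self, index: int) -> str:
        start, end = self.sentences[index]
        return self.text[start:end]


@dataclass(frozen=True)
class SplitNote:
    """The ``<text_a>`` / ``<text_b>`` decomposition of a note.

    ``text_a`` ends at the end of the first flagged sentence; ``text_b`` is
    the remainder. When no keyword matched, ``matched`` is False, ``text_a``
    is the whole note and ``text_b`` is empty (the template then falls back
    to end-of-input insertion).
    """

    note_id: str
    text_a: str
    text_b: str
    matched: bool
    split_sentence_index: int | None = None

    @property
    def text(self) -> str:
        return self.text_a + self.text_b


def _trim(text: str, start: int, end: int) -> tuple[int, int] | None:
    """Shrink a span to exclude surrounding whitespace; None if empty."""
    while start < end and text[start].isspace():
        start += 1
    while end > start and text[end - 1].isspace():
        end -= 1
    if start == end:
        return None
    return (start, end)


def segment_sentences(text: str, note_id: str = "") -> SegmentedNote:
    """Decompose ``text`` into sentence spans (flags left empty).

    Deterministic; empty text yields zero sentences.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for match in _BOUNDARY.finditer(text):
        span = _trim(text, start, match.start())
        if span is not None:
            spans.append(span)
        start = match.end()
    tail = _trim(text, start, len(text))
    if tail is not None:
        spans.append(tail)
    return SegmentedNote(note_id=note_id, text=text, sentences=tuple(spans))


def flag_keyword_sentences(seg: SegmentedNote,
                           keywords: Sequence[str]) -> SegmentedNote:
    """Return a copy of ``seg`` with keyword-bearing sentences flagged.

    A sentence is flagged iff its lowercase text contains at least one
    keyword as a substring. An empty keyword list flags nothing.
    """
    kws = [k.lower() for k in keywords if k]
    flags = tuple(
        i for i, (s, e) in enumerate(seg.sentences)
        if any(k in seg.text[s:e].lower() for k in kws)
    )
    return dataclasses.replace(seg, flags=flags)


def split_at_sentence(seg: SegmentedNote, index: int,
                      matched: bool = True) -> SplitNote:
    """Split the note text at the end of sentence ``index``."""
    end = seg.sentences[index][1]
    return SplitNote(note_id=seg.note_id, text_a=seg.text[:end],
                     text_b=seg.text[end:], matched=matched,
                     split_sentence_index=index)


def split_at_first_flag(seg: SegmentedNote) -> SplitNote:
    """Split at the end of the first flagged sentence.

    Later flags are ignored: only the first keyword-bearing sentence
    anchors the split. With no flags the whole text becomes ``text_a`` and
    ``matched`` is False.
    """
    if seg.flags:
        return split_at_sentence(seg, seg.flags[0], matched=True)
    return SplitNote(note_id=seg.note_id, text_a=seg.text, text_b="",
                     matched=False, split_sentence_index=None)


# -- corpus I/O ------------------------------------------------------------


def read_notes_jsonl(path: str | Path,
                     spec: TaskSpec | None = None) -> list[Note]:
    """Read a JSONL note corpus (keys ``id``, ``text``, optional ``label``).

    When a task spec is given, raw labels are passed through
    ``spec.label_remap`` and the final label must be one of the task's
    classes.
    """
    notes: list[Note] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            record = json.loads(line)
            label = record.get("label")
            if spec is not None and label is not None:
                label = spec.label_remap.get(label, label)
                if label not in spec.classes:
                    raise SchemaError(
                        f"{path}:{lineno}: label {record.get('label')!r} "
                        f"not in classes {list(spec.classes)} after remap")
            notes.append(Note(id=str(record["id"]), text=record["text"],
                              label=label))
    return notes


def write_notes_jsonl(notes: Iterable[Note], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for note in notes:
            record = {"id": note.id, "text": note.text}
            if note.label is not None:
                record["label"] = note.label
            fh.write(json.dumps(record) + "\n")
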