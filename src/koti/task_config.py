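"""Task specifications for prompt-based clinical note classification.

A :class:`TaskSpec` couples a cloze template (e.g. ``"smoking: [MASK]"``)
with an ordered set of label classes, a one-word verbalizer entry per class,
and the keyword list used to anchor template insertion inside long notes.
Specs are plain YAML/JSON files so that a new classification task can be
added without touching code.

The mask placeholder in config files is always the literal ``[MASK]``; it is
substituted with the backend tokenizer's actual mask token when the model
input is assembled, because different pretrained models spell their mask
token differently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

MASK_PLACEHOLDER = "[MASK]"

_FILE_KEYS = ("name", "template", "classes", "label_words", "keywords",
              "label_remap", "positive_class")


class TaskConfigError(ValueError):
    """Base class for invalid task specifications."""


class TemplateError(TaskConfigError):
    """Template does not contain exactly one mask placeholder."""


class SchemaError(TaskConfigError):
    """Classes, label words, keywords or remaps are inconsistent."""


@dataclass(frozen=True)
class TaskSpec:
    """A validated classification task definition.

    Parameters
    ----------
    name:
        Short identifier, e.g. ``"smk"``.
    template_text:
        Prefix-style cloze template containing the literal ``[MASK]``
        placeholder exactly once.
    classes:
        Ordered label class names (at least two). The order is meaningful:
        argmax ties in the verbalizer resolve to the earliest class.
    label_words:
        One single verbalizer word per class; words must be pairwise
        distinct and tokenize to a single token under the backend tokenizer.
    keywords:
        Lowercase anchor strings matched case-insensitively as plain
        substrings against each sentence. May be empty, in which case every
        note falls back to end-of-input template insertion.
    label_remap:
        Optional mapping from raw corpus labels to class names, applied by
        the JSONL note reader.
    positive_class:
        Class whose F1 summarises binary tasks; defaults to the first class.
    """

    name: str
    template_text: str
    classes: tuple[str, ...]
    label_words: Mapping[str, str]
    keywords: tuple[str, ...] = ()
    label_remap: Mapping[str, str] = field(default_factory=dict)
    positive_class: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        object.__setattr__(self, "label_words", dict(self.label_words))
        object.__setattr__(
            self, "keywords",
            tuple(str(k).lower() for k in self.keywords))
        object.__setattr__(self, "label_remap", dict(self.label_remap))
        if self.positive_class is None and self.classes:
            object.__setattr__(self, "positive_class", self.classes[0])
        self._validate()

    def _validate(self) -> None:
        if not self.name:
            raise SchemaError("task name must be non-empty")
        n_masks = self.template_text.count(MASK_PLACEHOLDER)
        if n_masks != 1:
            raise TemplateError(
                f"template must contain {MASK_PLACEHOLDER!r} exactly once, "
                f"found {n_masks} in {self.template_text!r}")
        if len(self.classes) < 2:
            raise SchemaError("at least two classes are required")
        if len(set(self.classes)) != len(self.classes):
            raise SchemaError("class names must be unique")
        if set(self.label_words) != set(self.classes):
            raise SchemaError(
                "label_words must have exactly one entry per class; got "
                f"{sorted(self.label_words)} for classes {list(self.classes)}")
        words = list(self.label_words.values())
        if len(set(words)) != len(words):
            raise SchemaError(f"label words must be pairwise distinct: {words}")
        for kw in self.keywords:
            if not kw:
                raise SchemaError("keywords must be non-empty strings")
        for raw, cls in self.label_remap.items():
            if cls not in self.classes:
                raise SchemaError(
                    f"label_remap value {cls!r} (for raw label {raw!r}) "
                    "is not a class")
        if self.positive_class not in self.classes:
            raise SchemaError(
                f"positive_class {self.positive_class!r} is not a class")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "template": self.template_text,
            "classes": list(self.classes),
            "label_words": dict(self.label_words),
            "keywords": list(self.keywords),
            "label_remap": dict(self.label_remap),
            "positive_class": self.positive_class,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "TaskSpec":
        unknown = set(data) - set(_FILE_KEYS)
        if unknown:
            raise SchemaError(f"unknown task config keys: {sorted(unknown)}")
        try:
            return cls(
                name=data["name"],
                template_text=data["template"],
                classes=tuple(data["classes"]),
                label_words=dict(data["label_words"]),
                keywords=tuple(data.get("keywords") or ()),
                label_remap=dict(data.get("label_remap") or {}),
                positive_class=data.get("positive_class"),
            )
        except KeyError as exc:  # pragma: no cover - defensive
            raise SchemaError(f"missing task config key: {exc}") from exc


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".yaml", ".yml"):
        return "yaml"
    if suffix == ".json":
        return "json"
    raise TaskConfigError(
        f"cannot infer format from {path.name!r}; pass format='yaml'|'json'")


def load_task_spec(path: str | Path, fmt: str | None = None) -> TaskSpec:
    """Load and validate a task spec from a YAML or JSON file."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    text = path.read_text(encoding="utf-8")
    data = yaml.safe_load(text) if fmt == "yaml" else json.loads(text)
    if not isinstance(data, Mapping):
        raise SchemaError(f"task config in {path} is not a mapping")
    return TaskSpec.from_dict(data)


def save_task_spec(spec: TaskSpec, path: str | Path,
                   fmt: str | None = None) -> None:
    """Write a task spec; ``load_task_spec`` round-trips it losslessly."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    data = spec.to_dict()
    if fmt == "yaml":
        path.write_text(yaml.safe_dump(data, sort_keys=False),
                        encoding="utf-8")
    else:
        path.write_text(json.dumps(data, indent=2), encoding="utf-8")


def packaged_task_names() -> list[str]:
    """Names of the task specs shipped with the package."""
    root = resources.files("koti.tasks")
    return sorted(p.name.removesuffix(".yaml")
                  for p in root.iterdir() if p.name.endswith(".yaml"))


def packaged_task(name: str) -> TaskSpec:
    """Load one of the shipped task specs (``dys``, ``oa``, ``dep``,
    ``pvd``, ``smk``) by name."""
    ref = resources.files("koti.tasks") / f"{name}.yaml"
    try:
        text = ref.read_text(encoding="utf-8")
    except FileNotFoundError:
        raise TaskConfigError(
            f"no packaged task {name!r}; available: {packaged_task_names()}"
        ) from None
    return TaskSpec.from_dict(yaml.safe_load(text))
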