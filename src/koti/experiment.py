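"""Few-shot protocols, metrics, statistical comparisons and sweeps.

The evaluation protocol mirrors common few-shot practice for clinical
note classification: for each of ``runs`` repetitions a training set is
drawn from the labeled pool — balanced (k examples per class), size-matched
random (k·C examples reflecting the natural class mix), or a fixed total —
the backend is (optionally) fine-tuned on it, and performance is measured
on the remaining pool. Zero-shot evaluation skips sampling and training
entirely. Binary tasks are summarized by the positive class's F1;
multiclass tasks by macro-F1.

Method comparisons report ΔF1 and percent change, with p-values from a
two-sided paired t-test and the Holm–Bonferroni step-down correction
across the family of per-task tests. With five comparisons at α = 0.05
the most stringent Holm threshold is 0.05/5 = 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import precision_recall_fscore_support

from .backend import FinetuneConfig, WhitespaceTokenizer, finetune, \
    make_mock_backend
from .insertion import Method, make_budget, prepare_input
from .note_processing import Note
from .task_config import TaskSpec
from .verbalizer import build_verbalizer, predict_class, verbalize


class ExperimentError(ValueError):
    """Invalid sampling/evaluation request."""


class SamplingError(ExperimentError):
    """The pool cannot support the requested training draw."""


@dataclass(frozen=True)
class FewShotConfig:
    """Training-set sampling policy for few-shot runs.

    ``strategy`` is ``balanced`` (exactly ``k`` per class),
    ``random_matched`` (a simple random sample of ``k·C`` notes, class mix
    reflecting the pool), or ``fixed_total`` (a simple random sample of
    ``k`` notes). Sampling is without replacement; run ``i`` derives its
    RNG from ``(seed, i)`` so runs are independent and reproducible.
    """

    strategy: str = "balanced"
    k: int = 4
    runs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("balanced", "random_matched", "fixed_total"):
            raise ExperimentError(f"unknown strategy {self.strategy!r}")
        if self.k < 1:
            raise ExperimentError("k must be >= 1")
        if self.runs < 1:
            raise ExperimentError("runs must be >= 1")


@dataclass(frozen=True)
class RunResult:
    """Metrics for one evaluation run."""

    method: str
    task: str
    run_index: int
    n_train: int
    per_class: Mapping[str, tuple[float, float, float]]  # P, R, F1
    summary_f1: float

    def to_row(self) -> dict:
        row = {"method": self.method, "task": self.task,
               "run": self.run_index, "n_train": self.n_train,
               "summary_f1": self.summary_f1}
        for cls, (p, r, f1) in self.per_class.items():
            row[f"precision_{cls}"] = p
            row[f"recall_{cls}"] = r
            row[f"f1_{cls}"] = f1
        return row


def results_frame(results: Sequence[RunResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


def _run_rng(seed: int, run_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, run_index]))


def sample_training_set(pool: Sequence[Note], cfg: FewShotConfig,
                        run_index: int) -> tuple[list[Note], list[Note]]:
    """Draw one train/eval split; deterministic given (seed, run_index)."""
    if any(n.label is None for n in pool):
        raise SamplingError("every note in the pool needs a gold label")
    rng = _run_rng(cfg.seed, run_index)
    indices = np.arange(len(pool))
    if cfg.strategy == "balanced":
        chosen: list[int] = []
        labels = np.array([n.label for n in pool])
        for cls in sorted(set(labels)):
            members = indices[labels == cls]
            if len(members) < cfg.k:
                raise SamplingError(
                    f"class {cls!r} has only {len(members)} members, "
                    f"need k={cfg.k}")
            chosen.extend(rng.choice(members, size=cfg.k, replace=False))
        chosen_set = set(chosen)
    else:
        if cfg.strategy == "random_matched":
            n_classes = len({n.label for n in pool})
            size = cfg.k * n_classes
        else:  # fixed_total
            size = cfg.k
        if size > len(pool):
            raise SamplingError(f"cannot draw {size} from pool of "
                                f"{len(pool)}")
        chosen = list(rng.choice(indices, size=size, replace=False))
        chosen_set = set(chosen)
    train = [pool[i] for i in sorted(chosen_set)]
    eval_set = [pool[i] for i in indices if i not in chosen_set]
    return train, eval_set


def evaluate(preds: Sequence[str], golds: Sequence[str],
             spec: TaskSpec) -> tuple[dict, float]:
    """Per-class precision/recall/F1 and the task's summary F1.

    Degenerate 0/0 ratios are scored 0. Binary tasks are summarized by the
    positive class's F1; multiclass tasks by macro-F1 (the unweighted mean
    of per-class F1).
    """
    if len(preds) != len(golds) or not golds:
        raise ExperimentError("preds and golds must be equal-length, >= 1")
    bad = {x for x in (*preds, *golds) if x not in spec.classes}
    if bad:
        raise ExperimentError(f"labels outside task classes: {sorted(bad)}")
    p, r, f1, _ = precision_recall_fscore_support(
        golds, preds, labels=list(spec.classes), zero_division=0)
    per_class = {cls: (float(p[i]), float(r[i]), float(f1[i]))
                 for i, cls in enumerate(spec.classes)}
    if len(spec.classes) == 2:
        summary = per_class[spec.positive_class][2]
    else:
        summary = float(np.mean(f1))
    return per_class, summary


def predict_notes(notes: Sequence[Note], spec: TaskSpec, method: Method,
                  backend, tokenizer, budget, offset: int = 0,
                  verbalizer=None) -> list[str]:
    """Classify notes end to end: assemble input, score, verbalize."""
    verb = verbalizer or build_verbalizer(spec, tokenizer)
    preds = []
    for note in notes:
        pinput = prepare_input(note.text, spec, method, tokenizer, budget,
                               offset=offset, note_id=note.id)
        dist = verbalize(backend.score(pinput), verb)
        preds.append(predict_class(dist))
    return preds


@dataclass(frozen=True)
class ExperimentResult:
    results: tuple[RunResult, ...]
    mean_f1: float
    sd_f1: float

    def to_frame(self) -> pd.DataFrame:
        return results_frame(self.results)


def run_experiment(spec: TaskSpec, notes: Sequence[Note], method: Method,
                   backend, tokenizer, *, model_max: int = 512,
                   few_shot: FewShotConfig | None = None,
                   finetune_cfg: FinetuneConfig | None = None,
                   offset: int = 0) -> ExperimentResult:
    """Zero- or few-shot evaluation of one method on one task.

    Zero-shot (``few_shot=None``): a single run over the whole pool, no
    training. Few-shot: for each run, sample a training set, fine-tune a
    fresh copy of the backend on it (a no-op for untrainable backends),
    and evaluate on the remaining notes.
    """
    method = Method(method)
    budget = make_budget(spec, tokenizer, model_max=model_max, method=method)
    verb = build_verbalizer(spec, tokenizer)
    results: list[RunResult] = []
    if few_shot is None:
        preds = predict_notes(notes, spec, method, backend, tokenizer,
                              budget, offset=offset, verbalizer=verb)
        per_class, summary = evaluate(preds, [n.label for n in notes], spec)
        results.append(RunResult(method=method.value, task=spec.name,
                                 run_index=0, n_train=0,
                                 per_class=per_class, summary_f1=summary))
    else:
        ft_cfg = finetune_cfg or FinetuneConfig()
        for run_index in range(few_shot.runs):
            train, eval_set = sample_training_set(notes, few_shot, run_index)
            run_backend = backend.clone() if hasattr(backend, "clone") \
                else backend
            if getattr(run_backend, "trainable", False) and ft_cfg.epochs:
                examples = [
                    (prepare_input(n.text, spec, method, tokenizer, budget,
                                   offset=offset, note_id=n.id), n.label)
                    for n in train]
                run_cfg = replace(ft_cfg,
                                  seed=int(_run_rng(ft_cfg.seed, run_index)
                                           .integers(2**31)))
                run_backend, _ = finetune(run_backend, examples, run_cfg,
                                          verb)
            preds = predict_notes(eval_set, spec, method, run_backend,
                                  tokenizer, budget, offset=offset,
                                  verbalizer=verb)
            per_class, summary = evaluate(preds,
                                          [n.label for n in eval_set], spec)
            results.append(RunResult(method=method.value, task=spec.name,
                                     run_index=run_index,
                                     n_train=len(train),
                                     per_class=per_class,
                                     summary_f1=summary))
    f1s = np.array([r.summary_f1 for r in results])
    return ExperimentResult(results=tuple(results),
                            mean_f1=float(f1s.mean()),
                            sd_f1=float(f1s.std(ddof=1)) if len(f1s) > 1
                            else 0.0)


# -- statistics ------------------------------------------------------------


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided paired t-test p-value.

    Conventions for degenerate pairings: identical vectors (all
    differences exactly zero) give p = 1.0; a nonzero constant difference
    has zero variance, an infinite t statistic, and returns p = 0.0 with a
    warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ExperimentError("paired t-test needs two equal-length "
                              "vectors of >= 2 values")
    diff = a - b
    if np.all(diff == 0):
        return 1.0
    if float(np.std(diff)) == 0.0:
        warnings.warn("constant nonzero paired difference: t is infinite, "
                      "returning p=0", stacklevel=2)
        return 0.0
    return float(stats.ttest_rel(a, b).pvalue)


def holm_bonferroni(p_values: Sequence[float], alpha: float = 0.05
                    ) -> tuple[list[float], list[bool]]:
    """Holm–Bonferroni step-down procedure.

    Sorting the m p-values ascending, the rank-i threshold is
    ``alpha / (m - i + 1)`` and hypotheses are rejected sequentially until
    the first failure. Returns the thresholds in rank order and the
    rejection decisions mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ExperimentError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ExperimentError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ExperimentError("alpha must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = [alpha / (m - i) for i in range(m)]  # rank i+1
    rejected = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= thresholds[rank]:
            rejected[idx] = True
        else:
            break
    return thresholds, [bool(x) for x in rejected]


@dataclass(frozen=True)
class ComparisonRow:
    task: str
    delta_f1: float
    percent_change: float | None
    p_value: float


@dataclass(frozen=True)
class ComparisonResult:
    """Per-task ΔF1 with Holm-corrected paired-test decisions.

    ``rows`` hold the per-task comparisons (the Holm family); ``overall``
    pairs per-task means across tasks when more than one task is present.
    ``percent_change`` is 100·ΔF1/baseline and is None when the baseline
    mean F1 is zero.
    """

    method_pair: tuple[str, str]
    rows: tuple[ComparisonRow, ...]
    alpha: float
    holm_thresholds: tuple[float, ...]
    rejected: tuple[bool, ...]
    overall: ComparisonRow | None = None

    def to_frame(self) -> pd.DataFrame:
        records = []
        for row, rej in zip(self.rows, self.rejected):
            records.append({"task": row.task, "delta_f1": row.delta_f1,
                            "percent_change": row.percent_change,
                            "p_value": row.p_value, "rejected": rej})
        if self.overall is not None:
            records.append({"task": "all", "delta_f1": self.overall.delta_f1,
                            "percent_change": self.overall.percent_change,
                            "p_value": self.overall.p_value,
                            "rejected": self.overall.p_value <= self.alpha})
        return pd.DataFrame(records)


def _percent(delta: float, baseline: float) -> float | None:
    return 100.0 * delta / baseline if baseline > 0 else None


def compare_methods(results_a: Sequence[RunResult],
                    results_b: Sequence[RunResult],
                    pairing: str = "runs",
                    alpha: float = 0.05) -> ComparisonResult:
    """Compare two methods' run results task by task.

    ``pairing='runs'`` pairs the repeated runs within each task (p-value
    per task) and additionally reports an overall row pairing per-task
    mean F1s. ``pairing='tasks'`` skips per-task tests and pairs per-task
    means only. Holm correction is applied across the per-task family.
    """
    if pairing not in ("runs", "tasks"):
        raise ExperimentError(f"unknown pairing {pairing!r}")

    def by_task(results):
        grouped: dict[str, dict[int, float]] = {}
        for r in results:
            grouped.setdefault(r.task, {})[r.run_index] = r.summary_f1
        return grouped

    grouped_a, grouped_b = by_task(results_a), by_task(results_b)
    if set(grouped_a) != set(grouped_b):
        raise ExperimentError(
            f"task mismatch: {sorted(grouped_a)} vs {sorted(grouped_b)}")
    tasks = sorted(grouped_a)
    method_pair = (results_a[0].method, results_b[0].method)

    means_a, means_b, rows = [], [], []
    for task in tasks:
        runs_a, runs_b = grouped_a[task], grouped_b[task]
        if set(runs_a) != set(runs_b):
            raise ExperimentError(f"run mismatch in task {task!r}")
        keys = sorted(runs_a)
        va = [runs_a[k] for k in keys]
        vb = [runs_b[k] for k in keys]
        mean_a, mean_b = float(np.mean(va)), float(np.mean(vb))
        means_a.append(mean_a)
        means_b.append(mean_b)
        if pairing == "runs":
            p = paired_ttest(va, vb) if len(keys) >= 2 else float("nan")
            rows.append(ComparisonRow(task=task, delta_f1=mean_a - mean_b,
                                      percent_change=_percent(
                                          mean_a - mean_b, mean_b),
                                      p_value=p))

    overall = None
    if len(tasks) >= 2:
        delta = float(np.mean(means_a) - np.mean(means_b))
        overall = ComparisonRow(
            task="all", delta_f1=delta,
            percent_change=_percent(delta, float(np.mean(means_b))),
            p_value=paired_ttest(means_a, means_b))

    if pairing == "tasks":
        if overall is None:
            raise ExperimentError("pairing='tasks' needs >= 2 tasks")
        rows = [overall]
        overall = None

    thresholds, rejected = holm_bonferroni([r.p_value for r in rows], alpha)
    return ComparisonResult(method_pair=method_pair, rows=tuple(rows),
                            alpha=alpha, holm_thresholds=tuple(thresholds),
                            rejected=tuple(rejected), overall=overall)


# -- hyper-parameter search ------------------------------------------------


@dataclass(frozen=True)
class SearchResult:
    best: FinetuneConfig
    best_mean: float
    log: tuple[dict, ...]


def random_search(space: Mapping[str, Sequence], n_draws: int,
                  evaluate_draw: Callable[[FinetuneConfig, int],
                                          Sequence[float]],
                  seed: int = 0) -> SearchResult:
    """Uniform random hyper-parameter search.

    ``space`` maps :class:`FinetuneConfig` field names (learning_rate,
    batch_size, epochs, ...) to candidate lists. Each of ``n_draws`` draws
    is scored by ``evaluate_draw`` (typically the mean summary F1 over
    several resampled fine-tuning runs); the draw with the best mean wins,
    earliest draw on ties. The full search log is returned.
    """
    if n_draws < 1:
        raise ExperimentError("n_draws must be >= 1")
    if not space or any(len(v) == 0 for v in space.values()):
        raise ExperimentError("search space must be non-empty")
    rng = np.random.default_rng(seed)
    log: list[dict] = []
    best_idx, best_mean = -1, -np.inf
    for draw_index in range(n_draws):
        draw = {key: values[int(rng.integers(len(values)))]
                for key, values in sorted(space.items())}
        cfg = FinetuneConfig(**draw)
        scores = list(evaluate_draw(cfg, draw_index))
        mean = float(np.mean(scores))
        log.append({"draw": draw_index, "config": draw, "scores": scores,
                    "mean": mean})
        if mean > best_mean:
            best_idx, best_mean = draw_index, mean
    best = FinetuneConfig(**log[best_idx]["config"])
    return SearchResult(best=best, best_mean=best_mean, log=tuple(log))


# -- canonical simulation protocol -----------------------------------------


def zero_shot_position_study(cfg, methods: Sequence[Method] = (
        Method.KOTI, Method.STI_K, Method.STI_S),
        offsets: Sequence[int] = (), seeds: Sequence[int] = range(10),
        model_max: int = 512, mock_overrides: dict | None = None) -> dict:
    """Zero-shot comparison of insertion methods on synthetic corpora.

    For each corpus seed, a fresh synthetic corpus is generated from
    ``cfg`` (a :class:`~koti.synth_data.SynthConfig`), the mock backend is
    wired to its cue lexicon, and every requested method (plus every
    requested KOTI offset) is evaluated zero-shot. Returns mean summary F1
    per method and per offset across seeds, plus the per-seed table.
    """
    from dataclasses import replace as dc_replace

    from .synth_data import generate_corpus, synth_task_spec

    spec = synth_task_spec(cfg)
    mock_cfg = cfg.mock_backend_config(**(mock_overrides or {}))
    per_seed: list[dict] = []
    for seed in seeds:
        corpus = generate_corpus(dc_replace(cfg, seed=int(seed)))
        notes = [n.to_note() for n in corpus]
        tokenizer = WhitespaceTokenizer()
        for note in notes:  # fix vocabulary ids in corpus order
            tokenizer.encode(note.text)
        backend = make_mock_backend(spec, tokenizer, mock_cfg,
                                    max_input=model_max)
        row: dict = {"seed": int(seed)}
        for method in methods:
            res = run_experiment(spec, notes, method, backend, tokenizer,
                                 model_max=model_max)
            row[Method(method).value] = res.mean_f1
        for off in offsets:
            res = run_experiment(spec, notes, Method.KOTI_OFFSET, backend,
                                 tokenizer, model_max=model_max,
                                 offset=int(off))
            row[f"offset_{off}"] = res.mean_f1
        per_seed.append(row)
    table = pd.DataFrame(per_seed)
    summary = {
        "methods": {Method(m).value: float(table[Method(m).value].mean())
                    for m in methods},
        "offsets": {int(o): float(table[f"offset_{o}"].mean())
                    for o in offsets},
        "per_seed": table,
    }
    return summary
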