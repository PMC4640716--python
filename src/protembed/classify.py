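"""Binary classification over summed sequence vectors.

A task (family membership, disordered vs. structured) is a balanced
dataset: the positive class plus an equal number of negatives drawn at
random from a background pool.  A maximum-margin (SVM) classifier is
evaluated by stratified k-fold cross-validation; sensitivity, specificity
and accuracy are computed from the confusion counts pooled over folds:

    sensitivity = TP / (TP + FN)
    specificity = TN / (FP + TN)
    accuracy    = (TP + TN) / (P + N)

Across tasks the metrics are aggregated as a weighted average, with
weights proportional to the number of instances per task.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .sequence import SequenceVector

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.TN + other.TN, self.FN + other.FN)


@dataclass
class ClassifierConfig:
    """SVM settings: linear kernel, C = 1.0 by default."""

    kernel: str = "linear"
    C: float = 1.0


@dataclass
class BinaryDataset:
    task_name: str
    positives: list[SequenceVector]
    negatives: list[SequenceVector]
    sampling_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.positives) != len(self.negatives):
            raise ValueError("positive and negative classes must be balanced")
        if len(self.positives) < 2:
            raise ValueError("need at least 2 instances per class")
        pos_ids = {v.id for v in self.positives}
        neg_ids = {v.id for v in self.negatives}
        if pos_ids & neg_ids:
            raise ValueError("positive and negative id sets overlap")

    @property
    def n_instances(self) -> int:
        return len(self.positives) + len(self.negatives)


@dataclass
class TaskResult:
    task_name: str
    n_instances: int
    sensitivity: float
    specificity: float
    accuracy: float
    per_fold: list[ConfusionCounts] = field(default_factory=list)
    per_fold_metrics: list[tuple[float, float, float]] = field(default_factory=list)


def assemble_binary_dataset(task_name: str, positive_ids: Sequence[str],
                            background_pool: Sequence[SequenceVector],
                            vectors: Mapping[str, SequenceVector],
                            seed: int = 0) -> BinaryDataset:
    """Balanced dataset: given positives plus equally many random negatives.

    Negatives are drawn uniformly without replacement (seeded) from the
    background pool after removing any vector whose id is a positive.
    """
    positives = [vectors[i] for i in positive_ids]
    pos_set = set(positive_ids)
    pool = [v for v in background_pool if v.id not in pos_set]
    if len(pool) < len(positives):
        raise ValueError(
            f"background pool has {len(pool)} non-positive members, "
            f"need {len(positives)}"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(pool), size=len(positives), replace=False)
    negatives = [pool[i] for i in sorted(picked)]
    return BinaryDataset(task_name=task_name, positives=positives,
                         negatives=negatives, sampling_seed=seed)


def compute_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) from a confusion table."""
    P = counts.TP + counts.FN
    N = counts.TN + counts.FP
    if P == 0 or N == 0:
        raise ValueError("confusion table has an empty class")
    return (counts.TP / P, counts.TN / N, (counts.TP + counts.TN) / (P + N))


def cross_validate(dataset: BinaryDataset, folds: int = 10,
                   classifier_config: ClassifierConfig | None = None,
                   seed: int = 0) -> TaskResult:
    """Stratified k-fold cross-validation of an SVM on one task.

    Per fold, features are standardized on the training split only, a
    maximum-margin classifier is fit, and the held-out confusion counts are
    recorded.  Headline metrics come from the counts pooled over folds
    (per-fold metrics are also kept on the result).
    """
    cfg = classifier_config or ClassifierConfig()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if min(len(dataset.positives), len(dataset.negatives)) < folds:
        raise ValueError(
            f"task {dataset.task_name!r}: class smaller than fold count {folds}"
        )
    X = np.vstack([v.vector for v in dataset.positives + dataset.negatives])
    y = np.array([1] * len(dataset.positives) + [0] * len(dataset.negatives))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold: list[ConfusionCounts] = []
    per_fold_metrics: list[tuple[float, float, float]] = []
    for train_idx, test_idx in skf.split(X, y):
        clf = make_pipeline(
            StandardScaler(),
            SVC(kernel=cfg.kernel, C=cfg.C, random_state=seed),
        )
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        truth = y[test_idx]
        counts = ConfusionCounts(
            TP=int(((pred == 1) & (truth == 1)).sum()),
            FP=int(((pred == 1) & (truth == 0)).sum()),
            TN=int(((pred == 0) & (truth == 0)).sum()),
            FN=int(((pred == 0) & (truth == 1)).sum()),
        )
        per_fold.append(counts)
        per_fold_metrics.append(compute_metrics(counts))
    pooled = per_fold[0]
    for c in per_fold[1:]:
        pooled = pooled + c
    sens, spec, acc = compute_metrics(pooled)
    return TaskResult(task_name=dataset.task_name,
                      n_instances=dataset.n_instances,
                      sensitivity=sens, specificity=spec, accuracy=acc,
                      per_fold=per_fold, per_fold_metrics=per_fold_metrics)


def weighted_average(results: Sequence[TaskResult]
                     ) -> tuple[float, float, float]:
    """Instance-weighted mean of (sensitivity, specificity, accuracy)."""
    if not results:
        raise ValueError("no task results to average")
    w = np.array([r.n_instances for r in results], dtype=np.float64)
    w /= w.sum()
    sens = float(np.dot(w, [r.sensitivity for r in results]))
    spec = float(np.dot(w, [r.specificity for r in results]))
    acc = float(np.dot(w, [r.accuracy for r in results]))
    return sens, spec, acc


def run_family_benchmark(families: Mapping[str, Sequence[str]],
                         vectors: Mapping[str, SequenceVector],
                         background_pool: Sequence[SequenceVector],
                         folds: int = 10,
                         classifier_config: ClassifierConfig | None = None,
                         seed: int = 0
                         ) -> tuple[list[TaskResult], tuple[float, float, float]]:
    """One balanced one-vs-background task per family, largest family first.

    Families with fewer members than the fold count cannot be
    cross-validated; they are skipped with a warning and excluded from the
    weighted summary.
    """
    if not families:
        raise ValueError("empty family map")
    ordered = sorted(families, key=lambda f: (-len(families[f]), f))
    results: list[TaskResult] = []
    for i, fam in enumerate(ordered):
        ids = families[fam]
        if len(ids) < folds:
            logger.warning("skipping family %s: %d members < %d folds",
                           fam, len(ids), folds)
            continue
        dataset = assemble_binary_dataset(fam, ids, background_pool, vectors,
                                          seed=seed + i)
        results.append(cross_validate(dataset, folds=folds,
                                      classifier_config=classifier_config,
                                      seed=seed + i))
    if not results:
        raise ValueError("no family large enough to cross-validate")
    return results, weighted_average(results)


def sample_length_matched(pool: Sequence, lengths: Mapping[str, int] | None,
                          size: int, target_mean: float, seed: int = 0,
                          tolerance: float = 0.05, max_iter: int = 20000):
    """Sample ``size`` pool items whose mean length matches ``target_mean``.

    ``lengths`` maps item id to length (when items are
    :class:`SequenceVector` and ``lengths`` is None, lengths are taken as
    ``n_known + n_unknown``, the overlapping n-gram count, a proxy
    proportional to sequence length).  Starts from a random subset and
    swaps items in/out while the swap moves the subset mean toward the
    target; raises if the relative tolerance cannot be met.
    """
    if size > len(pool):
        raise ValueError("pool smaller than requested sample")

    def length_of(item) -> float:
        if lengths is not None:
            return float(lengths[item.id])
        return float(item.n_known + item.n_unknown)

    rng = np.random.default_rng(seed)
    L = np.array([length_of(v) for v in pool])
    chosen = list(rng.choice(len(pool), size=size, replace=False))
    chosen_set = set(chosen)
    mean = L[chosen].mean()
    for _ in range(max_iter):
        if abs(mean - target_mean) <= tolerance * target_mean:
            return [pool[i] for i in sorted(chosen_set)]
        out_i = int(rng.integers(0, size))
        cand = int(rng.integers(0, len(pool)))
        if cand in chosen_set:
            continue
        new_mean = mean + (L[cand] - L[chosen[out_i]]) / size
        if abs(new_mean - target_mean) < abs(mean - target_mean):
            chosen_set.discard(chosen[out_i])
            chosen_set.add(cand)
            chosen[out_i] = cand
            mean = new_mean
    raise ValueError(
        f"could not match mean length {target_mean:.1f} within "
        f"{tolerance:.0%} (best {mean:.1f})"
    )


def write_results_csv(results: Sequence[TaskResult],
                      summary: tuple[float, float, float], path) -> None:
    """CSV: task_name, n_pos, n_neg, specificity, sensitivity, accuracy."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["task_name", "n_pos", "n_neg", "specificity",
                         "sensitivity", "accuracy"])
        for r in results:
            half = r.n_instances // 2
            writer.writerow([r.task_name, half, half, f"{r.specificity:.4f}",
                             f"{r.sensitivity:.4f}", f"{r.accuracy:.4f}"])
        sens, spec, acc = summary
        n_total = sum(r.n_instances for r in results)
        writer.writerow(["weighted_average", n_total // 2, n_total // 2,
                         f"{spec:.4f}", f"{sens:.4f}", f"{acc:.4f}"])
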