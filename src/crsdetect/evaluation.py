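"""Evaluation battery: splits, confusion matrices, ROC/AUC, LOSO.

Implements the study's metrics from their printed formulas:

    TPR = TP/(TP+FN)        FPR = FP/(FP+TN)
    precision = TP/(TP+FP)  recall = TPR
    F1 = 2·precision·recall/(precision+recall)

with the zero-denominator convention that an undefined precision,
recall or F1 is reported as 0.  ROC curves sweep all unique scores
(plus +∞) as thresholds and AUC is the trapezoidal area, which equals
the Mann-Whitney pairwise-concordance probability with ties counted ½.

Datasets are split 60/20/20 into training/testing/evaluation by
nearest-integer rounding with the remainder absorbed by the training
subset (n=1054 → 632/211/211).  Leave-one-subject-out (LOSO)
cross-validation holds each participant out in turn; participants whose
accuracy falls strictly beyond mean ± 1 SD are flagged as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "RocCurve",
    "LosoReport",
    "split_sizes",
    "split_dataset",
    "confusion",
    "rates",
    "roc_auc",
    "loso",
    "flag_outliers",
    "confound_attribution",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K×K count matrix; rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        k = len(self.class_names)
        if c.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {c.shape}")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def binary_cells(self, positive_class: str | int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) under a one-vs-rest reduction."""
        p = (
            self.class_names.index(positive_class)
            if isinstance(positive_class, str)
            else int(positive_class)
        )
        c = self.counts
        tp = int(c[p, p])
        fp = int(c[:, p].sum() - c[p, p])
        fn = int(c[p, :].sum() - c[p, p])
        tn = int(c.sum() - tp - fp - fn)
        return tp, fp, fn, tn


@dataclass(frozen=True)
class RocCurve:
    points: np.ndarray  # ordered (FPR, TPR) pairs
    auc: float
    thresholds: np.ndarray = field(default=None, repr=False)


@dataclass(frozen=True)
class LosoReport:
    per_participant_accuracy: dict[str, float]
    mean_accuracy: float
    sd: float
    outliers: tuple[str, ...]


def split_sizes(n: int, proportions: Sequence[float] = (0.6, 0.2, 0.2)) -> tuple[int, ...]:
    """Nearest-integer subset sizes; the first (training) subset absorbs
    the rounding remainder so sizes always sum to n."""
    props = np.asarray(proportions, dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {props.sum()!r}")
    sizes = [int(round(p * n)) for p in props]
    sizes[0] += n - sum(sizes)
    if min(sizes) < 0:
        raise ValueError(f"proportions {proportions} infeasible for n={n}")
    return tuple(sizes)


def split_dataset(
    n_or_labels,
    proportions: Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[np.ndarray, ...]:
    """Seeded train/test/evaluation index split.

    Pass an integer for an unstratified split of range(n), or a label
    sequence for a stratified split (per-class application of the same
    rounding rule, preserving class proportions within ±1 item).
    Returns disjoint, exhaustive index arrays, one per proportion.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    k = len(proportions)
    if isinstance(n_or_labels, (int, np.integer)):
        n = int(n_or_labels)
        if n < len(proportions):
            raise ValueError(f"n={n} too small to split {k} ways")
        sizes = split_sizes(n, proportions)
        order = rng.permutation(n)
        out, start = [], 0
        for s in sizes:
            out.append(np.sort(order[start : start + s]))
            start += s
        return tuple(out)
    labels = np.asarray(n_or_labels)
    if labels.shape[0] < k:
        raise ValueError(f"n={labels.shape[0]} too small to split {k} ways")
    parts: list[list[np.ndarray]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        order = rng.permutation(idx.size)
        sizes = split_sizes(idx.size, proportions)
        start = 0
        for j, s in enumerate(sizes):
            parts[j].append(idx[order[start : start + s]])
            start += s
    return tuple(np.sort(np.concatenate(p)) for p in parts)


def confusion(
    true_labels: Sequence, predicted_labels: Sequence, class_names: Sequence[str]
) -> ConfusionMatrix:
    """Tally a K×K confusion matrix; labels may be names or indices."""
    t = list(true_labels)
    p = list(predicted_labels)
    if len(t) != len(p):
        raise ValueError(f"label sequences differ in length: {len(t)} vs {len(p)}")
    names = tuple(class_names)
    lut = {name: i for i, name in enumerate(names)}

    def _idx(x):
        return lut[x] if isinstance(x, str) else int(x)

    counts = np.zeros((len(names), len(names)), dtype=int)
    for ti, pi in zip(t, p):
        counts[_idx(ti), _idx(pi)] += 1
    return ConfusionMatrix(counts=counts, class_names=names)


def rates(
    cm: ConfusionMatrix, positive_class: str | int
) -> dict[str, float]:
    """TPR/FPR/precision/recall/F1 under a one-vs-rest reduction.

    Zero-denominator convention: a rate with an empty denominator is 0.
    """
    tp, fp, fn, tn = cm.binary_cells(positive_class)

    def _div(a: int, b: int) -> float:
        return a / b if b else 0.0

    tpr = _div(tp, tp + fn)
    fpr = _div(fp, fp + tn)
    precision = _div(tp, tp + fp)
    recall = tpr
    f1 = _div(2 * precision * recall, precision + recall) if (precision + recall) else 0.0
    return {"tpr": tpr, "fpr": fpr, "precision": precision, "recall": recall, "f1": f1}


def roc_auc(scores: Sequence[float], true_labels: Sequence[int]) -> RocCurve:
    """ROC curve over all unique score thresholds and trapezoidal AUC.

    ``scores`` are positive-class probabilities, ``true_labels`` binary
    (1 = positive).  Endpoints (0,0) and (1,1) are always included; tied
    scores contribute a single ROC vertex, so the trapezoid between tied
    groups counts ties as half-concordant — the Mann-Whitney convention.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(true_labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # group tied scores: one vertex per unique score
    distinct = np.nonzero(np.diff(s_sorted))[0]
    group_ends = np.r_[distinct, s_sorted.size - 1]
    tps = np.cumsum(y_sorted == 1)[group_ends]
    fps = np.cumsum(y_sorted == 0)[group_ends]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    thresholds = np.r_[np.inf, s_sorted[group_ends]]
    return RocCurve(points=np.stack([fpr, tpr], axis=1), auc=auc, thresholds=thresholds)


def flag_outliers(per_participant_accuracy: dict[str, float]) -> tuple[str, ...]:
    """Participants whose accuracy lies strictly beyond mean ± 1 SD (sample SD)."""
    accs = np.array(list(per_participant_accuracy.values()), dtype=float)
    mean = float(accs.mean())
    sd = float(accs.std(ddof=1)) if accs.size > 1 else 0.0
    return tuple(
        pid
        for pid, a in per_participant_accuracy.items()
        if a > mean + sd or a < mean - sd
    )


def loso(
    windows: np.ndarray,
    labels: Sequence[int],
    participants: Sequence[str],
    model_factory: Callable[[], object],
    seed: int = 0,
) -> LosoReport:
    """Leave-one-subject-out cross-validation.

    One fold per participant: the fold's participant is entirely absent
    from its training set; accuracy is window-level on the held-out
    participant.  ``model_factory()`` must return an object with
    sklearn-style ``fit(X, y)`` / ``predict(X)``.
    """
    x = np.asarray(windows)
    y = np.asarray(labels, dtype=int)
    pids = np.asarray(participants)
    unique = list(dict.fromkeys(participants))  # preserve first-seen order
    if len(unique) < 2:
        raise ValueError(f"LOSO needs >= 2 participants, got {len(unique)}")
    per: dict[str, float] = {}
    for pid in unique:
        test_mask = pids == pid
        clf = model_factory()
        clf.fit(x[~test_mask], y[~test_mask])
        pred = np.asarray(clf.predict(x[test_mask]))
        per[pid] = float((pred == y[test_mask]).mean())
    accs = np.array(list(per.values()))
    return LosoReport(
        per_participant_accuracy=per,
        mean_accuracy=float(accs.mean()),
        sd=float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
        outliers=flag_outliers(per),
    )


def confound_attribution(
    cm: ConfusionMatrix, smoking_class: str | int = "smoking"
) -> dict[str, dict[str, float]]:
    """Per-confounder smoking confusion rates from a multi-class matrix.

    For each non-smoking gesture g: ``predicted_as_smoking`` is the
    row-normalized rate that g is classified as smoking, and
    ``smoking_predicted_as`` the rate that smoking is classified as g.
    """
    s = (
        cm.class_names.index(smoking_class)
        if isinstance(smoking_class, str)
        else int(smoking_class)
    )
    c = cm.counts.astype(float)
    row_sums = c.sum(axis=1)
    out: dict[str, dict[str, float]] = {}
    for g, name in enumerate(cm.class_names):
        if g == s:
            continue
        out[name] = {
            "predicted_as_smoking": c[g, s] / row_sums[g] if row_sums[g] else 0.0,
            "smoking_predicted_as": c[s, g] / row_sums[s] if row_sums[s] else 0.0,
        }
    return out
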