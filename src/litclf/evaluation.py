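"""Model evaluation: confusion metrics, repeated k-fold CV, ROC/AUC.

Metric definitions are the textbook ones.  With P = TP + FN positive and
N = TN + FP negative instances:

    ACC = (TP + TN) / (P + N)
    PPV = TP / (TP + FP)      (precision)
    TPR = TP / (TP + FN)      (recall / sensitivity)

A ratio with a zero denominator is reported as absent (``None``) with a
warning, never silently coerced to 0.  Multiclass precision/recall are
macro-averaged over one-vs-rest reductions by default; micro-averaging is
available via a flag.

Cross-validation follows the repeated k-fold protocol: within each repeat
the corpus is partitioned into k equal-sized folds (stratified by class
by default), each fold is held out once, and — crucially — the vocabulary
and IDF statistics are rebuilt on the training folds only, so no test
document influences the feature space it is scored in.
"""

from __future__ import annotations

import csv
import random
import statistics
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .corpus_io import Corpus
from .features import build_vocabulary, vectorize_corpus, vectors_to_csr
from .models import (
    TrainConfig,
    MultinomialNaiveBayes,
    OneVsRestClassifier,
)
from .preprocess import StopwordList, preprocess_document

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ROCCurve",
    "CVResult",
    "PipelineConfig",
    "confusion_counts",
    "classification_metrics",
    "multiclass_metrics",
    "kfold_indices",
    "stratified_kfold_indices",
    "cross_validate",
    "roc_auc",
    "macro_roc_auc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def P(self) -> int:
        return self.TP + self.FN

    @property
    def Nneg(self) -> int:
        return self.TN + self.FP

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """ACC/PPV/TPR; an undefined ratio is None, not zero."""

    accuracy: float
    precision: Optional[float]
    recall: Optional[float]
    per_class: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ROCCurve:
    """Threshold-sweep operating points and the trapezoidal area."""

    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    auc: float

    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr, self.tpr))


def confusion_counts(
    truth: Sequence, predicted: Sequence, positive
) -> ConfusionCounts:
    """Tally one-vs-rest outcomes against a designated positive class."""
    if len(truth) != len(predicted):
        raise ValueError(
            f"truth ({len(truth)}) and predicted ({len(predicted)}) differ in length"
        )
    if not truth:
        raise ValueError("cannot tally an empty prediction set")
    tp = tn = fp = fn = 0
    for t, p in zip(truth, predicted):
        t_pos, p_pos = t == positive, p == positive
        if t_pos and p_pos:
            tp += 1
        elif t_pos:
            fn += 1
        elif p_pos:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def _safe_ratio(num: int, den: int, name: str) -> Optional[float]:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as absent")
        return None
    return num / den


def classification_metrics(c: ConfusionCounts) -> MetricsReport:
    """ACC, PPV and TPR from one binary confusion table."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    acc = (c.TP + c.TN) / c.total
    ppv = _safe_ratio(c.TP, c.TP + c.FP, "precision")
    tpr = _safe_ratio(c.TP, c.TP + c.FN, "recall")
    return MetricsReport(accuracy=acc, precision=ppv, recall=tpr)


def multiclass_metrics(
    truth: Sequence, predicted: Sequence, average: str = "macro"
) -> MetricsReport:
    """Overall accuracy plus macro- (default) or micro-averaged PPV/TPR
    over one-vs-rest reductions."""
    if average not in ("macro", "micro"):
        raise ValueError("average must be 'macro' or 'micro'")
    classes = sorted(set(truth))
    acc = sum(t == p for t, p in zip(truth, predicted)) / len(truth)
    per_class = {}
    for c in classes:
        counts = confusion_counts(truth, predicted, positive=c)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = classification_metrics(counts)
        per_class[c] = {"precision": m.precision, "recall": m.recall,
                        "counts": counts}
    if average == "macro":
        precisions = [v["precision"] for v in per_class.values()
                      if v["precision"] is not None]
        recalls = [v["recall"] for v in per_class.values()
                   if v["recall"] is not None]
        ppv = statistics.mean(precisions) if precisions else None
        tpr = statistics.mean(recalls) if recalls else None
    else:
        tp = sum(v["counts"].TP for v in per_class.values())
        fp = sum(v["counts"].FP for v in per_class.values())
        fn = sum(v["counts"].FN for v in per_class.values())
        ppv = _safe_ratio(tp, tp + fp, "micro precision")
        tpr = _safe_ratio(tp, tp + fn, "micro recall")
    return MetricsReport(accuracy=acc, precision=ppv, recall=tpr,
                         per_class=per_class)


def kfold_indices(n: int, k: int, seed: int) -> list[list[int]]:
    """Partition 0..n-1 into k seeded random folds with sizes differing
    by at most one."""
    if not (2 <= k <= n):
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    order = list(range(n))
    random.Random(seed).shuffle(order)
    base, extra = divmod(n, k)
    folds, start = [], 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        folds.append(sorted(order[start : start + size]))
        start += size
    return folds


def stratified_kfold_indices(
    labels: Sequence, k: int, seed: int
) -> list[list[int]]:
    """k folds with near-equal class proportions in every fold."""
    n = len(labels)
    if not (2 <= k <= n):
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = random.Random(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for c in sorted(set(labels)):
        idx = [i for i, lab in enumerate(labels) if lab == c]
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[(j + offset) % k].append(i)
        offset += len(idx) % k  # rotate which folds get the remainder
    return [sorted(f) for f in folds]


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings: featurization plus classifier."""

    classifier: str = "svm"  # nb | svm | logreg
    train: TrainConfig = field(default_factory=TrainConfig)
    ngram_orders: frozenset[int] = frozenset({1, 2})
    min_df: int = 2
    stopwords: Optional[StopwordList] = None
    collapse_repeats: bool = False
    average: str = "macro"

    def __post_init__(self) -> None:
        if self.classifier not in ("nb", "svm", "logreg"):
            raise ValueError("classifier must be nb, svm or logreg")


def _fit_predict(train_vecs, test_vecs, labels_train, config: PipelineConfig):
    """Train the configured classifier and score the held-out vectors."""
    if config.classifier == "nb":
        res = MultinomialNaiveBayes(train_vecs, labels_train).fit(
            config.train.smoothing
        )
        return [res.predict(v)[0] for v in test_vecs]
    loss = "hinge" if config.classifier == "svm" else "logistic"
    res = OneVsRestClassifier(train_vecs, labels_train, loss=loss).fit(config.train)
    return res.predict_many(test_vecs)


@dataclass
class CVResult:
    """Per-repeat, per-fold metrics with grand summaries."""

    k: int
    repeats: int
    seeds: list[int]
    classifier: str
    regularizer: str
    rows: list[dict]  # repeat, fold, accuracy, precision, recall

    def accuracies(self) -> list[float]:
        return [r["accuracy"] for r in self.rows]

    @property
    def mean_accuracy(self) -> float:
        return statistics.mean(self.accuracies())

    @property
    def std_accuracy(self) -> float:
        accs = self.accuracies()
        return statistics.stdev(accs) if len(accs) > 1 else 0.0

    def _mean_of(self, key: str) -> Optional[float]:
        vals = [r[key] for r in self.rows if r[key] is not None]
        return statistics.mean(vals) if vals else None

    def summary(self) -> str:
        ppv, tpr = self._mean_of("precision"), self._mean_of("recall")
        lines = [
            f"Repeated {self.k}-fold cross-validation "
            f"({self.repeats} repeats, {len(self.rows)} folds)",
            "=" * 52,
            f"classifier:     {self.classifier} ({self.regularizer})",
            f"mean accuracy:  {self.mean_accuracy:.4f} "
            f"(sd {self.std_accuracy:.4f})",
            f"mean precision: {ppv:.4f}" if ppv is not None else "mean precision: n/a",
            f"mean recall:    {tpr:.4f}" if tpr is not None else "mean recall:    n/a",
        ]
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> None:
        """Tidy export: repeat, fold, classifier, regularizer, metric, value."""
        with open(path, "w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle)
            writer.writerow(
                ["repeat", "fold", "classifier", "regularizer", "metric", "value"]
            )
            for r in self.rows:
                for metric in ("accuracy", "precision", "recall"):
                    val = r[metric]
                    writer.writerow(
                        [
                            r["repeat"],
                            r["fold"],
                            self.classifier,
                            self.regularizer,
                            metric,
                            "" if val is None else f"{val:.6f}",
                        ]
                    )


def cross_validate(
    corpus: Corpus,
    config: Optional[PipelineConfig] = None,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    stratified: bool = True,
) -> CVResult:
    """Repeated k-fold cross-validation of the full pipeline.

    Documents are preprocessed once; per fold, the vocabulary (and hence
    all IDF statistics) is rebuilt from the training folds only, the
    classifier is trained on them and scored on the held-out fold.
    Repeat r uses seed ``seed + r``.
    """
    config = config or PipelineConfig()
    labels = corpus.labels()
    if any(lab is None for lab in labels):
        raise ValueError("cross-validation requires a fully labeled corpus")
    for c in sorted(set(labels)):
        if labels.count(c) < k:
            raise ValueError(f"class {c!r} has fewer than k={k} members")
    token_seqs = [
        preprocess_document(d, config.stopwords, config.collapse_repeats)
        for d in corpus
    ]
    rows = []
    seeds = [seed + r for r in range(repeats)]
    for r, rseed in enumerate(seeds):
        if stratified:
            folds = stratified_kfold_indices(labels, k, rseed)
        else:
            folds = kfold_indices(len(labels), k, rseed)
        for f, test_idx in enumerate(folds):
            test_set = set(test_idx)
            train_idx = [i for i in range(len(labels)) if i not in test_set]
            assert not test_set.intersection(train_idx)
            vocab = build_vocabulary(
                [token_seqs[i] for i in train_idx],
                orders=config.ngram_orders,
                min_df=config.min_df,
            )
            train_vecs = vectorize_corpus(
                [token_seqs[i] for i in train_idx],
                vocab,
                [labels[i] for i in train_idx],
            )
            test_vecs = vectorize_corpus(
                [token_seqs[i] for i in test_idx], vocab
            )
            train_cfg = replace(config.train, seed=rseed)
            fold_cfg = replace(config, train=train_cfg)
            predicted = _fit_predict(
                vectors_to_csr(train_vecs),
                vectors_to_csr(test_vecs) if config.classifier != "nb"
                else test_vecs,
                [labels[i] for i in train_idx],
                fold_cfg,
            )
            truth = [labels[i] for i in test_idx]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = multiclass_metrics(truth, predicted, average=config.average)
            rows.append(
                {
                    "repeat": r,
                    "fold": f,
                    "accuracy": m.accuracy,
                    "precision": m.precision,
                    "recall": m.recall,
                }
            )
    return CVResult(
        k=k,
        repeats=repeats,
        seeds=seeds,
        classifier=config.classifier,
        regularizer=config.train.regularizer,
        rows=rows,
    )


def roc_auc(scores: Sequence[float], truth: Sequence, positive=1) -> ROCCurve:
    """ROC curve from a threshold sweep over the unique scores.

    Equal scores are grouped into a single threshold step, which makes the
    trapezoidal area equal to the Mann-Whitney statistic with ties
    counted one half.
    """
    if len(scores) != len(truth):
        raise ValueError("scores and truth differ in length")
    y = np.asarray([1 if t == positive else 0 for t in truth])
    P = int(y.sum())
    N = len(y) - P
    if P == 0 or N == 0:
        raise ValueError("ROC needs both classes present in truth")
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    fpr, tpr = [0.0], [0.0]
    tp = fp = 0
    i = 0
    n = len(s_sorted)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int(y_sorted[i:j].sum())
        fp += (j - i) - int(y_sorted[i:j].sum())
        fpr.append(fp / N)
        tpr.append(tp / P)
        i = j
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(tuple(fpr), tuple(tpr), auc)


def macro_roc_auc(
    per_class_scores: dict, truth: Sequence
) -> tuple[float, dict[str, ROCCurve]]:
    """Macro-average of one-vs-rest AUCs; per-class curves returned too."""
    curves = {}
    for c, scores in per_class_scores.items():
        curves[c] = roc_auc(scores, truth, positive=c)
    macro = statistics.mean(cv.auc for cv in curves.values())
    return macro, curves
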