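"""Stratified cross-validation, the recommender metric suite and rankings.

Models are validated with stratified 5-fold cross-validation and three
metrics — accuracy, weighted-average F1 and macro-average F1 — plus the
top-k metric: the fraction of reactions whose ground-truth catalyst
appears among the model's k highest-probability suggestions.  Per-fold
means and standard deviations are the headline numbers; pooled
out-of-fold figures are reported alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence
import warnings

import numpy as np
from sklearn.metrics import f1_score

RARE_CLASS_WARNING = (
    "some classes have fewer than k members; their records are dealt into "
    "distinct folds"
)


@dataclass
class Ranking:
    """Probability vector over the registry plus the derived order.

    Ties in probability are broken by ascending catalyst index, making
    top-k deterministic.
    """

    probabilities: np.ndarray
    order: np.ndarray = field(init=False)

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.ndim != 1:
            raise ValueError("Ranking wraps a single probability vector")
        self.probabilities = p
        self.order = np.argsort(-p, kind="stable")

    def top_k(self, k: int, names: Sequence[str] | None = None) -> list[tuple]:
        """First k (index, name, confidence) triples."""
        if not 1 <= k <= len(self.probabilities):
            raise ValueError(f"k must be in 1..{len(self.probabilities)}")
        out = []
        for idx in self.order[:k]:
            name = names[idx] if names is not None else str(idx)
            out.append((int(idx), name, float(self.probabilities[idx])))
        return out


def stratified_kfold(
    labels: Sequence[int], k: int = 5, seed: int = 0
) -> np.ndarray:
    """Fold assignment (0..k-1) per record, stratified by label.

    Each class's members are dealt into the currently least-loaded folds,
    which keeps fold sizes within +-1, preserves per-class proportions
    within +-1 per fold, and places the members of any class with fewer
    than k records into distinct folds (with a warning).
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignment = np.full(len(labels), -1, dtype=np.int64)
    load = np.zeros(k, dtype=np.int64)
    classes, counts = np.unique(labels, return_counts=True)
    if (counts < k).any():
        warnings.warn(RARE_CLASS_WARNING)
    # deal large classes first so small ones can balance the remainder
    for cls in classes[np.argsort(-counts, kind="stable")]:
        members = np.where(labels == cls)[0]
        rng.shuffle(members)
        for start in range(0, len(members), k):
            chunk = members[start : start + k]
            # least-loaded folds take this round's members (ties by index)
            folds = np.lexsort((np.arange(k), load))[: len(chunk)]
            for m, f in zip(chunk, folds):
                assignment[m] = f
                load[f] += 1
    return assignment


def f1_scores(
    y_true: Sequence[int], y_pred: Sequence[int], registry_size: int
) -> tuple[np.ndarray, float, float]:
    """(per-class F1, weighted F1, macro F1).

    Per-class F1 uses the 0/0 -> 0 convention; macro averages over the
    classes present in the true labels, weighted averages by support.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("need equal-length, nonempty label sequences")
    all_labels = np.arange(registry_size)
    per_class = f1_score(y_true, y_pred, labels=all_labels, average=None, zero_division=0)
    present = np.unique(y_true)
    weighted = float(
        f1_score(y_true, y_pred, labels=present, average="weighted", zero_division=0)
    )
    macro = float(
        f1_score(y_true, y_pred, labels=present, average="macro", zero_division=0)
    )
    return per_class, weighted, macro


def topk_accuracy(
    probabilities: np.ndarray, y_true: Sequence[int], k: int
) -> float:
    """Fraction of rows whose true label is among the k top-ranked
    catalysts (ties broken by ascending index)."""
    probabilities = np.asarray(probabilities, dtype=np.float64)
    y_true = np.asarray(y_true)
    n_classes = probabilities.shape[1]
    if not 1 <= k <= n_classes:
        raise ValueError(f"k must be in 1..{n_classes}")
    order = np.argsort(-probabilities, axis=1, kind="stable")
    hits = (order[:, :k] == y_true[:, None]).any(axis=1)
    return float(hits.mean())


@dataclass
class MetricsReport:
    """Per-fold and aggregate metrics of one cross-validation run."""

    per_fold: list[dict]
    pooled: dict
    mean: dict
    sd: dict

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "per_fold": self.per_fold,
                "pooled": self.pooled,
                "mean": self.mean,
                "sd": self.sd,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


_METRIC_KEYS = ("accuracy", "f1_weighted", "f1_macro")


def _fold_metrics(y_true, proba, registry_size, topk_values) -> dict:
    y_pred = np.argmax(proba, axis=1)
    _, weighted, macro = f1_scores(y_true, y_pred, registry_size)
    out = {
        "accuracy": float((y_pred == y_true).mean()),
        "f1_weighted": weighted,
        "f1_macro": macro,
    }
    for k in topk_values:
        out[f"top{k}"] = topk_accuracy(proba, y_true, k)
    return out


def cross_validate(
    build_model: Callable[[], object],
    X,
    y: Sequence[int],
    registry_size: int,
    k: int = 5,
    seed: int = 0,
    topk_values: Sequence[int] = (1, 2, 4, 5, 10),
) -> MetricsReport:
    """Stratified k-fold cross-validation of a fit/predict_proba model.

    ``build_model`` returns a fresh unfitted estimator per fold.  X may be
    any indexable the estimator accepts (feature matrix, list of pairs).
    The report carries per-fold metrics, their mean and sd (the
    paper-facing "mean +- sd" form), and pooled out-of-fold metrics.
    """
    y = np.asarray(y)
    topk_values = [kk for kk in topk_values if kk <= registry_size]
    folds = stratified_kfold(y, k=k, seed=seed)
    per_fold = []
    pooled_proba = np.zeros((len(y), registry_size))
    X_arr = np.asarray(X, dtype=object) if isinstance(X, list) else X
    for fold in range(k):
        test = folds == fold
        train = ~test
        model = build_model()
        if isinstance(X_arr, np.ndarray) and X_arr.dtype == object:
            X_train = list(X_arr[train])
            X_test = list(X_arr[test])
        else:
            X_train, X_test = X_arr[train], X_arr[test]
        model.fit(X_train, y[train])
        proba = model.predict_proba(X_test)
        if proba.shape[1] != registry_size:
            raise ValueError(
                f"model emitted {proba.shape[1]} classes, expected {registry_size}"
            )
        pooled_proba[test] = proba
        per_fold.append(_fold_metrics(y[test], proba, registry_size, topk_values))
    keys = list(per_fold[0])
    mean = {kk: float(np.mean([f[kk] for f in per_fold])) for kk in keys}
    sd = {kk: float(np.std([f[kk] for f in per_fold])) for kk in keys}
    pooled = _fold_metrics(y, pooled_proba, registry_size, topk_values)
    return MetricsReport(per_fold=per_fold, pooled=pooled, mean=mean, sd=sd)
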