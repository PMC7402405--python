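"""Confusion-matrix metrics, rank-based AUC, the 10-fold cross-validation
protocol and the coil/strand correlation analysis.

The five headline metrics are

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    accuracy    = (TN + TP) / (FN + FP + TN + TP)
    MCC         = (TN*TP - FN*FP) /
                  sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A metric whose denominator vanishes is reported as NaN (missing), never as
zero, and is excluded from cross-fold means with a logged warning.  AUC is
the Mann-Whitney U statistic normalized by n_pos * n_neg, with ties
counted one half.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold

from .io_formats import FeatureTable
from .model import ClassifierConfig, decision_scores, predict, train

logger = logging.getLogger(__name__)

METRIC_NAMES = (
    "sensitivity", "specificity", "precision", "accuracy", "mcc", "auc",
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    mcc: float
    auc: float = float("nan")
    per_fold: list[dict] = field(default_factory=list)
    n_folds: int = 1

    def as_dict(self) -> dict:
        def clean(v):
            if isinstance(v, float) and math.isnan(v):
                return None
            return v

        d = {name: clean(getattr(self, name)) for name in METRIC_NAMES}
        d["n_folds"] = self.n_folds
        d["per_fold"] = [
            {k: clean(v) for k, v in fold.items()} for fold in self.per_fold
        ]
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.as_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def confusion(
    true_labels: Sequence[int], predicted_labels: Sequence[int]
) -> ConfusionCounts:
    """Four-way cross-tabulation of aligned 0/1 sequences."""
    y = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if y.shape != p.shape:
        raise ValueError(
            f"length mismatch: {len(y)} true labels vs {len(p)} predictions"
        )
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den != 0 else float("nan")


def metrics(c: ConfusionCounts) -> MetricsReport:
    """The five confusion-matrix metrics for a single evaluation."""
    mcc_den = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    return MetricsReport(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        precision=_ratio(c.tp, c.tp + c.fp),
        accuracy=_ratio(c.tn + c.tp, c.total),
        mcc=_ratio(c.tn * c.tp - c.fn * c.fp, mcc_den),
    )


def auc(true_labels: Sequence[int], scores: Sequence[float]) -> float:
    """Probability a random positive outscores a random negative.

    Equals the Mann-Whitney U statistic over (positive, negative) pairs,
    normalized by the number of pairs; ties count 0.5.  NaN if only one
    class is present.
    """
    y = np.asarray(true_labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must be aligned")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(s)  # average ranks on ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _nanmean(values: list[float], name: str) -> float:
    arr = np.asarray(values, dtype=float)
    bad = int(np.isnan(arr).sum())
    if bad:
        logger.warning(
            "%s undefined in %d of %d folds; excluded from the mean",
            name, bad, len(arr),
        )
    if bad == len(arr):
        return float("nan")
    return float(np.nanmean(arr))


def cross_validate(
    table: FeatureTable,
    config: ClassifierConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
    stratified: bool = True,
    aggregate: str = "mean",
    train_transform=None,
) -> MetricsReport:
    """K-fold cross-validation of the SVM stage.

    Folds partition the data with sizes differing by at most one; each fold
    is predicted by a model trained (and standardized) on the other folds
    only.  ``aggregate='mean'`` averages per-fold metrics unweighted;
    ``'pooled'`` accumulates one confusion matrix (AUC then pools all
    scores).  ``train_transform``, if given, maps each training partition
    to the table actually fitted (e.g. imbalance cleaning within folds);
    the held-out fold is never transformed.
    """
    if aggregate not in ("mean", "pooled"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    config = config or ClassifierConfig()
    y = table.labels
    splitter_cls = StratifiedKFold if stratified else KFold
    splitter = splitter_cls(n_splits=n_folds, shuffle=True, random_state=seed)
    per_fold: list[dict] = []
    pooled_counts = np.zeros(4, dtype=int)  # tp, tn, fp, fn
    pooled_scores: list[np.ndarray] = []
    pooled_truth: list[np.ndarray] = []
    for fold_no, (train_idx, test_idx) in enumerate(
        splitter.split(table.X, y), start=1
    ):
        y_test = y[test_idx]
        if len(np.unique(y_test)) < 2 or len(np.unique(y[train_idx])) < 2:
            raise ValueError(
                f"fold {fold_no} contains a single class; enable "
                "stratification or use fewer folds"
            )
        train_table = table.subset(train_idx)
        if train_transform is not None:
            train_table = train_transform(train_table)
        model = train(train_table, config=config)
        scores = decision_scores(model, table.X[test_idx])
        preds = (scores >= 0.0).astype(int)
        c = confusion(y_test, preds)
        rep = metrics(c)
        fold_auc = auc(y_test, scores)
        per_fold.append(
            {
                "fold": fold_no,
                "n": int(len(test_idx)),
                "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "precision": rep.precision,
                "accuracy": rep.accuracy,
                "mcc": rep.mcc,
                "auc": fold_auc,
            }
        )
        pooled_counts += (c.tp, c.tn, c.fp, c.fn)
        pooled_scores.append(scores)
        pooled_truth.append(y_test)
    if aggregate == "mean":
        agg = {
            name: _nanmean([f[name] for f in per_fold], name)
            for name in METRIC_NAMES
        }
    else:
        rep = metrics(ConfusionCounts(*pooled_counts))
        agg = {name: getattr(rep, name) for name in METRIC_NAMES[:5]}
        agg["auc"] = auc(
            np.concatenate(pooled_truth), np.concatenate(pooled_scores)
        )
    return MetricsReport(per_fold=per_fold, n_folds=n_folds, **agg)


def abs_pearson(a: Sequence[float], b: Sequence[float]) -> float:
    """Absolute product-moment correlation; NaN on zero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("columns must have equal length")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(abs(np.corrcoef(a, b)[0, 1]))


def coil_strand_correlation(
    table: FeatureTable, offset: int = 0
) -> dict[str, float]:
    """|Pearson r| between the coil and strand probabilities at a window
    offset, for positive rows, negative rows and all rows."""
    pc_col = f"struct_pos{offset:+d}_pc"
    pe_col = f"struct_pos{offset:+d}_pe"
    for col in (pc_col, pe_col):
        if col not in table.column_names:
            raise ValueError(f"feature column {col!r} not in table")
    pc = table.X[:, table.column_names.index(pc_col)]
    pe = table.X[:, table.column_names.index(pe_col)]
    pos = table.labels == 1
    return {
        "positive": abs_pearson(pc[pos], pe[pos]),
        "negative": abs_pearson(pc[~pos], pe[~pos]),
        "all": abs_pearson(pc, pe),
    }
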