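"""Binary-classification metrics and the five-fold cross-validation protocol.

The five measures are computed from the confusion table (TP: interacting
pairs predicted interacting; FN: interacting predicted non-interacting; FP:
non-interacting predicted interacting; TN: non-interacting predicted
non-interacting):

    ACC = (TP + TN) / (TP + FP + TN + FN)
    SN  = TP / (TP + FN)
    PPV = TP / (TP + FP)
    F   = 2 * SN * PPV / (SN + PPV)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

A metric whose denominator is zero is reported as undefined (NaN) with an
explicit flag, never silently as 0.

Cross-validation uses a stratified random 5-way split: each fold in turn is
the holdout, the model is trained on the other four, and the per-fold
metrics are summarized as mean +/- sample (n-1) standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .descriptors import feature_matrix
from .gbdt import GBDTConfig, GBDTModel, fit_gbdt
from .sequence_io import InteractionPair, ProteinSequence


class EvaluationError(ValueError):
    """Raised for invalid evaluation inputs (length mismatch, bad folds)."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    """The five evaluation measures; undefined entries are NaN and flagged."""

    acc: float
    sn: float
    ppv: float
    fscore: float
    mcc: float
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {
            "acc": self.acc,
            "sn": self.sn,
            "ppv": self.ppv,
            "fscore": self.fscore,
            "mcc": self.mcc,
        }


def confusion(
    y_true: Sequence[int] | np.ndarray, y_pred: Sequence[int] | np.ndarray
) -> ConfusionCounts:
    """Count TP/FP/TN/FN for 0/1 label vectors of equal length."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape:
        raise EvaluationError(
            f"confusion: length mismatch ({t.shape} vs {p.shape})"
        )
    if not (set(np.unique(t)) <= {0, 1} and set(np.unique(p)) <= {0, 1}):
        raise EvaluationError("confusion: labels must be 0/1")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def metrics(c: ConfusionCounts) -> Metrics:
    """The five measures from a confusion table; zero denominators -> NaN + flag."""
    undefined: set[str] = set()
    if c.total == 0:
        raise EvaluationError("metrics: empty confusion table")
    acc = (c.tp + c.tn) / c.total

    if c.tp + c.fn > 0:
        sn = c.tp / (c.tp + c.fn)
    else:
        sn = math.nan
        undefined.add("sn")
    if c.tp + c.fp > 0:
        ppv = c.tp / (c.tp + c.fp)
    else:
        ppv = math.nan
        undefined.add("ppv")
    if not math.isnan(sn) and not math.isnan(ppv) and (sn + ppv) > 0:
        fscore = 2.0 * sn * ppv / (sn + ppv)
    else:
        fscore = math.nan
        undefined.add("fscore")
    denom = (c.tp + c.fn) * (c.tn + c.fp) * (c.tp + c.fp) * (c.tn + c.fn)
    if denom > 0:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    else:
        mcc = math.nan
        undefined.add("mcc")
    return Metrics(
        acc=acc, sn=sn, ppv=ppv, fscore=fscore, mcc=mcc,
        undefined=frozenset(undefined),
    )


def stratified_folds(
    labels: Sequence[int] | np.ndarray, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Disjoint index folds with class proportions preserved per fold.

    Within each class the indices are shuffled with the given seed and dealt
    round-robin; same seed -> identical folds.
    """
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for k, i in enumerate(idx):
            folds[k % n_folds].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


@dataclass
class CVResult:
    """Per-fold metrics plus the mean and sample-sd summary rows."""

    fold_metrics: list[Metrics]
    mean: dict[str, float] = field(default_factory=dict)
    std: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        table = pd.DataFrame([m.as_dict() for m in self.fold_metrics])
        self.mean = table.mean().to_dict()
        self.std = table.std(ddof=1).to_dict()

    def to_frame(self, percent: bool = False) -> pd.DataFrame:
        """Report table: one row per fold plus an Average+/-Std row."""
        scale = 100.0 if percent else 1.0
        rows = [
            {k: scale * v for k, v in m.as_dict().items()}
            for m in self.fold_metrics
        ]
        df = pd.DataFrame(rows, index=[f"fold{i+1}" for i in range(len(rows))])
        df.loc["mean"] = {k: scale * v for k, v in self.mean.items()}
        df.loc["std"] = {k: scale * v for k, v in self.std.items()}
        return df


def five_fold_cv(
    pairs: Sequence[InteractionPair],
    sequences: Mapping[str, ProteinSequence] | Sequence[ProteinSequence],
    gbdt_config: GBDTConfig | None = None,
    seed: int = 0,
    n_folds: int = 5,
) -> CVResult:
    """Stratified five-fold cross-validation of the full pipeline.

    Pair vectors are computed once; for each fold the classifier is trained
    on the other folds and evaluated on the holdout. Requires both classes
    in every training split and holdout (guaranteed by stratification when
    each class has at least ``n_folds`` members).
    """
    if len(pairs) < 2 * n_folds:
        raise EvaluationError(
            f"five_fold_cv: need at least {2 * n_folds} pairs, got {len(pairs)}"
        )
    X, y = feature_matrix(pairs, sequences)
    if np.unique(y).size < 2:
        raise EvaluationError("five_fold_cv: both classes must be present")
    folds = stratified_folds(y, n_folds, seed)
    for k, fold in enumerate(folds):
        if np.unique(y[fold]).size < 2:
            raise EvaluationError(
                f"five_fold_cv: fold {k + 1} contains a single class; "
                "use more data or fewer folds"
            )
    fold_metrics: list[Metrics] = []
    all_idx = np.arange(len(y))
    for fold in folds:
        train = np.setdiff1d(all_idx, fold)
        model = fit_gbdt(X[train], y[train], gbdt_config)
        pred = model.predict(X[fold])
        fold_metrics.append(metrics(confusion(y[fold], pred)))
    return CVResult(fold_metrics=fold_metrics)
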