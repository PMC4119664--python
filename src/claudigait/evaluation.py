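"""Leave-one-out cross-validation, confusion reporting and pairwise
feature screening.

Every held-out subject is predicted by a model whose normalization,
grid search and training saw only the other N-1 subjects (the grid
search is re-run inside every fold, so nothing leaks from the held-out
subject).  Results aggregate into a per-class success/failure table plus
overall accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .classifier import (
    BASELINE_METHODS,
    CLASS_ORDER,
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    train_baseline,
    train_presented,
)
from .features import FEATURE_NAMES

METHODS = ("presented",) + BASELINE_METHODS


@dataclass
class ConfusionReport:
    """Per-class success/failure counts of one leave-one-out run."""

    method: str
    classes: tuple
    truths: np.ndarray
    predictions: np.ndarray

    def __post_init__(self) -> None:
        self.truths = np.asarray(self.truths, dtype=object)
        self.predictions = np.asarray(self.predictions, dtype=object)
        if self.truths.shape != self.predictions.shape:
            raise ValueError("truths and predictions must align")

    def success(self, label) -> int:
        sel = self.truths == label
        return int(np.sum(self.predictions[sel] == label))

    def total(self, label) -> int:
        return int(np.sum(self.truths == label))

    def failure(self, label) -> int:
        return self.total(label) - self.success(label)

    def accuracy(self, label=None) -> float:
        if label is None:
            return float(np.mean(self.predictions == self.truths))
        return self.success(label) / self.total(label)

    @property
    def overall_accuracy(self) -> float:
        return self.accuracy()

    def to_frame(self) -> pd.DataFrame:
        """Success / Failure / Total / Accuracy table, one column per
        class plus an 'All' column; accuracies rounded to 2 decimals."""
        cols = {}
        for c in self.classes:
            cols[c] = [self.success(c), self.failure(c), self.total(c),
                       round(self.accuracy(c), 2)]
        n = len(self.truths)
        cols["All"] = [
            sum(self.success(c) for c in self.classes),
            sum(self.failure(c) for c in self.classes),
            n,
            round(self.overall_accuracy, 2),
        ]
        return pd.DataFrame(cols, index=["Success", "Failure", "Total", "Accuracy"])


def _fit_predict(X, y, test_X, method, seed, masks, C_grid, gamma_grid):
    if method == "presented":
        model = train_presented(X, y, masks=masks, C_grid=C_grid,
                                gamma_grid=gamma_grid, seed=seed)
        return model.predict(test_X)
    return train_baseline(X, y, method, seed=seed, C_grid=C_grid,
                          gamma_grid=gamma_grid).predict(test_X)


def loocv(
    X,
    y,
    method: str = "presented",
    seed: int = 0,
    masks: dict | None = None,
    C_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    progress=None,
) -> ConfusionReport:
    """Leave-one-out cross-validation: N folds for N subjects, with all
    fitting (normalization, grid search, training) re-done on each
    N-1-subject remainder.  Requires >= 2 subjects per class."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    labels, counts = np.unique(y.astype(str), return_counts=True)
    if np.any(counts < 2):
        bad = labels[counts < 2].tolist()
        raise ValueError(f"classes with a single member make grid search impossible: {bad}")
    n = len(y)
    preds = np.empty(n, dtype=object)
    for i in range(n):
        rest = np.delete(np.arange(n), i)
        preds[i] = _fit_predict(
            X[rest], y[rest], X[i][None, :], method, seed, masks, C_grid, gamma_grid
        )[0]
        if progress is not None:
            progress(i + 1, n)
    classes = tuple(c for c in CLASS_ORDER if c in set(y.tolist()))
    return ConfusionReport(method=method, classes=classes, truths=y, predictions=preds)


def compare_methods(
    X,
    y,
    methods=METHODS,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Leave-one-out accuracy of several methods, as a two-column table
    (method, accuracy in percent, 2 decimals), best first."""
    rows = []
    for m in methods:
        rep = loocv(X, y, method=m, seed=seed, **kwargs)
        rows.append({"method": m, "accuracy_pct": round(100.0 * rep.overall_accuracy, 2)})
    return (
        pd.DataFrame(rows)
        .sort_values("accuracy_pct", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def screen_features(X, y, feature_names=None) -> pd.DataFrame:
    """All-pairs group comparisons per feature: unadjusted two-sample
    t tests plus Tukey-Kramer adjusted p-values.  Reporting only -- the
    classifier does not consume this table.  Pairs where both groups have
    zero within-group variance are flagged and skipped."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object).astype(str)
    if feature_names is None:
        feature_names = FEATURE_NAMES
    groups = [c for c in CLASS_ORDER if c in set(y.tolist())]
    groups += sorted(set(y.tolist()) - set(groups))
    for g in groups:
        if np.sum(y == g) < 2:
            raise ValueError(f"group {g!r} needs >= 2 subjects")
    rows = []
    for j, fname in enumerate(feature_names):
        col = X[:, j]
        tk = None
        if all(np.var(col[y == g]) > 0 for g in groups):
            tukey = pairwise_tukeyhsd(col, y)
            summary = pd.DataFrame(
                tukey.summary().data[1:], columns=tukey.summary().data[0]
            )
            tk = {
                frozenset((r["group1"], r["group2"])): float(r["p-adj"])
                for _, r in summary.iterrows()
            }
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                g1, g2 = groups[a], groups[b]
                x1, x2 = col[y == g1], col[y == g2]
                if np.var(x1) == 0 and np.var(x2) == 0:
                    rows.append({"feature": fname, "group_1": g1, "group_2": g2,
                                 "t_stat": np.nan, "p_unadjusted": np.nan,
                                 "p_tukey": np.nan, "skipped": True})
                    continue
                t, p = sps.ttest_ind(x1, x2, equal_var=True)
                rows.append({
                    "feature": fname, "group_1": g1, "group_2": g2,
                    "t_stat": float(t), "p_unadjusted": float(p),
                    "p_tukey": tk[frozenset((g1, g2))] if tk is not None else np.nan,
                    "skipped": False,
                })
    return pd.DataFrame(rows)
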