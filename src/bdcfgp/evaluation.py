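"""Splitting, cross-validation and imbalance-aware multiclass metrics.

Metrics follow the one-vs-rest construction: each class in turn is treated as
positive and all others as negative, giving per-class TP/TN/FP/FN, from which
sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP) and
F1 = 2TP/(2TP+FP+FN) are computed and support-weighted into report-level
values.  Balanced accuracy is (weighted sensitivity + weighted specificity)/2;
macro-averaged recall is reported alongside because the two can differ
noticeably under imbalance.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions (default 60/20/20), stratified by class."""

    train_fraction: float = 0.60
    validation_fraction: float = 0.20
    test_fraction: float = 0.20
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train_fraction + self.validation_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, not 1")
        if min(self.train_fraction, self.validation_fraction, self.test_fraction) < 0:
            raise ValueError("fractions must be non-negative")


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer allocation of n by floors plus largest fractional remainders.

    Ties in the fractional part resolve by position (train before validation
    before test).
    """
    exact = [n * f for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    rem = n - sum(base)
    fracs = [e - b for e, b in zip(exact, base)]
    order = sorted(range(len(fractions)), key=lambda i: (-fracs[i], i))
    for i in order[:rem]:
        base[i] += 1
    return base


def split_dataset(
    y: Sequence, spec: SplitSpec = SplitSpec()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition row indices into disjoint train/validation/test index arrays.

    Under stratification each class is allocated separately by largest
    remainder, so per-partition class proportions stay within one instance of
    the parent's.  Classes with fewer than three members cannot reach every
    partition and are kept whole in the training split (with a warning).
    """
    ya = np.asarray(y)
    if len(ya) == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(spec.seed)
    fractions = (spec.train_fraction, spec.validation_fraction, spec.test_fraction)

    parts: tuple[list[int], list[int], list[int]] = ([], [], [])
    if spec.stratified:
        for cls in np.unique(ya):
            idx = np.flatnonzero(ya == cls)
            rng.shuffle(idx)
            if len(idx) < 3:
                warnings.warn(
                    f"class {cls!r} has only {len(idx)} member(s); keeping it "
                    "entirely in the training split"
                )
                parts[0].extend(idx)
                continue
            n_tr, n_va, n_te = _largest_remainder(len(idx), fractions)
            parts[0].extend(idx[:n_tr])
            parts[1].extend(idx[n_tr : n_tr + n_va])
            parts[2].extend(idx[n_tr + n_va :])
    else:
        idx = np.arange(len(ya))
        rng.shuffle(idx)
        n_tr, n_va, n_te = _largest_remainder(len(idx), fractions)
        parts[0].extend(idx[:n_tr])
        parts[1].extend(idx[n_tr : n_tr + n_va])
        parts[2].extend(idx[n_tr + n_va :])

    return tuple(np.sort(np.asarray(p, dtype=int)) for p in parts)  # type: ignore[return-value]


def stratified_kfold(
    y: Sequence, k: int = 10, seed: int = 0
) -> list[np.ndarray]:
    """Stratified k-fold partition of row indices (fold sizes differ by <= 1).

    Classes with fewer members than k are spread over as many folds as they
    have members (scikit-learn emits a warning in that case).
    """
    ya = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(ya, return_counts=True)
    if counts.min() < k:
        warnings.warn(
            f"smallest class has {counts.min()} members (< {k} folds); it will "
            "appear in only that many folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return [test for _, test in skf.split(np.zeros((len(ya), 1)), ya)]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def support(self) -> int:
        return self.tp + self.fn

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true: Sequence, y_pred: Sequence) -> dict:
    """Per-class one-vs-rest TP/TN/FP/FN over all labels present in truth or
    prediction."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if len(yt) != len(yp):
        raise ValueError("y_true and y_pred lengths differ")
    if len(yt) == 0:
        raise ValueError("empty label sequences")
    out = {}
    for cls in np.unique(np.concatenate([yt, yp])):
        t = yt == cls
        p = yp == cls
        out[cls.item() if hasattr(cls, "item") else cls] = ConfusionCounts(
            tp=int(np.sum(t & p)),
            tn=int(np.sum(~t & ~p)),
            fp=int(np.sum(~t & p)),
            fn=int(np.sum(t & ~p)),
        )
    return out


@dataclass
class MetricsReport:
    """Support-weighted multiclass metrics with per-class breakdown.

    All values are fractions in [0, 1]; multiply by 100 to report as
    percentages.  ``zero_division_classes`` lists classes where some
    denominator was zero and the affected metric was reported as 0.
    """

    balanced_accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    macro_recall: float
    averaging: str = "weighted"
    per_class: dict = field(default_factory=dict)
    zero_division_classes: list = field(default_factory=list)


def _safe_div(num: float, den: float, flags: list, cls, metric: str) -> float:
    if den == 0:
        flags.append((cls, metric))
        return 0.0
    return num / den


def compute_metrics(counts: Mapping) -> MetricsReport:
    """Report-level metrics from per-class one-vs-rest confusion counts."""
    flags: list = []
    per_class = {}
    supports = []
    for cls, c in counts.items():
        sens = _safe_div(c.tp, c.tp + c.fn, flags, cls, "sensitivity")
        spec = _safe_div(c.tn, c.tn + c.fp, flags, cls, "specificity")
        prec = _safe_div(c.tp, c.tp + c.fp, flags, cls, "precision")
        f1 = _safe_div(2 * c.tp, 2 * c.tp + c.fp + c.fn, flags, cls, "f1")
        per_class[cls] = {
            "sensitivity": sens,
            "specificity": spec,
            "precision": prec,
            "f1": f1,
            "support": c.support,
        }
        supports.append(c.support)

    w = np.asarray(supports, dtype=float)
    if w.sum() == 0:
        raise ValueError("total support is zero")
    w = w / w.sum()

    def wavg(metric: str) -> float:
        return float(
            np.sum(w * np.array([per_class[c][metric] for c in per_class]))
        )

    sens_w = wavg("sensitivity")
    spec_w = wavg("specificity")
    macro = float(
        np.mean([per_class[c]["sensitivity"] for c in per_class if per_class[c]["support"] > 0])
    )
    return MetricsReport(
        balanced_accuracy=(sens_w + spec_w) / 2.0,
        sensitivity=sens_w,
        specificity=spec_w,
        precision=wavg("precision"),
        f1=wavg("f1"),
        macro_recall=macro,
        per_class=per_class,
        zero_division_classes=[c for c, _ in flags],
    )


def evaluate_predictions(y_true: Sequence, y_pred: Sequence) -> MetricsReport:
    """Convenience wrapper: confusion counts then metrics."""
    return compute_metrics(confusion_counts(y_true, y_pred))


def accuracy(y_true: Sequence, y_pred: Sequence) -> float:
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if len(yt) != len(yp) or len(yt) == 0:
        raise ValueError("label sequences must be equal-length and non-empty")
    return float(np.mean(yt == yp))


def pearson_screen(
    X: pd.DataFrame, y: Sequence
) -> dict[str, float | None]:
    """Pearson correlation of each feature column with the encoded target.

    Constant columns are reported as ``None`` (undefined), not 0.
    """
    ya = np.asarray(y, dtype=float)
    if len(X) < 2:
        raise ValueError("need at least two rows for a correlation")
    out: dict[str, float | None] = {}
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        if np.ptp(v) == 0 or np.ptp(ya) == 0:
            out[str(col)] = None
            continue
        r, _ = stats.pearsonr(v, ya)
        out[str(col)] = float(r)
    return out
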