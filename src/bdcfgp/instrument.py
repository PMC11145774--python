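"""Model of the Burns Depression Checklist (BDC) screening instrument.

The BDC is a 25-item self-report questionnaire.  Each item is answered on a
five-point Likert scale ("Not at all" ... "Extremely") encoded as an ordinal
weight 0-4, so the total score ranges 0-100.  Conventional Depression
Screening (CDS) sums the 25 weights and bins the total into one of six
severity levels (no depression through extreme depression).

This module reads, cleans and encodes response tables and computes the CDS
score and label.  Cleaning is whole-row deletion of records with any missing
item; no imputation is performed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Number of questionnaire items.
N_ITEMS = 25
#: Maximum Likert weight per item.
MAX_WEIGHT = 4
#: Default item column names in CSV files.
ITEM_COLUMNS = tuple(f"F{i}" for i in range(1, N_ITEMS + 1))
#: Default severity-label column name.
LABEL_COLUMN = "PT"


class SeverityLevel(IntEnum):
    """The six depression severity levels, ordinal-coded 0-5 in clinical order."""

    NO_DEPRESSION = 0
    NORMAL_BUT_UNHAPPY = 1
    MILD_DEPRESSION = 2
    MODERATE_DEPRESSION = 3
    SEVERE_DEPRESSION = 4
    EXTREME_DEPRESSION = 5

    @property
    def label(self) -> str:
        return _LEVEL_LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "SeverityLevel":
        key = str(label).strip().lower()
        try:
            return _LABEL_TO_LEVEL[key]
        except KeyError:
            raise ValueError(
                f"unknown severity label {label!r}; expected one of "
                f"{sorted(set(_LEVEL_LABELS.values()))}"
            ) from None


_LEVEL_LABELS = {
    SeverityLevel.NO_DEPRESSION: "No depression",
    SeverityLevel.NORMAL_BUT_UNHAPPY: "Normal but unhappy",
    SeverityLevel.MILD_DEPRESSION: "Mild depression",
    SeverityLevel.MODERATE_DEPRESSION: "Moderate depression",
    SeverityLevel.SEVERE_DEPRESSION: "Severe depression",
    SeverityLevel.EXTREME_DEPRESSION: "Extreme depression",
}
_LABEL_TO_LEVEL = {v.lower(): k for k, v in _LEVEL_LABELS.items()}

#: Published cut-points for the overall (0-100) score, one contiguous band per
#: level in ``SeverityLevel`` order.
SCREENING_BANDS: tuple[tuple[int, int], ...] = (
    (0, 5),
    (6, 10),
    (11, 25),
    (26, 50),
    (51, 75),
    (76, 100),
)

#: Likert response categories in weight order 0..4.
RESPONSE_CATEGORIES = ("Not at all", "Somewhat", "Moderate", "A lot", "Extremely")
_CATEGORY_TO_WEIGHT = {c.lower(): w for w, c in enumerate(RESPONSE_CATEGORIES)}


def encode_label(category: str) -> int:
    """Encode a Likert response string to its ordinal weight 0-4.

    Matching is case-insensitive with surrounding whitespace stripped.
    """
    key = str(category).strip().lower()
    try:
        return _CATEGORY_TO_WEIGHT[key]
    except KeyError:
        raise ValueError(
            f"unknown response category {category!r}; accepted categories are "
            f"{list(RESPONSE_CATEGORIES)}"
        ) from None


@dataclass(frozen=True)
class ResponseRecord:
    """One participant's 25 ordinal item weights plus an optional observed label."""

    weights: tuple[int, ...]
    observed_label: SeverityLevel | None = None

    def __post_init__(self) -> None:
        if len(self.weights) != N_ITEMS:
            raise ValueError(f"expected {N_ITEMS} weights, got {len(self.weights)}")
        for i, w in enumerate(self.weights):
            if not (0 <= int(w) <= MAX_WEIGHT):
                raise ValueError(f"weight {w!r} at item {i + 1} outside 0-{MAX_WEIGHT}")


@dataclass
class ResponseTable:
    """A cleaned, encoded table of responses.

    ``df`` holds one integer column per item (``F1``..``F25``) and, when a
    severity label is present, an integer ``PT`` column of ordinal codes 0-5.
    """

    df: pd.DataFrame
    provenance: str = ""
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_labels(self) -> bool:
        return LABEL_COLUMN in self.df.columns

    def weights(self) -> np.ndarray:
        """Item-weight matrix of shape (n, 25)."""
        return self.df.loc[:, list(ITEM_COLUMNS)].to_numpy(dtype=int)

    def labels(self) -> np.ndarray:
        if not self.has_labels:
            raise ValueError("table has no severity label column")
        return self.df[LABEL_COLUMN].to_numpy(dtype=int)

    def records(self) -> Iterable[ResponseRecord]:
        labels = self.df[LABEL_COLUMN] if self.has_labels else None
        for pos, (_, row) in enumerate(self.df.iterrows()):
            lbl = SeverityLevel(int(labels.iloc[pos])) if labels is not None else None
            yield ResponseRecord(tuple(int(row[c]) for c in ITEM_COLUMNS), lbl)


def cds_score(weights: Sequence[int] | ResponseRecord) -> int:
    """Conventional screening score: the sum of all 25 item weights (0-100)."""
    if isinstance(weights, ResponseRecord):
        weights = weights.weights
    arr = np.asarray(weights, dtype=int)
    if arr.shape != (N_ITEMS,):
        raise ValueError(f"expected {N_ITEMS} weights, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > MAX_WEIGHT:
        raise ValueError(f"weights must lie in 0-{MAX_WEIGHT}")
    return int(arr.sum())


def cds_severity(score: int) -> SeverityLevel:
    """Map a total score to its severity level via the published cut-points."""
    score = int(score)
    if not (0 <= score <= N_ITEMS * MAX_WEIGHT):
        raise ValueError(f"score {score} outside 0-{N_ITEMS * MAX_WEIGHT}")
    for level, (lo, hi) in zip(SeverityLevel, SCREENING_BANDS):
        if lo <= score <= hi:
            return level
    raise AssertionError("screening bands must cover 0-100")  # pragma: no cover


def _encode_item_frame(items: pd.DataFrame) -> pd.DataFrame:
    """Encode a raw item block (strings or numerics) to integer weights 0-4."""
    out = {}
    for col in items.columns:
        s = items[col]
        if s.dtype == object:
            numeric = pd.to_numeric(s, errors="coerce")
            if numeric.notna().all():
                s = numeric
            else:
                s = s.map(encode_label)
        vals = pd.to_numeric(s)
        bad = vals[(vals < 0) | (vals > MAX_WEIGHT) | (vals != vals.round())]
        if len(bad):
            idx = bad.index[0]
            raise ValueError(
                f"item column {col!r} has out-of-range weight {bad.iloc[0]!r} "
                f"at row index {idx}"
            )
        out[col] = vals.astype(int)
    return pd.DataFrame(out, index=items.index)


def load_responses(
    path: str | Path,
    item_columns: Sequence[str] = ITEM_COLUMNS,
    label_column: str | None = LABEL_COLUMN,
) -> ResponseTable:
    """Read a response CSV, drop incomplete rows and encode to ordinal weights.

    Item cells may be weights 0-4 or the Likert category strings.  Rows with
    any missing item are removed (whole-row deletion); the dropped count is
    logged and recorded on the returned table.

    Raises a schema error naming absent columns, and a value error (with the
    offending row) for out-of-range weights or unknown categories.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=object)
    missing = [c for c in item_columns if c not in raw.columns]
    if missing:
        raise ValueError(f"input {path} is missing item columns: {missing}")

    items = raw.loc[:, list(item_columns)]
    blank = items.isna() | (items.astype(str).apply(lambda s: s.str.strip()) == "")
    keep = ~blank.any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d rows with missing items from %s", n_dropped, path)

    items = _encode_item_frame(items.loc[keep])
    items.columns = list(ITEM_COLUMNS)

    df = items.reset_index(drop=True)
    if label_column is not None and label_column in raw.columns:
        lab = raw.loc[keep, label_column].reset_index(drop=True)
        numeric = pd.to_numeric(lab, errors="coerce")
        if numeric.notna().all():
            codes = numeric.astype(int)
            if ((codes < 0) | (codes > 5)).any():
                raise ValueError("severity codes must lie in 0-5")
        else:
            codes = lab.map(lambda s: int(SeverityLevel.from_label(s)))
        df[LABEL_COLUMN] = codes.astype(int)

    return ResponseTable(df=df, provenance=str(path), n_dropped=n_dropped)


def write_responses(
    table: ResponseTable, path: str | Path, categorical: bool = False
) -> None:
    """Write a response table as CSV in the input schema.

    With ``categorical=True`` item weights are written as the human-readable
    Likert strings and labels as level names.
    """
    df = table.df.copy()
    if categorical:
        for c in ITEM_COLUMNS:
            df[c] = df[c].map(lambda w: RESPONSE_CATEGORIES[int(w)])
        if LABEL_COLUMN in df.columns:
            df[LABEL_COLUMN] = df[LABEL_COLUMN].map(
                lambda v: SeverityLevel(int(v)).label
            )
    df.to_csv(path, index=False)
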