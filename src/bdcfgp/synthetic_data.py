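"""Synthetic BDC-like response generator.

Emulates a survey of 25-item Likert responses with a prescribed severity-class
distribution.  For each requested class the generator draws a target total
score uniformly from that class's published band, then distributes the total
over the 25 items as a uniformly random bounded composition (each item 0-4,
summing exactly to the target).  Every emitted record therefore satisfies its
requested class exactly, and the class histogram is reproduced exactly.

The shipped default class counts are the study's distribution: 14 / 23 / 180 /
360 / 67 / 10 (no depression ... extreme depression), 654 respondents in
total, with the moderate class holding 55% of the sample.

Items are exchangeable by default (no group carries more signal than
another); an optional ``group_weights`` mode biases score mass toward chosen
groups so the four group targets vary non-trivially.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .instrument import (
    ITEM_COLUMNS,
    LABEL_COLUMN,
    MAX_WEIGHT,
    N_ITEMS,
    SCREENING_BANDS,
    ResponseTable,
    SeverityLevel,
)

#: The study's class distribution (no depression ... extreme), total 654.
DEFAULT_CLASS_COUNTS: tuple[int, ...] = (14, 23, 180, 360, 67, 10)


@dataclass(frozen=True)
class GeneratorSpec:
    """What to generate: per-class counts, seed, and optional group biasing.

    ``group_weights`` maps group name (TFG/APR/PSG/SUG) to a relative
    propensity multiplier applied to that group's items; ``None`` keeps all
    items exchangeable.
    """

    class_counts: tuple[int, ...] = DEFAULT_CLASS_COUNTS
    seed: int = 0
    group_weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if len(self.class_counts) != len(SeverityLevel):
            raise ValueError("class_counts needs one entry per severity level")
        if any(c < 0 for c in self.class_counts):
            raise ValueError("class counts must be non-negative")
        if sum(self.class_counts) < 1:
            raise ValueError("total count must be >= 1")


@lru_cache(maxsize=None)
def _composition_counts(parts: int, bound: int) -> tuple[tuple[int, ...], ...]:
    """table[m][t] = number of compositions of t into m parts, each 0..bound.

    Exact integer dynamic programme; sizes here are tiny (m <= 25, t <= 100).
    """
    max_t = parts * bound
    table = [[0] * (max_t + 1) for _ in range(parts + 1)]
    table[0][0] = 1
    for m in range(1, parts + 1):
        for t in range(0, m * bound + 1):
            table[m][t] = sum(
                table[m - 1][t - v] for v in range(min(bound, t) + 1)
            )
    return tuple(tuple(row) for row in table)


def sample_bounded_composition(
    total: int,
    parts: int = N_ITEMS,
    bound: int = MAX_WEIGHT,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Uniform random vector of ``parts`` integers in 0..bound summing to total.

    Sequential conditional draws: the first entry takes value v with
    probability (compositions of total-v into the remaining parts) divided by
    (compositions of total into all parts), which makes the joint draw exactly
    uniform over all valid compositions.
    """
    if not (0 <= total <= parts * bound):
        raise ValueError(f"total {total} infeasible for {parts} parts of 0..{bound}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    table = _composition_counts(parts, bound)
    out = np.empty(parts, dtype=int)
    t = total
    for pos in range(parts):
        m_left = parts - pos - 1
        lo = max(0, t - m_left * bound)
        hi = min(bound, t)
        weights = np.array(
            [table[m_left][t - v] for v in range(lo, hi + 1)], dtype=float
        )
        v = lo + rng.choice(len(weights), p=weights / weights.sum())
        out[pos] = v
        t -= v
    assert t == 0
    return out


def _biased_composition(
    total: int,
    item_weights: np.ndarray,
    bound: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Near-uniform composition with per-item propensity weights.

    Allocates the total one unit at a time to items with remaining capacity,
    proportionally to their weights; not exactly uniform, used only for the
    optional group-signal mode.
    """
    parts = len(item_weights)
    out = np.zeros(parts, dtype=int)
    for _ in range(total):
        cap = out < bound
        w = item_weights * cap
        out[rng.choice(parts, p=w / w.sum())] += 1
    return out


def generate_dataset(spec: GeneratorSpec = GeneratorSpec()) -> ResponseTable:
    """Generate a labeled response table matching ``spec`` exactly.

    Each record's conventional screening label equals its requested class by
    construction; rows are shuffled so classes are interleaved.
    """
    rng = np.random.default_rng(spec.seed)

    item_weights = None
    if spec.group_weights is not None:
        from .fgp import DEFAULT_GROUPS

        item_weights = np.ones(N_ITEMS, dtype=float)
        for g in DEFAULT_GROUPS:
            mult = float(spec.group_weights.get(g.name, 1.0))
            if mult <= 0:
                raise ValueError("group weights must be positive")
            for i in g.member_indices:
                item_weights[i - 1] = mult

    rows = []
    labels = []
    for level, count in zip(SeverityLevel, spec.class_counts):
        lo, hi = SCREENING_BANDS[int(level)]
        for _ in range(count):
            total = int(rng.integers(lo, hi + 1))
            if item_weights is None:
                w = sample_bounded_composition(total, rng=rng)
            else:
                w = _biased_composition(total, item_weights, MAX_WEIGHT, rng)
            rows.append(w)
            labels.append(int(level))

    order = rng.permutation(len(rows))
    df = pd.DataFrame(
        np.asarray(rows, dtype=int)[order], columns=list(ITEM_COLUMNS)
    )
    df[LABEL_COLUMN] = np.asarray(labels, dtype=int)[order]
    return ResponseTable(df=df, provenance=f"synthetic(seed={spec.seed})")
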