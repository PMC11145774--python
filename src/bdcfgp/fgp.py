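"""Feature Group Partitioning (FGP).

FGP replaces the 25 raw questionnaire items with four ordinal group targets.
The items fall into four fixed clinical groups:

* TFG — thoughts and feelings (items 1-10)
* APR — activities and personal relationships (items 11-17)
* PSG — physical symptoms (items 18-22)
* SUG — suicidal urges (items 23-25)

For each group we compute an individual score IS (the group's weight sum),
derive an individual range table IR (six severity bands scaled to the group's
maximum score), and emit an individual target IT (the band the score falls
in).  The prediction target PT comes from the prediction target score
PTS = TFG-IS + APR-IS + PSG-IS + SUG-IS compared against the overall range
table, which coincides with the instrument's published cut-points — so PT is
identical to the conventional screening label by construction.

Band derivation: with score threshold Sth = (items in group) x (max weight),
the upper bounds of the first five bands are round-half-up of
(a, b, c, d, e) x Sth with defaults (0.05, 0.1, 0.25, 0.5, 0.75); the last
band ends at Sth.  Each lower bound is the previous upper bound plus one.
If rounding makes an upper bound fall below its lower bound the band is
clamped to a single score (upper = lower) so no band is empty; for the
suicidal-urges group this yields the 2-2 "normal but unhappy" band.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .instrument import (
    ITEM_COLUMNS,
    LABEL_COLUMN,
    MAX_WEIGHT,
    N_ITEMS,
    ResponseTable,
    SeverityLevel,
)

#: FGP target column names in output tables.
TARGET_COLUMNS = ("TFG_IT", "APR_IT", "PSG_IT", "SUG_IT")


@dataclass(frozen=True)
class FeatureGroupSpec:
    """A named item group: contiguous 1-based item indices and its item count."""

    name: str
    member_indices: tuple[int, ...]

    @property
    def threshold(self) -> int:
        """Item count of the group (the group's F[n])."""
        return len(self.member_indices)


#: The four fixed groups partitioning items 1..25 (10/7/5/3 items).
DEFAULT_GROUPS: tuple[FeatureGroupSpec, ...] = (
    FeatureGroupSpec("TFG", tuple(range(1, 11))),
    FeatureGroupSpec("APR", tuple(range(11, 18))),
    FeatureGroupSpec("PSG", tuple(range(18, 23))),
    FeatureGroupSpec("SUG", tuple(range(23, 26))),
)


@dataclass(frozen=True)
class BandConstants:
    """Fractions of the score threshold giving the first five band upper bounds."""

    a: float = 0.05
    b: float = 0.1
    c: float = 0.25
    d: float = 0.5
    e: float = 0.75

    def __post_init__(self) -> None:
        vals = (self.a, self.b, self.c, self.d, self.e)
        if not all(0 < v < 1 for v in vals):
            raise ValueError("band constants must lie in (0, 1)")
        if not all(x < y for x, y in zip(vals, vals[1:])):
            raise ValueError("band constants must be strictly increasing")

    @property
    def fractions(self) -> tuple[float, ...]:
        return (self.a, self.b, self.c, self.d, self.e)


DEFAULT_CONSTANTS = BandConstants()


def _round_half_up(x: float) -> int:
    """Round-half-up on the exact decimal value (1.4 -> 1, 1.5 -> 2)."""
    return int(Decimal(str(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SeverityRangeTable:
    """Six contiguous severity bands covering integer scores 0..Sth."""

    scope: str
    score_threshold: int
    bands: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.bands) != len(SeverityLevel):
            raise ValueError("a range table needs exactly six bands")
        lo0, _ = self.bands[0]
        if lo0 != 0:
            raise ValueError("first band must start at 0")
        if self.bands[-1][1] != self.score_threshold:
            raise ValueError("last band must end at the score threshold")
        prev_hi = -1
        for lo, hi in self.bands:
            if lo != prev_hi + 1:
                raise ValueError("bands must be contiguous")
            if hi < lo:
                raise ValueError("every band needs lower <= upper")
            prev_hi = hi

    def band(self, level: SeverityLevel) -> tuple[int, int]:
        return self.bands[int(level)]

    def level_for(self, score: int) -> SeverityLevel:
        """First level whose band upper bound is >= score (the if/elif cascade)."""
        score = int(score)
        if not (0 <= score <= self.score_threshold):
            raise ValueError(
                f"score {score} outside [0, {self.score_threshold}] for "
                f"{self.scope} ranges"
            )
        for level in SeverityLevel:
            if score <= self.bands[int(level)][1]:
                return level
        raise AssertionError("bands cover the full score range")  # pragma: no cover

    def to_dict(self) -> dict[str, tuple[int, int]]:
        return {lvl.label: self.bands[int(lvl)] for lvl in SeverityLevel}


def compute_individual_ranges(
    group_size: int,
    weight_threshold: int = MAX_WEIGHT,
    constants: BandConstants = DEFAULT_CONSTANTS,
    scope: str = "",
) -> SeverityRangeTable:
    """Derive a group's severity bands from its item count.

    Sth = group_size x weight_threshold; band upper bounds are round-half-up
    of each constant times Sth (the last is Sth itself); lower bounds chain
    from the previous upper; empty bands are clamped to a single score.
    """
    if group_size < 1 or weight_threshold < 1:
        raise ValueError("group size and weight threshold must be >= 1")
    sth = group_size * weight_threshold
    if sth < len(SeverityLevel) - 1:
        raise ValueError(
            f"score threshold {sth} cannot host {len(SeverityLevel)} non-empty "
            "integer bands"
        )
    uppers = [_round_half_up(f * sth) for f in constants.fractions] + [sth]
    bands: list[tuple[int, int]] = []
    lo = 0
    for hi in uppers:
        hi = max(hi, lo)  # non-empty-band clamp
        bands.append((lo, hi))
        lo = hi + 1
    return SeverityRangeTable(
        scope=scope or f"F{group_size}", score_threshold=sth, bands=tuple(bands)
    )


def overall_range_table(
    weight_threshold: int = MAX_WEIGHT,
    constants: BandConstants = DEFAULT_CONSTANTS,
) -> SeverityRangeTable:
    """The prediction-target range table over the full 25-item score."""
    return compute_individual_ranges(
        N_ITEMS, weight_threshold, constants, scope="OVERALL"
    )


def group_range_tables(
    groups: Sequence[FeatureGroupSpec] = DEFAULT_GROUPS,
    weight_threshold: int = MAX_WEIGHT,
    constants: BandConstants = DEFAULT_CONSTANTS,
) -> dict[str, SeverityRangeTable]:
    """Range tables for each group plus the OVERALL prediction-target table."""
    tables = {
        g.name: compute_individual_ranges(
            g.threshold, weight_threshold, constants, scope=g.name
        )
        for g in groups
    }
    tables["OVERALL"] = overall_range_table(weight_threshold, constants)
    return tables


@dataclass(frozen=True)
class GroupScores:
    """Per-group weight sums (IS) for one respondent."""

    tfg_is: int
    apr_is: int
    psg_is: int
    sug_is: int

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.tfg_is, self.apr_is, self.psg_is, self.sug_is)


def _check_partition(groups: Sequence[FeatureGroupSpec]) -> None:
    covered = [i for g in groups for i in g.member_indices]
    if sorted(covered) != list(range(1, N_ITEMS + 1)):
        raise ValueError("groups must partition items 1..25 with no overlap")


def compute_individual_scores(
    weights: Sequence[int], groups: Sequence[FeatureGroupSpec] = DEFAULT_GROUPS
) -> GroupScores:
    """Sum each group's item weights (the CIS step)."""
    _check_partition(groups)
    arr = np.asarray(weights, dtype=int)
    if arr.shape != (N_ITEMS,):
        raise ValueError(f"expected {N_ITEMS} weights, got shape {arr.shape}")
    sums = [int(arr[[i - 1 for i in g.member_indices]].sum()) for g in groups]
    return GroupScores(*sums)


def compute_pts(scores: GroupScores) -> int:
    """Prediction target score: the sum of the four group scores."""
    return sum(scores.as_tuple())


def compute_individual_target(
    score: int, ranges: SeverityRangeTable
) -> SeverityLevel:
    """Convert a group score into its severity target (the CIT step)."""
    return ranges.level_for(score)


@dataclass(frozen=True)
class FGPRecord:
    """The four group targets plus the prediction target for one respondent."""

    tfg_it: SeverityLevel
    apr_it: SeverityLevel
    psg_it: SeverityLevel
    sug_it: SeverityLevel
    pt: SeverityLevel


def fgp_record(
    weights: Sequence[int],
    tables: Mapping[str, SeverityRangeTable] | None = None,
    groups: Sequence[FeatureGroupSpec] = DEFAULT_GROUPS,
) -> FGPRecord:
    """Run CIS + CIT for one respondent and derive PT from PTS."""
    if tables is None:
        tables = group_range_tables(groups)
    scores = compute_individual_scores(weights, groups)
    targets = [
        compute_individual_target(s, tables[g.name])
        for s, g in zip(scores.as_tuple(), groups)
    ]
    pt = tables["OVERALL"].level_for(compute_pts(scores))
    return FGPRecord(*targets, pt)


def fgp_transform(
    table: ResponseTable | pd.DataFrame,
    constants: BandConstants = DEFAULT_CONSTANTS,
    groups: Sequence[FeatureGroupSpec] = DEFAULT_GROUPS,
) -> pd.DataFrame:
    """Transform a 25-item response table to the 4+1 column FGP table.

    Returns a frame with ordinal-coded columns TFG_IT, APR_IT, PSG_IT, SUG_IT
    and PT — four predictors and one target per respondent.
    """
    _check_partition(groups)
    if isinstance(table, ResponseTable):
        W = table.weights()
    else:
        W = table.loc[:, list(ITEM_COLUMNS)].to_numpy(dtype=int)
    tables = group_range_tables(groups, constants=constants)

    out = {}
    group_sums = []
    for g, col in zip(groups, TARGET_COLUMNS):
        idx = [i - 1 for i in g.member_indices]
        s = W[:, idx].sum(axis=1)
        group_sums.append(s)
        rt = tables[g.name]
        out[col] = np.array([int(rt.level_for(v)) for v in s], dtype=int)

    pts = np.sum(group_sums, axis=0)
    overall = tables["OVERALL"]
    out[LABEL_COLUMN] = np.array([int(overall.level_for(v)) for v in pts], dtype=int)
    return pd.DataFrame(out)


def range_report(
    constants: BandConstants = DEFAULT_CONSTANTS,
    weight_threshold: int = MAX_WEIGHT,
    groups: Sequence[FeatureGroupSpec] = DEFAULT_GROUPS,
) -> pd.DataFrame:
    """Audit table of every band per group and overall (severity x scope)."""
    tables = group_range_tables(groups, weight_threshold, constants)
    rows = []
    for lvl in SeverityLevel:
        row: dict[str, object] = {"severity": lvl.label}
        for scope in [g.name for g in groups] + ["OVERALL"]:
            lo, hi = tables[scope].band(lvl)
            row[scope] = f"{lo} to {hi}"
        rows.append(row)
    return pd.DataFrame(rows)
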