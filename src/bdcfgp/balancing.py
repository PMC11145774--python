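"""Multiclass class balancing by synthetic oversampling (SMOTE and ADASYN).

Both samplers raise every class to the majority-class count by appending
interpolated synthetic rows; originals are always preserved.

SMOTE draws a random minority point f_i, one of its k nearest same-class
neighbours f_near, and a fraction R ~ U[0, 1], then interpolates.  The
conventional direction places the synthetic point on the segment between the
pair, f_i + (f_near - f_i) x R; an alternative "as-printed" direction
f_i + (f_i - f_near) x R extrapolates on the opposite side of f_i and is kept
behind a flag for comparison.

ADASYN allocates per-point synthetic quotas adaptively: minority points with
more opposite-class points among their k nearest neighbours (in the whole
dataset) receive proportionally more synthetics, concentrating new samples
near the decision boundary.  Quotas are floored and the remainder assigned to
the highest-ratio points so the class hits its target count exactly.

With ``snap_to_grid`` (default on, appropriate for ordinal features) each
synthetic coordinate is rounded to the nearest integer and clipped to the
feature's observed (or configured) range, keeping categorical-likelihood
models downstream valid.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

SMOTE = "smote"
ADASYN = "adasyn"
CONVENTIONAL = "conventional"
AS_PRINTED = "as-printed"


@dataclass(frozen=True)
class OversamplerConfig:
    """Sampler settings.

    k is the neighbour count (reduced with a warning for classes smaller than
    k+1); ``direction`` applies to SMOTE only; ``value_range`` optionally fixes
    the (low, high) grid bounds used when snapping, otherwise each feature's
    observed min/max is used; ``scope`` chooses between balancing the training
    split only (leakage guard) and the whole dataset.
    """

    method: str = SMOTE
    k: int = 5
    seed: int = 0
    direction: str = CONVENTIONAL
    snap_to_grid: bool = True
    value_range: tuple[float, float] | None = None
    scope: str = "train-only"

    def __post_init__(self) -> None:
        if self.method not in (SMOTE, ADASYN):
            raise ValueError(f"unknown method {self.method!r}")
        if self.direction not in (CONVENTIONAL, AS_PRINTED):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.scope not in ("train-only", "whole-dataset"):
            raise ValueError(f"unknown scope {self.scope!r}")


def interpolate_smote(
    f_i: Sequence[float],
    f_near: Sequence[float],
    r: float,
    direction: str = CONVENTIONAL,
) -> np.ndarray:
    """One SMOTE interpolation step between a minority point and a neighbour."""
    a = np.asarray(f_i, dtype=float)
    b = np.asarray(f_near, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    if not (0.0 <= r <= 1.0):
        raise ValueError("R must lie in [0, 1]")
    if direction == CONVENTIONAL:
        return a + (b - a) * r
    if direction == AS_PRINTED:
        return a + (a - b) * r
    raise ValueError(f"unknown direction {direction!r}")


def interpolate_adasyn(
    f_i: Sequence[float], fz_i: Sequence[float], lam: float
) -> np.ndarray:
    """One ADASYN interpolation step (always toward the neighbour)."""
    a = np.asarray(f_i, dtype=float)
    b = np.asarray(fz_i, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    return a + (b - a) * lam


def _same_class_neighbours(Xc: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    """Indices of each point's k nearest same-class neighbours (self excluded)."""
    n = len(Xc)
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1, metric="minkowski", p=2).fit(Xc)
    idx = nn.kneighbors(Xc, return_distance=False)[:, 1:]
    return idx, k_eff


def _adasyn_ratios(X: np.ndarray, y: np.ndarray, cls, k: int) -> np.ndarray:
    """Fraction of opposite-class points among each minority point's k NN."""
    mask = y == cls
    k_eff = min(k, len(X) - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1, metric="minkowski", p=2).fit(X)
    idx = nn.kneighbors(X[mask], return_distance=False)[:, 1:]
    other = (~mask)[idx]
    return other.sum(axis=1) / k_eff


def _allocate_quotas(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer quotas proportional to ``weights`` summing exactly to ``total``.

    Floors the proportional shares, then hands the remainder to the
    highest-weight points (stable order for ties).
    """
    if weights.sum() == 0:
        weights = np.ones_like(weights, dtype=float)
    norm = weights / weights.sum()
    quotas = np.floor(norm * total).astype(int)
    short = total - quotas.sum()
    if short > 0:
        order = np.argsort(-norm, kind="stable")
        quotas[order[:short]] += 1
    return quotas


def _snap(synth: np.ndarray, X: np.ndarray, value_range) -> np.ndarray:
    lo, hi = (
        value_range
        if value_range is not None
        else (X.min(axis=0), X.max(axis=0))
    )
    return np.clip(np.rint(synth), lo, hi)


def oversample(
    X: pd.DataFrame | np.ndarray,
    y: Sequence,
    config: OversamplerConfig = OversamplerConfig(),
) -> tuple[pd.DataFrame | np.ndarray, np.ndarray, np.ndarray]:
    """Balance every class up to the majority count.

    Returns ``(X_balanced, y_balanced, is_synthetic)``; originals come first
    in their input order, synthetic rows are appended grouped by class in
    sorted class order.  Fully deterministic for a given config.
    """
    is_frame = isinstance(X, pd.DataFrame)
    cols = list(X.columns) if is_frame else None
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y)
    if len(Xa) == 0:
        raise ValueError("cannot oversample an empty dataset")
    if len(Xa) != len(ya):
        raise ValueError("X and y lengths differ")
    classes, counts = np.unique(ya, return_counts=True)
    if len(classes) < 2:
        raise ValueError("oversampling needs at least two classes")
    target = int(counts.max())

    rng = np.random.default_rng(config.seed)
    synth_X: list[np.ndarray] = []
    synth_y: list[np.ndarray] = []

    for cls, n_c in zip(classes, counts):
        deficit = target - int(n_c)
        if deficit == 0:
            continue
        Xc = Xa[ya == cls]
        if n_c == 1:
            warnings.warn(
                f"class {cls!r} has a single member; replicating it {deficit} times"
            )
            new = np.repeat(Xc, deficit, axis=0)
            synth_X.append(new)
            synth_y.append(np.full(deficit, cls, dtype=ya.dtype))
            continue
        if n_c - 1 < config.k:
            warnings.warn(
                f"class {cls!r} has {n_c} members; reducing k from "
                f"{config.k} to {n_c - 1}"
            )
        nbr_idx, k_eff = _same_class_neighbours(Xc, config.k)

        if config.method == SMOTE:
            seeds = rng.integers(0, len(Xc), size=deficit)
        else:
            ratios = _adasyn_ratios(Xa, ya, cls, config.k)
            quotas = _allocate_quotas(ratios, deficit)
            assert quotas.sum() == deficit
            seeds = np.repeat(np.arange(len(Xc)), quotas)

        picks = rng.integers(0, k_eff, size=deficit)
        fracs = rng.random(size=deficit)
        f_i = Xc[seeds]
        f_nb = Xc[nbr_idx[seeds, picks]]
        if config.method == SMOTE and config.direction == AS_PRINTED:
            new = f_i + (f_i - f_nb) * fracs[:, None]
        else:
            new = f_i + (f_nb - f_i) * fracs[:, None]
        if config.snap_to_grid:
            new = _snap(new, Xa, config.value_range)
        synth_X.append(new)
        synth_y.append(np.full(deficit, cls, dtype=ya.dtype))

    if synth_X:
        X_new = np.vstack([Xa] + synth_X)
        y_new = np.concatenate([ya] + synth_y)
        n_synth = sum(len(s) for s in synth_X)
    else:
        X_new, y_new, n_synth = Xa.copy(), ya.copy(), 0
    flags = np.zeros(len(X_new), dtype=bool)
    flags[len(Xa):] = True
    assert n_synth == flags.sum()

    if is_frame:
        X_out: pd.DataFrame | np.ndarray = pd.DataFrame(X_new, columns=cols)
    else:
        X_out = X_new
    return X_out, y_new, flags
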