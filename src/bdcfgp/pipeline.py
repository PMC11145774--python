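"""End-to-end orchestration of the four screening approaches.

An approach is a feature representation plus an optional balancing step:

* CDS — the 25 raw item weights as predictors;
* FGP — the 4 ordinal group targets as predictors;
* FGP+SMOTE / FGP+ADASYN — FGP features with classes oversampled to parity.

A run loads or generates a labeled response table, builds the features,
splits 60/20/20 stratified, balances (training split only by default; a
whole-dataset scope reproduces the published 654 -> 2160 accounting), trains
the requested classifiers, and evaluates each on the training split, on ten
stratified folds of the validation split (mean fold accuracy), and on the
held-out test split with full imbalance-aware metrics.

One global seed fans out through a seed sequence to per-stage substreams
(generation, split, balancing, one per model), so any stage can be rerun in
isolation and identical configs give byte-identical reports.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import balancing, evaluation, fgp, instrument, modeling, synthetic_data

logger = logging.getLogger(__name__)

APPROACHES = ("cds", "fgp")
BALANCERS = ("none", "smote", "adasyn")


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs; fully determines the report."""

    approach: str = "fgp"
    balance: str = "none"
    models: tuple[str, ...] = modeling.MODEL_NAMES
    seed: int = 0
    input_path: str | None = None
    class_counts: tuple[int, ...] = synthetic_data.DEFAULT_CLASS_COUNTS
    split: evaluation.SplitSpec | None = None
    sampler_k: int = 5
    sampler_direction: str = balancing.CONVENTIONAL
    balance_scope: str = "train-only"
    constants: fgp.BandConstants = field(default_factory=fgp.BandConstants)
    cv_folds: int = 10

    def __post_init__(self) -> None:
        if self.approach not in APPROACHES:
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.balance not in BALANCERS:
            raise ValueError(f"unknown balance {self.balance!r}")
        for m in self.models:
            if m not in modeling.MODEL_NAMES:
                raise ValueError(f"unknown model {m!r}")


@dataclass
class ModelResult:
    model: str
    training_accuracy: float
    validation_accuracy: float
    testing_accuracy: float
    test_metrics: evaluation.MetricsReport
    training_seconds: float


@dataclass
class RunReport:
    config: RunConfig
    feature_count: int
    class_counts_input: dict
    class_counts_balanced: dict | None
    split_sizes: tuple[int, int, int]
    n_dropped: int
    results: dict[str, ModelResult]

    def to_dict(self, include_timings: bool = False) -> dict:
        d: dict = {
            "config": asdict(self.config),
            "feature_count": self.feature_count,
            "class_counts_input": {str(k): v for k, v in self.class_counts_input.items()},
            "class_counts_balanced": (
                {str(k): v for k, v in self.class_counts_balanced.items()}
                if self.class_counts_balanced is not None
                else None
            ),
            "split_sizes": list(self.split_sizes),
            "n_dropped": self.n_dropped,
            "results": {},
        }
        if d["config"]["split"] is not None:
            d["config"]["split"] = asdict(self.config.split)
        for name, r in self.results.items():
            m = r.test_metrics
            d["results"][name] = {
                "training_accuracy": r.training_accuracy,
                "validation_accuracy": r.validation_accuracy,
                "testing_accuracy": r.testing_accuracy,
                "balanced_accuracy": m.balanced_accuracy,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "precision": m.precision,
                "f1": m.f1,
                "macro_recall": m.macro_recall,
            }
            if include_timings:
                d["results"][name]["training_seconds"] = r.training_seconds
        return d

    def save(self, path: str | Path, include_timings: bool = False) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(include_timings), indent=2, sort_keys=True) + "\n"
        )


def _count_dict(y) -> dict:
    classes, counts = np.unique(y, return_counts=True)
    return {int(c): int(n) for c, n in zip(classes, counts)}


def _substream_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds below 2**31 for each pipeline stage."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _features_and_labels(
    table: instrument.ResponseTable, config: RunConfig
) -> tuple[pd.DataFrame, np.ndarray, tuple[float, float]]:
    if config.approach == "fgp":
        out = fgp.fgp_transform(table, constants=config.constants)
        X = out.loc[:, list(fgp.TARGET_COLUMNS)]
        y = out[instrument.LABEL_COLUMN].to_numpy()
        return X, y, (0.0, 5.0)
    X = table.df.loc[:, list(instrument.ITEM_COLUMNS)]
    if table.has_labels:
        y = table.labels()
    else:
        y = np.array([int(instrument.cds_severity(s)) for s in X.sum(axis=1)])
    return X, y, (0.0, 4.0)


def _model_config(name: str, seed: int, approach: str) -> modeling.ModelConfig:
    # CNB must know the categorical alphabet size: 5 raw weight values for
    # CDS features, 6 ordinal codes for FGP features.
    n_cat = 5 if approach == "cds" else 6
    if name == "cnb":
        return modeling.ModelConfig(name, seed, {"min_categories": n_cat})
    if name == "stacking":
        return modeling.ModelConfig(name, seed, {"cnb": {"min_categories": n_cat}})
    return modeling.ModelConfig(name, seed)


def load_or_generate(config: RunConfig) -> instrument.ResponseTable:
    if config.input_path is not None:
        return instrument.load_responses(config.input_path)
    gen_seed = _substream_seeds(config.seed, 1)[0]
    return synthetic_data.generate_dataset(
        synthetic_data.GeneratorSpec(class_counts=config.class_counts, seed=gen_seed)
    )


def run_pipeline(
    config: RunConfig, table: instrument.ResponseTable | None = None
) -> RunReport:
    """Execute one full approach run and return its report."""
    seeds = _substream_seeds(config.seed, 4 + len(config.models))
    if table is None:
        table = load_or_generate(config)

    X, y, value_range = _features_and_labels(table, config)
    counts_in = _count_dict(y)
    counts_bal: dict | None = None

    sampler = None
    if config.balance != "none":
        sampler = balancing.OversamplerConfig(
            method=config.balance,
            k=config.sampler_k,
            seed=seeds[2],
            direction=config.sampler_direction,
            snap_to_grid=True,
            value_range=value_range,
            scope=config.balance_scope,
        )

    if sampler is not None and config.balance_scope == "whole-dataset":
        X, y, _ = balancing.oversample(X, y, sampler)
        counts_bal = _count_dict(y)

    split = config.split or evaluation.SplitSpec(seed=seeds[1])
    tr, va, te = evaluation.split_dataset(y, split)
    Xa = np.asarray(X, dtype=float)
    X_tr, y_tr = Xa[tr], y[tr]
    X_va, y_va = Xa[va], y[va]
    X_te, y_te = Xa[te], y[te]

    if sampler is not None and config.balance_scope == "train-only":
        X_tr, y_tr, _ = balancing.oversample(X_tr, y_tr, sampler)
        X_tr = np.asarray(X_tr, dtype=float)
        counts_bal = _count_dict(y_tr)

    folds = evaluation.stratified_kfold(y_va, k=config.cv_folds, seed=seeds[3])

    results: dict[str, ModelResult] = {}
    for name, m_seed in zip(config.models, seeds[4:]):
        t0 = time.perf_counter()
        model = modeling.build_and_train(
            _model_config(name, m_seed, config.approach), X_tr, y_tr
        )
        elapsed = time.perf_counter() - t0
        logger.info("trained %s in %.3f s", name, elapsed)

        train_acc = evaluation.accuracy(y_tr, modeling.predict(model, X_tr))
        pred_va = modeling.predict(model, X_va)
        fold_accs = [evaluation.accuracy(y_va[f], pred_va[f]) for f in folds]
        pred_te = modeling.predict(model, X_te)
        results[name] = ModelResult(
            model=name,
            training_accuracy=train_acc,
            validation_accuracy=float(np.mean(fold_accs)),
            testing_accuracy=evaluation.accuracy(y_te, pred_te),
            test_metrics=evaluation.evaluate_predictions(y_te, pred_te),
            training_seconds=elapsed,
        )

    return RunReport(
        config=config,
        feature_count=Xa.shape[1],
        class_counts_input=counts_in,
        class_counts_balanced=counts_bal,
        split_sizes=(len(tr), len(va), len(te)),
        n_dropped=table.n_dropped,
        results=results,
    )


def compare_approaches(
    reports: Sequence[RunReport] | Mapping[str, RunReport]
) -> pd.DataFrame:
    """Side-by-side metric table across runs sharing a model set.

    One row per (approach, model); columns include the train/validation and
    train/test accuracy gaps — the overfitting diagnostic.  If the runs'
    model sets differ, the intersection is used with a warning.
    """
    if isinstance(reports, Mapping):
        named = list(reports.items())
    else:
        named = [
            (f"{r.config.approach}+{r.config.balance}", r) for r in reports
        ]
    if len(named) < 2:
        raise ValueError("need at least two reports to compare")

    shared = set(named[0][1].results)
    for _, r in named[1:]:
        shared &= set(r.results)
    if any(shared != set(r.results) for _, r in named):
        import warnings

        warnings.warn("model sets differ across reports; using the intersection")

    rows = []
    for label, r in named:
        for m in sorted(shared):
            res = r.results[m]
            met = res.test_metrics
            rows.append(
                {
                    "approach": label,
                    "model": m,
                    "training_accuracy": res.training_accuracy,
                    "validation_accuracy": res.validation_accuracy,
                    "testing_accuracy": res.testing_accuracy,
                    "train_val_gap": res.training_accuracy - res.validation_accuracy,
                    "train_test_gap": res.training_accuracy - res.testing_accuracy,
                    "balanced_accuracy": met.balanced_accuracy,
                    "sensitivity": met.sensitivity,
                    "specificity": met.specificity,
                    "precision": met.precision,
                    "f1": met.f1,
                }
            )
    return pd.DataFrame(rows)
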