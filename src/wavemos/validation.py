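"""Grouped cross-validation of MOS predictors and its performance metrics.

Reconstructed-speech corpora come in dataset-sized groups (one group per
source study), and trials within a group share recording conditions, task
and vocoder.  A model validated by plain random splits would leak that
group structure; the harness here therefore uses leave-one-dataset-out
(LODO) folds — or leave-one-trial-out (LOTO) when only one group exists
or the model is cheap to refit — and scores the *aggregated* out-of-sample
predictions once, rather than averaging per-fold scores.  On small unequal
folds those two conventions genuinely differ, and the aggregated form is
the one used throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .scorer import (FeatureVector, McdMinMax, PiecewiseLinearScorer, ScorerError,
                     fit_model, fit_piecewise, predict, predict_piecewise,
                     DEFAULT_THRESHOLD, MODEL_KINDS)


class ValidationError(ValueError):
    """Invalid split request or degenerate inputs."""


@dataclass(frozen=True)
class Sample:
    """One trial: objective metrics plus its subjective MOS target."""

    trial_id: str
    dataset_id: str
    stoi: float
    mcd_db: float
    entropy: float
    mos: float


@dataclass(frozen=True)
class Fold:
    """A single cross-validation fold; test/train index lists into the samples."""

    held_out: str
    test_idx: tuple
    train_idx: tuple


@dataclass
class CVReport:
    """Aggregated out-of-sample cross-validation result.

    Every trial is predicted exactly once, by a model whose training fold
    excluded that trial's group; folds that could not be fitted are
    flagged and their trials excluded from the aggregate.
    """

    model_kind: str
    split: str
    seed: int
    fold_assignments: dict
    oos_predictions: dict
    truths: dict
    r_squared: float
    mae: float
    skipped_folds: list = field(default_factory=list)

    @property
    def has_warnings(self) -> bool:
        return bool(self.skipped_folds)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    def predictions_frame(self) -> pd.DataFrame:
        rows = [{"trial_id": t, "fold": self.fold_assignments[t],
                 "predicted": p, "mos": self.truths[t]}
                for t, p in sorted(self.oos_predictions.items())]
        return pd.DataFrame(rows)


def r_squared(pred, truth) -> float:
    """Coefficient of determination: 1 - SS_res / SS_tot about the truth mean."""
    pred = np.asarray(list(pred), dtype=np.float64)
    truth = np.asarray(list(truth), dtype=np.float64)
    if pred.size != truth.size:
        raise ValidationError("prediction/truth length mismatch")
    if pred.size < 2:
        raise ValidationError("need at least two points")
    ss_tot = np.sum((truth - truth.mean()) ** 2)
    if ss_tot == 0.0:
        raise ValidationError("R^2 undefined for constant truth")
    ss_res = np.sum((pred - truth) ** 2)
    return float(1.0 - ss_res / ss_tot)


def mae(pred, truth) -> float:
    """Mean absolute error between predictions and truth."""
    pred = np.asarray(list(pred), dtype=np.float64)
    truth = np.asarray(list(truth), dtype=np.float64)
    if pred.size != truth.size:
        raise ValidationError("prediction/truth length mismatch")
    return float(np.mean(np.abs(pred - truth)))


def lodo_split(samples) -> list[Fold]:
    """Leave-one-dataset-out folds, one per dataset_id, iterated in sorted order."""
    samples = list(samples)
    groups = sorted({s.dataset_id for s in samples})
    if len(groups) < 2:
        raise ValidationError(
            "leave-one-dataset-out needs >= 2 datasets; "
            "use leave-one-trial-out for a single dataset")
    folds = []
    for g in groups:
        test = tuple(i for i, s in enumerate(samples) if s.dataset_id == g)
        train = tuple(i for i, s in enumerate(samples) if s.dataset_id != g)
        folds.append(Fold(held_out=g, test_idx=test, train_idx=train))
    return folds


def loto_split(samples) -> list[Fold]:
    """Leave-one-trial-out folds, one per trial, iterated in sorted trial order."""
    samples = list(samples)
    if len(samples) < 2:
        raise ValidationError("leave-one-trial-out needs >= 2 trials")
    order = sorted(range(len(samples)), key=lambda i: samples[i].trial_id)
    folds = []
    for i in order:
        train = tuple(j for j in range(len(samples)) if j != i)
        folds.append(Fold(held_out=samples[i].trial_id,
                          test_idx=(i,), train_idx=train))
    return folds


def _features_for(samples, transform: McdMinMax):
    return [FeatureVector(stoi=s.stoi, mcd_feature=transform(s.mcd_db),
                          entropy=s.entropy, raw_mcd_db=s.mcd_db)
            for s in samples]


def cross_validate(samples, model_kind: str = "random_forest",
                   split: str = "lodo", seed: int = 0,
                   hyperparameters: dict | None = None,
                   threshold: float = DEFAULT_THRESHOLD) -> CVReport:
    """Grouped cross-validation of one model kind over metric/MOS samples.

    Per fold a fresh model is fitted on the training trials and evaluated
    on the held-out group; the MCD min-max feature transform is refitted
    on each training fold so no information from the held-out group leaks
    into the features.  R^2 and MAE are computed once on the aggregated
    out-of-sample predictions.  Folds on which the model cannot be fitted
    (e.g. a piecewise entropy group left with too few trials) are skipped
    with a warning and listed in the report.
    """
    samples = list(samples)
    if model_kind not in MODEL_KINDS + ("piecewise", "oracle"):
        raise ValidationError(f"unknown model kind {model_kind!r}")
    folds = lodo_split(samples) if split == "lodo" else loto_split(samples)
    if split not in ("lodo", "loto"):
        raise ValidationError(f"unknown split kind {split!r}")

    fold_assignments: dict = {}
    oos: dict = {}
    truths: dict = {}
    skipped: list = []
    for fold in folds:
        train = [samples[i] for i in fold.train_idx]
        test = [samples[i] for i in fold.test_idx]
        transform = McdMinMax.fit([s.mcd_db for s in train])
        train_f = _features_for(train, transform)
        test_f = _features_for(test, transform)
        train_y = [s.mos for s in train]
        try:
            if model_kind == "oracle":
                # harness check: a predictor that returns the true MOS must
                # score R^2 = 1, MAE = 0 through the whole pipeline
                preds = [s.mos for s in test]
            elif model_kind == "piecewise":
                model = fit_piecewise(train_f, train_y, threshold=threshold,
                                      feature_transform=transform.to_dict())
                preds = [predict_piecewise(model, f) for f in test_f]
            else:
                model = fit_model(train_f, train_y, kind=model_kind,
                                  hyperparameters=hyperparameters, seed=seed)
                preds = [predict(model, f) for f in test_f]
        except ScorerError as exc:
            warnings.warn(f"fold {fold.held_out!r} skipped: {exc}")
            skipped.append(fold.held_out)
            continue
        for s, p in zip(test, preds):
            fold_assignments[s.trial_id] = fold.held_out
            oos[s.trial_id] = float(p)
            truths[s.trial_id] = float(s.mos)

    if len(oos) < 2:
        raise ValidationError("too few out-of-sample predictions to score")
    keys = sorted(oos)
    r2 = r_squared([oos[k] for k in keys], [truths[k] for k in keys])
    err = mae([oos[k] for k in keys], [truths[k] for k in keys])
    return CVReport(model_kind=model_kind, split=split, seed=seed,
                    fold_assignments=fold_assignments, oos_predictions=oos,
                    truths=truths, r_squared=r2, mae=err, skipped_folds=skipped)
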