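"""Predicted-MOS models mapping objective metrics to perceptual quality.

Two model families share a feature vector of (segmental STOI, an MCD
feature, and the spectral entropy of the reference):

* :class:`PiecewiseLinearScorer` — an interpretable baseline with two
  linear regimes gated on signal complexity.  Simple, low-entropy
  utterances are the regime where the correlation-based score is
  unreliable; complex, high-entropy utterances are where the distance-
  based score misleads.  The default coefficients are

      score = 0.101 + 0.544 * MCD + 0.089 * STOI   (entropy < 0.7)
      score = 0.921 - 0.892 * MCD + 0.223 * STOI   (entropy >= 0.7)

  evaluated literally on whatever ``mcd_feature`` is supplied (the
  bounded, unitless transform of raw MCD is configured separately and
  recorded).  Entropy exactly at the threshold takes the high regime.

* :class:`TrainableScorer` — an RBF-kernel support vector regressor or a
  random-forest regressor trained on (STOI, MCD feature) alone; entropy
  is not an input to the trainable models.

Raw MCD is in decibels and unbounded, so model inputs use a recorded
affine min-max transform fitted on the training pool; the transform is
stored with the model and re-applied at prediction time.
"""

from __future__ import annotations

import base64
import io
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import SVR

#: Published default coefficients (intercept, mcd slope, stoi slope) per regime.
DEFAULT_THRESHOLD = 0.7
DEFAULT_LOW_COEFFS = (0.101, 0.544, 0.089)
DEFAULT_HIGH_COEFFS = (0.921, -0.892, 0.223)

MODEL_KINDS = ("svr_rbf", "random_forest")


class ScorerError(ValueError):
    """Invalid scorer configuration or state."""


@dataclass(frozen=True)
class FeatureVector:
    """Inputs to the quality scorers for one trial."""

    stoi: float
    mcd_feature: float
    entropy: float
    raw_mcd_db: float | None = None

    def __post_init__(self) -> None:
        vals = [self.stoi, self.mcd_feature, self.entropy]
        if not all(np.isfinite(vals)):
            raise ScorerError("feature values must be finite")
        if not 0.0 <= self.entropy <= 1.0:
            raise ScorerError(f"entropy must lie in [0,1], got {self.entropy}")


@dataclass(frozen=True)
class McdMinMax:
    """Recorded affine map taking raw MCD (dB) to a bounded unitless feature."""

    lo: float
    hi: float

    @classmethod
    def fit(cls, raw_mcd_db) -> "McdMinMax":
        arr = np.asarray(list(raw_mcd_db), dtype=np.float64)
        if arr.size == 0:
            raise ScorerError("cannot fit a min-max transform on no data")
        return cls(lo=float(arr.min()), hi=float(arr.max()))

    def __call__(self, raw_db: float) -> float:
        span = self.hi - self.lo
        if span <= 0:
            return 0.0
        return (float(raw_db) - self.lo) / span

    def to_dict(self) -> dict:
        return {"kind": "minmax", "lo": self.lo, "hi": self.hi}


@dataclass(frozen=True)
class PiecewiseLinearScorer:
    """Two-regime linear MOS predictor gated on reference-signal entropy."""

    threshold: float = DEFAULT_THRESHOLD
    low_coeffs: tuple = DEFAULT_LOW_COEFFS
    high_coeffs: tuple = DEFAULT_HIGH_COEFFS
    feature_transform: dict = field(default_factory=lambda: {"kind": "identity"})

    def predict(self, f: FeatureVector) -> float:
        coeffs = self.high_coeffs if f.entropy >= self.threshold else self.low_coeffs
        intercept, mcd_slope, stoi_slope = coeffs
        return float(intercept + mcd_slope * f.mcd_feature + stoi_slope * f.stoi)

    def to_dict(self) -> dict:
        return {"model": "piecewise_linear", "threshold": self.threshold,
                "low_coeffs": list(self.low_coeffs),
                "high_coeffs": list(self.high_coeffs),
                "feature_transform": self.feature_transform}


def predict_piecewise(model: PiecewiseLinearScorer, f: FeatureVector) -> float:
    """Evaluate the piecewise linear scorer on one feature vector."""
    return model.predict(f)


def fit_piecewise(features, mos_scores, threshold: float = DEFAULT_THRESHOLD,
                  feature_transform: dict | None = None) -> PiecewiseLinearScorer:
    """Ordinary-least-squares fit of the two-regime linear scorer.

    Samples are split into low/high groups by reference entropy at
    ``threshold`` and one linear model (intercept + MCD and STOI slopes)
    is fitted per group.  Each group needs at least 3 samples and a
    full-rank design; otherwise a rank-deficiency error names the group.
    """
    features = list(features)
    y = np.asarray(list(mos_scores), dtype=np.float64)
    if len(features) != y.size:
        raise ScorerError("features and targets differ in length")
    coeffs = {}
    for name, keep in (("low", lambda f: f.entropy < threshold),
                       ("high", lambda f: f.entropy >= threshold)):
        idx = [i for i, f in enumerate(features) if keep(f)]
        if len(idx) < 3:
            raise ScorerError(
                f"entropy group '{name}' has {len(idx)} samples; "
                "need >= 3 to fit intercept and two slopes")
        x = np.array([[1.0, features[i].mcd_feature, features[i].stoi] for i in idx])
        if np.linalg.matrix_rank(x) < 3:
            raise ScorerError(f"rank-deficient design in entropy group '{name}'")
        beta, *_ = np.linalg.lstsq(x, y[idx], rcond=None)
        coeffs[name] = tuple(float(b) for b in beta)
    return PiecewiseLinearScorer(
        threshold=threshold, low_coeffs=coeffs["low"], high_coeffs=coeffs["high"],
        feature_transform=feature_transform or {"kind": "identity"})


DEFAULT_HYPERPARAMETERS = {
    "svr_rbf": {"C": 1.0, "gamma": "scale", "epsilon": 0.1},
    "random_forest": {"n_estimators": 500, "max_depth": None},
}


@dataclass
class TrainableScorer:
    """SVR or random-forest MOS predictor over (STOI, MCD feature).

    Hyperparameters, seed, and the MCD feature transform are recorded so a
    refit from identical data reproduces identical predictions.
    """

    kind: str
    hyperparameters: dict
    seed: int
    feature_transform: McdMinMax | None = None
    _estimator: object = None
    _target_range: tuple | None = None

    @property
    def fitted(self) -> bool:
        return self._estimator is not None

    def to_dict(self) -> dict:
        blob = base64.b64encode(pickle.dumps(self._estimator)).decode("ascii")
        ft = self.feature_transform.to_dict() if self.feature_transform else None
        return {"model": self.kind, "hyperparameters": self.hyperparameters,
                "seed": self.seed, "feature_transform": ft,
                "target_range": self._target_range, "fitted_state": blob}


def fit_model(features, mos_scores, kind: str,
              hyperparameters: dict | None = None, seed: int = 0) -> TrainableScorer:
    """Train an SVR or random-forest MOS predictor on (stoi, mcd_feature).

    Entropy is deliberately not an input: the trainable models learn the
    complexity-dependent structure from the two objective metrics alone.
    When the supplied feature vectors carry ``raw_mcd_db``, a min-max
    transform is fitted on the training pool and recorded; otherwise the
    given ``mcd_feature`` values are used as-is.
    """
    features = list(features)
    y = np.asarray(list(mos_scores), dtype=np.float64)
    if len(features) != y.size:
        raise ScorerError("features and targets differ in length")
    if len(features) < 5:
        raise ScorerError(f"need at least 5 training samples, got {len(features)}")
    if kind not in MODEL_KINDS:
        raise ScorerError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
    hp = dict(DEFAULT_HYPERPARAMETERS[kind])
    hp.update(hyperparameters or {})

    transform = None
    if all(f.raw_mcd_db is not None for f in features):
        transform = McdMinMax.fit(f.raw_mcd_db for f in features)
        x = np.array([[f.stoi, transform(f.raw_mcd_db)] for f in features])
    else:
        x = np.array([[f.stoi, f.mcd_feature] for f in features])

    if kind == "svr_rbf":
        est = SVR(kernel="rbf", **hp)
    else:
        est = RandomForestRegressor(random_state=seed, **hp)
    est.fit(x, y)
    return TrainableScorer(kind=kind, hyperparameters=hp, seed=seed,
                           feature_transform=transform, _estimator=est,
                           _target_range=(float(y.min()), float(y.max())))


def predict(model: TrainableScorer, f: FeatureVector) -> float:
    """Predicted MOS for one feature vector, on the training-target scale."""
    if not model.fitted:
        raise ScorerError("model must be fitted before prediction")
    if model.feature_transform is not None and f.raw_mcd_db is not None:
        mcd_feat = model.feature_transform(f.raw_mcd_db)
    else:
        mcd_feat = f.mcd_feature
    x = np.array([[f.stoi, mcd_feat]])
    return float(model._estimator.predict(x)[0])


def fit_output_calibration(predictions, mos_scores) -> tuple[float, float]:
    """Least-squares affine map (scale, offset) from model output to MOS.

    The default piecewise coefficients produce scores on a normalized
    quality scale; when 1-5 MOS targets are available this fits
    ``mos ~= scale * score + offset`` so predictions can be reported on
    the opinion scale.  Fit it on training data only and store the pair
    alongside the model.
    """
    x = np.asarray(list(predictions), dtype=np.float64)
    y = np.asarray(list(mos_scores), dtype=np.float64)
    if x.size != y.size or x.size < 2:
        raise ScorerError("calibration needs >= 2 matched (score, MOS) pairs")
    if np.ptp(x) == 0:
        raise ScorerError("calibration undefined for constant scores")
    design = np.stack([x, np.ones_like(x)], axis=1)
    (scale, offset), *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(scale), float(offset)


def save_model(model, path: str | Path) -> None:
    """Serialize a scorer (piecewise or trainable) to a JSON file."""
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def load_model(path: str | Path):
    """Load a scorer serialized by :func:`save_model`."""
    doc = json.loads(Path(path).read_text())
    if doc["model"] == "piecewise_linear":
        return PiecewiseLinearScorer(
            threshold=doc["threshold"],
            low_coeffs=tuple(doc["low_coeffs"]),
            high_coeffs=tuple(doc["high_coeffs"]),
            feature_transform=doc.get("feature_transform", {"kind": "identity"}))
    ft = doc.get("feature_transform")
    transform = McdMinMax(lo=ft["lo"], hi=ft["hi"]) if ft else None
    est = pickle.loads(base64.b64decode(doc["fitted_state"]))
    tr = doc.get("target_range")
    return TrainableScorer(kind=doc["model"], hyperparameters=doc["hyperparameters"],
                           seed=doc["seed"], feature_transform=transform,
                           _estimator=est,
                           _target_range=tuple(tr) if tr else None)
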