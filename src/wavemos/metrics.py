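"""Objective reconstruction metrics: Pearson CC, segmental MFCC STOI, and MCD.

Three complementary views of reference/reconstruction similarity:

* ``cc_full`` — Pearson correlation between the flattened MFCC matrices of
  the whole utterance.  Scale- and offset-insensitive, and notoriously
  sensitive to the analysis window length (``cc_window_sensitivity``
  quantifies that inflation).
* ``stoi_mfcc`` — a segmental intelligibility score: the MFCC matrices are
  cut into consecutive short-time segments, the Pearson correlation is taken
  per segment, and the segment correlations are averaged.  Being
  correlation-based it is invariant to affine rescaling of the features.
* ``mcd`` — mel cepstral distortion: the decibel-scaled mean Euclidean
  distance between cepstral frames.  Distance-based, hence sensitive to the
  absolute spectral offsets that correlation-based scores ignore.

The deliberate dissociation between the last two — an offset moves MCD but
barely touches STOI; envelope-only reconstructions of simple utterances can
keep STOI high while quality is poor — is why a single metric is not enough
and the scorer module combines them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .audio_io import AudioPair, Waveform
from .features import (FeatureConfig, MfccMatrix, mfcc_pair, stft_magnitude,
                       normalized_entropy)

#: MCD scaling constant: converts a natural-log cepstral distance to dB.
MCD_DB_CONST = (10.0 / np.log(10.0)) * np.sqrt(2.0)


class ConstantInputError(ValueError):
    """Correlation undefined: one input has zero variance."""


class MetricError(ValueError):
    """Precondition violation in a metric computation."""


@dataclass(frozen=True)
class StoiResult:
    """Segmental STOI score plus segmentation provenance."""

    score: float
    n_segments: int
    n_skipped: int
    single_segment_fallback: bool = False

    def __float__(self) -> float:
        return self.score


@dataclass(frozen=True)
class MetricRecord:
    """Per-trial objective metric bundle with feature-config provenance."""

    trial_id: str
    dataset_id: str
    cc: float
    stoi: float
    mcd_db: float
    entropy: float
    n_frames: int
    stoi_segments: int
    stoi_skipped: int
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)

    def to_row(self) -> dict:
        return {
            "trial_id": self.trial_id,
            "dataset_id": self.dataset_id,
            "cc": self.cc,
            "stoi": self.stoi,
            "mcd_db": self.mcd_db,
            "entropy": self.entropy,
            "n_frames": self.n_frames,
            "config_hash": self.feature_config.digest(),
        }


def pearson_cc(x, y) -> float:
    """Pearson correlation coefficient r of two equal-length sequences.

    r = sum((x_i - xbar)(y_i - ybar)) / sqrt(sum((x_i - xbar)^2) sum((y_i - ybar)^2))

    Raises :class:`ConstantInputError` when either input has zero
    variance, leaving the fallback policy to the caller.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise MetricError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise MetricError("correlation needs at least two points")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt(np.sum(dx * dx))
    sy = np.sqrt(np.sum(dy * dy))
    if sx == 0.0 or sy == 0.0:
        raise ConstantInputError("correlation undefined for constant input")
    r = float(np.sum(dx * dy) / (sx * sy))
    return float(np.clip(r, -1.0, 1.0))


def cc_full(pair: AudioPair, config: FeatureConfig | None = None) -> float:
    """Whole-utterance Pearson CC between flattened MFCC matrices."""
    config = config or FeatureConfig()
    ref, rec = mfcc_pair(pair.reference, pair.reconstruction, config)
    return pearson_cc(ref.coeffs.ravel(), rec.coeffs.ravel())


def stoi_mfcc(ref: MfccMatrix, rec: MfccMatrix,
              segment_frames: int = 30) -> StoiResult:
    """Segmental MFCC intelligibility: mean per-segment Pearson correlation.

    Frames are partitioned into consecutive non-overlapping segments of
    ``segment_frames``; trailing frames not filling a segment are dropped.
    For each segment the correlation between the flattened reference and
    reconstruction sub-matrices is computed, and the mean over segments
    is returned.  Constant segments (zero variance on either side) are
    skipped and counted rather than assigned an arbitrary correlation.
    If the matrices are shorter than one segment, a single segment
    covering all frames is used and flagged.
    """
    if not ref.comparable_with(rec):
        raise MetricError("MFCC matrices differ in coefficient count or framing")
    if ref.n_frames != rec.n_frames:
        raise MetricError("frame-count mismatch: align the pair before features")
    if segment_frames < 1:
        raise MetricError("segment_frames must be >= 1")
    t = ref.n_frames
    fallback = t < segment_frames
    seg = t if fallback else segment_frames
    n_segments = t // seg
    corrs = []
    skipped = 0
    for j in range(n_segments):
        sl = slice(j * seg, (j + 1) * seg)
        try:
            corrs.append(pearson_cc(ref.coeffs[sl].ravel(), rec.coeffs[sl].ravel()))
        except ConstantInputError:
            skipped += 1
    if not corrs:
        raise ConstantInputError("every segment was constant; STOI undefined")
    return StoiResult(score=float(np.mean(corrs)),
                      n_segments=n_segments, n_skipped=skipped,
                      single_segment_fallback=fallback)


def mcd(ref: MfccMatrix, rec: MfccMatrix, exclude_c0: bool = True) -> float:
    """Mel cepstral distortion in dB.

    MCD = (10 / ln 10) * sqrt(2) * (1/T) * sum_t sqrt(sum_m (c_m(t) - chat_m(t))^2)

    with m running over coefficients 1..M-1 when ``exclude_c0`` (the
    conventional choice: the energy coefficient is dropped) else 0..M-1.
    Zero iff the compared coefficients are identical; symmetric in its
    arguments.
    """
    if not ref.comparable_with(rec):
        raise MetricError("MFCC matrices differ in coefficient count or framing")
    if ref.n_frames != rec.n_frames:
        raise MetricError("frame-count mismatch: align the pair before features")
    start = 1 if exclude_c0 else 0
    if start >= ref.n_coeffs:
        raise MetricError("no coefficients left after excluding c0")
    diff = ref.coeffs[:, start:] - rec.coeffs[:, start:]
    per_frame = np.sqrt(np.sum(diff * diff, axis=1))
    return float(MCD_DB_CONST * per_frame.mean())


def cc_window_sensitivity(pair: AudioPair, window_lengths,
                          config: FeatureConfig | None = None):
    """Mean whole-window CC as a function of analysis window length.

    For each requested window length the aligned pair is split into
    consecutive non-overlapping windows, ``cc_full`` is computed per
    window, and the mean is returned.  Windows in which either side has
    constant features are skipped.  A window longer than the audio is
    evaluated as a single whole-signal window and flagged.

    Returns a list of ``(window_seconds, mean_cc, n_windows, flagged)``.
    """
    config = config or FeatureConfig()
    rate = pair.reference.rate
    n = len(pair.reference)
    min_samples = int(round(config.frame_len * rate))
    curve = []
    for w_sec in window_lengths:
        w_n = int(round(w_sec * rate))
        flagged = w_n > n
        if flagged:
            w_n = n
        n_windows = n // w_n
        ccs = []
        for k in range(n_windows):
            sl = slice(k * w_n, (k + 1) * w_n)
            if (sl.stop - sl.start) < min_samples:
                continue
            sub = AudioPair(
                reference=Waveform(pair.reference.samples[sl], rate, pair.reference.id),
                reconstruction=Waveform(pair.reconstruction.samples[sl], rate,
                                        pair.reconstruction.id),
                dataset_id=pair.dataset_id, trial_id=pair.trial_id)
            try:
                ccs.append(cc_full(sub, config))
            except ConstantInputError:
                continue
        if not ccs:
            warnings.warn(f"no valid windows at {w_sec} s; entry omitted from mean")
            curve.append((float(w_sec), float("nan"), 0, True))
        else:
            curve.append((float(w_sec), float(np.mean(ccs)), len(ccs), flagged))
    return curve


def evaluate_pair(pair: AudioPair, config: FeatureConfig | None = None) -> MetricRecord:
    """All per-trial objective metrics as one provenance-carrying record.

    The entropy is that of the *reference* spectrogram: it characterises
    the intrinsic complexity of the target utterance, which decides which
    regime of the piecewise scorer applies.
    """
    config = config or FeatureConfig()
    ref_m, rec_m = mfcc_pair(pair.reference, pair.reconstruction, config)
    cc = pearson_cc(ref_m.coeffs.ravel(), rec_m.coeffs.ravel())
    stoi = stoi_mfcc(ref_m, rec_m, segment_frames=config.segment_frames)
    distortion = mcd(ref_m, rec_m, exclude_c0=config.exclude_c0)
    spec = stft_magnitude(pair.reference, frame_len=config.frame_len, hop=config.hop)
    entropy = normalized_entropy(spec)
    return MetricRecord(trial_id=pair.trial_id, dataset_id=pair.dataset_id,
                        cc=cc, stoi=stoi.score, mcd_db=distortion, entropy=entropy,
                        n_frames=ref_m.n_frames, stoi_segments=stoi.n_segments,
                        stoi_skipped=stoi.n_skipped, feature_config=config)
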