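"""Short-time spectral features: STFT magnitudes, MFCCs, and spectral entropy.

All objective metrics in this package operate on mel-frequency cepstral
coefficients (MFCCs) of the reference and reconstructed utterance, computed
with identical framing so the two matrices are frame-for-frame comparable.
The normalised Shannon entropy of the reference spectrogram serves as a
scale-free complexity measure in [0, 1]; it gates the two regimes of the
piecewise linear quality scorer (simple monosyllabic bursts score low,
broadband multi-syllable utterances score high).

No centring or padding is used: a signal of n samples with frame length
``frame`` and hop ``hop`` (in samples) yields ``1 + (n - frame) // hop``
frames, and MFCC matrices share this frame count with the STFT.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.fft import dct, rfft

from .audio_io import Waveform, DEFAULT_RATE

#: Dynamic-range clamp for log mel energies: bands more than 80 dB below the
#: utterance's peak band energy are floored, keeping log() finite on silent
#: bands without letting digital silence dominate cepstral distances.
_DYNAMIC_RANGE = 1e-8
#: Absolute fallback floor for an all-zero signal.
_ABS_FLOOR = 1e-30


class FeatureError(ValueError):
    """Invalid feature configuration or degenerate input."""


@dataclass(frozen=True)
class FeatureConfig:
    """Framing and MFCC settings shared by every metric in a run.

    Defaults are conventional wide-band speech settings: 25 ms Hann
    frames with a 10 ms hop, a 40-band mel filterbank and 13 cepstral
    coefficients.  ``segment_frames`` is the short-time analysis length
    of the segmental intelligibility score (30 frames ~ 300 ms);
    ``exclude_c0`` drops the energy coefficient from the cepstral
    distortion, the convention in speech-synthesis evaluation.
    """

    rate: int = DEFAULT_RATE
    frame_len: float = 0.025
    hop: float = 0.010
    n_mfcc: int = 13
    n_mels: int = 40
    segment_frames: int = 30
    exclude_c0: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Short stable hash for provenance tracking in output tables."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class Spectrogram:
    """Non-negative STFT magnitudes, frames x frequency bins."""

    magnitudes: np.ndarray
    frame_len: float
    hop: float
    rate: int

    def __post_init__(self) -> None:
        mags = np.asarray(self.magnitudes, dtype=np.float64)
        object.__setattr__(self, "magnitudes", mags)
        if mags.ndim != 2 or mags.shape[0] < 1:
            raise FeatureError("spectrogram needs at least one frame")
        if np.any(mags < 0):
            raise FeatureError("spectrogram magnitudes must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[0]

    def to_csv(self, path) -> None:
        """Export magnitudes for inspection, one frame per row."""
        np.savetxt(path, self.magnitudes, delimiter=",")


@dataclass(frozen=True)
class MfccMatrix:
    """Frames x M cepstral coefficient matrix plus the framing that made it."""

    coeffs: np.ndarray
    n_coeffs: int
    includes_c0: bool
    frame_len: float
    hop: float

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coeffs, dtype=np.float64)
        object.__setattr__(self, "coeffs", coeffs)
        if coeffs.ndim != 2 or coeffs.shape[1] != self.n_coeffs:
            raise FeatureError("coefficient matrix shape does not match n_coeffs")
        if not np.all(np.isfinite(coeffs)):
            raise FeatureError("MFCC values must be finite")

    @property
    def n_frames(self) -> int:
        return self.coeffs.shape[0]

    def comparable_with(self, other: "MfccMatrix") -> bool:
        return (self.n_coeffs == other.n_coeffs
                and self.frame_len == other.frame_len
                and self.hop == other.hop)

    def to_csv(self, path) -> None:
        """Export coefficients for inspection, one frame per row."""
        np.savetxt(path, self.coeffs, delimiter=",")


def _frame(samples: np.ndarray, frame: int, hop: int) -> np.ndarray:
    """Slice a signal into overlapping frames, dropping the tail remainder."""
    n = samples.size
    if n < frame:
        raise FeatureError(
            f"waveform of {n} samples is shorter than one frame ({frame} samples)")
    n_frames = 1 + (n - frame) // hop
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    return samples[idx]


def stft_magnitude(w: Waveform, frame_len: float = 0.025,
                   hop: float = 0.010) -> Spectrogram:
    """Hann-windowed STFT magnitude of a waveform."""
    if not (frame_len >= hop > 0):
        raise FeatureError("require frame_len >= hop > 0")
    frame = int(round(frame_len * w.rate))
    hop_n = int(round(hop * w.rate))
    frames = _frame(w.samples, frame, hop_n)
    window = np.hanning(frame)
    mags = np.abs(rfft(frames * window, axis=1))
    return Spectrogram(magnitudes=mags, frame_len=frame_len, hop=hop, rate=w.rate)


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, rate: int,
                   fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, n_fft // 2 + 1)."""
    fmax = rate / 2.0 if fmax is None else fmax
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bins = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    fb = np.zeros((n_mels, bins.size))
    for m in range(n_mels):
        lo, mid, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (bins - lo) / max(mid - lo, 1e-12)
        down = (hi - bins) / max(hi - mid, 1e-12)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
    return fb


def mfcc(w: Waveform, n_mfcc: int = 13, frame_len: float = 0.025,
         hop: float = 0.010, n_mels: int = 40) -> MfccMatrix:
    """Mel-frequency cepstral coefficients: mel filterbank -> log -> DCT-II.

    Coefficients 0..n_mfcc-1 are kept, including the energy coefficient
    c0; metrics downstream decide whether to exclude it.  Frame count
    matches :func:`stft_magnitude` under the same framing.
    """
    if n_mfcc > n_mels:
        raise FeatureError(f"n_mfcc ({n_mfcc}) cannot exceed n_mels ({n_mels})")
    spec = stft_magnitude(w, frame_len=frame_len, hop=hop)
    power = spec.magnitudes ** 2
    frame = int(round(frame_len * w.rate))
    fb = mel_filterbank(n_mels, frame, w.rate)
    mel_energy = power @ fb.T
    floor = max(mel_energy.max() * _DYNAMIC_RANGE, _ABS_FLOOR)
    log_mel = np.log(np.maximum(mel_energy, floor))
    cepstra = dct(log_mel, type=2, norm="ortho", axis=1)[:, :n_mfcc]
    return MfccMatrix(coeffs=cepstra, n_coeffs=n_mfcc, includes_c0=True,
                      frame_len=frame_len, hop=hop)


def mfcc_pair(ref: Waveform, rec: Waveform,
              config: FeatureConfig) -> tuple[MfccMatrix, MfccMatrix]:
    """MFCCs of both sides of a pair under one shared configuration."""
    kw = dict(n_mfcc=config.n_mfcc, frame_len=config.frame_len,
              hop=config.hop, n_mels=config.n_mels)
    return mfcc(ref, **kw), mfcc(rec, **kw)


def normalized_entropy(spec: Spectrogram) -> float:
    """Normalised Shannon entropy of the time-frequency magnitude distribution.

    The magnitude matrix is flattened and normalised to a probability
    distribution p_i = m_i / sum(m); the Shannon entropy
    H = -sum p_i log p_i is divided by log(K), K the total cell count,
    giving a scale-free complexity in [0, 1]: 0 for a single spectro-
    temporal peak, 1 for perfectly uniform energy.  Invariant to global
    amplitude scaling of the waveform.
    """
    m = spec.magnitudes.ravel()
    total = m.sum()
    if total <= 0:
        raise FeatureError("entropy undefined for an all-zero spectrogram")
    p = m / total
    nz = p[p > 0]
    h = -np.sum(nz * np.log(nz))
    k = m.size
    if k < 2:
        return 0.0
    return float(min(max(h / np.log(k), 0.0), 1.0))


def waveform_entropy(w: Waveform, config: FeatureConfig | None = None) -> float:
    """Convenience wrapper: normalised spectral entropy of a waveform."""
    config = config or FeatureConfig()
    return normalized_entropy(
        stft_magnitude(w, frame_len=config.frame_len, hop=config.hop))
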