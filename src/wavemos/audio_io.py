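"""Waveform loading, resampling, and reference/reconstruction pairing.

Reconstructed-speech evaluation always operates on a *pair* of signals:
the clean reference utterance and the waveform reconstructed from neural
data.  This module normalises both sides to a common representation
(mono float64 in [-1, 1] at a shared sample rate) and aligns their
lengths without any time-warping — silent periods are deliberately kept,
because a speech-BCI system that emits spurious noise during silence
should be penalised for it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

DEFAULT_RATE = 16_000
#: Directory-ingestion naming convention: ``<trial_id>_ref.wav`` / ``<trial_id>_rec.wav``
REF_SUFFIX = "_ref"
REC_SUFFIX = "_rec"


class AudioIOError(IOError):
    """Unreadable or empty audio input."""


@dataclass(frozen=True)
class Waveform:
    """Mono audio signal: dimensionless samples in [-1, 1] plus a sample rate in Hz."""

    samples: np.ndarray
    rate: int
    id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.rate <= 0:
            raise ValueError(f"sample rate must be positive, got {self.rate}")
        if samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional (mono)")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("Waveform samples must be finite")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class AudioPair:
    """A reference/reconstruction pair with equal rates and sample counts."""

    reference: Waveform
    reconstruction: Waveform
    dataset_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        if self.reference.rate != self.reconstruction.rate:
            raise ValueError("paired waveforms must share a sample rate")
        if len(self.reference) != len(self.reconstruction):
            raise ValueError("paired waveforms must share a sample count; align first")


def _to_float(samples: np.ndarray) -> np.ndarray:
    """Map integer PCM to [-1, 1]; pass float audio through."""
    if np.issubdtype(samples.dtype, np.floating):
        return samples.astype(np.float64)
    if samples.dtype == np.uint8:  # 8-bit WAV is unsigned, offset binary
        return (samples.astype(np.float64) - 128.0) / 128.0
    info = np.iinfo(samples.dtype)
    return samples.astype(np.float64) / -float(info.min)


def load_waveform(path: str | Path, target_rate: int = DEFAULT_RATE,
                  id: str | None = None) -> Waveform:
    """Load a WAV file as a mono waveform resampled to ``target_rate``.

    Multichannel audio is averaged across channels.  Peak normalisation is
    applied only if the decoded signal exceeds full scale, so valid audio
    passes through with its level intact.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except (OSError, ValueError) as exc:
        raise AudioIOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise AudioIOError(f"empty audio file: {path}")
    samples = _to_float(np.atleast_1d(data))
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    if rate != target_rate:
        frac = Fraction(target_rate, rate)
        samples = resample_poly(samples, frac.numerator, frac.denominator)
    peak = np.max(np.abs(samples)) if samples.size else 0.0
    if peak > 1.0:
        samples = samples / peak
    return Waveform(samples=samples, rate=target_rate,
                    id=path.stem if id is None else id)


def write_waveform(w: Waveform, path: str | Path, *, subtype: str = "pcm16") -> None:
    """Write a waveform as RIFF WAV (16-bit PCM by default, or float32)."""
    path = Path(path)
    clipped = np.clip(w.samples, -1.0, 1.0)
    if subtype == "pcm16":
        data = np.round(clipped * 32767.0).astype(np.int16)
    elif subtype == "float32":
        data = clipped.astype(np.float32)
    else:
        raise ValueError(f"unsupported WAV subtype: {subtype}")
    wavfile.write(path, w.rate, data)


def align_pair(ref: Waveform, rec: Waveform, policy: str = "truncate",
               dataset_id: str = "", trial_id: str = "") -> AudioPair:
    """Length-align a reference/reconstruction pair without time-warping.

    ``truncate`` cuts both to the shorter length; ``pad`` zero-pads the
    shorter at the end.  Rates must already agree (resample on load).
    """
    if ref.rate != rec.rate:
        raise ValueError(
            f"sample-rate mismatch ({ref.rate} vs {rec.rate} Hz): "
            "resample both waveforms to a common rate before aligning")
    if policy not in ("truncate", "pad"):
        raise ValueError(f"unknown alignment policy: {policy!r}")
    n_ref, n_rec = len(ref), len(rec)
    if n_ref == n_rec:
        pass
    elif policy == "truncate":
        n = min(n_ref, n_rec)
        ref = replace(ref, samples=ref.samples[:n])
        rec = replace(rec, samples=rec.samples[:n])
    else:
        n = max(n_ref, n_rec)
        if n_ref < n:
            ref = replace(ref, samples=np.pad(ref.samples, (0, n - n_ref)))
        if n_rec < n:
            rec = replace(rec, samples=np.pad(rec.samples, (0, n - n_rec)))
    return AudioPair(reference=ref, reconstruction=rec,
                     dataset_id=dataset_id, trial_id=trial_id or ref.id)


def load_pair_directory(ref_dir: str | Path, rec_dir: str | Path,
                        target_rate: int = DEFAULT_RATE,
                        policy: str = "truncate") -> tuple[list[AudioPair], list[str]]:
    """Pair up ``<trial>_ref.wav`` / ``<trial>_rec.wav`` files from two directories.

    Returns (pairs sorted by trial id, basenames that found no partner).
    Files named ``<trial>.wav`` on both sides are also accepted.
    """
    def index(d: Path) -> dict[str, Path]:
        out: dict[str, Path] = {}
        for p in sorted(d.glob("*.wav")):
            stem = p.stem
            for suffix in (REF_SUFFIX, REC_SUFFIX):
                if stem.endswith(suffix):
                    stem = stem[: -len(suffix)]
                    break
            out[stem] = p
        return out

    refs = index(Path(ref_dir))
    recs = index(Path(rec_dir))
    common = sorted(set(refs) & set(recs))
    orphans = sorted((set(refs) ^ set(recs)))
    pairs = []
    for trial in common:
        ref = load_waveform(refs[trial], target_rate, id=trial)
        rec = load_waveform(recs[trial], target_rate, id=trial)
        pairs.append(align_pair(ref, rec, policy=policy, trial_id=trial))
    return pairs, orphans
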