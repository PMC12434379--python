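# Methods

This note documents the models, parameter choices and numerical
conventions behind `wavemos`, and what the synthetic benchmark does and
does not establish.

## Signal representation

All metrics operate on mel-frequency cepstral coefficients (MFCCs)
computed with one shared configuration (`FeatureConfig`), recorded in
every output for comparability:

| parameter | default | unit | rationale |
|---|---|---|---|
| working rate | 16 000 | Hz | speech-band standard; all audio resampled on load |
| frame / hop | 25 / 10 | ms | conventional wide-band speech framing, Hann window |
| mel bands | 40 | – | standard filterbank resolution at 16 kHz |
| cepstral coefficients | 13 | – | the usual 12–13 including c0 |
| STOI segment | 30 | frames | ≈300 ms, the standard short-time analysis length |
| MCD excludes c0 | yes | – | energy offset is a level, not a spectral, error |

Framing uses no centring or padding: `1 + (n − frame)//hop` frames, so
STFT and MFCC matrices of a pair are frame-for-frame comparable.
Multichannel audio is averaged to mono; no silence trimming, loudness
normalization or time-warping is applied anywhere — a reconstruction
that emits noise during silence should pay for it, and dynamic time
warping is deliberately out of scope.

Mel log energies are floored at 80 dB below the utterance's peak band
energy. An absolute floor is wrong for synthetic material: digitally
silent bands would otherwise sit at the floor constant and dominate
every cepstral distance. The relative clamp also preserves the cepstral
identity that amplitude scaling moves only c0.

## Objective metrics

* **Pearson CC** is computed from its definitional sums (and cross-
  checked against `scipy.stats.pearsonr` in tests). Constant inputs
  raise an error rather than silently returning 0 — the caller decides.
* **Segmental STOI (MFCC variant)** partitions the frame axis into
  consecutive non-overlapping segments, correlates the flattened
  sub-matrices (all coefficients jointly, not per-coefficient), and
  averages. Trailing frames short of a full segment are dropped;
  constant segments are skipped and counted; matrices shorter than one
  segment fall back to a single all-frames segment and are flagged.
  With segment length equal to the frame count the score degenerates to
  whole-utterance CC, which the tests pin.
* **MCD** is the decibel-scaled mean per-frame Euclidean cepstral
  distance, constant `(10/ln 10)·√2`. It is symmetric, non-negative and
  zero iff the compared coefficients are identical.
* **Normalized entropy** flattens the STFT magnitude matrix to a
  probability distribution and reports `H / log K` (natural logs, K =
  cell count), giving 0 for a single spectro-temporal peak and 1 for
  uniform energy. The time–frequency domain and the log-cell-count
  normalization are this package's choices: only on a [0, 1] scale is a
  fixed gating threshold of 0.7 meaningful across signal lengths.

`cc_window_sensitivity` documents the best-known CC artefact: splitting
a pair into windows of increasing length and averaging per-window CC
shows the score inflating with window size whenever the reconstruction
tracks the coarse energy envelope but not the fine structure.

## Subjective module

MOS is the arithmetic mean of all (rater × repetition) integer scores
of a trial. Cronbach's alpha treats raters as items: repetitions are
first averaged within each (trial, rater) cell — alpha should measure
between-rater agreement, not within-rater test-retest noise — then the
standard variance formula is applied across trials with unbiased (n−1)
variances. Unbalanced panels are rejected rather than imputed.
Presentation order for rating sessions is a seeded permutation with
each trial appearing a fixed number of times.

## Predicted-MOS models

The **piecewise linear scorer** carries the published default
coefficients: intercept/MCD-slope/STOI-slope of (0.101, 0.544, 0.089)
below the entropy threshold 0.7 and (0.921, −0.892, 0.223) at or above
it. Entropy exactly at the threshold takes the high regime (the
published inequalities are strict on both sides and leave equality
undefined; a documented tie-break was required). The scorer evaluates
its coefficients literally on whatever `mcd_feature` it is given; the
published coefficients are only plausible on a bounded unitless MCD, so
the raw-dB→feature transform (min–max over a training pool) is an
explicit, serialized object rather than an implicit convention.
`fit_piecewise` refits both regimes by ordinary least squares and
requires at least 3 samples and a full-rank design per regime.

The **trainable scorers** are scikit-learn's `SVR(kernel="rbf", C=1.0,
gamma="scale")` and `RandomForestRegressor(n_estimators=500)` with an
explicit seed; inputs are (STOI, MCD-feature) only — entropy is not an
input to the trainable models. Hyperparameters, seed and the fitted
MCD transform are recorded in the model and serialized with it.

## Cross-validation

Folds are grouped: leave-one-dataset-out (one fold per source study) or
leave-one-trial-out. The MCD feature transform is refitted on each
training fold, so no statistics of the held-out group leak into the
features. R² (about the aggregate truth mean) and MAE are computed
**once on the pooled out-of-sample predictions**, not averaged per
fold — on small unequal folds the two conventions genuinely differ, and
a test pins the distinction on a constructed counterexample. Folds on
which a model cannot be fitted (e.g. a piecewise entropy group left
with fewer than 3 trials) are skipped with a warning and listed in the
report rather than imputed. Fold order is fixed by sorted dataset id.

## Synthetic benchmark

The generator emulates the *shape* of a small multi-study
reconstructed-speech corpus — ten datasets of 4–8 trials, utterances of
1.3–3.4 s, a 14-rater × 3-repetition panel — and, by construction, the
two documented single-metric failure modes:

* **Utterances.** `simple`: one narrowband harmonic burst (few
  harmonics below ~1 kHz, one formant, squared-Hann energy bell), a
  monosyllabic word surrogate; normalized entropy ≈ 0.60–0.69.
  `complex`: 4–6 bursts with distinct formant patterns up to 6 kHz,
  weak broadband components and pauses; entropy ≈ 0.86–0.93. The fixed
  0.7 gate therefore separates the two classes on this corpus.
* **Degradations**, applied in order:
  * a time-constant *spectral tilt* (`spectral_offset_db`, ±half the
    value at the band edges) or a random per-band coloration
    (`eq_band_db`) — both shift every MFCC frame by a nearly constant
    offset vector: MCD rises, segmental correlations and perceived
    quality barely move;
  * *envelope-only* replacement — noise carrying the signal's average
    spectrum and temporal envelope but no harmonic fine structure: on
    simple utterances the two marginals are almost the whole signal, so
    STOI stays deceptively high while the audio is unintelligible;
  * additive *speech-shaped* noise at `noise_sd` × signal RMS. The
    noise spectrum follows the smoothed signal spectrum: a decoder's
    error lives in the bands it drives, and broadband white noise on
    spectrally sparse synthetic material saturates every cepstral
    metric at once instead of degrading them gradually.
* **Quality model.** Each trial has a latent quality q ∈ [0.15, 0.95];
  plain trials receive noise_sd = 1.2(1−q); the first dataset is the
  simple-task/envelope-pathology family, the last the tilt family.
  Ratings are rounded, clipped Gaussians around 1 + 4q with per-rater
  bias (sd = rater_sd/2) and per-rating noise (sd = rater_sd, default
  0.3). All randomness derives from one master seed via named
  substreams (audio / degradation / ratings / layout).

What passing tests on this benchmark show: the metrics, models and
validation harness behave as designed under controlled mechanisms, and
the qualitative model ordering (non-linear regressors above the
entropy-gated linear baseline under LODO) emerges from those mechanisms
— in 9 of 10 benchmark seeds at the default study size. What they do
not show: performance on real reconstructed speech. The generator's
rater panel is more consistent than a human one (alpha ≈ 0.99 at the
default rater_sd versus ≈ 0.87–0.89 reported for real panels), its
degradations are a three-mechanism caricature of vocoder error, and
absolute R²/MAE values on it are not comparable to values measured on
real corpora.

## Problem sizes and determinism

The test suite runs the statistical checks at deliberately small sizes:
20 seeds for Monte-Carlo orderings (entropy by class, STOI noise
monotonicity, window-length inflation, envelope dissociation), 100
seeds × 400 samples for piecewise coefficient recovery, and 10
benchmark seeds (~60 trials each) for the end-to-end model comparison.
Every stochastic path takes an explicit integer seed; re-running any
operation with the same inputs and configuration is bit-identical,
which the tests assert for audio synthesis, metric records, rating
simulation and model fits.

## Known limitations

* The MFCC-segment STOI variant is not canonical one-third-octave STOI
  (no band clipping); an external STOI can be swapped in by computing
  scores on its own features, but the literal segmental form governs
  everything here.
* No time alignment beyond truncate/pad: genuinely misaligned pairs
  will score poorly on all metrics (DTW is explicitly out of scope).
* The piecewise scorer's output scale is "normalized predicted
  quality"; mapping to the 1–5 MOS scale is an affine fit on training
  MOS and is only as good as that training pool.
* Entropy gating assumes the reference's complexity is the right
  regime selector; for material whose entropy sits near 0.7 the regime
  assignment is brittle by nature.
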