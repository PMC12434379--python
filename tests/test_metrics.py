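import numpy as np
import pytest
from scipy import stats

from wavemos import (ConstantInputError, DegradationSpec, MetricError,
                     MfccMatrix, Waveform, align_pair, cc_full,
                     cc_window_sensitivity, degrade, evaluate_pair, mcd,
                     mfcc, pearson_cc, stoi_mfcc, MCD_DB_CONST)


def _mat(array):
    a = np.asarray(array, dtype=float)
    return MfccMatrix(coeffs=a, n_coeffs=a.shape[1], includes_c0=True,
                      frame_len=0.025, hop=0.010)


class TestPearsonCC:
    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(50)
        assert pearson_cc(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_sign_flip_gives_minus_one(self, rng):
        x = rng.standard_normal(50)
        assert pearson_cc(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_hand_oracle_four_points(self):
        # direct evaluation: num = 6.5, denom = sqrt(5 * 8.75)
        expected = 6.5 / np.sqrt(5.0 * 8.75)
        assert pearson_cc([1, 2, 3, 4], [1, 2, 3, 5]) == pytest.approx(
            expected, abs=1e-12)

    def test_matches_scipy_on_random_data(self, rng):
        x, y = rng.standard_normal((2, 200))
        assert pearson_cc(x, y) == pytest.approx(
            stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ConstantInputError):
            pearson_cc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(MetricError):
            pearson_cc([1, 2], [1, 2, 3])


class TestCcFull:
    def test_identical_audio_is_one(self, identity_pair):
        assert cc_full(identity_pair) == pytest.approx(1.0, abs=1e-9)

    def test_decreasing_in_white_noise_level(self, complex_wave):
        means = []
        for sd in (0.002, 0.02, 0.2):
            vals = []
            for s in range(10):
                noise = np.random.default_rng(s).standard_normal(len(complex_wave))
                rec = Waveform(np.clip(complex_wave.samples + sd * noise, -1, 1),
                               complex_wave.rate)
                vals.append(cc_full(align_pair(complex_wave, rec)))
            means.append(np.mean(vals))
        assert means[0] < 1.0
        assert means[0] > means[1] > means[2]


class TestStoiMfcc:
    def test_identical_matrices_score_one(self, rng):
        m = _mat(rng.standard_normal((90, 13)))
        res = stoi_mfcc(m, m, segment_frames=30)
        assert res.score == pytest.approx(1.0, abs=1e-12)
        assert res.n_segments == 3 and res.n_skipped == 0

    def test_affine_invariance(self, rng):
        a = rng.standard_normal((60, 13))
        res = stoi_mfcc(_mat(a), _mat(2.5 * a + 3.0), segment_frames=30)
        assert res.score == pytest.approx(1.0, abs=1e-12)

    def test_two_segment_toy_equals_mean_of_segment_oracles(self, rng):
        a = rng.standard_normal((20, 4))
        b = rng.standard_normal((20, 4))
        r1 = pearson_cc(a[:10].ravel(), b[:10].ravel())
        r2 = pearson_cc(a[10:].ravel(), b[10:].ravel())
        res = stoi_mfcc(_mat(a), _mat(b), segment_frames=10)
        assert res.score == pytest.approx((r1 + r2) / 2, abs=1e-12)

    def test_short_input_falls_back_to_single_segment(self, rng):
        a = rng.standard_normal((7, 5))
        b = rng.standard_normal((7, 5))
        res = stoi_mfcc(_mat(a), _mat(b), segment_frames=30)
        assert res.single_segment_fallback
        assert res.score == pytest.approx(pearson_cc(a.ravel(), b.ravel()))

    def test_constant_segments_skipped_and_counted(self, rng):
        a = rng.standard_normal((20, 3))
        b = rng.standard_normal((20, 3))
        a[:10] = 1.0  # first segment constant on the reference side
        res = stoi_mfcc(_mat(a), _mat(b), segment_frames=10)
        assert res.n_skipped == 1
        assert res.score == pytest.approx(
            pearson_cc(a[10:].ravel(), b[10:].ravel()))

    def test_full_length_segment_degenerates_to_cc(self, rng):
        a = rng.standard_normal((40, 6))
        b = rng.standard_normal((40, 6))
        res = stoi_mfcc(_mat(a), _mat(b), segment_frames=40)
        assert res.score == pytest.approx(pearson_cc(a.ravel(), b.ravel()),
                                          abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        a = _mat(rng.standard_normal((60, 5)))
        b = _mat(rng.standard_normal((60, 5)))
        assert stoi_mfcc(a, b, 20).score == pytest.approx(
            stoi_mfcc(b, a, 20).score, abs=1e-12)


def _brute_force_mcd(ref, rec, exclude_c0=True):
    start = 1 if exclude_c0 else 0
    total = 0.0
    frames = ref.shape[0]
    for t in range(frames):
        acc = 0.0
        for m in range(start, ref.shape[1]):
            acc += (ref[t, m] - rec[t, m]) ** 2
        total += np.sqrt(acc)
    return (10.0 / np.log(10.0)) * np.sqrt(2.0) * total / frames


class TestMcd:
    def test_identical_is_zero(self, rng):
        m = _mat(rng.standard_normal((10, 13)))
        assert mcd(m, m) == 0.0

    def test_single_frame_unit_difference_equals_constant(self):
        a = _mat(np.zeros((1, 2)))
        b = _mat(np.array([[0.0, 1.0]]))
        assert mcd(a, b, exclude_c0=True) == pytest.approx(MCD_DB_CONST)

    @pytest.mark.parametrize("exclude_c0", [True, False])
    def test_matches_double_loop_oracle(self, rng, exclude_c0):
        a = rng.standard_normal((3, 5))
        b = rng.standard_normal((3, 5))
        assert mcd(_mat(a), _mat(b), exclude_c0) == pytest.approx(
            _brute_force_mcd(a, b, exclude_c0), abs=1e-10)

    def test_symmetric_and_nonnegative(self, rng):
        a = _mat(rng.standard_normal((8, 13)))
        b = _mat(rng.standard_normal((8, 13)))
        d = mcd(a, b)
        assert d >= 0
        assert d == pytest.approx(mcd(b, a), abs=1e-12)

    def test_frame_count_mismatch_rejected(self, rng):
        a = _mat(rng.standard_normal((8, 13)))
        b = _mat(rng.standard_normal((9, 13)))
        with pytest.raises(MetricError, match="frame-count"):
            mcd(a, b)


class TestDissociation:
    """Constant cepstral offsets move the distance metric, not the
    correlation metric — the core failure mode the scorer is built around."""

    def test_constant_offset_keeps_stoi_raises_mcd(self, complex_wave):
        ref = mfcc(complex_wave)
        shifted = _mat(ref.coeffs + 1.0)
        base = _mat(ref.coeffs.copy())
        assert stoi_mfcc(ref, shifted, 30).score == pytest.approx(1.0, abs=1e-9)
        assert mcd(ref, shifted) > mcd(ref, base)
        assert mcd(ref, shifted) > 0


class TestWindowSensitivity:
    def test_identical_audio_curve_is_flat_one(self, identity_pair):
        curve = cc_window_sensitivity(identity_pair, [0.2, 0.5, 1.0])
        assert len(curve) == 3
        for _, cc, _, flagged in curve:
            assert cc == pytest.approx(1.0, abs=1e-9)
            assert not flagged

    def test_window_longer_than_audio_flagged(self, identity_pair):
        curve = cc_window_sensitivity(identity_pair, [10.0])
        assert curve[0][3] is True
        assert curve[0][2] == 1


class TestEvaluatePair:
    def test_identity_metrics(self, identity_pair):
        rec = evaluate_pair(identity_pair)
        assert rec.cc == pytest.approx(1.0, abs=1e-9)
        assert rec.stoi == pytest.approx(1.0, abs=1e-9)
        assert rec.mcd_db == 0.0
        assert 0.0 <= rec.entropy <= 1.0

    def test_reevaluation_is_bit_identical(self, noisy_pair, config):
        r1 = evaluate_pair(noisy_pair, config)
        r2 = evaluate_pair(noisy_pair, config)
        assert (r1.cc, r1.stoi, r1.mcd_db, r1.entropy) == \
               (r2.cc, r2.stoi, r2.mcd_db, r2.entropy)

    def test_record_carries_config_provenance(self, noisy_pair, config):
        rec = evaluate_pair(noisy_pair, config)
        assert rec.feature_config == config
        assert rec.to_row()["config_hash"] == config.digest()
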