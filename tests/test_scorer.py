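import numpy as np
import pytest

from wavemos import (FeatureVector, McdMinMax, PiecewiseLinearScorer,
                     ScorerError, fit_model, fit_piecewise, load_model,
                     predict, predict_piecewise, save_model,
                     DEFAULT_HIGH_COEFFS, DEFAULT_LOW_COEFFS, DEFAULT_THRESHOLD)


def fv(stoi=0.0, mcd=0.0, entropy=0.5, raw=None):
    return FeatureVector(stoi=stoi, mcd_feature=mcd, entropy=entropy,
                         raw_mcd_db=raw)


class TestPiecewisePredict:
    def test_low_regime_intercept(self):
        assert predict_piecewise(PiecewiseLinearScorer(), fv(entropy=0.5)) == 0.101

    def test_high_regime_intercept(self):
        assert predict_piecewise(PiecewiseLinearScorer(), fv(entropy=0.9)) == 0.921

    def test_hand_evaluated_low_regime_point(self):
        got = predict_piecewise(PiecewiseLinearScorer(),
                                fv(stoi=1.0, mcd=1.0, entropy=0.5))
        assert got == pytest.approx(0.101 + 0.544 + 0.089)

    def test_entropy_at_threshold_uses_high_regime(self):
        got = predict_piecewise(PiecewiseLinearScorer(),
                                fv(entropy=DEFAULT_THRESHOLD))
        assert got == 0.921

    def test_linear_within_regime(self, rng):
        m = PiecewiseLinearScorer()
        a = rng.uniform(-1, 1, 2)
        b = rng.uniform(-1, 1, 2)
        delta = (predict_piecewise(m, fv(stoi=a[0] + b[0], mcd=a[1] + b[1]))
                 - predict_piecewise(m, fv(stoi=a[0], mcd=a[1])))
        slopes = np.array([m.low_coeffs[2], m.low_coeffs[1]])
        assert delta == pytest.approx(float(slopes @ b), abs=1e-12)


class TestFitPiecewise:
    def _simulate(self, rng, n=200, noise=0.0):
        model = PiecewiseLinearScorer()
        feats, ys = [], []
        for _ in range(n):
            low = rng.random() < 0.5
            f = fv(stoi=rng.uniform(-1, 1), mcd=rng.uniform(0, 1),
                   entropy=rng.uniform(0, 0.7) if low else rng.uniform(0.7, 1))
            feats.append(f)
            ys.append(predict_piecewise(model, f) + noise * rng.standard_normal())
        return feats, ys

    def test_noiseless_data_recovers_default_coefficients(self, rng):
        feats, ys = self._simulate(rng)
        fitted = fit_piecewise(feats, ys)
        np.testing.assert_allclose(fitted.low_coeffs, DEFAULT_LOW_COEFFS, atol=1e-8)
        np.testing.assert_allclose(fitted.high_coeffs, DEFAULT_HIGH_COEFFS, atol=1e-8)

    def test_single_group_data_raises_rank_error_naming_other_group(self, rng):
        feats = [fv(stoi=rng.uniform(-1, 1), mcd=rng.uniform(0, 1), entropy=0.2)
                 for _ in range(10)]
        with pytest.raises(ScorerError, match="high"):
            fit_piecewise(feats, list(np.arange(10.0)))

    def test_degenerate_design_rejected(self):
        feats = [fv(stoi=1.0, mcd=1.0, entropy=e) for e in
                 (0.1, 0.2, 0.3, 0.8, 0.85, 0.9)]
        with pytest.raises(ScorerError, match="rank"):
            fit_piecewise(feats, [1, 2, 3, 4, 5, 6])


class TestTrainableScorer:
    def _data(self, rng, n=60):
        feats = [fv(stoi=rng.uniform(0, 1), mcd=rng.uniform(0, 1),
                    entropy=rng.random()) for _ in range(n)]
        ys = [1 + 3 * f.stoi - 2 * f.mcd_feature + 0.3 * f.stoi * f.mcd_feature
              for f in feats]
        return feats, ys

    @pytest.mark.parametrize("kind", ["svr_rbf", "random_forest"])
    def test_in_sample_fit_is_strong_on_smooth_data(self, rng, kind):
        feats, ys = self._data(rng)
        model = fit_model(feats, ys, kind=kind, seed=0)
        preds = np.array([predict(model, f) for f in feats])
        ss_res = np.sum((preds - np.asarray(ys)) ** 2)
        ss_tot = np.sum((np.asarray(ys) - np.mean(ys)) ** 2)
        assert 1 - ss_res / ss_tot > 0.9

    def test_same_data_and_seed_reproduce_predictions(self, rng):
        feats, ys = self._data(rng)
        m1 = fit_model(feats, ys, kind="random_forest", seed=3)
        m2 = fit_model(feats, ys, kind="random_forest", seed=3)
        probe = fv(stoi=0.4, mcd=0.6, entropy=0.5)
        assert predict(m1, probe) == predict(m2, probe)

    def test_too_few_samples_rejected(self):
        feats = [fv(stoi=0.1 * i, mcd=0.1 * i, entropy=0.5) for i in range(3)]
        with pytest.raises(ScorerError, match="at least 5"):
            fit_model(feats, [1, 2, 3], kind="svr_rbf")

    def test_unknown_kind_rejected(self, rng):
        feats, ys = self._data(rng, n=10)
        with pytest.raises(ScorerError, match="unknown model kind"):
            fit_model(feats, ys, kind="gradient_boost")

    def test_single_unlimited_tree_memorizes_training_points(self, rng):
        feats, ys = self._data(rng, n=20)
        model = fit_model(feats, ys, kind="random_forest",
                          hyperparameters={"n_estimators": 1, "max_depth": None,
                                           "bootstrap": False}, seed=0)
        for f, y in zip(feats[:5], ys[:5]):
            assert predict(model, f) == pytest.approx(y, abs=1e-9)

    def test_forest_predictions_stay_within_target_range(self, rng):
        feats, ys = self._data(rng)
        model = fit_model(feats, ys, kind="random_forest", seed=1)
        probes = [fv(stoi=rng.uniform(-3, 3), mcd=rng.uniform(-3, 3),
                     entropy=0.5) for _ in range(50)]
        lo, hi = min(ys), max(ys)
        for p in probes:
            assert lo - 1e-9 <= predict(model, p) <= hi + 1e-9

    def test_unfitted_model_cannot_predict(self):
        from wavemos.scorer import TrainableScorer
        m = TrainableScorer(kind="svr_rbf", hyperparameters={}, seed=0)
        with pytest.raises(ScorerError, match="fitted"):
            predict(m, fv())

    def test_recorded_mcd_transform_applied_at_prediction(self, rng):
        feats = [fv(stoi=rng.uniform(0, 1), mcd=0.0, entropy=0.5,
                    raw=rng.uniform(5, 25)) for _ in range(30)]
        ys = [5 - 0.15 * f.raw_mcd_db for f in feats]
        model = fit_model(feats, ys, kind="random_forest", seed=0)
        assert model.feature_transform is not None
        assert model.feature_transform(model.feature_transform.lo) == 0.0
        assert model.feature_transform(model.feature_transform.hi) == 1.0
        # predictions use raw_mcd_db through the stored transform
        p = predict(model, fv(stoi=0.5, mcd=123.0, raw=10.0))
        assert np.isfinite(p)


class TestSerialization:
    def test_piecewise_round_trip(self, tmp_path):
        m = PiecewiseLinearScorer()
        save_model(m, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        assert back == m

    def test_trainable_round_trip_preserves_predictions(self, rng, tmp_path):
        feats = [fv(stoi=rng.uniform(0, 1), mcd=rng.uniform(0, 1),
                    entropy=0.5) for _ in range(20)]
        ys = list(rng.uniform(1, 5, 20))
        m = fit_model(feats, ys, kind="random_forest", seed=2)
        save_model(m, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        probe = fv(stoi=0.3, mcd=0.7, entropy=0.5)
        assert predict(back, probe) == predict(m, probe)


def test_minmax_transform_requires_data():
    with pytest.raises(ScorerError):
        McdMinMax.fit([])


class TestOutputCalibration:
    def test_recovers_exact_affine_relation(self, rng):
        from wavemos import fit_output_calibration
        scores = rng.uniform(0, 1, 30)
        mos = 4.0 * scores + 1.0
        scale, offset = fit_output_calibration(scores, mos)
        assert scale == pytest.approx(4.0)
        assert offset == pytest.approx(1.0)

    def test_constant_scores_rejected(self):
        from wavemos import fit_output_calibration
        with pytest.raises(ScorerError, match="constant"):
            fit_output_calibration([0.5, 0.5, 0.5], [1, 2, 3])
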