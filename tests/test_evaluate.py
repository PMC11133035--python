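"""Quality metrics and the response-prediction cross-validation protocol."""

import numpy as np
import pytest

from csrevcorr import (
    NoiseSpec,
    ResponseVector,
    Template,
    balanced_accuracy,
    generate_stimuli,
    kfold_prediction_cv,
    paired_accuracy_ttest,
    predict_responses,
    revcorr_reconstruct,
    simulate_responses,
    template_correlation,
    template_r2,
)
from conftest import simulate_session


class TestTemplateR2:
    def test_identity_scores_one(self, s50):
        assert template_r2(s50.pixels, s50) == pytest.approx(1.0)

    def test_negation_also_scores_one_with_negative_sign(self, s50):
        neg = -s50.pixels
        assert template_r2(neg, s50) == pytest.approx(1.0)
        assert template_correlation(neg, s50) == pytest.approx(-1.0)

    def test_affine_rescaling_invariance(self, s50):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2500)
        assert template_r2(3.2 * x - 7.0, s50) == pytest.approx(template_r2(x, s50))

    def test_independent_images_near_zero(self, s50):
        rng = np.random.default_rng(1)
        assert template_r2(rng.normal(size=2500), s50) < 0.01

    def test_constant_input_rejected(self, s50):
        with pytest.raises(ValueError):
            template_r2(np.full(2500, 0.3), s50)

    def test_shape_mismatch_rejected(self, s50):
        with pytest.raises(ValueError):
            template_r2(np.zeros(100), s50)


class TestPrediction:
    def test_true_template_reproduces_noiseless_responses(self, s50, noiseless_10k):
        stim, resp = noiseless_10k
        pred = predict_responses(s50, stim)
        assert np.array_equal(pred.values, resp.values)

    def test_negated_template_inverts_every_prediction(self, s50):
        stim = generate_stimuli(500, (50, 50), seed=30)
        pred = predict_responses(s50, stim)
        anti = predict_responses(1.0 - s50.pixels, stim)
        # 1 - x flips the sign of every centered pixel
        assert np.array_equal(anti.values, -pred.values)

    def test_estimate_predicts_fresh_trials_above_chance(self, s50, noiseless_10k):
        stim, resp = noiseless_10k
        rec = revcorr_reconstruct(stim, resp)
        test_stim, test_resp = simulate_session(s50, 2000, seed=31)
        acc = balanced_accuracy(predict_responses(rec, test_stim), test_resp)
        assert acc > 0.5


class TestBalancedAccuracy:
    def test_perfect_agreement(self):
        y = ResponseVector(np.array([1, -1, 1, -1], dtype=np.int8))
        assert balanced_accuracy(y, y) == 1.0

    def test_degenerate_predictor_scores_half(self):
        actual = ResponseVector(np.array([1, 1, -1, -1], dtype=np.int8))
        allyes = ResponseVector(np.ones(4, dtype=np.int8))
        assert balanced_accuracy(allyes, actual) == 0.5

    def test_hand_computed_confusion_table(self):
        # TP=3, FN=1, TN=2, FP=2 -> (3/4 + 2/4) / 2 = 0.625
        actual = np.array([1, 1, 1, 1, -1, -1, -1, -1], dtype=np.int8)
        pred = np.array([1, 1, 1, -1, 1, 1, -1, -1], dtype=np.int8)
        assert balanced_accuracy(pred, actual) == pytest.approx(0.625)

    def test_single_class_actual_names_missing_class(self):
        actual = ResponseVector(np.ones(4, dtype=np.int8))
        with pytest.raises(ValueError, match="no"):
            balanced_accuracy(actual, actual)

    def test_invariant_to_duplicating_one_class(self):
        actual = np.array([1, 1, -1, -1, -1], dtype=np.int8)
        pred = np.array([1, -1, 1, -1, -1], dtype=np.int8)
        base = balanced_accuracy(pred, actual)
        dup_actual = np.concatenate([actual, actual[actual == 1]])
        dup_pred = np.concatenate([pred, pred[actual == 1]])
        assert balanced_accuracy(dup_pred, dup_actual) == pytest.approx(base)


class TestKfoldCV:
    def test_oracle_template_scores_perfectly_noiseless(self, s50, noiseless_10k):
        stim, resp = noiseless_10k
        rep = kfold_prediction_cv(
            stim, resp, method="template", k=5,
            method_params={"template": s50}, seed=3,
        )
        assert rep.balanced_accuracy == pytest.approx(1.0)
        assert rep.folds == 5 and rep.n_eval == 10000

    def test_revcorr_pooled_accuracy_at_scale(self, noiseless_10k):
        stim, resp = noiseless_10k
        rep = kfold_prediction_cv(stim, resp, method="revcorr", k=5, seed=3)
        assert 0.75 < rep.balanced_accuracy < 1.0
        assert len(rep.per_fold) == 5

    def test_oracle_upper_bounds_estimator_noiseless(self, s50, noiseless_10k):
        stim, resp = noiseless_10k
        est = kfold_prediction_cv(stim, resp, method="revcorr", k=5, seed=3)
        oracle = kfold_prediction_cv(
            stim, resp, method="template", k=5,
            method_params={"template": s50}, seed=3,
        )
        assert oracle.balanced_accuracy >= est.balanced_accuracy

    def test_leave_one_out_on_toy(self, s20):
        stim, resp = simulate_session(s20, 20, seed=33)
        rep = kfold_prediction_cv(stim, resp, method="revcorr", k=20, seed=0)
        assert 0.0 <= rep.balanced_accuracy <= 1.0
        # single-trial folds cannot contain both classes
        assert len(rep.flagged_folds) == 20

    def test_cs_at_least_revcorr_under_heavy_noise(self, s50):
        wins = 0
        for r in range(10):
            stim, resp = simulate_session(
                s50, 10000, sigma=50.0, mechanism="additive_gaussian", seed=700 + 9 * r
            )
            cs = kfold_prediction_cv(
                stim, resp, "cs", k=5, method_params={"gamma": 64}, seed=r
            ).balanced_accuracy
            rc = kfold_prediction_cv(stim, resp, "revcorr", k=5, seed=r).balanced_accuracy
            wins += cs >= rc
        assert wins >= 8

    def test_invalid_k_rejected(self, s20):
        stim, resp = simulate_session(s20, 10, seed=1)
        with pytest.raises(ValueError):
            kfold_prediction_cv(stim, resp, k=1)
        with pytest.raises(ValueError):
            kfold_prediction_cv(stim, resp, k=11)

    def test_contiguous_folds_differ_from_shuffled(self, s20):
        stim, resp = simulate_session(s20, 200, seed=40)
        a = kfold_prediction_cv(stim, resp, "revcorr", k=4, seed=5, contiguous=True)
        b = kfold_prediction_cv(stim, resp, "revcorr", k=4, seed=5, contiguous=False)
        assert a.folds == b.folds == 4  # both run; assignments differ internally


def test_paired_ttest_wrapper_smoke():
    t, p = paired_accuracy_ttest([0.61, 0.58, 0.64, 0.59, 0.62],
                                 [0.56, 0.55, 0.60, 0.58, 0.57])
    assert t > 0 and 0 < p < 0.05
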