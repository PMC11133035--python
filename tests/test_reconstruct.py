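"""Reverse correlation and the closed-form 1-bit sparse estimator."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csrevcorr import (
    BasisSpec,
    NoiseSpec,
    ResponseVector,
    StimulusSet,
    Template,
    cs_reconstruct,
    generate_stimuli,
    revcorr_reconstruct,
    simulate_responses,
    soft_threshold_topk,
)
from csrevcorr.basis import build_basis, inverse_coefficients


def _cosine(a, b):
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


class TestRevcorr:
    def test_two_trial_hand_example(self):
        stim = StimulusSet(np.array([[1, 0], [0, 1]], dtype=np.int8))
        resp = ResponseVector(np.array([1, -1], dtype=np.int8))
        rec = revcorr_reconstruct(stim, resp, shape=(1, 2))
        # centered rows are [.5,-.5] and [-.5,.5]; mean(yes) - mean(no)
        assert np.allclose(rec.x_hat, [1.0, -1.0])

    def test_single_class_falls_back_to_phi_t_y(self):
        stim = StimulusSet(np.array([[1, 0], [1, 1]], dtype=np.int8))
        resp = ResponseVector(np.array([1, 1], dtype=np.int8))
        with pytest.warns(UserWarning, match="one sign"):
            rec = revcorr_reconstruct(stim, resp, shape=(1, 2))
        expected = (stim.matrix - 0.5).sum(axis=0) / 2  # column sums / l
        assert np.allclose(rec.x_hat, expected)

    def test_phi_t_y_form_matches_dense(self):
        rng = np.random.default_rng(0)
        stim = StimulusSet(rng.integers(0, 2, (30, 12), dtype=np.int8))
        y = rng.choice([-1, 1], 30).astype(np.int8)
        resp = ResponseVector(y)
        rec = revcorr_reconstruct(stim, resp, shape=(3, 4), form="phi_t_y")
        dense = (stim.matrix - 0.5).T.astype(float) @ y / 30
        assert np.allclose(rec.x_hat, dense)

    def test_pinv_form_matches_lstsq_oracle(self):
        rng = np.random.default_rng(1)
        stim = StimulusSet(rng.integers(0, 2, (40, 6), dtype=np.int8))
        y = rng.choice([-1, 1], 40).astype(np.int8)
        rec = revcorr_reconstruct(stim, ResponseVector(y), shape=(2, 3), form="pinv")
        oracle = np.linalg.pinv(stim.matrix - 0.5) @ y
        assert np.allclose(rec.x_hat, oracle, atol=1e-8)

    def test_response_count_mismatch(self):
        stim = StimulusSet(np.array([[1, 0]], dtype=np.int8))
        with pytest.raises(ValueError):
            revcorr_reconstruct(stim, ResponseVector(np.array([1, -1], dtype=np.int8)))


class TestThresholding:
    def test_hard_keeps_largest(self):
        out, lam = soft_threshold_topk(np.array([3.0, -1.0, 2.0]), 1, mode="hard")
        assert np.allclose(out, [3, 0, 0]) and lam == 0.0

    def test_soft_shrinks_by_next_magnitude(self):
        out, lam = soft_threshold_topk(np.array([3.0, -1.0, 2.0]), 1, mode="soft")
        assert np.allclose(out, [1, 0, 0]) and lam == 2.0

    def test_gamma_at_least_length_is_identity(self):
        v = np.array([3.0, -1.0, 2.0])
        out, lam = soft_threshold_topk(v, 3, mode="soft")
        assert np.array_equal(out, v) and lam == 0.0

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold_topk(np.zeros(4), 2)

    def test_tie_at_threshold_prefers_lower_index(self):
        out, _ = soft_threshold_topk(np.array([2.0, -2.0, 1.0]), 1, mode="hard")
        assert np.allclose(out, [2, 0, 0])

    @pytest.mark.parametrize("trial", range(20))
    def test_hard_matches_subset_enumeration_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(3, 13))
        v = np.round(rng.normal(size=n), 3)
        gamma = int(rng.integers(1, n + 1))
        got, _ = soft_threshold_topk(v, gamma, mode="hard")
        # oracle: among all gamma-subsets, max total |v|; lexicographically
        # smallest index set on ties
        best = max(
            itertools.combinations(range(n), gamma),
            key=lambda idx: (np.abs(v[list(idx)]).sum(), [-i for i in idx]),
        )
        expected = np.zeros(n)
        expected[list(best)] = v[list(best)]
        assert np.allclose(got, expected)

    @pytest.mark.parametrize("trial", range(10))
    def test_soft_lambda_matches_threshold_enumeration_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(3, 13))
        v = rng.normal(size=n)
        gamma = int(rng.integers(1, n))
        _, lam = soft_threshold_topk(v, gamma, mode="soft")
        # oracle: smallest candidate threshold leaving at most gamma nonzeros
        candidates = sorted(np.abs(v))
        feasible = [
            t for t in [0.0] + candidates
            if np.count_nonzero(np.maximum(np.abs(v) - t, 0)) <= gamma
        ]
        assert lam == pytest.approx(min(feasible))


class TestCompressiveSensing:
    def test_unit_norm_and_sparsity(self, s20):
        stim = generate_stimuli(500, (20, 20), seed=2)
        resp = simulate_responses(s20, stim, NoiseSpec(0.0), seed=3)
        for gamma in (1, 16, 399, 400):
            coeffs, rec = cs_reconstruct(stim, resp, gamma)
            assert np.linalg.norm(coeffs.s_hat) == pytest.approx(1.0, abs=1e-8)
            assert np.count_nonzero(coeffs.s_hat) <= gamma

    def test_gamma_m_hard_mode_equals_revcorr_direction(self):
        rng = np.random.default_rng(4)
        stim = StimulusSet(rng.integers(0, 2, (200, 36), dtype=np.int8))
        y = rng.choice([-1, 1], 200).astype(np.int8)
        resp = ResponseVector(y)
        _, cs = cs_reconstruct(stim, resp, 36, BasisSpec(6, 6), mode="hard")
        rc = revcorr_reconstruct(stim, resp, shape=(6, 6), form="phi_t_y")
        assert _cosine(cs.x_hat, rc.x_hat) == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("k", [5, 17, 40, 77, 101, 30, 55, 68, 90, 130])
    def test_single_basis_function_recovered_at_gamma_1(self, k):
        spec = BasisSpec(12, 12)
        col = inverse_coefficients(
            np.eye(144)[k], spec
        )
        # rescale the basis image into [0, 1]; affine maps preserve direction
        col01 = (col - col.min()) / (col.max() - col.min())
        tpl = Template(col01, (12, 12))
        stim = generate_stimuli(4000, (12, 12), seed=k)
        resp = simulate_responses(tpl, stim, NoiseSpec(0.0), seed=k + 1)
        coeffs, _ = cs_reconstruct(stim, resp, 1)
        assert np.flatnonzero(coeffs.s_hat)[0] == k

    def test_scalar_invariance_of_normalized_estimate(self):
        # dropping the 1/m factor changes nothing after zeta-normalization
        rng = np.random.default_rng(6)
        stim = StimulusSet(rng.integers(0, 2, (100, 16), dtype=np.int8))
        resp = ResponseVector(rng.choice([-1, 1], 100).astype(np.int8))
        spec = BasisSpec(4, 4)
        coeffs, _ = cs_reconstruct(stim, resp, 5, spec)
        theta = (stim.matrix - 0.5) @ build_basis(spec)
        v_unscaled = theta.T @ resp.values.astype(float)  # no 1/m
        kept, _ = soft_threshold_topk(v_unscaled, 5, mode="soft")
        manual = kept / np.linalg.norm(kept)
        assert np.allclose(coeffs.s_hat, manual, atol=1e-10)

    def test_degenerate_cancelled_responses_raise(self):
        stim = StimulusSet(np.array([[1, 0, 1, 0], [1, 0, 1, 0]], dtype=np.int8))
        resp = ResponseVector(np.array([1, -1], dtype=np.int8))
        with pytest.raises(ValueError):
            cs_reconstruct(stim, resp, 2, BasisSpec(2, 2))

    def test_gamma_validation(self, s20):
        stim = generate_stimuli(10, (20, 20), seed=0)
        resp = simulate_responses(s20, stim, NoiseSpec(0.0), seed=0)
        with pytest.raises(ValueError):
            cs_reconstruct(stim, resp, 0)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    st.lists(st.floats(-100, 100), min_size=4, max_size=12).filter(
        lambda v: any(x != 0 for x in v)
    ),
    st.integers(1, 12),
)
def test_threshold_sparsity_property(values, gamma):
    v = np.asarray(values)
    out, lam = soft_threshold_topk(v, gamma, mode="soft")
    assert np.count_nonzero(out) <= gamma
    assert lam >= 0
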