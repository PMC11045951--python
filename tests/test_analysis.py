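"""Evaluation metrics against brute-force and exact-enumeration oracles."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from spikepc import (
    RDM,
    compare_groups,
    compute_rdm,
    decode,
    nrmse,
    resample_test_sets,
    second_order_rsa,
)


class TestNRMSE:
    def test_perfect_prediction_is_zero(self):
        t = np.array([0.2, 1.4, 3.0])
        assert nrmse(t, t.copy()) == 0.0

    def test_hand_computed_example(self):
        """target [0,1] vs prediction [1,0]: RMSE 1 over range 1 -> 1."""
        assert nrmse(np.array([0.0, 1.0]), np.array([1.0, 0.0])) == pytest.approx(1.0)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        t, p = rng.random(50), rng.random(50)
        sq = sum((a - b) ** 2 for a, b in zip(t, p)) / 50
        expected = np.sqrt(sq) / (max(t) - min(t))
        assert nrmse(t, p) == pytest.approx(expected)

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError):
            nrmse(np.ones(5), np.zeros(5))

    @settings(deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5), seed=st.integers(0, 2**16))
    def test_affine_invariance(self, a, b, seed):
        """Common affine rescaling of target and prediction is a no-op."""
        rng = np.random.default_rng(seed)
        t, p = rng.random(20), rng.random(20)
        assert nrmse(a * t + b, a * p + b) == pytest.approx(nrmse(t, p), rel=1e-6)


class TestRDM:
    def test_identical_responses_give_zero_distance(self):
        r = np.random.default_rng(1).random(10)
        rdm = compute_rdm([r, r.copy(), r + 0.0])
        off = rdm.matrix[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.0, atol=1e-12)

    def test_antiranked_responses_give_two(self):
        r = np.arange(10.0)
        rdm = compute_rdm([r, r[::-1]])
        assert rdm.matrix[0, 1] == pytest.approx(2.0)

    def test_axioms_hold(self):
        rng = np.random.default_rng(2)
        rdm = compute_rdm(rng.random((6, 12)))
        M = rdm.matrix
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 0.0)
        assert np.all((M >= -1e-12) & (M <= 2 + 1e-12))

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(3)
        R = rng.random((5, 9))
        rdm = compute_rdm(R)
        for i in range(5):
            for j in range(i + 1, 5):
                ri, rj = stats.rankdata(R[i]), stats.rankdata(R[j])
                expected = 1 - np.corrcoef(ri, rj)[0, 1]
                assert rdm.matrix[i, j] == pytest.approx(expected)

    def test_constant_response_flagged_not_zeroed(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            rdm = compute_rdm([np.ones(5), np.arange(5.0), np.arange(5.0) ** 2])
        assert rdm.flagged == [0]
        assert np.isnan(rdm.matrix[0, 1])
        assert np.isfinite(rdm.matrix[1, 2])

    def test_needs_at_least_two_responses(self):
        with pytest.raises(ValueError):
            compute_rdm([np.arange(4.0)])


class TestSecondOrderRSA:
    def test_self_similarity_is_one(self):
        rdm = compute_rdm(np.random.default_rng(4).random((5, 8)))
        assert second_order_rsa(rdm, rdm) == pytest.approx(1.0)

    def test_matches_brute_force_spearman_on_triangles(self):
        rng = np.random.default_rng(5)
        a = compute_rdm(rng.random((5, 8)))
        b = compute_rdm(rng.random((5, 8)))
        iu = np.triu_indices(5, k=1)
        expected = stats.spearmanr(a.matrix[iu], b.matrix[iu]).statistic
        assert second_order_rsa(a, b) == pytest.approx(expected)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(6)
        a = compute_rdm(rng.random((6, 10)))
        b = compute_rdm(rng.random((6, 10)))
        rho = second_order_rsa(a, b)
        warped = RDM(matrix=np.exp(3 * b.matrix))  # strictly increasing map
        np.fill_diagonal(warped.matrix, 0.0)
        assert second_order_rsa(a, warped) == pytest.approx(rho)

    def test_unrelated_rdms_near_zero_in_expectation(self):
        rng = np.random.default_rng(7)
        a = compute_rdm(rng.random((8, 12)))
        rhos = [second_order_rsa(a, compute_rdm(rng.random((8, 12))))
                for _ in range(200)]
        assert abs(np.mean(rhos)) < 0.05

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        a = compute_rdm(rng.random((4, 6)))
        b = compute_rdm(rng.random((5, 6)))
        with pytest.raises(ValueError):
            second_order_rsa(a, b)


class TestDecode:
    def test_separable_classes_decode_perfectly(self):
        X0 = np.random.default_rng(9).normal(0, 0.1, (20, 3))
        X1 = X0 + np.array([5.0, 0, 0])
        X = np.vstack([X0, X1])
        y = np.array([0] * 20 + [1] * 20)
        res = decode(X, y, [(X, y)])
        assert res.accuracies[0] == 1.0

    def test_shuffled_labels_decode_at_chance(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(300, 5))
        y = rng.integers(0, 3, 300)  # labels independent of features
        sets = list(resample_test_sets(X[200:], y[200:], n_sets=30,
                                       set_size=80, seed=11))
        res = decode(X[:200], y[:200], sets)
        sd = np.sqrt((1 / 3) * (2 / 3) / 80)
        assert abs(res.mean - 1 / 3) < 3 * sd + 0.05

    def test_single_class_training_rejected(self):
        X = np.ones((5, 2))
        with pytest.raises(ValueError):
            decode(X, np.zeros(5), [(X, np.zeros(5))])

    def test_resamples_have_requested_size_and_protocol_count(self):
        X, y = np.zeros((50, 2)), np.arange(50) % 2
        sets = list(resample_test_sets(X, y, n_sets=100, set_size=40, seed=0))
        assert len(sets) == 100
        assert all(s[1].size == 40 for s in sets)


def exact_mannwhitney_p(a, b) -> float:
    """Exhaustive-enumeration two-sided Mann-Whitney p-value (no ties)."""
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)

    def u_stat(idx_a):
        aa = pooled[list(idx_a)]
        bb = np.delete(pooled, list(idx_a))
        return sum((x > y) + 0.5 * (x == y) for x in aa for y in bb)

    observed = u_stat(range(n))
    mean_u = n * m / 2
    count = total = 0
    for idx in combinations(range(n + m), n):
        u = u_stat(idx)
        if abs(u - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestCompareGroups:
    def test_identical_samples_give_p_near_one(self):
        a = np.arange(1.0, 9.0)
        res = compare_groups(a, a.copy())
        assert res.p_value > 0.9

    def test_strongly_shifted_samples_give_tiny_p(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, 100)
        res = compare_groups(a, a + 50.0)
        assert res.p_value < 0.001

    def test_matches_exact_enumeration_for_small_n(self):
        rng = np.random.default_rng(13)
        for n, m in [(5, 5), (6, 4), (7, 5)]:
            a = rng.normal(0, 1, n)
            b = rng.normal(0.8, 1, m)
            res = compare_groups(a, b)
            exact = exact_mannwhitney_p(a, b)
            # normal approximation vs exact law: agree within 0.08 absolute
            assert res.p_value == pytest.approx(exact, abs=0.08)

    def test_bootstrap_cis_bracket_the_means(self):
        rng = np.random.default_rng(14)
        a, b = rng.normal(2, 0.5, 200), rng.normal(5, 0.5, 200)
        res = compare_groups(a, b, seed=1)
        assert res.ci_a[0] < a.mean() < res.ci_a[1]
        assert res.ci_b[0] < b.mean() < res.ci_b[1]
        assert res.ci_a[1] - res.ci_a[0] < 0.5

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(np.array([]), np.array([1.0]))
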