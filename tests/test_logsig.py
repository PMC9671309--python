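"""Signature/log-signature core: closed forms, Chen algebra, Lyndon basis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moodsig.logsig import (
    brute_force_coefficient,
    logsig,
    lyndon_words,
    path_signature,
    segment_signature,
    tensor_exp,
    tensor_identity,
    tensor_log,
    tensor_mul,
    witt_dimension,
)

from conftest import random_path


class TestSegmentSignature:
    @pytest.mark.parametrize(
        "increment,p,expected_levels",
        [
            # 1-D closed form a^k / k!
            ([2.0], 3, [1.0, 2.0, 2.0, 4.0 / 3.0]),
            ([0.0, 0.0, 0.0], 3, [1.0, 0.0, 0.0, 0.0]),
        ],
    )
    def test_closed_form(self, increment, p, expected_levels):
        t = segment_signature(increment, p)
        for k, expected in enumerate(expected_levels):
            if k <= 1 or len(increment) == 1:
                np.testing.assert_allclose(
                    np.asarray(t.levels[k]).ravel()[0] if k else t.levels[0],
                    expected,
                )
            else:
                np.testing.assert_allclose(t.levels[k], expected)

    def test_diagonal_increment_level2(self):
        t = segment_signature([1.0, 1.0], 2)
        np.testing.assert_allclose(t.levels[2], 0.5)
        assert t.coefficient((1, 2)) == 0.5

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            segment_signature([1.0], 0)
        with pytest.raises(ValueError):
            segment_signature([], 2)


class TestTensorAlgebra:
    def test_identity_is_neutral(self, rng):
        B = path_signature(random_path(rng, 3), 3)
        I = tensor_identity(3, 3)
        assert tensor_mul(I, B).allclose(B, atol=1e-14)
        assert tensor_mul(B, I).allclose(B, atol=1e-14)

    def test_hand_multiplied_exponentials(self):
        # exp(e1) * exp(e2) at p=2: level 2 is e1e1/2 + e1e2 + e2e2/2
        A = segment_signature([1.0, 0.0], 2)
        B = segment_signature([0.0, 1.0], 2)
        C = tensor_mul(A, B)
        np.testing.assert_allclose(
            C.levels[2], np.array([[0.5, 1.0], [0.0, 0.5]]), atol=1e-14
        )

    def test_associativity(self, rng):
        A, B, C = (path_signature(random_path(rng, 2), 3) for _ in range(3))
        left = tensor_mul(tensor_mul(A, B), C)
        right = tensor_mul(A, tensor_mul(B, C))
        assert left.allclose(right, atol=1e-12)

    def test_mismatched_tensors_rejected(self):
        with pytest.raises(ValueError):
            tensor_mul(tensor_identity(2, 2), tensor_identity(3, 2))


class TestPathSignature:
    def test_collinear_segments_match_single_segment(self):
        two = path_signature([[0.0], [1.0], [3.0]], 3)
        one = path_signature([[0.0], [3.0]], 3)
        assert two.allclose(one, atol=1e-12)

    def test_l_shaped_path_level2(self):
        sig = path_signature([[0, 0], [1, 0], [1, 1]], 2)
        np.testing.assert_allclose(sig.levels[1], [1.0, 1.0])
        np.testing.assert_allclose(
            sig.levels[2], np.array([[0.5, 1.0], [0.0, 0.5]]), atol=1e-14
        )

    def test_level1_is_total_increment(self, rng):
        path = random_path(rng, 3)
        sig = path_signature(path, 3)
        np.testing.assert_allclose(sig.levels[1], path[-1] - path[0], atol=1e-12)

    def test_truncation_consistency(self, rng):
        path = random_path(rng, 2)
        assert path_signature(path, 3).truncate(2).allclose(
            path_signature(path, 2), atol=1e-13
        )

    def test_subdivision_invariance(self, rng):
        path = random_path(rng, 3)
        seg = int(rng.integers(0, path.shape[0] - 1))
        lam = rng.uniform(0.1, 0.9)
        mid = path[seg] + lam * (path[seg + 1] - path[seg])
        refined = np.insert(path, seg + 1, mid, axis=0)
        assert path_signature(path, 3).allclose(
            path_signature(refined, 3), atol=1e-10
        )

    def test_chen_identity(self, rng):
        X = random_path(rng, 3)
        Y = np.vstack([X[-1], random_path(rng, 3)[1:] + X[-1]])
        joined = np.vstack([X, Y[1:]])
        assert path_signature(joined, 3).allclose(
            tensor_mul(path_signature(X, 3), path_signature(Y, 3)), atol=1e-12
        )

    def test_shuffle_relation_level2(self, rng):
        sig = path_signature(random_path(rng, 3), 2)
        S1 = sig.levels[1]
        for i in range(3):
            for j in range(3):
                assert abs(
                    S1[i] * S1[j] - (sig.levels[2][i, j] + sig.levels[2][j, i])
                ) < 1e-10

    def test_degenerate_constant_path(self):
        sig = path_signature([[1.0, 2.0]] * 4, 3)
        assert sig.allclose(tensor_identity(2, 3), atol=1e-14)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            path_signature([[0.0, 0.0]], 2)


class TestTensorLog:
    def test_log_of_primitive_exponential(self):
        L = tensor_log(segment_signature([0.3, -0.7], 3))
        np.testing.assert_allclose(L.levels[1], [0.3, -0.7], atol=1e-14)
        np.testing.assert_allclose(L.levels[2], 0.0, atol=1e-14)
        np.testing.assert_allclose(L.levels[3], 0.0, atol=1e-14)

    def test_log_identity_is_zero(self):
        L = tensor_log(tensor_identity(3, 3))
        for k in range(4):
            np.testing.assert_allclose(L.levels[k], 0.0, atol=1e-15)

    def test_exp_log_round_trip(self, rng):
        sig = path_signature(random_path(rng, 3, max_segments=3), 3)
        assert tensor_exp(tensor_log(sig)).allclose(sig, atol=1e-12)

    def test_rejects_nonunital(self):
        bad = tensor_identity(2, 2)
        bad.levels[0] = np.asarray(2.0)
        with pytest.raises(ValueError):
            tensor_log(bad)


class TestLyndonBasis:
    def test_d2_p3_enumeration(self):
        assert lyndon_words(2, 3).words == (
            (1,), (2,), (1, 2), (1, 1, 2), (1, 2, 2)
        )

    @pytest.mark.parametrize("d,p,count", [(5, 3, 55), (2, 3, 5), (1, 3, 1)])
    def test_word_counts(self, d, p, count):
        assert len(lyndon_words(d, p)) == count
        assert witt_dimension(d, p) == count

    def test_dimension_law_sweep(self):
        for d in range(1, 7):
            for p in range(1, 5):
                assert len(lyndon_words(d, p)) == witt_dimension(d, p)

    def test_words_are_lyndon(self):
        for w in lyndon_words(3, 4).words:
            rotations = [w[i:] + w[:i] for i in range(1, len(w))]
            assert all(w < r for r in rotations)

    def test_ordering_by_length_then_lex(self):
        words = lyndon_words(3, 3).words
        keys = [(len(w), w) for w in words]
        assert keys == sorted(keys)


class TestLogsigCoordinates:
    def test_l_shaped_path_levy_area(self):
        ls = logsig([[0, 0], [1, 0], [1, 1]], 2)
        assert ls.basis.words == ((1,), (2,), (1, 2))
        np.testing.assert_allclose(ls.coords, [1.0, 1.0, 0.5], atol=1e-12)

    def test_single_segment_has_no_higher_coords(self, rng):
        a, b = rng.uniform(-1, 1, (2, 4))
        ls = logsig([a, b], 3)
        d = {w: c for w, c in ls.as_dict().items() if len(w) >= 2}
        assert all(abs(c) < 1e-12 for c in d.values())

    def test_path_times_reversal_is_trivial(self, rng):
        path = random_path(rng, 3)
        back_and_forth = np.vstack([path, path[::-1][1:]])
        np.testing.assert_allclose(logsig(back_and_forth, 3).coords, 0.0, atol=1e-10)

    def test_level1_coords_are_increments(self, rng):
        path = random_path(rng, 5)
        ls = logsig(path, 3)
        np.testing.assert_allclose(ls.coords[:5], path[-1] - path[0], atol=1e-12)


class TestBruteForceOracle:
    def test_level1_exact(self, rng):
        path = random_path(rng, 2)
        assert abs(
            brute_force_coefficient(path, (1,), 500) - (path[-1, 0] - path[0, 0])
        ) < 1e-12

    def test_1d_closed_form(self):
        val = brute_force_coefficient([[0.0], [1.5]], (1, 1), 5000)
        assert abs(val - 1.5**2 / 2) < 1e-3

    def test_l_path_against_chen(self):
        val = brute_force_coefficient([[0, 0], [1, 0], [1, 1]], (2, 1), 10000)
        assert abs(val) < 1e-3
        val = brute_force_coefficient([[0, 0], [1, 0], [1, 1]], (1, 2), 10000)
        assert abs(val - 1.0) < 1e-3


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.sampled_from([2, 3]))
def test_signature_matches_oracle(seed, d):
    """Chen-product signature coefficients agree with the nested-Riemann oracle."""
    rng = np.random.default_rng(seed)
    path = random_path(rng, d)
    sig = path_signature(path, 2)
    for i in range(1, d + 1):
        for j in range(1, d + 1):
            bf = brute_force_coefficient(path, (i, j), 20000)
            assert abs(sig.coefficient((i, j)) - bf) < 1e-3
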