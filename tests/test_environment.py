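"""Folding oracle, SHAPE oracle, pair extraction and reward computation."""

import itertools

import numpy as np
import pytest

from rnaqdesign.environment import (
    CANONICAL_PAIRS,
    ShapeProfile,
    ShapeThresholds,
    compute_rewards,
    extract_pairs_hungarian,
    nussinov_fold,
    oracle_shape,
    predict_structure,
    read_shape_profile,
    write_shape_profile,
)
from rnaqdesign.fixtures import random_sequence
from rnaqdesign.structures import SecondaryStructure, parse_dotbracket


def enumerate_nested_pairings(seq: str, min_loop: int = 3):
    """Independent oracle: generate every nested canonical pairing explicitly."""

    def gen(i: int, j: int):
        if j - i <= min_loop:
            yield frozenset()
            return
        yield from gen(i, j - 1)  # j unpaired
        for k in range(i, j - min_loop):
            if (seq[k], seq[j]) in CANONICAL_PAIRS:
                for left in gen(i, k - 1):
                    for inner in gen(k + 1, j - 1):
                        yield left | inner | {(k, j)}

    yield from gen(0, len(seq) - 1)


def max_pairs_exhaustive(seq: str, min_loop: int = 3) -> int:
    if not seq:
        return 0
    return max(len(p) for p in enumerate_nested_pairings(seq, min_loop))


def brute_force_assignment_value(w: np.ndarray) -> float:
    """Maximum-weight one-to-one assignment by exhaustive permutation."""
    n = w.shape[0]
    best = -np.inf
    for perm in itertools.permutations(range(n)):
        best = max(best, sum(w[i, p] for i, p in enumerate(perm)))
    return best


@pytest.mark.parametrize(
    "seq, pairs",
    [
        ("GGGAAACCC", {(0, 8), (1, 7), (2, 6)}),
        ("AAAAAA", set()),
        ("GC", set()),
        ("", set()),
    ],
)
def test_nussinov_examples(seq, pairs):
    assert nussinov_fold(seq).pairs == frozenset(pairs)


def test_nussinov_rejects_bad_input():
    with pytest.raises(ValueError, match="invalid characters"):
        nussinov_fold("ACGX")


def test_nussinov_matches_exhaustive_enumeration(rng):
    """DP pair count equals brute-force maximum over nested pairings (n <= 12)."""
    for _ in range(60):
        n = int(rng.integers(2, 13))
        seq = random_sequence(n, rng)
        assert len(nussinov_fold(seq).pairs) == max_pairs_exhaustive(seq)


def test_nussinov_respects_structure_invariants(rng):
    for _ in range(30):
        seq = random_sequence(int(rng.integers(5, 40)), rng)
        s = nussinov_fold(seq)
        for i, j in s.pairs:
            assert (seq[i], seq[j]) in CANONICAL_PAIRS
            assert j - i - 1 >= 3


def test_nussinov_traceback_deterministic(rng):
    seq = random_sequence(30, rng)
    assert nussinov_fold(seq) == nussinov_fold(seq)


def test_oracle_shape_rule():
    s = parse_dotbracket("(((...)))")
    prof = oracle_shape("GGGAAACCC", s, noise_sd=0.0)
    assert np.allclose(prof.reactivities, [0.1, 0.1, 0.1, 0.9, 0.9, 0.9, 0.1, 0.1, 0.1])
    unpaired = oracle_shape("AAAA", SecondaryStructure(4), noise_sd=0.0)
    assert np.allclose(unpaired.reactivities, 0.9)


def test_oracle_shape_seeded_noise():
    s = parse_dotbracket("(((...)))")
    a = oracle_shape("GGGAAACCC", s, noise_sd=0.2, seed=5)
    b = oracle_shape("GGGAAACCC", s, noise_sd=0.2, seed=5)
    c = oracle_shape("GGGAAACCC", s, noise_sd=0.2, seed=6)
    assert np.array_equal(a.reactivities, b.reactivities)
    assert not np.array_equal(a.reactivities, c.reactivities)
    assert np.all(a.reactivities >= 0)
    with pytest.raises(ValueError, match="length"):
        oracle_shape("GGG", s)


class TestHungarianExtraction:
    def test_single_strong_entry(self):
        prob = np.full((8, 8), 0.01)
        prob[2, 7] = prob[7, 2] = 0.95
        assert extract_pairs_hungarian(prob, 0.5).pairs == {(2, 7)}

    def test_all_weak(self):
        assert extract_pairs_hungarian(np.full((8, 8), 0.01), 0.5).pairs == frozenset()

    def test_two_disjoint_entries(self):
        prob = np.full((8, 8), 0.01)
        prob[0, 5] = prob[5, 0] = 0.9
        prob[1, 4] = prob[4, 1] = 0.8
        # (1,4) spans exactly min_loop; use min_loop=2 so both are admissible
        assert extract_pairs_hungarian(prob, 0.5, min_loop=2).pairs == {(0, 5), (1, 4)}

    def test_min_loop_band_zeroed(self):
        prob = np.zeros((8, 8))
        prob[0, 3] = prob[3, 0] = 0.99  # within the default band
        assert extract_pairs_hungarian(prob, 0.5).pairs == frozenset()

    def test_rejects_asymmetric(self):
        prob = np.zeros((6, 6))
        prob[0, 5] = 0.9
        with pytest.raises(ValueError, match="symmetric"):
            extract_pairs_hungarian(prob, 0.5)

    def test_matches_brute_force_on_random_matrices(self, rng):
        """Assignment value matches exhaustive permutation search (100 cases)."""
        for _ in range(100):
            w = rng.random((8, 8))
            w = (w + w.T) / 2
            band = np.abs(np.subtract.outer(np.arange(8), np.arange(8))) <= 3
            masked = w.copy()
            masked[band] = 0.0
            result = extract_pairs_hungarian(w, threshold=0.5)
            best = brute_force_assignment_value(masked)
            # our mutual pairs must come from an optimal assignment
            from scipy.optimize import linear_sum_assignment

            rows, cols = linear_sum_assignment(masked, maximize=True)
            assert masked[rows, cols].sum() == pytest.approx(best, abs=1e-9)
            for i, j in result.pairs:
                assert masked[i, j] >= 0.5


def test_shape_constraint_examples():
    from rnaqdesign.environment import shape_constraint_satisfied

    thr = ShapeThresholds(unpaired_min=0.5, paired_max=0.25)
    assert shape_constraint_satisfied(False, 0.6, thr)
    assert not shape_constraint_satisfied(True, 0.3, thr)
    assert shape_constraint_satisfied(True, 0.2, thr)
    assert not shape_constraint_satisfied(False, 0.5, thr)  # strict inequality
    with pytest.raises(ValueError):
        ShapeThresholds(unpaired_min=0.2, paired_max=0.25)


class TestComputeRewards:
    target = parse_dotbracket("(((...)))")

    def test_perfect_match_all_constraints_met(self):
        shape = ShapeProfile(np.array([0.1] * 3 + [0.9] * 3 + [0.1] * 3))
        r = compute_rewards(self.target, self.target, shape)
        assert np.array_equal(r, np.ones(9))

    def test_shape_violation_zeroes_one_position(self):
        vals = np.array([0.1] * 3 + [0.9] * 3 + [0.1] * 3)
        vals[0] = 0.4  # paired position above paired_max
        r = compute_rewards(self.target, self.target, ShapeProfile(vals))
        assert r[0] == 0.0 and r[1:].sum() == 8

    def test_wrong_partner_is_zero_regardless_of_shape(self):
        predicted = parse_dotbracket("((.(..).))")
        target = parse_dotbracket("(((....)))")
        r = compute_rewards(predicted, target)
        # positions 0, 9 agree; the rest pair differently or differ in status
        status_p = predicted.pairing_status()
        status_t = target.pairing_status()
        expected = [1.0 if status_p[t] == status_t[t] else 0.0 for t in range(10)]
        assert np.array_equal(r, expected)

    def test_reward_counts_matching_positions(self, rng):
        """Structure-only reward sum = L - (# positions with differing status)."""
        from rnaqdesign.fixtures import random_structure

        for _ in range(20):
            L = int(rng.integers(5, 30))
            a = random_structure(L, rng)
            b = random_structure(L, rng)
            diff = sum(
                1 for x, y in zip(a.pairing_status(), b.pairing_status()) if x != y
            )
            assert compute_rewards(a, b).sum() == L - diff
            assert np.array_equal(compute_rewards(a, b), compute_rewards(b, a))

    def test_environment_self_consistency(self, rng, predictor):
        """A sequence earns all-ones reward against its own fold."""
        for _ in range(10):
            seq = random_sequence(int(rng.integers(8, 30)), rng)
            target = predictor.fold(seq)
            r = compute_rewards(predictor.fold(seq), target)
            assert np.array_equal(r, np.ones(len(seq)))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_rewards(SecondaryStructure(5), SecondaryStructure(6))


def test_predict_structure_dispatch(predictor):
    s = predict_structure(predictor, "GGGAAACCC")
    assert s.pairs == {(0, 8), (1, 7), (2, 6)}

    class MatrixPredictor:
        def fold(self, sequence):
            n = len(sequence)
            prob = np.zeros((n, n))
            prob[0, n - 1] = prob[n - 1, 0] = 0.9
            return prob

        def shape(self, sequence):
            return ShapeProfile(np.full(len(sequence), 0.5))

    s2 = predict_structure(MatrixPredictor(), "GGGAAACCC")
    assert s2.pairs == {(0, 8)}


def test_shape_profile_roundtrip(tmp_path):
    prof = ShapeProfile(np.array([0.1, 0.9, 0.45]))
    path = tmp_path / "shape.txt"
    write_shape_profile(str(path), prof)
    back = read_shape_profile(str(path))
    assert np.allclose(back.reactivities, prof.reactivities)
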