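"""GED/MORD against brute-force oracles, trimming, and transforms."""

import numpy as np
import pytest

from morphloss import (
    MISSING,
    CharacterMatrix,
    ged_wills,
    mord,
    per_character_dissimilarity,
    sqrt_transform,
    trim_incomparable,
)
from morphloss.distance import INCOMPARABLE

from conftest import random_matrix


def oracle_gower(data: np.ndarray) -> np.ndarray:
    """Double-loop Gower dissimilarity (= MORD for binary data)."""
    n = data.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            comp = diff = 0
            for k in range(data.shape[1]):
                a, b = data[i, k], data[j, k]
                if a == MISSING or b == MISSING:
                    continue
                comp += 1
                diff += int(a != b)
            D[i, j] = diff / comp if i != j else 0.0
    return D


def oracle_ged_wills(data: np.ndarray) -> np.ndarray:
    """Brute-force Wills GED: pooled mean substitution, then Euclidean norm."""
    n, p = data.shape
    dissims = []
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(p):
                a, b = data[i, k], data[j, k]
                if a != MISSING and b != MISSING:
                    dissims.append(float(a != b))
    d_bar = float(np.mean(dissims))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            total = 0.0
            for k in range(p):
                a, b = data[i, k], data[j, k]
                delta = float(a != b) if (a != MISSING and b != MISSING) else d_bar
                total += delta**2
            D[i, j] = np.sqrt(total)
    return D


class TestPerCharacterDissimilarity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(0, 0, 0), (1, 1, 0), (0, 1, 1), (1, 0, 1)],
    )
    def test_scored_pairs(self, a, b, expected):
        assert per_character_dissimilarity(a, b) == expected

    @pytest.mark.parametrize("a,b", [(1, MISSING), (MISSING, 0), (MISSING, MISSING)])
    def test_missing_is_incomparable(self, a, b):
        assert per_character_dissimilarity(a, b) is INCOMPARABLE

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            per_character_dissimilarity(2, 0)


class TestMord:
    def test_hand_worked_example(self):
        data = np.array([[0, 1, MISSING, 1, 0], [0, 0, 1, MISSING, 1]])
        dm = mord(CharacterMatrix(taxa=["A", "B"], data=data))
        assert dm.D[0, 1] == pytest.approx(2 / 3)
        assert dm.comparable_counts[0, 1] == 3

    def test_identical_and_opposite_rows(self):
        data = np.array([[0, 1, 0], [0, 1, 0], [1, 0, 1]])
        dm = mord(CharacterMatrix(taxa=list("ABC"), data=data))
        assert dm.D[0, 1] == 0.0
        assert dm.D[0, 2] == 1.0

    def test_zero_comparable_pair_raises_with_pair_names(self):
        data = np.array([[0, MISSING], [MISSING, 1]])
        with pytest.raises(ValueError, match="A.*B"):
            mord(CharacterMatrix(taxa=["A", "B"], data=data))

    def test_matches_double_loop_oracle_on_random_matrices(self):
        rng = np.random.default_rng(17)
        for case in range(200):
            n = int(rng.integers(3, 9))
            p = int(rng.integers(2, 13))
            while True:
                m = random_matrix(rng, n, p, p_missing=float(rng.uniform(0, 0.4)))
                comp = (m.scored.astype(int) @ m.scored.astype(int).T)
                if (comp + np.eye(n) * 99 > 0).all():
                    break
            assert np.allclose(mord(m).D, oracle_gower(m.data), atol=1e-12)

    def test_complete_matrix_equals_hamming_fraction(self):
        rng = np.random.default_rng(23)
        m = random_matrix(rng, 6, 11)
        dm = mord(m)
        hamming = (m.data[:, None, :] != m.data[None, :, :]).sum(axis=2)
        assert np.allclose(dm.D, hamming / 11, atol=1e-12)

    def test_expected_mord_invariant_under_random_column_deletion(self):
        """For a fixed pair, the expected MORD over random column subsets
        equals the complete-data MORD (unbiasedness under random loss)."""
        rng = np.random.default_rng(31)
        full = random_matrix(rng, 2, 40)
        true = mord(full).D[0, 1]
        n_draws = 4000
        vals = np.empty(n_draws)
        for d in range(n_draws):
            keep = rng.random(40) < 0.5
            if not keep.any():
                keep[rng.integers(40)] = True
            sub = CharacterMatrix(taxa=["A", "B"], data=full.data[:, keep])
            vals[d] = mord(sub).D[0, 1]
        se = vals.std(ddof=1) / np.sqrt(n_draws)
        assert abs(vals.mean() - true) < 3 * se


class TestGedWills:
    def test_complete_matrix_is_sqrt_hamming(self):
        rng = np.random.default_rng(29)
        m = random_matrix(rng, 7, 12)
        dm = ged_wills(m)
        hamming = (m.data[:, None, :] != m.data[None, :, :]).sum(axis=2)
        assert np.allclose(dm.D, np.sqrt(hamming), atol=1e-12)

    def test_fully_incomparable_pair_gets_mean_substitution_everywhere(self):
        data = np.array(
            [
                [0, 1, MISSING, MISSING],
                [MISSING, MISSING, 1, 0],
                [0, 1, 1, 0],
            ]
        )
        m = CharacterMatrix(taxa=list("ABC"), data=data)
        dm = ged_wills(m)
        assert dm.D[0, 1] == pytest.approx(dm.mean_dissimilarity * np.sqrt(4))

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(41)
        for case in range(200):
            n = int(rng.integers(3, 9))
            p = int(rng.integers(2, 13))
            m = random_matrix(rng, n, p, p_missing=float(rng.uniform(0, 0.4)))
            if not (m.scored.any()):
                continue
            assert np.allclose(ged_wills(m).D, oracle_ged_wills(m.data), atol=1e-12)

    def test_bounded_by_sqrt_n_characters(self):
        rng = np.random.default_rng(43)
        for _ in range(20):
            m = random_matrix(rng, 6, 10, p_missing=0.3)
            assert ged_wills(m).D.max() <= np.sqrt(10) + 1e-12

    def test_nothing_calculable_raises(self):
        data = np.array([[0, MISSING], [MISSING, 1]])
        # every pairwise comparison hits a MISSING cell
        with pytest.raises(ValueError, match="calculable"):
            ged_wills(CharacterMatrix(taxa=["A", "B"], data=data))


class TestTrim:
    def test_complete_matrix_untouched(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, 5, 8)
        trimmed, removed = trim_incomparable(m)
        assert removed == []
        assert trimmed.taxa == m.taxa

    def test_removes_most_incomplete_offender_only(self):
        data = np.array(
            [
                [0, 1, 0, MISSING, MISSING],
                [1, 1, 1, MISSING, MISSING],
                [MISSING, MISSING, MISSING, 1, MISSING],
            ]
        )
        m = CharacterMatrix(taxa=list("ABC"), data=data)
        trimmed, removed = trim_incomparable(m)
        assert removed == ["C"]
        assert trimmed.taxa == ["A", "B"]
        mord(trimmed)  # all pairs now comparable

    def test_equal_missingness_tie_removes_lexicographically_first(self):
        data = np.array(
            [
                [0, MISSING, 1, MISSING],
                [MISSING, 1, MISSING, 0],
                [0, 1, 1, 0],
                [0, 1, 1, 0],
            ]
        )
        m = CharacterMatrix(taxa=["b_tax", "a_tax", "c_tax", "d_tax"], data=data)
        trimmed, removed = trim_incomparable(m)
        assert removed == ["a_tax"]

    def test_raises_when_fewer_than_two_taxa_would_remain(self):
        data = np.array([[0, MISSING], [MISSING, 1]])
        with pytest.raises(ValueError, match="fewer than two"):
            trim_incomparable(CharacterMatrix(taxa=["A", "B"], data=data))


class TestSqrtTransform:
    def test_elementwise_square_root(self):
        data = np.array([[0, 0, 1, 1], [0, 1, 1, 0]])
        dm = mord(CharacterMatrix(taxa=["A", "B"], data=data))
        assert dm.D[0, 1] == pytest.approx(0.5)
        out = sqrt_transform(dm)
        assert out.D[0, 1] == pytest.approx(np.sqrt(0.5))
        assert out.metric == "sqrt_mord"

    def test_rejects_non_mord_input(self):
        rng = np.random.default_rng(7)
        dm = ged_wills(random_matrix(rng, 4, 6))
        with pytest.raises(ValueError, match="MORD"):
            sqrt_transform(dm)

    def test_preserves_bounds(self):
        rng = np.random.default_rng(11)
        m = random_matrix(rng, 6, 9, p_missing=0.2)
        out = sqrt_transform(mord(m))
        assert ((out.D >= 0) & (out.D <= 1)).all()
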