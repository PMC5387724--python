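"""MI core: weights, pair frequencies, MI, APC, Z-scores, cMI, conservation.

The key correctness anchor is a deliberately naive brute-force oracle
(`oracle_mi`) that recounts weighted pair frequencies with explicit Python
loops and sums the MI terms over all 400 residue pairs; the vectorised
pipeline must agree with it to 1e-10 on small alignments.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from udgcoev.coevolution import (
    DegenerateAlignmentError,
    apc_correction,
    conservation,
    cumulative_mi,
    encode_alignment,
    mutual_information,
    pair_frequencies,
    sequence_weights,
    significant_pairs,
    zscore_normalize,
    CoevolutionModel,
    N_AA,
)
from udgcoev.curation import AMINO_ACIDS
from conftest import make_alignment


# ---------------------------------------------------------------- oracle --

def oracle_pair_table(rows, weights, i, j, lam):
    """Direct weighted counting of the joint distribution of columns i, j."""
    counts = {}
    total = 0.0
    for row, w in zip(rows, weights):
        a, b = row[i], row[j]
        if a in AMINO_ACIDS and b in AMINO_ACIDS:
            counts[(a, b)] = counts.get((a, b), 0.0) + w
            total += w
    if lam + total == 0:
        return None, total
    table = {}
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            table[(a, b)] = (lam / 400 + counts.get((a, b), 0.0)) / (lam + total)
    return table, total


def oracle_mi(rows, weights, i, j, lam):
    """MI(i, j) by direct summation over all 400 residue pairs."""
    table, total = oracle_pair_table(rows, weights, i, j, lam)
    if table is None or (lam == 0 and total == 0):
        return float("nan")
    fa = {a: sum(table[(a, b)] for b in AMINO_ACIDS) for a in AMINO_ACIDS}
    fb = {b: sum(table[(a, b)] for a in AMINO_ACIDS) for b in AMINO_ACIDS}
    mi = 0.0
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            f = table[(a, b)]
            if f > 0 and fa[a] > 0 and fb[b] > 0:
                mi += f * math.log(f / (fa[a] * fb[b]))
    return mi


def oracle_apc(mi):
    """APC by explicit per-entry arithmetic."""
    L = mi.shape[0]
    col_mean = [
        sum(mi[i, k] for k in range(L) if k != i) / (L - 1) for i in range(L)
    ]
    grand = sum(
        mi[i, j] for i in range(L) for j in range(L) if i != j
    ) / (L * (L - 1))
    out = np.zeros_like(mi)
    for i in range(L):
        for j in range(L):
            if i != j:
                out[i, j] = mi[i, j] - col_mean[i] * col_mean[j] / grand
    return out


# --------------------------------------------------------------- weights --

class TestSequenceWeights:
    def test_all_dissimilar_rows_weight_one(self):
        aln = make_alignment(["AAAAAAAAAA", "CCCCCCCCCC", "DDDDDDDDDD"])
        assert np.allclose(sequence_weights(aln), 1.0)

    def test_identical_rows_share_weight(self):
        aln = make_alignment(["ACDEFGHIKL"] * 4)
        assert np.allclose(sequence_weights(aln), 0.25)

    def test_cluster_sizes_3_2_1_from_brute_force(self):
        rows = [
            "AAAAAAAAAA",       # cluster of 3: mutually >= 70% identical
            "AAAAAAACCC",
            "AAAAAAACCA",
            "DDDDDDDDDD",       # cluster of 2
            "DDDDDDDEEE",
            "WYWYWYWYWY",       # singleton
        ]
        aln = make_alignment(rows)
        # brute-force identity matrix confirms the intended clusters at 0.62
        ident = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                matches = sum(a == b for a, b in zip(rows[i], rows[j]))
                ident[i, j] = matches / 10
        groups = [(0, 1, 2), (3, 4), (5,)]
        for g in groups:
            for i in g:
                for j in g:
                    if i != j:
                        assert ident[i, j] >= 0.62
        for ga in groups:
            for gb in groups:
                if ga is not gb:
                    assert all(ident[i, j] < 0.62 for i in ga for j in gb)
        w = sequence_weights(aln, 0.62)
        assert np.allclose(w, [1 / 3, 1 / 3, 1 / 3, 1 / 2, 1 / 2, 1.0])
        assert w.sum() == pytest.approx(3.0)


# ----------------------------------------------------- pair frequencies --

class TestPairFrequencies:
    def test_identical_rows_concentrate_mass(self):
        aln = make_alignment(["AC", "AC"])
        fm = pair_frequencies(aln, np.ones(2), 0.0)
        a, c = AMINO_ACIDS.index("A"), AMINO_ACIDS.index("C")
        assert fm.pair_table(0, 1)[a, c] == pytest.approx(1.0)

    def test_even_split(self):
        aln = make_alignment(["AC", "AD"])
        fm = pair_frequencies(aln, np.ones(2), 0.0)
        tbl = fm.pair_table(0, 1)
        a = AMINO_ACIDS.index("A")
        assert tbl[a, AMINO_ACIDS.index("C")] == pytest.approx(0.5)
        assert tbl[a, AMINO_ACIDS.index("D")] == pytest.approx(0.5)

    def test_matches_brute_force_with_pseudocount(self, toy_alignment):
        weights = np.array([1.0, 0.5, 1.0, 0.25])
        fm = pair_frequencies(toy_alignment, weights, 0.05)
        rows = [r.residues for r in toy_alignment.records]
        for i in range(4):
            for j in range(4):
                table, _ = oracle_pair_table(rows, weights, i, j, 0.05)
                expected = np.array(
                    [[table[(a, b)] for b in AMINO_ACIDS] for a in AMINO_ACIDS]
                )
                np.testing.assert_allclose(fm.pair_table(i, j), expected, atol=1e-12)

    def test_tables_sum_to_one_and_marginalize(self, toy_alignment):
        fm = pair_frequencies(toy_alignment, np.ones(4), 0.0)
        tbl = fm.pair_table(0, 2)
        assert tbl.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(tbl.sum(axis=1), fm.marginals[0], atol=1e-12)

    def test_zero_eligible_pair_flagged(self):
        aln = make_alignment(["A-", "-C"])
        fm = pair_frequencies(aln, np.ones(2), 0.0)
        assert fm.flagged_pairs[0, 1]
        assert not fm.flagged_pairs[0, 0]


# ------------------------------------------------------------------- MI --

class TestMutualInformation:
    def test_independent_columns_zero(self):
        # joint exactly equals product of marginals: all 4 combinations once
        aln = make_alignment(["AC", "AD", "CC", "CD"])
        fm = pair_frequencies(aln, np.ones(4), 0.0)
        assert mutual_information(fm)[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_perfectly_coupled_binary_pair_is_ln2(self):
        aln = make_alignment(["AC", "AC", "CD", "CD"])
        fm = pair_frequencies(aln, np.ones(4), 0.0)
        assert mutual_information(fm)[0, 1] == pytest.approx(math.log(2), abs=1e-12)

    def test_diagonal_is_column_entropy_at_zero_pseudocount(self):
        aln = make_alignment(["AX", "CX", "CX", "DX"])
        fm = pair_frequencies(aln, np.ones(4), 0.0)
        mi = mutual_information(fm)
        h = -(0.25 * math.log(0.25) * 2 + 0.5 * math.log(0.5))
        assert mi[0, 0] == pytest.approx(h, abs=1e-12)

    def test_matches_brute_force_oracle_with_pseudocount(self, toy_alignment):
        weights = np.array([1.0, 0.5, 1.0, 0.25])
        fm = pair_frequencies(toy_alignment, weights, 0.05)
        mi = mutual_information(fm)
        rows = [r.residues for r in toy_alignment.records]
        for i in range(4):
            for j in range(4):
                assert mi[i, j] == pytest.approx(
                    oracle_mi(rows, weights, i, j, 0.05), abs=1e-10
                )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_oracle_equivalence_on_random_small_alignments(self, seed):
        """Pipeline vs brute force to 1e-10 on alignments up to 10x10."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        L = int(rng.integers(2, 11))
        alphabet = "ACDEG-"
        rows = [
            "".join(rng.choice(list(alphabet), size=L)) for _ in range(n)
        ]
        weights = rng.uniform(0.1, 1.0, size=n)
        lam = float(rng.choice([0.0, 0.05, 0.5]))
        aln = make_alignment(rows)
        fm = pair_frequencies(aln, weights, lam)
        mi = mutual_information(fm)
        for i in range(L):
            for j in range(L):
                expected = oracle_mi(rows, weights, i, j, lam)
                if math.isnan(expected):
                    assert np.isnan(mi[i, j])
                else:
                    assert mi[i, j] == pytest.approx(expected, abs=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_symmetry_and_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        rows = ["".join(rng.choice(list("ACDEFGHIKL"), size=8)) for _ in range(12)]
        fm = pair_frequencies(make_alignment(rows), np.ones(12), 0.05)
        mi = mutual_information(fm)
        np.testing.assert_allclose(mi, mi.T, atol=1e-12)
        assert np.all(mi >= 0)


# ------------------------------------------------------------------ APC --

class TestApcCorrection:
    def test_constant_off_diagonal_matrix_zeroed(self):
        m = np.full((5, 5), 0.7)
        np.fill_diagonal(m, 0.0)
        np.testing.assert_allclose(apc_correction(m), 0.0, atol=1e-12)

    def test_preserves_symmetry(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(0, 1, size=(6, 6))
        m = (m + m.T) / 2
        mip = apc_correction(m)
        np.testing.assert_allclose(mip, mip.T, atol=1e-12)

    def test_hand_built_4x4_matches_manual_arithmetic(self):
        m = np.array(
            [
                [0.0, 0.4, 0.1, 0.2],
                [0.4, 0.0, 0.3, 0.5],
                [0.1, 0.3, 0.0, 0.6],
                [0.2, 0.5, 0.6, 0.0],
            ]
        )
        mip = apc_correction(m)
        expected = oracle_apc(m)
        np.testing.assert_allclose(mip, expected, atol=1e-12)

    def test_mean_reduction_on_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            m = rng.uniform(0, 1, size=(8, 8))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0.0)
            off = ~np.eye(8, dtype=bool)
            assert apc_correction(m)[off].mean() <= m[off].mean() + 1e-12

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValueError):
            apc_correction(np.zeros((2, 2)))


# ------------------------------------------------------------------- Z --

class TestZScores:
    def test_deterministic_given_seed(self, toy_alignment):
        w = np.ones(4)
        z1 = zscore_normalize(toy_alignment, w, 0.05, n_permutations=20, seed=7)
        z2 = zscore_normalize(toy_alignment, w, 0.05, n_permutations=20, seed=7)
        np.testing.assert_array_equal(z1, z2)

    def test_different_seeds_differ(self, toy_alignment):
        w = np.ones(4)
        z1 = zscore_normalize(toy_alignment, w, 0.05, n_permutations=20, seed=1)
        z2 = zscore_normalize(toy_alignment, w, 0.05, n_permutations=20, seed=2)
        assert not np.array_equal(z1, z2)

    def test_degenerate_alignment_rejected(self):
        aln = make_alignment(["AAA"] * 5)
        with pytest.raises(DegenerateAlignmentError):
            zscore_normalize(aln, np.ones(5), 0.0, n_permutations=5, seed=0)

    def test_planted_pair_attains_max_z(self):
        from udgcoev.simulate import CoupledAlignmentSpec, generate_coupled_alignment

        aln = generate_coupled_alignment(
            CoupledAlignmentSpec(n_rows=200, n_columns=30, coupled_pairs=[(3, 17, 1.0)], seed=11)
        )
        res = CoevolutionModel(aln).fit(n_permutations=50, seed=11)
        assert res.top_pair()[:2] == (3, 17)


# --------------------------------------------------- pairs, cMI, conservation --

class TestSignificantPairs:
    def test_empty_below_threshold(self):
        z = np.zeros((4, 4))
        assert significant_pairs(z, 6.5) == []

    def test_single_pair(self):
        z = np.zeros((4, 4))
        z[1, 3] = z[3, 1] = 7.0
        assert significant_pairs(z, 6.5) == [(1, 3, 7.0)]

    def test_ties_ordered_lexicographically(self):
        z = np.zeros((5, 5))
        for i, j in [(0, 4), (1, 2), (0, 2)]:
            z[i, j] = z[j, i] = 8.0
        assert [(p[0], p[1]) for p in significant_pairs(z, 6.5)] == [
            (0, 2), (0, 4), (1, 2)
        ]


class TestCumulativeMI:
    def test_no_significant_pairs_all_zero(self):
        np.testing.assert_array_equal(cumulative_mi(np.zeros((4, 4))), 0.0)

    def test_single_pair_contributes_to_both_ends(self):
        z = np.zeros((4, 4))
        z[0, 2] = z[2, 0] = 8.0
        cmi = cumulative_mi(z, 6.5)
        np.testing.assert_allclose(cmi, [8.0, 0.0, 8.0, 0.0])

    def test_three_pairs_manual_sums(self):
        z = np.zeros((4, 4))
        for i, j, v in [(0, 1, 7.0), (0, 2, 8.0), (2, 3, 9.0)]:
            z[i, j] = z[j, i] = v
        np.testing.assert_allclose(cumulative_mi(z, 6.5), [15.0, 7.0, 17.0, 9.0])


class TestConservation:
    def test_background_distributed_column_scores_zero(self):
        # 20 rows, one of each residue, uniform background
        aln = make_alignment([aa * 2 for aa in AMINO_ACIDS])
        cons = conservation(aln, np.ones(20))
        np.testing.assert_allclose(cons, 0.0, atol=1e-12)

    def test_fully_conserved_column_is_ln20(self):
        aln = make_alignment(["AA"] * 5)
        cons = conservation(aln, np.ones(5))
        assert cons[0] == pytest.approx(math.log(20), abs=1e-12)

    def test_two_state_column_is_ln10(self):
        aln = make_alignment(["A", "C"])
        cons = conservation(aln, np.ones(2))
        assert cons[0] == pytest.approx(math.log(10), abs=1e-12)

    def test_zero_background_where_observed_rejected(self):
        aln = make_alignment(["A"])
        bg = np.zeros(N_AA)
        bg[1:] = 1.0 / 19
        with pytest.raises(ValueError):
            conservation(aln, np.ones(1), bg)
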