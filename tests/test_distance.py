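"""Weighted array edit distance: forced costs, oracle agreement, invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from repeatarray import (
    LengthError,
    RepeatDistanceParams,
    array_edit_alignment,
    array_edit_distance,
    brute_force_distance,
    distance_matrix,
    unit_hamming,
)
from repeatarray.distance import read_phylip

from conftest import mutate

RAW = RepeatDistanceParams(masked=False)


@pytest.fixture(scope="module")
def abc(anc_unit):
    """Units A, B, C pairwise >= 4 mismatches apart, plus helpers."""
    A = anc_unit
    B = mutate(anc_unit, (0, "G"), (1, "C"), (2, "T"), (3, "A"))
    C = mutate(anc_unit, (60, "C"), (61, "A"), (63, "C"), (64, "G"))
    return A, B, C


class TestUnitHamming:
    def test_counts_mismatches(self, anc_unit):
        assert unit_hamming(anc_unit, anc_unit) == 0
        assert unit_hamming(anc_unit, mutate(anc_unit, (0, "G"), (5, "C"))) == 2

    def test_masked_codon_difference_invisible(self, anc_unit):
        u = mutate(anc_unit, (46, "T"))  # inside contact codon 16
        from repeatarray import partition_allele

        a, b = partition_allele(anc_unit)[0], partition_allele(u)[0]
        assert unit_hamming(a, b, masked=False) == 1
        assert unit_hamming(a, b, masked=True) == 0

    def test_n_mismatches_everything(self):
        assert unit_hamming("ANG", "ANG") == 1
        assert unit_hamming("AAG", "ANG") == 1

    def test_unequal_lengths_rejected(self):
        with pytest.raises(LengthError):
            unit_hamming("AAA", "AAAA")


class TestForcedCosts:
    """The three canonical event costs under the published weights."""

    def test_single_substitution_costs_w_mut(self, abc):
        A, B, C = abc
        B1 = mutate(B, (40, "A") if B[40] != "A" else (40, "T"))
        assert array_edit_distance([A, B, C], [A, B1, C], RAW) == pytest.approx(1.0)

    def test_adjacent_duplicate_insertion_costs_w_slippage(self, abc):
        A, B, C = abc
        assert array_edit_distance([A, B, C], [A, B, B, C], RAW) == pytest.approx(1.75)

    def test_novel_insertion_costs_w_indel(self, abc, anc_unit):
        A, B, C = abc
        D = mutate(anc_unit, (10, "C"), (20, "A"), (30, "G"), (70, "C"), (71, "A"), (72, "T"))
        for u in (A, B, C):
            assert unit_hamming(u, D) >= 4
        assert array_edit_distance([A, B, C], [A, B, D, C], RAW) == pytest.approx(3.5)

    def test_two_point_substitution(self, abc):
        A, B, C = abc
        B2 = mutate(B, (39, "G"), (41, "T"))
        assert array_edit_distance([A, B, C], [A, B2, C], RAW) == pytest.approx(2.0)

    def test_empty_array_pure_indel(self, abc):
        A, B, C = abc
        assert array_edit_distance([], [A], RAW) == pytest.approx(3.5)
        assert array_edit_distance([A, A], [], RAW) == pytest.approx(2 * 1.75)
        assert brute_force_distance([A], [A], RAW) == 0.0


short = st.text(alphabet="ACGTN", min_size=4, max_size=4)
arrays = st.lists(short, min_size=0, max_size=4)


class TestOracle:
    def test_small_sweep_agrees(self, unit_alphabet):
        u0, u_hv, u_far = unit_alphabet
        pool = [u0, u_hv, u_far]
        arrays = [
            list(c) for n in range(0, 4) for c in itertools.product(pool, repeat=n)
        ]
        for masked in (False, True):
            p = RepeatDistanceParams(masked=masked)
            for a, b in itertools.combinations_with_replacement(arrays, 2):
                assert array_edit_distance(a, b, p) == pytest.approx(
                    brute_force_distance(a, b, p)
                )

    @given(arrays, arrays)
    def test_agrees_on_random_short_units(self, a, b):
        assert array_edit_distance(a, b, RAW) == pytest.approx(
            brute_force_distance(a, b, RAW)
        )

    def test_refuses_long_arrays(self, abc):
        A, _, _ = abc
        with pytest.raises(Exception):
            brute_force_distance([A] * 5, [A], RAW)


class TestInvariants:
    def test_self_distance_zero(self, abc):
        A, B, C = abc
        for arr in ([A], [A, B], [A, B, C, A]):
            assert array_edit_distance(arr, arr, RAW) == 0.0

    @given(arrays, arrays)
    def test_symmetry(self, a, b):
        assert array_edit_distance(a, b, RAW) == pytest.approx(
            array_edit_distance(b, a, RAW)
        )

    @given(short, short)
    def test_single_unit_reduces_to_hamming(self, s, t):
        assert array_edit_distance([s], [t], RAW) == pytest.approx(
            RAW.w_mut * unit_hamming(s, t)
        )

    @given(arrays, arrays, st.floats(min_value=0.1, max_value=5))
    def test_scale_equivariance(self, a, b, c):
        d1 = array_edit_distance(a, b, RAW)
        d2 = array_edit_distance(a, b, RAW.scaled(c))
        assert d2 == pytest.approx(c * d1)

    def test_masking_never_increases_distance(self, unit_alphabet):
        u0, u_hv, u_far = unit_alphabet
        rng = np.random.default_rng(0)
        pool = [u0, u_hv, u_far]
        for _ in range(200):
            a = [pool[i] for i in rng.integers(3, size=rng.integers(1, 5))]
            b = [pool[i] for i in rng.integers(3, size=rng.integers(1, 5))]
            dm = array_edit_distance(a, b, RepeatDistanceParams(masked=True))
            du = array_edit_distance(a, b, RepeatDistanceParams(masked=False))
            assert dm <= du + 1e-9

    def test_alignment_traceback_consistent(self, abc):
        A, B, C = abc
        cost, ops = array_edit_alignment([A, B, C], [A, B, B, C], RAW)
        assert cost == pytest.approx(1.75)
        kinds = [op[0] for op in ops]
        assert kinds.count("insert") == 1
        assert kinds.count("match") == 3


class TestMatrix:
    def test_identical_alleles_zero_matrix(self, make_allele, anc_unit):
        alleles = [make_allele([anc_unit] * 3) for _ in range(3)]
        dm = distance_matrix(alleles, RAW)
        assert np.allclose(dm.values, 0)

    def test_symmetric_on_random_input(self, unit_alphabet):
        u0, u_hv, u_far = unit_alphabet
        rng = np.random.default_rng(1)
        pool = [u0, u_hv, u_far]
        arrays = [
            [pool[i] for i in rng.integers(3, size=rng.integers(2, 6))]
            for _ in range(20)
        ]
        dm = distance_matrix(arrays, RAW)
        assert np.allclose(dm.values, dm.values.T)

    def test_masked_elementwise_below_unmasked(self, unit_alphabet):
        u0, u_hv, u_far = unit_alphabet
        rng = np.random.default_rng(2)
        pool = [u0, u_hv, u_far]
        arrays = [
            [pool[i] for i in rng.integers(3, size=4)] for _ in range(10)
        ]
        m = distance_matrix(arrays, RepeatDistanceParams(masked=True)).values
        u = distance_matrix(arrays, RepeatDistanceParams(masked=False)).values
        assert (m <= u + 1e-9).all()

    def test_dedupe_keeps_multiplicities(self, make_allele, anc_unit):
        other = mutate(anc_unit, (0, "G"))
        alleles = [
            make_allele([anc_unit] * 3),
            make_allele([anc_unit] * 3),
            make_allele([other] * 3),
        ]
        dm = distance_matrix(alleles, RAW, dedupe=True)
        assert len(dm.labels) == 2
        assert sorted(dm.weights.values()) == [1, 2]

    def test_phylip_round_trip(self, tmp_path, unit_alphabet):
        u0, u_hv, u_far = unit_alphabet
        dm = distance_matrix([[u0], [u_hv], [u_far]], RAW)
        path = tmp_path / "m.phylip"
        dm.write_phylip(path, header_lines=["test"])
        back = read_phylip(path)
        assert back.labels == dm.labels
        assert np.allclose(back.values, dm.values, atol=1e-6)
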