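"""Data model, SCN normalization and divide/assemble round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from r1hic.hicdata import (
    BiasVector,
    ContactMap,
    DegenerateMatrixError,
    assemble_prediction,
    divide_submatrices,
    enumerate_block_pairs,
    read_cool,
    read_matrix,
    scn_denormalize,
    scn_normalize,
    write_bias_bed,
    write_cool,
    write_matrix,
)

from conftest import random_symmetric


class TestContactMap:
    def test_rejects_asymmetric_negative_and_nonsquare(self):
        with pytest.raises(ValueError):
            ContactMap("c", 10, np.arange(4.0).reshape(2, 2))
        with pytest.raises(ValueError):
            ContactMap("c", 10, -np.ones((2, 2)))
        with pytest.raises(ValueError):
            ContactMap("c", 10, np.ones((2, 3)))

    def test_empty_rows_mask(self):
        c = np.zeros((3, 3))
        c[0, 0] = 2.0
        m = ContactMap("c", 10, c)
        np.testing.assert_array_equal(m.empty_rows(), [False, True, True])


class TestSCN:
    def test_all_ones_fixed_point(self):
        # iterative row/column scaling of the 4x4 ones matrix converges to
        # uniform 0.25 entries with bias 2 everywhere
        m = ContactMap("c", 10, np.ones((4, 4)))
        norm, bias = scn_normalize(m)
        np.testing.assert_allclose(norm.counts, 0.25, atol=1e-9)
        np.testing.assert_allclose(bias.b, 2.0, atol=1e-6)
        assert bias.converged

    def test_rows_sum_to_one_and_symmetric(self):
        counts = random_symmetric(16, seed=5) + 0.05
        norm, bias = scn_normalize(ContactMap("c", 10, counts))
        np.testing.assert_allclose(norm.counts.sum(axis=1), 1.0, atol=1e-5)
        np.testing.assert_allclose(norm.counts, norm.counts.T)
        assert bias.converged

    def test_diagonal_matrix_with_pseudocount_normalizes(self):
        counts = np.diag([4.0, 4.0]) + 1e-3
        norm, _ = scn_normalize(ContactMap("c", 10, counts))
        np.testing.assert_allclose(norm.counts.sum(axis=1), 1.0, atol=1e-5)

    def test_zero_rows_left_zero_with_unit_bias(self):
        counts = random_symmetric(8, seed=6) + 0.1
        counts[3, :] = 0.0
        counts[:, 3] = 0.0
        norm, bias = scn_normalize(ContactMap("c", 10, counts))
        assert np.all(norm.counts[3] == 0)
        assert bias.b[3] == 1.0
        keep = np.arange(8) != 3
        np.testing.assert_allclose(norm.counts[keep].sum(axis=1), 1.0, atol=1e-5)

    def test_all_zero_matrix_is_degenerate(self):
        with pytest.raises(DegenerateMatrixError):
            scn_normalize(ContactMap("c", 10, np.zeros((4, 4))))

    def test_normalize_denormalize_round_trip(self):
        counts = random_symmetric(12, seed=7) + 0.2
        m = ContactMap("c", 10, counts)
        norm, bias = scn_normalize(m)
        back = scn_denormalize(norm.counts, bias)
        np.testing.assert_allclose(back, counts, rtol=1e-8)

    def test_non_convergence_flagged(self):
        counts = random_symmetric(16, seed=8) + 0.05
        _, bias = scn_normalize(ContactMap("c", 10, counts), max_iter=1)
        assert not bias.converged


class TestDenormalize:
    def test_identity_bias(self):
        x = random_symmetric(5, seed=9)
        bias = BiasVector(np.ones(5), True, 1)
        np.testing.assert_array_equal(scn_denormalize(x, bias), x)

    def test_elementwise_product(self):
        x = np.eye(2)
        bias = BiasVector(np.array([2.0, 3.0]), True, 1)
        np.testing.assert_allclose(
            scn_denormalize(x, bias), [[4.0, 0.0], [0.0, 9.0]]
        )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            scn_denormalize(np.ones((3, 3)), BiasVector(np.ones(2), True, 1))


def brute_force_pairs(N, half, bin_size, cutoff):
    out = []
    for i in range(N // half):
        for j in range(N // half):
            if j > i and (j - i) * half * bin_size <= cutoff:
                out.append((i, j))
    return sorted(out)


class TestDivideAssemble:
    def test_block_pair_count_oracle(self):
        # 1200 bins at 10 kb with n=400 and a 2 Mb cutoff: only adjacent
        # block pairs survive, giving floor(N / (n/2)) - 1 = 5 pairs
        pairs = enumerate_block_pairs(1200, 200, 10_000, 2_000_000)
        assert pairs == brute_force_pairs(1200, 200, 10_000, 2_000_000)
        assert len(pairs) == 5
        assert pairs == [(i, i + 1) for i in range(5)]

    @given(
        nblocks=st.integers(2, 12),
        cutoff_blocks=st.integers(1, 12),
    )
    @settings(deadline=None, max_examples=25)
    def test_pair_enumeration_matches_brute_force(self, nblocks, cutoff_blocks):
        N, half, bs = nblocks * 8, 8, 10_000
        cutoff = cutoff_blocks * half * bs
        assert enumerate_block_pairs(N, half, bs, cutoff) == brute_force_pairs(
            N, half, bs, cutoff
        )

    def _make_pair_inputs(self, N_hr=256, seed=10):
        hr = ContactMap("c", 10_000, random_symmetric(N_hr, seed=seed))
        lr = ContactMap("c", 40_000, random_symmetric(N_hr // 4, seed=seed + 1))
        return hr, lr

    def test_single_tiling(self):
        hr, lr = self._make_pair_inputs(N_hr=128)
        pairs = divide_submatrices(hr, lr, n=128)
        assert len(pairs) == 1
        assert pairs[0].block_pair == (0, 1)

    def test_sides_and_pooled_views(self):
        hr, lr = self._make_pair_inputs()
        pairs = divide_submatrices(hr, lr, n=128)
        p = pairs[0]
        assert p.hr_target.shape == (128, 128)
        assert p.lr_input.shape == (32, 32)  # same span, 4x coarser bins
        assert p.lr_down2.shape == (16, 16)
        assert p.lr_down4.shape == (8, 8)
        pooled = p.lr_input.reshape(16, 2, 16, 2).mean(axis=(1, 3))
        np.testing.assert_allclose(p.lr_down2, pooled)
        for mat in (p.hr_target, p.lr_input, p.lr_down2, p.lr_down4):
            np.testing.assert_allclose(mat, mat.T)
            assert mat.min() >= 0

    def test_genomic_start_and_distance_omission(self):
        hr, lr = self._make_pair_inputs()
        pairs = divide_submatrices(hr, lr, n=128, max_distance_bp=2_000_000)
        # half-block = 64 bins = 640 kb; pairs up to (j - i) = 3 retained
        assert max(j - i for i, j in (p.block_pair for p in pairs)) == 3
        assert pairs[0].genomic_start == 0
        by_pair = {p.block_pair: p for p in pairs}
        assert by_pair[(1, 2)].genomic_start == 64 * 10_000

    def test_bin_size_mismatch_and_too_small(self):
        hr, lr = self._make_pair_inputs()
        with pytest.raises(ValueError):
            divide_submatrices(hr, hr, n=128)
        with pytest.raises(ValueError):
            divide_submatrices(
                ContactMap("c", 10_000, random_symmetric(64)), lr, n=128
            )

    def test_divide_then_assemble_is_identity_on_band(self):
        hr, lr = self._make_pair_inputs()
        pairs = divide_submatrices(hr, lr, n=128)
        assembled, mask = assemble_prediction(
            [(p.block_pair, p.hr_target) for p in pairs],
            hr.N,
            bin_size=hr.bin_size,
        )
        np.testing.assert_allclose(assembled.counts[mask], hr.counts[mask])
        np.testing.assert_allclose(assembled.counts, assembled.counts.T)
        assert np.all(assembled.counts[~mask] == 0)

    def test_overlap_averaging(self):
        a = np.full((8, 8), 2.0)
        b = np.full((8, 8), 4.0)
        assembled, mask = assemble_prediction(
            [((0, 1), a), ((1, 2), b)], 12, bin_size=10
        )
        # block (1,1) is covered by both pairs: mean of 2 and 4
        np.testing.assert_allclose(assembled.counts[4:8, 4:8], 3.0)
        np.testing.assert_allclose(assembled.counts[0:4, 0:4], 2.0)
        np.testing.assert_allclose(assembled.counts[8:12, 8:12], 4.0)
        assert not mask[0, 11]

    def test_assemble_rejects_bad_shapes(self):
        with pytest.raises(ValueError):
            assemble_prediction([((0, 1), np.ones((8, 6)))], 12)
        with pytest.raises(ValueError):
            assemble_prediction([((0, 5), np.ones((8, 8)))], 12)


class TestIO:
    @pytest.mark.parametrize("suffix", [".npz", ".tsv"])
    def test_matrix_round_trip(self, tmp_path, suffix, small_map):
        path = tmp_path / f"map{suffix}"
        write_matrix(small_map, str(path))
        back = read_matrix(str(path))
        np.testing.assert_allclose(back.counts, small_map.counts, rtol=1e-9)
        assert back.bin_size == small_map.bin_size
        assert back.chrom == small_map.chrom

    def test_cool_round_trip(self, tmp_path):
        counts = np.rint(random_symmetric(20, seed=11) * 10)
        m = ContactMap("chr9", 10_000, counts)
        path = tmp_path / "map.cool"
        write_cool(m, str(path))
        back = read_cool(str(path))
        np.testing.assert_allclose(back.counts, m.counts)
        assert back.chrom == "chr9"
        assert back.bin_size == 10_000
        # reader dispatch by extension
        again = read_matrix(str(path), chrom="chr9")
        np.testing.assert_allclose(again.counts, m.counts)

    def test_bias_bed_export(self, tmp_path, small_map):
        _, bias = scn_normalize(small_map)
        path = tmp_path / "bias.bed"
        write_bias_bed(bias, small_map, str(path))
        rows = [l.split("\t") for l in path.read_text().splitlines()]
        assert len(rows) == small_map.N
        assert rows[1][0] == "chrT"
        assert int(rows[1][1]) == small_map.bin_size
        np.testing.assert_allclose(float(rows[0][3]), bias.b[0])
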