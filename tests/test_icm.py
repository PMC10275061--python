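"""The image-clustering stages: smoothing, cutoff, edges, CMU calling, linking."""

import numpy as np
import pytest
from scipy import ndimage

import cmuscan as cs
from cmuscan.icm import DEFAULT_KERNEL, _block_stats
from conftest import make_manifest


def block_image(blocks, p, value=0.9, fill=0.0):
    """Exact block-diagonal support image: blocks = [(start, stop), ...]."""
    T = np.full((p, p), fill)
    for a, b in blocks:
        T[a:b, a:b] = value
    np.fill_diagonal(T, 1.0)
    return T


def maximal_block_oracle(T, min_cpgs, alpha, density):
    """Exhaustive maximal-interval search for block-diagonal images.

    Greedily extends runs whose off-diagonal entries are all non-zero;
    applies the same length/density/mean acceptance as the caller.
    """
    p = T.shape[0]
    S = np.abs(T) > 0
    found = []
    i = 0
    while i < p:
        j = i
        while j + 1 < p and S[i : j + 2, i : j + 2][~np.eye(j + 2 - i, dtype=bool)].all():
            j += 1
        d, mean_abs = _block_stats(T, i, j + 1)
        if (j - i + 1) >= min_cpgs and d >= density and mean_abs >= alpha:
            found.append((i, j + 1))
        i = j + 1
    return found


def window_for(p, spacing=100):
    m = make_manifest([spacing * (i + 1) for i in range(p)])
    return m, cs.tile_windows(m)[0]


class TestSmoothing:
    def test_constant_matrix_preserved(self):
        c = np.full((10, 10), 0.5)
        out = cs.smooth_image(c)
        off = ~np.eye(10, dtype=bool)
        assert np.allclose(out[off], 0.5, atol=1e-12)

    def test_spike_attenuated_by_center_weight(self):
        # direct convolution oracle for an isolated off-diagonal spike
        R = np.zeros((12, 12))
        np.fill_diagonal(R, 1.0)
        R[2, 8] = R[8, 2] = 0.9
        out = cs.smooth_image(R)
        oracle = ndimage.convolve(R, DEFAULT_KERNEL, mode="reflect")
        assert out[2, 8] == pytest.approx(oracle[2, 8])
        assert out[2, 8] == pytest.approx(0.9 * DEFAULT_KERNEL[1, 1])

    def test_output_symmetric_unit_diagonal_clipped(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(-1, 1, (15, 15))
        R = (A + A.T) / 2
        np.fill_diagonal(R, 1.0)
        out = cs.smooth_image(R)
        assert np.array_equal(out, out.T)
        assert (np.diag(out) == 1.0).all()
        assert np.abs(out).max() <= 1.0

    def test_oversized_kernel_shrunk_with_warning(self):
        R = np.eye(3)
        with pytest.warns(UserWarning, match="shrunk"):
            out = cs.smooth_image(R, np.ones((7, 7)) / 49)
        assert out.shape == (3, 3)


class TestCutoff:
    def test_sign_retained_and_threshold(self):
        R = np.array([[1.0, 0.7, 0.5], [0.7, 1.0, -0.65], [0.5, -0.65, 1.0]])
        T = cs.apply_cutoff(R, 0.6)
        assert T[0, 1] == 0.7 and T[0, 2] == 0.0 and T[1, 2] == -0.65

    def test_zero_alpha_is_identity_and_idempotent(self):
        rng = np.random.default_rng(1)
        R = rng.uniform(-1, 1, (8, 8))
        assert np.array_equal(cs.apply_cutoff(R, 1e-300), R)
        T = cs.apply_cutoff(R, 0.5)
        assert np.array_equal(cs.apply_cutoff(T, 0.5), T)


class TestDetectEdges:
    def test_two_exact_blocks_single_boundary(self):
        T = block_image([(0, 5), (5, 10)], 10)
        assert cs.detect_edges(T) == [5]

    def test_all_ones_support_no_interior_boundary(self):
        T = np.full((8, 8), 0.9)
        np.fill_diagonal(T, 1.0)
        assert cs.detect_edges(T) == []

    def test_all_zero_support_empty(self):
        assert cs.detect_edges(np.zeros((6, 6))) == []


class TestCallContiguous:
    def test_planted_block_called_exactly(self):
        m, w = window_for(20)
        T = block_image([(7, 13)], 20)
        cmus = cs.call_contiguous_cmus(T, w, m, cs.ICMParams())
        assert len(cmus) == 1
        assert cmus[0].probe_indices.tolist() == list(range(7, 13))
        # genomic extent: 1-based first pos - 1 .. last pos
        assert cmus[0].start == m.pos[7] - 1 and cmus[0].end == m.pos[12]

    def test_three_probe_block_rejected_by_min_cpgs(self):
        m, w = window_for(12)
        T = block_image([(4, 7)], 12)
        assert cs.call_contiguous_cmus(T, w, m, cs.ICMParams()) == []

    def test_two_blocks_with_null_gap(self):
        m, w = window_for(20)
        T = block_image([(2, 7), (10, 15)], 20)
        cmus = cs.call_contiguous_cmus(T, w, m, cs.ICMParams())
        assert [tuple(c.probe_indices[[0, -1]]) for c in cmus] == [(2, 6), (10, 14)]

    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_equivalence_on_random_block_images(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(8, 41))
        blocks = []
        i = 0
        while i < p - 2:
            size = int(rng.integers(2, 11))
            stop = min(i + size, p)
            if rng.random() < 0.7:
                blocks.append((i, stop))
            i = stop + int(rng.integers(1, 4))
        T = np.zeros((p, p))
        for a, b in blocks:
            T[a:b, a:b] = rng.uniform(0.65, 0.95)
        np.fill_diagonal(T, 1.0)
        params = cs.ICMParams()
        m, w = window_for(p)
        got = [
            (int(c.probe_indices[0]), int(c.probe_indices[-1]) + 1)
            for c in cs.call_contiguous_cmus(T, w, m, params)
        ]
        want = maximal_block_oracle(T, params.min_cpgs, params.alpha, params.block_density)
        assert got == want


class TestLinking:
    def _linked_image(self, inter, p=24):
        T = block_image([(2, 8), (14, 20)], p)
        T[2:8, 14:20] = inter
        T[14:20, 2:8] = inter
        return T

    def test_positive_interblock_link(self):
        m, w = window_for(24)
        T = self._linked_image(0.8)
        cmus = cs.call_contiguous_cmus(T, w, m, cs.ICMParams())
        ncs = cs.link_noncontiguous(cmus, T, w, cs.ICMParams())
        assert len(ncs) == 1 and ncs[0].n_members == 2
        assert ncs[0].pairwise_sign[0, 1] == 1
        assert ncs[0].span == ("chr1", cmus[0].start, cmus[1].end)

    def test_zero_interblock_no_link(self):
        m, w = window_for(24)
        T = self._linked_image(0.0)
        cmus = cs.call_contiguous_cmus(T, w, m, cs.ICMParams())
        assert cs.link_noncontiguous(cmus, T, w, cs.ICMParams()) == []

    def test_middle_anticorrelated_three_member_signs(self):
        # middle block negatively correlated with both flanks, flanks positive
        T = block_image([(0, 6), (9, 15), (18, 24)], 26)
        T[0:6, 9:15] = T[9:15, 0:6] = -0.8
        T[9:15, 18:24] = T[18:24, 9:15] = -0.8
        T[0:6, 18:24] = T[18:24, 0:6] = 0.8
        m, w = window_for(26)
        cmus = cs.call_contiguous_cmus(T, w, m, cs.ICMParams())
        ncs = cs.link_noncontiguous(cmus, T, w, cs.ICMParams())
        assert len(ncs) == 1 and ncs[0].n_members == 3
        s = ncs[0].pairwise_sign
        assert (s[0, 1], s[1, 2], s[0, 2]) == (-1, -1, 1)

    def test_members_always_in_contiguous_list(self, basic_data):
        cset = basic_data["cmu_set"]
        contiguous_ids = {c.id for c in cset.contiguous}
        for nc in cset.noncontiguous:
            for mcmu in nc.members:
                assert mcmu.id in contiguous_ids


class TestScanDataset:
    def test_planted_blocks_recovered(self, basic_data):
        from conftest import recovery

        n_rec, n_false = recovery(basic_data["cmu_set"], basic_data["truth"]["blocks"])
        assert n_rec >= 19
        assert n_false <= 1

    def test_pure_noise_yields_no_cmus(self):
        spec = cs.simulate.SyntheticSpec(
            n_samples=200,
            chrom_lengths={"chr1": 500_000},
            mean_gap=1000,
            jitter=250,
            rng_seed=11,
        )
        m, b, _ = cs.simulate.generate_block_beta(spec)
        t = cs.inverse_normal_transform(b)
        assert cs.scan_dataset(t, m).contiguous == []

    def test_window_log_partitions_probes(self, basic_data):
        log = basic_data["cmu_set"].window_log
        assert sum(e["n_probes"] for e in log) == len(basic_data["manifest"])
        assert sum(e["n_cmus"] for e in log) == len(basic_data["cmu_set"].contiguous)

    def test_nesting_across_alphas(self, basic_data):
        t, m = basic_data["transformed"], basic_data["manifest"]
        sets = {a: cs.scan_dataset(t, m, cs.ICMParams(alpha=a)) for a in (0.4, 0.6, 0.8)}
        for lo, hi in [(0.4, 0.6), (0.6, 0.8), (0.4, 0.8)]:
            lo_runs = [set(c.probe_indices) for c in sets[lo].contiguous]
            for c in sets[hi].contiguous:
                assert any(set(c.probe_indices) <= r for r in lo_runs), (
                    f"CMU at alpha={hi} not contained in any alpha={lo} CMU"
                )
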