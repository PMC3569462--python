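"""Normalized-cuts superpixels: affinity oracle, small-instance ncut
optimality, the variable-size partition rule, and refinement behaviour."""

import itertools

import numpy as np
import pytest

import octsp
import octsp.pipeline as pl
from octsp.featuremap import compose_feature_map
from octsp.superpixel import (
    SegmentationParams,
    SuperPixel,
    build_affinity,
    initial_segmentation,
    ncut_segment,
    ncut_value,
    partition_count,
    partition_count_raw,
    recursive_refine,
    segment_stats,
)

PARAMS_TOY = SegmentationParams(
    k_init=4, s_min=2, affinity_radius=1.5, sigma_intensity=0.2, sigma_spatial=2.0
)


class TestAffinity:
    def test_constant_image_depends_only_on_distance(self):
        img = np.full((6, 6), 0.5)
        mask = np.ones((6, 6), bool)
        W, coords = build_affinity(img, mask, PARAMS_TOY)
        # all pairs at equal distance share the same weight
        vals = {}
        Wc = W.tocoo()
        for r, c, v in zip(Wc.row, Wc.col, Wc.data):
            d = round(float(np.linalg.norm(coords[r] - coords[c])), 6)
            vals.setdefault(d, set()).add(round(float(v), 12))
        assert vals and all(len(s) == 1 for s in vals.values())

    def test_pairs_beyond_radius_have_zero_weight(self):
        img = np.zeros((1, 5))
        mask = np.ones((1, 5), bool)
        W, coords = build_affinity(img, mask, PARAMS_TOY)  # radius 1.5
        i = {tuple(c): k for k, c in enumerate(coords)}
        assert W[i[(0, 0)], i[(0, 4)]] == 0.0
        assert W[i[(0, 0)], i[(0, 3)]] == 0.0
        assert W[i[(0, 0)], i[(0, 1)]] > 0.0

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(0)
        img = rng.random((5, 5))
        mask = rng.random((5, 5)) > 0.2
        mask[2, 2] = True
        p = SegmentationParams(
            k_init=2, s_min=1, affinity_radius=2.3, sigma_intensity=0.3,
            sigma_spatial=3.0,
        )
        W, coords = build_affinity(img, mask, p)
        n = len(coords)
        ref = np.zeros((n, n))
        for a in range(n):
            for b in range(n):
                if a == b:
                    continue
                dist2 = float(((coords[a] - coords[b]) ** 2).sum())
                if dist2 <= p.affinity_radius**2:
                    ia = img[tuple(coords[a])]
                    ib = img[tuple(coords[b])]
                    ref[a, b] = np.exp(-((ia - ib) ** 2) / p.sigma_intensity**2) * np.exp(
                        -dist2 / p.sigma_spatial**2
                    )
        W = W.toarray()
        bridged = np.abs(W - ref) > 1e-12
        # any extra entries must be bridge edges (value 1e-3) between
        # disconnected fragments; the formula entries themselves agree
        assert np.all(np.abs(W[~bridged] - ref[~bridged]) <= 1e-12)
        assert np.all(np.abs(W[bridged] - 1e-3) < 1e-12)
        assert np.all(np.diag(W) == 0)
        np.testing.assert_allclose(W, W.T)


class TestNcut:
    def _two_blob(self):
        # 3x4 image: left 3x2 dark, right 3x2 bright -> 12 nodes
        img = np.zeros((3, 4))
        img[:, 2:] = 1.0
        mask = np.ones((3, 4), bool)
        p = SegmentationParams(
            k_init=2, s_min=1, affinity_radius=1.5, sigma_intensity=0.4,
            sigma_spatial=4.0,
        )
        return build_affinity(img, mask, p)

    def test_k_equals_one_and_n(self):
        W, coords = self._two_blob()
        assert np.all(ncut_segment(W, coords, 1, -0.1) == 0)
        lab = ncut_segment(W, coords, len(coords), -0.1)
        assert len(np.unique(lab)) == len(coords)

    def test_two_blob_partition_is_exhaustive_minimum(self):
        W, coords = self._two_blob()
        lab = ncut_segment(W, coords, 2, -0.1, seed=0)
        # the recovered segments are exactly the two intensity blobs
        blob = coords[:, 1] >= 2
        assert (np.all(lab == blob) or np.all(lab == ~blob))
        # and the ncut objective equals the exhaustive minimum over all
        # 2-labelings of the 12 nodes
        n = len(coords)
        best = np.inf
        for bits in range(1, 2 ** (n - 1)):
            assign = np.array([(bits >> i) & 1 for i in range(n)])
            best = min(best, ncut_value(W, assign))
        assert ncut_value(W, lab) == pytest.approx(best, abs=1e-9)

    def test_deterministic_given_seed(self):
        W, coords = self._two_blob()
        a = ncut_segment(W, coords, 4, -0.1, seed=3)
        b = ncut_segment(W, coords, 4, -0.1, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_segments_connected_and_exhaustive(self):
        rng = np.random.default_rng(1)
        img = rng.random((8, 8))
        mask = np.ones((8, 8), bool)
        W, coords = build_affinity(img, mask, PARAMS_TOY)
        for k in (2, 5, 9):
            lab = ncut_segment(W, coords, k, -0.1, seed=0)
            assert len(np.unique(lab)) == k
            for s in range(k):
                sel = lab == s
                Wb = W.tocoo()
                from scipy.sparse import coo_matrix, csgraph

                same = sel[Wb.row] & sel[Wb.col]
                sub = coo_matrix(
                    (Wb.data[same], (Wb.row[same], Wb.col[same])), shape=W.shape
                )
                ncomp, comp = csgraph.connected_components(sub, directed=False)
                assert len(np.unique(comp[sel])) == 1


class TestPartitionCount:
    P = SegmentationParams(s_min=50)

    def _sp(self, size, mean_t, sd_t=0.0, dev=0.0):
        return SuperPixel(label=1, size=size, mean_t=mean_t, sd_t=sd_t, mean_dev=dev)

    def test_minimal_size_never_splits(self):
        assert partition_count(self._sp(50, 10.0, 30.0, 5.0), 80, 1.0, 160, self.P) == 0
        assert partition_count(self._sp(99, 10.0, 30.0, 5.0), 80, 1.0, 160, self.P) == 0

    def test_thick_homogeneous_never_splits(self):
        # thicker than the map average and SD below the map SD
        assert partition_count(self._sp(1000, 120.0, 5.0), 80, 10.0, 160, self.P) == 0
        assert partition_count(self._sp(1000, 120.0, 10.0), 80, 10.0, 160, self.P) == 0

    def test_thick_heterogeneous_splits_gently(self):
        n = partition_count(self._sp(500, 120.0, 30.0), 80, 10.0, 160, self.P)
        # C_thick * (500/50) * (30/10) = 6, capped at floor(500/100) = 5
        assert n == 5
        n2 = partition_count(self._sp(500, 120.0, 15.0), 80, 10.0, 160, self.P)
        assert n2 == 3  # 0.2 * 10 * 1.5

    def test_zero_map_sd_disables_thick_branch(self):
        assert partition_count(self._sp(1000, 120.0, 30.0), 80, 0.0, 160, self.P) == 0

    def test_thin_branch_formula_and_cap(self):
        # S = 10*S_min, mean_T = T_max/4, D = 0.5:
        # raw N = round(1.2 * 10 * (0.75 + 0.5)) = 15, then the size cap
        # floor(S / (2*S_min)) = 5 binds
        sp = self._sp(500, 40.0, 0.0, 0.5)
        assert partition_count_raw(sp, 80.0, 10.0, 160.0, self.P) == 15
        assert partition_count(sp, 80.0, 10.0, 160.0, self.P) == 5

    def test_round_half_away_from_zero(self):
        # raw value exactly 2.5 -> 3 (away from zero)
        sp = self._sp(250, 160.0 * 7 / 12, 0.0, 0.0)
        assert partition_count_raw(sp, 160.0, 10.0, 160.0, self.P) == 3


class TestRefinement:
    def _uniform_fm(self, grid):
        t = np.full((grid.n, grid.n), 90.0)
        disc = grid.disc_mask()
        t[disc] = 0.0
        return compose_feature_map(
            t, np.full_like(t, 0.8), np.zeros_like(t), disc, grid
        )

    def test_uniform_map_stays_at_k_init(self, grid64, params64):
        fm = self._uniform_fm(grid64)
        spm, W, coords = initial_segmentation(fm, params64)
        assert spm.n_segments == params64.k_init
        refined = recursive_refine(spm, fm, params64, W, coords)
        assert refined.n_segments < 1.2 * params64.k_init

    def test_refine_idempotent(self, processed_pair64, grid64, atlas64, params64):
        res_g = processed_pair64[1]
        spm = res_g["superpixel_map"]
        again = recursive_refine(spm, res_g["feature_map"], params64)
        assert again.n_segments == spm.n_segments

    def test_partition_validity(self, processed_pair64, grid64):
        from scipy.sparse import coo_matrix
        from scipy import ndimage

        for res in processed_pair64[:2]:
            spm = res["superpixel_map"]
            region = ~res["feature_map"].disc_mask
            labels = spm.labels
            assert np.all((labels > 0) == region)  # tiles the evaluable region
            sizes = np.array([s.size for s in spm.segments])
            assert sizes.sum() == region.sum()  # conservation
            assert np.all(sizes >= 1)
            assert [s.label for s in spm.segments] == list(
                range(1, spm.n_segments + 1)
            )
            # connectivity (8-neighbour) of every segment
            for s in spm.segments:
                comp, ncomp = ndimage.label(
                    labels == s.label, structure=np.ones((3, 3))
                )
                assert ncomp == 1

    def test_stats_match_bruteforce(self, processed_pair64):
        res = processed_pair64[1]
        spm = res["superpixel_map"]
        fm = res["feature_map"]
        for s in spm.segments[::17]:
            sel = spm.labels == s.label
            assert s.size == sel.sum()
            assert s.mean_t == pytest.approx(fm.thickness[sel].mean())
            assert s.sd_t == pytest.approx(fm.thickness[sel].std())
            assert s.mean_dev == pytest.approx(fm.deviation[sel].mean())

    def test_defect_sector_gets_smaller_superpixels(self, processed_pair64, grid64):
        res_g, glaucoma = processed_pair64[1], processed_pair64[3]
        spm = res_g["superpixel_map"]
        d = glaucoma.truth.defects[0]
        r, theta = grid64.polar()
        off = np.abs((theta - d.center_angle + 180.0) % 360.0 - 180.0)
        sector = (
            (off < d.angular_width / 2)
            & ~glaucoma.maps.disc_mask
            & (r * grid64.spacing_mm < d.radial_extent_mm)
        )
        sizes = {s.label: s.size for s in spm.segments}
        inside = np.unique(spm.labels[sector & (spm.labels > 0)])
        outside = np.setdiff1d(np.unique(spm.labels[~sector & (spm.labels > 0)]), inside)
        mean_in = np.mean([sizes[l] for l in inside])
        mean_out = np.mean([sizes[l] for l in outside])
        assert mean_in < mean_out

    def test_superpixel_count_nondecreasing_in_depth(
        self, grid64, atlas64, params64, thresholds64
    ):
        from conftest import make_twin

        counts = []
        for depth in (0.0, 0.6, 0.9):
            eye = make_twin(grid64, depth, seed=6)
            res = pl.process_eye(eye, atlas64, params64, thresholds64)
            counts.append(res["n_segments"])
        assert counts[0] <= counts[1] <= counts[2]
        assert counts[0] < counts[2]
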