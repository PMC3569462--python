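"""Normative atlas: bundle detection, angular warp, atlas statistics,
deviation calibration and scan QC."""

import numpy as np
import pytest
from scipy import ndimage

import octsp
import octsp.atlas as A
import octsp.featuremap as FM
from octsp.synthetic import sample_phenotype

GRID200 = octsp.GridSpec()


def _inpainted(eye):
    return FM.inpaint_vessels(
        eye.maps.thickness, eye.maps.vessel_mask, eye.maps.disc_mask
    )


def _flat_paths(grid, sup, inf, radii=None):
    r = A.default_radii(grid) if radii is None else radii
    return A.BundlePaths(r, np.full(len(r), float(sup)), np.full(len(r), float(inf)))


class TestBundleDetection:
    def test_recovers_implanted_angles_within_5deg(self):
        eye = octsp.generate_eye(
            octsp.EyePhenotype(bundle_angles=(65.0, 295.0)), GRID200, rng_seed=3
        )
        p = A.detect_bundle_paths(_inpainted(eye), GRID200)
        assert np.abs(p.superior_deg - 65.0).max() < 5.0
        assert np.abs(p.inferior_deg - 295.0).max() < 5.0

    def test_rotation_equivariance(self):
        eye = octsp.generate_eye(
            octsp.EyePhenotype(bundle_angles=(65.0, 295.0)), GRID200, rng_seed=3
        )
        t = _inpainted(eye)
        base = A.detect_bundle_paths(t, GRID200)
        # array rotation by -10 deg moves content by +10 deg in the map's
        # temporal-zero counter-clockwise angular convention
        rot = ndimage.rotate(t, -10.0, reshape=False, order=1)
        shifted = A.detect_bundle_paths(rot, GRID200)
        assert abs(shifted.superior_deg.mean() - base.superior_deg.mean() - 10.0) < 2.0
        assert abs(shifted.inferior_deg.mean() - base.inferior_deg.mean() - 10.0) < 2.0

    def test_flat_map_raises(self, grid64):
        with pytest.raises(ValueError, match="no bundle"):
            A.detect_bundle_paths(np.full((grid64.n, grid64.n), 90.0), grid64)

    def test_repeatability_across_noise_seeds(self, grid64):
        angles = []
        for seed in (21, 22):
            eye = octsp.generate_eye(
                octsp.EyePhenotype(bundle_angles=(65.0, 295.0), vessel_seed=9),
                grid64,
                rng_seed=seed,
            )
            p = A.detect_bundle_paths(_inpainted(eye), grid64)
            angles.append(p.superior_deg.mean())
        assert abs(angles[0] - angles[1]) < A.SMOOTH_DEG


class TestNormalization:
    def test_identity_warp_is_exact(self, healthy_eye64, grid64):
        t = _inpainted(healthy_eye64)
        paths = _flat_paths(grid64, 65.0, 295.0)
        out = A.normalize_map(t, paths, paths, grid64)
        assert np.abs(out - t).max() < 1.0  # in fact exact at grid points
        assert np.abs(out - t).max() < 1e-9

    def test_round_trip_moves_bundles_to_reference(self):
        eye = octsp.generate_eye(
            octsp.EyePhenotype(bundle_angles=(75.0, 285.0)), GRID200, rng_seed=3
        )
        t = _inpainted(eye)
        own = A.detect_bundle_paths(t, GRID200)
        ref = _flat_paths(GRID200, 65.0, 295.0, radii=own.radii_px)
        normed = A.normalize_map(t, own, ref, GRID200)
        p2 = A.detect_bundle_paths(normed, GRID200)
        assert abs(p2.superior_deg.mean() - 65.0) < 2.0
        assert abs(p2.inferior_deg.mean() - 295.0) < 2.0

    def test_inverse_warp_recovers_map(self, healthy_eye64, grid64):
        t = _inpainted(healthy_eye64)
        own = _flat_paths(grid64, 75.0, 285.0)
        ref = _flat_paths(grid64, 65.0, 295.0)
        warped = A.normalize_map(t, own, ref, grid64)
        back = A.normalize_map(warped, own, ref, grid64, invert=True)
        r, _ = grid64.polar()
        ring = (r > grid64.disc_radius_px + 2) & (r < grid64.n / 2 - 2)
        err = np.abs(back - t)[ring]
        # two resampling passes: small everywhere on a smooth map
        assert err.mean() < 1.0
        assert np.percentile(err, 99) < 6.0

    def test_non_monotone_anchors_rejected(self, grid64):
        r = A.default_radii(grid64)
        with pytest.raises(ValueError):
            A.BundlePaths(r, np.full(len(r), 190.0), np.full(len(r), 295.0))
        with pytest.raises(ValueError):
            A.BundlePaths(r, np.full(len(r), 65.0), np.full(len(r), 170.0))


class TestAtlas:
    def test_identical_maps_zero_sd(self, grid64):
        m = np.random.default_rng(0).random((grid64.n, grid64.n)) * 100
        paths = _flat_paths(grid64, 65.0, 295.0)
        atlas = A.build_atlas([m, m.copy()], paths, grid64)
        assert np.all(atlas.sd_map == 0)
        np.testing.assert_allclose(atlas.mean_map, m)

    def test_constant_maps_hand_arithmetic(self, grid64):
        n = grid64.n
        paths = _flat_paths(grid64, 65.0, 295.0)
        atlas = A.build_atlas(
            [np.full((n, n), 100.0), np.full((n, n), 102.0)], paths, grid64
        )
        np.testing.assert_allclose(atlas.mean_map, 101.0)
        np.testing.assert_allclose(atlas.sd_map, np.sqrt(2.0))

    def test_matches_bruteforce_stack_statistics(self, grid64):
        rng = np.random.default_rng(5)
        maps = [rng.random((grid64.n, grid64.n)) * 120 for _ in range(7)]
        atlas = A.build_atlas(maps, _flat_paths(grid64, 65.0, 295.0), grid64)
        stack = np.stack(maps)
        mean_bf = stack.sum(0) / 7
        sd_bf = np.sqrt(((stack - mean_bf) ** 2).sum(0) / 6)
        np.testing.assert_allclose(atlas.mean_map, mean_bf, atol=1e-10)
        np.testing.assert_allclose(atlas.sd_map, sd_bf, atol=1e-10)

    def test_requires_two_maps_and_matching_grids(self, grid64):
        paths = _flat_paths(grid64, 65.0, 295.0)
        with pytest.raises(ValueError):
            A.build_atlas([np.zeros((grid64.n, grid64.n))], paths, grid64)
        with pytest.raises(ValueError):
            A.build_atlas(
                [np.zeros((grid64.n, grid64.n)), np.zeros((10, 10))], paths, grid64
            )

    def test_normalization_reduces_bundle_flank_sd(self, grid64):
        """Aligning bundle locations shrinks the population SD at the
        superior/inferior temporal regions (the bundle flanks)."""
        rng = np.random.default_rng(2)
        eyes = [
            octsp.generate_eye(
                sample_phenotype("healthy", rng), grid64,
                rng_seed=int(rng.integers(2**31)),
            )
            for _ in range(46)
        ]
        maps = [_inpainted(e) for e in eyes]
        atlas, _ = A.build_atlas_from_cohort(maps, grid64)
        sd_raw = np.stack(maps).std(axis=0, ddof=1)
        r, theta = grid64.polar()
        ring = (r * grid64.spacing_mm > 1.2) & (r * grid64.spacing_mm < 2.5)
        flank = np.zeros_like(ring)
        for b in (65.0, 295.0):
            d = np.abs((theta - b + 180.0) % 360.0 - 180.0)
            flank |= (d > 10) & (d < 40)
        sel = ring & flank
        assert atlas.sd_map[sel].mean() < sd_raw[sel].mean()


class TestDeviation:
    def _toy_atlas(self, grid):
        n = grid.n
        return A.NormativeAtlas(
            mean_map=np.full((n, n), 100.0),
            sd_map=np.full((n, n), 10.0),
            reference_paths=_flat_paths(grid, 65.0, 295.0),
            n_eyes=46,
            grid=grid,
        )

    def test_map_equal_to_mean_has_no_deficit(self, grid64):
        atlas = self._toy_atlas(grid64)
        dev = A.deviation_map(atlas.mean_map.copy(), atlas)
        assert not dev.below_cutoff.any()
        assert np.all(dev.deficit == 0)

    def test_two_sd_below_gives_unit_deficit(self, grid64):
        atlas = self._toy_atlas(grid64)
        t = atlas.mean_map.copy()
        t[5, 7] = 100.0 - 2 * 10.0
        dev = A.deviation_map(t, atlas)
        assert dev.deficit[5, 7] == pytest.approx(1.0)
        assert dev.below_cutoff[5, 7]
        assert dev.deficit.sum() == pytest.approx(1.0)

    def test_deficit_positive_iff_below_cutoff(self, grid64):
        atlas = self._toy_atlas(grid64)
        rng = np.random.default_rng(0)
        t = rng.normal(100.0, 10.0, (grid64.n, grid64.n))
        dev = A.deviation_map(t, atlas)
        np.testing.assert_array_equal(dev.deficit > 0, dev.below_cutoff)

    def test_zero_sd_pixels_unevaluable(self, grid64):
        atlas = self._toy_atlas(grid64)
        atlas.sd_map[0, 0] = 0.0
        dev = A.deviation_map(np.zeros((grid64.n, grid64.n)), atlas)
        assert not dev.evaluable[0, 0]
        assert not dev.below_cutoff[0, 0]
        assert dev.deficit[0, 0] == 0.0

    def test_grid_mismatch_raises(self, grid64):
        atlas = self._toy_atlas(grid64)
        with pytest.raises(ValueError):
            A.deviation_map(np.zeros((5, 5)), atlas)

    def test_cutoff_calibration_one_and_two_sd(self, grid64):
        """An eye drawn from the atlas's own distribution flags ~15.9% of
        pixels at mean-1SD and ~2.3% at the conventional mean-2SD."""
        atlas = self._toy_atlas(grid64)
        rng = np.random.default_rng(123)
        n_draws = 1_000_000
        shape = (n_draws // grid64.n**2 + 1, grid64.n, grid64.n)
        draws = rng.normal(100.0, 10.0, shape)
        flagged1 = np.mean([A.deviation_map(d, atlas).below_cutoff.mean() for d in draws])
        flagged2 = np.mean(
            [A.deviation_map(d, atlas, n_sd=2.0).below_cutoff.mean() for d in draws]
        )
        assert flagged1 == pytest.approx(0.1587, abs=0.005)
        assert flagged2 == pytest.approx(0.0228, abs=0.005)


class TestQc:
    @pytest.mark.parametrize(
        "bad_runs,expect_pass,reason",
        [
            ([(0, 17)], False, "consecutive"),  # 17/200 consecutive > 8%
            ([(0, 16)], True, "ok"),  # exactly 8%: not strictly greater
            ([(i * 8, 1) for i in range(25)], False, "cumulative"),  # 25/200 > 12%
            ([(0, 17), (30, 10)], False, "consecutive+cumulative"),
        ],
    )
    def test_qc_rules(self, bad_runs, expect_pass, reason):
        flags = np.zeros(200, bool)
        for start, length in bad_runs:
            flags[start : start + length] = True
        passed, why = A.qc_scan(flags)
        assert passed == expect_pass
        assert why == reason

    def test_empty_flags_raise(self):
        with pytest.raises(ValueError):
            A.qc_scan(np.array([], bool))
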