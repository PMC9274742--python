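"""Spatial statistics: distance transforms, spot detection, histograms."""

import numpy as np
import pytest
from scipy import ndimage

from carspat3d import lsfm
from carspat3d.types import LabelMask, SpotSet, VolumeImage

from conftest import brute_force_surface_distance, match_spots, random_blob_mask


def ball_mask(shape, spacing, center, radius):
    from carspat3d.types import voxel_centers

    zz, yy, xx = voxel_centers(shape, spacing)
    c = np.asarray(center, float)
    d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
    return LabelMask((d2 <= radius**2).astype(np.int32), spacing, {1: "tumor"})


class TestApplyMask:
    def test_half_mask_halves_sum(self):
        vol = VolumeImage(np.ones((4, 4, 4)), (1, 1, 1))
        data = np.zeros((4, 4, 4), np.int32)
        data[:2] = 1
        out = lsfm.apply_tumor_mask(vol, LabelMask(data, (1, 1, 1)))
        assert out.data.sum() == 32

    def test_full_and_empty_masks(self):
        vol = VolumeImage(np.ones((3, 3, 3)), (1, 1, 1))
        full = LabelMask(np.ones((3, 3, 3), np.int32), (1, 1, 1))
        empty = LabelMask(np.zeros((3, 3, 3), np.int32), (1, 1, 1))
        assert np.array_equal(lsfm.apply_tumor_mask(vol, full).data, vol.data)
        assert lsfm.apply_tumor_mask(vol, empty).data.sum() == 0


class TestDistanceToSurface:
    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            mask = random_blob_mask(rng, max_side=14)
            spacing = tuple(rng.choice([0.5, 1.0, 2.0], size=3))
            if mask.all():
                continue
            dmap = lsfm.distance_to_surface(
                LabelMask(mask.astype(np.int32), spacing, {1: "tumor"})
            )
            oracle = brute_force_surface_distance(mask, spacing)
            assert np.allclose(
                np.nan_to_num(dmap.values), np.nan_to_num(oracle), atol=1e-9
            )

    def test_sphere_max_depth_near_radius(self):
        m = ball_mask((41, 41, 41), (1, 1, 1), (20.5, 20.5, 20.5), 15.0)
        dmap = lsfm.distance_to_surface(m)
        assert abs(np.nanmax(dmap.values) - 15.0) <= 1.0

    def test_single_voxel_depth_below_one(self):
        data = np.zeros((5, 5, 5), np.int32)
        data[2, 2, 2] = 1
        dmap = lsfm.distance_to_surface(LabelMask(data, (1, 1, 1)))
        assert 0 <= dmap.values[2, 2, 2] <= 1.0

    def test_axis_permutation_invariance(self):
        rng = np.random.default_rng(3)
        mask = random_blob_mask(rng, max_side=12)
        spacing = (0.5, 1.0, 2.0)
        dmap = lsfm.distance_to_surface(LabelMask(mask.astype(np.int32), spacing))
        perm = (2, 0, 1)
        dmap_p = lsfm.distance_to_surface(
            LabelMask(
                np.transpose(mask, perm).astype(np.int32),
                tuple(spacing[a] for a in perm),
            )
        )
        assert np.allclose(
            np.nan_to_num(dmap_p.values),
            np.nan_to_num(np.transpose(dmap.values, perm)),
        )

    def test_degenerate_masks_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            lsfm.distance_to_surface(LabelMask(np.zeros((3, 3, 3), np.int32), (1, 1, 1)))
        with pytest.raises(ValueError, match="no surface"):
            lsfm.distance_to_surface(LabelMask(np.ones((3, 3, 3), np.int32), (1, 1, 1)))


class TestVesselSegmentation:
    def test_noiseless_phantom_dice(self):
        from carspat3d.synthetic import TumorPhantomSpec, VesselParams, CellParams

        spec = TumorPhantomSpec(
            tumor_radii_um=(110.0, 130.0, 130.0),
            cell_params=CellParams(n_cells=0),
            vessel_params=VesselParams(n_trunks=3, max_centerline_points=300),
            noise_sd=0.0,
            seed=5,
        )
        from carspat3d.synthetic import make_tumor_phantom

        channels, tmask, vmask, _ = make_tumor_phantom(spec)
        seg = lsfm.segment_vessels(channels["lectin"], tmask)
        a, b = seg.binary(), vmask.binary()
        dice = 2 * (a & b).sum() / (a.sum() + b.sum())
        assert dice >= 0.95

    def test_zero_channel_warns_empty(self):
        vol = VolumeImage(np.zeros((10, 10, 10)), (1, 1, 1))
        mask = ball_mask((10, 10, 10), (1, 1, 1), (5, 5, 5), 4.0)
        with pytest.warns(UserWarning, match="empty"):
            seg = lsfm.segment_vessels(vol, mask, threshold=0.5)
        assert not seg.binary().any()

    def test_explicit_threshold_definition(self):
        rng = np.random.default_rng(0)
        data = rng.random((12, 12, 12)).astype(np.float32)
        mask = LabelMask(np.ones((12, 12, 12), np.int32), (1, 1, 1))
        seg = lsfm.segment_vessels(
            VolumeImage(data, (1, 1, 1)), mask, threshold=0.5, min_component_voxels=1
        )
        assert np.array_equal(seg.binary(), data >= 0.5)


class TestDetectSpots:
    def test_recovery_on_separated_phantom(self, separated_tumor):
        spec, channels, tmask, _, cells, spots = separated_tumor
        precision, recall, locs = match_spots(spots, cells)
        assert precision >= 0.95
        assert recall >= 0.95
        assert np.mean(locs) <= min(spec.voxel_spacing_um)

    def test_radii_at_least_minimum(self, separated_tumor):
        *_, spots = separated_tumor
        assert np.all(spots.radius_um >= 4.0 - 1e-6)

    def test_empty_channel_gives_empty_spotset(self):
        vol = VolumeImage(np.zeros((12, 12, 12), np.float32), (2, 2, 2))
        mask = ball_mask((12, 12, 12), (2, 2, 2), (12, 12, 12), 10.0)
        assert len(lsfm.detect_spots(vol, mask)) == 0

    def test_spacing_coarser_than_min_diameter_rejected(self):
        vol = VolumeImage(np.zeros((5, 5, 5), np.float32), (10, 2, 2))
        mask = LabelMask(np.ones((5, 5, 5), np.int32), (10, 2, 2))
        with pytest.raises(ValueError, match="coarser"):
            lsfm.detect_spots(vol, mask, min_diameter_um=8.0)


class TestHistograms:
    def test_uniform_spots_follow_shell_volumes(self):
        rng = np.random.default_rng(11)
        m = ball_mask((61, 61, 61), (2, 2, 2), (61, 61, 61), 50.0)
        dmap = lsfm.distance_to_surface(m)
        # uniform spots inside the ball via rejection
        pts = rng.uniform(11, 111, size=(40000, 3))
        r = np.linalg.norm(pts - 61.0, axis=1)
        pts = pts[r <= 50.0][:8000]
        spots = SpotSet(pts, 5.0, 1.0)
        hist = lsfm.spot_distance_histogram(spots, dmap, bin_width_um=10.0)
        vox = dmap.values[dmap.defined]
        expected = np.histogram(vox, bins=hist.bin_edges)[0]
        # interior shells: the outermost bin mixes interpolation at the
        # surface with partial voxels, so compare depths 10-40 µm
        sel = (hist.bin_edges[:-1] >= 10.0) & (hist.bin_edges[1:] <= 40.0)
        e = expected[sel] / expected[sel].sum()
        o = hist.counts[sel] / hist.counts[sel].sum()
        assert np.abs(e - o).max() < 0.03

    def test_histogram_normalizes_and_ignores_order(self):
        m = ball_mask((21, 21, 21), (1, 1, 1), (10.5, 10.5, 10.5), 8.0)
        dmap = lsfm.distance_to_surface(m)
        rng = np.random.default_rng(5)
        pts = 10.5 + rng.uniform(-4, 4, size=(200, 3))
        h1 = lsfm.spot_distance_histogram(SpotSet(pts, 4, 1), dmap, 2.0)
        h2 = lsfm.spot_distance_histogram(SpotSet(pts[::-1], 4, 1), dmap, 2.0)
        assert h1.relative_frequency.sum() == pytest.approx(1.0)
        assert np.array_equal(h1.counts, h2.counts)

    def test_empty_spotset_histogram(self):
        m = ball_mask((11, 11, 11), (1, 1, 1), (5.5, 5.5, 5.5), 4.0)
        h = lsfm.spot_distance_histogram(SpotSet.empty(), lsfm.distance_to_surface(m))
        assert h.n_total == 0
        assert h.relative_frequency.sum() == 0

    def test_spots_on_vessels_all_in_first_bin(self):
        data = np.zeros((11, 11, 31), np.int32)
        data[5, 5, :] = 1
        vm = LabelMask(data, (2, 2, 2), {1: "vessel"})
        coords = np.array([[11.0, 11.0, 5.0], [11.0, 11.0, 41.0]])
        h = lsfm.spot_vessel_distances(SpotSet(coords, 4, 1), vm, bin_width_um=10.0)
        assert h.counts[0] == 2

    def test_straight_tube_distance_geometry(self):
        # tube along z at (y,x) = (25, 25) µm with radius one voxel
        data = np.zeros((21, 25, 25), np.int32)
        data[:, 12, 12] = 1
        vm = LabelMask(data, (2, 2, 2), {1: "vessel"})
        dmap = lsfm.distance_to_vessels(vm)
        for offset in (6.0, 10.0, 16.0):
            d = dmap.sample([[21.0, 25.0, 25.0 + offset]])[0]
            assert abs(d - offset) <= 2.0 + 1.0  # one voxel + boundary shift

    def test_empty_vessel_mask_rejected(self):
        vm = LabelMask(np.zeros((5, 5, 5), np.int32), (1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            lsfm.distance_to_vessels(vm)


class TestDecayFit:
    def test_recovers_decay_length_from_true_cells(self, decay_tumor):
        spec, _, tmask, _, cells, _ = decay_tumor
        dmap = lsfm.distance_to_surface(tmask)
        lam = lsfm.fit_surface_decay(cells, dmap)
        truth = spec.cell_params.surface_decay_length_um
        assert abs(lam - truth) / truth <= 0.2

    def test_too_few_spots_rejected(self):
        m = ball_mask((11, 11, 11), (1, 1, 1), (5.5, 5.5, 5.5), 4.0)
        with pytest.raises(ValueError, match="at least"):
            lsfm.fit_surface_decay(SpotSet.empty(), lsfm.distance_to_surface(m))


class TestPeripheryCore:
    def test_threshold_beyond_max_depth_gives_all_periphery(self):
        m = ball_mask((21, 21, 21), (2, 2, 2), (21, 21, 21), 16.0)
        spots = SpotSet(np.full((5, 3), 21.0), 4, 1)
        out = lsfm.periphery_core_split(m, spots, boundary_distance_um=1e5, mode="fixed")
        assert out["periphery_pct"] == 100.0

    def test_uniform_spots_equal_volume_split_balances(self):
        rng = np.random.default_rng(2)
        m = ball_mask((61, 61, 61), (2, 2, 2), (61, 61, 61), 50.0)
        pts = rng.uniform(11, 111, size=(40000, 3))
        pts = pts[np.linalg.norm(pts - 61.0, axis=1) <= 49.0][:4000]
        out = lsfm.periphery_core_split(m, SpotSet(pts, 4, 1), mode="equal_volume")
        assert abs(out["periphery_pct"] - 50.0) < 4.0

    def test_surface_biased_spots_favor_periphery(self, decay_tumor):
        _, _, tmask, _, cells, _ = decay_tumor
        out = lsfm.periphery_core_split(tmask, cells)
        assert out["periphery_pct"] > out["core_pct"]

    def test_empty_spots_rejected(self):
        m = ball_mask((11, 11, 11), (1, 1, 1), (5.5, 5.5, 5.5), 4.0)
        with pytest.raises(ValueError, match="empty"):
            lsfm.periphery_core_split(m, SpotSet.empty())


class TestDensityClusters:
    def test_cluster_members_outrank_isolated(self):
        rng = np.random.default_rng(4)
        cluster = rng.normal(0, 5, size=(40, 3)) + 100.0
        isolated = np.array([[500.0, 500.0, 500.0], [900.0, 100.0, 500.0]])
        spots = SpotSet(np.vstack([cluster, isolated]), 4, 1)
        classes = lsfm.density_clusters(spots, radius_um=50.0, n_classes=3)
        assert classes[:40].min() == classes.max()
        assert classes[40:].max() == 0

    def test_uniform_spots_fill_classes_evenly(self):
        rng = np.random.default_rng(9)
        spots = SpotSet(rng.uniform(0, 1000, size=(1000, 3)), 4, 1)
        classes = lsfm.density_clusters(spots, radius_um=150.0, n_classes=5)
        occ = np.bincount(classes, minlength=5) / len(classes)
        assert occ.min() > 0.1

    def test_infinite_radius_single_class(self):
        rng = np.random.default_rng(1)
        spots = SpotSet(rng.uniform(0, 100, size=(50, 3)), 4, 1)
        classes = lsfm.density_clusters(spots, radius_um=1e9, n_classes=4)
        assert np.all(classes == classes[0])

    def test_fewer_spots_than_classes_warns(self):
        spots = SpotSet(np.zeros((2, 3)), 4, 1)
        with pytest.warns(UserWarning, match="single class"):
            classes = lsfm.density_clusters(spots, n_classes=5)
        assert np.all(classes == 0)


class TestMiddleThirdProfile:
    def test_constant_tumor_gives_flat_profile(self):
        m = ball_mask((31, 31, 31), (2, 2, 2), (31, 31, 31), 24.0)
        vol = VolumeImage(np.full((31, 31, 31), 7.0), (2, 2, 2))
        prof = lsfm.middle_third_profile(vol, m)
        assert np.allclose(prof.gray_value, 7.0)

    def test_nine_slices_uses_indices_three_to_five(self):
        data = np.zeros((9, 9, 9), np.int32)
        data[:, 2:7, 2:7] = 1
        m = LabelMask(data, (1, 1, 1), {1: "tumor"})
        vol_data = np.zeros((9, 9, 9))
        vol_data[:] = np.arange(9)[:, None, None]  # value = z index
        prof = lsfm.middle_third_profile(VolumeImage(vol_data, (1, 1, 1)), m, axis=0)
        assert prof.gray_value.max() == 5  # slices 3..5 only

    def test_bright_shell_peaks_at_margins(self):
        m = ball_mask((41, 41, 41), (2, 2, 2), (41, 41, 41), 32.0)
        dmap = lsfm.distance_to_surface(m)
        shell = np.where(np.nan_to_num(dmap.values, nan=1e9) < 8.0, 100.0, 10.0)
        shell[~m.binary()] = 0.0
        prof = lsfm.middle_third_profile(
            VolumeImage(shell, (2, 2, 2)), m, reduce="centerline"
        )
        v = prof.gray_value.to_numpy()
        assert v[0] > v[len(v) // 2] and v[-1] > v[len(v) // 2]

    def test_degenerate_extent_rejected(self):
        data = np.zeros((5, 9, 9), np.int32)
        data[2, 2:7, 2:7] = 1
        m = LabelMask(data, (1, 1, 1), {1: "tumor"})
        with pytest.raises(ValueError, match="slices"):
            lsfm.middle_third_profile(VolumeImage(np.zeros((5, 9, 9)), (1, 1, 1)), m)


class TestColorExport:
    def test_ramp_endpoints_and_round_trip(self, tmp_path):
        spots = SpotSet([[0, 0, 0], [10, 10, 10], [5, 5, 5]], 4, 1)
        df = lsfm.colorcode_spots(spots, np.array([0.0, 100.0, 50.0]))
        assert tuple(df.loc[0, ["red", "green", "blue"]]) == (255, 0, 0)
        assert tuple(df.loc[1, ["red", "green", "blue"]]) == (0, 0, 255)
        p = tmp_path / "spots.ply"
        lsfm.write_ply(p, df)
        back = lsfm.read_ply(p)
        assert np.array_equal(back[["red", "green", "blue"]], df[["red", "green", "blue"]])

    def test_single_spot_maps_to_midpoint(self):
        df = lsfm.colorcode_spots(SpotSet([[1, 2, 3]], 4, 1), np.array([42.0]))
        assert df.loc[0, "red"] == 128 and df.loc[0, "blue"] == 128
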