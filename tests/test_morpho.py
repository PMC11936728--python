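import math

import numpy as np
import pandas as pd
import pytest

from capflow.morpho import (
    blood_volume_fraction,
    diameter_limit_um,
    filter_capillaries,
    length_density,
    plaque_quantify,
    polyline_length,
    region_volume,
    relative_sd_increase,
    segment_diameters,
    segmentation_metrics,
    tortuosity,
)
from capflow.synthdata import (
    PlaqueSpec,
    SegmentSpec,
    VolumeGroundTruth,
    make_vessel_volume,
)


@pytest.fixture(scope="module")
def straight_tube():
    pts = np.array([[20.0, 30.0, 5.0], [20.0, 30.0, 58.0]])
    truth = VolumeGroundTruth(
        shape=(40, 64, 64),
        segments=[SegmentSpec(pts, radius_um=3.0)],
    )
    return make_vessel_volume(truth)


class TestSegmentDiameters:
    def test_cylinder_diameter_within_half_voxel(self, straight_tube):
        binary, skeleton, _, truth_table = straight_tube
        table = segment_diameters(binary, skeleton)
        assert len(table) == 1
        assert table["diameter_um"].iloc[0] == pytest.approx(
            truth_table["diameter_um"].iloc[0], abs=0.5
        )
        assert table["diameter_sd_um"].iloc[0] < 0.5

    def test_varying_radius_tube_has_positive_sd(self):
        a = SegmentSpec(
            np.array([[20.0, 30.0, 5.0], [20.0, 30.0, 30.0]]), radius_um=3.0
        )
        b = SegmentSpec(
            np.array([[20.0, 30.0, 30.0], [20.0, 30.0, 58.0]]), radius_um=5.0
        )
        truth = VolumeGroundTruth(shape=(44, 64, 64), segments=[a, b])
        with pytest.warns(UserWarning):  # the two tubes touch at the joint
            binary, skeleton, _, _ = make_vessel_volume(truth)
        merged = (skeleton > 0).astype(int)  # one segment, two radii
        table = segment_diameters(binary, merged)
        d = table["diameter_um"].iloc[0]
        assert 6.0 < d < 10.0
        assert table["diameter_sd_um"].iloc[0] > 0.5

    def test_single_voxel_line_limit(self):
        # degenerate 1-voxel-wide line: the nearest background voxel
        # center is one voxel away, so the convention reports 2 voxels
        binary = np.zeros((5, 5, 20), dtype=bool)
        binary[2, 2, 2:18] = True
        skeleton = binary.astype(int)
        table = segment_diameters(binary, skeleton)
        assert table["diameter_um"].iloc[0] == pytest.approx(2.0)

    def test_anisotropic_voxels_use_physical_distance(self):
        binary = np.zeros((9, 9, 20), dtype=bool)
        binary[3:6, 3:6, 2:18] = True
        skeleton = np.zeros_like(binary, dtype=int)
        skeleton[4, 4, 2:18] = 1
        iso = segment_diameters(binary, skeleton, (1.0, 1.0, 1.0))
        stretched = segment_diameters(binary, skeleton, (2.0, 1.0, 1.0))
        # background is nearer in y/x than along stretched z
        assert stretched["diameter_um"].iloc[0] == pytest.approx(
            iso["diameter_um"].iloc[0]
        )

    def test_skeleton_outside_mask_rejected(self):
        binary = np.zeros((4, 4, 4), dtype=bool)
        skeleton = np.zeros((4, 4, 4), dtype=int)
        skeleton[1, 1, 1] = 1
        with pytest.raises(ValueError):
            segment_diameters(binary, skeleton)


class TestFilterCapillaries:
    def test_limit_from_pixels(self):
        assert diameter_limit_um(8, 1.15) == pytest.approx(9.2)

    def test_all_small_kept(self):
        table = pd.DataFrame({"diameter_um": [5.0, 4.2, 6.1]})
        out = filter_capillaries(table)
        assert len(out) == 3
        assert out.attrs["n_before"] == 3

    def test_large_vessel_removed(self):
        table = pd.DataFrame({"diameter_um": [5.0, 12.0, 5.5]})
        out = filter_capillaries(table)
        assert len(out) == 2
        assert 12.0 not in out["diameter_um"].values


class TestTortuosity:
    def test_straight_segment(self):
        pts = np.array([[0.0, 0.0, 0.0], [0.0, 5.0, 5.0], [0.0, 10.0, 10.0]])
        assert tortuosity(pts) == pytest.approx(1.0)

    def test_semicircle_is_half_pi(self):
        theta = np.linspace(0.0, np.pi, 400)
        pts = np.stack(
            [np.zeros_like(theta), 10 * np.sin(theta), 10 * np.cos(theta)],
            axis=1,
        )
        assert tortuosity(pts) == pytest.approx(np.pi / 2, rel=0.01)

    def test_random_walk_matches_brute_force(self):
        rng = np.random.default_rng(4)
        pts = np.cumsum(rng.normal(size=(30, 3)), axis=0)
        arc = sum(
            math.dist(pts[i], pts[i + 1]) for i in range(len(pts) - 1)
        )
        chord = math.dist(pts[0], pts[-1])
        assert tortuosity(pts) == pytest.approx(arc / chord)
        assert polyline_length(pts) == pytest.approx(arc)

    def test_tortuosity_at_least_one(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            pts = np.cumsum(rng.normal(size=(12, 3)), axis=0)
            assert tortuosity(pts) >= 1.0 - 1e-12

    def test_closed_loop_flagged(self):
        pts = np.array([[0.0, 0, 0], [0, 1, 0], [0, 1, 1], [0.0, 0, 0]])
        with pytest.raises(ValueError):
            tortuosity(pts)


class TestDensities:
    def test_length_density_arithmetic(self):
        table = pd.DataFrame({"length_um": [100.0]})
        assert length_density(table, 0.001) == pytest.approx(100_000.0)

    def test_empty_table_zero(self):
        assert length_density(pd.DataFrame({"length_um": []}), 1.0) == 0.0

    def test_generated_volume_skeleton_length_near_truth(self, straight_tube):
        binary, skeleton, _, truth_table = straight_tube
        # length measured from the rasterized centerline voxels
        zz, yy, xx = np.nonzero(skeleton)
        order = np.argsort(xx)
        pts = np.stack([zz[order], yy[order], xx[order]], axis=1).astype(float)
        measured = polyline_length(pts)
        vol_uL = binary.size * 1.0e-9  # 1 µm³ voxels; 1 µL = 1e9 µm³
        assert length_density(
            pd.DataFrame({"length_um": [measured]}), vol_uL
        ) == pytest.approx(
            truth_table["length_um"].sum() / vol_uL, rel=0.02
        )

    def test_blood_volume_empty(self):
        assert blood_volume_fraction(np.zeros((4, 4, 4), bool)) == 0.0

    def test_blood_volume_half_filled(self):
        vol = np.zeros((4, 4, 4), bool)
        vol[:2] = True
        assert blood_volume_fraction(vol) == pytest.approx(0.5)

    def test_cylinder_volume_analytic(self, straight_tube):
        binary, _, _, truth_table = straight_tube
        frac = blood_volume_fraction(binary)
        expected = truth_table["volume_um3"].iloc[0] / binary.size
        assert frac == pytest.approx(expected, rel=0.12)  # rasterization

    def test_additive_over_disjoint_subvolumes(self, straight_tube):
        binary, _, _, _ = straight_tube
        whole = blood_volume_fraction(binary)
        left = binary[:, :, :32]
        right = binary[:, :, 32:]
        combined = (
            blood_volume_fraction(left) * left.size
            + blood_volume_fraction(right) * right.size
        ) / binary.size
        assert combined == pytest.approx(whole)


class TestPlaques:
    def test_empty_mask(self):
        table = plaque_quantify(np.zeros((5, 5, 5), bool))
        assert table.attrs["n_objects"] == 0
        assert table.attrs["burden_pct"] == 0.0

    def test_cube_volume(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[5:15, 5:15, 5:15] = True
        table = plaque_quantify(mask)
        assert table.attrs["n_objects"] == 1
        assert table["volume_um3"].iloc[0] == pytest.approx(1000.0)

    def test_two_spheres_counted_and_measured(self):
        truth = VolumeGroundTruth(
            shape=(40, 64, 64),
            plaques=[
                PlaqueSpec((10.0, 40.0, 20.0), 5.0),
                PlaqueSpec((30.0, 50.0, 45.0), 8.0),
            ],
        )
        _, _, plaque_mask, _ = make_vessel_volume(truth)
        table = plaque_quantify(plaque_mask)
        assert table.attrs["n_objects"] == 2
        analytic = sorted(
            4.0 / 3.0 * math.pi * r**3 for r in (5.0, 8.0)
        )
        measured = sorted(table["volume_um3"])
        for m, a in zip(measured, analytic):
            assert m == pytest.approx(a, rel=0.05)

    def test_burden_bounded_and_size_classes_assigned(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[:2, :2, :2] = True
        table = plaque_quantify(mask, size_class_edges_um3=(5.0, 20.0, 100.0))
        assert 0.0 <= table.attrs["burden_pct"] <= 100.0
        assert table["size_class"].iloc[0] == "small"  # 8 µm³ in (5, 20]


class TestSegmentationMetrics:
    def test_identical_masks(self):
        mask = np.random.default_rng(0).random((4, 5, 5)) > 0.5
        m = segmentation_metrics(mask, mask)
        assert (m.dsc, m.precision, m.recall) == (1.0, 1.0, 1.0)

    def test_disjoint_masks(self):
        a = np.zeros((3, 4, 4), bool)
        b = np.zeros((3, 4, 4), bool)
        a[0], b[2] = True, True
        assert segmentation_metrics(a, b).dsc == 0.0

    def test_half_overlap(self):
        a = np.zeros((1, 10, 20), bool)
        b = np.zeros((1, 10, 20), bool)
        a[0, :, :10] = True  # |A| = 100
        b[0, :, 5:15] = True  # |B| = 100, overlap 50
        m = segmentation_metrics(a, b)
        assert m.dsc == pytest.approx(0.5)
        assert m.precision == pytest.approx(0.5)
        assert m.recall == pytest.approx(0.5)

    def test_both_empty_convention(self):
        empty = np.zeros((2, 2, 2), bool)
        m = segmentation_metrics(empty, empty)
        assert (m.dsc, m.precision, m.recall) == (1.0, 1.0, 1.0)


class TestVolumetrics:
    def test_mri_voxel_volume(self):
        assert region_volume(1, (150.0, 150.0, 200.0)) == pytest.approx(0.0045)

    def test_zero_voxels(self):
        assert region_volume(0, (150.0, 150.0, 200.0)) == 0.0

    def test_thousand_voxels(self):
        assert region_volume(1000, (150.0, 150.0, 200.0)) == pytest.approx(4.5)

    def test_relative_sd_increase_paper_values(self):
        assert relative_sd_increase(0.182, 0.207) == pytest.approx(
            13.73, abs=0.01
        )

    def test_relative_sd_increase_trivial(self):
        assert relative_sd_increase(1.0, 1.0) == 0.0
        assert relative_sd_increase(1.0, 2.0) == pytest.approx(100.0)
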