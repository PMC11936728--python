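import numpy as np
import pytest

from capflow.dilution import gamma_kernel
from capflow.synthdata import (
    BolusShape,
    DecayGroundTruth,
    FlowGroundTruth,
    PlaqueSpec,
    SegmentSpec,
    StallGroundTruth,
    TransportGroundTruth,
    VolumeGroundTruth,
    make_bolus_pair,
    make_decay,
    make_linescan,
    make_stall_series,
    make_vessel_volume,
    random_stall_truth,
    rasterize_stallogram,
    spawn_rngs,
)


class TestDeterminism:
    def test_stall_series_reproducible(self):
        truth = random_stall_truth(10, 20, rng=1)
        a = make_stall_series(truth, snr=5, seed=9)
        b = make_stall_series(truth, snr=5, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_linescan_reproducible(self):
        truth = FlowGroundTruth(duration_s=0.5)
        a = make_linescan(truth, seed=4)
        b = make_linescan(truth, seed=4)
        np.testing.assert_array_equal(a.image, b.image)

    def test_bolus_reproducible(self):
        truth = TransportGroundTruth(noise_sd=0.05)
        a = make_bolus_pair(truth, seed=2)
        b = make_bolus_pair(truth, seed=2)
        np.testing.assert_array_equal(a.vof, b.vof)

    def test_spawned_streams_differ(self):
        r1, r2 = spawn_rngs(0, 2)
        assert r1.random() != r2.random()


class TestStallGenerator:
    def test_no_events_gives_all_zero_raster(self):
        truth = StallGroundTruth(n_segments=5, n_volumes=60)
        np.testing.assert_array_equal(rasterize_stallogram(truth), 0)

    def test_single_event_rasterized_exactly(self):
        truth = StallGroundTruth(
            n_segments=8, n_volumes=60, events=[(3, 10, 6)]
        )
        gram = rasterize_stallogram(truth)
        assert gram.sum() == 6
        assert gram[3, 10:16].sum() == 6

    def test_overlapping_events_merge(self):
        truth = StallGroundTruth(
            n_segments=4, n_volumes=30, events=[(1, 5, 5), (1, 8, 5)]
        )
        gram = rasterize_stallogram(truth)
        assert gram[1].sum() == 8  # union of [5,10) and [8,13)

    def test_event_outside_recording_rejected(self):
        with pytest.raises(ValueError):
            StallGroundTruth(n_segments=4, n_volumes=10, events=[(0, 8, 5)])

    def test_series_shape_and_labels(self):
        truth = StallGroundTruth(n_segments=9, n_volumes=12)
        series, labels, gram = make_stall_series(truth, snr=10, seed=0)
        assert series.shape[0] == 12
        assert series.shape[1:] == labels.shape
        assert set(np.unique(labels)) == set(range(10))
        assert gram.shape == (9, 12)

    def test_stalled_frames_at_background_level(self):
        truth = StallGroundTruth(
            n_segments=4, n_volumes=10, events=[(0, 2, 3)]
        )
        series, labels, _ = make_stall_series(truth, snr=50, seed=1)
        seg = labels == 1
        stalled_mean = series[3][seg].mean()
        flowing_mean = series[0][seg].mean()
        assert abs(stalled_mean) < 0.1
        assert flowing_mean > 0.9


class TestLinescanGenerator:
    def test_axial_streak_geometry(self):
        # 0.23 mm/s at 0.23 µm / 1 ms advances one pixel per line:
        # consecutive lines shift the dark streak by exactly one column
        truth = FlowGroundTruth(
            velocity_mm_s=0.23, flux_cells_s=5, duration_s=0.4
        )
        rec = make_linescan(truth, noise_sd=0.0, seed=0, path="axial")
        dark = rec.image < 0.5
        rows = np.flatnonzero(dark.any(axis=1))
        mid = rows[len(rows) // 2]
        c0 = np.flatnonzero(dark[mid])
        c1 = np.flatnonzero(dark[mid + 1])
        assert np.array_equal(c1, c0 + 1)

    def test_transverse_lumen_width(self):
        truth = FlowGroundTruth(diameter_um=5.0, duration_s=0.2)
        rec = make_linescan(truth, noise_sd=0.0, seed=0, path="transverse")
        bright = rec.image[0] > 0.5
        width_um = bright.sum() * truth.pixel_size_um
        assert width_um == pytest.approx(5.0, abs=2 * truth.pixel_size_um)

    def test_inconsistent_flux_errors(self):
        truth = FlowGroundTruth(
            velocity_mm_s=0.2, flux_cells_s=80.0
        )  # occupancy 2.4
        with pytest.raises(ValueError):
            make_linescan(truth, seed=0)

    def test_polarity_switch(self):
        truth = FlowGroundTruth(duration_s=0.2, flux_cells_s=20)
        normal = make_linescan(truth, noise_sd=0.0, seed=1, path="axial")
        flipped = make_linescan(
            truth, noise_sd=0.0, seed=1, path="axial", invert_polarity=True
        )
        np.testing.assert_allclose(
            flipped.image, normal.image.max() + normal.image.min() - normal.image
        )


class TestBolusGenerator:
    def test_gamma_kernel_moments(self):
        # alpha 4, beta 0.5 s: mean 2.0 s, SD 1.0 s
        t = np.arange(0.0, 40.0, 0.001)
        k = gamma_kernel(t, 4.0, 0.5)
        mass = np.trapezoid(k, t)
        mean = np.trapezoid(t * k, t) / mass
        sd = np.sqrt(np.trapezoid((t - mean) ** 2 * k, t) / mass)
        assert mass == pytest.approx(1.0, abs=1e-6)
        assert mean == pytest.approx(2.0, abs=1e-6)
        assert sd == pytest.approx(1.0, abs=1e-6)

    def test_transit_longer_than_record_rejected(self):
        truth = TransportGroundTruth(alpha=30.0, beta=1.0)
        with pytest.raises(ValueError):
            make_bolus_pair(truth, aif=BolusShape(duration_s=20.0), seed=0)

    def test_snr_overrides_noise(self):
        truth = TransportGroundTruth(noise_sd=0.0)
        clean = make_bolus_pair(truth, seed=5)
        noisy = make_bolus_pair(truth, seed=5, snr=20)
        resid = noisy.vof - clean.vof
        assert resid.std() == pytest.approx(clean.vof.max() / 20, rel=0.2)


class TestDecayGenerator:
    def test_noiseless_log_counts_linear_in_time(self):
        truth = DecayGroundTruth(tau_us=30.0, background=0.0)
        decay = make_decay(truth, seed=0, poisson=False)
        slope = np.polyfit(decay.t_us, np.log(decay.counts), 1)[0]
        assert slope == pytest.approx(-1.0 / 30.0, rel=1e-9)

    def test_short_window_warns(self):
        truth = DecayGroundTruth(tau_us=400.0)
        with pytest.warns(UserWarning):
            make_decay(truth, seed=0, span_us=290.0)

    def test_noise_scales_with_sweep_count(self):
        truth_few = DecayGroundTruth(tau_us=30.0, n_sweeps=10)
        truth_many = DecayGroundTruth(tau_us=30.0, n_sweeps=15000)
        clean = make_decay(truth_many, seed=0, poisson=False).counts
        r_few = make_decay(truth_few, seed=1).counts - clean
        r_many = make_decay(truth_many, seed=1).counts - clean
        assert r_few.std() > 10 * r_many.std()


class TestVolumeGenerator:
    def test_straight_tube_truth_table(self):
        pts = np.array([[10.0, 10.0, 2.0], [10.0, 10.0, 30.0]])
        truth = VolumeGroundTruth(
            shape=(20, 20, 32), segments=[SegmentSpec(pts, radius_um=3.0)]
        )
        _, _, _, table = make_vessel_volume(truth)
        assert table["tortuosity"].iloc[0] == pytest.approx(1.0)
        assert table["length_um"].iloc[0] == pytest.approx(28.0)
        assert table["diameter_um"].iloc[0] == 6.0

    def test_segment_leaving_volume_rejected(self):
        pts = np.array([[10.0, 10.0, 2.0], [10.0, 10.0, 60.0]])
        truth = VolumeGroundTruth(
            shape=(20, 20, 32), segments=[SegmentSpec(pts, radius_um=2.0)]
        )
        with pytest.raises(ValueError):
            make_vessel_volume(truth)

    def test_intersecting_tubes_warn(self):
        a = SegmentSpec(
            np.array([[10.0, 10.0, 2.0], [10.0, 10.0, 30.0]]), radius_um=2.0
        )
        b = SegmentSpec(
            np.array([[10.0, 2.0, 15.0], [10.0, 18.0, 15.0]]), radius_um=2.0
        )
        truth = VolumeGroundTruth(shape=(20, 20, 32), segments=[a, b])
        with pytest.warns(UserWarning):
            make_vessel_volume(truth)

    def test_disjoint_plaques_stay_disjoint(self):
        truth = VolumeGroundTruth(
            shape=(30, 30, 30),
            plaques=[
                PlaqueSpec((8.0, 8.0, 8.0), 3.0),
                PlaqueSpec((22.0, 22.0, 22.0), 4.0),
            ],
        )
        _, _, mask, _ = make_vessel_volume(truth)
        from scipy import ndimage

        _, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        assert n == 2

    def test_rasterized_radius_within_half_voxel(self):
        pts = np.array([[10.0, 10.0, 2.0], [10.0, 10.0, 30.0]])
        truth = VolumeGroundTruth(
            shape=(20, 20, 32), segments=[SegmentSpec(pts, radius_um=3.0)]
        )
        binary, _, _, _ = make_vessel_volume(truth)
        # width of the tube through its axis, in voxels
        width = binary[:, 10, 16].sum()
        assert abs(width - 6.0) <= 1.0  # 2 x half a voxel
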