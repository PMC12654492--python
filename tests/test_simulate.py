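import numpy as np
import pytest

from beadquant import (
    ArrayLayout,
    CircularROI,
    LogLinearResponse,
    OpticsParams,
    SignalModel,
    measure_intensity,
    random_occupancy,
    render_dilution_series,
    render_pair,
    write_ground_truth,
    read_detections,
)
from beadquant.errors import ImageSizeError, ValidationError
from beadquant.simulate import default_image_shape


class TestRenderPair:
    def test_noiseless_roi_means_equal_background_plus_signal(self, small_layout, clean_optics):
        """With no noise and CV 0, every bead's disk mean reads bg + amplitude."""
        occ = random_occupancy(small_layout, 1.0, 0)
        signal = SignalModel(positive_fraction=1.0, signal_cv=0.0)
        _, fl, gt = render_pair(small_layout, occ, clean_optics, signal, seed=1)
        expected = signal.background_level + signal.mean_signal
        for cx, cy in gt.centers:
            m = measure_intensity(fl, CircularROI(cx=cx, cy=cy, r=gt.radius_px))
            # 16-bit quantization leaves sub-gray-level residuals only
            assert m.mean_intensity == pytest.approx(expected, abs=0.5)

    def test_zero_blur_is_exact_up_to_quantization(self, small_layout):
        optics = OpticsParams(noise_sd=0.0, background_gradient=0.0, blur_sigma_px=0.0)
        occ = random_occupancy(small_layout, 1.0, 0)
        signal = SignalModel(positive_fraction=1.0, signal_cv=0.0)
        _, fl, gt = render_pair(small_layout, occ, optics, signal, seed=1)
        m = measure_intensity(fl, CircularROI(cx=gt.centers[0, 0], cy=gt.centers[0, 1], r=gt.radius_px))
        assert m.mean_intensity == pytest.approx(
            signal.background_level + signal.mean_signal, abs=0.5
        )

    def test_blank_condition_reads_background_only(self, small_layout, clean_optics):
        occ = random_occupancy(small_layout, 1.0, 0)
        signal = SignalModel(positive_fraction=0.0)
        _, fl, gt = render_pair(small_layout, occ, clean_optics, signal, seed=1)
        assert np.all(gt.true_signal == 0)
        for cx, cy in gt.centers[:5]:
            m = measure_intensity(fl, CircularROI(cx=cx, cy=cy, r=gt.radius_px))
            assert m.mean_intensity == pytest.approx(signal.background_level, abs=0.5)

    def test_full_reference_array_has_590_centers(self, reference_layout, default_optics):
        occ = random_occupancy(reference_layout, 1.0, 0)
        bf, fl, gt = render_pair(reference_layout, occ, default_optics, SignalModel(), seed=3)
        assert gt.n_beads == 590
        assert bf.shape == fl.shape
        assert bf.dtype == fl.dtype == np.uint16

    def test_channels_share_geometry_and_truth_is_complete(self, small_pair, small_layout):
        bf, fl, gt = small_pair
        assert bf.shape == fl.shape
        assert gt.n_beads == gt.occupancy.n_occupied == small_layout.total_traps
        assert len(gt.true_signal) == gt.n_beads

    def test_fixed_seed_reproduces_bit_identical_images(self, small_layout, default_optics):
        occ = random_occupancy(small_layout, 0.7, 5)
        args = (small_layout, occ, default_optics, SignalModel(positive_fraction=0.5))
        bf1, fl1, gt1 = render_pair(*args, seed=9)
        bf2, fl2, gt2 = render_pair(*args, seed=9)
        assert np.array_equal(bf1, bf2) and np.array_equal(fl1, fl2)
        assert np.array_equal(gt1.true_signal, gt2.true_signal)
        bf3, _, _ = render_pair(*args, seed=10)
        assert not np.array_equal(bf1, bf3)

    def test_mixture_has_exact_positive_count_and_zero_mass(self, small_layout, clean_optics):
        occ = random_occupancy(small_layout, 1.0, 0)
        signal = SignalModel(positive_fraction=0.5)
        _, _, gt = render_pair(small_layout, occ, clean_optics, signal, seed=4)
        n_pos = int((gt.true_signal > 0).sum())
        assert n_pos == round(0.5 * gt.n_beads)
        assert np.all(gt.true_signal[gt.true_signal <= 0] == 0)

    def test_too_small_image_raises_sizing_error(self, small_layout, default_optics):
        occ = random_occupancy(small_layout, 1.0, 0)
        min_shape = default_image_shape(small_layout, default_optics)
        with pytest.raises(ImageSizeError, match="requires at least"):
            render_pair(
                small_layout, occ, default_optics, SignalModel(), seed=0,
                shape=(min_shape[0] - 10, min_shape[1]),
            )


class TestGroundTruthAnnotations:
    def test_single_centered_bead_line(self, tmp_path):
        from beadquant.simulate import GroundTruth
        from beadquant.geometry import OccupancyMap

        layout = ArrayLayout(n_rows=1, pillars_per_row=2)
        occ = OccupancyMap(layout, np.array([True]))
        gt = GroundTruth(
            centers=np.array([[50.0, 40.0]]), radius_px=10.0,
            true_signal=np.array([0.0]), occupancy=occ,
        )
        path = tmp_path / "gt.txt"
        write_ground_truth(gt, (80, 100), path)
        assert path.read_text().strip() == "0 0.500000 0.500000 0.200000 0.250000"

    def test_roundtrip_with_read_detections(self, small_pair, tmp_path):
        bf, _, gt = small_pair
        path = tmp_path / "gt.txt"
        write_ground_truth(gt, bf.shape, path)
        boxes = read_detections(path, bf.shape)
        assert len(boxes) == gt.n_beads
        centers = np.array([b.center for b in boxes])
        # annotations are written row-major in trap order; match directly
        assert np.allclose(centers, gt.centers, atol=1e-2)
        assert np.allclose([b.w for b in boxes], 2 * gt.radius_px, atol=1e-2)

    def test_empty_truth_writes_empty_file(self, tmp_path):
        from beadquant.simulate import GroundTruth
        from beadquant.geometry import OccupancyMap

        layout = ArrayLayout(n_rows=1, pillars_per_row=2)
        occ = OccupancyMap(layout, np.array([False]))
        gt = GroundTruth(
            centers=np.empty((0, 2)), radius_px=10.0,
            true_signal=np.empty(0), occupancy=occ,
        )
        path = tmp_path / "gt.txt"
        write_ground_truth(gt, (100, 100), path)
        assert path.read_text() == ""

    def test_out_of_frame_bead_rejected(self, tmp_path):
        from beadquant.simulate import GroundTruth
        from beadquant.geometry import OccupancyMap

        layout = ArrayLayout(n_rows=1, pillars_per_row=2)
        occ = OccupancyMap(layout, np.array([True]))
        gt = GroundTruth(
            centers=np.array([[5.0, 5.0]]), radius_px=10.0,
            true_signal=np.array([0.0]), occupancy=occ,
        )
        with pytest.raises(ValidationError, match="out of frame"):
            write_ground_truth(gt, (100, 100), tmp_path / "gt.txt")


class TestDilutionSeries:
    def test_series_counts_and_blanks(self, small_layout, clean_optics):
        concs = [10.0**k for k in range(1, 8)]
        pairs = render_dilution_series(
            small_layout, clean_optics, SignalModel(), concs, replicates=3, seed=0
        )
        assert len(pairs) == 24  # 7 concentrations x 3 + 3 blanks
        blanks = [p for p in pairs if p.condition == "blank"]
        assert len(blanks) == 3
        assert all(p.concentration == 0.0 for p in blanks)
        assert all(np.all(p.ground_truth.true_signal == 0) for p in blanks)

    def test_validation_of_concentrations(self, small_layout, clean_optics):
        with pytest.raises(ValidationError, match="strictly positive"):
            render_dilution_series(small_layout, clean_optics, SignalModel(), [0.0, 10.0])
        with pytest.raises(ValidationError, match="strictly increasing"):
            render_dilution_series(small_layout, clean_optics, SignalModel(), [100.0, 10.0])
        with pytest.raises(ValidationError, match="replicates"):
            render_dilution_series(
                small_layout, clean_optics, SignalModel(), [10.0, 100.0, 1000.0], replicates=0
            )

    def test_noiseless_means_linear_in_log_concentration(self, small_layout, clean_optics):
        """Default response: disk means follow bg + s*log10(c) exactly."""
        concs = [1e2, 1e4, 1e6]
        resp = LogLinearResponse(slope_per_decade=1000.0)
        signal = SignalModel(signal_cv=0.0)
        pairs = render_dilution_series(
            small_layout, clean_optics, signal, concs, response=resp, replicates=1, seed=0
        )
        means = {}
        for p in pairs:
            if p.condition == "blank":
                continue
            gt = p.ground_truth
            vals = [
                measure_intensity(
                    p.fluorescence, CircularROI(cx=cx, cy=cy, r=gt.radius_px)
                ).mean_intensity
                for cx, cy in gt.centers[:10]
            ]
            means[p.concentration] = np.mean(vals)
        for c, m in means.items():
            expected = signal.background_level + 1000.0 * np.log10(c)
            assert m == pytest.approx(expected, abs=0.5)

    def test_zero_slope_response_indistinguishable_from_blank(self, small_layout, clean_optics):
        resp = LogLinearResponse(slope_per_decade=0.0)
        pairs = render_dilution_series(
            small_layout, clean_optics, SignalModel(signal_cv=0.0),
            [10.0, 1000.0, 100000.0], response=resp, replicates=1, seed=0,
        )
        for p in pairs:
            assert np.all(p.ground_truth.true_signal == 0)

    def test_series_seeding_is_deterministic(self, small_layout, clean_optics):
        concs = [10.0, 1000.0, 100000.0]
        a = render_dilution_series(small_layout, clean_optics, SignalModel(), concs, replicates=2, seed=7)
        b = render_dilution_series(small_layout, clean_optics, SignalModel(), concs, replicates=2, seed=7)
        for pa, pb in zip(a, b):
            assert pa.seed == pb.seed
            assert np.array_equal(pa.fluorescence, pb.fluorescence)
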