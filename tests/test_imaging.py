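"""Segmentation, ROI growth, intensity normalization, lane densitometry."""

import numpy as np
import pytest

from transquant import imaging
from transquant.simulate import ImageSimConfig, gen_images
from transquant.simulate.images import PlacementError, _disk_mask


class TestSegmentNuclei:
    def test_recovers_simulated_nucleus_count(self):
        (hoechst, _, _), truth = gen_images(ImageSimConfig(n_cells=5, seed=1))
        nuclei = imaging.segment_nuclei(hoechst)
        assert nuclei.max() == 5
        assert len(truth.table("cells")) == 5

    def test_blank_image_yields_zero_nuclei(self):
        blank = np.zeros((64, 64))
        assert imaging.segment_nuclei(blank).max() == 0

    def test_touching_disks_merge_into_one_component(self):
        """Global thresholding cannot separate abutting nuclei."""
        img = np.zeros((64, 64))
        img[_disk_mask((64, 64), 30, 25, 6)] = 100.0
        img[_disk_mask((64, 64), 30, 35, 6)] = 100.0
        nuclei = imaging.segment_nuclei(img, threshold=50.0)
        assert nuclei.max() == 1

    def test_min_area_filter(self):
        img = np.zeros((64, 64))
        img[_disk_mask((64, 64), 20, 20, 6)] = 100.0
        img[10, 50] = 100.0  # single bright pixel
        nuclei = imaging.segment_nuclei(img, min_area=5, threshold=50.0)
        assert nuclei.max() == 1


class TestGrowCells:
    def test_single_cell_roi_equals_eif3b_disk(self):
        shape = (64, 64)
        hoechst = np.zeros(shape)
        eif3b = np.zeros(shape)
        hoechst[_disk_mask(shape, 32, 32, 5)] = 100.0
        cell = _disk_mask(shape, 32, 32, 14)
        eif3b[cell] = 100.0
        nuclei = imaging.segment_nuclei(hoechst, threshold=50.0)
        rois = imaging.grow_cells(nuclei, eif3b, threshold=50.0)
        assert np.array_equal(rois > 0, cell)

    def test_two_separated_cells_get_disjoint_rois(self):
        (hoechst, eif3b, _), truth = gen_images(
            ImageSimConfig(n_cells=4, noise_sd=0.0, seed=2))
        nuclei = imaging.segment_nuclei(hoechst)
        rois = imaging.grow_cells(nuclei, eif3b)
        labels = np.unique(rois)
        # every ROI contains exactly one nucleus
        for lab in labels[labels != 0]:
            inside = np.unique(nuclei[(rois == lab) & (nuclei > 0)])
            assert inside.size == 1

    def test_nucleus_without_cytoplasm_keeps_nucleus_roi(self):
        shape = (64, 64)
        hoechst = np.zeros(shape)
        nucleus = _disk_mask(shape, 32, 32, 5)
        hoechst[nucleus] = 100.0
        nuclei = imaging.segment_nuclei(hoechst, threshold=50.0)
        rois = imaging.grow_cells(nuclei, np.zeros(shape), threshold=50.0)
        assert np.array_equal(rois > 0, nucleus)

    def test_border_cells_excluded_by_default(self):
        shape = (64, 64)
        hoechst = np.zeros(shape)
        eif3b = np.zeros(shape)
        hoechst[_disk_mask(shape, 10, 10, 4)] = 100.0
        eif3b[_disk_mask(shape, 10, 10, 12)] = 100.0  # reaches the border
        nuclei = imaging.segment_nuclei(hoechst, threshold=50.0)
        assert imaging.grow_cells(nuclei, eif3b, threshold=50.0).max() == 0
        kept = imaging.grow_cells(nuclei, eif3b, threshold=50.0,
                                  exclude_border=False)
        assert kept.max() == 1


class TestMeasureAndNormalize:
    def _rois(self, means):
        """One image with len(means) single-pixel-valued square ROIs."""
        rois = np.zeros((40, 40), dtype=np.int32)
        img = np.zeros((40, 40))
        for i, m in enumerate(means, start=1):
            rois[5 * i:5 * i + 3, 5:8] = i
            img[5 * i:5 * i + 3, 5:8] = m
        return rois, img

    def test_treated_normalized_to_control_mean(self):
        ctrl_rois, ctrl_img = self._rois([100.0, 100.0])
        trt_rois, trt_img = self._rois([60.0, 60.0])
        res = imaging.measure_and_normalize(
            {"control": [ctrl_rois], "treated": [trt_rois]},
            {"control": [ctrl_img], "treated": [trt_img]}, control="control")
        assert res.normalized_means["treated"] == pytest.approx(0.6)
        assert res.normalized_means["control"] == pytest.approx(1.0)

    def test_scaling_equivariance_is_exact(self):
        rois, img = self._rois([80.0, 120.0, 40.0])
        res1 = imaging.measure_and_normalize(
            {"control": [rois], "t": [rois]},
            {"control": [img], "t": [img * 0.5]}, control="control")
        res2 = imaging.measure_and_normalize(
            {"control": [rois], "t": [rois]},
            {"control": [img * 13.0], "t": [img * 6.5]}, control="control")
        assert (res1.normalized_means["t"]
                == pytest.approx(res2.normalized_means["t"], rel=1e-12))

    def test_missing_control_rejected(self):
        rois, img = self._rois([10.0])
        with pytest.raises(ValueError):
            imaging.measure_and_normalize({"t": [rois]}, {"t": [img]},
                                          control="control")

    def test_condition_ratio_recovered_from_simulated_images(self):
        """Full segmentation chain recovers the treated/control intensity
        ratio against the per-draw ground truth within 5%."""
        results = {}
        truths = {}
        for cond, mean, seed in (("control", 1000.0, 10), ("treated", 600.0, 11)):
            (hoechst, eif3b, puromycin), truth = gen_images(
                ImageSimConfig(n_cells=20, puromycin_mean=mean, seed=seed))
            nuclei = imaging.segment_nuclei(hoechst)
            rois = imaging.grow_cells(nuclei, eif3b)
            results[cond] = (rois, puromycin)
            truths[cond] = truth.table("cells")["true_mean_puromycin"].mean()
        res = imaging.measure_and_normalize(
            {c: [v[0]] for c, v in results.items()},
            {c: [v[1]] for c, v in results.items()}, control="control")
        estimated = res.normalized_means["treated"]
        expected = truths["treated"] / truths["control"]
        assert estimated == pytest.approx(expected, rel=0.05)


class TestLaneDensitometry:
    def test_identical_lanes_are_unity(self):
        lane = np.array([1.0, 4.0, 2.0, 1.0])
        load = np.array([2.0, 2.0, 2.0, 2.0])
        ctrl = imaging.lane_densitometry(lane, load)
        res = imaging.lane_densitometry(lane, load, control=ctrl)
        assert res.relative_to_control == pytest.approx(1.0)

    def test_halved_signal_and_doubled_loading(self):
        lane = np.array([1.0, 4.0, 2.0, 1.0])
        load = np.ones(4)
        ctrl = imaging.lane_densitometry(lane, load)
        halved = imaging.lane_densitometry(lane * 0.5, load, control=ctrl)
        assert halved.relative_to_control == pytest.approx(0.5)
        overloaded = imaging.lane_densitometry(lane, load * 2.0, control=ctrl)
        assert overloaded.relative_to_control == pytest.approx(0.5)

    def test_zero_loading_rejected(self):
        with pytest.raises(ValueError):
            imaging.lane_densitometry(np.ones(4), np.zeros(4))


class TestImageSimulator:
    def test_zero_cells_gives_background_only(self):
        (hoechst, eif3b, puromycin), truth = gen_images(
            ImageSimConfig(n_cells=0, noise_sd=0.0, seed=0))
        assert np.all(hoechst == 100.0) and np.all(puromycin == 100.0)
        assert truth.table("cells").empty

    def test_fixed_seed_reproducible(self):
        cfg = ImageSimConfig(n_cells=6, seed=3)
        (a, _, _), _ = gen_images(cfg)
        (b, _, _), _ = gen_images(cfg)
        np.testing.assert_array_equal(a, b)

    def test_impossible_placement_raises(self):
        with pytest.raises(PlacementError):
            gen_images(ImageSimConfig(image_shape=(96, 96), n_cells=50,
                                      max_attempts=200, seed=0))

    def test_noise_free_ratio_by_construction(self):
        (_, _, p1), t1 = gen_images(ImageSimConfig(
            n_cells=3, noise_sd=0.0, cell_lognormal_sd=0.0,
            puromycin_mean=1000.0, seed=4))
        (_, _, p2), t2 = gen_images(ImageSimConfig(
            n_cells=3, noise_sd=0.0, cell_lognormal_sd=0.0,
            puromycin_mean=500.0, seed=4))
        r = (t2.table("cells")["true_mean_puromycin"].mean()
             / t1.table("cells")["true_mean_puromycin"].mean())
        assert r == pytest.approx(0.5)


def test_plot_helpers_render(tmp_path):
    import matplotlib
    matplotlib.use("Agg")
    from transquant import plots
    from transquant import polysome as P
    from transquant.simulate import TraceSimConfig, gen_trace
    tr, _ = gen_trace(TraceSimConfig(seed=0))
    ax = plots.plot_trace(tr, P.detect_peaks(tr))
    assert ax.get_xlabel() == "elution position"
    import pandas as pd
    table = pd.DataFrame({"passes_filter": [True, True],
                          "rd_control": [1.0, 2.0],
                          "rd_treated": [0.5, 1.0]})
    assert plots.plot_rd_scatter(table) is not None
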