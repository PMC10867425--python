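"""Image core: projection, detection, mask photometry, ring, ratios."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from civa.quantify import (
    DetectConfig,
    ImageStack,
    LabelMask,
    RingConfig,
    cell_and_ring,
    crescent_class,
    crescent_thresholds,
    detect_particles,
    estimate_background,
    kc_cyto_ratio,
    measure_in_mask,
    project_stack,
    quantify_stack,
)
from civa.simulate import ImageSimConfig, sim_image_stack


def _match(det_xy, truth_xy, tol=2.0):
    d, j = cKDTree(truth_xy).query(det_xy)
    matched = d <= tol
    return matched, j


class TestProjection:
    def test_single_z_identity(self):
        data = np.random.default_rng(0).random((2, 1, 2, 8, 8))
        stack = ImageStack(data, ["reference", "measurement"], 0.1)
        assert np.array_equal(project_stack(stack, "max"), data[:, 0])

    def test_max_picks_per_column_maxima(self):
        data = np.zeros((1, 3, 2, 4, 4))
        data[0, 1, 0, 2, 2] = 9.0
        stack = ImageStack(data, ["reference", "measurement"], 0.1)
        assert project_stack(stack, "max")[0, 0, 2, 2] == 9.0

    def test_mean_of_constant(self):
        data = np.full((1, 3, 2, 4, 4), 7.0)
        stack = ImageStack(data, ["reference", "measurement"], 0.1)
        assert np.allclose(project_stack(stack, "mean"), 7.0)


class TestDetect:
    def test_noise_free_spots_recovered_with_subpixel_centroids(self, clean_stack):
        cfg, stack, truth = clean_stack
        ref = project_stack(stack)[0, 0]
        mask = detect_particles(ref)
        assert mask.n_particles == 2 * cfg.n_pairs
        truth_xy = truth.spots[truth.spots.frame == 0][["y_px", "x_px"]].to_numpy()
        matched, j = _match(mask.centroids(), truth_xy, tol=1.0)
        assert matched.all() and len(set(j)) == len(truth_xy)

    def test_uniform_image_yields_empty_mask(self):
        assert detect_particles(np.full((32, 32), 5.0)).n_particles == 0

    def test_single_pixel_impulse_removed_by_size_filter(self):
        img = np.zeros((32, 32))
        img[16, 16] = 100.0
        mask = detect_particles(img, DetectConfig(min_size_px=4))
        assert mask.n_particles == 0

    def test_label_mask_invariants(self, noisy_stack):
        _, stack, _ = noisy_stack
        mask = detect_particles(project_stack(stack)[0, 0])
        labels = mask.table["label"].tolist()
        assert labels == list(range(1, len(labels) + 1))
        assert (mask.table["area_px"] >= 4).all()


class TestMeasureInMask:
    def test_constant_image(self):
        labels = np.zeros((6, 6), dtype=int)
        labels[1:3, 1:3] = 1
        mask = LabelMask(labels, pd.DataFrame({"label": [1], "area_px": [4],
                                               "y_px": [1.5], "x_px": [1.5]}))
        out = measure_in_mask(mask, np.full((6, 6), 3.5))
        assert out["mean"].tolist() == [3.5]

    def test_hand_computed_means_on_counter_image(self):
        img = np.arange(36, dtype=float).reshape(6, 6)
        labels = np.zeros((6, 6), dtype=int)
        labels[0, 0:2] = 1          # pixels 0, 1 -> mean 0.5
        labels[5, 4:6] = 2          # pixels 34, 35 -> mean 34.5
        mask = LabelMask(labels, pd.DataFrame({"label": [1, 2], "area_px": [2, 2],
                                               "y_px": [0, 5], "x_px": [0.5, 4.5]}))
        out = measure_in_mask(mask, img)
        assert out["mean"].tolist() == [0.5, 34.5]

    def test_one_row_per_label_and_empty(self, noisy_stack):
        _, stack, _ = noisy_stack
        proj = project_stack(stack)
        mask = detect_particles(proj[0, 0])
        out = measure_in_mask(mask, proj[0, 1])
        assert out["label"].tolist() == mask.table["label"].tolist()
        empty = LabelMask(np.zeros((4, 4), int),
                          pd.DataFrame(columns=["label", "area_px", "y_px", "x_px"]))
        assert measure_in_mask(empty, np.zeros((4, 4))).empty

    def test_shape_mismatch(self):
        mask = LabelMask(np.zeros((4, 4), int),
                         pd.DataFrame(columns=["label", "area_px", "y_px", "x_px"]))
        with pytest.raises(ValueError):
            measure_in_mask(mask, np.zeros((5, 5)))


class TestCellAndRing:
    def _disk_image(self, radius=50, size=128, level=100.0):
        yy, xx = np.mgrid[0:size, 0:size]
        c = (size - 1) / 2
        return ((yy - c) ** 2 + (xx - c) ** 2 <= radius**2) * level + 10.0

    def test_ring_is_erosion_difference_on_disk(self):
        img = self._disk_image()
        cfg = RingConfig(smooth_sigma=0.0, erode_outer_px=5, erode_inner_px=15)
        cell, ring = cell_and_ring(img, cfg)
        outer = ndi.binary_erosion(cell, ndi.generate_binary_structure(2, 1), iterations=5)
        inner = ndi.binary_erosion(cell, ndi.generate_binary_structure(2, 1), iterations=15)
        # same construction: ring area equals the two erosion areas' difference
        assert ring.sum() == outer.sum() - inner.sum()
        assert (ring & ~cell).sum() == 0  # ring inside cell

    def test_ring_excludes_particles(self, clean_stack):
        _, stack, truth = clean_stack
        meas = project_stack(stack)[0, 1]
        particles = truth.mask(0).labels
        cell, ring = cell_and_ring(meas, particle_mask=particles)
        assert not (ring & (particles > 0)).any()

    def test_blank_image_raises(self):
        with pytest.raises(ValueError, match="no cell"):
            cell_and_ring(np.zeros((32, 32)))

    def test_bad_ring_geometry(self):
        with pytest.raises(ValueError):
            cell_and_ring(self._disk_image(), RingConfig(erode_outer_px=15, erode_inner_px=5))


class TestRatio:
    def test_unity_when_spot_equals_ring(self):
        (m,) = kc_cyto_ratio(0, [1], [10.0], [200.0], ring_mean=200.0, background=0.0)
        assert m.ratio == 1.0

    def test_hand_computed_with_background(self):
        (m,) = kc_cyto_ratio(0, [1], [10.0], [300.0], ring_mean=200.0, background=100.0)
        assert m.ratio == 2.0

    def test_ring_at_background_raises(self):
        with pytest.raises(ValueError, match="indistinguishable"):
            kc_cyto_ratio(0, [1], [1.0], [300.0], ring_mean=100.0, background=100.0)

    def test_noise_free_truth_mask_recovery_is_exact(self, clean_stack):
        """With the generator's own footprints, the configured ratio is
        recovered to the accuracy of the spot tails in the ring (~0.2%)."""
        cfg, stack, truth = clean_stack
        meas = project_stack(stack, "mean")[0, 1].astype(float)
        tmask = truth.mask(0)
        means = measure_in_mask(tmask, meas)["mean"].to_numpy()
        cell, ring = cell_and_ring(meas, particle_mask=tmask.labels)
        bg = estimate_background(meas, cell)
        ratios = (means - bg) / (meas[ring].mean() - bg)
        assert bg == cfg.camera_offset
        assert np.allclose(ratios, cfg.true_ratio_meas, rtol=5e-3)

    def test_affine_rescaling_invariance(self, clean_stack):
        """Gain/offset changes of the camera leave the ratio unchanged when
        background is re-estimated."""
        cfg, stack, _ = clean_stack
        base = quantify_stack(stack)
        rescaled = ImageStack(stack.data * 3.0 + 50.0, stack.channel_names,
                              stack.pixel_size_um, stack.z_step_um,
                              stack.frame_interval_min, stack.reference_channel,
                              stack.measurement_channel)
        out = quantify_stack(rescaled)
        assert len(out) == len(base)
        assert np.allclose(np.sort(out.ratio), np.sort(base.ratio), rtol=1e-2)


class TestFullPipeline:
    def test_ratio_recovery_snr10(self, noisy_stack):
        cfg, stack, truth = noisy_stack
        df = quantify_stack(stack)
        assert abs(df.ratio.mean() - cfg.true_ratio_meas) <= 0.05 * cfg.true_ratio_meas

    def test_ratio_recovery_snr3(self):
        errs = []
        for seed in range(5):
            cfg = ImageSimConfig(seed=seed, snr=3.0, poisson=True, n_frames=2)
            stack, _ = sim_image_stack(cfg)
            df = quantify_stack(stack)
            errs.append(abs(df.ratio.mean() - cfg.true_ratio_meas) / cfg.true_ratio_meas)
        assert np.mean(errs) <= 0.15

    def test_detection_precision_recall(self, noisy_stack):
        cfg, stack, truth = noisy_stack
        df = quantify_stack(stack)
        tp = npred = ntruth = 0
        for t in sorted(df.frame.unique()):
            det = df[df.frame == t][["y_px", "x_px"]].to_numpy()
            tr = truth.spots[truth.spots.frame == t][["y_px", "x_px"]].to_numpy()
            matched, j = _match(det, tr)
            tp += len(set(j[matched]))
            npred += len(det)
            ntruth += len(tr)
        assert tp / npred >= 0.95 and tp / ntruth >= 0.95

    def test_output_schema(self, clean_stack):
        _, stack, _ = clean_stack
        df = quantify_stack(stack)
        assert list(df.columns) == ["frame", "label", "y_px", "x_px", "area_px",
                                    "mean_ref", "mean_meas", "cyto_mean",
                                    "background", "ratio"]
        assert (df.ratio > 0).all()


class TestCrescentClass:
    def test_interval_lookup(self):
        assert crescent_class([1.2], (0.9, 1.1, 1.3)) == ["medium"]
        assert crescent_class([0.5], (0.9, 1.1, 1.3)) == ["none"]
        assert crescent_class([2.0], (0.9, 1.1, 1.3)) == ["high"]

    def test_monotone_in_ratio(self):
        order = {"none": 0, "low": 1, "medium": 2, "high": 3}
        rs = np.linspace(0, 3, 50)
        classes = [order[c] for c in crescent_class(rs, (0.9, 1.1, 1.3))]
        assert classes == sorted(classes)

    def test_thresholds_from_control_quartiles(self):
        control = [0.8, 1.0, 1.2, 1.4]
        t = crescent_thresholds(control)
        assert t[0] < t[1] < t[2]

    def test_non_monotone_thresholds_rejected(self):
        with pytest.raises(ValueError):
            crescent_class([1.0], (1.3, 1.1, 0.9))
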