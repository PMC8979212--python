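"""Cascade mechanics: patch samplers, window tiling, centroid localization,
score assembly, thresholding and restoration."""

import numpy as np
import pytest
from scipy import stats as sps

from gtvcascade import (BinaryMask, ImageVolume, ROIBox, ScoreMap, assemble,
                        binarize_and_restore, locate_center,
                        sample_patch_stage1, sample_patch_stage2,
                        sliding_window_infer, window_origins)
from gtvcascade.cascade import gt_centroid
from gtvcascade.network import NetworkSpec, SegNetwork


class ConstantNet(SegNetwork):
    """Stub network returning a constant score; exposes call counting."""

    def __init__(self, value=0.7, in_channels=1):
        super().__init__(NetworkSpec.for_stage(1, levels=2, base_features=4,
                                               in_channels=in_channels))
        self.value = value
        self.calls = 0

    def forward(self, x, train=False):
        self.calls += 1
        return np.full((1, *x.shape[1:]), self.value, dtype=np.float32)


class TestWindowTiling:
    @pytest.mark.parametrize("extent,patch,stride,expected", [
        (128, 128, 64, [0]),
        (192, 128, 64, [0, 64]),
        (200, 128, 64, [0, 64, 72]),       # final window clamped to border
        (130, 128, 64, [0, 2]),
        (64, 128, 64, [0]),                # undersized: single padded window
    ])
    def test_origin_lattice(self, extent, patch, stride, expected):
        assert window_origins(extent, patch, stride) == expected

    @pytest.mark.parametrize("shape,expected_windows", [
        ((128, 128, 64), 1),
        ((192, 192, 96), 8),               # 2 x 2 x 2 at stride 64x64x32
        ((256, 192, 64), 3 * 2 * 1),
    ])
    def test_window_count_closed_form(self, shape, expected_windows):
        net = ConstantNet()
        v = ImageVolume(np.zeros(shape, np.float32))
        sliding_window_infer(net, v, (128, 128, 64), (64, 64, 32))
        assert net.calls == expected_windows
        for ext, p, s in zip(shape, (128, 128, 64), (64, 64, 32)):
            n_axis = int(np.ceil((ext - p) / s)) + 1 if ext > p else 1
            assert len(window_origins(ext, p, s)) == n_axis

    def test_every_voxel_covered_and_averaging_invariant(self):
        net = ConstantNet(value=0.42)
        v = ImageVolume(np.zeros((192, 160, 96), np.float32))
        s1 = sliding_window_infer(net, v, (128, 128, 64), (64, 64, 32))
        assert s1.data.shape == (192, 160, 96)
        # overlap-averaging of a constant output stays exactly constant
        assert np.allclose(s1.data, 0.42, atol=1e-7)


class TestSamplers:
    def _case(self, shape=(96, 96, 48)):
        rng = np.random.default_rng(0)
        v = ImageVolume(rng.normal(size=shape).astype(np.float32))
        gt = np.zeros(shape, np.uint8)
        gt[40:60, 30:50, 20:30] = 1
        return v, BinaryMask(gt)

    def test_exact_size_volume_single_origin(self):
        v, gt = self._case((64, 64, 32))
        patch, label = sample_patch_stage1(v, gt, (64, 64, 32), np.random.default_rng(3))
        assert np.array_equal(patch[0], v.first_channel)
        assert np.array_equal(label, gt.data)

    def test_same_seed_same_patch(self):
        v, gt = self._case()
        p1, l1 = sample_patch_stage1(v, gt, (64, 64, 32), np.random.default_rng(5))
        p2, l2 = sample_patch_stage1(v, gt, (64, 64, 32), np.random.default_rng(5))
        assert np.array_equal(p1, p2) and np.array_equal(l1, l2)

    def test_stage1_origin_uniformity(self):
        # valid z-origins for a 48-deep volume and 32-deep patch: {0..16}
        v, gt = self._case()
        rng = np.random.default_rng(11)
        counts = np.zeros(17)
        for _ in range(1000):
            patch, _ = sample_patch_stage1(v, gt, (96, 96, 32), rng)
            # recover origin by matching the first slice
            for oz in range(17):
                if np.array_equal(patch[0][:, :, 0], v.first_channel[:, :, oz]):
                    counts[oz] += 1
                    break
        assert counts.sum() == 1000
        p = sps.chisquare(counts).pvalue
        assert p > 0.01

    def test_stage2_center_without_jitter(self):
        v, gt = self._case()
        patch, label = sample_patch_stage2(v, gt, (48, 32, 16), (0, 0, 0),
                                           np.random.default_rng(0))
        c = gt_centroid(gt)
        start = tuple(ci - s // 2 for ci, s in zip(c, (48, 32, 16)))
        assert np.array_equal(
            patch[0], v.first_channel[start[0]:start[0]+48, start[1]:start[1]+32,
                                      start[2]:start[2]+16])
        assert label.sum() == gt.data.sum()  # tumor fits inside the crop

    def test_stage2_jitter_marginals_uniform(self):
        v, gt = self._case()
        c = np.array(gt_centroid(gt))
        rng = np.random.default_rng(2)
        offsets = []
        for _ in range(4000):
            patch, _ = sample_patch_stage2(v, gt, (8, 8, 8), (3, 3, 3), rng)
            # recover the jitter from the crop's corner voxel
            for dx in range(-3, 4):
                for dy in range(-3, 4):
                    for dz in range(-3, 4):
                        s = c + [dx, dy, dz] - [4, 4, 4]
                        if np.array_equal(patch[0], v.first_channel[
                                s[0]:s[0]+8, s[1]:s[1]+8, s[2]:s[2]+8]):
                            offsets.append((dx, dy, dz))
        offsets = np.array(offsets)
        assert len(offsets) == 4000
        for ax in range(3):
            counts = np.bincount(offsets[:, ax] + 3, minlength=7)
            assert sps.chisquare(counts).pvalue > 0.01

    def test_stage2_border_padding_preserves_gt(self):
        shape = (40, 40, 20)
        rng = np.random.default_rng(0)
        v = ImageVolume(rng.normal(size=shape).astype(np.float32))
        gt = np.zeros(shape, np.uint8)
        gt[0:6, 0:6, 0:4] = 1  # touches the volume border
        gtm = BinaryMask(gt)
        _, label = sample_patch_stage2(v, gtm, (48, 32, 16), (0, 0, 0),
                                       np.random.default_rng(1))
        assert label.sum() == gt.sum()

    def test_empty_gt_rejected(self):
        v, _ = self._case()
        empty = BinaryMask(np.zeros(v.shape, np.uint8))
        with pytest.raises(ValueError, match="no GTV"):
            sample_patch_stage2(v, empty, (48, 32, 16), (3, 3, 3),
                                np.random.default_rng(0))


class TestLocateCenter:
    def test_centered_cube_symmetry(self):
        s = np.zeros((31, 31, 31), np.float32)
        s[10:20, 10:20, 10:20] = 1.0  # 10^3 cube centred at 14.5 -> rounds to 15
        assert locate_center(ScoreMap(s)) == (15, 15, 15)

    def test_largest_component_wins(self):
        s = np.zeros((40, 20, 20), np.float32)
        s[2:7, 2:6, 2:7] = 0.9     # 100 voxels
        s[30:35, 10:12, 10:11] = 0.9  # 10 voxels
        center = locate_center(ScoreMap(s))
        assert center == (4, 4, 4)  # centroid (4, 3.5, 4.0) rounds half-up

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="no coarse detection"):
            locate_center(ScoreMap(np.zeros((8, 8, 8), np.float32)))


class TestAssembly:
    def _maps(self):
        s1 = ScoreMap(np.full((32, 32, 16), 0.8, np.float32))
        s2 = ScoreMap(np.full((8, 8, 8), 0.4, np.float32), provenance="stage2")
        roi = ROIBox((16, 16, 8), (8, 8, 8))
        return s1, s2, roi

    def test_published_weight_arithmetic(self):
        s1, s2, roi = self._maps()
        s = assemble(s1, s2, roi, 0.5)
        assert s.data[16, 16, 8] == pytest.approx(0.6)  # 0.5*0.8 + 0.5*0.4

    def test_outside_roi_keeps_stage1(self):
        s1, s2, roi = self._maps()
        s1.data[0, 0, 0] = 0.3
        s = assemble(s1, s2, roi, 0.5)
        assert s.data[0, 0, 0] == pytest.approx(0.3)

    def test_weight_one_recovers_stage1(self):
        s1, s2, roi = self._maps()
        s = assemble(s1, s2, roi, 1.0)
        assert np.array_equal(s.data, s1.data)

    def test_monotone_and_bounded(self, rng):
        s1 = ScoreMap(rng.random((16, 16, 8)).astype(np.float32))
        lo = ScoreMap(np.zeros((8, 8, 8), np.float32), provenance="stage2")
        hi = ScoreMap(np.ones((8, 8, 8), np.float32), provenance="stage2")
        roi = ROIBox((8, 8, 4), (8, 8, 8))
        s_lo = assemble(s1, lo, roi, 0.5).data
        s_hi = assemble(s1, hi, roi, 0.5).data
        assert (s_hi >= s_lo).all()
        assert s_lo.min() >= 0.0 and s_hi.max() <= 1.0

    def test_roi_outside_grid_rejected(self):
        s1, s2, _ = self._maps()
        with pytest.raises(ValueError, match="outside"):
            assemble(s1, s2, ROIBox((100, 100, 100), (8, 8, 8)), 0.5)


class TestPredictCase:
    def test_no_coarse_detection_yields_empty_mask_with_warning(self, desk_case):
        """A cascade whose stage 1 never crosses the detection threshold
        returns an empty mask flagged with a warning instead of raising."""
        from gtvcascade import CascadeModel, PipelineConfig, predict_case
        from gtvcascade.preprocessing import (compute_foreground_stats,
                                              preprocess_case)

        cfg = PipelineConfig.tiny()
        vol, body, _ = preprocess_case(desk_case.volume, cfg.target_spacing)
        stats = compute_foreground_stats([vol], [body])
        model = CascadeModel(stage1=ConstantNet(0.2), stage2=ConstantNet(0.2),
                             stats=stats, config=cfg)
        with pytest.warns(UserWarning, match="no coarse detection"):
            pred = predict_case(model, desk_case.volume)
        assert pred.n_foreground == 0
        assert pred.meta["warning"] == "no coarse detection"
        assert pred.shape == desk_case.volume.shape


class TestBinarizeRestore:
    META = {"crop_offset": (0, 0, 0), "cropped_shape": (8, 8, 8),
            "original_shape": (8, 8, 8), "original_spacing": (1.0, 1.0, 1.0)}

    def test_threshold_inclusive_at_exact_value(self):
        s = ScoreMap(np.full((8, 8, 8), 0.6, np.float32))
        mask = binarize_and_restore(s, 0.6, dict(self.META))
        assert mask.data.all()

    def test_just_below_threshold_empty(self):
        s = ScoreMap(np.full((8, 8, 8), 0.59, np.float32))
        mask = binarize_and_restore(s, 0.6, dict(self.META))
        assert mask.n_foreground == 0

    def test_identity_restoration_equals_direct_threshold(self, rng):
        scores = rng.random((8, 8, 8)).astype(np.float32)
        s = ScoreMap(scores)
        mask = binarize_and_restore(s, 0.6, dict(self.META))
        assert np.array_equal(mask.data, (scores >= 0.6).astype(np.uint8))

    def test_crop_offset_placement(self, rng):
        meta = {"crop_offset": (3, 4, 5), "cropped_shape": (8, 8, 8),
                "original_shape": (20, 20, 20), "original_spacing": (1.0, 1.0, 2.0)}
        s = ScoreMap(np.ones((8, 8, 8), np.float32))
        mask = binarize_and_restore(s, 0.6, meta)
        assert mask.shape == (20, 20, 20)
        assert mask.data[3:11, 4:12, 5:13].all()
        assert mask.n_foreground == 8**3
        assert mask.spacing == (1.0, 1.0, 2.0)

    def test_missing_provenance_rejected(self):
        s = ScoreMap(np.ones((8, 8, 8), np.float32))
        with pytest.raises(ValueError, match="provenance"):
            binarize_and_restore(s, 0.6, {"crop_offset": (0, 0, 0)})
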