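"""Cone masking, morphology, cropping, and clip-construction contracts."""

import numpy as np
import pytest
from skimage import morphology

from echofuse import preprocess as pp
from echofuse import synthetic
from echofuse.errors import ConfigurationError, NoConeFoundError


def _video(frames):
    return pp.RawVideo(np.asarray(frames, dtype=np.uint8))


def _iou(a, b):
    return (a & b).sum() / (a | b).sum()


class TestMotionMask:
    def test_static_video_gives_empty_mask(self):
        frames = np.full((5, 16, 16, 3), 37, dtype=np.uint8)
        cone = pp.compute_motion_mask(_video(frames))
        assert not cone.mask.any()

    def test_single_alternating_pixel_is_isolated(self):
        frames = np.zeros((6, 16, 16, 3), dtype=np.uint8)
        frames[::2, 5, 7] = 255
        cone = pp.compute_motion_mask(_video(frames))
        expected = np.zeros((16, 16), dtype=bool)
        expected[5, 7] = True
        assert np.array_equal(cone.mask, expected)

    def test_single_frame_video_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            pp.compute_motion_mask(_video(np.zeros((1, 16, 16, 3))))

    def test_mask_covers_cone_and_nothing_but_cone_or_ecg(self, default_study):
        params = default_study["params"]
        cone_gt = synthetic.cone_mask(params, "A4c")
        ecg = synthetic.ecg_trace_mask(params)
        cone = pp.compute_motion_mask(_video(default_study["videos"]["A4c"]))
        assert (cone.mask & cone_gt).sum() >= 0.95 * cone_gt.sum()
        assert not (cone.mask & ~cone_gt & ~ecg).any()


class TestRefineMask:
    def test_empty_mask_raises_no_cone_found(self):
        empty = pp.ConeMask(np.zeros((32, 32), dtype=bool), (0, 0, 0))
        with pytest.raises(NoConeFoundError):
            pp.refine_mask(empty)

    def test_ecg_trace_removed_cone_kept(self, default_study):
        params = default_study["params"]
        cone_gt = synthetic.cone_mask(params, "A4c")
        trace = synthetic.ecg_trace_mask(params)
        refined = pp.refine_mask(pp.ConeMask(cone_gt | trace, (0, 0, 0)),
                                 erosion_radius=3, dilation_radius=3)
        assert not (refined.mask & trace & ~cone_gt).any()
        assert _iou(refined.mask, cone_gt) >= 0.95

    def test_near_idempotent_on_convex_disk(self):
        mask = np.zeros((120, 120), dtype=bool)
        rr, cc = np.mgrid[0:120, 0:120]
        mask[(rr - 60) ** 2 + (cc - 60) ** 2 <= 40 ** 2] = True
        refined = pp.refine_mask(pp.ConeMask(mask, (0, 0, 0)),
                                 erosion_radius=3, dilation_radius=3)
        assert _iou(refined.mask, mask) >= 0.98

    def test_keeps_largest_component_only(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:40, 10:40] = True      # large blob
        mask[50:58, 50:58] = True      # smaller island
        refined = pp.refine_mask(pp.ConeMask(mask, (0, 0, 0)),
                                 erosion_radius=1, dilation_radius=1)
        assert not refined.mask[48:, 48:].any()
        assert refined.mask[20, 20]


class TestCropAndResize:
    def test_square_side_is_max_of_extents(self):
        mask = np.zeros((200, 200), dtype=bool)
        mask[50:150, 20:170] = True          # 100 rows x 150 cols
        cone = pp.ConeMask(mask, pp._bounding_square(mask))
        assert cone.bounding_square[2] == 150

    def test_output_is_224_by_224(self, default_study):
        video = pp.RawVideo(default_study["videos"]["A4c"])
        cone = pp.refine_mask(pp.compute_motion_mask(video))
        out = pp.crop_and_resize(video, cone, side=224)
        assert out.frames.shape[1:] == (224, 224, 3)

    def test_burned_in_text_zeroed(self, default_study):
        """Out-of-cone content (incl. static annotations) vanishes: every
        nonzero output pixel lies inside the cropped cone mask."""
        params = default_study["params"]
        video = pp.RawVideo(default_study["videos"]["A4c"])
        cone_gt = synthetic.cone_mask(params, "A4c")
        # annotations are present in the raw frames...
        ann = (video.frames[0].mean(axis=2) > 100) & ~cone_gt
        assert ann.any()
        cone = pp.ConeMask(cone_gt, pp._bounding_square(cone_gt))
        r0, c0, sq = cone.bounding_square
        out = pp.crop_and_resize(video, cone, side=sq)
        # ...but the crop's support is exactly the cone mask
        h, w = cone_gt.shape
        crop_mask = np.zeros((sq, sq), dtype=bool)
        rs, re = max(r0, 0), min(r0 + sq, h)
        cs, ce = max(c0, 0), min(c0 + sq, w)
        crop_mask[rs - r0:re - r0, cs - c0:ce - c0] = cone_gt[rs:re, cs:ce]
        assert out.frames[0][~crop_mask].max() == 0

    def test_overhanging_square_pads_with_zeros(self):
        frames = np.full((3, 40, 60, 3), 200, dtype=np.uint8)
        mask = np.zeros((40, 60), dtype=bool)
        mask[0:40, 0:60] = True
        cone = pp.ConeMask(mask, pp._bounding_square(mask))
        out = pp.crop_and_resize(pp.RawVideo(frames), cone,
                                 side=cone.bounding_square[2])
        assert out.frames.shape[1] == 60
        assert out.frames[0, 50:, :].max() == 0       # padded rows


class TestSelectClip:
    def test_short_video_zero_padded_to_64(self):
        frames = np.full((40, 8, 8, 3), 9, dtype=np.uint8)
        clip = pp.select_clip(_video(frames), clip_length=64)
        assert clip.frames.shape[0] == 64
        assert (clip.frames[40:] == 0).all()
        assert (clip.frames[:40] == 9).all()

    def test_long_video_truncated_to_first_64(self):
        frames = (np.arange(100, dtype=np.uint8)[:, None, None, None]
                  * np.ones((1, 8, 8, 3), dtype=np.uint8))
        clip = pp.select_clip(_video(frames), clip_length=64)
        assert np.array_equal(clip.frames, frames[:64])
        assert clip.start_frame == 0

    def test_random_mode_with_exact_length_starts_at_zero(self, rng):
        frames = np.random.default_rng(0).integers(
            0, 255, (64, 8, 8, 3)).astype(np.uint8)
        clip = pp.select_clip(_video(frames), clip_length=64,
                              start_mode="random", rng=rng)
        assert clip.start_frame == 0
        assert np.array_equal(clip.frames, frames)

    def test_random_mode_is_deterministic_given_rng(self):
        frames = np.random.default_rng(1).integers(
            0, 255, (100, 8, 8, 3)).astype(np.uint8)
        c1 = pp.select_clip(_video(frames), 16, "random",
                            np.random.default_rng(5))
        c2 = pp.select_clip(_video(frames), 16, "random",
                            np.random.default_rng(5))
        assert c1.start_frame == c2.start_frame
        assert np.array_equal(c1.frames, c2.frames)

    def test_invalid_clip_length_rejected(self):
        with pytest.raises(ConfigurationError):
            pp.select_clip(_video(np.zeros((4, 8, 8, 3))), clip_length=0)


class TestPipelineProperties:
    def test_first_frame_mode_is_deterministic(self, small_study):
        video = pp.RawVideo(small_study["videos"]["A2c"])
        a = pp.preprocess_video(video, side=64, clip_length=16)
        b = pp.preprocess_video(video, side=64, clip_length=16)
        assert np.array_equal(a.frames, b.frames)

    def test_nonzero_fraction_matches_cone_area(self, default_study):
        """Output support ~ cone-area fraction of the crop square (5%)."""
        video = pp.RawVideo(default_study["videos"]["A4c"])
        cone = pp.refine_mask(pp.compute_motion_mask(video))
        out = pp.crop_and_resize(video, cone, side=224)
        nonzero = (out.frames.mean(axis=3) > 0).mean()
        cone_frac = cone.mask.sum() / cone.bounding_square[2] ** 2
        assert abs(nonzero - cone_frac) < 0.05

    def test_masking_is_idempotent(self, small_study):
        video = pp.RawVideo(small_study["videos"]["PLAX"])
        cone = pp.refine_mask(pp.compute_motion_mask(video))
        masked = pp.RawVideo(video.frames
                             * cone.mask[None, :, :, None].astype(np.uint8))
        again = pp.compute_motion_mask(masked)
        assert not (again.mask & ~cone.mask).sum() > 0.01 * cone.mask.sum()
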