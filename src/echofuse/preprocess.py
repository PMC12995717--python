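"""Echo video standardization: cone masking, cropping, resizing, clips.

The ultrasound sector (cone) is the only region of a recorded frame
whose pixels change over time — burned-in annotations and the frame
background are static. The cone is therefore recovered as the set of
pixels whose temporal intensity variance exceeds a threshold, cleaned
with erosion/dilation to drop thin moving elements such as ECG traces,
cropped to the smallest enclosing square, zeroed outside the mask, and
resized to a fixed side (default 224). Fixed-length clips (default 64
frames) are then cut from the front of the video, or from a random
start for robustness probes, padding short videos with all-zero frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology, transform
from skimage.filters import threshold_otsu

from .errors import ConfigurationError, NoConeFoundError

DEFAULT_SIDE = 224
DEFAULT_CLIP_LENGTH = 64
# disk radius of the morphological structuring element at 224-pixel scale;
# scaled proportionally for other input sizes
DEFAULT_RADIUS_AT_224 = 3


@dataclass
class RawVideo:
    """(T, H, W, 3) uint8 frame stack; frame_rate is carried as metadata
    only (frame rates are not normalized)."""

    frames: np.ndarray
    frame_rate: float | None = None

    def __post_init__(self):
        f = np.asarray(self.frames)
        if f.ndim != 4 or f.shape[3] != 3:
            raise ValueError(f"frames must be (T, H, W, 3), got {f.shape}")
        if f.shape[1] < 8 or f.shape[2] < 8:
            raise ValueError("frames must be at least 8x8 pixels")
        self.frames = f


@dataclass
class ConeMask:
    """Boolean cone mask plus its smallest enclosing axis-aligned square,
    as (row0, col0, side) in 0-based, half-open pixel coordinates."""

    mask: np.ndarray
    bounding_square: tuple[int, int, int]


@dataclass
class ProcessedClip:
    """Fixed-length (T_clip, S, S, 3) uint8 clip; padded frames are zero."""

    frames: np.ndarray
    side: int
    clip_length: int
    start_frame: int


def _grayscale(frames: np.ndarray) -> np.ndarray:
    return frames.mean(axis=3)


def _bounding_square(mask: np.ndarray) -> tuple[int, int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    side = max(r1 - r0, c1 - c0)
    # center the square on the tight bounding box; it may overhang the
    # frame, in which case cropping pads with zeros
    r_start = r0 - (side - (r1 - r0)) // 2
    c_start = c0 - (side - (c1 - c0)) // 2
    return (r_start, c_start, side)


def compute_motion_mask(video: RawVideo,
                        variance_threshold: float | None = None) -> ConeMask:
    """Mask of pixels with temporal intensity variance above threshold.

    ``variance_threshold=None`` applies Otsu's threshold to the
    log-compressed per-pixel temporal-variance image. The log keeps the
    dominant Otsu split at background-vs-cone rather than between
    low-variance speckle and high-variance moving structures inside the
    cone, and adapts across intensity scales. An explicit threshold is
    interpreted on the raw variance scale (intensity units squared).
    """
    frames = video.frames
    if frames.shape[0] < 2:
        raise ValueError("motion mask needs at least 2 frames")
    var = _grayscale(frames.astype(np.float64)).var(axis=0)
    if variance_threshold is None:
        logvar = np.log1p(var)
        if np.ptp(logvar) == 0:
            variance_threshold = np.inf  # fully static video -> empty mask
        else:
            variance_threshold = float(np.expm1(threshold_otsu(logvar)))
    mask = var > variance_threshold
    square = _bounding_square(mask) if mask.any() else (0, 0, 0)
    return ConeMask(mask=mask, bounding_square=square)


def refine_mask(cone: ConeMask, erosion_radius: int = None,
                dilation_radius: int = None) -> ConeMask:
    """Erosion then dilation with disk elements; keep the largest
    connected component (one cone per video)."""
    mask = cone.mask
    if erosion_radius is None:
        erosion_radius = max(1, round(DEFAULT_RADIUS_AT_224
                                      * min(mask.shape) / 224))
    if dilation_radius is None:
        dilation_radius = erosion_radius
    if erosion_radius < 0 or dilation_radius < 0:
        raise ValueError("radii must be non-negative")
    if not mask.any():
        raise NoConeFoundError("no cone found: input mask is empty")
    refined = mask
    if erosion_radius > 0:
        refined = morphology.erosion(refined, morphology.disk(erosion_radius))
    if dilation_radius > 0:
        refined = morphology.dilation(refined, morphology.disk(dilation_radius))
    if not refined.any():
        raise NoConeFoundError("no cone found: mask empty after morphology")
    labels = measure.label(refined)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    refined = labels == largest
    return ConeMask(mask=refined, bounding_square=_bounding_square(refined))


def crop_and_resize(video: RawVideo, cone: ConeMask,
                    side: int = DEFAULT_SIDE) -> RawVideo:
    """Zero out-of-mask pixels, crop the enclosing square, resize to side."""
    if not cone.mask.any():
        raise NoConeFoundError("cannot crop with an empty cone mask")
    frames = video.frames
    t_n, h, w, _ = frames.shape
    masked = frames * cone.mask[None, :, :, None].astype(np.uint8)
    r0, c0, sq = cone.bounding_square
    # gather the square, padding with zeros wherever it overhangs the frame
    out = np.zeros((t_n, sq, sq, 3), dtype=frames.dtype)
    rs, re = max(r0, 0), min(r0 + sq, h)
    cs, ce = max(c0, 0), min(c0 + sq, w)
    out[:, rs - r0:re - r0, cs - c0:ce - c0] = masked[:, rs:re, cs:ce]
    if sq != side:
        resized = np.empty((t_n, side, side, 3), dtype=np.float64)
        for t in range(t_n):
            resized[t] = transform.resize(out[t].astype(np.float64), (side, side, 3),
                                          order=1, anti_aliasing=sq > side,
                                          preserve_range=True)
        out = np.clip(np.rint(resized), 0, 255).astype(np.uint8)
    return RawVideo(frames=out, frame_rate=video.frame_rate)


def select_clip(video: RawVideo, clip_length: int = DEFAULT_CLIP_LENGTH,
                start_mode: str = "first",
                rng: np.random.Generator | None = None) -> ProcessedClip:
    """Cut a fixed-length clip; zero-pad the tail of short videos.

    ``start_mode="first"`` takes frames [0, clip_length); ``"random"``
    draws the start uniformly (no wraparound; short tails are padded),
    the inference-robustness probe mode.
    """
    if clip_length <= 0:
        raise ConfigurationError("clip_length must be positive")
    frames = video.frames
    t_n = frames.shape[0]
    if start_mode == "first":
        start = 0
    elif start_mode == "random":
        if rng is None:
            raise ConfigurationError("random start mode requires an rng")
        start = int(rng.integers(0, max(t_n - clip_length, 0) + 1))
    else:
        raise ConfigurationError(f"unknown start_mode {start_mode!r}")
    out = np.zeros((clip_length,) + frames.shape[1:], dtype=frames.dtype)
    avail = frames[start:start + clip_length]
    out[:avail.shape[0]] = avail
    return ProcessedClip(frames=out, side=frames.shape[1],
                         clip_length=clip_length, start_frame=start)


def preprocess_video(video: RawVideo, side: int = DEFAULT_SIDE,
                     clip_length: int = DEFAULT_CLIP_LENGTH,
                     start_mode: str = "first",
                     rng: np.random.Generator | None = None,
                     variance_threshold: float | None = None) -> ProcessedClip:
    """Full standardization: motion mask -> morphology -> crop/resize -> clip."""
    cone = compute_motion_mask(video, variance_threshold)
    cone = refine_mask(cone)
    cropped = crop_and_resize(video, cone, side=side)
    return select_clip(cropped, clip_length=clip_length,
                       start_mode=start_mode, rng=rng)
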