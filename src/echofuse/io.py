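"""Manifest and video readers/writers.

Videos are exchanged as NPZ (key ``frames``, T x H x W x 3 uint8), AVI/MP4
(when an imageio codec backend is available), or DICOM multi-frame
ultrasound files (pixel data only). The study manifest is a CSV with one
row per video: patient_id, study_id, view, doppler, path, label.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ManifestError, VideoDecodeError
from .preprocess import RawVideo

DEFAULT_VIEW_VOCABULARY = ("A4c", "A2c", "A5c", "PLAX", "other")
REQUIRED_COLUMNS = ("patient_id", "study_id", "view", "doppler", "path", "label")


def read_manifest(path: str | Path, view_vocabulary=DEFAULT_VIEW_VOCABULARY,
                  check_paths: bool = False) -> pd.DataFrame:
    """Load and validate a study manifest CSV."""
    path = Path(path)
    manifest = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in manifest.columns]
    if missing:
        raise ManifestError(f"manifest {path} missing column(s): "
                            f"{', '.join(missing)}")
    unknown = sorted(set(manifest["view"]) - set(view_vocabulary))
    if unknown:
        raise ManifestError(
            f"unknown view name(s) {unknown}; extend the view vocabulary "
            f"(current: {list(view_vocabulary)})")
    key = ["study_id", "view", "doppler", "path"]
    dup = manifest.duplicated(key, keep=False)
    if dup.any():
        rows = (manifest.index[dup] + 2).tolist()   # 1-based incl. header
        raise ManifestError(f"duplicate (study, view, doppler, path) rows "
                            f"at lines {rows}")
    manifest["doppler"] = manifest["doppler"].astype(bool)
    if check_paths:
        dangling = [(i + 2, p) for i, p in enumerate(manifest["path"])
                    if not Path(p).exists()]
        if dangling:
            raise ManifestError(f"dangling path(s): {dangling[:5]}"
                                + ("..." if len(dangling) > 5 else ""))
    return manifest


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False)


def manifest_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _to_rgb_uint8(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames)
    if frames.ndim == 3:                      # grayscale (T, H, W)
        frames = frames[..., None]
    if frames.shape[-1] == 1:
        frames = np.repeat(frames, 3, axis=-1)
    if frames.shape[-1] != 3:
        raise VideoDecodeError(f"unsupported channel count {frames.shape[-1]}")
    if frames.dtype != np.uint8:
        lo, hi = float(frames.min()), float(frames.max())
        scale = 255.0 / (hi - lo) if hi > lo else 0.0
        frames = ((frames - lo) * scale).astype(np.uint8)
    return frames


def read_video(path: str | Path) -> RawVideo:
    """Decode a video file into (T, H, W, 3) uint8 frames.

    Grayscale sources are replicated across the three channels; DICOM
    reads pixel data only (no header de-identification is attempted).
    """
    path = Path(path)
    if not path.exists():
        raise VideoDecodeError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix == ".npz":
        try:
            with np.load(path) as data:
                frames = data["frames"]
        except KeyError as exc:
            raise VideoDecodeError(f"{path}: NPZ lacks a 'frames' array") from exc
        except Exception as exc:
            raise VideoDecodeError(f"{path}: undecodable NPZ ({exc})") from exc
        return RawVideo(_to_rgb_uint8(frames))
    if suffix in (".dcm", ".dicom"):
        import pydicom
        try:
            ds = pydicom.dcmread(str(path))
        except Exception as exc:
            raise VideoDecodeError(f"{path}: unreadable DICOM: {exc}") from exc
        try:
            frames = ds.pixel_array
        except Exception as exc:
            syntax = ds.file_meta.get("TransferSyntaxUID", "?") \
                if hasattr(ds, "file_meta") else "?"
            raise VideoDecodeError(
                f"{path}: DICOM pixel decode failed "
                f"(transfer syntax {syntax}): {exc}") from exc
        if frames.ndim == 2:
            frames = frames[None]
        return RawVideo(_to_rgb_uint8(frames),
                        frame_rate=float(ds.CineRate) if "CineRate" in ds else None)
    if suffix in (".avi", ".mp4", ".mov", ".mkv"):
        import imageio.v3 as iio
        try:
            frames = iio.imread(path)
        except Exception as exc:
            raise VideoDecodeError(
                f"{path}: video decode failed; no working codec backend "
                f"for {suffix} ({exc})") from exc
        return RawVideo(_to_rgb_uint8(np.asarray(frames)))
    raise VideoDecodeError(f"{path}: unsupported video format {suffix!r}")


def write_video_npz(frames: np.ndarray, path: str | Path) -> None:
    np.savez_compressed(path, frames=np.asarray(frames, dtype=np.uint8))
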