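"""Synthetic multiview echocardiogram-like video generator.

Emulates the structural features of clinical echo recordings that the
preprocessing and modelling stages depend on, without any acoustic
physics: a bright sector-shaped ultrasound cone on a black background,
frame-to-frame speckle inside the cone, a periodically moving
endocardial "wall" band whose oscillation amplitude encodes a per-view
latent variable, static burned-in annotation blocks outside the cone, a
thin moving ECG-like trace, and optional colored doppler patches.

Each study draws one independent standard-normal latent per view; the
binary study label is a deterministic function of all three latents
(``sum`` rule: thresholded standardized sum; ``any`` rule: OR of
per-view exceedances). Because the label depends jointly on the views,
the all-view Bayes-optimal AUC is 1.0 while any single view has a
strictly smaller ceiling — the planted structure used to demonstrate
the advantage of mid-fusion over single-view models.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError

DEFAULT_VIEWS = ("A4c", "A2c", "PLAX")

# Small per-view tilt (degrees) of the cone axis so a view classifier
# trained on these videos has geometric signal to separate the views.
VIEW_TILT_DEG = {"A4c": 0.0, "A2c": 8.0, "PLAX": -8.0}

MANIFEST_COLUMNS = ["patient_id", "study_id", "view", "doppler", "path", "label"]


@dataclass(frozen=True)
class SynthParams:
    """Configuration of the synthetic echo-video generator.

    Geometry fields are in pixels unless stated otherwise; ``None``
    pixel fields are resolved as fractions of ``frame_size`` (see
    ``resolved``), so one parameter set scales across resolutions.
    """

    n_studies: int = 100
    views: tuple[str, ...] = DEFAULT_VIEWS
    frame_count: int = 72
    frame_size: int = 112
    cone_half_angle: float = 32.0          # degrees
    cone_apex: tuple[float, float] = (0.08, 0.5)   # fractional (row, col)
    cone_radius_frac: float = 0.75         # of frame_size
    speckle_sd: float = 25.0               # intensity units
    base_intensity: float = 70.0           # mean in-cone brightness
    wall_base_amplitude: float | None = None   # px; default 0.05*frame_size
    wall_amp_per_latent: float | None = None   # px per latent unit; 0.035*frame_size
    wall_period: float = 16.0              # frames per oscillation cycle
    latent_sd: float = 1.0
    label_rule: str = "sum"                # {"sum", "any"}
    prevalence: float = 0.25
    annotation_flag: bool = True
    ecg_flag: bool = True
    doppler_fraction: float = 0.0
    multi_study_fraction: float = 0.2      # patients contributing 2 studies
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.prevalence < 1.0):
            raise ConfigurationError("prevalence must be strictly inside (0, 1)")
        if self.n_studies < 1:
            raise ConfigurationError("n_studies must be >= 1")
        if self.frame_count < 2:
            raise ConfigurationError("frame_count must be >= 2")
        if self.label_rule not in ("sum", "any"):
            raise ConfigurationError(f"unknown label_rule {self.label_rule!r}")
        if len(self.views) < 1:
            raise ConfigurationError("at least one view required")
        # geometry: the cone sector must fit inside the frame for every view
        f = self.frame_size
        apex_r, apex_c = self.cone_apex[0] * f, self.cone_apex[1] * f
        radius = self.cone_radius_frac * f
        max_tilt = max(abs(VIEW_TILT_DEG.get(v, 0.0)) for v in self.views)
        theta = np.deg2rad(self.cone_half_angle + max_tilt)
        if (apex_r + radius > f or apex_c + radius * np.sin(theta) > f
                or apex_c - radius * np.sin(theta) < 0):
            raise ConfigurationError(
                "cone exceeds frame bounds; shrink cone_radius_frac or "
                "cone_half_angle")

    def resolved(self) -> "SynthParams":
        """Fill pixel defaults that scale with frame_size."""
        updates = {}
        if self.wall_base_amplitude is None:
            updates["wall_base_amplitude"] = 0.05 * self.frame_size
        if self.wall_amp_per_latent is None:
            updates["wall_amp_per_latent"] = 0.035 * self.frame_size
        return dataclasses.replace(self, **updates) if updates else self


@dataclass
class LatentState:
    """Per-study latents (one per view) and the induced binary label."""

    z: np.ndarray
    label: int


def _rng_for(params: SynthParams, *key: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, *key])


def label_from_latents(z: np.ndarray, params: SynthParams) -> int:
    """Deterministic label rule; z has one entry per view."""
    v = len(params.views)
    if params.label_rule == "sum":
        c = norm.ppf(1.0 - params.prevalence)
        return int(z.sum() / np.sqrt(v) > c)
    # "any": per-view cutoffs chosen so the OR has the configured prevalence
    c_i = norm.ppf((1.0 - params.prevalence) ** (1.0 / v))
    return int(np.any(z > c_i))


def cone_mask(params: SynthParams, view: str) -> np.ndarray:
    """Ground-truth boolean mask of the ultrasound sector for ``view``."""
    f = params.frame_size
    apex = np.array([params.cone_apex[0] * f, params.cone_apex[1] * f])
    radius = params.cone_radius_frac * f
    tilt = np.deg2rad(VIEW_TILT_DEG.get(view, 0.0))
    half = np.deg2rad(params.cone_half_angle)
    rr, cc = np.mgrid[0:f, 0:f]
    dr, dc = rr - apex[0], cc - apex[1]
    dist = np.hypot(dr, dc)
    ang = np.arctan2(dc, dr)          # 0 = straight down
    return (dist <= radius) & (np.abs(ang - tilt) <= half)


def wall_band_region(params: SynthParams, view: str) -> np.ndarray:
    """Ground-truth region swept by the moving wall band (label signal).

    The annulus covering the band at any amplitude up to 3 latent s.d.,
    intersected with the cone — the discriminative region grad-CAM
    should localize.
    """
    p = params.resolved()
    f = p.frame_size
    apex = np.array([p.cone_apex[0] * f, p.cone_apex[1] * f])
    radius = p.cone_radius_frac * f
    r_wall = 0.55 * radius
    a_max = p.wall_base_amplitude + 3.0 * p.wall_amp_per_latent * p.latent_sd
    half_thick = max(1.5, 0.03 * f)
    rr, cc = np.mgrid[0:f, 0:f]
    dist = np.hypot(rr - apex[0], cc - apex[1])
    annulus = np.abs(dist - r_wall) <= (a_max + half_thick)
    return annulus & cone_mask(p, view)


def ecg_trace_mask(params: SynthParams) -> np.ndarray:
    """Ground-truth pixel set of the ECG-like trace (the only out-of-cone
    pixels allowed to vary over time)."""
    f = params.frame_size
    ecg_row = int(0.94 * f)
    cols = np.arange(f)
    rows = np.clip(ecg_row + np.round(
        1.5 * np.sin(cols / f * 6 * np.pi)).astype(int), 0, f - 1)
    mask = np.zeros((f, f), dtype=bool)
    mask[rows, cols] = True
    return mask


def _render_view(p: SynthParams, view: str, z: float, doppler: bool,
                 rng: np.random.Generator) -> np.ndarray:
    f, t_n = p.frame_size, p.frame_count
    mask = cone_mask(p, view)
    apex = np.array([p.cone_apex[0] * f, p.cone_apex[1] * f])
    radius = p.cone_radius_frac * f
    tilt = np.deg2rad(VIEW_TILT_DEG.get(view, 0.0))
    half = np.deg2rad(p.cone_half_angle)
    rr, cc = np.mgrid[0:f, 0:f]
    dist = np.hypot(rr - apex[0], cc - apex[1])
    ang = np.arctan2(cc - apex[1], rr - apex[0])

    r_wall = 0.55 * radius
    half_thick = max(1.5, 0.03 * f)
    amp = float(np.clip(p.wall_base_amplitude + p.wall_amp_per_latent * z,
                        0.3, 0.35 * r_wall))
    phase = rng.uniform(0.0, 2.0 * np.pi)
    wall_ang = np.abs(ang - tilt) <= 0.7 * half

    frames = np.zeros((t_n, f, f), dtype=np.uint8)
    static = np.zeros((f, f), dtype=np.float64)

    if p.annotation_flag:
        # static burned-in text blocks in the top corners, outside the cone
        for r0, c0 in ((1, 1), (1, f - int(0.22 * f) - 1)):
            h, w = max(3, int(0.06 * f)), int(0.2 * f)
            block = rng.uniform(120, 255, size=(h, w))
            block *= rng.random((h, w)) > 0.35      # text-like dot pattern
            region = static[r0:r0 + h, c0:c0 + w]
            outside = ~mask[r0:r0 + h, c0:c0 + w]
            region[outside] = block[outside]

    ecg_row = int(0.94 * f)
    ecg_cols = np.arange(f)
    ecg_wiggle = (ecg_row
                  + np.round(1.5 * np.sin(ecg_cols / f * 6 * np.pi)).astype(int))
    ecg_wiggle = np.clip(ecg_wiggle, 0, f - 1)

    if p.ecg_flag:
        static[ecg_wiggle, ecg_cols] = np.maximum(static[ecg_wiggle, ecg_cols], 90)

    doppler_center = None
    if doppler:
        # place the color patch on the wall-band annulus inside the cone
        d_ang = tilt + rng.uniform(-0.4, 0.4) * half
        d_r = r_wall
        doppler_center = apex + d_r * np.array([np.cos(d_ang), np.sin(d_ang)])
        doppler_mask = ((rr - doppler_center[0]) ** 2
                        + (cc - doppler_center[1]) ** 2) <= (0.08 * f) ** 2
        doppler_mask &= mask

    rgb = np.zeros((t_n, f, f, 3), dtype=np.uint8)
    for t in range(t_n):
        frame = static.copy()
        speckle = p.base_intensity + rng.normal(0.0, p.speckle_sd, size=(f, f))
        frame[mask] = speckle[mask]
        r_t = r_wall + amp * np.sin(2.0 * np.pi * t / p.wall_period + phase)
        band = (np.abs(dist - r_t) <= half_thick) & wall_ang & mask
        # bright wall band carries speckle too (keeps every in-cone pixel
        # time-varying, as in real tissue)
        frame[band] = 210.0 + 0.4 * (speckle[band] - p.base_intensity)
        if p.ecg_flag:
            sweep = int(round((f - 1) * (t % t_n) / max(1, t_n - 1)))
            lo, hi = max(0, sweep - 1), min(f, sweep + 2)
            frame[ecg_wiggle[lo:hi], ecg_cols[lo:hi]] = 230.0
        gray = np.clip(frame, 0, 255).astype(np.uint8)
        rgb[t] = gray[..., None]
        if doppler:
            red = rgb[t, ..., 0].astype(np.int16)
            blue = rgb[t, ..., 2].astype(np.int16)
            red[doppler_mask] += 70
            blue[doppler_mask] -= 40
            rgb[t, ..., 0] = np.clip(red, 0, 255).astype(np.uint8)
            rgb[t, ..., 2] = np.clip(blue, 0, 255).astype(np.uint8)
    return rgb


def _patient_assignment(params: SynthParams) -> list[str]:
    """Deterministic study -> patient mapping; a configurable fraction of
    patients contribute two studies (exercises patient-level splitting)."""
    rng = _rng_for(params, 1_000_003)
    ids = []
    patient = 0
    i = 0
    while i < params.n_studies:
        n_here = 2 if rng.random() < params.multi_study_fraction else 1
        for _ in range(min(n_here, params.n_studies - i)):
            ids.append(f"P{patient:05d}")
            i += 1
        patient += 1
    return ids


def generate_latents(params: SynthParams, study_index: int) -> LatentState:
    rng = _rng_for(params, 2, study_index)
    z = rng.standard_normal(len(params.views)) * params.latent_sd
    return LatentState(z=z, label=label_from_latents(z, params))


def generate_study(params: SynthParams, study_index: int):
    """Render all views of one study.

    Returns ``(videos, latents, patient_id, study_id, doppler_flags)``
    where ``videos`` maps view name -> (T, H, W, 3) uint8 array.
    Deterministic given ``(params.seed, study_index)``.
    """
    p = params.resolved()
    latents = generate_latents(p, study_index)
    videos: dict[str, np.ndarray] = {}
    doppler_flags: dict[str, bool] = {}
    for vi, view in enumerate(p.views):
        rng = _rng_for(p, 3, study_index, vi)
        doppler = bool(rng.random() < p.doppler_fraction)
        videos[view] = _render_view(p, view, float(latents.z[vi]), doppler, rng)
        doppler_flags[view] = doppler
    patients = _patient_assignment(p)
    return (videos, latents, patients[study_index], f"S{study_index:05d}",
            doppler_flags)


def generate_dataset(params: SynthParams, outdir: str | Path,
                     write_videos: bool = True) -> pd.DataFrame:
    """Write one NPZ per (study, view) plus a manifest CSV; return the manifest."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {outdir}: {exc}") from exc
    rows = []
    for i in range(params.n_studies):
        videos, latents, patient_id, study_id, doppler_flags = generate_study(
            params, i)
        for view, frames in videos.items():
            path = outdir / f"{study_id}_{view}.npz"
            if write_videos:
                try:
                    np.savez_compressed(path, frames=frames)
                except OSError as exc:
                    raise IOError(f"failed writing {path}: {exc}") from exc
            rows.append({
                "patient_id": patient_id, "study_id": study_id, "view": view,
                "doppler": doppler_flags[view], "path": str(path),
                "label": latents.label,
            })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def bayes_auc_single_view(params: SynthParams, view_index: int,
                          n_draws: int = 1_000_000, seed: int = 12345) -> float:
    """Monte-Carlo estimate of the Bayes-optimal AUC of one view's latent.

    Under the ``sum`` rule the label is a deterministic function of all
    latents, so the all-view ceiling is 1.0 while each single view sees
    only a noisy correlate; this is the oracle for fusion-advantage tests.
    """
    if params.label_rule != "sum":
        raise ConfigurationError("Bayes single-view AUC oracle assumes label_rule='sum'")
    from scipy.stats import rankdata

    rng = np.random.default_rng(seed)
    v = len(params.views)
    c = norm.ppf(1.0 - params.prevalence)
    zs = rng.standard_normal((n_draws, v)) * params.latent_sd
    labels = (zs.sum(axis=1) / np.sqrt(v)) > c
    scores = zs[:, view_index]
    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = n_draws - n_pos
    if n_pos == 0 or n_neg == 0:
        return 1.0
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)
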