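"""Grad-CAM and guided grad-CAM adapted to 3D video inputs.

Grad-CAM weights the final convolutional block's activation channels by
the spatiotemporally-averaged gradient of the target logit, rectifies
the weighted sum, and upsamples it trilinearly to the input clip,
giving a coarse per-frame localization of the evidence. Guided
backpropagation refines this to pixel level by passing only positive
gradients through positively-activated ReLUs; guided grad-CAM is the
elementwise product of the two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .models import MultiviewModel, SingleViewModel
from .nn.layers import ReLU

CONFIDENCE_THRESHOLD = 0.95


@dataclass
class SaliencyMap:
    """Per-frame saliency aligned to the input clip.

    ``cam`` is the per-frame max-normalized grad-CAM in [0, 1];
    ``cam_raw`` keeps the unnormalized values. ``guided``, when
    computed, is the signed pixel-level gradient map of shape
    (T, S, S, 3).
    """

    cam: np.ndarray
    cam_raw: np.ndarray
    target_class: int
    score_at_generation: float
    guided: np.ndarray | None = None


def _score_from_logits(logits: np.ndarray, n_classes: int) -> np.ndarray:
    if n_classes == 1:
        return 1.0 / (1.0 + np.exp(-logits[:, 0]))
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _target_grad(logits: np.ndarray, target: int, n_classes: int) -> np.ndarray:
    """Seed gradient selecting the target logit (binary: class 1 is the
    logit itself, class 0 its negation)."""
    grad = np.zeros_like(logits)
    if n_classes == 1:
        if target not in (0, 1):
            raise ValueError(f"invalid binary target {target}")
        grad[:, 0] = 1.0 if target == 1 else -1.0
    else:
        if not (0 <= target < n_classes):
            raise ValueError(f"target {target} outside {n_classes} classes")
        grad[:, target] = 1.0
    return grad


def _cam_from(activation: np.ndarray, grad: np.ndarray,
              out_shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """(C, T', H', W') activation + gradient -> upsampled, normalized cam."""
    weights = grad.mean(axis=(1, 2, 3))                      # (C,)
    cam = np.maximum((weights[:, None, None, None] * activation).sum(axis=0),
                     0.0)
    zoom = [o / i for o, i in zip(out_shape, cam.shape)]
    cam_raw = ndimage.zoom(cam, zoom, order=1)               # trilinear
    cam_raw = np.maximum(cam_raw, 0.0)
    norm = cam_raw.copy()
    frame_max = norm.max(axis=(1, 2), keepdims=True)
    np.divide(norm, frame_max, out=norm, where=frame_max > 0)
    return norm, cam_raw


def grad_cam_video(model: SingleViewModel, clip: np.ndarray,
                   target: int = 1) -> SaliencyMap:
    """Grad-CAM for a single-view model on one (1, 3, T, S, S) clip
    (or (3, T, S, S), auto-batched)."""
    if clip.ndim == 4:
        clip = clip[None]
    model.eval()
    n_classes = model.head.fc.out_features
    logits = model.forward_logits(clip)
    score = _score_from_logits(logits, n_classes)
    emb_grad = model.head.backward(_target_grad(logits, target, n_classes))
    model.zero_grad()
    activation = model.last_embedding[0]
    grad = emb_grad[0]
    out_shape = clip.shape[2:]
    cam, cam_raw = _cam_from(activation, grad, out_shape)
    s = float(score[0] if np.ndim(score) == 1 else score[0, target])
    return SaliencyMap(cam=cam, cam_raw=cam_raw, target_class=target,
                       score_at_generation=s)


def grad_cam_multiview(model: MultiviewModel, clips: list[np.ndarray],
                       target: int = 1) -> list[SaliencyMap]:
    """Per-view grad-CAM maps (one per trunk) for a multiview model."""
    clips = [c[None] if c.ndim == 4 else c for c in clips]
    model.eval()
    logits = model.forward_logits(clips)
    score = _score_from_logits(logits, model.config.n_classes)
    g = model.fc.backward(_target_grad(logits, target, model.config.n_classes))
    grads = model.fusion.backward(g)
    model.zero_grad()
    maps = []
    for clip, emb, ge in zip(clips, model.last_embeddings, grads):
        cam, cam_raw = _cam_from(emb[0], ge[0], clip.shape[2:])
        s = float(score[0] if np.ndim(score) == 1 else score[0, target])
        maps.append(SaliencyMap(cam=cam, cam_raw=cam_raw, target_class=target,
                                score_at_generation=s))
    return maps


class _guided:
    def __init__(self, model):
        self.relus = [m for m in model.modules() if isinstance(m, ReLU)]

    def __enter__(self):
        for r in self.relus:
            r.guided = True

    def __exit__(self, *exc):
        for r in self.relus:
            r.guided = False


def guided_backprop(model: SingleViewModel, clip: np.ndarray,
                    target: int = 1) -> np.ndarray:
    """Signed input-gradient map with guided-ReLU backward; shape equals
    the clip's (T, S, S, 3)."""
    if clip.ndim == 4:
        clip = clip[None]
    model.eval()
    n_classes = model.head.fc.out_features
    with _guided(model):
        logits = model.forward_logits(clip)
        gin = model.backward_logits(_target_grad(logits, target, n_classes))
    model.zero_grad()   # discard parameter gradients from the probe
    return np.ascontiguousarray(gin[0].transpose(1, 2, 3, 0))


def guided_grad_cam(cam: np.ndarray, guided: np.ndarray) -> np.ndarray:
    """Elementwise product of the (T, S, S) cam with the (T, S, S, 3)
    guided map."""
    cam = np.asarray(cam)
    guided = np.asarray(guided)
    if cam.shape != guided.shape[:3]:
        raise ValueError(
            f"cam shape {cam.shape} does not match guided map {guided.shape}")
    return guided * cam[..., None]


def select_explanation_cases(scores,
                             threshold: float = CONFIDENCE_THRESHOLD) -> np.ndarray:
    """Indices of confident positive predictions (score > threshold)."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    cases = np.flatnonzero(scores > threshold)
    if cases.size == 0:
        warnings.warn(f"no predictions above {threshold}; nothing to explain")
    return cases


def localization_score(cam: np.ndarray, region: np.ndarray) -> float:
    """Fraction of total cam mass inside a ground-truth spatial region
    (region is (S, S) boolean, broadcast over frames)."""
    total = float(cam.sum())
    if total == 0:
        return 0.0
    return float(cam[:, region].sum() / total)
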