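"""Desk-scale end-to-end experiments on synthetic multiview data.

These harnesses realize the full study protocol at CPU scale: generate
synthetic studies with a planted cross-view label structure, run the
standard preprocessing into 16x32x32 clips, split by patient 70/15/15,
train three tiny single-view models and one tiny multiview model under
the same protocol, score the held-out test studies (including the
late-fusion average comparator), and compare AUCs with DeLong tests
under Bonferroni correction — the scaled-down analogue of the clinical
comparison in which mid-fusion beats every single view and the
score-average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation, preprocess, synthetic, training
from .models import (BackboneConfig, MultiviewConfig, build_multiview_model,
                     build_single_view_model, late_fusion_average)

logger = logging.getLogger(__name__)

CLIP_LENGTH = 16
CLIP_SIDE = 32


def default_experiment_params(n_studies: int, seed: int) -> synthetic.SynthParams:
    """Study conditions for the fusion experiment: 64-px source videos
    (downscaled to 32-px clips), 24 frames, sum label rule at 25%
    prevalence."""
    return synthetic.SynthParams(
        n_studies=n_studies, frame_size=64, frame_count=24,
        label_rule="sum", prevalence=0.25, seed=seed)


def build_clip_datasets(params: synthetic.SynthParams,
                        clip_length: int = CLIP_LENGTH,
                        side: int = CLIP_SIDE):
    """Generate + preprocess every study into in-memory clip arrays.

    Returns (manifest, clips) where clips maps view -> (N, T, S, S, 3)
    uint8 aligned with the manifest's study order.
    """
    p = params.resolved()
    n = p.n_studies
    clips = {v: np.empty((n, clip_length, side, side, 3), dtype=np.uint8)
             for v in p.views}
    rows = []
    for i in range(n):
        videos, latents, patient_id, study_id, doppler = \
            synthetic.generate_study(p, i)
        for view, frames in videos.items():
            clip = preprocess.preprocess_video(
                preprocess.RawVideo(frames), side=side,
                clip_length=clip_length)
            clips[view][i] = clip.frames
        rows.append({"patient_id": patient_id, "study_id": study_id,
                     "label": latents.label})
    manifest = pd.DataFrame(rows)
    return manifest, clips


def _partition_indices(manifest: pd.DataFrame, split) -> dict[str, np.ndarray]:
    parts = manifest["patient_id"].map(split.assignment)
    return {name: np.flatnonzero(parts == name)
            for name in training.PARTITIONS}


@dataclass
class FusionExperimentResult:
    aucs: dict[str, float]
    best_single_view: str
    auc_gap: float
    comparisons: dict[str, evaluation.ComparisonResult]
    bayes_single_view_auc: float
    test_scores: dict[str, np.ndarray]
    test_labels: np.ndarray
    records: dict[str, training.TrainRecord] = field(default_factory=dict)
    n_studies: int = 0


def run_fusion_experiment(n_studies: int = 2000, seed: int = 0,
                          epochs_single: int = 8, epochs_multi: int = 10,
                          batch_size: int = 16,
                          augment: training.AugmentParams | None = None,
                          ) -> FusionExperimentResult:
    """Train multiview vs single-view models on planted-sum-rule data.

    Because the label is a deterministic function of all three latents,
    the all-view Bayes AUC is 1.0 while each single view is capped at
    the Monte-Carlo single-view ceiling; a trained multiview model
    should open a clear AUC gap over the best single view.
    """
    params = default_experiment_params(n_studies, seed)
    logger.info("generating %d synthetic studies", n_studies)
    manifest, clips = build_clip_datasets(params)
    labels = manifest["label"].to_numpy()
    split = training.split_by_patient(manifest, seed=seed)
    assert training.check_no_leakage(manifest, split) == 0
    idx = _partition_indices(manifest, split)

    def subset_single(view, part):
        return training.ClipDataset(clips=clips[view][idx[part]],
                                    labels=labels[idx[part]])

    def subset_multi(part):
        return training.MultiviewDataset(
            clips={v: clips[v][idx[part]] for v in params.views},
            labels=labels[idx[part]])

    hp = training.HyperParams(learning_rate=0.01, scheduler_patience=3,
                              scheduler_factor=0.5, epochs=epochs_single,
                              batch_size=batch_size, seed=seed)
    scores: dict[str, np.ndarray] = {}
    records: dict[str, training.TrainRecord] = {}
    backbone = BackboneConfig(clip_length=CLIP_LENGTH, side=CLIP_SIDE)
    for vi, view in enumerate(params.views):
        logger.info("training single-view model for %s", view)
        model = build_single_view_model(backbone, seed=seed * 101 + vi)
        rec = training.train(model, subset_single(view, "train"),
                             subset_single(view, "dev"), hp,
                             augment=augment, mode="single_view")
        ckpt = training.select_checkpoint(rec, "max_dev_auc")
        model.load_state_dict(ckpt.state)
        scores[view] = training.predict_scores(
            model, subset_single(view, "test"), "single_view")
        records[view] = rec

    logger.info("training multiview model")
    mv_cfg = MultiviewConfig(backbone=backbone)
    mv = build_multiview_model(mv_cfg, seed=seed * 101 + 7)
    hp_mv = training.HyperParams(learning_rate=0.01, scheduler_patience=3,
                                 scheduler_factor=0.5, epochs=epochs_multi,
                                 batch_size=batch_size, seed=seed + 1)
    rec = training.train(mv, subset_multi("train"), subset_multi("dev"),
                         hp_mv, augment=augment, mode="multiview")
    ckpt = training.select_checkpoint(rec, "max_dev_auc")
    mv.load_state_dict(ckpt.state)
    scores["multiview"] = training.predict_scores(mv, subset_multi("test"),
                                                  "multiview")
    records["multiview"] = rec
    scores["average"] = late_fusion_average(
        [scores[v] for v in params.views])

    test_labels = labels[idx["test"]]
    aucs = {name: evaluation.roc_auc(s, test_labels).auc
            for name, s in scores.items()}
    best_single = max(params.views, key=lambda v: aucs[v])
    comparisons = evaluation.compare_models(scores, "multiview", test_labels)
    bayes = synthetic.bayes_auc_single_view(params, 0, seed=seed + 999)
    return FusionExperimentResult(
        aucs=aucs, best_single_view=best_single,
        auc_gap=aucs["multiview"] - aucs[best_single],
        comparisons=comparisons, bayes_single_view_auc=bayes,
        test_scores=scores, test_labels=test_labels, records=records,
        n_studies=n_studies)


def delong_type_i_error(n_reps: int = 500, n_per_class: int = 50,
                        alpha: float = 0.05, seed: int = 0) -> float:
    """Empirical type-I error of the paired DeLong test under the null
    (two independent noise score vectors, shared labels)."""
    labels = np.concatenate([np.ones(n_per_class), np.zeros(n_per_class)])
    rejections = 0
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, 23, rep])
        a = rng.random(2 * n_per_class)
        b = rng.random(2 * n_per_class)
        if evaluation.delong_test(a, b, labels).p_raw < alpha:
            rejections += 1
    return rejections / n_reps


def bootstrap_auc_coverage(n_reps: int = 200, n: int = 500,
                           prevalence: float = 0.3, shift: float = 1.0,
                           n_boot: int = 1000, seed: int = 0) -> float:
    """Coverage of the nominal-90% bootstrap AUC interval under a
    binormal generating process with known true AUC Phi(shift/sqrt(2))."""
    from scipy.stats import norm as _norm

    def _rank_auc(s, l):
        # tie-free rank AUC (the generating scores are continuous)
        r = np.empty(s.size)
        r[np.argsort(s)] = np.arange(s.size)
        m = int(l.sum())
        return (r[l == 1].mean() - (m - 1) / 2.0) / (s.size - m)

    true_auc = float(_norm.cdf(shift / np.sqrt(2)))
    covered = 0
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, 29, rep])
        labels = (rng.random(n) < prevalence).astype(int)
        if labels.min() == labels.max():
            labels[:2] = [0, 1]
        scores = rng.normal(0.0, 1.0, n) + shift * labels
        lo, hi = evaluation.bootstrap_ci(
            _rank_auc, scores, labels,
            n_boot=n_boot, seed=int(rng.integers(2**31 - 1)))
        if lo <= true_auc <= hi:
            covered += 1
    return covered / n_reps


# trunk for explainability probes: only 2x spatial downsampling so the
# final convolutional block keeps a 16x16 map whose receptive fields do
# not smear grad-CAM mass far beyond the discriminative band
LOCALIZATION_BACKBONE = BackboneConfig(
    clip_length=CLIP_LENGTH, side=CLIP_SIDE,
    widths=(12, 16, 24, 32, 32),
    strides=((1, 2, 2), (1, 1, 1), (2, 1, 1), (2, 1, 1), (1, 1, 1)))


def discriminative_region_in_clip(params: synthetic.SynthParams, view: str,
                                  side: int = CLIP_SIDE) -> np.ndarray:
    """Map the generator's wall-band ground-truth region into processed
    clip coordinates (ground-truth cone crop + nearest-neighbor resize)."""
    from skimage import transform

    p = params.resolved()
    region = synthetic.wall_band_region(p, view)
    cone = synthetic.cone_mask(p, view)
    r0, c0, sq = preprocess._bounding_square(cone)
    h = w = p.frame_size
    canvas = np.zeros((sq, sq), bool)
    rs, re = max(r0, 0), min(r0 + sq, h)
    cs, ce = max(c0, 0), min(c0 + sq, w)
    canvas[rs - r0:re - r0, cs - c0:ce - c0] = region[rs:re, cs:ce]
    return transform.resize(canvas.astype(float), (side, side), order=0) > 0.5


def run_localization_experiment(n_studies: int = 250, seed: int = 0,
                                epochs: int = 20):
    """Train a tiny single-view model on a task its view fully determines
    (label = sign of that view's latent), for explainability probes.

    The checkpoint with the lowest development loss is used (the most
    confident well-fit epoch, as for the view/doppler classifiers), so
    positive cases clear the >0.95 confidence bar.

    Returns (model, test_set, test_scores, params, view).
    """
    params = synthetic.SynthParams(
        n_studies=n_studies, frame_size=64, frame_count=24,
        label_rule="sum", prevalence=0.5, seed=seed)
    manifest, clips = build_clip_datasets(params)
    view = params.views[0]
    # degenerate single-view-determined label: z_0 above its median
    labels = np.array([
        int(synthetic.generate_latents(params.resolved(), i).z[0] > 0)
        for i in range(params.n_studies)])
    split = training.split_by_patient(manifest, seed=seed)
    idx = _partition_indices(manifest, split)
    model = build_single_view_model(LOCALIZATION_BACKBONE, seed=seed)
    hp = training.HyperParams(learning_rate=0.01, scheduler_patience=3,
                              scheduler_factor=0.5, epochs=epochs,
                              batch_size=16, seed=seed)
    train_set = training.ClipDataset(clips[view][idx["train"]],
                                     labels[idx["train"]])
    dev_set = training.ClipDataset(clips[view][idx["dev"]], labels[idx["dev"]])
    rec = training.train(model, train_set, dev_set, hp, mode="single_view")
    ckpt = training.select_checkpoint(rec, "min_dev_loss")
    model.load_state_dict(ckpt.state)
    test_idx = np.concatenate([idx["test"], idx["dev"]])
    test_set = training.ClipDataset(clips[view][test_idx], labels[test_idx])
    test_scores = training.predict_scores(model, test_set, "single_view")
    return model, test_set, test_scores, params, view
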