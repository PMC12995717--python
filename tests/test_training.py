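"""Protocol conformance: splits, sweeps, scheduler, augmentation, loop."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from echofuse import models, training
from echofuse.errors import ConfigurationError, TrainingDivergedError


def _manifest(n_patients=100, studies_per_patient=None):
    rows = []
    s = 0
    for p in range(n_patients):
        k = 1 if studies_per_patient is None else studies_per_patient.get(p, 1)
        for _ in range(k):
            for view in ("A4c", "A2c", "PLAX"):
                rows.append({"patient_id": f"P{p:04d}",
                             "study_id": f"S{s:05d}", "view": view,
                             "doppler": False, "path": f"S{s:05d}_{view}.npz",
                             "label": s % 2})
            s += 1
    return pd.DataFrame(rows)


class TestSplitByPatient:
    def test_exact_integer_split_of_100_patients(self):
        split = training.split_by_patient(_manifest(100), seed=0)
        sizes = {part: len(split.patients(part))
                 for part in training.PARTITIONS}
        assert sizes == {"train": 70, "dev": 15, "test": 15}

    def test_multi_study_patient_stays_in_one_partition(self):
        manifest = _manifest(20, studies_per_patient={3: 4})
        split = training.split_by_patient(manifest, seed=1)
        assert training.check_no_leakage(manifest, split) == 0
        parts = manifest[manifest["patient_id"] == "P0003"][
            "patient_id"].map(split.assignment)
        assert parts.nunique() == 1

    def test_same_seed_reproduces_assignment(self):
        m = _manifest(37)
        a = training.split_by_patient(m, seed=9).assignment
        b = training.split_by_patient(m, seed=9).assignment
        assert a == b

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match="3 patients"):
            training.split_by_patient(_manifest(2), seed=0)


class TestFilterCompleteStudies:
    def test_study_missing_required_view_excluded(self):
        m = _manifest(5)
        m = m[~((m["study_id"] == "S00002") & (m["view"] == "PLAX"))]
        out = training.filter_complete_studies(m, ("A4c", "A2c", "PLAX"))
        assert "S00002" not in set(out["study_id"])
        assert out["study_id"].nunique() == 4

    def test_exclusion_fraction_matches_construction(self):
        """A cohort constructed with 56.1% of studies lacking the doppler
        view reports that exclusion fraction."""
        n = 1000
        m = _manifest(n)
        m["doppler"] = True
        incomplete = m["study_id"].isin({f"S{i:05d}" for i in range(561)})
        m = m[~(incomplete & (m["view"] == "A4c"))]
        out, frac = training.filter_complete_studies(
            m, ("A4c", "A2c", "PLAX"), doppler_required=True,
            return_stats=True)
        assert frac == pytest.approx(0.561)
        assert out["study_id"].nunique() == n - 561

    def test_complete_manifest_passes_through(self):
        m = _manifest(8)
        out = training.filter_complete_studies(m, ("A4c", "A2c", "PLAX"))
        assert out["study_id"].nunique() == 8
        assert len(out) == 24

    def test_duplicate_candidates_resolved_by_path_order(self):
        m = _manifest(3)
        extra = m.iloc[[0]].assign(path="A_first_sorts_before.npz")
        m = pd.concat([m, extra], ignore_index=True)
        out = training.filter_complete_studies(m, ("A4c", "A2c", "PLAX"))
        chosen = out[(out["study_id"] == "S00000") & (out["view"] == "A4c")]
        assert chosen["path"].item() == "A_first_sorts_before.npz"


class TestHyperparamSweep:
    def test_learning_rates_log_uniform(self):
        trials = training.sample_hyperparams(10_000, seed=3)
        lrs = np.array([t.learning_rate for t in trials])
        assert lrs.min() >= 1e-6 and lrs.max() <= 5e-2
        lo, hi = np.log10(1e-6), np.log10(5e-2)
        stat = stats.kstest(np.log10(lrs), "uniform", args=(lo, hi - lo))
        assert stat.pvalue > 0.01

    def test_patience_and_factor_from_finite_sets(self):
        trials = training.sample_hyperparams(500, seed=4)
        assert {t.scheduler_patience for t in trials} <= {3, 5, 7, 10}
        assert {t.scheduler_factor for t in trials} <= {0.3, 0.5, 0.7}

    def test_same_seed_gives_identical_trials(self):
        a = training.sample_hyperparams(40, seed=5)
        b = training.sample_hyperparams(40, seed=5)
        assert a == b

    def test_out_of_range_hyperparams_rejected(self):
        with pytest.raises(ConfigurationError):
            training.HyperParams(learning_rate=0.1)
        with pytest.raises(ConfigurationError):
            training.HyperParams(scheduler_patience=4)


class TestPlateauScheduler:
    def test_strict_improvement_never_decays(self):
        hp = training.HyperParams(scheduler_patience=3, scheduler_factor=0.5)
        losses = [1.0 * 0.9 ** i for i in range(10)]   # 10%/epoch improvement
        assert training.plateau_lr_step(0.01, losses, hp) == 0.01

    def test_constant_loss_decays_after_fourth_bad_epoch(self):
        """patience=3: bad epochs 2,3,4 survive; the 4th bad epoch (5th
        overall) triggers lr 0.01 -> 0.005."""
        hp = training.HyperParams(scheduler_patience=3, scheduler_factor=0.5)
        assert training.plateau_lr_step(0.01, [1.0] * 4, hp) == 0.01
        assert training.plateau_lr_step(0.01, [1.0] * 5, hp) \
            == pytest.approx(0.005)

    def test_decay_resets_patience_counter(self):
        hp = training.HyperParams(scheduler_patience=3, scheduler_factor=0.5)
        # 9 constant epochs: decay at epoch 5, counter resets, next decay
        # would need 4 more bad epochs (epoch 9)
        assert training.plateau_lr_step(0.01, [1.0] * 8, hp) \
            == pytest.approx(0.005)
        assert training.plateau_lr_step(0.01, [1.0] * 9, hp) \
            == pytest.approx(0.0025)

    @given(st.lists(st.floats(0.1, 10.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_learning_rate_never_increases(self, losses):
        hp = training.HyperParams(scheduler_patience=3, scheduler_factor=0.3)
        sched = training.PlateauScheduler(0.01, 0.3, 3, 0.05)
        lrs = [sched.step(l) for l in losses]
        assert all(b <= a + 1e-15 for a, b in zip(lrs, lrs[1:]))

    def test_view_classifier_recipe(self):
        hp = training.view_classifier_hyperparams()
        assert hp.learning_rate == 0.01
        assert hp.scheduler_factor == 0.5
        assert hp.scheduler_patience == 50
        assert hp.scheduler_threshold == 0.01
        assert hp.scheduler_threshold_mode == "abs"
        assert hp.epochs == 1000


class TestAugmentation:
    def _clip(self, rng):
        return rng.integers(0, 255, (6, 16, 16, 3)).astype(np.uint8)

    def test_identity_ranges_are_bit_exact(self, rng):
        params = training.AugmentParams(crop_scale_range=(1.0, 1.0),
                                        color_jitter_range=(1.0, 1.0),
                                        rotation_range_deg=(0.0, 0.0))
        clip = self._clip(rng)
        out = training.augment_clip(clip, params, rng)
        assert out is clip or np.array_equal(out, clip)

    def test_shape_preserved_across_draws(self, rng):
        params = training.AugmentParams()
        clip = self._clip(rng)
        for _ in range(50):
            out = training.augment_clip(clip, params, rng)
            assert out.shape == clip.shape

    def test_rotation_draws_within_declared_range(self, rng):
        params = training.AugmentParams()
        clip = self._clip(rng)
        for _ in range(200):
            _, draw = training.augment_clip(clip, params, rng,
                                            return_params=True)
            assert -5.0 <= draw["rotation_deg"] <= 5.0
            assert 0.95 <= draw["crop_scale"] <= 1.0
            assert 0.8 <= draw["color_jitter"] <= 1.2


def _toy_dataset(n=48, seed=0, planted=True):
    """Clips whose mean brightness carries the label (fast to learn)."""
    rng = np.random.default_rng(seed)
    labels = (np.arange(n) % 2).astype(np.float64)
    clips = rng.integers(40, 80, (n, 16, 32, 32, 3)).astype(np.uint8)
    if planted:
        clips[labels == 1] += 60
    return training.ClipDataset(clips=clips, labels=labels)


class TestTrainLoop:
    def test_loss_decreases_on_learnable_data(self):
        model = models.build_single_view_model(models.BackboneConfig(), seed=0)
        hp = training.HyperParams(learning_rate=0.01, epochs=3, batch_size=8,
                                  seed=0, scheduler_patience=3,
                                  scheduler_factor=0.5)
        rec = training.train(model, _toy_dataset(48), _toy_dataset(24, 1), hp)
        assert len(rec.entries) == 3
        assert rec.entries[-1]["train_loss"] < rec.entries[0]["train_loss"]
        lrs = [e["lr"] for e in rec.entries]
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))

    def test_nan_loss_aborts_with_diagnostic(self):
        model = models.build_single_view_model(models.BackboneConfig(), seed=0)
        model.head.fc.weight.data[...] = np.nan
        hp = training.HyperParams(epochs=1, batch_size=8, seed=0)
        with pytest.raises(TrainingDivergedError, match="epoch 1"):
            training.train(model, _toy_dataset(16), _toy_dataset(16, 1), hp)

    def test_deterministic_given_seed(self):
        hp = training.HyperParams(learning_rate=0.01, epochs=1, batch_size=8,
                                  seed=7)
        recs = []
        for _ in range(2):
            model = models.build_single_view_model(models.BackboneConfig(),
                                                   seed=3)
            recs.append(training.train(model, _toy_dataset(32),
                                       _toy_dataset(16, 1), hp))
        assert recs[0].entries[0]["train_loss"] \
            == recs[1].entries[0]["train_loss"]


class TestSelectCheckpoint:
    def _record(self, aucs, losses=None):
        rec = training.TrainRecord()
        losses = losses or [0.5] * len(aucs)
        for i, (a, l) in enumerate(zip(aucs, losses), start=1):
            rec.entries.append({"epoch": i, "dev_auc": a, "dev_loss": l,
                                "train_loss": l, "lr": 0.01})
            rec.checkpoints.append({"epoch": i})
        return rec

    def test_max_dev_auc_picks_argmax(self):
        ckpt = training.select_checkpoint(self._record([0.6, 0.8, 0.7]))
        assert ckpt.epoch == 2

    def test_ties_break_to_earliest_epoch(self):
        ckpt = training.select_checkpoint(self._record([0.7, 0.7, 0.7]))
        assert ckpt.epoch == 1

    def test_min_dev_loss_criterion(self):
        ckpt = training.select_checkpoint(
            self._record([0.5, 0.5, 0.5], [0.5, 0.4, 0.4]), "min_dev_loss")
        assert ckpt.epoch == 2
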