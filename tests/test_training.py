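"""Training loops: scheduling, early stopping, modes, determinism."""

import numpy as np
import pytest

from echoclr.fixtures import CohortManifest, FixtureConfig, StudyRecord, generate_cohort
from echoclr.sampling import split_studies
from echoclr.training import (Checkpoint, ConfigurationError,
                              DegenerateLabelError, FinetuneConfig, FineTuner,
                              Pretrainer, PretrainConfig, default_lr_grid,
                              match_epoch_budget, select_learning_rate)


@pytest.fixture(scope="module")
def mini_cohort():
    cfg = FixtureConfig(n_studies=12, frame_size=32, frames_per_video=8,
                        videos_per_study=(2, 2), prevalence=0.5,
                        missing_label_rate=0.0, exclusion_rate=0.0, seed=17)
    manifest, videos = generate_cohort(cfg)
    return manifest, videos


class TestEpochBudget:
    def test_equal_sizes_unchanged(self):
        assert match_epoch_budget(100, 100, 300) == 300

    def test_reproduces_300_to_520_ratio(self):
        assert match_epoch_budget(26, 15, 300) == 520

    def test_rounding_stays_within_one_epoch(self):
        for pairs, items, ep in [(7, 3, 11), (5, 9, 40), (13, 4, 25)]:
            out = match_epoch_budget(pairs, items, ep)
            assert abs(out * items - pairs * ep) <= items

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            match_epoch_budget(0, 10, 300)


class TestLearningRateSelection:
    def test_argmin(self):
        assert select_learning_rate([0.1, 0.05, 0.001], [0.68, 0.61, 0.70]) == 0.05

    def test_single_entry(self):
        assert select_learning_rate([1e-4], [0.5]) == 1e-4

    def test_tie_goes_to_larger_rate(self):
        assert select_learning_rate([0.1, 0.001], [0.6, 0.6]) == 0.1

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_learning_rate([], [])

    def test_published_grids(self):
        assert default_lr_grid("ssl", 0.05) == [0.1, 0.05, 0.001]
        assert default_lr_grid("random", 0.10) == [1e-4, 5e-5, 1e-5]
        assert default_lr_grid("kinetics", 0.01) == [1e-4, 5e-5, 1e-5]
        assert default_lr_grid("ssl", 0.25) == [0.1]
        assert default_lr_grid("random", 1.0) == [1e-4]


class TestPretrainer:
    def _config(self, mode, epochs=2, seed=17):
        return PretrainConfig(mode=mode, encoder="tiny", batch_size=8,
                              lr=1e-3, epochs=epochs, seed=seed)

    def test_smoke_run_logs_and_improves(self, mini_cohort):
        manifest, videos = mini_cohort
        result = Pretrainer(manifest, videos, self._config("echoclr", epochs=20)).fit()
        assert len(result.history) == 20
        assert result.history.total.iloc[-1] < result.history.total.iloc[0]
        assert np.isfinite(result.history.nt_xent).all()
        assert np.isfinite(result.history.reorder).all()

    def test_mode_contracts(self, mini_cohort):
        manifest, videos = mini_cohort
        mi = Pretrainer(manifest, videos, self._config("misimclr")).fit()
        assert mi.history.reorder.isna().all()
        assert (mi.history.total == mi.history.nt_xent).all()
        sim = Pretrainer(manifest, videos, self._config("simclr")).fit()
        assert len(sim.history) == 2

    def test_seeded_determinism(self, mini_cohort):
        manifest, videos = mini_cohort
        a = Pretrainer(manifest, videos, self._config("echoclr")).fit()
        b = Pretrainer(manifest, videos, self._config("echoclr")).fit()
        assert a.history.equals(b.history)
        for x, y in zip(a.checkpoint.encoder_state, b.checkpoint.encoder_state):
            np.testing.assert_array_equal(x, y)

    def test_multi_instance_needs_pairable_studies(self, mini_cohort):
        manifest, videos = mini_cohort
        singles = CohortManifest([
            StudyRecord(study_id=r.study_id, video_ids=r.video_ids[:1])
            for r in manifest])
        with pytest.raises(ConfigurationError):
            Pretrainer(singles, videos, self._config("echoclr"))
        Pretrainer(singles, videos, self._config("simclr"))  # fine without pairs

    def test_checkpoint_round_trip(self, mini_cohort, tmp_path):
        manifest, videos = mini_cohort
        result = Pretrainer(manifest, videos, self._config("echoclr", epochs=1)).fit()
        path = tmp_path / "ckpt.npz"
        result.checkpoint.save(path)
        loaded = Checkpoint.load(path)
        assert loaded.encoder_name == "tiny"
        assert loaded.fingerprint == result.checkpoint.fingerprint
        for a, b in zip(loaded.encoder_state, result.checkpoint.encoder_state):
            np.testing.assert_array_equal(a, b)


class TestFineTuner:
    def _tuner(self, mini_cohort, val_losses=None, **overrides):
        manifest, videos = mini_cohort
        split = split_studies(manifest.study_ids, seed=3)
        kwargs = dict(init="random", task="severe_as", ratio=1.0, clip_len=8,
                      max_epochs=30, patience=5, lr=1e-4, batch_size=8,
                      encoder="tiny", seed=0)
        kwargs.update(overrides)
        config = FinetuneConfig(**kwargs)
        tuner = FineTuner(manifest, videos, config, split.studies("train"),
                          split.studies("val"))
        if val_losses is not None:
            seq = iter(val_losses)
            tuner._val_loss = lambda *a, **k: next(seq)
        return tuner

    def test_patience_arithmetic(self, mini_cohort):
        """Val losses [0.7, 0.6, 0.61..0.65] stop after epoch 7, keep epoch 2."""
        tuner = self._tuner(mini_cohort,
                            val_losses=[0.7, 0.6, 0.61, 0.62, 0.63, 0.64, 0.65, 0.1])
        result = tuner.fit()
        assert len(result.history) == 7
        assert result.best_epoch == 2
        assert result.val_loss == pytest.approx(0.6)

    def test_max_epochs_without_trigger_returns_argmin(self, mini_cohort):
        tuner = self._tuner(mini_cohort, max_epochs=6,
                            val_losses=[0.50, 0.49, 0.52, 0.48, 0.50, 0.51])
        result = tuner.fit()
        assert len(result.history) == 6
        assert result.best_epoch == 4

    def test_early_stop_bound(self, mini_cohort):
        tuner = self._tuner(mini_cohort, max_epochs=12,
                            val_losses=[0.3] + [0.4] * 30)
        result = tuner.fit()
        assert len(result.history) <= min(12, result.best_epoch + 5)

    def test_degenerate_labels_rejected(self, mini_cohort):
        manifest, videos = mini_cohort
        positives = CohortManifest(
            [r for r in manifest.records if r.severe_as_label == 1])
        config = FinetuneConfig(init="random", task="severe_as", lr=1e-4,
                                clip_len=8, encoder="tiny", seed=0)
        with pytest.raises(DegenerateLabelError):
            FineTuner(manifest, videos, config,
                      positives.study_ids, manifest.study_ids[:2])

    def test_kinetics_init_needs_stats(self):
        with pytest.raises(ConfigurationError):
            FinetuneConfig(init="kinetics").validate()
        FinetuneConfig(init="kinetics",
                       kinetics_stats=([0.43, 0.39, 0.37], [0.22, 0.22, 0.21])
                       ).validate()

    def test_kinetics_standardization_path_runs(self, mini_cohort):
        tuner = self._tuner(mini_cohort, init="kinetics", max_epochs=2, patience=1,
                            kinetics_stats=([0.43, 0.39, 0.37], [0.22, 0.22, 0.21]))
        result = tuner.fit()
        assert len(result.history) >= 1
        scores = result.predict_videos(mini_cohort[1])
        assert all(0.0 <= s <= 1.0 for s in scores.values())

    def test_prediction_scores_are_probabilities(self, mini_cohort):
        manifest, videos = mini_cohort
        tuner = self._tuner(mini_cohort, max_epochs=2, patience=1)
        result = tuner.fit()
        scores = result.predict_videos(videos)
        assert set(scores) == set(videos)
        assert all(0.0 <= s <= 1.0 for s in scores.values())
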