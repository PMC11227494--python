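"""Splitting, titration, positive pairs, clips, permutations, augmentation."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import chisquare

from echoclr.fixtures import CohortManifest, EchoVideo, StudyRecord
from echoclr.sampling import (AugmentationConfig, Clip, augment_clip,
                              enumerate_positive_pairs, permutation_rank,
                              permutation_unrank, sample_clip, shuffle_clip,
                              split_studies, titrate)


def _manifest(sizes):
    return CohortManifest([
        StudyRecord(study_id=f"s{i}", video_ids=[f"s{i}_v{j}" for j in range(m)])
        for i, m in enumerate(sizes)])


class TestSplit:
    def test_750_100_150_of_1000(self):
        ids = [f"s{i}" for i in range(1000)]
        split = split_studies(ids, seed=0)
        assert len(split.studies("train")) == 750
        assert len(split.studies("val")) == 100
        assert len(split.studies("test")) == 150

    def test_partition_and_seed_behaviour(self):
        ids = [f"s{i}" for i in range(37)]
        a = split_studies(ids, seed=1)
        b = split_studies(ids, seed=1)
        c = split_studies(ids, seed=2)
        assert a.assignment == b.assignment
        assert a.assignment != c.assignment
        union = a.studies("train") + a.studies("val") + a.studies("test")
        assert sorted(union) == sorted(ids)

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            split_studies(["a", "b", "a", "c"], seed=0)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_studies([f"s{i}" for i in range(10)], fractions=(0.5, 0.2, 0.2), seed=0)


class TestTitrate:
    @pytest.mark.parametrize("n,ratio,expected", [
        (5194, 0.01, 51), (5194, 0.05, 259), (5194, 0.10, 519),
        (5194, 0.25, 1298), (5194, 0.50, 2597), (5194, 1.00, 5194),
        (5311, 0.01, 53), (5311, 0.05, 265), (5311, 0.10, 531),
        (5311, 0.25, 1327), (5311, 0.50, 2655), (5311, 1.00, 5311),
    ])
    def test_printed_study_counts(self, n, ratio, expected):
        """The floor rule reproduces every published titration count."""
        ids = [f"s{i}" for i in range(n)]
        assert len(titrate(ids, ratio, seed=0)) == expected

    def test_subset_without_replacement(self):
        ids = [f"s{i}" for i in range(40)]
        sub = titrate(ids, 0.25, seed=4)
        assert len(sub) == len(set(sub)) == 10
        assert set(sub) <= set(ids)

    def test_full_ratio_identity(self):
        ids = ["a", "b", "c"]
        assert titrate(ids, 1.0, seed=0) == ids

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            titrate(["a", "b"], 0.01, seed=0)


class TestPositivePairs:
    def test_three_videos_three_pairs(self):
        pairs = enumerate_positive_pairs(_manifest([3]))
        assert len(pairs) == 3
        assert {(p.video_id_a, p.video_id_b) for p in pairs} == {
            ("s0_v0", "s0_v1"), ("s0_v0", "s0_v2"), ("s0_v1", "s0_v2")}

    def test_single_video_study_contributes_nothing(self):
        assert enumerate_positive_pairs(_manifest([1, 1])) == []

    def test_counts_match_brute_force_on_random_manifests(self, rng):
        for _ in range(50):
            sizes = rng.integers(1, 6, size=rng.integers(1, 12))
            manifest = _manifest(sizes.tolist())
            pairs = enumerate_positive_pairs(manifest)
            brute = 0
            for r in manifest:
                for a in r.video_ids:
                    for b in r.video_ids:
                        if a < b:
                            brute += 1
            assert len(pairs) == brute == sum(m * (m - 1) // 2 for m in sizes)
            assert len(set(pairs)) == len(pairs)


def _gray_video(t, h=32, w=32):
    frames = np.arange(t, dtype=np.uint8)[:, None, None] * np.ones((h, w), np.uint8)
    return EchoVideo(study_id="s", video_id="v", frames=frames)


class TestSampleClip:
    def test_whole_video_when_exact_length(self):
        clip = sample_clip(_gray_video(4), 4, seed=0)
        assert clip.start == 0
        np.testing.assert_allclose(clip.frames[:, 0, 0] * 255, [0, 1, 2, 3])

    def test_loop_padding(self):
        clip = sample_clip(_gray_video(3), 4, seed=0)
        np.testing.assert_allclose(clip.frames[:, 0, 0] * 255, [0, 1, 2, 0])

    def test_values_scaled_to_unit_interval(self, small_cohort):
        _, _, videos = small_cohort
        clip = sample_clip(next(iter(videos.values())), 4, seed=1)
        assert clip.frames.dtype == np.float32
        assert 0.0 <= clip.frames.min() and clip.frames.max() <= 1.0

    def test_start_uniform(self):
        """T=20, K=16 admits starts {0..4}; 5000 draws pass a chi-square test."""
        video = _gray_video(20)
        counts = np.zeros(5)
        rng = np.random.default_rng(123)
        for _ in range(5000):
            counts[sample_clip(video, 16, rng).start] += 1
        assert chisquare(counts).pvalue > 0.01


class TestPermutations:
    def test_identity_and_reverse_ranks(self):
        assert permutation_rank((0, 1, 2, 3)) == 0
        # brute-force lexicographic enumeration as the oracle
        universe = sorted(itertools.permutations(range(4)))
        assert permutation_rank((3, 2, 1, 0)) == universe.index((3, 2, 1, 0)) == 23

    def test_rank_matches_lexicographic_enumeration(self):
        for k in (2, 3, 4):
            for i, perm in enumerate(sorted(itertools.permutations(range(k)))):
                assert permutation_rank(perm) == i
                assert permutation_unrank(i, k) == perm

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            permutation_rank((0, 0, 1))
        with pytest.raises(ValueError):
            permutation_unrank(24, 4)


class TestShuffleClip:
    def test_inverse_restores_original(self, rng):
        clip = Clip(frames=rng.random((4, 8, 8)).astype(np.float32),
                    video_id="v", start=0)
        shuffled, label = shuffle_clip(clip, seed=5)
        inverse = np.empty(4, int)
        inverse[list(label.order)] = np.arange(4)
        np.testing.assert_array_equal(shuffled.frames[inverse], clip.frames)
        assert 0 <= label.class_index < math.factorial(4)
        assert permutation_rank(label.order) == label.class_index

    def test_orders_uniform_over_24000_draws(self):
        clip = Clip(frames=np.zeros((4, 4, 4), np.float32), video_id="v", start=0)
        counts = np.zeros(24)
        rng = np.random.default_rng(7)
        for _ in range(24000):
            counts[shuffle_clip(clip, rng)[1].class_index] += 1
        # each class ~ Binomial(24000, 1/24): mean 1000, sd ~ 31
        sd = math.sqrt(24000 * (1 / 24) * (23 / 24))
        assert np.abs(counts - 1000).max() < 3 * sd


class TestAugmentClip:
    def _clip(self, rng, h=32, w=32):
        return Clip(frames=rng.random((4, h, w)).astype(np.float32),
                    video_id="v", start=0)

    def test_disabled_config_is_identity(self, rng):
        clip = self._clip(rng)
        cfg = AugmentationConfig(max_pad=0, flip_prob=0.0, rotation_prob=0.0)
        out = augment_clip(clip, cfg, seed=0)
        np.testing.assert_array_equal(out.frames, clip.frames)

    def test_flip_is_involution(self, rng):
        clip = self._clip(rng)
        cfg = AugmentationConfig(max_pad=0, flip_prob=1.0, rotation_prob=0.0)
        once = augment_clip(clip, cfg, seed=1)
        twice = augment_clip(once, cfg, seed=2)
        np.testing.assert_array_equal(twice.frames, clip.frames)

    def test_shape_and_range_preserved(self, rng):
        clip = self._clip(rng)
        out = augment_clip(clip, AugmentationConfig(), seed=3)
        assert out.frames.shape == clip.frames.shape
        assert out.frames.min() >= 0.0 and out.frames.max() <= 1.0

    def test_clip_consistency_across_frames(self, rng):
        """Identical input frames must remain identical after augmentation:
        the whole clip receives one geometric transform."""
        frame = rng.random((32, 32)).astype(np.float32)
        clip = Clip(frames=np.stack([frame] * 4), video_id="v", start=0)
        for seed in range(10):
            out = augment_clip(clip, AugmentationConfig(), seed=seed)
            for t in range(1, 4):
                np.testing.assert_array_equal(out.frames[t], out.frames[0])

    def test_deterministic_given_seed(self, rng):
        clip = self._clip(rng)
        a = augment_clip(clip, AugmentationConfig(), seed=9)
        b = augment_clip(clip, AugmentationConfig(), seed=9)
        np.testing.assert_array_equal(a.frames, b.frames)
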