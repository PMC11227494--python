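"""View classification, hull masking, downsampling, manifest filtering."""

import numpy as np
import pytest

from echoclr.evaluation import auroc
from echoclr.fixtures import EchoVideo, FixtureConfig, generate_cohort, wall_thickness_score
from echoclr.preprocess import (ConstantViewClassifier, binarize_and_hull_mask,
                                classify_view, downsample_video,
                                filter_manifest, preprocess_video)


def _video(frames, vid="v0"):
    return EchoVideo(study_id="s0", video_id=vid, frames=np.asarray(frames, np.uint8))


class TestClassifyView:
    def test_constant_plax_classifier_retained(self, small_cohort):
        _, _, videos = small_cohort
        video = next(iter(videos.values()))
        clf = ConstantViewClassifier(("PLAX", "A4C"), (1.0, 0.0))
        dec = classify_view(video, clf, seed=0)
        assert dec.retained
        assert dec.selected_view == "PLAX"
        assert dec.mean_probs[0] == pytest.approx(1.0)

    def test_two_frame_average(self):
        """Frame probs 0.8 and 0.6 average to a 0.7 video-level PLAX prob."""
        frames = np.zeros((2, 32, 32), np.uint8)
        frames[0] += 10  # distinguish frames by intensity
        video = _video(frames)

        class ByIntensity:
            class_names = ("PLAX", "other")

            def __call__(self, frame):
                p = 0.8 if frame.mean() > 5 else 0.6
                return np.array([p, 1 - p])

        dec = classify_view(video, ByIntensity(), n_frames=2, seed=0)
        assert dec.mean_probs[0] == pytest.approx(0.7)
        assert dec.retained

    def test_mean_matches_brute_force_average(self, rng):
        """With n_frames == T (all frames sampled), the video-level vector is
        the plain average of the per-frame vectors."""
        frames = rng.integers(0, 256, (6, 40, 40), dtype=np.uint8)
        video = _video(frames)

        class Hashing:
            class_names = ("PLAX", "A4C", "A2C")

            def __call__(self, frame):
                h = abs(hash(round(float(frame.mean()), 3))) % 97
                raw = np.array([h + 1, (h * 7) % 31 + 1, (h * 13) % 17 + 1], float)
                return raw / raw.sum()

        clf = Hashing()
        dec = classify_view(video, clf, n_frames=6, frame_size=40, seed=5)
        from skimage.transform import resize
        expected = np.mean([clf(resize(f.astype(float), (40, 40), order=1,
                                       anti_aliasing=False, preserve_range=True))
                            for f in frames], axis=0)
        np.testing.assert_allclose(dec.mean_probs, expected, atol=1e-12)

    def test_deterministic_given_seed(self, small_cohort):
        _, _, videos = small_cohort
        video = next(iter(videos.values()))
        clf = ConstantViewClassifier(("PLAX", "A4C"), (0.6, 0.4))
        a = classify_view(video, clf, seed=3)
        b = classify_view(video, clf, seed=3)
        np.testing.assert_array_equal(a.mean_probs, b.mean_probs)

    def test_bad_probability_vector_rejected(self):
        video = _video(np.zeros((2, 32, 32)))

        class Bad:
            class_names = ("PLAX", "other")

            def __call__(self, frame):
                return np.array([0.9, 0.5])  # sums to 1.4

        with pytest.raises(ValueError):
            classify_view(video, Bad(), seed=0)


class TestHullMask:
    def test_bright_rectangle_unchanged(self):
        frames = np.zeros((3, 40, 40), np.uint8)
        frames[:, 10:30, 12:28] = 250
        video = _video(frames)
        out = binarize_and_hull_mask(video)
        np.testing.assert_array_equal(out.frames, frames)

    def test_triangle_support_matches_point_in_polygon_oracle(self):
        """Support after masking equals the triangle (its own convex hull),
        checked pixel-by-pixel with a barycentric-sign oracle."""
        h = w = 60
        verts = np.array([[10.0, 30.0], [50.0, 10.0], [50.0, 52.0]])  # (row, col)
        frames = np.full((2, h, w), 80, np.uint8)  # dim background everywhere
        from skimage.draw import polygon
        rr, cc = polygon(verts[:, 0], verts[:, 1])
        frames[:, rr, cc] = 240
        out = binarize_and_hull_mask(_video(frames), threshold=200)

        def inside(p, a, b, c):
            def cross(o, u, v):
                return (u[0] - o[0]) * (v[1] - o[1]) - (u[1] - o[1]) * (v[0] - o[0])
            d1, d2, d3 = cross(a, b, p), cross(b, c, p), cross(c, a, p)
            neg = (d1 < 0) or (d2 < 0) or (d3 < 0)
            pos = (d1 > 0) or (d2 > 0) or (d3 > 0)
            return not (neg and pos)

        support = out.frames[0] > 0
        oracle = np.zeros((h, w), bool)
        for r in range(h):
            for c in range(w):
                oracle[r, c] = inside((r, c), *verts)
        # discretization can disagree along the hull boundary only
        mismatch = support ^ oracle
        assert mismatch.mean() < 0.02
        interior = np.zeros_like(oracle)
        for r in range(h):
            for c in range(w):
                interior[r, c] = inside((r, c), *(verts + np.array([[2, 0], [-2, 1], [-2, -1]])))
        assert support[interior].all()

    def test_idempotent(self, small_cohort):
        _, _, videos = small_cohort
        video = next(iter(videos.values()))
        once = binarize_and_hull_mask(video)
        twice = binarize_and_hull_mask(once)
        np.testing.assert_array_equal(once.frames, twice.frames)

    def test_never_increases_intensity(self, small_cohort):
        _, _, videos = small_cohort
        for video in list(videos.values())[:5]:
            out = binarize_and_hull_mask(video)
            assert (out.frames <= video.frames).all()

    def test_no_contour_returns_unchanged(self, caplog):
        video = _video(np.full((2, 32, 32), 50, np.uint8))
        out = binarize_and_hull_mask(video, threshold=200)
        np.testing.assert_array_equal(out.frames, video.frames)


class TestDownsample:
    def test_shape_contract(self):
        video = _video(np.zeros((5, 224, 224)))
        out = downsample_video(video, 112)
        assert out.frames.shape == (5, 112, 112)

    def test_constant_frame_stays_constant(self):
        video = _video(np.full((2, 64, 64), 137))
        out = downsample_video(video, 32)
        assert (out.frames == 137).all()

    def test_bilinear_convexity(self, small_cohort):
        _, _, videos = small_cohort
        video = next(iter(videos.values()))
        out = downsample_video(video, 32)
        for t in range(video.n_frames):
            assert out.frames[t].min() >= video.frames[t].min()
            assert out.frames[t].max() <= video.frames[t].max()

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            downsample_video(_video(np.zeros((1, 20, 20))), 112)


class TestFilterManifest:
    def test_empty_flag_set_is_identity(self, small_cohort):
        _, manifest, _ = small_cohort
        out = filter_manifest(manifest, set())
        assert out.study_ids == manifest.study_ids

    def test_partition(self, small_cohort):
        _, manifest, _ = small_cohort
        kept = filter_manifest(manifest, {"llg_as"})
        removed = [r for r in manifest if "llg_as" in r.exclusion_flags]
        assert len(kept) + len(removed) == len(manifest)
        assert set(kept.study_ids).isdisjoint(r.study_id for r in removed)
        assert all("llg_as" not in r.exclusion_flags for r in kept)


class TestChainPreservesSignal:
    def test_planted_signal_survives_preprocessing(self):
        """Hull masking + downsampling keeps the oracle AUROC within 0.05."""
        cfg = FixtureConfig(n_studies=200, prevalence=0.5, frame_size=64,
                            frames_per_video=2, effect_size=2.0,
                            missing_label_rate=0.0, seed=31)
        manifest, videos = generate_cohort(cfg)
        labels = [r.severe_as_label for r in manifest]
        raw = [np.mean([wall_thickness_score(videos[v]) for v in r.video_ids])
               for r in manifest]
        pre = [np.mean([wall_thickness_score(preprocess_video(videos[v], size=32))
                        for v in r.video_ids]) for r in manifest]
        a_raw, a_pre = auroc(labels, raw), auroc(labels, pre)
        assert abs(a_raw - a_pre) < 0.05, (a_raw, a_pre)
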