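"""Video curation: view classification, content masking, downsampling.

The curation chain mirrors routine echo pipelines: (1) decide the
echocardiographic view of each video by averaging frame-level classifier
probabilities over ten randomly sampled frames and keeping PLAX videos;
(2) strip everything outside the central image content by binarizing at a
fixed intensity threshold and masking outside the convex hull of the
largest bright contour; (3) spatially downsample to the model resolution.

The view classifier itself is pluggable — any callable mapping a 2D frame
to a probability vector over named view classes.  No pretrained weights
ship with the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image
from skimage.transform import resize

from .fixtures import CohortManifest, EchoVideo

logger = logging.getLogger(__name__)

__all__ = [
    "ViewDecision", "classify_view", "binarize_and_hull_mask",
    "downsample_video", "filter_manifest", "preprocess_video",
    "ConstantViewClassifier",
]

DEFAULT_THRESHOLD = 200
DEFAULT_SIZE = 112
PLAX = "PLAX"


@dataclass
class ViewDecision:
    video_id: str
    class_names: tuple[str, ...]
    mean_probs: np.ndarray
    selected_view: str
    retained: bool


class ConstantViewClassifier:
    """Trivial frame classifier emitting a fixed probability vector."""

    def __init__(self, class_names: tuple[str, ...], probs):
        self.class_names = tuple(class_names)
        self.probs = np.asarray(probs, dtype=np.float64)

    def __call__(self, frame: np.ndarray) -> np.ndarray:
        return self.probs


def _check_probs(p: np.ndarray, n_classes: int) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64).ravel()
    if p.shape[0] != n_classes or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(
            f"classifier must return a length-{n_classes} probability vector, got {p!r}")
    return p


def classify_view(video: EchoVideo, frame_classifier, n_frames: int = 10,
                  frame_size: int = 224, seed: int = 0) -> ViewDecision:
    """Average frame-level view probabilities into a video-level decision.

    ``n_frames`` frames are sampled without replacement (with replacement
    when the video is shorter), resized to ``frame_size`` squared, scored
    by the classifier, and the probability vectors averaged; the video is
    retained iff the argmax class is PLAX.
    """
    class_names = tuple(frame_classifier.class_names)
    rng = np.random.default_rng(seed)
    t = video.n_frames
    if t >= n_frames:
        idx = rng.choice(t, size=n_frames, replace=False)
    else:
        idx = rng.choice(t, size=n_frames, replace=True)
    probs = np.zeros(len(class_names), dtype=np.float64)
    for i in idx:
        frame = resize(video.frames[i].astype(np.float64), (frame_size, frame_size),
                       order=1, anti_aliasing=False, preserve_range=True)
        probs += _check_probs(frame_classifier(frame), len(class_names))
    probs /= n_frames
    selected = class_names[int(np.argmax(probs))]
    return ViewDecision(video_id=video.video_id, class_names=class_names,
                        mean_probs=probs, selected_view=selected,
                        retained=(selected == PLAX))


def binarize_and_hull_mask(video: EchoVideo, threshold: int = DEFAULT_THRESHOLD) -> EchoVideo:
    """Zero all pixels outside the convex hull of the largest bright contour.

    The binary mask is the union over frames of intensity >= ``threshold``
    (one hull per video, so the field of view does not jitter over time).
    If nothing reaches the threshold the video is returned unchanged.
    """
    if not (0 <= threshold <= 255):
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    bright = (video.frames >= threshold).any(axis=0)
    if not bright.any():
        logger.warning("video %s: no pixel reaches threshold %d; left unmasked",
                       video.video_id, threshold)
        return video
    labels, n = ndimage.label(bright)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        largest = int(np.argmax(sizes)) + 1
    else:
        largest = 1
    hull = convex_hull_image(labels == largest)
    masked = np.where(hull[None, :, :], video.frames, 0).astype(np.uint8)
    return EchoVideo(study_id=video.study_id, video_id=video.video_id,
                     frames=masked, fps=video.fps, view=video.view)


def downsample_video(video: EchoVideo, size: int = DEFAULT_SIZE) -> EchoVideo:
    """Bilinearly resize every frame to ``size`` x ``size``."""
    h, w = video.frames.shape[1:]
    if h < size / 4 or w < size / 4:
        raise ValueError(f"frames {h}x{w} too small to resize to {size}x{size}")
    out = resize(video.frames.astype(np.float64), (video.n_frames, size, size),
                 order=1, anti_aliasing=False, preserve_range=True)
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return EchoVideo(study_id=video.study_id, video_id=video.video_id,
                     frames=out, fps=video.fps, view=video.view)


def preprocess_video(video: EchoVideo, threshold: int = DEFAULT_THRESHOLD,
                     size: int = DEFAULT_SIZE) -> EchoVideo:
    """Full per-video chain: hull masking then spatial downsampling."""
    return downsample_video(binarize_and_hull_mask(video, threshold), size)


def filter_manifest(manifest: CohortManifest, excluded_flags: set[str]) -> CohortManifest:
    """Drop studies carrying any excluded flag (e.g. low-flow low-gradient AS)."""
    kept = [r for r in manifest if not (r.exclusion_flags & set(excluded_flags))]
    logger.info("filter_manifest: kept %d of %d studies (excluded flags: %s)",
                len(kept), len(manifest), sorted(excluded_flags))
    return CohortManifest(kept)
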