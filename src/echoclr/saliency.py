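"""Grad-CAM for 3D video encoders with temporal max-projection.

The class-activation volume is the ReLU-rectified, channel-weighted sum of
the last convolution block's activations, with channel weights obtained by
global-average-pooling the gradient of the target logit over the full
spatiotemporal grid (the canonical Grad-CAM recipe extended to 3D).  For
the default encoder on a 32-frame 112x112 clip the raw grid is 7x7x4
(height x width x time).  The grid is spline-interpolated (order 3) back
to the clip resolution 112x112x32 and collapsed to a single 2D heatmap by
the pixelwise maximum along time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import zoom

from .fixtures import EchoVideo
from .models import DiseaseHead, VideoEncoder
from .sampling import Clip, sample_clip

logger = logging.getLogger(__name__)

__all__ = ["SaliencyVolume", "gradcam_volume", "project_saliency", "saliency_map",
           "save_overlay"]

SALIENCY_FRAMES = 32


@dataclass
class SaliencyVolume:
    raw: np.ndarray        # (H', W', T') non-negative weights
    upsampled: np.ndarray  # (H, W, T)
    projected: np.ndarray  # (H, W) pixelwise max over time


def _clip_to_batch(clip: Clip) -> np.ndarray:
    x = clip.frames[None, None]  # (1, 1, K, H, W)
    return np.repeat(x, 3, axis=1).astype(np.float32)


def gradcam_volume(encoder: VideoEncoder, head: DiseaseHead, clip: Clip | EchoVideo,
                   target: str = "positive") -> np.ndarray:
    """Raw Grad-CAM grid (height x width x time) for the disease logit.

    ``clip`` may be a 32-frame clip or a video (its first 32 frames are
    taken, loop-padded when shorter).  ``target`` selects the sign of the
    differentiated pre-sigmoid logit: "positive" (default) or "negative".
    """
    if isinstance(clip, EchoVideo):
        if clip.n_frames < SALIENCY_FRAMES:
            logger.info("video %s has %d < %d frames; loop-padding",
                        clip.video_id, clip.n_frames, SALIENCY_FRAMES)
        clip = sample_clip(clip, SALIENCY_FRAMES, seed=0)
    x = _clip_to_batch(clip)
    h = encoder.forward(x, train=False)
    acts = encoder.last_block_activation[0]  # (C, T', H', W')
    logit = head.forward(h, train=False)
    sign = {"positive": 1.0, "negative": -1.0}[target]
    dh = sign * np.ones_like(logit)[:, None] @ head.fc.weight.value  # d logit / d h
    dacts = encoder.grad_wrt_last_block(dh)[0]
    weights = dacts.mean(axis=(1, 2, 3))  # GAP over the full 3D grid
    cam = np.einsum("c,cthw->thw", weights, acts)
    cam = np.maximum(cam, 0.0)
    _ = logit  # the logit value itself is not part of the map
    return cam.transpose(1, 2, 0)  # (H', W', T')


def project_saliency(raw: np.ndarray, out_hw: int = 112,
                     out_t: int = SALIENCY_FRAMES) -> SaliencyVolume:
    """Upsample a raw grid to clip resolution and max-project over time."""
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 3:
        raise ValueError(f"raw grid must be (H', W', T'), got {raw.shape}")
    if np.any(raw < 0):
        raise ValueError("raw grid must be non-negative")
    factors = (out_hw / raw.shape[0], out_hw / raw.shape[1], out_t / raw.shape[2])
    up = zoom(raw, factors, order=3)
    up = np.maximum(up, 0.0)  # cubic splines can overshoot below zero
    return SaliencyVolume(raw=raw, upsampled=up, projected=up.max(axis=2))


def saliency_map(encoder: VideoEncoder, head: DiseaseHead, clip: Clip | EchoVideo,
                 out_hw: int | None = None, target: str = "positive") -> SaliencyVolume:
    """End-to-end: Grad-CAM grid, upsampling, temporal max-projection.

    ``out_hw`` defaults to the clip's own spatial resolution.
    """
    if isinstance(clip, EchoVideo):
        clip = sample_clip(clip, SALIENCY_FRAMES, seed=0)
    raw = gradcam_volume(encoder, head, clip, target=target)
    hw = out_hw if out_hw is not None else clip.frames.shape[1]
    return project_saliency(raw, out_hw=hw, out_t=clip.k)


def save_overlay(volume: SaliencyVolume, clip: Clip, path) -> None:
    """Write the projected heatmap over the clip's first frame as a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(clip.frames[0], cmap="gray", vmin=0.0, vmax=1.0)
    m = volume.projected
    denom = m.max() if m.max() > 0 else 1.0
    ax.imshow(m / denom, cmap="inferno", alpha=0.45,
              extent=(0, clip.frames.shape[2], clip.frames.shape[1], 0))
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
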