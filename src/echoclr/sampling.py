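"""Splits, label titration, positive pairs, clips, permutations, augmentation.

Every operation here is a pure function of its inputs and a seed, so the
whole data pipeline is bit-reproducible.

Conventions:

* Study-level splitting shuffles study ids and takes the first
  ``floor(0.75 n)`` for training, the next ``floor(0.10 n)`` for
  validation, and the remainder for testing.
* Label titration draws ``floor(ratio * n)`` studies uniformly without
  replacement — the floor rule reproduces the printed study counts at
  every ratio (e.g. 5194 x 0.10 -> 519, 5311 x 0.25 -> 1327).
* Frame orderings of a K-frame clip are encoded as their lexicographic
  rank in [0, K!) via the Lehmer code, the target space of the
  frame-reordering pretext task.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fixtures import CohortManifest, EchoVideo

__all__ = [
    "SplitAssignment", "Clip", "PermutationLabel", "PositivePair",
    "AugmentationConfig", "split_studies", "titrate",
    "enumerate_positive_pairs", "sample_clip", "permutation_rank",
    "permutation_unrank", "shuffle_clip", "augment_clip",
]

DEFAULT_FRACTIONS = (0.75, 0.10, 0.15)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class SplitAssignment:
    assignment: dict[str, str]  # study_id -> {"train","val","test"}
    fractions: tuple[float, float, float]
    seed: int

    def studies(self, split: str) -> list[str]:
        return [s for s, sp in self.assignment.items() if sp == split]

    def __getitem__(self, study_id: str) -> str:
        return self.assignment[study_id]


@dataclass
class Clip:
    """K consecutive (possibly loop-padded) frames rescaled to [0, 1]."""

    frames: np.ndarray  # (K, H, W) float32 in [0,1]
    video_id: str
    start: int

    @property
    def k(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class PermutationLabel:
    order: tuple[int, ...]
    class_index: int


@dataclass(frozen=True)
class PositivePair:
    study_id: str
    video_id_a: str
    video_id_b: str


@dataclass
class AugmentationConfig:
    max_pad: int = 8
    flip_prob: float = 0.5
    rotation_range: tuple[float, float] = (-10.0, 10.0)
    rotation_prob: float = 0.5

    def validate(self) -> None:
        for p in (self.flip_prob, self.rotation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0,1]")
        if self.max_pad < 0:
            raise ValueError("max_pad must be >= 0")


def split_studies(study_ids, fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
                  seed: int = 0) -> SplitAssignment:
    """Randomly partition studies into train/val/test at the study level."""
    ids = list(study_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate study ids")
    if len(ids) < 3:
        raise ValueError("need at least 3 studies to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n = len(ids)
    n_train = int(math.floor(fractions[0] * n))
    n_val = int(math.floor(fractions[1] * n))
    assignment = {}
    for i, sid in enumerate(order):
        if i < n_train:
            assignment[sid] = "train"
        elif i < n_train + n_val:
            assignment[sid] = "val"
        else:
            assignment[sid] = "test"
    return SplitAssignment(assignment=assignment, fractions=tuple(fractions), seed=seed)


def titrate(train_study_ids, ratio: float, seed: int = 0) -> list[str]:
    """Uniformly subsample ``floor(ratio * n)`` training studies."""
    ids = list(train_study_ids)
    if not 0.0 < ratio <= 1.0:
        raise ValueError(f"ratio must be in (0, 1], got {ratio}")
    k = int(math.floor(ratio * len(ids)))
    if k == 0:
        raise ValueError(f"ratio {ratio} of {len(ids)} studies selects nothing")
    if k == len(ids):
        return ids
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(ids), size=k, replace=False)
    return [ids[i] for i in sorted(picked)]


def enumerate_positive_pairs(manifest: CohortManifest) -> list[PositivePair]:
    """All unordered pairs of distinct videos within each study."""
    pairs = []
    for r in manifest:
        for a, b in itertools.combinations(sorted(r.video_ids), 2):
            pairs.append(PositivePair(study_id=r.study_id, video_id_a=a, video_id_b=b))
    return pairs


def sample_clip(video: EchoVideo, k: int, seed=0) -> Clip:
    """A clip of ``k`` consecutive frames with a uniform random start.

    Videos shorter than ``k`` are looped (frame t -> t mod T) from the
    first frame.  Intensities are rescaled from [0, 255] to [0, 1].
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    t = video.n_frames
    if t == 0:
        raise ValueError("empty video")
    rng = _rng(seed)
    if t >= k:
        start = int(rng.integers(0, t - k + 1))
        idx = np.arange(start, start + k)
    else:
        start = 0
        idx = np.arange(k) % t
    frames = video.frames[idx].astype(np.float32) / 255.0
    return Clip(frames=frames, video_id=video.video_id, start=start)


def permutation_rank(order) -> int:
    """Lexicographic rank of a permutation of 0..K-1 (Lehmer code)."""
    order = tuple(int(i) for i in order)
    k = len(order)
    if sorted(order) != list(range(k)):
        raise ValueError(f"{order} is not a permutation of 0..{k - 1}")
    rank = 0
    for i, v in enumerate(order):
        smaller_right = sum(1 for u in order[i + 1:] if u < v)
        rank += smaller_right * math.factorial(k - 1 - i)
    return rank


def permutation_unrank(class_index: int, k: int) -> tuple[int, ...]:
    """Inverse of :func:`permutation_rank`."""
    if not 0 <= class_index < math.factorial(k):
        raise ValueError(f"class_index {class_index} outside [0, {k}!)")
    remaining = list(range(k))
    order = []
    r = class_index
    for i in range(k):
        f = math.factorial(k - 1 - i)
        j, r = divmod(r, f)
        order.append(remaining.pop(j))
    return tuple(order)


def shuffle_clip(clip: Clip, seed=0) -> tuple[Clip, PermutationLabel]:
    """Uniformly permute a clip's frames; the drawn order is the target.

    Output frame j is input frame ``order[j]``.
    """
    k = clip.k
    if k < 2:
        raise ValueError("need at least 2 frames to shuffle")
    rng = _rng(seed)
    order = tuple(int(i) for i in rng.permutation(k))
    shuffled = Clip(frames=clip.frames[list(order)].copy(),
                    video_id=clip.video_id, start=clip.start)
    return shuffled, PermutationLabel(order=order, class_index=permutation_rank(order))


def augment_clip(clip: Clip, config: AugmentationConfig | None = None, seed=0) -> Clip:
    """Clip-consistent augmentation: one transform drawn per clip.

    Zero-pads by a random amount up to ``max_pad`` pixels per spatial
    dimension then crops a random window back to the original size;
    horizontally flips with probability ``flip_prob``; rotates within
    ``rotation_range`` degrees with probability ``rotation_prob``.  All
    frames of the clip receive the identical geometric transform.
    """
    config = config or AugmentationConfig()
    config.validate()
    rng = _rng(seed)
    frames = clip.frames
    k, h, w = frames.shape

    pad_h = int(rng.integers(0, config.max_pad + 1))
    pad_w = int(rng.integers(0, config.max_pad + 1))
    if pad_h or pad_w:
        padded = np.pad(frames, ((0, 0), (pad_h, pad_h), (pad_w, pad_w)))
        off_h = int(rng.integers(0, 2 * pad_h + 1))
        off_w = int(rng.integers(0, 2 * pad_w + 1))
        frames = padded[:, off_h:off_h + h, off_w:off_w + w]

    if rng.random() < config.flip_prob:
        frames = frames[:, :, ::-1]

    if rng.random() < config.rotation_prob:
        angle = float(rng.uniform(*config.rotation_range))
        frames = ndimage.rotate(frames, angle, axes=(1, 2), reshape=False,
                                order=1, mode="constant", cval=0.0)
        frames = np.clip(frames, 0.0, 1.0)

    return Clip(frames=np.ascontiguousarray(frames, dtype=np.float32),
                video_id=clip.video_id, start=clip.start)
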