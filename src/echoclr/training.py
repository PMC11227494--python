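"""Pretraining and fine-tuning loops.

``Pretrainer`` runs self-supervised pretraining in one of three modes:

* ``simclr``    — each video yields two independently augmented copies of
  one sampled clip (no multi-instance sampling, no pretext task);
* ``misimclr``  — positive pairs are two distinct videos of the same
  study; one epoch visits every unique pair once;
* ``echoclr``   — multi-instance pairs plus the frame-reordering pretext
  task: each clip's frames are shuffled before encoding and a linear head
  must recover the ordering; the loss is the unweighted sum of NT-Xent
  and the K!-way reorder cross-entropy.

``FineTuner`` trains a binary disease head on 16-frame clips from a
titrated fraction of labeled training studies, with early stopping on
validation loss (patience 5, at most 30 epochs) and restoration of the
best-epoch weights.  Learning-rate grids follow the initialization mode:
SSL checkpoints use {0.1, 0.05, 0.001} at titration ratios <= 10%, random
and Kinetics initializations {1e-4, 5e-5, 1e-5}; above 10% a single rate
per mode.  ``finetune_grid`` fits one model per rate and keeps the rate
whose early-stopping checkpoint has the lowest validation loss (ties go
to the larger rate).

Both fit() entry points return Results objects carrying the loss
history, the selected checkpoint and a ``summary()`` table; every run is
bit-reproducible given its config seed.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .fixtures import CohortManifest, EchoVideo
from .models import (DiseaseHead, Projector, ReorderHead, VideoEncoder,
                     make_encoder)
from .objectives import nt_xent_loss_and_grad, reorder_cross_entropy_and_grad
from .sampling import (AugmentationConfig, Clip, augment_clip,
                       enumerate_positive_pairs, sample_clip, shuffle_clip,
                       titrate)

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError", "DegenerateLabelError", "PretrainConfig",
    "FinetuneConfig", "Checkpoint", "match_epoch_budget",
    "select_learning_rate", "default_lr_grid", "Pretrainer",
    "PretrainResult", "FineTuner", "FinetuneResult", "finetune_grid",
    "inference_clip", "predict_videos",
]

MODES = ("simclr", "misimclr", "echoclr")
INITS = ("random", "kinetics", "ssl")


class ConfigurationError(ValueError):
    pass


class DegenerateLabelError(ValueError):
    """The titrated training subset contains a single class."""


def _fingerprint(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PretrainConfig:
    mode: str = "echoclr"
    k: int = 4
    tau: float = 0.5
    lr: float = 0.1
    batch_size: int = 392       # clips per step; pairs contribute two each
    epochs: int = 300
    encoder: str = "r3d18"
    augment: AugmentationConfig = field(default_factory=AugmentationConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.batch_size % 2:
            raise ConfigurationError("batch_size must be even (pairs of clips)")
        if self.k < 2 and self.mode == "echoclr":
            raise ConfigurationError("frame reordering needs k >= 2")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["augment"] = dict(self.augment.__dict__)
        return d


@dataclass
class FinetuneConfig:
    init: str = "random"        # random | kinetics | ssl
    task: str = "lvh"           # which manifest label to fit
    ratio: float = 1.0
    clip_len: int = 16
    max_epochs: int = 30
    patience: int = 5
    lr: float | None = None     # set per-run by finetune_grid
    batch_size: int = 16
    encoder: str = "r3d18"
    kinetics_stats: tuple | None = None   # (mean[3], std[3]) channel stats
    augment: AugmentationConfig = field(default_factory=AugmentationConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.init not in INITS:
            raise ConfigurationError(f"init must be one of {INITS}, got {self.init!r}")
        if self.patience >= self.max_epochs:
            raise ConfigurationError("patience must be smaller than max_epochs")
        if self.init == "kinetics" and self.kinetics_stats is None:
            raise ConfigurationError(
                "kinetics init requires channel standardization stats")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["augment"] = dict(self.augment.__dict__)
        return d


@dataclass
class Checkpoint:
    encoder_name: str
    encoder_state: list[np.ndarray]
    head_states: dict[str, list[np.ndarray]]
    epoch: int
    val_loss: float | None
    fingerprint: str

    def save(self, path: str | Path) -> None:
        arrays = {}
        for i, a in enumerate(self.encoder_state):
            arrays[f"enc_{i:04d}"] = a
        for name, state in self.head_states.items():
            for i, a in enumerate(state):
                arrays[f"head_{name}_{i:04d}"] = a
        meta = json.dumps({
            "encoder_name": self.encoder_name,
            "head_names": sorted(self.head_states),
            "epoch": self.epoch,
            "val_loss": self.val_loss,
            "fingerprint": self.fingerprint,
        })
        np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            enc_keys = sorted(k for k in data.files if k.startswith("enc_"))
            encoder_state = [data[k] for k in enc_keys]
            head_states = {}
            for name in meta["head_names"]:
                keys = sorted(k for k in data.files if k.startswith(f"head_{name}_"))
                head_states[name] = [data[k] for k in keys]
        return cls(encoder_name=meta["encoder_name"], encoder_state=encoder_state,
                   head_states=head_states, epoch=meta["epoch"],
                   val_loss=meta["val_loss"], fingerprint=meta["fingerprint"])


def match_epoch_budget(pairs_per_epoch: int, items_per_epoch: int,
                       pair_epochs: int) -> int:
    """Epoch count equalizing examples seen between pair- and item-based runs.

    A pair-sampling epoch shows ``pairs_per_epoch`` examples while a
    single-video epoch shows ``items_per_epoch``; the single-video run
    therefore trains for round(pair_epochs * pairs / items) epochs (the
    rule that turns 300 pair epochs into 520 single-video epochs at the
    26:15 pair:item ratio).
    """
    if pairs_per_epoch <= 0 or items_per_epoch <= 0 or pair_epochs <= 0:
        raise ValueError("all arguments must be positive")
    return int(math.floor(pair_epochs * pairs_per_epoch / items_per_epoch + 0.5))


def select_learning_rate(grid, val_losses) -> float:
    """Grid entry with minimal validation loss; ties go to the larger rate."""
    grid = list(grid)
    losses = list(val_losses)
    if not grid or len(grid) != len(losses):
        raise ValueError("need one validation loss per grid entry")
    best = min(losses)
    candidates = [lr for lr, l in zip(grid, losses) if l == best]
    chosen = max(candidates)
    if len(candidates) > 1:
        logger.info("learning-rate tie at loss %.6f; choosing larger rate %g",
                    best, chosen)
    return chosen


def default_lr_grid(init: str, ratio: float) -> list[float]:
    """The published learning-rate grids by initialization and titration."""
    if init == "ssl":
        return [0.1, 0.05, 0.001] if ratio <= 0.10 else [0.1]
    return [1e-4, 5e-5, 1e-5] if ratio <= 0.10 else [1e-4]


def _to_batch(clips: list[Clip]) -> np.ndarray:
    """Stack clips and replicate grayscale to the 3 channels the stem expects."""
    x = np.stack([c.frames for c in clips])[:, None]
    return np.repeat(x, 3, axis=1).astype(np.float32)


def inference_clip(video: EchoVideo, k: int) -> Clip:
    """Deterministic evaluation clip: the first k frames (loop-padded)."""
    idx = np.arange(k) % video.n_frames
    return Clip(frames=video.frames[idx].astype(np.float32) / 255.0,
                video_id=video.video_id, start=0)


# ---------------------------------------------------------------------------
# Pretraining
# ---------------------------------------------------------------------------

class PretrainResult:
    """Outcome of self-supervised pretraining.

    Holds the live model objects (encoder, projector, reorder head), the
    per-epoch loss history, and the final checkpoint; also provides the
    two pretext-quality diagnostics: frame-reorder accuracy and
    positive-pair retrieval.
    """

    def __init__(self, config: PretrainConfig, encoder: VideoEncoder,
                 projector: Projector, reorder_head: ReorderHead | None,
                 history: pd.DataFrame, checkpoint: Checkpoint):
        self.config = config
        self.encoder = encoder
        self.projector = projector
        self.reorder_head = reorder_head
        self.history = history
        self.checkpoint = checkpoint

    def summary(self) -> str:
        first, last = self.history.iloc[0], self.history.iloc[-1]
        lines = [
            f"Self-supervised pretraining ({self.config.mode}, K={self.config.k}, "
            f"tau={self.config.tau}, encoder={self.config.encoder})",
            f"  epochs run        : {len(self.history)}",
            f"  total loss        : {first.total:.4f} (first) -> {last.total:.4f} (last)",
            f"  NT-Xent component : {first.nt_xent:.4f} -> {last.nt_xent:.4f}",
        ]
        if self.reorder_head is not None:
            lines.append(
                f"  reorder component : {first.reorder:.4f} -> {last.reorder:.4f}"
                f" (chance {math.log(self.reorder_head.n_classes):.4f})")
        else:
            lines.append("  reorder component : absent (no pretext task)")
        return "\n".join(lines)

    def _encode(self, clips: list[Clip], batch: int = 32) -> np.ndarray:
        hs = []
        for i in range(0, len(clips), batch):
            hs.append(self.encoder.forward(_to_batch(clips[i:i + batch]), train=False))
        return np.concatenate(hs, axis=0)

    def reorder_accuracy(self, videos: list[EchoVideo], n_clips_per_video: int = 2,
                         seed: int = 0) -> float:
        """Fraction of shuffled clips whose frame ordering is predicted exactly."""
        if self.reorder_head is None:
            raise ConfigurationError("this run has no reorder head")
        rng = np.random.default_rng(seed)
        clips, targets = [], []
        for v in videos:
            for _ in range(n_clips_per_video):
                c = sample_clip(v, self.config.k, rng)
                c, label = shuffle_clip(c, rng)
                clips.append(c)
                targets.append(label.class_index)
        h = self._encode(clips)
        logits = self.reorder_head.forward(h, train=False)
        return float((np.argmax(logits, axis=1) == np.asarray(targets)).mean())

    def retrieval_top1(self, manifest: CohortManifest,
                       videos: dict[str, EchoVideo], seed: int = 0
                       ) -> tuple[float, float]:
        """Positive-pair retrieval: (top-1 accuracy, chance level).

        Each video is embedded from one clip; an anchor retrieves
        correctly when its nearest other embedding (cosine) belongs to the
        same study.  Chance is the expected hit rate of a random ranking.
        """
        rng = np.random.default_rng(seed)
        vids, study_of = [], {}
        for r in manifest:
            if len(r.video_ids) < 2:
                continue
            for vid in r.video_ids:
                vids.append(vid)
                study_of[vid] = r.study_id
        if len(vids) < 3:
            raise ConfigurationError("need at least two multi-video studies")
        clips = [sample_clip(videos[v], self.config.k, rng) for v in vids]
        if self.config.mode == "echoclr":
            clips = [shuffle_clip(c, rng)[0] for c in clips]
        z = self.projector.forward(self._encode(clips), train=False)
        z = z / np.linalg.norm(z, axis=1, keepdims=True)
        sims = z @ z.T
        np.fill_diagonal(sims, -np.inf)
        nearest = np.argmax(sims, axis=1)
        hits = [study_of[vids[i]] == study_of[vids[j]] for i, j in enumerate(nearest)]
        same = [sum(study_of[u] == study_of[v] for u in vids if u != v)
                for v in vids]
        chance = float(np.mean([s / (len(vids) - 1) for s in same]))
        return float(np.mean(hits)), chance


class Pretrainer:
    """Fits the self-supervised objective on a cohort of videos."""

    def __init__(self, manifest: CohortManifest, videos: dict[str, EchoVideo],
                 config: PretrainConfig):
        config.validate()
        self.manifest = manifest
        self.videos = videos
        self.config = config
        if config.mode in ("misimclr", "echoclr"):
            self.pairs = enumerate_positive_pairs(manifest)
            if not self.pairs:
                raise ConfigurationError(
                    "multi-instance mode needs at least one study with >= 2 videos")
        else:
            self.pairs = None
        self.items = [vid for r in manifest for vid in r.video_ids]

    def fit(self, epochs: int | None = None) -> PretrainResult:
        cfg = self.config
        epochs = epochs if epochs is not None else cfg.epochs
        rng = np.random.default_rng(cfg.seed)
        encoder = make_encoder(cfg.encoder, rng=np.random.default_rng([cfg.seed, 1]))
        projector = Projector(rng=np.random.default_rng([cfg.seed, 2]))
        reorder_head = (ReorderHead(cfg.k, rng=np.random.default_rng([cfg.seed, 3]))
                        if cfg.mode == "echoclr" else None)
        params = encoder.params() + projector.params()
        if reorder_head is not None:
            params = params + reorder_head.params()
        opt = nn.Adam(params, lr=cfg.lr)

        rows = []
        pairs_per_step = max(2, cfg.batch_size // 2)
        for epoch in range(1, epochs + 1):
            sums = {"nt_xent": 0.0, "reorder": 0.0, "total": 0.0}
            steps = 0
            for clips, targets in self._epoch_batches(rng, pairs_per_step):
                x = _to_batch(clips)
                h = encoder.forward(x, train=True)
                z = projector.forward(h, train=True)
                loss_c, dz = nt_xent_loss_and_grad(z, cfg.tau)
                dh = projector.backward(dz.astype(np.float32))
                loss_r = 0.0
                if reorder_head is not None:
                    logits = reorder_head.forward(h, train=True)
                    loss_r, dlogits = reorder_cross_entropy_and_grad(logits, targets)
                    dh = dh + reorder_head.backward(dlogits.astype(np.float32))
                encoder.backward(dh.astype(np.float32))
                opt.step()
                opt.zero_grad()
                sums["nt_xent"] += loss_c
                sums["reorder"] += loss_r
                sums["total"] += loss_c + loss_r
                steps += 1
            row = {k: v / max(steps, 1) for k, v in sums.items()}
            row["epoch"] = epoch
            if reorder_head is None:
                row["reorder"] = float("nan")
                row["total"] = row["nt_xent"]
            rows.append(row)
            logger.info("pretrain epoch %d/%d: total %.4f (nt_xent %.4f, reorder %s)",
                        epoch, epochs, row["total"], row["nt_xent"],
                        "absent" if reorder_head is None else f"{row['reorder']:.4f}")

        history = pd.DataFrame(rows, columns=["epoch", "nt_xent", "reorder", "total"])
        heads = {"projector": [p.value for p in projector.params()]}
        if reorder_head is not None:
            heads["reorder"] = [p.value for p in reorder_head.params()]
        ckpt = Checkpoint(encoder_name=cfg.encoder,
                          encoder_state=encoder.state_arrays(),
                          head_states=heads, epoch=epochs, val_loss=None,
                          fingerprint=_fingerprint(cfg.to_dict()))
        return PretrainResult(cfg, encoder, projector, reorder_head, history, ckpt)

    def _epoch_batches(self, rng: np.random.Generator, pairs_per_step: int):
        cfg = self.config
        if self.pairs is not None:
            order = rng.permutation(len(self.pairs))
            for i in range(0, len(order), pairs_per_step):
                chunk = [self.pairs[j] for j in order[i:i + pairs_per_step]]
                if len(chunk) < 2:
                    continue  # NT-Xent needs at least two pairs
                clips, targets = [], []
                for p in chunk:
                    for vid in (p.video_id_a, p.video_id_b):
                        c = augment_clip(sample_clip(self.videos[vid], cfg.k, rng),
                                         cfg.augment, rng)
                        if cfg.mode == "echoclr":
                            c, label = shuffle_clip(c, rng)
                            targets.append(label.class_index)
                        clips.append(c)
                yield clips, targets
        else:
            order = rng.permutation(len(self.items))
            step = max(2, cfg.batch_size // 2)
            for i in range(0, len(order), step):
                chunk = [self.items[j] for j in order[i:i + step]]
                if len(chunk) < 2:
                    continue
                clips = []
                for vid in chunk:
                    base = sample_clip(self.videos[vid], cfg.k, rng)
                    for _ in range(2):  # two independently augmented copies
                        clips.append(augment_clip(base, cfg.augment, rng))
                yield clips, []


# ---------------------------------------------------------------------------
# Fine-tuning
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _standardize(x: np.ndarray, stats: tuple | None) -> np.ndarray:
    if stats is None:
        return x
    mean, std = (np.asarray(a, dtype=np.float32).reshape(1, 3, 1, 1, 1) for a in stats)
    return (x - mean) / std


class FinetuneResult:
    """Outcome of supervised fine-tuning: best checkpoint plus diagnostics."""

    def __init__(self, config: FinetuneConfig, encoder: VideoEncoder,
                 head: DiseaseHead, history: pd.DataFrame, best_epoch: int,
                 checkpoint: Checkpoint, train_studies: list[str]):
        self.config = config
        self.encoder = encoder
        self.head = head
        self.history = history
        self.best_epoch = best_epoch
        self.checkpoint = checkpoint
        self.train_studies = train_studies

    @property
    def val_loss(self) -> float:
        return float(self.checkpoint.val_loss)

    def summary(self) -> str:
        return "\n".join([
            f"Fine-tuning ({self.config.task}, init={self.config.init}, "
            f"ratio={self.config.ratio:g}, lr={self.config.lr:g})",
            f"  labeled training studies : {len(self.train_studies)}",
            f"  epochs run               : {len(self.history)} "
            f"(best epoch {self.best_epoch}, patience {self.config.patience})",
            f"  best validation loss     : {self.val_loss:.4f}",
        ])

    def predict_videos(self, videos: dict[str, EchoVideo],
                       video_ids: list[str] | None = None,
                       batch: int = 32) -> dict[str, float]:
        """Per-video disease probabilities from the deterministic clip."""
        ids = list(video_ids) if video_ids is not None else list(videos)
        clips = [inference_clip(videos[v], self.config.clip_len) for v in ids]
        scores = []
        for i in range(0, len(clips), batch):
            x = _standardize(_to_batch(clips[i:i + batch]),
                             self.config.kinetics_stats)
            h = self.encoder.forward(x, train=False)
            scores.extend(_sigmoid(self.head.forward(h, train=False)).tolist())
        return dict(zip(ids, scores))


class FineTuner:
    """Supervised fine-tuning of a (possibly pretrained) encoder."""

    def __init__(self, manifest: CohortManifest, videos: dict[str, EchoVideo],
                 config: FinetuneConfig, train_studies: list[str],
                 val_studies: list[str], init_checkpoint: Checkpoint | None = None):
        config.validate()
        if config.init == "ssl" and init_checkpoint is None:
            raise ConfigurationError("ssl init requires a pretraining checkpoint")
        self.manifest = manifest
        self.videos = videos
        self.config = config
        self.init_checkpoint = init_checkpoint
        self.train_studies = titrate(train_studies, config.ratio, seed=config.seed)
        self.val_studies = list(val_studies)
        self.train_items = self._labeled_items(self.train_studies)
        self.val_items = self._labeled_items(self.val_studies)
        labels = {y for _, y in self.train_items}
        if len(labels) < 2:
            raise DegenerateLabelError(
                f"titrated subset has a single class ({labels}); "
                "cannot fit a binary classifier")
        if not self.val_items:
            raise ConfigurationError("no labeled validation studies")

    def _labeled_items(self, study_ids: list[str]) -> list[tuple[str, int]]:
        key = "lvh_label" if self.config.task == "lvh" else "severe_as_label"
        items = []
        for sid in study_ids:
            r = self.manifest[sid]
            y = getattr(r, key)
            if y is None:
                continue  # usable for SSL, skipped for supervised fitting
            for vid in r.video_ids:
                items.append((vid, int(y)))
        return items

    def _build_model(self) -> tuple[VideoEncoder, DiseaseHead]:
        cfg = self.config
        encoder = make_encoder(cfg.encoder, rng=np.random.default_rng([cfg.seed, 11]))
        if cfg.init == "ssl":
            if self.init_checkpoint.encoder_name != cfg.encoder:
                raise ConfigurationError(
                    f"checkpoint encoder {self.init_checkpoint.encoder_name!r} "
                    f"!= configured encoder {cfg.encoder!r}")
            encoder.load_state(self.init_checkpoint.encoder_state)
        elif cfg.init == "kinetics":
            if self.init_checkpoint is not None:
                encoder.load_state(self.init_checkpoint.encoder_state)
            # else: externally supplied weights absent; the standardization
            # stats still apply, matching the transfer-learning recipe
        head = DiseaseHead(rng=np.random.default_rng([cfg.seed, 12]))
        return encoder, head

    def _val_loss(self, encoder: VideoEncoder, head: DiseaseHead,
                  batch: int = 32) -> float:
        losses = []
        for i in range(0, len(self.val_items), batch):
            chunk = self.val_items[i:i + batch]
            clips = [inference_clip(self.videos[v], self.config.clip_len)
                     for v, _ in chunk]
            y = np.array([lab for _, lab in chunk], dtype=np.float64)
            x = _standardize(_to_batch(clips), self.config.kinetics_stats)
            p = _sigmoid(head.forward(encoder.forward(x, train=False), train=False))
            p = np.clip(p, 1e-7, 1 - 1e-7)
            losses.extend((-(y * np.log(p) + (1 - y) * np.log(1 - p))).tolist())
        return float(np.mean(losses))

    def fit(self) -> FinetuneResult:
        cfg = self.config
        if cfg.lr is None:
            raise ConfigurationError("set config.lr (or use finetune_grid)")
        rng = np.random.default_rng([cfg.seed, 13])
        encoder, head = self._build_model()
        opt = nn.Adam(encoder.params() + head.params(), lr=cfg.lr)

        rows = []
        best_loss = math.inf
        best_epoch = 0
        best_state: tuple | None = None
        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(len(self.train_items))
            train_losses = []
            for i in range(0, len(order), cfg.batch_size):
                chunk = [self.train_items[j] for j in order[i:i + cfg.batch_size]]
                clips = [augment_clip(sample_clip(self.videos[v], cfg.clip_len, rng),
                                      cfg.augment, rng) for v, _ in chunk]
                y = np.array([lab for _, lab in chunk], dtype=np.float64)
                x = _standardize(_to_batch(clips), cfg.kinetics_stats)
                h = encoder.forward(x, train=True)
                logit = head.forward(h, train=True)
                p = np.clip(_sigmoid(logit), 1e-7, 1 - 1e-7)
                loss = float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())
                dlogit = ((p - y) / len(chunk)).astype(np.float32)
                encoder.backward(head.backward(dlogit))
                opt.step()
                opt.zero_grad()
                train_losses.append(loss)
            vloss = self._val_loss(encoder, head)
            rows.append({"epoch": epoch, "train_loss": float(np.mean(train_losses)),
                         "val_loss": vloss})
            logger.info("finetune epoch %d: train %.4f val %.4f",
                        epoch, rows[-1]["train_loss"], vloss)
            if vloss < best_loss:
                best_loss = vloss
                best_epoch = epoch
                best_state = (copy.deepcopy(encoder.state_arrays()),
                              copy.deepcopy([p.value for p in head.params()]))
            elif epoch - best_epoch >= cfg.patience:
                logger.info("early stop after epoch %d (best epoch %d)",
                            epoch, best_epoch)
                break

        encoder.load_state(best_state[0])
        head.load_state(best_state[1])
        ckpt = Checkpoint(encoder_name=cfg.encoder,
                          encoder_state=encoder.state_arrays(),
                          head_states={"disease": [p.value for p in head.params()]},
                          epoch=best_epoch, val_loss=best_loss,
                          fingerprint=_fingerprint(cfg.to_dict()))
        return FinetuneResult(cfg, encoder, head, pd.DataFrame(rows),
                              best_epoch, ckpt, self.train_studies)


def finetune_grid(manifest: CohortManifest, videos: dict[str, EchoVideo],
                  config: FinetuneConfig, train_studies: list[str],
                  val_studies: list[str], init_checkpoint: Checkpoint | None = None,
                  grid: list[float] | None = None
                  ) -> tuple[FinetuneResult, pd.DataFrame]:
    """Fit once per learning rate and keep the validation-loss winner."""
    grid = grid if grid is not None else default_lr_grid(config.init, config.ratio)
    results = []
    for lr in grid:
        cfg = copy.deepcopy(config)
        cfg.lr = float(lr)
        ft = FineTuner(manifest, videos, cfg, train_studies, val_studies,
                       init_checkpoint=init_checkpoint)
        results.append(ft.fit())
    losses = [r.val_loss for r in results]
    chosen = select_learning_rate(grid, losses)
    winner = results[grid.index(chosen)]
    table = pd.DataFrame({"lr": grid, "val_loss": losses,
                          "selected": [lr == chosen for lr in grid]})
    return winner, table


def predict_videos(result: FinetuneResult, videos: dict[str, EchoVideo],
                   manifest: CohortManifest, study_ids: list[str]
                   ) -> tuple[dict[str, list[float]], dict[str, int]]:
    """Scores grouped by study plus the matching labels, ready to aggregate."""
    key = "lvh_label" if result.config.task == "lvh" else "severe_as_label"
    grouped: dict[str, list[float]] = {}
    labels: dict[str, int] = {}
    wanted = []
    for sid in study_ids:
        r = manifest[sid]
        y = getattr(r, key)
        if y is None:
            continue
        labels[sid] = int(y)
        wanted.extend(r.video_ids)
    scores = result.predict_videos(videos, wanted)
    for sid in labels:
        grouped[sid] = [scores[v] for v in manifest[sid].video_ids]
    return grouped, labels
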