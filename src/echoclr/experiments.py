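"""Desk-scale reference experiments.

These functions bundle the standard end-to-end runs of the package on the
synthetic cohort at a scale a single CPU handles: self-supervised
pretraining with the reduced encoder followed by the pretext-quality
diagnostics, and the label-titration comparison of an EchoCLR-initialized
versus a randomly initialized classifier.  The study conditions (cohort
size, frame geometry, planted effect, schedules) are fixed here so that
scripts and tests exercise one canonical configuration.

Scale notes: pretraining uses 20 epochs of the reduced encoder on a
300-study cohort at 64 x 64 resolution; fine-tuning compares initializations
at the 5% titration over five seeds, with one learning rate per
initialization taken from the published grids (0.001 for SSL checkpoints,
1e-4 for random initialization).
"""

from __future__ import annotations

import numpy as np

from .evaluation import aggregate_study_predictions, auroc
from .fixtures import CohortManifest, EchoVideo, FixtureConfig, generate_cohort
from .sampling import SplitAssignment, split_studies
from .training import (FinetuneConfig, FineTuner, Pretrainer, PretrainConfig,
                       PretrainResult, predict_videos)

__all__ = ["desk_scale_cohort", "pretext_learnability", "label_efficiency",
           "run_desk_scale_benchmark"]

N_STUDIES = 300
FRAME_SIZE = 64
PRETRAIN_EPOCHS = 20
PRETRAIN_LR = 3e-3
PRETRAIN_BATCH = 16
TITRATION_RATIO = 0.05
SSL_LR = 0.001     # from the published SSL grid {0.1, 0.05, 0.001}
RANDOM_LR = 1e-4   # from the published random/kinetics grid {1e-4, 5e-5, 1e-5}
N_FINETUNE_SEEDS = 5


def desk_scale_cohort(seed: int) -> tuple[CohortManifest, dict[str, EchoVideo],
                                          SplitAssignment]:
    config = FixtureConfig(n_studies=N_STUDIES, frame_size=FRAME_SIZE,
                           frames_per_video=32, prevalence=0.3,
                           effect_size=2.0, seed=seed)
    manifest, videos = generate_cohort(config)
    split = split_studies(manifest.study_ids, seed=seed)
    return manifest, videos, split


def _subset(manifest: CohortManifest, split: SplitAssignment, name: str) -> CohortManifest:
    return CohortManifest([r for r in manifest if split[r.study_id] == name])


def pretext_learnability(manifest: CohortManifest, videos: dict[str, EchoVideo],
                         split: SplitAssignment, seed: int
                         ) -> tuple[PretrainResult, dict[str, float]]:
    """Pretrain EchoCLR and measure both pretext diagnostics on validation."""
    config = PretrainConfig(mode="echoclr", encoder="tiny",
                            batch_size=PRETRAIN_BATCH, lr=PRETRAIN_LR,
                            epochs=PRETRAIN_EPOCHS, seed=seed)
    result = Pretrainer(_subset(manifest, split, "train"), videos, config).fit()
    val_manifest = _subset(manifest, split, "val")
    val_videos = [videos[v] for r in val_manifest for v in r.video_ids]
    reorder_acc = result.reorder_accuracy(val_videos, n_clips_per_video=4, seed=1)
    top1, chance = result.retrieval_top1(val_manifest, videos, seed=1)
    return result, {"reorder_val_accuracy": reorder_acc,
                    "retrieval_top1": top1, "retrieval_chance": chance}


def label_efficiency(manifest: CohortManifest, videos: dict[str, EchoVideo],
                     split: SplitAssignment, pretrain: PretrainResult
                     ) -> dict[str, float]:
    """Median test AUROC over seeds: EchoCLR init vs random init at 5% labels."""
    medians = {}
    for init, ckpt, lr in [("ssl", pretrain.checkpoint, SSL_LR),
                           ("random", None, RANDOM_LR)]:
        aucs = []
        for seed in range(N_FINETUNE_SEEDS):
            config = FinetuneConfig(init=init, task="severe_as",
                                    ratio=TITRATION_RATIO, lr=lr,
                                    encoder="tiny", batch_size=16, seed=seed)
            tuner = FineTuner(manifest, videos, config, split.studies("train"),
                              split.studies("val"), init_checkpoint=ckpt)
            result = tuner.fit()
            grouped, labels = predict_videos(result, videos, manifest,
                                             split.studies("test"))
            preds = aggregate_study_predictions(grouped, labels)
            aucs.append(auroc([p.label for p in preds],
                              [p.pooled_score for p in preds]))
        medians[init] = float(np.median(aucs))
    return {"auroc_echoclr_init_median": medians["ssl"],
            "auroc_random_init_median": medians["random"],
            "auroc_init_gap": medians["ssl"] - medians["random"]}


def run_desk_scale_benchmark(seed: int = 7) -> dict[str, float]:
    """Full pipeline: cohort -> pretraining diagnostics -> titration gap."""
    manifest, videos, split = desk_scale_cohort(seed)
    pretrain, pretext = pretext_learnability(manifest, videos, split, seed)
    out = dict(pretext)
    out.update(label_efficiency(manifest, videos, split, pretrain))
    return out
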