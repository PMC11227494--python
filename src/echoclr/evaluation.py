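"""Study-level evaluation: AUROC/AUPR with percentile-bootstrap inference.

Labels describe studies, but the model scores videos; video scores are
averaged into a single study-level score before any metric is computed.
Confidence intervals use the nonparametric percentile bootstrap at the
study level (default 10,000 resamples).  Differences between two models'
AUROCs on the same studies are tested one-sided with the bootstrap scheme
of pROC's roc.test: the observed difference divided by the bootstrap
standard deviation of paired resampled differences, referred to the
standard normal tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import average_precision_score, roc_auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "StudyPrediction", "MetricResult", "aggregate_study_predictions",
    "auroc", "aupr", "bootstrap_ci", "bootstrap_auroc_pvalue",
]


@dataclass
class StudyPrediction:
    study_id: str
    video_scores: list[float]
    pooled_score: float
    label: int


@dataclass
class MetricResult:
    metric: str
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    n: int
    n_skipped: int = 0

    def __str__(self) -> str:
        return (f"{self.metric} {self.point:.3f} "
                f"(95% CI [{self.ci_low:.3f}, {self.ci_high:.3f}], "
                f"n={self.n}, B={self.n_boot})")


def aggregate_study_predictions(video_scores: dict[str, list[float]],
                                labels: dict[str, int]) -> list[StudyPrediction]:
    """Average per-video scores into one study-level prediction each."""
    out = []
    for study_id, scores in video_scores.items():
        scores = [float(s) for s in scores]
        if not scores:
            raise ValueError(f"study {study_id} has no video scores")
        if any(s < 0 or s > 1 for s in scores):
            raise ValueError(f"study {study_id}: scores must lie in [0, 1]")
        out.append(StudyPrediction(study_id=study_id, video_scores=scores,
                                   pooled_score=float(np.mean(scores)),
                                   label=int(labels[study_id])))
    return out


def _check_binary(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("metric undefined: labels contain a single class")


def auroc(labels, scores) -> float:
    """Probability a random positive outscores a random negative (ties 1/2)."""
    labels = np.asarray(labels)
    _check_binary(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def aupr(labels, scores) -> float:
    """Average precision (step-wise area under the precision-recall curve)."""
    labels = np.asarray(labels)
    _check_binary(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=np.float64)))


_METRICS = {"auroc": auroc, "aupr": aupr}


def _auroc_rows(labels: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Row-wise Mann-Whitney AUROC (average ranks, so ties count 1/2).

    ``labels`` and ``scores`` are (B, n); rows must contain both classes.
    Agrees with :func:`auroc` exactly; used to vectorize the bootstrap.
    """
    ranks = rankdata(scores, method="average", axis=1)
    n_pos = labels.sum(axis=1)
    n_neg = labels.shape[1] - n_pos
    pos_rank_sum = (ranks * labels).sum(axis=1)
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _resample_indices(rng: np.random.Generator, labels: np.ndarray,
                      n_boot: int) -> tuple[np.ndarray, int]:
    """(n_boot, n) bootstrap index matrix; single-class rows are redrawn."""
    n = labels.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    skipped = 0
    while True:
        lab = labels[idx]
        bad = np.flatnonzero(lab.min(axis=1) == lab.max(axis=1))
        if bad.size == 0:
            return idx, skipped
        skipped += bad.size
        idx[bad] = rng.integers(0, n, size=(bad.size, n))


def bootstrap_ci(labels, scores, metric: str = "auroc", n_boot: int = 10_000,
                 seed: int = 0) -> MetricResult:
    """Percentile-bootstrap 95% CI of a metric, resampling studies."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    n = labels.shape[0]
    if n < 10:
        raise ValueError(f"need >= 10 studies to bootstrap, got {n}")
    if n_boot < 100:
        logger.warning("bootstrap with only %d replicates is unreliable", n_boot)
    fn = _METRICS[metric]
    point = fn(labels, scores)
    rng = np.random.default_rng(seed)
    idx, skipped = _resample_indices(rng, labels, n_boot)
    if metric == "auroc":
        stats = _auroc_rows(labels[idx], scores[idx])
    else:
        stats = np.array([fn(labels[i], scores[i]) for i in idx])
    if skipped:
        logger.info("bootstrap_ci: redrew %d single-class resamples", skipped)
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return MetricResult(metric=metric, point=point, ci_low=float(lo),
                        ci_high=float(hi), n_boot=n_boot, seed=seed, n=n,
                        n_skipped=skipped)


def bootstrap_auroc_pvalue(labels, scores_a, scores_b, n_boot: int = 2000,
                           seed: int = 0) -> float:
    """One-sided bootstrap test that model A's AUROC exceeds model B's.

    Paired study resamples give the bootstrap SD of the AUROC difference;
    the statistic D = (AUROC_A - AUROC_B) / sd is referred to the upper
    normal tail, p = 1 - Phi(D).
    """
    labels = np.asarray(labels)
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    if not (labels.shape == scores_a.shape == scores_b.shape):
        raise ValueError("labels and both score vectors must be paired (same length)")
    diff = auroc(labels, scores_a) - auroc(labels, scores_b)
    rng = np.random.default_rng(seed)
    idx, _ = _resample_indices(rng, labels, n_boot)
    lab = labels[idx]
    diffs = _auroc_rows(lab, scores_a[idx]) - _auroc_rows(lab, scores_b[idx])
    sd = float(diffs.std(ddof=1))
    if sd == 0.0:
        return 0.5 if diff == 0.0 else (0.0 if diff > 0 else 1.0)
    d = diff / sd
    return float(1.0 - norm.cdf(d))
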