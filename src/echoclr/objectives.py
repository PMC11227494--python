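"""Pretraining objectives.

The contrastive term is the temperature-normalized cross-entropy (NT-Xent)
loss over a batch of 2N projected embeddings arranged so that rows
(2k, 2k+1) are a positive pair:

    l(i, j) = -log[ exp(sim(z_i, z_j)/tau) / sum_{k != i} exp(sim(z_i, z_k)/tau) ]

with sim the cosine similarity and tau the temperature; the batch loss is
the mean of l over both orderings of every positive pair (2N terms).
Because only cosine similarities enter, the loss is invariant to rescaling
all embeddings by a positive constant.

The pretext term is a K!-way cross-entropy: a single linear head predicts
the lexicographic rank of the frame ordering applied to each clip; chance
level is exactly ln K!.  The combined objective is the unweighted sum of
the two terms.

Each loss comes in a value-only form and a value-plus-gradient form used
by the training loop (gradients are derived analytically through the
cosine normalization).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .sampling import PermutationLabel

__all__ = [
    "EmbeddingBatch", "DegenerateEmbeddingError", "cosine_similarity_matrix",
    "nt_xent_loss", "nt_xent_loss_and_grad", "reorder_cross_entropy",
    "reorder_cross_entropy_and_grad", "echoclr_loss", "EchoCLRLoss",
]


class DegenerateEmbeddingError(ValueError):
    """An embedding row has (near-)zero norm; cosine similarity is undefined."""


@dataclass
class EmbeddingBatch:
    """2N projected embeddings; rows (2k, 2k+1) form positive pair k."""

    z: np.ndarray
    tau: float = 0.5

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.float64)
        if self.z.ndim != 2 or self.z.shape[0] % 2:
            raise ValueError(f"embeddings must be (2N, d), got {self.z.shape}")
        if self.tau <= 0:
            raise ValueError(f"temperature must be positive, got {self.tau}")

    @property
    def n_pairs(self) -> int:
        return self.z.shape[0] // 2


def _normalize_rows(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(z, axis=1)
    if np.any(norms < 1e-12):
        raise DegenerateEmbeddingError("zero-norm embedding row")
    return z / norms[:, None], norms


def cosine_similarity_matrix(z: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities of the rows of ``z``."""
    u, _ = _normalize_rows(np.asarray(z, dtype=np.float64))
    return u @ u.T


def _positive_index(m: int) -> np.ndarray:
    """partner[i] for the (2k, 2k+1) pairing."""
    idx = np.arange(m)
    return idx ^ 1


def nt_xent_loss(batch: EmbeddingBatch | np.ndarray, tau: float | None = None) -> float:
    """NT-Xent loss averaged over both orderings of every positive pair."""
    if not isinstance(batch, EmbeddingBatch):
        batch = EmbeddingBatch(batch, tau=0.5 if tau is None else tau)
    elif tau is not None:
        batch = EmbeddingBatch(batch.z, tau=tau)
    loss, _ = nt_xent_loss_and_grad(batch.z, batch.tau)
    return loss


def nt_xent_loss_and_grad(z: np.ndarray, tau: float = 0.5) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the raw embeddings."""
    z = np.asarray(z, dtype=np.float64)
    m = z.shape[0]
    if m < 4 or m % 2:
        raise ValueError(f"need 2N embeddings with N >= 2, got {m} rows")
    u, norms = _normalize_rows(z)
    s = u @ u.T
    pos = _positive_index(m)

    logits = s / tau
    np.fill_diagonal(logits, -np.inf)  # the indicator 1[i != k]
    row_max = logits.max(axis=1, keepdims=True)
    expv = np.exp(logits - row_max)
    denom = expv.sum(axis=1)
    log_denom = np.log(denom) + row_max[:, 0]
    pos_logit = logits[np.arange(m), pos]
    losses = log_denom - pos_logit
    loss = float(losses.mean())

    # d loss / d s[i,k] for each anchor row i: softmax/tau minus the
    # positive indicator/tau, averaged over the m anchors.
    softmax = expv / denom[:, None]
    g = softmax / (tau * m)
    g[np.arange(m), pos] -= 1.0 / (tau * m)
    np.fill_diagonal(g, 0.0)

    # s = u u^T  =>  dL/du = (g + g^T) u ; then back through row normalization
    du = (g + g.T) @ u
    dz = (du - (du * u).sum(axis=1, keepdims=True) * u) / norms[:, None]
    return loss, dz


def _as_class_indices(targets: Sequence[PermutationLabel | int]) -> np.ndarray:
    out = np.array([t.class_index if isinstance(t, PermutationLabel) else int(t)
                    for t in targets], dtype=np.int64)
    return out


def reorder_cross_entropy(logits: np.ndarray,
                          targets: Sequence[PermutationLabel | int]) -> float:
    loss, _ = reorder_cross_entropy_and_grad(logits, targets)
    return loss


def reorder_cross_entropy_and_grad(logits: np.ndarray,
                                   targets: Sequence[PermutationLabel | int]
                                   ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy between predicted and true frame orderings."""
    logits = np.asarray(logits, dtype=np.float64)
    y = _as_class_indices(targets)
    n, c = logits.shape
    if y.shape[0] != n:
        raise ValueError(f"{n} logit rows but {y.shape[0]} targets")
    if np.any((y < 0) | (y >= c)):
        raise ValueError(f"class index outside [0, {c})")
    shifted = logits - logits.max(axis=1, keepdims=True)
    logp = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    loss = float(-logp[np.arange(n), y].mean())
    grad = np.exp(logp)
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class EchoCLRLoss(NamedTuple):
    total: float
    nt_xent: float
    reorder: float | None


def echoclr_loss(batch: EmbeddingBatch, logits: np.ndarray | None = None,
                 targets: Sequence[PermutationLabel | int] | None = None) -> EchoCLRLoss:
    """Unweighted sum of the contrastive and frame-reorder objectives.

    With ``logits``/``targets`` omitted the reorder term is disabled and
    the total equals the NT-Xent loss alone (the MI-SimCLR ablation).
    """
    contrastive = nt_xent_loss(batch)
    if logits is None or targets is None:
        return EchoCLRLoss(total=contrastive, nt_xent=contrastive, reorder=None)
    pretext = reorder_cross_entropy(logits, targets)
    return EchoCLRLoss(total=contrastive + pretext, nt_xent=contrastive, reorder=pretext)
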