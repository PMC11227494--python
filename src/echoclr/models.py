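"""Video encoders and heads.

The default encoder is an 18-layer 3D residual network (the r3d_18 layout:
a 3x7x7 stem followed by four stages of two basic blocks at 64/128/256/512
channels) mapping a 3-channel clip to a 512-dimensional representation h.
On a 3x32x112x112 clip its last convolution block emits a 512x4x7x7
activation grid (channels x time x height x width), the grid Grad-CAM
consumes.

A reduced encoder (``tiny``) with three conv/BN stages and a linear lift to
the same 512-dimensional representation space is provided for CPU-scale
experiments; it honours the identical contract, so the projector, the
frame-reorder head and the disease head are encoder-agnostic.
"""

from __future__ import annotations

import math

import numpy as np

from . import nn

FEATURE_DIM = 512


class VideoEncoder:
    """Common contract: clip batch (B, 3, T, H, W) -> representation (B, 512).

    After ``forward`` the attribute ``last_block_activation`` holds the
    activation grid of the last convolution block, (B, C, T', H', W').
    """

    feature_dim = FEATURE_DIM
    features: nn.Sequential
    fc: nn.Linear | None

    def __init__(self):
        self.pool = nn.GlobalAvgPool3d()
        self.last_block_activation: np.ndarray | None = None

    def params(self) -> list[nn.Param]:
        ps = self.features.params()
        if self.fc is not None:
            ps = ps + self.fc.params()
        return ps

    def buffers(self) -> list[np.ndarray]:
        return self.features.buffers()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        a = self.features.forward(np.asarray(x, dtype=np.float32), train=train)
        self.last_block_activation = a
        h = a.mean(axis=(2, 3, 4))
        self._pool_shape = a.shape
        if self.fc is not None:
            h = self.fc.forward(h, train=train)
        return h

    def backward(self, dh: np.ndarray) -> None:
        """Full backward through the encoder (training mode forward required)."""
        da = self.grad_wrt_last_block(dh)
        self.features.backward(da)

    def grad_wrt_last_block(self, dh: np.ndarray) -> np.ndarray:
        """d(loss)/d(last-block activation); works in train or eval mode.

        The layers above the last block (global average pool and the optional
        linear lift) are linear, so their backward needs only the weights.
        """
        if self.fc is not None:
            self.fc.weight.grad += dh.T @ (
                self.last_block_activation.mean(axis=(2, 3, 4)))
            self.fc.bias.grad += dh.sum(axis=0)
            dh = dh @ self.fc.weight.value
        b, c, t, h, w = self._pool_shape
        da = np.broadcast_to(
            (dh / float(t * h * w))[:, :, None, None, None], self._pool_shape)
        return da.astype(np.float32).copy()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.params()] + self.buffers()

    def load_state(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError(
                f"state mismatch: encoder has {len(own)} arrays, got {len(arrays)}")
        for dst, src in zip(own, arrays):
            if dst.shape != np.shape(src):
                raise ValueError(f"shape mismatch {dst.shape} vs {np.shape(src)}")
            dst[...] = src


class VideoResNet18(VideoEncoder):
    """18-layer 3D residual network (stem + 4 stages x 2 basic blocks)."""

    name = "r3d18"

    def __init__(self, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        stem = [
            nn.Conv3d(3, 64, (3, 7, 7), stride=(1, 2, 2), padding=(1, 3, 3), rng=rng),
            nn.BatchNorm3d(64),
            nn.ReLU(),
        ]
        blocks = [
            nn.BasicBlock3d(64, 64, 1, rng=rng), nn.BasicBlock3d(64, 64, 1, rng=rng),
            nn.BasicBlock3d(64, 128, 2, rng=rng), nn.BasicBlock3d(128, 128, 1, rng=rng),
            nn.BasicBlock3d(128, 256, 2, rng=rng), nn.BasicBlock3d(256, 256, 1, rng=rng),
            nn.BasicBlock3d(256, 512, 2, rng=rng), nn.BasicBlock3d(512, 512, 1, rng=rng),
        ]
        self.features = nn.Sequential(*stem, *blocks)
        self.fc = None


class TinyVideoEncoder(VideoEncoder):
    """Reduced three-stage encoder for CPU-scale training.

    Downsamples space in every stage and time in the last two, pools
    globally, and lifts the channel features to the standard 512-d
    representation with one linear map.
    """

    name = "tiny"

    def __init__(self, rng: np.random.Generator | None = None,
                 widths: tuple[int, int, int] = (8, 16, 32)):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        w1, w2, w3 = widths
        self.features = nn.Sequential(
            nn.Conv3d(3, w1, 3, stride=(1, 2, 2), padding=1, rng=rng),
            nn.BatchNorm3d(w1), nn.ReLU(),
            nn.Conv3d(w1, w2, 3, stride=2, padding=1, rng=rng),
            nn.BatchNorm3d(w2), nn.ReLU(),
            nn.Conv3d(w2, w3, 3, stride=2, padding=1, rng=rng),
            nn.BatchNorm3d(w3), nn.ReLU(),
        )
        self.fc = nn.Linear(w3, FEATURE_DIM, rng=rng)


def make_encoder(name: str, rng: np.random.Generator | None = None) -> VideoEncoder:
    if name == "r3d18":
        return VideoResNet18(rng=rng)
    if name == "tiny":
        return TinyVideoEncoder(rng=rng)
    raise ValueError(f"unknown encoder {name!r} (choose 'r3d18' or 'tiny')")


class Projector:
    """SimCLR-style projection head g: 512 -> 256 -> ReLU -> 128."""

    out_dim = 128

    def __init__(self, rng: np.random.Generator | None = None, in_dim: int = FEATURE_DIM,
                 hidden: int = 256, out_dim: int = 128):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.net = nn.Sequential(nn.Linear(in_dim, hidden, rng=rng), nn.ReLU(),
                                 nn.Linear(hidden, out_dim, rng=rng))
        self.out_dim = out_dim

    def params(self):
        return self.net.params()

    def forward(self, h: np.ndarray, train: bool = True) -> np.ndarray:
        return self.net.forward(h, train=train)

    def backward(self, dz: np.ndarray) -> np.ndarray:
        return self.net.backward(dz)


class ReorderHead:
    """Single fully-connected map from the representation h to K! logits.

    Weights start at zero so the head opens at the uniform distribution
    (loss exactly ln K!); a large random init produces spuriously peaked
    logits whose noisy early gradients delay the pretext task's take-off.
    """

    def __init__(self, k: int, rng: np.random.Generator | None = None,
                 in_dim: int = FEATURE_DIM):
        self.k = k
        self.n_classes = math.factorial(k)
        self.fc = nn.Linear(in_dim, self.n_classes, rng=rng)
        self.fc.weight.value[...] = 0.0

    def params(self):
        return self.fc.params()

    def forward(self, h: np.ndarray, train: bool = True) -> np.ndarray:
        return self.fc.forward(h, train=train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.fc.backward(dlogits)


class DiseaseHead:
    """Binary classification head: representation -> one pre-sigmoid logit."""

    def __init__(self, rng: np.random.Generator | None = None, in_dim: int = FEATURE_DIM):
        self.fc = nn.Linear(in_dim, 1, rng=rng)

    def params(self):
        return self.fc.params()

    def forward(self, h: np.ndarray, train: bool = True) -> np.ndarray:
        return self.fc.forward(h, train=train)[:, 0]

    def backward(self, dlogit: np.ndarray) -> np.ndarray:
        return self.fc.backward(dlogit[:, None])

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.params()]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        for dst, src in zip(self.state_arrays(), arrays):
            dst[...] = src
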