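"""Pooling mechanisms: variable-size channel set -> one region representation.

Four mechanisms are provided:

* **average** — plain channel mean.
* **rocket_attention** — each channel gets an importance score from a single
  linear layer over its frozen random-convolution (ROCKET) features
  (proportion-of-positive-values and maximum of each kernel's feature map);
  softmax over the region's scores gives the weights of a channel average.
* **continuous_attention** — a small scoring network emits one score per
  channel per timestep; a per-timestep softmax over channels yields an
  attention matrix and a time-varying weighted average.
* **head_region** — one designated region per montage split produces a
  search embedding from its ROCKET features; other regions weight their
  channels by the softmaxed cosine similarity between each channel's
  embedding and the search embedding.

All mechanisms accept either plain NumPy arrays (inference) or autodiff
tensors (training); plain inputs give plain outputs.  ROCKET kernels are
frozen and shared across all regions and montage splits; features are
constant per (subject, channel) and can be precomputed before training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence, Tuple, Union

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "RocketKernelSet",
    "sample_rocket_kernels",
    "rocket_transform",
    "rocket_features",
    "average_pool",
    "score_channels_linear",
    "attention_pool",
    "continuous_attention_pool",
    "ContinuousScorer",
    "compute_search_embedding",
    "head_region_attention_pool",
]

logger = logging.getLogger(__name__)

ArrayLike = Union[np.ndarray, Tensor]

#: kernel lengths sampled uniformly, as in the ROCKET transform
ROCKET_LENGTHS = (7, 9, 11)


def _tensorize(*values: ArrayLike) -> Tuple[bool, List[Tensor]]:
    """Convert to tensors; report whether every input was a plain array."""
    plain = not any(isinstance(v, Tensor) for v in values)
    return plain, [v if isinstance(v, Tensor) else Tensor(v) for v in values]


def _detensorize(plain: bool, *outputs: Tensor):
    outs = tuple(o.numpy() if plain else o for o in outputs)
    return outs[0] if len(outs) == 1 else outs


# ---------------------------------------------------------------------------
# ROCKET kernels and features


@dataclass(frozen=True)
class RocketKernelSet:
    """Frozen random dilated convolution kernels (shared across regions)."""

    lengths: np.ndarray  # (n,) int
    weights: tuple  # n arrays, weights[i] has shape (lengths[i],)
    biases: np.ndarray  # (n,)
    dilations: np.ndarray  # (n,) int
    max_receptive_field: int

    @property
    def num_kernels(self) -> int:
        return len(self.lengths)

    @property
    def num_features(self) -> int:
        return 2 * self.num_kernels

    def receptive_fields(self) -> np.ndarray:
        return (self.lengths - 1) * self.dilations + 1

    def to_dict(self) -> dict:
        return {
            "lengths": self.lengths.tolist(),
            "weights": [w.tolist() for w in self.weights],
            "biases": self.biases.tolist(),
            "dilations": self.dilations.tolist(),
            "max_receptive_field": self.max_receptive_field,
        }

    @staticmethod
    def from_dict(d: dict) -> "RocketKernelSet":
        return RocketKernelSet(
            np.asarray(d["lengths"], dtype=int),
            tuple(np.asarray(w, dtype=float) for w in d["weights"]),
            np.asarray(d["biases"], dtype=float),
            np.asarray(d["dilations"], dtype=int),
            int(d["max_receptive_field"]),
        )


def sample_rocket_kernels(
    num_kernels: int, max_receptive_field: int, rng: np.random.Generator
) -> RocketKernelSet:
    """Sample frozen kernels: length uniform on {7, 9, 11}; mean-centered
    standard-normal weights; bias uniform on [-1, 1]; dilation a power of two
    keeping the receptive field within ``max_receptive_field``."""
    if num_kernels < 1:
        raise ValueError("num_kernels must be >= 1")
    if max_receptive_field < max(ROCKET_LENGTHS):
        raise ValueError(
            f"max_receptive_field must be >= {max(ROCKET_LENGTHS)}, "
            f"got {max_receptive_field}"
        )
    lengths = rng.choice(ROCKET_LENGTHS, size=num_kernels)
    weights = []
    biases = np.empty(num_kernels)
    dilations = np.empty(num_kernels, dtype=int)
    for i, length in enumerate(lengths):
        w = rng.normal(0.0, 1.0, size=int(length))
        weights.append(w - w.mean())
        biases[i] = rng.uniform(-1.0, 1.0)
        max_exp = int(np.floor(np.log2((max_receptive_field - 1) / (length - 1))))
        dilations[i] = 2 ** int(rng.integers(0, max_exp + 1))
    return RocketKernelSet(
        lengths.astype(int), tuple(weights), biases, dilations, max_receptive_field
    )


def rocket_transform(signal: np.ndarray, kernels: RocketKernelSet) -> np.ndarray:
    """ROCKET features of one channel: valid-mode dilated convolution per
    kernel, then (PPV, max) of each feature map.

    Feature order: all proportion-of-positive-values first, then all maxima,
    in kernel sampling order.
    """
    signal = np.asarray(signal, dtype=float).reshape(-1)
    return rocket_features(signal[None, :], kernels)[0]


def rocket_features(X: np.ndarray, kernels: RocketKernelSet) -> np.ndarray:
    """ROCKET features for every row of ``X`` (channels x T) -> (channels,
    2 * num_kernels).  Kernels are grouped by (length, dilation) so each
    group is one strided einsum."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (channels x time)")
    C, T = X.shape
    max_rf = int(kernels.receptive_fields().max())
    if T < max_rf:
        raise ValueError(
            f"signal length {T} shorter than max kernel receptive field {max_rf}"
        )
    n = kernels.num_kernels
    ppv = np.empty((C, n))
    mx = np.empty((C, n))
    groups: dict = {}
    for i in range(n):
        groups.setdefault(
            (int(kernels.lengths[i]), int(kernels.dilations[i])), []
        ).append(i)
    for (length, dilation), idx in groups.items():
        n_out = T - (length - 1) * dilation
        W = np.stack([kernels.weights[i] for i in idx])  # (g, length)
        b = kernels.biases[idx]
        # explicit tap-by-tap accumulation (bias last): bit-reproducible
        # left-to-right order, matching the defining sum exactly
        fmap = np.zeros((len(idx), C, n_out))
        for m in range(length):
            fmap += W[:, m][:, None, None] * X[None, :, m * dilation : m * dilation + n_out]
        fmap += b[:, None, None]
        ppv[:, idx] = (fmap > 0).mean(axis=2).T
        mx[:, idx] = fmap.max(axis=2).T
    return np.concatenate([ppv, mx], axis=1)


# ---------------------------------------------------------------------------
# pooling mechanisms


def average_pool(X_region: ArrayLike) -> ArrayLike:
    """Mean over channels at each timestep; (C, T) -> (T,)."""
    plain, (X,) = _tensorize(X_region)
    if X.shape[0] < 1:
        raise ValueError("region must contain at least one channel")
    return _detensorize(plain, X.mean(axis=0))


def score_channels_linear(features: ArrayLike, w: ArrayLike) -> ArrayLike:
    """Importance scores w^T z_k per channel; ``features`` is (C, F)."""
    plain, (Z, wt) = _tensorize(features, w)
    if Z.shape[1] != wt.shape[0]:
        raise ValueError(
            f"feature dim {Z.shape[1]} does not match weight dim {wt.shape[0]}"
        )
    return _detensorize(plain, Z @ wt)


def attention_pool(X_region: ArrayLike, scores: ArrayLike):
    """Softmax the scores into an attention vector and average the channels.

    Returns ``(representation (T,), attention (C,))``.
    """
    plain, (X, s) = _tensorize(X_region, scores)
    if s.shape[0] != X.shape[0]:
        raise ValueError("one score per channel required")
    if not np.all(np.isfinite(s.data)):
        raise ValueError("non-finite attention score")
    a = nn.softmax(s, axis=0)
    rep = (a.reshape(1, -1) @ X).reshape(-1)
    return _detensorize(plain, rep, a)


def continuous_attention_pool(X_region: ArrayLike, score_series: ArrayLike):
    """Per-timestep softmax over channels; returns ``(rep (T,), A (C, T))``."""
    plain, (X, S) = _tensorize(X_region, score_series)
    if X.shape != S.shape:
        raise ValueError(
            f"score series shape {S.shape} must match region shape {X.shape}"
        )
    A = nn.softmax(S, axis=0)
    rep = (A * X).sum(axis=0)
    return _detensorize(plain, rep, A)


class ContinuousScorer(nn.Module):
    """Channel-wise scoring network g: (1, T) -> (1, T) for continuous
    attention: a two-module Inception backbone with two filters per conv,
    followed by a pointwise linear map to one score per timestep."""

    def __init__(self, rng: np.random.Generator, depth: int = 2, filters: int = 2):
        from .inception import InceptionBackbone  # local: avoids import cycle

        self.backbone = InceptionBackbone(
            input_channels=1, depth=depth, filters=filters, rng=rng
        )
        self.head = nn.Conv1d(self.backbone.out_channels, 1, 1, rng)

    def __call__(self, X_region: ArrayLike) -> ArrayLike:
        """(C, T) -> (C, T): each channel scored independently."""
        plain, (X,) = _tensorize(X_region)
        C, T = X.shape
        feats = self.backbone(X.reshape(C, 1, T))  # (C, F, T)
        scores = self.head(feats).reshape(C, T)
        return _detensorize(plain, scores)


def compute_search_embedding(
    Z_head: ArrayLike, W1: ArrayLike, W2: ArrayLike
) -> ArrayLike:
    """Search embedding of a head region: s = [ (W1 Z) ⊙ softmax_ch(W2 Z) ] 1.

    ``Z_head`` is features x channels; the softmax runs over channels so each
    embedding coordinate weights the head channels independently.
    """
    plain, (Z, w1, w2) = _tensorize(Z_head, W1, W2)
    if w1.shape[1] != Z.shape[0] or w2.shape[1] != Z.shape[0]:
        raise ValueError(
            f"weight column count must equal feature count {Z.shape[0]}"
        )
    if w1.shape[0] != w2.shape[0]:
        raise ValueError("W1 and W2 must share their embedding dimension")
    gate = nn.softmax(w2 @ Z, axis=1)
    s = ((w1 @ Z) * gate).sum(axis=1)
    return _detensorize(plain, s)


def head_region_attention_pool(
    X_region: ArrayLike,
    Z_region: ArrayLike,
    s: ArrayLike,
    W1: ArrayLike,
    eps: float = 1e-12,
):
    """Weight channels by softmaxed cosine similarity to the search embedding.

    Each channel k is embedded as e_k = W1 z_k (the same W1 that produced the
    head embedding); attention a = softmax_k cos(e_k, s); the representation
    is a^T X.  Zero-norm embeddings get similarity ~0 (epsilon-guarded
    denominator) with a logged warning.  Returns ``(rep (T,), a (C,))``.
    """
    plain, (X, Z, sv, w1) = _tensorize(X_region, Z_region, s, W1)
    if Z.shape[1] != X.shape[0]:
        raise ValueError("Z_region must have one column per region channel")
    E = w1 @ Z  # (d, C)
    e_norms = np.linalg.norm(E.data, axis=0)
    s_norm = np.linalg.norm(sv.data)
    if s_norm < eps or np.any(e_norms < eps):
        logger.warning(
            "zero-norm embedding in head-region pooling; cosine treated as 0"
        )
    dots = (E * sv.reshape(-1, 1)).sum(axis=0)  # (C,)
    denom = (E * E).sum(axis=0) ** 0.5 * (sv * sv).sum() ** 0.5 + eps
    cos = dots / denom
    a = nn.softmax(cos, axis=0)
    rep = (a.reshape(1, -1) @ X).reshape(-1)
    return _detensorize(plain, rep, a)


def init_attention_weights(
    shape: Sequence[int], rng: np.random.Generator, scale: float = 0.01
) -> Tensor:
    """Small-variance normal init for trainable scoring weights."""
    return Tensor(rng.normal(0.0, scale, size=tuple(shape)), requires_grad=True)
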