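"""Compact Inception-style classifier for multivariate time series.

The network follows the InceptionTime design: stacked Inception modules
(bottleneck 1x1 conv; parallel convolutions of several kernel lengths; a
max-pool branch with its own bottleneck; concatenation, batch norm, ReLU)
with a linear shortcut connection every third module, temporal global average
pooling, and a single linear output unit.  The raw logit is exposed for the
with-logits binary cross-entropy loss; the sigmoid is applied only for
prediction.  Being fully convolutional up to the global pooling, the model
accepts any input length at or above its receptive field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "InceptionConfig",
    "InceptionModule",
    "InceptionBackbone",
    "InceptionClassifier",
    "build_classifier",
    "training_step",
]


@dataclass(frozen=True)
class InceptionConfig:
    """Hyperparameters of the classifier.

    Defaults are the full-size configuration (depth 6, 32 filters, kernel
    lengths 10/20/40, bottleneck 32, shortcut every third module); desk-scale
    experiments shrink depth and filter count through this config.
    """

    input_rows: int
    depth: int = 6
    num_filters: int = 32
    bottleneck: int = 32
    kernel_lengths: Tuple[int, ...] = (10, 20, 40)
    residual_period: int = 3

    def __post_init__(self) -> None:
        if self.input_rows <= 0:
            raise ValueError("input_rows must be positive")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.residual_period != 3:
            raise ValueError("shortcut connections are placed every third module")


class InceptionModule(nn.Module):
    def __init__(
        self,
        in_channels: int,
        filters: int,
        bottleneck: int,
        kernel_lengths: Tuple[int, ...],
        rng: np.random.Generator,
    ):
        b = min(bottleneck, in_channels)
        self.bottleneck = nn.Conv1d(in_channels, b, 1, rng)
        self.convs = [nn.Conv1d(b, filters, k, rng) for k in kernel_lengths]
        self.pool_conv = nn.Conv1d(in_channels, filters, 1, rng)
        self.out_channels = filters * (len(kernel_lengths) + 1)
        self.bn = nn.BatchNorm1d(self.out_channels)

    def __call__(self, x: Tensor) -> Tensor:
        z = self.bottleneck(x)
        branches = [conv(z) for conv in self.convs]
        branches.append(self.pool_conv(nn.maxpool1d_same(x, 3)))
        return self.bn(nn.concat(branches, axis=1)).relu()


class InceptionBackbone(nn.Module):
    """Stack of Inception modules with residual shortcuts every third one."""

    def __init__(
        self,
        input_channels: int,
        depth: int,
        filters: int,
        rng: np.random.Generator,
        bottleneck: int = 32,
        kernel_lengths: Tuple[int, ...] = (10, 20, 40),
        residual_period: int = 3,
    ):
        self.modules_list = []
        self.shortcuts = []
        self.shortcut_bns = []
        self.residual_period = residual_period
        c = input_channels
        res_c = input_channels
        for d in range(depth):
            module = InceptionModule(c, filters, bottleneck, kernel_lengths, rng)
            self.modules_list.append(module)
            c = module.out_channels
            if (d + 1) % residual_period == 0:
                self.shortcuts.append(nn.Conv1d(res_c, c, 1, rng))
                self.shortcut_bns.append(nn.BatchNorm1d(c))
                res_c = c
        self.out_channels = c

    def __call__(self, x: Tensor) -> Tensor:
        res = x
        shortcut_idx = 0
        for d, module in enumerate(self.modules_list):
            x = module(x)
            if (d + 1) % self.residual_period == 0:
                short = self.shortcut_bns[shortcut_idx](
                    self.shortcuts[shortcut_idx](res)
                )
                x = (x + short).relu()
                res = x
                shortcut_idx += 1
        return x


class InceptionClassifier(nn.Module):
    """Backbone + temporal global average pooling + one linear logit unit."""

    def __init__(self, config: InceptionConfig, rng: np.random.Generator):
        self.config = config
        self.backbone = InceptionBackbone(
            input_channels=config.input_rows,
            depth=config.depth,
            filters=config.num_filters,
            rng=rng,
            bottleneck=config.bottleneck,
            kernel_lengths=config.kernel_lengths,
            residual_period=config.residual_period,
        )
        self.head = nn.Linear(self.backbone.out_channels, 1, rng)

    def __call__(self, x) -> Tensor:
        """(B, C, T) -> (B,) raw logits."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        feats = self.backbone(x)
        pooled = feats.mean(axis=2)  # GAP over time
        return self.head(pooled).reshape(-1)

    def predict_proba(self, x) -> np.ndarray:
        """Sigmoid class-1 probabilities in evaluation mode."""
        self.set_training(False)
        logits = self(x if isinstance(x, Tensor) else Tensor(np.asarray(x)))
        return 1.0 / (1.0 + np.exp(-logits.numpy()))


def build_classifier(
    config: InceptionConfig, rng: np.random.Generator
) -> InceptionClassifier:
    return InceptionClassifier(config, rng)


def training_step(
    model: InceptionClassifier,
    optimizer: nn.Adam,
    batch_x,
    batch_y,
    extra_forward=None,
) -> float:
    """One Adam step on a batch with binary cross-entropy on logits.

    ``extra_forward`` optionally maps the raw batch to the classifier input
    (e.g. a trainable pooling front end), keeping its parameters in the same
    backward pass.
    """
    y = np.asarray(batch_y, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("labels must be binary (0/1)")
    model.set_training(True)
    x = extra_forward(batch_x) if extra_forward is not None else batch_x
    logits = model(x)
    loss = nn.bce_with_logits(logits, y)
    if not np.isfinite(loss.item()):
        raise RuntimeError(
            f"non-finite training loss {loss.item()}; "
            f"logit range [{logits.numpy().min():.3g}, {logits.numpy().max():.3g}]"
        )
    optimizer.zero_grad()
    loss.backward()
    optimizer.step()
    return loss.item()
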