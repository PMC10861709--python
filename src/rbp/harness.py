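"""Cross-validated evaluation of channel-count robustness.

Protocol: subjects are split into stratified folds; within each fold the
non-test subjects are split 75/25 into train/validation; the classifier is
trained on the *densest* channel system only; after every epoch the
validation AUC is computed on every channel-system version and the epoch
with the best mean is kept; test AUC is then reported per channel-system
version with the kept weights.  A grid search over ``min_nodes`` and
``num_montage_splits`` repeats this per grid cell.

``ExperimentConfig`` defaults are the full-scale settings (50 epochs, Adam
at 1e-4, batch 16, depth-6/32-filter classifier); :meth:`ExperimentConfig.
desk_scale` returns the CPU-friendly configuration used by this package's
own evaluation runs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import nn
from .baselines import build_interpolator, interpolate, zero_fill
from .inception import InceptionClassifier, InceptionConfig, build_classifier, training_step
from .rbp_layer import RBPConfig, RBPLayer, build_rbp
from .synthetic import SyntheticDataset

__all__ = [
    "CVPlan",
    "ExperimentConfig",
    "RunResult",
    "make_cv_plan",
    "compute_auc",
    "train_and_evaluate",
    "grid_search",
]

METHODS = ("rbp", "spline", "zero_fill")


@dataclass(frozen=True)
class CVPlan:
    """Subject-level train/val/test partition per fold."""

    n_folds: int
    val_fraction: float
    seed: int
    folds: Tuple[Dict[str, Tuple[int, ...]], ...]  # keys: train, val, test

    def __post_init__(self) -> None:
        all_test: List[int] = []
        for fold in self.folds:
            groups = [set(fold["train"]), set(fold["val"]), set(fold["test"])]
            for a in range(3):
                for b in range(a + 1, 3):
                    if groups[a] & groups[b]:
                        raise ValueError("train/val/test overlap within a fold")
            all_test.extend(fold["test"])
        if len(all_test) != len(set(all_test)):
            raise ValueError("test folds overlap across folds")


def make_cv_plan(
    subject_ids: Sequence[str],
    labels: Sequence[int],
    n_folds: int = 5,
    val_fraction: float = 0.25,
    seed: int = 0,
) -> CVPlan:
    """Stratified folds; non-test subjects split train/val (default 75/25)."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < n_folds:
        raise ValueError("need at least n_folds subjects per class")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = []
    idx = np.arange(len(y))
    for f, (rest, test) in enumerate(skf.split(idx, y)):
        train, val = train_test_split(
            rest,
            test_size=val_fraction,
            stratify=y[rest],
            random_state=seed + 1000 + f,
        )
        folds.append(
            {
                "train": tuple(int(i) for i in train),
                "val": tuple(int(i) for i in val),
                "test": tuple(int(i) for i in test),
            }
        )
    return CVPlan(n_folds, val_fraction, seed, tuple(folds))


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class ExperimentConfig:
    """Training configuration; defaults are the full-scale settings."""

    method: str = "rbp"
    epochs: int = 50
    learning_rate: float = 1e-4
    batch_size: int = 16
    depth: int = 6
    num_filters: int = 32
    bottleneck: int = 32
    # RBP-specific
    pooling_mechanism: str = "rocket_attention"
    num_montage_splits: int = 25
    min_nodes: int = 1
    num_kernels: int = 1000
    max_receptive_field: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")

    @staticmethod
    def desk_scale(**overrides) -> "ExperimentConfig":
        """CPU-friendly configuration for the synthetic evaluation runs:
        short training (10 epochs, Adam 1e-3, batch 32), a compact depth-2 /
        4-filter classifier, and average-pooling RBP with 5 montage splits."""
        base = ExperimentConfig(
            epochs=10,
            learning_rate=1e-3,
            batch_size=32,
            depth=2,
            num_filters=4,
            bottleneck=8,
            pooling_mechanism="average",
            num_montage_splits=5,
            min_nodes=2,
            num_kernels=100,
        )
        return replace(base, **overrides)


@dataclass
class RunResult:
    """Per-fold test AUCs and model-selection traces."""

    config: ExperimentConfig
    system_names: List[str]
    test_auc: Dict[Tuple[int, str], float] = field(default_factory=dict)
    val_curves: List[List[float]] = field(default_factory=list)
    selected_epochs: List[int] = field(default_factory=list)

    def mean_test_auc(self) -> Dict[str, float]:
        out = {}
        for name in self.system_names:
            vals = [v for (f, s), v in self.test_auc.items() if s == name]
            out[name] = float(np.mean(vals))
        return out


class _MethodFrontEnd:
    """Maps recordings of any channel-system version to classifier input."""

    def __init__(self, method: str, config: ExperimentConfig, data: SyntheticDataset):
        self.method = method
        base = data.systems[data.base_name]
        if method == "rbp":
            smallest = data.systems[f"synthetic{min(data.spec.subset_sizes)}"]
            self.layer: Optional[RBPLayer] = build_rbp(
                RBPConfig(
                    num_montage_splits=config.num_montage_splits,
                    min_nodes=config.min_nodes,
                    pooling_mechanism=config.pooling_mechanism,
                    seed_splits=config.seed,
                    seed_weights=config.seed + 1,
                    num_kernels=config.num_kernels,
                    max_receptive_field=config.max_receptive_field,
                ),
                base,
                smallest,
            )
            for name in data.system_names():
                self.layer.register_channel_system(data.systems[name])
            self.input_rows = self.layer.total_regions
        else:
            self.layer = None
            self.ops = {}
            for name in data.system_names():
                system = data.systems[name]
                if method == "spline" and name != base.name:
                    self.ops[name] = build_interpolator(system, base)
                else:
                    self.ops[name] = None  # zero-fill / identity
            self.systems = data.systems
            self.base = base
            self.input_rows = len(base)
        self.data = data

    def trainable_parameters(self) -> List[nn.Tensor]:
        return self.layer.parameters() if self.layer is not None else []

    def map_batch(self, X: np.ndarray, system_name: str, training: bool = False):
        """(B, C, T) recordings of ``system_name`` -> classifier input."""
        if self.method == "rbp":
            if training and self.layer.parameters():
                return self.layer.forward_batch(X, system_name)
            return self.layer.transform_batch(X, system_name)
        if system_name == self.base.name:
            return np.asarray(X, dtype=float)
        system = self.systems[system_name]
        if self.method == "zero_fill":
            return np.stack([zero_fill(x, system, self.base) for x in X])
        op = self.ops[system_name]
        return np.stack([interpolate(x, op) for x in X])


def _predict_in_chunks(
    model: InceptionClassifier, X: np.ndarray, chunk: int = 32
) -> np.ndarray:
    probs = []
    for lo in range(0, len(X), chunk):
        probs.append(model.predict_proba(X[lo : lo + chunk]))
    return np.concatenate(probs)


def _snapshot(model, front_end) -> dict:
    state = {"model": copy.deepcopy(model.state_arrays())}
    if front_end.layer is not None:
        state["rbp"] = [p.data.copy() for p in front_end.layer.parameters()]
    return state


def _restore(model, front_end, state: dict) -> None:
    model.load_state_arrays(state["model"])
    if front_end.layer is not None:
        for p, saved in zip(front_end.layer.parameters(), state["rbp"]):
            p.data = saved.copy()


def train_and_evaluate(
    method: str,
    config: ExperimentConfig,
    data: SyntheticDataset,
    cv_plan: CVPlan,
) -> RunResult:
    """Run the full protocol for one method; see module docstring."""
    config = replace(config, method=method)
    system_names = data.system_names()
    base_name = data.base_name
    result = RunResult(config, system_names)

    for fold_idx, fold in enumerate(cv_plan.folds):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(7, fold_idx))
        )
        front_end = _MethodFrontEnd(method, config, data)
        model = build_classifier(
            InceptionConfig(
                input_rows=front_end.input_rows,
                depth=config.depth,
                num_filters=config.num_filters,
                bottleneck=config.bottleneck,
            ),
            rng,
        )
        params = model.parameters() + front_end.trainable_parameters()
        optimizer = nn.Adam(params, lr=config.learning_rate)

        train_idx = np.array(fold["train"])
        val_idx = np.array(fold["val"])
        test_idx = np.array(fold["test"])
        y = data.labels

        # training inputs: densest system only
        X_train_raw = data.recordings_for(base_name)[train_idx]
        static_front = not front_end.trainable_parameters()
        X_train = (
            front_end.map_batch(X_train_raw, base_name) if static_front else None
        )

        # validation inputs per channel-system version (static methods only)
        val_inputs = {}
        if static_front:
            for name in system_names:
                val_inputs[name] = front_end.map_batch(
                    data.recordings_for(name)[val_idx], name
                )

        val_curve: List[float] = []
        best = (-np.inf, None, -1)
        for epoch in range(config.epochs):
            order = rng.permutation(len(train_idx))
            for lo in range(0, len(order), config.batch_size):
                sel = order[lo : lo + config.batch_size]
                if static_front:
                    batch_x = X_train[sel]
                else:
                    batch_x = front_end.map_batch(
                        X_train_raw[sel], base_name, training=True
                    )
                training_step(model, optimizer, batch_x, y[train_idx][sel])
            # per-epoch model selection on the mean validation AUC
            aucs = []
            for name in system_names:
                xin = (
                    val_inputs[name]
                    if static_front
                    else front_end.map_batch(
                        data.recordings_for(name)[val_idx], name
                    )
                )
                probs = _predict_in_chunks(model, xin)
                aucs.append(compute_auc(probs, y[val_idx]))
            mean_auc = float(np.mean(aucs))
            val_curve.append(mean_auc)
            if mean_auc > best[0]:
                best = (mean_auc, _snapshot(model, front_end), epoch)

        _restore(model, front_end, best[1])
        result.val_curves.append(val_curve)
        result.selected_epochs.append(best[2])
        for name in system_names:
            xin = front_end.map_batch(data.recordings_for(name)[test_idx], name)
            probs = _predict_in_chunks(model, xin)
            result.test_auc[(fold_idx, name)] = compute_auc(probs, y[test_idx])
    return result


def grid_search(
    method: str,
    min_nodes_grid: Sequence[int],
    num_splits_grid: Sequence[int],
    data: SyntheticDataset,
    cv_plan: CVPlan,
    config: Optional[ExperimentConfig] = None,
) -> pd.DataFrame:
    """Mean test AUC per channel-system version over the hyperparameter grid."""
    if not len(min_nodes_grid) or not len(num_splits_grid):
        raise ValueError("grid must be non-empty")
    config = config or ExperimentConfig.desk_scale()
    rows = []
    for mn in min_nodes_grid:
        for ns in num_splits_grid:
            cell = replace(config, min_nodes=mn, num_montage_splits=ns)
            res = train_and_evaluate(method, cell, data, cv_plan)
            row = {"min_nodes": mn, "num_montage_splits": ns}
            row.update(
                {f"auc_{k}": v for k, v in res.mean_test_auc().items()}
            )
            rows.append(row)
    return pd.DataFrame(rows)
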