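"""The Region Based Pooling layer: fixed-dimension output for any montage.

A layer holds ``n`` randomized montage splits of a base montage plus one set
of pooling parameters per (split, region).  Any channel system whose channels
leave no region empty can be *registered*; a recording from a registered
system is mapped to a ``total_regions x T`` matrix — one z-normalized region
representation per region, rows ordered by (split index, region index) — so
recordings with different channel counts all produce the same output shape.

Feasibility is guaranteed by construction against a declared
minimum-resolution system: every region of every split contains at least
``min_nodes`` of its channels, so that system (and any denser nested system)
always registers.
"""

from __future__ import annotations

import base64
import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import nn, pooling
from .channel_systems import ChannelSystem, ElectrodePosition, ProjectedMontage, project_to_2d
from .montage_split import (
    DEFAULT_SPLIT_VECTORS,
    DegenerateSplitError,
    IncompatibleChannelSystemError,
    MontageSplit,
    RegionAssignment,
    SplitVector,
    assign_channels,
    generate_montage_split,
    sample_split_vector,
    split_from_dict,
    split_to_dict,
)
from .nn import Tensor
from .pooling import (
    ContinuousScorer,
    RocketKernelSet,
    attention_pool,
    compute_search_embedding,
    continuous_attention_pool,
    head_region_attention_pool,
    init_attention_weights,
    rocket_features,
    sample_rocket_kernels,
    score_channels_linear,
)

__all__ = ["POOLING_MECHANISMS", "RBPConfig", "RBPOutput", "RBPLayer", "build_rbp"]

POOLING_MECHANISMS = (
    "average",
    "rocket_attention",
    "continuous_attention",
    "head_region",
)

_FORMAT_VERSION = 1
_NORM_EPS = 1e-8


@dataclass(frozen=True)
class RBPConfig:
    """Layer hyperparameters.

    ``num_kernels`` / ``max_receptive_field`` follow the full-size setting
    (1000 kernels, receptive field at most 250 samples); ``embedding_dim``
    is the head-region search-embedding width (64).
    """

    num_montage_splits: int = 5
    min_nodes: int = 2
    pooling_mechanism: str = "average"
    split_vector_pool: Tuple[SplitVector, ...] = DEFAULT_SPLIT_VECTORS
    seed_splits: int = 0
    seed_weights: int = 0
    num_kernels: int = 1000
    max_receptive_field: int = 250
    embedding_dim: int = 64
    max_build_attempts: int = 100

    def __post_init__(self) -> None:
        if self.num_montage_splits < 1:
            raise ValueError("num_montage_splits must be >= 1")
        if self.min_nodes < 1:
            raise ValueError("min_nodes must be >= 1")
        if self.pooling_mechanism not in POOLING_MECHANISMS:
            raise ValueError(
                f"unknown pooling mechanism {self.pooling_mechanism!r}; "
                f"choose from {POOLING_MECHANISMS}"
            )


@dataclass
class RBPOutput:
    """Stacked region representations of one recording."""

    data: Union[np.ndarray, Tensor]  # (total_regions, T)
    row_index: Tuple[Tuple[int, int], ...]  # row -> (split, region)

    def numpy(self) -> np.ndarray:
        return self.data.numpy() if isinstance(self.data, Tensor) else self.data


def _znorm_rows(Y: np.ndarray) -> np.ndarray:
    mu = Y.mean(axis=-1, keepdims=True)
    sd = Y.std(axis=-1, keepdims=True)
    return (Y - mu) / (sd + _NORM_EPS)


def _znorm_tensor(row: Tensor) -> Tensor:
    mu = row.mean()
    centered = row - mu
    sd = (centered * centered).mean() ** 0.5
    return centered / (sd + _NORM_EPS)


class RBPLayer:
    """Built by :func:`build_rbp`; see module docstring."""

    def __init__(
        self,
        config: RBPConfig,
        base_montage: ChannelSystem,
        min_resolution: ChannelSystem,
        splits: List[MontageSplit],
        head_regions: Optional[List[int]],
        kernels: Optional[RocketKernelSet],
        params: Dict[str, object],
    ):
        self.config = config
        self.base_montage = base_montage
        self.min_resolution = min_resolution
        self.splits = list(splits)
        self.head_regions = head_regions
        self.kernels = kernels
        self.params = params
        self.registry: Dict[str, List[RegionAssignment]] = {}
        self._avg_matrices: Dict[str, np.ndarray] = {}
        self.row_index: Tuple[Tuple[int, int], ...] = tuple(
            (split.index, region.region_index)
            for split in self.splits
            for region in split.regions
        )

    # -- bookkeeping -----------------------------------------------------
    @property
    def total_regions(self) -> int:
        return sum(len(split) for split in self.splits)

    @property
    def needs_rocket(self) -> bool:
        return self.config.pooling_mechanism in ("rocket_attention", "head_region")

    def parameters(self) -> List[Tensor]:
        out: List[Tensor] = []
        for value in self.params.values():
            if isinstance(value, Tensor):
                out.append(value)
            elif isinstance(value, nn.Module):
                out.extend(value.parameters())
        return out

    def set_training(self, mode: bool) -> None:
        for value in self.params.values():
            if isinstance(value, nn.Module):
                value.set_training(mode)

    # -- registration ----------------------------------------------------
    def register_channel_system(self, system: ChannelSystem) -> None:
        """Compute and store region assignments for ``system``.

        Raises :class:`IncompatibleChannelSystemError` if any region of any
        montage split would be empty.
        """
        projected = project_to_2d(system)
        assignments = [assign_channels(split, projected) for split in self.splits]
        self.registry[system.name] = assignments
        self._avg_matrices.pop(system.name, None)

    def _assignments(self, system_name: str) -> List[RegionAssignment]:
        if system_name not in self.registry:
            raise KeyError(
                f"channel system {system_name!r} is not registered; "
                f"known: {sorted(self.registry)}"
            )
        return self.registry[system_name]

    def _average_matrix(self, system_name: str) -> np.ndarray:
        """(total_regions, n_channels) mean-pooling operator for a system."""
        if system_name not in self._avg_matrices:
            assignments = self._assignments(system_name)
            n_channels = sum(
                len(idx) for idx in assignments[0].channels.values()
            )
            P = np.zeros((self.total_regions, n_channels))
            row = 0
            for split, assignment in zip(self.splits, assignments):
                for region in split.regions:
                    idx = assignment.channels[region.id]
                    P[row, list(idx)] = 1.0 / len(idx)
                    row += 1
            self._avg_matrices[system_name] = P
        return self._avg_matrices[system_name]

    # -- forward ---------------------------------------------------------
    def compute_rocket_features(self, X: np.ndarray) -> Optional[np.ndarray]:
        """(C, T) -> (C, 2*num_kernels) frozen features, or None if the
        mechanism does not use them.  Constant per (subject, channel), so
        callers should cache the result across epochs."""
        if not self.needs_rocket:
            return None
        return rocket_features(np.asarray(X, dtype=float), self.kernels)

    def forward(
        self,
        X: Union[np.ndarray, Tensor],
        system_name: str,
        features: Optional[np.ndarray] = None,
    ) -> RBPOutput:
        """Pool one recording (channels x T) into region representations.

        ``features`` are precomputed ROCKET features for the recording's
        channels (ignored by mechanisms that do not use them).  Output rows
        are z-normalized over time with an epsilon-guarded denominator.
        """
        assignments = self._assignments(system_name)
        mech = self.config.pooling_mechanism
        X_data = X.numpy() if isinstance(X, Tensor) else np.asarray(X, dtype=float)
        if X_data.ndim != 2:
            raise ValueError("recording must be 2-D (channels x time)")

        if mech == "average":
            Y = self._average_matrix(system_name) @ X_data
            return RBPOutput(_znorm_rows(Y), self.row_index)

        if self.needs_rocket and features is None:
            features = self.compute_rocket_features(X_data)

        Xt = X if isinstance(X, Tensor) else Tensor(X_data)
        rows: List[Tensor] = []
        for split, assignment in zip(self.splits, assignments):
            head_idx = (
                self.head_regions[split.index] if mech == "head_region" else None
            )
            if mech == "head_region":
                head_region = split.regions[head_idx]
                head_channels = list(assignment.channels[head_region.id])
                Z_head = features[head_channels].T  # features x channels
            for region in split.regions:
                idx = list(assignment.channels[region.id])
                X_region = Xt.take_rows(idx, axis=0)
                if mech == "rocket_attention":
                    w = self.params[_key(split.index, region.region_index, "w")]
                    scores = score_channels_linear(Tensor(features[idx]), w)
                    rep, _ = attention_pool(X_region, scores)
                elif mech == "continuous_attention":
                    scorer = self.params[
                        _key(split.index, region.region_index, "g")
                    ]
                    rep, _ = continuous_attention_pool(X_region, scorer(X_region))
                elif mech == "head_region":
                    if region.region_index == head_idx:
                        w = self.params[_key(split.index, head_idx, "w")]
                        scores = score_channels_linear(Tensor(features[idx]), w)
                        rep, _ = attention_pool(X_region, scores)
                    else:
                        W1 = self.params[
                            _key(split.index, region.region_index, "W1")
                        ]
                        W2 = self.params[
                            _key(split.index, region.region_index, "W2")
                        ]
                        s = compute_search_embedding(Tensor(Z_head), W1, W2)
                        rep, _ = head_region_attention_pool(
                            X_region, Tensor(features[idx].T), s, W1
                        )
                else:  # pragma: no cover - guarded by RBPConfig
                    raise ValueError(f"unknown mechanism {mech!r}")
                rows.append(_znorm_tensor(rep))
        out = nn.stack(rows, axis=0)
        return RBPOutput(out, self.row_index)

    def transform(
        self,
        X: np.ndarray,
        system_name: str,
        features: Optional[np.ndarray] = None,
    ) -> np.ndarray:
        """Like :meth:`forward` but always returns a plain array."""
        return self.forward(X, system_name, features=features).numpy()

    def transform_batch(
        self,
        Xs: np.ndarray,
        system_name: str,
        features_list: Optional[Sequence[np.ndarray]] = None,
    ) -> np.ndarray:
        """Pool a stack of recordings (B, C, T) -> (B, total_regions, T)."""
        Xs = np.asarray(Xs, dtype=float)
        if self.config.pooling_mechanism == "average":
            Y = np.einsum(
                "rc,bct->brt", self._average_matrix(system_name), Xs, optimize=True
            )
            return _znorm_rows(Y)
        outs = []
        for b in range(Xs.shape[0]):
            feats = None if features_list is None else features_list[b]
            outs.append(self.transform(Xs[b], system_name, features=feats))
        return np.stack(outs, axis=0)

    def forward_batch(
        self,
        Xs: np.ndarray,
        system_name: str,
        features_list: Optional[Sequence[np.ndarray]] = None,
    ) -> Tensor:
        """Batched forward keeping the autodiff graph (for joint training of
        pooling parameters with a downstream model)."""
        if self.config.pooling_mechanism == "average":
            return Tensor(self.transform_batch(Xs, system_name))
        outs = []
        for b in range(np.asarray(Xs).shape[0]):
            feats = None if features_list is None else features_list[b]
            outs.append(self.forward(Xs[b], system_name, features=feats).data)
        return nn.stack(outs, axis=0)

    # -- persistence -----------------------------------------------------
    def save(self, path: str) -> None:
        """Single-file JSON container (arrays base64-encoded, checksummed)."""
        payload = {
            "format_version": _FORMAT_VERSION,
            "config": _config_to_dict(self.config),
            "base_montage": _system_to_dict(self.base_montage),
            "min_resolution": _system_to_dict(self.min_resolution),
            "splits": [split_to_dict(s) for s in self.splits],
            "head_regions": self.head_regions,
            "kernels": self.kernels.to_dict() if self.kernels else None,
            "params": _params_to_dict(self.params),
            "registered": [
                _system_to_dict(sys)
                for sys in self._registered_systems.values()
            ]
            if hasattr(self, "_registered_systems")
            else [],
        }
        blob = json.dumps(payload, sort_keys=True)
        digest = hashlib.sha256(blob.encode()).hexdigest()
        with open(path, "w") as fh:
            json.dump({"sha256": digest, "payload": payload}, fh, sort_keys=True)

    @staticmethod
    def load(path: str) -> "RBPLayer":
        with open(path) as fh:
            wrapper = json.load(fh)
        payload = wrapper.get("payload")
        blob = json.dumps(payload, sort_keys=True)
        if hashlib.sha256(blob.encode()).hexdigest() != wrapper.get("sha256"):
            raise ValueError("model container checksum mismatch (file tampered?)")
        if payload["format_version"] != _FORMAT_VERSION:
            raise ValueError(
                f"unsupported container version {payload['format_version']}"
            )
        config = _config_from_dict(payload["config"])
        base = _system_from_dict(payload["base_montage"])
        min_res = _system_from_dict(payload["min_resolution"])
        splits = [split_from_dict(d) for d in payload["splits"]]
        kernels = (
            RocketKernelSet.from_dict(payload["kernels"])
            if payload["kernels"]
            else None
        )
        params = _params_from_dict(payload["params"], config)
        layer = RBPLayer(
            config, base, min_res, splits, payload["head_regions"], kernels, params
        )
        for sys_dict in payload["registered"]:
            layer.register_channel_system(_system_from_dict(sys_dict))
        return layer

    def register_and_remember(self, system: ChannelSystem) -> None:
        """Register a system and keep it for persistence round trips."""
        self.register_channel_system(system)
        if not hasattr(self, "_registered_systems"):
            self._registered_systems = {}
        self._registered_systems[system.name] = system


def _key(i: int, j: int, name: str) -> str:
    return f"{i}:{j}:{name}"


def build_rbp(
    config: RBPConfig,
    base_montage: ChannelSystem,
    min_resolution: ChannelSystem,
) -> RBPLayer:
    """Generate montage splits and pooling parameters.

    Each split draws its own vector from the pool and its own angles from a
    dedicated seeded stream; degenerate splits are re-sampled up to
    ``config.max_build_attempts`` times.  Deterministic given the seeds.
    """
    projected = project_to_2d(base_montage)
    min_res_proj = project_to_2d(min_resolution)

    splits: List[MontageSplit] = []
    head_regions: List[int] = []
    for i in range(config.num_montage_splits):
        split = None
        for attempt in range(config.max_build_attempts):
            seed_seq = np.random.SeedSequence(
                entropy=config.seed_splits, spawn_key=(i, attempt)
            )
            rng = np.random.default_rng(seed_seq)
            vector = sample_split_vector(config.split_vector_pool, rng)
            try:
                split = generate_montage_split(
                    projected,
                    vector,
                    config.min_nodes,
                    min_res_proj,
                    rng,
                    index=i,
                    rng_seed=config.seed_splits,
                )
                break
            except DegenerateSplitError:
                continue
        if split is None:
            raise DegenerateSplitError(
                f"could not generate montage split {i} in "
                f"{config.max_build_attempts} attempts (min_nodes too large?)"
            )
        splits.append(split)
        head_regions.append(int(rng.integers(len(split))))

    weights_ss = np.random.SeedSequence(entropy=config.seed_weights, spawn_key=(0,))
    kernels_rng, params_rng = (
        np.random.default_rng(s) for s in weights_ss.spawn(2)
    )

    kernels = None
    mech = config.pooling_mechanism
    if mech in ("rocket_attention", "head_region"):
        kernels = sample_rocket_kernels(
            config.num_kernels, config.max_receptive_field, kernels_rng
        )

    params: Dict[str, object] = {}
    nf = 2 * config.num_kernels
    for split in splits:
        for region in split.regions:
            i, j = split.index, region.region_index
            if mech == "rocket_attention":
                params[_key(i, j, "w")] = init_attention_weights((nf,), params_rng)
            elif mech == "continuous_attention":
                params[_key(i, j, "g")] = ContinuousScorer(params_rng)
            elif mech == "head_region":
                if j == head_regions[split.index]:
                    params[_key(i, j, "w")] = init_attention_weights(
                        (nf,), params_rng
                    )
                else:
                    params[_key(i, j, "W1")] = init_attention_weights(
                        (config.embedding_dim, nf), params_rng
                    )
                    params[_key(i, j, "W2")] = init_attention_weights(
                        (config.embedding_dim, nf), params_rng
                    )

    layer = RBPLayer(
        config,
        base_montage,
        min_resolution,
        splits,
        head_regions if mech == "head_region" else None,
        kernels,
        params,
    )
    return layer


# ---------------------------------------------------------------------------
# container helpers


def _b64_array(a: np.ndarray) -> dict:
    a = np.ascontiguousarray(a, dtype=np.float64)
    return {
        "shape": list(a.shape),
        "data": base64.b64encode(a.tobytes()).decode("ascii"),
    }


def _unb64_array(d: dict) -> np.ndarray:
    buf = base64.b64decode(d["data"])
    return np.frombuffer(buf, dtype=np.float64).reshape(d["shape"]).copy()


def _params_to_dict(params: Dict[str, object]) -> dict:
    out = {}
    for key, value in params.items():
        if isinstance(value, Tensor):
            out[key] = {"kind": "tensor", "array": _b64_array(value.data)}
        elif isinstance(value, nn.Module):
            out[key] = {
                "kind": "module",
                "arrays": {
                    name: _b64_array(arr)
                    for name, arr in value.state_arrays().items()
                },
            }
    return out


def _params_from_dict(d: dict, config: RBPConfig) -> Dict[str, object]:
    params: Dict[str, object] = {}
    for key, value in d.items():
        if value["kind"] == "tensor":
            params[key] = Tensor(_unb64_array(value["array"]), requires_grad=True)
        else:
            scorer = ContinuousScorer(np.random.default_rng(0))
            scorer.load_state_arrays(
                {name: _unb64_array(a) for name, a in value["arrays"].items()}
            )
            params[key] = scorer
    return params


def _system_to_dict(system: ChannelSystem) -> dict:
    return {
        "name": system.name,
        "electrodes": [[e.label, e.x, e.y, e.z] for e in system.electrodes],
    }


def _system_from_dict(d: dict) -> ChannelSystem:
    return ChannelSystem(
        d["name"],
        tuple(ElectrodePosition(l, x, y, z) for l, x, y, z in d["electrodes"]),
    )


def _config_to_dict(config: RBPConfig) -> dict:
    return {
        "num_montage_splits": config.num_montage_splits,
        "min_nodes": config.min_nodes,
        "pooling_mechanism": config.pooling_mechanism,
        "split_vector_pool": [list(v.k) for v in config.split_vector_pool],
        "seed_splits": config.seed_splits,
        "seed_weights": config.seed_weights,
        "num_kernels": config.num_kernels,
        "max_receptive_field": config.max_receptive_field,
        "embedding_dim": config.embedding_dim,
        "max_build_attempts": config.max_build_attempts,
    }


def _config_from_dict(d: dict) -> RBPConfig:
    return RBPConfig(
        num_montage_splits=d["num_montage_splits"],
        min_nodes=d["min_nodes"],
        pooling_mechanism=d["pooling_mechanism"],
        split_vector_pool=tuple(
            SplitVector(tuple(v)) for v in d["split_vector_pool"]
        ),
        seed_splits=d["seed_splits"],
        seed_weights=d["seed_weights"],
        num_kernels=d["num_kernels"],
        max_receptive_field=d["max_receptive_field"],
        embedding_dim=d["embedding_dim"],
        max_build_attempts=d["max_build_attempts"],
    )
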