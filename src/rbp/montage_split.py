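"""Randomized angular partitioning of a projected montage into regions.

A *montage split* divides the 2-D projected montage into non-overlapping
regions by a recursive angular procedure driven by a *split vector*
``k = (k_1, ..., k_p)``: at level 1 the full montage is cut into ``k_1``
angular sectors around its centroid, each containing (as near as possible)
the same number of channels; at level 2 each sector is cut into ``k_2``
sub-sectors around its own centroid, and so on.  Recursion stops after ``p``
levels or earlier, per region, when a candidate cut would leave any child
with fewer than ``min_nodes`` channels of a declared minimum-resolution
system.

Each region stores its full lineage of (centroid, start angle, angular
interval) constraints, so membership of an *arbitrary* 2-D point is decidable
— channels of channel systems never seen at construction time can be assigned
to regions.  Sibling intervals are half-open and jointly cover the full
circle, so every point belongs to exactly one leaf region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .channel_systems import ProjectedMontage

__all__ = [
    "DEFAULT_SPLIT_VECTORS",
    "SplitVector",
    "AngularConstraint",
    "Region",
    "MontageSplit",
    "RegionAssignment",
    "SplitError",
    "InfeasibleSplitError",
    "DegenerateGeometryError",
    "DegenerateSplitError",
    "IncompatibleChannelSystemError",
    "sample_split_vector",
    "angular_partition",
    "generate_montage_split",
    "assign_channels",
]

TWO_PI = 2.0 * np.pi


class SplitError(ValueError):
    """Base class for montage-splitting failures."""


class InfeasibleSplitError(SplitError):
    """Fewer points than requested sectors."""


class DegenerateGeometryError(SplitError):
    """All points coincide with the centroid; angles are undefined."""


class DegenerateSplitError(SplitError):
    """The generated montage split would have fewer than two regions."""


class IncompatibleChannelSystemError(SplitError):
    """A channel system leaves at least one region empty."""


@dataclass(frozen=True)
class SplitVector:
    """Per-level branching factors of the recursive angular partition."""

    k: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.k) < 1:
            raise SplitError("split vector must have at least one level")
        if any(int(v) < 2 for v in self.k):
            raise SplitError(f"all split-vector entries must be >= 2, got {self.k}")
        object.__setattr__(self, "k", tuple(int(v) for v in self.k))

    @property
    def p(self) -> int:
        return len(self.k)

    def __iter__(self):
        return iter(self.k)


#: the seven split vectors used by default when building a pooling layer
DEFAULT_SPLIT_VECTORS: Tuple[SplitVector, ...] = tuple(
    SplitVector(k)
    for k in [
        (3, 3, 3),
        (4, 2, 4),
        (2, 4, 2),
        (2, 2, 2, 2, 2),
        (3, 2, 3),
        (2, 3, 2),
        (3, 4, 2),
    ]
)


@dataclass(frozen=True)
class AngularConstraint:
    """One lineage level: point angle about ``centroid`` (measured from
    ``theta0``) must fall in the half-open offset interval ``[lo, hi)``."""

    centroid: Tuple[float, float]
    theta0: float
    lo: float
    hi: float

    def offset(self, point: np.ndarray) -> float:
        dx = point[0] - self.centroid[0]
        dy = point[1] - self.centroid[1]
        return float(np.mod(np.arctan2(dy, dx) - self.theta0, TWO_PI))

    def contains(self, point: np.ndarray) -> bool:
        off = self.offset(point)
        return self.lo <= off < self.hi

    def contains_many(self, points: np.ndarray) -> np.ndarray:
        """Vectorized membership for an (n, 2) array of points."""
        dx = points[:, 0] - self.centroid[0]
        dy = points[:, 1] - self.centroid[1]
        off = np.mod(np.arctan2(dy, dx) - self.theta0, TWO_PI)
        return (self.lo <= off) & (off < self.hi)


@dataclass(frozen=True)
class Region:
    """Leaf region of a montage split, defined by its lineage of constraints."""

    split_index: int
    region_index: int
    lineage: Tuple[AngularConstraint, ...]

    @property
    def id(self) -> Tuple[int, int]:
        return (self.split_index, self.region_index)

    def contains(self, point: np.ndarray) -> bool:
        return all(c.contains(point) for c in self.lineage)

    def contains_many(self, points: np.ndarray) -> np.ndarray:
        """Vectorized membership for an (n, 2) array of points."""
        mask = np.ones(len(points), dtype=bool)
        for c in self.lineage:
            mask &= c.contains_many(points)
        return mask


@dataclass(frozen=True)
class MontageSplit:
    """One partition of the projected montage into leaf regions."""

    index: int
    regions: Tuple[Region, ...]
    split_vector: SplitVector
    source_montage: str
    rng_seed: int

    def __post_init__(self) -> None:
        if len(self.regions) < 2:
            raise DegenerateSplitError(
                f"montage split {self.index} has {len(self.regions)} region(s); "
                "need at least 2"
            )

    def __len__(self) -> int:
        return len(self.regions)

    def region_of(self, point: np.ndarray) -> Region:
        """The unique leaf region containing ``point``."""
        for region in self.regions:
            if region.contains(point):
                return region
        # cannot happen: sibling intervals tile the circle at every level
        raise SplitError(f"point {point} matched no region (split {self.index})")


@dataclass(frozen=True)
class RegionAssignment:
    """Channel indices of one system, grouped by region of one montage split."""

    system_name: str
    split_index: int
    channels: Dict[Tuple[int, int], Tuple[int, ...]] = field(hash=False)

    def counts(self) -> Dict[Tuple[int, int], int]:
        return {rid: len(idx) for rid, idx in self.channels.items()}


def sample_split_vector(
    pool: Sequence[SplitVector], rng: np.random.Generator
) -> SplitVector:
    """Draw one split vector uniformly at random from ``pool``."""
    if len(pool) == 0:
        raise SplitError("split-vector pool is empty")
    return pool[int(rng.integers(len(pool)))]


def angular_partition(
    points: Dict[str, np.ndarray], k: int, rng: np.random.Generator
) -> Tuple[List[AngularConstraint], List[List[str]]]:
    """Cut a point set into ``k`` angular sectors of near-equal channel count.

    The centroid of the points is the pivot; a random start angle ``theta0``
    is drawn; points are ordered by azimuth (offset from ``theta0``, ties
    broken by label) and cut into ``k`` contiguous groups whose sizes differ
    by at most one, earlier groups receiving the remainder.  Sector
    boundaries sit at the angular midpoint between the last member of one
    group and the first member of the next; the first boundary is ``theta0``
    itself.  Returns the ``k`` half-open constraints and their member labels.
    """
    labels = list(points.keys())
    n = len(labels)
    if k < 2:
        raise SplitError(f"k must be >= 2, got {k}")
    if n < k:
        raise InfeasibleSplitError(f"cannot cut {n} points into {k} sectors")
    coords = np.array([points[l] for l in labels], dtype=float)
    centroid = coords.mean(axis=0)
    rel = coords - centroid
    radii = np.hypot(rel[:, 0], rel[:, 1])
    if np.all(radii < 1e-12):
        raise DegenerateGeometryError("all points coincide with the centroid")

    theta0 = float(rng.uniform(0.0, TWO_PI))
    offsets = np.mod(np.arctan2(rel[:, 1], rel[:, 0]) - theta0, TWO_PI)
    order = sorted(range(n), key=lambda i: (offsets[i], labels[i]))

    q, r = divmod(n, k)
    sizes = [q + 1] * r + [q] * (k - r)
    groups: List[List[int]] = []
    start = 0
    for s in sizes:
        groups.append(order[start : start + s])
        start += s

    boundaries = [0.0]
    for g in range(1, k):
        prev_last = offsets[groups[g - 1][-1]]
        cur_first = offsets[groups[g][0]]
        boundaries.append(0.5 * (prev_last + cur_first))
    boundaries.append(TWO_PI)

    ctr = (float(centroid[0]), float(centroid[1]))
    constraints = [
        AngularConstraint(ctr, theta0, boundaries[g], boundaries[g + 1])
        for g in range(k)
    ]
    member_labels = [[labels[i] for i in grp] for grp in groups]
    return constraints, member_labels


def _count_members(
    lineage: Tuple[AngularConstraint, ...], montage: ProjectedMontage
) -> int:
    return sum(
        1
        for l in montage.labels
        if all(c.contains(montage.points[l]) for c in lineage)
    )


def generate_montage_split(
    montage: ProjectedMontage,
    split_vector: SplitVector,
    min_nodes: int,
    min_resolution: ProjectedMontage,
    rng: np.random.Generator,
    *,
    index: int = 0,
    rng_seed: int = 0,
) -> MontageSplit:
    """Run the recursive angular partition on ``montage``.

    At each level every current leaf is a candidate for splitting with that
    level's branching factor.  A candidate cut is accepted only if *every*
    child would hold at least ``min_nodes`` channels of ``min_resolution``
    (evaluated with the child's own geometric predicate); otherwise the
    region stays a leaf while its siblings may still split.  The accepted
    leaves, in depth-first sector order, are the returned regions.
    """
    if len(montage) < 2:
        raise DegenerateSplitError("montage must have at least 2 channels")
    if min_nodes < 1:
        raise SplitError(f"min_nodes must be >= 1, got {min_nodes}")

    # each leaf tracks (lineage, member labels of the montage being split)
    leaves: List[Tuple[Tuple[AngularConstraint, ...], List[str]]] = [
        ((), list(montage.labels))
    ]
    for k in split_vector:
        next_leaves: List[Tuple[Tuple[AngularConstraint, ...], List[str]]] = []
        for lineage, members in leaves:
            if len(members) < k:
                next_leaves.append((lineage, members))
                continue
            pts = {l: montage.points[l] for l in members}
            try:
                constraints, groups = angular_partition(pts, k, rng)
            except DegenerateGeometryError:
                next_leaves.append((lineage, members))
                continue
            children = [
                (lineage + (c,), grp) for c, grp in zip(constraints, groups)
            ]
            feasible = all(
                _count_members(child_lineage, min_resolution) >= min_nodes
                for child_lineage, _ in children
            )
            if feasible:
                next_leaves.extend(children)
            else:
                next_leaves.append((lineage, members))
        leaves = next_leaves

    regions = tuple(
        Region(index, j, lineage) for j, (lineage, _) in enumerate(leaves)
    )
    return MontageSplit(index, regions, split_vector, montage.system_name, rng_seed)


def assign_channels(
    split: MontageSplit, projected: ProjectedMontage
) -> RegionAssignment:
    """Assign every channel of ``projected`` to its unique leaf region.

    Fails with :class:`IncompatibleChannelSystemError` if any region of the
    split receives no channel — such a system cannot be pooled by this split.
    """
    channels: Dict[Tuple[int, int], List[int]] = {
        region.id: [] for region in split.regions
    }
    for idx, label in enumerate(projected.labels):
        region = split.region_of(projected.points[label])
        channels[region.id].append(idx)
    empty = [rid for rid, idx in channels.items() if not idx]
    if empty:
        raise IncompatibleChannelSystemError(
            f"system {projected.system_name!r} leaves region(s) {empty} of "
            f"montage split {split.index} empty"
        )
    return RegionAssignment(
        projected.system_name,
        split.index,
        {rid: tuple(idx) for rid, idx in channels.items()},
    )


# ---------------------------------------------------------------------------
# JSON (de)serialization — floats survive exactly via repr round-trip


def split_to_dict(split: MontageSplit) -> dict:
    return {
        "index": split.index,
        "split_vector": list(split.split_vector.k),
        "source_montage": split.source_montage,
        "rng_seed": split.rng_seed,
        "regions": [
            {
                "region_index": r.region_index,
                "lineage": [
                    {
                        "centroid": list(c.centroid),
                        "theta0": c.theta0,
                        "lo": c.lo,
                        "hi": c.hi,
                    }
                    for c in r.lineage
                ],
            }
            for r in split.regions
        ],
    }


def split_from_dict(d: dict) -> MontageSplit:
    regions = tuple(
        Region(
            d["index"],
            r["region_index"],
            tuple(
                AngularConstraint(
                    (c["centroid"][0], c["centroid"][1]),
                    c["theta0"],
                    c["lo"],
                    c["hi"],
                )
                for c in r["lineage"]
            ),
        )
        for r in d["regions"]
    )
    return MontageSplit(
        d["index"],
        regions,
        SplitVector(tuple(d["split_vector"])),
        d["source_montage"],
        d["rng_seed"],
    )


def split_to_json(split: MontageSplit) -> str:
    return json.dumps(split_to_dict(split))


def split_from_json(text: str) -> MontageSplit:
    return split_from_dict(json.loads(text))
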