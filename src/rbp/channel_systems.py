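"""Electrode montages: loading, 2-D projection, and nested subsets.

A *channel system* is a named, ordered set of labeled electrode positions on
(approximately) the unit sphere, with the vertex on +z.  Recordings from a
channel system are ``channels x time`` arrays whose row order is the system's
electrode order.  Montage geometry is flattened to the plane with an azimuthal
equidistant projection about the vertex — the standard layout used for EEG
topographic maps — which preserves the angular neighborhoods that the region
splitting algorithm operates on.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Union

import numpy as np

__all__ = [
    "ElectrodePosition",
    "ChannelSystem",
    "ProjectedMontage",
    "MontageError",
    "load_montage",
    "write_montage",
    "project_to_2d",
    "derive_subset",
]


class MontageError(ValueError):
    """Malformed montage file or invalid electrode geometry."""


@dataclass(frozen=True)
class ElectrodePosition:
    """A labeled 3-D electrode position (head modeled as a unit sphere)."""

    label: str
    x: float
    y: float
    z: float

    #: sanity bounds on the position norm; digitized montages are close to
    #: the unit sphere but rarely exactly on it
    NORM_BOUNDS = (0.5, 1.5)

    def __post_init__(self) -> None:
        if not self.label:
            raise MontageError("electrode label must be non-empty")
        pos = np.array([self.x, self.y, self.z], dtype=float)
        if not np.all(np.isfinite(pos)):
            raise MontageError(f"non-finite coordinates for electrode {self.label!r}")
        lo, hi = self.NORM_BOUNDS
        norm = float(np.linalg.norm(pos))
        if not (lo <= norm <= hi):
            raise MontageError(
                f"electrode {self.label!r} has norm {norm:.4f} outside [{lo}, {hi}]"
            )

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class ChannelSystem:
    """Named, ordered electrode set; order is the canonical channel order."""

    name: str
    electrodes: tuple

    def __post_init__(self) -> None:
        if len(self.electrodes) == 0:
            raise MontageError(f"channel system {self.name!r} has no electrodes")
        labels = [e.label for e in self.electrodes]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise MontageError(f"duplicate electrode labels: {dupes}")

    def __len__(self) -> int:
        return len(self.electrodes)

    @property
    def labels(self) -> List[str]:
        return [e.label for e in self.electrodes]

    def positions(self) -> np.ndarray:
        """(n, 3) array of electrode positions in canonical order."""
        return np.array([e.position for e in self.electrodes], dtype=float)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no electrode {label!r} in system {self.name!r}") from None


@dataclass(frozen=True)
class ProjectedMontage:
    """2-D image of a channel system under the azimuthal projection."""

    system_name: str
    points: Dict[str, np.ndarray] = field(hash=False)

    @property
    def labels(self) -> List[str]:
        return list(self.points.keys())

    def coords(self, labels: Sequence[str] | None = None) -> np.ndarray:
        labs = self.labels if labels is None else list(labels)
        return np.array([self.points[l] for l in labs], dtype=float)

    def subset(self, labels: Sequence[str], name: str) -> "ProjectedMontage":
        missing = [l for l in labels if l not in self.points]
        if missing:
            raise MontageError(f"labels not in projected montage: {missing}")
        return ProjectedMontage(name, {l: self.points[l] for l in labels})

    def __len__(self) -> int:
        return len(self.points)


def _parse_row(line: str, lineno: int) -> ElectrodePosition:
    parts = line.replace(",", " ").split()
    if len(parts) != 4:
        raise MontageError(
            f"line {lineno}: expected 'label x y z', got {line.rstrip()!r}"
        )
    label = parts[0]
    try:
        x, y, z = (float(v) for v in parts[1:])
    except ValueError as exc:
        raise MontageError(f"line {lineno}: non-numeric coordinate: {exc}") from None
    return ElectrodePosition(label, x, y, z)


def load_montage(path: Union[str, "io.TextIOBase"], name: str) -> ChannelSystem:
    """Read a montage file (``label x y z``, whitespace or comma delimited).

    Lines starting with ``#`` and blank lines are ignored.  Row order in the
    file becomes the canonical channel order.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    electrodes = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        electrodes.append(_parse_row(stripped, lineno))
    if not electrodes:
        raise MontageError("montage file contains no electrodes")
    return ChannelSystem(name, tuple(electrodes))


def write_montage(system: ChannelSystem, path: Union[str, "io.TextIOBase"]) -> None:
    """Write a montage in the same plain-text dialect ``load_montage`` reads."""
    out = io.StringIO()
    out.write(f"# montage: {system.name} ({len(system)} electrodes)\n")
    for e in system.electrodes:
        out.write(f"{e.label} {e.x:.6f} {e.y:.6f} {e.z:.6f}\n")
    text = out.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def project_to_2d(system: ChannelSystem) -> ProjectedMontage:
    """Azimuthal equidistant projection about the vertex (+z).

    Positions are unit-normalized first; the planar radius of an electrode is
    its polar angle from +z in radians and its planar azimuth equals its 3-D
    azimuth, so the vertex maps to the origin and angular distances from the
    vertex are preserved exactly.
    """
    points: Dict[str, np.ndarray] = {}
    for e in system.electrodes:
        pos = e.position
        norm = np.linalg.norm(pos)
        if norm < 1e-12:
            raise MontageError(f"electrode {e.label!r} has zero norm")
        ux, uy, uz = pos / norm
        polar = float(np.arccos(np.clip(uz, -1.0, 1.0)))
        azimuth = float(np.arctan2(uy, ux))
        points[e.label] = np.array(
            [polar * np.cos(azimuth), polar * np.sin(azimuth)], dtype=float
        )
    return ProjectedMontage(system.name, points)


def derive_subset(
    system: ChannelSystem, labels: Sequence[str], name: str
) -> ChannelSystem:
    """Channel system restricted to ``labels``, in the order given."""
    known = set(system.labels)
    unknown = [l for l in labels if l not in known]
    if unknown:
        raise MontageError(
            f"labels not in system {system.name!r}: {unknown}"
        )
    by_label = {e.label: e for e in system.electrodes}
    return ChannelSystem(name, tuple(by_label[l] for l in labels))
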