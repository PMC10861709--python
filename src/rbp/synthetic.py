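"""Synthetic montage families and labeled EEG-like recordings.

The generator emulates the study setting every other module is evaluated in:
a high-density base montage (129 channels by default) with nested
lower-resolution subsets (65 and 32), and per-subject multichannel
recordings with a known binary class structure — a spatially localized
band-limited oscillation whose amplitude differs between classes, on top of
1/f background noise plus white sensor noise.

Two properties matter for the evaluation design:

* the class effect is *spatially smooth* (Gaussian gain in projected
  distance from the effect center), so spherical spline interpolation is a
  fair competitor;
* every channel's noise is drawn from a stream keyed by (subject, channel
  label), so restricting a base recording to a subset system is *identical*
  to generating from the subset directly — the "same data, fewer channels"
  comparison is exact.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .channel_systems import ChannelSystem, ElectrodePosition, derive_subset, project_to_2d

__all__ = [
    "SyntheticDatasetSpec",
    "SyntheticDataset",
    "generate_montage_family",
    "generate_recordings",
    "generate_dataset",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Parameters of the class-conditional signal model.

    Defaults are the desk-scale study conditions: 200 balanced subjects,
    128 Hz, 2 s windows, montage family 129/65/32.  The full-scale setting
    (500 Hz, 10 s) is reachable through ``sampling_rate`` / ``duration``.
    The class effect is an 8-12 Hz oscillation centered on a posterior scalp
    location whose amplitude is ``amplitude_ratio`` times larger for class 1;
    ``amplitude_ratio = 1`` is the statistical null.
    """

    n_subjects: int = 200
    sampling_rate: float = 128.0
    duration: float = 2.0
    base_size: int = 129
    subset_sizes: Tuple[int, ...] = (65, 32)
    effect_center: Tuple[float, float] = (0.55, -0.95)  # projected plane
    effect_sigma: float = 0.6  # Gaussian gain width (radians on the plane)
    band: Tuple[float, float] = (8.0, 12.0)  # Hz
    amplitude_ratio: float = 3.0
    effect_amplitude: float = 0.25
    noise_exponent: float = 1.0  # 1/f^a background
    background_sd: float = 1.0
    white_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects % 2 != 0:
            raise ValueError("n_subjects must be even (balanced classes)")
        if self.amplitude_ratio < 1.0:
            raise ValueError("amplitude_ratio must be >= 1 (1 is the null)")
        if any(
            s2 >= s1
            for s1, s2 in zip((self.base_size,) + self.subset_sizes, self.subset_sizes)
        ):
            raise ValueError("subset sizes must be strictly decreasing")
        if self.duration < 2.0 / self.band[0]:
            raise ValueError(
                "window must cover at least two periods of the effect band"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the upper hemisphere (vertex at +z)."""
    i = np.arange(n)
    z = 1.0 - (i + 0.5) / n  # (0, 1): strictly above the equator plane
    r = np.sqrt(1.0 - z**2)
    phi = i * _GOLDEN_ANGLE
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _farthest_point_order(points: np.ndarray) -> List[int]:
    """Greedy max-min ordering; prefixes are quasi-uniform subsets."""
    n = len(points)
    start = int(np.argmax(points[:, 2]))  # nearest the vertex
    order = [start]
    dist = np.linalg.norm(points - points[start], axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(dist))
        order.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(points - points[nxt], axis=1))
    return order


def generate_montage_family(
    spec: SyntheticDatasetSpec,
) -> Dict[str, ChannelSystem]:
    """Base montage plus nested subsets, keyed ``synthetic<size>``.

    Subsets are prefixes of a farthest-point ordering of the base lattice,
    which preserves approximately uniform scalp coverage; labels are stable
    across subsets, so the subset systems are truly nested.
    """
    pts = _fibonacci_hemisphere(spec.base_size)
    electrodes = tuple(
        ElectrodePosition(f"E{i + 1:03d}", *pts[i]) for i in range(spec.base_size)
    )
    base = ChannelSystem(f"synthetic{spec.base_size}", electrodes)
    order = _farthest_point_order(pts)
    family = {base.name: base}
    for size in spec.subset_sizes:
        labels = [base.electrodes[i].label for i in sorted(order[:size])]
        family[f"synthetic{size}"] = derive_subset(base, labels, f"synthetic{size}")
    return family


def _channel_stream(seed: int, subject: int, label: str) -> np.random.Generator:
    key = zlib.crc32(label.encode())
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(subject, 0, key))
    )


def _subject_stream(seed: int, subject: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(subject, 1))
    )


def _one_over_f(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum = rng.normal(size=len(freqs)) + 1j * rng.normal(size=len(freqs))
    scale = np.zeros(len(freqs))
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * scale, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, band: Tuple[float, float]
) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum = rng.normal(size=len(freqs)) + 1j * rng.normal(size=len(freqs))
    mask = (freqs >= band[0]) & (freqs <= band[1])
    x = np.fft.irfft(spectrum * mask, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_recordings(
    spec: SyntheticDatasetSpec, montage: ChannelSystem
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Recordings for every subject on ``montage``.

    Returns ``(X, labels, subject_ids)`` with ``X`` of shape
    (n_subjects, len(montage), n_samples).  Fully seeded: channel streams are
    keyed by (subject, channel label) and the oscillation by subject alone,
    so generating on a subset montage reproduces exactly the corresponding
    rows of the base montage generation.
    """
    n, T = spec.n_subjects, spec.n_samples
    projected = project_to_2d(montage)
    center = np.asarray(spec.effect_center, dtype=float)
    dists = np.linalg.norm(projected.coords() - center, axis=1)
    gains = np.exp(-(dists**2) / (2.0 * spec.effect_sigma**2))

    # balanced labels, shuffled by a dataset-level stream
    labels = np.repeat([0, 1], n // 2)
    np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(2,))
    ).shuffle(labels)

    X = np.empty((n, len(montage), T))
    for s in range(n):
        osc = _band_noise(_subject_stream(spec.seed, s), T, spec.sampling_rate, spec.band)
        amp = spec.effect_amplitude * (
            spec.amplitude_ratio if labels[s] == 1 else 1.0
        )
        for c, e in enumerate(montage.electrodes):
            rng = _channel_stream(spec.seed, s, e.label)
            bg = spec.background_sd * _one_over_f(
                rng, T, spec.sampling_rate, spec.noise_exponent
            )
            white = rng.normal(0.0, spec.white_sd, size=T)
            X[s, c] = bg + white + amp * gains[c] * osc
    subject_ids = [f"sub-{s:04d}" for s in range(n)]
    return X, labels, subject_ids


@dataclass
class SyntheticDataset:
    """Generated study data: montage family + base recordings + labels."""

    spec: SyntheticDatasetSpec
    systems: Dict[str, ChannelSystem]
    X_base: np.ndarray  # (n_subjects, base_size, T)
    labels: np.ndarray
    subject_ids: List[str]

    @property
    def base_name(self) -> str:
        return f"synthetic{self.spec.base_size}"

    def system_names(self) -> List[str]:
        return [self.base_name] + [
            f"synthetic{s}" for s in self.spec.subset_sizes
        ]

    def recordings_for(self, system_name: str) -> np.ndarray:
        """Row-restrict the base recordings to a nested system (exact, by
        the per-channel seeding guarantee)."""
        base = self.systems[self.base_name]
        system = self.systems[system_name]
        idx = [base.index_of(l) for l in system.labels]
        return self.X_base[:, idx, :]

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": self.subject_ids, "label": self.labels})


def generate_dataset(spec: SyntheticDatasetSpec) -> SyntheticDataset:
    """Montage family + base-system recordings in one call."""
    systems = generate_montage_family(spec)
    base = systems[f"synthetic{spec.base_size}"]
    X, labels, subject_ids = generate_recordings(spec, base)
    return SyntheticDataset(spec, systems, X, labels, subject_ids)
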