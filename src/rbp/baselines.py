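"""Baselines for mapping recordings between channel systems.

Two standard approaches for presenting a low-density recording to a model
trained on a denser montage:

* **zero-filling** — copy shared channels into the target order and insert
  all-zero rows for absent channels;
* **spherical spline interpolation** (Perrin et al.) — estimate potentials
  at unmeasured scalp positions from measured electrodes with spline kernels
  on the unit sphere.  The kernel is

      g(x) = (1 / 4π) Σ_{n=1}^{N} (2n + 1) / (n^m (n + 1)^m) P_n(x),

  with ``P_n`` the Legendre polynomial, ``m`` the spline order and ``N`` the
  series truncation.  Because the spline system depends only on electrode
  geometry, the whole operation reduces to a precomputed linear map from
  source-channel values to target-channel values, applied per timestep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import eval_legendre

from .channel_systems import ChannelSystem

__all__ = [
    "InterpolationOperator",
    "zero_fill",
    "spline_g_kernel",
    "build_interpolator",
    "interpolate",
]


def zero_fill(
    X: np.ndarray, source: ChannelSystem, target: ChannelSystem
) -> np.ndarray:
    """Map (``|source|``, T) onto (``|target|``, T), zeroing missing rows."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] != len(source):
        raise ValueError(
            f"recording has {X.shape[0]} rows but source system has {len(source)}"
        )
    target_labels = target.labels
    missing = [l for l in source.labels if l not in set(target_labels)]
    if missing:
        raise ValueError(f"source channels absent from target system: {missing}")
    out = np.zeros((len(target), X.shape[1]), dtype=float)
    src_index = {label: i for i, label in enumerate(source.labels)}
    for t_idx, label in enumerate(target_labels):
        if label in src_index:
            out[t_idx] = X[src_index[label]]
    return out


def spline_g_kernel(x, m: int = 4, N: int = 50):
    """Spherical spline kernel g(x) for x = cos(angle between electrodes)."""
    if m < 2:
        raise ValueError("spline order m must be >= 2")
    if N < 1:
        raise ValueError("Legendre truncation N must be >= 1")
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1.0 + 1e-9):
        raise ValueError("kernel argument must lie in [-1, 1]")
    x = np.clip(x, -1.0, 1.0)
    n = np.arange(1, N + 1)
    coeff = (2 * n + 1) / (n**m * (n + 1.0) ** m)
    # eval_legendre broadcasts over outer-product of orders and arguments
    P = eval_legendre(n[:, None], x.ravel()[None, :])
    out = (coeff @ P) / (4.0 * np.pi)
    return out.reshape(x.shape) if x.shape else float(out[0])


@dataclass(frozen=True)
class InterpolationOperator:
    """Precomputed linear map from source channels to target channels."""

    source_name: str
    target_name: str
    m: int
    lam: float
    N: int
    matrix: np.ndarray  # (|target|, |source|)


def _unit_positions(system: ChannelSystem) -> np.ndarray:
    pos = system.positions()
    norms = np.linalg.norm(pos, axis=1, keepdims=True)
    return pos / norms


def build_interpolator(
    source: ChannelSystem,
    target: ChannelSystem,
    m: int = 4,
    lam: float = 1e-5,
    N: int = 50,
) -> InterpolationOperator:
    """Assemble the spherical-spline mapping matrix.

    Solves, for source values v:  (G_ss + λI) c + c0 1 = v  with  1^T c = 0,
    then evaluates  u = c0 + G_ts c  at the target electrodes; both steps
    fold into one matrix.  Defaults m=4, N=50 truncation, λ=1e-5 are the
    customary stabilized choices for scalp potentials.
    """
    ns = len(source)
    if ns < 4:
        raise ValueError(
            f"spline interpolation needs >= 4 source electrodes, got {ns}"
        )
    src = _unit_positions(source)
    tgt = _unit_positions(target)
    cos_ss = np.clip(src @ src.T, -1.0, 1.0)
    cos_ts = np.clip(tgt @ src.T, -1.0, 1.0)
    G_ss = spline_g_kernel(cos_ss, m=m, N=N)
    G_ts = spline_g_kernel(cos_ts, m=m, N=N)

    # bordered system [[G+λI, 1], [1^T, 0]] @ [c; c0] = [v; 0]
    M = np.zeros((ns + 1, ns + 1))
    M[:ns, :ns] = G_ss + lam * np.eye(ns)
    M[:ns, ns] = 1.0
    M[ns, :ns] = 1.0
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e14:
        raise np.linalg.LinAlgError(
            f"spline system is numerically singular (condition number {cond:.3g})"
        )
    # columns of B give [c; c0] per unit source value
    B = np.linalg.solve(M, np.vstack([np.eye(ns), np.zeros((1, ns))]))
    mapping = G_ts @ B[:ns, :] + B[ns, :][None, :]
    return InterpolationOperator(
        source.name, target.name, m, float(lam), N, mapping
    )


def interpolate(X: np.ndarray, op: InterpolationOperator) -> np.ndarray:
    """Apply the mapping matrix per timestep: (|source|, T) -> (|target|, T)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != op.matrix.shape[1]:
        raise ValueError(
            f"recording shape {X.shape} does not match operator with "
            f"{op.matrix.shape[1]} source channels"
        )
    return op.matrix @ X
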