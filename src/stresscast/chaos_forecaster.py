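"""Analog (nearest-neighbor) forecasting on the reconstructed phase space.

The dynamics are treated as a continuous map F on the embedded trajectory:
if X_j is close to the last vector X_N, then F(X_j) is close to F(X_N), so
the successor values of the q nearest neighbors of X_N, combined with
Gaussian kernel weights, approximate the next observation.  Applied
recursively this yields an m-day range forecast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import PredictionError
from .lyapunov import ChaosProfile
from .phase_space import reconstruct
from .sequence_io import ForecastResult, LabelScheme, StressSequence

__all__ = [
    "NeighborSet",
    "kernel_weights",
    "find_neighbors",
    "predict_next_chaos",
    "forecast_range_chaos",
]


@dataclass(frozen=True)
class NeighborSet:
    """The q nearest phase-space neighbors of the trajectory's last vector."""

    target_index: int
    neighbors: np.ndarray  # indices into the phase space, successors exist
    weights: np.ndarray  # kernel weights, non-negative, sum to 1


def kernel_weights(distances: Sequence[float]) -> np.ndarray:
    """Gaussian kernel weights: softmax of -||distance||^2 / 2.

    w_j = exp(-d_j^2/2) / sum_q exp(-d_q^2/2); computed with the max-shift
    softmax identity for numerical stability.
    """
    d2 = -0.5 * np.asarray(distances, dtype=float) ** 2
    d2 -= d2.max()
    w = np.exp(d2)
    return w / w.sum()


def find_neighbors(ps, q: int) -> NeighborSet:
    """q nearest predecessors of the last phase-space vector.

    Candidates are restricted to vectors with an in-sample successor value,
    i.e. indices j < N-1 (0-based).  Ties in distance break to the smaller
    index via a stable sort.
    """
    N = ps.N
    target = N - 1
    if N - 1 < 1:
        raise PredictionError("no candidate neighbor has a successor")
    q = min(q, N - 1)
    cand = np.arange(N - 1)
    dists = np.linalg.norm(ps.vectors[cand] - ps.vectors[target], axis=1)
    order = np.argsort(dists, kind="stable")[:q]
    chosen = cand[order]
    return NeighborSet(
        target_index=target,
        neighbors=chosen,
        weights=kernel_weights(dists[order]),
    )


def predict_next_chaos(ps, q: int = 3) -> tuple[float, int]:
    """Kernel-weighted average of neighbor successors; also a rounded level.

    Returns ``(continuous estimate, level)`` where the level is the estimate
    rounded half-up and clipped to the valid raw range 1..5.
    """
    ns = find_neighbors(ps, q)
    succ = np.array([ps.successor_value(int(j)) for j in ns.neighbors])
    s_hat = float(np.dot(ns.weights, succ))
    level = int(np.clip(np.floor(s_hat + 0.5), 1, 5))
    return s_hat, level


def forecast_range_chaos(
    seq: StressSequence,
    profile: ChaosProfile,
    m: int,
    q: int = 3,
    scheme: LabelScheme | None = None,
) -> ForecastResult:
    """Recursive m-step analog forecast with fixed embedding (tau, d).

    Each rounded prediction is appended to the sequence, the trajectory is
    re-embedded, and the next step predicted, m times.  When a label scheme
    is given, the per-day class is the scheme's class of the predicted level
    and the probability mass sits entirely on that class.
    """
    if m < 1:
        raise PredictionError("horizon m must be >= 1")
    levels = list(seq.levels)
    classes: list[int] = []
    out_levels: list[int] = []
    for _ in range(m):
        ps = reconstruct(np.asarray(levels, dtype=float), profile.tau, profile.d)
        _, level = predict_next_chaos(ps, q)
        levels.append(level)
        out_levels.append(level)
        classes.append(scheme.class_of(level) if scheme else level)
    k = scheme.num_class if scheme else 6
    probs = np.zeros((m, k))
    probs[np.arange(m), classes] = 1.0
    return ForecastResult(
        user_id=seq.user_id,
        classes=classes,
        probabilities=probs,
        levels=out_levels,
        method="chaos",
    )
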