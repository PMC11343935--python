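"""Largest Lyapunov exponent and the predictable time range.

Nearby phase-space trajectories of a chaotic system separate exponentially;
the mean log separation D(q) of each vector from its nearest neighbor, q
steps downstream, grows linearly with slope equal to the largest Lyapunov
exponent l_max until the separation saturates at the attractor diameter.
A positive l_max marks chaos, and its reciprocal bounds the horizon over
which forecasts remain meaningful: m = floor(1/l_max) days.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EstimationError, InsufficientDataError
from .phase_space import (
    PhaseSpace,
    all_nearest_neighbors,
    delay_scan,
    reconstruct,
    select_dimension,
)
from .sequence_io import StressSequence

__all__ = [
    "DivergenceCurve",
    "ChaosProfile",
    "divergence_curve",
    "largest_lyapunov",
    "predictable_range",
    "chaos_profile",
    "horizon_vs_length",
]


@dataclass(frozen=True)
class DivergenceCurve:
    qs: np.ndarray  # 0..q_max
    D_values: np.ndarray  # mean log separation at each q
    n_pairs: int  # pairs retained at every q
    n_excluded: int  # pairs dropped for a zero separation at some q
    fit_range: tuple[int, int] | None = None  # (q_lo, q_hi) used for the slope


@dataclass(frozen=True)
class ChaosProfile:
    """Summary of one sequence's dynamics: embedding, exponent, horizon."""

    tau: int
    d: int
    l_max: float
    m: int | None  # predictable range in days; None when not chaotic

    @property
    def is_chaotic(self) -> bool:
        return self.l_max > 0


def divergence_curve(
    ps: PhaseSpace, q_max: int, exclusion: int = 1
) -> DivergenceCurve:
    """Mean log nearest-neighbor separation D(q) for q = 0..q_max.

    D(q) = (1/N') sum_k ln ||X_{n(k,d)+q} - X_{k+q}|| over the N' indices k
    whose own and neighbor trajectories both remain inside the embedding for
    every q <= q_max.  Pairs with an exactly zero separation at any q are
    excluded (their count is reported); discrete-valued series make such ties
    common.
    """
    if q_max < 1:
        raise InsufficientDataError("q_max must be >= 1")
    N = ps.N
    limit = N - q_max  # both k and its neighbor must stay <= N-1 after q steps
    if limit < 2:
        raise InsufficientDataError(
            f"q_max={q_max} leaves fewer than 2 usable vectors (N={N})"
        )
    nbrs = all_nearest_neighbors(
        ps.vectors[:limit], exclusion=exclusion, candidate_limit=limit
    )
    ks = np.arange(limit)
    qs = np.arange(q_max + 1)
    # separations: (limit, q_max+1)
    sep = np.linalg.norm(
        ps.vectors[ks[:, None] + qs[None, :]]
        - ps.vectors[nbrs[:, None] + qs[None, :]],
        axis=2,
    )
    keep = (sep > 0).all(axis=1)
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise EstimationError("every neighbor pair degenerates to zero separation")
    D = np.log(sep[keep]).mean(axis=0)
    return DivergenceCurve(
        qs=qs, D_values=D, n_pairs=int(keep.sum()), n_excluded=n_excluded
    )


def _linear_fit(qs: np.ndarray, D: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and R^2 of D against q."""
    slope, intercept = np.polyfit(qs, D, 1)
    pred = slope * qs + intercept
    ss_res = float(np.sum((D - pred) ** 2))
    ss_tot = float(np.sum((D - D.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), r2


def largest_lyapunov(
    curve: DivergenceCurve,
    fit_range: tuple[int, int] | None = None,
    r2_threshold: float = 0.95,
) -> float:
    """Slope of the divergence curve over its initial linear segment.

    With no explicit ``fit_range``, the fit window is the longest initial
    segment (at least 3 points) whose least-squares fit keeps R^2 at or above
    ``r2_threshold`` — a reproducible stand-in for "fit before the plateau".
    A flat curve (zero variance) has slope 0 by convention.
    """
    qs, D = curve.qs, curve.D_values
    if fit_range is not None:
        lo, hi = fit_range
        sel = (qs >= lo) & (qs <= hi)
        if sel.sum() < 2:
            raise EstimationError(f"fit range {fit_range} holds fewer than 2 points")
        slope, _ = _linear_fit(qs[sel], D[sel])
        return slope
    if len(qs) < 3:
        raise EstimationError("need at least 3 points to auto-select a fit range")
    if np.allclose(D, D[0]):
        return 0.0
    best = None
    for hi in range(2, len(qs)):
        slope, r2 = _linear_fit(qs[: hi + 1], D[: hi + 1])
        if r2 >= r2_threshold:
            best = slope
        elif best is not None:
            break
    if best is None:
        warnings.warn(
            "no initial segment reaches the R^2 threshold; "
            "using the first 3 points",
            stacklevel=2,
        )
        best, _ = _linear_fit(qs[:3], D[:3])
    return best


def predictable_range(l_max: float) -> tuple[int | None, bool]:
    """Horizon m = floor(1/l_max) days (minimum 1) when l_max > 0.

    A non-positive exponent means trajectories do not diverge: the sequence
    is not chaotic and the horizon is unbounded (returned as None).
    Returns ``(m, is_chaotic)``.
    """
    if l_max > 0:
        return max(1, math.floor(1.0 / l_max)), True
    return None, False


def chaos_profile(
    seq: "StressSequence | Sequence[float]",
    tau: int | None = None,
    d: int | None = None,
    tau_max: int = 10,
    d_max: int = 10,
    q_max: int = 15,
    ev_eps: float = 0.05,
    exclusion: int = 1,
    r2_threshold: float = 0.95,
    fit_range: tuple[int, int] | None = None,
    bins: int | None = None,
) -> ChaosProfile:
    """Full pipeline: delay, dimension, exponent, horizon for one sequence.

    ``tau`` / ``d`` may be pinned; otherwise they are selected by the
    mutual-information and EV-saturation criteria.  ``q_max`` is clipped to
    what the embedded trajectory can support.
    """
    x = np.asarray(seq.values() if isinstance(seq, StressSequence) else seq, float)
    n = len(x)
    if n >= 2 and np.ptp(x) == 0:
        # fixed-point dynamics: trajectories never separate
        return ChaosProfile(tau=1, d=1, l_max=0.0, m=None)
    if tau is None:
        tau = delay_scan(x, min(tau_max, n - 2), bins=bins).selected_tau
    if d is None:
        d_cap = max(2, min(d_max, (n - 4) // max(tau, 1)))
        d, _ = select_dimension(x, tau, d_max=d_cap, eps=ev_eps, exclusion=exclusion)
    ps = reconstruct(x, tau, d)
    # leave enough vectors that every index keeps a candidate under the
    # Theiler window: pool size >= 2*exclusion + 2
    q_eff = min(q_max, ps.N - (2 * exclusion + 2))
    if q_eff < 2:
        raise InsufficientDataError("trajectory too short for a divergence curve")
    curve = divergence_curve(ps, q_eff, exclusion=exclusion)
    l_max = largest_lyapunov(curve, fit_range=fit_range, r2_threshold=r2_threshold)
    m, _ = predictable_range(l_max)
    return ChaosProfile(tau=int(tau), d=int(d), l_max=float(l_max), m=m)


def horizon_vs_length(
    seq: "StressSequence | Sequence[float]",
    lengths: Sequence[int],
    **profile_kwargs,
) -> list[dict]:
    """Run the full pipeline on each prefix length; report m per length.

    The returned records carry ``length``, ``m``, ``l_max`` and a
    ``saturation_length`` entry (on the last record) giving the first length
    after which m stops increasing.  Prefixes where the estimate fails are
    reported with m = None.
    """
    x = np.asarray(seq.values() if isinstance(seq, StressSequence) else seq, float)
    records: list[dict] = []
    for L in lengths:
        if L > len(x):
            raise InsufficientDataError(f"prefix length {L} exceeds n={len(x)}")
        try:
            prof = chaos_profile(x[:L], **profile_kwargs)
            records.append({"length": int(L), "m": prof.m, "l_max": prof.l_max})
        except (InsufficientDataError, EstimationError) as exc:
            records.append({"length": int(L), "m": None, "error": str(exc)})
    sat = None
    ms = [r["m"] for r in records]
    for i in range(len(ms)):
        tail = [m for m in ms[i:] if m is not None]
        if ms[i] is not None and tail and all(m <= ms[i] for m in tail):
            sat = records[i]["length"]
            break
    if records:
        records[-1]["saturation_length"] = sat
    return records
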