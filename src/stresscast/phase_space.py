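"""Phase-space reconstruction of a scalar series by delay embedding.

The time delay tau is chosen at the first local minimum of the lagged mutual
information; the embedding dimension d is chosen where the mean
nearest-neighbor distance-ratio statistic E(d) saturates, i.e. where the
variation EV(d) = E(d+1)/E(d) stops changing (false nearest neighbors have
disappeared).  Both criteria operate on a single observed series, as Takens'
theorem permits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import EstimationError, InsufficientDataError, SearchError
from .sequence_io import StressSequence

__all__ = [
    "PhaseSpace",
    "DelayScan",
    "DimensionScan",
    "mutual_information",
    "select_time_delay",
    "reconstruct",
    "nearest_neighbor",
    "all_nearest_neighbors",
    "dimension_scan",
    "select_embedding_dimension",
]


def _as_series(seq: "StressSequence | Sequence[float] | np.ndarray") -> np.ndarray:
    if isinstance(seq, StressSequence):
        return seq.values()
    return np.asarray(seq, dtype=float)


@dataclass(frozen=True)
class PhaseSpace:
    """Delay-embedded trajectory: N = n-(d-1)*tau vectors of dimension d.

    Vector k (0-based) is ``(s_k, s_{k+tau}, ..., s_{k+(d-1)tau})``.
    """

    tau: int
    d: int
    vectors: np.ndarray  # (N, d)
    source: np.ndarray  # the scalar series, length n

    @property
    def N(self) -> int:
        return self.vectors.shape[0]

    @property
    def n(self) -> int:
        return self.source.shape[0]

    def successor_value(self, j: int) -> float:
        """s_{j + (d-1)tau + 1}: the scalar following vector j's last entry."""
        idx = j + (self.d - 1) * self.tau + 1
        if idx >= self.n:
            raise IndexError(f"vector {j} has no successor value")
        return float(self.source[idx])


@dataclass(frozen=True)
class DelayScan:
    taus: np.ndarray
    M_values: np.ndarray  # mutual information in bits, one per tau
    selected_tau: int
    is_fallback: bool = False


@dataclass(frozen=True)
class DimensionScan:
    ds: np.ndarray
    E_values: np.ndarray
    EV_values: np.ndarray  # EV(d) = E(d+1)/E(d); last entry is NaN
    selected_d: int = 0
    is_fallback: bool = False


# ---------------------------------------------------------------------------
# time delay
# ---------------------------------------------------------------------------


def _discretize_for_mi(x: np.ndarray, bins: int | None) -> np.ndarray:
    """Map the series onto integer symbols for plug-in probabilities.

    Discrete integer series are used as-is; continuous series fall back to a
    fixed-width histogram (default 16 bins).
    """
    if bins is None:
        if np.allclose(x, np.round(x)):
            return np.round(x).astype(int)
        bins = 16
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return np.zeros(len(x), dtype=int)
    edges = np.linspace(lo, hi, bins + 1)
    return np.clip(np.searchsorted(edges, x, side="right") - 1, 0, bins - 1)


def mutual_information(
    seq: "StressSequence | Sequence[float]", tau: int, bins: int | None = None
) -> float:
    """Mutual information (bits) between the series and its tau-lagged copy.

    Probabilities are empirical (plug-in) frequencies over the symbol
    alphabet: M = H(A) + H(B) - H(A,B) where A = (s_1..s_{n-tau}) and
    B = (s_{1+tau}..s_n).
    """
    x = _as_series(seq)
    n = len(x)
    if not 1 <= tau < n:
        raise InsufficientDataError(f"need 1 <= tau < n, got tau={tau}, n={n}")
    sym = _discretize_for_mi(x, bins)
    a, b = sym[: n - tau], sym[tau:]
    k = int(sym.max()) + 1
    joint = np.zeros((k, k))
    np.add.at(joint, (a, b), 1.0)
    joint /= joint.sum()
    pa, pb = joint.sum(axis=1), joint.sum(axis=0)

    def _ent(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    return max(0.0, _ent(pa) + _ent(pb) - _ent(joint.ravel()))


def first_local_minimum(M_values: Sequence[float], m0: float = np.inf) -> int | None:
    """1-based position of the first interior local minimum of a curve.

    Position t qualifies when M(t-1) > M(t) < M(t+1); ``m0`` stands in for
    M(0) (for a mutual-information curve, the unlagged self-information, an
    upper bound on every lagged value).  Returns None when no interior
    minimum exists.
    """
    M = np.asarray(M_values, dtype=float)
    m_prev = m0
    for i in range(len(M) - 1):
        if m_prev > M[i] < M[i + 1]:
            return i + 1
        m_prev = M[i]
    return None


def delay_scan(
    seq: "StressSequence | Sequence[float]",
    tau_max: int,
    bins: int | None = None,
) -> DelayScan:
    """Scan tau = 1..tau_max; select the first local minimum of M(tau)."""
    x = _as_series(seq)
    n = len(x)
    if tau_max >= n:
        raise InsufficientDataError(f"tau_max={tau_max} must be < n={n}")
    if tau_max < 1:
        raise InsufficientDataError("tau_max must be >= 1")
    taus = np.arange(1, tau_max + 1)
    M = np.array([mutual_information(x, int(t), bins) for t in taus])
    pos = first_local_minimum(M, m0=_self_information(x, bins))
    if pos is not None:
        return DelayScan(taus, M, int(taus[pos - 1]))
    tau = int(taus[np.argmin(M)])
    warnings.warn(
        "mutual information has no interior local minimum; "
        f"falling back to argmin tau={tau}",
        stacklevel=2,
    )
    return DelayScan(taus, M, tau, is_fallback=True)


def _self_information(x: np.ndarray, bins: int | None) -> float:
    sym = _discretize_for_mi(x, bins)
    _, counts = np.unique(sym, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def select_time_delay(
    seq: "StressSequence | Sequence[float]", tau_max: int, bins: int | None = None
) -> int:
    return delay_scan(seq, tau_max, bins).selected_tau


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------


def reconstruct(
    seq: "StressSequence | Sequence[float]", tau: int, d: int
) -> PhaseSpace:
    """Delay-embed the series into N = n-(d-1)*tau vectors of dimension d."""
    x = _as_series(seq)
    n = len(x)
    if tau < 1 or d < 1:
        raise InsufficientDataError("tau and d must be positive")
    N = n - (d - 1) * tau
    if N < 2:
        raise InsufficientDataError(
            f"series of length {n} leaves N={N} < 2 vectors for tau={tau}, d={d}"
        )
    idx = np.arange(N)[:, None] + tau * np.arange(d)[None, :]
    return PhaseSpace(tau=int(tau), d=int(d), vectors=x[idx], source=x)


def nearest_neighbor(ps: PhaseSpace, k: int, exclusion: int = 1) -> int:
    """Index of the nearest neighbor of vector k under a Theiler window.

    Candidates j must satisfy |j-k| > exclusion; ties break to the smaller
    index.
    """
    V = ps.vectors
    if ps.N < 2:
        raise SearchError("need at least 2 vectors")
    dist = np.linalg.norm(V - V[k], axis=1)
    dist[np.abs(np.arange(ps.N) - k) <= exclusion] = np.inf
    j = int(np.argmin(dist))  # argmin takes the first (smallest) index on ties
    if not np.isfinite(dist[j]):
        raise SearchError(f"Theiler window {exclusion} excludes all candidates of {k}")
    return j


def all_nearest_neighbors(
    vectors: np.ndarray,
    exclusion: int = 1,
    candidate_limit: int | None = None,
    dist_floor: float = 0.0,
) -> np.ndarray:
    """Nearest neighbor of every vector under the Theiler window.

    Uses a k-d tree, widening the query until a candidate outside the
    exclusion window is found.  When ``candidate_limit`` restricts the
    neighbor pool to the first L vectors (needed when neighbors must have
    successors), queries run against that subset.

    Candidates at distance <= ``dist_floor`` (exact duplicates, common in
    discrete-valued series) are used only when no farther candidate exists:
    a duplicate point carries no information about local expansion.
    """
    V = np.asarray(vectors, dtype=float)
    N = V.shape[0]
    pool = V if candidate_limit is None else V[:candidate_limit]
    L = pool.shape[0]
    if L < 1:
        raise SearchError("empty candidate pool")
    tree = cKDTree(pool)
    out = np.full(N, -1, dtype=int)
    k = min(L, 2 * exclusion + 2)
    pending = np.arange(N)
    while pending.size:
        dists, idxs = tree.query(V[pending], k=k)
        if k == 1:
            dists, idxs = dists[:, None], idxs[:, None]
        still = []
        for row, i in enumerate(pending):
            admissible = np.abs(idxs[row] - i) > exclusion
            ok = admissible & (dists[row] > dist_floor)
            if not ok.any() and k >= L:
                ok = admissible  # only duplicates remain: accept them
            if ok.any():
                # k-d tree returns candidates sorted by distance; among exact
                # distance ties prefer the smaller index
                cand = idxs[row][ok]
                dcand = dists[row][ok]
                out[i] = int(cand[dcand <= dcand[0]].min())
            else:
                still.append(i)
        pending = np.array(still, dtype=int)
        if pending.size:
            if k >= L:
                raise SearchError(
                    f"Theiler window {exclusion} excludes all candidates for "
                    f"{pending.size} vector(s)"
                )
            k = min(L, 2 * k)
    return out


def dimension_scan(
    seq: "StressSequence | Sequence[float]",
    tau: int,
    d_max: int,
    exclusion: int = 1,
    eps_floor: float = 1e-12,
) -> DimensionScan:
    """E(d) and EV(d) = E(d+1)/E(d) for d = 1..d_max.

    For each d the nearest neighbor n(k,d) is found in the d-dimensional
    embedding; r(k,d) is the ratio of the pair's distance in d+1 dimensions to
    its distance in d dimensions (the same neighbor is kept, not re-searched).
    The average runs over the indices k that exist in both embeddings.  Pairs
    whose d-dimensional distance falls below ``eps_floor`` are skipped:
    discrete series produce exact ties that would otherwise divide by zero.
    """
    x = _as_series(seq)
    n = len(x)
    if d_max < 2:
        raise InsufficientDataError("d_max must be >= 2")
    if n - d_max * tau < 2:
        raise InsufficientDataError(
            f"series of length {n} too short for d_max={d_max}, tau={tau}"
        )
    ds = np.arange(1, d_max + 1)
    E = np.full(d_max, np.nan)
    for di, d in enumerate(ds):
        ps_lo = reconstruct(x, tau, int(d))
        ps_hi = reconstruct(x, tau, int(d) + 1)
        N_hi = ps_hi.N
        # neighbors searched in dimension d, among vectors that also exist at d+1
        nbrs = all_nearest_neighbors(
            ps_lo.vectors[:N_hi], exclusion=exclusion, candidate_limit=N_hi
        )
        ks = np.arange(N_hi)
        lo = np.linalg.norm(ps_lo.vectors[ks] - ps_lo.vectors[nbrs], axis=1)
        hi = np.linalg.norm(ps_hi.vectors[ks] - ps_hi.vectors[nbrs], axis=1)
        keep = lo > eps_floor
        if not keep.any():
            raise EstimationError(
                f"all neighbor pairs degenerate (zero distance) at d={d}"
            )
        E[di] = float(np.mean(hi[keep] / lo[keep]))
    EV = np.full(d_max, np.nan)
    EV[:-1] = E[1:] / E[:-1]
    return DimensionScan(ds=ds, E_values=E, EV_values=EV)


def select_embedding_dimension(scan: DimensionScan, eps: float = 0.05) -> int:
    """Smallest d whose EV(d) and EV(d+1) both sit within eps of 1.

    Saturation of EV at 1 marks the disappearance of false nearest neighbors;
    requiring two consecutive saturated values guards against single-point
    flukes.  Falls back to d_max with a warning when nothing saturates (the
    signature of a stochastic series).
    """
    ev = scan.EV_values
    ok = np.abs(ev - 1.0) <= eps
    for i in range(len(ev) - 1):
        if ok[i] and ok[i + 1]:
            return int(scan.ds[i])
    d_max = int(scan.ds[-1])
    warnings.warn(
        f"EV(d) does not saturate by d={d_max}; series may be stochastic",
        stacklevel=2,
    )
    return d_max


def select_dimension(
    seq: "StressSequence | Sequence[float]",
    tau: int,
    d_max: int = 10,
    eps: float = 0.05,
    exclusion: int = 1,
) -> tuple[int, DimensionScan]:
    scan = dimension_scan(seq, tau, d_max, exclusion=exclusion)
    d0 = select_embedding_dimension(scan, eps)
    return d0, DimensionScan(
        ds=scan.ds,
        E_values=scan.E_values,
        EV_values=scan.EV_values,
        selected_d=d0,
        is_fallback=(d0 == scan.ds[-1] and not _saturated(scan, eps)),
    )


def _saturated(scan: DimensionScan, eps: float) -> bool:
    ev = scan.EV_values
    ok = np.abs(ev - 1.0) <= eps
    return any(ok[i] and ok[i + 1] for i in range(len(ev) - 1))
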