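"""Transition path theory on discrete Markov chains.

Committors are obtained by a direct linear solve of the discrete
boundary-value problem; reactive flux, net flux, max-bottleneck pathway
decomposition, macro-state flux aggregation, transition-state selection by
committor window, mean first passage times, Markov chain Monte Carlo
trajectory synthesis, and the MFPT-based nucleation-rate estimate
J = 1/(MFPT * V) build on top.
"""

from __future__ import annotations

import heapq
import warnings
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .errors import EstimationError

__all__ = [
    "TPTResult",
    "KineticSummary",
    "committors",
    "reactive_flux",
    "decompose_pathways",
    "macro_flux",
    "transition_state_microstates",
    "mfpt",
    "sample_chain",
    "nucleation_rate",
    "analyze",
]


@dataclass
class TPTResult:
    """Committors, reactive fluxes and ranked pathways for one A -> B study."""

    A: np.ndarray
    B: np.ndarray
    q_plus: np.ndarray
    q_minus: np.ndarray
    flux: np.ndarray
    net_flux: np.ndarray
    total_flux: float
    pathways: list[tuple[list[int], float]] = field(default_factory=list)
    macro_net_flux: Optional[np.ndarray] = None


@dataclass
class KineticSummary:
    """Macro-pair MFPT matrix (physical time) and the nucleation rate."""

    mfpt_matrix: np.ndarray
    rate: float
    volume: float


def _validate_sets(n: int, A, B) -> tuple[np.ndarray, np.ndarray]:
    A = np.unique(np.asarray(list(A), dtype=int))
    B = np.unique(np.asarray(list(B), dtype=int))
    if A.size == 0 or B.size == 0:
        raise ValueError("source and sink sets must be non-empty")
    if np.intersect1d(A, B).size:
        raise ValueError("source and sink sets must be disjoint")
    if A.max() >= n or B.max() >= n or A.min() < 0 or B.min() < 0:
        raise ValueError("state index out of range")
    return A, B


def committors(
    T: np.ndarray, A: Sequence[int], B: Sequence[int],
    pi: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward and backward committors of the chain ``T`` between A and B.

    q_plus solves q(i) = sum_j T_ij q(j) on intermediate states with
    q|A = 0, q|B = 1 (sparse direct solve).  q_minus is the forward
    committor of the time-reversed chain with the roles of A and B swapped;
    for a reversible chain q_minus = 1 - q_plus.
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    A, B = _validate_sets(n, A, B)
    q_plus = _forward_committor(T, A, B)
    if pi is None:
        from .msm import _stationary

        pi = _stationary(T)
    with np.errstate(invalid="ignore", divide="ignore"):
        T_rev = (pi[None, :] * T.T) / pi[:, None]
    q_minus = _forward_committor(T_rev, B, A)
    return q_plus, q_minus


def _forward_committor(T: np.ndarray, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    n = T.shape[0]
    q = np.zeros(n)
    q[B] = 1.0
    inter = np.setdiff1d(np.arange(n), np.concatenate([A, B]))
    if inter.size:
        M = sp.csc_matrix(np.eye(inter.size) - T[np.ix_(inter, inter)])
        rhs = T[np.ix_(inter, B)].sum(axis=1)
        try:
            q[inter] = spsolve(M, rhs)
        except Exception as exc:
            raise EstimationError(
                f"singular committor system on states {inter.tolist()}: {exc}"
            ) from exc
        if not np.all(np.isfinite(q)):
            bad = inter[~np.isfinite(q[inter])]
            raise EstimationError(f"committor solve produced non-finite values at {bad.tolist()}")
    return np.clip(q, 0.0, 1.0)


def reactive_flux(
    T: np.ndarray,
    pi: np.ndarray,
    q_plus: np.ndarray,
    q_minus: np.ndarray,
    A: Sequence[int],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Gross and net reactive flux matrices and the total A -> B flux.

    flux_ij = pi_i q_minus(i) T_ij q_plus(j) for i != j;
    net_ij = max(0, flux_ij - flux_ji); the net flux is divergence-free at
    every intermediate state.  Total flux is the gross flux out of A.
    """
    T = np.asarray(T, dtype=float)
    A = np.unique(np.asarray(list(A), dtype=int))
    flux = (pi * q_minus)[:, None] * T * q_plus[None, :]
    np.fill_diagonal(flux, 0.0)
    net = np.clip(flux - flux.T, 0.0, None)
    notA = np.setdiff1d(np.arange(T.shape[0]), A)
    total = float(flux[np.ix_(A, notA)].sum())
    return flux, net, total


def _widest_path(net: np.ndarray, A: np.ndarray, B: np.ndarray):
    """Max-bottleneck path from the set A to the set B on the net-flux graph."""
    n = net.shape[0]
    width = np.full(n, -np.inf)
    prev = np.full(n, -1)
    heap = []
    for a in A:
        width[a] = np.inf
        heapq.heappush(heap, (-width[a], int(a)))
    Bset = set(int(b) for b in B)
    visited = np.zeros(n, dtype=bool)
    while heap:
        negw, u = heapq.heappop(heap)
        if visited[u]:
            continue
        visited[u] = True
        if u in Bset:
            path = [u]
            while prev[path[-1]] >= 0:
                path.append(int(prev[path[-1]]))
            return path[::-1], float(width[u])
        for v in np.flatnonzero(net[u] > 0):
            w = min(width[u], net[u, v])
            if w > width[v]:
                width[v] = w
                prev[v] = u
                heapq.heappush(heap, (-w, int(v)))
    return None, 0.0


def decompose_pathways(
    net_flux: np.ndarray,
    A: Sequence[int],
    B: Sequence[int],
    min_fraction: float = 0.0,
) -> list[tuple[list[int], float]]:
    """Iterative max-bottleneck decomposition of the net flux into pathways.

    Repeatedly extracts the widest A -> B path, subtracts its bottleneck
    flux along the path and records ``(path, flux)``; stops when the
    remaining flux fraction drops below ``min_fraction`` or the graph
    disconnects.  With ``min_fraction=0`` the pathway fluxes sum to the
    total flux.
    """
    net = np.array(net_flux, dtype=float, copy=True)
    A = np.unique(np.asarray(list(A), dtype=int))
    B = np.unique(np.asarray(list(B), dtype=int))
    total = net[A, :].sum() - net[:, A].sum()
    if total <= 0:
        warnings.warn("no A->B flux to decompose", stacklevel=2)
        return []
    pathways: list[tuple[list[int], float]] = []
    remaining = total
    while remaining > max(min_fraction * total, 1e-300):
        path, bott = _widest_path(net, A, B)
        if path is None or bott <= 0:
            if remaining > 1e-12 * total:
                warnings.warn("net-flux graph disconnected before full decomposition",
                              stacklevel=2)
            break
        for u, v in zip(path[:-1], path[1:]):
            net[u, v] -= bott
        pathways.append((path, bott))
        remaining -= bott
    pathways.sort(key=lambda pf: -pf[1])
    return pathways


def macro_flux(net_flux: np.ndarray, crisp: Sequence[int]) -> np.ndarray:
    """Aggregate a microstate net flux onto macro-states.

    F_AB = sum_{i in A, j in B} net_ij, then the macro-level net part
    max(0, F_AB - F_BA) with a zero diagonal.
    """
    crisp = np.asarray(crisp, dtype=int)
    m = int(crisp.max()) + 1
    M = np.zeros((len(crisp), m))
    M[np.arange(len(crisp)), crisp] = 1.0
    F = M.T @ np.asarray(net_flux, dtype=float) @ M
    np.fill_diagonal(F, 0.0)
    return np.clip(F - F.T, 0.0, None)


def transition_state_microstates(
    q_plus: np.ndarray, window: tuple[float, float] = (0.45, 0.55)
) -> np.ndarray:
    """Microstates with committor inside ``window`` (the isocommittor TS)."""
    lo, hi = window
    out = np.flatnonzero((q_plus >= lo) & (q_plus <= hi))
    if out.size == 0:
        warnings.warn("no microstates inside the committor window", stacklevel=2)
    return out


def mfpt(
    T: np.ndarray, targets: Sequence[int], lag_time: float = 1.0
) -> np.ndarray:
    """Mean first passage time to ``targets`` from every state.

    Solves (I - T_restricted) m = lag_time on non-target states; target
    states have MFPT 0.  The result is in the unit of ``lag_time``.
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    targets = np.unique(np.asarray(list(targets), dtype=int))
    if targets.size == 0:
        raise ValueError("targets must be non-empty")
    rest = np.setdiff1d(np.arange(n), targets)
    m = np.zeros(n)
    if rest.size:
        M = np.eye(rest.size) - T[np.ix_(rest, rest)]
        try:
            m[rest] = np.linalg.solve(M, np.full(rest.size, lag_time))
        except np.linalg.LinAlgError as exc:
            raise EstimationError(f"MFPT system singular: {exc}") from exc
    return m


def sample_chain(
    T: np.ndarray,
    n_steps: int,
    n_traj: int = 1,
    seed: int = 0,
    start_distribution: Optional[np.ndarray] = None,
) -> list[np.ndarray]:
    """Markov chain Monte Carlo trajectories from the transition matrix.

    Categorical sampling per step, reproducible under a fixed seed.  The
    start state of each trajectory is drawn from ``start_distribution``
    (stationary-free uniform draw when omitted).
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    rng = np.random.default_rng(seed)
    cum = [np.cumsum(T[s]) for s in range(n)]
    for c in cum:
        c[-1] = 1.0  # guard against rounding
    out = []
    for _ in range(n_traj):
        if start_distribution is None:
            s = int(rng.integers(n))
        else:
            s = int(np.searchsorted(np.cumsum(start_distribution), rng.random()))
        traj = np.empty(n_steps, dtype=np.int32)
        u = rng.random(n_steps)
        for t in range(n_steps):
            traj[t] = s
            s = bisect_left(cum[s], u[t])
        out.append(traj)
    return out


def nucleation_rate(mfpt_seconds: float, volume_m3: float) -> float:
    """Nucleation rate J = 1/(MFPT * V) in events per second per m^3."""
    if mfpt_seconds <= 0 or volume_m3 <= 0:
        raise ValueError("MFPT and volume must be positive")
    return 1.0 / (mfpt_seconds * volume_m3)


def analyze(
    T: np.ndarray,
    pi: np.ndarray,
    A: Sequence[int],
    B: Sequence[int],
    min_fraction: float = 0.0,
    crisp: Optional[Sequence[int]] = None,
) -> TPTResult:
    """One-call TPT study: committors, fluxes, pathways, optional macro flux."""
    A_, B_ = _validate_sets(np.asarray(T).shape[0], A, B)
    q_plus, q_minus = committors(T, A_, B_, pi=pi)
    flux, net, total = reactive_flux(T, pi, q_plus, q_minus, A_)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pathways = decompose_pathways(net, A_, B_, min_fraction=min_fraction)
    macro = macro_flux(net, crisp) if crisp is not None else None
    return TPTResult(
        A=A_, B=B_, q_plus=q_plus, q_minus=q_minus,
        flux=flux, net_flux=net, total_flux=total,
        pathways=pathways, macro_net_flux=macro,
    )
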