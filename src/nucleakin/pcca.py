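"""PCCA+ lumping of microstates into metastable macro-states.

Robust Perron Cluster Cluster Analysis exploits the simplex structure of
the dominant eigenvectors of a reversible transition matrix: rows of the
eigenvector matrix lie (approximately) in a simplex whose vertices
correspond to the metastable sets.  The inner-simplex algorithm picks the
most spread-out vertex rows, maps eigenvector rows to fuzzy memberships by
the inverse vertex transform, and projects the result onto the probability
simplex.  Crisp assignments take the argmax membership.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EstimationError
from .msm import eigenspectrum, _is_reversible


@dataclass
class MacroModel:
    """Fuzzy memberships, crisp lumping and the coarse-grained chain."""

    membership: np.ndarray    # n_micro x n_macro, rows on the simplex
    crisp: np.ndarray         # micro -> macro argmax map
    macro_pi: np.ndarray
    macro_T: np.ndarray

    @property
    def n_macro(self) -> int:
        return self.membership.shape[1]

    def states_of(self, macro: int) -> np.ndarray:
        """Microstate indices crisply assigned to ``macro``."""
        return np.flatnonzero(self.crisp == macro)


def _inner_simplex_vertices(X: np.ndarray, n_macro: int) -> list[int]:
    """Indices of the ``n_macro`` most spread-out eigenvector rows."""
    norms = (X * X).sum(axis=1)
    idx = [int(np.argmax(norms))]
    # Gram-Schmidt on differences from the first vertex
    basis: list[np.ndarray] = []
    for _ in range(1, n_macro):
        diffs = X - X[idx[0]]
        for b in basis:
            diffs = diffs - np.outer(diffs @ b, b)
        dist = (diffs * diffs).sum(axis=1)
        dist[idx] = -np.inf
        nxt = int(np.argmax(dist))
        idx.append(nxt)
        v = diffs[nxt]
        nv = np.linalg.norm(v)
        if nv > 1e-12:
            basis.append(v / nv)
    return idx


def pcca_plus(T: np.ndarray, pi: np.ndarray, n_macro: int) -> MacroModel:
    """Lump a reversible transition matrix into ``n_macro`` macro-states.

    Raises :class:`EstimationError` when ``T`` is not reversible with
    respect to ``pi``.  Crisp assignment ties go to the lower macro index.
    """
    T = np.asarray(T, dtype=float)
    pi = np.asarray(pi, dtype=float)
    n = T.shape[0]
    if not 1 <= n_macro <= n:
        raise ValueError("n_macro must be in [1, n_micro]")
    if not _is_reversible(T, pi, tol=1e-6):
        raise EstimationError("PCCA+ requires a reversible transition matrix")
    vals, right = eigenspectrum(T, pi, m=n_macro)
    X = right  # n x n_macro, first column constant 1
    vertices = _inner_simplex_vertices(X, n_macro)
    A = np.linalg.inv(X[vertices])
    chi = X @ A
    # feasibility projection onto the probability simplex
    chi = np.clip(chi, 0.0, None)
    rowsum = chi.sum(axis=1)
    bad = rowsum <= 0
    if np.any(bad):
        chi[bad] = 1.0 / n_macro
        rowsum[bad] = 1.0
    chi = chi / rowsum[:, None]
    crisp = np.argmax(chi, axis=1)
    # relabel macro-states by their lowest micro member for determinism
    order = np.argsort([np.flatnonzero(crisp == c).min() if np.any(crisp == c) else n
                        for c in range(n_macro)])
    remap = np.empty(n_macro, dtype=int)
    remap[order] = np.arange(n_macro)
    chi = chi[:, order]
    crisp = remap[crisp]
    macro_T, macro_pi = coarse_grain(T, pi, crisp, n_macro=n_macro)
    return MacroModel(membership=chi, crisp=crisp, macro_pi=macro_pi, macro_T=macro_T)


def coarse_grain(
    T: np.ndarray, pi: np.ndarray, crisp: np.ndarray, n_macro: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stationary-flux aggregation of a chain under a crisp lumping.

    macro_pi_A = sum_{i in A} pi_i and
    macro_T_AB = sum_{i in A, j in B} pi_i T_ij / macro_pi_A.
    """
    crisp = np.asarray(crisp, dtype=int)
    m = n_macro or int(crisp.max()) + 1
    macro_pi = np.zeros(m)
    np.add.at(macro_pi, crisp, pi)
    F = pi[:, None] * T
    M = np.zeros((len(crisp), m))
    M[np.arange(len(crisp)), crisp] = 1.0
    macro_F = M.T @ F @ M
    with np.errstate(invalid="ignore", divide="ignore"):
        macro_T = np.where(macro_pi[:, None] > 0, macro_F / macro_pi[:, None], 0.0)
    return macro_T, macro_pi
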