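"""Greedy spectral column selection for collective variables.

Given the instantaneous and time-lagged covariance matrices (C0, Ctau) of a
candidate CV pool, a small subset of CVs is chosen so that the Nystrom
reconstruction of the pool from those columns preserves the slowest
relaxation timescales of the generalized eigenvalue problem
Ctau v = lambda C0 v.  Selection is greedy: one column is added at a time,
picking the candidate that most reduces the error in the top-m generalized
eigenvalues of the column-restricted problem relative to the full problem;
ties go to the lower column index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.linalg import eigh

from .cv_featurize import CVSeries
from .errors import EstimationError

#: relative diagonal regularization applied to C0 before generalized solves
_C0_REG = 1e-10


@dataclass
class CorrPair:
    """Mean-free instantaneous and (symmetrized) time-lagged covariances."""

    C0: np.ndarray
    Ctau: np.ndarray
    tau: float          # lag in ps
    n_samples: int


@dataclass
class SelectionResult:
    """Ordered greedy selection with per-size diagnostics."""

    selected: list[int]
    names: tuple[str, ...]
    timescale_curves: dict[int, np.ndarray] = field(default_factory=dict)
    reconstruction_error: dict[int, float] = field(default_factory=dict)

    @property
    def selected_names(self) -> tuple[str, ...]:
        return tuple(self.names[i] for i in self.selected)


def _as_matrix_list(series: Union[CVSeries, Sequence[CVSeries], np.ndarray, Sequence[np.ndarray]]):
    if isinstance(series, CVSeries):
        return [series.matrix], series.stride
    if isinstance(series, np.ndarray):
        return [series], 1.0
    mats, stride = [], 1.0
    for s in series:
        if isinstance(s, CVSeries):
            mats.append(s.matrix)
            stride = s.stride
        else:
            mats.append(np.asarray(s, dtype=float))
    return mats, stride


def estimate_correlations(series, tau: float) -> CorrPair:
    """Symmetric estimators of C0 and C(tau) over all (t, t+tau) pairs.

    ``series`` is one CVSeries/array or a list of them (multiple
    trajectories); lagged pairs never cross trajectory boundaries.  ``tau``
    is in ps and must be a multiple of the frame stride.
    """
    mats, stride = _as_matrix_list(series)
    lag = int(round(tau / stride))
    if lag < 1:
        raise ValueError(f"lag {tau} ps is below the frame stride {stride} ps")
    if all(len(m) <= lag for m in mats):
        raise ValueError("lag exceeds the length of every trajectory")
    K = mats[0].shape[1]
    sxy = np.zeros((K, K))
    sxx = np.zeros((K, K))
    mean = np.zeros(K)
    n = 0
    for m in mats:
        if len(m) <= lag:
            continue
        x, y = m[:-lag], m[lag:]
        mean += x.sum(axis=0) + y.sum(axis=0)
        n += len(x)
    mean /= 2 * n
    for m in mats:
        if len(m) <= lag:
            continue
        x, y = m[:-lag] - mean, m[lag:] - mean
        sxy += x.T @ y
        sxx += x.T @ x + y.T @ y
    C0 = sxx / (2 * n)
    Ctau = (sxy + sxy.T) / (2 * n)
    return CorrPair(C0=C0, Ctau=Ctau, tau=lag * stride, n_samples=n)


def nystrom_reconstruct(C: np.ndarray, cols: Sequence[int]) -> np.ndarray:
    """Nystrom reconstruction C[:, S] pinv(C[S, S]) C[S, :].

    Exact whenever the selected columns span the column space of ``C``; the
    sub-block pseudo-inverse is truncated at relative tolerance 1e-10.
    """
    cols = list(cols)
    if not cols or len(set(cols)) != len(cols):
        raise ValueError("cols must be non-empty and unique")
    C = np.asarray(C, dtype=float)
    W = C[np.ix_(cols, cols)]
    return C[:, cols] @ np.linalg.pinv(W, rcond=1e-10) @ C[cols, :]


def _regularize(C0: np.ndarray) -> np.ndarray:
    K = C0.shape[0]
    return C0 + np.eye(K) * (_C0_REG * np.trace(C0) / K)


def _top_eigenvalues(Ctau: np.ndarray, C0: np.ndarray, m: int) -> np.ndarray:
    try:
        vals = eigh(Ctau, _regularize(C0), eigvals_only=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise EstimationError(f"generalized eigensolve failed: {exc}") from exc
    return np.sort(vals)[::-1][:m]


def implied_timescales_from_eigs(eigs: np.ndarray, tau: float) -> np.ndarray:
    """t_i = -tau/ln(lambda_i) with eigenvalues clipped into (0, 1).

    Non-positive eigenvalues have no relaxation interpretation and yield
    timescale 0 with a warning; eigenvalues >= 1 are clipped just below 1.
    """
    eigs = np.asarray(eigs, dtype=float)
    if np.any(eigs <= 0):
        warnings.warn("non-positive eigenvalues set to timescale 0", stacklevel=2)
    out = np.zeros_like(eigs)
    pos = eigs > 0
    clipped = np.clip(eigs[pos], None, 1.0 - 1e-15)
    out[pos] = -tau / np.log(clipped)
    return out


def spectral_oasis_select(
    series,
    tau: float,
    n_select: int,
    m: int,
    corr: Optional[CorrPair] = None,
) -> SelectionResult:
    """Greedy spectral column selection of ``n_select`` CVs.

    At each step the candidate column minimizing the squared error of the
    top-``m`` generalized eigenvalues of the restricted problem
    (Ctau[S,S], C0[S,S]) against the full-pool spectrum is added.  For each
    intermediate size the top-m implied timescales and the Frobenius error
    of the Nystrom reconstruction of Ctau are recorded.
    """
    names: tuple[str, ...]
    if isinstance(series, CVSeries):
        names = series.names
    elif isinstance(series, (list, tuple)) and series and isinstance(series[0], CVSeries):
        names = series[0].names
    else:
        names = tuple(f"cv{i}" for i in range(np.asarray(
            series if isinstance(series, np.ndarray) else series[0]).shape[1]))
    if corr is None:
        corr = estimate_correlations(series, tau)
    K = corr.C0.shape[0]
    if not 1 <= n_select <= K:
        raise ValueError("n_select must be in [1, K]")
    if not 1 <= m <= n_select:
        raise ValueError("m must be in [1, n_select]")

    full = _top_eigenvalues(corr.Ctau, corr.C0, m)
    selected: list[int] = []
    result = SelectionResult(selected=selected, names=names)
    while len(selected) < n_select:
        best_err, best_col = np.inf, None
        for c in range(K):
            if c in selected:
                continue
            S = selected + [c]
            sub = _top_eigenvalues(
                corr.Ctau[np.ix_(S, S)], corr.C0[np.ix_(S, S)], min(m, len(S))
            )
            padded = np.zeros(m)
            padded[: len(sub)] = sub
            err = float(((full - padded) ** 2).sum())
            if err < best_err - 1e-15:  # strict improvement; ties keep lower index
                best_err, best_col = err, c
        selected.append(best_col)
        size = len(selected)
        sub = _top_eigenvalues(
            corr.Ctau[np.ix_(selected, selected)],
            corr.C0[np.ix_(selected, selected)],
            min(m, size),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result.timescale_curves[size] = implied_timescales_from_eigs(sub, corr.tau)
        result.reconstruction_error[size] = float(
            np.linalg.norm(corr.Ctau - nystrom_reconstruct(corr.Ctau, selected), "fro")
        )
    return result
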