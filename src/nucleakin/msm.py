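"""Microstate Markov state model estimation and validation.

Workflow: standardize CVs, discretize with greedy k-centers clustering,
count lagged transitions, estimate a (by default reversible) transition
matrix on the largest strongly connected set, then validate with implied
timescales, the Chapman-Kolmogorov test and GMRQ cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .cv_featurize import CVSeries
from .errors import EstimationError

__all__ = [
    "KCentersResult",
    "MicrostateModel",
    "ITSCurve",
    "kcenters",
    "assign_to_centers",
    "count_transitions",
    "estimate_T",
    "eigenspectrum",
    "implied_timescales",
    "ck_test",
    "gmrq",
    "build_msm",
    "save_model",
    "load_model",
]


def _as_arrays(data) -> list[np.ndarray]:
    if isinstance(data, CVSeries):
        return [data.matrix]
    if isinstance(data, np.ndarray):
        return [data]
    return [d.matrix if isinstance(d, CVSeries) else np.asarray(d, dtype=float) for d in data]


@dataclass
class KCentersResult:
    centers: np.ndarray          # n_states x K, original CV coordinates
    dtrajs: list[np.ndarray]
    mean: np.ndarray             # standardization applied before clustering
    scale: np.ndarray
    radius: float                # covering radius in standardized space


@dataclass
class MicrostateModel:
    """Discretization plus estimated transition matrix and spectrum."""

    centers: np.ndarray
    dtrajs: list[np.ndarray]
    lag: int                      # frames
    counts: np.ndarray
    T: np.ndarray
    pi: np.ndarray
    active: np.ndarray            # microstate indices kept after trimming
    lag_time: float = 1.0         # physical time per lag step (ps)
    mean: Optional[np.ndarray] = None
    scale: Optional[np.ndarray] = None
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_states(self) -> int:
        return self.T.shape[0]


@dataclass
class ITSCurve:
    lags: np.ndarray
    timescales: np.ndarray        # len(lags) x m; NaN where undefined


def kcenters(data, n_states: int, seed: int) -> KCentersResult:
    """Greedy k-centers clustering on standardized CVs.

    The first center is a seeded uniform draw; each subsequent center is
    the frame farthest from the existing centers.  The greedy scheme covers
    the data within twice the optimal covering radius.  Deterministic under
    a fixed seed.
    """
    mats = _as_arrays(data)
    X = np.concatenate(mats, axis=0)
    total = len(X)
    if n_states > total:
        raise ValueError(f"n_states={n_states} exceeds {total} frames")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale

    rng = np.random.default_rng(seed)
    first = int(rng.integers(total))
    center_idx = [first]
    dist = ((Z - Z[first]) ** 2).sum(axis=1)
    for _ in range(1, n_states):
        nxt = int(np.argmax(dist))  # argmax takes the first maximum: lower index
        center_idx.append(nxt)
        dist = np.minimum(dist, ((Z - Z[nxt]) ** 2).sum(axis=1))
    centers_z = Z[center_idx]
    assign = _nearest(Z, centers_z)
    dtrajs, off = [], 0
    for m in mats:
        dtrajs.append(assign[off: off + len(m)].copy())
        off += len(m)
    return KCentersResult(
        centers=X[center_idx].copy(),
        dtrajs=dtrajs,
        mean=mean,
        scale=scale,
        radius=float(np.sqrt(dist.max())),
    )


def _nearest(Z: np.ndarray, centers_z: np.ndarray) -> np.ndarray:
    # chunked distance computation; ties resolved to the lower center index
    out = np.empty(len(Z), dtype=int)
    step = max(1, int(2e7 // max(len(centers_z), 1)))
    for s in range(0, len(Z), step):
        block = Z[s: s + step]
        d2 = ((block[:, None, :] - centers_z[None, :, :]) ** 2).sum(axis=2)
        out[s: s + step] = np.argmin(d2, axis=1)
    return out


def assign_to_centers(data, result: KCentersResult) -> list[np.ndarray]:
    """Map new CV trajectories onto existing k-centers."""
    mats = _as_arrays(data)
    centers_z = (result.centers - result.mean) / result.scale
    return [_nearest((m - result.mean) / result.scale, centers_z) for m in mats]


def count_transitions(
    dtrajs: Sequence[np.ndarray], lag: int, n_states: Optional[int] = None,
    mode: str = "sliding",
) -> np.ndarray:
    """Lagged transition count matrix; pairs never cross trajectory bounds."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if mode not in ("sliding", "strided"):
        raise ValueError(f"unknown counting mode {mode!r}")
    dtrajs = [np.asarray(d, dtype=int) for d in dtrajs]
    n = n_states or (max(int(d.max()) for d in dtrajs if len(d)) + 1)
    counts = np.zeros((n, n))
    step = 1 if mode == "sliding" else lag
    for d in dtrajs:
        if len(d) <= lag:
            continue
        i, j = d[:-lag:step], d[lag::step]
        np.add.at(counts, (i, j), 1.0)
    return counts


def _largest_scc(counts: np.ndarray) -> np.ndarray:
    adj = csr_matrix(counts > 0)
    n_comp, comp = connected_components(adj, directed=True, connection="strong")
    # keep the component with the most observed transitions
    weights = np.array(
        [counts[np.ix_(comp == c, comp == c)].sum() for c in range(n_comp)]
    )
    return np.flatnonzero(comp == int(np.argmax(weights)))


def estimate_T(
    counts: np.ndarray,
    reversible: bool = True,
    tol: float = 1e-10,
    max_iter: int = 1_000_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Transition matrix and stationary law from a count matrix.

    The counts are first restricted to the largest strongly connected
    component.  Non-reversible estimation row-normalizes counts; the
    reversible (default) maximum-likelihood estimate under detailed balance
    is found by the standard self-consistent fixed-point iteration on the
    unnormalized edge weights x_ij,

        x_ij <- (c_ij + c_ji) / (c_i/x_i + c_j/x_j),

    iterated until the stationary law moves by less than ``tol``.

    Returns ``(T, pi, active)`` with ``active`` the retained state indices.
    """
    counts = np.asarray(counts, dtype=float)
    active = _largest_scc(counts)
    if active.size == 0:
        raise EstimationError("no ergodic set: the count graph has no strongly connected component")
    C = counts[np.ix_(active, active)]
    rows = C.sum(axis=1)
    if np.any(rows == 0):
        raise EstimationError("a state in the connected set has no outgoing counts")
    if not reversible:
        T = C / rows[:, None]
    else:
        Csym = C + C.T
        x = Csym.copy()
        pi_prev = x.sum(axis=1) / x.sum()
        for _ in range(max_iter):
            xi = x.sum(axis=1)
            denom = (rows / xi)[:, None] + (rows / xi)[None, :]
            with np.errstate(invalid="ignore", divide="ignore"):
                x = np.where(Csym > 0, Csym / denom, 0.0)
            pi = x.sum(axis=1) / x.sum()
            if np.abs(pi - pi_prev).max() < tol:
                break
            pi_prev = pi
        else:
            raise EstimationError("reversible MLE fixed point failed to converge")
        T = x / x.sum(axis=1)[:, None]
    pi = _stationary(T)
    return T, pi, active


def _stationary(T: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(T.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def eigenspectrum(T: np.ndarray, pi: Optional[np.ndarray] = None, m: Optional[int] = None):
    """Eigenvalues (descending) and right eigenvectors of ``T``.

    For a reversible matrix the symmetrized form ensures a real spectrum;
    otherwise eigenvalues are sorted by real part with imaginary parts
    dropped after a symmetry check.
    """
    n = T.shape[0]
    m = m or n
    if pi is not None and _is_reversible(T, pi):
        d = np.sqrt(pi)
        S = (d[:, None] * T) / d[None, :]
        vals, U = np.linalg.eigh((S + S.T) / 2)
        order = np.argsort(vals)[::-1]
        vals = vals[order][:m]
        right = (U[:, order[:m]] / d[:, None])
        # normalize the stationary eigenvector to be constant 1
        right[:, 0] = right[:, 0] / right[0, 0]
        return vals, right
    vals, vecs = np.linalg.eig(T)
    order = np.argsort(-vals.real)
    return vals[order][:m].real, vecs[:, order[:m]].real


def _is_reversible(T: np.ndarray, pi: np.ndarray, tol: float = 1e-8) -> bool:
    F = pi[:, None] * T
    return bool(np.abs(F - F.T).max() <= tol * max(F.max(), 1e-300))


def implied_timescales(
    dtrajs: Sequence[np.ndarray],
    lags: Sequence[int],
    m: int,
    reversible: bool = True,
    lag_time: float = 1.0,
) -> ITSCurve:
    """Implied timescales t_i(tau) = -tau/ln(lambda_i(tau)) for several lags.

    Timescales are in the unit of ``lag_time`` (physical time per frame).
    Non-positive or unit eigenvalues leave the timescale undefined (NaN).
    """
    lags = np.asarray(list(lags), dtype=int)
    out = np.full((len(lags), m), np.nan)
    for li, lag in enumerate(lags):
        counts = count_transitions(dtrajs, int(lag))
        T, pi, _ = estimate_T(counts, reversible=reversible)
        vals, _ = eigenspectrum(T, pi, m=m + 1)
        nontrivial = vals[1: m + 1]
        for k, lam in enumerate(nontrivial):
            if 0.0 < lam < 1.0:
                out[li, k] = -lag * lag_time / np.log(lam)
    return ITSCurve(lags=lags, timescales=out)


def ck_test(
    model: MicrostateModel,
    dtrajs: Sequence[np.ndarray],
    sets: Sequence[Sequence[int]],
    k_max: int,
    n_boot: int = 20,
    seed: int = 0,
) -> dict:
    """Chapman-Kolmogorov test on metastable sets.

    For each set A the model residence probability from ``T^k`` is compared
    with a re-estimation at lag ``k*lag``; bootstrap bands (over
    trajectories, or blocks when only one trajectory is available) quantify
    the estimation uncertainty.
    """
    sets = [np.asarray(list(s), dtype=int) for s in sets]
    ks = np.arange(0, k_max + 1)
    model_curves = np.empty((len(sets), len(ks)))
    Tk = np.eye(model.n_states)
    # map raw microstate indices to active-set positions
    index_of = {int(s): k for k, s in enumerate(model.active)}
    for ki, k in enumerate(ks):
        for si, A in enumerate(sets):
            Apos = np.array([index_of[a] for a in A if int(a) in index_of], dtype=int)
            w = model.pi[Apos] / model.pi[Apos].sum()
            model_curves[si, ki] = float(w @ Tk[np.ix_(Apos, Apos)].sum(axis=1))
        Tk = Tk @ model.T

    def estimate_curves(trajs) -> np.ndarray:
        est = np.full((len(sets), len(ks)), np.nan)
        est[:, 0] = 1.0
        for ki, k in enumerate(ks[1:], start=1):
            try:
                counts = count_transitions(trajs, int(k * model.lag), n_states=len(model.counts))
                Tk_est, pi_est, active = estimate_T(counts, reversible=False)
            except EstimationError:
                continue
            pos = {int(s): q for q, s in enumerate(active)}
            for si, A in enumerate(sets):
                Apos = np.array([pos[a] for a in A if int(a) in pos], dtype=int)
                if Apos.size == 0:
                    continue
                w = pi_est[Apos] / pi_est[Apos].sum()
                est[si, ki] = float(w @ Tk_est[np.ix_(Apos, Apos)].sum(axis=1))
        return est

    dtrajs = [np.asarray(d, dtype=int) for d in dtrajs]
    estimated = estimate_curves(dtrajs)
    rng = np.random.default_rng(seed)
    if len(dtrajs) > 1:
        units = dtrajs
    else:  # block bootstrap on a single trajectory
        block = max(10 * k_max * model.lag, 10 * model.lag)
        d = dtrajs[0]
        units = [d[s: s + block] for s in range(0, len(d), block)]
    boot = np.full((n_boot, len(sets), len(ks)), np.nan)
    for b in range(n_boot):
        pick = rng.integers(len(units), size=len(units))
        boot[b] = estimate_curves([units[p] for p in pick])
    lower = np.nanpercentile(boot, 2.5, axis=0)
    upper = np.nanpercentile(boot, 97.5, axis=0)
    return {
        "k": ks,
        "model": model_curves,
        "estimated": estimated,
        "lower": lower,
        "upper": upper,
    }


def gmrq(
    data,
    n_states: int,
    lag: int,
    m: int,
    n_folds: int = 2,
    seed: int = 0,
    reversible: bool = True,
) -> tuple[float, np.ndarray]:
    """Cross-validated generalized matrix Rayleigh quotient score.

    Trajectories are split into folds; on each training fold an MSM is
    built (k-centers + transition matrix) and its top-``m`` eigenvectors
    are scored on the held-out fold via the generalized Rayleigh quotient
    trace.  Higher is better; the score of a perfectly Markovian process
    approaches the sum of its top-m eigenvalues.
    """
    mats = _as_arrays(data)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if len(mats) < n_folds:  # split single/few trajectories into segments
        segs = []
        for mtx in mats:
            parts = np.array_split(mtx, int(np.ceil(n_folds * 2 / len(mats))))
            segs.extend([p for p in parts if len(p) > lag])
        mats = segs
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(mats))
    folds = np.array_split(order, n_folds)
    scores = []
    for f in folds:
        test_idx = set(int(v) for v in f)
        train = [mats[k] for k in range(len(mats)) if k not in test_idx]
        test = [mats[k] for k in range(len(mats)) if k in test_idx]
        if not train or not test:
            continue
        kc = kcenters(train, n_states, seed=seed)
        counts = count_transitions(kc.dtrajs, lag, n_states=n_states)
        T, pi, active = estimate_T(counts, reversible=reversible)
        vals, right = eigenspectrum(T, pi, m=m)
        V = np.zeros((n_states, min(m, right.shape[1])))
        V[active, :] = right[:, : V.shape[1]]
        test_dtrajs = assign_to_centers(test, kc)
        C = count_transitions(test_dtrajs, lag, n_states=n_states)
        Ntot = C.sum()
        if Ntot == 0:
            continue
        C00 = np.diag(C.sum(axis=1) / Ntot)
        C0t = (C + C.T) / (2 * Ntot)
        A = V.T @ C00 @ V
        B = V.T @ C0t @ V
        scores.append(float(np.trace(np.linalg.pinv(A) @ B)))
    if not scores:
        raise EstimationError("GMRQ: no usable folds")
    return float(np.mean(scores)), np.array(scores)


def build_msm(
    data,
    n_states: int,
    lag: int,
    seed: int,
    reversible: bool = True,
    lag_time: float = 1.0,
) -> MicrostateModel:
    """Convenience wrapper: k-centers + counting + estimation + spectrum."""
    kc = kcenters(data, n_states, seed=seed)
    counts = count_transitions(kc.dtrajs, lag, n_states=n_states)
    T, pi, active = estimate_T(counts, reversible=reversible)
    vals, _ = eigenspectrum(T, pi, m=min(10, len(T)))
    return MicrostateModel(
        centers=kc.centers,
        dtrajs=kc.dtrajs,
        lag=lag,
        counts=counts,
        T=T,
        pi=pi,
        active=active,
        lag_time=lag_time,
        mean=kc.mean,
        scale=kc.scale,
        eigenvalues=vals,
    )


def save_model(model: MicrostateModel, path) -> None:
    """Serialize a model to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as fh:
        for name in ("centers", "counts", "T", "pi", "active", "eigenvalues"):
            fh.create_dataset(name, data=getattr(model, name))
        if model.mean is not None:
            fh.create_dataset("mean", data=model.mean)
            fh.create_dataset("scale", data=model.scale)
        g = fh.create_group("dtrajs")
        for k, d in enumerate(model.dtrajs):
            g.create_dataset(str(k), data=d)
        fh.attrs["lag"] = model.lag
        fh.attrs["lag_time"] = model.lag_time


def load_model(path) -> MicrostateModel:
    import h5py

    with h5py.File(path, "r") as fh:
        dtrajs = [fh["dtrajs"][k][...] for k in sorted(fh["dtrajs"], key=int)]
        return MicrostateModel(
            centers=fh["centers"][...],
            dtrajs=dtrajs,
            lag=int(fh.attrs["lag"]),
            counts=fh["counts"][...],
            T=fh["T"][...],
            pi=fh["pi"][...],
            active=fh["active"][...],
            lag_time=float(fh.attrs["lag_time"]),
            mean=fh["mean"][...] if "mean" in fh else None,
            scale=fh["scale"][...] if "scale" in fh else None,
            eigenvalues=fh["eigenvalues"][...],
        )
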