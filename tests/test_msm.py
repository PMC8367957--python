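"""Discretization, transition-matrix estimation and MSM validation."""

import numpy as np
import pytest

from nucleakin.errors import EstimationError
from nucleakin.msm import (
    build_msm, ck_test, count_transitions, eigenspectrum, estimate_T, gmrq,
    implied_timescales, kcenters,
)
from nucleakin.tpt import sample_chain


# ---------------------------------------------------------------------------
# k-centers

def test_kcenters_separates_blobs(rng):
    a = rng.standard_normal((500, 2)) * 0.1
    b = rng.standard_normal((500, 2)) * 0.1 + 10.0
    X = np.vstack([a, b])
    res = kcenters([X], n_states=2, seed=0)
    d = res.dtrajs[0]
    assert len(set(d[:500])) == 1 and len(set(d[500:])) == 1
    assert d[0] != d[-1]


def test_kcenters_degenerate_every_frame_a_center(rng):
    X = rng.standard_normal((20, 3))
    res = kcenters([X], n_states=20, seed=1)
    assert res.radius < 1e-12
    assert len(set(res.dtrajs[0].tolist())) == 20


def test_kcenters_deterministic_under_seed(rng):
    X = rng.standard_normal((300, 4))
    r1 = kcenters([X], 10, seed=3)
    r2 = kcenters([X], 10, seed=3)
    assert np.array_equal(r1.centers, r2.centers)
    assert np.array_equal(r1.dtrajs[0], r2.dtrajs[0])


def test_kcenters_too_many_states(rng):
    with pytest.raises(ValueError):
        kcenters([rng.standard_normal((5, 2))], 6, seed=0)


# ---------------------------------------------------------------------------
# counting

def test_count_transitions_enumerated():
    c = count_transitions([np.array([0, 0, 1, 1])], lag=1)
    assert np.array_equal(c, [[1, 1], [0, 1]])


def test_count_transitions_no_cross_boundary():
    c = count_transitions([np.array([0, 1]), np.array([1, 0])], lag=1)
    assert np.array_equal(c, [[0, 1], [1, 0]])


def test_count_row_sums_equal_occupancy(rng):
    d = rng.integers(0, 4, size=1000)
    lag = 7
    c = count_transitions([d], lag=lag)
    occ = np.bincount(d[:-lag], minlength=4)
    assert np.array_equal(c.sum(axis=1), occ)


# ---------------------------------------------------------------------------
# estimation

def test_estimate_symmetric_counts():
    T, pi, active = estimate_T(np.array([[8.0, 2], [2, 8]]), reversible=True)
    assert np.allclose(T, [[0.8, 0.2], [0.2, 0.8]], atol=1e-10)
    assert np.allclose(pi, [0.5, 0.5], atol=1e-10)


def test_estimate_nonreversible_analytic_pi():
    T, pi, _ = estimate_T(np.array([[90.0, 10], [20, 80]]), reversible=False)
    assert np.allclose(T, [[0.9, 0.1], [0.2, 0.8]])
    assert np.allclose(pi, [2 / 3, 1 / 3], atol=1e-12)


def test_reversible_estimate_detailed_balance_and_likelihood(rng):
    counts = rng.integers(1, 60, size=(5, 5)).astype(float)
    T, pi, _ = estimate_T(counts, reversible=True)
    F = pi[:, None] * T
    assert np.abs(F - F.T).max() < 1e-8
    assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)

    # likelihood at the MLE beats the naive symmetrized-count estimator
    def loglik(Tm):
        mask = counts > 0
        return float((counts[mask] * np.log(Tm[mask])).sum())

    sym = counts + counts.T
    T_base = sym / sym.sum(axis=1)[:, None]
    assert loglik(T) >= loglik(T_base) - 1e-9


def test_estimation_trims_to_connected_set():
    # state 2 is only entered, never left: falls outside the ergodic set
    counts = np.array([[5.0, 5, 1], [5, 5, 0], [0, 0, 0]])
    T, pi, active = estimate_T(counts, reversible=False)
    assert list(active) == [0, 1]
    assert T.shape == (2, 2)


# ---------------------------------------------------------------------------
# implied timescales

def test_implied_timescale_closed_form():
    T = np.array([[0.85, 0.15], [0.15, 0.85]])  # lambda_2 = 0.7
    trajs = sample_chain(T, 60000, 2, seed=4)
    its = implied_timescales(trajs, lags=[1, 2, 4], m=1)
    expected = -1 / np.log(0.7)
    for li, lag in enumerate(its.lags):
        assert its.timescales[li, 0] == pytest.approx(expected, rel=0.1)


def test_non_markovian_timescales_grow_then_plateau():
    # hidden 3-state chain observed through a 2-state lumping is non-Markovian
    T = np.array([[0.95, 0.05, 0.0], [0.05, 0.90, 0.05], [0.0, 0.05, 0.95]])
    hidden = sample_chain(T, 200000, 1, seed=5)[0]
    observed = np.where(hidden == 2, 1, 0)  # merge states 0 and 1
    its = implied_timescales([observed], lags=[1, 5, 20], m=1)
    t = its.timescales[:, 0]
    assert t[1] > t[0]
    assert t[2] > t[1] * 0.8  # approaching a plateau, not diverging


def test_negative_eigenvalue_timescale_undefined():
    # strongly oscillatory chain: lambda_2 < 0 at lag 1
    T = np.array([[0.05, 0.95], [0.95, 0.05]])
    trajs = sample_chain(T, 20000, 1, seed=6)
    its = implied_timescales(trajs, lags=[1], m=1)
    assert np.isnan(its.timescales[0, 0])


# ---------------------------------------------------------------------------
# Chapman-Kolmogorov

def test_ck_self_consistent_on_markovian_data():
    T = np.array([[0.97, 0.03, 0.0], [0.03, 0.94, 0.03], [0.0, 0.03, 0.97]])
    trajs = sample_chain(T, 50000, 4, seed=7)
    model = build_msm([t[:, None].astype(float) for t in trajs],
                      n_states=3, lag=1, seed=0)
    # metastable groupings in model state indexing
    sets = [[int(np.argmin(np.abs(model.centers[:, 0] - v)))] for v in (0, 2)]
    res = ck_test(model, model.dtrajs, sets, k_max=5, n_boot=10, seed=1)
    for si in range(2):
        for ki in range(1, 6):
            lo, hi = res["lower"][si, ki], res["upper"][si, ki]
            band = max(hi - lo, 0.02)
            assert res["model"][si, ki] > lo - band
            assert res["model"][si, ki] < hi + band


def test_ck_detects_non_markovian_lumping():
    # hidden trap: observed state 1 lumps a short-lived (1) and a
    # long-lived (2) hidden state, giving strongly non-exponential dwells
    T = np.array([[0.90, 0.10, 0.00],
                  [0.45, 0.45, 0.10],
                  [0.00, 0.005, 0.995]])
    hidden = sample_chain(T, 200000, 1, seed=8)[0]
    observed = np.where(hidden == 0, 0, 1)
    model = build_msm([observed[:, None].astype(float)], n_states=2, lag=1, seed=0)
    res = ck_test(model, model.dtrajs, [[0], [1]], k_max=20, n_boot=10, seed=2)
    # the Markovian prediction misses the long-time residence by far more
    # than the bootstrap uncertainty
    gap = np.abs(res["model"][:, -1] - res["estimated"][:, -1]).max()
    band = np.nanmax(res["upper"][:, -1] - res["lower"][:, -1])
    assert gap > 2 * band


# ---------------------------------------------------------------------------
# GMRQ

def test_gmrq_two_state_score(rng):
    T = np.array([[0.9, 0.1], [0.2, 0.8]])
    lam2 = np.sort(np.linalg.eigvals(T).real)[0]
    trajs = sample_chain(T, 40000, 4, seed=9)
    data = [t[:, None].astype(float) + rng.standard_normal((len(t), 1)) * 0.05
            for t in trajs]
    score, _ = gmrq(data, n_states=2, lag=1, m=2, n_folds=2, seed=0)
    assert score == pytest.approx(1 + lam2, abs=0.03)


def test_gmrq_m1_is_unity(rng):
    T = np.array([[0.9, 0.1], [0.2, 0.8]])
    trajs = sample_chain(T, 5000, 4, seed=10)
    data = [t[:, None].astype(float) for t in trajs]
    score, _ = gmrq(data, n_states=2, lag=1, m=1, n_folds=2, seed=0)
    assert score == pytest.approx(1.0, abs=1e-8)


def test_gmrq_does_not_reward_overfitting(rng):
    # two well-separated blobs: 2 states suffice; 50 states overfit
    a = rng.standard_normal((4, 3000, 1)) * 0.1
    b = rng.standard_normal((4, 3000, 1)) * 0.1 + 10
    T = np.array([[0.95, 0.05], [0.05, 0.95]])
    data = []
    for k in range(4):
        d = sample_chain(T, 3000, 1, seed=20 + k)[0]
        data.append(np.where(d[:, None] == 0, a[k], b[k]))
    s2, _ = gmrq(data, n_states=2, lag=1, m=2, n_folds=2, seed=0)
    s50, _ = gmrq(data, n_states=50, lag=1, m=2, n_folds=2, seed=0)
    assert s50 <= s2 + 0.05


# ---------------------------------------------------------------------------
# spectrum sanity

def test_eigenspectrum_bounds(rng):
    counts = rng.integers(1, 30, size=(6, 6)).astype(float)
    T, pi, _ = estimate_T(counts, reversible=True)
    vals, vecs = eigenspectrum(T, pi)
    assert vals[0] == pytest.approx(1.0, abs=1e-10)
    assert np.all(vals <= 1 + 1e-10) and np.all(vals >= -1 - 1e-10)
    assert np.allclose(vecs[:, 0], 1.0, atol=1e-8)
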