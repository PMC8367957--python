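"""Transition path theory: exactness checks and sampling oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import propagate_ensemble
from nucleakin.errors import EstimationError
from nucleakin.msm import estimate_T
from nucleakin.tpt import (
    analyze, committors, decompose_pathways, macro_flux, mfpt,
    nucleation_rate, reactive_flux, sample_chain, transition_state_microstates,
)


def symmetric_walk(n=5):
    T = np.zeros((n, n))
    for i in range(n):
        if i > 0:
            T[i, i - 1] = 0.5
        if i < n - 1:
            T[i, i + 1] = 0.5
    T[0, 0] = T[-1, -1] = 0.5
    return T


def random_reversible(rng, n):
    counts = rng.integers(1, 40, size=(n, n)).astype(float)
    T, pi, _ = estimate_T(counts, reversible=True)
    return T, pi


def test_committor_of_unbiased_walk_is_linear():
    T = symmetric_walk(5)
    qp, qm = committors(T, [0], [4])
    assert np.allclose(qp, [0, 0.25, 0.5, 0.75, 1.0], atol=1e-12)


def test_reversible_backward_committor_identity(rng):
    T, pi = random_reversible(rng, 12)
    qp, qm = committors(T, [0, 1], [10, 11], pi=pi)
    assert np.abs(qm - (1 - qp)).max() < 1e-10


def test_committor_matches_shooting_oracle(rng):
    T, pi = random_reversible(rng, 20)
    A, B = [0], [19]
    qp, _ = committors(T, A, B, pi=pi)
    n_shots = 4000
    for s in (3, 9, 15):
        starts = np.full(n_shots, s)
        states, _ = propagate_ensemble(T, starts, 20000, rng, absorbing=A + B)
        est = (states == 19).mean()
        se = np.sqrt(max(est * (1 - est), 1e-6) / n_shots)
        assert abs(qp[s] - est) < 3 * se + 1e-9


def test_committor_sets_validated():
    T = symmetric_walk(4)
    with pytest.raises(ValueError):
        committors(T, [0], [0])
    with pytest.raises(ValueError):
        committors(T, [], [1])


def test_absorbing_intermediate_is_diagnosed():
    T = np.eye(5)
    with pytest.raises(EstimationError):
        committors(T, [0], [4])


# ---------------------------------------------------------------------------
# reactive flux

def test_flux_three_state_hand_computation():
    T = np.array([[0.9, 0.1, 0.0], [0.05, 0.9, 0.05], [0.0, 0.1, 0.9]])
    from nucleakin.msm import _stationary

    pi = _stationary(T)
    qp, qm = committors(T, [0], [2], pi=pi)
    flux, net, total = reactive_flux(T, pi, qp, qm, [0])
    assert total == pytest.approx(pi[0] * 0.1 * qp[1], abs=1e-14)


@settings(deadline=None, max_examples=15, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_net_flux_divergence_free(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 12))
    T, pi = random_reversible(rng, n)
    A, B = [0], [n - 1]
    qp, qm = committors(T, A, B, pi=pi)
    _, net, _ = reactive_flux(T, pi, qp, qm, A)
    div = net.sum(axis=1) - net.sum(axis=0)
    assert np.abs(div[1:-1]).max() < 1e-12


def test_total_flux_symmetric_under_ab_swap(rng):
    T, pi = random_reversible(rng, 10)
    qp, qm = committors(T, [0], [9], pi=pi)
    _, _, fwd = reactive_flux(T, pi, qp, qm, [0])
    qp2, qm2 = committors(T, [9], [0], pi=pi)
    _, _, bwd = reactive_flux(T, pi, qp2, qm2, [9])
    assert fwd == pytest.approx(bwd, rel=1e-10)


# ---------------------------------------------------------------------------
# pathways

def test_single_chain_single_pathway():
    T = symmetric_walk(4)
    from nucleakin.msm import _stationary

    pi = _stationary(T)
    qp, qm = committors(T, [0], [3], pi=pi)
    _, net, total = reactive_flux(T, pi, qp, qm, [0])
    paths = decompose_pathways(net, [0], [3])
    assert len(paths) == 1
    assert paths[0][0] == [0, 1, 2, 3]
    assert paths[0][1] == pytest.approx(total, rel=1e-10)


def test_parallel_branches_flux_ratio():
    # hand-built net flux: A=0 -> {1 or 2} -> B=3 with bottlenecks 0.7 / 0.3
    net = np.zeros((4, 4))
    net[0, 1] = net[1, 3] = 0.7
    net[0, 2] = net[2, 3] = 0.3
    paths = decompose_pathways(net, [0], [3])
    assert [p for p, _ in paths] == [[0, 1, 3], [0, 2, 3]]
    assert paths[0][1] / paths[1][1] == pytest.approx(7 / 3, rel=1e-10)


def test_full_decomposition_conserves_total_flux(rng):
    T, pi = random_reversible(rng, 15)
    res = analyze(T, pi, [0], [14], min_fraction=0.0)
    assert sum(f for _, f in res.pathways) == pytest.approx(res.total_flux, abs=1e-10)


def test_no_path_yields_empty_with_warning():
    net = np.zeros((3, 3))
    with pytest.warns(UserWarning):
        assert decompose_pathways(net, [0], [2]) == []


# ---------------------------------------------------------------------------
# macro flux and transition states

def test_macro_flux_identity_and_conservation(rng):
    T, pi = random_reversible(rng, 10)
    qp, qm = committors(T, [0], [9], pi=pi)
    _, net, _ = reactive_flux(T, pi, qp, qm, [0])
    assert np.allclose(macro_flux(net, np.arange(10)), net)
    crisp = np.array([0, 0, 0, 1, 1, 1, 1, 2, 2, 2])
    F = macro_flux(net, crisp)
    div = F.sum(axis=1) - F.sum(axis=0)
    assert abs(div[1]) < 1e-12  # intermediate macro-state conserves flux


def test_transition_state_window():
    T = symmetric_walk(5)
    qp, _ = committors(T, [0], [4])
    assert list(transition_state_microstates(qp, (0.45, 0.55))) == [2]
    with pytest.warns(UserWarning):
        assert transition_state_microstates(qp, (0.30, 0.30)).size == 0


def test_two_branch_networks_have_distinct_transition_states():
    # two chains sharing only source 0: 0-1-2-3 and 0-4-5-6
    n = 7
    T = np.zeros((n, n))
    edges = [(0, 1), (1, 2), (2, 3), (0, 4), (4, 5), (5, 6)]
    for a, b in edges:
        T[a, b] = T[b, a] = 0.2
    np.fill_diagonal(T, 1 - T.sum(axis=1))
    qp1, _ = committors(T, [0], [3])
    qp2, _ = committors(T, [0], [6])
    ts1 = set(transition_state_microstates(qp1, (0.3, 0.7)))
    ts2 = set(transition_state_microstates(qp2, (0.3, 0.7)))
    assert ts1 and ts2
    assert ts1.isdisjoint(ts2)
    assert ts1 <= {1, 2} and ts2 <= {4, 5}


# ---------------------------------------------------------------------------
# MFPT, sampling, rate

def test_mfpt_two_state_geometric():
    T = np.array([[0.9, 0.1], [0.2, 0.8]])
    m = mfpt(T, [1], lag_time=1.0)
    assert m[0] == pytest.approx(10.0, abs=1e-12)
    assert m[1] == 0.0


def test_mfpt_matches_sampling_oracle(rng):
    T, _ = random_reversible(rng, 10)
    target = [7]
    m = mfpt(T, target)
    n_walkers = 10000
    starts = np.full(n_walkers, 2)
    _, hits = propagate_ensemble(T, starts, 100000, rng, absorbing=target)
    assert (hits > 0).all()
    est = hits.mean()
    se = hits.std(ddof=1) / np.sqrt(n_walkers)
    assert abs(m[2] - est) < 3 * se


def test_sample_chain_identity_and_determinism():
    T = np.eye(3)
    d = sample_chain(T, 50, 2, seed=3)
    for t in d:
        assert len(set(t.tolist())) == 1
    a = sample_chain(symmetric_walk(4), 1000, 2, seed=9)
    b = sample_chain(symmetric_walk(4), 1000, 2, seed=9)
    assert all(np.array_equal(x, y) for x, y in zip(a, b))


def test_sample_chain_frequencies_match_T(rng):
    T, _ = random_reversible(rng, 4)
    d = sample_chain(T, 200000, 1, seed=13)[0]
    counts = np.zeros((4, 4))
    np.add.at(counts, (d[:-1], d[1:]), 1.0)
    rows = counts.sum(axis=1)
    T_emp = counts / rows[:, None]
    se = np.sqrt(T * (1 - T) / rows[:, None])
    assert np.all(np.abs(T_emp - T) < np.maximum(3 * se, 1e-3))


def test_nucleation_rate_arithmetic():
    assert nucleation_rate(1.0, 1.0) == 1.0
    assert nucleation_rate(2.0, 1.0) == pytest.approx(0.5)
    assert nucleation_rate(1.0, 2.0) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        nucleation_rate(-1.0, 1.0)
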