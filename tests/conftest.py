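"""Shared fixtures: small random frames and reference chains."""

import numpy as np
import pytest

from nucleakin.trajectory_io import Frame


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture
def random_frame(rng):
    """50 molecules at liquid-like density in a periodic cube."""
    n = 50
    L = (n / 33.0) ** (1 / 3)
    return Frame(
        oxygen_positions=rng.uniform(0, L, (n, 3)),
        box=np.array([L, L, L]),
        periodic=np.array([True, True, True]),
    )


@pytest.fixture
def open_frame(rng):
    """Non-periodic random cloud (safe to rotate rigidly)."""
    pos = rng.normal(0.0, 0.3, (30, 3)) + 5.0
    return Frame(
        oxygen_positions=pos,
        box=np.array([10.0, 10.0, 10.0]),
        periodic=np.array([False, False, False]),
    )


def propagate_ensemble(T, start_states, n_steps, rng, absorbing=None):
    """Vectorized Markov propagation of many walkers; used as a sampling
    oracle for committors and MFPTs (independent of tpt.sample_chain)."""
    T = np.asarray(T, dtype=float)
    cum = np.cumsum(T, axis=1)
    states = np.asarray(start_states, dtype=int).copy()
    hit_time = np.full(states.shape, -1, dtype=int)
    absorbed = np.zeros(states.shape, dtype=bool)
    absorbing = set() if absorbing is None else set(int(a) for a in absorbing)
    for t in range(1, n_steps + 1):
        active = ~absorbed
        if not active.any():
            break
        u = rng.random(active.sum())
        rows = cum[states[active]]
        states[active] = (u[:, None] > rows).sum(axis=1)
        if absorbing:
            newly = active.copy()
            newly[active] = np.isin(states[active], list(absorbing))
            hit_time[newly & (hit_time < 0)] = t
            absorbed |= newly
    return states, hit_time
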