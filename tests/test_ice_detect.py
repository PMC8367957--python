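"""Bond-order ice detection against independent brute-force oracles."""

import warnings

import numpy as np
import pytest
from scipy.special import sph_harm_y

from nucleakin.errors import GeometryError
from nucleakin.ice_detect import (
    DetectionParams, Phase, PhaseLabelFrame, assign_layers, averaged_qbar,
    classify, largest_ice_cluster, nearest_neighbors, qlm,
)
from nucleakin.synthetic import LatticeSpec, build_lattice
from nucleakin.trajectory_io import Frame


# ---------------------------------------------------------------------------
# independent direct-summation oracle (explicit loops, no shared helpers)

def _oracle_min_image(d, box, periodic):
    out = []
    for k in range(3):
        v = d[k]
        if periodic[k]:
            while v > box[k] / 2:
                v -= box[k]
            while v < -box[k] / 2:
                v += box[k]
        out.append(v)
    return np.array(out)


def _oracle_neighbors(frame, i, n):
    dists = []
    for j in range(frame.n_molecules):
        if j == i:
            continue
        d = _oracle_min_image(frame.oxygen_positions[j] - frame.oxygen_positions[i],
                              frame.box, frame.periodic)
        dists.append((np.linalg.norm(d), j))
    dists.sort()
    return [j for _, j in dists[:n]]


def _oracle_qbar(frame, i, l, n):
    """Direct summation of the averaged bond-order parameter."""
    def small_q(j):
        nbrs = _oracle_neighbors(frame, j, n)
        acc = np.zeros(2 * l + 1, dtype=complex)
        for k in nbrs:
            d = _oracle_min_image(frame.oxygen_positions[k] - frame.oxygen_positions[j],
                                  frame.box, frame.periodic)
            r = np.linalg.norm(d)
            theta = np.arccos(d[2] / r)
            phi = np.arctan2(d[1], d[0])
            for mi, m in enumerate(range(-l, l + 1)):
                acc[mi] += sph_harm_y(l, m, theta, phi)
        return acc / len(nbrs)

    members = [i] + _oracle_neighbors(frame, i, n)
    avg = np.zeros(2 * l + 1, dtype=complex)
    for j in members:
        avg += small_q(j)
    avg /= len(members)
    return np.sqrt(4 * np.pi / (2 * l + 1) * np.sum(np.abs(avg) ** 2))


# ---------------------------------------------------------------------------

def test_nearest_neighbors_chain_and_periodic_image():
    pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
    f_open = Frame(oxygen_positions=pos + 0.5, box=np.array([10.0, 10, 10]),
                   periodic=np.array([False] * 3))
    assert set(nearest_neighbors(f_open, 1, 2)) == {0, 2}
    f_per = Frame(oxygen_positions=pos, box=np.array([4.0, 10, 10]),
                  periodic=np.array([True, False, False]))
    assert set(nearest_neighbors(f_per, 0, 2)) == {1, 3}


def test_nearest_neighbors_matches_brute_force(random_frame):
    for i in (0, 17, 42):
        for n in (3, 4, 7):
            got = nearest_neighbors(random_frame, i, n)
            assert list(got) == _oracle_neighbors(random_frame, i, n)


def test_nearest_neighbors_rejects_too_many():
    f = Frame(oxygen_positions=np.random.default_rng(0).random((5, 3)),
              box=np.array([2.0, 2, 2]))
    with pytest.raises(ValueError):
        nearest_neighbors(f, 0, 5)


def test_qlm_single_neighbor_along_z():
    f = Frame(oxygen_positions=np.array([[1.0, 1, 1], [1.0, 1, 1.3]]),
              box=np.array([5.0, 5, 5]), periodic=np.array([False] * 3))
    q = qlm(f, 0, [1], 6)
    expected = np.zeros(13, dtype=complex)
    expected[6] = sph_harm_y(6, 0, 0.0, 0.0)  # only m=0 survives on the axis
    assert np.abs(q - expected).max() < 1e-12


def test_qlm_zero_separation_is_degenerate():
    f = Frame(oxygen_positions=np.array([[1.0, 1, 1], [1.0, 1, 1]]),
              box=np.array([5.0, 5, 5]), periodic=np.array([False] * 3))
    with pytest.raises(GeometryError):
        qlm(f, 0, [1], 6)


def test_qbar_matches_direct_summation_oracle(random_frame):
    params = DetectionParams()
    for l in (4, 6):
        mine = averaged_qbar(random_frame, l, params, n_neighbors=4)
        for i in (0, 13, 29, 44):
            assert mine[i] == pytest.approx(
                _oracle_qbar(random_frame, i, l, 4), abs=1e-12
            )


def test_qbar_rotation_invariance(open_frame, rng):
    params = DetectionParams()
    base = averaged_qbar(open_frame, 6, params, n_neighbors=4)
    # random rotation matrix via QR
    M, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    center = open_frame.oxygen_positions.mean(axis=0)
    rotated = Frame(
        oxygen_positions=(open_frame.oxygen_positions - center) @ M.T + center,
        box=open_frame.box, periodic=open_frame.periodic,
    )
    rot = averaged_qbar(rotated, 6, params, n_neighbors=4)
    assert np.abs(base - rot).max() < 1e-10


def test_hex_lattice_is_hexagonal_ice():
    frame = build_lattice(LatticeSpec(kind="hex_slab", n_molecules=150, noise_sd=0.0))
    q6 = averaged_qbar(frame, 6, DetectionParams(), n_neighbors=4)
    assert np.all(q6 > 0.45)
    labels = classify(frame)
    assert np.all(labels.labels == Phase.HEX)
    assert len(labels.largest_nucleus) == frame.n_molecules


def test_rhombic_monolayer_is_rhombic_ice():
    frame = build_lattice(LatticeSpec(kind="rhombic_monolayer", n_molecules=64, noise_sd=0.0))
    params = DetectionParams()
    q4 = averaged_qbar(frame, 4, params, n_neighbors=3)
    assert np.all(q4 > 0.6)
    labels = classify(frame, params)
    assert np.all(labels.labels == Phase.RHOMBIC)
    # precedence matters here: these molecules also satisfy the hexagonal
    # interface condition qbar6 > 0.5, yet the rhombic rule wins
    assert np.any(labels.qbar6 > 0.5)


def test_liquid_rarely_misdetected():
    frame = build_lattice(LatticeSpec(kind="liquid", n_molecules=200, noise_sd=0.0, seed=11))
    q6 = averaged_qbar(frame, 6, DetectionParams(), n_neighbors=4)
    assert (q6 > 0.45).mean() < 0.05
    labels = classify(frame)
    assert (labels.labels == Phase.LIQUID).mean() > 0.95


def test_classification_is_deterministic():
    frame = build_lattice(LatticeSpec(kind="liquid", n_molecules=60, noise_sd=0.0, seed=7))
    a = classify(frame)
    b = classify(frame)
    assert np.array_equal(a.labels, b.labels)
    assert np.array_equal(a.largest_nucleus, b.largest_nucleus)
    assert np.array_equal(a.qbar6, b.qbar6)


# ---------------------------------------------------------------------------
# clustering and layers

def _label_frame(labels, n):
    return PhaseLabelFrame(
        labels=np.asarray(labels, dtype=np.int8),
        layer=np.zeros(n, dtype=int),
        largest_nucleus=np.empty(0, dtype=int),
        qbar4=np.zeros(n), qbar6=np.zeros(n),
    )


def test_largest_cluster_picks_bigger_island():
    # island of 7 at x ~ 0, island of 3 at x ~ 5
    pos = np.vstack([
        np.column_stack([np.arange(7) * 0.3, np.zeros(7), np.zeros(7)]),
        np.column_stack([5 + np.arange(3) * 0.3, np.zeros(3), np.zeros(3)]),
    ])
    f = Frame(oxygen_positions=pos, box=np.array([20.0, 20, 20]),
              periodic=np.array([False] * 3))
    plf = _label_frame([Phase.HEX] * 10, 10)
    cluster = largest_ice_cluster(plf, f, cutoff=0.35)
    assert set(cluster) == set(range(7))


def test_all_liquid_gives_empty_cluster(random_frame):
    plf = _label_frame([Phase.LIQUID] * 50, 50)
    assert largest_ice_cluster(plf, random_frame, 0.35).size == 0


def test_largest_cluster_matches_union_find_oracle(random_frame, rng):
    labels = rng.choice([Phase.LIQUID, Phase.HEX, Phase.RHOMBIC], size=50,
                        p=[0.4, 0.4, 0.2])
    plf = _label_frame(labels, 50)
    cutoff = 0.35
    got = set(largest_ice_cluster(plf, random_frame, cutoff))

    # brute-force union-find over all pairs
    parent = list(range(50))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    ice = [i for i in range(50) if labels[i] != Phase.LIQUID]
    for a in ice:
        for b in ice:
            if a < b:
                d = _oracle_min_image(
                    random_frame.oxygen_positions[b] - random_frame.oxygen_positions[a],
                    random_frame.box, random_frame.periodic)
                if np.linalg.norm(d) <= cutoff:
                    parent[find(a)] = find(b)
    comps = {}
    for i in ice:
        comps.setdefault(find(i), set()).add(i)
    best = max(comps.values(), key=lambda s: (len(s), -min(s)))
    assert got == best


def test_layer_arithmetic_and_slab():
    f = Frame(oxygen_positions=np.array([[0, 0, 0.1], [0, 0, 0.40]]),
              box=np.array([2.0, 2, 2]), surface_top_z=0.0)
    params = DetectionParams(layer_spacing=0.368)
    assert list(assign_layers(f, params)) == [0, 1]

    slab = build_lattice(LatticeSpec(kind="hex_slab", n_molecules=120,
                                     noise_sd=0.0, n_layers=3))
    layers = assign_layers(slab)
    assert sorted(set(layers.tolist())) == [0, 1, 2]


def test_layers_below_surface_warn_and_clamp():
    f = Frame(oxygen_positions=np.array([[0, 0, 0.5], [0, 0, 0.3]]),
              box=np.array([2.0, 2, 2]), surface_top_z=0.4)
    with pytest.warns(UserWarning, match="below the surface"):
        layers = assign_layers(f)
    assert list(layers) == [0, 0]
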