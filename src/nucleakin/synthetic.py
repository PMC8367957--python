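"""Ground-truth synthetic inputs for every pipeline stage.

Two generators are provided.

``build_two_pathway_network`` constructs an 8-state metastable kinetic
network with the topology of a surface-nucleation study: a liquid basin I
feeds a pre-nucleation basin II, from which flux bifurcates into a direct
("classical") branch II -> IV of hexagonal-ice growth and an indirect
("non-classical") branch II -> III -> {IV, V} passing through a
rhombic/hexagonal mixed state III, before both coalesce into growth states
VI -> {VII, VIII}.  The branch probability at II is tuned by bisection so
that transition path theory applied to the exact matrix yields a requested
classical flux fraction.  ``emit_trajectories`` samples the hidden chain
and emits noisy 5-component CV observations per state.

``build_lattice`` produces ideal molecular configurations for the ice
detector: a wurtzite-like hexagonal-ice oxygen lattice (cell a = 0.4519 nm,
c = 0.7357 nm), a planar square-net rhombic monolayer, and a random
hard-sphere liquid at 33 molecules/nm^3, each with seeded Gaussian thermal
displacement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._geometry import minimum_image
from .cv_featurize import CVSeries, SELECTED5
from .errors import NucleakinError
from .msm import _stationary
from .tpt import committors, reactive_flux, sample_chain
from .trajectory_io import Frame

STATE_NAMES = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")

#: CV emission means per state (rows: states I..VIII; columns: SELECTED5).
#: The progression mimics nucleation: the nucleus grows monotonically along
#: the network, rhombic ice peaks in the mixed state III and decays again.
DEFAULT_EMISSION_MEANS = np.array(
    [
        #  n_ice  n_rhomb  hex_l2  hex_l3  hex_up
        [5.0,    1.0,     1.0,    0.0,    0.0],   # I   liquid
        [80.0,   20.0,    15.0,   5.0,    1.0],   # II  pre-nucleation
        [200.0,  120.0,   30.0,   10.0,   3.0],   # III rhombic/hex mixture
        [300.0,  30.0,    80.0,   40.0,   10.0],  # IV  post-critical hex
        [320.0,  40.0,    85.0,   45.0,   12.0],  # V   post-critical mixed
        [450.0,  20.0,    120.0,  80.0,   40.0],  # VI  growth
        [600.0,  10.0,    160.0,  120.0,  90.0],  # VII grown
        [620.0,  10.0,    165.0,  125.0,  95.0],  # VIII grown
    ]
)

DEFAULT_EMISSION_SDS = np.full((8, 5), 5.0)


@dataclass
class GroundTruthNetwork:
    """Exact 8-state chain with CV emission laws and the target flux split."""

    T_true: np.ndarray
    emission_means: np.ndarray = field(default_factory=lambda: DEFAULT_EMISSION_MEANS.copy())
    emission_sds: np.ndarray = field(default_factory=lambda: DEFAULT_EMISSION_SDS.copy())
    pathway_split: float = 0.5
    state_names: tuple[str, ...] = STATE_NAMES

    @property
    def n_states(self) -> int:
        return self.T_true.shape[0]

    @property
    def pi(self) -> np.ndarray:
        return _stationary(self.T_true)


def _network_matrix(x: float, metastability: float) -> np.ndarray:
    """Row-stochastic matrix of the two-pathway topology.

    ``x`` is the classical branch probability at state II (share of the
    forward probability going II -> IV rather than II -> III).
    """
    mu = metastability
    r = 1.0 - mu
    T = np.zeros((8, 8))
    I, II, III, IV, V, VI, VII, VIII = range(8)
    T[I, II] = r
    T[II, I] = 0.3 * r
    T[II, IV] = 0.7 * r * x
    T[II, III] = 0.7 * r * (1.0 - x)
    T[III, II] = 0.3 * r
    T[III, IV] = 0.35 * r
    T[III, V] = 0.35 * r
    T[IV, II] = 0.15 * r
    T[IV, III] = 0.15 * r
    T[IV, VI] = 0.7 * r
    T[V, III] = 0.3 * r
    T[V, VI] = 0.7 * r
    T[VI, IV] = 0.15 * r
    T[VI, V] = 0.15 * r
    T[VI, VII] = 0.35 * r
    T[VI, VIII] = 0.35 * r
    T[VII, VI] = r
    T[VIII, VI] = r
    np.fill_diagonal(T, 1.0 - T.sum(axis=1))
    return T


def classical_flux_fraction(T: np.ndarray, pi: Optional[np.ndarray] = None) -> float:
    """Share of the I -> {VII, VIII} net flux leaving II through the
    direct edge II -> IV (the classical branch)."""
    if pi is None:
        pi = _stationary(T)
    qp, qm = committors(T, [0], [6, 7], pi=pi)
    _, net, _ = reactive_flux(T, pi, qp, qm, [0])
    classical = net[1, 3]
    nonclassical = net[1, 2]
    if classical + nonclassical <= 0:
        raise NucleakinError("no flux leaves state II")
    return float(classical / (classical + nonclassical))


def build_two_pathway_network(
    pathway_split: float = 0.5,
    metastability: float = 0.95,
    seed: int = 0,
    tol: float = 0.01,
) -> GroundTruthNetwork:
    """Construct the 8-state network with a requested classical flux split.

    The branch probability at state II is tuned by bisection until TPT on
    the exact matrix gives the requested classical fraction within ``tol``.
    ``seed`` is accepted for interface uniformity; the construction is
    deterministic.
    """
    if not 0.0 <= pathway_split <= 1.0:
        raise ValueError("pathway_split must lie in [0, 1]")
    if not 0.0 < metastability < 1.0:
        raise ValueError("metastability must lie in (0, 1)")
    lo, hi = 0.0, 1.0
    x = pathway_split
    for _ in range(60):
        f = classical_flux_fraction(_network_matrix(x, metastability))
        if abs(f - pathway_split) <= tol * 0.5:
            break
        if f < pathway_split:
            lo = x
        else:
            hi = x
        x = 0.5 * (lo + hi)
    T = _network_matrix(x, metastability)
    return GroundTruthNetwork(T_true=T, pathway_split=pathway_split)


def emit_trajectories(
    net: GroundTruthNetwork,
    n_traj: int,
    n_steps: int,
    seed: int = 0,
    stride: float = 1.0,
) -> tuple[list[CVSeries], list[np.ndarray]]:
    """Sample hidden chains from ``T_true`` and emit noisy CV observations.

    Per step the observation is the state's emission mean plus independent
    Gaussian noise, rounded to non-negative integer counts.  Returns the CV
    series and the true hidden state sequences for recovery scoring.
    """
    dtrajs = sample_chain(net.T_true, n_steps, n_traj, seed=seed,
                          start_distribution=net.pi)
    rng = np.random.default_rng(seed + 1_000_003)
    series = []
    for d in dtrajs:
        obs = net.emission_means[d] + rng.standard_normal((n_steps, 5)) * net.emission_sds[d]
        obs = np.clip(np.round(obs), 0, None)
        series.append(CVSeries(data=pd.DataFrame(obs, columns=list(SELECTED5)),
                               stride=stride))
    return series, dtrajs


def append_noise_cvs(
    series: list[CVSeries], n_noise: int = 13, seed: int = 0, sd: float = 1.0
) -> list[CVSeries]:
    """Extend 5-CV series with uninformative white-noise channels.

    Produces an 18-column pool for exercising CV selection: the first five
    columns carry the kinetics, the rest are i.i.d. noise.
    """
    rng = np.random.default_rng(seed)
    out = []
    for s in series:
        noise = rng.standard_normal((len(s), n_noise)) * sd
        df = s.data.copy()
        for k in range(n_noise):
            df[f"noise{k + 1}"] = noise[:, k]
        out.append(CVSeries(data=df, stride=s.stride))
    return out


def match_macrostates(
    crisp: np.ndarray,
    dtrajs_est: list[np.ndarray],
    series: list[CVSeries],
    emission_means: np.ndarray,
) -> np.ndarray:
    """Bijection between recovered macro-states and generative basins.

    Each macro-state's mean observed CV vector is matched to the closest
    emission mean by optimal assignment.  Returns ``perm`` with
    ``perm[basin] = macro`` so that recovered quantities can be read in the
    generative state order.
    """
    from scipy.optimize import linear_sum_assignment

    n_macro = int(crisp.max()) + 1
    dim = emission_means.shape[1]
    sums = np.zeros((n_macro, dim))
    counts = np.zeros(n_macro)
    for d, s in zip(dtrajs_est, series):
        mac = crisp[np.asarray(d, dtype=int)]
        X = s.matrix
        np.add.at(sums, mac, X)
        np.add.at(counts, mac, 1.0)
    means = sums / np.maximum(counts, 1.0)[:, None]
    cost = ((means[None, :, :] - emission_means[:, None, :]) ** 2).sum(axis=2)
    basins, macros = linear_sum_assignment(cost)
    perm = np.empty(len(basins), dtype=int)
    perm[basins] = macros
    return perm


# ---------------------------------------------------------------------------
# ideal molecular configurations

A_HEX = 0.4519   # nm, hexagonal a
C_HEX = 0.7357   # nm, hexagonal c
OO_BOND = 0.276  # nm, nearest O-O distance (3c/8)
LIQUID_DENSITY = 33.0   # molecules / nm^3
LIQUID_MIN_DIST = 0.2   # nm hard-core rejection distance


@dataclass
class LatticeSpec:
    """Specification of an ideal configuration for the detector."""

    kind: str                      # hex_slab | rhombic_monolayer | liquid
    n_molecules: int = 200
    noise_sd: float = 0.01         # nm Gaussian displacement
    seed: int = 0
    n_layers: Optional[int] = None  # hex_slab only: finite bilayer count

    def __post_init__(self) -> None:
        if self.kind not in ("hex_slab", "rhombic_monolayer", "liquid"):
            raise ValueError(f"unknown lattice kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _hex_cell() -> tuple[np.ndarray, np.ndarray]:
    """Orthorhombic cell (a, sqrt(3) a, c) of the hexagonal-ice oxygen
    sublattice: wurtzite sites of both species, 8 oxygens per cell."""
    frac_hex = [(1/3, 2/3, 0.0), (2/3, 1/3, 0.5), (1/3, 2/3, 3/8), (2/3, 1/3, 7/8)]
    pts = []
    for (u, v, w) in frac_hex:
        x = A_HEX * (u - v / 2)
        y = A_HEX * v * np.sqrt(3) / 2
        z = C_HEX * w
        for (sx, sy) in ((0.0, 0.0), (A_HEX / 2, A_HEX * np.sqrt(3) / 2)):
            pts.append((x + sx, y + sy, z))
    cell = np.array(pts)
    dims = np.array([A_HEX, A_HEX * np.sqrt(3), C_HEX])
    return cell % dims, dims


def build_lattice(spec: LatticeSpec) -> Frame:
    """Generate an ideal configuration according to ``spec``.

    hex_slab: periodic hexagonal-ice crystal; with ``n_layers`` set, a
    finite slab of that many bilayers above a virtual surface
    (``surface_top_z`` 0.05 nm below the lowest oxygen).
    rhombic_monolayer: planar square net (O-O 0.276 nm) one interface
    height above a virtual surface.
    liquid: hard-sphere rejection packing at 33 molecules/nm^3.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "hex_slab":
        frame = _build_hex(spec)
    elif spec.kind == "rhombic_monolayer":
        frame = _build_rhombic(spec)
    else:
        frame = _build_liquid(spec, rng)
    if spec.noise_sd > 0:
        frame.oxygen_positions = frame.oxygen_positions + rng.normal(
            0.0, spec.noise_sd, frame.oxygen_positions.shape
        )
    return frame


def _build_hex(spec: LatticeSpec) -> Frame:
    cell, dims = _hex_cell()
    if spec.n_layers is None:
        nz = max(1, round((spec.n_molecules / 8) ** (1 / 3) * dims[0] / dims[2] * 2))
        lateral = max(1, int(np.ceil(np.sqrt(spec.n_molecules / (8 * nz)))))
        nx, ny = lateral, lateral
    else:
        nz = int(np.ceil(spec.n_layers / 2))
        lateral = max(2, int(np.ceil(np.sqrt(spec.n_molecules / (4 * spec.n_layers)))))
        nx, ny = lateral, lateral
    pts = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                pts.append(cell + np.array([i, j, k]) * dims)
    pos = np.vstack(pts)
    box = np.array([nx, ny, nz]) * dims
    if spec.n_layers is None:
        pos %= box
        return Frame(oxygen_positions=pos, box=box, periodic=np.array([True] * 3),
                     surface_top_z=None)
    # finite slab cut between bilayers (shift by 3c/8) so that both surface
    # levels keep 3 of their 4 lattice neighbours, like a contact layer that
    # donates one hydrogen bond to the substrate
    spacing = C_HEX / 2
    pos[:, 2] = (pos[:, 2] - 3 * C_HEX / 8) % (nz * C_HEX)
    keep = pos[:, 2] < spec.n_layers * spacing - 1e-9
    pos = pos[keep]
    box = np.array([box[0], box[1], spec.n_layers * spacing + 2.0])
    return Frame(
        oxygen_positions=pos,
        box=box,
        periodic=np.array([True, True, False]),
        surface_top_z=float(pos[:, 2].min() - 0.05),
    )


def _build_rhombic(spec: LatticeSpec) -> Frame:
    s = OO_BOND
    lateral = max(2, int(np.ceil(np.sqrt(spec.n_molecules))))
    xs, ys = np.meshgrid(np.arange(lateral) * s, np.arange(lateral) * s)
    z_plane = 0.5
    pos = np.column_stack([xs.ravel(), ys.ravel(), np.full(lateral * lateral, z_plane)])
    box = np.array([lateral * s, lateral * s, 3.0])
    return Frame(
        oxygen_positions=pos,
        box=box,
        periodic=np.array([True, True, False]),
        surface_top_z=z_plane - 0.25,  # monolayer sits inside the interface band
    )


def _build_liquid(spec: LatticeSpec, rng: np.random.Generator) -> Frame:
    n = spec.n_molecules
    L = (n / LIQUID_DENSITY) ** (1 / 3)
    box = np.array([L, L, L])
    periodic = np.array([True] * 3)
    pos: list[np.ndarray] = []
    attempts = 0
    while len(pos) < n:
        p = rng.uniform(0.0, L, 3)
        if pos:
            arr = np.asarray(pos)
            dr = minimum_image(arr - p, box, periodic)
            if (dr * dr).sum(axis=1).min() < LIQUID_MIN_DIST**2:
                attempts += 1
                if attempts > 1000 * n:
                    raise NucleakinError("liquid packing failed; density too high")
                continue
        pos.append(p)
    return Frame(oxygen_positions=np.asarray(pos), box=box, periodic=periodic,
                 surface_top_z=None)
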