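"""Molecule-level ice polymorph detection with averaged bond-order parameters.

Each water molecule is classified as hexagonal ice, rhombic ice or liquid
from the rotationally invariant averaged Steinhardt parameters

    qbar_l(i) = ( 4*pi/(2l+1) * sum_m | (1/(N_i+1)) sum_{j in {i} u nbrs(i)}
                  q_{l,m}(j) |^2 )^{1/2},

with q_{l,m}(j) the mean spherical harmonic Y_{l,m} over the minimum-image
bond vectors from j to its N_j nearest oxygen neighbours.  Averaging the
q_{l,m} over the first neighbour shell before taking the rotational
invariant sharpens the separation between polymorphs and the liquid.

Two classification regimes are used.  Bulk molecules use N_i = 4 (tetrahedral
coordination) and a single hexagonal-ice threshold qbar6 > 0.45.  Molecules
at the surface-water interface use N_i = 3 (one bond is donated to the
surface): hexagonal ice requires qbar6 > 0.5 with qbar4 < 0.6, while
qbar4 > 0.6 marks the planar four-coordinated rhombic-ice motif.  The
rhombic condition is unconditional on qbar4, so it takes precedence when
both fire.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import sph_harm_y

from ._geometry import minimum_image
from .errors import ConfigError, GeometryError, NucleakinError
from .trajectory_io import Frame


class Phase(IntEnum):
    LIQUID = 0
    HEX = 1
    RHOMBIC = 2


@dataclass
class DetectionParams:
    """Thresholds and geometric parameters of the ice detector.

    Defaults: hexagonal ice in the bulk at qbar6 > 0.45 with 4 neighbours;
    at the interface (within ``interface_z_cutoff`` of the surface top) 3
    neighbours are used and hexagonal/rhombic ice require qbar6 > 0.5 with
    qbar4 < 0.6, respectively qbar4 > 0.6.  ``layer_spacing`` defaults to
    c/2 of the hexagonal ice cell (c = 0.7357 nm); ``cluster_cutoff`` to the
    first minimum of the O-O pair correlation of simulated water.
    """

    l_orders: tuple[int, ...] = (4, 6)
    n_neighbors_bulk: int = 4
    n_neighbors_interface: int = 3
    qbar6_bulk: float = 0.45
    qbar6_interface: float = 0.5
    qbar4_low: float = 0.6
    qbar4_high: float = 0.6
    cluster_cutoff: float = 0.35  # nm
    interface_z_cutoff: float = 0.35  # nm
    layer_spacing: float = 0.36785  # nm, c/2

    def __post_init__(self) -> None:
        for t in (self.qbar6_bulk, self.qbar6_interface, self.qbar4_low, self.qbar4_high):
            if not 0.0 < t < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")
        if self.n_neighbors_bulk < 1 or self.n_neighbors_interface < 1:
            raise ValueError("neighbour counts must be >= 1")
        if min(self.cluster_cutoff, self.interface_z_cutoff, self.layer_spacing) <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass
class PhaseLabelFrame:
    """Per-molecule polymorph labels plus layer and nucleus assignments."""

    labels: np.ndarray            # int8, values from Phase
    layer: np.ndarray             # non-negative int, 0 = contact layer
    largest_nucleus: np.ndarray   # sorted molecule indices
    qbar4: np.ndarray
    qbar6: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.layer = np.asarray(self.layer, dtype=int)
        self.largest_nucleus = np.sort(np.asarray(self.largest_nucleus, dtype=int))
        ice = set(np.flatnonzero(self.labels != Phase.LIQUID))
        if not set(self.largest_nucleus).issubset(ice):
            raise NucleakinError("largest_nucleus contains liquid molecules")

    @property
    def n_molecules(self) -> int:
        return len(self.labels)


def nearest_neighbors(frame: Frame, i: int, n: int) -> np.ndarray:
    """Indices of the ``n`` nearest oxygen neighbours of molecule ``i``.

    Minimum-image Euclidean metric; ties at identical distance are broken by
    the lower molecule index; ``i`` itself is excluded.
    """
    N = frame.n_molecules
    if n >= N:
        raise ValueError(f"n={n} neighbours requested but only {N - 1} available")
    dr = minimum_image(frame.oxygen_positions - frame.oxygen_positions[i],
                       frame.box, frame.periodic)
    d = np.sqrt((dr * dr).sum(axis=1))
    d[i] = np.inf
    order = np.lexsort((np.arange(N), d))
    return order[:n]


def _all_neighbors(frame: Frame, n_per_molecule: np.ndarray) -> list[np.ndarray]:
    """Neighbour lists for every molecule; ``n_per_molecule[i]`` neighbours each."""
    pos = frame.oxygen_positions
    N = len(pos)
    out = []
    for i in range(N):
        dr = minimum_image(pos - pos[i], frame.box, frame.periodic)
        d = np.sqrt((dr * dr).sum(axis=1))
        d[i] = np.inf
        order = np.lexsort((np.arange(N), d))
        out.append(order[: n_per_molecule[i]])
    return out


def qlm(frame: Frame, i: int, neighbors: Sequence[int], l: int) -> np.ndarray:
    """Neighbour-averaged spherical harmonics q_{l,m}(i), m = -l..l."""
    neighbors = np.asarray(neighbors, dtype=int)
    if neighbors.size == 0:
        raise ValueError("qlm requires a non-empty neighbour list")
    dr = minimum_image(
        frame.oxygen_positions[neighbors] - frame.oxygen_positions[i],
        frame.box, frame.periodic,
    )
    r = np.sqrt((dr * dr).sum(axis=1))
    if np.any(r < 1e-12):
        raise GeometryError(f"zero-length separation vector at molecule {i}")
    theta = np.arccos(np.clip(dr[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(dr[:, 1], dr[:, 0])
    return np.array(
        [sph_harm_y(l, m, theta, phi).mean() for m in range(-l, l + 1)]
    )


def averaged_qbar(
    frame: Frame,
    l: int,
    params: DetectionParams,
    n_neighbors: Optional[int] = None,
) -> np.ndarray:
    """Averaged bond-order parameter qbar_l for every molecule.

    With ``n_neighbors=None`` the per-molecule neighbour count follows the
    interface/bulk rule derived from ``frame.surface_top_z`` (all bulk when
    the frame has no surface).
    """
    if n_neighbors is not None:
        n_per = np.full(frame.n_molecules, int(n_neighbors))
    else:
        n_per = np.where(
            _interface_mask(frame, params),
            params.n_neighbors_interface,
            params.n_neighbors_bulk,
        )
    nbrs = _all_neighbors(frame, n_per)
    return _qbar_from_neighbors(frame, nbrs, l)


def _qbar_from_neighbors(frame: Frame, nbrs: list[np.ndarray], l: int) -> np.ndarray:
    q = np.empty((frame.n_molecules, 2 * l + 1), dtype=complex)
    for j in range(frame.n_molecules):
        q[j] = qlm(frame, j, nbrs[j], l)
    out = np.empty(frame.n_molecules)
    for i in range(frame.n_molecules):
        avg = (q[i] + q[nbrs[i]].sum(axis=0)) / (len(nbrs[i]) + 1)
        out[i] = np.sqrt(4 * np.pi / (2 * l + 1) * (np.abs(avg) ** 2).sum())
    return out


def _interface_mask(frame: Frame, params: DetectionParams) -> np.ndarray:
    """True for molecules within the interface band above the surface."""
    if frame.surface_top_z is None:
        return np.zeros(frame.n_molecules, dtype=bool)
    dz = frame.oxygen_positions[:, 2] - frame.surface_top_z
    return dz <= params.interface_z_cutoff


def classify(
    frame: Frame,
    params: Optional[DetectionParams] = None,
    require_surface: bool = False,
) -> PhaseLabelFrame:
    """Classify every molecule and fill in layers and the largest nucleus.

    Interface molecules (within ``interface_z_cutoff`` above
    ``surface_top_z``) use the 3-neighbour rules; the rhombic condition
    qbar4 > 0.6 takes precedence over the hexagonal one.  All other
    molecules use the 4-neighbour bulk rule and are never labelled rhombic.
    A frame with ``surface_top_z`` unset is treated as a homogeneous bulk
    system unless ``require_surface`` is set, in which case that is a
    configuration error.
    """
    params = params or DetectionParams()
    if frame.surface_top_z is None and require_surface:
        raise ConfigError("surface_top_z is unset but a surface was required")
    interface = _interface_mask(frame, params)
    n_per = np.where(interface, params.n_neighbors_interface, params.n_neighbors_bulk)
    nbrs = _all_neighbors(frame, n_per)
    qbar4 = _qbar_from_neighbors(frame, nbrs, 4)
    qbar6 = _qbar_from_neighbors(frame, nbrs, 6)

    labels = np.full(frame.n_molecules, Phase.LIQUID, dtype=np.int8)
    bulk = ~interface
    labels[bulk & (qbar6 > params.qbar6_bulk)] = Phase.HEX
    hex_if = interface & (qbar6 > params.qbar6_interface) & (qbar4 < params.qbar4_low)
    labels[hex_if] = Phase.HEX
    labels[interface & (qbar4 > params.qbar4_high)] = Phase.RHOMBIC  # precedence

    if frame.surface_top_z is not None:
        layer = assign_layers(frame, params)
    else:
        layer = np.zeros(frame.n_molecules, dtype=int)
    result = PhaseLabelFrame(
        labels=labels,
        layer=layer,
        largest_nucleus=np.empty(0, dtype=int),
        qbar4=qbar4,
        qbar6=qbar6,
    )
    result.largest_nucleus = largest_ice_cluster(result, frame, params.cluster_cutoff)
    return result


def largest_ice_cluster(
    labels: PhaseLabelFrame, frame: Frame, cutoff: float
) -> np.ndarray:
    """Largest connected cluster of ice-labelled molecules.

    Edges connect ice molecules whose minimum-image O-O distance is at most
    ``cutoff``.  Ties between equally large components go to the component
    containing the smallest molecule index.  Returns sorted indices (empty
    for an all-liquid frame).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ice = np.flatnonzero(labels.labels != Phase.LIQUID)
    if ice.size == 0:
        return np.empty(0, dtype=int)
    pos = frame.oxygen_positions[ice]
    n = len(ice)
    rows, cols = [], []
    for a in range(n):
        dr = minimum_image(pos - pos[a], frame.box, frame.periodic)
        close = np.flatnonzero((dr * dr).sum(axis=1) <= cutoff * cutoff)
        rows.extend([a] * len(close))
        cols.extend(close.tolist())
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, comp = connected_components(adj, directed=False)
    sizes = np.bincount(comp, minlength=n_comp)
    best = np.flatnonzero(sizes == sizes.max())
    if len(best) > 1:  # tie: component with the smallest member index wins
        first_member = [ice[comp == c].min() for c in best]
        best = [best[int(np.argmin(first_member))]]
    return np.sort(ice[comp == best[0]])


def assign_layers(frame: Frame, params: Optional[DetectionParams] = None) -> np.ndarray:
    """Layer index floor((z - surface_top_z)/layer_spacing), clamped at 0.

    Molecules more than 0.05 nm below the surface top trigger a geometry
    warning (and are clamped into layer 0).
    """
    params = params or DetectionParams()
    if frame.surface_top_z is None:
        raise ConfigError("assign_layers requires surface_top_z")
    dz = frame.oxygen_positions[:, 2] - frame.surface_top_z
    if np.any(dz < -0.05):
        warnings.warn(
            f"{int((dz < -0.05).sum())} molecules lie below the surface top; "
            "clamped into layer 0",
            stacklevel=2,
        )
    return np.maximum(np.floor(dz / params.layer_spacing).astype(int), 0)
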