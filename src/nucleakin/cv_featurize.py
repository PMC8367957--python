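"""Collective variables (CVs) from labelled frames.

The candidate pool holds 18 structural/geometric descriptors of the largest
ice nucleus and the layer-resolved ice populations; the 5-member subset
``SELECTED5`` (total ice and rhombic ice in the largest nucleus, hexagonal
ice of the nucleus in the 2nd, 3rd and upper layers) is the set that
describes the slow nucleation kinetics.  Layer numbering is 1-based in CV
names ("layer1" = contact layer, internal layer index 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._geometry import unwrap_cluster
from .errors import NucleakinError
from .ice_detect import Phase, PhaseLabelFrame
from .trajectory_io import Frame

POOL18 = (
    "n_ice_nucleus",
    "n_rhombic_nucleus",
    "n_hex_layer1",
    "n_hex_layer2",
    "n_hex_layer3",
    "n_hex_upper",
    "n_rhombic_layer1",
    "n_rhombic_layer2",
    "n_rhombic_layer3",
    "n_rhombic_upper",
    "n_hex_total",
    "n_rhombic_total",
    "n_ice_total",
    "n_hex_nucleus",
    "max_layer_occupied",
    "nucleus_xy_extent",
    "nucleus_height",
    "sphericity",
)

SELECTED5 = (
    "n_ice_nucleus",
    "n_rhombic_nucleus",
    "n_hex_layer2",
    "n_hex_layer3",
    "n_hex_upper",
)


@dataclass
class CVSeries:
    """Per-frame CV vectors as a DataFrame plus the frame stride in ps."""

    data: pd.DataFrame
    stride: float = 1.0

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise NucleakinError("CVSeries must not contain missing values")
        if len(set(self.data.columns)) != len(self.data.columns):
            raise NucleakinError("CV names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, names: Sequence[str]) -> "CVSeries":
        return CVSeries(data=self.data.loc[:, list(names)].copy(), stride=self.stride)


def sphericity(nucleus_positions: np.ndarray, frame: Frame) -> float:
    """Shape anisotropy of a nucleus: smallest/largest gyration eigenvalue.

    1 for a spherically symmetric cluster, 0 for a coplanar or collinear
    one.  Positions are minimum-image unwrapped before the gyration tensor
    is formed.  Fewer than 4 molecules leave the shape undefined; returns 0
    with a warning.
    """
    nucleus_positions = np.asarray(nucleus_positions, dtype=float)
    if len(nucleus_positions) < 4:
        warnings.warn("sphericity undefined for < 4 molecules; returning 0", stacklevel=2)
        return 0.0
    pos = unwrap_cluster(nucleus_positions, frame.box, frame.periodic)
    centered = pos - pos.mean(axis=0)
    gyr = centered.T @ centered / len(pos)
    ev = np.linalg.eigvalsh(gyr)
    if ev[-1] <= 0:
        return 0.0
    return float(max(ev[0], 0.0) / ev[-1])


def _frame_cv_row(
    plf: PhaseLabelFrame, frame: Optional[Frame]
) -> dict[str, float]:
    labels = plf.labels
    layer = plf.layer
    in_nuc = np.zeros(len(labels), dtype=bool)
    in_nuc[plf.largest_nucleus] = True
    hexm = labels == Phase.HEX
    rhm = labels == Phase.RHOMBIC
    ice = hexm | rhm

    def layer_count(mask: np.ndarray, lo: int, hi: Optional[int]) -> int:
        sel = mask & in_nuc & (layer >= lo)
        if hi is not None:
            sel &= layer <= hi
        return int(sel.sum())

    row = {
        "n_ice_nucleus": int(in_nuc.sum()),
        "n_rhombic_nucleus": int((rhm & in_nuc).sum()),
        "n_hex_layer1": layer_count(hexm, 0, 0),
        "n_hex_layer2": layer_count(hexm, 1, 1),
        "n_hex_layer3": layer_count(hexm, 2, 2),
        "n_hex_upper": layer_count(hexm, 3, None),
        "n_rhombic_layer1": layer_count(rhm, 0, 0),
        "n_rhombic_layer2": layer_count(rhm, 1, 1),
        "n_rhombic_layer3": layer_count(rhm, 2, 2),
        "n_rhombic_upper": layer_count(rhm, 3, None),
        "n_hex_total": int(hexm.sum()),
        "n_rhombic_total": int(rhm.sum()),
        "n_ice_total": int(ice.sum()),
        "n_hex_nucleus": int((hexm & in_nuc).sum()),
        "max_layer_occupied": int(layer[ice].max()) + 1 if ice.any() else 0,
    }
    if frame is not None and len(plf.largest_nucleus) >= 2:
        pos = unwrap_cluster(
            frame.oxygen_positions[plf.largest_nucleus], frame.box, frame.periodic
        )
        row["nucleus_xy_extent"] = float(
            max(np.ptp(pos[:, 0]), np.ptp(pos[:, 1]))
        )
        row["nucleus_height"] = float(np.ptp(pos[:, 2]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            row["sphericity"] = sphericity(frame.oxygen_positions[plf.largest_nucleus], frame)
    else:
        row["nucleus_xy_extent"] = 0.0
        row["nucleus_height"] = 0.0
        row["sphericity"] = 0.0
    return row


def compute_cvs(
    labels: Sequence[PhaseLabelFrame],
    mode: str = "pool18",
    frames: Optional[Sequence[Frame]] = None,
    stride: float = 1.0,
) -> CVSeries:
    """Compute per-frame CV vectors.

    ``mode="pool18"`` yields the full candidate pool; ``mode="selected5"``
    the five slow-dynamics CVs (a pure column subset of the pool).  The
    geometric pool members (extent, height, sphericity) require ``frames``;
    without coordinates they are reported as 0.
    """
    if mode not in ("pool18", "selected5"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = list(labels)
    if not labels:
        raise NucleakinError("compute_cvs requires at least one labelled frame")
    if frames is not None and len(frames) != len(labels):
        raise NucleakinError("frames and labels sequences differ in length")
    rows = [
        _frame_cv_row(plf, frames[k] if frames is not None else None)
        for k, plf in enumerate(labels)
    ]
    df = pd.DataFrame(rows, columns=list(POOL18))
    series = CVSeries(data=df, stride=stride)
    if mode == "selected5":
        return series.subset(SELECTED5)
    return series
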