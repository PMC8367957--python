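"""Minimum-image helpers for orthorhombic periodic boxes."""

from __future__ import annotations

import numpy as np


def minimum_image(dr: np.ndarray, box: np.ndarray, periodic: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Parameters
    ----------
    dr : (..., 3) displacements in nm.
    box : (3,) orthorhombic box lengths in nm.
    periodic : (3,) booleans, per-axis periodicity.
    """
    dr = np.array(dr, dtype=float, copy=True)
    for d in range(3):
        if periodic[d]:
            dr[..., d] -= box[d] * np.round(dr[..., d] / box[d])
    return dr


def minimum_image_distance(
    a: np.ndarray, b: np.ndarray, box: np.ndarray, periodic: np.ndarray
) -> np.ndarray:
    """Pairwise minimum-image distances between points ``a`` and a point ``b``."""
    dr = minimum_image(np.asarray(a) - np.asarray(b), box, periodic)
    return np.sqrt((dr * dr).sum(axis=-1))


def unwrap_cluster(
    positions: np.ndarray, box: np.ndarray, periodic: np.ndarray
) -> np.ndarray:
    """Unwrap a compact cluster around its first member.

    Valid while the cluster diameter is below half the box in every periodic
    direction; larger (percolating) clusters cannot be unwrapped unambiguously.
    """
    positions = np.asarray(positions, dtype=float)
    ref = positions[0]
    return ref + minimum_image(positions - ref, box, periodic)
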