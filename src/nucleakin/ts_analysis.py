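"""Transition-state ensemble statistics.

Characterizes critical-nucleus ensembles selected by committor analysis:
mean hexagonal/rhombic composition of the largest nucleus, the
disorderliness (rhombic-to-hexagonal count ratio), and the mean potential
energy per nucleus molecule, each with bootstrap standard errors.
Potential energies are consumed from a table produced by the user's MD
toolchain; no force field is evaluated here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import NucleakinError
from .ice_detect import Phase, PhaseLabelFrame


@dataclass
class NucleusStats:
    n_hex: float
    n_rhombic: float
    disorderliness: float
    mean_pe_per_molecule: float
    se_n_hex: float
    se_n_rhombic: float
    se_disorderliness: float
    se_pe: float
    n_frames: int


def disorderliness(n_rhombic: float, n_hex: float) -> float:
    """Rhombic-to-hexagonal count ratio of a nucleus."""
    if n_hex <= 0:
        raise ValueError("disorderliness undefined for a nucleus without hexagonal ice")
    return float(n_rhombic) / float(n_hex)


def bootstrap_se(values: Sequence[float], n_boot: int = 200, seed: int = 0) -> float:
    """Bootstrap standard error of the mean (resampling with replacement)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("bootstrap_se requires at least one value")
    rng = np.random.default_rng(seed)
    idx = rng.integers(values.size, size=(n_boot, values.size))
    return float(values[idx].mean(axis=1).std(ddof=0))


def ts_ensemble_stats(
    labels: Sequence[PhaseLabelFrame],
    pe_table: Optional[Sequence[float]] = None,
    n_boot: int = 200,
    seed: int = 0,
) -> NucleusStats:
    """Composition and energy statistics over a transition-state ensemble.

    ``labels`` holds the frames assigned to the TS microstates; ``pe_table``
    the per-frame mean potential energy per nucleus molecule (kJ/mol),
    aligned with ``labels`` (may be omitted, yielding NaN energy fields).
    The disorderliness is the ratio of the ensemble-mean counts.
    """
    labels = list(labels)
    if not labels:
        raise NucleakinError("empty transition-state ensemble")
    if pe_table is not None:
        pe = np.asarray(pe_table, dtype=float)
        if pe.shape != (len(labels),):
            raise NucleakinError(
                f"energy table has {pe.size} entries for {len(labels)} frames"
            )
    else:
        pe = None

    n_hex = np.empty(len(labels))
    n_rh = np.empty(len(labels))
    for k, plf in enumerate(labels):
        nuc = plf.largest_nucleus
        n_hex[k] = int((plf.labels[nuc] == Phase.HEX).sum())
        n_rh[k] = int((plf.labels[nuc] == Phase.RHOMBIC).sum())
    mean_hex = float(n_hex.mean())
    mean_rh = float(n_rh.mean())

    rng = np.random.default_rng(seed)
    idx = rng.integers(len(labels), size=(n_boot, len(labels)))
    boot_hex = n_hex[idx].mean(axis=1)
    boot_rh = n_rh[idx].mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        boot_dis = np.where(boot_hex > 0, boot_rh / boot_hex, np.nan)
    if pe is not None:
        boot_pe = pe[idx].mean(axis=1)
        mean_pe, se_pe = float(pe.mean()), float(boot_pe.std(ddof=0))
    else:
        mean_pe, se_pe = float("nan"), float("nan")

    return NucleusStats(
        n_hex=mean_hex,
        n_rhombic=mean_rh,
        disorderliness=disorderliness(mean_rh, mean_hex) if mean_hex > 0 else float("nan"),
        mean_pe_per_molecule=mean_pe,
        se_n_hex=float(boot_hex.std(ddof=0)),
        se_n_rhombic=float(boot_rh.std(ddof=0)),
        se_disorderliness=float(np.nanstd(boot_dis, ddof=0)),
        se_pe=se_pe,
        n_frames=len(labels),
    )
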