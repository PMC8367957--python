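"""Read and write molecular configurations and per-molecule label tables.

Coordinates are stored in nanometres internally.  Supported on-disk formats
are plain/extended XYZ, orthorhombic LAMMPS text dumps, and tab-separated
label tables.  Triclinic cells are rejected explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ConfigError, FormatError, ParseError, StructureError

#: Default LAMMPS dump length unit is Angstrom; internal unit is nm.
ANGSTROM_TO_NM = 0.1

# Species roles recognised by the parsers.
OXYGEN = "O"
HYDROGEN = "H"
SURFACE = "surface"


@dataclass
class Frame:
    """One molecular configuration.

    Attributes
    ----------
    oxygen_positions : (N, 3) float array, nm.
    box : (3,) orthorhombic box lengths, nm.
    periodic : (3,) booleans.
    time : frame time in ps.
    hydrogen_positions : optional (2N, 3) float array, nm.
    surface_top_z : z of the topmost fixed surface-atom layer (nm), or None
        for a homogeneous (surface-free) system.
    """

    oxygen_positions: np.ndarray
    box: np.ndarray
    periodic: np.ndarray = field(default_factory=lambda: np.array([True, True, True]))
    time: float = 0.0
    hydrogen_positions: Optional[np.ndarray] = None
    surface_top_z: Optional[float] = None

    def __post_init__(self) -> None:
        self.oxygen_positions = np.asarray(self.oxygen_positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.periodic = np.asarray(self.periodic, dtype=bool)
        if self.oxygen_positions.ndim != 2 or self.oxygen_positions.shape[1] != 3:
            raise StructureError("oxygen_positions must have shape (N, 3)")
        if self.n_molecules < 1:
            raise StructureError("a Frame requires at least one molecule")
        if not np.all(np.isfinite(self.oxygen_positions)):
            raise StructureError("non-finite coordinates")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise StructureError("box must be three positive lengths")
        if self.hydrogen_positions is not None:
            self.hydrogen_positions = np.asarray(self.hydrogen_positions, dtype=float)
            if len(self.hydrogen_positions) != 2 * self.n_molecules:
                raise StructureError(
                    "expected 2 hydrogens per water molecule, got "
                    f"{len(self.hydrogen_positions)} for {self.n_molecules} oxygens"
                )

    @property
    def n_molecules(self) -> int:
        return len(self.oxygen_positions)


@dataclass
class Trajectory:
    """An ordered, uniformly spaced sequence of frames."""

    frames: list[Frame]
    stride: float = 1.0  # ps between consecutive frames

    def __post_init__(self) -> None:
        if not self.frames:
            raise StructureError("a Trajectory must contain at least one frame")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


def _classify_species(symbol: str, species_map: Optional[dict]) -> str:
    if species_map is not None:
        try:
            return species_map[symbol]
        except KeyError:
            raise ConfigError(f"species {symbol!r} missing from species map") from None
    if symbol.upper() == "O":
        return OXYGEN
    if symbol.upper() == "H":
        return HYDROGEN
    return SURFACE


def read_xyz(
    path,
    box: Optional[Sequence[float]] = None,
    stride: float = 1.0,
    species_map: Optional[dict] = None,
    length_scale: float = 1.0,
) -> Trajectory:
    """Read a plain or extended XYZ file into a :class:`Trajectory`.

    The element column assigns atom roles: ``O`` and ``H`` are water atoms,
    anything else is a surface atom (override with ``species_map``).  Surface
    atoms are excluded from ``oxygen_positions``; their maximum z is recorded
    as ``surface_top_z``.  The box is taken from an extended-XYZ ``Lattice``
    entry when present, otherwise from the ``box`` argument.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    ln = 0
    n_oxy_ref = None
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            natoms = int(lines[ln].strip())
        except ValueError:
            raise ParseError(
                f"line {ln + 1}: expected an atom count, got {lines[ln]!r}"
            ) from None
        comment = lines[ln + 1] if ln + 1 < len(lines) else ""
        frame_box = _parse_lattice(comment)
        if frame_box is None:
            if box is None:
                raise ConfigError("no box given and no Lattice entry in XYZ comment")
            frame_box = np.asarray(box, dtype=float)
        if ln + 1 + natoms >= len(lines) + 0 and ln + 2 + natoms > len(lines):
            raise ParseError(f"line {ln + 1}: truncated XYZ block ({natoms} atoms declared)")
        oxy, hyd, surf_z = [], [], []
        for k in range(natoms):
            parts = lines[ln + 2 + k].split()
            if len(parts) < 4:
                raise ParseError(f"line {ln + 3 + k}: expected 'element x y z'")
            role = _classify_species(parts[0], species_map)
            try:
                xyz = np.array([float(v) for v in parts[1:4]]) * length_scale
            except ValueError:
                raise ParseError(f"line {ln + 3 + k}: bad coordinate") from None
            if role == OXYGEN:
                oxy.append(xyz)
            elif role == HYDROGEN:
                hyd.append(xyz)
            else:
                surf_z.append(xyz[2])
        if not oxy:
            raise StructureError(f"XYZ block at line {ln + 1} contains no oxygen atoms")
        if n_oxy_ref is None:
            n_oxy_ref = len(oxy)
        elif len(oxy) != n_oxy_ref:
            raise StructureError(
                f"inconsistent oxygen count across frames: {len(oxy)} vs {n_oxy_ref}"
            )
        if surf_z:
            top_z = max(surf_z)
        else:  # no explicit surface atoms: fall back to the comment entry
            top_z = _parse_comment_scalar(comment, "Surface_top_z=")
        frames.append(
            Frame(
                oxygen_positions=np.array(oxy),
                box=frame_box,
                time=len(frames) * stride,
                hydrogen_positions=np.array(hyd) if hyd else None,
                surface_top_z=top_z,
            )
        )
        ln += 2 + natoms
    if not frames:
        raise ParseError("empty XYZ file")
    return Trajectory(frames=frames, stride=stride)


def _parse_comment_scalar(comment: str, key: str) -> Optional[float]:
    pos = comment.find(key)
    if pos < 0:
        return None
    return float(comment[pos + len(key):].split()[0])


def _parse_lattice(comment: str) -> Optional[np.ndarray]:
    """Extract an orthorhombic box from an extended-XYZ Lattice entry."""
    key = "Lattice="
    pos = comment.find(key)
    if pos < 0:
        return None
    rest = comment[pos + len(key):]
    quote = rest[0] if rest and rest[0] in "\"'" else None
    val = rest[1:rest.index(quote, 1)] if quote else rest.split()[0]
    nums = np.array([float(v) for v in val.split()])
    if nums.size != 9:
        raise FormatError("Lattice entry must hold 9 numbers")
    mat = nums.reshape(3, 3)
    if np.abs(mat - np.diag(np.diag(mat))).max() > 1e-10:
        raise FormatError("triclinic lattice in XYZ comment; orthorhombic cells only")
    return np.diag(mat).astype(float)


def write_xyz(traj: Trajectory, path, precision: int = 8) -> None:
    """Write oxygen (and hydrogen) coordinates as extended XYZ, nm units."""
    with open(path, "w") as fh:
        for frame in traj:
            n = frame.n_molecules + (
                len(frame.hydrogen_positions) if frame.hydrogen_positions is not None else 0
            )
            lat = "Lattice=\"%g 0 0 0 %g 0 0 0 %g\"" % tuple(frame.box)
            surf = (" Surface_top_z=%.8f" % frame.surface_top_z
                    if frame.surface_top_z is not None else "")
            fh.write(f"{n}\n{lat} Properties=species:S:1:pos:R:3 "
                     f"Time={frame.time}{surf}\n")
            for p in frame.oxygen_positions:
                fh.write("O %.*f %.*f %.*f\n" % (precision, p[0], precision, p[1], precision, p[2]))
            if frame.hydrogen_positions is not None:
                for p in frame.hydrogen_positions:
                    fh.write("H %.*f %.*f %.*f\n" % (precision, p[0], precision, p[1], precision, p[2]))


def read_lammps_dump(
    path,
    type_map: Optional[dict] = None,
    length_scale: float = ANGSTROM_TO_NM,
    stride: float = 1.0,
) -> Trajectory:
    """Read an orthorhombic LAMMPS text dump.

    ``type_map`` maps integer atom types to roles ``"O"``, ``"H"`` or
    ``"surface"`` (default ``{1: "O", 2: "H"}``).  Scaled coordinates
    (``xs ys zs``) are unscaled with the box bounds.  Atoms are sorted by id.
    Dump lengths are assumed to be Angstrom and converted to nm
    (``length_scale=0.1``); pass ``length_scale=1.0`` for nm dumps.
    """
    if type_map is None:
        type_map = {1: OXYGEN, 2: HYDROGEN}
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    ln = 0
    n_oxy_ref = None
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        if not lines[ln].startswith("ITEM: TIMESTEP"):
            raise FormatError(f"line {ln + 1}: expected 'ITEM: TIMESTEP'")
        timestep = int(lines[ln + 1])
        if not lines[ln + 2].startswith("ITEM: NUMBER OF ATOMS"):
            raise FormatError(f"line {ln + 3}: expected 'ITEM: NUMBER OF ATOMS'")
        natoms = int(lines[ln + 3])
        bounds_header = lines[ln + 4]
        if not bounds_header.startswith("ITEM: BOX BOUNDS"):
            raise FormatError(f"line {ln + 5}: missing 'ITEM: BOX BOUNDS'")
        if "xy" in bounds_header or "xz" in bounds_header or "yz" in bounds_header:
            raise FormatError("triclinic BOX BOUNDS; orthorhombic dumps only")
        lo = np.empty(3)
        hi = np.empty(3)
        for d in range(3):
            parts = lines[ln + 5 + d].split()
            if len(parts) < 2:
                raise FormatError(f"line {ln + 6 + d}: bad BOX BOUNDS line")
            lo[d], hi[d] = float(parts[0]), float(parts[1])
        atoms_header = lines[ln + 8]
        if not atoms_header.startswith("ITEM: ATOMS"):
            raise FormatError(f"line {ln + 9}: expected 'ITEM: ATOMS'")
        cols = atoms_header.split()[2:]
        col_idx = {c: k for k, c in enumerate(cols)}
        scaled = "xs" in col_idx
        needed = ("id", "type") + (("xs", "ys", "zs") if scaled else ("x", "y", "z"))
        for c in needed:
            if c not in col_idx:
                raise FormatError(f"dump lacks required column {c!r}")
        box = (hi - lo) * length_scale
        records = []
        for k in range(natoms):
            parts = lines[ln + 9 + k].split()
            aid = int(parts[col_idx["id"]])
            atype = int(parts[col_idx["type"]])
            if atype not in type_map:
                raise ConfigError(f"atom type {atype} has no entry in the type map")
            if scaled:
                frac = np.array([float(parts[col_idx[c]]) for c in ("xs", "ys", "zs")])
                xyz = (lo + frac * (hi - lo)) * length_scale
            else:
                xyz = np.array([float(parts[col_idx[c]]) for c in ("x", "y", "z")]) * length_scale
            records.append((aid, type_map[atype], xyz))
        records.sort(key=lambda r: r[0])
        oxy = np.array([r[2] for r in records if r[1] == OXYGEN])
        hyd = np.array([r[2] for r in records if r[1] == HYDROGEN])
        surf = [r[2][2] for r in records if r[1] == SURFACE]
        if len(oxy) == 0:
            raise StructureError(f"dump frame at line {ln + 1} contains no oxygens")
        if n_oxy_ref is None:
            n_oxy_ref = len(oxy)
        elif len(oxy) != n_oxy_ref:
            raise StructureError("inconsistent oxygen count across dump frames")
        frames.append(
            Frame(
                oxygen_positions=oxy,
                box=box,
                time=float(timestep),
                hydrogen_positions=hyd if len(hyd) else None,
                surface_top_z=max(surf) if surf else None,
            )
        )
        ln += 9 + natoms
    if not frames:
        raise ParseError("empty LAMMPS dump")
    return Trajectory(frames=frames, stride=stride)


def write_lammps_dump(traj: Trajectory, path, length_scale: float = ANGSTROM_TO_NM) -> None:
    """Write oxygens as a minimal orthorhombic LAMMPS dump (type 1 = O)."""
    with open(path, "w") as fh:
        for idx, frame in enumerate(traj):
            fh.write("ITEM: TIMESTEP\n%d\n" % idx)
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % frame.n_molecules)
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for d in range(3):
                fh.write("0.0 %.10f\n" % (frame.box[d] / length_scale))
            fh.write("ITEM: ATOMS id type x y z\n")
            for i, p in enumerate(frame.oxygen_positions, start=1):
                fh.write(
                    "%d 1 %.10f %.10f %.10f\n"
                    % (i, p[0] / length_scale, p[1] / length_scale, p[2] / length_scale)
                )


# ---------------------------------------------------------------------------
# label tables

LABEL_HEADER = "frame\tmolecule\tlabel\tlayer\tin_nucleus"


def write_labels(labels: Sequence, path) -> None:
    """Write a sequence of per-frame phase labels as a TSV table.

    One row per molecule per frame with columns
    ``frame, molecule, label, layer, in_nucleus``.
    """
    from .ice_detect import Phase  # local import to avoid a cycle

    labels = list(labels)
    if not labels:
        raise ValueError("write_labels requires a non-empty label sequence")
    with open(path, "w") as fh:
        fh.write(LABEL_HEADER + "\n")
        for f_idx, plf in enumerate(labels):
            nucleus = set(int(i) for i in plf.largest_nucleus)
            for m_idx in range(len(plf.labels)):
                fh.write(
                    f"{f_idx}\t{m_idx}\t{Phase(plf.labels[m_idx]).name}\t"
                    f"{int(plf.layer[m_idx])}\t{int(m_idx in nucleus)}\n"
                )


def read_labels(path) -> list:
    """Inverse of :func:`write_labels` (q-bar columns are not round-tripped)."""
    from .ice_detect import Phase, PhaseLabelFrame

    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != LABEL_HEADER:
        raise FormatError("label table lacks the expected header line")
    per_frame: dict[int, list] = {}
    for ln, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 5:
            raise ParseError(f"line {ln}: expected 5 tab-separated fields")
        f_idx = int(parts[0])
        per_frame.setdefault(f_idx, []).append(
            (int(parts[1]), Phase[parts[2]], int(parts[3]), int(parts[4]))
        )
    out = []
    for f_idx in sorted(per_frame):
        rows = sorted(per_frame[f_idx])
        lab = np.array([r[1] for r in rows], dtype=np.int8)
        layer = np.array([r[2] for r in rows], dtype=int)
        nucleus = np.array([r[0] for r in rows if r[3]], dtype=int)
        out.append(
            PhaseLabelFrame(
                labels=lab,
                layer=layer,
                largest_nucleus=nucleus,
                qbar4=np.full(len(rows), np.nan),
                qbar6=np.full(len(rows), np.nan),
            )
        )
    return out
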