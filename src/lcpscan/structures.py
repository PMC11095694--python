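"""Molecular structures, trajectories and PDB/XYZ input-output.

Coordinates are in Å throughout.  Residue numbering follows the input file;
nothing is renumbered.  Multi-model PDB files are the trajectory format of
the package (``MODEL``/``ENDMDL`` blocks), alongside plain XYZ blocks read
against a known topology.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "MolecularStructure",
    "Trajectory",
    "PDBParseError",
    "PDBFormatError",
    "read_pdb",
    "write_pdb",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "strip_species",
    "assign_radii",
    "load_radius_table",
]

# Residue names treated as water by the selection keyword `water`.
WATER_RESNAMES = {"HOH", "WAT", "TIP3", "TIP", "SOL", "H2O"}

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HIE", "HID", "HIP", "CYX", "ASH", "GLH", "LYN",
}


class PDBParseError(ValueError):
    """Raised when a PDB record cannot be parsed; names the offending line."""


class PDBFormatError(ValueError):
    """Raised when a structure cannot be represented in fixed-column PDB."""


@dataclass
class Atom:
    """A single atom with optional geometry/energy parameters.

    ``vdw_radius`` (Å), ``partial_charge`` (e), ``lj_epsilon`` (kcal/mol)
    and ``lj_rmin_half`` (Å) stay ``None`` until a parameter set assigns
    them.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    vdw_radius: float | None = None
    partial_charge: float | None = None
    lj_epsilon: float | None = None
    lj_rmin_half: float | None = None
    record: str = "ATOM"
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive when set")
        if self.lj_epsilon is not None and self.lj_epsilon < 0:
            raise ValueError("lj_epsilon must be non-negative when set")


class MolecularStructure:
    """An ordered collection of atoms with an optional bond list."""

    def __init__(self, atoms: Sequence[Atom], bonds: Sequence[tuple[int, int]] | None = None):
        self.atoms: list[Atom] = list(atoms)
        self.bonds: list[tuple[int, int]] = [tuple(b) for b in bonds] if bonds else []
        n = len(self.atoms)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) references atom outside 0..{n - 1}")

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Å. A fresh copy each call."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, xyz in zip(self.atoms, coords):
            atom.position = xyz.copy()

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def radii(self) -> np.ndarray:
        """Per-atom vdW radii; raises if any atom has none assigned."""
        missing = [a.serial for a in self.atoms if a.vdw_radius is None]
        if missing:
            raise ValueError(f"atoms without vdw_radius (serials): {missing[:10]}")
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def residue_index(self) -> dict[tuple[str, int], list[int]]:
        """Mapping (chain_id, residue_number) -> atom indices, file order."""
        index: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            index.setdefault((a.chain_id, a.residue_number), []).append(i)
        return index

    def subset(self, indices: Iterable[int]) -> "MolecularStructure":
        """New structure with the selected atoms; bonds are re-mapped and
        those crossing the selection boundary dropped."""
        idx = list(indices)
        old_to_new = {old: new for new, old in enumerate(idx)}
        atoms = [replace(self.atoms[i], position=self.atoms[i].position.copy()) for i in idx]
        bonds = [
            (old_to_new[i], old_to_new[j])
            for i, j in self.bonds
            if i in old_to_new and j in old_to_new
        ]
        return MolecularStructure(atoms, bonds)

    def copy(self) -> "MolecularStructure":
        return self.subset(range(self.n_atoms))

    def select(self, expression: str) -> np.ndarray:
        from .selection import select

        return select(self, expression)


@dataclass
class Trajectory:
    """A reference topology plus per-frame coordinates.

    ``frames`` has shape (n_frames, n_atoms, 3); ``box`` is an optional
    (n_frames, 3) array of orthorhombic box edge lengths, Å.
    """

    topology: MolecularStructure
    frames: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames have {self.frames.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("trajectory coordinates must be finite")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.n_frames, 3):
                raise ValueError("box must have shape (n_frames, 3)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame_structure(self, i: int) -> MolecularStructure:
        s = self.topology.copy()
        s.set_coords(self.frames[i])
        return s


# ---------------------------------------------------------------------------
# PDB input/output (fixed-column)
# ---------------------------------------------------------------------------

def _guess_element(name: str) -> str:
    stripped = name.strip()
    if not stripped:
        return "X"
    # Two-letter elements appear with the first character in column 13.
    if len(name) >= 2 and name[0] != " " and not name[0].isdigit():
        two = name[:2].strip().upper()
        if two in {"FE", "ZN", "MG", "MN", "CU", "NA", "CL", "BR", "CA"}:
            return two
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _parse_atom_line(line: str, lineno: int) -> Atom:
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0  # serials may overflow; not load-bearing
    name = line[12:16]
    altloc = line[16].strip()
    resname = line[17:20].strip() or line[17:21].strip()
    chain = line[21].strip() or " "
    try:
        resnum = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed coordinate columns: {line.rstrip()!r}") from exc
    try:
        occupancy = float(line[54:60])
    except (ValueError, IndexError):
        occupancy = 1.0
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element:
        element = _guess_element(name)
    return Atom(
        serial=serial,
        name=name.strip(),
        element=element,
        residue_name=resname,
        residue_number=resnum,
        chain_id=chain,
        position=np.array([x, y, z]),
        record="HETATM" if line.startswith("HETATM") else "ATOM",
        altloc=altloc,
        occupancy=occupancy,
    )


def _resolve_altloc(atoms: list[Atom]) -> list[Atom]:
    """Keep the highest-occupancy altloc per atom identity; ties break by
    altloc label order.  Atoms without an altloc label pass through
    untouched (they are never merged)."""
    best: dict[tuple, int] = {}
    order: list[int | tuple] = []
    for i, a in enumerate(atoms):
        if not a.altloc:
            order.append(i)
            continue
        key = (a.chain_id, a.residue_number, a.residue_name, a.name)
        if key not in best:
            best[key] = i
            order.append(key)
        else:
            b = atoms[best[key]]
            if (a.occupancy, _neg_label(a.altloc)) > (b.occupancy, _neg_label(b.altloc)):
                best[key] = i
    return [atoms[item] if isinstance(item, int) else atoms[best[item]] for item in order]


def _neg_label(label: str) -> tuple:
    # Sort helper: earlier altloc labels win ties, so invert for max().
    return tuple(-ord(c) for c in (label or "~"))


def read_pdb(
    path: str | Path,
    chain_filter: str | None = None,
    model_policy: str = "first",
) -> MolecularStructure | Trajectory:
    """Read a PDB file.

    With ``model_policy='all'`` and more than one ``MODEL`` block the result
    is a :class:`Trajectory` whose topology is the first model.  HETATM
    records (heme, ligands) are retained; altloc duplicates resolve to the
    highest-occupancy record.
    """
    if model_policy not in ("first", "all"):
        raise ValueError("model_policy must be 'first' or 'all'")
    path = Path(path)
    models: list[list[Atom]] = []
    current: list[Atom] = []
    in_model = False
    box: list[float] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                atom = _parse_atom_line(line, lineno)
                if chain_filter is not None and atom.chain_id != chain_filter:
                    continue
                current.append(atom)
            elif line.startswith("CRYST1"):
                try:
                    box = [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                except ValueError:
                    box = None
            elif line.startswith("MODEL"):
                in_model = True
                if current:
                    models.append(current)
                    current = []
            elif line.startswith("ENDMDL"):
                models.append(current)
                current = []
            elif line.startswith("END") and not in_model and current:
                models.append(current)
                current = []
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise ValueError(f"{path}: no atoms read" + (f" (chain filter {chain_filter!r})" if chain_filter else ""))

    models = [_resolve_altloc(m) for m in models]
    first = MolecularStructure(models[0])
    if model_policy == "first" or len(models) == 1:
        return first
    n = first.n_atoms
    for k, m in enumerate(models):
        if len(m) != n:
            raise ValueError(f"{path}: model {k + 1} has {len(m)} atoms, expected {n}")
    frames = np.array([[a.position for a in m] for m in models])
    boxes = np.tile(np.asarray(box, dtype=float), (len(models), 1)) if box else None
    return Trajectory(first, frames, box=boxes)


def _format_atom_line(a: Atom, serial: int) -> str:
    x, y, z = a.position
    for v in (x, y, z):
        if not (-999.999 <= v <= 9999.999):
            raise PDBFormatError(f"coordinate {v:.3f} exceeds PDB fixed-width range")
    if not (-999 <= a.residue_number <= 9999):
        raise PDBFormatError(f"residue number {a.residue_number} exceeds PDB range")
    if not (0 <= serial <= 99999):
        raise PDBFormatError(f"serial {serial} exceeds PDB range")
    name = a.name
    if len(name) < 4:
        # Standard alignment: 1-2 letter element names start in column 14.
        name = f" {name:<3s}" if len(a.element) == 1 else f"{name:<4s}"
    record = "HETATM" if a.record == "HETATM" else "ATOM  "
    return (
        f"{record}{serial:>5d} {name:<4.4s}{a.altloc or ' ':1.1s}{a.residue_name:<4.4s}"
        f"{a.chain_id:1.1s}{a.residue_number:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}          "
        f"{a.element:>2.2s}\n"
    )


def write_pdb(
    structure: MolecularStructure | Trajectory,
    path: str | Path,
    box: np.ndarray | None = None,
) -> None:
    """Write a structure (single block) or trajectory (MODEL/ENDMDL blocks)."""
    path = Path(path)
    with open(path, "w") as fh:
        if isinstance(structure, Trajectory):
            if structure.box is not None:
                b = structure.box[0]
                fh.write(f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}  90.00  90.00  90.00 P 1           1\n")
            for k in range(structure.n_frames):
                fh.write(f"MODEL     {k + 1:>4d}\n")
                for i, a in enumerate(structure.topology.atoms):
                    clone = replace(a, position=structure.frames[k, i])
                    fh.write(_format_atom_line(clone, i + 1))
                fh.write("ENDMDL\n")
        else:
            if box is not None:
                fh.write(f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}  90.00  90.00  90.00 P 1           1\n")
            for i, a in enumerate(structure.atoms):
                fh.write(_format_atom_line(a, i + 1))
        fh.write("END\n")


# ---------------------------------------------------------------------------
# XYZ trajectory input/output
# ---------------------------------------------------------------------------

def read_xyz_trajectory(path: str | Path, topology: MolecularStructure) -> Trajectory:
    """Read a multi-frame XYZ file against a known topology.

    Every block must contain exactly the topology's atom count, and element
    symbols must match the topology atom-for-atom.
    """
    path = Path(path)
    n = topology.n_atoms
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame_index = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        frame_index += 1
        try:
            count = int(lines[pos].split()[0])
        except ValueError as exc:
            raise ValueError(f"frame {frame_index}: bad atom-count line {pos + 1}") from exc
        if count != n:
            raise ValueError(f"frame {frame_index}: has {count} atoms, topology has {n}")
        block = lines[pos + 2 : pos + 2 + count]
        if len(block) < count:
            raise ValueError(f"frame {frame_index}: truncated block")
        coords = np.empty((n, 3))
        for i, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"frame {frame_index}: short atom line: {line!r}")
            if parts[0].upper() != topology.atoms[i].element.upper():
                raise ValueError(
                    f"frame {frame_index}: element {parts[0]!r} at atom {i} "
                    f"does not match topology {topology.atoms[i].element!r}"
                )
            coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(coords)
        pos += 2 + count
    if not frames:
        raise ValueError(f"{path}: no frames read")
    return Trajectory(topology, np.array(frames))


def write_xyz_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for k in range(trajectory.n_frames):
            fh.write(f"{trajectory.n_atoms}\nframe {k + 1}\n")
            for atom, xyz in zip(trajectory.topology.atoms, trajectory.frames[k]):
                fh.write(f"{atom.element:<2s} {xyz[0]:14.6f} {xyz[1]:14.6f} {xyz[2]:14.6f}\n")


# ---------------------------------------------------------------------------
# Structure editing and parameter assignment
# ---------------------------------------------------------------------------

def strip_species(structure: MolecularStructure, residue_names: Sequence[str]) -> MolecularStructure:
    """Remove all atoms of the listed residue names (e.g. co-crystallized
    imidazole, diols, waters).  Absent names are a no-op."""
    drop = {r.upper() for r in residue_names}
    keep = [i for i, a in enumerate(structure.atoms) if a.residue_name.upper() not in drop]
    return structure.subset(keep)


def load_radius_table(name_or_path: str | Path = "united") -> dict[str, float]:
    """Load a vdW radius table (element -> Å).

    ``"united"`` and ``"bondi"`` name the bundled tables; any other value is
    read as a two-column text file path.
    """
    bundled = {"united": "vdw_radii_united.tsv", "bondi": "vdw_radii_bondi.tsv"}
    if str(name_or_path) in bundled:
        ref = importlib.resources.files("lcpscan.data") / bundled[str(name_or_path)]
        text = ref.read_text()
    else:
        text = Path(name_or_path).read_text()
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        element, radius = line.split()
        table[element.upper()] = float(radius)
    return table


def assign_radii(
    structure: MolecularStructure,
    radius_set: str | dict[str, float] = "united",
    default: float | None = None,
) -> MolecularStructure:
    """Return a copy with every atom's ``vdw_radius`` set from a table.

    Unknown elements fall back to ``default``; with no default they raise,
    listing the offending elements.
    """
    table = radius_set if isinstance(radius_set, dict) else load_radius_table(radius_set)
    table = {k.upper(): v for k, v in table.items()}
    out = structure.copy()
    unknown = sorted({a.element.upper() for a in out.atoms if a.element.upper() not in table})
    if unknown and default is None:
        raise ValueError(f"no radius for elements {unknown} and no default configured")
    for a in out.atoms:
        a.vdw_radius = table.get(a.element.upper(), default)
    return out
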