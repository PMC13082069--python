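"""Structure and trajectory I/O.

Reads fixed-column PDB files (single- and multi-model) and a
whitespace-delimited per-frame XYZ table, assigns van der Waals radii,
and resolves atom selections.  All coordinates are in Angstrom and all
residue numbering is the 1-based author numbering read verbatim from the
file, since channel residues are conventionally referred to by author
numbers (V625, S620, ...).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    LookupError_,
    ParseError,
    ShapeError,
)

#: Built-in element-keyed vdW radius table (Angstrom).  HOLE-style pore
#: profiling is radius-set-relative, so the set in use is always explicit
#: and overridable; this default follows the common Bondi-derived values.
DEFAULT_VDW_TABLE: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure; positions in Angstrom."""

    serial: int
    atom_name: str
    residue_name: str
    residue_id: int
    chain_id: str
    position: tuple[float, float, float]
    element: str = ""
    vdw_radius: float | None = None

    def __post_init__(self):
        if not all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.serial}")
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise ValueError(f"non-positive vdW radius for atom {self.serial}")


@dataclass
class Structure:
    """An ordered collection of atoms plus a chain -> subunit map."""

    atoms: list[AtomRecord]
    subunit_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        keys = [(a.chain_id, a.residue_id, a.atom_name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate atom identifier {dup}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """Coordinates as an (n_atoms, 3) array, Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def chain_ids(self) -> list[str]:
        out = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def vdw_radii(self) -> np.ndarray:
        radii = [a.vdw_radius for a in self.atoms]
        if any(r is None for r in radii):
            raise LookupError_("structure has atoms without assigned vdW radii")
        return np.array(radii, dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ShapeError(
                f"coordinate array {coords.shape} does not match roster "
                f"({len(self.atoms)} atoms)"
            )
        atoms = [
            replace(a, position=tuple(xyz)) for a, xyz in zip(self.atoms, coords)
        ]
        return Structure(atoms, dict(self.subunit_map))


@dataclass
class Trajectory:
    """Frames sharing one atom roster; frame_dt in ns."""

    roster: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    frame_dt: float = 1.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (len(self.roster), 3):
            raise ShapeError(
                f"frames array {self.frames.shape} does not match roster of "
                f"{len(self.roster)} atoms"
            )
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int) -> Structure:
        return self.roster.with_coords(self.frames[i])


@dataclass(frozen=True)
class Selection:
    """Atom selection by chain, residue id and/or atom name (set semantics)."""

    chain_ids: frozenset[str] | None = None
    residue_ids: frozenset[int] | None = None
    atom_names: frozenset[str] | None = None

    @classmethod
    def of(
        cls,
        chains: Iterable[str] | str | None = None,
        residues: Iterable[int] | int | None = None,
        atoms: Iterable[str] | str | None = None,
    ) -> "Selection":
        def norm(x, scalar_types):
            if x is None:
                return None
            if isinstance(x, scalar_types):
                return frozenset([x])
            return frozenset(x)

        return cls(
            chain_ids=norm(chains, str),
            residue_ids=norm(residues, int),
            atom_names=norm(atoms, str),
        )

    def matches(self, atom: AtomRecord) -> bool:
        if self.chain_ids is not None and atom.chain_id not in self.chain_ids:
            return False
        if self.residue_ids is not None and atom.residue_id not in self.residue_ids:
            return False
        if self.atom_names is not None and atom.atom_name not in self.atom_names:
            return False
        return True


# ---------------------------------------------------------------------------
# PDB reading / writing (fixed columns)
# ---------------------------------------------------------------------------

def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    for ch in stripped:
        if ch.isalpha():
            # two-letter elements in protein context are rare; single letter
            # covers C/N/O/S/H/P, which is what the vdW table knows.
            return ch.upper()
    return ""


def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord, str]:
    """Parse one ATOM/HETATM record; returns (atom, altloc)."""
    try:
        serial = int(line[6:11])
        atom_name = line[12:16].strip()
        altloc = line[16:17].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21:22].strip()
        residue_id = int(line[22:26])
        icode = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed ATOM record at line {lineno}: {exc}") from exc
    if icode:
        raise ParseError(
            f"insertion code '{icode}' at line {lineno} is not supported"
        )
    if not element:
        element = _guess_element(atom_name)
    atom = AtomRecord(
        serial=serial,
        atom_name=atom_name,
        residue_name=residue_name,
        residue_id=residue_id,
        chain_id=chain_id,
        position=(x, y, z),
        element=element,
    )
    return atom, altloc


def read_structure(path: str | Path) -> Structure:
    """Read the first model of a PDB file into a :class:`Structure`.

    Fixed-column parsing; insertion codes are rejected; for alternate
    locations the first altloc is kept and the rest dropped with a warning.
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    seen_altloc: dict[tuple, str] = {}
    dropped_altlocs = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "ENDMDL":
                break
            if rec not in ("ATOM", "HETATM"):
                continue
            atom, altloc = _parse_atom_line(line, lineno)
            key = (atom.chain_id, atom.residue_id, atom.atom_name)
            if key in seen_altloc:
                if altloc and altloc != seen_altloc[key]:
                    dropped_altlocs += 1
                    continue
                raise ParseError(
                    f"duplicate atom {key} at line {lineno}"
                )
            seen_altloc[key] = altloc
            atoms.append(atom)
    if dropped_altlocs:
        warnings.warn(
            f"dropped {dropped_altlocs} alternate-location records "
            "(kept first altloc)"
        )
    if not atoms:
        raise EmptyInputError(f"no ATOM/HETATM records in {path}")
    return Structure(atoms)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a single-model PDB file (fixed columns, %8.3f coordinates)."""
    path = Path(path)
    with path.open("w") as fh:
        _write_model_atoms(structure, structure.coords(), fh)
        fh.write("END\n")


def _write_model_atoms(structure: Structure, coords: np.ndarray, fh) -> None:
    for atom, xyz in zip(structure.atoms, coords):
        name = atom.atom_name
        # PDB convention: 1-3 character names start in column 14
        name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
        fh.write(
            "ATOM  {serial:>5d} {name}{alt}{res:<3s} {chain}{resid:>4d}{icode}"
            "   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n".format(
                serial=atom.serial % 100000,
                name=name_field,
                alt=" ",
                res=atom.residue_name[:3],
                chain=(atom.chain_id or " ")[:1],
                resid=atom.residue_id,
                icode=" ",
                x=xyz[0],
                y=xyz[1],
                z=xyz[2],
                occ=1.0,
                b=0.0,
                el=atom.element[:2],
            )
        )


def write_trajectory_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB file, one MODEL per frame."""
    path = Path(path)
    with path.open("w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"MODEL     {i + 1:>4d}\n")
            _write_model_atoms(traj.roster, traj.frames[i], fh)
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_trajectory_xyz(traj: Trajectory, path: str | Path) -> None:
    """Write frames as a whitespace table: frame, atom_serial, x, y, z."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# frame atom_serial x y z\n")
        for i in range(traj.n_frames):
            for atom, xyz in zip(traj.roster.atoms, traj.frames[i]):
                fh.write(
                    f"{i} {atom.serial} "
                    f"{xyz[0]:.3f} {xyz[1]:.3f} {xyz[2]:.3f}\n"
                )


def _read_frames_multimodel_pdb(path: Path, n_atoms: int) -> np.ndarray:
    frames: list[np.ndarray] = []
    current: list[tuple[float, float, float]] = []
    in_model = False
    saw_model_card = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model_card = True
                in_model = True
                current = []
            elif rec == "ENDMDL":
                frames.append(np.array(current, dtype=float))
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                atom, _ = _parse_atom_line(line, lineno)
                current.append(atom.position)
                in_model = in_model or not saw_model_card
    if not saw_model_card and current:
        frames.append(np.array(current, dtype=float))
    if not frames:
        raise EmptyInputError(f"no coordinate models in {path}")
    for i, fr in enumerate(frames):
        if fr.shape != (n_atoms, 3):
            raise ShapeError(
                f"frame {i} has {fr.shape[0]} atoms, roster has {n_atoms}"
            )
    return np.stack(frames)


def _read_frames_xyz_table(path: Path, n_atoms: int) -> np.ndarray:
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.size == 0:
        raise EmptyInputError(f"no rows in {path}")
    if data.shape[1] != 5:
        raise ParseError(
            f"XYZ table must have 5 columns (frame, atom_serial, x, y, z), "
            f"got {data.shape[1]}"
        )
    frame_ids = data[:, 0].astype(int)
    order = np.argsort(frame_ids, kind="stable")
    data = data[order]
    frame_ids = frame_ids[order]
    uniq = np.unique(frame_ids)
    frames = []
    for i, f in enumerate(uniq):
        block = data[frame_ids == f]
        if block.shape[0] != n_atoms:
            raise ShapeError(
                f"frame {i} has {block.shape[0]} atoms, roster has {n_atoms}"
            )
        frames.append(block[:, 2:5])
    return np.stack(frames)


def read_trajectory(
    path: str | Path, roster: Structure, frame_dt: float = 1.0
) -> Trajectory:
    """Read a multi-model PDB or an XYZ frame table against a roster.

    Format is chosen by extension: ``.pdb`` -> multi-model PDB, anything
    else -> whitespace XYZ table (columns frame, atom_serial, x, y, z).
    """
    path = Path(path)
    if path.suffix.lower() in (".pdb", ".ent"):
        frames = _read_frames_multimodel_pdb(path, len(roster))
    else:
        frames = _read_frames_xyz_table(path, len(roster))
    return Trajectory(roster=roster, frames=frames, frame_dt=frame_dt)


# ---------------------------------------------------------------------------
# vdW radii and selections
# ---------------------------------------------------------------------------

def assign_vdw_radii(
    structure: Structure,
    table: dict[str, float] | None = None,
    default: float | None = None,
) -> Structure:
    """Return a copy of the structure with vdW radii assigned per element.

    Unknown elements take ``default`` (with a warning) or raise a lookup
    error listing every offending element if no default is supplied.
    """
    table = DEFAULT_VDW_TABLE if table is None else table
    unknown = sorted(
        {a.element for a in structure.atoms if a.element not in table}
    )
    if unknown and default is None:
        raise LookupError_(
            f"no vdW radius for elements {unknown} and no default supplied"
        )
    if unknown:
        warnings.warn(
            f"elements {unknown} not in vdW table; using default {default} A"
        )
    atoms = [
        replace(a, vdw_radius=table.get(a.element, default))
        for a in structure.atoms
    ]
    return Structure(atoms, dict(structure.subunit_map))


def resolve_selection(structure: Structure, sel: Selection) -> list[int]:
    """Resolve a selection to a strictly increasing atom index list."""
    idx = [i for i, a in enumerate(structure.atoms) if sel.matches(a)]
    if not idx:
        warnings.warn(f"selection {sel} matched no atoms")
    return idx


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as UTF-8 CSV with one header row."""
    pd.DataFrame(df).to_csv(path, index=False, encoding="utf-8")
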