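"""Macromolecular structure I/O in PDB format.

The residue coordinate system used throughout the package is *author*
numbering (the numbers printed in a deposited structure, e.g. E1213), never a
sequential index, because functional-site tables cite author numbers.
Only the first MODEL of a file is read; HETATM records (waters, ligands) are
skipped — the geometry downstream is protein/nucleic backbone only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "CoordinateSet",
    "PDBParseError",
    "EmptyStructureError",
    "EmptySelectionError",
    "read_structure",
    "write_structure",
    "select_atoms",
]


class PDBParseError(ValueError):
    """A fixed-width record could not be parsed; message names the line."""


class EmptyStructureError(ValueError):
    """A file or structure contained no usable ATOM records."""


class EmptySelectionError(LookupError):
    """An atom selection matched nothing (distinct from a parse failure)."""


#: 3-letter -> 1-letter codes for the 20 standard amino acids.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class Residue:
    chain_id: str
    number: int
    aa_code: str = "X"
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)
    resname: str = ""  # 3-letter record name, kept for faithful round-trips

    def __post_init__(self) -> None:
        if not self.resname:
            self.resname = ONE_TO_THREE.get(self.aa_code, "UNK")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    """Ordered residue container; iteration order is file order."""

    id: str
    residues: list[Residue] = field(default_factory=list)
    source_path: Optional[str] = None

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue_index(self) -> dict[tuple[str, int, str], Residue]:
        return {r.key: r for r in self.residues}

    def find_residue(self, chain_id: str, number: int,
                     insertion_code: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.chain_id == chain_id and r.number == number \
                    and r.insertion_code == insertion_code:
                return r
        return None

    def copy(self) -> "Structure":
        return Structure(
            id=self.id,
            residues=[
                replace(r, atoms=[replace(a, position=a.position.copy())
                                  for a in r.atoms])
                for r in self.residues
            ],
            source_path=self.source_path,
        )


@dataclass
class CoordinateSet:
    """Labelled N×3 coordinate matrix; the unit handed to superposition."""

    labels: list[tuple[str, int, str]]  # (chain_id, residue number, atom name)
    coords: np.ndarray  # (N, 3), Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an N×3 matrix")
        if len(self.labels) != len(self.coords):
            raise ValueError("labels and coords lengths differ")
        if len(self.labels) == 0:
            raise ValueError("CoordinateSet must be non-empty")

    def __len__(self) -> int:
        return len(self.labels)


def _parse_float(line: str, lineno: int, span: tuple[int, int],
                 what: str, default: Optional[float] = None) -> float:
    text = line[span[0]:span[1]].strip()
    if not text:
        if default is not None:
            return default
        raise PDBParseError(f"line {lineno}: missing {what} field")
    try:
        return float(text)
    except ValueError:
        raise PDBParseError(
            f"line {lineno}: malformed {what} field {text!r}") from None


def read_structure(path: str | Path, altloc_policy: str = "first",
                   structure_id: Optional[str] = None) -> Structure:
    """Read ATOM records from a PDB file.

    Parameters
    ----------
    path
        PDB file to read.
    altloc_policy
        ``"first"`` keeps the first alternate conformer encountered for each
        atom name; ``"highest_occupancy"`` keeps the conformer with the
        largest occupancy.
    structure_id
        Label for the returned structure; defaults to the file stem.

    HETATM records are skipped; only the first MODEL block is read; author
    residue numbers, chain IDs and insertion codes are preserved verbatim.
    """
    if altloc_policy not in ("first", "highest_occupancy"):
        raise ValueError(f"unknown altloc_policy {altloc_policy!r}")
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc

    residues: list[Residue] = []
    index: dict[tuple[str, int, str], Residue] = {}
    # per-residue: atom name -> list of (altloc, atom, position-in-residue)
    altgroups: dict[tuple[str, int, str], dict[str, list]] = {}

    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6]
        if record == "ENDMDL":
            break  # ignore MODEL blocks beyond the first
        if record != "ATOM  ":
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: ATOM record too short")
        name = line[12:16].strip()
        if not name:
            raise PDBParseError(f"line {lineno}: empty atom name")
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain_id = line[21].strip()
        try:
            number = int(line[22:26])
        except ValueError:
            raise PDBParseError(
                f"line {lineno}: malformed residue number "
                f"{line[22:26]!r}") from None
        icode = line[26].strip()
        x = _parse_float(line, lineno, (30, 38), "x coordinate")
        y = _parse_float(line, lineno, (38, 46), "y coordinate")
        z = _parse_float(line, lineno, (46, 54), "z coordinate")
        occ = _parse_float(line, lineno, (54, 60), "occupancy", default=1.0)
        b = _parse_float(line, lineno, (60, 66), "B-factor", default=0.0)
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = name.lstrip("0123456789")[:1]

        key = (chain_id, number, icode)
        res = index.get(key)
        if res is None:
            res = Residue(chain_id=chain_id, number=number,
                          aa_code=THREE_TO_ONE.get(resname, "X"),
                          insertion_code=icode, atoms=[], resname=resname)
            index[key] = res
            residues.append(res)
            altgroups[key] = {}
        atom = Atom(name=name, element=element, position=np.array([x, y, z]),
                    occupancy=occ, b_factor=b)
        altgroups[key].setdefault(name, []).append((altloc, atom))

    if not residues:
        raise EmptyStructureError(f"{path}: no ATOM records")

    for res in residues:
        chosen: list[Atom] = []
        for name, variants in altgroups[res.key].items():
            if len(variants) == 1 or altloc_policy == "first":
                chosen.append(variants[0][1])
            else:
                chosen.append(max(variants, key=lambda v: v[1].occupancy)[1])
        res.atoms = chosen

    return Structure(id=structure_id or path.stem, residues=residues,
                     source_path=str(path))


def _format_atom_name(name: str) -> str:
    # Standard PDB alignment: names shorter than 4 chars start in column 14.
    return name if len(name) >= 4 else f" {name:<3s}"


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write fixed-width PDB ATOM records (coordinates to 3 decimals).

    Author numbering, chain IDs and insertion codes survive a round-trip
    through :func:`read_structure`. A TER record separates chains and the
    file terminates with END.
    """
    if not structure.residues:
        raise EmptyStructureError("refusing to write an empty structure")
    path = Path(path)
    lines: list[str] = []
    serial = 0
    prev_chain: Optional[str] = None
    for res in structure.residues:
        if prev_chain is not None and res.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = res.chain_id
        resname = res.resname or ONE_TO_THREE.get(res.aa_code, "UNK")
        for a in res.atoms:
            serial += 1
            x, y, z = a.position
            lines.append(
                f"ATOM  {serial:5d} {_format_atom_name(a.name)} "
                f"{resname:>3s} {res.chain_id:1s}{res.number:4d}"
                f"{res.insertion_code or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
                f"          {a.element:>2s}"
            )
    lines.append("END")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def select_atoms(structure: Structure, atom_name: str = "CA",
                 residue_filter: Optional[Iterable[tuple[str, int]]] = None,
                 ) -> CoordinateSet:
    """Select atoms by name (default Cα), optionally restricted to residues.

    ``residue_filter`` is a set of ``(chain_id, residue_number)`` pairs.
    Order follows structure (file) order. Raises
    :class:`EmptySelectionError` when nothing matches.
    """
    if not structure.residues:
        raise EmptyStructureError("cannot select from an empty structure")
    wanted = set(residue_filter) if residue_filter is not None else None
    labels: list[tuple[str, int, str]] = []
    coords: list[np.ndarray] = []
    for res in structure.residues:
        if wanted is not None and (res.chain_id, res.number) not in wanted:
            continue
        for a in res.atoms:
            if a.name == atom_name:
                labels.append((res.chain_id, res.number, a.name))
                coords.append(a.position)
    if not labels:
        raise EmptySelectionError(
            f"no atoms named {atom_name!r} matched the selection in "
            f"structure {structure.id!r}")
    return CoordinateSet(labels=labels, coords=np.vstack(coords))
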