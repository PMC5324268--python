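"""Protein structure data model and PDB input/output.

The structure model is deliberately minimal: ordered residues carrying named
heavy atoms with Cartesian coordinates in Angstrom.  It is the geometric
substrate for interatomic-bond detection; everything a residue interaction
network needs is a residue identity and atom positions, so occupancies,
B-factors, anisotropic parameters and heteroatoms are dropped on input.

Reading goes through :mod:`gemmi`; writing emits standard fixed-column
ATOM/TER/END records directly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "ResidueKey",
    "Structure",
    "StructureError",
    "PDBFormatError",
    "read_pdb",
    "write_pdb",
    "STANDARD_AA",
    "AA_THREE_TO_ONE",
    "AA_ONE_TO_THREE",
]

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_ONE_TO_THREE = {v: k for k, v in AA_THREE_TO_ONE.items()}

#: residue identifier used as graph node id: (chain_id, seq_num, icode)
ResidueKey = tuple[str, int, str]


class StructureError(ValueError):
    """Invalid structure content (missing residues/atoms, bad model index)."""


class PDBFormatError(StructureError):
    """File is not usable as a PDB coordinate file."""


@dataclass
class Atom:
    """A named atom with coordinates in Angstrom."""

    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not self.name:
            raise StructureError("atom name must be non-empty")

    def distance(self, other: "Atom") -> float:
        return float(np.linalg.norm(self.coords - other.coords))


@dataclass
class Residue:
    """One amino-acid residue: identity plus its ordered atoms."""

    chain_id: str
    seq_num: int
    aa: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_num, self.icode)

    @property
    def is_standard(self) -> bool:
        return self.aa in STANDARD_AA

    def atom(self, name: str) -> Atom | None:
        """First atom with the given name, or None if the residue lacks it."""
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Residue {self.chain_id}:{self.aa}{self.seq_num}{self.icode} ({len(self.atoms)} atoms)>"


@dataclass
class Structure:
    """An ordered collection of residues from one coordinate model."""

    id: str
    residues: list[Residue] = field(default_factory=list)
    model_num: int = 1

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise StructureError("duplicate residue identifiers in structure")

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, chain_id: str, seq_num: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.key == (chain_id, seq_num, icode):
                return r
        return None

    def copy(self) -> "Structure":
        return copy.deepcopy(self)

    def validate(self) -> None:
        if not self.residues:
            raise StructureError("structure has no residues")
        for r in self.residues:
            if not r.atoms:
                raise StructureError(f"residue {r.key} has no atoms")


def read_pdb(path: str | Path, model: int = 0) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Parameters
    ----------
    path
        PDB coordinate file with at least one ATOM record.
    model
        Zero-based model index; multi-model (NMR-style) files default to the
        first model.

    HETATM records and waters are dropped; for alternate locations only the
    first conformer (altloc blank or 'A') is kept.  Hydrogens are retained if
    present but nothing downstream requires them.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (OSError, FileNotFoundError):
        raise
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"{path}: not parseable as PDB: {exc}") from exc
    if len(st) == 0:
        raise PDBFormatError(f"{path}: no coordinate models found")
    if model < 0 or model >= len(st):
        raise IndexError(f"{path}: model index {model} out of range (file has {len(st)})")

    residues: list[Residue] = []
    for chain in st[model]:
        for res in chain:
            if res.het_flag != "A":  # ATOM records only: no HETATM, no waters
                continue
            atoms: list[Atom] = []
            seen: set[str] = set()
            for at in res:
                if at.altloc not in ("", "\0", "A"):
                    continue
                if at.name in seen:  # first altloc wins
                    continue
                seen.add(at.name)
                atoms.append(
                    Atom(
                        name=at.name,
                        element=at.element.name if at.element else "",
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    )
                )
            if not atoms:
                continue
            icode = res.seqid.icode.strip()
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_num=res.seqid.num,
                    aa=res.name,
                    atoms=atoms,
                    icode=icode,
                )
            )
    if not residues:
        raise PDBFormatError(f"{path}: no ATOM records (polymer residues) found")
    return Structure(id=path.stem, residues=residues, model_num=model + 1)


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: element right-justified in 13-14; names of < 4 chars
    # with a 1-letter element get a leading blank.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4}"
    return f" {name:<3}"


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write standard ATOM/TER/END records, preserving author numbering.

    Coordinates are emitted in the 8.3 fixed field, so a read/write round trip
    preserves them to three decimals.  Serial numbers are assigned 1-based in
    file order.
    """
    s.validate()
    path = Path(path)
    lines: list[str] = []
    serial = 0
    prev_chain: str | None = None
    last_res: Residue | None = None
    for res in s.residues:
        if res.seq_num > 9999 or res.seq_num < -999:
            raise StructureError(
                f"residue number {res.seq_num} overflows the 4-column PDB field"
            )
        if prev_chain is not None and res.chain_id != prev_chain and last_res is not None:
            serial += 1
            lines.append(_ter_line(serial, last_res))
        for at in res.atoms:
            serial += 1
            if serial > 99999:
                raise StructureError("atom serial overflow (>99999)")
            x, y, z = at.coords
            if max(abs(x), abs(y), abs(z)) >= 10000:
                raise StructureError("coordinate overflows the 8.3 PDB field")
            lines.append(
                f"ATOM  {serial:5d} {_format_atom_name(at.name, at.element)}"
                f" {res.aa:>3s} {res.chain_id[:1]:1s}{res.seq_num:4d}{res.icode or ' ':1s}"
                f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {at.element:>2s}"
            )
        prev_chain = res.chain_id
        last_res = res
    if last_res is not None:
        serial += 1
        lines.append(_ter_line(serial, last_res))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _ter_line(serial: int, res: Residue) -> str:
    return (
        f"TER   {serial:5d}      {res.aa:>3s} "
        f"{res.chain_id[:1]:1s}{res.seq_num:4d}{res.icode or ' ':1s}"
    )
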