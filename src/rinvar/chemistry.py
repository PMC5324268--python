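"""Amino-acid interaction chemistry: which atoms can form which bonds.

The detector rules operate on named atom groups per residue type:
hydrophobic carbons, hydrogen-bond donors and acceptors (heavy atoms, since
modelled structures commonly lack hydrogens), charged atoms for salt bridges,
and ordered aromatic ring cycles for stacking interactions.

The assignment ships as packaged delimited text (``data/chemistry_groups.tsv``)
so users can substitute their own dialect; :func:`load_chemistry` accepts an
alternative path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = ["ChemistryEntry", "ChemistryTable", "load_chemistry", "chemistry"]


@dataclass(frozen=True)
class ChemistryEntry:
    """Interaction-capable atom groups of one amino-acid type."""

    aa: str
    hydrophobic_atoms: frozenset[str] = frozenset()
    hbond_donors: frozenset[str] = frozenset()
    hbond_acceptors: frozenset[str] = frozenset()
    cationic_atoms: frozenset[str] = frozenset()
    anionic_atoms: frozenset[str] = frozenset()
    #: ordered ring cycles (5 or 6 atoms each); TRP contributes two
    aromatic_rings: tuple[tuple[str, ...], ...] = ()

    @property
    def is_aromatic(self) -> bool:
        return bool(self.aromatic_rings)

    def all_atoms(self) -> frozenset[str]:
        ring = frozenset(a for r in self.aromatic_rings for a in r)
        return (
            self.hydrophobic_atoms
            | self.hbond_donors
            | self.hbond_acceptors
            | self.cationic_atoms
            | self.anionic_atoms
            | ring
        )


class ChemistryTable:
    """Lookup of :class:`ChemistryEntry` by three-letter amino-acid code."""

    def __init__(self, entries: dict[str, ChemistryEntry]):
        self._entries = dict(entries)

    def __contains__(self, aa: str) -> bool:
        return aa in self._entries

    def __getitem__(self, aa: str) -> ChemistryEntry:
        try:
            return self._entries[aa]
        except KeyError:
            raise KeyError(
                f"no chemistry entry for residue type {aa!r} (non-standard?)"
            ) from None

    def get(self, aa: str) -> ChemistryEntry | None:
        return self._entries.get(aa)

    @property
    def amino_acids(self) -> frozenset[str]:
        return frozenset(self._entries)


def _parse_rows(text: str) -> dict[str, ChemistryEntry]:
    groups: dict[str, dict[str, list]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, group, atoms_str = line.split("\t")
        atoms = tuple(a.strip() for a in atoms_str.split(",") if a.strip())
        groups.setdefault(aa, {})[group] = atoms

    entries = {}
    for aa, g in groups.items():
        rings = []
        for key in ("ring1", "ring2"):
            if key in g:
                cycle = g[key]
                if len(cycle) not in (5, 6):
                    raise ValueError(f"{aa} {key}: ring cycles must have 5 or 6 atoms")
                rings.append(cycle)
        entries[aa] = ChemistryEntry(
            aa=aa,
            hydrophobic_atoms=frozenset(g.get("hydrophobic", ())),
            hbond_donors=frozenset(g.get("donor", ())),
            hbond_acceptors=frozenset(g.get("acceptor", ())),
            cationic_atoms=frozenset(g.get("cationic", ())),
            anionic_atoms=frozenset(g.get("anionic", ())),
            aromatic_rings=tuple(rings),
        )
    return entries


def load_chemistry(path: str | Path | None = None) -> ChemistryTable:
    """Load a chemistry table, by default the packaged one (all 20 standard AAs)."""
    if path is None:
        text = resources.files("rinvar.data").joinpath("chemistry_groups.tsv").read_text()
    else:
        text = Path(path).read_text()
    return ChemistryTable(_parse_rows(text))


_DEFAULT: ChemistryTable | None = None


def chemistry(aa: str) -> ChemistryEntry:
    """Packaged group assignment for a standard amino acid (module-level cache)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_chemistry()
    return _DEFAULT[aa]
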