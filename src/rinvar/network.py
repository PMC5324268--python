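"""Interatomic-bond detection and residue interaction graph construction.

A structure is turned into an undirected, unweighted residue graph in two
steps.  First, five geometric detectors scan every residue pair for evidence
of non-covalent contact — hydrophobic carbon packing, hydrogen bonds, salt
bridges, π-π stacking and cation-π interactions — using the atom groups of
the packaged chemistry table and a strict distance rule (atom-atom distance
below 5.0 Å by default; hydrogen bonds use a tighter donor-acceptor cutoff).
Second, all evidence for a pair is collapsed into a single binary edge:
a pair either interacts or it does not, regardless of how many atom pairs
or bond types support the contact.

Detection is on heavy atoms only, so hydrogen-bearing and hydrogen-free
inputs give identical graphs.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .chemistry import ChemistryEntry, ChemistryTable, load_chemistry
from .structure import Residue, ResidueKey, Structure

__all__ = [
    "BondType",
    "BondEvidence",
    "InteractionEdge",
    "DetectorConfig",
    "detect_interactions",
    "detect_pair",
    "build_graph",
    "export_graph",
    "import_graph",
    "node_label",
    "parse_node_label",
]

logger = logging.getLogger(__name__)


class BondType(enum.Enum):
    """The five detected non-covalent interaction types."""

    HYDROPHOBIC = "hydrophobic"
    HBOND = "hbond"
    SALT_BRIDGE = "salt_bridge"
    PI_PI = "pi_pi"
    CATION_PI = "cation_pi"


@dataclass(frozen=True)
class BondEvidence:
    """One atom pair supporting a detected bond."""

    atom_i: str
    atom_j: str
    distance: float
    bond_type: BondType


@dataclass
class InteractionEdge:
    """All detected bond evidence between one residue pair (i before j in file order)."""

    res_i: ResidueKey
    res_j: ResidueKey
    evidence: list[BondEvidence] = field(default_factory=list)

    @property
    def bond_types(self) -> frozenset[BondType]:
        return frozenset(e.bond_type for e in self.evidence)


@dataclass(frozen=True)
class DetectorConfig:
    """Distance criteria for the five detectors.

    ``cutoff`` is the global strict atom-atom bound in Å.  Hydrogen bonds use
    the tighter donor-to-acceptor heavy-atom bound ``hbond_cutoff`` (no angle
    term, since structures may lack hydrogens).  π-π stacking additionally
    requires the ring centroids within ``pipi_centroid_cutoff`` (set to None
    to disable); this excludes geometrically implausible edge-on far contacts
    that the plain atom rule would admit.
    """

    cutoff: float = 5.0
    hbond_cutoff: float = 3.5
    pipi_centroid_cutoff: float | None = 7.0

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")
        if self.hbond_cutoff <= 0:
            raise ValueError(f"hbond_cutoff must be positive, got {self.hbond_cutoff}")

    @property
    def effective_hbond_cutoff(self) -> float:
        return min(self.hbond_cutoff, self.cutoff)


def _atoms(res: Residue, names) -> list[tuple[str, np.ndarray]]:
    # missing atoms (truncated side chains) are silently skipped
    return [(a.name, a.coords) for a in res.atoms if a.name in names]


def _pairs_within(
    ai: list[tuple[str, np.ndarray]],
    aj: list[tuple[str, np.ndarray]],
    cutoff: float,
    bond_type: BondType,
) -> list[BondEvidence]:
    out = []
    for name_i, ci in ai:
        for name_j, cj in aj:
            d = float(np.linalg.norm(ci - cj))
            if d < cutoff:
                out.append(BondEvidence(name_i, name_j, d, bond_type))
    return out


def _sequence_adjacent(ri: Residue, rj: Residue) -> bool:
    return ri.chain_id == rj.chain_id and abs(ri.seq_num - rj.seq_num) == 1


def detect_hydrophobic(
    ri: Residue, rj: Residue, ci: ChemistryEntry, cj: ChemistryEntry, cfg: DetectorConfig
) -> list[BondEvidence]:
    return _pairs_within(
        _atoms(ri, ci.hydrophobic_atoms),
        _atoms(rj, cj.hydrophobic_atoms),
        cfg.cutoff,
        BondType.HYDROPHOBIC,
    )


def detect_hbond(
    ri: Residue, rj: Residue, ci: ChemistryEntry, cj: ChemistryEntry, cfg: DetectorConfig
) -> list[BondEvidence]:
    """Donor-to-acceptor heavy-atom contacts, both directions.

    For sequence-adjacent residues the covalently constrained peptide-bond
    neighbourhood (amide N of the later residue against the carbonyl C/O of
    the earlier) is excluded: those atoms sit within hydrogen-bond range by
    covalent geometry alone.
    """
    ev = _pairs_within(
        _atoms(ri, ci.hbond_donors), _atoms(rj, cj.hbond_acceptors),
        cfg.effective_hbond_cutoff, BondType.HBOND,
    )
    ev += [
        BondEvidence(e.atom_j, e.atom_i, e.distance, e.bond_type)
        for e in _pairs_within(
            _atoms(rj, cj.hbond_donors), _atoms(ri, ci.hbond_acceptors),
            cfg.effective_hbond_cutoff, BondType.HBOND,
        )
    ]
    if _sequence_adjacent(ri, rj):
        earlier_is_i = ri.seq_num < rj.seq_num
        banned = {("O", "N"), ("C", "N")} if earlier_is_i else {("N", "O"), ("N", "C")}
        ev = [e for e in ev if (e.atom_i, e.atom_j) not in banned]
    return ev


def detect_salt_bridge(
    ri: Residue, rj: Residue, ci: ChemistryEntry, cj: ChemistryEntry, cfg: DetectorConfig
) -> list[BondEvidence]:
    ev = _pairs_within(
        _atoms(ri, ci.cationic_atoms), _atoms(rj, cj.anionic_atoms),
        cfg.cutoff, BondType.SALT_BRIDGE,
    )
    ev += [
        BondEvidence(e.atom_j, e.atom_i, e.distance, e.bond_type)
        for e in _pairs_within(
            _atoms(rj, cj.cationic_atoms), _atoms(ri, ci.anionic_atoms),
            cfg.cutoff, BondType.SALT_BRIDGE,
        )
    ]
    return ev


def _ring_atoms_and_centroid(res: Residue, ring: tuple[str, ...]):
    atoms = _atoms(res, set(ring))
    if len(atoms) < 3:  # too truncated to define a ring plane
        return None
    centroid = np.mean([c for _, c in atoms], axis=0)
    return atoms, centroid


def detect_pi_pi(
    ri: Residue, rj: Residue, ci: ChemistryEntry, cj: ChemistryEntry, cfg: DetectorConfig
) -> list[BondEvidence]:
    ev: list[BondEvidence] = []
    for ring_i in ci.aromatic_rings:
        ring_data_i = _ring_atoms_and_centroid(ri, ring_i)
        if ring_data_i is None:
            continue
        atoms_i, cen_i = ring_data_i
        for ring_j in cj.aromatic_rings:
            ring_data_j = _ring_atoms_and_centroid(rj, ring_j)
            if ring_data_j is None:
                continue
            atoms_j, cen_j = ring_data_j
            if (
                cfg.pipi_centroid_cutoff is not None
                and float(np.linalg.norm(cen_i - cen_j)) >= cfg.pipi_centroid_cutoff
            ):
                continue
            ev += _pairs_within(atoms_i, atoms_j, cfg.cutoff, BondType.PI_PI)
    # the same atom pair may belong to two ring pairings (TRP); deduplicate
    seen: set[tuple[str, str]] = set()
    unique = []
    for e in ev:
        if (e.atom_i, e.atom_j) not in seen:
            seen.add((e.atom_i, e.atom_j))
            unique.append(e)
    return unique


def detect_cation_pi(
    ri: Residue, rj: Residue, ci: ChemistryEntry, cj: ChemistryEntry, cfg: DetectorConfig
) -> list[BondEvidence]:
    ev: list[BondEvidence] = []
    for res_c, chem_c, res_a, chem_a, flip in (
        (ri, ci, rj, cj, False),
        (rj, cj, ri, ci, True),
    ):
        if not chem_c.cationic_atoms or not chem_a.aromatic_rings:
            continue
        cat = _atoms(res_c, chem_c.cationic_atoms)
        for ring in chem_a.aromatic_rings:
            found = _pairs_within(
                cat, _atoms(res_a, set(ring)), cfg.cutoff, BondType.CATION_PI
            )
            if flip:
                found = [
                    BondEvidence(e.atom_j, e.atom_i, e.distance, e.bond_type)
                    for e in found
                ]
            ev += found
    seen: set[tuple[str, str]] = set()
    unique = []
    for e in ev:
        if (e.atom_i, e.atom_j) not in seen:
            seen.add((e.atom_i, e.atom_j))
            unique.append(e)
    return unique


_DETECTORS = (
    detect_hydrophobic,
    detect_hbond,
    detect_salt_bridge,
    detect_pi_pi,
    detect_cation_pi,
)


def detect_pair(
    ri: Residue,
    rj: Residue,
    chem: ChemistryTable,
    cfg: DetectorConfig,
) -> list[BondEvidence]:
    """Run all five detectors on one residue pair (symmetric in its arguments)."""
    ci, cj = chem.get(ri.aa), chem.get(rj.aa)
    if ci is None or cj is None:
        return []
    ev: list[BondEvidence] = []
    for det in _DETECTORS:
        ev += det(ri, rj, ci, cj, cfg)
    return ev


def detect_interactions(
    s: Structure,
    cutoff: float = 5.0,
    config: DetectorConfig | None = None,
    chem: ChemistryTable | None = None,
) -> list[InteractionEdge]:
    """Detect all interacting residue pairs of a structure.

    Returns one :class:`InteractionEdge` per residue pair with at least one
    piece of bond evidence, in file order.  Sequence-adjacent residues are
    eligible (helical backbone hydrogen bonds at i,i±3/4 are genuine network
    edges); intra-residue contacts are not.  Residue types absent from the
    chemistry table are skipped with a logged warning.
    """
    if config is None:
        config = DetectorConfig(cutoff=cutoff)
    if chem is None:
        chem = load_chemistry()

    skipped = {r.aa for r in s.residues if r.aa not in chem}
    if skipped:
        logger.warning("skipping residue types without chemistry entries: %s",
                       ", ".join(sorted(skipped)))

    residues = s.residues
    # prefilter candidate pairs by any heavy-atom proximity
    coords, owner = [], []
    for idx, r in enumerate(residues):
        for a in r.heavy_atoms():
            coords.append(a.coords)
            owner.append(idx)
    prefilter_radius = max(
        config.cutoff,
        config.pipi_centroid_cutoff or 0.0,
    )
    candidates: set[tuple[int, int]] = set()
    if coords:
        tree = cKDTree(np.asarray(coords))
        for k, l in tree.query_pairs(prefilter_radius):
            i, j = owner[k], owner[l]
            if i != j:
                candidates.add((min(i, j), max(i, j)))

    edges: list[InteractionEdge] = []
    for i, j in sorted(candidates):
        ev = detect_pair(residues[i], residues[j], chem, config)
        if ev:
            edges.append(InteractionEdge(residues[i].key, residues[j].key, ev))
    return edges


def build_graph(
    edges: list[InteractionEdge],
    all_residues: list[Residue] | Structure,
) -> nx.Graph:
    """Collapse bond evidence into a binary undirected residue graph.

    Nodes are residue keys for *every* residue of the structure, so isolated
    residues remain as degree-0 nodes; each interacting pair contributes
    exactly one unweighted edge regardless of its supporting evidence.
    """
    residues = list(all_residues)
    g = nx.Graph()
    for r in residues:
        g.add_node(r.key, aa=r.aa)
    for e in edges:
        for key in (e.res_i, e.res_j):
            if key not in g:
                raise ValueError(f"edge references residue {key} not in the node set")
        g.add_edge(
            e.res_i,
            e.res_j,
            bond_types=",".join(sorted(t.value for t in e.bond_types)),
        )
    return g


def node_label(key: ResidueKey, aa: str) -> str:
    chain, seq, icode = key
    return f"{chain}:{seq}{icode}:{aa}"


def parse_node_label(label: str) -> tuple[ResidueKey, str]:
    chain, pos, aa = label.split(":")
    num = "".join(c for c in pos if c.isdigit() or c == "-")
    icode = pos[len(num):]
    return (chain, int(num), icode), aa


def export_graph(g: nx.Graph, path: str | Path, format: str = "edgelist") -> None:
    """Write the residue graph with ``chain:resnum:aa`` node ids.

    Formats: ``edgelist`` (tab-separated ``node_i  node_j  bond_types``) or
    ``graphml``.
    """
    path = Path(path)
    labelled = nx.relabel_nodes(
        g, {n: node_label(n, g.nodes[n].get("aa", "UNK")) for n in g.nodes}
    )
    if format == "edgelist":
        lines = ["# node_i\tnode_j\tbond_types"]
        for u in labelled.nodes:
            labelled.nodes[u].clear()
        for u, v, data in labelled.edges(data=True):
            lines.append(f"{u}\t{v}\t{data.get('bond_types', '')}")
        # keep isolated nodes recoverable
        for n in labelled.nodes:
            if labelled.degree(n) == 0:
                lines.append(f"{n}\t\t")
        path.write_text("\n".join(lines) + "\n")
    elif format == "graphml":
        nx.write_graphml(labelled, path)
    else:
        raise ValueError(f"unknown graph format {format!r} (use 'edgelist' or 'graphml')")


def import_graph(path: str | Path, format: str = "edgelist") -> nx.Graph:
    """Re-import a graph written by :func:`export_graph` (labelled-isomorphic)."""
    path = Path(path)
    g = nx.Graph()
    if format == "edgelist":
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            key_u, aa_u = parse_node_label(parts[0])
            g.add_node(key_u, aa=aa_u)
            if len(parts) >= 2 and parts[1].strip():
                key_v, aa_v = parse_node_label(parts[1])
                g.add_node(key_v, aa=aa_v)
                g.add_edge(key_u, key_v,
                           bond_types=parts[2] if len(parts) > 2 else "")
    elif format == "graphml":
        raw = nx.read_graphml(path)
        mapping = {}
        for n in raw.nodes:
            key, aa = parse_node_label(n)
            mapping[n] = key
            raw.nodes[n]["aa"] = aa
        g = nx.relabel_nodes(raw, mapping)
    else:
        raise ValueError(f"unknown graph format {format!r}")
    return g
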