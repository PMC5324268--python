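"""Synthetic test structures with known ground truth.

Everything upstream of the Δ statistic is testable without downloading any
real structure:

* :func:`make_helix` builds an idealized α-helical peptide with template side
  chains from a one-letter sequence.
* :func:`make_bundle` places several parallel helices and rigidly nudges
  side chains to plant contacts of chosen bond types at chosen distances.
* :func:`oracle_scan` is an independent brute-force re-implementation of the
  interatomic-bond rules (plain nested loops over every atom pair) whose
  output is the ground-truth contact map the production detector must match.
* :func:`graph_fixture` returns small named graphs paired with closed-form
  centrality values.
* :func:`mutation_scenario` builds seeded bundles where a substitution
  provably loses (or gains) planted contacts, with the expected sign of the
  degree change ΔD as ground truth.

Planted geometry is decidable, not physically realistic: side chains are
translated rigidly off their backbone to hit exact target distances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .chemistry import ChemistryTable, load_chemistry
from .mutagenesis import MutationSpec, load_templates, mutate
from .structure import (
    AA_ONE_TO_THREE,
    Atom,
    Residue,
    ResidueKey,
    Structure,
)

__all__ = [
    "PlantSpec",
    "PlantedContactMap",
    "make_helix",
    "make_bundle",
    "oracle_scan",
    "graph_fixture",
    "mutation_scenario",
    "shipped_fixtures",
    "place_atom",
]

_BACKBONE = {"N", "CA", "C", "O", "OXT"}
_VDW_FLOOR = 2.4  # Å; planting below this is sterically infeasible


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Natural-extension placement: position d with |c-d| = bond,
    angle(b,c,d) = angle and dihedral(a,b,c,d) = torsion."""
    ang, tor = math.radians(angle_deg), math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-math.cos(ang), math.sin(ang) * math.cos(tor), math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# canonical α-helix dihedrals; these realize ~1.5 Å rise and ~100° twist
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0


def _helix_backbone(n: int) -> list[dict[str, np.ndarray]]:
    """Ideal α-helical backbone (N, CA, C, O per residue) built by chaining
    ideal peptide geometry."""
    res: list[dict[str, np.ndarray]] = []
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([1.458, 0.0, 0.0])
    C = place_atom(np.array([0.0, 1.0, 0.0]), N, CA, 1.525, 111.2, 0.0)
    res.append({"N": N, "CA": CA, "C": C})
    for _ in range(1, n):
        prev = res[-1]
        Nn = place_atom(prev["N"], prev["CA"], prev["C"], 1.329, 116.2, _PSI)
        CAn = place_atom(prev["CA"], prev["C"], Nn, 1.458, 121.7, _OMEGA)
        Cn = place_atom(prev["C"], Nn, CAn, 1.525, 111.2, _PHI)
        prev["O"] = place_atom(Nn, prev["CA"], prev["C"], 1.231, 120.8, 180.0)
        res.append({"N": Nn, "CA": CAn, "C": Cn})
    last = res[-1]
    last["O"] = place_atom(last["N"], last["CA"], last["C"], 1.231, 120.8, _PSI + 180.0)
    return res


@dataclass(frozen=True)
class PlantSpec:
    """One engineered contact: a residue pair, target bond type and distance."""

    chain_a: str
    seq_a: int
    chain_b: str
    seq_b: int
    bond_type: str  # BondType value string, e.g. "salt_bridge"
    distance: float
    atoms_a: tuple[str, ...] | None = None  # optional override of the atom group
    atoms_b: tuple[str, ...] | None = None


@dataclass
class PlantedContactMap:
    """Ground-truth contacts of a fixture, from the generator's own scan."""

    contacts: dict[tuple[ResidueKey, ResidueKey], frozenset[str]] = field(default_factory=dict)
    planted: list[tuple[PlantSpec, float]] = field(default_factory=list)  # (spec, achieved Å)

    @property
    def edge_set(self) -> set[tuple[ResidueKey, ResidueKey]]:
        return set(self.contacts)

    def types(self, key_a: ResidueKey, key_b: ResidueKey) -> frozenset[str]:
        return self.contacts.get((key_a, key_b)) or self.contacts.get((key_b, key_a)) or frozenset()


def make_helix(
    sequence: str,
    rise: float = 1.5,
    twist: float = 100.0,
    seed: int = 0,
    chain_id: str = "A",
    start: int = 1,
    z_shift: float = 0.0,
    x_shift: float = 0.0,
    scan: bool = True,
) -> tuple[Structure, PlantedContactMap]:
    """Idealized α-helix with template side chains; deterministic for a given input.

    ``rise`` and ``twist`` document the canonical helix parameters the
    backbone realizes; only the canonical values are supported.  The returned
    contact map comes from :func:`oracle_scan` on the finished structure.
    """
    if len(sequence) < 3:
        raise ValueError("sequence must have at least 3 residues")
    bad = [c for c in sequence.upper() if c not in AA_ONE_TO_THREE]
    if bad:
        raise ValueError(f"invalid amino-acid letters: {bad}")
    if abs(rise - 1.5) > 0.05 or abs(twist - 100.0) > 2.0:
        raise ValueError("only canonical helix parameters (rise 1.5 Å, twist 100°) are supported")

    backbone = _helix_backbone(len(sequence))
    offset = np.array([x_shift, 0.0, z_shift])
    residues = []
    for i, letter in enumerate(sequence.upper()):
        atoms = [
            Atom(name=n, element=n[0], coords=backbone[i][n] + offset)
            for n in ("N", "CA", "C", "O")
        ]
        residues.append(
            Residue(chain_id=chain_id, seq_num=start + i, aa="GLY", atoms=atoms)
        )
    s = Structure(id=f"helix_{sequence}", residues=residues)

    templates = load_templates()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, letter in enumerate(sequence.upper()):
            aa = AA_ONE_TO_THREE[letter]
            if aa == "GLY":
                continue
            s = mutate(
                s,
                MutationSpec(chain_id=chain_id, seq_num=start + i, wt_aa="GLY", mut_aa=aa),
                templates=templates,
            )
    cmap = oracle_scan(s) if scan else PlantedContactMap()
    return s, cmap


def _plant_groups(chem: ChemistryTable, aa: str, bond_type: str, donor_side: bool):
    e = chem[aa]
    ring = frozenset(a for r in e.aromatic_rings for a in r)
    if bond_type == "hydrophobic":
        return e.hydrophobic_atoms
    if bond_type == "hbond":
        return e.hbond_donors if donor_side else e.hbond_acceptors
    if bond_type == "salt_bridge":
        return e.cationic_atoms if donor_side else e.anionic_atoms
    if bond_type == "pi_pi":
        return ring
    if bond_type == "cation_pi":
        return e.cationic_atoms if donor_side else ring
    raise ValueError(f"unknown bond type {bond_type!r}")


def make_bundle(
    helix_specs: list[tuple[str, str]] | list[str],
    inter_axis_distance: float = 12.0,
    planted_pairs: list[PlantSpec] = (),
    seed: int = 0,
) -> tuple[Structure, PlantedContactMap]:
    """Parallel helices with side chains nudged to plant chosen contacts.

    ``helix_specs`` is a list of sequences (chains are lettered A, B, ...) or
    of ``(sequence, chain_id)`` pairs; helix *k* is offset by
    ``k * inter_axis_distance`` along x.  For each planted pair, the closest
    atom pair between the two residues' relevant groups is found and the
    second residue's side chain is rigidly translated along that line until
    the pair sits at the target distance.  The ground-truth map is the
    oracle scan of the final structure, with the plants recorded.
    """
    if len(helix_specs) < 2:
        raise ValueError("a bundle needs at least 2 helices")
    chem = load_chemistry()
    residues: list[Residue] = []
    for k, spec in enumerate(helix_specs):
        seq, chain = spec if isinstance(spec, tuple) else (spec, chr(ord("A") + k))
        h, _ = make_helix(seq, chain_id=chain, x_shift=k * inter_axis_distance, scan=False)
        residues.extend(h.residues)
    s = Structure(id="bundle", residues=residues)

    planted: list[tuple[PlantSpec, float]] = []
    for p in planted_pairs:
        if p.distance < _VDW_FLOOR:
            raise ValueError(
                f"planted distance {p.distance} Å below the {_VDW_FLOOR} Å van der Waals floor"
            )
        ra = s.residue(p.chain_a, p.seq_a)
        rb = s.residue(p.chain_b, p.seq_b)
        if ra is None or rb is None:
            raise ValueError(f"planted pair references a missing residue: {p}")
        names_a = p.atoms_a or _plant_groups(chem, ra.aa, p.bond_type, donor_side=True)
        names_b = p.atoms_b or _plant_groups(chem, rb.aa, p.bond_type, donor_side=False)
        atoms_a = [a for a in ra.atoms if a.name in names_a]
        atoms_b = [b for b in rb.atoms if b.name in names_b]
        if not atoms_a or not atoms_b:
            raise ValueError(f"no candidate atoms for plant {p}")
        pairs = [(a, b, a.distance(b)) for a in atoms_a for b in atoms_b]
        a_star, b_star, d = min(pairs, key=lambda t: t[2])
        shift = (d - p.distance) * (a_star.coords - b_star.coords) / d
        for atom in rb.atoms:
            if atom.name not in _BACKBONE:
                atom.coords = atom.coords + shift
        planted.append((p, a_star.distance(b_star)))

    cmap = oracle_scan(s)
    cmap.planted = planted
    return s, cmap


def oracle_scan(
    s: Structure,
    cutoff: float = 5.0,
    hbond_cutoff: float = 3.5,
    pipi_centroid_cutoff: float | None = 7.0,
    chem: ChemistryTable | None = None,
) -> PlantedContactMap:
    """Brute-force contact scan: the independent ground-truth detector.

    Deliberately implemented as plain nested loops over every residue pair
    and every heavy-atom pair, evaluating each bond rule directly from the
    chemistry table — no spatial index, no shared code with the production
    detector.  Strict ``<`` comparisons throughout; hydrogen bonds exclude
    the covalent peptide-bond neighbourhood of sequence-adjacent residues.
    """
    if chem is None:
        chem = load_chemistry()
    hb = min(hbond_cutoff, cutoff)
    contacts: dict[tuple[ResidueKey, ResidueKey], set[str]] = {}

    residues = s.residues
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            ri, rj = residues[i], residues[j]
            ei, ej = chem.get(ri.aa), chem.get(rj.aa)
            if ei is None or ej is None:
                continue
            adjacent = ri.chain_id == rj.chain_id and abs(ri.seq_num - rj.seq_num) == 1
            first, second = (ri, rj) if ri.seq_num < rj.seq_num else (rj, ri)

            rings_i = [
                [a for a in ri.atoms if a.name in ring] for ring in ei.aromatic_rings
            ]
            rings_j = [
                [a for a in rj.atoms if a.name in ring] for ring in ej.aromatic_rings
            ]
            ring_ok: set[tuple[int, int]] = set()
            for ki, ringa in enumerate(rings_i):
                for kj, ringb in enumerate(rings_j):
                    if len(ringa) < 3 or len(ringb) < 3:
                        continue
                    if pipi_centroid_cutoff is None:
                        ring_ok.add((ki, kj))
                        continue
                    cen_a = np.mean([a.coords for a in ringa], axis=0)
                    cen_b = np.mean([b.coords for b in ringb], axis=0)
                    if float(np.linalg.norm(cen_a - cen_b)) < pipi_centroid_cutoff:
                        ring_ok.add((ki, kj))

            found: set[str] = set()
            for a in ri.atoms:
                if a.element == "H":
                    continue
                for b in rj.atoms:
                    if b.element == "H":
                        continue
                    d = a.distance(b)
                    if d >= cutoff:
                        continue
                    if a.name in ei.hydrophobic_atoms and b.name in ej.hydrophobic_atoms:
                        found.add("hydrophobic")
                    if d < hb:
                        donor_i = a.name in ei.hbond_donors and b.name in ej.hbond_acceptors
                        donor_j = b.name in ej.hbond_donors and a.name in ei.hbond_acceptors
                        if donor_i or donor_j:
                            banned = adjacent and (
                                (a.name == "N" and ri is second and b.name in ("O", "C"))
                                or (b.name == "N" and rj is second and a.name in ("O", "C"))
                            )
                            if not banned:
                                found.add("hbond")
                    if (a.name in ei.cationic_atoms and b.name in ej.anionic_atoms) or (
                        a.name in ei.anionic_atoms and b.name in ej.cationic_atoms
                    ):
                        found.add("salt_bridge")
                    if (
                        a.name in ei.cationic_atoms
                        and any(b.name in r for r in ej.aromatic_rings)
                    ) or (
                        b.name in ej.cationic_atoms
                        and any(a.name in r for r in ei.aromatic_rings)
                    ):
                        found.add("cation_pi")
                    for ki, ringa_names in enumerate(ei.aromatic_rings):
                        for kj, ringb_names in enumerate(ej.aromatic_rings):
                            if (
                                (ki, kj) in ring_ok
                                and a.name in ringa_names
                                and b.name in ringb_names
                            ):
                                found.add("pi_pi")
            if found:
                contacts[(ri.key, rj.key)] = frozenset(found)

    return PlantedContactMap(contacts={k: frozenset(v) for k, v in contacts.items()})


# ---------------------------------------------------------------------------
# analytic graph fixtures


def graph_fixture(name: str) -> tuple[nx.Graph, dict]:
    """Named graph with closed-form centrality values.

    Names: ``path_n``, ``cycle_n``, ``star_n`` (one hub, n-1 leaves),
    ``complete_n``, ``two_cliques_bridge``.  The returned dict has keys
    ``b_ct_raw``, ``b_ct``, ``degree``, ``cc_ct``, ``c_ct``, ``e_ct``,
    ``eb_ct`` mapping nodes (or edges) to hand-derived values.
    """
    if name == "two_cliques_bridge":
        return _two_cliques_bridge()
    kind, _, n_str = name.partition("_")
    try:
        n = int(n_str)
    except ValueError:
        raise ValueError(f"unknown graph fixture {name!r}") from None
    if kind == "path":
        return _path_fixture(n)
    if kind == "cycle":
        return _cycle_fixture(n)
    if kind == "star":
        return _star_fixture(n)
    if kind == "complete":
        return _complete_fixture(n)
    raise ValueError(f"unknown graph fixture {name!r}")


def _norm(raw: dict, n: int) -> dict:
    denom = (n - 1) * (n - 2) / 2.0
    return {k: (v / denom if denom else 0.0) for k, v in raw.items()}


def _path_fixture(n: int):
    g = nx.path_graph(n)
    raw = {i: float(i * (n - 1 - i)) for i in range(n)}
    c_ct = {
        i: (n - 1) / (i * (i + 1) / 2.0 + (n - 1 - i) * (n - i) / 2.0) for i in range(n)
    }
    expected = {
        "b_ct_raw": raw,
        "b_ct": _norm(raw, n),
        "degree": {i: 1 if i in (0, n - 1) else 2 for i in range(n)},
        "cc_ct": {i: 0.0 for i in range(n)},
        "c_ct": c_ct,
        "e_ct": {i: max(i, n - 1 - i) for i in range(n)},
        "eb_ct": {(i, i + 1): float((i + 1) * (n - 1 - i)) for i in range(n - 1)},
    }
    return g, expected


def _cycle_fixture(n: int):
    g = nx.cycle_graph(n)
    k = n // 2
    sum_d = float(k * (k + 1)) if n % 2 else float(k * k)  # per-node distance sum
    b_raw = sum_d / 2.0 - (n - 1) / 2.0
    eb = n * sum_d / 2.0 / n  # total pair mass spread evenly over the n edges
    expected = {
        "b_ct_raw": {i: b_raw for i in range(n)},
        "b_ct": _norm({i: b_raw for i in range(n)}, n),
        "degree": {i: 2 for i in range(n)},
        "cc_ct": {i: 1.0 if n == 3 else 0.0 for i in range(n)},
        "c_ct": {i: (n - 1) / sum_d for i in range(n)},
        "e_ct": {i: k for i in range(n)},
        "eb_ct": {e: eb for e in g.edges()},
    }
    return g, expected


def _star_fixture(n: int):
    g = nx.star_graph(n - 1)  # node 0 = hub, n-1 leaves
    raw = {0: (n - 1) * (n - 2) / 2.0, **{i: 0.0 for i in range(1, n)}}
    expected = {
        "b_ct_raw": raw,
        "b_ct": _norm(raw, n),
        "degree": {0: n - 1, **{i: 1 for i in range(1, n)}},
        "cc_ct": {i: 0.0 for i in range(n)},
        "c_ct": {0: 1.0, **{i: (n - 1) / (1.0 + 2.0 * (n - 2)) for i in range(1, n)}},
        "e_ct": {0: 1, **{i: 2 for i in range(1, n)}},
        "eb_ct": {(0, i): float(n - 1) for i in range(1, n)},
    }
    return g, expected


def _complete_fixture(n: int):
    g = nx.complete_graph(n)
    expected = {
        "b_ct_raw": {i: 0.0 for i in range(n)},
        "b_ct": {i: 0.0 for i in range(n)},
        "degree": {i: n - 1 for i in range(n)},
        "cc_ct": {i: 1.0 for i in range(n)},
        "c_ct": {i: 1.0 for i in range(n)},
        "e_ct": {i: 1 for i in range(n)},
        "eb_ct": {e: 1.0 for e in g.edges()},
    }
    return g, expected


def _two_cliques_bridge():
    # K3 {a1,a2,a3} and K3 {b1,b2,b3} joined by the bridge a3-b3
    g = nx.Graph()
    g.add_edges_from(
        [("a1", "a2"), ("a1", "a3"), ("a2", "a3"),
         ("b1", "b2"), ("b1", "b3"), ("b2", "b3"), ("a3", "b3")]
    )
    raw = {"a1": 0.0, "a2": 0.0, "b1": 0.0, "b2": 0.0, "a3": 6.0, "b3": 6.0}
    expected = {
        "b_ct_raw": raw,
        "b_ct": _norm(raw, 6),
        "degree": {"a1": 2, "a2": 2, "b1": 2, "b2": 2, "a3": 3, "b3": 3},
        "cc_ct": {"a1": 1.0, "a2": 1.0, "b1": 1.0, "b2": 1.0, "a3": 1 / 3, "b3": 1 / 3},
        "c_ct": {n: (0.5 if n in ("a1", "a2", "b1", "b2") else 5 / 7) for n in g},
        "e_ct": {n: (3 if n in ("a1", "a2", "b1", "b2") else 2) for n in g},
        "eb_ct": {
            ("a1", "a2"): 1.0, ("b1", "b2"): 1.0,
            ("a1", "a3"): 4.0, ("a2", "a3"): 4.0,
            ("b1", "b3"): 4.0, ("b2", "b3"): 4.0,
            ("a3", "b3"): 9.0,
        },
    }
    return g, expected


# ---------------------------------------------------------------------------
# mutation scenarios


def mutation_scenario(
    seed: int, direction: str = "loss"
) -> tuple[Structure, MutationSpec, int]:
    """Seeded bundle where one substitution provably changes the site degree.

    ``direction="loss"``: a central phenylalanine holds 3-5 planted
    hydrophobic contacts at its ring tip; mutating it to serine removes the
    ring, and the serine side chain cannot reach the partners, so the degree
    change ΔD at the site is negative.  ``direction="gain"`` is the reverse:
    partners are planted against the ring of the *future* phenylalanine of a
    glycine site, so GLY→PHE gains contacts.

    Returns ``(wt_structure, mutation_spec, expected_sign)`` where the sign
    (-1 or +1) is verified at generation time by oracle scans of the WT and
    mutant structures.
    """
    if direction not in ("loss", "gain"):
        raise ValueError(f"direction must be 'loss' or 'gain', got {direction!r}")
    rng = np.random.default_rng(seed)
    n_partners = int(rng.integers(3, 6))
    site_seq = 5
    central_seq_aa = "F" if direction == "loss" else "G"
    central = f"AAAA{central_seq_aa}AAAA"

    helices: list[tuple[str, str]] = [(central, "A")]
    partner_chains = []
    for k in range(n_partners):
        chain = chr(ord("B") + k)
        helices.append(("AAAALAAAA", chain))
        partner_chains.append(chain)

    residues: list[Residue] = []
    # central helix at the origin; partners ringed around it far enough away
    # that only the planted nudges create inter-helix contacts
    ring_radius = 18.0
    h, _ = make_helix(central, chain_id="A", scan=False)
    residues.extend(h.residues)
    for k, chain in enumerate(partner_chains):
        angle = 2 * math.pi * k / n_partners + float(rng.uniform(0, 0.4))
        h, _ = make_helix("AAAALAAAA", chain_id=chain, scan=False)
        offset = np.array(
            [ring_radius * math.cos(angle), ring_radius * math.sin(angle), 0.0]
        )
        for r in h.residues:
            for a in r.atoms:
                a.coords = a.coords + offset
        residues.extend(h.residues)
    wt = Structure(id=f"scenario_{direction}_{seed}", residues=residues)

    spec = MutationSpec(
        chain_id="A",
        seq_num=site_seq,
        wt_aa="PHE" if direction == "loss" else "GLY",
        mut_aa="SER" if direction == "loss" else "PHE",
    )

    # reference structure that carries the PHE ring (WT for loss, mutant for gain)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ringed = wt if direction == "loss" else mutate(wt, spec)
    phe = ringed.residue("A", site_seq)
    ca = phe.atom("CA").coords
    tip = max(
        (phe.atom(n) for n in ("CZ", "CE1", "CE2")), key=lambda a: float(np.linalg.norm(a.coords - ca))
    )
    outward = (tip.coords - ca) / np.linalg.norm(tip.coords - ca)

    # park each partner leucine's CD1 on the outward ray beyond the ring tip,
    # spread slightly so the partners do not collide with one another
    for k, chain in enumerate(partner_chains):
        target_d = float(rng.uniform(4.0, 4.8))
        leu = wt.residue(chain, site_seq)
        perp = np.cross(outward, [0.0, 0.0, 1.0])
        perp = perp / np.linalg.norm(perp)
        lateral = (k - (n_partners - 1) / 2.0) * 2.6
        goal = tip.coords + target_d * outward + lateral * perp
        shift = goal - leu.atom("CD1").coords
        for a in leu.atoms:
            if a.name not in _BACKBONE:
                a.coords = a.coords + shift

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mut = mutate(wt, spec)
    site = ("A", site_seq, "")
    d_wt = _oracle_degree(wt, site)
    d_mut = _oracle_degree(mut, site)
    expected = -1 if direction == "loss" else 1
    if np.sign(d_mut - d_wt) != expected:
        raise RuntimeError(
            f"scenario construction failed: oracle ΔD = {d_mut - d_wt} for {direction}"
        )
    return wt, spec, expected


def _oracle_degree(s: Structure, site: ResidueKey) -> int:
    cmap = oracle_scan(s)
    return sum(1 for (a, b) in cmap.contacts if a == site or b == site)


def shipped_fixtures() -> dict[str, tuple[Structure, PlantedContactMap]]:
    """The standard fixture set; together the plants cover all five bond types."""
    out: dict[str, tuple[Structure, PlantedContactMap]] = {}
    out["helix_ala10"] = make_helix("AAAAAAAAAA")
    out["helix_gly10"] = make_helix("GGGGGGGGGG")
    out["helix_mixed"] = make_helix("AVLIFSTYNQKEDRH")
    out["bundle_hydrophobic"] = make_bundle(
        ["AAALAAA", "AAALAAA"],
        planted_pairs=[PlantSpec("A", 4, "B", 4, "hydrophobic", 4.5)],
    )
    out["bundle_salt"] = make_bundle(
        ["AAAKAAA", "AAADAAA"],
        planted_pairs=[PlantSpec("A", 4, "B", 4, "salt_bridge", 3.0)],
    )
    out["bundle_hbond"] = make_bundle(
        ["AAASAAA", "AAANAAA"],
        planted_pairs=[PlantSpec("A", 4, "B", 4, "hbond", 3.0)],
    )
    out["bundle_pipi"] = make_bundle(
        ["AAAFAAA", "AAAFAAA"],
        planted_pairs=[PlantSpec("A", 4, "B", 4, "pi_pi", 4.0)],
    )
    out["bundle_cation_pi"] = make_bundle(
        ["AAAKAAA", "AAAYAAA"],
        planted_pairs=[PlantSpec("A", 4, "B", 4, "cation_pi", 4.0)],
    )
    return out
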