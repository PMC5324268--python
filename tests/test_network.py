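"""Bond detectors, binary edge collapse, and graph export."""

import networkx as nx
import numpy as np
import pytest

from rinvar.chemistry import load_chemistry
from rinvar.fixtures import PlantSpec, make_bundle, oracle_scan
from rinvar.network import (
    BondType,
    DetectorConfig,
    InteractionEdge,
    build_graph,
    detect_interactions,
    detect_pair,
    export_graph,
    import_graph,
)
from rinvar.structure import Atom, Residue, Structure

CHEM = load_chemistry()


def _pair_structure(aa_i, atoms_i, aa_j, atoms_j):
    """Two residues with hand-placed atoms, backbones far apart."""
    def res(seq, aa, named, base):
        atoms = [
            Atom("N", "N", base + np.array([0.0, 20.0, 0.0])),
            Atom("CA", "C", base + np.array([1.5, 20.0, 0.0])),
            Atom("C", "C", base + np.array([2.5, 20.0, 1.0])),
            Atom("O", "O", base + np.array([3.5, 20.0, 1.0])),
        ]
        atoms += [Atom(n, n[0], np.asarray(c, float)) for n, c in named]
        return Residue("A", seq, aa, atoms)

    return Structure(id="pair", residues=[
        res(1, aa_i, atoms_i, np.zeros(3)),
        res(5, aa_j, atoms_j, np.array([40.0, 0.0, 0.0])),
    ])


class TestDetectorRules:
    def test_hydrophobic_pair_below_cutoff(self):
        s = _pair_structure(
            "LEU", [("CB", [0, 0, 0]), ("CD1", [1, 0, 0])],
            "LEU", [("CD1", [5.5, 0, 0])],
        )
        edges = detect_interactions(s)
        assert len(edges) == 1
        assert edges[0].bond_types == {BondType.HYDROPHOBIC}
        (ev,) = edges[0].evidence
        assert (ev.atom_i, ev.atom_j) == ("CD1", "CD1")
        assert ev.distance == pytest.approx(4.5)

    def test_exactly_at_cutoff_is_excluded(self):
        s = _pair_structure("LEU", [("CD1", [0, 0, 0])], "LEU", [("CD1", [5.0, 0, 0])])
        assert detect_interactions(s) == []

    def test_salt_bridge_also_scores_as_hbond(self, fixture_set):
        _, cmap = fixture_set["bundle_salt"]
        types = cmap.types(("A", 4, ""), ("B", 4, ""))
        assert {"salt_bridge", "hbond"} <= types

    def test_hbond_respects_tighter_cutoff(self):
        # donor-acceptor at 4.0 Å: inside the global cutoff, outside the H-bond one
        s = _pair_structure("SER", [("OG", [0, 0, 0])], "ASN", [("OD1", [4.0, 0, 0])])
        edges = detect_interactions(s)
        assert all(BondType.HBOND not in e.bond_types for e in edges)
        s2 = _pair_structure("SER", [("OG", [0, 0, 0])], "ASN", [("OD1", [3.0, 0, 0])])
        (edge,) = detect_interactions(s2)
        assert BondType.HBOND in edge.bond_types

    def test_pi_pi_needs_centroid_proximity(self):
        # rings whose nearest atoms touch but whose centroids are far: an
        # edge-on sliver excluded by the centroid bound, admitted without it
        ring = [("CG", [0, 0, 0]), ("CD1", [1.39, 0, 0]), ("CE1", [2.08, 1.2, 0]),
                ("CZ", [1.39, 2.4, 0]), ("CE2", [0, 2.4, 0]), ("CD2", [-0.69, 1.2, 0])]
        far_ring = [(n, [c[0] + 4.9, c[1] + 4.3, c[2]]) for n, c in ring]
        s = _pair_structure("PHE", ring, "PHE", far_ring)
        loose = DetectorConfig(pipi_centroid_cutoff=None)
        types_loose = {t for e in detect_interactions(s, config=loose) for t in e.bond_types}
        tight = DetectorConfig(pipi_centroid_cutoff=5.0)
        types_tight = {t for e in detect_interactions(s, config=tight) for t in e.bond_types}
        assert BondType.PI_PI in types_loose
        assert BondType.PI_PI not in types_tight

    def test_cation_pi_between_lysine_and_ring(self, fixture_set):
        _, cmap = fixture_set["bundle_cation_pi"]
        assert "cation_pi" in cmap.types(("A", 4, ""), ("B", 4, ""))

    def test_peptide_bond_pair_not_hbond_evidence(self, ala_helix):
        s, _ = ala_helix
        for e in detect_interactions(s):
            if abs(e.res_i[1] - e.res_j[1]) == 1:
                for ev in e.evidence:
                    assert {ev.atom_i, ev.atom_j} != {"O", "N"} or ev.bond_type != BondType.HBOND

    def test_detector_symmetry(self, mixed_helix):
        s, _ = mixed_helix
        cfg = DetectorConfig()
        for i in range(0, len(s.residues), 3):
            for j in range(i + 1, len(s.residues), 2):
                fwd = detect_pair(s.residues[i], s.residues[j], CHEM, cfg)
                rev = detect_pair(s.residues[j], s.residues[i], CHEM, cfg)
                assert {(e.atom_i, e.atom_j, e.bond_type) for e in fwd} == \
                       {(e.atom_j, e.atom_i, e.bond_type) for e in rev}

    def test_edge_set_monotone_in_cutoff(self, mixed_helix):
        s, _ = mixed_helix
        def edge_set(c):
            cfg = DetectorConfig(cutoff=c, hbond_cutoff=min(3.5, c))
            return {(e.res_i, e.res_j) for e in detect_interactions(s, config=cfg)}
        e35, e45, e50 = edge_set(3.5), edge_set(4.5), edge_set(5.0)
        assert e35 <= e45 <= e50

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig(cutoff=0.0)

    def test_production_matches_bruteforce_oracle(self, mixed_helix):
        s, cmap = mixed_helix
        prod = {
            (e.res_i, e.res_j): frozenset(t.value for t in e.bond_types)
            for e in detect_interactions(s)
        }
        assert prod == dict(cmap.contacts)


class TestGraphBuild:
    def test_multi_evidence_collapses_to_one_edge(self, fixture_set):
        s, _ = fixture_set["bundle_salt"]
        edges = detect_interactions(s)
        g = build_graph(edges, s)
        assert g.number_of_edges() == len(edges)
        rich = max(edges, key=lambda e: len(e.evidence))
        assert len(rich.evidence) > 1  # many atom pairs, still one edge

    def test_empty_edges_keep_all_nodes(self, ala_helix):
        s, _ = ala_helix
        g = build_graph([], s)
        assert g.number_of_nodes() == 10 and g.number_of_edges() == 0

    def test_unknown_residue_in_edge_rejected(self, ala_helix):
        s, _ = ala_helix
        ghost = InteractionEdge(("Z", 1, ""), s.residues[0].key, [])
        with pytest.raises(ValueError):
            build_graph([ghost], s)

    def test_planted_bundle_edges_match_ground_truth(self):
        s, cmap = make_bundle(
            ["AAALAAA", "AAALAAA"],
            planted_pairs=[PlantSpec("A", 4, "B", 4, "hydrophobic", 4.5)],
        )
        g = build_graph(detect_interactions(s), s)
        assert set(map(frozenset, g.edges)) == set(map(frozenset, cmap.edge_set))


class TestGraphExport:
    @pytest.mark.parametrize("fmt", ["edgelist", "graphml"])
    def test_roundtrip_is_labelled_isomorphic(self, tmp_path, mixed_helix, fmt):
        s, _ = mixed_helix
        g = build_graph(detect_interactions(s), s)
        p = tmp_path / f"g.{fmt}"
        export_graph(g, p, fmt)
        back = import_graph(p, fmt)
        assert set(back.nodes) == set(g.nodes)
        assert {frozenset(e) for e in back.edges} == {frozenset(e) for e in g.edges}
        assert all(back.nodes[n]["aa"] == g.nodes[n]["aa"] for n in g.nodes)

    def test_empty_graph_exports_header_only(self, tmp_path):
        export_graph(nx.Graph(), tmp_path / "e.tsv", "edgelist")
        lines = (tmp_path / "e.tsv").read_text().splitlines()
        assert lines == ["# node_i\tnode_j\tbond_types"]

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_graph(nx.Graph(), tmp_path / "x", "dot")
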