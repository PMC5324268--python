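# Methods

## Model

A protein structure is reduced to an undirected, unweighted residue
interaction network (RIN): nodes are residues, and an edge is present
whenever at least one non-covalent interatomic contact is detected between
the two residues.  The modelling assumption is that a point substitution
perturbs function mainly through the local rewiring of this contact graph,
and that the perturbation is summarized well by the change in shortest-path
centrality at the mutated site.  The pipeline is deliberately geometric and
deterministic: no energies, no dynamics, no stochastic optimization.

## Bond detection

Five detectors scan every residue pair on heavy atoms only (so structures
with and without hydrogens give identical graphs).  All comparisons are
strict (`<`).

| detector     | atom groups (per residue type)                   | criterion |
|--------------|--------------------------------------------------|-----------|
| hydrophobic  | aliphatic side-chain C not bonded to N/O, plus all aromatic ring C | d < 5.0 Å |
| hydrogen bond| donor heavy atoms (N/O/S carriers) × acceptor heavy atoms | d < 3.5 Å |
| salt bridge  | cationic (Lys NZ; Arg NE/CZ/NH1/NH2) × anionic (Asp OD1/2; Glu OE1/2) | d < 5.0 Å |
| π-π          | aromatic ring atoms of Phe/Tyr/His/Trp (Trp: both rings) | any atom pair < 5.0 Å **and** ring centroids < 7.0 Å |
| cation-π     | cationic atom × aromatic ring atom               | d < 5.0 Å |

Parameters (all configurable per run): global cutoff 5.0 Å — the
conventional upper bound for side-chain contact detection in RIN work;
donor-acceptor bound 3.5 Å — the standard heavy-atom hydrogen-bond
distance, used without an angle term because screening-grade models
commonly lack hydrogens; π-π centroid bound 7.0 Å — a sanity filter that
removes edge-on ring pairs whose nearest atoms touch while the rings
themselves point apart (disable with `pipi_centroid_cutoff=None`).

Group membership is data, not code: `data/chemistry_groups.tsv` assigns
every heavy atom of the 20 standard amino acids to its groups and can be
replaced by the user.  Dialect choices baked into the packaged table:
histidine is neutral (donor/acceptor and aromatic, never cationic);
cysteine SG may donate and accept; methionine SD accepts; sulfur-bonded
carbons count as hydrophobic (Met CB/CG/CE) while N/O-bonded ones do not
(Ser CB, Lys CE, Arg CD are excluded); glycine contributes only backbone
atoms, including no CA hydrophobicity.

Sequence-adjacent residues are eligible pairs — helical backbone hydrogen
bonds at i,i±3/4 are real network edges — but the covalently constrained
peptide-bond neighbourhood (amide N of residue i+1 against carbonyl C/O of
residue i, which sit within hydrogen-bond range by covalent geometry alone)
is excluded from hydrogen-bond evidence.

All evidence for a pair collapses to one binary edge; the number of
supporting atom pairs and bond types is retained on the
`InteractionEdge` record but does not weight the graph.

## Mutagenesis

`mutate` replaces one residue's side chain with a canonical-conformer
template of the target type: backbone atoms (N, CA, C, O) are preserved
bit-for-bit, CB is kept when both types have one, and remaining side-chain
atoms are placed by mapping the template's local N–CA–CB frame onto the
actual backbone (Kabsch superposition on N/CA/C when no CB exists, e.g.
mutating glycine).  Templates are Chemical Component Dictionary
ideal-geometry heavy atoms shipped as packaged JSON
(`data/sidechain_templates.json`); users may substitute their own
coordinates, which doubles as the rotamer hook.

Consequences, by design: the operation is exactly deterministic and
byte-stable on non-target residues; no refinement or rotamer search is
performed, so clashes can occur — any non-bonded heavy-atom pair closer
than 2.0 Å is reported as a `StericClashWarning`, never repaired.
Mutations to or from proline are applied but flagged (the backbone ring is
not re-closed).  Because real mutant structures relax, absolute Δ values
from unrefined templates are a screening signal, not a prediction of the
refined geometry.

## Centrality

Six metrics on unweighted hop-count shortest paths, with Brandes-style
fractional tie handling (never arbitrary tie-breaking):

* **B_ct** — pair-sum betweenness, normalized by (N′−1)(N′−2)/2 within each
  connected component (component size N′), so values live in [0, 1] on
  disconnected graphs too; raw values retained.
* **EB_ct** — raw edge betweenness (endpoint pairs included), used for
  ranking/visualization, not normalized.
* **D** — degree; **CC_ct** — triangle fraction 2e_n/k_n(k_n−1), defined as
  0 for degree ≤ 1 (the formula is 0/0 there).
* **C_ct** — inverse mean distance over *reachable* nodes
  (component-local), 0 for isolated nodes.
* **E_ct** — maximum finite shortest-path distance, 0 for isolated nodes.

B_ct and C_ct are additionally reported ×100 (`report_scale`), the scale on
which Δ statistics and the classification cutoff are quoted.  Whether
betweenness should be normalized per component or over the whole graph is a
genuine convention choice on disconnected graphs; per-component is
implemented because it keeps the [0, 1] interpretation for every node.

## Δ statistic, cutoff and calibration

For each variant, Δvalue = mutant value − WT value at the mutated node
(positions must match; residue identity differs).  The classifier is
`pathogenic-like iff |ΔB_ct| > cutoff`, strict, with default cutoff 0.26 on
the ×100 scale; scores exactly at the cutoff are benign-like (no packaged
reference value sits on the boundary, so the convention is free there).

Calibration on a labelled set: ROC over |ΔB_ct| with gain-of-function as
positives; AUC is the tie-corrected rank (Mann–Whitney) statistic, which
the tests verify equals the trapezoid area; the 95% CI uses DeLong's
placement-value variance; the operating point maximizes the Youden index
(ties toward the smaller cutoff) and is reported as the midpoint of the
indifference interval between adjacent achieving scores.  Group location
comparison uses the unpaired two-sample rank-sum test on |ΔB_ct| (the
paired signed-rank form is available as `variant="signed-rank"` for
equal-length paired samples).

The packaged reference set (`data/reported_deltas.tsv`, SHA-256 guarded) is
83 NaV1.7 variants with published ΔB_ct values: 30 gain-of-function (20
IEM, 5 SFN, 5 PEPD) and 53 controls (4 electrophysiologically silent
variants, 49 cross-species homolog substitutions).  Those ΔB_ct values were
derived on a refined homology model with a third-party engine's bond
dialect, so they are reference data for the statistical layer, not a target
the structural pipeline re-derives; recomputing group means from the
printed per-variant values carries up to ±0.01 of propagated rounding.

## Synthetic data

The fixtures module emulates exactly what the detectors need and nothing
more: ideal α-helical peptides (backbone chained at φ/ψ = −57°/−47°, which
realizes the canonical 1.5 Å rise and ~100° twist) with template side
chains, and parallel helix bundles in which side chains are rigidly
translated to put chosen atom pairs at chosen distances ("planting" a
contact of a chosen bond type).  Ground truth comes from `oracle_scan`, a
brute-force nested-loop re-implementation of the bond rules kept
deliberately separate from the production detector; the production/oracle
agreement check is therefore a genuine dual-route test.  Mutation
scenarios plant 3–5 hydrophobic partners on the ring tip of a
phenylalanine and mutate it to serine (contact loss) or the reverse
(glycine to phenylalanine, contact gain), with the expected ΔD sign
verified by oracle scans at generation time.

What passing these tests shows: the detectors, graph collapse, centrality
code and Δ bookkeeping are correct against independent implementations on
decidable geometry.  What it does not show: performance on real,
energy-relaxed protein structures — planted fixtures have detached side
chains, no packing context, no solvent, and contacts placed one at a time,
none of which resemble native environments.

## Numerical choices and degenerate inputs

Strict inequalities at every distance cutoff (a pair exactly at the cutoff
does not bond); first coordinate model and first alternate location only;
insertion codes preserved; atoms named in a detector group but absent from
a (truncated) residue are silently skipped; rings with fewer than three
present atoms contribute no π evidence; empty graphs and isolated nodes are
legal everywhere (metrics return 0 by the conventions above); planted
distances below a 2.4 Å van der Waals floor are rejected.  PDB output uses
the fixed 8.3 coordinate field, so round trips preserve coordinates to
three decimals; residue numbers above 9999 and coordinates ≥ 10000 Å are
format errors, not silent truncation.

## Problem sizes

The default validation suite uses graphs of ≤ 12 nodes for exhaustive
path-enumeration cross-checks (200 random draws in the acceptance script),
eight shipped fixture structures of 10–15 residues per helix, and 20
seeded mutation scenarios of ~50 residues — sizes at which the brute-force
oracles are exact and fast.  The production code itself scales to
full-size channel models (KD-tree candidate prefiltering; Brandes
betweenness is O(|N||E|)).

## Known limitations

* Single most-common-conformer side-chain placement without relaxation
  biases absolute Δ values on real structures; signs and large magnitudes
  are the trustworthy part of the signal.
* The hydrogen-bond rule is distance-only; with hydrogens present a
  directional term would be stricter.
* No disulfides, no water-mediated bridges, no ligands or nucleic acids,
  no mmCIF input, no multi-residue or insertion/deletion variants.
* The 0.26 cutoff was calibrated on one channel family in one
  conformational state; transferring it to other proteins requires
  re-calibration with `roc` on a labelled set.
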