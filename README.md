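# rinvar

Residue interaction network analysis of protein point variants: build a
contact graph from a structure, mutate residues in silico, and score each
variant by how much it shifts the betweenness centrality of the mutated
site.

## The problem

Missense variants in the voltage-gated sodium channel NaV1.7 (*SCN9A*)
cause painful gain-of-function syndromes — inherited erythromelalgia (IEM),
paroxysmal extreme pain disorder (PEPD) and small fibre neuropathy (SFN) —
while many other substitutions leave the channel's biophysics untouched.
Deciding which newly observed variants deserve expensive voltage-clamp
characterization is a triage problem.  One structural signal that separates
the two classes is topological: represent the protein as a graph whose
nodes are residues and whose edges are detected non-covalent interatomic
contacts, and ask how much a substitution rewires the shortest-path traffic
through the mutated position.

`rinvar` implements that pipeline for structural bioinformaticians and
ion-channel groups: PDB in, residue interaction network (RIN) out, with
per-variant Δ-centrality statistics and a ROC-calibrated classification
rule on top.

## The statistic

For a graph G = (N, E) with unweighted shortest-path counts σ_st and
σ_st(n) (those passing through node n), the betweenness centrality of n is

    B_ct(n) = Σ_{s≠n≠t} σ_st(n) / σ_st ,

normalized per connected component by (N′−1)(N′−2)/2 and reported ×100.
Alongside B_ct the package computes edge betweenness EB_ct, degree D,
clustering coefficient CC_ct = 2e_n / k_n(k_n−1), closeness
C_ct = 1/mean d(n,m) (×100) and eccentricity E_ct = max finite d(n,m).

A variant is scored by

    ΔB_ct = (B_ct^mutant − B_ct^WT) × 100      (at the mutated site)

and called **pathogenic-like** when |ΔB_ct| > 0.26, the cutoff that
maximizes the Youden index on the packaged reference set of 83 NaV1.7
variants (30 electrophysiologically confirmed gain-of-function mutations,
53 presumed-benign controls).

Edges are detected by five geometric rules on heavy atoms (hydrophobic
packing, hydrogen bond, salt bridge, π-π stacking, cation-π) with a strict
5.0 Å atom-atom bound (3.5 Å donor-acceptor for hydrogen bonds) and
collapsed into binary contacts.  Mutants are built by deterministic
template side-chain replacement — no refinement — so the package is a
screening tool, not a substitute for molecular mechanics.

## Worked example

Classify the packaged reference set:

```sh
rinvar report --reported -o out/
```

prints

```json
{
  "n": 83, "n_gf": 30, "n_control": 53,
  "cutoff": 0.26,
  "counts": {"tp": 23, "fp": 9, "tn": 44, "fn": 7},
  "sensitivity": 0.7666666666666667,
  "specificity": 0.8301886792452831,
  "mean_abs_delta_b_ct_gf": 1.1421333333333332,
  "mean_abs_delta_b_ct_control": 0.19849735849056607,
  "rank_sum_statistic": 1284.0,
  "p_value": 3.6208561156477376e-06,
  "auc": 0.8075471698113208,
  "auc_ci_95": [0.7003720451240314, 0.9147222944986102],
  "best_cutoff": 0.2645
}
```

(abridged): the strict |ΔB_ct| > 0.26 rule recovers 23 of the 30
gain-of-function variants (77% sensitivity) at 83% specificity; the
two groups differ strongly in |ΔB_ct| (rank-sum p ≈ 4·10⁻⁶) and the score
discriminates with AUC 0.81 (DeLong 95% CI 0.70–0.91).  The Youden-optimal
cutoff re-derived from the data is 0.2645, the midpoint of the indifference
interval around 0.26.

Build a network from a structure (here a synthetic helix):

```sh
rinvar fixtures -o fx/            # writes test PDBs with ground-truth maps
rinvar build-net fx/helix_ala10.pdb -o net/
head -3 net/nodes.tsv
```

```
node    b_ct_raw  b_ct      b_ct_scaled  degree  cc_ct   c_ct    c_ct_scaled  e_ct
A:1     0.5       0.013888  1.388888     3       0.3333  0.5625  56.25        3
A:2     0.7       0.019444  1.944444     4       0.5     0.6428  64.28        2
```

Batch-screen variants (`rinvar delta structure.pdb variants.tsv -o out/`)
with a delimited list of labels like `I848T`; each row is mutated,
re-detected and reported as a Δ row with its classification call.

The same operations are available as a library:

```python
from rinvar import read_pdb, mutate, parse_mutation_label
from rinvar import detect_interactions, build_graph, profile, compute_delta

wt = read_pdb("structure.pdb")
spec = parse_mutation_label("I848T", chain_id="A")
mut = mutate(wt, spec)
p_wt = profile(build_graph(detect_interactions(wt), wt))
p_mut = profile(build_graph(detect_interactions(mut), mut))
rec = compute_delta(p_wt, p_mut, ("A", 848, ""), label="I848T")
print(rec.delta_b_ct, rec.call)
```

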