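# Methods

## Similarity model

Two protein–ligand complexes are compared with four metrics.

**Tanimoto (ligand chemistry).** Count-based circular fingerprints of the
heavy-atom ligand graph, radius 2, hashed to 2048 buckets (RDKit Morgan
generator). For count fingerprints the Tanimoto coefficient is
Σᵢ min(aᵢ,bᵢ) / Σᵢ max(aᵢ,bᵢ) over the union of occupied buckets; two empty
fingerprints score 1 by convention (identical degenerate objects). Bucket
collisions are implementation-dependent, so the generator parameters are
fixed constants of the package.

**TM-score (protein fold).** The structural aligner is a pluggable
contract. The production adapter shells out to an external TM-align binary
and parses both length-normalized scores, the sequence identity and the
rigid transform. The default (and test-time) aligner superposes
index-matched Cα atoms by least squares (Kabsch) and evaluates the TM-score
formula TM(L) = (1/L) Σᵢ 1/(1 + (dᵢ/d₀(L))²) with
d₀(L) = max(0.5, 1.24·(L−15)^⅓ − 1.8), under both chain-length
normalizations; the larger value is the similarity score, so a protein
well-represented inside a larger one still scores high. The index-matched
aligner assumes the residue correspondence is positional — true for the
synthetic fixtures by construction, not for real remote homologs, which is
exactly why the contract keeps TM-align pluggable for real data.

**Pocket-aligned ligand RMSD (pose).** Ligand B's heavy-atom coordinates
are carried through the protein superposition (x ↦ R x + t), then compared
to ligand A's by nearest-neighbour RMSD. With unequal atom counts the
distances run from each atom of the *larger* cloud to its nearest
neighbour in the smaller (penalizing size mismatch); with equal counts,
from A to B. Hydrogens are excluded throughout: crystal structures rarely
resolve them, and including them would make the metric depend on a
protonation model rather than on the observed pose.

**ΔpK.** Absolute difference of the labels; the affinity bands below are
symmetric, so only the magnitude matters.

The display score S = TM + Tanimoto + (1 − RMSD) − ΔpK summarizes a pair
(self-comparison: exactly 3). Negative values are legal (distant pairs).

## Curation

**Leakage filter (train vs test).** A training complex is excluded when a
test complex satisfies ΔpK ≤ 1 *and* either (a) Tanimoto > 0.9 — the ligand
is essentially identical, so its label could be memorized regardless of the
protein — or (b) TM > 0.8 and Tanimoto + (1 − RMSD) > 0.8 — similar fold
with a combined ligand/pose similarity. The combined term trades chemistry
against pose: a modestly similar ligand needs a very similar pose to
trigger, a near-identical ligand triggers even with pose deviations.
Boundary semantics: the comparisons written as "higher than" are strict;
the ±1 pK band is inclusive. Pairs with ΔpK > 1 are never excluded —
structurally similar complexes with divergent affinity are activity cliffs
and are deliberately kept. The filter runs against the union of all test
sets before redundancy removal; a missing entry in a similarity table is a
hard error, because silently keeping an unscored pair would hide leakage.

**Redundancy removal (train vs train).** Stricter thresholds (TM > 0.8,
Tanimoto + (1 − RMSD) > 1.3, ΔpK < 0.5, all strict) define an undirected
adjacency graph of near-duplicates. A greedy loop removes the node with the
highest degree until the graph is edgeless. Degree ties prefer general-set
over refined-set members (the refined set is the higher-quality
subcollection), then the worst diffraction resolution — interpreted as the
numerically largest Å value, with missing resolution sorting as worst —
then the lexicographically smallest id. The last rule is a determinism
closure: with it, the removal trace is invariant to node insertion order,
which the tests verify against an independent naive re-implementation that
recomputes all degrees from scratch each iteration. The greedy rule is not
a minimum vertex cover and is not meant to be; it is a transparent,
auditable heuristic whose trace (id, degree, tie-break) is part of the
output.

**Independence flags.** A test complex is independent when *no* training
complex (of the unfiltered set) triggers the leakage rule against it; the
independent subset supports evaluation unaffected by pre-existing leakage.

## Interaction graphs

A complex becomes a sparse graph: ligand heavy atoms are atom-level nodes;
every pocket residue — any heavy atom within 5 Å (inclusive) of any ligand
heavy atom — is one node anchored at its Cα; non-water heteroatoms in
contact become single atom-featurized nodes (waters are excluded: they are
solvent, not persistent interaction partners). Edges: ligand covalent
bonds, one interaction edge per (ligand atom, pocket residue) contact
within the cutoff, and one self-loop per node; every undirected edge is
stored in both directions. Contact detection is a KD-tree radius query —
the radius semantics is the contract, the tree an implementation detail.

Node features are fixed zero-padded blocks: atom-type one-hot
(B, C, N, O, P, S, Se, metal, halogen; the metal/halogen membership lists
are serialized with the schema), ring membership, hybridization, formal
charge, aromaticity, atomic mass (scaled by 1/100), bonded hydrogens,
degree, tetrahedral chirality, amino-acid one-hot, and an optional
residue-embedding slot. Edge features: edge-type one-hot
(covalent/self-loop/non-covalent), four distance slots (covalent edges use
the first for bond length; interaction edges carry distances from the
ligand atom to the residue's N, Cα, C and virtual Cβ; heteroatom contacts
use a single distance), bond type, conjugation, ring membership,
stereochemistry. All geometric features are inter-atomic distances, so the
representation is rigid-motion invariant — verified by a property test.

**Virtual Cβ.** Built identically for every residue (glycine included)
from the frame b₁ = Cα−N, b₂ = C−Cα, b₁×b₂ (each normalized), combined
with coefficients (−0.5827, 0.5680, −0.5407) and rescaled to a Cα–Cβ bond
length of exactly 1.522 Å. The construction is translation- and
rotation-equivariant and chirality-fixed: it always places Cβ on the same
side of the backbone frame, so a mirrored backbone keeps the construction's
handedness (a reflection cannot commute with a cross-product-based
out-of-plane construction; the tests assert preserved distances and fixed
handedness rather than a mirror equality that no such construction can
satisfy).

**Embeddings.** Residue- and ligand-level embedding providers are a
contract: deterministic, fixed declared widths. The package ships a
deterministic stub keyed by a cryptographic hash of (seed, sequence,
position) or (seed, line notation), so no model download is ever required;
adapters for protein/chemistry language models can implement the same
contract. Ligand embeddings initialize the graph's global features.

## Model

The network alternates three attention node convolutions with two edge
convolutions after an initial node dimensionality reduction; the global
vector is refreshed after every node convolution from (previous global,
mean-pooled node features) through a learned linear+ReLU map, and a
dropout + two-fully-connected-layer head (ReLU between) maps the final
global vector to the predicted pK.

The node convolution is the GATv2-style update given in the README, with
multi-head outputs concatenated. Self-loops are explicit edges; the
self-message uses the receiver transform Θs, neighbour messages use Θt, and
the attention softmax runs over N(i) ∪ {i} with a detached per-receiver
max-shift for numerical stability (analytically the shift cancels). When an
edge dimension is configured, a third matrix Θe lifts edge features into
both the attention argument and the message — this is the path through
which interaction distances reach the prediction. The edge convolution is a
two-layer perceptron on (source, target, edge) features; its internals are
a documented contract, not a fixed equation. Mean pooling was chosen for
the global update (the reduction is otherwise unconstrained).

The whole model runs on a small in-repo reverse-mode autodiff engine over
NumPy (broadcast arithmetic, matmul, gather/scatter segment ops,
LeakyReLU/exp/sqrt). A finite-difference gradient check validates the
engine end-to-end; the checker skips coordinates where two step sizes
disagree, i.e. where the loss sits on a ReLU kink and a finite difference
does not estimate the one-sided derivative. Linear biases are initialized
uniformly in ±1/√fan_in (not zero) so pre-activations do not start exactly
on the kink.

**Training.** Full-batch SGD with momentum (defaults: learning rate 0.02
for general use, 0.05 in the bundled experiments; momentum 0.9) minimizing
the RMSE of predicted pK; the output bias starts at the training-label mean
so early epochs fit structure rather than the DC offset. Early stopping
halts a fold when validation RMSE has not improved for 100 consecutive
epochs (patience configurable), and the parameters of the best validation
checkpoint are restored. k-fold cross-validation (default 5) shares one
seed-fixed split realization across model variants; the final predictor
averages the fold models. Non-finite losses abort the fold with a
diagnostic rather than continuing silently. Hidden widths (32 by default,
16 in the bundled experiments), head count (2) and the head width are
desk-scale choices; the learning rate, batch regime and momentum are
exposed configuration with the defaults above.

## Synthetic data

The fixture generator emulates the *similarity structure* of a curated
affinity dataset, not its chemistry or folds. Toy proteins are idealized
helical backbones (rise 1.5 Å per residue, twist drawn per seed from
88–112°, Cα wobble 0.3 Å) with randomized sequences — distinct seeds give
structurally distinct chains under the index-matched aligner. Toy ligands
are built from a 24-entry scaffold library (all ≥ 5 heavy atoms) with
optional random single-atom decorations that move the fingerprint away
from the scaffold, embedded in 3-D with a seeded ETKDG. Labels are drawn
uniformly in pK 2–12, the range of curated affinity collections.

A scenario plants (i) leaked training complexes — exact structural copies
of a test complex with a label drawn within ±0.9 pK — and (ii) redundancy
clusters — groups sharing protein, ligand and pose with labels within a
±0.2 pK half-band — on top of background complexes with distinct scaffolds
and geometries. Every scenario is self-verifying: the realized similarity
matrices are checked to sit at least 0.05 from every threshold each pair is
meant to trigger or avoid, with bounded retries and a hard error otherwise.
Because planted copies are *exact* copies, passing tests demonstrate the
bookkeeping and threshold logic of the pipeline, not the aligner's ability
to detect remote homology in real structures — that is what the TM-align
adapter is for.

Model experiments use lighter-weight random toy graphs whose label signal
is placed either in one global feature (learnability check: a linear
function must be fit to < 0.1 RMSE) or entirely in the ligand–residue
interaction-edge distances (ablation check: deleting protein nodes destroys
the signal, so validation RMSE must degrade — asserted as a sign test over
five seeds). Node features in these graphs are low-amplitude noise so the
placed signal dominates. Problem sizes (19-complex scenarios, 80–200-graph
training sets, ≤ 250 epochs) were chosen so the full study runs in about a
minute on one CPU.

## Known limitations

* The index-matched fixture aligner cannot detect similarity between
  differently-ordered chains; real-data runs need TM-align on PATH.
* Preprocessing reproduces the *categories* of structural exclusions
  (inexact labels, sanitization failures, unknown pocket residues, missing
  pocket atoms, tiny ligands); exact per-category counts on any given
  collection depend on the chemistry toolkit's validation behaviour.
* The model is desk-scale: the architecture follows the printed layer
  sequence and update equations, but hidden dimensions are small and no
  GPU-scale training is attempted.
* First NMR model only; no protonation/tautomer enumeration; one ligand
  per SDF (first molecule used, with a warning).
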