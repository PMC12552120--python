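# gems-affinity

Structure-based curation of protein–ligand binding-affinity datasets and a
sparse interaction-graph attention GNN for affinity scoring.

## The problem

Deep-learning scoring functions for protein–ligand binding affinity are
typically trained on large structure collections and benchmarked on held-out
complexes. When near-duplicates of benchmark complexes leak into the
training set, a model can reach an impressive benchmark score by
memorization alone, and its reported accuracy says little about how it will
behave on genuinely new complexes. This package provides, for computational
chemists and ML practitioners in drug discovery:

1. **Pair similarity metrics** for complexes: count-fingerprint Tanimoto of
   the ligands (radius 2, 2048 buckets, Σmin/Σmax), protein TM-score
   (normalized by both chain lengths, larger value used), pocket-aligned
   ligand RMSD (ligand coordinates carried through the protein
   superposition, nearest-neighbour RMSD), and |ΔpK|; combined into
   *S* = TM + Tanimoto + (1 − RMSD) − ΔpK.
2. **A leakage filter**: a training complex is excluded against a test
   complex when ΔpK ≤ 1 and either Tanimoto > 0.9 (ligand identity) or
   TM > 0.8 with Tanimoto + (1 − RMSD) > 0.8 (structural overlap).
   Activity cliffs (ΔpK > 1) are always retained.
3. **Greedy redundancy removal**: stricter thresholds (TM > 0.8,
   Tanimoto + (1 − RMSD) > 1.3, ΔpK < 0.5) define an adjacency graph of
   near-duplicates inside the training set; the most-connected complex is
   removed repeatedly (general-set before refined-set, then worst
   resolution, then smallest id) until no edge remains.
4. **Search baselines** that quantify leakage: predict each test complex by
   averaging the labels of its *k* most similar training complexes.
5. **Interaction graphs + an attention GNN**: ligand atoms and
   Cα-anchored pocket residues as nodes, covalent/interaction/self-loop
   edges with distance features, dynamically updated global features, and a
   GATv2-style attention update

   x′ᵢ = αᵢᵢ Θs xᵢ + Σ_{j∈N(i)} αᵢⱼ Θt xⱼ,  αᵢⱼ = softmax_k aᵀ LeakyReLU(Θs xᵢ + Θt xₖ)

   trained with SGD on the RMSE of predicted pK values, 5-fold
   cross-validation, early stopping, and fold-ensemble prediction.

A synthetic-fixture module generates toy complexes with *planted* similarity
structure, so every algorithm is exercised end-to-end without downloads.

## Worked example

```bash
python examples/03_cleansplit_curation.py
```

```
training complexes in:        19
excluded (train-test overlap): ['tr_leak00', 'tr_leak01', 'tr_leak02']
excluded (redundancy):         ['tr_red01', 'tr_red02', 'tr_red10', 'tr_red11']
retained:                      12
planted ground truth recovered: True
independent test complexes:    ['te03', 'te04'] (2/5)
```

The scenario planted three leaked training complexes (near-copies of test
complexes te00–te02) and two 3-member redundancy clusters. The filter
recovers exactly the planted leaks, thins each cluster to one surviving
member (4 removals), and flags the two test complexes without any leakage
partner as the independent subset.

The baseline example shows why this matters
(`python examples/04_search_baselines.py`):

```
  RMSE on leaked tests (3):      0.556 pK
  RMSE on independent tests (2): 3.192 pK
```

a label-averaging nearest-neighbour "predictor" looks accurate exactly
where leakage exists and collapses elsewhere.

Other examples: index parsing and preprocessing (`01`), pair similarity and
the S score (`02`), interaction-graph construction and protein ablation
(`05`), cross-validated GNN training with fold ensembling (`06`). A thin
CLI (`gems fixtures|similarity|filter|baselines`) wraps the same library
calls for file-based use.

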