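# ixprofile

Network-reordered integrative expression profiling for two-class
microarray / expression classification.

## The problem

Classical expression classifiers treat each gene as an independent
feature, so groups of functionally related genes whose individual
differential expression is weak (and usually dismissed as noise) go
undetected, even though their *coordinated* shift carries real signal.
`ixprofile` exploits protein–protein interaction (PPI) knowledge to
recover that signal: if interacting genes are placed at neighboring
positions on a one-dimensional axis, a kernel superposition of their
expression builds a peak where several weak, coordinated genes sit
together — a peak that can exceed the one formed by a single strongly
differential gene.

The pipeline has four stages:

1. **Subnetwork construction** (`network`): disease seed genes are
   expanded by nearest-neighbor hops through a scored interaction edge
   list, and the induced subgraph (largest connected component) becomes
   the disease-specific PPI network.
2. **Reordering** (`reorder`): an ant-colony optimization reordering
   (ACOR) heuristic assigns the N network genes to positions 1..N so
   that interacting genes are positionally close. Ants perform
   pheromone-biased random walks (transition weight
   τ<sub>uv</sub><sup>α</sup>·deg(v)<sup>β</sup>, evaporation ρ), their
   visit density ranks the genes, and an insertion local search then
   minimizes the linear arrangement cost
   Σ<sub>(u,v)∈E</sub> |π(u) − π(v)|.
   Baselines: damped random-walk (PageRank-style) ranking, average-linkage
   hierarchical clustering of node neighborhoods, and random permutation.
   A brute-force minimizer over all N! arrangements is available as an
   oracle for N ≤ 9.
3. **Integrative eXpression Profiling** (`ixp`): each sample's
   expression vector x is mapped onto the ordering and integrated with
   a Gaussian influence function,

   F(i) = Σ<sub>j</sub> w(g<sub>j</sub>) · x(g<sub>j</sub>) ·
   exp(−(i − π(g<sub>j</sub>))² / 2σ(r)²),  σ(r) = r · b,

   where w are degree-normalized (or unit) gene weights, r ∈ [0, 1) is
   the horizontal influence coefficient and b the base bandwidth in
   positions. At r = 0 this is exactly the weighted raw profile; the
   kernel is deliberately not renormalized, preserving the additive
   "new peak" effect.
4. **Classification** (`classify`): a linear SVM is trained on the IXP
   features of one labeled dataset and blind-tested on another, sweeping
   r over 0.0–0.9 for each ordering method.

A synthetic-data module (`synthdata`) generates planted-partition
networks with two-group expression in which some modules carry
coordinated weak shifts, so the whole pipeline is testable end to end
without any external database.

## Worked example

Simulate a study (40-gene modular network, 20 + 20 samples per dataset,
two of four modules carrying 0.4-sd coordinated shifts), reorder it with
ACOR, and sweep classification accuracy:

```sh
ixp simulate --out demo --seed 11
ixp reorder --edges demo/edges.tsv --method acor --seed 11 \
    --out demo/ordering.tsv --adjacency-out demo/adjacency.tsv
ixp sweep --edges demo/edges.tsv \
    --train demo/train.tsv --train-labels demo/train_labels.tsv \
    --test demo/test.tsv  --test-labels demo/test_labels.tsv \
    --out demo/sweep.tsv --seed 11
```

which prints

```
wrote 7 files to demo
acor ordering of 40 genes, arrangement cost 845 -> demo/ordering.tsv
50 cells -> demo/sweep.tsv; best: acor r=0.6 accuracy=0.8500
```

The arrangement cost is the summed positional distance across network
edges (smaller = interacting genes more contiguous). The sweep grid
(`demo/sweep.tsv`, long format `method  r  accuracy`) starts

```
method	r	accuracy
acor	0.0	0.675
acor	0.1	0.8
acor	0.2	0.8
```

Accuracy at r = 0 (0.675) is the raw-profile baseline — identical for
every ordering method, since the delta kernel only permutes feature
columns. Smoothing along the ACOR order lifts blind-test accuracy to
0.85 at r = 0.6: the coordinated weak modules, contiguous under ACOR,
are aggregated into detectable peaks. `demo/adjacency.tsv` holds the
reordered adjacency matrix for heatmap rendering.

The same stages are available as library calls
(`ixprofile.generate_case`, `acor_reorder`, `transform_dataset`,
`run_sweep`); see the module docstrings.

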