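# mesoresolve

Multi-resolution mesoscale analysis of weighted networks: soft, cumulative,
and windowed thresholding; resolution-parametrized community detection;
bipartivity, laterality, and community-radius diagnostics; rewiring probes;
synthetic benchmark generators; and nonparametric permutation comparison of
diagnostic curves between groups of networks.

## The problem

Brain connectivity — anatomical (fiber densities from diffusion imaging) or
functional (correlations from resting-state fMRI) — arrives as a weighted
undirected network whose edge weights span a continuum from weak to strong.
Single-number diagnostics computed on the full matrix, or on one arbitrary
binarization, are dominated by the strongest edges and hide structure
carried by weaker ones.  `mesoresolve` instead computes **mesoscopic
response functions (MRFs)**: curves of a diagnostic versus a control
parameter that sweeps through weight or organizational scales.  The package
targets researchers comparing network architecture across subjects or
clinical groups, and anyone validating mesoscale methods against synthetic
benchmarks with known ground truth.

## Core quantities

**Modularity with structural resolution.**  For a partition assigning node
*i* to community *g<sub>i</sub>*,

  Q = (1/2m) Σ<sub>ij</sub> [ A<sub>ij</sub> − γ k<sub>i</sub>k<sub>j</sub>/2m ] δ(g<sub>i</sub>, g<sub>j</sub>),

with the Newman–Girvan null P<sub>ij</sub> = k<sub>i</sub>k<sub>j</sub>/2m.
The weighted form Q<sup>w</sup> substitutes weights for the binary
adjacency, node strengths s<sub>i</sub> for degrees, and total edge weight
for m.  The resolution γ multiplies the null term: small γ yields few large
communities, large γ fragments the network into singletons.  Q is maximized
by a seeded Louvain-style greedy algorithm; because near-degenerate optima
are generic, diagnostics are reported as means ± SD over independent
restarts (20 by default).

**Bipartivity.**  From the eigenvalues λ<sub>j</sub> of the binary
adjacency matrix,

  β = Σ<sub>j</sub> cosh λ<sub>j</sub> / Σ<sub>j</sub> e<sup>λ<sub>j</sub></sup> ∈ [½, 1],

the fraction of subgraph centrality contributed by even closed walks: 1
exactly for bipartite graphs, approaching ½ for complete graphs.  A
two-group split is obtained from the eigenvector of the most negative
eigenvalue of the modularity matrix A − k kᵀ/2m.

**Laterality and radius.**  With nodes labeled by one of two categories
(e.g. hemispheres), a community's laterality Λ<sub>c</sub> =
|N<sub>L,c</sub> − N<sub>R,c</sub>|/N<sub>c</sub>; the partition-level
value is size-weighted and corrected by the expectation under random label
reassignment (1000 shuffles).  For spatially embedded nodes, a community's
radius ρ<sub>c</sub> is the norm of the per-dimension standard deviation of
its node coordinates, normalized by the whole-network radius.

**Thresholding.**  Soft thresholding maps normalized weights w → w<sup>r</sup>
(no edge removed; r < 1 equalizes, r > 1 amplifies strong edges).  Windowed
thresholding binarizes a fixed fraction *s* of edges in a contiguous band of
weight ranks with mean percentile W̄, so every graph in the family has
identical density and each (s, W̄) selects a unique edge set.

## Worked example

A fractal hierarchical benchmark network with three levels (complete
elementary groups of 64 at weight 1; sibling modules joined at weights ½
and ¼, density halving per level):

```python
import numpy as np
from mesoresolve import (generate_fractal_hierarchical, louvain_optimize,
                         mrf_windowed)

net, truth = generate_fractal_hierarchical(256, 24192, 64, seed=7)
print(f"FH network: N={net.n_nodes}, M={net.n_edges}, levels={truth['n_levels']}")

res = louvain_optimize(net, gamma=1.0, n_runs=20, seed=1)
print(res.summary())

curve = mrf_windowed(net, s=0.25, diagnostic="Q_binary", n_runs=5, seed=2,
                     n_points=9)
beta = mrf_windowed(net, s=0.25, diagnostic="bipartivity", n_points=9)
print("\n  wbar    Q_binary  bipartivity")
for w, q, b in zip(curve.grid, curve.values, beta.values):
    print(f"  {w:.3f}   {q:.3f}     {b:.3f}")
```

Output:

```
FH network: N=256, M=24143, levels=3
Modularity maximization
===============================================
mode: weighted    gamma: 1    runs: 20
diagnostic                     mean         sd
-----------------------------------------------
quality                     0.35817          0
n_communities                     2          0
n_singletons                      0          0
n_nonsingleton                    2          0
mean_nonsingleton_size          128          0

  wbar    Q_binary  bipartivity
  0.125   0.079     1.000
  0.219   0.078     1.000
  0.312   0.075     1.000
  0.406   0.292     0.724
  0.500   0.500     1.000
  0.594   0.445     1.000
  0.688   0.654     0.500
  0.781   0.669     0.500
  0.875   0.667     0.500
```

Every Louvain restart finds the same two-module split of the full weighted
network (Q<sup>w</sup> ≈ 0.358).  The windowed curves resolve what that
single number hides: binary modularity rises in three plateaus — one per
hierarchy level (weak inter-module edges ≈ 0.08, mid-level pairs ≈ 0.5,
elementary cliques ≈ 0.67) — while bipartivity steps down from 1 (windows
inside one level are bipartite between modules) to ½ (cliques), dipping at
mixed windows where odd cycles first appear.

A command-line interface mirrors the library
(`mesoresolve generate | threshold | community | mesoscale | rewire | mrf |
compare`); every run takes a master `--seed` and writes a manifest, and
repeated runs are byte-identical.

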