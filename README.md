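# anatnet

Anatomical network analysis (AnNA) for musculoskeletal systems.

Comparative anatomists model an anatomical system — a head, a forelimb,
a hindlimb — as an unweighted, undirected network: bones and muscles are
nodes, and a link records physical contact between two structures, coded
as 0/1 in a labeled adjacency matrix. Network statistics then quantify
the system's morphological organization free of *a priori* assumptions:
how complex it is, how integrated, and how it decomposes into
**connectivity modules** — groups of structures more connected among
themselves than to the rest. Contrasting left and right sides, or
normal and abnormal specimens, turns qualitative impressions of
asymmetry or disorganization into numbers.

`anatnet` implements this pipeline end to end for researchers in
morphology, evo-devo and teratology:

- **Parameters** — N (nodes), K (links), density
  `D = 2K/(N(N−1))`, mean clustering coefficient C, mean shortest path
  length L, and heterogeneity H (coefficient of variation of the degree
  sequence, a proxy for differentiation of parts), plus degree/clustering
  distribution fits (Poisson, uniform, exponential, power law) and a
  small-world index against a seeded Erdős–Rényi ensemble.
- **Modules** — walktrap community detection (short random walks,
  default `steps = 3`) with the merge sequence cut at maximum
  modularity `Q = Σ_s [e_s/m − (d_s/2m)²]`; a delete-one-link jackknife
  standard error of Q; the conventional classification (Q < 0.3 low,
  Q > 0.3 high, confident when `Q − Q_error > 0.3`); and a one-sided
  Wilcoxon rank-sum test of each module's internal versus external
  connections. The clusterer is a scikit-learn estimator
  (`Walktrap().fit_predict(graph)`).
- **Comparison** — right-minus-left deltas of all parameters, adjusted
  Rand index / NMI between the two module decompositions on shared
  structures, and a permutation null for asymmetry based on
  degree-preserving edge rewiring.
- **Synthetic data** — stochastic block models with planted modules,
  bone/muscle typing, and perturbed bilateral pairs, matching the size,
  density and modularity ranges of real musculoskeletal networks, so
  every stage is testable against known ground truth.

See `docs/methods.md` for the models, conventions and caveats.

## Worked example

```python
from anatnet import (SyntheticSpec, generate_planted,
                     network_parameters, modularity_report)

spec = SyntheticSpec(block_sizes=(15, 15, 15, 15), p_in=0.4, p_out=0.01,
                     seed=7, connect_strategy="spanning_bridge")
planted = generate_planted(spec)          # 60 structures, 4 planted modules
net = planted.network

p = network_parameters(net)
print(f"N={p.N} K={p.K} D={p.D:.6f} C={p.C:.6f} L={p.L:.6f} H={p.H:.6f}")

res = modularity_report(net)
print(f"modules={res.n_modules} Q={res.Q:.6f} "
      f"Q_error={res.Q_error:.6f} class={res.modularity_class}")
for rep in res.module_reports:
    print(f"  module {rep.module_id}: {len(rep.bones)} bones, "
          f"{len(rep.muscles)} muscles, p={rep.p_value:.2e}")
```

prints

```
N=60 K=189 D=0.106780 C=0.349877 L=2.962712 H=0.315204
modules=4 Q=0.658688 Q_error=0.021300 class=confident_high
  module 1: 5 bones, 10 muscles, p=2.34e-06
  module 2: 4 bones, 11 muscles, p=1.21e-06
  module 3: 6 bones, 9 muscles, p=8.65e-07
  module 4: 4 bones, 11 muscles, p=1.24e-06
```

The four detected modules recover the four planted blocks exactly
(adjusted Rand index 1.0 against the generator's truth); Q ≈ 0.66 with
a jackknife error of ≈ 0.02 clears the 0.3 threshold, so the partition
is confidently better than random. Each module's members connect
significantly more inside than outside their module (rank-sum p ≈ 10⁻⁶).

On real data the entry point is a labeled 0/1 adjacency CSV:

```python
from anatnet import read_adjacency
net = read_adjacency("adult_head.csv", tissue_map={...})
```

or the command line:

```sh
anatnet --out-dir results metrics  head.csv forelimb.csv
anatnet --out-dir results modules  head.csv
anatnet --out-dir results compare  forelimb_left.csv forelimb_right.csv
anatnet --out-dir results simulate --suite
```

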