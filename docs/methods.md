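# Methods

`anatnet` analyses anatomical systems — heads, forelimbs, hindlimbs — as
unweighted, undirected, simple networks. Bones and muscles are nodes; an
edge records physical contact between two structures, coded 0/1 in a
labeled adjacency matrix. The package quantifies the topology of such
networks, decomposes them into connectivity modules, and contrasts
paired (left/right, normal/abnormal) networks. This note documents the
models, conventions and numerical choices behind each stage, and what
the synthetic test beds do and do not establish.

## Network model and descriptive parameters

A network is a set of uniquely labeled nodes typed by tissue (`bone`,
`muscle`, `other`) and body side (`left`, `right`, `midline`,
`unspecified`), with side inferred from a configurable label-suffix rule
(default: substring match on `.Left` / `.Right`). Adjacency matrices are
validated strictly — non-square shape, label mismatches, non-binary or
blank cells, asymmetric cell pairs, and nonzero diagonals are errors,
never auto-repaired, because in hand-curated contact matrices these are
transcription bugs. Isolated structures are retained in the node count:
N counts anatomical parts, not only connected ones.

Six parameters summarize each network:

- **N, K** — counts of structures and contacts.
- **D = 2K / (N(N−1))** — density, the realized fraction of possible
  contacts.
- **C** — mean local clustering coefficient. Nodes with degree < 2 have
  no defined local coefficient; by default they contribute 0 to the mean
  (keeping C defined and bounded for every network), with an `exclude`
  alternative available. The published tables we anchor against do not
  state their convention, so it is configurable and documented rather
  than hard-wired.
- **L** — mean shortest-path length over unordered node pairs, in
  links. On fragmented networks the default averages over reachable
  pairs only (a `strict` mode raises instead); infinite distances would
  otherwise leave L undefined.
- **H** — heterogeneity, the coefficient of variation of the degree
  sequence using the population (divide-by-N) standard deviation: the
  degree sequence is fully observed, not sampled. H = 0 exactly on
  regular structures; larger H signals differentiation of parts
  (anisomerism).

## Degree/clustering distribution fits and the small-world check

Before a modularity analysis it is standard to confirm a non-random
connectivity pattern: right-skewed degree and clustering distributions
and a small-world organization. `fit_distribution` fits four families by
maximum likelihood:

- Poisson (rate = sample mean) and uniform — discrete families, tested
  by chi-square with tail bins pooled until expected counts reach 5;
- exponential (scale = sample mean) and power law — continuous tail
  families, tested by Kolmogorov–Smirnov against the fitted law. The
  power law uses the continuous MLE `alpha = 1 + n / sum(log(x/x_min))`
  with `x_min` chosen by KS minimization over candidate values.

AIC is reported for cross-family ranking and is always evaluated on the
full sample; for the power law this uses a full-support fit anchored at
the smallest positive value, because the KS-chosen tail covers only a
subsample and AICs computed on different data are not comparable. KS
p-values are the asymptotic ones and are approximate when parameters are
estimated from the same data; they are used for ranking and rough
screening, not sharp inference.

`small_world` compares observed C and L with means over a seeded
Erdős–Rényi G(N, K) ensemble (default 1000 graphs; the seed is a
required argument): `sigma = (C/C_rand) / (L/L_rand)`, with `C_rand`
floor-clamped at `1/(N(N−1))` to keep the ratio defined on very sparse
networks. Sigma > 1 indicates clustering in excess of random at
comparable path length.

## Module detection: short random walks

Connectivity modules — groups of structures more connected among
themselves than to the rest — are delimited with the walktrap
agglomeration. On each connected component:

1. The lazy random walk (a self-loop added to every vertex, transition
   matrix `P = (A + I) / (d + 1)`) is iterated `steps` times
   (default 3, short walks). The self-loop makes the short walk
   aperiodic and matches the reference implementations of the
   algorithm; without it the merge order diverges from the canonical
   one.
2. The distance between communities C1, C2 is the degree-weighted
   Euclidean distance between their mean t-step probability vectors,
   `r² = Σ_k (P_{C1k} − P_{C2k})² / d_k`.
3. Communities start as singletons and only adjacent communities merge,
   greedily minimizing the Ward-style increase
   `ΔΣ = |C1||C2| / (|C1|+|C2|) · r² / n`. Ties in ΔΣ (compared after
   rounding to 10 decimals, so float summation noise cannot flip the
   order) are broken toward the lexicographically smallest
   (min id, max id) pair, ids inherited from input node order — making
   the procedure fully deterministic and stable under node permutation.
4. The merge sequence is cut at the level maximizing modularity
   `Q = Σ_s [e_s/m − (d_s/2m)²]`, ties resolved toward the coarser
   partition. On disconnected networks the cut level is chosen per
   component (Q is additive over modules), components never merge — no
   random walk crosses them — and isolated nodes become singleton
   modules.

The implementation was cross-checked against python-igraph's walktrap:
on all 994 connected graphs of the standard small-graph atlas (≤ 7
nodes) the detected maximum-modularity cut has identical Q in 986
cases, the remainder being tie-break differences split roughly evenly
between the two implementations.

**Known limitation.** Like any agglomerative heuristic, walktrap is
near-optimal only where modular structure exists. On small planted
two-block graphs the cut reaches ≥ 90% of the exhaustively enumerated
maximum Q in over 90% of cases, but on unstructured (Erdős–Rényi)
graphs — where the global maximum Q is itself near zero — the dendrogram
frequently misses the best partition, and the ≥ 0.9-of-optimum rate
drops to roughly 0.55–0.75 depending on size and density. This equally
affects the reference igraph implementation; it is a property of the
algorithm, not of this re-implementation. Conclusions should therefore
rest on detected modules only when the prerequisite checks (Q well
above 0, small-world organization) hold.

## Q classification and jackknife error

The delete-one-link jackknife treats each contact as an independent
observation: Q is recomputed with each link removed in turn, the
partition held fixed, and

    Q_error = sqrt( (m−1)/m · Σ_i (Q_i − Q̄)² ).

The partition is held fixed across deletions deliberately: re-detecting
modules per replicate would make the Q_i incomparable (different
partitions measure different quantities), whereas the fixed-partition
delete-one is the standard jackknife for a statistic of the link sample.

Partitions are classified by the conventional thresholds: Q < 0.3 low
modularity; Q ≥ 0.3 high; and `confident_high` when Q − Q_error > 0.3,
i.e. when the jackknife band clears the threshold.

## Per-module significance

For each module, every member's internal degree (links to the same
module) is compared with its external degree (links elsewhere) by a
one-sided Wilcoxon rank-sum test, alternative internal > external; the
null is that members connect equally within and outside the module. The
exact null distribution of the rank-sum statistic is used when both
samples have at most 10 values and no cross-sample ties; otherwise a
tie-corrected normal approximation. Completely tied samples (every
internal equal to every external value) carry no evidence and report
p = 1. Modules with fewer than 3 members are flagged `too_small`: the
test cannot detect a difference at such sizes, mirroring how
single-structure modules are reported in practice. Raw p-values are the
primary output; a Benjamini–Hochberg column is emitted alongside for
reference but never gates any decision.

## Paired-network comparison and the asymmetry null

`compare_pair` matches structures across sides by stripping the side
token from labels (homonymy, not graph alignment), reports
right-minus-left deltas of the six parameters and the module count, and
scores partition agreement on the shared structures with the adjusted
Rand index (primary, because chance-corrected) and normalized mutual
information (secondary).

`asymmetry_null` turns "marked asymmetry" into a p-value. The observed
statistic is 1 − ARI of the two partitions. Null replicates apply the
same seeded degree-preserving edge rewiring, at a user-set rate, to the
left network twice and re-detect modules in both copies; the p-value is
the add-one permutation estimate `(1 + #{null ≥ obs}) / (n_perm + 1)`.
The rewiring rate encodes how much connectivity disagreement counts as
measurement noise rather than true asymmetry; it has no canonical value
(default 0.1) and should be chosen by the analyst. The null is mildly
conservative by construction: the left network stands in for the
unobserved common base and is itself one perturbation noisier, so null
pairs disagree slightly more than measurement-equivalent observed pairs.
In calibration simulations (four 10-node blocks, p_in = 0.45,
p_out = 0.03, rate 0.05, 100 permutations) the empirical type-I error at
α = 0.05 is ≈ 0.02 over 200 trials — conservative but within a factor of
a few of nominal. The conservativeness grows with network size and
rate, so small rates are recommended.

## Synthetic data

The generators emulate the statistical shape of real musculoskeletal
contact networks — tens to ~120 structures, ~100–270 contacts, density
0.04–0.07, modular with detected Q around 0.38–0.56 — using stochastic
block models: planted modules of given sizes, intra-/inter-module edge
probabilities `p_in ≥ p_out`, nodes typed bone/muscle by a Bernoulli
draw (default bone fraction 0.4, a typical bone share of published
musculoskeletal networks), and an optional `spanning_bridge` strategy
that adds a minimal recorded set of inter-block edges to connect the
graph. Bilateral pairs perturb a common base by degree-preserving
double-edge swaps (isolating connectivity changes from degree changes —
a misattached muscle re-routes contacts without changing contact
counts much) and independent node deletion, then tag sides with
`.Left`/`.Right` tokens. One master seed expands into per-stage
substreams so stages can be re-run independently.

`emulation_suite` provides six fixed-seed networks spanning the
realistic N/K/D ranges with block structure chosen so the detected Q
lands inside the empirical 0.38–0.56 band (66% of links intra-block,
5–9 blocks).

What the synthetic beds do **not** capture: spatial embedding and
planarity-like constraints of anatomy, degree correlations between
bones and muscles (bipartite-ish contact patterns), serial homology,
and left-right correlations beyond the perturbation model. Passing the
recovery and calibration tests therefore demonstrates correctness of
the algorithms under the planted-block model, not fidelity of any
biological conclusion drawn from real matrices.

## Problem sizes and determinism

Simulation-based tests use deliberately modest problem sizes — planted
networks of 40–120 nodes, 20-seed recovery batteries, 200-trial
calibration of the permutation null with 100 permutations each, and
exhaustive partition enumeration limited to graphs of ≤ 10 nodes
(Bell(10) ≈ 1.16·10⁵ partitions) — chosen so the full suite re-runs
quickly while keeping Monte-Carlo error well inside the asserted
margins. Every stochastic component takes an explicit integer seed;
identical seeds give byte-identical outputs, including written CSV
fixtures.
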