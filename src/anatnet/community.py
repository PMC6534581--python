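"""Connectivity-module detection and modularity statistics.

A connectivity module is a group of anatomical structures with more
contacts among themselves than to structures outside the group.  Modules
are delimited with a short-random-walk agglomeration (walktrap): the
t-step transition probabilities of a random walker started at each node
define a distance between nodes (and communities), communities are
merged greedily in Ward fashion, and the merge sequence is cut at the
partition maximizing the modularity

    Q = sum_s [ e_s / m  -  (d_s / 2m)^2 ]

where ``m`` is the number of links, ``e_s`` the number of intra-module
links of module ``s`` and ``d_s`` its total degree.  Q = 0 for the
trivial single-module partition; Q < 0.3 is read as low modularity,
Q > 0.3 as high, and when Q minus its jackknife standard error still
exceeds 0.3 the partition is confidently better than random.

The jackknife error treats each link as an independent observation:
Q is recomputed with each link deleted in turn (partition held fixed)
and the delete-one estimates are combined into a standard error.

Each module's significance is assessed with a one-sided Wilcoxon
rank-sum test of its members' internal versus external degrees (null:
members are equally connected inside and outside the module).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin

from .network import AnatomicalNetwork, Tissue

__all__ = [
    "Partition",
    "WalktrapConfig",
    "ModuleReport",
    "ModularityResult",
    "Walktrap",
    "walktrap_partition",
    "modularity_Q",
    "jackknife_Q_error",
    "module_significance",
    "classify_modularity",
    "modularity_report",
    "write_modularity_table",
    "write_module_reports",
]

# ΔSigma values are rounded to this many decimals before comparison so
# that float summation noise cannot flip the deterministic tie-break.
_TIE_DECIMALS = 10


@dataclass(frozen=True)
class Partition:
    """Assignment of every node label to a module id (1..n_modules)."""

    assignment: Mapping[str, int]

    def __post_init__(self) -> None:
        ids = set(self.assignment.values())
        if not ids:
            return
        if ids != set(range(1, len(ids) + 1)):
            raise ValueError(
                f"module ids must be contiguous integers from 1, got {sorted(ids)}"
            )

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, module_id: int) -> tuple[str, ...]:
        if module_id not in set(self.assignment.values()):
            raise KeyError(f"unknown module id {module_id}")
        return tuple(lbl for lbl, mid in self.assignment.items() if mid == module_id)

    def labels_for(self, node_labels: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[lbl] for lbl in node_labels])


@dataclass(frozen=True)
class WalktrapConfig:
    """Settings of the short-random-walk agglomeration.

    ``steps`` is the random-walk length t (default 3, short walks);
    the merge sequence is always cut at maximum modularity Q.
    """

    steps: int = 3
    objective_cut: str = "max_Q"

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError(f"steps must be >= 1, got {self.steps}")
        if self.objective_cut != "max_Q":
            raise ValueError(f"unsupported objective_cut {self.objective_cut!r}")


@dataclass(frozen=True)
class ModuleReport:
    """Membership and significance of one connectivity module."""

    module_id: int
    bones: tuple[str, ...]
    muscles: tuple[str, ...]
    others: tuple[str, ...]
    p_value: float
    too_small: bool


@dataclass(frozen=True)
class ModularityResult:
    """Partition of a network with its quality statistics."""

    partition: Partition
    Q: float
    Q_error: float
    modularity_class: str
    module_reports: tuple[ModuleReport, ...] = field(default=())

    @property
    def n_modules(self) -> int:
        return self.partition.n_modules


# ---------------------------------------------------------------------
# Walktrap agglomeration
# ---------------------------------------------------------------------

def _component_agglomeration(comp, A, deg, steps, m):
    """Run the short-random-walk agglomeration on one connected
    component.

    Parameters
    ----------
    comp : list of int
        Global node indices of the component, in input node order.
    A : ndarray
        Full dense adjacency matrix.
    deg : ndarray
        Full degree vector.
    m : int
        Global link count (Q contributions use the global m).

    Returns
    -------
    levels : list of (float, dict)
        Per merge level, the component's contribution to Q and the
        membership map {community id: [global node indices]}.  Level 0
        is the all-singletons partition.
    """
    s = len(comp)
    local = {g: i for i, g in enumerate(comp)}
    sub = A[np.ix_(comp, comp)].astype(float)
    # lazy walk: a self-loop on every vertex makes the short walk
    # aperiodic and is the standard walktrap preprocessing
    walk = sub + np.eye(s)
    d = walk.sum(axis=1)
    P = walk / d[:, None]
    Pt = np.linalg.matrix_power(P, steps)
    inv_d = 1.0 / d

    # community state, keyed by the smallest global node index it contains
    size = {g: 1 for g in comp}
    vec = {g: Pt[local[g]].copy() for g in comp}          # sum of member rows
    members = {g: [g] for g in comp}
    e_intra = {g: 0.0 for g in comp}
    d_sum = {g: float(deg[g]) for g in comp}
    # inter-community edge weights
    w = {g: {} for g in comp}
    for i in range(s):
        for j in range(i + 1, s):
            if sub[i, j]:
                a, b = comp[i], comp[j]
                w[a][b] = w[a].get(b, 0.0) + 1.0
                w[b][a] = w[b].get(a, 0.0) + 1.0

    def term(c):
        return e_intra[c] / m - (d_sum[c] / (2.0 * m)) ** 2

    def delta_sigma(a, b):
        mu_a = vec[a] / size[a]
        mu_b = vec[b] / size[b]
        r2 = float((((mu_a - mu_b) ** 2) * inv_d).sum())
        return (size[a] * size[b]) / (size[a] + size[b]) * r2 / s

    cache = {}
    for a in comp:
        for b in w[a]:
            if a < b:
                cache[(a, b)] = delta_sigma(a, b)

    contrib = sum(term(c) for c in comp)
    levels = [(contrib, {c: list(ms) for c, ms in members.items()})]

    while cache:
        # deterministic pick: smallest (rounded ΔSigma, min id, max id)
        (a, b) = min(cache, key=lambda k: (round(cache[k], _TIE_DECIMALS), k))
        new, old = (a, b) if a < b else (b, a)
        contrib -= term(a) + term(b)
        e_intra[new] = e_intra[a] + e_intra[b] + w[a].get(b, 0.0)
        d_sum[new] = d_sum[a] + d_sum[b]
        size[new] = size[a] + size[b]
        vec[new] = vec[a] + vec[b]
        members[new] = members[a] + members[b]
        contrib += term(new)
        # merge neighbour weights
        nbrs = {}
        for c in (a, b):
            for nb, wt in w[c].items():
                if nb not in (a, b):
                    nbrs[nb] = nbrs.get(nb, 0.0) + wt
        for c in (a, b):
            for nb in w[c]:
                cache.pop((min(c, nb), max(c, nb)), None)
                if nb not in (a, b):
                    del w[nb][c]
        del w[a], w[b]
        if old in size:
            for tbl in (size, vec, members, e_intra, d_sum):
                del tbl[old]
        w[new] = {}
        for nb, wt in nbrs.items():
            w[new][nb] = wt
            w[nb][new] = wt
            cache[(min(new, nb), max(new, nb))] = delta_sigma(new, nb)
        levels.append((contrib, {c: list(ms) for c, ms in members.items()}))
    return levels


def _best_level(levels):
    """Index of the maximum-Q level; ties resolved toward the coarser
    (later, fewer-modules) partition for determinism."""
    best = 0
    for i, (q, _) in enumerate(levels):
        if round(q, _TIE_DECIMALS) >= round(levels[best][0], _TIE_DECIMALS):
            best = i
    return best


def _as_label_adjacency(X):
    """Coerce estimator input to (labels, adjacency ndarray, tissues)."""
    if isinstance(X, AnatomicalNetwork):
        labels = list(X.labels)
        n = len(labels)
        idx = {lbl: i for i, lbl in enumerate(labels)}
        A = np.zeros((n, n), dtype=float)
        for e in X.edges:
            u, v = tuple(e)
            A[idx[u], idx[v]] = A[idx[v], idx[u]] = 1.0
        return labels, A
    if isinstance(X, nx.Graph):
        labels = [str(v) for v in X.nodes]
        A = nx.to_numpy_array(X, nodelist=list(X.nodes), weight=None)
        np.fill_diagonal(A, 0.0)
        return labels, (A > 0).astype(float)
    A = np.asarray(X, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency input must be a square matrix")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency input must be symmetric")
    A = (A > 0).astype(float)
    np.fill_diagonal(A, 0.0)
    return [str(i) for i in range(A.shape[0])], A


class Walktrap(ClusterMixin, BaseEstimator):
    """Short-random-walk community detection (scikit-learn estimator).

    Implements the walktrap agglomeration: random walks of length
    ``steps`` define degree-normalized probability-vector distances
    between nodes; adjacent communities are merged greedily by minimal
    Ward-style increase in mean squared distance; the merge sequence is
    cut at the partition with maximum modularity Q.  Disconnected
    networks are agglomerated per connected component (a random walk
    cannot cross components), isolated nodes becoming singleton modules.

    The procedure is fully deterministic for a fixed input node order:
    among equal-ΔSigma merge candidates the pair with the smallest
    (min id, max id) key is merged, ids inherited from input order.

    Parameters
    ----------
    steps : int, default=3
        Random-walk length t (short walks).

    Attributes
    ----------
    labels_ : ndarray of shape (n_nodes,)
        Zero-based module index per node, in input node order.
    partition_ : Partition
        The same assignment with 1-based contiguous module ids.
    Q_ : float
        Modularity of the selected cut.
    n_modules_ : int
        Number of modules in the selected cut.
    node_labels_ : list of str
        Node labels in input order.

    Examples
    --------
    >>> import networkx as nx
    >>> g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
    >>> Walktrap(steps=3).fit_predict(g)
    array([0, 0, 0, 1, 1, 1])
    """

    def __init__(self, steps: int = 3):
        self.steps = steps

    def fit(self, X, y=None):
        """Detect modules in a network.

        Parameters
        ----------
        X : AnatomicalNetwork, networkx.Graph, or square (0/1) array
            The network whose modules are sought; must have >= 1 link.
        y : ignored
        """
        config = WalktrapConfig(steps=self.steps)
        labels, A = _as_label_adjacency(X)
        n = len(labels)
        m = int(A.sum()) // 2
        if m < 1:
            raise ValueError("walktrap requires a network with at least one link")
        deg = A.sum(axis=1)

        g = nx.from_numpy_array(A)
        seen = set()
        components = []
        for i in range(n):  # deterministic component order: input node order
            if i not in seen:
                comp = sorted(nx.node_connected_component(g, i))
                seen.update(comp)
                components.append(comp)

        module_members: list[list[int]] = []
        Q = 0.0
        for comp in components:
            if len(comp) == 1 or A[np.ix_(comp, comp)].sum() == 0:
                for i in comp:  # isolates: singleton modules, zero Q terms
                    module_members.append([i])
                    Q += 0.0 - (deg[i] / (2.0 * m)) ** 2 if deg[i] else 0.0
                continue
            levels = _component_agglomeration(comp, A, deg, config.steps, m)
            q_c, membership = levels[_best_level(levels)]
            Q += q_c
            for _, nodes in sorted(membership.items()):
                module_members.append(sorted(nodes))

        # contiguous ids ordered by first member in input node order
        module_members.sort(key=lambda ms: ms[0])
        assignment = {}
        for mid, ms in enumerate(module_members, start=1):
            for i in ms:
                assignment[labels[i]] = mid
        self.node_labels_ = labels
        self.partition_ = Partition({lbl: assignment[lbl] for lbl in labels})
        self.labels_ = np.array([assignment[lbl] - 1 for lbl in labels])
        self.Q_ = float(Q)
        self.n_modules_ = len(module_members)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def walktrap_partition(
    network: AnatomicalNetwork, config: WalktrapConfig | None = None
) -> Partition:
    """Functional wrapper over :class:`Walktrap`."""
    config = config or WalktrapConfig()
    return Walktrap(steps=config.steps).fit(network).partition_


# ---------------------------------------------------------------------
# Modularity statistics
# ---------------------------------------------------------------------

def _module_sums(network: AnatomicalNetwork, partition: Partition):
    if set(partition.assignment) != set(network.labels):
        raise ValueError("partition node labels do not match the network")
    k = partition.n_modules
    e = np.zeros(k)
    d = np.zeros(k)
    assign = partition.assignment
    for lbl, degree in network.degrees().items():
        d[assign[lbl] - 1] += degree
    for edge in network.edges:
        u, v = tuple(edge)
        if assign[u] == assign[v]:
            e[assign[u] - 1] += 1
    return e, d


def modularity_Q(network: AnatomicalNetwork, partition: Partition) -> float:
    """Modularity Q = sum_s [e_s/m - (d_s/2m)^2] of a partition."""
    m = network.n_edges
    if m < 1:
        raise ValueError("modularity is undefined for an edgeless network")
    e, d = _module_sums(network, partition)
    return float((e / m - (d / (2.0 * m)) ** 2).sum())


def jackknife_Q_error(network: AnatomicalNetwork, partition: Partition) -> float:
    """Delete-one-link jackknife standard error of Q.

    Each link is treated as an independent observation: Q is recomputed
    with each link removed in turn, the partition held fixed, and

        Q_error = sqrt( (m-1)/m * sum_i (Q_i - Q_bar)^2 ).
    """
    m = network.n_edges
    if m < 2:
        raise ValueError("jackknife error requires at least 2 links")
    e, d = _module_sums(network, partition)
    assign = partition.assignment
    q_i = np.empty(m)
    m1 = m - 1
    for i, edge in enumerate(sorted(tuple(sorted(t)) for t in network.edges)):
        u, v = edge
        e_i = e.copy()
        d_i = d.copy()
        d_i[assign[u] - 1] -= 1
        d_i[assign[v] - 1] -= 1
        if assign[u] == assign[v]:
            e_i[assign[u] - 1] -= 1
        q_i[i] = (e_i / m1 - (d_i / (2.0 * m1)) ** 2).sum()
    return float(math.sqrt((m - 1) / m * ((q_i - q_i.mean()) ** 2).sum()))


def module_significance(
    network: AnatomicalNetwork, partition: Partition, module_id: int
) -> ModuleReport:
    """One-sided Wilcoxon rank-sum test of a module's internal versus
    external connections.

    For each member the internal degree (links to the same module) and
    external degree (links elsewhere) are compared; the alternative is
    internal > external.  The exact null distribution is used when both
    samples have <= 10 values and no cross-sample ties, a tie-corrected
    normal approximation otherwise.  Modules with fewer than 3 members
    are flagged ``too_small`` — too few nodes for the test to detect a
    difference.
    """
    members = partition.members(module_id)  # raises KeyError if unknown
    assign = partition.assignment
    internal, external = [], []
    for lbl in members:
        nbrs = list(network.neighbors(lbl))
        internal.append(sum(1 for nb in nbrs if assign[nb] == module_id))
        external.append(sum(1 for nb in nbrs if assign[nb] != module_id))
    internal = np.array(internal)
    external = np.array(external)
    if np.all(internal == external) and np.unique(internal).size <= 1:
        p = 1.0  # completely tied samples carry no evidence
    else:
        exact = len(internal) <= 10 and len(external) <= 10 and not np.intersect1d(
            internal, external
        ).size
        p = float(
            stats.mannwhitneyu(
                internal,
                external,
                alternative="greater",
                method="exact" if exact else "asymptotic",
            ).pvalue
        )
    bones = tuple(l for l in members if network.node(l).tissue is Tissue.BONE)
    muscles = tuple(l for l in members if network.node(l).tissue is Tissue.MUSCLE)
    others = tuple(l for l in members if network.node(l).tissue is Tissue.OTHER)
    return ModuleReport(module_id, bones, muscles, others, p, len(members) < 3)


def classify_modularity(Q: float, Q_error: float) -> str:
    """Classify a partition's modularity: ``low`` when Q < 0.3, ``high``
    when Q >= 0.3, and ``confident_high`` when Q - Q_error > 0.3."""
    if Q < 0.3:
        return "low"
    if Q - Q_error > 0.3:
        return "confident_high"
    return "high"


def modularity_report(
    network: AnatomicalNetwork, config: WalktrapConfig | None = None
) -> ModularityResult:
    """Full modularity analysis of one network: walktrap partition,
    Q, jackknife error, classification, and per-module significance."""
    config = config or WalktrapConfig()
    partition = walktrap_partition(network, config)
    Q = modularity_Q(network, partition)
    Q_error = jackknife_Q_error(network, partition) if network.n_edges >= 2 else 0.0
    reports = tuple(
        module_significance(network, partition, mid)
        for mid in range(1, partition.n_modules + 1)
    )
    return ModularityResult(partition, Q, Q_error, classify_modularity(Q, Q_error), reports)


# ---------------------------------------------------------------------
# Tabular exports
# ---------------------------------------------------------------------

def write_modularity_table(results: Mapping[str, ModularityResult], path) -> None:
    """Summary CSV: ``name,n_modules,Q,Q_error,class`` (one network per
    row)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "n_modules", "Q", "Q_error", "class"])
        for name, res in results.items():
            writer.writerow(
                [name, res.n_modules, f"{res.Q:.6f}", f"{res.Q_error:.9f}", res.modularity_class]
            )


def write_module_reports(result: ModularityResult, path) -> None:
    """Per-module CSV: ``module_id,p_value,p_bh,too_small,bones,muscles``
    with member labels semicolon-joined.

    ``p_bh`` is a supplementary Benjamini–Hochberg adjusted column; the
    primary ``p_value`` column stays unadjusted.
    """
    import csv

    raw = [r.p_value for r in result.module_reports]
    p_bh = stats.false_discovery_control(raw) if raw else []
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["module_id", "p_value", "p_bh", "too_small", "bones", "muscles"])
        for rep, adj in zip(result.module_reports, p_bh):
            writer.writerow(
                [
                    rep.module_id,
                    f"{rep.p_value:.6g}",
                    f"{adj:.6g}",
                    rep.too_small,
                    ";".join(rep.bones),
                    ";".join(rep.muscles + rep.others),
                ]
            )
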