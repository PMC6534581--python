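"""Topological parameters of anatomical networks.

The six descriptive statistics reported for each musculoskeletal network
are:

- ``N`` — number of nodes (anatomical structures; a broad measure of
  morphological complexity),
- ``K`` — number of links (physical contacts),
- ``D`` — density of connections, ``2K / (N(N-1))``, the fraction of
  theoretically possible contacts that are realized,
- ``C`` — mean clustering coefficient, the prevalence of triangular
  motifs (C = 0 loosely integrated, C = 1 fully integrated),
- ``L`` — mean shortest path length in links (L = 1 all parts closely
  related; larger L, parts more distantly related),
- ``H`` — heterogeneity of connections, the coefficient of variation of
  the degree sequence (H = 0 when every part has the same number of
  contacts; a proxy for anisomerism, the differentiation of parts).

This module also provides the prerequisite checks used before a
modularity analysis: goodness-of-fit of the degree distribution P(k) and
clustering distribution C(k) against four theoretical families, and a
small-world index against an Erdős–Rényi ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network import AnatomicalNetwork

__all__ = [
    "NetworkParameters",
    "DistributionFamily",
    "DistributionFit",
    "SmallWorldReport",
    "density",
    "mean_clustering",
    "mean_path_length",
    "heterogeneity",
    "network_parameters",
    "parameter_table",
    "write_parameter_table",
    "fit_distribution",
    "small_world",
]


@dataclass(frozen=True)
class NetworkParameters:
    """The six descriptive statistics of one network."""

    N: int
    K: int
    D: float
    C: float
    L: float
    H: float


def density(N: int, K: int) -> float:
    """Density of connections D = 2K / (N(N-1)).

    Raises
    ------
    ValueError
        If ``N < 2`` or ``K`` exceeds the number of possible links.
    """
    if N < 2:
        raise ValueError(f"density requires N >= 2, got N={N}")
    max_links = N * (N - 1) // 2
    if not 0 <= K <= max_links:
        raise ValueError(f"K={K} out of range [0, {max_links}] for N={N}")
    return 2.0 * K / (N * (N - 1))


def mean_clustering(
    network: AnatomicalNetwork, low_degree: str = "zero"
) -> float:
    """Mean local clustering coefficient C.

    ``low_degree`` controls nodes with fewer than two neighbours, for
    which the local coefficient is undefined: ``"zero"`` (default)
    counts them as 0 in the mean, keeping C defined and bounded for all
    networks; ``"exclude"`` averages over nodes of degree >= 2 only.
    """
    if network.n_nodes == 0:
        return 0.0
    g = network.to_networkx()
    local = nx.clustering(g)  # degree<2 nodes get 0.0
    if low_degree == "zero":
        values = list(local.values())
    elif low_degree == "exclude":
        values = [c for lbl, c in local.items() if g.degree[lbl] >= 2]
        if not values:
            return 0.0
    else:
        raise ValueError(f"low_degree must be 'zero' or 'exclude', got {low_degree!r}")
    return float(np.mean(values))


def mean_path_length(
    network: AnatomicalNetwork, disconnected: str = "reachable"
) -> float:
    """Mean shortest-path length L over unordered node pairs, in links.

    ``disconnected="reachable"`` (default) averages over reachable pairs
    only, leaving L finite on fragmented networks; ``"strict"`` raises
    on disconnected networks.
    """
    if network.n_edges == 0:
        raise ValueError("mean path length is undefined for an edgeless network")
    if disconnected not in ("reachable", "strict"):
        raise ValueError(f"disconnected must be 'reachable' or 'strict', got {disconnected!r}")
    g = network.to_networkx()
    if disconnected == "strict" and not nx.is_connected(g):
        raise ValueError("network is disconnected and disconnected='strict'")
    total = 0
    pairs = 0
    for source, lengths in nx.all_pairs_shortest_path_length(g):
        for target, dist in lengths.items():
            if target != source:
                total += dist
                pairs += 1
    if pairs == 0:
        raise ValueError("no reachable node pairs")
    return total / pairs  # each unordered pair counted twice; ratio unchanged


def heterogeneity(network: AnatomicalNetwork) -> float:
    """Heterogeneity H: population std of the degree sequence over its
    mean (coefficient of variation); exactly 0 on regular networks."""
    if network.n_edges == 0:
        raise ValueError("heterogeneity is undefined when the mean degree is zero")
    degs = np.array(list(network.degrees().values()), dtype=float)
    return float(degs.std() / degs.mean())


def network_parameters(
    network: AnatomicalNetwork,
    low_degree: str = "zero",
    disconnected: str = "reachable",
) -> NetworkParameters:
    """Compute all six parameters for one network."""
    N, K = network.n_nodes, network.n_edges
    return NetworkParameters(
        N=N,
        K=K,
        D=density(N, K),
        C=mean_clustering(network, low_degree=low_degree),
        L=mean_path_length(network, disconnected=disconnected),
        H=heterogeneity(network),
    )


def parameter_table(
    networks: Mapping[str, AnatomicalNetwork],
    low_degree: str = "zero",
    disconnected: str = "reachable",
) -> pd.DataFrame:
    """One row of N, K, D, C, L, H per named network, in input order.

    Per-network failures are re-raised with the network name attached.
    """
    rows = []
    for name, net in networks.items():
        try:
            p = network_parameters(net, low_degree=low_degree, disconnected=disconnected)
        except Exception as exc:
            raise type(exc)(f"{name}: {exc}") from exc
        rows.append({"name": name, "N": p.N, "K": p.K, "D": p.D, "C": p.C, "L": p.L, "H": p.H})
    return pd.DataFrame(rows, columns=["name", "N", "K", "D", "C", "L", "H"])


def write_parameter_table(table: pd.DataFrame, path) -> None:
    """Export a parameter table as CSV with 6-decimal fixed-point
    formatting for D, C, L, H."""
    out = table.copy()
    for col in ("D", "C", "L", "H"):
        out[col] = out[col].map(lambda x: f"{x:.6f}")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------
# Distribution fitting
# ---------------------------------------------------------------------

class DistributionFamily(str, Enum):
    POISSON = "poisson"
    UNIFORM = "uniform"
    EXPONENTIAL = "exponential"
    POWER_LAW = "power_law"


@dataclass(frozen=True)
class DistributionFit:
    """Maximum-likelihood fit of one theoretical family to a sample of
    degrees or local clustering values.

    ``gof_stat``/``gof_p`` come from a chi-square test (discrete
    families: Poisson, uniform) or a Kolmogorov–Smirnov test against
    the fitted distribution (continuous tail families: exponential,
    power-law).  ``aic`` is comparable across families because it is
    always evaluated on the full sample.
    """

    family: DistributionFamily
    params: tuple[float, ...]
    gof_stat: float
    gof_p: float
    aic: float
    n: int


def _chi_square_gof(values: np.ndarray, pmf, support: np.ndarray, n_params: int):
    """Chi-square GOF with tail bins pooled until expected counts >= 5."""
    n = len(values)
    expected = n * np.array([pmf(k) for k in support], dtype=float)
    observed = np.array([(values == k).sum() for k in support], dtype=float)
    # pool adjacent bins (left to right) until each pooled bin has
    # expected mass >= 5; remainder merges into the last bin
    obs_bins, exp_bins = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= 5:
            obs_bins.append(acc_o)
            exp_bins.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 or acc_o > 0:
        if obs_bins:
            obs_bins[-1] += acc_o
            exp_bins[-1] += acc_e
        else:
            obs_bins, exp_bins = [acc_o], [acc_e]
    obs_arr, exp_arr = np.array(obs_bins), np.array(exp_bins)
    # normalise tiny mass mismatch from truncating the support
    exp_arr *= obs_arr.sum() / exp_arr.sum()
    dof = max(len(obs_arr) - 1 - n_params, 1)
    stat = float(((obs_arr - exp_arr) ** 2 / exp_arr).sum())
    return stat, float(stats.chi2.sf(stat, dof))


def _fit_power_law_tail(x: np.ndarray):
    """Continuous power-law fit with x_min chosen by KS minimization.

    For each candidate x_min (unique sample values), the exponent is the
    continuous MLE ``alpha = 1 + n_tail / sum(log(x/x_min))`` and the
    candidate minimizing the KS distance between the tail empirical CDF
    and the fitted Pareto CDF is retained.
    """
    candidates = np.unique(x)[:-1]  # need at least 2 tail points
    best = None
    for xmin in candidates:
        tail = np.sort(x[x >= xmin])
        n_tail = len(tail)
        log_ratio = np.log(tail / xmin).sum()
        if log_ratio <= 0:
            continue
        alpha = 1.0 + n_tail / log_ratio
        ecdf = np.arange(1, n_tail + 1) / n_tail
        fitted = 1.0 - (tail / xmin) ** (1.0 - alpha)
        ks = float(
            max(
                np.abs(fitted - ecdf).max(),
                np.abs(fitted - np.arange(0, n_tail) / n_tail).max(),
            )
        )
        if best is None or ks < best[0]:
            best = (ks, alpha, float(xmin), n_tail)
    if best is None:
        raise ValueError("degenerate sample for power-law fit (all values equal)")
    return best


def fit_distribution(
    values: Sequence[float], family: "DistributionFamily | str"
) -> DistributionFit:
    """Fit one theoretical family to a sample (degrees or clustering
    values) by maximum likelihood and test goodness of fit.

    Raises
    ------
    ValueError
        If the sample has fewer than 5 values, or is degenerate for the
        requested family (e.g. all values equal for the power law).
    """
    family = DistributionFamily(family)
    x = np.asarray(values, dtype=float)
    if len(x) < 5:
        raise ValueError(f"sample too small for distribution fitting (n={len(x)} < 5)")
    n = len(x)

    if family is DistributionFamily.POISSON:
        if np.any(x < 0) or np.any(x != np.round(x)):
            raise ValueError("Poisson family requires non-negative integer values")
        lam = float(x.mean())
        loglik = float(stats.poisson.logpmf(x.astype(int), lam).sum())
        support = np.arange(0, int(x.max()) + 1)
        stat, p = _chi_square_gof(x, lambda k: stats.poisson.pmf(k, lam), support, 1)
        return DistributionFit(family, (lam,), stat, p, 2 * 1 - 2 * loglik, n)

    if family is DistributionFamily.UNIFORM:
        if np.all(x == np.round(x)):
            # discrete uniform on the observed integer range
            lo, hi = int(x.min()), int(x.max())
            width = hi - lo + 1
            loglik = -n * math.log(width)
            support = np.arange(lo, hi + 1)
            stat, p = _chi_square_gof(x, lambda k: 1.0 / width, support, 2)
            return DistributionFit(family, (float(lo), float(hi)), stat, p, 2 * 2 - 2 * loglik, n)
        lo, hi = float(x.min()), float(x.max())
        if hi == lo:
            raise ValueError("degenerate sample for continuous uniform fit")
        loglik = -n * math.log(hi - lo)
        stat, p = stats.kstest(x, "uniform", args=(lo, hi - lo))
        return DistributionFit(family, (lo, hi), float(stat), float(p), 2 * 2 - 2 * loglik, n)

    if family is DistributionFamily.EXPONENTIAL:
        if np.any(x < 0):
            raise ValueError("exponential family requires non-negative values")
        scale = float(x.mean())
        if scale == 0:
            raise ValueError("degenerate sample for exponential fit (all zeros)")
        loglik = float(stats.expon.logpdf(x, scale=scale).sum())
        stat, p = stats.kstest(x, "expon", args=(0, scale))
        return DistributionFit(family, (scale,), float(stat), float(p), 2 * 1 - 2 * loglik, n)

    # power law
    pos = x[x > 0]
    if len(pos) < 5:
        raise ValueError("power-law family requires at least 5 positive values")
    if np.unique(pos).size < 2:
        raise ValueError("degenerate sample for power-law fit (all values equal)")
    ks, alpha, xmin, n_tail = _fit_power_law_tail(pos)
    gof_p = float(stats.kstwo.sf(ks, n_tail))
    # AIC on the full positive sample (support anchored at its minimum)
    # so the criterion is comparable with the other families
    x0 = float(pos.min())
    alpha_full = 1.0 + len(pos) / float(np.log(pos / x0).sum()) if np.log(pos / x0).sum() > 0 else np.inf
    if np.isfinite(alpha_full):
        loglik = float(
            (np.log(alpha_full - 1) - np.log(x0) - alpha_full * np.log(pos / x0)).sum()
        )
    else:
        loglik = -np.inf
    return DistributionFit(
        DistributionFamily.POWER_LAW, (alpha, xmin), ks, gof_p, 2 * 2 - 2 * loglik, n
    )


# ---------------------------------------------------------------------
# Small-world check
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class SmallWorldReport:
    """Observed C and L against an Erdős–Rényi G(N, K) ensemble.

    ``sigma = (C_obs/C_rand_mean) / (L_obs/L_rand_mean)``; sigma > 1
    indicates clustering in excess of random at comparable path length —
    the small-world regime that licenses a modularity analysis.
    """

    C_obs: float
    L_obs: float
    C_rand_mean: float
    L_rand_mean: float
    sigma: float
    n_random: int
    seed: int


def small_world(
    network: AnatomicalNetwork, n_random: int = 1000, seed: int = 0
) -> SmallWorldReport:
    """Small-world index of a network against a seeded random ensemble
    with identical N and K.

    ``C_rand_mean`` is floor-clamped at ``1/(N(N-1))`` so the ratio is
    always defined.
    """
    if network.n_edges == 0:
        raise ValueError("small-world index is undefined for an edgeless network")
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    N, K = network.n_nodes, network.n_edges
    C_obs = mean_clustering(network)
    L_obs = mean_path_length(network)
    rng = np.random.default_rng(seed)
    c_vals, l_vals = [], []
    for _ in range(n_random):
        g = nx.gnm_random_graph(N, K, seed=int(rng.integers(2**31 - 1)))
        c_vals.append(float(np.mean(list(nx.clustering(g).values()))))
        total = pairs = 0
        for source, lengths in nx.all_pairs_shortest_path_length(g):
            for target, dist in lengths.items():
                if target != source:
                    total += dist
                    pairs += 1
        l_vals.append(total / pairs if pairs else 1.0)
    C_rand = max(float(np.mean(c_vals)), 1.0 / (N * (N - 1)))
    L_rand = float(np.mean(l_vals))
    sigma = (C_obs / C_rand) / (L_obs / L_rand)
    return SmallWorldReport(C_obs, L_obs, C_rand, L_rand, sigma, n_random, seed)
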