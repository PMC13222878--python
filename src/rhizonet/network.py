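"""Condition-specific co-occurrence networks and their validation.

One network per (site × compartment × treatment) condition: genera are
nodes and an edge joins two genera whose abundance correlation passes a
raw p < 0.01 screen (Spearman by default, t-approximation on n−2 degrees
of freedom, as produced by Hmisc::rcorr). Negative correlations form
edges too; the sign is kept as an edge attribute and degree counts both
signs.

Observed topology is compared against Erdős–Rényi G(n, m) null ensembles
that hold the node and edge counts fixed; a network is declared
*non-random* when any tested metric is two-sidedly extreme at p < 0.05
(the metric list is configurable — calibration experiments should pass a
single metric). Hubs are the k highest-degree genera (ties broken by
betweenness, then label, and logged), and hub shifts between untreated
and amended networks partition into maintained / lost / gained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AbundanceTable, Condition, CooccurrenceNetwork, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "correlation_screen",
    "build_network",
    "TopologyMetrics",
    "topology",
    "NullComparison",
    "null_ensemble",
    "top_hubs",
    "HubShift",
    "hub_shift",
]


def _pearson_matrix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = x.shape[0]
    rho = np.corrcoef(x, rowvar=False)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    np.fill_diagonal(p, 0.0)
    return rho, p


def correlation_screen(
    t: AbundanceTable,
    method: str = "spearman",
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """All-pairs correlation coefficients and two-sided p-values.

    Spearman p-values use the t-approximation on n−2 df (the convention of
    Hmisc::rcorr). Zero-variance taxa cannot be correlated and are
    excluded with a log entry; their labels are returned as the third
    element.

    Requires at least 4 samples.
    """
    if t.n_samples < 4:
        raise ValidationError(f"need ≥ 4 samples for a correlation screen, "
                              f"have {t.n_samples}")
    x = t.counts.to_numpy(dtype=float)
    variances = x.var(axis=0)
    dropped = [taxon for taxon, v in zip(t.taxa, variances) if v == 0]
    if dropped:
        log.info("correlation_screen: excluded %d zero-variance taxa", len(dropped))
    keep = [taxon for taxon in t.taxa if taxon not in set(dropped)]
    x = t.counts[keep].to_numpy(dtype=float)
    if method == "spearman":
        # rank-transform then Pearson == Spearman; keeps the p-value
        # machinery identical to the Pearson branch (rcorr-compatible)
        ranks = np.apply_along_axis(stats.rankdata, 0, x)
        rho, p = _pearson_matrix(ranks)
    elif method == "pearson":
        rho, p = _pearson_matrix(x)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    rho_df = pd.DataFrame(rho, index=keep, columns=keep)
    p_df = pd.DataFrame(p, index=keep, columns=keep)
    return rho_df, p_df, dropped


def build_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    edge_alpha: float = 0.01,
    condition: Condition | None = None,
    keep_isolated: bool = False,
    method: str = "spearman",
) -> CooccurrenceNetwork:
    """Threshold the screen into a graph: edge iff p < edge_alpha.

    Edge weight is the correlation coefficient; its sign is stored
    separately. Isolated nodes are dropped by default so ``n_nodes``
    counts connected genera.
    """
    if list(rho.index) != list(p.index) or list(rho.columns) != list(p.columns):
        raise ValidationError("rho and p matrices are misaligned")
    g = nx.Graph()
    taxa = list(rho.index)
    if keep_isolated:
        g.add_nodes_from(taxa)
    rho_v = rho.to_numpy()
    p_v = p.to_numpy()
    n = len(taxa)
    for i in range(n):
        for j in range(i + 1, n):
            if p_v[i, j] < edge_alpha:
                g.add_edge(taxa[i], taxa[j],
                           rho=float(rho_v[i, j]),
                           p=float(p_v[i, j]),
                           sign=1 if rho_v[i, j] >= 0 else -1)
    return CooccurrenceNetwork(graph=g, edge_alpha=edge_alpha,
                               condition=condition, method=method)


@dataclass
class TopologyMetrics:
    n_nodes: int
    n_edges: int
    degree: pd.Series
    betweenness: pd.Series
    clustering_coefficient: float
    average_path_length: float
    modularity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "clustering_coefficient": self.clustering_coefficient,
            "average_path_length": self.average_path_length,
            "modularity": self.modularity,
        }


def _average_path_length(g: nx.Graph) -> float:
    """Mean shortest-path length over *connected* node pairs only.

    Disconnected networks are the norm for thresholded correlation graphs,
    so unreachable pairs are excluded rather than treated as infinite.
    NaN when no connected pair exists.
    """
    total, pairs = 0, 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for target, dist in lengths.items():
            if dist > 0:
                total += dist
                pairs += 1
    return total / pairs if pairs else float("nan")


def _modularity(g: nx.Graph, seed: int) -> float:
    if g.number_of_edges() == 0:
        return float("nan")
    communities = nx.community.louvain_communities(g, weight=None, seed=seed)
    return float(nx.community.modularity(g, communities, weight=None))


def topology(net: CooccurrenceNetwork | nx.Graph, seed: int = 0) -> TopologyMetrics:
    """Node- and network-level metrics of a co-occurrence graph.

    Betweenness is unnormalised shortest-path betweenness; clustering is
    the global transitivity; modularity scores the partition found by
    seeded Louvain. Undefined metrics on empty graphs come back NaN.
    """
    g = net.graph if isinstance(net, CooccurrenceNetwork) else net
    degree = pd.Series(dict(g.degree()), dtype=float).sort_index()
    betweenness = pd.Series(nx.betweenness_centrality(g, normalized=False)).sort_index()
    return TopologyMetrics(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        degree=degree,
        betweenness=betweenness,
        clustering_coefficient=float(nx.transitivity(g)) if g.number_of_nodes() else float("nan"),
        average_path_length=_average_path_length(g),
        modularity=_modularity(g, seed),
    )


@dataclass
class NullComparison:
    """Observed topology vs an ensemble of G(n, m) random graphs."""

    observed: dict[str, float]
    null_mean: dict[str, float]
    null_sd: dict[str, float]
    p_values: dict[str, float]
    n_graphs: int
    seed: int
    alpha: float = 0.05
    metrics: tuple[str, ...] = ()

    @property
    def non_random(self) -> bool:
        return any(self.p_values[m] < self.alpha for m in self.metrics)


_METRIC_FUNCS = {
    "clustering_coefficient": lambda g, seed: float(nx.transitivity(g)),
    "average_path_length": lambda g, seed: _average_path_length(g),
    "modularity": _modularity,
}


def null_ensemble(
    net: CooccurrenceNetwork | nx.Graph,
    n_graphs: int = 999,
    seed: int = 0,
    metrics: tuple[str, ...] = ("clustering_coefficient", "average_path_length", "modularity"),
    alpha: float = 0.05,
    model: str = "gnm",
) -> NullComparison:
    """Compare observed topology against same-(n, m) random graphs.

    ``model="gnm"`` draws uniform Erdős–Rényi graphs with the observed
    node and edge counts; ``model="rewire"`` degree-preservingly rewires
    the observed graph instead. Two-sided empirical p-values use the
    add-one convention; the *non-random* verdict fires when any metric in
    ``metrics`` has p < alpha.
    """
    g = net.graph if isinstance(net, CooccurrenceNetwork) else net
    n, m = g.number_of_nodes(), g.number_of_edges()
    if m > n * (n - 1) // 2:
        raise ValidationError("edge count exceeds the simple-graph maximum")
    if n_graphs < 99:
        raise ValidationError("n_graphs must be ≥ 99")
    unknown = set(metrics) - set(_METRIC_FUNCS)
    if unknown:
        raise ValidationError(f"unknown metrics {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    observed = {name: _METRIC_FUNCS[name](g, seed) for name in metrics}
    null_values: dict[str, list[float]] = {name: [] for name in metrics}
    for _ in range(n_graphs):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if model == "gnm":
            null_g = nx.gnm_random_graph(n, m, seed=sub_seed)
        elif model == "rewire":
            null_g = g.copy()
            if m > 1:
                nx.double_edge_swap(null_g, nswap=4 * m, max_tries=40 * m + 100,
                                    seed=sub_seed)
        else:
            raise ValidationError(f"unknown null model {model!r}")
        for name in metrics:
            null_values[name].append(_METRIC_FUNCS[name](null_g, sub_seed))
    p_values, null_mean, null_sd = {}, {}, {}
    for name in metrics:
        vals = np.asarray(null_values[name], dtype=float)
        ok = np.isfinite(vals) & np.isfinite(observed[name])
        null_mean[name] = float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")
        null_sd[name] = float(np.nanstd(vals, ddof=1)) if np.isfinite(vals).sum() > 1 else float("nan")
        if not np.isfinite(observed[name]):
            p_values[name] = 1.0
            continue
        vals = vals[np.isfinite(vals)]
        n_eff = len(vals)
        ge = int((vals >= observed[name]).sum())
        le = int((vals <= observed[name]).sum())
        p = 2.0 * min((1 + ge) / (1 + n_eff), (1 + le) / (1 + n_eff))
        p_values[name] = float(min(p, 1.0))
    return NullComparison(observed=observed, null_mean=null_mean, null_sd=null_sd,
                          p_values=p_values, n_graphs=n_graphs, seed=seed,
                          alpha=alpha, metrics=tuple(metrics))


def top_hubs(net: CooccurrenceNetwork | nx.Graph, k: int = 10) -> list[str]:
    """The k highest-degree genera (network hubs).

    Tie-break: degree desc, then betweenness desc, then lexicographic
    label; any tie crossing the k-th place is logged.
    """
    g = net.graph if isinstance(net, CooccurrenceNetwork) else net
    if g.number_of_nodes() < k:
        raise ValidationError(f"network has {g.number_of_nodes()} nodes, need ≥ {k}")
    betweenness = nx.betweenness_centrality(g, normalized=False)
    ordered = sorted(g.nodes(),
                     key=lambda v: (-g.degree(v), -betweenness[v], str(v)))
    if len(ordered) > k and g.degree(ordered[k - 1]) == g.degree(ordered[k]):
        log.warning("top_hubs: degree tie across the k=%d boundary "
                    "(broken by betweenness, then label)", k)
    return ordered[:k]


@dataclass
class HubShift:
    """Set algebra of hub membership between untreated and treated networks."""

    maintained: set[str]
    lost: set[str]
    gained: set[str]
    k: int

    def counts(self) -> dict[str, int]:
        return {"maintained": len(self.maintained), "lost": len(self.lost),
                "gained": len(self.gained), "k": self.k}


def hub_shift(untreated_hubs: list[str], treated_hubs: list[str]) -> HubShift:
    """maintained = both lists; lost = untreated only; gained = treated only."""
    if len(untreated_hubs) != len(treated_hubs):
        raise ValidationError("hub lists must have equal length k")
    if len(set(untreated_hubs)) != len(untreated_hubs):
        raise ValidationError("duplicate label in the untreated hub list")
    if len(set(treated_hubs)) != len(treated_hubs):
        raise ValidationError("duplicate label in the treated hub list")
    u, t = set(untreated_hubs), set(treated_hubs)
    return HubShift(maintained=u & t, lost=u - t, gained=t - u,
                    k=len(untreated_hubs))
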