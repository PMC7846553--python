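"""Correlation-bin co-expression networks and differential-correlation tests.

The gene-to-gene layer of the pipeline: per-group Pearson correlation
matrices over all probe pairs, partitioned into nine fixed correlation
ranges (0.2-wide steps, with the |rho| > 0.8 extremes forming the
"high-correlation" networks); seven graph-theory summaries per network;
node-subsampling inference for graph parameters; group-specific
(non-shared-node) networks; Fisher r-to-z differential-edge networks; and
the probability density of pairwise correlation differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ExpressionDataset

DEFAULT_MAX_PROBES = 5000


def pair_count(n_probes: int) -> int:
    """Number of unordered probe pairs, C(n, 2)."""
    return n_probes * (n_probes - 1) // 2


# --------------------------------------------------------------------------
# correlation matrices
# --------------------------------------------------------------------------


@dataclass
class CorrelationMatrix:
    probe_ids: pd.Index
    matrix: np.ndarray  # symmetric, unit diagonal
    group: str
    n_samples: int
    excluded_probes: list = field(default_factory=list)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def pair_values(self) -> np.ndarray:
        """Upper-triangle correlations (one entry per unordered pair)."""
        iu = np.triu_indices(self.n_probes, k=1)
        return self.matrix[iu]


def group_correlation_matrix(
    ds: ExpressionDataset,
    group: str,
    method: str = "pearson",
    max_probes: int = DEFAULT_MAX_PROBES,
) -> CorrelationMatrix:
    """All-pairs correlation matrix of one group's probes.

    Zero-variance probes are excluded (and reported on the result).  The
    all-pairs computation is quadratic in probes; inputs beyond
    ``max_probes`` require raising the guard explicitly.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if ds.n_probes > max_probes:
        raise ValueError(
            f"{ds.n_probes} probes exceed the all-pairs guard ({max_probes}); "
            "pass a larger max_probes to confirm"
        )
    m = ds.group_matrix(group)
    if m.shape[1] < 4:
        raise ValueError("need at least 4 samples in the group")
    values = m.to_numpy()
    keep = values.std(axis=1) > 0
    excluded = list(ds.probe_ids[~keep])
    values = values[keep]
    if method == "spearman":
        values = stats.rankdata(values, axis=1)
    corr = np.corrcoef(values)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(
        probe_ids=ds.probe_ids[keep],
        matrix=corr,
        group=group,
        n_samples=m.shape[1],
        excluded_probes=excluded,
    )


# --------------------------------------------------------------------------
# correlation bins (nine 0.2-wide ranges)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationBin:
    label: str
    lower: float
    upper: float
    lower_closed: bool
    upper_closed: bool
    high_correlation: bool = False

    def contains(self, v: float) -> bool:
        lo_ok = v >= self.lower if self.lower_closed else v > self.lower
        hi_ok = v <= self.upper if self.upper_closed else v < self.upper
        return lo_ok and hi_ok


@dataclass(frozen=True)
class CorrelationBinSpec:
    """The fixed nine-bin partition of [-1, 1].

    Positive bins are left-open/right-closed, the central bin is closed on
    both sides, negative bins are left-closed/right-open, and the two extreme
    bins (|rho| > 0.8) are the high-correlation networks; rho = +/-1 falls in
    the extremes.
    """

    bins: tuple[CorrelationBin, ...] = (
        CorrelationBin("(0.8,1]", 0.8, 1.0, False, True, high_correlation=True),
        CorrelationBin("(0.6,0.8]", 0.6, 0.8, False, True),
        CorrelationBin("(0.4,0.6]", 0.4, 0.6, False, True),
        CorrelationBin("(0.2,0.4]", 0.2, 0.4, False, True),
        CorrelationBin("[-0.2,0.2]", -0.2, 0.2, True, True),
        CorrelationBin("[-0.4,-0.2)", -0.4, -0.2, True, False),
        CorrelationBin("[-0.6,-0.4)", -0.6, -0.4, True, False),
        CorrelationBin("[-0.8,-0.6)", -0.8, -0.6, True, False),
        CorrelationBin("[-1,-0.8)", -1.0, -0.8, True, False, high_correlation=True),
    )

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bins]

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Vectorized bin index (0..8, ordered as ``bins``) per value."""
        v = np.asarray(values, float)
        if np.any(v < -1) or np.any(v > 1):
            raise ValueError("correlations must lie in [-1, 1]")
        out = np.full(v.shape, 4, dtype=int)  # central [-0.2, 0.2]
        pos = v > 0.2
        out[pos] = 3 - np.searchsorted([0.4, 0.6, 0.8], v[pos], side="left")
        neg = v < -0.2
        out[neg] = 5 + (3 - np.searchsorted([-0.8, -0.6, -0.4], v[neg], side="right"))
        return out


def bin_networks(
    corr: CorrelationMatrix,
    spec: CorrelationBinSpec | None = None,
    build: str = "all",
) -> tuple[dict[str, nx.Graph], pd.DataFrame]:
    """Partition all probe pairs into the nine correlation-range networks.

    Returns ``(networks, table)`` where ``networks`` maps each bin label to an
    undirected graph (edges weighted by rho; only probes with at least one
    in-bin edge appear as nodes) and ``table`` is the per-bin count /
    percentage summary.  Counts always conserve the total pair count.

    ``build`` limits which graphs are materialized: ``"all"`` (default),
    ``"high"`` (only the two |rho| > 0.8 extremes — the middle bins of a
    large study hold millions of edges each), or ``"none"`` (table only).
    """
    if build not in ("all", "high", "none"):
        raise ValueError("build must be 'all', 'high' or 'none'")
    spec = spec or CorrelationBinSpec()
    p = corr.n_probes
    iu = np.triu_indices(p, k=1)
    values = corr.matrix[iu]
    idx = spec.assign(values)
    counts = np.bincount(idx, minlength=len(spec.bins))
    total = values.size
    table = pd.DataFrame(
        {
            "bin": spec.labels,
            "high_correlation": [b.high_correlation for b in spec.bins],
            "n_pairs": counts,
            "percentage": 100.0 * counts / total if total else 0.0,
        }
    )
    networks: dict[str, nx.Graph] = {}
    ids = np.asarray(corr.probe_ids)
    for k, b in enumerate(spec.bins):
        if build == "none" or (build == "high" and not b.high_correlation):
            continue
        g = nx.Graph(bin=b.label, group=corr.group, high_correlation=b.high_correlation)
        mask = idx == k
        g.add_weighted_edges_from(
            zip(ids[iu[0][mask]], ids[iu[1][mask]], values[mask].astype(float))
        )
        networks[b.label] = g
    return networks, table


def high_correlation_networks(
    corr: CorrelationMatrix, threshold: float = 0.8
) -> tuple[nx.Graph, nx.Graph]:
    """The (positive, negative) |rho| > threshold networks of one group."""
    networks, _ = bin_networks(corr, build="high")
    return networks["(0.8,1]"], networks["[-1,-0.8)"]


# --------------------------------------------------------------------------
# graph-theory summaries
# --------------------------------------------------------------------------


@dataclass
class GraphSummary:
    """The seven graph parameters reported per network.

    Integration metrics (characteristic path length, diameter) are computed
    with unweighted breadth-first shortest paths; on a disconnected graph
    they refer to the largest connected component and
    ``largest_component_only`` is set.  Modularity is the quality of a
    greedy (Louvain-type) community partition on absolute edge weights;
    eigenvector centrality is the mean over nodes of the max-normalized
    leading eigenvector of the absolute adjacency.
    """

    n_nodes: int
    number_of_links: int
    average_node_degree: float
    characteristic_path_length: float
    diameter: int
    average_clustering_coefficient: float
    modularity: float
    eigenvector_centrality: float
    largest_component_only: bool
    communities: list[set] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "number_of_links": self.number_of_links,
            "average_node_degree": self.average_node_degree,
            "characteristic_path_length": self.characteristic_path_length,
            "diameter": self.diameter,
            "average_clustering_coefficient": self.average_clustering_coefficient,
            "modularity": self.modularity,
            "eigenvector_centrality": self.eigenvector_centrality,
            "largest_component_only": self.largest_component_only,
        }


def _abs_weight_copy(g: nx.Graph) -> nx.Graph:
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    h.add_weighted_edges_from(
        (u, v, abs(d.get("weight", 1.0))) for u, v, d in g.edges(data=True)
    )
    return h


def eigenvector_centrality_scores(g: nx.Graph, tol: float = 1e-12, max_iter: int = 10_000) -> dict:
    """Leading-eigenvector scores by power iteration on |A| + I, normalized
    to unit maximum.  The identity shift makes the dominant eigenvalue unique
    in magnitude (bipartite-safe) without changing eigenvectors."""
    nodes = list(g.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    a = np.abs(nx.to_numpy_array(g, nodelist=nodes, weight="weight"))
    a += np.eye(n)
    x = np.full(n, 1.0 / math.sqrt(n))
    for _ in range(max_iter):
        y = a @ x
        y_norm = np.linalg.norm(y)
        if y_norm == 0:
            break
        y /= y_norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    x = np.abs(x)
    x /= x.max()
    return dict(zip(nodes, x))


def louvain_partition(
    g: nx.Graph, seed: int = 0, restarts: int | None = None
) -> tuple[list[set], float]:
    """Greedy modularity-optimizing communities on absolute edge weights,
    with the achieved modularity Q.

    The greedy optimizer is seed-dependent; ``restarts`` independent runs are
    performed and the best-Q partition kept.  By default small graphs (where
    a single greedy pass is both cheapest and most variable) get 16 restarts
    and large ones 4.
    """
    h = _abs_weight_copy(g)
    if restarts is None:
        restarts = 16 if h.number_of_nodes() <= 200 else 4
    if h.number_of_edges() == 0:
        communities = [{n} for n in h.nodes]
        return communities, 0.0
    best: tuple[float, list[set]] | None = None
    for r in range(max(1, restarts)):
        communities = nx.community.louvain_communities(h, weight="weight", seed=seed + r)
        q = float(nx.community.modularity(h, communities, weight="weight"))
        if best is None or q > best[0]:
            best = (q, list(communities))
    return best[1], best[0]


def graph_summary(g: nx.Graph, seed: int = 0) -> GraphSummary:
    """The seven-parameter summary of one network."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    n = g.number_of_nodes()
    links = g.number_of_edges()
    degrees = [d for _, d in g.degree()]
    components = list(nx.connected_components(g))
    giant = g.subgraph(max(components, key=len))
    flagged = len(components) > 1
    if giant.number_of_nodes() > 1:
        cpl = nx.average_shortest_path_length(giant)  # unweighted BFS
        diam = nx.diameter(giant)
    else:
        cpl, diam = 0.0, 0
    communities, q = louvain_partition(g, seed=seed)
    centrality = eigenvector_centrality_scores(g)
    return GraphSummary(
        n_nodes=n,
        number_of_links=links,
        average_node_degree=float(np.mean(degrees)),
        characteristic_path_length=float(cpl),
        diameter=int(diam),
        average_clustering_coefficient=float(nx.average_clustering(g)),
        modularity=q,
        eigenvector_centrality=float(np.mean(list(centrality.values()))),
        largest_component_only=flagged,
        communities=communities,
    )


def specific_networks(net_a: nx.Graph, net_b: nx.Graph) -> tuple[nx.Graph, nx.Graph]:
    """Group-specific networks: each input restricted to the nodes absent
    from the other (shared nodes removed, so edges touching a shared node
    drop as well)."""
    if net_a.graph.get("bin") != net_b.graph.get("bin"):
        raise ValueError("specific networks require the same correlation bin")
    shared = set(net_a.nodes) & set(net_b.nodes)
    only_a = nx.Graph(net_a.subgraph(set(net_a.nodes) - shared))
    only_b = nx.Graph(net_b.subgraph(set(net_b.nodes) - shared))
    only_a.graph.update(net_a.graph, specific=True)
    only_b.graph.update(net_b.graph, specific=True)
    return only_a, only_b


_SUBSAMPLE_METRICS = {
    "average_node_degree": lambda g, seed: 2 * g.number_of_edges() / max(g.number_of_nodes(), 1),
    "average_clustering_coefficient": lambda g, seed: nx.average_clustering(g),
    "modularity": lambda g, seed: louvain_partition(g, seed=seed)[1],
    "eigenvector_centrality": lambda g, seed: float(
        np.mean(list(eigenvector_centrality_scores(g).values()))
    ),
}


@dataclass
class SubsampleTestResult:
    metric: str
    t: float
    p: float
    values_a: np.ndarray
    values_b: np.ndarray


def subsample_metric_test(
    net_a: nx.Graph,
    net_b: nx.Graph,
    metric: str,
    fraction: float = 0.9,
    reps: int = 100,
    seed: int = 0,
) -> SubsampleTestResult:
    """Node-subsampling significance test of one graph parameter.

    For each network, ``reps`` induced subgraphs on a uniform random
    ``fraction`` of the nodes are drawn and the metric recorded; the two
    metric distributions are compared by a Student's t-test.  Integration
    metrics (path length, diameter) and the raw link count are not eligible.
    """
    if metric not in _SUBSAMPLE_METRICS:
        raise ValueError(
            f"metric must be one of {sorted(_SUBSAMPLE_METRICS)}; got {metric!r}"
        )
    rng = np.random.default_rng(seed)
    fn = _SUBSAMPLE_METRICS[metric]

    def sample(g: nx.Graph) -> np.ndarray:
        nodes = np.asarray(list(g.nodes), dtype=object)
        if nodes.size < 10:
            raise ValueError("network must have at least 10 nodes")
        k = math.ceil(fraction * nodes.size)
        out = np.empty(reps)
        for r in range(reps):
            chosen = rng.choice(nodes, size=k, replace=False)
            sub = g.subgraph(chosen)
            out[r] = fn(sub, int(rng.integers(0, 2**31 - 1)))
        return out

    va, vb = sample(net_a), sample(net_b)
    t, p = stats.ttest_ind(va, vb, equal_var=True)
    return SubsampleTestResult(metric=metric, t=float(t), p=float(p), values_a=va, values_b=vb)


# --------------------------------------------------------------------------
# differential (Fisher r-to-z) networks
# --------------------------------------------------------------------------


def fisher_z_statistic(r1, r2, n1: int, n2: int):
    """z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))."""
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need more than 3 samples per group")
    denom = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return (np.arctanh(r1) - np.arctanh(r2)) / denom


def differential_edges(
    corr1: CorrelationMatrix,
    corr2: CorrelationMatrix,
    alphas: tuple[float, ...] = (0.05,),
    significant_only: bool = False,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[float, nx.Graph]]:
    """Fisher r-to-z test of correlation change for every probe pair.

    Returns the per-pair record table and, per significance level, the
    network of significantly changed pairs, with Louvain community labels
    and degree attributes on the nodes (node size conventionally scales
    with degree).  Pairs with |r| = 1 in either group (infinite atanh) are
    excluded and counted in ``table.attrs["n_excluded"]``.  With
    ``significant_only`` the table keeps only pairs significant at the
    loosest level (memory saver at scale).
    """
    if not corr1.probe_ids.equals(corr2.probe_ids):
        raise ValueError("correlation matrices must share one probe set")
    p = corr1.n_probes
    iu = np.triu_indices(p, k=1)
    r1 = corr1.matrix[iu]
    r2 = corr2.matrix[iu]
    finite = (np.abs(r1) < 1) & (np.abs(r2) < 1)
    n_excluded = int((~finite).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(finite, fisher_z_statistic(r1, r2, corr1.n_samples, corr2.n_samples), np.nan)
    pval = 2 * stats.norm.sf(np.abs(z))
    ids = np.asarray(corr1.probe_ids)
    keep = finite
    if significant_only:
        keep = keep & (pval < max(alphas))
    table = pd.DataFrame(
        {
            "probe1": ids[iu[0][keep]],
            "probe2": ids[iu[1][keep]],
            "r_group1": r1[keep],
            "r_group2": r2[keep],
            "z": z[keep],
            "p": pval[keep],
        }
    )
    for alpha in alphas:
        table[f"significant_{alpha:g}"] = table["p"] < alpha
    table.attrs["n_excluded"] = n_excluded

    graphs: dict[float, nx.Graph] = {}
    for alpha in alphas:
        g = nx.Graph(alpha=alpha, kind="differential")
        mask = finite & (pval < alpha)
        for i, j, d in zip(iu[0][mask], iu[1][mask], (r2 - r1)[mask]):
            g.add_edge(ids[i], ids[j], weight=float(d))
        communities, _ = louvain_partition(g, seed=seed)
        for c_idx, members in enumerate(communities):
            for node in members:
                g.nodes[node]["community"] = c_idx
        for node, deg in g.degree():
            g.nodes[node]["degree"] = deg
            g.nodes[node]["size"] = float(deg)
        graphs[alpha] = g
    return table, graphs


def changed_corr_stable_mean_pairs(
    ds: ExpressionDataset,
    subsample_size: int = 3000,
    alpha: float = 0.05,
    seed: int = 0,
    max_probes: int = DEFAULT_MAX_PROBES,
) -> dict:
    """Count probe pairs whose correlation changes significantly (Fisher
    r-to-z, two-sided) while neither probe changes its mean (Welch t-test
    p >= alpha), on a random probe subsample, extrapolated to all pairs.
    """
    from .metrics import me_differential

    rng = np.random.default_rng(seed)
    p_total = ds.n_probes
    size = min(subsample_size, p_total)
    chosen = np.sort(rng.choice(p_total, size=size, replace=False))
    sub = ds.subset_probes(ds.probe_ids[chosen])

    me = me_differential(sub, alpha)
    stable = (me["me_p"] >= alpha).to_numpy()

    c1 = group_correlation_matrix(sub, sub.group1, max_probes=max_probes)
    c2 = group_correlation_matrix(sub, sub.group2, max_probes=max_probes)
    if len(c1.probe_ids) != size or len(c2.probe_ids) != size:
        keep = c1.probe_ids.intersection(c2.probe_ids)
        sub = sub.subset_probes(keep)
        stable = (me.loc[keep, "me_p"] >= alpha).to_numpy()
        c1 = group_correlation_matrix(sub, sub.group1, max_probes=max_probes)
        c2 = group_correlation_matrix(sub, sub.group2, max_probes=max_probes)
        size = len(keep)

    iu = np.triu_indices(size, k=1)
    r1 = c1.matrix[iu]
    r2 = c2.matrix[iu]
    finite = (np.abs(r1) < 1) & (np.abs(r2) < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = fisher_z_statistic(r1, r2, c1.n_samples, c2.n_samples)
    pz = 2 * stats.norm.sf(np.abs(z))
    pair_stable = stable[iu[0]] & stable[iu[1]]
    found = int((finite & pair_stable & (pz < alpha)).sum())
    sampled_pairs = pair_count(size)
    total_pairs = pair_count(p_total)
    scale = total_pairs / sampled_pairs if sampled_pairs else np.nan
    return {
        "count": found,
        "sampled_probes": size,
        "sampled_pairs": sampled_pairs,
        "total_pairs": total_pairs,
        "sampling_fraction": sampled_pairs / total_pairs if total_pairs else np.nan,
        "extrapolated_count": found * scale,
    }


@dataclass
class CorrelationDifferencePdf:
    """Density estimates of pairwise correlations per group and of their
    difference, with the spread/covariance summary that explains why the
    difference distribution is the more compact one whenever the two groups'
    correlations covary positively."""

    edges_group: np.ndarray
    density_group1: np.ndarray
    density_group2: np.ndarray
    edges_diff: np.ndarray
    density_diff: np.ndarray
    sd_group1: float
    sd_group2: float
    sd_diff: float
    covariance: float


def correlation_difference_pdf(
    corr1: CorrelationMatrix, corr2: CorrelationMatrix, bins: int = 100
) -> CorrelationDifferencePdf:
    if not corr1.probe_ids.equals(corr2.probe_ids):
        raise ValueError("correlation matrices must share one probe set")
    v1 = corr1.pair_values()
    v2 = corr2.pair_values()
    diff = v2 - v1
    edges_group = np.linspace(-1, 1, bins + 1)
    edges_diff = np.linspace(-2, 2, bins + 1)
    d1, _ = np.histogram(v1, bins=edges_group, density=True)
    d2, _ = np.histogram(v2, bins=edges_group, density=True)
    dd, _ = np.histogram(diff, bins=edges_diff, density=True)
    cov = float(np.cov(v1, v2)[0, 1]) if v1.size > 1 else 0.0
    return CorrelationDifferencePdf(
        edges_group=edges_group,
        density_group1=d1,
        density_group2=d2,
        edges_diff=edges_diff,
        density_diff=dd,
        sd_group1=float(v1.std(ddof=1)) if v1.size > 1 else 0.0,
        sd_group2=float(v2.std(ddof=1)) if v2.size > 1 else 0.0,
        sd_diff=float(diff.std(ddof=1)) if diff.size > 1 else 0.0,
        covariance=cov,
    )


# --------------------------------------------------------------------------
# export
# --------------------------------------------------------------------------

_FORMATS = ("gexf", "graphml", "edgelist")


def export_network(g: nx.Graph, path, fmt: str = "gexf", seed: int = 0) -> None:
    """Write a network with degree and community node attributes.

    Formats: GEXF, GraphML, or a plain TSV edge list (source, target,
    weight).  The write -> read round trip preserves nodes, edges and
    weights.
    """
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose from {_FORMATS}")
    g = nx.Graph(g)
    if g.number_of_nodes() and not all("community" in d for _, d in g.nodes(data=True)):
        communities, _ = louvain_partition(g, seed=seed)
        for c_idx, members in enumerate(communities):
            for node in members:
                g.nodes[node]["community"] = c_idx
    for node, deg in g.degree():
        g.nodes[node]["degree"] = deg
    path = str(path)
    if fmt == "gexf":
        nx.write_gexf(g, path)
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, d in g.edges(data=True):
                fh.write(f"{u}\t{v}\t{d.get('weight', 1.0)!r}\n")


def read_network(path, fmt: str = "gexf") -> nx.Graph:
    if fmt == "gexf":
        return nx.Graph(nx.read_gexf(str(path)))
    if fmt == "graphml":
        return nx.Graph(nx.read_graphml(str(path)))
    if fmt == "edgelist":
        g = nx.Graph()
        df = pd.read_csv(path, sep="\t")
        for _, row in df.iterrows():
            g.add_edge(str(row["source"]), str(row["target"]), weight=float(row["weight"]))
        return g
    raise ValueError(f"unknown format {fmt!r}; choose from {_FORMATS}")
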