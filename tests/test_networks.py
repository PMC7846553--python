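"""Correlation networks: bins, graph metrics vs brute-force oracles,
differential edges, export round-trips."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from paritynet import networks as net
from paritynet.networks import (
    CorrelationBinSpec,
    CorrelationMatrix,
    bin_networks,
    changed_corr_stable_mean_pairs,
    correlation_difference_pdf,
    differential_edges,
    eigenvector_centrality_scores,
    export_network,
    fisher_z_statistic,
    graph_summary,
    group_correlation_matrix,
    louvain_partition,
    pair_count,
    read_network,
    specific_networks,
    subsample_metric_test,
)

from _oracles import average_clustering, path_metrics_largest_component
from conftest import make_dataset


def corr_from_matrix(m: np.ndarray, group="g", n=50) -> CorrelationMatrix:
    ids = pd.Index([f"P{i}" for i in range(m.shape[0])])
    return CorrelationMatrix(ids, np.asarray(m, float), group, n)


# -- correlation matrices --------------------------------------------------


def test_duplicate_and_negated_probes():
    rng = np.random.default_rng(0)
    base = rng.normal(size=12)
    values = np.vstack([base, base, -base])
    ds = make_dataset(values, 6, 6)
    c = group_correlation_matrix(ds, ds.group1)
    assert c.matrix[0, 1] == pytest.approx(1.0)
    assert c.matrix[0, 2] == pytest.approx(-1.0)


def test_zero_variance_probe_excluded_with_report():
    rng = np.random.default_rng(1)
    values = rng.normal(size=(4, 12))
    values[1] = 2.0
    ds = make_dataset(values, 6, 6)
    c = group_correlation_matrix(ds, ds.group1)
    assert c.excluded_probes == ["P0001"]
    assert c.n_probes == 3


def test_probe_guard_requires_override():
    rng = np.random.default_rng(2)
    ds = make_dataset(rng.normal(size=(30, 12)), 6, 6)
    with pytest.raises(ValueError):
        group_correlation_matrix(ds, ds.group1, max_probes=10)
    c = group_correlation_matrix(ds, ds.group1, max_probes=30)
    assert c.n_probes == 30


def test_pair_count_closed_form():
    assert pair_count(4) == 6
    assert pair_count(18653) == 173_957_878


# -- bins ------------------------------------------------------------------


def test_bin_spec_has_nine_ranges_partitioning_everything():
    spec = CorrelationBinSpec()
    assert len(spec.bins) == 9
    for v in np.linspace(-1, 1, 2001):
        hits = [b for b in spec.bins if b.contains(v)]
        assert len(hits) == 1, v


@given(st.lists(st.floats(-1, 1), min_size=1, max_size=200))
def test_vectorized_assignment_matches_interval_definitions(values):
    spec = CorrelationBinSpec()
    idx = spec.assign(np.array(values))
    for v, k in zip(values, idx):
        assert spec.bins[k].contains(v)


def test_boundary_values_fall_in_printed_bins():
    spec = CorrelationBinSpec()
    cases = {1.0: "(0.8,1]", 0.8: "(0.6,0.8]", 0.2: "[-0.2,0.2]",
             -0.2: "[-0.2,0.2]", -0.4: "[-0.4,-0.2)", -0.8: "[-0.8,-0.6)",
             -1.0: "[-1,-0.8)"}
    for v, label in cases.items():
        assert spec.labels[spec.assign(np.array([v]))[0]] == label


def test_bin_networks_conserve_pairs_and_tag_extremes():
    rng = np.random.default_rng(3)
    ds = make_dataset(rng.normal(size=(40, 20)), 10, 10)
    c = group_correlation_matrix(ds, ds.group1)
    nets, table = bin_networks(c)
    assert len(nets) == 9
    assert table["n_pairs"].sum() == pair_count(40)
    assert table["percentage"].sum() == pytest.approx(100)
    assert table.loc[table["high_correlation"], "bin"].tolist() == ["(0.8,1]", "[-1,-0.8)"]
    for label, g in nets.items():
        spec_bin = next(b for b in CorrelationBinSpec().bins if b.label == label)
        for _, _, d in g.edges(data=True):
            assert spec_bin.contains(d["weight"])


def test_toy_matrix_all_high_positive():
    m = np.full((5, 5), 0.9)
    np.fill_diagonal(m, 1.0)
    nets, table = bin_networks(corr_from_matrix(m))
    assert nets["(0.8,1]"].number_of_edges() == pair_count(5)
    assert table.set_index("bin").loc["(0.8,1]", "n_pairs"] == 10


# -- graph summaries -------------------------------------------------------


def test_triangle_and_path_summaries():
    tri = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
    s = graph_summary(tri)
    assert (s.number_of_links, s.average_node_degree) == (3, 2.0)
    assert (s.characteristic_path_length, s.diameter) == (1.0, 1)
    assert s.average_clustering_coefficient == 1.0

    path = nx.path_graph(4)
    s = graph_summary(path)
    assert s.diameter == 3
    assert s.average_clustering_coefficient == 0.0


def test_two_disconnected_cliques_modularity_half():
    g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
    communities, q = louvain_partition(g, seed=0)
    assert q == pytest.approx(0.5)
    assert sorted(map(len, communities)) == [6, 6]
    assert graph_summary(g).largest_component_only


def test_star_eigenvector_centrality_closed_form():
    k = 9
    g = nx.star_graph(k)  # hub 0 plus k leaves
    scores = eigenvector_centrality_scores(g)
    assert scores[0] == pytest.approx(1.0)
    for leaf in range(1, k + 1):
        assert scores[leaf] == pytest.approx(1 / np.sqrt(k), rel=1e-6)


def test_metrics_match_bruteforce_oracle_on_random_graphs():
    rng = np.random.default_rng(7)
    for _ in range(5):
        n = int(rng.integers(8, 30))
        g = nx.gnp_random_graph(n, 0.2, seed=int(rng.integers(0, 10_000)))
        if g.number_of_edges() == 0:
            continue
        adj = nx.to_numpy_array(g)
        s = graph_summary(g)
        cpl, diam = path_metrics_largest_component(adj)
        assert s.characteristic_path_length == pytest.approx(cpl)
        assert s.diameter == diam
        assert s.average_clustering_coefficient == pytest.approx(average_clustering(adj))
        assert s.number_of_links == int(adj.sum() / 2)


# -- specific networks -----------------------------------------------------


def _tagged(edges, bin_label="(0.8,1]"):
    g = nx.Graph(bin=bin_label)
    g.add_edges_from(edges)
    return g


def test_specific_networks_cases():
    a = _tagged([(1, 2), (2, 3)])
    b = _tagged([(1, 2), (2, 3)])
    sa, sb = specific_networks(a, b)
    assert sa.number_of_nodes() == sb.number_of_nodes() == 0

    b2 = _tagged([(7, 8)])
    sa, sb = specific_networks(a, b2)
    assert set(sa.edges) == set(a.edges)
    assert set(sb.edges) == set(b2.edges)

    # 6-node overlap: shared nodes 3,4 removed along with their edges
    a3 = _tagged([(1, 2), (2, 3), (3, 4)])
    b3 = _tagged([(3, 4), (4, 5), (5, 6)])
    sa, sb = specific_networks(a3, b3)
    assert set(sa.nodes) == {1, 2} and set(sa.edges) == {(1, 2)}
    assert set(sb.nodes) == {5, 6} and set(sb.edges) == {(5, 6)}

    with pytest.raises(ValueError):
        specific_networks(a, _tagged([(1, 2)], bin_label="[-1,-0.8)"))


# -- subsampling inference -------------------------------------------------


def test_subsample_test_separates_clique_from_path():
    clique = nx.complete_graph(30)
    path = nx.path_graph(30)
    res = subsample_metric_test(clique, path, "average_node_degree", seed=0)
    assert res.p < 0.001
    res2 = subsample_metric_test(clique, path, "average_node_degree", seed=0)
    assert res2.p == res.p  # fixed seed pair reproduces exactly


def test_subsample_test_rejects_small_networks_and_bad_metric():
    small = nx.complete_graph(5)
    with pytest.raises(ValueError):
        subsample_metric_test(small, small, "average_node_degree")
    with pytest.raises(ValueError):
        subsample_metric_test(nx.complete_graph(20), nx.complete_graph(20), "diameter")


def test_subsample_null_rate_near_alpha():
    """Identical networks under different subsampling seeds should reject
    at roughly the nominal level."""
    g = nx.gnp_random_graph(40, 0.15, seed=3)
    rejections = 0
    runs = 120
    for r in range(runs):
        res = subsample_metric_test(g, g, "average_node_degree", reps=25, seed=1000 + r)
        rejections += res.p < 0.05
    rate = rejections / runs
    assert 0.0 <= rate < 0.15


# -- differential edges ----------------------------------------------------


def test_fisher_z_examples():
    assert fisher_z_statistic(0.5, 0.5, 42, 71) == 0.0
    z = fisher_z_statistic(0.9, 0.0, 71, 42)
    assert z == pytest.approx(np.arctanh(0.9) / np.sqrt(1 / 68 + 1 / 39), abs=1e-6)
    assert z == pytest.approx(7.33, abs=0.01)


def test_differential_edges_identity_and_exclusions():
    rng = np.random.default_rng(8)
    m = np.corrcoef(rng.normal(size=(6, 20)))
    c1 = corr_from_matrix(m, "g1", 42)
    c2 = corr_from_matrix(m.copy(), "g2", 71)
    table, graphs = differential_edges(c1, c2, alphas=(0.05,))
    assert (table["z"] == 0).all()
    assert (table["p"] == 1).all()
    assert graphs[0.05].number_of_edges() == 0

    m2 = m.copy()
    m2[0, 1] = m2[1, 0] = 1.0  # atanh infinite -> excluded
    table2, _ = differential_edges(corr_from_matrix(m2, "g1", 42), c2)
    assert table2.attrs["n_excluded"] == 1
    assert len(table2) == pair_count(6) - 1


def test_differential_edges_null_calibration():
    """Bivariate-normal null: rejection rate within 3 MC SE of alpha."""
    rng = np.random.default_rng(9)
    sims = 4000
    rej = 0
    r1 = np.empty(sims)
    r2 = np.empty(sims)
    for s in range(sims):
        a = rng.normal(size=(2, 42))
        b = rng.normal(size=(2, 71))
        r1[s] = np.corrcoef(a)[0, 1]
        r2[s] = np.corrcoef(b)[0, 1]
    z = fisher_z_statistic(r1, r2, 42, 71)
    from scipy import stats as sps

    p = 2 * sps.norm.sf(np.abs(z))
    rate = (p < 0.05).mean()
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / sims)


def test_differential_network_nodes_carry_degree_and_community():
    rng = np.random.default_rng(10)
    base = rng.normal(size=(8, 42))
    ds1 = base
    # contrast group: first four probes strongly coupled
    ds2 = rng.normal(size=(8, 71))
    ds2[1] = ds2[0] + rng.normal(0, 0.1, 71)
    ds2[2] = ds2[0] + rng.normal(0, 0.1, 71)
    c1 = corr_from_matrix(np.corrcoef(ds1), "g1", 42)
    c2 = corr_from_matrix(np.corrcoef(ds2), "g2", 71)
    _, graphs = differential_edges(c1, c2, alphas=(0.05,))
    g = graphs[0.05]
    assert g.number_of_edges() > 0
    for node, data in g.nodes(data=True):
        assert data["degree"] == g.degree(node)
        assert data["size"] == float(g.degree(node))
        assert "community" in data


# -- changed-correlation / stable-mean pairs -------------------------------


def test_changed_corr_stable_mean_finds_planted_module(study_data):
    ds, truth = study_data
    res = changed_corr_stable_mean_pairs(ds, subsample_size=600, seed=0)
    module_pairs = sum(
        pair_count(len(m["probes"])) for m in truth.modules
    )
    assert res["count"] >= module_pairs  # all planted module pairs qualify
    assert res["extrapolated_count"] == res["count"]  # full sample, no scaling
    assert res["sampling_fraction"] == 1.0


def test_changed_corr_extrapolation_scale():
    ds, _ = __import__("paritynet.simulate", fromlist=["generate_dataset"]).generate_dataset(
        __import__("paritynet.simulate", fromlist=["null_config"]).null_config(100, seed=2)
    )
    res = changed_corr_stable_mean_pairs(ds, subsample_size=40, seed=1)
    assert res["total_pairs"] == pair_count(100)
    assert res["sampled_pairs"] == pair_count(40)
    assert res["extrapolated_count"] == pytest.approx(
        res["count"] * pair_count(100) / pair_count(40)
    )


# -- correlation-difference PDF --------------------------------------------


def test_correlation_difference_identities():
    rng = np.random.default_rng(11)
    m1 = np.corrcoef(rng.normal(size=(15, 42)))
    m2 = np.corrcoef(rng.normal(size=(15, 71)))
    c1 = corr_from_matrix(m1, "g1", 42)
    c2 = corr_from_matrix(m2, "g2", 71)
    pdf = correlation_difference_pdf(c1, c2)
    # Var(diff) = Var1 + Var2 - 2 Cov to machine precision
    assert pdf.sd_diff**2 == pytest.approx(
        pdf.sd_group1**2 + pdf.sd_group2**2 - 2 * pdf.covariance
    )
    same = correlation_difference_pdf(c1, corr_from_matrix(m1.copy(), "g2", 71))
    assert same.sd_diff == 0.0


# -- export ----------------------------------------------------------------


@pytest.mark.parametrize("fmt", ["gexf", "graphml", "edgelist"])
def test_export_round_trip(tmp_path, fmt):
    g = nx.Graph(bin="(0.8,1]")
    g.add_edge("P1", "P2", weight=0.91)
    g.add_edge("P2", "P3", weight=0.85)
    path = tmp_path / f"net.{fmt}"
    export_network(g, path, fmt)
    back = read_network(path, fmt)
    assert set(back.nodes) == set(g.nodes)
    assert set(map(frozenset, back.edges)) == set(map(frozenset, g.edges))
    for u, v, d in g.edges(data=True):
        assert back[u][v]["weight"] == pytest.approx(d["weight"])


def test_export_empty_network_and_degree_attribute(tmp_path):
    empty = nx.Graph()
    export_network(empty, tmp_path / "empty.gexf", "gexf")
    assert read_network(tmp_path / "empty.gexf").number_of_edges() == 0

    g = nx.complete_graph(4)
    export_network(g, tmp_path / "k4.graphml", "graphml")
    back = read_network(tmp_path / "k4.graphml", "graphml")
    for node, data in back.nodes(data=True):
        assert int(data["degree"]) == back.degree(node)
    with pytest.raises(ValueError):
        export_network(g, tmp_path / "x.bin", "parquet")
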