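"""IBD graph construction, metrics, cliques and CPM communities."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from paleokin.network import (best_partition_exhaustive, build_graph,
                              classify_cliques, cpm_quality,
                              detect_communities, enumerate_cliques,
                              graph_summary, module_means, node_metrics)


def _meta(iids, sites=None, sexes=None):
    return pd.DataFrame({
        "iid": iids,
        "site": sites or ["s1"] * len(iids),
        "sex": sexes or ["M"] * len(iids),
        "style": [""] * len(iids),
    })


def _ibd(rows):
    return pd.DataFrame(rows, columns=["iid1", "iid2", "chromosome",
                                       "start_cM", "end_cM"]).assign(
        length_cM=lambda d: d.end_cM - d.start_cM)


# ---------------------------------------------------------------------------
# Thresholded graph construction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("segments, edge_at_1, edge_at_2", [
    ([("a", "b", "1", 0.0, 15.0)], True, False),
    ([("a", "b", "1", 0.0, 13.0), ("a", "b", "2", 0.0, 13.0)], True, True),
    ([("a", "b", "1", 0.0, 11.0), ("a", "b", "2", 0.0, 11.0),
      ("a", "b", "3", 0.0, 11.0)], False, False),
])
def test_edge_thresholds(segments, edge_at_1, edge_at_2):
    meta = _meta(["a", "b"])
    ibd = _ibd(segments)
    assert build_graph(ibd, meta, 12.0, 1).has_edge("a", "b") is edge_at_1
    assert build_graph(ibd, meta, 12.0, 2).has_edge("a", "b") is edge_at_2


def test_unknown_individual_raises_with_offenders():
    with pytest.raises(KeyError, match="ghost"):
        build_graph(_ibd([("a", "ghost", "1", 0.0, 20.0)]), _meta(["a"]))


def test_stricter_graph_is_subgraph_of_looser():
    rng = np.random.default_rng(0)
    rows = []
    iids = [f"i{k}" for k in range(12)]
    for a, b in itertools.combinations(iids, 2):
        for _ in range(rng.integers(0, 4)):
            ln = rng.uniform(5, 30)
            rows.append((a, b, "1", 0.0, ln))
    ibd = _ibd(rows)
    g1 = build_graph(ibd, _meta(iids), 12.0, 1)
    g2 = build_graph(ibd, _meta(iids), 12.0, 2)
    assert set(g2.edges) <= set(g1.edges)


# ---------------------------------------------------------------------------
# Summaries and node metrics on closed-form graphs
# ---------------------------------------------------------------------------

def test_graph_summary_closed_forms():
    k4 = nx.complete_graph(4)
    assert graph_summary(k4) == {"n": 4, "m": 6, "density": 1.0,
                                 "average_degree": 3.0}
    path = nx.path_graph(3)
    assert graph_summary(path)["density"] == pytest.approx(2 / 3)
    empty = nx.empty_graph(10)
    assert graph_summary(empty)["density"] == 0.0


@pytest.mark.parametrize("n", [3, 5, 8])
def test_metrics_closed_forms(n):
    complete = nx.complete_graph(n)
    cycle = nx.cycle_graph(n)
    star = nx.star_graph(n)       # n + 1 nodes, hub 0
    for g in (complete, cycle, star):
        nx.set_node_attributes(g, "s1", "module")
    mc = node_metrics(complete)
    assert np.allclose(mc["k"], 1.0) and np.allclose(mc["C"], 1.0)
    my = node_metrics(cycle)
    assert np.allclose(my["k"], 2 / (n - 1))
    assert np.allclose(my["C"], 1.0 if n == 3 else 0.0)
    ms = node_metrics(star)
    assert ms.loc[0, "k"] == pytest.approx(1.0)
    leaves = [u for u in star.nodes if u != 0]
    assert np.allclose(ms.loc[leaves, "k"], 1 / n)
    assert np.allclose(ms["C"], 0.0)


def test_path_metrics():
    g = nx.path_graph(3)
    nx.set_node_attributes(g, "s1", "module")
    m = node_metrics(g)
    assert m.loc[1, "k"] == pytest.approx(1.0)
    assert m.loc[1, "C"] == 0.0
    assert m.loc[0, "k"] == pytest.approx(0.5)


def test_strengths_split_by_module_hand_computed():
    # modules {a, b, c} and {x}; within weights 5 and 8, between weight 12
    g = nx.Graph()
    g.add_edge("a", "b", max_cM=5.0)
    g.add_edge("a", "c", max_cM=8.0)
    g.add_edge("a", "x", max_cM=12.0)
    for u in "abc":
        g.nodes[u]["module"] = "m1"
    g.nodes["x"]["module"] = "m2"
    m = node_metrics(g)
    assert m.loc["a", "w_within"] == pytest.approx(13.0)
    assert m.loc["a", "w_between"] == pytest.approx(12.0)
    assert m.loc["a", "kW"] == 2 and m.loc["a", "kB"] == 1
    assert m.loc["a", "kB_over_k"] == pytest.approx(1 / 3)
    mm = module_means(m)
    assert mm.loc["m2", "w_between"] == pytest.approx(12.0)


def test_metrics_reject_empty_graph():
    with pytest.raises(ValueError):
        node_metrics(nx.Graph())


def test_single_node_graph_gets_zero_centrality():
    g = nx.Graph()
    g.add_node("a", module="m", sex="M")
    m = node_metrics(g)
    assert m.loc["a", "k"] == 0.0


# ---------------------------------------------------------------------------
# Maximal cliques
# ---------------------------------------------------------------------------

def _brute_force_maximal_cliques(g, min_size):
    nodes = sorted(g.nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    adj = [0] * len(nodes)
    for u, v in g.edges:
        adj[idx[u]] |= 1 << idx[v]
        adj[idx[v]] |= 1 << idx[u]
    cliques = []
    for mask in range(1, 1 << len(nodes)):
        members = [i for i in range(len(nodes)) if mask >> i & 1]
        if len(members) < min_size:
            continue
        if all(adj[i] >> j & 1 for i, j in itertools.combinations(members, 2)):
            others = (i for i in range(len(nodes)) if not mask >> i & 1)
            if not any(all(adj[i] >> j & 1 for j in members) for i in others):
                cliques.append(tuple(nodes[i] for i in members))
    return sorted(cliques)


def test_clique_examples():
    k4 = nx.complete_graph(4)
    assert [c.nodes for c in enumerate_cliques(k4)] == [(0, 1, 2, 3)]
    g = nx.Graph([(0, 1), (1, 2), (0, 2), (1, 3), (2, 3)])  # two triangles, shared edge
    assert len(enumerate_cliques(g)) == 2
    assert enumerate_cliques(nx.empty_graph(5)) == []


def test_cliques_match_brute_force_on_random_graphs():
    rng = np.random.default_rng(7)
    for rep in range(200):
        n = int(rng.integers(3, 13))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.9)),
                                seed=int(rng.integers(1 << 31)))
        ours = sorted(c.nodes for c in enumerate_cliques(g))
        assert ours == _brute_force_maximal_cliques(g, 3)


def test_clique_classification_and_counts():
    g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"),
                  ("c", "d"), ("d", "e"), ("c", "e")])
    meta = _meta(list("abcde"), sites=["s1", "s1", "s1", "s2", "s2"],
                 sexes=["F", "M", "M", "F", "M"])
    for u in g.nodes:
        g.nodes[u]["module"] = meta.set_index("iid").at[u, "site"]
        g.nodes[u]["sex"] = meta.set_index("iid").at[u, "sex"]
    cl = enumerate_cliques(g)
    assert {c.classification for c in cl} == {"within", "between"}
    res = classify_cliques(cl, meta)
    assert res["overall_cliques"] == {"within": 1, "between": 1}
    # manual tally: within clique (a,b,c): s1 F1 M2; between (c,d,e): c=s1 M, d,e=s2 F/M
    s1 = res["sites"]["s1"]["participation"]
    assert s1["F"] == {"within": 1, "between": 0}
    assert s1["M"] == {"within": 2, "between": 1}


def test_all_within_when_single_module():
    g = nx.complete_graph(4)
    meta = _meta(list(range(4)))
    for u in g.nodes:
        g.nodes[u].update(module="s1", sex="M")
    res = classify_cliques(enumerate_cliques(g), meta)
    assert res["overall_cliques"]["between"] == 0


# ---------------------------------------------------------------------------
# CPM communities
# ---------------------------------------------------------------------------

def test_two_disjoint_triangles_found_exactly():
    g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    part = detect_communities(g, gamma=0.04, seed=0)
    assert part.quality == pytest.approx(2 * (3 - 0.04 * 3))
    assert len(set(part.membership.values())) == 2
    assert part.membership[0] == part.membership[1] == part.membership[2]


def test_single_edge_merges_at_low_gamma_splits_at_high():
    g = nx.Graph([("a", "b")])
    assert len(set(detect_communities(g, 0.04).membership.values())) == 1
    assert len(set(detect_communities(g, 2.0).membership.values())) == 2


def test_gamma_must_be_positive():
    with pytest.raises(ValueError):
        detect_communities(nx.Graph([(0, 1)]), gamma=0.0)


def _independent_quality(g, membership, gamma):
    q = 0.0
    comms = {}
    for u, c in membership.items():
        comms.setdefault(c, []).append(u)
    for members in comms.values():
        e = g.subgraph(members).number_of_edges()
        n = len(members)
        q += e - gamma * n * (n - 1) / 2
    return q


def test_detected_quality_is_recomputable():
    g = nx.gnp_random_graph(15, 0.3, seed=4)
    part = detect_communities(g, 0.1, seed=1)
    assert part.quality == pytest.approx(
        _independent_quality(g, part.membership, 0.1))
    assert cpm_quality(g, part.membership, 0.1) == pytest.approx(part.quality)
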