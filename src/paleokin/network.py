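"""IBD-sharing network construction and the site-level graph statistics.

Individuals are nodes (annotated with burial site = "module", genetic sex and
pottery style); an edge joins a pair sharing at least ``min_n_segments`` IBD
segments each of at least ``min_seg_cM`` (the 1x12 cM and 2x12 cM variants of
the analysis).  On that graph the module computes normalised degree
centrality, local clustering, within/between-module strengths (weighted by
the maximum shared segment), maximal cliques of size >= 3 with within/between
classification, and communities under the constant Potts model (CPM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "build_graph",
    "node_metrics",
    "graph_summary",
    "enumerate_cliques",
    "classify_cliques",
    "detect_communities",
    "cpm_quality",
    "CliqueRecord",
    "Partition",
]


@dataclass(frozen=True)
class CliqueRecord:
    nodes: tuple[str, ...]
    classification: str            # "within" | "between"
    modules: tuple[str, ...]       # module of each node
    sex_counts: dict[str, int] = field(hash=False, default_factory=dict)


@dataclass
class Partition:
    membership: dict[str, int]
    gamma: float
    quality: float


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def build_graph(ibd: pd.DataFrame, metadata: pd.DataFrame,
                min_seg_cM: float = 12.0, min_n_segments: int = 1) -> nx.Graph:
    """Thresholded IBD graph.

    An edge requires >= ``min_n_segments`` segments of >= ``min_seg_cM``
    between the pair; edge attributes (n_segments, max_cM, total_cM) are then
    computed from the pair's full segment list.  All individuals present in
    ``metadata`` become nodes, connected or not.
    """
    known = set(metadata["iid"])
    if len(ibd):
        offenders = sorted((set(ibd["iid1"]) | set(ibd["iid2"])) - known)
        if offenders:
            raise KeyError(f"IBD table references individuals absent from metadata: {offenders}")
    g = nx.Graph(min_seg_cM=min_seg_cM, min_n_segments=min_n_segments)
    for row in metadata.itertuples(index=False):
        g.add_node(row.iid, module=row.site, sex=row.sex,
                   style=getattr(row, "style", ""))
    if not len(ibd):
        return g
    lengths = (ibd["end_cM"] - ibd["start_cM"]).to_numpy(dtype=float)
    df = ibd.assign(_len=lengths)
    for (a, b), chunk in df.groupby(["iid1", "iid2"], sort=True):
        if a == b:
            continue
        seg = chunk["_len"].to_numpy()
        if int(np.sum(seg >= min_seg_cM)) >= min_n_segments:
            g.add_edge(a, b, n_segments=int(len(seg)), max_cM=float(seg.max()),
                       total_cM=float(seg.sum()))
    return g


def graph_summary(graph: nx.Graph) -> dict:
    n = graph.number_of_nodes()
    m = graph.number_of_edges()
    return {
        "n": n,
        "m": m,
        "density": 2.0 * m / (n * (n - 1)) if n > 1 else 0.0,
        "average_degree": 2.0 * m / n if n else 0.0,
    }


# ---------------------------------------------------------------------------
# Node metrics
# ---------------------------------------------------------------------------

def node_metrics(graph: nx.Graph) -> pd.DataFrame:
    """Per-node centrality, clustering and within/between strength.

    k is degree/(n-1), C the unweighted local clustering coefficient;
    strengths sum the ``max_cM`` edge weights towards neighbours in the same
    (w_within) or a different (w_between) module; kW/kB are the corresponding
    edge counts.  Returns a DataFrame indexed by iid; single-node graphs get
    k = 0 by convention.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("metrics of an empty graph are undefined")
    n = graph.number_of_nodes()
    cent = (nx.degree_centrality(graph) if n > 1
            else {u: 0.0 for u in graph})
    clus = nx.clustering(graph)
    rows = []
    for u, data in graph.nodes(data=True):
        mod = data.get("module")
        kw = kb = 0
        ww = wb = 0.0
        for v in graph.neighbors(u):
            w = graph.edges[u, v].get("max_cM", 1.0)
            if graph.nodes[v].get("module") == mod:
                kw += 1
                ww += w
            else:
                kb += 1
                wb += w
        k_raw = kw + kb
        rows.append({
            "iid": u, "module": mod, "sex": data.get("sex", "U"),
            "k": cent[u], "C": clus[u],
            "kW": kw, "kB": kb, "kB_over_k": kb / k_raw if k_raw else np.nan,
            "w_within": ww, "w_between": wb,
        })
    return pd.DataFrame(rows).set_index("iid")


def module_means(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-module means of the node metrics (k, C, kW, kB, kB/k, strengths)."""
    cols = ["k", "C", "kW", "kB", "kB_over_k", "w_within", "w_between"]
    return metrics.groupby("module")[cols].mean()


# ---------------------------------------------------------------------------
# Cliques
# ---------------------------------------------------------------------------

def enumerate_cliques(graph: nx.Graph, min_size: int = 3) -> list[CliqueRecord]:
    """Maximal cliques of size >= ``min_size`` in deterministic order."""
    cliques = []
    for nodes in nx.find_cliques(graph):
        if len(nodes) < min_size:
            continue
        nodes = tuple(sorted(nodes))
        modules = tuple(graph.nodes[u].get("module") for u in nodes)
        sexes: dict[str, int] = {}
        for u in nodes:
            s = graph.nodes[u].get("sex", "U")
            sexes[s] = sexes.get(s, 0) + 1
        cliques.append(CliqueRecord(
            nodes=nodes,
            classification="within" if len(set(modules)) == 1 else "between",
            modules=modules, sex_counts=sexes,
        ))
    cliques.sort(key=lambda c: c.nodes)
    return cliques


def classify_cliques(cliques: list[CliqueRecord], metadata: pd.DataFrame) -> dict:
    """Within/between clique participation per site and sex, with chi-square.

    A node participates once per clique it belongs to.  For every site, the
    site-wide within/between participation totals define the expected
    frequencies; each sex group's observed (within, between) counts are then
    tested against them with a Pearson chi-square (df = 1).  A 2x2 sex-by-
    classification chi-square per site is also reported, together with an
    overall Mantel-Haenszel test of the sex contrast stratified by site
    (``overall_sex_contrast``; z > 0 means female between-participation
    exceeds its expectation).  Groups with a zero expected cell are skipped
    with a warning entry.
    """
    meta = metadata.set_index("iid")
    counts: dict[str, dict[str, np.ndarray]] = {}
    overall = {"within": 0, "between": 0}
    for cl in cliques:
        overall[cl.classification] += 1
        j = 0 if cl.classification == "within" else 1
        for u in cl.nodes:
            site = meta.at[u, "site"]
            sex = meta.at[u, "sex"]
            site_d = counts.setdefault(site, {})
            site_d.setdefault(sex, np.zeros(2))[j] += 1
    result = {"overall_cliques": overall, "sites": {}}
    for site, by_sex in sorted(counts.items()):
        tot = np.sum(list(by_sex.values()), axis=0)
        site_res = {"participation": {s: {"within": int(v[0]), "between": int(v[1])}
                                      for s, v in sorted(by_sex.items())},
                    "totals": {"within": int(tot[0]), "between": int(tot[1])},
                    "tests": {}}
        p_tot = tot / tot.sum()
        for sex, obs in sorted(by_sex.items()):
            expected = obs.sum() * p_tot
            if np.any(expected == 0):
                site_res["tests"][sex] = {"warning": "zero expected cell; test skipped"}
                continue
            stat = float(np.sum((obs - expected) ** 2 / expected))
            site_res["tests"][sex] = {
                "statistic": stat,
                "p": float(sstats.chi2.sf(stat, df=1)),
                "between_fraction": float(obs[1] / obs.sum()) if obs.sum() else np.nan,
            }
        if {"M", "F"} <= set(by_sex) and by_sex["M"].sum() and by_sex["F"].sum():
            table = np.array([by_sex["F"], by_sex["M"]])
            if table.sum(axis=0).all():
                exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
                stat = float(np.sum((table - exp) ** 2 / exp))
                site_res["sex_contrast"] = {
                    "statistic": stat,
                    "p": float(sstats.chi2.sf(stat, df=1)),
                    "female_between_fraction": float(by_sex["F"][1] / by_sex["F"].sum()),
                    "male_between_fraction": float(by_sex["M"][1] / by_sex["M"].sum()),
                }
        result["sites"][site] = site_res

    # Mantel-Haenszel sex contrast stratified by site (female between excess)
    num = var = 0.0
    for site, by_sex in counts.items():
        if not {"M", "F"} <= set(by_sex):
            continue
        t = np.array([by_sex["F"], by_sex["M"]], dtype=float)
        n = t.sum()
        r = t.sum(axis=1)
        c = t.sum(axis=0)
        if n < 2 or r.min() == 0 or c.min() == 0:
            continue
        num += t[0, 1] - r[0] * c[1] / n
        var += r[0] * r[1] * c[0] * c[1] / (n * n * (n - 1))
    if var > 0:
        z = num / np.sqrt(var)
        result["overall_sex_contrast"] = {
            "z": float(z),
            "p": float(2.0 * sstats.norm.sf(abs(z))),
            "female_between_excess": bool(z > 0),
        }
    return result


# ---------------------------------------------------------------------------
# Constant Potts model communities
# ---------------------------------------------------------------------------

def cpm_quality(graph: nx.Graph, membership: dict[str, int], gamma: float) -> float:
    """Unweighted CPM quality Q = sum_c [E_c - gamma * n_c (n_c - 1) / 2]."""
    sizes: dict[int, int] = {}
    for u in graph.nodes:
        c = membership[u]
        sizes[c] = sizes.get(c, 0) + 1
    internal: dict[int, int] = {}
    for u, v in graph.edges:
        if membership[u] == membership[v]:
            internal[membership[u]] = internal.get(membership[u], 0) + 1
    return float(sum(internal.get(c, 0) - gamma * n * (n - 1) / 2.0
                     for c, n in sizes.items()))


def detect_communities(graph: nx.Graph, gamma: float = 0.04,
                       iterations: int = 10000, seed: int = 0,
                       restarts: int = 10) -> Partition:
    """Leiden community detection under the constant Potts model.

    Runs the Leiden local-moving/refinement algorithm on the unweighted
    adjacency with resolution ``gamma``; ``iterations`` caps the improvement
    rounds (the algorithm stops earlier at a fixed point) and ``restarts``
    seeded restarts keep the best-quality partition (Leiden is a heuristic;
    a single run can stall in a local optimum on small graphs).  Community
    ids are canonicalised by their lexicographically smallest member.
    """
    if gamma <= 0:
        raise ValueError("resolution gamma must be positive")
    nodes = sorted(graph.nodes)
    if not nodes:
        return Partition({}, gamma, 0.0)
    index = {u: i for i, u in enumerate(nodes)}
    g = ig.Graph(n=len(nodes),
                 edges=[(index[u], index[v]) for u, v in graph.edges])
    best = None
    for r in range(max(1, restarts)):
        part = leidenalg.find_partition(
            g, leidenalg.CPMVertexPartition, resolution_parameter=gamma,
            n_iterations=min(iterations, 1000), seed=int(seed) + r,
        )
        if best is None or part.quality() > best.quality():
            best = part
    membership = {u: best.membership[index[u]] for u in nodes}
    # canonical ids: communities numbered by smallest member
    reps: dict[int, str] = {}
    for u in nodes:
        c = membership[u]
        if c not in reps or u < reps[c]:
            reps[c] = u
    order = {c: r for r, c in enumerate(sorted(reps, key=lambda c: reps[c]))}
    membership = {u: order[c] for u, c in membership.items()}
    return Partition(membership, gamma, cpm_quality(graph, membership, gamma))


def best_partition_exhaustive(graph: nx.Graph, gamma: float) -> Partition:
    """Exhaustive CPM optimum over all set partitions (small graphs only).

    Independent oracle for :func:`detect_communities`; enumerates restricted
    growth strings, so it is only usable up to ~10 nodes.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n > 12:
        raise ValueError("exhaustive search is limited to 12 nodes")
    best_q, best_m = -np.inf, None
    code = [0] * n

    def rec(i: int, maxc: int):
        nonlocal best_q, best_m
        if i == n:
            m = {u: c for u, c in zip(nodes, code)}
            q = cpm_quality(graph, m, gamma)
            if q > best_q:
                best_q, best_m = q, m
            return
        for c in range(maxc + 1):
            code[i] = c
            rec(i + 1, max(maxc, c + 1))

    if n == 0:
        return Partition({}, gamma, 0.0)
    rec(0, 0)
    return Partition(best_m, gamma, best_q)
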