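"""Bipartite exposure-feature association networks.

Significant associations for one exposure window become an undirected
bipartite graph: exposures and molecular features are the nodes, and each
significant exposure-feature pair is one signed edge (multiple categorical
contrasts collapse to a single edge carrying the sign of the smallest-p
contrast).  The module computes topology statistics (degree, shortest
paths, connected components), detects communities of co-signalling
exposures by deterministic greedy modularity maximization, and emits
per-cluster summaries (exposures ranked by association count, per-layer
feature counts, unique annotated genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .core_data import LAYERS

logger = logging.getLogger("exwas")

#: layers whose features carry gene annotation usable in summaries
ANNOTATABLE_LAYERS = ("methylation", "expression", "mirna", "protein")


@dataclass
class AssocNetwork:
    period: str
    graph: nx.Graph
    component_id: dict[str, int] = field(default_factory=dict)
    cluster_id: dict[str, int] = field(default_factory=dict)
    modularity: float | None = None

    @property
    def exposures(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "exposure")

    @property
    def features(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "feature")


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    mean_degree: float
    avg_shortest_path: float
    component_sizes: list[int]
    largest_component_fraction: float  # percent of nodes


@dataclass
class ClusterSummary:
    cluster_id: int
    exposures: list[str]  # ordered by number of associations, descending
    exposure_assoc_counts: list[int]
    per_layer_feature_counts: dict[str, int]
    n_features: int
    n_annotated_genes: int


def build_network(significant: pd.DataFrame, period: str) -> AssocNetwork:
    """Build the period's bipartite network from a significant-association
    table (either this pipeline's flagged output or an externally supplied
    catalogue with columns exposure, period, feature, layer, effect, p).

    Multiple contrasts of one exposure-feature pair collapse to one edge
    whose sign is that of the smallest-p contrast.  A display filter marks
    components holding at least two molecular features.
    """
    sub = significant[significant["period"] == period]
    g = nx.Graph()
    net = AssocNetwork(period, g)
    if sub.empty:
        logger.warning("no significant associations for period %r; empty network", period)
        return net

    exposures = set(sub["exposure"])
    features = set(sub["feature"])
    clash = exposures & features
    if clash:
        raise ValueError(
            f"bipartite violation: {sorted(clash)[0]!r} appears as both exposure and feature"
        )
    dedup = sub.sort_values(["p", "exposure", "feature"]).drop_duplicates(
        ["exposure", "feature"], keep="first"
    )
    for name in sorted(exposures):
        fam = sub.loc[sub["exposure"] == name, "family"].iloc[0] if "family" in sub else ""
        g.add_node(name, kind="exposure", family=fam)
    for name in sorted(features):
        layer = sub.loc[sub["feature"] == name, "layer"].iloc[0]
        g.add_node(name, kind="feature", layer=layer)
    for _, r in dedup.sort_values(["exposure", "feature"]).iterrows():
        g.add_edge(r["exposure"], r["feature"],
                   sign=1 if r["effect"] >= 0 else -1,
                   weight=float(abs(r["effect"])), p=float(r["p"]))

    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    for i, comp in enumerate(comps):
        n_feat = sum(1 for n in comp if g.nodes[n]["kind"] == "feature")
        display = n_feat >= 2
        for n in comp:
            net.component_id[n] = i
            g.nodes[n]["component"] = i
            g.nodes[n]["display"] = display
    return net


def display_subgraph(net: AssocNetwork) -> nx.Graph:
    """Subgraph of components with at least two molecular features (the
    display filter)."""
    keep = [n for n, d in net.graph.nodes(data=True) if d.get("display", False)]
    return net.graph.subgraph(keep).copy()


def network_statistics(
    net: AssocNetwork,
    path_length_convention: str = "edges",
    on_display_subset: bool = False,
) -> NetworkStats:
    """Degrees, shortest paths and component sizes.

    The average shortest path is the mean BFS distance over all unordered
    reachable node pairs (pairs in different components are excluded);
    counted in edges by default, or in nodes on the path (edges + 1) under
    the alternative convention.
    """
    g = display_subgraph(net) if on_display_subset else net.graph
    n_nodes = g.number_of_nodes()
    if n_nodes == 0:
        raise ValueError("empty network")
    n_edges = g.number_of_edges()
    mean_degree = 2.0 * n_edges / n_nodes
    total, pairs = 0.0, 0
    for node, dists in nx.all_pairs_shortest_path_length(g):
        for other, d in dists.items():
            if other != node:
                total += d
                pairs += 1
    # each unordered pair counted twice; ratio unaffected
    avg = total / pairs if pairs else float("nan")
    if path_length_convention == "nodes":
        avg += 1.0
    sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    return NetworkStats(
        n_nodes=n_nodes,
        n_edges=n_edges,
        mean_degree=mean_degree,
        avg_shortest_path=avg,
        component_sizes=sizes,
        largest_component_fraction=100.0 * sizes[0] / n_nodes,
    )


def detect_communities(net: AssocNetwork) -> AssocNetwork:
    """Greedy modularity communities on the largest connected component.

    Smaller components keep their component as their cluster.  Cluster ids
    are assigned deterministically: communities of the largest component
    first (by size, then smallest member label), then the remaining
    components in component order.  The partition modularity of the largest
    component is stored on the network.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise ValueError("cannot cluster a network without edges")
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    largest = g.subgraph(comps[0])
    if largest.number_of_edges() > 0:
        communities = list(nx.community.greedy_modularity_communities(largest))
        net.modularity = nx.community.modularity(largest, communities)
    else:
        communities = [set(largest.nodes)]
        net.modularity = 0.0
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    cid = 0
    for comm in communities:
        for n in sorted(comm):
            net.cluster_id[n] = cid
            g.nodes[n]["cluster"] = cid
        cid += 1
    for comp in comps[1:]:
        for n in sorted(comp):
            net.cluster_id[n] = cid
            g.nodes[n]["cluster"] = cid
        cid += 1
    logger.info("period %s: %d clusters, modularity %.3f of largest component",
                net.period, cid, net.modularity)
    return net


def cluster_summary(
    net: AssocNetwork, annotations: dict[str, str] | None = None
) -> list[ClusterSummary]:
    """Per-cluster membership summary.

    Exposures are ordered by their number of associations (edges) inside
    the cluster, descending (ties lexicographic); feature counts are per
    molecular layer; the gene tally is the unique annotated genes across
    CpGs, transcript clusters, miRNAs and proteins.
    """
    if not net.cluster_id:
        raise ValueError("run detect_communities first")
    annotations = annotations or {}
    g = net.graph
    out = []
    for cid in sorted(set(net.cluster_id.values())):
        members = [n for n, c in net.cluster_id.items() if c == cid]
        expo = [n for n in members if g.nodes[n]["kind"] == "exposure"]
        feats = [n for n in members if g.nodes[n]["kind"] == "feature"]
        counts = {e: g.degree(e) for e in expo}
        expo_sorted = sorted(expo, key=lambda e: (-counts[e], e))
        per_layer = {layer: 0 for layer in LAYERS}
        genes = set()
        for f in feats:
            layer = g.nodes[f].get("layer", "")
            if layer in per_layer:
                per_layer[layer] += 1
            if layer in ANNOTATABLE_LAYERS:
                gene = annotations.get(f)
                if gene:
                    genes.update(x.strip() for x in str(gene).split(";") if x.strip())
        out.append(
            ClusterSummary(
                cluster_id=cid,
                exposures=expo_sorted,
                exposure_assoc_counts=[counts[e] for e in expo_sorted],
                per_layer_feature_counts=per_layer,
                n_features=len(feats),
                n_annotated_genes=len(genes),
            )
        )
    return out


def summary_table(summaries: list[ClusterSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {"cluster": s.cluster_id,
             "exposures": ", ".join(s.exposures),
             **{f"n_{k}": v for k, v in s.per_layer_feature_counts.items()},
             "n_features": s.n_features,
             "n_annotated_genes": s.n_annotated_genes}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_network(net: AssocNetwork, directory: str | Path, stem: str | None = None) -> None:
    """GraphML plus node/edge tab-delimited tables for external viewers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or f"network_{net.period}"
    nx.write_graphml(net.graph, directory / f"{stem}.graphml")
    nodes = pd.DataFrame(
        [
            {"node": n, **{k: v for k, v in d.items()}}
            for n, d in sorted(net.graph.nodes(data=True))
        ]
    )
    edges = pd.DataFrame(
        [
            {"source": u, "target": v, **{k: w for k, w in d.items()}}
            for u, v, d in sorted(net.graph.edges(data=True))
        ]
    )
    nodes.to_csv(directory / f"{stem}_nodes.tsv", sep="\t", index=False)
    edges.to_csv(directory / f"{stem}_edges.tsv", sep="\t", index=False)
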