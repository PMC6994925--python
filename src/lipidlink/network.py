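"""Annotation-filtered lipid-gene Pearson correlation network.

Edges connect lipid-lipid and lipid-gene pairs whose Pearson correlation
across the analysis samples exceeds a magnitude threshold (default 0.6);
gene-gene pairs are never connected.  Genes enter the network only if an
HMDB-style annotation table links them to at least one network lipid and
they survive the integration (O2PLS) retention filter.  Subnetworks are
detected from topology (greedy modularity by default, connected components
as a sensitivity mode) and each node is labelled with its dietary-reversal
status from the differential overlap analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .differential import ComparisonOverlap

logger = logging.getLogger(__name__)


def pearson_edges(
    lipid_values: pd.DataFrame,
    gene_values: pd.DataFrame | None = None,
    gene_set=None,
    threshold: float = 0.6,
) -> pd.DataFrame:
    """All lipid-lipid and lipid-gene edges with |r| > threshold.

    Both frames are samples x features on the same sample axis.  ``gene_set``
    restricts which gene columns participate.  Constant features are skipped
    with a log message; no self-edges; gene-gene pairs are never computed
    into edges.  Returns a frame (source, target, r, kind).
    """
    lip = lipid_values
    gen = gene_values
    if gen is not None:
        if gene_set is not None:
            missing = set(gene_set) - set(gen.columns)
            if missing:
                raise ValueError(f"gene_set members absent: {sorted(missing)[:5]}")
            gen = gen[[g for g in gen.columns if g in set(gene_set)]]
        if not lip.index.equals(gen.index):
            raise ValueError("lipid and gene frames must share the sample axis")

    def _drop_constant(df: pd.DataFrame, what: str) -> pd.DataFrame:
        sd = df.std(axis=0, ddof=0)
        const = sd[sd == 0].index.tolist()
        if const:
            logger.warning("%d constant %s feature(s) skipped: %s",
                           len(const), what, const[:5])
            df = df.drop(columns=const)
        return df

    lip = _drop_constant(lip, "lipid")
    n_lip = lip.shape[1]
    blocks = [lip]
    if gen is not None and gen.shape[1]:
        gen = _drop_constant(gen, "gene")
        blocks.append(gen)
    combined = pd.concat(blocks, axis=1)
    names = combined.columns.tolist()
    corr = np.corrcoef(combined.to_numpy(dtype=float), rowvar=False)

    rows = []
    n_tot = len(names)
    for i in range(n_tot):
        for j in range(i + 1, n_tot):
            if i >= n_lip and j >= n_lip:
                continue  # gene-gene: never an edge
            r = corr[i, j]
            if np.isfinite(r) and abs(r) > threshold:
                kind = "lipid-lipid" if j < n_lip else "lipid-gene"
                rows.append((names[i], names[j], float(r), kind))
    return pd.DataFrame(rows, columns=["source", "target", "r", "kind"])


def filter_genes_by_annotation(
    annotation: pd.DataFrame,
    candidate_genes,
    network_lipids,
) -> tuple[list[str], dict[str, int]]:
    """HMDB-style two-stage gene filter.

    Stage 1: genes annotated to at least one lipid of the lipid set.
    Stage 2: intersect with the integration-retained candidate genes.
    Returns the final gene set and both stage counts, mirroring the
    316 -> 92 style funnel such studies report.
    """
    lipids = set(network_lipids)
    annotated = sorted(
        set(annotation.loc[annotation["lipid"].isin(lipids), "gene"])
    )
    final = sorted(set(annotated) & set(candidate_genes))
    counts = {"annotated_to_network_lipids": len(annotated), "after_o2pls_filter": len(final)}
    if not final:
        logger.warning("annotation filter retained no genes")
    return final, counts


@dataclass
class CorrelationNetwork:
    """The built network plus per-node attributes."""

    graph: nx.Graph
    node_kind: dict[str, str] = field(default_factory=dict)      # lipid / gene
    subnetworks: dict[str, int] = field(default_factory=dict)    # node -> id
    reversal_status: dict[str, str] = field(default_factory=dict)
    is_top_o2pls: dict[str, bool] = field(default_factory=dict)

    @property
    def n_lipids(self) -> int:
        return sum(1 for k in self.node_kind.values() if k == "lipid")

    @property
    def n_genes(self) -> int:
        return sum(1 for k in self.node_kind.values() if k == "gene")

    def summary(self) -> dict:
        sizes = pd.Series(self.subnetworks).value_counts().to_dict() if self.subnetworks else {}
        return {
            "n_nodes": self.graph.number_of_nodes(),
            "n_lipids": self.n_lipids,
            "n_genes": self.n_genes,
            "n_edges": self.graph.number_of_edges(),
            "n_subnetworks": len(set(self.subnetworks.values())) if self.subnetworks else 0,
            "subnetwork_sizes": {int(k): int(v) for k, v in sizes.items()},
        }


def build_network(
    edges: pd.DataFrame, top_o2pls=None
) -> CorrelationNetwork:
    """Simple graph over all edge-incident nodes (isolates excluded by
    construction); duplicate edges collapse.  Gene-gene edges are asserted
    absent."""
    g = nx.Graph()
    kind: dict[str, str] = {}
    for _, row in edges.iterrows():
        s, t, r, k = row["source"], row["target"], row["r"], row["kind"]
        if k == "lipid-lipid":
            kind.setdefault(s, "lipid")
            kind.setdefault(t, "lipid")
        else:
            kind.setdefault(s, "lipid")
            kind[t] = "gene"
        g.add_edge(s, t, r=float(r))
    assert not any(
        kind.get(u) == "gene" and kind.get(v) == "gene" for u, v in g.edges
    ), "gene-gene edge must never appear"
    if g.number_of_edges() == 0:
        logger.warning("empty edge list: network has no nodes")
    top = set(top_o2pls or [])
    net = CorrelationNetwork(
        graph=g,
        node_kind=kind,
        is_top_o2pls={n: n in top for n in g.nodes},
    )
    for n in g.nodes:
        g.nodes[n]["kind"] = kind[n]
        g.nodes[n]["is_top_o2pls"] = bool(net.is_top_o2pls[n])
    return net


def detect_subnetworks(
    network: CorrelationNetwork,
    method: str = "modularity",
    large_threshold: int | None = None,
) -> pd.DataFrame:
    """Partition nodes into subnetworks.

    ``method="components"`` uses connected components; ``"modularity"`` uses
    greedy modularity maximisation on a lexicographically ordered copy of the
    graph so ties break deterministically.  Subnetwork ids are assigned in
    decreasing size order (lexicographic tie-break).  A subnetwork is flagged
    ``large`` at >= ``large_threshold`` nodes, defaulting to
    max(24, ceil(0.10 * node count)).
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty network")
    ordered = nx.Graph()
    ordered.add_nodes_from(sorted(g.nodes))
    ordered.add_edges_from(
        sorted((min(u, v), max(u, v)) for u, v in g.edges),
    )
    for u, v, d in g.edges(data=True):
        ordered[u][v].update(d)

    if method == "components":
        parts = [set(c) for c in nx.connected_components(ordered)]
    elif method == "modularity":
        parts = [
            set(c)
            for c in nx.community.greedy_modularity_communities(ordered)
        ]
    else:
        raise ValueError(f"unknown method {method!r}")
    parts.sort(key=lambda c: (-len(c), min(c)))

    if large_threshold is None:
        large_threshold = max(24, int(np.ceil(0.10 * g.number_of_nodes())))

    membership: dict[str, int] = {}
    rows = []
    for i, part in enumerate(parts):
        for node in part:
            membership[node] = i
        rows.append(
            {"subnetwork": i, "size": len(part), "large": len(part) >= large_threshold}
        )
    network.subnetworks = membership
    for n in ordered.nodes:
        network.graph.nodes[n]["subnetwork"] = membership[n]
    return pd.DataFrame(rows)


def annotate_reversal(
    network: CorrelationNetwork, overlaps: list[ComparisonOverlap]
) -> CorrelationNetwork:
    """Label each node's dietary-reversal status.

    A node is ``reversed_up_in_disease`` / ``reversed_down_in_disease`` when
    it is a common feature of any disease/reversal overlap with positive /
    negative disease log2FC; otherwise ``not_reversed``.  A node reversed in
    opposite directions across models takes the direction of the larger
    |log2FC| and the conflict is logged.
    """
    best: dict[str, tuple[float, float]] = {}  # node -> (|lfc|, lfc)
    conflicts: list[str] = []
    for ov in overlaps:
        for _, row in ov.table.iterrows():
            f = row["feature"]
            lfc = float(row["disease_log2fc"])
            if f in best and np.sign(lfc) != np.sign(best[f][1]):
                conflicts.append(f)
            if f not in best or abs(lfc) > best[f][0]:
                best[f] = (abs(lfc), lfc)
    if conflicts:
        logger.warning("conflicting reversal directions across models: %s",
                       sorted(set(conflicts))[:10])
    status = {}
    for n in network.graph.nodes:
        if n in best:
            status[n] = (
                "reversed_up_in_disease" if best[n][1] > 0 else "reversed_down_in_disease"
            )
        else:
            status[n] = "not_reversed"
        network.graph.nodes[n]["reversal_status"] = status[n]
    network.reversal_status = status
    return network


def export_graphml(network: CorrelationNetwork, path) -> None:
    """GraphML export with node attributes (kind, reversal_status,
    is_top_o2pls, subnetwork) and the edge correlation ``r``."""
    nx.write_graphml(network.graph, path)


def export_edge_list(network: CorrelationNetwork, path) -> None:
    rows = [
        {"source": u, "target": v, "r": d.get("r", np.nan)}
        for u, v, d in sorted(network.graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "r"]).to_csv(
        path, sep="\t", index=False
    )
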