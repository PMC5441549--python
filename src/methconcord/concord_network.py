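"""Methylation-expression concordance networks and hierarchical clustering.

The concordance network ties differentially methylated (DM) and
differentially expressed (DE) genes together over a user-supplied
interactome. Edges between two DE genes are kept whenever the genes are
adjacent in the interactome; an edge between a DM gene and a DE gene is kept
only when the directions are concordant with a regulatory reading of promoter
methylation — hypomethylation with up-regulated expression (activation) or
hypermethylation with down-regulated expression (inhibition). Every candidate
edge is retained in the result with a kept/rejected annotation and a reason,
so the filter is auditable.

Hierarchical clustering follows the classic microarray convention:
agglomerative, average linkage, uncentered-correlation (cosine) distance,
with deterministic leaf ordering given the input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_formats import canonical_gene

#: Direction pairs (methylation, expression) considered concordant.
CONCORDANT_PAIRS = {("hypo", "up"), ("hyper", "down")}


def build_concordance_network(de: dict[str, str], dm: dict[str, str],
                              interactome: nx.Graph,
                              de_magnitude: dict[str, float] | None = None,
                              dm_magnitude: dict[str, float] | None = None) -> nx.Graph:
    """Concordance network over DE and DM genes adjacent in an interactome.

    ``de`` maps gene -> "up"/"down"; ``dm`` maps gene -> "hypo"/"hyper";
    optional magnitude maps carry |effect| for plotting. Gene matching against
    the interactome is case-insensitive. Edge attribute ``kept`` is True with
    ``reason`` in {"de-de", "concordant", "dm-dm"} or False with reason
    "discordant". A gene that is both DM and DE acts as DE for edge
    classification (source attribute "both").
    """
    if interactome.number_of_nodes() == 0:
        raise ValueError("empty interactome")
    de_c = {canonical_gene(g): d for g, d in de.items()}
    dm_c = {canonical_gene(g): d for g, d in dm.items()}
    for d in de_c.values():
        if d not in ("up", "down"):
            raise ValueError(f"DE direction must be up/down, got {d!r}")
    for d in dm_c.values():
        if d not in ("hypo", "hyper"):
            raise ValueError(f"DM direction must be hypo/hyper, got {d!r}")
    de_mag = {canonical_gene(g): v for g, v in (de_magnitude or {}).items()}
    dm_mag = {canonical_gene(g): v for g, v in (dm_magnitude or {}).items()}

    graph = nx.Graph()
    members = {}
    for node in interactome.nodes:
        c = canonical_gene(node)
        if c in de_c or c in dm_c:
            members[node] = c
    for node, c in members.items():
        source = "both" if (c in de_c and c in dm_c) else ("DE" if c in de_c else "DM")
        mag = max(abs(de_mag.get(c, 0.0)), abs(dm_mag.get(c, 0.0)))
        graph.add_node(node, source=source, de_direction=de_c.get(c),
                       dm_direction=dm_c.get(c), magnitude=mag)
    for a, b in interactome.edges:
        if a not in members or b not in members or a == b:
            continue
        kept, reason = _classify_edge(members[a], members[b], de_c, dm_c)
        graph.add_edge(a, b, kept=kept, reason=reason)
    return graph


def _classify_edge(a: str, b: str, de: dict[str, str], dm: dict[str, str]) -> tuple[bool, str]:
    a_de, b_de = a in de, b in de
    if a_de and b_de:
        return True, "de-de"
    if not a_de and not b_de:
        return True, "dm-dm"
    meth, expr = (a, b) if b_de else (b, a)
    if (dm[meth], de[expr]) in CONCORDANT_PAIRS:
        return True, "concordant"
    return False, "discordant"


def kept_subgraph(network: nx.Graph) -> nx.Graph:
    """Subgraph of kept edges (all nodes retained, including isolated ones)."""
    sub = nx.Graph()
    sub.add_nodes_from(network.nodes(data=True))
    sub.add_edges_from((a, b, d) for a, b, d in network.edges(data=True) if d.get("kept"))
    return sub


def degree_stats(network: nx.Graph) -> tuple[dict, pd.DataFrame]:
    """Per-node incident-edge counts with min/max and two distinct means.

    ``edges_per_node`` is E/N (the ratio of edge count to node count);
    ``mean_degree`` is 2E/N (the average number of incident edges per node).
    Both are reported because "average interactions per node" is ambiguous
    between the two conventions.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    degrees = dict(network.degree())
    table = pd.DataFrame({"gene": list(degrees), "degree": list(degrees.values())})
    table = table.sort_values(["degree", "gene"], ascending=[False, True]).reset_index(drop=True)
    n, e = network.number_of_nodes(), network.number_of_edges()
    summary = {"n_nodes": n, "n_edges": e,
               "min_degree": int(table["degree"].min()),
               "max_degree": int(table["degree"].max()),
               "edges_per_node": e / n,
               "mean_degree": 2 * e / n}
    return summary, table


# ---------------------------------------------------------------------------
# Hierarchical clustering (average linkage, uncentered correlation)
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    """Row/column dendrograms and orderings of a clustered matrix."""

    matrix: pd.DataFrame = field(repr=False)
    col_linkage: np.ndarray = field(repr=False)
    col_order: list
    row_linkage: np.ndarray | None = field(repr=False, default=None)
    row_order: list | None = None

    def cut_columns(self, n_clusters: int) -> pd.Series:
        """Column cluster labels when the column tree is cut into ``n_clusters``."""
        labels = hierarchy.fcluster(self.col_linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.matrix.columns, name="cluster")

    def ordered(self) -> pd.DataFrame:
        rows = self.row_order if self.row_order is not None else list(self.matrix.index)
        return self.matrix.loc[rows, self.col_order]


def uncentered_correlation_distance(X: np.ndarray) -> np.ndarray:
    """Condensed distance 1 - (x.y)/(|x||y|) between the columns of X.

    The uncentered correlation is the cosine similarity without mean
    subtraction (the classic clustering convention for expression heat maps).
    A zero-norm (constant-zero) column has undefined similarity; its distance
    is defined as 1 with a warning.
    """
    norms = np.linalg.norm(X, axis=0)
    zero = norms == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-norm column(s); distance to them set to 1")
    safe = np.where(zero, 1.0, norms)
    Xn = X / safe
    sim = Xn.T @ Xn
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    np.fill_diagonal(sim, 1.0)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    # symmetrize against floating-point asymmetry before condensing
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return squareform(dist, checks=False)


def hierarchical_cluster(matrix: pd.DataFrame, cluster_rows: bool = True,
                         max_rows: int | None = 5000) -> ClusterResult:
    """Average-linkage clustering of columns (and rows) on uncentered correlation.

    ``matrix`` is typically the significant probes x samples. Row clustering
    is skipped when the matrix has more than ``max_rows`` rows (quadratic
    memory) or ``cluster_rows`` is False; leaf ordering is deterministic given
    the input order.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 columns to cluster")
    X = matrix.to_numpy(dtype=float)
    col_link = hierarchy.linkage(uncentered_correlation_distance(X), method="average")
    col_order = [matrix.columns[i] for i in hierarchy.leaves_list(col_link)]
    row_link, row_order = None, None
    if cluster_rows and matrix.shape[0] >= 2 and (max_rows is None or matrix.shape[0] <= max_rows):
        row_link = hierarchy.linkage(uncentered_correlation_distance(X.T), method="average")
        row_order = [matrix.index[i] for i in hierarchy.leaves_list(row_link)]
    return ClusterResult(matrix=matrix, col_linkage=col_link, col_order=col_order,
                         row_linkage=row_link, row_order=row_order)


def network_to_edge_table(network: nx.Graph) -> pd.DataFrame:
    """Edge-list table with kept/rejected annotation (stable ordering)."""
    rows = [{"gene_a": min(str(a), str(b)), "gene_b": max(str(a), str(b)),
             "kept": bool(d.get("kept", True)), "reason": d.get("reason", "")}
            for a, b, d in network.edges(data=True)]
    table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "kept", "reason"])
    return table.sort_values(["gene_a", "gene_b"], kind="stable").reset_index(drop=True)


def network_to_node_table(network: nx.Graph) -> pd.DataFrame:
    rows = []
    for n, d in network.nodes(data=True):
        rows.append({"gene": str(n), "source": d.get("source", ""),
                     "de_direction": d.get("de_direction") or "",
                     "dm_direction": d.get("dm_direction") or "",
                     "magnitude": d.get("magnitude", np.nan),
                     "degree": network.degree(n)})
    table = pd.DataFrame(rows, columns=["gene", "source", "de_direction",
                                        "dm_direction", "magnitude", "degree"])
    return table.sort_values("gene", kind="stable").reset_index(drop=True)
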