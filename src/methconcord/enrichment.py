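"""Gene-set over-representation, activation z-scores, seed-PPI network
construction and the binomial enrichment Z-test.

Over-representation uses the right-tailed Fisher/hypergeometric test with
Benjamini-Hochberg correction. The seed network is a subnetwork of a
user-supplied interactome induced on designated seed genes (e.g. GWAS risk
loci) and their first-degree neighbors. Enrichment of a query gene list in
that network is scored with a binomial-approximation Z statistic

    Z = (O - E) / sqrt((N - 1) p q)

where O is the observed number of query genes inside the network, p the
expected frequency of network genes (network size over the gene universe),
q = 1 - p, E = |query| * p the expected count, and N the total number of
genes (the universe by default; an alternate reading with N = |query|, which
makes the statistic the standard one-sample proportion z-test, is selectable).
Significance is one-tailed normal, critical Z = 1.65 at P < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .io_formats import canonical_gene

logger = logging.getLogger(__name__)

#: One-tailed critical Z for significance at P < 0.05.
CRITICAL_Z = 1.65


@dataclass
class PPIEnrichResult:
    """Binomial Z-test of query-gene enrichment in a PPI network."""

    O: int              # observed query genes in the network
    E: float            # expected count under the null
    N: int              # total gene count entering the variance term
    p: float            # expected frequency of network genes
    q: float            # 1 - p
    Z: float
    P_one_tailed: float
    n_query: int
    n_network: int

    @property
    def significant(self) -> bool:
        return self.Z >= CRITICAL_Z


def fisher_ora(query, gene_sets: dict[str, set[str]], universe,
               min_overlap: int = 0) -> pd.DataFrame:
    """Right-tailed Fisher over-representation of a query list against gene sets.

    Gene matching is case-insensitive. Every set is intersected with the
    universe; the query must be a subset of the universe. p is the
    hypergeometric upper tail P(X >= overlap); q is BH-adjusted across sets;
    records are sorted by p.
    """
    uni = {canonical_gene(g) for g in universe}
    qry = {canonical_gene(g) for g in query}
    if not uni:
        raise ValueError("empty universe")
    if not qry:
        raise ValueError("empty query")
    stray = qry - uni
    if stray:
        raise ValueError(f"query gene(s) not in universe: {sorted(stray)[:5]}")
    rows = []
    M, n = len(uni), len(qry)
    for name, members in gene_sets.items():
        inset = {canonical_gene(g) for g in members} & uni
        K = len(inset)
        k = len(inset & qry)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append({"set_name": name, "overlap": k, "set_size": K,
                     "query_size": n, "universe_size": M, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out = out[out["overlap"] >= min_overlap]
    return out.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)


def activation_zscore(consistency_signs) -> tuple[float, str]:
    """Sign-consistency activation z-score and predicted state.

    ``consistency_signs`` holds +1 per gene whose observed direction matches
    the annotated activating direction and -1 per mismatch;
    z = sum(signs)/sqrt(N). State is "Increased" for z >= 2, "Decreased" for
    z <= -2 (|z| >= 2 deemed significant) and "none" otherwise. An empty
    vector returns (nan, "none"): no direction can be predicted.
    """
    signs = np.asarray(list(consistency_signs), dtype=float)
    if signs.size == 0:
        return float("nan"), "none"
    if not np.all(np.isin(signs, (-1.0, 1.0))):
        raise ValueError("consistency signs must be +/-1")
    z = signs.sum() / np.sqrt(signs.size)
    state = "Increased" if z >= 2 else "Decreased" if z <= -2 else "none"
    return float(z), state


def build_seed_network(seeds, interactome: nx.Graph) -> nx.Graph:
    """Subnetwork induced on seed genes and their first-degree neighbors.

    Seeds absent from the interactome are logged and skipped; if none is
    present the network is undefined and an error is raised. Node attribute
    ``seed`` marks seed status; a seed with no edges is retained as a
    singleton.
    """
    by_canon = {canonical_gene(n): n for n in interactome.nodes}
    present, absent = [], []
    for s in seeds:
        node = by_canon.get(canonical_gene(s))
        (present if node is not None else absent).append(node if node is not None else s)
    if absent:
        logger.info("%d seed gene(s) absent from interactome: %s", len(absent), absent[:10])
    if not present:
        raise ValueError("no seed gene present in the interactome")
    nodes = set(present)
    for s in present:
        nodes.update(interactome.neighbors(s))
    sub = interactome.subgraph(nodes).copy()
    nx.set_node_attributes(sub, {n: (n in set(present)) for n in sub.nodes}, "seed")
    return sub


def ppi_enrichment_ztest(query, network: nx.Graph, universe_size: int,
                         n_binding: str = "universe") -> PPIEnrichResult:
    """Binomial Z-test for enrichment of a query gene list in a PPI network.

    p = (network node count)/universe_size, E = |query| * p,
    O = |query inside network| (case-insensitive), and
    Z = (O - E)/sqrt((N - 1) p q) with N per ``n_binding``: "universe"
    (default, N = universe_size) or "query" (N = |query|, the standard
    one-sample proportion z-test). One-tailed P = 1 - Phi(Z); significant
    iff Z >= 1.65. Invariant to gene order and case.
    """
    if universe_size < 2:
        raise ValueError("universe_size must be >= 2")
    net_nodes = {canonical_gene(n) for n in network.nodes}
    if len(net_nodes) > universe_size:
        raise ValueError("network has more nodes than the universe")
    qry = {canonical_gene(g) for g in query}
    if not qry:
        raise ValueError("empty query")
    p = len(net_nodes) / universe_size
    if p <= 0 or p >= 1:
        raise ValueError(f"network frequency p={p} gives zero variance")
    q = 1.0 - p
    O = len(qry & net_nodes)
    E = len(qry) * p
    if n_binding == "universe":
        N = universe_size
    elif n_binding == "query":
        N = len(qry)
    else:
        raise ValueError("n_binding must be 'universe' or 'query'")
    if N < 2:
        raise ValueError("N must be >= 2")
    Z = (O - E) / np.sqrt((N - 1) * p * q)
    return PPIEnrichResult(O=O, E=float(E), N=int(N), p=float(p), q=float(q),
                           Z=float(Z), P_one_tailed=z_to_p_one_tailed(Z),
                           n_query=len(qry), n_network=len(net_nodes))


def z_to_p_one_tailed(z: float) -> float:
    """Upper-tail standard-normal P for a Z-score.

    Computed via the complementary error function (scipy's ndtr machinery),
    accurate far into the tail (up to |Z| ~ 37, beyond which the double
    underflows), so values like 2e-37 are exact rather than rounded to zero.
    """
    if not np.isfinite(z):
        raise ValueError("Z must be finite")
    return float(stats.norm.sf(z))
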