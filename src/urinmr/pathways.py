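"""Pathway over-representation and topology-impact analysis.

The significant-metabolite list is tested against each pathway with
the hypergeometric upper-tail test (query hits among pathway members,
drawn from the library's compound universe), and a topology "impact"
score weights hits by their relative betweenness centrality in the
pathway's compound graph — hits at bottleneck positions move the score
more than peripheral ones.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import pandas as pd
from scipy import stats

from .io import Pathway, PathwayLibrary

logger = logging.getLogger(__name__)


@dataclass
class OraResult:
    pathway_id: str
    pathway_name: str
    hits: set[str]
    k: int  # hit count
    K: int  # pathway size
    n: int  # query size (mapped)
    N: int  # background size
    p: float
    impact: float


def ora_hypergeometric(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p: P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise ValueError(f"inconsistent counts: k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def relative_betweenness(graph: nx.Graph) -> dict[str, float]:
    """Betweenness centrality normalized by (v-1)(v-2)/2 per node.

    Shortest-path counting on the unweighted, undirected compound
    graph; graphs with fewer than 3 nodes have no strictly-between
    positions, so all centralities are 0.
    """
    if graph.number_of_nodes() < 3:
        return {node: 0.0 for node in graph.nodes}
    return nx.betweenness_centrality(graph, normalized=True)


def pathway_impact(hits: Iterable[str], graph: nx.Graph) -> float:
    """Share of total betweenness centrality carried by the hit nodes."""
    centrality = relative_betweenness(graph)
    hits = set(hits)
    unknown = hits - set(graph.nodes)
    if unknown:
        raise ValueError(f"hits not in graph: {sorted(unknown)}")
    denom = sum(centrality.values())
    if denom == 0:
        return 0.0
    return sum(centrality[h] for h in hits) / denom


def pathway_graph(pathway: Pathway) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(c.lower() for c in pathway.compounds)
    g.add_edges_from((a.lower(), b.lower()) for a, b in pathway.edges)
    return g


def _canonicalize(names: Iterable[str], synonyms: dict[str, str]) -> set[str]:
    syn = {k.lower(): v.lower() for k, v in synonyms.items()}
    out = set()
    for name in names:
        low = name.lower().strip()
        out.add(syn.get(low, low))
    return out


def run_pathway_analysis(
    significant: Iterable[str],
    library: PathwayLibrary,
    background: set[str] | None = None,
) -> pd.DataFrame:
    """One ORA row per pathway, sorted by p.

    Name matching is case-insensitive through the library's synonym
    map; duplicate query names collapse before testing.  The background
    defaults to the library's compound universe; ``n`` counts the query
    compounds that map into the background.  Queries that map to no
    pathway produce an empty result with a warning.
    """
    if not library.pathways:
        raise ValueError("empty pathway library")
    universe = {b.lower() for b in background} if background else library.universe()
    query = _canonicalize(significant, library.synonyms) & universe
    if not query:
        warnings.warn("no significant metabolite maps to any pathway compound")
        return pd.DataFrame(
            columns=["pathway_id", "pathway_name", "k", "K", "n", "N", "p", "impact", "hits"]
        )
    N, n = len(universe), len(query)
    rows = []
    for pw in library.pathways:
        compounds = {c.lower() for c in pw.compounds} & universe
        if not compounds:
            continue
        hits = query & compounds
        p = ora_hypergeometric(len(hits), n, len(compounds), N)
        impact = pathway_impact(hits, pathway_graph(pw))
        rows.append(
            {
                "pathway_id": pw.id, "pathway_name": pw.name,
                "k": len(hits), "K": len(compounds), "n": n, "N": N,
                "p": p, "impact": impact, "hits": ";".join(sorted(hits)),
            }
        )
    out = pd.DataFrame(rows).sort_values(["p", "pathway_id"], kind="stable")
    return out.reset_index(drop=True)
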