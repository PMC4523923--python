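"""Anchored clusters of imported nodes and hypergeometric term enrichment.

Clusters follow the degree-1 rule of the published network figure: every
imported node whose *only* neighbor is a screen bait or prey is assigned to
the cluster anchored at that neighbor. Each cluster is then tested for
over-representation of annotation terms with a one-sided hypergeometric
(Fisher) test against a node universe, with Benjamini–Hochberg correction
across the terms tested within the cluster. Terms are opaque labels; no
ontology structure is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class Cluster:
    cluster_id: str
    anchor: str
    members: list[str]
    enriched_terms: pd.DataFrame | None = field(default=None, repr=False)


def define_clusters(graph: nx.Graph) -> list[Cluster]:
    """Group qualifying imported nodes by their unique screen-node anchor.

    A node qualifies if its role is ``imported``, its degree is exactly 1,
    and its sole neighbor has role ``bait`` or ``prey``. Anchors without any
    qualifying neighbor yield no cluster; every qualifying node belongs to
    exactly one cluster.
    """
    members_by_anchor: dict[str, list[str]] = {}
    for node, data in graph.nodes(data=True):
        if data.get("role") != "imported" or graph.degree(node) != 1:
            continue
        (anchor,) = graph.neighbors(node)
        if graph.nodes[anchor].get("role") in ("bait", "prey"):
            members_by_anchor.setdefault(anchor, []).append(node)
    return [
        Cluster(cluster_id=f"cluster_{anchor}", anchor=anchor, members=sorted(members))
        for anchor, members in sorted(members_by_anchor.items())
    ]


def _annotation_map(annotations: pd.DataFrame) -> dict[str, set[str]]:
    terms: dict[str, set[str]] = {}
    for node, term in zip(annotations["node"], annotations["term"]):
        terms.setdefault(str(term), set()).add(str(node))
    return terms


def enrich_terms(
    members: list[str] | set[str],
    annotations: pd.DataFrame,
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in one cluster.

    For a universe of M nodes of which K carry the term and a cluster of n
    members with k carrying it, the p-value is the upper tail
    P(X >= k) for X ~ Hypergeom(M, K, n). q-values are Benjamini–Hochberg
    across all terms tested for this cluster; output is sorted by (q, p,
    term). Members must lie within the universe.
    """
    members = set(members) & universe
    if not members:
        return pd.DataFrame(columns=["term", "overlap", "p", "q"])
    term_nodes = {
        term: nodes & universe for term, nodes in _annotation_map(annotations).items()
    }
    term_nodes = {t: n for t, n in term_nodes.items() if n}
    if not term_nodes:
        return pd.DataFrame(columns=["term", "overlap", "p", "q"])

    M, n = len(universe), len(members)
    rows = []
    for term, nodes in sorted(term_nodes.items()):
        k = len(nodes & members)
        p = float(hypergeom.sf(k - 1, M, len(nodes), n))
        rows.append({"term": term, "overlap": k, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values(["q", "p", "term"], ignore_index=True)


def enrich_clusters(
    clusters: list[Cluster],
    annotations: pd.DataFrame,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Run enrichment for every cluster; long-format result table.

    The default universe is every annotated node; pass an explicit universe
    (e.g. annotated nodes present in the network) to restrict it. Results
    are also attached to each cluster's ``enriched_terms``.
    """
    if universe is None:
        universe = set(annotations["node"].astype(str))
    frames = []
    for cluster in clusters:
        res = enrich_terms(cluster.members, annotations, universe)
        cluster.enriched_terms = res
        if not res.empty:
            res = res.copy()
            res.insert(0, "anchor", cluster.anchor)
            res.insert(0, "cluster", cluster.cluster_id)
            frames.append(res)
    if not frames:
        return pd.DataFrame(columns=["cluster", "anchor", "term", "overlap", "p", "q"])
    return pd.concat(frames, ignore_index=True)
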