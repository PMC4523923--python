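"""Evidence-integrated interaction network with a five-class edge taxonomy.

Screen-derived robustness records are merged with an external-evidence table
(STRING-like: per-pair confidence plus an evidence channel) into one
undirected attributed graph. Each edge carries exactly one of five classes,
mirroring the line styles of the published network figure:

===========================  ==============  =====================================
class                        figure style    rule
===========================  ==============  =====================================
``TAPMS_SUPPORTED``          thick green     robust candidate with experimental
                                             external support (any confidence)
``TAPMS_ROBUST``             thick black     robust candidate, no support
``TAPMS_LOW``                thin grey       candidate of low robustness (< 0.5)
``TAPMS_MARGINAL_SUPPORTED`` dashed green    best score in (0.7, 0.8], supported
``EXTERNAL_ONLY``            dashed grey     not observed in the screen;
                                             experimental evidence >= 0.9
===========================  ==============  =====================================

Screen-observed pairs count as externally supported on *any* experimental-
channel confidence; edges imported from the evidence table alone require the
high-confidence threshold (default 0.9) and must touch a screen node
(optionally chaining through other imported nodes). Node roles are ``bait``,
``prey`` or ``imported``.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .io import write_table

EDGE_CLASSES = (
    "TAPMS_SUPPORTED",
    "TAPMS_ROBUST",
    "TAPMS_LOW",
    "TAPMS_MARGINAL_SUPPORTED",
    "EXTERNAL_ONLY",
)
#: lower index wins when duplicate edges conflict
_PRECEDENCE = {cls: i for i, cls in enumerate(EDGE_CLASSES)}

DEFAULT_MIN_EXTERNAL_SCORE = 0.9
MARGINAL_BAND = (0.7, 0.8)  # (exclusive, inclusive] on max_avg_score


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _experimental_scores(evidence: pd.DataFrame) -> dict[tuple[str, str], float]:
    """Max experimental-channel score per unordered pair."""
    scores: dict[tuple[str, str], float] = {}
    if evidence is None or evidence.empty:
        return scores
    exp = evidence[evidence["channel"] == "experimental"]
    for a, b, s in zip(exp["node_a"], exp["node_b"], exp["score"]):
        key = _pair_key(str(a), str(b))
        if s > scores.get(key, -1.0):
            scores[key] = float(s)
    return scores


def has_external_support(pair: tuple[str, str], evidence: pd.DataFrame) -> bool:
    """True iff an experimental-channel edge exists for the pair, any score."""
    return _pair_key(*pair) in _experimental_scores(evidence)


def assign_edge_class(
    robustness: float, max_avg_score: float, supported: bool
) -> str | None:
    """Edge class of a screen-observed pair, or None for no edge.

    The rules form a disjoint truth table over (candidate, robust, score
    band, supported); a pair that is neither a candidate nor a supported
    marginal yields no TAP-MS edge.
    """
    candidate = max_avg_score > 0.8
    if candidate:
        if robustness >= 0.5:
            return "TAPMS_SUPPORTED" if supported else "TAPMS_ROBUST"
        return "TAPMS_LOW"
    lo, hi = MARGINAL_BAND
    if lo < max_avg_score <= hi and supported:
        return "TAPMS_MARGINAL_SUPPORTED"
    return None


def import_external_edges(
    screen_nodes: set[str],
    evidence: pd.DataFrame,
    min_score: float = DEFAULT_MIN_EXTERNAL_SCORE,
    observed_pairs: set[tuple[str, str]] | None = None,
    allow_chaining: bool = False,
) -> tuple[dict[tuple[str, str], float], set[str]]:
    """High-confidence experimental edges not observed in the screen.

    Keeps experimental-channel edges with score >= ``min_score`` whose pair
    is not among ``observed_pairs`` and which touch at least one screen node
    (with ``allow_chaining``, also edges reachable through other kept
    edges). Returns the kept edges with their scores plus the set of newly
    imported (non-screen) nodes.
    """
    observed = {_pair_key(*p) for p in (observed_pairs or set())}
    candidates = {
        pair: score
        for pair, score in _experimental_scores(evidence).items()
        if score >= min_score and pair not in observed and pair[0] != pair[1]
    }
    kept: dict[tuple[str, str], float] = {}
    accepted_nodes = set(screen_nodes)
    changed = True
    while changed:
        changed = False
        for pair, score in sorted(candidates.items()):
            if pair in kept:
                continue
            if pair[0] in accepted_nodes or pair[1] in accepted_nodes:
                kept[pair] = score
                if allow_chaining:
                    before = len(accepted_nodes)
                    accepted_nodes.update(pair)
                    changed = changed or len(accepted_nodes) > before
    imported_nodes = {n for pair in kept for n in pair} - set(screen_nodes)
    return kept, imported_nodes


def merge_reciprocal(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse directional bait→prey records onto unordered pairs.

    Reciprocal bait–bait observations keep the maximum robustness and the
    maximum average score; the candidate flag is re-derived from the merged
    score. Output columns: ``node_a node_b robustness max_avg_score
    candidate`` with node_a <= node_b.
    """
    merged: dict[tuple[str, str], dict] = {}
    for row in records.itertuples(index=False):
        key = _pair_key(str(row.bait), str(row.prey))
        if key[0] == key[1]:
            continue  # no self-loops
        entry = merged.setdefault(
            key, {"robustness": 0.0, "max_avg_score": 0.0}
        )
        entry["robustness"] = max(entry["robustness"], float(row.robustness))
        entry["max_avg_score"] = max(entry["max_avg_score"], float(row.max_avg_score))
    rows = [
        {
            "node_a": a,
            "node_b": b,
            "robustness": v["robustness"],
            "max_avg_score": v["max_avg_score"],
            "candidate": v["max_avg_score"] > 0.8,
        }
        for (a, b), v in sorted(merged.items())
    ]
    return pd.DataFrame(
        rows, columns=["node_a", "node_b", "robustness", "max_avg_score", "candidate"]
    )


def assemble_network(
    records: pd.DataFrame,
    evidence: pd.DataFrame | None,
    min_external_score: float = DEFAULT_MIN_EXTERNAL_SCORE,
    allow_chaining: bool = False,
) -> nx.Graph:
    """Build the full attributed interaction network.

    ``records`` is the classified robustness table (columns ``bait prey
    robustness max_avg_score candidate``). ``evidence`` may be None or empty,
    in which case only unsupported TAP-MS edge classes can appear.
    """
    if evidence is None:
        evidence = pd.DataFrame(columns=["node_a", "node_b", "score", "channel"])
    exp_scores = _experimental_scores(evidence)
    pairs = merge_reciprocal(records)

    baits = sorted(set(records["bait"].astype(str)))
    preys = sorted(set(records["prey"].astype(str)) - set(baits))
    graph = nx.Graph()
    for node in baits:
        graph.add_node(node, role="bait")
    for node in preys:
        graph.add_node(node, role="prey")

    def _add_edge(a: str, b: str, cls: str, **attrs) -> None:
        if graph.has_edge(a, b):
            if _PRECEDENCE[cls] >= _PRECEDENCE[graph.edges[a, b]["class"]]:
                return
        graph.add_edge(a, b, **{"class": cls, **attrs})

    observed_pairs: set[tuple[str, str]] = set()
    for row in pairs.itertuples(index=False):
        key = (row.node_a, row.node_b)
        observed_pairs.add(key)
        score = exp_scores.get(key)
        cls = assign_edge_class(row.robustness, row.max_avg_score, score is not None)
        if cls is None:
            continue
        attrs = {"robustness": float(row.robustness), "max_avg_score": float(row.max_avg_score)}
        if score is not None:
            attrs["external_score"] = score
        _add_edge(row.node_a, row.node_b, cls, **attrs)

    screen_nodes = set(baits) | set(preys)
    kept, imported_nodes = import_external_edges(
        screen_nodes,
        evidence,
        min_score=min_external_score,
        observed_pairs=observed_pairs,
        allow_chaining=allow_chaining,
    )
    for node in sorted(imported_nodes):
        graph.add_node(node, role="imported")
    for (a, b), score in sorted(kept.items()):
        _add_edge(a, b, "EXTERNAL_ONLY", external_score=score)

    # imported nodes are only ever added together with a kept edge
    return graph


def write_network(graph: nx.Graph, outdir: str | Path, stem: str = "network") -> dict[str, Path]:
    """Write GraphML plus SIF and an edge-attribute TSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graphml = outdir / f"{stem}.graphml"
    ordered = nx.Graph()
    ordered.add_nodes_from(sorted(graph.nodes(data=True)))
    ordered.add_edges_from(
        (min(a, b), max(a, b), d) for a, b, d in sorted(graph.edges(data=True))
    )
    nx.write_graphml(ordered, graphml)

    sif = outdir / f"{stem}.sif"
    with open(sif, "w") as fh:
        for a, b, data in sorted(ordered.edges(data=True)):
            fh.write(f"{a}\t{data['class']}\t{b}\n")
        for node in sorted(nx.isolates(ordered)):
            fh.write(f"{node}\n")

    rows = [
        {
            "node_a": a,
            "node_b": b,
            "class": data["class"],
            "robustness": data.get("robustness", ""),
            "max_avg_score": data.get("max_avg_score", ""),
            "external_score": data.get("external_score", ""),
        }
        for a, b, data in sorted(ordered.edges(data=True))
    ]
    edges_tsv = write_table(
        pd.DataFrame(
            rows,
            columns=["node_a", "node_b", "class", "robustness", "max_avg_score", "external_score"],
        ),
        outdir / f"{stem}_edges.tsv",
    )
    return {"graphml": graphml, "sif": sif, "edges": edges_tsv}


def read_network(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)
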