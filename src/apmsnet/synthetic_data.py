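"""Synthetic inputs for the interactomics pipeline, with ground truth.

This module emulates every input the downstream analysis consumes:

* bait–prey spectral-count tables from a tandem-affinity-purification screen,
  with replicated purifications, no-bait control runs, a shared contaminant
  background and planted true interactions at a configurable enrichment;
* a STRING-like external-evidence edge table with an ``experimental`` channel,
  per-edge confidence scores, supported true pairs, imported neighbor nodes
  and noise edges;
* a node→term annotation table with one term planted on a chosen node subset;
* ribosome-footprint read positions over a gene, concentrated strictly
  downstream of a planted translation start apart from a small uniform leak.

Counts are Poisson. The rate for bait ``b``, prey ``p``, replicate ``r`` is::

    depth(b, r) * background_rate * enrichment     if (b, p) is a true pair
    depth(b, r) * background_rate * present(p; b, r)   otherwise

where ``depth`` is a mean-one log-normal per-purification depth factor (so
spectral-count normalization has something to correct) and ``present`` is a
Bernoulli presence indicator: a configurable fraction of contaminant preys is
"sticky" and shows up in most purifications, controls included, while the
rest appear sporadically. Control purifications contain contaminants only.

Identification scores emulate search-engine (Mascot-like) protein scores:
they grow with spectral abundance (clipped to ``id_score_range``), so the
identification-score sweep axis removes low-evidence records first, the way
a real Mascot threshold does.

All generation is reproducible: one :class:`numpy.random.Generator` seeded
from ``SynthConfig.seed`` drives every draw in a fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import BED_COLUMNS

SPECTRAL_COLUMNS = ["bait", "prey", "replicate", "count", "id_score"]
CONTROL_COLUMNS = ["control_run", "prey", "count", "id_score"]
EVIDENCE_COLUMNS = ["node_a", "node_b", "score", "channel"]
ANNOTATION_COLUMNS = ["node", "term"]


@dataclass
class SynthConfig:
    """Parameters of the synthetic AP-MS screen.

    Defaults mirror the screen conditions the pipeline is benchmarked at:
    four replicate purifications per bait, a background of ~2 spectra per
    contaminant prey per purification, and ten-fold enrichment of planted
    true interactions.
    """

    n_baits: int = 8
    n_preys: int = 200
    n_controls: int = 4
    n_replicates: int = 4
    background_rate: float = 2.0
    enrichment: float = 10.0
    planted_density: float = 0.05
    id_score_range: tuple[float, float] = (5.0, 60.0)
    seed: int = 0
    # depth factors are log-normal with E[depth]=1; sigma=0 disables them
    depth_sigma: float = 0.3
    # contaminant presence model: sticky preys appear almost everywhere
    sticky_fraction: float = 0.3
    sticky_presence: float = 0.95
    base_presence: float = 0.35
    # identification-score model: id = clip(lo + slope*count + N(0, noise))
    id_score_slope: float = 4.0
    id_score_noise: float = 2.0

    def __post_init__(self) -> None:
        for name in ("n_baits", "n_preys", "n_controls", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.enrichment < 1:
            raise ValueError("enrichment must be >= 1")
        if not 0.0 <= self.planted_density <= 1.0:
            raise ValueError("planted_density must lie in [0, 1]")
        lo, hi = self.id_score_range
        if not lo < hi:
            raise ValueError("id_score_range must be an increasing interval")
        for name in ("sticky_fraction", "sticky_presence", "base_presence"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated screen, for recovery tests."""

    baits: list[str]
    preys: list[str]
    true_pairs: set[tuple[str, str]]
    contaminant_preys: set[str]
    sticky_preys: set[str]
    depth_factors: dict[str, float] = field(default_factory=dict)
    seed: int = 0


def _purification_id(bait: str, replicate: int) -> str:
    return f"{bait}:{replicate}"


def generate_apms_dataset(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate one AP-MS screen.

    Returns
    -------
    table : DataFrame
        Spectral counts, columns ``bait prey replicate count id_score``;
        only records with a positive count are emitted (a prey unobserved
        in a purification simply has no record).
    controls : DataFrame
        No-bait control purifications, columns
        ``control_run prey count id_score``.
    truth : SyntheticTruth
    """
    rng = np.random.default_rng(config.seed)
    baits = [f"bait{i:02d}" for i in range(1, config.n_baits + 1)]
    preys = [f"prey{i:03d}" for i in range(1, config.n_preys + 1)]

    planted_mask = rng.random((config.n_baits, config.n_preys)) < config.planted_density
    true_pairs = {
        (baits[i], preys[j])
        for i, j in zip(*np.nonzero(planted_mask), strict=True)
    }

    n_sticky = int(round(config.sticky_fraction * config.n_preys))
    sticky_idx = rng.choice(config.n_preys, size=n_sticky, replace=False)
    presence_prob = np.full(config.n_preys, config.base_presence)
    presence_prob[sticky_idx] = config.sticky_presence

    mu = -0.5 * config.depth_sigma**2  # mean-one log-normal
    depth_factors: dict[str, float] = {}

    def _draw_depth() -> float:
        if config.depth_sigma == 0:
            return 1.0
        return float(np.exp(rng.normal(mu, config.depth_sigma)))

    def _id_scores(counts: np.ndarray) -> np.ndarray:
        lo, hi = config.id_score_range
        raw = lo + config.id_score_slope * counts + rng.normal(
            0.0, config.id_score_noise, size=counts.shape
        )
        return np.clip(raw, lo, hi)

    table_rows: list[pd.DataFrame] = []
    for i, bait in enumerate(baits):
        for rep in range(1, config.n_replicates + 1):
            depth = _draw_depth()
            depth_factors[_purification_id(bait, rep)] = depth
            present = rng.random(config.n_preys) < presence_prob
            rate = np.where(
                planted_mask[i],
                depth * config.background_rate * config.enrichment,
                depth * config.background_rate * present,
            )
            counts = rng.poisson(rate)
            nz = np.nonzero(counts)[0]
            if nz.size == 0:
                continue
            table_rows.append(
                pd.DataFrame(
                    {
                        "bait": bait,
                        "prey": np.asarray(preys, dtype=object)[nz],
                        "replicate": rep,
                        "count": counts[nz],
                        "id_score": np.round(_id_scores(counts[nz].astype(float)), 3),
                    }
                )
            )

    control_rows: list[pd.DataFrame] = []
    for k in range(1, config.n_controls + 1):
        run = f"ctrl{k:02d}"
        depth = _draw_depth()
        depth_factors[run] = depth
        present = rng.random(config.n_preys) < presence_prob
        counts = rng.poisson(depth * config.background_rate * present)
        nz = np.nonzero(counts)[0]
        if nz.size == 0:
            continue
        control_rows.append(
            pd.DataFrame(
                {
                    "control_run": run,
                    "prey": np.asarray(preys, dtype=object)[nz],
                    "count": counts[nz],
                    "id_score": np.round(_id_scores(counts[nz].astype(float)), 3),
                }
            )
        )

    table = (
        pd.concat(table_rows, ignore_index=True)
        if table_rows
        else pd.DataFrame(columns=SPECTRAL_COLUMNS)
    )
    controls = (
        pd.concat(control_rows, ignore_index=True)
        if control_rows
        else pd.DataFrame(columns=CONTROL_COLUMNS)
    )
    truth = SyntheticTruth(
        baits=baits,
        preys=preys,
        true_pairs=true_pairs,
        contaminant_preys=set(preys),
        sticky_preys={preys[j] for j in sticky_idx},
        depth_factors=depth_factors,
        seed=config.seed,
    )
    return table, controls, truth


def generate_evidence_table(
    truth: SyntheticTruth,
    support_prob: float = 0.6,
    noise_edges: int = 30,
    n_imported: int = 12,
    n_anchors: int = 3,
    imported_score_range: tuple[float, float] = (0.9, 1.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate a STRING-like external-evidence table.

    Each planted true pair gains an ``experimental``-channel edge with
    probability ``support_prob`` (any confidence, so the screen-support rule
    "no confidence threshold" is exercised). ``n_imported`` external nodes
    (``ext01`` ...) each attach by one high-confidence experimental edge to
    one of ``n_anchors`` randomly chosen screen nodes — these become the
    degree-1 imported nodes that anchored clusters are built from. Noise
    edges connect random screen-node pairs on a random channel.
    """
    if not 0.0 <= support_prob <= 1.0:
        raise ValueError("support_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, float, str]] = []

    ordered_pairs = sorted(truth.true_pairs)
    supported = rng.random(len(ordered_pairs)) < support_prob
    for (bait, prey), keep in zip(ordered_pairs, supported, strict=True):
        if keep:
            rows.append((bait, prey, float(np.round(rng.uniform(0.15, 1.0), 3)), "experimental"))

    screen_nodes = sorted(set(truth.baits) | set(truth.preys))
    if n_imported > 0:
        anchors = list(rng.choice(screen_nodes, size=min(n_anchors, len(screen_nodes)), replace=False))
        lo, hi = imported_score_range
        for k in range(1, n_imported + 1):
            anchor = anchors[int(rng.integers(len(anchors)))]
            rows.append((f"ext{k:02d}", anchor, float(np.round(rng.uniform(lo, hi), 3)), "experimental"))

    seen = {tuple(sorted((a, b))) + (ch,) for a, b, _, ch in rows}
    attempts = 0
    made = 0
    while made < noise_edges and attempts < 50 * max(noise_edges, 1):
        attempts += 1
        a, b = rng.choice(screen_nodes, size=2, replace=False)
        channel = "experimental" if rng.random() < 0.3 else "other"
        key = tuple(sorted((a, b))) + (channel,)
        if key in seen:
            continue
        seen.add(key)
        rows.append((str(a), str(b), float(np.round(rng.random(), 3)), channel))
        made += 1

    return pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)


def generate_annotations(
    nodes: Sequence[str],
    n_terms: int,
    planted_term: tuple[str, Iterable[str]] | None = None,
    background_rate: float = 0.05,
    term_rate: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Annotate nodes with opaque term labels.

    ``planted_term = (name, subset)`` annotates every node of ``subset`` plus
    background nodes at ``background_rate``; each of the ``n_terms`` other
    terms annotates every node independently at ``term_rate``.
    """
    rng = np.random.default_rng(seed)
    nodes = list(nodes)
    rows: list[tuple[str, str]] = []

    if planted_term is not None:
        name, subset = planted_term
        subset = set(subset)
        if not subset <= set(nodes):
            raise ValueError("planted-term subset must be a subset of nodes")
        hits = rng.random(len(nodes)) < background_rate
        for node, hit in zip(nodes, hits, strict=True):
            if node in subset or hit:
                rows.append((node, name))

    for t in range(1, n_terms + 1):
        term = f"term{t:02d}"
        hits = rng.random(len(nodes)) < term_rate
        for node, hit in zip(nodes, hits, strict=True):
            if hit:
                rows.append((node, term))

    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def generate_footprint_reads(
    gene_length: int,
    annotated_start: int,
    true_start: int,
    depth: int,
    leak: float = 0.01,
    seed: int = 0,
    gene_id: str = "gene",
    read_length: int = 28,
) -> pd.DataFrame:
    """Simulate ribosome-footprint read positions over one gene.

    Reads start uniformly downstream of ``true_start`` except for a fraction
    ``leak`` scattered uniformly over the whole region (background from
    neighboring features and mapping noise). Coordinates are 0-based
    half-open; only start positions matter downstream.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not 0 <= annotated_start <= true_start < gene_length:
        raise ValueError("require 0 <= annotated_start <= true_start < gene_length")
    if not 0.0 <= leak <= 1.0:
        raise ValueError("leak must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_leak = int(rng.binomial(depth, leak)) if depth > 0 else 0
    leak_starts = rng.integers(0, gene_length, size=n_leak)
    signal_starts = rng.integers(true_start, gene_length, size=depth - n_leak)
    starts = np.concatenate([leak_starts, signal_starts]).astype(int)
    df = pd.DataFrame(
        {
            "chrom": gene_id,
            "start": starts,
            "end": np.minimum(starts + read_length, gene_length),
            "name": [f"read{i:06d}" for i in range(len(starts))],
            "score": 0,
            "strand": "+",
        }
    )
    return df[BED_COLUMNS]
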