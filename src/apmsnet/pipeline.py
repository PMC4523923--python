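"""End-to-end orchestration: simulate → score → sweep → network → cluster → startsite.

A single YAML-able configuration dictionary drives every stage. All
randomness flows from one root seed through named per-stage substreams
(``numpy.random.SeedSequence``), so identical config + seed yields
byte-identical outputs and any stage can be re-run from its on-disk inputs.
Each run emits a JSON manifest listing stage parameters and the SHA-256
digest of every output file.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import enrichment, network, robustness, scoring, startsite, synthetic_data
from .io import read_bed, read_table, sha256_file, write_bed, write_table

logger = logging.getLogger("apmsnet")

STAGES = ("simulate", "score", "sweep", "network", "cluster", "startsite")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "synth": {
        "n_baits": 8,
        "n_preys": 200,
        "n_controls": 4,
        "n_replicates": 4,
        "background_rate": 2.0,
        "enrichment": 10.0,
        "planted_density": 0.05,
    },
    "evidence": {
        "support_prob": 0.6,
        "noise_edges": 30,
        "n_imported": 12,
        "n_anchors": 3,
    },
    "annotations": {
        "n_terms": 20,
        "planted_term": "term_planted",
        "background_rate": 0.05,
        "term_rate": 0.15,
    },
    "footprint": {
        "gene_id": "LTO1like",
        "gene_length": 900,
        "annotated_start": 0,
        "true_start": 108,
        "candidate_starts": [0, 108],
        "depth": 5000,
        "leak": 0.01,
    },
    "scoring": {
        "id_score_min": 10.0,
        "normalize": False,
        "cap_high_counts": False,
        "prior_true": 0.1,
        "pseudocount": 0.5,
        "cap_quantile": 0.95,
        "min_enrichment": 2.0,
    },
    "grid": {
        "tau_lo": 0.8,
        "tau_hi": 0.95,
        "tau_step": 0.01,
        "m_values": [10, 20, 30, 40, 50],
        "include_cap_axis": True,
        "include_norm_axis": True,
    },
    "network": {"min_external_score": 0.9, "allow_chaining": False},
    "enrichment": {},
    "startsite": {"window": 30, "ratio_min": 5.0},
}


def _deep_update(base: dict, overrides: dict) -> dict:
    for key, value in overrides.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge defaults, an optional YAML file and programmatic overrides."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            _deep_update(config, yaml.safe_load(fh) or {})
    if overrides:
        _deep_update(config, overrides)
    return config


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2**31)."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31))


def _scoring_options(cfg: dict, **over) -> scoring.ScoringOptions:
    params = {**cfg["scoring"], **over}
    return scoring.ScoringOptions(
        normalize=bool(params["normalize"]),
        cap_high_counts=bool(params["cap_high_counts"]),
        id_score_min=float(params["id_score_min"]),
        prior_true=float(params["prior_true"]),
        pseudocount=float(params["pseudocount"]),
        cap_quantile=float(params["cap_quantile"]),
        min_enrichment=float(params["min_enrichment"]),
    )


def _grid(cfg: dict) -> robustness.ParameterGrid:
    g = cfg["grid"]
    return robustness.build_parameter_grid(
        tau_range=(g["tau_lo"], g["tau_hi"], g["tau_step"]),
        m_set=g["m_values"],
        include_cap_axis=g["include_cap_axis"],
        include_norm_axis=g["include_norm_axis"],
    )


def run_simulate(cfg: dict, outdir: Path) -> dict[str, Path]:
    seed = stage_seed(cfg["seed"], "simulate")
    synth = synthetic_data.SynthConfig(seed=seed, **cfg["synth"])
    table, controls, truth = synthetic_data.generate_apms_dataset(synth)
    meta = {"seed": seed}
    outputs = {
        "spectral_counts": write_table(table, outdir / "spectral_counts.tsv", meta),
        "controls": write_table(controls, outdir / "controls.tsv", meta),
    }

    ev_cfg = cfg["evidence"]
    evidence = synthetic_data.generate_evidence_table(
        truth,
        support_prob=ev_cfg["support_prob"],
        noise_edges=ev_cfg["noise_edges"],
        n_imported=ev_cfg["n_imported"],
        n_anchors=ev_cfg["n_anchors"],
        seed=seed + 1,
    )
    outputs["evidence"] = write_table(evidence, outdir / "evidence.tsv", {"seed": seed + 1})

    # plant the annotation term on the imported nodes of the best-populated anchor
    ext = evidence[evidence["node_a"].str.startswith("ext")]
    planted_subset: list[str] = []
    if not ext.empty:
        anchor = ext["node_b"].value_counts().idxmax()
        planted_subset = sorted(ext.loc[ext["node_b"] == anchor, "node_a"])
    nodes = sorted(
        set(truth.baits) | set(truth.preys) | set(evidence["node_a"]) | set(evidence["node_b"])
    )
    ann_cfg = cfg["annotations"]
    annotations = synthetic_data.generate_annotations(
        nodes,
        n_terms=ann_cfg["n_terms"],
        planted_term=(ann_cfg["planted_term"], planted_subset) if planted_subset else None,
        background_rate=ann_cfg["background_rate"],
        term_rate=ann_cfg["term_rate"],
        seed=seed + 2,
    )
    outputs["annotations"] = write_table(annotations, outdir / "annotations.tsv", {"seed": seed + 2})

    fp = cfg["footprint"]
    reads = synthetic_data.generate_footprint_reads(
        gene_length=fp["gene_length"],
        annotated_start=fp["annotated_start"],
        true_start=fp["true_start"],
        depth=fp["depth"],
        leak=fp["leak"],
        seed=seed + 3,
        gene_id=fp["gene_id"],
    )
    outputs["footprints"] = write_bed(reads, outdir / "footprints.bed", {"seed": seed + 3})

    truth_record = {
        "seed": seed,
        "true_pairs": sorted(list(p) for p in truth.true_pairs),
        "planted_term_members": planted_subset,
        "true_start": fp["true_start"],
    }
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth_record, indent=1, sort_keys=True))
    outputs["truth"] = truth_path
    return outputs


def run_score(cfg: dict, outdir: Path) -> dict[str, Path]:
    table = read_table(outdir / "spectral_counts.tsv")
    controls = read_table(outdir / "controls.tsv")
    options = _scoring_options(cfg)
    scores = scoring.score_dataset(table, controls, options)
    return {
        "scores": write_table(
            scores, outdir / "scores.tsv", {"seed": cfg["seed"], "id_score_min": options.id_score_min}
        )
    }


def run_sweep_stage(cfg: dict, outdir: Path) -> dict[str, Path]:
    table = read_table(outdir / "spectral_counts.tsv")
    controls = read_table(outdir / "controls.tsv")
    grid = _grid(cfg)
    base = _scoring_options(cfg)
    sweep = robustness.run_sweep(table, controls, grid, base_options=base)
    records = robustness.classify_robustness(robustness.robustness_fraction(sweep))
    return {
        "robustness": write_table(
            records,
            outdir / "robustness.tsv",
            {"seed": cfg["seed"], "n_combinations": len(grid)},
        )
    }


def run_network_stage(cfg: dict, outdir: Path) -> dict[str, Path]:
    records = read_table(outdir / "robustness.tsv")
    evidence = read_table(outdir / "evidence.tsv")
    net = network.assemble_network(
        records,
        evidence,
        min_external_score=cfg["network"]["min_external_score"],
        allow_chaining=cfg["network"]["allow_chaining"],
    )
    return dict(network.write_network(net, outdir))


def run_cluster_stage(cfg: dict, outdir: Path, extra_clusters: str | Path | None = None) -> dict[str, Path]:
    net = network.read_network(outdir / "network.graphml")
    annotations = read_table(outdir / "annotations.tsv")
    clusters = enrichment.define_clusters(net)
    if extra_clusters is not None:
        extra = read_table(extra_clusters)
        for cid, group in extra.groupby("cluster"):
            clusters.append(
                enrichment.Cluster(
                    cluster_id=str(cid),
                    anchor=str(group["anchor"].iloc[0]),
                    members=sorted(group["member"].astype(str)),
                )
            )
    universe = set(annotations["node"].astype(str)) & set(net.nodes)
    result = enrichment.enrich_clusters(clusters, annotations, universe)
    return {"enrichment": write_table(result, outdir / "enrichment.tsv", {"seed": cfg["seed"]})}


def run_startsite_stage(cfg: dict, outdir: Path) -> dict[str, Path]:
    reads = read_bed(outdir / "footprints.bed")
    fp, ss_cfg = cfg["footprint"], cfg["startsite"]
    track = startsite.bin_reads(
        reads,
        gene_length=fp["gene_length"],
        window=ss_cfg["window"],
        gene_id=fp["gene_id"],
        candidate_starts=fp["candidate_starts"],
        annotated_start=fp["annotated_start"],
    )
    call = startsite.call_start_codon(track, ratio_min=ss_cfg["ratio_min"])
    result = pd.DataFrame(
        [
            {
                "gene": call.gene_id,
                "chosen_start": call.chosen_start,
                "offset": call.offset,
                "ratio": round(call.ratio, 4) if call.ratio == call.ratio else "",
                "annotated_supported": call.annotated_supported,
            }
        ]
    )
    return {
        "start_site": write_table(result, outdir / "start_site.tsv", {"seed": cfg["seed"]}),
        "profile": write_table(
            startsite.profile_table(track), outdir / "footprint_profile.tsv", {"seed": cfg["seed"]}
        ),
    }


_STAGE_RUNNERS = {
    "simulate": run_simulate,
    "score": run_score,
    "sweep": run_sweep_stage,
    "network": run_network_stage,
    "cluster": run_cluster_stage,
    "startsite": run_startsite_stage,
}


def run_all(config: dict, outdir: str | Path) -> dict:
    """Run every stage in order; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config["seed"], "stages": []}
    for stage in STAGES:
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_RUNNERS[stage](config, outdir)
        except Exception as exc:  # pragma: no cover - error path
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        elapsed = time.perf_counter() - t0
        logger.info("stage %-9s done in %.2fs", stage, elapsed)
        manifest["stages"].append(
            {
                "name": stage,
                "outputs": {
                    name: {"path": path.name, "sha256": sha256_file(path)}
                    for name, path in sorted(outputs.items())
                },
            }
        )
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
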