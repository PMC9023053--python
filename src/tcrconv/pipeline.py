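"""End-to-end pipeline: prep -> alice -> cluster -> annotate -> stats -> expand.

Configured by a YAML file; every stage writes TSV outputs into the run
directory, and a manifest records the config hash, per-stage seeds, and the
package version so any run can be reproduced byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import __version__
from .alice_stat import (
    DEFAULT_ALPHA,
    DEFAULT_N_BATCHES,
    DEFAULT_N_SIM,
    normalized_hits,
    run_alice,
)
from .annotation import (
    cumulative_specific_frequency,
    match_clonotype,
    propagate_cluster_specificity,
    read_specificity_db,
)
from .cluster_graph import build_graph, export_gml, extract_clusters, hits_plus_neighbors
from .expansion import DEFAULT_FDR, DEFAULT_LFC, call_expanded, nb_exact_test
from .generative_model import RecombinationModel, SimulationCache
from .repertoire_io import (
    Repertoire,
    downsample,
    read_repertoire,
    remove_singletons,
    write_repertoire,
)
from .repertoire_stats import clonality, subset_match_count

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed and the stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with the analysis's default thresholds."""

    samples: List[dict]  # each: {path, sample_id?, subset?}
    model_path: str
    out_dir: str
    db_path: Optional[str] = None
    patient_hla: Optional[List[str]] = None
    counts_path: Optional[str] = None
    design_path: Optional[str] = None
    focal_condition: Optional[str] = None
    alpha: float = DEFAULT_ALPHA
    n_sim: int = DEFAULT_N_SIM
    n_batches: int = DEFAULT_N_BATCHES
    q_factor: float = 1.0
    seed: int = 0
    remove_singletons: bool = True
    downsample_to: Optional[int] = None
    min_cluster_size: int = 2
    node_set: str = "hits+neighbors"  # or "all"
    majority_threshold: float = 0.5
    central_lo: int = 4
    central_hi_offset: int = 3
    fdr: float = DEFAULT_FDR
    lfc: float = DEFAULT_LFC

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if not cfg.samples:
            raise ValueError("config must list at least one sample")
        if not cfg.model_path:
            raise ValueError("config missing model_path")
        for s in cfg.samples:
            if "path" not in s:
                raise ValueError("each sample entry needs a 'path'")
        if cfg.node_set not in ("hits+neighbors", "all"):
            raise ValueError(f"unknown node_set {cfg.node_set!r}")
        return cfg

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}


def _key_str(key) -> str:
    return "|".join(key)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    model = RecombinationModel.from_yaml(config.model_path)
    db = read_specificity_db(config.db_path) if config.db_path else None

    cache = SimulationCache(
        model,
        max(1, config.n_sim // config.n_batches) * config.n_batches,
        config.n_batches,
        stage_seed(config.seed, "alice"),
    )

    summary_rows = []
    per_sample: Dict[str, dict] = {}
    for entry in config.samples:
        stage = "prep"
        try:
            rep = read_repertoire(entry["path"])
            rep.sample_id = entry.get("sample_id", rep.sample_id)
            rep.metadata["subset"] = entry.get("subset", "")
            n_input = len(rep.aggregated())
            if config.downsample_to is not None:
                rep = downsample(
                    rep, config.downsample_to, stage_seed(config.seed, f"prep:{rep.sample_id}")
                )
            prepped = remove_singletons(rep.aggregated()) if config.remove_singletons else rep.aggregated()
            write_repertoire(prepped, out / f"{rep.sample_id}.prepped.tsv")

            stage = "alice"
            results = run_alice(
                rep.aggregated(),
                model,
                alpha=config.alpha,
                n_sim=config.n_sim,
                n_batches=config.n_batches,
                q_factor=config.q_factor,
                sim_cache=cache,
            )
            hits = {r.key for r in results if r.is_hit}
            _write_alice_tsv(results, out / f"{rep.sample_id}.alice.tsv")

            stage = "cluster"
            if config.node_set == "all":
                node_keys = set(prepped.keys())
            else:
                node_keys = hits_plus_neighbors(prepped, hits)
            node_clonotypes = [c for c in prepped.clonotypes if c.key in node_keys]
            graph = build_graph(node_clonotypes, sample_id=rep.sample_id, hit_keys=hits)
            clusters = extract_clusters(graph, min_size=config.min_cluster_size)

            stage = "annotate"
            cluster_labels: Dict[str, str] = {}
            labeled_keys = set()
            if db is not None:
                matches = {}
                for c in node_clonotypes:
                    found = match_clonotype(
                        c,
                        db,
                        patient_hla=config.patient_hla,
                        central_lo=config.central_lo,
                        central_hi_offset=config.central_hi_offset,
                    )
                    if found:
                        matches[c.key] = found
                for cid, members in clusters.clusters.items():
                    member_keys = [tuple(n[:3]) for n in members]
                    label = propagate_cluster_specificity(
                        member_keys, matches, config.majority_threshold
                    )
                    cluster_labels[cid] = label
                    if label != "unassigned":
                        labeled_keys.update(member_keys)
                for node in graph.nodes:
                    for cid, members in clusters.clusters.items():
                        if node in members and cluster_labels[cid] != "unassigned":
                            graph.nodes[node]["specificity"] = cluster_labels[cid]
            export_gml(graph, out / f"{rep.sample_id}.clusters.gml")
            _write_cluster_tsv(clusters, cluster_labels, out / f"{rep.sample_id}.clusters.tsv")

            stage = "stats"
            div = clonality(prepped) if len(prepped) else None
            cluster_member_keys = {
                tuple(n[:3]) for members in clusters.clusters.values() for n in members
            }
            taa_bulk = cumulative_specific_frequency(prepped, labeled_keys, "bulk")
            taa_cluster = cumulative_specific_frequency(
                prepped, labeled_keys, "cluster_related", cluster_member_keys
            )
            row = {
                "sample": rep.sample_id,
                "subset": rep.metadata.get("subset", ""),
                "n_input_clonotypes": n_input,
                "n_after_prep": len(prepped),
                "n_hits": len(hits),
                "normalized_hits": normalized_hits(results, n_input),
                "n_clusters": len(clusters.clusters),
                "cluster_weight_total": sum(clusters.weights.values()),
                "taa_freq_bulk": taa_bulk,
                "taa_freq_cluster_related": taa_cluster,
                "clonality": div.clonality if div else float("nan"),
            }
            summary_rows.append(row)
            per_sample[rep.sample_id] = {
                "repertoire": prepped,
                "hits": hits,
                "clusters": clusters,
            }
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage {stage!r} failed for input {entry['path']}: {exc}"
            ) from exc

    expansion_summary = {}
    if config.counts_path and config.design_path:
        try:
            counts = pd.read_csv(config.counts_path, sep="\t", index_col=0)
            design_df = pd.read_csv(config.design_path, sep="\t")
            design = dict(zip(design_df["sample"], design_df["condition"]))
            results = nb_exact_test(
                counts,
                design,
                focal_condition=config.focal_condition,
                fdr=config.fdr,
                lfc=config.lfc,
            )
            expanded = sorted(call_expanded(results, config.fdr, config.lfc))
            _write_expansion_tsv(results, out / "expansion.tsv")
            expansion_summary["n_expanded"] = len(expanded)
            expanded_keys = [tuple(k.split("|")) for k in expanded]
            for sid, data in per_sample.items():
                expansion_summary[f"expanded_matched_{sid}"] = subset_match_count(
                    expanded_keys, data["repertoire"]
                )
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage 'expand' failed for input {config.counts_path}: {exc}"
            ) from exc

    summary = pd.DataFrame(summary_rows)
    for k, v in sorted(expansion_summary.items()):
        summary[k] = v
    summary.to_csv(out / "summary.tsv", sep="\t", index=False, float_format="%.9g")

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stage_seeds": {
            s: stage_seed(config.seed, s) for s in ("prep", "alice", "simulate")
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return out


def _write_alice_tsv(results, path) -> None:
    rows = []
    for r in results:
        rows.append(
            {
                "cdr3aa": r.key[0],
                "v": r.key[1],
                "j": r.key[2],
                "d_obs": r.d_obs,
                "ball_pgen": r.ball_pgen.point if r.ball_pgen else 0.0,
                "lambda": r.lambda_expected,
                "p": r.p_value,
                "q": r.q_value,
                "hit": int(r.is_hit),
            }
        )
    pd.DataFrame(
        rows,
        columns=["cdr3aa", "v", "j", "d_obs", "ball_pgen", "lambda", "p", "q", "hit"],
    ).to_csv(path, sep="\t", index=False, float_format="%.9g")


def _write_cluster_tsv(clusters, labels, path) -> None:
    rows = []
    for cid, members in sorted(clusters.clusters.items()):
        for node in members:
            rows.append(
                {
                    "cluster_id": cid,
                    "cdr3aa": node[0],
                    "v": node[1],
                    "j": node[2],
                    "sample": node[3],
                    "freq": clusters.graph.nodes[node].get("freq", 0.0),
                    "specificity": labels.get(cid, ""),
                }
            )
    pd.DataFrame(
        rows,
        columns=["cluster_id", "cdr3aa", "v", "j", "sample", "freq", "specificity"],
    ).to_csv(path, sep="\t", index=False, float_format="%.9g")


def _write_expansion_tsv(results, path) -> None:
    pd.DataFrame(
        [
            {
                "key": r.key,
                "log2fc": r.log2fc,
                "p": r.p_value,
                "q": r.q_value,
                "called": int(r.called),
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.9g")
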