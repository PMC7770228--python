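"""End-to-end orchestration: one config in, a directory of artifacts out.

``run_pipeline`` reads (or simulates) an expression tensor, builds both the
variability and averaged time course networks, detects modules, computes
module summaries and the network overlap, and serializes everything —
including the config itself and a manifest of artifact checksums — so every
reported number is recomputable from the run directory alone. ``report``
renders a human-readable summary from those artifacts and re-verifies the
checksums.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analytics, communities, io_formats, networks
from .errors import SchemaError, StageError
from .types import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "report"]

VERSION = "0.1.0"


@dataclass
class RunConfig:
    """Every parameter of every stage, serializable to/from YAML."""

    expression: str = ""
    metadata: str = ""
    hvg: str | None = None
    gene_sets: str | None = None

    fdr: float = 0.10
    k: int = 4
    gaps: int = 1
    circular: bool = False
    positive_only: bool = False
    min_joint_obs: int = 8
    exact_n_max: int = 9

    alpha: float = 0.05  # Bonferroni family-wise level, averaged route

    seed: int = 0
    restarts: int = 10
    resolution: float = 1.0

    day_start: int = 0
    day_end: int = 12
    min_module_size: int = 5

    version: str = VERSION

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        data.pop("version", None)
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every stage and write all artifacts into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"version": VERSION}

    try:
        tensor = io_formats.read_expression(config.expression, config.metadata)
    except SchemaError:
        raise
    except Exception as e:  # noqa: BLE001 - annotate stage
        raise StageError(f"stage read_expression failed: {e}") from e
    log["n_genes_input"] = tensor.n_genes
    log["n_timepoints"] = tensor.n_timepoints
    log["n_individuals"] = tensor.n_individuals

    hvg = io_formats.read_gene_list(config.hvg) if config.hvg else None
    gene_sets = (
        io_formats.read_gmt(config.gene_sets) if config.gene_sets else None
    )

    # -- variability route -------------------------------------------------
    try:
        tp_sets = networks.per_timepoint_networks(
            tensor, config.fdr, None, config.min_joint_obs,
            config.exact_n_max, config.positive_only,
        )
        var_net = networks.build_variability_network(
            tensor, config.fdr, config.k, config.gaps, config.circular,
            min_joint_obs=config.min_joint_obs,
            exact_n_max=config.exact_n_max,
            positive_only=config.positive_only,
            timepoint_sets=tp_sets,
        )
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage variability_network failed: {e}") from e
    log["per_timepoint"] = [
        {"zt": es.timepoint_zt, "m_tested": es.n_tested,
         "n_selected": len(es)} for es in tp_sets
    ]
    log["variability_edges"] = var_net.n_edges
    log["variability_genes"] = var_net.n_genes

    # -- averaged route ----------------------------------------------------
    try:
        avg_net = networks.build_averaged_network(
            tensor, config.alpha, config.exact_n_max, config.positive_only
        )
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage averaged_network failed: {e}") from e
    log["averaged_edges"] = avg_net.n_edges
    log["averaged_genes"] = avg_net.n_genes
    log["overlap"] = networks.network_overlap(var_net, avg_net)

    # -- modules -----------------------------------------------------------
    try:
        partition = communities.louvain_partition(
            var_net, seed=config.stage_seed("louvain"),
            resolution=config.resolution, restarts=config.restarts,
        )
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage louvain failed: {e}") from e
    log["n_modules"] = partition.n_modules
    log["modularity"] = partition.modularity
    log["n_modules_min_size"] = sum(
        1 for s in partition.sizes().values() if s >= config.min_module_size
    )

    # -- analytics ---------------------------------------------------------
    day_window = (config.day_start, config.day_end)
    summaries = analytics.module_summaries(
        var_net, partition, hvg=hvg, gene_sets=gene_sets,
        averaged_net=avg_net, day_window=day_window,
        min_size=config.min_module_size,
    ) if partition.n_modules else pd.DataFrame()

    # consistency audit: intra-module detections never exceed network totals
    etd = analytics.edge_time_distribution(var_net, partition)
    totals = var_net.per_timepoint_edge_counts()
    intra = np.zeros_like(totals)
    for v in etd.values():
        intra += v
    if (intra > totals).any():
        raise StageError("audit failed: intra-module detections exceed totals")

    # -- write artifacts ---------------------------------------------------
    io_formats.write_network(
        var_net, out / "variability_edges.tsv", out / "variability.graphml"
    )
    io_formats.write_network(
        avg_net, out / "averaged_edges.tsv", out / "averaged.graphml"
    )
    io_formats.write_partition(partition, out / "modules.tsv")
    pd.DataFrame(
        {"zt": var_net.timepoints_zt, "n_edges_detected": totals}
    ).to_csv(out / "edge_counts_per_timepoint.tsv", sep="\t", index=False)
    if not summaries.empty:
        summaries.to_csv(out / "module_summary.tsv", sep="\t")
    else:
        (out / "module_summary.tsv").write_text("module_id\tsize\n")
    config.to_yaml(out / "config.yaml")
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=float)

    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.name not in ("manifest.json",) and p.is_file()
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("pipeline complete: %s", out)
    return out


def _require(path: Path) -> Path:
    if not path.exists():
        raise StageError(f"missing artifact: {path.name}")
    return path


def report(run_dir: str | Path) -> str:
    """Human-readable summary recomputed from a run directory's artifacts.

    Verifies the checksum manifest first, so a tampered artifact fails
    loudly instead of producing a silently inconsistent report.
    """
    run = Path(run_dir)
    manifest = json.loads(_require(run / "manifest.json").read_text())
    for name, digest in manifest.items():
        p = _require(run / name)
        if _sha256(p) != digest:
            raise StageError(f"artifact {name} does not match its checksum")

    log = json.loads(_require(run / "run_log.json").read_text())
    edges = pd.read_csv(_require(run / "variability_edges.tsv"), sep="\t")
    modules = pd.read_csv(_require(run / "modules.tsv"), sep="\t")
    if len(edges) != log["variability_edges"]:
        raise StageError("edge file row count disagrees with run log")

    lines = [
        "variability network run summary",
        "===============================",
        f"genes in input            : {log['n_genes_input']}",
        f"timepoints x individuals  : "
        f"{log['n_timepoints']} x {log['n_individuals']}",
        f"variability network       : {log['variability_edges']} edges, "
        f"{log['variability_genes']} genes",
        f"averaged network          : {log['averaged_edges']} edges, "
        f"{log['averaged_genes']} genes",
        f"shared genes / edges      : {log['overlap']['shared_genes']} / "
        f"{log['overlap']['shared_edges']}",
        f"modules (total)           : {log['n_modules']}"
        + (f", modularity {log['modularity']:.4f}"
           if log["n_modules"] else ""),
        f"modules >= min size       : {log['n_modules_min_size']}",
    ]
    summary_path = run / "module_summary.tsv"
    if summary_path.exists():
        try:
            summary = pd.read_csv(summary_path, sep="\t")
        except pd.errors.EmptyDataError:
            summary = pd.DataFrame()
        if len(summary):
            lines.append("")
            lines.append("module summary (>= min size):")
            lines.append(summary.to_string(index=False))
    per_tp = log.get("per_timepoint", [])
    if per_tp:
        lines.append("")
        lines.append("per-timepoint BH selections (before persistence):")
        for rec in per_tp:
            lines.append(
                f"  ZT{rec['zt']:>2}: m={rec['m_tested']}, "
                f"selected={rec['n_selected']}"
            )
    return "\n".join(lines)
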