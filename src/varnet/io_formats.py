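"""Readers and writers for every on-disk artifact the pipeline touches.

Formats are deliberately plain: TSV for matrices, metadata, edge lists and
partitions; GMT for gene sets; GraphML for networks; YAML for configuration.
Edge rows are written with gene pairs in canonical (lexicographic) order and
sorted, so edge files are byte-stable across runs on identical input.
"""
from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

from .errors import SchemaError
from .types import (
    CoexpressionNetwork,
    EdgeSupport,
    ExpressionTensor,
    GeneSetCollection,
    ModulePartition,
    SampleMetadata,
    canonical_pair,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_metadata",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "write_network",
    "read_network",
    "write_partition",
    "read_partition",
]

_META_COLUMNS = ["sample_id", "timepoint_zt", "individual"]


def read_metadata(metadata_path: str | Path) -> list[SampleMetadata]:
    """Read the sample metadata table (sample_id, timepoint_zt, individual)."""
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise SchemaError(f"metadata missing columns: {missing}")
    records = [
        SampleMetadata(row.sample_id, int(row.timepoint_zt), int(row.individual))
        for row in meta.itertuples()
    ]
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise SchemaError("duplicate sample_id in metadata")
    slots = [(r.timepoint_zt, r.individual_index) for r in records]
    if len(set(slots)) != len(slots):
        raise SchemaError("duplicate (timepoint_zt, individual) pair in metadata")
    return records


def read_expression(
    matrix_path: str | Path, metadata_path: str | Path
) -> ExpressionTensor:
    """Read a genes-x-samples TSV matrix plus metadata into a tensor.

    Genes keep file order. Every sample column must appear in the metadata;
    empty cells become NaN (absent, not zero). Samples missing for a
    (timepoint, individual) slot are NaN throughout.
    """
    records = read_metadata(metadata_path)
    by_sample = {r.sample_id: r for r in records}

    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    mat.index = mat.index.astype(str)
    if mat.index.duplicated().any():
        dups = mat.index[mat.index.duplicated()].unique().tolist()
        raise SchemaError(f"duplicate gene IDs in matrix: {dups[:5]}")
    unknown = [s for s in mat.columns if s not in by_sample]
    if unknown:
        raise SchemaError(f"matrix samples absent from metadata: {unknown[:5]}")

    timepoints = sorted({r.timepoint_zt for r in records})
    individuals = sorted({r.individual_index for r in records})
    tp_idx = {t: i for i, t in enumerate(timepoints)}
    ind_idx = {i: j for j, i in enumerate(individuals)}

    values = np.full((mat.shape[0], len(timepoints), len(individuals)), np.nan)
    for sample in mat.columns:
        r = by_sample[sample]
        values[:, tp_idx[r.timepoint_zt], ind_idx[r.individual_index]] = (
            mat[sample].to_numpy(dtype=float)
        )
    return ExpressionTensor(values, list(mat.index), timepoints)


def write_expression(
    tensor: ExpressionTensor, matrix_path: str | Path, metadata_path: str | Path
) -> None:
    """Write a tensor back to the matrix + metadata TSV pair.

    Sample ids are synthesized as ``ZT<t>_<i>``; slots that are entirely NaN
    are still written (as empty cells) so the round-trip preserves shape.
    """
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for ti, t in enumerate(tensor.timepoints_zt):
        for ii in range(tensor.n_individuals):
            sid = f"ZT{t}_{ii + 1}"
            columns[sid] = tensor.values[:, ti, ii]
            meta_rows.append({"sample_id": sid, "timepoint_zt": t,
                              "individual": ii + 1})
    df = pd.DataFrame(columns, index=tensor.gene_ids)
    df.index.name = "gene_id"
    df.to_csv(matrix_path, sep="\t", na_rep="")
    pd.DataFrame(meta_rows).to_csv(metadata_path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB gene...).

    Duplicate genes within a line are dropped with a logged warning; a line
    with fewer than three fields is a parse error naming the line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(
                    f"{path}: line {lineno}: GMT line needs >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name = fields[0]
            genes: list[str] = []
            seen: set[str] = set()
            dup = 0
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    dup += 1
                    continue
                seen.add(g)
                genes.append(g)
            if dup:
                logger.warning(
                    "GMT set %r (line %d): dropped %d duplicate gene(s)",
                    name, lineno, dup,
                )
            sets[name] = genes
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, ""] + list(genes)) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene ID per line (HVG lists, universes)."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# networks


def _fmt_float(x: float) -> str:
    return "nan" if math.isnan(x) else format(x, ".10g")


def write_network(
    net: CoexpressionNetwork,
    edge_path: str | Path | None = None,
    graphml_path: str | Path | None = None,
) -> None:
    """Write a network as an edge-list TSV and/or GraphML.

    TSV columns: gene_a, gene_b, n_support, support_zt (comma-joined ZT
    hours), mean_rho. Rows are sorted on the canonical pair so output is
    byte-stable. GraphML carries the same attributes (vectors serialized as
    comma-joined strings) plus the timepoint grid and provenance.
    """
    tps = net.timepoints_zt
    rows = []
    for a, b in sorted(net.edge_pairs()):
        d = net.graph.edges[a, b]
        mask = d.get("support")
        if mask is not None:
            zts = ",".join(str(tps[i]) for i in np.flatnonzero(mask))
            n_support = int(mask.sum())
        else:
            zts, n_support = "", 0
        rows.append((a, b, n_support, zts, d.get("mean_rho", np.nan)))

    if edge_path is not None:
        with open(edge_path, "w") as fh:
            fh.write("gene_a\tgene_b\tn_support\tsupport_zt\tmean_rho\n")
            for a, b, n, zts, rho in rows:
                fh.write(f"{a}\t{b}\t{n}\t{zts}\t{_fmt_float(rho)}\n")

    if graphml_path is not None:
        g = nx.Graph()
        g.graph["timepoints_zt"] = ",".join(str(t) for t in tps)
        for key, val in net.provenance.items():
            g.graph[f"prov_{key}"] = str(val)
        g.add_nodes_from(net.graph.nodes)
        for a, b in sorted(net.edge_pairs()):
            d = net.graph.edges[a, b]
            attrs = {"mean_rho": float(d.get("mean_rho", np.nan))}
            mask = d.get("support")
            if mask is not None:
                attrs["support"] = ",".join("1" if m else "0" for m in mask)
                attrs["rho_by_tp"] = ",".join(_fmt_float(r) for r in d["rho"])
                attrs["n_support"] = int(mask.sum())
            if "p" in d:
                attrs["p"] = float(d["p"])
            g.add_edge(a, b, **attrs)
        nx.write_graphml(g, graphml_path)


def read_network(graphml_path: str | Path) -> CoexpressionNetwork:
    """Reconstruct a network written by :func:`write_network`."""
    g = nx.read_graphml(graphml_path)
    tp_str = g.graph.get("timepoints_zt", "")
    tps = [int(t) for t in tp_str.split(",") if t != ""]
    provenance = {
        k[len("prov_"):]: v for k, v in g.graph.items() if k.startswith("prov_")
    }
    net = CoexpressionNetwork(tps, provenance)
    net.graph.add_nodes_from(g.nodes)
    for a, b, d in g.edges(data=True):
        a, b = canonical_pair(a, b)
        attrs = {}
        if "p" in d:
            attrs["p"] = float(d["p"])
        if "support" in d:
            mask = np.array([c == "1" for c in d["support"].split(",")])
            rho = np.array([float(x) for x in d["rho_by_tp"].split(",")])
            net.add_edge(a, b, EdgeSupport((a, b), mask, rho),
                         mean_rho=float(d.get("mean_rho", np.nan)), **attrs)
        else:
            net.add_edge(a, b, mean_rho=float(d.get("mean_rho", np.nan)), **attrs)
    return net


def write_partition(partition: ModulePartition, path: str | Path) -> None:
    """Partition TSV: gene_id, module_id (sorted by gene)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tmodule_id\n")
        for gene in sorted(partition.assignment):
            fh.write(f"{gene}\t{partition.assignment[gene]}\n")


def read_partition(path: str | Path) -> ModulePartition:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "module_id": int})
    if list(df.columns) != ["gene_id", "module_id"]:
        raise SchemaError(f"{path}: expected columns gene_id, module_id")
    assignment = dict(zip(df.gene_id, df.module_id))
    return ModulePartition(assignment, modularity=float("nan"), seed=-1)
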