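"""Module-level analytics on an inferred co-expression network.

Covers: per-module distributions of edge detections over the day/night
cycle, night-edge percentages, highly-variable-gene (HVG) content and
Fisher gene-set enrichment, per-module overlap with the averaged time
course network, the module meta-graph, attribute assortativity on that
graph, and z-scored mean expression profiles for plotting.

Conventions: an edge "detected at" a timepoint means its support mask is
true there, so one edge can contribute several detections; day is the ZT
interval ``[day_start, day_end)`` (default [0, 12), lights on at ZT0).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .types import CoexpressionNetwork, GeneSetCollection, ModulePartition

logger = logging.getLogger(__name__)

__all__ = [
    "edge_time_distribution",
    "night_edge_percentage",
    "night_edge_percentage_by_edge",
    "set_enrichment",
    "EnrichmentResult",
    "averaged_overlap_per_module",
    "build_module_graph",
    "assortativity_pearson",
    "zscore_profiles",
    "module_summaries",
]


def edge_time_distribution(
    net: CoexpressionNetwork, partition: ModulePartition
) -> dict[int, np.ndarray]:
    """Per-module counts of intra-module edge detections at each timepoint.

    For module m and timepoint slot t: the number of edges with both
    endpoints in m whose support mask is true at t.
    """
    t = len(net.timepoints_zt)
    counts: dict[int, np.ndarray] = {
        m: np.zeros(t, dtype=int) for m in partition.module_ids()
    }
    for a, b, d in net.graph.edges(data=True):
        ma = partition.assignment.get(a)
        mb = partition.assignment.get(b)
        if ma is None or ma != mb:
            continue
        mask = d.get("support")
        if mask is not None:
            counts[ma] += mask.astype(int)
    return counts


def night_edge_percentage(
    edge_time_counts: np.ndarray,
    timepoints_zt,
    day_window: tuple[int, int] = (0, 12),
) -> float | None:
    """Percentage of edge detections falling in the night timepoints.

    Night is every ZT hour outside ``[day_start, day_end)``. Returns None
    (flagged, not computed) when the module has no detections at all.
    """
    counts = np.asarray(edge_time_counts)
    total = counts.sum()
    if total == 0:
        logger.warning("night_edge_percentage undefined: no edge detections")
        return None
    day_start, day_end = day_window
    night = np.array(
        [not (day_start <= zt < day_end) for zt in timepoints_zt]
    )
    return float(100.0 * counts[night].sum() / total)


def night_edge_percentage_by_edge(
    net: CoexpressionNetwork,
    partition: ModulePartition,
    module_id: int,
    day_window: tuple[int, int] = (0, 12),
) -> float | None:
    """Alternative night convention: percentage of intra-module edges whose
    detections fall mostly at night (ties count as night).

    Contrast with :func:`night_edge_percentage`, which counts detections.
    """
    day_start, day_end = day_window
    night = np.array(
        [not (day_start <= zt < day_end) for zt in net.timepoints_zt]
    )
    n_edges = n_night = 0
    for a, b, d in net.graph.edges(data=True):
        if (partition.assignment.get(a) != module_id
                or partition.assignment.get(b) != module_id):
            continue
        mask = d.get("support")
        if mask is None or not mask.any():
            continue
        n_edges += 1
        if mask[night].sum() >= mask[~night].sum():
            n_night += 1
    if n_edges == 0:
        logger.warning("night_edge_percentage_by_edge undefined: no edges")
        return None
    return float(100.0 * n_night / n_edges)


@dataclass
class EnrichmentResult:
    """Fisher's exact test of a module against one gene set."""

    overlap: int
    module_size: int
    set_size: int  # within the background
    background_size: int
    odds_ratio: float  # Haldane-corrected when a cell is zero
    odds_ratio_raw: float  # may be inf/nan on zero cells
    p_two_sided: float
    p_enrich: float
    p_deplete: float
    table: tuple[tuple[int, int], tuple[int, int]] = field(repr=False, default=None)


def set_enrichment(
    module_genes, gene_set, background
) -> EnrichmentResult:
    """Fisher's exact test for over/under-representation of a gene set.

    The 2x2 table classifies the background universe by (in module) x
    (in set); the gene set is first intersected with the background. Both
    one-sided p-values and the two-sided p are reported. The odds ratio is
    Haldane-corrected (0.5 added to every cell) whenever a cell is zero;
    the uncorrected table and raw odds ratio are also returned.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background universe")
    module = set(module_genes) & bg
    gset = set(gene_set) & bg
    a = len(module & gset)
    b = len(module - gset)
    c = len(gset - module)
    d = len(bg) - a - b - c
    table = np.array([[a, b], [c, d]])
    raw_or, p_two = stats.fisher_exact(table, alternative="two-sided")
    _, p_enrich = stats.fisher_exact(table, alternative="greater")
    _, p_deplete = stats.fisher_exact(table, alternative="less")
    if (table == 0).any():
        t = table + 0.5
        odds = float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    else:
        odds = float(raw_or)
    return EnrichmentResult(
        overlap=a,
        module_size=len(module),
        set_size=len(gset),
        background_size=len(bg),
        odds_ratio=odds,
        odds_ratio_raw=float(raw_or),
        p_two_sided=float(p_two),
        p_enrich=float(p_enrich),
        p_deplete=float(p_deplete),
        table=((a, b), (c, d)),
    )


def permutation_enrichment_p(
    module_genes, gene_set, background, n_perm: int = 10_000, seed: int = 0
) -> float:
    """Label-permutation p for set over-representation (alternative to Fisher).

    Draws random modules of the same size from the background and reports
    the fraction with overlap >= observed (add-one corrected).
    """
    rng = np.random.default_rng(seed)
    bg = np.array(sorted(set(background)))
    module = set(module_genes) & set(bg)
    gset = set(gene_set) & set(bg)
    obs = len(module & gset)
    k = len(module)
    hits = 0
    for _ in range(n_perm):
        draw = rng.choice(bg, size=k, replace=False)
        if len(set(draw) & gset) >= obs:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def averaged_overlap_per_module(
    partition: ModulePartition, averaged_net: CoexpressionNetwork
) -> dict[int, tuple[int, float]]:
    """Per module: (count, percentage) of members present in the averaged net."""
    nodes = averaged_net.genes()
    out: dict[int, tuple[int, float]] = {}
    for m in partition.module_ids():
        members = partition.members(m)
        n = sum(1 for g in members if g in nodes)
        out[m] = (n, 100.0 * n / len(members))
    return out


def build_module_graph(
    net: CoexpressionNetwork,
    partition: ModulePartition,
    min_size: int = 5,
    hvg=None,
    day_window: tuple[int, int] = (0, 12),
) -> nx.Graph:
    """Meta-graph of modules with >= ``min_size`` genes.

    Edge weight = number of network edges whose endpoints lie in the two
    different modules. Node attributes: ``size``, ``pct_night_edges``
    (None when the module has no intra-module detections) and, when an HVG
    list is supplied, ``pct_hvg``.
    """
    sizes = partition.sizes()
    keep = {m for m, s in sizes.items() if s >= min_size}
    mg = nx.Graph()
    etd = edge_time_distribution(net, partition)
    hvg_set = set(hvg) if hvg is not None else None
    for m in sorted(keep):
        attrs = {
            "size": sizes[m],
            "pct_night_edges": night_edge_percentage(
                etd[m], net.timepoints_zt, day_window
            ),
        }
        if hvg_set is not None:
            members = partition.members(m)
            attrs["pct_hvg"] = 100.0 * sum(
                1 for g in members if g in hvg_set
            ) / len(members)
        mg.add_node(m, **attrs)
    for a, b in net.graph.edges:
        ma = partition.assignment.get(a)
        mb = partition.assignment.get(b)
        if ma is None or mb is None or ma == mb:
            continue
        if ma not in keep or mb not in keep:
            continue
        if mg.has_edge(ma, mb):
            mg.edges[ma, mb]["weight"] += 1
        else:
            mg.add_edge(ma, mb, weight=1)
    return mg


def assortativity_pearson(
    mg: nx.Graph, attribute: str
) -> tuple[float, float]:
    """Attribute assortativity of the module graph.

    Pearson correlation between endpoint attribute values over all
    connected module pairs, on orientation-symmetrized endpoint lists
    (each edge contributes both (u,v) and (v,u)), with a two-sided
    t-distribution p-value. Edges with a missing endpoint attribute are
    skipped; a constant attribute leaves the statistic undefined
    (returns (nan, nan) with a warning).
    """
    xs: list[float] = []
    ys: list[float] = []
    for u, v in mg.edges:
        au = mg.nodes[u].get(attribute)
        av = mg.nodes[v].get(attribute)
        if au is None or av is None:
            continue
        xs.extend([au, av])
        ys.extend([av, au])
    if len(xs) < 6:  # fewer than 3 usable edges
        raise ValueError("need >= 3 module-graph edges with the attribute")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        warnings.warn("assortativity undefined: constant attribute")
        return (float("nan"), float("nan"))
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p)


def zscore_profiles(
    tensor, partition: ModulePartition | None = None
) -> pd.DataFrame:
    """Per-gene z-scored mean time profiles (sample sd, ddof=1).

    Each gene's mean-over-individuals profile is centred and scaled to unit
    sample standard deviation across timepoints. Genes with constant
    profiles are flagged (warning) and omitted. When a partition is given a
    ``module`` column is appended (NaN for unassigned genes).
    """
    profiles = tensor.mean_profiles()
    sd = profiles.std(axis=1, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant profile(s) omitted from z-scoring"
        )
    keep = ~const & ~np.isnan(sd)
    z = (profiles[keep] - profiles[keep].mean(axis=1, keepdims=True)) / sd[
        keep, None
    ]
    genes = [g for g, k in zip(tensor.gene_ids, keep) if k]
    df = pd.DataFrame(z, index=genes, columns=tensor.timepoints_zt)
    df.index.name = "gene_id"
    if partition is not None:
        df["module"] = [partition.assignment.get(g, np.nan) for g in genes]
    return df


def module_summaries(
    net: CoexpressionNetwork,
    partition: ModulePartition,
    hvg=None,
    gene_sets: GeneSetCollection | None = None,
    averaged_net: CoexpressionNetwork | None = None,
    background=None,
    day_window: tuple[int, int] = (0, 12),
    min_size: int = 1,
    night_convention: str = "detections",
) -> pd.DataFrame:
    """One row per module: size, night-edge %, HVG content + enrichment,
    per-set Fisher enrichment, and averaged-network overlap.

    ``background`` defaults to all network genes (enrichment is relative to
    the network, not the transcriptome). ``night_convention`` is
    ``"detections"`` (count edge-timepoint detections) or ``"edges"``
    (per-edge majority vote).
    """
    if night_convention not in ("detections", "edges"):
        raise ValueError("night_convention must be 'detections' or 'edges'")
    etd = edge_time_distribution(net, partition)
    if background is None:
        background = net.genes()
    hvg_set = set(hvg) & set(background) if hvg is not None else None
    avg_overlap = (
        averaged_overlap_per_module(partition, averaged_net)
        if averaged_net is not None
        else None
    )
    rows = []
    sizes = partition.sizes()
    for m in partition.module_ids():
        if sizes[m] < min_size:
            continue
        members = partition.members(m)
        if night_convention == "detections":
            pct_night = night_edge_percentage(
                etd[m], net.timepoints_zt, day_window
            )
        else:
            pct_night = night_edge_percentage_by_edge(
                net, partition, m, day_window
            )
        row: dict = {
            "module_id": m,
            "size": sizes[m],
            "pct_night_edges": pct_night,
        }
        if hvg_set is not None:
            n_hvg = sum(1 for g in members if g in hvg_set)
            row["n_hvg"] = n_hvg
            row["pct_hvg"] = 100.0 * n_hvg / len(members)
            enr = set_enrichment(members, hvg_set, background)
            row["hvg_fisher_p"] = enr.p_two_sided
        if avg_overlap is not None:
            row["n_in_averaged"], row["pct_in_averaged"] = avg_overlap[m]
        if gene_sets is not None:
            for name in gene_sets.names():
                enr = set_enrichment(members, gene_sets[name], background)
                row[f"{name}_overlap"] = enr.overlap
                row[f"{name}_odds_ratio"] = enr.odds_ratio
                row[f"{name}_p"] = enr.p_two_sided
        rows.append(row)
    return pd.DataFrame(rows).set_index("module_id")
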