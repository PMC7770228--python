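"""Louvain module detection and partition robustness comparison.

Louvain greedily maximizes Newman-Girvan modularity; like all stochastic
community detection it can return somewhat different partitions from run to
run, so the partitioner is seeded and supports restarts (keeping the
max-modularity run). Edges are unweighted by default: the input network is
already thresholded, so edge presence — not correlation strength — carries
the signal. Robustness across pipeline settings (e.g. persistence k=3 vs
k=4) is assessed by cross-tabulating two partitions on their shared genes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from networkx.algorithms import community as nx_community

from .types import CoexpressionNetwork, ModulePartition

logger = logging.getLogger(__name__)

__all__ = ["louvain_partition", "compare_partitions", "PartitionOverlap"]


def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, CoexpressionNetwork) else net


def _canonical_relabel(communities: list[set[str]]) -> dict[str, int]:
    """Contiguous ids from 0, largest module first (ties: smallest gene id)."""
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    return {g: mid for mid, comm in enumerate(ordered) for g in comm}


def louvain_partition(
    net: CoexpressionNetwork | nx.Graph,
    seed: int = 0,
    resolution: float = 1.0,
    restarts: int = 1,
    weighted: bool = False,
) -> ModulePartition:
    """Louvain community detection on the (thresholded) network.

    Deterministic given ``seed``. With ``restarts > 1`` the algorithm runs
    ``restarts`` times on seeds ``seed, seed+1, ...`` and keeps the
    partition with the highest modularity. ``weighted=True`` uses each
    edge's ``|mean_rho|`` as weight; default treats edges as unweighted.
    """
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        return ModulePartition({}, float("nan"), seed, resolution)
    weight = None
    if weighted:
        weight = "abs_rho"
        for a, b, d in g.edges(data=True):
            d["abs_rho"] = abs(d.get("mean_rho", 1.0))
    best: list[set] | None = None
    best_q = -np.inf
    best_seed = seed
    for r in range(max(1, restarts)):
        comms = nx_community.louvain_communities(
            g, weight=weight, resolution=resolution, seed=seed + r
        )
        q = nx_community.modularity(
            g, comms, weight=weight, resolution=resolution
        ) if g.number_of_edges() else float("nan")
        if best is None or (q == q and q > best_q):
            best, best_q, best_seed = comms, q, seed + r
    logger.info(
        "louvain: %d modules, modularity %.4f (seed %d of %d restart(s))",
        len(best), best_q, best_seed, max(1, restarts),
    )
    return ModulePartition(
        _canonical_relabel([set(c) for c in best]), float(best_q), best_seed,
        resolution,
    )


@dataclass
class PartitionOverlap:
    """Module-by-module overlap between two partitions on shared genes.

    ``table`` counts shared genes for every (module-of-p1, module-of-p2)
    pair; ``best_jaccard`` gives, for each module of p1, the best Jaccard
    index against any module of p2 (both restricted to shared genes).
    """

    table: pd.DataFrame
    best_jaccard: dict[int, float]
    n_shared_genes: int


def compare_partitions(p1: ModulePartition, p2: ModulePartition) -> PartitionOverlap:
    """Cross-tabulate two partitions over their shared gene universe."""
    shared = sorted(set(p1.assignment) & set(p2.assignment))
    if not shared:
        raise ValueError("partitions share no genes")
    a = pd.Series({g: p1.assignment[g] for g in shared}, name="p1")
    b = pd.Series({g: p2.assignment[g] for g in shared}, name="p2")
    table = pd.crosstab(a, b)
    sizes1 = a.value_counts()
    sizes2 = b.value_counts()
    best: dict[int, float] = {}
    for m1 in table.index:
        jac = 0.0
        for m2 in table.columns:
            inter = int(table.loc[m1, m2])
            if inter == 0:
                continue
            union = int(sizes1[m1] + sizes2[m2] - inter)
            jac = max(jac, inter / union)
        best[int(m1)] = jac
    return PartitionOverlap(table, best, len(shared))
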