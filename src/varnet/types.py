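"""Core in-memory containers for the variability-network pipeline.

The central object is the :class:`ExpressionTensor`: a dense
``(gene, timepoint, individual)`` array of normalized expression values for a
panel of genetically identical individuals sampled at fixed Zeitgeber times.
Missing values are ``NaN`` (absent, never zero). Networks are thin wrappers
around :class:`networkx.Graph` carrying per-edge timepoint support.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx

from .errors import SchemaError

__all__ = [
    "ExpressionTensor",
    "SampleMetadata",
    "TimepointEdgeSet",
    "EdgeSupport",
    "CoexpressionNetwork",
    "ModulePartition",
    "GeneSetCollection",
    "canonical_pair",
]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the gene pair in canonical (lexicographic) order."""
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class SampleMetadata:
    """One sample: an individual measured at one Zeitgeber timepoint."""

    sample_id: str
    timepoint_zt: int
    individual_index: int

    def __post_init__(self):
        if not (0 <= self.timepoint_zt < 24):
            raise SchemaError(
                f"sample {self.sample_id!r}: timepoint_zt {self.timepoint_zt} "
                "outside [0, 24)"
            )
        if self.individual_index < 1:
            raise SchemaError(
                f"sample {self.sample_id!r}: individual index must be >= 1"
            )


@dataclass
class ExpressionTensor:
    """Genes x timepoints x individuals expression values.

    Parameters
    ----------
    values
        Array of shape ``(n_genes, n_timepoints, n_individuals)``. Missing
        observations are ``NaN``.
    gene_ids
        Unique gene identifiers, ordered as in the source matrix.
    timepoints_zt
        Strictly increasing Zeitgeber hours, one per timepoint slot.
    """

    values: np.ndarray
    gene_ids: list[str]
    timepoints_zt: list[int]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.timepoints_zt = [int(t) for t in self.timepoints_zt]
        if self.values.ndim != 3:
            raise SchemaError("expression tensor must be 3-dimensional")
        g, t, _ = self.values.shape
        if g != len(self.gene_ids):
            raise SchemaError("gene_ids length does not match tensor")
        if t != len(self.timepoints_zt):
            raise SchemaError("timepoints_zt length does not match tensor")
        if len(set(self.gene_ids)) != g:
            raise SchemaError("duplicate gene IDs")
        if any(b <= a for a, b in zip(self.timepoints_zt, self.timepoints_zt[1:])):
            raise SchemaError("timepoints must be strictly increasing")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def n_individuals(self) -> int:
        return self.values.shape[2]

    def mean_profiles(self) -> np.ndarray:
        """Per-gene mean-over-individuals profile, shape (n_genes, n_timepoints)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            return np.nanmean(self.values, axis=2)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class TimepointEdgeSet:
    """BH-selected gene pairs at one timepoint.

    Only selected pairs are materialized; ``n_tested`` records the multiple-
    testing burden m for that timepoint (pairs with a defined correlation).
    """

    timepoint_zt: int
    pairs: list[tuple[str, str]]  # canonical order
    rho: np.ndarray
    p_value: np.ndarray
    n_tested: int
    fdr: float
    p_threshold: float  # BH step-up cut actually applied (0 if none selected)

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        self.p_value = np.asarray(self.p_value, dtype=float)
        for a, b in self.pairs:
            if a >= b:
                raise ValueError(f"pair ({a}, {b}) not canonical")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class EdgeSupport:
    """Per-timepoint significance mask and correlations for one gene pair."""

    pair: tuple[str, str]
    support_mask: np.ndarray  # bool, one slot per timepoint
    rho_by_timepoint: np.ndarray  # float, NaN where unscorable

    def __post_init__(self):
        self.support_mask = np.asarray(self.support_mask, dtype=bool)
        self.rho_by_timepoint = np.asarray(self.rho_by_timepoint, dtype=float)
        if self.support_mask.shape != self.rho_by_timepoint.shape:
            raise ValueError("mask and rho vectors must have equal length")

    @property
    def n_supporting(self) -> int:
        return int(self.support_mask.sum())


class CoexpressionNetwork:
    """Undirected gene network with per-edge timepoint support.

    Edges carry ``support`` (boolean mask over timepoints), ``rho``
    (per-timepoint Spearman rho, NaN where untested) and ``mean_rho`` (mean
    over supporting timepoints; for the averaged route, the single profile
    correlation). ``provenance`` records the route and parameters used.
    """

    def __init__(
        self,
        timepoints_zt: Sequence[int],
        provenance: Mapping | None = None,
    ):
        self.graph = nx.Graph()
        self.timepoints_zt = [int(t) for t in timepoints_zt]
        self.provenance: dict = dict(provenance or {})

    # -- construction -----------------------------------------------------
    def add_edge(self, a: str, b: str, support: EdgeSupport | None = None,
                 mean_rho: float = np.nan, **attrs) -> None:
        a, b = canonical_pair(a, b)
        data = dict(attrs)
        if support is not None:
            data["support"] = support.support_mask
            data["rho"] = support.rho_by_timepoint
            data["n_support"] = support.n_supporting
            sel = support.support_mask
            if np.isnan(mean_rho) and sel.any():
                mean_rho = float(np.nanmean(support.rho_by_timepoint[sel]))
        data["mean_rho"] = float(mean_rho)
        self.graph.add_edge(a, b, **data)

    # -- queries ----------------------------------------------------------
    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_genes(self) -> int:
        return self.graph.number_of_nodes()

    def genes(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {canonical_pair(a, b) for a, b in self.graph.edges}

    def edge_support(self, a: str, b: str) -> EdgeSupport:
        a, b = canonical_pair(a, b)
        d = self.graph.edges[a, b]
        mask = d.get("support")
        rho = d.get("rho")
        if mask is None:
            mask = np.zeros(len(self.timepoints_zt), dtype=bool)
            rho = np.full(len(self.timepoints_zt), np.nan)
        return EdgeSupport((a, b), mask, rho)

    def edges_detected_at(self, slot: int) -> int:
        """Count edges whose support mask is true at timepoint slot ``slot``."""
        n = 0
        for _, _, d in self.graph.edges(data=True):
            mask = d.get("support")
            if mask is not None and mask[slot]:
                n += 1
        return n

    def per_timepoint_edge_counts(self) -> np.ndarray:
        return np.array(
            [self.edges_detected_at(s) for s in range(len(self.timepoints_zt))]
        )

    def __repr__(self) -> str:
        route = self.provenance.get("route", "?")
        return (f"CoexpressionNetwork(route={route}, genes={self.n_genes}, "
                f"edges={self.n_edges})")


@dataclass
class ModulePartition:
    """Gene -> module assignment from community detection.

    Module ids are contiguous integers from 0, ordered by decreasing module
    size (ties broken by smallest member gene id) so runs are comparable.
    """

    assignment: dict[str, int]
    modularity: float
    seed: int
    resolution: float = 1.0

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, module_id: int) -> list[str]:
        return sorted(g for g, m in self.assignment.items() if m == module_id)

    def module_ids(self) -> list[int]:
        return sorted(set(self.assignment.values()))

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for m in self.assignment.values():
            out[m] = out.get(m, 0) + 1
        return out


@dataclass
class GeneSetCollection:
    """Named gene sets plus (optionally) a declared background universe."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    universe: list[str] | None = None

    def __post_init__(self):
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise SchemaError(f"gene set {name!r} contains duplicates")
        if self.universe is not None:
            uni = set(self.universe)
            for name, genes in self.sets.items():
                extra = set(genes) - uni
                if extra:
                    raise SchemaError(
                        f"gene set {name!r} has genes outside the declared "
                        f"universe: {sorted(extra)[:5]}"
                    )

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)
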