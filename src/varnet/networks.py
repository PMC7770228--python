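"""The two co-expression inference routes.

Variability route: at each Zeitgeber timepoint, Spearman rank correlation is
computed for every gene pair across the individuals sampled at that
timepoint; pairs are selected per timepoint by Benjamini-Hochberg step-up at
a stated FDR (default 10%), and an edge enters the network only if it is
selected at >= k near-consecutive timepoints (default k=4 with at most one
gap inside the window) — the temporal persistence filter.

Averaged route: the conventional construction. Each gene is reduced to its
mean-over-individuals time profile, Spearman correlation is computed between
profile pairs, and edges pass a Bonferroni cut at alpha / (number of tested
pairs).

Exact Spearman p-values (full permutation null) are used for small n; the
t-distribution approximation above ``exact_n_max`` (default 9).
"""
from __future__ import annotations

import itertools
import logging
import math
from functools import lru_cache
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import StageError
from .types import (
    CoexpressionNetwork,
    EdgeSupport,
    ExpressionTensor,
    TimepointEdgeSet,
    canonical_pair,
)

logger = logging.getLogger(__name__)

__all__ = [
    "spearman_with_p",
    "bh_select",
    "per_timepoint_networks",
    "persistence_filter",
    "build_variability_network",
    "build_averaged_network",
    "network_overlap",
]

DEFAULT_EXACT_N_MAX = 9
DEFAULT_MIN_JOINT_OBS = 8  # joint observations needed to score a pair


# ---------------------------------------------------------------------------
# Spearman correlation with exact or approximate two-sided p


def _t_approx_p(rho: float, n: int) -> float:
    if n < 3:
        return 1.0
    r = min(max(rho, -1.0), 1.0)
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@lru_cache(maxsize=256)
def _exact_null_counts(rx: tuple, ry: tuple) -> tuple[np.ndarray, int]:
    """Null distribution of the rank Pearson statistic by full enumeration.

    Keyed on the two sorted rank multisets: permuting either vector leaves
    the permutation null unchanged, so the cache is shared across pairs with
    the same tie structure.
    """
    rx_a = np.array(rx, dtype=float)
    n = len(rx_a)
    rx_c = rx_a - rx_a.mean()
    denom_x = float(np.sqrt((rx_c ** 2).sum()))
    stats_all = np.empty(math.factorial(n))
    ry_arr = np.array(ry, dtype=float)
    ry_c_mean = ry_arr.mean()
    denom_y = float(np.sqrt(((ry_arr - ry_c_mean) ** 2).sum()))
    for i, perm in enumerate(itertools.permutations(ry)):
        py = np.array(perm, dtype=float) - ry_c_mean
        stats_all[i] = float(rx_c @ py) / (denom_x * denom_y)
    return stats_all, n


def spearman_with_p(
    x: Sequence[float],
    y: Sequence[float],
    exact_n_max: int = DEFAULT_EXACT_N_MAX,
) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with a two-sided p-value.

    For ``n <= exact_n_max`` the p-value is exact: the fraction of all n!
    permutations of one rank vector whose |rho| reaches the observed |rho|.
    Above that, the usual t-distribution approximation on
    ``t = rho * sqrt((n-2)/(1-rho^2))`` is used.

    A constant vector makes rho undefined: returns ``(nan, nan)`` rather
    than raising, so callers can leave the pair unscored.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return (float("nan"), float("nan"))
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_n_max:
        null, _ = _exact_null_counts(tuple(sorted(rx)), tuple(sorted(ry)))
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        p = _t_approx_p(rho, n)
    return rho, p


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up


def bh_select(p_values: Sequence[float], fdr: float) -> np.ndarray:
    """Benjamini-Hochberg step-up selection mask.

    Rejects all hypotheses with ``p <= p_(k*)`` where
    ``k* = max{k : p_(k) <= k * fdr / m}``; the returned boolean mask is
    aligned with the input order. Empty input gives an empty mask.
    """
    p = np.asarray(p_values, dtype=float)
    if not (0 < fdr < 1):
        raise ValueError("fdr must be in (0, 1)")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = (np.arange(1, m + 1) * fdr) / m
    passing = np.flatnonzero(ranked <= crit)
    if passing.size == 0:
        return np.zeros(m, dtype=bool)
    cut = ranked[passing[-1]]
    return p <= cut


def bh_threshold(p_values: Sequence[float], fdr: float) -> float:
    """The step-up p cut actually applied (0.0 when nothing is selected)."""
    p = np.asarray(p_values, dtype=float)
    mask = bh_select(p, fdr) if p.size else np.zeros(0, dtype=bool)
    return float(p[mask].max()) if mask.any() else 0.0


# ---------------------------------------------------------------------------
# per-timepoint correlation + selection


def _spearman_matrix_complete(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman for complete data ``x`` of shape (genes, n).

    Returns (rho matrix, valid-gene mask). Constant genes are flagged
    invalid; their rows/columns are NaN.
    """
    n = x.shape[1]
    ranks = stats.rankdata(x, axis=1)
    sd = ranks.std(axis=1)
    valid = sd > 0
    rho = np.full((x.shape[0], x.shape[0]), np.nan)
    if valid.sum() >= 2:
        rv = ranks[valid]
        rho_v = np.corrcoef(rv)
        np.clip(rho_v, -1.0, 1.0, out=rho_v)
        ix = np.flatnonzero(valid)
        rho[np.ix_(ix, ix)] = rho_v
    return rho, valid


def _p_matrix_from_rho(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided t-approximation p for every entry of a rho matrix."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho ** 2, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0] = np.nextafter(0, 1)  # keep p in (0, 1]
    p = np.minimum(p, 1.0)
    p[p == 0] = np.nextafter(0, 1)
    return p


def _pairwise_spearman_missing(
    x: np.ndarray, min_joint: int, exact_n_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete Spearman for data with NaNs. Returns (rho, p)."""
    g = x.shape[0]
    rho = np.full((g, g), np.nan)
    p = np.full((g, g), np.nan)
    obs = ~np.isnan(x)
    for i in range(g):
        for j in range(i + 1, g):
            joint = obs[i] & obs[j]
            if joint.sum() < max(min_joint, 3):
                continue
            r, pv = spearman_with_p(x[i, joint], x[j, joint], exact_n_max)
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = pv
    return rho, p


def per_timepoint_networks(
    tensor: ExpressionTensor,
    fdr: float = 0.10,
    gene_filter: Callable[[str], bool] | None = None,
    min_joint_obs: int = DEFAULT_MIN_JOINT_OBS,
    exact_n_max: int = DEFAULT_EXACT_N_MAX,
    positive_only: bool = False,
    pool_timepoints: bool = False,
) -> list[TimepointEdgeSet]:
    """BH-selected correlated pairs at each timepoint.

    By default all gene pairs with a defined correlation at a timepoint
    form the multiple-testing family for that timepoint and BH is applied
    within each timepoint separately; ``pool_timepoints`` instead pools
    every (pair, timepoint) p-value into one family and applies BH once.
    Only selected pairs are materialized.
    """
    genes = tensor.gene_ids
    keep = (
        np.ones(len(genes), dtype=bool)
        if gene_filter is None
        else np.array([bool(gene_filter(g)) for g in genes])
    )
    if keep.sum() < 2:
        raise StageError("fewer than 2 genes pass the gene filter")
    sub = np.flatnonzero(keep)
    names = [genes[i] for i in sub]

    iu, ju = np.triu_indices(len(names), k=1)
    per_tp: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for ti, zt in enumerate(tensor.timepoints_zt):
        x = tensor.values[sub, ti, :]
        has_nan = np.isnan(x).any()
        if has_nan:
            rho, p = _pairwise_spearman_missing(x, min_joint_obs, exact_n_max)
        else:
            n = x.shape[1]
            if n <= exact_n_max:
                rho, p = _pairwise_spearman_missing(x, 3, exact_n_max)
            else:
                rho, _ = _spearman_matrix_complete(x)
                p = _p_matrix_from_rho(rho, n)
        pv = p[iu, ju]
        rv = rho[iu, ju]
        tested = ~np.isnan(pv)
        if positive_only:
            tested &= rv > 0
        per_tp.append((pv, rv, tested))

    if pool_timepoints:
        all_p = np.concatenate([pv[t] for pv, _, t in per_tp])
        pooled_mask = (
            bh_select(all_p, fdr) if all_p.size else np.zeros(0, dtype=bool)
        )
        cut = float(all_p[pooled_mask].max()) if pooled_mask.any() else 0.0

    out: list[TimepointEdgeSet] = []
    for zt, (pv, rv, tested) in zip(tensor.timepoints_zt, per_tp):
        m = int(tested.sum())
        if m == 0:
            out.append(TimepointEdgeSet(zt, [], [], [], 0, fdr, 0.0))
            continue
        mask = np.zeros(pv.shape, dtype=bool)
        if pool_timepoints:
            mask[tested] = pv[tested] <= cut if cut > 0 else False
            thr = cut
        else:
            mask[tested] = bh_select(pv[tested], fdr)
            thr = 0.0
        sel = np.flatnonzero(mask)
        pairs = [canonical_pair(names[iu[s]], names[ju[s]]) for s in sel]
        if not pool_timepoints:
            thr = float(pv[sel].max()) if sel.size else 0.0
        out.append(
            TimepointEdgeSet(zt, pairs, rv[sel], pv[sel], m, fdr, thr)
        )
        logger.debug("ZT%d: tested m=%d, selected %d", zt, m, len(pairs))
    return out


# ---------------------------------------------------------------------------
# persistence filter


def persistence_filter(
    support, k: int = 4, gaps: int = 1, circular: bool = False
) -> bool:
    """Temporal persistence predicate on a significance mask.

    True iff some window of timepoint slots (i) starts and ends on a
    significant slot, (ii) contains >= k significant slots, and (iii) has at
    most ``gaps`` non-significant slots inside. The defaults (k=4, gaps=1)
    keep an edge significant at, e.g., ZT 8, 10, 14 and 16 on a 2-hour grid:
    the window ZT8..ZT16 holds four hits around a single gap at ZT12.

    ``support`` may be an :class:`EdgeSupport` or a boolean mask. With
    ``circular`` the last slot is treated as adjacent to the first
    (windows may wrap, up to the full cycle length).
    """
    if k < 1 or gaps < 0:
        raise ValueError("need k >= 1 and gaps >= 0")
    mask = support.support_mask if isinstance(support, EdgeSupport) else support
    mask = np.asarray(mask, dtype=bool)
    t = mask.size
    if t == 0:
        return False
    if circular:
        ext = np.concatenate([mask, mask[: t - 1]])
        hits = np.flatnonzero(ext)
        max_len = t
    else:
        ext = mask
        hits = np.flatnonzero(mask)
        max_len = t
    for a_i, a in enumerate(hits):
        if a >= t:  # windows must start within the first copy
            break
        for b in hits[a_i:]:
            length = b - a + 1
            if length > max_len:
                break
            inside = int(ext[a : b + 1].sum())
            if inside >= k and (length - inside) <= gaps:
                return True
    return False


# ---------------------------------------------------------------------------
# network builders


def _rho_for_pair_at_all_timepoints(
    tensor: ExpressionTensor,
    gi: int,
    gj: int,
    min_joint_obs: int,
) -> np.ndarray:
    rho = np.full(tensor.n_timepoints, np.nan)
    xi = tensor.values[gi]
    xj = tensor.values[gj]
    for ti in range(tensor.n_timepoints):
        joint = ~np.isnan(xi[ti]) & ~np.isnan(xj[ti])
        nj = int(joint.sum())
        if nj < max(min_joint_obs, 3):
            continue
        ri = stats.rankdata(xi[ti, joint])
        rj = stats.rankdata(xj[ti, joint])
        if np.ptp(ri) == 0 or np.ptp(rj) == 0:
            continue
        rho[ti] = float(np.corrcoef(ri, rj)[0, 1])
    return rho


def build_variability_network(
    tensor: ExpressionTensor,
    fdr: float = 0.10,
    k: int = 4,
    gaps: int = 1,
    circular: bool = False,
    gene_filter: Callable[[str], bool] | None = None,
    min_joint_obs: int = DEFAULT_MIN_JOINT_OBS,
    exact_n_max: int = DEFAULT_EXACT_N_MAX,
    positive_only: bool = False,
    timepoint_sets: list[TimepointEdgeSet] | None = None,
) -> CoexpressionNetwork:
    """Variability network: per-timepoint selection + persistence filter.

    Nodes are exactly the genes incident to at least one surviving edge.
    Each edge retains its full support mask and per-timepoint rho vector.
    ``timepoint_sets`` lets callers reuse the per-timepoint selection when
    building several networks (e.g. k=3 vs k=4) from the same tensor.
    """
    net = CoexpressionNetwork(
        tensor.timepoints_zt,
        provenance={
            "route": "variability",
            "fdr": fdr, "k": k, "gaps": gaps, "circular": circular,
            "positive_only": positive_only, "min_joint_obs": min_joint_obs,
        },
    )
    if tensor.n_genes < 2:
        return net
    if timepoint_sets is None:
        timepoint_sets = per_timepoint_networks(
            tensor, fdr, gene_filter, min_joint_obs, exact_n_max, positive_only
        )
    t = tensor.n_timepoints
    support: dict[tuple[str, str], np.ndarray] = {}
    for ti, es in enumerate(timepoint_sets):
        for pair in es.pairs:
            support.setdefault(pair, np.zeros(t, dtype=bool))[ti] = True

    gidx = tensor.gene_index()
    n_candidates = 0
    for pair, mask in support.items():
        if mask.sum() < k:
            continue
        n_candidates += 1
        if not persistence_filter(mask, k=k, gaps=gaps, circular=circular):
            continue
        rho = _rho_for_pair_at_all_timepoints(
            tensor, gidx[pair[0]], gidx[pair[1]], min_joint_obs
        )
        net.add_edge(pair[0], pair[1], EdgeSupport(pair, mask, rho))
    logger.info(
        "variability network: %d pairs selected somewhere, %d with >=%d hits, "
        "%d edges survive persistence (k=%d, gaps=%d)",
        len(support), n_candidates, k, net.n_edges, k, gaps,
    )
    return net


def build_averaged_network(
    tensor: ExpressionTensor,
    alpha: float = 0.05,
    exact_n_max: int = DEFAULT_EXACT_N_MAX,
    positive_only: bool = False,
) -> CoexpressionNetwork:
    """Averaged time course network: Spearman on mean profiles + Bonferroni.

    Each gene's profile is its mean expression over individuals at every
    timepoint; an edge exists iff the profile correlation's p-value passes
    ``alpha / m`` with m the number of tested (non-constant) pairs.
    """
    if tensor.n_timepoints < 3:
        raise StageError("averaged network needs >= 3 timepoints")
    profiles = tensor.mean_profiles()
    n = tensor.n_timepoints
    net = CoexpressionNetwork(
        tensor.timepoints_zt,
        provenance={"route": "averaged", "alpha": alpha},
    )
    if tensor.n_genes < 2:
        return net
    if np.isnan(profiles).any() or n <= exact_n_max:
        g = tensor.n_genes
        rho = np.full((g, g), np.nan)
        p = np.full((g, g), np.nan)
        for i in range(g):
            for j in range(i + 1, g):
                joint = ~np.isnan(profiles[i]) & ~np.isnan(profiles[j])
                if joint.sum() < 3:
                    continue
                r, pv = spearman_with_p(
                    profiles[i, joint], profiles[j, joint], exact_n_max
                )
                rho[i, j], p[i, j] = r, pv
        iu, ju = np.triu_indices(g, k=1)
        pv, rv = p[iu, ju], rho[iu, ju]
    else:
        rho, _ = _spearman_matrix_complete(profiles)
        p = _p_matrix_from_rho(rho, n)
        iu, ju = np.triu_indices(tensor.n_genes, k=1)
        pv, rv = p[iu, ju], rho[iu, ju]

    tested = ~np.isnan(pv)
    if positive_only:
        tested &= rv > 0
    m = int(tested.sum())
    if m == 0:
        return net
    cut = alpha / m
    sel = np.flatnonzero(tested & (pv <= cut))
    for s in sel:
        a, b = canonical_pair(tensor.gene_ids[iu[s]], tensor.gene_ids[ju[s]])
        net.add_edge(a, b, mean_rho=float(rv[s]), p=float(pv[s]))
    net.provenance["m_tested"] = m
    net.provenance["bonferroni_cut"] = cut
    return net


def network_overlap(
    a: CoexpressionNetwork, b: CoexpressionNetwork
) -> dict[str, int]:
    """Shared gene and shared (canonical) edge counts between two networks."""
    shared_genes = a.genes() & b.genes()
    shared_edges = a.edge_pairs() & b.edge_pairs()
    return {"shared_genes": len(shared_genes), "shared_edges": len(shared_edges)}
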