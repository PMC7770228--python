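import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import varnet
from varnet.errors import StageError
from varnet.networks import bh_threshold


# ---------------------------------------------------------------------------
# independent oracles (deliberately separate from the implementation path)


def enumeration_spearman_p(x, y):
    """Two-sided exact p by brute force over all n! orderings of y."""
    rho_obs = stats.spearmanr(x, y).statistic
    hits = total = 0
    for perm in itertools.permutations(y):
        r = stats.spearmanr(x, perm).statistic
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            hits += 1
    return hits / total


def stepup_bh(p, fdr):
    """Literal step-up definition: find k* then reject p <= p_(k*)."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p)
    kstar = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * fdr / m:
            kstar = k
    if kstar == 0:
        return np.zeros(m, dtype=bool)
    return p <= p[order[kstar - 1]]


def brute_force_persistence(mask, k, gaps, circular=False):
    """Scan every window (optionally wrapping) for the persistence predicate."""
    mask = list(mask)
    t = len(mask)
    ext = mask + (mask[:-1] if circular else [])
    for a in range(t):
        for b in range(a, min(a + t, len(ext))):
            window = ext[a : b + 1]
            if not (window[0] and window[-1]):
                continue
            hits = sum(window)
            if hits >= k and (len(window) - hits) <= gaps:
                return True
    return False


# ---------------------------------------------------------------------------
# spearman_with_p


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(1, 15, dtype=float)
        rho, p = varnet.spearman_with_p(x, np.exp(x / 3))
        assert rho == pytest.approx(1.0)
        assert p < 1e-6
        rho, _ = varnet.spearman_with_p(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_n5_example_against_enumeration(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        rho, p = varnet.spearman_with_p(x, y)
        assert rho == pytest.approx(0.8)
        # 16 of the 120 rank permutations reach |rho| >= 0.8
        assert p == pytest.approx(16 / 120)
        assert p == pytest.approx(enumeration_spearman_p(x, y))

    def test_constant_vector_flagged_not_raised(self):
        rho, p = varnet.spearman_with_p([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert math.isnan(rho) and math.isnan(p)

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_exact_p_equals_enumeration(self, n, rng):
        for _ in range(3):
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            _, p = varnet.spearman_with_p(x, y)
            assert p == pytest.approx(enumeration_spearman_p(x, y))

    def test_exact_p_with_ties_equals_enumeration(self, rng):
        x = np.array([1.0, 1.0, 2.0, 3.0, 4.0, 2.0])
        y = np.array([3.0, 1.0, 1.0, 2.0, 5.0, 4.0])
        _, p = varnet.spearman_with_p(x, y)
        assert p == pytest.approx(enumeration_spearman_p(x, y))

    def test_large_n_matches_t_approximation(self, rng):
        x = rng.standard_normal(14)
        y = rng.standard_normal(14)
        rho, p = varnet.spearman_with_p(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


# ---------------------------------------------------------------------------
# bh_select


class TestBH:
    def test_hand_worked_stepup(self):
        # thresholds 0.025 / 0.05 / 0.075 / 0.10: first three selected
        mask = varnet.bh_select([0.01, 0.02, 0.04, 0.5], 0.10)
        assert mask.tolist() == [True, True, True, False]

    def test_all_ones_none_selected(self):
        assert not varnet.bh_select([1.0, 1.0, 1.0], 0.10).any()

    def test_single_p(self):
        assert varnet.bh_select([0.05], 0.10).tolist() == [True]

    def test_empty_input(self):
        assert varnet.bh_select([], 0.10).size == 0

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=40),
           st.floats(0.01, 0.5))
    def test_matches_literal_stepup_definition(self, p, fdr):
        got = varnet.bh_select(p, fdr)
        assert got.tolist() == stepup_bh(p, fdr).tolist()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 50))
            got = varnet.bh_select(p, 0.10)
            ref = multipletests(p, alpha=0.10, method="fdr_bh")[0]
            assert got.tolist() == ref.tolist()


# ---------------------------------------------------------------------------
# persistence filter


class TestPersistence:
    @pytest.mark.parametrize("mask,expected", [
        ([1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0], True),
        # the canonical worked case: significant at ZT 8, 10, 14, 16 on a
        # 2-hour grid; one gap (ZT12) inside a window whose ends are hits
        ([0, 0, 0, 0, 1, 1, 0, 1, 1, 0, 0, 0], True),
        ([1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0], False),
        ([1, 1, 1, 0, 0, 1, 1, 1, 0, 0, 0, 0], False),
        ([0] * 12, False),
    ])
    def test_default_window_semantics(self, mask, expected):
        assert varnet.persistence_filter(np.array(mask, bool)) is expected

    def test_k3_accepts_run_of_three(self):
        mask = np.array([0, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0], bool)
        assert varnet.persistence_filter(mask, k=3)
        assert not varnet.persistence_filter(mask, k=4)

    def test_circular_wraparound(self):
        mask = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1], bool)
        assert not varnet.persistence_filter(mask, k=4, gaps=0)
        assert varnet.persistence_filter(mask, k=4, gaps=0, circular=True)

    @settings(max_examples=300, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=14),
           st.integers(1, 6), st.integers(0, 3), st.booleans())
    def test_matches_brute_force_window_scan(self, mask, k, gaps, circular):
        got = varnet.persistence_filter(
            np.array(mask, bool), k=k, gaps=gaps, circular=circular
        )
        assert got == brute_force_persistence(mask, k, gaps, circular)


# ---------------------------------------------------------------------------
# per-timepoint selection and the two network builders


class TestPerTimepoint:
    def test_planted_pair_selected_everywhere(self, planted_tensor):
        sets = varnet.per_timepoint_networks(planted_tensor, fdr=0.10)
        assert len(sets) == 12
        for es in sets:
            assert ("g00", "g01") in es.pairs
            i = es.pairs.index(("g00", "g01"))
            assert es.rho[i] == pytest.approx(1.0)
            assert es.p_value[i] <= bh_threshold(es.p_value, 0.10)

    def test_single_timepoint_tensor(self, rng):
        t = varnet.ExpressionTensor(
            rng.standard_normal((5, 1, 10)), list("abcde"), [4]
        )
        sets = varnet.per_timepoint_networks(t, fdr=0.10)
        assert len(sets) == 1 and sets[0].timepoint_zt == 4

    def test_too_few_genes_after_filter(self, small_tensor):
        with pytest.raises(StageError):
            varnet.per_timepoint_networks(
                small_tensor, gene_filter=lambda g: g == "g00"
            )

    def test_missing_data_uses_joint_observations(self, rng):
        values = rng.standard_normal((3, 1, 14))
        values[1] = values[0]
        values[0, 0, :4] = np.nan  # pair scored on the 10 joint individuals
        t = varnet.ExpressionTensor(values, ["a", "b", "c"], [0])
        sets = varnet.per_timepoint_networks(t, fdr=0.10, min_joint_obs=8)
        assert ("a", "b") in sets[0].pairs

    def test_pooled_bh_uses_one_global_family(self, rng):
        """Pooled selection count equals BH on the concatenated p-values."""
        small_tensor = varnet.ExpressionTensor(
            rng.standard_normal((10, 4, 14)),
            [f"g{i:02d}" for i in range(10)], [0, 6, 12, 18])
        per_tp = varnet.per_timepoint_networks(small_tensor, fdr=0.4)
        pooled = varnet.per_timepoint_networks(
            small_tensor, fdr=0.4, pool_timepoints=True)
        # recompute the pooled family independently: all tested pairs
        from scipy import stats as ss

        all_p = []
        for ti in range(small_tensor.n_timepoints):
            x = small_tensor.values[:, ti, :]
            ranks = ss.rankdata(x, axis=1)
            rho = np.corrcoef(ranks)
            iu, ju = np.triu_indices(small_tensor.n_genes, k=1)
            r = np.clip(rho[iu, ju], -1 + 1e-12, 1 - 1e-12)
            n = small_tensor.n_individuals
            t = r * np.sqrt((n - 2) / (1 - r**2))
            all_p.append(2 * ss.t.sf(np.abs(t), df=n - 2))
        all_p = np.concatenate(all_p)
        expected = int(varnet.bh_select(all_p, 0.4).sum())
        assert sum(len(es) for es in pooled) == expected
        assert sum(len(es) for es in per_tp) != expected or expected == 0

    def test_pair_below_min_joint_obs_unscored(self, rng):
        values = rng.standard_normal((2, 1, 14))
        values[0, 0, :8] = np.nan  # only 6 joint observations remain
        t = varnet.ExpressionTensor(values, ["a", "b"], [0])
        sets = varnet.per_timepoint_networks(t, fdr=0.10, min_joint_obs=8)
        assert sets[0].n_tested == 0


class TestVariabilityNetwork:
    def test_recovers_module_coupled_six_timepoints(self):
        spec = varnet.default_spec(seed=7)
        tensor, truth = varnet.generate(spec)
        net = varnet.build_variability_network(tensor)
        true_edges = truth.true_edge_union()
        inferred = net.edge_pairs()
        assert len(inferred & true_edges) / max(len(inferred), 1) > 0.9
        # nodes are exactly the genes incident to surviving edges
        incident = {g for pair in inferred for g in pair}
        assert net.genes() == incident

    def test_two_timepoint_coupling_fails_persistence(self):
        t = 12
        spec = varnet.SyntheticSpec(
            n_genes=30,
            modules=(varnet.ModuleSpec(
                10, varnet.window_coupling(t, 2, 2, 0.95)),),
            seed=3,
        )
        tensor, truth = varnet.generate(spec)
        net = varnet.build_variability_network(tensor, k=4, gaps=1)
        assert not (net.edge_pairs() & truth.true_edge_union())

    def test_empty_tensor_gives_empty_network(self):
        t = varnet.ExpressionTensor(
            np.empty((0, 3, 5)), [], [0, 8, 16]
        )
        net = varnet.build_variability_network(t)
        assert net.n_edges == 0 and net.n_genes == 0

    def test_every_edge_reverifies_persistence(self, planted_tensor):
        net = varnet.build_variability_network(planted_tensor, k=4, gaps=1)
        for a, b in net.edge_pairs():
            sup = net.edge_support(a, b)
            assert varnet.persistence_filter(sup, k=4, gaps=1)

    def test_invariant_under_gene_order_permutation(self, rng):
        spec = varnet.SyntheticSpec(
            n_genes=40,
            modules=(varnet.ModuleSpec(
                8, varnet.window_coupling(12, 0, 6, 0.9)),),
            seed=11,
        )
        tensor, _ = varnet.generate(spec)
        perm = rng.permutation(tensor.n_genes)
        shuffled = varnet.ExpressionTensor(
            tensor.values[perm],
            [tensor.gene_ids[i] for i in perm],
            tensor.timepoints_zt,
        )
        net1 = varnet.build_variability_network(tensor)
        net2 = varnet.build_variability_network(shuffled)
        assert net1.edge_pairs() == net2.edge_pairs()


class TestAveragedNetwork:
    def test_identical_sine_profiles_connected(self, rng):
        zt = np.arange(0, 24, 2)
        mu = 5 + 2 * np.cos(2 * np.pi * (zt - 8) / 24)
        # exact tie structure must match between the genes: rank ties at
        # symmetric ZT pairs around the peak are averaged identically
        values = np.empty((2, 12, 14))
        values[0] = np.tile(mu[:, None], (1, 14))
        values[1] = np.tile(2 * mu[:, None] + 1, (1, 14))
        t = varnet.ExpressionTensor(values, ["a", "b"], list(zt))
        net = varnet.build_averaged_network(t, alpha=0.05)
        assert ("a", "b") in net.edge_pairs()
        assert net.graph.edges["a", "b"]["mean_rho"] == pytest.approx(1.0)

    def test_antiphase_profiles_negative_edge(self, rng):
        values = np.empty((2, 12, 4))
        values[0] = np.arange(1, 13)[:, None] + rng.standard_normal((12, 4)) * 1e-6
        values[1] = np.arange(12, 0, -1)[:, None] + rng.standard_normal((12, 4)) * 1e-6
        t = varnet.ExpressionTensor(
            values, ["a", "b"], list(range(0, 24, 2)))
        net = varnet.build_averaged_network(t, alpha=0.05)
        assert ("a", "b") in net.edge_pairs()
        assert net.graph.edges["a", "b"]["mean_rho"] == pytest.approx(-1.0)

    def test_flat_noise_yields_almost_no_edges(self, rng):
        values = rng.standard_normal((50, 12, 14))
        t = varnet.ExpressionTensor(
            values, [f"g{i}" for i in range(50)], list(range(0, 24, 2)))
        net = varnet.build_averaged_network(t, alpha=0.05)
        assert net.n_edges <= 1  # Bonferroni at m=1225 is nearly airtight

    def test_too_few_timepoints(self, rng):
        t = varnet.ExpressionTensor(
            rng.standard_normal((4, 2, 5)), list("abcd"), [0, 12])
        with pytest.raises(StageError):
            varnet.build_averaged_network(t)


def test_network_overlap_hand_count():
    a = varnet.CoexpressionNetwork([0])
    for pair in [("g1", "g2"), ("g2", "g3")]:
        a.add_edge(*pair, mean_rho=0.5)
    b = varnet.CoexpressionNetwork([0])
    for pair in [("g2", "g3"), ("g4", "g5")]:
        b.add_edge(*pair, mean_rho=0.5)
    assert varnet.network_overlap(a, b) == {"shared_genes": 2, "shared_edges": 1}
    assert varnet.network_overlap(a, a) == {"shared_genes": 3, "shared_edges": 2}
    c = varnet.CoexpressionNetwork([0])
    c.add_edge("x1", "x2", mean_rho=0.5)
    assert varnet.network_overlap(a, c) == {"shared_genes": 0, "shared_edges": 0}
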