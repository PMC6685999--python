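import numpy as np
import pandas as pd
import pytest

from noarewire import synthetic
from noarewire.diffcoex import (
    CorrelationMatrices,
    DiffCoExParams,
    adjacency_change,
    condition_correlations,
    detect_modules,
    module_dispersion,
    module_dispersion_test,
    pick_soft_threshold,
    topological_overlap,
)
from noarewire.iotypes import ExpressionMatrix, SyntheticTruth
from noarewire.stress import StressGrouping, StressThresholds


def _grouping(labels):
    return StressGrouping(
        labels=pd.Series(labels), thresholds=StressThresholds(0, 0), min_group=0
    )


def _random_corr_pair(rng, n):
    def one():
        a = rng.normal(size=(n, n + 5))
        c = np.corrcoef(a)
        np.fill_diagonal(c, 1.0)
        return c
    genes = [f"g{i}" for i in range(n)]
    return CorrelationMatrices(gene_order=genes, c1=one(), c2=one())


def adjacency_brute_force(c1, c2, beta):
    n = c1.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            a1 = np.sign(c1[i, j]) * c1[i, j] ** 2
            a2 = np.sign(c2[i, j]) * c2[i, j] ** 2
            d[i, j] = (0.5 * abs(a1 - a2)) ** (beta / 2.0)
    return d


def tom_brute_force(d):
    n = d.shape[0]
    a = d.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestAdjacencyChange:
    def test_equal_conditions_give_zero(self):
        rng = np.random.default_rng(0)
        c = _random_corr_pair(rng, 8)
        c = CorrelationMatrices(gene_order=c.gene_order, c1=c.c1, c2=c.c1.copy())
        assert np.all(adjacency_change(c, 6) == 0)

    def test_hand_evaluations(self):
        genes = ["a", "b"]
        c1 = np.array([[1.0, 1.0], [1.0, 1.0]])
        c2 = np.array([[1.0, -1.0], [-1.0, 1.0]])
        d = adjacency_change(CorrelationMatrices(genes, c1, c2), beta=2)
        assert d[0, 1] == pytest.approx(1.0)

        c1 = np.array([[1.0, 0.6], [0.6, 1.0]])
        c2 = np.eye(2)
        d = adjacency_change(CorrelationMatrices(genes, c1, c2), beta=6)
        assert d[0, 1] == pytest.approx(0.18**3)  # 0.005832

    def test_beta_below_one_rejected(self):
        c = _random_corr_pair(np.random.default_rng(1), 5)
        with pytest.raises(ValueError):
            adjacency_change(c, 0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(3, 15))
            c = _random_corr_pair(rng, n)
            beta = int(rng.integers(1, 9))
            np.testing.assert_allclose(
                adjacency_change(c, beta),
                adjacency_brute_force(c.c1, c.c2, beta),
                atol=1e-12,
            )

    def test_condition_swap_invariance(self):
        rng = np.random.default_rng(3)
        c = _random_corr_pair(rng, 10)
        swapped = CorrelationMatrices(c.gene_order, c.c2, c.c1)
        np.testing.assert_allclose(
            adjacency_change(c, 4), adjacency_change(swapped, 4), atol=1e-14
        )


class TestTopologicalOverlap:
    def test_zero_adjacency(self):
        tom = topological_overlap(np.zeros((4, 4)))
        assert np.all(np.diag(tom) == 1)
        off = tom[~np.eye(4, dtype=bool)]
        assert np.all(off == 0)

    def test_three_gene_hand_value(self):
        d = np.full((3, 3), 0.5)
        np.fill_diagonal(d, 0.0)
        tom = topological_overlap(d)
        assert tom[0, 1] == pytest.approx((0.25 + 0.5) / (1 + 1 - 0.5))

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(3, 13))
            d = rng.uniform(0, 1, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            np.testing.assert_allclose(
                topological_overlap(d), tom_brute_force(d), atol=1e-12
            )

    def test_entries_stay_in_range(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(0, 1, size=(20, 20))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        tom = topological_overlap(d)
        assert np.all((tom >= 0) & (tom <= 1))

    def test_out_of_range_adjacency_rejected(self):
        with pytest.raises(ValueError):
            topological_overlap(np.full((3, 3), 1.5))


class TestConditionCorrelations:
    def test_unit_diagonals_and_sample_order_invariance(self, planted_expression):
        expr, grouping = planted_expression
        c = condition_correlations(expr, grouping)
        assert np.all(np.diag(c.c1) == 1) and np.all(np.diag(c.c2) == 1)
        shuffled = ExpressionMatrix(
            values=expr.values[expr.sample_ids[::-1]], value_kind=expr.value_kind
        )
        c2 = condition_correlations(shuffled, grouping)
        np.testing.assert_allclose(c.c1, c2.c1, atol=1e-12)
        np.testing.assert_allclose(c.c2, c2.c2, atol=1e-12)

    def test_planted_shared_factor_correlation(self):
        truth = synthetic.default_truth(
            n_genes=100, n_modules=1, module_size=30, r_low=0.7, r_high=0.0, n_hubs=0
        )
        groups = {f"s{i:04d}": ("low" if i < 60 else "high") for i in range(120)}
        expr, _ = synthetic.simulate_expression(
            100, groups, truth, nb_dispersion=0.05, seed=8
        )
        logc = ExpressionMatrix(values=np.log2(expr.values + 0.5), value_kind="normalized")
        c = condition_correlations(logc, _grouping(groups))
        idx = [c.gene_order.index(g) for g in sorted(truth.planted_modules["M1"][0])]
        iu = np.triu_indices(len(idx), 1)
        low_mean = c.c1[np.ix_(idx, idx)][iu].mean()
        high_mean = c.c2[np.ix_(idx, idx)][iu].mean()
        assert 0.55 <= low_mean <= 0.85
        assert -0.15 <= high_mean <= 0.15

    def test_zero_variance_gene_warned_and_zeroed(self, caplog):
        vals = np.vstack([np.ones(12), np.arange(12, dtype=float)])
        expr = ExpressionMatrix(
            values=pd.DataFrame(vals, index=["flat", "ok"], columns=[f"s{i}" for i in range(12)]),
            value_kind="normalized",
        )
        labels = {f"s{i}": ("low" if i < 6 else "high") for i in range(12)}
        with caplog.at_level("WARNING"):
            c = condition_correlations(expr, _grouping(labels))
        assert c.c1[0, 1] == 0.0
        assert "zero-variance" in caplog.text


class TestPickSoftThreshold:
    def test_single_candidate_returned(self):
        c = _random_corr_pair(np.random.default_rng(0), 60)
        assert pick_soft_threshold(c, candidates=(6,)) == 6

    def test_scale_free_structure_returns_small_beta(self):
        # hub-like weights give a power-law connectivity at low beta already
        rng = np.random.default_rng(1)
        n = 300
        w = np.clip((np.arange(1, n + 1) / 8.0) ** (-0.7), 0, 0.98)
        rng.shuffle(w)
        c1 = np.sqrt(np.outer(w, w))
        np.fill_diagonal(c1, 1.0)
        c = CorrelationMatrices([f"g{i}" for i in range(n)], c1, np.eye(n))
        beta = pick_soft_threshold(c, candidates=tuple(range(1, 21)), r2_target=0.85)
        assert beta <= 6

    def test_structureless_input_takes_fallback(self, caplog):
        n = 60
        c1 = np.full((n, n), 0.5)
        np.fill_diagonal(c1, 1.0)
        c = CorrelationMatrices([f"g{i}" for i in range(n)], c1, np.eye(n))
        with caplog.at_level("WARNING"):
            beta = pick_soft_threshold(c, candidates=(2, 3, 4))
        assert beta in (2, 3, 4)
        assert "no candidate beta" in caplog.text

    def test_empty_candidates_rejected(self):
        c = _random_corr_pair(np.random.default_rng(2), 10)
        with pytest.raises(ValueError):
            pick_soft_threshold(c, candidates=())


class TestDetectModules:
    def _block_dissim(self, sizes, within=0.8, n_extra=0, seed=0):
        """TOM dissimilarity with planted high-adjacency blocks."""
        n = sum(sizes) + n_extra
        d = np.zeros((n, n))
        start = 0
        rng = np.random.default_rng(seed)
        for size in sizes:
            block = slice(start, start + size)
            d[block, block] = within + rng.uniform(-0.02, 0.02, (size, size))
            start += size
        d = np.clip((d + d.T) / 2, 0, 1)
        np.fill_diagonal(d, 0.0)
        tom = topological_overlap(d)
        genes = [f"g{i}" for i in range(n)]
        return 1 - tom, genes

    def test_two_planted_blocks_recovered_exactly(self):
        dissim, genes = self._block_dissim([50, 50])
        params = DiffCoExParams(beta=2, min_module_size=30, n_perm=1)
        modules = detect_modules(dissim, genes, params)
        groups = {m: set(modules.index[modules == m]) for m in (1, 2)}
        assert {frozenset(g) for g in groups.values()} == {
            frozenset(genes[:50]), frozenset(genes[50:]),
        }

    def test_small_block_left_unassigned(self):
        dissim, genes = self._block_dissim([20], n_extra=80)
        params = DiffCoExParams(beta=2, min_module_size=30, n_perm=1)
        modules = detect_modules(dissim, genes, params)
        assert (modules == 0).all()

    def test_gene_order_permutation_gives_same_partition(self):
        dissim, genes = self._block_dissim([40, 40], n_extra=20)
        params = DiffCoExParams(beta=2, min_module_size=30, n_perm=1)
        base = detect_modules(dissim, genes, params)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(genes))
        permuted = detect_modules(
            dissim[np.ix_(perm, perm)], [genes[i] for i in perm], params
        )
        for m in set(base[base > 0]):
            members = set(base.index[base == m])
            labels = {permuted[g] for g in members}
            assert len(labels) == 1 and labels != {0}

    def test_fewer_genes_than_min_size_all_unassigned(self, caplog):
        dissim = np.zeros((5, 5))
        with caplog.at_level("WARNING"):
            modules = detect_modules(dissim, [f"g{i}" for i in range(5)],
                                     DiffCoExParams(beta=2, n_perm=1))
        assert (modules == 0).all()


class TestDispersion:
    def test_identical_conditions_give_zero(self):
        c = np.random.default_rng(0).normal(size=(6, 6))
        c = np.corrcoef(c)
        assert module_dispersion(c, c.copy(), np.arange(4)) == 0.0

    def test_planted_module_maximally_significant(self, planted_expression, planted_bundle):
        expr, grouping = planted_expression
        truth = planted_bundle["truth"]
        genes = expr.gene_ids
        modules = pd.Series(0, index=pd.Index(genes, name="gene"))
        for i, (name, (members, _, _)) in enumerate(truth.planted_modules.items(), 1):
            modules[modules.index.isin(members)] = i
        params = DiffCoExParams(beta=2, n_perm=1000, seed=5)
        results = module_dispersion_test(expr, grouping, modules, params)
        assert len(results) == 3
        for r in results:
            assert r.p_value == pytest.approx(1 / 1001)

    def test_condition_swap_leaves_dispersion_unchanged(self, planted_expression):
        expr, grouping = planted_expression
        flipped = {"low": "high", "high": "low"}
        swapped = _grouping({s: flipped.get(g, g) for s, g in grouping.labels.items()})
        c = condition_correlations(expr, grouping)
        cs = condition_correlations(expr, swapped)
        idx = np.arange(30)
        assert module_dispersion(c.c1, c.c2, idx) == pytest.approx(
            module_dispersion(cs.c1, cs.c2, idx)
        )

    def test_undersized_module_rejected(self):
        c = np.eye(3)
        with pytest.raises(ValueError):
            module_dispersion(c, c, np.array([0]))
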