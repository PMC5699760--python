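import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepatodimorph import (
    AdjacencyMatrix,
    CorrelationMatrix,
    ExpressionMatrix,
    average_linkage,
    connectivity,
    cut_modules,
    default_cut_height,
    export_edges,
    module_recovery,
    pearson_correlation,
    scale_free_fit,
    select_beta,
    soft_adjacency,
    tom,
)
from hepatodimorph.network import DomainError, FitError, ModuleAssignment

# --------------------------------------------------------------- oracles


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop evaluation of the weighted topological overlap."""
    n = a.shape[0]
    k = a.sum(axis=1)
    omega = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            omega[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return omega


def naive_upgma(d: np.ndarray):
    """O(n^3) UPGMA reference: merge the min-average pair, track sizes.

    Returns a list of ({id_a, id_b}, height) in SciPy id convention.
    """
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}  # cluster id -> leaf members
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            avg = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or avg < best[0]:
                best = (avg, a, b)
        avg, a, b = best
        merges.append(({a, b}, avg))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def ari_formula(labels_a, labels_b) -> float:
    """Adjusted Rand index evaluated directly from the contingency table."""
    from math import comb

    cats_a = sorted(set(labels_a))
    cats_b = sorted(set(labels_b))
    table = np.zeros((len(cats_a), len(cats_b)), dtype=int)
    for x, y in zip(labels_a, labels_b):
        table[cats_a.index(x), cats_b.index(y)] += 1
    n = len(labels_a)
    sum_ij = sum(comb(int(v), 2) for v in table.flat)
    sum_a = sum(comb(int(v), 2) for v in table.sum(axis=1))
    sum_b = sum(comb(int(v), 2) for v in table.sum(axis=0))
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def random_adjacency(rng, n):
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


# ------------------------------------------------------------ correlation


class TestCorrelation:
    def test_duplicate_and_negated_gene(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=10)
        matrix = ExpressionMatrix(
            ["a", "b", "c"], [f"s{i}" for i in range(10)],
            np.vstack([base, base, -base]),
        )
        cor = pearson_correlation(matrix)
        assert cor.values[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert cor.values[0, 2] == pytest.approx(-1.0, abs=1e-12)
        assert np.allclose(np.diag(cor.values), 1.0)

    def test_matches_textbook_formula_on_toy_pair(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 3.0, 8.0])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        r_expect = cov / (x.std() * y.std())
        matrix = ExpressionMatrix(["x", "y"], [f"s{i}" for i in range(5)], np.vstack([x, y]))
        assert pearson_correlation(matrix).values[0, 1] == pytest.approx(r_expect, abs=1e-12)

    def test_zero_variance_gene_rejected(self):
        matrix = ExpressionMatrix(
            ["flat", "ok"], ["s0", "s1", "s2"], np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]])
        )
        with pytest.raises(DomainError, match="flat"):
            pearson_correlation(matrix)


# -------------------------------------------------------------- adjacency


class TestAdjacency:
    def test_power_examples(self):
        cor = CorrelationMatrix(["a", "b"], np.array([[1.0, -0.5], [-0.5, 1.0]]))
        adj6 = soft_adjacency(cor, 6)
        assert adj6.values[0, 1] == pytest.approx(0.5**6)
        adj1 = soft_adjacency(cor, 1)
        assert adj1.values[0, 1] == pytest.approx(0.5)
        assert adj6.values[0, 0] == 0.0

    def test_beta_must_be_positive(self):
        cor = CorrelationMatrix(["a", "b"], np.eye(2))
        with pytest.raises(ValueError):
            soft_adjacency(cor, 0)

    @given(st.floats(0.01, 0.99), st.integers(1, 19))
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing_in_beta(self, r, beta):
        cor = CorrelationMatrix(["a", "b"], np.array([[1.0, r], [r, 1.0]]))
        low = soft_adjacency(cor, beta).values[0, 1]
        high = soft_adjacency(cor, beta + 1).values[0, 1]
        assert high < low

    def test_invariant_at_extreme_correlations(self):
        for r in (0.0, 1.0):
            cor = CorrelationMatrix(["a", "b"], np.array([[1.0, r], [r, 1.0]]))
            assert soft_adjacency(cor, 3).values[0, 1] == soft_adjacency(cor, 9).values[0, 1]


class TestConnectivity:
    def test_complete_zero_and_toy(self):
        ones = np.ones((5, 5)) - np.eye(5)
        assert np.allclose(connectivity(AdjacencyMatrix(list("abcde"), 1, ones)), 4.0)
        zero = np.zeros((4, 4))
        assert np.allclose(connectivity(AdjacencyMatrix(list("abcd"), 1, zero)), 0.0)
        toy = np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        assert connectivity(AdjacencyMatrix(list("abc"), 1, toy)) == pytest.approx(
            [0.5, 0.6, 0.7]
        )


# ---------------------------------------------------------- scale-free fit


class TestScaleFreeFit:
    def test_exact_power_law_fits_perfectly(self):
        # occupied bins hold identical k values, counts proportional to
        # k^-1.5 exactly: 64 x k=1, 8 x k=4, 1 x k=16
        k = np.array([1.0] * 64 + [4.0] * 8 + [16.0])
        fit = scale_free_fit(k, n_bins=10)
        assert fit.slope == pytest.approx(-1.5, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit.signed_index == pytest.approx(1.0, abs=1e-10)
        assert fit.bins_used == 3

    def test_uniform_density_has_zero_signed_index(self):
        # one gene per occupied bin: flat p(k), slope 0
        k = np.linspace(1, 10, 10)
        fit = scale_free_fit(k, n_bins=10)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.signed_index == 0.0

    def test_increasing_density_gets_negative_index(self):
        k = np.array([1.0] + [4.0] * 8 + [16.0] * 64)
        fit = scale_free_fit(k, n_bins=10)
        assert fit.signed_index < 0

    def test_too_few_bins_is_an_error(self):
        with pytest.raises(FitError):
            scale_free_fit(np.array([2.0, 2.0, 2.0]), n_bins=10)


class TestSelectBeta:
    def test_smallest_qualifying_candidate_wins(self):
        # strong power-law-ish structure already at beta=1
        rng = np.random.default_rng(2)
        n = 300
        x = np.zeros((n, 60))
        factor = rng.normal(size=60)
        x[:50] = 0.9 * factor + 0.3 * rng.normal(size=(50, 60))
        x[50:] = rng.normal(size=(n - 50, 60))
        cor = pearson_correlation(ExpressionMatrix(
            [f"g{i}" for i in range(n)], [f"s{j}" for j in range(60)], x))
        beta, fits = select_beta(cor, candidates=range(1, 21), target=0.5)
        qualifying = [f.beta for f in fits if np.isfinite(f.signed_index) and f.signed_index >= 0.5]
        assert beta == min(qualifying)
        assert len(fits) == 20

    def test_fallback_to_argmax_when_no_candidate_qualifies(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(40, 30))
        cor = pearson_correlation(ExpressionMatrix(
            [f"g{i}" for i in range(40)], [f"s{j}" for j in range(30)], x))
        beta, fits = select_beta(cor, candidates=[1, 2, 3], target=1.01)
        finite = [f for f in fits if np.isfinite(f.signed_index)]
        assert beta == max(finite, key=lambda f: f.signed_index).beta


# ---------------------------------------------------------------- TOM


class TestTOM:
    def test_all_zero_adjacency(self):
        omega = tom(AdjacencyMatrix(list("abc"), 6, np.zeros((3, 3)))).values
        assert np.allclose(omega, np.eye(3))

    def test_complete_graph_has_maximal_overlap(self):
        a = np.ones((4, 4)) - np.eye(4)
        omega = tom(AdjacencyMatrix(list("abcd"), 1, a)).values
        assert np.allclose(omega, 1.0)

    @pytest.mark.parametrize("n", [3, 5, 10, 20])
    def test_matches_brute_force(self, n):
        rng = np.random.default_rng(n)
        a = random_adjacency(rng, n)
        omega = tom(AdjacencyMatrix([f"g{i}" for i in range(n)], 2, a)).values
        assert np.allclose(omega, brute_force_tom(a), atol=1e-12, rtol=0)

    @given(st.integers(0, 10_000), st.integers(3, 15))
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_symmetry(self, seed, n):
        rng = np.random.default_rng(seed)
        a = random_adjacency(rng, n)
        omega = tom(AdjacencyMatrix([f"g{i}" for i in range(n)], 2, a)).values
        assert np.all(omega >= 0) and np.all(omega <= 1 + 1e-12)
        assert np.allclose(omega, omega.T)
        assert np.allclose(np.diag(omega), 1.0)

    def test_near_zero_adjacency_tom_is_near_adjacency(self):
        rng = np.random.default_rng(8)
        a = random_adjacency(rng, 12) * 1e-4
        omega = tom(AdjacencyMatrix([f"g{i}" for i in range(12)], 2, a)).values
        off = ~np.eye(12, dtype=bool)
        assert np.allclose(omega[off], a[off], atol=1e-6)

    def test_out_of_range_adjacency_rejected(self):
        bad = np.array([[0.0, 1.5], [1.5, 0.0]])
        with pytest.raises(DomainError):
            tom(AdjacencyMatrix(["a", "b"], 1, bad))


# -------------------------------------------------------------- clustering


class TestAverageLinkage:
    def test_two_blocks_merge_last(self):
        rng = np.random.default_rng(4)
        d = np.full((8, 8), 0.9) + rng.uniform(-0.01, 0.01, (8, 8))
        d[:4, :4] = 0.1 + rng.uniform(-0.01, 0.01, (4, 4))
        d[4:, 4:] = 0.1 + rng.uniform(-0.01, 0.01, (4, 4))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        dendro = average_linkage(d, [f"g{i}" for i in range(8)])
        assert dendro.merges[-1, 2] == pytest.approx(0.9, abs=0.02)
        # the two final children each contain one full block
        asg = cut_modules(dendro, height=0.5, min_size=2)
        blocks = sorted(sorted(v) for v in asg.modules().values())
        assert blocks == [[f"g{i}" for i in range(4)], [f"g{i}" for i in range(4, 8)]]

    def test_two_leaves(self):
        d = np.array([[0.0, 0.42], [0.42, 0.0]])
        dendro = average_linkage(d, ["a", "b"])
        assert dendro.merges.shape == (1, 4)
        assert dendro.merges[0, 2] == pytest.approx(0.42)

    @pytest.mark.parametrize("n", [4, 8, 12, 15])
    def test_matches_naive_reference(self, n):
        rng = np.random.default_rng(100 + n)
        d = rng.uniform(0.1, 1.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        dendro = average_linkage(d, [f"g{i}" for i in range(n)])
        reference = naive_upgma(d)
        assert len(reference) == n - 1
        for row, (pair, height) in zip(dendro.merges, reference):
            assert {int(row[0]), int(row[1])} == pair
            assert row[2] == pytest.approx(height, abs=1e-10)

    def test_asymmetric_input_rejected(self):
        d = np.array([[0.0, 0.5, 0.2], [0.4, 0.0, 0.3], [0.2, 0.3, 0.0]])
        with pytest.raises(DomainError):
            average_linkage(d, ["a", "b", "c"])


class TestCutModules:
    def _simple_dendrogram(self):
        d = np.full((10, 10), 0.95)
        d[:5, :5] = 0.2
        d[5:, 5:] = 0.25
        np.fill_diagonal(d, 0.0)
        return average_linkage(d, [f"g{i}" for i in range(10)])

    def test_cut_above_root_is_one_module(self):
        dendro = self._simple_dendrogram()
        asg = cut_modules(dendro, height=2.0, min_size=3)
        assert len(asg.modules()) == 1
        assert set(next(iter(asg.modules().values()))) == set(dendro.gene_ids)

    def test_cut_below_all_merges_is_all_grey(self):
        dendro = self._simple_dendrogram()
        asg = cut_modules(dendro, height=0.05, min_size=2)
        assert asg.modules() == {}
        assert set(asg.labels.values()) == {"grey"}

    def test_min_size_sends_small_clusters_to_grey(self):
        dendro = self._simple_dendrogram()
        asg = cut_modules(dendro, height=0.5, min_size=6)
        assert asg.modules() == {}

    def test_palette_order_follows_size_rank(self):
        d = np.full((12, 12), 0.95)
        d[:7, :7] = 0.2
        d[7:, 7:] = 0.2
        np.fill_diagonal(d, 0.0)
        dendro = average_linkage(d, [f"g{i:02d}" for i in range(12)])
        asg = cut_modules(dendro, height=0.5, min_size=2)
        mods = asg.modules()
        assert len(mods["turquoise"]) == 7
        assert len(mods["blue"]) == 5

    def test_gap_rule_default_on_planted_blocks(self):
        dendro = self._simple_dendrogram()
        height = default_cut_height(dendro)
        assert 0.25 < height < 0.95
        asg = cut_modules(dendro, min_size=3)
        assert len(asg.modules()) == 2


class TestModuleRecovery:
    def test_identical_partitions(self):
        labels = {f"g{i}": ("blue" if i < 5 else "grey") for i in range(10)}
        truth = {f"g{i}": ("m1" if i < 5 else "background") for i in range(10)}
        assert module_recovery(ModuleAssignment(labels), truth) == pytest.approx(1.0)

    def test_singletons_vs_one_block_is_chance_level(self):
        labels = {f"g{i}": f"c{i}" for i in range(12)}
        truth = {f"g{i}": "m1" for i in range(12)}
        assert abs(module_recovery(ModuleAssignment(labels), truth)) < 1e-9

    def test_matches_direct_ari_formula_on_small_case(self):
        labels = {"a": "m1", "b": "m1", "c": "m2", "d": "m2", "e": "m2", "f": "grey"}
        truth = {"a": "x", "b": "x", "c": "x", "d": "y", "e": "y", "f": "y"}
        genes = sorted(labels)
        expected = ari_formula([labels[g] for g in genes], [truth[g] for g in genes])
        assert module_recovery(ModuleAssignment(labels), truth) == pytest.approx(
            expected, abs=1e-12
        )

    def test_different_universe_rejected(self):
        with pytest.raises(ValueError):
            module_recovery(ModuleAssignment({"a": "m"}), {"b": "m"})


class TestExportEdges:
    def test_threshold_examples(self):
        from hepatodimorph import TOMMatrix

        vals = np.array([[1.0, 0.2, 0.5], [0.2, 1.0, 0.9], [0.5, 0.9, 1.0]])
        m = TOMMatrix(["a", "b", "c"], vals)
        assert export_edges(m, 0.4) == [("a", "c", 0.5), ("b", "c", 0.9)]
        assert len(export_edges(m, 0.0)) == 3
        with pytest.raises(ValueError):
            export_edges(m, 1.01)

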