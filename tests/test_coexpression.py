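import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from coexgwas.coexpression import (
    adjacency,
    build_network,
    detect_modules,
    merge_modules,
    module_eigengene,
    pick_soft_threshold,
    stability_check,
    topological_overlap,
)
from coexgwas.data_io import ExpressionMatrix
from coexgwas.synthetic import SimulationConfig, simulate_expression
from tests.conftest import make_expr


def random_adjacency(rng, n):
    r = rng.uniform(-1, 1, size=(n, n))
    r = (r + r.T) / 2
    a = np.abs(r) ** 3
    np.fill_diagonal(a, 1.0)
    return a


class TestAdjacency:
    def test_perfect_correlation_gives_one(self, rng):
        x = rng.normal(size=20)
        expr = make_expr(np.vstack([x, 2 * x + 1]))
        a = adjacency(expr, power=6)
        assert a[0, 1] == pytest.approx(1.0)

    def test_unsigned_definition(self):
        # r = -0.5 at power 6 -> 0.5^6
        x = np.array([1.0, -1.0, 1.0, -1.0, 0.0, 0.0, 2.0, -2.0])
        y = np.array([-0.5, 0.5, -0.5, 0.5, 0.0, 0.0, -1.0, 1.0])
        r = np.corrcoef(x, y)[0, 1]
        expr = make_expr(np.vstack([x, y]))
        a = adjacency(expr, power=6)
        assert a[0, 1] == pytest.approx(abs(r) ** 6)

    def test_power_one_is_absolute_correlation(self, rng):
        X = rng.normal(size=(5, 30))
        a = adjacency(make_expr(X), power=1)
        np.testing.assert_allclose(a, np.abs(np.corrcoef(X)), atol=1e-12)

    def test_constant_gene_is_error(self):
        expr = make_expr([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="g0"):
            adjacency(expr, power=6)


class TestTopologicalOverlap:
    def test_fully_connected_triple(self):
        a = np.ones((3, 3))
        np.testing.assert_allclose(topological_overlap(a), np.ones((3, 3)))

    def test_three_node_path_hand_computed(self):
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 0.5
        a[1, 2] = a[2, 1] = 0.5
        tom = topological_overlap(a)
        assert tom[0, 2] == pytest.approx(0.25 / 1.5)
        assert tom[0, 1] == pytest.approx((0.5) / (min(0.5, 1.0) + 1 - 0.5))

    def test_block_diagonal_stays_block_diagonal(self, rng):
        blocks = [random_adjacency(rng, 4) for _ in range(2)]
        a = np.zeros((8, 8))
        a[:4, :4] = blocks[0]
        a[4:, 4:] = blocks[1]
        np.fill_diagonal(a, 1.0)
        tom = topological_overlap(a)
        assert np.all(tom[:4, 4:] == 0)

    def test_properties_on_random_adjacency(self, rng):
        for n in (5, 17, 40):
            tom = topological_overlap(random_adjacency(rng, n))
            assert np.allclose(tom, tom.T)
            assert np.allclose(np.diag(tom), 1.0)
            assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12


class TestPickSoftThreshold:
    def test_planted_structure_reaches_target(self):
        cfg = SimulationConfig(seed=2, n_samples=100)
        expr, _, _ = simulate_expression(cfg)
        scan = pick_soft_threshold(expr)
        assert scan.reached_target
        assert 2 <= scan.chosen_power <= 20

    def test_white_noise_takes_fallback_path(self, rng):
        expr = make_expr(rng.normal(size=(100, 60)))
        scan = pick_soft_threshold(expr)
        assert not scan.reached_target
        assert scan.chosen_power in scan.powers

    def test_non_default_powers_honored(self, rng):
        expr = make_expr(rng.normal(size=(50, 40)))
        scan = pick_soft_threshold(expr, powers=[3, 5, 9])
        assert scan.powers == [3, 5, 9]
        assert scan.chosen_power in (3, 5, 9)

    def test_too_few_genes_rejected(self, rng):
        with pytest.raises(ValueError):
            pick_soft_threshold(make_expr(rng.normal(size=(5, 30))))


class TestDetectModules:
    def test_two_planted_blocks_recovered(self, rng):
        truth = np.array([1] * 50 + [2] * 50)
        f1, f2 = rng.normal(size=(2, 120))
        X = np.empty((100, 120))
        for i in range(100):
            f = f1 if truth[i] == 1 else f2
            X[i] = np.sqrt(0.7) * f + np.sqrt(0.3) * rng.normal(size=120)
        expr = make_expr(X)
        part, _ = build_network(expr)
        assert len(part.module_ids) == 2
        assert adjusted_rand_score(truth, part.labels) >= 0.9

    def test_small_block_left_unassigned(self):
        cfg = SimulationConfig(
            seed=5, n_samples=100, n_genes=200, n_modules=1, module_size=10,
            module_cor=0.7,
        )
        expr, labels, _ = simulate_expression(cfg)
        part, _ = build_network(expr)
        assert set(part.labels[labels == 1]) == {0}

    def test_gene_order_permutation_invariance(self, rng):
        cfg = SimulationConfig(seed=9, n_samples=100)
        expr, labels, _ = simulate_expression(cfg)
        part, _ = build_network(expr)
        perm = rng.permutation(expr.n_genes)
        shuffled = ExpressionMatrix(expr.data.iloc[perm])
        part2, _ = build_network(shuffled)
        lab2 = pd.Series(part2.labels, index=part2.gene_ids).loc[part.gene_ids]
        assert adjusted_rand_score(part.labels, lab2) == pytest.approx(1.0)

    def test_fewer_genes_than_min_size_all_unassigned(self, rng):
        tom = topological_overlap(random_adjacency(rng, 10))
        part = detect_modules(tom, min_module_size=30)
        assert part.module_ids == []


class TestModuleEigengene:
    def test_identical_members_give_their_profile(self):
        x = np.arange(10.0)
        expr = make_expr(np.vstack([x, x, x]))
        e = module_eigengene(expr, ["g0", "g1", "g2"])
        c = np.corrcoef(e, x)[0, 1]
        assert c == pytest.approx(1.0)

    def test_sign_convention_invariant_to_global_flip(self, rng):
        X = rng.normal(size=(5, 30))
        X[1:] = X[0] * 0.8 + 0.2 * X[1:]
        e1 = module_eigengene(make_expr(X), [f"g{i}" for i in range(5)])
        e2 = module_eigengene(make_expr(-X), [f"g{i}" for i in range(5)])
        np.testing.assert_allclose(e1, -e2, atol=1e-10)
        # mean correlation with members is non-negative under the convention
        cors = [np.corrcoef(e1, X[i])[0, 1] for i in range(5)]
        assert np.mean(cors) >= 0

    def test_explains_at_least_any_single_member(self, rng):
        X = rng.normal(size=(8, 40))
        expr = make_expr(X)
        ids = [f"g{i}" for i in range(8)]
        e = module_eigengene(expr, ids)
        Xs = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        var_e = np.sum((Xs @ e) ** 2)
        for i in range(8):
            m = Xs[i] / np.linalg.norm(Xs[i])
            assert var_e >= np.sum((Xs @ m) ** 2) - 1e-9

    def test_too_few_members_rejected(self, rng):
        expr = make_expr(rng.normal(size=(3, 10)))
        with pytest.raises(ValueError):
            module_eigengene(expr, ["g0"])


class TestMergeModules:
    def test_duplicated_module_merged(self, rng):
        f = rng.normal(size=100)
        X = np.vstack(
            [0.9 * f + 0.1 * rng.normal(size=(40, 100))]
        )
        expr = make_expr(X)
        labels = np.array([1] * 20 + [2] * 20)  # same factor, two labels
        from coexgwas.coexpression import ModulePartition

        part = ModulePartition(expr.gene_ids, labels)
        merged = merge_modules(part, expr)
        assert len(merged.module_ids) == 1

    def test_orthogonal_modules_unchanged(self, rng):
        f1, f2 = rng.normal(size=(2, 200))
        X = np.vstack(
            [
                0.9 * f1 + 0.2 * rng.normal(size=(30, 200)),
                0.9 * f2 + 0.2 * rng.normal(size=(30, 200)),
            ]
        )
        expr = make_expr(X)
        from coexgwas.coexpression import ModulePartition

        part = ModulePartition(expr.gene_ids, np.array([1] * 30 + [2] * 30))
        merged = merge_modules(part, expr)
        assert len(merged.module_ids) == 2

    def test_merge_count_strictly_decreases(self, planted_expression):
        expr, labels = planted_expression
        from coexgwas.coexpression import ModulePartition

        # split each true module into two labels; merging must reduce count
        split = labels * 2 - (np.arange(len(labels)) % 2) * (labels > 0)
        part = ModulePartition(expr.gene_ids, split.astype(int))
        merged = merge_modules(part, expr, merge_cor=0.8)
        assert len(merged.module_ids) <= len(part.module_ids)


class TestStabilityCheck:
    def test_seed_reproducibility(self, rng):
        cfg = SimulationConfig(seed=4, n_samples=60, n_genes=120, n_modules=2)
        expr, _, _ = simulate_expression(cfg)
        a = stability_check(expr, n_perm=3, seed=5)
        b = stability_check(expr, n_perm=3, seed=5)
        assert a.n_modules.tolist() == b.n_modules.tolist()

    def test_zero_permutations_gives_empty_summary(self, planted_expression):
        expr, _ = planted_expression
        assert stability_check(expr, n_perm=0).empty
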