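import numpy as np
import pytest
from scipy.stats import spearmanr

from conftest import make_genotypes
from epiforest.forest import (
    ForestConfig,
    analyze,
    default_mtry,
    fit_forest,
    gini_importance,
    grow_tree,
    oob_error,
    permutation_importance,
)


def gini_impurity(y):
    if y.size == 0:
        return 0.0
    p1 = y.mean()
    return 1 - p1**2 - (1 - p1) ** 2


def brute_force_best_split(X, y, sample_idx):
    """Exhaustive (variable, cutpoint) search maximizing Gini decrease.

    Ties broken by lowest variable index then lowest cutpoint, mirroring the
    tree grower's deterministic rule.
    """
    ys = y[sample_idx]
    parent = gini_impurity(ys)
    n = sample_idx.size
    best = (0.0, -1, -1)
    for v in range(X.shape[1]):
        xv = X[sample_idx, v]
        for cut in (0, 1):
            left = xv <= cut
            nl = left.sum()
            if nl == 0 or nl == n:
                continue
            d = parent - nl / n * gini_impurity(ys[left]) - (n - nl) / n * gini_impurity(
                ys[~left]
            )
            if d > best[0] + 1e-12:
                best = (d, v, cut)
    return best


def walk_tree_partitions(tree, X):
    """Yield (node_index, member_sample_positions) over internal nodes."""
    stack = [(0, tree.bootstrap_indices)]
    while stack:
        node, members = stack.pop()
        if tree.feature[node] < 0:
            continue
        yield node, members
        going_left = X[members, tree.feature[node]] <= tree.cut[node]
        stack.append((tree.left[node], members[going_left]))
        stack.append((tree.right[node], members[~going_left]))


class TestTreeGrowing:
    def test_separable_case_root_split(self):
        # y perfectly determined by X <= 0 on SNP 2; mtry = p
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, size=(40, 5)).astype(np.int8)
        y = (X[:, 2] > 0).astype(np.int8)
        tree = grow_tree(make_genotypes(X), y, ForestConfig(ntree=1, mtry=5), tree_seed=1)
        assert tree.feature[0] == 2 and tree.cut[0] == 0
        # both children pure leaves
        assert tree.feature[tree.left[0]] == -1 and tree.feature[tree.right[0]] == -1

    def test_hand_computed_gini_gain(self):
        # balanced node (5,5) split into pure (5,0)/(0,5): decrease = 0.5
        X = np.repeat([[0], [2]], 5, axis=0).astype(np.int8)
        y = np.repeat([0, 1], 5).astype(np.int8)
        d, v, cut = brute_force_best_split(X, y, np.arange(10))
        assert d == pytest.approx(0.5, abs=1e-12) and v == 0

    def test_every_node_split_matches_exhaustive_oracle(self):
        # with mtry = p the grower's choice must equal the brute-force optimum
        rng = np.random.default_rng(42)
        for trial in range(30):
            X = rng.integers(0, 3, size=(20, 8)).astype(np.int8)
            y = rng.integers(0, 2, size=20).astype(np.int8)
            if y.min() == y.max():
                continue
            tree = grow_tree(make_genotypes(X), y, ForestConfig(ntree=1, mtry=8), trial)
            for node, members in walk_tree_partitions(tree, X):
                d, v, cut = brute_force_best_split(X, y, members)
                assert (v, cut) == (tree.feature[node], tree.cut[node]), f"trial {trial}"
                node_gain = tree.gain[node] * tree.bootstrap_indices.size / members.size
                assert node_gain == pytest.approx(d, abs=1e-9)

    def test_single_class_input_yields_stump(self):
        X = np.zeros((10, 3), dtype=np.int8)
        y = np.ones(10, dtype=np.int8)
        tree = grow_tree(make_genotypes(X), y, ForestConfig(ntree=1, mtry=3), 0)
        assert tree.feature[0] == -1 and tree.pred[0] == 1


class TestForestFitting:
    def test_determinism(self, strong_signal_data):
        G, y = strong_signal_data
        cfg = ForestConfig(ntree=20, mtry=3, seed=5)
        f1, f2 = fit_forest(G, y, cfg), fit_forest(G, y, cfg)
        for t1, t2 in zip(f1.trees, f2.trees):
            np.testing.assert_array_equal(t1.feature, t2.feature)
            np.testing.assert_array_equal(t1.bootstrap_indices, t2.bootstrap_indices)
            np.testing.assert_array_equal(t1.oob_indices, t2.oob_indices)

    def test_oob_fraction_matches_bootstrap_exclusion(self):
        # P(excluded) = (1 - 1/n)^n ~ 0.368 at n = 1000
        G = make_genotypes(np.random.default_rng(1).integers(0, 3, (1000, 5)))
        y = (np.random.default_rng(2).random(1000) < 0.5).astype(np.int8)
        forest = fit_forest(G, y, ForestConfig(ntree=100, mtry=2, seed=3))
        frac = np.mean([t.oob_indices.size / 1000 for t in forest.trees])
        assert frac == pytest.approx((1 - 1 / 1000) ** 1000, abs=0.005)

    def test_single_tree_forest_prediction_is_tree_prediction(self, strong_signal_data):
        G, y = strong_signal_data
        forest = fit_forest(G, y, ForestConfig(ntree=1, mtry=10, seed=7))
        tree = forest.trees[0]
        preds = tree.predict(G.values, tree.oob_indices)
        err = oob_error(forest, G, y)
        assert err == pytest.approx(np.mean(preds != y[tree.oob_indices]))

    def test_default_mtry_is_tenth_of_panel(self):
        assert default_mtry(1000) == 100
        assert default_mtry(5) == 1  # floors at one candidate


class TestOOBError:
    def test_null_phenotype_near_half(self):
        # single-dataset OOB error is noisy (votes share trees), so average
        # over a few independent null datasets
        from epiforest.gensim import simulate_independent_genotypes

        errs = []
        for seed in range(4):
            G = simulate_independent_genotypes(500, [0.3] * 12, seed=60 + seed)
            y = np.zeros(500, dtype=np.int8)
            y[np.random.default_rng(70 + seed).permutation(500)[:250]] = 1
            errs.append(oob_error(fit_forest(G, y, ForestConfig(ntree=250, mtry=4, seed=9)), G, y))
        assert np.mean(errs) == pytest.approx(0.5, abs=0.03)

    def test_separable_phenotype_near_zero(self):
        G = make_genotypes(
            np.random.default_rng(3).integers(0, 3, (400, 1)), mafs=[0.5]
        )
        y = (G.values[:, 0] > 0).astype(np.int8)
        forest = fit_forest(G, y, ForestConfig(ntree=101, mtry=1, seed=11))
        assert oob_error(forest, G, y) < 0.05

    def test_comparable_to_reference_implementation(self, strong_signal_data):
        sklearn_ensemble = pytest.importorskip("sklearn.ensemble")
        G, y = strong_signal_data
        ours = oob_error(fit_forest(G, y, ForestConfig(ntree=300, mtry=3, seed=13)), G, y)
        ref = sklearn_ensemble.RandomForestClassifier(
            n_estimators=300, max_features=3, oob_score=True, random_state=0
        ).fit(G.values, y)
        assert ours == pytest.approx(1 - ref.oob_score_, abs=0.05)


class TestImportance:
    def test_unused_variable_has_zero_importance(self, strong_signal_data):
        G, y = strong_signal_data
        # add a constant SNP that can never split
        X = np.hstack([G.values, np.zeros((G.n, 1), dtype=np.int8)])
        Gc = make_genotypes(X, mafs=list(G.mafs) + [0.3])
        forest = fit_forest(Gc, y, ForestConfig(ntree=50, mtry=11, seed=15))
        assert all(10 not in t.used_vars for t in forest.trees)
        raw, scaled, meng = permutation_importance(forest, Gc, y, seed=16)
        assert raw[10] == 0.0 and scaled[10] == 0.0 and meng[10] == 0.0
        assert gini_importance(forest)[10] == 0.0

    def test_causal_snp_tops_raw_mda(self):
        # strong single causal SNP among 10: best raw MDA in >= 18/20 replicates
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            from epiforest.gensim import simulate_independent_genotypes

            G = simulate_independent_genotypes(250, [0.3] * 10, rng)
            y = ((G.values[:, 4] + rng.normal(0, 0.8, 250)) > 0.5).astype(np.int8)
            rep_out = analyze(G, y, ForestConfig(ntree=100, mtry=3, seed=rep))
            wins += int(np.argmax(rep_out.raw_mda) == 4)
        assert wins >= 18

    def test_constant_oob_column_gives_zero_decrease(self):
        # permuting a column that is constant over the OOB set is a no-op
        X = np.zeros((30, 2), dtype=np.int8)
        X[:15, 0] = 2
        X[:, 1] = np.tile([0, 1, 2], 10)
        y = (X[:, 0] > 0).astype(np.int8)
        G = make_genotypes(X)
        forest = fit_forest(G, y, ForestConfig(ntree=40, mtry=2, seed=17))
        raw, _, _ = permutation_importance(forest, G, y, seed=18)
        # SNP 0 fully determines y, but only trees whose OOB set mixes both
        # genotype groups can register a decrease; assert it is non-negative
        # and strictly positive overall
        assert raw[0] > 0

    def test_single_split_tree_gini_value(self):
        # root-only tree splitting a balanced node to purity: score = 0.5
        X = np.repeat([[0], [2]], 20, axis=0).astype(np.int8)
        y = np.repeat([0, 1], 20).astype(np.int8)
        forest = fit_forest(make_genotypes(X), y, ForestConfig(ntree=1, mtry=1, seed=19))
        tree = forest.trees[0]
        yb = y[tree.bootstrap_indices]
        expected = gini_impurity(yb)  # impurity fully removed at the root
        assert gini_importance(forest)[0] == pytest.approx(expected, abs=1e-12)

    def test_gini_accounting_identity(self, strong_signal_data):
        # per-tree sum of weighted gains equals total impurity reduction of
        # the tree's leaf partition
        G, y = strong_signal_data
        forest = fit_forest(G, y, ForestConfig(ntree=5, mtry=10, seed=23))
        for tree in forest.trees:
            n_inbag = tree.bootstrap_indices.size
            total_gain = tree.gain.sum()
            yb = y[tree.bootstrap_indices]
            leaf_impurity = 0.0
            stack = [(0, tree.bootstrap_indices)]
            while stack:
                node, members = stack.pop()
                if tree.feature[node] < 0:
                    leaf_impurity += members.size / n_inbag * gini_impurity(y[members])
                    continue
                going_left = G.values[members, tree.feature[node]] <= tree.cut[node]
                stack.append((tree.left[node], members[going_left]))
                stack.append((tree.right[node], members[~going_left]))
            assert total_gain == pytest.approx(gini_impurity(yb) - leaf_impurity, abs=1e-9)

    def test_half_forest_rank_stability(self):
        # raw-MDA ranking agrees between two independent half-forests on a
        # graded-signal panel (effect strength increases with SNP index, so
        # the true ordering is meaningful across the whole panel)
        from epiforest.gensim import simulate_independent_genotypes

        rng = np.random.default_rng(55)
        G = simulate_independent_genotypes(400, [0.3] * 8, rng)
        betas = np.linspace(0.0, 1.4, 8)
        y = ((G.values @ betas + rng.normal(0, 1.0, 400)) > np.median(G.values @ betas)).astype(
            np.int8
        )
        r1 = analyze(G, y, ForestConfig(ntree=250, mtry=3, seed=31)).raw_mda
        r2 = analyze(G, y, ForestConfig(ntree=250, mtry=3, seed=32)).raw_mda
        assert spearmanr(r1, r2).statistic > 0.8

    def test_meng_equals_raw_scaled_by_usage(self, strong_signal_data):
        G, y = strong_signal_data
        forest = fit_forest(G, y, ForestConfig(ntree=60, mtry=3, seed=33))
        raw, _, meng = permutation_importance(forest, G, y, seed=34)
        used = np.zeros(G.p)
        for t in forest.trees:
            used[t.used_vars] += 1
        mask = used > 0
        np.testing.assert_allclose(meng[mask], raw[mask] * 60 / used[mask], atol=1e-12)
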