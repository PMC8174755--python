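import itertools

import numpy as np
import pytest
from skbio import TreeNode

from rhizovar.community import (
    DistanceMatrix,
    bray_curtis,
    constrained_pcoa,
    distance_matrix,
    pcoa,
    permanova,
    shannon,
    t_test,
    weighted_unifrac,
)
from rhizovar.io import AsvTable, ValidationError
from tests.conftest import one_factor_designs


class TestShannon:
    @pytest.mark.parametrize("counts,expected", [
        ((10, 10, 10, 10), np.log(4)),
        ((5, 0, 0), 0.0),
        ((1, 2, 3), 1.0114),
    ])
    def test_values(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected, abs=1e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            shannon((0, 0))


class TestBrayCurtis:
    @pytest.mark.parametrize("x,y,expected", [
        ((1, 2, 3), (1, 2, 3), 0.0),
        ((1, 0, 2), (0, 3, 0), 1.0),
        ((2, 2, 0), (0, 2, 4), 0.6),
    ])
    def test_values(self, x, y, expected):
        assert bray_curtis(x, y) == pytest.approx(expected)

    def test_both_zero_rejected(self):
        with pytest.raises(ValidationError):
            bray_curtis((0, 0), (0, 0))


def _brute_force_unifrac(x, y, tree, ids, normalized):
    """Independent oracle: enumerate every branch, collect descendant tips
    by direct traversal, accumulate the weighted differences."""
    p = np.asarray(x, float) / np.sum(x)
    q = np.asarray(y, float) / np.sum(y)
    idx = {a: i for i, a in enumerate(ids)}
    num = 0.0
    den = 0.0
    for node in tree.traverse(include_self=False):
        tips = [t.name for t in node.tips(include_self=True)]
        pb = sum(p[idx[t]] for t in tips if t in idx)
        qb = sum(q[idx[t]] for t in tips if t in idx)
        num += (node.length or 0.0) * abs(pb - qb)
        den += (node.length or 0.0) * (pb + qb)
    return num / den if normalized else num


class TestWeightedUnifrac:
    def test_identical_samples_zero(self):
        tree = TreeNode.read(["((A:1,B:1):1,C:2);"])
        assert weighted_unifrac((1, 2, 3), (2, 4, 6), tree, ["A", "B", "C"]) == pytest.approx(0.0)

    def test_disjoint_subtrees_hand_computed(self):
        tree = TreeNode.read(["((A:1,B:1):1,C:2);"])
        raw = weighted_unifrac((10, 0, 0), (0, 0, 10), tree, ["A", "B", "C"], normalized=False)
        norm = weighted_unifrac((10, 0, 0), (0, 0, 10), tree, ["A", "B", "C"], normalized=True)
        assert raw == pytest.approx(4.0)
        assert norm == pytest.approx(1.0)

    @pytest.mark.parametrize("normalized", [True, False])
    def test_matches_brute_force_on_random_trees(self, normalized, rng):
        for _ in range(50):
            n = 10
            names = [f"L{i}" for i in range(n)]
            nodes = [TreeNode(name=nm, length=float(rng.uniform(0.1, 2))) for nm in names]
            while len(nodes) > 1:
                i, j = sorted(rng.choice(len(nodes), 2, replace=False))
                merged = TreeNode(children=[nodes[j], nodes[i]],
                                  length=float(rng.uniform(0.1, 2)))
                nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [merged]
            tree = nodes[0]
            x = rng.integers(0, 20, n) + (rng.random(n) < 0.5)
            y = rng.integers(0, 20, n) + (rng.random(n) < 0.5)
            x[0] += 1
            y[-1] += 1
            ours = weighted_unifrac(x, y, tree, names, normalized=normalized)
            oracle = _brute_force_unifrac(x, y, tree, names, normalized)
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_agrees_with_skbio(self, rng):
        from skbio.diversity.beta import weighted_unifrac as sk_unifrac

        tree = TreeNode.read(["(((A:0.4,B:0.6):0.3,C:0.8):0.2,(D:0.5,E:0.5):0.7);"])
        ids = list("ABCDE")
        for _ in range(10):
            x = rng.integers(0, 30, 5) + 1
            y = rng.integers(0, 30, 5) + 1
            ours = weighted_unifrac(x, y, tree, ids, normalized=True)
            ref = sk_unifrac(x, y, taxa=ids, tree=tree, normalized=True)
            assert ours == pytest.approx(float(ref), abs=1e-10)

    def test_missing_leaf_named_in_error(self):
        tree = TreeNode.read(["((A:1,B:1):1,C:2);"])
        with pytest.raises(ValidationError, match="ZZ"):
            weighted_unifrac((1, 1), (1, 1), tree, ["A", "ZZ"])


class TestPcoa:
    def test_three_equidistant_points(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(["a", "b", "c"], d, "bray_curtis"))
        np.testing.assert_allclose(sorted(res.eigenvalues, reverse=True), [0.5, 0.5, 0.0], atol=1e-12)
        np.testing.assert_allclose(res.percent_explained, [50.0, 50.0], atol=1e-9)

    def test_points_on_a_line_recovered(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        d = np.abs(x[:, None] - x[None, :])
        res = pcoa(DistanceMatrix(list("abcd"), d, "bray_curtis"))
        axis1 = res.coordinates[:, 0]
        gaps = np.diff(np.sort(axis1))
        np.testing.assert_allclose(sorted(gaps), [1.0, 2.0, 3.0], atol=1e-9)

    def test_reconstruction_of_euclidean_distances(self, rng):
        pts = rng.normal(size=(8, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(8)], d, "bray_curtis"))
        coords = res.coordinates
        rec = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.testing.assert_allclose(rec, d, atol=1e-9)

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            pcoa(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]]), "bray_curtis"))


def _oracle_permanova_f(d, groups):
    """Direct-formula pseudo-F for a one-factor design (independent path)."""
    n = len(groups)
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    levels = sorted(set(groups))
    x = np.column_stack([np.ones(n)] + [[1.0 if gr == l else 0.0 for gr in groups] for l in levels[1:]])
    h = x @ np.linalg.pinv(x.T @ x) @ x.T
    h0 = np.ones((n, n)) / n
    ss_term = np.trace(h @ g) - np.trace(h0 @ g)
    ss_res = np.trace(g) - np.trace(h @ g)
    df1 = len(levels) - 1
    df2 = n - len(levels)
    return (ss_term / df1) / (ss_res / df2)


class TestPermanova:
    def test_exact_enumeration_two_groups(self, rng):
        designs = one_factor_designs(["stdN", "stdN", "lowN", "lowN"], factor="nitrogen")
        pts = np.array([[0.0], [0.3], [2.0], [2.5]])
        d = np.abs(pts - pts.T)
        dm = DistanceMatrix([x.sample_id for x in designs], d, "bray_curtis")
        groups = ["stdN", "stdN", "lowN", "lowN"]
        f_obs = _oracle_permanova_f(d, groups)
        count = 0
        total = 0
        for perm in itertools.permutations(range(4)):
            dp = d[np.ix_(perm, perm)]
            total += 1
            if _oracle_permanova_f(dp, groups) >= f_obs - 1e-12:
                count += 1
        p_exact = count / total
        res = permanova(dm, designs, ["nitrogen"], n_perm=4999, seed=1)
        assert res.pseudo_f["nitrogen"] == pytest.approx(f_obs, abs=1e-9)
        assert res.p["nitrogen"] == pytest.approx(p_exact, abs=0.02)

    def test_decomposition_identity(self, rng):
        designs = one_factor_designs(
            ["M", "S", "MS", "SM"] * 4, factor="plot"
        )
        pts = rng.normal(size=(16, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = DistanceMatrix([x.sample_id for x in designs], d, "bray_curtis")
        res = permanova(dm, designs, ["species", "rotation"], n_perm=49, seed=2)
        assert sum(res.ss.values()) + res.residual_ss == pytest.approx(res.total_ss, abs=1e-9)

    def test_irrelevant_factor_explains_little(self, rng):
        designs = one_factor_designs(["stdN", "lowN"] * 10, factor="nitrogen")
        pts = rng.normal(size=(20, 5))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = DistanceMatrix([x.sample_id for x in designs], d, "bray_curtis")
        res = permanova(dm, designs, ["nitrogen"], n_perm=99, seed=3)
        assert res.r2["nitrogen"] < 0.2

    def test_single_level_term_rejected(self, rng):
        designs = one_factor_designs(["stdN"] * 4, factor="nitrogen")
        d = np.abs(rng.normal(size=(4, 1)) - rng.normal(size=(1, 4)))
        np.fill_diagonal(d, 0)
        d = (d + d.T) / 2
        dm = DistanceMatrix([x.sample_id for x in designs], d, "bray_curtis")
        with pytest.raises(ValidationError, match="single level"):
            permanova(dm, designs, ["nitrogen"], n_perm=9, seed=0)


class TestConstrainedPcoa:
    def test_inertia_decomposition(self, rng):
        designs = one_factor_designs(["stdN", "lowN"] * 6, factor="nitrogen")
        pts = rng.normal(size=(12, 4))
        pts[:, 0] += np.array([1.5, 0.0] * 6)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = DistanceMatrix([x.sample_id for x in designs], d, "bray_curtis")
        res = constrained_pcoa(dm, designs, ["nitrogen"])
        total = pcoa(dm).eigenvalues.sum()
        constrained = res.eigenvalues[res.eigenvalues > 1e-10].sum()
        # residual inertia computed independently
        assert constrained <= total + 1e-9
        assert res.percent_explained[0] > 0

    def test_binary_constraint_separates_groups(self, rng):
        designs = one_factor_designs(["stdN", "lowN"] * 8, factor="nitrogen")
        pts = rng.normal(size=(16, 3))
        pts[:, 0] += np.array([3.0, 0.0] * 8)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = DistanceMatrix([x.sample_id for x in designs], d, "bray_curtis")
        res = constrained_pcoa(dm, designs, ["nitrogen"])
        axis1 = res.coordinates[:, 0]
        std_scores = axis1[::2]
        low_scores = axis1[1::2]
        assert (std_scores.mean() - low_scores.mean()) ** 2 > 1.0

    def test_shuffled_labels_explain_almost_nothing(self, rng):
        labels = ["stdN", "lowN"] * 10
        designs = one_factor_designs(labels, factor="nitrogen")
        pts = rng.normal(size=(20, 5))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = DistanceMatrix([x.sample_id for x in designs], d, "bray_curtis")
        res = constrained_pcoa(dm, designs, ["nitrogen"])
        total = pcoa(dm).eigenvalues
        total = total[total > 0].sum()
        constrained = res.eigenvalues[res.eigenvalues > 1e-10].sum()
        assert constrained / total < 0.25

    def test_aliased_constraint_rejected(self, rng):
        designs = one_factor_designs(["M", "S"] * 4, factor="plot")
        pts = rng.normal(size=(8, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = DistanceMatrix([x.sample_id for x in designs], d, "bray_curtis")
        # species is a deterministic function of plot here -> aliased
        with pytest.raises(ValidationError, match="aliased"):
            constrained_pcoa(dm, designs, ["plot", "species"])


class TestWelchT:
    def test_identical_samples(self):
        t, p = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_welch(self):
        t, p = t_test([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert p == pytest.approx(0.2879, abs=1e-4)

    def test_one_tailed_is_half_two_tailed_on_hypothesized_side(self):
        t2, p2 = t_test([1, 2, 3], [2, 3, 4], tails="two")
        t1, p1 = t_test([1, 2, 3], [2, 3, 4], tails="one", side="less")
        assert p1 == pytest.approx(p2 / 2)
        assert t1 == pytest.approx(t2)

    def test_degenerate_equal_constant_groups(self):
        t, p = t_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)


class TestDistanceMatrixBuilder:
    def test_metric_properties_on_simulation(self, small_dataset, full_design):
        table = small_dataset["table"]
        sub = AsvTable(table.counts[:12], table.sample_ids[:12], table.asv_ids)
        dm_bc = distance_matrix(sub, metric="bray_curtis")
        dm_wu = distance_matrix(sub, metric="weighted_unifrac", tree=small_dataset["tree"])
        for dm in (dm_bc, dm_wu):
            assert np.allclose(dm.d, dm.d.T)
            assert np.all(np.diag(dm.d) == 0)
            assert dm.d.min() >= 0
            assert dm.d.max() <= 1 + 1e-12

    def test_unifrac_matrix_matches_pairwise_function(self, small_dataset):
        table = small_dataset["table"]
        tree = small_dataset["tree"]
        sub = AsvTable(table.counts[:5], table.sample_ids[:5], table.asv_ids)
        dm = distance_matrix(sub, metric="weighted_unifrac", tree=tree)
        for i in range(5):
            for j in range(i + 1, 5):
                ref = weighted_unifrac(sub.counts[i], sub.counts[j], tree, sub.asv_ids)
                assert dm.d[i, j] == pytest.approx(ref, abs=1e-12)
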