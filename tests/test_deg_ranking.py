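import itertools
import math

import numpy as np
import pytest
from scipy.stats import rankdata

from degprune import (
    ExpressionMatrix,
    GroupDesign,
    PruningParams,
    SimulationConfig,
    compute_features,
    prune,
    rank_genes,
    score_fold_change,
    score_rank_product,
    score_ttest,
    score_wad,
    simulate,
)

from conftest import features_from_points


def _matrix(values, n_a, n_b):
    values = np.asarray(values, dtype=float)
    ids = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    design = GroupDesign({s: s[0].upper() for s in ids})
    return ExpressionMatrix(
        [f"g{i}" for i in range(values.shape[0])], ids, values, design
    )


class TestFoldChange:
    def test_score_is_absolute_log_ratio(self):
        # log2 means 2 vs 4: a 4-fold change scores 2.0; the conventional
        # 2-fold significance cutoff corresponds to a score of 1.0
        f = features_from_points(ag=[3.0], ad=[2.0])
        assert score_fold_change(f)[0] == 2.0

    def test_identical_means_score_zero(self):
        f = features_from_points(ag=[5.0], ad=[0.0])
        assert score_fold_change(f)[0] == 0.0

    def test_matches_mean_difference_oracle(self):
        matrix, _ = simulate(SimulationConfig(n_genes=200, n_deg=10, seed=4))
        f = compute_features(matrix)
        np.testing.assert_allclose(
            score_fold_change(f), np.abs(f.mean_a - f.mean_b), rtol=0, atol=0
        )


class TestTTest:
    def test_textbook_pooled_t(self):
        m = _matrix([[1, 2, 3, 4, 5, 6]], 3, 3)
        f = compute_features(m)
        # means 2 and 5, pooled s^2 = 1, |t| = 3 / sqrt(2/3)
        expected = 3.0 / math.sqrt(2.0 / 3.0)
        assert score_ttest(m, f)[0] == pytest.approx(expected, abs=1e-6)

    def test_equal_means_score_zero(self):
        m = _matrix([[1, 3, 1, 3]], 2, 2)
        f = compute_features(m)
        assert score_ttest(m, f)[0] == 0.0

    def test_zero_variance_gene_gets_finite_large_score(self):
        m = _matrix([[2, 2, 3, 3], [2, 4, 3, 5]], 2, 2)
        f = compute_features(m)
        scores = score_ttest(m, f, variance_floor=1e-8)
        assert np.isfinite(scores[0])
        # |diff|=1, se^2 = floor -> 1/sqrt(1e-8) = 1e4
        assert scores[0] == pytest.approx(1e4, rel=1e-6)
        assert scores[0] > scores[1]  # ranked above the noisy gene

    def test_welch_flag_uses_unpooled_variances(self):
        m = _matrix([[0, 0.2, 0.4, 5, 6, 7, 8, 9]], 3, 5)
        f = compute_features(m)
        va, vb = f.var_a[0], f.var_b[0]
        expected = abs(f.mean_a[0] - f.mean_b[0]) / math.sqrt(va / 3 + vb / 5 + 1e-8)
        assert score_ttest(m, f, welch=True)[0] == pytest.approx(expected, rel=1e-12)

    def test_requires_two_samples_per_condition(self):
        m = _matrix([[1, 2, 3]], 1, 2)
        with pytest.raises(ValueError, match="fold change or rank product"):
            score_ttest(m)


def brute_force_rank_product(values, n_a, n_b):
    """Enumerate every (A, B) sample pair and its full rank lists."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    up_ranks = [[] for _ in range(n)]
    down_ranks = [[] for _ in range(n)]
    for a, b in itertools.product(range(n_a), range(n_a, n_a + n_b)):
        diff = values[:, b] - values[:, a]
        ru = rankdata(-diff)
        rd = rankdata(diff)
        for i in range(n):
            up_ranks[i].append(ru[i])
            down_ranks[i].append(rd[i])
    scores = np.empty(n)
    for i in range(n):
        rp_up = math.prod(up_ranks[i]) ** (1.0 / len(up_ranks[i]))
        rp_down = math.prod(down_ranks[i]) ** (1.0 / len(down_ranks[i]))
        scores[i] = -math.log(min(rp_up, rp_down))
    return scores


class TestRankProduct:
    def test_single_pair_matches_fold_change_order_on_balanced_directions(self):
        # pairwise diffs 8, -6, 4, -2: with up- and down-regulation strengths
        # interleaved, the min(RP_up, RP_down) order coincides with |diff|
        # order. (In general the two-sided combination ranks the weakest
        # gene as the top "down" candidate, so exact FC-order identity holds
        # only on such direction-balanced inputs.)
        m = _matrix([[1, 9], [9, 3], [2, 6], [5, 3]], 1, 1)
        f = compute_features(m)
        rp_order = rank_genes(score_rank_product(m)).order
        fc_order = rank_genes(score_fold_change(f)).order
        np.testing.assert_array_equal(rp_order, fc_order)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(17)
        for n_a, n_b in [(2, 1), (2, 3), (3, 3)]:
            values = rng.normal(5, 1, size=(5, n_a + n_b))
            m = _matrix(values, n_a, n_b)
            np.testing.assert_allclose(
                score_rank_product(m),
                brute_force_rank_product(values, n_a, n_b),
                rtol=0,
                atol=1e-10,
            )

    def test_constant_matrix_ties_everything(self):
        m = _matrix(np.full((6, 4), 3.0), 2, 2)
        scores = score_rank_product(m)
        assert np.all(scores == scores[0])
        # all ranks tied at (N+1)/2
        assert scores[0] == pytest.approx(-math.log((6 + 1) / 2))


class TestWad:
    def test_normalization_endpoints(self):
        f = features_from_points(ag=[1.0, 3.0, 5.0], ad=[2.0, 2.0, 2.0])
        scores = score_wad(f)
        assert scores[2] == 2.0  # max-ag gene: weight 1, score = its ad
        assert scores[0] == 0.0  # min-ag gene: score 0 regardless of ad
        assert scores[1] == 1.0

    def test_constant_ag_degenerates_to_fold_change(self):
        f = features_from_points(ag=[4.0, 4.0, 4.0], ad=[1.0, 3.0, 2.0])
        np.testing.assert_array_equal(score_wad(f), [1.0, 3.0, 2.0])

    def test_matches_minmax_multiply_oracle(self):
        rng = np.random.default_rng(23)
        ag = rng.normal(7, 1.5, 100)
        ad = np.abs(rng.normal(0, 1, 100))
        f = features_from_points(ag, ad)
        w = (ag - ag.min()) / (ag.max() - ag.min())
        np.testing.assert_allclose(score_wad(f), ad * w, rtol=0, atol=1e-12)


class TestRankGenes:
    def test_descending_order(self):
        np.testing.assert_array_equal(rank_genes(np.array([3.0, 1.0, 2.0])).order, [0, 2, 1])

    def test_ties_broken_by_input_order(self):
        np.testing.assert_array_equal(rank_genes(np.array([2.0, 2.0, 1.0])).order, [0, 1, 2])

    def test_append_mode_puts_survivors_first(self):
        pruning = prune(
            features_from_points([0, 10, 0, 20], [0, 10, 0, 20]), PruningParams(1.0, 1)
        )
        np.testing.assert_array_equal(pruning.survivor_mask, [False, True, False, True])
        r = rank_genes(np.array([9.0, 1.0, 8.0, 2.0]), pruning=pruning, mode="append")
        np.testing.assert_array_equal(r.order, [3, 1, 0, 2])

    def test_exclude_mode_drops_pruned_genes(self):
        pruning = prune(
            features_from_points([0, 10, 0, 20], [0, 10, 0, 20]), PruningParams(1.0, 1)
        )
        r = rank_genes(np.array([9.0, 1.0, 8.0, 2.0]), pruning=pruning, mode="exclude")
        np.testing.assert_array_equal(r.order, [3, 1])

    def test_rejects_non_finite_scores(self):
        with pytest.raises(ValueError):
            rank_genes(np.array([1.0, np.nan]))


class TestProperties:
    def test_scores_invariant_to_condition_swap(self, tiny_matrix):
        f = compute_features(tiny_matrix)
        flipped = {
            s: ("B" if c == "A" else "A")
            for s, c in tiny_matrix.design.assignment.items()
        }
        swapped = tiny_matrix.with_design(GroupDesign(flipped))
        g = compute_features(swapped)
        np.testing.assert_allclose(score_fold_change(f), score_fold_change(g))
        np.testing.assert_allclose(score_wad(f), score_wad(g))
        np.testing.assert_allclose(
            score_ttest(tiny_matrix, f), score_ttest(swapped, g), rtol=1e-12
        )

    def test_append_mode_never_worsens_a_kept_genes_rank(self):
        matrix, truth = simulate(SimulationConfig(n_genes=800, n_deg=30, seed=13))
        f = compute_features(matrix)
        pruning = prune(f, PruningParams(0.2, 4))
        scores = score_wad(f)
        plain = rank_genes(scores)
        pruned = rank_genes(scores, pruning=pruning, mode="append")
        rank_plain = np.empty(800, dtype=int)
        rank_plain[plain.order] = np.arange(800)
        rank_pruned = np.empty(800, dtype=int)
        rank_pruned[pruned.order] = np.arange(800)
        kept = pruning.survivor_mask
        assert np.all(rank_pruned[kept] <= rank_plain[kept])
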