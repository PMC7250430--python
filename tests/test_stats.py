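import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_dunn_z, brute_force_kruskal
from ventgrowth.simulate import simulate_rate_table
from ventgrowth.stats import (
    PairwiseResult,
    StatsError,
    aligned_rank_transform,
    art_anova,
    brown_forsythe,
    dunn_test,
    kruskal_wallis,
    letter_display,
    shapiro_wilk,
)


class TestDistributionChecks:
    def test_shapiro_accepts_normal_samples(self):
        hits = sum(
            shapiro_wilk(np.random.default_rng(s).normal(size=200))[1] > 0.05
            for s in range(100)
        )
        assert hits >= 90

    def test_shapiro_rejects_exponential_samples(self):
        hits = sum(
            shapiro_wilk(np.random.default_rng(s).exponential(size=200))[1] < 0.05
            for s in range(100)
        )
        assert hits >= 99

    def test_shapiro_needs_three_points(self):
        with pytest.raises(StatsError):
            shapiro_wilk([1.0, 2.0])

    def test_brown_forsythe_nominal_size_under_null(self):
        rej = sum(
            brown_forsythe(
                np.random.default_rng(2 * s).normal(size=50),
                np.random.default_rng(2 * s + 1).normal(size=50),
            )[1] < 0.05
            for s in range(300)
        )
        assert 0.01 <= rej / 300 <= 0.10

    def test_brown_forsythe_detects_variance_ratio(self):
        hits = sum(
            brown_forsythe(
                np.random.default_rng(2 * s).normal(scale=1.0, size=50),
                np.random.default_rng(2 * s + 1).normal(scale=10.0, size=50),
            )[1] < 0.001
            for s in range(100)
        )
        assert hits >= 99

    def test_brown_forsythe_degenerate_input_warns_not_rejects(self):
        with pytest.warns(RuntimeWarning):
            stat, p = brown_forsythe([1.0, 1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_brown_forsythe_small_group_rejected(self):
        with pytest.raises(StatsError):
            brown_forsythe([1.0, 2.0], [3.0])


def _frame(levels_a, levels_b, n, values):
    rows = []
    it = iter(values)
    for a in levels_a:
        for b in levels_b:
            for _ in range(n):
                rows.append((a, b, next(it)))
    return pd.DataFrame(rows, columns=["A", "B", "response"])


class TestAlignedRankTransform:
    def test_constant_response_gives_zero_alignment_and_tied_ranks(self):
        df = _frame([1, 2], [1, 2], 3, [5.0] * 12)
        art = aligned_rank_transform(df, "A", "B")
        for eff in ("A", "B", "A:B"):
            np.testing.assert_allclose(art.frame[f"aligned_{eff}"], 0.0)
            np.testing.assert_allclose(art.frame[f"rank_{eff}"], 6.5)

    def test_pure_main_effect_aligns_away_from_other_columns(self):
        # 2x2, n=2, noiseless +/-1 A effect: hand cell-means algebra gives
        # aligned-for-B and aligned-for-interaction identically zero and
        # aligned-for-A reproducing the +/-1 pattern
        df = _frame([1, 2], [1, 2], 2, [1.0, 1.0, 1.0, 1.0, -1.0, -1.0, -1.0, -1.0])
        art = aligned_rank_transform(df, "A", "B")
        np.testing.assert_allclose(art.frame["aligned_B"], 0.0, atol=1e-12)
        np.testing.assert_allclose(art.frame["aligned_A:B"], 0.0, atol=1e-12)
        expected_a = np.where(df["A"] == 1, 1.0, -1.0)
        np.testing.assert_allclose(art.frame["aligned_A"], expected_a, atol=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_rank_columns_are_permutations_with_tied_averages(self, seed):
        rng = np.random.default_rng(seed)
        df = _frame([1, 2, 3], [1, 2], 3, rng.normal(size=18).round(1))
        art = aligned_rank_transform(df, "A", "B")
        n = len(df)
        for eff in ("A", "B", "A:B"):
            assert art.frame[f"rank_{eff}"].sum() == pytest.approx(n * (n + 1) / 2)

    def test_unbalanced_cells_still_align_exactly(self):
        rng = np.random.default_rng(4)
        rows = [
            (a, b, rng.normal())
            for a, b, n in [(1, 1, 3), (1, 2, 5), (2, 1, 4), (2, 2, 2)]
            for _ in range(n)
        ]
        df = pd.DataFrame(rows, columns=["A", "B", "response"])
        # alignment identity is asserted internally to 1e-9
        aligned_rank_transform(df, "A", "B")

    def test_empty_cell_named_in_error(self):
        df = _frame([1, 2], [1, 2], 2, range(8))
        df = df[~((df["A"] == 2) & (df["B"] == 1))]
        with pytest.raises(StatsError, match="A=2.*B=1"):
            aligned_rank_transform(df, "A", "B")

    def test_single_level_factor_rejected(self):
        df = _frame([1], [1, 2], 3, range(6))
        with pytest.raises(StatsError):
            aligned_rank_transform(df, "A", "B")


class TestArtAnova:
    def test_matches_statsmodels_anova_on_rank_columns(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        tab, _ = simulate_rate_table(
            range(3), range(4), 5,
            effects_a={0: 0.5, 2: -0.5}, interaction={(0, 0): 1.0}, seed=8,
        )
        art = aligned_rank_transform(tab, "A", "B")
        tests = {t.effect: t for t in art_anova(art)}
        frame = art.frame.rename(columns={"rank_A:B": "rank_AB"})
        for eff, col, term in [
            ("A", "rank_A", "C(A)"),
            ("B", "rank_B", "C(B)"),
            ("A:B", "rank_AB", "C(A):C(B)"),
        ]:
            model = ols(f"{col} ~ C(A) * C(B)", frame).fit()
            table = sm.stats.anova_lm(model, typ=2)
            assert tests[eff].f_statistic == pytest.approx(
                table.loc[term, "F"], rel=1e-9
            )
            assert tests[eff].p_value == pytest.approx(
                table.loc[term, "PR(>F)"], rel=1e-9, abs=1e-12
            )

    def test_strong_main_effect_detected_others_near_null(self):
        detected_a, rej_b = 0, 0
        n_sims = 200
        for s in range(n_sims):
            tab, _ = simulate_rate_table(
                range(3), range(3), 6, effects_a={0: 5.0, 1: -5.0}, seed=s
            )
            tests = {t.effect: t for t in art_anova(
                aligned_rank_transform(tab, "A", "B")
            )}
            detected_a += tests["A"].p_value < 0.001
            rej_b += tests["B"].p_value < 0.05
        assert detected_a >= 0.99 * n_sims
        assert rej_b / n_sims < 0.12  # non-focal effect stays near nominal

    def test_unbalanced_layout_rejected(self):
        df = _frame([1, 2], [1, 2], 2, range(8)).iloc[:-1]
        art = aligned_rank_transform(df, "A", "B")
        with pytest.raises(StatsError):
            art_anova(art)


class TestKruskalWallis:
    def test_hand_computed_example(self):
        h, p = kruskal_wallis([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert h == pytest.approx(7.2)

    @given(st.integers(0, 100_000))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_groups = rng.integers(2, 5)
        sizes = rng.integers(1, 5, size=n_groups)
        while sizes.sum() > 12 or sizes.sum() < 3:
            sizes = rng.integers(1, 5, size=n_groups)
        groups = [rng.integers(0, 6, size=n).astype(float) for n in sizes]
        if np.ptp(np.concatenate(groups)) == 0:
            return
        h, _ = kruskal_wallis(*groups)
        assert h == pytest.approx(brute_force_kruskal(groups), abs=1e-12)

    def test_identical_single_value_groups_give_zero(self):
        h, p = kruskal_wallis([1.0, 1.0], [1.0])
        assert h == 0.0 and p == 1.0

    def test_null_rejection_near_nominal(self):
        rej = sum(
            kruskal_wallis(
                *np.random.default_rng(s).normal(size=(3, 10))
            )[1] < 0.05
            for s in range(400)
        )
        assert 0.02 <= rej / 400 <= 0.08

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            kruskal_wallis([1.0, 2.0], [])


class TestDunn:
    def test_matches_brute_force_z(self):
        rng = np.random.default_rng(12)
        groups = {i: rng.integers(0, 8, size=4).astype(float) for i in range(4)}
        expected = brute_force_dunn_z(list(groups.values()))
        results = dunn_test(groups)
        for r in results:
            assert r.z == pytest.approx(expected[(r.level_i, r.level_j)], abs=1e-12)

    def test_extreme_pair_dominates_adjacent_pairs(self):
        res = {
            (r.level_i, r.level_j): abs(r.z)
            for r in dunn_test({0: [1, 2, 3], 1: [4, 5, 6], 2: [7, 8, 9]})
        }
        assert res[(0, 2)] > res[(0, 1)]
        assert res[(0, 2)] > res[(1, 2)]

    def test_identical_groups_z_zero_p_one(self):
        (r,) = dunn_test({"x": [1.0, 2.0], "y": [1.0, 2.0]})
        assert r.z == 0.0 and r.p_value == 1.0

    def test_no_adjustment_is_identity(self):
        groups = {0: [1.0, 2.0], 1: [3.0, 4.0], 2: [5.0, 6.0]}
        for r in dunn_test(groups, adjustment="none"):
            assert r.p_adjusted == r.p_value

    @pytest.mark.parametrize("method", ["bonferroni", "holm"])
    def test_adjusted_p_never_below_unadjusted(self, method):
        rng = np.random.default_rng(2)
        groups = {i: rng.normal(size=5) for i in range(4)}
        for r in dunn_test(groups, adjustment=method):
            assert r.p_adjusted >= r.p_value - 1e-15

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            dunn_test({0: [1.0], 1: []})


def _pairwise_from_pattern(levels, significant_pairs):
    return [
        PairwiseResult(a, b, 0.0, 1.0, 1.0, frozenset((a, b)) in significant_pairs)
        for a, b in itertools.combinations(levels, 2)
    ]


class TestLetterDisplay:
    def test_full_separation(self):
        pw = _pairwise_from_pattern(
            [1, 2, 3],
            {frozenset((1, 2)), frozenset((1, 3)), frozenset((2, 3))},
        )
        assert letter_display(pw) == {1: {"a"}, 2: {"b"}, 3: {"c"}}

    def test_no_separation(self):
        pw = _pairwise_from_pattern([1, 2, 3], set())
        assert letter_display(pw) == {1: {"a"}, 2: {"a"}, 3: {"a"}}

    def test_chain_pattern(self):
        pw = _pairwise_from_pattern([1, 2, 3], {frozenset((1, 3))})
        assert letter_display(pw) == {1: {"a"}, 2: {"a", "b"}, 3: {"b"}}

    def test_missing_pair_rejected(self):
        pw = _pairwise_from_pattern([1, 2], set())
        with pytest.raises(StatsError):
            letter_display(pw, levels=[1, 2, 3])

    @pytest.mark.parametrize("n_levels", [2, 3, 4])
    def test_share_letter_iff_not_significant_exhaustive(self, n_levels):
        levels = list(range(n_levels))
        pairs = list(itertools.combinations(levels, 2))
        for mask in range(2 ** len(pairs)):
            sig = {
                frozenset(p) for i, p in enumerate(pairs) if mask >> i & 1
            }
            letters = letter_display(_pairwise_from_pattern(levels, sig))
            for a, b in pairs:
                shares = bool(letters[a] & letters[b])
                assert shares != (frozenset((a, b)) in sig), (mask, a, b)
            assert all(letters[lv] for lv in levels)
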