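"""Agreement and factorial statistics against hand computations and
independent oracles (enumeration, permutation, sklearn/pingouin/R
reference values frozen from their published algorithms)."""

import itertools
import math

import numpy as np
import pytest

from mretrap.agreement import (
    bland_altman,
    cohens_kappa,
    cv_percent,
    friedman_test,
    icc_band,
    icc_two_way_mixed,
    kappa_band,
    pairwise_wilcoxon_bonferroni,
    wilcoxon_signed_rank,
)


class TestCohensKappa:
    def test_identical_ratings_perfect(self):
        k, band = cohens_kappa([1, 2, 3, 4, 5, 1], [1, 2, 3, 4, 5, 1])
        assert k == pytest.approx(1.0)
        assert band == "almost perfect"

    def test_hand_example_zero_kappa(self):
        # p_o = 0.5, p_e = 0.5 -> kappa = 0
        k, band = cohens_kappa([1, 1, 2, 2], [1, 2, 1, 2])
        assert k == pytest.approx(0.0)
        assert band == "poor"

    def test_band_cut_points(self):
        assert kappa_band(0.83) == "almost perfect"
        assert kappa_band(0.80) == "substantial"
        assert kappa_band(0.61) == "substantial"
        assert kappa_band(0.57) == "moderate"
        assert kappa_band(0.10) == "slight"
        assert kappa_band(-0.2) == "poor"

    def test_degenerate_single_category_rejected(self):
        with pytest.raises(ValueError, match="p_e"):
            cohens_kappa([3, 3, 3], [3, 3, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa([1, 2], [1, 2, 3])

    def test_matches_sklearn_on_random_ratings(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.integers(1, 6, 30)
            b = np.where(rng.random(30) < 0.3, rng.integers(1, 6, 30), a)
            k, _ = cohens_kappa(a, b)
            assert k == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_subject_permutation_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.integers(1, 6, 20)
        b = rng.integers(1, 6, 20)
        perm = rng.permutation(20)
        assert cohens_kappa(a, b)[0] == pytest.approx(
            cohens_kappa(a[perm], b[perm])[0]
        )


class TestICC:
    def test_duplicated_column_gives_one(self):
        x = np.random.default_rng(0).normal(size=(10, 1))
        assert icc_two_way_mixed(np.hstack([x, x])) == pytest.approx(1.0)

    def test_variance_ratio_closed_form(self):
        # subjects ~ var 4, rater error ~ var 1 -> ICC ~ 4/5 = 0.8
        rng = np.random.default_rng(2)
        n = 10_000
        s = rng.normal(0, 2, (n, 1))
        x = s + rng.normal(0, 1, (n, 2))
        assert icc_two_way_mixed(x) == pytest.approx(0.8, abs=0.02)

    def test_independent_columns_give_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10_000, 2))
        assert icc_two_way_mixed(x) == pytest.approx(0.0, abs=0.03)

    def test_matches_pingouin_consistency_form(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(4)
        x = rng.normal(size=(12, 3)) + 2 * rng.normal(size=(12, 1))
        mine = icc_two_way_mixed(x)
        d = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "y": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(d, targets="subj", raters="rater", ratings="y")
        icc3 = float(ref.loc[ref["Type"] == "ICC(C,1)", "ICC"].iloc[0]) \
            if "ICC(C,1)" in set(ref["Type"]) else float(ref.ICC.iloc[2])
        assert mine == pytest.approx(icc3, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            icc_two_way_mixed(np.ones((5, 2)))

    def test_koo_li_bands(self):
        assert icc_band(0.3) == "poor"
        assert icc_band(0.6) == "moderate"
        assert icc_band(0.8) == "good"
        assert icc_band(0.95) == "excellent"


class TestBlandAltman:
    def test_identical_pairs(self):
        res = bland_altman([(2.0, 2.0), (3.0, 3.0), (4.0, 4.0)])
        assert res.bias == 0 and res.loa == 0

    def test_constant_difference(self):
        res = bland_altman([(2, 1), (3, 2), (4, 3), (5, 4)])
        assert res.bias == pytest.approx(1.0)
        assert res.sd_diff == pytest.approx(0.0)
        assert res.ub == res.lb == pytest.approx(1.0)

    def test_hand_example_d_0_2(self):
        # d = {0, 2}: bias 1, SD = sqrt(2), LoA = 1.96 sqrt(2) ~ 2.772
        res = bland_altman([(1.0, 1.0), (3.0, 1.0)])
        assert res.bias == pytest.approx(1.0)
        assert res.sd_diff == pytest.approx(math.sqrt(2), rel=1e-12)
        assert res.loa == pytest.approx(2.7718, abs=1e-3)

    def test_bounds_and_antisymmetry(self):
        rng = np.random.default_rng(5)
        pairs = rng.normal(5, 1, (20, 2))
        res = bland_altman(pairs)
        assert res.ub - res.lb == pytest.approx(2 * res.loa, rel=1e-12)
        res_swapped = bland_altman(pairs[:, ::-1])
        assert res_swapped.bias == pytest.approx(-res.bias, rel=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([(1.0, 2.0)])


class TestCV:
    def test_identical_pairs_zero(self):
        assert cv_percent([(3, 3), (5, 5)]) == 0

    def test_hand_example_single_pair(self):
        # (3, 5): SD = sqrt(2) ~ 1.414, mean 4 -> 35.36%
        assert cv_percent([(3.0, 5.0)]) == pytest.approx(35.355, abs=0.01)

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        pairs = rng.uniform(1, 5, (15, 2))
        assert cv_percent(pairs) == pytest.approx(cv_percent(7.3 * pairs), rel=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cv_percent([(1.0, -1.0)])


def brute_force_friedman_stat(x):
    """Independent mid-rank computation of the Friedman statistic with
    tie correction (textbook formula, no shared code)."""
    n, k = x.shape
    ranks = np.empty_like(x, dtype=float)
    for i, row in enumerate(x):
        order = np.argsort(row)
        r = np.empty(k)
        j = 0
        while j < k:
            tied = [order[j]]
            while j + len(tied) < k and row[order[j + len(tied)]] == row[order[j]]:
                tied.append(order[j + len(tied)])
            mid = j + (len(tied) + 1) / 2
            for t in tied:
                r[t] = mid
            j += len(tied)
        ranks[i] = r
    rj = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum((rj - n * (k + 1) / 2) ** 2)
    ties = sum(
        float(np.sum(c**3 - c))
        for c in (np.unique(row, return_counts=True)[1] for row in x)
    )
    corr = 1 - ties / (n * k * (k * k - 1))
    return stat / corr if corr > 0 else 0.0


class TestFriedman:
    def test_identical_columns(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 4))
        stat, df, p = friedman_test(x)
        assert stat == 0 and p == 1

    def test_df_is_conditions_minus_one(self):
        x = np.random.default_rng(7).normal(size=(9, 12))
        _, df, _ = friedman_test(x)
        assert df == 11

    def test_statistic_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            x = rng.integers(1, 4, size=(6, 4)).astype(float)
            stat, _, _ = friedman_test(x)
            assert stat == pytest.approx(brute_force_friedman_stat(x), rel=1e-12)

    def test_frozen_r_reference_values(self):
        # friedman.test in R 4.3.3 on these exact matrices
        rng = np.random.default_rng(42)
        x = rng.normal(size=(7, 4)).round(3)
        stat, df, p = friedman_test(x)
        assert stat == pytest.approx(10.714, abs=1e-3)
        assert p == pytest.approx(0.01338, abs=1e-5)
        y = np.array(
            [
                [1.0, 2, 2, 3],
                [2, 1, 3, 3],
                [1, 1, 2, 2],
                [3, 2, 2, 1],
                [1, 2, 3, 3],
            ]
        )
        stat, _, p = friedman_test(y)
        assert stat == pytest.approx(4.9091, abs=1e-4)
        assert p == pytest.approx(0.1786, abs=1e-4)

    def test_tail_p_matches_permutation_enumeration(self):
        """In the decision-relevant tail the chi-squared approximation
        agrees with the exact within-block permutation distribution."""
        x = np.array(
            [[1.0, 2.0, 3.1], [1.2, 2.1, 3.0], [0.9, 2.2, 3.3],
             [1.1, 1.9, 2.8], [1.0, 2.3, 3.2]]
        )
        stat, _, p = friedman_test(x)
        perms = list(itertools.permutations(range(3)))
        count = total = 0
        for combo in itertools.product(perms, repeat=5):
            xp = np.vstack([x[i, list(pi)] for i, pi in enumerate(combo)])
            count += brute_force_friedman_stat(xp) >= stat - 1e-9
            total += 1
        assert p == pytest.approx(count / total, abs=0.01)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(8, 3))
        s1, _, _ = friedman_test(x)
        s2, _, _ = friedman_test(np.exp(x))
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_incomplete_blocks_rejected(self):
        x = np.ones((4, 3))
        x[1, 2] = np.nan
        with pytest.raises(ValueError):
            friedman_test(x)


def brute_force_wilcoxon_p(d):
    """Exact two-sided signed-rank p by enumerating every sign assignment."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    absd = np.abs(d)
    order = np.argsort(absd)
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and absd[order[j + 1]] == absd[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    w_small = min(w_obs, total - w_obs)
    hits = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = float(np.dot(signs, ranks))
        if w <= w_small + 1e-9 or w >= total - w_small - 1e-9:
            hits += 1
    return min(1.0, hits / 2**n)


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        assert wilcoxon_signed_rank([1, 2, 3], [1, 2, 3]) == 1.0

    def test_frozen_r_reference(self):
        # wilcox.test(a, b, paired=TRUE) in R 4.3.3 -> p = 0.15625
        a = [1.2, 2.3, 0.5, 2.8, 1.9, 3.3]
        b = [0.8, 2.0, 0.9, 2.1, 1.0, 2.5]
        assert wilcoxon_signed_rank(a, b) == pytest.approx(0.15625, abs=1e-12)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(10)
        for n in (5, 6, 8, 10):
            for _ in range(5):
                a = rng.normal(0.4, 1, n)
                b = rng.normal(0, 1, n)
                assert wilcoxon_signed_rank(a, b) == pytest.approx(
                    brute_force_wilcoxon_p(a - b), abs=1e-12
                )

    def test_matches_scipy_exact_without_ties(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(11)
        a = rng.normal(0.5, 1, 9)
        b = rng.normal(0, 1, 9)
        assert wilcoxon_signed_rank(a, b) == pytest.approx(
            scipy_wilcoxon(a, b, method="exact").pvalue, abs=1e-12
        )

    def test_large_n_normal_approximation_close_to_scipy(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(12)
        a = rng.normal(0.3, 1, 40)
        b = rng.normal(0, 1, 40)
        ref = scipy_wilcoxon(a, b, correction=True, method="approx").pvalue
        assert wilcoxon_signed_rank(a, b) == pytest.approx(ref, rel=0.02)


class TestPropertyInvariants:
    from hypothesis import given, settings, strategies as st

    pair_lists = st.lists(
        st.tuples(
            st.floats(0.5, 50, allow_nan=False), st.floats(0.5, 50, allow_nan=False)
        ),
        min_size=2,
        max_size=30,
    )

    @given(pairs=pair_lists)
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_bland_altman_bound_identities(self, pairs):
        res = bland_altman(pairs)
        assert res.ub - res.lb == pytest.approx(2 * res.loa, abs=1e-9)
        assert res.lb <= res.bias <= res.ub
        swapped = bland_altman([(b, a) for a, b in pairs])
        assert swapped.bias == pytest.approx(-res.bias, abs=1e-9)

    @given(pairs=pair_lists, scale=st.floats(0.1, 100, allow_nan=False))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_cv_scale_invariant(self, pairs, scale):
        scaled = [(a * scale, b * scale) for a, b in pairs]
        assert cv_percent(scaled) == pytest.approx(cv_percent(pairs), rel=1e-9)

    @given(
        d=st.lists(st.floats(-5, 5, allow_nan=False), min_size=3, max_size=15)
    )
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_wilcoxon_p_is_a_probability(self, d):
        d = np.asarray(d)
        p = wilcoxon_signed_rank(d, np.zeros_like(d))
        assert 0 < p <= 1


class TestPairwiseBonferroni:
    def test_identical_conditions_adjusted_to_one(self):
        x = np.tile(np.arange(6.0)[:, None], (1, 3))
        out = pairwise_wilcoxon_bonferroni(x)
        assert all(p == 1.0 for p in out.values())

    def test_bonferroni_multiplies_by_family_size(self):
        rng = np.random.default_rng(13)
        x = np.column_stack([rng.normal(0, 1, 8), rng.normal(2, 1, 8), rng.normal(4, 1, 8)])
        raw_01 = wilcoxon_signed_rank(x[:, 0], x[:, 1])
        out = pairwise_wilcoxon_bonferroni(x)
        assert out[(0, 1)] == pytest.approx(min(1.0, 3 * raw_01))

    def test_labels_and_pair_selection(self):
        x = np.random.default_rng(14).normal(size=(6, 3))
        out = pairwise_wilcoxon_bonferroni(
            x, condition_labels=["a", "b", "c"], pairs=[(0, 2)]
        )
        assert list(out) == [("a", "c")]
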