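"""Ranking, GSEA, over-representation, delay statistics and classical tests.

Exact tests are checked against full-enumeration oracles built here from
first principles (itertools over arrangements / tables)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from blastoseq.enrichment import (
    GeneSet,
    blastocyst_stage_value,
    bootstrap_mean_ci,
    chisq_goodness_of_fit,
    delay_correlation,
    enrichment_score,
    fisher_exact_2x2,
    gsea,
    ora_hypergeometric,
    rank_by_signed_significance,
    weighted_dev_log2fc,
    welch_ttest,
    wilcoxon_ranksum_exact,
)


def _res(padj, lfc, ids=None):
    ids = ids or [f"g{i}" for i in range(len(padj))]
    return pd.DataFrame({"padj": padj, "log2FC": lfc}, index=ids)


class TestRanking:
    def test_signed_score(self):
        r = rank_by_signed_significance(_res([0.01, 1.0], [-2.0, 3.0]))
        assert r["g0"] == pytest.approx(-2.0)
        assert r["g1"] == pytest.approx(0.0)

    def test_padj_one_scores_zero_regardless_of_sign(self):
        r = rank_by_signed_significance(_res([1.0, 1.0], [5.0, -5.0]))
        assert (r == 0).all()

    def test_na_dropped_and_floor_applied(self):
        r = rank_by_signed_significance(_res([np.nan, 0.0], [1.0, 1.0]))
        assert list(r.index) == ["g1"]
        assert r["g1"] == pytest.approx(300.0)

    def test_tie_break_larger_lfc_more_extreme(self):
        res = _res([0.01, 0.01, 0.01, 0.01], [1.0, 2.0, -1.0, -2.0])
        r = rank_by_signed_significance(res)
        assert list(r.index)[:2] == ["g1", "g0"]  # top: larger |lfc| first
        assert list(r.index)[-2:] == ["g2", "g3"]  # bottom: larger |lfc| last


def brute_force_es(scores, in_set, weight=1.0):
    """Literal running-sum over the whole list."""
    s = np.abs(np.asarray(scores, dtype=float)) ** weight
    nh = in_set.sum()
    total = s[in_set].sum()
    if total <= 0:
        s = np.ones_like(s)
        total = float(nh)
    miss = 1.0 / (len(s) - nh)
    run, best = 0.0, 0.0
    for i in range(len(s)):
        run += s[i] / total if in_set[i] else -miss
        # earliest extremum wins; 1e-9 guards against float-noise ties
        if abs(run) > abs(best) + 1e-9:
            best = run
    return best


class TestGsea:
    def test_full_set_es_one(self):
        ranked = pd.Series([3.0, 2.0, 1.0], index=["a", "b", "c"])
        es, leading = enrichment_score(ranked, {"a", "b", "c"})
        assert es == 1.0

    def test_hand_enumeration_three_genes(self):
        ranked = pd.Series([3.0, 2.0, 1.0], index=["a", "b", "c"])
        es, leading = enrichment_score(ranked, {"a"})
        # running sum: +1 at a, then -1/2, -1/2 -> [1, 0.5, 0]; ES = 1 at a
        assert es == pytest.approx(1.0)
        assert leading == 1

    def test_matches_brute_force_on_random_lists(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(4, 10))
            scores = np.sort(rng.normal(0, 2, n))[::-1]
            ranked = pd.Series(scores, index=[f"g{i}" for i in range(n)])
            nh = int(rng.integers(1, n))
            members = set(rng.choice(ranked.index, size=nh, replace=False))
            in_set = ranked.index.isin(list(members))
            es, _ = enrichment_score(ranked, members)
            assert es == pytest.approx(brute_force_es(scores, in_set), abs=1e-12)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        ranked = pd.Series([4.0, 2.0, 1.0, -1.0, -3.0], index=list("abcde"))
        members = {"a", "b"}
        res = gsea(ranked, [GeneSet("s", members)], n_perm=20_000, seed=1, min_size=1, max_size=5)
        es_obs, _ = enrichment_score(ranked, members)
        # exhaustive null over all C(5,2) = 10 placements
        null = []
        for pos in itertools.combinations(range(5), 2):
            in_set = np.zeros(5, bool)
            in_set[list(pos)] = True
            null.append(brute_force_es(ranked.to_numpy(), in_set))
        exact_p = sum(abs(e) >= abs(es_obs) for e in null) / len(null)
        mc_p = res.loc["s", "pvalue"]
        se = math.sqrt(exact_p * (1 - exact_p) / 20_000)
        # mc_p carries +1 smoothing, a <= 1/(n_perm+1) offset
        assert abs(mc_p - exact_p) <= 2 * se + 1 / 20_001 + 1e-6

    def test_antisymmetry_under_ranking_reversal(self):
        rng = np.random.default_rng(12)
        scores = np.sort(rng.normal(0, 1, 30))[::-1]
        ranked = pd.Series(scores, index=[f"g{i}" for i in range(30)])
        members = set(rng.choice(ranked.index, 8, replace=False))
        es1, _ = enrichment_score(ranked, members)
        flipped = pd.Series(-scores[::-1], index=ranked.index[::-1])
        es2, _ = enrichment_score(flipped, members)
        assert es2 == pytest.approx(-es1, abs=1e-12)

    def test_es_bounded(self):
        rng = np.random.default_rng(13)
        scores = np.sort(rng.normal(0, 1, 40))[::-1]
        ranked = pd.Series(scores, index=[f"g{i}" for i in range(40)])
        for nh in (1, 5, 20, 39):
            es, _ = enrichment_score(ranked, set(ranked.index[:nh]))
            assert -1.0 <= es <= 1.0

    def test_empty_intersection_skipped(self):
        ranked = pd.Series([1.0, 0.5], index=["a", "b"])
        res = gsea(ranked, [GeneSet("none", {"zz"})], n_perm=10, min_size=1, max_size=5)
        assert len(res) == 0
        assert res.attrs["skipped"][0][0] == "none"

    def test_seed_determinism(self):
        rng = np.random.default_rng(14)
        ranked = pd.Series(
            np.sort(rng.normal(0, 1, 50))[::-1], index=[f"g{i}" for i in range(50)]
        )
        sets = [GeneSet("s", set(ranked.index[5:20]))]
        a = gsea(ranked, sets, n_perm=200, seed=9)
        b = gsea(ranked, sets, n_perm=200, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestOra:
    def test_closed_form(self):
        universe = [f"u{i}" for i in range(10)]
        s = GeneSet("s", set(universe[:5]))
        hits = set(universe[:4])
        res = ora_hypergeometric(hits, universe, [s])
        assert res.loc["s", "pvalue"] == pytest.approx(5 / 210, rel=1e-9)

    def test_disjoint_set_p_one(self):
        universe = [f"u{i}" for i in range(10)]
        s = GeneSet("s", set(universe[5:]))
        res = ora_hypergeometric(set(universe[:3]), universe, [s])
        assert res.loc["s", "pvalue"] <= 1.0
        assert res.loc["s", "overlap"] == 0

    def test_hits_equal_universe_p_one(self):
        universe = [f"u{i}" for i in range(6)]
        s = GeneSet("s", set(universe[:3]))
        res = ora_hypergeometric(set(universe), universe, [s])
        assert res.loc["s", "pvalue"] == pytest.approx(1.0)

    def test_monotone_in_overlap(self):
        universe = [f"u{i}" for i in range(30)]
        s = GeneSet("s", set(universe[:10]))
        ps = []
        for k in range(0, 9):
            hits = set(universe[:k]) | set(universe[10 : 10 + (8 - k)])
            ps.append(ora_hypergeometric(hits, universe, [s]).loc["s", "pvalue"])
        assert all(ps[i] >= ps[i + 1] - 1e-12 for i in range(len(ps) - 1))

    def test_matches_enumeration_small(self):
        # P(overlap >= k) by enumerating all C(N, n) hit draws
        universe = list(range(8))
        s = GeneSet("s", {0, 1, 2})
        hits = {0, 1, 6}
        res = ora_hypergeometric(hits, universe, [s])
        count = sum(
            1 for draw in itertools.combinations(universe, 3) if len(set(draw) & s.members) >= 2
        )
        assert res.loc["s", "pvalue"] == pytest.approx(count / math.comb(8, 3), rel=1e-9)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            ora_hypergeometric(set(), set(), [GeneSet("s", {1})])


class TestDelayConstructions:
    def test_blastocyst_max(self):
        df = pd.DataFrame({"E3.5_ICM": [5.0, 8.0, 0.0], "E3.5_TE": [8.0, 8.0, 0.0]})
        assert list(blastocyst_stage_value(df)) == [8.0, 8.0, 0.0]

    def test_missing_stage_column_errors(self):
        with pytest.raises(KeyError):
            blastocyst_stage_value(pd.DataFrame({"E3.5_ICM": [1.0]}))

    @pytest.mark.parametrize("a,b,expected", [(2, -2, 1.0), (3, 3, 3.0), (0, 4, 1.0)])
    def test_weighted_lfc(self, a, b, expected):
        assert weighted_dev_log2fc(np.array([a]), np.array([b]))[0] == pytest.approx(expected)

    def test_weighted_lfc_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            weighted_dev_log2fc(np.array([np.inf]), np.array([1.0]))

    def test_perfect_linear_correlation(self):
        x = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        out = delay_correlation(x, -2 * x)
        assert out["all"] == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(15)
        idx = [f"g{i}" for i in range(1000)]
        out = delay_correlation(
            pd.Series(rng.normal(size=1000), index=idx),
            pd.Series(rng.normal(size=1000), index=idx),
        )
        assert abs(out["all"]) < 0.1

    def test_too_few_points_errors(self):
        x = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            delay_correlation(x, x)

    def test_significant_subset_reported(self):
        idx = [f"g{i}" for i in range(20)]
        x = pd.Series(np.arange(20.0), index=idx)
        mask = pd.Series([True] * 10 + [False] * 10, index=idx)
        out = delay_correlation(x, x * 3, significant=mask)
        assert out["significant"] == pytest.approx(1.0)


class TestBootstrap:
    def test_constant_vector(self):
        assert bootstrap_mean_ci([5, 5, 5, 5]) == (5.0, 5.0, 5.0)

    def test_seed_deterministic(self):
        x = np.random.default_rng(16).normal(size=40)
        assert bootstrap_mean_ci(x, seed=3) == bootstrap_mean_ci(x, seed=3)

    def test_interval_contains_sample_mean_typically(self):
        x = np.random.default_rng(17).normal(size=100)
        m, lo, hi = bootstrap_mean_ci(x, seed=1)
        assert lo <= m <= hi


class TestChisq:
    def test_uniform_observed(self):
        stat, df, p = chisq_goodness_of_fit([25, 25, 25, 25], [0.25] * 4)
        assert stat == 0.0 and df == 3 and p == pytest.approx(1.0)

    def test_closed_form_binary(self):
        stat, df, p = chisq_goodness_of_fit([6, 33], [0.5, 0.5])
        assert stat == pytest.approx(18.6923, rel=1e-4)
        assert p == pytest.approx(1.536e-05, rel=1e-3)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            chisq_goodness_of_fit([10, 10], [0.5, 0.4])

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError, match="expected"):
            chisq_goodness_of_fit([10, 10], [1.0, 0.0])


def wilcoxon_enumeration(x, y):
    """Two-sided exact p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)
    obs = sum(1 for xi in x for yj in y if xi > yj)  # U statistic of x
    us = []
    for idx in itertools.combinations(range(len(pooled)), n):
        gx = pooled[list(idx)]
        gy = np.delete(pooled, list(idx))
        us.append(sum(1 for xi in gx for yj in gy if xi > yj))
    us = np.array(us)
    lo = (us <= obs).mean()
    hi = (us >= obs).mean()
    return min(1.0, 2 * min(lo, hi))


class TestWilcoxon:
    def test_small_exact_value(self):
        assert wilcoxon_ranksum_exact([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_singletons(self):
        assert wilcoxon_ranksum_exact([5.0], [5.0]) == 1.0

    def test_symmetric_sets(self):
        assert wilcoxon_ranksum_exact([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum_exact([], [1.0])

    def test_matches_enumeration_all_small_splits(self):
        rng = np.random.default_rng(18)
        for n in range(1, 6):
            for m in range(n, 10 - n + 1):
                if n + m > 10:
                    continue
                vals = rng.permutation(np.arange(1.0, n + m + 1))  # tie-free
                x, y = vals[:n], vals[n:]
                assert wilcoxon_ranksum_exact(x, y) == pytest.approx(
                    wilcoxon_enumeration(x, y), rel=1e-9
                )


def fisher_enumeration(table):
    """Two-sided Fisher p: sum hypergeometric probs <= observed prob."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    p_obs = prob(a)
    return sum(
        prob(k)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(k) <= p_obs * (1 + 1e-9)
    )


class TestFisher:
    def test_diagonal_table(self):
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252, rel=1e-9)

    def test_balanced_table(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [0, 0]])

    def test_matches_enumeration_small_tables(self):
        rng = np.random.default_rng(19)
        for _ in range(60):
            t = rng.integers(0, 5, size=(2, 2))
            if t.sum() == 0 or t.sum() > 10:
                continue
            assert fisher_exact_2x2(t) == pytest.approx(fisher_enumeration(t), rel=1e-7)


class TestWelch:
    def test_identical_groups(self):
        assert welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_strongly_separated(self):
        rng = np.random.default_rng(20)
        x = rng.normal(0, 1, 50)
        y = rng.normal(10, 1, 50)
        assert welch_ttest(x, y) < 1e-10

    def test_single_observation_errors(self):
        with pytest.raises(ValueError):
            welch_ttest([1.0], [1.0, 2.0])

    def test_zero_variance_equal_means(self):
        assert welch_ttest([2.0, 2.0], [2.0, 2.0]) == 1.0
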