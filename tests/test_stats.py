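import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from qeegbands.stats import (
    AnovaResult,
    benjamini_hochberg,
    kruskal_wallis,
    resampling_mixed_anova,
    significance_marker,
    spearman_with_fdr,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# independent oracles


def oracle_rank_sum_p(x, y):
    """Exact two-sided rank-sum p by enumerating all group allocations."""
    combined = np.concatenate([x, y])
    n1 = len(x)
    ranks = rankdata(combined)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array([
        ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        for idx in itertools.combinations(range(len(combined)), n1)
    ])
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


def oracle_signed_rank_p(x1, x2):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(x2, float) - np.asarray(x1, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([0, 1], repeat=len(d))
    ])
    return min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))


def oracle_bh(p):
    """Hand-rolled BH step-up: p_(i) * m / i with running minimum from the top."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adjusted[idx] = running
    return adjusted


def kruskal_h(samples):
    """Tie-corrected H computed from first principles, for the permutation oracle."""
    all_vals = np.concatenate(samples)
    ranks = rankdata(all_vals)
    n = all_vals.size
    start, h = 0, 0.0
    for s in samples:
        r = ranks[start : start + len(s)]
        h += r.sum() ** 2 / len(s)
        start += len(s)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie_term if tie_term > 0 else np.nan


# ---------------------------------------------------------------------------


class TestSignificanceMarker:
    @pytest.mark.parametrize(
        "p,marker",
        [(0.0005, "***"), (0.005, "**"), (0.012, "*"), (0.049, "*"),
         (0.064, "•"), (0.099, "•"), (0.1, "n.s."), (0.5, "n.s."), (1.0, "n.s.")],
    )
    def test_thresholds(self, p, marker):
        assert significance_marker(p) == marker

    @pytest.mark.parametrize("p", [-0.1, 1.1])
    def test_out_of_range(self, p):
        with pytest.raises(ValueError):
            significance_marker(p)


class TestKruskalWallis:
    def test_separated_groups_significant(self):
        res = kruskal_wallis([[1, 2, 3], [10, 11, 12], [20, 21, 22]])
        assert res.p < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            kruskal_wallis([[1, 2], []])

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            kruskal_wallis([[1, 2, 3]])

    def test_null_calibration(self, rng):
        hits = 0
        reps = 1000
        for _ in range(reps):
            groups = [rng.normal(size=10) for _ in range(3)]
            hits += kruskal_wallis(groups).p < 0.05
        assert 0.03 <= hits / reps <= 0.07

    def test_permutation_oracle_rank_agreement(self, rng):
        """Chi-square p's track the exhaustive permutation p's in rank order."""
        chi2_ps, perm_ps = [], []
        for _ in range(12):
            data = rng.normal(size=9)
            samples = [data[:3], data[3:6], data[6:]]
            chi2_ps.append(kruskal_wallis(samples).p)
            h_obs = kruskal_h(samples)
            hs = []
            indices = set(range(9))
            for first in itertools.combinations(range(9), 3):
                rest = sorted(indices - set(first))
                for second in itertools.combinations(rest, 3):
                    third = sorted(set(rest) - set(second))
                    hs.append(kruskal_h([data[list(first)], data[list(second)], data[third]]))
            perm_ps.append((np.asarray(hs) >= h_obs - 1e-12).mean())
        from scipy.stats import spearmanr

        rho, _ = spearmanr(chi2_ps, perm_ps)
        assert rho > 0.9

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(size=8) for _ in range(3)]
        p1 = kruskal_wallis(groups).p
        p2 = kruskal_wallis([np.exp(g) for g in groups]).p
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestWilcoxonRankSum:
    def test_exact_extreme_table(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p == pytest.approx(0.1)
        assert "exact" in res.method

    def test_identical_samples_maximal_p(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p > 0.9

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_rank_sum([], [1])

    def test_exact_oracle_equivalence(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(2, 9, size=2)
            pool = rng.permutation(np.arange(100, dtype=float))
            x, y = pool[:n1], pool[n1 : n1 + n2]
            res = wilcoxon_rank_sum(x, y)
            assert res.p == pytest.approx(oracle_rank_sum_p(x, y), abs=1e-12)

    def test_power_monotone_in_shift(self, rng):
        rates = []
        for shift in (0.0, 0.8, 1.6):
            hits = sum(
                wilcoxon_rank_sum(rng.normal(size=15), rng.normal(size=15) + shift).p < 0.05
                for _ in range(200)
            )
            rates.append(hits / 200)
        assert rates[0] < rates[1] < rates[2]

    def test_monotone_transform_invariance(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=12)
        assert wilcoxon_rank_sum(x, y).p == pytest.approx(
            wilcoxon_rank_sum(np.exp(x), np.exp(y)).p, abs=1e-12
        )

    def test_large_sample_uses_asymptotic(self, rng):
        res = wilcoxon_rank_sum(rng.normal(size=20), rng.normal(size=20))
        assert "asymptotic" in res.method


class TestWilcoxonSignedRank:
    def test_uniform_shift_n6(self):
        x1 = np.arange(6.0)
        res = wilcoxon_signed_rank(x1, x1 + 1)
        assert res.p == pytest.approx(2 / 64)

    def test_degenerate_all_zero(self):
        x = np.arange(5.0)
        with pytest.warns(UserWarning, match="degenerate|zero"):
            res = wilcoxon_signed_rank(x, x)
        assert res.p == 1.0
        assert res.statistic == 0.0

    def test_antisymmetry_of_p(self, rng):
        x1, x2 = rng.normal(size=10), rng.normal(size=10)
        assert wilcoxon_signed_rank(x1, x2).p == pytest.approx(
            wilcoxon_signed_rank(x2, x1).p, abs=1e-12
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            wilcoxon_signed_rank([1, 2], [1, 2, 3])

    def test_exact_oracle_equivalence(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 9))
            x1 = rng.normal(size=n)
            magnitudes = rng.permutation(np.arange(1, n + 1, dtype=float))
            signs = rng.choice([-1.0, 1.0], size=n)
            x2 = x1 + signs * magnitudes  # distinct |differences|: exact case
            res = wilcoxon_signed_rank(x1, x2)
            assert res.p == pytest.approx(oracle_signed_rank_p(x1, x2), abs=1e-12)

    def test_zeros_dropped(self):
        # one tied pair is dropped; remaining 5 shifted pairs -> 2/32
        x1 = np.arange(6.0)
        x2 = x1 + np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        res = wilcoxon_signed_rank(x1, x2)
        assert res.p == pytest.approx(2 / 32)


def make_anova_table(rng, n_per_group=(8, 8, 8), visit_shift=(0.0, 0.0, 0.0)):
    rows, sid = [], 0
    for g, (group, n) in enumerate(zip(("CRB_rTMS", "CRB_sham", "PLC_sham"), n_per_group)):
        for _ in range(n):
            sid += 1
            subject_effect = rng.normal()
            v1 = subject_effect + rng.normal()
            v2 = subject_effect + rng.normal() + visit_shift[g]
            rows += [(f"S{sid:02d}", group, "V1", v1), (f"S{sid:02d}", group, "V2", v2)]
    return pd.DataFrame(rows, columns=["subject_id", "group", "visit", "relative_power"])


class TestResamplingMixedAnova:
    def test_determinism_same_seed(self, rng):
        table = make_anova_table(rng)
        r1 = resampling_mixed_anova(table, n_iter=500, seed=42)
        r2 = resampling_mixed_anova(table, n_iter=500, seed=42)
        assert r1 == r2

    def test_different_seeds_within_mc_error(self, rng):
        table = make_anova_table(rng)
        r1 = resampling_mixed_anova(table, n_iter=4000, seed=1)
        r2 = resampling_mixed_anova(table, n_iter=4000, seed=2)
        for a, b in [(r1.p_group, r2.p_group), (r1.p_visit, r2.p_visit)]:
            assert abs(a - b) < 4 / np.sqrt(4000)

    def test_visit_effect_detected(self, rng):
        table = make_anova_table(rng, visit_shift=(1.5, 1.5, 1.5))
        res = resampling_mixed_anova(table, n_iter=2000, seed=7)
        assert res.p_visit < 0.01

    def test_interaction_detected(self, rng):
        table = make_anova_table(rng, n_per_group=(15, 15, 15), visit_shift=(2.5, 0.0, 0.0))
        res = resampling_mixed_anova(table, n_iter=2000, seed=7)
        assert res.p_interaction < 0.05

    def test_missing_visit_dropped_with_warning(self, rng):
        table = make_anova_table(rng)
        table = table.drop(table[(table.subject_id == "S01") & (table.visit == "V2")].index)
        with pytest.warns(UserWarning, match="S01"):
            res = resampling_mixed_anova(table, n_iter=200, seed=3)
        assert res.n_subjects == (7, 8, 8)

    def test_tiny_group_rejected(self, rng):
        table = make_anova_table(rng, n_per_group=(1, 8, 8))
        with pytest.raises(ValueError, match="fewer than 2"):
            resampling_mixed_anova(table, n_iter=100, seed=1)

    def test_result_fields(self, rng):
        res = resampling_mixed_anova(make_anova_table(rng), n_iter=100, seed=5)
        assert isinstance(res, AnovaResult)
        for p in (res.p_group, res.p_visit, res.p_interaction):
            assert 0 <= p <= 1
        assert res.n_iter == 100 and res.seed == 5


class TestBenjaminiHochberg:
    def test_hand_case_all_equal(self):
        np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.03]), [0.03])

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=40)
        assert (benjamini_hochberg(p) >= p - 1e-15).all()

    def test_monotone_in_sorted_order(self, rng):
        p = np.sort(rng.uniform(size=40))
        adj = benjamini_hochberg(p)
        assert (np.diff(adj) >= -1e-15).all()

    def test_matches_hand_oracle(self, rng):
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 30)))
            np.testing.assert_allclose(benjamini_hochberg(p), oracle_bh(p), atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


def make_correlation_inputs(rng, n_subjects=12, noise=0.0, missing=()):
    rows_p, rows_s = [], []
    for i in range(n_subjects):
        for visit in ("V1", "V2"):
            sid = f"S{i:02d}"
            alpha = rng.uniform(0.1, 0.5)
            rows_p.append((sid, "CRB_sham", visit, "whole_scalp", "alpha", alpha))
            score = 2 * alpha + noise * rng.normal()
            if (sid, visit) in missing:
                score = np.nan
            rows_s.append((sid, visit, score))
    powers = pd.DataFrame(rows_p, columns=["subject_id", "group", "visit", "zone", "band", "relative_power"])
    scores = pd.DataFrame(rows_s, columns=["subject_id", "visit", "TestA"])
    return scores, powers


class TestSpearmanWithFdr:
    def test_perfect_monotone(self, rng):
        scores, powers = make_correlation_inputs(rng, noise=0.0)
        out = spearman_with_fdr(scores, powers)
        assert out.loc[0, "rho"] == pytest.approx(1.0)
        assert out.loc[0, "p_raw"] < 1e-10

    def test_pairwise_deletion_bookkeeping(self, rng):
        missing = {("S00", "V1"), ("S01", "V1"), ("S02", "V2")}
        scores, powers = make_correlation_inputs(rng, n_subjects=12, missing=missing)
        out = spearman_with_fdr(scores, powers)
        assert out.loc[0, "n_pairs"] == 2 * 12 - 3

    def test_too_few_pairs_flagged(self, rng):
        scores, powers = make_correlation_inputs(rng, n_subjects=2)
        scores.loc[0, "TestA"] = np.nan
        scores.loc[1, "TestA"] = np.nan
        out = spearman_with_fdr(scores, powers)
        assert np.isnan(out.loc[0, "rho"])
        assert out.loc[0, "n_pairs"] == 2

    def test_null_calibration(self, rng):
        hits, reps = 0, 1000
        from scipy.stats import spearmanr

        # calibration of the underlying per-cell test on independent data
        for _ in range(reps):
            hits += spearmanr(rng.normal(size=30), rng.normal(size=30)).pvalue < 0.05
        assert 0.03 <= hits / reps <= 0.07

    def test_adjustment_is_one_family(self, rng):
        rows_p, rows_s = [], []
        for i in range(10):
            sid = f"S{i}"
            for band in ("alpha", "delta"):
                rows_p.append((sid, "CRB_sham", "V1", "whole_scalp", band, rng.uniform()))
            rows_s.append((sid, "V1", rng.normal(), rng.normal()))
        powers = pd.DataFrame(rows_p, columns=["subject_id", "group", "visit", "zone", "band", "relative_power"])
        scores = pd.DataFrame(rows_s, columns=["subject_id", "visit", "TestA", "TestB"])
        out = spearman_with_fdr(scores, powers)
        valid = out[out["p_raw"].notna()]
        np.testing.assert_allclose(
            valid["p_adj"].to_numpy(), oracle_bh(valid["p_raw"].to_numpy()), atol=1e-12
        )
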