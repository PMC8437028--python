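"""Binomial-GLM age tests, BH adjustment, and trajectory categorization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import studentized_range

from poolsel import af_testing, synthetic_data as sd
from poolsel.af_testing import categorize_locus
from poolsel.af_testing import test_age_effect as run_age_test


def _loglik(k, n, p):
    """Binomial log-likelihood (kernel), with 0*log(0) = 0."""
    k, n = np.asarray(k, float), np.asarray(n, float)
    p = np.clip(p, 1e-300, 1 - 1e-300)
    return float(np.sum(k * np.log(p) + (n - k) * np.log(1 - p)))


def oracle_age_deviance(days, n_minor, n_major):
    """LRT statistic for a day factor by explicit likelihood arithmetic.

    The by-day binomial MLE is the pooled per-day fraction; the null MLE is
    the overall pooled fraction.  Independent of the GLM fitting route.
    """
    days = np.asarray(days)
    k, n = np.asarray(n_minor, float), np.asarray(n_minor, float) + np.asarray(n_major, float)
    ll_full = 0.0
    for d in np.unique(days):
        m = days == d
        ll_full += _loglik(k[m], n[m], k[m].sum() / n[m].sum())
    ll_null = _loglik(k, n, k.sum() / n.sum())
    return 2.0 * (ll_full - ll_null)


def _counts_frame(records):
    return pd.DataFrame(records, columns=["locus_id", "day", "n_major", "n_minor"])


class TestAgeEffect:
    def test_flat_counts_are_not_significant(self):
        rows = [("L1", d, 50, 50) for d in (0, 2, 6, 10) for _ in range(5)]
        res = run_age_test(_counts_frame(rows))
        assert res.loc["L1", "p_value"] > 0.9
        assert not res.loc["L1", "significant"]

    def test_strong_reversal_is_overwhelming_and_matches_oracle(self):
        rows = [("L1", 2, 90, 10) for _ in range(5)] + [("L1", 22, 10, 90) for _ in range(5)]
        df = _counts_frame(rows)
        res = run_age_test(df)
        assert res.loc["L1", "deviance"] > 100
        assert res.loc["L1", "p_value"] < 1e-10
        expected = oracle_age_deviance(df["day"], df["n_minor"], df["n_major"])
        assert res.loc["L1", "deviance"] == pytest.approx(expected, rel=1e-6)

    def test_glm_deviance_matches_likelihood_oracle_on_synthetic_data(self, balanced_experiment):
        counts, _, _ = balanced_experiment
        res = run_age_test(counts)
        for locus in list(res.index)[:10]:
            grp = counts[counts["locus_id"] == locus]
            expected = oracle_age_deviance(grp["day"], grp["n_minor"], grp["n_major"])
            assert res.loc[locus, "deviance"] == pytest.approx(expected, rel=1e-5, abs=1e-6)

    def test_bh_adjustment_matches_step_up_oracle(self, neutral_experiment):
        counts, _, _ = neutral_experiment
        res = run_age_test(counts)
        p = res["p_value"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        stepped = p[order] * m / np.arange(1, m + 1)
        expected = np.minimum.accumulate(stepped[::-1])[::-1]  # textbook BH step-up
        np.testing.assert_allclose(res["q_bh"].to_numpy()[order], np.minimum(expected, 1.0), atol=1e-12)
        assert (res["q_bh"] >= res["p_value"] - 1e-12).all()
        assert (res["significant"] == (res["q_bh"] < 0.05)).all()

    def test_single_day_locus_excluded_with_warning(self):
        rows = [("L1", 2, 50, 50)] * 3 + [("L2", 2, 50, 50), ("L2", 6, 40, 60)]
        with pytest.warns(UserWarning, match="single day"):
            res = run_age_test(_counts_frame(rows))
        assert "L1" not in res.index and "L2" in res.index


def _maf_groups(means, sd_within=0.005, n_rep=5, seed=0, days=(2, 6, 10, 14)):
    rng = np.random.default_rng(seed)
    return {d: np.clip(m + rng.normal(0, sd_within, n_rep), 0, 1) for d, m in zip(days, means)}


class TestCategorization:
    def test_flat_trajectory_is_gradual(self):
        cat = categorize_locus(_maf_groups([0.3, 0.3, 0.3, 0.3], seed=1), overall_significant=True)
        assert cat.category == "G"

    def test_single_step_is_unidirectional_and_matches_range_oracle(self):
        groups = _maf_groups([0.10, 0.10, 0.40, 0.40], seed=2)
        cat = categorize_locus(groups, overall_significant=True)
        assert cat.category == "UD"
        sig = [iv for iv in cat.intervals if iv[3]]
        assert len(sig) == 1 and sig[0][:3] == (6, 10, "up")
        # oracle: studentized-range statistic for the 6->10 pair vs the 5% critical value
        vals = [groups[d] for d in sorted(groups)]
        n, k = len(vals[0]), len(vals)
        mse = np.mean([np.var(v, ddof=1) for v in vals])
        q_stat = abs(vals[2].mean() - vals[1].mean()) / np.sqrt(mse / n)
        q_crit = studentized_range.ppf(0.95, k, k * (n - 1))
        assert q_stat > q_crit

    def test_up_then_down_is_bidirectional(self):
        cat = categorize_locus(_maf_groups([0.10, 0.40, 0.10, 0.10], seed=3), overall_significant=True)
        assert cat.category == "BD"

    def test_non_significant_locus_is_ns(self):
        cat = categorize_locus(_maf_groups([0.1, 0.4, 0.1, 0.4], seed=4), overall_significant=False)
        assert cat.category == "NS" and not cat.intervals

    def test_degenerate_zero_variance_flags_and_treats_change_as_significant(self):
        groups = {2: np.full(3, 0.1), 6: np.full(3, 0.4)}
        with pytest.warns(UserWarning, match="zero within-day variance"):
            cat = categorize_locus(groups, overall_significant=True)
        assert cat.degenerate and cat.category == "UD"

    def test_allele_flip_preserves_category_and_reverses_directions(self):
        groups = _maf_groups([0.10, 0.40, 0.10, 0.40], seed=5)
        cat = categorize_locus(groups, overall_significant=True)
        flipped = categorize_locus({d: 1 - v for d, v in groups.items()}, overall_significant=True)
        assert cat.category == flipped.category
        for a, b in zip(cat.intervals, flipped.intervals):
            assert a[3] == b[3]
            if a[3]:
                assert a[2] != b[2]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        start=st.floats(0.05, 0.5),
        steps=st.lists(st.floats(0.02, 0.1), min_size=3, max_size=5),
        seed=st.integers(0, 1000),
    )
    def test_monotone_trajectories_never_bidirectional(self, start, steps, seed):
        means = np.minimum(np.cumsum([start] + steps), 0.95)
        groups = _maf_groups(means, sd_within=0.005, seed=seed, days=tuple(range(len(means))))
        cat = categorize_locus(groups, overall_significant=True)
        assert cat.category != "BD"


class TestTukeyCalibration:
    def test_sequential_pair_false_positive_rate_at_nominal_level(self):
        """On flat (no-change) loci, the fraction showing any significant
        sequential pair stays within Tukey's family-wise 5% level + 3 MC s.e.
        (sequential pairs are a subset of the all-pairs family)."""
        rng = np.random.default_rng(123)
        n_loci, days = 500, (2, 6, 10, 14)
        hits = 0
        for _ in range(n_loci):
            groups = {d: 0.3 + rng.normal(0, 0.01, 5) for d in days}
            cat = categorize_locus(groups, overall_significant=True)
            hits += cat.category != "G"
        se = np.sqrt(0.05 * 0.95 / n_loci)
        assert hits / n_loci <= 0.05 + 3 * se


class TestCategorizeAll:
    def test_summary_table_covers_significant_loci(self, balanced_experiment):
        counts, _, _ = balanced_experiment
        from poolsel import filtering

        per_sample, _, _ = filtering.compute_maf(counts)
        tests = run_age_test(counts)
        cats = af_testing.categorize_all(per_sample, tests)
        assert set(cats.index) == set(tests.index)
        assert set(cats["category"]) <= {"G", "UD", "BD", "NS"}
        # non-significant loci are labelled NS, not categorized
        ns = tests.index[~tests["significant"]]
        assert (cats.loc[cats.index.isin(ns), "category"] == "NS").all()
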