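import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ctwaist import (
    CohortParams,
    CrossTab,
    DataError,
    bland_altman,
    compare_auc_paired,
    concordance,
    discordant_pairs,
    generate_cohort,
    icc_consistency,
    limits_of_agreement,
    mcnemar_test,
    pearson_r,
    roc_auc,
    sens_spec_from_crosstab,
    youden_cutoff,
)
from ctwaist.datasets import example_crosstab


# ---------------------------------------------------------------------------
# independent oracles


def brute_auc(scores, labels):
    """Concordant-pair fraction with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_youden(scores, labels):
    """Exhaustive sweep over midpoint thresholds; same tie-break rule."""
    uniq = sorted(set(scores))
    cands = [(a + b) / 2 for a, b in zip(uniq, uniq[1:])]
    best = None
    for c in cands:
        tp = sum(1 for s, l in zip(scores, labels) if l == 1 and s >= c)
        fn = sum(1 for s, l in zip(scores, labels) if l == 1 and s < c)
        tn = sum(1 for s, l in zip(scores, labels) if l == 0 and s < c)
        fp = sum(1 for s, l in zip(scores, labels) if l == 0 and s >= c)
        sens, spec = tp / (tp + fn), tn / (tn + fp)
        key = (round(sens + spec - 1, 12), round(spec, 12), -c)
        if best is None or key > best[0]:
            best = (key, c)
    return best[1]


def anova_icc_c1(x, y):
    """Two-way ANOVA mean squares computed from first principles."""
    data = np.column_stack([x, y]).astype(float)
    n, k = data.shape
    grand = data.mean()
    ms_rows = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    ss_cols = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_err = ((data - grand) ** 2).sum() - k * ((data.mean(axis=1) - grand) ** 2).sum() - ss_cols
    ms_err = ss_err / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)


# ---------------------------------------------------------------------------


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, _, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_hand_computed_value(self):
        r, _, _ = pearson_r([1, 2, 3], [1, 2, 4])
        assert r == pytest.approx(3 / math.sqrt(28 / 3), abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(DataError):
            pearson_r([1.0, 1.0, 1.0], [1, 2, 3])

    def test_ci_brackets_r(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(scale=0.5, size=50)
        r, (lo, hi), p = pearson_r(x, y)
        assert lo < r < hi
        assert p < 1e-6


class TestBlandAltman:
    def test_identical_series(self):
        x = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(x, x)
        assert ba.mean_diff == 0 and ba.loa_low == 0 and ba.loa_high == 0

    def test_closed_form_diffs(self):
        ba = bland_altman(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert ba.mean_diff == pytest.approx(2.0)
        assert ba.sd_diff == pytest.approx(1.0)
        assert ba.loa_low == pytest.approx(0.04)
        assert ba.loa_high == pytest.approx(3.96)

    def test_summary_loa_arithmetic(self):
        lo, hi = limits_of_agreement(6.1, 4.0)
        assert lo == pytest.approx(-1.74)
        assert hi == pytest.approx(13.94)

    def test_loa_cover_95pct_of_normal_diffs(self, rng):
        x = rng.normal(size=10_000)
        y = x + rng.normal(loc=1.0, scale=2.0, size=10_000)
        ba = bland_altman(y, x)
        d = y - x
        frac = np.mean((d >= ba.loa_low) & (d <= ba.loa_high))
        assert 0.935 <= frac <= 0.965

    def test_too_short_rejected(self):
        with pytest.raises(DataError):
            bland_altman([1.0], [2.0])


class TestIcc:
    def test_identity_gives_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        icc, _ = icc_consistency(x, x)
        assert icc == pytest.approx(1.0)

    def test_constant_offset_ignored(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        icc, _ = icc_consistency(x, x + 5.0)
        assert icc == pytest.approx(1.0)

    def test_matches_anova_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 3.0, 5.0, 6.0])
        icc, _ = icc_consistency(x, y)
        assert icc == pytest.approx(anova_icc_c1(x, y), abs=1e-10)

    def test_matches_pingouin_icc3(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(80, 9, 40)
        y = x + 6 + rng.normal(0, 4, 40)
        icc, (lo, hi) = icc_consistency(x, y)
        df = pd.DataFrame(
            {
                "subject": np.r_[np.arange(40), np.arange(40)],
                "rater": ["a"] * 40 + ["b"] * 40,
                "score": np.r_[x, y],
            }
        )
        ref = pingouin.intraclass_corr(df, "subject", "rater", "score")
        row = ref[ref.Type == "ICC(C,1)"].iloc[0]
        assert icc == pytest.approx(row.ICC, abs=1e-10)
        # pingouin rounds its CI to 2 decimals
        assert (lo, hi) == pytest.approx(tuple(row.CI95), abs=0.005)

    def test_noise_degrades_icc_monotonically(self, rng):
        x = rng.normal(0, 5, 300)
        iccs = []
        for sd in [0.5, 2.0, 8.0]:
            y = x + rng.normal(0, sd, 300)
            iccs.append(icc_consistency(x, y)[0])
        assert iccs[0] > iccs[1] > iccs[2]

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError):
            icc_consistency([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.youden_j == pytest.approx(1.0)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_all_ties_give_half(self):
        res = roc_auc([5.0] * 6, [0, 1, 0, 1, 0, 1])
        assert res.auc == 0.5

    def test_enumerated_example(self):
        res = roc_auc([1, 2, 3, 4], [0, 1, 0, 1])
        assert res.auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_matches_sklearn_on_random_data(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        scores = rng.normal(size=200)
        labels = (scores + rng.normal(size=200) > 0).astype(int)
        assert roc_auc(scores, labels).auc == pytest.approx(
            sk.roc_auc_score(labels, scores), abs=1e-12
        )

    def test_brute_force_oracle_small_inputs(self, rng):
        """AUC equals the concordant-pair fraction and the Youden cutoff
        equals an exhaustive sweep, over many random inputs of n <= 12
        (including heavy ties)."""
        for _ in range(300):
            n = rng.integers(4, 13)
            scores = rng.integers(0, 6, n).astype(float)  # ties likely
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max() or len(set(scores)) < 2:
                continue
            res = roc_auc(scores, labels)
            assert res.auc == pytest.approx(brute_auc(scores, labels), abs=1e-12)
            assert res.cutoff == pytest.approx(brute_youden(scores, labels), abs=1e-12)

    def test_ci_contains_auc(self, rng):
        scores = rng.normal(size=100)
        labels = (scores + rng.normal(size=100) > 0).astype(int)
        res = roc_auc(scores, labels)
        assert res.auc_ci_low <= res.auc <= res.auc_ci_high


class TestCompareAucPaired:
    def test_identical_scores(self):
        s = [1.0, 2.0, 3.0, 4.0]
        z, p = compare_auc_paired(s, s, [0, 1, 0, 1])
        assert z == 0.0 and p == 1.0

    def test_signal_vs_noise_significant(self, rng):
        n = 200
        labels = rng.integers(0, 2, n)
        while labels.min() == labels.max():
            labels = rng.integers(0, 2, n)
        s1 = labels + rng.normal(0, 0.05, n)  # near-perfect separation
        s2 = rng.normal(0, 1, n)  # pure noise
        _, p = compare_auc_paired(s1, s2, labels)
        assert p < 0.001

    def test_null_pvalues_approximately_uniform(self, rng):
        """Type-I error control: equal-signal scores give a p-value that is
        uniform on [0, 1] (KS check over replicates)."""
        from scipy import stats as ss

        pvals = []
        for _ in range(400):
            n = 120
            latent = rng.normal(0, 1, n)
            labels = (latent + rng.normal(0, 1, n) > 0).astype(int)
            if labels.min() == labels.max():
                continue
            s1 = latent + rng.normal(0, 1, n)
            s2 = latent + rng.normal(0, 1, n)
            pvals.append(compare_auc_paired(s1, s2, labels)[1])
        ks = ss.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(DataError):
            compare_auc_paired([1, 2], [1, 2, 3], [0, 1, 1])


class TestCrossTab:
    def test_women_reference_sens_spec(self):
        ss = sens_spec_from_crosstab(example_crosstab("women"))
        assert ss["ct"]["sensitivity_pct"] == 87.5
        assert ss["ct"]["sensitivity_frac"] == (56, 64)
        assert ss["manual"]["sensitivity_pct"] == 85.9
        assert ss["manual"]["sensitivity_frac"] == (55, 64)
        assert ss["manual"]["specificity_pct"] == 89.7
        assert ss["manual"]["specificity_frac"] == (235, 262)

    def test_men_reference_sens_spec(self):
        ss = sens_spec_from_crosstab(example_crosstab("men"))
        assert ss["ct"]["sensitivity_pct"] == 83.5
        assert ss["ct"]["sensitivity_frac"] == (152, 182)
        assert ss["ct"]["specificity_pct"] == 83.9
        assert ss["ct"]["specificity_frac"] == (209, 249)
        assert ss["manual"]["sensitivity_pct"] == 81.9
        assert ss["manual"]["sensitivity_frac"] == (149, 182)

    def test_women_concordance(self):
        pct, conc, total = concordance(example_crosstab("women"))
        assert (pct, conc, total) == (90.2, 294, 326)

    def test_men_concordance_by_summation(self):
        # direct summation of the bundled counts
        pct, conc, total = concordance(example_crosstab("men"))
        assert (pct, conc, total) == (86.3, 372, 431)

    def test_degenerate_denominator_raises(self):
        counts = np.zeros((2, 2, 4), int)
        counts[1, 1, 3] = 10  # all mass in concordant obesity cell
        with pytest.raises(DataError):
            sens_spec_from_crosstab(CrossTab(counts))

    def test_identity_table_full_concordance(self):
        counts = np.zeros((2, 2, 4), int)
        counts[0, 0, 1] = 30
        counts[1, 1, 2] = 20
        assert concordance(CrossTab(counts))[0] == 100.0

    def test_bmi_column_permutation_invariance(self):
        ct = example_crosstab("women")
        permuted = CrossTab(ct.counts[:, :, [1, 0, 3, 2]])  # swap within groups
        assert sens_spec_from_crosstab(ct) == sens_spec_from_crosstab(permuted)
        assert concordance(ct) == concordance(permuted)

    def test_from_cohort_roundtrip_and_marginals(self):
        df = generate_cohort(400, CohortParams(), seed=6)
        xt = CrossTab.from_cohort(df, 91.7, 85.0)
        assert xt.total == 400
        assert (xt.bmi_totals() >= 0).all()

    def test_csv_roundtrip(self, tmp_path):
        ct = example_crosstab("men")
        p = tmp_path / "xt.csv"
        ct.to_csv(p)
        back = CrossTab.from_csv(p)
        np.testing.assert_array_equal(back.counts, ct.counts)

    def test_discordant_pairs_women_positive_columns(self):
        b, c = discordant_pairs(example_crosstab("women"), (2, 3))
        assert (b, c) == (4, 5)


class TestMcNemar:
    def test_reference_discordants_give_p_one(self):
        assert mcnemar_test(4, 5) == pytest.approx(1.0)

    def test_no_discordants(self):
        assert mcnemar_test(0, 0) == 1.0

    def test_binomial_enumeration(self):
        # b=10, c=2: 2 * P(X <= 2 | n=12, 0.5) = 2*(1+12+66)/4096
        assert mcnemar_test(10, 2) == pytest.approx(2 * (1 + 12 + 66) / 4096)

    def test_matches_statsmodels_exact(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        for b, c in [(4, 5), (10, 2), (0, 7), (12, 12)]:
            table = [[0, b], [c, 0]]
            ref = sm.mcnemar(table, exact=True).pvalue
            assert mcnemar_test(b, c) == pytest.approx(ref, abs=1e-12)

    def test_large_counts_chi_square_branch(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        ref = sm.mcnemar([[0, 30], [12, 0]], exact=False, correction=True).pvalue
        assert mcnemar_test(30, 12) == pytest.approx(ref, abs=1e-10)

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError):
            mcnemar_test(-1, 3)
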