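"""Method-comparison statistics for paired waist-circumference data.

Everything needed to compare an imaging-derived measurement against a
reference measurement on the same subjects:

* Pearson correlation with Fisher-z confidence interval;
* Bland–Altman mean difference and 95% limits of agreement;
* two-way consistency intraclass correlation ICC(C,1), single measures,
  with the McGraw–Wong F-based confidence interval;
* ROC analysis: AUC by the Mann–Whitney formulation with tie correction,
  DeLong variance for the CI, Youden-optimal cutoff with its
  sensitivity/specificity, and the paired DeLong z-test for comparing
  two AUCs measured on the same subjects;
* 2 × 2 × BMI-category cross-tabulations with per-method sensitivity /
  specificity, concordance, and McNemar tests on discordant pairs.

Cutoff semantics throughout: *positive* means value >= cutoff.
Percentages are reported to 0.1 alongside their raw fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

BMI_CATEGORIES = ("underweight", "normal", "overweight", "obesity")
BMI_EDGES = (18.5, 25.0, 30.0)
#: BMI categories counted as disease-positive (overweight/obesity).
POSITIVE_BMI = (2, 3)
NEGATIVE_BMI = (0, 1)


# ---------------------------------------------------------------------------
# correlation / agreement


def pearson_r(x, y) -> tuple[float, tuple[float, float], float]:
    """Pearson r with 95% Fisher-z CI and two-sided t-test p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1D arrays of equal length")
    if len(x) < 3:
        raise DataError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("Pearson correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(0.95)  # Fisher z-transform interval
    return float(res.statistic), (float(ci.low), float(ci.high)), float(res.pvalue)


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference, SD of differences, and 95% limits of agreement (cm)."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland–Altman agreement of paired measurements; differences are x - y.

    LoA = mean ± 1.96·SD with the n-1 SD denominator.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1D arrays of equal length")
    n = len(x)
    if n < 2:
        raise DataError("Bland-Altman needs n >= 2")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(mean, sd, mean - 1.96 * sd, mean + 1.96 * sd, n)


def limits_of_agreement(mean_diff: float, sd_diff: float) -> tuple[float, float]:
    """LoA from summary statistics alone: mean ± 1.96·SD."""
    return mean_diff - 1.96 * sd_diff, mean_diff + 1.96 * sd_diff


def icc_consistency(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(C,1): two-way model, single measures, consistency definition.

    ICC = (MS_rows − MS_error) / (MS_rows + (k−1)·MS_error) with k = 2
    raters; the CI uses the F-distribution bounds of McGraw & Wong.
    Insensitive to a fixed offset between the two methods.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1D arrays of equal length")
    n = len(x)
    if n < 3:
        raise DataError("ICC needs n >= 3")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows == 0:
        raise DataError("zero between-subject variance: ICC undefined")
    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    if ms_err == 0:
        return float(icc), (float(icc), float(icc))
    f_obs = ms_rows / ms_err
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    lo = (f_l - 1) / (f_l + k - 1)
    hi = (f_u - 1) / (f_u + k - 1)
    return float(icc), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# ROC


@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative) of
    the Mann-Whitney AUC, as in DeLong et al. (1988)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # psi(x, y) = 1 if x > y, 0.5 if tie, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)  # length m
    v01 = cmp.mean(axis=0)  # length n
    auc = float(cmp.mean())
    return auc, v10, v01


def _check_binary(labels: np.ndarray) -> None:
    u = np.unique(labels)
    if not np.array_equal(u, [0, 1]):
        raise DataError("labels must contain both classes coded 0/1")


def roc_auc(scores, labels, alpha: float = 0.05) -> RocResult:
    """ROC analysis of one score against binary labels.

    AUC by the tie-corrected Mann–Whitney statistic, CI from the DeLong
    variance (normal approximation, clipped to [0, 1]); the reported
    cutoff maximizes Youden's J over midpoints between consecutive
    sorted unique scores, with ties broken toward higher specificity and
    then the lower cutoff.  A subject is test-positive when
    score >= cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DataError("scores and labels must be 1D arrays of equal length")
    _check_binary(labels)
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    ci_low, ci_high = max(0.0, auc - half), min(1.0, auc + half)

    cutoff, sens, spec, j = youden_cutoff(scores, labels)
    return RocResult(auc, float(ci_low), float(ci_high), cutoff, sens, spec, j)


def youden_cutoff(scores, labels) -> tuple[float, float, float, float]:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Candidates are midpoints between consecutive sorted unique scores;
    positives are score >= cutoff.  Ties on J prefer higher specificity,
    then the lower cutoff value.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_binary(labels)
    uniq = np.unique(scores)
    if len(uniq) == 1:
        # no informative threshold; declare everyone positive
        c = float(uniq[0])
        sens, spec = 1.0, 0.0
        return c, sens, spec, 0.0
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    pos = labels == 1
    best = None
    for c in candidates:
        test_pos = scores >= c
        sens = float((test_pos & pos).sum() / pos.sum())
        spec = float((~test_pos & ~pos).sum() / (~pos).sum())
        j = sens + spec - 1.0
        key = (round(j, 12), round(spec, 12), -c)
        if best is None or key > best[0]:
            best = (key, float(c), sens, spec, j)
    _, c, sens, spec, j = best
    return c, sens, spec, float(j)


def compare_auc_paired(s1, s2, labels) -> tuple[float, float]:
    """Paired DeLong z-test for the difference between two AUCs measured
    on the same subjects.  Returns (z, two-sided p); identical scores
    give z = 0, p = 1."""
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (s1.shape == s2.shape == labels.shape) or s1.ndim != 1:
        raise DataError("s1, s2 and labels must be 1D arrays of equal length")
    _check_binary(labels)
    auc1, v10_1, v01_1 = _delong_components(s1, labels)
    auc2, v10_2, v01_2 = _delong_components(s2, labels)
    m, n = len(v10_1), len(v01_1)
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var_diff <= 0:
        return 0.0, 1.0
    z = (auc1 - auc2) / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


# ---------------------------------------------------------------------------
# cross-tabulation


@dataclass
class CrossTab:
    """Counts by (ct_class, manual_class, BMI category).

    ``counts`` has shape (2, 2, 4): axis 0 is the CT class (0 = below,
    1 = at/above cutoff), axis 1 the manual class, axis 2 the BMI
    category (underweight, normal, overweight, obesity).
    """

    counts: np.ndarray
    cutoffs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2, 4):
            raise DataError("crosstab counts must have shape (2, 2, 4)")
        if (self.counts < 0).any():
            raise DataError("crosstab counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def bmi_totals(self) -> np.ndarray:
        return self.counts.sum(axis=(0, 1))

    @classmethod
    def from_cohort(
        cls,
        cohort: pd.DataFrame,
        ct_cutoff_cm: float,
        manual_cutoff_cm: float,
        bmi_edges: tuple[float, float, float] = BMI_EDGES,
    ) -> "CrossTab":
        """Cross-classify a cohort DataFrame (columns wc_ct_cm,
        wc_manual_cm, bmi_kg_m2); positive means value >= cutoff."""
        ct_cls = (cohort["wc_ct_cm"] >= ct_cutoff_cm).astype(int)
        man_cls = (cohort["wc_manual_cm"] >= manual_cutoff_cm).astype(int)
        bmi_cat = np.digitize(cohort["bmi_kg_m2"], bmi_edges)
        counts = np.zeros((2, 2, 4), dtype=int)
        np.add.at(counts, (ct_cls.to_numpy(), man_cls.to_numpy(), bmi_cat), 1)
        return cls(
            counts,
            {"ct_cutoff_cm": ct_cutoff_cm, "manual_cutoff_cm": manual_cutoff_cm},
        )

    def to_frame(self) -> pd.DataFrame:
        """Render in the conventional published layout: one row per
        (CT class, manual class) combination, one column per BMI category."""
        rows = []
        labels = {0: "below", 1: "at_or_above"}
        for ct in (0, 1):
            for man in (0, 1):
                rows.append(
                    {
                        "ct_class": labels[ct],
                        "manual_class": labels[man],
                        **{
                            BMI_CATEGORIES[b]: int(self.counts[ct, man, b])
                            for b in range(4)
                        },
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, cutoffs: dict | None = None) -> "CrossTab":
        df = pd.read_csv(path)
        counts = np.zeros((2, 2, 4), dtype=int)
        idx = {"below": 0, "at_or_above": 1}
        for _, row in df.iterrows():
            ct, man = idx[row["ct_class"]], idx[row["manual_class"]]
            for b, cat in enumerate(BMI_CATEGORIES):
                counts[ct, man, b] = int(row[cat])
        return cls(counts, cutoffs or {})


def sens_spec_from_crosstab(ct: CrossTab) -> dict:
    """Per-method sensitivity/specificity against BMI-defined disease.

    Disease-positive subjects are the overweight + obesity BMI columns.
    For the CT method test-positive means ct_class at/above; for the
    manual method, manual_class at/above.  Returns, per method, the
    percentage (to 0.1) and the raw fraction.
    """
    counts = ct.counts
    pos_cols = list(POSITIVE_BMI)
    neg_cols = list(NEGATIVE_BMI)
    out: dict = {}
    for method, axis in (("ct", 0), ("manual", 1)):
        test_pos = counts.take(1, axis=axis)  # (other_class, bmi)
        test_neg = counts.take(0, axis=axis)
        tp = int(test_pos[:, pos_cols].sum())
        fn = int(test_neg[:, pos_cols].sum())
        tn = int(test_neg[:, neg_cols].sum())
        fp = int(test_pos[:, neg_cols].sum())
        if tp + fn == 0 or tn + fp == 0:
            raise DataError("zero denominator in sensitivity or specificity")
        out[method] = {
            "sensitivity_pct": round(100.0 * tp / (tp + fn), 1),
            "sensitivity_frac": (tp, tp + fn),
            "specificity_pct": round(100.0 * tn / (tn + fp), 1),
            "specificity_frac": (tn, tn + fp),
        }
    return out


def concordance(ct: CrossTab) -> tuple[float, int, int]:
    """Proportion of subjects classified concordantly by both methods
    (both below or both at/above), over all BMI categories.
    Returns (proportion as % to 0.1, concordant count, total)."""
    if ct.total == 0:
        raise DataError("empty crosstab")
    conc = int(ct.counts[0, 0].sum() + ct.counts[1, 1].sum())
    return round(100.0 * conc / ct.total, 1), conc, ct.total


def discordant_pairs(ct: CrossTab, bmi_cols: tuple[int, ...]) -> tuple[int, int]:
    """Discordant counts (b, c) over the given BMI columns: b = CT-negative
    & manual-positive, c = CT-positive & manual-negative."""
    cols = list(bmi_cols)
    b = int(ct.counts[0, 1, cols].sum())
    c = int(ct.counts[1, 0, cols].sum())
    return b, c


def mcnemar_test(b: int, c: int) -> float:
    """McNemar test on discordant-pair counts.

    Exact two-sided binomial when b + c <= 25, chi-square with
    continuity correction otherwise; b = c = 0 gives p = 1.
    """
    if b < 0 or c < 0:
        raise DataError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    if n <= 25:
        k = min(b, c)
        tail = sum(comb(n, i) for i in range(k + 1)) / 2.0**n
        return float(min(1.0, 2.0 * tail))
    chi2 = (abs(b - c) - 1.0) ** 2 / n
    return float(stats.chi2.sf(chi2, df=1))
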