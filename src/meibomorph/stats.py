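"""Cohort statistics: normality-gated group comparisons, correlations, power.

The comparison logic mirrors standard ophthalmic-cohort practice:

* continuous variables — Shapiro-Wilk normality per group at α = 0.05;
  both normal → two-sample t (Welch when an F variance-ratio test
  rejects equal variances at 0.05), otherwise Mann-Whitney U;
* categorical variables — chi-square, or Fisher's exact test when any
  expected cell count falls below 5;
* all tests two-sided, no multiple-testing correction by default
  (a Benjamini-Hochberg helper is available).

Eyes are treated as independent observations (no within-patient
clustering), matching how such cohorts are usually reported; see the
methods note for the caveat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

logger = logging.getLogger(__name__)

ALPHA_GATE = 0.05  # gate level for normality and variance-ratio pre-tests


@dataclass
class TestResult:
    variable: str
    test_name: str  # t | welch_t | mann_whitney | chi_square | fisher
    statistic: float
    p_value: float
    group_summaries: dict[str, tuple[float, float, int]] = field(default_factory=dict)
    df: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValidationError(f"p-value out of [0, 1]: {self.p_value}")


def _variance_ratio_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided F test on the ratio of sample variances."""
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if min(vx, vy) == 0:
        return 0.0
    f = vx / vy
    p = sps.f.sf(f, len(x) - 1, len(y) - 1)
    return 2 * min(p, 1 - p)


def compare_groups(
    table: pd.DataFrame, variable: str, group_col: str = "group"
) -> TestResult:
    """Two-group comparison of one column, with the normality-gated test choice."""
    for col in (variable, group_col):
        if col not in table.columns:
            raise ValidationError(f"missing column {col!r}")
    groups = [g for g, _ in table.groupby(group_col, sort=True)]
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, found {groups}")
    sub = table[[group_col, variable]].dropna()
    a = sub.loc[sub[group_col] == groups[0], variable]
    b = sub.loc[sub[group_col] == groups[1], variable]
    if a.empty or b.empty:
        raise ValidationError(f"a group has no data for {variable!r}")

    if pd.api.types.is_numeric_dtype(sub[variable]):
        x, y = a.to_numpy(float), b.to_numpy(float)
        if min(len(x), len(y)) < 3:
            raise ValidationError(f"need >= 3 values per group for {variable!r}")
        summaries = {
            groups[0]: (float(x.mean()), float(x.std(ddof=1)), len(x)),
            groups[1]: (float(y.mean()), float(y.std(ddof=1)), len(y)),
        }
        normal = (
            sps.shapiro(x).pvalue > ALPHA_GATE and sps.shapiro(y).pvalue > ALPHA_GATE
        )
        if normal:
            equal_var = _variance_ratio_test(x, y) > ALPHA_GATE
            res = sps.ttest_ind(x, y, equal_var=equal_var)
            name = "t" if equal_var else "welch_t"
            df = len(x) + len(y) - 2 if equal_var else float(res.df)
            return TestResult(variable, name, float(res.statistic), float(res.pvalue),
                              summaries, df=df)
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        return TestResult(variable, "mann_whitney", float(res.statistic),
                          float(res.pvalue), summaries)

    # categorical
    contingency = pd.crosstab(sub[group_col], sub[variable])
    expected = sps.contingency.expected_freq(contingency.to_numpy())
    if (expected < 5).any():
        if contingency.shape != (2, 2):
            raise ValidationError(
                "Fisher's exact fallback requires a 2x2 table "
                f"(got {contingency.shape} for {variable!r})"
            )
        odds, p = sps.fisher_exact(contingency.to_numpy())
        return TestResult(variable, "fisher", float(odds), float(p))
    chi2, p, dof, _ = sps.chi2_contingency(contingency.to_numpy())
    return TestResult(variable, "chi_square", float(chi2), float(p), df=float(dof))


def summary_ttest(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "pooled",
) -> TestResult:
    """Two-sample t-test from printed summary statistics (mean, SD, n)."""
    if min(sd1, sd2) <= 0:
        raise ValidationError("standard deviations must be positive")
    if min(n1, n2) < 2:
        raise ValidationError("need n >= 2 per group")
    if variant not in ("pooled", "welch"):
        raise ValidationError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    equal_var = variant == "pooled"
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    if equal_var:
        df = n1 + n2 - 2
    else:
        q1, q2 = sd1**2 / n1, sd2**2 / n2
        df = (q1 + q2) ** 2 / (q1**2 / (n1 - 1) + q2**2 / (n2 - 1))
    return TestResult(
        variable="",
        test_name="t" if equal_var else "welch_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_summaries={"group1": (mean1, sd1, n1), "group2": (mean2, sd2, n2)},
        df=float(df),
    )


def correlation_matrix(
    table: pd.DataFrame, columns: list[str], method: str = "spearman"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise correlation matrix with p-values on complete pairs.

    ``sex`` (or any object column) must already be encoded numerically;
    constant columns yield NaN entries with a warning.  Returns
    ``(correlations, p_values)`` as symmetric DataFrames with unit/zero
    diagonals.
    """
    if method not in ("spearman", "pearson"):
        raise ValidationError(f"method must be 'spearman' or 'pearson', got {method!r}")
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    data = table[columns]
    if len(data.dropna()) < 3:
        raise ValidationError("need at least 3 complete rows")
    k = len(columns)
    corr = pd.DataFrame(np.eye(k), index=columns, columns=columns)
    pvals = pd.DataFrame(np.zeros((k, k)), index=columns, columns=columns)
    fn = sps.spearmanr if method == "spearman" else sps.pearsonr
    for i in range(k):
        for j in range(i + 1, k):
            pair = data[[columns[i], columns[j]]].dropna().to_numpy(float)
            if len(pair) < 3 or np.ptp(pair[:, 0]) == 0 or np.ptp(pair[:, 1]) == 0:
                logger.warning(
                    "constant or empty pair (%s, %s): correlation recorded as missing",
                    columns[i], columns[j],
                )
                r, p = np.nan, np.nan
            else:
                res = fn(pair[:, 0], pair[:, 1])
                r, p = float(res.statistic), float(res.pvalue)
            corr.iloc[i, j] = corr.iloc[j, i] = r
            pvals.iloc[i, j] = pvals.iloc[j, i] = p
    return corr, pvals


def encode_sex(series: pd.Series) -> pd.Series:
    """female = 0, male = 1, so positive coefficients mean 'higher in males'."""
    return series.map({"female": 0.0, "male": 1.0})


def power_sample_size(
    effect_d: float, alpha: float = 0.05, power: float = 0.80, sides: str = "two-sided"
) -> int:
    """Smallest per-group n for a two-sample t-test at the requested power.

    Exact noncentral-t power function with an integer search.
    """
    if effect_d <= 0:
        raise ValidationError("effect_d must be > 0")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValidationError("alpha and power must lie in (0, 1)")
    if sides not in ("two-sided", "one-sided"):
        raise ValidationError("sides must be 'two-sided' or 'one-sided'")

    def achieved(n: int) -> float:
        df = 2 * n - 2
        nc = effect_d * np.sqrt(n / 2.0)
        if sides == "two-sided":
            crit = sps.t.ppf(1 - alpha / 2, df)
            return float(sps.nct.sf(crit, df, nc) + sps.nct.cdf(-crit, df, nc))
        crit = sps.t.ppf(1 - alpha, df)
        return float(sps.nct.sf(crit, df, nc))

    n = 2
    while achieved(n) < power:
        n += 1
        if n > 1_000_000:
            raise ValidationError("requested power is unreachable at this effect size")
    return n


def benjamini_hochberg(p_values: list[float], alpha: float = 0.05) -> np.ndarray:
    """FDR-adjusted p-values (off by default in every pipeline)."""
    return multipletests(p_values, alpha=alpha, method="fdr_bh")[1]
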