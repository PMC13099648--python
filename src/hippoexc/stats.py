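"""Statistical framework shared across pipeline stages.

Likelihood-ratio testing of age + genotype effects against an
intercept-only null (Gaussian likelihood, profiled variance), FDR control
(Benjamini-Hochberg), normality-routed post hoc pairwise tests (Shapiro-Wilk
gate: Student's t vs Mann-Whitney U), one-/two-way ANOVA with Tukey HSD,
the Cochran-Mantel-Haenszel stratified test, Pearson correlation, and
per-cluster proportional-representation t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LrtResult",
    "PosthocResult",
    "CmhResult",
    "lrt_age_genotype",
    "fdr_bh",
    "posthoc_pairwise",
    "anova",
    "cmh_test",
    "pearson_corr",
    "cluster_proportion_tests",
]


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class PosthocResult:
    test_used: str  # "t-test" or "mann-whitney"
    statistic: float
    p: float


@dataclass(frozen=True)
class CmhResult:
    chi2: float
    p: float
    common_odds_ratio: float
    n_strata_used: int


def lrt_age_genotype(values, genotype, age, reference: str = "exact") -> LrtResult:
    """Likelihood-ratio test of a Gaussian model with age + genotype main
    effects against an intercept-only null.

    statistic = 2(l_full - l_null) = n ln(RSS0/RSS1) with df = number of
    added factor parameters.  The p-value uses the exact finite-sample null
    distribution of this statistic (it is a monotone function of the nested
    F statistic, so the F reference is exact under Gaussian errors); the
    asymptotic chi-square reference, which is anti-conservative at small n,
    is available with ``reference="chisq"``.
    """
    y = np.asarray(values, dtype=float)
    df_ = pd.DataFrame({"genotype": np.asarray(genotype), "age": np.asarray(age)})
    if df_["genotype"].nunique() < 2 or df_["age"].nunique() < 2:
        raise ValueError("need at least two levels of each factor")
    X = pd.get_dummies(df_, columns=["genotype", "age"], drop_first=True).astype(float)
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise ValueError("singular design matrix")
    n, p_full = y.size, X.shape[1]
    if n - p_full <= 0:
        raise ValueError("no residual degrees of freedom")
    full = sm.OLS(y, X).fit()
    null = sm.OLS(y, np.ones((n, 1))).fit()
    k = p_full - 1
    stat = max(2.0 * (full.llf - null.llf), 0.0)
    if reference == "chisq":
        p = float(sps.chi2.sf(stat, k))
    elif reference == "exact":
        # LR = n ln(1 + k F / (n - p)); invert and refer to F(k, n - p)
        f_equiv = (np.expm1(stat / n)) * (n - p_full) / k
        p = float(sps.f.sf(f_equiv, k, n - p_full))
    else:
        raise ValueError("reference must be 'exact' or 'chisq'")
    return LrtResult(float(stat), int(k), p)


def fdr_bh(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, rejection flags at level q)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def posthoc_pairwise(group_a, group_b, alpha_normality: float = 0.05) -> PosthocResult:
    """Distribution-aware two-group comparison.

    Both groups pass Shapiro-Wilk at ``alpha_normality`` -> unpaired
    two-tailed Student's t; otherwise two-tailed Mann-Whitney U (exact for
    small tie-free samples, tie-corrected normal approximation otherwise).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need n >= 3 per group")
    normal = (sps.shapiro(a).pvalue > alpha_normality
              and sps.shapiro(b).pvalue > alpha_normality)
    if normal:
        res = sps.ttest_ind(a, b)
        return PosthocResult("t-test", float(res.statistic), float(res.pvalue))
    method = "exact" if (a.size <= 20 and b.size <= 20) else "asymptotic"
    try:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:  # ties with exact method
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return PosthocResult("mann-whitney", float(res.statistic), float(res.pvalue))


def anova(values, factors: dict, design: str = "oneway"):
    """Classical ANOVA with Tukey HSD post hoc contrasts.

    ``oneway``: one factor; ``twoway``: two crossed factors, type II sums
    of squares with interaction.  Returns (anova_table, tukey DataFrame);
    Tukey compares all factor-level (combination) groups pairwise.
    """
    y = np.asarray(values, dtype=float)
    fnames = list(factors)
    df = pd.DataFrame({"y": y})
    for name in fnames:
        arr = np.asarray(factors[name]).astype(str)
        if arr.size != y.size:
            raise ValueError(f"factor {name} length mismatch")
        df[name] = arr

    if design == "oneway":
        if len(fnames) != 1:
            raise ValueError("oneway design needs exactly one factor")
        f = fnames[0]
        counts = df.groupby(f)["y"].count()
        if (counts < 2).any() or len(counts) < 2:
            raise ValueError("need >= 2 groups with n >= 2 each")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # F on zero-residual data
            model = ols(f"y ~ C({f})", data=df).fit()
            table = anova_lm(model, typ=1)
        group = df[f]
    elif design == "twoway":
        if len(fnames) != 2:
            raise ValueError("twoway design needs exactly two factors")
        f1, f2 = fnames
        cell_counts = df.groupby([f1, f2])["y"].count()
        expected = df[f1].nunique() * df[f2].nunique()
        if len(cell_counts) < expected or (cell_counts < 1).any():
            raise ValueError("empty cell in two-way design")
        model = ols(f"y ~ C({f1}) + C({f2}) + C({f1}):C({f2})", data=df).fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # F on zero-residual data
            table = anova_lm(model, typ=2)
        group = df[f1] + ":" + df[f2]
    else:
        raise ValueError("design must be 'oneway' or 'twoway'")

    # a factor explaining zero variation has F = 0 by convention, not NaN
    if "F" in table.columns:
        zero_ss = table["sum_sq"] == 0
        table.loc[zero_ss, "F"] = table.loc[zero_ss, "F"].fillna(0.0)
        if "PR(>F)" in table.columns:
            table.loc[zero_ss & table["PR(>F)"].isna(), "PR(>F)"] = 1.0

    if group.nunique() >= 2 and np.ptp(y) > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance pairs
            tk = pairwise_tukeyhsd(y, group.values)
        tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    else:
        tukey = pd.DataFrame()
    return table, tukey


def cmh_test(strata) -> CmhResult:
    """Cochran-Mantel-Haenszel test over K 2x2 strata (no continuity correction).

    Strata with a zero margin carry no information and are dropped with a
    warning.  Returns the MH chi-square, its p-value, and the MH common
    odds ratio.
    """
    tables = []
    for t in strata:
        t = np.asarray(t, dtype=float)
        if t.shape != (2, 2) or (t < 0).any():
            raise ValueError("each stratum must be a nonnegative 2x2 table")
        if t.sum() == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            warnings.warn("dropping stratum with a zero margin")
            continue
        tables.append(t)
    if not tables:
        raise ValueError("no usable strata")
    st = StratifiedTable(tables)
    res = st.test_null_odds(correction=False)
    return CmhResult(
        chi2=float(res.statistic),
        p=float(res.pvalue),
        common_odds_ratio=float(st.oddsratio_pooled),
        n_strata_used=len(tables),
    )


def pearson_corr(x, y) -> tuple[float, float]:
    """Two-sided Pearson product-moment correlation (r, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need aligned samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def cluster_proportion_tests(props: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Per-cluster t-tests on per-sample cluster proportions between 2 groups.

    ``props`` columns: sample, group, cluster, proportion.  Returns one row
    per cluster with raw p, BH-adjusted p, and enrichment flags on both.
    """
    req = {"sample", "group", "cluster", "proportion"}
    if not req.issubset(props.columns):
        raise ValueError(f"props must have columns {sorted(req)}")
    groups = sorted(props["group"].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    rows = []
    for cl, sub in props.groupby("cluster"):
        a = sub.loc[sub["group"] == groups[0], "proportion"].to_numpy(float)
        b = sub.loc[sub["group"] == groups[1], "proportion"].to_numpy(float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"cluster {cl}: need >= 2 samples per group")
        if np.ptp(np.r_[a, b]) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(a, b)
        rows.append({"cluster": cl, "statistic": float(t), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"], out["enriched_adj"] = fdr_bh(out["p_raw"].values, q)
    out["enriched_raw"] = out["p_raw"] < q
    return out
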