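"""Shared statistical procedures.

Every pipeline stage routes its hypothesis tests through this module so the
whole package uses a single audited implementation of each procedure: unpaired
two-sample t-tests (pooled or Welch), Mann-Whitney U, two-sample
Kolmogorov-Smirnov, the Holm-Šidák step-down multiple-comparison correction,
two-way (type-II) ANOVA for crossed factors, the classical two-way
repeated-measures (mixed between-within) ANOVA, and single-step Šidák
post-hoc comparisons.

Scalar tests delegate to :mod:`scipy.stats`; the two-way type-II ANOVA
delegates to :mod:`statsmodels`.  The Holm-Šidák step-down, the Šidák
post-hoc and the mixed-design ANOVA sums of squares are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "TestResult",
    "two_sample_t",
    "mann_whitney",
    "ks_two_sample",
    "holm_sidak",
    "sidak_adjust",
    "two_way_anova",
    "two_way_rm_anova",
    "sidak_posthoc",
    "results_table",
]


@dataclass
class TestResult:
    """Outcome of one hypothesis test.

    ``df`` is a single number for t-like tests and a ``(df1, df2)`` pair for
    F tests.  ``p_adjusted`` is filled only when a multiple-comparison
    correction was applied; ``significant`` compares the adjusted p (raw p
    when no adjustment) against ``alpha``.
    """

    name: str
    statistic: float
    df: float | tuple[float, float] | None
    p: float
    p_adjusted: float | None = None
    alpha: float = 0.05
    flags: list[str] = field(default_factory=list)

    @property
    def effective_p(self) -> float:
        return self.p if self.p_adjusted is None else self.p_adjusted

    @property
    def significant(self) -> bool:
        return bool(self.effective_p < self.alpha)

    def as_row(self, analysis: str = "", effect: str = "") -> dict:
        df1, df2 = (self.df if isinstance(self.df, tuple) else (self.df, None))
        return {
            "analysis": analysis,
            "effect": effect or self.name,
            "statistic": self.name,
            "value": self.statistic,
            "df1": df1,
            "df2": df2,
            "p_raw": self.p,
            "p_adj": self.p_adjusted,
            "significant": self.significant,
        }


def results_table(rows: list[tuple[str, str, TestResult]]) -> pd.DataFrame:
    """Serialise ``(analysis, effect, result)`` triples to the tidy CSV schema."""
    return pd.DataFrame([r.as_row(a, e) for a, e, r in rows])


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def two_sample_t(
    a,
    b,
    pooled: bool = True,
    two_tailed: bool = True,
    alpha: float = 0.05,
) -> TestResult:
    """Unpaired two-sample t-test (pooled-variance Student by default).

    With ``pooled=False`` a Welch test is run instead.  The degenerate case
    of zero pooled variance is resolved by convention: equal means give
    t = 0, p = 1 (flagged); unequal means give an infinite t, p = 0.
    """
    a, b = _as_1d(a, "a"), _as_1d(b, "b")
    if a.size < 2 or b.size < 2:
        raise ValidationError("two_sample_t needs >=2 values per group")
    na, nb = a.size, b.size
    df = na + nb - 2 if pooled else None
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        flags = ["zero_variance"]
        if a.mean() == b.mean():
            return TestResult("t", 0.0, float(na + nb - 2), 1.0, alpha=alpha, flags=flags)
        t = np.inf if a.mean() > b.mean() else -np.inf
        return TestResult("t", float(t), float(na + nb - 2), 0.0, alpha=alpha, flags=flags)
    alternative = "two-sided" if two_tailed else "greater"
    res = sps.ttest_ind(a, b, equal_var=pooled, alternative=alternative)
    df = float(df if pooled else res.df)
    return TestResult("t", float(res.statistic), df, float(res.pvalue), alpha=alpha)


def mann_whitney(a, b, alpha: float = 0.05) -> TestResult:
    """Two-tailed Mann-Whitney U test.

    Exact enumeration for small tie-free samples (both n <= 20); normal
    approximation with tie correction otherwise.
    """
    a, b = _as_1d(a, "a"), _as_1d(b, "b")
    if a.size < 1 or b.size < 1:
        raise ValidationError("mann_whitney needs >=1 value per group")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(a.size, b.size) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult("U", float(res.statistic), None, float(res.pvalue), alpha=alpha)


def ks_two_sample(a, b, alpha: float = 0.05) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    a, b = _as_1d(a, "a"), _as_1d(b, "b")
    if a.size < 2 or b.size < 2:
        raise ValidationError("ks_two_sample needs >=2 values per group")
    res = sps.ks_2samp(a, b, method="asymp")
    return TestResult("D", float(res.statistic), None, float(res.pvalue), alpha=alpha)


def sidak_adjust(p: float, m: int) -> float:
    """Single-step Šidák adjustment 1 - (1 - p)^m for m planned comparisons."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p-value {p} outside [0, 1]")
    if m < 1:
        raise ValidationError("m must be >= 1")
    if m == 1:
        return float(p)
    return float(min(1.0, 1.0 - (1.0 - p) ** m))


def holm_sidak(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm-Šidák step-down correction.

    Sort the m raw p-values ascending; the i-th smallest gets the candidate
    adjustment 1 - (1 - p_(i))^(m - i + 1); adjusted p-values are made
    monotone by a running maximum down the sorted list and capped at 1.
    Returns ``(adjusted, reject)`` in the original order, rejecting while the
    adjusted p is below ``alpha``.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        candidate = 1.0 - (1.0 - p[idx]) ** (m - i)
        running = max(running, candidate)
        adj_sorted[i] = min(1.0, running)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted < alpha


def two_way_anova(values, factor_a, factor_b, alpha: float = 0.05,
                  names: tuple[str, str] = ("A", "B")) -> dict[str, TestResult]:
    """Two-way crossed ANOVA with type-II sums of squares (unbalanced-safe).

    Returns main effects and the interaction keyed by the factor names.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    y = _as_1d(values, "values")
    fa = np.asarray(factor_a).ravel()
    fb = np.asarray(factor_b).ravel()
    if not (y.size == fa.size == fb.size):
        raise ValidationError("values and factors must have equal length")
    if np.unique(fa).size < 2 or np.unique(fb).size < 2:
        raise ValidationError("each factor needs >=2 levels")
    df = pd.DataFrame({"y": y, "fa": fa.astype(str), "fb": fb.astype(str)})
    model = smf.ols("y ~ C(fa) * C(fb)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out: dict[str, TestResult] = {}
    keymap = {"C(fa)": names[0], "C(fb)": names[1],
              "C(fa):C(fb)": f"{names[0]}x{names[1]}"}
    df_resid = float(table.loc["Residual", "df"])
    for row, key in keymap.items():
        out[key] = TestResult(
            "F", float(table.loc[row, "F"]),
            (float(table.loc[row, "df"]), df_resid),
            float(table.loc[row, "PR(>F)"]), alpha=alpha,
        )
    return out


@dataclass
class MixedAnovaFit:
    """Fitted mixed (between x within) ANOVA with the error terms post-hocs need."""

    results: dict[str, TestResult]
    cell_means: pd.DataFrame      # index: between level, columns: within level
    cell_ns: pd.DataFrame
    ms_error_between: float
    df_error_between: float
    ms_error_within: float
    df_error_within: float

    @property
    def ms_error_pooled(self) -> float:
        """Pooled error for between-group comparisons at a single within level."""
        ss = (self.ms_error_between * self.df_error_between
              + self.ms_error_within * self.df_error_within)
        return ss / (self.df_error_between + self.df_error_within)

    @property
    def df_error_pooled(self) -> float:
        return self.df_error_between + self.df_error_within


def two_way_rm_anova(values, between, within, subject,
                     alpha: float = 0.05) -> MixedAnovaFit:
    """Two-way repeated-measures (mixed) ANOVA, classical univariate SS.

    ``between`` assigns each observation to a group (each subject belongs to
    exactly one), ``within`` is the repeated factor observed once per subject
    per level.  The between-subject effect is tested against the
    subjects-within-groups error (df = N_subjects - n_groups); the within
    main effect and the interaction are tested against the subject x within
    residual.  Subjects missing any within level are excluded listwise.  No
    sphericity correction is applied (matching the uncorrected df convention
    of common analysis software).
    """
    df = pd.DataFrame({
        "y": _as_1d(values, "values"),
        "g": np.asarray(between).ravel().astype(str),
        "w": np.asarray(within).ravel().astype(str),
        "s": np.asarray(subject).ravel().astype(str),
    })
    if not (len(df) == df["g"].size == df["w"].size == df["s"].size):
        raise ValidationError("ragged inputs")
    levels_w = sorted(df["w"].unique())
    k = len(levels_w)
    if k < 2:
        raise ValidationError("within factor needs >=2 levels")
    # listwise-complete subjects only
    counts = df.groupby("s")["w"].nunique()
    complete = counts[counts == k].index
    excluded = sorted(set(df["s"]) - set(complete))
    df = df[df["s"].isin(complete)]
    subjects = df["s"].unique()
    n_sub = subjects.size
    if n_sub < 2:
        raise ValidationError("need >=2 complete subjects")
    groups = sorted(df["g"].unique())
    n_g = len(groups)
    if n_g < 2:
        raise ValidationError("between factor needs >=2 levels")

    grand = df["y"].mean()
    ss_total = ((df["y"] - grand) ** 2).sum()
    sub_means = df.groupby("s")["y"].mean()
    ss_subjects = k * ((sub_means - grand) ** 2).sum()
    g_of_sub = df.groupby("s")["g"].first()
    n_per_group = g_of_sub.groupby(g_of_sub).size()
    g_means = df.groupby("g")["y"].mean()
    ss_group = k * (n_per_group * (g_means - grand) ** 2).sum()
    ss_err_between = ss_subjects - ss_group
    w_means = df.groupby("w")["y"].mean()
    ss_within_factor = n_sub * ((w_means - grand) ** 2).sum()
    cell = df.groupby(["g", "w"])["y"].agg(["mean", "count"]).reset_index()
    ss_cells = (cell["count"] * (cell["mean"] - grand) ** 2).sum()
    ss_interaction = ss_cells - ss_group - ss_within_factor
    ss_err_within = ss_total - ss_subjects - ss_within_factor - ss_interaction

    df_group, df_err_b = n_g - 1.0, n_sub - float(n_g)
    df_within, df_int = k - 1.0, (n_g - 1.0) * (k - 1.0)
    df_err_w = df_err_b * (k - 1.0)
    if df_err_b <= 0 or df_err_w <= 0:
        raise ValidationError("not enough subjects for the error terms")

    ms_err_b = ss_err_between / df_err_b
    ms_err_w = ss_err_within / df_err_w

    def ftest(name, ss, df1, ms_err, df2):
        if ms_err == 0.0:
            f = 0.0 if ss == 0.0 else np.inf
            p = 1.0 if ss == 0.0 else 0.0
            return TestResult("F", f, (df1, df2), p, alpha=alpha,
                              flags=["zero_error_variance"])
        f = (ss / df1) / ms_err
        p = float(sps.f.sf(f, df1, df2))
        return TestResult("F", float(f), (df1, df2), p, alpha=alpha)

    results = {
        "between": ftest("between", ss_group, df_group, ms_err_b, df_err_b),
        "within": ftest("within", ss_within_factor, df_within, ms_err_w, df_err_w),
        "interaction": ftest("interaction", ss_interaction, df_int, ms_err_w, df_err_w),
    }
    if excluded:
        for r in results.values():
            r.flags.append(f"excluded_subjects={','.join(excluded)}")
    cm = cell.pivot(index="g", columns="w", values="mean")
    cn = cell.pivot(index="g", columns="w", values="count")
    return MixedAnovaFit(results, cm, cn, float(ms_err_b), float(df_err_b),
                         float(ms_err_w), float(df_err_w))


def sidak_posthoc(fit: MixedAnovaFit, comparisons: list[tuple[str, str, str]] | None = None,
                  alpha: float = 0.05) -> dict[str, TestResult]:
    """Šidák-corrected post-hoc between-group comparisons after a mixed ANOVA.

    ``comparisons`` lists ``(group_a, group_b, within_level)`` cells; by
    default the first two groups are compared at every within level.  Each
    comparison uses the pooled error term (between + within residual) and
    the single-step adjustment 1 - (1 - p)^m with m = number of comparisons.
    """
    groups = list(fit.cell_means.index)
    wlevels = list(fit.cell_means.columns)
    if comparisons is None:
        if len(groups) < 2:
            raise ValidationError("need two groups for post-hoc comparisons")
        comparisons = [(groups[0], groups[1], w) for w in wlevels]
    m = len(comparisons)
    out: dict[str, TestResult] = {}
    for ga, gb, w in comparisons:
        if ga not in groups or gb not in groups or w not in wlevels:
            raise ValidationError(f"unknown cell in comparison ({ga}, {gb}, {w})")
        ma, mb = fit.cell_means.loc[ga, w], fit.cell_means.loc[gb, w]
        na, nb = fit.cell_ns.loc[ga, w], fit.cell_ns.loc[gb, w]
        se = np.sqrt(fit.ms_error_pooled * (1.0 / na + 1.0 / nb))
        if se == 0.0:
            t, p = (0.0, 1.0) if ma == mb else (np.inf, 0.0)
        else:
            t = (ma - mb) / se
            p = 2.0 * float(sps.t.sf(abs(t), fit.df_error_pooled))
        res = TestResult("t", float(t), fit.df_error_pooled, p, alpha=alpha)
        res.p_adjusted = sidak_adjust(min(1.0, p), m)
        out[f"{ga}-{gb}@{w}"] = res
    return out
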