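"""Group-comparison layer mirroring the study's testing conventions:
Shapiro-Wilk normality check, unpaired Student's t-test for two groups,
one-way ANOVA with Bonferroni-corrected pairwise post hocs for more,
two-way ANOVA for genotype x timepoint designs, and two-sample
Kolmogorov-Smirnov for cumulative distributions. Significance bands:
* p<0.05, ** p<0.01, *** p<0.001.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as st

__all__ = [
    "TestResult",
    "stars",
    "compare_groups",
    "compare_distributions",
    "two_way_anova",
    "treatment_contrast",
]


@dataclass
class TestResult:
    metric: str
    groups: tuple
    test: str
    statistic: float
    p_raw: float
    p_adjusted: float
    n_per_group: tuple
    normality_p: tuple = ()
    normal: bool | None = None
    reliable: bool = True
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.p_adjusted < 0.05

    @property
    def stars(self) -> str:
        return stars(self.p_adjusted)

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "groups": " vs ".join(map(str, self.groups)),
            "test": self.test,
            "statistic": self.statistic,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "n": "/".join(map(str, self.n_per_group)),
            "normal": self.normal,
            "significant": self.significant,
            "stars": self.stars,
            "reliable": self.reliable,
            "note": self.note,
        }


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _normality(samples: list[np.ndarray]) -> tuple[tuple, bool | None]:
    ps = []
    for s in samples:
        if s.size >= 3 and np.ptp(s) > 0:
            ps.append(float(st.shapiro(s).pvalue))
        else:
            ps.append(np.nan)
    valid = [p for p in ps if not np.isnan(p)]
    normal = all(p > 0.05 for p in valid) if valid else None
    return tuple(ps), normal


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    group_col: str = "group",
    nonparametric_fallback: bool = False,
) -> list[TestResult]:
    """Compare a metric across the groups of a tidy table (one row per
    experimental unit — MEA well or patched cell).

    Two groups: unpaired Student's t-test. More: one-way ANOVA followed by
    all pairwise t-tests with Bonferroni correction (factor = number of
    pairs). Normality is assessed per group with Shapiro-Wilk and reported;
    the parametric test is the default regardless, with an optional
    rank-based (Mann-Whitney) fallback behind ``nonparametric_fallback``.
    Groups with n < 3 flag the result unreliable rather than dropping it.
    """
    sub = table[[group_col, metric]].dropna()
    levels = list(pd.unique(sub[group_col]))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = {g: sub.loc[sub[group_col] == g, metric].to_numpy(dtype=float)
               for g in levels}
    ns = tuple(samples[g].size for g in levels)
    reliable = all(n >= 3 for n in ns)
    norm_ps, normal = _normality([samples[g] for g in levels])
    use_ranks = nonparametric_fallback and normal is False

    results: list[TestResult] = []
    if len(levels) == 2:
        a, b = samples[levels[0]], samples[levels[1]]
        if use_ranks:
            res = st.mannwhitneyu(a, b, alternative="two-sided")
            name = "Mann-Whitney U"
        else:
            res = st.ttest_ind(a, b)
            name = "Student's t (unpaired)"
        results.append(TestResult(
            metric=metric, groups=tuple(levels), test=name,
            statistic=float(res.statistic), p_raw=float(res.pvalue),
            p_adjusted=float(res.pvalue), n_per_group=ns,
            normality_p=norm_ps, normal=normal, reliable=reliable,
            note="" if reliable else "group with n < 3",
        ))
        return results

    f = st.f_oneway(*[samples[g] for g in levels])
    results.append(TestResult(
        metric=metric, groups=tuple(levels), test="one-way ANOVA",
        statistic=float(f.statistic), p_raw=float(f.pvalue),
        p_adjusted=float(f.pvalue), n_per_group=ns,
        normality_p=norm_ps, normal=normal, reliable=reliable,
    ))
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    for ga, gb in pairs:
        res = st.ttest_ind(samples[ga], samples[gb])
        results.append(TestResult(
            metric=metric, groups=(ga, gb),
            test="pairwise t + Bonferroni",
            statistic=float(res.statistic), p_raw=float(res.pvalue),
            p_adjusted=float(min(res.pvalue * m, 1.0)),
            n_per_group=(samples[ga].size, samples[gb].size),
            normal=normal,
            reliable=samples[ga].size >= 3 and samples[gb].size >= 3,
            note=f"Bonferroni factor {m}",
        ))
    return results


def compare_distributions(
    a: np.ndarray, b: np.ndarray, metric: str = "amplitude",
    labels: tuple = ("a", "b"),
) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test on pooled per-event values
    (cumulative-distribution comparison)."""
    res = st.ks_2samp(np.asarray(a, float), np.asarray(b, float))
    return TestResult(
        metric=metric, groups=labels, test="Kolmogorov-Smirnov",
        statistic=float(res.statistic), p_raw=float(res.pvalue),
        p_adjusted=float(res.pvalue),
        n_per_group=(len(a), len(b)),
    )


def two_way_anova(
    table: pd.DataFrame, metric: str, factor_a: str, factor_b: str
) -> list[TestResult]:
    """Two-way ANOVA (type II) with interaction, e.g. genotype x DIV;
    samples are treated as independent across cells."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = table[[factor_a, factor_b, metric]].dropna().rename(columns={metric: "_y"})
    model = ols(f"_y ~ C({factor_a}) * C({factor_b})", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    out = []
    for term in aov.index:
        if term == "Residual":
            continue
        p = float(aov.loc[term, "PR(>F)"])
        out.append(TestResult(
            metric=metric, groups=(term,), test="two-way ANOVA",
            statistic=float(aov.loc[term, "F"]), p_raw=p, p_adjusted=p,
            n_per_group=(len(df),),
        ))
    return out


def treatment_contrast(
    baseline: pd.DataFrame,
    treated: pd.DataFrame,
    metrics: list[str],
    pairing: str = "unpaired",
    unit_col: str = "well",
    labels: tuple = ("baseline", "treated"),
) -> list[TestResult]:
    """Pre/post pharmacology contrast per metric.

    ``paired`` requires matching unit identifiers in both phases and uses
    a paired t-test; mismatches raise with the offending units listed.
    ``unpaired`` pools via the standard two-group path."""
    results = []
    if pairing == "paired":
        missing = sorted(set(baseline[unit_col]) ^ set(treated[unit_col]))
        if missing:
            raise ValueError(f"paired design, units present in only one phase: {missing}")
        b = baseline.set_index(unit_col).sort_index()
        t = treated.set_index(unit_col).sort_index()
        for m in metrics:
            x, y = b[m].to_numpy(float), t[m].to_numpy(float)
            if np.allclose(x, y):
                stat, p = 0.0, 1.0
            else:
                res = st.ttest_rel(x, y)
                stat, p = float(res.statistic), float(res.pvalue)
            results.append(TestResult(
                metric=m, groups=labels, test="Student's t (paired)",
                statistic=stat, p_raw=p, p_adjusted=p,
                n_per_group=(x.size, y.size),
            ))
        return results
    if pairing != "unpaired":
        raise ValueError("pairing must be 'paired' or 'unpaired'")
    for m in metrics:
        combined = pd.concat([
            pd.DataFrame({"group": labels[0], m: baseline[m]}),
            pd.DataFrame({"group": labels[1], m: treated[m]}),
        ], ignore_index=True)
        results.extend(compare_groups(combined, m))
    return results
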