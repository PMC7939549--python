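"""Statistical toolbox used across the pipeline.

Proportions (bounded in [0, 1]) are variance-stabilized with the arcsin
square-root transform before parametric testing; ratios are log-transformed
so multiplicative effects become additive. Two-group comparisons report
Cohen's d (pooled SD); multi-group parametric designs use one-way ANOVA with
Tukey HSD post-hoc tests, nonparametric ones Kruskal-Wallis with Dunn's
post-hoc procedure. Box-plot summaries follow the Tukey rule: whiskers at the
extreme points within 1.5 IQR of the quartiles, everything beyond flagged as
outlier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupData",
    "ComparisonResult",
    "transform",
    "compare",
    "tukey_box",
    "cohens_d",
]


@dataclass
class GroupData:
    """A labelled sample of values; ``value_kind`` selects the transform."""

    group_label: str
    values: np.ndarray
    value_kind: str = "raw"  # raw | proportion | ratio

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.value_kind not in ("raw", "proportion", "ratio"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")

    def transformed(self) -> np.ndarray:
        return transform(self.values, self.value_kind)


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    effect_size_d: float | None = None
    posthoc: pd.DataFrame | None = None


def transform(values, kind: str) -> np.ndarray:
    """Variable transform: arcsin(sqrt(p)) for proportions, ln for ratios."""
    x = np.asarray(values, dtype=float)
    if kind == "raw":
        return x
    if kind == "proportion":
        bad = np.nonzero((x < 0) | (x > 1))[0]
        if bad.size:
            raise ValueError(f"proportion out of [0, 1] at index {bad[0]}")
        return np.arcsin(np.sqrt(x))
    if kind == "ratio":
        bad = np.nonzero(x <= 0)[0]
        if bad.size:
            raise ValueError(f"ratio must be > 0; offending index {bad[0]}")
        return np.log(x)
    raise ValueError(f"unknown transform kind {kind!r}")


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with pooled standard deviation."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def _dunn(groups: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    """Dunn's rank-based post-hoc z tests with tie correction (Bonferroni)."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie = counts[counts > 1]
    tie_term = (tie**3 - tie).sum() / (12.0 * (n - 1)) if tie.size else 0.0
    mean_ranks, sizes = [], []
    pos = 0
    for g in groups:
        mean_ranks.append(ranks[pos:pos + g.size].mean())
        sizes.append(g.size)
        pos += g.size
    rows = []
    m = len(groups) * (len(groups) - 1) // 2
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term)
                         * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2 * sps.norm.sf(abs(z))
            rows.append({"group_a": labels[i], "group_b": labels[j],
                         "z": z, "p_unadjusted": p,
                         "p_adjusted": min(1.0, p * m)})
    return pd.DataFrame(rows)


def compare(groups: list[GroupData], design: str,
            data: pd.DataFrame | None = None) -> ComparisonResult:
    """Run the named test on the (transformed) group values.

    designs: two_group_t, paired_t, mann_whitney, anova_tukey, kruskal_dunn,
    rm_two_way_anova. Effect size d is reported for two-group designs on the
    transformed scale for t tests and on the raw values for Mann-Whitney.
    For ``rm_two_way_anova`` pass a long-format DataFrame with columns
    ``subject``, ``factor_a``, ``factor_b``, ``value`` via ``data`` instead
    of ``groups``; the reported statistic/p belong to the interaction term.
    """
    if design == "rm_two_way_anova":
        if data is None:
            raise ValueError("rm_two_way_anova requires a long-format DataFrame")
        from statsmodels.stats.anova import AnovaRM
        res = AnovaRM(data, depvar="value", subject="subject",
                      within=["factor_a", "factor_b"]).fit()
        tab = res.anova_table
        inter = tab.loc["factor_a:factor_b"]
        return ComparisonResult("rm_two_way_anova", float(inter["F Value"]),
                                float(inter["Pr > F"]), posthoc=tab)

    if not groups:
        raise ValueError("no groups supplied")
    vals = [g.transformed() for g in groups]
    labels = [g.group_label for g in groups]

    if design in ("two_group_t", "paired_t", "mann_whitney"):
        if len(groups) != 2:
            raise ValueError(f"{design} needs exactly two groups")
        a, b = vals
        if min(a.size, b.size) < 2:
            raise ValueError("need at least two values per group")
        if design == "two_group_t":
            stat, p = sps.ttest_ind(a, b)
            d = cohens_d(a, b)
        elif design == "paired_t":
            if a.size != b.size:
                raise ValueError("paired design needs equal group sizes")
            stat, p = sps.ttest_rel(a, b)
            d = cohens_d(a, b)
        else:
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            d = cohens_d(groups[0].values, groups[1].values)
        return ComparisonResult(design, float(stat), float(p), d)

    if design in ("anova_tukey", "kruskal_dunn"):
        if len(groups) < 3:
            raise ValueError(f"{design} needs at least three groups")
        if design == "anova_tukey":
            stat, p = sps.f_oneway(*vals)
            from statsmodels.stats.multicomp import pairwise_tukeyhsd
            flat = np.concatenate(vals)
            labs = np.concatenate([[lab] * v.size for lab, v in zip(labels, vals)])
            hsd = pairwise_tukeyhsd(flat, labs)
            posthoc = pd.DataFrame(hsd.summary().data[1:],
                                   columns=hsd.summary().data[0])
        else:
            stat, p = sps.kruskal(*vals)
            posthoc = _dunn(vals, labels)
        return ComparisonResult(design, float(stat), float(p), posthoc=posthoc)

    raise ValueError(f"unknown design {design!r}")


def tukey_box(values) -> dict:
    """Five-number box summary with Tukey 1.5-IQR outlier flagging."""
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValueError("tukey_box needs at least one value")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = x[(x < lo_fence) | (x > hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": float(inside.min()),
        "whisker_hi": float(inside.max()),
        "outliers": outliers,
    }
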