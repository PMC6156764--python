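"""Condition-level proliferation rates and group-comparison statistics.

The proliferation rate of a condition is the ratio of transfected
EdU-positive cells to all transfected cells — except in control
transfections, where no marker-positive subpopulation exists and the ratio
of all EdU-positive cells to all cells is used instead.

Group comparison follows the screening chain common in this assay
literature: Levene's test for homogeneity of variances first; if it passes
(P > 0.05), a one-way ANOVA followed by Tukey's HSD pairwise comparisons.
If Levene fails the report records the violation and returns descriptive
statistics only, rather than silently switching tests.  Two-group
comparisons use the unpaired two-tailed t-test (pooled variance by
default, Welch by flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ConditionSummary:
    """Cell counts and the derived proliferation rate for one field."""

    condition: str
    n_total: int
    n_transfected: int
    n_proliferating: int
    n_transfected_proliferating: int
    proliferation_rate: float = float("nan")
    replicate: str | int = 0

    def __post_init__(self) -> None:
        if self.n_transfected_proliferating > min(self.n_transfected, self.n_proliferating):
            raise ValueError(
                "double-positive count exceeds a marginal count "
                f"({self.n_transfected_proliferating} > "
                f"min({self.n_transfected}, {self.n_proliferating}))"
            )


def summarize_condition(
    records: pd.DataFrame, condition: str, replicate: str | int = 0,
    is_control: bool = False,
) -> ConditionSummary:
    """Count cells in a classified per-cell table and compute the rate."""
    t = records["transfected"].to_numpy(dtype=bool)
    p = records["proliferating"].to_numpy(dtype=bool)
    s = ConditionSummary(
        condition=condition,
        n_total=len(records),
        n_transfected=int(t.sum()),
        n_proliferating=int(p.sum()),
        n_transfected_proliferating=int((t & p).sum()),
        replicate=replicate,
    )
    s.proliferation_rate = proliferation_rate(s, is_control=is_control)
    return s


def proliferation_rate(summary: ConditionSummary, is_control: bool = False) -> float:
    """Rate = double-positive / transfected; control conditions use
    EdU-positive / total instead.  A zero denominator raises, naming the
    condition."""
    if is_control:
        if summary.n_total == 0:
            raise ZeroDivisionError(
                f"condition {summary.condition!r}: no cells to compute a control rate"
            )
        return summary.n_proliferating / summary.n_total
    if summary.n_transfected == 0:
        raise ZeroDivisionError(
            f"condition {summary.condition!r}: no transfected cells"
        )
    return summary.n_transfected_proliferating / summary.n_transfected


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star legend."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def two_group_test(a, b, equal_var: bool = True) -> float:
    """Unpaired two-tailed t-test p-value.

    If both groups are degenerate (zero variance) with equal means the test
    statistic is 0/0; by convention p = 1 is returned.
    """
    a = np.asarray(list(a), dtype=np.float64)
    b = np.asarray(list(b), dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 1.0
        return 0.0
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.pvalue)


@dataclass
class GroupComparison:
    """Result of the Levene -> ANOVA -> Tukey chain."""

    levene_p: float
    variance_homogeneous: bool
    anova_f: float | None
    anova_p: float | None
    pairwise: pd.DataFrame | None  # columns: group_a, group_b, diff, p_adj, stars
    descriptives: pd.DataFrame  # per-group n, mean, sd

    @property
    def significant_pairs(self) -> list[tuple[str, str]]:
        if self.pairwise is None:
            return []
        sig = self.pairwise[self.pairwise["p_adj"] < 0.05]
        return list(zip(sig["group_a"], sig["group_b"]))

    def report(self) -> str:
        lines = [
            f"Levene's test: P = {self.levene_p:.4g} "
            f"({'variances homogeneous' if self.variance_homogeneous else 'VARIANCE HOMOGENEITY VIOLATED'})"
        ]
        if self.variance_homogeneous:
            lines.append(f"One-way ANOVA: F = {self.anova_f:.4g}, P = {self.anova_p:.4g}")
            lines.append("Tukey HSD pairwise comparisons:")
            for _, r in self.pairwise.iterrows():
                lines.append(
                    f"  {r['group_a']} vs {r['group_b']}: "
                    f"diff = {r['diff']:+.4g}, P = {r['p_adj']:.4g} {r['stars']}"
                )
        else:
            lines.append("ANOVA not run; descriptive statistics only:")
        for _, r in self.descriptives.iterrows():
            lines.append(
                f"  {r['group']}: n = {int(r['n'])}, mean = {r['mean']:.4g}, sd = {r['sd']:.4g}"
            )
        return "\n".join(lines)


def compare_groups(rates: dict, alpha_levene: float = 0.05) -> GroupComparison:
    """Compare per-replicate rates across conditions.

    Parameters
    ----------
    rates
        Mapping of condition name -> sequence of per-replicate rates;
        at least 2 groups with at least 2 replicates each.
    """
    groups = {k: np.asarray(list(v), dtype=np.float64) for k, v in rates.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")
    names = list(groups)
    samples = [groups[n] for n in names]

    desc = pd.DataFrame(
        {
            "group": names,
            "n": [s.size for s in samples],
            "mean": [s.mean() for s in samples],
            "sd": [s.std(ddof=1) for s in samples],
        }
    )

    if all(s.std(ddof=1) == 0 for s in samples):
        # Levene is 0/0 on fully degenerate data; variances are trivially equal
        levene_p = 1.0
    else:
        levene_p = float(sps.levene(*samples, center="mean").pvalue)
    homogeneous = levene_p > alpha_levene
    if not homogeneous:
        return GroupComparison(levene_p, False, None, None, None, desc)

    if all(s.std(ddof=1) == 0 for s in samples) and len({s.mean() for s in samples}) == 1:
        # identical constant groups: no between-group variance, nothing significant
        f_stat, anova_p = 0.0, 1.0
        rows = [
            {"group_a": a, "group_b": b, "diff": 0.0, "p_adj": 1.0, "stars": "ns"}
            for i, a in enumerate(names)
            for b in names[i + 1:]
        ]
        return GroupComparison(levene_p, True, f_stat, anova_p, pd.DataFrame(rows), desc)

    f_stat, anova_p = sps.f_oneway(*samples)
    tukey = sps.tukey_hsd(*samples)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p_adj = float(tukey.pvalue[i, j])
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "diff": samples[i].mean() - samples[j].mean(),
                    "p_adj": p_adj,
                    "stars": significance_stars(p_adj),
                }
            )
    return GroupComparison(
        float(levene_p), True, float(f_stat), float(anova_p), pd.DataFrame(rows), desc
    )
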