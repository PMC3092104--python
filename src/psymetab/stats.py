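"""Descriptive case-control comparisons and per-cluster ANOVA.

Categorical covariates are compared case vs matched control with the
uncorrected Pearson chi-square (df = 1); continuous covariates with the
two-sided Mann-Whitney U test.  Cluster-level metabolite differences
across the four diagnostic groups (three psychosis strata, controls
pooled) use one-way ANOVA on log cluster scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clustering import ClusterScoreMatrix

#: demographic-table variables: (column, kind)
TABLE1_VARIABLES = [
    ("age", "continuous"),
    ("antipsychotic_current", "categorical"),
    ("t2d", "categorical"),
    ("metabolic_syndrome", "categorical"),
    ("metabolic_comorbidity", "categorical"),
    ("daily_smoking", "categorical"),
    ("diet_vegetables", "categorical"),
    ("diet_high_fat_milk", "categorical"),
    ("diet_vegetable_oils", "categorical"),
    ("diet_high_fat_cheese", "categorical"),
    ("bmi", "continuous"),
    ("systolic_bp", "continuous"),
    ("diastolic_bp", "continuous"),
    ("glucose", "continuous"),
    ("cotinine", "continuous"),
    ("total_chol", "continuous"),
    ("hdl", "continuous"),
    ("triglycerides", "continuous"),
    ("insulin", "continuous"),
    ("homa_ir", "continuous"),
    ("fasting_time", "continuous"),
    ("waist", "continuous"),
    ("crp", "continuous"),
    ("bdi", "continuous"),
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = case exposed, b = case unexposed, c = control exposed,
    d = control unexposed."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class GroupComparisonResult:
    statistic: float
    p_value: float
    test: str
    groups: tuple = ()
    note: str = ""

    def stars(self) -> str:
        """Significance annotation at the 0.05 / 0.001 thresholds."""
        if self.p_value < 0.001:
            return "***"
        return "*" if self.p_value < 0.05 else ""


def chi_square_2x2(t: ContingencyTable2x2) -> GroupComparisonResult:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction.

    Equivalent to n(ad-bc)^2 / [(a+b)(c+d)(a+c)(b+d)].
    """
    table = np.array([[t.a, t.b], [t.c, t.d]], float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal: chi-square undefined")
    stat, p, dof, _ = sps.chi2_contingency(table, correction=False)
    assert dof == 1
    return GroupComparisonResult(float(stat), float(p), "chi-square")


def mann_whitney_u(x, y) -> GroupComparisonResult:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact enumeration when the combined sample is small (<= 12) and
    tie-free; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return GroupComparisonResult(float(x.size * y.size / 2.0), 1.0,
                                     "mann-whitney", note="all values identical")
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size + y.size <= 12 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return GroupComparisonResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                                 "mann-whitney", note=method)


def diagnostic_groups(cohort: pd.DataFrame) -> pd.Series:
    """Four-level label per subject: the three case strata plus pooled
    controls."""
    lab = cohort["stratum"].where(cohort["role"] == "case", "control")
    return pd.Series(lab.to_numpy(), index=cohort["subject_id"].to_numpy(),
                     name="group")


def anova_cluster_profiles(scores: ClusterScoreMatrix | pd.DataFrame,
                           groups: pd.Series, log: bool = True) -> pd.DataFrame:
    """One-way ANOVA per cluster across the diagnostic groups.

    Operates on natural-log cluster scores by default (concentrations are
    log-normal); returns per-cluster F, p and significance stars.
    """
    values = scores.log_scores if (log and isinstance(scores, ClusterScoreMatrix)) \
        else (scores.scores if isinstance(scores, ClusterScoreMatrix) else scores)
    values = values.loc[groups.index]
    levels = groups.unique()
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    for g in levels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    rows = []
    for cluster in values.columns:
        samples = [values.loc[groups[groups == g].index, cluster].to_numpy()
                   for g in levels]
        f, p = sps.f_oneway(*samples)
        res = GroupComparisonResult(float(f), float(p), "anova", tuple(levels))
        rows.append({"cluster": cluster, "F": res.statistic, "p": res.p_value,
                     "stars": res.stars()})
    return pd.DataFrame(rows).set_index("cluster")


def table1_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum case vs matched-control summary of the demographic
    variables: mean (SD) or count (%) plus the appropriate test's p."""
    rows = []
    for var, kind in TABLE1_VARIABLES:
        if var not in cohort.columns:
            continue
        row = {"variable": var, "kind": kind}
        for stratum in ("schizophrenia", "onap", "affective"):
            sub = cohort[cohort["stratum"] == stratum]
            cases = sub[sub["role"] == "case"][var].dropna()
            ctrls = sub[sub["role"] == "control"][var].dropna()
            if len(cases) == 0 or len(ctrls) == 0:
                continue
            if kind == "categorical":
                a, c = int(cases.sum()), int(ctrls.sum())
                b, d = len(cases) - a, len(ctrls) - c
                row[f"{stratum}_cases"] = f"{a} ({100 * a / len(cases):.1f}%)"
                row[f"{stratum}_controls"] = f"{c} ({100 * c / len(ctrls):.1f}%)"
                try:
                    row[f"{stratum}_p"] = chi_square_2x2(
                        ContingencyTable2x2(a, b, c, d)).p_value
                except ValueError:
                    row[f"{stratum}_p"] = np.nan
            else:
                row[f"{stratum}_cases"] = f"{cases.mean():.2f} ({cases.std():.2f})"
                row[f"{stratum}_controls"] = f"{ctrls.mean():.2f} ({ctrls.std():.2f})"
                row[f"{stratum}_p"] = mann_whitney_u(cases, ctrls).p_value
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def plot_cluster_profiles(profile_means: pd.DataFrame, anova: pd.DataFrame | None = None,
                          path=None):
    """Plain bar summary of mean cluster profiles per diagnostic group
    (stand-in for beanplot panels)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(profile_means)), 4))
    profile_means.plot.bar(ax=ax)
    ax.set_ylabel("mean log cluster score")
    if anova is not None:
        for i, cl in enumerate(profile_means.index):
            if cl in anova.index and anova.loc[cl, "stars"]:
                ax.annotate(anova.loc[cl, "stars"], (i, ax.get_ylim()[1] * 0.95),
                            ha="center")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
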