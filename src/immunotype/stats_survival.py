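"""Group-comparison statistics and survival analysis.

Thin, explicitly-documented wrappers around scipy / statsmodels / lifelines
that fix the conventions used throughout the pipeline: declared tails, exact
vs asymptotic Mann-Whitney paths, degenerate-input handling, Benjamini-
Hochberg adjustment, and pairwise + k-group log-rank tests on Kaplan-Meier
product-limit curves.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ClinicalTable

__all__ = [
    "ComparisonResult",
    "SurvivalResult",
    "mann_whitney",
    "students_t",
    "anova_oneway",
    "spearman",
    "fisher_exact_test",
    "bh_adjust",
    "km_logrank",
]


@dataclass
class ComparisonResult:
    """One statistical comparison: statistic, p, declared tail, group sizes."""

    test: str
    statistic: float
    p: float
    tail: str
    ns: tuple[int, ...]
    effect_direction: str | None = None
    method: str | None = None
    estimate: float | None = None  # rho for Spearman, odds ratio for Fisher

    def __post_init__(self) -> None:
        if not np.isnan(self.p):
            assert 0.0 <= self.p <= 1.0


def mann_whitney(x, y, tail: str = "two-sided") -> ComparisonResult:
    """Mann-Whitney U test of two independent samples.

    ``tail``: ``"two-sided"``, ``"greater"`` (x stochastically greater than y)
    or ``"less"``. Uses exact enumeration when the combined n <= 12 and there
    are no ties, otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    stat, p = stats.mannwhitneyu(x, y, alternative=tail, method=method)
    direction = "x" if np.median(x) >= np.median(y) else "y"
    return ComparisonResult(test="mann-whitney-u", statistic=float(stat), p=float(p),
                            tail=tail, ns=(len(x), len(y)),
                            effect_direction=direction, method=method)


def students_t(x, y, tail: str = "two-sided", equal_var: bool = True) -> ComparisonResult:
    """Student's t test of two independent samples (pooled variance)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    stat, p = stats.ttest_ind(x, y, equal_var=equal_var, alternative=tail)
    direction = "x" if x.mean() >= y.mean() else "y"
    return ComparisonResult(test="students-t", statistic=float(stat), p=float(p),
                            tail=tail, ns=(len(x), len(y)), effect_direction=direction)


def anova_oneway(groups: list) -> ComparisonResult:
    """One-way ANOVA F test across >= 2 groups.

    Degenerate inputs are handled explicitly: zero between- and within-group
    variance gives F = 0, P = 1; zero within- with nonzero between-group
    variance gives F = inf, P = 0.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    ns = tuple(len(g) for g in groups)
    if sum(ns) <= len(groups):
        raise ValueError("total n must exceed the number of groups")
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0.0:
        if ssb == 0.0:
            return ComparisonResult(test="anova", statistic=0.0, p=1.0,
                                    tail="two-sided", ns=ns)
        return ComparisonResult(test="anova", statistic=float("inf"), p=0.0,
                                tail="two-sided", ns=ns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.f_oneway(*groups)
    return ComparisonResult(test="anova", statistic=float(stat), p=float(p),
                            tail="two-sided", ns=ns)


def spearman(x, y) -> ComparisonResult:
    """Spearman rank correlation (average ranks for ties, t-approximation P)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors with n >= 3")
    if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        warnings.warn("constant input vector; correlation undefined")
        return ComparisonResult(test="spearman", statistic=np.nan, p=np.nan,
                                tail="two-sided", ns=(len(x),), estimate=np.nan)
    rho, p = stats.spearmanr(x, y)
    return ComparisonResult(test="spearman", statistic=float(rho), p=float(p),
                            tail="two-sided", ns=(len(x),), estimate=float(rho),
                            effect_direction="positive" if rho >= 0 else "negative")


def fisher_exact_test(table, tail: str = "two-sided") -> ComparisonResult:
    """Fisher's exact test of a 2x2 contingency table."""
    table = np.asarray(table, float)
    if table.shape != (2, 2):
        raise ValueError("Fisher exact test needs a 2x2 table")
    odds, p = stats.fisher_exact(table, alternative=tail)
    return ComparisonResult(test="fisher-exact", statistic=float(odds), p=float(p),
                            tail=tail, ns=(int(table[0].sum()), int(table[1].sum())),
                            estimate=float(odds))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (input order preserved)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SurvivalResult:
    """Kaplan-Meier curves per group with pairwise and k-group log-rank tests.

    ``curves`` maps group -> DataFrame(time, survival, at_risk); ``pairwise``
    has one row per group pair with the 1-df log-rank chi-square and P;
    ``k_group`` is the joint test over all groups. ``median_survival`` is the
    KM median per group (NaN when the curve never crosses 0.5).
    """

    endpoint: str
    curves: dict[str, pd.DataFrame]
    pairwise: pd.DataFrame
    k_group_statistic: float
    k_group_p: float
    median_survival: dict[str, float]
    n_events: dict[str, int] = field(default_factory=dict)

    def curve_grid(self) -> pd.DataFrame:
        """All curves stacked long-form (group, time, survival, at_risk)."""
        frames = [c.assign(group=g) for g, c in self.curves.items()]
        return pd.concat(frames, ignore_index=True)


def km_logrank(clinical: ClinicalTable, grouping: pd.Series,
               endpoint: str = "OS") -> SurvivalResult:
    """Kaplan-Meier product-limit curves per group plus log-rank tests.

    ``grouping`` maps sample id -> group label; samples missing the endpoint
    or the grouping are excluded. Groups with no observations are dropped
    with a warning; a pairwise test is reported as NaN when neither group has
    an event.
    """
    from .subtyping import SubtypeAssignment
    if isinstance(grouping, SubtypeAssignment):
        grouping = grouping.labels
    surv = clinical.endpoint(endpoint)
    joined = surv.join(grouping.rename("group"), how="inner").dropna(subset=["group"])
    if joined.empty:
        raise ValueError("no samples with both endpoint and grouping")

    groups = [g for g in pd.unique(grouping.dropna()) if (joined["group"] == g).any()]
    skipped = set(pd.unique(grouping.dropna())) - set(groups)
    if skipped:
        warnings.warn(f"groups with no observations excluded: {sorted(skipped)}")
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")

    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    n_events: dict[str, int] = {}
    for g in groups:
        sub = joined[joined["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["status"])
        sf = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill()
        curves[g] = pd.DataFrame({"time": sf.index.to_numpy(),
                                  "survival": sf.to_numpy(),
                                  "at_risk": at_risk.to_numpy()})
        medians[g] = float(kmf.median_survival_time_)
        n_events[g] = int(sub["status"].sum())

    rows = []
    for g1, g2 in itertools.combinations(groups, 2):
        s1 = joined[joined["group"] == g1]
        s2 = joined[joined["group"] == g2]
        if s1["status"].sum() == 0 and s2["status"].sum() == 0:
            warnings.warn(f"no events in pair ({g1}, {g2}); log-rank not computable")
            rows.append({"group_a": g1, "group_b": g2,
                         "chi2": np.nan, "p": np.nan})
            continue
        res = logrank_test(s1["time"], s2["time"],
                           event_observed_A=s1["status"], event_observed_B=s2["status"])
        rows.append({"group_a": g1, "group_b": g2,
                     "chi2": float(res.test_statistic), "p": float(res.p_value)})
    pairwise = pd.DataFrame(rows)

    if joined["status"].sum() == 0:
        k_stat, k_p = np.nan, np.nan
    else:
        kres = multivariate_logrank_test(joined["time"], joined["group"], joined["status"])
        k_stat, k_p = float(kres.test_statistic), float(kres.p_value)

    return SurvivalResult(endpoint=endpoint.upper(), curves=curves, pairwise=pairwise,
                          k_group_statistic=k_stat, k_group_p=k_p,
                          median_survival=medians, n_events=n_events)
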