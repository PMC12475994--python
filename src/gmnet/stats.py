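"""Group-level inference: summary-statistic tests, ANCOVA and adjusted
correlations.

Demographics are compared with pooled-variance t-tests, one-way ANOVA with
LSD post hoc, and Pearson chi-square (no continuity correction). Network
metrics are compared with a covariate-adjusted linear model (ANCOVA, group
tested by extra sum of squares) followed by Bonferroni-corrected pairwise
contrasts, and clinical associations use partial Pearson correlations
(residualized on the nuisance covariates, df = n - 2 - k).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import RankDeficiencyError

GROUPS = ("HC", "DM", "DKD")
DEFAULT_COVARIATES = ("age", "gender", "education", "TIV")


@dataclass
class StatResult:
    """Outcome of a single hypothesis test or contrast."""

    statistic: float
    df: tuple
    p: float
    test: str
    effect_direction: str = None
    estimate: float = None
    p_adjusted: float = None
    contrast: str = None
    post_hoc: list = field(default_factory=list)

    def __post_init__(self):
        if not (0 <= self.p <= 1 + 1e-12):
            raise ValueError(f"p-value out of range: {self.p}")
        if self.p_adjusted is not None and self.p_adjusted < self.p - 1e-12:
            raise ValueError("adjusted p must be >= raw p")


def ttest_from_summary(m1, sd1, n1, m2, sd2, n2, variant: str = "pooled") -> StatResult:
    """Two-sample t-test reconstructed from group means, SDs and sizes."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant: {variant!r}")
    t, p = sps.ttest_ind_from_stats(
        m1, sd1, n1, m2, sd2, n2, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = n1 + n2 - 2
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    direction = "group1>group2" if m1 > m2 else ("group1<group2" if m1 < m2 else "equal")
    return StatResult(statistic=float(t), df=(float(df),), p=float(p),
                      test=f"t-{variant}", effect_direction=direction,
                      estimate=float(m1 - m2))


def _anova_components(means, sds, ns):
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ns = np.asarray(ns, int)
    if len(means) < 2 or np.any(ns < 2):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if np.any(sds < 0):
        raise ValueError("SDs must be non-negative")
    n_total = ns.sum()
    k = len(means)
    grand = np.sum(ns * means) / n_total
    ssb = np.sum(ns * (means - grand) ** 2)
    ssw = np.sum((ns - 1) * sds**2)
    if ssw <= 0:
        raise ValueError("degenerate within-group variance")
    msw = ssw / (n_total - k)
    return ssb, msw, k, n_total


def anova_from_summary(means, sds, ns) -> StatResult:
    """One-way ANOVA reconstructed from group means, SDs and sizes."""
    ssb, msw, k, n_total = _anova_components(means, sds, ns)
    df1, df2 = k - 1, n_total - k
    f = (ssb / df1) / msw
    p = float(sps.f.sf(f, df1, df2))
    return StatResult(statistic=float(f), df=(df1, df2), p=p, test="anova")


def lsd_posthoc(means, sds, ns, labels=None) -> list:
    """Least-significant-difference pairwise tests sharing the ANOVA MSW."""
    _, msw, k, n_total = _anova_components(means, sds, ns)
    df = n_total - k
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    results = []
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(msw * (1 / ns[i] + 1 / ns[j]))
        t = (means[i] - means[j]) / se
        p = float(2 * sps.t.sf(abs(t), df))
        direction = (f"{labels[i]}>{labels[j]}" if t > 0
                     else (f"{labels[i]}<{labels[j]}" if t < 0 else "equal"))
        results.append(StatResult(statistic=float(t), df=(df,), p=p, test="lsd",
                                  contrast=f"{labels[i]} vs {labels[j]}",
                                  effect_direction=direction,
                                  estimate=float(means[i] - means[j])))
    return results


def chi_square_test(table) -> StatResult:
    """Pearson chi-square on an r x c contingency table, no continuity
    correction."""
    table = np.asarray(table, float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    res = sps.chi2_contingency(table, correction=False)
    return StatResult(statistic=float(res.statistic), df=(int(res.dof),),
                      p=float(res.pvalue), test="chi2")


def _design_matrices(cohort: pd.DataFrame, covariates, group_col="group",
                     reference="HC"):
    """Full-rank design: intercept + (k-1) group dummies + covariates."""
    groups = pd.Categorical(cohort[group_col])
    levels = [g for g in GROUPS if g in groups.categories] or list(groups.categories)
    if reference not in levels:
        reference = levels[0]
    non_ref = [g for g in levels if g != reference]
    n = len(cohort)
    dummies = np.column_stack(
        [(cohort[group_col] == g).to_numpy(float) for g in non_ref]
    )
    cov = (cohort[list(covariates)].to_numpy(float)
           if covariates else np.empty((n, 0)))
    x_full = np.column_stack([np.ones(n), dummies, cov])
    x_reduced = np.column_stack([np.ones(n), cov])
    names = ["intercept"] + [f"group[{g}]" for g in non_ref] + list(covariates)
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise RankDeficiencyError(
            f"design matrix rank deficient (columns: {names})"
        )
    return x_full, x_reduced, non_ref, reference, names


def _ols(x, y):
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return beta, float(resid @ resid)


def ancova_group_test(y, cohort: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                      group_col: str = "group") -> StatResult:
    """Covariate-adjusted group comparison by extra sum of squares.

    Fits ``y ~ group dummies + covariates`` by least squares and tests the
    group effect against the covariates-only model with an F test on
    (k-1, n - p_full) degrees of freedom.
    """
    y = np.asarray(y, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    x_full, x_reduced, non_ref, reference, _ = _design_matrices(
        cohort, covariates, group_col
    )
    n, p_full = x_full.shape
    df1 = len(non_ref)
    df2 = n - p_full
    _, ssr_full = _ols(x_full, y)
    _, ssr_red = _ols(x_reduced, y)
    f = ((ssr_red - ssr_full) / df1) / (ssr_full / df2)
    f = max(f, 0.0)
    p = float(sps.f.sf(f, df1, df2))
    return StatResult(statistic=float(f), df=(df1, df2), p=p, test="ancova")


def bonferroni_posthoc(y, cohort: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                       group_col: str = "group", m: int = None) -> list:
    """Pairwise group contrasts from the full ANCOVA model.

    Adjusted p = min(1, raw * m); m defaults to the number of group pairs.
    """
    y = np.asarray(y, float)
    x_full, _, non_ref, reference, _ = _design_matrices(cohort, covariates,
                                                        group_col)
    n, p_full = x_full.shape
    df = n - p_full
    beta, ssr = _ols(x_full, y)
    sigma2 = ssr / df
    xtx_inv = np.linalg.inv(x_full.T @ x_full)

    levels = [reference] + non_ref
    coef = {reference: np.zeros(p_full)}
    for idx, g in enumerate(non_ref):
        vec = np.zeros(p_full)
        vec[1 + idx] = 1.0
        coef[g] = vec
    pairs = list(itertools.combinations(levels, 2))
    if m is None:
        m = len(pairs)
    results = []
    for g1, g2 in pairs:
        c = coef[g1] - coef[g2]
        est = float(c @ beta)
        se = float(np.sqrt(sigma2 * c @ xtx_inv @ c))
        t = est / se
        p_raw = float(2 * sps.t.sf(abs(t), df))
        direction = f"{g1}>{g2}" if est > 0 else (f"{g1}<{g2}" if est < 0 else "equal")
        results.append(StatResult(
            statistic=float(t), df=(df,), p=p_raw,
            p_adjusted=min(1.0, p_raw * m), test="ancova-posthoc",
            contrast=f"{g1} vs {g2}", effect_direction=direction, estimate=est,
        ))
    return results


def adjusted_correlation(x, y, cohort: pd.DataFrame = None,
                         covariates=()) -> StatResult:
    """Partial Pearson correlation after residualizing on covariates.

    Both variables are regressed (with intercept) on the covariate columns
    of ``cohort``; the residuals are correlated and tested with
    df = n - 2 - k, two-sided, uncorrected.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    k = len(covariates)
    if n <= k + 3:
        raise ValueError("too few observations for the covariate count")
    if covariates:
        z = np.column_stack([np.ones(n),
                             cohort[list(covariates)].to_numpy(float)])
        if np.linalg.matrix_rank(z) < z.shape[1]:
            raise RankDeficiencyError("covariate matrix rank deficient")
        x = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
        y = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2 - k
    r_clipped = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clipped * np.sqrt(df / (1 - r_clipped**2))
    p = float(2 * sps.t.sf(abs(t), df))
    if abs(r) >= 1 - 1e-14:
        p = 0.0
    return StatResult(statistic=float(t), df=(df,), p=p, test="partial-pearson",
                      estimate=r,
                      effect_direction="positive" if r > 0 else "negative")


def nodal_group_screen(nodal_auc: pd.DataFrame, cohort: pd.DataFrame,
                       covariates=DEFAULT_COVARIATES, alpha: float = 0.05,
                       group_col: str = "group") -> pd.DataFrame:
    """Per-node ANCOVA screen with gated Bonferroni post hoc.

    Parameters
    ----------
    nodal_auc : DataFrame
        One row per subject (aligned with ``cohort``), one column per node;
        values are per-subject AUCs of a nodal metric.

    Returns a tidy table with one row per node carrying the overall F and p
    plus, where the overall test clears ``alpha``, the pairwise contrasts
    (raw and Bonferroni-adjusted p, direction).
    """
    if len(nodal_auc) != len(cohort):
        raise ValueError("nodal_auc and cohort must have equal row counts")
    rows = []
    for node in nodal_auc.columns:
        y = nodal_auc[node].to_numpy(float)
        record = {"node": node, "f": np.nan, "p": np.nan, "error": ""}
        try:
            overall = ancova_group_test(y, cohort, covariates, group_col)
            record["f"] = overall.statistic
            record["p"] = overall.p
            record["significant"] = overall.p < alpha
            if overall.p < alpha:
                for contrast in bonferroni_posthoc(y, cohort, covariates,
                                                   group_col):
                    key = contrast.contrast.replace(" ", "")
                    record[f"{key}_p_raw"] = contrast.p
                    record[f"{key}_p_bonf"] = contrast.p_adjusted
                    record[f"{key}_direction"] = contrast.effect_direction
        except Exception as exc:  # per-node failures must not abort the screen
            record["error"] = str(exc)
            record["significant"] = False
        rows.append(record)
    return pd.DataFrame(rows)
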