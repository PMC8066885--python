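"""Cohort-level statistics: effect sizes, exact rank tests, correlations.

Group comparisons follow the small-sample, non-parametric approach of the
source study design: Cohen's d with the pooled standard deviation, the
coefficient of variation, an exact (permutation-null) Mann-Whitney U test,
ANCOVA for covariate-adjusted comparisons, direct and partial Spearman rank
correlations, and the GOSE recovery dichotomy (8 = recovered, < 8 = not).
P values are two-sided and reported without multiple-comparison correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .errors import DomainError, InputError, SingularFitError, UndefinedStatisticError

__all__ = [
    "GroupComparison",
    "cohens_d",
    "coefficient_of_variation",
    "cv_percent_label",
    "exact_mann_whitney",
    "spearman_direct",
    "spearman_partial",
    "ancova_compare",
    "recovery_split",
    "compare_groups",
    "outcome_correlations",
]

# Combined-sample cap for the exact Mann-Whitney null: subset counts stay
# below 2**53 (exactly representable in float64) up to n = 50.
EXACT_MW_MAX_N = 50


def cohens_d(mean_p, sd_p, n_p, mean_c, sd_c, n_c) -> float:
    """Standardized mean difference with the pooled standard deviation.

    d = (mean_p - mean_c) / sqrt(((n_p-1) sd_p^2 + (n_c-1) sd_c^2) / (n_p+n_c-2))

    with the patient-minus-control sign convention: negative d means lower
    values in patients.
    """
    if n_p < 2 or n_c < 2:
        raise InputError("cohens_d requires n >= 2 in each group")
    if sd_p < 0 or sd_c < 0:
        raise DomainError("standard deviations must be >= 0")
    pooled_var = ((n_p - 1) * sd_p**2 + (n_c - 1) * sd_c**2) / (n_p + n_c - 2)
    if pooled_var == 0:
        raise UndefinedStatisticError("pooled SD is zero; effect size undefined")
    return float((mean_p - mean_c) / math.sqrt(pooled_var))


def coefficient_of_variation(mean: float, sd: float) -> float:
    """Coefficient of variation in percent: 100 * sd / mean (mean > 0)."""
    if mean <= 0:
        raise DomainError(f"CV requires a positive mean, got {mean}")
    return 100.0 * sd / mean


def cv_percent_label(mean: float, sd: float) -> str:
    """CV rounded to the nearest integer percent, e.g. '6%'."""
    return f"{round(coefficient_of_variation(mean, sd)):d}%"


def _mw_null_distribution(doubled_ranks: np.ndarray, n_x: int):
    """Exact permutation null of the x rank-sum by shift/convolution DP.

    ``doubled_ranks`` are the pooled midranks times two (integers, so ties
    are handled exactly).  Returns (support offset 0 array of subset counts
    f[s] = #subsets of size n_x with doubled rank-sum s).  Counts are exact
    integers held in float64.
    """
    total = int(doubled_ranks.sum())
    f = np.zeros((n_x + 1, total + 1))
    f[0, 0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        # iterate subset size downwards so each item is used at most once
        for k in range(n_x, 0, -1):
            f[k, r:] += f[k - 1, : total + 1 - r]
    return f[n_x]


def exact_mann_whitney(x, y):
    """Exact two-sided Mann-Whitney U test under the permutation null.

    The null distribution of the rank-sum is enumerated exactly with a
    shift/convolution dynamic program over the pooled midranks (doubled to
    stay integral under ties), so tied data keep permutation exactness.
    Returns (U of the first sample, two-sided p), with
    p = min(1, 2 * min(P(U <= u), P(U >= u))).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be non-empty")
    n_x, n_y = x.size, y.size
    n = n_x + n_y
    if n > EXACT_MW_MAX_N:
        raise InputError(
            f"exact Mann-Whitney supports combined n <= {EXACT_MW_MAX_N}, got {n}"
        )

    ranks = sps.rankdata(np.concatenate([x, y]))  # midranks
    doubled = np.rint(2 * ranks).astype(np.int64)
    r_x2 = int(doubled[:n_x].sum())
    u = (r_x2 - n_x * (n_x + 1)) / 2.0  # U statistic of x

    counts = _mw_null_distribution(doubled, n_x)
    total = counts.sum()
    p_le = counts[: r_x2 + 1].sum() / total
    p_ge = counts[r_x2:].sum() / total
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return float(u), float(p)


def _t_approx_p(r: float, df: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt(df / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df))


def spearman_direct(x, y):
    """Spearman rank correlation: Pearson correlation of the midranks.

    The p value uses the t approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise InputError("spearman_direct requires paired samples with n >= 3")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedStatisticError("zero rank variance; correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    return r, _t_approx_p(r, x.size - 2)


def spearman_partial(x, y, z):
    """Partial Spearman correlation of x and y adjusting for covariate z.

    All three variables are ranked; the first-order partial-correlation
    formula is applied to the pairwise rank correlations, and the p value
    uses the t approximation with n - 3 degrees of freedom (one lost to the
    covariate).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if not (x.size == y.size == z.size) or x.size < 4:
        raise InputError("spearman_partial requires paired samples with n >= 4")
    r_xy, _ = spearman_direct(x, y)
    r_xz, _ = spearman_direct(x, z)
    r_yz, _ = spearman_direct(y, z)
    denom = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom <= 0:
        raise UndefinedStatisticError(
            "covariate is rank-collinear with a variable; partial correlation undefined"
        )
    r = float((r_xy - r_xz * r_yz) / math.sqrt(denom))
    return r, _t_approx_p(r, x.size - 3)


def ancova_compare(values, group, covariate):
    """Covariate-adjusted group comparison via the linear model
    value ~ group + covariate (main effects, no interaction).

    Returns (adjusted group difference for the second group level relative
    to the first, two-sided p of that coefficient).
    """
    values = np.asarray(values, dtype=float).ravel()
    group = np.asarray(group).ravel()
    covariate = np.asarray(covariate, dtype=float).ravel()
    if not (values.size == group.size == covariate.size):
        raise InputError("values, group and covariate must have equal length")
    levels = sorted(pd.unique(group).tolist())
    if len(levels) != 2:
        raise InputError(f"exactly two group levels required, got {levels}")
    counts = [int((group == lv).sum()) for lv in levels]
    if min(counts) < 2:
        raise InputError("both groups need >= 2 observations")
    if np.ptp(covariate) == 0:
        raise SingularFitError("covariate is constant; nothing to adjust for")

    df = pd.DataFrame({
        "value": values,
        "grp": pd.Categorical(group, categories=levels),
        "cov": covariate,
    })
    fit = smf.ols("value ~ grp + cov", data=df).fit()
    term = f"grp[T.{levels[1]}]"
    if term not in fit.params.index or not np.isfinite(fit.bse[term]) or fit.bse[term] == 0:
        raise SingularFitError("group indicator collinear with the covariate")
    return float(fit.params[term]), float(fit.pvalues[term])


def recovery_split(gose: int) -> str:
    """GOSE recovery dichotomy: 8 -> 'recovered', 1-7 -> 'non_recovered'."""
    g = int(gose)
    if g != gose or not 1 <= g <= 8:
        raise DomainError(f"GOSE must be an integer in [1, 8], got {gose!r}")
    return "recovered" if g == 8 else "non_recovered"


@dataclass
class GroupComparison:
    """Patient-vs-control summary for one metric, Table-3 style."""

    region: str
    n_p: int
    n_c: int
    mean_p: float
    sd_p: float
    cv_p: float
    median_p: float
    iqr_p: float
    mean_c: float
    sd_c: float
    cv_c: float
    median_c: float
    iqr_c: float
    mw_u: float
    mw_p_value: float
    cohens_d: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _summary(v: np.ndarray):
    q1, q3 = np.percentile(v, [25, 75])
    return (
        float(v.mean()),
        float(v.std(ddof=1)),
        float(np.median(v)),
        float(q3 - q1),
    )


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    group_col: str = "group",
    patient_label: str = "patient",
    control_label: str = "control",
    exclude_ids=None,
) -> GroupComparison:
    """Full group comparison (summaries, exact MW, Cohen's d) for one metric.

    ``exclude_ids`` is an explicit subject-exclusion list (e.g. unmatched
    oldest patients), applied before any statistics; it is never inferred.
    """
    df = table
    if exclude_ids:
        df = df[~df["id"].isin(set(exclude_ids))]
    vp = df.loc[df[group_col] == patient_label, metric].dropna().to_numpy(float)
    vc = df.loc[df[group_col] == control_label, metric].dropna().to_numpy(float)
    if vp.size < 2 or vc.size < 2:
        raise InputError(
            f"metric {metric!r}: need >= 2 values per group, got "
            f"{vp.size} patients / {vc.size} controls"
        )
    mean_p, sd_p, med_p, iqr_p = _summary(vp)
    mean_c, sd_c, med_c, iqr_c = _summary(vc)
    u, p = exact_mann_whitney(vp, vc)
    return GroupComparison(
        region=metric,
        n_p=vp.size,
        n_c=vc.size,
        mean_p=mean_p,
        sd_p=sd_p,
        cv_p=coefficient_of_variation(mean_p, sd_p),
        median_p=med_p,
        iqr_p=iqr_p,
        mean_c=mean_c,
        sd_c=sd_c,
        cv_c=coefficient_of_variation(mean_c, sd_c),
        median_c=med_c,
        iqr_c=iqr_c,
        mw_u=u,
        mw_p_value=p,
        cohens_d=cohens_d(mean_p, sd_p, vp.size, mean_c, sd_c, vc.size),
    )


def outcome_correlations(
    table: pd.DataFrame,
    metrics,
    outcomes,
    covariate: str = "days_since_injury",
    group_col: str = "group",
    patient_label: str = "patient",
) -> pd.DataFrame:
    """Direct and covariate-adjusted Spearman correlations, Table-4 style.

    Computed among patients only (outcome instruments are administered to
    patients); one row per (metric, outcome) pair with direct r/p and
    partial r/p adjusting for the covariate.
    """
    pat = table[table[group_col] == patient_label]
    rows = []
    for metric in metrics:
        for outcome in outcomes:
            sub = pat[[metric, outcome, covariate]].dropna()
            x = sub[metric].to_numpy(float)
            y = sub[outcome].to_numpy(float)
            z = sub[covariate].to_numpy(float)
            r_d, p_d = spearman_direct(x, y)
            r_p, p_p = spearman_partial(x, y, z)
            rows.append({
                "metric": metric,
                "outcome": outcome,
                "n": len(sub),
                "direct_r": r_d,
                "direct_p": p_d,
                "partial_r": r_p,
                "partial_p": p_p,
            })
    return pd.DataFrame(rows)
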