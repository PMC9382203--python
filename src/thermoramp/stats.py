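"""The study's statistical battery.

Natural-log transforms, independent-samples t-tests (Welch by default,
pooled available), Mann–Whitney U (exact enumeration for small untied
samples, normal approximation with tie correction otherwise), and a mixed
two-way ANOVA — one between-subjects factor (O2 treatment) crossed with one
repeated factor (temperature step) — with the Greenhouse–Geisser epsilon
adjustment applied to the within and interaction tests, since sphericity is
assumed violated for thermal-ramping data.

The split-plot sums of squares and the epsilon estimator are implemented
from first principles; the t and U tests delegate to scipy behind this
surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "ln_transform",
    "percent_difference",
    "t_test_independent",
    "mann_whitney",
    "mixed_anova",
    "validate_long",
]

LONG_COLUMNS = ("subject", "group", "level", "value")


@dataclass(frozen=True)
class AnovaResult:
    """One effect from the mixed two-way ANOVA.

    ``gg_epsilon`` is the Greenhouse–Geisser sphericity correction
    (1/(k−1) ≤ ε ≤ 1); degrees of freedom of the within and interaction
    effects are multiplied by it before the p-value is computed. The
    between-groups effect is not subject to sphericity, so its ε is 1.
    ``degenerate`` marks zero error variance (F undefined, reported NaN).
    """

    effect: str
    F: float
    df_num: float
    df_den: float
    gg_epsilon: float
    p_gg: float
    degenerate: bool = False


def ln_transform(values):
    """Element-wise natural log; rejects non-positive values."""
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise ValueError("ln transform requires strictly positive values")
    return np.log(v)


def percent_difference(reference: float, other: float) -> float:
    """100 × (other − reference) / reference."""
    if reference == 0:
        raise ValueError("reference must be non-zero")
    return 100.0 * (other - reference) / reference


def t_test_independent(x, y, equal_var: bool = False) -> tuple[float, float, float]:
    """Two-sided independent-samples t-test.

    Welch by default (``equal_var=False``); pooled Student with
    ``equal_var=True``. Returns ``(t, df, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            # No variance, no difference: conventionally t=0, p=1.
            df = len(x) + len(y) - 2 if equal_var else float(len(x) + len(y) - 2)
            return 0.0, float(df), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def mann_whitney(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns ``(U_x, p)``.

    ``method='auto'`` uses exact enumeration when n1+n2 ≤ 20 and the pooled
    data are untied, otherwise the normal approximation with tie correction.
    ``U + U′ = n1·n2`` always holds for the returned statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("need at least one observation per group")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        # All observations identical: U = U' = n1*n2/2, no evidence either way.
        return 0.5 * len(x) * len(y), 1.0
    if method == "auto":
        method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def validate_long(data: pd.DataFrame) -> None:
    """Check the tidy long-format contract for repeated measurements."""
    missing = [c for c in LONG_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"long-format data missing columns: {missing}")
    dup = data.duplicated(subset=["subject", "level"])
    if dup.any():
        raise ValueError("each (subject, level) pair may appear at most once")
    groups_per_subject = data.groupby("subject")["group"].nunique()
    if (groups_per_subject > 1).any():
        raise ValueError("each subject must be nested in exactly one group")


def _gg_epsilon(wide: np.ndarray, group_codes: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the pooled within-group covariance."""
    k = wide.shape[1]
    if k < 2:
        raise ValueError("need at least 2 within-subject levels")
    n, g = len(wide), len(np.unique(group_codes))
    pooled = np.zeros((k, k))
    for code in np.unique(group_codes):
        sub = wide[group_codes == code]
        pooled += (len(sub) - 1) * np.cov(sub, rowvar=False)
    pooled /= n - g
    # Double-center, then epsilon = tr(S)^2 / ((k-1) * sum(S^2)).
    row = pooled.mean(axis=0, keepdims=True)
    col = pooled.mean(axis=1, keepdims=True)
    s_dc = pooled - row - col + pooled.mean()
    denom = (k - 1) * float(np.sum(s_dc**2))
    if denom <= 0:
        return 1.0
    eps = float(np.trace(s_dc)) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _mixed_anova_arrays(wide: np.ndarray, group_codes: np.ndarray) -> list[AnovaResult]:
    """Split-plot ANOVA on a complete subjects×levels matrix."""
    n, k = wide.shape
    codes = np.unique(group_codes)
    g = len(codes)
    if g < 2:
        raise ValueError("need at least 2 groups")
    for code in codes:
        if np.sum(group_codes == code) < 2:
            raise ValueError("need at least 2 subjects per group")
    grand = wide.mean()
    subj_means = wide.mean(axis=1)
    level_means = wide.mean(axis=0)
    group_means = np.array([wide[group_codes == c].mean() for c in codes])
    cell_means = np.vstack([wide[group_codes == c].mean(axis=0) for c in codes])
    n_per = np.array([np.sum(group_codes == c) for c in codes])

    ss_group = k * float(np.sum(n_per * (group_means - grand) ** 2))
    group_mean_per_subj = group_means[np.searchsorted(codes, group_codes)]
    ss_subj = k * float(np.sum((subj_means - group_mean_per_subj) ** 2))
    ss_level = n * float(np.sum((level_means - grand) ** 2))
    ss_inter = float(
        np.sum(
            n_per[:, None]
            * (cell_means - group_means[:, None] - level_means[None, :] + grand) ** 2
        )
    )
    ss_total = float(np.sum((wide - grand) ** 2))
    ss_err = ss_total - ss_group - ss_subj - ss_level - ss_inter

    df_group, df_subj = g - 1.0, float(n - g)
    df_level = k - 1.0
    df_inter = (g - 1.0) * (k - 1.0)
    df_err = (n - g) * (k - 1.0)
    eps = _gg_epsilon(wide, group_codes)

    def effect(name, ss, df1, ms_err, df2, use_eps):
        e = eps if use_eps else 1.0
        if ms_err <= 0:
            return AnovaResult(name, float("nan"), df1, df2, e, float("nan"), True)
        f = (ss / df1) / ms_err
        p = float(sps.f.sf(f, e * df1, e * df2))
        return AnovaResult(name, float(f), df1, df2, e, p, False)

    ms_subj = ss_subj / df_subj if df_subj > 0 else 0.0
    ms_err = ss_err / df_err if df_err > 0 else 0.0
    return [
        effect("group", ss_group, df_group, ms_subj, df_subj, False),
        effect("within", ss_level, df_level, ms_err, df_err, True),
        effect("interaction", ss_inter, df_inter, ms_err, df_err, True),
    ]


def mixed_anova(data: pd.DataFrame) -> list[AnovaResult]:
    """Mixed two-way ANOVA with Greenhouse–Geisser adjustment.

    ``data`` is tidy long format with columns ``subject``, ``group``,
    ``level``, ``value``. Subjects missing any within level are removed
    (listwise deletion) so the design is complete; this mirrors restricting
    the repeated factor to temperatures every fish reached.
    """
    validate_long(data)
    wide_df = data.pivot(index="subject", columns="level", values="value")
    complete = wide_df.dropna()
    if complete.shape[1] < 2:
        raise ValueError("need at least 2 within-subject levels")
    group_of = data.drop_duplicates("subject").set_index("subject")["group"]
    groups = group_of.loc[complete.index]
    codes, _ = pd.factorize(groups, sort=True)
    return _mixed_anova_arrays(complete.to_numpy(dtype=float), codes)


def anova_table(results: list[AnovaResult]) -> pd.DataFrame:
    """Tidy frame of ANOVA effects."""
    return pd.DataFrame(
        {
            "effect": [r.effect for r in results],
            "F": [r.F for r in results],
            "df_num": [r.df_num for r in results],
            "df_den": [r.df_den for r in results],
            "gg_epsilon": [r.gg_epsilon for r in results],
            "p_gg": [r.p_gg for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )
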