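"""Classical association statistics between group structures.

χ² crosstabulations with cell-wise Pearson residuals, a Pearson correlation
matrix with Bonferroni multiplicity control, a mixed-design (split-plot)
repeated-measures ANOVA with Greenhouse–Geisser sphericity correction, and
Welch two-sample t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CrosstabResult",
    "CorrMatrix",
    "AnovaResult",
    "crosstab_chi2",
    "corr_matrix",
    "rm_anova",
    "welch_t",
]


@dataclass
class CrosstabResult:
    observed: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    df: int
    pvalue: float
    residuals: pd.DataFrame  # (O - E) / sqrt(E)
    low_expected: bool  # any expected cell < 5


@dataclass
class CorrMatrix:
    r: pd.DataFrame
    pvalues: pd.DataFrame
    significant: pd.DataFrame  # after Bonferroni at alpha / m
    m: int  # number of tested unique pairs
    undefined_pairs: list[tuple[str, str]]


@dataclass
class AnovaResult:
    """Split-plot ANOVA table entries for (between, within, interaction)."""

    table: pd.DataFrame  # effect x [F, df1, df2, p, df1_gg, df2_gg, p_gg]
    epsilon: float  # Greenhouse-Geisser


# ---------------------------------------------------------------------------


def crosstab_chi2(a, b, dropna: bool = True) -> CrosstabResult:
    """Pearson χ² (no continuity correction) with cell-wise Pearson residuals.

    Levels with zero total are dropped with a warning flag implicit in the
    table shape; an expected count below 5 sets ``low_expected``.
    """
    a = pd.Series(a).reset_index(drop=True)
    b = pd.Series(b).reset_index(drop=True)
    if len(a) != len(b):
        raise ValueError("vectors must have equal length")
    obs = pd.crosstab(a, b, dropna=dropna)
    obs = obs.loc[obs.sum(axis=1) > 0, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("crosstab needs >= 2 levels on each margin")
    chi2, p, df, exp = stats.chi2_contingency(obs.to_numpy(), correction=False)
    expected = pd.DataFrame(exp, index=obs.index, columns=obs.columns)
    resid = (obs - expected) / np.sqrt(expected)
    return CrosstabResult(
        observed=obs, expected=expected, chi2=float(chi2), df=int(df),
        pvalue=float(p), residuals=resid, low_expected=bool((exp < 5).any()),
    )


def corr_matrix(X: pd.DataFrame, alpha: float = 0.05) -> CorrMatrix:
    """Pairwise Pearson r with two-sided t-based p and Bonferroni flags.

    All unique off-diagonal pairs count toward the Bonferroni divisor m.
    Pairs involving a constant column get NaN r and are listed as undefined.
    """
    X = pd.DataFrame(X)
    cols = list(X.columns)
    d = len(cols)
    r = pd.DataFrame(np.eye(d), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((d, d)), index=cols, columns=cols)
    undefined = []
    m = d * (d - 1) // 2
    for i in range(d):
        for j in range(i + 1, d):
            pair = X[[cols[i], cols[j]]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"need >= 3 complete pairs for ({cols[i]}, {cols[j]})"
                )
            x, y = pair.iloc[:, 0].to_numpy(float), pair.iloc[:, 1].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                rij, pij = np.nan, np.nan
                undefined.append((cols[i], cols[j]))
            else:
                res = stats.pearsonr(x, y)
                rij, pij = float(res.statistic), float(res.pvalue)
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    sig = p < (alpha / m)
    np.fill_diagonal(sig.values, False)
    return CorrMatrix(r=r, pvalues=p, significant=sig, m=m, undefined_pairs=undefined)


# ---------------------------------------------------------------------------
# Mixed-design repeated-measures ANOVA
# ---------------------------------------------------------------------------


def _gg_epsilon(wide: np.ndarray, groups: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the pooled within-group covariance."""
    p = wide.shape[1]
    S = np.zeros((p, p))
    dof = 0
    for g in np.unique(groups):
        W = wide[groups == g]
        if len(W) > 1:
            S += np.cov(W, rowvar=False) * (len(W) - 1)
            dof += len(W) - 1
    S /= dof
    # double-centered covariance
    row = S.mean(axis=0)
    grand = S.mean()
    Sc = S - row[None, :] - row[:, None] + grand
    num = np.trace(Sc) ** 2
    den = (p - 1) * np.sum(Sc**2)
    eps = num / den if den > 0 else 1.0
    return float(min(max(eps, 1.0 / (p - 1)), 1.0))


def rm_anova(
    long: pd.DataFrame,
    subject: str = "subject",
    within: str = "within",
    between: str = "between",
    value: str = "value",
) -> AnovaResult:
    """Split-plot ANOVA: one within-subject and one between-subjects factor.

    Requires a complete balanced within-design (every subject observed at all
    within levels).  Sums of squares follow the classical univariate
    decomposition; the within and interaction effects are reported both
    uncorrected and with Greenhouse–Geisser-corrected degrees of freedom.
    """
    df = long[[subject, within, between, value]].dropna()
    wide = df.pivot_table(index=subject, columns=within, values=value)
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"subjects missing within-levels: {bad}")
    grp = df.groupby(subject)[between].first().loc[wide.index]
    Y = wide.to_numpy(float)
    groups = grp.to_numpy()
    n, p = Y.shape
    glev = np.unique(groups)
    g = len(glev)

    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    group_means = {lv: Y[groups == lv].mean() for lv in glev}
    level_means = Y.mean(axis=0)
    cell_means = {lv: Y[groups == lv].mean(axis=0) for lv in glev}
    n_g = {lv: int((groups == lv).sum()) for lv in glev}

    ss_total = float(((Y - grand) ** 2).sum())
    ss_subjects = float(p * ((subj_means - grand) ** 2).sum())
    ss_between = float(p * sum(n_g[lv] * (group_means[lv] - grand) ** 2 for lv in glev))
    ss_subj_err = ss_subjects - ss_between
    ss_within = float(n * ((level_means - grand) ** 2).sum())
    ss_cells = float(
        sum(n_g[lv] * ((cell_means[lv] - grand) ** 2).sum() for lv in glev)
    )
    ss_inter = ss_cells - ss_between - ss_within
    ss_err_within = ss_total - ss_subjects - ss_within - ss_inter

    df_b, df_bs = g - 1, n - g
    df_w, df_i = p - 1, (p - 1) * (g - 1)
    df_ew = (p - 1) * (n - g)

    def ms(ss, d):
        return ss / d if d > 0 else np.nan

    def f_ratio(ms_eff, ms_err):
        # zero effect variance is F = 0 even in a noise-free design
        if ms_eff == 0:
            return 0.0
        return ms_eff / ms_err if ms_err > 0 else np.nan

    f_b = f_ratio(ms(ss_between, df_b), ms(ss_subj_err, df_bs))
    f_w = f_ratio(ms(ss_within, df_w), ms(ss_err_within, df_ew))
    f_i = f_ratio(ms(ss_inter, df_i), ms(ss_err_within, df_ew))

    eps = _gg_epsilon(Y, groups)
    rows = []
    rows.append(
        (between, f_b, df_b, df_bs, float(stats.f.sf(f_b, df_b, df_bs)),
         df_b, df_bs, float(stats.f.sf(f_b, df_b, df_bs)))
    )
    for name, f, d1, d2 in ((within, f_w, df_w, df_ew), ("interaction", f_i, df_i, df_ew)):
        rows.append(
            (name, f, d1, d2, float(stats.f.sf(f, d1, d2)),
             d1 * eps, d2 * eps, float(stats.f.sf(f, d1 * eps, d2 * eps)))
        )
    table = pd.DataFrame(
        rows,
        columns=["effect", "F", "df1", "df2", "p", "df1_gg", "df2_gg", "p_gg"],
    ).set_index("effect")
    return AnovaResult(table=table, epsilon=eps)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch two-sample t with Satterthwaite df, two-sided p.

    Degenerate case: both groups constant with equal means → (0, n-2, 1).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        return np.inf, float(x.size + y.size - 2), 0.0
    se2x, se2y = vx / x.size, vy / y.size
    t = (x.mean() - y.mean()) / np.sqrt(se2x + se2y)
    df = (se2x + se2y) ** 2 / (
        se2x**2 / (x.size - 1) + se2y**2 / (y.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)
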