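"""Preprocessing: transform selection, iterative Grubbs outlier removal, kNN imputation.

The three steps run in a fixed order on the metabolomics block of a cohort:
(1) for every continuous variable a normalizing transform (none / log / sqrt /
reciprocal) is chosen by Kolmogorov–Smirnov tests against a moment-matched
normal; (2) outliers are removed variable-by-variable with iterated two-sided
Grubbs tests, each detected outlier replaced by the missing marker; (3) all
missing cells (original plus removed outliers) are filled by distance-weighted
k-nearest-neighbour imputation on standardized rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synth import CohortTable

__all__ = [
    "TransformReport",
    "OutlierReport",
    "select_transform",
    "apply_transform",
    "grubbs_iterative",
    "knn_impute",
    "preprocess_cohort",
]

_TRANSFORMS = ("none", "log", "sqrt", "reciprocal")


@dataclass
class TransformReport:
    variable: str
    ks_pvalues: dict[str, float]  # candidate -> KS p against fitted normal
    chosen: str


@dataclass
class OutlierReport:
    variable: str
    removed_indices: list[int]
    statistics: list[float] = field(default_factory=list)  # Grubbs G per iteration
    critical_values: list[float] = field(default_factory=list)
    n_iterations: int = 0


def _ks_normal_p(x: np.ndarray) -> float:
    """KS p-value of x against a normal with moment-estimated parameters.

    Plain (non-Lilliefors) KS: anticonservative because the parameters are
    estimated from the same data, matching the usual direct use of the test.
    """
    mu, sd = np.mean(x), np.std(x, ddof=1)
    return stats.kstest(x, "norm", args=(mu, sd)).pvalue


def apply_transform(x: np.ndarray, transform: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if transform == "none":
        return x
    if transform == "log":
        return np.log(x)
    if transform == "sqrt":
        return np.sqrt(x)
    if transform == "reciprocal":
        return 1.0 / x
    raise ValueError(f"unknown transform {transform!r}")


def select_transform(
    x: np.ndarray, alpha: float = 0.05, variable: str = ""
) -> TransformReport:
    """Choose the normalizing transform for one variable.

    The untransformed data win whenever their KS test is non-significant;
    otherwise the candidate with the largest p-value wins; if every candidate
    stays significant, "none" is recorded (no transform rescues normality).
    log and reciprocal require strictly positive data, sqrt non-negative data;
    inapplicable candidates are skipped.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError(f"variable {variable!r}: all values missing")
    if x.size < 8:
        raise ValueError(f"variable {variable!r}: needs >= 8 non-missing values")
    if np.std(x, ddof=1) == 0:
        raise ValueError(f"variable {variable!r}: zero variance")

    pvals: dict[str, float] = {"none": _ks_normal_p(x)}
    if np.all(x > 0):
        pvals["log"] = _ks_normal_p(np.log(x))
        pvals["reciprocal"] = _ks_normal_p(1.0 / x)
    if np.all(x >= 0):
        sq = np.sqrt(x)
        if np.std(sq, ddof=1) > 0:
            pvals["sqrt"] = _ks_normal_p(sq)

    if pvals["none"] > alpha:
        chosen = "none"
    else:
        best = max(pvals, key=lambda k: pvals[k])
        chosen = best if pvals[best] > alpha else "none"
    return TransformReport(variable=variable, ks_pvalues=pvals, chosen=chosen)


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the t distribution."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_iterative(
    x: np.ndarray, alpha: float = 0.05, variable: str = ""
) -> tuple[np.ndarray, OutlierReport]:
    """Iterated two-sided Grubbs test, one point removed per iteration.

    Returns the vector with detected outliers replaced by NaN, plus the
    report.  Iteration stops at the first non-significant test or when fewer
    than 3 observed values remain.  A zero-variance vector is returned clean.
    """
    x = np.asarray(x, dtype=float).copy()
    report = OutlierReport(variable=variable, removed_indices=[])
    while True:
        obs = np.flatnonzero(~np.isnan(x))
        if obs.size < 3:
            break
        vals = x[obs]
        mu, sd = np.mean(vals), np.std(vals, ddof=1)
        report.n_iterations += 1
        if sd == 0:
            break
        dev = np.abs(vals - mu)
        j = int(np.argmax(dev))
        g = dev[j] / sd
        crit = grubbs_critical(obs.size, alpha)
        report.statistics.append(float(g))
        report.critical_values.append(float(crit))
        if g > crit:
            x[obs[j]] = np.nan
            report.removed_indices.append(int(obs[j]))
        else:
            break
    return x, report


def knn_impute(table: CohortTable, k: int = 3, columns: list[str] | None = None) -> CohortTable:
    """Distance-weighted k-nearest-neighbour imputation (default k = 3).

    Rows are compared on standardized, pairwise-complete columns (mean of
    squared standardized differences over the columns both rows observe);
    each missing cell is filled with the inverse-distance-weighted mean of the
    k nearest rows observed on that column.  A Gaussian-kernel-free fallback
    applies at zero distance: exact neighbours get uniform weights.  Observed
    cells are never touched.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out = table.copy()
    cols = columns if columns is not None else list(out.data.columns)
    X = out.data[cols].to_numpy(dtype=float)
    n, d = X.shape
    if n == 0 or not np.isnan(X).any():
        return out
    all_missing = [cols[j] for j in range(d) if np.all(np.isnan(X[:, j]))]
    if all_missing:
        raise ValueError(f"columns missing in all rows: {all_missing}")
    if np.isnan(X).all(axis=1).any():
        raise ValueError("every row must have at least one observed value")

    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    sd[~(sd > 0)] = 1.0
    Z = (X - mu) / sd
    obs = ~np.isnan(Z)

    filled = X.copy()
    for i in range(n):
        miss_j = np.flatnonzero(~obs[i])
        for j in miss_j:
            cand = np.flatnonzero(obs[:, j])
            cand = cand[cand != i]
            dists = np.empty(cand.size)
            for t, c in enumerate(cand):
                shared = obs[i] & obs[c]
                if not shared.any():
                    dists[t] = np.inf
                    continue
                diff = Z[i, shared] - Z[c, shared]
                dists[t] = np.sqrt(np.mean(diff**2))
            order = np.argsort(dists, kind="stable")[: min(k, cand.size)]
            nn = cand[order]
            nd = dists[order]
            finite = np.isfinite(nd)
            nn, nd = nn[finite], nd[finite]
            if nn.size == 0:
                raise ValueError("no comparable neighbour rows for imputation")
            if np.any(nd == 0):
                w = (nd == 0).astype(float)
            else:
                w = 1.0 / nd
            filled[i, j] = float(np.sum(w * X[nn, j]) / np.sum(w))
    out.data[cols] = filled
    return out


def preprocess_cohort(
    table: CohortTable, alpha: float = 0.05, k: int = 3
) -> tuple[CohortTable, list[TransformReport], list[OutlierReport]]:
    """Run the full preprocessing chain on the metabolomics block.

    Order: transform selection → iterative Grubbs outlier removal (on the
    transformed scale, outliers blanked in the working table) → kNN
    imputation of all missing cells.  The returned table holds the
    transformed, outlier-free, imputed metabolomics columns; other columns
    pass through untouched.
    """
    out = table.copy()
    metab = out.metabolomic_columns
    treports: list[TransformReport] = []
    oreports: list[OutlierReport] = []
    for col in metab:
        x = out.data[col].to_numpy(dtype=float)
        tr = select_transform(x, alpha=alpha, variable=col)
        treports.append(tr)
        mask = ~np.isnan(x)
        y = x.copy()
        y[mask] = apply_transform(x[mask], tr.chosen)
        y, orep = grubbs_iterative(y, alpha=alpha, variable=col)
        oreports.append(orep)
        out.data[col] = y
    out = knn_impute(out, k=k, columns=metab)
    return out, treports, oreports
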