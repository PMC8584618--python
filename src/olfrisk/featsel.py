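"""Resampled feature selection with ABC-curve aggregation.

Three selectors — an all-relevant shadow-feature test built on random-forest
importances (Boruta-style), cross-validated LASSO, and LMG relative
importance (the Shapley decomposition of R² over predictor orderings) — are
each re-run on Monte-Carlo subsamples (two-thirds of the cohort per run).
Per-feature selection counts over the runs are then partitioned by computed
ABC analysis into the "important few" (A), intermediates (B) and the
"trivial many" (C); the final feature set takes the top-f features by count,
with f the modal per-run selected-set size, and flags any disagreement with
ABC set-A membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LassoCV

__all__ = [
    "FeatureReport",
    "ABCResult",
    "boruta_select",
    "lasso_select",
    "lmg_importance",
    "resampled_selection",
    "abc_analysis",
    "final_feature_set",
]


@dataclass
class ABCResult:
    order: list[int]  # item indices sorted by descending value
    set_a: list[int]
    set_b: list[int]
    set_c: list[int]
    ab_limit: int  # number of items in A
    bc_limit: int  # number of items in A+B


@dataclass
class FeatureReport:
    features: list[str]
    counts: np.ndarray  # selections per feature over runs
    runs: int
    modal_set_size: int
    final_set: list[str]
    abc_labels: dict[str, str]  # feature -> "A" | "B" | "C" | "never"
    disagreement: bool
    set_sizes: np.ndarray = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Selectors
# ---------------------------------------------------------------------------


def boruta_select(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.01,
    max_iter: int = 100,
    seed: int = 0,
    n_trees: int = 100,
    bonferroni: bool = True,
) -> list[int]:
    """All-relevant selection by shadow-feature testing (regression mode).

    Each iteration appends a column-permuted shadow copy of every live
    feature, fits a random-forest regressor, and scores a *hit* for every
    real feature whose importance exceeds the maximum shadow importance.
    Accumulated hits are tested against Binomial(iterations, 0.5): a feature
    with significantly more hits than expected (two-sided p < alpha, by
    default Bonferroni-adjusted across the d features) is confirmed;
    significantly fewer and it is rejected and dropped from further
    iterations.  Features still undecided at max_iter are not selected.
    Returns the confirmed feature indices.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if np.std(y) == 0:
        raise ValueError("constant response")
    n, d = X.shape
    if d < 2:
        raise ValueError("need >= 2 features")
    rng = np.random.default_rng(seed)
    undecided = list(range(d))
    confirmed: list[int] = []
    hits = np.zeros(d, int)
    trials = np.zeros(d, int)
    while undecided and trials.max(initial=0) < max_iter:
        design_cols = confirmed + undecided  # rejected features leave the forest
        Xd = X[:, design_cols]
        # at least 5 shadows, so the shadow maximum stays a meaningful bar
        # even when few features remain live
        shadow_src = list(range(Xd.shape[1]))
        while len(shadow_src) < 5:
            shadow_src.append(shadow_src[len(shadow_src) % Xd.shape[1]])
        shadows = np.column_stack(
            [rng.permutation(Xd[:, j]) for j in shadow_src]
        )
        rf = RandomForestRegressor(
            n_estimators=n_trees, max_features="sqrt",
            random_state=int(rng.integers(2**31)), n_jobs=1,
        )
        rf.fit(np.column_stack([Xd, shadows]), y)
        imp = rf.feature_importances_
        shadow_max = imp[Xd.shape[1]:].max()
        for pos, j in enumerate(design_cols):
            if j in undecided:
                trials[j] += 1
                if imp[pos] > shadow_max:
                    hits[j] += 1
        # binomial decisions (two-sided at alpha); rejected features drop out
        a_eff = alpha / d if bonferroni else alpha
        still = []
        for j in undecided:
            res = stats.binomtest(int(hits[j]), int(trials[j]), 0.5)
            if res.pvalue < a_eff:
                if hits[j] > trials[j] / 2.0:
                    confirmed.append(j)
                continue
            still.append(j)
        undecided = still
    return sorted(confirmed)


def lasso_select(
    X: np.ndarray, y: np.ndarray, folds: int = 5, seed: int = 0
) -> list[int]:
    """Features with nonzero coefficients at the CV-minimal L1 penalty."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = X.shape[0]
    if n < folds:
        raise ValueError(f"n={n} smaller than folds={folds}")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    model = LassoCV(cv=folds, random_state=seed, alphas=60, max_iter=5000)
    model.fit(Z, y - y.mean())
    return sorted(np.flatnonzero(np.abs(model.coef_) > 1e-10).tolist())


def _r2_from_corr(Ryy: np.ndarray, ryx: np.ndarray, subset: tuple[int, ...]) -> float:
    if not subset:
        return 0.0
    idx = list(subset)
    R = Ryy[np.ix_(idx, idx)]
    r = ryx[idx]
    try:
        beta = np.linalg.solve(R, r)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(R, r, rcond=None)[0]
    return float(r @ beta)


def lmg_importance(
    X: np.ndarray, y: np.ndarray, max_exact: int = 12,
    n_orderings: int = 200, seed: int = 0,
) -> np.ndarray:
    """LMG relative importance: average R² increment over predictor orderings.

    The Shapley decomposition of the full-model R².  Exact subset enumeration
    (with the combinatorial ordering weights) for d <= max_exact; Monte-Carlo
    over random orderings beyond that.  Importances are non-negative (up to
    numerical noise) and sum to the full-model R².
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, d = X.shape
    if n <= d + 2:
        raise ValueError("need n > d + 2")
    sdx = X.std(axis=0, ddof=1)
    if np.any(sdx == 0) or y.std(ddof=1) == 0:
        raise ValueError("singular design (constant column or response)")
    Zx = (X - X.mean(axis=0)) / sdx
    zy = (y - y.mean()) / y.std(ddof=1)
    Rxx = (Zx.T @ Zx) / (n - 1)
    ryx = (Zx.T @ zy) / (n - 1)

    imp = np.zeros(d)
    if d <= max_exact:
        r2 = {(): 0.0}
        for size in range(1, d + 1):
            for sub in combinations(range(d), size):
                r2[sub] = _r2_from_corr(Rxx, ryx, sub)
        from math import factorial

        for j in range(d):
            others = [i for i in range(d) if i != j]
            for size in range(0, d):
                w = factorial(size) * factorial(d - size - 1) / factorial(d)
                for sub in combinations(others, size):
                    with_j = tuple(sorted(sub + (j,)))
                    imp[j] += w * (r2[with_j] - r2[sub])
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_orderings):
            order = rng.permutation(d)
            prev: tuple[int, ...] = ()
            r2_prev = 0.0
            for j in order:
                cur = tuple(sorted(prev + (j,)))
                r2_cur = _r2_from_corr(Rxx, ryx, cur)
                imp[j] += r2_cur - r2_prev
                prev, r2_prev = cur, r2_cur
        imp /= n_orderings
    return imp


# ---------------------------------------------------------------------------
# Computed ABC analysis
# ---------------------------------------------------------------------------


def abc_analysis(values: np.ndarray) -> ABCResult:
    """Partition positive values into sets A ("important few"), B, and C.

    Values are sorted descending; over the cumulative-item-fraction x and
    cumulative-contribution fraction y the A|B limit sits at the curve point
    nearest the ideal point (0, 1) and the B|C limit at the break-even point
    where the curve's slope falls to 1 (items at or above the mean).  If the
    nearest-to-ideal point falls beyond break-even, the A|B limit moves to
    break-even.  Invariant to positive rescaling of the input.
    """
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("empty input")
    if np.any(values <= 0):
        raise ValueError("abc_analysis requires strictly positive values")
    n = values.size
    order = np.argsort(-values, kind="stable")
    v = values[order]
    x = np.arange(1, n + 1) / n
    ycum = np.cumsum(v) / v.sum()
    dist2 = x**2 + (1.0 - ycum) ** 2
    ab = int(np.argmin(dist2)) + 1  # items in A (1-based count)
    mean = v.mean()
    at_or_above = np.flatnonzero(v >= mean)
    bc = int(at_or_above[-1]) + 1 if at_or_above.size else 1
    if ab > bc:
        ab = bc
    return ABCResult(
        order=order.tolist(),
        set_a=order[:ab].tolist(),
        set_b=order[ab:bc].tolist(),
        set_c=order[bc:].tolist(),
        ab_limit=ab,
        bc_limit=bc,
    )


# ---------------------------------------------------------------------------
# Resampled selection and aggregation
# ---------------------------------------------------------------------------


def _run_selector(selector, X, y, seed: int, **kw) -> list[int]:
    if callable(selector):
        return selector(X, y, seed=seed, **kw)
    if selector == "boruta":
        return boruta_select(X, y, seed=seed, **kw)
    if selector == "lasso":
        return lasso_select(X, y, seed=seed, **kw)
    if selector == "lmg":
        imp = lmg_importance(X, y, seed=seed, **kw)
        pos = np.flatnonzero(imp > 0)
        if pos.size == 0:
            return []
        abc = abc_analysis(imp[pos])
        return sorted(pos[abc.set_a].tolist())
    raise ValueError(f"unknown selector {selector!r}")


def resampled_selection(
    selector,
    X: np.ndarray,
    y: np.ndarray,
    runs: int = 1000,
    subsample_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    **selector_kwargs,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Re-run one selector on Monte-Carlo subsamples; collect per-feature counts.

    Per run, ⌊subsample_fraction·n⌋ subjects are drawn without replacement and
    the selector's chosen set recorded.  For the LMG selector a run's set is
    ABC set A of that run's importances.  Returns (counts, per-run set sizes,
    n_failed_runs); failed runs contribute no counts.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, d = X.shape
    m = int(np.floor(subsample_fraction * n))
    rng = np.random.default_rng(seed)
    counts = np.zeros(d, int)
    sizes = np.zeros(runs, int)
    failures = 0
    for r in range(runs):
        idx = rng.choice(n, size=m, replace=False)
        try:
            sel = _run_selector(
                selector, X[idx], y[idx],
                seed=int(rng.integers(2**31)), **selector_kwargs,
            )
        except ValueError:
            failures += 1
            sizes[r] = -1
            continue
        counts[sel] += 1
        sizes[r] = len(sel)
    return counts, sizes[sizes >= 0], failures


def final_feature_set(
    counts: np.ndarray,
    set_sizes: np.ndarray,
    features: list[str] | None = None,
    runs: int | None = None,
) -> FeatureReport:
    """Aggregate resampled counts into the final feature set.

    The final set keeps the top-f features by selection count, where f is the
    most common selected-set size across runs; count ties at the cut include
    every tied feature and raise the disagreement flag.  ABC set-A membership
    of the counts is reported alongside, with the flag raised whenever the
    two rules differ.  Features never selected are labelled "never".
    """
    counts = np.asarray(counts, int)
    set_sizes = np.asarray(set_sizes, int)
    if set_sizes.size == 0:
        raise ValueError("runs must be > 0")
    d = counts.size
    features = features if features is not None else [f"x{j}" for j in range(d)]
    runs = runs if runs is not None else int(set_sizes.size)

    vals, freq = np.unique(set_sizes, return_counts=True)
    modal = int(vals[np.argmax(freq)])

    labels = {f: "never" for f in features}
    pos = np.flatnonzero(counts > 0)
    if pos.size:
        abc = abc_analysis(counts[pos].astype(float))
        for name, s in (("A", abc.set_a), ("B", abc.set_b), ("C", abc.set_c)):
            for i in s:
                labels[features[pos[i]]] = name
    a_set = {f for f, lab in labels.items() if lab == "A"}

    disagreement = False
    if modal == 0 or not pos.size:
        final: list[str] = []
        disagreement = bool(a_set)
    else:
        order = np.argsort(-counts, kind="stable")
        cut = counts[order[modal - 1]] if modal <= d else 0
        chosen = np.flatnonzero(counts >= max(cut, 1))
        final = [features[j] for j in sorted(chosen, key=lambda j: -counts[j])]
        if len(final) != modal:
            disagreement = True  # ties at the boundary widened the set
    if set(final) != a_set:
        disagreement = True
    return FeatureReport(
        features=list(features), counts=counts, runs=runs,
        modal_set_size=modal, final_set=final, abc_labels=labels,
        disagreement=disagreement, set_sizes=set_sizes,
    )
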