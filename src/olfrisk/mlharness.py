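"""Permutation-controlled Monte-Carlo cross-validation classification harness.

The question "does feature block X predict group label y?" is answered by
repeated random subsampling: per run the cohort is split class-proportionally
into 2/3 training and 1/3 test subsets, a classifier is fitted and scored on
the held-out third, and the per-run metric distribution is summarized as the
median with the 2.5–97.5 percentile interval.  A negative control refits each
run on freshly permuted training labels; any systematic departure from 50%
balanced accuracy there flags overfitting or leakage.

Five classifier families cover distinct inductive biases: random forest,
gradient-boosted trees, an entropy-based decision tree standing in for a
rule inducer, logistic regression, and an RBF support-vector machine.  The
classifier backends are standard library estimators behind a uniform
fit/predict/score contract; the splitting, permutation, metric formulas and
summaries are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

__all__ = [
    "CLASSIFIER_FAMILIES",
    "SplitPlan",
    "ConfusionMetrics",
    "PerformanceSummary",
    "binarize_risk",
    "stratified_mc_splits",
    "confusion_metrics",
    "make_classifier",
    "run_cv",
]

METRIC_NAMES = (
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "f1",
    "balanced_accuracy",
    "roc_auc",
)

CLASSIFIER_FAMILIES = ("random_forest", "boosting", "rules", "logistic", "svm")


@dataclass
class SplitPlan:
    runs: int
    train_indices: list[np.ndarray]
    test_indices: list[np.ndarray]
    labels: np.ndarray
    seed: int


@dataclass
class ConfusionMetrics:
    """All values in percent; NaN where undefined (e.g. PPV without positives)."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float
    balanced_accuracy: float
    roc_auc: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


@dataclass
class PerformanceSummary:
    classifier: str
    feature_set: str
    condition: str  # "original" | "permuted"
    median: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    nan_runs: dict[str, int]
    runs: int
    per_run: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


# ---------------------------------------------------------------------------


def binarize_risk(score: float, breakpoint: float = 11) -> str:
    """'low' iff score <= breakpoint (default 11: risk categories 1–2 vs 3–5)."""
    if score < 0:
        raise ValueError("risk score must be non-negative")
    return "low" if score <= breakpoint else "high"


def stratified_mc_splits(
    labels: np.ndarray,
    runs: int = 1000,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> SplitPlan:
    """Class-proportional Monte-Carlo train/test splits, reproducible from seed.

    Per run and class, round(n_class * train_fraction) subjects go to training
    (at least 1 on each side), the rest to test; train and test are disjoint
    and exhaust the cohort.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 3):
        small = classes[counts < 3].tolist()
        raise ValueError(f"classes too small for splitting: {small}")
    per_class_idx = [np.flatnonzero(labels == c) for c in classes]
    n_train = [
        int(np.clip(round(len(ix) * train_fraction), 1, len(ix) - 1))
        for ix in per_class_idx
    ]
    train_sets, test_sets = [], []
    for _ in range(runs):
        tr_parts, te_parts = [], []
        for ix, nt in zip(per_class_idx, n_train):
            perm = rng.permutation(ix)
            tr_parts.append(perm[:nt])
            te_parts.append(perm[nt:])
        train_sets.append(np.sort(np.concatenate(tr_parts)))
        test_sets.append(np.sort(np.concatenate(te_parts)))
    return SplitPlan(
        runs=runs, train_indices=train_sets, test_indices=test_sets,
        labels=labels, seed=seed,
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def _rank_auc(truth_pos: np.ndarray, scores: np.ndarray) -> float:
    """ROC-AUC via the Mann–Whitney rank formulation with tie mid-ranks."""
    n_pos = int(truth_pos.sum())
    n_neg = int((~truth_pos).sum())
    if n_pos == 0 or n_neg == 0:
        return np.nan
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores), float)
    sorted_scores = scores[order]
    i = 0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    r_pos = ranks[truth_pos].sum()
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def confusion_metrics(
    truth: np.ndarray,
    predicted: np.ndarray,
    scores: np.ndarray | None = None,
    positive: object = 1,
) -> ConfusionMetrics:
    """Two-class confusion metrics in percent; NaN where undefined.

    ``positive`` names the clinically adverse class (higher risk / reduced
    olfaction).  ``scores`` (higher = more positive) enable the rank-based
    ROC-AUC; without them AUC is NaN.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    t = truth == positive
    p = predicted == positive
    tp = int(np.sum(t & p))
    fn = int(np.sum(t & ~p))
    fp = int(np.sum(~t & p))
    tn = int(np.sum(~t & ~p))

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else np.nan

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    # F1 is the harmonic mean of PPV and sensitivity: undefined whenever
    # either ingredient is (no positive predictions / no positive truths)
    if (tp + fp) == 0 or (tp + fn) == 0:
        f1 = np.nan
    else:
        f1 = ratio(2 * tp, 2 * tp + fp + fn)
    bal = (sens + spec) / 2.0 if not (np.isnan(sens) or np.isnan(spec)) else np.nan
    auc = np.nan
    if scores is not None and not np.isnan(sens) and not np.isnan(spec):
        auc = 100.0 * _rank_auc(t, np.asarray(scores, float))
    return ConfusionMetrics(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        f1=f1, balanced_accuracy=bal, roc_auc=auc,
    )


# ---------------------------------------------------------------------------
# Classifier factory
# ---------------------------------------------------------------------------


def make_classifier(
    family: str, seed: int = 0, n_features: int | None = None,
    max_features_multiplier: float = 1.0,
):
    """Instantiate one classifier family with the study's hyperparameters.

    random forest: 500 trees, max 7 terminal nodes, mtry = multiplier·√p;
    boosting: depth 5, learning rate 0.25, 5 parallel trees; rules: an
    entropy decision tree (rule-inducer stand-in); logistic and RBF-SVM are
    fitted on standardized features.
    """
    if family == "random_forest":
        mtry = None
        if n_features:
            mtry = int(np.clip(round(max_features_multiplier * np.sqrt(n_features)),
                               1, n_features))
        return RandomForestClassifier(
            n_estimators=500, max_leaf_nodes=7, max_features=mtry,
            random_state=seed, n_jobs=1,
        )
    if family == "boosting":
        return XGBClassifier(
            n_estimators=50, max_depth=5, learning_rate=0.25,
            num_parallel_tree=5, random_state=seed, n_jobs=1,
            eval_metric="logloss", verbosity=0,
        )
    if family == "rules":
        return DecisionTreeClassifier(criterion="entropy", random_state=seed)
    if family == "logistic":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=1000, random_state=seed)
        )
    if family == "svm":
        return make_pipeline(StandardScaler(), SVC(random_state=seed))
    raise ValueError(f"unknown classifier family {family!r}")


def _predict_scores(clf, X) -> np.ndarray | None:
    if hasattr(clf, "predict_proba"):
        try:
            return clf.predict_proba(X)[:, 1]
        except Exception:
            pass
    if hasattr(clf, "decision_function"):
        return clf.decision_function(X)
    return None


# ---------------------------------------------------------------------------
# The harness
# ---------------------------------------------------------------------------


def run_cv(
    X: np.ndarray,
    y: np.ndarray,
    family: str,
    plan: SplitPlan,
    condition: str = "original",
    feature_set: str = "",
    positive: object = 1,
) -> PerformanceSummary:
    """Fit/evaluate one classifier family over every split of the plan.

    Under ``condition="permuted"`` the training labels are freshly permuted
    each run before fitting (the test labels stay untouched), which removes
    any feature–label association while preserving marginals — the negative
    control.  Degenerate training splits (a single class) are skipped and
    counted as NaN runs.  Metrics whose value is undefined in a run are
    excluded from the median/percentiles with their count reported.
    """
    if condition not in ("original", "permuted"):
        raise ValueError("condition must be 'original' or 'permuted'")
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("run_cv handles two-class problems")
    y01 = (y == positive).astype(int)
    rng = np.random.default_rng(
        np.random.SeedSequence([plan.seed, 1 if condition == "permuted" else 0])
    )

    per_run = {m: np.full(plan.runs, np.nan) for m in METRIC_NAMES}
    for r in range(plan.runs):
        tr, te = plan.train_indices[r], plan.test_indices[r]
        ytr = y01[tr]
        if condition == "permuted":
            ytr = rng.permutation(ytr)
        if np.unique(ytr).size < 2 or np.unique(y01[te]).size < 2:
            continue  # counted as NaN run for every metric
        clf = make_classifier(family, seed=plan.seed + r, n_features=X.shape[1])
        clf.fit(X[tr], ytr)
        pred = clf.predict(X[te])
        scores = _predict_scores(clf, X[te])
        cm = confusion_metrics(y01[te], pred, scores, positive=1)
        for m in METRIC_NAMES:
            per_run[m][r] = getattr(cm, m)

    median, lo, hi, nan_runs = {}, {}, {}, {}
    for m in METRIC_NAMES:
        vals = per_run[m]
        ok = vals[~np.isnan(vals)]
        nan_runs[m] = int(np.isnan(vals).sum())
        if ok.size:
            median[m] = float(np.median(ok))
            lo[m] = float(np.percentile(ok, 2.5))
            hi[m] = float(np.percentile(ok, 97.5))
        else:
            median[m] = lo[m] = hi[m] = np.nan
    return PerformanceSummary(
        classifier=family, feature_set=feature_set, condition=condition,
        median=median, ci_low=lo, ci_high=hi, nan_runs=nan_runs,
        runs=plan.runs, per_run=per_run,
    )
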