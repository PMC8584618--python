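"""End-to-end orchestration: preprocess → modes → cluster → assoc → classify → select.

One master seed drives every stage through ``numpy.random.SeedSequence``
spawning, so a persisted configuration reproduces a run bit-identically (up
to the determinism of the classifier backends, which are themselves seeded).
Each stage writes its own JSON report into the run directory; the final
verdict section states whether olfactory features improved risk-group
prediction.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, cluster, featsel, mlharness, modes, preprocess
from .synth import CategoryMap, CohortTable, GeneratorConfig, categorize_tdi, generate_cohort

logger = logging.getLogger("olfrisk")

__all__ = ["RunConfig", "run_pipeline", "write_report"]


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    input_prefix: str | None = None  # load a cohort instead of generating one
    out_dir: str = "olfrisk_run"
    master_seed: int = 0
    alpha: float = 0.05
    knn_k: int = 3
    m_max: int = 5
    k_range: tuple[int, int] = (2, 8)
    cv_runs: int = 1000
    risk_breakpoint: int = 11
    classifiers: tuple[str, ...] = ("random_forest", "logistic")
    featsel_runs: int = 200
    featsel_methods: tuple[str, ...] = ("lasso",)
    stages: tuple[str, ...] = (
        "preprocess", "modes", "cluster", "assoc", "classify", "select",
    )
    improvement_margin: float = 5.0  # percentage points of balanced accuracy


def _stage_seeds(master: int, names: tuple[str, ...]) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _summary_record(s: mlharness.PerformanceSummary) -> dict:
    return {
        "classifier": s.classifier,
        "feature_set": s.feature_set,
        "condition": s.condition,
        "median": _jsonable(s.median),
        "ci_low": _jsonable(s.ci_low),
        "ci_high": _jsonable(s.ci_high),
        "nan_runs": _jsonable(s.nan_runs),
        "runs": s.runs,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; return (and write) the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(
        config.master_seed,
        ("generate", "modes", "cluster", "classify", "select"),
    )
    report: dict = {"seeds": seeds, "config": _jsonable(asdict(config))}

    def log_stage(name: str, t0: float, **params):
        logger.info("stage=%s elapsed=%.2fs params=%s", name, time.time() - t0, params)

    # --- cohort ---------------------------------------------------------
    t0 = time.time()
    if config.input_prefix:
        table = CohortTable.from_csv(config.input_prefix)
    else:
        gen = GeneratorConfig(**{**asdict(config.generator), "seed": seeds["generate"]})
        table, _truth = generate_cohort(gen)
        table.to_csv(out / "cohort")
    log_stage("cohort", t0, n=table.n_subjects)

    # --- preprocess -----------------------------------------------------
    if "preprocess" in config.stages:
        t0 = time.time()
        table, treps, oreps = preprocess.preprocess_cohort(
            table, alpha=config.alpha, k=config.knn_k
        )
        report["preprocess"] = {
            "transforms": [
                {"variable": r.variable, "chosen": r.chosen,
                 "ks_pvalues": _jsonable(r.ks_pvalues)}
                for r in treps
            ],
            "outliers_removed": int(sum(len(r.removed_indices) for r in oreps)),
            "per_variable_outliers": {
                r.variable: len(r.removed_indices) for r in oreps
            },
        }
        log_stage("preprocess", t0, alpha=config.alpha, k=config.knn_k)

    tdi = table.data[table.tdi_column].to_numpy(float)
    risk = table.data[table.risk_column].to_numpy(float)
    metab_cols = table.metabolomic_columns
    olf_cols = table.olfactory_subtest_columns

    # --- modes ----------------------------------------------------------
    if "modes" in config.stages:
        t0 = time.time()
        sel_tdi = modes.select_mode_count(tdi, config.m_max, seed=seeds["modes"])
        sel_risk = modes.select_mode_count(risk, config.m_max, seed=seeds["modes"] + 1)
        fit = sel_tdi.chosen_fit
        bounds = modes.bayes_boundaries(fit) if fit.M >= 2 else []
        report["modes"] = {
            "tdi": {
                "chosen_m": sel_tdi.chosen_m,
                "bic": _jsonable(sel_tdi.bic_table),
                "means": _jsonable(fit.means),
                "sds": _jsonable(fit.sds),
                "weights": _jsonable(fit.weights),
                "boundaries": _jsonable(bounds),
                "ks_p": sel_tdi.ks_pvalue,
            },
            "risk": {
                "chosen_m": sel_risk.chosen_m,
                "bic": _jsonable(sel_risk.bic_table),
                "ks_p": sel_risk.ks_pvalue,
            },
        }
        log_stage("modes", t0, m_max=config.m_max)

    # --- cluster --------------------------------------------------------
    if "cluster" in config.stages:
        t0 = time.time()
        pca = cluster.pca_project(table.data[metab_cols].to_numpy(float), metab_cols)
        k, votes, sols = cluster.choose_k(
            pca.retained_scores,
            range(config.k_range[0], config.k_range[1] + 1),
            seed=seeds["cluster"],
        )
        sol = sols[k]
        report["cluster"] = {
            "eigenvalues": _jsonable(pca.eigenvalues),
            "retained": pca.retained,
            "k": k,
            "votes": _jsonable(votes),
            "silhouette": sol.silhouette,
        }
        cluster_labels = sol.labels
        pd.DataFrame(
            pca.retained_scores,
            index=table.data.index,
            columns=[f"PC{i+1}" for i in range(pca.retained)],
        ).assign(cluster=cluster_labels).to_csv(out / "scores.csv")
        log_stage("cluster", t0, k=k)
    else:  # pragma: no cover - cluster labels needed downstream
        cluster_labels = None

    # --- association stats ----------------------------------------------
    if "assoc" in config.stages:
        t0 = time.time()
        cmap = CategoryMap()
        tdi_cat = np.array([categorize_tdi(min(max(v, 1.0), 48.0), cmap) for v in tdi])
        risk_bin = np.array(
            [mlharness.binarize_risk(s, config.risk_breakpoint) for s in risk]
        )
        assoc_rep: dict = {}
        try:
            ct = assoc.crosstab_chi2(tdi_cat, risk_bin)
            assoc_rep["tdi_category_vs_risk"] = {
                "chi2": ct.chi2, "df": ct.df, "p": ct.pvalue,
                "low_expected": ct.low_expected,
            }
        except ValueError as exc:
            assoc_rep["tdi_category_vs_risk"] = {"error": str(exc)}
        if cluster_labels is not None:
            ct2 = assoc.crosstab_chi2(cluster_labels, risk_bin)
            assoc_rep["cluster_vs_risk"] = {
                "chi2": ct2.chi2, "df": ct2.df, "p": ct2.pvalue,
            }
        corr_cols = olf_cols + [table.tdi_column, table.risk_column, "age", "bmi"]
        corr_cols += metab_cols
        corr_cols = [c for c in corr_cols if c in table.data.columns]
        cm = assoc.corr_matrix(table.data[corr_cols], alpha=config.alpha)
        olf_all = olf_cols + [table.tdi_column]
        non_olf = [c for c in corr_cols if c not in olf_all]
        sig_olf = {
            o: [c for c in non_olf if bool(cm.significant.loc[o, c])]
            for o in olf_all
        }
        assoc_rep["olfactory_significant_partners"] = sig_olf
        long = table.data[olf_cols].copy()
        long["subject"] = table.data.index
        long["between"] = risk_bin
        long = long.melt(
            id_vars=["subject", "between"], var_name="within", value_name="value"
        )
        an = assoc.rm_anova(long)
        assoc_rep["rm_anova"] = _jsonable(
            {
                eff: dict(row) for eff, row in an.table.iterrows()
            }
        )
        report["assoc"] = assoc_rep
        log_stage("assoc", t0)

    # --- classification harness -----------------------------------------
    if "classify" in config.stages:
        t0 = time.time()
        risk_bin = np.array(
            [mlharness.binarize_risk(s, config.risk_breakpoint) for s in risk]
        )
        plan = mlharness.stratified_mc_splits(
            risk_bin, runs=config.cv_runs, seed=seeds["classify"]
        )
        feature_sets = {
            "metabolomics": metab_cols,
            "olfactory": olf_cols,
            "both": metab_cols + olf_cols,
        }
        records = []
        for fam in config.classifiers:
            for fs_name, cols in feature_sets.items():
                X = table.data[cols].to_numpy(float)
                s = mlharness.run_cv(
                    X, risk_bin, fam, plan, "original",
                    feature_set=fs_name, positive="high",
                )
                records.append(s)
                if fs_name == "metabolomics":
                    records.append(
                        mlharness.run_cv(
                            X, risk_bin, fam, plan, "permuted",
                            feature_set=fs_name, positive="high",
                        )
                    )
        report["classify"] = [_summary_record(s) for s in records]
        rows = []
        for s in records:
            for m, vals in s.per_run.items():
                for r, v in enumerate(vals):
                    rows.append((s.classifier, s.feature_set, s.condition, m, r, v))
        pd.DataFrame(
            rows, columns=["classifier", "feature_set", "condition", "metric",
                           "run", "value"],
        ).to_csv(out / "per_run_metrics.csv", index=False)
        log_stage("classify", t0, runs=config.cv_runs)

    # --- feature selection ----------------------------------------------
    if "select" in config.stages:
        t0 = time.time()
        feats = metab_cols + olf_cols + ["age", "bmi"]
        feats = [c for c in feats if c in table.data.columns]
        X = table.data[feats].to_numpy(float)
        sel_rep = {}
        for method in config.featsel_methods:
            counts, sizes, fails = featsel.resampled_selection(
                method, X, risk, runs=config.featsel_runs,
                seed=seeds["select"],
            )
            fr = featsel.final_feature_set(counts, sizes, feats)
            sel_rep[method] = {
                "counts": _jsonable(dict(zip(feats, counts))),
                "modal_set_size": fr.modal_set_size,
                "final_set": fr.final_set,
                "abc_labels": fr.abc_labels,
                "disagreement": fr.disagreement,
                "failed_runs": fails,
            }
        report["select"] = {"target": "risk_score", "methods": sel_rep}
        log_stage("select", t0, runs=config.featsel_runs)

    # --- verdict ---------------------------------------------------------
    report["verdict"] = _verdict(report, config)
    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
    (out / "report.md").write_text(write_report(report))
    return report


def _verdict(report: dict, config: RunConfig) -> dict:
    """Do olfactory features improve risk-group prediction?"""
    improved = None
    olf_alone_informative = None
    details = []
    if "classify" in report:
        by_key = {
            (r["classifier"], r["feature_set"], r["condition"]): r
            for r in report["classify"]
        }
        improvements = []
        olf_cover_50 = []
        for fam in config.classifiers:
            met = by_key.get((fam, "metabolomics", "original"))
            both = by_key.get((fam, "both", "original"))
            olf = by_key.get((fam, "olfactory", "original"))
            if met and both:
                delta = (both["median"]["balanced_accuracy"]
                         - met["median"]["balanced_accuracy"])
                improvements.append(delta)
                details.append(f"{fam}: both-vs-metabolomics Δbalanced accuracy = {delta:+.1f}")
            if olf:
                covers = (olf["ci_low"]["balanced_accuracy"] <= 50.0
                          <= olf["ci_high"]["balanced_accuracy"])
                olf_cover_50.append(covers)
                details.append(
                    f"{fam}: olfactory-only balanced accuracy "
                    f"{olf['median']['balanced_accuracy']:.1f} "
                    f"[{olf['ci_low']['balanced_accuracy']:.1f}, "
                    f"{olf['ci_high']['balanced_accuracy']:.1f}]"
                )
        if improvements:
            improved = any(d >= config.improvement_margin for d in improvements)
        if olf_cover_50:
            olf_alone_informative = not all(olf_cover_50)
    statement = (
        "olfactory features do not improve risk-group prediction"
        if improved is False and olf_alone_informative is not True
        else "olfactory features show predictive signal for the risk grouping"
        if improved or olf_alone_informative
        else "inconclusive (classification stage not run)"
    )
    return {
        "improved": improved,
        "olfactory_alone_informative": olf_alone_informative,
        "statement": statement,
        "details": details,
    }


def _fmt(v) -> str:
    return "undefined" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.1f}"


def write_report(report: dict) -> str:
    """Render the report bundle as human-readable markdown."""
    lines = ["# olfrisk run report", ""]
    if "modes" in report:
        t = report["modes"]["tdi"]
        lines += [
            "## Mode structure",
            f"TDI: chosen M = {t['chosen_m']}, boundaries = "
            + (", ".join(f"{b:.2f}" for b in t["boundaries"]) or "none"),
            f"Risk score: chosen M = {report['modes']['risk']['chosen_m']}",
            "",
        ]
    if "cluster" in report:
        c = report["cluster"]
        lines += [
            "## Metabolomic clustering",
            f"k = {c['k']} (majority vote), average silhouette = {c['silhouette']:.3f}",
            "",
        ]
    if "classify" in report:
        lines += [
            "## Classification (median (2.5–97.5) over runs, %)",
            "| classifier | features | condition | bal. acc. | AUC | F1 |",
            "|---|---|---|---|---|---|",
        ]
        for r in report["classify"]:
            def cell(metric):
                med = r["median"].get(metric)
                lo, hi = r["ci_low"].get(metric), r["ci_high"].get(metric)
                k = r["nan_runs"].get(metric, 0)
                if med is None:
                    return f"undefined ({k} runs)"
                s = f"{med:.1f} ({_fmt(lo)}–{_fmt(hi)})"
                if k:
                    s += f" [{k} undefined]"
                return s
            lines.append(
                f"| {r['classifier']} | {r['feature_set']} | {r['condition']} | "
                f"{cell('balanced_accuracy')} | {cell('roc_auc')} | {cell('f1')} |"
            )
        lines.append("")
    if "select" in report:
        lines.append("## Feature selection")
        for method, m in report["select"]["methods"].items():
            lines.append(
                f"- {method}: final set = {m['final_set']} "
                f"(modal size {m['modal_set_size']}, disagreement={m['disagreement']})"
            )
        lines.append("")
    else:
        lines += ["## Feature selection", "not run", ""]
    if "verdict" in report:
        lines += ["## Verdict", report["verdict"]["statement"], ""]
        lines += [f"- {d}" for d in report["verdict"]["details"]]
    return "\n".join(lines) + "\n"
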