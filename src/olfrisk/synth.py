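"""Synthetic cohort generation and clinical score categorization.

The generator emulates the statistical structure of a mid-size cross-sectional
diabetes-risk cohort in which three blocks of information coexist:

* olfactory performance measured with the Sniffin' Sticks battery — three
  subtests (odor threshold T, discrimination D, identification I) whose sum,
  the TDI score (range 1–48), follows a two-component Gaussian mixture with a
  small low-performance mode;
* a FINDRISK questionnaire score (integer, unimodal) estimating the 10-year
  risk of developing type 2 diabetes, mapped onto five ordinal risk
  categories;
* a 15-variable metabolomics panel (10 baseline serum markers plus 5
  post-glucose-challenge change scores) carrying an implanted two-cluster
  structure that is correlated with the risk score but — by default —
  independent of olfaction.  The default therefore encodes the *null*
  configuration: smell tells you nothing about diabetes risk.

Latent truth (mixture-mode labels, cluster labels, injected outlier/missing
cells) is returned in a sidecar so tests can act as oracles; it is never part
of the analysis-facing table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROLE_OLFACTORY_SUBTEST",
    "ROLE_OLFACTORY_TOTAL",
    "ROLE_RISK_SCORE",
    "ROLE_METABOLOMIC_BASELINE",
    "ROLE_METABOLOMIC_DELTA",
    "ROLE_DEMOGRAPHIC",
    "ROLE_CONFOUNDER",
    "CohortTable",
    "GeneratorConfig",
    "CategoryMap",
    "CohortTruth",
    "generate_cohort",
    "sample_tdi_mixture",
    "categorize_risk",
    "categorize_tdi",
]

# ---------------------------------------------------------------------------
# Column roles
# ---------------------------------------------------------------------------

ROLE_OLFACTORY_SUBTEST = "olfactory_subtest"
ROLE_OLFACTORY_TOTAL = "olfactory_total"
ROLE_RISK_SCORE = "risk_score"
ROLE_METABOLOMIC_BASELINE = "metabolomic_baseline"
ROLE_METABOLOMIC_DELTA = "metabolomic_delta"
ROLE_DEMOGRAPHIC = "demographic"
ROLE_CONFOUNDER = "confounder"

_VALID_ROLES = {
    ROLE_OLFACTORY_SUBTEST,
    ROLE_OLFACTORY_TOTAL,
    ROLE_RISK_SCORE,
    ROLE_METABOLOMIC_BASELINE,
    ROLE_METABOLOMIC_DELTA,
    ROLE_DEMOGRAPHIC,
    ROLE_CONFOUNDER,
}

# (name, role, unit mean, unit sd, sign of its link to metabolic risk)
# HDL is protective, hence the negative sign.
_METABOLOMIC_SPEC: list[tuple[str, str, float, float, float]] = [
    ("triglycerides", ROLE_METABOLOMIC_BASELINE, 120.0, 55.0, +1.0),
    ("cholesterol", ROLE_METABOLOMIC_BASELINE, 205.0, 38.0, +1.0),
    ("ldl", ROLE_METABOLOMIC_BASELINE, 128.0, 33.0, +1.0),
    ("hdl", ROLE_METABOLOMIC_BASELINE, 58.0, 15.0, -1.0),
    ("hba1c", ROLE_METABOLOMIC_BASELINE, 5.5, 0.45, +1.0),
    ("glucose_0", ROLE_METABOLOMIC_BASELINE, 98.0, 14.0, +1.0),
    ("ffa_0", ROLE_METABOLOMIC_BASELINE, 0.55, 0.2, +1.0),
    ("proinsulin_0", ROLE_METABOLOMIC_BASELINE, 8.0, 4.0, +1.0),
    ("cpeptide_0", ROLE_METABOLOMIC_BASELINE, 2.1, 0.8, +1.0),
    ("insulin_0", ROLE_METABOLOMIC_BASELINE, 10.0, 5.0, +1.0),
    ("glucose_delta", ROLE_METABOLOMIC_DELTA, 35.0, 30.0, +1.0),
    ("ffa_delta", ROLE_METABOLOMIC_DELTA, -0.35, 0.15, -1.0),
    ("proinsulin_delta", ROLE_METABOLOMIC_DELTA, 12.0, 8.0, +1.0),
    ("cpeptide_delta", ROLE_METABOLOMIC_DELTA, 4.5, 2.2, +1.0),
    ("insulin_delta", ROLE_METABOLOMIC_DELTA, 45.0, 30.0, +1.0),
]

# Variables carrying the implanted two-cluster mean shift (8 of 15; the
# insulin-resistance axis of the panel).
_CLUSTER_SHIFT_VARS = (
    "triglycerides",
    "hdl",
    "hba1c",
    "glucose_0",
    "proinsulin_0",
    "insulin_0",
    "glucose_delta",
    "insulin_delta",
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Subjects × role-tagged variables with NaN as the missing marker."""

    data: pd.DataFrame
    roles: dict[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.roles) - set(self.data.columns)
        if unknown:
            raise ValueError(f"roles refer to absent columns: {sorted(unknown)}")
        bad = {r for r in self.roles.values() if r not in _VALID_ROLES}
        if bad:
            raise ValueError(f"unknown column roles: {sorted(bad)}")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def columns_with_role(self, *roles: str) -> list[str]:
        return [c for c in self.data.columns if self.roles.get(c) in roles]

    @property
    def metabolomic_columns(self) -> list[str]:
        return self.columns_with_role(
            ROLE_METABOLOMIC_BASELINE, ROLE_METABOLOMIC_DELTA
        )

    @property
    def olfactory_subtest_columns(self) -> list[str]:
        return self.columns_with_role(ROLE_OLFACTORY_SUBTEST)

    @property
    def risk_column(self) -> str:
        cols = self.columns_with_role(ROLE_RISK_SCORE)
        if len(cols) != 1:
            raise ValueError(f"expected exactly one risk-score column, got {cols}")
        return cols[0]

    @property
    def tdi_column(self) -> str:
        cols = self.columns_with_role(ROLE_OLFACTORY_TOTAL)
        if len(cols) != 1:
            raise ValueError(f"expected exactly one TDI column, got {cols}")
        return cols[0]

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), dict(self.roles))

    # -- persistence: CSV table + JSON role manifest ---------------------

    def to_csv(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>.csv`` (empty cell = missing) and ``<prefix>.roles.json``."""
        prefix = Path(prefix)
        csv_path = prefix.with_suffix(".csv")
        manifest_path = prefix.with_suffix(".roles.json")
        self.data.to_csv(csv_path, index=True, index_label="subject_id")
        manifest_path.write_text(json.dumps(self.roles, indent=2))
        return csv_path, manifest_path

    @classmethod
    def from_csv(cls, prefix: str | Path) -> "CohortTable":
        prefix = Path(prefix)
        data = pd.read_csv(prefix.with_suffix(".csv"), index_col="subject_id")
        roles = json.loads(prefix.with_suffix(".roles.json").read_text())
        return cls(data, roles)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the structure of the motivating cohort: n = 163
    subjects, the printed TDI mixture (means 24.9 / 34.32, sds 3.42 / 3.2,
    weights 0.167 / 0.83), a unimodal integer risk score, and a metabolomics
    panel with two latent clusters tied to the risk score.  The olfaction ↔
    risk association is OFF by default (the null configuration).
    """

    n: int = 163
    seed: int = 0
    tdi_means: tuple[float, float] = (24.9, 34.32)
    tdi_sds: tuple[float, float] = (3.42, 3.2)
    tdi_weights: tuple[float, float] = (0.167, 0.83)
    risk_mean: float = 11.5
    risk_sd: float = 4.0
    risk_max: int = 26
    cluster_shift: float = 2.5  # SD units between the two latent clusters
    risk_metabolome_slope: float = 0.35  # SD of metabolite per SD of risk score
    olfaction_association: bool = False
    olfaction_effect: float = 0.5  # |corr| scale of the implanted TDI→risk link
    age_identification_effect: float = 0.8  # identification points lost per age SD
    within_block_corr: float = 0.3
    n_missing: int = 6
    n_outliers: int = 12
    outlier_magnitude: float = 8.0  # SD multiples

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        w = np.asarray(self.tdi_weights, dtype=float)
        # printed weights may be rounded (0.167 + 0.83 = 0.997): allow slack,
        # the sampler renormalizes
        if w.min() < 0 or abs(w.sum() - 1.0) > 0.01:
            raise ValueError("mixture weights must be non-negative and sum to ~1")
        if min(self.tdi_sds) <= 0 or self.risk_sd <= 0:
            raise ValueError("standard deviations must be positive")
        n_cells = self.n * len(_METABOLOMIC_SPEC)
        if self.n > 0 and self.n_missing + self.n_outliers >= n_cells:
            raise ValueError("n_missing + n_outliers must be < n * n_columns")
        if self.n_missing < 0 or self.n_outliers < 0:
            raise ValueError("injection counts must be non-negative")


@dataclass
class CohortTruth:
    """Latent ground truth emitted alongside a generated cohort (oracle sidecar)."""

    mode_label: np.ndarray  # 0 = lower TDI mode, 1 = upper
    cluster_label: np.ndarray  # 0/1 latent metabolomic cluster
    outlier_cells: list[tuple[str, str]]  # (subject_id, column)
    missing_cells: list[tuple[str, str]]


@dataclass
class CategoryMap:
    """Clinical categorization of the two primary scores.

    ``risk_bins`` maps ordered, gap-free integer score intervals to a risk
    label and the associated 10-year diabetes risk in percent; ``tdi_cuts``
    are the two olfactory-category boundaries (anosmia below the first,
    normosmia above the second).
    """

    risk_bins: list[tuple[float, float, str, float]] = field(
        default_factory=lambda: [
            (-0.5, 6.5, "low risk", 1.0),
            (6.5, 11.5, "slightly increased", 4.0),
            (11.5, 14.5, "medium risk", 17.0),
            (14.5, 20.5, "high risk", 33.0),
            (20.5, np.inf, "very high", 50.0),
        ]
    )
    tdi_cuts: tuple[float, float] = (16.5, 30.5)
    tdi_labels: tuple[str, str, str] = ("anosmia", "hyposmia", "normosmia")

    def validate(self) -> None:
        los = [b[0] for b in self.risk_bins]
        his = [b[1] for b in self.risk_bins]
        if any(hi <= lo for lo, hi in zip(los, his)):
            raise ValueError("risk bins must be non-empty intervals")
        if any(abs(his[i] - los[i + 1]) > 1e-12 for i in range(len(his) - 1)):
            raise ValueError("risk bins must partition the range without gap/overlap")
        risks = [b[3] for b in self.risk_bins]
        if any(b <= a for a, b in zip(risks, risks[1:])):
            raise ValueError("risk percentages must be strictly increasing")
        if not self.tdi_cuts[0] < self.tdi_cuts[1]:
            raise ValueError("TDI cuts must be increasing")


# ---------------------------------------------------------------------------
# Score categorizers
# ---------------------------------------------------------------------------


def categorize_risk(
    score: float, category_map: CategoryMap | None = None
) -> tuple[str, float]:
    """Map an integer FINDRISK score to its (label, 10-year risk %) category."""
    cmap = category_map or CategoryMap()
    cmap.validate()
    if score < 0:
        raise ValueError(f"risk score must be non-negative, got {score}")
    for lo, hi, label, pct in cmap.risk_bins:
        if lo < score <= hi or (np.isinf(hi) and score > lo):
            return label, pct
    raise ValueError(f"score {score} not covered by the category map")


def categorize_tdi(tdi: float, category_map: CategoryMap | None = None) -> str:
    """Map a TDI sum score to {anosmia, hyposmia, normosmia}."""
    cmap = category_map or CategoryMap()
    cmap.validate()
    if not (1.0 <= tdi <= 48.0):
        raise ValueError(f"TDI must lie in [1, 48], got {tdi}")
    lo, hi = cmap.tdi_cuts
    if tdi < lo:
        return cmap.tdi_labels[0]
    if tdi <= hi:
        return cmap.tdi_labels[1]
    return cmap.tdi_labels[2]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def sample_tdi_mixture(
    n: int,
    rng: np.random.Generator,
    means: Sequence[float] = (24.9, 34.32),
    sds: Sequence[float] = (3.42, 3.2),
    weights: Sequence[float] = (0.167, 0.83),
) -> tuple[np.ndarray, np.ndarray]:
    """Draw continuous TDI values from the two-mode Gaussian mixture.

    Returns ``(values, component)`` with components indexed in ascending order
    of mean.  Used directly by mode-recovery experiments; :func:`generate_cohort`
    post-processes the draws into instrument-granular subtests.
    """
    order = np.argsort(means)
    means = np.asarray(means, float)[order]
    sds = np.asarray(sds, float)[order]
    weights = np.asarray(weights, float)[order]
    comp = rng.choice(len(means), size=n, p=weights / weights.sum())
    values = rng.normal(means[comp], sds[comp])
    return values, comp


def _block_correlated_noise(
    rng: np.random.Generator, n: int, sizes: Sequence[int], rho: float
) -> np.ndarray:
    """Standard-normal margins with equicorrelation ``rho`` inside each block."""
    cols = []
    for size in sizes:
        shared = rng.normal(size=(n, 1))
        own = rng.normal(size=(n, size))
        cols.append(np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own)
    return np.concatenate(cols, axis=1)


def generate_cohort(config: GeneratorConfig) -> tuple[CohortTable, CohortTruth]:
    """Generate a synthetic cohort plus its latent-truth sidecar.

    The generation order matters: TDI mixture → subtests (with the age →
    identification link) → risk score (optionally coupled to TDI) → correlated
    demographics → metabolomics (cluster shift + risk slope) → outlier
    injection → missingness injection.  Everything is driven by one
    ``numpy.random.Generator`` seeded from ``config.seed``, so a fixed config
    yields a bit-identical cohort.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    # --- olfaction: mixture draw, then instrument-granular decomposition ---
    tdi_raw, mode_label = sample_tdi_mixture(
        n, rng, config.tdi_means, config.tdi_sds, config.tdi_weights
    )
    tdi_raw = np.clip(tdi_raw, 1.0, 48.0)

    # demographics (age first: it feeds identification)
    age_z = rng.normal(size=n)
    # T/D/I decomposition: Dirichlet proportions centred on (0.25, 0.375, 0.375)
    centre = np.array([0.25, 0.375, 0.375])
    props = rng.dirichlet(centre * 150.0, size=max(n, 1))[:n]
    thr = np.round(props[:, 0] * tdi_raw * 4.0) / 4.0  # threshold: 0.25 steps
    disc = np.round(props[:, 1] * tdi_raw)
    ident = np.round(
        props[:, 2] * tdi_raw - config.age_identification_effect * age_z
    )
    thr = np.clip(thr, 1.0, 16.0)
    disc = np.clip(disc, 0.0, 16.0)
    ident = np.clip(ident, 0.0, 16.0)
    tdi = thr + disc + ident  # identity holds by construction

    # --- risk score -----------------------------------------------------
    tdi_z = (tdi_raw - np.mean(config.tdi_means)) / 5.0
    e = config.olfaction_effect if config.olfaction_association else 0.0
    risk_noise = rng.normal(size=n)
    risk_latent = -e * tdi_z + np.sqrt(max(1.0 - e**2, 0.0)) * risk_noise
    risk_raw = config.risk_mean + config.risk_sd * risk_latent
    risk = np.clip(np.round(risk_raw), 0, config.risk_max).astype(int)
    risk_z = (risk_raw - config.risk_mean) / config.risk_sd

    # --- demographics correlated with risk ------------------------------
    age = 52.9 + 12.7 * (0.45 * risk_z + np.sqrt(1 - 0.45**2) * age_z)
    age = np.clip(np.round(age), 18, 69).astype(int)
    bmi = 27.0 + 4.5 * (0.4 * risk_z + np.sqrt(1 - 0.4**2) * rng.normal(size=n))
    bmi = np.clip(np.round(bmi, 1), 17.0, 48.0)
    sex = rng.integers(0, 2, size=n)
    smoker = (rng.random(size=n) < 0.25).astype(int)
    antihypertensives = (rng.random(size=n) < 0.2 + 0.1 * (risk_z > 0)).astype(int)

    # --- metabolomics ----------------------------------------------------
    cluster_label = rng.integers(0, 2, size=n)
    names = [s[0] for s in _METABOLOMIC_SPEC]
    signs = np.array([s[4] for s in _METABOLOMIC_SPEC])
    n_baseline = sum(1 for s in _METABOLOMIC_SPEC if s[1] == ROLE_METABOLOMIC_BASELINE)
    z = _block_correlated_noise(
        rng, n, [n_baseline, len(names) - n_baseline], config.within_block_corr
    )
    shift_mask = np.array([nm in _CLUSTER_SHIFT_VARS for nm in names], float)
    z = (
        z
        + signs * shift_mask * config.cluster_shift * (cluster_label[:, None] - 0.5)
        + signs * config.risk_metabolome_slope * risk_z[:, None]
    )
    metab = {
        nm: spec[2] + spec[3] * z[:, j]
        for j, (nm, spec) in enumerate(zip(names, _METABOLOMIC_SPEC))
    }

    subject_id = [f"S{i + 1:04d}" for i in range(n)]
    data = pd.DataFrame(
        {
            "threshold": thr,
            "discrimination": disc,
            "identification": ident,
            "tdi": tdi,
            "findrisk": risk,
            "age": age,
            "bmi": bmi,
            "sex": sex,
            "smoker": smoker,
            "antihypertensives": antihypertensives,
            **metab,
        },
        index=pd.Index(subject_id, name="subject_id"),
    )
    roles = {
        "threshold": ROLE_OLFACTORY_SUBTEST,
        "discrimination": ROLE_OLFACTORY_SUBTEST,
        "identification": ROLE_OLFACTORY_SUBTEST,
        "tdi": ROLE_OLFACTORY_TOTAL,
        "findrisk": ROLE_RISK_SCORE,
        "age": ROLE_DEMOGRAPHIC,
        "bmi": ROLE_DEMOGRAPHIC,
        "sex": ROLE_DEMOGRAPHIC,
        "smoker": ROLE_CONFOUNDER,
        "antihypertensives": ROLE_CONFOUNDER,
        **{nm: spec[1] for nm, spec in zip(names, _METABOLOMIC_SPEC)},
    }

    # --- outliers then missingness, into metabolomic columns only --------
    outlier_cells: list[tuple[str, str]] = []
    missing_cells: list[tuple[str, str]] = []
    if n > 0 and (config.n_outliers or config.n_missing):
        metab_cols = names
        delta_cols = [
            nm for nm, spec in zip(names, _METABOLOMIC_SPEC)
            if spec[1] == ROLE_METABOLOMIC_DELTA
        ]
        # outliers can hit any metabolomic column; missingness mimics skipped
        # post-challenge measurements, so it targets the delta columns
        out_pool = [(i, c) for i in range(n) for c in metab_cols]
        out_idx = rng.choice(len(out_pool), size=min(config.n_outliers, len(out_pool)),
                             replace=False)
        chosen_out = [out_pool[i] for i in out_idx]
        for i, col in chosen_out:
            mu, sd = data[col].mean(), data[col].std(ddof=1)
            direction = 1.0 if rng.random() < 0.5 else -1.0
            z_out = config.outlier_magnitude * (1.0 + 0.5 * rng.random())
            data.iloc[i, data.columns.get_loc(col)] = mu + direction * z_out * sd
            outlier_cells.append((subject_id[i], col))
        miss_pool = [
            (i, c) for i in range(n) for c in delta_cols
            if (subject_id[i], c) not in set(outlier_cells)
        ]
        miss_idx = rng.choice(len(miss_pool), size=min(config.n_missing, len(miss_pool)),
                              replace=False)
        for i, col in (miss_pool[j] for j in miss_idx):
            data.iloc[i, data.columns.get_loc(col)] = np.nan
            missing_cells.append((subject_id[i], col))

    table = CohortTable(data, roles)
    truth = CohortTruth(
        mode_label=mode_label,
        cluster_label=cluster_label,
        outlier_cells=outlier_cells,
        missing_cells=missing_cells,
    )
    return table, truth
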