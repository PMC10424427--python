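"""LASSO-logistic classification with nested cross-validation.

The discovery pipeline fitted on every training set is::

    CFR  →  [feature-group selection]  →  z-score  →  L1 logistic regression

Two modes are supported.  ``proposed`` uses hierarchical CFR and treats the
candidate feature group as a tuning parameter alongside the regularisation
strength λ; ``conventional`` uses standard CFR, fixes the group to ``all``
and tunes λ only.  Hyperparameters are tuned by an inner stratified k-fold
grid search scored by AUROC; generalisation performance is the mean outer
test-fold AUROC over ``outer_folds × outer_repeats`` splits, and statistical
significance against AUROC = 0.5 comes from permuting the labels and
re-running the entire nested procedure.

The penalized objective is ``(1/n)·Σ logloss + λ·‖β‖₁`` with an unpenalized
intercept, fitted on z-scored features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, KFold

from .features.extract import FeatureTable
from .features.registry import FeatureKey
from .selection import (
    CandidateGroupSet,
    CfrConfig,
    GroupHierarchy,
    enumerate_candidate_groups,
    hierarchical_cfr,
    standard_cfr,
)

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-3, 1, 20))

_SEED_MOD = 2**31 - 1


# ---------------------------------------------------------------------------
# Targets


def binarize_target(values, rule="median", positive_label=None) -> np.ndarray:
    """Binarize a per-lesion target variable.

    ``median`` — positive iff value > cohort median (continuous targets);
    ``stage`` — positive iff ordinal stage is 3 or 4;
    ``one_vs_all`` — positive iff value equals ``positive_label``.
    """
    v = np.asarray(values)
    if len(np.unique(v)) < 2:
        raise ValueError("target is constant")
    if rule == "median":
        v = v.astype(float)
        return (v > np.median(v)).astype(int)
    if rule == "stage":
        return np.isin(v.astype(int), (3, 4)).astype(int)
    if rule == "one_vs_all":
        if positive_label is None:
            raise ValueError("one_vs_all requires positive_label")
        return (v == positive_label).astype(int)
    raise ValueError(f"unknown binarization rule: {rule}")


# ---------------------------------------------------------------------------
# Standardization


@dataclass
class Standardization:
    mean: np.ndarray
    sd: np.ndarray
    kept_cols: np.ndarray  # indices of non-constant training columns

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (x[:, self.kept_cols] - self.mean) / self.sd


def zscore_fit(train: np.ndarray) -> Standardization:
    """Per-column (mean, sd) from training rows; zero-sd columns are dropped."""
    if train.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    kept = np.flatnonzero(sd > 0)
    if kept.size == 0:
        raise ValueError("all feature columns are constant on the training data")
    if kept.size < train.shape[1]:
        warnings.warn(
            f"dropped {train.shape[1] - kept.size} constant columns before z-scoring",
            stacklevel=2,
        )
    return Standardization(mean[kept], sd[kept], kept)


def zscore_fit_apply(
    train: np.ndarray, apply_rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray, Standardization]:
    """Standardize with training statistics only (no leakage into test rows)."""
    std = zscore_fit(train)
    return std.apply(train), std.apply(apply_rows), std


# ---------------------------------------------------------------------------
# LASSO-logistic


def fit_lr_lasso(
    x: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-8
) -> tuple[np.ndarray, float]:
    """Minimize (1/n)·Σ logloss + λ‖β‖₁ (intercept unpenalized).

    Returns ``(coefficients, intercept)``.  Solved with liblinear using
    ``C = 1/(n·λ)``, which is the same objective up to a positive factor;
    liblinear's intercept is handled as a scaled bias column, so a large
    ``intercept_scaling`` leaves it penalized only with weight 1e-3 — the
    coefficients agree with an exactly-unpenalized-intercept solver to ~1e-4
    on standardized inputs.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n = x.shape[0]
    clf = LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / (n * lam),
        solver="liblinear",
        tol=tol,
        max_iter=5000,
        fit_intercept=True,
        intercept_scaling=1000.0,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(x, y)
    return clf.coef_.ravel().copy(), float(clf.intercept_[0])


def _predict_proba(x: np.ndarray, coef: np.ndarray, intercept: float) -> np.ndarray:
    z = x @ coef + intercept
    return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# Configuration and results


@dataclass
class CvConfig:
    outer_folds: int = 5
    outer_repeats: int = 100
    inner_folds: int = 3
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    seed: int = 0
    stratified: bool = True
    cfr: CfrConfig | None = None  # None → CFR skipped (pre-reduced tables)
    hierarchy: GroupHierarchy = field(default_factory=GroupHierarchy)

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if len(self.lambda_grid) == 0:
            raise ValueError("lambda_grid must be non-empty")


@dataclass
class FitResult:
    selected_group: str
    lam: float
    coefficients: dict[FeatureKey, float]  # nonzero entries only
    intercept: float
    standardization: Standardization
    feature_keys: list[FeatureKey]  # columns the model was fitted on

    def predict_proba_table(self, table: FeatureTable) -> np.ndarray:
        x = table.subset(self.feature_keys).values
        coef = np.array(
            [self.coefficients.get(k, 0.0) for k in
             (self.feature_keys[i] for i in self.standardization.kept_cols)]
        )
        return _predict_proba(self.standardization.apply(x), coef, self.intercept)

    @property
    def n_nonzero(self) -> int:
        return len(self.coefficients)


@dataclass
class ValidationResult:
    per_split_auroc: list[float]
    per_split_fit: list[FitResult]
    config: CvConfig
    mode: str

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.per_split_auroc))


@dataclass
class PermutationResult:
    observed_mean_auroc: float
    null_aurocs: list[float]

    @property
    def p_value(self) -> float:
        null = np.asarray(self.null_aurocs)
        return float((1 + (null >= self.observed_mean_auroc).sum()) / (1 + null.size))


# ---------------------------------------------------------------------------
# Pipeline internals (numpy core for speed)


def _splitter(n_splits: int, stratified: bool, seed: int):
    cls = StratifiedKFold if stratified else KFold
    return cls(n_splits=n_splits, shuffle=True, random_state=seed % _SEED_MOD)


def _run_cfr(table: FeatureTable, config: CvConfig, mode: str) -> list[FeatureKey]:
    if config.cfr is None:
        return table.keys()
    if mode == "proposed":
        kept, _ = hierarchical_cfr(table, config.cfr, config.hierarchy)
    else:
        kept, _ = standard_cfr(table, config.cfr)
    return kept


def _group_columns(
    keys: list[FeatureKey], mode: str
) -> tuple[dict[str, np.ndarray], CandidateGroupSet | None]:
    if mode == "conventional":
        return {"all": np.arange(len(keys))}, None
    group_set = enumerate_candidate_groups(keys)
    index = {k: i for i, k in enumerate(keys)}
    cols = {
        name: np.array([index[k] for k in members])
        for name, members in group_set.groups.items()
    }
    return cols, group_set


def tune_inner(
    x: np.ndarray,
    y: np.ndarray,
    group_cols: dict[str, np.ndarray],
    lambda_grid,
    inner_folds: int,
    seed: int,
    stratified: bool = True,
) -> tuple[str, float]:
    """Grid search over (feature group, λ) by mean inner-fold AUROC.

    Exact score ties prefer the smaller group, then the larger λ (sparser,
    more interpretable models win ties).
    """
    folds = list(_splitter(inner_folds, stratified, seed).split(x, y))
    best = None
    for name, cols in group_cols.items():
        xg = x[:, cols]
        for lam in lambda_grid:
            scores = []
            for tr, te in folds:
                xtr, xte, _ = zscore_fit_apply(xg[tr], xg[te])
                coef, b0 = fit_lr_lasso(xtr, y[tr], lam)
                scores.append(roc_auc_score(y[te], _predict_proba(xte, coef, b0)))
            key = (float(np.mean(scores)), -len(cols), float(lam))
            if best is None or key > best[0]:
                best = (key, name, float(lam))
    return best[1], best[2]


def _fit_on(
    table_train: FeatureTable,
    y_train: np.ndarray,
    config: CvConfig,
    mode: str,
    tuning_seed: int,
) -> FitResult:
    """CFR → tune (group, λ) → z-score → LASSO fit, all on training rows."""
    kept = _run_cfr(table_train, config, mode)
    reduced = table_train.subset(kept)
    x = reduced.values
    group_cols, _ = _group_columns(kept, mode)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        group, lam = tune_inner(
            x, y_train, group_cols, config.lambda_grid, config.inner_folds,
            tuning_seed, config.stratified,
        )
        cols = group_cols[group]
        feature_keys = [kept[i] for i in cols]
        std = zscore_fit(x[:, cols])
        coef, b0 = fit_lr_lasso(std.apply(x[:, cols]), y_train, lam)
    nz = {
        feature_keys[std.kept_cols[j]]: float(c)
        for j, c in enumerate(coef)
        if c != 0.0
    }
    return FitResult(group, lam, nz, b0, std, feature_keys)


def nested_cv_evaluate(
    table: FeatureTable,
    y,
    config: CvConfig,
    mode: str = "proposed",
) -> ValidationResult:
    """Repeated stratified nested CV of the full discovery pipeline.

    Every training-side step (CFR, group/λ tuning, standardization, fitting)
    sees outer-training rows only; each outer-test fold contributes one AUROC
    and one fitted model, giving ``outer_folds × outer_repeats`` results.
    """
    if mode not in {"proposed", "conventional"}:
        raise ValueError(f"unknown mode: {mode}")
    y = np.asarray(y)
    if len(table) != len(y):
        raise ValueError("table and labels differ in length")
    aurocs: list[float] = []
    fits: list[FitResult] = []
    ids = np.array(table.lesion_ids)
    for r in range(config.outer_repeats):
        split_seed = (config.seed + r) % _SEED_MOD
        for f, (tr, te) in enumerate(
            _splitter(config.outer_folds, config.stratified, split_seed).split(ids, y)
        ):
            t_train = table.subset_rows(ids[tr])
            tuning_seed = (config.seed * 9973 + r * config.outer_folds + f) % _SEED_MOD
            fit = _fit_on(t_train, y[tr], config, mode, tuning_seed)
            proba = fit.predict_proba_table(table.subset_rows(ids[te]))
            aurocs.append(float(roc_auc_score(y[te], proba)))
            fits.append(fit)
    return ValidationResult(aurocs, fits, config, mode)


def permutation_test(
    table: FeatureTable,
    y,
    config: CvConfig,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "proposed",
    observed: ValidationResult | None = None,
) -> PermutationResult:
    """Permutation test of the entire nested-CV procedure (H0: AUROC = 0.5).

    Each permutation shuffles the labels and re-runs the whole nested CV; the
    one-sided p-value is ``(1 + #{null ≥ observed}) / (1 + n_perm)``.  The
    permutation stream is drawn from ``seed`` independently of the fold
    stream inside the nested CV.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    y = np.asarray(y)
    if observed is None:
        observed = nested_cv_evaluate(table, y, config, mode)
    rng = np.random.default_rng(seed)
    null = [
        nested_cv_evaluate(table, rng.permutation(y), config, mode).mean_auroc
        for _ in range(n_perm)
    ]
    return PermutationResult(observed.mean_auroc, null)


def fit_final_model(
    table: FeatureTable,
    y,
    config: CvConfig,
    mode: str = "proposed",
) -> FitResult:
    """Tune on all data via the inner CV, then fit once on all data."""
    y = np.asarray(y)
    return _fit_on(table, y, config, mode, tuning_seed=config.seed % _SEED_MOD)
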