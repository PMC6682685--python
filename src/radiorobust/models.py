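"""Patient-grouped classification experiments.

The modeling protocol mirrors a small-cohort radiogenomic study: patients
are split 80/20 into train/test with label stratification, repeated 10
times; features are reduced either by recursive feature elimination (RFE,
with grouped cross-validation choosing the feature count) or by PCA
retaining 95% cumulative variance; random-forest and logistic-regression
classifiers are tuned by grouped 5-fold cross-validation maximizing AUROC.
All fitting — standardization, reduction, hyperparameters — sees training
patients only; every patient id touched during fit is recorded so leakage
is auditable.

Samples are slices (the oversampled design), grouped by patient; a
per-patient aggregation of predicted scores is available as a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFECV
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedGroupKFold,
    StratifiedKFold,
)
from sklearn.preprocessing import StandardScaler

import logging

log = logging.getLogger(__name__)

from .robustness import feature_columns


def _max_folds(y: np.ndarray, groups: Sequence[str]) -> int:
    """Largest fold count such that every validation fold can contain both
    classes: the minority class's patient-group count."""
    df = pd.DataFrame({"y": np.asarray(y), "g": np.asarray(groups)})
    per_class = df.groupby("y")["g"].nunique()
    return int(per_class.min())


def _grouped_cv(y: np.ndarray, groups: Sequence[str], n_folds: int, seed: int):
    """Patient-grouped stratified CV splitter, reduced to the feasible fold
    count.  When the minority class has a single patient group, grouped CV
    cannot produce two-class folds; an ungrouped stratified split is used
    instead (logged)."""
    feasible = _max_folds(y, groups)
    if feasible >= 2:
        folds = min(n_folds, feasible)
        return StratifiedGroupKFold(
            n_splits=folds, shuffle=True, random_state=seed
        ), True
    log.warning(
        "minority class has a single patient group; falling back to "
        "ungrouped stratified CV"
    )
    folds = min(n_folds, int(np.bincount(np.asarray(y)).min()), 5)
    return StratifiedKFold(
        n_splits=max(2, folds), shuffle=True, random_state=seed
    ), False

RF_GRID: Dict[str, list] = {
    "n_estimators": [200, 650, 1100, 1550, 2000],
    "max_depth": [10, 40, 70, 100],
    "min_samples_split": [2, 5, 10],
    "min_samples_leaf": [1, 2, 4],
}
# l1_ratio 1.0 is an L1 penalty, 0.0 an L2 penalty
LR_GRID: Dict[str, list] = {
    "l1_ratio": [1.0, 0.0],
    "C": list(np.logspace(-3, 5, 9)),
}

#: reduced grids for desk-scale runs (same ranges, coarser steps)
RF_GRID_SMALL: Dict[str, list] = {
    "n_estimators": [200],
    "max_depth": [10, 100],
    "min_samples_split": [2],
    "min_samples_leaf": [1],
}
LR_GRID_SMALL: Dict[str, list] = {
    "l1_ratio": [1.0, 0.0],
    "C": [0.01, 1.0, 100.0],
}


@dataclass
class SplitPlan:
    """Repeated stratified patient-wise train/test splits."""

    repetitions: List[Tuple[List[str], List[str]]]
    test_frac: float = 0.2

    def validate(self) -> None:
        for train, test in self.repetitions:
            if set(train) & set(test):
                raise ValueError("train/test patient overlap")


@dataclass
class EvalResult:
    """Per-repetition metrics plus their mean/SD aggregate."""

    per_rep: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["auroc", "sensitivity", "specificity", "accuracy"]
        )
    )
    fit_patients: List[List[str]] = field(default_factory=list)

    def aggregate(self) -> Dict[str, float]:
        agg = {}
        for c in ("auroc", "sensitivity", "specificity", "accuracy"):
            agg[f"{c}_mean"] = float(self.per_rep[c].mean())
            agg[f"{c}_sd"] = float(self.per_rep[c].std(ddof=1))
        return agg


def patient_splits(
    patient_labels: pd.Series,
    n_rep: int = 10,
    test_frac: float = 0.2,
    seed: int = 0,
) -> SplitPlan:
    """Stratified patient-wise splits: each repetition holds out
    ``test_frac`` of the patients of each class (at least one)."""
    rng = np.random.default_rng(seed)
    classes = patient_labels.unique()
    for c in classes:
        if (patient_labels == c).sum() < 2:
            raise ValueError(f"class {c} has fewer than 2 patients")
    reps = []
    for _ in range(n_rep):
        train: List[str] = []
        test: List[str] = []
        for c in classes:
            ids = list(patient_labels.index[patient_labels == c])
            rng.shuffle(ids)
            n_test = max(1, int(round(test_frac * len(ids))))
            n_test = min(n_test, len(ids) - 1)
            test.extend(ids[:n_test])
            train.extend(ids[n_test:])
        reps.append((sorted(train), sorted(test)))
    plan = SplitPlan(repetitions=reps, test_frac=test_frac)
    plan.validate()
    return plan


def _default_rfe_estimator(seed: int):
    return LogisticRegression(
        C=1.0, solver="liblinear", random_state=seed, max_iter=2000,
    )


def rfe_select(
    x: pd.DataFrame,
    y: np.ndarray,
    groups: Sequence[str],
    estimator=None,
    n_folds: int = 10,
    step: float = 0.1,
    seed: int = 0,
) -> List[str]:
    """Recursive feature elimination with grouped cross-validation.

    The optimal feature count is chosen by grouped ``n_folds``-fold CV
    AUROC (folds reduced to the number of patient groups if necessary);
    returns the selected feature names.
    """
    if x.shape[1] < 2:
        return list(x.columns)
    cv, grouped = _grouped_cv(y, groups, n_folds, seed)
    est = estimator if estimator is not None else _default_rfe_estimator(seed)
    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)
    rfecv = RFECV(
        estimator=clone(est),
        step=step,
        cv=cv,
        scoring="roc_auc",
        min_features_to_select=1,
    )
    rfecv.fit(xs, y, groups=np.asarray(groups) if grouped else None)
    return [c for c, s in zip(x.columns, rfecv.support_) if s]


def pca_reduce(x_train: pd.DataFrame, var_cutoff: float = 0.95):
    """Standardize + PCA keeping the smallest component count reaching
    ``var_cutoff`` cumulative explained variance (fitted on train only).

    Returns ``(transform_fn, n_components)``.
    """
    if np.allclose(x_train.to_numpy().var(axis=0), 0):
        raise ValueError("zero-variance input")
    scaler = StandardScaler().fit(x_train)
    xs = scaler.transform(x_train)
    pca = PCA(n_components=var_cutoff, svd_solver="full").fit(xs)

    def transform(x: pd.DataFrame) -> np.ndarray:
        return pca.transform(scaler.transform(x))

    return transform, int(pca.n_components_)


def fit_classifier(
    kind: str,
    x: np.ndarray,
    y: np.ndarray,
    groups: Sequence[str],
    param_grid: Optional[Dict] = None,
    n_folds: int = 5,
    seed: int = 0,
):
    """Tune and fit a random forest or logistic regression.

    Hyperparameters are selected by grouped ``n_folds``-fold CV maximizing
    AUROC over the given grid (defaults: tree counts 200-2000 and depths
    10-100 for RF; L1/L2 penalty with strengths 1e-3..1e5 for LR), then the
    best configuration is refitted on the full training data.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite features")
    if kind == "rf":
        base = RandomForestClassifier(random_state=seed, n_jobs=1)
        grid = RF_GRID if param_grid is None else param_grid
    elif kind == "lr":
        base = LogisticRegression(
            solver="liblinear", random_state=seed, max_iter=2000
        )
        grid = LR_GRID if param_grid is None else param_grid
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    y = np.asarray(y)
    if np.bincount(y).min() < 2:
        # too few samples in a class for any cross-validation: fit the
        # first grid configuration directly
        log.warning("class with <2 samples; skipping hyperparameter search")
        base.set_params(**{k: v[0] for k, v in grid.items()})
        return base.fit(x, y)
    cv, grouped = _grouped_cv(y, groups, n_folds, seed)
    search = GridSearchCV(
        base, grid, scoring="roc_auc",
        cv=cv,
        refit=True, n_jobs=1,
    )
    search.fit(x, y, groups=np.asarray(groups) if grouped else None)
    return search.best_estimator_


def evaluate(model, x_test: np.ndarray, y_test: np.ndarray) -> Dict[str, float]:
    """AUROC (rank-based, midrank ties) plus sensitivity/specificity/
    accuracy at predicted-probability threshold 0.5."""
    y_test = np.asarray(y_test)
    if len(np.unique(y_test)) < 2:
        raise ValueError("test set contains a single class")
    scores = model.predict_proba(np.asarray(x_test, dtype=float))[:, 1]
    pred = (scores >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y_test == 1)))
    fn = int(np.sum((pred == 0) & (y_test == 1)))
    tn = int(np.sum((pred == 0) & (y_test == 0)))
    fp = int(np.sum((pred == 1) & (y_test == 0)))
    return {
        "auroc": float(roc_auc_score(y_test, scores)),
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "accuracy": (tp + tn) / len(y_test),
    }


def _combine(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Join feature tables on (patient_id, slice_index), prefixing
    duplicate feature names with the table index."""
    base = tables[0].copy()
    for i, t in enumerate(tables[1:], start=1):
        feats = feature_columns(t)
        renames = {
            f: f"set{i}.{f}" for f in feats if f in base.columns
        }
        t = t.rename(columns=renames)
        base = base.merge(
            t[["patient_id", "slice_index"] + [renames.get(f, f) for f in feats]],
            on=["patient_id", "slice_index"],
            how="inner",
        )
    return base


def run_experiment(
    features,
    reduction: str,
    kind: str,
    plan: SplitPlan,
    param_grid: Optional[Dict] = None,
    rfe_folds: int = 10,
    cv_folds: int = 5,
    seed: int = 0,
    aggregate_patients: bool = False,
) -> EvalResult:
    """Full repeated-split experiment for one feature set x reduction x model.

    ``features`` is a slice-level feature table (or list of tables to
    combine) with ``patient_id``, ``slice_index``, ``label`` columns.
    Metrics are slice-level unless ``aggregate_patients`` averages
    predicted scores per patient before evaluation.
    """
    if reduction not in ("rfe", "pca", "none"):
        raise ValueError(f"unknown reduction {reduction!r}")
    if isinstance(features, (list, tuple)):
        table = _combine(list(features))
    else:
        table = features
    feats = feature_columns(table)
    result = EvalResult()
    rows = []
    for rep, (train_ids, test_ids) in enumerate(plan.repetitions):
        tr = table[table.patient_id.isin(train_ids)]
        te = table[table.patient_id.isin(test_ids)]
        y_tr = tr["label"].to_numpy()
        y_te = te["label"].to_numpy()
        groups = tr["patient_id"].to_numpy()
        x_tr_df, x_te_df = tr[feats], te[feats]
        # drop features constant on train (undefined under standardization)
        keep = [f for f in feats if x_tr_df[f].nunique() > 1]
        x_tr_df, x_te_df = x_tr_df[keep], x_te_df[keep]
        rep_seed = (seed * 1009 + rep) % (2**31)
        if reduction == "rfe":
            sel = rfe_select(
                x_tr_df, y_tr, groups, n_folds=rfe_folds, seed=rep_seed
            )
            scaler = StandardScaler().fit(x_tr_df[sel])
            x_tr = scaler.transform(x_tr_df[sel])
            x_te = scaler.transform(x_te_df[sel])
        elif reduction == "pca":
            transform, _ = pca_reduce(x_tr_df)
            x_tr = transform(x_tr_df)
            x_te = transform(x_te_df)
        else:
            scaler = StandardScaler().fit(x_tr_df)
            x_tr = scaler.transform(x_tr_df)
            x_te = scaler.transform(x_te_df)
        model = fit_classifier(
            kind, x_tr, y_tr, groups, param_grid=param_grid,
            n_folds=cv_folds, seed=rep_seed,
        )
        if aggregate_patients:
            scores = model.predict_proba(x_te)[:, 1]
            df = pd.DataFrame(
                {"pid": te["patient_id"], "score": scores, "y": y_te}
            ).groupby("pid").agg(score=("score", "mean"), y=("y", "first"))
            metrics = _metrics_from_scores(
                df["score"].to_numpy(), df["y"].to_numpy()
            )
        else:
            metrics = evaluate(model, x_te, y_te)
        rows.append(metrics)
        result.fit_patients.append(sorted(set(groups)))
    result.per_rep = pd.DataFrame(rows)
    return result


def _metrics_from_scores(scores: np.ndarray, y: np.ndarray) -> Dict[str, float]:
    if len(np.unique(y)) < 2:
        raise ValueError("test set contains a single class")
    pred = (scores >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    return {
        "auroc": float(roc_auc_score(y, scores)),
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "accuracy": (tp + tn) / len(y),
    }


def run_clinical(
    label_table: pd.DataFrame,
    kind: str,
    plan: SplitPlan,
    param_grid: Optional[Dict] = None,
    seed: int = 0,
) -> EvalResult:
    """Clinical-covariates-only model (age, sex, KPS), one sample per
    patient."""
    t = label_table.copy()
    t["sex_num"] = (t["sex"] == "M").astype(float)
    feats = ["age", "sex_num", "kps"]
    result = EvalResult()
    rows = []
    for rep, (train_ids, test_ids) in enumerate(plan.repetitions):
        tr = t[t.patient_id.isin(train_ids)]
        te = t[t.patient_id.isin(test_ids)]
        scaler = StandardScaler().fit(tr[feats])
        model = fit_classifier(
            kind,
            scaler.transform(tr[feats]),
            tr["label"].to_numpy(),
            tr["patient_id"].to_numpy(),
            param_grid=param_grid,
            seed=(seed * 1009 + rep) % (2**31),
        )
        rows.append(
            evaluate(model, scaler.transform(te[feats]), te["label"].to_numpy())
        )
        result.fit_patients.append(sorted(tr["patient_id"]))
    result.per_rep = pd.DataFrame(rows)
    return result


def run_factorial(
    feature_sets: Dict[str, pd.DataFrame],
    plan: SplitPlan,
    label_table: Optional[pd.DataFrame] = None,
    param_grids: Optional[Dict[str, Dict]] = None,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Factorial runner over feature sets x {rfe, pca} x {rf, lr}, plus a
    combined set and an optional clinical per-patient model; emits one
    results row per configuration with mean/SD AUROC across repetitions.
    """
    param_grids = param_grids or {}
    combos = dict(feature_sets)
    if len(feature_sets) > 1:
        combos["Combined"] = list(feature_sets.values())
    rows = []
    for name, feats in combos.items():
        for reduction in ("rfe", "pca"):
            for kind in ("rf", "lr"):
                res = run_experiment(
                    feats, reduction, kind, plan,
                    param_grid=param_grids.get(kind), seed=seed, **kwargs,
                )
                agg = res.aggregate()
                rows.append(
                    {
                        "feature_set": name,
                        "reduction": reduction,
                        "model": kind,
                        "auroc_mean": agg["auroc_mean"],
                        "auroc_sd": agg["auroc_sd"],
                        "sensitivity": agg["sensitivity_mean"],
                        "specificity": agg["specificity_mean"],
                        "accuracy": agg["accuracy_mean"],
                    }
                )
    if label_table is not None:
        for kind in ("rf", "lr"):
            res = run_clinical(
                label_table, kind, plan,
                param_grid=param_grids.get(kind), seed=seed,
            )
            agg = res.aggregate()
            rows.append(
                {
                    "feature_set": "Clinical per patient",
                    "reduction": "none",
                    "model": kind,
                    "auroc_mean": agg["auroc_mean"],
                    "auroc_sd": agg["auroc_sd"],
                    "sensitivity": agg["sensitivity_mean"],
                    "specificity": agg["specificity_mean"],
                    "accuracy": agg["accuracy_mean"],
                }
            )
    return pd.DataFrame(rows)
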