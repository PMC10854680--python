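"""Repeated patient-wise evaluation of SVM and SVM+ models.

Protocol: in each of ``n_iterations`` repetitions the cohort is split
patient-wise (no patient shared between sets) into 80% train / 20% test,
with a further 20% of the train patients reserved as a validation set; an
exhaustive grid over the box constraint C and the Gaussian kernel scale is
ranked by validation AUROC; the winning model is refit on train+validation
and scored on the held-out test set.  F1, sensitivity and specificity use
the sign of the decision score; AUROC and AUPRC use the raw scores.  Means
and standard deviations over iterations are reported per privileged-
information type ("none" = plain SVM; TS-ECG, SF-ECG or EHR = SVM+).

Features are z-scored with train-fold statistics before the Gaussian
kernel (mixed-unit features otherwise collapse the kernel); hyperparameters
never see the test fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .exceptions import EvaluationError, InputError, ParameterError
from .pipeline import PI_TYPES, REGULAR_SPACES, FeaturizedCohort
from .svmplus import SvmPlusHyperparams, fit_svm_baseline, fit_svmplus

__all__ = [
    "METRIC_NAMES",
    "SplitPlan",
    "GridSpace",
    "Metrics",
    "MetricsReport",
    "patient_wise_split",
    "grid_search",
    "compute_metrics",
    "run_experiment",
]

METRIC_NAMES = ("f1", "sensitivity", "specificity", "auroc", "auprc")


@dataclass(frozen=True)
class SplitPlan:
    """Patient-wise repeated-split settings."""

    test_fraction: float = 0.20
    validation_fraction_of_train: float = 0.20
    n_iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1 or not 0 < self.validation_fraction_of_train < 1:
            raise ParameterError("split fractions must be in (0, 1)")
        if self.n_iterations < 1:
            raise ParameterError("n_iterations must be >= 1")


@dataclass(frozen=True)
class GridSpace:
    """Hyperparameter grid: C values and kernel-scale multipliers of sqrt(d)."""

    box_constraints: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    scale_multipliers: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)

    def __post_init__(self) -> None:
        if not self.box_constraints or not self.scale_multipliers:
            raise ParameterError("grid must be non-empty")
        if min(self.box_constraints) <= 0 or min(self.scale_multipliers) <= 0:
            raise ParameterError("grid values must be positive")

    def scales(self, n_features: int) -> tuple[float, ...]:
        root_d = float(np.sqrt(n_features))
        return tuple(m * root_d for m in self.scale_multipliers)


def patient_wise_split(
    patient_ids: Sequence[str] | np.ndarray,
    plan: SplitPlan,
    iteration_seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index arrays (train, validation, test), disjoint at the patient level.

    All instances of one patient land in the same set.  Fractions apply to
    patients (to the nearest patient); with 100 single-instance patients the
    sets hold 64 / 16 / 20 patients.
    """
    ids = np.asarray(patient_ids)
    unique = np.unique(ids)
    if unique.size < 3:
        raise InputError("patient-wise splitting needs at least 3 distinct patients")
    rng = np.random.default_rng(iteration_seed)
    order = rng.permutation(unique)
    n_test = max(int(round(plan.test_fraction * unique.size)), 1)
    n_rest = unique.size - n_test
    n_val = max(int(round(plan.validation_fraction_of_train * n_rest)), 1)
    if n_rest - n_val < 1:
        raise InputError("too few patients for a non-empty training set")
    test_patients = set(order[:n_test])
    val_patients = set(order[n_test : n_test + n_val])
    test_idx = np.flatnonzero([p in test_patients for p in ids])
    val_idx = np.flatnonzero([p in val_patients for p in ids])
    train_idx = np.flatnonzero(
        [(p not in test_patients) and (p not in val_patients) for p in ids]
    )
    return train_idx, val_idx, test_idx


@dataclass(frozen=True)
class Metrics:
    """Threshold metrics at score 0 plus ranking metrics on raw scores."""

    f1: float
    sensitivity: float
    specificity: float
    auroc: float
    auprc: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.0
) -> Metrics:
    """F1/sensitivity/specificity by sign thresholding, AUROC/AUPRC by rank.

    The positive class is the qSOFA increase (+1).  AUROC uses the
    trapezoidal tie-averaged rank statistic; AUPRC uses step-interpolated
    precision (average precision).  Single-class label vectors make the
    ranking metrics undefined and raise an error.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    if scores.size != labels.size:
        raise InputError("scores and labels must be the same length")
    if np.unique(labels).size < 2:
        raise EvaluationError("AUROC/AUPRC undefined for single-class labels")
    pred = np.where(scores >= threshold, 1, -1)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == -1)))
    fn = int(np.sum((pred == -1) & (labels == 1)))
    tn = int(np.sum((pred == -1) & (labels == -1)))
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return Metrics(
        f1=f1,
        sensitivity=sensitivity,
        specificity=specificity,
        auroc=float(roc_auc_score(labels, scores)),
        auprc=float(average_precision_score(labels, scores)),
    )


class _Standardizer:
    """Column z-scoring with train statistics (constant columns untouched)."""

    def __init__(self, X: np.ndarray) -> None:
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self.sd = sd

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def _fit_and_score(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xte: np.ndarray,
    C: float,
    scale: float,
    Xstar_tr: np.ndarray | None,
    gamma: float,
    nu: float,
    privileged_scale: float | None,
) -> np.ndarray:
    if Xstar_tr is None:
        model = fit_svm_baseline(Xtr, ytr, C=C, scale=scale)
        return model.decision_function(Xte)
    hp = SvmPlusHyperparams(
        C=C,
        gamma=gamma,
        nu=nu,
        regular_scale=scale,
        privileged_scale=privileged_scale if privileged_scale else 1.0,
    )
    model = fit_svmplus(Xtr, Xstar_tr, ytr, hp)
    return model.decision_function(Xte)


def grid_search(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xval: np.ndarray,
    yval: np.ndarray,
    grid: GridSpace,
    Xstar_tr: np.ndarray | None = None,
    gamma: float = 1.0,
    nu: float = 0.5,
    privileged_scale: float | None = None,
) -> tuple[float, float, float]:
    """Exhaustive grid over (C, scale); argmax of validation AUROC.

    Ties break deterministically toward smaller C, then smaller scale
    (candidates are visited in that order and only a strictly greater AUROC
    replaces the incumbent).  Returns (best_C, best_scale, best_auroc).
    """
    best: tuple[float, float, float] | None = None
    n_failures = 0
    for C in sorted(grid.box_constraints):
        for scale in sorted(grid.scales(Xtr.shape[1])):
            try:
                scores = _fit_and_score(
                    Xtr, ytr, Xval, C, scale, Xstar_tr, gamma, nu, privileged_scale
                )
                auroc = float(roc_auc_score(yval, scores))
            except Exception:
                n_failures += 1
                continue
            if best is None or auroc > best[2]:
                best = (C, scale, auroc)
    if best is None:
        raise EvaluationError(f"all {n_failures} grid candidates failed")
    return best


@dataclass
class MetricsReport:
    """Per-iteration metrics and their mean/std summary, keyed by PI type."""

    regular_space: str
    records: pd.DataFrame  # long format: iteration, pi_type, metric, value

    def summary(self) -> pd.DataFrame:
        """Numeric mean and std per (pi_type, metric)."""
        g = self.records.groupby(["pi_type", "metric"])["value"]
        out = g.agg(["mean", "std"]).reset_index()
        out["std"] = out["std"].fillna(0.0)
        return out

    def table(self) -> pd.DataFrame:
        """One row per PI type, cells formatted 'mean (std)'."""
        s = self.summary()
        s["cell"] = s.apply(lambda r: f"{r['mean']:.2f} ({r['std']:.2f})", axis=1)
        wide = s.pivot(index="pi_type", columns="metric", values="cell")
        order = [p for p in PI_TYPES if p in wide.index]
        cols = [m for m in METRIC_NAMES if m in wide.columns]
        return wide.loc[order, cols]

    def mean(self, pi_type: str, metric: str) -> float:
        s = self.summary()
        row = s[(s.pi_type == pi_type) & (s.metric == metric)]
        if row.empty:
            raise KeyError((pi_type, metric))
        return float(row["mean"].iloc[0])

    def to_csv(self, records_path, table_path=None) -> None:
        self.records.to_csv(records_path, index=False)
        if table_path is not None:
            self.table().to_csv(table_path)


def run_experiment(
    features: FeaturizedCohort,
    regular_space: str = "ecg",
    pi_types: Sequence[str] = PI_TYPES,
    plan: SplitPlan | None = None,
    grid: GridSpace | None = None,
    gamma: float = 1.0,
    nu: float = 0.5,
    progress: bool = False,
) -> MetricsReport:
    """The full repeated-holdout comparison for one regular-space choice.

    For every iteration: patient-wise split, per-PI-type grid search on
    validation AUROC, refit on train+validation, metrics on test.  A failing
    iteration aborts the run (skipping folds would bias the means).
    """
    if regular_space not in REGULAR_SPACES:
        raise InputError(f"regular_space must be one of {REGULAR_SPACES}")
    for pi_type in pi_types:
        if pi_type not in PI_TYPES:
            raise InputError(f"unknown PI type {pi_type!r}")
    plan = plan or SplitPlan()
    grid = grid or GridSpace()
    X_all = features.regular(regular_space)
    seeds = np.random.SeedSequence(plan.seed).generate_state(plan.n_iterations) & 0x7FFFFFFF
    rows: list[dict] = []
    for it in range(plan.n_iterations):
        train_idx, val_idx, test_idx = patient_wise_split(
            features.patient_ids, plan, int(seeds[it])
        )
        fit_idx = np.concatenate([train_idx, val_idx])
        for check_name, idx in (("train", train_idx), ("validation", val_idx), ("test", test_idx)):
            if np.unique(features.y[idx]).size < 2:
                raise EvaluationError(
                    f"iteration {it}: single-class {check_name} set; "
                    "cohort too small or too imbalanced for this plan"
                )
        for pi_type in pi_types:
            try:
                rows.extend(
                    _one_iteration(
                        features, X_all, train_idx, val_idx, test_idx, fit_idx,
                        pi_type, grid, gamma, nu, it,
                    )
                )
            except Exception as exc:  # abort with context, never skip
                raise EvaluationError(
                    f"iteration {it}, PI type {pi_type!r} failed: {exc}"
                ) from exc
        if progress:
            import sys

            print(f"iteration {it + 1}/{plan.n_iterations} done", file=sys.stderr)
    return MetricsReport(regular_space=regular_space, records=pd.DataFrame(rows))


def _one_iteration(
    features: FeaturizedCohort,
    X_all: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    test_idx: np.ndarray,
    fit_idx: np.ndarray,
    pi_type: str,
    grid: GridSpace,
    gamma: float,
    nu: float,
    iteration: int,
) -> list[dict]:
    y = features.y
    Xstar_all = features.privileged(pi_type)

    # hyperparameter selection: train fold only, scored on validation
    zs = _Standardizer(X_all[train_idx])
    Xtr, Xval = zs(X_all[train_idx]), zs(X_all[val_idx])
    Xstar_tr = priv_scale = None
    if Xstar_all is not None:
        zs_p = _Standardizer(Xstar_all[train_idx])
        Xstar_tr = zs_p(Xstar_all[train_idx])
        priv_scale = float(np.sqrt(Xstar_tr.shape[1]))
    C, scale, _ = grid_search(
        Xtr, y[train_idx], Xval, y[val_idx], grid,
        Xstar_tr=Xstar_tr, gamma=gamma, nu=nu, privileged_scale=priv_scale,
    )

    # final fit on train+validation, scored on the held-out test set
    zs = _Standardizer(X_all[fit_idx])
    Xfit, Xte = zs(X_all[fit_idx]), zs(X_all[test_idx])
    Xstar_fit = None
    if Xstar_all is not None:
        zs_p = _Standardizer(Xstar_all[fit_idx])
        Xstar_fit = zs_p(Xstar_all[fit_idx])
    scores = _fit_and_score(
        Xfit, y[fit_idx], Xte, C, scale, Xstar_fit, gamma, nu, priv_scale
    )
    metrics = compute_metrics(scores, y[test_idx])
    return [
        {"iteration": iteration, "pi_type": pi_type, "metric": name, "value": value}
        for name, value in metrics.as_dict().items()
    ]
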