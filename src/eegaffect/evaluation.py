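"""Train/test machinery, ensemble-tree regression, metrics, and the three
evaluation protocols: top-N inclusion curves, incremental learning over
subjects, and leave-one-subject-out cross-validation.

The regressor is a 100-tree random forest with the squared-error split
criterion; splits are at segment-row level (each 1-s segment is one sample,
carrying its parent trial's label).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import (explained_variance_score, mean_absolute_error,
                             mean_squared_error, r2_score)
from sklearn.model_selection import train_test_split

from .core import LabelVector, Montage, default_montage
from .features import SPECS, FeatureMatrix
from .selection import ScoreTable

__all__ = [
    "MetricsReport", "CurvePoint", "split_train_test", "fit_predict_forest",
    "compute_metrics", "top_n_curve", "incremental_learning", "loso_cv",
]


@dataclass
class MetricsReport:
    """RMSE / R^2 / MAE / explained variance for one train/test evaluation."""

    rmse: float
    r2: float
    mae: float
    ev: float
    n_test: int

    def to_dict(self) -> dict:
        return {"rmse": self.rmse, "r2": self.r2, "mae": self.mae,
                "ev": self.ev, "n_test": self.n_test}


def _labels(y) -> np.ndarray:
    return y.values if isinstance(y, LabelVector) else np.asarray(y, dtype=float)


def compute_metrics(y_true, y_pred) -> MetricsReport:
    """RMSE (root mean squared residual), R^2 (variance explained about the
    mean), MAE, and explained variance (R^2 without the systematic-offset
    term); EV equals R^2 whenever the mean residual is zero."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need equal-length vectors with at least 2 entries")
    if np.var(y_true) == 0:
        raise ValueError("R^2/EV undefined for a constant target")
    return MetricsReport(
        rmse=float(np.sqrt(mean_squared_error(y_true, y_pred))),
        r2=float(r2_score(y_true, y_pred)),
        mae=float(mean_absolute_error(y_true, y_pred)),
        ev=float(explained_variance_score(y_true, y_pred)),
        n_test=int(y_true.size),
    )


def split_train_test(X: np.ndarray, y, test_fraction: float = 0.2,
                     seed: int | None = 0):
    """Shuffled segment-row split into disjoint, exhaustive train/test parts."""
    X = np.asarray(X, dtype=float)
    yv = _labels(y)
    if X.shape[0] < 5:
        raise ValueError("need at least 5 rows to split")
    idx_tr, idx_te = train_test_split(np.arange(X.shape[0]),
                                      test_size=test_fraction,
                                      random_state=seed, shuffle=True)
    return (X[idx_tr], yv[idx_tr]), (X[idx_te], yv[idx_te])


def fit_predict_forest(X_train, y_train, X_test, n_trees: int = 100,
                       seed: int | None = 0) -> np.ndarray:
    """Fit the 100-tree squared-error random forest and predict test rows."""
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    for name, arr in (("train", X_train), ("test", X_test)):
        if not np.isfinite(arr).all():
            bad = np.flatnonzero(~np.isfinite(arr).all(axis=0))
            raise ValueError(f"non-finite values in {name} columns {bad.tolist()}")
    model = RandomForestRegressor(n_estimators=n_trees,
                                  criterion="squared_error",
                                  random_state=seed)
    model.fit(X_train, np.asarray(y_train, dtype=float))
    return model.predict(X_test)


def _evaluate_matrix(X, yv, test_fraction, n_trees, seed) -> MetricsReport:
    (Xtr, ytr), (Xte, yte) = split_train_test(X, yv, test_fraction, seed)
    pred = fit_predict_forest(Xtr, ytr, Xte, n_trees=n_trees, seed=seed)
    return compute_metrics(yte, pred)


@dataclass
class CurvePoint:
    """One point of a top-N inclusion curve."""

    n_included: int
    metrics: MetricsReport


def top_n_curve(rankings: ScoreTable, fm: FeatureMatrix, y,
                mode: str = "electrode", seed: int | None = 0,
                n_trees: int = 100,
                montage: Montage | None = None) -> list[CurvePoint]:
    """Evaluate the regressor on the top-N ranked electrodes or features for
    N = 1..max.

    Electrode mode drops asymmetry-pair columns first (they belong to two
    electrodes); feature mode accumulates whole feature-code blocks in rank
    order.
    """
    yv = _labels(y)
    points = []
    names = rankings.names_by_rank
    for n in range(1, len(names) + 1):
        chosen = set(names[:n])
        if mode == "electrode":
            idx = [i for i, (loc, code) in enumerate(fm.column_meta)
                   if not SPECS[code].per_pair and loc in chosen]
        elif mode == "feature":
            idx = [i for i, (_, code) in enumerate(fm.column_meta)
                   if code in chosen]
        else:
            raise ValueError("mode must be 'electrode' or 'feature'")
        sub = fm.select_columns(idx)
        points.append(CurvePoint(n, _evaluate_matrix(sub.values, yv, 0.2,
                                                     n_trees, seed)))
    return points


def _subject_groups(fm: FeatureMatrix):
    order, rows = [], {}
    for i, (subj, _, _) in enumerate(fm.row_meta):
        if subj not in rows:
            order.append(subj)
            rows[subj] = []
        rows[subj].append(i)
    return order, rows


def incremental_learning(fm: FeatureMatrix, y, seed: int | None = 0,
                         n_trees: int = 100) -> list[MetricsReport]:
    """Grow the training pool one subject at a time (input order); at each
    step shuffle the pooled rows, split 80:20, fit, and report test metrics.
    """
    yv = _labels(y)
    order, rows = _subject_groups(fm)
    if len(order) < 2:
        raise ValueError("incremental learning needs at least 2 subjects")
    reports = []
    pooled: list[int] = []
    for subj in order:
        if len(rows[subj]) < 2:
            raise ValueError(f"subject {subj!r} has fewer than 2 rows")
        pooled.extend(rows[subj])
        idx = np.asarray(pooled)
        reports.append(_evaluate_matrix(fm.values[idx], yv[idx], 0.2,
                                        n_trees, seed))
    return reports


def loso_cv(fm: FeatureMatrix, y, seed: int | None = 0, n_trees: int = 100):
    """Leave-one-subject-out cross-validation.

    One fold per subject: train on every other subject's segments, test on
    the held-out subject.  Returns per-subject reports plus the (mean, SD)
    of fold RMSEs.
    """
    yv = _labels(y)
    order, rows = _subject_groups(fm)
    if len(order) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    reports: dict[object, MetricsReport] = {}
    for subj in order:
        test_idx = np.asarray(rows[subj])
        train_idx = np.asarray([i for s in order if s != subj
                                for i in rows[s]])
        pred = fit_predict_forest(fm.values[train_idx], yv[train_idx],
                                  fm.values[test_idx], n_trees=n_trees,
                                  seed=seed)
        reports[subj] = compute_metrics(yv[test_idx], pred)
    rmses = np.array([r.rmse for r in reports.values()])
    return reports, (float(rmses.mean()), float(rmses.std()))
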