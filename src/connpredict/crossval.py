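"""Leakage-safe cross-validated prediction.

Implements the evaluation protocol around the regression engine: features
are min-max scaled *inside* each fold (parameters estimated on the
training rows only, then applied unchanged to the test rows), the model is
fit on the training rows and applied to the held-out rows, and accuracy is
summarised as the Pearson correlation between observed and predicted
scores, the partial correlation controlling for nuisance covariates, and
the mean absolute error on the raw score scale.

Two schemes are provided: leave-one-out (deterministic) and repeated
k-fold with near-equal fold sizes, where the partition RNG for repeat
``b`` is seeded by ``(seed, b)`` and the reported metrics are the mean of
the per-repeat metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from . import rvr

__all__ = [
    "CVResult",
    "minmax_scale_fold",
    "run_loocv",
    "run_repeated_kfold",
    "prediction_accuracy",
    "encode_covariates",
]


@dataclass
class CVResult:
    """Out-of-sample predictions with fold bookkeeping and metrics."""

    observed: np.ndarray
    predicted: np.ndarray
    fold_assignment: np.ndarray  # (n,) for LOOCV, (repeats, n) for k-fold
    metrics: dict
    covariates_used: list
    scheme: str
    seed: int | None = None
    per_repeat_metrics: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "seed": self.seed,
            "covariates_used": list(self.covariates_used),
            "metrics": {k: float(v) for k, v in self.metrics.items()},
            "per_repeat_metrics": [
                {k: float(v) for k, v in m.items()} for m in self.per_repeat_metrics],
            "observed": self.observed.tolist(),
            "predicted": self.predicted.tolist(),
            "fold_assignment": self.fold_assignment.tolist(),
        }


def minmax_scale_fold(train, test):
    """Scale each feature to [0, 1] on the training rows; apply the same
    affine map to the test rows (which may therefore fall outside [0, 1]).

    A feature with zero training range carries no information and is
    mapped to 0 in both sets.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.ndim != 2 or test.ndim != 2 or train.shape[1] != test.shape[1]:
        raise ValueError("train/test must be 2-D with equal feature dimension")
    lo = train.min(axis=0)
    rng = train.max(axis=0) - lo
    safe = np.where(rng > 0.0, rng, 1.0)
    train_s = (train - lo) / safe
    test_s = (test - lo) / safe
    dead = rng == 0.0
    if dead.any():
        train_s[:, dead] = 0.0
        test_s[:, dead] = 0.0
    return train_s, test_s


def encode_covariates(phenotypes: pd.DataFrame, covariates) -> np.ndarray:
    """Build a numeric covariate matrix from phenotype columns.

    Binary sex codes {M, F, 0, 1} map to 0/1; other categoricals are
    one-hot encoded with the first level dropped.  Returns an (n, q) array
    (q = 0 when no covariates are requested).
    """
    covariates = list(covariates or [])
    n = len(phenotypes)
    cols = []
    for name in covariates:
        if name not in phenotypes.columns:
            raise KeyError(f"covariate column '{name}' missing from phenotype table")
        col = phenotypes[name]
        if col.isna().any():
            raise ValueError(f"covariate column '{name}' contains missing values")
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
        else:
            vals = col.astype(str).str.upper()
            uniq = sorted(vals.unique())
            if set(uniq) <= {"M", "F"} or set(uniq) <= {"0", "1"}:
                key = "F" if "F" in set(uniq) else "1"
                cols.append((vals == key).to_numpy(dtype=float))
            else:
                for level in uniq[1:]:  # first level dropped
                    cols.append((vals == level).to_numpy(dtype=float))
    if not cols:
        return np.empty((n, 0))
    return np.column_stack(cols)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def prediction_accuracy(observed, predicted, covariate_matrix=None) -> dict:
    """Accuracy metrics: ``r``, covariate-controlled ``partial_r``, ``mae``.

    ``partial_r`` is the Pearson correlation of the residuals of observed
    and predicted after each is regressed on [1, covariates]; ``mae`` is
    computed on the raw (unresidualised) scores.
    """
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    n = observed.size
    Z = np.empty((n, 0)) if covariate_matrix is None else \
        np.asarray(covariate_matrix, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] != n:
        raise ValueError("covariate matrix row count does not match scores")
    if n - Z.shape[1] < 3:
        raise ValueError("fewer than 3 effective subjects after covariate adjustment")
    r = _pearson(observed, predicted)
    if Z.shape[1] == 0:
        partial_r = r
    else:
        D = np.column_stack([np.ones(n), Z])
        coef_o, *_ = np.linalg.lstsq(D, observed, rcond=None)
        coef_p, *_ = np.linalg.lstsq(D, predicted, rcond=None)
        partial_r = _pearson(observed - D @ coef_o, predicted - D @ coef_p)
    mae = float(np.mean(np.abs(observed - predicted)))
    return {"r": r, "partial_r": partial_r, "mae": mae}


def prepare_folds(features: np.ndarray, fold_indices):
    """Per-fold scaled feature blocks; scaling never sees the test rows.

    Returns a list of ``(train_idx, test_idx, train_scaled, test_scaled)``.
    Shared between the observed CV run and permutation re-runs: the
    scaling parameters depend only on the features, so permuting the score
    vector leaves them unchanged.
    """
    folds = []
    for train_idx, test_idx in fold_indices:
        tr, te = minmax_scale_fold(features[train_idx], features[test_idx])
        folds.append((train_idx, test_idx, tr, te))
    return folds


def fit_fold(features: np.ndarray, y: np.ndarray, train_idx, test_idx,
             engine_kwargs=None):
    """Scale on the training rows, fit, and return (model, test predictions)."""
    tr, te = minmax_scale_fold(features[train_idx], features[test_idx])
    model = rvr.fit_rvr(tr, y[train_idx], **(engine_kwargs or {}))
    return model, rvr.predict(model, te)


def _run_prepared(folds, y: np.ndarray, engine_kwargs=None) -> np.ndarray:
    predicted = np.full(y.shape[0], np.nan)
    for train_idx, test_idx, tr, te in folds:
        try:
            model = rvr.fit_rvr(tr, y[train_idx], **(engine_kwargs or {}))
        except Exception as err:
            raise RuntimeError(
                f"engine failure in fold testing subjects {list(test_idx)}: {err}"
            ) from err
        predicted[test_idx] = rvr.predict(model, te)
    return predicted

def loocv_fold_indices(n: int):
    return [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]


def kfold_indices(n: int, k: int, seed: int, repeat: int):
    """Random partition into k near-equal folds; the first ``n mod k``
    folds get the extra subject.  RNG is seeded by (seed, repeat)."""
    if k > n:
        raise ValueError(f"k={k} exceeds the number of subjects n={n}")
    state = int(np.random.SeedSequence([seed, repeat]).generate_state(1)[0] % (2**31))
    kf = KFold(n_splits=k, shuffle=True, random_state=state)
    return [(tr, te) for tr, te in kf.split(np.arange(n))]


def _extract_y(phenotypes, score_column="psqi"):
    if isinstance(phenotypes, pd.DataFrame):
        return phenotypes[score_column].to_numpy(dtype=float)
    return np.asarray(phenotypes, dtype=float).ravel()


def run_loocv(features, phenotypes, covariates=None, engine_kwargs=None,
              score_column: str = "psqi") -> CVResult:
    """Leave-one-out cross-validated prediction.

    Each subject is predicted by a model trained (with per-fold scaling)
    on the other n-1 subjects.  Deterministic: no randomness enters the
    fold layout.
    """
    X = np.asarray(features, dtype=float)
    y = _extract_y(phenotypes, score_column)
    n = X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if y.shape[0] != n:
        raise ValueError("feature matrix and phenotypes disagree on n")
    Z = encode_covariates(phenotypes, covariates) \
        if isinstance(phenotypes, pd.DataFrame) else np.empty((n, 0))
    folds = prepare_folds(X, loocv_fold_indices(n))
    predicted = _run_prepared(folds, y, engine_kwargs)
    metrics = prediction_accuracy(y, predicted, Z)
    return CVResult(observed=y, predicted=predicted,
                    fold_assignment=np.arange(n), metrics=metrics,
                    covariates_used=list(covariates or []), scheme="loocv")


def run_repeated_kfold(features, phenotypes, covariates=None, k: int = 10,
                       repeats: int = 20, seed: int = 0, engine_kwargs=None,
                       score_column: str = "psqi") -> CVResult:
    """Repeated k-fold cross-validation; metrics averaged over repeats."""
    X = np.asarray(features, dtype=float)
    y = _extract_y(phenotypes, score_column)
    n = X.shape[0]
    if y.shape[0] != n:
        raise ValueError("feature matrix and phenotypes disagree on n")
    Z = encode_covariates(phenotypes, covariates) \
        if isinstance(phenotypes, pd.DataFrame) else np.empty((n, 0))
    assignment = np.empty((repeats, n), dtype=int)
    per_repeat = []
    last_predicted = None
    for b in range(repeats):
        idx = kfold_indices(n, k, seed, b)
        for f, (_, te) in enumerate(idx):
            assignment[b, te] = f
        folds = prepare_folds(X, idx)
        predicted = _run_prepared(folds, y, engine_kwargs)
        per_repeat.append(prediction_accuracy(y, predicted, Z))
        last_predicted = predicted
    metrics = {key: float(np.mean([m[key] for m in per_repeat]))
               for key in per_repeat[0]}
    return CVResult(observed=y, predicted=last_predicted,
                    fold_assignment=assignment, metrics=metrics,
                    covariates_used=list(covariates or []),
                    scheme=f"kfold(k={k}, repeats={repeats})", seed=seed,
                    per_repeat_metrics=per_repeat)
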