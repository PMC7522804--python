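"""Permutation-based significance of prediction accuracy.

The null hypothesis is that the connectome features carry no information
about the score.  The observed accuracy (correlation ``r`` and MAE between
predicted and observed scores) is compared with a null distribution built
by shuffling the score vector without replacement and re-running the FULL
cross-validation pipeline — per-fold scaling and model refits included —
once per permutation.  Covariates are never permuted.

P-values are proportions of the null that beat the observed value:
higher-or-equal for ``r``, lower-or-equal for MAE (ties counted as
exceeding, the conservative direction).  The literal proportion can be 0;
an optional smoothed rule ``(b + 1) / (n_perm + 1)`` is available because
the literal rule understates uncertainty at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crossval import (encode_covariates, kfold_indices, loocv_fold_indices,
                       prediction_accuracy, prepare_folds, _extract_y,
                       _run_prepared, run_loocv, run_repeated_kfold)

__all__ = ["PermutationResult", "permutation_test"]


@dataclass
class PermutationResult:
    """Observed metrics, permutation null distributions and p-values."""

    observed_r: float
    observed_partial_r: float
    observed_mae: float
    null_r: np.ndarray
    null_partial_r: np.ndarray
    null_mae: np.ndarray
    n_perm: int
    seed: int
    scheme: str
    smoothed: bool = False
    failed: int = 0
    covariates_used: list = field(default_factory=list)

    def _prop(self, count: int) -> float:
        # denominator is the realised null size (equals n_perm when no
        # permutation run failed)
        n_valid = int(self.null_r.size)
        if self.smoothed:
            return (count + 1) / (n_valid + 1)
        return count / n_valid

    @property
    def p_r(self) -> float:
        return self._prop(int(np.sum(self.null_r >= self.observed_r)))

    @property
    def p_partial_r(self) -> float:
        return self._prop(int(np.sum(self.null_partial_r >= self.observed_partial_r)))

    @property
    def p_mae(self) -> float:
        return self._prop(int(np.sum(self.null_mae <= self.observed_mae)))

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "seed": self.seed,
            "n_perm": self.n_perm,
            "failed": self.failed,
            "smoothed": self.smoothed,
            "covariates_used": list(self.covariates_used),
            "observed": {"r": self.observed_r, "partial_r": self.observed_partial_r,
                         "mae": self.observed_mae},
            "p_values": {"p_r": self.p_r, "p_partial_r": self.p_partial_r,
                         "p_mae": self.p_mae},
            "null_r": self.null_r.tolist(),
            "null_partial_r": self.null_partial_r.tolist(),
            "null_mae": self.null_mae.tolist(),
        }


def permutation_test(features, phenotypes, covariates=None, scheme: str = "loocv",
                     k: int = 10, repeats: int = 20, n_perm: int = 1000,
                     seed: int = 0, engine_kwargs=None, smoothed: bool = False,
                     score_column: str = "psqi") -> PermutationResult:
    """Permutation test of cross-validated prediction accuracy.

    Permutation ``b`` shuffles the score vector once globally (RNG seeded
    by ``(seed, b)``) and applies the shuffled scores consistently across
    all folds — and, for repeated k-fold, across all repeats, whose fold
    layouts are identical to the observed run.  Fold scaling depends only
    on the features and is computed once.

    A failing permutation run is recorded, excluded from the null and
    counted in ``failed``; more than 1% failures aborts.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(features, dtype=float)
    y = _extract_y(phenotypes, score_column)
    n = X.shape[0]
    import pandas as pd
    Z = encode_covariates(phenotypes, covariates) \
        if isinstance(phenotypes, pd.DataFrame) else np.empty((n, 0))

    if scheme == "loocv":
        observed = run_loocv(X if not isinstance(phenotypes, pd.DataFrame) else X,
                             phenotypes, covariates, engine_kwargs,
                             score_column=score_column)
        layouts = [prepare_folds(X, loocv_fold_indices(n))]
        scheme_desc = "loocv"
    elif scheme == "kfold":
        observed = run_repeated_kfold(X, phenotypes, covariates, k=k,
                                      repeats=repeats, seed=seed,
                                      engine_kwargs=engine_kwargs,
                                      score_column=score_column)
        layouts = [prepare_folds(X, kfold_indices(n, k, seed, b))
                   for b in range(repeats)]
        scheme_desc = f"kfold(k={k}, repeats={repeats})"
    else:
        raise ValueError(f"unknown scheme '{scheme}'")

    null_r, null_pr, null_mae = [], [], []
    failed = 0
    for b in range(n_perm):
        rng = np.random.default_rng([seed, b])
        y_perm = y[rng.permutation(n)]
        try:
            per_layout = []
            for folds in layouts:
                pred = _run_prepared(folds, y_perm, engine_kwargs)
                per_layout.append(prediction_accuracy(y_perm, pred, Z))
            null_r.append(float(np.mean([m["r"] for m in per_layout])))
            null_pr.append(float(np.mean([m["partial_r"] for m in per_layout])))
            null_mae.append(float(np.mean([m["mae"] for m in per_layout])))
        except Exception:
            failed += 1
            if failed > max(1, 0.01 * n_perm):
                raise RuntimeError(
                    f"more than 1% of permutation runs failed ({failed}/{b + 1})")
    return PermutationResult(
        observed_r=observed.metrics["r"],
        observed_partial_r=observed.metrics["partial_r"],
        observed_mae=observed.metrics["mae"],
        null_r=np.asarray(null_r), null_partial_r=np.asarray(null_pr),
        null_mae=np.asarray(null_mae),
        n_perm=n_perm, seed=seed, scheme=scheme_desc, smoothed=smoothed,
        failed=failed, covariates_used=list(covariates or []))
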