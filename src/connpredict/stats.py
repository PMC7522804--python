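"""Supporting statistics: partial correlation and FDR screening.

Partial correlation between two variables controlling for an arbitrary
covariate set is computed by residualising both on [1, covariates] with
least squares and correlating the residuals; the p-value comes from the
t-transform with ``n - 2 - q`` degrees of freedom (q covariates).
Benjamini-Hochberg FDR (via statsmodels) corrects region-wise screens for
multiple comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PartialCorrelationResult",
    "partial_correlation",
    "fdr_bh",
    "strength_covariate_screen",
]


@dataclass
class PartialCorrelationResult:
    r: float
    p: float
    n: int
    covariates: list


def _residualize(v: np.ndarray, D: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(D, v, rcond=None)
    return v - D @ coef


def partial_correlation(x, y, covariates=None,
                        covariate_names=None) -> PartialCorrelationResult:
    """Partial Pearson correlation of ``x`` and ``y`` given covariates.

    With no covariates this reduces exactly to the plain Pearson
    correlation and its textbook p-value.  Degenerate inputs (a residual
    with zero variance, e.g. when ``y`` is itself a covariate) raise
    ``ValueError`` rather than returning NaN.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    Z = np.empty((n, 0)) if covariates is None else np.asarray(covariates, float)
    if Z.ndim == 1:
        Z = Z[:, None]
    q = Z.shape[1]
    if n < q + 3:
        raise ValueError(f"need at least q+3={q + 3} observations, got {n}")
    if q:
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), Z]))
        if rank < q + 1:
            names = covariate_names or list(range(q))
            raise ValueError(
                f"rank-deficient covariate matrix (columns {list(names)}: "
                f"rank {rank - 1} < {q})")
    D = np.column_stack([np.ones(n), Z])
    rx = _residualize(x, D)
    ry = _residualize(y, D)
    if np.allclose(rx, 0.0) or np.allclose(ry, 0.0):
        raise ValueError(
            "degenerate partial correlation: a variable is fully explained "
            "by the covariates")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - q
    r_ = min(max(r, -1.0), 1.0)
    if abs(r_) == 1.0:
        p = 0.0
    else:
        t = r_ * np.sqrt(df / (1.0 - r_ * r_))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return PartialCorrelationResult(r=r, p=max(p, np.finfo(float).tiny), n=n,
                                    covariates=list(covariate_names or []))


def fdr_bh(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up over a family of p-values.

    Returns ``(reject mask, adjusted p-values)``; both empty for empty
    input.  The rejection set is invariant to input ordering.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def strength_covariate_screen(strengths, phenotypes: pd.DataFrame, target: str,
                              controls, regions=None, q: float = 0.05,
                              region_ids=None) -> pd.DataFrame:
    """Per-region partial correlation between nodal strength and a
    phenotype, FDR-corrected across the supplied regions.

    ``strengths`` is a subjects x regions matrix; ``regions`` (indices
    into its columns, typically the top-50 contributing regions) limits
    the screen.  ``target`` is the phenotype of interest (e.g. age,
    daytime sleepiness, head motion) and ``controls`` the covariates to
    partial out.
    """
    from .crossval import encode_covariates

    S = np.asarray(strengths, dtype=float)
    if target not in phenotypes.columns:
        raise KeyError(f"phenotype column '{target}' missing")
    tvec = phenotypes[target].to_numpy(dtype=float)
    Z = encode_covariates(phenotypes, controls)
    cols = np.arange(S.shape[1]) if regions is None else np.asarray(regions, int)
    ids = list(cols) if region_ids is None else [region_ids[c] for c in cols]
    rows = []
    for c, rid in zip(cols, ids):
        res = partial_correlation(S[:, c], tvec, Z, covariate_names=list(controls))
        rows.append({"region_id": rid, "r": res.r, "p": res.p})
    out = pd.DataFrame(rows)
    reject, p_adj = fdr_bh(out["p"].to_numpy(), q=q)
    out["p_adj"] = p_adj
    out["significant"] = reject
    return out
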