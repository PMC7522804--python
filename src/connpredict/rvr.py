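"""Relevance vector regression (sparse Bayesian linear-kernel regression).

The model predicts a continuous score ``y`` from a feature vector ``x``
through a linear kernel expansion over the training samples,

    f(x) = sum_s beta_s (x . x_s) + beta_0,

where the sum runs over the "relevance vectors": the training samples whose
weight survives evidence-based hyperparameter optimisation.  Each weight
carries an independent zero-mean Gaussian prior ``beta_i ~ N(0, 1/alpha_i)``;
type-II maximum likelihood drives most ``alpha_i`` to infinity, pruning the
corresponding samples and leaving a sparse solution.  The procedure has no
user-tuned regularisation constant.

Hyperparameter updates are the classic fixed-point scheme:

    gamma_i  = 1 - alpha_i * Sigma_ii
    alpha_i <- gamma_i / mu_i**2
    sigma2  <- ||y - Phi mu||^2 / (n - sum_i gamma_i)

with ``mu`` and ``Sigma`` the posterior mean and covariance of the weights
given the current hyperparameters.  The fit is deterministic: no random
initialisation, so identical inputs give bit-identical models.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RVRModel", "fit_rvr", "predict", "back_project_weights"]

#: samples whose weight precision exceeds this are pruned from the model
PRUNE_THRESHOLD = 1e9
#: convergence: largest absolute change in log(alpha) between iterations
CONVERGENCE_TOL = 1e-6
MAX_ITER = 1000
#: floor for the noise variance, prevents division by zero on
#: interpolable (noiseless) targets
SIGMA2_FLOOR = 1e-12
#: jitter added to the posterior precision when its Cholesky factor fails
JITTER = 1e-10

_LOG2PI = float(np.log(2.0 * np.pi))


def _rvr_core(PtP, Pty, yty, n, alpha0, sigma2_0, update_alpha, update_sigma,
              prune_threshold, tol, max_iter, jitter):
    """Iterate the fixed-point updates on the precomputed Gram blocks.

    ``PtP = Phi' Phi`` and ``Pty = Phi' y`` for the full design
    ``Phi = [1 | K]`` (column 0 is the bias).  After the hyperparameters
    converge (or the iteration cap is hit) one final posterior is computed so
    the reported weights are consistent with the final alpha and sigma2.
    Returns the state plus the per-evaluation log marginal likelihood.
    """
    m = PtP.shape[0]
    alpha = alpha0.copy()
    sigma2 = sigma2_0
    active = np.ones(m, np.bool_)
    mu_full = np.zeros(m)
    evidence = np.full(max_iter + 1, np.nan)
    n_iter = 0
    converged = not (update_alpha or update_sigma)
    jittered = False
    for it in range(max_iter + 1):
        idx = np.where(active)[0]
        ma = idx.size
        H = np.empty((ma, ma))
        for a in range(ma):
            for b in range(a + 1):
                v = PtP[idx[a], idx[b]] / sigma2
                H[a, b] = v
                H[b, a] = v
            H[a, a] += alpha[idx[a]]
        L = _chol_lower(H)
        jit = jitter
        attempts = 0
        while L[0, 0] < 0.0 and attempts < 20:
            # re-condition with escalating jitter until the factorisation holds
            jittered = True
            for a in range(ma):
                H[a, a] += jit
            jit *= 10.0
            L = _chol_lower(H)
            attempts += 1
        if L[0, 0] < 0.0:
            break  # keep the previous iteration's posterior
        # posterior mean: two triangular solves of H mu = Pty/sigma2
        mu = np.empty(ma)
        for a in range(ma):
            s = Pty[idx[a]] / sigma2
            for k in range(a):
                s -= L[a, k] * mu[k]
            mu[a] = s / L[a, a]
        for a in range(ma - 1, -1, -1):
            s = mu[a]
            for k in range(a + 1, ma):
                s -= L[k, a] * mu[k]
            mu[a] = s / L[a, a]
        # diag of the posterior covariance from the inverse Cholesky factor
        diag_sigma = _inv_chol_diag(L)
        mu_full[:] = 0.0
        for a in range(ma):
            mu_full[idx[a]] = mu[a]
        # log evidence via the determinant identity
        # |C| = sigma2^n |H| / prod(alpha);  y'C^-1 y = (y'y - y'Phi mu)/sigma2
        logdetH = 0.0
        for a in range(ma):
            logdetH += 2.0 * np.log(L[a, a])
        logalpha_sum = 0.0
        ymu = 0.0
        for a in range(ma):
            logalpha_sum += np.log(alpha[idx[a]])
            ymu += Pty[idx[a]] * mu[a]
        quad = (yty - ymu) / sigma2
        evidence[it] = -0.5 * (n * _LOG2PI + n * np.log(sigma2)
                               + logdetH - logalpha_sum + quad)
        n_iter = it + 1
        if converged or it == max_iter:
            break
        gamma = np.empty(ma)
        for a in range(ma):
            gamma[a] = 1.0 - alpha[idx[a]] * diag_sigma[a]
        if update_sigma:
            # ||y - Phi mu||^2 = y'y - 2 mu'Phi'y + mu'Phi'Phi mu
            rss = yty - 2.0 * ymu
            for a in range(ma):
                acc = 0.0
                for b in range(ma):
                    acc += PtP[idx[a], idx[b]] * mu[b]
                rss += mu[a] * acc
            if rss < 0.0:
                rss = 0.0
            denom = n - gamma.sum()
            if denom < 1e-10:
                denom = 1e-10
            new_sigma2 = rss / denom
            if new_sigma2 < SIGMA2_FLOOR:
                new_sigma2 = SIGMA2_FLOOR
        else:
            new_sigma2 = sigma2
        if update_alpha:
            new_alpha = np.empty(ma)
            for a in range(ma):
                g = gamma[a]
                if g < 1e-12:
                    g = 1e-12
                mu2 = mu[a] * mu[a]
                if mu2 < 1e-300:  # underflow-safe: weight is effectively zero
                    new_alpha[a] = np.inf
                else:
                    new_alpha[a] = g / mu2
            # bias column is never pruned; cap its precision at the threshold
            if active[0] and new_alpha[0] > prune_threshold:
                new_alpha[0] = prune_threshold
            delta = 0.0
            for a in range(ma):
                na = new_alpha[a]
                keep = na < prune_threshold or idx[a] == 0
                if keep:
                    d = abs(np.log(min(na, prune_threshold * 10.0))
                            - np.log(alpha[idx[a]]))
                    if d > delta:
                        delta = d
                alpha[idx[a]] = na
                if not keep:
                    active[idx[a]] = False
        else:
            delta = abs(np.log(new_sigma2) - np.log(sigma2))
        sigma2 = new_sigma2
        if not active.any():
            break
        if delta < tol:
            converged = True  # one more pass recomputes the posterior
    return alpha, mu_full, sigma2, active, n_iter, converged, evidence, jittered


def _chol_lower(H):
    """Cholesky factor of ``H``; signals failure via a negative [0,0] entry.

    Hand-rolled lower-triangular factorisation so the same code runs under
    numba (which cannot catch LAPACK failures) and plain numpy.
    """
    m = H.shape[0]
    L = np.zeros_like(H)
    for j in range(m):
        s = H[j, j]
        for k in range(j):
            s -= L[j, k] * L[j, k]
        if s <= 0.0:
            L[0, 0] = -1.0
            return L
        d = np.sqrt(s)
        L[j, j] = d
        for i in range(j + 1, m):
            t = H[i, j]
            for k in range(j):
                t -= L[i, k] * L[j, k]
            L[i, j] = t / d
    return L


def _inv_chol_diag(L):
    """diag(H^-1) given the lower Cholesky factor L of H.

    Column j of W = L^-1 is computed by forward substitution; then
    (H^-1)_jj = sum_k W_kj^2.
    """
    m = L.shape[0]
    diag = np.empty(m)
    w = np.empty(m)
    for j in range(m):
        w[j] = 1.0 / L[j, j]
        for i in range(j + 1, m):
            s = 0.0
            for k in range(j, i):
                s -= L[i, k] * w[k]
            w[i] = s / L[i, i]
        acc = 0.0
        for k in range(j, m):
            acc += w[k] * w[k]
        diag[j] = acc
    return diag


try:  # jit-compile the update loop; fall back to pure numpy transparently
    import numba

    _chol_lower = numba.njit(cache=True)(_chol_lower)
    _inv_chol_diag = numba.njit(cache=True)(_inv_chol_diag)
    _rvr_core = numba.njit(cache=True)(_rvr_core)
except Exception:  # pragma: no cover - numba present in supported envs
    pass


@dataclass
class RVRModel:
    """A fitted relevance vector regression model.

    Attributes
    ----------
    relevance_indices : ndarray of int
        Training-sample indices whose weights survived pruning.
    sample_weights : ndarray
        Weight ``beta_s`` for each relevance vector, in index order.
    bias : float
        Intercept ``beta_0`` (score units).
    alphas : ndarray
        Retained precision hyperparameters, aligned with
        ``[bias] + relevance vectors``.
    noise_variance : float
        Estimated observation noise ``sigma^2`` (score units squared).
    relevance_vectors : ndarray
        Feature rows of the retained training samples (needed both for
        prediction and for back-projection to feature weights).
    """

    relevance_indices: np.ndarray
    sample_weights: np.ndarray
    bias: float
    alphas: np.ndarray
    noise_variance: float
    relevance_vectors: np.ndarray
    n_features: int
    n_training_samples: int
    kernel: str = "linear"
    n_iterations_run: int = 0
    converged: bool = False
    evidence_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def log_evidence(self) -> float:
        """Log marginal likelihood at the final iteration."""
        return float(self.evidence_path[-1]) if self.evidence_path.size else np.nan

    def to_json(self) -> str:
        """Serialize the model (weights, hyperparameters, iteration log)."""
        return json.dumps({
            "kernel": self.kernel,
            "relevance_indices": self.relevance_indices.tolist(),
            "sample_weights": self.sample_weights.tolist(),
            "bias": self.bias,
            "alphas": self.alphas.tolist(),
            "noise_variance": self.noise_variance,
            "relevance_vectors": self.relevance_vectors.tolist(),
            "n_features": self.n_features,
            "n_training_samples": self.n_training_samples,
            "n_iterations_run": self.n_iterations_run,
            "converged": self.converged,
            "evidence_path": self.evidence_path.tolist(),
            "config": {
                "prune_threshold": PRUNE_THRESHOLD,
                "convergence_tol": CONVERGENCE_TOL,
                "max_iter": MAX_ITER,
                "sigma2_floor": SIGMA2_FLOOR,
            },
        })

    @classmethod
    def from_json(cls, text: str) -> "RVRModel":
        d = json.loads(text)
        return cls(
            relevance_indices=np.asarray(d["relevance_indices"], dtype=int),
            sample_weights=np.asarray(d["sample_weights"], dtype=float),
            bias=float(d["bias"]),
            alphas=np.asarray(d["alphas"], dtype=float),
            noise_variance=float(d["noise_variance"]),
            relevance_vectors=np.asarray(d["relevance_vectors"], dtype=float),
            n_features=int(d["n_features"]),
            n_training_samples=int(d["n_training_samples"]),
            kernel=d["kernel"],
            n_iterations_run=int(d["n_iterations_run"]),
            converged=bool(d["converged"]),
            evidence_path=np.asarray(d["evidence_path"], dtype=float),
        )


def _bias_only(y: np.ndarray, p: int, n: int, note: str) -> RVRModel:
    warnings.warn(f"RVR collapsed to a bias-only model: {note}")
    return RVRModel(
        relevance_indices=np.empty(0, dtype=int),
        sample_weights=np.empty(0),
        bias=float(np.mean(y)),
        alphas=np.empty(0),
        noise_variance=max(float(np.var(y)), SIGMA2_FLOOR),
        relevance_vectors=np.empty((0, p)),
        n_features=p,
        n_training_samples=n,
        converged=True,
    )


def fit_rvr(X, y, *, update_alpha: bool = True, update_sigma: bool = True,
            init_alpha=None, init_sigma2: float | None = None,
            max_iter: int = MAX_ITER) -> RVRModel:
    """Fit relevance vector regression with a linear kernel.

    Parameters
    ----------
    X : (n, p) array
        Training feature matrix (typically min-max scaled per fold).
    y : (n,) array
        Target scores.
    update_alpha, update_sigma : bool
        Disable to freeze hyperparameters at their initial values; with
        ``update_alpha=False`` the fit reduces to kernel ridge regression
        with a shared penalty, which is used as an exact cross-check.
    init_alpha : float or (n+1,) array, optional
        Initial weight precisions (default ``1/n`` for every column).
    init_sigma2 : float, optional
        Initial noise variance (default ``0.1 * var(y)``).

    Returns
    -------
    RVRModel
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be a 2-D samples x features matrix")
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError(f"X has {n} rows but y has {y.shape[0]} entries")
    if n < 3:
        raise ValueError("need at least 3 training samples")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("X and y must be finite (no NaN/inf)")
    if np.var(y) == 0.0:
        return _bias_only(y, p, n, "constant target")

    K = X @ X.T
    Phi = np.concatenate([np.ones((n, 1)), K], axis=1)
    PtP = Phi.T @ Phi
    Pty = Phi.T @ y
    yty = float(y @ y)

    m = n + 1
    if init_alpha is None:
        alpha0 = np.full(m, 1.0 / n)
    else:
        alpha0 = np.broadcast_to(np.asarray(init_alpha, dtype=float), (m,)).copy()
    sigma2_0 = float(init_sigma2) if init_sigma2 is not None \
        else max(0.1 * float(np.var(y)), SIGMA2_FLOOR)

    alpha, mu, sigma2, active, n_iter, converged, evidence, jittered = _rvr_core(
        np.ascontiguousarray(PtP), np.ascontiguousarray(Pty), yty, n,
        np.ascontiguousarray(alpha0), sigma2_0, update_alpha, update_sigma,
        PRUNE_THRESHOLD, CONVERGENCE_TOL, int(max_iter), JITTER)
    if jittered:
        warnings.warn("posterior precision re-conditioned with jitter")
    evidence = evidence[:n_iter]

    sample_active = active[1:]
    if not sample_active.any():
        if not active[0]:
            return _bias_only(y, p, n, "all samples pruned")
        model_bias = float(mu[0])
        return RVRModel(
            relevance_indices=np.empty(0, dtype=int),
            sample_weights=np.empty(0),
            bias=model_bias,
            alphas=alpha[:1].copy(),
            noise_variance=float(sigma2),
            relevance_vectors=np.empty((0, p)),
            n_features=p, n_training_samples=n,
            n_iterations_run=n_iter, converged=bool(converged),
            evidence_path=evidence,
        )

    rel = np.where(sample_active)[0]
    keep_cols = np.concatenate([[0], rel + 1]) if active[0] else rel + 1
    return RVRModel(
        relevance_indices=rel,
        sample_weights=mu[rel + 1].copy(),
        bias=float(mu[0]),
        alphas=alpha[keep_cols].copy(),
        noise_variance=float(sigma2),
        relevance_vectors=X[rel].copy(),
        n_features=p, n_training_samples=n,
        n_iterations_run=n_iter, converged=bool(converged),
        evidence_path=evidence,
    )


def predict(model: RVRModel, X_test) -> np.ndarray:
    """Predict scores: ``f(x) = sum_s beta_s (x . x_s) + beta_0``."""
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    if X_test.shape[1] != model.n_features:
        raise ValueError(
            f"test features have dimension {X_test.shape[1]}, "
            f"model was trained with {model.n_features}")
    if model.relevance_indices.size == 0:
        return np.full(X_test.shape[0], model.bias)
    return X_test @ model.relevance_vectors.T @ model.sample_weights + model.bias


def back_project_weights(model: RVRModel) -> np.ndarray:
    """Per-feature contribution weights ``w = sum_s beta_s x_s``.

    The linear kernel makes the model exactly equivalent to the primal form
    ``f(x) = w . x + beta_0``; the absolute value of each entry of ``w``
    measures how much that feature contributes to the prediction.
    """
    if model.relevance_indices.size == 0:
        return np.zeros(model.n_features)
    return model.relevance_vectors.T @ model.sample_weights
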