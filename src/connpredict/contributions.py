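"""Model interpretation: contributing regions, edge-level prediction and
network-pair aggregation.

After cross-validation establishes that prediction beats chance, a single
model is fit on the full sample and its per-feature contribution weights
are recovered by back-projection.  Features (regions, or edges in the
second stage) are ranked by absolute weight; the top-k (default 50)
regions define the subset whose pairwise connectivity feeds the
edge-level second-stage model.  Edge weights are finally aggregated into
a symmetric system-pair matrix over the seven cognitive systems.

The edge-level stage reuses the full-sample top-k regions, so its CV
metrics are interpretive (the selection saw all subjects); a fully nested
mode re-selects the top-k inside each training fold for an honest
out-of-sample estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import rvr
from .crossval import CVResult, minmax_scale_fold, run_loocv, run_repeated_kfold
from .features import extract_edge_features, nodal_strength
from .synthetic import SYSTEMS as SYSTEM_ORDER

__all__ = [
    "ContributionReport",
    "NetworkContributionMatrix",
    "full_sample_weights",
    "edge_level_prediction",
    "network_aggregate",
]


@dataclass
class ContributionReport:
    """Feature weights from the full-sample model, ranked by |weight|.

    ``abs_rank[k]`` is the feature index with the (k+1)-th largest
    absolute weight; exact ties break by feature (atlas) index, which
    makes the ranking deterministic.
    """

    feature_ids: list
    weights: np.ndarray
    abs_rank: np.ndarray
    top_k_ids: list
    k: int
    model: rvr.RVRModel | None = None

    def table(self) -> pd.DataFrame:
        ranks = np.empty(len(self.feature_ids), dtype=int)
        ranks[self.abs_rank] = np.arange(1, len(self.feature_ids) + 1)
        top = set(map(tuple, self.top_k_ids)) if self.top_k_ids and \
            isinstance(self.top_k_ids[0], tuple) else set(self.top_k_ids)
        return pd.DataFrame({
            "feature_id": self.feature_ids,
            "weight": self.weights,
            "abs_rank": ranks,
            "in_top_k": [fid in top for fid in self.feature_ids],
        })


@dataclass
class NetworkContributionMatrix:
    """System-pair sums of absolute edge contribution weights.

    ``values[a, b]`` is the sum of |weight| over edges with one endpoint
    in system ``a`` and the other in system ``b``; the diagonal holds
    within-system sums.  ``signed_values`` carries the plain (signed)
    sums as a secondary output.
    """

    systems: list
    values: np.ndarray
    signed_values: np.ndarray

    def frame(self, signed: bool = False) -> pd.DataFrame:
        v = self.signed_values if signed else self.values
        return pd.DataFrame(v, index=self.systems, columns=self.systems)


def _rank_by_abs(weights: np.ndarray) -> np.ndarray:
    # descending |weight|; ties broken by ascending feature index
    order = np.lexsort((np.arange(weights.size), -np.abs(weights)))
    return order


def full_sample_weights(features, y, feature_ids=None, k: int = 50,
                        engine_kwargs=None) -> ContributionReport:
    """Fit one model on all subjects and rank features by |weight|.

    Features are min-max scaled over the full sample, mirroring the
    training transform of the CV stage (there is no held-out set here).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    X_s, _ = minmax_scale_fold(X, X[:0])
    model = rvr.fit_rvr(X_s, y, **(engine_kwargs or {}))
    w = rvr.back_project_weights(model)
    if feature_ids is None:
        feature_ids = list(range(X.shape[1]))
    if len(feature_ids) != w.size:
        raise ValueError("feature_ids length does not match feature count")
    order = _rank_by_abs(w)
    top = [feature_ids[i] for i in order[: min(k, w.size)]]
    return ContributionReport(feature_ids=list(feature_ids), weights=w,
                              abs_rank=order, top_k_ids=top, k=k, model=model)


def build_edge_matrix(connectomes, subset):
    """Stack per-subject edge features over a region subset.

    Returns ``(matrix, index_map)`` where matrix is subjects x C with
    C = K(K-1)/2.
    """
    sets = [extract_edge_features(cm, subset) for cm in connectomes]
    index_map = sets[0].index_map
    return np.vstack([s.values for s in sets]), index_map


def edge_level_prediction(connectomes, top_regions, phenotypes, covariates=None,
                          scheme: str = "loocv", k: int = 10, repeats: int = 20,
                          seed: int = 0, top_k_edges: int = 50,
                          engine_kwargs=None, nested: bool = False,
                          score_column: str = "psqi"):
    """Second-stage prediction from connectivity among the top regions.

    Builds the K(K-1)/2 edge features per subject (1,225 for K=50), runs
    the same CV pipeline, and reports a full-sample edge-weight ranking
    with the top ``top_k_edges`` edges.  With ``nested=True`` the region
    subset must instead be re-derived inside each fold; see
    :func:`nested_edge_loocv`.

    Returns ``(CVResult, ContributionReport over edges)``.
    """
    if len(top_regions) < 2:
        raise ValueError("need at least 2 top regions for edge features")
    if nested:
        raise ValueError(
            "nested selection has its own entry point: nested_edge_loocv")
    X, index_map = build_edge_matrix(connectomes, top_regions)
    y = phenotypes[score_column].to_numpy(dtype=float) \
        if isinstance(phenotypes, pd.DataFrame) else np.asarray(phenotypes, float)
    if scheme == "loocv":
        cv = run_loocv(X, phenotypes, covariates, engine_kwargs,
                       score_column=score_column)
    elif scheme == "kfold":
        cv = run_repeated_kfold(X, phenotypes, covariates, k=k, repeats=repeats,
                                seed=seed, engine_kwargs=engine_kwargs,
                                score_column=score_column)
    else:
        raise ValueError(f"unknown scheme '{scheme}'")
    report = full_sample_weights(X, y, feature_ids=index_map, k=top_k_edges,
                                 engine_kwargs=engine_kwargs)
    return cv, report


def nested_edge_loocv(connectomes, phenotypes, covariates=None, top_k: int = 50,
                      engine_kwargs=None, score_column: str = "psqi") -> CVResult:
    """Fully nested edge-level LOOCV.

    Inside each fold the contributing regions are re-selected from the
    training subjects only (nodal-strength model on n-1 subjects), the
    edge features among that fold's top-k regions are extracted, and the
    held-out subject is predicted.  Slower but free of selection leakage.
    """
    y = phenotypes[score_column].to_numpy(dtype=float) \
        if isinstance(phenotypes, pd.DataFrame) else np.asarray(phenotypes, float)
    n = len(connectomes)
    strengths = np.vstack([nodal_strength(cm).strengths for cm in connectomes])
    from .crossval import encode_covariates, prediction_accuracy
    Z = encode_covariates(phenotypes, covariates) \
        if isinstance(phenotypes, pd.DataFrame) else np.empty((n, 0))
    predicted = np.full(n, np.nan)
    for i in range(n):
        train = np.delete(np.arange(n), i)
        rep = full_sample_weights(strengths[train], y[train], k=top_k,
                                  engine_kwargs=engine_kwargs)
        regions = sorted(rep.top_k_ids)
        X, _ = build_edge_matrix([connectomes[j] for j in train] + [connectomes[i]],
                                 regions)
        tr, te = minmax_scale_fold(X[:-1], X[-1:])
        model = rvr.fit_rvr(tr, y[train], **(engine_kwargs or {}))
        predicted[i] = rvr.predict(model, te)[0]
    metrics = prediction_accuracy(y, predicted, Z)
    return CVResult(observed=y, predicted=predicted, fold_assignment=np.arange(n),
                    metrics=metrics, covariates_used=list(covariates or []),
                    scheme=f"nested-loocv(top_k={top_k})")


def network_aggregate(edge_report: ContributionReport,
                      region_systems: dict) -> NetworkContributionMatrix:
    """Aggregate edge weights into a symmetric system-pair matrix.

    ``region_systems`` maps region id -> system label.  Every scored edge
    contributes its |weight| (and, secondarily, its signed weight) to
    exactly one unordered system pair.  Raises ``KeyError`` naming any
    unlabeled region.
    """
    systems = list(SYSTEM_ORDER)
    pos = {s: i for i, s in enumerate(systems)}
    for s in set(region_systems.values()):
        if s not in pos:  # allow custom labels by extending the order
            pos[s] = len(systems)
            systems.append(s)
    S = len(systems)
    vals = np.zeros((S, S))
    signed = np.zeros((S, S))
    for (ri, rj), w in zip(edge_report.feature_ids, edge_report.weights):
        for r in (ri, rj):
            if r not in region_systems:
                raise KeyError(f"region {r} has no system label")
        a, b = sorted((pos[region_systems[ri]], pos[region_systems[rj]]))
        vals[a, b] += abs(w)
        signed[a, b] += w
        if a != b:
            vals[b, a] = vals[a, b]
            signed[b, a] = signed[a, b]
    return NetworkContributionMatrix(systems=systems, values=vals,
                                     signed_values=signed)
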