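"""Connectome feature extraction.

From regional BOLD time series the pipeline computes, per subject, a
region-by-region Pearson correlation matrix (the functional connectome),
and from that matrix two kinds of feature vectors:

* nodal connectivity strength — for each region, the signed sum of its
  correlations with every other region (a degree-like centrality; with R
  regions each strength sums R-1 terms);
* edge features — the upper-triangular correlation values among a chosen
  region subset (K regions give K(K-1)/2 features).

Correlations are used as-is: no absolute value, no Fisher z-transform and
no thresholding by default (global-signal regression upstream makes
negative correlations common and they are retained as informative).
Optional ``fisher_z`` / ``absolute`` switches are provided for sensitivity
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RegionalTimeSeries",
    "ConnectivityMatrix",
    "NodalStrengthVector",
    "EdgeFeatureSet",
    "compute_connectivity",
    "nodal_strength",
    "extract_edge_features",
]

SYMMETRY_TOL = 1e-12


@dataclass
class RegionalTimeSeries:
    """Mean BOLD time series per region: a time x region matrix."""

    subject_id: str
    data: np.ndarray
    region_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be a 2-D time x region matrix")
        if self.data.shape[0] < 3:
            raise ValueError("need at least 3 time points")
        if not np.isfinite(self.data).all():
            raise ValueError(f"subject {self.subject_id}: missing/non-finite samples")
        if not self.region_ids:
            self.region_ids = list(range(self.data.shape[1]))
        if len(self.region_ids) != self.data.shape[1]:
            raise ValueError("region_ids length does not match column count")


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region Pearson correlation matrix (unit diagonal)."""

    subject_id: str
    values: np.ndarray
    region_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=SYMMETRY_TOL, rtol=0.0):
            raise ValueError(f"subject {self.subject_id}: matrix not symmetric")
        if not np.all(np.diag(v) == 1.0):
            raise ValueError(f"subject {self.subject_id}: diagonal must be exactly 1")
        if np.any(np.abs(v) > 1.0 + 1e-12):
            raise ValueError(f"subject {self.subject_id}: entries outside [-1, 1]")
        if not self.region_ids:
            self.region_ids = list(range(v.shape[0]))
        if len(self.region_ids) != v.shape[0]:
            raise ValueError("region_ids length does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class NodalStrengthVector:
    """Per-region sum of connectivity to all other regions."""

    subject_id: str
    strengths: np.ndarray
    region_ids: list = field(default_factory=list)


@dataclass
class EdgeFeatureSet:
    """Upper-triangular connectivity values among a region subset.

    ``index_map`` lists the (i, j) region-id pairs (i before j in atlas
    order) corresponding to each feature, lexicographically ordered.
    """

    subject_id: str
    values: np.ndarray
    index_map: list  # list of (region_i, region_j) tuples


def compute_connectivity(ts: RegionalTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between every pair of regional time series.

    Raises on zero-variance regions: a constant regional signal is a data
    error, not a zero correlation.
    """
    data = ts.data
    sd = data.std(axis=0)
    dead = np.where(sd == 0.0)[0]
    if dead.size:
        names = [ts.region_ids[i] for i in dead]
        raise ValueError(
            f"subject {ts.subject_id}: zero-variance region(s) {names}")
    C = np.corrcoef(data, rowvar=False)
    # exact unit diagonal and symmetry, guarding float round-off
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return ConnectivityMatrix(ts.subject_id, C, list(ts.region_ids))


def nodal_strength(C: ConnectivityMatrix, *, fisher_z: bool = False,
                   absolute: bool = False) -> NodalStrengthVector:
    """Signed sum of each region's connectivity to all other regions.

    ``strength_i = sum_{j != i} r_ij``; the diagonal is excluded by
    construction.  ``fisher_z`` applies arctanh to the off-diagonal values
    first (values at +-1 are clipped to +-(1-1e-15) to stay finite);
    ``absolute`` sums magnitudes instead of signed values.
    """
    v = C.values.copy()
    np.fill_diagonal(v, 0.0)
    if fisher_z:
        off = ~np.eye(v.shape[0], dtype=bool)
        v[off] = np.arctanh(np.clip(v[off], -1 + 1e-15, 1 - 1e-15))
    if absolute:
        v = np.abs(v)
    return NodalStrengthVector(C.subject_id, v.sum(axis=1), list(C.region_ids))


def extract_edge_features(C: ConnectivityMatrix, subset) -> EdgeFeatureSet:
    """Connectivity values among ``subset`` regions, upper triangle only.

    The subset is reordered to atlas order; a subset of size K yields
    K(K-1)/2 features.
    """
    subset = list(subset)
    if len(set(subset)) != len(subset):
        raise ValueError("duplicate region ids in subset")
    if len(subset) < 2:
        raise ValueError("need at least 2 regions for edge features")
    pos = {rid: k for k, rid in enumerate(C.region_ids)}
    missing = [rid for rid in subset if rid not in pos]
    if missing:
        raise ValueError(f"region ids not in matrix: {missing}")
    order = sorted(subset, key=pos.__getitem__)
    ids = np.array([pos[rid] for rid in order])
    sub = C.values[np.ix_(ids, ids)]
    iu = np.triu_indices(len(order), k=1)
    index_map = [(order[a], order[b]) for a, b in zip(*iu)]
    return EdgeFeatureSet(C.subject_id, sub[iu], index_map)
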