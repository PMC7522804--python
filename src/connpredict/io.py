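"""Plain-text readers and writers for connectomes, features and phenotypes.

File dialects are deliberately simple: square numeric matrices for
connectomes (tab, comma or whitespace delimited, with an optional header
row of region ids), CSV phenotype tables with a ``subject`` key column,
and a tab-delimited region-metadata table with ``region_id``, ``name``,
``hemisphere`` and ``system`` columns.  Imaging formats are never
consumed; preprocessing is upstream of this package.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .features import ConnectivityMatrix, RegionalTimeSeries

__all__ = [
    "read_matrix",
    "read_connectome",
    "read_connectomes",
    "read_timeseries",
    "read_phenotypes",
    "read_regions",
    "write_features",
    "read_features",
]

REQUIRED_PHENO_COLUMNS = ("subject", "psqi")


def _sniff_delimiter(first_line: str):
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    return None  # any whitespace


def read_matrix(path) -> np.ndarray:
    """Read a numeric matrix, auto-detecting the delimiter and skipping an
    optional non-numeric header row."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delim = _sniff_delimiter(first)
    tokens = first.strip().split(delim)
    skip = 0
    try:
        float(tokens[0])
    except ValueError:
        skip = 1
    return np.loadtxt(path, delimiter=delim, skiprows=skip, ndmin=2)


def read_connectome(path, region_ids=None, subject_id=None) -> ConnectivityMatrix:
    """Read one subject's square correlation matrix.

    The subject id defaults to the ``sub-...`` prefix of the file name.
    If ``region_ids`` is given the matrix size is validated against it.
    """
    path = Path(path)
    values = read_matrix(path)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path.name}: connectome must be square, "
                         f"got {values.shape}")
    if region_ids is not None and len(region_ids) != values.shape[0]:
        raise ValueError(
            f"{path.name}: matrix has {values.shape[0]} regions but metadata "
            f"lists {len(region_ids)}")
    if subject_id is None:
        m = re.match(r"(sub-[A-Za-z0-9]+)", path.name)
        subject_id = m.group(1) if m else path.stem
    return ConnectivityMatrix(subject_id, values,
                              list(region_ids) if region_ids is not None else [])


def read_connectomes(directory, subjects, region_ids=None) -> list:
    """Read one connectome per subject, in phenotype-table order.

    Files are located as ``<subject>_connectome.<ext>``; subjects without
    a file (or files without a phenotype row) are reported together.
    """
    directory = Path(directory)
    available = {}
    for p in sorted(directory.glob("*_connectome.*")):
        available[p.name.split("_connectome")[0]] = p
    missing = [s for s in subjects if s not in available]
    extra = [s for s in available if s not in set(subjects)]
    if missing or extra:
        raise ValueError(
            f"subject mismatch between connectomes and phenotypes: "
            f"missing files for {missing}, unmatched files for {extra}")
    return [read_connectome(available[s], region_ids, subject_id=s)
            for s in subjects]


def read_timeseries(path, subject_id=None) -> RegionalTimeSeries:
    values = read_matrix(path)
    if subject_id is None:
        p = Path(path)
        m = re.match(r"(sub-[A-Za-z0-9]+)", p.name)
        subject_id = m.group(1) if m else p.stem
    return RegionalTimeSeries(subject_id, values)


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype CSV with at least ``subject`` and ``psqi`` columns.

    Sex codes are normalised to {M, F}; subject ids must be unique and
    scores must lie in the 0-21 instrument range.
    """
    df = pd.read_csv(path)
    for col in REQUIRED_PHENO_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"phenotype table lacks required column '{col}'")
    if df["subject"].duplicated().any():
        dupes = df.loc[df["subject"].duplicated(), "subject"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    if ((df["psqi"] < 0) | (df["psqi"] > 21)).any():
        raise ValueError("psqi scores outside the 0-21 instrument range")
    if "sex" in df.columns:
        mapping = {"M": "M", "F": "F", "0": "M", "1": "F"}
        sx = df["sex"].astype(str).str.strip().str.upper()
        bad = sorted(set(sx) - set(mapping))
        if bad:
            raise ValueError(f"unrecognised sex codes: {bad}")
        df["sex"] = sx.map(mapping)
    return df


def read_regions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"region_id", "system"}
    if not required <= set(df.columns):
        raise ValueError(f"region metadata needs columns {sorted(required)}")
    return df


def write_features(path, subjects, matrix, feature_names=None) -> None:
    """Write a subjects x features table as CSV with a ``subject`` key."""
    matrix = np.asarray(matrix)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(matrix.shape[1])]
    df = pd.DataFrame(matrix, columns=[str(f) for f in feature_names])
    df.insert(0, "subject", list(subjects))
    df.to_csv(path, index=False)


def read_features(path):
    """Read a features CSV; returns (subjects, matrix, feature_names)."""
    df = pd.read_csv(path)
    if "subject" not in df.columns:
        raise ValueError("features table lacks the 'subject' key column")
    subjects = df["subject"].tolist()
    rest = df.drop(columns="subject")
    return subjects, rest.to_numpy(dtype=float), list(rest.columns)
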