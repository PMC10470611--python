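"""Alpha diversity, Bray-Curtis dissimilarity and geographic distances.

Alpha diversity follows the study convention of being computed on the
rarefied table (equal depth across samples); the functions warn when column
sums are unequal and can be forced.  Distance matrices are
``skbio.DistanceMatrix`` objects, which serialise to the mothur/QIIME
square-TSV dialect via ``write``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .tables import CompositionTable, CountTable, SampleSheet

__all__ = [
    "richness",
    "inverse_simpson",
    "alpha_diversity_table",
    "bray_curtis_matrix",
    "geo_distance_matrix",
    "haversine_m",
]

EARTH_RADIUS_M = 6_371_000.0


def richness(counts) -> int:
    """Observed richness: number of taxa with count > 0."""
    return int(np.count_nonzero(np.asarray(counts) > 0))


def inverse_simpson(counts) -> float:
    """Inverse Simpson index 1 / sum(p_i^2) on within-sample proportions."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total == 0:
        raise ValueError("inverse Simpson undefined for an all-zero sample")
    p = c / total
    return float(1.0 / np.sum(p**2))


def alpha_diversity_table(t: CountTable, force: bool = False) -> pd.DataFrame:
    """Per-sample observed richness and inverse Simpson.

    Expects a rarefied table; refuses unequal sample depths unless
    ``force=True`` (unequal depth makes richness incomparable).
    """
    sums = t.sample_sums()
    if len(set(sums.tolist())) > 1:
        if not force:
            raise ValueError(
                "alpha diversity expects a rarefied table (equal sample sums); "
                "pass force=True to override"
            )
        warnings.warn("alpha diversity on unrarefied table")
    return pd.DataFrame(
        {
            "sample_id": list(t.sample_ids),
            "richness": [richness(t.counts[:, j]) for j in range(t.n_samples)],
            "inverse_simpson": [inverse_simpson(t.counts[:, j]) for j in range(t.n_samples)],
        }
    ).set_index("sample_id", drop=False)


def bray_curtis_matrix(c: CompositionTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities on relative abundances.

    BC(a, b) = sum|a_i - b_i| / sum(a_i + b_i); with column-normalised
    input this equals half the L1 distance.
    """
    condensed = pdist(c.values.T, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(c.sample_ids))


def haversine_m(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in metres (Earth radius 6,371 km)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return float(2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a)))


def geo_distance_matrix(sheet: SampleSheet, collapse: str = "per_individual") -> DistanceMatrix:
    """Haversine distances between sampled plants.

    ``per_individual`` averages duplicate coordinates per plant individual
    (the two leaf sides of one plant share a location); ``per_sample`` keeps
    one row per sample.
    """
    df = sheet.df
    for col in ("latitude", "longitude"):
        if col not in df.columns:
            raise ValueError(f"sample sheet lacks {col!r}")
    missing = df[df[["latitude", "longitude"]].isna().any(axis=1)]["sample_id"].tolist()
    if missing:
        raise ValueError(f"samples missing coordinates: {missing}")
    if collapse == "per_individual":
        pts = df.groupby("plant_individual")[["latitude", "longitude"]].mean()
    elif collapse == "per_sample":
        pts = df.set_index("sample_id")[["latitude", "longitude"]]
    else:
        raise ValueError(f"unknown collapse {collapse!r}")
    ids = list(pts.index.astype(str))
    n = len(ids)
    mat = np.zeros((n, n))
    lat = pts["latitude"].to_numpy()
    lon = pts["longitude"].to_numpy()
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = haversine_m(lat[i], lon[i], lat[j], lon[j])
    return DistanceMatrix(mat, ids=ids)
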