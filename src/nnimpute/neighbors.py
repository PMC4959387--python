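"""Donor-based (hot-deck) nearest-neighbour primitives.

A *recipient* row with a missing value receives a replacement derived from
*donor* rows that are complete.  Similarity is the Minkowski norm

    d(a, b) = ( sum_i |a_i - b_i|^p )^(1/p)

over a caller-chosen feature subset; ``p = 2`` is Euclidean, ``p = 1``
Manhattan, and fractional exponents (e.g. ``p = 0.5``) are supported for
high-dimensional settings.  Donor values are combined by one of three rules:

``1nn``
    the single nearest donor's value (an actually occurring value),
``knn``
    the unweighted mean of the ``k`` nearest donors,
``wknn``
    the inverse-distance-weighted mean of the ``k`` nearest donors
    (KNNimpute-style weighting); exact matches (distance 0) take the whole
    weight, as the limit of the weighting scheme.

Ties in donor distance are always broken by ascending row index so that every
ranking is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import DataMatrix

METHODS = ("1nn", "knn", "wknn", "mean")


@dataclass
class DonorRanking:
    """Donor rows ordered by nondecreasing distance to a recipient."""

    donor_indices: np.ndarray
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.donor_indices = np.asarray(self.donor_indices, dtype=int)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.donor_indices.shape != self.distances.shape:
            raise ValueError("indices and distances must have equal length")
        if np.any(np.diff(self.distances) < 0):
            raise ValueError("distances must be nondecreasing")

    def __len__(self) -> int:
        return len(self.donor_indices)


def _pairwise_distances(
    pool: np.ndarray, recipient: np.ndarray, feature_idx: np.ndarray, p: float
) -> np.ndarray:
    """Minkowski distance of one recipient to every pool row, vectorized."""
    diff = np.abs(pool[:, feature_idx] - recipient[feature_idx])
    if p == 2.0:
        return np.sqrt(np.einsum("ij,ij->i", diff, diff))
    if p == 1.0:
        return diff.sum(axis=1)
    return diff.__ipow__(p).sum(axis=1) ** (1.0 / p)


def minkowski_distance(
    a: Sequence[float],
    b: Sequence[float],
    p: float = 2.0,
    feature_idx: Sequence[int] | None = None,
) -> float:
    """Minkowski distance between two vectors over ``feature_idx``.

    Both vectors must be observed (non-NaN) at every selected index.
    """
    if p <= 0:
        raise ValueError("exponent p must be positive")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if feature_idx is None:
        feature_idx = np.arange(a.shape[-1])
    feature_idx = np.asarray(feature_idx, dtype=int)
    if feature_idx.size == 0:
        raise ValueError("no comparable features")
    av, bv = a[feature_idx], b[feature_idx]
    if np.isnan(av).any() or np.isnan(bv).any():
        raise ValueError("incomplete vector: missing value at a selected feature")
    return float((np.abs(av - bv) ** p).sum() ** (1.0 / p))


def rank_donors(
    recipient: Sequence[float],
    pool: DataMatrix | np.ndarray,
    target_attr: str | int,
    feature_idx: Sequence[int],
    p: float = 2.0,
) -> DonorRanking:
    """Rank every pool row by distance to the recipient (ascending).

    The pool must be observed at ``target_attr`` and at all ``feature_idx``
    positions; the recipient must be observed at all ``feature_idx``
    positions.  Ties are broken by ascending row index.
    """
    if isinstance(pool, DataMatrix):
        target_idx = pool.index(target_attr) if isinstance(target_attr, str) else int(target_attr)
        if not pool.mask[:, target_idx].all():
            raise ValueError("pool must be observed at the target attribute")
        pool_vals = pool.values
    else:
        pool_vals = np.asarray(pool, dtype=float)
        target_idx = int(target_attr)
    feature_idx = np.asarray(feature_idx, dtype=int)
    if feature_idx.size == 0:
        raise ValueError("no comparable features")
    if target_idx in feature_idx:
        raise ValueError("target attribute may not be a distance feature")
    if pool_vals.shape[0] == 0:
        raise ValueError("no donors available")
    recipient = np.asarray(recipient, dtype=float)
    if np.isnan(recipient[feature_idx]).any():
        raise ValueError("incomplete vector: recipient missing a selected feature")
    if np.isnan(pool_vals[:, feature_idx]).any():
        raise ValueError("incomplete vector: pool missing a selected feature")
    dist = _pairwise_distances(pool_vals, recipient, feature_idx, float(p))
    order = np.argsort(dist, kind="stable")  # stable sort = ties by ascending row index
    return DonorRanking(order, dist[order])


def aggregate_donor_values(
    donor_values: Sequence[float],
    distances: Sequence[float],
    method: str = "knn",
    k: int = 5,
) -> float:
    """Combine the ``k`` nearest donors' values into one imputed value.

    ``distances`` must be sorted ascending and aligned with ``donor_values``.
    For ``wknn``, weights are proportional to 1/distance, normalized over the
    k donors; if any of the k distances is exactly zero the result is the
    plain mean of the zero-distance donors (the limit of the weights).
    """
    values = np.asarray(donor_values, dtype=float)
    dist = np.asarray(distances, dtype=float)
    if values.shape != dist.shape:
        raise ValueError("values and distances must have equal length")
    if method not in ("1nn", "knn", "wknn"):
        raise ValueError(f"unknown aggregation method {method!r}")
    if method == "1nn":
        k = 1
    if k < 1:
        raise ValueError("k must be >= 1")
    if values.size < k:
        raise ValueError("insufficient donors")
    if np.any(np.diff(dist) < 0):
        raise ValueError("distances must be sorted ascending")
    if method == "1nn":
        return float(values[0])
    v, d = values[:k], dist[:k]
    if method == "knn":
        return float(v.mean())
    zero = d == 0.0
    if zero.any():
        return float(v[zero].mean())
    w = 1.0 / d
    return float((w * v).sum() / w.sum())


def mean_impute_value(pool: DataMatrix | np.ndarray, target_attr: str | int) -> float:
    """Arithmetic mean of the target attribute over the (complete-case) pool."""
    if isinstance(pool, DataMatrix):
        j = pool.index(target_attr) if isinstance(target_attr, str) else int(target_attr)
        col = pool.values[:, j]
        if not pool.mask[:, j].all():
            raise ValueError("pool must be observed at the target attribute")
    else:
        col = np.asarray(pool, dtype=float)[:, int(target_attr)]
    if col.size == 0:
        raise ValueError("no donors available")
    return float(col.mean())
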