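"""RReliefF attribute weighting for continuous regression targets.

ReliefF-family algorithms score attribute relevance by contrasting an
instance with its nearest neighbours: an attribute is rewarded when differing
on it co-occurs with differing on the target, and penalized when it differs
while the target does not.  Unlike correlation screens this captures
multivariate, non-linear dependencies.  For a continuous target (RReliefF)
the hit/miss dichotomy is replaced by probabilities of target difference,
accumulated as

    W[A] = N_dC&dA[A] / N_dC  -  (N_dA[A] - N_dC&dA[A]) / (m - N_dC)

where, over all m iterated instances and their k nearest neighbours with
rank-decayed contribution d_ij:

    N_dC       += diff_target * d_ij
    N_dA[A]    += diff_A * d_ij
    N_dC&dA[A] += diff_target * diff_A * d_ij

Implementation choices (deterministic by construction):

* every row is used as an iteration instance (no random subsampling),
* neighbour contributions decay with rank j as exp(-(j / sigma)^2) with
  sigma = n_neighbors / 2, normalized to sum to one,
* attribute differences are normalized by the attribute's observed range,
  so weights are scale-free; constant attributes contribute zero,
* neighbour search uses Manhattan distance on range-normalized features.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .data import DataMatrix


@dataclass
class AttributeWeights:
    """Relevance weight per candidate attribute (may be negative)."""

    weights: np.ndarray
    attr_names: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1 or len(self.attr_names) != self.weights.size:
            raise ValueError("one weight per attribute required")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")


def _normalize_by_range(x: np.ndarray) -> np.ndarray:
    lo = x.min(axis=0)
    rng = x.max(axis=0) - lo
    rng = np.where(rng == 0.0, 1.0, rng)  # constant columns -> zero diffs
    return (x - lo) / rng


def rrelieff_weights(
    features: DataMatrix | np.ndarray,
    target: Sequence[float],
    n_neighbors: int = 10,
    attr_names: list[str] | None = None,
) -> AttributeWeights:
    """RReliefF weights of each feature for a continuous target.

    Runs on complete data only (no NaNs).  Deterministic and invariant to
    row order: all rows serve as iteration instances.
    """
    if isinstance(features, DataMatrix):
        if not features.mask.all():
            raise ValueError("RReliefF requires complete data")
        X = features.values
        names = list(features.attr_names)
    else:
        X = np.asarray(features, dtype=float)
        names = attr_names if attr_names is not None else [f"a{i}" for i in range(X.shape[1])]
    y = np.asarray(target, dtype=float)
    m, q = X.shape
    if y.shape != (m,):
        raise ValueError("target must align with feature rows")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("RReliefF requires complete data")
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    if m <= n_neighbors:
        raise ValueError("need more rows than neighbors")
    y_range = y.max() - y.min()
    if y_range == 0.0:
        raise ValueError("degenerate regression target")

    Xn = _normalize_by_range(X)
    yn = (y - y.min()) / y_range

    D = cdist(Xn, Xn, metric="cityblock")
    np.fill_diagonal(D, np.inf)
    # stable argsort: neighbour ties broken by ascending row index
    nbr = np.argsort(D, axis=1, kind="stable")[:, :n_neighbors]  # (m, k)

    ranks = np.arange(1, n_neighbors + 1, dtype=float)
    sigma = n_neighbors / 2.0
    w = np.exp(-((ranks / sigma) ** 2))
    w /= w.sum()  # (k,) identical for every instance

    d_c = np.abs(yn[:, None] - yn[nbr])  # (m, k)
    d_a = np.abs(Xn[:, None, :] - Xn[nbr, :])  # (m, k, q)

    n_dc = float(np.sum(d_c * w[None, :]))
    n_da = np.einsum("ika,k->a", d_a, w)
    n_dcda = np.einsum("ik,ika,k->a", d_c, d_a, w)

    if n_dc == 0.0 or n_dc >= m:
        raise ValueError("degenerate regression target")
    weights = n_dcda / n_dc - (n_da - n_dcda) / (m - n_dc)
    return AttributeWeights(weights, names)


def select_top_fraction(weights: AttributeWeights, fraction: float) -> list[int]:
    """Indices of the top ``ceil(fraction * q)`` attributes by weight.

    Ties are broken by ascending attribute index; the result is returned in
    original attribute order.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    q = weights.weights.size
    s = ceil(fraction * q)
    # sort by descending weight, ties by ascending index
    order = np.lexsort((np.arange(q), -weights.weights))
    return sorted(int(i) for i in order[:s])
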