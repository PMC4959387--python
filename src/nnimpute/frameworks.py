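"""Imputation frameworks: plain, ReliefF-filtered, bagged, random-subspace,
fully randomized, and a mean-imputation baseline.

Every framework maps an incomplete :class:`~nnimpute.data.DataMatrix` to a
completed one.  Donors are always the complete cases C(X); each missing
attribute is imputed independently, and imputed values are never reused as
donor features within the same pass.  The frameworks differ in what the
nearest-neighbour search sees:

plain
    all candidate attributes against the full donor pool,
filtered
    attribute subset selected once per target attribute by RReliefF on C(X),
bagged
    an ensemble over with-replacement donor subsamples of size
    ``ceil(bag_fraction * m)`` (averaged over ``ensemble_runs`` runs),
subspace
    an ensemble over random attribute subsets of size ``l = floor(sqrt(q))``,
full_random
    both randomizations combined, random-forest style.

Candidate attributes exclude the target attribute, the outcome (unless
``include_outcome``), and any attribute unobserved in the recipient.
Ensembles are reproducible: each missing cell gets its own RNG substream
derived from ``(seed, row, column)``, so results do not depend on the order
in which cells are processed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import DataMatrix
from .neighbors import METHODS, _pairwise_distances, aggregate_donor_values
from .relieff import rrelieff_weights, select_top_fraction

FRAMEWORKS = ("plain", "filtered", "bagged", "subspace", "full_random")


@dataclass
class ImputationConfig:
    """All knobs of the imputer.

    Defaults follow the benchmark study: k = 5 donors, Euclidean metric,
    RReliefF with 10 neighbours keeping the top 10 % of attributes, donor
    bags of 10 % of the pool, 50 ensemble runs, and z-scored features in the
    distance (standardized by the complete-case mean and SD; attributes in
    this kind of table differ by orders of magnitude, and unstandardized
    distances let a single large-scale attribute dominate the metric).
    """

    method: str = "knn"  # 1nn | knn | wknn | mean
    k: int = 5
    p: float = 2.0  # Minkowski exponent
    framework: str = "plain"
    relieff_fraction: float = 0.10
    relieff_neighbors: int = 10
    bag_fraction: float = 0.10
    ensemble_runs: int = 50
    subspace_size: int | None = None  # None -> floor(sqrt(q))
    standardize_features: bool = True
    include_outcome: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.framework not in FRAMEWORKS:
            raise ValueError(f"unknown framework {self.framework!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.p <= 0:
            raise ValueError("Minkowski exponent must be positive")
        if not (0.0 < self.bag_fraction <= 1.0):
            raise ValueError("bag_fraction must be in (0, 1]")
        if not (0.0 < self.relieff_fraction <= 1.0):
            raise ValueError("relieff_fraction must be in (0, 1]")
        if self.ensemble_runs < 1:
            raise ValueError("ensemble_runs must be >= 1")

    def label(self) -> str:
        """Stable identifier used for seed substreams and result tables."""
        if self.method == "mean":
            return "mean"
        return f"{self.framework}/{self.method}/k={self.k}/p={self.p:g}"


def complete_cases(dataset: DataMatrix) -> DataMatrix:
    """The donor pool C(X): exactly the rows with no missing entries."""
    return dataset.take_rows(np.flatnonzero(dataset.complete_rows()))


# ---------------------------------------------------------------------------
# shared machinery


class _Engine:
    """Per-dataset state shared by all frameworks during one imputation pass."""

    def __init__(self, dataset: DataMatrix, cfg: ImputationConfig):
        self.dataset = dataset
        self.cfg = cfg
        cc = np.flatnonzero(dataset.complete_rows())
        if cc.size == 0:
            raise ValueError("no donors available (no complete cases)")
        self.pool = dataset.values[cc]  # raw donor values (m x d)
        self.m = self.pool.shape[0]
        if cfg.method != "mean" and self.m < (1 if cfg.method == "1nn" else cfg.k):
            raise ValueError("insufficient donors: complete-case pool smaller than k")
        # matrices used for distance computation (optionally standardized)
        if cfg.standardize_features and self.m > 1:
            mu = self.pool.mean(axis=0)
            sd = self.pool.std(axis=0, ddof=1)
            sd = np.where(sd == 0.0, 1.0, sd)
            self.dist_pool = (self.pool - mu) / sd
            self.dist_rec = (dataset.values - mu) / sd
        else:
            self.dist_pool = self.pool
            self.dist_rec = dataset.values
        # candidate attribute set per target column (recipient-independent part)
        oi = dataset.outcome_index
        excl_outcome = oi is not None and not cfg.include_outcome
        self.candidates = {}
        for j in range(dataset.n_attrs):
            cand = [
                c
                for c in range(dataset.n_attrs)
                if c != j and not (excl_outcome and c == oi)
            ]
            self.candidates[j] = np.asarray(cand, dtype=int)

    def cell_rng(self, i: int, j: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.cfg.seed & 0xFFFFFFFF, i, j])
        )

    def recipient_features(self, i: int, j: int, cand: np.ndarray) -> np.ndarray:
        """Candidates observed in recipient ``i`` (pairwise-available rule)."""
        obs = self.dataset.mask[i]
        feats = cand[obs[cand]]
        if feats.size == 0:
            raise ValueError("no comparable features for recipient")
        return feats

    def nn_value(self, i: int, j: int, feats: np.ndarray) -> float:
        dist = _pairwise_distances(self.dist_pool, self.dist_rec[i], feats, self.cfg.p)
        order = np.argsort(dist, kind="stable")
        return aggregate_donor_values(
            self.pool[order, j], dist[order], self.cfg.method, self.cfg.k
        )


def _run_imputation(dataset: DataMatrix, cfg: ImputationConfig, cell_value) -> DataMatrix:
    """Fill every missing cell with ``cell_value(engine, i, j)``; repackage."""
    out = dataset.copy()
    rows, cols = np.nonzero(~dataset.mask)
    if rows.size:
        eng = _Engine(dataset, cfg)
        for i, j in zip(rows.tolist(), cols.tolist()):
            out.values[i, j] = cell_value(eng, i, j)
    out.original_mask = dataset.mask.copy()
    out.mask = np.ones_like(out.mask, dtype=bool)
    return out


def _ensure_k_feasible(m: int, size: int, k: int) -> int:
    # bag size floored at k so aggregation stays feasible
    return max(size, k)


# ---------------------------------------------------------------------------
# frameworks


def impute_mean(dataset: DataMatrix, cfg: ImputationConfig) -> DataMatrix:
    """Baseline: replace each missing value by the complete-case mean."""

    def value(eng: _Engine, i: int, j: int) -> float:
        return float(eng.pool[:, j].mean())

    return _run_imputation(dataset, cfg, value)


def impute_plain(dataset: DataMatrix, cfg: ImputationConfig) -> DataMatrix:
    """Hot-deck NN imputation against the full complete-case pool."""
    if cfg.method == "mean":
        return impute_mean(dataset, cfg)

    def value(eng: _Engine, i: int, j: int) -> float:
        feats = eng.recipient_features(i, j, eng.candidates[j])
        return eng.nn_value(i, j, feats)

    return _run_imputation(dataset, cfg, value)


def impute_filtered(dataset: DataMatrix, cfg: ImputationConfig) -> DataMatrix:
    """NN imputation on an RReliefF-selected attribute subset.

    For each attribute with missing values, weights are computed once on the
    complete cases with that attribute as the regression target; distances
    then use only the top ``relieff_fraction`` of candidates.
    """
    if cfg.method == "mean":
        return impute_mean(dataset, cfg)
    rows, cols = np.nonzero(~dataset.mask)
    if rows.size == 0:
        return impute_plain(dataset, cfg)
    eng = _Engine(dataset, cfg)
    selected: dict[int, np.ndarray] = {}
    for j in np.unique(cols):
        cand = eng.candidates[j]
        if cand.size < 2:
            raise ValueError("filtered framework needs at least 2 candidate attributes")
        names = [dataset.attr_names[c] for c in cand]
        w = rrelieff_weights(
            eng.pool[:, cand], eng.pool[:, j], cfg.relieff_neighbors, attr_names=names
        )
        keep = select_top_fraction(w, cfg.relieff_fraction)
        selected[int(j)] = cand[np.asarray(keep, dtype=int)]

    def value(eng: _Engine, i: int, j: int) -> float:
        feats = eng.recipient_features(i, j, selected[j])
        return eng.nn_value(i, j, feats)

    return _run_imputation(dataset, cfg, value)


def impute_bagged(dataset: DataMatrix, cfg: ImputationConfig) -> DataMatrix:
    """Ensemble over with-replacement donor subsamples (bagging).

    Each run draws ``ceil(bag_fraction * m)`` donors with replacement,
    imputes from that subset, and the final value is the arithmetic mean
    over ``ensemble_runs`` runs.
    """
    if cfg.method == "mean":
        return impute_mean(dataset, cfg)

    def value(eng: _Engine, i: int, j: int) -> float:
        feats = eng.recipient_features(i, j, eng.candidates[j])
        dist = _pairwise_distances(eng.dist_pool, eng.dist_rec[i], feats, cfg.p)
        size = _ensure_k_feasible(eng.m, math.ceil(cfg.bag_fraction * eng.m), cfg.k)
        rng = eng.cell_rng(i, j)
        vals = np.empty(cfg.ensemble_runs)
        for r in range(cfg.ensemble_runs):
            idx = rng.integers(0, eng.m, size)
            order = np.lexsort((idx, dist[idx]))  # distance, ties by pool row index
            sel = idx[order]
            vals[r] = aggregate_donor_values(
                eng.pool[sel, j], dist[sel], cfg.method, cfg.k
            )
        return float(vals.mean())

    return _run_imputation(dataset, cfg, value)


def _subspace_size(cfg: ImputationConfig, q: int) -> int:
    l = cfg.subspace_size if cfg.subspace_size is not None else int(math.isqrt(q))
    return max(1, l)


def impute_random_subspace(dataset: DataMatrix, cfg: ImputationConfig) -> DataMatrix:
    """Ensemble over random attribute subsets of size ``l = floor(sqrt(q))``.

    ``q`` is the number of candidate attributes after the global exclusions
    (target and, by default, the outcome), fixed per dataset so runs are
    comparable across recipients.
    """
    if cfg.method == "mean":
        return impute_mean(dataset, cfg)

    def value(eng: _Engine, i: int, j: int) -> float:
        admissible = eng.recipient_features(i, j, eng.candidates[j])
        l = min(_subspace_size(cfg, eng.candidates[j].size), admissible.size)
        rng = eng.cell_rng(i, j)
        vals = np.empty(cfg.ensemble_runs)
        for r in range(cfg.ensemble_runs):
            feats = rng.choice(admissible, size=l, replace=False)
            vals[r] = eng.nn_value(i, j, feats)
        return float(vals.mean())

    return _run_imputation(dataset, cfg, value)


def impute_full_random(dataset: DataMatrix, cfg: ImputationConfig) -> DataMatrix:
    """Random-forest-like double randomization: attribute draw, then donor bag."""
    if cfg.method == "mean":
        return impute_mean(dataset, cfg)

    def value(eng: _Engine, i: int, j: int) -> float:
        admissible = eng.recipient_features(i, j, eng.candidates[j])
        l = min(_subspace_size(cfg, eng.candidates[j].size), admissible.size)
        size = _ensure_k_feasible(eng.m, math.ceil(cfg.bag_fraction * eng.m), cfg.k)
        rng = eng.cell_rng(i, j)
        vals = np.empty(cfg.ensemble_runs)
        for r in range(cfg.ensemble_runs):
            feats = rng.choice(admissible, size=l, replace=False)
            dist = _pairwise_distances(eng.dist_pool, eng.dist_rec[i], feats, cfg.p)
            idx = rng.integers(0, eng.m, size)
            order = np.lexsort((idx, dist[idx]))
            sel = idx[order]
            vals[r] = aggregate_donor_values(
                eng.pool[sel, j], dist[sel], cfg.method, cfg.k
            )
        return float(vals.mean())

    return _run_imputation(dataset, cfg, value)


_DISPATCH = {
    "plain": impute_plain,
    "filtered": impute_filtered,
    "bagged": impute_bagged,
    "subspace": impute_random_subspace,
    "full_random": impute_full_random,
}


def impute(dataset: DataMatrix, cfg: ImputationConfig) -> DataMatrix:
    """Impute every missing cell according to ``cfg``; observed cells are untouched."""
    if cfg.method == "mean":
        return impute_mean(dataset, cfg)
    return _DISPATCH[cfg.framework](dataset, cfg)
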