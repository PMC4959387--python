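"""Estimator quality metrics and trade-off summaries.

Given repeated-sampling estimates x_1..x_n of a population truth theta:

    Bias = mean(x) - theta
    Var  = sum((x_i - mean(x))^2) / (n - 1)
    MSE  = sum((x_i - theta)^2) / n

so that MSE = Bias^2 + Var * (n-1)/n holds as an algebraic identity.

Imputation *inaccuracy* is the mean proportional absolute deviation of
imputed from true values over the originally-missing cells:

    Inaccuracy = mean_i |xhat_i - x_i| / x_i

Two trade-off helpers summarize accuracy against distribution distortion:
`k_tradeoff_intersection` finds the neighbour count where min-max-normalized
inaccuracy and SD-distortion curves cross (their average is minimal), and
`tradeoff_rank` produces the cross-configuration rank summary used for
real-data experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import DataMatrix

#: predictors of the benchmark regression model, in order
MODEL_PREDICTORS = ("X0", "X1", "X2", "X3")


@dataclass
class EstimatorSummary:
    """Bias, variance and MSE of repeated estimates against a truth value."""

    bias: float
    variance: float
    mse: float
    n_reps: int


def estimator_summary(estimates: Sequence[float], theta: float) -> EstimatorSummary:
    """Summarize repeated-sampling estimates against population truth ``theta``."""
    x = np.asarray(estimates, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 estimates (variance undefined)")
    bias = float(x.mean() - theta)
    variance = float(x.var(ddof=1))
    mse = float(np.mean((x - theta) ** 2))
    return EstimatorSummary(bias=bias, variance=variance, mse=mse, n_reps=int(x.size))


def inaccuracy(truth: Sequence[float], imputed: Sequence[float]) -> float:
    """Mean proportional absolute deviation of imputed from true values."""
    t = np.asarray(truth, dtype=float)
    v = np.asarray(imputed, dtype=float)
    if t.shape != v.shape or t.size == 0:
        raise ValueError("truth and imputed must have equal nonzero length")
    if np.any(t == 0.0):
        raise ValueError("proportional difference undefined for zero truth value")
    return float(np.mean(np.abs(v - t) / np.abs(t)))


def fit_linear_model(
    dataset: DataMatrix,
    predictors: Sequence[str] = MODEL_PREDICTORS,
    outcome: str | None = None,
) -> np.ndarray:
    """OLS fit of the outcome on ``predictors`` with intercept.

    Returns the coefficient vector ``(intercept, b_1, ..., b_p)`` in
    predictor order.  The data must be complete.
    """
    if outcome is None:
        oi = dataset.outcome_index
        if oi is None:
            raise ValueError("dataset has no outcome attribute")
        outcome = dataset.attr_names[oi]
    cols = [dataset.index(a) for a in predictors]
    X = dataset.values[:, cols]
    y = dataset.column(outcome)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("model fit requires complete data")
    design = np.column_stack([np.ones(len(y)), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient design")
    return coef


def yhat_correlation(
    dataset: DataMatrix,
    coef: np.ndarray,
    predictors: Sequence[str] = MODEL_PREDICTORS,
    outcome: str | None = None,
) -> float:
    """Pearson correlation of the model's fitted values with the true outcome."""
    if outcome is None:
        oi = dataset.outcome_index
        if oi is None:
            raise ValueError("dataset has no outcome attribute")
        outcome = dataset.attr_names[oi]
    cols = [dataset.index(a) for a in predictors]
    X = dataset.values[:, cols]
    yhat = coef[0] + X @ np.asarray(coef[1:], dtype=float)
    y = dataset.column(outcome)
    if np.std(yhat) == 0.0:
        raise ValueError("zero-variance fitted values")
    return float(np.corrcoef(yhat, y)[0, 1])


# ---------------------------------------------------------------------------
# trade-off summaries


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        warnings.warn("degenerate normalization: constant metric column", stacklevel=2)
        return np.zeros_like(x, dtype=float)
    return (x - lo) / (hi - lo)


def k_tradeoff_intersection(
    inaccuracy_by_k: Sequence[float],
    sd_mse_by_k: Sequence[float],
    k_grid: Sequence[int],
) -> int:
    """Neighbour count balancing accuracy against dispersion distortion.

    Both curves are min-max normalized over ``k_grid``.  Along increasing k
    the inaccuracy curve falls while the distortion curve rises; the best
    trade-off is where they cross: the smallest k at which normalized
    distortion strictly exceeds normalized inaccuracy.  If the curves never
    cross (e.g. degenerate or non-monotone input), the k minimizing the
    average of the two normalized curves is returned, ties going to the
    smaller k.
    """
    k = np.asarray(k_grid, dtype=int)
    if k.size < 2:
        raise ValueError("k_grid must contain at least 2 values")
    a = np.asarray(inaccuracy_by_k, dtype=float)
    b = np.asarray(sd_mse_by_k, dtype=float)
    if a.shape != k.shape or b.shape != k.shape:
        raise ValueError("curves must align with k_grid")
    order = np.argsort(k, kind="stable")
    k, a, b = k[order], a[order], b[order]
    an, bn = _minmax(a), _minmax(b)
    crossed = np.flatnonzero(bn > an)
    if crossed.size:
        return int(k[int(crossed[0])])
    avg = (an + bn) / 2.0
    return int(k[int(np.argmin(avg))])  # argmin takes the first (smallest k) on ties


def tradeoff_rank(
    inacc: pd.DataFrame,
    dispersion: pd.DataFrame,
) -> pd.Series:
    """Rank configurations by the accuracy/distortion compromise.

    Both frames are configurations (rows) by target attributes (columns);
    ``inacc`` holds mean imputation inaccuracy and ``dispersion`` the
    SD-distortion metric (e.g. MSE of the imputed variable's SD).  Per
    attribute, each metric is min-max normalized across configurations, the
    two are averaged and ranked (1 = best, average ranks on ties); the final
    rank is the rank of the mean per-attribute rank.
    """
    if not inacc.index.equals(dispersion.index) or not inacc.columns.equals(
        dispersion.columns
    ):
        raise ValueError("metric frames must share index and columns")
    if len(inacc.index) < 2 or inacc.shape[1] < 1:
        raise ValueError("need >= 2 configurations and >= 1 attribute")
    per_attr = []
    for col in inacc.columns:
        score = (_minmax(inacc[col].to_numpy()) + _minmax(dispersion[col].to_numpy())) / 2.0
        per_attr.append(rankdata(score, method="average"))
    mean_rank = np.mean(per_attr, axis=0)
    return pd.Series(rankdata(mean_rank, method="average"), index=inacc.index, name="rank")


@dataclass
class MetricTable:
    """Tidy long-format metric summaries plus run provenance.

    ``table`` has one row per configuration x metric with columns
    (rate, framework, method, k, config, metric, bias, variance, mse, mean,
    theta, n_reps).  ``meta`` carries seeds and problem sizes; ``failures``
    lists (rep, seed, error) tuples of replicates that raised.
    """

    table: pd.DataFrame
    meta: dict
    failures: list = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.failures is None:
            self.failures = []

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def lookup(self, metric: str, value: str = "mse", **keys) -> float:
        """Single metric value for a configuration, e.g.
        ``lookup('beta_X0', framework='plain', method='knn', rate=0.15)``."""
        df = self.table
        sel = df["metric"] == metric
        for col, want in keys.items():
            sel &= df[col] == want
        hits = df.loc[sel, value]
        if len(hits) != 1:
            raise KeyError(f"{len(hits)} rows match metric={metric!r}, {keys!r}")
        return float(hits.iloc[0])
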