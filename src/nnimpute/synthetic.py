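"""Synthetic benchmark population, sampling, and missingness injection.

The benchmark emulates an epidemiological table in which a continuous
outcome Y depends linearly on a handful of covariates while most attributes
are pure, "coloured" noise:

    Y = 50 + b0*X0 + b1*X1 + b2*X2 + b3*X3 + eps,
    b = (ln 2, ln 4, ln 0.5, ln 0.25),   eps ~ N(40, 4)

* (X0, X3, X4) trivariate normal: means (200, 50, 100), SDs (40, 10, 20),
  correlations r03 = 0.75, r04 = 0.6, r34 = 0.5 — X0 has informative
  partners a nearest-neighbour imputer can exploit.
* (X1, X5) bivariate normal: means (20, 500), SDs (4, 100), r = 0.5.
* X2 noncentral chi-square with df = 3 and noncentrality 20 (mean 23) —
  skewed and unrelated to everything else, the hard case.
* X6 ~ Bernoulli(0.5) and X7 ~ Uniform(30, 60) drive the MAR mechanism.
* 50 noise attributes: 15 noncentral chi-square (noncentrality in [10, 50],
  df in {2..5}), 20 normals (mu in [10, 200], sigma = mu/5), and six
  correlated multinormal blocks (3 of width 3, 3 of width 2) with means in
  [10, 100], SDs in [mu/5, mu/2] and pairwise correlations in [0.2, 0.6].
  Their hyperparameters are drawn once from ``noise_seed`` and then frozen,
  so different populations share one noise design.

Missingness is injected on single attributes, MCAR (independent Bernoulli)
or MAR, where four categories A-D built from (X6, X7 >= 48) carry
geometrically increasing risk 1 : 1.5 : 1.5^2 : 1.5^3 and the base rate is
calibrated analytically so the expected overall rate matches the request.
Pre-masking values are kept in ``DataMatrix.truth`` for scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import ROLE_AUXILIARY, ROLE_IMPUTABLE, ROLE_OUTCOME, DataMatrix
from .evaluation import fit_linear_model, yhat_correlation

#: regression coefficients (natural logs) of the population model
BETA = (math.log(2), math.log(4), math.log(0.5), math.log(0.25))

#: attributes that receive missingness in the benchmark study
STUDY_ATTRS = ("X0", "X1", "X2")


@dataclass
class PopulationSpec:
    """Every distribution parameter of the synthetic population."""

    beta: tuple[float, float, float, float] = BETA
    intercept: float = 50.0
    eps_mu: float = 40.0
    eps_sigma: float = 4.0
    block1_mu: tuple[float, float, float] = (200.0, 50.0, 100.0)  # X0, X3, X4
    block1_sd: tuple[float, float, float] = (40.0, 10.0, 20.0)
    block1_rho: tuple[float, float, float] = (0.75, 0.6, 0.5)  # r03, r04, r34
    block2_mu: tuple[float, float] = (20.0, 500.0)  # X1, X5
    block2_sd: tuple[float, float] = (4.0, 100.0)
    block2_rho: float = 0.5
    x2_noncentrality: float = 20.0
    x2_df: int = 3
    x6_p: float = 0.5
    x7_range: tuple[float, float] = (30.0, 60.0)
    n_noise: int = 50
    noise_seed: int = 97

    @property
    def x2_mean(self) -> float:
        return self.x2_df + self.x2_noncentrality


@dataclass
class MissingnessSpec:
    """Mechanism and rate of injected missingness for one attribute."""

    mechanism: str = "MCAR"  # MCAR | MAR
    rate: float = 0.15
    mar_covariates: tuple[str, str] = ("X6", "X7")
    mar_threshold: float = 48.0  # 60th percentile of Uniform(30, 60)
    risk_ratio: float = 1.5

    def __post_init__(self) -> None:
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValueError("mechanism must be MCAR or MAR")
        if not (0.0 < self.rate < 1.0):
            raise ValueError("rate must be in (0, 1)")


@dataclass
class TruthParams:
    """Population-level truth an estimator is judged against."""

    coef: np.ndarray  # OLS (intercept, b_X0, b_X1, b_X2, b_X3) on the population
    corr: float  # Pearson correlation of fitted Yhat with Y
    mean: dict[str, float]  # population mean of X0, X1, X2
    sd: dict[str, float]  # population SD (ddof=1) of X0, X1, X2

    @property
    def theta_beta(self) -> dict[str, float]:
        return {"X0": self.coef[1], "X1": self.coef[2], "X2": self.coef[3]}


# ---------------------------------------------------------------------------
# noise design


def _positive_definite_corr(rng: np.random.Generator, size: int) -> np.ndarray:
    """Random correlation matrix with entries in [0.2, 0.6]; redrawn until PD."""
    while True:
        corr = np.eye(size)
        iu = np.triu_indices(size, 1)
        corr[iu] = rng.uniform(0.2, 0.6, size=len(iu[0]))
        corr = corr + corr.T - np.eye(size)
        if np.linalg.eigvalsh(corr).min() > 1e-8:
            return corr


def _noise_design(spec: PopulationSpec) -> list[tuple]:
    """Frozen per-column noise hyperparameters, drawn once from noise_seed."""
    rng = np.random.default_rng(spec.noise_seed)
    cols: list[tuple] = []
    for _ in range(15):
        lam = rng.uniform(10.0, 50.0)
        df = int(rng.integers(2, 6))
        cols.append(("ncx2", df, lam))
    for _ in range(20):
        mu = rng.uniform(10.0, 200.0)
        cols.append(("normal", mu, mu / 5.0))
    for width in (3, 3, 3, 2, 2, 2):
        mus = rng.uniform(10.0, 100.0, width)
        sds = rng.uniform(mus / 5.0, mus / 2.0)
        corr = _positive_definite_corr(rng, width)
        cov = corr * np.outer(sds, sds)
        cols.append(("mvn", mus, cov))
    return cols


# ---------------------------------------------------------------------------
# generation


def generate_population(
    spec: PopulationSpec | None = None,
    size: int = 1_000_000,
    seed: int = 0,
) -> DataMatrix:
    """Draw a complete population table: Y, X0..X7 and 50 noise attributes."""
    if spec is None:
        spec = PopulationSpec()
    if size < 2:
        raise ValueError("population size must be >= 2")
    rng = np.random.default_rng(seed)

    sd1 = np.asarray(spec.block1_sd)
    r03, r04, r34 = spec.block1_rho
    corr1 = np.array([[1.0, r03, r04], [r03, 1.0, r34], [r04, r34, 1.0]])
    x034 = rng.multivariate_normal(spec.block1_mu, corr1 * np.outer(sd1, sd1), size=size)

    sd2 = np.asarray(spec.block2_sd)
    corr2 = np.array([[1.0, spec.block2_rho], [spec.block2_rho, 1.0]])
    x15 = rng.multivariate_normal(spec.block2_mu, corr2 * np.outer(sd2, sd2), size=size)

    x2 = rng.noncentral_chisquare(spec.x2_df, spec.x2_noncentrality, size=size)
    x6 = rng.binomial(1, spec.x6_p, size=size).astype(float)
    x7 = rng.uniform(*spec.x7_range, size=size)
    eps = rng.normal(spec.eps_mu, spec.eps_sigma, size=size)

    x0, x3, x4 = x034[:, 0], x034[:, 1], x034[:, 2]
    x1, x5 = x15[:, 0], x15[:, 1]
    b0, b1, b2, b3 = spec.beta
    y = spec.intercept + b0 * x0 + b1 * x1 + b2 * x2 + b3 * x3 + eps

    noise_cols = []
    for col in _noise_design(spec):
        kind = col[0]
        if kind == "ncx2":
            noise_cols.append(rng.noncentral_chisquare(col[1], col[2], size=size))
        elif kind == "normal":
            noise_cols.append(rng.normal(col[1], col[2], size=size))
        else:
            block = rng.multivariate_normal(col[1], col[2], size=size)
            noise_cols.extend(block.T)
    noise = np.column_stack(noise_cols)

    values = np.column_stack([y, x0, x1, x2, x3, x4, x5, x6, x7, noise])
    names = ["Y"] + [f"X{i}" for i in range(8)] + [f"N{i:02d}" for i in range(spec.n_noise)]
    roles = [ROLE_OUTCOME] + [
        ROLE_IMPUTABLE if n in STUDY_ATTRS else ROLE_AUXILIARY for n in names[1:]
    ]
    return DataMatrix(values, np.ones_like(values, dtype=bool), names, roles)


def compute_truth(population: DataMatrix) -> TruthParams:
    """Population truth: OLS coefficients, Yhat-Y correlation, moments."""
    if not population.mask.all():
        raise ValueError("truth parameters require a complete population")
    coef = fit_linear_model(population)
    corr = yhat_correlation(population, coef)
    mean = {a: float(population.column(a).mean()) for a in STUDY_ATTRS}
    sd = {a: float(population.column(a).std(ddof=1)) for a in STUDY_ATTRS}
    return TruthParams(coef=coef, corr=corr, mean=mean, sd=sd)


def draw_sample(population: DataMatrix, n: int, seed: int = 0) -> DataMatrix:
    """Uniform without-replacement row sample, deterministic per seed."""
    if n < 1 or n > population.n_cases:
        raise ValueError("sample size must be in [1, population size]")
    rng = np.random.default_rng(seed)
    idx = rng.choice(population.n_cases, size=n, replace=False)
    return population.take_rows(idx)


# ---------------------------------------------------------------------------
# missingness


def _mask_cells(dataset: DataMatrix, j: int, miss: np.ndarray) -> DataMatrix:
    out = dataset.copy()
    if out.truth is None:
        out.truth = dataset.values.copy()
    out.mask[miss, j] = False
    out.values[miss, j] = np.nan
    return out


def inject_mcar(
    dataset: DataMatrix,
    attr: str,
    rate: float,
    seed: int = 0,
    exact_count: bool = False,
) -> DataMatrix:
    """Mask ``attr`` completely at random at the given expected rate.

    With ``exact_count=True`` exactly ``round(rate * n)`` cells are masked
    instead of an independent Bernoulli draw per case.
    """
    if not (0.0 < rate < 1.0):
        raise ValueError("rate must be in (0, 1)")
    j = dataset.index(attr)
    if not dataset.mask[:, j].all():
        raise ValueError(f"attribute {attr!r} already has missing values")
    rng = np.random.default_rng(seed)
    n = dataset.n_cases
    if exact_count:
        miss = np.zeros(n, dtype=bool)
        miss[rng.choice(n, size=int(round(rate * n)), replace=False)] = True
    else:
        miss = rng.random(n) < rate
    return _mask_cells(dataset, j, miss)


def mar_categories(dataset: DataMatrix, spec: MissingnessSpec) -> np.ndarray:
    """Category code 0..3 (A..D) from the two MAR covariates."""
    c6 = dataset.column(spec.mar_covariates[0]) > 0.5
    c7 = dataset.column(spec.mar_covariates[1]) >= spec.mar_threshold
    return (c6.astype(int) + 2 * c7.astype(int)).astype(int)


def inject_mar(
    dataset: DataMatrix,
    attr: str,
    spec: MissingnessSpec,
    seed: int = 0,
) -> DataMatrix:
    """Mask ``attr`` at random given (X6, X7) with geometric category risks.

    The base probability is calibrated from the covariates' theoretical
    category frequencies (0.3, 0.3, 0.2, 0.2) so the expected overall rate
    equals ``spec.rate``.
    """
    j = dataset.index(attr)
    if not dataset.mask[:, j].all():
        raise ValueError(f"attribute {attr!r} already has missing values")
    for cov in spec.mar_covariates:
        if not dataset.mask[:, dataset.index(cov)].all():
            raise ValueError("MAR covariates must be fully observed")
    risks = spec.risk_ratio ** np.arange(4)
    # P(A..D) under X6 ~ Bernoulli(0.5), X7 uniform with threshold at its 60th pct
    cat_probs = np.array([0.3, 0.3, 0.2, 0.2])
    base = spec.rate / float(cat_probs @ risks)
    if base * risks.max() > 1.0:
        raise ValueError("unreachable rate: category probability would exceed 1")
    cats = mar_categories(dataset, spec)
    p = base * risks[cats]
    rng = np.random.default_rng(seed)
    miss = rng.random(dataset.n_cases) < p
    return _mask_cells(dataset, j, miss)


def inject_study_missingness(
    sample: DataMatrix, rate: float, seed: int
) -> DataMatrix:
    """The benchmark pattern: MAR on X0, MCAR on X1 and X2, all at ``rate``."""
    ss = np.random.SeedSequence([int(seed)]).generate_state(4)
    out = inject_mar(sample, "X0", MissingnessSpec("MAR", rate), seed=int(ss[0]))
    out = inject_mcar(out, "X1", rate, seed=int(ss[1]))
    out = inject_mcar(out, "X2", rate, seed=int(ss[2]))
    return out
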