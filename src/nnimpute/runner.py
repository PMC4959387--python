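"""Seeded orchestration of the simulation study and real-data experiments.

`run_simulation` reproduces the benchmark: repeatedly sample n cases from
the synthetic population, inject MAR missingness on X0 and MCAR on X1/X2,
impute under each configured framework/method, and summarize regression
coefficients, the fitted-vs-true outcome correlation, means, SDs and
imputation inaccuracy as bias/variance/MSE against the population truth.

`run_k_curve` runs the accuracy-versus-distortion trade-off experiment for
plain kNN over a grid of k and reports where the normalized curves cross.

`run_real_dataset` mirrors the procedure on an arbitrary complete table with
a fixed (pre-specified) regression model: MCAR-mask the model variables,
impute, refit, and rank configurations by the normalized
inaccuracy/SD-distortion compromise.

Seed discipline: one master seed; every sample draw, missingness draw and
imputation run receives a substream keyed by (purpose, rate, replicate) and,
for imputers, the configuration label — results are therefore independent of
the order in which configurations are executed.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import DataMatrix
from .evaluation import (
    MetricTable,
    estimator_summary,
    fit_linear_model,
    inaccuracy,
    k_tradeoff_intersection,
    tradeoff_rank,
    yhat_correlation,
)
from .frameworks import ImputationConfig, complete_cases, impute
from .neighbors import _pairwise_distances, aggregate_donor_values
from .relieff import rrelieff_weights, select_top_fraction
from .synthetic import (
    STUDY_ATTRS,
    PopulationSpec,
    TruthParams,
    compute_truth,
    draw_sample,
    generate_population,
    inject_mcar,
    inject_study_missingness,
)

logger = logging.getLogger(__name__)

_SAMPLE, _MISS, _CURVE = 101, 103, 107  # substream tags


def _child_seed(*keys: int) -> int:
    """Deterministic 31-bit child seed from integer keys."""
    entropy = [int(k) & 0xFFFFFFFF for k in keys]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] >> 1)


def _config_key(cfg: ImputationConfig) -> int:
    return zlib.crc32(cfg.label().encode())


def study_configurations(
    methods: Sequence[str] = ("1nn", "knn", "wknn"),
    relieff_fractions: Sequence[float] = (0.10, 0.20, 0.30),
    include_ensembles: bool = True,
    k: int = 5,
    p: float = 2.0,
) -> list[ImputationConfig]:
    """The benchmark's configuration grid: plain, filtered at each ReliefF
    fraction, the three ensembles, and the mean baseline."""
    configs = [ImputationConfig(method=m, k=k, p=p, framework="plain") for m in methods]
    for s in relieff_fractions:
        configs += [
            ImputationConfig(method=m, k=k, p=p, framework="filtered", relieff_fraction=s)
            for m in methods
        ]
    if include_ensembles:
        for fw in ("bagged", "subspace", "full_random"):
            configs += [ImputationConfig(method=m, k=k, p=p, framework=fw) for m in methods]
    configs.append(ImputationConfig(method="mean"))
    return configs


@dataclass
class ExperimentConfig:
    """Reproducible description of a full simulation study."""

    population_seed: int = 11
    noise_seed: int = 97
    master_seed: int = 202
    n_population: int = 1_000_000
    n_sample: int = 400
    n_reps: int = 500
    missing_rates: tuple[float, ...] = (0.15, 0.30)
    configurations: list[ImputationConfig] = field(default_factory=study_configurations)
    k_grid: tuple[int, ...] = tuple(range(1, 11))

    def population_spec(self) -> PopulationSpec:
        return PopulationSpec(noise_seed=self.noise_seed)


def build_population(cfg: ExperimentConfig) -> tuple[DataMatrix, TruthParams]:
    pop = generate_population(cfg.population_spec(), cfg.n_population, cfg.population_seed)
    return pop, compute_truth(pop)


def _rep_metrics(
    masked: DataMatrix, imputed: DataMatrix, attrs: Sequence[str] = STUDY_ATTRS
) -> dict[str, float]:
    coef = fit_linear_model(imputed)
    out = {"corr": yhat_correlation(imputed, coef)}
    for a in attrs:
        j = imputed.index(a)
        out[f"beta_{a}"] = float(coef[1 + list(attrs).index(a)])
        col = imputed.values[:, j]
        out[f"mean_{a}"] = float(col.mean())
        out[f"sd_{a}"] = float(col.std(ddof=1))
        holes = ~masked.mask[:, j]
        if holes.any():
            out[f"inaccuracy_{a}"] = inaccuracy(masked.truth[holes, j], col[holes])
        else:
            out[f"inaccuracy_{a}"] = np.nan
    return out


def run_simulation(
    cfg: ExperimentConfig,
    population: DataMatrix | None = None,
    truth: TruthParams | None = None,
    progress: Callable[[int], None] | None = None,
) -> MetricTable:
    """Run the full repeated-sampling study and summarize it per configuration."""
    if population is None:
        population, truth = build_population(cfg)
    elif truth is None:
        truth = compute_truth(population)

    estimates: dict[tuple, dict[str, list[float]]] = {}
    failures: list[tuple] = []
    for rate in cfg.missing_rates:
        rtag = int(round(rate * 100))
        for rep in range(cfg.n_reps):
            sample = draw_sample(
                population, cfg.n_sample, seed=_child_seed(cfg.master_seed, _SAMPLE, rtag, rep)
            )
            miss_seed = _child_seed(cfg.master_seed, _MISS, rtag, rep)
            masked = inject_study_missingness(sample, rate, seed=miss_seed)
            for ic in cfg.configurations:
                run_cfg = replace(
                    ic, seed=_child_seed(cfg.master_seed, _config_key(ic), rtag, rep)
                )
                try:
                    imputed = impute(masked, run_cfg)
                    metrics = _rep_metrics(masked, imputed)
                except Exception as exc:  # noqa: BLE001 - reported, not dropped
                    logger.warning(
                        "rep %d (rate %.2f, seed %d, %s) failed: %s",
                        rep, rate, miss_seed, ic.label(), exc,
                    )
                    failures.append((rate, rep, ic.label(), miss_seed, repr(exc)))
                    continue
                store = estimates.setdefault((rate, ic.label()), {})
                for key, val in metrics.items():
                    store.setdefault(key, []).append(val)
            if progress is not None:
                progress(rep)

    theta_map = {"corr": truth.corr}
    for a in STUDY_ATTRS:
        theta_map[f"beta_{a}"] = truth.theta_beta[a]
        theta_map[f"mean_{a}"] = truth.mean[a]
        theta_map[f"sd_{a}"] = truth.sd[a]

    rows = []
    by_label = {ic.label(): ic for ic in cfg.configurations}
    for (rate, label), store in estimates.items():
        ic = by_label[label]
        for metric, vals in store.items():
            arr = np.asarray(vals, dtype=float)
            arr = arr[~np.isnan(arr)]
            base = dict(
                rate=rate,
                framework="mean" if ic.method == "mean" else ic.framework,
                method=ic.method,
                k=ic.k,
                config=label,
                metric=metric,
                n_reps=int(arr.size),
            )
            if metric.startswith("inaccuracy"):
                rows.append(
                    base | dict(bias=np.nan, variance=np.nan, mse=np.nan,
                                mean=float(arr.mean()), theta=np.nan)
                )
            else:
                s = estimator_summary(arr, theta_map[metric])
                rows.append(
                    base | dict(bias=s.bias, variance=s.variance, mse=s.mse,
                                mean=float(arr.mean()), theta=theta_map[metric])
                )
    table = pd.DataFrame(rows)
    meta = dict(
        master_seed=cfg.master_seed,
        population_seed=cfg.population_seed,
        noise_seed=cfg.noise_seed,
        n_population=cfg.n_population,
        n_sample=cfg.n_sample,
        n_reps=cfg.n_reps,
        missing_rates=list(cfg.missing_rates),
    )
    return MetricTable(table=table, meta=meta, failures=failures)


# ---------------------------------------------------------------------------
# k trade-off curve


@dataclass
class KCurveResult:
    """Accuracy and distortion curves over a grid of neighbour counts."""

    k_grid: list[int]
    inaccuracy: list[float]  # mean inaccuracy per k
    sd_mse: list[float]  # MSE of the imputed variable's SD per k
    sd_mean: list[float]  # mean imputed-variable SD per k
    best_k: int
    n_reps: int

    def curves_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(k=self.k_grid, inaccuracy=self.inaccuracy,
                 sd_mse=self.sd_mse, sd_mean=self.sd_mean)
        )


def run_k_curve(
    cfg: ExperimentConfig,
    attr: str = "X0",
    rate: float = 0.30,
    n_reps: int = 100,
    population: DataMatrix | None = None,
    truth: TruthParams | None = None,
    framework: str = "plain",
    relieff_fraction: float = 0.20,
    p: float = 2.0,
    standardize_features: bool = True,
) -> KCurveResult:
    """Trade-off experiment: plain (or filtered) kNN on one MCAR-masked
    attribute across ``cfg.k_grid``, sharing one donor ranking per recipient."""
    if population is None:
        population, truth = build_population(cfg)
    elif truth is None:
        truth = compute_truth(population)
    k_grid = sorted(cfg.k_grid)
    kmax = max(k_grid)
    rtag = int(round(rate * 100))

    inacc = {k: [] for k in k_grid}
    sds = {k: [] for k in k_grid}
    for rep in range(n_reps):
        sample = draw_sample(
            population, cfg.n_sample, seed=_child_seed(cfg.master_seed, _SAMPLE, _CURVE, rtag, rep)
        )
        masked = inject_mcar(
            sample, attr, rate, seed=_child_seed(cfg.master_seed, _MISS, _CURVE, rtag, rep)
        )
        pool = complete_cases(masked)
        if pool.n_cases < kmax:
            raise ValueError("insufficient donors for the largest k in the grid")
        j = masked.index(attr)
        oi = masked.outcome_index
        cand = np.array(
            [c for c in range(masked.n_attrs) if c != j and c != oi], dtype=int
        )
        if framework == "filtered":
            names = [masked.attr_names[c] for c in cand]
            w = rrelieff_weights(pool.values[:, cand], pool.values[:, j], attr_names=names)
            cand = cand[np.asarray(select_top_fraction(w, relieff_fraction), dtype=int)]
        if standardize_features:
            mu = pool.values.mean(axis=0)
            sd = pool.values.std(axis=0, ddof=1)
            sd = np.where(sd == 0.0, 1.0, sd)
            dist_pool = (pool.values - mu) / sd
            dist_rec = (masked.values - mu) / sd
        else:
            dist_pool, dist_rec = pool.values, masked.values
        holes = np.flatnonzero(~masked.mask[:, j])
        imputed_by_k = {k: masked.values[:, j].copy() for k in k_grid}
        for i in holes:
            dist = _pairwise_distances(dist_pool, dist_rec[i], cand, p)
            order = np.argsort(dist, kind="stable")
            dvals, dsort = pool.values[order, j], dist[order]
            for k in k_grid:
                imputed_by_k[k][i] = aggregate_donor_values(dvals, dsort, "knn", k)
        truths = masked.truth[holes, j]
        for k in k_grid:
            col = imputed_by_k[k]
            inacc[k].append(inaccuracy(truths, col[holes]))
            sds[k].append(float(col.std(ddof=1)))

    inacc_curve = [float(np.mean(inacc[k])) for k in k_grid]
    sd_mse_curve = [estimator_summary(sds[k], truth.sd[attr]).mse for k in k_grid]
    sd_mean_curve = [float(np.mean(sds[k])) for k in k_grid]
    if len(k_grid) == 1:
        best = int(k_grid[0])  # nothing to trade off
    else:
        best = k_tradeoff_intersection(inacc_curve, sd_mse_curve, k_grid)
    return KCurveResult(
        k_grid=list(k_grid),
        inaccuracy=inacc_curve,
        sd_mse=sd_mse_curve,
        sd_mean=sd_mean_curve,
        best_k=best,
        n_reps=n_reps,
    )


# ---------------------------------------------------------------------------
# real (or stand-in) complete datasets with a fixed model


@dataclass
class ModelSpec:
    """A fixed, pre-specified regression model refit after each imputation."""

    outcome: str
    predictors: list[str]
    kind: str = "auto"  # auto | linear | logistic

    def resolve_kind(self, y: np.ndarray) -> str:
        if self.kind != "auto":
            return self.kind
        return "logistic" if set(np.unique(y)) <= {0.0, 1.0} else "linear"


def _fit_fixed_model(dataset: DataMatrix, model: ModelSpec) -> np.ndarray:
    """Per-predictor coefficients of the fixed model (intercept dropped)."""
    y = dataset.column(model.outcome)
    kind = model.resolve_kind(y)
    if kind == "linear":
        coef = fit_linear_model(dataset, predictors=model.predictors, outcome=model.outcome)
        return np.asarray(coef[1:], dtype=float)
    import statsmodels.api as sm

    X = np.column_stack([dataset.column(a) for a in model.predictors])
    fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0, maxiter=200)
    return np.asarray(fit.params[1:], dtype=float)


def run_real_dataset(
    data: DataMatrix,
    model: ModelSpec,
    rate: float = 0.15,
    n_reps: int = 500,
    configurations: Sequence[ImputationConfig] | None = None,
    master_seed: int = 0,
) -> tuple[MetricTable, pd.Series]:
    """MCAR-mask the model variables of a complete table, impute, refit, rank.

    Truth is the complete-data fit (coefficients and per-variable SDs); the
    returned Series ranks configurations by the averaged normalized
    inaccuracy and SD-distortion, 1 = best trade-off.
    """
    if not data.mask.all():
        raise ValueError("real-data experiment requires a complete table")
    for a in model.predictors + [model.outcome]:
        data.index(a)  # raises on absent model variable
    if configurations is None:
        configurations = [
            ImputationConfig(method="wknn", k=k, framework=fw)
            for fw in ("plain", "filtered")
            for k in (1, 3, 10)
        ]
    theta_coef = _fit_fixed_model(data, model)
    theta_sd = {a: float(data.column(a).std(ddof=1)) for a in model.predictors}

    store: dict[str, dict[str, list[float]]] = {}
    failures: list[tuple] = []
    rtag = int(round(rate * 100))
    for rep in range(n_reps):
        masked = data
        for ai, a in enumerate(model.predictors):
            masked = inject_mcar(
                masked, a, rate, seed=_child_seed(master_seed, _MISS, rtag, rep, ai)
            )
        for ic in configurations:
            run_cfg = replace(ic, seed=_child_seed(master_seed, _config_key(ic), rtag, rep))
            try:
                imputed = impute(masked, run_cfg)
                coef = _fit_fixed_model(imputed, model)
            except Exception as exc:  # noqa: BLE001
                logger.warning("real-data rep %d (%s) failed: %s", rep, ic.label(), exc)
                failures.append((rate, rep, ic.label(), repr(exc)))
                continue
            rec = store.setdefault(ic.label(), {})
            for ai, a in enumerate(model.predictors):
                j = imputed.index(a)
                holes = ~masked.mask[:, j]
                rec.setdefault(f"coef_{a}", []).append(float(coef[ai]))
                rec.setdefault(f"sd_{a}", []).append(float(imputed.values[:, j].std(ddof=1)))
                if holes.any():
                    rec.setdefault(f"inaccuracy_{a}", []).append(
                        inaccuracy(masked.truth[holes, j], imputed.values[holes, j])
                    )

    rows = []
    labels = [ic.label() for ic in configurations if ic.label() in store]
    inacc_df = pd.DataFrame(index=labels, columns=model.predictors, dtype=float)
    sd_df = pd.DataFrame(index=labels, columns=model.predictors, dtype=float)
    for label in labels:
        ic = next(c for c in configurations if c.label() == label)
        rec = store[label]
        for ai, a in enumerate(model.predictors):
            coef_s = estimator_summary(rec[f"coef_{a}"], float(theta_coef[ai]))
            sd_s = estimator_summary(rec[f"sd_{a}"], theta_sd[a])
            mean_inacc = float(np.mean(rec[f"inaccuracy_{a}"]))
            inacc_df.loc[label, a] = mean_inacc
            sd_df.loc[label, a] = sd_s.mse
            rows += [
                dict(rate=rate, framework=ic.framework, method=ic.method, k=ic.k,
                     config=label, metric=f"coef_{a}", bias=coef_s.bias,
                     variance=coef_s.variance, mse=coef_s.mse,
                     mean=float(np.mean(rec[f"coef_{a}"])), theta=float(theta_coef[ai]),
                     n_reps=coef_s.n_reps),
                dict(rate=rate, framework=ic.framework, method=ic.method, k=ic.k,
                     config=label, metric=f"sd_{a}", bias=sd_s.bias,
                     variance=sd_s.variance, mse=sd_s.mse,
                     mean=float(np.mean(rec[f"sd_{a}"])), theta=theta_sd[a],
                     n_reps=sd_s.n_reps),
                dict(rate=rate, framework=ic.framework, method=ic.method, k=ic.k,
                     config=label, metric=f"inaccuracy_{a}", bias=np.nan,
                     variance=np.nan, mse=np.nan, mean=mean_inacc, theta=np.nan,
                     n_reps=len(rec[f"inaccuracy_{a}"])),
            ]
    ranks = tradeoff_rank(inacc_df, sd_df)
    meta = dict(master_seed=master_seed, rate=rate, n_reps=n_reps,
                predictors=list(model.predictors), outcome=model.outcome)
    return MetricTable(table=pd.DataFrame(rows), meta=meta, failures=failures), ranks
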