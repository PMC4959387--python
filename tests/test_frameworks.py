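"""The imputation frameworks and their shared invariants."""

import numpy as np
import pytest

from nnimpute import (
    DataMatrix,
    ImputationConfig,
    complete_cases,
    draw_sample,
    impute,
    inject_mcar,
    inject_study_missingness,
)

ALL_FRAMEWORK_CONFIGS = [
    ImputationConfig(method="1nn", framework="plain"),
    ImputationConfig(method="knn", k=3, framework="plain"),
    ImputationConfig(method="wknn", k=3, framework="plain"),
    ImputationConfig(method="knn", k=3, framework="filtered", relieff_fraction=0.3),
    ImputationConfig(method="knn", k=3, framework="bagged", ensemble_runs=10),
    ImputationConfig(method="knn", k=3, framework="subspace", ensemble_runs=10),
    ImputationConfig(method="knn", k=3, framework="full_random", ensemble_runs=10),
    ImputationConfig(method="mean"),
]


@pytest.fixture
def masked_sample(population):
    sample = draw_sample(population, 150, seed=21)
    return inject_study_missingness(sample, 0.15, seed=22)


def test_complete_cases_toy():
    values = np.array([[1.0, 2.0], [np.nan, 3.0], [4.0, 5.0], [6.0, 7.0]])
    dm = DataMatrix(values, ~np.isnan(values), ["a", "b"])
    cc = complete_cases(dm)
    assert cc.n_cases == 3
    np.testing.assert_allclose(cc.values[:, 0], [1.0, 4.0, 6.0])
    full = complete_cases(cc)
    np.testing.assert_array_equal(full.values, cc.values)


def test_complete_case_fraction(population):
    """Independent 15% missingness on 3 attributes leaves ~0.85^3 complete."""
    sample = draw_sample(population, 4000, seed=31)
    m = sample
    for i, a in enumerate(("X0", "X1", "X2")):
        m = inject_mcar(m, a, 0.15, seed=100 + i)
    frac = complete_cases(m).n_cases / 4000
    assert frac == pytest.approx(0.85**3, abs=0.03)


def test_plain_toy_values(toy_table):
    one = impute(toy_table, ImputationConfig(method="1nn", framework="plain"))
    assert one.values[3, 1] == pytest.approx(10.0)
    two = impute(toy_table, ImputationConfig(method="knn", k=2, framework="plain"))
    assert two.values[3, 1] == pytest.approx(15.0)
    assert one.mask.all() and not one.original_mask[3, 1]


def test_mean_method_fills_pool_mean(toy_table):
    out = impute(toy_table, ImputationConfig(method="mean"))
    assert out.values[3, 1] == pytest.approx((10 + 20 + 50) / 3)


def test_no_missing_is_identity(population):
    sample = draw_sample(population, 60, seed=41)
    out = impute(sample, ImputationConfig(method="knn", k=3))
    np.testing.assert_array_equal(out.values, sample.values)


def test_insufficient_donors_rejected(toy_table):
    with pytest.raises(ValueError, match="insufficient donors"):
        impute(toy_table, ImputationConfig(method="knn", k=5, framework="plain"))


def test_filtered_full_fraction_equals_plain(masked_sample):
    cfg = ImputationConfig(method="knn", k=3, framework="filtered", relieff_fraction=1.0)
    filt = impute(masked_sample, cfg)
    plain = impute(masked_sample, ImputationConfig(method="knn", k=3, framework="plain"))
    np.testing.assert_allclose(filt.values, plain.values)


def test_filtered_selects_duplicated_target_feature():
    """A feature that duplicates the target must survive the filter."""
    rng = np.random.default_rng(5)
    n = 60
    target = rng.normal(50, 10, n)
    copy = target.copy()
    noise = rng.normal(0, 1, size=(n, 6))
    values = np.column_stack([target, copy, noise])
    values[0, 0] = np.nan
    dm = DataMatrix(values, ~np.isnan(values), ["t", "dup"] + [f"n{i}" for i in range(6)])
    out = impute(dm, ImputationConfig(method="1nn", framework="filtered",
                                      relieff_fraction=0.14, relieff_neighbors=5))
    # with the duplicate driving the distance, the nearest donor shares its value
    donor = np.argmin(np.abs(copy[1:] - copy[0])) + 1
    assert out.values[0, 0] == pytest.approx(target[donor])


def test_bagged_degenerate_cases():
    # constant donor values: the imputed value is that constant for any seed
    values = np.array([[0.0, 7.0], [1.0, 7.0], [2.0, 7.0], [0.5, np.nan]])
    dm = DataMatrix(values, ~np.isnan(values), ["a", "b"])
    for seed in (1, 2, 3):
        out = impute(dm, ImputationConfig(method="1nn", framework="bagged",
                                          ensemble_runs=5, seed=seed))
        assert out.values[3, 1] == pytest.approx(7.0)
    # pool of one donor: every run returns that donor's value
    one = DataMatrix(np.array([[0.0, 3.0], [0.5, np.nan]]),
                     ~np.isnan(np.array([[0.0, 3.0], [0.5, np.nan]])), ["a", "b"])
    out = impute(one, ImputationConfig(method="1nn", framework="bagged", ensemble_runs=7))
    assert out.values[1, 1] == pytest.approx(3.0)


def test_subspace_single_candidate_equals_plain():
    values = np.array([[1.0, 10.0], [2.0, 20.0], [10.0, 50.0], [1.5, np.nan]])
    dm = DataMatrix(values, ~np.isnan(values), ["a", "b"])
    sub = impute(dm, ImputationConfig(method="knn", k=2, framework="subspace",
                                      ensemble_runs=8, seed=3))
    plain = impute(dm, ImputationConfig(method="knn", k=2, framework="plain"))
    assert sub.values[3, 1] == pytest.approx(plain.values[3, 1])


def test_full_random_single_donor():
    values = np.array([[0.0, 3.0], [0.5, np.nan]])
    dm = DataMatrix(values, ~np.isnan(values), ["a", "b"])
    out = impute(dm, ImputationConfig(method="1nn", framework="full_random",
                                      ensemble_runs=6, seed=9))
    assert out.values[1, 1] == pytest.approx(3.0)


def test_ensemble_averaging_reduces_seed_variance():
    """The 50-run ensemble's imputed value varies less across seeds than a
    single randomized run (averaging effect)."""
    rng = np.random.default_rng(11)
    donors = np.column_stack([rng.normal(0, 1, 30), rng.normal(10, 5, 30)])
    values = np.vstack([donors, [0.1, np.nan]])
    dm = DataMatrix(values, ~np.isnan(values), ["a", "b"])

    def final_value(runs, seed):
        cfg = ImputationConfig(method="1nn", framework="full_random",
                               ensemble_runs=runs, seed=seed)
        return impute(dm, cfg).values[30, 1]

    many = np.array([final_value(20, s) for s in range(20)])
    single = np.array([final_value(1, s) for s in range(20)])
    assert many.var() < single.var()


@pytest.mark.parametrize("cfg", ALL_FRAMEWORK_CONFIGS, ids=lambda c: c.label())
def test_framework_invariants(masked_sample, cfg):
    """Observed cells bit-identical; output complete; deterministic per seed;
    imputed values inside the donor pool's [min, max] for their attribute."""
    out1 = impute(masked_sample, cfg)
    out2 = impute(masked_sample, cfg)
    np.testing.assert_array_equal(out1.values, out2.values)  # determinism
    assert out1.mask.all()
    obs = masked_sample.mask
    np.testing.assert_array_equal(out1.values[obs], masked_sample.values[obs])
    pool = complete_cases(masked_sample)
    holes = ~masked_sample.mask
    for j in np.unique(np.nonzero(holes)[1]):
        col = pool.values[:, j]
        imputed = out1.values[holes[:, j], j]
        assert imputed.min() >= col.min() - 1e-9
        assert imputed.max() <= col.max() + 1e-9


def test_plain_1nn_values_occur_in_pool(masked_sample):
    out = impute(masked_sample, ImputationConfig(method="1nn", framework="plain"))
    pool = complete_cases(masked_sample)
    holes = ~masked_sample.mask
    for j in np.unique(np.nonzero(holes)[1]):
        for v in out.values[holes[:, j], j]:
            assert np.isclose(pool.values[:, j], v).any()


def test_seed_changes_ensemble_output(masked_sample):
    a = impute(masked_sample, ImputationConfig(method="knn", k=3, framework="bagged",
                                               ensemble_runs=5, seed=1))
    b = impute(masked_sample, ImputationConfig(method="knn", k=3, framework="bagged",
                                               ensemble_runs=5, seed=2))
    assert not np.array_equal(a.values, b.values)


def test_subspace_size_rule():
    from nnimpute.frameworks import _subspace_size

    cfg = ImputationConfig(framework="subspace")
    assert _subspace_size(cfg, 57) == 7  # floor(sqrt(57))
    assert _subspace_size(cfg, 1) == 1
    assert _subspace_size(ImputationConfig(framework="subspace", subspace_size=4), 57) == 4


def test_config_validation():
    with pytest.raises(ValueError):
        ImputationConfig(method="median")
    with pytest.raises(ValueError):
        ImputationConfig(framework="boosted")
    with pytest.raises(ValueError):
        ImputationConfig(k=0)
    with pytest.raises(ValueError):
        ImputationConfig(bag_fraction=0.0)
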