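"""Synthetic population, sampling, and MCAR/MAR missingness mechanisms."""

import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from nnimpute import (
    MissingnessSpec,
    PopulationSpec,
    compute_truth,
    draw_sample,
    generate_population,
    inject_mar,
    inject_mcar,
    inject_study_missingness,
)
from nnimpute.synthetic import _noise_design, mar_categories


def test_population_shape_and_roles(population):
    assert population.n_attrs == 59
    assert population.attr_names[:9] == ["Y"] + [f"X{i}" for i in range(8)]
    assert population.outcome_index == 0
    assert population.mask.all()


def test_population_moments(population):
    n = population.n_cases
    x0 = population.column("X0")
    assert x0.mean() == pytest.approx(200.0, abs=3 * 40 / math.sqrt(n))
    assert x0.std(ddof=1) == pytest.approx(40.0, rel=0.02)
    assert np.corrcoef(x0, population.column("X3"))[0, 1] == pytest.approx(0.75, abs=0.01)
    assert np.corrcoef(x0, population.column("X4"))[0, 1] == pytest.approx(0.60, abs=0.01)
    assert np.corrcoef(population.column("X1"), population.column("X5"))[0, 1] == pytest.approx(
        0.5, abs=0.01
    )
    # noncentral chi-square: mean df + lambda, variance 2(df + 2 lambda)
    x2 = population.column("X2")
    assert x2.mean() == pytest.approx(23.0, abs=0.2)
    assert x2.var(ddof=1) == pytest.approx(2 * (3 + 40), rel=0.05)
    assert population.column("X6").mean() == pytest.approx(0.5, abs=0.01)
    x7 = population.column("X7")
    assert 30.0 <= x7.min() and x7.max() <= 60.0


def test_population_reproducible_and_noise_design_frozen():
    spec = PopulationSpec()
    a = generate_population(spec, 500, seed=5)
    b = generate_population(spec, 500, seed=5)
    np.testing.assert_array_equal(a.values, b.values)
    design = _noise_design(spec)
    assert sum(3 if c[0] == "mvn" and len(c[1]) == 3 else 2 if c[0] == "mvn" else 1
               for c in design) == 50
    assert repr(design) == repr(_noise_design(spec))  # frozen given noise_seed
    # a different population seed shares the same noise design
    c = generate_population(spec, 500, seed=6)
    assert not np.array_equal(a.values, c.values)


def test_compute_truth_recovers_model(population, truth):
    assert truth.coef[1] == pytest.approx(math.log(2), abs=0.02)
    assert truth.coef[2] == pytest.approx(math.log(4), abs=0.05)
    assert truth.coef[3] == pytest.approx(math.log(0.5), abs=0.02)
    assert truth.sd["X0"] == pytest.approx(40.0, rel=0.02)
    assert 0.95 < truth.corr < 1.0


def test_noise_free_population_has_perfect_correlation():
    spec = PopulationSpec(eps_sigma=0.0)
    pop = generate_population(spec, 3000, seed=1)
    truth = compute_truth(pop)
    assert truth.corr == pytest.approx(1.0, abs=1e-9)


def test_draw_sample(population):
    s = draw_sample(population, 400, seed=3)
    assert s.values.shape == (400, 59)
    np.testing.assert_array_equal(
        s.values, draw_sample(population, 400, seed=3).values
    )
    assert not np.array_equal(s.values, draw_sample(population, 400, seed=4).values)
    small = generate_population(PopulationSpec(), 50, seed=0)
    perm = draw_sample(small, 50, seed=1)
    np.testing.assert_allclose(
        np.sort(perm.values[:, 0]), np.sort(small.values[:, 0])
    )
    with pytest.raises(ValueError):
        draw_sample(small, 51)


def test_inject_mcar_counts_and_truth_store(population):
    s = draw_sample(population, 400, seed=7)
    m = inject_mcar(s, "X1", 0.15, seed=9)
    j = m.index("X1")
    n_miss = int((~m.mask[:, j]).sum())
    # Binomial(400, 0.15): mean 60, sd ~7.1; allow 4 sd
    assert 32 <= n_miss <= 89
    assert np.isnan(m.values[~m.mask[:, j], j]).all()
    # hidden truth store recovers the pre-masking table exactly
    np.testing.assert_allclose(m.truth, s.values)
    np.testing.assert_allclose(m.values[m.mask], s.values[m.mask])
    exact = inject_mcar(s, "X1", 0.15, seed=9, exact_count=True)
    assert int((~exact.mask[:, j]).sum()) == 60
    with pytest.raises(ValueError):
        inject_mcar(m, "X1", 0.15)  # already missing


def test_mcar_masking_independent_of_value(population):
    """Masked and unmasked true values are exchangeable: a rank test is
    non-significant at alpha = 0.01 in >= 53 of 60 seeded runs."""
    ok = 0
    for seed in range(60):
        s = draw_sample(population, 400, seed=3000 + seed)
        m = inject_mcar(s, "X2", 0.3, seed=4000 + seed)
        j = m.index("X2")
        miss = ~m.mask[:, j]
        p = mannwhitneyu(m.truth[miss, j], m.truth[~miss, j]).pvalue
        ok += p > 0.01
    assert ok >= 53


def test_inject_mar_category_risks(population):
    """Per-category missingness rates follow 1 : 1.5 : 1.5^2 : 1.5^3."""
    spec = MissingnessSpec("MAR", 0.15)
    counts = np.zeros(4)
    misses = np.zeros(4)
    for seed in range(200):
        s = draw_sample(population, 400, seed=5000 + seed)
        m = inject_mar(s, "X0", spec, seed=6000 + seed)
        cats = mar_categories(m, spec)
        miss = ~m.mask[:, m.index("X0")]
        for c in range(4):
            counts[c] += (cats == c).sum()
            misses[c] += miss[cats == c].sum()
    rates = misses / counts
    ratios = rates / rates[0]
    np.testing.assert_allclose(ratios, [1.0, 1.5, 2.25, 3.375], rtol=0.12)
    assert misses.sum() / counts.sum() == pytest.approx(0.15, rel=0.05)
    # analytic base: 0.15 / 1.875 = 0.08 -> P(miss | D) = 0.27
    assert rates[3] == pytest.approx(0.27, rel=0.12)


def test_inject_mar_unreachable_rate(population):
    s = draw_sample(population, 400, seed=1)
    with pytest.raises(ValueError, match="unreachable rate"):
        inject_mar(s, "X0", MissingnessSpec("MAR", 0.60))


def test_mar_value_independent_within_category(population):
    """Within a MAR category the masking is independent of the X0 value."""
    spec = MissingnessSpec("MAR", 0.30)
    ok = 0
    for seed in range(40):
        s = draw_sample(population, 400, seed=7000 + seed)
        m = inject_mar(s, "X0", spec, seed=8000 + seed)
        cats = mar_categories(m, spec)
        j = m.index("X0")
        miss = ~m.mask[:, j]
        sel = cats == 3  # the highest-risk category has enough masked cases
        p = mannwhitneyu(m.truth[sel & miss, j], m.truth[sel & ~miss, j]).pvalue
        ok += p > 0.01
    assert ok >= 35


def test_inject_study_missingness(population):
    s = draw_sample(population, 400, seed=2)
    m = inject_study_missingness(s, 0.15, seed=3)
    missing_by_attr = {
        a: int((~m.mask[:, m.index(a)]).sum()) for a in ("X0", "X1", "X2")
    }
    assert all(v > 0 for v in missing_by_attr.values())
    assert m.mask[:, m.index("Y")].all()
    np.testing.assert_allclose(m.truth, s.values)
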