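# Methods

This note documents the models, estimators and numerical choices behind
`nnimpute`: what the synthetic benchmark generates, how each imputation
framework works, how results are scored, and where the design was genuinely
open and a choice had to be made.

## The synthetic population

`generate_population` draws a complete table of 59 attributes:

* **Outcome.** Y = 50 + ln(2)·X0 + ln(4)·X1 + ln(0.5)·X2 + ln(0.25)·X3 + ε
  with ε ~ N(μ = 40, σ = 4).  Logarithms are natural; the error's nonzero
  mean simply shifts the effective intercept to 90 and is implemented
  literally.
* **Informative block.** (X0, X3, X4) trivariate normal with means
  (200, 50, 100), SDs (40, 10, 20) and correlations ρ₀₃ = 0.75, ρ₀₄ = 0.6,
  ρ₃₄ = 0.5.  X0 is the variable whose imputation can genuinely profit from
  auxiliary information.
* **Second block.** (X1, X5) bivariate normal, means (20, 500), SDs
  (4, 100), ρ = 0.5.
* **X2.** Noncentral χ² with df = 3 and noncentrality λ = 20 (mean 23,
  variance 2(df + 2λ) = 86).  We parameterize by (df, λ); the location
  parameter μ of a noncentral χ² is its noncentrality.  X2 has no
  correlated partner — it is the worst case for any donor-based imputer,
  and its imputation error is essentially the distributional constant
  E|x' − x|/x of two independent draws (≈ 0.565 for 1NN).
* **MAR drivers.** X6 ~ Bernoulli(0.5), X7 ~ Uniform(30, 60).
* **Noise.** 50 attributes whose hyperparameters are drawn once from
  `noise_seed` and then frozen across populations: 15 noncentral χ² with
  λ ~ U[10, 50] and df ∈ {2..5}; 20 normals with μ ~ U[10, 200], σ = μ/5;
  three trivariate and three bivariate normal blocks with μ ~ U[10, 100],
  σ ~ U[μ/5, μ/2] and pairwise correlations drawn uniformly from
  [0.2, 0.6] (redrawn until positive definite).  The blocks make the noise
  "coloured" rather than white: correlated junk is what defeats naive
  distance metrics in practice.

Population regeneration is bit-identical given (`noise_seed`, population
seed, size).  `compute_truth` records the truth θ: the population OLS fit
of Y on (X0, X1, X2, X3), the Pearson correlation of its fitted values with
Y, and the population means and SDs of X0, X1, X2.

## Missingness mechanisms

`inject_mcar` masks each case independently with probability `rate`
(Bernoulli); an `exact_count` option masks exactly round(rate·n) cells for
users who need fixed counts.  `inject_mar` assigns categories A–D from
(X6, X7 ≥ 48), where 48 is the 60th percentile of Uniform(30, 60), with
relative risks 1 : 1.5 : 1.5² : 1.5³.  The base probability is calibrated
analytically from the theoretical category frequencies (0.3, 0.3, 0.2, 0.2),
so base = rate/1.875 and the expected overall rate is exact; rates above
1/3.375 of the maximum risk raise an error rather than silently capping.
Both mechanisms keep the pre-masking values in a truth store so inaccuracy
can be scored later.  The benchmark pattern is MAR on X0 and MCAR on X1 and
X2, all at the same rate (0.15 or 0.30).

## Distances, donors, aggregation

Donors are always the fully complete cases C(X).  Each missing attribute is
imputed independently; imputed values are never reused as donor features in
the same pass.  The distance between recipient and donor is the Minkowski
norm over the candidate attributes — everything except the target
attribute, the outcome Y (by default; `include_outcome` reverses this, to
avoid leaking the outcome into its own predictors), and any attribute the
recipient itself is missing (the pairwise-available convention).

**Feature standardization (default on).**  Distances are computed on
z-scored features, using complete-case means and SDs.  The attributes of
this kind of table differ by orders of magnitude (X5 has σ = 100, X1 has
σ = 4); on raw scales a single wide attribute owns the metric and the
informative partners of the target are invisible.  Standardization is what
makes the nearest-neighbour machinery behave as the benchmark's reference
results imply, and it is the statistically defensible default; the
`standardize_features` switch restores raw distances for users who want
them.

Tie-breaking is everywhere deterministic: donor rankings use a stable sort,
so equal distances resolve by ascending row index.  Aggregation: 1NN takes
the first donor; kNN averages the first k; wkNN weights the first k by
1/distance normalized to sum to one, and if any of the k distances is
exactly zero the exact matches take all the weight (the limit of the
scheme).  kNN with k = m reproduces the pool mean, and wkNN with all-equal
distances reproduces kNN — both are tested identities.

## Frameworks

* **plain** — the full pool and all candidate attributes.
* **filtered** — RReliefF is run once per target attribute on C(X) (target
  as regression response, candidates as features) and the distance then
  uses the top ⌈s·q⌉ attributes, s ∈ {0.10, 0.20, 0.30}.  The ceiling
  guarantees a non-empty subset at s = 0.10.
* **bagged** — for each missing cell, 50 independent with-replacement donor
  subsamples of size ⌈0.10·m⌉ (floored at k so aggregation stays feasible);
  the imputed value is the mean of the per-subsample imputations.
* **subspace** — 50 random attribute subsets of size l = ⌊√q⌋, drawn
  uniformly without replacement from the recipient's admissible candidates;
  q is fixed per dataset (candidates after global exclusions), so runs are
  comparable across recipients.
* **full_random** — per run an attribute subset, then a donor bag, then NN
  imputation; the mean over 50 runs.

Ensemble reproducibility uses counter-based seeding: every missing cell
gets its own `SeedSequence(seed, row, column)` substream, so results are
independent of the order in which cells (or configurations) are processed.

## RReliefF

The regression Relief variant scores an attribute by contrasting each
instance with its nearest neighbours, accumulating the probability mass of
"attribute differs" jointly with "target differs":

    W[A] = N_dC&dA[A]/N_dC − (N_dA[A] − N_dC&dA[A])/(m − N_dC).

Choices (the algorithm family leaves them open): every row serves as an
iteration instance — no random subsampling, which removes a hidden RNG and
makes weights deterministic and row-order invariant; neighbours (10 by
default) are found by Manhattan distance on range-normalized features;
rank-j contributions decay as exp(−(j/σ)²) with σ = n_neighbors/2,
normalized to sum to one; attribute and target differences are normalized
by the observed range, so weights are scale-free and constant attributes
score zero.  A constant target is rejected as degenerate.

## Evaluation

For repeated estimates x₁..xₙ of a truth θ: Bias = x̄ − θ,
Var = Σ(xᵢ − x̄)²/(n−1) (the standard squared-deviation sample variance),
MSE = Σ(xᵢ − θ)²/n, so MSE = Bias² + Var·(n−1)/n is an exact identity and
is asserted as such.  Inaccuracy is the mean proportional absolute
deviation over originally-missing cells; it is scale-invariant and
undefined when a true value is zero (an error, not a silent skip).

**The k trade-off.**  Over a grid of k, plain kNN's mean inaccuracy falls
while the MSE of the imputed variable's sample SD rises.  Both curves are
min-max normalized over the grid; the reported best k is the smallest k at
which normalized distortion strictly exceeds normalized inaccuracy — the
grid point at which the falling and rising curves have crossed.  When the
curves never cross (degenerate input), the k minimizing their average is
returned, ties to the smaller k.  The crossing rule is used because it is
the robust formalization of "where the curves intersect": under the
benchmark conditions the intersection sits between k = 2 and k = 3 and the
crossing lands on 3 across seeds, while the argmin of the averaged curves
wobbles between 2 and 3 with Monte-Carlo noise.

**Configuration ranking.**  For complete datasets with a fixed model
(`run_real_dataset`): per model variable, min-max normalize mean inaccuracy
and SD-distortion (MSE of the variable's SD against the complete-data SD)
across configurations, average the two, rank (average ranks on ties), then
rank the mean per-variable rank.  Refits use OLS for continuous outcomes
and maximum-likelihood logistic regression for binary ones, always with the
pre-specified variable set — stepwise selection is deliberately out of
scope, since a data-dependent model would make the comparison
irreproducible.

## Problem sizes

The full benchmark conditions are a 10⁶ population, 500 replicates of
n = 400, and 50-run ensembles.  The package's own test suite reruns the
study at a 250k population and 200 replicates, and the examples use 100k
populations with 30–50 replicates — sizes chosen so the statistical
conclusions are stable (Monte-Carlo standard errors a few percent of the
quantities compared) while the suite stays fast.  `scripts/acceptance.py`
uses the full 10⁶ population with the experiment's 100 replicates.

## What the generator does and does not emulate

The benchmark emulates a medium-sized epidemiological table: a linear
outcome model, a mix of symmetric and skewed continuous attributes, one
binary attribute, correlated informative partners, and a majority of
correlated-noise attributes.  It does not emulate categorical/ordinal
similarity (explicitly out of scope), MNAR mechanisms, nonlinear
outcome–covariate relationships, heteroscedastic errors, or missingness on
more than three designated attributes.  Passing tests therefore demonstrate
correct behaviour under MCAR/MAR with continuous data and moderate (15–30 %)
missingness; they say nothing about MNAR data or heavily categorical
tables.

## Known limitations

* Exact donor search only — pools are a few hundred rows, so no indexing or
  approximate NN is provided; cost is O(cells × m × features).
* Single imputation only: the ensembles average into one completed table
  and do not expose between-imputation variance.
* The RReliefF weighting is deterministic by design; implementations that
  subsample iteration instances will select slightly noisier subsets and
  can show somewhat larger errors for the filtered framework.
* Inaccuracy is undefined for true zeros, which limits the metric to
  positive-valued attributes (as in the benchmark).
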