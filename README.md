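# nnimpute

Nearest-neighbour hot-deck imputation for numeric tables, together with a
fully seeded simulation benchmark that quantifies not only how *accurately*
an imputer fills holes but how badly it *distorts the distribution* of the
imputed variable — the trade-off that decides which imputer you should
actually use.

## The problem and the methods

In hot-deck imputation a record with a missing value (the *recipient*)
receives a replacement from similar complete records (*donors*).  Donors are
the complete cases C(X); similarity is the Minkowski norm over a feature
subset,

    d(a, b) = ( Σᵢ |aᵢ − bᵢ|^p )^(1/p),      p ∈ {0.5, 1, 2},

computed by default on z-scored features.  Three aggregation rules are
provided:

* **1NN** — the nearest donor's value (always an actually occurring value);
* **kNN** — the unweighted mean of the k nearest donors (default k = 5);
* **wkNN** — the inverse-distance-weighted mean of the k nearest donors.

Each rule runs inside five *frameworks*: **plain** (full donor pool, all
attributes), **filtered** (attributes pre-selected per target by RReliefF, a
regression Relief algorithm that scores multivariate relevance without a
linearity assumption), **bagged** (average over 50 with-replacement donor
subsamples of 10 % of the pool), **subspace** (average over 50 random
attribute subsets of size ⌊√q⌋), and **full_random** (both randomizations,
random-forest style) — plus a **mean-imputation** baseline.

The benchmark generates a population of 10⁶ records in which a continuous
outcome follows

    Y = 50 + ln(2)·X0 + ln(4)·X1 + ln(0.5)·X2 + ln(0.25)·X3 + ε,  ε ~ N(40, 4),

with correlated multinormal blocks (X0, X3, X4) and (X1, X5), a skewed
noncentral-χ² attribute X2, MAR drivers X6, X7, and 50 "coloured" noise
attributes.  Repeatedly drawing samples of n = 400, injecting MAR
missingness on X0 and MCAR on X1/X2 at 15 % or 30 %, imputing and refitting
the model yields, per imputer configuration:

* **bias / variance / MSE** of the regression coefficients, of the
  correlation between fitted and true Y, and of the imputed variables'
  means and SDs, all against the population truth θ
  (Bias = x̄ − θ, Var = Σ(xᵢ−x̄)²/(n−1), MSE = Σ(xᵢ−θ)²/n);
* **inaccuracy** — the mean proportional error (1/n_miss) Σ |x̂ᵢ − xᵢ|/xᵢ
  over the originally-missing cells.

## A worked example

`python examples/simulation_study.py` (50 replicates of n = 400 at 15 %
missingness, 100k population) prints:

```
configuration             MSE beta_X0  MSE SD(X0)  inacc X0
plain/1nn/k=5/p=2              0.0324       1.473    0.2019
plain/knn/k=5/p=2              0.0077       6.961    0.1626
plain/wknn/k=5/p=2             0.0077       6.950    0.1625
filtered/knn/k=5/p=2           0.0028       6.057    0.1389
mean                           0.0130       10.900   0.1821
```

Read it column-wise: averaging five donors (kNN/wkNN) estimates the X0
coefficient four times better than taking a single donor (1NN) and imputes
more accurately — but it shrinks the imputed variable's spread, so its MSE
of SD(X0) is ~5× worse than 1NN's (mean imputation is worst on both
distortion counts).  RReliefF filtering, which strips the 50 noise
attributes out of the distance, improves accuracy and inference further.
`python examples/k_tradeoff.py` scans k = 1..10 and shows the two
min-max-normalized error curves crossing at **k = 3** — the number of
neighbours that best balances accuracy against distortion.  The other
examples demonstrate CSV imputation, RReliefF weighting and the
configuration-ranking protocol for complete datasets with a fixed model.

A thin CLI wraps the same machinery:

```
nnimpute impute --input holes.csv --output filled.csv --method wknn --k 3 \
    --framework filtered --relieff-fraction 0.2 --seed 17
nnimpute simulate-data --out data/ --population-size 100000
nnimpute k-curve --attr X0 --rate 0.30 --reps 100
```

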