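"""Rank imputation configurations on a complete table with a fixed model.

This mirrors the real-data protocol: take a complete dataset and a
pre-specified regression model, repeatedly MCAR-mask the model's variables
at 15%, impute under each configuration, refit, and summarize.  The final
ranking averages the min-max-normalized inaccuracy and SD-distortion across
the model variables — rank 1 is the best accuracy/distortion compromise.

A synthetic stand-in table (400 cases drawn from the benchmark population)
is used here so the example runs without any download; point `data` at any
complete CSV via DataMatrix.read_csv to use your own.
"""

from nnimpute import (
    ExperimentConfig,
    ImputationConfig,
    ModelSpec,
    PopulationSpec,
    draw_sample,
    generate_population,
    run_real_dataset,
)

population = generate_population(PopulationSpec(), size=100_000, seed=11)
data = draw_sample(population, 400, seed=3)

model = ModelSpec(outcome="Y", predictors=["X0", "X1", "X2", "X3"])
configs = [
    ImputationConfig(method="wknn", k=k, framework=fw)
    for fw in ("plain", "filtered")
    for k in (1, 3, 10)
]
table, ranks = run_real_dataset(
    data, model, rate=0.15, n_reps=30, configurations=configs, master_seed=9
)

print("trade-off ranks over 30 MCAR replicates (1 = best):")
for label, rank in ranks.sort_values().items():
    print(f"  rank {rank:4.1f}  {label}")
print(
    "\nsmall k preserves dispersion, filtering removes noise from the metric;"
    "\ntheir combination wins the accuracy-versus-distortion compromise."
)
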