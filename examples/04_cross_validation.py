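"""Species-stratified cross-validation and the SISR statistic.

A library with exactly k sequences per species splits into k folds, one
sequence of every species per fold; each fold in turn is the query set.
SISR = (correctly identified queries) / (all queries), pooled over species.
"""

from barcodeforest import (
    FeatureSpec, ForestConfig, SimulationParams, generate_library, run_cv,
)

k = 5
lib = generate_library(SimulationParams(
    n_species=20, seqs_per_species=k, length=600,
    within_sub_rate=0.05, seed=9))

result = run_cv(lib, FeatureSpec.gapped(),
                ForestConfig(ntree=200, seed=9), k=k, seed=9)

for f, value in enumerate(result.per_fold_sisr, start=1):
    print(f"fold {f}: SISR {value:.3f}")
print(f"\nmean SISR {result.mean_sisr:.3f} +/- {result.sd_sisr:.3f} "
      f"(sd over the {k} folds)")

worst = min(result.per_species.items(), key=lambda kv: kv[1][1] / kv[1][0])
print(f"hardest species: {worst[0]} "
      f"({worst[1][1]}/{worst[1][0]} queries correct)")
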