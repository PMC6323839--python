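"""Train the species classifier and identify query sequences.

The classifier is a bagged forest of decision trees: each tree grows on a
bootstrap resample and splits on mtry randomly drawn features; a query is
assigned to the species winning the majority of tree votes.  The out-of-bag
(OOB) error printed below is the internal error estimate computed from the
rows each tree did not see.
"""

from barcodeforest import (
    FeatureSpec, ForestConfig, SimulationParams, encode_dataset,
    generate_library, generate_query_set, predict, train,
)

lib = generate_library(SimulationParams(
    n_species=15, seqs_per_species=5, length=600,
    within_sub_rate=0.01, seed=3))
spec = FeatureSpec.gapped()

model = train(encode_dataset(lib, spec), ForestConfig(ntree=200, seed=3),
              feature_spec=spec)
print(f"trained on {len(lib)} sequences / {lib.n_species} species; "
      f"OOB error {model.oob_error:.3f}")

queries = generate_query_set(lib, per_species=1, within_sub_rate=0.01, seed=4)
encoded = encode_dataset(queries, spec)
print("\nquery                predicted   vote fraction")
for rec, (species, fraction) in zip(queries, predict(model, encoded)):
    flag = "" if species == rec.species else "  <- wrong"
    print(f"{rec.record_id:<20} {species:<10} {fraction:.2f}{flag}")
print("\nvote fraction = share of the 200 trees voting for the winner.")
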