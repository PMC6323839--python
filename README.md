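# barcodeforest

Alignment-free species identification from DNA barcodes.

DNA barcoding assigns an unknown specimen to a species by comparing a short
standardized genomic region (COI in animals, ITS in fungi, matK/rbcL in
plants) against a reference library of labelled sequences. For the fungal
barcode ITS, alignment-based assignment is fragile: the region is highly
variable in length and riddled with indels. `barcodeforest` sidesteps
alignment entirely — each sequence is encoded as a fixed-length vector of
**gapped base-pair compositions** and classified with a multiclass
**random forest** tuned by its out-of-bag (OOB) error.

It is intended for anyone building or evaluating a barcode reference
library: assign species labels to query sequences, cross-validate a
library's identification accuracy, and tune the classifier — all from a
Python API or a small command-line tool.

## The method

**Encoding.** For a sequence of length *N* and gap size *g*, the *g*-spaced
feature for the ordered base pair (*s*, *t*) is

> D*_g_*(*s*, *t*) / (*N* − 1),

where D*_g_*(*s*, *t*) counts positions *i* with sequence[*i*] = *s* and
sequence[*i* + *g* + 1] = *t* — exactly *g* bases skipped between the pair
(*g* = 0 is the contiguous dinucleotide). Each gap size contributes 16
features; the default representation stacks gaps 1–5 (80 features), with an
option to include the *g* = 0 block (96 features). Contiguous *k*-mer
compositions (4^*k* features per order; 340 for *k* ∈ {1..4}) are available
for comparison. Because these are compositions, sequences of unequal length
encode to the same dimensionality with no alignment.

**Classifier.** A bagged ensemble of *ntree* CART trees (default 500), each
grown on a bootstrap resample and splitting on *mtry* randomly drawn
features (default ⌊√p⌋, e.g. 9 for p = 96). Prediction is by hard majority
vote. Each resample leaves out ≈ 1/e ≈ 36.8% of rows; these out-of-bag rows
give an internal error estimate used for tuning: sweep *ntree* 1…500 and
find where the OOB curve stabilizes, then sweep *mtry* over
{1, √p/2, √p, 2√p, 3√p, p/2, p} and keep the minimizer.

**Evaluation.** Accuracy is the species identification success rate,
SISR = Σ<sub>h</sub> n<sub>h</sub> / Σ<sub>h</sub> N<sub>h</sub> (correctly
identified queries over all queries, pooled across the H species), measured
by species-stratified k-fold cross-validation: a library with exactly k
sequences per species is dealt into k folds holding one sequence of every
species, so every training split is perfectly balanced.

## Worked example

```python
from barcodeforest import (FeatureSpec, ForestConfig, SimulationParams,
                           generate_library, run_cv)

lib = generate_library(SimulationParams(
    n_species=20, seqs_per_species=5, length=600,
    within_sub_rate=0.05, seed=9))
result = run_cv(lib, FeatureSpec.gapped(),
                ForestConfig(ntree=200, seed=9), k=5, seed=9)
print(result.per_fold_sisr, result.mean_sisr, result.sd_sisr)
```

prints

```
[1.0, 1.0, 1.0, 1.0, 1.0] 1.0 0.0
```

— every one of the 100 held-out sequences (one per species per fold) was
assigned to its true species: with independently drawn species ancestors
(~25% pairwise identity) a 5% within-species substitution rate leaves the
classes cleanly separable. See `examples/` for narrative scripts covering
encoding, simulation, training/prediction, cross-validation and tuning;
each prints its numbers with a line on what they mean.

The same workflow is available from a shell:

```bash
barcodeforest simulate --n-species 20 --seqs-per-species 5 --seed 9 --out-dir run
barcodeforest cv --reference run/library.fasta -k 5 --ntree 200 --seed 9 --out-dir run
barcodeforest train --reference run/library.fasta --seed 9 --out-dir run
barcodeforest predict --model run/model.joblib --query run/library.fasta --out-dir run
```

Reference FASTA headers are pipe-delimited (`recordid|species|...`, species
field configurable with `--species-field`); with a fixed `--seed` every
output file is byte-reproducible.

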