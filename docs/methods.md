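# Methods

## Model and procedure

`barcodeforest` treats barcode-based species identification as multiclass
supervised classification: the reference library is the training set, one
class per species, and a query sequence is assigned the label of the class
winning the majority of tree votes in a bagged forest. The assumptions are
those of any closed-world classifier: every query belongs to one of the
reference species (there is no "none of the above" outcome), and the
within-species variation seen at prediction time resembles that in the
library. No probability calibration, variable-importance analysis or
class weighting is performed; the stratified cross-validation design keeps
classes balanced by construction instead.

### Sequence encoding

For gap size g, the feature for the ordered pair (s, t) is
D_g(s, t)/(N − 1): D_g counts positions i with sequence[i] = s and
sequence[i + g + 1] = t, i.e. exactly g skipped bases between the pair, not
"up to g". The denominator is N − 1 for every gap size, although only
N − 1 − g such pairs exist; a single-gap block therefore sums to
(N − 1 − g)/(N − 1) rather than 1 (and to 0 when N ≤ g + 1). This mild
non-normalization is deliberate — it keeps the formula exactly as defined —
and is covered by an exact block-sum property test. k-mer blocks use the
standard composition denominator N − k + 1 and sum to 1.

Column identity is fully determined by the `FeatureSpec`: gap blocks in
ascending g, then k-mer blocks in ascending k, words lexicographic over
A < C < G < T within a block. Models persist their spec and column names
and refuse feature matrices whose columns do not match.

The default gapped representation is gaps {1..5} (80 features). The g = 0
contiguous-dinucleotide block can be added (`include_gap0=True`, 96
features); 96 is also the representation for which the default split width
⌊√p⌋ equals 9. Both conventions are first-class because both dimensionality
conventions circulate for "gaps 1–5" encodings, and which one a given study
used is often undocumented; the package makes the choice explicit rather
than silent.

### Forest

Trees are scikit-learn `DecisionTreeClassifier`s (CART, Gini impurity,
grown to purity); the bagging layer is implemented here so that the
ensemble contract is exact and fully seeded:

* each tree is fit on a bootstrap resample of the n training rows
  (n draws with replacement) and considers `mtry` randomly drawn features
  at each split;
* prediction is a **hard majority vote** over trees (not averaged
  probabilities); vote ties go to the lexicographically smallest species
  label so results are deterministic;
* the rows left out of a tree's resample (≈ 1/e ≈ 36.8% on average) are its
  out-of-bag set. Every row is scored by the majority vote of only the
  trees for which it was out of bag, and the OOB error is the
  misclassified fraction among rows that received at least one such vote.
  Rows never out of bag are excluded from the denominator; if no row has a
  vote (possible only for a tiny forest on tiny data) the error is NaN and
  tuning ranks NaN as worst.

One RNG stream per forest (`numpy.random.default_rng(seed)`) draws both the
bootstrap rows and each tree's internal seed, so a forest of size t is a
prefix of the forest of size t′ > t under the same seed, and identical
(data, config) pairs give bit-identical models.

### Tuning

Two-stage, OOB-driven. Stage 1 grows a single forest to `max_trees`
(default 500) and records the OOB error after every added tree; the
stabilization point is the smallest size from which the error stays within
0.005 of the final error. The 0.005 tolerance makes an otherwise visual
judgement computable; the operational default stays ntree = 500 regardless,
since extra trees never hurt OOB error systematically. Stage 2 fixes ntree
and trains one forest per value of the grid
{1, √p/2, √p, 2√p, 3√p, p/2, p} — each term floored, clamped to [1, p],
de-duplicated, ascending (for p = 96: 1, 4, 9, 19, 29, 48, 96) — keeping
the lowest-OOB value, ties to the smaller mtry. Flooring is used for √p
because it is the only integerization for which ⌊√96⌋ = 9 equals the
conventional default split width at p = 96.

### Cross-validation and SISR

`make_folds` requires exactly k records per species (use
`subsample_k_per_species` first), permutes each species' records with a
seeded RNG and deals one per fold, so folds partition the library, each
fold holds one sequence of every species, and every training split has
k − 1 per species. SISR = Σ n_h / Σ N_h is pooled over species, not a
macro-average, so common and rare species weigh by their query counts
(irrelevant under the balanced CV design, where every species contributes
one query per fold). The summary is the mean over the k per-fold SISRs
± their sample standard deviation (denominator k − 1); a standard error
would be this divided by √k — the package reports the SD and labels it as
such. Species never predicted correctly contribute n_h = 0 with no
smoothing, and no sequence-identity screening is applied between folds.

## Synthetic data generator

`generate_library` emulates the structure that makes barcode references
learnable: many species, few (3–10) sequences per species, high
between-species divergence, tunable within-species variability. Each
species' ancestor is drawn uniformly over {A,C,G,T}^length (length default
600, a typical fungal ITS span), so two ancestors agree at ~25% of
positions; each library sequence is an independent copy of its ancestor
with per-base substitutions at `within_sub_rate` to a uniformly chosen
different base (Jukes–Cantor-like) and, optionally, 1-base indels at
`indel_rate` (default 0, so Hamming-distance oracles stay exact; enabling
indels exercises the encoder's length robustness). `generate_query_set`
draws fresh mutants of the retained ancestors, labelled with the truth for
scoring. `generate_two_level_library` adds a genus level (species ancestors
mutated from shared genus ancestors) for harder, related-species
benchmarks; it is not the default.

What this does **not** emulate: real ITS length variation and indel
structure, compositional bias, paralogy/intragenomic variation, shared
phylogenetic history among all species, label noise, or species whose
barcodes are genuinely unresolvable. Passing tests on this generator
therefore demonstrate that the encoder–classifier–CV machinery is correct
and that well-separated species are identified at the expected rates; they
do not predict accuracy on any real reference library, where
between-species divergence can approach within-species divergence.

Default study design used by the test suite and the acceptance script:
20 species × k sequences, 600 bp, within-species substitution 1%, ntree
200, k ∈ {3, 5, 7}. For the monotonicity-in-k check the substitution rate
is 0.10 — chosen once as a realistic upper bound of intraspecific ITS
divergence — because at 1% the curve is saturated at SISR 1.0 and a trend
cannot be observed. These sizes keep every check on a single CPU in
seconds to a few minutes.

## Numerical and design choices

* **Alphabet policy.** Sequences are upper-cased before counting; any
  character outside {A, C, G, T} (ambiguity codes, RNA U) invalidates the
  record — dropped with a logged reason during library construction,
  raised as an error for single-record calls and query prediction.
  Sequences shorter than 2 bases cannot form a pair and are rejected.
* **Header dialect.** Pipe-delimited FASTA headers; record id is field 1,
  species a configurable 1-based field (default 2). Written files use
  `id|species`, which round-trips.
* **Degenerate inputs.** Empty FASTA, single-species training sets,
  mtry > p, k mismatching a species' count, and zero query totals all
  raise informative errors rather than degrade silently.
* **Determinism.** All randomness flows from explicit integer seeds
  (numpy `default_rng` / `SeedSequence`); per-fold model seeds derive from
  (config seed, fold index). CLI outputs are byte-identical under a fixed
  `--seed`; without one, a clock-derived seed is used and recorded in the
  provenance sidecar (which then also carries a timestamp).
* **Persistence.** Models serialize via joblib with a plain-text JSON
  sidecar (feature spec, class labels, config, OOB error) so a prediction
  can be audited without unpickling.

## Known limitations

Closed-world assignment only — a query from a species absent from the
reference is silently forced into the nearest class (the vote fraction is
a rough confidence but is not calibrated). The composition encoding
discards positional information beyond the gap structure, so species
differing only by large-scale rearrangements of identical composition are
indistinguishable. The pure-Python bagging loop is comfortable at
reference-library scale (10²–10⁴ sequences) but is not engineered for
millions of rows.
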