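"""Species-stratified cross-validation and the SISR statistic.

The species identification success rate (SISR) for a query set of H species
is Σ_h n_h / Σ_h N_h, where N_h is the number of query sequences of species
h and n_h the number of those classified correctly — i.e. the pooled
fraction of correctly identified queries.

Cross-validation is stratified by species: a library with exactly k
sequences per species is split into k folds such that every fold holds
exactly one sequence of every species.  Each fold in turn is the query set
while the other k-1 folds train the model, so every training split is
perfectly balanced with k-1 sequences per species.  The reported accuracy
is the SISR averaged over the k folds, with its standard deviation across
folds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from . import classifier
from .classifier import ForestConfig
from .features import FeatureSpec, encode_dataset
from .io import ReferenceLibrary


def sisr(per_species_correct: Mapping[str, int],
         per_species_total: Mapping[str, int]) -> float:
    """Pooled success rate Σ_h n_h / Σ_h N_h over the species in
    ``per_species_total``; correct counts may not exceed totals."""
    total = 0
    correct = 0
    for sp, n_total in per_species_total.items():
        n_correct = per_species_correct.get(sp, 0)
        if n_total < 0 or n_correct < 0:
            raise ValueError(f"negative count for species {sp!r}")
        if n_correct > n_total:
            raise ValueError(
                f"species {sp!r}: correct ({n_correct}) exceeds total ({n_total})"
            )
        total += n_total
        correct += n_correct
    if total == 0:
        raise ValueError("no query sequences: total count is zero")
    return correct / total


@dataclass
class CVPlan:
    """Fold assignment for species-stratified k-fold cross-validation.

    ``folds[f]`` lists the record positions of fold f; every species
    contributes exactly one record to every fold and the folds partition
    the library.
    """

    k: int
    folds: list[list[int]]
    seed: int

    def fold_of(self) -> dict[int, int]:
        return {pos: f for f, members in enumerate(self.folds) for pos in members}


def make_folds(lib: ReferenceLibrary, k: int, seed: int) -> CVPlan:
    """Deal each species' k records into k folds, one per fold, in seeded
    random order.  Every species must have exactly k records (use
    ``subsample_k_per_species`` first)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    for sp, positions in lib.species_index.items():
        if len(positions) != k:
            raise ValueError(
                f"species {sp!r} has {len(positions)} records; "
                f"k-fold stratified CV requires exactly {k}"
            )
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for sp, positions in lib.species_index.items():
        order = rng.permutation(k)
        for f, i in enumerate(order):
            folds[f].append(positions[i])
    return CVPlan(k=k, folds=[sorted(members) for members in folds], seed=seed)


@dataclass
class EvaluationResult:
    """Per-fold SISR values, their mean and standard deviation, and the
    pooled per-species (observed, correct) counts across all folds."""

    per_fold_sisr: list[float]
    mean_sisr: float
    sd_sisr: float
    per_species: dict[str, tuple[int, int]]

    def to_tsv(self, path: str | Path) -> None:
        """One row per species (species, observed N_h, correct n_h) plus a
        summary row carrying mean ± sd SISR — the training-result layout."""
        lines = ["species\tobserved\tcorrect"]
        for sp in sorted(self.per_species):
            n_obs, n_cor = self.per_species[sp]
            lines.append(f"{sp}\t{n_obs}\t{n_cor}")
        lines.append(f"#mean_sisr\t{self.mean_sisr:.6f}\t+/-{self.sd_sisr:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")


def run_cv(lib: ReferenceLibrary, spec: FeatureSpec, config: ForestConfig,
           k: int, seed: int) -> EvaluationResult:
    """Species-stratified k-fold CV of the forest on ``lib``.

    For each fold: train on the records outside the fold, predict the fold,
    and score it with SISR.  The mean and sample standard deviation are
    taken over the k per-fold SISRs; per-species counts are pooled over
    folds, so Σ N_h equals the library size.

    Per-fold model seeds derive from ``config.seed`` and the fold index, so
    the whole run is reproducible from one seed while folds stay
    independent.
    """
    plan = make_folds(lib, k, seed)
    matrix = encode_dataset(lib, spec)
    all_positions = set(range(len(lib)))

    per_fold: list[float] = []
    per_species: dict[str, tuple[int, int]] = {
        sp: (0, 0) for sp in lib.species_index
    }
    for f, members in enumerate(plan.folds):
        train_rows = sorted(all_positions - set(members))
        fold_seed = int(np.random.SeedSequence([config.seed, f]).generate_state(1)[0]
                        % (2**31 - 1))
        model = classifier.train(
            matrix.subset(train_rows),
            replace(config, seed=fold_seed),
            feature_spec=spec,
        )
        test = matrix.subset(members)
        predictions = classifier.predict(model, test)
        fold_correct: dict[str, int] = {}
        fold_total: dict[str, int] = {}
        for true_label, (pred_label, _) in zip(test.labels, predictions):
            fold_total[true_label] = fold_total.get(true_label, 0) + 1
            hit = int(pred_label == true_label)
            fold_correct[true_label] = fold_correct.get(true_label, 0) + hit
            n_obs, n_cor = per_species[true_label]
            per_species[true_label] = (n_obs + 1, n_cor + hit)
        per_fold.append(sisr(fold_correct, fold_total))

    mean = float(np.mean(per_fold))
    sd = float(np.std(per_fold, ddof=1)) if k > 1 else 0.0
    return EvaluationResult(
        per_fold_sisr=per_fold,
        mean_sisr=mean,
        sd_sisr=sd,
        per_species=per_species,
    )
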