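"""Multiclass random-forest species classifier with out-of-bag tuning.

The forest is a bagged ensemble of CART trees (scikit-learn
``DecisionTreeClassifier``): each tree is grown on a bootstrap resample of
the training rows, and every split considers ``mtry`` features drawn at
random.  Prediction is by hard majority vote over the trees, ties broken by
the lexicographically smallest species label.

Each bootstrap resample leaves out, on average, (1 - 1/n)^n -> 1/e ≈ 36.8%
of the rows; those out-of-bag (OOB) rows provide an internal error estimate
with no held-out set: every row is scored by the majority vote of only the
trees for which it was out of bag, and the OOB error is the misclassified
fraction among rows that received at least one such vote.

Tuning follows the two-stage OOB procedure: sweep ntree from 1 to a maximum
(500 by default) with the default mtry = floor(sqrt(p)) and locate where the
OOB curve stabilizes, then with ntree fixed sweep mtry over the grid
{1, sqrt(p)/2, sqrt(p), 2*sqrt(p), 3*sqrt(p), p/2, p} and keep the value with
the lowest OOB error.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix, FeatureSpec

#: OOB stabilization tolerance for the ntree sweep: the curve is considered
#: stable from the first forest size whose error stays within this distance
#: of the final error.
STABILIZATION_TOL = 0.005


def default_mtry(p: int) -> int:
    """Default number of candidate features per split: floor(sqrt(p)), >= 1."""
    if p < 1:
        raise ValueError("p must be >= 1")
    return max(1, math.isqrt(p))


def mtry_grid(p: int) -> list[int]:
    """Candidate mtry values {1, √p/2, √p, 2√p, 3√p, p/2, p}.

    Each term is floored to an integer, clamped to [1, p], de-duplicated and
    returned ascending.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    root = math.sqrt(p)
    raw = (1, root / 2, root, 2 * root, 3 * root, p / 2, p)
    values = sorted({min(p, max(1, math.floor(v))) for v in raw})
    return values


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters.

    ``mtry=None`` resolves to ``default_mtry(p)`` at training time.
    ``seed`` drives the bootstrap draws and per-tree randomness; identical
    (data, config) pairs give bit-identical models.
    """

    ntree: int = 500
    mtry: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")


@dataclass
class TuningResult:
    """Grid of (parameter value, OOB error) pairs and the selected value."""

    grid: list[tuple[int, float]]
    best: int


@dataclass
class TrainedModel:
    """A fitted forest plus everything needed to reproduce its predictions."""

    trees: list[DecisionTreeClassifier]
    class_labels: np.ndarray  # sorted species labels, H entries
    config: ForestConfig      # with mtry resolved
    oob_error: float
    feature_spec: FeatureSpec | None
    column_names: list[str]
    per_species_oob: dict[str, tuple[int, int]] = field(default_factory=dict)
    """Per training species: (rows observed, rows correctly classified by
    their OOB vote) — the content of a training-result file."""

    @property
    def n_features(self) -> int:
        return len(self.column_names)


def _iter_trees(X: np.ndarray, y: np.ndarray, mtry: int, ntree: int, seed: int):
    """Yield (tree, oob_mask) pairs for a growing bagged forest.

    One RNG stream drawn from ``seed`` produces both the bootstrap rows and
    each tree's internal seed, so the forest is a pure function of
    (X, y, mtry, ntree, seed) and a forest of size t is a prefix of the
    forest of size t' > t under the same seed.
    """
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    for _ in range(ntree):
        boot = rng.integers(0, n, size=n)
        tree_seed = int(rng.integers(0, 2**31 - 1))
        tree = DecisionTreeClassifier(max_features=mtry, random_state=tree_seed)
        tree.fit(X[boot], y[boot])
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[boot] = False
        yield tree, oob_mask


def _oob_error(votes: np.ndarray, y: np.ndarray) -> float:
    """Majority-vote OOB error over rows with at least one OOB vote.

    NaN when no row has any vote (possible only for tiny forests on tiny
    data); tuning treats NaN as worst.
    """
    voted = votes.sum(axis=1) > 0
    if not voted.any():
        return float("nan")
    pred = votes.argmax(axis=1)  # argmax takes the first max: smallest label
    return float(np.mean(pred[voted] != y[voted]))


def _validate_training_input(features: FeatureMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    classes, y = np.unique(features.labels, return_inverse=True)
    if classes.size < 2:
        raise ValueError(
            f"training needs >= 2 species; got {classes.size} "
            f"({', '.join(map(repr, classes[:3]))})"
        )
    return features.values, y, classes


def train(features: FeatureMatrix, config: ForestConfig = ForestConfig(),
          feature_spec: FeatureSpec | None = None) -> TrainedModel:
    """Fit a bagged forest of ``config.ntree`` trees on ``features``.

    Class labels are the sorted distinct species of ``features.labels``.
    The returned model carries the OOB error and per-species OOB counts.
    """
    X, y, classes = _validate_training_input(features)
    p = X.shape[1]
    mtry = config.mtry if config.mtry is not None else default_mtry(p)
    if mtry > p:
        raise ValueError(f"mtry={mtry} exceeds the number of features p={p}")
    resolved = replace(config, mtry=mtry)

    votes = np.zeros((X.shape[0], classes.size), dtype=np.int64)
    trees = []
    for tree, oob_mask in _iter_trees(X, y, mtry, config.ntree, config.seed):
        trees.append(tree)
        if oob_mask.any():
            pred = tree.predict(X[oob_mask])
            votes[np.flatnonzero(oob_mask), pred] += 1

    oob_error = _oob_error(votes, y)
    voted = votes.sum(axis=1) > 0
    oob_pred = votes.argmax(axis=1)
    per_species: dict[str, tuple[int, int]] = {}
    for h, label in enumerate(classes):
        rows = y == h
        correct = int(np.sum(rows & voted & (oob_pred == y)))
        per_species[str(label)] = (int(rows.sum()), correct)

    return TrainedModel(
        trees=trees,
        class_labels=classes,
        config=resolved,
        oob_error=oob_error,
        feature_spec=feature_spec,
        column_names=list(features.column_names),
        per_species_oob=per_species,
    )


def predict(model: TrainedModel, features: FeatureMatrix) -> list[tuple[str, float]]:
    """Majority-vote prediction for each row of ``features``.

    Returns (species, vote_fraction) per row, where vote_fraction is the
    winning class's share of the ntree tree votes.  ``features`` must be
    encoded with the model's feature spec: same p and column order.
    """
    if list(features.column_names) != list(model.column_names):
        raise ValueError(
            f"feature mismatch: model expects {model.n_features} columns "
            f"({model.column_names[:3]}...), got {features.n_features}"
        )
    X = features.values
    votes = np.zeros((X.shape[0], model.class_labels.size), dtype=np.int64)
    for tree in model.trees:
        pred = tree.predict(X)
        votes[np.arange(X.shape[0]), pred] += 1
    winners = votes.argmax(axis=1)  # ties -> smallest (lexicographic) label
    ntree = len(model.trees)
    return [
        (str(model.class_labels[w]), votes[i, w] / ntree)
        for i, w in enumerate(winners)
    ]


def tune_ntree(features: FeatureMatrix, max_trees: int = 500,
               mtry: int | None = None, seed: int = 0,
               tol: float = STABILIZATION_TOL) -> TuningResult:
    """OOB error as a function of forest size, from one growing forest.

    The curve is recorded at every size 1..max_trees by accumulating OOB
    votes tree by tree.  ``best`` is the smallest size from which the error
    stays within ``tol`` of the error at ``max_trees`` (the stabilization
    point of the curve); the full curve is returned for plotting.
    """
    if max_trees < 1:
        raise ValueError("max_trees must be >= 1")
    X, y, classes = _validate_training_input(features)
    p = X.shape[1]
    mtry = mtry if mtry is not None else default_mtry(p)
    if mtry > p:
        raise ValueError(f"mtry={mtry} exceeds p={p}")

    votes = np.zeros((X.shape[0], classes.size), dtype=np.int64)
    curve: list[float] = []
    for tree, oob_mask in _iter_trees(X, y, mtry, max_trees, seed):
        if oob_mask.any():
            pred = tree.predict(X[oob_mask])
            votes[np.flatnonzero(oob_mask), pred] += 1
        curve.append(_oob_error(votes, y))

    final = curve[-1]
    best = max_trees
    for t in range(max_trees, 0, -1):
        err = curve[t - 1]
        stable = math.isnan(err) if math.isnan(final) else (
            not math.isnan(err) and abs(err - final) <= tol
        )
        if stable:
            best = t
        else:
            break
    return TuningResult(grid=list(enumerate(curve, start=1)), best=best)


def tune_mtry(features: FeatureMatrix, ntree: int = 500, seed: int = 0) -> TuningResult:
    """Train one forest per value of ``mtry_grid(p)`` (same seed stream) and
    select the mtry with the lowest OOB error; ties go to the smaller mtry."""
    if ntree < 1:
        raise ValueError("ntree must be >= 1")
    p = features.n_features
    grid = []
    best_value, best_err = None, math.inf
    for m in mtry_grid(p):
        model = train(features, ForestConfig(ntree=ntree, mtry=m, seed=seed))
        err = model.oob_error
        grid.append((m, err))
        score = math.inf if math.isnan(err) else err
        if score < best_err:
            best_value, best_err = m, score
    return TuningResult(grid=grid, best=best_value)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a model: an opaque joblib blob at ``path`` plus a plain-text
    JSON sidecar (``<path>.meta.json``) recording the feature spec, class
    labels, configuration and OOB error."""
    path = Path(path)
    joblib.dump(model, path)
    sidecar = {
        "feature_spec": model.feature_spec.to_dict() if model.feature_spec else None,
        "class_labels": [str(c) for c in model.class_labels],
        "config": {"ntree": model.config.ntree, "mtry": model.config.mtry,
                   "seed": model.config.seed},
        "oob_error": None if math.isnan(model.oob_error) else model.oob_error,
        "n_features": model.n_features,
    }
    Path(str(path) + ".meta.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )


def load_model(path: str | Path) -> TrainedModel:
    model = joblib.load(path)
    if not isinstance(model, TrainedModel):
        raise TypeError(f"{path} does not contain a TrainedModel")
    return model
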