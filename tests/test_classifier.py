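"""Forest training, prediction, OOB behaviour and hyperparameter tuning."""

import math

import numpy as np
import pytest

from barcodeforest import (
    FeatureSpec,
    ForestConfig,
    default_mtry,
    encode_dataset,
    load_model,
    mtry_grid,
    predict,
    save_model,
    train,
    tune_mtry,
    tune_ntree,
)
from barcodeforest.synth import SimulationParams, generate_library


@pytest.fixture
def encoded(separable_library):
    return encode_dataset(separable_library, FeatureSpec.gapped())


class TestMtryRules:
    @pytest.mark.parametrize("p,expected", [(96, 9), (81, 9), (1, 1), (2, 1)])
    def test_default_is_floor_sqrt(self, p, expected):
        assert default_mtry(p) == expected

    def test_grid_p96(self):
        # floors of 1, 9.798/2, 9.798, 19.60, 29.39, 48, 96
        assert mtry_grid(96) == [1, 4, 9, 19, 29, 48, 96]

    def test_grid_clamps_and_dedups(self):
        assert mtry_grid(4) == [1, 2, 4]
        assert mtry_grid(1) == [1]

    def test_grid_within_bounds(self):
        for p in (1, 2, 7, 16, 80, 340):
            grid = mtry_grid(p)
            assert grid == sorted(set(grid))
            assert all(1 <= m <= p for m in grid)


class TestTrain:
    def test_separable_species_low_oob(self, encoded):
        model = train(encoded, ForestConfig(ntree=100, seed=1))
        assert model.oob_error <= 0.1

    def test_single_class_raises(self, encoded):
        solo = encoded.subset(range(4))  # all rows of one species
        assert len(set(solo.labels)) == 1
        with pytest.raises(ValueError, match="2 species"):
            train(solo, ForestConfig(ntree=5, seed=0))

    def test_mtry_exceeding_p_raises(self, encoded):
        with pytest.raises(ValueError, match="mtry"):
            train(encoded, ForestConfig(ntree=5, mtry=encoded.n_features + 1, seed=0))

    def test_seed_reproducibility(self, encoded):
        a = train(encoded, ForestConfig(ntree=40, seed=9))
        b = train(encoded, ForestConfig(ntree=40, seed=9))
        assert a.oob_error == b.oob_error
        assert predict(a, encoded) == predict(b, encoded)

    def test_oob_error_in_unit_interval(self, noisy_library):
        matrix = encode_dataset(noisy_library, FeatureSpec.gapped())
        model = train(matrix, ForestConfig(ntree=30, seed=2))
        assert 0.0 <= model.oob_error <= 1.0

    def test_per_species_oob_counts(self, encoded):
        model = train(encoded, ForestConfig(ntree=100, seed=1))
        for n_obs, n_cor in model.per_species_oob.values():
            assert 0 <= n_cor <= n_obs == 4


class TestPredict:
    def test_training_rows_recovered(self, separable_library, encoded):
        model = train(encoded, ForestConfig(ntree=100, seed=1))
        for (species, fraction), rec in zip(predict(model, encoded),
                                            separable_library):
            assert species == rec.species
            assert fraction > 0.5

    def test_labels_from_closed_world(self, encoded):
        model = train(encoded, ForestConfig(ntree=20, seed=0))
        queries = encode_dataset(
            generate_library(SimulationParams(
                n_species=3, seqs_per_species=2, length=200, seed=99)),
            FeatureSpec.gapped(),
        )
        for species, fraction in predict(model, queries):
            assert species in set(model.class_labels)
            assert 0.0 <= fraction <= 1.0

    def test_column_mismatch_raises(self, separable_library, encoded):
        model = train(encoded, ForestConfig(ntree=5, seed=0))
        other = encode_dataset(separable_library, FeatureSpec.kmer((1, 2)))
        with pytest.raises(ValueError, match="feature mismatch"):
            predict(model, other)


def test_bootstrap_oob_fraction_approaches_1_over_e():
    """Across bootstrap resamples of n items, the mean fraction left out of
    a resample tends to 1/e (~36.8%)."""
    rng = np.random.default_rng(123)
    n, reps = 1000, 2000
    absent = np.empty(reps)
    for r in range(reps):
        boot = rng.integers(0, n, size=n)
        absent[r] = 1.0 - np.unique(boot).size / n
    assert absent.mean() * 100 == pytest.approx(36.8, abs=0.5)


class TestTuneNtree:
    def test_curve_shape_and_best(self, encoded):
        result = tune_ntree(encoded, max_trees=30, seed=4)
        assert len(result.grid) == 30
        assert 1 <= result.best <= 30

    def test_single_tree(self, encoded):
        result = tune_ntree(encoded, max_trees=1, seed=4)
        assert len(result.grid) == 1
        assert result.best == 1

    def test_ensemble_beats_single_tree_on_average(self):
        """Averaging over bootstrapped trees reduces OOB error relative to a
        single tree; checked across seeds to absorb resampling noise."""
        lib = generate_library(SimulationParams(
            n_species=6, seqs_per_species=5, length=300,
            within_sub_rate=0.05, seed=21))
        matrix = encode_dataset(lib, FeatureSpec.gapped())
        first, last = [], []
        for seed in range(5):
            curve = [err for _, err in tune_ntree(matrix, max_trees=60,
                                                  seed=seed).grid]
            first.append(curve[0])
            last.append(curve[-1])
        assert np.mean(last) <= np.mean(first)

    def test_stabilization_point_is_stable_suffix(self, encoded):
        result = tune_ntree(encoded, max_trees=50, seed=4, tol=0.005)
        final = result.grid[-1][1]
        for t, err in result.grid[result.best - 1:]:
            assert abs(err - final) <= 0.005 or (math.isnan(err) and math.isnan(final))


class TestTuneMtry:
    def test_grid_and_best_contract(self, encoded):
        result = tune_mtry(encoded, ntree=40, seed=6)
        p = encoded.n_features
        assert [m for m, _ in result.grid] == mtry_grid(p)
        assert result.best in mtry_grid(p)
        finite = [(m, e) for m, e in result.grid if not math.isnan(e)]
        best_err = min(e for _, e in finite)
        assert dict(finite)[result.best] == best_err


class TestPersistence:
    def test_round_trip_predictions(self, tmp_path, encoded):
        spec = FeatureSpec.gapped()
        model = train(encoded, ForestConfig(ntree=30, seed=8), feature_spec=spec)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        assert (tmp_path / "model.joblib.meta.json").exists()
        restored = load_model(path)
        assert restored.feature_spec == spec
        assert predict(restored, encoded) == predict(model, encoded)
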