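"""Training tables, climatology encodings, folds and observation combinations."""

import numpy as np
import pytest

from mlec import (
    Field,
    GridSpec,
    PredictorSpec,
    TrainingTable,
    WorldConfig,
    build_observation_matrix,
    build_training_table,
    climatology_features,
    generate_world,
    kfold_split,
    nominal_fold_sizes,
)
from mlec.features import MONTH_NAMES


def field(spec, values, var="x", units="1"):
    return Field(spec, values, np.ones(spec.shape, bool), var, units, "t")


@pytest.fixture
def spec10():
    return GridSpec.global_grid(10.0)


class TestClimatology:
    def test_constant_series(self, spec10):
        months = [field(spec10, np.full(spec10.shape, 4.2)) for _ in range(120)]
        feats = climatology_features(months)
        assert len(feats) == 13
        for f in feats:
            assert np.allclose(f.values, 4.2)

    def test_month_index_series_closed_form(self, spec10):
        months = [field(spec10, np.full(spec10.shape, float(i % 12 + 1))) for i in range(120)]
        feats = climatology_features(months)
        for m in range(12):
            assert np.allclose(feats[m].values, m + 1)
        assert np.allclose(feats[12].values, 6.5)

    def test_random_series_matches_bruteforce(self, spec10, rng):
        months = [field(spec10, rng.random(spec10.shape)) for _ in range(120)]
        feats = climatology_features(months)
        for m in range(12):
            brute = np.mean([months[y * 12 + m].values for y in range(10)], axis=0)
            assert np.allclose(feats[m].values, brute, atol=1e-14)
        assert np.allclose(feats[12].values, np.mean([f.values for f in months], axis=0))

    def test_incomplete_decade_rejected(self, spec10):
        with pytest.raises(ValueError, match="120"):
            climatology_features([field(spec10, np.zeros(spec10.shape))] * 119)


def predictor_entry(spec, rng, monthly=True):
    entry = {"annual": field(spec, rng.random(spec.shape))}
    entry["monthly"] = [field(spec, rng.random(spec.shape)) for _ in range(12)] if monthly else None
    return entry


class TestTrainingTable:
    def test_feature_count_and_rows(self, spec10, rng):
        pspec = PredictorSpec(("a", "b", "c"), ("s1", "s2"))
        assert pspec.n_features == 41
        predictors = {v: predictor_entry(spec10, rng) for v in "abc"}
        predictors.update({v: predictor_entry(spec10, rng, monthly=False) for v in ("s1", "s2")})
        mask = np.zeros(spec10.shape, bool)
        mask.ravel()[:57] = True
        target = field(spec10, rng.random(spec10.shape), var="fire_carbon_emission")
        table = build_training_table(predictors, target, pspec, mask, "m0")
        assert table.X.shape == (57, 41)
        assert np.allclose(table.y, target.values[mask])

    def test_missing_variable_named_in_error(self, spec10, rng):
        pspec = PredictorSpec(("a",), ())
        with pytest.raises(KeyError, match="'a'"):
            build_training_table({}, field(spec10, np.zeros(spec10.shape)), pspec, np.ones(spec10.shape, bool), "m")

    def test_multimodel_mean_commutes_with_table_building(self, rng):
        """Averaging member fields then building equals averaging member tables."""
        w = generate_world(WorldConfig(spec=GridSpec.global_grid(15.0), seed=3, n_models=3))
        pspec = PredictorSpec(
            tuple(sorted(["temperature", "lai"])), ("orography",),
            historical_decade=w.hist_decade, target_decade="2010s",
        )
        tables = []
        for i in range(3):
            preds = w.predictor_fields(i)
            sub = {v: preds[v] for v in ("temperature", "lai", "orography")}
            tables.append(
                build_training_table(sub, w.target_emission(i, "2010s"), pspec, w.land_mask, str(i))
            )
        mm = w.predictor_fields("multimodel_mean")
        sub = {v: mm[v] for v in ("temperature", "lai", "orography")}
        mm_table = build_training_table(
            sub, w.target_emission("multimodel_mean", "2010s"), pspec, w.land_mask, "multimodel_mean"
        )
        assert np.allclose(mm_table.X, np.mean([t.X for t in tables], axis=0), atol=1e-12)
        assert np.allclose(mm_table.y, np.mean([t.y for t in tables], axis=0), atol=1e-12)

    def test_csv_roundtrip(self, tmp_path, spec10, rng):
        pspec = PredictorSpec(("a",), ("s",))
        predictors = {"a": predictor_entry(spec10, rng), "s": predictor_entry(spec10, rng, monthly=False)}
        table = build_training_table(
            predictors, field(spec10, rng.random(spec10.shape)), pspec, np.ones(spec10.shape, bool), "m0"
        )
        table.to_csv(tmp_path / "t.csv", tmp_path / "t.json")
        back = TrainingTable.from_csv(tmp_path / "t.csv", tmp_path / "t.json")
        assert np.allclose(back.X, table.X)
        assert np.allclose(back.y, table.y)
        assert back.feature_meta == table.feature_meta
        assert back.provenance == "m0"


class TestKFold:
    def test_printed_sample_arithmetic(self):
        assert nominal_fold_sizes(11_325, 10) == (10_193, 1_132)

    def test_each_fold_single_sample(self):
        folds = kfold_split(10, 10, seed=0)
        assert sorted(np.bincount(folds)) == [1] * 10

    @pytest.mark.parametrize("n,k,seed", [(103, 10, 0), (11_325, 10, 1), (57, 5, 2)])
    def test_folds_partition_indices(self, n, k, seed):
        folds = kfold_split(n, k, seed)
        assert folds.shape == (n,)
        counts = np.bincount(folds, minlength=k)
        assert counts.sum() == n
        assert counts.max() - counts.min() <= 1

    def test_deterministic_and_seed_sensitive(self):
        a = kfold_split(200, 10, seed=4)
        assert np.array_equal(a, kfold_split(200, 10, seed=4))
        assert not np.array_equal(a, kfold_split(200, 10, seed=5))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(5, 10)


class TestObservationMatrix:
    def _obs(self, spec, rng, counts):
        obs = {}
        for var, c in counts.items():
            obs[var] = [predictor_entry(spec, rng, monthly=False) for _ in range(c)]
        return obs

    def test_full_cartesian_product(self, spec10, rng):
        pspec = PredictorSpec((), ("a", "b", "c"))
        obs = self._obs(spec10, rng, {"a": 2, "b": 2, "c": 2})
        mats = build_observation_matrix(obs, pspec, np.ones(spec10.shape, bool), cap=8)
        assert len(mats) == 8
        assert len({label for _, label in mats}) == 8

    def test_single_dataset_per_variable(self, spec10, rng):
        pspec = PredictorSpec((), ("a", "b"))
        obs = self._obs(spec10, rng, {"a": 1, "b": 1})
        mats = build_observation_matrix(obs, pspec, np.ones(spec10.shape, bool), cap=5)
        assert len(mats) == 1

    def test_capped_subsample_is_reproducible(self, spec10, rng):
        pspec = PredictorSpec((), ("a", "b", "c", "d"))
        obs = self._obs(spec10, rng, {v: 3 for v in "abcd"})  # 81 combos
        mats1 = build_observation_matrix(obs, pspec, np.ones(spec10.shape, bool), cap=10, seed=7)
        mats2 = build_observation_matrix(obs, pspec, np.ones(spec10.shape, bool), cap=10, seed=7)
        labels1 = [l for _, l in mats1]
        assert len(labels1) == len(set(labels1)) == 10
        assert labels1 == [l for _, l in mats2]

    def test_missing_dataset_rejected(self, spec10, rng):
        pspec = PredictorSpec((), ("a", "b"))
        obs = self._obs(spec10, rng, {"a": 1})
        with pytest.raises(ValueError, match="'b'"):
            build_observation_matrix(obs, pspec, np.ones(spec10.shape, bool))


def test_unbiased_noiseless_world_gives_identical_model_and_obs_features():
    w = generate_world(
        WorldConfig(
            spec=GridSpec.global_grid(15.0), seed=9,
            model_bias_amplitude=0.0, link_perturbation=0.0, obs_noise_sd=0.0,
        )
    )
    from mlec.synthetic import DYNAMIC_VARIABLES, STATIC_VARIABLES

    pspec = PredictorSpec(DYNAMIC_VARIABLES, STATIC_VARIABLES, historical_decade=w.hist_decade)
    preds = w.predictor_fields(0)
    table = build_training_table(
        preds, w.target_emission(0, "2010s"), pspec, w.land_mask, "0"
    )
    mats = build_observation_matrix(w.observations, pspec, w.land_mask, cap=1, seed=0)
    assert np.allclose(mats[0][0], table.X, atol=1e-12)
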