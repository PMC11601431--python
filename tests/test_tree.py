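"""Tree-regressor protocol: guards, determinism, recovery, importance."""

import numpy as np
import pytest

from protpka.dataset import AugmentationPolicy, make_splits
from protpka.evaluation import aggregate_protocol
from protpka.synth import (GroundTruthModel, SyntheticSpec, generate_dataset,
                           jitter_conformers)
from protpka.tree import (MODEL_FAMILIES, TreePkaRegressor, TreeTrainConfig,
                          load_model, permutation_importance, predict,
                          run_protocol, save_model, train_tree)

FAST = TreeTrainConfig(cv_folds=3,
                       param_grid={"max_depth": [4], "learning_rate": [0.1],
                                   "max_iter": [200]},
                       seed=0)


@pytest.fixture(scope="module")
def acid_dataset():
    """~60 acid sites with mild noise (module-scoped: several tests share it)."""
    spec = SyntheticSpec(n_sites=60, seed=17, noise_sigma=0.1,
                         aa_mix={"ASP": 0.5, "GLU": 0.5})
    return generate_dataset(spec)


class TestTreePkaRegressor:
    def test_constant_labels_give_constant_predictor(self, acid_dataset):
        X = np.asarray(
            acid_dataset.features[["buried_ratio", "n_polar10"]], float)
        y = np.full(len(X), 4.2)
        with pytest.warns(UserWarning, match="constant"):
            est = TreePkaRegressor(param_grid={"max_iter": [50]},
                                   cv_folds=3).fit(X, y)
        assert np.allclose(est.predict(X), 4.2, atol=1e-6)

    def test_same_seed_same_predictions(self, acid_dataset):
        ds = acid_dataset
        X = np.asarray(ds.features[["buried_ratio", "n_polar10",
                                    "d0_neg_O"]], float)
        a = TreePkaRegressor(cv_folds=3, param_grid={"max_iter": [100]},
                             random_state=5).fit(X, ds.labels)
        b = TreePkaRegressor(cv_folds=3, param_grid={"max_iter": [100]},
                             random_state=5).fit(X, ds.labels)
        assert np.array_equal(a.predict(X), b.predict(X))

    def test_nonfinite_labels_rejected(self, acid_dataset):
        X = np.asarray(acid_dataset.features[["buried_ratio"]], float)[:40]
        y = np.full(40, np.nan)
        with pytest.raises(ValueError):
            TreePkaRegressor().fit(X, y)

    @pytest.mark.parametrize("family", MODEL_FAMILIES)
    def test_families_interchangeable(self, family, acid_dataset):
        ds = acid_dataset
        grid = ({"n_estimators": [60]}
                if family in ("extra_trees", "random_forest", "gbm", "xgb")
                else {"max_iter": [60]})
        cfg = TreeTrainConfig(model_family=family, cv_folds=3,
                              param_grid=grid, seed=0)
        model = train_tree(ds.features, ds.labels, cfg, "acid")
        pred = predict(model, ds.features)
        assert np.isfinite(pred).all()
        rmse = float(np.sqrt(np.mean((pred - ds.labels) ** 2)))
        assert rmse < 1.0


class TestPartitionGuards:
    def test_acid_model_refuses_base_rows(self, acid_dataset):
        model = train_tree(acid_dataset.features, acid_dataset.labels,
                           FAST, "acid")
        lys_rows = acid_dataset.features.copy()
        lys_rows["aa"] = "LYS"
        lys_rows["res_type"] = "LYS"
        with pytest.raises(ValueError, match="cannot score"):
            predict(model, lys_rows)

    def test_empty_feature_table_gives_empty_output(self, acid_dataset):
        model = train_tree(acid_dataset.features, acid_dataset.labels,
                           FAST, "acid")
        assert predict(model, acid_dataset.features.iloc[:0]).size == 0

    def test_training_partition_purity_enforced(self, acid_dataset):
        mixed = acid_dataset.features.copy()
        mixed.loc[mixed.index[0], "aa"] = "HIS"
        with pytest.raises(ValueError, match="fed"):
            train_tree(mixed, acid_dataset.labels, FAST, "acid")

    def test_save_load_round_trip(self, acid_dataset, tmp_path):
        model = train_tree(acid_dataset.features, acid_dataset.labels,
                           FAST, "acid")
        save_model(model, tmp_path / "bundle")
        back = load_model(tmp_path / "bundle")
        assert back.partition == "acid"
        assert np.allclose(predict(back, acid_dataset.features),
                           predict(model, acid_dataset.features))


class TestInterpolation:
    def test_noiseless_training_rows_are_reproduced(self):
        spec = SyntheticSpec(n_sites=50, seed=23, noise_sigma=0.0,
                             aa_mix={"GLU": 1.0})
        ds = generate_dataset(spec)
        deep = TreeTrainConfig(cv_folds=3,
                               param_grid={"max_depth": [8],
                                           "learning_rate": [0.3],
                                           "max_iter": [500],
                                           "min_samples_leaf": [1]},
                               seed=0)
        model = train_tree(ds.features, ds.labels, deep, "acid")
        pred = predict(model, ds.features)
        assert np.median(np.abs(pred - ds.labels)) < 0.2


class TestProtocol:
    @pytest.fixture(scope="class")
    def protocol_dataset(self):
        """100 sites with enough basic residues to train both partitions."""
        spec = SyntheticSpec(n_sites=100, seed=41, noise_sigma=0.2,
                             aa_mix={"ASP": 0.3, "GLU": 0.3,
                                     "HIS": 0.2, "LYS": 0.2})
        return generate_dataset(spec)

    @pytest.fixture(scope="class")
    def protocol_run(self, protocol_dataset):
        ds = protocol_dataset
        plan = make_splits(ds.records, n_splits=3, seed=5)
        preds = run_protocol(ds.records, ds.structures, plan, FAST)
        return ds, plan, preds

    def test_no_test_key_in_its_training_split(self, protocol_run):
        ds, plan, preds = protocol_run
        for split_id, grp in preds.groupby("split_id"):
            train_keys = plan.train_keys(split_id)
            assert not set(grp["unique_key"]) & train_keys

    def test_one_prediction_per_record_structure_pair(self, protocol_run):
        ds, plan, preds = protocol_run
        for split_id in range(plan.n_splits):
            expected = sum(len(r.structure_refs) for r in ds.records
                           if r.unique_key in plan.test_keys(split_id))
            assert (preds["split_id"] == split_id).sum() == expected

    def test_augmentation_leaves_test_rows_unchanged(self, protocol_dataset):
        ds = protocol_dataset
        plan = make_splits(ds.records, n_splits=2, seed=5)
        conformers = {}
        structures = dict(ds.structures)
        for rec in ds.records:
            sid = rec.structure_refs[0]
            texts = jitter_conformers(structures[sid], 2, 0.2,
                                      seed=rec.resseq)
            ids = []
            for j, text in enumerate(texts):
                cid = f"{sid}_alt{j}"
                structures[cid] = text
                ids.append(cid)
            conformers[rec.unique_key] = ids
        base = run_protocol(ds.records, structures, plan, FAST)
        augmented = run_protocol(ds.records, structures, plan, FAST,
                                 augmentation=AugmentationPolicy(),
                                 conformer_source=conformers)
        assert len(augmented) == len(base)
        assert set(augmented["unique_key"]) == set(base["unique_key"])

    def test_noiseless_burial_signal_is_recovered(self):
        """With noise-free labels driven by burial alone, the protocol's
        holdout RMSE collapses toward zero."""
        spec = SyntheticSpec(n_sites=250, seed=31, noise_sigma=0.0,
                             aa_mix={"ASP": 0.5, "GLU": 0.5}, max_polar=0,
                             max_his=0, max_negative=0, max_positive=0)
        ds = generate_dataset(spec)
        plan = make_splits(ds.records, n_splits=3, seed=5)
        cfg = TreeTrainConfig(cv_folds=3,
                              param_grid={"max_depth": [4, 6],
                                          "learning_rate": [0.1],
                                          "max_iter": [300]}, seed=0)
        preds = run_protocol(ds.records, ds.structures, plan, cfg)
        report = aggregate_protocol(preds)
        assert report.mean["rmse"] < 0.15

    def test_aggregates_are_finite(self, protocol_run):
        _, _, preds = protocol_run
        report = aggregate_protocol(preds)
        assert np.isfinite(report.mean["rmse"])
        assert len(report.per_split) == 3


class TestPermutationImportance:
    def test_pure_noise_labels_have_no_important_features(self, acid_dataset):
        """With a grid spanning weak to strong learners, CV selection on
        pure-noise labels settles on a near-constant model, so no feature
        carries permutation importance."""
        ds = acid_dataset
        rng = np.random.default_rng(3)
        noise = rng.normal(5.0, 1.0, len(ds.features))
        graded = TreeTrainConfig(
            cv_folds=5, seed=0,
            param_grid={"max_depth": [2, 4], "learning_rate": [0.05, 0.1],
                        "max_iter": [5, 50, 200]})
        model = train_tree(ds.features, noise, graded, "acid")
        imp = permutation_importance(model, ds.features, noise,
                                     n_repeats=10, seed=0)
        assert imp["importance"].abs().max() < 0.05

    def test_ranking_is_stable_across_repeat_counts(self):
        spec = SyntheticSpec(n_sites=80, seed=29, noise_sigma=0.1,
                             aa_mix={"ASP": 1.0})
        truth = GroundTruthModel(acid_polar=1e-9, acid_neg_prox=-1e-9)
        ds = generate_dataset(spec, truth)
        model = train_tree(ds.features, ds.labels, FAST, "acid")
        one = permutation_importance(model, ds.features, ds.labels,
                                     n_repeats=1, seed=0)
        ten = permutation_importance(model, ds.features, ds.labels,
                                     n_repeats=10, seed=0)
        assert one["feature"].iloc[0] == ten["feature"].iloc[0] == \
            "buried_ratio"
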