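"""Gradient-boosted tree regressors for acid and base pKa's.

Acidic (Asp/Glu/Cys/Tyr) and basic (His/Lys) residues get separate models:
the same microenvironment feature (burial, polar crowding, a nearby
carboxylate) shifts acid and base pKa's in opposite directions, and a
single regressor would have to spend capacity disentangling the two
regimes.  The boosting core is delegated to established implementations
(sklearn histogram/classic GBM and forests, xgboost); this module owns the
protocol around them — MSE loss, k-fold cross-validated grid selection,
seeding, partition/catalog guards, and the repeated-holdout evaluation
loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import (ExtraTreesRegressor, GradientBoostingRegressor,
                              HistGradientBoostingRegressor,
                              RandomForestRegressor)
from sklearn.inspection import partial_dependence
from sklearn.inspection import permutation_importance as _sk_permutation
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.utils.validation import check_is_fitted, validate_data
from xgboost import XGBRegressor

from .dataset import (ACID_AA, BASE_AA, AugmentationPolicy, PkaRecord,
                      SplitPlan, augment_training)
from .features import DEFAULT_CATALOG, FeatureCatalog, featurize_structure
from .structure import read_structure

__all__ = ["TreePkaRegressor", "TreeTrainConfig", "TrainedPkaModel",
           "train_tree", "predict", "run_protocol", "permutation_importance",
           "partial_dependence_slope", "save_model", "load_model",
           "MODEL_FAMILIES"]


def _families():
    return {
        "hist_gbm": (
            lambda rs: HistGradientBoostingRegressor(random_state=rs),
            {"max_depth": [4, 6, 8], "learning_rate": [0.05, 0.1],
             "max_iter": [300, 600]}),
        "gbm": (
            lambda rs: GradientBoostingRegressor(random_state=rs),
            {"max_depth": [4, 6, 8], "learning_rate": [0.05, 0.1],
             "n_estimators": [300, 600]}),
        "xgb": (
            lambda rs: XGBRegressor(objective="reg:squarederror",
                                    tree_method="hist", n_jobs=1,
                                    verbosity=0, random_state=rs),
            {"max_depth": [4, 6, 8], "learning_rate": [0.05, 0.1],
             "n_estimators": [300, 600]}),
        "extra_trees": (
            lambda rs: ExtraTreesRegressor(random_state=rs, n_jobs=1),
            {"n_estimators": [300, 600], "max_features": [1.0, 0.5]}),
        "random_forest": (
            lambda rs: RandomForestRegressor(random_state=rs, n_jobs=1),
            {"n_estimators": [300, 600], "max_features": [1.0, 0.5]}),
    }


MODEL_FAMILIES = tuple(_families())


class TreePkaRegressor(RegressorMixin, BaseEstimator):
    """Cross-validated tree-ensemble pKa regressor (sklearn estimator).

    Fits the chosen family over a small hyperparameter grid, selecting by
    mean k-fold MSE, and refits the best configuration on all data.
    Deterministic given ``random_state``.

    Parameters
    ----------
    model_family : one of ``MODEL_FAMILIES``
    cv_folds : folds of the shuffled KFold used for grid selection
    param_grid : grid mapping, or None for the family default
    random_state : master seed for CV shuffling and the tree ensemble
    """

    def __init__(self, model_family: str = "hist_gbm", cv_folds: int = 10,
                 param_grid: dict | None = None, random_state: int = 0):
        self.model_family = model_family
        self.cv_folds = cv_folds
        self.param_grid = param_grid
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_samples=2)
        if self.model_family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.model_family!r}; "
                             f"choose from {MODEL_FAMILIES}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not np.all(np.isfinite(y)):
            raise ValueError("labels must be finite")
        factory, default_grid = _families()[self.model_family]
        if np.unique(y).size == 1:
            warnings.warn("single unique label; fitting a constant predictor",
                          stacklevel=2)
            self.regressor_ = DummyRegressor(strategy="constant",
                                             constant=float(y[0])).fit(X, y)
            self.best_params_ = {}
            self.cv_mse_ = 0.0
            return self
        grid = self.param_grid if self.param_grid is not None else default_grid
        cv = KFold(n_splits=min(self.cv_folds, len(y)), shuffle=True,
                   random_state=self.random_state)
        search = GridSearchCV(factory(self.random_state), grid, cv=cv,
                              scoring="neg_mean_squared_error", n_jobs=1,
                              refit=True)
        search.fit(X, y)
        self.regressor_ = search.best_estimator_
        self.best_params_ = search.best_params_
        self.cv_mse_ = -float(search.best_score_)
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return np.asarray(self.regressor_.predict(X), dtype=float)


@dataclass
class TreeTrainConfig:
    model_family: str = "hist_gbm"
    cv_folds: int = 10
    param_grid: dict | None = None
    seed: int = 0


@dataclass
class TrainedPkaModel:
    """A fitted partition-specific regressor plus its training fingerprint."""
    partition: str                      # "acid" | "base"
    catalog_version: str
    estimator: TreePkaRegressor
    feature_names: list[str]
    fingerprint: dict = field(default_factory=dict)

    @property
    def allowed_aa(self) -> frozenset:
        return ACID_AA if self.partition == "acid" else BASE_AA


def _design_matrix(features: pd.DataFrame,
                   catalog: FeatureCatalog) -> np.ndarray:
    if "catalog_version" in features.columns and len(features):
        versions = set(features["catalog_version"])
        if versions != {catalog.version}:
            raise ValueError(f"feature rows carry catalog {versions}, "
                             f"expected {catalog.version!r}")
    return catalog.encode(features).to_numpy(dtype=float)


def train_tree(features: pd.DataFrame, labels, config: TreeTrainConfig,
               partition: str, catalog: FeatureCatalog = DEFAULT_CATALOG,
               split_id: int | None = None) -> TrainedPkaModel:
    """Fit one partition model under the CV protocol."""
    if partition not in ("acid", "base"):
        raise ValueError("partition must be 'acid' or 'base'")
    labels = np.asarray(labels, dtype=float)
    if len(features) < 30:
        raise ValueError(f"need >= 30 training rows, got {len(features)}")
    allowed = ACID_AA if partition == "acid" else BASE_AA
    stray = set(features["aa"]) - allowed
    if stray:
        raise ValueError(f"{partition} model fed {sorted(stray)} rows")
    est = TreePkaRegressor(model_family=config.model_family,
                           cv_folds=config.cv_folds,
                           param_grid=config.param_grid,
                           random_state=config.seed)
    est.fit(_design_matrix(features, catalog), labels)
    return TrainedPkaModel(partition=partition, catalog_version=catalog.version,
                           estimator=est, feature_names=catalog.names,
                           fingerprint={"split_id": split_id,
                                        "seed": config.seed,
                                        "model_family": config.model_family})


def predict(model: TrainedPkaModel, features: pd.DataFrame,
            catalog: FeatureCatalog = DEFAULT_CATALOG) -> np.ndarray:
    """Predicted pKa per feature row, guarded by partition and catalog."""
    if catalog.version != model.catalog_version:
        raise ValueError(f"catalog {catalog.version!r} does not match model "
                         f"({model.catalog_version!r})")
    if len(features) == 0:
        return np.empty(0)
    stray = set(features["aa"]) - model.allowed_aa
    if stray:
        raise ValueError(f"{model.partition} model cannot score "
                         f"{sorted(stray)} residues")
    return model.estimator.predict(_design_matrix(features, catalog))


class _FeatureStore:
    """Featurize each structure once; index rows by (structure, chain, resseq)."""

    def __init__(self, structures, catalog: FeatureCatalog):
        self._structures = structures
        self._catalog = catalog
        self._cache: dict[str, pd.DataFrame] = {}

    def row(self, structure_id: str, chain: str, resseq: int) -> pd.Series:
        if structure_id not in self._cache:
            source = self._structures[structure_id]
            st = source if hasattr(source, "residues") else read_structure(source)
            st.source_id = structure_id
            self._cache[structure_id] = featurize_structure(st, self._catalog)
        df = self._cache[structure_id]
        hit = df[(df["chain"] == chain) & (df["resseq"] == resseq)]
        if len(hit) != 1:
            raise KeyError(f"no unique site ({chain}, {resseq}) "
                           f"in {structure_id}")
        return hit.iloc[0]


def _instance_table(records: list[PkaRecord], store: _FeatureStore
                    ) -> pd.DataFrame:
    """One row per (record, structure) pair: features + identity + label."""
    rows = []
    for rec in records:
        for sid in rec.structure_refs:
            row = store.row(sid, rec.chain, rec.resseq).copy()
            row["protein"] = rec.protein
            row["mutation"] = rec.mutation
            row["conf_state"] = rec.conf_state
            row["unique_key"] = rec.unique_key
            row["pka_exp"] = rec.pka_exp
            row["structure_ref"] = sid
            rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)


def run_protocol(records: list[PkaRecord], structures, split_plan: SplitPlan,
                 config: TreeTrainConfig = TreeTrainConfig(),
                 catalog: FeatureCatalog = DEFAULT_CATALOG,
                 augmentation: AugmentationPolicy | None = None,
                 conformer_source=None) -> pd.DataFrame:
    """Train acid+base models on every split, predict every test instance.

    Returns one prediction per (record, structure) pair per split, with
    columns split_id, unique_key, structure_ref, aa, partition, pka_exp,
    pka_pred.  Conformer augmentation, when enabled, is applied to the
    training records only, after splitting.
    """
    store = _FeatureStore(structures, catalog)
    out = []
    for split_id in range(split_plan.n_splits):
        train_keys = split_plan.train_keys(split_id)
        test_keys = split_plan.test_keys(split_id)
        train_recs = [r for r in records if r.unique_key in train_keys]
        test_recs = [r for r in records if r.unique_key in test_keys]
        if augmentation is not None and conformer_source is not None:
            train_recs = augment_training(train_recs, conformer_source,
                                          augmentation)
        try:
            for partition, recs_filter in (("acid", ACID_AA), ("base", BASE_AA)):
                tr = [r for r in train_recs if r.aa in recs_filter]
                te = [r for r in test_recs if r.aa in recs_filter]
                if not te:
                    continue
                train_tab = _instance_table(tr, store)
                test_tab = _instance_table(te, store)
                model = train_tree(train_tab, train_tab["pka_exp"], config,
                                   partition, catalog, split_id=split_id)
                preds = predict(model, test_tab, catalog)
                res = test_tab[["unique_key", "structure_ref", "aa",
                                "pka_exp"]].copy()
                res["pka_pred"] = preds
                res["partition"] = partition
                res["split_id"] = split_id
                out.append(res)
        except Exception as exc:
            raise RuntimeError(f"protocol failed at split {split_id}") from exc
    return pd.concat(out, ignore_index=True)


def save_model(model: TrainedPkaModel, directory) -> None:
    """Persist as a directory bundle: manifest.json + regressor artifact."""
    import json
    from pathlib import Path

    import joblib
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"partition": model.partition,
                "catalog_version": model.catalog_version,
                "feature_names": model.feature_names,
                "fingerprint": model.fingerprint}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    joblib.dump(model.estimator, directory / "regressor.joblib")


def load_model(directory) -> TrainedPkaModel:
    import json
    from pathlib import Path

    import joblib
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    est = joblib.load(directory / "regressor.joblib")
    return TrainedPkaModel(partition=manifest["partition"],
                           catalog_version=manifest["catalog_version"],
                           estimator=est,
                           feature_names=manifest["feature_names"],
                           fingerprint=manifest["fingerprint"])


def permutation_importance(model: TrainedPkaModel, features: pd.DataFrame,
                           labels, n_repeats: int = 5, seed: int = 0,
                           catalog: FeatureCatalog = DEFAULT_CATALOG
                           ) -> pd.DataFrame:
    """Mean MSE increase on permuting each feature column, ranked.

    Ties are broken by catalog order.  Serves as the model-inspection
    surface (a permutation analogue of attribution plots).
    """
    X = _design_matrix(features, catalog)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 features")
    y = np.asarray(labels, dtype=float)
    res = _sk_permutation(model.estimator, X, y, n_repeats=n_repeats,
                          random_state=seed,
                          scoring="neg_mean_squared_error", n_jobs=1)
    order = np.lexsort((np.arange(X.shape[1]), -res.importances_mean))
    return pd.DataFrame({
        "feature": [catalog.names[i] for i in order],
        "importance": res.importances_mean[order],
        "importance_sd": res.importances_std[order]})


def partial_dependence_slope(model: TrainedPkaModel, features: pd.DataFrame,
                             feature_name: str,
                             catalog: FeatureCatalog = DEFAULT_CATALOG,
                             grid_resolution: int = 20) -> float:
    """Least-squares slope of the partial-dependence curve of one feature."""
    X = _design_matrix(features, catalog)
    idx = catalog.names.index(feature_name)
    pd_res = partial_dependence(model.estimator, X, [idx],
                                grid_resolution=grid_resolution)
    grid = np.asarray(pd_res["grid_values"][0], dtype=float)
    avg = np.asarray(pd_res["average"][0], dtype=float)
    if grid.size < 2 or np.ptp(grid) == 0:
        return 0.0
    return float(np.polyfit(grid, avg, 1)[0])
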