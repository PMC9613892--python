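"""Subpart x horizon submodels, stacked meta-prediction, and ablation.

The predictive architecture: nine gradient-boosted (XGBoost) classifiers,
one per MDS-UPDRS subpart {I, II, III} x horizon {12, 24, 36 months},
trained on baseline features only.  Their predicted progression
probabilities become *meta-features* which, together with the baseline
features, feed a final boosted meta-predictor of 12-month (or 24/36-month)
MDS-UPDRS Total progression.  Direct Total classifiers are trained for
comparison but their outputs are never meta-features.

Hyperparameters are tuned by random search over the configured space
(validation F1 objective); feature selection (top-25 by mean |Shapley
attribution| of an explainer fitted on an internal split) is applied per
submodel and again at the meta level.  Meta-features for training subjects
are produced out-of-fold (5-fold by default) so no subject's meta-feature
comes from a model that trained on that subject.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier

from .evaluation import classification_metrics
from .features import (FeatureSchema, Imputer, Scaler, drop_high_missingness,
                       fit_explainer, rank_features, select_top)

log = logging.getLogger(__name__)

__all__ = [
    "SearchSpace", "ModelConfig", "SubmodelRecord", "SubmodelSet",
    "stratified_split", "tune_submodel", "train_submodels",
    "comparator_models", "build_meta_features", "train_meta",
    "run_experiment", "ablate", "ExperimentResult",
]

SUBPARTS = ("i", "ii", "iii")
HORIZONS = (12, 24, 36)
# column names a feature matrix must never contain (label leakage guard)
FORBIDDEN_FEATURES = ("progressor", "label", "slope", "status")


@dataclass
class SearchSpace:
    """Random-search ranges for the boosted-tree hyperparameters.

    Regularization/learning-rate style parameters span [1e-8, 1] sampled
    log-uniformly; DART-specific parameters (rate_drop, skip_drop,
    sample_type, normalize_type) are sampled for every trial but only passed
    to the model when the booster is "dart".
    """

    lambda_range: tuple[float, float] = (1e-8, 1.0)
    alpha_range: tuple[float, float] = (1e-8, 1.0)
    eta_range: tuple[float, float] = (1e-8, 1.0)
    gamma_range: tuple[float, float] = (1e-8, 1.0)
    rate_drop_range: tuple[float, float] = (1e-8, 1.0)
    skip_drop_range: tuple[float, float] = (1e-8, 1.0)
    subsample_range: tuple[float, float] = (0.5, 1.0)
    colsample_bytree_range: tuple[float, float] = (0.5, 1.0)
    scale_pos_weight_range: tuple[float, float] = (0.8, 1.2)
    max_depth_range: tuple[int, int] = (6, 36)
    min_child_weight_range: tuple[int, int] = (1, 10)
    grow_policies: tuple[str, ...] = ("depthwise", "lossguide")
    sample_types: tuple[str, ...] = ("uniform", "weighted")
    normalize_types: tuple[str, ...] = ("tree", "forest")

    def _log_uniform(self, rng: np.random.Generator,
                     lo_hi: tuple[float, float]) -> float:
        lo, hi = lo_hi
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    def sample(self, rng: np.random.Generator) -> dict:
        return {
            "lambda": self._log_uniform(rng, self.lambda_range),
            "alpha": self._log_uniform(rng, self.alpha_range),
            "eta": self._log_uniform(rng, self.eta_range),
            "gamma": self._log_uniform(rng, self.gamma_range),
            "rate_drop": self._log_uniform(rng, self.rate_drop_range),
            "skip_drop": self._log_uniform(rng, self.skip_drop_range),
            "subsample": float(rng.uniform(*self.subsample_range)),
            "colsample_bytree": float(rng.uniform(*self.colsample_bytree_range)),
            "scale_pos_weight": float(rng.uniform(*self.scale_pos_weight_range)),
            "max_depth": int(rng.integers(self.max_depth_range[0],
                                          self.max_depth_range[1] + 1)),
            "min_child_weight": int(rng.integers(
                self.min_child_weight_range[0],
                self.min_child_weight_range[1] + 1)),
            "grow_policy": str(rng.choice(self.grow_policies)),
            "sample_type": str(rng.choice(self.sample_types)),
            "normalize_type": str(rng.choice(self.normalize_types)),
        }


@dataclass
class ModelConfig:
    """Knobs of the training procedure (not of individual models)."""

    n_trials: int = 25
    n_estimators: int = 60
    booster: str = "gbtree"
    oof_folds: int = 10
    top_k: int = 25
    test_fraction: float = 0.25
    threshold: float = 0.5
    meta_horizon: int = 12                       # primary meta target
    meta_horizons: tuple[int, ...] = (12, 24, 36)  # all meta-predictors built
    space: SearchSpace = field(default_factory=SearchSpace)


def _xgb_model(params: dict, cfg: ModelConfig, seed: int) -> xgb.XGBClassifier:
    kwargs = dict(
        n_estimators=cfg.n_estimators, booster=cfg.booster,
        reg_lambda=params["lambda"], reg_alpha=params["alpha"],
        learning_rate=params["eta"], gamma=params["gamma"],
        subsample=params["subsample"],
        colsample_bytree=params["colsample_bytree"],
        scale_pos_weight=params["scale_pos_weight"],
        max_depth=params["max_depth"],
        min_child_weight=params["min_child_weight"],
        grow_policy=params["grow_policy"],
        tree_method="hist", eval_metric="logloss", n_jobs=1,
        random_state=int(seed) % (2 ** 31))
    if cfg.booster == "dart":
        kwargs.update(rate_drop=params["rate_drop"],
                      skip_drop=params["skip_drop"],
                      sample_type=params["sample_type"],
                      normalize_type=params["normalize_type"])
    return xgb.XGBClassifier(**kwargs)


def _f1(y_true: np.ndarray, y_prob: np.ndarray, threshold: float) -> float:
    return classification_metrics(y_true, y_prob, threshold).f1


def _check_features(X: pd.DataFrame) -> None:
    leaked = [c for c in X.columns
              if any(tok in c.lower() for tok in FORBIDDEN_FEATURES)]
    if leaked:
        raise ValueError(f"label-derived column(s) in feature matrix: {leaked}")


def stratified_split(ids: pd.Index, labels: pd.Series,
                     test_fraction: float = 0.25, seed: int = 0
                     ) -> tuple[pd.Index, pd.Index]:
    """Disjoint, exhaustive, label-stratified partition of subjects.

    Prevalence in each part stays within the stratification tolerance of the
    parent by construction.  Raises when a class has fewer than 2 members.
    """
    y = labels.reindex(ids)
    if y.isna().any():
        raise ValueError("labels missing for some subjects")
    if y.value_counts().min() < 2:
        raise ValueError("a label class has fewer than 2 members")
    tr, te = train_test_split(np.asarray(ids), test_size=test_fraction,
                              stratify=y.values,
                              random_state=int(seed) % (2 ** 31))
    return pd.Index(tr), pd.Index(te)


def tune_submodel(X_tr: pd.DataFrame, y_tr: pd.Series,
                  X_val: pd.DataFrame, y_val: pd.Series,
                  cfg: ModelConfig, seed: int = 0
                  ) -> tuple[dict, xgb.XGBClassifier, float]:
    """Random hyperparameter search maximizing validation F1.

    Returns (best params, model fitted on the training rows, best F1).
    Deterministic given seed; ties broken by trial order.
    """
    if cfg.n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    best = None
    for trial in range(cfg.n_trials):
        params = cfg.space.sample(rng)
        model = _xgb_model(params, cfg, seed=seed + trial)
        model.fit(X_tr, y_tr)
        f1 = _f1(y_val.values, model.predict_proba(X_val)[:, 1],
                 cfg.threshold)
        if best is None or f1 > best[2]:
            best = (params, model, f1)
    return best


@dataclass
class SubmodelRecord:
    part: str
    horizon: int
    features: list[str]
    params: dict
    model: xgb.XGBClassifier
    val_f1: float
    oof_prob: pd.Series          # out-of-fold probabilities, training rows
    oof_fold: pd.Series          # audit: fold index per training row
    fold_train_ids: list[set]    # audit: training ids per fold
    ranking: pd.DataFrame


class SubmodelSet(dict):
    """Mapping (part, horizon) -> SubmodelRecord; ``direct`` holds the
    direct Total classifiers by horizon."""

    def __init__(self):
        super().__init__()
        self.direct: dict[int, SubmodelRecord] = {}


def _fit_one_target(X: pd.DataFrame, y: pd.Series, cfg: ModelConfig,
                    seed: int, part: str, horizon: int) -> SubmodelRecord | None:
    """Feature-select, tune, fit and out-of-fold-predict one target."""
    rows = y.index.intersection(X.index)
    y = y.loc[rows].astype(int)
    if y.nunique() < 2:
        warnings.warn(f"target ({part},{horizon}) single-class; skipped")
        return None
    Xr = X.loc[rows]

    tr, val = stratified_split(rows, y, cfg.test_fraction, seed)
    itr, ite = stratified_split(tr, y.loc[tr], cfg.test_fraction, seed + 1)
    explainer = fit_explainer(Xr.loc[itr], y.loc[itr].values, seed=seed)
    ranking = rank_features(explainer, Xr.loc[ite])
    feats = select_top(ranking, cfg.top_k)

    params, _, val_f1 = tune_submodel(Xr.loc[tr, feats], y.loc[tr],
                                      Xr.loc[val, feats], y.loc[val],
                                      cfg, seed=seed + 2)
    model = _xgb_model(params, cfg, seed=seed + 3)
    model.fit(Xr[feats], y)

    n_folds = min(cfg.oof_folds, int(y.value_counts().min()))
    skf = StratifiedKFold(n_splits=max(2, n_folds), shuffle=True,
                          random_state=seed % (2 ** 31))
    oof = pd.Series(np.nan, index=rows, dtype=float)
    fold_id = pd.Series(-1, index=rows, dtype=int)
    fold_train_ids = []
    for k, (a, b) in enumerate(skf.split(Xr[feats], y)):
        m = _xgb_model(params, cfg, seed=seed + 10 + k)
        m.fit(Xr.iloc[a][feats], y.iloc[a])
        oof.iloc[b] = m.predict_proba(Xr.iloc[b][feats])[:, 1]
        fold_id.iloc[b] = k
        fold_train_ids.append(set(rows[a]))
    return SubmodelRecord(part, horizon, feats, params, model, val_f1,
                          oof, fold_id, fold_train_ids, ranking)


def train_submodels(X: pd.DataFrame, labels: pd.DataFrame,
                    cfg: ModelConfig, seed: int = 0) -> SubmodelSet:
    """Train the nine subpart x horizon submodels plus the three direct
    Total classifiers, each with its own top-k feature set.

    ``X`` must contain baseline features only (validated against obviously
    label-derived column names); ``labels`` is the long table from
    ``label_progression``.
    """
    _check_features(X)
    out = SubmodelSet()
    for i, part in enumerate(SUBPARTS):
        for j, h in enumerate(HORIZONS):
            y = labels[(labels["part"] == part)
                       & (labels["horizon"] == h)].set_index(
                           "participant_id")["progressor"]
            rec = _fit_one_target(X, y, cfg, seed + 100 * i + 10 * j, part, h)
            if rec is not None:
                out[(part, h)] = rec
    for j, h in enumerate(HORIZONS):
        y = labels[(labels["part"] == "total")
                   & (labels["horizon"] == h)].set_index(
                       "participant_id")["progressor"]
        rec = _fit_one_target(X, y, cfg, seed + 1000 + 10 * j, "total", h)
        if rec is not None:
            out.direct[h] = rec
    return out


class BalancedRandomForest:
    """Random forest with class-balanced bootstrap samples: each tree is
    grown on an equal-size resample of both classes (majority undersampled),
    so minority recall is not sacrificed to the base rate.  Probabilities
    are the across-tree average."""

    def __init__(self, n_estimators: int = 200, seed: int = 0):
        self.n_estimators = n_estimators
        self.seed = seed
        self.trees_: list[DecisionTreeClassifier] = []

    def fit(self, X, y) -> "BalancedRandomForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(self.seed)
        idx0, idx1 = np.where(y == 0)[0], np.where(y == 1)[0]
        if len(idx0) == 0 or len(idx1) == 0:
            raise ValueError("both classes required")
        m = min(len(idx0), len(idx1))
        self.trees_ = []
        for _ in range(self.n_estimators):
            s = np.concatenate([rng.choice(idx0, m, replace=True),
                                rng.choice(idx1, m, replace=True)])
            tree = DecisionTreeClassifier(
                max_features="sqrt", random_state=int(rng.integers(2 ** 31)))
            tree.fit(X[s], y[s])
            self.trees_.append(tree)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        p = np.mean([t.predict_proba(X)[:, 1] for t in self.trees_], axis=0)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def comparator_models(X_tr: pd.DataFrame, y_tr: pd.Series,
                      X_val: pd.DataFrame, y_val: pd.Series,
                      seed: int = 0, threshold: float = 0.5) -> dict:
    """Logistic-regression and balanced random-forest comparators with
    validation F1s."""
    lr = LogisticRegression(max_iter=2000, random_state=seed % (2 ** 31))
    lr.fit(X_tr, y_tr)
    brf = BalancedRandomForest(n_estimators=200, seed=seed % (2 ** 31))
    brf.fit(X_tr, y_tr)
    out = {}
    for name, model in (("logistic_regression", lr),
                        ("balanced_random_forest", brf)):
        prob = model.predict_proba(X_val)[:, 1]
        out[name] = {"model": model,
                     "f1": _f1(y_val.values, prob, threshold)}
    return out


def build_meta_features(submodels: SubmodelSet, X: pd.DataFrame,
                        training: bool,
                        base_cols: list[str] | None = None) -> pd.DataFrame:
    """Nine submodel probability columns joined to the (selected) baseline
    features.

    For training rows the probabilities are out-of-fold (a subject's own
    fold never produced its meta-feature; missing targets are filled with
    the training-mean probability).  For external rows the submodels fitted
    on the full training split are applied.  ``base_cols`` restricts which
    baseline columns are appended (default: all of ``X``).
    """
    if len(submodels) == 0:
        raise ValueError("no submodels available")
    meta = pd.DataFrame(index=X.index)
    for (part, h), rec in sorted(submodels.items()):
        col = f"pred_{part}_{h}m"
        if training:
            prob = rec.oof_prob.reindex(X.index)
            prob = prob.fillna(rec.oof_prob.mean())
        else:
            prob = pd.Series(
                rec.model.predict_proba(X[rec.features])[:, 1], index=X.index)
        meta[col] = prob.values
    assert ((meta.values >= 0) & (meta.values <= 1)).all()
    return pd.concat([meta, X[base_cols] if base_cols is not None else X],
                     axis=1)


def audit_oof(submodels: SubmodelSet) -> bool:
    """Protocol assertion: for every submodel and fold, no subject is both
    in that fold's training set and assigned that fold's predictions."""
    for rec in submodels.values():
        for k, train_ids in enumerate(rec.fold_train_ids):
            val_ids = set(rec.oof_fold.index[rec.oof_fold == k])
            if val_ids & train_ids:
                return False
    return True


def train_meta(meta_X: pd.DataFrame, y: pd.Series, cfg: ModelConfig,
               seed: int = 0) -> SubmodelRecord:
    """Tuned boosted meta-classifier over meta-features + baseline features,
    with feature selection applied again at the meta level (so longer-horizon
    meta-features can be selected)."""
    rec = _fit_one_target(meta_X, y, cfg, seed, "meta_total", cfg.meta_horizon)
    if rec is None:
        raise ValueError("meta target is single-class")
    return rec


# ---------------------------------------------------------------------------
# end-to-end experiment (shared by the pipeline, the ablation, and tests)
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    submodels: SubmodelSet
    meta: SubmodelRecord
    transforms: dict                 # fitted imputer/scaler/kept columns
    holdout: dict                    # metrics on the training-cohort holdout
    external: dict | None            # metrics on the external cohort
    holdout_direct: dict | None
    external_direct: dict | None
    comparators: dict
    metas: dict = field(default_factory=dict)   # horizon -> SubmodelRecord
    metas_holdout: dict = field(default_factory=dict)  # horizon -> metrics
    dropped_class: str | None = None
    noop: bool = False


def fit_transforms(X_train: pd.DataFrame, schema: FeatureSchema) -> dict:
    """Missingness filter + typed imputer + scaler, fitted on training rows
    only.  Returns the frozen transform bundle."""
    Xf, removed = drop_high_missingness(X_train)
    imputer = Imputer(schema).fit(Xf)
    scaler = Scaler().fit(imputer.transform(Xf))
    return {"columns": list(Xf.columns), "removed": removed,
            "imputer": imputer, "scaler": scaler}


def apply_transforms(X: pd.DataFrame, transforms: dict) -> pd.DataFrame:
    cols = [c for c in transforms["columns"] if c in X.columns]
    missing = [c for c in transforms["columns"] if c not in X.columns]
    out = transforms["scaler"].transform(
        transforms["imputer"].transform(X[cols]))
    # external cohorts may lack columns entirely (e.g. no imaging): encode
    # as the training mean (0 after scaling)
    for c in missing:
        out[c] = 0.0
    return out[transforms["columns"]]


def run_experiment(X_a: pd.DataFrame, labels_a: pd.DataFrame,
                   schema: FeatureSchema, cfg: ModelConfig, seed: int,
                   X_b: pd.DataFrame | None = None,
                   labels_b: pd.DataFrame | None = None,
                   drop_class: str | None = None,
                   with_comparators: bool = False) -> ExperimentResult:
    """Full training-cohort experiment: split, fit transforms, train the
    nine submodels + direct Total models + meta-predictor, evaluate on the
    holdout split and (optionally) on an external cohort.

    ``drop_class`` removes every feature column of one class tag before any
    fitting (feature-class ablation); dropping a class with no columns in
    the data is a warned no-op.
    """
    noop = False
    if drop_class is not None:
        drop_cols = [c for c in schema.columns_of_class(drop_class)
                     if c in X_a.columns]
        if not drop_cols:
            warnings.warn(f"ablation {drop_class!r}: no matching columns; "
                          "no-op")
            noop = True
        X_a = X_a.drop(columns=drop_cols)
        if X_b is not None:
            X_b = X_b.drop(columns=[c for c in drop_cols if c in X_b.columns])

    meta_y = labels_a[(labels_a["part"] == "total")
                      & (labels_a["horizon"] == cfg.meta_horizon)].set_index(
                          "participant_id")["progressor"]
    ids = X_a.index.intersection(meta_y.index)
    train_ids, test_ids = stratified_split(ids, meta_y, cfg.test_fraction,
                                           seed)
    transforms = fit_transforms(X_a.loc[train_ids], schema)
    Xtr = apply_transforms(X_a.loc[train_ids], transforms)
    Xte = apply_transforms(X_a.loc[test_ids], transforms)

    labels_tr = labels_a[labels_a["participant_id"].isin(set(train_ids))]
    submodels = train_submodels(Xtr, labels_tr, cfg, seed=seed + 1)
    assert audit_oof(submodels), "out-of-fold protocol violated"

    # the meta-table pairs the nine probabilities with the SELECTED baseline
    # features: the union of the submodels' top-k selections (plus the
    # direct-Total selection), not the full baseline matrix — feature
    # selection then runs again at the meta level
    selected = set().union(*(rec.features for rec in submodels.values()))
    direct_rec = submodels.direct.get(cfg.meta_horizon)
    if direct_rec is not None:
        selected |= set(direct_rec.features)
    base_cols = sorted(selected)
    meta_train = build_meta_features(submodels, Xtr, training=True,
                                     base_cols=base_cols)
    meta_rec = train_meta(meta_train, meta_y.loc[train_ids], cfg,
                          seed=seed + 2)

    def meta_metrics(X_ext: pd.DataFrame, y_ext: pd.Series) -> dict:
        mx = build_meta_features(submodels, X_ext, training=False,
                                 base_cols=base_cols)
        rows = y_ext.index.intersection(mx.index)
        prob = meta_rec.model.predict_proba(
            mx.loc[rows, meta_rec.features])[:, 1]
        return classification_metrics(y_ext.loc[rows].values, prob,
                                      cfg.threshold).to_dict()

    def direct_metrics(X_ext: pd.DataFrame, y_ext: pd.Series) -> dict | None:
        rec = submodels.direct.get(cfg.meta_horizon)
        if rec is None:
            return None
        rows = y_ext.index.intersection(X_ext.index)
        prob = rec.model.predict_proba(X_ext.loc[rows, rec.features])[:, 1]
        return classification_metrics(y_ext.loc[rows].values, prob,
                                      cfg.threshold).to_dict()

    holdout = meta_metrics(Xte, meta_y.loc[test_ids])
    holdout_direct = direct_metrics(Xte, meta_y.loc[test_ids])

    # meta-predictors for the remaining horizons (same submodels/meta-features)
    metas: dict[int, SubmodelRecord] = {cfg.meta_horizon: meta_rec}
    metas_holdout: dict[int, dict] = {cfg.meta_horizon: holdout}
    for h in cfg.meta_horizons:
        if h == cfg.meta_horizon:
            continue
        y_h = labels_a[(labels_a["part"] == "total")
                       & (labels_a["horizon"] == h)].set_index(
                           "participant_id")["progressor"]
        y_h_tr = y_h.reindex(train_ids).dropna()
        if y_h_tr.nunique() < 2:
            continue
        sub_cfg = ModelConfig(**{**cfg.__dict__, "meta_horizon": h})
        rec_h = train_meta(meta_train.loc[meta_train.index.intersection(
            y_h_tr.index)], y_h_tr, sub_cfg, seed=seed + 3 + h)
        metas[h] = rec_h
        mx = build_meta_features(submodels, Xte, training=False,
                                 base_cols=base_cols)
        rows = y_h.index.intersection(mx.index)
        if len(rows) and y_h.loc[rows].nunique() == 2:
            prob = rec_h.model.predict_proba(mx.loc[rows, rec_h.features])[:, 1]
            metas_holdout[h] = classification_metrics(
                y_h.loc[rows].values, prob, cfg.threshold).to_dict()

    external = external_direct = None
    if X_b is not None and labels_b is not None:
        meta_y_b = labels_b[(labels_b["part"] == "total")
                            & (labels_b["horizon"] == cfg.meta_horizon)
                            ].set_index("participant_id")["progressor"]
        Xb = apply_transforms(X_b, transforms)
        external = meta_metrics(Xb, meta_y_b)
        external_direct = direct_metrics(Xb, meta_y_b)

    comparators = {}
    if with_comparators:
        ctr, cval = stratified_split(train_ids, meta_y.loc[train_ids],
                                     cfg.test_fraction, seed + 5)
        comp = comparator_models(Xtr.loc[ctr], meta_y.loc[ctr],
                                 Xtr.loc[cval], meta_y.loc[cval],
                                 seed=seed + 6, threshold=cfg.threshold)
        comparators = {k: {"f1": v["f1"]} for k, v in comp.items()}

    return ExperimentResult(submodels, meta_rec, transforms, holdout,
                            external, holdout_direct, external_direct,
                            comparators, metas, metas_holdout, drop_class,
                            noop)


def ablate(X_a: pd.DataFrame, labels_a: pd.DataFrame, schema: FeatureSchema,
           cfg: ModelConfig, seed: int,
           X_b: pd.DataFrame | None = None,
           labels_b: pd.DataFrame | None = None,
           classes: tuple[str, ...] = ("genetic", "physician-exam",
                                       "survey", "imaging")) -> dict:
    """Feature-class ablation: refit the full pipeline without each class
    and report the metric deltas against the full model."""
    # ablation only needs the primary-horizon meta-predictor
    cfg = ModelConfig(**{**cfg.__dict__, "meta_horizons": (cfg.meta_horizon,)})
    full = run_experiment(X_a, labels_a, schema, cfg, seed, X_b, labels_b)
    out = {"full": full, "ablations": {}}
    for cls in classes:
        res = run_experiment(X_a, labels_a, schema, cfg, seed, X_b, labels_b,
                             drop_class=cls)
        delta = None
        if res.holdout.get("roc_auc") is not None and \
                full.holdout.get("roc_auc") is not None:
            delta = res.holdout["roc_auc"] - full.holdout["roc_auc"]
        out["ablations"][cls] = {"result": res, "delta_roc_auc": delta}
    return out
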