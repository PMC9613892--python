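"""Feature engineering: missingness filtering, typed imputation,
train-anchored standardization, and Shapley-attribution feature ranking.

Every transform is fitted on training rows only and the fitted parameters
are frozen and reapplied unchanged to any external cohort, so no statistic
of a test cohort ever leaks into the modelling path.  Feature importance is
computed with exact tree-path Shapley attributions (TreeSHAP, as implemented
natively by XGBoost via ``pred_contribs``): for a tree ensemble these are
exact, and per-row attributions plus the base value reconstruct the model
margin.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb

from .synthetic import MOCA_SUBSCORES, N_ITEMS, PART_NAMES, LongitudinalCohort

log = logging.getLogger(__name__)

__all__ = [
    "FeatureSchema", "build_baseline_features", "drop_high_missingness",
    "Imputer", "Scaler", "fit_explainer", "shap_values", "rank_features",
    "select_top",
]

FEATURE_CLASSES = ("genetic", "physician-exam", "survey", "imaging",
                   "demographic")
CONTINUOUS, ORDINAL, CATEGORICAL = "continuous", "ordinal", "categorical"

# Columns accepted in input but excluded from modelling by default: the
# Epworth Sleepiness Scale adds minimal predictive power next to the
# MDS-UPDRS components, and treatment flags are used for label adjustment,
# not prediction.
DEFAULT_EXCLUDED = ("ess_total", "epworth_total", "tx_levodopa",
                    "tx_dopamine_agonist", "tx_other_pd_med", "treated_any")


@dataclass
class FeatureSchema:
    """Column dictionary: per feature a type (continuous / ordinal /
    categorical) and a feature-class tag (genetic / physician-exam / survey /
    imaging / demographic)."""

    table: pd.DataFrame  # columns: column, dtype, feature_class

    def __post_init__(self) -> None:
        bad = set(self.table["feature_class"]) - set(FEATURE_CLASSES)
        if bad:
            raise ValueError(f"unknown feature class(es): {sorted(bad)}")
        bad = set(self.table["dtype"]) - {CONTINUOUS, ORDINAL, CATEGORICAL}
        if bad:
            raise ValueError(f"unknown dtype(s): {sorted(bad)}")
        if self.table["column"].duplicated().any():
            raise ValueError("duplicate columns in schema")

    def dtype(self, col: str) -> str:
        return self.table.set_index("column").loc[col, "dtype"]

    def feature_class(self, col: str) -> str:
        return self.table.set_index("column").loc[col, "feature_class"]

    def columns_of_class(self, feature_class: str) -> list[str]:
        if feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class: {feature_class}")
        t = self.table
        return t.loc[t["feature_class"] == feature_class, "column"].tolist()

    def subset(self, columns: list[str]) -> "FeatureSchema":
        t = self.table[self.table["column"].isin(set(columns))]
        return FeatureSchema(t.reset_index(drop=True))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureSchema":
        return cls(pd.read_csv(path, sep="\t"))


def build_baseline_features(cohort: LongitudinalCohort,
                            prs: pd.DataFrame | None = None
                            ) -> tuple[pd.DataFrame, FeatureSchema]:
    """Assemble the subject x baseline-feature matrix and its schema.

    Baseline (month 0) MDS-UPDRS items, subpart summaries and Total are
    joined to the subject-level static features and, when provided, the
    per-subject polygenic scores (DataFrame indexed by participant with
    columns pd_prs / ea_prs).  Excluded-by-default columns are dropped here.
    """
    base = cohort.visits[cohort.visits["visit_month"] == 0].set_index(
        "participant_id").drop(columns=["visit_month"])
    subj = cohort.subjects.set_index("participant_id")
    X = subj.join(base, how="inner")
    if prs is not None:
        X = X.join(prs, how="left")
    X = X.drop(columns=[c for c in DEFAULT_EXCLUDED if c in X.columns])
    if "sex" in X.columns:
        X["sex"] = (X["sex"] == "F").astype(int)

    rows = []

    def tag(col: str, dtype: str, fclass: str) -> None:
        if col in X.columns:
            rows.append((col, dtype, fclass))

    tag("age_at_baseline", CONTINUOUS, "demographic")
    tag("sex", CATEGORICAL, "demographic")
    tag("education_years", ORDINAL, "demographic")
    for g in ("GBA", "LRRK2", "SNCA"):
        tag(f"{g}_carrier", CATEGORICAL, "genetic")
    tag("monogenic_any", CATEGORICAL, "genetic")
    tag("pd_prs", CONTINUOUS, "genetic")
    tag("ea_prs", CONTINUOUS, "genetic")
    for name in MOCA_SUBSCORES:
        tag(name, ORDINAL, "survey")
    tag("moca_total", CONTINUOUS, "survey")
    tag("se_adl", ORDINAL, "survey")
    tag("upsit_total", CONTINUOUS, "survey")
    tag("hoehn_yahr", ORDINAL, "physician-exam")
    for sbr in ("sbr_caudate_r", "sbr_caudate_l", "sbr_putamen_r",
                "sbr_putamen_l"):
        tag(sbr, CONTINUOUS, "imaging")
    part_class = {"i": "survey", "ii": "survey", "iii": "physician-exam"}
    for p, n in zip(PART_NAMES, N_ITEMS):
        for k in range(1, n + 1):
            tag(f"mds_updrs_{p}_item_{k:02d}", ORDINAL, part_class[p])
        tag(f"mds_updrs_{p}_summary_score", CONTINUOUS, part_class[p])
    # Total is dominated by the physician-exam part III component
    tag("mds_updrs_total_score", CONTINUOUS, "physician-exam")

    schema = FeatureSchema(pd.DataFrame(
        rows, columns=["column", "dtype", "feature_class"]))
    return X[schema.table["column"].tolist()].astype(float), schema


def drop_high_missingness(table: pd.DataFrame, threshold: float = 0.5
                          ) -> tuple[pd.DataFrame, list[str]]:
    """Remove columns whose missing fraction is STRICTLY above threshold;
    returns (filtered table, removed column names)."""
    frac = table.isna().mean(axis=0)
    removed = frac.index[frac > threshold].tolist()
    if removed:
        log.info("dropping %d high-missingness columns: %s",
                 len(removed), removed)
    return table.drop(columns=removed), removed


class Imputer:
    """Typed single-value imputation: continuous -> training mean,
    ordinal -> training median, categorical -> training mode.  Fitted on
    training rows only; parameters reused verbatim on test rows."""

    def __init__(self, schema: FeatureSchema):
        self.schema = schema
        self.values_: dict[str, float] | None = None

    def fit(self, train: pd.DataFrame) -> "Imputer":
        values = {}
        types = self.schema.table.set_index("column")["dtype"]
        for col in train.columns:
            obs = train[col].dropna()
            if obs.empty:
                raise ValueError(f"all-missing column {col!r}: should have "
                                 "been dropped by the missingness filter")
            kind = types.get(col, CONTINUOUS)
            if kind == CONTINUOUS:
                values[col] = float(obs.mean())
            elif kind == ORDINAL:
                values[col] = float(obs.median())
            else:
                values[col] = float(obs.mode().iloc[0])
        self.values_ = values
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.values_ is None:
            raise RuntimeError("Imputer not fitted")
        out = table.copy()
        for col, v in self.values_.items():
            if col in out.columns:
                out[col] = out[col].fillna(v)
        return out


class Scaler:
    """Standard scaler (subtract training mean, divide by training SD).

    Zero-variance columns are centred but not rescaled (scale forced to 1,
    with a warning).
    """

    def __init__(self):
        self.mean_: pd.Series | None = None
        self.scale_: pd.Series | None = None

    def fit(self, train: pd.DataFrame) -> "Scaler":
        self.mean_ = train.mean(axis=0)
        sd = train.std(axis=0, ddof=0)
        zero = sd[sd == 0].index.tolist()
        if zero:
            warnings.warn(f"zero-variance columns scaled by 1: {zero}")
            sd[zero] = 1.0
        self.scale_ = sd
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.mean_ is None:
            raise RuntimeError("Scaler not fitted")
        cols = table.columns
        return (table - self.mean_[cols]) / self.scale_[cols]

    def params_json(self) -> str:
        return json.dumps({"mean": self.mean_.to_dict(),
                           "scale": self.scale_.to_dict()}, sort_keys=True)


# ---------------------------------------------------------------------------
# Shapley attribution ranking
# ---------------------------------------------------------------------------

# n_jobs pinned to 1 so fits are bit-reproducible across machines
EXPLAINER_PARAMS = dict(n_estimators=80, max_depth=4, learning_rate=0.15,
                        subsample=0.9, colsample_bytree=0.9,
                        tree_method="hist", eval_metric="logloss", n_jobs=1)


def fit_explainer(X: pd.DataFrame, y: np.ndarray, seed: int = 0,
                  **overrides) -> xgb.XGBClassifier:
    """Fit the gradient-boosted explainer used for attribution ranking."""
    params = {**EXPLAINER_PARAMS, **overrides}
    model = xgb.XGBClassifier(random_state=int(seed) % (2 ** 31), **params)
    model.fit(X, y)
    return model


def shap_values(model: xgb.XGBClassifier, X: pd.DataFrame) -> np.ndarray:
    """Exact per-row tree-path attributions, shape (n, p+1); the last column
    is the base value and rows sum to the model margin."""
    booster = model.get_booster()
    dm = xgb.DMatrix(X, feature_names=list(X.columns))
    return booster.predict(dm, pred_contribs=True)


def rank_features(model: xgb.XGBClassifier, X: pd.DataFrame) -> pd.DataFrame:
    """Rank features by mean |Shapley attribution| (descending; ties broken
    by column name for determinism).  ``direction`` is the sign of the
    correlation between feature value and its attribution: negative means
    low values push toward the progressor class."""
    contrib = shap_values(model, X)[:, :-1]
    mean_abs = np.abs(contrib).mean(axis=0)
    direction = np.zeros(X.shape[1])
    xv = X.values
    for j in range(X.shape[1]):
        sx, sc = np.std(xv[:, j]), np.std(contrib[:, j])
        if sx > 0 and sc > 0:
            direction[j] = np.corrcoef(xv[:, j], contrib[:, j])[0, 1]
    out = pd.DataFrame({"feature": X.columns, "mean_abs_shap": mean_abs,
                        "direction": direction})
    return out.sort_values(["mean_abs_shap", "feature"],
                           ascending=[False, True],
                           kind="stable").reset_index(drop=True)


def select_top(ranked: pd.DataFrame, k: int = 25) -> list[str]:
    """Top-k feature names from a ranking table (all, with a warning, when
    fewer than k are available)."""
    if len(ranked) < k:
        warnings.warn(f"only {len(ranked)} features available; returning all")
    return ranked["feature"].head(k).tolist()
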