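"""Splits, hyperparameter search, submodels, stacking, comparators."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import recall_score, roc_auc_score
import xgboost as xgb

from pdprog.modeling import (BalancedRandomForest, ModelConfig, SearchSpace,
                             audit_oof, build_meta_features,
                             comparator_models, run_experiment,
                             stratified_split, train_meta, train_submodels,
                             tune_submodel)
from pdprog.pipeline import synthesize_features

FAST = ModelConfig(n_trials=2, n_estimators=40, oof_folds=3)


@pytest.fixture(scope="module")
def fitted_experiment():
    """One small end-to-end experiment shared by the stacking tests."""
    X, lab, schema, _, _ = synthesize_features(seed=42, n_subjects=300)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_experiment(X, lab, schema, FAST, seed=1)
    return res


class TestStratifiedSplit:
    def _labels(self, n=100, k=64, seed=0):
        rng = np.random.default_rng(seed)
        y = np.zeros(n, dtype=int)
        y[rng.choice(n, k, replace=False)] = 1
        return pd.Series(y, index=pd.Index([f"s{i}" for i in range(n)]))

    def test_proportional_allocation(self):
        y = self._labels()
        tr, te = stratified_split(y.index, y, 0.25, seed=0)
        assert len(tr) == 75 and len(te) == 25
        assert abs(y.loc[tr].sum() - 48) <= 1

    def test_deterministic(self):
        y = self._labels()
        a = stratified_split(y.index, y, 0.25, seed=3)
        b = stratified_split(y.index, y, 0.25, seed=3)
        assert list(a[0]) == list(b[0]) and list(a[1]) == list(b[1])

    def test_disjoint_exhaustive(self):
        y = self._labels()
        tr, te = stratified_split(y.index, y, 0.25, seed=1)
        assert set(tr) | set(te) == set(y.index)
        assert not set(tr) & set(te)

    def test_prevalence_preserved_over_many_cohorts(self):
        rng = np.random.default_rng(7)
        for trial in range(100):
            n = int(rng.integers(80, 200))
            prev = rng.uniform(0.3, 0.7)
            y = pd.Series((rng.random(n) < prev).astype(int),
                          index=pd.Index([f"s{i}" for i in range(n)]))
            if y.value_counts().min() < 2:
                continue
            tr, _ = stratified_split(y.index, y, 0.25, seed=trial)
            assert abs(y.loc[tr].mean() - y.mean()) <= 0.03

    def test_tiny_class_rejected(self):
        y = pd.Series([1] + [0] * 20,
                      index=pd.Index([f"s{i}" for i in range(21)]))
        with pytest.raises(ValueError):
            stratified_split(y.index, y, 0.25, seed=0)


class TestSearchSpace:
    def test_samples_lie_inside_printed_ranges(self):
        space = SearchSpace()
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = space.sample(rng)
            for key in ("lambda", "alpha", "eta", "gamma", "rate_drop",
                        "skip_drop"):
                assert 1e-8 <= p[key] <= 1.0
            assert 0.5 <= p["subsample"] <= 1.0
            assert 0.5 <= p["colsample_bytree"] <= 1.0
            assert 0.8 <= p["scale_pos_weight"] <= 1.2
            assert 6 <= p["max_depth"] <= 36
            assert 1 <= p["min_child_weight"] <= 10
            assert p["grow_policy"] in ("depthwise", "lossguide")
            assert p["sample_type"] in ("uniform", "weighted")
            assert p["normalize_type"] in ("tree", "forest")


def _separable_task(seed, n=160):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((n, 5)),
                     columns=[f"f{j}" for j in range(5)],
                     index=pd.Index([f"s{i}" for i in range(n)]))
    y = pd.Series((X["f0"] + 0.1 * rng.standard_normal(n) > 0).astype(int),
                  index=X.index)
    return X, y


class TestTuneSubmodel:
    def test_single_trial_returns_the_sampled_draw(self):
        X, y = _separable_task(0)
        cfg = ModelConfig(n_trials=1, n_estimators=20)
        params, model, f1 = tune_submodel(X[:120], y[:120], X[120:], y[120:],
                                          cfg, seed=11)
        expected = cfg.space.sample(np.random.default_rng(11))
        assert params == expected

    def test_zero_trials_rejected(self):
        X, y = _separable_task(0)
        with pytest.raises(ValueError):
            tune_submodel(X[:120], y[:120], X[120:], y[120:],
                          ModelConfig(n_trials=0), seed=0)

    def test_tuned_at_least_matches_default_on_separable_task(self):
        """Paired comparison against an untuned default-config model."""
        cfg = ModelConfig(n_trials=5, n_estimators=40)
        wins = 0
        for seed in range(10):
            X, y = _separable_task(100 + seed)
            Xtr, ytr, Xv, yv = X[:120], y[:120], X[120:], y[120:]
            _, _, tuned_f1 = tune_submodel(Xtr, ytr, Xv, yv, cfg, seed=seed)
            default = xgb.XGBClassifier(n_estimators=40, tree_method="hist",
                                        n_jobs=1, random_state=seed)
            default.fit(Xtr, ytr)
            from pdprog.evaluation import classification_metrics
            d_f1 = classification_metrics(
                yv.values, default.predict_proba(Xv)[:, 1]).f1
            wins += tuned_f1 >= d_f1
        assert wins >= 8


class TestTrainSubmodels:
    def test_label_leak_guard(self, small_cohort):
        X = pd.DataFrame({"x": [1.0, 2.0], "slope_total": [0.1, 0.2]})
        with pytest.raises(ValueError, match="label-derived"):
            train_submodels(X, pd.DataFrame(), FAST, seed=0)

    def test_pure_noise_features_give_chance_auc(self):
        rng = np.random.default_rng(5)
        n = 1200
        X = pd.DataFrame(rng.standard_normal((n, 10)),
                         columns=[f"f{j}" for j in range(10)],
                         index=pd.Index([f"s{i}" for i in range(n)]))
        y = pd.Series(rng.integers(0, 2, n), index=X.index)
        tr, te = stratified_split(X.index, y, 0.25, seed=0)
        model = xgb.XGBClassifier(n_estimators=40, tree_method="hist",
                                  n_jobs=1, random_state=0)
        model.fit(X.loc[tr], y.loc[tr])
        auc = roc_auc_score(y.loc[te], model.predict_proba(X.loc[te])[:, 1])
        assert abs(auc - 0.5) <= 0.08

    def test_catchup_attribution_sign_in_own_submodel(self, medium_cohort):
        """The planted catch-up direction: low baseline MDS-III pushes the
        12-month MDS-III submodel toward the progressor class."""
        from pdprog.features import build_baseline_features
        from pdprog.labels import label_progression
        cohort, _ = medium_cohort
        lab = label_progression(cohort)
        X, schema = build_baseline_features(cohort)
        X = X.fillna(X.mean())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            subs = train_submodels(
                X, lab[lab["part"] != "total"], FAST, seed=0)
        rec = subs[("iii", 12)]
        row = rec.ranking[rec.ranking["feature"]
                          == "mds_updrs_iii_summary_score"]
        assert row.index[0] < 3            # among top-3 attributions
        assert row["direction"].iloc[0] < 0


class TestComparators:
    def test_logistic_regression_solves_separable_task(self):
        X, y = _separable_task(1, n=200)
        out = comparator_models(X[:150], y[:150], X[150:], y[150:], seed=0)
        assert out["logistic_regression"]["f1"] >= 0.95

    def test_deterministic(self):
        X, y = _separable_task(2, n=200)
        a = comparator_models(X[:150], y[:150], X[150:], y[150:], seed=5)
        b = comparator_models(X[:150], y[:150], X[150:], y[150:], seed=5)
        assert a["balanced_random_forest"]["f1"] == \
            b["balanced_random_forest"]["f1"]

    def test_balanced_forest_minority_recall(self):
        """On an 80:20 task the balanced (majority-undersampled) forest
        recalls the minority class at least as well as an unweighted forest
        (paired over seeds)."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            n = 400
            X = pd.DataFrame(rng.standard_normal((n, 6)))
            margin = X[0] + 0.8 * rng.standard_normal(n)
            y = (margin > np.quantile(margin, 0.8)).astype(int)
            Xtr, ytr, Xte, yte = X[:300], y[:300], X[300:], y[300:]
            brf = BalancedRandomForest(
                n_estimators=100, seed=seed).fit(Xtr, ytr)
            rf = RandomForestClassifier(
                n_estimators=100, n_jobs=1, random_state=seed).fit(Xtr, ytr)
            wins += (recall_score(yte, brf.predict(Xte))
                     >= recall_score(yte, rf.predict(Xte)))
        assert wins >= 8


class TestStacking:
    def test_probability_columns_in_unit_interval(self, fitted_experiment):
        res = fitted_experiment
        for rec in res.submodels.values():
            assert rec.oof_prob.between(0, 1).all()

    def test_oof_protocol_audit(self, fitted_experiment):
        assert audit_oof(fitted_experiment.submodels)

    def test_own_fold_never_produces_meta_feature(self, fitted_experiment):
        rec = next(iter(fitted_experiment.submodels.values()))
        for k, train_ids in enumerate(rec.fold_train_ids):
            fold_members = set(rec.oof_fold.index[rec.oof_fold == k])
            assert not fold_members & train_ids

    def test_oracle_meta_features_solve_task(self):
        """Probabilities equal to the labels make the meta task trivial."""
        rng = np.random.default_rng(0)
        n = 300
        idx = pd.Index([f"s{i}" for i in range(n)])
        y = pd.Series(rng.integers(0, 2, n), index=idx)
        meta = pd.DataFrame({"pred_iii_12m": y.astype(float),
                             "noise": rng.standard_normal(n)}, index=idx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = train_meta(meta, y, FAST, seed=0)
        prob = rec.model.predict_proba(meta[rec.features])[:, 1]
        from pdprog.evaluation import classification_metrics
        assert classification_metrics(y.values, prob).f1 == 1.0

    def test_shuffled_meta_features_give_chance_auc(self):
        rng = np.random.default_rng(1)
        n = 1200
        idx = pd.Index([f"s{i}" for i in range(n)])
        y = pd.Series(rng.integers(0, 2, n), index=idx)
        meta = pd.DataFrame(
            {"pred_iii_12m": rng.permutation(y.astype(float).values),
             "x": rng.standard_normal(n)}, index=idx)
        tr, te = stratified_split(idx, y, 0.25, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = train_meta(meta.loc[tr], y.loc[tr], FAST, seed=0)
        prob = rec.model.predict_proba(meta.loc[te, rec.features])[:, 1]
        assert abs(roc_auc_score(y.loc[te], prob) - 0.5) <= 0.08

    def test_iii_submodel_dominates_when_only_iii_drives_total(self):
        """Configure the generator so only MDS-III progression separates
        subtypes; the III 12-month submodel probability must then correlate
        most with the 12-month Total label among the nine meta-features."""
        from pdprog.synthetic import EffectSizes
        slope_means = {"motor_catchup": (0.0, 0.0, 6.0),
                       "nonmotor_catchup": (0.0, 0.0, 6.0),
                       "nonprogressor": (0.0, 0.0, -6.0)}
        # zero every effect shared across subparts so I/II slopes carry no
        # information about the III-driven Total label
        iii_only = EffectSizes(baseline_own=-0.32, baseline_other=0.0,
                               pd_prs_mds2=0.0, pd_prs_mds3=-3.0,
                               ea_prs_mds3=1.2, moca_mds1=0.0,
                               seadl_mds2=0.0)
        X, lab, schema, _, _ = synthesize_features(
            seed=9, n_subjects=500,
            sim_overrides={"subtype_slope_means": slope_means,
                           "shared_slope_sd": 0.0, "effect_sizes": iii_only})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_experiment(X, lab, schema, FAST, seed=2)
        y = lab[(lab["part"] == "total") & (lab["horizon"] == 12)].set_index(
            "participant_id")["progressor"]
        corr = {}
        for (part, h), rec in res.submodels.items():
            joined = rec.oof_prob.to_frame("p").join(y).dropna()
            corr[(part, h)] = abs(np.corrcoef(joined["p"],
                                              joined["progressor"])[0, 1])
        best = max(corr, key=corr.get)
        assert best[0] == "iii"

    def test_missing_submodel_rejected(self):
        from pdprog.modeling import SubmodelSet
        with pytest.raises(ValueError):
            build_meta_features(SubmodelSet(), pd.DataFrame(), training=True)


class TestAblation:
    def test_dropping_absent_class_is_warned_noop(self):
        X, lab, schema, _, _ = synthesize_features(
            seed=3, n_subjects=250, imaging=False)
        with pytest.warns(UserWarning, match="no-op"):
            res = run_experiment(X, lab, schema, FAST, seed=0,
                                 drop_class="imaging")
        assert res.noop

    def test_unknown_class_rejected(self):
        X, lab, schema, _, _ = synthesize_features(seed=3, n_subjects=250)
        with pytest.raises(ValueError, match="unknown feature class"):
            run_experiment(X, lab, schema, FAST, seed=0,
                           drop_class="astrology")
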