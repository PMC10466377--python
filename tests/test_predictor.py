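import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import average_precision_score

from delblocks import curation, synthdel
from delblocks.chemspace import ChemSpace
from delblocks.predictor import (
    IMPUTATION_STRATEGIES,
    BinderClassifier,
    EvalReport,
    build_features,
    evaluate,
    impute_pbind,
    run_holdout_workflow,
    split_bb_holdout,
    split_random,
)
from delblocks.productivity import compute_pbind
from tests.conftest import make_records


def _no_leakage(split):
    for p in (1, 2, 3):
        test_bbs = set(split.test[f"bb{p}"])
        train_bbs = set(split.train[f"bb{p}"])
        if not test_bbs <= train_bbs:
            return False
    return True


class TestSplitRandom:
    def test_tiny_factorial(self):
        rows = [
            (a, b, c, 0)
            for a in ("a1", "a2")
            for b in ("b1", "b2")
            for c in ("c1", "c2")
        ]
        split = split_random(make_records(rows), test_fraction=0.125, seed=0)
        assert len(split.test) == 1
        assert _no_leakage(split)

    def test_singleton_bb_forced_to_train(self):
        rows = [("a1", "b1", "c1", 0)] * 6 + [("solo", "b1", "c1", 1)]
        rec = make_records(rows).drop_duplicates().reset_index(drop=True)
        rec = make_records(rows)
        for seed in range(10):
            split = split_random(rec, test_fraction=0.3, seed=seed)
            assert "solo" not in set(split.test["bb1"])

    def test_synthetic_library_set_containment(self, default_labeled):
        split = split_random(default_labeled, test_fraction=0.10, seed=7)
        assert _no_leakage(split)
        assert len(split.train) + len(split.test) == len(default_labeled)
        assert abs(len(split.test) / len(default_labeled) - 0.10) <= 0.01

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            split_random(make_records([("a", "b", "c", 0)]), test_fraction=1.5)


class TestSplitHoldout:
    def test_holdout_partition(self, default_labeled):
        split = split_bb_holdout(default_labeled, bb_fraction=0.05, seed=3)
        held = {p: set(split.held_out[p]) for p in (1, 2, 3)}
        for p in (1, 2, 3):
            assert not held[p] & set(split.train[f"bb{p}"])
        # every holdout row contains at least one held-out building block
        in_holdout = np.zeros(len(split.holdout), dtype=bool)
        for p in (1, 2, 3):
            in_holdout |= split.holdout[f"bb{p}"].isin(held[p]).to_numpy()
        assert in_holdout.all()
        assert len(split.train) + len(split.holdout) == len(default_labeled)

    def test_zero_fraction_keeps_everything(self, default_labeled):
        split = split_bb_holdout(default_labeled, bb_fraction=0.0, seed=0)
        assert len(split.holdout) == 0
        assert len(split.train) == len(default_labeled)

    def test_named_bb_removed_everywhere(self):
        rows = [("a", "x", "m", 0), ("a", "y", "n", 1), ("b", "x", "m", 0), ("b", "y", "n", 0)]
        rec = make_records(rows)
        for seed in range(5):
            split = split_bb_holdout(rec, bb_fraction=0.5, seed=seed)
            for bb in split.held_out[1]:
                # every record containing a held-out bb lands in the holdout
                assert (split.train["bb1"] != bb).all()
                assert (split.holdout["bb1"] == bb).sum() == (rec["bb1"] == bb).sum()


def _toy_model():
    """Hand-built fitted chemical space: two clusters and one noise point."""
    model = ChemSpace()
    model.ids_ = ["a", "b", "c", "d", "e"]
    model.embedding_ = np.array([[0, 0], [1, 0], [0.5, 0.5], [10, 10], [20, -20.0]])
    model.labels_ = np.array([0, 0, 0, 1, -1])
    model._reach_ = {0: 1.0, 1: 1.0}
    model._input_nn_max_ = 1.0
    return model


class TestImputation:
    def test_median_and_mean(self):
        model = _toy_model()
        pbind = pd.Series([0.1, 0.2, 0.9, 0.5, 0.0], index=model.ids_)
        coords = np.array([[0.4, 0.1]])
        for strategy, expected in [("cluster_median", 0.2), ("cluster_mean", 0.4)]:
            est, noise = impute_pbind(coords, np.array([0]), model, pbind, strategy)
            assert est[0] == pytest.approx(expected)
            assert not noise[0]

    def test_nearest_copies_coincident_member(self):
        model = _toy_model()
        pbind = pd.Series([0.1, 0.2, 0.9, 0.5, 0.0], index=model.ids_)
        est, _ = impute_pbind(
            np.array([[0.5, 0.5]]), np.array([0]), model, pbind, "cluster_nearest"
        )
        assert est[0] == 0.9

    def test_random_is_seeded_member(self):
        model = _toy_model()
        pbind = pd.Series([0.1, 0.2, 0.9, 0.5, 0.0], index=model.ids_)
        est1, _ = impute_pbind(np.array([[0, 0]]), np.array([0]), model, pbind, "cluster_random", seed=5)
        est2, _ = impute_pbind(np.array([[0, 0]]), np.array([0]), model, pbind, "cluster_random", seed=5)
        assert est1[0] == est2[0]
        assert est1[0] in {0.1, 0.2, 0.9}

    def test_noise_gets_global_median_flagged(self):
        model = _toy_model()
        pbind = pd.Series([0.1, 0.2, 0.9, 0.5, 0.0], index=model.ids_)
        est, noise = impute_pbind(np.array([[50, 50]]), np.array([-1]), model, pbind, "cluster_mean")
        assert noise[0]
        assert est[0] == np.median(pbind)

    def test_estimates_stay_in_unit_interval(self):
        model = _toy_model()
        pbind = pd.Series([0.0, 1.0, 0.3, 0.5, 0.9], index=model.ids_)
        rng = np.random.default_rng(0)
        coords = rng.normal(0, 5, size=(20, 2))
        labels = rng.choice([0, 1, -1], size=20)
        for strategy in IMPUTATION_STRATEGIES:
            est, _ = impute_pbind(coords, labels, model, pbind, strategy, seed=1)
            assert ((est >= 0) & (est <= 1)).all()

    def test_unknown_strategy(self):
        with pytest.raises(ValueError, match="unknown strategy"):
            impute_pbind(np.zeros((1, 2)), np.array([0]), _toy_model(), pd.Series(dtype=float), "knn")


class TestBinderClassifier:
    def test_separable_case_depth_one(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, size=(400, 3))
        y = (X[:, 2] > 0.5).astype(int)
        clf = BinderClassifier().fit(X, y)
        assert clf.max_depth_ == 1
        report = evaluate(y, clf.predict(X), clf.predict_proba(X)[:, 1])
        assert report.precision == 1.0 and report.recall == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            BinderClassifier().fit(np.zeros((10, 3)), np.zeros(10))

    def test_null_features_score_near_hit_rate(self):
        # Labels independent of features: CV PR-AUC collapses to the hit rate.
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(2000, 3))
        y = (rng.uniform(size=2000) < 0.2).astype(int)
        clf = BinderClassifier(max_depth_grid=(1, 2, 3)).fit(X, y)
        assert clf.cv_scores_[clf.max_depth_] < 0.2 * 2.0

    def test_selected_depth_no_worse_than_depth_one(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(500, 3))
        y = ((X[:, 0] > 0.5) & (X[:, 2] > 0.5)).astype(int)
        clf = BinderClassifier().fit(X, y)
        assert clf.cv_scores_[clf.max_depth_] >= clf.cv_scores_[1]

    def test_tree_export_round_trip(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(size=(200, 3))
        y = (X[:, 2] > 0.5).astype(int)
        clf = BinderClassifier().fit(X, y)
        d = clf.to_dict()
        assert d["max_depth"] == clf.max_depth_
        assert d["root"]["n"] == 200


class TestEvaluate:
    def test_printed_counts_arithmetic(self):
        report = EvalReport(tp=9432, fp=364, fn=10302 - 9432, tn=443380 - 10302 - 364)
        assert round(report.precision, 3) == 0.963
        assert round(report.recall, 3) == 0.916
        assert report.baseline == pytest.approx(10302 / 443380)

    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1, 1])
        report = evaluate(y, y, y.astype(float))
        assert report.precision == 1.0 and report.recall == 1.0 and report.pr_auc == 1.0

    def test_random_scores_near_hit_rate(self):
        rng = np.random.default_rng(0)
        y = (rng.uniform(size=20000) < 0.05).astype(int)
        score = rng.uniform(size=20000)
        report = evaluate(y, (score > 0.5).astype(int), score)
        assert report.pr_auc == pytest.approx(0.05, abs=0.02)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [], [])

    @settings(deadline=None, max_examples=60)
    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500), st.integers(1, 500))
    def test_confusion_identities(self, tp, fp, fn, tn):
        report = EvalReport(tp, fp, fn, tn)
        if tp + fp:
            assert report.precision == tp / (tp + fp)
        if tp + fn:
            assert report.recall == tp / (tp + fn)
        assert report.baseline == (tp + fn) / (tp + fp + fn + tn)


class TestHoldoutWorkflow:
    @pytest.fixture(scope="class")
    def tiny(self):
        cfg = synthdel.scenario("smooth_space", n_bb=(10, 10, 60), n_clusters=(2, 2, 6))
        ds = synthdel.generate(cfg)
        rec = curation.label_binders(ds.records, lambda0=cfg.lambda_background)
        return ds, rec

    def test_single_trial_matches_manual_composition(self, tiny):
        ds, rec = tiny
        params = dict(min_cluster_size_grid=(3, 5), min_samples_grid=(1, 3))
        res = run_holdout_workflow(
            rec, ds.distance_matrices, strategies=("cluster_mean",),
            n_trials=1, seed=9, chemspace_params=params,
        )
        # Recompose the same trial stage by stage with the same seeds.
        tseed = res.trial_seeds[0]
        split = split_bb_holdout(rec, bb_fraction=0.05, seed=tseed)
        pbind_maps = {p: compute_pbind(split.train, p)["pbind"] for p in (1, 2, 3)}
        imputed = {}
        for p in (1, 2, 3):
            train_bbs = sorted(split.train[f"bb{p}"].unique())
            model = ChemSpace(**params).fit(ds.distance_matrices[p].subset(train_bbs))
            new_bbs = sorted(set(split.holdout[f"bb{p}"].unique()) - set(train_bbs))
            rect = ds.distance_matrices[p].rectangular(new_bbs, train_bbs)
            coords = model.transform(rect)
            labels = model.predict(rect)
            est, _ = impute_pbind(coords, labels, model, pbind_maps[p], "cluster_mean", seed=tseed)
            imputed[p] = pd.concat([pbind_maps[p], pd.Series(est, index=new_bbs, dtype=float)])
        clf = BinderClassifier().fit(
            build_features(split.train, pbind_maps), split.train["binder"].to_numpy()
        )
        X_hold = build_features(split.holdout, imputed)
        manual = evaluate(
            split.holdout["binder"].to_numpy(),
            clf.predict(X_hold),
            clf.predict_proba(X_hold)[:, 1],
        )
        report = res.reports["cluster_mean"][0]
        assert report.to_dict() == manual.to_dict()

    def test_report_structure(self, tiny):
        ds, rec = tiny
        res = run_holdout_workflow(
            rec, ds.distance_matrices, n_trials=2, seed=4,
            chemspace_params=dict(min_cluster_size_grid=(3, 5), min_samples_grid=(1, 3)),
        )
        assert set(res.mean_pr_auc) == set(IMPUTATION_STRATEGIES)
        assert all(len(v) == 2 for v in res.reports.values())
        assert 0 <= res.baseline <= 1

    def test_unlabeled_rejected(self, tiny):
        ds, rec = tiny
        with pytest.raises(ValueError, match="labeled"):
            run_holdout_workflow(rec.drop(columns="binder"), ds.distance_matrices)


class TestBuildFeatures:
    def test_missing_pbind_named(self):
        rec = make_records([("a", "x", "m", 1)])
        maps = {1: pd.Series({"a": 0.5}), 2: pd.Series({"x": 0.1}), 3: pd.Series(dtype=float)}
        with pytest.raises(KeyError, match="p3"):
            build_features(rec, maps)

    def test_cluster_features_appended(self):
        rec = make_records([("a", "x", "m", 1)])
        maps = {1: pd.Series({"a": 0.5}), 2: pd.Series({"x": 0.1}), 3: pd.Series({"m": 0.9})}
        clusters = {1: pd.Series({"a": 0}), 2: pd.Series({"x": 1}), 3: pd.Series({"m": 2})}
        X = build_features(rec, maps, clusters)
        assert X.shape == (1, 6)
        assert X[0].tolist() == [0.5, 0.1, 0.9, 0.0, 1.0, 2.0]
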