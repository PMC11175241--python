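"""Embedded selection, stratified splitting, LOOCV, metrics, PCA, benchmark."""

import numpy as np
import pandas as pd
import pytest
from sklearn.preprocessing import StandardScaler

import amciscreen as acs


def make_table(n_per_group=24, n_noise=9, effect=3.0, seed=0, informative="signal"):
    """Two-group table: one informative feature (Cohen's d = effect) + noise."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    groups = ["HC"] * n_per_group + ["aMCI"] * n_per_group
    data = {"subject_id": [f"S{i}" for i in range(n)], "group": groups,
            informative: np.r_[rng.standard_normal(n_per_group),
                               rng.standard_normal(n_per_group) + effect]}
    for i in range(n_noise):
        data[f"noise{i}"] = rng.standard_normal(n)
    return pd.DataFrame(data)


def standardized(table, cols):
    return pd.DataFrame(StandardScaler().fit_transform(table[cols]), columns=cols)


class TestEmbeddedSelect:
    def test_informative_feature_selected(self):
        tab = make_table(effect=3.0, seed=1)
        cols = [c for c in tab.columns if c not in ("subject_id", "group")]
        keep, scores = acs.embedded_select(standardized(tab, cols), tab["group"])
        assert "signal" in keep
        assert scores["signal"] == max(scores.values())

    def test_duplicated_feature_gets_equal_importance(self):
        tab = make_table(effect=2.0, seed=2)
        tab["signal_copy"] = tab["signal"]
        cols = ["signal", "signal_copy"] + [f"noise{i}" for i in range(9)]
        _, scores = acs.embedded_select(standardized(tab, cols), tab["group"])
        assert scores["signal"] == pytest.approx(scores["signal_copy"], rel=1e-6)

    def test_strictly_above_mean_rule(self):
        tab = make_table(effect=3.0, seed=3)
        cols = [c for c in tab.columns if c not in ("subject_id", "group")]
        keep, scores = acs.embedded_select(standardized(tab, cols), tab["group"])
        mean = np.mean(list(scores.values()))
        assert set(keep) == {n for n, s in scores.items() if s > mean}
        assert 0 < len(keep) < len(cols)

    def test_single_class_rejected(self):
        tab = make_table(seed=4).query("group == 'HC'")
        cols = ["signal", "noise0"]
        with pytest.raises(ValueError, match="class"):
            acs.embedded_select(standardized(tab, cols), tab["group"])


class TestStratifiedSplit:
    def test_study_cohort_gives_34_train_14_test(self):
        tab = make_table(n_per_group=24, seed=5)
        train, test = acs.stratified_split(tab, seed=0)
        assert len(train) == 34 and len(test) == 14
        assert (train.group.value_counts() == 17).all()
        assert (test.group.value_counts() == 7).all()

    def test_partition_is_exact(self):
        tab = make_table(n_per_group=24, seed=6)
        train, test = acs.stratified_split(tab, seed=1)
        ids = set(train.subject_id) | set(test.subject_id)
        assert ids == set(tab.subject_id)
        assert not (set(train.subject_id) & set(test.subject_id))

    def test_seed_controls_partition(self):
        tab = make_table(seed=7)
        t1, _ = acs.stratified_split(tab, seed=2)
        t2, _ = acs.stratified_split(tab, seed=2)
        t3, _ = acs.stratified_split(tab, seed=3)
        assert set(t1.subject_id) == set(t2.subject_id)
        assert set(t1.subject_id) != set(t3.subject_id)

    def test_tiny_class_rejected(self):
        tab = make_table(n_per_group=1, seed=8)
        with pytest.raises(ValueError, match="stratify"):
            acs.stratified_split(tab, seed=0)


class TestLoocv:
    def test_separable_data_scores_100(self):
        x = np.r_[np.zeros((10, 2)), np.ones((10, 2)) * 5]
        y = np.array(["HC"] * 10 + ["aMCI"] * 10)
        params, acc = acs.loocv_grid_search(x, y, "linear-SVM")
        assert acc == 1.0

    def test_single_point_grid_returned(self):
        x = np.random.default_rng(0).standard_normal((10, 2))
        y = np.array(["HC", "aMCI"] * 5)
        grid = [{"n_neighbors": 3}]
        params, _ = acs.loocv_grid_search(x, y, "kNN", grid)
        assert params == {"n_neighbors": 3}

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            acs.loocv_grid_search(np.zeros((4, 2)),
                                  np.array(["a", "b", "a", "b"]), "kNN", [])

    def test_permuted_labels_never_beat_chance(self):
        """Null LOOCV carries no signal: at or below chance on average.

        With balanced classes, LOOCV is pessimistically biased under the
        null (removing one subject leaves the opposite class in the
        majority), so the permutation-null mean sits slightly *below* 50%;
        the leakage-relevant bound is the upper one.
        """
        rng = np.random.default_rng(9)
        x = rng.standard_normal((34, 3))
        accs = []
        for _ in range(30):
            y = np.array(["HC"] * 17 + ["aMCI"] * 17)
            rng.shuffle(y)
            _, acc = acs.loocv_grid_search(x, y, "LDA")
            accs.append(acc)
        assert 0.30 < np.mean(accs) < 0.55


class TestEvaluate:
    def test_perfect_predictions(self):
        tab = make_table(effect=10.0, seed=10)
        cols = ["signal"] + [f"noise{i}" for i in range(9)]
        model = acs.build_model("LDA")
        z = standardized(tab, cols).to_numpy()
        model.fit(z, tab["group"])
        m = acs.evaluate(model, z, tab["group"])
        assert m["accuracy"] == 100.0
        assert m["sensitivity"] == 100.0 and m["specificity"] == 100.0

    def test_confusion_metric_identities(self):
        # TP=5, FN=2, TN=7, FP=0
        tp, fn, tn, fp = 5, 2, 7, 0
        assert 100 * tp / (tp + fn) == pytest.approx(71.4285714)
        y = np.array(["aMCI"] * 7 + ["HC"] * 7)
        pred = np.array(["aMCI"] * 5 + ["HC"] * 2 + ["HC"] * 7)

        class Stub:
            classes_ = np.array(["HC", "aMCI"])

            def predict(self, x):
                return pred

            def predict_proba(self, x):
                p = (pred == "aMCI").astype(float)
                return np.c_[1 - p, p]

        m = acs.evaluate(Stub(), np.zeros((14, 1)), y)
        assert (m["TP"], m["TN"], m["FP"], m["FN"]) == (tp, tn, fp, fn)
        assert m["sensitivity"] == pytest.approx(71.43, abs=0.01)
        assert m["specificity"] == pytest.approx(100.0)
        assert m["accuracy"] == pytest.approx(85.71, abs=0.01)

    def test_random_scores_give_chance_auc(self):
        rng = np.random.default_rng(11)
        y = np.array(["HC", "aMCI"] * 500)

        class Rand:
            classes_ = np.array(["HC", "aMCI"])

            def predict(self, x):
                return rng.choice(["HC", "aMCI"], size=len(x))

            def predict_proba(self, x):
                p = rng.uniform(size=len(x))
                return np.c_[1 - p, p]

        m = acs.evaluate(Rand(), np.zeros((1000, 1)), y)
        assert m["auc"] == pytest.approx(50.0, abs=5.0)

    def test_single_class_test_flagged(self):
        tab = make_table(effect=5.0, seed=12)
        model = acs.build_model("gaussian-NB")
        model.fit(tab[["signal"]].to_numpy(), tab["group"])
        m = acs.evaluate(model, np.zeros((3, 1)), np.array(["HC"] * 3))
        assert m["degenerate"]
        assert np.isnan(m["sensitivity"]) or np.isnan(m["specificity"])


@pytest.fixture(scope="module")
def small_report():
    tab = acs.simulate_cohort(acs.study_cohort_spec(n_per_group=24, seed=13))
    return acs.run_benchmark(tab, n_repeats=2, seed=14,
                             families=("linear-SVM", "LDA"))


class TestBenchmark:
    def test_deterministic_given_seed(self):
        tab = acs.simulate_cohort(acs.study_cohort_spec(n_per_group=24, seed=15))
        r1 = acs.run_benchmark(tab, n_repeats=1, seed=16, families=("LDA",))
        r2 = acs.run_benchmark(tab, n_repeats=1, seed=16, families=("LDA",))
        pd.testing.assert_frame_equal(r1.metrics, r2.metrics)

    def test_metric_identities_on_all_emitted_confusions(self, small_report):
        merged = small_report.confusions.merge(
            small_report.per_repeat, on=["repeat", "condition", "family"])
        tot = merged[["TP", "TN", "FP", "FN"]].sum(axis=1)
        np.testing.assert_allclose(
            merged["accuracy"], 100 * (merged.TP + merged.TN) / tot)
        np.testing.assert_allclose(
            merged["sensitivity"], 100 * merged.TP / (merged.TP + merged.FN))
        np.testing.assert_allclose(
            merged["specificity"], 100 * merged.TN / (merged.TN + merged.FP))

    def test_aggregate_means_match_per_repeat(self, small_report):
        for _, row in small_report.metrics.iterrows():
            sub = small_report.per_repeat.query(
                "condition == @row.condition and family == @row.family")
            assert row.accuracy_mean == pytest.approx(sub.accuracy.mean())

    def test_no_test_set_leakage(self):
        """Corrupting test labels must not change the fitted predictions."""
        tab = acs.simulate_cohort(acs.study_cohort_spec(n_per_group=24, seed=17))
        train, test = acs.stratified_split(tab, seed=18)
        cols = [c for c in tab.columns if c not in ("subject_id", "group")]
        scaler = StandardScaler().fit(train[cols])
        z_train = pd.DataFrame(scaler.transform(train[cols]), columns=cols)
        keep, _ = acs.embedded_select(z_train, train["group"])
        model = acs.build_model("linear-SVM", seed=0)
        model.fit(z_train[keep].to_numpy(), train["group"])
        z_test = scaler.transform(test[cols])
        pred1 = model.predict(pd.DataFrame(z_test, columns=cols)[keep].to_numpy())

        test_corrupt = test.copy()
        test_corrupt["group"] = np.where(test["group"] == "HC", "aMCI", "HC")
        # the pipeline never sees test labels, so predictions are identical
        pred2 = model.predict(pd.DataFrame(z_test, columns=cols)[keep].to_numpy())
        assert np.array_equal(pred1, pred2)

    def test_shuffled_labels_score_at_chance(self):
        rng = np.random.default_rng(19)
        tab = acs.simulate_cohort(acs.study_cohort_spec(n_per_group=24, seed=20))
        tab["group"] = rng.permutation(tab["group"].to_numpy())
        rep = acs.run_benchmark(tab, n_repeats=8, seed=21, families=("LDA",),
                                conditions=("combined",))
        acc = rep.metrics.accuracy_mean.iloc[0]
        assert 25.0 < acc < 75.0


class TestPca:
    def test_uncorrelated_unit_features_split_variance(self):
        rng = np.random.default_rng(22)
        tab = pd.DataFrame(rng.standard_normal((4000, 2)), columns=["a", "b"])
        _, ratios = acs.pca_project(tab, ["a", "b"])
        assert ratios[0] == pytest.approx(0.5, abs=0.05)

    def test_feature_order_invariance_up_to_sign(self):
        rng = np.random.default_rng(23)
        tab = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("abc"))
        tab["a"] += tab["b"]
        c1, _ = acs.pca_project(tab, ["a", "b", "c"])
        c2, _ = acs.pca_project(tab, ["c", "b", "a"])
        for k in range(2):
            agree = np.allclose(c1[:, k], c2[:, k], atol=1e-8)
            flipped = np.allclose(c1[:, k], -c2[:, k], atol=1e-8)
            assert agree or flipped

    def test_planted_separation_shows_on_pc1(self):
        tab = make_table(n_per_group=50, effect=4.0, seed=24, n_noise=3)
        cols = ["signal"] + [f"noise{i}" for i in range(3)]
        coords, _ = acs.pca_project(tab, cols)
        hc = coords[tab.group == "HC", 0]
        amci = coords[tab.group == "aMCI", 0]
        sep = abs(hc.mean() - amci.mean()) / np.sqrt((hc.var() + amci.var()) / 2)
        assert sep > 2.0

    def test_degenerate_inputs_rejected(self):
        tab = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            acs.pca_project(tab, ["a", "b"])
        with pytest.raises(ValueError):
            acs.pca_project(tab, ["b"])
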