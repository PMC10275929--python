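import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from physioaffect.affect import (
    AffectPoint, PROBLEMS, WindowClassifier, assign_quadrant, bonferroni_threshold,
    compare_models, consistency_filter, evaluate, fit, loio_split,
    measure_estimation_time, quadrant_of_raw, rescale_rating,
)
from physioaffect.io import SelfReport, StimulusEvent


class TestRescaling:
    @pytest.mark.parametrize("raw, expected", [(5, 0.0), (1, -4.0), (9, 4.0)])
    def test_endpoints_and_center(self, raw, expected):
        assert rescale_rating(raw) == expected

    @pytest.mark.parametrize("raw", [0.5, 9.5, -1])
    def test_out_of_range_rejected(self, raw):
        with pytest.raises(ValueError):
            rescale_rating(raw)

    @given(st.floats(-4, 4))
    def test_affine_inverse(self, x):
        assert rescale_rating(x + 5.0) == pytest.approx(x)


class TestQuadrants:
    @pytest.mark.parametrize("v, a, expected", [
        (2, 3, "HAHV"), (-2, 1.5, "HALV"), (1.5, -2, "LAHV"), (-2, -2, "LALV"),
        (0.5, -0.5, "N"), (1, 1, "N"), (-1, 1, "N"),
        (1.0001, 1, "HAHV"), (0, 2, "HALV"), (2, 0, "LAHV"),
    ])
    def test_examples_and_boundaries(self, v, a, expected):
        assert assign_quadrant(AffectPoint(v, a)) == expected

    @given(st.floats(-4, 4), st.floats(-4, 4))
    @settings(max_examples=300)
    def test_partition_is_exhaustive_and_exclusive(self, v, a):
        q = assign_quadrant(AffectPoint(v, a))
        assert q in ("HAHV", "HALV", "LALV", "LAHV", "N")

    def test_neutral_box_is_6_25_percent_of_plane(self):
        grid = np.linspace(-3.995, 3.995, 800)
        vv, aa = np.meshgrid(grid, grid)
        frac = np.mean([
            assign_quadrant(AffectPoint(v, a)) == "N"
            for v, a in zip(vv.ravel(), aa.ravel())
        ])
        assert frac == pytest.approx(4 / 64, abs=1e-3)

    def test_point_outside_plane_rejected(self):
        with pytest.raises(ValueError):
            AffectPoint(5.0, 0.0)


class TestConsistencyFilter:
    def _ev(self, image_id, v, a):
        return StimulusEvent(image_id, v + 5, a + 5, onset_s=300.0)

    def test_diagonal_opposition_excluded(self):
        events = [self._ev("x", 3, 3)]  # HAHV
        reports = [SelfReport("x", 2, 2)]  # rescaled (-3,-3) = LALV
        kept, log = consistency_filter(events, reports)
        assert kept == []
        assert log[0]["action"] == "excluded"
        assert {log[0]["iaps_quadrant"], log[0]["sam_quadrant"]} == {"HAHV", "LALV"}

    def test_single_axis_disagreement_kept(self):
        events = [self._ev("x", 3, 3)]
        reports = [SelfReport("x", 2, 8)]  # (-3, 3) = HALV
        kept, _ = consistency_filter(events, reports)
        assert kept == ["x"]

    def test_neutral_self_report_kept(self):
        events = [self._ev("x", 3, 3)]
        reports = [SelfReport("x", 5, 5)]  # N
        kept, _ = consistency_filter(events, reports)
        assert kept == ["x"]

    def test_missing_report_kept_with_warning(self):
        kept, log = consistency_filter([self._ev("x", 3, 3)], [])
        assert kept == ["x"]
        assert log[0]["reason"] == "missing self-report"


def toy_windows(images_per_class=3, windows_per_image=4, seed=0):
    """Labeled window table with separable class-dependent features."""
    rng = np.random.default_rng(seed)
    rows = []
    for qi, q in enumerate(("HAHV", "HALV", "LALV", "LAHV", "N")):
        for i in range(images_per_class):
            for w in range(windows_per_image):
                rows.append({
                    "participant_id": "P", "image_id": f"{q}_{i}",
                    "window_start_s": 100.0 * qi + 20 * i + w, "quadrant": q,
                    "x0": qi + 0.05 * rng.standard_normal(),
                    "x1": (qi % 2) + 0.05 * rng.standard_normal(),
                })
    return pd.DataFrame(rows)


class TestLoioSplit:
    def test_one_image_per_class_held_out(self):
        df = toy_windows()
        train, test = loio_split(df, PROBLEMS["FIVE_CLASS"], seed=0)
        assert test["image_id"].nunique() == 5
        assert test.groupby("label")["image_id"].nunique().eq(1).all()
        assert not set(train["image_id"]) & set(test["image_id"])

    def test_four_class_excludes_neutral(self):
        train, test = loio_split(toy_windows(), PROBLEMS["FOUR_CLASS"], seed=0)
        assert test["image_id"].nunique() == 4
        assert "N" not in set(train["quadrant"]) | set(test["quadrant"])

    def test_binary_maps_quadrants(self):
        train, test = loio_split(toy_windows(), PROBLEMS["HL_VALENCE"], seed=0)
        assert set(train["label"]) == {"high", "low"}
        assert test["image_id"].nunique() == 2

    def test_same_seed_same_split(self):
        df = toy_windows()
        a = loio_split(df, PROBLEMS["FIVE_CLASS"], seed=7)
        b = loio_split(df, PROBLEMS["FIVE_CLASS"], seed=7)
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_class_with_one_image_rejected(self):
        df = toy_windows(images_per_class=1)
        with pytest.raises(ValueError, match="HAHV"):
            loio_split(df, PROBLEMS["FIVE_CLASS"], seed=0)


def separable_clouds(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 0.3, (n // 2, 2)), rng.normal(4, 0.3, (n // 2, 2))])
    y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    return X, y


class TestClassifiers:
    def test_lda_separates_linear_clouds(self):
        X, y = separable_clouds()
        model = WindowClassifier("LDA").fit(X, y)
        assert (model.predict(X) == y).all()

    def test_1nn_reproduces_training_labels(self):
        X, y = separable_clouds(seed=1)
        model = WindowClassifier("KNN", n_neighbors=1).fit(X, y)
        assert (model.predict(X) == y).all()

    def test_gaussian_svm_beats_lda_on_xor(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(-1, 1, (200, 2))
        y = (np.sign(X[:, 0] * X[:, 1]) > 0).astype(int)
        lda = WindowClassifier("LDA").fit(X, y)
        svm = WindowClassifier("SVM_GAUSSIAN", C=10.0).fit(X, y)
        acc_lda = (lda.predict(X) == y).mean()
        acc_svm = (svm.predict(X) == y).mean()
        assert abs(acc_lda - 0.5) < 0.15
        assert acc_svm > 0.9

    def test_feature_subset_and_missing_feature_error(self):
        df = toy_windows()
        train, test = loio_split(df, PROBLEMS["FIVE_CLASS"], seed=0)
        model = fit("KNN", train, feature_subset=["x0", "x1"], n_neighbors=3)
        model.predict(test)
        with pytest.raises(KeyError, match="x1"):
            model.predict(test.drop(columns=["x1"]))

    def test_knn_small_class_rejected(self):
        X = np.zeros((6, 2))
        y = np.array(["a"] * 4 + ["b"] * 2)
        with pytest.raises(ValueError, match="K=5"):
            WindowClassifier("KNN", n_neighbors=5).fit(X, y)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            WindowClassifier("MLP").fit(np.zeros((4, 2)), [0, 0, 1, 1])


class TestEvaluate:
    def _report(self, y_true, y_pred):
        class Dummy:
            algorithm = "KNN"
            classes_ = sorted(set(y_true))
            def predict(self, X):
                return np.asarray(y_pred)
        test = pd.DataFrame({"label": y_true})
        return evaluate(Dummy(), test)

    def test_confusion_3113_accuracy(self):
        y_true = ["a"] * 4 + ["b"] * 4
        y_pred = ["a", "a", "a", "b", "a", "b", "b", "b"]
        rep = self._report(y_true, y_pred)
        np.testing.assert_array_equal(rep.confusion, [[3, 1], [1, 3]])
        assert rep.accuracy == pytest.approx(0.75)

    def test_per_class_f_harmonic_mean(self):
        # class a: precision 0.5, recall 1.0 -> F = 2/3
        rep = self._report(["a", "b"], ["a", "a"])
        row = rep.per_class.set_index("class").loc["a"]
        assert row["precision"] == pytest.approx(0.5)
        assert row["recall"] == pytest.approx(1.0)
        assert row["f1"] == pytest.approx(2 / 3)

    def test_perfect_predictions(self):
        rep = self._report(["a", "b", "a"], ["a", "b", "a"])
        assert rep.accuracy == 1.0
        assert rep.f_score == 1.0

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(3)
        labels = ["u", "v", "w"]
        y_true = rng.choice(labels, 200).tolist()
        y_pred = rng.choice(labels, 200).tolist()
        rep = self._report(y_true, y_pred)
        acc = sum(t == p for t, p in zip(y_true, y_pred)) / 200
        assert rep.accuracy == pytest.approx(acc)
        fs = []
        for c in labels:
            tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
            fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
            fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            fs.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        assert rep.f_score == pytest.approx(np.mean(fs))


class TestCompareModels:
    def test_bonferroni_threshold(self):
        assert bonferroni_threshold() == pytest.approx(0.05 / 6)
        assert round(bonferroni_threshold(), 3) == 0.008

    def test_identical_groups_not_significant(self):
        out = compare_models({"a": [0.5, 0.5, 0.5], "b": [0.5, 0.5, 0.5]})
        row = out.iloc[0]
        assert row["F"] == 0.0 and row["p"] == 1.0 and not row["significant"]

    def test_two_group_anova_matches_hand_computation(self):
        """[1,2,3] vs [4,5,6]: SSB 13.5 (df 1), SSW 4 (df 4) -> F = 13.5."""
        g1, g2 = [1, 2, 3], [4, 5, 6]
        grand = np.mean(g1 + g2)
        ssb = 3 * (np.mean(g1) - grand) ** 2 + 3 * (np.mean(g2) - grand) ** 2
        ssw = sum((v - np.mean(g1)) ** 2 for v in g1) + sum((v - np.mean(g2)) ** 2 for v in g2)
        f_hand = (ssb / 1) / (ssw / 4)
        assert f_hand == pytest.approx(13.5)
        out = compare_models({"a": g1, "b": g2})
        assert out.iloc[0]["F"] == pytest.approx(13.5)
        assert out.iloc[0]["p"] == pytest.approx(sstats.f.sf(13.5, 1, 4))

    def test_all_six_pairwise_comparisons_present(self):
        groups = {a: list(np.random.default_rng(i).uniform(size=4)) for i, a in
                  enumerate(["KNN", "SVMc", "SVMg", "LDA"])}
        out = compare_models(groups)
        assert len(out) == 6
        assert out.attrs["p_threshold"] == pytest.approx(0.008333, abs=1e-6)

    def test_degenerate_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_models({"a": [1.0], "b": [2.0, 3.0]})


def test_measure_estimation_time_is_positive():
    X, y = separable_clouds()
    model = WindowClassifier("LDA").fit(X, y)
    ms = measure_estimation_time(model, lambda: X[:1])
    assert ms > 0
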