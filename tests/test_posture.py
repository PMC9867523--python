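import numpy as np
import pytest
from scipy import ndimage
from sklearn.metrics import precision_recall_fscore_support

from chairkit import synthgen
from chairkit.chairio import ChairGeometry
from chairkit.posture import (
    FIVE_CLASSES,
    SEVEN_CLASSES,
    CMDataset,
    ModelSpec,
    decision_map,
    default_grid,
    evaluate,
    train,
    transition_frequencies,
    tune,
)


def two_blob_dataset(n=50, sd=0.1, seed=0, centers=((5.0, 5.0), (25.0, 5.0))):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(c, sd, size=(n, 2)) for c in centers])
    y = np.array(["P1"] * n + ["P2"] * n, dtype=object)
    return CMDataset(X, y, ("P1", "P2"))


def eval_toy(y, yhat, labels=("0", "1")):
    ds = CMDataset(np.zeros((len(y), 2)), np.array(y, dtype=object), labels)

    class Fixed:
        def predict(self, X):
            return np.array(yhat, dtype=object)

    return evaluate(Fixed(), ds)


class TestCMDataset:
    def test_p4_rejected(self):
        with pytest.raises(ValueError, match="P4"):
            CMDataset(np.zeros((1, 2)), np.array(["P4"]), ("P1", "P4"))

    def test_label_outside_class_set_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            CMDataset(np.zeros((1, 2)), np.array(["P9"]), ("P1", "P2"))


class TestTrain:
    @pytest.mark.parametrize(
        "spec",
        [
            ModelSpec.make("knn", k=5),
            ModelSpec.make("nc", metric="euclidean"),
            ModelSpec.make("svm", kernel="linear", C=1.0),
            ModelSpec.make("gmm", covariance="tied"),
        ],
    )
    def test_separable_clusters_perfect(self, spec):
        tr = two_blob_dataset(seed=1)
        te = two_blob_dataset(seed=2)
        model = train(tr, spec)
        assert evaluate(model, te).accuracy == 1.0

    def test_knn_k1_returns_own_label(self):
        ds = two_blob_dataset(n=10, seed=3)
        model = train(ds, ModelSpec.make("knn", k=1))
        pred = model.predict(ds.X[:5])
        np.testing.assert_array_equal(pred, ds.y[:5])

    def test_k_exceeding_n_errors(self):
        ds = two_blob_dataset(n=5)
        with pytest.raises(ValueError, match="exceeds"):
            train(ds, ModelSpec.make("knn", k=100))

    def test_single_class_errors(self):
        ds = CMDataset(np.random.default_rng(0).normal(size=(10, 2)), np.array(["P1"] * 10), ("P1", "P2"))
        with pytest.raises(ValueError, match="2 classes"):
            train(ds, ModelSpec.make("nc"))

    def test_gmm_single_point_class_full_cov_errors(self):
        X = np.vstack([np.random.default_rng(0).normal(size=(10, 2)), [[9.0, 9.0]]])
        y = np.array(["P1"] * 10 + ["P2"], dtype=object)
        ds = CMDataset(X, y, ("P1", "P2"))
        with pytest.raises(ValueError, match="covariance"):
            train(ds, ModelSpec.make("gmm", covariance="full"))

    def test_nc_centroids_near_cluster_means(self, stats):
        n = 2000
        X, y = synthgen.gen_cm_dataset(stats, FIVE_CLASSES, n, seed=5)
        model = train(CMDataset(X, y, FIVE_CLASSES), ModelSpec.make("nc", metric="euclidean"))
        for cls, centroid in zip(model.classes_, model.centroids_):
            row = stats.row(cls)
            se_x, se_y = row["sd_x"] / np.sqrt(n), row["sd_y"] / np.sqrt(n)
            assert abs(centroid[0] - row["mean_x"]) < 3 * se_x
            assert abs(centroid[1] - row["mean_y"]) < 3 * se_y


class TestTune:
    def test_single_point_grid(self):
        ds = two_blob_dataset(n=20)
        spec, acc = tune(ds, [ModelSpec.make("nc", metric="euclidean")])
        assert spec.kwargs["metric"] == "euclidean"
        assert 0.0 <= acc <= 1.0

    def test_svm_grid_reaches_perfect_cv(self):
        ds = two_blob_dataset(n=25)
        spec, acc = tune(ds, default_grid("svm"))
        assert acc == 1.0

    def test_small_class_errors(self):
        X = np.random.default_rng(0).normal(size=(8, 2))
        y = np.array(["P1"] * 5 + ["P2"] * 3, dtype=object)
        with pytest.raises(ValueError, match="P2"):
            tune(CMDataset(X, y, ("P1", "P2")), default_grid("nc"))

    def test_stratification_counting_oracle(self):
        from sklearn.model_selection import StratifiedKFold

        rng = np.random.default_rng(4)
        y = np.array(["P1"] * 40 + ["P2"] * 25 + ["P3"] * 15, dtype=object)
        X = rng.normal(size=(len(y), 2))
        skf = StratifiedKFold(n_splits=5, shuffle=False)
        for _, va in skf.split(X, y):
            fold_y = y[va]
            for cls, total in (("P1", 40), ("P2", 25), ("P3", 15)):
                expected = total / 5
                assert abs((fold_y == cls).sum() - expected) <= 1


class TestEvaluate:
    def test_hand_computed_metrics(self):
        rep = eval_toy(["1", "1", "0", "0"], ["1", "0", "0", "0"])
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.precision == pytest.approx(5 / 6)
        assert rep.recall == pytest.approx(0.75)
        assert rep.f1 == pytest.approx((0.8 + 2 / 3) / 2)

    def test_agreement_with_reference_implementation(self):
        rng = np.random.default_rng(9)
        y = rng.choice(["0", "1", "2"], 200)
        yhat = rng.choice(["0", "1", "2"], 200)
        rep = eval_toy(y, yhat, labels=("0", "1", "2"))
        p, r, f, _ = precision_recall_fscore_support(y, yhat, labels=["0", "1", "2"], average="macro", zero_division=0)
        assert rep.precision == pytest.approx(p)
        assert rep.recall == pytest.approx(r)
        assert rep.f1 == pytest.approx(f)

    def test_perfect_predictions(self):
        rep = eval_toy(["0", "1", "0"], ["0", "1", "0"])
        assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 1.0
        assert np.all(rep.confusion == np.diag(np.diag(rep.confusion)))

    def test_constant_prediction_balanced(self):
        rep = eval_toy(["0", "0", "1", "1"], ["0", "0", "0", "0"])
        assert rep.accuracy == pytest.approx(0.5)
        assert rep.recall == pytest.approx(0.5)

    def test_macro_equals_per_label_mean(self):
        rng = np.random.default_rng(10)
        y = rng.choice(["0", "1", "2"], 100)
        yhat = rng.choice(["0", "1", "2"], 100)
        rep = eval_toy(y, yhat, labels=("0", "1", "2"))
        assert rep.precision == pytest.approx(rep.per_label["precision"].mean())
        assert rep.recall == pytest.approx(rep.per_label["recall"].mean())
        assert rep.f1 == pytest.approx(rep.per_label["f1"].mean())
        assert rep.confusion.sum() == 100

    def test_empty_testset_errors(self):
        with pytest.raises(ValueError, match="empty"):
            eval_toy([], [])


class TestDecisionMap:
    def test_grid_size_counting_oracle(self, geometry):
        ds = two_blob_dataset()
        model = train(ds, ModelSpec.make("nc"))
        xs, ys, labels = decision_map(model, geometry, step=0.1)
        assert labels.shape == (262, 304)
        assert len(xs) == int(np.floor(30.3 / 0.1)) + 1

    def test_labels_in_class_set(self, geometry):
        ds = two_blob_dataset()
        model = train(ds, ModelSpec.make("nc"))
        _, _, labels = decision_map(model, geometry, step=1.0)
        assert set(np.unique(labels)) <= {"P1", "P2"}

    def test_nc_boundary_is_perpendicular_bisector(self, geometry):
        ds = two_blob_dataset(sd=0.01, seed=6, centers=((5.0, 5.0), (25.0, 5.0)))
        model = train(ds, ModelSpec.make("nc"))
        step = 0.1
        xs, ys, labels = decision_map(model, geometry, step=step)
        c1 = ds.X[ds.y == "P1"].mean(axis=0)
        c2 = ds.X[ds.y == "P2"].mean(axis=0)
        for i in range(labels.shape[0]):
            row = labels[i]
            flips = np.flatnonzero(row[:-1] != row[1:])
            for j in flips:
                pt = np.array([xs[j] + step / 2, ys[i]])
                d1, d2 = np.linalg.norm(pt - c1), np.linalg.norm(pt - c2)
                # boundary cells are equidistant to within one grid step
                assert abs(d1 - d2) <= step * np.sqrt(2)

    def test_invalid_step_errors(self, geometry):
        model = train(two_blob_dataset(), ModelSpec.make("nc"))
        with pytest.raises(ValueError):
            decision_map(model, geometry, step=0.0)


class TestKnnIslands:
    def test_fewer_islands_with_larger_k(self, stats, geometry):
        """More neighbors -> fewer 4-connected decision islands."""
        X, y = synthgen.gen_cm_dataset(stats, FIVE_CLASSES, 2000, seed=1)
        ds = CMDataset(X, y, FIVE_CLASSES)
        counts = []
        for k in (250, 1000, 3000):
            model = train(ds, ModelSpec.make("knn", k=k))
            _, _, labels = decision_map(model, geometry, step=0.3)
            total = 0
            for cls in FIVE_CLASSES:
                _, ncomp = ndimage.label(labels == cls)
                total += ncomp
            counts.append(total)
        assert counts[0] >= counts[1] >= counts[2]


class TestGMMClassCountEffect:
    def test_five_class_beats_seven_class(self, stats):
        spec = ModelSpec.make("gmm", covariance="tied")
        accs = {}
        for classes in (FIVE_CLASSES, SEVEN_CLASSES):
            Xtr, ytr = synthgen.gen_cm_dataset(stats, classes, 800, seed=1)
            Xte, yte = synthgen.gen_cm_dataset(stats, classes, 400, seed=2)
            model = train(CMDataset(Xtr, ytr, classes), spec)
            accs[len(classes)] = evaluate(model, CMDataset(Xte, yte, classes)).accuracy
        assert accs[5] > accs[7]


class TestParameterRecovery:
    @pytest.mark.parametrize("cls", SEVEN_CLASSES)
    def test_sample_means_within_4se(self, stats, cls):
        n = 5000
        draws = synthgen.gen_cm_samples(stats, cls, n, seed=33)
        row = stats.row(cls)
        assert abs(draws[:, 0].mean() - row["mean_x"]) < 4 * row["sd_x"] / np.sqrt(n)
        assert abs(draws[:, 1].mean() - row["mean_y"]) < 4 * row["sd_y"] / np.sqrt(n)


@pytest.fixture(scope="module")
def session(geometry):
    plan = synthgen.SessionPlan(
        bouts=[("P1", 20.0), ("P3", 20.0), ("P5", 20.0)], transition_s=6.0, seed=21
    )
    return synthgen.gen_posture_session(plan, g=geometry, fs=20.0)


class TestTransitionFrequencies:
    def test_constant_classifier_rows_100(self, session, geometry):
        stream, truth = session

        class Constant:
            def predict(self, X):
                return np.array(["P1"] * len(X), dtype=object)

        table = transition_frequencies(Constant(), stream, geometry, truth.bout_intervals, FIVE_CLASSES)
        assert (table["P1"] == 100.0).all()

    def test_rows_sum_to_100(self, session, stats, geometry):
        stream, truth = session
        X, y = synthgen.gen_cm_dataset(stats, FIVE_CLASSES, 500, seed=1)
        model = train(CMDataset(X, y, FIVE_CLASSES), ModelSpec.make("nc"))
        table = transition_frequencies(model, stream, geometry, truth.bout_intervals, FIVE_CLASSES)
        np.testing.assert_allclose(table.sum(axis=1), 100.0, atol=0.01)
        assert "Average" in table.index

    def test_path_through_intermediate_region(self, session, stats, geometry):
        """A linear P1 -> P3 CM path crosses P2's centroid region."""
        stream, truth = session
        X, y = synthgen.gen_cm_dataset(stats, FIVE_CLASSES, 500, seed=1)
        model = train(CMDataset(X, y, FIVE_CLASSES), ModelSpec.make("nc"))
        table = transition_frequencies(model, stream, geometry, truth.bout_intervals, FIVE_CLASSES)
        assert table.loc["P1-P3", "P2"] > 0

    def test_single_bout_errors(self, geometry, stats):
        plan = synthgen.SessionPlan(bouts=[("P1", 10.0)], seed=1)
        stream, truth = synthgen.gen_posture_session(plan, g=geometry, fs=20.0)
        with pytest.raises(ValueError, match="2 bouts"):
            transition_frequencies(None, stream, geometry, truth.bout_intervals, FIVE_CLASSES)
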