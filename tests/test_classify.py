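import numpy as np
import pytest

from nirsmat import (
    DiscriminantModel,
    evaluate,
    fit_discriminant,
    loocv,
    predict,
    search_feature_pairs,
    stratified_split,
)
from nirsmat.classify import (
    DIRECT_FEATURES,
    STAGE1_FEATURES,
    STAGE2_FEATURE_SETS,
    ClassifyError,
    direct_classify,
    stepwise_classify,
)
from nirsmat.features import canonical_feature_name

from conftest import make_feature_table


def two_gaussian_classes(rng, n=200, sep=3.0):
    X = np.vstack([rng.normal(0, 1, (n, 2)), rng.normal(sep, 1, (n, 2))])
    y = np.array(["HC"] * n + ["CM"] * n)
    return X, y


class TestFit:
    def test_one_dimensional_hand_example(self):
        # classes {0,0,2,2} and {4,4,6,6}: means 1 and 5; each class has
        # population variance 1, so the pooled variance is 1
        X = np.array([[0.0], [0.0], [2.0], [2.0], [4.0], [4.0], [6.0], [6.0]])
        y = np.array(["HC"] * 4 + ["CM"] * 4)
        model = fit_discriminant(X, y, "LDA", shrinkage=0.0)
        assert model.means[:, 0] == pytest.approx([1.0, 5.0])
        assert model.covariances[0][0, 0] == pytest.approx(1.0)
        assert model.priors == pytest.approx([0.5, 0.5])

    def test_identical_classes_fall_back_to_tie_rule(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 2))
        Xall = np.vstack([X, X])
        y = np.array(["HC"] * 10 + ["CM"] * 10)
        model = fit_discriminant(Xall, y, "QDA")
        assert np.array_equal(model.means[0], model.means[1])
        preds = predict(model, rng.normal(size=(20, 2)))
        assert set(preds) == {"HC"}  # equal scores -> earlier class

    def test_qda_equals_lda_under_equal_covariances(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(40, 2))
        B = A + np.array([3.0, -1.0])  # identical sample covariance by construction
        X = np.vstack([A, B])
        y = np.array(["HC"] * 40 + ["CM"] * 40)
        qda = fit_discriminant(X, y, "QDA", shrinkage=0.0)
        lda = fit_discriminant(X, y, "LDA", shrinkage=0.0)
        pts = rng.normal(0, 3, size=(100, 2))
        _, sq = predict(qda, pts, return_scores=True)
        _, sl = predict(lda, pts, return_scores=True)
        # decision functions agree: score differences match to 1e-9
        assert np.allclose(sq[:, 0] - sq[:, 1], sl[:, 0] - sl[:, 1], atol=1e-9)

    def test_singular_covariance_advises_shrinkage(self):
        X = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [5.0, 5.0], [6.0, 6.0], [7.0, 7.0]])
        y = np.array(["HC", "HC", "HC", "CM", "CM", "CM"])
        with pytest.raises(ClassifyError, match="shrinkage"):
            fit_discriminant(X, y, "QDA", shrinkage=0.0)

    def test_class_with_one_sample_rejected(self):
        X = np.zeros((3, 2))
        y = np.array(["HC", "HC", "CM"])
        with pytest.raises(ClassifyError, match="at least 2"):
            fit_discriminant(X, y, "LDA")


class TestPredict:
    def _identity_lda(self, means, classes):
        k, p = np.asarray(means).shape
        return DiscriminantModel(
            kind="LDA",
            classes=list(classes),
            priors=np.full(k, 1.0 / k),
            means=np.asarray(means, dtype=float),
            covariances=np.eye(p)[None, :, :],
            shrinkage=0.0,
        )

    def test_analytic_boundary_x_plus_y_equals_one(self):
        model = self._identity_lda([[0, 0], [1, 1]], ["HC", "CM"])
        assert predict(model, [[0.4, 0.4]])[0] == "HC"
        assert predict(model, [[0.6, 0.6]])[0] == "CM"

    def test_tie_on_boundary_goes_to_first_class(self):
        model = self._identity_lda([[0, 0], [1, 1]], ["HC", "CM"])
        assert predict(model, [[0.5, 0.5]])[0] == "HC"

    def test_identity_lda_equals_nearest_centroid(self):
        rng = np.random.default_rng(2)
        means = rng.normal(size=(3, 4))
        model = self._identity_lda(means, ["HC", "CM", "MOH"])
        pts = rng.normal(0, 2, size=(300, 4))
        d = ((pts[:, None, :] - means[None]) ** 2).sum(axis=2)
        centroid_labels = np.array(["HC", "CM", "MOH"])[np.argmin(d, axis=1)]
        assert np.array_equal(predict(model, pts), centroid_labels)

    def test_reference_implementation_agreement(self):
        """Our LDA and QDA agree with scikit-learn on 200 test points."""
        sklearn_da = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(3)
        # large training sets so 1/n vs 1/(n-1) covariance weighting is moot
        Xtr, ytr = two_gaussian_classes(rng, n=500, sep=2.0)
        Xte = rng.normal(1.0, 2.0, size=(200, 2))
        ours_qda = predict(fit_discriminant(Xtr, ytr, "QDA", shrinkage=0.0), Xte)
        ours_lda = predict(fit_discriminant(Xtr, ytr, "LDA", shrinkage=0.0), Xte)
        ref_qda = sklearn_da.QuadraticDiscriminantAnalysis().fit(Xtr, ytr).predict(Xte)
        ref_lda = sklearn_da.LinearDiscriminantAnalysis().fit(Xtr, ytr).predict(Xte)
        assert np.array_equal(ours_qda, ref_qda)
        assert np.array_equal(ours_lda, ref_lda)

    def test_dimension_mismatch_rejected(self):
        model = self._identity_lda([[0, 0], [1, 1]], ["HC", "CM"])
        with pytest.raises(ClassifyError, match="features"):
            predict(model, [[1.0, 2.0, 3.0]])

    def test_prior_only_prediction_at_extreme_shrinkage(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(5, 1, (10, 2))])
        y = np.array(["HC"] * 20 + ["CM"] * 10)
        model = fit_discriminant(X, y, "LDA", shrinkage=1e12)
        preds = predict(model, rng.normal(2.5, 3, size=(50, 2)))
        assert set(preds) == {"HC"}  # majority class everywhere


class TestSplit:
    def test_cohort_split_sizes(self):
        rng = np.random.default_rng(5)
        table = make_feature_table(["HC"] * 13 + ["CM"] * 9 + ["MOH"] * 12, rng)
        train, test = stratified_split(table, seed=0)
        assert len(train) == 23 and len(test) == 11
        assert dict(zip(*np.unique(train.labels, return_counts=True))) == {
            "HC": 9, "CM": 6, "MOH": 8,
        }

    def test_migraine_only_split_sizes(self):
        rng = np.random.default_rng(6)
        table = make_feature_table(["CM"] * 9 + ["MOH"] * 12, rng)
        train, test = stratified_split(table, seed=0)
        assert len(train) == 14 and len(test) == 7

    def test_split_is_disjoint_and_complete(self):
        rng = np.random.default_rng(7)
        table = make_feature_table(["HC"] * 5 + ["CM"] * 5, rng)
        train, test = stratified_split(table, seed=3)
        ids = set(train.df.subject_id) | set(test.df.subject_id)
        assert len(ids) == 10
        assert not set(train.df.subject_id) & set(test.df.subject_id)

    def test_degenerate_fractions_rejected(self):
        rng = np.random.default_rng(8)
        table = make_feature_table(["HC"] * 4 + ["CM"] * 4, rng)
        for frac in (0.0, 1.0):
            with pytest.raises(ClassifyError):
                stratified_split(table, train_fraction=frac)


class TestLoocv:
    def test_perfectly_separated_classes_score_one(self):
        rng = np.random.default_rng(9)
        labels = ["HC"] * 10 + ["CM"] * 10
        info = {canonical_feature_name(DIRECT_FEATURES[0]): {"HC": -10.0, "CM": 10.0}}
        table = make_feature_table(labels, rng, informative=info)
        assert loocv(table, "LDA", [DIRECT_FEATURES[0]]) == 1.0

    def test_shuffled_labels_score_near_chance(self):
        rng = np.random.default_rng(10)
        labels = list(np.repeat(["HC", "CM", "MOH"], 100))
        rng.shuffle(labels)
        table = make_feature_table(labels, rng)
        acc = loocv(table, "QDA", list(DIRECT_FEATURES))
        assert 0.23 <= acc <= 0.43  # chance 1/3 within a 5-sigma binomial band

    def test_held_out_subject_never_influences_its_fold(self):
        """Perturbing one subject's features changes only predictions that
        see it in training — its own fold's trained model is untouched."""
        from nirsmat.classify import _fit_arrays, _loocv_arrays, _scores_arrays, _order_classes

        rng = np.random.default_rng(11)
        X = rng.normal(size=(12, 2))
        y = np.array(["HC"] * 6 + ["CM"] * 6)
        preds = _loocv_arrays(X, y, "QDA", 1e-6)
        for i in range(len(X)):
            mask = np.arange(len(X)) != i
            classes = _order_classes(y[mask])
            p, m, c = _fit_arrays(X[mask], y[mask], classes, "QDA", 1e-6)
            s = _scores_arrays(X[i : i + 1], "QDA", p, m, c)
            assert preds[i] == classes[int(np.argmax(s[0]))]
            # fold-i model refit after poisoning row i is identical
            Xp = X.copy()
            Xp[i] += 1e6
            p2, m2, c2 = _fit_arrays(Xp[mask], y[mask], classes, "QDA", 1e-6)
            assert np.array_equal(m, m2) and np.array_equal(c, c2)

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(12)
        table = make_feature_table(["HC", "CM"], rng)
        with pytest.raises(ClassifyError):
            loocv(table, "LDA", list(DIRECT_FEATURES))


class TestPairSearch:
    def test_planted_pair_ranks_first(self):
        rng = np.random.default_rng(13)
        labels = ["HC"] * 13 + ["CM"] * 9 + ["MOH"] * 12
        pair = tuple(canonical_feature_name(f) for f in STAGE2_FEATURE_SETS["set1"])
        info = {
            pair[0]: {"HC": -6.0, "CM": 6.0, "MOH": 6.0},
            pair[1]: {"HC": 6.0, "CM": 6.0, "MOH": -6.0},
        }
        table = make_feature_table(labels, rng, informative=info)
        candidates = list(pair) + [f for f in list(table.df.columns[3:])[:10] if f not in pair]
        ranked = search_feature_pairs(table, candidate_features=candidates)
        assert set(ranked[0][0]) == set(pair)
        assert ranked[0][1] > 0.9

    def test_ranking_is_deterministic(self):
        rng = np.random.default_rng(14)
        table = make_feature_table(["HC"] * 6 + ["CM"] * 6, rng)
        candidates = list(table.df.columns[3:9])
        r1 = search_feature_pairs(table, candidate_features=candidates)
        r2 = search_feature_pairs(table, candidate_features=candidates)
        assert r1 == r2


class TestEvaluate:
    def test_perfect_agreement(self):
        rep = evaluate(["HC", "CM", "MOH"], ["HC", "CM", "MOH"])
        assert rep.accuracy == 1.0
        assert np.array_equal(rep.confusion_matrix, np.eye(3, dtype=int))
        assert all(v == 1.0 for v in rep.sensitivity.values())
        assert all(v == 1.0 for v in rep.specificity.values())

    def test_counting_oracle_binary_case(self):
        rep = evaluate(["CM", "CM", "MOH", "MOH"], ["CM", "MOH", "MOH", "MOH"])
        assert rep.sensitivity["CM"] == 0.5
        assert rep.specificity["CM"] == 1.0
        assert rep.sensitivity["MOH"] == 1.0
        assert rep.specificity["MOH"] == 0.5

    def test_binary_accuracy_identity(self):
        rng = np.random.default_rng(15)
        y_true = rng.choice(["HC", "CM"], size=50)
        y_pred = rng.choice(["HC", "CM"], size=50)
        rep = evaluate(y_true, y_pred)
        n_pos = np.sum(y_true == "HC")
        n_neg = 50 - n_pos
        acc = (rep.sensitivity["HC"] * n_pos + rep.specificity["HC"] * n_neg) / 50
        assert rep.accuracy == pytest.approx(acc)

    def test_matrix_entries_sum_to_n(self):
        rng = np.random.default_rng(16)
        y_true = rng.choice(["HC", "CM", "MOH"], size=40)
        y_pred = rng.choice(["HC", "CM", "MOH"], size=40)
        assert evaluate(y_true, y_pred).confusion_matrix.sum() == 40

    def test_unknown_label_rejected(self):
        with pytest.raises(ClassifyError, match="labels"):
            evaluate(["HC"], ["XX"], classes=["HC", "CM"])


class TestSchemes:
    def _planted_direct_table(self, rng):
        labels = ["HC"] * 13 + ["CM"] * 9 + ["MOH"] * 12
        info = {
            canonical_feature_name(DIRECT_FEATURES[0]): {"HC": -6.0, "CM": 0.0, "MOH": 6.0},
            canonical_feature_name(DIRECT_FEATURES[1]): {"HC": 0.0, "CM": 6.0, "MOH": -6.0},
        }
        return make_feature_table(labels, rng, informative=info)

    def test_direct_with_planted_effects_recovers_labels(self):
        table = self._planted_direct_table(np.random.default_rng(17))
        rep = direct_classify(table, seed=0)
        assert rep.test_accuracy >= 0.8
        assert rep.loocv_accuracy >= 0.8

    def test_direct_report_is_deterministic(self):
        table = self._planted_direct_table(np.random.default_rng(18))
        r1 = direct_classify(table, seed=4)
        r2 = direct_classify(table, seed=4)
        assert np.array_equal(r1.confusion_matrix, r2.confusion_matrix)
        assert r1.train_accuracy == r2.train_accuracy
        assert r1.loocv_accuracy == r2.loocv_accuracy

    def test_direct_permuted_labels_near_chance(self):
        rng = np.random.default_rng(19)
        labels = list(np.repeat(["HC", "CM", "MOH"], 100))
        rng.shuffle(labels)
        table = make_feature_table(labels, rng)
        rep = direct_classify(table, seed=0)
        assert 0.23 <= rep.loocv_accuracy <= 0.43

    def _planted_stepwise_table(self, rng):
        labels = ["HC"] * 13 + ["CM"] * 9 + ["MOH"] * 12
        info = {
            canonical_feature_name(STAGE1_FEATURES[0]): {"HC": -5.0, "CM": 5.0, "MOH": 5.0},
            canonical_feature_name(STAGE1_FEATURES[1]): {"HC": 0.0, "CM": 2.0, "MOH": 2.0},
            canonical_feature_name(STAGE2_FEATURE_SETS["set1"][0]): {"HC": 0.0, "CM": -5.0, "MOH": 5.0},
        }
        return make_feature_table(labels, rng, informative=info)

    def test_stepwise_with_planted_effects_recovers_labels(self):
        table = self._planted_stepwise_table(np.random.default_rng(20))
        rep = stepwise_classify(table, seed=0)
        assert rep.accuracy >= 0.8

    def test_stepwise_composition_contract(self):
        """Row sums of the composed matrix equal per-class cohort counts,
        and stage-1 HC predictions are never relabelled CM/MOH (the HC
        column receives only stage-1 output)."""
        table = self._planted_stepwise_table(np.random.default_rng(21))
        rep = stepwise_classify(table, seed=1)
        counts = {c: int(np.sum(table.labels == c)) for c in rep.classes}
        for i, c in enumerate(rep.classes):
            assert rep.confusion_matrix[i].sum() == counts[c]
        assert rep.confusion_matrix.sum() == len(table)
        assert set(rep.extras["stage2"]) == {"train_accuracy", "test_accuracy", "loocv_accuracy"}

    def test_stepwise_reports_true_label_routing(self):
        table = self._planted_stepwise_table(np.random.default_rng(22))
        rep = stepwise_classify(table, seed=0)
        alt = rep.extras["true_label_routing"]
        assert alt.confusion_matrix.sum() == len(table)
        # with true-label routing no HC subject can be mislabelled migraine
        hc_idx = rep.classes.index("HC")
        assert alt.confusion_matrix[hc_idx, hc_idx] == np.sum(table.labels == "HC")

    def test_unknown_stage2_set_rejected(self):
        table = self._planted_stepwise_table(np.random.default_rng(23))
        with pytest.raises(ClassifyError, match="set"):
            stepwise_classify(table, cm_moh_feature_set="set3")
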