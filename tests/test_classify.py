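import numpy as np
import pandas as pd
import pytest

from methatlas.classify import (
    MortalityRiskClassifier,
    SubtypeClassifier,
    default_myeloid_labels,
    metrics,
)
from methatlas.datamodel import ValidationError
from oracles import metrics_from_confusion

TINY_GRID = {"n_estimators": [50], "num_leaves": [7],
             "reg_alpha": [0.0], "reg_lambda": [0.0]}


def _blobs(n_per, centers, sd=0.3, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for k, c in enumerate(centers):
        X.append(rng.normal(c, sd, size=(n_per, len(c))))
        y += [f"class{k}"] * n_per
    return np.vstack(X), np.array(y)


class TestSubtypeClassifier:
    def test_separable_blobs_classified_perfectly(self):
        X, y = _blobs(40, [(0, 0, 0, 0, 0), (4, 0, 0, 0, 0), (0, 4, 0, 0, 0)])
        clf = SubtypeClassifier(seed=0, param_grid=TINY_GRID).fit(X, y)
        assert (clf.predict(X) == y).all()
        probs = clf.predict_proba(X)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_single_informative_coordinate(self):
        X, y = _blobs(30, [(0, 0, 0, 0, 0), (5, 0, 0, 0, 0)], sd=0.2, seed=1)
        clf = SubtypeClassifier(seed=0, param_grid=TINY_GRID).fit(X, y)
        m = metrics(y, clf.predict(X))
        assert (m["per_class_concordance"] == 1.0).all()

    def test_shuffled_labels_give_chance_kappa_held_out(self):
        X, y = _blobs(400, [(0, 0, 0, 0, 0), (4, 0, 0, 0, 0)], seed=2)
        y_shuffled = np.random.default_rng(0).permutation(y)
        order = np.random.default_rng(1).permutation(len(y))
        train, test = order[:300], order[300:]
        clf = SubtypeClassifier(seed=0, param_grid=TINY_GRID).fit(
            X[train], y_shuffled[train])
        m = metrics(y_shuffled[test], clf.predict(X[test]))
        assert abs(m["cohens_kappa"]) < 0.12

    def test_single_sample_class_rejected(self):
        X = np.zeros((3, 5))
        with pytest.raises(ValidationError, match="single sample"):
            SubtypeClassifier(param_grid=TINY_GRID).fit(X, ["a", "a", "b"])

    def test_vocabulary_enforced(self):
        X = np.zeros((4, 5))
        with pytest.raises(ValidationError, match="vocabulary"):
            SubtypeClassifier(vocabulary=("a",), param_grid=TINY_GRID).fit(
                X, ["a", "a", "b", "b"])

    def test_one_class_cohort_predicts_it_with_certainty(self):
        X = np.random.default_rng(0).normal(size=(10, 5))
        clf = SubtypeClassifier(param_grid=TINY_GRID).fit(X, ["only"] * 10)
        preds = clf.predict_subtypes(X[:2])
        assert preds[0].top_label == "only"
        assert preds[0].class_probabilities.max() == 1.0

    def test_wrong_dimensionality_rejected(self):
        X, y = _blobs(20, [(0, 0, 0, 0, 0), (4, 0, 0, 0, 0)])
        clf = SubtypeClassifier(seed=0, param_grid=TINY_GRID).fit(X, y)
        with pytest.raises(ValidationError, match="coordinates"):
            clf.predict_proba(X[:, :3])

    def test_training_determinism(self):
        X, y = _blobs(30, [(0, 0, 0, 0, 0), (3, 1, 0, 0, 0), (0, 3, 1, 0, 0)], seed=4)
        p1 = SubtypeClassifier(seed=7).fit(X, y).predict_proba(X)
        p2 = SubtypeClassifier(seed=7).fit(X, y).predict_proba(X)
        assert np.array_equal(p1, p2)


class TestConfidenceGating:
    @pytest.mark.parametrize("pmax,expected", [(0.49, False), (0.51, True), (0.5, True)])
    def test_gate_is_exactly_half_on_max_probability(self, pmax, expected, monkeypatch):
        clf = SubtypeClassifier()
        clf.classes_ = np.array(["a", "b", "c"], dtype=object)
        clf.model_ = object()
        clf.n_features_in_ = 5
        probs = np.array([[pmax, (1.0 - pmax) * 0.6, (1.0 - pmax) * 0.4]])
        monkeypatch.setattr(SubtypeClassifier, "predict_proba",
                            lambda self, X: probs)
        pred = clf.predict_subtypes(np.zeros((1, 5)))[0]
        assert pred.confident is expected
        assert pred.reported_label == ("a" if pmax >= 0.5 else "Not confident")
        assert pred.second_label == "b"


class TestRiskClassifier:
    def test_horizon_labeling_rule(self):
        labels, usable = MortalityRiskClassifier.horizon_labels(
            [30, 30, 70, 60], [1, 0, 0, 0], 60.0)
        assert labels[0] == 1 and usable[0]          # death inside horizon
        assert not usable[1]                          # censored before horizon
        assert labels[2] == 0 and usable[2]           # followed past horizon
        assert labels[3] == 0 and usable[3]           # followed to the horizon

    def test_too_few_events_rejected(self):
        X = np.zeros((15, 5))
        t = np.full(15, 80.0)
        e = np.zeros(15); e[:3] = 1; t[:3] = 10.0
        with pytest.raises(ValidationError, match=">=10"):
            MortalityRiskClassifier(param_grid=TINY_GRID).fit(X, t, e)

    def test_coordinate_linked_hazard_is_learned(self):
        rng = np.random.default_rng(3)
        n = 500
        X = rng.normal(size=(n, 5))
        lp = 1.2 * X[:, 0]
        t_event = rng.exponential(40.0, n) * np.exp(-lp)
        censor = rng.uniform(0, 120, n)
        t = np.minimum(t_event, censor)
        e = (t_event <= censor).astype(int)
        train, test = np.arange(0, 350), np.arange(350, n)
        clf = MortalityRiskClassifier(seed=0, param_grid=TINY_GRID).fit(
            X[train], t[train], e[train])
        labels, usable = clf.horizon_labels(t[test], e[test], 60.0)
        from methatlas.survstats import roc_auc

        p = clf.predict_proba(X[test][usable])[:, 1]
        assert roc_auc(labels[usable], p) >= 0.8

    def test_risk_groups_follow_cutoff(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 5))
        t = np.where(X[:, 0] > 0, 10.0, 100.0) + rng.uniform(0, 5, 60)
        e = (X[:, 0] > 0).astype(int)
        clf = MortalityRiskClassifier(seed=0, param_grid=TINY_GRID).fit(X, t, e)
        preds = clf.predict_risk(X[:10])
        for p in preds:
            assert p.group == ("high" if p.p_death_5y >= 0.5 else "low")


class TestMetrics:
    def test_perfect_and_empty(self):
        m = metrics(["a", "b"], ["a", "b"])
        assert m["accuracy"] == m["weighted_f1"] == m["cohens_kappa"] == 1.0
        with pytest.raises(ValidationError):
            metrics([], [])

    def test_fixed_confusion_matches_oracle(self):
        cm = np.array([[8, 1, 1], [2, 6, 2], [0, 0, 10]])
        y_true, y_pred = [], []
        for i in range(3):
            for j in range(3):
                y_true += [f"c{i}"] * cm[i, j]
                y_pred += [f"c{j}"] * cm[i, j]
        got = metrics(y_true, y_pred)
        want = metrics_from_confusion(cm)
        assert got["accuracy"] == pytest.approx(want["accuracy"], abs=1e-12)
        assert got["weighted_f1"] == pytest.approx(want["weighted_f1"], abs=1e-12)
        assert got["cohens_kappa"] == pytest.approx(want["cohens_kappa"], abs=1e-12)
        assert np.allclose(got["per_class_concordance"].to_numpy(),
                           want["per_class_recall"], atol=1e-12)

    def test_random_confusions_match_oracle(self, rng):
        for _ in range(10):
            cm = rng.integers(0, 20, size=(4, 4)) + np.eye(4, dtype=int)
            y_true, y_pred = [], []
            for i in range(4):
                for j in range(4):
                    y_true += [f"c{i}"] * cm[i, j]
                    y_pred += [f"c{j}"] * cm[i, j]
            got = metrics(y_true, y_pred)
            want = metrics_from_confusion(cm)
            assert got["cohens_kappa"] == pytest.approx(want["cohens_kappa"], abs=1e-12)
            assert got["weighted_f1"] == pytest.approx(want["weighted_f1"], abs=1e-12)

    def test_chance_predictions_give_near_zero_kappa(self, rng):
        y = rng.choice(["a", "b", "c"], size=3000)
        yp = rng.choice(["a", "b", "c"], size=3000)
        assert abs(metrics(y, yp)["cohens_kappa"]) < 0.1


def test_default_myeloid_labels_cover_aml_apl_mds():
    labs = default_myeloid_labels()
    assert any(l.startswith("AML") for l in labs)
    assert any(l.startswith("MDS") for l in labs)
    assert not any(l.startswith("B-ALL") for l in labs)
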