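"""Feature assembly, fold stratification, in-fold selection, the weighted
ensemble, and leakage-free nested CV."""

import numpy as np
import pandas as pd
import pytest

from neuroadapt.fusion import (
    CLASS_ORDER, EnsembleModel, FeatureTable, Selector, assemble_features,
    fit_ensemble, nested_cv, select_topk, stratified_folds, temporal_holdout,
)


def modality_row(pid, group, order=0, **over):
    row = {"participant": pid, "group": group, "condition": "AR",
           "recruitment_order": order,
           "eeg": {"tbr": 2.0, "theta": 30.0},
           "ecg": {"lf_hf": 2.0, "rmssd_ms": 45.0},
           "gaze": {"fixation_ms": 300.0}}
    row.update(over)
    return row


def gaussian_table(rng, n=100, n_features=12, separation=3.0):
    from neuroadapt.synth.cohort import group_counts
    counts = group_counts(n)
    rows = []
    order = 0
    for gi, g in enumerate(CLASS_ORDER):
        centre = np.zeros(n_features)
        centre[gi * 2:gi * 2 + 2] = separation
        for _ in range(counts[g]):
            x = centre + rng.standard_normal(n_features)
            row = {"participant": f"{g}{order}", "group": g,
                   "condition": "AR", "recruitment_order": order}
            row.update({f"syn.f{j}": x[j] for j in range(n_features)})
            rows.append(row)
            order += 1
    return FeatureTable(frame=pd.DataFrame.from_records(rows))


class TestAssemble:
    def test_row_and_column_counts(self):
        t = assemble_features([modality_row("p1", "ASD"),
                               modality_row("p2", "TD", 1)])
        assert t.n_rows == 2
        assert len(t.feature_names) == 5
        assert "eeg.tbr" in t.feature_names

    def test_missing_modality_dropped_with_named_warning(self):
        rows = [modality_row("p1", "ASD"),
                modality_row("p2", "TD", gaze={})]
        with pytest.warns(UserWarning, match="p2"):
            t = assemble_features(rows)
        assert t.n_rows == 1

    def test_duplicate_feature_name_rejected(self):
        frame = pd.DataFrame({"participant": ["a"], "group": ["TD"],
                              "x": [1.0]})
        frame = pd.concat([frame, frame["x"]], axis=1)  # duplicate column
        with pytest.raises(ValueError, match="duplicate"):
            FeatureTable(frame=frame)


class TestFolds:
    def test_stratification_within_one_row(self, rng):
        t = gaussian_table(rng)
        plan = stratified_folds(t.y, 10, 5, seed=0)
        global_counts = pd.Series(t.y).value_counts()
        for _, te in plan.outer:
            counts = pd.Series(t.y[te]).value_counts()
            for cls in global_counts.index:
                expected = global_counts[cls] / 10
                assert abs(counts.get(cls, 0) - expected) <= 1

    def test_deterministic_given_seed(self, rng):
        t = gaussian_table(rng)
        p1 = stratified_folds(t.y, 10, 5, seed=3)
        p2 = stratified_folds(t.y, 10, 5, seed=3)
        for (a, _), (b, _) in zip(p1.outer, p2.outer):
            assert np.array_equal(a, b)

    def test_small_class_and_bad_k_rejected(self):
        y = np.array(["ASD"] * 3 + ["TD"] * 30)
        with pytest.raises(ValueError, match="ASD"):
            stratified_folds(y, 10, 5, seed=0)
        with pytest.raises(ValueError, match="at least 2"):
            stratified_folds(y, 1, 5, seed=0)


class TestSelection:
    def test_separating_feature_wins_k1(self, rng):
        n = 60
        y = np.repeat(["A", "B"], n // 2)
        X = rng.standard_normal((n, 10))
        X[:, 4] += np.where(y == "A", 5.0, -5.0)
        sel = select_topk(X, y, k=1)
        assert list(sel.indices) == [4]

    def test_k_equal_feature_count_is_identity(self, rng):
        X = rng.standard_normal((30, 6))
        y = np.repeat(["A", "B"], 15)
        sel = select_topk(X, y, k=6)
        assert list(sel.indices) == list(range(6))

    def test_nonpositive_k_rejected(self, rng):
        with pytest.raises(ValueError, match="positive"):
            select_topk(rng.standard_normal((10, 3)),
                        np.repeat(["A", "B"], 5), k=0)

    def test_transform_zscales_with_training_stats(self, rng):
        X = rng.standard_normal((50, 4)) * 5 + 3
        y = np.repeat(["A", "B"], 25)
        sel = select_topk(X, y, k=4)
        Z = sel.transform(X)
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(Z.std(axis=0), 1, atol=1e-9)


class _StubModel:
    def __init__(self, proba, classes):
        self._p = np.asarray(proba)
        self.classes_ = np.asarray(classes)

    def predict_proba(self, X):
        return np.tile(self._p, (len(X), 1))


def identity_selector(n_features):
    return Selector(indices=np.arange(n_features),
                    medians=np.zeros(n_features), means=np.zeros(n_features),
                    sds=np.ones(n_features), scores=np.zeros(n_features))


class TestEnsemble:
    def test_weighted_sum_arithmetic(self):
        classes = ["c1", "c2"]
        model = EnsembleModel(
            models=[_StubModel([0.6, 0.4], classes),
                    _StubModel([0.2, 0.8], classes),
                    _StubModel([0.5, 0.5], classes)],
            weights=(0.4, 0.35, 0.25),
            selector=identity_selector(2), classes=np.array(classes))
        proba = model.predict_proba(np.zeros((1, 2)))
        assert proba[0, 0] == pytest.approx(0.435)
        assert proba[0, 1] == pytest.approx(0.565)
        assert model.predict(np.zeros((1, 2)))[0] == "c2"

    def test_degenerate_weights_follow_first_model(self, rng):
        X = rng.standard_normal((60, 5))
        y = np.where(X[:, 0] > 0, "A", "B")
        sel = select_topk(X, y, k=5)
        model = fit_ensemble(X, y, sel, weights=(1.0, 0.0, 0.0), seed=0)
        svm_pred = model.models[0].predict(sel.transform(X))
        assert np.array_equal(model.predict(X), svm_pred)

    def test_weights_renormalized_with_warning(self, rng):
        X = rng.standard_normal((40, 4))
        y = np.repeat(["A", "B"], 20)
        sel = select_topk(X, y, k=4)
        with pytest.warns(UserWarning, match="renormaliz"):
            model = fit_ensemble(X, y, sel, weights=(0.8, 0.7, 0.5), seed=0)
        assert sum(model.weights) == pytest.approx(1.0)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((20, 4))
        y = np.repeat(["A"], 20)
        with pytest.raises(ValueError, match="single-class"):
            fit_ensemble(X, y, identity_selector(4))


class TestNestedCV:
    def test_single_informative_feature_selected_across_folds(self, rng):
        n = 80
        y = np.repeat(["A", "B"], n // 2)
        X = rng.standard_normal((n, 20))
        X[:, 7] += np.where(y == "A", 4.0, -4.0)
        plan = stratified_folds(y, 10, 5, seed=1)
        hits = sum(7 in select_topk(X[tr], y[tr], k=1).indices
                   for tr, _ in plan.outer)
        assert hits >= 9

    def test_leakage_guard_perturbed_test_row_cannot_move_its_fold(self, rng):
        # a test row influences nothing fitted in its own fold: perturbing
        # it leaves the fold's selector and every other prediction in that
        # fold unchanged
        t = gaussian_table(rng, n=60, separation=1.0)
        plan = stratified_folds(t.y, 5, 3, seed=2)
        rep1 = nested_cv(t, plan, k_features=8, n_trees=50)
        tr0, te0 = plan.outer[0]
        victim = te0[0]
        frame = t.frame.copy()
        frame.iloc[victim, 4:] = 1e6
        t2 = FeatureTable(frame=frame)
        rep2 = nested_cv(t2, plan, k_features=8, n_trees=50)
        others = [i for i in te0 if i != victim]
        assert np.array_equal(rep1.predictions[others],
                              rep2.predictions[others])
        s1 = select_topk(t.X[tr0], t.y[tr0], k=8)
        s2 = select_topk(t2.X[tr0], t2.y[tr0], k=8)
        assert np.array_equal(s1.indices, s2.indices)
        assert np.allclose(s1.means, s2.means)

    def test_report_confusion_row_sums_match_class_counts(self, rng):
        t = gaussian_table(rng, n=60)
        plan = stratified_folds(t.y, 5, 3, seed=0)
        rep = nested_cv(t, plan, k_features=8, n_trees=50)
        counts = pd.Series(t.y).value_counts()
        for cls in rep.confusion.index:
            assert rep.confusion.loc[cls].sum() == counts[cls]


class TestTemporalHoldout:
    def test_split_by_recruitment_order(self, rng):
        t = gaussian_table(rng, n=100)
        dev, hold = temporal_holdout(t, 0.2, k_outer=5, k_inner=3,
                                     k_features=6, n_trees=50)
        # reports exist and the split was 80/20 by order
        assert dev.confusion.to_numpy().sum() == 80
        assert hold.confusion.to_numpy().sum() == 20

    def test_bad_fraction_rejected(self, rng):
        t = gaussian_table(rng, n=60)
        with pytest.raises(ValueError, match="fraction"):
            temporal_holdout(t, 1.5)
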