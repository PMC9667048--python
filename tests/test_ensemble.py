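"""Stratified resampling, ECOC linear SVM and majority-vote ensembling."""

import numpy as np
import pandas as pd
import pytest

from petdx.ensemble import (
    SplitScheme,
    SVMConfig,
    make_splits,
    run_ensemble,
    train_multiclass_linear,
)
from petdx.roifeat import FeatureMatrix


def _table(sizes: dict[str, int]) -> pd.DataFrame:
    rows = [
        {"id": f"{cls}_{k:03d}", "class": cls, "leakage": False}
        for cls, n in sizes.items()
        for k in range(n)
    ]
    return pd.DataFrame(rows)


STUDY_SIZES = {"AD": 63, "DLB": 79, "FTD": 23, "NC": 41}
STUDY_LEAKAGE = {"AD": 20, "DLB": 20, "FTD": 10, "NC": 29}


def _leakage_ids(table, counts):
    ids = []
    for cls, n in counts.items():
        ids.extend(table.loc[table["class"] == cls, "id"].iloc[:n])
    return frozenset(ids)


class TestMakeSplits:
    def test_stratified_train_sizes_round_half_to_even(self):
        """Class sizes (63, 79, 23, 41) -> train sizes (44, 55, 16, 29)."""
        table = _table(STUDY_SIZES)
        scheme = SplitScheme(n_iterations=3, master_seed=1)
        for train, test in make_splits(table, scheme):
            classes = pd.Series([s.split("_")[0] for s in train]).value_counts()
            assert classes.to_dict() == {"AD": 44, "DLB": 55, "FTD": 16, "NC": 29}
            assert len(train) + len(test) == 206

    def test_leakage_subjects_never_tested(self):
        table = _table(STUDY_SIZES)
        leak = _leakage_ids(table, STUDY_LEAKAGE)
        scheme = SplitScheme(n_iterations=10, leakage_ids=leak, master_seed=2)
        for train, test in make_splits(table, scheme):
            assert not leak.intersection(test)
            assert leak.issubset(train)

    def test_reduced_dataset_eligibility_counts(self):
        """Leakage (20,20,10,29) of (63,79,23,41) leaves (43,59,13,12) = 127."""
        table = _table(STUDY_SIZES)
        leak = _leakage_ids(table, STUDY_LEAKAGE)
        scheme = SplitScheme(n_iterations=50, leakage_ids=leak, master_seed=3)
        tested = set()
        for _, test in make_splits(table, scheme):
            tested.update(test)
        assert len(tested) == 127
        per_class = pd.Series([s.split("_")[0] for s in tested]).value_counts()
        assert per_class.to_dict() == {"AD": 43, "DLB": 59, "FTD": 13, "NC": 12}

    def test_fully_leaked_class_never_tested(self):
        table = _table({"AD": 5, "DLB": 5, "FTD": 5, "NC": 5})
        leak = frozenset(table.loc[table["class"] == "FTD", "id"])
        scheme = SplitScheme(n_iterations=5, leakage_ids=leak, master_seed=4)
        for _, test in make_splits(table, scheme):
            assert not any(s.startswith("FTD") for s in test)

    def test_same_master_seed_identical_sequence(self):
        table = _table(STUDY_SIZES)
        a = make_splits(table, SplitScheme(n_iterations=5, master_seed=7))
        b = make_splits(table, SplitScheme(n_iterations=5, master_seed=7))
        assert a == b

    def test_expected_test_appearances(self):
        """500 iterations at 70/30: ~150 expected test appearances, >= 50 always."""
        table = _table(STUDY_SIZES)
        # without leakage: every subject expected ~30% of 500 = 150 times
        counts: dict[str, int] = {}
        for _, test in make_splits(table, SplitScheme(n_iterations=500, master_seed=5)):
            for s in test:
                counts[s] = counts.get(s, 0) + 1
        assert set(counts) == set(table["id"])
        assert min(counts.values()) >= 50
        assert 130 <= np.mean(list(counts.values())) <= 170
        # with leakage: the eligible subjects absorb the test slots but the
        # floor still holds
        leak = _leakage_ids(table, STUDY_LEAKAGE)
        counts = {}
        scheme = SplitScheme(n_iterations=500, leakage_ids=leak, master_seed=5)
        for _, test in make_splits(table, scheme):
            for s in test:
                counts[s] = counts.get(s, 0) + 1
        assert set(counts) == set(table["id"]) - leak
        assert min(counts.values()) >= 50


def _toy_features(rng, n_per_class=12, spread=4.0):
    """Four well-separated 2-D class clouds."""
    centers = {"AD": (0, 0), "DLB": (spread, 0), "FTD": (0, spread), "NC": (spread, spread)}
    X, ids, labels = [], [], []
    for cls, c in centers.items():
        X.append(rng.normal(c, 0.3, size=(n_per_class, 2)))
        ids.extend(f"{cls}_{k:03d}" for k in range(n_per_class))
        labels.extend([cls] * n_per_class)
    return FeatureMatrix(
        values=np.vstack(X),
        feature_names=["f0", "f1"],
        subject_ids=ids,
        class_labels=labels,
        leakage_flags=np.zeros(4 * n_per_class, bool),
    )


class TestTrainMulticlassLinear:
    def test_four_classes_give_six_learners(self, rng):
        fm = _toy_features(rng)
        model = train_multiclass_linear(fm.values, fm.labels_array())
        assert len(model.learners_) == 6
        assert model.coding_.shape == (4, 6)

    def test_separable_toy_set_fits_perfectly(self, rng):
        fm = _toy_features(rng)
        model = train_multiclass_linear(fm.values, fm.labels_array())
        assert (model.predict(fm.values) == fm.labels_array()).all()

    def test_duplicate_feature_column_same_predictions(self, rng):
        fm = _toy_features(rng)
        X = fm.values
        X_dup = np.column_stack([X, X[:, 0]])
        y = fm.labels_array()
        a = train_multiclass_linear(X, y).predict(X)
        b = train_multiclass_linear(X_dup, y).predict(X_dup)
        assert (a == b).all()

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            train_multiclass_linear(rng.normal(size=(5, 2)), np.array(["AD"] * 5))

    def test_one_vs_all_coding_available(self, rng):
        fm = _toy_features(rng)
        model = train_multiclass_linear(
            fm.values, fm.labels_array(), SVMConfig(coding="ova")
        )
        assert len(model.learners_) == 4
        assert (model.predict(fm.values) == fm.labels_array()).all()

    def test_class_margins_match_linear_coefficients(self, rng):
        fm = _toy_features(rng)
        model = train_multiclass_linear(fm.values, fm.labels_array())
        W, b = model.linear_class_coefficients()
        np.testing.assert_allclose(
            model.class_margins(fm.values), fm.values @ W.T + b, atol=1e-10
        )


class TestRunEnsemble:
    def test_modal_final_label(self, rng):
        fm = _toy_features(rng)
        scheme = SplitScheme(n_iterations=15, master_seed=6)
        result = run_ensemble(fm, scheme)
        truth = dict(zip(fm.subject_ids, fm.class_labels))
        # separable problem: mode equals the truth for every tested subject
        for sid, label in result.final_labels.items():
            assert label == truth[sid]

    def test_class_scores_sum_to_one_and_mode_dominates(self, rng):
        fm = _toy_features(rng)
        result = run_ensemble(fm, SplitScheme(n_iterations=15, master_seed=6))
        sums = result.class_scores.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        for sid, label in result.final_labels.items():
            assert result.class_scores.loc[sid, label] >= 1.0 / len(result.class_order)

    def test_leakage_subjects_have_no_final_label(self, rng):
        fm = _toy_features(rng)
        leak = frozenset(fm.subject_ids[:5])
        result = run_ensemble(
            fm, SplitScheme(n_iterations=10, leakage_ids=leak, master_seed=7)
        )
        assert not leak.intersection(result.final_labels)
        assert set(result.final_labels) == set(fm.subject_ids) - leak

    def test_reproducible_given_master_seed(self, rng):
        fm = _toy_features(rng)
        scheme = SplitScheme(n_iterations=10, master_seed=8)
        r1 = run_ensemble(fm, scheme)
        r2 = run_ensemble(fm, scheme)
        assert r1.final_labels == r2.final_labels
        pd.testing.assert_frame_equal(r1.class_scores, r2.class_scores)
        pd.testing.assert_frame_equal(r1.iteration_records, r2.iteration_records)

    def test_tie_breaks_follow_canonical_class_order(self):
        """An AD/DLB vote tie resolves to AD (AD < DLB < FTD < NC)."""
        rng = np.random.default_rng(0)
        # two overlapping clouds -> frequent ties at tiny iteration counts
        X = np.vstack(
            [rng.normal(0, 1, (6, 1)), rng.normal(0.1, 1, (6, 1)),
             rng.normal(5, 0.1, (6, 1)), rng.normal(8, 0.1, (6, 1))]
        )
        fm = FeatureMatrix(
            values=X,
            feature_names=["f0"],
            subject_ids=[f"s{k}" for k in range(24)],
            class_labels=["AD"] * 6 + ["DLB"] * 6 + ["FTD"] * 6 + ["NC"] * 6,
            leakage_flags=np.zeros(24, bool),
        )
        result = run_ensemble(fm, SplitScheme(n_iterations=2, master_seed=9))
        for sid, label in result.final_labels.items():
            scores = result.class_scores.loc[sid]
            tied = [c for c in result.class_order if scores[c] == scores.max()]
            assert label == tied[0]
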