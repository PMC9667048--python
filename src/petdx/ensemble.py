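"""Repeated stratified linear-SVM ensemble with majority voting.

The classifier retrains a multi-class maximum-margin linear model over many
(default 500) stratified 70/30 train/test resamples.  Multi-class handling
is one-vs-one error-correcting output codes: one binary linear SVM per
unordered class pair, decoded by loss-weighted voting (mean binary hinge
loss against the coding matrix).  A subject's final label is the modal
predicted label over all resamples in which it landed in the test set.

Leakage control: subjects used to identify the metabolic patterns are
forced into every training split and never appear in a test set, so their
pattern scores cannot inflate prospective performance.  With the study
counts — 20/20/10/29 derivation subjects out of 63 AD, 79 DLB, 23 FTD and
41 NC — this leaves 43 + 59 + 13 + 12 = 127 label-eligible subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from petdx.labels import class_rank
from petdx.roifeat import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SplitScheme",
    "SVMConfig",
    "ECOCModel",
    "EnsembleResult",
    "make_splits",
    "train_multiclass_linear",
    "run_ensemble",
]


@dataclass
class SplitScheme:
    """Resampling scheme for the ensemble.

    Each iteration draws a stratified split: per class,
    ``round(train_fraction * n)`` subjects (round half to even) go to
    training — leakage subjects first — and the rest to testing.  Iteration
    *i* uses the RNG seeded by ``(master_seed, i)``, so the whole split
    sequence is reproducible from ``master_seed`` alone.
    """

    n_iterations: int = 500
    train_fraction: float = 0.7
    stratified: bool = True
    leakage_ids: frozenset = field(default_factory=frozenset)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        self.leakage_ids = frozenset(self.leakage_ids)


@dataclass
class SVMConfig:
    """Binary-learner and coding settings.

    ``C`` is the (untuned) SVM regularization strength; features are
    z-scored with training-fold statistics when ``standardize`` is on.
    ``coding`` is "ovo" (one-vs-one, the default) or "ova" (one-vs-all).
    """

    C: float = 1.0
    coding: str = "ovo"
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.coding not in ("ovo", "ova"):
            raise ValueError(f"unknown coding {self.coding!r}")


def _train_size(n: int, train_fraction: float) -> int:
    # round half to even on the exact fraction, then keep >= 1 and < n
    return int(round(train_fraction * n))


def make_splits(
    subject_table: pd.DataFrame, scheme: SplitScheme
) -> list[tuple[list[str], list[str]]]:
    """Generate the stratified (train_ids, test_ids) sequence.

    Leakage subjects are forced into training first; if a class's training
    quota exceeds its leakage count the remainder is drawn at random from
    the non-leakage subjects, and the rest are tested.  A class whose
    subjects are all leakage is simply never tested.  The training quota is
    adjusted by one when it would otherwise leave no test subject for a
    class that has eligible ones.
    """
    by_class: dict[str, list[str]] = {}
    for cls, group in subject_table.groupby("class", sort=False):
        by_class[cls] = group["id"].tolist()
    classes = sorted(by_class, key=class_rank)

    leak: dict[str, list[str]] = {}
    nonleak: dict[str, list[str]] = {}
    for cls in classes:
        ids = by_class[cls]
        leak[cls] = [s for s in ids if s in scheme.leakage_ids]
        nonleak[cls] = [s for s in ids if s not in scheme.leakage_ids]
        if not ids:
            raise ValueError(f"class {cls} has no subjects")

    splits: list[tuple[list[str], list[str]]] = []
    for i in range(scheme.n_iterations):
        rng = np.random.default_rng([scheme.master_seed, i])
        train: list[str] = []
        test: list[str] = []
        for cls in classes:
            n = len(by_class[cls])
            n_train = _train_size(n, scheme.train_fraction)
            n_train = max(n_train, len(leak[cls]), 1)
            if n_train >= n and nonleak[cls]:
                n_train = n - 1  # keep at least one test subject when possible
            n_extra = n_train - len(leak[cls])
            perm = rng.permutation(nonleak[cls]) if nonleak[cls] else np.array([])
            train.extend(leak[cls])
            train.extend(perm[:n_extra].tolist())
            test.extend(perm[n_extra:].tolist())
        splits.append((train, test))
    return splits


class ECOCModel:
    """One-vs-one (or one-vs-all) linear SVM with loss-weighted decoding.

    For K classes and coding matrix M (K x L with entries in {-1, 0, +1}),
    the decoded per-class loss is the mean binary hinge loss
    ``max(0, 1 - m_kl * s_l) / 2`` over the learners the class takes part
    in; prediction is the argmin, with ties broken by the canonical class
    order.  ``class_margins`` exposes the *linear* per-class score (mean of
    signed learner margins), which is what the exact linear Shapley
    attribution explains.
    """

    def __init__(self, classes, coding, learners, mean_, scale_):
        self.classes_ = list(classes)
        self.coding_ = np.asarray(coding, dtype=float)  # K x L
        self.learners_ = learners
        self.mean_ = mean_
        self.scale_ = scale_

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def _learner_margins(self, X: np.ndarray) -> np.ndarray:
        Xs = self._standardize(X)
        return np.column_stack([clf.decision_function(Xs) for clf in self.learners_])

    def class_losses(self, X: np.ndarray) -> np.ndarray:
        """n x K matrix of mean binary hinge losses per class."""
        s = self._learner_margins(X)  # n x L
        m = self.coding_  # K x L
        active = np.abs(m) > 0
        hinge = np.maximum(0.0, 1.0 - s[:, None, :] * m[None, :, :]) / 2.0
        return (hinge * active[None]).sum(axis=2) / active.sum(axis=1)[None, :]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class decoded scores (negative mean hinge loss; higher = better)."""
        return -self.class_losses(X)

    def class_margins(self, X: np.ndarray) -> np.ndarray:
        """Linear per-class score: mean of signed learner margins (n x K)."""
        s = self._learner_margins(X)
        m = self.coding_
        active = np.abs(m) > 0
        return (s[:, None, :] * m[None, :, :]).sum(axis=2) / active.sum(axis=1)[None, :]

    def linear_class_coefficients(self) -> tuple[np.ndarray, np.ndarray]:
        """(W, b) with ``class_margins(X) == X @ W.T + b`` in raw feature space."""
        w_raw = []
        b_raw = []
        for clf in self.learners_:
            w = clf.coef_[0] / self.scale_
            b = clf.intercept_[0] - np.sum(clf.coef_[0] * self.mean_ / self.scale_)
            w_raw.append(w)
            b_raw.append(b)
        w_raw = np.asarray(w_raw)  # L x d
        b_raw = np.asarray(b_raw)  # L
        m = self.coding_
        n_active = (np.abs(m) > 0).sum(axis=1)
        W = (m @ w_raw) / n_active[:, None]
        b = (m @ b_raw) / n_active
        return W, b

    def predict(self, X: np.ndarray) -> np.ndarray:
        losses = self.class_losses(X)
        # stable argmin: ties resolve to the earlier class in canonical order
        idx = np.argmin(losses, axis=1)
        return np.asarray([self.classes_[i] for i in idx])


def train_multiclass_linear(
    X: np.ndarray, y, config: SVMConfig | None = None
) -> ECOCModel:
    """Fit the multi-class linear-kernel SVM on one training fold.

    One binary SVM per unordered class pair (ovo) or per class (ova);
    K classes give K(K-1)/2 ovo learners.  Standardization statistics are
    computed from this fold only.
    """
    config = config or SVMConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(set(y.tolist()), key=class_rank)
    if len(classes) < 2:
        raise ValueError("training set must contain at least 2 classes")

    if config.standardize:
        mean_ = X.mean(axis=0)
        scale_ = X.std(axis=0)
        scale_[scale_ == 0] = 1.0
    else:
        mean_ = np.zeros(X.shape[1])
        scale_ = np.ones(X.shape[1])
    Xs = (X - mean_) / scale_

    learners = []
    if config.coding == "ovo":
        pairs = list(combinations(range(len(classes)), 2))
        coding = np.zeros((len(classes), len(pairs)))
        for l, (a, b) in enumerate(pairs):
            coding[a, l] = 1.0
            coding[b, l] = -1.0
            sel = (y == classes[a]) | (y == classes[b])
            yl = np.where(y[sel] == classes[a], 1, -1)
            clf = SVC(kernel="linear", C=config.C)
            clf.fit(Xs[sel], yl)
            learners.append(clf)
    else:  # one-vs-all
        coding = -np.ones((len(classes), len(classes)))
        for l, cls in enumerate(classes):
            coding[l, l] = 1.0
            yl = np.where(y == cls, 1, -1)
            clf = SVC(kernel="linear", C=config.C)
            clf.fit(Xs, yl)
            learners.append(clf)
    return ECOCModel(classes, coding, learners, mean_, scale_)


@dataclass
class EnsembleResult:
    """Per-iteration predictions plus the majority-vote summary.

    ``class_scores`` rows (one per tested subject) are the fractions of
    test appearances in which each class was predicted; they sum to 1 and
    serve as the one-vs-all ROC score.  Subjects never tested (all-leakage)
    carry no final label.
    """

    iteration_records: pd.DataFrame  # iteration, id, true, predicted
    final_labels: dict[str, str]
    test_counts: dict[str, int]
    class_scores: pd.DataFrame  # index id, one column per class
    class_order: tuple[str, ...]

    def tested_ids(self) -> list[str]:
        return list(self.final_labels)


def run_ensemble(
    feature_matrix: FeatureMatrix,
    scheme: SplitScheme,
    config: SVMConfig | None = None,
) -> EnsembleResult:
    """Train/test the model over every split and majority-vote final labels.

    Standardization statistics come from each training fold only, and each
    fold's model is applied prospectively to its test subjects.  The final
    label is the modal prediction over a subject's test appearances; modal
    ties break first by higher vote fraction (equal by definition of a tie)
    then by the canonical class order AD < DLB < FTD < NC.
    """
    config = config or SVMConfig()
    table = feature_matrix.subject_table()
    splits = make_splits(table, scheme)
    classes = sorted(set(feature_matrix.class_labels), key=class_rank)

    idx_of = {sid: i for i, sid in enumerate(feature_matrix.subject_ids)}
    X = feature_matrix.values
    y = feature_matrix.labels_array()

    votes: dict[str, np.ndarray] = {}
    records: list[tuple[int, str, str, str]] = []
    for it, (train_ids, test_ids) in enumerate(splits):
        if not test_ids:
            continue
        tr = [idx_of[s] for s in train_ids]
        te = [idx_of[s] for s in test_ids]
        model = train_multiclass_linear(X[tr], y[tr], config)
        preds = model.predict(X[te])
        for sid, true_lab, pred in zip(test_ids, y[te], preds):
            vec = votes.setdefault(sid, np.zeros(len(classes)))
            vec[classes.index(pred)] += 1
            records.append((it, sid, true_lab, pred))

    never_tested = [s for s in feature_matrix.subject_ids if s not in votes]
    if never_tested:
        logger.info(
            "%d subject(s) never appeared in a test set (leakage); "
            "excluded from final labels",
            len(never_tested),
        )

    final: dict[str, str] = {}
    counts: dict[str, int] = {}
    score_rows = []
    score_ids = []
    for sid in feature_matrix.subject_ids:
        if sid not in votes:
            continue
        vec = votes[sid]
        counts[sid] = int(vec.sum())
        frac = vec / vec.sum()
        final[sid] = classes[int(np.argmax(frac))]  # argmax keeps first on ties
        score_rows.append(frac)
        score_ids.append(sid)

    class_scores = pd.DataFrame(score_rows, index=score_ids, columns=classes)
    iteration_records = pd.DataFrame(
        records, columns=["iteration", "id", "true", "predicted"]
    )
    return EnsembleResult(
        iteration_records=iteration_records,
        final_labels=final,
        test_counts=counts,
        class_scores=class_scores,
        class_order=tuple(classes),
    )
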