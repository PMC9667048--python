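"""Model explanation: NCA feature weighting and Shapley importance maps.

Two complementary views of what drives the classifier:

* **Neighborhood component analysis (NCA)** learns non-negative per-feature
  weights maximizing a soft leave-one-out nearest-neighbor classification
  objective minus an L2 penalty ``lambda * sum(w**2)``.  Weighted distances
  are ``d(i, j) = sum_r w_r**2 * |x_ir - x_jr|``; reference probabilities
  ``p_ij`` are softmax of ``-d`` over ``j != i``.  Weights rank features,
  feed a selection-frequency histogram over resamples, and an F1-versus-
  top-k-features curve.

* **Shapley values** attribute each subject's per-class score to features.
  For the linear per-class margin the marginal-expectation Shapley value
  has the closed form ``phi_j = w_j * (x_j - reference_mean_j)``; a
  Monte-Carlo estimator over random feature orderings handles any score
  function, with absent features imputed from a background sample
  (independently, or from a Gaussian conditional on the present features in
  the dependent mode).  Class-specific importance maps are group means of
  absolute Shapley values painted onto the atlas parcels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold

from petdx.ensemble import SplitScheme, SVMConfig, make_splits, run_ensemble, train_multiclass_linear
from petdx.metrics import confusion, per_class_metrics
from petdx.preprocess import Atlas
from petdx.roifeat import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NCAWeights",
    "ShapleyValues",
    "ShapleyTable",
    "ImportanceMap",
    "nca_objective",
    "fit_nca",
    "select_lambda",
    "selection_frequency",
    "f1_vs_topk",
    "shapley_linear_exact",
    "shapley_sampling",
    "shapley_table_linear",
    "class_importance_map",
]


# ---------------------------------------------------------------------------
# Neighborhood component analysis
# ---------------------------------------------------------------------------


@dataclass
class NCAWeights:
    """Fitted per-feature weights with the optimizer's objective trace."""

    w: np.ndarray
    lam: float
    objective_trace: list[float]
    converged: bool


def _abs_diffs(X: np.ndarray) -> np.ndarray:
    """Pairwise per-feature absolute differences, shape (n, n, d)."""
    return np.abs(X[:, None, :] - X[None, :, :])


def nca_objective(
    w: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    _absdiff: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Leave-one-out NCA objective (to maximize) and its analytic gradient.

    value = mean_i p_i - lambda * sum_r w_r**2, where p_i is subject i's
    probability of being matched to a same-class neighbor under the softmax
    reference distribution.  Row-max shifting guards the exponentials.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    w = np.asarray(w, dtype=float)
    if w.shape != (d,):
        raise ValueError("weight vector length must match feature count")
    A = _abs_diffs(X) if _absdiff is None else _absdiff

    dist = A @ (w**2)  # (n, n)
    np.fill_diagonal(dist, np.inf)
    shift = dist.min(axis=1, keepdims=True)  # subtract row min of d
    p = np.exp(-(dist - shift))
    np.fill_diagonal(p, 0.0)
    p /= p.sum(axis=1, keepdims=True)

    same = y[:, None] == y[None, :]
    np.fill_diagonal(same, False)
    p_i = (p * same).sum(axis=1)
    value = float(p_i.mean() - lam * np.sum(w**2))

    # d p_i / d w_r = 2 w_r [ p_i * sum_k p_ik a_ikr - sum_{j same} p_ij a_ijr ]
    term_all = np.einsum("ij,ijr->ir", p, A)
    term_same = np.einsum("ij,ijr->ir", p * same, A)
    grad = 2.0 * w * ((p_i[:, None] * term_all - term_same).sum(axis=0) / n)
    grad -= 2.0 * lam * w
    return value, grad


def fit_nca(
    X: np.ndarray,
    y,
    lam: float,
    seed: int = 0,
    max_iter: int = 400,
    gtol: float = 1e-6,
) -> NCAWeights:
    """Maximize the NCA objective with L-BFGS from the all-ones start.

    The start and optimizer are deterministic, so ``seed`` only matters for
    API symmetry with the stochastic explainers.  Since the objective
    depends on ``w`` through ``w**2`` only, the returned weights are
    projected to their absolute values.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    A = _abs_diffs(X)
    trace: list[float] = []

    def neg(wv: np.ndarray) -> tuple[float, np.ndarray]:
        value, grad = nca_objective(wv, X, y, lam, _absdiff=A)
        if not np.isfinite(value):
            raise FloatingPointError(
                f"non-finite NCA objective at step {len(trace)}; trace={trace}"
            )
        return -value, -grad

    def record(wv: np.ndarray) -> None:
        value, _ = nca_objective(wv, X, y, lam, _absdiff=A)
        trace.append(value)

    w0 = np.ones(X.shape[1])
    record(w0)
    res = minimize(
        neg,
        w0,
        jac=True,
        method="L-BFGS-B",
        callback=record,
        options={"maxiter": max_iter, "gtol": gtol},
    )
    return NCAWeights(
        w=np.abs(res.x), lam=lam, objective_trace=trace, converged=bool(res.success)
    )


def _weighted_1nn_predict(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, w: np.ndarray
) -> np.ndarray:
    d = np.abs(X_test[:, None, :] - X_train[None, :, :]) @ (w**2)
    return y_train[np.argmin(d, axis=1)]


def select_lambda(
    X: np.ndarray, y, lambda_grid, n_folds: int = 5, seed: int = 0
) -> float:
    """Pick the regularization by cross-validated 1-NN loss.

    For each lambda, NCA is fitted on each training fold and the held-out
    fold is classified by the nearest neighbor in the weighted-distance
    space; the lambda with minimum mean error wins, ties going to the
    smaller value.
    """
    lambda_grid = sorted(float(l) for l in lambda_grid)
    if not lambda_grid:
        raise ValueError("lambda grid is empty")
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(lambda_grid) == 1:
        return lambda_grid[0]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best_lam, best_loss = lambda_grid[0], np.inf
    for lam in lambda_grid:
        losses = []
        for tr, te in folds:
            w = fit_nca(X[tr], y[tr], lam).w
            pred = _weighted_1nn_predict(X[tr], y[tr], X[te], w)
            losses.append(float(np.mean(pred != y[te])))
        mean_loss = float(np.mean(losses))
        if mean_loss < best_loss:  # strict: ties keep the smaller lambda
            best_lam, best_loss = lam, mean_loss
    return best_lam


def selection_frequency(
    feature_matrix: FeatureMatrix,
    scheme: SplitScheme,
    lambda_policy=0.01,
    threshold_fraction: float = 0.3,
) -> tuple[np.ndarray, int]:
    """How often each feature is selected across training resamples.

    Per iteration NCA is fitted on the standardized training split (with
    lambda either fixed or chosen by a callable ``(X, y, seed) -> lambda``)
    and features with weight above ``threshold_fraction * max(weight)`` are
    marked.  Returns per-feature selection frequencies in [0, 1] and the
    number of iterations skipped due to fit failures.
    """
    splits = make_splits(feature_matrix.subject_table(), scheme)
    idx_of = {s: i for i, s in enumerate(feature_matrix.subject_ids)}
    y = feature_matrix.labels_array()
    marks = np.zeros(feature_matrix.n_features)
    n_ok = 0
    n_failed = 0
    for it, (train_ids, _) in enumerate(splits):
        tr = [idx_of[s] for s in train_ids]
        Xt = feature_matrix.values[tr]
        mu, sd = Xt.mean(axis=0), Xt.std(axis=0)
        sd[sd == 0] = 1.0
        Xt = (Xt - mu) / sd
        lam = (
            lambda_policy(Xt, y[tr], it)
            if callable(lambda_policy)
            else float(lambda_policy)
        )
        try:
            w = fit_nca(Xt, y[tr], lam).w
        except FloatingPointError as exc:
            logger.warning("NCA fit failed in iteration %d: %s", it, exc)
            n_failed += 1
            continue
        if w.max() > 0:
            marks += w > threshold_fraction * w.max()
        n_ok += 1
    if n_ok == 0:
        raise RuntimeError("no successful NCA fit across iterations")
    return marks / n_ok, n_failed


def f1_vs_topk(
    feature_matrix: FeatureMatrix,
    ranked_features: list[str],
    scheme: SplitScheme,
    config: SVMConfig | None = None,
    k_grid=None,
) -> dict:
    """Per-class F1 as a function of the number of top-ranked features.

    For each k the full ensemble is re-run (same split scheme, hence same
    seeds) on the k most important features.  Returns the k grid, one F1
    curve per class and the smallest argmax-k per class.  k values beyond
    the feature count are truncated with a notice.
    """
    avail = [f for f in ranked_features if f in feature_matrix.feature_names]
    if k_grid is None:
        k_grid = list(range(1, len(avail) + 1))
    ks = []
    for k in k_grid:
        if k > len(avail):
            logger.info("k=%d exceeds %d ranked features; truncated", k, len(avail))
            k = len(avail)
        if k not in ks:
            ks.append(k)
    curves: dict[str, list[float]] = {}
    classes = None
    for k in ks:
        sub = feature_matrix.select_features(avail[:k])
        result = run_ensemble(sub, scheme, config)
        truth = dict(zip(sub.subject_ids, sub.class_labels))
        tested = result.tested_ids()
        cm = confusion(
            [truth[s] for s in tested],
            [result.final_labels[s] for s in tested],
            result.class_order,
        )
        report = per_class_metrics(cm)
        if classes is None:
            classes = list(report.per_class)
            curves = {c: [] for c in classes}
        for c in classes:
            curves[c].append(report.per_class[c]["f1"])
    argmax_k = {c: ks[int(np.argmax(curves[c]))] for c in curves}
    return {"k": ks, "f1": {c: np.asarray(v) for c, v in curves.items()}, "argmax_k": argmax_k}


# ---------------------------------------------------------------------------
# Shapley values
# ---------------------------------------------------------------------------


@dataclass
class ShapleyValues:
    """Attributions for one subject: phi is (features, classes)."""

    phi: np.ndarray
    se: np.ndarray | None
    feature_names: list[str]
    class_order: tuple[str, ...]
    meta: dict = field(default_factory=dict)


@dataclass
class ShapleyTable:
    """Stacked attributions: phi is (subjects, features, classes)."""

    phi: np.ndarray
    subject_ids: list[str]
    run_ids: np.ndarray
    feature_names: list[str]
    class_order: tuple[str, ...]
    meta: dict = field(default_factory=dict)


@dataclass
class ImportanceMap:
    """Per-class per-ROI mean absolute Shapley value (all values >= 0)."""

    values: dict[str, np.ndarray]  # class -> per-feature importance
    feature_names: list[str]

    def to_volumes(self, atlas: Atlas) -> dict[str, np.ndarray]:
        """Paint each class's importance onto the atlas parcels."""
        name_to_id = {v: k for k, v in atlas.label_table.items()}
        out = {}
        for cls, vals in self.values.items():
            grid = np.zeros(atlas.labels.shape, dtype=float)
            for fname, val in zip(self.feature_names, vals):
                if fname not in name_to_id:
                    continue
                grid[atlas.parcel_mask(name_to_id[fname])] = val
            out[cls] = grid
        return out


def shapley_linear_exact(model_or_coeffs, x, reference_means) -> np.ndarray:
    """Closed-form Shapley values for a linear per-class score.

    When the score is ``f_k(x) = w_k . x + b_k`` and absent features are
    replaced by independent background expectations, the Shapley value of
    feature j for class k is ``w_kj * (x_j - reference_mean_j)`` and the
    efficiency identity holds exactly.  Accepts either a coefficient pair
    ``(W, b)`` (K x d and K) or a fitted model exposing
    ``linear_class_coefficients()``.  Returns phi with shape (d, K).
    """
    if hasattr(model_or_coeffs, "linear_class_coefficients"):
        W, _ = model_or_coeffs.linear_class_coefficients()
    else:
        W = np.asarray(model_or_coeffs[0], dtype=float)
    x = np.asarray(x, dtype=float)
    ref = np.asarray(reference_means, dtype=float)
    return (W * (x - ref)[None, :]).T  # (d, K)


def _conditional_gaussian_draws(
    rng: np.random.Generator,
    x: np.ndarray,
    present: np.ndarray,
    mu: np.ndarray,
    cov: np.ndarray,
    n_draws: int,
) -> np.ndarray:
    """Draw absent features from N(mu, cov) conditional on the present ones."""
    d = len(x)
    absent = ~present
    out = np.tile(x, (n_draws, 1))
    if not absent.any():
        return out
    if not present.any():
        out[:, absent] = rng.multivariate_normal(
            mu[absent], cov[np.ix_(absent, absent)], size=n_draws, method="svd"
        )
        return out
    c_ss = cov[np.ix_(present, present)]
    c_as = cov[np.ix_(absent, present)]
    c_aa = cov[np.ix_(absent, absent)]
    sol = np.linalg.solve(c_ss, (x[present] - mu[present]))
    cond_mu = mu[absent] + c_as @ sol
    cond_cov = c_aa - c_as @ np.linalg.solve(c_ss, c_as.T)
    cond_cov = (cond_cov + cond_cov.T) / 2.0
    out[:, absent] = rng.multivariate_normal(cond_mu, cond_cov, size=n_draws, method="svd")
    return out


def shapley_sampling(
    score_fn,
    x,
    background,
    n_samples: int = 200,
    seed: int = 0,
    dependent: bool = False,
    n_draws: int = 30,
) -> ShapleyValues:
    """Monte-Carlo Shapley attribution over random feature orderings.

    ``score_fn`` maps an (m, d) array to (m, K) per-class scores.  Each of
    ``n_samples`` random orderings contributes one marginal-contribution
    estimate per feature: features before j in the ordering take the
    explained subject's values, the rest are imputed from ``background`` —
    the full background sample in independent mode, or ``n_draws`` draws
    from the Gaussian conditional on the present features (background
    mean/covariance, ridge-regularized if singular) in dependent mode.
    The estimate is unbiased for the marginal-expectation Shapley value and
    the per-feature Monte-Carlo SE is reported.
    """
    x = np.asarray(x, dtype=float)
    background = np.asarray(background, dtype=float)
    d = x.shape[0]
    rng = np.random.default_rng(seed)

    mu = background.mean(axis=0)
    cov = None
    if dependent:
        cov = np.cov(background, rowvar=False)
        cov = np.atleast_2d(cov)
        if np.linalg.matrix_rank(cov) < d:
            ridge = 1e-6 * max(np.trace(cov) / d, 1.0)
            logger.warning(
                "singular background covariance; ridge-regularizing with %.2e", ridge
            )
            cov = cov + ridge * np.eye(d)

    def coalition_value(present: np.ndarray) -> np.ndarray:
        if dependent:
            draws = _conditional_gaussian_draws(rng, x, present, mu, cov, n_draws)
        else:
            draws = background.copy()
            draws[:, present] = x[present]
        return score_fn(draws).mean(axis=0)

    n_classes = np.atleast_2d(score_fn(x[None, :])).shape[1]
    contribs = np.zeros((n_samples, d, n_classes))
    for s in range(n_samples):
        order = rng.permutation(d)
        present = np.zeros(d, dtype=bool)
        v_prev = coalition_value(present)
        for j in order:
            present[j] = True
            v_next = coalition_value(present)
            contribs[s, j] = v_next - v_prev
            v_prev = v_next
    phi = contribs.mean(axis=0)
    se = contribs.std(axis=0, ddof=1) / np.sqrt(n_samples)
    return ShapleyValues(
        phi=phi,
        se=se,
        feature_names=[f"x{j}" for j in range(d)],
        class_order=tuple(str(k) for k in range(n_classes)),
        meta={
            "method": "permutation-sampling",
            "n_samples": n_samples,
            "seed": seed,
            "dependent": dependent,
        },
    )


def shapley_table_linear(
    feature_matrix: FeatureMatrix,
    scheme: SplitScheme,
    config: SVMConfig | None = None,
    n_runs: int = 10,
) -> ShapleyTable:
    """Exact linear Shapley values of training subjects across resamples.

    For each of the first ``n_runs`` splits of the scheme, the multi-class
    model is refitted on the training subjects and every training subject's
    per-class margin is attributed with the closed form, using the training
    mean as the reference (the background of the same run).
    """
    splits = make_splits(feature_matrix.subject_table(), scheme)[:n_runs]
    idx_of = {s: i for i, s in enumerate(feature_matrix.subject_ids)}
    y = feature_matrix.labels_array()
    phis, sids, runs = [], [], []
    class_order = None
    for run, (train_ids, _) in enumerate(splits):
        tr = [idx_of[s] for s in train_ids]
        X = feature_matrix.values[tr]
        model = train_multiclass_linear(X, y[tr], config)
        class_order = tuple(model.classes_)
        ref = X.mean(axis=0)
        for sid, row in zip(train_ids, X):
            phis.append(shapley_linear_exact(model, row, ref))
            sids.append(sid)
            runs.append(run)
    return ShapleyTable(
        phi=np.stack(phis),
        subject_ids=sids,
        run_ids=np.asarray(runs),
        feature_names=list(feature_matrix.feature_names),
        class_order=class_order,
        meta={"method": "linear-exact", "n_runs": len(splits)},
    )


def class_importance_map(
    shapley_table: ShapleyTable, subject_table, atlas: Atlas | None = None
) -> ImportanceMap:
    """Group-mean absolute Shapley value per feature, per class.

    For each class the mean of |phi| is taken over all (run, subject)
    entries whose *true* label is that class.  A class with no subjects
    yields a zero map with a logged notice.  The atlas argument is kept for
    call-site symmetry with map painting (see ``ImportanceMap.to_volumes``).
    """
    truth = dict(zip(subject_table["id"], subject_table["class"]))
    labels = np.asarray([truth[s] for s in shapley_table.subject_ids])
    values: dict[str, np.ndarray] = {}
    for k, cls in enumerate(shapley_table.class_order):
        sel = labels == cls
        if not sel.any():
            logger.info("class %s has no subjects; importance map is zero", cls)
            values[cls] = np.zeros(len(shapley_table.feature_names))
            continue
        values[cls] = np.abs(shapley_table.phi[sel, :, k]).mean(axis=0)
    return ImportanceMap(values=values, feature_names=list(shapley_table.feature_names))
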