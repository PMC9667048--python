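"""Metabolic brain patterns: SSM/PCA derivation and topographic profile rating.

The scaled subprofile model (SSM) removes subject- and group-level offsets
from log-transformed scans before PCA:

* log transform every masked scan,
* subtract each subject's own mean (row centering) — this removes the
  per-subject global-uptake factor, since a multiplicative scale becomes an
  additive log offset,
* subtract the group mean profile (GMP, column centering).

The residuals (subject residual profiles, SRP) are decomposed by PCA in
subject space; a pattern is a voxel-weight vector built from the principal
component(s) whose subject scores best separate the disease group from the
controls.  A new scan is scored prospectively by topographic profile rating
(TPR): the dot product of its own residual profile (against the stored GMP)
with the pattern weights, Z-transformed against the score mean/SD of the
control subjects of the derivation cohort.  By construction the score is
invariant to global intensity scaling of the input scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from petdx.preprocess import Volume
from petdx.roifeat import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PatternConfig",
    "SRPMatrix",
    "MetabolicPattern",
    "PatternScore",
    "log_transform",
    "double_center",
    "derive_pattern",
    "tpr_score",
    "pattern_feature_matrix",
]


@dataclass
class PatternConfig:
    """Settings for pattern derivation.

    ``var_threshold`` limits the candidate components to the leading ones
    that jointly explain at least this fraction of SRP variance.  ``mode``
    selects either the single candidate whose subject scores best separate
    the groups by two-sample t statistic (``"best_t"``, the default) or a
    logistic-regression-weighted combination of all candidates
    (``"logistic"``).
    """

    var_threshold: float = 0.5
    mode: str = "best_t"

    def __post_init__(self) -> None:
        if not 0 < self.var_threshold <= 1:
            raise ValueError("var_threshold must be in (0, 1]")
        if self.mode not in ("best_t", "logistic"):
            raise ValueError(f"unknown derivation mode {self.mode!r}")


@dataclass
class SRPMatrix:
    """Subjects x masked-voxels matrix of subject residual profiles."""

    values: np.ndarray
    subject_ids: list[str]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("SRP values must be 2-D")


@dataclass
class MetabolicPattern:
    """A voxel-weight pattern with everything needed for single-case scoring.

    ``weights`` and ``gmp`` (group mean log profile) are vectors over the
    in-mask voxels in C scan order; ``nc_score_mean``/``nc_score_sd`` are
    the raw-score statistics of the control derivation subjects used for the
    Z transform.  Sign convention: the positive derivation group's mean
    score exceeds the reference group's.
    """

    name: str
    weights: np.ndarray
    gmp: np.ndarray
    nc_score_mean: float
    nc_score_sd: float
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.gmp = np.asarray(self.gmp, dtype=float)
        if self.weights.shape != self.gmp.shape:
            raise ValueError("weights and gmp must share the voxel index")
        if not self.nc_score_sd > 0:
            raise ValueError("nc_score_sd must be positive")


@dataclass
class PatternScore:
    subject_id: str
    raw_score: float
    z_score: float


def log_transform(volume: Volume) -> np.ndarray:
    """Natural log of the in-mask intensities, in voxel-index (C) order.

    Raises on any non-positive in-mask voxel rather than clamping silently;
    preprocessing floors intensities, so a zero here indicates a volume that
    skipped the chain.
    """
    vals = volume.masked_values()
    if np.any(vals <= 0):
        bad = int(np.sum(vals <= 0))
        raise ValueError(f"{bad} non-positive voxel(s) inside the mask")
    return np.log(vals)


def double_center(log_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-center then column-center a subjects x voxels log matrix.

    Returns the residual (SRP) matrix and the group mean profile (the
    column means removed after row centering).  Rows and columns of the
    result sum to ~0.
    """
    log_matrix = np.asarray(log_matrix, dtype=float)
    if log_matrix.ndim != 2 or log_matrix.shape[0] < 2 or log_matrix.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 voxels")
    row_centered = log_matrix - log_matrix.mean(axis=1, keepdims=True)
    gmp = row_centered.mean(axis=0)
    return row_centered - gmp, gmp


def _log_matrix(volumes: list[Volume]) -> np.ndarray:
    return np.stack([log_transform(v) for v in volumes])


def derive_pattern(
    disease_volumes: list[Volume],
    nc_volumes: list[Volume],
    config: PatternConfig | None = None,
    name: str = "pattern",
    positive_group: str = "disease",
) -> MetabolicPattern:
    """Derive a metabolic pattern from a two-group identification cohort.

    The SRP matrix of the combined cohort is decomposed by SVD in subject
    space (efficient for voxels >> subjects; voxel loadings come from the
    right singular vectors).  Candidates are the leading components jointly
    explaining at least ``config.var_threshold`` of the variance; the
    returned weights are either the single best-discriminating candidate or
    a logistic combination of all candidates.  The sign is fixed so the
    ``positive_group`` ("disease" or "nc") has the higher mean score, and
    the control group's raw-score mean/SD are stored for the Z transform.
    """
    config = config or PatternConfig()
    if len(disease_volumes) < 3 or len(nc_volumes) < 3:
        raise ValueError("need at least 3 subjects in each derivation group")
    if positive_group not in ("disease", "nc"):
        raise ValueError("positive_group must be 'disease' or 'nc'")
    mask = disease_volumes[0].mask
    for v in disease_volumes + nc_volumes:
        if not np.array_equal(v.mask, mask):
            raise ValueError("all derivation volumes must share one mask")

    log_mat = _log_matrix(disease_volumes + nc_volumes)
    srp, gmp = double_center(log_mat)
    if not np.any(np.abs(srp) > 1e-12):
        raise ValueError("degenerate SRP matrix (all residuals zero)")

    n_dis = len(disease_volumes)
    u, sv, vt = np.linalg.svd(srp, full_matrices=False)
    var = sv**2
    var_frac = var / var.sum()
    n_cand = int(np.searchsorted(np.cumsum(var_frac), config.var_threshold) + 1)
    n_cand = min(n_cand, len(sv))
    scores = u * sv  # subject scores, one column per component
    is_dis = np.zeros(len(log_mat), dtype=bool)
    is_dis[:n_dis] = True

    def welch_t(col: np.ndarray) -> float:
        a, b = col[is_dis], col[~is_dis]
        se2 = a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)
        return (a.mean() - b.mean()) / np.sqrt(se2) if se2 > 0 else 0.0

    if config.mode == "best_t":
        tstats = [welch_t(scores[:, k]) for k in range(n_cand)]
        best = int(np.argmax(np.abs(tstats)))
        weights = vt[best].copy()
        subj_scores = scores[:, best].copy()
        meta_components = [best]
    else:
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(max_iter=1000)
        clf.fit(scores[:, :n_cand], is_dis.astype(int))
        coef = clf.coef_[0]
        weights = coef @ vt[:n_cand]
        norm = np.linalg.norm(weights)
        if norm == 0:
            raise ValueError("logistic combination produced a zero pattern")
        weights = weights / norm
        subj_scores = srp @ weights
        meta_components = list(range(n_cand))

    pos = is_dis if positive_group == "disease" else ~is_dis
    if subj_scores[pos].mean() <= subj_scores[~pos].mean():
        weights = -weights
        subj_scores = -subj_scores

    nc_scores = subj_scores[~is_dis]
    nc_sd = float(nc_scores.std(ddof=1))
    if not nc_sd > 0:
        raise ValueError("control derivation scores are constant; cannot Z-transform")
    return MetabolicPattern(
        name=name,
        weights=weights,
        gmp=gmp,
        nc_score_mean=float(nc_scores.mean()),
        nc_score_sd=nc_sd,
        mask=mask,
        meta={
            "components": meta_components,
            "variance_explained": [float(var_frac[k]) for k in meta_components],
            "n_candidates": n_cand,
            "mode": config.mode,
            "positive_group": positive_group,
        },
    )


def tpr_score(volume: Volume, pattern: MetabolicPattern) -> PatternScore:
    """Topographic profile rating of a single scan against a pattern.

    The scan's residual profile (log vector minus its own mean minus the
    stored GMP) is projected onto the pattern weights; the raw score is
    Z-transformed with the stored control statistics.  Multiplying the scan
    by any positive constant leaves the score unchanged.
    """
    if not np.array_equal(volume.mask, pattern.mask):
        raise ValueError("volume mask does not match the pattern's voxel index")
    log_vec = log_transform(volume)
    srp = log_vec - log_vec.mean() - pattern.gmp
    raw = float(srp @ pattern.weights)
    z = (raw - pattern.nc_score_mean) / pattern.nc_score_sd
    return PatternScore(subject_id="", raw_score=raw, z_score=float(z))


def pattern_feature_matrix(
    volumes: list[Volume],
    patterns: list[MetabolicPattern],
    subject_table: pd.DataFrame,
) -> FeatureMatrix:
    """Score every subject on every pattern and assemble the feature matrix.

    Columns follow the pattern list order and carry the pattern names;
    class labels and leakage flags come from the subject table (columns
    ``id, class, leakage``).  Any scoring failure aborts with the subject id.
    """
    if not patterns:
        raise ValueError("need at least one pattern")
    if len(volumes) != len(subject_table):
        raise ValueError("one volume per subject-table row required")
    ids = subject_table["id"].tolist()
    values = np.empty((len(volumes), len(patterns)), dtype=float)
    for i, (sid, vol) in enumerate(zip(ids, volumes)):
        for j, pat in enumerate(patterns):
            try:
                values[i, j] = tpr_score(vol, pat).z_score
            except Exception as exc:  # noqa: BLE001 - reported with subject id
                raise RuntimeError(f"scoring failed for subject {sid}: {exc}") from exc
    return FeatureMatrix(
        values=values,
        feature_names=[p.name for p in patterns],
        subject_ids=ids,
        class_labels=subject_table["class"].tolist(),
        leakage_flags=subject_table["leakage"].to_numpy(dtype=bool),
    )
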