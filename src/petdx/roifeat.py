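"""Atlas-ROI uptake features: globally normalized mean uptake per parcel.

The second feature set of the classifier: after global-uptake scaling every
scan has masked mean 1, so the mean intensity of an atlas parcel is an
SUVR-like uptake ratio (region relative to whole brain).  Composite ROIs —
e.g. pooling bilateral structures into one region — are voxel-count-weighted
means of their member parcels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from petdx.labels import CLASS_ORDER
from petdx.preprocess import Atlas, Volume

__all__ = ["FeatureMatrix", "roi_means", "merge_rois", "roi_feature_matrix"]


@dataclass
class FeatureMatrix:
    """Subjects x named features with class labels and leakage flags.

    The classifier consumes either four pattern-expression Z-scores or K
    ROI uptake ratios through this one container.  ``leakage_flags`` marks
    subjects used for pattern identification, which must never appear in a
    classifier test set.
    """

    values: np.ndarray
    feature_names: list[str]
    subject_ids: list[str]
    class_labels: list[str]
    leakage_flags: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_names = list(self.feature_names)
        self.subject_ids = list(self.subject_ids)
        self.class_labels = list(self.class_labels)
        self.leakage_flags = np.asarray(self.leakage_flags, dtype=bool)
        n, d = self.values.shape
        if len(self.feature_names) != d:
            raise ValueError("feature_names length mismatch")
        if len(set(self.feature_names)) != d:
            raise ValueError("feature names must be unique")
        if len(self.subject_ids) != n or len(self.class_labels) != n:
            raise ValueError("subject metadata length mismatch")
        if len(self.leakage_flags) != n:
            raise ValueError("leakage_flags length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains missing/non-finite values")
        unknown = set(self.class_labels) - set(CLASS_ORDER)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def labels_array(self) -> np.ndarray:
        return np.asarray(self.class_labels)

    def select_features(self, names: list[str]) -> "FeatureMatrix":
        """Restrict to the given features, preserving the given order."""
        idx = [self.feature_names.index(n) for n in names]
        return replace(
            self, values=self.values[:, idx], feature_names=[self.feature_names[i] for i in idx]
        )

    def subject_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.subject_ids,
                "class": self.class_labels,
                "leakage": self.leakage_flags,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        df = self.subject_table()
        for j, name in enumerate(self.feature_names):
            df[name] = self.values[:, j]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        meta = ["id", "class", "leakage"]
        feats = [c for c in df.columns if c not in meta and c != "seed"]
        return cls(
            values=df[feats].to_numpy(dtype=float),
            feature_names=feats,
            subject_ids=df["id"].astype(str).tolist(),
            class_labels=df["class"].tolist(),
            leakage_flags=df["leakage"].to_numpy(dtype=bool),
        )


def roi_means(volume: Volume, atlas: Atlas) -> np.ndarray:
    """Mean in-mask intensity per ROI, in label-table order.

    Parcels are restricted to the volume's brain mask before averaging;
    out-of-mask atlas voxels are ignored.  On a globally scaled volume
    (masked mean 1) these are uptake ratios.  The operation is linear in
    intensity.  A parcel with no in-mask voxels raises, naming the label.
    """
    if volume.data.shape != atlas.labels.shape:
        raise ValueError("volume and atlas grids do not match")
    base_mean: dict[int, float] = {}
    base_count: dict[int, int] = {}
    for roi in atlas.base_ids():
        sel = (atlas.labels == roi) & volume.mask
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"ROI {roi} ({atlas.label_table[roi]}) has no in-mask voxels")
        base_mean[roi] = float(volume.data[sel].mean())
        base_count[roi] = n
    out = []
    for roi in atlas.roi_ids:
        if roi in atlas.composites:
            members = atlas.composites[roi]
            total = sum(base_count[m] for m in members)
            out.append(sum(base_count[m] * base_mean[m] for m in members) / total)
        else:
            out.append(base_mean[roi])
    return np.asarray(out)


def merge_rois(atlas: Atlas, merge_spec: dict[int, tuple[int, ...]]) -> Atlas:
    """Add composite ROIs (disjoint unions of existing parcels) to an atlas.

    ``merge_spec`` maps each new id to the member ids it pools; member sets
    must be disjoint across new ids and the new ids must be unused.  The
    label grid is unchanged; composites only extend the label table, and
    their means are voxel-count-weighted means of the members.
    """
    if not merge_spec:
        return atlas
    base = set(atlas.base_ids())
    seen: set[int] = set()
    table = dict(atlas.label_table)
    composites = dict(atlas.composites)
    for new_id, members in merge_spec.items():
        members = tuple(int(m) for m in members)
        if new_id in table:
            raise ValueError(f"composite id {new_id} already exists")
        missing = [m for m in members if m not in base]
        if missing:
            raise ValueError(f"composite {new_id} references unknown ROIs {missing}")
        overlap = seen.intersection(members)
        if overlap:
            raise ValueError(f"overlapping member sets: ROIs {sorted(overlap)} reused")
        seen.update(members)
        member_names = "+".join(atlas.label_table[m] for m in members)
        table[new_id] = f"composite({member_names})"
        composites[new_id] = members
    return Atlas(
        labels=atlas.labels,
        label_table=table,
        spacing_mm=atlas.spacing_mm,
        composites=composites,
    )


def roi_feature_matrix(
    volumes: list[Volume], atlas: Atlas, subject_table: pd.DataFrame
) -> FeatureMatrix:
    """Stack per-subject ROI uptake vectors into a feature matrix.

    Labels and leakage flags come from the subject table (columns
    ``id, class, leakage``).  A grid mismatch aborts naming the subject.
    """
    if len(volumes) != len(subject_table):
        raise ValueError("one volume per subject-table row required")
    ids = subject_table["id"].tolist()
    rows = []
    for sid, vol in zip(ids, volumes):
        try:
            rows.append(roi_means(vol, atlas))
        except ValueError as exc:
            raise ValueError(f"subject {sid}: {exc}") from exc
    return FeatureMatrix(
        values=np.stack(rows),
        feature_names=[atlas.label_table[r] for r in atlas.roi_ids],
        subject_ids=ids,
        class_labels=subject_table["class"].tolist(),
        leakage_flags=subject_table["leakage"].to_numpy(dtype=bool),
    )
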