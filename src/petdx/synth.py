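"""Synthetic four-class FDG-PET cohorts with known ground truth.

Real dementia FDG-PET cohorts cannot be redistributed, so every downstream
stage of the pipeline is exercised on simulated data in which the "disease"
is planted explicitly: each diagnostic class carries a topography — a set of
atlas ROIs whose mean uptake is reduced by a known fraction — on top of a
smooth baseline uptake field, per-subject global-uptake scaling and iid
voxel noise.  Controls (NC) carry no regional effect.

The generator is fully deterministic given the cohort seed, and with all
noise sources switched off the planted ROI uptake ratios are recovered
exactly, which the test-suite uses as a closed-form oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from petdx.labels import CLASS_ORDER
from petdx.preprocess import Atlas, Volume

__all__ = [
    "ClassTopography",
    "SyntheticCohortSpec",
    "default_topographies",
    "default_cohort_spec",
    "make_toy_atlas",
    "simulate_cohort",
]


@dataclass
class ClassTopography:
    """The regional hypometabolism planted for one diagnostic class.

    ``hypometabolism_fraction`` is the mean relative uptake reduction in the
    affected ROIs (0.25 = 25 % lower than baseline); ``variability`` is the
    between-subject SD of that reduction.  The NC class must be effect-free.
    """

    class_label: str
    affected_rois: tuple[int, ...] = ()
    hypometabolism_fraction: float = 0.0
    variability: float = 0.0

    def __post_init__(self) -> None:
        self.affected_rois = tuple(int(r) for r in self.affected_rois)
        if not 0.0 <= self.hypometabolism_fraction < 1.0:
            raise ValueError("hypometabolism_fraction must lie in [0, 1)")
        if self.variability < 0:
            raise ValueError("variability must be >= 0")
        if self.class_label == "NC" and self.affected_rois:
            raise ValueError("NC topography must have no affected ROIs")


@dataclass
class SyntheticCohortSpec:
    """Cohort-level simulation settings.

    Defaults mirror the study conditions the pipeline is meant to emulate:
    63 AD, 79 DLB, 23 FTD and 41 NC scans (206 in total) on a common grid.
    ``global_scale_sd`` is the SD of the log-normal per-subject global
    uptake factor; ``noise_sd`` the SD of additive iid voxel noise.
    """

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"AD": 63, "DLB": 79, "FTD": 23, "NC": 41}
    )
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_rois: int = 8
    global_scale_sd: float = 0.15
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_class.values()):
            raise ValueError("class counts must be >= 0")
        if self.n_rois < 4:
            raise ValueError("need at least 4 ROIs")
        if self.global_scale_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise levels must be >= 0")

    @property
    def n_subjects(self) -> int:
        return sum(self.n_per_class.values())


def default_topographies(
    hypometabolism_fraction: float = 0.25, variability: float = 0.05
) -> list[ClassTopography]:
    """Planted disease topographies on the default 8-ROI toy atlas.

    Each dementia class hypometabolizes a disjoint pair of parcels; NC has
    no regional effect.  A 25 % mean reduction with 5 % between-subject SD
    gives clearly separable but overlapping class distributions once global
    scaling and voxel noise are added.
    """
    return [
        ClassTopography("AD", (1, 2), hypometabolism_fraction, variability),
        ClassTopography("DLB", (3, 4), hypometabolism_fraction, variability),
        ClassTopography("FTD", (5, 6), hypometabolism_fraction, variability),
        ClassTopography("NC"),
    ]


def default_cohort_spec(seed: int = 0) -> SyntheticCohortSpec:
    return SyntheticCohortSpec(seed=seed)


def _ellipsoid_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal 'brain' mask with semi-axes at 42 % of each grid extent."""
    center = [(n - 1) / 2.0 for n in grid_shape]
    semi = [0.42 * n for n in grid_shape]
    axes = np.ogrid[tuple(slice(0, n) for n in grid_shape)]
    r2 = sum(((ax - c) / a) ** 2 for ax, c, a in zip(axes, center, semi))
    return r2 <= 1.0


def make_toy_atlas(
    grid_shape: tuple[int, int, int],
    n_rois: int,
    seed: int,
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> Atlas:
    """Build a toy parcellation: a Voronoi tessellation of the brain mask.

    ``n_rois`` interior seed voxels are drawn at random and every in-mask
    voxel is assigned to its nearest seed (physical distance).  Because
    Voronoi cells are convex and the mask is an ellipsoid, every parcel is
    non-empty (it contains its own seed) and connected, and the parcels
    partition the mask exactly.
    """
    if n_rois < 4:
        raise ValueError(f"need n_rois >= 4, got {n_rois}")
    mask = _ellipsoid_mask(tuple(grid_shape))
    coords = np.argwhere(mask)
    if len(coords) < n_rois:
        raise ValueError(
            f"grid {tuple(grid_shape)} has only {len(coords)} in-mask voxels, "
            f"cannot host {n_rois} parcels"
        )
    rng = np.random.default_rng(seed)
    seed_idx = rng.choice(len(coords), size=n_rois, replace=False)
    seeds = coords[seed_idx].astype(float)
    scale = np.asarray(spacing_mm, dtype=float)
    d2 = (((coords[:, None, :] - seeds[None, :, :]) * scale) ** 2).sum(axis=2)
    assignment = np.argmin(d2, axis=1) + 1
    labels = np.zeros(tuple(grid_shape), dtype=np.int32)
    labels[tuple(coords.T)] = assignment
    label_table = {i: f"roi_{i:02d}" for i in range(1, n_rois + 1)}
    return Atlas(labels=labels, label_table=label_table, spacing_mm=spacing_mm)


def _baseline_field(atlas: Atlas) -> np.ndarray:
    """Smooth radial uptake baseline, higher centrally (gray-matter-like)."""
    shape = atlas.labels.shape
    center = [(n - 1) / 2.0 for n in shape]
    semi = [0.42 * n for n in shape]
    axes = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((ax - c) / a) ** 2 for ax, c, a in zip(axes, center, semi))
    return 1.0 + 0.4 * np.clip(1.0 - r2, 0.0, None)


def simulate_cohort(
    spec: SyntheticCohortSpec,
    topographies: list[ClassTopography],
    atlas: Atlas,
    leakage_per_class: dict[str, int] | None = None,
) -> tuple[list[Volume], pd.DataFrame]:
    """Simulate one cohort of subject volumes plus its subject table.

    Each subject's volume is::

        baseline(x) * roi_multiplier(x) * global_scale + voxel_noise(x)

    where ``roi_multiplier`` is 1 everywhere except in the subject's class
    topography, where it is ``1 - fraction + N(0, variability)``;
    ``global_scale`` is log-normal with log-SD ``spec.global_scale_sd`` (so
    intensities stay positive); voxel noise is iid Gaussian, and the result
    is floored at 1e-6 inside the mask so the downstream log transform is
    always defined.

    ``leakage_per_class`` flags the first *k* subjects of each class as
    pattern-derivation subjects (``leakage=True`` in the table); they are
    the ones later barred from classifier test sets.

    Returns the volumes and a table with columns ``id, class, leakage, seed``.
    """
    topo_by_class = {t.class_label: t for t in topographies}
    base_ids = set(atlas.base_ids())
    for topo in topographies:
        unknown = [r for r in topo.affected_rois if r not in base_ids]
        if unknown:
            raise ValueError(
                f"topography for {topo.class_label} refers to unknown ROI ids {unknown}"
            )
    leakage_per_class = leakage_per_class or {}

    mask = atlas.mask
    baseline = _baseline_field(atlas)
    rng = np.random.default_rng(spec.seed)
    roi_voxels = {r: atlas.labels == r for r in base_ids}

    volumes: list[Volume] = []
    rows: list[dict] = []
    for cls in CLASS_ORDER:
        n = spec.n_per_class.get(cls, 0)
        if n == 0:
            continue
        if cls not in topo_by_class:
            raise ValueError(f"no topography given for class {cls}")
        topo = topo_by_class[cls]
        n_leak = leakage_per_class.get(cls, 0)
        for k in range(n):
            mult = np.ones_like(baseline)
            for roi in topo.affected_rois:
                reduction = topo.hypometabolism_fraction + rng.normal(
                    0.0, topo.variability
                )
                mult[roi_voxels[roi]] = max(1.0 - reduction, 0.05)
            gscale = float(np.exp(rng.normal(0.0, spec.global_scale_sd)))
            data = baseline * mult * gscale
            if spec.noise_sd > 0:
                data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
            data = np.maximum(data, 1e-6)
            data[~mask] = 0.0
            volumes.append(Volume(data=data, spacing_mm=spec.voxel_size_mm, mask=mask))
            rows.append(
                {
                    "id": f"{cls}_{k:03d}",
                    "class": cls,
                    "leakage": k < n_leak,
                    "seed": spec.seed,
                }
            )
    table = pd.DataFrame(rows, columns=["id", "class", "leakage", "seed"])
    return volumes, table
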