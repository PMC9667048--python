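"""NIfTI and table I/O for volumes, atlases, patterns and feature matrices."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from petdx.preprocess import Atlas, Volume
from petdx.ssmpca import MetabolicPattern

__all__ = [
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "save_atlas",
    "load_atlas",
    "save_pattern",
    "load_pattern",
]


def _affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def _spacing_of(img) -> tuple[float, float, float]:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def save_volume(volume: Volume, path) -> None:
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.spacing_mm)), str(path))


def save_mask(mask: np.ndarray, spacing_mm, path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), _affine(spacing_mm)), str(path))


def load_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata()) > 0


def load_volume(path, mask_path) -> Volume:
    img = nib.load(str(path))
    return Volume(
        data=np.asarray(img.get_fdata(), dtype=float),
        spacing_mm=_spacing_of(img),
        mask=load_mask(mask_path),
    )


def save_atlas(atlas: Atlas, path, table_path=None) -> None:
    """Write the label grid as NIfTI and the label table (+composites) as TSV."""
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), _affine(atlas.spacing_mm)), str(path))
    if table_path is not None:
        rows = [
            {
                "id": rid,
                "name": name,
                "members": ",".join(map(str, atlas.composites.get(rid, ()))),
            }
            for rid, name in atlas.label_table.items()
        ]
        pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)


def load_atlas(path, table_path) -> Atlas:
    img = nib.load(str(path))
    table = pd.read_csv(table_path, sep="\t", keep_default_na=False)
    label_table = {}
    composites = {}
    for _, row in table.iterrows():
        rid = int(row["id"])
        label_table[rid] = str(row["name"])
        members = str(row.get("members", "") or "")
        if members:
            composites[rid] = tuple(int(m) for m in members.split(","))
    return Atlas(
        labels=np.asarray(img.get_fdata(), dtype=np.int32),
        label_table=label_table,
        spacing_mm=_spacing_of(img),
        composites=composites,
    )


def save_pattern(pattern: MetabolicPattern, directory) -> None:
    """Serialize a pattern: weight + GMP NIfTI volumes and a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spacing = (1.0, 1.0, 1.0)
    for stem, vec in (("weights", pattern.weights), ("gmp", pattern.gmp)):
        grid = np.zeros(pattern.mask.shape, dtype=np.float32)
        grid[pattern.mask] = vec
        nib.save(nib.Nifti1Image(grid, _affine(spacing)), str(directory / f"{stem}.nii"))
    save_mask(pattern.mask, spacing, directory / "mask.nii")
    sidecar = {
        "name": pattern.name,
        "nc_score_mean": pattern.nc_score_mean,
        "nc_score_sd": pattern.nc_score_sd,
        "sign_convention": "positive-group mean score > reference mean",
        "meta": pattern.meta,
    }
    (directory / "pattern.json").write_text(json.dumps(sidecar, indent=2))


def load_pattern(directory) -> MetabolicPattern:
    directory = Path(directory)
    sidecar = json.loads((directory / "pattern.json").read_text())
    mask = load_mask(directory / "mask.nii")
    weights = np.asarray(nib.load(str(directory / "weights.nii")).get_fdata())[mask]
    gmp = np.asarray(nib.load(str(directory / "gmp.nii")).get_fdata())[mask]
    return MetabolicPattern(
        name=sidecar["name"],
        weights=weights,
        gmp=gmp,
        nc_score_mean=sidecar["nc_score_mean"],
        nc_score_sd=sidecar["nc_score_sd"],
        mask=mask,
        meta=sidecar.get("meta", {}),
    )
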