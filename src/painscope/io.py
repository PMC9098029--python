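"""NIfTI and table readers/writers for datasets, parcellations and weight maps.

All volumes are exchanged as ``.nii``/``.nii.gz`` through nibabel; metadata,
label tables and result tables are CSV/TSV through pandas.  Readers never
reorder rows: metadata row *i* always corresponds to volume *i*.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datasets import MaskGeometry, StudyDataset
from .spaces import Parcellation

__all__ = [
    "load_dataset",
    "save_dataset",
    "load_label_image",
    "save_label_image",
    "save_weight_map",
    "load_weight_map",
    "save_mask",
]


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def _load_volumes(images_path) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Return (n, x, y, z) data array, affine and shape from a 4-D file,
    a directory of 3-D files (sorted by name) or an explicit path list."""
    if isinstance(images_path, (list, tuple)):
        paths = [Path(p) for p in images_path]
    else:
        images_path = Path(images_path)
        if images_path.is_dir():
            paths = sorted(p for p in images_path.iterdir()
                           if p.name.endswith((".nii", ".nii.gz")))
        else:
            paths = [images_path]
    vols, affine, shape = [], None, None
    for p in paths:
        img = nib.load(str(p))
        data = np.asarray(img.get_fdata(), float)
        if data.ndim == 3:
            data = data[..., None]
        if data.ndim != 4:
            raise ValueError(f"{p}: expected 3-D or 4-D image, got {data.ndim}-D")
        if affine is None:
            affine, shape = img.affine, data.shape[:3]
        else:
            if data.shape[:3] != shape or not np.allclose(img.affine, affine,
                                                          atol=1e-4):
                raise ValueError(f"{p}: grid/affine mismatch with first image")
        vols.append(np.moveaxis(data, -1, 0))
    return np.concatenate(vols, axis=0), affine, shape


def load_dataset(images_path, metadata_path, mask_path=None,
                 study_id: str | None = None) -> StudyDataset:
    """Load trial-level beta maps plus a metadata table into a StudyDataset.

    ``images_path`` may be one 4-D NIfTI, a directory of 3-D NIfTIs (sorted
    by filename) or a list of paths.  If no mask is given, the in-mask voxel
    set is computed as the voxels that are finite and non-zero in at least
    one volume; an explicit mask with non-finite values inside it is an error.
    """
    data, affine, shape = _load_volumes(images_path)
    meta = _read_table(metadata_path)
    if len(meta) != data.shape[0]:
        raise ValueError(
            f"metadata has {len(meta)} rows but images have {data.shape[0]} "
            f"volumes"
        )
    flat = data.reshape(data.shape[0], -1)
    if mask_path is not None:
        mask_img = nib.load(str(mask_path))
        if mask_img.shape[:3] != shape or not np.allclose(mask_img.affine,
                                                          affine, atol=1e-4):
            raise ValueError("mask grid/affine mismatch with images")
        mask = np.asarray(mask_img.get_fdata()).reshape(-1) > 0
    else:
        finite = np.isfinite(flat).all(axis=0)
        nonzero = np.abs(flat).max(axis=0) > 0
        mask = finite & nonzero
    indices = np.flatnonzero(mask)
    features = flat[:, indices]
    bad = ~np.isfinite(features)
    if bad.any():
        t, v = np.argwhere(bad)[0]
        raise ValueError(
            f"non-finite voxel value at trial {t}, in-mask voxel index {v} "
            f"(flat voxel {indices[v]})"
        )
    if study_id is None:
        study_id = str(meta["study_id"].iloc[0]) if "study_id" in meta else "study"
    geometry = MaskGeometry(tuple(shape), affine, indices)
    meta = meta.drop(columns=[c for c in ("study_id",) if c in meta])
    return StudyDataset(study_id, geometry, features, meta)


def save_dataset(dataset: StudyDataset, images_path, metadata_path) -> None:
    """Write a StudyDataset as one 4-D NIfTI plus a metadata CSV."""
    geo = dataset.geometry
    vol = np.zeros((dataset.n_trials,) + tuple(geo.shape), dtype=np.float32)
    flat = vol.reshape(dataset.n_trials, -1)
    flat[:, geo.indices] = dataset.features
    img = nib.Nifti1Image(np.moveaxis(vol, 0, -1), geo.affine)
    nib.save(img, str(images_path))
    meta = dataset.meta.copy()
    meta.insert(0, "study_id", dataset.study_id)
    meta.to_csv(metadata_path, index=False)


# ----------------------------------------------------------------------
# parcellations


def load_label_image(path, label_table_path) -> Parcellation:
    """Read an integer label image and its label table into a Parcellation.

    The table must have columns ``label`` (integer), ``region``, ``frsn``,
    ``crsn`` and ``pathway`` (0/1 flag for membership in the nociceptive
    pathways set).  An optional ``meta`` 0/1 column marks regions in the
    meta-analytic mask.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    rounded = np.round(data)
    if not np.allclose(data, rounded, atol=1e-6):
        raise ValueError("label image contains non-integer values")
    labels_flat = rounded.astype(int).reshape(-1)
    table = _read_table(label_table_path)
    known = set(table["label"].astype(int))
    present = set(np.unique(labels_flat[labels_flat != 0]).tolist())
    missing = sorted(present - known)
    if missing:
        raise ValueError(f"labels present in image but absent from table: "
                         f"{missing}")
    indices = np.flatnonzero(labels_flat != 0)
    geometry = MaskGeometry(tuple(data.shape[:3]), img.affine, indices)
    voxel_regions = labels_flat[indices]
    table = table.set_index(table["label"].astype(int))
    region_names = table["region"].astype(str).to_dict()
    region_frsn = table["frsn"].astype(str).to_dict()
    frsn_crsn = (table.groupby(table["frsn"].astype(str))["crsn"]
                 .first().astype(str).to_dict())
    pathway = set(table.index[table["pathway"].astype(int) > 0])
    meta_regions = (set(table.index[table["meta"].astype(int) > 0])
                    if "meta" in table else set())
    return Parcellation(
        geometry=geometry,
        voxel_regions=voxel_regions,
        region_names=region_names,
        region_frsn=region_frsn,
        frsn_crsn=frsn_crsn,
        pathway_regions=pathway,
        meta_regions=meta_regions,
    )


def save_label_image(parc: Parcellation, path, label_table_path) -> None:
    """Write a Parcellation as a label NIfTI plus its label table."""
    geo = parc.geometry
    vol = geo.unmask(parc.voxel_regions.astype(float))
    nib.save(nib.Nifti1Image(vol.astype(np.int32), geo.affine), str(path))
    rows = []
    for label in sorted(parc.region_names):
        frsn = parc.region_frsn[label]
        rows.append({
            "label": label,
            "region": parc.region_names[label],
            "frsn": frsn,
            "crsn": parc.frsn_crsn[frsn],
            "pathway": int(label in parc.pathway_regions),
            "meta": int(label in parc.meta_regions),
        })
    pd.DataFrame(rows).to_csv(label_table_path, index=False)


# ----------------------------------------------------------------------
# weight maps and masks


def save_weight_map(weights: np.ndarray, geometry: MaskGeometry, path,
                    sidecar: dict | None = None) -> None:
    """Write a voxel-weight vector as a NIfTI (zeros outside the mask)."""
    weights = np.asarray(weights, float)
    if weights.shape != (geometry.n_voxels,):
        raise ValueError(
            f"weight vector has length {weights.shape}, mask has "
            f"{geometry.n_voxels} voxels"
        )
    nib.save(nib.Nifti1Image(geometry.unmask(weights), geometry.affine),
             str(path))
    if sidecar is not None:
        with open(os.fspath(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2, default=float)


def load_weight_map(path, geometry: MaskGeometry) -> np.ndarray:
    """Read a weight NIfTI back into a length-V vector over the mask."""
    img = nib.load(str(path))
    if img.shape[:3] != tuple(geometry.shape):
        raise ValueError("weight map grid mismatch")
    return np.asarray(img.get_fdata()).reshape(-1)[geometry.indices]


def save_mask(indices_or_bool: np.ndarray, geometry: MaskGeometry, path) -> None:
    """Write a voxel subset (bool over mask, or flat in-mask indices) as NIfTI."""
    arr = np.asarray(indices_or_bool)
    vec = np.zeros(geometry.n_voxels)
    if arr.dtype == bool:
        vec[arr] = 1.0
    else:
        vec[arr.astype(int)] = 1.0
    nib.save(nib.Nifti1Image(geometry.unmask(vec), geometry.affine), str(path))
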