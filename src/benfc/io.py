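"""Readers and writers for the standard formats the pipeline touches.

NIfTI-1 for all volumes (via nibabel), TSV for motion / clinical / expression
/ edge-list tables, JSON for result manifests. All round-trips are lossless
up to the declared storage precision (float32 for 4D BOLD, float64 for maps).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import (
    Bold4D,
    BrainMask,
    ClinicalTable,
    ExpressionMatrix,
    MotionParams,
    ParcelAtlas,
    ScalarMap,
    VolumeGrid,
)

__all__ = [
    "read_bold",
    "write_bold",
    "read_map",
    "write_map",
    "read_mask",
    "write_mask",
    "read_atlas",
    "write_atlas",
    "read_motion",
    "write_motion",
    "read_clinical",
    "write_clinical",
    "read_expression_table",
    "write_expression_table",
    "read_edges",
    "write_edges",
    "write_json",
    "read_json",
]


def _grid_from_img(img: nib.Nifti1Image) -> VolumeGrid:
    dims = tuple(int(d) for d in img.shape[:3])
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(dims, zooms, np.asarray(img.affine, float))


def read_bold(path, tr_s: float | None = None, subject_id: str = "", session="pre") -> Bold4D:
    """Read a 4D NIfTI; TR comes from the header time step unless overridden.

    Raises a dimensionality error for non-4D images and an explicit error
    when the header carries no usable TR and no override is given.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got {img.ndim}D")
    if tr_s is None:
        zooms = img.header.get_zooms()
        tr_s = float(zooms[3]) if len(zooms) > 3 else 0.0
        if not tr_s > 0:
            raise ValueError(
                f"{path}: header time step is missing or zero; "
                "pass tr_s explicitly (CLI: --tr)"
            )
    data = np.asarray(img.dataobj, dtype=np.float64)
    return Bold4D(_grid_from_img(img), data, float(tr_s), subject_id, session)


def write_bold(bold: Bold4D, path) -> None:
    """Write float32 NIfTI-1 with TR recorded in the header."""
    img = nib.Nifti1Image(bold.data.astype(np.float32), bold.grid.affine)
    img.header.set_zooms((*bold.grid.voxel_size_mm, bold.tr_s))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_map(path, kind="ben") -> ScalarMap:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {img.ndim}D")
    return ScalarMap(_grid_from_img(img), np.asarray(img.dataobj, float), kind)


def write_map(m: ScalarMap, path) -> None:
    """Write float64 NIfTI-1; re-reading preserves dims/affine/values."""
    img = nib.Nifti1Image(m.values.astype(np.float64), m.grid.affine)
    img.header.set_zooms(m.grid.voxel_size_mm)
    nib.save(img, str(path))


def read_mask(path) -> BrainMask:
    img = nib.load(str(path))
    return BrainMask(_grid_from_img(img), np.asarray(img.dataobj) > 0.5)


def write_mask(mask: BrainMask, path) -> None:
    img = nib.Nifti1Image(mask.include.astype(np.uint8), mask.grid.affine)
    img.header.set_zooms(mask.grid.voxel_size_mm)
    nib.save(img, str(path))


def read_atlas(path, hemisphere_tsv=None) -> ParcelAtlas:
    """Read an integer-label atlas; hemisphere map from optional TSV sidecar
    (columns parcel_id, hemisphere) or derived from parcel centroids."""
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj)
    if not np.allclose(labels, np.round(labels)):
        raise ValueError(f"{path}: atlas labels are not integers")
    hemi = {}
    if hemisphere_tsv is not None:
        t = pd.read_csv(hemisphere_tsv, sep="\t")
        hemi = {int(r.parcel_id): str(r.hemisphere) for r in t.itertuples()}
    return ParcelAtlas(_grid_from_img(img), labels.astype(np.int32), hemisphere=hemi)


def write_atlas(atlas: ParcelAtlas, path, hemisphere_tsv=None) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int32), atlas.grid.affine)
    img.header.set_zooms(atlas.grid.voxel_size_mm)
    nib.save(img, str(path))
    if hemisphere_tsv is not None:
        pd.DataFrame(
            {"parcel_id": atlas.parcel_ids,
             "hemisphere": [atlas.hemisphere[p] for p in atlas.parcel_ids]}
        ).to_csv(hemisphere_tsv, sep="\t", index=False)


_MOTION_COLS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def read_motion(path) -> MotionParams:
    t = pd.read_csv(path, sep="\t")
    missing = [c for c in _MOTION_COLS if c not in t.columns]
    if missing:
        raise ValueError(f"{path}: motion TSV missing columns {missing}")
    return MotionParams(
        t[_MOTION_COLS[:3]].to_numpy(float), t[_MOTION_COLS[3:]].to_numpy(float)
    )


def write_motion(motion: MotionParams, path) -> None:
    pd.DataFrame(
        np.hstack([motion.translations_mm, motion.rotations_rad]),
        columns=_MOTION_COLS,
    ).to_csv(path, sep="\t", index=False)


def read_clinical(path) -> ClinicalTable:
    return ClinicalTable(pd.read_csv(path, sep="\t"))


def write_clinical(clin: ClinicalTable, path) -> None:
    clin.table.to_csv(path, sep="\t", index=False)


def read_expression_table(path) -> ExpressionMatrix:
    """TSV with a header of gene symbols and a first column of parcel ids.

    Duplicate gene columns and non-numeric cells are rejected; row order is
    preserved as in the file.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    genes = header[1:]
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise ValueError(f"{path}: duplicate gene symbol(s) {dupes}")
    t = pd.read_csv(path, sep="\t", header=0, names=["parcel_id", *genes])
    try:
        values = t[genes].to_numpy(dtype=float)
        parcels = t["parcel_id"].to_numpy(dtype=int)
    except (ValueError, TypeError) as e:
        raise ValueError(f"{path}: non-numeric cell in expression table: {e}") from e
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: non-finite expression values")
    return ExpressionMatrix(list(parcels), genes, values)


def write_expression_table(expr: ExpressionMatrix, path) -> None:
    df = expr.to_frame()
    df.index.name = "parcel_id"
    df.to_csv(path, sep="\t")


def read_edges(path) -> pd.DataFrame:
    """Edge list TSV: gene_a, gene_b, confidence in [0, 1]; undirected, no
    self-loops, no duplicate pairs."""
    t = pd.read_csv(path, sep="\t")
    for c in ("gene_a", "gene_b", "confidence"):
        if c not in t.columns:
            raise ValueError(f"{path}: edge list missing column {c!r}")
    conf = t["confidence"].to_numpy(float)
    if ((conf < 0) | (conf > 1)).any():
        raise ValueError(f"{path}: confidence outside [0, 1]")
    if (t["gene_a"] == t["gene_b"]).any():
        raise ValueError(f"{path}: self-loop in edge list")
    key = t.apply(lambda r: tuple(sorted((r.gene_a, r.gene_b))), axis=1)
    if key.duplicated().any():
        raise ValueError(f"{path}: duplicate undirected edge")
    return t


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonify(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
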