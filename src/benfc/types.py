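"""Shared domain types for the entropy/connectivity pipeline.

Conventions
-----------
* Voxel indexing is 0-based; maps live on voxel centers; world coordinates
  come from the 4x4 affine (RAS+ for synthetic grids).
* Undefined voxels (outside the mask, zero temporal variance) are stored as
  NaN and excluded from every statistic downstream.
* Any two grid-bearing objects used together must share dims and affine;
  mismatches raise before any computation starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GridMismatchError",
    "VolumeGrid",
    "Bold4D",
    "BrainMask",
    "MotionParams",
    "ScalarMap",
    "ClinicalTable",
    "ParcelAtlas",
    "ExpressionMatrix",
    "ParcelProfile",
    "check_same_grid",
]

MapKind = Literal["ben", "t", "p", "fc_z", "density", "expression"]
Session = Literal["pre", "post", "control"]
Hemisphere = Literal["left", "right", "midline"]


class GridMismatchError(ValueError):
    """Two grid-bearing objects do not share dims/affine."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D voxel grid: dimensions, voxel size in mm, and index->world affine."""

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        vs = tuple(float(v) for v in self.voxel_size_mm)
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "voxel_size_mm", vs)
        if any(d < 1 for d in dims):
            raise ValueError(f"grid dims must all be >= 1, got {dims}")
        if any(v <= 0 for v in vs):
            raise ValueError(f"voxel size must be strictly positive, got {vs}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        object.__setattr__(self, "affine", aff)

    @classmethod
    def isotropic(cls, dims: Sequence[int], voxel_mm: float = 3.0) -> "VolumeGrid":
        """RAS+ grid with isotropic voxels, origin at the grid center."""
        dims = tuple(int(d) for d in dims)
        aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        aff[:3, 3] = -voxel_mm * (np.asarray(dims) - 1) / 2.0
        return cls(dims, (voxel_mm,) * 3, aff)

    def same_as(self, other: "VolumeGrid", atol: float = 1e-5) -> bool:
        return self.dims == other.dims and np.allclose(
            self.affine, other.affine, atol=atol
        )


def check_same_grid(*objs) -> VolumeGrid:
    """Assert all arguments share one grid; return it."""
    grids = [o.grid for o in objs]
    for g in grids[1:]:
        if not grids[0].same_as(g):
            raise GridMismatchError(
                f"grid mismatch: dims {grids[0].dims} vs {g.dims} or differing affines"
            )
    return grids[0]


@dataclass
class Bold4D:
    """One session's 4D BOLD signal (x, y, z, t) with its repetition time."""

    grid: VolumeGrid
    data: np.ndarray
    tr_s: float
    subject_id: str = ""
    session: Session = "pre"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"Bold4D data must be 4D, got ndim={self.data.ndim}")
        if self.data.shape[:3] != self.grid.dims:
            raise GridMismatchError(
                f"data spatial shape {self.data.shape[:3]} != grid dims {self.grid.dims}"
            )
        if self.data.shape[3] < 2:
            raise ValueError("Bold4D needs at least 2 time points")
        if not self.tr_s > 0:
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray) -> "Bold4D":
        return Bold4D(self.grid, data, self.tr_s, self.subject_id, self.session)


@dataclass
class BrainMask:
    """Boolean inclusion mask on a grid."""

    grid: VolumeGrid
    include: np.ndarray

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool)
        if self.include.shape != self.grid.dims:
            raise GridMismatchError(
                f"mask shape {self.include.shape} != grid dims {self.grid.dims}"
            )
        if not self.include.any():
            raise ValueError("mask must include at least one voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.include.sum())


@dataclass
class MotionParams:
    """Rigid-body motion estimates per volume (translations mm, rotations rad)."""

    translations_mm: np.ndarray
    rotations_rad: np.ndarray

    def __post_init__(self) -> None:
        self.translations_mm = np.atleast_2d(np.asarray(self.translations_mm, float))
        self.rotations_rad = np.atleast_2d(np.asarray(self.rotations_rad, float))
        if self.translations_mm.shape[1] != 3 or self.rotations_rad.shape[1] != 3:
            raise ValueError("motion parameters need 3 translation + 3 rotation columns")
        if self.translations_mm.shape[0] != self.rotations_rad.shape[0]:
            raise ValueError("translation and rotation row counts differ")

    @property
    def n_volumes(self) -> int:
        return self.translations_mm.shape[0]

    def drop_initial(self, k: int) -> "MotionParams":
        return MotionParams(self.translations_mm[k:], self.rotations_rad[k:])


@dataclass
class ScalarMap:
    """A 3D scalar map (entropy, t, p, Fisher-z FC, density); NaN = undefined."""

    grid: VolumeGrid
    values: np.ndarray
    kind: MapKind = "ben"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.dims:
            raise GridMismatchError(
                f"map shape {self.values.shape} != grid dims {self.grid.dims}"
            )

    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    def in_mask(self, mask: BrainMask) -> np.ndarray:
        check_same_grid(self, mask)
        return self.values[mask.include]


@dataclass
class ClinicalTable:
    """Per-subject HAMD (0-52) and MMSE (0-30) scores, pre and post."""

    table: pd.DataFrame

    REQUIRED = ("subject_id", "hamd_pre", "hamd_post", "mmse_pre", "mmse_post")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        if self.table["subject_id"].duplicated().any():
            raise ValueError("duplicate subject_id in clinical table")
        for col in ("hamd_pre", "hamd_post"):
            v = self.table[col].to_numpy(float)
            if ((v < 0) | (v > 52)).any():
                raise ValueError(f"{col} outside [0, 52]")
        for col in ("mmse_pre", "mmse_post"):
            v = self.table[col].to_numpy(float)
            if ((v < 0) | (v > 30)).any():
                raise ValueError(f"{col} outside [0, 30]")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ParcelAtlas:
    """Integer-labeled parcellation (0 = background) with hemisphere lookup."""

    grid: VolumeGrid
    labels: np.ndarray
    parcel_ids: list[int] = field(default_factory=list)
    hemisphere: Mapping[int, Hemisphere] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if self.labels.shape != self.grid.dims:
            raise GridMismatchError("atlas labels shape != grid dims")
        present = sorted(int(v) for v in np.unique(self.labels) if v != 0)
        if not self.parcel_ids:
            self.parcel_ids = present
        else:
            self.parcel_ids = [int(p) for p in self.parcel_ids]
            unknown = set(present) - set(self.parcel_ids)
            if unknown:
                raise ValueError(f"labels present but not in parcel_ids: {sorted(unknown)}")
        if len(set(self.parcel_ids)) != len(self.parcel_ids):
            raise ValueError("parcel_ids must be distinct")
        if not self.hemisphere:
            self.hemisphere = self._hemispheres_from_centroids()

    def _hemispheres_from_centroids(self) -> dict[int, Hemisphere]:
        """Assign hemispheres from parcel centroid world-x (RAS+: x<0 left)."""
        out: dict[int, Hemisphere] = {}
        aff = self.grid.affine
        for pid in self.parcel_ids:
            idx = np.argwhere(self.labels == pid)
            if len(idx) == 0:
                out[pid] = "midline"
                continue
            c = idx.mean(axis=0)
            wx = aff[0, 0] * c[0] + aff[0, 1] * c[1] + aff[0, 2] * c[2] + aff[0, 3]
            half = self.grid.voxel_size_mm[0] / 2.0
            out[pid] = "left" if wx < -half else ("right" if wx > half else "midline")
        return out

    def parcels_in(self, hemisphere_filter: str) -> list[int]:
        if hemisphere_filter == "both":
            return list(self.parcel_ids)
        if hemisphere_filter not in ("left", "right"):
            raise ValueError(f"unknown hemisphere filter {hemisphere_filter!r}")
        return [p for p in self.parcel_ids if self.hemisphere[p] == hemisphere_filter]


@dataclass
class ExpressionMatrix:
    """Parcels x genes expression values with symbols and parcel ids."""

    parcel_ids: list[int]
    gene_symbols: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.parcel_ids = [int(p) for p in self.parcel_ids]
        self.gene_symbols = [str(g) for g in self.gene_symbols]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.parcel_ids), len(self.gene_symbols)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.parcel_ids)}, {len(self.gene_symbols)})"
            )
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            dupes = sorted(
                {g for g in self.gene_symbols if self.gene_symbols.count(g) > 1}
            )
            raise ValueError(f"duplicate gene symbols: {dupes}")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_symbols)

    def column(self, gene: str) -> np.ndarray:
        try:
            j = self.gene_symbols.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene symbol {gene!r}") from None
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.parcel_ids, columns=self.gene_symbols
        )


@dataclass
class ParcelProfile:
    """One value per parcel (e.g. mean t, mean expression); NaN = undefined."""

    parcel_ids: list[int]
    values: np.ndarray
    n_voxels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.parcel_ids = [int(p) for p in self.parcel_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.parcel_ids),):
            raise ValueError("profile values must be one per parcel")
        if self.n_voxels is None:
            self.n_voxels = np.zeros(len(self.parcel_ids), dtype=int)
        else:
            self.n_voxels = np.asarray(self.n_voxels, dtype=int)

    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.parcel_ids)
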