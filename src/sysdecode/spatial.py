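"""Volume grids, probability maps, masks, parcellations and their geometry.

All cross-volume operations in this package require the operands to live on
the *same* grid (identical shape and affine); resampling between grids is an
explicit step (:func:`resample_to_grid`), never something done silently.
Voxel indices are 0-based; world coordinates are MNI millimetres obtained by
applying the 4x4 affine to homogeneous voxel indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from nilearn.image import resample_img

__all__ = [
    "VolumeGrid",
    "ProbabilityMap",
    "RegionMask",
    "Parcellation",
    "NetworkPartition",
    "resample_to_grid",
    "threshold_probability",
    "overlap_fraction",
    "mask_union",
    "mask_intersection",
    "any_overlap",
]


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D sampling grid: array shape plus voxel-to-world affine.

    Parameters
    ----------
    shape:
        Number of voxels along each axis (i, j, k).
    affine:
        4x4 matrix mapping 0-based voxel indices to world (MNI) mm.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if any(s < 1 for s in shape) or len(shape) != 3:
            raise ValueError("shape must be three positive integers")
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge length of a voxel along each axis, in mm."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_centers(self, ijk: np.ndarray) -> np.ndarray:
        """World-mm coordinates of the given (n, 3) voxel indices."""
        ijk = np.atleast_2d(ijk)
        hom = np.c_[ijk, np.ones(len(ijk))]
        return (self.affine @ hom.T).T[:, :3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of (n, 3) world-mm points."""
        xyz = np.atleast_2d(xyz)
        hom = np.c_[xyz, np.ones(len(xyz))]
        return (np.linalg.inv(self.affine) @ hom.T).T[:, :3]

    def same_as(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    @classmethod
    def isotropic(cls, shape: tuple[int, int, int], voxel_mm: float = 2.0,
                  origin: tuple[float, float, float] | None = None) -> "VolumeGrid":
        """Axis-aligned grid with cubic voxels, centred on the origin by default."""
        shape = tuple(int(s) for s in shape)
        if origin is None:
            origin = tuple(-voxel_mm * (s - 1) / 2 for s in shape)
        aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        aff[:3, 3] = origin
        return cls(shape, aff)


def _check_conforms(grid: VolumeGrid, arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.shape != grid.shape:
        raise ValueError(f"array shape {arr.shape} != grid shape {grid.shape}")
    return arr


def _require_same_grid(a: VolumeGrid, b: VolumeGrid) -> None:
    if not a.same_as(b):
        raise GridMismatchError("operands live on different grids; resample first")


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-voxel probabilities in [0, 1] on a grid (e.g. a cytoarchitectonic
    seed probability map)."""

    grid: VolumeGrid
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        vals = _check_conforms(self.grid, self.values).astype(float)
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValueError("probability values must lie in [0, 1]")
        object.__setattr__(self, "values", vals)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.values.astype(np.float32), self.grid.affine)

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image, name: str = "") -> "ProbabilityMap":
        data = np.asarray(img.get_fdata(), dtype=float)
        return cls(VolumeGrid(data.shape, img.affine), data, name=name)


@dataclass(frozen=True)
class RegionMask:
    """Boolean voxel set on a grid. Empty masks are legal; operations that
    need a nonempty region (seed extraction, overlap denominators) reject
    them at the point of use."""

    grid: VolumeGrid
    members: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        mem = _check_conforms(self.grid, self.members).astype(bool)
        object.__setattr__(self, "members", mem)

    @property
    def n_voxels(self) -> int:
        return int(self.members.sum())

    @property
    def is_empty(self) -> bool:
        return not self.members.any()

    def voxel_indices(self) -> np.ndarray:
        """(n, 3) array of member voxel indices."""
        return np.argwhere(self.members)

    def voxel_centers_mm(self) -> np.ndarray:
        """(n, 3) world-mm coordinates of member voxel centers."""
        return self.grid.voxel_centers(self.voxel_indices())

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.members.astype(np.uint8), self.grid.affine)

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image, name: str = "") -> "RegionMask":
        data = np.asarray(img.get_fdata())
        return cls(VolumeGrid(data.shape, img.affine), data > 0.5, name=name)


@dataclass(frozen=True)
class Parcellation:
    """Integer label volume (0 = background) plus a label table.

    The table is a DataFrame indexed by label with columns
    ``name``, ``hemisphere`` (L/R) and ``group``.
    """

    grid: VolumeGrid
    labels: np.ndarray
    table: pd.DataFrame

    def __post_init__(self) -> None:
        lab = _check_conforms(self.grid, self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.allclose(lab, np.round(lab)):
                raise ValueError("labels must be integers")
            lab = np.round(lab).astype(np.int32)
        if lab.min() < 0:
            raise ValueError("labels must be non-negative")
        present = set(np.unique(lab)) - {0}
        known = set(int(i) for i in self.table.index)
        missing = present - known
        if missing:
            raise ValueError(f"labels missing from table: {sorted(missing)}")
        object.__setattr__(self, "labels", lab)

    @property
    def label_ids(self) -> list[int]:
        return [int(i) for i in self.table.index]

    def parcel_mask(self, label: int) -> RegionMask:
        name = str(self.table.loc[label, "name"]) if label in self.table.index else str(label)
        return RegionMask(self.grid, self.labels == label, name=name)

    def parcel_size(self, label: int) -> int:
        return int((self.labels == label).sum())

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.labels.astype(np.int32), self.grid.affine)

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image, table: pd.DataFrame) -> "Parcellation":
        data = np.asarray(img.get_fdata())
        return cls(VolumeGrid(data.shape, img.affine), np.round(data).astype(np.int32), table)


@dataclass(frozen=True)
class NetworkPartition:
    """Assignment of voxels to K named intrinsic networks (label 0 =
    unassigned), e.g. the canonical seven-network cortical partition."""

    grid: VolumeGrid
    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lab = _check_conforms(self.grid, self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            lab = np.round(lab).astype(np.int32)
        if lab.min() < 0:
            raise ValueError("network labels must be non-negative")
        names = {int(k): str(v) for k, v in self.names.items()}
        if len(set(names.values())) != len(names):
            raise ValueError("network names must be unique")
        present = set(np.unique(lab)) - {0}
        if not present <= set(names):
            raise ValueError("unnamed network labels present")
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "names", names)

    @property
    def network_ids(self) -> list[int]:
        return sorted(self.names)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.labels.astype(np.int32), self.grid.affine)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def resample_to_grid(source, target: VolumeGrid, method: str | None = None):
    """Resample a volume onto ``target``.

    Probability maps use trilinear interpolation (values clipped back to
    [0, 1]); label volumes (Parcellation, NetworkPartition) require
    nearest-neighbour, since interpolating labels is meaningless.
    """
    is_labels = isinstance(source, (Parcellation, NetworkPartition))
    if method is None:
        method = "nearest" if is_labels else "trilinear"
    if method not in ("trilinear", "nearest"):
        raise ValueError(f"unknown method {method!r}")
    if is_labels and method == "trilinear":
        raise ValueError("trilinear interpolation is invalid for label volumes")

    img = source.to_nifti()
    interp = "nearest" if method == "nearest" else "linear"
    out = resample_img(
        img,
        target_affine=target.affine,
        target_shape=target.shape,
        interpolation=interp,
        force_resample=True,
        copy_header=False,
    )
    data = np.asarray(out.get_fdata())

    if isinstance(source, ProbabilityMap):
        return ProbabilityMap(target, np.clip(data, 0.0, 1.0), name=source.name)
    if isinstance(source, Parcellation):
        return Parcellation(target, np.round(data).astype(np.int32), source.table)
    if isinstance(source, NetworkPartition):
        return NetworkPartition(target, np.round(data).astype(np.int32), source.names)
    if isinstance(source, RegionMask):
        return RegionMask(target, np.round(data).astype(np.int32) > 0, name=source.name)
    raise TypeError(f"cannot resample {type(source).__name__}")


def threshold_probability(pmap: ProbabilityMap, tau: float = 0.25,
                          name: str | None = None) -> RegionMask:
    """Voxels with probability strictly greater than ``tau``.

    The default 0.25 keeps only voxels assigned to the region with more
    than 25% cytoarchitectonic probability. The inequality is strict; an
    empty result is legal.
    """
    if not (0.0 <= tau < 1.0):
        raise ValueError("tau must lie in [0, 1)")
    return RegionMask(pmap.grid, pmap.values > tau,
                      name=pmap.name if name is None else name)


def overlap_fraction(cover: RegionMask, parcellation: Parcellation, label: int) -> float:
    """Fraction of the parcel's voxels that fall inside ``cover``.

    The direction matters: this is a property of the *parcel* (how much of
    the region is covered by, e.g., a thresholded connectivity map), not of
    the cover.
    """
    _require_same_grid(cover.grid, parcellation.grid)
    parcel = parcellation.labels == label
    n = int(parcel.sum())
    if n == 0:
        raise ValueError(f"parcel {label} has no voxels")
    return float((parcel & cover.members).sum() / n)


def mask_union(a: RegionMask, b: RegionMask, name: str = "") -> RegionMask:
    _require_same_grid(a.grid, b.grid)
    return RegionMask(a.grid, a.members | b.members, name=name)


def mask_intersection(a: RegionMask, b: RegionMask, name: str = "") -> RegionMask:
    _require_same_grid(a.grid, b.grid)
    return RegionMask(a.grid, a.members & b.members, name=name)


def any_overlap(a: RegionMask, b: RegionMask) -> bool:
    """True iff the two masks share at least one voxel."""
    _require_same_grid(a.grid, b.grid)
    return bool((a.members & b.members).any())
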