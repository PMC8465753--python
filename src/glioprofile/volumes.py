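"""Geometry-aware volumes and low-level 3D mask operators.

All spatial quantities are expressed in world millimetres through the
voxel-to-world affine of a :class:`VolumeGeometry`. Voxel indices are
0-based and world coordinates refer to voxel centres. Distance operators
assume an axis-aligned affine (no shear/rotation), which holds for masks
registered to a standard reference space; the voxel spacing is read off
the affine column norms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np
from scipy import ndimage


class GeometryMismatchError(ValueError):
    """Two volumes that must share a geometry do not."""


class EmptyMaskError(ValueError):
    """An operator requiring foreground voxels received an empty mask."""


@dataclass(frozen=True)
class VolumeGeometry:
    """Shape, spacing and voxel-to-world mapping shared by one case's volumes.

    Parameters
    ----------
    shape : tuple of 3 int
        Lattice dimensions in voxels.
    affine : (4, 4) ndarray
        Invertible voxel-index -> world-mm mapping (voxel centres).
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("voxel-to-world affine is not invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm along each axis (affine column norms)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @classmethod
    def isotropic(cls, shape: tuple[int, int, int], spacing: float = 1.0,
                  origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> "VolumeGeometry":
        aff = np.diag([spacing, spacing, spacing, 1.0])
        aff[:3, 3] = origin
        return cls(shape, aff)

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to (N, 3) world-mm coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinate lattices (x, y, z), each of ``shape``."""
        grids = np.meshgrid(*(np.arange(s) for s in self.shape), indexing="ij")
        idx = np.stack([g.ravel() for g in grids], axis=1)
        world = self.voxel_to_world(idx)
        return tuple(world[:, i].reshape(self.shape) for i in range(3))

    def close_to(self, other: "VolumeGeometry", tol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=tol)


def _require_same_geometry(a, b) -> None:
    if not a.geometry.close_to(b.geometry):
        raise GeometryMismatchError("operands do not share a geometry")


@dataclass
class BinaryMask:
    """A hard segmentation on a geometry (boolean lattice)."""

    geometry: VolumeGeometry
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.shape != self.geometry.shape:
            raise ValueError("mask lattice shape must equal geometry.shape")

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def is_empty(self) -> bool:
        return not self.data.any()

    def volume_ml(self) -> float:
        """Mask volume in millilitres (voxel count x voxel volume / 1000)."""
        return self.voxel_count * self.geometry.voxel_volume_mm3 / 1000.0


@dataclass
class ProbabilityMap:
    """A soft segmentation: per-voxel probabilities in [0, 1]."""

    geometry: VolumeGeometry
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != self.geometry.shape:
            raise ValueError("map lattice shape must equal geometry.shape")
        if not np.isfinite(self.data).all():
            raise ValueError("probability map contains non-finite values")
        if self.data.min() < 0.0 or self.data.max() > 1.0:
            raise ValueError("probability values must lie in [0, 1]")

    def binarize(self, threshold: float) -> BinaryMask:
        return BinaryMask(self.geometry, self.data >= threshold)


@dataclass
class LabeledComponents:
    """Connected components of a mask: label 0 is background, labels 1..K foreground."""

    geometry: VolumeGeometry
    labels: np.ndarray
    connectivity: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.geometry.shape:
            raise ValueError("label lattice shape must equal geometry.shape")

    @property
    def count(self) -> int:
        return int(self.labels.max())

    @property
    def sizes(self) -> np.ndarray:
        """Voxel count per label, index 0 corresponding to label 1."""
        if self.count == 0:
            return np.zeros(0, dtype=np.int64)
        return np.bincount(self.labels.ravel(), minlength=self.count + 1)[1:]

    def component_mask(self, label: int) -> BinaryMask:
        return BinaryMask(self.geometry, self.labels == label)


# --------------------------------------------------------------------------
# NIfTI I/O

def load_volume(path: Union[str, Path]) -> Union[BinaryMask, ProbabilityMap]:
    """Load a NIfTI volume as a mask or probability map.

    Integer-valued data with at most two distinct values loads as a
    :class:`BinaryMask`; anything else loads as a :class:`ProbabilityMap`
    and must lie in [0, 1]. Non-finite values are rejected.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise ValueError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if not np.isfinite(data).all():
        raise ValueError(f"{path}: volume contains non-finite values")
    geometry = VolumeGeometry(data.shape, np.asarray(img.affine, dtype=float))
    values = np.unique(data)
    integral = np.allclose(values, np.round(values))
    if integral and values.size <= 2:
        return BinaryMask(geometry, data > 0)
    if data.min() < 0.0 or data.max() > 1.0:
        raise ValueError(f"{path}: probability values outside [0, 1]")
    return ProbabilityMap(geometry, data)


def save_volume(volume: Union[BinaryMask, ProbabilityMap], path: Union[str, Path]) -> None:
    """Write a mask (uint8) or probability map (float32) to NIfTI."""
    if isinstance(volume, BinaryMask):
        data = volume.data.astype(np.uint8)
    else:
        data = volume.data.astype(np.float32)
    img = nib.Nifti1Image(data, volume.geometry.affine)
    nib.save(img, str(path))


# --------------------------------------------------------------------------
# Mask operators

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def connected_components(mask: BinaryMask, connectivity: int = 26) -> LabeledComponents:
    """Label connected components under a 6/18/26 neighbourhood."""
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be one of 6, 18, 26")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, _ = ndimage.label(mask.data, structure=structure)
    return LabeledComponents(mask.geometry, labels, connectivity)


def _ball(radius: int) -> np.ndarray:
    """Voxel ball: offsets with Euclidean index norm <= radius."""
    r = int(radius)
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    return dx * dx + dy * dy + dz * dz <= r * r


def binary_closing(mask: BinaryMask, radius_voxels: int = 2, iterations: int = 2) -> BinaryMask:
    """Morphological closing with a spherical voxel kernel, zero-padded borders.

    The lattice is padded so the dilation can expand freely before eroding,
    keeping the operation extensive (no input voxel is ever removed).
    """
    if radius_voxels < 1 or iterations < 1:
        raise ValueError("radius and iterations must be positive")
    if mask.is_empty:
        return BinaryMask(mask.geometry, np.zeros(mask.geometry.shape, bool))
    pad = radius_voxels * iterations + 1
    padded = np.pad(mask.data, pad)
    closed = ndimage.binary_closing(padded, structure=_ball(radius_voxels),
                                    iterations=iterations)
    sl = tuple(slice(pad, pad + s) for s in mask.geometry.shape)
    return BinaryMask(mask.geometry, closed[sl])


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    _require_same_geometry(a, b)
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


def boundary_voxels(mask: BinaryMask) -> np.ndarray:
    """Boolean lattice of surface voxels (foreground with a background 6-neighbour)."""
    structure = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask.data, structure=structure, border_value=0)
    return mask.data & ~eroded


def _directed_surface_distances(src: np.ndarray, dst: np.ndarray,
                                spacing: np.ndarray) -> np.ndarray:
    """Distances (mm) from each True voxel of src to the nearest True voxel of dst."""
    dt = ndimage.distance_transform_edt(~dst, sampling=spacing)
    return dt[src]


def hd95(a: BinaryMask, b: BinaryMask) -> float:
    """Symmetric 95th-percentile Hausdorff distance between mask surfaces, in mm.

    Defined as the max of the two directed 95th percentiles over surface
    voxels. Undefined for empty masks.
    """
    _require_same_geometry(a, b)
    if a.is_empty or b.is_empty:
        raise EmptyMaskError("hd95 is undefined for empty masks")
    spacing = a.geometry.spacing
    ba, bb = boundary_voxels(a), boundary_voxels(b)
    d_ab = _directed_surface_distances(ba, bb, spacing)
    d_ba = _directed_surface_distances(bb, ba, spacing)
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


def directed_distance_percentile(src: BinaryMask, dst: BinaryMask,
                                 percentile: float = 95.0) -> float:
    """Directed percentile distance (mm) from src surface voxels to dst voxels."""
    _require_same_geometry(src, dst)
    if src.is_empty or dst.is_empty:
        raise EmptyMaskError("directed distance is undefined for empty masks")
    d = _directed_surface_distances(boundary_voxels(src), dst.data,
                                    src.geometry.spacing)
    return float(np.percentile(d, percentile))


def min_surface_distance(a: BinaryMask, b: BinaryMask) -> float:
    """Minimum world distance (mm) between any voxel centres of a and b; 0 on overlap."""
    _require_same_geometry(a, b)
    if a.is_empty or b.is_empty:
        raise EmptyMaskError("distance is undefined for empty masks")
    if np.logical_and(a.data, b.data).any():
        return 0.0
    dt = ndimage.distance_transform_edt(~b.data, sampling=a.geometry.spacing)
    return float(dt[a.data].min())


def resample_to_geometry(mask: BinaryMask, target: VolumeGeometry) -> BinaryMask:
    """Nearest-neighbour resampling through world coordinates.

    Target voxels whose world position maps outside the source lattice
    become background.
    """
    if mask.geometry.close_to(target):
        return BinaryMask(target, mask.data.copy())
    grids = np.meshgrid(*(np.arange(s) for s in target.shape), indexing="ij")
    tgt_idx = np.stack([g.ravel() for g in grids], axis=1).astype(float)
    world = target.affine[:3, :3] @ tgt_idx.T + target.affine[:3, 3:4]
    src_aff_inv = np.linalg.inv(mask.geometry.affine)
    src_idx = src_aff_inv[:3, :3] @ world + src_aff_inv[:3, 3:4]
    src_idx = np.round(src_idx).astype(np.int64)
    inside = np.all((src_idx >= 0) &
                    (src_idx < np.array(mask.geometry.shape)[:, None]), axis=0)
    out = np.zeros(int(np.prod(target.shape)), dtype=bool)
    ii = src_idx[:, inside]
    out[inside] = mask.data[ii[0], ii[1], ii[2]]
    return BinaryMask(target, out.reshape(target.shape))
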