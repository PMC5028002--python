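"""Core containers: volumes, cortical surfaces, per-vertex maps and masks.

Conventions
-----------
* Voxel indices are 0-based; world coordinates are obtained through the
  4x4 grid-to-world affine.
* Inter-image operations require identical grids (shape, voxel size,
  affine); a :class:`~corticomap.errors.GridMismatchError` is raised
  otherwise.  Resampling is an explicit opt-in
  (:func:`resample_nearest`), never a silent default.
* Non-finite voxels are recorded in a validity mask and excluded from all
  statistics, never zeroed.
* Per-vertex surface area is one third of the summed areas of incident
  triangles, computed on the midthickness surface (mean of white and
  pial coordinates).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import (
    DimensionalityError,
    FaceIndexError,
    GridMismatchError,
    MaskBoundsError,
    MissingFileError,
    NotNiftiError,
    ParentMismatchError,
    SurfaceFormatError,
    VertexCountMismatchError,
)

__all__ = [
    "Volume",
    "TimeSeriesVolume",
    "CorticalSurface",
    "VertexMap",
    "VertexMask",
    "VoxelMask",
    "read_volume",
    "write_volume",
    "read_surface",
    "write_surface",
    "mask_algebra",
    "resample_nearest",
]


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

@dataclass
class Volume:
    """A 3D scalar grid with voxel size and a grid-to-world transform.

    Parameters
    ----------
    data:
        3D array of intensities (arbitrary units).
    voxel_size:
        Length-3 tuple of mm per axis; all entries must be positive.
    transform:
        4x4 grid-to-world affine.
    space_tag:
        Free-text label of the coordinate space (used only for provenance).
    valid:
        Boolean array of the same shape; ``False`` marks voxels whose value
        must not enter any statistic.  Non-finite input voxels are flagged
        here automatically.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    transform: np.ndarray
    space_tag: str = "native"
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"Volume data must be 3D, got {self.data.ndim}D"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel dimensions must be > 0: {self.voxel_size}")
        self.transform = np.asarray(self.transform, dtype=float)
        if self.transform.shape != (4, 4):
            raise ValueError("transform must be a 4x4 affine")
        finite = np.isfinite(self.data)
        if self.valid is None:
            self.valid = finite
        else:
            self.valid = np.asarray(self.valid, dtype=bool) & finite
        # keep the array clean for interpolation; flagged voxels carry 0
        if not finite.all():
            self.data = np.where(finite, self.data, 0.0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def same_grid(self, other: "Volume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.transform, other.transform)
        )

    def require_same_grid(self, other: "Volume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"volumes are on different grids: {self.shape}/{other.shape}"
            )

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map N x 3 world coordinates to continuous voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.transform)
        hom = np.c_[xyz, np.ones(len(xyz))]
        return (hom @ inv.T)[:, :3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        hom = np.c_[ijk, np.ones(len(ijk))]
        return (hom @ self.transform.T)[:, :3]


@dataclass
class TimeSeriesVolume:
    """A 4D series of frames sharing one grid (last axis = time)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    transform: np.ndarray
    frame_interval: float = 1.0
    space_tag: str = "native"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise DimensionalityError(
                f"time-series data must be 4D, got {self.data.ndim}D"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.transform = np.asarray(self.transform, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def frame(self, t: int) -> Volume:
        return Volume(self.data[..., t], self.voxel_size, self.transform,
                      space_tag=self.space_tag)


def read_volume(path: str | os.PathLike) -> Volume | TimeSeriesVolume:
    """Read a NIfTI volume (3D) or time series (4D).

    Raises
    ------
    MissingFileError, NotNiftiError, DimensionalityError
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise MissingFileError(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several classes here
        raise NotNiftiError(f"{path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()
    affine = img.affine
    if data.ndim == 3:
        return Volume(data, zooms[:3], affine)
    if data.ndim == 4:
        dt = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        return TimeSeriesVolume(data, zooms[:3], affine, frame_interval=dt)
    raise DimensionalityError(f"{path}: {data.ndim}D image; expected 3D or 4D")


def write_volume(vol: Volume | TimeSeriesVolume, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.transform)
    zooms = list(vol.voxel_size)
    if isinstance(vol, TimeSeriesVolume):
        zooms.append(vol.frame_interval)
    img.header.set_zooms(tuple(zooms))
    nib.save(img, os.fspath(path))


# ---------------------------------------------------------------------------
# Surfaces
# ---------------------------------------------------------------------------

@dataclass
class CorticalSurface:
    """Triangulated cortical sheet with paired white and pial coordinates."""

    vertices_white: np.ndarray
    vertices_pial: np.ndarray
    faces: np.ndarray
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        self.vertices_white = np.asarray(self.vertices_white, dtype=float)
        self.vertices_pial = np.asarray(self.vertices_pial, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices_white.shape != self.vertices_pial.shape:
            raise VertexCountMismatchError(
                f"white {self.vertices_white.shape} vs pial "
                f"{self.vertices_pial.shape}"
            )
        n = len(self.vertices_white)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise FaceIndexError(
                f"face index out of range [0, {n}): "
                f"min={self.faces.min()}, max={self.faces.max()}"
            )
        self._vertex_areas: np.ndarray | None = None
        self._adjacency = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices_white)

    @property
    def midthickness(self) -> np.ndarray:
        return 0.5 * (self.vertices_white + self.vertices_pial)

    @property
    def thickness(self) -> np.ndarray:
        """Per-vertex white-to-pial Euclidean distance (mm)."""
        return np.linalg.norm(self.vertices_pial - self.vertices_white, axis=1)

    def vertex_areas(self) -> np.ndarray:
        """Per-vertex area: one third of incident midthickness triangle areas."""
        if self._vertex_areas is None:
            v = self.midthickness
            tri = v[self.faces]
            cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
            tri_area = 0.5 * np.linalg.norm(cross, axis=1)
            areas = np.zeros(self.n_vertices)
            for k in range(3):
                np.add.at(areas, self.faces[:, k], tri_area / 3.0)
            self._vertex_areas = areas
        return self._vertex_areas

    def total_area(self) -> float:
        return float(self.vertex_areas().sum())

    def adjacency(self):
        """Sparse vertex adjacency (symmetric, from shared triangle edges)."""
        if self._adjacency is None:
            f = self.faces
            e = np.r_[f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]
            n = self.n_vertices
            a = coo_matrix(
                (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)
            )
            self._adjacency = ((a + a.T) > 0).tocsr()
        return self._adjacency


def read_surface(path: str | os.PathLike,
                 pial_path: str | os.PathLike | None = None,
                 hemisphere: str = "left") -> CorticalSurface:
    """Read a GIFTI surface.

    ``path`` may hold white + pial + triangle arrays in a single file
    (two POINTSET arrays, white first) or the white surface only, with
    the pial geometry in ``pial_path``.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise MissingFileError(path)
    img = nib.load(path)
    points = [d.data for d in img.darrays
              if d.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]]
    tris = [d.data for d in img.darrays
            if d.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]]
    if not points or not tris:
        raise SurfaceFormatError(f"{path}: needs POINTSET and TRIANGLE arrays")
    white = points[0]
    if len(points) >= 2:
        pial = points[1]
    elif pial_path is not None:
        pimg = nib.load(os.fspath(pial_path))
        ppoints = [d.data for d in pimg.darrays
                   if d.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]]
        if not ppoints:
            raise SurfaceFormatError(f"{pial_path}: no POINTSET array")
        pial = ppoints[0]
    else:
        pial = white
    return CorticalSurface(white, pial, tris[0], hemisphere=hemisphere)


def write_surface(surface: CorticalSurface, path: str | os.PathLike) -> None:
    """Write white + pial + triangles into one GIFTI file (white first)."""
    intent_p = nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]
    intent_t = nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]
    arrays = [
        nib.gifti.GiftiDataArray(
            surface.vertices_white.astype(np.float32), intent=intent_p),
        nib.gifti.GiftiDataArray(
            surface.vertices_pial.astype(np.float32), intent=intent_p),
        nib.gifti.GiftiDataArray(
            surface.faces.astype(np.int32), intent=intent_t),
    ]
    nib.save(nib.gifti.GiftiImage(darrays=arrays), os.fspath(path))


# ---------------------------------------------------------------------------
# Per-vertex maps and masks
# ---------------------------------------------------------------------------

@dataclass
class VertexMap:
    """Per-vertex scalar map on one hemisphere's surface."""

    values: np.ndarray
    surface_ref: str
    depth_fraction: float = 0.5
    valid: np.ndarray | None = None
    n_vertices: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not (0.0 <= self.depth_fraction <= 1.0):
            raise ValueError("depth_fraction must lie in [0, 1]")
        finite = np.isfinite(self.values)
        if self.valid is None:
            self.valid = finite
        else:
            self.valid = np.asarray(self.valid, dtype=bool) & finite
        if self.n_vertices is None:
            self.n_vertices = len(self.values)
        elif self.n_vertices != len(self.values):
            raise VertexCountMismatchError(
                f"map length {len(self.values)} != surface "
                f"vertex count {self.n_vertices}"
            )

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


class _IndexMask:
    """Common behaviour of vertex and voxel masks: a sorted unique index set."""

    def __init__(self, indices, parent_ref: str, parent_size: int | None = None):
        idx = np.unique(np.asarray(indices, dtype=np.int64))
        if idx.size and idx.min() < 0:
            raise MaskBoundsError("negative mask index")
        if parent_size is not None and idx.size and idx.max() >= parent_size:
            raise MaskBoundsError(
                f"mask index {idx.max()} outside parent of size {parent_size}"
            )
        self.indices = idx
        self.parent_ref = parent_ref
        self.parent_size = parent_size

    def __len__(self) -> int:
        return int(self.indices.size)

    def __contains__(self, i: int) -> bool:
        return bool(np.isin(i, self.indices))

    def as_set(self) -> set[int]:
        return set(int(i) for i in self.indices)

    def to_text(self, path: str | os.PathLike) -> None:
        """Write one integer index per line (diff-friendly export)."""
        np.savetxt(os.fspath(path), self.indices, fmt="%d")

    @classmethod
    def from_text(cls, path: str | os.PathLike, parent_ref: str,
                  parent_size: int | None = None):
        idx = np.loadtxt(os.fspath(path), dtype=np.int64, ndmin=1)
        return cls(idx, parent_ref, parent_size)


class VertexMask(_IndexMask):
    """Subset of vertices of one surface."""


class VoxelMask(_IndexMask):
    """Subset of voxels of one volume, as flat (C-order) indices."""

    def __init__(self, indices, parent_ref: str,
                 parent_shape: tuple[int, ...] | None = None):
        size = int(np.prod(parent_shape)) if parent_shape is not None else None
        super().__init__(indices, parent_ref, size)
        self.parent_shape = parent_shape

    def to_ijk(self) -> np.ndarray:
        if self.parent_shape is None:
            raise MaskBoundsError("parent_shape unknown; cannot unravel")
        return np.column_stack(np.unravel_index(self.indices, self.parent_shape))

    def to_dense(self) -> np.ndarray:
        dense = np.zeros(self.parent_shape, dtype=bool)
        dense.flat[self.indices] = True
        return dense

    @classmethod
    def from_dense(cls, dense: np.ndarray, parent_ref: str) -> "VoxelMask":
        return cls(np.flatnonzero(dense), parent_ref, dense.shape)


def mask_algebra(a: _IndexMask, b: _IndexMask, op: str) -> _IndexMask:
    """Exact set algebra on masks sharing a parent.

    ``op`` is one of ``union``, ``intersection``, ``difference``.
    """
    if a.parent_ref != b.parent_ref:
        raise ParentMismatchError(f"{a.parent_ref!r} vs {b.parent_ref!r}")
    if op == "union":
        idx = np.union1d(a.indices, b.indices)
    elif op == "intersection":
        idx = np.intersect1d(a.indices, b.indices)
    elif op == "difference":
        idx = np.setdiff1d(a.indices, b.indices)
    else:
        raise ValueError(f"unknown op {op!r}")
    cls = type(a)
    if isinstance(a, VoxelMask):
        return cls(idx, a.parent_ref, a.parent_shape)
    return cls(idx, a.parent_ref, a.parent_size)


# ---------------------------------------------------------------------------
# Explicit resampling opt-in
# ---------------------------------------------------------------------------

def resample_nearest(vol: Volume, template: Volume) -> Volume:
    """Nearest-neighbour resampling of ``vol`` onto ``template``'s grid.

    Provided as an explicit opt-in; grid mismatches otherwise raise.
    """
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in template.shape],
                             indexing="ij")
    world = template.voxel_to_world(
        np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]))
    src = vol.world_to_voxel(world)
    data = map_coordinates(vol.data, src.T, order=0, mode="nearest")
    valid = map_coordinates(vol.valid.astype(float), src.T, order=0,
                            mode="constant", cval=0.0) > 0.5
    return Volume(data.reshape(template.shape), template.voxel_size,
                  template.transform, space_tag=template.space_tag,
                  valid=valid.reshape(template.shape))


def surface_components(surface: CorticalSurface, mask: VertexMask):
    """Edge-connected components of a vertex mask; list of index arrays."""
    if len(mask) == 0:
        return []
    adj = surface.adjacency()[mask.indices][:, mask.indices]
    n_comp, labels = connected_components(adj, directed=False)
    return [mask.indices[labels == c] for c in range(n_comp)]
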