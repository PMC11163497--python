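"""Planar organ contours, voxel grids and the conversions between them.

Structures are represented the way radiotherapy structure sets store them:
ordered closed planar polygons on axial CT slices, in patient-space
millimetres (x/y in-plane, z superior-inferior).  A structure can also be
voxelised onto a regular grid for volume-overlap metrics, and a voxel mask
can be traced back into per-slice boundary polygons.

Voxel membership uses pixel-centre inclusion under the even-odd rule: a
voxel is set iff its centre lies inside an odd number of that slice's
polygons, with points on a polygon boundary counting as inside that
polygon.  This supports holes (annuli) and multi-part cross-sections with a
single deterministic convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage import measure

from ._exceptions import (
    DegenerateStructureError,
    ExtentError,
    GridMismatchError,
    SliceAlignmentError,
)

__all__ = [
    "ContourSlice",
    "ContourStack",
    "VoxelGrid",
    "BinaryMask",
    "StructurePair",
    "rasterize_contour_stack",
    "trace_mask_to_contours",
]

#: Absolute slack (mm) used when comparing z coordinates against grid planes.
_Z_EPS = 1e-9


def _as_polygon(vertices) -> np.ndarray:
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("polygon vertices must be an (n, 2) array of (x, y) mm")
    # drop an explicit closing vertex; closure is implicit
    if arr.shape[0] >= 2 and np.allclose(arr[0], arr[-1]):
        arr = arr[:-1]
    if arr.shape[0] < 3:
        raise ValueError("a polygon needs at least 3 distinct vertices")
    return arr


@dataclass(frozen=True)
class ContourSlice:
    """All polygons of one structure on one axial slice.

    Parameters
    ----------
    z : float
        Slice position in mm (superior-inferior axis).
    polygons : tuple of (n, 2) float arrays
        Closed planar polygons in mm; the last vertex implicitly connects
        back to the first.  Multiple polygons encode multi-part
        cross-sections or, under the even-odd rule, holes.
    """

    z: float
    polygons: tuple[np.ndarray, ...]

    def __post_init__(self):
        object.__setattr__(
            self, "polygons", tuple(_as_polygon(p) for p in self.polygons)
        )
        if not self.polygons:
            raise ValueError("a contour slice must hold at least one polygon")


@dataclass(frozen=True)
class ContourStack:
    """One organ's contours over an ordered stack of axial slices."""

    organ_name: str
    slices: tuple[ContourSlice, ...]

    def __post_init__(self):
        slices = tuple(
            s if isinstance(s, ContourSlice) else ContourSlice(*s) for s in self.slices
        )
        slices = tuple(sorted(slices, key=lambda s: s.z))
        zs = np.array([s.z for s in slices])
        if zs.size == 0:
            raise ValueError("a contour stack must hold at least one slice")
        if np.any(np.diff(zs) <= _Z_EPS):
            raise ValueError(
                f"duplicate or non-increasing slice z positions in {self.organ_name!r}"
            )
        object.__setattr__(self, "slices", slices)

    @property
    def z_positions(self) -> np.ndarray:
        return np.array([s.z for s in self.slices])

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    def xy_bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) over all polygons, in mm."""
        pts = np.vstack([p for s in self.slices for p in s.polygons])
        return (pts[:, 0].min(), pts[:, 1].min(), pts[:, 0].max(), pts[:, 1].max())


@dataclass(frozen=True)
class VoxelGrid:
    """Regular axis-aligned voxel lattice in patient-space mm.

    ``origin`` is the centre of voxel (0, 0, 0); voxel (i, j, k) is centred
    at ``origin + (i*dx, j*dy, k*dz)``.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self):
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing components must be > 0")
        if any(n < 1 for n in self.shape):
            raise ValueError("grid shape components must be >= 1")

    def x_centers(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.shape[0]) * self.spacing[0]

    def y_centers(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.shape[1]) * self.spacing[1]

    def z_planes(self) -> np.ndarray:
        return self.origin[2] + np.arange(self.shape[2]) * self.spacing[2]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def xy_extent(self) -> tuple[float, float, float, float]:
        """In-plane extent of the voxel lattice (voxel boundaries), mm."""
        ox, oy = self.origin[0], self.origin[1]
        dx, dy = self.spacing[0], self.spacing[1]
        nx, ny = self.shape[0], self.shape[1]
        return (ox - dx / 2, oy - dy / 2, ox + (nx - 0.5) * dx, oy + (ny - 0.5) * dy)

    def z_index(self, z: float) -> int:
        """Nearest grid plane for a slice at ``z``; error beyond dz/2."""
        dz = self.spacing[2]
        k = int(round((z - self.origin[2]) / dz))
        if k < 0 or k >= self.shape[2]:
            raise SliceAlignmentError(
                f"slice z={z:g} mm lies outside the grid's z range"
            )
        if abs(z - (self.origin[2] + k * dz)) > dz / 2 + _Z_EPS:
            raise SliceAlignmentError(
                f"slice z={z:g} mm does not align with any grid plane within dz/2"
            )
        return k


@dataclass
class BinaryMask:
    """Voxelised structure occupancy on a :class:`VoxelGrid`.

    ``voxels`` is a boolean array ordered (x, y, z) and must match
    ``grid.shape``.
    """

    grid: VoxelGrid
    voxels: np.ndarray

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.grid.shape:
            raise ValueError(
                f"voxel array shape {self.voxels.shape} != grid shape {self.grid.shape}"
            )

    @property
    def volume_mm3(self) -> float:
        return float(self.voxels.sum()) * self.grid.voxel_volume


@dataclass(frozen=True)
class StructurePair:
    """A gold-standard and an auto-generated contour of the same organ."""

    patient_id: str
    organ_name: str
    gold: ContourStack
    auto: ContourStack

    def __post_init__(self):
        if self.gold.organ_name != self.auto.organ_name:
            raise ValueError(
                "gold and auto stacks name different organs: "
                f"{self.gold.organ_name!r} vs {self.auto.organ_name!r}"
            )


def _covers_centers(polygon: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Boolean (len(xs), len(ys)) array: pixel centre inside-or-on ``polygon``."""
    poly = _ShapelyPolygon(polygon)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    # intersects == covers for point queries: boundary counts as inside
    return shapely.intersects_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)


def rasterize_contour_stack(stack: ContourStack, grid: VoxelGrid) -> BinaryMask:
    """Voxelise a contour stack onto ``grid`` by even-odd pixel-centre fill.

    Every slice of the stack must map to a grid plane within half a slice
    thickness, and every polygon must lie within the grid's in-plane
    extent.

    Raises
    ------
    ExtentError
        If any polygon vertex falls outside the grid's xy extent.
    SliceAlignmentError
        If a slice z has no grid plane within dz/2.
    """
    xmin, ymin, xmax, ymax = grid.xy_extent()
    voxels = np.zeros(grid.shape, dtype=bool)
    xs, ys = grid.x_centers(), grid.y_centers()
    for sl in stack.slices:
        k = grid.z_index(sl.z)
        parity = np.zeros((grid.shape[0], grid.shape[1]), dtype=bool)
        for poly in sl.polygons:
            if (
                poly[:, 0].min() < xmin - _Z_EPS
                or poly[:, 0].max() > xmax + _Z_EPS
                or poly[:, 1].min() < ymin - _Z_EPS
                or poly[:, 1].max() > ymax + _Z_EPS
            ):
                raise ExtentError(
                    f"polygon of {stack.organ_name!r} at z={sl.z:g} exceeds "
                    "the grid's in-plane extent"
                )
            # restrict the point-in-polygon test to the polygon's bbox window
            i0 = int(np.searchsorted(xs, poly[:, 0].min() - grid.spacing[0]))
            i1 = int(np.searchsorted(xs, poly[:, 0].max() + grid.spacing[0]))
            j0 = int(np.searchsorted(ys, poly[:, 1].min() - grid.spacing[1]))
            j1 = int(np.searchsorted(ys, poly[:, 1].max() + grid.spacing[1]))
            window = _covers_centers(poly, xs[i0:i1], ys[j0:j1])
            parity[i0:i1, j0:j1] ^= window
        voxels[:, :, k] |= parity
    return BinaryMask(grid=grid, voxels=voxels)


def trace_mask_to_contours(mask: BinaryMask, organ_name: str = "structure") -> ContourStack:
    """Trace per-slice boundary polygons from a binary mask.

    Boundaries are placed at the 0.5 iso-level between voxel centres
    (sub-pixel marching squares), so re-rasterising the traced stack onto
    the same grid reproduces the mask exactly.
    """
    grid = mask.grid
    ox, oy = grid.origin[0], grid.origin[1]
    dx, dy = grid.spacing[0], grid.spacing[1]
    slices: list[ContourSlice] = []
    for k in range(grid.shape[2]):
        plane = mask.voxels[:, :, k]
        if not plane.any():
            continue
        padded = np.pad(plane.astype(float), 1)
        polys = []
        for contour in measure.find_contours(padded, level=0.5):
            # padded index space -> mm; rows index x, cols index y
            pts = np.column_stack(
                [ox + (contour[:, 0] - 1) * dx, oy + (contour[:, 1] - 1) * dy]
            )
            if pts.shape[0] >= 4:  # closed loops repeat the first point
                polys.append(pts)
        if polys:
            slices.append(ContourSlice(z=grid.z_planes()[k], polygons=tuple(polys)))
    if not slices:
        raise DegenerateStructureError("mask is empty; nothing to trace")
    return ContourStack(organ_name=organ_name, slices=tuple(slices))


def fit_grid(
    stacks: Iterable[ContourStack],
    spacing: Sequence[float] = (1.0, 1.0, 2.0),
    margin_voxels: int = 2,
) -> VoxelGrid:
    """Build the smallest grid (plus margin) covering all ``stacks``.

    The z planes are anchored on the minimum slice z, so stacks generated
    on a common slice lattice align exactly; in-plane the origin is placed
    on a whole-spacing lattice for reproducibility.
    """
    stacks = list(stacks)
    if not stacks:
        raise ValueError("need at least one stack to fit a grid")
    dx, dy, dz = (float(s) for s in spacing)
    bounds = np.array([s.xy_bounds() for s in stacks])
    xmin, ymin = bounds[:, 0].min(), bounds[:, 1].min()
    xmax, ymax = bounds[:, 2].max(), bounds[:, 3].max()
    zs = np.concatenate([s.z_positions for s in stacks])
    zmin, zmax = zs.min(), zs.max()
    ox = np.floor(xmin / dx) * dx - margin_voxels * dx
    oy = np.floor(ymin / dy) * dy - margin_voxels * dy
    nx = int(np.ceil((xmax - ox) / dx)) + 1 + margin_voxels
    ny = int(np.ceil((ymax - oy) / dy)) + 1 + margin_voxels
    nz = int(round((zmax - zmin) / dz)) + 1
    return VoxelGrid(origin=(ox, oy, zmin), spacing=(dx, dy, dz), shape=(nx, ny, nz))


def check_same_grid(a: BinaryMask, b: BinaryMask) -> None:
    """Raise :class:`GridMismatchError` unless both masks share one grid."""
    ga, gb = a.grid, b.grid
    if not (
        np.allclose(ga.origin, gb.origin)
        and np.allclose(ga.spacing, gb.spacing)
        and ga.shape == gb.shape
    ):
        raise GridMismatchError("masks are defined on different voxel grids")
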