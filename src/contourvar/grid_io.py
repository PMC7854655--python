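"""Voxel grids, binary delineations, and the formats they arrive in.

All world coordinates are in the DICOM patient frame (LPS): +x = Left,
+y = Posterior, +z = Superior.  World units are millimetres; reported
volumes are cm^3 and reported distances cm.  Grids are axis-aligned with
the anatomical axes (oblique orientations are rejected), use 0-based voxel
indexing, and place the grid origin at the centre of voxel (0, 0, 0).

Observer delineations are accepted either as DICOM RT Structure Set
contour polygons (rasterized onto a caller-supplied grid) or as binary
NIfTI label volumes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pydicom
from matplotlib.path import Path as _PolygonPath

__all__ = [
    "VoxelGrid",
    "LabelVolume",
    "ContourPolygonSet",
    "ObserverCohort",
    "read_rtstruct",
    "rasterize",
    "read_mask",
    "write_mask",
    "write_probability_map",
    "build_cohort",
    "DIRECTIONS",
]

#: The six anatomical directions deviations are reported along.
DIRECTIONS = ("Right", "Left", "Anterior", "Posterior", "Superior", "Inferior")

# LPS axis codes: which world axis each code lives on, and the sign of that
# code's outward direction on the axis.
_WORLD_AXIS = {"R": 0, "L": 0, "A": 1, "P": 1, "I": 2, "S": 2}
_OUTWARD_SIGN = {"R": -1, "L": +1, "A": -1, "P": +1, "I": -1, "S": +1}
_POSITIVE_CODE = ("L", "P", "S")
_NEGATIVE_CODE = ("R", "A", "I")

# Tolerances, stated once.
ORIGIN_TOL_MM = 1e-4        # round-trip identity tolerance on origins
OBLIQUE_TOL = 1e-5          # relative off-axis tolerance when decoding affines
BINARY_ROUND_TOL = 1e-6     # mask voxel values must round to {0,1} within this
PLANAR_TOL_MM = 1e-3        # contour vertices must share a slice coordinate


@dataclass(frozen=True)
class VoxelGrid:
    """A shared axis-aligned sampling lattice.

    Parameters
    ----------
    shape : (nx, ny, nz) voxel counts per grid axis.
    spacing : strictly positive voxel spacing per grid axis, mm.
    origin : LPS world coordinate of the centre of voxel (0, 0, 0), mm.
    axcodes : anatomical direction of *increasing* index along each grid
        axis, e.g. ``("L", "P", "S")``; must cover the three axis pairs.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    axcodes: tuple[str, str, str] = ("L", "P", "S")

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "axcodes", tuple(str(c) for c in self.axcodes))
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be strictly positive, got {self.spacing}")
        bad = [c for c in self.axcodes if c not in _WORLD_AXIS]
        if bad:
            raise ValueError(f"unknown axis codes {bad}; expected letters from RLAPSI")
        world_axes = sorted(_WORLD_AXIS[c] for c in self.axcodes)
        if world_axes != [0, 1, 2]:
            raise ValueError(
                f"axcodes {self.axcodes} must cover the three anatomical axis "
                "pairs exactly once"
            )

    # -- coordinate frame ------------------------------------------------

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def grid_axis_for(self, world_axis: int) -> tuple[int, int]:
        """Grid axis sampling `world_axis`, and the sign of d(world)/d(index)."""
        for a, code in enumerate(self.axcodes):
            if _WORLD_AXIS[code] == world_axis:
                sign = +1 if code in _POSITIVE_CODE else -1
                return a, sign
        raise AssertionError("axcodes invariant violated")

    def axis_coordinates(self, grid_axis: int) -> np.ndarray:
        """World coordinate (mm, on this axis' world axis) of every voxel centre."""
        code = self.axcodes[grid_axis]
        sign = +1 if code in _POSITIVE_CODE else -1
        world_axis = _WORLD_AXIS[code]
        idx = np.arange(self.shape[grid_axis], dtype=float)
        return self.origin[world_axis] + sign * idx * self.spacing[grid_axis]

    @property
    def affine_lps(self) -> np.ndarray:
        """4x4 affine mapping voxel index -> LPS world mm."""
        A = np.zeros((4, 4))
        A[3, 3] = 1.0
        for a, code in enumerate(self.axcodes):
            w = _WORLD_AXIS[code]
            sign = +1 if code in _POSITIVE_CODE else -1
            A[w, a] = sign * self.spacing[a]
        A[:3, 3] = self.origin
        return A

    def approx_equal(self, other: "VoxelGrid", origin_tol: float = ORIGIN_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and self.axcodes == other.axcodes
            and np.allclose(self.spacing, other.spacing, atol=1e-9)
            and np.allclose(self.origin, other.origin, atol=origin_tol)
        )


@dataclass
class LabelVolume:
    """One binary delineation on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.shape != self.grid.shape:
            raise ValueError(
                f"occupancy shape {arr.shape} does not match grid {self.grid.shape}"
            )
        self.data = arr.astype(bool)

    @property
    def foreground_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cm3(self) -> float:
        return self.foreground_count * self.grid.voxel_volume_cm3

    @property
    def empty(self) -> bool:
        return not self.data.any()


@dataclass
class ContourPolygonSet:
    """Closed planar polygons of one structure, vertices in world mm (LPS).

    Each polygon is an (n, 3) array whose vertices share one slice
    coordinate (the axis with zero coordinate range).
    """

    polygons: list[np.ndarray]
    name: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        checked = []
        for k, poly in enumerate(self.polygons):
            pts = np.asarray(poly, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
                raise ValueError(f"polygon {k}: need an (n>=3, 3) vertex array")
            checked.append(pts)
        self.polygons = checked


@dataclass
class ObserverCohort:
    """All observers' delineations of one structure, on one shared grid."""

    grid: VoxelGrid
    observer_ids: tuple[str, ...]
    volumes: tuple[LabelVolume, ...]
    label: str = ""

    def __post_init__(self) -> None:
        self.observer_ids = tuple(str(o) for o in self.observer_ids)
        self.volumes = tuple(self.volumes)
        if len(self.observer_ids) != len(self.volumes):
            raise ValueError("one observer id per volume required")
        if len(self.volumes) < 2:
            raise ValueError("an observer cohort needs at least 2 observers")
        if len(set(self.observer_ids)) != len(self.observer_ids):
            raise ValueError(f"observer ids must be unique, got {self.observer_ids}")
        for oid, vol in zip(self.observer_ids, self.volumes):
            if not vol.grid.approx_equal(self.grid):
                raise ValueError(f"observer {oid!r} is not on the cohort grid")

    def __len__(self) -> int:
        return len(self.volumes)

    def stacked(self) -> np.ndarray:
        """(J, nx, ny, nz) boolean stack of all observers."""
        return np.stack([v.data for v in self.volumes], axis=0)

    def vote_counts(self) -> np.ndarray:
        """Per-voxel number of observers marking the voxel foreground."""
        return self.stacked().sum(axis=0)


# ---------------------------------------------------------------------------
# DICOM RT-STRUCT reading
# ---------------------------------------------------------------------------

def read_rtstruct(path: str | os.PathLike, roi_name: str) -> ContourPolygonSet:
    """Read one ROI's contour polygons from a DICOM RT Structure Set.

    ``roi_name`` is matched case-insensitively and must identify exactly one
    ROI; otherwise the error lists the available ROI names.  Vertices are
    returned in the DICOM patient coordinate system (LPS mm).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"RT-STRUCT file not found: {path}")
    ds = pydicom.dcmread(str(path))
    if "StructureSetROISequence" not in ds or "ROIContourSequence" not in ds:
        raise ValueError(f"{path} is not a DICOM RT Structure Set")

    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    matches = [n for n, name in names.items() if name.lower() == roi_name.lower()]
    if not matches:
        raise KeyError(
            f"ROI {roi_name!r} not found in {path.name}; "
            f"available ROIs: {sorted(names.values())}"
        )
    if len(matches) > 1:
        raise KeyError(
            f"ROI {roi_name!r} is ambiguous in {path.name}; "
            f"candidates: {[names[n] for n in matches]}"
        )
    roi_number = matches[0]

    polygons: list[np.ndarray] = []
    for rc in ds.ROIContourSequence:
        if int(rc.ReferencedROINumber) != roi_number:
            continue
        for item in getattr(rc, "ContourSequence", []):
            pts = np.asarray(item.ContourData, dtype=float).reshape(-1, 3)
            if pts.shape[0] < 3:
                raise ValueError(
                    f"contour item of ROI {names[roi_number]!r} has "
                    f"{pts.shape[0]} vertices (need >= 3)"
                )
            if _planar_axis(pts) is None:
                raise ValueError(
                    f"non-planar contour item in ROI {names[roi_number]!r}: "
                    "vertices do not share a slice coordinate"
                )
            polygons.append(pts)
    return ContourPolygonSet(polygons, name=names[roi_number], source=str(path))


def _planar_axis(pts: np.ndarray, tol: float = PLANAR_TOL_MM) -> int | None:
    """World axis along which all vertices agree, preferring z (axial slices)."""
    spans = np.ptp(pts, axis=0)
    for axis in (2, 1, 0):
        if spans[axis] <= tol:
            return axis
    return None


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize(polygons: ContourPolygonSet, grid: VoxelGrid) -> LabelVolume:
    """Rasterize planar polygons onto a grid.

    A voxel is foreground iff its centre lies inside an odd number of that
    slice's polygons (even–odd rule); no partial-volume weighting.  Each
    polygon is assigned to the nearest grid slice along its constant axis
    and must lie within half a slice spacing of it.
    """
    out = np.zeros(grid.shape, dtype=bool)
    for k, pts in enumerate(polygons.polygons):
        w_slice = _planar_axis(pts)
        if w_slice is None:
            raise ValueError(f"polygon {k}: vertices do not share a slice coordinate")
        a_slice, sign = grid.grid_axis_for(w_slice)
        coord = float(pts[:, w_slice].mean())
        f = sign * (coord - grid.origin[w_slice]) / grid.spacing[a_slice]
        idx = int(round(f))
        if abs(f - idx) > 0.5 + 1e-9 or not (0 <= idx < grid.shape[a_slice]):
            raise ValueError(
                f"polygon {k} at {coord:.3f} mm is not within half a slice "
                f"spacing of any grid slice plane (axis {'xyz'[w_slice]})"
            )

        ga, gb = [a for a in range(3) if a != a_slice]
        wa = _WORLD_AXIS[grid.axcodes[ga]]
        wb = _WORLD_AXIS[grid.axcodes[gb]]
        ca = grid.axis_coordinates(ga)
        cb = grid.axis_coordinates(gb)
        A, B = np.meshgrid(ca, cb, indexing="ij")
        centres = np.column_stack([A.ravel(), B.ravel()])
        verts = pts[:, [wa, wb]]
        ring = _PolygonPath(np.vstack([verts, verts[:1]]), closed=True)
        inside = ring.contains_points(centres).reshape(A.shape)

        slicer: list[slice | int] = [slice(None)] * 3
        slicer[a_slice] = idx
        out[tuple(slicer)] ^= inside  # even–odd across rings on one slice
    return LabelVolume(grid, out)


# ---------------------------------------------------------------------------
# NIfTI masks
# ---------------------------------------------------------------------------

_RAS_TO_LPS = np.diag([-1.0, -1.0, 1.0, 1.0])


def _grid_from_affine(affine_ras: np.ndarray, shape: Sequence[int]) -> VoxelGrid:
    A = (_RAS_TO_LPS @ affine_ras)[:3, :]
    M = A[:, :3]
    spacing = []
    axcodes = []
    for a in range(3):
        col = M[:, a]
        mags = np.abs(col)
        w = int(np.argmax(mags))
        if (mags.sum() - mags[w]) > OBLIQUE_TOL * mags[w]:
            raise ValueError(
                f"oblique affine: voxel axis {a} is not aligned with a single "
                f"anatomical axis (direction cosines {col / np.linalg.norm(col)})"
            )
        spacing.append(float(mags[w]))
        code = _POSITIVE_CODE[w] if col[w] > 0 else _NEGATIVE_CODE[w]
        axcodes.append(code)
    return VoxelGrid(
        shape=tuple(int(n) for n in shape),
        spacing=tuple(spacing),
        origin=tuple(float(x) for x in A[:, 3]),
        axcodes=tuple(axcodes),
    )


def read_mask(path: str | os.PathLike) -> LabelVolume:
    """Read a binary NIfTI mask; nonzero voxels become foreground.

    The affine must be axis-aligned; voxel values must round to {0, 1}
    within ``BINARY_ROUND_TOL``.
    """
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape[:3])
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    rounded = np.rint(data)
    if np.max(np.abs(data - rounded)) > BINARY_ROUND_TOL or not np.isin(
        rounded, (0.0, 1.0)
    ).all():
        raise ValueError(
            f"{path}: mask values must be binary "
            f"(0/1 within {BINARY_ROUND_TOL}); found values outside {{0, 1}}"
        )
    return LabelVolume(grid, rounded > 0.5)


def write_mask(volume: LabelVolume, path: str | os.PathLike) -> None:
    """Write a binary LabelVolume as a {0,1} NIfTI; inverse of :func:`read_mask`.

    Only binary masks are accepted — export probability maps with
    :func:`write_probability_map`.
    """
    if not isinstance(volume, LabelVolume):
        raise TypeError(
            f"write_mask writes binary LabelVolumes only, got {type(volume).__name__}; "
            "use write_probability_map for float maps"
        )
    _write_nifti(volume.data.astype(np.uint8), volume.grid, path)


def write_probability_map(data: np.ndarray, grid: VoxelGrid, path: str | os.PathLike) -> None:
    """Export a per-voxel probability map (values in [0, 1]) as float NIfTI."""
    arr = np.asarray(data, dtype=np.float32)
    if arr.shape != grid.shape:
        raise ValueError(f"map shape {arr.shape} does not match grid {grid.shape}")
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    _write_nifti(arr, grid, path)


def _write_nifti(arr: np.ndarray, grid: VoxelGrid, path: str | os.PathLike) -> None:
    path = Path(path)
    if not path.parent.is_dir():
        raise OSError(f"cannot write {path}: directory {path.parent} does not exist")
    affine_ras = _RAS_TO_LPS @ grid.affine_lps
    img = nib.Nifti1Image(arr, affine_ras)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _resample_nearest(volume: LabelVolume, grid: VoxelGrid) -> LabelVolume:
    """Nearest-neighbour resampling of voxel centres onto `grid` (binary-safe)."""
    src = volume.grid
    # For each source axis: which target axis feeds it, the source index
    # sampled at every index of that target axis, and an in-range mask.
    per_source_axis: list[tuple[int, np.ndarray, np.ndarray]] = [None] * 3  # type: ignore[list-item]
    for t in range(3):
        w = _WORLD_AXIS[grid.axcodes[t]]
        s_axis, s_sign = src.grid_axis_for(w)
        coords = grid.axis_coordinates(t)
        f = s_sign * (coords - src.origin[w]) / src.spacing[s_axis]
        idx = np.rint(f).astype(int)
        valid = (idx >= 0) & (idx < src.shape[s_axis])
        per_source_axis[s_axis] = (t, np.clip(idx, 0, src.shape[s_axis] - 1), valid)

    shape = grid.shape
    fancy = []
    valid_mask = np.ones(shape, dtype=bool)
    for s in range(3):
        t, idx, valid = per_source_axis[s]
        bshape = [1, 1, 1]
        bshape[t] = shape[t]
        fancy.append(idx.reshape(bshape))
        valid_mask = valid_mask & valid.reshape(bshape)
    data = volume.data[tuple(np.broadcast_arrays(*fancy))]
    data = data & valid_mask
    return LabelVolume(grid, data)


def build_cohort(
    volumes: Iterable[tuple[str, LabelVolume]],
    target_grid: VoxelGrid | str = "auto",
    label: str = "",
) -> ObserverCohort:
    """Place all observers' delineations on one common grid.

    ``target_grid="auto"`` uses the first volume's grid; other volumes are
    resampled by nearest neighbour of voxel centres.  An empty volume is an
    error naming the observer: it signals a missing delineation, and the
    caller must drop that observer explicitly (a cohort may legitimately be
    smaller than the full observer panel, e.g. 6 of 7 clinicians).
    """
    items = [(str(oid), vol) for oid, vol in volumes]
    if len(items) < 2:
        raise ValueError(f"need at least 2 observers, got {len(items)}")
    for oid, vol in items:
        if vol.empty:
            raise ValueError(
                f"observer {oid!r} supplied an empty delineation; drop this "
                "observer explicitly before building the cohort"
            )
    grid = items[0][1].grid if isinstance(target_grid, str) else target_grid
    placed = []
    for oid, vol in items:
        if vol.grid.approx_equal(grid):
            placed.append((oid, LabelVolume(grid, vol.data)))
        else:
            placed.append((oid, _resample_nearest(vol, grid)))
    return ObserverCohort(
        grid=grid,
        observer_ids=tuple(oid for oid, _ in placed),
        volumes=tuple(v for _, v in placed),
        label=label,
    )
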