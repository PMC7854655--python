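"""Shared fixtures and independent oracles for the test suite.

The oracle functions here deliberately avoid the package's own code
paths: point-in-polygon is a hand-written crossing-number test, the
conformity index enumerates observer pairs explicitly, and the STAPLE
E-step is evaluated with plain probability products (no log domain).
"""

from __future__ import annotations

import itertools

import numpy as np
import pydicom
import pytest
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import generate_uid

from contourvar import LabelVolume, ObserverCohort, VoxelGrid


# ---------------------------------------------------------------------------
# Grid / volume helpers
# ---------------------------------------------------------------------------

def small_grid(shape=(10, 10, 10), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
               axcodes=("L", "P", "S")) -> VoxelGrid:
    return VoxelGrid(shape=shape, spacing=spacing, origin=origin, axcodes=axcodes)


def volume_from_indices(grid: VoxelGrid, indices) -> LabelVolume:
    data = np.zeros(grid.shape, dtype=bool)
    for idx in indices:
        data[tuple(idx)] = True
    return LabelVolume(grid, data)


def cohort_from_masks(masks, grid=None, ids=None, label="test") -> ObserverCohort:
    masks = [np.asarray(m, dtype=bool) for m in masks]
    grid = grid or small_grid(shape=masks[0].shape)
    ids = ids or [f"obs{i + 1:02d}" for i in range(len(masks))]
    return ObserverCohort(
        grid=grid,
        observer_ids=tuple(ids),
        volumes=tuple(LabelVolume(grid, m) for m in masks),
        label=label,
    )


def random_cohort(rng, n_observers=None, shape=(10, 10, 10), rate=0.3):
    """Random nonempty binary masks on a shared small grid."""
    n = n_observers or int(rng.integers(3, 8))
    masks = []
    while len(masks) < n:
        m = rng.random(shape) < rate
        if m.any():
            masks.append(m)
    return cohort_from_masks(masks)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def point_in_polygon_crossing(x: float, y: float, poly: np.ndarray) -> bool:
    """Even–odd (crossing number) point-in-polygon test, hand-rolled."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


def ci_gen_bruteforce(cohort: ObserverCohort) -> float:
    """CI_gen by explicit enumeration of unordered observer pairs."""
    masks = [v.data for v in cohort.volumes]
    inter = 0
    union = 0
    for a, b in itertools.combinations(masks, 2):
        inter += int((a & b).sum())
        union += int((a | b).sum())
    return inter / union


def fleiss_kappa_direct(votes: np.ndarray, n_raters: int) -> float:
    """Fleiss' kappa from per-item positive-vote counts, two categories."""
    votes = np.asarray(votes, dtype=float)
    n = n_raters
    counts = np.stack([votes, n - votes], axis=1)  # (N, 2) per-category counts
    p_bar_i = ((counts * (counts - 1)).sum(axis=1)) / (n * (n - 1))
    p_bar = p_bar_i.mean()
    p_c = counts.sum(axis=0) / counts.sum()
    p_e = float((p_c ** 2).sum())
    return (p_bar - p_e) / (1 - p_e)


def staple_estep_bruteforce(D: np.ndarray, p, q, prior: float) -> np.ndarray:
    """Posterior W by plain probability products, one voxel at a time."""
    D = np.asarray(D, dtype=int)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    out = []
    for i in range(D.shape[1]):
        a = prior
        b = 1.0 - prior
        for j in range(D.shape[0]):
            if D[j, i]:
                a *= p[j]
                b *= 1.0 - q[j]
            else:
                a *= 1.0 - p[j]
                b *= q[j]
        out.append(a / (a + b))
    return np.array(out)


# ---------------------------------------------------------------------------
# DICOM RT-STRUCT fixture builder
# ---------------------------------------------------------------------------

def build_rtstruct(path, rois: dict[str, list[np.ndarray]]) -> None:
    """Write a minimal RT Structure Set with the given {roi name: polygons}.

    Each polygon is an (n, 3) vertex array in patient (LPS) mm.
    """
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.RTStructureSetStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = "synthetic"

    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for number, (name, polygons) in enumerate(rois.items(), start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = generate_uid()
        ds.StructureSetROISequence.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = []
        for poly in polygons:
            item = Dataset()
            item.ContourGeometricType = "CLOSED_PLANAR"
            pts = np.asarray(poly, dtype=float)
            item.NumberOfContourPoints = len(pts)
            item.ContourData = [float(v) for v in pts.ravel()]
            rc.ContourSequence.append(item)
        ds.ROIContourSequence.append(rc)

    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)


@pytest.fixture
def square_rtstruct(tmp_path):
    """RT-STRUCT with one square ROI 'CTV-Pelvis' on slice z = 2 mm."""
    square = np.array(
        [[-0.5, -0.5, 2.0], [9.5, -0.5, 2.0], [9.5, 9.5, 2.0], [-0.5, 9.5, 2.0]]
    )
    path = tmp_path / "rtstruct.dcm"
    build_rtstruct(path, {"CTV-Pelvis": [square]})
    return path
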