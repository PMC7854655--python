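"""Phantom structures and simulated observer cohorts with known truth.

Real multi-observer delineation studies rarely deposit their imaging, so
every pipeline stage here is exercised against simulated cohorts whose
generative parameters are known exactly:

* a geometric phantom (union of ellipsoids) stands in for the true
  structure — the default is a pelvis-scale body with inguinal "wings",
  ~600 cm^3, on a 96×96×60 grid at 2×2×3 mm;
* a voxel-wise Bernoulli rater marks true-foreground voxels with a known
  per-observer sensitivity and true-background voxels at one minus a known
  specificity, matching the STAPLE generative model, so performance-level
  recovery can be measured;
* a boundary-perturbation rater expands or contracts the truth by a known
  signed margin per anatomical direction (a separable bounding-box warp),
  so directional deviations have exact expected values.  Applied margins
  are quantized to whole voxels and recorded per observer.

Both simulators are pure functions of (inputs, seed): one named random
stream per cohort, with the observer index folded into the substream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .grid_io import (
    DIRECTIONS,
    LabelVolume,
    ObserverCohort,
    VoxelGrid,
    _OUTWARD_SIGN,
    _WORLD_AXIS,
)

__all__ = [
    "PhantomSpec",
    "BernoulliRaterSpec",
    "BoundaryRaterSpec",
    "BoundarySimulation",
    "make_phantom",
    "simulate_bernoulli_raters",
    "simulate_boundary_raters",
    "default_phantom_spec",
    "default_bernoulli_spec",
]


@dataclass(frozen=True)
class PhantomSpec:
    """A "true" structure as a union of ellipsoids.

    components : iterable of (centre_mm, semi_axes_mm) pairs in LPS world
        coordinates; all semi-axes strictly positive.
    """

    grid: VoxelGrid
    components: tuple[tuple[tuple[float, float, float], tuple[float, float, float]], ...]
    label: str = "phantom"

    def __post_init__(self) -> None:
        comps = tuple(
            (tuple(map(float, c)), tuple(map(float, r))) for c, r in self.components
        )
        object.__setattr__(self, "components", comps)
        if not comps:
            raise ValueError("a phantom needs at least one ellipsoid component")
        for _, radii in comps:
            if any(r <= 0 for r in radii):
                raise ValueError(f"semi-axes must be positive, got {radii}")


def make_phantom(spec: PhantomSpec) -> LabelVolume:
    """Voxel foreground iff the voxel centre lies inside any ellipsoid."""
    grid = spec.grid
    # world coordinates of voxel centres, broadcast per axis
    coords_world = [None, None, None]
    for a in range(3):
        w = _WORLD_AXIS[grid.axcodes[a]]
        bshape = [1, 1, 1]
        bshape[a] = grid.shape[a]
        coords_world[w] = grid.axis_coordinates(a).reshape(bshape)
    data = np.zeros(grid.shape, dtype=bool)
    for centre, radii in spec.components:
        m = (
            ((coords_world[0] - centre[0]) / radii[0]) ** 2
            + ((coords_world[1] - centre[1]) / radii[1]) ** 2
            + ((coords_world[2] - centre[2]) / radii[2]) ** 2
        ) <= 1.0
        data |= m
    if not data.any():
        raise ValueError("phantom is empty on this grid")
    return LabelVolume(grid, data)


def _bbox_region(mask: np.ndarray, margin: int) -> np.ndarray:
    region = np.zeros(mask.shape, dtype=bool)
    slices = []
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        idx = np.flatnonzero(np.any(mask, axis=other))
        lo = max(int(idx[0]) - margin, 0)
        hi = min(int(idx[-1]) + margin, mask.shape[axis] - 1)
        slices.append(slice(lo, hi + 1))
    region[tuple(slices)] = True
    return region


@dataclass(frozen=True)
class BernoulliRaterSpec:
    """Per-observer sensitivity/specificity for the voxel-wise error model."""

    sensitivities: tuple[float, ...]
    specificities: tuple[float, ...]
    margin_voxels: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        p = tuple(float(x) for x in self.sensitivities)
        q = tuple(float(x) for x in self.specificities)
        object.__setattr__(self, "sensitivities", p)
        object.__setattr__(self, "specificities", q)
        if len(p) != len(q) or len(p) < 2:
            raise ValueError("need matched sensitivity/specificity lists, >= 2 observers")
        # 1.0 is allowed so the noiseless perfect-agreement limit is expressible
        if not all(0 < x <= 1 for x in p + q):
            raise ValueError("probabilities must lie in (0, 1]")


def simulate_bernoulli_raters(
    truth: LabelVolume, spec: BernoulliRaterSpec, label: str = "bernoulli-cohort"
) -> ObserverCohort:
    """Independent voxel-wise Bernoulli observers of a true structure.

    Within the analysis region (truth bounding box + margin), observer j
    marks a true-foreground voxel with probability p_j and a true-background
    voxel with probability 1 − q_j, independently per voxel; outside the
    region everything is background.  Seeded and reproducible; an observer
    whose mask comes out empty is redrawn at most 5 times.
    """
    if truth.empty:
        raise ValueError("truth volume is empty")
    region = _bbox_region(truth.data, spec.margin_voxels)
    flat = region.ravel()
    t = truth.data.ravel()[flat]
    volumes = []
    ids = []
    for j, (p, q) in enumerate(zip(spec.sensitivities, spec.specificities)):
        rng = np.random.default_rng((int(spec.seed), j))
        for attempt in range(5):
            u = rng.random(t.size)
            marked = np.where(t, u < p, u < 1.0 - q)
            if marked.any():
                break
        else:
            raise RuntimeError(f"observer {j} produced an empty mask 5 times")
        data = np.zeros(truth.grid.shape, dtype=bool)
        data.ravel()[flat] = marked
        volumes.append(LabelVolume(truth.grid, data))
        ids.append(f"obs{j + 1:02d}")
    return ObserverCohort(
        grid=truth.grid, observer_ids=tuple(ids), volumes=tuple(volumes), label=label
    )


# ---------------------------------------------------------------------------
# Boundary-perturbation raters
# ---------------------------------------------------------------------------

def _as_direction_map(value: float | Mapping[str, float]) -> dict[str, float]:
    if isinstance(value, Mapping):
        out = {d: float(value.get(d, 0.0)) for d in DIRECTIONS}
        unknown = set(value) - set(DIRECTIONS)
        if unknown:
            raise ValueError(f"unknown directions {sorted(unknown)}")
        return out
    return {d: float(value) for d in DIRECTIONS}


@dataclass(frozen=True)
class BoundaryRaterSpec:
    """Observers who shift the structure's borders by random signed margins.

    ``mean_offset_mm`` and ``jitter_sd_mm`` give, per anatomical direction
    (or as one scalar for all six), the mean and SD of the signed margin an
    observer applies to that border; positive margins expand outward.  The
    defaults produce border differences on the centimetre scale typical of
    real multi-observer target-volume studies (extremes up to ~2 cm).
    """

    n_observers: int = 7
    mean_offset_mm: float | Mapping[str, float] = 0.0
    jitter_sd_mm: float | Mapping[str, float] = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_observers < 2:
            raise ValueError("need at least 2 observers")
        object.__setattr__(self, "mean_offset_mm", _as_direction_map(self.mean_offset_mm))
        object.__setattr__(self, "jitter_sd_mm", _as_direction_map(self.jitter_sd_mm))
        if any(v < 0 for v in self.jitter_sd_mm.values()):
            raise ValueError("jitter SDs must be nonnegative")


@dataclass(frozen=True)
class BoundarySimulation:
    """A boundary-perturbed cohort plus the margins actually applied.

    ``applied_margin_cm[observer_id][direction]`` is the voxel-quantized
    signed margin, i.e. the expected deviation of that observer's border
    from the truth in that direction.
    """

    cohort: ObserverCohort
    applied_margin_cm: dict[str, dict[str, float]]


def _warp_mask(
    truth: LabelVolume, end_margins: dict[int, list[int]]
) -> tuple[np.ndarray, dict[int, list[int]]]:
    """Expand/contract the truth bounding box by whole voxels per axis end.

    ``end_margins[axis] = [low_end, high_end]`` in voxels, positive =
    outward.  The mask is resampled by a separable linear rescale of its
    bounding box (nearest neighbour), so the extent change along each axis
    equals the applied margin exactly and axes do not interact.  Expansions
    are clipped at the grid edge; the margins actually applied are returned
    alongside the mask.  A contraction that collapses the support is an
    error.
    """
    shape = truth.grid.shape
    fancy = []
    valid = np.ones(shape, dtype=bool)
    applied: dict[int, list[int]] = {}
    for a in range(3):
        other = tuple(x for x in range(3) if x != a)
        idx = np.flatnonzero(np.any(truth.data, axis=other))
        lo, hi = int(idx[0]), int(idx[-1])
        m_lo = min(end_margins[a][0], lo)           # clip expansion at edge
        m_hi = min(end_margins[a][1], shape[a] - 1 - hi)
        new_lo, new_hi = lo - m_lo, hi + m_hi
        if new_hi < new_lo:
            raise ValueError(
                f"margins ({m_lo}, {m_hi}) voxels collapse axis {a} "
                f"support [{lo}, {hi}]"
            )
        applied[a] = [m_lo, m_hi]
        i = np.arange(shape[a])
        if new_hi == new_lo:
            f = np.full(shape[a], float(lo))
        else:
            f = lo + (i - new_lo) * (hi - lo) / (new_hi - new_lo)
        src = np.clip(np.rint(f).astype(int), lo, hi)
        ok = (i >= new_lo) & (i <= new_hi)
        bshape = [1, 1, 1]
        bshape[a] = shape[a]
        fancy.append(src.reshape(bshape))
        valid &= ok.reshape(bshape)
    out = truth.data[tuple(np.broadcast_arrays(*fancy))]
    return out & valid, applied


def _direction_axis_end(grid: VoxelGrid, direction: str) -> tuple[int, int]:
    """Grid axis and end (0 = low index, 1 = high index) a direction points at."""
    code = direction[0]
    w = _WORLD_AXIS[code]
    a, sign = grid.grid_axis_for(w)
    return a, (1 if sign * _OUTWARD_SIGN[code] > 0 else 0)


def simulate_boundary_raters(
    truth: LabelVolume, spec: BoundaryRaterSpec, label: str = "boundary-cohort"
) -> BoundarySimulation:
    """Observers whose borders deviate from the truth by known signed margins.

    Each observer draws one signed margin per direction
    (mean_offset + jitter_sd · N(0,1), quantized to whole voxels of the
    relevant spacing) and the truth is warped accordingly.  The applied
    extreme margin per direction is returned so expected deviations are
    known exactly (up to the voxel quantization).
    """
    if truth.empty:
        raise ValueError("truth volume is empty")
    grid = truth.grid
    volumes = []
    ids = []
    applied: dict[str, dict[str, float]] = {}
    for j in range(spec.n_observers):
        rng = np.random.default_rng((int(spec.seed), j))
        end_margins = {a: [0, 0] for a in range(3)}
        dir_of_end: dict[tuple[int, int], str] = {}
        for d in DIRECTIONS:
            a, end = _direction_axis_end(grid, d)
            m_mm = spec.mean_offset_mm[d] + spec.jitter_sd_mm[d] * rng.standard_normal()
            end_margins[a][end] = int(np.rint(m_mm / grid.spacing[a]))
            dir_of_end[(a, end)] = d
        data, applied_vox = _warp_mask(truth, end_margins)
        applied_j = {
            dir_of_end[(a, end)]: applied_vox[a][end] * grid.spacing[a] / 10.0
            for a in range(3)
            for end in (0, 1)
        }
        applied_j = {d: applied_j[d] for d in DIRECTIONS}  # canonical key order
        if not data.any():
            raise ValueError(f"observer {j} mask is empty after boundary warp")
        oid = f"obs{j + 1:02d}"
        volumes.append(LabelVolume(grid, data))
        ids.append(oid)
        applied[oid] = applied_j
    cohort = ObserverCohort(
        grid=grid, observer_ids=tuple(ids), volumes=tuple(volumes), label=label
    )
    return BoundarySimulation(cohort=cohort, applied_margin_cm=applied)


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def default_phantom_spec(label: str = "pelvis-phantom") -> PhantomSpec:
    """Pelvis-scale two-component phantom, ~600 cm^3 on a 2×2×3 mm grid."""
    shape = (96, 96, 60)
    spacing = (2.0, 2.0, 3.0)
    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
    grid = VoxelGrid(shape=shape, spacing=spacing, origin=origin)
    components = (
        ((0.0, 0.0, 25.0), (54.0, 45.0, 40.0)),    # pelvic body
        ((0.0, 12.0, -35.0), (65.0, 30.0, 24.0)),  # inguinal wings
    )
    return PhantomSpec(grid=grid, components=components, label=label)


def default_bernoulli_spec(seed: int = 0, n_observers: int = 7) -> BernoulliRaterSpec:
    """Seven observers with sensitivities 0.85–0.95 and specificities 0.93–0.99."""
    p = tuple(np.linspace(0.85, 0.95, n_observers))
    q = tuple(np.linspace(0.93, 0.99, n_observers))
    return BernoulliRaterSpec(sensitivities=p, specificities=q, seed=seed)
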