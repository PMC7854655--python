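"""Signed maximum boundary deviations along the six anatomical directions.

Each observer's contour is compared with the consensus reference by the
difference of whole-volume outward extents per direction: the deviation
in, say, the Superior direction is the most superior voxel-centre
coordinate of the observer minus that of the reference, regardless of the
slice either extreme lies on.  Positive values mean the observer's border
extends farther outward than the reference in that direction.

Extents are taken over voxel centres (not outer faces); the half-voxel
offset is common to observer and reference and cancels in every reported
deviation.  All deviations are reported in cm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid_io import DIRECTIONS, LabelVolume, ObserverCohort, _OUTWARD_SIGN, _WORLD_AXIS

__all__ = [
    "DeviationRecord",
    "DeviationSummary",
    "directional_extent",
    "deviations",
    "deviation_summary",
]


@dataclass(frozen=True)
class DeviationRecord:
    """One observer's six signed boundary deviations (cm) vs. the reference."""

    observer_id: str
    deviations_cm: dict[str, float]

    def __post_init__(self) -> None:
        if tuple(self.deviations_cm) != DIRECTIONS:
            raise ValueError(
                f"deviations must carry exactly the six directions {DIRECTIONS}"
            )


@dataclass(frozen=True)
class DeviationSummary:
    """Per-direction mean and sample SD (cm) across a cohort's observers."""

    mean_cm: dict[str, float]
    sd_cm: dict[str, float]
    n_observers: int

    def __post_init__(self) -> None:
        if tuple(self.mean_cm) != DIRECTIONS or tuple(self.sd_cm) != DIRECTIONS:
            raise ValueError("summary must carry exactly the six directions")
        if any(s < 0 for s in self.sd_cm.values()):
            raise ValueError("standard deviations must be nonnegative")


def directional_extent(volume: LabelVolume, direction: str) -> float:
    """Outward extent (cm) of the foreground along one anatomical direction.

    The maximum, over foreground voxel centres, of the world coordinate
    measured outward along the direction's axis — e.g. the Superior extent
    is the max z (LPS) and the Right extent the max (−x).
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    if volume.empty:
        raise ValueError("directional extent of an empty volume is undefined")
    code = direction[0]
    world_axis = _WORLD_AXIS[code]
    outward = _OUTWARD_SIGN[code]
    grid_axis, _ = volume.grid.grid_axis_for(world_axis)
    other = tuple(a for a in range(3) if a != grid_axis)
    hit = np.any(volume.data, axis=other)
    coords = volume.grid.axis_coordinates(grid_axis)[hit]
    return float(np.max(outward * coords)) / 10.0


def deviations(
    observer: LabelVolume, reference: LabelVolume, observer_id: str = ""
) -> DeviationRecord:
    """Signed extent differences observer − reference per direction, cm.

    Positive means the observer's contour is larger than the reference in
    that direction.
    """
    if not observer.grid.approx_equal(reference.grid):
        raise ValueError("observer and reference must share one grid")
    devs = {
        d: directional_extent(observer, d) - directional_extent(reference, d)
        for d in DIRECTIONS
    }
    return DeviationRecord(observer_id=observer_id, deviations_cm=devs)


def deviation_summary(
    cohort: ObserverCohort, reference: LabelVolume
) -> tuple[list[DeviationRecord], DeviationSummary]:
    """Per-observer records plus per-direction mean ± sample SD across observers."""
    records = [
        deviations(vol, reference, observer_id=oid)
        for oid, vol in zip(cohort.observer_ids, cohort.volumes)
    ]
    table = np.array(
        [[r.deviations_cm[d] for d in DIRECTIONS] for r in records]
    )
    summary = DeviationSummary(
        mean_cm={d: float(m) for d, m in zip(DIRECTIONS, table.mean(axis=0))},
        sd_cm={d: float(s) for d, s in zip(DIRECTIONS, table.std(axis=0, ddof=1))},
        n_observers=len(records),
    )
    return records, summary
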