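"""STAPLE consensus estimation for multi-observer binary delineations.

Simultaneous Truth and Performance Level Estimation treats the true
structure as a hidden binary field T and each observer j's delineation
D_j as a noisy view of it, governed by a sensitivity p_j = P(D_j=1 | T=1)
and a specificity q_j = P(D_j=0 | T=0).  An expectation–maximization loop
alternates between the per-voxel posterior W_i = P(T_i=1 | D, p, q) and
maximum-likelihood updates of (p, q).  Thresholding W at a confidence
level (0.80 by default) yields the consensus reference contour.

Estimation runs over an *analysis region* — the bounding box of the
observers' union plus a margin — because specificity (and every voxel-wise
agreement statistic downstream) depends on how much plain background is
included; the region is therefore carried in the result and logged in
every report.

The EM here uses a spatially homogeneous prior f(T=1) (no Markov-random-
field smoothing) and is fully deterministic: identical inputs yield
bit-identical parameter trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .grid_io import LabelVolume, ObserverCohort, VoxelGrid

__all__ = [
    "StapleConfig",
    "StapleResult",
    "DegenerateConsensusError",
    "analysis_region",
    "staple_e_step",
    "run_staple",
    "consensus_mask",
]


class DegenerateConsensusError(RuntimeError):
    """Raised when thresholding the probability map leaves no voxels."""


@dataclass(frozen=True)
class StapleConfig:
    """EM settings.

    prior_mode : ``"volume-fraction"`` sets f(T=1) to the mean over
        observers of (foreground voxels / region voxels); a float in (0, 1)
        fixes it.
    tolerance : convergence threshold on the max absolute change of W.
    max_iterations : EM iteration cap.
    epsilon : clip applied to p, q (and the initial values) so perfect
        agreement cannot produce degenerate log-likelihoods.
    margin_voxels : analysis-region margin around the union bounding box.
    """

    prior_mode: str | float = "volume-fraction"
    tolerance: float = 1e-7
    max_iterations: int = 100
    epsilon: float = 1e-6
    margin_voxels: int = 5

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be a positive integer")
        if not (0 < self.epsilon < 0.5):
            raise ValueError("epsilon must lie in (0, 0.5)")
        if self.margin_voxels < 0:
            raise ValueError("margin_voxels must be nonnegative")
        if not isinstance(self.prior_mode, str):
            if not (0 < float(self.prior_mode) < 1):
                raise ValueError("fixed prior must lie strictly in (0, 1)")
        elif self.prior_mode != "volume-fraction":
            raise ValueError(f"unknown prior mode {self.prior_mode!r}")


@dataclass
class StapleResult:
    """Consensus probability map plus per-observer performance levels.

    ``probability_map`` holds W over the full grid; voxels outside
    ``region`` carry W = 0 by convention.
    """

    grid: VoxelGrid
    probability_map: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    prior: float
    region: np.ndarray
    iterations: int
    converged: bool
    observer_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def region_voxels(self) -> int:
        return int(self.region.sum())


def analysis_region(cohort: ObserverCohort, margin_voxels: int = 5) -> np.ndarray:
    """Bounding box of the observers' union, padded by ``margin_voxels``.

    Returned as a boolean mask on the cohort grid, clipped at grid edges.
    """
    if margin_voxels < 0:
        raise ValueError("margin_voxels must be nonnegative")
    union = np.logical_or.reduce([v.data for v in cohort.volumes])
    region = np.zeros(cohort.grid.shape, dtype=bool)
    slices = []
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        hit = np.any(union, axis=other)
        idx = np.flatnonzero(hit)
        lo = max(int(idx[0]) - margin_voxels, 0)
        hi = min(int(idx[-1]) + margin_voxels, cohort.grid.shape[axis] - 1)
        slices.append(slice(lo, hi + 1))
    region[tuple(slices)] = True
    return region


def staple_e_step(
    D: np.ndarray, p: np.ndarray, q: np.ndarray, prior: float
) -> np.ndarray:
    """One E-step: posterior W_i = P(T_i = 1 | D, p, q), in the log domain.

    ``D`` is a (J, N) binary matrix of observer decisions over region voxels.
    """
    D = np.asarray(D, dtype=float)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    lp, l1p = np.log(p), np.log1p(-p)
    lq, l1q = np.log(q), np.log1p(-q)
    # log a_i = log f1 + sum_j [D_ij log p_j + (1-D_ij) log(1-p_j)]
    log_a = np.log(prior) + l1p.sum() + (lp - l1p) @ D
    # log b_i = log f0 + sum_j [D_ij log(1-q_j) + (1-D_ij) log q_j]
    log_b = np.log1p(-prior) + lq.sum() + (l1q - lq) @ D
    return expit(log_a - log_b)


def run_staple(
    cohort: ObserverCohort,
    config: StapleConfig | None = None,
    region: np.ndarray | None = None,
) -> StapleResult:
    """Estimate the consensus probability map and observer performance levels.

    Initial sensitivities and specificities start near 1 (0.9999, pulled
    inside the epsilon clip range); voxels outside the analysis region are
    assigned W = 0.
    """
    config = config or StapleConfig()
    if region is None:
        region = analysis_region(cohort, config.margin_voxels)
    region = np.asarray(region, dtype=bool)
    if region.shape != cohort.grid.shape:
        raise ValueError(
            f"region shape {region.shape} does not match cohort grid "
            f"{cohort.grid.shape}"
        )
    flat = region.ravel()
    D = np.stack([v.data.ravel()[flat] for v in cohort.volumes]).astype(float)
    J, N = D.shape
    if N == 0:
        raise ValueError("analysis region is empty")

    eps = config.epsilon
    if isinstance(config.prior_mode, str):
        prior = float(D.mean())  # mean over observers of foreground fraction
        prior = float(np.clip(prior, eps, 1 - eps))
    else:
        prior = float(config.prior_mode)

    init = min(0.9999, 1 - eps)
    p = np.full(J, init)
    q = np.full(J, init)
    W = np.full(N, prior)
    converged = False
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        W_new = staple_e_step(D, p, q, prior)
        assert np.isfinite(W_new).all()
        sum_w = W_new.sum()
        sum_not_w = (1.0 - W_new).sum()
        # M-step; a degenerate posterior mass is impossible with a clipped
        # prior strictly inside (0,1), so guard with assertions only.
        assert sum_w > 0 and sum_not_w > 0
        p = np.clip(D @ W_new / sum_w, eps, 1 - eps)
        q = np.clip((1.0 - D) @ (1.0 - W_new) / sum_not_w, eps, 1 - eps)
        delta = float(np.max(np.abs(W_new - W)))
        W = W_new
        if delta < config.tolerance:
            converged = True
            break

    wmap = np.zeros(cohort.grid.shape)
    wmap.ravel()[flat] = W
    return StapleResult(
        grid=cohort.grid,
        probability_map=wmap,
        sensitivities=p,
        specificities=q,
        prior=prior,
        region=region,
        iterations=iterations,
        converged=converged,
        observer_ids=cohort.observer_ids,
    )


def consensus_mask(result: StapleResult, level: float = 0.80) -> LabelVolume:
    """Threshold the probability map at a confidence level (inclusive >=).

    The 0.80 default gives the reference contour the agreement and
    deviation statistics are measured against.
    """
    if not (0 < level <= 1):
        raise ValueError(f"confidence level must lie in (0, 1], got {level}")
    mask = (result.probability_map >= level) & result.region
    if not mask.any():
        raise DegenerateConsensusError(
            f"consensus at level {level} is empty — degenerate consensus"
        )
    return LabelVolume(result.grid, mask)
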