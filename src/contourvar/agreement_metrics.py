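"""Agreement statistics for a multi-observer delineation cohort.

Covers the generalized conformity index, per-observer volume statistics,
the apparent (chance-uncorrected) voxel-wise agreement, Fleiss-type
multi-rater kappa with its large-sample z test, performance-level
summaries from a STAPLE fit, and the conventional interpretation bands
for both conformity and kappa.

Voxel-wise statistics (apparent agreement, kappa, and — through the
STAPLE fit — specificity) are computed over an analysis region and change
with it, so every summary embeds a description of the region it used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import comb
from scipy.stats import norm

from .consensus_staple import StapleResult, consensus_mask
from .grid_io import ObserverCohort

__all__ = [
    "AgreementSummary",
    "KappaResult",
    "UndefinedKappaError",
    "ci_gen",
    "classify_ci",
    "volume_stats",
    "apparent_agreement",
    "overall_kappa",
    "classify_kappa",
    "performance_summary",
    "summarize_agreement",
]


class UndefinedKappaError(ValueError):
    """All region voxels fall in a single category, so chance agreement is 1."""


# ---------------------------------------------------------------------------
# Generalized conformity index
# ---------------------------------------------------------------------------

def ci_gen(cohort: ObserverCohort) -> float:
    r"""Generalized conformity index.

    CI_gen = (sum over unordered observer pairs of |A_i ∩ A_j|)
           / (sum over unordered observer pairs of |A_i ∪ A_j|),

    a single ratio of the two sums — not the mean of pairwise Jaccard
    indices.  Voxel counts are used, so the value is spacing-independent.
    1 means perfect conformity; values below 0.5 are conventionally read
    as weak agreement and values >= 0.7 as acceptable.
    """
    votes = cohort.vote_counts()
    sizes = np.array([v.foreground_count for v in cohort.volumes], dtype=float)
    # sum_pairs |A_i ∩ A_j| = sum over voxels of C(votes, 2)
    inter_sum = float(comb(votes, 2, exact=False).sum())
    # sum_pairs |A_i ∪ A_j| = (J-1) * sum_j |A_j| - sum_pairs |A_i ∩ A_j|
    union_sum = (len(cohort) - 1) * sizes.sum() - inter_sum
    return inter_sum / union_sum


def classify_ci(value: float) -> str:
    """Interpretation band: < 0.5 "weak", >= 0.7 "acceptable", else "intermediate"."""
    if not (0 <= value <= 1):
        raise ValueError(f"CI_gen must lie in [0, 1], got {value}")
    if value < 0.5:
        return "weak"
    if value >= 0.7:
        return "acceptable"
    return "intermediate"


# ---------------------------------------------------------------------------
# Volume statistics
# ---------------------------------------------------------------------------

def volume_stats(cohort: ObserverCohort) -> dict[str, float]:
    """Min/max/mean/sample-SD of observer volumes plus union and intersection, cm^3."""
    vols = np.array([v.volume_cm3 for v in cohort.volumes])
    votes = cohort.vote_counts()
    vox = cohort.grid.voxel_volume_cm3
    return {
        "volume_min": float(vols.min()),
        "volume_max": float(vols.max()),
        "volume_mean": float(vols.mean()),
        "volume_sd": float(vols.std(ddof=1)),
        "volume_union": float((votes > 0).sum() * vox),
        "volume_intersection": float((votes == len(cohort)).sum() * vox),
    }


# ---------------------------------------------------------------------------
# Voxel-wise agreement
# ---------------------------------------------------------------------------

def _pair_agreement_fractions(cohort: ObserverCohort, region: np.ndarray) -> np.ndarray:
    """Per region voxel: fraction of unordered observer pairs that agree."""
    region = np.asarray(region, dtype=bool)
    if region.shape != cohort.grid.shape:
        raise ValueError("region shape does not match cohort grid")
    if not region.any():
        raise ValueError("analysis region is empty")
    n = len(cohort)
    k = cohort.vote_counts()[region].astype(float)
    return (comb(k, 2) + comb(n - k, 2)) / comb(n, 2)


def apparent_agreement(cohort: ObserverCohort, region: np.ndarray) -> float:
    """Mean over region voxels of the fraction of agreeing observer pairs.

    Chance-uncorrected; identical to the observed-agreement term P̄ of the
    Fleiss kappa computation.
    """
    return float(_pair_agreement_fractions(cohort, region).mean())


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    z: float
    p_value: float
    observed_agreement: float
    chance_agreement: float


def overall_kappa(cohort: ObserverCohort, region: np.ndarray) -> KappaResult:
    r"""Fleiss' multi-rater kappa over region voxels, two categories (in/out).

    With n observers, N region voxels and per-voxel positive-vote counts
    k_i:  P̄ = mean_i [C(k_i,2)+C(n-k_i,2)] / C(n,2),  P̄_e = p̄₁² + p̄₀²,
    κ = (P̄ − P̄_e)/(1 − P̄_e).  The z statistic uses Fleiss' large-sample
    variance under the null of chance agreement; the p-value is the
    two-sided normal tail.  κ = 1 iff agreement is perfect with both
    categories present; if only one category occurs in the region, chance
    agreement is 1 and kappa is undefined (raised, not NaN-propagated).
    """
    region = np.asarray(region, dtype=bool)
    n = len(cohort)
    frac = _pair_agreement_fractions(cohort, region)
    k = cohort.vote_counts()[region].astype(float)
    N = k.size
    p1 = float(k.mean()) / n
    p0 = 1.0 - p1
    p_bar = float(frac.mean())
    p_e = p1 * p1 + p0 * p0
    if p_e >= 1.0:
        raise UndefinedKappaError(
            "every region voxel is in a single category; chance agreement is 1 "
            "and kappa is undefined"
        )
    kappa = (p_bar - p_e) / (1.0 - p_e)
    p_cubed = p1 ** 3 + p0 ** 3
    var = (
        2.0
        / (N * n * (n - 1))
        * (p_e - (2 * n - 3) * p_e ** 2 + 2 * (n - 2) * p_cubed)
        / (1.0 - p_e) ** 2
    )
    z = kappa / math.sqrt(var)
    p_value = 2.0 * float(norm.sf(abs(z)))
    return KappaResult(float(kappa), float(z), p_value, p_bar, p_e)


def classify_kappa(value: float) -> str:
    """Landis–Koch interpretation band for a kappa value."""
    if value > 1:
        raise ValueError(f"kappa cannot exceed 1, got {value}")
    if value < 0:
        return "poor"
    if value <= 0.20:
        return "slight"
    if value <= 0.40:
        return "fair"
    if value <= 0.60:
        return "moderate"
    if value <= 0.80:
        return "substantial"
    return "almost perfect"


# ---------------------------------------------------------------------------
# Performance levels and the combined summary
# ---------------------------------------------------------------------------

def performance_summary(result: StapleResult) -> dict[str, float]:
    """Sample mean and SD (n−1 denominator) of sensitivities and specificities."""
    p = np.asarray(result.sensitivities)
    q = np.asarray(result.specificities)
    return {
        "sensitivity_mean": float(p.mean()),
        "sensitivity_sd": float(p.std(ddof=1)),
        "specificity_mean": float(q.mean()),
        "specificity_sd": float(q.std(ddof=1)),
    }


@dataclass
class AgreementSummary:
    """One structure's agreement summary (volumes in cm^3)."""

    volume_min: float
    volume_max: float
    volume_mean: float
    volume_sd: float
    volume_union: float
    volume_intersection: float
    consensus_volume: float
    consensus_level: float
    overall_kappa: float
    kappa_z: float
    kappa_p: float
    apparent_agreement: float
    sensitivity_mean: float
    sensitivity_sd: float
    specificity_mean: float
    specificity_sd: float
    ci_gen: float
    kappa_band: str
    ci_band: str
    n_observers: int
    region_voxels: int
    region_description: str

    def __post_init__(self) -> None:
        ordered = (
            self.volume_intersection,
            self.volume_min,
            self.volume_mean,
            self.volume_max,
            self.volume_union,
        )
        if not all(a <= b + 1e-9 for a, b in zip(ordered, ordered[1:])):
            raise ValueError(f"volume ordering invariant violated: {ordered}")
        if not (0 <= self.ci_gen <= 1):
            raise ValueError("ci_gen out of [0, 1]")
        if not (0 <= self.apparent_agreement <= 1):
            raise ValueError("apparent agreement out of [0, 1]")
        if self.overall_kappa > 1:
            raise ValueError("kappa exceeds 1")

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_agreement(
    cohort: ObserverCohort,
    result: StapleResult,
    level: float = 0.80,
) -> AgreementSummary:
    """Assemble the full per-structure agreement summary.

    Combines volume statistics, CI_gen, apparent agreement, Fleiss kappa
    with its significance test, STAPLE performance levels, the consensus
    volume at ``level``, and the interpretation bands.  The analysis region
    of ``result`` is reused for every voxel-wise statistic.
    """
    region = result.region
    kres = overall_kappa(cohort, region)
    vols = volume_stats(cohort)
    perf = performance_summary(result)
    cons = consensus_mask(result, level)
    margin_note = (
        f"union bounding box + margin; {int(region.sum())} voxels "
        f"of {int(np.prod(cohort.grid.shape))}"
    )
    return AgreementSummary(
        **vols,
        consensus_volume=cons.volume_cm3,
        consensus_level=level,
        overall_kappa=kres.kappa,
        kappa_z=kres.z,
        kappa_p=kres.p_value,
        apparent_agreement=kres.observed_agreement,
        **perf,
        ci_gen=ci_gen(cohort),
        kappa_band=classify_kappa(kres.kappa),
        ci_band=classify_ci(ci_gen(cohort)),
        n_observers=len(cohort),
        region_voxels=int(region.sum()),
        region_description=margin_note,
    )
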