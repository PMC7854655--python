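# Methods

## The estimation problem

Several observers delineate the same anatomical structure on a common CT
grid. Each delineation is a binary voxel field `D_j`. We want (i) a
principled consensus structure to serve as a reference, (ii) summary
statistics of how much the observers agree, and (iii) where — along which
anatomical borders — the disagreement concentrates.

## STAPLE consensus

The hidden true structure is a binary field `T`. Observer `j` sees it
through a voxel-wise channel with sensitivity `p_j = P(D_j=1 | T=1)` and
specificity `q_j = P(D_j=0 | T=0)`; voxels are conditionally independent
given `T`. EM alternates:

* **E-step** — per voxel `i`, with prior `f₁ = f(T=1)`:

  `a_i = f₁ · Π_j p_j^{D_ij} (1−p_j)^{1−D_ij}`,
  `b_i = (1−f₁) · Π_j (1−q_j)^{D_ij} q_j^{1−D_ij}`,
  `W_i = a_i / (a_i + b_i)`,

  evaluated in the log domain (the products over observers become a dot
  product of the vote vector with `log p − log(1−p)` terms, so the E-step
  is one matrix–vector multiply).

* **M-step** — `p_j = Σ_i W_i D_ij / Σ_i W_i`,
  `q_j = Σ_i (1−W_i)(1−D_ij) / Σ_i (1−W_i)`.

Assumptions worth stating: the prior is spatially homogeneous (no
Markov-random-field smoothing term — spatial regularity enters only
through the structure of the delineations themselves), observers are
conditionally independent, and performance is spatially constant per
observer.

Numerical choices:

* `p, q` are clipped to `[ε, 1−ε]` with `ε = 1e−6`; without the clip,
  perfect agreement drives parameters to 1 and the log-likelihood
  degenerates. Initial values are `min(0.9999, 1−ε)`.
* The prior defaults to the **volume fraction**: the mean over observers
  of (foreground voxels / region voxels); a fixed scalar in (0, 1) can be
  supplied instead.
* Convergence is declared when the max absolute change of `W` falls
  below `1e−7` (the map drives every downstream output, so convergence
  is monitored on it rather than on the parameters), with a cap of 100
  iterations. On the default simulated cohorts EM converges in ~8
  iterations.
* The EM contains no randomness: identical inputs give bit-identical
  trajectories.

The consensus reference contour is `W ≥ level` with `level = 0.80` by
default; the threshold is inclusive, and an empty result raises rather
than silently returning a degenerate reference.

### The analysis region

Specificity, apparent agreement and kappa all depend on how much plain
background is evaluated: over a whole CT they are inflated toward 1.
Estimation therefore runs on the bounding box of the observers' union
expanded by a margin (default 5 voxels per side, clipped at grid edges).
`W` is 0 outside the region by convention. Because the choice changes the
voxel-wise statistics, the region (voxel count and definition) is
embedded in every summary and in the run log.

## Agreement statistics

* **Generalized conformity index** — the ratio of the summed pairwise
  intersections to the summed pairwise unions over all unordered observer
  pairs. Computed from vote counts: `Σ_pairs |∩| = Σ_i C(k_i, 2)` where
  `k_i` is the positive-vote count at voxel `i`, and
  `Σ_pairs |∪| = (J−1) Σ_j |A_j| − Σ_pairs |∩|`. Voxel counts make the
  value spacing-independent; it is invariant under observer permutation
  and uniform grid refinement. Interpretation bands: < 0.5 weak,
  ≥ 0.7 acceptable, otherwise intermediate.
* **Apparent agreement** — mean over region voxels of the fraction of
  agreeing unordered observer pairs; identical to the observed-agreement
  term `P̄` of the Fleiss computation (asserted equal in the tests).
* **Overall kappa** — Fleiss' multi-rater kappa on the binary in/out
  labels over the region: `κ = (P̄ − P̄_e)/(1 − P̄_e)` with
  `P̄_e = p̄₁² + p̄₀²`. The z statistic uses Fleiss' large-sample variance
  under the null of chance agreement and the p-value is the two-sided
  normal tail; published analyses of this kind do not always print their
  kappa variant or test, so the formula used here is stated explicitly
  and the region it was computed over is logged with it. If the region
  contains a single category, chance agreement is 1 and kappa is raised
  as undefined rather than propagated as NaN. Bands: < 0 poor, 0–0.20
  slight, 0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80 substantial,
  0.81–1.00 almost perfect.
* **Volume statistics and performance levels** — sample SD (n−1
  denominator) throughout.

## Directional boundary deviations

For direction `d` (Right, Left, Anterior, Posterior, Superior, Inferior)
the *outward extent* of a volume is the maximum over foreground voxel
centres of the world coordinate measured outward along that direction's
axis (LPS frame: Superior extent = max z, Right extent = max −x). An
observer's deviation in direction `d` is its extent minus the reference's
extent, in cm; positive means the observer's border lies farther
outward. The two extremes may lie on different slices — the statistic is
a whole-volume bound, deliberately not slice-matched.

Conventions: voxel centres (not outer faces) define extents; the
half-voxel offset is shared by observer and reference and cancels in
every deviation. Reported to 2 decimals (cm) in the CSV outputs. A
surface-mesh distance variant is deliberately out of scope.

## Geometry and I/O

The world frame is LPS (DICOM patient convention); grids are axis-aligned
with the anatomical axes, 0-based, with the origin at the centre of voxel
(0,0,0); oblique orientations are rejected outright. NIfTI affines (RAS)
are converted on read/write. Rasterization of RT-STRUCT polygons uses
voxel centres and the even–odd rule with no partial-volume weighting
(matching common treatment-planning rasterizers); a polygon is assigned
to the nearest slice if within half a slice spacing. Resampling between
grids is nearest-neighbour on voxel centres, which preserves binarity;
cohorts in one study normally share geometry, so the path is rarely
exercised and the CLI never invents a grid spacing. Volumes are reported
in cm³, distances in cm, world coordinates in mm.

## Synthetic cohorts

The generator provides the study conditions the tests and the acceptance
script run under:

* **Phantom** — union of ellipsoids; the default is a two-component
  "pelvic body + inguinal wings" shape of ≈ 600 cm³ (≈ 50 000 foreground
  voxels) on a 96×96×60 grid at 2×2×3 mm, matching the volume scale of
  real pelvic target structures while simulating in well under a second.
* **Bernoulli raters** — within the truth's bounding box + margin,
  observer `j` marks true-foreground voxels with probability `p_j` and
  true-background voxels with probability `1−q_j`, independently. This is
  exactly the STAPLE generative model, so it measures parameter recovery:
  the default panel of 7 observers spans sensitivities 0.85–0.95 and
  specificities 0.93–0.99, and recovery errors are ~0.002 (sensitivity)
  and ~0.015 (specificity) mean absolute. The residual specificity bias
  is structural: background voxels that several observers mark by chance
  are absorbed into the estimated truth, slightly flattering `q̂`.
  `p = q = 1` is allowed so the noiseless perfect-agreement limit is
  expressible exactly.
* **Boundary raters** — each observer draws one signed margin per
  direction (mean offset + jitter SD, default 0 ± 6 mm, quantized to
  whole voxels) and the truth is warped by a separable linear rescale of
  its bounding box per axis. Separability means each axis' extents change
  independently and by exactly the applied margin, so expected deviations
  are known without tolerance; margins are uniform per direction rather
  than a spatially varying field for the same reason. Expansions are
  clipped at the grid edge and the margins *actually applied* are
  recorded per observer (returned as a `BoundarySimulation`). The 6 mm
  jitter produces border differences up to ~2 cm, the dynamic range seen
  in real multi-observer target-volume studies.

Both simulators are pure functions of (inputs, seed): one stream per
cohort with the observer index folded into the substream, so replicates
are portable.

What the simulations do *not* emulate: spatially correlated disagreement
(real observers disagree along anatomically ambiguous borders, not
voxel-independently), systematic inter-observer style differences beyond
a scalar margin, deformation, or CT intensities. Passing tests therefore
demonstrate algorithmic correctness under the stated error models, not
clinical performance.

## Problem sizes

The test suite and the acceptance script run the full-scale default
phantom (≈ 320 k region voxels, 7 observers); STAPLE parameter recovery
is verified over 20 seeded replicates in the tests and summarized over 5
replicates in the acceptance script — EM converges in ~8 iterations per
replicate, so both complete in seconds.

## Known limitations

* No Markov-random-field spatial prior; the homogeneous-prior EM is the
  whole consensus model, and no MRF hook is provided.
* Single-label (binary) structures only; no multi-label STAPLE.
* Oblique and curved reformats are rejected, not resampled.
* Whether published "kappa-corrected agreement" values from
  treatment-planning toolkits are Fleiss' kappa exactly is generally not
  documentable; comparisons across implementations should compare the
  logged region and formula, not just the number.
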