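# contourvar

Interobserver contour-variability analysis for radiotherapy structure
sets: STAPLE consensus estimation, agreement metrics, and signed
directional boundary deviations.

When several clinicians delineate the same clinical target volume (CTV)
on a planning CT, their contours disagree — and the size and direction of
that disagreement is what delineation guidelines need to know.
`contourvar` takes a cohort of binary delineations of one structure
(DICOM RT-STRUCT polygons or NIfTI masks on a shared voxel grid) and
produces:

* a **consensus structure**: the STAPLE (Simultaneous Truth and
  Performance Level Estimation) expectation–maximization algorithm
  estimates a per-voxel probability map `W` of the hidden true structure
  together with each observer's sensitivity `p_j` and specificity `q_j`;
  thresholding `W` at the 80 % confidence level gives the reference
  contour (the "CTV-80");
* **agreement statistics**: the generalized conformity index

  CI_gen = Σ_{pairs i,j} |A_i ∩ A_j| / Σ_{pairs i,j} |A_i ∪ A_j|,

  a single ratio over all unordered observer pairs (not a mean of
  pairwise Jaccard indices); volume min/max/mean/SD/union/intersection;
  the apparent (chance-uncorrected) voxel-wise agreement; Fleiss'
  multi-rater kappa with its large-sample z test; and the conventional
  interpretation bands (Landis–Koch for kappa; CI_gen < 0.5 weak,
  ≥ 0.7 acceptable);
* **directional boundary deviations**: for each observer and each of the
  six anatomical directions (Right, Left, Anterior, Posterior, Superior,
  Inferior), the signed difference of whole-volume outward extents
  between the observer's contour and the consensus, in cm — positive
  when the observer's border lies farther outward. The extremes need not
  lie on the same axial plane.

Because voxel-wise statistics (kappa, apparent agreement, specificity)
depend on how much plain background is evaluated, all of them are
computed over an explicit *analysis region* (union bounding box plus a
margin) that is embedded in every report.

A fully tested synthetic-data module generates phantom structures and
simulated observer cohorts with known generative parameters, so the whole
pipeline is verifiable without clinical data.

## Worked example

Seven simulated observers of a ~600 cm³ pelvis-scale phantom, with
voxel-wise Bernoulli errors (sensitivities 0.85–0.95, specificities
0.93–0.99):

```python
from contourvar import (
    default_phantom_spec, default_bernoulli_spec, make_phantom,
    simulate_bernoulli_raters, run_staple, summarize_agreement,
)

truth = make_phantom(default_phantom_spec())
cohort = simulate_bernoulli_raters(truth, default_bernoulli_spec(seed=0))
result = run_staple(cohort)
summary = summarize_agreement(cohort, result, level=0.80)
```

which yields

```
observers            : 7
volume mean ± SD     : 618.09 ± 19.45 cm^3
volume union / inter : 1074.44 / 287.77 cm^3
consensus (80%)      : 601.82 cm^3
CI_gen               : 0.659 (intermediate)
overall kappa        : 0.756 (substantial), p = 0
apparent agreement   : 0.934
mean sensitivity     : 0.900 ± 0.036
mean specificity     : 0.977 ± 0.013
```

The estimated sensitivities/specificities recover the generative values,
the 80 %-level consensus volume (601.8 cm³) matches the 602.1 cm³ truth,
and kappa reads "substantial" on the Landis–Koch bands.

Directional deviations are best illustrated with the boundary-perturbation
simulator, whose observers shift each border by a known signed margin
(SD 6 mm here):

```python
from contourvar import (
    BoundaryRaterSpec, simulate_boundary_raters, consensus_mask,
    deviation_summary,
)

sim = simulate_boundary_raters(truth, BoundaryRaterSpec(n_observers=7, seed=0))
reference = consensus_mask(run_staple(sim.cohort), 0.80)
records, devs = deviation_summary(sim.cohort, reference)
```

```
deviation Right      : +0.09 ± 0.16 cm
deviation Left       : -0.14 ± 0.36 cm
deviation Anterior   : -0.23 ± 0.53 cm
deviation Posterior  : -0.46 ± 0.69 cm
deviation Superior   : +0.04 ± 0.36 cm
deviation Inferior   : -0.26 ± 0.82 cm
```

— per-direction mean ± SD across observers, centimetre scale, signed
outward.

## Command line

```bash
contourvar simulate --out study/ --seed 0        # phantom + 7 observers + manifest
contourvar analyze study/manifest.json --out report/ --level 0.8 --margin 5
contourvar consensus study/manifest.json --out cons/           # STAPLE only
contourvar metrics study/manifest.json --reference study/truth.nii.gz --out m/
```

`analyze` writes `summary.csv`/`summary.json` (one row per structure:
volumes, CI_gen, kappa, performance levels), `deviations.csv` (one row
per observer plus mean/SD rows, six direction columns in cm),
`consensus_<structure>.nii.gz`, `wmap_<structure>.nii.gz`, and
`run_log.json` with the exact configuration. Reruns on the same inputs
produce byte-identical CSV/JSON.

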