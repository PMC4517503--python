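# Methods

## Problem setting

Several expert readers contour the left ventricle (endocardial and
epicardial boundaries) on every short-axis slice of a cine CMR study, at
end-diastole (ED; epicardium and endocardium) and end-systole (ES;
endocardium only).  Readers differ systematically — each centre's
protocol places contours consistently tighter or wider — so derived
volumes and mass carry per-reader bias.  The pipeline fuses the readers'
contours into consensus contours, derives LV function from any contour
stack, and quantifies inter-reader and reader-consensus agreement.

Everything operates on contours in physical millimetre coordinates; no
pixel intensities are read.  Pixel (0,0) is centred at (dx/2, dy/2);
slice index 0 is the most apical contoured slice; polygons are stored
counter-clockwise and must be simple with nonzero area.

## Rasterization

A contour becomes a binary decision map on a grid supersampled by an
integer factor (default 4, configurable): a cell is foreground iff its
centre is inside the polygon under the even-odd rule.  Boundary-touching
centres are resolved by a half-open convention (an edge claims rows with
`y_lo <= y_c < y_hi`; the strict `x_c < x_edge` test keeps left edges in
and right edges out), which makes the map deterministic and tie-free and
covers an axis-aligned, grid-aligned square exactly.  At factor 4 the
mask area of a convex contour with diameter >= 10 pixels is within 1% of
the polygon area (test-enforced), and mask area converges to polygon area
as the factor grows.

## STAPLE fusion

Per (frame, slice, surface) key, independently, reader masks are fused by
Simultaneous Truth and Performance Level Estimation.  The E-step computes
the consensus probability per cell from the current sensitivities p_j and
specificities q_j and a scalar prior; the M-step re-estimates p_j
(weighted fraction of consensus-foreground cells the reader marked) and
q_j (weighted fraction of consensus-background cells the reader left
unmarked).  Numerical and design choices:

- **Initialization**: W⁰ is the pixel-voting map (per-cell fraction of
  readers marking the cell).
- **Prior**: scalar, fixed at the ROI mean of W⁰ and not re-estimated.
  A fixed scalar prior keeps the EM stable and the log-likelihood
  monotone; a spatial prior is out of scope.
- **ROI restriction**: EM runs only inside the union of reader masks
  dilated by a physical margin (default 5 mm, exact Euclidean distance
  transform).  Without it, unbounded background drives every specificity
  to 1 and washes out the sensitivity weighting.  The ROI is recorded in
  the result; cells outside it get W = 0.
- **Convergence**: mean absolute change in W below 1e-6, at most 100
  iterations (both configurable).  Non-convergence returns the last
  iterate flagged `converged=False`.
- **Clamping**: p, q and the prior are clamped to [1e-6, 1 - 1e-6] inside
  the E-step so perfectly agreeing readers do not produce log(0); all
  products are computed in log space.  A zero M-step denominator (no
  consensus mass of one class) yields the upper clamp value with a
  warning — the vacuous reading of a proportion with an empty reference
  class.
- **Pattern compression**: cells with identical reader-decision vectors
  share the same W, so the EM runs over the <= 2^R distinct patterns with
  cell-count weights.  This is an exact reformulation of the per-cell
  iteration (the unit tests check the M-step against brute-force per-cell
  summation) and makes the EM cost independent of grid size.
- **Consensus extraction**: threshold W at 0.5, keep the largest
  4-connected component, trace its boundary by marching squares at the
  supersampled resolution, and lightly simplify (tolerance of a quarter
  supersampled cell).  Thresholds and component policy are package
  choices made for determinism and single-contour output.
- **Slice inclusion**: a consensus contour is produced only where at
  least `min_readers` (default 4) readers contoured the key; other keys
  are reported as skipped.

The per-iteration observed-data log-likelihood is recorded and is
non-decreasing (tolerance 1e-9, property-tested); a converged result is a
fixed point of one further M/E cycle.

## Volumetrics

Volumes use slice summation: Σ (cavity area × inter-slice distance),
where the distance is the centre-to-centre slice spacing (equal to the
thickness for contiguous stacks, larger for gapped ones).  Missing slices
contribute nothing — no interpolation or partial-slice correction — so
slice omission appears as volume bias, which is part of the phenomenon
being measured.  Mass is (ED epicardial volume − EDV) × 1.05 g/ml; EF is
100 (EDV − ESV)/EDV; the ES frame of a cine sequence is the argmin of
mid-ventricular cavity area with ties resolved to the earliest frame.

Areas can be computed from the polygon (shoelace) or from the
supersampled mask.  The pipeline default is polygon areas for reader and
consensus stacks, with the consensus polygon itself derived from the
fused mask; the mask backend exists for studies of discretization
behaviour.  The two differ by the rasterization error (< 1% for
realistic contours).

## Agreement statistics

For index F in {EDV, ESV, LVM, EF} on an R-reader x N-case grid:

- inter-reader RMSE `E_i = sqrt( Σ_{j≠i} Σ_k (F_i(k) − F_j(k))² / (N(R−1)) )`
- consensus RMSE `E_C = sqrt( Σ_j Σ_k (F_C(k) − F_j(k))² / (NR) )`
- Bland-Altman per reader against the consensus: bias = mean difference,
  precision = sample SD of the differences (N−1 denominator — the
  estimator choice is ours), limits of agreement at bias ± 1.96 SD.
- per-case consensus standard error: RMS reader deviation from the
  consensus divided by sqrt(R).  This is one defensible reading of a
  "standard error between readers and consensus" and is isolated in a
  single function so it can be swapped.

Missing cells are disallowed rather than pairwise-deleted: the analysis
assumes every reader analyzed every case.

## Synthetic cohorts

The phantom is a truncated-ellipsoid stack: the endocardial radius
follows `r(s) ∝ sqrt(1 − (1 − u_s)²)` from apex to base with small
monotonicity-preserving jitter, plus mild low-order angular irregularity
(Fourier modes 2-3, amplitude ~1.5%, shared across slices and frames).
The target EDV fixes the scale; the wall thickness is solved from a
target mass (quadratic in w); ES scales the endocardium in-plane by
`sqrt(1 − EF/100)`, so the phantom's EF is exact by construction.
Phenotype parameter bands:

| phenotype     | EDV (ml)  | EF (%)  | LVM (g)  |
|---------------|-----------|---------|----------|
| healthy       | 110-180   | 55-68   | 80-140   |
| dilated       | 240-360   | 18-35   | 130-190  |
| hypertrophic  | 110-190   | 55-70   | 150-195  |

chosen so a default mixed cohort spans the volume and mass range of a
mixed-pathology clinical population.  Default cohort shape: 15 cases,
7 readers, 10-15 contiguous slices of 8 or 10 mm, isotropic in-plane
pixels of 1.1-2.1 mm, 180 mm field of view.

Simulated readers displace each true contour radially about its centroid
by a per-surface systematic bias plus smooth zero-mean noise (constant
term and Fourier modes 1-3; pointwise SD ~0.87 of the nominal
`noise_sd_mm`), and omit the most apical and/or most basal slice with a
small probability.  Draws producing self-intersections, collapsed radii
or un-nested ED surfaces are redrawn (up to 10 attempts).  The default
panel uses zero-mean endocardial biases spanning ±1.5 mm and epicardial
biases ±1.2 mm of mixed sign, noise SD 0.8 mm and skip probability 0.05;
on a typical ventricle this induces volume-bias spreads of roughly
±20-45 ml and mass biases of roughly ±50 g — the order observed between
real reading centres.  Reader sensitivity/specificity are emergent from
the geometry, never set directly.

All randomness flows from a single cohort seed through spawned
`SeedSequence` children (one per case, then one per entity), recorded in
a manifest; reruns are byte-identical.

What the generator does *not* emulate: pixel intensities and
contrast-dependent ambiguity, papillary/trabecular anatomy, outflow-tract
shape, long-axis motion (ES changes are purely in-plane), or
reader-specific slice-selection habits beyond end-slice omission.
Passing tests therefore demonstrate correctness of the fusion,
volumetric and statistical machinery under the assumed error structure —
radial systematic bias plus smooth noise — not performance on clinical
images.

## Problem sizes in the checks

The end-to-end distributional check runs 20 independent cohorts of
15 cases x 7 readers (the default study shape) and requires the
consensus RMSE to beat every reader RMSE on all four indices in at least
18 of them; one cohort takes ~10 s on one CPU.  The STAPLE
parameter-recovery experiment uses 7 raters corrupting a known truth on a
10^4-cell ROI (sensitivity 0.95, specificity 0.98) over 10 seeds, with
mean absolute recovery error required below 0.02.

## Known limitations

- The consensus contour is re-extracted from a 4x raster, so
  consensus-linked statistics on a noiseless cohort are zero only up to
  discretization (~0.3% of area per slice), while reader-only statistics
  are exactly zero.
- The wall thickness of a phantom is constant per case; real hearts show
  regional thinning (e.g. infarct scar).
- STAPLE here is binary and per-slice; no multi-label fusion, spatial
  prior or inter-slice regularization.
- The per-case consensus SE estimator is a convention (see above), not a
  derived sampling variance.
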