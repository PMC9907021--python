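# Methods

## Data model and geometry

A `BinaryMask` is a 3D boolean array with axes (slice, row, column),
positive per-axis spacing in mm and an origin giving the physical
coordinate of the center of voxel (0, 0, 0); voxel (i, j, k) sits at
`origin + (i, j, k) * spacing`. NIfTI affines must be axis-aligned
(diagonal up to sign): negative diagonal entries are honoured by flipping
the stored array and shifting the origin to the new corner voxel, and any
oblique rotation is rejected rather than resampled — resampling would
silently change every metric value. All masks of one (case, ROI) must
share a grid exactly (spacing within 1e-4 mm, origin within 1e-3 mm);
observers may be missing for an ROI, and all per-ROI analyses use only
the observers present. Masks pass through as drawn: no hole filling or
component cleanup is applied, since the handling of such masks is a
property of the data, not of the benchmark.

## Agreement metrics

* **DSC** = 2|A∩B| / (|A|+|B|) by voxel counts. Two empty masks score
  1.0 (perfect agreement on absence), exactly one empty scores 0.0; this
  keeps pairwise matrices total while the flag is visible in outputs.
* **Surfaces** are boundary voxels under 6-connectivity against the
  background, with the grid edge counted as background, and distances are
  Euclidean between boundary-voxel centers in physical mm
  (distance-transform semantics, not subvoxel meshes). A KD-tree answers
  nearest-surface queries exactly, which is why the test suite can demand
  agreement with an O(n²) brute-force oracle to 1e-9 mm.
* **MSD** is the mean of the two directed mean surface distances; **HD95**
  the maximum of the two directed 95th percentiles (linear interpolation).
* **Surface DSC (SDSC)** at tolerance τ is the element-count-weighted
  fraction of both surfaces lying within τ of the other surface.
  Distances exactly equal to τ count as within (a 1e-12 relative guard
  absorbs float noise at the boundary).
* **APL** (added path length) is computed slice-wise in 2D: reference
  boundary pixels (4-connectivity in-plane) farther than τ from the 3D
  test surface, summed over axial slices and scaled by the mean in-plane
  pixel spacing. An empty test mask yields the total reference boundary
  length. τ defaults to the ROI's SDSC tolerance.
* **Volume** is voxel count × voxel volume, reported in cc.

Surface metrics are undefined on empty masks; such values are recorded
missing, logged, and excluded from medians and tests, never imputed.

## STAPLE consensus

Each observer *j* is modelled as a per-voxel Bernoulli rater with
sensitivity *p_j* and specificity *q_j*. EM alternates

* E-step: `W_i = a_i / (a_i + b_i)` with
  `a_i = g · Π_j [p_j if D_ij else 1-p_j]`,
  `b_i = (1-g) · Π_j [q_j if ¬D_ij else 1-q_j]`,
* M-step: `p_j = Σ_{D_ij=1} W_i / Σ W_i`,
  `q_j = Σ_{D_ij=0} (1-W_i) / Σ (1-W_i)`,

with products accumulated in log space and *p*, *q*, *g* clamped to
[1e-7, 1-1e-7]. Choices that the algorithm statement leaves open, fixed
here:

* **Prior** *g*: a global scalar equal to the mean observer foreground
  proportion over the analysis region, computed once (a fixed-γ mode is
  retained for sensitivity studies).
* **Analysis region**: the union bounding box of all input masks dilated
  by 5 voxels. Specificity estimates otherwise depend on how much empty
  background the grid happens to carry; the posterior is re-embedded into
  the full grid (W = 0 outside) and is insensitive to the margin beyond
  the minimum (tested: margin 5 vs 10 differ by < 1e-6 mean |ΔW|).
* **Initialization** p₀ = q₀ = 0.99999; **convergence** on mean |ΔW|
  < 1e-6 with a 100-iteration cap, both reported with the full trace.
* **Consensus** binarizes W at 0.95 (ties included, ≥), the standard
  threshold for clinical consensus contours. A single input mask
  short-circuits to itself with p = q = 1 − ε.

`STAPLE(masks).fit()` returns a results object carrying the probability
map, consensus mask, per-rater (p̂, q̂), convergence trace and a
`summary()` table; `majority_vote` is kept as the unweighted baseline.
On cohorts that satisfy the Bernoulli assumptions exactly the EM recovers
the generating (p, q) closely (tested: 8 raters, p = 0.90, q = 0.99,
within ±0.03 / ±0.01) and identifies an adversarial (inverted) rater by
its sub-0.5 sensitivity. An independent implementation (SimpleITK's
STAPLE filter) serves as a cross-check in the test suite, never as the
implementation.

## Thresholds, tolerances and group comparison

The acceptability bar for a (ROI, metric) is the **median pairwise value
among experts**; the SDSC tolerance τ for an ROI is the **median pairwise
expert MSD**. Both use experts only and are undefined with fewer than two
usable experts. Crossing is `value ≥ bar` for similarity metrics and
`value ≤ bar` for distance metrics, ties crossing. Expert and nonexpert
pairwise distributions are compared with a two-sided Mann-Whitney U test
(exact when both n ≤ 8 and tie-free, tie-corrected normal approximation
otherwise) and banded ns / * / ** / *** / **** at 0.05 / 0.01 / 0.001 /
0.0001.

## Bootstrap minimum-observer experiments

For each subset size *k* (defaults 2–10, 15, 20, 25, capped at the
available nonexperts), 100 iterations draw *k* nonexperts **with
replacement** — duplicates enter STAPLE as independent raters — fuse
them, and score the consensus against the expert consensus. The curve
reports per-size mean and percentile 95% CI. The minimum observer count
is the smallest *k* whose **mean** crosses the bar (the plotted line, not
a CI bound), first crossing even if the curve later dips; a curve whose
terminal mean falls more than δ = 0.01 below its peak is flagged
nonsaturating. RNG streams are derived per (ROI, size) from one master
seed, so ROIs and sizes can run in any order, or in parallel, with
bitwise-identical results.

## Synthetic cohorts

The generator stands in for the patient images and observer pools of a
real multi-observer study:

* **Truth shapes**: spheres, ellipsoids, or smoothed-noise blobs
  (thresholded to a target volume, largest 6-connected component kept),
  deterministic given a seed.
* **Bernoulli observers** realize the STAPLE generative model exactly —
  the closed-loop test of the EM fit.
* **Boundary observers** perturb the truth's signed distance field with a
  smooth random field (white noise convolved with a Gaussian of width
  `smoothness_mm`, rescaled to σ mm), plus a constant margin composed of
  a group bias (`bias_mm`, positive inflates) and a per-observer style
  offset drawn from N(0, `style_sd_mm`²). The smooth field models
  slice-to-slice hand wobble; the style offset models systematic
  tight-vs-generous contouring differences between observers, which
  dominate real interobserver variability and which per-voxel noise
  cannot produce — without it, sub-voxel zero-mean noise leaves expert
  pairwise DSC near 0.95–0.99, far above the 0.75–0.9 range typical of
  expert panels, and the acceptability bar becomes pathologically tight.
* Seed streams are keyed by (observer index, ROI index) under one master
  seed, so adding observers never changes existing observers' masks, and
  whole cohorts round-trip bitwise through NIfTI + manifest CSV.

The **study-like preset** puts a 16 mm-radius structure on a
(36, 64, 64)-voxel grid at (2, 1, 1) mm — planning-CT-like slices — with
8 experts (σ = 1 mm) and 25 nonexperts (σ = 2 mm), both with a 2 mm style
spread, and two ROIs: one where nonexperts are only noisier and one where
they additionally over-segment by +1.5 mm. Under these conditions the
expert bar lands near DSC 0.87, the nonexpert median near 0.80, the
unbiased bootstrap crosses the bar at k ≈ 3–5, and the biased nonexpert
consensus is 1.1–1.6× the expert consensus volume — the qualitative
regime of real expert/nonexpert panels. What passing these tests does
*not* show: real anatomy is not spherical, real style differences are not
spatially constant, and real expert pools share guideline-induced
correlations; conclusions about specific organs require the real cohort
data.

## Pipeline and problem sizes

`CohortBenchmark(cohort, config).fit()` runs tolerance derivation,
pairwise IOV, thresholds, Mann-Whitney comparison, expert/nonexpert
STAPLE, consensus-vs-bar evaluation, the bootstrap curve and, optionally,
skill stratification (case-level score = unweighted mean observer-vs-
expert-consensus metric over the observer's ROIs; tertile classes split
at the 1/3 and 2/3 linear-interpolation quantiles, left-open/right-closed,
which splits 124 distinct scores 42/41/41 and 66 scores 22/22/22) and
cross-case Pearson correlation. One ROI's degenerate data never aborts a
run; failures are recorded per (case, ROI) and the exit code reflects
them. All outputs are pure functions of (cohort, config, seed).

Tests and the acceptance script run on 40–64-voxel grids with bootstrap
sizes truncated to the small-k range where crossings occur and 25–40
iterations per size — enough for the bootstrap means to be stable at the
asserted tolerances while a full run stays within minutes on one CPU.
Library defaults remain at the full experimental scale (sizes 2–10, 15,
20, 25; 100 iterations).

## Known limitations

* Surface metrics use boundary-voxel centers; packages that interpolate
  subvoxel surfaces will differ by up to about half a voxel diagonal.
* The STAPLE prior and convergence rule are not standardized across
  implementations; consensus masks at the 0.95 threshold are robust to
  these choices, but bitwise agreement with other tools is not promised.
* The Mann-Whitney exact method is used only for small tie-free samples;
  pairwise DSC values can tie at 1.0 in near-duplicate groups, where the
  asymptotic tie-corrected p is reported instead.
* Multi-label structures, oblique grids, dosimetric evaluation and
  DICOM RT-STRUCT conversion are out of scope; masks arrive as NIfTI.
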