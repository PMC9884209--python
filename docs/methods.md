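# Methods

This note documents the models and procedures the package implements, the
defaults it ships, the numerical choices behind them, and what its
synthetic benchmarks do and do not demonstrate about real slide data.

## Data model and conventions

All rasters are 0-based, row-major, with half-open extents everywhere
(bounding boxes, tiles). Physical units are micrometres, attached via a
pixel calibration (default 0.25 µm/px, a typical 40× scan; every reader
and generator takes an explicit value since scanners differ). The class
schema covers the major kidney compartments — full glomerulus (including
the tuft), glomerular tuft, tubule, artery (lumen + intima + media),
arterial lumen and non-tissue background (which by annotation convention
also absorbs large veins) — plus an optional artificial border class.
Tissue tiling uses 2500 µm square grid tiles resampled to 512 px, dropping
tiles that are ≥ 90% white; "white" is mean RGB ≥ 230/255 (configurable —
no principled constant exists, this is a conventional brightness cut).

## Border class and instance separation

A semantic label map cannot separate touching same-class instances, so an
artificial border class is constructed between them:

* **Tubules** — each instance's inner rim of width 3 px (the instance
  minus its radius-3 ball erosion) plus the overlap of radius-3 dilations
  between distinct tubule instances. The rim reading was chosen over an
  overlap-only reading because (a) the border class then coincides with
  the tubular basement-membrane ring around every tubule, and (b) it makes
  border removal followed by radius-3 re-dilation an approximate inverse,
  which is what the clean-up pipeline assumes. The rim is switchable off.
* **Glomeruli and arteries** — only the class-specific overlap of
  radius-7 dilations between distinct instances of the same class. Full
  rims are deliberately not used: they would erase genuine class
  transitions (e.g. tubule–glomerulus contact at the urinary pole).

Prediction clean-up runs, in order: border removal; per-class connected
components (8-connectivity by default; the choice is configurable and
matters only for single-pixel diagonal bridges); per-instance hole
filling restricted to unassigned background pixels, so a nested child
(tuft, lumen) is never overwritten; removal of instances below a minimum
area (default 30 µm² — roughly a 6 µm speck, far below any real
structure's cross-section); and constrained tubule re-dilation.

Re-dilation claims only pixels that (i) carried the border code in the
input, (ii) are unassigned, and (iii) would not make two tubule instances
8-adjacent; competing claims resolve to the lower id. Constraints (i) and
(iii) are what make the pipeline idempotent on its own output and keep
separated instances separated; without (i), every application would grow
tubules by another radius. On synthetic masks the whole
borderise → clean-up cycle recovers the ground-truth partition with exact
instance counts and ≥ 99.9% pixel agreement; the lost pixels are border
bands between abutting instances, which no local rule can reassign
perfectly.

Containment links (tuft → glomerulus, lumen → artery) use maximal pixel
overlap between the child and the hole-filled parent footprint dilated by
one pixel; the dilation covers children that form an open slit at the
parent boundary rather than an enclosed hole. Ties resolve to the lower
parent id.

## Morphometry

Area is pixel count × (µm/px)². Full glomeruli and arteries are measured
on their hole-filled footprint, so the glomerulus includes its tuft and
the artery its lumen — this is what makes the identities
`bowman_area = area_glom − area_tuft` and `wall_area = area_artery −
area_lumen` exact by construction. d_max is the maximum Feret diameter
computed on the sub-pixel marching-squares contour (convex hull then
max pairwise distance); measuring on the contour rather than pixel
centres or corners keeps the bias below ~1.4% for diameters ≥ 60 px.
Perimeter is the length of the marching-squares contour after a cyclic
5-point moving average — the raw staircase polygon overestimates smooth
boundaries by ≈ 5%, the smoothed one is accurate to < 1% for minor axes
≥ 10 px. The four shape descriptors are fixed as: circularity 4πA/P²
(clipped to [0, 1]), eccentricity of the second-moment ellipse, elongation
1 − minor/major axis length, solidity A / convex-hull area; they are
reported only for full glomeruli and glomerular tufts, and a glomerulus
without a segmented tuft simply has missing tuft-derived columns.
Wall diameter is (d_max(artery) − d_max(lumen))/2 — a definition, since
"wall thickness" has no canonical formula for non-circular sections.

Distances are boundary-to-boundary between pixel centres (per-instance
KD-trees with a bounding-box pruning bound; verified against brute force).
Instances whose boundary centres are ≤ √2 px apart are 8-adjacent, i.e.
touching, and are reported as distance 0. Nearest-glomerulus distance is
boundary-based for consistency with the tubule distance, although a
centroid-based reading would also be defensible.

The arteriole filter removes artery rows with full diameter strictly
below 50 µm (and their lumina). Patient summaries default to the median;
the mean is available by argument.

## Segmentation metrics

iDSC pools the per-instance best-overlap Dice scores of both directions
(prediction → truth and truth → prediction) into one mean. Pooling, rather
than averaging two directional means, was chosen because it weights every
instance equally regardless of direction; with balanced instance counts
the two conventions coincide. TP counting uses greedy highest-Dice-first
one-to-one matching with a strict > 0.5 threshold; on fixtures the greedy
count equals the optimal assignment (the threshold makes the match matrix
effectively bipartite-unweighted, where greedy is optimal in all but
adversarial ties). Two empty maps yield a NaN sentinel with a warning
rather than a fake perfect score.

## Cohort statistics

The two-sample Anderson–Darling test is the Scholz–Stephens k-sample A²
with midrank tie adjustment, as implemented in scipy; its p-value comes
from the published asymptotic interpolation and is floored/capped at
[0.001, 0.25], which does not affect decisions at the 0.05 level used
throughout. Measured type-I error at nominal 5% is ≈ 5% (n = 100/group).
Effect sizes use the percentile bootstrap (5000 reps, 95%) of the
difference in medians — percentile rather than BCa because the estimand
is a simple median difference at cohort sample sizes; measured coverage
of a known shift is ≈ 95–97%. Family comparisons: Kruskal–Wallis omnibus
then all pairwise two-sided Wilcoxon rank-sum tests with Bonferroni
multiplication within the family, capped at 1.

## Survival pipeline

The composite endpoint is ESKD and/or first halving of the initial eGFR,
whichever comes first, within a 15-year horizon; administrative censoring
is at exactly 15.0 years (the alternative — last visit before 15 — was
rejected as it conflates administrative and informative censoring).
Records without initial eGFR are dropped with a log message. Age and eGFR
covariates are binned in steps of 10.

Cut-offs for continuous biomarkers come from the maximally selected
log-rank statistic: an exhaustive scan of observed values within the
10th–90th percentile (the conventional maxstat range), standardized
|O − E|/√V with hypergeometric tie-corrected variance, smaller cut on
ties. The Miller–Siegmund improved-Bonferroni p-value for the maximal
statistic is reported but not used for selection — cut-offs serve only to
dichotomize, mirroring the design in which no continuous-scale model is
fitted (feature scales differ by orders of magnitude and normalisation
would destroy the histologic interpretability of a hazard ratio).
Continuous covariates remain available behind a flag.

Cox models are fitted by lifelines (Efron tie handling, Wald 95% CIs).
Model quality: Harrell's C (standard error by seeded patient-resampling
bootstrap of the fixed linear predictor — no installed library exposes a
closed form), AIC = −2ℓ + 2k, and BIC = −2ℓ + k·log(events), the
event count being the effective sample size of a partial likelihood.
Proportional hazards can be checked via the scaled-Schoenfeld trend test.
On simulated cohorts with a true step hazard (HR 2.0 at a known cut,
n = 500, ≈ 60% events), the scan recovers the cut within 10% of the
feature range and the adjusted HR lies in [1.6, 2.5] in ≈ 98% of runs.

## Trajectory analysis

Structures are treated as samples, features as variables. Features are
min-shifted per column to zero before relative-counts normalisation
(rows summing to 10⁴), since relative counts presume non-negative
entries. Dimension reduction is Pearson-residual correspondence analysis:
(O − E)/√E under the row×column independence model, truncated SVD, row
coordinates U·Σ, column signs fixed by the largest-magnitude loading.

The diffusion map uses a Gaussian kernel with per-point bandwidth equal
to the distance to the 5th nearest *distinct* neighbour (ignoring exact
duplicates makes the embedding invariant to duplicating the dataset, a
property the tests verify to 10⁻⁶), density normalisation (α = 1), and
the symmetric-normalised eigenproblem; the trivial constant eigenvector
is dropped, components are ordered by eigenvalue magnitude, scaled by
their eigenvalue, and normalised to unit degree-weighted RMS. The kernel
is dense by default; a kNN-sparsified variant reconnects disconnected
graphs by minimum-spanning-tree augmentation with a warning.

Louvain clustering runs on exactly the first two diffusion components
over a shared-nearest-neighbour graph (k = 20, Jaccard weights, pruned
below 1/15), seeded for determinism. The default modularity resolution
is 0.1: at resolution 1 a homogeneous cloud fragments into ~k/3
communities (the well-known resolution limit of modularity on dense kNN
graphs), while at 0.1 one tight blob stays in 1–2 communities and two
separated blobs are recovered exactly; progression structure then comes
from several communities along the manifold rather than dozens.

Backbone pseudotime: the user supplies an ordered healthy-to-diseased
cluster list (an advisory ordering by condition severity, or by the first
diffusion component, is computed when omitted); a piecewise-linear path
through the backbone cluster centroids is drawn, instances are projected
to their nearest path point, and arc-length positions are min–max scaled
to [0, 100]. This centroid-path projection approximates spline-based
trajectory fitting; it is exact for the piecewise-linear limit and within
projection ties satisfies the reversal symmetry pt → 100 − pt. Condition
composition along the trajectory uses 20 equal buckets with per-bucket
fractions (summing to 1 where non-empty) and lowess smoothing (span 0.5;
lowess is the local-linear cousin of loess and indistinguishable at this
bucket count).

Patient-level trajectories encode each patient's glomerular and tubular
cluster memberships as histograms, compared by the exact 1-Wasserstein
distance with Euclidean centroid distance as the ground metric, solved as
a linear programme (HiGHS) to optimality — measured metric-axiom
violations are ≤ 10⁻¹⁵. The glomerular and tubular matrices are combined
by element-wise mean after max-normalisation (an explicit design choice;
the two structure types have incommensurate distance scales), a patient
missing one structure type inherits the other's entries, and the combined
matrix is re-embedded with the same diffusion/backbone machinery.

## Synthetic generators

The generators define the benchmark conditions rather than imitate pixel
appearance — the pipeline consumes label maps, so intensity realism is
irrelevant by design.

* **Masks**: non-overlapping ellipses on a 1024² px canvas at 0.5 µm/px
  (a 512 µm field): 3 glomeruli (100–150 µm, inner tuft at 55–80% area),
  2 arteries (60–90 µm, lumen 15–35%), 12 tubules (30–60 µm), axis ratios
  0.6–1.0 — sizes in the range routinely reported for human kidney
  cross-sections. Analytic truth per instance: πab, 2a, Ramanujan
  perimeter, eccentricity, elongation. Packing is rejection sampling on
  bounding circles with a failure budget.
* **Corruption**: per-instance erosion, seeded instance dropping, and
  spurious background blobs; the report carries each instance's expected
  Dice from its pixel counts.
* **Cohorts**: n = 500 patients; a log-normal biomarker (median 10,
  log-sd 0.45) with a step log-hazard of log 2 above the cut at 10;
  baseline hazard 0.08/yr, random censoring 0.05/yr, 15-year horizon —
  roughly 60% events, enough to identify a dichotomized HR at n = 500.
  eGFR trajectories are emitted consistent with the simulated events so
  the endpoint builder reconstructs them.
* **Latent populations**: n = 2000 instances × 14 features; features are
  unit-amplitude monotone maps of t ~ U(0,1) (alternating direction;
  linear, quadratic, square-root and logistic shapes) plus Gaussian noise
  of sd 0.05 — five percent of the dynamic range, a moderate measurement
  noise; condition labels by thresholding t into thirds.

**What passing these benchmarks shows — and does not.** The geometry
benchmarks certify the measurement code (discretisation bias, separation
logic, metric implementations) under clean, convex, well-separated
shapes; real glomeruli are non-convex, touch more often, and carry
segmentation noise, so real-data accuracy is bounded by segmentation
quality, not by this layer. The cohort and trajectory benchmarks certify
statistical calibration and recovery under correctly specified generating
models (exponential hazards, monotone feature maps); they do not validate
the biological claim that any particular morphometric feature predicts
progression.

## Known limitations

* The border construction assumes instance-level ground truth; from a
  bare semantic raster, touching same-class instances cannot be told
  apart and fall back to connected components.
* Greedy TP matching can differ from optimal assignment under exact Dice
  ties just above threshold (not observed on tested fixtures).
* The scipy Anderson–Darling p-value is interpolated and clamped to
  [0.001, 0.25]; extreme tail probabilities are not resolved.
* The pseudotime is a geometric ordering; it has no calibrated time unit
  and inherits the backbone's healthy-to-diseased orientation from the
  user (or the advisory heuristic).
* Proprietary WSI formats, stain handling and CNN training are out of
  scope; inputs are label images, GeoJSON annotations and CSV tables.
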