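# nephromorph

Post-segmentation **pathomics** for kidney histology: once a whole-slide
image has been semantically segmented into kidney compartments (full
glomerulus, glomerular tuft, tubule, artery, arterial lumen, background),
this toolkit turns those label maps into quantitative, interpretable
morphometric data and runs the downstream analyses a nephropathology study
needs — instance separation, feature extraction, segmentation evaluation,
cohort statistics, digital-biomarker survival modelling and morphometric
pseudotime trajectories. It is aimed at computational-pathology
researchers who already have segmentation output (from any CNN or manual
annotation) and want the quantitative analysis layer.

## What it does

**Instance separation** (`nephromorph.postprocess`). Semantic output
cannot tell touching instances of the same class apart. An artificial
*border class* is built from ground truth — tubule inner rims via a
radius-3 ball-shaped structuring element, plus the class-specific overlap
of radius-7 dilations between distinct glomeruli or arteries — and a
prediction is cleaned by removing border pixels, relabelling 8-connected
components per class, filling holes, discarding instances below a minimum
area and constrained re-dilation of tubules.

**Morphometry** (`nephromorph.morphometry`). Per instance: area [µm²],
maximum Feret diameter d_max [µm], polygonal-contour perimeter [µm],
circularity 4πA/P², moment eccentricity, elongation 1 − b/a, solidity
(shape descriptors for glomeruli and tufts), tuft-area fraction
A_tuft/A_glom, Bowman's area A_glom − A_tuft, arterial wall area and wall
diameter, and boundary-to-boundary minimum distances (tubule → nearest
structure; glomerulus → nearest glomerulus). Small arterioles (full
diameter < 50 µm) are excluded by filter; summaries exist per slide
(counts, area percentages) and per patient (medians).

**Evaluation** (`nephromorph.seg_metrics`). DSC on rasters and the
instance Dice coefficient iDSC — the pooled mean of each instance's Dice
with its maximally overlapping counterpart, both directions — plus F1 and
PPV counting true positives strictly above Dice 0.5 with greedy
one-to-one matching.

**Cohort statistics** (`nephromorph.cohort_stats`). Two-sample
Anderson–Darling tests (Scholz–Stephens, midrank ties), 5000-rep
bootstrap 95% CIs of median differences, Kruskal–Wallis plus pairwise
Wilcoxon rank-sum with Bonferroni adjustment.

**Survival** (`nephromorph.survival`). Composite endpoint (ESKD and/or
halving of initial eGFR within 15 years), maximally selected log-rank
cut-offs for dichotomizing continuous biomarkers, Cox proportional-hazards
models (Efron ties) with Harrell's C, AIC and BIC, and side-by-side model
comparison (digital biomarkers vs histologic scores vs hybrid).

**Trajectories** (`nephromorph.trajectory`). Structures as samples,
features as variables: relative-counts normalisation → Pearson-residual
correspondence analysis → diffusion map (locally scaled kernel, density
normalisation) → Louvain clustering on the first two components → backbone
pseudotime on [0, 100] → 20-bucket condition fractions with loess curves,
and patient-level trajectories from exact 1-Wasserstein distances between
cluster histograms.

**Synthetic data** (`nephromorph.synthetic`). Every stage is testable
without any slide: masks of non-overlapping ellipses with analytic
features, controlled mask corruption, simulated cohorts with a known
step hazard, and latent-time populations with monotone feature maps.

## Worked example

```python
import nephromorph as nm

# synthetic slide with known ground truth
sem, gt, analytic = nm.generate_mask(nm.MaskSpec(seed=1))

# borderise, then recover instances as the pipeline would from a CNN map
bordered = nm.make_border_class(sem, instances=gt)
imap = nm.postprocess_prediction(bordered, nm.PostprocessConfig())
print(imap.n_instances, gt.n_instances)      # 22 22

ft = nm.apply_filters(nm.compute_features(imap))
glom = ft[ft["class"] == "full_glomerulus"].iloc[0]
print(round(glom["area"], 1), round(glom["tuft_area_fraction"], 3))
# 7726.2 0.573  -> a 7,726 um^2 glomerulus whose tuft fills 57.3% of it

rep = nm.idsc(imap, gt, "tubule")
print(round(rep.idsc, 3), rep.f1)            # 1.0 1.0
```

The recovered instance count matches the ground truth exactly, the
glomerular identities (Bowman's area + tuft area = glomerular area) hold
by construction, and the tubule instance Dice against ground truth rounds
to 1.0 — on well-separated synthetic shapes the border construction is
inverted essentially pixel-perfectly.

A full command-line pipeline is also available:

```bash
nephromorph simulate mask --seed 7 --out demo/
nephromorph postprocess --in demo/semantic.tif --out demo/inst.tif --calibration 0.5
nephromorph features --in demo/inst.tif --out demo/features.csv
```

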