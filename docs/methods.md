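# Methods

This note documents the models, parameter choices and numerical decisions
behind `reefspectra`, and what the synthetic experiments do and do not
show about real survey data.

## The scientific question

Two survey methods estimate the same quantity — the fractional cover of
benthic categories along reef transects:

- **Photoquadrat point-intercept (PQ).** A 0.25 m² quadrat is photographed
  at every meter of a 50 m transect; 20 nonaligned, systematically sampled
  points are overlaid on each photo and identified. Six transects yield
  300 photos and 6,000 points per site. Cover = point frequency.
- **Hyperspectral scanning (HS).** A diver-operated push-broom imager
  scans a ~1 m swath along the same transects (~300 m² per site), a
  classifier labels every pixel with a certainty value, and cover = pixel
  frequency among retained pixels.

The package simulates both methods on a shared ground truth and compares
their community estimates with the statistics used in reef ecology:
Bray–Curtis dissimilarity, ANOSIM, nMDS ordination, percent similarity,
and ANOVA + Tukey HSD on stony-coral cover, at two taxonomy tiers (broad
functional groups and high-resolution categories).

## Synthetic scenes and the forward optical model

**Class maps.** Each category receives a Gaussian random field smoothed to
a correlation length `patch_scale_m` (default 0.3 m); the per-pixel
category is the argmax of the fields plus per-category offsets. The
offsets are calibrated by a monotone fixed-point iteration (raising a
category's offset can only increase its cover) so realized pixel fractions
track the requested cover; `true_cover` is then recomputed exactly from
pixel counts, so cover conservation is exact by construction. Patchiness,
not realism, is the goal: real reefs have structured zonation, rugosity
and within-category spectral variability that these fields do not emulate.

**Transects and sites.** A site is `n_transects` independent scenes whose
cover vectors are Dirichlet draws around the site mean
(concentration 200 by default: transect-to-transect cover s.d. of a 30%
category ≈ 3 percentage points, similar to real transect heterogeneity).
Per-transect seeds derive deterministically from the site seed.

**Rendering.** At-sensor radiance is

    L(x, λ) = E(λ) · ρ_c(x)(λ) · s(x) · exp(−2 k(λ) h) + ε(x, λ)

with lamp spectrum E, category endmember ρ, multiplicative shading s in
(0, 1] (smoothed field, configurable strength; motivated by the strong
shading that reef rugosity casts under camera-mounted lights), two-way
Beer–Lambert water attenuation over the camera height h (default 1 m,
terrain-following as a diver would hold it), and Gaussian sensor noise
(additive s.d. 0.002, multiplicative 1% by default). The default
wavelength grid is 400–750 nm at 2.9 nm (121 bands); the attenuation
profile k(λ) = 0.02 + 2.6·((λ−400)/350)⁴ m⁻¹ is a simple monotone
water-like curve that makes the red/NIR tail nearly signal-free, so the
band-culling step has something real to do. The retained range after
culling is a property of the data, not an instrument assumption. A 10×10
cm matte grey plate (flat-ish reflectance ~0.30) is placed at the start of
each transect. The demo endmember library is synthetic (smooth baselines
plus Gaussian pigment-like features); for libraries of ≥4 categories the
two last categories share a spectral shape and differ only in albedo,
emulating pairs such as turf-on-pavement vs. bare pavement that
angle-based classifiers cannot separate.

Non-goals: inelastic scattering, sun glint, depth-varying ambient light,
navigation and georeferencing.

## Preprocessing

Order: smooth → drop low-signal bands → plate-normalize, each step logged
in the cube's provenance.

- Smoothing: Savitzky–Golay along the spectral axis only (window 7,
  polyorder 2) — polynomial-preserving, no spatial mixing.
- Band culling: a band is dropped when its scene-wide median radiance
  falls below 2% of the 95th-percentile band median (site-level pooling in
  the pipeline so all transects keep identical grids); at least 5 bands
  must survive, otherwise the input is rejected as degenerate.
- Plate normalization: each pixel spectrum is divided by
  (mean plate spectrum / known plate reflectance), converting radiance to
  estimated reflectance and cancelling the incident-light term. "Smoothed
  and standardized" is interpreted as exactly these two operations; no
  z-scoring is applied. Normalization is per transect (one plate per
  transect). Noise in dim red bands is amplified by the ratio — visible
  but harmless downstream, since the classifier standardizes per band.

## The classifier

A spectral–spatial residual network operating on a patch (default 7×7)
around each pixel, with the stage order: 1×1 convolution reducing the
band dimension (121 → 24 channels) → 2 pointwise spectral residual units →
channel adjustment (24 → 24 filters) → 2 spatial residual units (3×3
convolutions, reflect padding inside the patch) → average pooling over the
window → softmax. It is implemented in numpy with manual backpropagation
(verified against central finite differences in the test suite) and Adam
(step 1e-3, batch 256, ≤30 epochs, early stop on a validation-accuracy
plateau with patience 6). Inputs are standardized per band using training
pixels. These hyperparameters are the smallest configuration faithful to
that stage order that trains on one CPU in minutes; they are not tuned.

**Certainty** is the maximum softmax probability — no calibration is
applied, since none is specified for the original system. Labels use two
reserved values: −1 unclassified, −2 reference plate (excluded from all
cover accounting).

Class imbalance: inverse-frequency loss weights are available
(`class_weighting=True`) but off by default, matching the observation that
imbalanced libraries over-predict rare categories — the flag exists to
probe that behavior.

The spectral angle mapper (label = argmin arccos⟨x, e⟩/‖x‖‖e‖; certainty
= 1 − θ₁/θ₂) is the transparent baseline and oracle: on noiseless
identity-optics renders it recovers ground truth exactly, and the network
is required (by test) not to lose to it on the default benchmark that
contains the albedo-degenerate category pair.

## Survey simulation and thresholding

- PQ quadrats are 0.5 m × 0.5 m footprints at every `spacing_m` (default
  1 m); the footprint is tiled by a 5×4 cell grid with one uniform random
  point per cell ("nonaligned systematic" in its classical sense). Points
  read true labels — the photoquadrat is treated as the reference method;
  an observer-error model is deliberately not applied by default. Points
  falling on the plate are excluded. Because points are uniform within
  cells, pixel inclusion probabilities are uniform, and when the footprints
  tile the swath the estimator is exactly unbiased for pixel-count cover
  (the basis of the calibration test).
- HS cover at threshold t keeps pixels with certainty ≥ t and renormalizes
  over retained pixels (the retained fraction is always reported so the
  loss of rare taxa at high thresholds can be audited; un-renormalized
  cover is a one-liner from the same outputs).
- The threshold scan evaluates the 21-value grid {0, 0.05, …, 0.95, 0.99};
  for each threshold the combined HS+PQ community matrix is tested by
  ANOSIM with survey method as the grouping factor; `select_optimal`
  returns the threshold of maximal significance, ties resolved toward 0.

## Statistics

All comparison statistics are implemented in this package; scipy supplies
only distributions (F, studentized range) and rank assignment.

- **Bray–Curtis**: Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ); undefined (error) for all-zero pairs.
- **Percent similarity**: (1 − BC) × 100. Site-level similarity is
  reported under two averaging schemes, since either is defensible: the
  mean over matched transect pairs (primary) and the similarity of the
  method-mean profiles.
- **ANOSIM**: dissimilarities are ranked (average ranks on ties);
  R = (mean between-group rank − mean within-group rank)/(M/2),
  M = n(n−1)/2. Significance is one-sided under random relabeling with the
  +1 correction, 999 permutations by default; when the number of distinct
  relabelings (multinomial coefficient) does not exceed the requested
  permutations, all are enumerated and the exact p is returned (a 6+6
  design has 924, so the default is exact there).
- **nMDS**: Kruskal stress-1 = √(Σ(d−d̂)²/Σd²), alternating
  pool-adjacent-violators isotonic regression of configuration distances
  on dissimilarity ranks with Guttman majorization updates; restart 0 is
  initialized from classical (Torgerson) scaling, the rest randomly; an
  update that would increase stress terminates the restart, so the
  recorded stress sequence is non-increasing by construction; the best of
  `n_restarts` (default 20; 8 in the pipeline) is returned. Defaults
  k = 2, tol 1e-7.
- **ANOVA/Tukey**: standard one-way F; Tukey–Kramer
  q = |ȳᵢ−ȳⱼ|/√(MSW·(1/nᵢ+1/nⱼ)/2) with p from the studentized range
  distribution; for two groups this reduces exactly to the pooled t-test
  (q = t√2), which the tests assert to 1e-9. Zero within-group variance
  with unequal means is reported as F = ∞ with a degeneracy flag rather
  than an exception.
- The high-resolution tier is square-root transformed before
  dissimilarity by default (`sqrt_transform_high_tier`), damping the
  dominance of abundant taxa; the broad tier is analyzed untransformed.
  Both choices are configuration flags because the originating analyses
  state the transform only for visualization.

## Pipeline defaults and demo scale

The full-size protocol (6 transects × 50 m × 1 m at 2 cm pixels, 121
bands) renders ~7.5 M pixels per site and runs end to end in roughly a
quarter hour on one CPU. The tests and the acceptance script use smaller
sites — typically 3–6 transects of 5–12 m at the same 2 cm pixel size,
50 ROIs of 5×5 px per transect, ≤12 training epochs — chosen so the whole
suite runs in CPU minutes while exercising every stage at full fidelity.
Default demo site cover is turf/pavement-dominated (52%) with four coral
categories (28% total) and a tail of rarer groups, the typical skew of
Indo-Pacific fringing reefs; ROI sampling frequency ∝ cover^1.4 so the
top-3 categories hold the majority of annotated pixels, reproducing the
annotation imbalance of real libraries.

The 90/10 split is per pixel by default, which is optimistic: pixels of
one ROI are spatially correlated, so validation accuracy overstates
transfer to unseen reef. ROI-level splitting is available
(`split unit: the pixel` vs. grouping by ROI before splitting) for honest
validation; the demo keeps the pixel split because the quantity under
study is cover agreement, not classifier generalization.

## Behavior of the threshold scan under a matched null

On matched synthetic data (HS labels = ground truth; certainty increasing
with category dominance, as trained classifiers behave), the significance
curve is flat while nearly all pixels survive, then collapses once
thresholding strips the rarer categories — agreement at high thresholds is
far worse than with no threshold, and the scan selects a (near-)zero
threshold. One caveat discovered during development and worth stating:
ANOSIM is sensitive to dispersion as well as location. Under an exactly
matched null the HS rows are much less dispersed than the noisy PQ rows,
and mid-grid thresholds — which remove a transect-varying subset of
pixels — can transiently *equalize* the dispersions and raise the
significance before the systematic dominance bias takes over. The argmax
of the curve is therefore a noisy statistic over the flat region, while
the qualitative contrast (no-threshold ≫ high-threshold agreement) is
stable; the acceptance script reports both.

## What passing tests show — and what they don't

Passing tests show the machinery is correct: exact cover bookkeeping,
bit-reproducible seeded pipelines, statistics that match closed forms,
brute-force enumeration and independent implementations, an unbiased
point-intercept estimator, a classifier whose gradients, probability
outputs and determinism behave as specified, and a threshold scan with the
documented monotonicity. They do not show that a real classifier reaches
any particular accuracy on real reefs: synthetic endmembers are cleaner,
within-category variability lower, annotation noise absent, and water
optics far simpler than reality. Conclusions about the real method's
field performance require field data.

## Known limitations

- Forward model ignores ambient light, glint, scattering and
  depth-dependent attenuation changes; shading is a smooth multiplicative
  field, not geometry-derived.
- Certainty is raw softmax confidence; no calibration.
- The exact 128/91/52-category field taxonomy is not reconstructed; a
  12 → 8 → 5 demo hierarchy (labeled with standard broad group names)
  stands in, and user taxonomies load from CSV.
- Habitat maps are exported in local coordinates (world-file sidecar),
  not georeferenced.
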