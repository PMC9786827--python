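# Methods

This note documents the models, the parameters that matter, the numerical
choices, and the limits of what the synthetic validation shows.

## Vessel-referenced haemoglobin colourimetry

Haemoglobin absorbs green light and reflects most of the red, so the ratio
`(R − G)/R` of a pixel rises with haemoglobin content.  The central retinal
vessels carry essentially pure blood and serve as the per-image colour
standard: the reference is the **median** of the per-pixel ratio over
detected vessel pixels (median, not mean, for robustness to specular
highlights), and tissue haemoglobin is

```
Hb%(pixel) = 100 · [(R − G)/R]_pixel / reference
```

clipped to [0, 120] (the upper margin admits tissue slightly redder than the
vessel median without unbounded values).  Pixels with R = 0 read as 0%.
Because the quantity is a within-pixel ratio, any multiplicative
illumination change — vignetting, global gain — cancels exactly; this is
asserted as a test invariant.  The reading of "expressed as a percentage"
as ratio-to-vessel-reference is isolated in `hb_colorimetry.hb_map`, so an
alternative normalisation would touch one function.

Detected vessel masks are dilated by 2 px before tissue statistics: a missed
vessel pixel reads as ~100% haemoglobin and biases sector means upward, so a
safety margin is cheaper than perfect segmentation.

## Sector geometry

The "24 areas of the nerve" are realised as 3 equal-area concentric
elliptical annuli × 8 wedges of 45°, a factorisation that supports annulus
effects, wedge effects, and the 8 rim sectors with one indexing scheme.
Sector index = annulus·8 + wedge; annulus 0 is outermost; wedge 0 is centred
on the temporal horizontal axis; angles run counter-clockwise in canonical
(right-eye) orientation, superior at 90°.  Left eyes are mirrored
horizontally before any sector geometry (an involution, tested as such).
A sector whose vessel-free tissue has fewer than 10 px is imputed from the
adjacent wedges of its annulus and flagged.

## Disc, vessels, cup

Classical operators stand behind the detector contracts (published CNN
weights for these steps do not exist, and the interfaces accept any detector
satisfying the contracts):

* **Localisation**: difference-of-Gaussians (σ 15/45 px, matched to the
  expected disc diameter of ~80 px at the default scale) on the red channel
  — red is insensitive to haemoglobin, so the pale cup does not pull the
  centre — after grey-closing to erase vessels.  Confidence is the DoG peak
  squashed to [0, 1]; the refined centre is the centroid of the bright
  component around the peak.
* **Boundary**: threshold at the midpoint between the window median
  (background) and its 99.5th percentile (disc), morphological closing
  (radius 3, bridging vessel crossings), hole filling, convex hull (vessels
  bite concave notches out of the bright region), then an ellipse from
  second moments.  Histogram thresholds (Otsu) were rejected: on noise-free
  rasters the single-valued background falls on a bin edge and lands in the
  bright class.  Axis ratios outside [0.5, 2] signal a degenerate fit; the
  quality gate reports such images as low quality, not absent.
* **Vessels**: within 1.5 disc radii, pixels markedly darker in green than a
  local 75th-percentile background (the 75th percentile stays a tissue
  estimate even where vessels cluster, unlike a median) and with a
  blood-like colour ratio; a sufficiently high ratio alone is decisive,
  because inside dense vessel clusters the local background is itself
  vessel.  Colour thresholds are margins above the disc's own median ratio,
  so no particular vessel colour is assumed.  No thinning; width preserved.
* **Cup**: normalised-convolution smoothing (σ 3 px) of the Hb map —
  interpolating across excluded vessel corridors so the cup stays connected
  — thresholded at the 25th percentile of within-disc Hb as a seed, then the
  threshold is refined twice to the midpoint of the two class means (a
  seeded two-class split; the fixed percentile alone misplaces the boundary
  whenever the cup occupies other than 25% of the disc).  Largest connected
  component, minimum area 1% of the disc, minimum cup/rim contrast 3 Hb
  units (a uniform map yields no cup, C/D = 0).  Vertical C/D is the cup's
  vertical extent over the disc's vertical extent through the cup centroid
  column; `cd_area_ratio = cup_area_pct/100` by construction.

## Normative database and indices

Percentile curves are empirical, `pct(x) = 100·(#below + 0.5·#equal)/n`
(midpoint tie handling), built from severity-0 eyes only and **stratified by
disc-area tertile** — the implementation of "weighted by the disc area".
Large discs have physiologically larger cups; stratified lookup removes that
confound, and the resulting GDF is uncorrelated with disc area (|r| < 0.05
on a 10,000-eye cohort where disc area is independent of disease).

The raw discriminant is a weighted sum, higher = more normal:

* sector term: weighted mean of `(pct_s − 50)/50`, superior/inferior wedges
  double-weighted (disease attacks the vertical poles first);
* C/D term: `(50 − pct_vcd)/50`;
* classifier term: `w_cls · (score − 1)`, present only in GDF.  The neutral
  input (all percentiles 50, classifier score 1) therefore maps to raw 0,
  and toggling the classifier off changes the raw score by exactly `w_cls`
  when the score is 0.

Weights are configuration, not constants (only the influence ordering is
prescribed by the method): GDF uses 0.35 / 0.15 / 0.50
(sector / C/D / classifier), GIP uses 0.70 / 0.30 / 0.

The classifier stand-in is a logistic model on the (disc-area adjusted)
feature vector — any calibrated discriminator yields the near-dichotomous
score the indices assume; it is trained on simulated normals plus a
severity-0.3–1.0 glaucoma cohort and is deterministic at inference.

**Calibration** solves `a·q05 + b = 0` and `a·q01 + b = −15`, where q05/q01
are empirical percentiles of normal raw scores, then clips GDF to
[−100, +85] and GIP to [−100, +100].  The classifier scores entering the
calibration are **cross-fitted** (5 deterministic folds): in-sample scores
are optimistically confident, which shifts the anchors and inflates the
held-out positive rate; cross-fitting restores the intended 5%/1% transfer
to fresh eyes.  Calibrations are tagged with the weight set they were built
for; a GDF calibration cannot be applied to GIP or vice versa.

## Progression

Ordinary least squares of GIP (and cup-area %) on time in decimal years
(365.25 d/yr) from the first exam; two-sided p from the t distribution with
n − 2 df; an eye is flagged when p < α (default 0.01) and it has ≥ 4
examinations.  Two-sided testing with a separate direction label keeps the
null flag rate at exactly α (a one-sided worsening-only option exists in
config).  Zero-residual fits get p = 0 when the slope is non-zero and p = 1
for an exactly constant series.  The per-exam-count summary table reports,
per bin, the number of eyes, % progressed, and mean/sd of the flagged GIP
and cup slopes; in simulation, power rises with exam count while the mean
flagged |slope| falls — more exams detect subtler change.

## Quality gate

Five exclusion categories with fixed total precedence: disc absent
(detector confidence < 0.3) → excessive illumination (> 25% of central-field
pixels saturated in any channel) → low quality (variance of the Laplacian of
the median-denoised green channel < 10, or an unfittable disc boundary) →
disc sectioned (ellipse crosses the frame border) → disc near edge (centre
closer than 1.2 disc radii to a border) → ok.  The precedence order and all
thresholds are package choices recorded in config; the boundary between
"excessive illumination" and "low quality" in particular is a convention.
All metrics are populated for every image so exclusions remain auditable.

## Synthetic generator: what it emulates and what it does not

One eye is parameterised by disc area (Normal(1.93, 0.35) mm², matching the
reference cohort; median 1.90), axis ratio ~1.05, cup fraction
(Normal(0.20, 0.05) at severity 0), cup elongation, per-sector haemoglobin,
and severity g ∈ [0, 1].  Baseline tissue haemoglobin is Normal(65, 6)%
across eyes with 3% within-eye sector noise — no published normative Hb
distribution exists, so these are stated package defaults, easy to change in
config.  Severity depresses haemoglobin preferentially in the
superior/inferior wedges (up to 30 units, wedge profile
0.2/0.6/1.0/0.6 around the ring), adds up to 0.45 to the cup fraction and
0.55 to the cup elongation.  Disc area is drawn independently of severity.

The cup is an inner ellipse offset temporally, paler than the rim by a
factor 0.75; the cup's pallor is part of the ground-truth sector means
(`sector_hb = rim_hb · (1 − coverage·(1 − 0.75))`, with coverage computed
from the shared cup-geometry helper), and the renderer reproduces those
means exactly over vessel-free tissue — so a zero-noise render round-trips
through the full pipeline to within discretisation error (±3 Hb units,
asserted).  Vessels render at exactly the reference colour; tissue colour
satisfies the colour contract `(R−G)/R = ref · Hb/100` before noise.
Artefacts: multiplicative vignette (invisible to the ratio), additive
over-exposure with channel clipping, Gaussian blur, Gaussian sensor noise,
and truncation modes (sectioned / near-edge / absent) driving the exclusion
categories.  Identical seeds give byte-identical rasters.

Cohorts: age Normal(64.3, 12.9) clipped to [20, 95]; group-specific
age-dependent prevalence decides affected status per patient; affected
patients get per-eye severities from a Gaussian copula whose latent
correlation is inverse-corrected (ρ* = 2·sin(πρ/6)) so the Pearson
correlation of the two severities equals the requested parameter
(default 0.65).  Longitudinal series advance the cup-free tissue value by
`hb_slope` and the cup fraction by `cup_slope`, with independent acquisition
noise per exam; default exam spacing is annual with 20% jitter.

For large simulations a **feature-level shortcut**
(`simulate_measurements`) adds measurement noise (sector sd 2.5 Hb, C/D sd
0.03, cup-area sd 2 points, disc-area 3% relative) directly to the ground
truth, skipping rasterisation; the acceptance computations use it at
n = 5000 (build) / 10,000 (held-out), sizes chosen so anchor-quantile noise
is small against the calibration targets.  Image-level checks run at tens
of images.

What passing tests do **not** show: the phantom has no peripapillary
atrophy, no retinopathy lesions, no camera-specific colour response, and its
vessel/tissue contrast is cleaner than real fundus photographs — results
here validate the statistical machinery and the internal consistency of the
pipeline, not clinical performance on real images.  Real-cohort quantities
(observed screening-positive rates in diabetics, inter-eye r = 0.648-type
values, per-exam-count progression percentages) depend on an unavailable
patient population and are out of scope; the package reproduces the
calibration anchors and the qualitative patterns (power rising with exam
count, disc-area independence, GIP reproducibility ≥ GDF's).

## Known limitations

* The exact functional form of the published discriminant indices is not
  public; only monotonicity, influence ordering, anchors and ranges are
  enforced here, with weights in config.
* The cup estimator underestimates very large cups if the refinement guard
  rejects low-contrast splits; index-level simulations therefore use the
  geometric ground-truth C/D plus noise rather than the image-path cup.
* Vessel segmentation is tuned for curvilinear dark-red structures on a
  brighter disc; it is not a general retinal vessel segmenter.
* The quality-gate thresholds were calibrated on synthetic fixtures; real
  screening programmes would re-tune them on their own cameras.
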