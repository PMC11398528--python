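# Methods

This note records the models, parameter choices and numerical decisions
behind `microquant`, and what the synthetic benchmarks do and do not
demonstrate about real micrographs.

## Image primitives

**Rolling-ball background subtraction.** The background is the grey
-level opening of the image by a *ball* living in (x, y, intensity)
space with height profile √(r² − d²): the surface a ball of radius `r`
rolling under — and across the plateaus of — the intensity landscape
can reach.  This shape is what gives the classic operator its two-sided
behaviour: wide, *low* structures (cytoplasmic haze plateaus, ramps,
vignetting) are climbed and removed, while compact structures that are
*tall* relative to the ball height survive, because the ball cannot
follow sides that rise faster than its own profile.  An affine surface
is reproduced exactly (opening with any symmetric structuring function
is exact on affine inputs), so smooth gradients subtract to zero.  Two
engineering details mirror the classic tool: the background is
estimated on a 3×3-mean-smoothed copy and capped by the original pixel
values (a raw opening tracks noise *minima* and leaves a ≈2σ positive
residual floor that downstream unsharp gains would amplify), and for
radii above 12 px it is computed on a min-shrunk grid and bilinearly
interpolated back, which is accurate because the opening is smooth at
the ball scale.  A sliding-paraboloid variant (structuring surface
d²/2r, computed as an exact separable quadratic envelope rather than a
directional approximation) is available via `method="paraboloid"`; it
penetrates a peak of half-width `a` by only a²/2r regardless of width,
which preserves very wide bright objects but cannot climb onto haze
plateaus — the ball is the default because haze removal is what the
pipelines rely on.

One structural consequence worth knowing: a droplet whose diameter
reaches the second rolling ball's footprint (2 × 10 px in the
big-droplet pipeline) starts to be treated as background, so the
measured area response flattens at radius ≈ 10 px.  This is a property
of the published operator chain, not of this implementation; the
reference tool's arc-trimmed ball is narrower still.

**8-bit conversion** maps `lo → 0`, `hi → 255` with round-half-up;
bounds default to the image min/max and a constant image is rejected
without explicit bounds.  Inside the LD pipeline, inputs that already
live on a display-scaled 8-bit grid pass through unchanged
(`lo=0, hi=255`): a data-driven min–max stretch is correct for
native-depth camera frames but pathological on blank fields, where it
amplifies pure noise to full scale and the downstream ×10 unsharp gain
would manufacture speckle particles.  The macros this package
reimplements operated on display-scaled 8-bit micrographs, and the
synthetic generator emulates that acquisition product directly.

**Unsharp masking** is `(I − w·G_σ(I)) / (1 − w)`; on 8-bit images the
result is rounded and clamped to [0, 255] (clamping, not wrapping, on
overflow), which is what makes the saturation threshold (255) of the
small-droplet pipeline meaningful.  **Mean/median filters** use disk
footprints (radius 1 = centre + 4-neighbours) with reflective edges;
whether a printed "mean of 2 pixels" meant disk radius 2 or a 2×2
kernel is ambiguous — disk radius 2 is implemented.

**Rényi-entropy auto-threshold.** Three candidate thresholds maximise
the summed background/foreground Rényi entropies at α→1 (the
Shannon/Kapur limit), α = ½ and α = 2; the sorted candidates are
blended by the published weighted rule (weights 1/2/1, 0/1/3 or 3/1/0
depending on whether the candidates fall within 5 grey levels of each
other, scaled by the probability mass between the outer candidates).
Criterion values are quantised to 10 decimals before the arg-max so
exact ties (cuts through zero-mass gaps) resolve to the lowest
threshold irrespective of summation order.  Foreground is strictly
above the threshold.

**Tubeness** computes the Hessian of the σ-smoothed image by central
differences (exactly zero on constant and affine surfaces, which
sampled Gaussian-derivative kernels are not) and returns σ²·|λ₂| where
the smaller eigenvalue λ₂ < 0.  σ is interpreted in calibrated units
when the image carries a pixel size — the printed 0.05 with 0.031 µm
super-resolution pixels probes a 1.6 px scale — and effective scales
below 0.6 px are clamped with a warning, since curvature estimation is
undefined below the pixel grid.

**Watershed splitting** floods the negated Euclidean distance transform
from its regional maxima after h-maxima suppression at 0.5 px (maxima
whose separating saddle is shallower than half a pixel merge, so noise
-dented outlines do not oversplit) with seeds closer than 2 px fused.
Separation lines are one pixel wide; because the flood uses
4-connectivity, residual diagonal contacts between basins are broken by
demoting the shallower pixel of each contacting pair, so the split
parts are genuinely 8-disconnected for particle labelling.  Thin
structures (tubule networks) have near-flat distance transforms and
merge into a single seed per component, leaving them uncut.

**Particle analysis** labels 8-connected components (background
4-connected in hole filling, avoiding the dual-connectivity paradox)
and gates on area and circularity 4πA/P², clamped to ≤ 1, with a
Crofton multi-direction perimeter estimator — boundary-pixel counting
overestimates perimeters by up to ~30% and would silently tighten the
0.6 circularity gate.

## Quantification pipelines

Parameter defaults are the printed values of the protocols this
package reimplements (rolling-ball radii 50/10/5, unsharp 3 px/0.9 and
5 px/0.6 and 5 px/0.7, thresholds 100–255 and 255, particle gates
10–1000 px² and circularity 0.6–1, ER particle gate > 25 px² — "over
25" read as strictly greater — 3-slice projections, 20 sampled cells,
mean 2 px with 15-unit subtraction).  Open choices:

* Particles are assigned to the cell containing their centroid;
  particles outside every cell are reported in an "unassigned" bucket.
* "LD area per cell" is reported both as per-cell sums (primary) and as
  image total divided by cell count.
* Pipeline mode is explicit (`big`/`small`), plus an `auto` mode that
  runs the big-droplet variant and falls back to the small-droplet one
  when it finds fewer than one particle per cell (logged).  The
  original workflow chose per strain by eye, post hoc.
* The tubule mask is computed from the raw projection, not from the
  coarse-mask intermediate ("a mean filter was introduced" reads as a
  fresh chain); watershed runs on each mask and again on their union,
  as the protocol states both.
* Hole filling after thresholding floods enclosed regions.  For a
  reticulated organelle this is not hypothetical: the perinuclear ring
  always encloses the nucleus, and ring–tubule–rim circuits enclose
  cytoplasmic pockets.  The pipeline logs a QC warning when filling
  grows a mask by more than 20%, and the manual artifact-removal step
  of the original workflow is replaced by an explicit exclusion-mask
  input.  The generator exports exactly that annotation
  (`enclosed_pocket_mask`: nuclear interiors plus pockets enclosed by
  true ER circuits) so the benchmark exercises the same clean-up a
  human performed.
* A blank-field guard: when the two classes produced by the automatic
  threshold are separated by less than 6 background standard
  deviations, the mask is declared degenerate and returned empty with a
  warning.  Pure-noise fields threshold at their own upper tail with a
  separation of ≈4σ (inflated from ≈2.5σ by zero-clamping); genuine
  membrane signal in these chains sits tens of σ above background.

## Bleach boost

Each iteration averages the frame with a processed copy (mean 2 px →
rolling ball 50 px → subtract 15 → unsharp σ 5 px, weight 0.7); "this
process was repeated several times" becomes an explicit iteration count
(default 2) with an auto-stop when the frame mean moves by less than 1%.
The enhancement is a display/QC aid — boosted frames must not be used
for quantitative intensity measurements.

Why it works is worth stating precisely, because under a purely linear
model it could not: subtracting 15 units penalises dim late frames and
*reduces* the last/first contrast ratio.  The benefit comes from
ceiling compression.  On a display-scaled 8-bit movie whose early
frames are exposed near (and partly beyond) the top of the range, the
×3.3 unsharp gain clamps at 255 for early frames while late frames have
full headroom, so late frames are lifted proportionally more.  The
timelapse generator models that acquisition: droplet intensity ≈500 on
the 8-bit proxy scale at t = 0 (clipping at 255 for roughly the first
half hour of a k = 0.02/min decay), camera offset constant, fluorescent
signal decaying as e^{−kt}.  For a movie that never saturates, the
procedure sharpens individual frames but degrades the last/first ratio
— a documented limitation, and the reason the auto-stop exists.

## Statistics

Scipy provides Shapiro–Wilk, median-centred Levene (Brown–Forsythe),
Bartlett, t-tests and one-way ANOVA.  Welch's ANOVA, the
Brown–Forsythe adjusted-df F\* ANOVA and Dunnett's T3 are implemented
here: T3 refers each pairwise Welch statistic, with its own
Welch–Satterthwaite df, to the studentized maximum modulus distribution
SMM(k, ν) — the maximum of k independent |N(0,1)| variates studentized
by a common χ_ν/√ν denominator — evaluated by adaptive quadrature
(k = 1 reduces to the two-sided t distribution, verified).  A
conservative Šidák-on-Welch fallback is available as a cross-check
flag.  Pairwise comparisons are not gated on the omnibus test (matching
common practice of the graphing software the protocol used); the Welch
ANOVA p is the primary omnibus read-out, with the F\* ANOVA reported
alongside.  A Shapiro–Wilk failure routes to the Welch branch with a
warning: the protocol did not state this case and had no nonparametric
branch.  Measured under a Gaussian equal-variance null (3 groups,
n = 20), the full tree's family-wise type-I error is ≈0.04–0.05.

## Synthetic scenes

The generator emulates three acquisition products on display-scaled
8-bit grids: widefield LD fields (0.065 µm/px; cells of 1.8–2.4 µm
radius; 2–5 droplets per cell at radii 3–8 px; droplet amplitude 190
over a 30-unit cytoplasmic haze and 20-unit background with a smooth
gradient; Gaussian PSF σ 1.2 px; Poisson shot noise at 2 photons per
grey level plus σ = 3 read noise, giving spot SNR ≈ 15), super
-resolution ER mid-sections (0.031 µm/px; perinuclear ring of width
3 px at 0.35 of the cell radius, amplitude 200; cortical rim arcs
covering ~65% of the perimeter, amplitude 170; 1–2 px Bézier tubules at
amplitude 45 — deliberately dim, as thin tubules carry few
fluorophores, which is exactly the regime the dual-mask design
addresses; 3 z-slices 0.316 µm apart with out-of-focus attenuation and
blur), and 24-frame bleaching movies at 5-minute intervals with
k = 0.02/min as described above.  Per-object-class random sub-streams
keep cells fixed when tubule or droplet counts change, so response
-curve suites vary only the parameter under study; every scene is fully
determined by its seed.

Ground truth is analytic: rasterised disk areas per cell, the exact ER
mask and per-cell pixel fractions, the bleach constant, and the
enclosed-pocket annotation.

**What passing benchmarks show — and what they do not.**  The scenes
contain circular cells, disk-shaped droplets and smoothly curved
tubules with stationary noise; real micrographs add budding-cell
shapes, out-of-focus droplets, vacuolar autofluorescence, mixed droplet
brightness within a field, and structured camera artifacts.  The
benchmarks therefore validate the *mechanics* of the pipelines
(operator correctness, gating, assignment, determinism, statistical
calibration) and their accuracy under idealised optics; they do not
certify absolute accuracy on any particular real dataset.  Known
systematic effects visible already on synthetic data: threshold-based
area estimation carries a positive bias (~+10% at SNR 15) from noise in
the blurred edge skirt; the big-droplet pipeline's response flattens at
droplet radius ≈ 10 px (the second rolling ball's scale); an empty
field processed by the big-droplet pipeline can occasionally yield a
~10 px² noise particle — the small/no-droplet variant exists precisely
for such samples.

## Benchmark problem sizes

The shipped benchmarks use 20 LD fields of 10 cells (448² px), 20 ER
stacks of 3 cells (512² px), response curves over 8 radii × 20 seeds
and 5 tubule counts × 10 seeds, 200 histograms for the threshold
oracle, one 24-frame movie, and 2000/1000 Monte-Carlo replicates for
the statistics operating characteristics.  Response curves are reported
as means over their seeded replicates — the replicates exist to
estimate the response, and single-seed curves carry quantisation jitter
(±1 grey level in the automatic threshold; ±5 px² in watershed line
placement) that is noise, not signal.
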