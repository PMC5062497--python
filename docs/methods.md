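# Methods

This document records what the package computes, the default parameter
values and why they were chosen, the numerical decisions that affect
results, and the known limits of the synthetic generators.

## 1. Roundness from two photographs

### Score definition

The per-image score is the isoperimetric circularity

```
roundness = 4π · area / perimeter²
```

which is 1 for a perfect circle and decreases toward 0 as the outline
elongates or grows lobes. The overall score of a carcass is the
arithmetic mean of the scores of its top-view and side-view
photographs — a cheap 2-D proxy for 3-D sphericity that only requires
two orthogonal pictures.

Scores slightly above 1 can occur on rasterized near-circles because
area and perimeter are estimated from a discrete grid; they are
reported raw with a warning, never clamped, so that averages of many
scores stay unbiased.

### Pipeline

Each image passes through a fixed sequence; every binary mask records
its provenance (the ordered list of applied steps):

1. **Occlusions.** Caller-supplied circles (e.g. over a protruding tail,
   a leg, or attached soil) are painted white before any processing, so
   the artifact never touches the threshold statistics or the perimeter.
   Circles may extend past the image border; they are clipped and the
   clipping is logged.
2. **Blue channel.** Flesh tones have their weakest response in blue, so
   the blue plane gives the strongest object/background contrast against
   a white background.
3. **Otsu threshold.** Foreground is every pixel *at or below* the
   threshold that maximizes inter-class variance (the object is darker
   than the background). A constant image has no threshold and raises a
   degenerate-histogram error rather than guessing.
4. **Despeckle.** A 25-pixel binary median filter. The median of a
   binary window is a majority vote, so it is implemented as a separable
   box mean thresholded at ½ — mathematically identical for odd windows
   (no ties possible) and roughly two orders of magnitude faster than a
   generic median filter; equality against `scipy.ndimage.median_filter`
   and against a brute-force sliding-window oracle is asserted in the
   tests. Boundary handling is edge-including reflection. At the default
   ~27 px/mm this window erases isolated features up to ~0.7 mm across
   (an isolated blob survives only if it fills at least half the window)
   and smooths boundary detail at a similar scale. The window is
   interpretable as a diameter (default) or radius, and a true disk
   footprint is available as an alternative geometry.
5. **Largest component.** Exactly one 4-connected foreground component
   is kept (ties broken deterministically by first pixel in row-major
   order, with a warning). An empty mask raises a no-object error.
6. **Measure.** Area is the foreground pixel count. The default
   perimeter is the polygon length of the sub-pixel 0.5-level contour
   (marching squares) after Douglas–Peucker simplification with a
   1-pixel tolerance. The raw marching-squares polygon hugs the pixel
   staircase and overestimates smooth perimeters by ~5–6% (a disk would
   score ~0.90); the 1-px simplification removes the staircase without
   cutting true corners, giving < 1% error on disks, squares, ellipses
   and random smooth blobs simultaneously. Contours with ≤ 9 vertices
   (tiny objects) are left unsimplified; a single pixel has perimeter
   2√2 (its contour is a diamond). A raw pixel-edge counting estimator
   is available for comparison (`perimeter_estimator="pixel-edge"`); it
   is exact for axis-aligned shapes and biased high for everything else.

Default physical scales: 27.1 px/mm (top view) and 27.6 px/mm (side
view), applied when an image does not carry its own scale. They
correspond to the fixed camera geometry the defaults were calibrated
for; pass `px_per_mm` explicitly for any other setup.

Invariances verified by the test suite: translation (exact), rotation by
multiples of 90° (to 0.005 — not bit-identical, because Douglas–Peucker
simplification starts from a raster-scan-dependent vertex; 180° is
exact), arbitrary rotation (< 0.02), uniform scaling (< 0.01), and the
isoperimetric bound (≤ 1.005 on all tested shapes).

## 2. Synthetic image generator

`render_blob_pair(BlobSpec, ArtifactSpec)` produces a top/side pair of
RGB images whose **pipeline score** — not merely whose ideal continuous
circularity — hits a requested target.

**Shape.** The silhouette is a radial harmonic blob
`r(θ) = r₀ · (1 + Σ aₖ cos(kθ + φₖ))` with harmonic orders
`k ∈ {2, 5, 8, 11, …}` (one per requested harmonic). The k=2 mode gives
elongation; the spaced higher orders add lobes whose wavelength
(2πr₀/k ≳ 100 px at the defaults) stays far above both the pixel grid
and the despeckle window, so low roundness targets are reachable without
pinching the silhouette into pieces. Base amplitudes are drawn
uniformly and damped by 1/√k; total amplitude is capped at 0.78 to keep
the radius positive.

**Calibration.** The drawn amplitudes are scaled by a single factor
found by bisection, where the objective is the actual pipeline score of
the rendered frame. Tolerance 0.005 per view; if the target is
unreachable (e.g. 0.31 with a single harmonic) a calibration error is
raised rather than silently missing. Because calibration runs the real
pipeline, rendered pairs are valid end-to-end fixtures: scoring them
back recovers the target within ±0.01. Practical target range with the
default four harmonics: about 0.35–1.0; `target_roundness` is validated
to (0.3, 1].

**Artifacts.** `ArtifactSpec` adds two kinds of realism, and each
rendered view keeps its artifact-free twin (`clean_image`) so tests can
difference them:

- *Speckle*: dark dots at a Poisson-mean density per mm² with diameters
  drawn from 0.2–0.65 mm. The upper bound is deliberately below the
  ~0.7 mm removal limit of the 25-px majority window, and speckles are
  rejection-sampled to stay at least one diameter clear of the
  silhouette boundary, because a sub-millimetre dot that *straddles* the
  boundary merges with the object and survives any filter. Under these
  constraints despeckling restores the clean score to within 0.005.
- *Tail*: a tapered protrusion of given length/width/angle attached to
  the boundary, emitted together with the white occlusion circle that
  covers it. Scoring with the occlusion matches the clean twin within
  0.02; scoring without it visibly lowers the score, as a real tail
  would.

All randomness derives from `numpy` `SeedSequence` substreams of the
caller's seeds: the same `(BlobSpec, ArtifactSpec)` is bit-reproducible,
and shape noise is independent of artifact noise.

## 3. Study-table simulator

`simulate_study(StudyParams)` returns one row per breeding pair with
columns: pair id, parental pronotum widths (mm), carcass masses before
and after preparation (g) and their difference, nest roundness, male and
female desertion times (h), post-reproduction lifespans (days), brood
size, brood mass (g), average larval mass (g), and larval density
(brood size per prepared gram).

**Covariates.** Pronotum widths are Normal(5.0, 0.35) mm for both
sexes; unprepared carcass mass is truncated-Normal(11.95, 1.82) on
[8, 15] g (a typical laboratory mouse-carcass range); preparation
removes Normal(1.0, 0.5) g, clipped to keep the prepared mass positive;
desertion times are Uniform(24, 168) h.

**Structural equations.** Responses are linear in the covariates plus
independent Gaussian noise. Default coefficients (per unit of the
covariate):

| response | depends on | coefficient | residual SD |
|---|---|---|---|
| roundness | male size | +0.10 /mm | 0.10 |
| | female size | −0.08 /mm | |
| female lifespan (d) | roundness | +43.52 | 11.0 |
| | mass change | +4.80 /g | |
| male lifespan (d) | prepared mass | +3.45 /g | 13.0 |
| brood size | prepared mass | +1.89 /g | 9.0 |
| | male size | +9.35 /mm | |
| avg larval mass (g) | prepared mass | +0.006 /g | 0.015 |
| | brood size | −0.002 | |
| | male size | +0.001 /mm | |
| | female desertion | +0.0004 /h | |

Intercepts (0.55, 11.9, 7.2, −51.4, 0.043 g respectively) and residual
SDs were set so that a default 45-pair table lands near the summary
statistics the defaults are calibrated to — mean roundness ~0.64,
brood size ~16 ± 1.3 (SEM), average larval mass ~0.12 ± 0.004 g — and so
that each listed effect is detectable but not overwhelming at n = 45
(t-statistics of roughly 2–4). Brood size is rounded to a non-negative
integer (disable with `integer_brood=False` for exact-recovery tests);
average larval mass uses the realized brood size, and brood mass and
larval density are derived identities, so `brood_mass =
avg_larval_mass · brood_size` holds exactly in every table.

`with_noise_scale(s)` scales all residual SDs at once — convenient for
large-n recovery tests. `link_images_to_table` renders one calibrated
image pair per row (target = the row's roundness), writing PNGs, a
manifest and an occlusion list; rows whose roundness falls outside the
renderer's calibratable range propagate a calibration error rather than
silently producing an off-target image.

## 4. Statistical analysis

**Normality.** Shapiro–Wilk on each response (3 ≤ n ≤ 5000; constant
columns are an error, not a p-value).

**Linear models.** OLS via statsmodels. AIC is `−2ℓ + 2k` with `k`
counting every coefficient (intercept included) **plus the residual
variance** — the convention of R's `AIC`/`stepAIC`, so elimination
traces are comparable to an R workflow; the constant offset never
affects ranking. Backward elimination is greedy: each round refits
without each remaining candidate and drops the single term whose
removal lowers AIC most, stopping when no removal helps; the intercept
is never dropped; the full trace (term, AIC before/after) is recorded,
so the final AIC is provably ≤ that of every model visited. p-values of
dropped terms are reported from the last model that contained them and
flagged as such. Rows with a missing value in any column a model
touches are dropped for that model only, and counted. Rank-deficient
designs raise a collinearity error naming the offending columns.

**The five prediction models.** roundness ~ parental sizes + desertion
times + carcass mass; female lifespan, male lifespan and brood size ~
roundness + sizes + desertion times + carcass mass; average larval mass
additionally includes brood size. "Carcass mass" is ambiguous between
the unprepared mass, the prepared mass and the preparation mass change,
so each model is fitted once per admissible variant and the variant
whose reduced model attains the lowest AIC is reported, flagged in the
output (`mass_variant`). The roundness model only admits the unprepared
mass or the mass change, never the prepared mass it partly determines.

**Variance comparisons.** Pairs are split at the sample mean of
roundness ("round" = strictly above). Levene's test compares the spread
of brood size, average larval mass and larval density between the
groups. The median-centered (Brown–Forsythe) statistic is the default
for robustness; the mean-centered one is always computed alongside so a
disagreement about significance is visible. Degrees of freedom are
reported in the conventional (numerator, denominator) = (1, n − 2)
order, and the report footer says so. Two groups with no spread at all
give F = 0, p = 1; a group with fewer than two rows is an error.

**Correlation.** Brood mass is not modelled as a response: it
correlates with brood size at r ≈ 0.9 in simulated tables, so only
brood size is modelled and the Pearson correlation between the two is
reported instead.

## 5. Validation problem sizes

The acceptance tests (one per criterion, `tests/test_acceptance.py`)
use these package-chosen problem sizes:

1. Disk anchor: radius 400 px in a 1000×1000 frame, score 1.0 ± 0.01.
2. Ellipses, aspect ratios 1.5/2/3: within 0.02 of the closed form
   (Ramanujan perimeter), strictly decreasing.
3. 50 random harmonic blobs: area equals an independent flood-fill
   count exactly; area and perimeter within 2% of dense quadrature over
   the continuous boundary.
4. Six speckled blobs across targets 0.6–0.9: within 0.005 of their
   clean twins.
5. 500 simulated 45-pair studies: ≥ 90% coverage of the 95% CIs for
   the male-size→roundness and roundness→female-lifespan coefficients;
   estimates pooled over five 10,000-pair studies within 5% of truth
   (pooling keeps the Monte-Carlo error of the check itself ≈ 1.3%,
   well inside the 5% band).
6. 200 replicates at n = 200: a pure-noise covariate beside one strong
   predictor is eliminated at the rate the AIC rule implies —
   P(χ²₁ < 2) ≈ 0.843, checked within a 4σ binomial band. (Note this
   rate is a property of the AIC penalty of 2 and does not grow with n;
   a ≥ 95% elimination rate would require a BIC-like penalty.) AIC is
   asserted non-increasing on every trace.
7. 1000 equal-variance simulations at n = 45: Levene type-I error in
   [0.03, 0.07].

The deterministic acceptance target (`scripts/acceptance.py`) re-derives
anchor 1 and writes `results/acceptance.json`.

## 6. Limitations

- Two orthogonal views bound, but do not determine, 3-D sphericity; a
  shape can be round in both silhouettes yet non-spherical.
- The circularity score conflates elongation and boundary roughness;
  two different shape families can share a score.
- The blob generator is star-shaped by construction (single-valued
  r(θ)): it cannot produce folded or self-occluding silhouettes, and
  its artifact model (circular speckle, one straight tail) is a
  caricature of real soil and limbs.
- Speckles are kept clear of the silhouette boundary because
  boundary-straddling debris is not removable by any local filter; real
  images with dirt on the outline need occlusion circles.
- The study simulator is linear-Gaussian with independent covariates;
  it makes no attempt to model selection, censoring of lifespans, or
  covariance between parental traits.
- The elimination procedure is greedy single-term AIC descent, not an
  all-subsets search; with correlated candidates the retained set can
  depend on the drop order.
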