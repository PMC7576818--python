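# Methods

This note documents the models, conventions and numerical choices behind
`particulate`, and what its synthetic validation does and does not
establish about real microscope data.

## The measurement model

A lamella is imaged as a mosaic of 8-bit RGB tiles at one of two
magnifications. Deposited particles are assumed *dark on a bright
background*: segmentation keeps pixels whose working-channel value is
strictly below a threshold, and the boundary value is excluded. The blue
channel is used everywhere for global operations because it carries the
strongest particle contrast in transmitted-light images of organic
deposits; local refinement uses the blue channel at low zoom and an
8-bit-rescaled R+G+B sum at high zoom (both selectable through
`ScanConfig.crop_channel`, since either convention is defensible for a
given instrument).

Pixel sizes default to 1.55 µm/px (low zoom) and 0.155 µm/px (high
zoom), consistent with a 1392×1040 camera behind a ×5 objective at the
two zoom settings; both map the minimum area of their regime (50 and
0.5 µm²) to the same ≈21-pixel footprint, which is what makes a single
minimum-component-size rule work at both magnifications. All coordinates
are mosaic-level micrometres, origin at the top-left corner, x
rightward, y downward, pixel centres at `(index + 0.5)·px`.

### Frame rejection

Tiles containing macroscopic occluders are removed before segmentation
of high-zoom stacks. The statistic is the per-tile blue mean compared
with the median of tile means; the tolerance is `k·s̄` with `s̄` the
average per-tile standard deviation and `k = 2` by default. Two design
points:

* the test is **two-sided** on `|mean − median|`. Dark debris lowers a
  tile's mean, but anomalously bright frames (glare, dropped tile) are
  equally unusable, and a symmetric band costs nothing on clean stacks;
* the statistics are computed **once** from the full stack, not
  re-estimated iteratively. On stacks whose kept tiles are homogeneous
  this is idempotent: re-running rejection on the kept stack removes
  nothing further.

### Local refinement

The only published constraint on the refinement threshold is that it is
a function of the crop mean; the implementation uses `T = α·mean(crop)`
with `α = 0.6`. The calibration is geometric rather than statistical: on
a noise-free crop containing a dark particle (grey 40) on background
(grey 200), any `α` between ≈0.25 and ≈0.9 reproduces the global mask
exactly, and 0.6 centres that interval while keeping `T` below the
background under realistic noise. Decreasing `α` can only shrink the
refined mask (thresholding is monotone), which the tests assert.

### Measurement

Area is the pixel count times the pixel area. Elongation is the
major/minor axis ratio of the ellipse with the mask's second central
moments; each pixel contributes an additional 1/12 to the diagonal of
the covariance matrix (the variance of a unit square), so a discrete
`n`-pixel-long rectangle has variance exactly `n²/12` along its axis and
a one-pixel-wide line has a finite minor axis instead of a degenerate
zero. Particles touching tile borders are merged across tiles when
their mosaic bounding boxes meet within one pixel, and re-measured from
the merged pixel set; detection output is therefore invariant to tile
traversal order.

## Size classes, morphotypes, halos

Size classes partition areas as fine [0.5, 50), coarse [50, 1500],
macroscopic (1500, ∞) µm². The half-open boundary at 50 and the closed
one at 1500 keep the conventional "50–1500" coarse count intact; 0.5 µm²
is the detection floor and classification below it is an error.

Fibers are flagged at elongation ≥ 5. The generator plants fibers with
aspect ratios 6–12 and compact shapes below ≈3, so the cut separates the
two populations with margin; it is a configuration parameter, not a
fitted constant.

Drying halos (bright annuli left by evaporated droplets) are detected by
comparing the mean intensity of an annulus extending 5 px beyond the
particle boundary with the tile background mean. The comparison
threshold is `k` background **standard errors** of an annulus-sized mean
(`k·σ_bg/√n_annulus`, default `k = 2`): the annulus average of `n`
pixels fluctuates with `σ/√n`, and a threshold in raw standard
deviations would make a +30 grey-level halo undetectable under sensor
noise of σ = 32 while a SEM-scaled threshold keeps the false-positive
rate at the nominal level. The raw-σ variant remains available
(`scale="std"`). Halo evaluation runs on a mosaic window around each
particle so annuli straddling tile borders are not lost; only particles
at the outer mosaic edge are unevaluable and default to "no halo".

## Statistics

* **Density**: `d = N/A`. Dispersion, when a tile partition is supplied,
  is the sample standard deviation of per-tile densities scaled to the
  lamella, `sd(d_tiles)/√n_tiles` — i.e. tile-to-tile spatial
  inhomogeneity, not the Poisson counting error.
* **Summary grids**: marginal means are plain arithmetic means of the
  cell densities with sample (n−1) standard deviations. Published
  marginals rounded from unrounded inputs can differ from marginals
  recomputed from printed cells by one unit in the last decimal; the
  acceptance tests allow exactly that.
* **Cumulative size functions**: 30 log-spaced edges per class (binning
  is a reporting choice; the underlying quantity is the empirical CDF in
  percent, and the final edge always reports 100%).
* **Coating comparisons**: unpaired pooled-variance Student t-test on
  the per-holder cumulative fractions at the edges inside a contested
  window (defaults 200–900 µm² for coarse, <10 µm² for fine, where
  coating effects concentrate). No multiple-testing correction is
  applied; raw pairwise p-values are reported. The t-test is validated
  against a permutation oracle (10⁵ shuffles) in the test suite.
* **Coverage forecast**: strictly linear in the horizon,
  `coverage% = 100·h·Σ d·E[A]·10⁻⁶`, with no saturation or overlap
  correction — adequate while coverage ≪ 100%.
* **Cleanliness class**: smallest integer `N` with areal concentration
  (particles of equivalent diameter ≥ 1 µm, per m²) ≤ 10^N. The decade
  rule and the ≥ 1 µm cut (area ≥ π/4 µm²) are documented conventions.

## Size law

Observed coarse-particle histograms are monomodal and right-skewed with
hard range limits, so the generator (and the coverage forecast) uses a
**truncated log-normal parameterised by its mode**: with
`µ = ln(mode) + σ²`, the untruncated law has its most probable value at
`mode` (so a planted mode of 155 µm² is directly recoverable from the
histogram), and the truncated mean has the closed form

    E[A] = mode·e^{1.5σ²} · [Φ(b−σ) − Φ(a−σ)] / [Φ(b) − Φ(a)],

with `a = (ln lower − µ)/σ`, `b = (ln upper − µ)/σ`. Defaults: fine
(mode 2 µm², σ 1.0, 0.5–50), coarse (mode 155 µm², σ 0.7, 50–1500),
macroscopic (mode 3000 µm², σ 0.5, 1500–50000). With the calibrated
densities (coarse 1.6/mm², fine 3.3/mm²) these laws give a 40-period
coverage of ≈2.14%, which the Monte-Carlo planted-area estimate
reproduces to well within its sampling error.

## The synthetic generator

`sample_truth` draws per-class Poisson counts (mean = density × field
area), truncated log-normal areas via inverse-CDF sampling, morphotypes
from a per-class mix (coarse: 85% flat convex polygons, 10% round, 5%
fibers; fine: 70% round, 30% dividing pairs; macroscopic: 50% fibers),
and positions uniformly under a hard-core constraint (centre distance at
least twice the larger equivalent radius, placed largest-first with
bounded rejection sampling — an explicit `CrowdedFieldError`, never a
silent truncation). `render_tiles` rasterises shapes at pixel-centre
precision, recentres each shape on its planted centroid, adds a linear
illumination gradient, bright halo annuli, macroscopic occluder blobs,
and i.i.d. Gaussian sensor noise, then cuts the mosaic into tiles
(padded with background so the grid divides evenly).

Default conditions are the survey's: background 200, particle contrast
160 on blue (96 on red/green), noise σ = 32 (contrast-to-noise 5),
gradient amplitude 10 grey levels, halo fraction 0.1 at +30 grey levels.
Field size is configurable; the default 15.6 × 15.6 mm (≈243 mm²)
matches the per-lamella scanned area implied by counts over densities.
Occluders default to covering ≈60% of one tile: at noise σ = 32 a blob
must shift the tile mean by more than `2s̄ ≈ 64` grey levels to be
rejectable, which a 10–30% blob cannot do, so the default extent is
chosen to guarantee the generator's contract that an injected occluder
trips the rejection statistic.

**What the generator does not emulate**: optical point-spread and depth
of field (shapes have hard edges), flat-field vignetting beyond a linear
gradient, correlated sensor noise, particle aggregation (positions are
hard-core, not clustered), translucent or low-contrast particles, and
focus errors. Passing detection tests on these scenes therefore
demonstrates the correctness of the chain's logic and its statistical
behaviour at a stated contrast-to-noise ratio — not robustness to every
real-world imaging artefact.

## Problem sizes in the test and acceptance runs

Validation scenes are scaled to keep the suite fast while leaving every
statistical check well-powered: detection performance uses 2×2 mm scenes
at 8 particles/mm² over 10 seeds (recall and precision ≥ 0.95), density
recovery uses 20 replicates at the surveyed 1.6/mm², the histogram-mode
and truncated-mean checks use 10⁵–10⁶ direct draws, and the acceptance
script's Monte-Carlo cross-check plants ≈15,000 particles over thirty
10×10 mm scenes. Larger fields change none of the involved estimators,
only their sampling error.

## Known limitations

* Merging across tiles uses bounding-box adjacency; two distinct
  particles whose boxes touch exactly at a shared tile border would be
  merged (vanishingly rare at surveyed densities, impossible under the
  generator's hard-core rule).
* The dispersion reported for a density requires a tile partition;
  from a bare particle table it is undefined (NaN), by design.
* The elongation of very small fibers (< ~25 px) is noise-limited;
  morphotype flags below that footprint should not be over-read.
* `compare_coatings` treats per-holder cumulative fractions as
  independent observations; adjacent bins of a CDF are positively
  correlated, so the nominal p-values are approximate (they are used
  comparatively, as in the survey reports).
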