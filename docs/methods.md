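# Methods

This note documents the models, numerical choices and limitations of the
memsheet pipeline. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## ROI quantification and retention statistics

An `IntensityMeasurement` is the arithmetic mean over a square ROI minus the
mean over a caller-supplied background ROI placed next to the membrane.
Corrected means are **not** clipped at zero: sheets whose signal fluctuates
below background would otherwise bias replicate averages upward.

The retention regression is ordinary least squares constrained through the
origin, θ = Σxy/Σx². The constraint encodes the assay's physics: a sheet
expressing no tagged protein traps no reporter. R² is reported against the
*centered* total sum of squares (matching common plotting software); because
the model is origin-forced this R² can be negative for pathological data and
is reported as computed. The uncentered variant is stored alongside for
comparison.

Normalized comparisons express each replicate's test value as a percentage
of its control (control ≡ 100%) and build a two-sided 95% confidence
interval of the mean ratio from the t-distribution with n−1 degrees of
freedom; "significant" means the interval excludes 100%. The same operation
serves immunoprecipitation band ratios after `band_ratio` converts
integrated band intensities to endo/GFP ratios. Gel densitometry itself is
out of scope — band intensities enter as tabular values.

Stock hypothesis tests (Student t, one-way ANOVA, two-way ANOVA) are
delegated to scipy/statsmodels through `summarize_groups`; only the
normalized-CI comparison is bespoke.

## Colocalization

`pearson` computes the PCC over raw paired pixel values in the ROI — no
background subtraction, since the PCC is invariant under positive affine
rescaling of either channel (verified to 1e-12 in the tests).

`costes_test` scrambles **only the reporter channel** in non-overlapping
`block_px`×`block_px` tiles (default 4 px ≈ one PSF at 83.3 nm/px),
recomputes the PCC against the fixed first channel for each of
`n_scrambles` (default 100) uniformly random tile permutations, and reports
the fraction of scrambled PCCs strictly below the observed one. Ties count
as not-below, which is conservative toward exclusion. If the ROI side is
not a multiple of the block size, the ROI is cropped bottom/right to the
largest multiple and the observed PCC is computed on the same cropped
support, so observed and null always share a support. ROIs with P < 0.95
are excluded from downstream averaging. With 100 scrambles the null
exclusion rate is ~94–96% by construction (the observed value ranks
uniformly among 101 exchangeable values); the calibration test checks
uniformity of the null p-value (KS < 0.1) and the exclusion rate at 95 ± 3%.

## STED nano-cluster analysis

Processing order: crosstalk correction → blur → detection → refinement →
classification → distances. The long-red channel is corrected as
`longred − factor·red` (default factor 0.5), clipped at zero because
negative counts destabilize the center-of-mass step. Both channels are then
blurred with an isotropic Gaussian of σ = 0.5 px (reflective borders).

**Maxima detection** re-implements ImageJ's "Find maxima" noise-tolerance
semantics as a prominence criterion: pixels are merged in descending
intensity order (union-find); when two growing regions meet at level v, the
region whose peak is lower dies, with prominence = peak − v; the overall
dominant peak gets prominence = peak − min(image). A maximum is reported
when its prominence strictly exceeds the noise tolerance; a constant image
therefore yields none. Plateaus are reported at the plateau pixel nearest
the plateau centroid (lexicographic on exact ties); between equal-value
peaks merging below tolerance, the peak whose plateau contains the
row-major-smallest pixel survives. The implementation is validated against
an independent exhaustive oracle (per-level threshold labelling) by exact
set equality on hundreds of random images.

**Sub-pixel refinement** takes the intensity-weighted centroid over the
pixels whose centers lie inside a 5-px-diameter disc around the maximum,
after subtracting the disc minimum. The baseline subtraction matters: a
plain center of mass over a fixed window shrinks sub-pixel offsets roughly
in half through truncated flux (measured −0.15 px error at a 0.3 px offset
for a σ = 1.6 px spot), whereas the baseline-corrected centroid localizes
noiseless spots to ~0.005 px and Poisson-noise spots (1000 photons) with
~0.1 px RMSE and negligible bias. Candidates whose disc leaves the image
are excluded before classification; a disc with no signal above baseline
falls back to the integer position with a warning.

**Classification** fits A·exp(−(x−μ)²/(2σ²)) + b to the 31-px profile
(mean over the 3-px width) of a horizontal and a vertical linescan.
Initialization: b = min, A = max−min, μ = argmax, σ = 2 px; σ is bounded to
[0.5, 31] px and μ loosely to [−5, 35]; non-convergence yields R² = −∞. A
linescan passes when R² > 0.7 **and** μ ∈ [31/3, 62/3] (the middle third in
continuous 0-based coordinates); a maximum is accepted as a nano-cluster
when at least one linescan passes — the conjunction is per linescan. Note
that the R² gate alone cannot reject monotone ramps: with a free offset and
a wide σ a Gaussian flank fits a ramp almost perfectly; such profiles are
rejected because the fitted peak sits at the scan edge.

**Distances.** For each accepted reference cluster the Euclidean distance
(in nm, default 25 nm/px) to the nearest target-channel maximum is
computed; target maxima are sub-pixel refined too by default (a flag
disables it) but are not linescan-classified, mirroring the asymmetric
macro. The random control mirrors target positions left-right
(col → cols−1−col; a vertical flip is available via config — for
independent channels the choice is irrelevant in expectation, though
per-image values differ). For a homogeneous Poisson pattern of intensity λ
the mean nearest-neighbor distance is 1/(2√λ), which the implementation
reproduces within 2% at 10⁴ points. The tolerance sweep repeats the whole
analysis at (2,4), (4,8), (6,12), (2,12): higher tolerances keep fewer
maxima, lengthening the control distances, while the observed-vs-control
ordering should persist.

## Synthetic scenes

The generator emulates the features the pipeline is sensitive to, with two
optical presets: epi (83.3 nm/px, PSF σ = 140 nm ≈ 1.7 px) and STED
(25 nm/px, PSF σ = 40 nm = 1.6 px).

* **Domain field** ("PIP2-rich areas"): Gaussian-smoothed white noise,
  standardized, passed through a logistic soft threshold placed at the
  (1 − enriched_fraction) quantile (softness 0.5), then normalized to mean
  1. Two knobs — correlation length and enriched area fraction (default
  0.3) — produce contiguous rich areas resembling a smooth reporter
  pattern.
* **Nano-clusters**: centers drawn per pixel with probability
  ∝ domain^affinity plus uniform sub-pixel jitter; affinity 0 is complete
  spatial randomness, and the mean domain value at centers increases
  monotonically with affinity (checked over {0, 0.5, 1, 2}, 20 seeds).
  Copy numbers are 1 + Poisson(copies_mean − 1), default mean 4, since
  clusters contain several protein copies but no distribution is published.
* **Rendering**: each cluster contributes a pixel-integrated isotropic
  Gaussian carrying photons_per_emitter × copies photons (default 1000);
  flux is exact per spot, so total intensity equals background·n_pixels +
  photons·Σcopies within 1% whenever spots are ≥ 4σ from the border.
  Poisson shot noise is applied to the expectation; every stage is
  bit-reproducible given its seed. The smooth reporter channel is rendered
  as background + amplitude·(PSF-blurred domain) with shot noise.
* **Crosstalk** is added as primary + factor·bleed (default 0.5 between the
  STED channels), the artifact the correction step removes; on integer
  photon counts the mix/correct round trip is bit-exact.

The **retention experiment** emulation generates, per sheet, a fresh domain
field (72×72 px, correlation length 4 px), protein clusters with the
construct's affinity and an expression level drawn uniformly from 20–200
clusters (restricted to the central region so a corner background ROI stays
clean), and 1500 reporter molecules placed with affinity 1. Patching traps
the reporters within 1.5 px (~125 nm) of any protein cluster. The radius
matters: at 3 px the capture discs of a strongly expressing sheet tile the
whole region and retention saturates regardless of placement; at 1.5 px
coverage stays partial and the high-affinity construct retains ~36–44% of
the reporter — the same scale real patching assays report — while the
slope ratio θ(affinity 2)/θ(affinity 0) is ≈ 1.4 across seeds. Both
channels are rendered with shot noise and quantified through `measure_roi`
exactly like real data.

What the generator does **not** emulate: membrane topography or a realistic
TMA-DPH channel, photobleaching, stage drift, 3D PSFs, labelling
stochasticity of nanobodies, or cluster internal structure. Passing tests
therefore demonstrate that the pipeline measures what it claims on images
with the stated statistical structure — not that the biological conclusions
of any particular dataset are correct.

## Problem sizes and determinism

Test and acceptance runs use deliberately modest sizes chosen for quick,
repeatable runs: 64–192 px scenes, 100–200 Monte-Carlo repetitions per
calibration, 20 seeds per ordering check, 10⁴ points for the CSR closed
form. Every random draw flows from an explicit integer seed
(`numpy.random.default_rng`); `scripts/acceptance.py` derives all stage
seeds from its single `--seed` argument, and identical configurations
reproduce byte-identical output tables.

## Known limitations

* `find_maxima` runs a Python union-find over all pixels; fine up to a few
  hundred thousand pixels per ROI, not tuned for gigapixel mosaics.
* The Costes test scrambles whole tiles only; partial-tile remainders are
  cropped rather than wrapped.
* The linescan classifier assumes isolated, roughly isotropic spots; in
  dense fields overlapping clusters broaden profiles and lower the accepted
  fraction, which is faithful to the macro but means "accepted clusters"
  undercounts true clusters at high density.
* Through-origin R² has no unique definition; both centered and uncentered
  values are computed, centered is reported by default.
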