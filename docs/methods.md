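# Methods

This note documents the statistical model, the numerical choices behind it,
what the synthetic-data generator does and does not emulate, and the known
limitations. Parameter defaults given here are the package defaults,
asserted by `PipelineConfig.self_test()`.

## Chronological standardization

Radiocarbon determinations are calibrated non-Bayesianly: the posterior
over calendar age is proportional to
`Normal(age_14C; μ_curve(cal BP), sqrt(σ_meas² + σ_curve(cal BP)²))`
evaluated on the curve's native calendar grid with linear interpolation
implicit in that grid, normalized by the trapezoid rule. Curves use the
standard three-column format (cal BP, ¹⁴C age, σ). Routing is by
hemisphere at the equator: latitude ≥ 0 uses the northern curve, < 0 the
southern; a site exactly on the equator goes north. Ages beyond curve
support are excluded with a logged reason, never extrapolated; no marine
curve or reservoir (ΔR) corrections and no eggshell offset are applied.

The 1σ summary is the posterior standard deviation by default. A 68.3%
central-interval half-width is also computed and carried on the
`CalibratedDate`, since "1σ" in published compilations is ambiguous
between the two; for near-Gaussian posteriors they agree to a few
per cent.

When a layer carries both a calibrated ¹⁴C age and another radiometric
estimate, the combined mean is the arithmetic mean of the method means and
the combined half-range spans from the lowest lower bound to the highest
upper bound across methods (bounds at mean ± 1σ or ± stated half-range).
This is a conservative envelope rule, not inverse-variance pooling: dating
methods here have non-exchangeable systematic errors, and the envelope
never understates the disagreement between them.

Inclusion filters: radiometric dating only (radiocarbon or other); full
age range — max minus min, i.e. twice the half-range — at most 20,000
years (the rule is ≤); mean age within 14,000–120,000 BP inclusive.
Filtering is idempotent and order-independent and reports a per-rule
exclusion tally.

## Uncertainty-aware resampling (repeats)

Each repeat resolves three sources of stochasticity independently:

* **Dating uncertainty.** One age per occurrence from
  `TruncNormal(mean, (half/2)²)` truncated to mean ± half: the published ±
  is read as 2σ and the draw can never leave the published range. A zero
  half-range degenerates exactly to the mean. Sampled ages snap to the
  nearest climate slice (ties toward the more recent slice); ages falling
  off the time axis snap to the end slice and are counted.
* **Temporal sampling bias.** The record densifies toward the present
  (preservation, method availability). Slices at or older than the 78-ka
  boundary are kept whole; each younger slice is uniformly subsampled down
  to the count of one randomly drawn pre-boundary slice (empty ones
  included — the target distribution is the pre-boundary count
  distribution, zeros and all).
* **Background choice.** 200 background locations per retained presence,
  drawn uniformly with replacement from the land cells of the presence's
  slice. Presence cells are *not* excluded from the background pool: in a
  presence-background design the background characterizes availability,
  not absence.

Seeds follow a spawning tree (master → repeat → stage), so any repeat is
reproducible in isolation and repeats are exchangeable. Presences landing
on sea cells (coastline mismatch) are reassigned to the nearest land cell
within one cell's distance, else dropped with a log entry.

In the model frame both a presence and its 200 backgrounds carry the
*slice* time as `time_bp`. Using the pre-snap sampled age for presences
would put presence and background at slightly different times within the
same slice while their covariates come from the same slice; tying both to
the slice time keeps time exactly balanced between the classes.

## The two niche models

With covariates x₁…x₅ (LAI, BIO 7, BIO 8, BIO 10, BIO 16) and time t:

* fixed niche: `logit P(obs=1) = β₀ + Σ s_v(x_v)`
* changing niche: adds `s(t) + Σ ti(t, x_v)`

Smooths are cubic B-spline bases with k = 4 basis functions per margin
(the cap on flexibility), centred by a sum-to-zero constraint over the
training sample. Tensor interactions are row-wise Kronecker products of
the *centred* marginal bases, so `ti(t, x)` spans only genuine
interaction structure and excludes the additive main effects — the
changing-niche model therefore nests the fixed-niche model, and the
ΔAIC contrast isolates time-variation of the covariate effects.

Penalties are first-order coefficient differences. After centring removes
the constant, each term's penalty is full rank, so smoothing can shrink a
term to effectively zero degrees of freedom. This is deliberate: the
model-comparison logic needs interactions to vanish when the data carry no
niche change, and a penalty with a non-trivial null space (e.g.
second-order differences, whose null space is linear functions) would
leave each interaction a permanent free degree of freedom.

Fitting is penalized IRLS with step-halving on the penalized deviance;
smoothing parameters (one per term; a tensor term's penalty is
`S₁⊗I + I⊗S₂` under a single λ) are selected by Fellner–Schall updates,
iterated with warm-started IRLS to convergence of log λ. Time enters
affinely rescaled to [0, 1] (map recorded in the fit). Prediction clamps
covariates to the training range (flat basis extension); the fraction of
extrapolated cells is reported per slice.

**AIC.** Reported per-term effective degrees of freedom are block sums of
the influence trace tr(F), F = (XᵀWX + S)⁻¹XᵀWX. The AIC *penalty*,
however, uses tr(2F − F²) ≥ tr(F). With smoothing parameters selected on
the same data, the plain conditional AIC is optimistic about the flexible
model — in fixed-niche simulations the ΔAIC > 2 rule fired in 9/20 runs
with tr(F), versus 3/20 with tr(2F − F²), while detection of a genuinely
drifting optimum stayed at 20/20 with margins of 18–55 AIC units. For
binary observations AIC = deviance + 2·tr(2F − F²).

The comparison gate is ΔAIC = AIC(fixed) − AIC(changing) strictly
greater than 2.

## Evaluation

**Continuous Boyce index.** Windows of width 0.1 × (pooled suitability
range) slide across 101 equally spaced centres; per window, P is the
fraction of presences and E the fraction of background inside; the index
is the Pearson correlation between window centre and P/E over windows
with E > 0 (fewer than 3 valid windows, e.g. constant suitability, is
undefined and reported as such). Pearson is the default because the
acceptance gate (> 0.7) is defined on it; a Spearman variant windows on
pooled-rank-transformed suitabilities, which makes it exactly invariant
under strictly monotone transforms. The window count/width defaults are
declared configuration: the checks used to validate the index (ideal
ranking ≥ 0.9, null |index| ≤ 0.3) are insensitive to them.

**Moran's I.** Computed on presence residuals with row-standardized
inverse squared great-circle-distance weights and a permutation p-value
(999 permutations by default, two-sided). Inverse *squared* distance is
used because plain 1/d weights let distant, anticorrelated pairs dilute
the statistic to the point where even a perfect spatial gradient scores
only I ≈ 0.3; with 1/d² the same gradient scores ≈ 0.6. The power is a
parameter. Coincident points are separated by a deterministic ~1 m jitter
before weights are formed.

## Ensemble, zones, periods, niche breadth

Repeats enter the changing-niche ensemble when ΔAIC > 2 and Boyce > 0.7;
cell-wise mean (default) or median is taken over members. The fixed-niche
(null) ensemble uses the complementary gate ΔAIC < 2 only — it estimates
the habitat dynamics expected from climate fluctuation alone.

Minimum-predicted-area thresholds are computed once on the ensemble
suitabilities at all occurrences pooled over slices (not per slice): the
threshold at coverage c is the k-th smallest value, k = n − ⌈cn⌉ + 1, the
largest cutoff that still covers at least c of the occurrences, with no
rounding anywhere. Coverages 0.90/0.95/0.99 define nested core ⊆
peripheral ⊆ total zones.

Period aggregation uses the Marine Isotope Stage subdivision of the
120–14 ka window (5e…5a, early/late 4, early/mid/late 3, early/late 2).
Two boundary adjustments make the table a partition of the time axis:
MIS 5a is taken as 85–71 ka (closing a 1-kyr gap at the 5b/5a boundary in
the published subdivision) and late MIS 2 extends to 14 ka (the study
window's end). Slices belong to half-open (younger, older] bins; per-cell
period means are simple averages over member slices. The modal biome class
per cell per period breaks ties toward the drier class (desert < savannah
< forest) and flags tied cells.

Suitable habitat (core + peripheral) is summarized per slice and biome
class as area in km² with cosine-latitude cell weighting (planet radius
6371 km, configurable). Niche breadth is measured in climate space: the
five covariates are standardized over all land cells of all slices, a PCA
is fitted once, and per slice and class the suitable cells are projected
onto PC1–PC2; a Gaussian kernel density (normal-reference plug-in
bandwidth) is thresholded at the 1% quantile of its values at the data
points — so the suprathreshold region encloses 99% of the kernel mass in
the well-calibrated case — and its area is integrated on a 256×256 grid
padded by 3 bandwidths. A density-contour region was chosen over a convex
hull because hull area is unstable under outliers and does not converge to
the analytic 99% ellipse for Gaussian clouds, which is the oracle used to
validate the estimator (π·χ²₂(0.99) ≈ 28.9 for a standard normal cloud).
Class-slices with fewer than 3 suitable cells get area 0 with a degeneracy
flag.

## The synthetic-data generator

The generator emulates the *statistical structure* the pipeline assumes,
not the physics of any climate model: covariate fields are 2–3 sinusoidal
spatial harmonics (giving genuine spatial autocorrelation, which the
Moran's I diagnostics need) plus an optional linear temporal trend and
i.i.d. cell-slice noise; the land mask is a thresholded harmonic field;
biomes are covariate-threshold classes (LAI ≥ 3 forest, < 0.5 desert, else
savannah by default). Occurrences are drawn per slice with probability
proportional to a product-Gaussian suitability whose optima may drift
linearly across the window; reported ages get Gaussian error truncated to
the time range, with the reported half-range set to 2× the true error sd
(the generator reports its own uncertainty honestly on the ±-as-2σ
convention). Ground-truth columns travel with the table but no pipeline
stage reads them.

Default scale: 120 → 14 ka in 2,000-year steps (54 slices), a 20×20°
domain at 2° cells with ~15% sea, 6 occurrences per slice (≈ 290 presences
per repeat after effort equalization — comparable to the ~479-occurrence
scale of the real record after subsampling), dating error sd 1,000 years.
These sizes keep a full fit pair under ~5 s and a 10-repeat end-to-end run
around a minute.

What passing tests on this world do **not** show: robustness to
bias-corrected/downscaled real climate structure (sharp orography,
coastlines, Heinrich-event excursions), to spatially clustered discovery
effort, to non-Gaussian or asymmetric dating errors, or to niche shapes
far from smooth unimodality. They do establish that every stage computes
what it claims on data whose truth is known.

## Known limitations

* Smoothing selection is Fellner–Schall with one λ per term; mgcv-style
  per-margin λs for tensors and exact REML are not reproduced, so ΔAIC
  values are internally consistent but not numerically interchangeable
  with other engines. (A cross-check against an independent smoother on a
  univariate binomial smooth agrees in predictions to r > 0.98.)
* The Δ>2 calibration was characterized at the default synthetic scale
  (~300 presences, 1:200 class ratio); very different presence counts or
  ratios would warrant re-checking the null rate.
* Calibration is single-determination ("basic"); no Bayesian sequence
  modelling across layers.
* Stage subcommands of the CLI rerun the pipeline rather than resuming
  from intermediate artifacts; artifacts are nonetheless self-contained
  and individually re-loadable.
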