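# Methods

## Stochastic nucleation model

Droplets are treated as identical, independent reactors. With volumetric
nucleation rate *J* (mm⁻³ s⁻¹) and droplet volume *V* (mm³), the
probability of a nucleation event in d*t* is *J·V·*d*t*; waiting times
are therefore exponential with rate *J·V*, and the clear fraction of a
population of *N* droplets is the empirical survival function
`f_clear(t) = exp(−J·V·t)` in expectation. Times beyond the simulated
horizon are censored and carried as a `+inf` sentinel (serialized as an
empty CSV field).

Droplet volume follows the monolayer-capillary geometry: a droplet of
radius *r* with 2*r* ≤ capillary thickness *h* (default 200 μm) is a
sphere, `V = 4/3·π·r³`; a larger droplet is squashed to a disk,
`V = π·r²·h`. The default droplet radius is 50 μm — the papers in this
area rarely report the emulsion droplet size, and 100 μm-diameter drops
are typical of capillary-collected monolayer emulsions; this gives
V ≈ 5.24×10⁻⁴ mm³, matching the 5×10⁻⁴ mm³ reference volume used in the
recovery studies to the drawing precision.

## Synthetic imaging

Frames emulate crossed-polarizer contrast: dark background (0.08 on a
[0, 1] scale), each droplet a faint boundary ring (0.22), and each
nucleated droplet a bright compact blob (0.95) whose radius grows
linearly (0.03 px/s from a 2 px seed) and saturates at 40% of the
droplet radius. A single blob per droplet suffices because downstream
analysis needs only presence/absence, not morphology. Additive Gaussian
noise (sd 0.02 by default) is applied and intensities clipped; an
optional linear illumination gradient supports robustness tests. No
birefringence physics is modeled — only the bright-on-dark appearance.
Droplet centers are placed by seeded rejection sampling with no overlap;
an overcrowded configuration raises a capacity error rather than
degrading silently. Identical config + seed ⇒ bit-identical stacks.

What a green test on synthetic data does *not* establish: robustness to
real-microscope artifacts (drift, debris, uneven illumination, droplet
coalescence, multiple/faint crystals). An optional phase-correlation
drift estimator is provided but off by default (sealed capillaries are
stationary).

## Imaging pipeline

Segmentation: contrast normalization → Canny edges (σ = 2) → circular
Hough transform over the configured radius range → absolute accumulator
threshold 0.35 (fraction of perimeter supported; an absolute cut makes
blank frames yield zero detections) → greedy euclidean non-maximum
suppression at 1.5·min_radius. Hough radii are then refined to the
intensity-weighted centroid of the radial ring-profile peak: Canny fires
on the outer edge of the boundary ring, and the uncorrected ~2 px
overshoot propagates into an ~8% volume overestimate and a matching
underestimate of *J* when the volume is derived from segmented radii.
Masks of distinct droplets are made disjoint by assigning contested
pixels to the nearer center. Coordinates are (row, col), 0-based,
origin top-left.

Classification replaces the original machine-learning classifier with a
transparent feature-threshold classifier under the same contract (the
trained weights are not reproducible; thresholds are). Features per
droplet-frame, computed on an eroded interior (radius shrunk 20% minus
1 px, keeping the boundary ring out) with per-frame background
statistics so all features are offset-invariant:

- `bright_area_fraction` — fraction of interior pixels above background
  mean + 6·sd (default ≥ 0.01 calls crystal);
- `max_intensity` — interior max minus background mean (default ≥ 0.4);
- `gradient_energy` — mean Sobel magnitude (diagnostic only by default).

A `calibrate_thresholds` routine re-derives thresholds from any labeled
synthetic set by splitting the clear/crystal margin geometrically.

Tracking: droplets are stationary, so first-frame ROIs apply throughout.
Raw calls are debounced — two consecutive crystal frames are required to
commit, which suppresses single-frame debris flashes — and committed
states are monotone (clear → crystal only). The first-crystal time is
the timestamp of the first committed frame; a classification error model
matching the original study's is not claimed.

## Kinetics estimation

`f_clear` is computed per frame as N_clear/N. The rate fit is unweighted
OLS of `ln f_clear` vs *t* using only points with
`0.1 < f_clear < 0.75` (strict inequalities, so `f_clear = 0` can never
enter); `J = −slope/V`, with the slope's standard error scaled the same
way. Unweighted OLS is the simplest reading of "linearize and fit"; a
binomial-variance WLS option (`weighted=True`) exists for small-*N*
curves. At least 3 in-window points are required. The induction time is
the `f_clear = 0.75` crossing with linear interpolation between the
bracketing frames; a curve that never reaches the threshold returns a
not-reached sentinel with a warning, and a curve starting below 1
(crystals before imaging began) warns but is analyzed as observed. For
real data the volume defaults to the median segmented droplet radius
pushed through the monolayer volume model, overridable explicitly.
Replicate summaries report mean ± sample SD (n−1), with SD 0 and a
warning for a single replicate.

Numerical checks: the window-restricted OLS agrees with an independent
censored-exposure MLE (events / V·clear-time, both restricted to the
window's time span) within 5% across two orders of magnitude of *J·V*;
doubling *V* exactly halves *J*; perturbing points outside the window
never changes the estimate.

## Batch statistics

Nucleation probability is #crystal / (#crystal + #clear); precipitated
drops are excluded *before* any resampling, mirroring how they are
excluded from the probability itself. The default interval is the
percentile bootstrap (10⁴ resamples): each arm's non-precipitate
outcomes are resampled independently with replacement and the 2.5th and
97.5th percentiles of the recomputed difference are reported; BCa is
available behind a flag. Outcome arrays are sorted before resampling so
results are exactly invariant to outcome order. The original analysis
states neither the resample count nor the bootstrap flavor, so absolute
CI widths are not claimed to match it; empirical coverage at n = 32 is
verified to sit in [0.92, 0.98] under the null.

The batch driver's simulated world uses a control crystallization
probability of 0.25 (a plausible low-supersaturation baseline) with the
published absolute increases (+0.20 NHS, +0.50 MAL) and a 5%
precipitation rate per arm.

## Design choices where the source was open

- Induction threshold and fit window are constants of the analysis
  (0.75; 0.1–0.75 exclusive) and are the defaults everywhere; overrides
  are logged as warnings.
- The reference recovery studies fix V = 5×10⁻⁴ mm³, since the original
  droplet volume is unstated; absolute-rate comparisons inherit that
  assumption.
- Whether the original fit included the pre-decay lag is unstated; this
  implementation fits in-window points only.
- CSV/TIFF layouts are chosen so real microscope exports can be dropped
  in with no conversion beyond file naming.

## Known limitations

- Presence/absence only: no crystal counting, sizing, or polymorph
  calls; no precipitation inside emulsion droplets (batch outcomes only).
- No two-step or non-Poisson nucleation models, crystal-growth kinetics,
  or solubility-diagram modeling.
- The threshold classifier is calibrated for bright-on-dark crystal
  contrast; brightfield-only data would need recalibration.
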