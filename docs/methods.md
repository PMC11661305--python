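# Methods

## The smND assay

The assay treats a PALM localization table as a realization of a marked
spatial point process. A membrane patch carries complexes of size
k ∈ {1, 2, 3} at complex-level fractions (f_M, f_D, f_T). Each complex
exposes its k subunits at the vertices of a regular k-gon of edge
`subunit_spacing` (default 5 nm — the footprint of a small transporter
subunit; the true intra-complex geometry is unresolved at these scales, and
at 5 nm spacing versus ≥10 nm localization noise the k-gon choice is
immaterial). Each subunit is photoconverted and detected independently with
probability `p_detect`; each detected subunit contributes one localization
(plus `Poisson(blink_mean)` extra ones when blink merging is disabled),
displaced by isotropic Gaussian noise of std `sigma_loc`. Background
localizations arrive as a uniform Poisson process.

For every localization, the neighbor density **ND** is the number of other
localizations within a circle of **diameter** 40 nm (radius 20 nm — the
diameter/radius distinction is a classic off-by-two hazard and is pinned by
tests). The normalized histogram of ND is the experimental distribution
**PND_exp**. Because the generative model above fully specifies the imaging
process, the theoretical counterpart **PND_theo(f)** for any candidate
mixture is computed by forward Monte Carlo: simulate replicate fields at the
candidate fractions with the matched nuisance parameters, pool their
neighbor counts, and normalize. In the dilute, small-noise limit this
reproduces the closed-form composition of pure-state PNDs with
localization weights w_k ∝ k·f_k (a detected subunit of a size-k complex
sees Binomial(k−1, p_detect) detected partners), which the test suite checks
against the binomial form directly.

Fitting minimizes the residual sum of squares
Σ_n (PND_exp(n) − PND_theo(n; f))² over the mixture simplex with an
exhaustive coarse-to-fine grid (0.05 then 0.01 resolution in a neighborhood
of the coarse optimum). With only two free parameters the exhaustive grid is
deterministic and immune to local minima. Monte-Carlo PND_theo curves are
cached per (fractions, nuisance, seed) key, so the reference grid is built
once and shared across fields, conditions, bootstrap resamples and the
dissociation fits. Bootstrap uncertainties resample the per-localization ND
values and refit over the already-evaluated grid points (no fresh Monte
Carlo), which bounds their cost while preserving the sampling-noise scale.

Monte-Carlo budget: 3 replicate fields of 3000 complexes per grid point
(~12,000 localizations) keep each PND bin's Monte-Carlo standard error below
0.005. The companion statistic **TNPD** is defined here as the mean of the
distances to the first and second nearest neighbors of each localization;
other conventions exist (the pair itself, or the second-nearest distance
alone), and the choice is a flagged assumption — it only feeds a model-free
shift readout, never the mixture fit.

## Dissociation limiting models

A trimer can dissociate via T → M + D (equilibrium constant K1) or
T → 3M (K2). Only the limits K1/K2 → ∞ and K2/K1 → ∞ are used; the
constants themselves are never estimated. Parameterized by the extent
x ∈ [0, 1] (fraction of initial trimers dissociated), the complex-count
bookkeeping per initial trimer gives fractions (x, x, 1−x)/(1+x) for model 1
and (3x, 0, 1−x)/(1+2x) for model 2, with exact subunit conservation
(3T + 2D + M = 3) at every x and N̄ = 3/(1+x) and 3/(1+2x) respectively.
Both models run as one-dimensional constraints on the same residual-square
machinery as the unconstrained fit, so residuals are directly comparable;
model 1 bounds the trimer fraction from below and model 2 from above. The
bracketing is a statistical statement: at desk-scale fields
(~4000 localizations) the unconstrained estimate can overlap a bound within
its bootstrap uncertainty, and the bound-ordering check therefore runs at
10,000 complexes with 6 Monte-Carlo replicates per grid point.

## Localization engine

Background subtraction removes, from each frame, the mean of up to 50 frames
before and after it (the frame itself excluded; the window shrinks
symmetrically for short movies, with a log line). Candidates are strict 3×3
local maxima above `min_snr` times the frame's MAD-based robust noise sd,
with candidates closer than 9 px merged to the brighter one. Each 9×9
subregion is fitted with
I(x, y) = b + A·exp(−½[((x−x₀)/σx)² + ((y−y₀)/σy)²]) — the printed form of
such models often drops the amplitude and the −½; the standard form is used.
The fit is two-pass nonlinear least squares: an unweighted pass provides
starting values and a residual-based background sd, then the fit repeats
with per-pixel shot-noise weights (variance ≈ expected signal + background
variance). The weighting matters: unweighted least squares scatters ~18%
wider than the localization-error formula predicts, while the weighted fit
matches it within a few percent across a photons × background grid.

Integrated photons are N = 2π·A·σx·σy/a² for pixel size a; the
per-localization error is the square root of
σ²/N + a²/(12N) + 8πσ⁴b²/(a²N²) (photon, pixelation and background terms),
evaluated with the *fitted* σ — pixel integration widens the apparent width
to √(σ² + a²/12), and the fitted value is what the formula's derivation
refers to. SNR is defined as fitted amplitude over residual background sd
(the quantity is not standardized; the filter threshold is configurable).
Quality filters keep FWHM ∈ [117, 600] nm and error ∈ [0, 20] nm
(inclusive) and SNR > 3.6 (strict), matching the stated wording; the lower
FWHM bound is treated as an opaque constant. FWHM converts from the mean of
the fitted widths via 2√(2 ln 2)·σ. Duplicates within 50 nm across ≤1-frame
gaps merge transitively to the photon-weighted mean. Drift correction uses
redundant cross-correlation: localizations are binned temporally, rendered
as 20 nm 2D histograms, Gaussian-smoothed (σ = 2 px — sparse unsmoothed
renderings have no stable correlation peak), registered pairwise by
upsampled cross-correlation, combined by least squares with the first bin as
reference, and interpolated per frame. RCC requires repeated underlying
structure across time bins; on a structureless uniform field it has nothing
to register, which is a property of the method, not the implementation.

## TIRF penetration-depth calibration

Gold nanospheres suspended in gel above the coverslip are localized in z by
Gaussian fits of their epi-illumination intensity-vs-z trajectories
(profiles whose maximum sits at a scan endpoint are flagged invalid). A
least-squares plane z₀ = ax + by + c removes the coverslip tilt. TIRF-mode
SNR (against the standard deviation of the dimmest 14% of pixels) is binned
along the corrected z in 100 nm intervals (bins with <3 spheres dropped,
logged; fit unweighted by default with a count-weighting flag) and fitted
with S(z) = S₀·[exp(−(z−ζ)/d)·H(z−ζ) ⊛ N(0, σ_z²)] — the exponentially
modified Gaussian in closed form, evaluated through erfcx with a log-space
branch for numerical stability. σ_z absorbs the epi z measurement error and
is bounded by half the bin width; the onset ζ is needed because the
least-squares plane sits at the *mean* sphere height, so the coverslip —
where the decay starts — lies below corrected z = 0. Degenerate profiles
(flat SNR, depth at its bound) raise with diagnostics rather than returning
a number. The synthetic generator places sphere heights half-normally with
a 150 nm scale so that 84 spheres populate 4–5 of the prescribed 100 nm
bins — a calibration sample that spans fewer bins cannot constrain the fit.

## Puncta and ROIs

Marker-channel images are background-subtracted with a 50 px rolling ball,
thresholded with a moment-preserving (Tsai) bilevel threshold — the
algorithm behind the "Moments" auto-threshold of common image software,
implemented here on a 256-bin histogram — labeled 8-connected, and filtered
to area 0.12–4 µm² and circularity 0.04–1.00. Circularity uses the Crofton
perimeter estimate (≈ true boundary length for disks; the naive pixel-path
perimeter underestimates thin structures badly enough to pass a 1 px line
through the 0.04 cutoff). Rab5⁺ ROIs are puncta strictly below 0.3 µm²
(the ~0.4 µm² peak of the intensity-size profile is descriptive, not the
cutoff). Each positive ROI's exact pixel footprint is translated to a
uniformly random non-overlapping position inside the cell mask to form its
negative control, guaranteeing exactly equal counts and total areas; pairs
that cannot be placed are dropped from both sides with a warning.
Localization density is boundary-inclusive point-in-footprint count over
area.

## Condition comparison

The replication unit is the field (one cell's worth of pooled ROI
localizations); per-field fits are summarized as mean ± SEM and compared
with a two-sample Student t-test (pooled variance by default, Welch behind a
flag). Localizations are pooled across the selected ROIs of a condition
before PND aggregation. Reports record every parameter needed to reproduce
the run (seeds, radius, thresholds, nuisance, grid resolution) and are
byte-deterministic for a fixed configuration.

## What the synthetic data does and does not show

The generators emulate the *geometry and statistics* of the measurement —
mixture composition, detection thinning, localization noise, background,
blinking over-counting, camera shot noise, coverslip tilt, evanescent decay
— with uniform complex placement (dilute spatial Poisson) and a flat 2D
membrane. They do not model higher-order clustering beyond oligomers,
3D PSFs, dipole emission, realistic fluorophore photophysics, or
cell-to-cell expression variability. Passing tests therefore demonstrate
that the estimators recover truth *under the stated generative
assumptions*; on real data, unmodeled clustering or undercounting would bias
the mixture fit in ways the dissociation bounds are designed to bracket, not
eliminate.

Defaults and problem sizes: detection efficiency defaults to
`p_detect = 0.6` (a typical photoconversion efficiency for green-to-red
convertible tags; the true value for any given tag must be calibrated, which
is why it is an explicit nuisance parameter rather than a constant),
`sigma_loc = 10 nm` (~20 nm lateral resolution), complex density 5 µm⁻²
(dilute: most subunits have few neighbors), background 0.2 µm⁻². Fitting
tests use 3000-complex fields; the accuracy figure reported by
`scripts/acceptance.py` is the mean absolute fitted-fraction error over a
monomer:trimer dilution series at these conditions, and comes out around
3 percentage points — comfortably inside the assay's nominal 10-point
working error.
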