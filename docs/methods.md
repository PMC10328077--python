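# Methods

This note documents the models, estimators and numerical choices behind
`tirfquant`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Image formation model (simulator)

A focus with `n` surviving fluorophores at sub-pixel position (x, y)
contributes an expected photon count per pixel of

    E[I(r, c)] = λ + n · ν · Fx(c) · Fy(r)

where λ is the background rate (counts/pixel/frame), ν the photon scale per
fluorophore per frame, and Fx/Fy are differences of the Gaussian CDF across
the pixel edges — i.e. the symmetric 2-D Gaussian PSF of width `psf_sigma`
is *integrated over the pixel area*, not point-sampled, so sub-pixel
photometry and localization tests are exact. Observed counts are
Poisson-distributed around this expectation, plus additive Gaussian read
noise, plus an optional camera offset, clipped at zero. Setting
`shot_noise=False` with zero read noise yields the analytic expected image
("expectation mode"), used by the noiseless oracles.

Photobleaching is irreversible, per fluorophore, with probability `p` per
frame: survival follows binomial thinning, `n_{t+1} ~ Binomial(n_t, 1-p)`,
so surviving counts are non-increasing and `E[n_t] = N(1-p)^t`. Blinking,
maturation and simultaneous-bleach correlations are deliberately absent —
the stoichiometry model assumes monotone step-wise loss.

Defaults encode the emulated acquisition: 100 nm/pixel, 50 ms/frame,
`psf_sigma` 1.3 px, λ = 100 counts/pixel/frame, read noise 2 counts. The
photon scale ν is a free instrument parameter (the laser-power-to-count
conversion of the real microscope is unknown); the default ν = 2000
counts/fluorophore/frame puts a single dye at a photometric SNR of ≈ 13
(summed intensity over the sd of that sum) and a per-inner-pixel acceptance
SNR of ≈ 0.9 — a clean step-trace regime in which the 0.4 acceptance
threshold admits single dyes, as the stoichiometry calibration requires.
Two-colour fields assign a red partner, displaced by an isotropic Gaussian
of width `coloc_displacement_sigma` (default 0.3 px), to a configurable
fraction of green spots.

The tissue generator renders non-overlapping nuclei as filled discs in a
DAPI-like channel and builds two signal channels from equal-variance random
fields: channel A is a shared field and channel B is
α·shared + (1−α)·independent, so the expected Pearson correlation between
the channels is α/√(α² + (1−α)²) — analytically controllable for
correlation-recovery tests. Real tissue features it does not emulate:
autofluorescence (lipofuscin), spatially structured markers, touching
nuclei, chromatic shifts. Passing tests therefore demonstrate correctness
of the measurement chain, not robustness to those artefacts.

## Detection and localization

Candidates are local maxima of a difference-of-Gaussians band-pass
(widths σ and 2σ, σ = `mask_sigma_px`) exceeding the band-pass median plus
`candidate_threshold_sigmas` (default 4) times a median-absolute-deviation
noise estimate; duplicates within one PSF width are merged keeping the
brighter (ties toward smaller row, column).

Sub-pixel refinement is iterative Gaussian masking: subtract the ROI
border-ring mean, multiply by a unit-height Gaussian mask of width
`mask_sigma_px` centred on the current estimate, recompute the
intensity-weighted centroid, and repeat until the shift is below
`convergence_tol_px` (default 0.01 px, max 100 iterations). A ROI that is
non-positive everywhere after background subtraction is degenerate and
returns the seed unchanged. At single-dye photometric SNR 5 this estimator
matches a full least-squares Gaussian fit on identical frames (RMS ≈ 0.19
px, at the information limit of the data); noiseless accuracy is ≈ 0.01 px.

Photometry uses a square ROI of half-width 8 px (17×17; the "small square
region of interest" of this style of analysis is conventionally not
dimensioned, and 17×17 comfortably
contains a `psf_sigma` ≤ 2 px spot): background b = border-ring mean,
intensity I = Σ(roi − b) over the 15×15 inner square, and
SNR = (I / 225) / sd(ring). The SNR acceptance threshold 0.4 is strict
(`snr > 0.4`); with this definition 0.4 is a permissive per-pixel criterion
that accepts dim single dyes. A zero-variance ring (noiseless data) maps to
a large documented sentinel rather than a division error.

## Tracking

Foci are linked frame-to-frame by minimum-total-squared-displacement
bipartite assignment (Hungarian algorithm) restricted to pairs within
`link_radius_px` (default 5 px); unmatched foci start new tracks. No gap
frames are allowed by default: surface-captured complexes are essentially
immobile and a gap would corrupt the photobleaching trace. Tracks are kept
only when strictly longer than 3 frames.

## Chung–Kennedy filter

The edge-preserving filter used before step detection. For each sample t
and window size w ∈ {2, 4, 8}, a forward predictor (mean of the w preceding
samples) and a backward predictor (mean of the w following samples) are
formed, truncated at the trace ends (an empty window predicts the sample
itself). Each predictor is weighted by its summed squared prediction error
over the most recent w samples raised to −p (p = 2), with an additive
regularizer 1e−12 guarding exact zeros; weights are normalized to sum to 1
over all predictors. A predictor whose window straddles a step accrues a
large error and loses essentially all weight, so noiseless steps pass
through exactly while plateau noise is averaged. Window sizes and exponent
are conventional values from the filter's literature and are configurable.

## Step detection and single-dye calibration

Change points are found by recursive splitting at the largest
pooled-variance two-sample t statistic, splitting while the statistic
exceeds `step_sensitivity` (default 5; zero-variance splits with distinct
means count as infinite). Adjacent segments whose mean difference is below
a noise floor (default twice the robust noise sigma from median absolute
successive differences) are merged back. Only downward steps are reported,
with the frame index of the lower plateau's first sample.

A track ends when its focus bleaches below detectability, so the final step
to background is never observed in the trace. The single-dye sample is
therefore the mean of each trace's *final plateau* (after the last detected
step; the whole trace when no step is found), which is the period in which
almost always one fluorophore survives. I_single is the mode of a Gaussian
KDE over this sample — robust to the minority of multi-dye contaminants
(simultaneous final bleaching, unbleached traces), unlike the mean. The
choice of the KDE mode over a mean or spectral estimate is configurable in
the sense that `characteristic_intensity` accepts any candidate sample.

## Stoichiometry

For tracks starting within the first 10 movie frames (0-based frames 0–9;
molecules landing later are excluded, since field bleaching has already
begun) and at least 4 frames long, I₀ is the ordinary least-squares
intercept of the first 4 raw intensity points at the track's first frame —
raw, not filtered, because filtering serves step visualization while OLS
already averages noise. S = I₀ / I_single, with I_single estimated per
channel and per run. For a 10%/frame exponential decay the 4-point linear
intercept is within 0.5% of the true initial intensity.

## Colocalization

The "overlap integral" — a quantity usually quoted in single-molecule
colocalization work by name and cut-off only — is defined here explicitly
as the normalized cross-correlation of unit-height symmetric Gaussians at
the two centroids:

    O = [2σ_Aσ_B/(σ_A²+σ_B²)] · exp(−d²/(2(σ_A²+σ_B²)))

It is dimensionless, symmetric, in [0, 1], equal to 1 only for identical
position and width, and strictly decreasing in distance; for equal widths
O > 0.75 reduces to d < 2σ√ln(4/3). The width is fixed at the configured
PSF width rather than fitted per spot, for stability on dim foci. Pairing
is one-to-one, greedy by descending O among candidates within 3 combined
widths, computed on each track's first detected frame (later frames are
bleach-depleted). The colocalized proportion is colocalized green foci over
all green foci. Stratified stoichiometry summaries use a two-sided
two-sample Student's t-test; two zero-variance groups with distinct means
are reported as maximally significant with a `degenerate_variance` flag.

## Tissue analysis

Otsu's threshold maximizes between-class variance over a 256-bin histogram
of the data range (strictly-above pixels are foreground; a constant image
raises). Between well-separated modes the objective has an exact tie
plateau, so any plateau member is a valid threshold — oracle comparisons
are made on the achieved objective. Cleanup fills interior holes first,
then removes 8-connected components with area strictly below 50 px. Each
surviving nucleus gets a 100×100 px box centred on its mask centroid
(clipped at image borders; "bounding box of 100 pixels" is read as a
100×100 box, configurable via `roi_box_px`). Per-ROI Pearson correlation is
computed over all ROI pixels for every declared signal-channel pair
(undefined when either channel has zero ROI variance, reported as missing);
summed background-corrected intensity is Σ max(pixel − background, 0) with
the per-channel histogram mode as background.

## Problem sizes, determinism, degenerate inputs

The validation suite runs entirely on simulated data at desk scale: e.g.
stoichiometry recovery uses 130 spots per group for N ∈ {1, 2, 5, 10} on a
340×340 px field over 80 frames at bleach probability 0.05/frame (130
simulated spots leave ≥ 100 estimates per group after the pipeline's own
duration filter — an N = 1 spot has ≈ 14% probability of bleaching before
its 4th frame); localization uses fields of 200–520 spots; colocalization
uses 220 green foci at true fraction 0.5 and 200 + 200 random foci in a
100×100 µm field (0.02 foci/µm²) for the chance-colocalization control.
These sizes give stable medians and binomial intervals while keeping the
whole suite fast.

All randomness flows from a single seed through named substreams; identical
configuration and seed give bit-identical images and byte-identical output
tables. Degenerate inputs have defined behaviour throughout: empty traces,
constant images, zero-variance ROIs, uniform detection ROIs, empty channels
and unreadable TIFFs either raise a specific error or return a flagged
record, as documented per function.

## Known limitations

- The overlap-integral functional form and the SNR definition are
  conventions chosen and fixed here; both are documented and configurable,
  and conclusions that depend on their exact form should be checked against
  the recorded definitions above.
- No drift correction, gap closing, blinking correction or EMCCD gain
  modelling; the simulator's idealizations (see above) bound what passing
  tests demonstrate about real microscope data.
- Touching nuclei are not split (no watershed); dense tissue fields will
  merge adjacent cells into one ROI.
- Step detection assumes piecewise-constant traces; continuously decaying
  signals (e.g. strong field-wide photobleaching within a plateau) bias
  step sizes.
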