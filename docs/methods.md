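# Methods

This note records the models implemented by `azping`, the defaults that
matter, what the synthetic-data generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## The assay being modelled

Postsynaptic GCaMP at the *Drosophila* larval NMJ reports each quantal
release event as a local fluorescence transient at the releasing active
zone (AZ). Recordings come in pairs per cell: a stimulus-free episode
(spontaneous activity) and an evoked episode in which single action
potentials are delivered at 0.2 Hz (canonically 36 stimuli over 180 s,
3,600 frames at 20 Hz). AZ positions come from a post-hoc confocal image
of the AZ scaffold marker (BRP), registered onto the live movie.

## Synthetic-data generator

`generate_movie` renders each event as a separable kernel: an isotropic
spatial Gaussian of unit peak (σ = `psf_sigma`, default 0.5 μm, so that
neighboring ROIs see an attenuated copy of every event — the property the
conflict-resolution stage exists for) times a temporal envelope with
instant rise and single-exponential decay (`decay_tau`, default 0.2 s,
matching the ~200 ms decay of real quantal GCaMP transients). Per-pixel
signal is

    camera_offset + static AZ field + Σ events + bleach_slope · t + noise,

clipped and quantized to 16 bits. Defaults: 50 ms frame interval, live
pixel edge 0.10833 μm, confocal pixel edge 0.100 μm.

Choices worth knowing:

* **Static resting field.** Each AZ carries a constant resting punctum
  (`az_baseline`, default 2000 a.u.) in addition to its transients. Real
  NMJs have basal GCaMP fluorescence; without it the cross-correlation
  stabilizer would have no structure to lock onto between events.
* **Amplitudes** are truncated-normal (truncation at zero). No amplitude
  distribution is established for quantal events in this preparation; the
  choice is pragmatic, not inferred from data.
* **Noise** is additive Gaussian. Poisson shot noise, z-motion, and
  indicator kinetics (rise time, saturation) are not modelled, so passing
  tests demonstrate correctness of the *analysis* under its own
  assumptions, not robustness to every property of real recordings.
* **Drift** is integer-pixel and rigid, matching the integer x–y
  translation model of the stabilizer; sub-pixel or elastic motion is out
  of scope.
* **Randomness**: one `SeedSequence` per movie, split deterministically
  into placement / event / noise sub-streams, so outputs are bit-identical
  for a fixed seed.
* **Event rates** used in the property suites (0.04–0.08 events·AZ⁻¹·s⁻¹)
  are deliberately higher than typical real per-AZ rates so that a
  30-second synthetic movie carries enough events for stable
  sensitivity/precision estimates; the detector itself has no
  rate-dependent parameters.

## Stabilization and registration

Shifts are estimated per frame against frame 0 by normalized (zero-mean,
unit-variance) cross-correlation of Gaussian-smoothed images (σ = 5 px);
plain correlation would be intensity-biased. The smoothing affects only
the estimate — output frames are translated unsmoothed, with zero fill.
Only integer shifts are estimated, keeping the shift-recovery tests
oracle-exact against a brute-force search. Estimated shifts beyond
`max_shift` (default a quarter of the frame edge) are clamped with a
warning.

Control-point registration solves the affine (≥ 3 non-collinear pairs) or
bilinear (≥ 4 pairs, no 3 collinear) transform exactly at the minimal
point count and by least squares otherwise. Images are resampled by
inverse mapping with bilinear interpolation; the bilinear transform's
image inverse has no closed form, so the inverse map is the bilinear fit
of the swapped control points (exact at 4 points). Landmark selection is
delegated to input files — the workflow is user-guided.

## ROI quantification

AZ centers are prominence-based local maxima (h-maxima, mirroring the
noise-tolerance semantics of ImageJ's *find maxima*; default threshold 15,
the midpoint of the 10–20 range used in practice). ROIs are 650 nm
circles; a pixel belongs to the mask when its center lies inside the
circle (boundary inclusive), which at the 108.33 nm pixel edge gives the
canonical 29-pixel mask. Coordinates are 0-based, x = column, y = row,
pixel centers at integer coordinates.

Background ROIs are the same masks moved by one global offset vector into
a fluorescence-free region (the synthetic data guarantees a dark margin;
the pipeline picks the offset automatically when none is given).
Correction order is fixed: background subtraction first, then the per-ROI
ordinary-least-squares detrend, exactly removing any affine trend.

Inter-AZ distances are `sz_px · sqrt(dx² + dy²)` in micrometers — the
plain Euclidean distance scaled by the pixel edge.

## Event detection

The trace filter is a causal length-5 moving average; the detection SD is
taken over the full filtered trace (the simplest convention — a sliding
window would make the threshold non-stationary; filter width, threshold
multiple and run length are all parameters). A candidate run is every
maximal set of consecutive frames whose 3-frame forward mean of the raw
corrected signal exceeds 4×SD; the candidate's frame and amplitude are the
argmax and max of the corrected signal within the run.

Two consequences are worth stating plainly. First, the threshold is
self-regulating: transients inflate the filtered-trace SD, so the false
positive rate drops as activity rises; on pure noise, the flagged-frame
fraction is ≈ 10⁻³ (the analytic level of the 3-frame-mean/4×filtered-SD
rule on white noise). Second, two same-AZ events closer than a few frames
merge into a single run and are counted once — an intrinsic resolution
limit of the rule. Candidate acceptance is fully automatic: where lab
practice often adds a manual review of threshold crossings, this package
accepts all of them for reproducibility.

Conflict resolution keeps, per frame, the highest-amplitude candidate and
discards all others within the radius (2.5 μm evoked; 1,000 μm
spontaneous — effectively whole-field exclusivity), repeating on the
remainder; amplitude ties break toward the lower ROI id for determinism.
The evoked window is half-open, (stim, stim + 1 s], with stimulus frames
computed by floor at the movie frame rate; interleaved mode excludes the
same windows.

## Blob detection

Preprocessing: 3×3×3 median filter, then per frame t ≥ 15 the maximum
(for detection) or mean (for fitting) projection of frames t−15…t−6 is
subtracted and negatives clipped. Candidates are 8-connected components
(4-connectivity is an option) of the σ = 3 smoothed max-subtracted frame
above grey value 2 (calibrated to 8-bit movies — convert first), localized
at the coordinate-wise median pixel, with a 10-px edge exclusion. Because
one transient stays visible across several consecutive max-subtracted
frames, detections within 5 px and 6 frames of an earlier one are linked
to it; the first detection frame is the event's peak frame.

The 2D Gaussian fit minimizes the sum of squared residuals (the reduction
of the residual image to a scalar is this package's choice) over
(A, x₀, y₀, c, baseline) with Nelder–Mead started at 20 for all five
parameters and restarted three times from the best previous values — a
deterministic chain. The spread is symmetric (a single c), and
FWHM = 2√(2 ln 2)·c. Patches at movie borders are zero-padded to preserve
the 39×39 geometry. Non-convergence flags the fit rather than raising.

## Statistics

**Survival.** Per cell, a 3,600-point vector starts at the number of
spontaneously active AZs and loses 1 from each AZ's *first* evoked event
onward; curves are normalized to 1 and averaged across cells unweighted
(whether cells should be weighted by AZ count is not established; a
per-cell option exists). Fits are nonlinear least squares of
`exp(−Kt)` or `(1−plateau)·exp(−Kt) + plateau` with K > 0 and
plateau ∈ [0, 1]; K is per frame internally (reports convert by the frame
rate). Model choice uses the small-sample corrected AICc
`n·ln(rss/n) + 2k + 2k(k+1)/(n−k−1)` by default (plain AIC by flag). A
fitted K below 10⁻⁶/frame flags a boundary (the curve never decayed).

**Negative-binomial mixed model.** Counts are NB2 (variance μ + μ²/θ)
with log link, the four spontaneous-count groups (0, 1, 2, ≥3 — AZs with
three or more events pool into one level) as a factor and a Gaussian
random animal intercept. The marginal likelihood integrates the intercept
out with Gauss–Hermite quadrature (15 nodes by default; 11 suffice for
the simulation suites) and is maximized with L-BFGS-B at relative
tolerance 10⁻⁸. The factor test is a likelihood-ratio χ²₃ against the
intercept-only model with the same random structure. Fitted group means
are conditional means at a typical animal (random intercept 0), matching
the generator's parameterization. The implementation agrees with R's
glmmTMB to four significant figures on shared tables (cross-checked in
the test suite). The recovery benchmark draws the four groups with equal
probability so that its 10% tolerance measures estimator accuracy rather
than the sampling noise of the rare ≥3 group; the generator's default
group frequencies (0.62/0.25/0.09/0.04, mimicking how rare high-activity
AZs are) are used everywhere else, including the type-I suite.

**Mann–Kendall.** S = Σ_{i<j} sign(v_j − v_i), one-sided. The null
distribution is exact for n ≤ 10 without ties (Mahonian-number recursion
over inversion counts) and for n ≤ 8 with ties (full multiset
enumeration); beyond that, the tie-corrected normal approximation with
continuity correction. The intended use case — a monotone trend across
four fitted group means — always takes the exact path. A constant series
reports S = 0 at the mid-distribution p of 0.5.

**Hill fit.** `F(c) = F_max·cʰ/(K_Aʰ + cʰ) + C` by bounded nonlinear
least squares over the six-point external-Ca²⁺ titration grid
(0.4–12 mM); at c = K_A the fitted curve equals C + F_max/2 identically.

## Pipeline and I/O

16→8-bit conversion maps the global stack min–max linearly to 0–255 with
round-half-up (a fixed-divisor mode would also be deterministic; global
min–max is the default because the display-range behavior of the original
conversion is unspecified). TIFF I/O goes through `tifffile`; CSVs are
comma-separated, UTF-8, header row, 0-based coordinates. `run_pipeline`
executes simulate/load → stabilize → ROI detection → quantification →
event detection → counts → survival in order, writes every intermediate
artifact and a JSON report, and logs every resolved parameter and seed;
reports are byte-identical across reruns of the same config and seed.

## Problem sizes in the test and acceptance suites

The suites use desk-scale problem sizes chosen to keep sampling error
well inside each tolerance: 20 movies (64×64×200) for exact shift
recovery; 20 movies (96×96×600, 8 AZs) for detection metrics; 59 cells ×
50 AZs for plateau recovery and 100 replicates (8 cells × 30 AZs) for
AICc selection rates; 100 animals × 100 AZs for NB mean recovery and 500
null replicates (12 animals × 80 AZs) for the type-I rate; 5 noiseless
patches for the Gaussian-fit oracle. These sizes are the package's own
benchmark design, not properties of the method.

## Known limitations

* Integer-pixel stabilization cannot correct sub-pixel or rotational
  motion.
* The event detector cannot split same-AZ events closer than ~3 frames,
  and whole-field exclusivity discards genuinely simultaneous spontaneous
  events at distant AZs (by design, to avoid double-counting spread).
* The NB mixed model assumes a single Gaussian random intercept; no
  random slopes or crossed effects.
* The blob detector's grey-value-2 threshold presumes 8-bit input.
* Synthetic data omit shot noise, indicator kinetics and z-motion (above).
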