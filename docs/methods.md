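# Methods

## Signal models and phantom

The phantom is a ring (annulus) of "myocardium" centered in a 2D short-axis
grid, or a stack of identical rings for 3D volumes. The annulus is split
into three contiguous angular sectors of 120° each (configurable),
labelled LCX, LAD and RCA; every myocardial pixel carries exactly one
territory label. Tissue parameters are piecewise constant with optional
smooth within-tissue variation (a Gaussian-filtered random field scaled to
a fractional standard deviation). Defaults are typical 3 T myocardium:

| parameter | default | unit | rationale |
|---|---|---|---|
| S0 | 100 | a.u. | signal scale; σ is quoted relative to it |
| T1 | 1200 | ms | native myocardial T1 at 3 T |
| T2 | 45 | ms | native myocardial T2 at 3 T |
| T2\* | 30 | ms | baseline R2\* = 1000/30 ≈ 33.3 s⁻¹ |
| MPIO ΔR2\* | 40 | s⁻¹ | strong local rate increase from bound iron oxide |
| noise σ | 2 | a.u. | σ/S0 = 0.02, i.e. baseline SNR 50 |

Signal models (times in ms, rates in s⁻¹, converted internally):

* multi-echo: S(TE) = S0 · exp(−TE · (R2\* + R2′)), where R2′ is a smooth
  macroscopic field-inhomogeneity map (zero by default);
* inversion recovery (magnitude): S(TI) = |S0 · (1 − 2 e^(−TI/T1))|;
* T2 preparation: S(τ) = S0 · e^(−τ/T2).

Noise is Rician: independent Gaussian noise of standard deviation σ is
added to the real and imaginary channels (the noiseless signal taken as
real) and the modulus is returned. σ = 0 reproduces the models exactly.
Background pixels then follow a Rayleigh distribution with mean
σ·√(π/2), which the generators' tests verify by moment matching.

What the phantom does **not** emulate: cardiac or respiratory motion, coil
sensitivity profiles, bSSFP banding/off-resonance readout effects, partial
volume at tissue borders, k-space artifacts, and lesion transmurality
(the MPIO increment fills its whole territory). Passing tests therefore
demonstrate correctness of the *quantification* chain, not robustness to
acquisition physics that the simulation omits.

## Relaxometry

**R2\*/T2\* (core fit).** Per pixel, ordinary least squares of ln S
against TE over the echoes with signal strictly above `min_signal`;
R2\* = −slope (converted ms⁻¹ → s⁻¹), S0 = exp(intercept). The fit is
deliberately unweighted (a signal-squared-weighted variant sits behind a
flag for comparison). `min_signal` defaults to 3× the background noise
level estimated from the four image-corner patches via the Rayleigh mean
(σ̂ = mean/√(π/2)); this excludes Rician-floor echoes from the log-line.
Non-positive signals are excluded per-echo rather than clipped, since
clipping biases the slope. Pixels with fewer than two usable echoes, or a
non-positive fitted R2\*, are marked invalid rather than clamped. Fit
quality is the coefficient of determination R²; a line through fewer than
three points has no residual degree of freedom, so its quality is reported
as 0 (this is what flags two-echo chance fits on pure-noise background).

**T1 (magnitude IR).** Magnitude data lose the recovery curve's sign, so
polarity is restored by flipping the earliest TIs up to either side of the
minimum-signal TI and keeping the candidate with the lower residual. For
each candidate, the signed data are fitted to A(1 − 2 e^(−TI/T1)) by
nonlinear least squares solved as a 1-D problem: A is linear for fixed T1
and eliminated in closed form, and T1 is located by a 96-point
geometric grid over [20, 8000] ms followed by a bracketed golden-section
refinement (70 iterations, parameter resolution far below 1e−6 relative).
Solutions pinned at the search bounds or with non-physical amplitude are
invalid. An apparent-T1 three-parameter variant |A − B e^(−TI/T1\*)| with
the Look-Locker-style correction T1 = T1\*(B/A − 1) is available behind a
flag; the two-parameter ideal-IR form is the default because the phantom
simulates an ideal inversion.

**T2 (T2-prep).** Log-linear fit of ln S against preparation time over
strictly positive samples; T2 = −1/slope. Invalid when fewer than two
positive samples remain or the slope is non-negative.

All three fits are validated by noiseless round-trips (≤ 1e−6 relative
error at every myocardial pixel; the log-linear fits agree with a
brute-force normal-equations oracle to ≤ 1e−10) and by Monte-Carlo runs at
σ/S0 = 0.02 against independent scipy nonlinear-least-squares oracles.

## Territory statistics

**ΔR2\*.** Per territory, the difference of mean R2\* after vs before
contrast injection, computed over the intersection of the pre and post
validity masks; multiple short-axis slices are pooled per territory before
averaging. Maps are assumed co-registered, which holds exactly for the
phantom; misregistration handling is out of scope. The reported delta is
by construction exactly post_mean − pre_mean, and swapping pre and post
negates every delta.

**Ex vivo count ratio.** The histogram of valid R2\* over the whole
myocardium (lesion pixels included) is binned by the Freedman–Diaconis
rule (configurable fixed bin count), and a Gaussian amp·exp(−(x−μ)²/2σ²)
is fitted to the *bin counts* by nonlinear least squares — not by sample
moments, which only initialize the fit. Because a lesion adds a second
mode that can spoil a moment-based start, the fit initializes at the
dominant mode (peak bin, MAD-based σ) and falls back to the moments. The
threshold is exactly μ + 2σ, applied strictly (>). Counts are normalized
by the region's valid-pixel area (a physical-volume scale factor would
cancel in the ratio) and the lesion/reference ratio of normalized counts
is returned together with the full fit provenance (μ, σ, threshold,
counts, areas, histogram). Degenerate input with zero spread (noiseless,
zero-variation phantom) has no histogram to fit; the statistic then
short-circuits to μ = the constant value, σ = 0, zero counts above
threshold. A genuinely singular fit raises an error carrying the
histogram for inspection.

**Group comparisons** delegate to scipy.stats: Mann–Whitney U
(asymptotic normal approximation with tie correction and no continuity
correction, so identical samples give p = 1 exactly), Welch's t-test, or
one-way ANOVA followed by pairwise Welch tests with Bonferroni
multiplication capped at 1.

## Microscopy

**Coverage.** The stain threshold is calibrated on remote (uninjured)
sections: the 0.95 quantile — linear interpolation between order
statistics, the convention is fixed and documented because "approximately
95%" leaves it open — of all pooled nonzero red-channel intensities, one
global threshold per experiment. Tissue area is the Otsu-thresholded
green (autofluorescence) channel by default, or a fixed cut. Coverage is
the count of pixels strictly above the threshold *and* inside the tissue
mask, divided by the tissue pixel count.

**Spot counting.** Dark particles on a bright background: invert,
subtract a median-filtered background (window ≈ 4 r), threshold the
residual at max(Otsu, 6× the MAD-based residual noise — the noise floor
prevents a pure-background field from being segmented into false spots
and keeps the detector invariant to global intensity scaling), label
connected components and keep areas within [0.3, 3]·πr². Touching
particles count as one component by default; a distance-transform
watershed split is available behind a flag.

**Incubation binding.** A particle is bound when its center lies on a
cell or within one adjacency radius of it (default: one spot radius —
"exactly next to or on top of" is not metrically defined, so this
operationalization is explicit). Cell geometry may be a mask (exact
Euclidean distance transform) or a center list with radius.

## Flow chamber

The dwell of a track is the longest interval during which every position
stays within `stationary_radius` (default 2 µm ≈ two particle diameters;
adhesion is defined in the assay only by duration, so the displacement
radius is this package's operationalization) of the interval's *first*
position — the anchored definition is simpler than a pairwise-diameter
criterion and makes the bound set monotone in `min_dwell`. A track is
bound when its dwell is ≥ 10 s; observations beyond the 60 s window
(measured from the table's earliest timestamp, making labels invariant to
constant time shifts) are ignored, and tracks still stationary at the
window end count their observed dwell. The implementation is verified
against a brute-force all-intervals oracle and the generator's
ground-truth labels.

## Pipeline, determinism and problem sizes

Every stochastic step draws an explicit child seed from the config seed
via `numpy.random.SeedSequence`, so fixed config + seed reproduces every
numeric output byte-identically; reports are JSON with sorted keys and
CSV, series and maps are uncompressed NIfTI-1 with JSON sidecars, and a
manifest lists every artifact with its SHA-256.

Default problem sizes are chosen as desk-scale study conditions: in vivo
runs use three 64 × 64 short-axis slices (≈ 560 myocardial pixels per
territory per slice) at the four-echo in vivo TE schedule; ex vivo runs
use a 96 × 96 × 32 volume at 0.58 mm and the three-echo ex vivo schedule.
Monte-Carlo summaries use 20 repeated experiments for ΔR2\* recovery and
50 for the count-ratio null/lesion characterization.

## Known limitations

* The phantom's territories are equal angular sectors; real coronary
  territories are irregular and lesions are rarely transmural.
* The magnitude-IR T1 fit assumes an ideal inversion; scanner bSSFP
  readouts need the apparent-T1 correction (provided behind a flag) and
  generally a vendor-specific model.
* The count-ratio's single-Gaussian model is misspecified when the lesion
  mode is large; the statistic remains well-defined (the fit locks onto
  the dominant healthy mode) but μ and σ then describe only that mode.
* No image registration: pre/post ΔR2\* is only meaningful for
  co-registered maps.
* Spot counting assumes approximately circular, non-clumped particles;
  heavy clumping requires the watershed option and degrades accuracy.
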