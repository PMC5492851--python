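# Methods

This note documents the models, the synthetic-data forward model, the
numerical choices and the known limitations of `cstquant`. It states no
empirical result beyond what the test suite and `scripts/acceptance.py`
compute.

## Sensitized-emission FRET quantification

Three registered channels of one field are analyzed: donor (I_D), acceptor
(I_A) and FRET (I_FRET), all in detector counts after background
subtraction. Cross-talk is corrected with the two-leak model

    F_index = I_FRET − A·I_D − B·I_A,

where A and B are the fractions of donor and directly-excited acceptor
fluorescence leaking into the FRET channel. The intensity-independent
pixel measure is

    NFRET = 100 · F_index / √(I_D · I_A),

reported on the conventional ×100 scale. Negative pixels — possible after
the subtractions — are clamped to 0; pixels where either I_D or I_A is at
or below a signal floor (default 6 counts = 3× read noise) are marked
*invalid* (NaN) rather than zeroed, so "no signal" and "clamped zero" stay
distinguishable. Clamping can only raise values; the unclamped map is kept
alongside for bias-sensitive analyses (the zero-FRET control test uses it).

**Bleed-through calibration.** A and B are the OLS slopes of FRET-channel
vs reference-channel intensity over pooled pixels of single-fluorophore
images. Choices:

* free intercept — tolerates residual background; only the slope is
  interpreted;
* pixels at or below the signal floor are excluded to stabilize the fit;
* fewer than 100 usable pixels raises an under-determined-fit error;
* any image with a saturated pixel (count at the bit-depth ceiling,
  tolerance 0 by default) is discarded whole.

Because the reference channel itself carries shot noise, the slope is an
errors-in-variables estimate and is attenuated by roughly
σ²_noise/σ²_signal — a few per mill to a few percent at the default noise
scale; this is inherent to regressing one noisy channel on another and is
left uncorrected, matching common practice.

**Background subtraction** offers three scalar strategies: a user ROI, a
low percentile, and the default *dark-region* estimate — the median of the
darkest class of a three-class Otsu split. The median ignores the faint
tail of signal pixels that falls into the dark class, making the estimate
exact on noiseless scenes and unbiased to well under a count with shot
noise; a low percentile of a noisy image, by contrast, sits systematically
~2σ below the true background. Results are floored at 0.

**Filament segmentation** (for on-filament statistics) applies Otsu
hierarchically — first background vs cell, then cytosol vs filaments
within the cell — because the scenes have three intensity classes and a
single threshold segments the whole cell. The binary image is skeletonized
and dilated by 1 px, giving a ~3 px ribbon centered on each filament. With
the default noise this mask overlaps the generator truth with Jaccard
≈ 0.85 and ~94% precision; the few cytosolic pixels it admits pull the
on-filament mean a few percent below truth, which is the dominant residual
bias of the image pipeline.

**Statistics.** Condition summaries average per cell first and then across
cells when cell labels are given (matching per-cell box plots); per-pixel
mode is available. Pearson colocalization is the standard correlation over
masked pixels. Rendering maps NFRET linearly from the display range
(default 0–60) onto a 256-entry "fire" LUT interpolated from the classic
32 control points; 30 on a 0–60 range maps to index 128 under
round-half-even, invalid pixels render black.

## FRAP normalization and kinetics

Raw traces contain n_pre pre-bleach frames and n_post post-bleach frames
of mean ROI and whole-cell intensity. Normalization:

1. subtract the background from both series;
2. divide the ROI series by its pre-bleach mean (the mean of all pre-bleach
   frames, lower-variance than the first frame alone);
3. multiply each post-bleach point by (pre-bleach whole-cell mean)/(whole-
   cell at that frame) — a time-resolved correction that cancels smooth
   acquisition photobleaching exactly;
4. subtract the first post-bleach value v0 and divide by (1 − v0), so the
   bleach floor is 0 and full recovery is 1. The subtract-then-rescale
   convention makes Mob = A1* + A2* a true fraction and makes the
   generator/analyzer pair exactly inverse-consistent.

The model y(t) = y0 + A1*(1−e^(−t/τ1)) + A2*(1−e^(−t/τ2)) is fitted by
bounded trust-region least squares (amplitudes ≥ 0, τ > 0, |y0| ≤ 1) with
tolerances 1e-12, initialized from the data (τ1 = time to reach 25% of the
plateau, τ2 = 8·τ1, amplitudes split 30/70) plus three seeded perturbed
restarts; persistent failure sets `converged=False` instead of raising.
Components are relabeled post-fit so τ1 ≤ τ2; a fit with τ2/τ1 < 1.5 or a
vanishing amplitude is flagged `ill_conditioned` (the two components are
not separable — e.g. single-exponential truth). Derived quantities:
Mob = A1* + A2*, A1 = A1*/Mob, A2 = 1 − A1 (undefined, NaN, when both
amplitudes are zero). Condition summaries report mean ± SEM across
converged fits and count failures.

## Synthetic-data generator

The generator is defined as the exact algebraic inverse of the
quantification formulas, so recovery is well-posed and, without noise,
exact: the tests assert ≤1e-6 relative round-trip error on every
parameter.

**Filament scenes.** An irregular elliptical cell body (low-order radial
ripple) contains persistent-random-walk filament polylines (12 per 512²
field, scaled by area; step 2 px, heading SD 0.12 rad) starting near the
cell center — a schematic radial microtubule network. Polylines are drawn,
dilated by 1 px into the truth mask, and blurred with a σ = 1 px Gaussian
into a density field normalized to peak 1. Clean signals are
D = noise_scale · (density + 0.15·cell) counts and Acc = 0.95·D; the truth
NFRET map equals the preset's on-filament level on the mask, the cytosolic
level elsewhere in the cell, 0 outside; the sensitized term is constructed
pixelwise as S = (NFRET_truth/100)·√(D·Acc). Channels:

    I_D    = bg + D + ε
    I_A    = bg + Acc + ε
    I_FRET = bg + A·D + B·Acc + S + ε

with bg = 20 counts, Poisson shot noise on the mean (clean-signal peak
1000 counts by default; noise_scale = 0 disables noise entirely) plus
Gaussian read noise σ = 2 counts. A preset whose clean signal would exceed
the 16-bit ceiling raises a configuration error. Calibration scenes reuse
the same geometry with one fluorophore silenced, which spans a wide
intensity range and keeps the regression well-conditioned.

**FRAP traces.** Ground truth g(t) = A1*(1−e^(−t/τ1)) + A2*(1−e^(−t/τ2)).
The raw ROI trace is bg + L(t)·F_pre during pre-bleach and
bg + L(t)·F_pre·(f0 + (1−f0)·g(t)) after, with bleach residual f0 = 0.2;
the whole-cell trace is bg + L(t)·W_pre. L(t) decays exponentially to
1 − loss_total (default 8%, inside the 5–10% band the acquisition aims
for) over the series. Both series are *pixel averages* — a circular ROI of
radius 8 px (2 µm at 0.25 µm/px, ≈201 pixels) and a whole-cell mask of
2·10⁴ pixels — so Poisson noise pools over the averaged pixels and read
noise averages down by √n. This keeps the CSV traces statistically
identical to traces extracted from a simulated image stack, which is the
defining consistency requirement of the forward model. Frames: 10
pre-bleach + 120 post-bleach at 1.0 s (the interval is a package default;
it covers > 3·τ2 for the slowest preset). Each trace is deterministic per
(seed, trace index).

**Nocodazole time course.** The on-filament NFRET excess over cytosol
halves every `half_time_s` (default 600 s, so ten minutes of treatment
halves the signal) while polylines are dropped on the same half-time,
thinning the mask. The t = 0 frame is bit-identical to the plain scene for
the same seed.

**Presets.** Seven registry presets encode the measured condition
parameters: typical bleed-through A = 0.1 / B = 0.25; untreated sensor
NFRET 14.5 on filaments with mobile fraction 0.76 split 27.8% fast
(τ1 = 4.9 s) / 72.2% slow (τ2 = 35.2 s); nocodazole 0.91/53%, paclitaxel
0.93/55%; P301L NFRET 8 and 0.85/47%; ΔK280 copies P301L (their recovery
curves are near-identical); AT8 0.54 mobile with the untreated fast share
(not separately measured) and NFRET 10 (reduced, exact level not
published — a package choice). Amplitudes are derived so that both the
mobile fraction and the fast share are exact: A1* = share·Mob,
A2* = Mob − A1*. Time constants are shared across presets, as condition
effects were reported on fractions, not on time constants. The cytosolic
NFRET level is 2 for all presets (low residual proximity signal of the
soluble sensor).

## What the generator does and does not emulate

It reproduces the *algebraic structure* the pipeline inverts — cross-talk,
normalization, shot/read noise, acquisition loss, bleach residual — with
realistic intensity scales. It does not model optics (no PSF, no 3D), cell
heterogeneity (every trace of a condition shares one true parameter set,
so cross-trace SEMs are fit noise, not biological spread), sensor
photophysics beyond the stated terms, or cell movement. Passing recovery
tests therefore demonstrates correctness and statistical calibration of
the estimators on this model class, not robustness to real-microscope
artifacts.

## Problem sizes

Validation runs are desk-scale by design: calibration uses 20 seeds × 5
scenes per mode, FRAP conditions 30 traces each, image conditions 20
scenes each — matching the "at least 30 experiments per sample" scale of
the emulated study while completing in well under a minute per stage on
one CPU.

## Known limitations

* Bleed-through slopes carry the small errors-in-variables attenuation
  discussed above (≈1–3% low at default noise).
* On-filament NFRET means sit a few percent below truth because the
  estimated mask admits a small fraction of cytosolic pixels; using the
  truth mask (available for synthetic scenes) removes the bias.
* The biexponential fit is reliable when τ2/τ1 is well above the 1.5
  identifiability guard and the series spans several τ2; short or very
  noisy traces give skewed per-trace τ estimates.
* The four-step normalization assumes the whole-cell series tracks only
  acquisition loss; bleaching a substantial fraction of total cell
  fluorescence would violate this and is not modeled.
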