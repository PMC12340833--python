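# Methods

This note documents the models, parameter choices and numerical decisions
behind `adhesiondyn`, and what the synthetic-data validation does and does
not establish about real microscopy data.

## Generative model of an adhesion timelapse

Each simulated puncta follows a piecewise kinetic curve: a logistic rise

> I(t) = A / (1 + exp(−r_a (t − t_mid)))

multiplied, past a peak time t_peak, by an exponential fall
exp(−r_d (t − t_peak)). The peak is placed at t_mid + 6/r_a so the logistic
is ≈99.8 % saturated before decay begins; this makes the generative curve
consistent with the two fitted forms, so the half-max lifetime of the
generative curve and the lifetime derived from the fits agree to well
within one frame on noiseless data. (With an earlier peak, e.g.
t_mid + 3/r_a, the rise is still 5 % short of its plateau when decay
starts and the two lifetime definitions disagree by more than a second for
slow disassembly.)

Punctae are rendered as isotropic 2-D Gaussians (σ = 2.5 px by default,
a diffraction-limited-spot proxy at 0.1 µm pixels) at stationary positions
— adhesions are substrate-anchored — on top of a smooth-edged disk that
stands in for the cell body and translates at `cell_speed_um_s` with small
heading jitter, reflecting at the field margins. Channel 2 duplicates the
puncta signal on exactly `round(coloc_fraction · n_punctae)` punctae.

Default acquisition parameters are the study conditions the package
targets: 240 frames at 0.75 s (3 min) for tracking; FRAP traces with 3
prebleach frames, 0.5 s frames and 45 s of postbleach imaging.

**Noise.** Poisson shot noise on the clean image plus additive Gaussian
read noise of sd `noise_sd`, clipped at zero (camera counts are
nonnegative). `noise_sd = 0` disables *all* stochastic noise so a rendered
frame is an exact model evaluation; the oracle tests rely on this.
The default `noise_sd = 10` against peak amplitudes of 80–150 over a
background of ~35 gives an effective SNR of roughly 5–10.

**Positions** are sampled uniformly in the central 70 % of the field with
a minimum pairwise spacing of 4σ; configurations whose expected
nearest-neighbour spacing (0.5·√(A/n) for n uniform points in area A)
falls below 4σ are rejected as ill-posed for tracking.

**FRAP traces.** Postbleach RFI follows Y₀ + (P − Y₀)(1 − e^(−kt)) with
floor Y₀ = 1 − bleach_depth. The plateau P is chosen so that the
immobile-fraction formula evaluated on the noiseless curve at the final
time point of the trace returns `immobile_fraction_true` exactly — this is
what makes closure testable to 1e-4. The first prebleach frame is kept
noise-free so that it defines the normalization scale; RFI of that frame
is 1 by construction on any trace.

### What the generator does not emulate

Photobleaching during acquisition, blinking, depth (3-D) structure,
non-Gaussian spot shapes, adhesion sliding, camera-specific noise
calibration, and intensity heterogeneity within one adhesion. Passing
recovery tests therefore demonstrate that the *algorithms* are correct and
well-calibrated under realistic SNR, not that any particular biological
dataset will be measured without bias.

## Detection

The chain is: optional Gaussian prefilter (σ = 1 px) → regional-maxima
enhancement → per-frame Otsu threshold on the enhanced image → binary
opening (radius 1) → area filter (≥ 4 px). MFI and the intensity-weighted
centroid are always measured on the raw frame: downstream kinetics and
FRAP formulas operate on fluorescence, not on a transform.

Enhancement is built on the h-dome transform,
`frame − reconstruction_by_dilation(frame − h, frame)`. Three practical
hardenings were needed:

- **Marker validation.** The global maximum survives h-suppression
  regardless of its prominence; in a frame containing no true peak the
  flooded residue then lifts most of the frame. A candidate h-maximum must
  therefore also clear `median(frame) + h`.
- **Support floor.** The dome residue of pixel noise is positive almost
  everywhere and percolates; the support is cut at h/4 before connected
  components are taken.
- **Output.** Within surviving regions the output is the original
  intensity (not the capped dome residue), which preserves photometry for
  thresholding, makes the operation the identity inside kept regions, and
  makes it exactly idempotent.

The prefilter suppresses single-pixel noise prominences; it attenuates a
σ = 2.5 px Gaussian peak by the factor σ²/(σ²+1) ≈ 0.86, which the default
depth h = 45 accounts for. These defaults were validated by recovery
against ground truth (recall ≈ 0.95, precision ≈ 0.96–1.0, track purity
≈ 1.0 on the default stack) rather than chosen to match any published
per-cell counts. In recovery scoring, a ground-truth object counts as
"detectable" in a frame when its true amplitude is ≥ 60 — spots below the
enhancement depth are invisible to this detector by construction — while
precision counts a detection as correct if it matches *any* true object.

Whole-cell segmentation is coarse Gaussian smoothing (σ = 3 px), Otsu, and
the largest connected component above 200 px; smaller results flag the
frame as invalid.

## Tracking and migration speed

Linking is per-frame-pair minimum-cost bipartite assignment (Hungarian
algorithm) on centroid distance with a hard gate of 5 px and no gap
closing: a lost detection ends the track, which is what the first/last
frame QC filter presumes. Track filters remove tracks present in the first
or last movie frame and tracks of ≤ 8 frames (parameter `min_frames = 9`).
Manual curation of false positives is replaced by deterministic QC flags
so the pipeline is reproducible; flagged tracks are reported, never
silently dropped.

Migration speed is the mean over consecutive valid frame pairs of
Euclidean displacement divided by the frame interval. Binary centroids
carry ~0.25 px/axis of frame-to-frame segmentation noise, which biases a
mean-of-steps estimator upward; `measure_cell_trajectory` therefore
applies a centred 5-frame rolling mean to the centroid series (a rolling
mean commutes with linear drift, so steady motion is unaffected). With it,
a 0.05 µm/s simulated cell is recovered within ~10 % at default noise.

## Kinetics

Per track: subtract the first frame's MFI, then a centred three-frame
running average (dropping both endpoints); the fits run on the smoothed
series, split at its maximum (ties to the earliest).

- Assembly: 3-parameter logistic, initialized with A = window max, rate
  from the maximum finite-difference slope (max logistic slope = A·r/4),
  midpoint at the half-max sample. Bounded rates r ∈ [10⁻³, 10] s⁻¹.
- Disassembly: exponential decay with amplitude pinned to the observed
  smoothed peak P and *two* fitted parameters, the rate and the
  peak-crossing time t_d. The sampled argmax systematically precedes the
  true peak by up to one frame (the rise is nearly flat near the peak, the
  fall is not), so pinning t_d at the argmax biases the half-max time
  t_d + ln2/r_d by ~1 s; fitting t_d removes the bias (measured: max
  noiseless lifetime error 1.3 s → 0.12 s). The argmax sample itself is
  excluded from the window because the running average mixes rise and
  fall there.
- Lifetime = (t_d + ln2/r_d) − t_a, from the fitted curves, not raw data.
- A fit is rejected (`fit_ok = False`) when its window is shorter than 4
  samples, flat, fitted with SSE > 20 % of the window variance, when the
  rate lands on a bound, or when the lifetime comes out non-positive.
  Rejected tracks are excluded from population summaries and counted in
  the QC report.

Rates are in 1/s and lifetimes in s irrespective of the sampling interval
(tested at 0.5 and 0.75 s). Fits on *detected* tracks are conditioned on
the detection window: the track starts only when the puncta clears the
detection floor, so the first-frame baseline is substantial and fitted
rates are not expected to match generative rates one-for-one. Recovery
tests therefore feed the kinetics stage tracks that span the full curve;
at image SNR 10 (per-frame MFI noise ≈ amplitude/30 after mask averaging,
the lifetime oracle uses the harsher amplitude/10) the median relative
errors are < 10 % for rates and < 15 % for lifetimes.

## Colocalization

A track is channel-2 positive when, in at least half of its scorable
frames, the channel-2 mean intensity inside the puncta mask is ≥ 1.5× the
median channel-2 intensity in a 3-px annulus around the (slightly dilated)
mask. Double-positive punctae are conventionally identified by eye; there
is no standard quantitative criterion, so the three parameters are
exposed and results should always be reported alongside them. The
ratio-to-local-annulus form makes the call invariant to affine rescaling
of channel-2 intensities and to smooth illumination gradients. Frames
whose annulus leaves the image are skipped; tracks with no scorable frame
are labelled `undefined`.

## FRAP analysis

Normalization and immobile fraction follow the standard definitions
RFI = (I_t − I_bg,t)/(I_pre − I_bg,pre) and
IMf = 1 − (FRFI_f − FRFI₀)/(1 − FRFI₀). Time zero is the first postbleach
frame; prebleach frames are used only for normalization. The analysis
window (15 or 20 s depending on the experiment) bounds both the fit and
the "final time point" at which FRFI_f is evaluated. The acquisition-time
QC cut is strict: t_1/2 = 45 s is kept, 45.001 s is removed. ROUT outlier
removal runs on the halftimes of the surviving traces and removals
propagate to the immobile-fraction summaries. No correction is applied
for acquisition photobleaching of the unbleached reference.

## Statistics

**ROUT** is published for nonlinear regression; applied to a scalar
column the model degenerates to a constant location. Implementation:
iteratively-reweighted location estimate with Lorentzian weights
1/(1+(r/s)²); robust scale RSDR = 68.27th-percentile of |residuals| ×
n/(n−1); two-tailed t-tail probabilities of standardized residuals; and a
Benjamini–Hochberg step-up at rate Q (default 1 %). With n < 5 nothing is
flagged and a warning is raised. Monte-Carlo calibration over clean
Gaussian samples flags ≈ 0.01–0.1 % of points at Q = 1 %, and a 10×-median
injected value is always flagged.

**Rank-sum**: two-sided Mann-Whitney/Wilcoxon; exact when both samples
are ≤ 20 and tie-free (verified against full enumeration of all
assignments for n ≤ 8), otherwise the normal approximation with mid-rank
tie correction and no continuity correction (so identical groups give
p = 1 exactly). **Regression**: ordinary least squares with the t-test on
the slope; type-I rate ≈ 5 % on independent data. **SuperPlot tables**
report per-replicate means and group mean ± SEM at both the measurement
(n) and replicate (N) levels; rank-sum comparisons are run at the
measurement level, with the replicate table reported alongside.

In the group-contrast validation (two populations whose disassembly rates
differ 2-fold, n = 50 each), both groups draw assembly rates from the same
moderately narrow distribution (0.4–0.6 s⁻¹) so the comparison isolates
the manipulated variable, as in the genotype contrasts it emulates; with
the generator's full assembly spread the shared rise-time variance
(6/r_a ∈ 7.5–30 s) dominates the lifetime and dilutes the contrast.

## Problem sizes used in validation

Recovery runs use a 240-frame, 160×160, 2-channel stack with 30 punctae;
50-track populations for the lifetime oracle; 100 FRAP traces; 100
repeats of the 50-vs-50 group contrast; 500 regression and 200 ROUT
calibration repeats; and 20 repeats × 20 cells for the null
speed–duration correlation. These sizes give stable medians and rates on
a single CPU in a few minutes.

## Known limitations

- The detector's intensity-unit parameters (h, fixed thresholds) must be
  rescaled with image gain; only the Otsu threshold adapts automatically.
- No gap closing means blinking punctae fragment into several tracks.
- Single-exponential FRAP recovery only; diffusion-vs-binding models and
  double exponentials are out of scope.
- Colocalization assumes registered channels; no chromatic-shift
  correction is applied.
- Track tables written to CSV carry single-pixel masks, so colocalization
  re-run from CSV is less accurate than in-session classification with
  full masks.
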