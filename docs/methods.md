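# Methods

`dcevasc` analyzes dynamic contrast-enhanced (DCE) MRI of breast tumors
under neoadjuvant therapy. This note describes the models implemented, the
defaults and their rationale, what the synthetic phantoms emulate (and do
not), and the numerical choices that matter.

## Signal model and preprocessing

**Coil-sensitivity (B1) correction.** The breast-coil acquisition carries a
smooth multiplicative sensitivity field b(x); a matched body-coil
T1-weighted volume does not. Multiplying every dynamic frame by the
body/breast image ratio cancels b(x) exactly (verified to ~machine precision
on phantoms). The reverse ratio (breast/body), which some protocol
descriptions state, *squares* the shading instead; it is available behind
`direction="breast_over_body"` for protocol compatibility, but the
bias-removing direction is the default. Voxels with zero denominator are
zeroed and counted in the output metadata.

**Signal → concentration.** The spoiled-gradient-echo steady-state signal
is S = M0 sin α (1−E1)/(1−cos α E1) with E1 = exp(−TR/T1). With the
pre-injection mean S0 as the T1 = T10 anchor, the ratio S/S0 is inverted in
closed form for E1, giving T1(t) and C(t) = (1/T1(t) − 1/T10)/r1. Fixed
pre-contrast T1 values are used: 1200 ms for blood (left ventricle) and
900 ms for breast tissue. TR defaults to 5.46 ms. Flip angle (12°) and
relaxivity (5.0 L·mmol⁻¹·s⁻¹) are not dictated by the protocol constants
above; both are configuration entries echoed into all output metadata.
Signal ratios outside the invertible range (noise, artifacts) are clamped
and counted. A `relative_enhancement` mode returning (S−S0)/S0 is provided
for workflows that skip absolute quantification; the unit mode is recorded
in output metadata because TTP is invariant to it but AUC is not.

**Bolus arrival.** A curve's onset is the first frame exceeding the
baseline mean + k·SD (k = 3) that stays above threshold for ≥2 frames;
curves without such a frame carry a `NO_ONSET` sentinel that downstream
maps propagate. With a noiseless baseline (SD = 0) any strict rise counts.

**Subtraction image.** The late-enhancement image is the frame nearest to
injection + 238 s (ties round to the later frame) minus the mean of the
five pre-injection frames. On the 13 s grid with injection at 65 s this is
frame round(303/13) = 23.

## Tumor segmentation and volumetry

Within a user-supplied bounding VOI (a radiologist's rough volume), each
axial slice is thresholded at the Otsu level of the VOI voxels *of that
slice*, and marching squares extracts the iso-contours; filled contours,
united across slices and intersected with the VOI, form the mask.
"Local" Otsu is interpreted at VOI level (not a pixelwise window): the
VOI-first workflow makes this deterministic and scale-invariant — the mask
is unchanged under affine intensity rescaling. Contours that would exit the
VOI are closed along its boundary (the crop is padded below-threshold).
Interior holes stay filled; necrosis is removed only via an explicit
exclusion mask, which is subtracted last and can never contain tumor
voxels. Volume is voxel count × voxel volume, reported in cm³; at the
default 1.0×1.0×1.5 mm spacing, 1000 voxels are exactly 1.5 cm³.

## Semi-quantitative metrics

TTP is the time of the curve's global maximum (ties → earliest frame),
reported onset-relative by default with the absolute-time convention
exported alongside. AUC90 is the trapezoidal integral from onset to
onset + 90 s with linear interpolation at the window edge; when the series
ends early the integral runs to the end (the voxel is reported rather than
dropped, consistent with pairwise deletion downstream). AUC is linear in
curve amplitude; TTP is amplitude-invariant.

## Extended Tofts model

Tissue concentration follows
Ct(t) = vp·Cp(t) + Ktrans·(exp(−kep t) ∗ Cp)(t), with Cp the arterial input
function, Ktrans [/min] the transfer constant, kep = Ktrans/ve [/min] the
efflux rate, and vp, ve the plasma and interstitial volume fractions. The
plasma term is included because vp maps are a primary output; a standard
Tofts fit is the degenerate case vp = 0 (and on vp > 0 data it never fits
better — a tested invariant).

**Convolution.** exp(−kep t) ∗ Cp is evaluated by an exact recursion for
piecewise-linear Cp (the IIR form y_n = E y_{n−1} + increment with
E = exp(−kep Δt)), stable for any kep, exact at kep = 0 (cumulative
trapezoid), and agreeing with a dt = 0.05 s brute-force convolution to
≪0.5% at every frame.

**Fitting.** Per voxel, bounded nonlinear least squares over
(Ktrans, kep, vp) with Ktrans ∈ [0,5]/min, kep ∈ [0,10]/min, vp ∈ [0,1],
from three fixed starts ((0.1,0.5,0.05), (0.5,2.0,0.02), (0.02,0.1,0.1));
the best residual wins. ve is *derived* as Ktrans/kep so ve·kep = Ktrans is
exact by construction in every output voxel; the alternative
(Ktrans, ve, vp) parameterization is available behind a flag. Derived
fractions above 1 are clamped (ve = 1 with Ktrans = kep, preserving the
identity) and counted. All-zero curves get zero parameters and
converged = False. Commercial tools ship undocumented bounds/starts/losses;
the defaults here are declared rather than reverse-engineered.

**Population AIF.** Left-ventricle blood curves (converted with
T10 = 1200 ms) from the baseline visits are aligned on bolus arrival by
cross-correlating first differences against a reference curve (integer-
frame lags, ±5), interpolated to the reference grid and averaged.
Curves without a detectable bolus are excluded and counted. Hematocrit
correction cp = cb/(1−Hct) is off by default and configurable.

## Blanket-method fractal dimension

The subtraction image is treated as a surface. Upper/lower blankets grow by
u_e = max(u_{e−1}+1, 4-neighbor max), b_e = min(b_{e−1}−1, 4-neighbor min)
(classic 4-connected form; replicate padding at borders). The area at scale
e is A(e) = Σ_window (u_e − b_e)/(2e) over a 3×3 sliding window, and
fd = 2 − slope of the least-squares line of log A vs log e over e = 1..44.
The blanket recursion runs on the full slice; the window enters only
through the area sum (a 3×3-only recursion would be pathological). All 44
scales enter the fit by default; a sub-range is configurable. 44 blankets
is the count at which windowed and whole-image estimates agree on a
self-similar reference texture; `calibrate_blankets` reproduces that
calibration for any user-supplied texture (the classic reference texture is
an external image not shipped here).

A flat window gives A(e) constant and fd = 2.0 *exactly*. Intensities are
linearly rescaled to [0,255] before the unit-step recursion so the step is
comparable across subjects — this also makes fd exactly invariant under
affine intensity rescaling. On smooth steep gradients the discrete log-log
slope can stray marginally outside the admissible surface range; estimates
are clamped to [2,3] (a safety net, not the estimator: the tests assert
most pixels land inside unclamped).

Validation uses spectral-synthesis fractional-Brownian surfaces
(P(f) ∝ f^−(2H+2)), whose theoretical dimension is 3−H. The estimator needs
the texture relief to dominate the unit vertical step; validation therefore
normalizes surfaces to lag-1 increment SD = 100 with rescaling off, where
the 44-scale estimate for H = 0.5 lands near 2.38–2.41 — inside the ±0.15
validation band around 2.5, with the residual bias (morphological estimators
systematically compress toward 2 at high dimensions) documented rather than
corrected. The per-tumor summary is the median fd over mask voxels eroded
by one voxel in-plane (4-connectivity per slice); if erosion empties the
mask the summary is NaN with a warning — small tumors do not support a
reliable texture estimate.

## Synthetic phantoms and cohorts

The phantom emulates the acquisition geometry of a clinical breast
protocol: 13 s frame interval, 1.0×1.0×1.5 mm voxels, ≥5 pre-injection
frames, ≥300 s coverage, injection at t = 65 s (the sixth frame time, so
exactly five frames precede any enhancement; the bolus is identically zero
at the injection instant). The AIF is a delayed gamma-variate bolus plus a
difference-of-exponentials washout — smooth, causal and closed-form
integrable (peak 6 mM at 36 s post-injection, shape α = 3, scale 12 s,
tail 1 mM with rates 0.005/0.05 s⁻¹). No clinical AIF functional form is
prescribed anywhere; these are package defaults chosen to look like
published population AIFs, and every parameter is configurable.

Tumors are ellipsoids with smoothly varying parameter fields:
median Ktrans = 0.13/min, kep = 0.55/min, vp = 0.094 (clinical baseline
medians), ve derived, each modulated by ±30% low-frequency fields, with
ve + vp ≤ 1 enforced. A left-ventricle sphere carries Cp directly
(hematocrit off). Concentration is pushed through the same SPGR model the
preprocessing inverts (fixed T10 900/1200 ms, M0 = 1000), multiplied by a
smooth cosine-mode bias field (strength 0.3 by default), and degraded by
additive Gaussian noise (Rician optional). The default noise is zero —
phantoms are ground-truth devices; validation experiments set the SD via
`sigma_for_snr` (SNR 20 for the noisy recovery study, i.e. σ =
baseline-signal/20). All generators are pure functions of their seed.

Cohorts expand a baseline phantom into two arms × four visits
(baseline/1w/12w/25w). Arm effects are multiplicative changes on Ktrans,
kep, vp and tumor volume, defaulting to the observed clinical median
changes per arm and visit (e.g. bevacizumab-arm 1-week multipliers 0.70 /
0.556 / 0.463 on Ktrans/kep/vp); ve takes no multiplier of its own because
it is derived as Ktrans/kep throughout (reported clinical ve medians are
not jointly consistent with the Ktrans and kep medians — a consequence of
medians not being functionally related across parameters). Subject
heterogeneity is a mean-1 lognormal factor (CV 0.2 by default) drawn per
subject, visit and parameter; drawing it per-visit rather than once per
subject is deliberate — a time-constant factor would cancel in relative
changes and make null-calibration and power analyses degenerate. Volume
multipliers scale the ellipsoid axes by the cube root.

**What the phantoms do not emulate:** bulk motion, k-space sampling and
reconstruction artifacts, AIF delay/dispersion between ventricle and
breast, partial-volume mixing at tumor borders, necrotic cores (handled
only via explicit exclusion masks), and spatially correlated noise.
Passing tests therefore demonstrate the correctness of the computational
chain under the stated models, not robustness to these clinical effects.
The generation and the fit also share the piecewise-linear convolution on
the 13 s grid, so noiseless recovery is exact by construction; the noisy
(SNR 20) recovery study is the informative one for estimator spread.

## Statistics

The endpoint is the percentage change of each per-tumor median metric
relative to the subject's pre-treatment value; missing rows are handled by
pairwise deletion (a zero baseline flags the record undefined). Arms are
compared with a two-sided Mann–Whitney U test: exact null distribution for
combined n ≤ 20 without ties, normal approximation with tie correction
otherwise (the two paths agree to <0.02 at n = 10 vs 10). Significance is
p < 0.05 with **no multiple-testing correction** — many metric × timepoint
cells are tested at 0.05 each, so isolated flags must be read accordingly.
Voxel-level distributions are shown as Gaussian-kernel densities (Silverman
bandwidth, normalized to integrate to 1) with matching normalized
histograms; voxels pool with equal weight by default (per-patient weighting
is a caller-side option). Median confidence intervals in the report are
percentile bootstrap (2000 resamples, seed-controlled). Calibration under
the null design (no arm effect, n = 15/arm, CV 0.2) gives a type-I rate of
~5% over 1000 simulated cohorts, and a 0.5× Ktrans multiplier is detected
in ≳95% of cohorts at the same size.

## Problem sizes and numerical notes

Validation studies use grids from 12×12×4 (pipeline demo, 4 subjects/arm,
two visits) to 24×24×10 (≈900 tumor voxels for the SNR-20 recovery study);
these sizes make every study rerunnable in minutes on one CPU while keeping
≥500 voxels where the contracts require it. The voxel-wise fit costs ~10 ms
per voxel (three starts × trust-region solver on ~29 frames). Uniform time
grids use an IIR filter for the convolution recursion; non-uniform grids
fall back to an explicit loop. Degenerate inputs are contracts, not
accidents: all-zero curves, onset-free voxels, empty-after-erosion masks
and uniform-intensity VOI slices each have a defined, tested behavior
(sentinels, warnings or explicit errors).
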