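# Methods

## Signal model

Longitudinal magnetization only is modelled. Each slice excitation is an
ideal rectangular-profile 90° saturation pulse with perfect spoiling: it
nulls Mz inside the slab, which then relaxes as
`m0 + (Mz − m0)·exp(−Δt/T1)` until the next event. Transverse relaxation
is ignored throughout: CSF T2* far exceeds the 30 ms echo time, and the
pulsation metric is a ratio of same-tissue signals, so TE factors cancel.

Static CSF re-excited every TR settles at `S_static = m0(1 − e^(−TR/T1))`.
CSF that moves through the slice stack at the interleave's sweep pace (one
slice thickness per interTR) is re-excited every interTR instead, settling
at `m0(1 − e^(−interTR/T1))`. The ratio of the two is the saturation
ratio

    α = (1 − e^(−interTR/T1)) / (1 − e^(−TR/T1)),

0.194 for T1 4300 ms / TR 2000 ms / interTR 322 ms. The spin-column
simulator (`bloch.simulate_schedule`) reproduces this number physically:
a 1-D column of spin packets (0.1 mm spacing, two-slice inflow margin,
fresh fully-relaxed packets entering upstream) is advanced event by event
through the interleaved schedule, and at the tracking velocity the
upper target slice's steady signal over the static one equals α up to the
integer-millisecond truncation of the reported interTR. The simulator is
event-driven but exact: relaxation is applied as the closed-form
exponential between events and packets advect ballistically, so it matches
a fine-time-step integrator to machine precision (tested at 1e−6).

## Excitation schedule

The interleaved ascending order advances by `1 + ⌊√n_slices⌋` anatomical
slices per acquisition slot and wraps to the next start slice; slots are
uniform at `TR / n_slices` with no inter-packet dead time (the vendor does
not publish dead-time behaviour; uniform slots reproduce both printed
interTR values). Derived quantities follow the conventions that reproduce
the protocol's printed numbers: interTR is truncated (not rounded) to
integer milliseconds — 5 slots × 2000/31 ms = 322.58 → 322 — and the
capture bound `v_max = 2·thickness/interTR` is truncated to two decimals
(2.484 → 2.48 cm/s). The two-slice span defines the bound because a spin
displaced by more than two thicknesses during one interTR has left the
paired-slab system entirely.

## Capture response and the forward model

A through-plane velocity v displaces the lower slab's content by
`d = v·interTR`. The fraction of the upper slab occupied by displaced
lower-slab spins is the slab-overlap (triangular) response:

    f(v) = sign(v) · tri(|d| / thickness),   tri(x) = x        (x ≤ 1)
                                                      2 − x    (1 < x ≤ 2)
                                                      0        (x > 2)

so the response rises linearly to full exchange at one thickness per
interTR, folds back, and vanishes exactly at the printed capture bound
`v_max = 2·thickness/interTR`. (A hard clip at f = 1 would keep reporting
full exchange at arbitrarily high velocities, contradicting the capture
range; the overlap model makes the bound the support of the response.)

The paired-slice ratio implied by a pulsed fraction is the exact inverse
of the estimator:

    S_i / S_{i−1} = 1 + f · α/(1 − α),

with the lower slice at the static steady state. The derivation of the
original estimator is not published in a form we can reproduce (it lives
in a prior study's supplement); this package therefore *defines* its
forward model as the estimator's inverse, with the sign convention that
ascending in-range flow yields a positive CSFpulse and descending flow a
negative (clamped) one. Phantom generator and estimator share this model
by construction, which is what makes noise-free recovery exact; passing
recovery therefore validates the pipeline's bookkeeping (ROI, volumes,
discard rule, clamping, calibration), not the physiological truth of the
estimator. Of note, a full spin-column simulation of *continuous* constant
flow in an unbounded, fully-excited column produces nearly cancelling
effects on the two slices (each is darkened by inflow from its own
upstream neighbour) — the measurement targets bolus-like pulsation, not
steady flow, which is why the response curve is computed through the
capture-response model rather than the constant-velocity column.

## The metric

For each retained measurement,
`raw(n) = (1/α − 1)(S_i/S_{i−1} − 1)·ROIvolume`; negatives are clamped to
zero. `S_i` is the ROI-mean intensity of slice i's mask (mean, not sum, so
unequal mask sizes between the slices do not bias the ratio). ROIvolume
defaults to the upper target slice's total ROI volume
(`n_voxels × voxel volume`); the literal per-voxel reading is available as
`roi_volume_mode: per_voxel`. The first 5 of 160 measurements are
discarded before every computation (signals, ROI temporal means,
summaries), leaving 155 values. Summaries: `mean_pulse` is the mean of the
clamped series; z-scores are computed within subject on the clamped series
(the analysed quantity) with the sample (n−1) SD, and `abs_z_mean` is the
mean |z| (undefined for a constant series — reported missing with a
warning); `positive_ratio` counts raw > 0, ties at zero counting as
non-positive.

## ROI segmentation

The operator supplies the target slice pair and an in-plane bounding box;
inside the box the CSF mask is thresholded automatically on the
temporal-mean image (computed over the retained measurements). The default
policy is Otsu's between-class criterion, with the threshold placed at the
middle of the criterion's plateau so it sits mid-gap between the CSF and
background modes; fixed-value and percentile policies are configurable. A
percentile policy is only reliable when the CSF fraction of the box
happens to match the percentile, which is why it is not the default. Each
slice of the pair gets its own mask from the shared box.

## Synthetic data

The phantom is an 80×80×31-voxel, 160-measurement series (2.75 mm
in-plane, 4 mm slices) of uniform tissue background (default 0.12·m0,
giving ~3:1 CSF contrast) containing a bright CSF tube spanning slices
8–11. Each in-tube slice follows the forward model above, with the
velocity waveform evaluated at that slice's excitation instant; the bottom
tube slice has no moving CSF below it and stays at the static steady
state, making it the unmodulated reference the estimator assumes. Noise is
additive Gaussian (per voxel, SD relative to the CSF steady-state signal)
— not Rician, since only high-SNR magnitude ROIs are analysed. Images are
stored float64 so that quantisation does not contaminate exactness checks;
output is deterministic per seed. The waveform family (constant, sinusoid,
sinusoid + jitter) is a stand-in for unknown real velocity distributions;
the default 1.05 Hz cardiac-like sinusoid is aliased by the 2 s TR to an
apparent 0.05 Hz oscillation, as in real sampling. (Exactly 1.0 Hz would
alias to DC, making each subject's sampled velocity a phase-dependent
constant, and is avoided.)

The cohort generator reproduces the study structure: HC n=17 (10M/7F),
PDD-L n=16 (11M/5F), PDD-H n=19 (13M/6F), with age/education/MMSE/
duration/UPDRS drawn from the published group moments (MMSE, duration and
UPDRS absent for controls; UPDRS present for 11/15 of PDD-L/PDD-H).
Gender is assigned by exact count so the generated tables reproduce the
printed Fisher tests. Group pulsation targets are means ± SE (per-subject
SD = SE·√n); ROI voxel counts are means ± SD. Each subject's target mean
pulse is mapped to a waveform amplitude by inverting the *expected
clamped* estimator output under the generator's noise model
(`E[max(X,0)] = μΦ(μ/σ) + σφ(μ/σ)` per measurement, root-found on the
rising branch of the capture response), so targets are hit in expectation
despite the clamp's noise rectification. Targets outside the feasible band
(below the clamp's noise floor, above the capture maximum) are truncated
into it; infeasible group specifications raise. The cohort default voxel
noise is 1% of the CSF steady signal — at 5% the noise floor of the
clamped estimator would exceed the lowest published group mean. The
signal-level mode generates the pair's ROI-mean series directly (voxel
noise attenuated by √n_voxels) and is what the fast statistical
calibration checks use; phantom images and signal mode agree exactly in
the noise-free limit (tested).

What passing tests show — and what they do not: the phantoms contain no
motion, no slice-profile edge effects, no physiological noise, no
partial-volume boundary voxels and no anatomy, so green tests validate the
estimator pipeline and its statistics under the package's own forward
model, not performance on real patient data.

## Statistics

Pairwise tests default to the pooled-variance two-sample t-test (Welch
configurable); zero pooled variance uses the convention p = 1 for equal
means, p = 0 otherwise. Fisher's exact test (two-sided, hypergeometric)
handles gender tables; a zero margin degenerates to p = 1 with a warning.
Age adjustment regresses the measure on age across the pooled cohort and
returns residual + grand mean (pooled mean preserved exactly). The
bootstrap resamples within group (B ≥ 1000 enforced, default 10,000, seed
mandatory) and reports the 95% percentile CI of the mean difference with
p = min(1, 2·min(P(Δ≤0), P(Δ≥0))). The omnibus test is a one-way ANOVA
across the three groups with Bonferroni-multiplied pairwise t-tests (the
study's "two-way ANOVA" names a single grouping factor, so one-way is the
internally consistent reading; the discrepancy is noted here). Pearson
correlations use the t transform.

The built-in temporal high-pass (optional, `--highpass 0.01`) is
Gaussian-weighted running-line detrending (σ = 0.5/cutoff seconds) with
the removed trend's mean re-added, preserving the absolute signal level
the ratio depends on; it removes a linear drift essentially completely
while leaving broadband content nearly untouched. Motion and slice-timing
correction are delegated to upstream tools and are out of scope.

## Parameters and problem sizes

| Parameter | Default | Why |
|---|---|---|
| T1 (CSF, 3 T) | 4300 ms | literature-standard; configurable |
| m0 | 1 | arbitrary units; metric is a ratio |
| spin-packet spacing | 0.1 mm | ≪ slice thickness; exact advection |
| column margin | 2 slices | covers inflow over any tested velocity |
| convergence tol / cycles | 1e−8 / 20 | periodic steady state detector |
| discard | 5 measurements | equilibration, per protocol |
| threshold policy | Otsu | robust to CSF fraction of the box |
| background level | 0.12·m0 | ~3:1 CSF/tissue contrast |
| cohort voxel noise | 1% of S_static | keeps all group means feasible |
| bootstrap B | 10,000 | stable percentiles |

Validation problem sizes are chosen for speed without changing the
protocol's timing structure: brute-force physics comparisons use a
6-slice/1200 ms instance; phantom recovery uses 32×32 in-plane grids (the
31-slice axis and 160 measurements are always kept); statistical
calibration uses 600 signal-level null cohorts.

## Known limitations

- The forward model is the estimator's inverse by design; independent
  physical validation of the estimator (e.g. against phase-contrast
  stroke volume) is outside what synthetic data can provide.
- α's closed form assumes the pulsating compartment is fully re-excited
  every interTR; partial-exchange behaviour between α's two limits is not
  separately modelled.
- Velocity is piecewise-constant per excitation instant; intra-interval
  waveform shape is not modelled.
- Descending or multi-band/SMS slice orders, vendor dead time, B1
  inhomogeneity and slice-profile edge effects are not modelled.
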