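# Methods

This note records the models, conventions, defaults and known limitations of
`petdosim`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Units and activity convention

Internal times are hours and activities are fractions of injected activity
(FIA, dimensionless); minutes and Bq are converted at the ingestion
boundary. Activities are *non*-decay-corrected, i.e. physically present at
the sample's own clock time: residence-time integration requires physical
activity, and every time–activity curve must decay to zero. For well-counter
data the decay between sacrifice and counting is restored (divide by the
decay factor over the counting delay) so a value refers to sacrifice time;
no correction back to injection time is applied. This is the standard
reading of calibrated well-counter data; whether a given laboratory applies
the counting-delay restoration upstream should be checked before ingestion
(set `counting_delay_min` to zero if the counter already reports
sacrifice-time activity).

F-18 is shipped with a half-life of 109.771 min; other nuclides can be
registered, and every stage takes the nuclide as a parameter.

## Interspecies extrapolation

Percent injected activity per organ times total body weight is assumed
conserved across species (linear scaling). The standard animal averages
per-organ density (mass/volume) and organ/body-weight fraction over a
dissection cohort and rescales to a 35-g reference body weight. Only organs
with a known organ/body-weight ratio are extrapolated; all others reach the
dose stage through the remainder. Extrapolated organ FIA above 1 is
physically suspicious but algebraically legitimate, so it warns and is not
clamped. The shipped standard-mouse masses/densities and the 70-kg adult
phantom organ masses are representative literature-plausible values, not
measurements from any specific cohort; both are package data
(`data/standard_mouse.csv`, `data/human_phantom_70kg.csv`) so laboratory- or
phantom-specific tables can be swapped in.

## Time–activity curves and residence times

Curves are piecewise linear between samples. Before the first sample the
first value is held constant (with a 2-min first sample the effect on τ is
below 1 %; a `linear_from_zero` ramp is available). After the last sample
only physical decay is assumed — biological clearance beyond the last
measurement is neglected, a deliberately conservative (dose-overestimating)
assumption. The default horizon is 10 h with truncation; the truncated
tail's disintegrations are not lost but land in the remainder through the
conservation rule below. Integration is trapezoidal on a dense grid (step
≤ 0.01 h, sample times inserted so interpolation kinks are exact); for a
mono-exponential curve the integrator matches the closed form to better
than 0.5 % (asserted in the tests).

Uncertainty: two additional curves are built from mean ± 1 SD at every
sampling time (the lower curve floored at zero), pushed through the same
build–extrapolate–integrate chain, and the resulting residence-time window
is reported as a percent CV of the mean — a best/worst-case envelope rather
than a formal standard error.

Conservation: the remaining body is defined as
`τ_remainder = 1/λ_p − Σ τ_organ − τ_bladder`, so the total number of
disintegrations is conserved exactly (asserted to 1e-9 in every pipeline
report). Negative remainders signal inconsistent inputs and raise.

## Dynamic voiding-bladder model

Bladder contents within a cycle starting at the last void t₀ follow

    A(t) = f · e^(−λp·t) · (e^(−λb·t₀) − e^(−λb·t)),

the solution of filling at rate `f·λb·e^(−(λp+λb)t)` with physical decay and
complete, instantaneous voiding every `Tv` hours (no residual fraction).
Defaults: excreted fraction f = 0.5, biological half-life Tb = 3 h, voiding
interval Tv = 4 h; the sensitivity grid covers f ∈ {0.3, 0.4, 0.5} and
Tv ∈ {2, 4} h. The residence time is the sum of per-cycle closed-form
integrals. By default the series is summed to convergence rather than
truncated at the 10-h curve horizon: the model is purely theoretical (no
measurement ends it), convergence is geometric, and the full series is what
the conventional implementations of this model report — truncating at 10 h
would change the third significant figure (0.307 vs 0.308 h at the
defaults). A finite `horizon_h` reproduces the truncated variant when
consistency with a truncated measured curve is preferred. A
trapezoid-quadrature oracle (`bladder_residence_numeric`, grid snapped to
the voiding instants) verifies the closed form; its error is second-order
in the step (~3.6e-6 h at step 1e-4 h, ~1.5e-7 h at 2e-5 h).

## Dose engine

Absorbed doses follow the MIRD schema `D_T = Σ_S τ_S · S(T←S)` with
S-values in mGy/(MBq·h) supplied as data. S-value derivation from phantom
geometry is out of scope; the shipped `svalues_toy.csv` is a synthetic
self-dose-dominant table with plausible magnitudes for tests and demos, and
organ absorbed doses computed from it are illustrative only.

Effective dose uses radiation weighting factor 1 (photons/positrons), so
equivalent dose in mSv equals absorbed dose in mGy. ICRP 103 weights: 0.12
for red marrow, colon, lung, stomach, breast and remainder; 0.08 gonads;
0.04 for bladder, oesophagus, liver, thyroid; 0.01 for bone surface, brain,
salivary glands, skin. ICRP 60 weights: 0.20 gonads; 0.12 marrow, colon,
lung, stomach; 0.05 bladder, breast, liver, oesophagus, thyroid; 0.01 skin,
bone surface; 0.05 remainder. Tissues absent from a phantom dose vector are
resolved by a configurable surrogate map. Defaults, following
OLINDA/MIRDOSE-era practice: ICRP 103 colon = 0.57·ULI + 0.43·LLI,
oesophagus ← thymus, salivary glands ← brain, gonads = mean(testes,
ovaries), remainder = arithmetic mean of adrenals, gallbladder wall, heart
wall, kidneys, muscle, pancreas, small intestine, spleen, thymus, uterus;
ICRP 60 colon ← LLI wall with the ULI wall joining the remainder set
(adrenals, brain, ULI, small intestine, kidneys, muscle, pancreas, spleen,
thymus, uterus). The ICRP 103 remainder is formally a 13-tissue
mass-independent mean including tissues no classical phantom reports
(lymphatic nodes, oral mucosa, extrathoracic airways, prostate); the
10-organ arithmetic mean over available organs is the practical surrogate
and is configuration, not code. The gonad convention (testes only vs
testes/ovaries mean) moves the recomputed effective dose by less than 1 %
(asserted in the tests). Recomputed effective doses therefore carry a
mapping uncertainty of a few percent; against the reference study's printed
columns the ICRP 60 values land within ~1.2 % and the ICRP 103 values
within ~7.4 % of the published figures.

Injection limits divide a regulatory cap by the governing dose per MBq and
round to the nearest MBq: US single-scan/annual caps of 30/50 mSv for the
whole-body/blood-forming/eye/gonad set and 50/150 mSv for all other organs,
and the European 10 mSv-per-scan effective-dose cap. The lens of the eye is
not a phantom target organ; the critical set is represented by total body,
red marrow and the gonads.

Method comparison reports the Pearson product–moment correlation over the
shared target-organ list (all 25 rows of a standard dose table by default,
including total body) and per-organ percent deviations 100·(a−b)/a.

## PET quantification

Frame means decay-corrected to frame start are converted to physical
frame-average values via
`corrected · e^(−λ·t_start) · (1 − e^(−λΔt))/(λΔt)` and timestamped at the
frame midpoint (midpoint minimizes interpolation bias for monotone curves).
Sphere VOIs (default radius 2 mm) require an explicit organ volume — by
default the standard-animal organ fraction times the scanned body weight
over the organ density, with a CT-derived override — while whole-organ
masks default to the mask volume. Concentration-to-FIA conversion uses
volumes (ml); densities enter only when masses are supplied. No scatter,
partial-volume or spill-over correction is applied: reproducing those
biases, not correcting them, is the point of the comparison machinery.

## Synthetic data

The generator defines the study conditions: 6 time points (2, 5, 10, 30,
60, 120 min) × 4 animals, 5 % multiplicative lognormal counting noise, 5 %
organ-mass scatter, a 10-min counting delay, ~7 MBq injections, ~15 organs
with two-exponential kinetics (liver-dominant early uptake, renal and
hepatobiliary clearance), urinary fraction 0.5 with a 3-h biological
half-life. Amplitudes keep organs + urine below the injected activity at
all times (asserted). Fast components (k ≥ 1.5/h) are confined to the first
half hour where sampling is dense; slower components have rates ≤ 0.5/h.

Two ground-truth residence-time conventions are exposed.
`true_residence_time` integrates the analytic curve (biological state
frozen after the last design time, matching the trapped-activity
assumption). `design_residence_time` integrates, in closed form, the
piecewise-linear curve through the noiseless design samples. The difference
between them — 1.3 to 4.2 % across the default organs — is the
interpolation bias of the 6-point sampling design itself: linear
interpolation of convex multi-exponential decay over the sparse late
segments systematically overestimates the integral. Pipeline correctness is
therefore asserted against the design oracle (agreement to 0.5 %, in
practice exact for noiseless input), while parameter recovery under noise
is asserted against the analytic truth within 10 %, a band that absorbs
both the design bias and the counting noise.

The voxel phantom renders non-overlapping homogeneous ellipsoids on a
0.4 × 0.4 × 0.8 mm grid (80 × 80 × 40 voxels by default), blurs each frame
with a Gaussian point-spread function, optionally adds lognormal noise, and
re-applies the frame-start decay-correction convention. Frame values are
midpoint-equivalent, so the unblurred whole-organ means invert exactly
through the quantifier. Blur conserves total activity within 1 %
(boundary truncation); under increasing FWHM a centred sphere in a small
hot organ recovers monotonically less than the truth (partial volume) and
tissue shells around hot organs gain activity (spill-over) — the phantom
reproduces these biases qualitatively, not any scanner's calibrated
magnitudes.

What passing synthetic tests do *not* show about real data: real kinetics
are not sums of two exponentials, organ masses and densities vary with
strain and age, real counting noise is not purely multiplicative, contrast
agents perturb clearance, and real scanner PSFs are spatially variant with
scatter and randoms; the phantom's ellipsoid geometry only demonstrates
that the pipeline responds to resolution loss in the physically expected
direction.

## Problem sizes and numerical choices

Default problem sizes were chosen so the full suite runs in seconds: 360-row
synthetic studies, 45-frame or shorter schedules, and an 80 × 80 × 40
phantom grid; all scale up linearly through the same interfaces. Tie-breaks
and degenerate inputs: single-animal groups carry SD 0 with a warning;
empty VOI masks, overlapping phantom organs, non-contiguous frame
schedules, negative times/masses/activities and duplicate
(animal, organ, time) triples all raise; zero mean residence time reports
an absent CV rather than dividing by zero.

## Known limitations

No allometric (non-linear) scaling, no pediatric or sex-specific phantoms,
no compartmental model fitting, no blood-to-marrow model, no bladder-wall
mass dynamics, no decay chains or branching ratios, and no phantom S-value
computation — the dose engine is only as good as the S-value table it is
given. Reported %CV envelopes are best/worst-case windows, not confidence
intervals.
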