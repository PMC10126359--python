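# Methods

This note documents the models, parameter choices, and numerical
conventions behind `nirsmci`, and what the synthetic cohort does and does
not establish about real recordings.

## 1. Optical model and units

The modified Beer–Lambert law relates optical-density change at
wavelength λ to chromophore concentration changes:

    dOD(λ, t) = [ε_HbO(λ) ΔHbO(t) + ε_HbR(λ) ΔHbR(t)] · d · DPF(λ)

with *d* the source–detector distance and DPF the differential pathlength
factor correcting for scattering-lengthened photon paths. Molar base-10
extinction coefficients are taken from the Prahl (Oregon Medical Laser
Center) compiled hemoglobin spectra, the tabulation used by most
continuous-wave fNIRS toolchains: at 760 nm ε = (586, 1548.52) and at
850 nm ε = (1058, 691.32) cm⁻¹·M⁻¹ for (HbO, HbR). The 2×2 system is
solved per time point; the matrix condition number (≈4) is checked at
construction.

**Unit convention.** Reported concentration labels in prefrontal fNIRS
screening studies are often internally ambiguous ("μM/mm"). This package
stores *pathlength-scaled* concentration change in μM·mm — ΔOD divided by
DPF only — by default, with a config switch (`unit_mode="uM"`) that also
divides by *d*·DPF for absolute μM. The choice rescales every mHbO value
by one constant and cannot change any group contrast, ROC, correlation,
or ranking. DPF defaults to 6.0 at both wavelengths (typical adult
forehead); it too only sets the global scale.

## 2. Preprocessing chain

Order: intensity → ΔOD (log₁₀, referenced to the mean over the initial
3 min rest) → Beer–Lambert inversion → channel QC → band-pass → spatial
filter. Filtering after the (linear) inversion commutes with filtering
before it, so the order only matters for the QC statistics.

* **Channel QC.** A channel is rejected when any sample deviates more
  than 300 μM·mm from the channel mean (*peak rule*). The alternative
  reading — channel standard deviation above 300 — is available as
  `spike_rule="sd"`, but a sustained SD of 300 μM·mm would require
  absurd amplitudes, whereas spikes are local events; the peak rule is
  therefore the default. The first and last 10 s are excluded from the
  QC statistic (filter/edge transients). Rejecting every channel is an
  error (subject unusable), never a silent drop.
* **Band-pass.** 4th-order Butterworth, 0.01–0.2 Hz, applied
  forward–backward (`sosfiltfilt`). Zero-phase application is chosen
  because event-locked averaging must not incur a group delay; the
  effective magnitude response is the square of the single-pass design.
  The passband retains a 0.05 Hz probe within 5 % and attenuates cardiac
  pulsation at 1.1 Hz by more than 40 dB (both verified against the
  analytic magnitude-response oracle).
* **Spatial filter.** "Eigenvector-based" filtering removes the leading
  *k* spatial eigenvectors (left singular vectors of the mean-centered
  channel × time matrix), k = 1 by default — the global systemic
  component. The eigenvectors are estimated from the **initial rest
  segment** and projected out of the entire recording. Estimating them
  from the task data itself would be self-defeating here: a task-evoked
  response shares one time course across channels, so the task matrix is
  itself near rank-1 and whole-matrix SVD would subtract the signal of
  interest. The rest-basis estimate captures the spatial pattern of
  systemic interference (Mayer waves, scalp blood flow) instead. The op
  also accepts an arbitrary basis, or the matrix itself (whole-matrix
  SVD), for non-pipeline use. If the basis segment carries less than
  10 % of the full-series RMS there is nothing to estimate interference
  from and the filter is skipped — this makes the noise-free limit well
  defined.

## 3. Feature extraction

Each block contributes one epoch time-locked to the encoding onset,
spanning −2 s to +12 s. Epochs are baseline-corrected by subtracting the
mean over [−2, 0) s — raw drifting signals make a windowed mean
meaningless otherwise; `baseline_window=None` gives the literal uncorrected
reading. Trials are averaged pointwise; per channel, mHbO is the mean of
the averaged trace over the half-open window [3, 12) s in sample indices.
At 10 Hz the half-open grid average of a unit ramp is 7.45 vs the
continuous 7.5 — a documented discretization, not an error. Regional
values average a hemisphere's kept channels; the total averages all kept
channels, so with equal kept counts per hemisphere
mHbO_total = (mHbO_left + mHbO_right)/2 exactly. Epochs running past the
recording end are dropped with a warning; fewer than 12 of 15 usable
trials flags the subject as unusable. mHbO is computed on the
trial-averaged trace; for a plain mean this is identical to averaging
per-trial window means.

## 4. Synthetic cohort generator

The generator emulates the *study conditions*: two groups (84 healthy,
52 amnestic MCI), the 8-channel montage, the 3 min rest + 15-block
schedule, and group structure matching the published cohort tables.

**Timing.** Encoding duration is 6 s (digit sequences of 4–6 digits at a
deliberate 1 s/digit presentation), recall 6 s, inter-block rest 10 s.
The 3–12 s analysis window therefore extends from encoding into recall —
accepted as defined, since the window is anchored at encoding onset.

**Hemodynamics.** The unit response is a boxcar over each encoding period
convolved with a canonical double-gamma HRF (gamma peak 6 s, undershoot
16 s, dispersions 1 s, undershoot ratio 1/6; peak ≈5 s, integral
positive). Per-channel true HbO is a regional amplitude times this
response; ΔHbR = −ΔHbO/3 (fixed coupling; HbR is carried through but
never analyzed). The forward Beer–Lambert model then produces strictly
positive two-wavelength intensities around a unit baseline (only changes
matter after OD conversion).

**Amplitude normalization.** A drawn amplitude is *defined* as the value
the full default pipeline recovers in expectation. Two deterministic
gains are pre-compensated:

1. the scalar chain gain *c* — the analysis-window mean of the
   band-passed, epoch-averaged unit response (computed through exactly
   the same epoch/average/window code as the feature path), and
2. the 2×2 mixing **M** that removal of the systemic spatial component
   applies to the (left, right) regional means. With uniform channel
   gains inside each region and unit-norm interference profile p̂,
   **M** = I − outer(mean_region(p̂), sum_region(p̂)). The drawn regional
   features **f** are mapped to injected amplitudes **a** = M⁻¹f / c.

The systemic profile is fixed and deliberately heterogeneous *within*
each hemisphere (`SYSTEMIC_PROFILE`): were it uniform within regions, it
would lie in the span of the region indicators, **M** would be singular,
and the regional means would not be identifiable after projection.
Compensation is active only when the in-band systemic RMS (post-filter)
exceeds five times the in-band white-noise RMS — the regime in which the
rest-period eigenvector actually recovers p̂ — and in the noise-free limit
(where the pipeline skips the filter) it reduces to the identity.

**Noise.** Additive, in concentration units: global sinusoids sharing the
systemic profile — cardiac 1.1 Hz (amplitude 0.4 μM·mm), respiration
0.25 Hz (0.6), Mayer waves 0.095 Hz (2.0) — plus per-channel white noise
(SD 0.5 μM·mm per 10 Hz sample), slow random drift (±0.005 μM·mm/s), and
sparse Gaussian spike artifacts (0.3/min per channel, amplitude 5 μM·mm,
width 0.3 s). Amplitudes were chosen once to represent the high-quality,
motion-instructed recordings the study describes (no channel exceeds the
300 μM·mm rejection threshold, matching the reported zero rejections)
while keeping the in-band systemic component dominant over white noise
during rest. Under these defaults the per-subject feature extraction
error has SD ≈ 0.05 μM·mm with a ≈2 % attenuation bias (finite-sample
error in the rest-basis eigenvector), small against the between-subject
SDs of 0.14–0.24 μM·mm.

**Group calibration.** Regional amplitudes are drawn bivariate-normal per
group from the published means/SDs (left: 0.977/0.244 healthy vs
0.591/0.163 MCI; right: 0.895/0.222 vs 0.655/0.138). The left–right
correlation per group is *derived* from the published total-PFC SDs via
4σ²_total = σ²_L + σ²_R + 2ρσ_Lσ_R (ρ ≈ 0.78 healthy, 0.93 MCI). MoCA-K
is drawn jointly with the left amplitude: a shared within-group latent
correlation is solved numerically (root finding on a fixed 200 000-draw
common-random-number population) so that the *pooled* correlation across
both groups — between-group mean separation plus within-group association,
after rounding MoCA-K to integer points and clipping to 0–30 — equals the
target 0.500; the solved within-group value is ≈0.11, i.e. most of the
pooled association comes from the shared group contrast. Digit-span
scores are drawn normal per group and not truncated at a ceiling
(truncation would distort the calibrated moments; the instrument ceiling
is not modeled). Age, education, and sex (exact published counts) are
generated for cohort completeness only and do not enter the signal model.

**Determinism.** A cohort seed determines the latent table and, via a
`SeedSequence`, one child seed per subject; identical (spec, seed) pairs
reproduce byte-identical cohorts.

**What the generator does not emulate.** Real optical coupling and
per-channel gain variation; skewed or ceiling-limited score
distributions (all latent scores are normal — notably, the published
group moments make MoCA-K's standardized contrast d ≈ 1.87 *larger* than
left-PFC mHbO's d ≈ 1.78, so left PFC wins the Youden ranking in ~74 %
of replicate cohorts here rather than always, with integer coarseness of
MoCA-K the deciding factor); motion artifacts beyond additive spikes;
independent HbR dynamics; any demographic dependence of the signal.
Passing tests therefore show that the *pipeline* recovers a known ground
truth under realistic interference — not that real MCI cohorts behave
this way.

## 5. Diagnostic statistics conventions

* Group comparisons: pooled-variance two-sample *t* (df = n₁+n₂−2),
  two-sided; Welch available (`equal_var=False`). Pearson χ² without
  continuity correction for the 2×2 sex table. p-values are exact
  distribution transforms, reported to 3 decimals in rendered tables; no
  multiple-testing correction is applied (matching the source analysis
  style, α = 0.05).
* ROC orientation: every candidate score is lower in MCI, so a subject
  is classified MCI iff score ≤ cutoff. Thresholds are midpoints between
  adjacent distinct scores plus ±∞; a single distinct score degenerates
  to AUC 0.5 with a warning. The trapezoid AUC equals the Mann–Whitney
  pairwise statistic exactly (verified exhaustively on small instances
  and against scikit-learn).
* Youden-optimal cutoff: maximizes J; among ties the cutoff with the
  higher sensitivity wins (favoring MCI detection — a screening-context
  choice).
* Predictive values: `mci_positive` is the library default
  (PPV = P(MCI | predicted MCI)); `healthy_positive` treats the
  predicted-healthy row as positive. The two conventions swap (PPV, NPV)
  on any confusion matrix; rendered tables show both side by side.
* AUC significance tests and cross-validated classifiers are out of
  scope.

## 6. Problem sizes

Stochastic checks use sizes chosen to pin means well below the assertion
tolerances: 500 replicate cohorts of 136 subjects for the expected group
*t* (tolerance ±0.3) and expected pooled correlation (±0.03); 200
signal-level subjects for the full-chain group-mean check (±0.06);
100 000 scores per group for the binormal AUC closed-form check (±0.005).
`scripts/acceptance.py` uses the same 500-replicate design, seeded from
its `--seed` argument.

## 7. Known limitations

* The rest-basis spatial filter assumes the systemic component either
  clearly dominates the in-band rest covariance or is absent. In
  intermediate regimes (e.g. Mayer waves switched off but respiration
  on) the estimated eigenvector is a noise/interference mixture, its
  removal distorts task amplitudes, and the generator's pre-compensation
  does not apply — group means are then biased low.
* Extraction noise inflates observed feature SDs by ~2 % over the latent
  calibration targets and attenuates the observed pooled correlation
  comparably; the calibration is defined at the latent level.
* The half-open sample window makes windowed means depend slightly
  (≤0.7 % at 10 Hz) on the sampling grid.
* With rejected channels the left/right kept counts can differ, in which
  case mHbO_total is the kept-channel mean, not the mean of the two
  regional values.
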