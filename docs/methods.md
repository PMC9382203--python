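# Methods

This note documents the models, parameter choices and numerical conventions
behind `thermoramp`, and what the synthetic trials do and do not emulate.

## Thermal-ramping protocol

The temperature schedule starts with a 20-min measurement plateau at the
acclimation temperature (10 °C), then ramps step-wise through targets at
15, 20, 22 °C and every 1 °C thereafter. Nominal heating rates (5 °C h⁻¹ up
to 20 °C, 2 °C h⁻¹ above) are interpreted per segment *including* the
20-min plateau at the segment's target: 10→15 °C therefore takes 60 min —
a 40-min linear ramp followed by the 20-min plateau. This is the only
interpretation under which a 5 °C h⁻¹ nominal rate and a 40-min 10→15 °C
ramp coexist, and it makes the schedule self-consistent at 2 °C h⁻¹ as
well (1 °C steps: 10-min ramp + 20-min plateau).

Each plateau carries three intermittent-flow respirometry cycles (closed
3 min, flush 5 min by default; admissible ranges 2–5 and 5–8 min). Three
closed phases plus the two interleaved flushes occupy 19 min of the 20-min
plateau; the final flush overhangs into the next ramp. Closed
(measurement) phases always sit inside the constant-temperature plateau,
which is what makes a single step temperature per cycle exact.

## Synthetic trials

All channels are sampled at 10 Hz (dt = 0.1 s). One master seed drives the
whole cohort; each fish receives an independent, reproducible substream
(`SeedSequence(seed, spawn_key=(group, fish))`).

**O₂ channel.** During a closed phase the chamber concentration declines
linearly at `−ṀO₂(T)·m/(V−V_fish)` plus the background slope, where
V_fish = m/1.0 kg L⁻¹ (fish density 1). Between closed phases the chamber
relaxes exponentially to the treatment set-point (time constant 45 s).
Gaussian sensor noise (sd 0.08 % air saturation) is added to the % channel;
at this level every closed-phase fit keeps R² ≥ 0.95, matching the quality
of a well-behaved optode system. The background slope interpolates linearly
between +0.02 mg O₂ L⁻¹ min⁻¹ at 10 °C (pump-heating artefact) and
−0.01 mg O₂ L⁻¹ min⁻¹ at the CT_max temperature (slight microbial uptake),
and the same anchors are carried in the trial metadata for the correction
stage — the background assay is an input to the analysis, as it is in the
laboratory, not something inferred from the fish trace.

**ṀO₂ curve.** Routine ṀO₂ rises exponentially (Q10 = 2.35 from
85 mg O₂ kg⁻¹ h⁻¹ at 10 °C) up to a divergence temperature of 23 °C, above
which each treatment accelerates geometrically to its own ceiling —
292.8 mg O₂ kg⁻¹ h⁻¹ at 24.5 °C (normoxia) versus 462.1 at 25 °C
(hyperoxia) — and stays flat to CT_max. The ceilings are the two group
means the pipeline must recover; their ratio (+58%) factorises via the Fick
principle into the calibrated cardiac-output (+33%) and A–V O₂ (+19%)
contrasts, so the generator is internally Fick-consistent by construction.

**Flow channel.** Each beat is a half-rectified sinusoid over a small
diastolic baseline (10% of mean flow); instantaneous beat frequency follows
f_H(T), a Q10 curve that plateaus at high temperature (the chronotropic
ceiling): 55 bpm at 10 °C rising to 104 bpm ≥ 24.5 °C in normoxia and to
94.7 bpm ≥ 25 °C in hyperoxia. Stroke volume is temperature-independent at
0.60 (normoxia) and 0.876 (hyperoxia) ml beat⁻¹ kg⁻¹. Amplitude is set so
the continuous-time window mean equals f_H·V_S·m exactly; white noise at 5%
of the mean pulse amplitude is added. Heart rates above 150 bpm are
rejected as unresolvable at 10 Hz (< 4 samples per beat).

**CT_max.** Loss of equilibrium is drawn per fish from a normal law
truncated to (20, 30) °C: mean 26.0 °C (normoxia) versus 26.87 °C
(hyperoxia), sd 0.25 °C. The trial's channels end at the first moment the
ramp reaches the drawn temperature; a fish never loses equilibrium during
a plateau because plateau temperatures lie below its threshold.

**Blood panels.** Venous samples are generated at 10, 20, 24 and 26 °C and
at CT_max. Lactate follows baseline + 0.4·(e^{(T−T_on)} − 1) mM above a
treatment-specific onset (23.5 °C normoxia, 25.2 °C hyperoxia — the
attenuated anaerobiosis under hyperoxia); P_vO₂ declines linearly with
temperature from 4.2 kPa (normoxia) or 5.8 kPa (hyperoxia) at 10 °C, giving
a +1.2 kPa hyperoxia offset at 26 °C; haematocrit interpolates anchors and
runs lower under hyperoxia. Values get multiplicative log-normal noise
(CV 5%).

**Inter-individual variation.** Body mass is truncated-normal
(0.9 ± 0.14 kg on (0.4, 1.6)). Unit-mean log-normal factors scale the ṀO₂
curve (CV 6%), stroke volume (CV 4%) and the heart-rate curve (CV 3%);
the HR and SV factors are correlated at −0.6 on the log scale because
cardiac output, not its two factors, is the physiologically regulated
quantity. These dispersions are deliberately at the tight end of what
controlled, surgically instrumented cohorts show: they were fixed once, by
a power argument, so that the calibrated between-group contrasts are
identifiable from a single cohort of 9 fish per arm. Even so, the group
contrast computed from one cohort is a random quantity: the percent SV and
CO contrasts carry a sampling sd of ≈2–2.5 percentage points and the
CT_max difference ≈0.12 °C, so individual seeds can land 2σ or more from
the population values. Passing recovery tests therefore demonstrate an
unbiased, low-noise pipeline under these conditions — not that any single
real cohort of nine fish would pin the population contrast.

What the generator does **not** emulate: haemodynamic waveform realism
(pressure, compliance, respiratory modulation), optode drift or spikes
beyond white noise, in-chamber temperature micro-gradients (the ~0.15 °C
closed-phase warming is absorbed into the background slope), the
exhaustive-exercise/recovery history preceding ramping (trials start in the
recovered 10 °C state), and any behavioural component of loss of
equilibrium. Recovery results on synthetic cohorts say nothing about
optode calibration error or probe placement issues in real data.

## Analysis pipeline

**Units.** % air saturation converts to mg O₂ L⁻¹ through the
Benson–Krause freshwater solubility formulation at 101.325 kPa (salinity
0); it matches standard dissolved-oxygen tables to < 0.5% over 0–40 °C.

**Slope fitting and QC.** Closed-phase segments come from matched
closed_start/closed_end event pairs (≥ 10 samples each) and are labelled
with the protocol step nearest their mean temperature. Concentration vs
time (minutes) is fitted by ordinary least squares; a cycle passes QC when
R² ≥ 0.95 (configurable). QC failures are flagged, never silently dropped;
a step whose cycles all fail yields a missing routine value with a
warning. A zero-variance response leaves R² undefined (NaN, QC fail)
rather than erroring.

**Background correction.** Corrected slope = measured slope − bg(T), with
bg linear between the two anchor measurements. Sign convention: a positive
background (apparent O₂ gain) steepens the fish-attributed decline. ṀO₂ =
−corrected·60·(V − m)/m; negative results are flagged anomalous, not
clipped.

**Routine and maximal values.** Routine ṀO₂ per step is the mean of
QC-passing cycles; the maximum over steps breaks ties toward the higher
temperature. Cardiac windows reuse the exact closed-phase intervals:
per-cycle heart rate (two-pass peak detection: prominence 0.3 of the
window amplitude range, then a refractory distance of 60/(2.5·f_H_est) s
from a first-pass rate estimate; f_H = 60·(n−1)/span from the first-to-last
beat interval, unbiased for partial windows), per-cycle Q̇ = mean flow/m,
step values as cycle means, V_S = Q̇/f_H, A−V O₂ = ṀO₂/(60·Q̇). The
"maximal" cardiac values are those at the step of maximal routine ṀO₂,
even when Q̇ is numerically higher elsewhere. Stroke volume is carried
mass-specific (ml beat⁻¹ kg⁻¹); multiply by mass for the absolute form.

**Statistics.** The mixed two-way ANOVA uses split-plot sums of squares
(between-groups tested against subjects-within-groups; the repeated factor
and interaction against the within-subject residual). The
Greenhouse–Geisser epsilon comes from the double-centred pooled
*within-group* covariance of the repeated measures — the split-plot
estimator (this differs from pooling across groups, which inflates the
apparent non-sphericity when group means differ); ε is clipped to
[1/(k−1), 1] and multiplies both df of the within and interaction tests.
Subjects missing any level are removed listwise, mirroring the restriction
of repeated-measures comparisons to temperatures every fish reached
(≤ 25 °C). k = 2 forces ε = 1 exactly. t-tests default to Welch (the
equal-variance assumption of the original comparisons is not stated;
pooled is available). Mann–Whitney U uses exact enumeration when
n₁+n₂ ≤ 20 without ties, otherwise the tie-corrected normal approximation;
an all-identical degenerate sample returns U = n₁n₂/2, p = 1. The late-ramp
(26 °C) blood contrast pools each fish's 26 °C sample with its at-CT_max
sample when CT_max snaps to the 26 °C step, with a flag recording which
was used.

**LT50.** Two-parameter logistic (location = LT50, scale) fitted by
maximum likelihood (L-BFGS-B with analytic gradients; the slope 1/scale is
bounded to scale ∈ [0.05, 10] °C so perfectly separated assays remain
identifiable — the location is then pinned by the intermediate levels).
Confidence intervals are percentile bootstrap over individuals resampled
within temperature level; two fits are called significantly different when
their 95% CIs do not overlap.

## Numerical choices and degenerate inputs

- Event times snap to the 10 Hz grid; CT_max is estimated as the trace
  temperature at the loss-of-equilibrium event (grid error < 2·10⁻⁴ °C).
- Beat detection requires a ≥ 30 s window and raises on flat signals;
  windows with partial flow coverage are flagged `incomplete` (kept, with
  NaN values when no cycle was usable) rather than silently averaged.
- Degenerate ANOVA inputs (zero error variance) return NaN F with a
  `degenerate` flag instead of raising.
- Reports are rendered to markdown from the JSON dict itself, so every
  number in the human-readable report is machine-readable and reruns under
  a fixed seed are byte-identical.

## Problem sizes

Default trials simulate ~5–6 h of protocol at 10 Hz (~200k samples per
channel per fish); a full two-arm cohort (18 fish) generates and analyses
in a few seconds. The test suite's heaviest items are chosen to keep the
whole run under a minute: the ANOVA type-I-error simulation uses 2 000
null replicates (n = 9/group, k = 5), and LT50 bootstrap coverage uses 150
simulated assays × 199 bootstrap replicates.

## Known limitations

- The A–V O₂ difference is Fick-derived only; venous O₂ content is not
  reconstructed from P_vO₂ (no blood O₂-binding model).
- The generator's treatment effects are multiplicative shifts with flat
  high-temperature ceilings; it cannot express declining ṀO₂ or arrhythmic
  flow above the optimum, so the pipeline's behaviour on post-peak declines
  is untested beyond the tie-breaking rule.
- The literature table's heating-rate column reconstructs decimal points
  lost in transcription for three studies; species, O₂ levels, significance
  calls and CT_max differences are verbatim.
- Percent air saturation is converted assuming freshwater at standard
  pressure; brackish or altitude corrections are out of scope.
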