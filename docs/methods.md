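# Methods

This note documents the models, estimators, and numerical choices behind
`bgapipe`, and what the synthetic validation does and does not establish.

## Broadband gamma amplitude (BGA)

The quantity of interest is the instantaneous amplitude of the 50–150 Hz
band of an intracranial EEG channel, a robust proxy for local population
firing. The estimator:

1. decimate the raw signal to 512 Hz (polyphase FIR anti-aliasing);
2. re-reference to a bipolar montage between adjacent contacts of each
   depth-electrode shaft, suppressing volume-conducted common sources;
3. band-pass the full continuous recording in twenty non-overlapping 5 Hz
   sub-bands ([50,55), …, [145,150) Hz);
4. take the analytic-signal magnitude of each sub-band, decimate it to
   64 Hz (15.625 ms resolution), and divide it by its own full-session
   mean — this whitens the 1/f spectral decay so every sub-band
   contributes equally;
5. average the twenty unit-mean envelopes and multiply by 100.

The result is one BGA trace per channel in percent of the session mean
(session mean = 100 by construction, to rounding error).

Numerical choices. The sub-band filters are 4th-order Butterworth
band-passes applied forward–backward (`sosfiltfilt`), so the envelope
carries no group delay and latency estimates are unbiased; envelope
decimation is FIR anti-aliased (`resample_poly`), not bin-averaging, to
preserve timing; the Hilbert transform runs on the whole session (padded to
a fast FFT length) rather than per epoch, avoiding epoch-edge artifacts.
The narrow 5 Hz bands necessarily smear envelope transients by roughly
±100 ms; the latency tolerances used in validation absorb this. The
anatomical label of a bipolar pair defaults to the first contact's label
(a `bipolar_label` column overrides it per channel); response-dependent
labeling would be circular inside a pipeline.

## Epoching and exclusions

Epochs span [−500, 1500) ms around stimulus onset — 128 samples at 64 Hz,
onsets mapped to the nearest envelope sample at or before the event, no
interpolation. The mean over the half-open [−50, 0) ms interval (3 samples)
is subtracted per epoch and channel. Exclusions, applied in one pass:

* trials with an incorrect, missing, or ≥3 s response;
* all trials of any block whose accuracy over its original trials is
  below 75 % (missing responses count as incorrect; blocks are never
  re-admitted after individual exclusions);
* per channel, any epoch whose full window intersects an interictal-spike
  annotation on that channel (other channels keep the trial).

Retention is tracked as a trial × channel mask; every drop is written to an
exclusion ledger with the rule that fired.

## Channel-level inference

**Activity.** Per channel and condition, each trial contributes a paired
difference between its BGA at post-stimulus sample *t* and its own
pre-stimulus mean ([−500, 0) ms). These differences enter a two-sided
Wilcoxon signed-rank test per sample. The signed-rank p is computed by
exact enumeration of the positive-rank-sum null (a dynamic program over
doubled ranks, valid under midranked ties) for n ≤ 25 after zero-removal,
and by the normal approximation with continuity and tie corrections above.
As a deliberately conservative step, each sample's p is replaced by the
maximum over the forward six-sample window [t, t+5] (93.75 ms; truncated
at the series end) before Benjamini–Hochberg FDR control at q = 0.05
across the 96 post-stimulus samples of that channel × condition. A channel
is *active* if any sample survives for any condition. The windowed maximum
can only shrink the rejection set relative to raw-p FDR (verified as a
property test), which is what keeps the null false-positive rate of the
*any-sample, any-condition* union well below q in calibration.

**Contrasts and selectivity.** Between-condition tests pair trials by image
id — each image appears exactly once per condition, which is the only
pairing the design supports. The same windowed signed-rank machinery is
used, with the FDR family pooled across all active channels, all samples,
and the four contrasts (allo vs ego, ego vs allo, allo vs control, ego vs
control; the two allo/ego directions share two-sided p-values and both stay
in the family). Direction is the sign of the median paired difference.
Labels, with a significant direct allo/ego contrast taking precedence over
the indirect vs-control route:

* *allocentric-selective*: allo > ego anywhere; or allo > control with no
  surviving ego-vs-control sample (egocentric-selective symmetric);
* *spatial-selective*: both allo > control and ego > control;
* otherwise *active-nonselective*.

Contradictory direct contrasts (both directions significant at different
samples) are resolved by the earlier significant sample and logged.

**Late/motor responses.** The published criterion — a late peak plus epochs
visually aligned to the key press — is operationalized as: trial-averaged
peak later than 800 ms *and* Pearson correlation of per-trial peak times
with reaction time above 0.5. Both thresholds are configurable; the
correlation operationalization is a judgment call and the main caveat is
that motor responses falling outside the epoch window dilute the
correlation.

**Anatomy.** Channels map to nine regions of interest by anatomical label
(occipital OC; medial temporo-occipital mTempO; lateral temporal LTC;
intraparietal IPS; supramarginal SMG; precentral Precentr; anterior frontal
Afront; inferior frontal IFG; anterior insula AIC), with MFG/SFG split at
MNI y = 20 (y > 20 anterior; the boundary itself goes posterior). Labels
outside the table (hippocampus, temporal pole, …) are unassigned. Channels
of interest are the condition-selective channels in regions with selective
channels from ≥3 distinct patients.

## Group statistics

Mixed (split-plot) ANOVAs use the univariate repeated-measures approach:
each within-subject effect is an orthonormal (Helmert) contrast projection
of the complete within-cells of every unit, analyzed against the
between-group structure in its own error stratum. On balanced designs this
reproduces the textbook sums of squares exactly (tested against an
independent brute-force oracle at 1e-8 relative, and against pingouin /
statsmodels where those cover the design). With unbalanced groups the
within-effect hypotheses are tested on unweighted group means (Type III
convention). No sphericity correction is applied by default, matching the
integer-df convention of the channel-level iEEG literature;
Greenhouse–Geisser is available behind a flag. Units of analysis are
channels for the iEEG ANOVAs and subjects for behavior; channels missing
any within cell drop out listwise, which is what shrinks the error df for
partially-defined metrics such as onset latency.

Tukey HSD p-values come from the studentized range distribution with the
error stratum relevant to each family: the within stratum for condition
means (paired), Tukey–Kramer on unit means for region contrasts, and — for
the per-region-per-bin condition contrasts of the three-way design — an
error term pooled over the Condition and Condition × TimeBin strata (a
condition difference at a fixed bin draws on both), with k = 3 per cell.
The published post hoc on 270 interaction cells is underspecified; this
operationalization is documented here and configurable. The *time of
discrimination* of a region and contrast is the earliest 100 ms bin whose
Tukey-adjusted p falls below 0.05, reported as its half-open interval.

Latency metrics: magnitude is the maximum of the trial-averaged response
over [0, 1500) ms; t90 the first crossing of 90 % of that maximum (only
increases are analyzed — suppression yields an undefined t90); tsig the
first sample surviving the activity test's windowed FDR mask; binned means
cover [0, 1000) ms in ten half-open 100 ms bins (6 or 7 samples each,
averaged as-is).

## Synthetic studies and what they show

The generator emulates the study design: 8 sessions × 3 blocks × 16 trials
(384 trials, 128 per condition), one block per condition per session in
seed-counterbalanced order, each of 128 images once per condition, 3 s
trials, binary image-type tags balanced half/half. Behavioral accuracy is
Bernoulli (defaults 97.6 / 88.2 / 86.8 % for control / egocentric /
allocentric) and reaction times lognormal (means 688 / 885 / 967 ms,
log-scale SD 0.35) — positive skewed latencies with the published means.
Inter-block pauses are fixed at 5 s of simulated time (the real pauses
were subject-controlled; any positive value serves).

Recordings are built per contact as: shared per-shaft pink noise (20 µV
RMS, exponent 1 — the 1/f decay the whitening step compensates) + private
pink noise (15 µV) + a private 50–150 Hz Gaussian carrier (30 µV) whose
envelope is multiplied by (1 + g(t)). The gain g ramps 0 → peak over
`rise` ms starting `onset` ms after the stimulus (or relative to the key
press for motor archetypes), holds for `duration`, and ramps down.
A multiplicative gain on a band-limited carrier — not an additive tone —
is what the filter bank sees as a genuine broadband envelope change; a
tone would load one sub-band and destabilize whitening. Because both
contacts of a shaft share the archetype with independent carriers, the
bipolar derivation cancels the common pink background but keeps the
modulation. With these amplitudes the carrier dominates the gamma band
(~97 % of band power), so an injected gain of 0.8 reappears as ≈ +76–80 %
measured BGA. Response defaults: onset 300 ms, rise 100 ms, duration
500 ms, peak gain 0.8. Spike artifacts are single-cycle 70 ms sine
transients (300 µV) at Poisson times. One RNG sub-stream per operation,
derived from the master seed, keeps every stage independently
reproducible.

Validation sizes (chosen to exercise the stated conditions at desk scale):
null calibration uses 200 gain-zero channels and reduced designs of 40
trials per condition (8 sessions × 3 blocks × 5 trials); recovery uses 80
channels, 16 per archetype; time-of-discrimination recovery uses 30
replicates of bin-level data (9 regions × 12 channels, within-channel SD
8 %, channel SD 15 %, +25 % allocentric effect at bins 4–6).

What passing does **not** show about real data: the generator has no
volume conduction, no electrode geometry, no eye/muscle artifacts, no
line noise, no non-stationary background, and its trial-to-trial envelope
variability is purely stochastic — real condition-selective effects are
smaller, and rejection rates on real recordings will differ. The
simulations validate the *machinery* (calibration under the null, recovery
under a known signal), not effect sizes.

## Known limitations

* Channels are treated as independent units in the group ANOVAs (as in the
  channel-level literature); nesting of channels within patients is not
  modeled.
* The activity-detection FDR family is per channel × condition across time
  samples; pooling over conditions as well is a defensible alternative and
  a configuration away.
* The between-condition signed-rank test assumes image pairing; the
  generator guarantees it, real event tables must provide consistent
  image ids.
* EDF input is supported through `mne` when installed; the canonical
  interchange format is HDF5.
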