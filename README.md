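# bgapipe

Broadband gamma activity (BGA) analysis for intracranial EEG studies of
condition selectivity — from raw stereo-EEG recordings to a per-channel
selectivity taxonomy, latency metrics, and group-level mixed ANOVAs, plus a
synthetic-study generator that provides ground truth for every stage.

## What it does

Intracranial studies of cognitive selectivity (for example, egocentric vs
allocentric spatial judgments) typically ask three questions of every
recorded bipolar channel: does it respond to the task at all, does it
prefer one condition, and when does the preference emerge? `bgapipe`
implements that full analysis chain:

1. **BGA estimation** — decimate to 512 Hz, bipolar montage between
   adjacent shaft contacts, Hilbert filter bank over twenty 5 Hz sub-bands
   spanning 50–150 Hz, each sub-band envelope decimated to 64 Hz and
   whitened by its own session mean, averaged and scaled so BGA is in
   percent of the session mean (15.625 ms resolution).
2. **Epoching** — stimulus-locked [−500, 1500) ms epochs,
   [−50, 0) ms baseline subtraction, and exclusion of incorrect / slow
   (≥3 s) trials, low-accuracy (<75 %) blocks, and spike-contaminated
   epochs per channel.
3. **Channel statistics** — per-sample paired Wilcoxon signed-rank of each
   post-stimulus point against the trial's pre-stimulus mean, a
   conservative six-sample (93.75 ms) sliding max-p window, and
   Benjamini–Hochberg FDR (q = 0.05) across time samples to flag *active*
   channels; image-paired condition contrasts with the FDR family pooled
   over channels × samples × contrasts; classification into
   egocentric-/allocentric-/spatial-selective or active-nonselective;
   removal of key-press-locked motor channels (peak >800 ms and per-trial
   peaks tracking reaction time); ROI assignment from anatomical labels
   and the MNI y = 20 frontal split; channels of interest = selective
   channels in ROIs with ≥3 patients.
4. **Latency metrics** — response magnitude (max % over baseline), onset
   latency *tsig* (first FDR-significant sample), peak latency *t90*
   (first crossing of 90 % of the maximum), and ten 100 ms binned means.
5. **Group statistics** — χ² of selectivity proportions across ROIs,
   one-way repeated-measures ANOVA for behavior, two-way
   (Condition × ROI) and three-way (Condition × TimeBin × ROI) mixed
   ANOVAs with Tukey HSD, and the *time of discrimination* — the first
   100 ms bin at which two conditions separate in a region.

The split-plot ANOVA F for an effect with numerator df `q` tests
`MS_effect / MS_stratum`, with error dfs `(c−1)(N−r)` for within effects
and interactions and `N−r` between (N units, r groups, c within levels);
see `docs/methods.md` for the full statistical model and all defaults.

Because real recordings of this kind are rarely shareable, the
`bgapipe.synthetic` module is first-class: it generates the
8-session × 3-block × 16-trial design (384 trials, 128 per condition,
each of 128 images once per condition), behavioral accuracy and lognormal
reaction times, and contact-level raw signals — pink background plus a
50–150 Hz carrier whose envelope is multiplied by a parameterized
trapezoidal gain per condition — with every injected parameter recorded as
ground truth.

## Worked example

Simulate a small four-channel study (one channel per response archetype)
and run the whole pipeline:

```bash
bgapipe simulate --out demo/sim --seed 7 --trials-per-condition 24 --n-channels 4
# wrote synthetic study (8 contacts, 72 trials) to demo/sim
bgapipe run-all --recording demo/sim/recording.h5 \
    --channels demo/sim/channels.tsv --events demo/sim/events.tsv \
    --out demo/out
# 4 active channels; 3 channels of interest
```

`demo/out/summary.json` then reads:

```json
{
  "config_hash": "53e4f3ed168f",
  "labels": {
    "active_nonselective": 1,
    "allocentric_selective": 1,
    "egocentric_selective": 1,
    "spatial_selective": 1
  },
  "n_active": 4,
  "n_channels": 4,
  "n_choi": 3,
  "n_trials": 72
}
```

All four simulated channels respond to the task (`n_active`), and each
recovers exactly the selectivity class that was injected
(`demo/sim/ground_truth.tsv` lists the truth): the visually responsive but
condition-blind channel comes out `active_nonselective`, and the three
condition-selective channels are the channels of interest. Per-channel
evidence flags, ROI assignments, exclusion ledger, latency metrics, and
ANOVA tables are written alongside (`channel_results.tsv`,
`exclusions.tsv`, `metrics.tsv`, …). The same chain is available
stage-by-stage (`bgapipe preprocess / epoch / select / metrics / group`)
and as a library (`bgapipe.analyze`).

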