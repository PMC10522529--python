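"""Stimulus-locked epoching, baseline correction, and trial/epoch exclusion.

Epochs cover [-500, 1500) ms around stimulus onset at the 64 Hz envelope rate
(128 samples).  Exclusion rules:

(a) trials with an incorrect, missing, or too-slow (>= 3 s) response;
(b) every trial of a block whose accuracy, computed over all the block's
    trials before any other exclusion, falls below 75 %;
(c) per channel, epochs whose full window overlaps an interictal-spike
    annotation on that channel (other channels keep the trial).

Rules are applied in a single pass: a block is never re-admitted because its
accuracy would rise after individual-trial exclusions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bga import BGASeries

log = logging.getLogger(__name__)

REPORT_COLUMNS = ["trial_id", "channel", "rule", "detail"]


@dataclass
class EpochSet:
    """Trials x channels x time tensor of BGA with linked events.

    ``retained[t, c]`` marks epoch (trial t, channel c) as usable; excluded
    epochs stay in ``data`` but are masked.  ``exclusion_report`` lists one
    row per exclusion with the rule that fired.
    """

    data: np.ndarray
    times_ms: np.ndarray
    events: pd.DataFrame
    channels: pd.DataFrame
    env_fs: float
    baseline_corrected: bool = False
    retained: np.ndarray | None = None
    exclusion_report: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=REPORT_COLUMNS))

    def __post_init__(self):
        if self.retained is None:
            self.retained = np.ones(self.data.shape[:2], dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def condition_trials(self, condition: str, channel: int) -> np.ndarray:
        """Indices of retained trials of ``condition`` on ``channel``."""
        mask = (self.events["condition"].to_numpy() == condition) \
            & self.retained[:, channel]
        return np.flatnonzero(mask)


def extract_epochs(bga: BGASeries, events: pd.DataFrame,
                   window_ms: tuple[float, float] = (-500.0, 1500.0)
                   ) -> EpochSet:
    """Cut the continuous BGA into stimulus-locked epochs.

    Stimulus onsets are mapped to the nearest envelope sample at or before
    the onset; nothing is interpolated.  Trials whose window would leave the
    recording are dropped with a logged reason.
    """
    period_ms = bga.sample_period_ms
    n_pre = int(round(-window_ms[0] / period_ms))
    n_post = int(round(window_ms[1] / period_ms))
    n_time = n_pre + n_post
    times_ms = (np.arange(n_time) - n_pre) * period_ms

    env = bga.envelope
    n_env = env.shape[1]
    kept_rows, data, report = [], [], []
    for _, ev in events.iterrows():
        i0 = int(np.floor((ev["onset"] - bga.alignment) * bga.env_fs + 1e-9))
        lo, hi = i0 - n_pre, i0 + n_post
        if lo < 0 or hi > n_env:
            report.append({"trial_id": ev["trial_id"], "channel": "*",
                           "rule": "edge",
                           "detail": f"window [{lo}, {hi}) outside recording"})
            log.warning("trial %s too close to the recording edge; dropped",
                        ev["trial_id"])
            continue
        kept_rows.append(ev)
        data.append(env[:, lo:hi])
    if not data:
        raise ValueError("no trial fits inside the recording")
    tensor = np.stack(data, axis=0)  # trials x channels x time
    return EpochSet(data=tensor, times_ms=times_ms,
                    events=pd.DataFrame(kept_rows).reset_index(drop=True),
                    channels=bga.channels.copy(), env_fs=bga.env_fs,
                    exclusion_report=pd.DataFrame(report,
                                                  columns=REPORT_COLUMNS))


def baseline_correct(epochs: EpochSet,
                     interval_ms: tuple[float, float] = (-50.0, 0.0)
                     ) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over ``interval_ms``.

    The interval is half-open, so the stimulus-onset sample itself is never
    part of the baseline.  Applying the correction twice is a no-op.
    """
    mask = (epochs.times_ms >= interval_ms[0]) & (epochs.times_ms < interval_ms[1])
    if not mask.any():
        raise ValueError(f"baseline interval {interval_ms} contains no samples")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(data=epochs.data - base, times_ms=epochs.times_ms,
                    events=epochs.events.copy(), channels=epochs.channels.copy(),
                    env_fs=epochs.env_fs, baseline_corrected=True,
                    retained=epochs.retained.copy(),
                    exclusion_report=epochs.exclusion_report.copy())


def exclude_trials(epochs: EpochSet,
                   spikes: pd.DataFrame | None = None,
                   rt_limit_s: float = 3.0,
                   block_accuracy: float = 0.75) -> EpochSet:
    """Apply the behavioral and artifact exclusion rules (see module docs).

    Block accuracy counts a missing response as incorrect and is computed on
    all of the block's trials.  Spike overlap uses the epoch's full window in
    recording time.
    """
    ev = epochs.events
    retained = epochs.retained.copy()
    report = []

    correct = ev.get("correct")
    rt = ev.get("rt")
    if correct is not None:
        correct = correct.to_numpy(bool)
        if rt is not None:
            rtv = rt.to_numpy(float)
            responded = np.isfinite(rtv)
            in_time = responded & (rtv < rt_limit_s)
        else:  # no RT information: treat every response as timely
            rtv = np.full(len(ev), np.nan)
            responded = np.ones(len(ev), dtype=bool)
            in_time = responded

        # (b) block rule first on the *original* trials, then (a)
        block_bad = {}
        for block, grp in ev.groupby("block_id"):
            idx = grp.index.to_numpy()
            acc = float(np.mean(correct[idx] & in_time[idx]))
            block_bad[block] = acc < block_accuracy
        for t in range(len(ev)):
            tid = ev["trial_id"].iloc[t]
            if block_bad.get(ev["block_id"].iloc[t], False):
                retained[t, :] = False
                report.append({"trial_id": tid, "channel": "*",
                               "rule": "block_accuracy",
                               "detail": f"block {ev['block_id'].iloc[t]} "
                                         f"below {block_accuracy:.0%}"})
            elif not correct[t]:
                retained[t, :] = False
                report.append({"trial_id": tid, "channel": "*",
                               "rule": "incorrect", "detail": ""})
            elif not in_time[t]:
                retained[t, :] = False
                detail = ("no response" if not responded[t]
                          else f"rt={rtv[t]:.3f}s")
                report.append({"trial_id": tid, "channel": "*",
                               "rule": "too_slow", "detail": detail})
    else:
        log.warning("events carry no 'correct' column; behavioral rules skipped")

    if spikes is not None and len(spikes):
        names = list(epochs.channels["name"])
        w0 = epochs.times_ms[0] / 1000.0
        w1 = (epochs.times_ms[-1] + 1000.0 / epochs.env_fs) / 1000.0
        onsets = ev["onset"].to_numpy(float)
        for _, sp in spikes.iterrows():
            if sp["channel"] not in names:
                continue
            c = names.index(sp["channel"])
            s0, s1 = float(sp["onset"]), float(sp["onset"]) + float(sp["duration"])
            hit = (onsets + w0 < s1) & (onsets + w1 > s0)
            for t in np.flatnonzero(hit):
                if retained[t, c]:
                    retained[t, c] = False
                    report.append({"trial_id": ev["trial_id"].iloc[t],
                                   "channel": sp["channel"], "rule": "spike",
                                   "detail": f"spike at {s0:.3f}s"})

    if not retained.any():
        log.warning("all epochs excluded")
    full_report = pd.concat(
        [epochs.exclusion_report, pd.DataFrame(report, columns=REPORT_COLUMNS)],
        ignore_index=True)
    return EpochSet(data=epochs.data, times_ms=epochs.times_ms,
                    events=ev.copy(), channels=epochs.channels.copy(),
                    env_fs=epochs.env_fs,
                    baseline_corrected=epochs.baseline_corrected,
                    retained=retained, exclusion_report=full_report)
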