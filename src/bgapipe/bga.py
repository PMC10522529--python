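"""Broadband gamma amplitude (BGA) estimation.

The estimator follows the standard Hilbert filter-bank recipe for intracranial
recordings: the raw signal is decimated to 512 Hz, re-referenced to a bipolar
montage between adjacent contacts of each depth-electrode shaft, band-pass
filtered in consecutive non-overlapping 5 Hz sub-bands spanning 50-150 Hz,
and the analytic amplitude of each sub-band is decimated to 64 Hz and divided
by its own full-session mean (whitening away the 1/f spectral decay).  The 20
unit-mean envelopes are averaged and scaled by 100, giving a single BGA trace
per channel in percent of the session mean.

Filtering is zero-phase (forward-backward), so envelope latencies are not
biased by filter group delay.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
import scipy.signal as sps
from scipy.fft import next_fast_len

log = logging.getLogger(__name__)

#: channel-table columns expected by the pipeline
CHANNEL_COLUMNS = ["name", "shaft", "index", "mni_x", "mni_y", "mni_z",
                   "label", "patient", "white_matter", "heterotopic",
                   "epileptic", "seizure_onset"]


@dataclass
class Recording:
    """Multichannel iEEG signal (channels x samples, microvolts)."""

    signal: np.ndarray
    fs: float
    channels: pd.DataFrame
    patient_id: str | None = None

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains NaN or Inf")
        if len(self.channels) != self.signal.shape[0]:
            raise ValueError(
                f"channel table has {len(self.channels)} rows for "
                f"{self.signal.shape[0]} signal rows")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class BGASeries:
    """Whitened broadband gamma envelope, percent of session mean.

    ``alignment`` is the recording time (s) of the first envelope sample.
    """

    envelope: np.ndarray
    env_fs: float
    band: tuple[float, float]
    sub_band_width: float
    alignment: float
    channels: pd.DataFrame

    @property
    def sample_period_ms(self) -> float:
        return 1000.0 / self.env_fs


def _rate_fraction(num: float, den: float) -> Fraction:
    return Fraction(int(round(num * 1000)), int(round(den * 1000)))


def resample_raw(recording: Recording, target_fs: float = 512.0) -> Recording:
    """Anti-alias filter and decimate the raw signal to ``target_fs``.

    Only downsampling is supported; a recording already at the target rate
    passes through unchanged.
    """
    if recording.fs == target_fs:
        return recording
    if recording.fs < target_fs:
        raise ValueError(
            f"upsampling {recording.fs} -> {target_fs} Hz is not supported")
    frac = _rate_fraction(target_fs, recording.fs)
    out = sps.resample_poly(recording.signal, frac.numerator, frac.denominator,
                            axis=-1)
    return Recording(signal=out, fs=target_fs,
                     channels=recording.channels.copy(),
                     patient_id=recording.patient_id)


def bipolar_derive(recording: Recording) -> Recording:
    """Re-reference to bipolar pairs of adjacent contacts on each shaft.

    Output channel ``a-b`` carries ``signal_a - signal_b``.  The anatomical
    label defaults to the first contact's label; a per-channel override is
    honored through an optional ``bipolar_label`` column.  Boolean exclusion
    flags are OR-combined (conservative).
    """
    ch = recording.channels.reset_index(drop=True)
    for col in ("shaft", "index"):
        if col not in ch.columns:
            raise ValueError(f"channel table lacks required column {col!r}")
    rows, signals = [], []
    flag_cols = [c for c in ("white_matter", "heterotopic", "epileptic",
                             "seizure_onset") if c in ch.columns]
    for shaft, grp in ch.groupby("shaft", sort=False):
        grp = grp.sort_values("index")
        if len(grp) < 2:
            log.warning("shaft %s has a single contact; no bipolar pairs", shaft)
            continue
        idx = grp.index.to_numpy()
        for a, b in zip(idx[:-1], idx[1:]):
            ra, rb = ch.loc[a], ch.loc[b]
            signals.append(recording.signal[a] - recording.signal[b])
            label = ra.get("bipolar_label")
            if label is None or (isinstance(label, float) and np.isnan(label)):
                label = ra.get("label")
            row = {
                "name": f"{ra['name']}-{rb['name']}",
                "contact_a": ra["name"], "contact_b": rb["name"],
                "shaft": shaft, "index": ra["index"], "label": label,
                "patient": ra.get("patient"),
            }
            for c in ("mni_x", "mni_y", "mni_z"):
                if c in ch.columns:
                    row[c] = (ra[c] + rb[c]) / 2.0
            for c in flag_cols:
                row[c] = bool(ra[c]) or bool(rb[c])
            rows.append(row)
    if not rows:
        raise ValueError("no bipolar pairs could be derived")
    return Recording(signal=np.asarray(signals), fs=recording.fs,
                     channels=pd.DataFrame(rows),
                     patient_id=recording.patient_id)


def bga_envelope(recording: Recording,
                 band: tuple[float, float] = (50.0, 150.0),
                 sub_band_width: float = 5.0,
                 env_fs: float = 64.0,
                 filter_order: int = 4,
                 chunk_size: int = 64) -> BGASeries:
    """Hilbert filter-bank BGA estimate on the full continuous recording.

    For each sub-band ``[lo, lo + width)``: zero-phase Butterworth band-pass,
    analytic-signal magnitude, FIR anti-aliased decimation to ``env_fs``, and
    division by the sub-band's own full-session mean.  The per-channel output
    is the mean of the unit-mean sub-band envelopes times 100, so its session
    mean is 100 by construction.

    The Hilbert transform runs on the whole session, not per epoch, to avoid
    edge artifacts inside epochs.  Channels are processed in chunks of
    ``chunk_size`` to bound memory.
    """
    fs = recording.fs
    if fs <= 2 * band[1]:
        raise ValueError(f"fs={fs} Hz cannot represent the {band} Hz band")
    edges = np.arange(band[0], band[1] + 1e-9, sub_band_width)
    if len(edges) < 2:
        raise ValueError("band narrower than one sub-band")
    frac = _rate_fraction(env_fs, fs)
    n = recording.n_samples
    nfft = next_fast_len(n)
    names = list(recording.channels["name"])

    out = None
    for start in range(0, recording.signal.shape[0], chunk_size):
        x = recording.signal[start:start + chunk_size]
        acc = None
        for lo, hi in zip(edges[:-1], edges[1:]):
            sos = sps.butter(filter_order // 2, [lo, hi], btype="bandpass",
                             fs=fs, output="sos")
            xb = sps.sosfiltfilt(sos, x, axis=-1)
            env = np.abs(sps.hilbert(xb, N=nfft, axis=-1)[..., :n])
            envd = sps.resample_poly(env, frac.numerator, frac.denominator,
                                     axis=-1)
            np.clip(envd, 0.0, None, out=envd)  # FIR ringing can dip below 0
            m = envd.mean(axis=-1, keepdims=True)
            if np.any(m <= 0):
                bad = names[start + int(np.argmax(m[:, 0] <= 0))]
                raise ValueError(
                    f"zero-mean envelope in band [{lo}, {hi}) Hz on channel "
                    f"{bad!r} (identically zero signal?)")
            acc = envd / m if acc is None else acc + envd / m
        chunk_bga = acc / (len(edges) - 1) * 100.0
        out = chunk_bga if out is None else np.vstack([out, chunk_bga])

    return BGASeries(envelope=out, env_fs=env_fs, band=tuple(band),
                     sub_band_width=sub_band_width, alignment=0.0,
                     channels=recording.channels.copy())
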