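"""Per-channel, per-condition response metrics.

magnitude  - maximal increase of the trial-averaged BGA over [0, 1500) ms,
             in percent of the immediate pre-stimulus baseline;
tsig       - onset latency: time of the first post-stimulus sample whose
             baseline contrast survives the windowed FDR test (undefined
             when nothing survives; such channels drop out of downstream
             ANOVAs listwise);
t90        - peak latency: first time the mean response reaches 90 % of its
             maximum increase (undefined for non-positive responses, since
             only BGA increases are analyzed);
bins       - means over ten half-open 100 ms bins covering [0, 1000) ms.
"""
from __future__ import annotations

import numpy as np
import pandas as pd


def response_magnitude(mean_response: np.ndarray) -> float:
    """Maximum of the trial-averaged post-stimulus response (% units)."""
    return float(np.max(mean_response))


def onset_latency_tsig(sig) -> float | None:
    """Time (ms) of the first FDR-surviving post-stimulus sample, or None."""
    idx = np.flatnonzero(sig.reject)
    if idx.size == 0:
        return None
    return float(sig.times_ms[idx[0]])


def peak_latency_t90(mean_response: np.ndarray,
                     times_ms: np.ndarray) -> float | None:
    """Time (ms) of the first crossing of 90 % of the maximum increase."""
    mag = np.max(mean_response)
    if mag <= 0:
        return None
    idx = np.flatnonzero(mean_response >= 0.9 * mag)
    return float(times_ms[idx[0]])


def bin_average(mean_response: np.ndarray, times_ms: np.ndarray,
                bin_ms: float = 100.0, n_bins: int = 10) -> np.ndarray:
    """Means over half-open ``[k*bin_ms, (k+1)*bin_ms)`` bins, k = 0..n-1.

    Samples are assigned to bins by their own time stamp; at 64 Hz the bins
    alternate between 6 and 7 samples and are averaged as-is (no resampling).
    """
    out = np.empty(n_bins)
    for k in range(n_bins):
        mask = (times_ms >= k * bin_ms) & (times_ms < (k + 1) * bin_ms)
        if not mask.any():
            raise ValueError(f"bin {k} ([{k * bin_ms}, {(k + 1) * bin_ms}) ms)"
                             " contains no samples")
        out[k] = mean_response[mask].mean()
    return out


def channel_condition_metrics(epochs, activity_series: dict,
                              conditions: tuple[str, ...] | None = None,
                              bin_ms: float = 100.0,
                              n_bins: int = 10) -> pd.DataFrame:
    """Metrics table: one row per channel x condition.

    ``activity_series`` is the ``detect_active`` output keyed by
    ``(channel_name, condition)``; its rejection masks define tsig.
    """
    if conditions is None:
        conditions = tuple(pd.unique(epochs.events["condition"]))
    post = epochs.times_ms >= 0
    times_post = epochs.times_ms[post]
    rows = []
    for c, name in enumerate(epochs.channels["name"]):
        for cond in conditions:
            idx = epochs.condition_trials(cond, c)
            if idx.size == 0:
                continue
            mean_resp = epochs.data[idx][:, c][:, post].mean(axis=0)
            sig = activity_series.get((name, cond))
            tsig = onset_latency_tsig(sig) if sig is not None else None
            row = {
                "channel": name, "condition": cond, "n_trials": int(idx.size),
                "magnitude": response_magnitude(mean_resp),
                "tsig": np.nan if tsig is None else tsig,
                "t90": np.nan,
            }
            t90 = peak_latency_t90(mean_resp, times_post)
            if t90 is not None:
                row["t90"] = t90
            for k, v in enumerate(bin_average(mean_resp, times_post,
                                              bin_ms, n_bins)):
                row[f"bin_{k}"] = float(v)
            rows.append(row)
    return pd.DataFrame(rows)
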