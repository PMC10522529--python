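"""Readers and writers for the pipeline's standard on-disk formats.

Recordings travel as HDF5 (``/signal`` channels x samples in microvolts,
``/fs`` scalar) or EDF (read-only, through :mod:`mne` when available); all
tables are tab-separated text with BIDS-compatible column names where those
exist.  Every writer embeds the active configuration hash in a leading
comment line so results remain traceable to their parameters.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .bga import Recording, BGASeries

log = logging.getLogger(__name__)

EVENT_REQUIRED = ["trial_id", "onset", "condition"]
CHANNEL_REQUIRED = ["name", "shaft", "index", "label", "patient"]
SPIKE_REQUIRED = ["channel", "onset", "duration"]
KNOWN_CONDITIONS = {"control", "egocentric", "allocentric"}


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def write_recording_h5(path: str | Path, recording: Recording,
                       config_hash: str = "") -> None:
    """Persist signal + rate; ``track_times=False`` keeps output byte-stable."""
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=recording.signal, track_times=False)
        f.create_dataset("fs", data=float(recording.fs), track_times=False)
        f.attrs["config_hash"] = config_hash
        f.attrs["patient_id"] = recording.patient_id or ""


def read_recording(path: str | Path, channels: pd.DataFrame,
                   fmt: str | None = None) -> Recording:
    """Load a recording (HDF5 or EDF) and attach the channel table.

    The channel table must match the signal rows one-to-one by name (order
    for HDF5, header labels for EDF); mismatches raise with the offenders.
    """
    path = Path(path)
    fmt = fmt or ("edf" if path.suffix.lower() == ".edf" else "h5")
    if fmt == "h5":
        with h5py.File(path, "r") as f:
            if "fs" not in f:
                raise ValueError(f"{path}: missing /fs dataset")
            if "signal" not in f:
                raise ValueError(f"{path}: missing /signal dataset")
            signal = f["signal"][()]
            fs = float(f["fs"][()])
            patient = f.attrs.get("patient_id") or None
        if signal.shape[0] != len(channels):
            raise ValueError(
                f"{path}: {signal.shape[0]} signal rows vs "
                f"{len(channels)} channel-table rows")
        return Recording(signal=signal, fs=fs, channels=channels,
                         patient_id=patient)
    if fmt == "edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise ImportError("EDF support requires mne") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> microvolts
        names = list(raw.ch_names)
        missing = set(channels["name"]) - set(names)
        if missing:
            raise ValueError(f"{path}: channels absent from EDF: "
                             f"{sorted(missing)}")
        order = [names.index(n) for n in channels["name"]]
        return Recording(signal=data[order], fs=float(raw.info["sfreq"]),
                         channels=channels)
    raise ValueError(f"unknown recording format {fmt!r}")


def write_bga_h5(path: str | Path, bga: BGASeries,
                 config_hash: str = "") -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("bga", data=bga.envelope, track_times=False)
        f.create_dataset("env_fs", data=float(bga.env_fs), track_times=False)
        f.create_dataset("alignment", data=float(bga.alignment),
                         track_times=False)
        f.attrs["band"] = list(bga.band)
        f.attrs["sub_band_width"] = bga.sub_band_width
        f.attrs["config_hash"] = config_hash


def read_bga_h5(path: str | Path, channels: pd.DataFrame) -> BGASeries:
    with h5py.File(path, "r") as f:
        env = f["bga"][()]
        env_fs = float(f["env_fs"][()])
        alignment = float(f["alignment"][()])
        band = tuple(f.attrs["band"])
        width = float(f.attrs["sub_band_width"])
    if env.shape[0] != len(channels):
        raise ValueError(f"{path}: {env.shape[0]} BGA rows vs "
                         f"{len(channels)} channels")
    return BGASeries(envelope=env, env_fs=env_fs, band=band,
                     sub_band_width=width, alignment=alignment,
                     channels=channels)


def write_epochs_h5(path: str | Path, epochs, config_hash: str = "") -> None:
    """Persist an EpochSet tensor with its time axis and retention mask.

    The linked event rows and the exclusion report are tables and travel as
    separate TSVs.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, track_times=False)
        f.create_dataset("times_ms", data=epochs.times_ms, track_times=False)
        f.create_dataset("retained", data=epochs.retained, track_times=False)
        f.create_dataset("env_fs", data=float(epochs.env_fs),
                         track_times=False)
        f.attrs["baseline_corrected"] = bool(epochs.baseline_corrected)
        f.attrs["config_hash"] = config_hash


def read_epochs_h5(path: str | Path, events: pd.DataFrame,
                   channels: pd.DataFrame):
    from .epochs import EpochSet
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        times = f["times_ms"][()]
        retained = f["retained"][()].astype(bool)
        env_fs = float(f["env_fs"][()])
        baseline = bool(f.attrs["baseline_corrected"])
    if data.shape[0] != len(events):
        raise ValueError(f"{path}: {data.shape[0]} epochs vs "
                         f"{len(events)} event rows")
    if data.shape[1] != len(channels):
        raise ValueError(f"{path}: {data.shape[1]} channels vs "
                         f"{len(channels)} channel rows")
    return EpochSet(data=data, times_ms=times, events=events,
                    channels=channels, env_fs=env_fs,
                    baseline_corrected=baseline, retained=retained)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_table(path: str | Path, table: pd.DataFrame,
                config_hash: str = "") -> None:
    """TSV with a comment header carrying the configuration hash."""
    with open(path, "w") as f:
        if config_hash:
            f.write(f"# bgapipe-config-hash: {config_hash}\n")
        table.to_csv(f, sep="\t", index=False, na_rep="n/a",
                     float_format="%.10g")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["n/a"])


def read_events(path: str | Path) -> pd.DataFrame:
    ev = _read_tsv(path)
    missing = [c for c in EVENT_REQUIRED if c not in ev.columns]
    if missing:
        raise ValueError(f"{path}: missing event columns {missing}")
    onsets = ev["onset"].to_numpy(float)
    if np.any(np.diff(onsets) <= 0):
        bad = int(np.flatnonzero(np.diff(onsets) <= 0)[0]) + 1
        raise ValueError(f"{path}: onsets not strictly increasing at row {bad}")
    unknown = set(ev["condition"]) - KNOWN_CONDITIONS
    if unknown:
        row = int(ev.index[ev["condition"].isin(unknown)][0])
        raise ValueError(f"{path}: unknown condition {sorted(unknown)} "
                         f"first at row {row}")
    return ev


def read_channels(path: str | Path) -> pd.DataFrame:
    ch = _read_tsv(path)
    missing = [c for c in CHANNEL_REQUIRED if c not in ch.columns]
    if missing:
        raise ValueError(f"{path}: missing channel columns {missing}")
    for col in ("white_matter", "heterotopic", "epileptic", "seizure_onset"):
        if col in ch.columns:
            ch[col] = ch[col].astype(bool)
    return ch


def read_spikes(path: str | Path) -> pd.DataFrame:
    sp = _read_tsv(path)
    missing = [c for c in SPIKE_REQUIRED if c not in sp.columns]
    if missing:
        raise ValueError(f"{path}: missing spike columns {missing}")
    return sp


def write_json(path: str | Path, payload: dict, config_hash: str = "") -> None:
    body = {"config_hash": config_hash, **payload}
    Path(path).write_text(json.dumps(body, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
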