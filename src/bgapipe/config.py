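"""Pipeline configuration: every analysis tunable in one serializable object.

All times in files are seconds from recording start; epoch-relative times are
milliseconds; sample indices are 0-based; intervals are half-open ``[start, end)``.
"""
from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis parameters with their standard defaults.

    Parameters
    ----------
    band : (low, high) Hz of the broadband gamma range.
    sub_band_width : width of each Hilbert filter-bank sub-band, Hz.
    env_fs : sampling rate of the amplitude envelope, Hz.
    target_fs : raw signals are decimated to this rate before filtering, Hz.
    epoch_window_ms : epoch extent relative to stimulus onset.
    baseline_ms : pre-stimulus interval whose mean is subtracted per epoch.
    q : false discovery rate level for all channel-level tests.
    window_samples : length of the sliding max-p window (samples at ``env_fs``).
    rt_limit_s : responses at or beyond this latency count as too slow.
    block_accuracy : blocks below this accuracy are dropped wholesale.
    late_peak_ms : channels whose mean response peaks later than this *and*
        whose per-trial peaks track reaction time are treated as motor.
    late_rt_corr : peak-time/RT Pearson threshold operationalizing the
        "aligned to the key press" judgment.
    min_patients : minimum distinct patients per region for ChOI inclusion.
    min_trials : minimum retained trials for a channel x condition test.
    n_bins, bin_ms : post-stimulus averaging grid for the binned analysis.
    exact_cutoff : sample size at or below which the signed-rank null
        distribution is enumerated exactly.
    filter_order : order of each Butterworth band-pass (applied forward-backward).
    """

    band: tuple[float, float] = (50.0, 150.0)
    sub_band_width: float = 5.0
    env_fs: float = 64.0
    target_fs: float = 512.0
    epoch_window_ms: tuple[float, float] = (-500.0, 1500.0)
    baseline_ms: tuple[float, float] = (-50.0, 0.0)
    q: float = 0.05
    window_samples: int = 6
    rt_limit_s: float = 3.0
    block_accuracy: float = 0.75
    late_peak_ms: float = 800.0
    late_rt_corr: float = 0.5
    min_patients: int = 3
    min_trials: int = 5
    n_bins: int = 10
    bin_ms: float = 100.0
    exact_cutoff: int = 25
    filter_order: int = 4
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("band", "epoch_window_ms", "baseline_ms"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("band", "epoch_window_ms", "baseline_ms"):
            if key in d:
                d[key] = tuple(float(v) for v in d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        """Short content hash identifying this parameterization in outputs."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha1(canon.encode()).hexdigest()[:12]
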