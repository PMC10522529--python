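"""Synthetic stereo-EEG studies with known ground truth.

Generates the block/session experimental design, per-trial behavior, and raw
multichannel recordings in which condition-dependent broadband-gamma bursts
are injected multiplicatively on a band-limited noise carrier riding on pink
(1/f) background noise.  Every injected parameter is recorded, so the whole
downstream analysis chain can be validated against the truth.

Design layout (defaults): 8 sessions x 3 blocks x 16 trials = 384 trials,
one block per condition per session, 128 images each shown once per
condition.  Trials are 3 s apart (1.5 s stimulus + 1.5 s fixation).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.signal as sps

from .bga import Recording

log = logging.getLogger(__name__)

CONDITIONS = ("control", "egocentric", "allocentric")

#: default per-condition accuracy / mean RT (s), mirroring typical behavior
#: on this task: near-ceiling for the perceptual control, lower and slower
#: for the two spatial judgments.
DEFAULT_ACCURACY = {"control": 0.976, "egocentric": 0.882, "allocentric": 0.868}
DEFAULT_RT_MEAN = {"control": 0.688, "egocentric": 0.885, "allocentric": 0.967}

_IMAGE_TAGS = ("congruent", "allo_3d_eq_2d", "ego_size_rel", "allo_size_rel")

# sub-streams of the master seed, one per operation, so each generator can be
# re-run independently and deterministically
_STREAM_DESIGN, _STREAM_BEHAVIOR, _STREAM_RECORDING, _STREAM_SPIKES = range(4)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters of a simulated recording session."""

    n_sessions: int = 8
    n_blocks_per_session: int = 3
    n_trials_per_block: int = 16
    n_images: int = 128
    conditions: tuple[str, ...] = CONDITIONS
    stimulus_s: float = 1.5
    fixation_s: float = 1.5
    inter_block_gap_s: float = 5.0
    lead_in_s: float = 5.0
    tail_s: float = 5.0
    raw_fs: float = 512.0
    n_contacts_per_electrode: int = 2
    pink_exponent: float = 1.0
    pink_amplitude_uv: float = 15.0
    common_pink_amplitude_uv: float = 20.0
    gamma_amplitude_uv: float = 30.0
    seed: int = 0

    @property
    def trial_s(self) -> float:
        return self.stimulus_s + self.fixation_s

    @property
    def n_trials(self) -> int:
        return self.n_sessions * self.n_blocks_per_session * self.n_trials_per_block

    def validate(self) -> None:
        if min(self.n_sessions, self.n_blocks_per_session,
               self.n_trials_per_block, self.n_images) <= 0:
            raise ValueError("all design counts must be positive")
        if len(self.conditions) != self.n_blocks_per_session:
            raise ValueError(
                "one block per condition per session is required: "
                f"{len(self.conditions)} conditions vs "
                f"{self.n_blocks_per_session} blocks/session")
        if self.n_trials != self.n_images * len(self.conditions):
            raise ValueError(
                f"inconsistent design: {self.n_trials} trials != "
                f"{self.n_images} images x {len(self.conditions)} conditions")
        if self.n_contacts_per_electrode < 2:
            raise ValueError("need >= 2 contacts per electrode for bipolar pairs")


@dataclass(frozen=True)
class ChannelArchetype:
    """Ground-truth response profile of one simulated (bipolar) channel.

    ``gains`` maps condition -> multiplicative gamma-envelope gain at the
    response peak (0.8 means +80 %).  The response ramps 0 -> gain over
    ``rise_ms`` starting ``onset_ms`` after the lock event (stimulus onset,
    or the key press for ``lock='keypress'``), holds until ``duration_ms``
    after the response start, then ramps back down over ``rise_ms``.
    """

    kind: str
    gains: dict = field(default_factory=dict)
    onset_ms: float = 300.0
    rise_ms: float = 100.0
    duration_ms: float = 500.0
    lock: str = "stimulus"
    label: str = "MFG"
    mni: tuple[float, float, float] = (40.0, 10.0, 40.0)
    patient: str = "P01"

    def __post_init__(self):
        if self.duration_ms <= 0 or self.rise_ms < 0:
            raise ValueError("duration must be > 0 and rise >= 0")
        if any(g < 0 for g in self.gains.values()):
            raise ValueError("peak gains must be >= 0")
        if self.lock == "stimulus" and self.onset_ms < 0:
            raise ValueError("stimulus-locked onset must be >= 0")

    # -- factories for the canonical response classes ---------------------
    @classmethod
    def nonresponsive(cls, **kw) -> "ChannelArchetype":
        return cls(kind="nonresponsive", gains={}, **kw)

    @classmethod
    def visual_nonselective(cls, gain: float = 0.8, **kw) -> "ChannelArchetype":
        return cls(kind="visual_nonselective",
                   gains={c: gain for c in CONDITIONS}, **kw)

    @classmethod
    def egocentric_selective(cls, gain: float = 0.8, **kw) -> "ChannelArchetype":
        return cls(kind="egocentric_selective", gains={"egocentric": gain}, **kw)

    @classmethod
    def allocentric_selective(cls, gain: float = 0.8, **kw) -> "ChannelArchetype":
        return cls(kind="allocentric_selective", gains={"allocentric": gain}, **kw)

    @classmethod
    def spatial_selective(cls, gain: float = 0.8, **kw) -> "ChannelArchetype":
        return cls(kind="spatial_selective",
                   gains={"egocentric": gain, "allocentric": gain}, **kw)

    @classmethod
    def late_motor(cls, gain: float = 0.8, onset_ms: float = -100.0,
                   **kw) -> "ChannelArchetype":
        """Response locked to the key press (onset relative to the press)."""
        return cls(kind="late_motor", gains={c: gain for c in CONDITIONS},
                   onset_ms=onset_ms, lock="keypress", **kw)


@dataclass
class GroundTruth:
    """Injected parameters: one row per simulated bipolar channel + the trials."""

    channels: pd.DataFrame
    trials: pd.DataFrame


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def make_design(config: SimConfig) -> pd.DataFrame:
    """Build the trial event table for one simulated study.

    Each session contains one block per condition in seed-driven
    counterbalanced order; each image id occurs exactly once per condition
    over the whole design; binary image-type tags are balanced half/half
    across images.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_DESIGN)
    conds = list(config.conditions)

    # balanced image-type tags, one independent half/half split per tag
    n_img = config.n_images
    tags = {}
    for tag in _IMAGE_TAGS:
        half = np.zeros(n_img, dtype=bool)
        half[: n_img // 2] = True
        tags[tag] = rng.permutation(half)

    # chronological slots per condition receive a permutation of image ids
    image_order = {c: list(rng.permutation(n_img)) for c in conds}

    rows = []
    t = config.lead_in_s
    trial_id = 0
    for sess in range(config.n_sessions):
        order = rng.permutation(len(conds))
        for b, ci in enumerate(order):
            cond = conds[ci]
            block_id = sess * config.n_blocks_per_session + b
            for k in range(config.n_trials_per_block):
                img = image_order[cond].pop(0)
                rows.append({
                    "trial_id": trial_id,
                    "onset": t + k * config.trial_s,
                    "condition": cond,
                    "image_id": int(img),
                    "block_id": block_id,
                    "session_id": sess,
                    **{tag: bool(tags[tag][img]) for tag in _IMAGE_TAGS},
                })
                trial_id += 1
            t += config.n_trials_per_block * config.trial_s + config.inter_block_gap_s
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def simulate_behavior(design: pd.DataFrame,
                      accuracy: dict | None = None,
                      rt_mean: dict | None = None,
                      rt_sigma: float = 0.35,
                      rt_limit_s: float = 3.0,
                      seed: int = 0) -> pd.DataFrame:
    """Add correctness (Bernoulli) and reaction times (lognormal) per trial.

    ``rt_sigma`` is the log-scale spread; the lognormal location is set so
    the per-condition RT mean equals ``rt_mean``.  Responses at or past
    ``rt_limit_s`` are flagged ``too_slow``.
    """
    accuracy = dict(DEFAULT_ACCURACY if accuracy is None else accuracy)
    rt_mean = dict(DEFAULT_RT_MEAN if rt_mean is None else rt_mean)
    for cond in design["condition"].unique():
        if not 0.0 <= accuracy[cond] <= 1.0:
            raise ValueError(f"accuracy for {cond!r} outside [0, 1]")
    rng = _rng(seed, _STREAM_BEHAVIOR)
    out = design.copy()
    n = len(out)
    acc = out["condition"].map(accuracy).to_numpy(float)
    mean = out["condition"].map(rt_mean).to_numpy(float)
    mu = np.log(mean) - rt_sigma ** 2 / 2.0
    out["correct"] = rng.random(n) < acc
    out["rt"] = rng.lognormal(mu, rt_sigma)
    out["too_slow"] = out["rt"] >= rt_limit_s
    out["response_key"] = rng.choice(["left", "right"], size=n)
    return out


# ---------------------------------------------------------------------------
# recording
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                exponent: float, rms: float) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^exponent."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _gamma_carrier(rng: np.random.Generator, n: int, fs: float,
                   band: tuple[float, float], rms: float) -> np.ndarray:
    """Band-limited Gaussian noise carrier for the gamma-range response."""
    if band[1] >= fs / 2.0:
        raise ValueError(f"band edge {band[1]} Hz >= Nyquist {fs / 2.0} Hz")
    sos = sps.butter(2, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    return x * (rms / x.std())


def _gain_profile(design: pd.DataFrame, arch: ChannelArchetype,
                  n: int, fs: float) -> np.ndarray:
    """Trapezoidal multiplicative gain time course for one channel."""
    g = np.zeros(n)
    if not arch.gains:
        return g
    rise = max(arch.rise_ms, 1.0) / 1000.0
    dur = arch.duration_ms / 1000.0
    for _, tr in design.iterrows():
        gain = arch.gains.get(tr["condition"], 0.0)
        if gain == 0.0:
            continue
        if arch.lock == "keypress":
            if "rt" not in tr or not np.isfinite(tr.get("rt", np.nan)):
                raise ValueError("keypress-locked archetypes need trial RTs")
            start = tr["onset"] + tr["rt"] + arch.onset_ms / 1000.0
        else:
            start = tr["onset"] + arch.onset_ms / 1000.0
        t0, t1 = start, start + rise            # up-ramp
        t2, t3 = start + dur, start + dur + rise  # down-ramp
        i0, i3 = int(t0 * fs), min(int(t3 * fs) + 1, n)
        if i0 >= n:
            continue
        t = np.arange(i0, i3) / fs
        ramp_up = np.clip((t - t0) / rise, 0.0, 1.0)
        ramp_down = np.clip((t3 - t) / rise, 0.0, 1.0)
        g[i0:i3] += gain * np.minimum(ramp_up, ramp_down)
    return g


def simulate_recording(design: pd.DataFrame,
                       archetypes: list[ChannelArchetype],
                       config: SimConfig,
                       seed: int | None = None) -> tuple[Recording, GroundTruth]:
    """Synthesize contact-level raw signals for one archetype per electrode.

    Every contact on an electrode shaft shares the shaft's archetype (with an
    independent carrier), so the bipolar derivation cancels the shared pink
    background while retaining the injected envelope modulation.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    fs = config.raw_fs
    if config.gamma_amplitude_uv > 0 and 150.0 >= fs / 2.0:
        raise ValueError("raw_fs must exceed 300 Hz so the gamma band is representable")
    rng = _rng(seed, _STREAM_RECORDING)
    duration = float(design["onset"].max()) + config.trial_s + config.tail_s
    n = int(round(duration * fs))

    n_contacts = config.n_contacts_per_electrode
    sig_rows, ch_rows, gt_rows = [], [], []
    for e, arch in enumerate(archetypes):
        shaft = f"e{e:03d}"
        shared = _pink_noise(rng, n, fs, config.pink_exponent,
                             config.common_pink_amplitude_uv)
        gain = _gain_profile(design, arch, n, fs)
        for c in range(n_contacts):
            own = _pink_noise(rng, n, fs, config.pink_exponent,
                              config.pink_amplitude_uv)
            carrier = _gamma_carrier(rng, n, fs, (50.0, 150.0),
                                     config.gamma_amplitude_uv)
            sig_rows.append(shared + own + carrier * (1.0 + gain))
            ch_rows.append({
                "name": f"{shaft}c{c}", "shaft": shaft, "index": c,
                "mni_x": arch.mni[0], "mni_y": arch.mni[1], "mni_z": arch.mni[2],
                "label": arch.label, "patient": arch.patient,
                "white_matter": False, "heterotopic": False,
                "epileptic": False, "seizure_onset": False,
            })
        for c in range(n_contacts - 1):
            gt_rows.append({
                "channel": f"{shaft}c{c}-{shaft}c{c + 1}",
                "kind": arch.kind,
                **{f"gain_{cond}": arch.gains.get(cond, 0.0)
                   for cond in config.conditions},
                "onset_ms": arch.onset_ms, "rise_ms": arch.rise_ms,
                "duration_ms": arch.duration_ms, "lock": arch.lock,
            })
    recording = Recording(signal=np.asarray(sig_rows), fs=fs,
                          channels=pd.DataFrame(ch_rows))
    truth = GroundTruth(channels=pd.DataFrame(gt_rows), trials=design.copy())
    return recording, truth


# ---------------------------------------------------------------------------
# interictal spike artifacts
# ---------------------------------------------------------------------------

def inject_spikes(recording: Recording, rate_per_min: float,
                  channels: list[str] | None = None,
                  amplitude_uv: float = 300.0,
                  duration_s: float = 0.07,
                  seed: int = 0) -> tuple[Recording, pd.DataFrame]:
    """Add brief high-amplitude biphasic transients at Poisson times.

    Returns a new recording plus the annotation table (channel, onset,
    duration) of every injected event.
    """
    if rate_per_min < 0:
        raise ValueError("spike rate must be >= 0")
    rng = _rng(seed, _STREAM_SPIKES)
    signal = recording.signal.copy()
    names = list(recording.channels["name"])
    targets = names if channels is None else list(channels)
    fs = recording.fs
    n = signal.shape[1]
    dur_samp = max(int(round(duration_s * fs)), 2)
    waveform = amplitude_uv * np.sin(2 * np.pi * np.arange(dur_samp) / dur_samp)
    ann = []
    duration_min = n / fs / 60.0
    for name in targets:
        ch = names.index(name)
        count = rng.poisson(rate_per_min * duration_min)
        onsets = np.sort(rng.uniform(0.0, n / fs - duration_s, size=count))
        for onset in onsets:
            i0 = int(round(onset * fs))
            signal[ch, i0:i0 + dur_samp] += waveform[: n - i0]
            ann.append({"channel": name, "onset": float(onset),
                        "duration": float(duration_s)})
    annotations = pd.DataFrame(ann, columns=["channel", "onset", "duration"])
    out = Recording(signal=signal, fs=fs, channels=recording.channels.copy(),
                    patient_id=recording.patient_id)
    return out, annotations


# ---------------------------------------------------------------------------
# convenience: a complete small study in one call
# ---------------------------------------------------------------------------

def archetype_panel(counts: dict[str, int], gain: float = 0.8,
                    onset_ms: float = 300.0, rise_ms: float = 100.0,
                    duration_ms: float = 500.0,
                    n_patients: int = 6) -> list[ChannelArchetype]:
    """A list of archetypes, ``counts`` kind -> number, patients round-robin."""
    factories = {
        "nonresponsive": ChannelArchetype.nonresponsive,
        "visual_nonselective": ChannelArchetype.visual_nonselective,
        "egocentric_selective": ChannelArchetype.egocentric_selective,
        "allocentric_selective": ChannelArchetype.allocentric_selective,
        "spatial_selective": ChannelArchetype.spatial_selective,
        "late_motor": ChannelArchetype.late_motor,
    }
    panel, i = [], 0
    for kind, count in counts.items():
        make = factories[kind]
        for _ in range(count):
            kw = {"patient": f"P{i % n_patients:02d}"}
            if kind != "nonresponsive":
                if kind != "late_motor":
                    kw.update(onset_ms=onset_ms)
                kw.update(gain=gain)
            arch = make(**kw)
            if kind not in ("nonresponsive",):
                arch = replace(arch, rise_ms=rise_ms, duration_ms=duration_ms)
            panel.append(arch)
            i += 1
    return panel


def small_study_config(trials_per_condition: int = 40,
                       seed: int = 0) -> SimConfig:
    """A reduced design keeping the 8-session x 3-block structure.

    ``trials_per_condition`` must be divisible by 8 (sessions); images are
    reduced to match so each still appears once per condition.
    """
    if trials_per_condition % 8:
        raise ValueError("trials_per_condition must be a multiple of 8")
    per_block = trials_per_condition // 8
    return SimConfig(n_sessions=8, n_blocks_per_session=3,
                     n_trials_per_block=per_block,
                     n_images=trials_per_condition, seed=seed)
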