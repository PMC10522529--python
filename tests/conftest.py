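"""Shared fixtures: synthetic studies reused across test modules.

The two expensive session fixtures (null calibration and archetype
recovery) run the complete raw-signal -> group-statistics chain once and
are shared by the unit and acceptance tests.
"""
from __future__ import annotations

import numpy as np
import pytest

from bgapipe import synthetic as syn
from bgapipe.config import PipelineConfig
from bgapipe.pipeline import analyze

PERFECT_BEHAVIOR = {"control": 1.0, "egocentric": 1.0, "allocentric": 1.0}

ARCHETYPE_EXPECTED_LABEL = {
    "nonresponsive": "nonresponsive",
    "visual_nonselective": "active_nonselective",
    "egocentric_selective": "egocentric_selective",
    "allocentric_selective": "allocentric_selective",
    "spatial_selective": "spatial_selective",
}


def build_study(archetypes, seed, trials_per_condition=40, accuracy=None,
                rt_mean=None, rt_sigma=0.35):
    """Design + behavior + raw recording for a reduced 8-session study."""
    cfg = syn.small_study_config(trials_per_condition, seed=seed)
    design = syn.make_design(cfg)
    events = syn.simulate_behavior(
        design, accuracy=PERFECT_BEHAVIOR if accuracy is None else accuracy,
        rt_mean=rt_mean, rt_sigma=rt_sigma, seed=seed)
    recording, truth = syn.simulate_recording(events, archetypes, cfg,
                                              seed=seed)
    return recording, events, truth


@pytest.fixture(scope="session")
def null_study():
    """200 nonresponsive channels, 40 trials/condition, full pipeline."""
    panel = [syn.ChannelArchetype.nonresponsive(patient=f"P{i % 6:02d}")
             for i in range(200)]
    recording, events, truth = build_study(panel, seed=20)
    bundle = analyze(recording, events, PipelineConfig(), bipolar=True)
    return {"bundle": bundle, "truth": truth, "events": events}


@pytest.fixture(scope="session")
def recovery_study():
    """80 channels, 16 per response archetype, peak gain 0.8, onset 300 ms."""
    counts = {kind: 16 for kind in ARCHETYPE_EXPECTED_LABEL}
    panel = syn.archetype_panel(counts, gain=0.8, onset_ms=300.0)
    recording, events, truth = build_study(panel, seed=21)
    bundle = analyze(recording, events, PipelineConfig(), bipolar=True)
    results = bundle["results"].merge(truth.channels, on="channel")
    results["expected"] = results["kind"].map(ARCHETYPE_EXPECTED_LABEL)
    return {"bundle": bundle, "truth": truth, "events": events,
            "results": results}


@pytest.fixture(scope="session")
def late_motor_study():
    """One key-press-locked channel; key presses around 1 s with a modest
    spread so the motor response stays inside the epoch window."""
    panel = [syn.ChannelArchetype.late_motor(0.8)]
    recording, events, truth = build_study(
        panel, seed=23, trials_per_condition=24,
        rt_mean={"control": 1.0, "egocentric": 1.0, "allocentric": 1.0},
        rt_sigma=0.2)
    bundle = analyze(recording, events, PipelineConfig(), bipolar=True)
    return {"bundle": bundle, "truth": truth, "events": events}


@pytest.fixture(scope="session")
def single_ego_study():
    """One egocentric-selective channel (+80 % at 300 ms), 40 trials/cond."""
    panel = [syn.ChannelArchetype.egocentric_selective(0.8)]
    recording, events, truth = build_study(panel, seed=22)
    bundle = analyze(recording, events, PipelineConfig(), bipolar=True)
    return {"bundle": bundle, "truth": truth, "events": events}
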