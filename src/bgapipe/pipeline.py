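"""End-to-end orchestration: raw recording -> group statistics.

``analyze`` chains every stage in memory; ``run_pipeline`` additionally
persists each stage's outputs (and the exclusion ledger) under an output
directory.  With a fixed configuration the outputs are byte-identical
across runs.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import channel_stats as cs
from . import group_stats as gs
from . import io as bio
from . import latency
from .bga import Recording, bga_envelope, bipolar_derive, resample_raw
from .config import PipelineConfig
from .epochs import baseline_correct, exclude_trials, extract_epochs

log = logging.getLogger(__name__)


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") \
                    from exc
        return wrapper
    return deco


def analyze(recording: Recording, events: pd.DataFrame,
            config: PipelineConfig | None = None,
            spikes: pd.DataFrame | None = None,
            bipolar: bool = True) -> dict:
    """Run the full analysis chain and return the results bundle.

    Stages: resample -> bipolar derivation -> BGA envelope -> epoching ->
    baseline correction -> exclusions -> activity detection -> condition
    contrasts -> selectivity classification -> late-response filter -> ROI
    assignment -> channels of interest -> latency metrics -> group stats.
    Set ``bipolar=False`` when the recording already is a bipolar montage.
    """
    cfg = config or PipelineConfig()
    rec = _stage("resample")(resample_raw)(recording, cfg.target_fs)
    if bipolar:
        rec = _stage("bipolar")(bipolar_derive)(rec)
    bga = _stage("bga")(bga_envelope)(
        rec, band=cfg.band, sub_band_width=cfg.sub_band_width,
        env_fs=cfg.env_fs, filter_order=cfg.filter_order)
    ep = _stage("epoch")(extract_epochs)(bga, events, cfg.epoch_window_ms)
    ep = _stage("baseline")(baseline_correct)(ep, cfg.baseline_ms)
    ep = _stage("exclude")(exclude_trials)(ep, spikes, cfg.rt_limit_s,
                                           cfg.block_accuracy)

    active, act_series = _stage("detect_active")(cs.detect_active)(
        ep, q=cfg.q, window=cfg.window_samples, min_trials=cfg.min_trials,
        exact_cutoff=cfg.exact_cutoff)
    contrasts = _stage("contrast")(cs.contrast_conditions)(
        ep, active, q=cfg.q, window=cfg.window_samples,
        min_pairs=cfg.min_trials, exact_cutoff=cfg.exact_cutoff)
    late = _stage("late_filter")(cs.filter_late_response)(
        ep, peak_after_ms=cfg.late_peak_ms, rt_corr_thresh=cfg.late_rt_corr)
    rois = _stage("roi")(cs.assign_roi)(ep.channels)

    names = list(ep.channels["name"])
    rows = []
    for c, name in enumerate(names):
        flags = ep.channels.iloc[c]
        keep_late = bool(late.loc[late["channel"] == name, "keep"].iloc[0])
        excluded_anatomy = bool(flags.get("white_matter", False)
                                or flags.get("heterotopic", False))
        if active[c] and keep_late and not excluded_anatomy:
            per_channel = {pair: s for (n, pair), s in contrasts.items()
                           if n == name}
            label, evidence = cs.classify_selectivity(per_channel)
        else:
            label, evidence = "nonresponsive", {}
            if active[c]:
                label = "excluded"  # active but late/anatomy-filtered
        rows.append({
            "channel": name, "patient": flags.get("patient"),
            "roi": rois["roi"].iloc[c], "active": bool(active[c]),
            "keep_late": keep_late, "label": label,
            **{f"ev_{k}": v for k, v in evidence.items()},
        })
    results = cs.require_min_patients(pd.DataFrame(rows), cfg.min_patients)

    metrics = _stage("metrics")(latency.channel_condition_metrics)(
        ep, act_series, bin_ms=cfg.bin_ms, n_bins=cfg.n_bins)
    metrics = metrics.merge(results[["channel", "patient", "roi", "label",
                                     "choi"]], on="channel", how="left")

    group = _group_statistics(results, metrics, cfg)
    return {"config": cfg, "bga": bga, "epochs": ep, "active": active,
            "activity_series": act_series, "contrasts": contrasts,
            "results": results, "metrics": metrics, "late": late, **group}


def _group_statistics(results: pd.DataFrame, metrics: pd.DataFrame,
                      cfg: PipelineConfig) -> dict:
    """ChOI-level chi-squared, mixed ANOVAs and time of discrimination.

    Each test needs enough populated ROIs; with a too-small study the entry
    is left empty and the reason logged.
    """
    out = {"chi2": None, "anova_magnitude": None, "anova_bins": None,
           "discrimination": None}
    choi = results[results["choi"]]
    if choi.empty or choi["roi"].nunique() < 2:
        log.warning("too few channels of interest for group statistics")
        return out
    counts = pd.crosstab(choi["roi"], choi["label"])
    try:
        out["chi2"] = gs.chi2_proportions(counts)
    except ValueError as exc:
        log.warning("chi-squared skipped: %s", exc)
    m = metrics[metrics["choi"].fillna(False)]
    try:
        out["anova_magnitude"] = gs.mixed_anova_2way(
            m, dv="magnitude", within="condition", between="roi",
            subject="channel")
    except Exception as exc:
        log.warning("magnitude ANOVA skipped: %s", exc)
    try:
        long = m.melt(id_vars=["channel", "condition", "roi"],
                      value_vars=[f"bin_{k}" for k in range(cfg.n_bins)],
                      var_name="bin", value_name="value")
        long["bin"] = long["bin"].str.removeprefix("bin_").astype(int)
        out["anova_bins"] = gs.mixed_anova_3way(
            long, dv="value", within=("condition", "bin"), between="roi",
            subject="channel")
        out["discrimination"] = gs.time_of_discrimination(
            out["anova_bins"].posthoc, alpha=0.05, bin_ms=cfg.bin_ms)
    except Exception as exc:
        log.warning("binned ANOVA skipped: %s", exc)
    return out


def run_pipeline(recording: Recording, events: pd.DataFrame,
                 out_dir: str | Path,
                 config: PipelineConfig | None = None,
                 spikes: pd.DataFrame | None = None,
                 bipolar: bool = True) -> dict:
    """``analyze`` + persist every stage's outputs under ``out_dir``."""
    cfg = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h = cfg.hash()
    bundle = analyze(recording, events, cfg, spikes, bipolar=bipolar)

    cfg.to_yaml(out_dir / "config.yaml")
    bio.write_bga_h5(out_dir / "bga.h5", bundle["bga"], h)
    ep = bundle["epochs"]
    bio.write_table(out_dir / "exclusions.tsv", ep.exclusion_report, h)
    bio.write_table(out_dir / "channel_results.tsv", bundle["results"], h)
    bio.write_table(out_dir / "metrics.tsv", bundle["metrics"], h)
    bio.write_table(out_dir / "late_response.tsv", bundle["late"], h)
    if bundle["anova_magnitude"] is not None:
        bio.write_table(out_dir / "anova_magnitude.tsv",
                        bundle["anova_magnitude"].table, h)
        bio.write_table(out_dir / "anova_magnitude_posthoc.tsv",
                        bundle["anova_magnitude"].posthoc, h)
    if bundle["anova_bins"] is not None:
        bio.write_table(out_dir / "anova_bins.tsv",
                        bundle["anova_bins"].table, h)
    summary = {
        "n_channels": int(ep.n_channels),
        "n_trials": int(ep.n_trials),
        "n_active": int(np.sum(bundle["active"])),
        "n_choi": int(bundle["results"]["choi"].sum()),
        "labels": bundle["results"]["label"].value_counts().to_dict(),
    }
    if bundle["chi2"] is not None:
        c2 = bundle["chi2"]
        summary["chi2"] = {"statistic": c2.statistic, "df": c2.df,
                           "n": c2.n, "p": c2.p}
    if bundle["discrimination"] is not None:
        summary["time_of_discrimination"] = (
            bundle["discrimination"].to_dict(orient="records"))
    bio.write_json(out_dir / "summary.json", summary, h)
    return bundle
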