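"""Channel-level inference: activity detection, condition contrasts,
selectivity classification, late-response filtering, and ROI assignment.

Activity is tested per channel and condition by a paired Wilcoxon signed-rank
between each trial's pre-stimulus mean ([-500, 0) ms) and its BGA value at
every post-stimulus sample.  As a conservative adjustment, each sample's
p-value is replaced by the largest p within a six-sample (93.75 ms) forward
window before Benjamini-Hochberg FDR control across the time samples.  A
channel is active if any sample survives for any condition.

Between-condition contrasts pair trials by image id (each image occurs once
per condition), run the same windowed signed-rank machinery, and pool the
FDR family across all active channels, time samples, and the four contrasts
(allo vs ego, ego vs allo, allo vs control, ego vs control).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

log = logging.getLogger(__name__)

SELECTIVE_LABELS = ("egocentric_selective", "allocentric_selective",
                    "spatial_selective")

CONTRASTS = (("allocentric", "egocentric"),
             ("egocentric", "allocentric"),
             ("allocentric", "control"),
             ("egocentric", "control"))


@dataclass
class SignificanceSeries:
    """Per-sample test results for one channel and one comparison.

    ``direction[t]`` is the sign of the median paired difference (first
    operand minus second) at sample ``t``.
    """

    channel: str
    comparison: tuple
    times_ms: np.ndarray
    p_raw: np.ndarray
    p_windowed: np.ndarray
    reject: np.ndarray
    direction: np.ndarray


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(diffs, exact_cutoff: int = 25) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are discarded before ranking, ties are mid-ranked.  For
    n <= ``exact_cutoff`` the null distribution of the positive-rank sum is
    enumerated exactly (valid under ties); larger samples use the normal
    approximation with continuity and tie corrections.  All-zero input is the
    degenerate case and returns p = 1.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= exact_cutoff:
        return _exact_signed_rank_p(ranks, w)
    return _approx_signed_rank_p(ranks, w, n)


def _exact_signed_rank_p(ranks: np.ndarray, w: float) -> float:
    # work on doubled ranks so mid-ranks become integers
    r2 = np.round(2.0 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        dist[r:] = dist[r:] + dist[:-r]
    dist /= dist.sum()
    w2 = int(round(2.0 * w))
    cdf = dist[: w2 + 1].sum()
    sf = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def _approx_signed_rank_p(ranks: np.ndarray, w: float, n: int) -> float:
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= float((counts ** 3 - counts).sum()) / 48.0
    if var <= 0:
        return 1.0
    d = w - mu
    z = (d - 0.5 * np.sign(d)) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def sliding_window_max_p(p_raw: np.ndarray, window: int = 6) -> np.ndarray:
    """Replace each p with the max over the forward window [t, t + w - 1].

    The window is truncated at the end of the series, so the output has the
    same length.  At 64 Hz a six-sample window spans 93.75 ms.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.size < window:
        raise ValueError(f"series of {p.size} samples shorter than the "
                         f"{window}-sample window")
    padded = np.concatenate([p, np.full(window - 1, -np.inf)])
    return sliding_window_view(padded, window).max(axis=1)


def fdr_adjust(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: boolean rejection mask, same shape."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    flat = p.ravel()
    m = flat.size
    order = np.argsort(flat, kind="stable")
    thresh = (np.arange(1, m + 1) / m) * q
    below = flat[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.flatnonzero(below)[-1])
        reject[order[: k + 1]] = True
    return reject.reshape(p.shape)


# ---------------------------------------------------------------------------
# activity detection
# ---------------------------------------------------------------------------

def _paired_p_series(diffs: np.ndarray, exact_cutoff: int) -> np.ndarray:
    return np.array([wilcoxon_signed_rank(diffs[:, j], exact_cutoff)
                     for j in range(diffs.shape[1])])


def detect_active(epochs, q: float = 0.05, window: int = 6,
                  min_trials: int = 5, exact_cutoff: int = 25,
                  conditions: tuple[str, ...] | None = None
                  ) -> tuple[np.ndarray, dict]:
    """Flag channels with a significant post-stimulus response vs baseline.

    Returns ``(active, series)`` where ``active`` is a boolean per channel
    and ``series[(channel_name, condition)]`` holds the SignificanceSeries
    of each tested condition.  The FDR family is the post-stimulus time
    samples of one channel x condition.
    """
    if conditions is None:
        conditions = tuple(pd.unique(epochs.events["condition"]))
    pre = epochs.times_ms < 0
    post = epochs.times_ms >= 0
    times_post = epochs.times_ms[post]
    names = list(epochs.channels["name"])
    active = np.zeros(epochs.n_channels, dtype=bool)
    series: dict = {}
    for c in range(epochs.n_channels):
        for cond in conditions:
            idx = epochs.condition_trials(cond, c)
            if idx.size < min_trials:
                log.warning("channel %s condition %s: %d retained trials "
                            "< %d; skipped", names[c], cond, idx.size,
                            min_trials)
                continue
            x = epochs.data[idx, c]
            diffs = x[:, post] - x[:, pre].mean(axis=1, keepdims=True)
            p_raw = _paired_p_series(diffs, exact_cutoff)
            p_win = sliding_window_max_p(p_raw, window)
            reject = fdr_adjust(p_win, q)
            direction = np.sign(np.median(diffs, axis=0))
            series[(names[c], cond)] = SignificanceSeries(
                channel=names[c], comparison=("baseline", cond),
                times_ms=times_post, p_raw=p_raw, p_windowed=p_win,
                reject=reject, direction=direction)
            if reject.any():
                active[c] = True
    return active, series


# ---------------------------------------------------------------------------
# condition contrasts and selectivity
# ---------------------------------------------------------------------------

def contrast_conditions(epochs, active: np.ndarray, q: float = 0.05,
                        window: int = 6, min_pairs: int = 5,
                        exact_cutoff: int = 25,
                        contrasts: tuple = CONTRASTS) -> dict:
    """Image-paired signed-rank contrasts on every active channel.

    The FDR family pools the windowed p-values of all active channels, all
    post-stimulus samples, and all listed contrasts into one correction.
    """
    post = epochs.times_ms >= 0
    times_post = epochs.times_ms[post]
    names = list(epochs.channels["name"])
    ev = epochs.events
    pending: list[tuple] = []
    for c in np.flatnonzero(active):
        for (a, b) in contrasts:
            ia = epochs.condition_trials(a, c)
            ib = epochs.condition_trials(b, c)
            img_a = dict(zip(ev["image_id"].iloc[ia], ia))
            img_b = dict(zip(ev["image_id"].iloc[ib], ib))
            shared = sorted(set(img_a) & set(img_b))
            if len(shared) < min_pairs:
                log.warning("channel %s contrast %s vs %s: %d matched image "
                            "pairs < %d; undefined", names[c], a, b,
                            len(shared), min_pairs)
                continue
            xa = epochs.data[[img_a[i] for i in shared]][:, c][:, post]
            xb = epochs.data[[img_b[i] for i in shared]][:, c][:, post]
            diffs = xa - xb
            p_raw = _paired_p_series(diffs, exact_cutoff)
            p_win = sliding_window_max_p(p_raw, window)
            direction = np.sign(np.median(diffs, axis=0))
            pending.append((names[c], (a, b), p_raw, p_win, direction))
    if not pending:
        return {}
    pooled = np.concatenate([p_win for *_, p_win, _ in pending])
    reject_all = fdr_adjust(pooled, q)
    out: dict = {}
    pos = 0
    for name, pair, p_raw, p_win, direction in pending:
        rej = reject_all[pos: pos + p_win.size]
        pos += p_win.size
        out[(name, pair)] = SignificanceSeries(
            channel=name, comparison=pair, times_ms=times_post,
            p_raw=p_raw, p_windowed=p_win, reject=rej, direction=direction)
    return out


def classify_selectivity(channel_contrasts: dict) -> tuple[str, dict]:
    """Assign one selectivity label from the four contrast series.

    ``channel_contrasts`` maps ``(condA, condB)`` -> SignificanceSeries for
    a single active channel.  A significant direct allocentric-vs-egocentric
    contrast dominates the indirect vs-control route; a channel whose
    responses to both spatial conditions exceed the control is
    spatial-selective; no surviving contrast means active-but-nonselective.
    """
    def fired_gt(pair):
        s = channel_contrasts.get(pair)
        if s is None:
            return np.zeros(0, dtype=bool)
        return s.reject & (s.direction > 0)

    def fired_any(pair):
        s = channel_contrasts.get(pair)
        return s.reject if s is not None else np.zeros(0, dtype=bool)

    allo_gt_ego = fired_gt(("allocentric", "egocentric"))
    ego_gt_allo = fired_gt(("egocentric", "allocentric"))
    allo_gt_ctrl = fired_gt(("allocentric", "control"))
    ego_gt_ctrl = fired_gt(("egocentric", "control"))
    evidence = {
        "allo_gt_ego": bool(allo_gt_ego.any()),
        "ego_gt_allo": bool(ego_gt_allo.any()),
        "allo_gt_ctrl": bool(allo_gt_ctrl.any()),
        "ego_gt_ctrl": bool(ego_gt_ctrl.any()),
        "allo_ne_ctrl": bool(fired_any(("allocentric", "control")).any()),
        "ego_ne_ctrl": bool(fired_any(("egocentric", "control")).any()),
    }
    if evidence["allo_gt_ego"] and evidence["ego_gt_allo"]:
        first_allo = int(np.flatnonzero(allo_gt_ego)[0])
        first_ego = int(np.flatnonzero(ego_gt_allo)[0])
        log.warning("contradictory direct contrast directions; labeling by "
                    "the earlier significant sample")
        label = ("allocentric_selective" if first_allo <= first_ego
                 else "egocentric_selective")
    elif evidence["allo_gt_ego"]:
        label = "allocentric_selective"
    elif evidence["ego_gt_allo"]:
        label = "egocentric_selective"
    elif evidence["allo_gt_ctrl"] and evidence["ego_gt_ctrl"]:
        label = "spatial_selective"
    elif evidence["allo_gt_ctrl"] and not evidence["ego_ne_ctrl"]:
        label = "allocentric_selective"
    elif evidence["ego_gt_ctrl"] and not evidence["allo_ne_ctrl"]:
        label = "egocentric_selective"
    else:
        label = "active_nonselective"
    return label, evidence


# ---------------------------------------------------------------------------
# late/motor responses
# ---------------------------------------------------------------------------

def filter_late_response(epochs, peak_after_ms: float = 800.0,
                         rt_corr_thresh: float = 0.5) -> pd.DataFrame:
    """Drop channels whose response is key-press- rather than stimulus-locked.

    A channel is dropped iff its trial-averaged BGA peaks later than
    ``peak_after_ms`` *and* its per-trial peak times correlate with reaction
    time beyond ``rt_corr_thresh`` (the operationalization of "aligned to
    the key press" on the single-epoch plot).
    """
    post = epochs.times_ms >= 0
    times_post = epochs.times_ms[post]
    rt = epochs.events.get("rt")
    rows = []
    for c, name in enumerate(epochs.channels["name"]):
        idx = np.flatnonzero(epochs.retained[:, c])
        if idx.size == 0:
            rows.append({"channel": name, "keep": True, "peak_ms": np.nan,
                         "rt_corr": np.nan})
            continue
        x = epochs.data[idx][:, c][:, post]
        mean_peak = float(times_post[int(np.argmax(x.mean(axis=0)))])
        corr = np.nan
        if rt is not None:
            rts = rt.to_numpy(float)[idx]
            ok = np.isfinite(rts)
            trial_peaks = times_post[np.argmax(x, axis=1)]
            if ok.sum() >= 3 and np.std(trial_peaks[ok]) > 0 \
                    and np.std(rts[ok]) > 0:
                corr = float(np.corrcoef(trial_peaks[ok], rts[ok])[0, 1])
        drop = mean_peak > peak_after_ms and np.isfinite(corr) \
            and corr > rt_corr_thresh
        rows.append({"channel": name, "keep": not drop, "peak_ms": mean_peak,
                     "rt_corr": corr})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# anatomical grouping
# ---------------------------------------------------------------------------

#: anatomical label -> region of interest (frontal MFG/SFG split handled below)
_ROI_TABLE = {
    "MOG": "OC", "TOTZ": "OC", "CUN": "OC",
    "LG": "mTempO", "FuG": "mTempO", "LPHT": "mTempO",
    "ITG": "LTC", "MTG": "LTC", "STG": "LTC",
    "AngG": "IPS", "SPL": "IPS",
    "SMG": "SMG",
    "IFG": "IFG",
    "INS": "AIC",
    "PreG": "Precentr",
}

_FRONTAL_SPLIT = {"MFG", "SFG"}  # posterior (y < 20) -> Precentr, else Afront


def assign_roi(channels: pd.DataFrame) -> pd.DataFrame:
    """Map anatomical labels (plus the MNI y split for MFG/SFG) to ROIs.

    Labels outside the nine regions (hippocampus, temporal pole, ...) map to
    ``unassigned``.  A y coordinate exactly at 20 goes to the posterior
    region (the split uses strict inequalities on either side).
    """
    rows = []
    for _, ch in channels.iterrows():
        label = ch.get("label")
        y = ch.get("mni_y", np.nan)
        if label in _FRONTAL_SPLIT:
            if y is None or not np.isfinite(y):
                log.warning("channel %s: %s without MNI y; unassigned",
                            ch.get("name"), label)
                roi, rule = "unassigned", f"{label} missing y"
            elif y > 20:
                roi, rule = "Afront", f"{label}, y={y:g} > 20"
            else:
                roi, rule = "Precentr", f"{label}, y={y:g} <= 20"
        elif label in _ROI_TABLE:
            roi, rule = _ROI_TABLE[label], str(label)
        else:
            roi, rule = "unassigned", f"label {label!r} outside ROI set"
        rows.append({"channel": ch.get("name"), "roi": roi, "rule": rule})
    return pd.DataFrame(rows)


def require_min_patients(results: pd.DataFrame,
                         min_patients: int = 3) -> pd.DataFrame:
    """Mark channels of interest: condition-selective channels whose ROI has
    condition-selective channels from at least ``min_patients`` patients.

    ``results`` needs columns ``roi``, ``label`` and ``patient``; a boolean
    ``choi`` column (with a ``choi_reason`` for exclusions) is added.
    """
    out = results.copy()
    selective = out["label"].isin(SELECTIVE_LABELS)
    ok_roi = {}
    for roi, grp in out[selective & (out["roi"] != "unassigned")].groupby("roi"):
        ok_roi[roi] = grp["patient"].nunique() >= min_patients
    choi, reason = [], []
    for _, row in out.iterrows():
        if row["label"] not in SELECTIVE_LABELS:
            choi.append(False)
            reason.append("not condition-selective")
        elif row["roi"] == "unassigned":
            choi.append(False)
            reason.append("no ROI")
        elif not ok_roi.get(row["roi"], False):
            choi.append(False)
            reason.append(f"ROI {row['roi']} below {min_patients} patients")
        else:
            choi.append(True)
            reason.append("")
    out["choi"] = choi
    out["choi_reason"] = reason
    return out
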