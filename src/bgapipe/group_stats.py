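"""Group-level inference.

Mixed-design (split-plot) ANOVAs are computed with the univariate
repeated-measures approach: for each within-subject effect, the complete
within-cell data of every unit (channel, or subject for behavior) are
projected onto an orthonormal contrast basis spanning that effect, and the
contrast scores are analyzed against the group (ROI) structure in that
error stratum.  With balanced groups this reproduces the textbook split-plot
sums of squares exactly; with unbalanced groups the within-effect hypotheses
are tested on unweighted group means (Type III convention).  No sphericity
correction is applied by default, matching the integer degrees of freedom
convention of the channel-level literature; Greenhouse-Geisser is available
behind a flag.

Degrees of freedom (N units, r groups, within factors with c and b levels):

====================  ==========================  =====================
effect                df1                         df2
====================  ==========================  =====================
between (ROI)         r - 1                       N - r
within (Condition)    c - 1                       (c - 1)(N - r)
interaction C x ROI   (c - 1)(r - 1)              (c - 1)(N - r)
C x B x ROI           (c - 1)(b - 1)(r - 1)       (c - 1)(b - 1)(N - r)
====================  ==========================  =====================

Tukey HSD post hoc p-values come from the studentized range distribution
using the error stratum relevant to each comparison family.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class Chi2Result:
    statistic: float
    df: int
    n: int
    p: float


@dataclass
class AnovaTable:
    """Effect table plus Tukey post hoc contrasts."""

    table: pd.DataFrame
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)
    strata: dict = field(default_factory=dict)

    def effect(self, name: str) -> pd.Series:
        match = self.table[self.table["effect"] == name]
        if match.empty:
            raise KeyError(f"no effect named {name!r}")
        return match.iloc[0]


# ---------------------------------------------------------------------------
# chi-squared test of selectivity proportions
# ---------------------------------------------------------------------------

def chi2_proportions(counts: pd.DataFrame) -> Chi2Result:
    """Pearson chi-squared on an ROI x selectivity-label contingency table.

    All-zero rows or columns are dropped with a warning before testing.
    """
    t = counts.to_numpy(dtype=float)
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("counts must be nonnegative integers")
    keep_r = t.sum(axis=1) > 0
    keep_c = t.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        log.warning("dropping %d all-zero rows and %d all-zero columns",
                    int((~keep_r).sum()), int((~keep_c).sum()))
        t = t[keep_r][:, keep_c]
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return Chi2Result(statistic=float(stat), df=int(df), n=int(t.sum()),
                      p=float(p))


# ---------------------------------------------------------------------------
# split-plot machinery
# ---------------------------------------------------------------------------

def _helmert(k: int) -> np.ndarray:
    """k x (k-1) orthonormal contrast basis orthogonal to the unit vector."""
    h = np.zeros((k, k - 1))
    for j in range(1, k):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
        h[:, j - 1] /= np.sqrt(j * (j + 1))
    return h


def _effect_contrast(levels: tuple[int, ...], subset: tuple[bool, ...]
                     ) -> np.ndarray:
    """Kronecker contrast over within factors (mean weights off-effect)."""
    mats = [(_helmert(k) if inc else np.full((k, 1), 1.0 / k))
            for k, inc in zip(levels, subset)]
    c = mats[0]
    for m in mats[1:]:
        c = np.kron(c, m)
    return c


def _gg_epsilon(z: np.ndarray, groups: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from group-centered contrast scores."""
    glabels, ginv = np.unique(groups, return_inverse=True)
    resid = z.copy()
    for g in range(len(glabels)):
        resid[ginv == g] -= z[ginv == g].mean(axis=0)
    s = resid.T @ resid
    q = s.shape[0]
    tr = np.trace(s)
    return float(tr ** 2 / (q * (s * s).sum())) if (s * s).sum() > 0 else 1.0


def split_plot_anova(y: np.ndarray, groups: np.ndarray,
                     within_names: tuple[str, ...],
                     between_name: str = "ROI",
                     gg_correction: bool = False) -> AnovaTable:
    """Mixed ANOVA on ``y`` of shape (N units, l1, l2, ...).

    ``groups`` assigns each unit to a between-subject group; pass a constant
    array for a purely within design.  Returns the effect table plus the
    error strata needed for post hoc tests.
    """
    y = np.asarray(y, dtype=float)
    n_units = y.shape[0]
    levels = y.shape[1:]
    if len(levels) != len(within_names):
        raise ValueError("within_names must match the trailing axes of y")
    groups = np.asarray(groups)
    glabels, ginv = np.unique(groups, return_inverse=True)
    r = len(glabels)
    n_g = np.bincount(ginv).astype(float)
    rows, strata = [], {}

    # between-units stratum on unit means
    m = y.reshape(n_units, -1).mean(axis=1)
    gmeans = np.array([m[ginv == g].mean() for g in range(r)])
    ss_s = float(sum(((m[ginv == g] - gmeans[g]) ** 2).sum() for g in range(r)))
    df_s = n_units - r
    strata["between"] = {"ms_error": ss_s / df_s if df_s else np.nan,
                         "df_error": df_s, "n_g": n_g, "group_means": gmeans,
                         "groups": glabels}
    if r > 1:
        grand_w = m.mean()
        ss_a = float((n_g * (gmeans - grand_w) ** 2).sum())
        f_a = _safe_f(ss_a / (r - 1), ss_s / df_s)
        rows.append({"effect": between_name, "F": f_a, "df1": r - 1,
                     "df2": df_s, "p": float(stats.f.sf(f_a, r - 1, df_s)),
                     "ss": ss_a})

    flat = y.reshape(n_units, -1)
    for subset in itertools.product([False, True], repeat=len(levels)):
        if not any(subset):
            continue
        c = _effect_contrast(levels, subset)
        z = flat @ c
        q = z.shape[1]
        bg = np.array([z[ginv == g].mean(axis=0) for g in range(r)])
        resid = z - bg[ginv]
        ss_e = float((resid ** 2).sum())
        df_e = q * (n_units - r)
        eps = _gg_epsilon(z, groups) if gg_correction else 1.0
        name = " x ".join(n for n, inc in zip(within_names, subset) if inc)
        strata[name] = {"ms_error": ss_e / df_e if df_e else np.nan,
                        "df_error": df_e, "n_g": n_g, "groups": glabels,
                        "epsilon": eps}
        # within effect: unweighted mean of group means (Type III)
        u = bg.mean(axis=0)
        c_u = float((1.0 / n_g).sum()) / r ** 2
        ss_w = float(u @ u) / c_u
        f_w = _safe_f(ss_w / q, ss_e / df_e)
        rows.append({"effect": name, "F": f_w, "df1": q, "df2": df_e,
                     "p": float(stats.f.sf(f_w, q * eps, df_e * eps)),
                     "ss": ss_w})
        if r > 1:
            zbar_w = (n_g @ bg) / n_units
            ss_int = float((n_g[:, None] * (bg - zbar_w) ** 2).sum())
            df_int = q * (r - 1)
            f_int = _safe_f(ss_int / df_int, ss_e / df_e)
            rows.append({"effect": f"{name} x {between_name}", "F": f_int,
                         "df1": df_int, "df2": df_e,
                         "p": float(stats.f.sf(f_int, df_int * eps,
                                               df_e * eps)),
                         "ss": ss_int})
    return AnovaTable(table=pd.DataFrame(rows), strata=strata)


def _safe_f(ms_effect: float, ms_error: float) -> float:
    """F statistic with the degenerate zero-variance cases pinned down."""
    if ms_error <= 0:
        return 0.0 if ms_effect <= 0 else np.inf
    return ms_effect / ms_error


def _tukey_p(diff: float, se: float, k: int, df: float) -> float:
    if se <= 0 or df <= 0:
        return np.nan
    return float(stats.studentized_range.sf(abs(diff) / se, k, df))


def _pairwise(means: dict, n: dict, ms_error: float, df: float,
              family: str, extra: dict | None = None,
              paired_n: float | None = None) -> list[dict]:
    """Tukey(-Kramer) contrasts among ``means``; ``paired_n`` for repeated
    (within-unit) comparisons where every mean rests on the same units."""
    keys = list(means)
    out = []
    for a, b in itertools.combinations(keys, 2):
        if paired_n is not None:
            se = np.sqrt(ms_error / paired_n)
        else:
            se = np.sqrt(ms_error / 2.0 * (1.0 / n[a] + 1.0 / n[b]))
        diff = means[a] - means[b]
        row = {"level_a": a, "level_b": b, "diff": float(diff),
               "p": _tukey_p(diff, se, len(keys), df), "family": family}
        if extra:
            row.update(extra)
        out.append(row)
    return out


# ---------------------------------------------------------------------------
# public ANOVA interfaces
# ---------------------------------------------------------------------------

def rm_anova_behavior(data: pd.DataFrame, dv: str = "value",
                      within: str = "condition",
                      subject: str = "subject") -> AnovaTable:
    """One-way repeated-measures ANOVA with Tukey HSD on condition means.

    Subjects with missing cells are removed listwise (logged).
    """
    wide = data.pivot(index=subject, columns=within, values=dv)
    complete = wide.dropna()
    if len(complete) < len(wide):
        log.warning("dropped %d subjects with incomplete cells",
                    len(wide) - len(complete))
    y = complete.to_numpy()
    res = split_plot_anova(y, np.zeros(len(complete)), (within,))
    st = res.strata[within]
    means = dict(zip(complete.columns, y.mean(axis=0)))
    res.posthoc = pd.DataFrame(_pairwise(
        means, {}, st["ms_error"], st["df_error"], family=within,
        paired_n=len(complete)))
    return res


def _pivot_mixed(data, dv, within, between, subject):
    cols = [within] if isinstance(within, str) else list(within)
    wide = data.pivot_table(index=subject, columns=cols, values=dv,
                            aggfunc="mean")
    wide = wide.sort_index(axis=1)
    complete = wide.dropna()
    if len(complete) < len(wide):
        log.warning("listwise drop of %d units with incomplete cells",
                    len(wide) - len(complete))
    gmap = data.drop_duplicates(subject).set_index(subject)[between]
    groups = gmap.loc[complete.index].to_numpy()
    counts = pd.Series(groups).value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        log.warning("excluding groups with a single unit: %s", bad)
        keep = ~pd.Series(groups).isin(bad).to_numpy()
        complete, groups = complete[keep], groups[keep]
    return complete, groups


def mixed_anova_2way(data: pd.DataFrame, dv: str = "value",
                     within: str = "condition", between: str = "roi",
                     subject: str = "channel",
                     gg_correction: bool = False) -> AnovaTable:
    """Two-way mixed ANOVA (within Condition, between ROI; unit = channel).

    Channels missing any condition are dropped listwise, which is what
    shrinks the error df for metrics like onset latency where some cells are
    undefined.  Post hoc Tukey families: condition means (paired), ROI means
    (Tukey-Kramer on unit means), and condition pairs within each ROI.
    """
    complete, groups = _pivot_mixed(data, dv, within, between, subject)
    y = complete.to_numpy()
    res = split_plot_anova(y, groups, (within,), between_name=between,
                           gg_correction=gg_correction)
    conds = list(complete.columns)
    n_units = len(complete)
    st_w = res.strata[within]
    st_b = res.strata["between"]
    rows = []
    cond_means = dict(zip(conds, y.mean(axis=0)))
    rows += _pairwise(cond_means, {}, st_w["ms_error"], st_w["df_error"],
                      family=within, paired_n=n_units)
    g_index = {g: np.flatnonzero(groups == g) for g in np.unique(groups)}
    roi_means = {g: float(y[idx].mean()) for g, idx in g_index.items()}
    roi_n = {g: len(idx) for g, idx in g_index.items()}
    rows += _pairwise(roi_means, roi_n, st_b["ms_error"],
                      st_b["df_error"], family=between)
    for g, idx in g_index.items():
        cell = dict(zip(conds, y[idx].mean(axis=0)))
        rows += _pairwise(cell, {}, st_w["ms_error"], st_w["df_error"],
                          family=f"{within}@{between}",
                          extra={between: g}, paired_n=len(idx))
    res.posthoc = pd.DataFrame(rows)
    return res


def mixed_anova_3way(data: pd.DataFrame, dv: str = "value",
                     within: tuple[str, str] = ("condition", "bin"),
                     between: str = "roi", subject: str = "channel",
                     gg_correction: bool = False) -> AnovaTable:
    """Three-way mixed ANOVA (within Condition x TimeBin, between ROI).

    The post hoc family used downstream compares the three condition means
    within every ROI x bin cell, with the error term pooled over the two
    strata a condition contrast at a fixed bin draws on (Condition and
    Condition x TimeBin).
    """
    complete, groups = _pivot_mixed(data, dv, list(within), between, subject)
    cond_levels = sorted({c[0] for c in complete.columns})
    bin_levels = sorted({c[1] for c in complete.columns})
    y = complete.to_numpy().reshape(len(complete), len(cond_levels),
                                    len(bin_levels))
    res = split_plot_anova(y, groups, tuple(within), between_name=between,
                           gg_correction=gg_correction)
    st_c = res.strata[within[0]]
    st_cb = res.strata[f"{within[0]} x {within[1]}"]
    ms_pool = ((st_c["ms_error"] * st_c["df_error"]
                + st_cb["ms_error"] * st_cb["df_error"])
               / (st_c["df_error"] + st_cb["df_error"]))
    df_pool = st_c["df_error"] + st_cb["df_error"]
    rows = []
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        for bi, b in enumerate(bin_levels):
            cell = {c: float(y[idx, ci, bi].mean())
                    for ci, c in enumerate(cond_levels)}
            rows += _pairwise(cell, {}, ms_pool, df_pool,
                              family=f"{within[0]}@{between}x{within[1]}",
                              extra={between: g, within[1]: b},
                              paired_n=len(idx))
    res.posthoc = pd.DataFrame(rows)
    return res


def time_of_discrimination(posthoc: pd.DataFrame, alpha: float = 0.05,
                           bin_ms: float = 100.0,
                           between: str = "roi",
                           bin_col: str = "bin") -> pd.DataFrame:
    """First 100 ms bin at which two conditions differ, per ROI and contrast.

    Expects the per-ROI-per-bin condition family of ``mixed_anova_3way``'s
    post hoc table; returns the earliest significant bin as its half-open
    interval, or missing values when no bin survives.
    """
    fam = posthoc[posthoc["family"].str.contains("x", regex=False)
                  & posthoc["family"].str.startswith("condition")]
    rows = []
    for (roi, a, b), grp in fam.groupby([between, "level_a", "level_b"]):
        sig = grp[grp["p"] < alpha]
        if sig.empty:
            rows.append({between: roi, "contrast": f"{a} vs {b}",
                         "bin": np.nan, "start_ms": np.nan, "end_ms": np.nan})
        else:
            first = int(sig[bin_col].min())
            rows.append({between: roi, "contrast": f"{a} vs {b}",
                         "bin": first, "start_ms": first * bin_ms,
                         "end_ms": (first + 1) * bin_ms})
    return pd.DataFrame(rows)
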