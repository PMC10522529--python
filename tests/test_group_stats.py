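"""Chi-squared, mixed ANOVAs against oracles, Tukey HSD, discrimination."""
import numpy as np
import pandas as pd
import pytest

from bgapipe import group_stats as gs

CONDS = ["control", "egocentric", "allocentric"]


# ---------------------------------------------------------------------------
# independent sums-of-squares oracle for the balanced split-plot design
# ---------------------------------------------------------------------------

def oracle_mixed_2way(y, groups):
    """Textbook cell-mean sums of squares; balanced groups only."""
    n, c = y.shape
    glabels = np.unique(groups)
    r = len(glabels)
    n_per = n // r
    grand = y.mean()
    subj = y.mean(axis=1)
    g_of = {g: np.flatnonzero(groups == g) for g in glabels}
    gm = {g: y[idx].mean() for g, idx in g_of.items()}
    cm = y.mean(axis=0)
    gcm = {g: y[idx].mean(axis=0) for g, idx in g_of.items()}

    ss_a = n_per * c * sum((gm[g] - grand) ** 2 for g in glabels)
    ss_s = c * sum((subj[s] - gm[groups[s]]) ** 2 for s in range(n))
    ss_c = n * ((cm - grand) ** 2).sum()
    ss_ac = n_per * sum(((gcm[g] - gm[g] - cm + grand) ** 2).sum()
                        for g in glabels)
    resid = sum((y[s, j] - subj[s] - gcm[groups[s]][j] + gm[groups[s]]) ** 2
                for s in range(n) for j in range(c))
    f_a = (ss_a / (r - 1)) / (ss_s / (n - r))
    f_c = (ss_c / (c - 1)) / (resid / ((c - 1) * (n - r)))
    f_ac = (ss_ac / ((c - 1) * (r - 1))) / (resid / ((c - 1) * (n - r)))
    return {"between": f_a, "within": f_c, "interaction": f_ac}


def _mixed_df(n_per=8, n_groups=4, seed=0, effect=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        for s in range(n_per):
            ch = f"g{g}s{s}"
            base = rng.normal()
            for j, cond in enumerate(CONDS):
                rows.append({"channel": ch, "roi": f"R{g}",
                             "condition": cond,
                             "value": base + effect * g * j + rng.normal()})
    return pd.DataFrame(rows)


class TestChi2:
    def test_nine_by_three_df(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.integers(1, 20, (9, 3)))
        res = gs.chi2_proportions(t)
        assert res.df == 16

    def test_proportional_table_zero_statistic(self):
        t = pd.DataFrame([[10, 20, 30], [20, 40, 60]])
        assert gs.chi2_proportions(t).statistic == pytest.approx(0.0)

    def test_diagonal_two_by_two(self):
        res = gs.chi2_proportions(pd.DataFrame([[10, 0], [0, 10]]))
        assert res.statistic == pytest.approx(20.0)
        assert res.n == 20

    def test_zero_row_dropped(self):
        t = pd.DataFrame([[5, 5], [0, 0], [5, 5]])
        assert gs.chi2_proportions(t).df == 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            gs.chi2_proportions(pd.DataFrame([[1, -1]]))


class TestRmAnova:
    def test_37_subjects_gives_error_df_72(self):
        rng = np.random.default_rng(1)
        rows = [{"subject": s, "condition": c, "value": rng.normal()}
                for s in range(37) for c in CONDS]
        res = gs.rm_anova_behavior(pd.DataFrame(rows))
        eff = res.effect("condition")
        assert (eff["df1"], eff["df2"]) == (2, 72)

    def test_identical_values_give_zero_f(self):
        rows = [{"subject": s, "condition": c, "value": 1.0}
                for s in range(6) for c in CONDS]
        res = gs.rm_anova_behavior(pd.DataFrame(rows))
        assert res.effect("condition")["F"] == pytest.approx(0.0)

    def test_small_table_matches_ss_oracle(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(4, 3)) + [0.0, 0.5, 1.0]
        rows = [{"subject": s, "condition": c, "value": y[s, j]}
                for s in range(4) for j, c in enumerate(CONDS)]
        res = gs.rm_anova_behavior(pd.DataFrame(rows))
        # brute-force two-way (subject x condition) decomposition
        grand = y.mean()
        ss_c = 4 * ((y.mean(axis=0) - grand) ** 2).sum()
        resid = ((y - y.mean(axis=1, keepdims=True)
                  - y.mean(axis=0) + grand) ** 2).sum()
        f = (ss_c / 2) / (resid / 6)
        assert res.effect("condition")["F"] == pytest.approx(f, rel=1e-10)

    def test_matches_pingouin(self):
        import pingouin as pg
        rng = np.random.default_rng(3)
        rows = [{"subject": s, "condition": c, "value": rng.normal() + j}
                for s in range(10) for j, c in enumerate(CONDS)]
        df = pd.DataFrame(rows)
        res = gs.rm_anova_behavior(df)
        ref = pg.rm_anova(data=df, dv="value", within="condition",
                          subject="subject")
        assert res.effect("condition")["F"] == \
            pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)


class TestMixed2Way:
    def test_reference_df_identities(self):
        # 137 channels in 9 ROIs x 3 conditions -> interaction df (16, 256)
        sizes = [8, 16, 21, 8, 8, 43, 17, 10, 6]
        rng = np.random.default_rng(4)
        rows = []
        for g, size in enumerate(sizes):
            for s in range(size):
                for c in CONDS:
                    rows.append({"channel": f"g{g}s{s}", "roi": f"R{g}",
                                 "condition": c, "value": rng.normal()})
        res = gs.mixed_anova_2way(pd.DataFrame(rows))
        inter = res.effect("condition x roi")
        assert (inter["df1"], inter["df2"]) == (16, 256)
        assert res.effect("roi")["df2"] == 128

    def test_listwise_drop_shrinks_df(self):
        # removing one condition cell from 11 channels drops them listwise:
        # 126 channels remain, ROI error df = 117
        sizes = [8, 16, 21, 8, 8, 43, 17, 10, 6]
        rng = np.random.default_rng(5)
        rows = []
        for g, size in enumerate(sizes):
            for s in range(size):
                for c in CONDS:
                    rows.append({"channel": f"g{g}s{s}", "roi": f"R{g}",
                                 "condition": c, "value": rng.normal()})
        df = pd.DataFrame(rows)
        victims = df["channel"].unique()[::12][:11]  # spread across ROIs
        df = df[~(df["channel"].isin(victims)
                  & (df["condition"] == "control"))]
        res = gs.mixed_anova_2way(df)
        assert res.effect("roi")["df2"] == 117

    @pytest.mark.parametrize("seed", range(4))
    def test_balanced_f_matches_oracle(self, seed):
        df = _mixed_df(n_per=7, n_groups=3, seed=seed, effect=0.4)
        res = gs.mixed_anova_2way(df)
        wide = df.pivot(index="channel", columns="condition", values="value")
        wide = wide[CONDS].sort_index()
        groups = df.drop_duplicates("channel").set_index("channel")["roi"]
        oracle = oracle_mixed_2way(wide.to_numpy(),
                                   groups.loc[wide.index].to_numpy())
        assert res.effect("roi")["F"] == \
            pytest.approx(oracle["between"], rel=1e-8)
        assert res.effect("condition")["F"] == \
            pytest.approx(oracle["within"], rel=1e-8)
        assert res.effect("condition x roi")["F"] == \
            pytest.approx(oracle["interaction"], rel=1e-8)

    def test_balanced_matches_pingouin(self):
        import pingouin as pg
        df = _mixed_df(n_per=9, n_groups=4, seed=9, effect=0.3)
        res = gs.mixed_anova_2way(df)
        ref = pg.mixed_anova(data=df, dv="value", within="condition",
                             between="roi", subject="channel")
        ref_f = dict(zip(ref["Source"], ref["F"]))
        assert res.effect("roi")["F"] == pytest.approx(ref_f["roi"], rel=1e-9)
        assert res.effect("condition")["F"] == \
            pytest.approx(ref_f["condition"], rel=1e-9)
        assert res.effect("condition x roi")["F"] == \
            pytest.approx(ref_f["Interaction"], rel=1e-9)

    def test_type_one_error_calibration(self):
        # null data: the ROI main effect should reject at ~5 %
        n_rep = 400
        hits = 0
        for rep in range(n_rep):
            df = _mixed_df(n_per=5, n_groups=4, seed=1000 + rep)
            res = gs.mixed_anova_2way(df)
            hits += res.effect("roi")["p"] < 0.05
        rate = hits / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 3 * se

    def test_tukey_not_smaller_than_pairwise(self):
        from scipy import stats as sstats
        df = _mixed_df(n_per=10, n_groups=3, seed=11, effect=0.2)
        res = gs.mixed_anova_2way(df)
        st = res.strata["condition"]
        wide = df.pivot(index="channel", columns="condition", values="value")
        for _, row in res.posthoc[res.posthoc["family"] == "condition"] \
                .iterrows():
            d = wide[row["level_a"]] - wide[row["level_b"]]
            t_p = sstats.ttest_1samp(d, 0.0).pvalue
            # Tukey on k=3 means is more conservative than the naive
            # per-pair test at matched error assumptions
            q_as_t = sstats.studentized_range.sf(
                abs(d.mean()) / np.sqrt(st["ms_error"] / len(wide)), 2,
                st["df_error"])
            assert row["p"] >= q_as_t - 1e-12


class TestMixed3Way:
    def _bins_df(self, n_per=6, n_groups=3, seed=0, effect=0.0,
                 effect_bins=()):
        rng = np.random.default_rng(seed)
        rows = []
        for g in range(n_groups):
            for s in range(n_per):
                ch = f"g{g}s{s}"
                base = rng.normal(0, 1.5)
                for cond in CONDS:
                    for b in range(10):
                        v = base + rng.normal()
                        if g == 0 and cond == "allocentric" \
                                and b in effect_bins:
                            v += effect
                        rows.append({"channel": ch, "roi": f"R{g}",
                                     "condition": cond, "bin": b,
                                     "value": v})
        return pd.DataFrame(rows)

    def test_reference_df_identity(self):
        sizes = [8, 16, 21, 8, 8, 43, 17, 10, 6]
        rng = np.random.default_rng(6)
        rows = [{"channel": f"g{g}s{s}", "roi": f"R{g}", "condition": c,
                 "bin": b, "value": rng.normal()}
                for g, size in enumerate(sizes) for s in range(size)
                for c in CONDS for b in range(10)]
        res = gs.mixed_anova_3way(pd.DataFrame(rows))
        inter = res.effect("condition x bin x roi")
        assert (inter["df1"], inter["df2"]) == (144, 2304)

    def test_df_closed_forms_over_random_designs(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            r = int(rng.integers(2, 5))
            n_per = int(rng.integers(3, 7))
            c = 3
            b = int(rng.integers(2, 6))
            rows = [{"channel": f"g{g}s{s}", "roi": f"R{g}",
                     "condition": f"c{j}", "bin": k, "value": rng.normal()}
                    for g in range(r) for s in range(n_per)
                    for j in range(c) for k in range(b)]
            res = gs.mixed_anova_3way(pd.DataFrame(rows))
            n = r * n_per
            inter = res.effect("condition x bin x roi")
            assert inter["df1"] == (c - 1) * (b - 1) * (r - 1)
            assert inter["df2"] == (c - 1) * (b - 1) * (n - r)
            assert res.effect("roi")["df2"] == n - r

    def test_null_three_way_f_near_one(self):
        fs = [gs.mixed_anova_3way(self._bins_df(seed=2000 + rep))
              .effect("condition x bin x roi")["F"] for rep in range(25)]
        assert 0.85 < np.mean(fs) < 1.15

    def test_pure_within_matches_statsmodels(self):
        from statsmodels.stats.anova import AnovaRM
        df = self._bins_df(n_per=8, n_groups=1, seed=8)
        res = gs.mixed_anova_3way(df)
        ref = AnovaRM(df, depvar="value", subject="channel",
                      within=["condition", "bin"]).fit().anova_table
        assert res.effect("condition")["F"] == \
            pytest.approx(ref.loc["condition", "F Value"], rel=1e-8)
        assert res.effect("bin")["F"] == \
            pytest.approx(ref.loc["bin", "F Value"], rel=1e-8)
        assert res.effect("condition x bin")["F"] == \
            pytest.approx(ref.loc["condition:bin", "F Value"], rel=1e-8)

    def test_injected_effect_found_in_right_bins(self):
        df = self._bins_df(n_per=12, seed=9, effect=3.0,
                           effect_bins=(4, 5, 6))
        res = gs.mixed_anova_3way(df)
        tod = gs.time_of_discrimination(res.posthoc)
        row = tod[(tod["roi"] == "R0")
                  & (tod["contrast"] == "allocentric vs egocentric")]
        assert row["bin"].iloc[0] == 4


class TestDiscrimination:
    def test_no_significance_gives_none(self):
        ph = pd.DataFrame([{"family": "condition@roixbin", "roi": "R0",
                            "bin": b, "level_a": "allocentric",
                            "level_b": "egocentric", "diff": 0.0, "p": 0.9}
                           for b in range(10)])
        tod = gs.time_of_discrimination(ph)
        assert np.isnan(tod["bin"].iloc[0])

    def test_first_bin_interval_reported(self):
        ph = pd.DataFrame([{"family": "condition@roixbin", "roi": "R0",
                            "bin": b, "level_a": "allocentric",
                            "level_b": "egocentric", "diff": 1.0,
                            "p": 0.01 if b in (5, 6) else 0.8}
                           for b in range(10)])
        tod = gs.time_of_discrimination(ph)
        assert tod["start_ms"].iloc[0] == 500.0
        assert tod["end_ms"].iloc[0] == 600.0
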