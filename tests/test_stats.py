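"""Cell summaries, ANCOVA, effect sizes, and pairwise comparisons."""

import numpy as np
import pandas as pd
import pytest

from fodisc.stats import (
    ancova,
    analyze_study,
    bonferroni,
    pairwise_t,
    pairwise_t_from_summary,
    partial_eta_sq,
    report_text,
    summarize_cells,
)


def make_table(cell_values: dict, ages: dict | None = None) -> pd.DataFrame:
    rows = []
    for (group, singer), values in cell_values.items():
        age_list = (ages or {}).get((group, singer), [30.0] * len(values))
        for v, a in zip(values, age_list):
            rows.append({"group": group, "singer": singer,
                         "estimated_threshold_cents": v, "age_yr": a})
    return pd.DataFrame(rows)


class TestSummaries:
    def test_mean_sd(self):
        table = make_table({
            ("control", False): [10.0, 20.0, 30.0],
            ("control", True): [10.0, 20.0, 30.0],
            ("HVD", False): [10.0, 20.0, 30.0],
            ("HVD", True): [10.0, 20.0, 30.0],
        })
        s = summarize_cells(table)[0]
        assert s.mean_cents == 20.0
        assert s.sd_cents == pytest.approx(10.0)
        # 95% CI: mean ± t(0.975, 2)·sd/√3 with t quantile 4.302652729749462
        half = 4.302652729749462 * 10.0 / np.sqrt(3.0)
        assert s.ci95_low_cents == pytest.approx(20.0 - half)
        assert s.ci95_high_cents == pytest.approx(20.0 + half)

    def test_degenerate_cell(self):
        table = make_table({(g, s): [5.0, 5.0, 5.0]
                            for g in ("control", "HVD") for s in (False, True)})
        s = summarize_cells(table)[0]
        assert s.sd_cents == 0.0
        assert s.ci95_low_cents == s.ci95_high_cents == 5.0

    def test_missing_excluded_and_counted(self):
        table = make_table({(g, s): [10.0, 20.0, 30.0, np.nan]
                            for g in ("control", "HVD") for s in (False, True)})
        s = summarize_cells(table)[0]
        assert s.n == 3 and s.n_missing == 1

    def test_too_small_cell_rejected(self):
        table = make_table({(g, s): [10.0] for g in ("control", "HVD")
                            for s in (False, True)})
        with pytest.raises(ValueError):
            summarize_cells(table)


class TestEffectSize:
    @pytest.mark.parametrize("F, df1, df2, printed", [
        (20.49, 1, 115, 0.15),
        (17.33, 1, 115, 0.13),
        (5.42, 1, 115, 0.045),
        (0.0, 1, 115, 0.0),
    ])
    def test_partial_eta_sq_back_computation(self, F, df1, df2, printed):
        assert partial_eta_sq(F, df1, df2) == pytest.approx(printed, abs=0.005)

    def test_monotone_and_bounded(self):
        fs = np.linspace(0, 500, 100)
        etas = [partial_eta_sq(f, 1, 115) for f in fs]
        assert np.all(np.diff(etas) > 0)
        assert all(0 <= e < 1 for e in etas)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            partial_eta_sq(-1.0, 1, 115)


class TestBonferroni:
    @pytest.mark.parametrize("p, m, expected", [
        (0.0045, 2, 0.009),
        (0.6, 2, 1.0),
        (0.3, 1, 0.3),
    ])
    def test_adjustment(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    def test_invalid(self):
        with pytest.raises(ValueError):
            bonferroni(1.5, 2)


class TestPairwise:
    def test_identical_samples(self):
        a = [10.0, 20.0, 30.0, 25.0]
        res = pairwise_t(a, list(a))
        assert res.t == 0.0 and res.d == 0.0 and res.p_adj == 1.0

    def test_one_pooled_sd_difference(self, rng):
        a = rng.normal(0, 1, 50)
        sp = np.std(a, ddof=1)
        b = a + sp  # identical spread, means exactly one pooled SD apart
        res = pairwise_t(b, a)
        assert res.d == pytest.approx(1.0)

    def test_summary_inputs_reported_singers(self):
        # printed singer-cell moments give d ≈ 0.58 (the published 0.98
        # is inconsistent with its own cell statistics)
        res = pairwise_t_from_summary(25.0, 12.8, 43, 18.9, 7.5, 43,
                                      stratum="singers")
        assert res.d == pytest.approx(0.5815, abs=1e-3)
        assert res.df == 84

    def test_raw_equals_summary(self, rng):
        a = rng.normal(30, 10, 17)
        b = rng.normal(25, 8, 17)
        r1 = pairwise_t(a, b)
        r2 = pairwise_t_from_summary(np.mean(a), np.std(a, ddof=1), len(a),
                                     np.mean(b), np.std(b, ddof=1), len(b))
        assert r1.t == pytest.approx(r2.t, abs=1e-10)
        assert r1.d == pytest.approx(r2.d, abs=1e-10)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            pairwise_t([1.0], [2.0, 3.0])


def balanced_anova_oracle(table: pd.DataFrame) -> dict:
    """Textbook balanced two-way ANOVA decomposition (independent path)."""
    y = table["estimated_threshold_cents"].to_numpy()
    g = (table["group"] == "HVD").to_numpy(int)
    s = table["singer"].astype(bool).to_numpy(int)
    n = len(y) // 4
    grand = y.mean()
    mg = [y[g == i].mean() for i in (0, 1)]
    ms = [y[s == i].mean() for i in (0, 1)]
    mc = {(i, j): y[(g == i) & (s == j)].mean() for i in (0, 1) for j in (0, 1)}
    ss_g = 2 * n * sum((m - grand) ** 2 for m in mg)
    ss_s = 2 * n * sum((m - grand) ** 2 for m in ms)
    ss_i = n * sum(
        (mc[(i, j)] - mg[i] - ms[j] + grand) ** 2
        for i in (0, 1) for j in (0, 1)
    )
    ss_e = sum(
        ((y[(g == i) & (s == j)] - mc[(i, j)]) ** 2).sum()
        for i in (0, 1) for j in (0, 1)
    )
    df_e = len(y) - 4
    return {
        "group": (ss_g / 1) / (ss_e / df_e),
        "singer": (ss_s / 1) / (ss_e / df_e),
        "interaction": (ss_i / 1) / (ss_e / df_e),
    }


def type3_regression_oracle(table: pd.DataFrame,
                            include_age: bool = True) -> dict:
    """Type III F via explicit full-vs-reduced least squares.

    Sum-to-zero coding built by hand; each term's F comes from the SS
    increase when its columns are deleted from the full model.
    """
    y = table["estimated_threshold_cents"].to_numpy(float)
    g = np.where(table["group"] == "HVD", 1.0, -1.0)
    s = np.where(table["singer"].astype(bool), 1.0, -1.0)
    cols = {"intercept": np.ones_like(y), "group": g, "singer": s,
            "interaction": g * s}
    if include_age:
        cols["age"] = table["age_yr"].to_numpy(float)

    def rss(names):
        X = np.column_stack([cols[n] for n in names])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return float(resid @ resid)

    full_names = list(cols)
    rss_full = rss(full_names)
    df_resid = len(y) - len(full_names)
    out = {}
    for term in full_names:
        if term == "intercept":
            continue
        reduced = [n for n in full_names if n != term]
        out[term] = (rss(reduced) - rss_full) / (rss_full / df_resid)
    return out


class TestAncova:
    def make_balanced(self, rng, n=20):
        cells = {}
        ages = {}
        for g in ("control", "HVD"):
            for s in (False, True):
                base = 20 + 10 * (g == "HVD") + 5 * s
                cells[(g, s)] = list(rng.normal(base, 5, n))
                ages[(g, s)] = list(rng.uniform(20, 50, n))
        return make_table(cells, ages)

    def test_matches_model_comparison_oracle(self, rng):
        """Type III F values equal an explicit full-vs-reduced least-squares
        oracle to 1e-8 on random (including unbalanced) instances."""
        for _ in range(50):
            table = self.make_balanced(rng, n=6)
            # unbalance by dropping a few rows
            table = table.drop(table.index[rng.choice(len(table), 3,
                                                      replace=False)])
            table = table.reset_index(drop=True)
            rows = {r.term: r for r in ancova(table)}
            oracle = type3_regression_oracle(table)
            for term in ("group", "singer", "interaction", "age"):
                assert rows[term].F == pytest.approx(oracle[term],
                                                     abs=1e-8, rel=1e-8)

    def test_balanced_zero_slope_reduces_to_anova(self, rng):
        """On balanced cells with an age-orthogonal design the regression
        oracle without the covariate reproduces the textbook balanced
        two-way ANOVA decomposition to 1e-8."""
        table = self.make_balanced(rng, n=10)
        oracle = type3_regression_oracle(table, include_age=False)
        hand = balanced_anova_oracle(table)
        for term in ("group", "singer", "interaction"):
            assert oracle[term] == pytest.approx(hand[term], abs=1e-8,
                                                 rel=1e-8)

    def test_location_invariance(self, rng):
        table = self.make_balanced(rng)
        shifted = table.copy()
        shifted["estimated_threshold_cents"] += 100.0
        f1 = {r.term: r.F for r in ancova(table)}
        f2 = {r.term: r.F for r in ancova(shifted)}
        for term in f1:
            assert f1[term] == pytest.approx(f2[term], rel=1e-9)

    def test_default_design_df(self):
        from fodisc.cohort import generate_study
        table = generate_study(seed=1)
        n_usable = table["estimated_threshold_cents"].notna().sum()
        rows = ancova(table)
        # residual df is N − 5 (intercept, two factors, interaction, age);
        # 115 for a complete 120-participant study
        assert all(r.df2 == n_usable - 5 for r in rows)
        if n_usable == 120:
            assert rows[0].df2 == 115
        assert {r.term for r in rows} == {"group", "singer", "interaction",
                                          "age"}

    def test_empty_cell_rejected(self, rng):
        table = self.make_balanced(rng)
        table = table[~((table["group"] == "HVD") & table["singer"])]
        with pytest.raises(ValueError):
            ancova(table)


class TestAnalyzeStudy:
    def test_full_report(self):
        from fodisc.cohort import generate_study
        table = generate_study(seed=4)
        analysis = analyze_study(table)
        assert len(analysis["cell_summaries"]) == 4
        assert len(analysis["pairwise"]) == 2
        ge = analysis["group_effect_cents"]
        assert ge["non-singers"] > 0  # HVD worse by construction
        text = report_text(analysis)
        assert "ANCOVA" in text and "non-singers" in text
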