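"""Group-level analysis of fo-discrimination thresholds.

Reproduces the study-style analysis of a participant table: per-cell
summaries (mean, SD, 95% CI), a two-way ANCOVA of threshold on group ×
singer status with age as covariate (Type III sums of squares, sum-to-zero
factor coding — the convention for unbalanced designs reporting main
effects alongside an interaction), partial η² effect sizes, and follow-up
pooled-variance t tests of control vs. HVD within each singer stratum with
Bonferroni adjustment and Cohen's d.

The ANCOVA model is fit with statsmodels OLS; effect sizes, the pairwise
tests, and the reporting layer are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

THRESHOLD_COL = "estimated_threshold_cents"
AGE_COL = "age_yr"


@dataclass(frozen=True)
class CellSummary:
    group: str
    singer: bool
    n: int
    mean_cents: float
    sd_cents: float
    ci95_low_cents: float
    ci95_high_cents: float
    n_missing: int = 0

    @property
    def label(self) -> str:
        return f"{self.group}-{'singer' if self.singer else 'non-singer'}"


@dataclass(frozen=True)
class AncovaRow:
    term: str  # "group" | "singer" | "interaction" | "age"
    F: float
    df1: int
    df2: int
    p: float
    eta_sq_partial: float


@dataclass(frozen=True)
class PairwiseResult:
    stratum: str  # "non-singers" | "singers"
    t: float
    df: int
    p_raw: float
    p_adj: float
    d: float


def partial_eta_sq(F: float, df1: float, df2: float) -> float:
    """Partial η² from an F statistic: F·df1 / (F·df1 + df2)."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("F must be non-negative and dfs positive")
    return F * df1 / (F * df1 + df2)


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-adjusted p value: min(1, m·p_raw)."""
    if not 0 <= p_raw <= 1:
        raise ValueError("p_raw must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be at least 1")
    return min(1.0, m * p_raw)


def summarize_cells(table: pd.DataFrame,
                    value_col: str = THRESHOLD_COL) -> list[CellSummary]:
    """Per-cell mean, SD (n−1 denominator), and 95% t-based CI.

    Missing thresholds (flagged sessions) are excluded and counted in
    ``n_missing``.  A cell with fewer than two usable values is an error.
    """
    summaries = []
    for (group, singer), sub in table.groupby(["group", "singer"], sort=True):
        values = sub[value_col].to_numpy(dtype=float)
        ok = values[~np.isnan(values)]
        n = len(ok)
        if n < 2:
            raise ValueError(
                f"cell {group}/{'singer' if singer else 'non-singer'} has "
                f"{n} usable observations; need at least 2"
            )
        mean = float(np.mean(ok))
        sd = float(np.std(ok, ddof=1))
        half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        summaries.append(CellSummary(
            group=group, singer=bool(singer), n=n, mean_cents=mean,
            sd_cents=sd, ci95_low_cents=mean - half, ci95_high_cents=mean + half,
            n_missing=len(values) - n,
        ))
    return summaries


def ancova(table: pd.DataFrame,
           value_col: str = THRESHOLD_COL,
           age_col: str = AGE_COL) -> list[AncovaRow]:
    """Two-way ANCOVA: threshold ~ group × singer + age.

    Type III sums of squares with sum-to-zero factor coding; returns one
    row per term (group, singer, interaction, age) with F, dfs, p, and
    partial η².  For the default 120-participant design the error df is
    120 − 5 = 115.
    """
    data = table.dropna(subset=[value_col, age_col]).copy()
    counts = data.groupby(["group", "singer"]).size()
    if len(counts) < 4 or counts.min() < 2:
        raise ValueError("need at least 2 observations in each of 4 cells")
    data["_singer"] = np.where(data["singer"].astype(bool), "singer", "non-singer")
    model = smf.ols(
        f"{value_col} ~ C(group, Sum) * C(_singer, Sum) + {age_col}", data=data
    ).fit()
    aov = anova_lm(model, typ=3)
    df2 = int(aov.loc["Residual", "df"])
    name_map = {
        "C(group, Sum)": "group",
        "C(_singer, Sum)": "singer",
        "C(group, Sum):C(_singer, Sum)": "interaction",
        age_col: "age",
    }
    rows = []
    for raw, term in name_map.items():
        F = float(aov.loc[raw, "F"])
        df1 = int(aov.loc[raw, "df"])
        rows.append(AncovaRow(
            term=term, F=F, df1=df1, df2=df2,
            p=float(aov.loc[raw, "PR(>F)"]),
            eta_sq_partial=partial_eta_sq(F, df1, df2),
        ))
    return rows


def pairwise_t(a: Sequence[float], b: Sequence[float],
               stratum: str = "", m: int = 2) -> PairwiseResult:
    """Two-sided pooled-variance t test of sample a vs. b with Cohen's d.

    d = (mean_a − mean_b) / pooled SD, pooled over both samples with the
    usual (n−1)-weighted variance; p_adj is Bonferroni over ``m`` strata.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 observations")
    return _pairwise_from_moments(
        np.mean(a), np.std(a, ddof=1), len(a),
        np.mean(b), np.std(b, ddof=1), len(b), stratum, m,
    )


def pairwise_t_from_summary(mean_a: float, sd_a: float, n_a: int,
                            mean_b: float, sd_b: float, n_b: int,
                            stratum: str = "", m: int = 2) -> PairwiseResult:
    """The same test computed from (mean, SD, n) summaries."""
    if n_a < 2 or n_b < 2:
        raise ValueError("both samples need at least 2 observations")
    return _pairwise_from_moments(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                  stratum, m)


def _pairwise_from_moments(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                           stratum, m) -> PairwiseResult:
    df = n_a + n_b - 2
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    sp = np.sqrt(pooled_var)
    diff = mean_a - mean_b
    if sp == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        d = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        t = diff / (sp * np.sqrt(1.0 / n_a + 1.0 / n_b))
        d = diff / sp
    p_raw = float(2 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return PairwiseResult(stratum=stratum, t=float(t), df=int(df),
                          p_raw=p_raw, p_adj=bonferroni(p_raw, m), d=float(d))


def analyze_study(table: pd.DataFrame) -> dict:
    """Full analysis of a participant table, as a JSON-serializable dict.

    Contains the four cell summaries, the ANCOVA table, the within-stratum
    control-vs-HVD pairwise tests (HVD minus control, Bonferroni m = 2),
    and the two stratum group effects (difference of cell means, cents).
    """
    summaries = summarize_cells(table)
    aov = ancova(table)
    pairwise = []
    effects = {}
    for singer, stratum in ((False, "non-singers"), (True, "singers")):
        sub = table[table["singer"].astype(bool) == singer]
        hvd = sub.loc[sub["group"] == "HVD", THRESHOLD_COL]
        ctl = sub.loc[sub["group"] == "control", THRESHOLD_COL]
        pairwise.append(pairwise_t(hvd, ctl, stratum=stratum, m=2))
        effects[stratum] = float(np.nanmean(hvd) - np.nanmean(ctl))
    return {
        "cell_summaries": [asdict(s) for s in summaries],
        "ancova": [asdict(r) for r in aov],
        "pairwise": [asdict(p) for p in pairwise],
        "group_effect_cents": effects,
    }


def report_text(analysis: dict) -> str:
    """Human-readable analysis report."""
    lines = ["fo discrimination thresholds — group analysis", ""]
    lines.append("Cell summaries (cents):")
    for s in analysis["cell_summaries"]:
        who = f"{s['group']} {'singers' if s['singer'] else 'non-singers'}"
        lines.append(
            f"  {who:24s} n={s['n']:3d}  mean={s['mean_cents']:5.1f}  "
            f"SD={s['sd_cents']:4.1f}  "
            f"95% CI [{s['ci95_low_cents']:.1f}, {s['ci95_high_cents']:.1f}]"
            + (f"  ({s['n_missing']} flagged)" if s["n_missing"] else "")
        )
    lines.append("")
    lines.append("ANCOVA (threshold ~ group × singer status + age, Type III):")
    for r in analysis["ancova"]:
        lines.append(
            f"  {r['term']:12s} F({r['df1']},{r['df2']}) = {r['F']:6.2f}, "
            f"p = {r['p']:.4g}, partial eta^2 = {r['eta_sq_partial']:.3f}"
        )
    lines.append("")
    lines.append("Pairwise control vs. HVD (pooled t, Bonferroni m=2):")
    for p in analysis["pairwise"]:
        lines.append(
            f"  {p['stratum']:12s} t({p['df']}) = {p['t']:5.2f}, "
            f"p_adj = {p['p_adj']:.4g}, d = {p['d']:.2f}"
        )
    ge = analysis["group_effect_cents"]
    lines.append("")
    lines.append(
        f"Group effect (HVD − control): {ge['non-singers']:.1f} cents in "
        f"non-singers, {ge['singers']:.1f} cents in singers"
    )
    return "\n".join(lines)


def plot_thresholds(table: pd.DataFrame, path=None):
    """Per-cell individual thresholds with means and 95% CI bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summaries = {(s.group, s.singer): s for s in summarize_cells(table)}
    fig, axes = plt.subplots(1, 2, figsize=(7, 4), sharey=True)
    for ax, singer, title in zip(axes, (False, True), ("Non-singers", "Singers")):
        for x, group in enumerate(("control", "HVD")):
            sub = table[(table["group"] == group)
                        & (table["singer"].astype(bool) == singer)]
            vals = sub[THRESHOLD_COL].dropna()
            jitter = (np.arange(len(vals)) % 7 - 3) * 0.02
            ax.plot(x + jitter, vals, "o", alpha=0.4, ms=4)
            s = summaries[(group, singer)]
            ax.errorbar(
                [x], [s.mean_cents],
                yerr=[[s.mean_cents - s.ci95_low_cents],
                      [s.ci95_high_cents - s.mean_cents]],
                fmt="k_", capsize=6, lw=2, ms=16,
            )
        ax.set_xticks([0, 1], ["control", "HVD"])
        ax.set_title(title)
    axes[0].set_ylabel("fo discrimination threshold (cents)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
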