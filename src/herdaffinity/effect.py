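"""Affinity vs broken-affinity milk-deviation contrast.

Given the exclusive matched pairs and the residency table, each matched
cow's resident days are labelled ``affinity`` (its partner is resident in
the same pen that day) or ``broken`` (the partner is absent).  Daily
observed-minus-expected deviations from the Wood baselines are summarised
per cow and period type, and each pen gets a one-sided paired t-test of the
hypothesis that production deviations are higher during affinity than after
the pair is broken, with Holm's step-down correction across pens.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "label_periods",
    "summarize_deviation",
    "pen_paired_test",
    "holm_adjust",
    "dim_balance_check",
    "effect_report",
]


def _cow_days(residency: pd.DataFrame) -> pd.DataFrame:
    """Expand inclusive residency intervals to one row per cow-day."""
    if residency.empty:
        return pd.DataFrame(columns=["cow_id", "pen_id", "date"])
    n = (residency["exit_date"] - residency["entry_date"]).dt.days + 1
    cow = np.repeat(residency["cow_id"].to_numpy(), n)
    pen = np.repeat(residency["pen_id"].to_numpy(), n)
    start = np.repeat(residency["entry_date"].to_numpy(), n)
    offset = np.concatenate([np.arange(k) for k in n]).astype("timedelta64[D]")
    return pd.DataFrame({"cow_id": cow, "pen_id": pen, "date": start + offset})


def label_periods(pairs: pd.DataFrame, residency: pd.DataFrame) -> pd.DataFrame:
    """Per-day affinity/broken labels for every matched cow.

    ``pairs`` needs columns cow_a, cow_b (an exclusive matching).  A day is
    labelled ``affinity`` iff both mates are resident in the same pen that
    day, ``broken`` on any other day the cow itself is resident.  Returns
    one row per matched cow per resident day: cow_id, partner_id, pen_id,
    date, label.
    """
    days = _cow_days(residency)
    partner = {}
    for _, row in pairs.iterrows():
        partner[row["cow_a"]] = row["cow_b"]
        partner[row["cow_b"]] = row["cow_a"]
    mine = days[days["cow_id"].isin(partner)].copy()
    mine["partner_id"] = mine["cow_id"].map(partner)
    theirs = days.rename(columns={"cow_id": "partner_id", "pen_id": "partner_pen"})
    merged = mine.merge(theirs, on=["partner_id", "date"], how="left")
    merged["label"] = np.where(merged["partner_pen"] == merged["pen_id"], "affinity", "broken")
    out = merged[["cow_id", "partner_id", "pen_id", "date", "label"]]
    return out.sort_values(["cow_id", "date"], kind="stable").reset_index(drop=True)


def summarize_deviation(
    residual_frame: pd.DataFrame,
    periods: pd.DataFrame,
    min_period_days: int = 7,
) -> pd.DataFrame:
    """Per-cow, per-period-type deviation summaries.

    The mean deviation is the discrete observed-vs-expected area difference
    divided by the number of days; the SD is the sample standard deviation
    of the daily deviations (day-to-day variability).  Period types observed
    on fewer than ``min_period_days`` days are suppressed.
    """
    rf = residual_frame.drop(columns=["label"], errors="ignore")
    merged = rf.merge(periods[["cow_id", "date", "label"]], on=["cow_id", "date"], how="inner")
    if merged.empty:
        return pd.DataFrame(columns=["cow_id", "period_type", "mean_dev", "sd_dev", "n_days"])
    out = (
        merged.groupby(["cow_id", "label"], sort=True)["residual_kg"]
        .agg(mean_dev="mean", sd_dev=lambda s: s.std(ddof=1), n_days="size")
        .reset_index()
        .rename(columns={"label": "period_type"})
    )
    out = out[out["n_days"] >= min_period_days].reset_index(drop=True)
    return out


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def pen_paired_test(
    labelled_residuals: pd.DataFrame,
    min_period_days: int = 7,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-pen paired t-test of affinity vs broken deviations, Holm-adjusted.

    ``labelled_residuals`` is the residual frame joined with period labels
    (columns cow_id, pen_id, date, residual_kg, label).  Each cow observed
    in both period types for at least ``min_period_days`` days contributes
    one paired difference ``d = mean_dev(affinity) - mean_dev(broken)``;
    the test is one-sided (affinity higher) by default.  SD columns are the
    day-to-day SDs of the daily residuals pooled over the pen's eligible
    cows.  Pens with fewer than two eligible cows, or with all differences
    identical, are flagged ``testable=False`` and excluded from the Holm
    family.  An ``Overall`` row pools the daily residuals across pens with
    no test (the pens are the inference units).
    """
    rows = []
    for pen, g in labelled_residuals.groupby("pen_id", sort=True):
        summaries = summarize_deviation(g, g[["cow_id", "date", "label"]], min_period_days)
        wide = summaries.pivot(index="cow_id", columns="period_type", values="mean_dev")
        eligible = wide.dropna(subset=["affinity", "broken"]) if {"affinity", "broken"} <= set(wide.columns) else wide.iloc[:0]
        eligible_cows = eligible.index
        pooled = g[g["cow_id"].isin(eligible_cows)]
        sd_aff = pooled.loc[pooled["label"] == "affinity", "residual_kg"].std(ddof=1)
        sd_bro = pooled.loc[pooled["label"] == "broken", "residual_kg"].std(ddof=1)
        mean_aff = pooled.loc[pooled["label"] == "affinity", "residual_kg"].mean()
        mean_bro = pooled.loc[pooled["label"] == "broken", "residual_kg"].mean()
        d = (eligible["affinity"] - eligible["broken"]).to_numpy() if len(eligible) else np.array([])
        testable = len(d) >= 2 and np.ptp(d) > 0
        if testable:
            t_stat, p_raw = stats.ttest_1samp(d, 0.0, alternative=alternative)
        else:
            t_stat, p_raw = np.nan, np.nan
        rows.append(
            {
                "pen_id": str(pen),
                "n_cows": len(d),
                "mean_affinity": mean_aff,
                "mean_broken": mean_bro,
                "mean_diff": float(np.mean(d)) if len(d) else np.nan,
                "sd_affinity": sd_aff,
                "sd_broken": sd_bro,
                "t": float(t_stat) if testable else np.nan,
                "p_raw": float(p_raw) if testable else np.nan,
                "testable": testable,
            }
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = np.nan
    mask = out["testable"].to_numpy(dtype=bool) if len(out) else np.array([], dtype=bool)
    if mask.any():
        out.loc[mask, "p_holm"] = holm_adjust(out.loc[mask, "p_raw"].to_numpy())

    # pooled descriptive row across pens (no test: pens are the units)
    all_cows = labelled_residuals
    rows_overall = {
        "pen_id": "Overall",
        "n_cows": int(out["n_cows"].sum()),
        "mean_affinity": all_cows.loc[all_cows["label"] == "affinity", "residual_kg"].mean(),
        "mean_broken": all_cows.loc[all_cows["label"] == "broken", "residual_kg"].mean(),
        "mean_diff": np.nan,
        "sd_affinity": all_cows.loc[all_cows["label"] == "affinity", "residual_kg"].std(ddof=1),
        "sd_broken": all_cows.loc[all_cows["label"] == "broken", "residual_kg"].std(ddof=1),
        "t": np.nan,
        "p_raw": np.nan,
        "testable": False,
        "p_holm": np.nan,
    }
    return pd.concat([out, pd.DataFrame([rows_overall])], ignore_index=True)


def dim_balance_check(labelled_residuals: pd.DataFrame) -> dict:
    """DIM-distribution balance between affinity and broken days.

    An advisory confounding diagnostic: early lactation is intrinsically
    more variable, so the contrast is only clean if the DIM distributions of
    the two period types are similar.  Reports per-type DIM quartiles and
    the two-sample Kolmogorov-Smirnov statistic; never gates the analysis.
    """
    aff = labelled_residuals.loc[labelled_residuals["label"] == "affinity", "dim"].to_numpy()
    bro = labelled_residuals.loc[labelled_residuals["label"] == "broken", "dim"].to_numpy()
    if len(aff) == 0 or len(bro) == 0:
        raise ValueError("both period types must have labelled days")
    ks = stats.ks_2samp(aff, bro)
    quart = lambda a: {q: float(np.quantile(a, q)) for q in (0.25, 0.5, 0.75)}
    return {
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "dim_quartiles_affinity": quart(aff),
        "dim_quartiles_broken": quart(bro),
        "n_affinity_days": int(len(aff)),
        "n_broken_days": int(len(bro)),
    }


def effect_report(pen_tests: pd.DataFrame) -> str:
    """Plain-text table of the per-pen deviation contrast."""
    lines = [
        "Difference of actual to expected milk production, kg/day",
        f"{'':10s}{'Mean':>18s}{'SD':>18s}{'Paired t-test':>16s}",
        f"{'Item':10s}{'Broken':>9s}{'Affinity':>9s}{'Broken':>9s}{'Affinity':>9s}{'p (Holm)':>16s}",
    ]
    for _, r in pen_tests.iterrows():
        p = f"{r['p_holm']:.3f}" if np.isfinite(r.get("p_holm", np.nan)) else "NA"
        lines.append(
            f"{r['pen_id']:10s}{r['mean_broken']:9.2f}{r['mean_affinity']:9.2f}"
            f"{r['sd_broken']:9.2f}{r['sd_affinity']:9.2f}{p:>16s}"
        )
    return "\n".join(lines)
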