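"""Linking statistics between preceding-sleep photometry summaries and
next-day behavior: per-cluster Pearson correlations with Bonferroni control,
quartile-based Mann-Whitney comparison of port-visit speeds, generic group
comparisons, and coupling recovery on synthetic data."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidArgumentError,
    NoOverlapError,
)


def bonferroni(p: float, n_comparisons: int) -> float:
    return float(min(1.0, p * n_comparisons))


def build_link_table(
    sleep: pd.DataFrame,
    behavior: pd.DataFrame,
    day_offset: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Join behavior on day ``d`` with sleep summaries from day
    ``d - day_offset`` (the next-day convention).

    ``sleep`` is keyed by (mouse, day); ``behavior`` by (mouse, day, trial).
    Returns the inner join plus a report of dropped keys.
    """
    for df, cols in ((sleep, {"mouse", "day"}), (behavior, {"mouse", "day", "trial"})):
        if not cols.issubset(df.columns):
            raise InvalidArgumentError(f"missing key columns {cols - set(df.columns)}")
    s = sleep.copy()
    s["_behavior_day"] = s["day"] + day_offset
    merged = behavior.merge(
        s.drop(columns=["day"]).rename(columns={"_behavior_day": "day"}),
        on=["mouse", "day"],
        how="inner",
        suffixes=("", "_sleep"),
    )
    if merged.empty:
        raise NoOverlapError("sleep/behavior join produced no rows")
    beh_keys = set(zip(behavior["mouse"], behavior["day"]))
    sleep_keys = set(zip(s["mouse"], s["_behavior_day"]))
    report = {
        "n_rows": len(merged),
        "dropped_behavior_days": sorted(beh_keys - sleep_keys),
        "dropped_sleep_days": sorted(sleep_keys - beh_keys),
    }
    return merged, report


def correlate_occupancy_activity(
    table: pd.DataFrame,
    activity_col: str = "nrem_activity",
    n_clusters: int = 36,
    occupancy_prefix: str = "occ_",
) -> pd.DataFrame:
    """Per-cluster Pearson r (two-sided p, Bonferroni over ``n_clusters``)
    between sleep activity and next-day cluster occupancy, pooled across
    rows. Zero-variance clusters report NaN."""
    if len(table) < 5:
        raise InsufficientDataError("need at least 5 rows")
    act = table[activity_col].to_numpy(dtype=float)
    rows = []
    for k in range(n_clusters):
        col = f"{occupancy_prefix}{k}"
        occ = table[col].to_numpy(dtype=float) if col in table.columns else None
        if occ is None or np.std(occ) < 1e-15 or np.std(act) < 1e-15:
            rows.append({"cluster": k, "r": np.nan, "p_raw": np.nan,
                         "p_bonferroni": np.nan, "n": len(table)})
            continue
        r, p = stats.pearsonr(act, occ)
        rows.append({"cluster": k, "r": float(r), "p_raw": float(p),
                     "p_bonferroni": bonferroni(p, n_clusters), "n": len(table)})
    return pd.DataFrame(rows)


def quartile_speed_comparison(
    table: pd.DataFrame,
    activity_col: str = "nrem_activity",
    speed_col: str = "visit_speed",
    n_comparisons: int = 1,
) -> dict:
    """Pooled port-visit speeds of the lower vs upper quartile of mouse-days
    ranked by sleep activity, compared with a two-sided Mann-Whitney U.

    ``table`` has one row per visit with (mouse, day, activity, speed).
    """
    days = (
        table[["mouse", "day", activity_col]]
        .drop_duplicates(subset=["mouse", "day"])
        .reset_index(drop=True)
    )
    if len(days) < 8:
        raise InsufficientDataError("need at least 8 mouse-days")
    q1, q3 = np.percentile(days[activity_col], [25, 75])
    low_days = days[days[activity_col] <= q1]
    high_days = days[days[activity_col] >= q3]
    if len(low_days) < 2 or len(high_days) < 2:
        raise InsufficientDataError("fewer than 2 days per quartile")

    def _pool(sel: pd.DataFrame) -> np.ndarray:
        keys = set(zip(sel["mouse"], sel["day"]))
        m = [((mo, dy) in keys) for mo, dy in zip(table["mouse"], table["day"])]
        v = table.loc[m, speed_col].to_numpy(dtype=float)
        return v[np.isfinite(v)]

    low = _pool(low_days)
    high = _pool(high_days)
    if low.size == 0 or high.size == 0:
        raise InsufficientDataError("no visit speeds in one of the quartiles")
    method = "exact" if max(low.size, high.size) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(low, high, alternative="two-sided", method=method)
    return {
        "low_speeds": low,
        "high_speeds": high,
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "p_adjusted": bonferroni(res.pvalue, n_comparisons),
        "n_low_days": len(low_days),
        "n_high_days": len(high_days),
    }


def group_compare(
    values_a,
    values_b,
    test: str = "t",
    n_comparisons: int = 1,
) -> dict:
    """Two-sided t or Mann-Whitney U comparison with Bonferroni adjustment."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least 2 values")
    if test == "t":
        if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
            if np.mean(a) == np.mean(b):
                stat, p = 0.0, 1.0
            else:
                raise InvalidArgumentError(
                    "degenerate variance for t-test; use test='MWU'"
                )
        else:
            stat, p = stats.ttest_ind(a, b)
    elif test.upper() == "MWU":
        method = "exact" if max(a.size, b.size) <= 20 else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat, p = res.statistic, res.pvalue
    else:
        raise InvalidArgumentError(f"unknown test {test!r}")
    return {
        "statistic": float(stat),
        "p": float(p),
        "p_adjusted": bonferroni(float(p), n_comparisons),
    }


def logit(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


def coupling_recovery_table(ground_truth: dict) -> pd.DataFrame:
    """Per mouse-day slow-visit fractions paired with the preceding day's
    true standardized NREM activity (from synth_multiday_experiment output)."""
    visits = ground_truth["true_visits"]
    act = ground_truth["true_nrem_activity"].set_index(["mouse", "day"])["standardized"]
    rows = []
    for (m, d), g in visits.groupby(["mouse", "day"]):
        if d == 0:
            continue  # day-0 trials have no preceding sleep
        rows.append(
            {
                "mouse": m,
                "day": d,
                "n_slow": int((g["motif"] == "slow").sum()),
                "n_visits": len(g),
                "activity": float(act.loc[(m, d - 1)]),
            }
        )
    return pd.DataFrame(rows)


def recover_coupling(
    table: pd.DataFrame,
    true_coupling: float | None = None,
    n_boot: int = 500,
    seed: int = 0,
) -> dict:
    """OLS slope of the logit slow-visit fraction on standardized activity.

    ``table`` needs ``activity`` plus either ``slow_frac`` (used as-is) or
    counts ``n_slow``/``n_visits`` (continuity-corrected). Returns the slope,
    a bootstrap percentile CI and, when ``true_coupling`` is given, the bias.
    """
    if len(table) == 0 or ("n_visits" in table.columns and table["n_visits"].sum() == 0):
        raise InsufficientDataError("no visits to estimate coupling from")
    if "slow_frac" in table.columns:
        frac = table["slow_frac"].to_numpy(dtype=float)
        frac = np.clip(frac, 1e-9, 1 - 1e-9)
    else:
        frac = (table["n_slow"] + 0.5) / (table["n_visits"] + 1.0)
    y = logit(frac)
    x = table["activity"].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise InsufficientDataError("activity has zero variance")

    def _slope(xx, yy):
        c = np.polynomial.polynomial.polyfit(xx, yy, 1)
        return float(c[1])

    slope = _slope(x, y)
    rng = np.random.default_rng(seed)
    boots = []
    n = x.size
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if np.std(x[idx]) == 0:
            continue
        boots.append(_slope(x[idx], y[idx]))
    ci = (
        tuple(np.percentile(boots, [2.5, 97.5])) if boots else (np.nan, np.nan)
    )
    out = {"coupling": slope, "ci_low": float(ci[0]), "ci_high": float(ci[1])}
    if true_coupling is not None:
        out["bias"] = slope - true_coupling
    return out
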