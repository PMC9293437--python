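"""Absolute uptake partitioning and the season-level statistical analyses.

Posterior mean source proportions are multiplied by ground-area
transpiration to give the absolute water extracted from each soil layer
(mm d⁻¹).  Short observation gaps are filled by linear interpolation of
the proportions (renormalised to the simplex).  Weekly periods — the
first drought week, the last drought week and a post-drought week —
support the repeated-measures comparison; Pearson correlation tables
relate per-layer uptake series to total transpiration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PeriodDefinition",
    "absolute_uptake",
    "fill_gap",
    "percent_change",
    "ratio",
    "correlation_table",
    "compare_periods",
]


@dataclass(frozen=True)
class PeriodDefinition:
    """Three 7-day windows: drought onset (I), drought end (II), recovery (III)."""

    period_i: tuple[pd.Timestamp, pd.Timestamp]
    period_ii: tuple[pd.Timestamp, pd.Timestamp]
    period_iii: tuple[pd.Timestamp, pd.Timestamp]

    def __post_init__(self) -> None:
        windows = [self.period_i, self.period_ii, self.period_iii]
        for lo, hi in windows:
            if (hi - lo).days != 6:
                raise ValueError("each period must span exactly 7 days")
        for (a, b), (c, d) in itertools.combinations(windows, 2):
            if a <= d and c <= b:
                raise ValueError("periods must not overlap")

    @classmethod
    def from_drought(
        cls,
        drought_start: pd.Timestamp,
        drought_end: pd.Timestamp,
        season_end: pd.Timestamp,
        recovery_offset_days: int | None = None,
    ) -> "PeriodDefinition":
        """Anchor the windows to a drought segmentation.

        Period I: first 7 drought days.  Period II: last 7 days before
        the drought end.  Period III: by default the last 7 observed
        days; with ``recovery_offset_days`` given, the 7-day window
        starting that many days after the drought end.
        """
        start = pd.Timestamp(drought_start)
        end = pd.Timestamp(drought_end)
        p1 = (start, start + pd.Timedelta(days=6))
        p2 = (end - pd.Timedelta(days=7), end - pd.Timedelta(days=1))
        if recovery_offset_days is None:
            p3 = (pd.Timestamp(season_end) - pd.Timedelta(days=6), pd.Timestamp(season_end))
        else:
            lo = end + pd.Timedelta(days=recovery_offset_days)
            p3 = (lo, lo + pd.Timedelta(days=6))
        return cls(p1, p2, p3)

    def label(self, dates: pd.DatetimeIndex) -> pd.Series:
        """Period label ('I'/'II'/'III' or '') per date."""
        out = pd.Series("", index=dates)
        for name, (lo, hi) in zip(("I", "II", "III"), (self.period_i, self.period_ii, self.period_iii)):
            out[(dates >= lo) & (dates <= hi)] = name
        return out


def absolute_uptake(
    proportions: pd.DataFrame,
    transpiration: pd.Series,
    proportion_sd: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-layer absolute uptake U_k = p̄_k · E (mm d⁻¹).

    ``proportions`` is a (date × layer) frame of posterior means on the
    simplex; ``transpiration`` the matching daily ground-area E.
    Posterior SDs, when given, propagate first-order: SD(U_k) = SD(p_k)·E.
    Returns a tidy frame (date, layer, p_mean, uptake_mm, [uptake_sd]).
    """
    idx = proportions.index.intersection(transpiration.index)
    if len(idx) == 0:
        raise ValueError("proportions and transpiration share no dates")
    e = transpiration.loc[idx].astype(float)
    if (e < 0).any():
        raise ValueError("transpiration must be non-negative")
    p = proportions.loc[idx]
    rows = []
    for layer in p.columns:
        frame = pd.DataFrame(
            {
                "date": idx,
                "layer": layer,
                "p_mean": p[layer].to_numpy(),
                "e_mm": e.to_numpy(),
                "uptake_mm": p[layer].to_numpy() * e.to_numpy(),
            }
        )
        if proportion_sd is not None:
            frame["uptake_sd"] = proportion_sd.loc[idx, layer].to_numpy() * e.to_numpy()
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def fill_gap(proportions: pd.DataFrame, gap_dates: pd.DatetimeIndex) -> pd.DataFrame:
    """Fill missing days by linear interpolation of the flanking proportions.

    The interpolated vectors are renormalised to the simplex; the gap must
    be strictly inside the observed range (no extrapolation).  Returns the
    augmented frame with a boolean ``filled`` column.
    """
    gap_dates = pd.DatetimeIndex(gap_dates)
    obs = proportions.sort_index()
    if len(gap_dates) == 0:
        out = obs.copy()
        out["filled"] = False
        return out
    if gap_dates.min() <= obs.index.min() or gap_dates.max() >= obs.index.max():
        raise ValueError("gap must be bounded by observed days on both sides")
    if not gap_dates.intersection(obs.index).empty:
        raise ValueError("gap dates overlap observed days")
    full = obs.reindex(obs.index.union(gap_dates)).sort_index()
    interp = full.interpolate(method="time")
    interp = interp.div(interp.sum(axis=1), axis=0)
    interp["filled"] = interp.index.isin(gap_dates)
    return interp


def percent_change(before: float, after: float) -> int:
    """Percent reduction 100·(1 − after/before), nearest integer."""
    if before <= 0:
        raise ValueError("'before' must be positive")
    return round(100.0 * (1.0 - after / before))


def ratio(before: float, after: float) -> float:
    """Drop factor before/after, one decimal."""
    if after <= 0:
        raise ValueError("'after' must be positive")
    return round(before / after, 1)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return ""


def correlation_table(
    series_by_depth: pd.DataFrame,
    transpiration: pd.Series,
    period_mask: pd.Series | None = None,
) -> pd.DataFrame:
    """Upper-triangle Pearson correlation matrix across depths + transpiration.

    ``series_by_depth`` holds one column per soil layer (relative or
    absolute uptake); the total-transpiration column is appended.  Cells
    report r with significance stars (** P < 0.01, *** P < 0.001);
    correlations against a constant series are reported as NaN.
    Returns a tidy frame (row, col, r, p, stars, n).
    """
    df = series_by_depth.copy()
    df["transpiration"] = transpiration
    if period_mask is not None:
        df = df.loc[period_mask.reindex(df.index, fill_value=False)]
    df = df.dropna()
    cols = list(df.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            x, y = df[a].to_numpy(float), df[b].to_numpy(float)
            if len(x) < 3:
                raise ValueError(f"fewer than 3 paired days for ({a}, {b})")
            if np.std(x) == 0 or np.std(y) == 0:
                r, p = float("nan"), float("nan")
            else:
                r, p = stats.pearsonr(x, y)
            rows.append({"row": a, "col": b, "r": float(r), "p": float(p), "stars": _stars(p) if np.isfinite(p) else "", "n": len(x)})
    return pd.DataFrame(rows)


def _compact_letters(levels: list[str], distinct: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display by insert-and-absorb over significant pairs."""
    groups: list[set[str]] = [set(levels)]
    for a, b in sorted(distinct):
        new_groups: list[set[str]] = []
        for g in groups:
            if a in g and b in g:
                new_groups.extend(({x for x in g if x != b}, {x for x in g if x != a}))
            else:
                new_groups.append(g)
        # absorb subsets
        groups = [g for g in new_groups if not any(g < h for h in new_groups)]
        seen: list[set[str]] = []
        for g in groups:
            if g not in seen:
                seen.append(g)
        groups = seen
    order = {lvl: i for i, lvl in enumerate(levels)}
    groups.sort(key=lambda g: min(order[lvl] for lvl in g))
    letters = {lvl: "" for lvl in levels}
    for letter, g in zip("ABCDEFGH", groups):
        for lvl in g:
            letters[lvl] += letter
    return {lvl: "".join(sorted(v)) for lvl, v in letters.items()}


def compare_periods(weekly_means: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Repeated-measures ANOVA with Tukey HSD letters over the three periods.

    ``weekly_means`` is a tidy frame with columns ``tree``, ``period`` and
    ``value``: one weekly mean per tree per period (balanced
    within-subject design; an incomplete cell raises).  The Tukey
    comparison uses the within-subject (tree × period interaction) error
    term of the RM-ANOVA; significance letters share a character when the
    periods do not differ at ``alpha``.
    """
    required = {"tree", "period", "value"}
    if not required <= set(weekly_means.columns):
        raise ValueError(f"weekly_means needs columns {sorted(required)}")
    pivot = weekly_means.pivot_table(index="tree", columns="period", values="value")
    if pivot.isna().any().any():
        missing = [(t, p) for t in pivot.index for p in pivot.columns if pd.isna(pivot.loc[t, p])]
        raise ValueError(f"unbalanced design, missing cells: {missing}")
    data = pivot.to_numpy(float)
    n_subj, n_per = data.shape
    if n_per < 2 or n_subj < 2:
        raise ValueError("need at least two periods and two subjects")

    grand = data.mean()
    subj_means = data.mean(axis=1, keepdims=True)
    per_means = data.mean(axis=0, keepdims=True)
    ss_period = n_subj * float(np.sum((per_means - grand) ** 2))
    ss_error = float(np.sum((data - subj_means - per_means + grand) ** 2))
    df_period = n_per - 1
    df_error = (n_subj - 1) * (n_per - 1)
    ms_period = ss_period / df_period
    ms_error = ss_error / df_error if df_error > 0 else float("nan")
    if ms_error == 0:
        f_stat, p_value = float("nan"), 1.0
    else:
        f_stat = ms_period / ms_error
        p_value = float(stats.f.sf(f_stat, df_period, df_error))

    periods = list(pivot.columns)
    distinct: set[tuple[str, str]] = set()
    pairwise = []
    for a, b in itertools.combinations(periods, 2):
        diff = abs(pivot[a].mean() - pivot[b].mean())
        if ms_error > 0:
            q = diff / np.sqrt(ms_error / n_subj)
            p_adj = float(stats.studentized_range.sf(q, n_per, df_error))
        else:
            p_adj = 0.0 if diff > 0 else 1.0
        pairwise.append({"a": a, "b": b, "diff": diff, "p_adj": p_adj})
        if p_adj < alpha:
            distinct.add((a, b))
    letters = _compact_letters(periods, distinct)
    return {
        "f": f_stat,
        "p": p_value,
        "df": (df_period, df_error),
        "pairwise": pd.DataFrame(pairwise),
        "letters": letters,
    }
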