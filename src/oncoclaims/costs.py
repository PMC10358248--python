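"""Monthly cost aggregation and resource-category breakdown.

A cost "month" is a 30-day half-open window anchored at the episode start:
window k covers [start + 30(k-1), start + 30k).  A patient contributes
month k only when the full window fits inside the episode (episodes
shorter than 30 days contribute no cost months), and at most six months
are counted per episode.  Claim lines are binned into six resource
categories by the two-digit prefix of their clinical identification code.
Costs are kept in JPY throughout and converted to USD only when
summarized.

OS is excluded from the month-by-month analysis; it appears only in the
per-episode cumulative reference totals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CATEGORIES, MONTHLY_EPISODE_KINDS, AnalysisConfig, code_to_category
from .core import ClaimsDataset, jpy_to_usd

__all__ = [
    "month_windows",
    "monthly_costs",
    "summarize_costs",
    "category_shares",
    "episode_totals",
]

_DAY = pd.Timedelta(days=1)


def month_windows(start, end, config: AnalysisConfig | None = None):
    """Ordered full 30-day windows of one episode.

    Returns a list of (month_index, window_start, window_end) with
    half-open [window_start, window_end) ranges; empty when the episode is
    shorter than one month.
    """
    config = config or AnalysisConfig()
    ml = config.month_length_days
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    dur = (end - start).days
    n = min(config.cost_horizon_months, dur // ml)
    return [
        (k, start + (k - 1) * ml * _DAY, start + k * ml * _DAY)
        for k in range(1, n + 1)
    ]


def _window_table(episodes: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    rows = []
    for t in episodes.itertuples(index=False):
        if t.kind not in MONTHLY_EPISODE_KINDS:
            continue
        for k, ws, we in month_windows(t.start, t.end, config):
            rows.append((t.patient_id, t.kind, k, ws, we))
    return pd.DataFrame(
        rows, columns=["patient_id", "episode_kind", "month", "wstart", "wend"]
    )


def monthly_costs(
    ds: ClaimsDataset,
    episodes: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-patient monthly cost cells with six-category breakdown.

    One row per (patient, episode kind, month) for every full 30-day
    window, with the six category columns and ``total_jpy`` (zero-filled
    when no claims fall in the window).  Every claim line is attributed to
    at most one window; overlapping windows for the same patient raise a
    RuntimeError.
    """
    config = config or AnalysisConfig()
    windows = _window_table(episodes, config)
    base = windows[["patient_id", "episode_kind", "month"]].copy()
    if windows.empty:
        out = base
        for c in CATEGORIES:
            out[c] = np.int64(0)
        out["total_jpy"] = np.int64(0)
        return out

    claims = ds.claim_lines.reset_index(drop=True).reset_index(names="claim_no")
    merged = claims.merge(windows, on="patient_id", how="inner")
    inwin = merged[
        (merged["service_date"] >= merged["wstart"])
        & (merged["service_date"] < merged["wend"])
    ]
    dup = inwin["claim_no"].duplicated()
    if dup.any():
        raise RuntimeError(
            "overlapping episode windows: a claim line maps to multiple cells"
        )
    inwin = inwin.copy()
    inwin["category"] = inwin["code_category"].map(code_to_category)
    cells = (
        inwin.groupby(["patient_id", "episode_kind", "month", "category"])[
            "cost_jpy"
        ]
        .sum()
        .unstack("category", fill_value=0)
        .reindex(columns=list(CATEGORIES), fill_value=0)
        .reset_index()
    )
    out = base.merge(
        cells, on=["patient_id", "episode_kind", "month"], how="left"
    ).fillna(0)
    for c in CATEGORIES:
        out[c] = out[c].astype(np.int64)
    out["total_jpy"] = out[list(CATEGORIES)].sum(axis=1)
    return out.sort_values(
        ["patient_id", "episode_kind", "month"], kind="mergesort"
    ).reset_index(drop=True)


def summarize_costs(
    monthly: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Descriptive statistics of per-patient monthly totals, in USD.

    Grouped by (episode kind, month) — and by regimen ``label`` first if
    that column is present (the published table layout).  Columns: N,
    mean, sd, min, median, max; sd is the sample standard deviation and 0
    by convention for singleton cells.  Cells with no patients are simply
    absent.
    """
    config = config or AnalysisConfig()
    keys = [k for k in ("label", "episode_kind", "month") if k in monthly.columns]
    usd = jpy_to_usd(monthly["total_jpy"].to_numpy(), config)
    df = monthly[keys].copy()
    df["usd"] = usd
    g = df.groupby(keys)["usd"]
    out = g.agg(
        N="count",
        mean="mean",
        sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0,
        min="min",
        median="median",
        max="max",
    ).reset_index()
    return out


def category_shares(
    monthly: pd.DataFrame,
    config: AnalysisConfig | None = None,
    episode_kind: str = "PFS1",
) -> pd.DataFrame:
    """Six-category percentage split of monthly costs, per regimen and
    month, over the first ``share_horizon_months`` months of one episode
    kind (first-line treatment by default).

    ``monthly`` must carry a ``label`` column (first-line regimen).  Shares
    are pooled across patients: share_c = sum of category c / sum of
    totals x 100, so each cell's shares sum to 100.  Cells with zero total
    cost are omitted.
    """
    config = config or AnalysisConfig()
    if "label" not in monthly.columns:
        raise ValueError("monthly table must carry a first-line 'label' column")
    sub = monthly[
        (monthly["episode_kind"] == episode_kind)
        & (monthly["month"] <= config.share_horizon_months)
    ]
    sums = sub.groupby(["label", "month"])[list(CATEGORIES) + ["total_jpy"]].sum()
    sums = sums[sums["total_jpy"] > 0]
    shares = sums[list(CATEGORIES)].div(sums["total_jpy"], axis=0) * 100.0
    return shares.reset_index()


def episode_totals(
    ds: ClaimsDataset,
    episodes: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Cumulative cost and duration per episode, including OS (reference
    totals: no one-month minimum, no six-month cap).

    Episodes followed by another episode (PFS1, PD1) absorb claims over
    the half-open [start, end); terminal episodes (TC, PFS2, OS) include
    their end date, so OS absorbs every claim from the index date to the
    end of follow-up.
    """
    config = config or AnalysisConfig()
    cl_by = {pid: sub for pid, sub in ds.claim_lines.groupby("patient_id")}
    empty = ds.claim_lines.iloc[0:0]
    rows = []
    for t in episodes.itertuples(index=False):
        sub = cl_by.get(t.patient_id, empty)
        inclusive_end = t.kind in ("TC", "PFS2", "OS")
        upper = (
            (sub["service_date"] <= t.end)
            if inclusive_end
            else (sub["service_date"] < t.end)
        )
        total = int(sub.loc[(sub["service_date"] >= t.start) & upper, "cost_jpy"].sum())
        rows.append(
            {
                "patient_id": t.patient_id,
                "kind": t.kind,
                "start": t.start,
                "end": t.end,
                "duration_days": int((t.end - t.start).days),
                "total_cost_jpy": total,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "kind",
            "start",
            "end",
            "duration_days",
            "total_cost_jpy",
        ],
    )
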