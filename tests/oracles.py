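"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately avoid the vectorized pandas paths of the package:
the episode oracle walks the calendar day by day, and the cost oracle
re-derives summary statistics from raw claim lines with the statistics
module.  They must stay independent of the implementations they check.
"""

from __future__ import annotations

import datetime
import statistics

import pandas as pd

_ONE = datetime.timedelta(days=1)


def day_scan_episodes(ds, patient_id, dx_date, config):
    """Day-resolution episode segmentation for one patient.

    Iterates calendar days, tracking indicated-drug events, the 28-day
    combination window, the restart/switch rule and oral day supply by
    explicit counting.  Returns {kind: (start, end)} using date objects,
    or None when no first-line therapy exists.
    """
    dd = ds.drug_dictionary.set_index("drug_id")
    rx = ds.prescriptions[ds.prescriptions["patient_id"] == patient_id]
    indicated = {
        d
        for d in rx["drug_id"].unique()
        if dd.loc[d, "pancreatic_indication"] and dd.loc[d, "component"] != "supportive"
    }
    events: dict[datetime.date, list] = {}
    for r in rx.itertuples(index=False):
        if r.drug_id in indicated:
            events.setdefault(r.date.date(), []).append(
                (r.drug_id, r.route, float(r.quantity))
            )
    pat = ds.patients.set_index("patient_id").loc[patient_id]
    lfu = pat["last_follow_up"].date()
    death = None if pd.isna(pat["death_date"]) else pat["death_date"].date()
    dx = pd.Timestamp(dx_date).date()

    anchor = None
    d = dx
    while d <= dx + config.regimen_initiation_window_days * _ONE:
        if d in events:
            anchor = d
            break
        d += _ONE
    if anchor is None:
        return None

    first_seen: dict[str, datetime.date] = {}
    d = anchor
    while d <= lfu:
        for drug, _, _ in events.get(d, []):
            first_seen.setdefault(drug, d)
        d += _ONE
    components = {
        drug
        for drug, day in first_seen.items()
        if day <= anchor + config.combination_window_days * _ONE
    }

    switch = None
    d = anchor + _ONE
    while d <= lfu:
        if any(drug not in components for drug, _, _ in events.get(d, [])):
            switch = d
            break
        d += _ONE

    def line_end(drugs, lo, hi_exclusive):
        end = None
        for drug in drugs:
            last_day, last_route, last_qty = None, None, None
            d = lo
            while d <= lfu and (hi_exclusive is None or d < hi_exclusive):
                for g, route, qty in events.get(d, []):
                    if g == drug:
                        if last_day is None or d > last_day or qty > last_qty:
                            last_day, last_route, last_qty = d, route, qty
                d += _ONE
            if last_day is None:
                continue
            if last_route == "oral":
                dose = float(dd.loc[drug, "standard_daily_dose"])
                cover = 0
                while (cover + 1) * dose <= last_qty:
                    cover += 1
                cand = last_day + cover * _ONE
            else:
                cand = last_day
            end = cand if end is None else max(end, cand)
        return min(end, lfu)

    pfs1_end = line_end(components, anchor, switch)
    if switch is not None and pfs1_end > switch:
        pfs1_end = switch

    out = {"PFS1": (anchor, pfs1_end)}
    if switch is None:
        out["TC"] = (pfs1_end, lfu)
    else:
        out["PD1"] = (pfs1_end, switch)
        comp2 = set()
        d = switch
        while d <= min(lfu, switch + config.combination_window_days * _ONE):
            for drug, _, _ in events.get(d, []):
                comp2.add(drug)
            d += _ONE
        out["PFS2"] = (switch, line_end(comp2, switch, None))
    os_end = lfu if death is None else min(death, lfu)
    out["OS"] = (anchor, os_end)
    return out


def brute_force_cost_summary(ds, episodes, config):
    """Recompute the monthly cost table cell statistics from raw claim
    lines, without the cost engine.

    Returns {(kind, month): {"N", "mean", "sd", "min", "median", "max"}}
    in USD, over full 30-day windows capped at six months.
    """
    claims_by: dict[str, list] = {}
    for r in ds.claim_lines.itertuples(index=False):
        claims_by.setdefault(r.patient_id, []).append(
            (r.service_date.date(), int(r.cost_jpy))
        )
    cells: dict[tuple, list[float]] = {}
    for e in episodes.itertuples(index=False):
        if e.kind not in ("PFS1", "PD1", "TC", "PFS2"):
            continue
        start, end = e.start.date(), e.end.date()
        k = 1
        while (
            k <= config.cost_horizon_months
            and start + k * 30 * _ONE <= end
        ):
            lo = start + (k - 1) * 30 * _ONE
            hi = start + k * 30 * _ONE
            total = sum(
                c
                for d, c in claims_by.get(e.patient_id, [])
                if lo <= d < hi
            )
            cells.setdefault((e.kind, k), []).append(total / config.jpy_per_usd)
            k += 1
    out = {}
    for key, vals in cells.items():
        out[key] = {
            "N": len(vals),
            "mean": statistics.fmean(vals),
            "sd": statistics.stdev(vals) if len(vals) > 1 else 0.0,
            "min": min(vals),
            "median": statistics.median(vals),
            "max": max(vals),
        }
    return out
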