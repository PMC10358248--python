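"""Descriptive reports and the end-to-end pipeline.

Covers the study's output shapes: cohort attrition, first-line regimen
shares, transition flows to second-line therapy vs best supportive care,
baseline characteristics per regimen, monthly cost tables and resource
category shares.  All percentages are rounded half-up to one decimal (the
printed style; banker's rounding would differ on ties).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .config import RECOMMENDED_REGIMENS, REGIMENS, AnalysisConfig
from .core import ClaimsDataset, read_claims_dataset
from .cohort import AttritionReport, select_cohort
from .costs import category_shares, episode_totals, monthly_costs, summarize_costs
from .episodes import build_cohort_episodes
from .regimens import assignments_frame

__all__ = [
    "round_half_up",
    "pattern_from_counts",
    "TreatmentPatternReport",
    "treatment_pattern_report",
    "characteristics_table",
    "run_pipeline",
    "PipelineResult",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 -> 0.1), matching printed percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _pct(n: int, d: int) -> float:
    return round_half_up(100.0 * n / d) if d else 0.0


def pattern_from_counts(
    arm_sizes: dict[str, int],
    bsc_counts: dict[str, int],
    second_line_counts: dict[str, dict[str, int]] | None = None,
    total_first_line: int | None = None,
) -> dict:
    """Treatment-pattern percentages as pure count arithmetic.

    ``arm_sizes`` maps first-line regimen to N; ``bsc_counts`` to the
    number routed to best supportive care.  Overall second-line/BSC
    percentages are computed over the recommended-regimen arms only
    (FFX, GnP, GEM, S1); first-line shares use ``total_first_line`` as
    denominator (defaults to the sum of all arms).  All percentages are
    half-up to one decimal.
    """
    total = total_first_line or sum(arm_sizes.values())
    out: dict = {
        "first_line_n": dict(arm_sizes),
        "first_line_pct": {r: _pct(n, total) for r, n in arm_sizes.items()},
        "bsc_n": dict(bsc_counts),
        "bsc_pct": {},
        "second_line_pct": {},
        "second_line_mix_pct": {},
    }
    for r, n in arm_sizes.items():
        bsc = bsc_counts.get(r, 0)
        out["bsc_pct"][r] = _pct(bsc, n)
        out["second_line_pct"][r] = _pct(n - bsc, n)
    rec = [r for r in RECOMMENDED_REGIMENS if r in arm_sizes]
    denom = sum(arm_sizes[r] for r in rec)
    n_bsc = sum(bsc_counts.get(r, 0) for r in rec)
    out["overall_bsc_pct"] = _pct(n_bsc, denom)
    out["overall_second_line_pct"] = _pct(denom - n_bsc, denom)
    if second_line_counts:
        for r, dests in second_line_counts.items():
            d = sum(dests.values())
            out["second_line_mix_pct"][r] = {
                s: _pct(n, d) for s, n in dests.items()
            }
    return out


@dataclass
class TreatmentPatternReport:
    """First-line shares and post-first-line transition flows."""

    counts: dict

    def to_text(self) -> str:
        c = self.counts
        lines = ["First-line regimens:"]
        for r in REGIMENS:
            if r in c["first_line_n"]:
                lines.append(
                    f"  {r:<6} {c['first_line_n'][r]:>6d}  "
                    f"{c['first_line_pct'][r]:>5.1f}%"
                )
        lines.append(
            f"Overall (recommended arms): second line "
            f"{c['overall_second_line_pct']:.1f}%, BSC {c['overall_bsc_pct']:.1f}%"
        )
        for r in RECOMMENDED_REGIMENS:
            if r not in c["first_line_n"]:
                continue
            lines.append(
                f"  {r:<6} BSC {c['bsc_n'].get(r, 0):>5d} ({c['bsc_pct'][r]:.1f}%)"
            )
            for s, p in sorted(c["second_line_mix_pct"].get(r, {}).items()):
                lines.append(f"         -> {s:<6} {p:.1f}%")
        return "\n".join(lines)


def treatment_pattern_report(
    cohort: pd.DataFrame,
    assignments,
    episodes: pd.DataFrame | None = None,
) -> TreatmentPatternReport:
    """Transition-flow report from per-patient assignments.

    A patient routes to BSC iff no second-line assignment exists (a TC
    episode is present); the denominator for overall transition
    percentages is the four recommended arms, excluding OTHER.
    """
    first = {a.patient_id: a.label for a in assignments if a.line == 1}
    second = {a.patient_id: a.label for a in assignments if a.line == 2}
    arm_sizes = {r: 0 for r in REGIMENS}
    bsc = {r: 0 for r in REGIMENS}
    mix: dict[str, dict[str, int]] = {}
    for pid, label in first.items():
        arm_sizes[label] += 1
        if pid in second:
            mix.setdefault(label, {})
            mix[label][second[pid]] = mix[label].get(second[pid], 0) + 1
        else:
            bsc[label] += 1
    arm_sizes = {r: n for r, n in arm_sizes.items() if n}
    return TreatmentPatternReport(
        counts=pattern_from_counts(
            arm_sizes,
            {r: bsc[r] for r in arm_sizes},
            {r: mix[r] for r in mix},
        )
    )


def characteristics_table(
    cohort: pd.DataFrame,
    ds: ClaimsDataset,
    assignments,
    characteristics: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Baseline characteristics per first-line regimen.

    Returns a dict of small tables: summary (N, %), age (median/range,
    65-and-over split), sex, dx_year (per-year row-wise denominators, so
    each year's percentages sum to 100 across regimens), and — when a
    descriptive ``characteristics`` frame (weight_kg, bmi, stage,
    location, comorbidities) is supplied — weight, bmi, stage, location
    and comorbidity tables.  These descriptive fields are pass-through
    columns; no analysis logic attaches to them.
    """
    first = {a.patient_id: a for a in assignments if a.line == 1}
    pat = ds.patients.set_index("patient_id")
    dx = cohort.set_index("patient_id")["first_confirmed_diagnosis_date"]
    rows = []
    for pid, a in first.items():
        year = int(dx.loc[pid].year)
        age = year - int(pat.loc[pid, "birth_year"])
        rows.append(
            {
                "patient_id": pid,
                "label": a.label,
                "age": age,
                "sex": pat.loc[pid, "sex"],
                "dx_year": year,
            }
        )
    df = pd.DataFrame(rows)
    if characteristics is not None:
        df = df.merge(characteristics, on="patient_id", how="left")

    total = len(df)
    out: dict[str, pd.DataFrame] = {}
    g = df.groupby("label")
    out["summary"] = pd.DataFrame(
        {
            "N": g.size(),
            "pct": [ _pct(n, total) for n in g.size() ],
        }
    )
    out["age"] = g["age"].agg(median="median", min="min", max="max").join(
        pd.DataFrame(
            {
                "n_ge65": g.apply(lambda s: int((s["age"] >= 65).sum()),
                                  include_groups=False),
                "n_lt65": g.apply(lambda s: int((s["age"] < 65).sum()),
                                  include_groups=False),
            }
        )
    )
    out["age"]["pct_ge65"] = [
        _pct(r.n_ge65, r.n_ge65 + r.n_lt65) for r in out["age"].itertuples()
    ]
    out["sex"] = pd.DataFrame(
        {
            "n_male": g.apply(lambda s: int((s["sex"] == "male").sum()),
                              include_groups=False),
            "n_female": g.apply(lambda s: int((s["sex"] == "female").sum()),
                                include_groups=False),
        }
    )
    out["sex"]["pct_male"] = [
        _pct(r.n_male, r.n_male + r.n_female) for r in out["sex"].itertuples()
    ]

    # per-year rows: the denominator is the total number of patients that
    # year, so percentages sum to 100 across regimens within a row
    year_counts = df.pivot_table(
        index="dx_year", columns="label", aggfunc="size", fill_value=0
    )
    year_pct = year_counts.div(year_counts.sum(axis=1), axis=0) * 100.0
    out["dx_year_n"] = year_counts
    out["dx_year_pct"] = year_pct.map(round_half_up)

    if characteristics is not None:
        out["weight"] = g["weight_kg"].agg(
            n="count", mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0
        )
        bands = pd.cut(
            df["bmi"],
            bins=[-float("inf"), 18.5, 25.0, float("inf")],
            right=False,
            labels=["<18.5", "18.5-25", ">=25"],
        )
        out["bmi"] = df.assign(band=bands).pivot_table(
            index="band", columns="label", aggfunc="size", fill_value=0,
            observed=False,
        )
        for col in ("stage", "location"):
            out[col] = df.pivot_table(
                index=col, columns="label", aggfunc="size", fill_value=0
            )
        out["comorbidity"] = pd.DataFrame(
            {
                "chronic_pancreatitis": g["chronic_pancreatitis"].sum(),
                "t2dm": g["t2dm"].sum(),
            }
        ).astype(int)
    return out


@dataclass
class PipelineResult:
    """Everything the end-to-end pipeline produces."""

    cohort: pd.DataFrame
    attrition: AttritionReport
    assignments: list
    episodes: pd.DataFrame
    monthly: pd.DataFrame  # carries the first-line 'label' column
    cost_summary: pd.DataFrame
    shares: pd.DataFrame
    totals: pd.DataFrame
    patterns: TreatmentPatternReport


def run_pipeline(
    data, config: AnalysisConfig | None = None, out_dir=None
) -> PipelineResult:
    """Select -> classify -> segment -> aggregate -> report.

    ``data`` is a ClaimsDataset or a directory holding the CSV set.
    Deterministic given its inputs; when ``out_dir`` is given, writes
    cohort.csv, attrition.txt, regimens.csv, episodes.csv,
    monthly_costs.csv, cost_summary.csv, category_shares.csv,
    episode_totals.csv and treatment_patterns.txt.
    """
    config = config or AnalysisConfig()
    ds = data if isinstance(data, ClaimsDataset) else read_claims_dataset(data)

    cohort, attrition = select_cohort(ds, config)
    assignments, episodes = build_cohort_episodes(ds, cohort, config)
    monthly = monthly_costs(ds, episodes, config)
    first = pd.DataFrame(
        [
            {"patient_id": a.patient_id, "label": a.label}
            for a in assignments
            if a.line == 1
        ],
        columns=["patient_id", "label"],
    )
    monthly = monthly.merge(first, on="patient_id", how="left")
    summary = summarize_costs(monthly, config)
    shares = category_shares(monthly, config) if not monthly.empty else pd.DataFrame()
    totals = episode_totals(ds, episodes, config)
    patterns = treatment_pattern_report(cohort, assignments, episodes)

    result = PipelineResult(
        cohort=cohort,
        attrition=attrition,
        assignments=assignments,
        episodes=episodes,
        monthly=monthly,
        cost_summary=summary,
        shares=shares,
        totals=totals,
        patterns=patterns,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(res: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    kw = dict(index=False, lineterminator="\n")
    res.cohort.to_csv(out_dir / "cohort.csv", **kw)
    (out_dir / "attrition.txt").write_text(res.attrition.to_text() + "\n")
    assignments_frame(res.assignments).to_csv(out_dir / "regimens.csv", **kw)
    res.episodes.to_csv(out_dir / "episodes.csv", **kw)
    res.monthly.to_csv(out_dir / "monthly_costs.csv", **kw)
    res.cost_summary.to_csv(out_dir / "cost_summary.csv", **kw)
    res.shares.to_csv(out_dir / "category_shares.csv", **kw)
    res.totals.to_csv(out_dir / "episode_totals.csv", **kw)
    (out_dir / "treatment_patterns.txt").write_text(
        res.patterns.to_text() + "\n"
    )
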