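"""Synthetic claims simulator with planted ground truth.

Emulates the structure of a Japanese DPC-hospital claims extract for a
pancreatic-cancer chemotherapy cohort: first-line regimens drawn from a
configurable mix (FFX, GnP, GEM, S-1, other), cycle-structured prescription
streams, restart gaps inside a line, switches to a second-line regimen,
death or administrative censoring, and claim-line costs drawn per 30-day
month from lognormal distributions structured by resource category.

Every patient's intended cohort verdict, regimen labels, episode boundaries
and per-month per-category costs are recorded as ground truth so the whole
analysis pipeline can be verified by exact recovery.

Cost lines are dated inside the episode month that should absorb them, so
the cost engine's attribution is testable cell by cell.  Distractor records
(non-cancer diagnoses, supportive-care prescriptions, pre-treatment claim
lines) are dated outside every episode window.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .config import CATEGORIES, REGIMENS, AnalysisConfig
from .core import ClaimsDataset

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_dataset",
    "default_drug_dictionary",
    "write_ground_truth",
    "read_ground_truth",
]

_DAY = datetime.timedelta(days=1)

# -- drug dictionary and regimen plans ------------------------------------

#: (drug_id, ingredient, indicated, component, standard_daily_dose)
_DRUGS = [
    ("OXA", "oxaliplatin", True, "ffx", None),
    ("IRI", "irinotecan", True, "ffx", None),
    ("FU", "fluorouracil", True, "ffx", None),
    ("LV", "levofolinate", True, "ffx", None),
    ("GEM", "gemcitabine", True, "gemcitabine", None),
    ("NAB", "nab-paclitaxel", True, "nab_paclitaxel", None),
    ("TS1", "tegafur-gimeracil-oteracil", True, "s1", 4.0),
    ("ERL", "erlotinib", True, "erlotinib", 1.0),
    ("PAL", "palonosetron", False, "supportive", None),
    ("LOP", "loperamide", False, "supportive", None),
]

#: Per-regimen drug plan: (drug_id, route, interval_days).  Parenteral drugs
#: are administered every interval; oral drugs are dispensed every interval
#: with quantity = standard_daily_dose * interval (a full interval of supply).
REGIMEN_PLANS: dict[str, list[tuple[str, str, int]]] = {
    "FFX": [
        ("OXA", "parenteral", 14),
        ("IRI", "parenteral", 14),
        ("FU", "parenteral", 14),
        ("LV", "parenteral", 14),
    ],
    "GnP": [("GEM", "parenteral", 7), ("NAB", "parenteral", 7)],
    "GEM": [("GEM", "parenteral", 7)],
    "S1": [("TS1", "oral", 28)],
    # gemcitabine + erlotinib: guideline-suggested but grouped as "other"
    "OTHER": [("GEM", "parenteral", 7), ("ERL", "oral", 28)],
}

_BASE_INTERVAL = {"FFX": 14, "GnP": 7, "GEM": 7, "S1": 28, "OTHER": 7}

_DOSE = {d[0]: d[4] for d in _DRUGS}


def default_drug_dictionary() -> pd.DataFrame:
    return pd.DataFrame(
        _DRUGS,
        columns=[
            "drug_id",
            "ingredient",
            "pancreatic_indication",
            "component",
            "standard_daily_dose",
        ],
    ).astype({"standard_daily_dose": float})


def _plan_drugs(regimen: str) -> set[str]:
    return {d for d, _, _ in REGIMEN_PLANS[regimen]}


# -- configuration ---------------------------------------------------------


def _default_mix() -> dict[str, float]:
    # observed first-line shares in Japanese DPC practice, 2015-2018
    return {"GnP": 0.407, "GEM": 0.244, "S1": 0.213, "FFX": 0.071, "OTHER": 0.065}


def _default_p_second_line() -> dict[str, float]:
    # 1 - observed BSC conversion per arm
    return {"FFX": 0.517, "GnP": 0.348, "GEM": 0.297, "S1": 0.195, "OTHER": 0.30}


def _default_transitions() -> dict[str, dict[str, float]]:
    # second-line destination mix per first-line arm; transitions whose drug
    # set is contained in the first-line set are structurally undetectable
    # under the restart rule and carry probability 0
    return {
        "FFX": {"GnP": 0.752, "S1": 0.12, "GEM": 0.08, "OTHER": 0.048},
        "GnP": {"S1": 0.733, "FFX": 0.15, "OTHER": 0.117},
        "GEM": {"S1": 0.747, "GnP": 0.15, "FFX": 0.06, "OTHER": 0.043},
        "S1": {"GEM": 0.538, "GnP": 0.25, "FFX": 0.15, "OTHER": 0.062},
        "OTHER": {"S1": 0.5, "GnP": 0.3, "FFX": 0.2},
    }


def _default_cost_scale() -> dict[str, float]:
    # median monthly total cost scale, JPY (ordering GnP > FFX > GEM > S-1)
    return {
        "GnP": 780_000.0,
        "FFX": 700_000.0,
        "GEM": 347_000.0,
        "S1": 137_000.0,
        "OTHER": 350_000.0,
    }


def _default_category_shares() -> dict[str, dict[str, float]]:
    # medicines and hospitalization dominate intensive regimens; GEM/S-1
    # cost profiles are hospitalization-led
    return {
        "FFX": _share(med=0.47, hosp=0.39, admin=0.05, proc=0.04, exam=0.04),
        "GnP": _share(med=0.45, hosp=0.37, admin=0.06, proc=0.05, exam=0.05),
        "GEM": _share(med=0.25, hosp=0.52, admin=0.06, proc=0.07, exam=0.08),
        "S1": _share(med=0.15, hosp=0.55, admin=0.05, proc=0.10, exam=0.12),
        "OTHER": _share(med=0.30, hosp=0.48, admin=0.06, proc=0.06, exam=0.08),
    }


def _share(med, hosp, admin, proc, exam):
    other = round(1.0 - (med + hosp + admin + proc + exam), 10)
    return {
        "administration": admin,
        "medicines": med,
        "procedures": proc,
        "examinations": exam,
        "hospitalization": hosp,
        "other": other,
    }


class SimulationConfig(BaseModel):
    """Parameters of the synthetic cohort.

    Probability fields named ``p_*`` plant specific inclusion/exclusion
    violations; with all of them at 0 every patient is eligible.
    """

    n_patients: int = 200
    seed: int = 0

    regimen_mix: dict[str, float] = Field(default_factory=_default_mix)
    p_second_line: dict[str, float] = Field(default_factory=_default_p_second_line)
    second_line_transitions: dict[str, dict[str, float]] = Field(
        default_factory=_default_transitions
    )

    #: mean first-line treatment span in days, per regimen (geometric number
    #: of cycles, so episode ends always fall on prescription-derived dates)
    mean_pfs1_days: dict[str, float] = Field(
        default_factory=lambda: {
            "FFX": 110.0,
            "GnP": 115.0,
            "GEM": 90.0,
            "S1": 100.0,
            "OTHER": 90.0,
        }
    )
    mean_pd1_days: float = 18.0
    mean_tc_days: float = 55.0
    mean_pfs2_days: float = 85.0
    mean_post_second_line_days: float = 30.0

    restart_gap_probability: float = 0.15
    p_death_during_followup: float = 0.6

    monthly_cost_scale_jpy: dict[str, float] = Field(default_factory=_default_cost_scale)
    category_shares: dict[str, dict[str, float]] = Field(
        default_factory=_default_category_shares
    )
    #: lognormal scale (log-JPY); per-category month cost is
    #: share * scale * LogNormal(0, cost_sigma)
    cost_sigma: float = 0.35
    #: multiplier on the first month of every episode (treatment starts are
    #: admission-heavy, so month 1 costs run highest)
    first_month_cost_multiplier: float = 1.6

    #: violation probabilities (exclusion planting)
    p_no_definitive_dx: float = 0.0
    p_no_lookback_claim: float = 0.0
    p_late_chemo_start: float = 0.0
    p_dx_before_2015: float = 0.0
    p_surgery_or_radiotherapy: float = 0.0

    #: probability of distractor records (non-cancer diagnoses, supportive
    #: prescriptions, pre-treatment claims) — never inside episode windows
    noise: float = 0.3

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name, vec in [("regimen_mix", self.regimen_mix)]:
            tot = sum(vec.values())
            if tot <= 0:
                raise ValueError(f"{name} is degenerate (sums to {tot})")
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {tot})")
            if any(v < 0 for v in vec.values()):
                raise ValueError(f"{name} has negative entries")
            unknown = set(vec) - set(REGIMENS)
            if unknown:
                raise ValueError(f"{name} has unknown regimens {unknown}")
        for first, row in self.second_line_transitions.items():
            tot = sum(row.values())
            if row and abs(tot - 1.0) > 1e-9:
                raise ValueError(
                    f"transition row {first} must sum to 1 (got {tot})"
                )
            for second, p in row.items():
                if p > 0 and _plan_drugs(second) <= _plan_drugs(first):
                    raise ValueError(
                        f"transition {first}->{second} is undetectable: the "
                        f"second-line drug set is contained in the first-line "
                        f"set, so it is a restart, not a switch"
                    )
        for reg, shares in self.category_shares.items():
            if abs(sum(shares.values()) - 1.0) > 1e-9:
                raise ValueError(f"category shares for {reg} must sum to 1")
        for d in self.mean_pfs1_days.values():
            if d <= 0:
                raise ValueError("durations must be positive")
        return self


# -- ground truth ----------------------------------------------------------


@dataclass
class GroundTruth:
    """Planted labels and boundaries for every simulated patient.

    ``verdicts``
        one row per patient: inclusion verdict + exclusion reason, regimen
        labels for both lines, switch date, all episode boundaries, and the
        patient's total emitted claim cost.
    ``monthly_costs``
        one row per (patient, episode, month, category) for every *full*
        30-day month of an episode: the exact planted cost.
    ``characteristics``
        descriptive nuisance columns (weight, BMI, stage, location,
        comorbidities) that carry no analysis logic.
    """

    verdicts: pd.DataFrame
    monthly_costs: pd.DataFrame
    characteristics: pd.DataFrame


_VERDICT_DATE_COLS = [
    "dx_date",
    "anchor_date",
    "switch_date",
    "pfs1_start",
    "pfs1_end",
    "pd1_start",
    "pd1_end",
    "tc_start",
    "tc_end",
    "pfs2_start",
    "pfs2_end",
    "os_start",
    "os_end",
]


def write_ground_truth(gt: GroundTruth, data_dir) -> None:
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    v = gt.verdicts.copy()
    for c in _VERDICT_DATE_COLS:
        v[c] = pd.to_datetime(v[c]).dt.strftime("%Y-%m-%d").fillna("")
    v.to_csv(data_dir / "ground_truth.csv", index=False, lineterminator="\n")
    gt.monthly_costs.to_csv(
        data_dir / "ground_truth_monthly_costs.csv", index=False, lineterminator="\n"
    )
    gt.characteristics.to_csv(
        data_dir / "characteristics.csv", index=False, lineterminator="\n"
    )


def read_ground_truth(data_dir) -> GroundTruth:
    data_dir = Path(data_dir)
    v = pd.read_csv(data_dir / "ground_truth.csv", dtype={"patient_id": str},
                    keep_default_na=False)
    for c in _VERDICT_DATE_COLS:
        v[c] = pd.to_datetime(v[c].replace("", pd.NA), format="%Y-%m-%d")
    v["included"] = v["included"].map(lambda x: str(x) == "True")
    m = pd.read_csv(
        data_dir / "ground_truth_monthly_costs.csv", dtype={"patient_id": str}
    )
    ch = pd.read_csv(data_dir / "characteristics.csv", dtype={"patient_id": str})
    return GroundTruth(verdicts=v, monthly_costs=m, characteristics=ch)


# -- trajectory construction ----------------------------------------------


def _geometric_cycles(rng: np.random.Generator, mean_days: float, interval: int) -> int:
    """Number of treatment cycles, geometric with mean ≈ mean_days/interval."""
    p = min(1.0, interval / mean_days)
    return int(rng.geometric(p))


def _geometric_days(rng: np.random.Generator, mean_days: float) -> int:
    return int(rng.geometric(min(1.0, 1.0 / mean_days)))


def _line_events(
    rng: np.random.Generator,
    regimen: str,
    anchor: datetime.date,
    sim: SimulationConfig,
    mean_days: float,
) -> tuple[list[tuple[str, datetime.date, str, float]], datetime.date]:
    """Emit one line of chemotherapy.

    Returns (prescription events, treatment end date).  Events are
    (drug_id, date, route, quantity).  The end date follows the day-supply
    rule: parenteral drugs end on their last administration; oral drugs on
    last fill + quantity / standard daily dose.
    """
    base = _BASE_INTERVAL[regimen]
    k = _geometric_cycles(rng, mean_days, base)
    span = k * base

    gap_at, gap_len = None, 0
    if k >= 2 and rng.random() < sim.restart_gap_probability:
        gap_at = (1 + int(rng.integers(0, k - 1))) * base
        gap_len = int(rng.integers(35, 61))

    events: list[tuple[str, datetime.date, str, float]] = []
    end = anchor
    for drug_id, route, interval in REGIMEN_PLANS[regimen]:
        offsets = list(range(0, span, interval))
        if gap_at is not None:
            offsets = [o + gap_len if o >= gap_at else o for o in offsets]
        qty = 1.0 if route == "parenteral" else _DOSE[drug_id] * interval
        for o in offsets:
            events.append((drug_id, anchor + o * _DAY, route, qty))
        last = anchor + max(offsets) * _DAY
        drug_end = last if route == "parenteral" else last + int(
            qty // _DOSE[drug_id]
        ) * _DAY
        end = max(end, drug_end)
    return events, end


def _plant_costs(
    rng: np.random.Generator,
    pid: str,
    regimen: str,
    kind: str,
    start: datetime.date,
    end: datetime.date,
    sim: SimulationConfig,
    acfg: AnalysisConfig,
    claims: list,
    monthly_rows: list,
) -> None:
    """Draw per-category monthly costs for one episode and emit claim lines
    dated inside the 30-day window each cost belongs to.

    Full windows are recorded in the ground-truth monthly table; residual
    tail days (and sub-month episodes) receive a single small claim that is
    part of episode totals but of no monthly cell.
    """
    dur = (end - start).days
    ml = acfg.month_length_days
    n_months = min(acfg.cost_horizon_months, dur // ml)
    scale = sim.monthly_cost_scale_jpy[regimen]
    shares = sim.category_shares[regimen]
    for m in range(n_months):
        wstart = start + m * ml * _DAY
        boost = sim.first_month_cost_multiplier if m == 0 else 1.0
        for cat in CATEGORIES:
            mean = shares[cat] * scale * boost
            if mean <= 0:
                continue
            total = int(round(mean * rng.lognormal(0.0, sim.cost_sigma)))
            total = max(total, 1)
            code = _draw_code(rng, cat, acfg)
            n_lines = int(rng.integers(1, 3))
            cuts = sorted(rng.integers(0, total + 1, size=n_lines - 1).tolist())
            parts = np.diff(np.asarray([0] + cuts + [total]))
            for j, part in enumerate(parts):
                # first medicines line pinned to the window start so episode
                # starts are always observable record dates
                day = 0 if (j == 0 and cat == "medicines") else int(
                    rng.integers(0, ml)
                )
                claims.append((pid, wstart + day * _DAY, code, int(part)))
            monthly_rows.append((pid, kind, m + 1, cat, total))
    # tail claim: inside the episode but beyond the last full 30-day window;
    # strictly before the episode end so it can never bleed into a successor
    # episode's first month
    if n_months * ml < dur:
        tail_start = start + n_months * ml * _DAY
        day_span = (end - tail_start).days - 1
        day = 0 if day_span <= 0 else int(rng.integers(0, day_span + 1))
        claims.append(
            (
                pid,
                tail_start + day * _DAY,
                _draw_code(rng, "examinations", acfg),
                int(rng.integers(500, 20_000)),
            )
        )


def _draw_code(rng: np.random.Generator, category: str, acfg: AnalysisConfig) -> int:
    lo, hi = {
        "administration": (10, 19),
        "medicines": (20, 39),
        "procedures": (40, 59),
        "examinations": (60, 79),
        "hospitalization": (90, 99),
        "other": (80, 89),
    }[category]
    banned = acfg.surgery_codes | acfg.radiotherapy_codes
    while True:
        code = int(rng.integers(lo, hi + 1))
        if code not in banned:
            return code


_EXCLUSION_ORDER = [
    ("no_definitive_dx", "p_no_definitive_dx"),
    ("no_lookback_claim", "p_no_lookback_claim"),
    ("surgery_or_radiotherapy", "p_surgery_or_radiotherapy"),
    ("no_chemo_within_60d", "p_late_chemo_start"),
    ("dx_before_2015", "p_dx_before_2015"),
]


def _simulate_patient(
    i: int, sim: SimulationConfig, acfg: AnalysisConfig
) -> tuple[dict, list, list, list, list, list, dict]:
    """Build one patient; returns (patient row, diagnoses, prescriptions,
    claims, monthly ground-truth rows, nuisance characteristics)."""
    rng = np.random.default_rng([sim.seed, i])
    pid = f"P{i:06d}"

    regimens = list(sim.regimen_mix)
    first_line = rng.choice(regimens, p=[sim.regimen_mix[r] for r in regimens])
    first_line = str(first_line)

    violations = {
        reason: bool(rng.random() < getattr(sim, pfield))
        for reason, pfield in _EXCLUSION_ORDER
    }
    reason = next((r for r, _ in _EXCLUSION_ORDER if violations[r]), None)
    included = reason is None

    if violations["dx_before_2015"]:
        dx = datetime.date(2014, 1, 1) + int(rng.integers(0, 330)) * _DAY
    else:
        dx = datetime.date(2015, 1, 1) + int(rng.integers(0, 900)) * _DAY

    birth_year = int(rng.integers(1935, 1976))
    sex = "male" if rng.random() < 0.58 else "female"

    diagnoses, prescriptions, claims = [], [], []
    monthly_rows: list = []

    # index diagnosis (suspected-only when the definitive flag is withheld)
    diagnoses.append((pid, dx, "C25.9", not violations["no_definitive_dx"]))

    # lookback claim history
    if not violations["no_lookback_claim"]:
        back = int(rng.integers(acfg.lookback_days + 1, 120))
        claims.append(
            (pid, dx - back * _DAY, _draw_code(rng, "examinations", acfg),
             int(rng.integers(1_000, 30_000)))
        )

    # first-line chemotherapy
    if violations["no_chemo_within_60d"]:
        delay = int(rng.integers(acfg.chemo_window_days + 10,
                                 acfg.chemo_window_days + 90))
    else:
        delay = int(rng.integers(3, 31))
    anchor = dx + delay * _DAY

    events, pfs1_end = _line_events(
        rng, first_line, anchor, sim, sim.mean_pfs1_days.get(first_line, 90.0)
    )
    for drug_id, date, route, qty in events:
        prescriptions.append((pid, drug_id, date, route, qty))

    # second line?
    second_line = None
    switch = None
    pfs2_end = None
    if rng.random() < sim.p_second_line.get(first_line, 0.0):
        row = sim.second_line_transitions.get(first_line, {})
        if row:
            seconds = list(row)
            second_line = str(rng.choice(seconds, p=[row[s] for s in seconds]))
            switch = pfs1_end + max(1, _geometric_days(rng, sim.mean_pd1_days)) * _DAY
            # a switch inside the combination window would be absorbed into
            # the first-line component set by definition; plant it after
            switch = max(switch, anchor + (acfg.combination_window_days + 1) * _DAY)
            ev2, pfs2_end = _line_events(
                rng, second_line, switch, sim, sim.mean_pfs2_days
            )
            for drug_id, date, route, qty in ev2:
                prescriptions.append((pid, drug_id, date, route, qty))

    # terminal phase and follow-up end
    if second_line is None:
        tc_days = _geometric_days(rng, sim.mean_tc_days) if rng.random() > 0.05 else 0
        lfu = pfs1_end + tc_days * _DAY
    else:
        lfu = pfs2_end + _geometric_days(rng, sim.mean_post_second_line_days) * _DAY
    died = rng.random() < sim.p_death_during_followup
    death = lfu if died else None

    # episode boundaries (only meaningful when the patient is analyzable)
    ep = {
        "pfs1_start": anchor,
        "pfs1_end": pfs1_end,
        "os_start": anchor,
        "os_end": lfu,
        "pd1_start": None,
        "pd1_end": None,
        "tc_start": None,
        "tc_end": None,
        "pfs2_start": None,
        "pfs2_end": None,
    }
    if second_line is None:
        ep["tc_start"], ep["tc_end"] = pfs1_end, lfu
    else:
        ep["pd1_start"], ep["pd1_end"] = pfs1_end, switch
        ep["pfs2_start"], ep["pfs2_end"] = switch, pfs2_end

    # planted costs per episode (monthly ground truth only for included
    # patients — excluded ones never reach the cost engine)
    mrows = monthly_rows if included else []
    ep_cost = {"PFS1": 0, "PD1": 0, "TC": 0, "PFS2": 0}

    def _plant(regimen, kind, s, e):
        before = sum(c[3] for c in claims)
        _plant_costs(rng, pid, regimen, kind, s, e, sim, acfg, claims, mrows)
        ep_cost[kind] = sum(c[3] for c in claims) - before

    _plant(first_line, "PFS1", anchor, pfs1_end)
    if second_line is None:
        _plant(first_line, "TC", pfs1_end, lfu)
    else:
        _plant(first_line, "PD1", pfs1_end, switch)
        _plant(second_line, "PFS2", switch, pfs2_end)

    # surgery / radiotherapy after diagnosis (exclusion trigger)
    if violations["surgery_or_radiotherapy"]:
        codes = sorted(acfg.surgery_codes | acfg.radiotherapy_codes)
        surg_date = min(dx + int(rng.integers(1, 30)) * _DAY, lfu)
        claims.append(
            (pid, surg_date, codes[int(rng.integers(0, len(codes)))],
             int(rng.integers(200_000, 2_000_000)))
        )

    # distractors: non-cancer diagnosis + supportive prescriptions + a claim
    # strictly between diagnosis and treatment start (inside no episode);
    # all clamped to the follow-up window
    if rng.random() < sim.noise:
        diagnoses.append(
            (pid, min(dx + int(rng.integers(0, 5)) * _DAY, lfu), "E11.9", True)
        )
        prescriptions.append(
            (pid, "PAL" if rng.random() < 0.5 else "LOP",
             min(anchor + int(rng.integers(0, 15)) * _DAY, lfu), "oral", 10.0)
        )
        if delay >= 2:
            claims.append(
                (pid, dx + int(rng.integers(1, delay)) * _DAY,
                 _draw_code(rng, "procedures", acfg),
                 int(rng.integers(1_000, 50_000)))
            )

    assert all(c[1] <= lfu for c in claims)
    assert all(p[2] <= lfu for p in prescriptions)

    patient_row = {
        "patient_id": pid,
        "sex": sex,
        "birth_year": birth_year,
        "death_date": death,
        "last_follow_up": lfu,
    }
    verdict = {
        "patient_id": pid,
        "included": included,
        "exclusion_reason": reason or "",
        "first_line": first_line,
        "second_line": second_line or "",
        "dx_date": dx,
        "anchor_date": anchor,
        "switch_date": switch,
        **ep,
        "pfs1_cost_jpy": ep_cost["PFS1"],
        "pd1_cost_jpy": ep_cost["PD1"],
        "tc_cost_jpy": ep_cost["TC"],
        "pfs2_cost_jpy": ep_cost["PFS2"],
        "os_cost_jpy": sum(ep_cost.values()),
        "total_cost_jpy": int(sum(c[3] for c in claims)),
    }
    stage = str(rng.choice(["0", "I", "II", "III", "IV", "unknown"],
                           p=[0.01, 0.03, 0.07, 0.11, 0.60, 0.18]))
    chars = {
        "patient_id": pid,
        "weight_kg": round(float(rng.normal(56, 11)), 1),
        "bmi": round(float(rng.normal(21.5, 3.0)), 1),
        "stage": stage,
        "location": str(rng.choice(["head", "body", "tail", "unknown"],
                                   p=[0.42, 0.21, 0.14, 0.23])),
        "chronic_pancreatitis": bool(rng.random() < 0.10),
        "t2dm": bool(rng.random() < 0.43),
    }
    return patient_row, diagnoses, prescriptions, claims, monthly_rows, verdict, chars


def generate_dataset(
    sim: SimulationConfig, analysis_config: AnalysisConfig | None = None
) -> tuple[ClaimsDataset, GroundTruth]:
    """Simulate a claims dataset with known ground truth.

    Deterministic: identical (config, seed) produce identical output, and
    each patient draws from an independent stream keyed by (seed, index),
    so growing ``n_patients`` never reshuffles earlier patients.
    """
    acfg = analysis_config or AnalysisConfig()
    patients, diagnoses, prescriptions, claims = [], [], [], []
    monthly, verdicts, chars = [], [], []
    for i in range(sim.n_patients):
        p, dx, rx, cl, mo, v, ch = _simulate_patient(i, sim, acfg)
        patients.append(p)
        diagnoses.extend(dx)
        prescriptions.extend(rx)
        claims.extend(cl)
        monthly.extend(mo)
        verdicts.append(v)
        chars.append(ch)

    ds = ClaimsDataset(
        patients=_frame(patients, date_cols=["death_date", "last_follow_up"]),
        diagnoses=pd.DataFrame(
            diagnoses, columns=["patient_id", "date", "icd10", "definitive"]
        ).pipe(_dates, ["date"]),
        prescriptions=pd.DataFrame(
            prescriptions,
            columns=["patient_id", "drug_id", "date", "route", "quantity"],
        ).pipe(_dates, ["date"]),
        claim_lines=pd.DataFrame(
            claims,
            columns=["patient_id", "service_date", "code_category", "cost_jpy"],
        ).pipe(_dates, ["service_date"]),
        drug_dictionary=default_drug_dictionary(),
    ).validate().sorted()

    vdf = pd.DataFrame(verdicts)
    for c in _VERDICT_DATE_COLS:
        vdf[c] = pd.to_datetime(vdf[c])
    gt = GroundTruth(
        verdicts=vdf,
        monthly_costs=pd.DataFrame(
            monthly,
            columns=["patient_id", "episode_kind", "month", "category", "cost_jpy"],
        ),
        characteristics=pd.DataFrame(chars),
    )
    return ds, gt


def _frame(rows: list[dict], date_cols: list[str]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    return _dates(df, date_cols)


def _dates(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    for c in cols:
        df[c] = pd.to_datetime(df[c])
    return df
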