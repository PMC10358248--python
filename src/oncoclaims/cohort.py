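"""Cohort selection: inclusion criteria, exclusion, and the attrition report.

A patient enters the analysis cohort when they have (1) at least one
definitive pancreatic-cancer diagnosis (ICD-10 C25x), (2) any claim history
strictly more than 28 days before that first confirmed diagnosis (the
lookback criterion, screening out patients transferred mid-treatment from
another hospital), (3) no surgery or radiotherapy on or after the
diagnosis, (4) a pancreatic-indicated anticancer prescription within 60
days (inclusive) of the diagnosis, and (5) a first confirmed diagnosis on
or after 2015-01-01.  Criteria are applied in that order — the order of the
study's patient-flow diagram — and the first failing criterion becomes the
patient's single recorded exclusion reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import AnalysisConfig
from .core import ClaimsDataset

__all__ = [
    "EXCLUSION_REASONS",
    "AttritionReport",
    "first_confirmed_diagnosis",
    "has_lookback_claim",
    "has_surgery_or_radiotherapy",
    "chemo_within_window",
    "select_cohort",
]

#: Exclusion reasons in evaluation order (patient-flow-diagram order).
EXCLUSION_REASONS = (
    "no_definitive_dx",
    "no_lookback_claim",
    "surgery_or_radiotherapy",
    "no_chemo_within_60d",
    "dx_before_2015",
)

_DAY = pd.Timedelta(days=1)


@dataclass
class AttritionReport:
    """Ordered patient counts after each selection step.

    ``counts`` has one entry per box of the flow diagram: patients with a
    definitive diagnosis, then survivors of each subsequent criterion.
    """

    steps: list[str]
    counts: list[int]

    def __post_init__(self):
        if any(b > a for a, b in zip(self.counts, self.counts[1:])):
            raise ValueError("attrition counts must be non-increasing")

    def to_text(self) -> str:
        width = max(len(s) for s in self.steps)
        return "\n".join(
            f"{s:<{width}}  {c:>8d}" for s, c in zip(self.steps, self.counts)
        )


def indicated_drug_ids(ds: ClaimsDataset) -> set[str]:
    """Drug ids of pancreatic-indicated anticancer agents (supportive-care
    drugs are invisible to every selection and classification rule)."""
    dd = ds.drug_dictionary
    anticancer = dd["component"] != "supportive"
    return set(dd.loc[dd["pancreatic_indication"] & anticancer, "drug_id"])


# -- per-patient predicates on pre-filtered sub-frames ---------------------

def _first_dx(pat_dx: pd.DataFrame):
    hit = pat_dx[pat_dx["definitive"] & pat_dx["icd10"].str.startswith("C25")]
    return None if hit.empty else hit["date"].min()


def _has_lookback(pat_cl, pat_rx, pat_dx, dx_date, config) -> bool:
    cutoff = pd.Timestamp(dx_date) - config.lookback_days * _DAY
    return bool(
        (pat_cl["service_date"] < cutoff).any()
        or (pat_rx["date"] < cutoff).any()
        or (pat_dx["date"] < cutoff).any()
    )


def _has_surgery(pat_cl, dx_date, config) -> bool:
    codes = config.surgery_codes | config.radiotherapy_codes
    return bool(
        (
            pat_cl["code_category"].isin(codes)
            & (pat_cl["service_date"] >= pd.Timestamp(dx_date))
        ).any()
    )


def _chemo_within(pat_rx, drugs: set[str], dx_date, config) -> bool:
    lo = pd.Timestamp(dx_date)
    hi = lo + config.chemo_window_days * _DAY
    dates = pat_rx.loc[pat_rx["drug_id"].isin(drugs), "date"]
    return bool(((dates >= lo) & (dates <= hi)).any())


def _by_patient(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {pid: sub for pid, sub in df.groupby("patient_id")}


def _patient_frames(ds: ClaimsDataset, patient_id: str):
    if patient_id not in set(ds.patients["patient_id"]):
        raise KeyError(f"unknown patient: {patient_id}")
    return (
        ds.diagnoses[ds.diagnoses["patient_id"] == patient_id],
        ds.prescriptions[ds.prescriptions["patient_id"] == patient_id],
        ds.claim_lines[ds.claim_lines["patient_id"] == patient_id],
    )


# -- public per-patient operations ----------------------------------------

def first_confirmed_diagnosis(ds: ClaimsDataset, patient_id: str):
    """Earliest definitive C25x diagnosis date, or None.

    Raises KeyError for a patient absent from the patient table.
    """
    pat_dx, _, _ = _patient_frames(ds, patient_id)
    return _first_dx(pat_dx)


def has_lookback_claim(
    ds: ClaimsDataset, patient_id: str, dx_date, config: AnalysisConfig
) -> bool:
    """True iff any record (claim line, prescription or diagnosis) predates
    the diagnosis by strictly more than ``lookback_days``."""
    pat_dx, pat_rx, pat_cl = _patient_frames(ds, patient_id)
    return _has_lookback(pat_cl, pat_rx, pat_dx, dx_date, config)


def has_surgery_or_radiotherapy(
    ds: ClaimsDataset, patient_id: str, dx_date, config: AnalysisConfig
) -> bool:
    """True iff a claim line with a surgery/radiotherapy code is dated on or
    after the first confirmed diagnosis."""
    _, _, pat_cl = _patient_frames(ds, patient_id)
    return _has_surgery(pat_cl, dx_date, config)


def chemo_within_window(
    ds: ClaimsDataset, patient_id: str, dx_date, config: AnalysisConfig
) -> bool:
    """True iff a pancreatic-indicated anticancer prescription falls within
    [dx_date, dx_date + chemo_window_days], both ends inclusive."""
    _, pat_rx, _ = _patient_frames(ds, patient_id)
    return _chemo_within(pat_rx, indicated_drug_ids(ds), dx_date, config)


def select_cohort(
    ds: ClaimsDataset, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, AttritionReport]:
    """Apply all criteria, returning per-patient verdicts and the attrition
    report.

    The verdict table has one row per patient: patient_id,
    first_confirmed_diagnosis_date (NaT when absent), included, and
    exclusion_reason ('' for included patients).  Verdicts are independent
    of input row order.
    """
    config = config or AnalysisConfig()
    earliest = pd.Timestamp(config.earliest_index_diagnosis)
    drugs = indicated_drug_ids(ds)

    dx_by = _by_patient(ds.diagnoses)
    rx_by = _by_patient(ds.prescriptions)
    cl_by = _by_patient(ds.claim_lines)
    empty_dx = ds.diagnoses.iloc[0:0]
    empty_rx = ds.prescriptions.iloc[0:0]
    empty_cl = ds.claim_lines.iloc[0:0]

    rows = []
    for pid in sorted(ds.patients["patient_id"]):
        pat_dx = dx_by.get(pid, empty_dx)
        pat_rx = rx_by.get(pid, empty_rx)
        pat_cl = cl_by.get(pid, empty_cl)
        dx_date = _first_dx(pat_dx)
        reason = ""
        if dx_date is None:
            reason = "no_definitive_dx"
        elif not _has_lookback(pat_cl, pat_rx, pat_dx, dx_date, config):
            reason = "no_lookback_claim"
        elif _has_surgery(pat_cl, dx_date, config):
            reason = "surgery_or_radiotherapy"
        elif not _chemo_within(pat_rx, drugs, dx_date, config):
            reason = "no_chemo_within_60d"
        elif dx_date < earliest:
            reason = "dx_before_2015"
        rows.append(
            {
                "patient_id": pid,
                "first_confirmed_diagnosis_date": dx_date,
                "included": reason == "",
                "exclusion_reason": reason,
            }
        )
    cohort = pd.DataFrame(rows)
    cohort["first_confirmed_diagnosis_date"] = pd.to_datetime(
        cohort["first_confirmed_diagnosis_date"]
    )

    steps = [
        "definitive pancreatic-cancer diagnosis",
        "claim history >%d days before diagnosis" % config.lookback_days,
        "no surgery or radiotherapy after diagnosis",
        "chemotherapy within %d days of diagnosis" % config.chemo_window_days,
        "diagnosis on or after %s" % config.earliest_index_diagnosis,
    ]
    reason_of = cohort["exclusion_reason"]
    surv = (reason_of != "no_definitive_dx").sum()
    counts = [int(surv)]
    for r in EXCLUSION_REASONS[1:]:
        surv -= (reason_of == r).sum()
        counts.append(int(surv))
    return cohort, AttritionReport(steps=steps, counts=counts)
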