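"""Regimen determination from prescription streams.

A line of therapy is anchored at its first qualifying prescription; every
pancreatic-indicated anticancer drug first administered within the 28-day
combination window after the anchor is a component of the line.  The label
is a pure function of the component ingredient set:

* contains nab-paclitaxel                       -> GnP
* else >= 2 distinct FOLFIRINOX components
  (oxaliplatin, irinotecan, fluorouracil,
  folinate)                                     -> FFX
* else exactly gemcitabine                      -> GEM
* else exactly S-1                              -> S1
* anything else (incl. gemcitabine+erlotinib)   -> OTHER

nab-paclitaxel takes precedence over the FFX rule: it is the more specific
marker, so a set containing it plus FFX components is still GnP.  Drugs
without a pancreatic indication (supportive care) never enter a component
set.  Modified FOLFIRINOX is not distinguished from FFX.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import AnalysisConfig
from .core import ClaimsDataset

__all__ = [
    "RegimenAssignment",
    "classify_regimen",
    "first_line_drug_set",
    "second_line_assignment",
]

_DAY = pd.Timedelta(days=1)


@dataclass(frozen=True)
class RegimenAssignment:
    """One line of therapy for one patient."""

    patient_id: str
    line: int  # 1 or 2
    label: str  # FFX / GnP / GEM / S1 / OTHER
    component_drugs: frozenset[str]
    anchor_date: pd.Timestamp


def _indicated(ds: ClaimsDataset) -> pd.DataFrame:
    dd = ds.drug_dictionary
    return dd[dd["pancreatic_indication"] & (dd["component"] != "supportive")]


def classify_regimen(drug_ids, dictionary: pd.DataFrame) -> str:
    """Label a non-empty component drug set; see module docstring for the
    precedence rules."""
    ids = set(drug_ids)
    if not ids:
        raise ValueError("empty component drug set")
    dd = dictionary.set_index("drug_id")
    comps = dd.loc[sorted(ids), "component"]
    ingredients = dd.loc[sorted(ids), "ingredient"]
    if (comps == "nab_paclitaxel").any():
        return "GnP"
    n_ffx = ingredients[comps == "ffx"].nunique()
    if n_ffx >= 2:
        return "FFX"
    comp_set = set(comps)
    if comp_set == {"gemcitabine"}:
        return "GEM"
    if comp_set == {"s1"}:
        return "S1"
    return "OTHER"


def _first_line_from_rx(
    pat_rx: pd.DataFrame,
    indicated: set[str],
    dictionary: pd.DataFrame,
    patient_id: str,
    dx: pd.Timestamp,
    config: AnalysisConfig,
) -> RegimenAssignment | None:
    sub = pat_rx[
        pat_rx["drug_id"].isin(indicated)
        & (pat_rx["date"] >= dx)
        & (pat_rx["date"] <= dx + config.regimen_initiation_window_days * _DAY)
    ]
    if sub.empty:
        return None
    anchor = sub["date"].min()
    window = pat_rx[
        pat_rx["drug_id"].isin(indicated) & (pat_rx["date"] >= anchor)
    ]
    firsts = window.groupby("drug_id")["date"].min()
    hi = anchor + config.combination_window_days * _DAY
    components = frozenset(firsts.index[firsts <= hi])
    return RegimenAssignment(
        patient_id=patient_id,
        line=1,
        label=classify_regimen(components, dictionary),
        component_drugs=components,
        anchor_date=anchor,
    )


def _second_line_from_rx(
    pat_rx: pd.DataFrame,
    indicated: set[str],
    dictionary: pd.DataFrame,
    patient_id: str,
    switch: pd.Timestamp,
    config: AnalysisConfig,
) -> RegimenAssignment:
    hi = switch + config.combination_window_days * _DAY
    sub = pat_rx[
        pat_rx["drug_id"].isin(indicated)
        & (pat_rx["date"] >= switch)
        & (pat_rx["date"] <= hi)
    ]
    components = frozenset(sub["drug_id"])
    return RegimenAssignment(
        patient_id=patient_id,
        line=2,
        label=classify_regimen(components, dictionary),
        component_drugs=components,
        anchor_date=switch,
    )


def first_line_drug_set(
    ds: ClaimsDataset,
    patient_id: str,
    dx_date,
    config: AnalysisConfig | None = None,
) -> RegimenAssignment | None:
    """First-line assignment: anchor at the earliest indicated anticancer
    prescription initiated within 6 months (180 days) of the confirmed
    diagnosis; components are every indicated anticancer drug first
    administered within the 28-day combination window after the anchor.

    Returns None when no qualifying prescription exists.
    """
    config = config or AnalysisConfig()
    rx = ds.prescriptions
    return _first_line_from_rx(
        rx[rx["patient_id"] == patient_id],
        set(_indicated(ds)["drug_id"]),
        ds.drug_dictionary,
        patient_id,
        pd.Timestamp(dx_date),
        config,
    )


def second_line_assignment(
    ds: ClaimsDataset,
    patient_id: str,
    first_line: RegimenAssignment,
    switch_date,
    config: AnalysisConfig | None = None,
) -> RegimenAssignment | None:
    """Second-line assignment anchored at a detected switch date.

    Components are every indicated anticancer drug administered within the
    28-day combination window after the switch — including drugs shared
    with the first line (e.g. gemcitabine re-entering as part of GnP).
    Returns None when switch_date is None (the patient routes to best
    supportive care).
    """
    if switch_date is None:
        return None
    config = config or AnalysisConfig()
    rx = ds.prescriptions
    return _second_line_from_rx(
        rx[rx["patient_id"] == patient_id],
        set(_indicated(ds)["drug_id"]),
        ds.drug_dictionary,
        patient_id,
        pd.Timestamp(switch_date),
        config,
    )


def assignments_frame(assignments) -> pd.DataFrame:
    """Long-format regimens table: patient_id, line, label, components,
    anchor_date."""
    rows = [
        {
            "patient_id": a.patient_id,
            "line": a.line,
            "label": a.label,
            "component_drugs": "|".join(sorted(a.component_drugs)),
            "anchor_date": a.anchor_date,
        }
        for a in assignments
        if a is not None
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "line", "label", "component_drugs", "anchor_date"]
    )
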