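"""Treatment-episode segmentation.

Each first-line patient's timeline is cut into prescription-defined
episodes:

* **PFS1** — index date (first first-line prescription) to the computed end
  of first-line treatment.  For oral drugs the end extends beyond the last
  fill by the dispensed day supply (quantity / standard daily dose,
  floored); the end is capped at the last follow-up date.
* **PD1** — end of first-line treatment to the start of second-line
  chemotherapy (patients who switch).
* **TC** — end of first-line treatment to last follow-up (patients who
  never switch; terminal care / best supportive care).
* **PFS2** — first to last prescription of the second-line regimen, with
  the same day-supply extension.
* **OS** — index date to death or last follow-up, whichever is earlier.

A switch is the first prescription, after the first-line anchor, of an
indicated anticancer drug outside the first-line component set.
Re-prescription of any subset of the first-line drugs — even after a long
gap — is a restart of the same line, never a switch.  If a switch drug
appears before the computed first-line end, PFS1 is truncated at the
switch date and PD1 has zero length; zero-length episodes are kept (they
simply contribute no cost months), so every first-line patient routes to
exactly one of {PD1 (+PFS2), TC}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .config import AnalysisConfig
from .core import ClaimsDataset
from .regimens import RegimenAssignment

__all__ = [
    "Episode",
    "line_end_date",
    "detect_switch",
    "build_episodes",
    "build_cohort_episodes",
    "episodes_frame",
]

_DAY = pd.Timedelta(days=1)


@dataclass(frozen=True)
class Episode:
    patient_id: str
    kind: str  # PFS1 / PD1 / TC / PFS2 / OS
    start: pd.Timestamp
    end: pd.Timestamp
    end_reason: str  # switch / death / last_follow_up / last_prescription


class EpisodeConsistencyError(RuntimeError):
    """An internal invariant of the episode chain was violated."""


def _day_supply(quantity: float, daily_dose: float, config: AnalysisConfig) -> int:
    days = quantity / daily_dose
    if config.day_supply_rounding == "half_up":
        return math.floor(days + 0.5)
    return math.floor(days)


def line_end_date(
    prescriptions: pd.DataFrame,
    dictionary: pd.DataFrame,
    last_follow_up,
    config: AnalysisConfig | None = None,
) -> tuple[pd.Timestamp, str]:
    """Treatment end of one line, given the prescriptions of its drugs.

    Per drug, a parenteral drug contributes its last administration date;
    an oral drug its last fill date plus the floored day supply.  The line
    ends at the per-drug maximum, capped at ``last_follow_up`` (whichever
    is earlier).  Returns (end_date, reason) where reason is
    ``last_prescription`` or ``last_follow_up`` (when capped).

    Raises ValueError if an oral prescription's drug has no standard daily
    dose in the dictionary, or if no prescriptions are given.
    """
    config = config or AnalysisConfig()
    if prescriptions.empty:
        raise ValueError("a line must contain at least one prescription")
    dd = dictionary.set_index("drug_id")
    end = None
    for drug_id, sub in prescriptions.groupby("drug_id"):
        last = sub.sort_values(["date", "quantity"]).iloc[-1]
        if config.oral_extended_end and last["route"] == "oral":
            dose = dd.loc[drug_id, "standard_daily_dose"]
            if not dose > 0:
                raise ValueError(
                    f"oral drug {drug_id} lacks a standard daily dose"
                )
            candidate = last["date"] + _day_supply(
                float(last["quantity"]), float(dose), config
            ) * _DAY
        else:
            candidate = last["date"]
        end = candidate if end is None else max(end, candidate)
    lfu = pd.Timestamp(last_follow_up)
    if end > lfu:
        return lfu, "last_follow_up"
    return end, "last_prescription"


def _detect_switch_from_rx(
    pat_rx: pd.DataFrame, indicated: set[str], first_line: RegimenAssignment
):
    sub = pat_rx[
        pat_rx["drug_id"].isin(indicated - set(first_line.component_drugs))
        & (pat_rx["date"] > first_line.anchor_date)
    ]
    return None if sub.empty else sub["date"].min()


def detect_switch(
    ds: ClaimsDataset,
    patient_id: str,
    first_line: RegimenAssignment,
    config: AnalysisConfig | None = None,
):
    """Date of the first indicated anticancer prescription, after the
    first-line anchor, of a drug outside the first-line component set;
    None when the patient never switches."""
    from .cohort import indicated_drug_ids

    rx = ds.prescriptions
    return _detect_switch_from_rx(
        rx[rx["patient_id"] == patient_id], indicated_drug_ids(ds), first_line
    )


def build_episodes(
    ds: ClaimsDataset,
    patient_id: str,
    first_line: RegimenAssignment,
    second_line: RegimenAssignment | None,
    switch_date,
    config: AnalysisConfig | None = None,
    *,
    _patient: pd.Series | None = None,
    _pat_rx: pd.DataFrame | None = None,
) -> list[Episode]:
    """Segment one patient's record into its episode chain.

    Requires the first-line assignment; the second-line assignment and
    switch date come from :func:`detect_switch` /
    :func:`regimens.second_line_assignment` (both None for non-switchers).
    """
    config = config or AnalysisConfig()
    if _patient is None:
        _patient = ds.patients.set_index("patient_id").loc[patient_id]
    lfu = _patient["last_follow_up"]
    death = _patient["death_date"]
    anchor = first_line.anchor_date
    if _pat_rx is None:
        rx = ds.prescriptions
        _pat_rx = rx[rx["patient_id"] == patient_id]
    mine = _pat_rx

    fl_rx = mine[mine["drug_id"].isin(first_line.component_drugs)]
    fl_rx = fl_rx[fl_rx["date"] >= anchor]
    if switch_date is not None:
        fl_rx = fl_rx[fl_rx["date"] < switch_date]
    pfs1_end, pfs1_reason = line_end_date(
        fl_rx, ds.drug_dictionary, lfu, config
    )
    if switch_date is not None and pfs1_end > switch_date:
        pfs1_end, pfs1_reason = pd.Timestamp(switch_date), "switch"

    episodes = [Episode(patient_id, "PFS1", anchor, pfs1_end, pfs1_reason)]

    if switch_date is None:
        tc_reason = (
            "death" if pd.notna(death) and death == lfu else "last_follow_up"
        )
        episodes.append(Episode(patient_id, "TC", pfs1_end, lfu, tc_reason))
    else:
        if second_line is None:
            raise EpisodeConsistencyError(
                f"{patient_id}: switch detected but no second-line assignment"
            )
        episodes.append(
            Episode(patient_id, "PD1", pfs1_end, pd.Timestamp(switch_date), "switch")
        )
        sl_rx = mine[
            mine["drug_id"].isin(second_line.component_drugs)
            & (mine["date"] >= second_line.anchor_date)
        ]
        pfs2_end, pfs2_reason = line_end_date(
            sl_rx, ds.drug_dictionary, lfu, config
        )
        episodes.append(
            Episode(
                patient_id, "PFS2", second_line.anchor_date, pfs2_end, pfs2_reason
            )
        )

    os_end = lfu if pd.isna(death) else min(death, lfu)
    os_reason = "death" if pd.notna(death) and death <= lfu else "last_follow_up"
    episodes.append(Episode(patient_id, "OS", anchor, os_end, os_reason))

    _check_chain(episodes)
    return episodes


def _check_chain(episodes: list[Episode]) -> None:
    by_kind = {e.kind: e for e in episodes}
    if len(by_kind) != len(episodes):
        raise EpisodeConsistencyError("duplicate episode kinds")
    for e in episodes:
        if e.end < e.start:
            raise EpisodeConsistencyError(f"{e.kind} ends before it starts")
    pfs1 = by_kind["PFS1"]
    if "PD1" in by_kind and "TC" in by_kind:
        raise EpisodeConsistencyError("PD1 and TC are mutually exclusive")
    if ("PFS2" in by_kind) != ("PD1" in by_kind):
        raise EpisodeConsistencyError("PFS2 must accompany PD1")
    succ = by_kind.get("PD1") or by_kind.get("TC")
    if succ is None or succ.start != pfs1.end:
        raise EpisodeConsistencyError("episode chain has a gap after PFS1")
    if "PD1" in by_kind and by_kind["PFS2"].start != by_kind["PD1"].end:
        raise EpisodeConsistencyError("PFS2 must start at the switch date")
    osep = by_kind["OS"]
    if osep.start != pfs1.start:
        raise EpisodeConsistencyError("OS must start with first-line therapy")
    for e in episodes:
        if e.kind != "OS" and e.end > osep.end:
            raise EpisodeConsistencyError(f"{e.kind} extends beyond OS")


def build_cohort_episodes(
    ds: ClaimsDataset,
    cohort: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> tuple[list[RegimenAssignment], pd.DataFrame]:
    """Classify regimens and build episodes for every included patient.

    Returns (assignments for both lines, episode table).  Included patients
    without a qualifying first-line prescription (possible only under
    non-default windows) are skipped.
    """
    from .cohort import indicated_drug_ids
    from .regimens import _first_line_from_rx, _second_line_from_rx

    config = config or AnalysisConfig()
    indicated = indicated_drug_ids(ds)
    rx_by = {pid: sub for pid, sub in ds.prescriptions.groupby("patient_id")}
    empty_rx = ds.prescriptions.iloc[0:0]
    patients = ds.patients.set_index("patient_id")

    assignments: list[RegimenAssignment] = []
    episode_rows: list[Episode] = []
    included = cohort[cohort["included"]]
    for pid, dx_date in zip(
        included["patient_id"], included["first_confirmed_diagnosis_date"]
    ):
        pat_rx = rx_by.get(pid, empty_rx)
        fl = _first_line_from_rx(
            pat_rx, indicated, ds.drug_dictionary, pid,
            pd.Timestamp(dx_date), config,
        )
        if fl is None:
            continue
        switch = _detect_switch_from_rx(pat_rx, indicated, fl)
        sl = (
            None
            if switch is None
            else _second_line_from_rx(
                pat_rx, indicated, ds.drug_dictionary, pid, switch, config
            )
        )
        assignments.append(fl)
        if sl is not None:
            assignments.append(sl)
        episode_rows.extend(
            build_episodes(
                ds, pid, fl, sl, switch, config,
                _patient=patients.loc[pid], _pat_rx=pat_rx,
            )
        )
    return assignments, episodes_frame(episode_rows)


def episodes_frame(episodes: list[Episode]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "kind": e.kind,
                "start": e.start,
                "end": e.end,
                "end_reason": e.end_reason,
            }
            for e in episodes
        ],
        columns=["patient_id", "kind", "start", "end", "end_reason"],
    )
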