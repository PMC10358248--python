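"""Analysis configuration: every window, threshold and mapping constant.

All date-window conventions of the pipeline live here as named, documented
fields so the boundary arithmetic (strict vs inclusive) is auditable and can
be varied without touching algorithm code.
"""

from __future__ import annotations

import datetime
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator

#: Six healthcare-resource categories, keyed by the two-digit prefix of the
#: Japanese clinical identification (practice) code on each claim line.
CATEGORIES = (
    "administration",
    "medicines",
    "procedures",
    "examinations",
    "hospitalization",
    "other",
)

#: First-line / second-line regimen labels.
REGIMENS = ("FFX", "GnP", "GEM", "S1", "OTHER")

#: The four guideline-recommended regimens (OTHER excluded); this is the
#: denominator used for overall second-line / BSC transition percentages.
RECOMMENDED_REGIMENS = ("FFX", "GnP", "GEM", "S1")

EPISODE_KINDS = ("PFS1", "PD1", "TC", "PFS2", "OS")

#: Episode kinds that enter the month-by-month cost analysis (OS is reported
#: only as a cumulative reference total).
MONTHLY_EPISODE_KINDS = ("PFS1", "PD1", "TC", "PFS2")


def code_to_category(code_category: int) -> str:
    """Map a two-digit clinical identification code prefix to its resource
    category.

    administration 10-19, medicines 20-39, procedures 40-59, examinations
    60-79, hospitalization 90-99; everything else (i.e. 80-89) is "other".
    """
    if 10 <= code_category <= 19:
        return "administration"
    if 20 <= code_category <= 39:
        return "medicines"
    if 40 <= code_category <= 59:
        return "procedures"
    if 60 <= code_category <= 79:
        return "examinations"
    if 90 <= code_category <= 99:
        return "hospitalization"
    return "other"


class AnalysisConfig(BaseModel):
    """Tunable constants of the claims analysis.

    Defaults implement the study conventions: a strict >28-day lookback,
    an inclusive 60-day diagnosis-to-chemotherapy window, a 28-day
    combination window for regimen components, 30-day cost months capped
    at six, and the April-2019 exchange rate.
    """

    lookback_days: int = 28
    chemo_window_days: int = 60
    earliest_index_diagnosis: datetime.date = datetime.date(2015, 1, 1)
    #: "initiated within 6 months of a confirmed diagnosis", operationalized
    #: as 180 days because month arithmetic is otherwise undefined.
    regimen_initiation_window_days: int = 180
    combination_window_days: int = 28
    cost_horizon_months: int = 6
    share_horizon_months: int = 3
    month_length_days: int = 30
    jpy_per_usd: float = 114.59

    #: Two-digit claim-code categories that flag surgery / radiotherapy and
    #: trigger exclusion when dated on or after the index diagnosis.  The
    #: source receipt-code masters are not public, so these are config sets.
    surgery_codes: frozenset[int] = frozenset({50, 54})
    radiotherapy_codes: frozenset[int] = frozenset({81})

    #: Day-supply rounding for oral drugs: "floor" (partial days do not
    #: extend treatment, the default) or "half_up".
    day_supply_rounding: Literal["floor", "half_up"] = "floor"

    #: If True (default), first-line treatment end uses the oral day-supply
    #: extension; if False, the literal last-prescription-date variant.
    oral_extended_end: bool = True

    @field_validator(
        "lookback_days",
        "chemo_window_days",
        "regimen_initiation_window_days",
        "combination_window_days",
        "cost_horizon_months",
        "share_horizon_months",
        "month_length_days",
    )
    @classmethod
    def _positive(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("window constants must be positive")
        return v

    @field_validator("jpy_per_usd")
    @classmethod
    def _positive_rate(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("exchange rate must be positive")
        return v

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = self.model_dump(mode="json")
        data["surgery_codes"] = sorted(self.surgery_codes)
        data["radiotherapy_codes"] = sorted(self.radiotherapy_codes)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


DEFAULT_CONFIG = AnalysisConfig()
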