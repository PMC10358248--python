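"""Claims data model: validated tables, CSV readers/writers and currency
conversion.

The dataset dialect emulates a Japanese DPC-hospital claims extract and
consists of five linked tables:

``patients``
    patient_id, sex (male/female), birth_year, death_date (optional),
    last_follow_up.
``diagnoses``
    patient_id, date, icd10, definitive (confirmed vs suspected flag).
``prescriptions``
    patient_id, drug_id, date, route (oral/parenteral), quantity —
    dispensed dosage units for oral drugs, administrations for parenteral.
``claim_lines``
    patient_id, service_date, code_category (two-digit clinical
    identification code prefix, 10-99), cost_jpy.
``drug_dictionary``
    drug_id, ingredient, pancreatic_indication, component
    (ffx / gemcitabine / nab_paclitaxel / s1 / erlotinib /
    other_anticancer / supportive), standard_daily_dose (oral drugs).

All dates are ISO-8601 in CSV and numpy datetime64[ns] in memory.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig

__all__ = [
    "ClaimsDataset",
    "SchemaError",
    "ValidationError",
    "read_claims_dataset",
    "write_claims_dataset",
    "jpy_to_usd",
]


class SchemaError(ValueError):
    """A table is missing a required column or has an unparsable type."""


class ValidationError(ValueError):
    """Cross-table or per-row invariant violated."""


_SCHEMAS: dict[str, dict[str, str]] = {
    "patients": {
        "patient_id": "str",
        "sex": "str",
        "birth_year": "int",
        "death_date": "date?",
        "last_follow_up": "date",
    },
    "diagnoses": {
        "patient_id": "str",
        "date": "date",
        "icd10": "str",
        "definitive": "bool",
    },
    "prescriptions": {
        "patient_id": "str",
        "drug_id": "str",
        "date": "date",
        "route": "str",
        "quantity": "float",
    },
    "claim_lines": {
        "patient_id": "str",
        "service_date": "date",
        "code_category": "int",
        "cost_jpy": "int",
    },
    "drug_dictionary": {
        "drug_id": "str",
        "ingredient": "str",
        "pancreatic_indication": "bool",
        "component": "str",
        "standard_daily_dose": "float?",
    },
}

_SORT_KEYS: dict[str, list[str]] = {
    "patients": ["patient_id"],
    "diagnoses": ["patient_id", "date", "icd10"],
    "prescriptions": ["patient_id", "date", "drug_id"],
    "claim_lines": ["patient_id", "service_date", "code_category", "cost_jpy"],
    "drug_dictionary": ["drug_id"],
}

_ICD10_RE = re.compile(r"^[A-Z]\d")

VALID_COMPONENTS = {
    "ffx",
    "gemcitabine",
    "nab_paclitaxel",
    "s1",
    "erlotinib",
    "other_anticancer",
    "supportive",
}


@dataclass
class ClaimsDataset:
    """The five linked claims tables, in-memory as pandas DataFrames."""

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    claim_lines: pd.DataFrame
    drug_dictionary: pd.DataFrame

    def table_names(self) -> list[str]:
        return [f.name for f in dc_fields(self)]

    def validate(self) -> "ClaimsDataset":
        """Check schema, per-row and referential-integrity invariants.

        Returns self so calls can be chained; raises :class:`SchemaError`
        or :class:`ValidationError` on the first problem found.
        """
        for name in self.table_names():
            df = getattr(self, name)
            missing = set(_SCHEMAS[name]) - set(df.columns)
            if missing:
                raise SchemaError(
                    f"table '{name}' is missing column(s): {sorted(missing)}"
                )

        known = set(self.patients["patient_id"])
        if len(known) != len(self.patients):
            dup = self.patients.loc[
                self.patients["patient_id"].duplicated(), "patient_id"
            ]
            raise ValidationError(f"duplicate patient ids: {sorted(set(dup))}")
        for name, col in [
            ("diagnoses", "patient_id"),
            ("prescriptions", "patient_id"),
            ("claim_lines", "patient_id"),
        ]:
            df = getattr(self, name)
            orphan = set(df[col]) - known
            if orphan:
                raise ValidationError(
                    f"table '{name}' references unknown patient ids: "
                    f"{sorted(orphan)[:10]}"
                )

        bad_icd = ~self.diagnoses["icd10"].astype(str).str.match(_ICD10_RE)
        if bad_icd.any():
            raise ValidationError(
                f"malformed ICD-10 codes: "
                f"{sorted(set(self.diagnoses.loc[bad_icd, 'icd10']))[:10]}"
            )
        if (self.prescriptions["quantity"] <= 0).any():
            raise ValidationError("prescription quantity must be > 0")
        cc = self.claim_lines["code_category"]
        if ((cc < 10) | (cc > 99)).any():
            raise ValidationError("code_category must lie in [10, 99]")
        if (self.claim_lines["cost_jpy"] < 0).any():
            raise ValidationError("cost_jpy must be non-negative")

        bad_comp = set(self.drug_dictionary["component"]) - VALID_COMPONENTS
        if bad_comp:
            raise ValidationError(f"unknown drug components: {sorted(bad_comp)}")

        # every oral, pancreatic-indicated drug dispensed must carry a dose
        oral_ids = set(
            self.prescriptions.loc[
                self.prescriptions["route"] == "oral", "drug_id"
            ]
        )
        dd = self.drug_dictionary
        needs_dose = dd["drug_id"].isin(oral_ids) & dd["pancreatic_indication"]
        no_dose = needs_dose & ~(dd["standard_daily_dose"] > 0)
        if no_dose.any():
            raise ValidationError(
                "oral pancreatic-indicated drugs lack standard_daily_dose: "
                f"{sorted(dd.loc[no_dose, 'drug_id'])}"
            )

        # follow-up bounds
        pat = self.patients.set_index("patient_id")
        for name, col in [
            ("diagnoses", "date"),
            ("prescriptions", "date"),
            ("claim_lines", "service_date"),
        ]:
            df = getattr(self, name)
            if df.empty:
                continue
            lfu = pat.loc[df["patient_id"], "last_follow_up"].to_numpy()
            late = df[col].to_numpy() > lfu
            if late.any():
                raise ValidationError(
                    f"table '{name}' has service dates after last_follow_up "
                    f"for: {sorted(set(df.loc[late, 'patient_id']))[:10]}"
                )
        has_death = self.patients["death_date"].notna()
        if (
            self.patients.loc[has_death, "death_date"]
            > self.patients.loc[has_death, "last_follow_up"]
        ).any():
            raise ValidationError("death_date after last_follow_up")
        return self

    def sorted(self) -> "ClaimsDataset":
        """Canonical row order: by patient_id then date (then tie-breakers)."""
        out = {}
        for name in self.table_names():
            df = getattr(self, name)
            out[name] = (
                df.sort_values(_SORT_KEYS[name], kind="mergesort")
                .reset_index(drop=True)
            )
        return ClaimsDataset(**out)

    def equals(self, other: "ClaimsDataset") -> bool:
        a, b = self.sorted(), other.sorted()
        return all(
            getattr(a, name).equals(getattr(b, name))
            for name in self.table_names()
        )

    def subset(self, patient_ids) -> "ClaimsDataset":
        """Restrict the event tables to the given patients (dictionary kept)."""
        keep = set(patient_ids)
        return ClaimsDataset(
            patients=self.patients[self.patients["patient_id"].isin(keep)],
            diagnoses=self.diagnoses[self.diagnoses["patient_id"].isin(keep)],
            prescriptions=self.prescriptions[
                self.prescriptions["patient_id"].isin(keep)
            ],
            claim_lines=self.claim_lines[
                self.claim_lines["patient_id"].isin(keep)
            ],
            drug_dictionary=self.drug_dictionary,
        )


def _read_table(path: Path, name: str) -> pd.DataFrame:
    schema = _SCHEMAS[name]
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise SchemaError(f"cannot read {path}: {exc}") from exc
    missing = set(schema) - set(df.columns)
    if missing:
        raise SchemaError(
            f"file '{path}' (table '{name}') missing column(s): "
            f"{sorted(missing)}"
        )
    out = {}
    for col, kind in schema.items():
        s = df[col]
        if kind == "str":
            out[col] = s
        elif kind == "int":
            out[col] = s.astype(np.int64)
        elif kind == "float":
            out[col] = s.astype(float)
        elif kind == "float?":
            out[col] = pd.to_numeric(s.replace("", np.nan))
        elif kind == "bool":
            out[col] = s.astype(int).astype(bool)
        elif kind == "date":
            out[col] = pd.to_datetime(s, format="%Y-%m-%d")
        elif kind == "date?":
            out[col] = pd.to_datetime(s.replace("", pd.NA), format="%Y-%m-%d")
    return pd.DataFrame(out)


def read_claims_dataset(
    data_dir, config: AnalysisConfig | None = None
) -> ClaimsDataset:
    """Load and validate the five-table CSV set from ``data_dir``.

    Raises :class:`SchemaError` on missing files/columns and
    :class:`ValidationError` on integrity breaches.
    """
    data_dir = Path(data_dir)
    tables = {}
    for name in _SCHEMAS:
        path = data_dir / f"{name}.csv"
        if not path.exists():
            raise SchemaError(f"missing table file: {path}")
        tables[name] = _read_table(path, name)
    return ClaimsDataset(**tables).validate().sorted()


def _format_table(df: pd.DataFrame, name: str) -> pd.DataFrame:
    schema = _SCHEMAS[name]
    df = df.sort_values(_SORT_KEYS[name], kind="mergesort")
    out = {}
    for col, kind in schema.items():
        s = df[col]
        if kind in ("date", "date?"):
            out[col] = s.dt.strftime("%Y-%m-%d").fillna("")
        elif kind == "bool":
            out[col] = s.astype(int)
        elif kind == "float?":
            out[col] = s.map(lambda v: "" if pd.isna(v) else repr(float(v)))
        elif kind == "float":
            out[col] = s.map(lambda v: repr(float(v)))
        else:
            out[col] = s
    return pd.DataFrame(out)


def write_claims_dataset(ds: ClaimsDataset, data_dir) -> list[Path]:
    """Write the dataset as the canonical CSV set (bit-stable: fixed column
    order, canonical row sort, ISO dates)."""
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in _SCHEMAS:
        path = data_dir / f"{name}.csv"
        _format_table(getattr(ds, name), name).to_csv(
            path, index=False, lineterminator="\n"
        )
        paths.append(path)
    return paths


def jpy_to_usd(amount_jpy, config: AnalysisConfig | None = None):
    """Convert a non-negative JPY amount (scalar or array) to USD.

    Pure division by the configured rate (default 114.59 JPY per USD);
    no rounding happens at this layer.
    """
    rate = (config or AnalysisConfig()).jpy_per_usd
    arr = np.asarray(amount_jpy, dtype=float)
    if (arr < 0).any():
        raise ValueError("JPY amount must be non-negative")
    out = arr / rate
    return float(out) if np.isscalar(amount_jpy) else out
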