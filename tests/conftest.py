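import pandas as pd
import pytest

from oncoclaims import AnalysisConfig, ClaimsDataset, run_pipeline
from oncoclaims.simulate import SimulationConfig, default_drug_dictionary, generate_dataset


def make_dataset(
    patients,
    diagnoses=(),
    prescriptions=(),
    claim_lines=(),
    drug_dictionary=None,
    validate=True,
):
    """Hand-build a small dataset from plain tuples.

    patients: (pid, sex, birth_year, death_date | None, last_follow_up)
    diagnoses: (pid, date, icd10, definitive)
    prescriptions: (pid, drug_id, date, route, quantity)
    claim_lines: (pid, service_date, code_category, cost_jpy)
    """
    ds = ClaimsDataset(
        patients=pd.DataFrame(
            list(patients),
            columns=["patient_id", "sex", "birth_year", "death_date", "last_follow_up"],
        ).assign(
            death_date=lambda d: pd.to_datetime(d["death_date"]),
            last_follow_up=lambda d: pd.to_datetime(d["last_follow_up"]),
        ),
        diagnoses=pd.DataFrame(
            list(diagnoses), columns=["patient_id", "date", "icd10", "definitive"]
        ).assign(date=lambda d: pd.to_datetime(d["date"])),
        prescriptions=pd.DataFrame(
            list(prescriptions),
            columns=["patient_id", "drug_id", "date", "route", "quantity"],
        ).assign(date=lambda d: pd.to_datetime(d["date"])),
        claim_lines=pd.DataFrame(
            list(claim_lines),
            columns=["patient_id", "service_date", "code_category", "cost_jpy"],
        ).assign(service_date=lambda d: pd.to_datetime(d["service_date"])),
        drug_dictionary=(
            drug_dictionary if drug_dictionary is not None else default_drug_dictionary()
        ),
    )
    return ds.validate() if validate else ds


MIXED_VIOLATIONS = dict(
    p_no_definitive_dx=0.03,
    p_no_lookback_claim=0.08,
    p_late_chemo_start=0.05,
    p_dx_before_2015=0.05,
    p_surgery_or_radiotherapy=0.07,
)


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def mixed_cohort():
    """300 simulated patients with every violation type planted, plus the
    full pipeline result — shared across tests."""
    sim = SimulationConfig(n_patients=300, seed=11, **MIXED_VIOLATIONS)
    ds, gt = generate_dataset(sim)
    res = run_pipeline(ds)
    return sim, ds, gt, res


@pytest.fixture(scope="session")
def clean_cohort():
    """200 simulated patients with no planted violations."""
    sim = SimulationConfig(n_patients=200, seed=2)
    ds, gt = generate_dataset(sim)
    res = run_pipeline(ds)
    return sim, ds, gt, res
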