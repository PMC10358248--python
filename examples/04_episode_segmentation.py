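"""Segment one patient's record into treatment episodes.

A hand-built patient: GnP first line (with a restart gap that does NOT
split the line), then a switch to S-1.  The S-1 fill extends the
second-line end by its dispensed day supply (112 units / 4 per day = 28
days beyond the last fill).
"""

import pandas as pd

from oncoclaims import (
    build_episodes,
    detect_switch,
    first_line_drug_set,
    second_line_assignment,
)
from oncoclaims.core import ClaimsDataset
from oncoclaims.simulate import default_drug_dictionary

ds = ClaimsDataset(
    patients=pd.DataFrame(
        [("P1", "male", 1952, pd.NaT, pd.Timestamp("2017-06-30"))],
        columns=["patient_id", "sex", "birth_year", "death_date", "last_follow_up"],
    ),
    diagnoses=pd.DataFrame(
        [("P1", pd.Timestamp("2016-01-10"), "C25.0", True)],
        columns=["patient_id", "date", "icd10", "definitive"],
    ),
    prescriptions=pd.DataFrame(
        [
            ("P1", "GEM", "2016-01-20", "parenteral", 1.0),
            ("P1", "NAB", "2016-01-20", "parenteral", 1.0),
            ("P1", "GEM", "2016-02-03", "parenteral", 1.0),
            # 40-day gap, then a partial restart: still the same first line
            ("P1", "GEM", "2016-03-15", "parenteral", 1.0),
            # a drug outside the first-line set: the switch
            ("P1", "TS1", "2016-05-01", "oral", 112.0),
        ],
        columns=["patient_id", "drug_id", "date", "route", "quantity"],
    ).assign(date=lambda d: pd.to_datetime(d["date"])),
    claim_lines=pd.DataFrame(
        columns=["patient_id", "service_date", "code_category", "cost_jpy"]
    ).assign(service_date=lambda d: pd.to_datetime(d["service_date"])),
    drug_dictionary=default_drug_dictionary(),
).validate()

fl = first_line_drug_set(ds, "P1", "2016-01-10")
switch = detect_switch(ds, "P1", fl)
sl = second_line_assignment(ds, "P1", fl, switch)
print(f"first line : {fl.label} {sorted(fl.component_drugs)} anchored {fl.anchor_date.date()}")
print(f"switch date: {switch.date()} (restart on 2016-03-15 did not trigger it)")
print(f"second line: {sl.label} {sorted(sl.component_drugs)}")
print("\nepisode chain (gapless; OS spans everything):")
for e in build_episodes(ds, "P1", fl, sl, switch):
    days = (e.end - e.start).days
    print(f"  {e.kind:<5} {e.start.date()} .. {e.end.date()}  ({days:>3}d, end: {e.end_reason})")
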