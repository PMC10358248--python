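"""Episode segmentation: day-supply end dates, switch/restart rules,
chain construction, and equivalence with a day-resolution scanner."""

import pandas as pd
import pytest

from oncoclaims import (
    AnalysisConfig,
    build_episodes,
    detect_switch,
    first_line_drug_set,
    line_end_date,
    second_line_assignment,
)
from oncoclaims.simulate import (
    SimulationConfig,
    default_drug_dictionary,
    generate_dataset,
)

from conftest import MIXED_VIOLATIONS, make_dataset
from oracles import day_scan_episodes

CFG = AnalysisConfig()
DD = default_drug_dictionary()


def _rx_frame(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "drug_id", "date", "route", "quantity"]
    ).assign(date=lambda d: pd.to_datetime(d["date"]))


class TestLineEndDate:
    def test_oral_day_supply_extends_end(self):
        # 56 units at 4/day = 14 extra days after the last fill
        rx = _rx_frame([("P1", "TS1", "2016-05-01", "oral", 56.0)])
        end, reason = line_end_date(rx, DD, "2016-12-31", CFG)
        assert end == pd.Timestamp("2016-05-15")
        assert reason == "last_prescription"

    def test_parenteral_line_ends_at_last_administration(self):
        rx = _rx_frame(
            [
                ("P1", "GEM", "2016-05-01", "parenteral", 1.0),
                ("P1", "GEM", "2016-05-15", "parenteral", 1.0),
            ]
        )
        end, _ = line_end_date(rx, DD, "2016-12-31", CFG)
        assert end == pd.Timestamp("2016-05-15")

    def test_end_capped_at_last_follow_up(self):
        rx = _rx_frame([("P1", "TS1", "2016-05-01", "oral", 112.0)])
        end, reason = line_end_date(rx, DD, "2016-05-10", CFG)
        assert end == pd.Timestamp("2016-05-10")
        assert reason == "last_follow_up"

    def test_partial_day_supply_floors(self):
        # 57 units at 4/day: 14.25 days -> 14 under the default floor rule
        rx = _rx_frame([("P1", "TS1", "2016-05-01", "oral", 57.0)])
        end, _ = line_end_date(rx, DD, "2016-12-31", CFG)
        assert end == pd.Timestamp("2016-05-15")

    def test_literal_last_prescription_variant(self):
        cfg = AnalysisConfig(oral_extended_end=False)
        rx = _rx_frame([("P1", "TS1", "2016-05-01", "oral", 56.0)])
        end, _ = line_end_date(rx, DD, "2016-12-31", cfg)
        assert end == pd.Timestamp("2016-05-01")

    def test_empty_line_rejected(self):
        with pytest.raises(ValueError):
            line_end_date(_rx_frame([]), DD, "2016-12-31", CFG)


def _switch_ds(prescriptions, lfu="2017-12-31", death=None):
    return make_dataset(
        patients=[("P1", "male", 1950, death, lfu)],
        diagnoses=[("P1", "2016-01-10", "C25.0", True)],
        prescriptions=prescriptions,
    )


class TestDetectSwitch:
    def test_restart_of_member_drug_is_not_a_switch(self):
        """A GnP patient restarting gemcitabine alone after a 40-day gap
        continues the same first line."""
        ds = _switch_ds(
            [
                ("P1", "GEM", "2016-01-20", "parenteral", 1.0),
                ("P1", "NAB", "2016-01-20", "parenteral", 1.0),
                ("P1", "GEM", "2016-03-01", "parenteral", 1.0),
            ]
        )
        fl = first_line_drug_set(ds, "P1", "2016-01-10")
        assert detect_switch(ds, "P1", fl) is None

    def test_non_member_drug_triggers_switch(self):
        ds = _switch_ds(
            [
                ("P1", "GEM", "2016-01-20", "parenteral", 1.0),
                ("P1", "NAB", "2016-01-20", "parenteral", 1.0),
                ("P1", "TS1", "2016-07-28", "oral", 112.0),
            ]
        )
        fl = first_line_drug_set(ds, "P1", "2016-01-10")
        assert detect_switch(ds, "P1", fl) == pd.Timestamp("2016-07-28")

    def test_restart_gap_extends_pfs1_without_moving_switch(self):
        """Inserting an extra restart block of first-line drugs before the
        switch never changes the switch date, only extends PFS1."""
        base = [
            ("P1", "GEM", "2016-01-20", "parenteral", 1.0),
            ("P1", "NAB", "2016-01-20", "parenteral", 1.0),
            ("P1", "TS1", "2016-07-28", "oral", 112.0),
        ]
        restart = [
            ("P1", "GEM", "2016-04-15", "parenteral", 1.0),
            ("P1", "NAB", "2016-04-15", "parenteral", 1.0),
        ]
        ds0, ds1 = _switch_ds(base), _switch_ds(base + restart)
        fl0 = first_line_drug_set(ds0, "P1", "2016-01-10")
        fl1 = first_line_drug_set(ds1, "P1", "2016-01-10")
        s0, s1 = detect_switch(ds0, "P1", fl0), detect_switch(ds1, "P1", fl1)
        assert s0 == s1
        ep0 = {e.kind: e for e in build_episodes(
            ds0, "P1", fl0, second_line_assignment(ds0, "P1", fl0, s0), s0)}
        ep1 = {e.kind: e for e in build_episodes(
            ds1, "P1", fl1, second_line_assignment(ds1, "P1", fl1, s1), s1)}
        assert ep1["PFS1"].end > ep0["PFS1"].end
        assert ep1["PFS2"].start == ep0["PFS2"].start


class TestBuildEpisodes:
    def test_no_switch_yields_pfs1_tc_os_with_death(self):
        ds = _switch_ds(
            [
                ("P1", "GEM", "2016-01-20", "parenteral", 1.0),
                ("P1", "GEM", "2016-02-20", "parenteral", 1.0),
            ],
            lfu="2016-06-01",
            death="2016-06-01",
        )
        fl = first_line_drug_set(ds, "P1", "2016-01-10")
        eps = {e.kind: e for e in build_episodes(ds, "P1", fl, None, None)}
        assert set(eps) == {"PFS1", "TC", "OS"}
        assert eps["TC"].start == eps["PFS1"].end
        assert eps["TC"].end == pd.Timestamp("2016-06-01")
        assert eps["OS"].end == pd.Timestamp("2016-06-01")
        assert eps["OS"].end_reason == "death"

    def test_switch_yields_gapless_chain(self):
        ds = _switch_ds(
            [
                ("P1", "GEM", "2016-01-20", "parenteral", 1.0),
                ("P1", "GEM", "2016-03-01", "parenteral", 1.0),
                ("P1", "TS1", "2016-04-10", "oral", 112.0),
            ]
        )
        fl = first_line_drug_set(ds, "P1", "2016-01-10")
        sw = detect_switch(ds, "P1", fl)
        sl = second_line_assignment(ds, "P1", fl, sw)
        eps = {e.kind: e for e in build_episodes(ds, "P1", fl, sl, sw)}
        assert set(eps) == {"PFS1", "PD1", "PFS2", "OS"}
        assert eps["PD1"].start == eps["PFS1"].end
        assert eps["PD1"].end == eps["PFS2"].start == sw
        assert eps["PFS2"].end == pd.Timestamp("2016-05-08")  # fill + 28 days
        assert eps["OS"].start == eps["PFS1"].start

    def test_switch_before_computed_end_truncates_pfs1(self):
        """An S-1 fill covering 56 days, with a switch 31 days in: PFS1 is
        cut at the switch and PD1 has zero length."""
        ds = _switch_ds(
            [
                ("P1", "TS1", "2016-01-20", "oral", 224.0),
                ("P1", "GEM", "2016-02-20", "parenteral", 1.0),
            ]
        )
        fl = first_line_drug_set(ds, "P1", "2016-01-10")
        sw = detect_switch(ds, "P1", fl)
        sl = second_line_assignment(ds, "P1", fl, sw)
        eps = {e.kind: e for e in build_episodes(ds, "P1", fl, sl, sw)}
        assert eps["PFS1"].end == sw
        assert eps["PFS1"].end_reason == "switch"
        assert eps["PD1"].start == eps["PD1"].end == sw


def test_planted_episode_boundaries_recovered(mixed_cohort):
    _, _, gt, res = mixed_cohort
    ep = res.episodes.set_index(["patient_id", "kind"])
    inc = gt.verdicts[gt.verdicts["included"]]
    spans = {
        "PFS1": ("pfs1_start", "pfs1_end"),
        "PD1": ("pd1_start", "pd1_end"),
        "TC": ("tc_start", "tc_end"),
        "PFS2": ("pfs2_start", "pfs2_end"),
        "OS": ("os_start", "os_end"),
    }
    for r in inc.itertuples(index=False):
        for kind, (s, e) in spans.items():
            want = pd.notna(getattr(r, s))
            assert ((r.patient_id, kind) in ep.index) == want
            if want:
                got = ep.loc[(r.patient_id, kind)]
                assert got["start"] == getattr(r, s), (r.patient_id, kind)
                assert got["end"] == getattr(r, e), (r.patient_id, kind)


def test_day_scanner_agrees_on_random_cohorts():
    """The vectorized segmentation must match a naive day-by-day scanner."""
    for seed in range(3):
        sim = SimulationConfig(n_patients=50, seed=seed, **MIXED_VIOLATIONS)
        ds, gt = generate_dataset(sim)
        inc = gt.verdicts[gt.verdicts["included"]]
        for r in inc.itertuples(index=False):
            fl = first_line_drug_set(ds, r.patient_id, r.dx_date)
            sw = detect_switch(ds, r.patient_id, fl)
            sl = second_line_assignment(ds, r.patient_id, fl, sw)
            eng = {
                e.kind: (e.start.date(), e.end.date())
                for e in build_episodes(ds, r.patient_id, fl, sl, sw)
            }
            ora = day_scan_episodes(ds, r.patient_id, r.dx_date, CFG)
            assert eng == ora, r.patient_id
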