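"""Report arithmetic, characteristics tables and pipeline determinism."""

import pandas as pd
import pytest

from oncoclaims import (
    characteristics_table,
    pattern_from_counts,
    round_half_up,
    run_pipeline,
    treatment_pattern_report,
)


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected",
        [(68.65, 68.7), (68.64, 68.6), (31.25, 31.3), (0.05, 0.1), (99.95, 100.0)],
    )
    def test_half_up_on_ties(self, x, expected):
        assert round_half_up(x) == expected


class TestPatternArithmetic:
    def test_bsc_percentages_are_pure_count_arithmetic(self):
        out = pattern_from_counts(
            {"FFX": 200, "GnP": 300}, {"FFX": 50, "GnP": 150}
        )
        assert out["bsc_pct"]["FFX"] == 25.0
        assert out["second_line_pct"]["FFX"] == 75.0
        assert out["overall_bsc_pct"] == 40.0
        assert out["overall_second_line_pct"] == 60.0

    def test_other_arm_excluded_from_overall_denominator(self):
        out = pattern_from_counts(
            {"GEM": 100, "OTHER": 900}, {"GEM": 50, "OTHER": 900}
        )
        assert out["overall_bsc_pct"] == 50.0

    def test_all_bsc(self):
        out = pattern_from_counts({"GEM": 10}, {"GEM": 10})
        assert out["overall_bsc_pct"] == 100.0
        assert out["overall_second_line_pct"] == 0.0

    def test_first_line_shares_sum_to_100(self, mixed_cohort):
        _, _, _, res = mixed_cohort
        total = sum(res.patterns.counts["first_line_pct"].values())
        assert abs(total - 100.0) <= 0.3

    def test_recovered_flow_matches_planted_transitions(self):
        """Observed BSC rates per arm track the simulator's second-line
        probabilities within 3 binomial standard errors."""
        from oncoclaims.simulate import SimulationConfig, generate_dataset

        sim = SimulationConfig(n_patients=2000, seed=23)
        ds, gt = generate_dataset(sim)
        res = run_pipeline(ds)
        c = res.patterns.counts
        for reg, p_sl in sim.p_second_line.items():
            n = c["first_line_n"].get(reg, 0)
            if n < 30:
                continue
            se = (p_sl * (1 - p_sl) / n) ** 0.5
            assert abs(c["second_line_pct"][reg] / 100 - p_sl) <= 3 * se, reg


class TestCharacteristics:
    def test_uniform_age_cohort(self):
        from conftest import make_dataset
        from oncoclaims import select_cohort
        from oncoclaims.regimens import RegimenAssignment

        rows = []
        pats = []
        dxs = []
        for i in range(5):
            pid = f"P{i}"
            pats.append((pid, "female", 1946, None, "2017-12-31"))
            dxs.append((pid, "2016-03-01", "C25.0", True))
            rows.append(
                RegimenAssignment(pid, 1, "GEM", frozenset({"GEM"}),
                                  pd.Timestamp("2016-03-10"))
            )
        ds = make_dataset(patients=pats, diagnoses=dxs)
        cohort = pd.DataFrame(
            {
                "patient_id": [p[0] for p in pats],
                "first_confirmed_diagnosis_date": pd.Timestamp("2016-03-01"),
                "included": True,
                "exclusion_reason": "",
            }
        )
        tab = characteristics_table(cohort, ds, rows)
        assert tab["age"].loc["GEM", "median"] == 70
        assert tab["age"].loc["GEM", "min"] == tab["age"].loc["GEM", "max"] == 70
        assert tab["summary"].loc["GEM", "N"] == 5

    def test_dx_year_percentages_sum_to_100_per_year(self, mixed_cohort):
        _, ds, gt, res = mixed_cohort
        tab = characteristics_table(
            res.cohort, ds, res.assignments, gt.characteristics
        )
        row_sums = tab["dx_year_pct"].sum(axis=1)
        assert ((row_sums - 100.0).abs() <= 0.3).all()

    def test_medians_match_direct_recomputation(self, mixed_cohort):
        _, ds, gt, res = mixed_cohort
        tab = characteristics_table(res.cohort, ds, res.assignments)
        pat = ds.patients.set_index("patient_id")
        dx = res.cohort.set_index("patient_id")["first_confirmed_diagnosis_date"]
        by_label = {}
        for a in res.assignments:
            if a.line == 1:
                age = int(dx.loc[a.patient_id].year) - int(
                    pat.loc[a.patient_id, "birth_year"]
                )
                by_label.setdefault(a.label, []).append(age)
        for label, ages in by_label.items():
            assert tab["age"].loc[label, "median"] == pd.Series(ages).median()


class TestPipeline:
    def test_rerun_outputs_byte_identical(self, tmp_path, clean_cohort):
        _, ds, _, _ = clean_cohort
        run_pipeline(ds, out_dir=tmp_path / "a")
        run_pipeline(ds, out_dir=tmp_path / "b")
        files = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert "cost_summary.csv" in files and "episodes.csv" in files
        for name in files:
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_reports_do_not_mutate_inputs(self, clean_cohort):
        _, ds, _, res = clean_cohort
        before = res.cohort.copy()
        treatment_pattern_report(res.cohort, res.assignments, res.episodes)
        pd.testing.assert_frame_equal(before, res.cohort)


def test_cli_end_to_end(tmp_path):
    from click.testing import CliRunner

    from oncoclaims.cli import main

    runner = CliRunner()
    data_dir = tmp_path / "data"
    r = runner.invoke(
        main, ["generate", "--out", str(data_dir), "--seed", "3", "--n", "40"]
    )
    assert r.exit_code == 0, r.output
    out_dir = tmp_path / "reports"
    r = runner.invoke(main, ["run", "--data", str(data_dir), "--out", str(out_dir)])
    assert r.exit_code == 0, r.output
    assert (out_dir / "cost_summary.csv").exists()
    assert (out_dir / "treatment_patterns.txt").exists()
    cohort_csv = tmp_path / "cohort.csv"
    r = runner.invoke(
        main,
        ["select", "--data", str(data_dir), "--out", str(cohort_csv)],
    )
    assert r.exit_code == 0, r.output
    assert cohort_csv.exists()
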