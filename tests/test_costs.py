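"""Cost engine: month windows, attribution, conservation, summaries."""

import numpy as np
import pandas as pd
import pytest

from oncoclaims import (
    AnalysisConfig,
    CATEGORIES,
    episode_totals,
    jpy_to_usd,
    month_windows,
    monthly_costs,
    summarize_costs,
)
from oncoclaims.costs import category_shares

from conftest import make_dataset
from oracles import brute_force_cost_summary

CFG = AnalysisConfig()


class TestMonthWindows:
    @pytest.mark.parametrize(
        "days,expected",
        [(29, 0), (30, 1), (100, 3), (180, 6), (200, 6), (0, 0)],
    )
    def test_window_count(self, days, expected):
        start = pd.Timestamp("2016-01-01")
        assert len(month_windows(start, start + pd.Timedelta(days=days))) == expected

    def test_windows_are_half_open_and_contiguous(self):
        start = pd.Timestamp("2016-01-01")
        ws = month_windows(start, start + pd.Timedelta(days=95))
        assert ws[0][1] == start
        for (_, _, hi), (_, lo, _) in zip(ws, ws[1:]):
            assert hi == lo


def _episode_frame(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "kind", "start", "end", "end_reason"]
    ).assign(
        start=lambda d: pd.to_datetime(d["start"]),
        end=lambda d: pd.to_datetime(d["end"]),
    )


class TestAttribution:
    def _ds(self, claim_lines):
        return make_dataset(
            patients=[("P1", "male", 1950, None, "2017-12-31")],
            claim_lines=claim_lines,
        )

    def test_single_claim_lands_in_its_cell_in_usd(self):
        ds = self._ds([("P1", "2016-01-10", 25, 114_590)])
        eps = _episode_frame(
            [("P1", "PFS1", "2016-01-01", "2016-03-01", "last_prescription")]
        )
        m = monthly_costs(ds, eps)
        cell = m[(m["episode_kind"] == "PFS1") & (m["month"] == 1)].iloc[0]
        assert cell["medicines"] == 114_590
        assert jpy_to_usd(cell["medicines"]) == pytest.approx(1000.0)

    def test_claim_on_day_30_belongs_to_month_two(self):
        ds = self._ds([("P1", "2016-01-31", 25, 777)])  # episode day 30
        eps = _episode_frame(
            [("P1", "PFS1", "2016-01-01", "2016-03-01", "last_prescription")]
        )
        m = monthly_costs(ds, eps).set_index("month")
        assert m.loc[1, "total_jpy"] == 0
        assert m.loc[2, "total_jpy"] == 777

    def test_claim_outside_any_window_ignored(self):
        # 45-day episode: one window; a claim on day 40 is in the tail
        ds = self._ds([("P1", "2016-02-10", 25, 500)])
        eps = _episode_frame(
            [("P1", "PFS1", "2016-01-01", "2016-02-15", "last_prescription")]
        )
        m = monthly_costs(ds, eps)
        assert m["total_jpy"].sum() == 0

    def test_category_sums_equal_totals(self, mixed_cohort):
        _, _, _, res = mixed_cohort
        diff = res.monthly[list(CATEGORIES)].sum(axis=1) - res.monthly["total_jpy"]
        assert (diff.abs() <= 1e-6).all()

    def test_monthly_cells_equal_planted_costs(self, mixed_cohort):
        _, _, gt, res = mixed_cohort
        m = res.monthly.melt(
            id_vars=["patient_id", "episode_kind", "month"],
            value_vars=list(CATEGORIES),
            var_name="category",
            value_name="cost_jpy",
        ).set_index(["patient_id", "episode_kind", "month", "category"])["cost_jpy"]
        g = gt.monthly_costs.set_index(
            ["patient_id", "episode_kind", "month", "category"]
        )["cost_jpy"]
        assert g.index.difference(m.index).empty
        assert (m - g.reindex(m.index, fill_value=0)).abs().max() == 0

    def test_cell_n_is_non_increasing_in_month(self, mixed_cohort):
        _, _, _, res = mixed_cohort
        for (_, kind), grp in res.cost_summary.groupby(["label", "episode_kind"]):
            ns = grp.sort_values("month")["N"].tolist()
            assert all(b <= a for a, b in zip(ns, ns[1:])), kind


class TestSummaries:
    def test_two_patient_hand_arithmetic(self):
        ds = make_dataset(
            patients=[
                ("P1", "male", 1950, None, "2017-12-31"),
                ("P2", "male", 1950, None, "2017-12-31"),
            ],
            claim_lines=[
                ("P1", "2016-01-05", 25, round(100 * 114.59)),
                ("P2", "2016-01-05", 25, round(300 * 114.59)),
            ],
        )
        eps = _episode_frame(
            [
                ("P1", "PFS1", "2016-01-01", "2016-02-15", "last_prescription"),
                ("P2", "PFS1", "2016-01-01", "2016-02-15", "last_prescription"),
            ]
        )
        s = summarize_costs(monthly_costs(ds, eps)).set_index(["episode_kind", "month"])
        row = s.loc[("PFS1", 1)]
        assert row["N"] == 2
        assert row["mean"] == pytest.approx(200.0, abs=0.01)
        assert row["median"] == pytest.approx(200.0, abs=0.01)
        assert row["sd"] == pytest.approx(141.42, abs=0.01)

    def test_singleton_cell_sd_is_zero(self):
        ds = make_dataset(
            patients=[("P1", "male", 1950, None, "2017-12-31")],
            claim_lines=[("P1", "2016-01-05", 25, 1000)],
        )
        eps = _episode_frame(
            [("P1", "PFS1", "2016-01-01", "2016-02-15", "last_prescription")]
        )
        s = summarize_costs(monthly_costs(ds, eps))
        assert s["N"].iloc[0] == 1
        assert s["sd"].iloc[0] == 0.0
        assert s["mean"].iloc[0] == s["median"].iloc[0] == s["min"].iloc[0]

    def test_summary_matches_brute_force(self, mixed_cohort):
        _, ds, _, res = mixed_cohort
        expected = brute_force_cost_summary(ds, res.episodes, CFG)
        got = summarize_costs(
            res.monthly.drop(columns=["label"])
        ).set_index(["episode_kind", "month"])
        assert set(got.index) == set(expected)
        for key, stats in expected.items():
            row = got.loc[key]
            assert row["N"] == stats["N"]
            for stat in ("mean", "sd", "min", "median", "max"):
                assert row[stat] == pytest.approx(stats[stat], rel=1e-9), (key, stat)

    def test_usd_equals_jpy_scaled(self, mixed_cohort):
        _, _, _, res = mixed_cohort
        s = summarize_costs(res.monthly)
        jpy_means = (
            res.monthly.groupby(["label", "episode_kind", "month"])["total_jpy"]
            .mean()
            .reset_index(drop=True)
        )
        assert np.allclose(s["mean"].to_numpy(), jpy_means.to_numpy() / 114.59)


class TestShares:
    def test_all_hospitalization_gives_100_percent(self):
        ds = make_dataset(
            patients=[("P1", "male", 1950, None, "2017-12-31")],
            claim_lines=[("P1", "2016-01-05", 95, 50_000)],
        )
        eps = _episode_frame(
            [("P1", "PFS1", "2016-01-01", "2016-02-15", "last_prescription")]
        )
        m = monthly_costs(ds, eps).assign(label="GnP")
        shares = category_shares(m).set_index(["label", "month"])
        row = shares.loc[("GnP", 1)]
        assert row["hospitalization"] == pytest.approx(100.0)
        assert row[[c for c in CATEGORIES if c != "hospitalization"]].sum() == 0

    def test_shares_sum_to_100(self, mixed_cohort):
        _, _, _, res = mixed_cohort
        sums = res.shares[list(CATEGORIES)].sum(axis=1)
        assert np.allclose(sums, 100.0, atol=1e-6)

    def test_shares_limited_to_three_months(self, mixed_cohort):
        _, _, _, res = mixed_cohort
        assert res.shares["month"].max() <= 3


class TestEpisodeTotals:
    def test_totals_equal_planted_costs(self, mixed_cohort):
        _, _, gt, res = mixed_cohort
        tot = res.totals.set_index(["patient_id", "kind"])["total_cost_jpy"]
        inc = gt.verdicts[gt.verdicts["included"]]
        cols = {
            "PFS1": "pfs1_cost_jpy",
            "PD1": "pd1_cost_jpy",
            "TC": "tc_cost_jpy",
            "PFS2": "pfs2_cost_jpy",
            "OS": "os_cost_jpy",
        }
        for r in inc.itertuples(index=False):
            for kind, col in cols.items():
                if (r.patient_id, kind) in tot.index:
                    assert tot.loc[(r.patient_id, kind)] == getattr(r, col)

    def test_episode_total_at_least_monthly_cells(self, mixed_cohort):
        _, _, _, res = mixed_cohort
        cells = (
            res.monthly.groupby(["patient_id", "episode_kind"])["total_jpy"].sum()
        )
        tot = res.totals.set_index(["patient_id", "kind"])["total_cost_jpy"]
        for key, cell_sum in cells.items():
            assert tot.loc[key] >= cell_sum
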