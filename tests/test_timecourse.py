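"""Trend classification, intracellular cross-referencing and trajectories."""

import numpy as np
import pandas as pd
import pytest

import endomir as em
from endomir.errors import ContractError
from endomir.timecourse import TrendTable

from conftest import pearson_oracle

TIMES = (15.0, 30.0, 60.0, 120.0, 240.0)


def _tc_sheet(times=TIMES, replicates=1, compartment="conditioned_medium"):
    rows = []
    for t in times:
        for r in range(1, replicates + 1):
            rows.append(
                dict(
                    sample_id=f"s-t{t:g}-r{r}",
                    compartment=compartment,
                    donor="1332",
                    culture_medium="MCDB",
                    time_min=t,
                    replicate=r,
                )
            )
    return em.SampleSheet(pd.DataFrame(rows))


def _matrix(rows: dict, sheet) -> em.ProbeIntensityMatrix:
    return em.ProbeIntensityMatrix(
        pd.DataFrame(rows, index=list(sheet.table["sample_id"])).T
    )


class TestTrendClassify:
    def test_strictly_increasing_series_is_increasing(self):
        sheet = _tc_sheet()
        m = _matrix({"p": [1.0, 2.0, 3.0, 4.0, 5.0]}, sheet)
        tab = em.trend_classify(m, sheet, fraction="sec", mode="intensity")
        assert tab.table.loc["p", "category"] == "increasing"

    def test_constant_series_is_unchanged(self):
        sheet = _tc_sheet()
        m = _matrix({"p": [2.0] * 5}, sheet)
        tab = em.trend_classify(m, sheet, fraction="sec", mode="intensity")
        assert np.isnan(tab.table.loc["p", "r"])
        assert tab.table.loc["p", "category"] == "unchanged"

    def test_r_matches_hand_computed_pearson(self):
        sheet = _tc_sheet()
        values = [10.0, 8.0, 9.0, 4.0, 2.0]
        m = _matrix({"p": values}, sheet)
        tab = em.trend_classify(m, sheet, fraction="sec", mode="intensity")
        expected = pearson_oracle(list(TIMES), values)
        assert tab.table.loc["p", "r"] == pytest.approx(expected, abs=1e-12)
        # r ~ -0.94 with n=5 is significant at alpha=0.05 -> decreasing
        assert tab.table.loc["p", "category"] == "decreasing"

    def test_replicates_averaged_before_correlation(self):
        sheet = _tc_sheet(times=(10.0, 20.0, 40.0), replicates=2)
        # replicate pairs average to (1, 2, 4): linear in the time grid
        m = _matrix({"p": [0.5, 1.5, 1.0, 3.0, 3.0, 5.0]}, sheet)
        tab = em.trend_classify(m, sheet, fraction="sec", mode="intensity")
        assert tab.table.loc["p", "n_timepoints"] == 3
        assert tab.table.loc["p", "r"] == pytest.approx(1.0)

    def test_fewer_than_three_timepoints_rejected(self):
        sheet = _tc_sheet(times=(10.0, 20.0))
        m = _matrix({"p": [1.0, 2.0]}, sheet)
        with pytest.raises(ContractError, match="3 distinct time points"):
            em.trend_classify(m, sheet, fraction="sec", mode="intensity")

    def test_sample_order_invariance(self):
        sheet = _tc_sheet()
        m = _matrix({"p": [1.0, 2.0, 3.0, 4.0, 5.0], "q": [5.0, 1.0, 4.0, 2.0, 3.0]}, sheet)
        shuffled_sheet = em.SampleSheet(sheet.table.iloc[::-1].reset_index(drop=True))
        t1 = em.trend_classify(m, sheet, fraction="sec", mode="intensity")
        t2 = em.trend_classify(m, shuffled_sheet, fraction="sec", mode="intensity")
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_category_counts_conserved(self, small_world):
        sheet = em.preset_designs("timecourse", small_world.config)
        m = em.simulate_arrays(small_world, sheet, seed=12)
        sub = em.subtract_background(m, sheet)
        det = em.call_detection(sub, 0.05)
        tab = em.trend_classify(sub, sheet, fraction="sec", mode="intensity", detection=det)
        c = tab.counts()
        assert c["increasing"] + c["decreasing"] + c["unchanged"] == c["total"]

    def test_zero_noise_recovery_of_generator_truth(self):
        cfg = em.GeneratorConfig(
            n_mirnas=150, n_int_only=50, n_sec_only=40, n_shared=60,
            trend_counts=(39, 7), noise_sd=0.0, nonlinear_probe_fraction=0.0,
            seed=23,
        )
        w = em.generate_world(cfg)
        sheet = em.preset_designs("timecourse", cfg)
        m = em.simulate_arrays(w, sheet, seed=0)
        sub = em.subtract_background(m, sheet)
        tab = em.trend_classify(sub, sheet, fraction="sec", mode="intensity")
        truth = w.trend_truth().loc[tab.table.index]
        assert (tab.table["category"] == truth).all()
        assert tab.counts()["increasing"] == 39
        assert tab.counts()["decreasing"] == 7


class TestCrossReference:
    def _table(self, cats: dict, fraction) -> TrendTable:
        df = pd.DataFrame(
            {"r": 0.0, "p": 1.0, "q": 1.0, "category": pd.Series(cats), "n_timepoints": 5}
        )
        df.index.name = "mirna"
        return TrendTable(table=df, fraction=fraction, mode="normalized", alpha=0.05)

    def test_joined_row_keeps_both_categories(self):
        sec = self._table({"a": "decreasing"}, "sec")
        int_ = self._table({"a": "increasing"}, "int")
        joined, contingency = em.cross_reference(sec, int_)
        assert joined.iloc[0].tolist() == ["a", "decreasing", "increasing"]
        assert contingency.loc["decreasing", "increasing"] == 1

    def test_identical_tables_are_diagonal(self):
        cats = {"a": "increasing", "b": "decreasing", "c": "unchanged"}
        joined, contingency = em.cross_reference(self._table(cats, "sec"), self._table(cats, "int"))
        assert (joined["sec_category"] == joined["int_category"]).all()
        off = contingency.values.sum() - np.trace(contingency.values)
        assert off == 0

    def test_disjoint_tables_warn_and_return_empty(self):
        sec = self._table({"a": "increasing"}, "sec")
        int_ = self._table({"b": "increasing"}, "int")
        with pytest.warns(UserWarning, match="no miRNAs"):
            joined, contingency = em.cross_reference(sec, int_)
        assert joined.empty and contingency.empty

    def test_synthetic_contingency_matches_truth_at_zero_noise(self):
        cfg = em.GeneratorConfig(
            n_mirnas=120, n_int_only=30, n_sec_only=30, n_shared=40,
            trend_counts=(10, 5), noise_sd=0.0, nonlinear_probe_fraction=0.0,
            seed=31,
        )
        w = em.generate_world(cfg)
        sheet = em.preset_designs("timecourse", cfg)
        m = em.simulate_arrays(w, sheet, seed=0)
        sub = em.subtract_background(m, sheet)
        sec = em.trend_classify(sub, sheet, fraction="sec", mode="intensity")
        int_ = em.trend_classify(sub, sheet, fraction="int", mode="intensity")
        joined, contingency = em.cross_reference(sec, int_)
        # intracellular profiles are constant over time in the generator:
        # every joined miRNA is intracellularly unchanged, and the secretory
        # categories match the assigned truth
        assert set(joined["int_category"]) == {"unchanged"}
        truth = w.trend_truth()
        shared = joined.set_index("mirna")
        assert (shared["sec_category"] == truth.loc[shared.index]).all()


class TestTotalSignalTrajectory:
    def test_totals_equal_bruteforce_column_sums(self):
        sheet = _tc_sheet(times=(10.0, 20.0, 40.0))
        m = _matrix({"p": [1.0, 2.0, 3.0], "q": [4.0, 5.0, 6.0]}, sheet)
        tab = em.total_signal_trajectory(m, sheet, fraction="sec")
        assert tab["total_intensity"].tolist() == [5.0, 7.0, 9.0]

    def test_secreted_totals_increase_in_noiseless_generator(self):
        cfg = em.GeneratorConfig(
            n_mirnas=150, n_int_only=50, n_sec_only=40, n_shared=60,
            trend_counts=(39, 7), noise_sd=0.0, seed=23,
        )
        w = em.generate_world(cfg)
        sheet = em.preset_designs("timecourse", cfg)
        m = em.simulate_arrays(w, sheet, seed=0)
        sub = em.subtract_background(m, sheet)
        tab = em.total_signal_trajectory(sub, sheet, fraction="sec")
        assert tab["total_intensity"].is_monotonic_increasing

    def test_flat_intracellular_totals_constant_at_zero_noise(self):
        cfg = em.GeneratorConfig(
            n_mirnas=100, n_int_only=30, n_sec_only=30, n_shared=30,
            noise_sd=0.0, seed=2,
        )
        w = em.generate_world(cfg)
        sheet = em.preset_designs("timecourse", cfg)
        m = em.simulate_arrays(w, sheet, seed=0)
        tab = em.total_signal_trajectory(m, sheet, fraction="int")
        assert tab["total_intensity"].nunique() == 1
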