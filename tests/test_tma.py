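"""TMA scoring pipeline and survival statistics."""

import numpy as np
import pandas as pd
import pytest
from statistics import median

from collmot.tma import (
    ECM_MARKERS,
    ecm_score,
    exclude_low_cell_patients,
    km_estimate,
    logrank_test,
    patient_aggregate,
    score_cohort,
    yap_group,
)
from collmot.synthetic import make_survival_table


def build_cells(patient_counts: dict, value: float = 1.0) -> pd.DataFrame:
    """Minimal long-format cell table: one row per cell per marker."""
    markers = list(ECM_MARKERS) + ["YAP"]
    rows = []
    for pid, comps in patient_counts.items():
        for comp, n in comps.items():
            for marker in markers:
                rows.append(
                    pd.DataFrame(
                        {
                            "patient_id": pid,
                            "core_id": f"{pid}_core0",
                            "compartment": comp,
                            "cell_id": np.arange(n),
                            "marker": marker,
                            "nuclear_mean": value,
                            "extranuclear_mean": value,
                        }
                    )
                )
    if not rows:
        return pd.DataFrame(
            columns=["patient_id", "core_id", "compartment", "cell_id", "marker",
                     "nuclear_mean", "extranuclear_mean"]
        )
    return pd.concat(rows, ignore_index=True)


class TestExclusion:
    def test_below_threshold_in_one_compartment_excluded(self):
        cells = build_cells(
            {"A": {"stromal": 99, "epithelial": 500}, "B": {"stromal": 200, "epithelial": 200}}
        )
        filtered, report = exclude_low_cell_patients(cells)
        assert report.excluded_ids == ["A"]
        assert set(filtered["patient_id"]) == {"B"}

    def test_boundary_exactly_100_retained(self):
        cells = build_cells({"A": {"stromal": 100, "epithelial": 100}})
        _, report = exclude_low_cell_patients(cells)
        assert report.excluded_ids == [] and report.n_retained == 1

    def test_synthetic_cohort_retains_expected_patients(self, small_cohort):
        _, report = exclude_low_cell_patients(small_cohort.cells)
        assert report.n_retained == 27  # 30 patients, 3 forced low

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            exclude_low_cell_patients(build_cells({}))


class TestAggregation:
    def test_stromal_median(self):
        cells = build_cells({"A": {"stromal": 3, "epithelial": 3}})
        mask = (cells["marker"] == "fibronectin") & (cells["compartment"] == "stromal")
        cells.loc[mask, "extranuclear_mean"] = [1.0, 2.0, 9.0]
        summary = patient_aggregate(cells)
        assert summary.loc["A", "fibronectin"] == 2.0

    def test_cores_pooled(self):
        cells = build_cells({"A": {"stromal": 4, "epithelial": 2}})
        mask = (cells["marker"] == "laminin") & (cells["compartment"] == "stromal")
        cells.loc[mask, "extranuclear_mean"] = [1.0, 2.0, 3.0, 4.0]
        cells.loc[mask, "core_id"] = ["c1", "c1", "c2", "c2"]
        summary = patient_aggregate(cells)
        assert summary.loc["A", "laminin"] == 2.5

    def test_yap_epithelial_nuclear_mean(self):
        cells = build_cells({"A": {"stromal": 2, "epithelial": 3}})
        mask = (cells["marker"] == "YAP") & (cells["compartment"] == "epithelial")
        cells.loc[mask, "nuclear_mean"] = [10.0, 20.0, 30.0]
        assert patient_aggregate(cells).loc["A", "yap_nuclear"] == 20.0

    def test_missing_marker_rejected(self):
        cells = build_cells({"A": {"stromal": 2, "epithelial": 2}})
        with pytest.raises(ValueError, match="missing markers"):
            patient_aggregate(cells[cells["marker"] != "laminin"])

    def test_row_order_invariance(self, small_cohort):
        cells = small_cohort.cells
        shuffled = cells.sample(frac=1.0, random_state=0)
        a = patient_aggregate(cells).sort_index()
        b = patient_aggregate(shuffled).sort_index()
        pd.testing.assert_frame_equal(a, b)


class TestEcmScore:
    @staticmethod
    def hand_summaries():
        return pd.DataFrame(
            {
                "fibronectin": [5.0, 1.0, 4.0, 2.0],
                "collagen_I": [5.0, 1.0, 2.0, 4.0],
                "SMA": [5.0, 1.0, 4.0, 2.0],
                "laminin": [5.0, 1.0, 1.0, 4.0],
                "vinculin": [5.0, 1.0, 2.0, 3.0],
                "yap_nuclear": [1.0, 2.0, 3.0, 4.0],
            },
            index=["P1", "P2", "P3", "P4"],
        )

    def test_four_patient_table_matches_brute_force(self):
        summaries = self.hand_summaries()
        scored = ecm_score(summaries)
        for pid in summaries.index:
            expected = sum(
                summaries.loc[pid, m] > median(summaries[m]) for m in ECM_MARKERS
            )
            assert scored.loc[pid, "ecm_score"] == expected
            assert scored.loc[pid, "ecm_group"] == ("low" if expected <= 2 else "high")

    def test_all_above_and_all_below(self):
        scored = ecm_score(self.hand_summaries())
        assert scored.loc["P1", "ecm_score"] == 5 and scored.loc["P1", "ecm_group"] == "high"
        assert scored.loc["P2", "ecm_score"] == 0 and scored.loc["P2", "ecm_group"] == "low"

    def test_value_at_median_scores_zero(self):
        summaries = pd.DataFrame(
            {m: [1.0, 1.0, 2.0] for m in ECM_MARKERS} | {"yap_nuclear": [1, 2, 3]},
            index=["A", "B", "C"],
        )
        scored = ecm_score(summaries)
        # A and B sit exactly at the median (1.0): strictly-above rule gives 0
        assert scored.loc["A", "ecm_score"] == 0
        assert scored.loc["C", "ecm_score"] == 5

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError):
            ecm_score(self.hand_summaries().iloc[:1])

    def test_group_partition_exhaustive(self, small_cohort):
        scored, _ = score_cohort(small_cohort.cells)
        assert scored["ecm_score"].between(0, 5).all()
        assert set(scored["ecm_group"]) <= {"low", "high"}
        assert ((scored["ecm_score"] <= 2) == (scored["ecm_group"] == "low")).all()

    def test_pipeline_recovers_constructed_scores(self, small_cohort):
        scored, _ = score_cohort(small_cohort.cells)
        truth = small_cohort.truth.set_index("patient_id").loc[scored.index]
        assert (scored["ecm_score"] == truth["true_ecm_score"]).all()
        assert (scored["ecm_group"] == truth["true_ecm_group"]).all()


class TestYapGroup:
    def test_above_median_high_at_median_low(self):
        summaries = TestEcmScore.hand_summaries()
        groups = yap_group(summaries)  # yap values 1,2,3,4; median 2.5
        assert list(groups["yap_group"]) == ["low", "low", "high", "high"]

    def test_two_patient_split(self):
        summaries = TestEcmScore.hand_summaries().iloc[:2]
        groups = yap_group(summaries)
        assert sorted(groups["yap_group"]) == ["high", "low"]

    def test_value_equal_to_median_is_low(self):
        summaries = pd.DataFrame(
            {m: [1.0, 2.0, 3.0] for m in ECM_MARKERS} | {"yap_nuclear": [1.0, 2.0, 3.0]},
            index=["A", "B", "C"],
        )
        assert yap_group(summaries).loc["B", "yap_group"] == "low"


class TestKaplanMeier:
    def test_no_censoring_closed_form(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [1.0, 2 / 3, 1 / 3, 0.0], atol=1e-15)

    def test_all_censored_stays_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        np.testing.assert_allclose(km.survival, [1.0])

    def test_mixed_censoring_matches_hand_computation(self):
        times = [1, 2, 2, 3, 4, 4, 5, 6, 7, 8]
        events = [1, 0, 1, 1, 0, 1, 0, 1, 0, 0]
        km = km_estimate(times, events)
        expected = [1.0, 9 / 10, 8 / 10, 24 / 35, 4 / 7, 8 / 21]
        np.testing.assert_allclose(km.survival, expected, atol=1e-12)
        np.testing.assert_allclose(km.time, [0, 1, 2, 3, 4, 6])
        np.testing.assert_array_equal(km.at_risk, [10, 10, 9, 7, 6, 3])

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        tbl = make_survival_table(60, hazard_ratio=2.0, seed=9)
        km = km_estimate(tbl["time_months"], tbl["event"])
        kmf = KaplanMeierFitter().fit(tbl["time_months"], tbl["event"])
        for t, s in zip(km.time, km.survival):
            assert kmf.predict(t) == pytest.approx(s, abs=1e-10)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 40)
        km = km_estimate(t, np.ones(40, int))
        for ti, si in zip(km.time[1:], km.survival[1:]):
            assert si == pytest.approx(np.mean(t > ti), abs=1e-12)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [1, 1])

    def test_step_lookup(self):
        km = km_estimate([1.0, 2.0], [1, 1])
        assert km.at(0.5) == 1.0
        assert km.at(1.5) == pytest.approx(0.5)


class TestLogrank:
    def test_identical_groups_null(self):
        times = [1.0, 2.0, 3.0, 4.0] * 2
        events = [1, 1, 0, 1] * 2
        groups = ["a"] * 4 + ["b"] * 4
        res = logrank_test(times, events, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        tbl = make_survival_table(80, hazard_ratio=2.5, seed=4)
        mine = logrank_test(tbl["time_months"], tbl["event"], tbl["group"])
        hi = tbl["group"] == "high"
        theirs = ll_logrank(
            tbl.loc[hi, "time_months"], tbl.loc[~hi, "time_months"],
            tbl.loc[hi, "event"], tbl.loc[~hi, "event"],
        )
        assert mine.statistic == pytest.approx(theirs.test_statistic, rel=1e-9)
        assert mine.p_value == pytest.approx(theirs.p_value, rel=1e-9)

    def test_strong_effect_detected(self):
        tbl = make_survival_table(200, hazard_ratio=3.0, seed=5)
        res = logrank_test(tbl["time_months"], tbl["event"], tbl["group"])
        assert res.p_value < 0.01

    def test_one_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], ["a", "a"])

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [0, 0], ["a", "b"])
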