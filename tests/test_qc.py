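import numpy as np
import pandas as pd
import pytest

import cttolite as ct
from cttolite.qc import (
    flag_compliance,
    flag_severe_inconsistency,
    flag_worst_state,
    interviewer_summary,
    make_analytic_sample,
    run_qc,
)


def _resp(pairs, wheelchair=300.0, task=90.0):
    return pd.DataFrame(
        [
            {
                "respondent_id": 1,
                "interviewer_id": 1,
                "block_id": 1,
                "state": s,
                "ctto": v,
                "wheelchair_seconds": wheelchair,
                "task_seconds": task,
            }
            for s, v in pairs
        ]
    )


class TestCompliance:
    def test_above_both_thresholds(self):
        group = _resp([("11111", 1.0)] * 1, wheelchair=200.0, task=1800.0)
        flags = flag_compliance(group)
        assert not flags["wheelchair_time_violation"]
        assert not flags["ctto_time_violation"]

    def test_boundaries(self):
        # >= 3 min passes at exactly 180 s; >= 10 min passes at exactly 600 s
        ok = _resp([(f"1111{k}", 0.5) for k in range(1, 6)], wheelchair=180.0, task=120.0)
        flags = flag_compliance(ok)
        assert not flags["wheelchair_time_violation"]
        assert not flags["ctto_time_violation"]
        low_wc = _resp([("11111", 1.0)], wheelchair=179.0, task=700.0)
        assert flag_compliance(low_wc)["wheelchair_time_violation"]
        low_task = _resp([("11111", 1.0)], task=599.0)
        assert flag_compliance(low_task)["ctto_time_violation"]

    def test_missing_timings_flagged(self):
        group = _resp([("11111", 1.0)], wheelchair=np.nan)
        assert flag_compliance(group)["wheelchair_time_violation"]


class TestSevereInconsistency:
    def test_dominating_state_half_point_lower(self):
        # 11121 dominates 11122; -0.2 <= 0.4 - 0.5
        flagged, pairs = flag_severe_inconsistency(
            _resp([("11121", -0.2), ("11122", 0.4)])
        )
        assert flagged and ("11121", "11122") in pairs

    def test_monotone_data_not_flagged(self):
        flagged, pairs = flag_severe_inconsistency(
            _resp([("11112", 0.95), ("21232", 0.5), ("55555", -0.9)])
        )
        assert not flagged and not pairs

    def test_boundary_inclusive_at_half(self):
        assert flag_severe_inconsistency(_resp([("11121", -0.1), ("11122", 0.4)]))[0]
        assert not flag_severe_inconsistency(
            _resp([("11121", -0.05), ("11122", 0.4)])
        )[0]

    def test_duplicate_state_rejected(self):
        with pytest.raises(ValueError):
            flag_severe_inconsistency(_resp([("11121", 0.1), ("11121", 0.2)]))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        states = ["11111", "21111", "22111", "32211", "55555", "12345", "21212"]
        for _ in range(25):
            vals = np.round(rng.integers(-20, 21, size=len(states)) * 0.05, 2)
            group = _resp(list(zip(states, vals)))
            expected = any(
                ct.dominates(a, b) and va <= vb - 0.5 + 1e-9
                for a, va in zip(states, vals)
                for b, vb in zip(states, vals)
            )
            assert flag_severe_inconsistency(group)[0] == expected


class TestWorstState:
    def test_worst_state_lowest_ok(self):
        group = _resp([("55555", -0.9), ("11112", 0.9), ("12345", -0.9)])
        assert flag_worst_state(group) is False

    def test_other_state_strictly_below(self):
        group = _resp([("55555", -0.5), ("12345", -0.6)])
        assert flag_worst_state(group) is True

    def test_tie_at_minus_one_complies(self):
        group = _resp([("55555", -1.0), ("12345", -1.0)])
        assert flag_worst_state(group) is False

    def test_missing_worst_state_skipped(self):
        assert flag_worst_state(_resp([("12345", 0.0)])) is None


class TestInterviewerSummary:
    def test_single_interviewer_all_ones(self):
        frame = _resp([(f"1111{k}", 1.0) for k in range(1, 6)])
        summary = interviewer_summary(frame)
        row = summary[summary["interviewer_id"] == 1].iloc[0]
        assert row["proportion_at_1"] == 1.0
        assert row["proportion_at_minus1"] == 0.0
        assert row["proportion_worse_than_dead"] == 0.0

    def test_identical_interviewers_identical_rows(self):
        a = _resp([("11121", 0.5), ("55555", -0.5)])
        b = a.copy()
        b["interviewer_id"] = 2
        b["respondent_id"] = 2
        summary = interviewer_summary(pd.concat([a, b]))
        r1 = summary[summary["interviewer_id"] == 1].drop(columns="interviewer_id")
        r2 = summary[summary["interviewer_id"] == 2].drop(columns="interviewer_id")
        assert (r1.to_numpy() == r2.to_numpy()).all()

    def test_pooled_negative_fraction_near_study_level(self, study_cohort):
        # the study observed 44.3% of responses below zero
        summary = interviewer_summary(study_cohort)
        pooled = summary[summary["interviewer_id"] == "pooled"].iloc[0]
        assert pooled["proportion_worse_than_dead"] == pytest.approx(0.443, abs=0.03)


class TestAnalyticSample:
    def test_only_severe_inconsistency_excludes(self, lite_design, published_truth, quiet_noise):
        frame = ct.simulate_cohort(
            lite_design, 100, published_truth.scaled(0.5), quiet_noise,
            inconsistency_rate=0.1, seed=17, compliance_violation_rate=0.3,
        )
        report = run_qc(frame)
        analytic = make_analytic_sample(frame, report)
        flagged_truth = set(
            frame.loc[frame["flagged_inconsistent_truth"], "respondent_id"]
        )
        kept = set(analytic["respondent_id"])
        assert kept == set(frame["respondent_id"]) - set(
            report.respondent_flags.index[report.respondent_flags["severe_inconsistency"]]
        )
        # compliance violations alone never exclude
        compliance_only = report.respondent_flags[
            (report.respondent_flags["wheelchair_time_violation"]
             | report.respondent_flags["ctto_time_violation"])
            & ~report.respondent_flags["severe_inconsistency"]
        ]
        assert set(compliance_only.index) <= kept
        assert len(analytic) == 20 * len(kept)
        # injected inconsistencies are all caught (sensitivity 1.0)
        assert flagged_truth <= set(
            report.respondent_flags.index[report.respondent_flags["severe_inconsistency"]]
        )

    def test_sensitivity_one_and_low_false_positives(
        self, lite_design, published_truth, quiet_noise
    ):
        frame = ct.simulate_cohort(
            lite_design, 200, published_truth.scaled(0.5), quiet_noise,
            inconsistency_rate=0.15, seed=29,
        )
        report = run_qc(frame)
        truth_flag = frame.groupby("respondent_id")["flagged_inconsistent_truth"].any()
        qc_flag = report.respondent_flags["severe_inconsistency"]
        injected = truth_flag[truth_flag].index
        clean = truth_flag[~truth_flag].index
        assert qc_flag.loc[injected].all()  # sensitivity 1.0
        assert qc_flag.loc[clean].mean() < 0.05  # small-noise false positives

    def test_exclusion_is_idempotent(self, study_cohort):
        report = run_qc(study_cohort)
        once = make_analytic_sample(study_cohort, report)
        twice = make_analytic_sample(once, report)
        pd.testing.assert_frame_equal(once, twice)

    def test_all_flagged_gives_empty_sample(self):
        frame = _resp([("11121", -0.6), ("11122", 0.4), ("55555", -1.0)])
        report = run_qc(frame)
        assert report.n_flagged == 1
        assert len(make_analytic_sample(frame, report)) == 0
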