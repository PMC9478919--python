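"""Predictive-vs-prognostic assessment, AUC comparison, report assembly."""

import numpy as np
import pytest

from bctscore import evaluate as ev
from bctscore.pipeline import dump_json
from bctscore.score import ScoreCandidate
from bctscore.screen import derive_ratios, landmark_subset
from bctscore.survstats import td_roc_auc
from bctscore.trialsim import BiomarkerEffect, SimConfig, simulate_cohort

CAND = ScoreCandidate(rules=(("plr_T3", 140.0),), candidate_id="M1")


def low_confined_cohort(seed, log_hr=0.8):
    # treatment harms only marker-low patients: a predictive pattern
    cfg = SimConfig(
        n_treated=750, n_control=350, seed=seed, treatment_log_hr=0.0,
        predictive_effects=[
            BiomarkerEffect("plr", "T3", log_hr, threshold=140.0, side="low")
        ],
    )
    return simulate_cohort(cfg)


class TestPredictiveAssessment:
    def test_single_arm_cohort_rejected(self):
        df = simulate_cohort(SimConfig(n_treated=100, n_control=0, seed=1))
        with pytest.raises(ValueError, match="both arms"):
            ev.predictive_assessment(df, CAND)

    def test_low_confined_benefit_gives_discordant_strata(self):
        pa = ev.predictive_assessment(
            low_confined_cohort(81), CAND, endpoints=("OS",)
        )["OS"]
        assert not (pa.low.ci_low <= 1.0 <= pa.low.ci_high)
        assert pa.high.ci_low <= 1.0 <= pa.high.ci_high
        assert pa.interaction_p <= 0.05
        assert pa.predictive_discordant and pa.predictive_interaction

    def test_identical_arms_show_no_interaction(self):
        cfg = SimConfig(n_treated=500, n_control=500, seed=82, treatment_log_hr=0.0)
        pa = ev.predictive_assessment(simulate_cohort(cfg), CAND, endpoints=("OS",))["OS"]
        assert pa.high.ci_low <= 1.0 <= pa.high.ci_high
        assert pa.low.ci_low <= 1.0 <= pa.low.ci_high
        assert not pa.predictive_interaction

    def test_interaction_sign_tracks_stratum_hr_difference(self):
        for seed in (83, 84, 85):
            pa = ev.predictive_assessment(
                low_confined_cohort(seed), CAND, endpoints=("OS",)
            )["OS"]
            observed = np.sign(np.log(pa.high.hr) - np.log(pa.low.hr))
            assert np.sign(pa.interaction_coef) == observed

    def test_strata_partition_the_evaluable_cohort(self):
        df = low_confined_cohort(86)
        pa = ev.predictive_assessment(df, CAND, endpoints=("OS",))["OS"]
        panel = derive_ratios(df)
        from bctscore.score import classify

        risk = classify(panel, CAND)
        sub, _, _ = landmark_subset(df, "OS", CAND.landmark_timepoint)
        n_eval = int(risk.loc[sub.index].notna().sum())
        assert pa.high.n + pa.low.n == n_eval

    def test_sparse_stratum_flagged(self):
        import pandas as pd

        full = low_confined_cohort(87)
        df = pd.concat(
            [full[full["arm"] == "treated"].head(40),
             full[full["arm"] == "control"].head(20)]
        ).reset_index(drop=True)
        pa = ev.predictive_assessment(
            df, CAND, endpoints=("OS",), min_events=30
        )["OS"]
        assert not (pa.high.estimable and pa.low.estimable)


class TestAucComparison:
    def test_single_rule_score_equals_dichotomized_marker_auc(self):
        df = low_confined_cohort(88)
        table = ev.auc_comparison(df, CAND, endpoints=("OS",))
        treated = df[df["arm"] == "treated"]
        panel = derive_ratios(treated)
        sub, times, events = landmark_subset(treated, "OS", "T3")
        v = panel.loc[sub.index, "plr_T3"]
        ok = v.notna().to_numpy()
        ref = td_roc_auc(
            (v[ok] >= 140.0).to_numpy(float), times[ok], events[ok], 12.0
        ).auc
        score_auc = table.loc[table["marker"] == "score", "auc"].iloc[0]
        assert score_auc == pytest.approx(ref, abs=1e-12)

    def test_three_independent_signals_combine(self):
        # disjoint-cell effects: the 3-rule ordinal score should usually beat
        # each single marker for OS discrimination
        wins = 0
        for seed in range(3):
            cfg = SimConfig(
                n_treated=700, n_control=0, seed=90 + seed, treatment_log_hr=0.0,
                prognostic_effects=[
                    BiomarkerEffect("nlr", "T3", 0.4),
                    BiomarkerEffect("plr", "T3", 0.4, threshold=140.0),
                    BiomarkerEffect("nmr", "T2", 0.4, threshold=6.0),
                ],
            )
            df = simulate_cohort(cfg)
            cand = ScoreCandidate(
                rules=(("nlr_T3", 3.0), ("plr_T3", 140.0), ("nmr_T2", 6.0)),
                candidate_id="S3",
            )
            t = ev.auc_comparison(df, cand, endpoints=("OS",))
            score = t.loc[t["marker"] == "score", "auc"].iloc[0]
            singles = t.loc[t["marker"] != "score", "auc"]
            wins += score >= singles.max() - 0.02
        assert wins >= 2

    def test_null_marker_does_not_help(self):
        df = low_confined_cohort(94)
        with_null = ScoreCandidate(
            rules=(("plr_T3", 140.0), ("lmr_T1", 3.0)), candidate_id="N"
        )
        base = ev.auc_comparison(df, CAND, endpoints=("OS",))
        ext = ev.auc_comparison(df, with_null, endpoints=("OS",))
        a0 = base.loc[base["marker"] == "score", "auc"].iloc[0]
        a1 = ext.loc[ext["marker"] == "score", "auc"].iloc[0]
        assert a1 <= a0 + 0.05


class TestReport:
    def test_single_arm_cohorts_reported_with_gaps(self):
        two_arm = low_confined_cohort(95)
        single = simulate_cohort(
            SimConfig(n_treated=300, n_control=0, seed=96, cohort_label="VAL")
        )
        rep = ev.assemble_report(CAND, {"training": two_arm, "validation1": single})
        assert rep["cohorts"]["training"]["predictive"] is not None
        assert rep["cohorts"]["validation1"]["predictive"] is None
        assert "gaps" in rep["cohorts"]["validation1"]

    def test_byte_identical_for_identical_inputs(self):
        df = low_confined_cohort(97)
        a = ev.assemble_report(CAND, {"training": df})
        b = ev.assemble_report(CAND, {"training": df.copy()})
        assert dump_json(a) == dump_json(b)

    def test_km_cells_cross_sum_to_evaluable(self):
        df = low_confined_cohort(98)
        rep = ev.assemble_report(CAND, {"training": df})
        km = rep["cohorts"]["training"]["km"]
        total = sum(cell["n"] for cell in km.values())
        sub, _, _ = landmark_subset(df, "OS", "T3")
        from bctscore.score import classify

        risk = classify(derive_ratios(df), CAND)
        assert total == int(risk.loc[sub.index].notna().sum())

    def test_empty_cohort_set_rejected(self):
        with pytest.raises(ValueError, match="cohorts"):
            ev.assemble_report(CAND, {})
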