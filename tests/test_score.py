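"""Score candidates: enumeration, classification semantics, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bctscore.score import (
    ScoreCandidate,
    candidate_from_dict,
    classify,
    enumerate_candidates,
    rule_count,
    select_candidate,
)
from bctscore.trialsim import BiomarkerEffect, SimConfig, simulate_cohort

FINAL_RULES = (("nlr_T3", 5.0), ("plr_T3", 180.0), ("nmr_T2", 6.0))


def panel_of(nlr, plr, nmr) -> pd.DataFrame:
    return pd.DataFrame({"nlr_T3": [nlr], "plr_T3": [plr], "nmr_T2": [nmr]})


class TestEnumerate:
    def test_grid_sizes_multiply(self):
        cands = enumerate_candidates(
            {"nlr_T3": [4, 5], "plr_T3": [160, 170, 180, 190], "nmr_T2": [6, 7]}
        )
        assert len(cands) == 16
        assert len({c.candidate_id for c in cands}) == 16

    def test_single_option_each(self):
        assert len(enumerate_candidates({m: [c] for m, c in FINAL_RULES})) == 1

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty cutoff list"):
            enumerate_candidates({"nlr_T3": [5], "plr_T3": []})


class TestClassify:
    @pytest.mark.parametrize("rule", ["any_high", "majority", "all_high"])
    def test_boundary_values_are_high_under_every_rule(self, rule):
        cand = ScoreCandidate(rules=FINAL_RULES, combination_rule=rule)
        out = classify(panel_of(5.0, 180.0, 6.0), cand)
        assert out.iloc[0] == "high"

    @pytest.mark.parametrize("rule", ["any_high", "majority", "all_high"])
    def test_all_below_cutoffs_low_under_every_rule(self, rule):
        cand = ScoreCandidate(rules=FINAL_RULES, combination_rule=rule)
        assert classify(panel_of(4.9, 179.0, 5.9), cand).iloc[0] == "low"

    def test_single_positive_rule_depends_on_combination(self):
        p = panel_of(6.0, 100.0, 2.0)
        calls = {
            rule: classify(
                p, ScoreCandidate(rules=FINAL_RULES, combination_rule=rule)
            ).iloc[0]
            for rule in ("any_high", "majority", "all_high")
        }
        assert calls == {"any_high": "high", "majority": "low", "all_high": "low"}

    def test_missing_ratio_is_non_evaluable(self):
        cand = ScoreCandidate(rules=FINAL_RULES)
        out = classify(panel_of(6.0, np.nan, 9.0), cand)
        assert pd.isna(out.iloc[0])

    def test_unknown_biomarker_rejected(self):
        cand = ScoreCandidate(rules=(("cd8_T1", 1.0),))
        with pytest.raises(ValueError, match="unknown biomarker"):
            classify(panel_of(1, 1, 1), cand)

    @given(
        vals=st.tuples(
            st.floats(0.5, 20), st.floats(50, 400), st.floats(0.5, 30)
        ),
        bump=st.floats(0.0, 50.0),
        which=st.integers(0, 2),
        rule=st.sampled_from(["any_high", "majority", "all_high"]),
    )
    @settings(max_examples=80, deadline=None)
    def test_monotone_in_every_ratio(self, vals, bump, which, rule):
        # raising any ratio can never move a patient from high to low
        cand = ScoreCandidate(rules=FINAL_RULES, combination_rule=rule)
        before = classify(panel_of(*vals), cand).iloc[0]
        bumped = list(vals)
        bumped[which] += bump
        after = classify(panel_of(*bumped), cand).iloc[0]
        assert not (before == "high" and after == "low")

    def test_rule_validation(self):
        with pytest.raises(ValueError, match="at least one rule"):
            ScoreCandidate(rules=())
        with pytest.raises(ValueError, match="positive"):
            ScoreCandidate(rules=(("nlr_T3", -1.0),))
        with pytest.raises(ValueError, match="count_threshold"):
            ScoreCandidate(
                rules=FINAL_RULES, combination_rule="count_threshold",
                count_threshold=7,
            )

    def test_serialization_round_trip(self):
        cand = ScoreCandidate(rules=FINAL_RULES, candidate_id="C02")
        assert candidate_from_dict(cand.to_dict()) == cand


def _effect_cohort(seed, n=400):
    cfg = SimConfig(
        n_treated=n, n_control=0, seed=seed, treatment_log_hr=0.0,
        response_slope=2.0,
        prognostic_effects=[BiomarkerEffect("plr", "T3", 0.9, threshold=140.0)],
    )
    return simulate_cohort(cfg)


class TestSelect:
    def test_single_significant_candidate_selected(self):
        cand = ScoreCandidate(rules=(("plr_T3", 140.0),), candidate_id="C1")
        sel = select_candidate([cand], {"training": _effect_cohort(71, n=600)})
        assert sel.selected == cand
        assert sel.warning is None

    def test_identical_candidates_tie_breaks_lexicographically(self):
        a = ScoreCandidate(rules=(("plr_T3", 140.0),), candidate_id="CB")
        b = ScoreCandidate(rules=(("plr_T3", 140.0),), candidate_id="CA")
        sel = select_candidate([a, b], {"training": _effect_cohort(72, n=600)})
        assert sel.selected.candidate_id == "CA"
        scores = sel.table.groupby("candidate_id")["min_os_auc"].first()
        assert scores["CA"] == scores["CB"]

    def test_no_eligible_candidate_returns_warning(self):
        # a null cohort cannot make any candidate significant everywhere
        cfg = SimConfig(n_treated=300, n_control=0, seed=73, treatment_log_hr=0.0)
        cohort = simulate_cohort(cfg)
        cand = ScoreCandidate(rules=(("plr_T3", 160.0),), candidate_id="C1")
        sel = select_candidate([cand], {"training": cohort})
        assert sel.selected is None
        assert "no candidate" in sel.warning

    def test_selection_is_deterministic(self):
        cands = enumerate_candidates({"plr_T3": [130.0, 140.0, 150.0]})
        cohorts = {"training": _effect_cohort(74, n=600)}
        s1 = select_candidate(cands, cohorts)
        s2 = select_candidate(cands, cohorts)
        assert s1.selected == s2.selected
        pd.testing.assert_frame_equal(s1.table, s2.table)

    def test_rule_count_nan_only_when_component_missing(self):
        df = _effect_cohort(75, n=100)
        from bctscore.screen import derive_ratios

        panel = derive_ratios(df)
        cand = ScoreCandidate(rules=(("plr_T3", 140.0), ("nmr_T2", 6.0)))
        counts = rule_count(panel, cand)
        missing = panel["plr_T3"].isna() | panel["nmr_T2"].isna()
        assert counts[missing].isna().all()
        assert counts[~missing].between(0, 2).all()
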