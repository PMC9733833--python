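"""Stepwise covariate search: screening, thresholds, trace consistency."""

import numpy as np
import pytest

from valpop import (
    backward_step,
    fit,
    forward_step,
    generate_cohort,
    run_stepwise,
    screen_candidates,
)
from valpop.cohort import CohortConfig
from valpop.stepwise import CandidateCovariate, candidate_term, trace_frame


@pytest.fixture(scope="module")
def base_fit_small(small_cohort, base_model_spec):
    return fit(base_model_spec, small_cohort, compute_rse=False, compute_ebes=False)


class TestScreenCandidates:
    def test_rare_comedication_excluded(self, study_cohort):
        ds = study_cohort
        sub = ds.subjects.copy()
        sub["IBU"] = 0
        sub.loc[sub.index[:2], "IBU"] = 1  # 2/103 = 1.9% < 2.5%
        ds2 = type(ds)(subjects=sub, observations=ds.observations)
        names = {c.name for c in screen_candidates(ds2, comed_threshold_pct=2.5)}
        assert "IBU" not in names

    def test_zero_threshold_retains_all_present_comeds(self, study_cohort):
        sub = study_cohort.subjects.copy()
        sub["IBU"] = 0
        sub.loc[sub.index[0], "IBU"] = 1
        ds2 = type(study_cohort)(subjects=sub, observations=study_cohort.observations)
        names = {c.name for c in screen_candidates(ds2, comed_threshold_pct=0.0)}
        assert "IBU" in names

    def test_hwe_violating_snp_excluded(self, study_cohort):
        sub = study_cohort.subjects.copy()
        sub["rs1128503"] = "AG"  # universal heterozygosity: extreme HWE violation
        ds2 = type(study_cohort)(subjects=sub, observations=study_cohort.observations)
        names = {c.name for c in screen_candidates(ds2)}
        assert "rs1128503" not in names
        assert "rs3789243" in names

    def test_continuous_candidates_present(self, study_cohort):
        cands = {c.name: c for c in screen_candidates(study_cohort)}
        for name in ("AGE", "WT", "TDD"):
            assert cands[name].kind == "continuous"
            assert set(cands[name].forms_to_try) == {
                "linear", "power", "exponential", "piecewise"
            }


class TestCandidateTerm:
    def test_categorical_df_counts_non_reference_levels(self, study_cohort):
        cand = CandidateCovariate(
            "rs3789243", "categorical", ("multiplier",), ("AA", "AG", "GG")
        )
        term, inits, df = candidate_term(cand, "multiplier", study_cohort)
        assert df == 2 and set(inits) == set(term.coefficients)

    def test_piecewise_df_two(self, study_cohort):
        cand = CandidateCovariate("AGE", "continuous")
        _, inits, df = candidate_term(cand, "piecewise", study_cohort)
        assert df == 2 and len(inits) == 2


class TestForwardStep:
    def test_infinite_threshold_stops(self, base_fit_small, small_cohort):
        cands = [CandidateCovariate("AGE", "continuous", ("power",))]
        rec, new_fit = forward_step(
            base_fit_small, cands, small_cohort, delta_threshold=1e9
        )
        assert rec.action == "stop" and not rec.accepted
        assert new_fit is base_fit_small

    def test_zero_threshold_accepts_best(self, base_fit_small, small_cohort):
        cands = [CandidateCovariate("AGE", "continuous", ("power",))]
        rec, new_fit = forward_step(
            base_fit_small, cands, small_cohort, delta_threshold=0.0
        )
        assert rec.action == "add" and rec.covariate == "AGE"
        assert new_fit.ofv < base_fit_small.ofv

    def test_age_effect_detected(self, base_fit_small, small_cohort):
        """The generating age-power effect on CL is strong enough to be
        picked up even at n=40."""
        cands = [
            CandidateCovariate("AGE", "continuous", ("power",)),
            CandidateCovariate("SEX", "categorical", ("multiplier",), ("0", "1")),
        ]
        rec, _ = forward_step(base_fit_small, cands, small_cohort)
        assert rec.accepted and rec.covariate == "AGE"
        assert rec.delta_ofv < -3.84

    def test_candidate_order_invariance(self, base_fit_small, small_cohort):
        cands = [
            CandidateCovariate("AGE", "continuous", ("power",)),
            CandidateCovariate("WT", "continuous", ("power",)),
        ]
        rec_a, _ = forward_step(base_fit_small, cands, small_cohort)
        rec_b, _ = forward_step(base_fit_small, cands[::-1], small_cohort)
        assert rec_a.covariate == rec_b.covariate


class TestBackwardStep:
    def test_strong_term_not_removed(self, base_fit_small, small_cohort):
        cands = [CandidateCovariate("AGE", "continuous", ("power",))]
        _, with_age = forward_step(base_fit_small, cands, small_cohort)
        rec, kept = backward_step(with_age, small_cohort)
        assert rec.action == "stop"
        assert [t.covariate for t in kept.model.covariate_terms] == ["AGE"]

    def test_weak_term_removed_under_huge_threshold(self, base_fit_small, small_cohort):
        cands = [CandidateCovariate("AGE", "continuous", ("power",))]
        _, with_age = forward_step(base_fit_small, cands, small_cohort)
        rec, reduced = backward_step(with_age, small_cohort, removal_threshold=1e9)
        assert rec.action == "remove" and rec.covariate == "AGE"
        assert not reduced.model.covariate_terms

    def test_requires_a_covariate(self, base_fit_small, small_cohort):
        with pytest.raises(ValueError):
            backward_step(base_fit_small, small_cohort)


class TestRunStepwise:
    def test_empty_candidates_single_stop(self, base_fit_small, small_cohort):
        final, recs = run_stepwise(base_fit_small, [], small_cohort)
        assert len(recs) == 1 and recs[0].action == "stop"
        assert final.model.covariate_terms == []

    def test_trace_ofv_chain_is_consistent(self, base_fit_small, small_cohort):
        cands = [
            CandidateCovariate("AGE", "continuous", ("power", "exponential")),
            CandidateCovariate("SEX", "categorical", ("multiplier",), ("0", "1")),
        ]
        final, recs = run_stepwise(base_fit_small, cands, small_cohort)
        accepted = [r for r in recs if r.accepted]
        for prev, nxt in zip(recs, recs[1:]):
            if prev.accepted:
                assert nxt.ofv_before == pytest.approx(prev.ofv_after, abs=1e-6)
        for r in recs:
            assert r.delta_ofv == pytest.approx(r.ofv_after - r.ofv_before, abs=1e-9)
        frame = trace_frame(recs)
        assert list(frame.columns[:4]) == ["step", "action", "covariate", "form"]

    def test_age_retained_from_generating_model(self, base_fit_small, small_cohort):
        cands = [CandidateCovariate("AGE", "continuous", ("power",))]
        final, _ = run_stepwise(base_fit_small, cands, small_cohort)
        assert [t.covariate for t in final.model.covariate_terms] == ["AGE"]
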