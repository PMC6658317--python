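"""Crowd- and member-level accuracy metrics and the threshold sweep."""

from __future__ import annotations

import pytest

from crowdscreen.aggregation import Decision, Scope, decide_all, tallies_by_citation
from crowdscreen.formatting import percent
from crowdscreen.metrics import (
    MemberFilter,
    crowd_performance,
    member_performance,
    prevalence,
    threshold_sweep,
)
from crowdscreen.model import (
    Assessment,
    CitationRecord,
    ContractError,
    Level,
    ThresholdPolicy,
    Verdict,
)
from crowdscreen.simulate import SimulationConfig, perfect_config, simulate_dataset

from conftest import make_decision, make_labels


def test_sensitivity_when_two_eligible_citations_are_lost():
    """176 of 178 eligible retained -> sensitivity 98.9%."""
    labels = make_labels(178, 0)
    decisions = [make_decision(f"e{i}", excluded=(i < 2)) for i in range(178)]
    summary = crowd_performance(decisions, labels, ThresholdPolicy(0.5))
    assert summary.sensitivity is not None
    assert (summary.sensitivity.x, summary.sensitivity.n) == (176, 178)
    assert percent(summary.sensitivity.value) == 98.9


def test_degenerate_all_ineligible_all_excluded():
    labels = make_labels(0, 50)
    decisions = [make_decision(f"i{i}", excluded=True) for i in range(50)]
    summary = crowd_performance(decisions, labels, ThresholdPolicy(0.5))
    assert summary.sensitivity is None  # undefined, not zero
    assert summary.specificity.value == 1.0
    assert summary.work_performed.value == 1.0


def test_work_performed_and_implied_specificity_are_consistent():
    """1042 exclusions among 2323 citations with no eligible citation lost:
    work performed 44.9% and specificity 1042/2145 = 48.6%, with the printed
    Wilson interval 42.8-46.9 for work performed (the unique count that
    reproduces all four printed values)."""
    labels = make_labels(178, 2145)
    decisions = [make_decision(f"e{i}", excluded=False) for i in range(178)]
    decisions += [make_decision(f"i{i}", excluded=(i < 1042)) for i in range(2145)]
    summary = crowd_performance(decisions, labels, ThresholdPolicy(1.0))
    assert summary.total_excluded == 1042
    assert percent(summary.work_performed.value) == 44.9
    assert percent(summary.specificity.value) == 48.6
    assert percent(summary.sensitivity.value) == 100.0
    assert percent(summary.work_performed.lower) == 42.8
    assert percent(summary.work_performed.upper) == 46.9


def test_count_identity_holds_for_every_summary(small_fixture):
    records, votes = small_fixture
    for scope in Scope:
        curve = threshold_sweep(
            votes, records, [0.0, 0.25, 0.5, 0.75, 1.0], scope
        )
        for s in curve.summaries:
            assert s.total_excluded == (
                (s.n_eligible - s.eligible_retained) + s.ineligible_excluded
            )
            assert s.work_performed.n == s.n_eligible + s.n_ineligible


def test_missing_decision_label_is_a_contract_violation():
    with pytest.raises(ContractError):
        crowd_performance(
            [make_decision("ghost", excluded=False)],
            make_labels(1, 1),
            ThresholdPolicy(0.5),
        )


# --------------------------------------------------------------------------
# sweep
# --------------------------------------------------------------------------


def test_sweep_on_fixture_matches_hand_enumerated_sets(small_fixture):
    records, votes = small_fixture
    expected_excluded = {  # from the fixture's docstring (hand enumeration)
        0.0: {"c02", "c03", "c04", "c05", "c06", "c07", "c08", "c11", "c12"},
        0.5: {"c03", "c04", "c05", "c06", "c11", "c12"},
        0.75: {"c03", "c04", "c12"},
        1.0: {"c03", "c04"},
    }
    cutoffs = sorted(expected_excluded)
    curve = threshold_sweep(votes, records, cutoffs, Scope.CASCADE)
    eligible = {r.citation_id for r in records if r.expert_eligible}
    for cutoff, sens, work in zip(
        curve.cutoffs, curve.sensitivity, curve.work_performed
    ):
        excluded = expected_excluded[cutoff]
        assert work == len(excluded) / len(records)
        assert sens == 1 - len(excluded & eligible) / len(eligible)


def test_sweep_equals_per_cutoff_brute_force_recount(small_fixture):
    """The sweep must equal an independent per-cutoff recomputation that
    re-applies the either-level rule directly to the tallies."""
    records, votes = small_fixture
    abstract = tallies_by_citation(votes, Level.ABSTRACT)
    fulltext = tallies_by_citation(votes, Level.FULLTEXT)
    eligible = {r.citation_id for r in records if r.expert_eligible}
    cutoffs = [i / 10 for i in range(11)]
    curve = threshold_sweep(votes, records, cutoffs, Scope.CASCADE)
    for cutoff, sens, work in zip(
        curve.cutoffs, curve.sensitivity, curve.work_performed
    ):
        excluded = set()
        for r in records:
            for t in (abstract.get(r.citation_id), fulltext.get(r.citation_id)):
                if t is None or t.n_informative == 0:
                    continue
                frac = t.n_exclude / t.n_informative
                if (cutoff == 1.0 and frac == 1.0) or (
                    cutoff < 1.0 and frac > cutoff
                ):
                    excluded.add(r.citation_id)
        assert work == len(excluded) / len(records)
        assert sens == 1 - len(excluded & eligible) / len(eligible)


def test_sweep_rejects_unsorted_cutoffs(small_fixture):
    records, votes = small_fixture
    with pytest.raises(ContractError):
        threshold_sweep(votes, records, [0.75, 0.5])


def test_zero_cutoff_excludes_everything_with_an_exclude_vote():
    labels = make_labels(0, 5)
    votes = [
        Assessment(f"i{i}", "m1", Level.ABSTRACT, Verdict.EXCLUDE)
        for i in range(5)
    ] + [
        Assessment(f"i{i}", "m2", Level.ABSTRACT, Verdict.RETAIN)
        for i in range(5)
    ]
    curve = threshold_sweep(votes, labels, [0.0], Scope.ABSTRACT_ONLY)
    assert curve.work_performed == (1.0,)


def test_perfect_members_yield_ceiling_performance_at_every_cutoff():
    """All-accurate, never-abstaining members: sensitivity 100% and work
    performed exactly 1 - prevalence at every cutoff."""
    config = perfect_config(n_citations=200, n_members=12, seed=5,
                            prevalence=0.2)
    records, votes = simulate_dataset(config)
    prev = prevalence(records)
    curve = threshold_sweep(votes, records, [0.0, 0.3, 0.75, 1.0], Scope.CASCADE)
    for sens, work in zip(curve.sensitivity, curve.work_performed):
        assert sens == 1.0
        assert work == pytest.approx(1.0 - prev, abs=1e-12)


# --------------------------------------------------------------------------
# member-level metrics
# --------------------------------------------------------------------------


def _member_votes(member: str, labels, verdicts):
    return [
        Assessment(r.citation_id, member, Level.ABSTRACT, v)
        for r, v in zip(labels, verdicts)
    ]


def test_member_below_the_assessment_minimum_is_filtered_out():
    labels = make_labels(5, 60)
    votes = _member_votes("m49", labels[:49], [Verdict.RETAIN] * 49)
    votes += _member_votes("m50", labels[:50], [Verdict.RETAIN] * 50)
    out = member_performance(votes, labels, MemberFilter(50), Level.ABSTRACT)
    assert [m.member_id for m in out] == ["m50"]


def test_perfect_member_scores_100_on_both_axes():
    labels = make_labels(10, 50)
    verdicts = [
        Verdict.RETAIN if r.expert_eligible else Verdict.EXCLUDE for r in labels
    ]
    votes = _member_votes("m1", labels, verdicts)
    (m,) = member_performance(votes, labels, MemberFilter(50), Level.ABSTRACT)
    assert m.sensitivity == 1.0 and m.specificity == 1.0


def test_member_with_no_eligible_citations_has_absent_sensitivity():
    labels = make_labels(2, 60)
    ineligible = [r for r in labels if not r.expert_eligible]
    votes = _member_votes("m1", ineligible, [Verdict.EXCLUDE] * 60)
    (m,) = member_performance(votes, labels, MemberFilter(50), Level.ABSTRACT)
    assert m.sensitivity is None
    assert m.specificity == 1.0


def test_abstentions_do_not_enter_member_accuracy():
    labels = make_labels(25, 30)
    verdicts = []
    for r in labels:
        verdicts.append(
            Verdict.NO_ASSESSMENT
            if r.citation_id.endswith(("0", "5"))
            else (Verdict.RETAIN if r.expert_eligible else Verdict.EXCLUDE)
        )
    votes = _member_votes("m1", labels, verdicts)
    (m,) = member_performance(votes, labels, MemberFilter(50), Level.ABSTRACT)
    assert m.sensitivity == 1.0 and m.specificity == 1.0
    assert m.n_eligible_voted < 25 and m.n_ineligible_voted < 30
    assert m.n_assessments == 55  # abstentions still count as assessments


def test_raising_the_filter_never_adds_members():
    config = SimulationConfig(
        n_citations=120, n_members=10, seed=3,
        votes_per_citation_abstract=5, votes_per_citation_fulltext=4,
    )
    records, votes = simulate_dataset(config)
    previous = None
    for minimum in (1, 20, 50, 80):
        members = {
            m.member_id
            for m in member_performance(
                votes, records, MemberFilter(minimum), Level.ABSTRACT
            )
        }
        if previous is not None:
            assert members <= previous
        previous = members


def test_member_filter_counts_both_levels_within_a_review():
    # 30 abstract + 25 full-text assessments in one review passes a 50 filter
    labels = make_labels(0, 30)
    votes = _member_votes("m1", labels, [Verdict.EXCLUDE] * 30)
    votes += [
        Assessment(r.citation_id, "m1", Level.FULLTEXT, Verdict.EXCLUDE)
        for r in labels[:25]
    ]
    out = member_performance(votes, labels, MemberFilter(50), Level.FULLTEXT)
    assert [m.member_id for m in out] == ["m1"]


# --------------------------------------------------------------------------
# prevalence
# --------------------------------------------------------------------------


def test_prevalence_matches_the_study_population():
    assert percent(prevalence(make_labels(178, 2145))) == 7.7


def test_prevalence_zero_and_empty():
    assert prevalence(make_labels(0, 100)) == 0.0
    with pytest.raises(ContractError):
        prevalence([])


def test_prevalence_equals_direct_recount_on_simulated_labels():
    config = SimulationConfig(n_citations=500, n_members=10, seed=21,
                              votes_per_citation_abstract=4,
                              votes_per_citation_fulltext=4)
    records, _ = simulate_dataset(config)
    direct = sum(r.expert_eligible for r in records) / len(records)
    assert prevalence(records) == direct
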