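"""Crowd- and member-level screening accuracy.

Crowd metrics compare aggregated decisions with the expert gold standard:

* sensitivity — eligible citations retained / eligible citations,
* specificity — ineligible citations excluded / ineligible citations,
* work performed — citations excluded / all citations.

Undecided citations count as retained throughout: they still need the
investigative team, so they are work *not* performed.  The count identity
total_excluded = (n_eligible - eligible_retained) + ineligible_excluded holds
exactly for every summary.

Member metrics mirror the crowd ones per individual, on informative votes
only, restricted to members who completed the study's minimum number of
assessments in at least one review.
"""

from __future__ import annotations

from collections import defaultdict
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from typing import Optional

from crowdscreen.aggregation import (
    ADVANCEMENT_CUTOFF,
    CitationDecision,
    Decision,
    Scope,
    decide_all,
)
from crowdscreen.inference import wilson_ci
from crowdscreen.model import (
    Assessment,
    CitationRecord,
    ContractError,
    Level,
    MemberPerformance,
    PerformanceSummary,
    Proportion,
    ThresholdPolicy,
    Verdict,
)


@dataclass(frozen=True)
class SweepCurve:
    """Sensitivity and work performed across a grid of exclusion cutoffs.

    By construction sensitivity is non-decreasing and work performed
    non-increasing as the cutoff rises (stricter thresholds exclude less).
    """

    cutoffs: tuple[float, ...]
    sensitivity: tuple[Optional[float], ...]
    work_performed: tuple[float, ...]
    scope: Scope
    summaries: tuple[PerformanceSummary, ...] = ()


@dataclass(frozen=True)
class MemberFilter:
    """Minimum assessments (within a single review) for member-level metrics."""

    min_assessments: int = 50

    def __post_init__(self) -> None:
        if self.min_assessments < 1:
            raise ContractError("min_assessments must be at least 1")


def _proportion(x: int, n: int, confidence: float) -> Optional[Proportion]:
    if n == 0:
        return None
    return wilson_ci(x, n, confidence).as_proportion()


def crowd_performance(
    decisions: Iterable[CitationDecision],
    labels: Iterable[CitationRecord],
    policy: ThresholdPolicy,
    scope: Scope = Scope.CASCADE,
    confidence: float = 0.95,
) -> PerformanceSummary:
    """Summarise aggregated decisions against the expert labels.

    Sensitivity is None (undefined, not zero) when the label set contains no
    eligible citations; specificity likewise with no ineligible citations.
    """
    by_id = {r.citation_id: r for r in labels}
    n_eligible = n_ineligible = 0
    eligible_retained = ineligible_excluded = 0
    n_undecided = 0
    n_total = 0
    for d in decisions:
        record = by_id.get(d.citation_id)
        if record is None:
            raise ContractError(
                f"decision for unlabeled citation {d.citation_id!r}"
            )
        n_total += 1
        if d.undecided:
            n_undecided += 1
        excluded = d.final_decision is Decision.EXCLUDED
        if record.expert_eligible:
            n_eligible += 1
            if not excluded:
                eligible_retained += 1
        else:
            n_ineligible += 1
            if excluded:
                ineligible_excluded += 1
    if n_total == 0:
        raise ContractError("crowd_performance needs at least one decision")
    total_excluded = (n_eligible - eligible_retained) + ineligible_excluded
    return PerformanceSummary(
        threshold=policy,
        level_scope=scope.value,
        n_eligible=n_eligible,
        n_ineligible=n_ineligible,
        eligible_retained=eligible_retained,
        ineligible_excluded=ineligible_excluded,
        total_excluded=total_excluded,
        sensitivity=_proportion(eligible_retained, n_eligible, confidence),
        specificity=_proportion(ineligible_excluded, n_ineligible, confidence),
        work_performed=_proportion(total_excluded, n_total, confidence),
        n_undecided=n_undecided,
    )


def threshold_sweep(
    assessments: Iterable[Assessment],
    labels: Iterable[CitationRecord],
    cutoffs: Sequence[float],
    scope: Scope = Scope.CASCADE,
    advancement_cutoff: float = ADVANCEMENT_CUTOFF,
    confidence: float = 0.95,
) -> SweepCurve:
    """Evaluate the crowd at every cutoff of a sorted grid."""
    cutoffs = tuple(float(c) for c in cutoffs)
    if any(b < a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ContractError("cutoffs must be sorted ascending")
    votes = list(assessments)
    records = list(labels)
    summaries = []
    for cutoff in cutoffs:
        policy = ThresholdPolicy(cutoff)
        decisions = decide_all(votes, records, policy, scope, advancement_cutoff)
        summaries.append(
            crowd_performance(decisions, records, policy, scope, confidence)
        )
    return SweepCurve(
        cutoffs=cutoffs,
        sensitivity=tuple(
            s.sensitivity.value if s.sensitivity is not None else None
            for s in summaries
        ),
        work_performed=tuple(s.work_performed.value for s in summaries),
        scope=scope,
        summaries=tuple(summaries),
    )


def member_performance(
    assessments: Iterable[Assessment],
    labels: Iterable[CitationRecord],
    member_filter: MemberFilter = MemberFilter(),
    level: Level = Level.ABSTRACT,
) -> list[MemberPerformance]:
    """Per-member sensitivity/specificity at one level.

    A member is included when their total assessment count (both levels)
    within at least one review reaches the filter minimum.  Metrics use
    informative votes only; a member with no informative vote on any
    eligible citation gets sensitivity None (and symmetrically for
    specificity).  Output is sorted by member id.
    """
    votes = list(assessments)
    by_id = {r.citation_id: r for r in labels}

    per_review: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for a in votes:
        record = by_id.get(a.citation_id)
        if record is None:
            raise ContractError(f"vote on unlabeled citation {a.citation_id!r}")
        per_review[a.member_id][record.review_id] += 1
    eligible_members = {
        m
        for m, reviews in per_review.items()
        if max(reviews.values()) >= member_filter.min_assessments
    }

    n_level: dict[str, int] = defaultdict(int)
    sens_x: dict[str, int] = defaultdict(int)
    sens_n: dict[str, int] = defaultdict(int)
    spec_x: dict[str, int] = defaultdict(int)
    spec_n: dict[str, int] = defaultdict(int)
    for a in votes:
        if a.level is not level or a.member_id not in eligible_members:
            continue
        n_level[a.member_id] += 1
        if a.verdict is Verdict.NO_ASSESSMENT:
            continue
        if by_id[a.citation_id].expert_eligible:
            sens_n[a.member_id] += 1
            if a.verdict is Verdict.RETAIN:
                sens_x[a.member_id] += 1
        else:
            spec_n[a.member_id] += 1
            if a.verdict is Verdict.EXCLUDE:
                spec_x[a.member_id] += 1

    out = []
    for m in sorted(n_level):
        out.append(
            MemberPerformance(
                member_id=m,
                level=level,
                n_assessments=n_level[m],
                sensitivity=(
                    sens_x[m] / sens_n[m] if sens_n[m] > 0 else None
                ),
                specificity=(
                    spec_x[m] / spec_n[m] if spec_n[m] > 0 else None
                ),
                n_eligible_voted=sens_n[m],
                n_ineligible_voted=spec_n[m],
            )
        )
    return out


def prevalence(labels: Iterable[CitationRecord]) -> float:
    """Fraction of citations the experts judged eligible."""
    records = list(labels)
    if not records:
        raise ContractError("prevalence needs at least one citation")
    return sum(r.expert_eligible for r in records) / len(records)
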