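"""Per-citation decisions from vote tallies.

A citation's exclusion fraction is the share of *informative* votes
(exclude + retain) that excluded it; abstentions never enter the
denominator.  A threshold policy turns the fraction into a decision, the
advancement rule moves citations from abstract to full-text screening, and
the cascade combines both levels: a citation is excluded when its exclusion
fraction triggers the policy at either level.  Citations that were advanced
but never voted on at full text (typically unretrieved articles) are
retained — they fall back to the investigative team, so counting them as
crowd exclusions would overstate work performed.
"""

from __future__ import annotations

from collections import defaultdict
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from crowdscreen.model import (
    Assessment,
    CitationRecord,
    ContractError,
    Level,
    ThresholdPolicy,
    UndefinedFractionError,
    Verdict,
    VoteTally,
)

#: Default advancement rule: a citation moves to full text when at least this
#: fraction of informative abstract votes judged it eligible (i.e. its
#: exclusion fraction is at most 1 - ADVANCEMENT_CUTOFF).
ADVANCEMENT_CUTOFF = 0.25

#: Feasibility floor used by the study: minimum independent assessments per
#: citation at each level.
MIN_ASSESSMENTS_TARGET = 4


class Decision(str, Enum):
    EXCLUDED = "excluded"
    RETAINED = "retained"


class DecidingLevel(str, Enum):
    ABSTRACT = "abstract"
    FULLTEXT = "fulltext"
    NONE = "none"


class Scope(str, Enum):
    """Which screening levels a summary covers.

    ABSTRACT_ONLY evaluates abstract votes alone; CASCADE applies the
    either-level exclusion rule across abstract and full-text screening.
    """

    ABSTRACT_ONLY = "abstract"
    CASCADE = "cascade"


@dataclass(frozen=True)
class CitationDecision:
    """The aggregated crowd decision for one citation.

    ``abstract_fraction`` / ``fulltext_fraction`` are None when the citation
    has no informative votes at that level (e.g. a missing abstract, or an
    article nobody assessed).  ``undecided`` marks citations with an abstract
    but no informative vote at any usable level; such citations are RETAINED
    downstream (they demonstrably need investigator assessment) but are
    surfaced rather than silently folded in.
    """

    citation_id: str
    abstract_fraction: Optional[float]
    fulltext_fraction: Optional[float]
    advanced: bool
    final_decision: Decision
    deciding_level: DecidingLevel
    undecided: bool = False

    def __post_init__(self) -> None:
        if self.final_decision is Decision.EXCLUDED and self.deciding_level is (
            DecidingLevel.NONE
        ):
            raise ContractError("an excluded citation must name a deciding level")


@dataclass(frozen=True)
class CompletionReport:
    """How many citations reached the per-citation assessment target."""

    min_target: int
    n_citations: int
    n_complete: int

    @property
    def fraction_complete(self) -> float:
        if self.n_citations == 0:
            return 0.0
        return self.n_complete / self.n_citations


def exclusion_fraction(t: VoteTally) -> float:
    """Fraction of informative votes that excluded the citation.

    Raises :class:`UndefinedFractionError` when there are no informative
    votes (all abstentions or no votes at all).
    """
    if t.n_informative == 0:
        raise UndefinedFractionError(
            "exclusion fraction undefined: no informative votes"
        )
    return t.n_exclude / t.n_informative


def decide(fraction: float, policy: ThresholdPolicy) -> Decision:
    """Apply a threshold policy to an exclusion fraction."""
    return Decision.EXCLUDED if policy.excludes(fraction) else Decision.RETAINED


def advance_to_fulltext(
    record: CitationRecord,
    abstract_tally: Optional[VoteTally],
    cutoff: float = ADVANCEMENT_CUTOFF,
) -> bool:
    """Does the citation move on to full-text screening?

    Citations without an abstract are pushed forward automatically.
    Otherwise the citation advances when the retain fraction (1 - exclusion
    fraction over informative votes) is at least ``cutoff``.
    """
    if not record.has_abstract:
        return True
    if abstract_tally is None or abstract_tally.n_informative == 0:
        raise UndefinedFractionError(
            f"citation {record.citation_id!r}: advancement undecidable "
            "(abstract present but no informative abstract votes)"
        )
    return 1.0 - exclusion_fraction(abstract_tally) >= cutoff


def _fraction_or_none(t: Optional[VoteTally]) -> Optional[float]:
    if t is None or t.n_informative == 0:
        return None
    return exclusion_fraction(t)


def cascade_decision(
    record: CitationRecord,
    abstract_tally: Optional[VoteTally],
    fulltext_tally: Optional[VoteTally],
    policy: ThresholdPolicy,
    advancement_cutoff: float = ADVANCEMENT_CUTOFF,
) -> CitationDecision:
    """Two-level decision: excluded if either level triggers the policy.

    The abstract level takes precedence as deciding level.  A citation that
    advanced but has no informative full-text votes is RETAINED.  When the
    citation has an abstract but no informative votes at either level the
    decision is undecidable and :class:`UndefinedFractionError` is raised
    (batch callers map this to an undecided-but-retained record).
    """
    a_frac = _fraction_or_none(abstract_tally)
    f_frac = _fraction_or_none(fulltext_tally)

    if a_frac is None and f_frac is None and record.has_abstract:
        raise UndefinedFractionError(
            f"citation {record.citation_id!r}: no informative votes at "
            "either level"
        )

    if not record.has_abstract:
        advanced = True
    elif a_frac is None:
        advanced = False  # cannot pass the advancement rule without votes
    else:
        advanced = 1.0 - a_frac >= advancement_cutoff

    if a_frac is not None and policy.excludes(a_frac):
        return CitationDecision(
            record.citation_id, a_frac, f_frac, advanced,
            Decision.EXCLUDED, DecidingLevel.ABSTRACT,
        )
    if f_frac is not None and policy.excludes(f_frac):
        return CitationDecision(
            record.citation_id, a_frac, f_frac, advanced,
            Decision.EXCLUDED, DecidingLevel.FULLTEXT,
        )
    return CitationDecision(
        record.citation_id, a_frac, f_frac, advanced,
        Decision.RETAINED, DecidingLevel.NONE,
    )


def tallies_by_citation(
    assessments: Iterable[Assessment], level: Level
) -> dict[str, VoteTally]:
    """Group votes at one level into per-citation tallies."""
    counts: dict[str, list[int]] = defaultdict(lambda: [0, 0, 0])
    for a in assessments:
        if a.level is not level:
            continue
        c = counts[a.citation_id]
        if a.verdict is Verdict.EXCLUDE:
            c[0] += 1
        elif a.verdict is Verdict.RETAIN:
            c[1] += 1
        else:
            c[2] += 1
    return {cid: VoteTally(*c) for cid, c in counts.items()}


def decide_all(
    assessments: Iterable[Assessment],
    records: Iterable[CitationRecord],
    policy: ThresholdPolicy,
    scope: Scope = Scope.CASCADE,
    advancement_cutoff: float = ADVANCEMENT_CUTOFF,
) -> list[CitationDecision]:
    """Decide every citation in the label table under one policy.

    Citations whose decision is undecidable (abstract present, no
    informative votes) are emitted as undecided and RETAINED.  Under
    ABSTRACT_ONLY scope, full-text votes are ignored entirely; citations
    without an abstract are then retained by construction (they were never
    screened at abstract level).
    """
    votes = list(assessments)
    abstract = tallies_by_citation(votes, Level.ABSTRACT)
    fulltext = (
        tallies_by_citation(votes, Level.FULLTEXT)
        if scope is Scope.CASCADE
        else {}
    )
    out: list[CitationDecision] = []
    for record in records:
        a_t = abstract.get(record.citation_id)
        f_t = fulltext.get(record.citation_id)
        try:
            out.append(
                cascade_decision(record, a_t, f_t, policy, advancement_cutoff)
            )
        except UndefinedFractionError:
            out.append(
                CitationDecision(
                    record.citation_id, None, _fraction_or_none(f_t),
                    advanced=False, final_decision=Decision.RETAINED,
                    deciding_level=DecidingLevel.NONE, undecided=True,
                )
            )
    return out


def completion_report(
    assessments: Iterable[Assessment],
    level: Level,
    min_target: int = MIN_ASSESSMENTS_TARGET,
    citation_ids: Optional[Sequence[str]] = None,
) -> CompletionReport:
    """Count citations reaching the per-citation assessment target at a level.

    All assessments count toward the target, including abstentions (the
    feasibility target counts assessments performed, not verdicts cast).
    ``citation_ids`` fixes the denominator universe; by default it is the set
    of citations with at least one assessment at the level.
    """
    if min_target < 1:
        raise ContractError("min_target must be at least 1")
    counts: dict[str, int] = defaultdict(int)
    for a in assessments:
        if a.level is level:
            counts[a.citation_id] += 1
    universe = list(citation_ids) if citation_ids is not None else list(counts)
    n_complete = sum(1 for cid in universe if counts.get(cid, 0) >= min_target)
    return CompletionReport(
        min_target=min_target, n_citations=len(universe), n_complete=n_complete
    )
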