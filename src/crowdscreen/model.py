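"""Domain types and file I/O for crowd screening vote tables.

The unit of data is an :class:`Assessment`: one crowd member's verdict on one
citation at one screening level.  Verdicts are three-valued — ``retain``,
``exclude`` or ``no_assessment`` (an abstention: the member was not
comfortable judging the citation).  Gold labels live in
:class:`CitationRecord`: the expert decision (``expert_eligible``), whether
the citation had an abstract at all, and whether its full text could be
retrieved.

Vote and label tables are plain CSV; readers validate headers, tokens and
uniqueness and report offending row numbers.  Tokens are case-insensitive on
read and written in canonical lower case.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional

import pandas as pd


# --------------------------------------------------------------------------
# errors
# --------------------------------------------------------------------------


class ScreeningError(ValueError):
    """Base class for all domain errors raised by this package."""


class FormatError(ScreeningError):
    """A table is malformed (missing column, unknown token, bad boolean)."""


class DuplicateVoteError(ScreeningError):
    """A (citation, member, level) triple appears more than once."""


class UndefinedFractionError(ScreeningError):
    """An exclusion fraction was requested for a tally with no informative votes."""


class ContractError(ScreeningError):
    """A caller violated an operation's precondition."""


# --------------------------------------------------------------------------
# enumerations
# --------------------------------------------------------------------------


class Verdict(str, Enum):
    """One crowd member's judgement of one citation."""

    RETAIN = "retain"
    EXCLUDE = "exclude"
    NO_ASSESSMENT = "no_assessment"

    @classmethod
    def parse(cls, token: str) -> "Verdict":
        normal = str(token).strip().lower().replace("-", "_").replace(" ", "_")
        for member in cls:
            if normal == member.value:
                return member
        raise FormatError(f"unknown verdict token: {token!r}")


class Level(str, Enum):
    """Screening level; the cascade runs ABSTRACT before FULLTEXT."""

    ABSTRACT = "abstract"
    FULLTEXT = "fulltext"

    @classmethod
    def parse(cls, token: str) -> "Level":
        normal = str(token).strip().lower().replace("-", "_").replace(" ", "_")
        aliases = {"full_text": "fulltext"}
        normal = aliases.get(normal, normal)
        for member in cls:
            if normal == member.value:
                return member
        raise FormatError(f"unknown level token: {token!r}")


# --------------------------------------------------------------------------
# records
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Assessment:
    """One vote: a member's verdict on a citation at a screening level.

    ``exclusion_reason`` is free text and may be non-empty only when the
    verdict is EXCLUDE (members are prompted for the unmet criterion only
    when excluding).
    """

    citation_id: str
    member_id: str
    level: Level
    verdict: Verdict
    exclusion_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if not isinstance(self.level, Level):
            object.__setattr__(self, "level", Level.parse(self.level))
        if not isinstance(self.verdict, Verdict):
            object.__setattr__(self, "verdict", Verdict.parse(self.verdict))
        if self.exclusion_reason == "":
            object.__setattr__(self, "exclusion_reason", None)
        if self.exclusion_reason is not None and self.verdict is not Verdict.EXCLUDE:
            raise ContractError(
                f"exclusion_reason given for a {self.verdict.value} verdict "
                f"on citation {self.citation_id}"
            )


@dataclass(frozen=True)
class CitationRecord:
    """A citation with its gold label and availability flags.

    ``expert_eligible`` is the expert (gold standard) decision: True marks a
    true positive.  ``has_abstract`` is False for citations with no abstract,
    which skip abstract screening and are pushed straight to full text.
    ``fulltext_retrievable`` is False when the article could not be obtained.
    """

    citation_id: str
    review_id: str
    expert_eligible: bool
    has_abstract: bool = True
    fulltext_retrievable: bool = True


@dataclass(frozen=True)
class VoteTally:
    """Vote counts for one citation at one level.

    Informative votes are exclude + retain; abstentions never enter an
    exclusion-fraction denominator.
    """

    n_exclude: int
    n_retain: int
    n_abstain: int = 0

    def __post_init__(self) -> None:
        for name in ("n_exclude", "n_retain", "n_abstain"):
            if getattr(self, name) < 0:
                raise ContractError(f"{name} must be non-negative")

    @property
    def n_informative(self) -> int:
        return self.n_exclude + self.n_retain

    @property
    def n_total(self) -> int:
        return self.n_exclude + self.n_retain + self.n_abstain

    def __add__(self, other: "VoteTally") -> "VoteTally":
        return VoteTally(
            self.n_exclude + other.n_exclude,
            self.n_retain + other.n_retain,
            self.n_abstain + other.n_abstain,
        )


def tally(assessments: Iterable[Assessment]) -> VoteTally:
    """Count a citation's votes at one level into a :class:`VoteTally`.

    All assessments must share one citation_id and one level; the result is
    order-independent and additive over disjoint subsets.  An empty input
    yields the zero tally.
    """
    n_exclude = n_retain = n_abstain = 0
    key: Optional[tuple[str, Level]] = None
    for a in assessments:
        if key is None:
            key = (a.citation_id, a.level)
        elif (a.citation_id, a.level) != key:
            raise ContractError(
                f"tally() got mixed citations/levels: {key} vs "
                f"{(a.citation_id, a.level)}"
            )
        if a.verdict is Verdict.EXCLUDE:
            n_exclude += 1
        elif a.verdict is Verdict.RETAIN:
            n_retain += 1
        else:
            n_abstain += 1
    return VoteTally(n_exclude, n_retain, n_abstain)


@dataclass(frozen=True)
class ThresholdPolicy:
    """An exclusion cut-off on the fraction of exclude votes.

    Decision semantics: a citation is excluded iff its exclusion fraction is
    strictly greater than the cutoff, except at cutoff 1.0 where unanimity
    (fraction == 1) excludes.  Hence the 0 cut-off excludes on any exclude
    vote, and the 1.0 cut-off needs complete agreement.
    """

    cutoff: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.cutoff <= 1.0:
            raise ContractError(f"cutoff must lie in [0, 1], got {self.cutoff}")

    def excludes(self, fraction: float) -> bool:
        if not 0.0 <= fraction <= 1.0:
            raise ContractError(f"fraction must lie in [0, 1], got {fraction}")
        if self.cutoff == 1.0:
            return fraction == 1.0
        return fraction > self.cutoff


@dataclass(frozen=True)
class Proportion:
    """A binomial point estimate x/n with a confidence interval."""

    x: int
    n: int
    value: float
    lower: float
    upper: float


@dataclass(frozen=True)
class PerformanceSummary:
    """Crowd-level accuracy at one threshold and scope.

    sensitivity  — eligible citations retained / eligible citations
    specificity  — ineligible citations excluded / ineligible citations
    work_performed — citations excluded / all citations (work the
    investigative team is spared)

    sensitivity is None when the label set has no eligible citations
    (undefined, not zero); analogously for specificity.
    """

    threshold: ThresholdPolicy
    level_scope: str
    n_eligible: int
    n_ineligible: int
    eligible_retained: int
    ineligible_excluded: int
    total_excluded: int
    sensitivity: Optional[Proportion]
    specificity: Optional[Proportion]
    work_performed: Proportion
    n_undecided: int = 0


@dataclass(frozen=True)
class MemberPerformance:
    """Per-member accuracy at one level, on informative votes only.

    sensitivity is None when the member cast no informative vote on any
    expert-eligible citation; analogously for specificity.
    """

    member_id: str
    level: Level
    n_assessments: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    n_eligible_voted: int = 0
    n_ineligible_voted: int = 0


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

VOTE_COLUMNS = ["citation_id", "member_id", "level", "verdict"]
LABEL_COLUMNS = [
    "citation_id",
    "review_id",
    "expert_eligible",
    "has_abstract",
    "fulltext_retrievable",
]


def _require_columns(frame: pd.DataFrame, required: Sequence[str], what: str) -> None:
    for column in required:
        if column not in frame.columns:
            raise FormatError(f"{what} is missing required column {column!r}")


def read_votes(path: str | Path) -> list[Assessment]:
    """Parse a vote-table CSV into validated assessments.

    Header: ``citation_id,member_id,level,verdict[,exclusion_reason]``.
    Raises :class:`FormatError` for missing columns or unknown tokens (with
    the offending row number, header = line 1) and
    :class:`DuplicateVoteError` when a member voted twice on the same
    citation and level.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(frame, VOTE_COLUMNS, f"vote table {path}")
    has_reason = "exclusion_reason" in frame.columns
    out: list[Assessment] = []
    seen: set[tuple[str, str, Level]] = set()
    for i, row in enumerate(frame.itertuples(index=False)):
        line = i + 2  # header occupies line 1
        try:
            level = Level.parse(getattr(row, "level"))
            verdict = Verdict.parse(getattr(row, "verdict"))
            reason = getattr(row, "exclusion_reason") if has_reason else None
            a = Assessment(
                citation_id=str(getattr(row, "citation_id")),
                member_id=str(getattr(row, "member_id")),
                level=level,
                verdict=verdict,
                exclusion_reason=reason or None,
            )
        except ScreeningError as exc:
            raise type(exc)(f"row {line}: {exc}") from None
        key = (a.citation_id, a.member_id, a.level)
        if key in seen:
            raise DuplicateVoteError(
                f"row {line}: duplicate vote by member {a.member_id!r} on "
                f"citation {a.citation_id!r} at {a.level.value} level"
            )
        seen.add(key)
        out.append(a)
    return out


# spec-facing alias
parse_vote_table = read_votes


def write_votes(assessments: Iterable[Assessment], path: str | Path) -> None:
    """Serialise assessments to CSV with canonical lower-case tokens."""
    rows = list(assessments)
    frame = pd.DataFrame(
        {
            "citation_id": [a.citation_id for a in rows],
            "member_id": [a.member_id for a in rows],
            "level": [a.level.value for a in rows],
            "verdict": [a.verdict.value for a in rows],
            "exclusion_reason": [a.exclusion_reason or "" for a in rows],
        }
    )
    frame.to_csv(path, index=False)


def _parse_bool(token: str, line: int, column: str) -> bool:
    normal = str(token).strip().lower()
    if normal in {"true", "1", "yes"}:
        return True
    if normal in {"false", "0", "no"}:
        return False
    raise FormatError(f"row {line}: bad boolean {token!r} in column {column!r}")


def read_labels(path: str | Path) -> list[CitationRecord]:
    """Parse a label-table CSV into citation records.

    Header: ``citation_id,review_id,expert_eligible,has_abstract,
    fulltext_retrievable`` with true/false booleans.  Citation ids must be
    unique.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(frame, LABEL_COLUMNS, f"label table {path}")
    out: list[CitationRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False)):
        line = i + 2
        cid = str(getattr(row, "citation_id"))
        if cid in seen:
            raise DuplicateVoteError(f"row {line}: duplicate citation_id {cid!r}")
        seen.add(cid)
        out.append(
            CitationRecord(
                citation_id=cid,
                review_id=str(getattr(row, "review_id")),
                expert_eligible=_parse_bool(
                    getattr(row, "expert_eligible"), line, "expert_eligible"
                ),
                has_abstract=_parse_bool(
                    getattr(row, "has_abstract"), line, "has_abstract"
                ),
                fulltext_retrievable=_parse_bool(
                    getattr(row, "fulltext_retrievable"),
                    line,
                    "fulltext_retrievable",
                ),
            )
        )
    return out


def write_labels(records: Iterable[CitationRecord], path: str | Path) -> None:
    rows = list(records)
    frame = pd.DataFrame(
        {
            "citation_id": [r.citation_id for r in rows],
            "review_id": [r.review_id for r in rows],
            "expert_eligible": [str(r.expert_eligible).lower() for r in rows],
            "has_abstract": [str(r.has_abstract).lower() for r in rows],
            "fulltext_retrievable": [
                str(r.fulltext_retrievable).lower() for r in rows
            ],
        }
    )
    frame.to_csv(path, index=False)


def check_referential_integrity(
    assessments: Iterable[Assessment], records: Iterable[CitationRecord]
) -> None:
    """Every vote must refer to a citation present in the label table."""
    known = {r.citation_id for r in records}
    for a in assessments:
        if a.citation_id not in known:
            raise ContractError(
                f"vote on unknown citation {a.citation_id!r} "
                f"(not in label table)"
            )


def summaries_to_frame(summaries: Iterable[PerformanceSummary]) -> pd.DataFrame:
    """Flatten performance summaries to a tidy DataFrame, one row per summary."""

    def unpack(p: Optional[Proportion], prefix: str) -> dict[str, object]:
        if p is None:
            return {prefix: None, f"{prefix}_lower": None, f"{prefix}_upper": None}
        return {prefix: p.value, f"{prefix}_lower": p.lower, f"{prefix}_upper": p.upper}

    rows = []
    for s in summaries:
        row: dict[str, object] = {
            "cutoff": s.threshold.cutoff,
            "scope": s.level_scope,
            "n_eligible": s.n_eligible,
            "n_ineligible": s.n_ineligible,
            "eligible_retained": s.eligible_retained,
            "ineligible_excluded": s.ineligible_excluded,
            "total_excluded": s.total_excluded,
            "n_undecided": s.n_undecided,
        }
        row.update(unpack(s.sensitivity, "sensitivity"))
        row.update(unpack(s.specificity, "specificity"))
        row.update(unpack(s.work_performed, "work_performed"))
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(
    summaries: Iterable[PerformanceSummary], path: str | Path
) -> None:
    """Emit performance summaries as CSV or JSON depending on the suffix."""
    frame = summaries_to_frame(summaries)
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=2))
    else:
        frame.to_csv(path, index=False)
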