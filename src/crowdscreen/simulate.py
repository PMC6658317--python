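"""Synthetic crowds, citations and two-level vote tables.

The generator reproduces the statistical structure of a real multi-review
crowd screening project: citations get a Bernoulli gold label at the study
prevalence, a small fraction lack abstracts (and skip straight to full
text), member accuracies are Beta-distributed with medians matched to the
observed member-level accuracy, each citation receives a fixed number of
votes from members sampled without replacement, and full-text votes exist
only for citations passing the advancement rule and a retrieval Bernoulli.

Votes are conditionally independent given the gold label and the member's
profile — there is no per-citation difficulty effect.  Randomness derives
from one root seed split into fixed, named substreams, so any stage can be
regenerated independently and identical configs give byte-identical vote
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from crowdscreen.model import (
    Assessment,
    CitationRecord,
    ContractError,
    Level,
    Verdict,
    VoteTally,
)
from crowdscreen.aggregation import ADVANCEMENT_CUTOFF, advance_to_fulltext


class ParameterizationError(ValueError):
    """A requested accuracy distribution cannot be quantile-matched."""


@dataclass(frozen=True)
class AccuracyDistribution:
    """A Beta accuracy distribution pinned by its median.

    ``concentration`` is a + b, controlling spread around the median; an
    infinite concentration (or a median of exactly 0 or 1) degenerates to a
    point mass, which is how "force every member perfect" configs are
    expressed.
    """

    median: float
    concentration: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.median <= 1.0:
            raise ParameterizationError("median must lie in [0, 1]")
        if self.concentration <= 0.0:
            raise ParameterizationError("concentration must be positive")

    @property
    def degenerate(self) -> bool:
        return (
            math.isinf(self.concentration)
            or self.median in (0.0, 1.0)
        )

    def beta_params(self) -> tuple[float, float]:
        """Solve for (a, b) with a + b = concentration and median matched."""
        if self.degenerate:
            raise ParameterizationError(
                "degenerate distribution has no Beta parameters"
            )
        kappa = self.concentration
        eps = 1e-9

        def offset(a: float) -> float:
            return stats.beta.ppf(0.5, a, kappa - a) - self.median

        lo, hi = eps, kappa - eps
        if offset(lo) > 0 or offset(hi) < 0:
            raise ParameterizationError(
                f"cannot match median {self.median} at concentration {kappa}"
            )
        a = optimize.brentq(offset, lo, hi, xtol=1e-12)
        return float(a), float(kappa - a)

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.degenerate:
            return np.full(size, self.median)
        a, b = self.beta_params()
        return rng.beta(a, b, size=size)


@dataclass(frozen=True)
class MemberProfile:
    """Latent accuracy of one crowd member at each screening level."""

    member_id: str
    sens_abstract: float
    spec_abstract: float
    sens_fulltext: float
    spec_fulltext: float
    abstain_prob: float

    def __post_init__(self) -> None:
        for name in (
            "sens_abstract",
            "spec_abstract",
            "sens_fulltext",
            "spec_fulltext",
            "abstain_prob",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ContractError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; the defaults are the study's conditions.

    2323 citations at 7.7% eligible prevalence, 129/2323 missing abstracts,
    8 abstract and 7 full-text votes per citation (the observed medians),
    83.5% full-text retrieval, 71 active members (the subset that completed
    the 50-assessment minimum performed ~99% of all assessments), member
    accuracies median-matched to the observed per-member medians, and the
    ≥25%-eligible advancement rule.
    """

    n_citations: int = 2323
    prevalence: float = 0.077
    n_members: int = 71
    votes_per_citation_abstract: int = 8
    votes_per_citation_fulltext: int = 7
    missing_abstract_prob: float = 129 / 2323
    retrieval_prob: float = 0.835
    sens_abstract: AccuracyDistribution = AccuracyDistribution(0.966)
    spec_abstract: AccuracyDistribution = AccuracyDistribution(0.764)
    sens_fulltext: AccuracyDistribution = AccuracyDistribution(0.967)
    spec_fulltext: AccuracyDistribution = AccuracyDistribution(0.643)
    abstain_prob: float = 0.02
    advancement_cutoff: float = ADVANCEMENT_CUTOFF
    review_id: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_citations < 1 or self.n_members < 1:
            raise ContractError("need at least one citation and one member")
        if (
            self.votes_per_citation_abstract < 1
            or self.votes_per_citation_fulltext < 1
        ):
            raise ContractError("vote depths must be at least 1")
        for name in (
            "prevalence",
            "missing_abstract_prob",
            "retrieval_prob",
            "abstain_prob",
            "advancement_cutoff",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ContractError(f"{name} must lie in [0, 1], got {value}")
        depth = max(
            self.votes_per_citation_abstract, self.votes_per_citation_fulltext
        )
        if self.n_members < depth:
            raise ContractError(
                f"{depth} votes per citation need at least {depth} members, "
                f"got {self.n_members}"
            )


_STAGES = ("members", "labels", "abstract", "fulltext")


def _stage_rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    """Deterministic per-stage substream of the root seed."""
    children = np.random.SeedSequence(config.seed).spawn(len(_STAGES))
    return np.random.default_rng(children[_STAGES.index(stage)])


def draw_members(config: SimulationConfig) -> list[MemberProfile]:
    """Sample member accuracy profiles from the configured Beta distributions."""
    rng = _stage_rng(config, "members")
    n = config.n_members
    sens_a = config.sens_abstract.draw(rng, n)
    spec_a = config.spec_abstract.draw(rng, n)
    sens_f = config.sens_fulltext.draw(rng, n)
    spec_f = config.spec_fulltext.draw(rng, n)
    width = len(str(n))
    return [
        MemberProfile(
            member_id=f"m{i + 1:0{width}d}",
            sens_abstract=float(sens_a[i]),
            spec_abstract=float(spec_a[i]),
            sens_fulltext=float(sens_f[i]),
            spec_fulltext=float(spec_f[i]),
            abstain_prob=config.abstain_prob,
        )
        for i in range(n)
    ]


def _vote(
    rng: np.random.Generator,
    eligible: bool,
    sens: float,
    spec: float,
    abstain_prob: float,
) -> Verdict:
    if rng.random() < abstain_prob:
        return Verdict.NO_ASSESSMENT
    if eligible:
        return Verdict.RETAIN if rng.random() < sens else Verdict.EXCLUDE
    return Verdict.EXCLUDE if rng.random() < spec else Verdict.RETAIN


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[CitationRecord], list[Assessment]]:
    """Generate a full label table and two-level vote table.

    Citations without an abstract receive no abstract votes and advance
    automatically; full-text votes are generated only for citations that
    pass the advancement rule and whose article is retrievable.  A citation
    whose abstract votes are all abstentions cannot pass the advancement
    rule and receives no full-text votes.
    """
    members = draw_members(config)

    rng_labels = _stage_rng(config, "labels")
    n = config.n_citations
    width = len(str(n))
    eligible = rng_labels.random(n) < config.prevalence
    missing = rng_labels.random(n) < config.missing_abstract_prob
    retrievable = rng_labels.random(n) < config.retrieval_prob
    records = [
        CitationRecord(
            citation_id=f"c{i + 1:0{width}d}",
            review_id=config.review_id,
            expert_eligible=bool(eligible[i]),
            has_abstract=not bool(missing[i]),
            fulltext_retrievable=bool(retrievable[i]),
        )
        for i in range(n)
    ]

    votes: list[Assessment] = []

    rng_abs = _stage_rng(config, "abstract")
    abstract_tallies: dict[str, VoteTally] = {}
    for record in records:
        if not record.has_abstract:
            continue
        chosen = rng_abs.choice(
            config.n_members, size=config.votes_per_citation_abstract,
            replace=False,
        )
        counts = [0, 0, 0]  # exclude, retain, abstain
        for idx in chosen:
            profile = members[idx]
            verdict = _vote(
                rng_abs, record.expert_eligible,
                profile.sens_abstract, profile.spec_abstract,
                profile.abstain_prob,
            )
            votes.append(
                Assessment(record.citation_id, profile.member_id,
                           Level.ABSTRACT, verdict)
            )
            if verdict is Verdict.EXCLUDE:
                counts[0] += 1
            elif verdict is Verdict.RETAIN:
                counts[1] += 1
            else:
                counts[2] += 1
        abstract_tallies[record.citation_id] = VoteTally(*counts)

    rng_ft = _stage_rng(config, "fulltext")
    for record in records:
        t = abstract_tallies.get(record.citation_id)
        if record.has_abstract and (t is None or t.n_informative == 0):
            continue  # undecidable advancement: stays with the team
        if not advance_to_fulltext(record, t, config.advancement_cutoff):
            continue
        if not record.fulltext_retrievable:
            continue
        chosen = rng_ft.choice(
            config.n_members, size=config.votes_per_citation_fulltext,
            replace=False,
        )
        for idx in chosen:
            profile = members[idx]
            verdict = _vote(
                rng_ft, record.expert_eligible,
                profile.sens_fulltext, profile.spec_fulltext,
                profile.abstain_prob,
            )
            votes.append(
                Assessment(record.citation_id, profile.member_id,
                           Level.FULLTEXT, verdict)
            )
    return records, votes


def perfect_config(**overrides: object) -> SimulationConfig:
    """A config whose members are error-free and never abstain.

    Useful as a generator limit: at every cutoff the crowd then reaches
    sensitivity 100% and work performed 1 - prevalence.
    """
    base = dict(
        sens_abstract=AccuracyDistribution(1.0),
        spec_abstract=AccuracyDistribution(1.0),
        sens_fulltext=AccuracyDistribution(1.0),
        spec_fulltext=AccuracyDistribution(1.0),
        abstain_prob=0.0,
        missing_abstract_prob=0.0,
        retrieval_prob=1.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)  # type: ignore[arg-type]


def fixture_small() -> tuple[list[CitationRecord], list[Assessment]]:
    """A hand-coded 12-citation, 5-member fixture with known decisions.

    Eligible citations: c01, c02, c08, c11.  Cascade excluded sets:
      cutoff 0.0  -> {c02,c03,c04,c05,c06,c07,c08,c11,c12}
      cutoff 0.5  -> {c03,c04,c05,c06,c11,c12}
      cutoff 0.75 -> {c03,c04,c12}
      cutoff 1.0  -> {c03,c04}
    Abstract-only excluded sets:
      cutoff 0.0  -> {c02,c03,c04,c06,c07,c08,c11,c12}
      cutoff 0.5  -> {c03,c04,c11,c12}
      cutoff 0.75 -> {c03,c12}
      cutoff 1.0  -> {c03}
    c05 is the missing-abstract citation (auto-advanced); c07 advanced but
    has an unretrievable full text (retained in the cascade); c09 has zero
    votes and c10 all-abstain abstract votes (both undecided).
    """
    E, R, A = Verdict.EXCLUDE, Verdict.RETAIN, Verdict.NO_ASSESSMENT
    AB, FT = Level.ABSTRACT, Level.FULLTEXT

    def rec(cid: str, eligible: bool, has_abstract: bool = True,
            retrievable: bool = True) -> CitationRecord:
        return CitationRecord(cid, "fix", eligible, has_abstract, retrievable)

    records = [
        rec("c01", True),
        rec("c02", True),
        rec("c03", False),
        rec("c04", False),
        rec("c05", False, has_abstract=False),
        rec("c06", False),
        rec("c07", False, retrievable=False),
        rec("c08", True),
        rec("c09", False),
        rec("c10", False),
        rec("c11", True),
        rec("c12", False),
    ]

    plan: list[tuple[str, Level, list[Verdict]]] = [
        ("c01", AB, [R, R, R, R]),
        ("c01", FT, [R, R, R, R]),
        ("c02", AB, [E, R, R, R]),       # 0.25
        ("c02", FT, [R, R, R, R]),
        ("c03", AB, [E, E, E, E]),       # 1.0, not advanced
        ("c04", AB, [E, E, E, R]),       # 0.75, advanced at exactly 25%
        ("c04", FT, [E, E, E, E]),       # 1.0
        ("c05", FT, [E, E, E, R]),       # 0.75; no abstract
        ("c06", AB, [E, E, R, R, A]),    # 0.5
        ("c06", FT, [E, E, E, R]),       # 0.75
        ("c07", AB, [E, R, R, R]),       # 0.25, advanced, unretrieved
        ("c08", AB, [E, E, R, R]),       # 0.5
        ("c08", FT, [E, R, R, R]),       # 0.25
        ("c10", AB, [A, A, A]),          # all abstentions
        ("c11", AB, [E, E, E, R]),       # 0.75
        ("c11", FT, [R, R, R, R]),
        ("c12", AB, [E, E, E, E, R]),    # 0.8, not advanced
    ]
    members = ["m1", "m2", "m3", "m4", "m5"]
    votes = [
        Assessment(cid, members[i], level, verdict)
        for cid, level, verdicts in plan
        for i, verdict in enumerate(verdicts)
    ]
    return records, votes
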