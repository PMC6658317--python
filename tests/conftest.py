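"""Shared fixtures and hypothesis configuration."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from crowdscreen.model import Assessment, CitationRecord, Level, Verdict
from crowdscreen.aggregation import (
    CitationDecision,
    DecidingLevel,
    Decision,
)
from crowdscreen.simulate import fixture_small

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def small_fixture():
    """The hand-coded 12-citation, 5-member dataset with known decisions."""
    return fixture_small()


def make_labels(n_eligible: int, n_ineligible: int) -> list[CitationRecord]:
    """A flat label table: e* eligible then i* ineligible citations."""
    out = [
        CitationRecord(f"e{i}", "r", expert_eligible=True)
        for i in range(n_eligible)
    ]
    out += [
        CitationRecord(f"i{i}", "r", expert_eligible=False)
        for i in range(n_ineligible)
    ]
    return out


def make_decision(citation_id: str, excluded: bool) -> CitationDecision:
    """A minimal decision record for metric tests."""
    return CitationDecision(
        citation_id=citation_id,
        abstract_fraction=1.0 if excluded else 0.0,
        fulltext_fraction=None,
        advanced=not excluded,
        final_decision=Decision.EXCLUDED if excluded else Decision.RETAINED,
        deciding_level=DecidingLevel.ABSTRACT if excluded else DecidingLevel.NONE,
    )


def vote(cid: str, member: str, level: Level, verdict: Verdict) -> Assessment:
    return Assessment(cid, member, level, verdict)
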