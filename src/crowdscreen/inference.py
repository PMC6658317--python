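"""Statistical machinery: Wilson intervals, exact McNemar, sample size.

All proportions in the package carry Wilson score 95% intervals (no
continuity correction): the score-test inversion

    (p̂ + z²/2n ± z·sqrt(p̂(1-p̂)/n + z²/4n²)) / (1 + z²/n)

with z the standard-normal quantile for the confidence level.  Paired
screening policies are compared with the exact one-tailed McNemar test,
p = P(Bin(b+c, ½) ≥ b), where b counts discordant citations flipping in the
hypothesized direction — a less stringent exclusion threshold can only
exclude more, so the test is one-sided by design.  The sample-size planner
inverts the Wilson lower bound: the smallest n for which the assumed
sensitivity still keeps the interval's lower end above the target.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass
from decimal import ROUND_CEILING, ROUND_FLOOR, ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Optional

import numpy as np
from scipy import stats

from crowdscreen.aggregation import CitationDecision, Decision
from crowdscreen.model import CitationRecord, ContractError, Proportion


@dataclass(frozen=True)
class WilsonInterval:
    """Wilson score confidence interval for a binomial proportion."""

    x: int
    n: int
    confidence: float
    z: float
    lower: float
    upper: float

    @property
    def point(self) -> float:
        return self.x / self.n

    def as_proportion(self) -> Proportion:
        return Proportion(self.x, self.n, self.point, self.lower, self.upper)


def wilson_bounds(
    x: np.ndarray | int, n: np.ndarray | int, confidence: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Wilson score bounds (no continuity correction)."""
    z = float(stats.norm.ppf(1.0 - (1.0 - confidence) / 2.0))
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    p = x / n
    denom = 1.0 + z * z / n
    centre = p + z * z / (2.0 * n)
    half = z * np.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n))
    lower = np.clip((centre - half) / denom, 0.0, 1.0)
    upper = np.clip((centre + half) / denom, 0.0, 1.0)
    # boundary counts have exact bounds; snap away float residue
    lower = np.where(x == 0, 0.0, lower)
    upper = np.where(x == n, 1.0, upper)
    return lower, upper


def wilson_ci(x: int, n: int, confidence: float = 0.95) -> WilsonInterval:
    """Wilson score interval for x successes in n trials.

    For x = n the bounds reduce to [n/(n+z²), 1]; for x = 0 to [0, z²/(n+z²)].
    """
    if n < 1:
        raise ContractError("wilson_ci requires n >= 1")
    if not 0 <= x <= n:
        raise ContractError(f"wilson_ci requires 0 <= x <= n, got x={x}, n={n}")
    if not 0.0 < confidence < 1.0:
        raise ContractError("confidence must lie in (0, 1)")
    z = float(stats.norm.ppf(1.0 - (1.0 - confidence) / 2.0))
    lower, upper = wilson_bounds(x, n, confidence)
    return WilsonInterval(
        x=x, n=n, confidence=confidence, z=z,
        lower=float(lower), upper=float(upper),
    )


# --------------------------------------------------------------------------
# McNemar
# --------------------------------------------------------------------------


class Outcome(str, Enum):
    """Which screening outcome a paired comparison addresses."""

    SENSITIVITY = "sensitivity"      # eligible citations; event = retained
    WORK_PERFORMED = "work_performed"  # all citations; event = excluded
    SPECIFICITY = "specificity"      # ineligible citations; event = excluded


@dataclass(frozen=True)
class PairedDiscordance:
    """Discordant-pair counts for a paired policy comparison.

    ``b`` counts citations whose outcome flips in the hypothesized direction
    (the one favored by the less stringent policy); ``c`` counts flips the
    other way.
    """

    b: int
    c: int

    def __post_init__(self) -> None:
        if self.b < 0 or self.c < 0:
            raise ContractError("discordance counts must be non-negative")


def mcnemar_one_tailed(d: PairedDiscordance) -> float:
    """Exact one-tailed McNemar p-value: P(Bin(b+c, ½) ≥ b).

    Returns 1.0 when there are no discordant pairs.
    """
    n = d.b + d.c
    if n == 0:
        return 1.0
    return float(stats.binom.sf(d.b - 1, n, 0.5))


def paired_discordance(
    decisions_a: Iterable[CitationDecision],
    decisions_b: Iterable[CitationDecision],
    labels: Iterable[CitationRecord],
    outcome: Outcome,
    less_stringent: Optional[str] = None,
) -> PairedDiscordance:
    """Count discordant citations between two decision sets.

    Both sets must cover exactly the same citations.  The pair universe is
    eligible citations for SENSITIVITY, ineligible for SPECIFICITY and all
    citations for WORK_PERFORMED.  ``b`` counts citations excluded by the
    less stringent policy but retained by the other; ``less_stringent`` names
    that set ("a" or "b").  When omitted it is inferred as the set with more
    exclusions overall — exact for nested threshold policies, which strictly
    order their excluded sets.
    """
    a = {d.citation_id: d for d in decisions_a}
    b = {d.citation_id: d for d in decisions_b}
    if a.keys() != b.keys():
        raise ContractError("decision sets cover different citations")
    if less_stringent not in (None, "a", "b"):
        raise ContractError("less_stringent must be 'a', 'b' or None")

    if less_stringent is None:
        n_excl_a = sum(d.final_decision is Decision.EXCLUDED for d in a.values())
        n_excl_b = sum(d.final_decision is Decision.EXCLUDED for d in b.values())
        less_stringent = "b" if n_excl_b >= n_excl_a else "a"

    by_id = {r.citation_id: r for r in labels}
    if outcome is Outcome.SENSITIVITY:
        universe = [cid for cid in a if by_id[cid].expert_eligible]
    elif outcome is Outcome.SPECIFICITY:
        universe = [cid for cid in a if not by_id[cid].expert_eligible]
    else:
        universe = list(a)

    # direction favored by the less stringent policy: it excludes, the
    # stringent one retains
    loose, strict = (b, a) if less_stringent == "b" else (a, b)
    n_b = n_c = 0
    for cid in universe:
        loose_excl = loose[cid].final_decision is Decision.EXCLUDED
        strict_excl = strict[cid].final_decision is Decision.EXCLUDED
        if loose_excl and not strict_excl:
            n_b += 1
        elif strict_excl and not loose_excl:
            n_c += 1
    return PairedDiscordance(b=n_b, c=n_c)


# --------------------------------------------------------------------------
# sample size
# --------------------------------------------------------------------------


class RoundingMode(str, Enum):
    """How the expected success count x = f(sensitivity · n) is rounded."""

    HALF_UP = "half_up"
    FLOOR = "floor"
    CEIL = "ceil"


@dataclass(frozen=True)
class SampleSizeSpec:
    """Design inputs for the sensitivity-validation sample-size search.

    The planner finds the smallest number of eligible citations n such that,
    if the crowd retains the assumed fraction of them, the Wilson lower
    confidence bound still clears ``target_lower_bound``.
    """

    assumed_sensitivity: float
    target_lower_bound: float
    confidence: float = 0.95
    rounding_mode: RoundingMode = RoundingMode.HALF_UP

    def __post_init__(self) -> None:
        if not 0.0 < self.target_lower_bound < self.assumed_sensitivity <= 1.0:
            raise ContractError(
                "need 0 < target_lower_bound < assumed_sensitivity <= 1 "
                f"(got target={self.target_lower_bound}, "
                f"assumed={self.assumed_sensitivity})"
            )


_DECIMAL_ROUNDING = {
    RoundingMode.HALF_UP: ROUND_HALF_UP,
    RoundingMode.FLOOR: ROUND_FLOOR,
    RoundingMode.CEIL: ROUND_CEILING,
}


def expected_successes(
    assumed: float, n: int, mode: RoundingMode = RoundingMode.HALF_UP
) -> int:
    """Rounded expected success count x(n), clamped to [0, n].

    Uses decimal arithmetic so that e.g. 0.95 · 150 rounds from exactly
    142.5 rather than from its binary float neighbour.
    """
    exact = Decimal(str(assumed)) * Decimal(n)
    x = int(exact.to_integral_value(rounding=_DECIMAL_ROUNDING[RoundingMode(mode)]))
    return max(0, min(n, x))


def sample_size_for_sensitivity(
    spec: SampleSizeSpec, max_n: int = 100_000
) -> int:
    """Smallest n with wilson_ci(x(n), n).lower >= target_lower_bound.

    The search is an exact incremental scan; the Wilson lower bound is not
    monotone in n once x(n) jumps, so no bisection shortcut is taken.
    """
    for n in range(1, max_n + 1):
        x = expected_successes(spec.assumed_sensitivity, n, spec.rounding_mode)
        if wilson_ci(x, n, spec.confidence).lower >= spec.target_lower_bound:
            return n
    raise ContractError(
        f"no sample size up to {max_n} meets the target lower bound "
        f"{spec.target_lower_bound}"
    )
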