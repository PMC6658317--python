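# Methods

This note documents the statistical model behind `crowdscreen`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real screening data.

## The screening model

A screening project consists of citations `c = 1..N`, each with an expert
gold label (eligible / ineligible), and crowd assessments
`(citation, member, level, verdict)` with `level ∈ {abstract, fulltext}`
and `verdict ∈ {retain, exclude, no_assessment}`.  A member votes at most
once per citation per level.

**Exclusion fraction.** For a citation's votes at one level with counts
(`n_exclude`, `n_retain`, `n_abstain`), the exclusion fraction is

    f = n_exclude / (n_exclude + n_retain)

Abstentions are excluded from the denominator.  This is a deliberate
choice: a "no assessment" verdict records that the member was not
comfortable judging the citation, which carries no information about
eligibility.  It also makes the ≤75 %-exclusion advancement criterion and
the ≥25 %-eligible advancement rule exactly complementary, which is how the
two are described interchangeably in practice.  With zero informative votes
the fraction is undefined and the citation is *undecided* (see below), not
silently retained or excluded.

**Threshold policy.** A policy with cutoff `t ∈ [0, 1]` excludes a citation
iff `f > t` when `t < 1`, and iff `f = 1` when `t = 1`.  The strict
inequality matches the conventional labels: ">75 %", ">50 %" (a fraction
exactly equal to a sub-unity cutoff retains) and "=100 %" (unanimity).
Consequences: the 0 cutoff excludes on any exclude vote; raising the cutoff
can only shrink the excluded set, so sensitivity is non-decreasing and work
performed non-increasing in the cutoff.  This monotonicity is enforced as a
property test.

**Advancement.** A citation moves from abstract to full-text screening when
its retain fraction `1 − f` is at least the advancement cutoff (default
0.25), or automatically when it has no abstract.  A citation with an
abstract but only abstentions cannot pass the rule and stays with the team.

**Cascade.** A citation is excluded when its exclusion fraction triggers
the policy at *either* level; the abstract level takes precedence when
reporting which level decided.  Citations that advanced but received no
informative full-text votes — typically articles the crowd could not
retrieve — are retained: they fall back to the investigative team, and
counting them as crowd exclusions would overstate work performed.

**Undecided citations.** A labelled citation with an abstract but no
informative vote at any usable level is reported as undecided (a flag on
the decision record) and treated as retained in every metric: it
demonstrably still needs investigator assessment.  Surfacing these rather
than folding them in silently makes incomplete reviews visible.

## Crowd and member metrics

Against the expert labels, with `E` eligible and `I` ineligible citations:

- sensitivity = eligible retained / `E` (undefined when `E = 0`),
- specificity = ineligible excluded / `I` (undefined when `I = 0`),
- work performed = total excluded / (`E + I`).

The count identity `total_excluded = (E − eligible_retained) +
ineligible_excluded` holds exactly and is asserted for every summary.
Percentages are reported to one decimal with half-up rounding, matching the
conventional table style.

Member-level sensitivity/specificity mirror the crowd definitions per
member on informative votes only.  The inclusion filter requires a minimum
number of assessments (default 50) *within a single review, summed over
both levels*; this is the reading consistent with published member-level
tables, where included members can have as few as five full-text
assessments.  Metrics are then reported per level.  A member with no
informative vote on any eligible citation has undefined (absent)
sensitivity.

## Inference

**Wilson score intervals.** All proportions carry the score-test inversion
interval

    (p̂ + z²/2n ± z √(p̂(1−p̂)/n + z²/4n²)) / (1 + z²/n)

without continuity correction; `z` is the standard-normal quantile for the
confidence level (1.96 at 95 %), computed, not hard-coded.  The
no-continuity-correction choice is confirmed by exact agreement with the
published bounds for 178/178 (lower 97.9 %) and 176/178 (96.0–99.7 %).
Boundary counts snap exactly: lower = 0 at `x = 0`, upper = 1 at `x = n`.

**McNemar, exact and one-tailed.** Two threshold policies applied to the
same citations are compared on their discordant pairs.  Because policies at
nested cutoffs produce nested excluded sets, a less stringent policy can
only exclude more — so the test is one-sided by design:
`p = P(Bin(b+c, ½) ≥ b)`, where `b` counts citations flipping in the
direction favored by the less stringent policy (`p = 1` with no discordant
pairs).  For sensitivity the pair universe is the eligible citations, for
specificity the ineligible ones, for work performed all citations.  When
the caller does not name the less stringent set it is inferred as the one
with more exclusions overall, which is exact for nested threshold policies.
The exact binomial form (not the χ² approximation) is confirmed by
`(b, c) = (2, 0) → p = 0.25`.

**Sample-size planner.** Given an assumed sensitivity `s`, a target lower
bound `L < s` and a confidence level, the planner scans `n = 1, 2, …` and
returns the smallest `n` whose Wilson lower bound at `x(n)` retained
citations reaches `L`, with `x(n)` a rounding of `s·n` (half-up by default;
floor/ceil selectable, since `s·n` can land exactly on .5 — e.g.
0.95 × 150 = 142.5 — and no single convention is canonical).  Rounding is
done in decimal arithmetic so such ties are genuine ties.  Note that the
classical worked pair "142 of 150" has a Wilson lower bound of ≈89.8 %,
just *below* 90 %; the planner therefore returns the smallest exact
solution rather than reproducing that pair.

## The synthetic-data generator

`SimulationConfig` defaults encode the study conditions the package is
designed around:

| parameter | default | rationale |
|---|---|---|
| `n_citations` | 2323 | project size |
| `prevalence` | 0.077 | eligible fraction (178/2323) |
| `missing_abstract_prob` | 129/2323 | citations pushed straight to full text |
| `retrieval_prob` | 0.835 | full-text retrieval success (774/927) |
| `votes_per_citation_abstract` | 8 | observed median assessment depth |
| `votes_per_citation_fulltext` | 7 | observed median assessment depth |
| `n_members` | 71 | members meeting the 50-assessment minimum (≈99 % of votes) |
| accuracy medians | .966/.764 abstract, .967/.643 full text | observed member medians |
| `abstain_prob` | 0.02 | not reported anywhere; a small nuisance rate chosen once |
| `advancement_cutoff` | 0.25 | the ≥25 %-eligible rule |

Member accuracies are Beta-distributed with parameters solved so the
*median* hits the target exactly (`a + b = concentration`, default 30, and
`BetaInv(0.5; a, b) = median` by bisection); a median of exactly 0/1 or an
infinite concentration degenerates to a point mass, which is how
perfect-crowd limits are expressed.  Medians rather than means are matched
because the observed member summaries are medians of skewed distributions.

Votes are conditionally independent Bernoulli draws given the gold label
and the member's profile (eligible: retain w.p. sens; ineligible: exclude
w.p. spec), with the verdict replaced by an abstention w.p. `abstain_prob`.
Members per citation are sampled without replacement; vote depth is fixed
per level rather than drawn from the empirical 7–8 IQR (the simplest model
matching the observed medians; configurable).  Full-text votes exist only
for citations that pass the advancement rule and a retrieval Bernoulli.
One root seed is split into named substreams (members, labels, abstract,
fulltext), so stages regenerate independently and identical configs give
byte-identical tables.

**What the generator does *not* model.**  There is no per-citation
difficulty effect: real crowds agree much more strongly on easy exclusions
than conditional independence predicts, which is why a real project can
reach ~45 % unanimous-exclusion work while the independent-vote model at
the same member accuracies yields far less.  Consequently, synthetic runs
demonstrate the method's *structural* properties (monotone sweeps, cascade
dominance, estimator consistency, the perfect-crowd limit) and the
*arithmetic* of the metrics — not the absolute work-performed levels of any
particular real crowd.  A difficulty random effect is the documented
extension point.

## Numerical choices and degenerate inputs

- Exclusion fractions are exact ratios of small integers; decisions
  compare them with `>` / `==` without tolerances (ties like 6/8 = 0.75 are
  exact in binary floating point for the vote depths in scope).
- Undecidable situations raise `UndefinedFractionError` at the operation
  level; the batch driver converts them to undecided-retained records.
- An empty vote table is legal; every labelled citation is then undecided.
- Reported percentages round half-up at one decimal; p-values print with
  three decimals and a `<.001` floor.
- The sample-size scan is linear in `n` (the Wilson lower bound is not
  monotone in `n` once `x(n)` jumps, so bisection is unsafe).

## Problem sizes used in the checks

The test suite runs the full generator at the default 2323-citation scale
for calibration checks, and smaller projects (60–400 citations, 8–12
members) for the 100-dataset monotonicity sweep and recovery experiments;
Wilson coverage uses 10⁴ binomial replicates at n ∈ {20, 178, 2323} and
p = 0.5.  Member-accuracy recovery is measured on a balanced design
(prevalence 0.5, 200 votes per member) so both accuracy axes receive ~100
informative votes per member — at a 7.7 % prevalence a member would see
only ~15 eligible votes, which bounds any estimator's precision well above
the ±0.03 acceptance band; the balanced design isolates estimator
consistency from label scarcity.

## Known limitations

- No modelling of time-to-completion or member arrival dynamics.
- Vote depth is fixed per level, not heterogeneous.
- The member filter interpretation ("50 within one review, both levels")
  is the most consistent reading of the published tables but cannot be
  verified against the undeposited vote-level data.
- With zero discordant pairs the one-tailed exact McNemar p-value is 1.0 by
  definition; software conventions that report 0.5 in that case are not
  reproduced.
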