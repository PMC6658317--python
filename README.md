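# crowdscreen

Tools for evaluating **crowdsourced citation screening** in systematic
reviews (SRs).

When a systematic review team delegates title/abstract and full-text
screening to an online crowd, each candidate citation collects several
independent verdicts — *retain*, *exclude*, or *no assessment* (an
abstention).  `crowdscreen` turns such vote tables into per-citation
decisions and diagnostic-accuracy summaries, so that a review team can ask:
*if we trust the crowd at exclusion threshold t, how many eligible studies
would we lose, and how much screening work would we be spared?*

It is written for methodologists studying crowd/expert agreement and for SR
teams piloting crowd screening. The package provides:

- **Threshold-vote aggregation.** A citation's *exclusion fraction* is the
  share of exclude votes among informative (non-abstention) votes. Under a
  threshold policy with cutoff *t*, the citation is excluded iff its
  fraction is strictly greater than *t* (unanimity required at *t* = 1).
  The two-level **cascade** excludes a citation when either its abstract- or
  full-text-level fraction triggers the policy; citations with ≥25 %
  retain votes at abstract level (or with no abstract at all) advance to
  full-text screening.
- **Crowd metrics against an expert gold standard.** Sensitivity
  (eligible citations retained), specificity (ineligible citations
  excluded) and *work performed* (fraction of all citations excluded — the
  screening the investigative team never has to do), each with a Wilson
  score 95 % CI, plus per-member accuracy summaries and 0–100 % threshold
  sweeps.
- **Inference.** Wilson score intervals (no continuity correction), the
  exact one-tailed McNemar test `p = P(Bin(b+c, ½) ≥ b)` for comparing
  paired screening policies, and a sample-size planner that finds the
  smallest validation set keeping the Wilson lower bound for sensitivity
  above a target.
- **A synthetic vote generator** whose defaults reproduce the structure of
  a real six-review screening project (2323 citations at 7.7 % prevalence,
  8 votes per abstract, Beta-distributed member accuracies, missing
  abstracts, imperfect full-text retrieval), so every stage is testable
  without proprietary vote data.

## Worked example

Simulate a screening project at the default study conditions, aggregate at
the >75 % exclusion threshold, and plan a validation sample:

```bash
$ crowdscreen simulate --seed 3 --out-votes votes.csv --out-labels labels.csv
simulated 2323 citations (169 eligible)
wrote 26338 votes (17560 abstract, 8778 fulltext) to votes.csv

$ crowdscreen aggregate --votes votes.csv --labels labels.csv --cutoff 0.75
cutoff 0.75, scope cascade: 1069 of 2323 citations excluded
sensitivity    100.0% (95% CI 97.8-100.0; 169/169)
work performed 46.0% (95% CI 44.0-48.0; 1069/2323)
specificity    49.6% (95% CI 47.5-51.7; 1069/2154)

$ crowdscreen samplesize --assumed 1.0 --target 0.90
n = 35 (expected retained: 35; Wilson lower bound 90.1%)
```

Reading: at the >75 % threshold this simulated crowd loses none of the 169
eligible citations (sensitivity 100 %, with a Wilson lower bound of 97.8 %)
while excluding 46 % of the 2323 citations on the team's behalf.  The
sample-size call says that if the crowd is assumed perfectly sensitive, 35
eligible citations all retained are enough for the 95 % Wilson lower bound
to stay above 90 %.

The same operations are available as library calls:

```python
>>> from crowdscreen import wilson_ci, mcnemar_one_tailed, PairedDiscordance
>>> ci = wilson_ci(176, 178)          # 176 of 178 eligible citations retained
>>> round(100 * ci.lower, 1), round(100 * ci.upper, 1)
(96.0, 99.7)
>>> mcnemar_one_tailed(PairedDiscordance(b=2, c=0))   # 2 citations flipped
0.25
```

`crowdscreen report` assembles the full (scope × cutoff) table with Wilson
CIs and McNemar p-values against a reference cutoff, and
`crowdscreen sweep` exports sensitivity/work-performed curves over a cutoff
grid (add `--plot out.png` to render them).

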