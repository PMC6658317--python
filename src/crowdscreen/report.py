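"""Summary tables and sweep exports.

``build_summary_table`` assembles the headline report: one row per
(scope, cutoff), each carrying sensitivity / work performed / specificity
with Wilson intervals, plus exact one-tailed McNemar p-values comparing
every non-reference cutoff with the reference cutoff within its scope.
Percentages print to one decimal (half-up); p-values to three decimals with
a "<.001" floor.  The numeric CSV export of a sweep curve is canonical; the
matplotlib rendering is an optional convenience.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from crowdscreen.aggregation import CitationDecision, Scope, decide_all
from crowdscreen.aggregation import ADVANCEMENT_CUTOFF
from crowdscreen.formatting import format_p, format_percent
from crowdscreen.inference import (
    Outcome,
    mcnemar_one_tailed,
    paired_discordance,
)
from crowdscreen.metrics import SweepCurve, crowd_performance
from crowdscreen.model import (
    Assessment,
    CitationRecord,
    ContractError,
    PerformanceSummary,
    ThresholdPolicy,
    summaries_to_frame,
)

DEFAULT_CUTOFFS = (1.0, 0.75, 0.5)
DEFAULT_REFERENCE = 0.75


@dataclass(frozen=True)
class SummaryRow:
    """One report row: a performance summary plus comparisons to reference."""

    summary: PerformanceSummary
    is_reference: bool
    p_sensitivity: Optional[float] = None
    p_work_performed: Optional[float] = None
    p_specificity: Optional[float] = None


@dataclass(frozen=True)
class SummaryTable:
    rows: tuple[SummaryRow, ...]
    reference_cutoff: float

    def to_frame(self) -> pd.DataFrame:
        base = summaries_to_frame(r.summary for r in self.rows)
        base["is_reference"] = [r.is_reference for r in self.rows]
        base["p_sensitivity"] = [r.p_sensitivity for r in self.rows]
        base["p_work_performed"] = [r.p_work_performed for r in self.rows]
        base["p_specificity"] = [r.p_specificity for r in self.rows]
        return base

    def to_text(self) -> str:
        """Human-readable table in the conventional layout."""
        lines = [
            f"{'scope':<10}{'cutoff':<8}{'sensitivity (95% CI)':<28}"
            f"{'p':<8}{'work performed (95% CI)':<28}{'p':<8}"
            f"{'specificity (95% CI)':<28}{'p':<8}"
        ]
        for r in self.rows:
            s = r.summary

            def cell(p) -> str:
                if p is None:
                    return "NA"
                return (
                    f"{format_percent(p.value)} "
                    f"({format_percent(p.lower)}-{format_percent(p.upper)})"
                )

            def pcell(p: Optional[float]) -> str:
                return "(Ref)" if r.is_reference else format_p(p)

            lines.append(
                f"{s.level_scope:<10}{s.threshold.cutoff:<8g}"
                f"{cell(s.sensitivity):<28}{pcell(r.p_sensitivity):<8}"
                f"{cell(s.work_performed):<28}{pcell(r.p_work_performed):<8}"
                f"{cell(s.specificity):<28}{pcell(r.p_specificity):<8}"
            )
        return "\n".join(lines)

    def write(self, path: str | Path) -> None:
        """Emit the table as CSV or JSON depending on the suffix."""
        path = Path(path)
        frame = self.to_frame()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(frame.to_dict(orient="records"), indent=2))
        else:
            frame.to_csv(path, index=False)


def _p_value(
    ref: list[CitationDecision],
    other: list[CitationDecision],
    labels: list[CitationRecord],
    outcome: Outcome,
    less_stringent: str,
) -> Optional[float]:
    d = paired_discordance(ref, other, labels, outcome, less_stringent)
    return mcnemar_one_tailed(d)


def build_summary_table(
    assessments: Iterable[Assessment],
    labels: Iterable[CitationRecord],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    reference_cutoff: float = DEFAULT_REFERENCE,
    scopes: Sequence[Scope] = (Scope.ABSTRACT_ONLY, Scope.CASCADE),
    advancement_cutoff: float = ADVANCEMENT_CUTOFF,
    confidence: float = 0.95,
) -> SummaryTable:
    """Compute the (scope x cutoff) report with McNemar comparisons.

    Within each scope, every non-reference cutoff is compared with the
    reference: the lower of the two cutoffs is the less stringent policy
    (it excludes a superset), fixing the one-tailed direction.
    """
    cutoffs = tuple(float(c) for c in cutoffs)
    if float(reference_cutoff) not in cutoffs:
        raise ContractError(
            f"reference cutoff {reference_cutoff} not among cutoffs {cutoffs}"
        )
    votes = list(assessments)
    records = list(labels)
    rows: list[SummaryRow] = []
    for scope in scopes:
        decisions = {
            c: decide_all(votes, records, ThresholdPolicy(c), scope,
                          advancement_cutoff)
            for c in cutoffs
        }
        reference = decisions[float(reference_cutoff)]
        for c in cutoffs:
            summary = crowd_performance(
                decisions[c], records, ThresholdPolicy(c), scope, confidence
            )
            if c == float(reference_cutoff):
                rows.append(SummaryRow(summary, is_reference=True))
                continue
            less = "b" if c < reference_cutoff else "a"
            rows.append(
                SummaryRow(
                    summary,
                    is_reference=False,
                    p_sensitivity=_p_value(
                        reference, decisions[c], records,
                        Outcome.SENSITIVITY, less,
                    ),
                    p_work_performed=_p_value(
                        reference, decisions[c], records,
                        Outcome.WORK_PERFORMED, less,
                    ),
                    p_specificity=_p_value(
                        reference, decisions[c], records,
                        Outcome.SPECIFICITY, less,
                    ),
                )
            )
    return SummaryTable(rows=tuple(rows), reference_cutoff=float(reference_cutoff))


def export_sweep(curve: SweepCurve, path: str | Path) -> None:
    """Write a sweep curve as CSV: cutoff, sensitivity, work_performed.

    Sensitivity is empty where undefined (no eligible citations).
    """
    frame = pd.DataFrame(
        {
            "cutoff": curve.cutoffs,
            "sensitivity": [
                s if s is not None else None for s in curve.sensitivity
            ],
            "work_performed": curve.work_performed,
        }
    )
    frame.to_csv(path, index=False)


def read_sweep(path: str | Path, scope: Scope = Scope.CASCADE) -> SweepCurve:
    """Re-read an exported sweep curve (round-trip of :func:`export_sweep`)."""
    frame = pd.read_csv(path)
    sens = tuple(
        None if pd.isna(v) else float(v) for v in frame["sensitivity"]
    )
    return SweepCurve(
        cutoffs=tuple(float(c) for c in frame["cutoff"]),
        sensitivity=sens,
        work_performed=tuple(float(w) for w in frame["work_performed"]),
        scope=scope,
    )


def plot_sweep(curve: SweepCurve, path: str | Path) -> None:
    """Render sensitivity and work performed against the cutoff (optional).

    Requires matplotlib; the CSV export remains the canonical output.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    xs = [100 * c for c in curve.cutoffs]
    sens = [
        None if s is None else 100 * s for s in curve.sensitivity
    ]
    work = [100 * w for w in curve.work_performed]
    ax.plot(xs, sens, label="Sensitivity", color="tab:blue")
    ax.plot(xs, work, label="Work performed", color="tab:orange")
    ax.set_xlabel("Exclusion threshold (%)")
    ax.set_ylabel("Percent")
    ax.set_ylim(0, 105)
    ax.legend(loc="lower right")
    ax.set_title(f"Threshold sweep ({curve.scope.value})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
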