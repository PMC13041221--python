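"""Cumulative status counts and registration rates.

A report answers, per code system and per report date: of every change-log
code observed so far, how many are correctly standardized (initially or
after a governance proposal was adopted), how many still require
standardization, and how many fall outside governance scope.

The registration rate is ``assigned / total``, reported as a half-up
rounded integer percentage. The denominator is the governance-scope total:
the four status buckets plus any ``unclassified`` remainder carried from
source tallies that do not fully decompose. When a report was narrowed to
an in-scope subset before counting, the pre-narrowing total is kept as
``scope_note`` for the record; an alternative denominator policy can use it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import pandas as pd

from .code_systems import CodeSystemId
from .governance import GovernanceLedger, MappingStatus

#: Denominator policy: "in_scope" divides by the counted total (the four
#: buckets + unclassified); "collected_total" divides by scope_note when
#: present (i.e. includes items dropped by a pre-narrowing step).
DenominatorPolicy = Literal["in_scope", "collected_total"]


@dataclass(frozen=True)
class StatusCounts:
    """Status decomposition of the codes observed up to one date."""

    assigned_initial: int = 0
    assigned_after_revision: int = 0
    requiring_standardization: int = 0
    out_of_scope: int = 0
    unclassified: int = 0

    def __post_init__(self) -> None:
        for name in (
            "assigned_initial", "assigned_after_revision",
            "requiring_standardization", "out_of_scope", "unclassified",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def assigned(self) -> int:
        return self.assigned_initial + self.assigned_after_revision

    @property
    def total_collected(self) -> int:
        return (
            self.assigned
            + self.requiring_standardization
            + self.out_of_scope
            + self.unclassified
        )


_STATUS_TO_BUCKET = {
    MappingStatus.CORRECT_INITIALLY: "assigned_initial",
    MappingStatus.CORRECT_AFTER_REVISION: "assigned_after_revision",
    MappingStatus.PROPOSED: "requiring_standardization",
    MappingStatus.OUT_OF_SCOPE: "out_of_scope",
}


@dataclass
class CumulativeReport:
    system: CodeSystemId
    series: list[tuple[date, StatusCounts]] = field(default_factory=list)
    scope_note: Optional[int] = None  # total collected before scope narrowing


def registration_rate(
    counts: StatusCounts,
    policy: DenominatorPolicy = "in_scope",
    scope_note: Optional[int] = None,
) -> int:
    """Percentage of codes carrying a correct standard code, half-up rounded.

    ``policy="collected_total"`` uses the pre-narrowing total (scope_note)
    as the denominator when one is provided.
    """
    denom = counts.total_collected
    if policy == "collected_total" and scope_note is not None:
        denom = scope_note
    if denom <= 0:
        raise ZeroDivisionError("registration rate undefined for zero total")
    pct = Decimal(100 * counts.assigned) / Decimal(denom)
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def _tally(items, when: date) -> StatusCounts:
    buckets = {name: 0 for name in _STATUS_TO_BUCKET.values()}
    for item in items:
        status = item.status_as_of(when)
        if status is not None:
            buckets[_STATUS_TO_BUCKET[status]] += 1
    return StatusCounts(**buckets)


def cumulative_counts(
    ledger: GovernanceLedger,
    dates: Sequence[date],
    system: CodeSystemId,
) -> CumulativeReport:
    """Status counts at each report date for one code system.

    An item counts from its first observed event onward, in the bucket of
    its latest status on or before the report date — so an item observed
    twice on one date is counted once, by its final same-day status.
    Closed (deleted) items are excluded.
    """
    if not dates:
        raise ValueError("at least one report date is required")
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("report dates must be strictly increasing")
    items = [item for item in ledger.open_items() if item.system is system]
    series = [(d, _tally(items, d)) for d in dates]
    return CumulativeReport(system=system, series=series)


def per_institution_breakdown(
    ledger: GovernanceLedger, when: date
) -> pd.DataFrame:
    """Per-(institution, system) status counts at one date.

    Row sums over institutions equal the network-wide counts for each
    system — the per-institution view is a partition of the same items.
    """
    rows = []
    groups: dict[tuple[str, str], list] = {}
    for item in ledger.open_items():
        groups.setdefault((item.institution_id, item.system.value), []).append(item)
    for (inst, system), items in sorted(groups.items()):
        counts = _tally(items, when)
        if counts.total_collected == 0:
            continue
        rows.append(
            {
                "institution_id": inst,
                "system": system,
                "assigned_initial": counts.assigned_initial,
                "assigned_after_revision": counts.assigned_after_revision,
                "requiring_standardization": counts.requiring_standardization,
                "out_of_scope": counts.out_of_scope,
                "total": counts.total_collected,
            }
        )
    columns = [
        "institution_id", "system", "assigned_initial",
        "assigned_after_revision", "requiring_standardization",
        "out_of_scope", "total",
    ]
    return pd.DataFrame(rows, columns=columns)


REPORT_HEADER = [
    "date", "system", "assigned_initial", "assigned_after_revision",
    "requiring_standardization", "out_of_scope", "unclassified",
    "total", "rate_pct",
]


def write_report_csv(
    reports: Sequence[CumulativeReport],
    path: Union[str, Path],
    policy: DenominatorPolicy = "in_scope",
) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(REPORT_HEADER)
        for report in reports:
            for d, counts in report.series:
                rate: Union[int, str]
                try:
                    rate = registration_rate(counts, policy, report.scope_note)
                except ZeroDivisionError:
                    rate = ""
                writer.writerow([
                    d.isoformat(), report.system.value,
                    counts.assigned_initial, counts.assigned_after_revision,
                    counts.requiring_standardization, counts.out_of_scope,
                    counts.unclassified, counts.total_collected, rate,
                ])


def plot_cumulative(report: CumulativeReport, path: Union[str, Path]) -> None:
    """Stacked cumulative series of the four buckets over report dates."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dates = [d for d, _ in report.series]
    keys = list(_STATUS_TO_BUCKET.values())
    stacks = [[getattr(c, k) for _, c in report.series] for k in keys]
    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.stackplot(dates, stacks, labels=keys)
    ax.set_title(f"Cumulative change-log codes — {report.system.value}")
    ax.set_ylabel("codes")
    ax.legend(loc="upper left", fontsize=8)
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
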