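"""End-to-end governance cycles over multi-institution snapshot series.

Mirrors the operational loop: extract differences at each institution,
pool them at the governance center, classify into the ledger, have the
expert review the PROPOSED queue and accept one proposal per item, and
carry those proposals forward so later registrations can be recognised as
adoptions. The expert is an injected callable — automation ranks
candidates, people decide.
"""

from __future__ import annotations

from datetime import date
from typing import Callable, Mapping, Optional, Sequence

from .code_systems import CodeSystemId, StandardMaster
from .diff_engine import MappingSnapshot, diff_snapshots
from .governance import (
    ClassifierConfig,
    DEFAULT_CLASSIFIER,
    GovernanceLedger,
    LedgerItem,
    Proposal,
    ScopeRules,
    pending_proposal_items,
    suggest_candidates,
)
from .synthetic import GroundTruth

#: Expert callback: given a pending item and the review date, return the
#: accepted proposal or None to leave the item in the queue.
Expert = Callable[[LedgerItem, date], Optional[Proposal]]


def top_candidate_expert(
    masters: Mapping[CodeSystemId, StandardMaster], score_floor: float = 0.3
) -> Expert:
    """An expert stand-in that accepts the best-ranked candidate."""

    def expert(item: LedgerItem, when: date) -> Optional[Proposal]:
        master = masters[item.system]
        ranked = suggest_candidates(
            item.current_record, master, 1, proposal_date=when, score_floor=score_floor
        )
        return ranked[0] if ranked else None

    return expert


def ground_truth_expert(truth: GroundTruth,
                        masters: Mapping[CodeSystemId, StandardMaster]) -> Expert:
    """An expert stand-in that proposes the generation-time true code."""

    def expert(item: LedgerItem, when: date) -> Optional[Proposal]:
        rec = truth.records.get(item.key)
        if rec is None or rec.true_code is None:
            return None
        return Proposal(
            institution_id=item.institution_id,
            system=item.system,
            local_code=item.local_code,
            proposed_code=rec.true_code,
            proposed_name=masters[item.system].entries[rec.true_code],
            proposal_date=when,
            match_score=1.0,
            rationale="expert-reviewed",
        )

    return expert


def run_governance(
    snapshot_series: Mapping[str, Sequence[MappingSnapshot]],
    masters: Mapping[CodeSystemId, StandardMaster],
    rules: Mapping[CodeSystemId, ScopeRules],
    expert: Optional[Expert] = None,
    config: ClassifierConfig = DEFAULT_CLASSIFIER,
    ledger: Optional[GovernanceLedger] = None,
) -> GovernanceLedger:
    """Replay every institution's series period by period into one ledger.

    Series are aligned by snapshot index (period); each period's pooled
    change logs are applied, then the expert reviews the pending queue and
    accepted proposals are attached dated that period — so an adoption can
    only be recognised from the next period on, as in a monthly feedback
    loop.
    """
    from .governance import update_ledger  # local import avoids cycle at module load

    ledger = ledger if ledger is not None else GovernanceLedger()
    n_periods = max((len(s) for s in snapshot_series.values()), default=0)
    for t in range(1, n_periods):
        entries = []
        period_date: Optional[date] = None
        for inst in sorted(snapshot_series):
            series = snapshot_series[inst]
            if t < len(series):
                entries.extend(diff_snapshots(series[t - 1], series[t]))
                period_date = max(period_date or series[t].snapshot_date,
                                  series[t].snapshot_date)
        update_ledger(ledger, entries, masters, rules, (), config)
        if expert is not None and period_date is not None:
            accepted = []
            for item in pending_proposal_items(ledger):
                prop = expert(item, period_date)
                if prop is not None:
                    accepted.append(prop)
            if accepted:
                update_ledger(ledger, (), masters, rules, accepted, config)
    return ledger
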