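"""Four-status classification, candidate proposals, and the governance ledger.

Every change-log entry is classified against the standard master of its
code system into one of four mapping statuses:

* ``CORRECT_INITIALLY`` — a standard code was already registered, exists in
  the master, and the local name is consistent with the canonical name.
* ``PROPOSED`` — a standard code is registered but invalid / absent from
  the master / name-inconsistent, or no code is registered for an in-scope
  item; a corrected code is to be proposed to the institution.
* ``CORRECT_AFTER_REVISION`` — a previously proposed code was later
  registered by the institution (adoption of the proposal).
* ``OUT_OF_SCOPE`` — no code is registered and the item falls outside the
  governance framework (in-hospital preparations, Kampo medicines, medical
  devices, modifiers, ...), recognised by configurable name-pattern rules.

The decision flow on a single entry: if a standard code is present its
master validity is checked first, then the local name is compared with the
canonical name; if absent, scope rules decide between OUT_OF_SCOPE and
PROPOSED. Adoption (CORRECT_AFTER_REVISION) is never assigned by the
classifier alone — it is a ledger transition observed when a later entry
registers exactly the code of the item's active proposal.

The ledger is the accumulated per-key state: status history, active
proposal, current record. Updates are idempotent per
``(key, extraction_date)`` so re-feeding the same change logs is a no-op.
"""

from __future__ import annotations

import difflib
import json
import re
import unicodedata
from dataclasses import dataclass, field, replace
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .code_systems import (
    CodeSystemId,
    MalformedCodeError,
    StandardMaster,
    lookup_master,
)
from .diff_engine import ChangeLogEntry, ChangeType, MappingRecord


class MappingStatus(str, Enum):
    CORRECT_INITIALLY = "CORRECT_INITIALLY"
    CORRECT_AFTER_REVISION = "CORRECT_AFTER_REVISION"
    PROPOSED = "PROPOSED"
    OUT_OF_SCOPE = "OUT_OF_SCOPE"


_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Canonicalise a local or master name for comparison.

    NFKC compatibility normalization (unifies full-width/half-width),
    whitespace strip + collapse, and case fold. Idempotent.
    """
    text = unicodedata.normalize("NFKC", name)
    return _WS.sub(" ", text).strip().casefold()


def name_similarity(a: str, b: str) -> float:
    """Similarity of two names after normalization, in [0, 1]."""
    na, nb = normalize_name(a), normalize_name(b)
    if na == nb:
        return 1.0
    return difflib.SequenceMatcher(None, na, nb).ratio()


@dataclass(frozen=True)
class ScopeRule:
    """One exclusion predicate: a regex matched on the normalized name."""

    rule_id: str
    pattern: str

    def matches(self, name: str) -> bool:
        return re.search(self.pattern, normalize_name(name)) is not None


@dataclass(frozen=True)
class ScopeRules:
    """Ordered exclusion rules for one code system.

    Anything matching a rule (and carrying no standard code) is out of
    governance scope. Rules are data, loaded from config, because the set
    of excluded categories is a policy choice, not an algorithm.
    """

    system: CodeSystemId
    rules: tuple[ScopeRule, ...] = ()

    def __post_init__(self) -> None:
        ids = [r.rule_id for r in self.rules]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate rule_id in scope rules")

    def first_match(self, name: str) -> Optional[ScopeRule]:
        for rule in self.rules:
            if rule.matches(name):
                return rule
        return None


#: Default exclusion rules mirroring the categories reported out of scope:
#: drugs — in-hospital preparations, Kampo medicines, medical devices;
#: labs — institution-specific tests absent from the standard terminology;
#: diseases — modifiers and other non-diagnosis terms.
DEFAULT_SCOPE_RULES: dict[CodeSystemId, ScopeRules] = {
    CodeSystemId.DRUG_HOT: ScopeRules(
        CodeSystemId.DRUG_HOT,
        (
            ScopeRule("inhospital-prep", r"\bin-?hospital\b|\bhospital preparation\b"),
            ScopeRule("kampo", r"\bkampo\b"),
            ScopeRule("device", r"\bdevice\b"),
        ),
    ),
    CodeSystemId.LAB_JLAC10: ScopeRules(
        CodeSystemId.LAB_JLAC10,
        (ScopeRule("institution-specific", r"\bin-?house\b|\binstitution-specific\b"),),
    ),
    CodeSystemId.DISEASE_ICD10: ScopeRules(
        CodeSystemId.DISEASE_ICD10,
        (ScopeRule("modifier", r"\bmodifier\b"),),
    ),
}


@dataclass(frozen=True)
class ClassifierConfig:
    """Name-match policy for the "local name consistent with canonical
    name" test.

    By default consistency means exact equality after
    :func:`normalize_name`; setting ``similarity_threshold`` below 1.0
    relaxes it to a difflib ratio at or above the threshold.
    """

    similarity_threshold: float = 1.0

    def names_consistent(self, local_name: str, canonical_name: str) -> bool:
        if self.similarity_threshold >= 1.0:
            return normalize_name(local_name) == normalize_name(canonical_name)
        return name_similarity(local_name, canonical_name) >= self.similarity_threshold


DEFAULT_CLASSIFIER = ClassifierConfig()


def classify_entry(
    entry: ChangeLogEntry,
    master: StandardMaster,
    rules: ScopeRules,
    config: ClassifierConfig = DEFAULT_CLASSIFIER,
) -> tuple[MappingStatus, str]:
    """Classify one ADDED/MODIFIED entry per the governance decision flow.

    Returns ``(status, reason)``; the reason is a short audit string naming
    the branch taken. A malformed standard code is treated like a code the
    master does not contain (→ PROPOSED): the flow has no separate
    malformed branch, and either way the institution needs a corrected
    code.
    """
    if entry.change_type is ChangeType.DELETED:
        raise ValueError("DELETED entries are closed in the ledger, not classified")
    record = entry.after
    assert record is not None
    if record.system is not master.system:
        raise ValueError(
            f"entry system {record.system.value} does not match master {master.system.value}"
        )
    if rules.system is not record.system:
        raise ValueError("scope rules are for a different system")

    if record.standard_code:
        try:
            hit = lookup_master(record.standard_code, master)
        except MalformedCodeError as exc:
            return (MappingStatus.PROPOSED, f"standard code malformed ({exc.reason})")
        if not hit.present:
            return (MappingStatus.PROPOSED, "standard code not in master")
        assert hit.canonical_name is not None
        if config.names_consistent(record.local_name, hit.canonical_name):
            return (MappingStatus.CORRECT_INITIALLY, "code valid and name consistent")
        return (
            MappingStatus.PROPOSED,
            f"name inconsistent with master name {hit.canonical_name!r}",
        )

    rule = rules.first_match(record.local_name)
    if rule is not None:
        return (MappingStatus.OUT_OF_SCOPE, f"matched scope rule {rule.rule_id}")
    return (MappingStatus.PROPOSED, "no standard code registered, in scope")


@dataclass(frozen=True)
class Proposal:
    """A candidate (or expert-accepted) standard code for one local item."""

    institution_id: str
    system: CodeSystemId
    local_code: str
    proposed_code: str
    proposed_name: str
    proposal_date: date
    match_score: float
    rationale: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.match_score <= 1.0:
            raise ValueError("match_score must be in [0, 1]")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.institution_id, self.system.value, self.local_code)

    def to_dict(self) -> dict:
        return {
            "institution_id": self.institution_id,
            "system": self.system.value,
            "local_code": self.local_code,
            "proposed_code": self.proposed_code,
            "proposed_name": self.proposed_name,
            "proposal_date": self.proposal_date.isoformat(),
            "match_score": round(self.match_score, 6),
            "rationale": self.rationale,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Proposal":
        return cls(
            institution_id=data["institution_id"],
            system=CodeSystemId(data["system"]),
            local_code=data["local_code"],
            proposed_code=data["proposed_code"],
            proposed_name=data["proposed_name"],
            proposal_date=date.fromisoformat(data["proposal_date"]),
            match_score=data["match_score"],
            rationale=data.get("rationale", ""),
        )


def suggest_candidates(
    record: MappingRecord,
    master: StandardMaster,
    k: int,
    *,
    proposal_date: Optional[date] = None,
    score_floor: float = 0.0,
) -> list[Proposal]:
    """Rank the top-*k* master entries by name similarity to the record.

    This is decision support for expert review, not the decision: a local
    name like "albumin" can legitimately match several codes differing in
    specimen or method, so the expert's accepted proposal is an input
    elsewhere. Ties are broken by ascending code text; entries scoring
    below ``score_floor`` are dropped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    stamp = proposal_date or record.updated_date or date.today()
    scored = sorted(
        (
            (-name_similarity(record.local_name, name), code)
            for code, name in master.entries.items()
        ),
    )
    out = []
    for neg_score, code in scored[:k]:
        score = -neg_score
        if score < score_floor:
            continue
        out.append(
            Proposal(
                institution_id=record.institution_id,
                system=record.system,
                local_code=record.local_code,
                proposed_code=code,
                proposed_name=master.entries[code],
                proposal_date=stamp,
                match_score=score,
                rationale=f"name similarity {score:.3f} to master entry",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Ledger


class LedgerError(ValueError):
    pass


@dataclass
class LedgerItem:
    """Accumulated governance state of one (institution, system, local code)."""

    institution_id: str
    system: CodeSystemId
    local_code: str
    current_status: MappingStatus
    status_history: list[tuple[date, MappingStatus]]
    current_record: MappingRecord
    active_proposal: Optional[Proposal] = None
    closed: bool = False
    processed_dates: list[date] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.institution_id, self.system.value, self.local_code)

    @property
    def first_seen(self) -> date:
        return self.status_history[0][0]

    def status_as_of(self, when: date) -> Optional[MappingStatus]:
        """Latest status on or before *when*; None if not yet observed."""
        status = None
        for d, s in self.status_history:
            if d <= when:
                status = s
            else:
                break
        return status

    def to_dict(self) -> dict:
        return {
            "institution_id": self.institution_id,
            "system": self.system.value,
            "local_code": self.local_code,
            "current_status": self.current_status.value,
            "status_history": [[d.isoformat(), s.value] for d, s in self.status_history],
            "current_record": self.current_record.to_dict(),
            "active_proposal": self.active_proposal.to_dict() if self.active_proposal else None,
            "closed": self.closed,
            "processed_dates": [d.isoformat() for d in self.processed_dates],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "LedgerItem":
        return cls(
            institution_id=data["institution_id"],
            system=CodeSystemId(data["system"]),
            local_code=data["local_code"],
            current_status=MappingStatus(data["current_status"]),
            status_history=[
                (date.fromisoformat(d), MappingStatus(s))
                for d, s in data["status_history"]
            ],
            current_record=MappingRecord.from_dict(data["current_record"]),
            active_proposal=Proposal.from_dict(data["active_proposal"])
            if data.get("active_proposal")
            else None,
            closed=data.get("closed", False),
            processed_dates=[date.fromisoformat(d) for d in data.get("processed_dates", [])],
        )


@dataclass
class GovernanceLedger:
    """All ledger items, keyed by (institution_id, system, local_code)."""

    items: dict[tuple[str, str, str], LedgerItem] = field(default_factory=dict)

    @property
    def last_processed_date(self) -> Optional[date]:
        dates = [d for item in self.items.values() for d in item.processed_dates]
        return max(dates) if dates else None

    def open_items(self) -> Iterable[LedgerItem]:
        return (item for item in self.items.values() if not item.closed)


def update_ledger(
    ledger: GovernanceLedger,
    entries: Sequence[ChangeLogEntry],
    masters: Mapping[CodeSystemId, StandardMaster],
    rules: Mapping[CodeSystemId, ScopeRules],
    accepted_proposals: Sequence[Proposal] = (),
    config: ClassifierConfig = DEFAULT_CLASSIFIER,
) -> GovernanceLedger:
    """Apply a batch of change-log entries and accepted proposals in place.

    Events are replayed in date order (entries before proposals on the same
    date, since a proposal reacts to an extracted difference). Semantics:

    * ADDED/MODIFIED — classified; if the item holds an active proposal and
      the entry registers exactly the proposed code, the status becomes
      CORRECT_AFTER_REVISION and the proposal is closed; a different code
      is re-classified from scratch.
    * DELETED — the item is closed (kept for audit, excluded from reports).
    * An accepted proposal becomes its item's active proposal (replacing
      any previous one).

    Idempotence: a ``(key, extraction_date)`` pair already processed is
    skipped, so re-feeding identical change logs changes nothing. Entries
    strictly older than ``last_processed_date`` that were *not* previously
    processed are rejected as an out-of-order feed.

    Returns the same ledger object for chaining.
    """
    last = ledger.last_processed_date
    events: list[tuple[date, int, int, object]] = []
    for i, entry in enumerate(entries):
        events.append((entry.extraction_date, 0, i, entry))
    for i, prop in enumerate(accepted_proposals):
        events.append((prop.proposal_date, 1, i, prop))
    events.sort(key=lambda ev: (ev[0], ev[1], ev[2]))

    for when, kind, _, event in events:
        if kind == 1:
            _attach_proposal(ledger, event)  # type: ignore[arg-type]
            continue
        entry: ChangeLogEntry = event  # type: ignore[assignment]
        item = ledger.items.get(entry.key)
        already = item is not None and when in item.processed_dates
        if already:
            continue
        if last is not None and when < last:
            raise LedgerError(
                f"out-of-order change log: entry dated {when} precedes "
                f"last processed date {last}"
            )
        _process_entry(ledger, entry, masters, rules, config)
        last = max(last, when) if last else when
    return ledger


def _attach_proposal(ledger: GovernanceLedger, prop: Proposal) -> None:
    item = ledger.items.get(prop.key)
    if item is None:
        raise LedgerError(f"accepted proposal for unknown key {prop.key}")
    # Attach only while the item still awaits standardization; a proposal
    # re-fed after adoption (or after an independent correct registration)
    # is stale and ignored, which keeps replays of identical inputs no-ops.
    if not item.closed and item.current_status is MappingStatus.PROPOSED:
        item.active_proposal = prop


def _process_entry(
    ledger: GovernanceLedger,
    entry: ChangeLogEntry,
    masters: Mapping[CodeSystemId, StandardMaster],
    rules: Mapping[CodeSystemId, ScopeRules],
    config: ClassifierConfig,
) -> None:
    when = entry.extraction_date
    item = ledger.items.get(entry.key)

    if entry.change_type is ChangeType.DELETED:
        if item is not None and not item.closed:
            item.closed = True
            item.active_proposal = None
            item.processed_dates.append(when)
        return

    record = entry.after
    assert record is not None
    master = masters.get(record.system)
    if master is None:
        raise LedgerError(f"no master for system {record.system.value}")
    system_rules = rules.get(record.system, ScopeRules(record.system))

    # Adoption check: the institution registered exactly the proposed code.
    if (
        item is not None
        and not item.closed
        and item.active_proposal is not None
        and record.standard_code
        and record.standard_code == item.active_proposal.proposed_code
    ):
        status, reason = (
            MappingStatus.CORRECT_AFTER_REVISION,
            f"adopted proposed code {record.standard_code}",
        )
        item.active_proposal = None
    else:
        status, reason = classify_entry(entry, master, system_rules, config)

    if item is None:
        ledger.items[entry.key] = LedgerItem(
            institution_id=entry.institution_id,
            system=entry.system,
            local_code=entry.local_code,
            current_status=status,
            status_history=[(when, status)],
            current_record=record,
            processed_dates=[when],
        )
        return
    if item.closed:  # re-registration after deletion reopens the item
        item.closed = False
    item.current_status = status
    item.status_history.append((when, status))
    item.current_record = record
    item.processed_dates.append(when)
    if status is not MappingStatus.PROPOSED and status is not MappingStatus.CORRECT_AFTER_REVISION:
        # a fresh independent registration supersedes any open proposal
        item.active_proposal = None


def pending_proposal_items(ledger: GovernanceLedger) -> list[LedgerItem]:
    """Open PROPOSED items with no active proposal — the expert work queue."""
    return sorted(
        (
            item
            for item in ledger.open_items()
            if item.current_status is MappingStatus.PROPOSED
            and item.active_proposal is None
        ),
        key=lambda item: item.key,
    )


# ---------------------------------------------------------------------------
# Ledger / proposal JSON Lines I/O


def read_ledger(path: Union[str, Path]) -> GovernanceLedger:
    ledger = GovernanceLedger()
    path = Path(path)
    if not path.exists():
        return ledger
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                item = LedgerItem.from_dict(json.loads(line))
                ledger.items[item.key] = item
    return ledger


def write_ledger(ledger: GovernanceLedger, path: Union[str, Path]) -> None:
    """Serialize the ledger deterministically (items sorted by key)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for key in sorted(ledger.items):
            fh.write(json.dumps(ledger.items[key].to_dict(), ensure_ascii=False) + "\n")


def write_proposals(proposals: Iterable[Proposal], path: Union[str, Path]) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for prop in sorted(proposals, key=lambda p: p.key):
            fh.write(json.dumps(prop.to_dict(), ensure_ascii=False) + "\n")


def read_proposals(path: Union[str, Path]) -> list[Proposal]:
    out = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(Proposal.from_dict(json.loads(line)))
    return out


def export_sssom_stub(ledger: GovernanceLedger, path: Union[str, Path]) -> None:
    """Placeholder for a future SSSOM mapping-set export.

    Writes a short note; the SSSOM TSV format itself is intentionally not
    implemented here.
    """
    Path(path).write_text(
        "# SSSOM export not implemented; ledger holds "
        f"{len(ledger.items)} mappings.\n",
        encoding="utf-8",
    )
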