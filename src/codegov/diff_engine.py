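"""Snapshot diffing: the code-difference extraction step.

An institution's mapping table converts its local codes to standard codes.
Each delivered version of that table is a :class:`MappingSnapshot`; the diff
engine compares consecutive snapshots and emits a change log of ADDED /
MODIFIED / DELETED rows, keyed by ``(system, local_code)``. Only the
substantive fields — local name, standard code, standard name — are
compared; the per-row ``updated_date`` bookkeeping column is carried through
but never triggers a MODIFIED entry (institution clock noise must not
create spurious differences).

Change logs apply cleanly back onto the older snapshot
(:func:`apply_changelog`), which makes the diff verifiable by round trip.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .code_systems import CodeSystemId

#: Fields compared when deciding whether a record changed.
COMPARED_FIELDS = ("local_name", "standard_code", "standard_name")

SNAPSHOT_HEADER = [
    "institution_id", "system", "local_code", "local_name",
    "standard_code", "standard_name", "updated_date",
]


@dataclass(frozen=True)
class MappingRecord:
    """One local-code row of an institution's mapping table."""

    institution_id: str
    system: CodeSystemId
    local_code: str
    local_name: str
    standard_code: Optional[str] = None
    standard_name: Optional[str] = None
    updated_date: Optional[date] = None

    def __post_init__(self) -> None:
        if not self.institution_id or not self.local_code:
            raise ValueError("institution_id and local_code must be non-empty")
        if self.standard_name and not self.standard_code:
            raise ValueError("standard_name requires standard_code")

    @property
    def key(self) -> tuple[str, str]:
        return (self.system.value, self.local_code)

    def to_dict(self) -> dict:
        return {
            "institution_id": self.institution_id,
            "system": self.system.value,
            "local_code": self.local_code,
            "local_name": self.local_name,
            "standard_code": self.standard_code,
            "standard_name": self.standard_name,
            "updated_date": self.updated_date.isoformat() if self.updated_date else None,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MappingRecord":
        return cls(
            institution_id=data["institution_id"],
            system=CodeSystemId(data["system"]),
            local_code=data["local_code"],
            local_name=data["local_name"],
            standard_code=data.get("standard_code") or None,
            standard_name=data.get("standard_name") or None,
            updated_date=date.fromisoformat(data["updated_date"])
            if data.get("updated_date")
            else None,
        )


class SnapshotError(ValueError):
    pass


@dataclass
class MappingSnapshot:
    """A dated version of one institution's full mapping table.

    Records are keyed by ``(system, local_code)``; the constructor rejects
    duplicate keys and records belonging to another institution.
    """

    institution_id: str
    snapshot_date: date
    records: dict[tuple[str, str], MappingRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.records, dict):
            items: Iterable[MappingRecord] = self.records.values()
        else:  # accept any iterable of records
            items = self.records
        indexed: dict[tuple[str, str], MappingRecord] = {}
        for rec in items:
            if rec.institution_id != self.institution_id:
                raise SnapshotError(
                    f"record {rec.key} belongs to {rec.institution_id!r}, "
                    f"snapshot is {self.institution_id!r}"
                )
            if rec.key in indexed:
                raise SnapshotError(f"duplicate key {rec.key} in snapshot")
            indexed[rec.key] = rec
        self.records = indexed

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        """Record-set equality on the substantive fields.

        ``updated_date`` is bookkeeping and not a compared field, so two
        snapshots differing only in row timestamps are equal — consistent
        with the diff, which never emits an entry for such rows.
        """
        if not isinstance(other, MappingSnapshot):
            return NotImplemented
        if self.institution_id != other.institution_id:
            return False
        if self.records.keys() != other.records.keys():
            return False
        for key, mine in self.records.items():
            theirs = other.records[key]
            if any(
                getattr(mine, f) != getattr(theirs, f) for f in COMPARED_FIELDS
            ):
                return False
        return True


class ChangeType(str, Enum):
    ADDED = "ADDED"
    MODIFIED = "MODIFIED"
    DELETED = "DELETED"


@dataclass(frozen=True)
class ChangeLogEntry:
    """One difference between two consecutive snapshots."""

    change_type: ChangeType
    institution_id: str
    system: CodeSystemId
    local_code: str
    before: Optional[MappingRecord]
    after: Optional[MappingRecord]
    changed_fields: tuple[str, ...]
    extraction_date: date

    def __post_init__(self) -> None:
        ct = self.change_type
        if ct is ChangeType.ADDED and not (self.before is None and self.after):
            raise ValueError("ADDED requires before=None and after present")
        if ct is ChangeType.DELETED and not (self.before and self.after is None):
            raise ValueError("DELETED requires before present and after=None")
        if ct is ChangeType.MODIFIED:
            if self.before is None or self.after is None or not self.changed_fields:
                raise ValueError("MODIFIED requires both records and changed_fields")
        if not set(self.changed_fields) <= set(COMPARED_FIELDS):
            raise ValueError(f"changed_fields must be within {COMPARED_FIELDS}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.institution_id, self.system.value, self.local_code)

    def to_dict(self) -> dict:
        return {
            "change_type": self.change_type.value,
            "institution_id": self.institution_id,
            "system": self.system.value,
            "local_code": self.local_code,
            "before": self.before.to_dict() if self.before else None,
            "after": self.after.to_dict() if self.after else None,
            "changed_fields": list(self.changed_fields),
            "extraction_date": self.extraction_date.isoformat(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ChangeLogEntry":
        return cls(
            change_type=ChangeType(data["change_type"]),
            institution_id=data["institution_id"],
            system=CodeSystemId(data["system"]),
            local_code=data["local_code"],
            before=MappingRecord.from_dict(data["before"]) if data.get("before") else None,
            after=MappingRecord.from_dict(data["after"]) if data.get("after") else None,
            changed_fields=tuple(data.get("changed_fields", ())),
            extraction_date=date.fromisoformat(data["extraction_date"]),
        )


def diff_snapshots(
    prev: MappingSnapshot, curr: MappingSnapshot
) -> list[ChangeLogEntry]:
    """Compare two snapshots of the same institution's mapping table.

    Emits one entry per key added, deleted, or modified on any compared
    field, sorted by ``(system, local_code)`` so repeated runs are byte
    identical. Entries are stamped with the later snapshot's date.
    """
    if prev.institution_id != curr.institution_id:
        raise SnapshotError(
            f"institution mismatch: {prev.institution_id!r} vs {curr.institution_id!r}"
        )
    if prev.snapshot_date > curr.snapshot_date:
        raise SnapshotError("prev snapshot is newer than curr")
    entries: list[ChangeLogEntry] = []
    for key in sorted(prev.records.keys() | curr.records.keys()):
        before = prev.records.get(key)
        after = curr.records.get(key)
        if before is None and after is not None:
            entries.append(_entry(ChangeType.ADDED, None, after, (), curr.snapshot_date))
        elif before is not None and after is None:
            entries.append(_entry(ChangeType.DELETED, before, None, (), curr.snapshot_date))
        else:
            assert before is not None and after is not None
            changed = tuple(
                f for f in COMPARED_FIELDS
                if getattr(before, f) != getattr(after, f)
            )
            if changed:
                entries.append(
                    _entry(ChangeType.MODIFIED, before, after, changed, curr.snapshot_date)
                )
    return entries


def _entry(ct, before, after, changed, stamp) -> ChangeLogEntry:
    rec = after if after is not None else before
    return ChangeLogEntry(
        change_type=ct,
        institution_id=rec.institution_id,
        system=rec.system,
        local_code=rec.local_code,
        before=before,
        after=after,
        changed_fields=changed,
        extraction_date=stamp,
    )


def apply_changelog(
    prev: MappingSnapshot, entries: Sequence[ChangeLogEntry]
) -> MappingSnapshot:
    """Replay a change log onto the snapshot it was diffed from.

    ``apply_changelog(prev, diff_snapshots(prev, curr)) == curr`` — the diff
    is lossless on the compared fields.
    """
    records = dict(prev.records)
    stamp = prev.snapshot_date
    for entry in entries:
        key = (entry.system.value, entry.local_code)
        stamp = max(stamp, entry.extraction_date)
        if entry.change_type is ChangeType.ADDED:
            if key in records:
                raise SnapshotError(f"ADDED entry for existing key {key}")
            records[key] = entry.after
        elif entry.change_type is ChangeType.DELETED:
            if key not in records:
                raise SnapshotError(f"DELETED entry for missing key {key}")
            del records[key]
        else:
            if key not in records:
                raise SnapshotError(f"MODIFIED entry for missing key {key}")
            records[key] = entry.after
    return MappingSnapshot(prev.institution_id, stamp, records)


def batch_extract(
    snapshot_series: Sequence[MappingSnapshot],
) -> list[ChangeLogEntry]:
    """Diff every consecutive pair in a date-ordered snapshot series.

    The batch equivalent of the daily comparison run: with fewer than two
    snapshots there is nothing to compare and the output is empty.
    """
    if not snapshot_series:
        return []
    inst = snapshot_series[0].institution_id
    for a, b in zip(snapshot_series, snapshot_series[1:]):
        if b.institution_id != inst:
            raise SnapshotError("snapshot series mixes institutions")
        if a.snapshot_date > b.snapshot_date:
            raise SnapshotError("snapshot series is not date-ordered")
    out: list[ChangeLogEntry] = []
    for a, b in zip(snapshot_series, snapshot_series[1:]):
        out.extend(diff_snapshots(a, b))
    return out


# ---------------------------------------------------------------------------
# File formats: snapshots as CSV, change logs as JSON Lines.

def read_snapshot(path: Union[str, Path]) -> MappingSnapshot:
    """Read a snapshot CSV (empty string = absent standard code).

    The snapshot date is taken as the maximum ``updated_date`` in the file;
    rows without one are permitted.
    """
    path = Path(path)
    records: list[MappingRecord] = []
    with path.open(newline="", encoding="utf-8-sig") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != SNAPSHOT_HEADER:
            raise SnapshotError(f"{path}: expected header {','.join(SNAPSHOT_HEADER)}")
        for i, row in enumerate(reader, start=2):
            try:
                records.append(
                    MappingRecord(
                        institution_id=row["institution_id"],
                        system=CodeSystemId(row["system"]),
                        local_code=row["local_code"],
                        local_name=row["local_name"],
                        standard_code=row["standard_code"] or None,
                        standard_name=row["standard_name"] or None,
                        updated_date=date.fromisoformat(row["updated_date"])
                        if row["updated_date"]
                        else None,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise SnapshotError(f"{path}:{i}: {exc}") from exc
    if not records:
        raise SnapshotError(f"{path}: empty snapshot")
    snap_date = max(
        (r.updated_date for r in records if r.updated_date), default=date.min
    )
    return MappingSnapshot(records[0].institution_id, snap_date, records)


def write_snapshot(snapshot: MappingSnapshot, path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(SNAPSHOT_HEADER)
        for key in sorted(snapshot.records):
            r = snapshot.records[key]
            writer.writerow([
                r.institution_id, r.system.value, r.local_code, r.local_name,
                r.standard_code or "", r.standard_name or "",
                r.updated_date.isoformat() if r.updated_date else "",
            ])


def read_changelog(path: Union[str, Path]) -> list[ChangeLogEntry]:
    entries = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                entries.append(ChangeLogEntry.from_dict(json.loads(line)))
    return entries


def write_changelog(
    entries: Iterable[ChangeLogEntry], path: Union[str, Path]
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for entry in entries:
            fh.write(json.dumps(entry.to_dict(), ensure_ascii=False) + "\n")
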