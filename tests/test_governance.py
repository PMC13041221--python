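"""Classification decision table, candidate ranking, and ledger dynamics."""

from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codegov import (
    ChangeType,
    ClassifierConfig,
    CodeSystemId,
    GovernanceLedger,
    MappingStatus,
    Proposal,
    ScopeRule,
    ScopeRules,
    classify_entry,
    diff_snapshots,
    normalize_name,
    suggest_candidates,
    update_ledger,
)
from codegov.diff_engine import ChangeLogEntry
from codegov.governance import (
    DEFAULT_SCOPE_RULES,
    LedgerError,
    pending_proposal_items,
)

from .conftest import ALBUMIN_SERUM, ALBUMIN_URINE, GLUCOSE, make_record

D0, D1, D2 = date(2020, 7, 6), date(2020, 8, 6), date(2020, 9, 6)
LAB_RULES = ScopeRules(
    CodeSystemId.LAB_JLAC10,
    (ScopeRule("inhouse", r"\bin-?house\b"),),
)


def added_entry(record, when=D0):
    return ChangeLogEntry(
        change_type=ChangeType.ADDED,
        institution_id=record.institution_id,
        system=record.system,
        local_code=record.local_code,
        before=None,
        after=record,
        changed_fields=(),
        extraction_date=when,
    )


def modified_entry(before, after, when):
    (entry,) = diff_snapshots(
        _snap([before], D0), _snap([after], when)
    )
    return entry


def _snap(records, when):
    from codegov import MappingSnapshot

    return MappingSnapshot(records[0].institution_id, when, records)


class TestNormalizeName:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Albumin ", "albumin"),
            ("ＡＬＢ", "alb"),
            ("  total   protein ", "total protein"),
            ("", ""),
        ],
    )
    def test_examples(self, raw, expected):
        assert normalize_name(raw) == expected

    @given(st.text(max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_idempotent(self, text):
        once = normalize_name(text)
        assert normalize_name(once) == once


class TestDecisionTable:
    """Every cell of the classification flow produces the documented status."""

    def cell(self, lab_master, *, code, name):
        rec = make_record("L001", name, code, None if code is None else "x" * 0 or None)
        # standard_name irrelevant to classification; keep record minimal
        rec = make_record("L001", name, code)
        return classify_entry(added_entry(rec), lab_master, LAB_RULES)

    def test_code_in_master_name_consistent(self, lab_master):
        status, _ = self.cell(lab_master, code=ALBUMIN_SERUM, name="Albumin Serum")
        assert status is MappingStatus.CORRECT_INITIALLY

    def test_code_in_master_name_inconsistent(self, lab_master):
        status, reason = self.cell(lab_master, code=ALBUMIN_SERUM, name="albumin urine")
        assert status is MappingStatus.PROPOSED
        assert "inconsistent" in reason

    def test_code_valid_syntax_but_absent_from_master(self, lab_master):
        status, reason = self.cell(lab_master, code="9" * 17, name="albumin serum")
        assert status is MappingStatus.PROPOSED
        assert "not in master" in reason

    def test_code_malformed_treated_as_invalid(self, lab_master):
        status, reason = self.cell(lab_master, code="123", name="albumin serum")
        assert status is MappingStatus.PROPOSED
        assert "malformed" in reason

    def test_no_code_in_scope(self, lab_master):
        status, _ = self.cell(lab_master, code=None, name="albumin serum")
        assert status is MappingStatus.PROPOSED

    def test_no_code_matching_exclusion_rule(self, lab_master):
        status, reason = self.cell(lab_master, code=None, name="in-house assay 7")
        assert status is MappingStatus.OUT_OF_SCOPE
        assert "inhouse" in reason

    def test_code_present_shortcuts_scope_rules(self, lab_master):
        # scope exclusion applies only when no standard code is registered
        status, _ = self.cell(lab_master, code=ALBUMIN_SERUM, name="in-house assay")
        assert status is MappingStatus.PROPOSED

    def test_kampo_drug_out_of_scope(self, drug_master):
        rec = make_record(
            "D001", "kampo formulation 3", system=CodeSystemId.DRUG_HOT
        )
        status, _ = classify_entry(
            added_entry(rec), drug_master, DEFAULT_SCOPE_RULES[CodeSystemId.DRUG_HOT]
        )
        assert status is MappingStatus.OUT_OF_SCOPE

    def test_deleted_entries_are_not_classified(self, lab_master):
        rec = make_record("L001", "albumin")
        entry = ChangeLogEntry(
            ChangeType.DELETED, rec.institution_id, rec.system, rec.local_code,
            rec, None, (), D0,
        )
        with pytest.raises(ValueError):
            classify_entry(entry, lab_master, LAB_RULES)

    def test_system_mismatch_is_an_error(self, drug_master):
        rec = make_record("L001", "albumin", system=CodeSystemId.LAB_JLAC10)
        with pytest.raises(ValueError):
            classify_entry(added_entry(rec), drug_master, LAB_RULES)


def test_similarity_threshold_relaxes_name_match(lab_master):
    rec = make_record("L001", "albumin serum level", ALBUMIN_SERUM)
    strict, _ = classify_entry(added_entry(rec), lab_master, LAB_RULES)
    relaxed, _ = classify_entry(
        added_entry(rec), lab_master, LAB_RULES, ClassifierConfig(0.8)
    )
    assert strict is MappingStatus.PROPOSED
    assert relaxed is MappingStatus.CORRECT_INITIALLY


class TestSuggestCandidates:
    def test_exact_match_ranked_first_with_score_one(self, lab_master):
        rec = make_record("L001", "Albumin Serum")
        ranked = suggest_candidates(rec, lab_master, 3)
        assert ranked[0].proposed_code == ALBUMIN_SERUM
        assert ranked[0].match_score == 1.0

    def test_root_sharing_entries_precede_unrelated(self, lab_master):
        rec = make_record("L001", "albumin")
        ranked = suggest_candidates(rec, lab_master, 3)
        assert {ranked[0].proposed_code, ranked[1].proposed_code} == {
            ALBUMIN_SERUM, ALBUMIN_URINE,
        }
        assert ranked[2].proposed_code == GLUCOSE

    def test_ties_broken_by_ascending_code(self, lab_master):
        rec = make_record("L001", "albumin")
        ranked = suggest_candidates(rec, lab_master, 2)
        # serum/urine score identically against bare "albumin"
        assert ranked[0].match_score == ranked[1].match_score
        assert ranked[0].proposed_code < ranked[1].proposed_code

    def test_empty_master_and_bad_k(self, lab_master):
        from codegov import StandardMaster

        empty = StandardMaster(CodeSystemId.LAB_JLAC10, {})
        assert suggest_candidates(make_record("L", "x"), empty, 3) == []
        with pytest.raises(ValueError):
            suggest_candidates(make_record("L", "x"), lab_master, 0)

    def test_score_floor_filters_weak_candidates(self, lab_master):
        rec = make_record("L001", "zzzzzz")
        assert suggest_candidates(rec, lab_master, 3, score_floor=0.9) == []


class TestLedger:
    def masters(self, lab_master):
        return {CodeSystemId.LAB_JLAC10: lab_master}

    def rules(self):
        return {CodeSystemId.LAB_JLAC10: LAB_RULES}

    def test_adoption_of_proposed_code_becomes_correct_after_revision(self, lab_master):
        ledger = GovernanceLedger()
        wrong = make_record("L001", "albumin serum", GLUCOSE, updated=D0)
        update_ledger(ledger, [added_entry(wrong, D0)], self.masters(lab_master), self.rules())
        key = ("INST01", "LAB_JLAC10", "L001")
        assert ledger.items[key].current_status is MappingStatus.PROPOSED

        prop = Proposal("INST01", CodeSystemId.LAB_JLAC10, "L001",
                        ALBUMIN_SERUM, "albumin serum", D0, 1.0)
        fixed = make_record("L001", "albumin serum", ALBUMIN_SERUM, "albumin serum", updated=D1)
        update_ledger(
            ledger, [modified_entry(wrong, fixed, D1)],
            self.masters(lab_master), self.rules(), [prop],
        )
        item = ledger.items[key]
        assert item.current_status is MappingStatus.CORRECT_AFTER_REVISION
        assert item.active_proposal is None
        # CORRECT_AFTER_REVISION only ever follows a PROPOSED state
        statuses = [s for _, s in item.status_history]
        assert statuses.index(MappingStatus.PROPOSED) < statuses.index(
            MappingStatus.CORRECT_AFTER_REVISION
        )

    def test_registration_of_different_code_reclassified_from_scratch(self, lab_master):
        ledger = GovernanceLedger()
        wrong = make_record("L001", "glucose serum", None, updated=D0)
        update_ledger(ledger, [added_entry(wrong, D0)], self.masters(lab_master), self.rules())
        prop = Proposal("INST01", CodeSystemId.LAB_JLAC10, "L001",
                        ALBUMIN_SERUM, "albumin serum", D0, 1.0)
        # institution registers GLUCOSE instead of the proposed albumin code
        fixed = make_record("L001", "glucose serum", GLUCOSE, "glucose serum", updated=D1)
        update_ledger(
            ledger, [modified_entry(wrong, fixed, D1)],
            self.masters(lab_master), self.rules(), [prop],
        )
        item = ledger.items[("INST01", "LAB_JLAC10", "L001")]
        assert item.current_status is MappingStatus.CORRECT_INITIALLY

    def test_deleted_closes_item(self, lab_master):
        ledger = GovernanceLedger()
        rec = make_record("L001", "albumin serum", ALBUMIN_SERUM, updated=D0)
        update_ledger(ledger, [added_entry(rec, D0)], self.masters(lab_master), self.rules())
        entry = ChangeLogEntry(
            ChangeType.DELETED, "INST01", CodeSystemId.LAB_JLAC10, "L001",
            rec, None, (), D1,
        )
        update_ledger(ledger, [entry], self.masters(lab_master), self.rules())
        item = ledger.items[("INST01", "LAB_JLAC10", "L001")]
        assert item.closed
        assert list(ledger.open_items()) == []

    def test_update_is_idempotent(self, lab_master):
        import copy

        ledger = GovernanceLedger()
        entries = [added_entry(make_record("L001", "albumin serum", ALBUMIN_SERUM, updated=D0), D0)]
        update_ledger(ledger, entries, self.masters(lab_master), self.rules())
        before = copy.deepcopy(ledger)
        update_ledger(ledger, entries, self.masters(lab_master), self.rules())
        assert ledger.items == before.items

    def test_out_of_order_entries_rejected(self, lab_master):
        ledger = GovernanceLedger()
        update_ledger(
            ledger,
            [added_entry(make_record("L001", "albumin serum", ALBUMIN_SERUM, updated=D1), D1)],
            self.masters(lab_master), self.rules(),
        )
        stale = added_entry(make_record("L002", "glucose serum", GLUCOSE, updated=D0), D0)
        with pytest.raises(LedgerError):
            update_ledger(ledger, [stale], self.masters(lab_master), self.rules())

    def test_empty_update_is_noop(self, lab_master):
        ledger = GovernanceLedger()
        update_ledger(ledger, [], self.masters(lab_master), self.rules())
        assert ledger.items == {}

    def test_pending_queue_lists_proposed_items_without_proposal(self, lab_master):
        ledger = GovernanceLedger()
        update_ledger(
            ledger,
            [
                added_entry(make_record("L001", "albumin serum", ALBUMIN_SERUM, updated=D0), D0),
                added_entry(make_record("L002", "albumin urine", updated=D0), D0),
            ],
            self.masters(lab_master), self.rules(),
        )
        queue = pending_proposal_items(ledger)
        assert [item.local_code for item in queue] == ["L002"]


def test_ledger_jsonl_roundtrip(tmp_path, lab_master):
    from codegov import read_ledger, write_ledger

    ledger = GovernanceLedger()
    update_ledger(
        ledger,
        [added_entry(make_record("L001", "albumin serum", ALBUMIN_SERUM, updated=D0), D0)],
        {CodeSystemId.LAB_JLAC10: lab_master},
        {CodeSystemId.LAB_JLAC10: LAB_RULES},
    )
    path = tmp_path / "ledger.jsonl"
    write_ledger(ledger, path)
    assert read_ledger(path).items == ledger.items
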