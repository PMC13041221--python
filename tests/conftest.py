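from datetime import date

import pytest

from codegov import (
    CodeSystemId,
    MappingRecord,
    MappingSnapshot,
    StandardMaster,
)

ALBUMIN_SERUM = "3A015000002327101"
ALBUMIN_URINE = "3A015000001227101"  # same analyte, different specimen
GLUCOSE = "3D010000002327101"


@pytest.fixture
def lab_master() -> StandardMaster:
    return StandardMaster(
        CodeSystemId.LAB_JLAC10,
        {
            ALBUMIN_SERUM: "albumin serum",
            ALBUMIN_URINE: "albumin urine",
            GLUCOSE: "glucose serum",
        },
        version_date=date(2020, 7, 1),
    )


@pytest.fixture
def drug_master() -> StandardMaster:
    return StandardMaster(
        CodeSystemId.DRUG_HOT,
        {
            "1234567890123": "amoxicillin tablet 250mg",
            "9876543210987": "metformin tablet 500mg",
        },
    )


def make_record(
    local_code: str,
    local_name: str,
    standard_code: str | None = None,
    standard_name: str | None = None,
    system: CodeSystemId = CodeSystemId.LAB_JLAC10,
    institution: str = "INST01",
    updated: date = date(2020, 7, 6),
) -> MappingRecord:
    return MappingRecord(
        institution_id=institution,
        system=system,
        local_code=local_code,
        local_name=local_name,
        standard_code=standard_code,
        standard_name=standard_name,
        updated_date=updated,
    )


def make_snapshot(records, when: date, institution: str = "INST01") -> MappingSnapshot:
    return MappingSnapshot(institution, when, list(records))
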