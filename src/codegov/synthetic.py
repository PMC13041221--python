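"""Synthetic multi-institution mapping tables with known ground truth.

No real institutional mapping tables or licensed code masters can be
shipped, so the generator fabricates the whole study setting: a standard
master per code system, and per-institution snapshot series in which each
new local item is drawn from a four-way categorical —

* registered with the correct standard code and a consistent name,
* registered with a wrong (but master-valid) standard code,
* registered with no standard code although a correct one exists,
* a genuinely out-of-scope item (name matches an exclusion category).

Items lacking a correct code ("wrong" and "missing") may later adopt the
governance proposal: each subsequent period, with a fixed per-period
probability, the institution re-registers the true code — producing the
MODIFIED entries that drive CORRECT_AFTER_REVISION transitions downstream.

Everything is reproducible from a single integer seed; institutions get
derived sub-seeds so their series are independent but stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .code_systems import CodeSystemId, StandardMaster
from .diff_engine import MappingRecord, MappingSnapshot
from .governance import MappingStatus

# Lexicon roots: clinically flavoured but deliberately generic terms.
_ROOTS = {
    CodeSystemId.DRUG_HOT: [
        "amoxicillin", "metformin", "atorvastatin", "amlodipine", "omeprazole",
        "levothyroxine", "losartan", "furosemide", "warfarin", "prednisolone",
        "insulin aspart", "salbutamol", "cefazolin", "vancomycin", "heparin",
        "acetaminophen", "ibuprofen", "clopidogrel", "digoxin", "allopurinol",
    ],
    CodeSystemId.LAB_JLAC10: [
        "albumin", "glucose", "creatinine", "hemoglobin", "sodium",
        "potassium", "total protein", "bilirubin", "alt", "ast",
        "c-reactive protein", "platelet count", "urea nitrogen", "calcium",
        "cholesterol", "triglyceride", "amylase", "ferritin", "tsh", "hba1c",
    ],
    CodeSystemId.DISEASE_ICD10: [
        "hypertension", "diabetes mellitus", "pneumonia", "gastritis",
        "asthma", "heart failure", "cerebral infarction", "anemia",
        "chronic kidney disease", "atrial fibrillation", "osteoporosis",
        "depression", "dermatitis", "appendicitis", "migraine",
        "hyperlipidemia", "hepatitis", "colitis", "bronchitis", "insomnia",
    ],
}

_QUALIFIERS = {
    CodeSystemId.DRUG_HOT: [
        "tablet 100mg", "tablet 250mg", "capsule 50mg", "injection 10ml",
        "syrup 5%", "ointment 2%", "tablet 500mg", "injection 2ml",
    ],
    CodeSystemId.LAB_JLAC10: [
        "serum", "urine", "plasma", "whole blood", "csf",
        "serum quantitative", "urine qualitative", "blood gas",
    ],
    CodeSystemId.DISEASE_ICD10: [
        "unspecified", "acute", "chronic", "recurrent", "mild",
        "severe", "with complication", "in remission",
    ],
}

# Out-of-scope name templates keyed to the default exclusion rules.
_OUT_OF_SCOPE_TEMPLATES = {
    CodeSystemId.DRUG_HOT: [
        "kampo formulation {i}", "in-hospital preparation {i}",
        "infusion device {i}",
    ],
    CodeSystemId.LAB_JLAC10: ["in-house assay {i}"],
    CodeSystemId.DISEASE_ICD10: ["modifier term {i}"],
}

_TRUE_STATUS_CATEGORIES = ("correct", "wrong", "missing", "out_of_scope")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the deployed setting: 18 cooperating institutions,
    three code systems, 18 monthly-ish periods, and an endpoint status mix
    in which roughly a third of items arrive correctly coded, most of the
    rest need standardization, and ~5% are out of scope. Proposal adoption
    is rare per period (registrations increased only modestly under
    monthly feedback).
    """

    n_institutions: int = 18
    systems: tuple[CodeSystemId, ...] = (
        CodeSystemId.DRUG_HOT,
        CodeSystemId.LAB_JLAC10,
        CodeSystemId.DISEASE_ICD10,
    )
    n_dates: int = 18
    new_codes_per_date: float = 25.0  # mean new records / institution / period
    p_correct_initial: float = 0.34
    p_wrong_code: float = 0.24
    p_missing_code: float = 0.37
    p_out_of_scope: float = 0.05
    p_adopt_proposal_per_period: float = 0.002
    name_noise: float = 0.0
    master_size: int = 400  # codes per synthetic standard master
    seed: int = 0
    start_date: date = date(2020, 7, 6)
    period_days: int = 30

    def __post_init__(self) -> None:
        probs = (
            self.p_correct_initial, self.p_wrong_code,
            self.p_missing_code, self.p_out_of_scope,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("status probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("status probabilities must sum to 1")
        for p in (self.p_adopt_proposal_per_period, self.name_noise):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_institutions < 1 or self.n_dates < 1:
            raise ValueError("n_institutions and n_dates must be positive")

    @property
    def simplex(self) -> tuple[float, float, float, float]:
        return (
            self.p_correct_initial, self.p_wrong_code,
            self.p_missing_code, self.p_out_of_scope,
        )

    def period_date(self, t: int) -> date:
        return self.start_date + timedelta(days=self.period_days * t)


@dataclass(frozen=True)
class TruthRecord:
    """Generation-time truth for one key."""

    institution_id: str
    system: CodeSystemId
    local_code: str
    true_status: MappingStatus  # status at generation (before any adoption)
    true_code: Optional[str]  # correct standard code, None if out of scope
    created_period: int
    adoption_period: Optional[int]  # period the proposal gets adopted, if any
    name_noised: bool = False

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.institution_id, self.system.value, self.local_code)

    @property
    def final_status(self) -> MappingStatus:
        """Expected end-of-study status under the governance pipeline."""
        if self.true_status is MappingStatus.PROPOSED and self.adoption_period is not None:
            return MappingStatus.CORRECT_AFTER_REVISION
        return self.true_status

    def to_dict(self) -> dict:
        return {
            "institution_id": self.institution_id,
            "system": self.system.value,
            "local_code": self.local_code,
            "true_status": self.true_status.value,
            "true_code": self.true_code,
            "created_period": self.created_period,
            "adoption_period": self.adoption_period,
            "name_noised": self.name_noised,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TruthRecord":
        return cls(
            institution_id=data["institution_id"],
            system=CodeSystemId(data["system"]),
            local_code=data["local_code"],
            true_status=MappingStatus(data["true_status"]),
            true_code=data.get("true_code"),
            created_period=data["created_period"],
            adoption_period=data.get("adoption_period"),
            name_noised=data.get("name_noised", False),
        )


@dataclass
class GroundTruth:
    records: dict[tuple[str, str, str], TruthRecord] = field(default_factory=dict)

    def add(self, rec: TruthRecord) -> None:
        if rec.key in self.records:
            raise ValueError(f"duplicate ground-truth key {rec.key}")
        self.records[rec.key] = rec

    def write_jsonl(self, path: Union[str, Path]) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for key in sorted(self.records):
                fh.write(json.dumps(self.records[key].to_dict()) + "\n")

    @classmethod
    def read_jsonl(cls, path: Union[str, Path]) -> "GroundTruth":
        truth = cls()
        with Path(path).open(encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    truth.add(TruthRecord.from_dict(json.loads(line)))
        return truth


@dataclass
class SimulationResult:
    config: SimulationConfig
    masters: dict[CodeSystemId, StandardMaster]
    snapshots: dict[str, list[MappingSnapshot]]  # per institution, incl. empty baseline
    ground_truth: GroundTruth


def _random_code(system: CodeSystemId, rng: np.random.Generator) -> str:
    if system is CodeSystemId.DRUG_HOT:
        return "".join(str(d) for d in rng.integers(0, 10, size=13))
    if system is CodeSystemId.LAB_JLAC10:
        return "".join(str(d) for d in rng.integers(0, 10, size=17))
    letter = chr(ord("A") + int(rng.integers(0, 26)))
    body = f"{int(rng.integers(0, 100)):02d}"
    if rng.random() < 0.6:
        return f"{letter}{body}.{int(rng.integers(0, 10))}"
    return f"{letter}{body}"


def generate_master(
    system: CodeSystemId, n_codes: int, seed: int
) -> StandardMaster:
    """Build a synthetic standard master: unique valid codes, distinct names.

    Names combine a clinical root with a qualifier (specimen, dose form,
    severity ...), so different codes often share a root — exactly the
    situation that makes name-based candidate ranking non-trivial.
    """
    if n_codes < 1:
        raise ValueError("n_codes must be >= 1")
    rng = np.random.default_rng(seed)
    roots, quals = _ROOTS[system], _QUALIFIERS[system]
    codes: dict[str, str] = {}
    names_used: set[str] = set()
    while len(codes) < n_codes:
        code = _random_code(system, rng)
        if code in codes:
            continue
        name = f"{rng.choice(roots)} {rng.choice(quals)}"
        if name in names_used:
            name = f"{name} v{len(codes)}"
        names_used.add(name)
        codes[code] = name
    return StandardMaster(system, codes, version_date=date(2020, 7, 1))


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate snapshot series for every institution, plus ground truth.

    Each institution's series starts with an empty baseline snapshot so the
    first real snapshot diffs to pure ADDED entries, as when the difference
    tool is first deployed.
    """
    root_rng = np.random.default_rng(config.seed)
    master_seeds = {s: int(root_rng.integers(0, 2**31)) for s in config.systems}
    masters = {
        s: generate_master(s, config.master_size, master_seeds[s])
        for s in config.systems
    }
    master_items = {s: sorted(masters[s].entries.items()) for s in config.systems}

    inst_seeds = [int(root_rng.integers(0, 2**31)) for _ in range(config.n_institutions)]
    snapshots: dict[str, list[MappingSnapshot]] = {}
    truth = GroundTruth()

    for idx in range(config.n_institutions):
        inst = f"INST{idx + 1:02d}"
        rng = np.random.default_rng(inst_seeds[idx])
        records: dict[tuple[str, str], MappingRecord] = {}
        # adoption schedule: period -> list of keys to flip to the true code
        pending_adoptions: dict[int, list[tuple[str, str]]] = {}
        true_codes: dict[tuple[str, str], tuple[str, str]] = {}  # key -> (code, name)
        counter = 0
        baseline = MappingSnapshot(
            inst, config.period_date(0) - timedelta(days=config.period_days), {}
        )
        series = [baseline]
        oos_counter = 0

        for t in range(config.n_dates):
            when = config.period_date(t)
            # apply scheduled adoptions of governance proposals
            for key in pending_adoptions.pop(t, []):
                rec = records[key]
                code, name = true_codes[key]
                records[key] = replace(
                    rec, standard_code=code, standard_name=name, updated_date=when
                )
            n_new = int(rng.poisson(config.new_codes_per_date))
            for _ in range(n_new):
                system = config.systems[int(rng.integers(0, len(config.systems)))]
                counter += 1
                local_code = f"L{counter:06d}"
                key = (system.value, local_code)
                category = _TRUE_STATUS_CATEGORIES[
                    int(rng.choice(4, p=config.simplex))
                ]
                entries = master_items[system]
                code, name = entries[int(rng.integers(0, len(entries)))]
                noised = False
                adoption: Optional[int] = None

                if category == "out_of_scope":
                    oos_counter += 1
                    template = _OUT_OF_SCOPE_TEMPLATES[system][
                        int(rng.integers(0, len(_OUT_OF_SCOPE_TEMPLATES[system])))
                    ]
                    rec = MappingRecord(
                        inst, system, local_code,
                        template.format(i=oos_counter), None, None, when,
                    )
                    status = MappingStatus.OUT_OF_SCOPE
                    truth_code = None
                else:
                    truth_code = code
                    local_name = name
                    if config.name_noise and rng.random() < config.name_noise:
                        local_name = f"{name} local"
                        noised = True
                    if category == "correct":
                        rec = MappingRecord(
                            inst, system, local_code, local_name, code, name, when
                        )
                        status = MappingStatus.CORRECT_INITIALLY
                    else:
                        if category == "wrong":
                            other = entries[int(rng.integers(0, len(entries)))]
                            while other[0] == code and len(entries) > 1:
                                other = entries[int(rng.integers(0, len(entries)))]
                            rec = MappingRecord(
                                inst, system, local_code, local_name,
                                other[0], other[1], when,
                            )
                        else:  # missing
                            rec = MappingRecord(
                                inst, system, local_code, local_name, None, None, when
                            )
                        status = MappingStatus.PROPOSED
                        # geometric waiting time until the proposal is adopted
                        if config.p_adopt_proposal_per_period > 0:
                            wait = int(rng.geometric(config.p_adopt_proposal_per_period))
                            if t + wait < config.n_dates:
                                adoption = t + wait
                                pending_adoptions.setdefault(adoption, []).append(key)
                                true_codes[key] = (code, name)

                records[key] = rec
                truth.add(
                    TruthRecord(
                        institution_id=inst,
                        system=system,
                        local_code=local_code,
                        true_status=status,
                        true_code=truth_code,
                        created_period=t,
                        adoption_period=adoption,
                        name_noised=noised,
                    )
                )
            series.append(MappingSnapshot(inst, when, dict(records)))
        snapshots[inst] = series

    return SimulationResult(config, masters, snapshots, truth)
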