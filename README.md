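# codegov

Governance tooling for local-to-standard medical code mappings in
multi-institutional clinical data networks.

Hospitals keep facility-specific ("local") codes for drugs, laboratory
tests, and diseases in their EMRs. Pooled analysis across a network
requires mapping those to shared standard code systems — HOT for drug
products, JLAC-10 for laboratory tests (17-position codes combining
analyte, identification, specimen, method, and result identification),
and ICD-10 for diseases. The mapping tables drift constantly, and a
central governance team needs to see every change, judge it, and track
whether its corrections are adopted. `codegov` implements that loop:

* **diff engine** — compares consecutive mapping-table snapshots per
  institution and emits ADDED / MODIFIED / DELETED change logs that apply
  back losslessly;
* **classifier** — places each change into one of four statuses against
  the standard master: *correct initially*, *proposed standard code*,
  *correct after revision* (a proposal the institution later adopted),
  or *out of scope* (Kampo medicines, in-hospital preparations, devices,
  modifiers — recognised by configurable rules);
* **ledger** — accumulated per-code status history with active proposals
  and adoption transitions; idempotent under replay;
* **reporting** — cumulative per-date, per-system status counts and the
  registration rate `round(100 · assigned / total)` with half-up
  rounding;
* **synthetic** — a seeded multi-institution simulator with known ground
  truth, since real mapping tables and licensed masters cannot ship.

## Worked example

```python
from datetime import date
from codegov import *
from codegov.governance import DEFAULT_SCOPE_RULES

master = StandardMaster(CodeSystemId.LAB_JLAC10, {
    "3A015000002327101": "albumin serum",
    "3A015000001227101": "albumin urine",
})
prev = MappingSnapshot("INST01", date(2020, 7, 6), [])
curr = MappingSnapshot("INST01", date(2020, 8, 6), [
    MappingRecord("INST01", CodeSystemId.LAB_JLAC10, "L001", "Albumin Serum",
                  "3A015000002327101", "albumin serum", date(2020, 8, 6)),
    MappingRecord("INST01", CodeSystemId.LAB_JLAC10, "L002", "albumin serum",
                  "3A015000001227101", "albumin urine", date(2020, 8, 6)),
])
entries = diff_snapshots(prev, curr)
ledger = update_ledger(GovernanceLedger(), entries,
                       {CodeSystemId.LAB_JLAC10: master}, DEFAULT_SCOPE_RULES)
for key, item in sorted(ledger.items.items()):
    print(key[2], item.current_status.value)
counts = cumulative_counts(ledger, [date(2020, 9, 1)],
                           CodeSystemId.LAB_JLAC10).series[0][1]
print("rate:", registration_rate(counts), "%")
```

prints

```
L001 CORRECT_INITIALLY
L002 PROPOSED
rate: 50 %
```

`L001` carries the serum albumin code and a consistent name, so it is
correct as registered. `L002` is labelled "albumin serum" but coded as
*urine* albumin — same analyte, wrong specimen — so the classifier flags
it for a corrected proposal; one of the two codes is correctly assigned,
hence a 50% registration rate.

The same workflow is available from a shell:

```sh
codegov simulate --out-dir sim --seed 5 --institutions 2 --periods 3
codegov diff sim/INST01_t001.csv sim/INST01_t002.csv changes.jsonl
codegov govern changes.jsonl --masters sim/masters.csv \
        --ledger ledger.jsonl --proposals-out proposals.jsonl
codegov report ledger.jsonl --out-dir report --dates 2020-09-01 --plot
```

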