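# Methods

## The governance problem

Each hospital in a multi-institutional clinical data network maintains a
*mapping table* translating its EMR-local codes for drugs, laboratory
tests, and diseases into network-wide standard codes (HOT, JLAC-10 and
ICD-10 respectively). These tables drift: institutions add drugs,
reagents, and local test definitions continuously, and standard-code
fields are often left empty or filled incorrectly. `codegov` implements
the central governance loop around that drift:

1. **Diff** — consecutive versions of each institution's mapping table are
   compared; only the differences (added / modified / deleted rows) travel
   onward. The diff key is `(system, local_code)`; compared fields are
   local name, standard code, and standard name. The per-row
   `updated_date` is carried but never compared, so institution clock
   noise cannot fabricate changes. Diffs are lossless: applying a change
   log to the older snapshot reconstructs the newer one on the compared
   fields, which is verified by property test.
2. **Classify** — each added/modified row is placed into one of four
   statuses. With a standard code present: master validity is checked
   first, then name consistency → `CORRECT_INITIALLY` or `PROPOSED`. With
   no code: configurable exclusion rules decide `OUT_OF_SCOPE` versus
   `PROPOSED`. A syntactically malformed code is treated like a code the
   master does not contain (the flow has no separate malformed branch, and
   the remedial action is the same).
3. **Propose** — for `PROPOSED` items the package ranks master entries by
   normalized-name similarity (`difflib` ratio, ties broken by ascending
   code text). Ranking is decision support only; the *accepted* proposal
   is an input, standing in for expert review.
4. **Track adoption** — the ledger holds per-key status history and at
   most one active proposal. When a later entry registers exactly the
   proposed code, the status becomes `CORRECT_AFTER_REVISION` and the
   proposal closes. A *different* newly registered code is re-classified
   from scratch (the operational record does not prescribe this case;
   re-classification is the package's choice and treats the new
   registration as a fresh fact). Deletions close the item.
5. **Report** — cumulative per-date, per-system counts of the four
   buckets, plus the registration rate
   `round_half_up(100 · assigned / total)`, where
   `assigned = initial + after_revision`. The denominator is the counted
   total including any `unclassified` remainder (source tallies do not
   always decompose fully); a `collected_total` policy can instead divide
   by a recorded pre-narrowing total for code systems where most collected
   items were dropped before counting. Half-up rounding is implemented
   with `decimal` — banker's rounding would differ on exact halves.

## Code-syntax rules

* **JLAC-10**: 17 positions in five elements of widths 5/4/3/3/2
  (analyte, identification, specimen, method, result identification).
  All positions are digits except the analyte's second position, which may
  be an uppercase letter (e.g. albumin's analyte element `3A015`). Widths
  are config-overridable.
* **HOT**: all digits, length 13 by default; the 9-digit short form is
  accepted when configured.
* **ICD-10**: letter, two digits, then an optional dot-separated
  sub-classification of up to two alphanumerics (WHO pattern).

Code text is NFKC-normalized and trimmed before validation because
Japanese EMR exports mix full- and half-width characters. Name comparison
uses the same normalization plus whitespace collapse and case folding;
"consistent" means exact equality after normalization by default, with an
optional similarity threshold (suggested 0.9) for sites with noisier
naming conventions.

## Synthetic study design

No institutional mapping tables or licensed masters can be distributed,
so the `synthetic` module generates the whole setting: masters with valid
unique codes and root+qualifier names (shared roots make similarity
ranking non-trivial), and per-institution snapshot series in which each
new item is drawn from the four-way categorical
(correct / wrong code / missing code / out of scope). Wrong- and
missing-code items adopt the governance proposal in a later period with a
fixed per-period probability (geometric waiting time). Out-of-scope items
get names matching the default exclusion rules (Kampo formulations,
in-hospital preparations, devices; in-house assays; modifier terms).

Defaults mirror the deployed setting: 18 institutions, three code
systems, 18 periods of 30 days from 2020-07-06, ~25 new records per
institution per period, status simplex (0.34, 0.24, 0.37, 0.05) echoing
the drug endpoint decomposition, and a small per-period adoption
probability (0.002) reflecting the modest observed uptake under monthly
feedback. A single integer seed drives everything; institutions receive
derived sub-seeds so series are independent but reproducible, and
identical seeds yield byte-identical snapshot files.

What the generator does *not* emulate: real nomenclature, vendor export
dialects, per-institution staffing effects, calendar-accurate cadence
(daily extraction vs. weekly collection is collapsed into abstract
periods), and name noise beyond a simple suffix perturbation. Passing
recovery tests therefore demonstrates the pipeline's rule-exactness and
bookkeeping, not robustness to messy real-world naming.

## Verification strategy

With name noise disabled the classifier is rule-exact, so the pipeline
must recover every generated item's ground-truth status — the end-to-end
tests assert 100% agreement on ~10,000 keys across 3 institutions
(problem sizes chosen to keep the default suite fast while leaving
binomial sampling error on category fractions under a percentage point).
Adoption dynamics are stochastic: each PROPOSED item's adoption
probability is `1-(1-p)^r` with `r` periods remaining, and the pipeline's
`CORRECT_AFTER_REVISION` count is checked against the summed expectation
at a 1.96-pooled-σ bound over six independent replicate pipelines —
pooling adds sample size to stabilise a single-draw 95% test without
changing the bound.

The published endpoint statistics are arithmetic consequences of final
status tallies, so they are verified by feeding those tallies through the
reporting module: drugs 14,699 + 764 = 15,463 assigned of 43,387 → 36%;
labs 218 + 93 = 311 of the 1,091 in-scope codes → 29%; diseases 11,252 of
16,694 → 67%. The disease tally leaves a remainder of 3,001 codes that
the source decomposition does not account for; the report schema carries
this as an `unclassified` column included in the denominator rather than
guessing its composition.

## Numerical and design choices

* Determinism everywhere: sorted diff output, sorted ledger and proposal
  serialization, no timestamps in data files (manifests only) — re-runs
  are byte-identical, and `govern` re-fed identical change logs is a
  byte-level no-op via per-key processed-date bookkeeping.
* Out-of-order protection: entries older than the ledger's frontier are
  rejected unless they were already processed (then skipped silently).
* Scope rules, syntax options, and the name-match threshold live in YAML
  config, not code.
* Items with several events on one report date count once, by final
  same-day status.
* SSSOM mapping-set export is a stub noting the omission; the format is
  future work.

## Known limitations

* Name similarity is character-level (`difflib`); it has no clinical
  synonymy, so candidate ranking on real data would need a curated
  lexicon or embedding model behind the same interface.
* The ICD-10 pattern is the WHO form; the Japanese standard disease-name
  master edition may admit codes this validator rejects (configurable in
  principle, not shipped).
* Expert judgment is modelled as an input callback; nothing about the
  difficulty of choosing among multiple JLAC-10 candidates per local name
  is simulated.
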