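# Methods

## The problem and the approach

A write-enabled planning script is any executable permitted to modify
radiotherapy treatment-planning data. Its V&V testing reduces to a
before/after question: serialize the planning state into a *snapshot*
before execution, again after, and compare. plansnap implements the three
layers that make this rigorous — a closed, typed model of the planning
hierarchy; a canonical snapshot serialization; and an identifier-keyed
structural diff — plus the orchestration and self-validation around them.

## The planning model

The object inventory is fixed and explicit: patient (id, name), courses
(id, intent), external-beam plans (approval status, prescribed dose per
fraction in Gy, fraction count, optional structure-set reference), beams
(machine, energy label, monitor units, gantry/collimator/couch angles in
degrees [0, 360), technique, setup-field flag, optional MLC digest),
structure sets (image id) with structures (DICOM type, RGB color,
contours), and per-plan save-history and script-log audit entries
(ISO-8601 UTC timestamps). Commercial scripting APIs expose far more
fields; a closed inventory is what makes "every field is checked" a
testable statement. Extension goes through a schema-version bump.

Invariants: ids unique within their container; ids contain no `/`, `[`,
`]` or whitespace (enforced by sanitization on DICOM import); angles in
[0, 360); MU, dose, fractions non-negative; history timestamps
non-decreasing. `validate_model` re-checks all of them after every
mutation and store load.

**Model paths.** Objects and leaves are addressed as
`course[1xLung]/plan[F1LungR]/beam[G180]/monitor_units` — typed segments
keyed by id, with history/log entries keyed by index (they have no id;
their order *is* their identity).

**Data sources.** (a) DICOM-RT: each RTPLAN becomes a plan (beams from
`BeamSequence`, MU from the fraction group's beam metersets, dose per
fraction from `TargetPrescriptionDose`/fractions when present); each
RTSTRUCT a structure set. DICOM has no course object, so plans land in a
synthesized course `C1`. RTDOSE is tolerated and skipped. (b) The
directory store: one directory per patient holding a pretty-printed
`model.json` (format marker, store version, full hierarchy including
contours); writing is byte-deterministic, so an untouched store is
byte-identical across runs. This store is the mutation surface a
script-under-test edits, standing in for the planning database. (c) The
synthetic generator, below.

## Structure geometry

Detailed structure-set snapshots must react to any contour change without
carrying megabytes of coordinates. Each structure therefore surfaces three
derived fields: `volume_cc` (slab model: per-slice shoelace area x slice
thickness, mm³ → cm³; overlapping polygons add, holes are not modelled),
`point_count`, and `geometry_digest` — SHA-256 of the contours after
canonical rounding to 10⁻³ mm, with rings rotated to start at their
lexicographically smallest vertex, orientation chosen canonically, and
polygons sorted by (z, first point). The digest is invariant to polygon
order, cyclic vertex rotation and ring reversal, and flips for any
geometric change beyond the rounding quantum. Slice thickness is the
median z-spacing of a structure's contours (default 3.0 mm when a
structure has a single plane).

## Snapshots

Three subject kinds: `patient_summary` (patient id/name; per course:
intent and plan list with approval status; structure-set list with image
id), `plan_detailed` (every plan scalar, every beam scalar, full history
and script logs), `structure_set_detailed` (per structure: type, color
and the three derived geometry fields). Two representation rules keep the
diff semantics crisp:

* **Ids live in keys, not leaves.** A child is keyed `type[id]`; the
  snapshot root's own id lives in the snapshot's `subject_path` metadata.
  A rename therefore surfaces as exactly one key change, never as a key
  change *plus* a modified id field.
* **Canonical form.** Scalars are rendered once, canonically (shortest
  round-trip decimals; angles at 0.1°; booleans `true`/`false`; RGB as
  `r,g,b`), so scalar equality is string equality. Container children are
  stored sorted by key, with an `ordinal` attribute preserving the
  original model position for ordering-sensitive audits; `ordinal` is
  bookkeeping and never compared. Empty collections are omitted (the tree
  invariant is scalar ⇔ childless), so the first entry added to an empty
  collection reports as one added container.

Snapshots serialize to UTF-8 XML (one element per field node, key/kind as
attributes, scalar value as text), validated on read against the shipped
`snapshot.xsd`. Writing is byte-deterministic. The schema version is
gated on its major number: a newer major fails loudly rather than
coercing. `acquired_at` is wall-clock metadata, excluded from comparison
by construction (it is not a tree node).

## The diff

`match_children` pairs sibling sets by exact key, independent of order.
Leftovers of the same type are rename candidates, scored by *field
similarity* — the fraction of equal leaf values among the leaf paths the
two subtrees share — and greedily accepted in descending similarity
(threshold 0.5 by default; ties broken by original ordinal, then key).
Accepted pairs report one `renamed` difference and are then recursed
into; the rest are `removed`/`added`, where an added or removed subtree
counts as **one** difference at its container key. Difference paths are
*before-keyed*: beneath a renamed container, paths keep the old key, so
every reported path resolves in the before snapshot.

Numeric comparison defaults to exact canonical-string equality — a QA
tool must not silently absorb small changes. Per-field-class absolute
tolerances (`monitor_units=0.01`) and path-glob exclusions are opt-in.
Rename detection can be disabled, in which case renames report as
removed+added.

The greedy pairing is not a globally optimal assignment in adversarial
similarity matrices; for realistic instances — candidates derived from
distinct objects, similarities clustering near 1 for true pairs and near
0 otherwise — it coincides with the exhaustive optimum, which the test
suite checks by enumeration on small instances. Determinism was preferred
over optimality here: the same inputs must always produce the same
report.

Reports carry before/after snapshot references (subject, acquisition
time, source file), per-kind counts and a `clean` flag; they serialize to
XML against `report.xsd` and render to text grouped by subject, patient
summary first, then plans, then structure sets. For regression baselines
and cross-run comparison, `report_fingerprint` strips the run-varying
metadata (acquisition times, source paths) so that equivalent runs are
byte-comparable.

## The harness

A protocol file (documented plain-text block format, JSON equivalent, or
the `build_protocol` API) declares cases: store, subjects, script command
template and input payload. `run_case` copies the store (the clinical
database cannot be reverted; copies emulate reversion), snapshots,
writes the payload to a JSON input file, runs the script with
`{store}`/`{input}`/`{python}` substituted, snapshots again and compares
per subject. A renamed subject is re-located by the case's declared
post-run path, else by its pre-run path, else by unique type match.
Non-zero exit or timeout (default 300 s) → `script_failed` with
before-snapshots retained; a store the script corrupted → case `error`,
never a harness crash. `run_protocol` runs cases in order, isolated, and
writes an XML + text summary with per-case wall times. The
script-under-test contract is deliberately minimal — any executable
taking a store directory and an input file — so the same script body can
be exercised identically by the harness and by hand (execution-mode
equivalence is asserted byte-wise in the tests).

## Commissioning

The engine must earn trust before it judges scripts. `commission(seed,
n_models)` generates synthetic patients and (a) asserts no-change
comparisons clean — re-taken snapshots, XML round-trips and
sibling-permuted models, repeated to a configurable count; (b) mutates
every snapshot-visible leaf one at a time (invariant-preserving
perturbations: next enum value, +1.5 on reals, +5° mod 360 on angles,
seconds bump on timestamps, channel shift on colors) and requires a
difference at the exact mapped path; (c) renames every id-keyed object
and requires a `renamed` difference at its key. Sensitivity
(detected/injected) and false positives are written as XML; the gate is
sensitivity 1.0 with zero false positives. Derived geometry fields and
single-valued enums are excluded from (b): the former change only
through contours, the latter cannot legally change.

## Synthetic patients

The generator is seeded (stdlib `random.Random`, no global state; fixed
base dates, never wall clock) and deterministic per (seed, tier).
`minimal` is the smallest legal model: one course, one unapproved
single-beam plan, no structure sets. `typical` emulates a routine
clinical patient: 2–3 courses, plans cycling through all four approval
statuses so every patient mixes them, 2–4 beams per plan with clinical
value ranges (MU 40–350, energies 6X–15X, couch 0/90/270), 1–3 history
entries per plan, one structure set with 3–6 structures contoured as
regular polygons over 2–4 slices at 3 mm. `stress` scales to ≥5 courses
and ≥40 structures. What it does *not* emulate: realistic contour shapes
and inter-structure topology, dose distributions, machine-specific MLC
sequences, or the field breadth of a commercial database. Passing tests
therefore demonstrate the engine's detection logic, not coverage of any
vendor's full schema.

## Verification scales

The shipped battery uses sizes chosen to exercise every code path while
staying desk-runnable: commissioning over 5 typical patients (~900
injected mutations, ≥200 no-change comparisons), 500 random
model/mutation-set instances (≤50 leaves each) checked against an
independent flatten-and-reconstruct oracle, 100 sibling-permutation
trials, and ~800 serialization round-trips across the four formats.
Snapshot + compare of a typical patient takes ~2 ms per subject set on
one core, orders of magnitude inside the few-seconds-per-case envelope
interactive QA work requires.

## Known limitations

* No dose calculation or RTDOSE interpretation; no plan DICOM export.
* The similarity-based rename pairing can in principle mispair heavily
  and identically edited siblings renamed in the same run; the report is
  still *complete* (the oracle equivalence property holds — all leaf
  changes are accounted), only the renamed/modified labelling may shift.
* Contours are compared via digest only: the report says *that* geometry
  changed, not where.
* History entries are index-keyed; an insertion in the middle reports as
  a cascade of modifications plus one addition, which is faithful but
  verbose.
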