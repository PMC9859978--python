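# plansnap

Snapshot-based verification of **write-enabled treatment-planning scripts**.

Clinics increasingly automate radiotherapy planning with small user-written
scripts that *modify* data inside the treatment planning system (TPS):
renaming courses and plans to standard nomenclature, creating emergency
plans, adjusting parameters. Before such a script touches clinical data it
must go through verification & validation (V&V) testing — and the central
question of that testing is brutally simple: *what exactly did the script
change?* A physicist clicking through TPS windows to answer it takes
minutes per case and can miss fields; a tool that serializes the planning
state before and after execution and diffs the two answers it in
milliseconds, exhaustively, with a paper trail.

plansnap provides that tool, vendor-independently:

* **Model** — an in-memory hierarchy of planning objects (patient → courses
  → external-beam plans → beams, plus structure sets → contoured
  structures, with approval statuses, save history and script-log audit
  records), loadable from DICOM-RT files (RTPLAN/RTSTRUCT via pydicom),
  from a human-readable directory store, or from a built-in synthetic
  patient generator.
* **Snapshots** — versioned XML captures of one subject (patient summary,
  one plan in detail, one structure set in detail), with canonical scalar
  formatting and canonical child ordering, validated against a shipped XSD.
* **Id-keyed diff** — children are paired by their identifier, never by
  list position, so reordering is never a change and a deleted beam is one
  removed beam, not three modified ones. Leftover children are re-paired by
  field similarity so renames report as *renamed*, not removed+added.
* **Harness** — declarative test protocols (plain-text or built
  programmatically): snapshot → run the script as a subprocess on a private
  store copy → snapshot → compare → XML + text reports, one per subject,
  plus optional gold-standard comparison.
* **Commissioning** — the engine proves itself before you trust it: every
  snapshot-visible leaf of synthetic patients is mutated one at a time and
  must be detected at the correct path; hundreds of no-change comparisons
  must stay clean. The release gate is sensitivity 1.0 with zero false
  positives.

## Worked example

The packaged example reproduces a plan-labeling scenario: a QA patient has
a course `TEST_WESTE` holding one unapproved plan `Plan`; a renaming script
relabels them `1xLung` / `F1LungR` and stamps the plan's history and script
log.

```bash
plansnap example-rename --out example
plansnap run example/protocol.txt
```

prints

```
=== Patient summary: /
  renamed  courses/course[TEST_WESTE]: Id 'TEST_WESTE' -> '1xLung'
  renamed  courses/course[TEST_WESTE]/plans/plan[Plan]: Id 'Plan' -> 'F1LungR'
  [differences] added=0 removed=0 modified=0 renamed=2
=== Plan: course[TEST_WESTE]/plan[Plan] -> course[1xLung]/plan[F1LungR]
  added    history/entry[1]: <3 field(s)>
  added    script_logs: <3 field(s)>
  [differences] added=2 removed=0 modified=0 renamed=0
cases: 1 clean=0 differences=1 script_failed=0 error=0
```

and exits with code 1 (differences found). The four differences are exactly
the intended changes — the course rename, the plan rename, one new history
entry, one new script log — and nothing else, which is precisely the
reviewer's question answered. Reports are also written as XML under
`example/out/` for permanent documentation and regression baselines.

Other entry points: `plansnap synth` (emit a synthetic patient store),
`plansnap snapshot` (capture one subject or `--all`), `plansnap compare`
(two snapshot files offline), `plansnap commission` (the detection gate).

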