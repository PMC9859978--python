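"""Automated test-run orchestration and commissioning.

The automated flow per case is: snapshot the declared subjects (before),
write the case's input payload to a fresh JSON file, execute the
script-under-test as a subprocess with ``{store}``/``{input}`` placeholders
substituted, snapshot again (after), and compare pairwise — one report per
subject, written as XML with a combined text rendering. Every case runs on
its own copy of the store, emulating the database reversion a clinical
system cannot offer. A non-zero exit or timeout marks the case
``script_failed`` with the before-snapshots retained.

Commissioning validates the *engine itself*: for synthetic patients it
asserts that no-change comparisons are clean (no false positives) and that
every single-leaf mutation and every Id rename is detected at the correct
path (sensitivity). The gate for release is sensitivity 1.0 with zero false
positives.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from lxml import etree

from .diff import (
    CompareOptions,
    ComparisonReport,
    compare,
    render_reports_text,
    write_report_xml,
)
from .errors import CaseError, CommissioningError, PathError, StoreError
from .model import (
    ApplicationScriptLog,
    Beam,
    Course,
    HistoryEntry,
    MutationSpec,
    PatientModel,
    PlanSetup,
    apply_mutation,
    generate_synthetic_patient,
    iter_keyed_objects,
    iter_leaves,
    load_model,
    permute_siblings,
    perturb_value,
    store_model,
)
from .model import _perturbable  # commissioning shares the leaf filter
from .snapshot import (
    Snapshot,
    default_subjects,
    read_snapshot_xml,
    take_snapshot,
    write_snapshot_xml,
)
from .protocol import DEFAULT_TIMEOUT, Subject, TestCase, TestProtocol

CASE_STATUSES = ("clean", "differences", "script_failed", "error")


@dataclass
class CaseResult:
    case_id: str
    status: str
    reports: List[ComparisonReport] = field(default_factory=list)
    report_dir: Optional[str] = None
    wall_time_s: float = 0.0
    message: str = ""

    @property
    def counts(self) -> Dict[str, int]:
        totals = {"added": 0, "removed": 0, "modified": 0, "renamed": 0}
        for r in self.reports:
            for k, v in r.counts.items():
                totals[k] += v
        return totals


@dataclass
class RunSummary:
    results: List[CaseResult] = field(default_factory=list)

    @property
    def totals(self) -> Dict[str, int]:
        t = {s: 0 for s in CASE_STATUSES}
        for r in self.results:
            t[r.status] += 1
        return t


# ---------------------------------------------------------------------------
# Case execution

def _subject_tag(subject: Subject) -> str:
    safe = subject.path.strip("/").replace("/", ".").replace("[", "_").replace("]", "")
    return f"{subject.kind}.{safe}" if safe else subject.kind


def _locate_after(model: PatientModel, subject: Subject) -> str:
    """Post-run subject path: declared post path, else the pre-run path, else
    a unique same-type match."""
    from .model import resolve

    if subject.post_path:
        return subject.post_path
    try:
        resolve(model, subject.path if subject.path != "/" else "")
        return subject.path
    except PathError:
        pass
    if subject.kind == "plan_detailed":
        plans = [
            f"course[{c.id}]/plan[{p.id}]" for c in model.courses for p in c.plans
        ]
        if len(plans) == 1:
            return plans[0]
    if subject.kind == "structure_set_detailed":
        sets = [f"structure_set[{s.id}]" for s in model.structure_sets]
        if len(sets) == 1:
            return sets[0]
    raise CaseError(
        f"subject {subject.kind} {subject.path!r} not found after script run "
        "and no unique match; declare an expected post-run path"
    )


def _substitute(argv: List[str], store: Path, input_file: Path) -> List[str]:
    # plain token replacement: script args may contain literal braces
    mapping = {
        "{store}": str(store),
        "{input}": str(input_file),
        "{python}": sys.executable,
    }
    out = []
    for arg in argv:
        for token, value in mapping.items():
            arg = arg.replace(token, value)
        out.append(arg)
    return out


def run_case(
    case: TestCase,
    options: Optional[CompareOptions] = None,
    output_dir="plansnap_out",
    timeout: float = DEFAULT_TIMEOUT,
) -> CaseResult:
    """Execute one test case on a private copy of its store."""
    options = options or CompareOptions()
    out_dir = Path(output_dir) / case.case_id
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()
    result = CaseResult(case_id=case.case_id, status="error", report_dir=str(out_dir))
    try:
        store_src = Path(case.store_dir)
        work = out_dir / "store"
        if work.exists():
            shutil.rmtree(work)
        try:
            shutil.copytree(store_src, work)
            model = load_model(work)
        except (OSError, StoreError) as e:
            raise CaseError(f"cannot stage store {store_src}: {e}") from e

        before: List[Tuple[Subject, Snapshot]] = []
        for subject in case.subjects:
            snap = take_snapshot(model, subject.kind, subject.path)
            write_snapshot_xml(snap, out_dir / f"before.{_subject_tag(subject)}.xml")
            before.append((subject, snap))

        if case.script_command:
            input_file = out_dir / "input.json"
            input_file.write_text(
                json.dumps(case.input_payload, indent=2, sort_keys=True) + "\n",
                encoding="utf-8",
            )
            argv = _substitute(case.script_command, work, input_file)
            try:
                proc = subprocess.run(
                    argv,
                    capture_output=True,
                    text=True,
                    timeout=timeout,
                )
            except subprocess.TimeoutExpired:
                result.status = "script_failed"
                result.message = f"script timed out after {timeout:g} s"
                return result
            except OSError as e:
                result.status = "script_failed"
                result.message = f"cannot execute script: {e}"
                return result
            (out_dir / "script.log").write_text(
                f"command: {argv}\nexit: {proc.returncode}\n--- stdout ---\n"
                f"{proc.stdout}\n--- stderr ---\n{proc.stderr}\n",
                encoding="utf-8",
            )
            if proc.returncode != 0:
                result.status = "script_failed"
                result.message = f"script exited with code {proc.returncode}"
                return result

        try:
            model_after = load_model(work)
        except StoreError as e:
            raise CaseError(f"store corrupted by script: {e}") from e

        for subject, before_snap in before:
            after_path = _locate_after(model_after, subject)
            after_snap = take_snapshot(model_after, subject.kind, after_path)
            tag = _subject_tag(subject)
            write_snapshot_xml(after_snap, out_dir / f"after.{tag}.xml")
            report = compare(
                before_snap,
                after_snap,
                options,
                before_source=f"before.{tag}.xml",
                after_source=f"after.{tag}.xml",
            )
            write_report_xml(report, out_dir / f"report.{tag}.xml")
            result.reports.append(report)
            gold_file = case.gold_standard_refs.get(subject.path)
            if gold_file:
                gold_snap = read_snapshot_xml(gold_file)
                gold_report = compare(
                    after_snap, gold_snap, options,
                    before_source=f"after.{tag}.xml", after_source=str(gold_file),
                )
                write_report_xml(gold_report, out_dir / f"gold.{tag}.xml")
                result.reports.append(gold_report)

        (out_dir / "case.txt").write_text(
            render_reports_text(result.reports), encoding="utf-8"
        )
        result.status = "clean" if all(r.clean for r in result.reports) else "differences"
    except CaseError as e:
        result.status = "error"
        result.message = str(e)
    finally:
        result.wall_time_s = time.monotonic() - t0
    return result


def run_protocol(protocol: TestProtocol, output_dir: Optional[str] = None) -> RunSummary:
    """Run every case in order, isolated; individual case errors never abort
    the run. Writes ``summary.xml`` and ``summary.txt`` to the output dir."""
    out = Path(output_dir or protocol.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = RunSummary()
    for case in protocol.cases:
        summary.results.append(
            run_case(case, protocol.options, out, timeout=protocol.timeout)
        )
    _write_summary(summary, out)
    return summary


def _write_summary(summary: RunSummary, out: Path) -> None:
    root = etree.Element("run_summary")
    for k, v in summary.totals.items():
        root.set(k, str(v))
    for r in summary.results:
        el = etree.SubElement(root, "case")
        el.set("id", r.case_id)
        el.set("status", r.status)
        el.set("wall_time_s", f"{r.wall_time_s:.3f}")
        if r.report_dir:
            el.set("report_dir", r.report_dir)
        if r.message:
            el.set("message", r.message)
        counts = etree.SubElement(el, "counts")
        for k, v in r.counts.items():
            counts.set(k, str(v))
    (out / "summary.xml").write_bytes(
        etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    )
    lines = []
    for r in summary.results:
        c = r.counts
        lines.append(
            f"{r.case_id}: {r.status} ({r.wall_time_s:.2f} s) "
            f"added={c['added']} removed={c['removed']} modified={c['modified']} "
            f"renamed={c['renamed']}"
            + (f" — {r.message}" if r.message else "")
        )
    t = summary.totals
    lines.append(
        f"total: {len(summary.results)} case(s) — clean={t['clean']} "
        f"differences={t['differences']} script_failed={t['script_failed']} "
        f"error={t['error']}"
    )
    (out / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Commissioning

# model-path leaf -> (subject kind, subject-path builder, snapshot diff path)
def _expected_locus(model: PatientModel, leaf_path: str) -> Tuple[str, str, str]:
    """Map a model leaf path to (subject_kind, subject_path, diff_path)."""
    segs = leaf_path.split("/")
    if len(segs) == 1:
        return ("patient_summary", "/", segs[0])
    if segs[0].startswith("course["):
        if len(segs) == 2:  # course field (intent)
            return ("patient_summary", "/", f"courses/{segs[0]}/{segs[1]}")
        plan_subject = f"{segs[0]}/{segs[1]}"
        rest = segs[2:]
        if len(rest) == 1:
            return ("plan_detailed", plan_subject, rest[0])
        if rest[0].startswith("beam["):
            return ("plan_detailed", plan_subject, f"beams/{rest[0]}/{rest[1]}")
        if rest[0].startswith("history["):
            idx = rest[0][len("history["):-1]
            return ("plan_detailed", plan_subject, f"history/entry[{idx}]/{rest[1]}")
        if rest[0].startswith("script_log["):
            idx = rest[0][len("script_log["):-1]
            return ("plan_detailed", plan_subject, f"script_logs/log[{idx}]/{rest[1]}")
    if segs[0].startswith("structure_set["):
        if len(segs) == 2:
            return ("structure_set_detailed", segs[0], segs[1])
        return ("structure_set_detailed", segs[0], f"structures/{segs[1]}/{segs[2]}")
    raise PathError(f"cannot map leaf path {leaf_path!r} to a snapshot locus")


def _rename_locus(obj_path: str) -> Tuple[str, str, str]:
    """Map an Id-keyed object path to the subject/diff path where its rename
    must surface."""
    segs = obj_path.split("/")
    if segs[0].startswith("course["):
        if len(segs) == 1:
            return ("patient_summary", "/", f"courses/{segs[0]}")
        if len(segs) == 2:  # plan
            return ("patient_summary", "/", f"courses/{segs[0]}/plans/{segs[1]}")
        # beam
        return ("plan_detailed", f"{segs[0]}/{segs[1]}", f"beams/{segs[2]}")
    if segs[0].startswith("structure_set["):
        if len(segs) == 1:
            return ("patient_summary", "/", f"structure_sets/{segs[0]}")
        return ("structure_set_detailed", segs[0], f"structures/{segs[1]}")
    raise PathError(f"cannot map object path {obj_path!r}")


@dataclass
class CommissioningReport:
    n_models: int
    seed: int
    injected: int = 0
    detected: int = 0
    rename_injected: int = 0
    rename_detected: int = 0
    no_change_comparisons: int = 0
    false_positives: int = 0
    missed: List[str] = field(default_factory=list)
    false_positive_loci: List[str] = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        total = self.injected + self.rename_injected
        return (self.detected + self.rename_detected) / total if total else 1.0

    @property
    def passed(self) -> bool:
        return self.sensitivity == 1.0 and self.false_positives == 0


def commission(
    seed: int,
    n_models: int,
    complexity: str = "typical",
    options: Optional[CompareOptions] = None,
    no_change_target: int = 200,
    out_path=None,
    strict: bool = False,
) -> CommissioningReport:
    """Prove detection sensitivity of the snapshot/diff engine.

    For ``n_models`` synthetic patients (seeds ``seed..seed+n-1``): assert
    no-change comparisons clean (re-taken snapshots, XML round-trips and
    sibling-permuted models, repeated until ``no_change_target`` comparisons
    ran); mutate every snapshot-visible leaf one at a time and assert a
    difference at the mapped path; rename every Id-keyed object and assert a
    ``renamed`` difference. With ``strict=True`` any miss or false positive
    raises :class:`CommissioningError` listing the loci.
    """
    import random
    import tempfile

    if n_models < 1:
        raise CommissioningError(f"n_models must be >= 1, got {n_models}")
    options = options or CompareOptions()
    rng = random.Random(seed)
    rep = CommissioningReport(n_models=n_models, seed=seed)

    per_model_nochange = max(1, -(-no_change_target // n_models))
    for mi in range(n_models):
        model = generate_synthetic_patient(seed + mi, complexity)
        subjects = default_subjects(model)
        before = {
            (k, p): take_snapshot(model, k, p, acquired_at="commissioning")
            for k, p in subjects
        }

        # (a) no-change comparisons: retake, XML round-trip, sibling permutation
        with tempfile.TemporaryDirectory() as td:
            i = 0
            while i < per_model_nochange:
                for (k, p), snap in before.items():
                    variant = i % 3
                    if variant == 0:
                        other = take_snapshot(model, k, p, acquired_at="x")
                    elif variant == 1:
                        f = Path(td) / "rt.xml"
                        write_snapshot_xml(snap, f)
                        other = read_snapshot_xml(f)
                    else:
                        shuffled = permute_siblings(model, rng)
                        other = take_snapshot(shuffled, k, p, acquired_at="x")
                    report = compare(snap, other, options)
                    rep.no_change_comparisons += 1
                    if not report.clean:
                        rep.false_positives += 1
                        rep.false_positive_loci.append(
                            f"model {mi}: {k} {p}: {report.differences[0].path}"
                        )
                i += 1

        # (b) exhaustive single-leaf mutations
        for leaf_path, value in iter_leaves(model):
            if not _perturbable(leaf_path):
                continue
            spec = MutationSpec(leaf_path, "set_value", perturb_value(leaf_path, value))
            mutated = apply_mutation(model, spec)
            kind, subj, diff_path = _expected_locus(model, leaf_path)
            after = take_snapshot(mutated, kind, subj, acquired_at="x")
            report = compare(before[(kind, subj)], after, options)
            rep.injected += 1
            if any(d.path == diff_path for d in report.differences):
                rep.detected += 1
            else:
                rep.missed.append(f"model {mi}: {leaf_path} (expected {kind}:{diff_path})")

        # (c) rename every Id-keyed object
        for obj_path, _obj in iter_keyed_objects(model):
            spec = MutationSpec(obj_path, "rename", "RN_X1")
            mutated = apply_mutation(model, spec)
            kind, subj, diff_path = _rename_locus(obj_path)
            after = take_snapshot(mutated, kind, subj, acquired_at="x")
            report = compare(before[(kind, subj)], after, options)
            rep.rename_injected += 1
            if any(d.path == diff_path and d.change == "renamed" for d in report.differences):
                rep.rename_detected += 1
            else:
                rep.missed.append(
                    f"model {mi}: rename {obj_path} (expected renamed at {kind}:{diff_path})"
                )

    if out_path is not None:
        _write_commissioning_xml(rep, out_path)
    if strict and not rep.passed:
        detail = "; ".join(rep.missed + rep.false_positive_loci) or "unknown"
        raise CommissioningError(f"commissioning failed: {detail}")
    return rep


def _write_commissioning_xml(rep: CommissioningReport, path) -> None:
    root = etree.Element("commissioning_report")
    root.set("n_models", str(rep.n_models))
    root.set("seed", str(rep.seed))
    root.set("injected", str(rep.injected + rep.rename_injected))
    root.set("detected", str(rep.detected + rep.rename_detected))
    root.set("sensitivity", repr(rep.sensitivity))
    root.set("no_change_comparisons", str(rep.no_change_comparisons))
    root.set("false_positives", str(rep.false_positives))
    root.set("passed", "true" if rep.passed else "false")
    for m in rep.missed:
        etree.SubElement(root, "missed").text = m
    for m in rep.false_positive_loci:
        etree.SubElement(root, "false_positive").text = m
    Path(path).write_bytes(
        etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    )


# ---------------------------------------------------------------------------
# Packaged worked example: course/plan renaming script

FIXTURE_TIMESTAMP = "2022-06-01T09:00:00Z"


def renaming_example_model() -> PatientModel:
    """A QA patient with one course ``TEST_WESTE`` holding one unapproved
    external-beam plan ``Plan`` (two parallel-opposed beams)."""
    plan = PlanSetup(
        id="Plan",
        approval_status="unapproved",
        prescribed_dose_per_fraction=8.0,
        number_of_fractions=1,
        beams=[
            Beam(id="G090", monitor_units=120.0, gantry_angle=90.0, energy_label="6X"),
            Beam(id="G270", monitor_units=135.5, gantry_angle=270.0, energy_label="6X"),
        ],
        history=[
            HistoryEntry(
                timestamp="2022-06-01T08:00:00Z", user="planner1", action="Plan created"
            )
        ],
    )
    model = PatientModel(
        patient_id="PT00000",
        name="ZZ_SYNTH^QA",
        courses=[Course(id="TEST_WESTE", intent="unspecified", plans=[plan])],
    )
    return model


def renaming_example_case(store_dir: str) -> TestCase:
    """The packaged worked example: run the renaming script and expect the
    course rename, the plan rename, one added history entry and one added
    script log — and nothing else."""
    return TestCase(
        case_id="rename_course_and_plan",
        store_dir=store_dir,
        subjects=[
            Subject(kind="patient_summary", path="/"),
            Subject(
                kind="plan_detailed",
                path="course[TEST_WESTE]/plan[Plan]",
                post_path="course[1xLung]/plan[F1LungR]",
            ),
        ],
        script_command=[
            "{python}",
            "-m",
            "plansnap.examples.rename_course_and_plan",
            "{store}",
            "{input}",
        ],
        input_payload={
            "course_id": "TEST_WESTE",
            "new_course_id": "1xLung",
            "plan_id": "Plan",
            "new_plan_id": "F1LungR",
            "timestamp": FIXTURE_TIMESTAMP,
            "user": "tester",
        },
    )


def write_renaming_example(directory) -> Path:
    """Emit the worked example (store + protocol file); returns the protocol
    path. Run it with ``plansnap run <dir>/protocol.txt``."""
    from .protocol import build_protocol, save_protocol

    d = Path(directory)
    store = d / "store"
    store_model(renaming_example_model(), store)
    case = renaming_example_case(str(store))
    protocol = build_protocol([case], output_dir=str(d / "out"))
    proto_path = d / "protocol.txt"
    save_protocol(protocol, proto_path)
    return proto_path
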