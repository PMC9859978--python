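import json
import random
import subprocess
import sys

import pytest

from oracles import check_report_against_leaves
from plansnap.diff import CompareOptions, compare, report_fingerprint
from plansnap.errors import CommissioningError
from plansnap.harness import (
    commission,
    renaming_example_case,
    renaming_example_model,
    run_case,
    run_protocol,
    write_renaming_example,
)
from plansnap.model import generate_synthetic_patient, load_model, store_model
from plansnap.protocol import Subject, build_protocol, load_protocol
from plansnap.protocol import TestCase as Case
from plansnap.snapshot import read_snapshot_xml, take_snapshot, write_snapshot_xml

NOOP = ["{python}", "-m", "plansnap.examples.noop", "{store}", "{input}"]


def _store(tmp_path, model, name="store"):
    d = tmp_path / name
    store_model(model, d)
    return d


def _case(store_dir, case_id="c1", script=NOOP, subjects=None, payload=None):
    return Case(
        case_id=case_id,
        store_dir=str(store_dir),
        subjects=subjects or [Subject(kind="patient_summary", path="/")],
        script_command=script,
        input_payload=payload or {},
    )


class TestRunCase:
    def test_noop_script_is_clean(self, tmp_path, typical_model):
        store = _store(tmp_path, typical_model)
        result = run_case(_case(store), output_dir=tmp_path / "out")
        assert result.status == "clean"
        assert all(r.clean for r in result.reports)

    def test_rename_example_exact_differences(self, tmp_path):
        store = _store(tmp_path, renaming_example_model())
        case = renaming_example_case(str(store))
        result = run_case(case, output_dir=tmp_path / "out")
        assert result.status == "differences"
        diffs = [d for r in result.reports for d in r.differences]
        assert len(diffs) == 4
        by_change = sorted((d.change, d.path) for d in diffs)
        assert by_change == [
            ("added", "history/entry[1]"),
            ("added", "script_logs"),
            ("renamed", "courses/course[TEST_WESTE]"),
            ("renamed", "courses/course[TEST_WESTE]/plans/plan[Plan]"),
        ]
        rename = next(d for d in diffs if d.path == "courses/course[TEST_WESTE]")
        assert (rename.before, rename.after) == ("TEST_WESTE", "1xLung")

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_mutation_script_differences_match_oracle(self, tmp_path, k):
        """A script applying k seeded leaf mutations: every subject report
        must exactly explain the leaf-set change, and k loci must surface."""
        from plansnap.snapshot import default_subjects

        model = generate_synthetic_patient(4, "typical")
        store = _store(tmp_path, model)
        subjects = [Subject(kind=kd, path=p) for kd, p in default_subjects(model)]
        case = _case(
            store,
            case_id=f"mut{k}",
            script=["{python}", "-m", "plansnap.examples.apply_mutations",
                    "{store}", "{input}"],
            subjects=subjects,
            payload={"seed": str(100 + k), "count": str(k)},
        )
        out = tmp_path / "out"
        result = run_case(case, output_dir=out)
        assert result.status == "differences"
        total = 0
        for report in result.reports:
            before = read_snapshot_xml(out / f"mut{k}" / report.before_ref.source)
            after = read_snapshot_xml(out / f"mut{k}" / report.after_ref.source)
            assert not check_report_against_leaves(before.root, after.root, report)
            total += len(report.differences)
        # each mutated leaf appears in exactly one detailed subject; the
        # summary may add echoes (e.g. approval status), hence >= k
        assert total >= k

    def test_failing_script_keeps_before_snapshots(self, tmp_path, typical_model):
        store = _store(tmp_path, typical_model)
        case = _case(store, script=["{python}", "-c", "import sys; sys.exit(7)"])
        out = tmp_path / "out"
        result = run_case(case, output_dir=out)
        assert result.status == "script_failed"
        assert "7" in result.message
        assert (out / "c1" / "before.patient_summary.xml").is_file()

    def test_store_corrupting_script_is_case_error(self, tmp_path, typical_model):
        store = _store(tmp_path, typical_model)
        corrupt = "import sys,pathlib; pathlib.Path(sys.argv[1], 'model.json').write_text('{')"
        case = _case(store, script=["{python}", "-c", corrupt, "{store}"])
        result = run_case(case, output_dir=tmp_path / "out")
        assert result.status == "error"
        assert "corrupt" in result.message

    def test_missing_store_is_case_error(self, tmp_path):
        result = run_case(_case(tmp_path / "absent"), output_dir=tmp_path / "out")
        assert result.status == "error"

    def test_original_store_untouched(self, tmp_path):
        model = renaming_example_model()
        store = _store(tmp_path, model)
        before = (store / "model.json").read_bytes()
        run_case(renaming_example_case(str(store)), output_dir=tmp_path / "out")
        assert (store / "model.json").read_bytes() == before

    def test_timeout_marks_script_failed(self, tmp_path, minimal_model):
        store = _store(tmp_path, minimal_model)
        case = _case(store, script=["{python}", "-c", "import time; time.sleep(5)"])
        result = run_case(case, output_dir=tmp_path / "out", timeout=0.5)
        assert result.status == "script_failed"
        assert "timed out" in result.message

    def test_gold_standard_comparison(self, tmp_path):
        model = renaming_example_model()
        store = _store(tmp_path, model)
        gold = take_snapshot(model, "patient_summary", "/", acquired_at="gold")
        gold_file = tmp_path / "gold.xml"
        write_snapshot_xml(gold, gold_file)
        case = _case(store, script=NOOP)
        case.gold_standard_refs = {"/": str(gold_file)}
        result = run_case(case, output_dir=tmp_path / "out")
        assert result.status == "clean"
        assert len(result.reports) == 2  # before/after + after/gold


class TestRunProtocol:
    def test_three_noop_cases_all_clean(self, tmp_path, typical_model):
        store = _store(tmp_path, typical_model)
        protocol = build_protocol(
            [_case(store, case_id=f"c{i}") for i in range(3)],
            output_dir=str(tmp_path / "out"),
        )
        summary = run_protocol(protocol)
        assert len(summary.results) == 3
        assert summary.totals["clean"] == 3
        assert (tmp_path / "out" / "summary.xml").is_file()
        assert (tmp_path / "out" / "summary.txt").is_file()

    def test_one_failure_among_clean_cases(self, tmp_path, typical_model):
        store = _store(tmp_path, typical_model)
        cases = [
            _case(store, case_id="ok1"),
            _case(store, case_id="boom",
                  script=["{python}", "-c", "import sys; sys.exit(1)"]),
            _case(store, case_id="ok2"),
        ]
        summary = run_protocol(build_protocol(cases, output_dir=str(tmp_path / "out")))
        assert summary.totals == {"clean": 2, "differences": 0,
                                  "script_failed": 1, "error": 0}

    def test_case_isolation_under_reordering(self, tmp_path):
        model = renaming_example_model()
        store = _store(tmp_path, model)
        rename = renaming_example_case(str(store))
        noop = _case(store, case_id="noop")

        def fingerprints(order, out):
            protocol = build_protocol(list(order), output_dir=str(tmp_path / out))
            summary = run_protocol(protocol)
            fps = {}
            for r in summary.results:
                for f in sorted((tmp_path / out / r.case_id).glob("report.*.xml")):
                    fps[(r.case_id, f.name)] = report_fingerprint(f.read_bytes())
            return fps

        assert fingerprints([rename, noop], "o1") == fingerprints([noop, rename], "o2")

    def test_rerun_reports_byte_identical_modulo_metadata(self, tmp_path):
        store = _store(tmp_path, renaming_example_model())
        case = renaming_example_case(str(store))
        p1 = build_protocol([case], output_dir=str(tmp_path / "r1"))
        p2 = build_protocol([case], output_dir=str(tmp_path / "r2"))
        run_protocol(p1)
        run_protocol(p2)
        for f1 in sorted((tmp_path / "r1" / case.case_id).glob("report.*.xml")):
            f2 = tmp_path / "r2" / case.case_id / f1.name
            assert report_fingerprint(f1.read_bytes()) == report_fingerprint(f2.read_bytes())


class TestExecutionModeEquivalence:
    def test_harness_equals_manual_run(self, tmp_path):
        """Running the renaming script through the harness and invoking it by
        hand on a store copy produce identical reports (metadata aside)."""
        model = renaming_example_model()
        store = _store(tmp_path, model)
        case = renaming_example_case(str(store))
        out = tmp_path / "auto"
        result = run_case(case, output_dir=out)
        assert result.status == "differences"

        # manual mode: copy store, snapshot, run the script from a shell,
        # snapshot again, compare offline
        manual_store = _store(tmp_path, model, name="manual_store")
        before = {
            s.path: take_snapshot(model, s.kind, s.path, acquired_at="m")
            for s in case.subjects
        }
        input_file = tmp_path / "manual_input.json"
        input_file.write_text(json.dumps(case.input_payload))
        proc = subprocess.run(
            [sys.executable, "-m", "plansnap.examples.rename_course_and_plan",
             str(manual_store), str(input_file)],
            capture_output=True,
        )
        assert proc.returncode == 0, proc.stderr
        model_after = load_model(manual_store)
        from plansnap.diff import report_to_bytes

        for subject in case.subjects:
            after_path = subject.post_path or subject.path
            after = take_snapshot(model_after, subject.kind, after_path, acquired_at="m")
            manual_report = compare(before[subject.path], after)
            tag = subject.kind if subject.path == "/" else subject.kind + ".course_TEST_WESTE.plan_Plan"
            auto_bytes = (out / case.case_id / f"report.{tag}.xml").read_bytes()
            assert report_fingerprint(report_to_bytes(manual_report)) == \
                report_fingerprint(auto_bytes)


class TestCommissioning:
    def test_small_commissioning_run_passes(self):
        rep = commission(seed=1, n_models=1, no_change_target=30)
        assert rep.sensitivity == 1.0
        assert rep.false_positives == 0
        assert rep.passed
        assert rep.no_change_comparisons >= 30

    def test_zero_models_rejected(self):
        with pytest.raises(CommissioningError, match="n_models"):
            commission(seed=1, n_models=0)

    def test_sabotaged_engine_fails_naming_field_class(self):
        """Blinding the comparison to one field class must break the gate and
        name the ignored loci."""
        blinded = CompareOptions(ignore_paths=["*monitor_units", "*/monitor_units"])
        rep = commission(seed=1, n_models=1, options=blinded, no_change_target=5)
        assert not rep.passed
        assert any("monitor_units" in m for m in rep.missed)
        with pytest.raises(CommissioningError, match="monitor_units"):
            commission(seed=1, n_models=1, options=blinded, no_change_target=5,
                       strict=True)

    def test_report_xml_written(self, tmp_path):
        out = tmp_path / "commissioning.xml"
        rep = commission(seed=2, n_models=1, complexity="minimal",
                         no_change_target=5, out_path=out)
        assert out.is_file()
        text = out.read_text()
        assert 'passed="true"' in text
        assert f'false_positives="{rep.false_positives}"' in text


def test_write_renaming_example_is_runnable(tmp_path):
    proto_path = write_renaming_example(tmp_path)
    protocol = load_protocol(proto_path)
    summary = run_protocol(protocol)
    assert summary.totals["differences"] == 1
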