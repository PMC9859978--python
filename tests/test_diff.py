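import copy
import random

import pytest
from lxml import etree

from oracles import check_report_against_leaves, optimal_assignment
from plansnap.diff import (
    CompareOptions,
    compare,
    match_children,
    read_report_xml,
    render_report_text,
    render_reports_text,
    report_to_bytes,
    similarity,
    write_report_xml,
)
from plansnap.errors import ComparisonError
from plansnap.model import (
    MutationSpec,
    apply_mutation,
    generate_synthetic_patient,
    iter_leaves,
    permute_siblings,
    perturb_value,
    sample_set_value_mutations,
)
from plansnap.snapshot import FieldNode, default_subjects, take_snapshot


def _scalar(key, value):
    return FieldNode(key=key, kind="scalar", value=value)


def _container(key, children, ordinal=None):
    return FieldNode(
        key=key, kind="container", children=sorted(children, key=lambda c: c.key),
        ordinal=ordinal,
    )


class TestMatchChildren:
    def test_permuted_identical_keys_all_pair(self):
        kids = [
            _container(f"beam[B{i}]", [_scalar("monitor_units", str(10 * i))])
            for i in range(4)
        ]
        pairs, removed, added = match_children(kids, list(reversed(kids)))
        assert len(pairs) == 4 and not removed and not added

    def test_single_rename_pairs_by_similarity(self):
        before = [_container("course[TEST_WESTE]", [_scalar("intent", "unspecified")])]
        after = [_container("course[1xLung]", [_scalar("intent", "unspecified")])]
        pairs, removed, added = match_children(before, after)
        assert [(b.key, a.key) for b, a in pairs] == [("course[TEST_WESTE]", "course[1xLung]")]
        assert not removed and not added

    def test_dissimilar_leftovers_stay_removed_added(self):
        before = [_container("beam[A]", [_scalar("monitor_units", "100.0")])]
        after = [_container("beam[B]", [_scalar("monitor_units", "250.0")])]
        pairs, removed, added = match_children(before, after, 0.5)
        assert not pairs
        assert [n.key for n in removed] == ["beam[A]"]
        assert [n.key for n in added] == ["beam[B]"]

    def test_plain_field_keys_never_rename(self):
        before = [_scalar("machine", "TB1")]
        after = [_scalar("technique", "TB1")]
        pairs, removed, added = match_children(before, after)
        assert not pairs and len(removed) == 1 and len(added) == 1

    def test_duplicate_keys_rejected(self):
        kids = [_scalar("x", "1"), _scalar("x", "2")]
        with pytest.raises(ComparisonError, match="duplicate"):
            match_children(kids, [])

    @pytest.mark.parametrize("trial", range(20))
    def test_greedy_matches_exhaustive_assignment(self, trial):
        """On perturbed-copy instances (each after-child derived from one
        before-child), greedy pairing equals the exhaustive optimum."""
        rng = random.Random(trial)
        n = rng.randint(2, 5)
        before = []
        for i in range(n):
            leaves = [
                _scalar(f"f{j}", str(rng.randrange(1000))) for j in range(6)
            ]
            before.append(_container(f"beam[B{i}]", leaves, ordinal=i))
        # derive after-children: rename all, perturb a distinct minority of leaves
        after = []
        for i, node in enumerate(before):
            clone = copy.deepcopy(node)
            clone.key = f"beam[R{i}]"
            for leaf in rng.sample(clone.children, rng.randint(0, 2)):
                leaf.value = str(rng.randrange(1000, 2000))
            after.append(clone)
        rng.shuffle(after)
        pairs, _, _ = match_children(before, after, 0.5)
        got = {(b.key, a.key) for b, a in pairs}
        want, _ = optimal_assignment(before, after, similarity, 0.5)
        assert got == want


class TestCompare:
    @pytest.mark.parametrize("seed", range(5))
    def test_identity_is_clean(self, seed):
        model = generate_synthetic_patient(seed, "typical")
        for kind, path in default_subjects(model):
            snap = take_snapshot(model, kind, path, acquired_at="t")
            assert compare(snap, snap).clean

    def test_reorder_invariance(self, typical_model):
        rng = random.Random(11)
        before = {
            (k, p): take_snapshot(typical_model, k, p, acquired_at="t")
            for k, p in default_subjects(typical_model)
        }
        shuffled = permute_siblings(typical_model, rng)
        for (kind, path), snap in before.items():
            report = compare(snap, take_snapshot(shuffled, kind, path, acquired_at="t"))
            assert report.clean

    def test_every_single_leaf_mutation_detected(self, minimal_model):
        summary = take_snapshot(minimal_model, "patient_summary", "/", acquired_at="t")
        plan = take_snapshot(
            minimal_model, "plan_detailed", "course[C1]/plan[P1]", acquired_at="t"
        )
        for path, value in iter_leaves(minimal_model):
            if path.rsplit("/", 1)[-1] in ("plan_type",):
                continue
            mutated = apply_mutation(
                minimal_model, MutationSpec(path, "set_value", perturb_value(path, value))
            )
            hits = 0
            for snap, kind, spath in (
                (summary, "patient_summary", "/"),
                (plan, "plan_detailed", "course[C1]/plan[P1]"),
            ):
                after = take_snapshot(mutated, kind, spath, acquired_at="t")
                hits += len(compare(snap, after).differences)
            assert hits >= 1, f"mutation of {path} went undetected"

    def test_symmetry_maps_added_to_removed(self, typical_model):
        mutated = apply_mutation(
            typical_model,
            MutationSpec(
                f"course[{typical_model.courses[0].id}]",
                "add_child",
                {"kind": "plan", "id": "ZZNew"},
            ),
        )
        a = take_snapshot(typical_model, "patient_summary", "/", acquired_at="t")
        b = take_snapshot(mutated, "patient_summary", "/", acquired_at="t")
        fwd, rev = compare(a, b), compare(b, a)
        assert fwd.counts["added"] == rev.counts["removed"] == 1
        assert fwd.counts["removed"] == rev.counts["added"] == 0
        assert {d.path for d in fwd.differences} == {d.path for d in rev.differences}

    def test_numeric_tolerance_opt_in(self, minimal_model):
        mutated = apply_mutation(
            minimal_model,
            MutationSpec("course[C1]/plan[P1]/beam[B1]/monitor_units", "set_value", 100.4),
        )
        a = take_snapshot(minimal_model, "plan_detailed", "course[C1]/plan[P1]", acquired_at="t")
        b = take_snapshot(mutated, "plan_detailed", "course[C1]/plan[P1]", acquired_at="t")
        assert not compare(a, b).clean  # default: exact equality
        tol = CompareOptions(numeric_tolerance={"monitor_units": 0.5})
        assert compare(a, b, tol).clean
        tight = CompareOptions(numeric_tolerance={"monitor_units": 0.1})
        assert not compare(a, b, tight).clean

    def test_ignore_paths_skip_subtrees(self, minimal_model):
        mutated = apply_mutation(
            minimal_model,
            MutationSpec("course[C1]/plan[P1]/beam[B1]/monitor_units", "set_value", 42.0),
        )
        a = take_snapshot(minimal_model, "plan_detailed", "course[C1]/plan[P1]", acquired_at="t")
        b = take_snapshot(mutated, "plan_detailed", "course[C1]/plan[P1]", acquired_at="t")
        opts = CompareOptions(ignore_paths=["beams/*/monitor_units"])
        assert compare(a, b, opts).clean

    def test_rename_detection_can_be_disabled(self, rename_model):
        mutated = apply_mutation(
            rename_model, MutationSpec("course[TEST_WESTE]", "rename", "1xLung")
        )
        a = take_snapshot(rename_model, "patient_summary", "/", acquired_at="t")
        b = take_snapshot(mutated, "patient_summary", "/", acquired_at="t")
        on = compare(a, b)
        assert [d.change for d in on.differences] == ["renamed"]
        off = compare(a, b, CompareOptions(detect_renames=False))
        assert sorted(d.change for d in off.differences) == ["added", "removed"]

    def test_subject_kind_mismatch_rejected(self, typical_model):
        a = take_snapshot(typical_model, "patient_summary", "/")
        ss = typical_model.structure_sets[0]
        b = take_snapshot(typical_model, "structure_set_detailed", f"structure_set[{ss.id}]")
        with pytest.raises(ComparisonError):
            compare(a, b)

    @pytest.mark.parametrize("seed", range(30))
    def test_report_explains_leaf_transformation(self, seed):
        """Random mutation sets: the report must exactly account for the
        flattened leaf-set difference (rename folding included)."""
        rng = random.Random(seed)
        model = generate_synthetic_patient(seed % 7, "minimal" if seed % 2 else "typical")
        mutated = model
        for spec in sample_set_value_mutations(model, rng.randint(1, 5), rng):
            mutated = apply_mutation(mutated, spec)
        if rng.random() < 0.5 and mutated.courses:
            mutated = apply_mutation(
                mutated, MutationSpec(f"course[{mutated.courses[0].id}]", "rename", "RNC")
            )
        if rng.random() < 0.3:
            mutated = apply_mutation(
                mutated,
                MutationSpec(
                    f"course[{mutated.courses[-1].id}]",
                    "add_child",
                    {"kind": "plan", "id": "ZZAdd"},
                ),
            )
        for kind, path in default_subjects(model):
            before = take_snapshot(model, kind, path, acquired_at="t")
            after_path = path
            if kind == "plan_detailed" or kind == "structure_set_detailed":
                # follow the course rename for detailed subjects
                segs = path.split("/")
                if segs[0].startswith("course[") and not any(
                    c.id == segs[0][7:-1] for c in mutated.courses
                ):
                    segs[0] = "course[RNC]"
                    after_path = "/".join(segs)
            after = take_snapshot(mutated, kind, after_path, acquired_at="t")
            report = compare(before, after)
            problems = check_report_against_leaves(before.root, after.root, report)
            assert not problems, problems


class TestReportIO:
    def test_clean_report_xml(self, tmp_path, typical_model):
        snap = take_snapshot(typical_model, "patient_summary", "/", acquired_at="t")
        report = compare(snap, snap)
        f = tmp_path / "report.xml"
        write_report_xml(report, f)
        root = etree.parse(str(f)).getroot()
        assert root.get("clean") == "true"
        assert all(root.find("counts").get(k) == "0" for k in
                   ("added", "removed", "modified", "renamed"))

    @pytest.mark.parametrize("seed", range(5))
    def test_roundtrip_preserves_differences(self, tmp_path, seed):
        rng = random.Random(seed)
        model = generate_synthetic_patient(seed, "typical")
        mutated = model
        for spec in sample_set_value_mutations(model, 3, rng):
            mutated = apply_mutation(mutated, spec)
        a = take_snapshot(model, "patient_summary", "/", acquired_at="t")
        b = take_snapshot(mutated, "patient_summary", "/", acquired_at="t")
        report = compare(a, b)
        f = tmp_path / "report.xml"
        write_report_xml(report, f)
        loaded = read_report_xml(f)
        assert loaded.differences == report.differences
        assert loaded.counts == report.counts
        assert loaded.clean == report.clean

    def test_report_validates_against_shipped_schema(self, tmp_path, typical_model):
        from importlib import resources

        snap = take_snapshot(typical_model, "patient_summary", "/", acquired_at="t")
        f = tmp_path / "r.xml"
        write_report_xml(compare(snap, snap), f)
        with resources.files("plansnap.schemas").joinpath("report.xsd").open("rb") as fh:
            schema = etree.XMLSchema(etree.parse(fh))
        assert schema.validate(etree.parse(str(f)))

    def test_text_rendering_orders_summary_first(self, typical_model):
        course = typical_model.courses[0]
        plan_path = f"course[{course.id}]/plan[{course.plans[0].id}]"
        summary = take_snapshot(typical_model, "patient_summary", "/", acquired_at="t")
        plan = take_snapshot(typical_model, "plan_detailed", plan_path, acquired_at="t")
        text = render_reports_text([compare(plan, plan), compare(summary, summary)])
        assert text.index("Patient summary") < text.index("=== Plan")

    def test_render_shows_rename_values(self, rename_model):
        mutated = apply_mutation(
            rename_model, MutationSpec("course[TEST_WESTE]", "rename", "1xLung")
        )
        a = take_snapshot(rename_model, "patient_summary", "/", acquired_at="t")
        b = take_snapshot(mutated, "patient_summary", "/", acquired_at="t")
        text = render_report_text(compare(a, b))
        assert "TEST_WESTE" in text and "1xLung" in text

    def test_byte_determinism(self, typical_model):
        snap = take_snapshot(typical_model, "patient_summary", "/", acquired_at="t")
        report = compare(snap, snap)
        assert report_to_bytes(report) == report_to_bytes(report)
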