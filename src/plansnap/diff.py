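"""Id-keyed structural comparison of two snapshots.

Off-the-shelf XML diffs pair list elements by index; for planning objects
that is wrong — deleting the first of three beams must report one removed
beam, not three modified ones. Children here are paired by their key
(``type[id]`` for Id-keyed objects), independent of sibling order.

Rename detection: after exact-key pairing, leftover children of the same
type are greedily re-paired by descending field similarity (the fraction of
equal leaf values among the leaf paths the two subtrees share); pairs at or
above ``rename_similarity_threshold`` report as one ``renamed`` difference
plus whatever differs inside. With the threshold set above 1.0 this is
effectively off and renames report as removed+added.

All difference paths are *before-keyed*: a renamed subtree keeps its old key
in the paths of differences found beneath it, so every path is addressable
in the before snapshot.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from lxml import etree

from .errors import ComparisonError, SnapshotFormatError
from .snapshot import FieldNode, Snapshot

REPORT_SCHEMA_VERSION = "1.0"
CHANGE_KINDS = ("added", "removed", "modified", "renamed")


@dataclass
class Difference:
    path: str
    change: str  # added | removed | modified | renamed
    before: Optional[str] = None
    after: Optional[str] = None


@dataclass
class SnapshotRef:
    subject_kind: str
    subject_path: str
    acquired_at: str
    source: Optional[str] = None

    @classmethod
    def of(cls, s: Snapshot, source: Optional[str] = None) -> "SnapshotRef":
        return cls(s.subject_kind, s.subject_path, s.acquired_at, source)


@dataclass
class ComparisonReport:
    before_ref: SnapshotRef
    after_ref: SnapshotRef
    differences: List[Difference] = field(default_factory=list)

    @property
    def counts(self) -> Dict[str, int]:
        c = {k: 0 for k in CHANGE_KINDS}
        for d in self.differences:
            c[d.change] += 1
        return c

    @property
    def clean(self) -> bool:
        return not self.differences


@dataclass
class CompareOptions:
    """Comparison knobs. Defaults are strict: exact canonical-string equality
    (a QA tool must not hide small changes), no ignored paths, rename
    threshold 0.5."""

    numeric_tolerance: Dict[str, float] = field(default_factory=dict)
    ignore_paths: List[str] = field(default_factory=list)
    rename_similarity_threshold: float = 0.5
    detect_renames: bool = True  # off: renames report as removed+added

    def __post_init__(self) -> None:
        for k, v in self.numeric_tolerance.items():
            if v < 0:
                raise ComparisonError(f"negative tolerance for {k!r}")
        if not 0.0 <= self.rename_similarity_threshold <= 1.0:
            raise ComparisonError("rename_similarity_threshold outside [0,1]")


# ---------------------------------------------------------------------------
# Child matching

def _key_type(key: str) -> Optional[str]:
    """The type of a ``type[id]`` key, or None for plain field names."""
    i = key.find("[")
    return key[:i] if i > 0 and key.endswith("]") else None


def similarity(a: FieldNode, b: FieldNode) -> float:
    """Fraction of equal leaf values among the leaf paths shared by *a* and
    *b* (0 when they share none)."""
    la = dict(a.leaves())
    lb = dict(b.leaves())
    shared = la.keys() & lb.keys()
    if not shared:
        return 0.0
    equal = sum(1 for p in shared if la[p] == lb[p])
    return equal / len(shared)


def match_children(
    before_children: List[FieldNode],
    after_children: List[FieldNode],
    rename_similarity_threshold: float = 0.5,
    detect_renames: bool = True,
) -> Tuple[List[Tuple[FieldNode, FieldNode]], List[FieldNode], List[FieldNode]]:
    """Pair sibling sets by key, then re-pair same-type leftovers as rename
    candidates. Returns ``(pairs, removed, added)``; rename pairs are the
    pairs whose keys differ."""
    for side, children in (("before", before_children), ("after", after_children)):
        keys = [c.key for c in children]
        if len(keys) != len(set(keys)):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise ComparisonError(f"duplicate sibling key {dup!r} on {side} side")
    after_by_key = {c.key: c for c in after_children}
    pairs: List[Tuple[FieldNode, FieldNode]] = []
    left_b: List[FieldNode] = []
    matched_after = set()
    for bc in before_children:
        ac = after_by_key.get(bc.key)
        if ac is not None:
            pairs.append((bc, ac))
            matched_after.add(bc.key)
        else:
            left_b.append(bc)
    left_a = [c for c in after_children if c.key not in matched_after]

    # rename candidates: same-type leftovers, greedy by descending similarity
    candidates = []
    if not detect_renames:
        return pairs, left_b, left_a
    for bi, bc in enumerate(left_b):
        bt = _key_type(bc.key)
        if bt is None:
            continue
        for ai, ac in enumerate(left_a):
            if _key_type(ac.key) != bt or bc.kind != ac.kind:
                continue
            sim = similarity(bc, ac)
            if sim >= rename_similarity_threshold:
                candidates.append((sim, bc, ac, bi, ai))
    candidates.sort(
        key=lambda c: (
            -c[0],
            c[1].ordinal if c[1].ordinal is not None else 0,
            c[1].key,
            c[2].ordinal if c[2].ordinal is not None else 0,
            c[2].key,
        )
    )
    used_b, used_a = set(), set()
    for sim, bc, ac, bi, ai in candidates:
        if bi in used_b or ai in used_a:
            continue
        used_b.add(bi)
        used_a.add(ai)
        pairs.append((bc, ac))
    removed = [c for i, c in enumerate(left_b) if i not in used_b]
    added = [c for i, c in enumerate(left_a) if i not in used_a]
    return pairs, removed, added


# ---------------------------------------------------------------------------
# Comparison

def _summarize(node: FieldNode) -> str:
    if node.kind == "scalar":
        return node.value or ""
    n = sum(1 for _ in node.leaves())
    return f"<{n} field(s)>"


def _values_equal(path: str, a: str, b: str, options: CompareOptions) -> bool:
    if a == b:
        return True
    leaf = path.rsplit("/", 1)[-1]
    tol = options.numeric_tolerance.get(leaf)
    if tol is not None:
        try:
            return abs(float(a) - float(b)) <= tol
        except ValueError:
            return False
    return False


def _ignored(path: str, options: CompareOptions) -> bool:
    return any(fnmatch.fnmatchcase(path, pat) for pat in options.ignore_paths)


def _walk(
    bnode: FieldNode,
    anode: FieldNode,
    path: str,
    options: CompareOptions,
    out: List[Difference],
) -> None:
    if bnode.kind != anode.kind:
        out.append(
            Difference(path, "modified", before=_summarize(bnode), after=_summarize(anode))
        )
        return
    if bnode.kind == "scalar":
        if not _values_equal(path, bnode.value or "", anode.value or "", options):
            out.append(Difference(path, "modified", before=bnode.value, after=anode.value))
        return
    pairs, removed, added = match_children(
        bnode.children,
        anode.children,
        options.rename_similarity_threshold,
        options.detect_renames,
    )
    # deterministic order: before-document order, then added in after order
    order = {c.key: i for i, c in enumerate(bnode.children)}
    pairs.sort(key=lambda p: order[p[0].key])
    for bc, ac in pairs:
        child_path = f"{path}/{bc.key}" if path else bc.key
        if _ignored(child_path, options):
            continue
        if bc.key != ac.key:
            bt = _key_type(bc.key)
            out.append(
                Difference(
                    child_path,
                    "renamed",
                    before=bc.key[len(bt) + 1 : -1],
                    after=ac.key[len(bt) + 1 : -1],
                )
            )
        _walk(bc, ac, child_path, options, out)
    for bc in removed:
        child_path = f"{path}/{bc.key}" if path else bc.key
        if not _ignored(child_path, options):
            out.append(Difference(child_path, "removed", before=_summarize(bc)))
    for ac in added:
        child_path = f"{path}/{ac.key}" if path else ac.key
        if not _ignored(child_path, options):
            out.append(Difference(child_path, "added", after=_summarize(ac)))


def compare(
    before: Snapshot,
    after: Snapshot,
    options: Optional[CompareOptions] = None,
    before_source: Optional[str] = None,
    after_source: Optional[str] = None,
) -> ComparisonReport:
    """Compare two snapshots of the same subject kind.

    ``subject_path`` may differ (a renamed subject paired by the test case);
    ``acquired_at`` is carried as metadata and never diffed. The report is a
    deterministic function of the two trees and the options.
    """
    if before.subject_kind != after.subject_kind:
        raise ComparisonError(
            f"subject kinds differ: {before.subject_kind} vs {after.subject_kind}"
        )
    options = options or CompareOptions()
    report = ComparisonReport(
        before_ref=SnapshotRef.of(before, before_source),
        after_ref=SnapshotRef.of(after, after_source),
    )
    _walk(before.root, after.root, "", options, report.differences)
    return report


# ---------------------------------------------------------------------------
# Report XML + text rendering

_report_schema: Optional[etree.XMLSchema] = None


def _schema() -> etree.XMLSchema:
    global _report_schema
    if _report_schema is None:
        with resources.files("plansnap.schemas").joinpath("report.xsd").open("rb") as fh:
            _report_schema = etree.XMLSchema(etree.parse(fh))
    return _report_schema


def _ref_to_xml(ref: SnapshotRef, parent: etree._Element, tag: str) -> None:
    el = etree.SubElement(parent, tag)
    el.set("subject_kind", ref.subject_kind)
    el.set("subject_path", ref.subject_path)
    el.set("acquired_at", ref.acquired_at)
    if ref.source is not None:
        el.set("source", ref.source)


def report_to_bytes(report: ComparisonReport) -> bytes:
    root = etree.Element("comparison_report")
    root.set("schema_version", REPORT_SCHEMA_VERSION)
    root.set("clean", "true" if report.clean else "false")
    _ref_to_xml(report.before_ref, root, "before")
    _ref_to_xml(report.after_ref, root, "after")
    counts = etree.SubElement(root, "counts")
    for k in CHANGE_KINDS:
        counts.set(k, str(report.counts[k]))
    diffs = etree.SubElement(root, "differences")
    for d in report.differences:
        el = etree.SubElement(diffs, "difference")
        el.set("path", d.path)
        el.set("change", d.change)
        if d.before is not None:
            el.set("before", d.before)
        if d.after is not None:
            el.set("after", d.after)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def write_report_xml(report: ComparisonReport, path) -> None:
    Path(path).write_bytes(report_to_bytes(report))


def read_report_xml(path) -> ComparisonReport:
    try:
        tree = etree.parse(str(path))
    except (OSError, etree.XMLSyntaxError) as e:
        raise SnapshotFormatError(f"{path}: {e}") from e
    if not _schema().validate(tree):
        err = _schema().error_log[0]
        raise SnapshotFormatError(f"{path}: line {err.line}: {err.message}")
    root = tree.getroot()

    def ref(tag: str) -> SnapshotRef:
        el = root.find(tag)
        return SnapshotRef(
            el.get("subject_kind"), el.get("subject_path"), el.get("acquired_at"),
            el.get("source"),
        )

    report = ComparisonReport(before_ref=ref("before"), after_ref=ref("after"))
    for el in root.find("differences"):
        report.differences.append(
            Difference(el.get("path"), el.get("change"), el.get("before"), el.get("after"))
        )
    return report


_SECTION_ORDER = {"patient_summary": 0, "plan_detailed": 1, "structure_set_detailed": 2}
_SECTION_TITLE = {
    "patient_summary": "Patient summary",
    "plan_detailed": "Plan",
    "structure_set_detailed": "Structure set",
}


def render_report_text(report: ComparisonReport) -> str:
    """Console rendering of one report."""
    ref = report.before_ref
    title = _SECTION_TITLE.get(ref.subject_kind, ref.subject_kind)
    lines = [f"=== {title}: {ref.subject_path}"]
    if report.after_ref.subject_path != ref.subject_path:
        lines[0] += f" -> {report.after_ref.subject_path}"
    if report.clean:
        lines.append("  no differences")
    else:
        for d in report.differences:
            if d.change == "modified":
                lines.append(f"  modified {d.path}: {d.before!r} -> {d.after!r}")
            elif d.change == "renamed":
                lines.append(f"  renamed  {d.path}: Id {d.before!r} -> {d.after!r}")
            elif d.change == "added":
                lines.append(f"  added    {d.path}: {d.after}")
            else:
                lines.append(f"  removed  {d.path}: {d.before}")
    c = report.counts
    lines.append(
        f"  [{'clean' if report.clean else 'differences'}] "
        f"added={c['added']} removed={c['removed']} modified={c['modified']} "
        f"renamed={c['renamed']}"
    )
    return "\n".join(lines) + "\n"


def render_reports_text(reports: List[ComparisonReport]) -> str:
    """Combined rendering, patient-summary section first, then plans, then
    structure sets."""
    ordered = sorted(
        reports,
        key=lambda r: (
            _SECTION_ORDER.get(r.before_ref.subject_kind, 9),
            r.before_ref.subject_path,
        ),
    )
    return "".join(render_report_text(r) for r in ordered)


def report_fingerprint(xml_bytes: bytes) -> bytes:
    """Report bytes with run-varying metadata (acquired_at, source) removed;
    used for regression baselines and execution-mode equivalence checks."""
    root = etree.fromstring(xml_bytes)
    for tag in ("before", "after"):
        el = root.find(tag)
        if el is not None:
            el.attrib.pop("acquired_at", None)
            el.attrib.pop("source", None)
    return etree.tostring(root, pretty_print=True)
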