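"""Snapshots: versioned field-tree captures of one planning object.

A snapshot records the fields of one *subject* — the patient summary, one
plan in full detail, or one structure set in full detail — as a tree of
:class:`FieldNode`. Scalars are rendered through a canonical formatter so
that string equality of leaf values is well-defined; container children are
stored in canonical (sorted-key) order with an ``ordinal`` attribute keeping
the original model position for ordering-sensitive audits.

Two deliberate asymmetries with the raw model:

* An object's Id is carried by its container key (``plan[F1LungR]``) or, for
  the snapshot root, by ``subject_path`` metadata — never duplicated as a
  scalar leaf. A rename therefore surfaces as exactly one key change.
* Empty collections are omitted (the tree invariant is scalar <=> childless).

Snapshots serialize to UTF-8 XML validated against a shipped XSD; writing is
byte-deterministic and reading an unsupported major schema version fails
loudly rather than coercing.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterator, List, Optional, Tuple

from lxml import etree

from .errors import SnapshotFormatError, SubjectError
from .model import (
    PatientModel,
    PlanSetup,
    StructureSet,
    resolve,
    split_path,
)

SCHEMA_VERSION = "1.0"
SUBJECT_KINDS = ("patient_summary", "plan_detailed", "structure_set_detailed")

_ROOT_KEY = {
    "patient_summary": "patient",
    "plan_detailed": "plan",
    "structure_set_detailed": "structure_set",
}


@dataclass
class FieldNode:
    key: str
    kind: str  # "scalar" | "container"
    value: Optional[str] = None
    children: List["FieldNode"] = field(default_factory=list)
    ordinal: Optional[int] = None

    def child(self, key: str) -> Optional["FieldNode"]:
        for c in self.children:
            if c.key == key:
                return c
        return None

    def leaves(self, prefix: str = "") -> Iterator[Tuple[str, str]]:
        """Yield (path, value) for every scalar leaf under this node; the
        node's own key is not part of the paths."""
        if self.kind == "scalar":
            yield (prefix.rstrip("/"), self.value or "")
            return
        for c in self.children:
            if c.kind == "scalar":
                yield (f"{prefix}{c.key}", c.value or "")
            else:
                yield from c.leaves(f"{prefix}{c.key}/")


@dataclass
class Snapshot:
    subject_kind: str
    subject_path: str
    acquired_at: str
    schema_version: str
    root: FieldNode


# ---------------------------------------------------------------------------
# Canonical scalar formatting

def format_scalar(value: Any, angle: bool = False) -> str:
    """Canonical string form: booleans ``true``/``false``, angles to 0.1 deg,
    other reals as shortest round-trip decimals, RGB as ``r,g,b``."""
    if isinstance(value, bool):
        return "true" if value else "false"
    if angle:
        return f"{float(value):.1f}"
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, tuple):
        return ",".join(str(v) for v in value)
    return str(value)


_ANGLE_FIELDS = {"gantry_angle", "collimator_angle", "couch_angle"}


def _scalar(key: str, value: Any) -> FieldNode:
    return FieldNode(key=key, kind="scalar", value=format_scalar(value, key in _ANGLE_FIELDS))


def _container(key: str, children: List[FieldNode], ordinal: Optional[int] = None) -> FieldNode:
    children = sorted(children, key=lambda c: c.key)
    return FieldNode(key=key, kind="container", children=children, ordinal=ordinal)


# ---------------------------------------------------------------------------
# Tree builders

def _plan_tree(plan: PlanSetup, key: str, ordinal: Optional[int] = None) -> FieldNode:
    children = [
        _scalar("plan_type", plan.plan_type),
        _scalar("approval_status", plan.approval_status),
        _scalar("prescribed_dose_per_fraction", plan.prescribed_dose_per_fraction),
        _scalar("number_of_fractions", plan.number_of_fractions),
    ]
    if plan.structure_set_ref is not None:
        children.append(_scalar("structure_set_ref", plan.structure_set_ref))
    if plan.beams:
        beams = []
        for i, b in enumerate(plan.beams):
            fields = [
                _scalar("machine", b.machine),
                _scalar("energy_label", b.energy_label),
                _scalar("monitor_units", b.monitor_units),
                _scalar("gantry_angle", b.gantry_angle),
                _scalar("collimator_angle", b.collimator_angle),
                _scalar("couch_angle", b.couch_angle),
                _scalar("technique", b.technique),
                _scalar("is_setup_field", b.is_setup_field),
            ]
            if b.mlc_digest is not None:
                fields.append(_scalar("mlc_digest", b.mlc_digest))
            beams.append(_container(f"beam[{b.id}]", fields, ordinal=i))
        children.append(_container("beams", beams))
    if plan.history:
        children.append(
            _container(
                "history",
                [
                    _container(
                        f"entry[{i}]",
                        [
                            _scalar("timestamp", h.timestamp),
                            _scalar("user", h.user),
                            _scalar("action", h.action),
                        ],
                        ordinal=i,
                    )
                    for i, h in enumerate(plan.history)
                ],
            )
        )
    if plan.script_logs:
        children.append(
            _container(
                "script_logs",
                [
                    _container(
                        f"log[{i}]",
                        [
                            _scalar("script_name", l.script_name),
                            _scalar("timestamp", l.timestamp),
                            _scalar("user", l.user),
                        ],
                        ordinal=i,
                    )
                    for i, l in enumerate(plan.script_logs)
                ],
            )
        )
    return _container(key, children, ordinal=ordinal)


def _structure_set_tree(ss: StructureSet, key: str, ordinal: Optional[int] = None) -> FieldNode:
    children: List[FieldNode] = [_scalar("image_id", ss.image_id)]
    if ss.structures:
        children.append(
            _container(
                "structures",
                [
                    _container(
                        f"structure[{st.id}]",
                        [
                            _scalar("dicom_type", st.dicom_type),
                            _scalar("color", st.color),
                            _scalar("volume_cc", st.volume_cc),
                            _scalar("point_count", st.point_count),
                            _scalar("geometry_digest", st.geometry_digest),
                        ],
                        ordinal=i,
                    )
                    for i, st in enumerate(ss.structures)
                ],
            )
        )
    return _container(key, children, ordinal=ordinal)


def _summary_tree(model: PatientModel) -> FieldNode:
    children = [_scalar("patient_id", model.patient_id), _scalar("name", model.name)]
    if model.courses:
        courses = []
        for i, c in enumerate(model.courses):
            cc: List[FieldNode] = [_scalar("intent", c.intent)]
            if c.plans:
                cc.append(
                    _container(
                        "plans",
                        [
                            _container(
                                f"plan[{p.id}]",
                                [_scalar("approval_status", p.approval_status)],
                                ordinal=j,
                            )
                            for j, p in enumerate(c.plans)
                        ],
                    )
                )
            courses.append(_container(f"course[{c.id}]", cc, ordinal=i))
        children.append(_container("courses", courses))
    if model.structure_sets:
        children.append(
            _container(
                "structure_sets",
                [
                    _container(
                        f"structure_set[{s.id}]", [_scalar("image_id", s.image_id)], ordinal=i
                    )
                    for i, s in enumerate(model.structure_sets)
                ],
            )
        )
    return _container("patient", children)


def take_snapshot(
    model: PatientModel,
    subject_kind: str,
    subject_path: str = "",
    acquired_at: Optional[str] = None,
) -> Snapshot:
    """Capture one subject of *model* as a snapshot.

    The tree is a pure function of the model; only ``acquired_at`` (wall
    clock unless supplied) varies between calls.
    """
    if subject_kind not in SUBJECT_KINDS:
        raise SubjectError(f"unknown subject kind {subject_kind!r}")
    subject_path = "" if subject_path.strip() == "/" else subject_path.strip().strip("/")
    if subject_kind == "patient_summary":
        if split_path(subject_path):
            raise SubjectError("patient_summary subject_path must be the patient root")
        root = _summary_tree(model)
    else:
        obj = resolve(model, subject_path)
        if subject_kind == "plan_detailed":
            if not isinstance(obj, PlanSetup):
                raise SubjectError(f"{subject_path!r} is not a plan")
            root = _plan_tree(obj, _ROOT_KEY[subject_kind])
        else:
            if not isinstance(obj, StructureSet):
                raise SubjectError(f"{subject_path!r} is not a structure set")
            root = _structure_set_tree(obj, _ROOT_KEY[subject_kind])
    if acquired_at is None:
        acquired_at = (
            _dt.datetime.now(_dt.timezone.utc).replace(microsecond=0).isoformat()
        ).replace("+00:00", "Z")
    return Snapshot(
        subject_kind=subject_kind,
        subject_path=subject_path or "/",
        acquired_at=acquired_at,
        schema_version=SCHEMA_VERSION,
        root=root,
    )


def default_subjects(model: PatientModel) -> List[Tuple[str, str]]:
    """The ``--all`` expansion: patient summary, every plan, every structure set."""
    subjects: List[Tuple[str, str]] = [("patient_summary", "/")]
    for c in model.courses:
        for p in c.plans:
            subjects.append(("plan_detailed", f"course[{c.id}]/plan[{p.id}]"))
    for s in model.structure_sets:
        subjects.append(("structure_set_detailed", f"structure_set[{s.id}]"))
    return subjects


# ---------------------------------------------------------------------------
# XML serialization

def _load_schema(name: str) -> etree.XMLSchema:
    with resources.files("plansnap.schemas").joinpath(name).open("rb") as fh:
        return etree.XMLSchema(etree.parse(fh))


_snapshot_schema: Optional[etree.XMLSchema] = None


def _schema() -> etree.XMLSchema:
    global _snapshot_schema
    if _snapshot_schema is None:
        _snapshot_schema = _load_schema("snapshot.xsd")
    return _snapshot_schema


def _node_to_xml(node: FieldNode, parent: etree._Element) -> None:
    el = etree.SubElement(parent, "node")
    el.set("key", node.key)
    el.set("kind", node.kind)
    if node.ordinal is not None:
        el.set("ordinal", str(node.ordinal))
    if node.kind == "scalar":
        el.text = node.value or ""
    else:
        for c in node.children:
            _node_to_xml(c, el)


def _node_from_xml(el: etree._Element) -> FieldNode:
    kind = el.get("kind")
    ordinal = el.get("ordinal")
    node = FieldNode(
        key=el.get("key"),
        kind=kind,
        ordinal=int(ordinal) if ordinal is not None else None,
    )
    if kind == "scalar":
        node.value = el.text or ""
    else:
        node.children = [_node_from_xml(c) for c in el if c.tag == "node"]
    return node


def snapshot_to_bytes(snapshot: Snapshot) -> bytes:
    root = etree.Element("snapshot")
    root.set("schema_version", snapshot.schema_version)
    root.set("subject_kind", snapshot.subject_kind)
    root.set("subject_path", snapshot.subject_path)
    root.set("acquired_at", snapshot.acquired_at)
    _node_to_xml(snapshot.root, root)
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def write_snapshot_xml(snapshot: Snapshot, path) -> None:
    """Write one snapshot per file; identical snapshots yield identical bytes."""
    Path(path).write_bytes(snapshot_to_bytes(snapshot))


def _check_version(version: Optional[str], path) -> None:
    if not version:
        raise SnapshotFormatError(f"{path}: missing schema_version")
    major = version.split(".", 1)[0]
    if major != SCHEMA_VERSION.split(".", 1)[0]:
        raise SnapshotFormatError(
            f"{path}: unsupported schema_version {version!r} (supported major: "
            f"{SCHEMA_VERSION.split('.', 1)[0]})"
        )


def read_snapshot_xml(path) -> Snapshot:
    """Read and schema-validate a snapshot file.

    Raises :class:`SnapshotFormatError` naming the first offending element on
    any schema violation or unsupported major version.
    """
    try:
        tree = etree.parse(str(path))
    except (OSError, etree.XMLSyntaxError) as e:
        raise SnapshotFormatError(f"{path}: {e}") from e
    root = tree.getroot()
    if root.tag != "snapshot":
        raise SnapshotFormatError(f"{path}: root element is <{root.tag}>, expected <snapshot>")
    _check_version(root.get("schema_version"), path)
    if not _schema().validate(tree):
        err = _schema().error_log[0]
        raise SnapshotFormatError(f"{path}: line {err.line}: {err.message}")
    nodes = [c for c in root if c.tag == "node"]
    return Snapshot(
        subject_kind=root.get("subject_kind"),
        subject_path=root.get("subject_path"),
        acquired_at=root.get("acquired_at"),
        schema_version=root.get("schema_version"),
        root=_node_from_xml(nodes[0]),
    )
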