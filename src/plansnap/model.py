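"""Treatment-planning object model.

The hierarchy mirrors what a planning system exposes to scripts: a patient
holds treatment courses (each holding external-beam plans with beams, a save
history and script-execution logs) and structure sets (each holding contoured
structures). Objects are addressed by *model paths* — slash-separated typed
segments such as ``course[1xLung]/plan[F1LungR]/beam[G180]/monitor_units`` —
which are also the paths mutations and commissioning reports use.

The module provides four services around the types:

* a deterministic synthetic-patient generator (:func:`generate_synthetic_patient`),
* single-locus mutations for commissioning (:func:`apply_mutation`),
* a human-readable directory store that scripts-under-test read and modify
  (:func:`store_model` / :func:`load_model`),
* path resolution and leaf enumeration used by snapshots and the diff oracle.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Iterator, List, Optional, Tuple

from .errors import MutationError, PathError, StoreError
from .geometry import Contour, structure_geometry

STORE_FORMAT = "plansnap-store"
STORE_VERSION = "1"
STORE_FILE = "model.json"

COURSE_INTENTS = ("curative", "palliative", "emergent", "unspecified")
APPROVAL_STATUSES = (
    "unapproved",
    "planning_approved",
    "treatment_approved",
    "rejected",
)
PLAN_TYPES = ("external_beam",)

_ID_BAD = re.compile(r"[\[\]/\s]")


def sanitize_id(raw: str) -> str:
    """Ids appear inside ``type[id]`` path segments: brackets, slashes and
    whitespace are replaced with underscores."""
    return _ID_BAD.sub("_", raw) if raw else "_"


# ---------------------------------------------------------------------------
# Types


@dataclass
class HistoryEntry:
    timestamp: str  # ISO-8601
    user: str
    action: str


@dataclass
class ApplicationScriptLog:
    """Audit record the planning system attaches when a script modifies an object."""

    script_name: str
    timestamp: str  # ISO-8601
    user: str


@dataclass
class Beam:
    id: str
    machine: str = "TB1"
    energy_label: str = "6X"
    monitor_units: float = 100.0
    gantry_angle: float = 0.0
    collimator_angle: float = 0.0
    couch_angle: float = 0.0
    technique: str = "STATIC"
    is_setup_field: bool = False
    mlc_digest: Optional[str] = None


@dataclass
class PlanSetup:
    id: str
    plan_type: str = "external_beam"
    approval_status: str = "unapproved"
    prescribed_dose_per_fraction: float = 2.0  # Gy
    number_of_fractions: int = 0
    structure_set_ref: Optional[str] = None
    beams: List[Beam] = field(default_factory=list)
    history: List[HistoryEntry] = field(default_factory=list)
    script_logs: List[ApplicationScriptLog] = field(default_factory=list)


@dataclass
class Course:
    id: str
    intent: str = "unspecified"
    plans: List[PlanSetup] = field(default_factory=list)


@dataclass
class Structure:
    id: str
    dicom_type: str = "ORGAN"  # e.g. PTV, CTV, ORGAN, EXTERNAL
    color: Tuple[int, int, int] = (255, 0, 0)
    contours: List[Contour] = field(default_factory=list)
    # Derived from contours (see plansnap.geometry); kept on the object so the
    # store round-trips without recomputation.
    volume_cc: float = 0.0
    point_count: int = 0
    geometry_digest: str = ""

    def recompute_geometry(self, slice_thickness: float = 3.0) -> None:
        if self.contours:
            v, n, d = structure_geometry(self.contours, slice_thickness)
        else:
            v, n, d = 0.0, 0, ""
        self.volume_cc, self.point_count, self.geometry_digest = v, n, d


@dataclass
class StructureSet:
    id: str
    image_id: str = ""
    structures: List[Structure] = field(default_factory=list)


@dataclass
class PatientModel:
    patient_id: str
    name: str = ""
    courses: List[Course] = field(default_factory=list)
    structure_sets: List[StructureSet] = field(default_factory=list)


@dataclass
class MutationSpec:
    """One deliberate change to a model, used to commission the diff engine.

    ``target_path`` addresses the locus; ``kind`` is one of ``set_value``
    (path ends in a scalar field), ``rename`` (path ends at an Id-keyed
    object; payload is the new Id), ``add_child`` (path ends at a parent
    object; payload is ``{"kind": <child type>, ...fields}``) and
    ``remove_child`` (path ends at the child to delete).
    """

    target_path: str
    kind: str
    payload: Any = None


# ---------------------------------------------------------------------------
# Validation

def _check_unique(ids: List[str], what: str, where: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise MutationError(f"duplicate {what} Id {i!r} in {where}")
        seen.add(i)


def validate_model(model: PatientModel) -> None:
    """Raise :class:`MutationError` on any invariant breach."""
    _check_unique([c.id for c in model.courses], "course", f"patient {model.patient_id}")
    _check_unique(
        [s.id for s in model.structure_sets], "structure set", f"patient {model.patient_id}"
    )
    for course in model.courses:
        if course.intent not in COURSE_INTENTS:
            raise MutationError(f"invalid course intent {course.intent!r}")
        _check_unique([p.id for p in course.plans], "plan", f"course {course.id}")
        for plan in course.plans:
            if plan.plan_type not in PLAN_TYPES:
                raise MutationError(f"invalid plan_type {plan.plan_type!r}")
            if plan.approval_status not in APPROVAL_STATUSES:
                raise MutationError(f"invalid approval_status {plan.approval_status!r}")
            if plan.number_of_fractions < 0:
                raise MutationError(f"plan {plan.id}: number_of_fractions < 0")
            if plan.prescribed_dose_per_fraction < 0:
                raise MutationError(f"plan {plan.id}: dose per fraction < 0")
            _check_unique([b.id for b in plan.beams], "beam", f"plan {plan.id}")
            for b in plan.beams:
                if b.monitor_units < 0:
                    raise MutationError(f"beam {b.id}: monitor_units < 0")
                for attr in ("gantry_angle", "collimator_angle", "couch_angle"):
                    a = getattr(b, attr)
                    if not (0.0 <= a < 360.0):
                        raise MutationError(f"beam {b.id}: {attr}={a} outside [0,360)")
            last = None
            for h in plan.history:
                if last is not None and h.timestamp < last:
                    raise MutationError(f"plan {plan.id}: history timestamps decrease")
                last = h.timestamp
            for log in plan.script_logs:
                if not log.script_name:
                    raise MutationError(f"plan {plan.id}: empty script_name in log")
    for ss in model.structure_sets:
        _check_unique([s.id for s in ss.structures], "structure", f"structure set {ss.id}")


# ---------------------------------------------------------------------------
# Path grammar and resolution

_SEGMENT = re.compile(r"^([a-z_]+)\[(.+)\]$")

# child type -> (collection attribute, element type, keyed by id?)
_CHILDREN = {
    PatientModel: {
        "course": ("courses", Course, True),
        "structure_set": ("structure_sets", StructureSet, True),
    },
    Course: {"plan": ("plans", PlanSetup, True)},
    PlanSetup: {
        "beam": ("beams", Beam, True),
        "history": ("history", HistoryEntry, False),
        "script_log": ("script_logs", ApplicationScriptLog, False),
    },
    StructureSet: {"structure": ("structures", Structure, True)},
}


def split_path(path: str) -> List[str]:
    path = (path or "").strip().strip("/")
    return [s for s in path.split("/") if s] if path else []


def resolve(model: PatientModel, path: str) -> Any:
    """Resolve a model path to the object or scalar value it addresses.

    Raises :class:`PathError` with the offending segment on failure.
    """
    obj: Any = model
    for seg in split_path(path):
        obj = _step(obj, seg, path)
    return obj


def _step(obj: Any, seg: str, full: str) -> Any:
    m = _SEGMENT.match(seg)
    if m:
        typ, key = m.group(1), m.group(2)
        table = _CHILDREN.get(type(obj), {})
        if typ not in table:
            raise PathError(f"{full!r}: no {typ!r} children under {type(obj).__name__}")
        attr, _cls, keyed = table[typ]
        coll = getattr(obj, attr)
        if keyed:
            for child in coll:
                if child.id == key:
                    return child
            raise PathError(f"{full!r}: no {typ} with Id {key!r}")
        try:
            return coll[int(key)]
        except (ValueError, IndexError):
            raise PathError(f"{full!r}: no {typ}[{key}]") from None
    # plain field name
    if not hasattr(obj, seg) or seg.startswith("_"):
        raise PathError(f"{full!r}: {type(obj).__name__} has no field {seg!r}")
    return getattr(obj, seg)


def _resolve_parent(model: PatientModel, path: str) -> Tuple[Any, str]:
    segs = split_path(path)
    if not segs:
        raise PathError("empty target path")
    obj: Any = model
    for seg in segs[:-1]:
        obj = _step(obj, seg, path)
    return obj, segs[-1]


# ---------------------------------------------------------------------------
# Mutations

_SCALAR_FIELDS = {
    PatientModel: ("patient_id", "name"),
    Course: ("intent",),
    PlanSetup: (
        "plan_type",
        "approval_status",
        "prescribed_dose_per_fraction",
        "number_of_fractions",
        "structure_set_ref",
    ),
    Beam: (
        "machine",
        "energy_label",
        "monitor_units",
        "gantry_angle",
        "collimator_angle",
        "couch_angle",
        "technique",
        "is_setup_field",
        "mlc_digest",
    ),
    StructureSet: ("image_id",),
    Structure: ("dicom_type", "color"),
    HistoryEntry: ("timestamp", "user", "action"),
    ApplicationScriptLog: ("script_name", "timestamp", "user"),
}

_TEMPLATES = {
    "course": Course,
    "plan": PlanSetup,
    "beam": Beam,
    "structure_set": StructureSet,
    "structure": Structure,
    "history": HistoryEntry,
    "script_log": ApplicationScriptLog,
}


def apply_mutation(model: PatientModel, spec: MutationSpec) -> PatientModel:
    """Return a new model differing from *model* in exactly the mutated locus.

    The input model is never modified. Invariants are re-checked on the
    result; a violating payload raises :class:`MutationError`.
    """
    out = copy.deepcopy(model)
    if spec.kind == "set_value":
        parent, leaf = _resolve_parent(out, spec.target_path)
        if leaf not in _SCALAR_FIELDS.get(type(parent), ()):
            raise PathError(
                f"{spec.target_path!r}: {leaf!r} is not a mutable scalar field"
            )
        setattr(parent, leaf, _coerce(getattr(parent, leaf), spec.payload))
    elif spec.kind == "rename":
        target = resolve(out, spec.target_path)
        if not hasattr(target, "id"):
            raise PathError(f"{spec.target_path!r} does not address an Id-keyed object")
        new_id = str(spec.payload)
        if new_id == target.id:
            raise MutationError(f"rename payload equals current Id {new_id!r}")
        target.id = new_id
    elif spec.kind == "add_child":
        parent = resolve(out, spec.target_path) if split_path(spec.target_path) else out
        payload = dict(spec.payload or {})
        kind = payload.pop("kind", None)
        table = _CHILDREN.get(type(parent), {})
        if kind not in table:
            raise MutationError(
                f"cannot add {kind!r} child under {type(parent).__name__}"
            )
        attr, cls, _keyed = table[kind]
        if cls is Structure and "contours" in payload:
            payload["contours"] = [(z, [tuple(p) for p in pts]) for z, pts in payload["contours"]]
        if cls is Structure and "color" in payload:
            payload["color"] = tuple(payload["color"])
        child = cls(**payload)
        getattr(parent, attr).append(child)
    elif spec.kind == "remove_child":
        parent, seg = _resolve_parent(out, spec.target_path)
        m = _SEGMENT.match(seg)
        if not m:
            raise PathError(f"{spec.target_path!r} does not address a child object")
        typ, key = m.group(1), m.group(2)
        table = _CHILDREN.get(type(parent), {})
        if typ not in table:
            raise PathError(f"{spec.target_path!r}: no {typ!r} children here")
        attr, _cls, keyed = table[typ]
        coll = getattr(parent, attr)
        if keyed:
            idx = next((i for i, c in enumerate(coll) if c.id == key), None)
            if idx is None:
                raise PathError(f"{spec.target_path!r}: no {typ} with Id {key!r}")
        else:
            try:
                idx = int(key)
                coll[idx]
            except (ValueError, IndexError):
                raise PathError(f"{spec.target_path!r}: no {typ}[{key}]") from None
        del coll[idx]
    else:
        raise MutationError(f"unknown mutation kind {spec.kind!r}")
    validate_model(out)
    return out


def _coerce(current: Any, payload: Any) -> Any:
    """Coerce a payload to the type of the value it replaces."""
    if current is None or payload is None:
        return payload
    if isinstance(current, bool):
        return bool(payload)
    if isinstance(current, int) and not isinstance(current, bool):
        return int(payload)
    if isinstance(current, float):
        return float(payload)
    if isinstance(current, tuple):
        return tuple(payload)
    return str(payload)


# ---------------------------------------------------------------------------
# Leaf / container enumeration (used by commissioning and oracles)

def iter_leaves(model: PatientModel) -> Iterator[Tuple[str, Any]]:
    """Yield ``(model_path, value)`` for every snapshot-visible scalar leaf.

    Optional fields that are absent (``None``) are skipped; contours are not
    leaves (they surface through the derived geometry fields)."""

    def emit(obj: Any, prefix: str) -> Iterator[Tuple[str, Any]]:
        for f in _SCALAR_FIELDS.get(type(obj), ()):
            v = getattr(obj, f)
            if v is None:
                continue
            yield (f"{prefix}{f}", v)
        for typ, (attr, _cls, keyed) in _CHILDREN.get(type(obj), {}).items():
            for i, child in enumerate(getattr(obj, attr)):
                key = child.id if keyed else str(i)
                yield from emit(child, f"{prefix}{typ}[{key}]/")

    yield from emit(model, "")


def iter_keyed_objects(model: PatientModel) -> Iterator[Tuple[str, Any]]:
    """Yield ``(model_path, object)`` for every Id-keyed object (rename targets)."""

    def emit(obj: Any, prefix: str) -> Iterator[Tuple[str, Any]]:
        for typ, (attr, _cls, keyed) in _CHILDREN.get(type(obj), {}).items():
            if not keyed:
                continue
            for child in getattr(obj, attr):
                path = f"{prefix}{typ}[{child.id}]"
                yield (path, child)
                yield from emit(child, path + "/")

    yield from emit(model, "")


def permute_siblings(model: PatientModel, rng) -> PatientModel:
    """Return a copy with every Id-keyed sibling list shuffled.

    Index-keyed collections (history, script logs) keep their order: for them
    order is identity."""
    out = copy.deepcopy(model)
    rng.shuffle(out.courses)
    rng.shuffle(out.structure_sets)
    for c in out.courses:
        rng.shuffle(c.plans)
        for p in c.plans:
            rng.shuffle(p.beams)
    for ss in out.structure_sets:
        rng.shuffle(ss.structures)
    return out


def sample_set_value_mutations(model: PatientModel, k: int, rng) -> List[MutationSpec]:
    """Sample *k* distinct-leaf ``set_value`` mutations with guaranteed-new,
    invariant-preserving payloads (used by commissioning-style drivers)."""
    leaves = [lv for lv in iter_leaves(model) if _perturbable(lv[0])]
    rng.shuffle(leaves)
    return [
        MutationSpec(path, "set_value", perturb_value(path, value))
        for path, value in leaves[: min(k, len(leaves))]
    ]


def _perturbable(path: str) -> bool:
    leaf = path.rsplit("/", 1)[-1]
    # geometry fields are derived; plan_type has a single legal value
    return leaf not in ("volume_cc", "point_count", "geometry_digest", "plan_type")


def perturb_value(path: str, value: Any) -> Any:
    """A deterministic, invariant-preserving payload differing from *value*."""
    leaf = path.rsplit("/", 1)[-1]
    if leaf == "approval_status":
        i = APPROVAL_STATUSES.index(value)
        return APPROVAL_STATUSES[(i + 1) % len(APPROVAL_STATUSES)]
    if leaf == "intent":
        i = COURSE_INTENTS.index(value)
        return COURSE_INTENTS[(i + 1) % len(COURSE_INTENTS)]
    if leaf.endswith("_angle"):
        return round((float(value) + 5.0) % 360.0, 1)
    if leaf == "timestamp":
        # bumping seconds by one keeps histories non-decreasing
        return value[:18] + ("1" if value[18] != "1" else "2") + value[19:]
    if isinstance(value, bool):
        return not value
    if isinstance(value, int):
        return value + 1
    if isinstance(value, float):
        return round(value + 1.5, 6)
    if isinstance(value, tuple):
        r, g, b = value
        return ((r + 128) % 256, g, b)
    return str(value) + "~X"


# ---------------------------------------------------------------------------
# Synthetic patient generator

_COMPLEXITIES = ("minimal", "typical", "stress")

_COURSE_POOL = ["1xLung", "2xBrain", "3xBreast", "4xProstate", "C_QA", "TEST_A", "TEST_B",
                "5xHN", "6xRectum", "7xSpine"]
_PLAN_POOL = ["F1LungR", "F2BrainL", "F3Breast", "PlanA", "PlanB", "QA_Plan",
              "F4Prost", "F5HN", "F6Rect", "F7Spine", "Boost1", "Boost2"]
_STRUCT_POOL = ["PTV", "CTV", "GTV", "External", "SpinalCord", "Lung_L", "Lung_R",
                "Heart", "Esophagus", "Brain", "Liver", "Kidney_L", "Kidney_R",
                "Bladder", "Rectum", "Femur_L", "Femur_R", "Parotid_L", "Parotid_R"]
_TYPE_FOR = {"PTV": "PTV", "CTV": "CTV", "GTV": "GTV", "External": "EXTERNAL"}
_MACHINES = ["TB1", "TB2", "Edge1"]
_ENERGIES = ["6X", "10X", "15X", "6FFF"]
_USERS = ["planner1", "planner2", "physicist", "resident"]


def _pick_id(pool: List[str], used: set, rng, prefix: str) -> str:
    candidates = [p for p in pool if p not in used]
    new_id = rng.choice(candidates) if candidates else f"{prefix}{len(used) + 1}"
    while new_id in used:
        new_id += "x"
    used.add(new_id)
    return new_id


def _timestamp(base_day: int, minute: int) -> str:
    day = 1 + base_day % 28
    h, m = divmod(minute % 1440, 60)
    return f"2022-06-{day:02d}T{h:02d}:{m:02d}:00Z"


def generate_synthetic_patient(seed: int, complexity: str = "typical") -> PatientModel:
    """Deterministic synthetic patient at one of three complexity tiers.

    ``minimal`` is the smallest legal model (1 course, 1 unapproved plan,
    1 beam, no structure sets); ``typical`` resembles a routine clinical
    patient (2-3 courses, >=2 plans with mixed approval statuses, one
    structure set with several contoured structures, 2-4 beams per plan);
    ``stress`` has >=5 courses and >=40 structures to exercise scaling.
    """
    import random

    if complexity not in _COMPLEXITIES:
        raise ValueError(f"unknown complexity {complexity!r}")
    rng = random.Random(4 * int(seed) + _COMPLEXITIES.index(complexity))
    pid = f"PT{rng.randrange(10_000, 99_999)}"
    name = f"ZZ_SYNTH^{rng.choice(['Alpha', 'Bravo', 'Carol', 'Dmitri', 'Elena'])}"
    model = PatientModel(patient_id=pid, name=name)

    if complexity == "minimal":
        model.courses.append(
            Course(id="C1", intent="unspecified", plans=[PlanSetup(id="P1", beams=[Beam(id="B1")])])
        )
        validate_model(model)
        return model

    n_courses = rng.randint(2, 3) if complexity == "typical" else rng.randint(5, 7)
    n_sets = 1 if complexity == "typical" else rng.randint(3, 4)
    base_day = rng.randrange(28)

    used_ss: set = set()
    for si in range(n_sets):
        ss_id = f"CT_{si + 1}"
        used_ss.add(ss_id)
        ss = StructureSet(id=ss_id, image_id=f"IMG{rng.randrange(100, 999)}")
        n_struct = rng.randint(3, 6) if complexity == "typical" else rng.randint(14, 22)
        used_st: set = set()
        for _ in range(n_struct):
            sid = _pick_id(_STRUCT_POOL, used_st, rng, "Ring_")
            st = Structure(
                id=sid,
                dicom_type=_TYPE_FOR.get(sid, "ORGAN"),
                color=(rng.randrange(256), rng.randrange(256), rng.randrange(256)),
            )
            cx, cy = rng.uniform(-80, 80), rng.uniform(-80, 80)
            radius = rng.uniform(5, 40)
            n_pts = rng.randint(5, 9)
            z0 = rng.uniform(-100, 0)
            import math

            for slice_i in range(rng.randint(2, 4)):
                z = z0 + 3.0 * slice_i
                pts = [
                    (
                        round(cx + radius * math.cos(2 * math.pi * j / n_pts), 2),
                        round(cy + radius * math.sin(2 * math.pi * j / n_pts), 2),
                    )
                    for j in range(n_pts)
                ]
                st.contours.append((round(z, 2), pts))
            st.recompute_geometry(slice_thickness=3.0)
            ss.structures.append(st)
        model.structure_sets.append(ss)

    used_courses: set = set()
    used_plans: set = set()
    plan_counter = 0
    for _ in range(n_courses):
        course = Course(
            id=_pick_id(_COURSE_POOL, used_courses, rng, "C"),
            intent=rng.choice(COURSE_INTENTS),
        )
        for _ in range(rng.randint(1, 2)):
            # cycle approval statuses so the patient always mixes them
            status = APPROVAL_STATUSES[plan_counter % len(APPROVAL_STATUSES)]
            plan = PlanSetup(
                id=_pick_id(_PLAN_POOL, used_plans, rng, "P"),
                approval_status=status,
                prescribed_dose_per_fraction=rng.choice([1.8, 2.0, 2.67, 3.0, 8.0]),
                number_of_fractions=rng.choice([1, 5, 10, 15, 25, 30]),
                structure_set_ref=rng.choice(sorted(used_ss)) if used_ss and rng.random() < 0.8 else None,
            )
            plan_counter += 1
            used_beams: set = set()
            for _b in range(rng.randint(2, 4) if complexity == "typical" else rng.randint(2, 5)):
                angle = rng.randrange(0, 3600) / 10.0
                bid = f"G{angle:05.1f}".replace(".", "")
                while bid in used_beams:
                    bid += "x"
                used_beams.add(bid)
                plan.beams.append(
                    Beam(
                        id=bid,
                        machine=rng.choice(_MACHINES),
                        energy_label=rng.choice(_ENERGIES),
                        monitor_units=round(rng.uniform(40, 350), 1),
                        gantry_angle=angle,
                        collimator_angle=rng.randrange(0, 3600) / 10.0,
                        couch_angle=rng.choice([0.0, 0.0, 0.0, 90.0, 270.0]),
                        technique=rng.choice(["STATIC", "ARC"]),
                        is_setup_field=False,
                        mlc_digest=(f"{rng.getrandbits(64):016x}" if rng.random() < 0.7 else None),
                    )
                )
            minute = rng.randrange(0, 600)
            for hi in range(rng.randint(1, 3)):
                plan.history.append(
                    HistoryEntry(
                        timestamp=_timestamp(base_day, minute),
                        user=rng.choice(_USERS),
                        action=rng.choice(["Plan created", "Plan modified", "Status changed"]),
                    )
                )
                minute += rng.randrange(5, 120)
            if rng.random() < 0.3:
                plan.script_logs.append(
                    ApplicationScriptLog(
                        script_name=rng.choice(["AutoPlan", "NomenclatureCheck"]),
                        timestamp=_timestamp(base_day, minute),
                        user=rng.choice(_USERS),
                    )
                )
            course.plans.append(plan)
        model.courses.append(course)
    validate_model(model)
    return model


# ---------------------------------------------------------------------------
# Directory store

def _to_json(obj: Any) -> Any:
    if isinstance(obj, PatientModel):
        return {
            "patient_id": obj.patient_id,
            "name": obj.name,
            "courses": [_to_json(c) for c in obj.courses],
            "structure_sets": [_to_json(s) for s in obj.structure_sets],
        }
    if isinstance(obj, Course):
        return {"id": obj.id, "intent": obj.intent, "plans": [_to_json(p) for p in obj.plans]}
    if isinstance(obj, PlanSetup):
        return {
            "id": obj.id,
            "plan_type": obj.plan_type,
            "approval_status": obj.approval_status,
            "prescribed_dose_per_fraction": obj.prescribed_dose_per_fraction,
            "number_of_fractions": obj.number_of_fractions,
            "structure_set_ref": obj.structure_set_ref,
            "beams": [_to_json(b) for b in obj.beams],
            "history": [vars(h).copy() for h in obj.history],
            "script_logs": [vars(l).copy() for l in obj.script_logs],
        }
    if isinstance(obj, Beam):
        return vars(obj).copy()
    if isinstance(obj, StructureSet):
        return {"id": obj.id, "image_id": obj.image_id,
                "structures": [_to_json(s) for s in obj.structures]}
    if isinstance(obj, Structure):
        return {
            "id": obj.id,
            "dicom_type": obj.dicom_type,
            "color": list(obj.color),
            "contours": [[z, [list(p) for p in pts]] for z, pts in obj.contours],
            "volume_cc": obj.volume_cc,
            "point_count": obj.point_count,
            "geometry_digest": obj.geometry_digest,
        }
    raise TypeError(type(obj))


def _require(d: Dict, key: str, where: str) -> Any:
    if key not in d:
        raise StoreError(f"{where}: missing key {key!r}")
    return d[key]


def _from_json(d: Dict) -> PatientModel:
    model = PatientModel(
        patient_id=_require(d, "patient_id", STORE_FILE), name=d.get("name", "")
    )
    for cd in d.get("courses", []):
        course = Course(id=_require(cd, "id", "course"), intent=cd.get("intent", "unspecified"))
        for pd in cd.get("plans", []):
            plan = PlanSetup(
                id=_require(pd, "id", "plan"),
                plan_type=pd.get("plan_type", "external_beam"),
                approval_status=pd.get("approval_status", "unapproved"),
                prescribed_dose_per_fraction=float(pd.get("prescribed_dose_per_fraction", 0.0)),
                number_of_fractions=int(pd.get("number_of_fractions", 0)),
                structure_set_ref=pd.get("structure_set_ref"),
            )
            for bd in pd.get("beams", []):
                plan.beams.append(Beam(**bd))
            for hd in pd.get("history", []):
                plan.history.append(HistoryEntry(**hd))
            for ld in pd.get("script_logs", []):
                plan.script_logs.append(ApplicationScriptLog(**ld))
            course.plans.append(plan)
        model.courses.append(course)
    for sd in d.get("structure_sets", []):
        ss = StructureSet(id=_require(sd, "id", "structure_set"), image_id=sd.get("image_id", ""))
        for st in sd.get("structures", []):
            ss.structures.append(
                Structure(
                    id=_require(st, "id", "structure"),
                    dicom_type=st.get("dicom_type", "ORGAN"),
                    color=tuple(st.get("color", (255, 0, 0))),
                    contours=[(z, [tuple(p) for p in pts]) for z, pts in st.get("contours", [])],
                    volume_cc=float(st.get("volume_cc", 0.0)),
                    point_count=int(st.get("point_count", 0)),
                    geometry_digest=st.get("geometry_digest", ""),
                )
            )
        model.structure_sets.append(ss)
    return model


def store_model(model: PatientModel, directory) -> None:
    """Persist *model* under *directory* as a single pretty-printed JSON file.

    The layout is one directory per patient containing ``model.json`` with a
    format marker and store version; writing is byte-deterministic.
    """
    validate_model(model)
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    doc = {"format": STORE_FORMAT, "version": STORE_VERSION, "patient": _to_json(model)}
    (d / STORE_FILE).write_text(
        json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def load_model(directory) -> PatientModel:
    """Load a model written by :func:`store_model`; invalid stores raise
    :class:`StoreError` naming the offending file."""
    f = Path(directory) / STORE_FILE
    if not f.is_file():
        raise StoreError(f"no model store at {f}")
    try:
        doc = json.loads(f.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as e:
        raise StoreError(f"corrupt store file {f}: {e}") from e
    if not isinstance(doc, dict) or doc.get("format") != STORE_FORMAT:
        raise StoreError(f"{f} is not a {STORE_FORMAT} file")
    if str(doc.get("version")) != STORE_VERSION:
        raise StoreError(f"{f}: unsupported store version {doc.get('version')!r}")
    try:
        model = _from_json(doc.get("patient", {}))
        validate_model(model)
    except (TypeError, ValueError, MutationError) as e:
        raise StoreError(f"corrupt store file {f}: {e}") from e
    return model
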