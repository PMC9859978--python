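"""Read DICOM-RT files (RTPLAN / RTSTRUCT) into a :class:`PatientModel`.

This is the vendor-independent front door for real planning data: each
RTPLAN becomes a plan (beams from BeamSequence, monitor units from the
FractionGroup beam metersets), each RTSTRUCT a structure set. DICOM has no
course object, so plans land in a synthesized course ``C1``. RTDOSE files
are tolerated and skipped; anything else is a format error naming the path.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, List, Optional

import pydicom
from pydicom.errors import InvalidDicomError

from .errors import DicomFormatError
from .geometry import infer_slice_thickness
from .model import (
    Beam,
    Course,
    PatientModel,
    PlanSetup,
    Structure,
    StructureSet,
    sanitize_id,
    validate_model,
)

_DEFAULT_COURSE = "C1"

_APPROVAL_MAP = {
    "APPROVED": "treatment_approved",
    "REVIEWED": "planning_approved",
    "UNAPPROVED": "unapproved",
    "REJECTED": "rejected",
}


def _angle(value, default: float = 0.0) -> float:
    try:
        return float(value) % 360.0
    except (TypeError, ValueError):
        return default


def _read_plan(ds: pydicom.Dataset, path: str) -> PlanSetup:
    label = str(getattr(ds, "RTPlanLabel", "") or getattr(ds, "RTPlanName", "") or "Plan")
    plan = PlanSetup(id=sanitize_id(label))
    plan.approval_status = _APPROVAL_MAP.get(
        str(getattr(ds, "ApprovalStatus", "UNAPPROVED")).upper(), "unapproved"
    )

    metersets = {}
    fractions = 0
    for fg in getattr(ds, "FractionGroupSequence", []) or []:
        fractions = int(getattr(fg, "NumberOfFractionsPlanned", 0) or 0)
        for rb in getattr(fg, "ReferencedBeamSequence", []) or []:
            num = getattr(rb, "ReferencedBeamNumber", None)
            mu = getattr(rb, "BeamMeterset", None)
            if num is not None and mu is not None:
                metersets[int(num)] = float(mu)
    plan.number_of_fractions = fractions

    for dr in getattr(ds, "DoseReferenceSequence", []) or []:
        dose = getattr(dr, "TargetPrescriptionDose", None)
        if dose is not None and fractions > 0:
            plan.prescribed_dose_per_fraction = round(float(dose) / fractions, 6)
            break

    ref_ss = getattr(ds, "ReferencedStructureSetSequence", []) or []
    if ref_ss:
        uid = getattr(ref_ss[0], "ReferencedSOPInstanceUID", None)
        if uid:
            plan.structure_set_ref = sanitize_id(str(uid))

    for item in getattr(ds, "BeamSequence", []) or []:
        num = int(getattr(item, "BeamNumber", 0) or 0)
        bid = str(getattr(item, "BeamName", "") or f"Beam{num}")
        beam = Beam(
            id=sanitize_id(bid),
            machine=str(getattr(item, "TreatmentMachineName", "") or ""),
            monitor_units=metersets.get(num, 0.0),
            technique=str(getattr(item, "BeamType", "") or ""),
            is_setup_field=(
                str(getattr(item, "TreatmentDeliveryType", "TREATMENT")).upper() == "SETUP"
            ),
        )
        cps = getattr(item, "ControlPointSequence", []) or []
        if cps:
            cp0 = cps[0]
            energy = getattr(cp0, "NominalBeamEnergy", None)
            if energy is not None:
                beam.energy_label = f"{float(energy):g}X"
            beam.gantry_angle = _angle(getattr(cp0, "GantryAngle", 0.0))
            beam.collimator_angle = _angle(getattr(cp0, "BeamLimitingDeviceAngle", 0.0))
            beam.couch_angle = _angle(getattr(cp0, "PatientSupportAngle", 0.0))
        plan.beams.append(beam)
    if not plan.beams:
        raise DicomFormatError(f"{path}: RTPLAN has no BeamSequence")
    return plan


def _read_structure_set(ds: pydicom.Dataset, path: str) -> StructureSet:
    label = str(getattr(ds, "StructureSetLabel", "") or "StructureSet")
    ss = StructureSet(id=sanitize_id(label))
    frames = getattr(ds, "ReferencedFrameOfReferenceSequence", []) or []
    if frames:
        ss.image_id = sanitize_id(str(getattr(frames[0], "FrameOfReferenceUID", "") or ""))

    names = {}
    for roi in getattr(ds, "StructureSetROISequence", []) or []:
        names[int(roi.ROINumber)] = str(getattr(roi, "ROIName", "") or f"ROI{roi.ROINumber}")
    types = {}
    for obs in getattr(ds, "RTROIObservationsSequence", []) or []:
        num = getattr(obs, "ReferencedROINumber", None)
        if num is not None:
            types[int(num)] = str(getattr(obs, "RTROIInterpretedType", "") or "ORGAN")

    for rc in getattr(ds, "ROIContourSequence", []) or []:
        num = int(getattr(rc, "ReferencedROINumber", 0) or 0)
        st = Structure(
            id=sanitize_id(names.get(num, f"ROI{num}")),
            dicom_type=types.get(num, "ORGAN") or "ORGAN",
        )
        color = getattr(rc, "ROIDisplayColor", None)
        if color is not None and len(color) == 3:
            st.color = tuple(int(c) for c in color)
        for contour in getattr(rc, "ContourSequence", []) or []:
            data = [float(v) for v in (getattr(contour, "ContourData", []) or [])]
            if len(data) < 9 or len(data) % 3:
                continue
            pts = [(data[i], data[i + 1]) for i in range(0, len(data), 3)]
            st.contours.append((data[2], pts))
        if st.contours:
            st.recompute_geometry(infer_slice_thickness(st.contours))
        ss.structures.append(st)
    return ss


def load_dicom_rt(file_paths: Iterable) -> PatientModel:
    """Build one patient model from a set of RTPLAN/RTSTRUCT files.

    Files must share one PatientID (conflict is an input error); RTDOSE is
    skipped. Plans are placed under a synthesized course ``C1``.
    """
    paths = [Path(p) for p in file_paths]
    if not paths:
        raise DicomFormatError("no input files given")
    patient_id: Optional[str] = None
    patient_name = ""
    plans: List[PlanSetup] = []
    structure_sets: List[StructureSet] = []
    for p in paths:
        try:
            ds = pydicom.dcmread(str(p))
        except (InvalidDicomError, OSError, ValueError) as e:
            raise DicomFormatError(f"{p}: not a readable DICOM file ({e})") from e
        modality = str(getattr(ds, "Modality", "")).upper()
        if modality not in ("RTPLAN", "RTSTRUCT", "RTDOSE"):
            raise DicomFormatError(f"{p}: modality {modality or '?'} is not an RT object")
        pid = str(getattr(ds, "PatientID", "") or "")
        if patient_id is None:
            patient_id = pid
            patient_name = str(getattr(ds, "PatientName", "") or "")
        elif pid != patient_id:
            raise DicomFormatError(
                f"{p}: PatientID {pid!r} conflicts with {patient_id!r}"
            )
        if modality == "RTPLAN":
            plans.append(_read_plan(ds, str(p)))
        elif modality == "RTSTRUCT":
            structure_sets.append(_read_structure_set(ds, str(p)))
    model = PatientModel(patient_id=patient_id or "UNKNOWN", name=patient_name)
    if plans:
        model.courses.append(Course(id=_DEFAULT_COURSE, plans=plans))
    model.structure_sets = structure_sets
    validate_model(model)
    return model
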