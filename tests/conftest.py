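import pydicom
import pytest
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import generate_uid

from plansnap.harness import renaming_example_model
from plansnap.model import generate_synthetic_patient


@pytest.fixture(scope="session")
def typical_model():
    return generate_synthetic_patient(7, "typical")


@pytest.fixture
def minimal_model():
    return generate_synthetic_patient(0, "minimal")


@pytest.fixture
def rename_model():
    return renaming_example_model()


# ---------------------------------------------------------------------------
# DICOM fixture writers (binary files are created at test time only)

RTPLAN_SOP = "1.2.840.10008.5.1.4.1.1.481.5"
RTSTRUCT_SOP = "1.2.840.10008.5.1.4.1.1.481.3"
RTDOSE_SOP = "1.2.840.10008.5.1.4.1.1.481.2"


def _base_dataset(modality, sop_class, patient_id="PT123"):
    ds = Dataset()
    ds.PatientID = patient_id
    ds.PatientName = "ZZ^Test"
    ds.Modality = modality
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = generate_uid()
    return ds


def save_dicom(ds, path):
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = ds.SOPClassUID
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
    fds = FileDataset(str(path), ds, file_meta=meta, preamble=b"\0" * 128)
    fds.save_as(str(path), enforce_file_format=True)
    return path


def make_rtplan(path, patient_id="PT123", label="TestPlan",
                beams=(("G090", 90.0, 120.0), ("G270", 270.0, 135.5)),
                fractions=5, prescription=40.0):
    ds = _base_dataset("RTPLAN", RTPLAN_SOP, patient_id)
    ds.RTPlanLabel = label
    ds.ApprovalStatus = "UNAPPROVED"
    fg = Dataset()
    fg.NumberOfFractionsPlanned = fractions
    refs = []
    seq = []
    for num, (name, gantry, mu) in enumerate(beams, start=1):
        rb = Dataset()
        rb.ReferencedBeamNumber = num
        rb.BeamMeterset = mu
        refs.append(rb)
        b = Dataset()
        b.BeamNumber = num
        b.BeamName = name
        b.TreatmentMachineName = "TB1"
        b.BeamType = "STATIC"
        b.TreatmentDeliveryType = "TREATMENT"
        cp = Dataset()
        cp.NominalBeamEnergy = 6.0
        cp.GantryAngle = gantry
        cp.BeamLimitingDeviceAngle = 0.0
        cp.PatientSupportAngle = 0.0
        b.ControlPointSequence = [cp]
        seq.append(b)
    fg.ReferencedBeamSequence = refs
    ds.FractionGroupSequence = [fg]
    ds.BeamSequence = seq
    dr = Dataset()
    dr.TargetPrescriptionDose = prescription
    ds.DoseReferenceSequence = [dr]
    return save_dicom(ds, path)


def make_rtstruct(path, patient_id="PT123", label="CT_1",
                  rois=(("PTV", "PTV", 2), ("Cord", "ORGAN", 3), ("External", "EXTERNAL", 2))):
    """Each roi: (name, type, n_slices); square 10x10 contours, 3 mm apart."""
    ds = _base_dataset("RTSTRUCT", RTSTRUCT_SOP, patient_id)
    ds.StructureSetLabel = label
    roi_seq, contour_seq, obs_seq = [], [], []
    for num, (name, rtype, n_slices) in enumerate(rois, start=1):
        r = Dataset()
        r.ROINumber = num
        r.ROIName = name
        roi_seq.append(r)
        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ROIDisplayColor = [0, 255, 0]
        contours = []
        for zi in range(n_slices):
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            pts = [(0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0)]
            c.ContourData = [v for x, y in pts for v in (x, y, 3.0 * zi)]
            c.NumberOfContourPoints = len(pts)
            contours.append(c)
        rc.ContourSequence = contours
        contour_seq.append(rc)
        o = Dataset()
        o.ReferencedROINumber = num
        o.RTROIInterpretedType = rtype
        obs_seq.append(o)
    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.RTROIObservationsSequence = obs_seq
    return save_dicom(ds, path)


def make_rtdose(path, patient_id="PT123"):
    ds = _base_dataset("RTDOSE", RTDOSE_SOP, patient_id)
    return save_dicom(ds, path)


@pytest.fixture
def rtplan_file(tmp_path):
    return make_rtplan(tmp_path / "plan.dcm")


@pytest.fixture
def rtstruct_file(tmp_path):
    return make_rtstruct(tmp_path / "ss.dcm")
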