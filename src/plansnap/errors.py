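"""Exception hierarchy.

Every error raised by plansnap derives from :class:`PlanSnapError` so that
callers (and the CLI) can distinguish tool errors from programming errors.
"""


class PlanSnapError(Exception):
    """Base class for all plansnap errors."""


class PathError(PlanSnapError):
    """A model path (``course[C1]/plan[P1]/...``) did not resolve."""


class MutationError(PlanSnapError):
    """A mutation would violate a model invariant (e.g. duplicate Id)."""


class GeometryError(PlanSnapError):
    """Invalid contour geometry (e.g. a polygon with fewer than 3 points)."""


class StoreError(PlanSnapError):
    """Missing or corrupt model store; the message names the offending file."""


class DicomFormatError(PlanSnapError):
    """A file is unreadable or not an RT object; the message names the path."""


class SnapshotFormatError(PlanSnapError):
    """A snapshot XML file violates the schema or has an unsupported version."""


class SubjectError(PlanSnapError):
    """Snapshot subject kind does not match the object at subject_path."""


class ComparisonError(PlanSnapError):
    """Snapshots are not comparable (subject kinds differ, duplicate keys...)."""


class ProtocolError(PlanSnapError):
    """Malformed test-protocol file or invalid protocol structure."""


class CaseError(PlanSnapError):
    """A test case could not be run (missing store, corrupt state...)."""


class CommissioningError(PlanSnapError):
    """Commissioning preconditions violated or the detection gate failed."""
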