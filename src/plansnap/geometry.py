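"""Contour geometry: slice areas, volumes, and change-sensitive digests.

Structures are contoured as planar polygons on axial slices (coordinates in
mm, one z-plane per contour). Detailed structure-set snapshots do not carry
raw coordinates; instead they carry three derived fields computed here:

* ``volume_cc`` — sum over slices of (total shoelace area x slice thickness),
  converted from mm^3 to cm^3;
* ``point_count`` — total number of contour points;
* ``geometry_digest`` — SHA-256 of a canonical byte encoding of the contours,
  so that ANY geometric change (beyond 1e-3 mm rounding) flips the digest
  while representational changes (polygon order, cyclic vertex rotation,
  orientation reversal) do not.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, Sequence, Tuple

import numpy as np

from .errors import GeometryError

# One contour: (z_mm, [(x_mm, y_mm), ...])
Contour = Tuple[float, Sequence[Tuple[float, float]]]

#: Coordinates are rounded to this many decimals (1e-3 mm) before hashing.
ROUND_DECIMALS = 3


def polygon_area(points: Sequence[Tuple[float, float]]) -> float:
    """Absolute shoelace area (mm^2) of a planar polygon."""
    if len(points) < 3:
        raise GeometryError(f"polygon has {len(points)} point(s); need >= 3")
    arr = np.asarray(points, dtype=float)
    x, y = arr[:, 0], arr[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def _canonical_ring(points: Sequence[Tuple[float, float]]) -> Tuple[Tuple[float, float], ...]:
    """Canonical form of a polygon ring, invariant to cyclic rotation and
    orientation reversal: rotate so the lexicographically smallest vertex is
    first, then pick the lexicographically smaller of the two directions."""
    pts = [
        (round(float(x), ROUND_DECIMALS), round(float(y), ROUND_DECIMALS))
        for x, y in points
    ]
    if len(pts) < 3:
        raise GeometryError(f"polygon has {len(pts)} point(s); need >= 3")
    n = len(pts)
    start = min(range(n), key=lambda i: pts[i])
    fwd = tuple(pts[(start + i) % n] for i in range(n))
    rev_pts = list(reversed(pts))
    rstart = min(range(n), key=lambda i: rev_pts[i])
    rev = tuple(rev_pts[(rstart + i) % n] for i in range(n))
    return min(fwd, rev)


def canonical_contours(contours: Iterable[Contour]):
    """Rounded, canonically ordered contour list: polygons sorted by
    (z, first canonical point), each ring in canonical form."""
    canon = []
    for z, points in contours:
        ring = _canonical_ring(points)
        canon.append((round(float(z), ROUND_DECIMALS), ring))
    canon.sort(key=lambda c: (c[0], c[1]))
    return canon


def geometry_digest(contours: Iterable[Contour]) -> str:
    """SHA-256 hex digest of the canonical contour encoding."""
    h = hashlib.sha256()
    for z, ring in canonical_contours(contours):
        h.update(f"z={z:.3f}".encode())
        for x, y in ring:
            h.update(f";{x:.3f},{y:.3f}".encode())
        h.update(b"\n")
    return h.hexdigest()


def structure_geometry(
    contours: Sequence[Contour], slice_thickness: float
) -> Tuple[float, int, str]:
    """Compute ``(volume_cc, point_count, geometry_digest)`` for a contour set.

    Volume uses a slab model: each slice contributes its total polygon area
    times ``slice_thickness`` (mm); overlapping polygons on one slice simply
    add (holes are not modelled).
    """
    if slice_thickness <= 0:
        raise GeometryError(f"slice_thickness must be > 0, got {slice_thickness}")
    slice_area: dict = {}
    point_count = 0
    for z, points in contours:
        area = polygon_area(points)
        zr = round(float(z), ROUND_DECIMALS)
        slice_area[zr] = slice_area.get(zr, 0.0) + area
        point_count += len(points)
    volume_mm3 = sum(slice_area.values()) * float(slice_thickness)
    volume_cc = round(volume_mm3 / 1000.0, 6)
    return volume_cc, point_count, geometry_digest(contours)


def infer_slice_thickness(contours: Sequence[Contour], default: float = 3.0) -> float:
    """Median spacing of distinct contour z-planes; *default* if < 2 planes."""
    zs = sorted({round(float(z), ROUND_DECIMALS) for z, _ in contours})
    if len(zs) < 2:
        return default
    gaps = np.diff(zs)
    return float(np.median(gaps))
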