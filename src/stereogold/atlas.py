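"""Per-row alignment, height normalization, azimuth correction and density binning.

Every cilium is brought into a canonical right-handed frame (h, m, l):
``h`` along the cilium axis with the taper at the origin, ``m`` the
bundle's positive mechanosensitivity direction after "opening the V"
(rotating each cilium about its axis so its local outward row-normal faces
the global mechano direction), and ``l = h x m``. Azimuth is measured from
+m, positive counterclockwise viewed from the tip.

Assigned beads are binned into ~200-nm height segments x 4 radial sectors
per row; density is count / (sector area x number of cilia of the row).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, CorrectionError, ParameterError
from .io import KINOCILIUM_ROW
from .mapping import ProjectedBead
from .morphometry import CiliumGeometry

log = logging.getLogger(__name__)

#: radial sectors; "anterior" faces the positive mechano direction (tallest row)
SECTORS = ("anterior", "lateral_left", "posterior", "lateral_right")

DEFAULT_SEGMENT_HEIGHT_NM = 200.0


def cross_zyx(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Right-handed cross product for vectors stored in (z, y, x) order."""
    return np.cross(u[::-1], v[::-1])[::-1]


def rotate_about_axis(vec: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of ``vec`` about unit ``axis`` (zyx storage)."""
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return vec * c + cross_zyx(axis, vec) * s + axis * float(np.dot(axis, vec)) * (1.0 - c)


def n_segments_for(row_mean_height_nm: float, segment_height_nm: float = DEFAULT_SEGMENT_HEIGHT_NM) -> int:
    """Number of ~equal height segments for a row: nearest integer to H/segment, minimum 1."""
    if row_mean_height_nm <= 0 or segment_height_nm <= 0:
        raise ParameterError("heights must be positive")
    return max(1, int(math.floor(row_mean_height_nm / segment_height_nm + 0.5)))


def sector_of(azimuth_deg: float) -> str:
    """Quadrant sector of an azimuth in [-180, 180): boundaries at +/-45 and +/-135 deg."""
    a = float(azimuth_deg)
    if not (-180.0 <= a < 180.0):
        raise ParameterError(f"azimuth must be in [-180, 180), got {a}")
    if -45.0 <= a < 45.0:
        return "anterior"
    if 45.0 <= a < 135.0:
        return "lateral_left"
    if -135.0 <= a < -45.0:
        return "lateral_right"
    return "posterior"


def sector_area_um2(diameter_nm: float, segment_height_nm: float = DEFAULT_SEGMENT_HEIGHT_NM) -> float:
    """Area of one of four equal radial sectors of a cylindrical shell segment, in um^2."""
    if diameter_nm < 0 or segment_height_nm <= 0:
        raise ParameterError("diameter must be >= 0 and segment height > 0")
    return math.pi * diameter_nm * segment_height_nm / 4.0 * 1e-6


@dataclass
class AzimuthCorrection:
    """Rotation about a cilium's axis aligning its local row-normal with the mechano direction."""

    angle_deg: float
    axis: np.ndarray
    local_normal: np.ndarray  # outward in-plane normal of the row at this cilium


def azimuth_correction(
    cilium: CiliumGeometry,
    row_neighbors: list[CiliumGeometry],
    mechano_direction: np.ndarray,
) -> AzimuthCorrection:
    """Rotation opening the bundle's V at this cilium.

    The local row tangent is the unit vector between the base centroids of
    the two nearest same-row neighbors (a single neighbor at row ends); the
    local normal is the in-plane (perpendicular to the cilium axis)
    perpendicular of that tangent, signed toward the mechano direction. The
    returned rotation maps the local normal onto the mechano direction in
    the plane perpendicular to the axis.
    """
    axis = cilium.axis
    mech = np.asarray(mechano_direction, dtype=float)
    m_perp = mech - float(np.dot(mech, axis)) * axis
    nm = np.linalg.norm(m_perp)
    if nm < 1e-9:
        raise CorrectionError("mechano direction is parallel to the cilium axis")
    m_perp /= nm

    neighbors = [g for g in row_neighbors if g.cilium_id != cilium.cilium_id]
    if not neighbors:
        log.warning(
            "cilium %s has no same-row neighbor; azimuth correction is the identity",
            cilium.cilium_id,
        )
        return AzimuthCorrection(angle_deg=0.0, axis=axis, local_normal=m_perp)

    base = cilium.base_centroid_nm
    dists = [float(np.linalg.norm(g.base_centroid_nm - base)) for g in neighbors]
    order = np.argsort(dists)
    if len(neighbors) >= 2:
        a = neighbors[order[0]].base_centroid_nm
        b = neighbors[order[1]].base_centroid_nm
        tangent = b - a
    else:
        tangent = neighbors[order[0]].base_centroid_nm - base

    t_perp = tangent - float(np.dot(tangent, axis)) * axis
    nt = np.linalg.norm(t_perp)
    if nt < 1e-9:
        raise CorrectionError("row tangent is parallel to the cilium axis")
    t_perp /= nt

    normal = cross_zyx(axis, t_perp)
    if float(np.dot(normal, mech)) < 0:
        normal = -normal

    sin_a = float(np.dot(cross_zyx(normal, m_perp), axis))
    cos_a = float(np.dot(normal, m_perp))
    angle = math.atan2(sin_a, cos_a)
    return AzimuthCorrection(angle_deg=math.degrees(angle), axis=axis, local_normal=normal)


def _wrap_azimuth(deg: float) -> float:
    a = (deg + 180.0) % 360.0 - 180.0
    return -180.0 if a == 180.0 else a


@dataclass
class CanonicalCilium:
    """A cilium (and its beads) expressed in the canonical (h, m, l) frame."""

    cilium_id: int
    row: str
    height_nm: float
    height_scale: float
    origin_nm: np.ndarray  # taper point in the input frame
    frame: np.ndarray  # rows (h, m, l) unit vectors in the input frame
    canonical_points: np.ndarray  # (n, 3) columns (h, m, l) nm
    beads: list[ProjectedBead] = field(default_factory=list)


def canonicalize(
    cilium: CiliumGeometry,
    correction: AzimuthCorrection,
    row_max_height_nm: float,
    beads: list[ProjectedBead] | None = None,
) -> CanonicalCilium:
    """Map a cilium and its assigned beads into the canonical frame.

    Bead height fraction and azimuth are computed from the bead's surface
    projection point: height fraction = axial coordinate / cilium height
    (clamped to [0, 1]) so tips coincide at fraction 1 across the row;
    azimuth is measured from +m, counterclockwise viewed from the tip.
    """
    if row_max_height_nm < cilium.height_nm - 1e-6 * max(cilium.height_nm, 1.0):
        raise ParameterError(
            f"row_max_height_nm {row_max_height_nm} smaller than cilium height {cilium.height_nm}"
        )
    h = cilium.axis
    m = correction.local_normal - float(np.dot(correction.local_normal, h)) * h
    m /= np.linalg.norm(m)
    lvec = cross_zyx(h, m)
    frame = np.stack([h, m, lvec])
    origin = cilium.taper_nm

    canonical_points = (cilium.surface_points - origin) @ frame.T

    out_beads: list[ProjectedBead] = []
    height = cilium.height_nm
    for bead in beads or []:
        if bead.discarded or bead.cilium_id != cilium.cilium_id:
            continue
        q = frame @ (bead.surface_point_nm - origin)
        bead.height_fraction = float(np.clip(q[0] / height, 0.0, 1.0)) if height > 0 else 0.0
        bead.azimuth_deg = _wrap_azimuth(math.degrees(math.atan2(q[2], q[1])))
        bead.sector = sector_of(bead.azimuth_deg)
        out_beads.append(bead)

    return CanonicalCilium(
        cilium_id=cilium.cilium_id,
        row=cilium.row,
        height_nm=height,
        height_scale=height / row_max_height_nm if row_max_height_nm > 0 else 1.0,
        origin_nm=origin,
        frame=frame,
        canonical_points=canonical_points,
        beads=out_beads,
    )


@dataclass
class RowDensity:
    """Counts and derived densities for one row's (segment x sector) bins."""

    n_segments: int
    counts: np.ndarray  # (n_segments, 4) int
    sector_area_um2: float
    n_cilia: int

    @property
    def density(self) -> np.ndarray:
        """beads / um^2 / cilium: counts / (sector area x n_cilia)."""
        denom = self.sector_area_um2 * self.n_cilia
        if denom <= 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / denom


@dataclass
class DensityMap:
    """Per-row density matrices over (segment x sector) bins."""

    rows: dict[str, RowDensity] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return int(sum(r.counts.sum() for r in self.rows.values()))

    def iter_records(self):
        for row_name, rd in self.rows.items():
            for seg in range(rd.n_segments):
                for si, sector in enumerate(SECTORS):
                    yield {
                        "row": row_name,
                        "segment_index": seg,
                        "sector": sector,
                        "count": int(rd.counts[seg, si]),
                        "n_cilia": rd.n_cilia,
                        "sector_area_um2": rd.sector_area_um2,
                        "density_beads_per_um2": float(rd.density[seg, si]),
                    }

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.iter_records()))

    def __eq__(self, other) -> bool:  # value semantics for round-trip tests
        if not isinstance(other, DensityMap):
            return NotImplemented
        if set(self.rows) != set(other.rows):
            return False
        for name, a in self.rows.items():
            b = other.rows[name]
            if (
                a.n_segments != b.n_segments
                or a.n_cilia != b.n_cilia
                or a.sector_area_um2 != b.sector_area_um2
                or not np.array_equal(a.counts, b.counts)
            ):
                return False
        return True


def compute_density_map(
    projected_beads: list[ProjectedBead],
    canonical_cilia: list[CanonicalCilium],
    row_diameter_nm: dict[str, float],
    segment_height_nm: float = DEFAULT_SEGMENT_HEIGHT_NM,
    n_segments: dict[str, int] | None = None,
    include_kinocilium: bool = False,
) -> DensityMap:
    """Bin assigned beads into (row, segment, sector) and normalize to density.

    Segment index is ``floor(height_fraction * n_segments)`` clamped to the
    last segment; ``n_segments`` defaults to the nearest integer of the
    row's mean cilium height over ``segment_height_nm``. Kinocilia are
    excluded by default.
    """
    by_id = {c.cilium_id: c for c in canonical_cilia}
    row_names: list[str] = []
    for c in canonical_cilia:
        if c.row == KINOCILIUM_ROW and not include_kinocilium:
            continue
        if c.row not in row_names:
            row_names.append(c.row)

    rows: dict[str, RowDensity] = {}
    for row_name in row_names:
        members = [c for c in canonical_cilia if c.row == row_name]
        if n_segments and row_name in n_segments:
            n_seg = int(n_segments[row_name])
        else:
            mean_h = float(np.mean([c.height_nm for c in members]))
            n_seg = n_segments_for(mean_h, segment_height_nm)
        if row_name not in row_diameter_nm:
            raise ParameterError(f"no diameter supplied for row {row_name!r}")
        rows[row_name] = RowDensity(
            n_segments=n_seg,
            counts=np.zeros((n_seg, len(SECTORS)), dtype=np.int64),
            sector_area_um2=sector_area_um2(row_diameter_nm[row_name], segment_height_nm),
            n_cilia=len(members),
        )

    for bead in projected_beads:
        if bead.discarded:
            continue
        cil = by_id.get(bead.cilium_id)
        if cil is None:
            raise ConsistencyError(f"bead {bead.bead_id} references unknown cilium {bead.cilium_id}")
        if cil.row not in rows:
            continue  # e.g. kinocilium excluded
        if bead.height_fraction is None or bead.sector is None:
            raise ConsistencyError(f"bead {bead.bead_id} has not been canonicalized")
        rd = rows[cil.row]
        seg = min(int(bead.height_fraction * rd.n_segments), rd.n_segments - 1)
        bead.segment = seg
        rd.counts[seg, SECTORS.index(bead.sector)] += 1

    return DensityMap(rows=rows)


def representative_surface(
    canonical_cilia: list[CanonicalCilium],
    target_count: int = 5000,
    seed=None,
    triangulate: bool = False,
):
    """Overlay of a row's canonical surface clouds, decimated to ``target_count``.

    Triangulation (convex hull simplices) is best-effort output for
    visualization only; returns ``(points, simplices_or_None)``.
    """
    if not canonical_cilia:
        raise ParameterError("need at least one canonical cilium")
    pts = np.concatenate([c.canonical_points for c in canonical_cilia], axis=0)
    if len(pts) > target_count:
        rng = np.random.default_rng(seed)
        pts = pts[rng.choice(len(pts), size=target_count, replace=False)]
    simplices = None
    if triangulate and len(pts) >= 4:
        from scipy.spatial import ConvexHull

        try:
            simplices = ConvexHull(pts).simplices
        except Exception:  # degenerate clouds: triangulation stays None
            simplices = None
    return pts, simplices
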