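"""Bead centroid extraction and k-nearest-neighbor projection onto cilium surfaces.

Each bead centroid votes among the ``k`` nearest points of the pooled
surface cloud (all cilia); the cilium holding the majority wins and the
bead is snapped to that cilium's nearest surface point. Beads farther than
the cutoff (default 100 nm) from the winning surface are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .exceptions import ParameterError
from .io import BEAD_COLUMNS
from .morphometry import CiliumGeometry

DEFAULT_CUTOFF_NM = 100.0


@dataclass
class ProjectedBead:
    """One bead after assignment (or discard)."""

    bead_id: int
    centroid_nm: np.ndarray
    cilium_id: int | None
    surface_point_nm: np.ndarray | None
    distance_nm: float
    nearest_distance_nm: float
    discarded: bool
    reason: str | None = None
    # filled by bundle_atlas.canonicalize
    height_fraction: float | None = None
    azimuth_deg: float | None = None
    segment: int | None = None
    sector: str | None = None


def compute_bead_centroids(bead_volume: np.ndarray, spacing_nm, min_size: int = 1) -> pd.DataFrame:
    """26-connected components of the bead mask, reduced to centroids in nm.

    The centroid is the unweighted mean of a component's voxel centers. An
    empty mask yields an empty table.
    """
    mask = np.asarray(bead_volume) > 0
    if mask.ndim != 3:
        raise ParameterError(f"bead volume must be 3D, got ndim={mask.ndim}")
    structure = np.ones((3, 3, 3), dtype=bool)
    lab, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return pd.DataFrame(columns=BEAD_COLUMNS)
    ids = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(mask, lab, ids)
    centers = np.asarray(ndimage.center_of_mass(mask, lab, ids), dtype=float)
    keep = sizes >= min_size
    centers = centers[keep] * np.asarray(spacing_nm, dtype=float)
    return pd.DataFrame(
        {
            "bead_id": np.arange(len(centers)),
            "z_nm": centers[:, 0],
            "y_nm": centers[:, 1],
            "x_nm": centers[:, 2],
        }
    )


def pooled_surface(geometries: list[CiliumGeometry]) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate all surface clouds; returns (points, owner cilium ids)."""
    pts = np.concatenate([g.surface_points for g in geometries], axis=0)
    owners = np.concatenate(
        [np.full(len(g.surface_points), g.cilium_id, dtype=np.int64) for g in geometries]
    )
    return pts, owners


def project_beads(
    centroids: pd.DataFrame,
    geometries: list[CiliumGeometry],
    k: int = 10,
    cutoff_nm: float = DEFAULT_CUTOFF_NM,
) -> list[ProjectedBead]:
    """Assign each bead centroid to a cilium by majority vote among k nearest surface points.

    A vote tie is broken by the cilium owning the single nearest pooled
    surface point. ``distance_nm`` is measured to the winning cilium's
    nearest surface point; the global nearest distance is kept alongside
    for auditing. Beads with ``distance_nm > cutoff_nm`` are discarded with
    reason ``"cutoff"``.
    """
    if not geometries:
        raise ParameterError("no cilium geometries supplied")
    pts, owners = pooled_surface(geometries)
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if k > len(pts):
        raise ParameterError(f"k={k} exceeds pooled surface cloud size {len(pts)}")

    coords = centroids[["z_nm", "y_nm", "x_nm"]].to_numpy(dtype=float)
    bead_ids = centroids["bead_id"].to_numpy()
    out: list[ProjectedBead] = []
    if len(coords) == 0:
        return out

    tree = cKDTree(pts)
    dist, idx = tree.query(coords, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]

    cilium_trees = {
        g.cilium_id: (cKDTree(g.surface_points), g.surface_points) for g in geometries
    }

    for b in range(len(coords)):
        vote_owners = owners[idx[b]]
        uniq, counts = np.unique(vote_owners, return_counts=True)
        top = counts.max()
        winners = uniq[counts == top]
        winner = int(winners[0]) if len(winners) == 1 else int(vote_owners[0])

        ctree, cpts = cilium_trees[winner]
        d_win, j = ctree.query(coords[b])
        discarded = bool(d_win > cutoff_nm)
        out.append(
            ProjectedBead(
                bead_id=bead_ids[b],
                centroid_nm=coords[b],
                cilium_id=None if discarded else winner,
                surface_point_nm=None if discarded else cpts[j],
                distance_nm=float(d_win),
                nearest_distance_nm=float(dist[b, 0]),
                discarded=discarded,
                reason="cutoff" if discarded else None,
            )
        )
    return out


def projected_to_dataframe(beads: list[ProjectedBead]) -> pd.DataFrame:
    rows = []
    for p in beads:
        sp = p.surface_point_nm
        rows.append(
            {
                "bead_id": p.bead_id,
                "cilium_id": -1 if p.cilium_id is None else p.cilium_id,
                "distance_nm": p.distance_nm,
                "nearest_distance_nm": p.nearest_distance_nm,
                "surface_z_nm": np.nan if sp is None else sp[0],
                "surface_y_nm": np.nan if sp is None else sp[1],
                "surface_x_nm": np.nan if sp is None else sp[2],
                "height_fraction": np.nan if p.height_fraction is None else p.height_fraction,
                "azimuth_deg": np.nan if p.azimuth_deg is None else p.azimuth_deg,
                "segment": -1 if p.segment is None else p.segment,
                "sector": "" if p.sector is None else p.sector,
                "discarded": p.discarded,
                "reason": p.reason or "",
            }
        )
    return pd.DataFrame(rows)
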