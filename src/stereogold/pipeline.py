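"""End-to-end bundle analysis: volume -> geometries -> projected beads -> density map."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import atlas, mapping, morphometry
from .io import KINOCILIUM_ROW, AnnotatedVolume


@dataclass
class BundleAnalysis:
    geometries: list[morphometry.CiliumGeometry]
    projected: list[mapping.ProjectedBead]
    canonical: list[atlas.CanonicalCilium]
    density_map: atlas.DensityMap


def map_bundle(
    vol: AnnotatedVolume,
    k: int = 10,
    cutoff_nm: float = mapping.DEFAULT_CUTOFF_NM,
    resize_factor: int = 1,
    keep_fraction: float = 0.10,
    seed=0,
    segment_height_nm: float = atlas.DEFAULT_SEGMENT_HEIGHT_NM,
    row_diameter_nm: dict[str, float] | None = None,
    include_kinocilium: bool = False,
) -> BundleAnalysis:
    """Run the full bead-mapping pipeline on one annotated volume.

    Row diameters for sector areas default to the mean measured diameter per
    row. ``resize_factor`` defaults to 1 because phantoms are generated at
    post-reduction voxel sizes; use 4 for acquisition-scale volumes.
    """
    geometries = morphometry.analyze_bundle(
        vol, resize_factor=resize_factor, keep_fraction=keep_fraction, seed=seed
    )

    if vol.bead_centroids is not None:
        centroids = vol.bead_centroids
    elif vol.bead_volume is not None:
        centroids = mapping.compute_bead_centroids(vol.bead_volume, vol.spacing_nm)
    else:
        raise ValueError("volume carries neither bead centroids nor a bead volume")

    projected = mapping.project_beads(centroids, geometries, k=k, cutoff_nm=cutoff_nm)

    by_cilium: dict[int, list[mapping.ProjectedBead]] = {}
    for bead in projected:
        if not bead.discarded:
            by_cilium.setdefault(bead.cilium_id, []).append(bead)

    canonical: list[atlas.CanonicalCilium] = []
    by_row: dict[str, list[morphometry.CiliumGeometry]] = {}
    for g in geometries:
        by_row.setdefault(g.row, []).append(g)
    for row_name, members in by_row.items():
        row_max = max(g.height_nm for g in members)
        for g in members:
            corr = atlas.azimuth_correction(g, members, vol.mechano_direction)
            canonical.append(
                atlas.canonicalize(g, corr, row_max, beads=by_cilium.get(g.cilium_id, []))
            )

    if row_diameter_nm is None:
        row_diameter_nm = {
            row_name: float(np.mean([g.diameter_nm for g in members]))
            for row_name, members in by_row.items()
            if row_name != KINOCILIUM_ROW or include_kinocilium
        }

    density_map = atlas.compute_density_map(
        projected,
        canonical,
        row_diameter_nm,
        segment_height_nm=segment_height_nm,
        include_kinocilium=include_kinocilium,
    )
    return BundleAnalysis(
        geometries=geometries, projected=projected, canonical=canonical, density_map=density_map
    )
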