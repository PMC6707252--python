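"""Per-cilium surface extraction and axis/tip/taper/height/diameter estimation.

The label volume is first reduced in-plane (y, x) by an integer factor with
majority-vote label pooling; the milling axis (z) is already coarse and is
left untouched. Border voxels (labeled voxels with at least one six-connected
background neighbor) form the surface cloud, of which a seeded random
fraction is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    CiliumNotFoundError,
    DegenerateGeometryError,
    MeasurementError,
    ParameterError,
)
from .io import AnnotatedVolume

log = logging.getLogger(__name__)


@dataclass
class CiliumGeometry:
    """One cilium's subsampled surface cloud with its estimated geometry.

    ``surface_points`` are (n, 3) physical nm in (z, y, x); ``axis`` is a
    unit vector oriented taper -> tip (``axis . apical_direction > 0``).
    """

    cilium_id: int
    row: str
    surface_points: np.ndarray
    axis: np.ndarray
    tip_nm: np.ndarray
    taper_nm: np.ndarray
    height_nm: float
    diameter_nm: float
    base_centroid_nm: np.ndarray


def downsample_labels(labels: np.ndarray, factor: int) -> np.ndarray:
    """In-plane (y, x) majority-vote pooling of a label volume by ``factor``.

    Blocks are ``1 x factor x factor``; incomplete edge blocks are padded
    with background. Ties go to the smaller label value (background wins
    over any label on a tie).
    """
    if factor < 1 or int(factor) != factor:
        raise ParameterError(f"resize factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return labels
    nz, ny, nx = labels.shape
    py = (-ny) % factor
    px = (-nx) % factor
    if py or px:
        labels = np.pad(labels, ((0, 0), (0, py), (0, px)), constant_values=0)
    ny2, nx2 = labels.shape[1] // factor, labels.shape[2] // factor
    blocks = labels.reshape(nz, ny2, factor, nx2, factor).transpose(0, 1, 3, 2, 4)
    blocks = blocks.reshape(nz, ny2, nx2, factor * factor)
    values = np.unique(labels)
    counts = np.empty((len(values),) + blocks.shape[:3], dtype=np.int32)
    for i, v in enumerate(values):
        counts[i] = (blocks == v).sum(axis=-1)
    return values[np.argmax(counts, axis=0)]


def _border_mask(mask: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Voxels of ``mask`` with a six-connected background neighbor.

    The volume boundary counts as background, so finite objects always have
    a border.
    """
    bg = np.pad(background, 1, constant_values=True)
    nb = (
        bg[2:, 1:-1, 1:-1]
        | bg[:-2, 1:-1, 1:-1]
        | bg[1:-1, 2:, 1:-1]
        | bg[1:-1, :-2, 1:-1]
        | bg[1:-1, 1:-1, 2:]
        | bg[1:-1, 1:-1, :-2]
    )
    return mask & nb


def extract_surface_points(
    vol: AnnotatedVolume,
    cilium_id: int,
    resize_factor: int = 4,
    keep_fraction: float = 0.10,
    seed=None,
) -> np.ndarray:
    """Return a seeded ``keep_fraction`` subsample of the cilium's border voxels in nm."""
    if not (0 < keep_fraction <= 1.0):
        raise ParameterError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    ds = downsample_labels(vol.cilium_labels, resize_factor)
    mask = ds == cilium_id
    if not mask.any():
        raise CiliumNotFoundError(f"label {cilium_id} not present in volume")
    border = _border_mask(mask, ds == 0)
    assert border.any(), "finite labeled object with no border voxels"

    idx = np.argwhere(border).astype(float)
    sz, sy, sx = vol.spacing_nm
    f = float(resize_factor)
    half = (f - 1.0) / 2.0  # pooled-block center offset in original voxels
    pts = np.empty_like(idx)
    pts[:, 0] = idx[:, 0] * sz
    pts[:, 1] = (idx[:, 1] * f + half) * sy
    pts[:, 2] = (idx[:, 2] * f + half) * sx

    n = len(pts)
    n_keep = min(n, max(1, int(round(keep_fraction * n))))
    if keep_fraction >= 1.0:
        n_keep = n
    if n_keep < n:
        rng = np.random.default_rng(seed)
        pts = pts[rng.choice(n, size=n_keep, replace=False)]
    return pts


def estimate_axis_and_ends(
    points: np.ndarray,
    apical_direction: np.ndarray,
    extreme_fraction: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA axis (sign-fixed by the apical direction) and robust tip/taper points.

    Tip and taper are the means of the ``extreme_fraction`` most extreme
    points by axial projection, extrapolated along the axis by half the
    extreme band's span so the estimate tracks the true end rather than the
    band center (a plain band mean biases the height low by
    ``extreme_fraction x height`` on uniform surfaces).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ParameterError(f"points must be (n, 3), got {pts.shape}")
    if len(pts) < 20:
        raise ParameterError(f"need >= 20 points to orient a cilium, got {len(pts)}")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    w, v = np.linalg.eigh(cov)
    w, v = w[::-1], v[:, ::-1]
    if w[0] <= 0 or (w[0] - w[1]) < 0.05 * w[0]:
        raise DegenerateGeometryError(
            f"ambiguous principal axis: leading principal values {w[0]:.4g} vs {w[1]:.4g} differ by <5%"
        )
    axis = v[:, 0]
    if float(np.dot(axis, apical_direction)) < 0:
        axis = -axis

    proj = pts @ axis
    m = max(1, int(np.ceil(extreme_fraction * len(pts))))
    order = np.argsort(proj)
    lo, hi = order[:m], order[-m:]

    def _end(band: np.ndarray, sign: float) -> np.ndarray:
        mean = pts[band].mean(axis=0)
        span = float(proj[band].max() - proj[band].min())
        return mean + sign * (span / 2.0) * axis

    taper = _end(lo, -1.0)
    tip = _end(hi, +1.0)
    return axis, tip, taper


def measure_cilium(
    points: np.ndarray,
    axis: np.ndarray,
    tip: np.ndarray,
    taper: np.ndarray,
    mid_band: tuple[float, float] = (0.25, 0.75),
) -> tuple[float, float]:
    """Height (axial extent tip-taper) and diameter (2x median mid-band radius).

    The mid-band (normalized axial position in ``mid_band``) avoids the
    basal taper and the tip cap. A zero-height (single-slice) object returns
    height 0 and a diameter from all points.
    """
    pts = np.asarray(points, dtype=float)
    axis = np.asarray(axis, dtype=float)
    height = float(np.dot(np.asarray(tip, float) - np.asarray(taper, float), axis))
    centroid = pts.mean(axis=0)
    rel = pts - centroid
    radial = rel - np.outer(rel @ axis, axis)
    dist = np.linalg.norm(radial, axis=1)
    if height <= 0.0:
        return 0.0, float(2.0 * np.median(dist))
    t = (pts - np.asarray(taper, float)) @ axis / height
    in_band = (t >= mid_band[0]) & (t <= mid_band[1])
    if not in_band.any():
        raise MeasurementError("no surface points in the mid-band; cannot estimate diameter")
    return height, float(2.0 * np.median(dist[in_band]))


def analyze_cilium(
    vol: AnnotatedVolume,
    cilium_id: int,
    resize_factor: int = 4,
    keep_fraction: float = 0.10,
    seed=None,
) -> CiliumGeometry:
    """Surface extraction + orientation + measurement for one label."""
    points = extract_surface_points(
        vol, cilium_id, resize_factor=resize_factor, keep_fraction=keep_fraction, seed=seed
    )
    axis, tip, taper = estimate_axis_and_ends(points, vol.apical_direction)
    height, diameter = measure_cilium(points, axis, tip, taper)
    return CiliumGeometry(
        cilium_id=cilium_id,
        row=vol.label_table[cilium_id].row,
        surface_points=points,
        axis=axis,
        tip_nm=tip,
        taper_nm=taper,
        height_nm=height,
        diameter_nm=diameter,
        base_centroid_nm=taper,
    )


def analyze_bundle(
    vol: AnnotatedVolume,
    resize_factor: int = 4,
    keep_fraction: float = 0.10,
    seed=None,
) -> list[CiliumGeometry]:
    """Analyze every label present in the volume (seeded per label)."""
    rng = np.random.default_rng(seed)
    out = []
    for cid in vol.labels_present():
        out.append(
            analyze_cilium(
                vol,
                cid,
                resize_factor=resize_factor,
                keep_fraction=keep_fraction,
                seed=rng.integers(0, 2**32),
            )
        )
    return out


def geometries_to_dataframe(geometries: list[CiliumGeometry]):
    """Flatten geometry estimates into the geometry CSV schema."""
    import pandas as pd

    rows = []
    for g in geometries:
        rows.append(
            {
                "cilium_id": g.cilium_id,
                "row": g.row,
                "height_nm": g.height_nm,
                "diameter_nm": g.diameter_nm,
                "axis_z": g.axis[0],
                "axis_y": g.axis[1],
                "axis_x": g.axis[2],
                "tip_z_nm": g.tip_nm[0],
                "tip_y_nm": g.tip_nm[1],
                "tip_x_nm": g.tip_nm[2],
                "taper_z_nm": g.taper_nm[0],
                "taper_y_nm": g.taper_nm[1],
                "taper_x_nm": g.taper_nm[2],
                "base_z_nm": g.base_centroid_nm[0],
                "base_y_nm": g.base_centroid_nm[1],
                "base_x_nm": g.base_centroid_nm[2],
            }
        )
    return pd.DataFrame(rows)
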