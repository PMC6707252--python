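"""Read/write the package's file formats and validate metadata.

All coordinates downstream of this module are physical nanometres in
``(z, y, x)`` order, 0-based, voxel-center convention: voxel index
``(k, j, i)`` sits at ``(k*sz, j*sy, i*sx)`` nm. Voxel indices never leak
past this module.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import tifffile

from .exceptions import ValidationError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .atlas import DensityMap

log = logging.getLogger(__name__)

#: stereocilium rows in staircase order, tallest first
ROWS = ("tall", "middle", "short")
KINOCILIUM_ROW = "kinocilium"
VALID_ROWS = ROWS + (KINOCILIUM_ROW,)

BEAD_COLUMNS = ["bead_id", "z_nm", "y_nm", "x_nm"]
DENSITY_COLUMNS = [
    "row",
    "segment_index",
    "sector",
    "count",
    "n_cilia",
    "sector_area_um2",
    "density_beads_per_um2",
]

METADATA_KEYS = ("spacing_nm", "apical_direction", "mechano_direction", "labels")


def _as_unit(vec, name: str) -> np.ndarray:
    v = np.asarray(vec, dtype=float)
    if v.shape != (3,):
        raise ValidationError(f"{name} must be a 3-vector in (z, y, x), got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValidationError(f"{name} must be finite")
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise ValidationError(f"{name} must be a nonzero vector")
    if abs(n - 1.0) > 1e-6:
        log.warning("%s has norm %.6g, normalizing to unit length", name, n)
    return v / n


@dataclass(frozen=True)
class LabelInfo:
    """Row/bundle assignment of one cilium label."""

    bundle: int
    row: str


@dataclass
class AnnotatedVolume:
    """A cilium-label volume plus bead observations and acquisition geometry.

    Parameters
    ----------
    cilium_labels : (z, y, x) integer array, 0 = background.
    spacing_nm : voxel spacing ``(sz, sy, sx)`` in nm, strictly positive.
    apical_direction : unit vector (z, y, x) from cell body toward bundle tips.
    mechano_direction : unit vector (z, y, x) from the shortest row toward
        the tallest row (positive mechanosensitivity sense).
    label_table : label id -> :class:`LabelInfo`.
    bead_volume : optional bead mask/label volume on the same grid.
    bead_centroids : optional table with columns ``bead_id, z_nm, y_nm, x_nm``.
    """

    cilium_labels: np.ndarray
    spacing_nm: tuple[float, float, float]
    apical_direction: np.ndarray
    mechano_direction: np.ndarray
    label_table: dict[int, LabelInfo]
    bead_volume: np.ndarray | None = None
    bead_centroids: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        labels = np.asarray(self.cilium_labels)
        if labels.ndim != 3:
            raise ValidationError(f"cilium_labels must be 3D (z, y, x), got ndim={labels.ndim}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValidationError("cilium_labels must be an integer array")
        self.cilium_labels = labels

        spacing = tuple(float(s) for s in self.spacing_nm)
        if len(spacing) != 3 or any((not math.isfinite(s)) or s <= 0 for s in spacing):
            raise ValidationError(f"spacing_nm must be 3 positive finite values, got {self.spacing_nm}")
        self.spacing_nm = spacing

        self.apical_direction = _as_unit(self.apical_direction, "apical_direction")
        self.mechano_direction = _as_unit(self.mechano_direction, "mechano_direction")
        cosang = abs(float(np.dot(self.apical_direction, self.mechano_direction)))
        if cosang > math.cos(math.radians(1.0)):
            raise ValidationError(
                "apical_direction and mechano_direction are parallel within 1 degree"
            )

        present = set(int(v) for v in np.unique(labels)) - {0}
        unknown = sorted(present - set(self.label_table))
        if unknown:
            raise ValidationError(f"label ids {unknown} present in volume but missing from label_table")
        for lid, info in self.label_table.items():
            if info.row not in VALID_ROWS:
                raise ValidationError(f"label {lid}: unknown row {info.row!r} (expected one of {VALID_ROWS})")

        if self.bead_volume is not None:
            bv = np.asarray(self.bead_volume)
            if bv.shape != labels.shape:
                raise ValidationError(
                    f"bead volume shape {bv.shape} incongruent with label volume shape {labels.shape}"
                )
            self.bead_volume = bv
        if self.bead_centroids is not None:
            self.bead_centroids = validate_bead_table(self.bead_centroids, extent_nm=self.extent_nm)

    @property
    def extent_nm(self) -> tuple[float, float, float]:
        """Physical extent (z, y, x) in nm covered by the voxel grid."""
        return tuple(n * s for n, s in zip(self.cilium_labels.shape, self.spacing_nm))

    def labels_present(self) -> list[int]:
        """Sorted nonzero label ids actually present in the volume."""
        return sorted(int(v) for v in np.unique(self.cilium_labels) if v != 0)


def validate_bead_table(table: pd.DataFrame, extent_nm=None) -> pd.DataFrame:
    """Validate a bead-centroid table; warn (not fail) on out-of-box coordinates."""
    missing = [c for c in BEAD_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"bead table missing columns {missing}")
    table = table.reset_index(drop=True)
    if table["bead_id"].duplicated().any():
        dup = table.loc[table["bead_id"].duplicated(), "bead_id"].tolist()
        raise ValidationError(f"duplicate bead_id values {dup[:5]}")
    coords = table[["z_nm", "y_nm", "x_nm"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValidationError("bead coordinates must be finite")
    if extent_nm is not None:
        hi = np.asarray(extent_nm, dtype=float)
        outside = np.any(coords < 0, axis=1) | np.any(coords > hi, axis=1)
        if outside.any():
            log.warning("%d bead centroid(s) fall outside the volume bounding box", int(outside.sum()))
    return table


def _read_tiff_volume(path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValidationError(f"{path}: expected a (multi-page) grayscale TIFF, got ndim={arr.ndim}")
    return arr


def parse_label_table(raw: dict) -> dict[int, LabelInfo]:
    table: dict[int, LabelInfo] = {}
    for key, val in raw.items():
        try:
            lid = int(key)
        except (TypeError, ValueError):
            raise ValidationError(f"label id {key!r} is not an integer") from None
        if "row" not in val:
            raise ValidationError(f"label {lid}: metadata missing key 'row'")
        table[lid] = LabelInfo(bundle=int(val.get("bundle", 1)), row=str(val["row"]))
    return table


def read_metadata(path) -> dict:
    with open(path) as fh:
        meta = json.load(fh)
    for key in METADATA_KEYS:
        if key not in meta:
            raise ValidationError(f"metadata missing key {key!r}")
    return meta


def read_annotated_volume(label_path, bead_path, metadata_path) -> AnnotatedVolume:
    """Load a label volume, bead observations and the JSON metadata sidecar.

    ``bead_path`` may be a TIFF mask volume or a centroid CSV (by suffix),
    or ``None``.
    """
    meta = read_metadata(metadata_path)
    labels = _read_tiff_volume(label_path)
    if "shape_zyx" in meta:
        expected = tuple(int(n) for n in meta["shape_zyx"])
        if labels.shape != expected:
            raise ValidationError(
                f"label volume shape {labels.shape} does not match metadata shape_zyx {expected}"
            )

    bead_volume = None
    bead_centroids = None
    if bead_path is not None:
        bead_path = Path(bead_path)
        if bead_path.suffix.lower() == ".csv":
            bead_centroids = read_bead_centroids(bead_path)
        else:
            bead_volume = _read_tiff_volume(bead_path)

    return AnnotatedVolume(
        cilium_labels=labels,
        spacing_nm=tuple(meta["spacing_nm"]),
        apical_direction=np.asarray(meta["apical_direction"], dtype=float),
        mechano_direction=np.asarray(meta["mechano_direction"], dtype=float),
        label_table=parse_label_table(meta["labels"]),
        bead_volume=bead_volume,
        bead_centroids=bead_centroids,
    )


def write_annotated_volume(
    vol: AnnotatedVolume,
    label_path,
    metadata_path,
    bead_volume_path=None,
    bead_table_path=None,
) -> None:
    """Write label volume (16-bit multi-page TIFF), beads and metadata sidecar."""
    tifffile.imwrite(str(label_path), vol.cilium_labels.astype(np.uint16))
    if bead_volume_path is not None:
        if vol.bead_volume is None:
            raise ValidationError("no bead volume to write")
        tifffile.imwrite(str(bead_volume_path), vol.bead_volume.astype(np.uint8))
    if bead_table_path is not None:
        if vol.bead_centroids is None:
            raise ValidationError("no bead centroid table to write")
        write_bead_centroids(vol.bead_centroids, bead_table_path)
    meta = {
        "spacing_nm": list(vol.spacing_nm),
        "apical_direction": [float(v) for v in vol.apical_direction],
        "mechano_direction": [float(v) for v in vol.mechano_direction],
        "shape_zyx": [int(n) for n in vol.cilium_labels.shape],
        "labels": {
            str(lid): {"bundle": info.bundle, "row": info.row}
            for lid, info in vol.label_table.items()
        },
    }
    with open(metadata_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_bead_centroids(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_bead_table(df)


def write_bead_centroids(table: pd.DataFrame, path) -> None:
    validate_bead_table(table)
    table.loc[:, BEAD_COLUMNS].to_csv(path, index=False)


def write_density_map(dmap: "DensityMap", path) -> None:
    """Write a density map as CSV; lossless round trip via :func:`read_density_map`."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(DENSITY_COLUMNS)
        for rec in dmap.iter_records():
            writer.writerow(
                [
                    rec["row"],
                    rec["segment_index"],
                    rec["sector"],
                    rec["count"],
                    rec["n_cilia"],
                    repr(float(rec["sector_area_um2"])),
                    repr(float(rec["density_beads_per_um2"])),
                ]
            )


def read_density_map(path) -> "DensityMap":
    from .atlas import SECTORS, DensityMap, RowDensity

    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in DENSITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"density CSV missing columns {missing}")
    rows: dict[str, RowDensity] = {}
    for row_name, grp in df.groupby("row", sort=False):
        n_seg = int(grp["segment_index"].max()) + 1
        counts = np.zeros((n_seg, len(SECTORS)), dtype=np.int64)
        for _, rec in grp.iterrows():
            counts[int(rec["segment_index"]), SECTORS.index(rec["sector"])] = int(rec["count"])
        rows[str(row_name)] = RowDensity(
            n_segments=n_seg,
            counts=counts,
            sector_area_um2=float(grp["sector_area_um2"].iloc[0]),
            n_cilia=int(grp["n_cilia"].iloc[0]),
        )
    return DensityMap(rows=rows)
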