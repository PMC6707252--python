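"""Synthetic phantoms with known ground truth.

Bundle phantoms: three staircase rows of capped-cylinder cilia (basal linear
taper, inscribed hemispherical tip) arranged along a V in the plane
perpendicular to the apical axis, rasterized into an anisotropic label
volume. Gold beads are drawn per (height-fraction bin x radial sector) by
an inhomogeneous Poisson process on each cilium's surface, displaced
outward by |N(offset_mean, offset_sd)|, plus decoy beads rejection-sampled
to lie well beyond the discard cutoff from every surface.

Coat phantoms: flat-membrane TEM images with background, coat, membrane and
actin bands at known positions plus Gaussian noise, per animal group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from .atlas import SECTORS, cross_zyx, n_segments_for, sector_of
from .coat import ProfileBox
from .exceptions import SizingError, ValidationError
from .io import ROWS, AnnotatedVolume, LabelInfo, write_annotated_volume
from .mapping import DEFAULT_CUTOFF_NM

#: azimuth range (deg, measured from the local mechano normal) of each sector
SECTOR_RANGES = {
    "anterior": (-45.0, 45.0),
    "lateral_left": (45.0, 135.0),
    "posterior": (135.0, 225.0),
    "lateral_right": (225.0, 315.0),
}

#: printed per-row geometry used as phantom defaults (nm)
DEFAULT_ROW_HEIGHT_MEAN_NM = {"tall": 2390.0, "middle": 1930.0, "short": 1240.0}
DEFAULT_ROW_HEIGHT_SD_NM = {"tall": 160.0, "middle": 140.0, "short": 70.0}
DEFAULT_ROW_DIAMETER_NM = {"tall": 157.0, "middle": 182.0, "short": 129.0}

TAPER_MIN_RADIUS_FRACTION = 0.5


def uniform_field(rate: float) -> dict[str, float]:
    """A spatially uniform bead density (beads/um^2), same in every row."""
    return {row: float(rate) for row in ROWS}


def tip_enriched_field(
    row_height_mean_nm: Mapping[str, float],
    base_rate: float,
    top_rate: float,
    top_extent_nm: float = 300.0,
    segment_height_nm: float = 200.0,
) -> dict[str, np.ndarray]:
    """Bead density with ``top_rate`` over the apical ~``top_extent_nm`` of each row.

    Bin count per row follows the analysis segmenting rule; the top bins
    approximating ``top_extent_nm`` get ``top_rate``, the rest ``base_rate``.
    """
    field_: dict[str, np.ndarray] = {}
    for row, h in row_height_mean_nm.items():
        n_bins = n_segments_for(h, segment_height_nm)
        bin_h = h / n_bins
        n_top = min(n_bins, max(1, int(math.floor(top_extent_nm / bin_h + 0.5))))
        rates = np.full((n_bins, len(SECTORS)), float(base_rate))
        rates[n_bins - n_top :, :] = float(top_rate)
        field_[row] = rates
    return field_


@dataclass
class BundlePhantomSpec:
    """Parameters of a synthetic stereocilia bundle."""

    n_cilia_per_row: dict[str, int] = field(default_factory=lambda: {r: 6 for r in ROWS})
    row_height_mean_nm: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ROW_HEIGHT_MEAN_NM)
    )
    row_height_sd_nm: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ROW_HEIGHT_SD_NM)
    )
    row_diameter_nm: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ROW_DIAMETER_NM)
    )
    inter_cilium_spacing_nm: float = 320.0
    row_spacing_nm: float = 320.0
    v_angle_deg: float = 120.0
    taper_fraction: float = 0.15
    voxel_spacing_nm: tuple[float, float, float] = (15.0, 10.0, 10.0)  # (z, y, x)
    bead_offset_mean_nm: float = 15.0
    bead_offset_sd_nm: float = 5.0
    # beads/um^2 per row: scalar (uniform) or (n_bins, 4) array over
    # (height-fraction bin x sector); n_bins per row follows n_segments_for
    bead_density_field: Mapping[str, object] = field(default_factory=lambda: uniform_field(0.0))
    n_decoy_beads: int = 0
    decoy_margin_nm: float = 25.0  # extra clearance beyond the discard cutoff
    margin_nm: float = 150.0
    max_voxels: int = 80_000_000
    rng_seed: int = 0

    def validate(self) -> None:
        for name, table in (
            ("row_height_mean_nm", self.row_height_mean_nm),
            ("row_diameter_nm", self.row_diameter_nm),
        ):
            for row, v in table.items():
                if not (math.isfinite(v) and v > 0):
                    raise ValidationError(f"{name}[{row!r}] must be positive and finite, got {v}")
        for row, v in self.row_height_sd_nm.items():
            if not (math.isfinite(v) and v >= 0):
                raise ValidationError(f"row_height_sd_nm[{row!r}] must be >= 0, got {v}")
        for row, n in self.n_cilia_per_row.items():
            if n < 0:
                raise ValidationError(f"n_cilia_per_row[{row!r}] must be >= 0")
        if not (0.0 < self.v_angle_deg < 180.0):
            raise ValidationError(f"v_angle_deg must be in (0, 180), got {self.v_angle_deg}")
        if not (0.0 <= self.taper_fraction < 1.0):
            raise ValidationError(f"taper_fraction must be in [0, 1), got {self.taper_fraction}")
        if any(s <= 0 for s in self.voxel_spacing_nm):
            raise ValidationError(f"voxel_spacing_nm must be positive, got {self.voxel_spacing_nm}")
        if self.inter_cilium_spacing_nm <= 0 or self.row_spacing_nm <= 0 or self.margin_nm <= 0:
            raise ValidationError("spacings and margin must be positive")
        if self.bead_offset_mean_nm < 0 or self.bead_offset_sd_nm < 0:
            raise ValidationError("bead offset parameters must be >= 0")
        if self.n_decoy_beads < 0:
            raise ValidationError("n_decoy_beads must be >= 0")
        for row, rates in self.bead_density_field.items():
            arr = np.asarray(rates, dtype=float)
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValidationError(f"bead density for row {row!r} must be finite and >= 0")

    def resolved_rates(self) -> dict[str, np.ndarray]:
        """Per-row (n_bins, 4) rate tables; scalars broadcast over all bins."""
        out: dict[str, np.ndarray] = {}
        for row in ROWS:
            if self.n_cilia_per_row.get(row, 0) <= 0:
                continue
            n_bins = n_segments_for(self.row_height_mean_nm[row])
            raw = self.bead_density_field.get(row, 0.0)
            arr = np.asarray(raw, dtype=float)
            if arr.ndim == 0:
                arr = np.full((n_bins, len(SECTORS)), float(arr))
            if arr.shape != (n_bins, len(SECTORS)):
                raise ValidationError(
                    f"bead density for row {row!r} must be scalar or shape "
                    f"({n_bins}, {len(SECTORS)}), got {arr.shape}"
                )
            out[row] = arr
        return out


@dataclass
class GroundTruth:
    """Everything the generator knows: one record per bead, one per cilium."""

    beads: pd.DataFrame
    cilia: pd.DataFrame
    density: dict[str, np.ndarray]  # true rates (beads/um^2) per (bin, sector)
    n_bins: dict[str, int]


@dataclass
class _PhantomCilium:
    cilium_id: int
    row: str
    base_nm: np.ndarray  # (z, y, x); z is the taper end
    height_nm: float
    radius_nm: float
    taper_fraction: float
    local_normal: np.ndarray  # outward row normal (z, y, x)

    def surface_radius(self, t) -> np.ndarray:
        """Local surface radius at axial position(s) t in [0, H]."""
        t = np.asarray(t, dtype=float)
        r, h = self.radius_nm, self.height_nm
        out = np.full_like(t, r)
        if self.taper_fraction > 0:
            t_len = self.taper_fraction * h
            in_taper = t < t_len
            frac = TAPER_MIN_RADIUS_FRACTION
            out = np.where(in_taper, r * (frac + (1 - frac) * t / max(t_len, 1e-12)), out)
        cap_start = h - r
        in_cap = t > cap_start
        out = np.where(in_cap, np.sqrt(np.maximum(r**2 - (t - cap_start) ** 2, 0.0)), out)
        return out

    def signed_distance(self, p: np.ndarray) -> float:
        """Approximate signed distance from a point to the cilium surface (nm)."""
        dz = p[0] - self.base_nm[0]
        rho = math.hypot(p[1] - self.base_nm[1], p[2] - self.base_nm[2])
        r, h = self.radius_nm, self.height_nm
        if dz <= 0.0:
            return math.hypot(-dz, max(rho - float(self.surface_radius(0.0)), 0.0))
        cap_start = h - r
        if dz >= cap_start:
            return math.hypot(rho, dz - cap_start) - r
        return rho - float(self.surface_radius(dz))


def _layout_cilia(spec: BundlePhantomSpec, rng: np.random.Generator) -> list[_PhantomCilium]:
    """Place cilia on a V per row; rows stacked along +x (short -> tall)."""
    gamma = math.radians(spec.v_angle_deg / 2.0)
    cilia: list[_PhantomCilium] = []
    cid = 0
    # rows ordered short, middle, tall along +x so mechano = +x
    for xi, row in enumerate(("short", "middle", "tall")):
        n = spec.n_cilia_per_row.get(row, 0)
        if n <= 0:
            continue
        x_row = xi * spec.row_spacing_nm
        bases = []
        for j in range(n):
            s = (j - (n - 1) / 2.0) * spec.inter_cilium_spacing_nm
            y = s * math.sin(gamma)
            x = x_row - abs(s) * math.cos(gamma)
            bases.append((y, x))
        heights = rng.normal(spec.row_height_mean_nm[row], spec.row_height_sd_nm[row], size=n)
        r = spec.row_diameter_nm[row] / 2.0
        heights = np.clip(heights, 2.5 * r, None)
        for j, (y, x) in enumerate(bases):
            cid += 1
            cilia.append(
                _PhantomCilium(
                    cilium_id=cid,
                    row=row,
                    base_nm=np.array([0.0, y, x]),
                    height_nm=float(heights[j]),
                    radius_nm=r,
                    taper_fraction=spec.taper_fraction,
                    local_normal=np.zeros(3),
                )
            )
    # local outward normals via the same two-nearest-neighbor rule the
    # analysis uses, evaluated on true base positions
    axis = np.array([1.0, 0.0, 0.0])
    mech = np.array([0.0, 0.0, 1.0])
    by_row: dict[str, list[_PhantomCilium]] = {}
    for c in cilia:
        by_row.setdefault(c.row, []).append(c)
    for members in by_row.values():
        for c in members:
            others = [o for o in members if o is not c]
            if not others:
                c.local_normal = mech.copy()
                continue
            others.sort(key=lambda o: float(np.linalg.norm(o.base_nm - c.base_nm)))
            if len(others) >= 2:
                tangent = others[1].base_nm - others[0].base_nm
            else:
                tangent = others[0].base_nm - c.base_nm
            t_perp = tangent - float(np.dot(tangent, axis)) * axis
            t_perp /= np.linalg.norm(t_perp)
            normal = cross_zyx(axis, t_perp)
            if float(np.dot(normal, mech)) < 0:
                normal = -normal
            c.local_normal = normal
    return cilia


def expected_counts_per_cilium(
    rates: np.ndarray, diameter_nm: float, height_nm: float
) -> np.ndarray:
    """Expected bead count per (bin, sector) for one cilium under the cylinder-area model."""
    n_bins = rates.shape[0]
    bin_area_um2 = math.pi * diameter_nm * (height_nm / n_bins) / 4.0 * 1e-6
    return rates * bin_area_um2


def generate_bundle_phantom(spec: BundlePhantomSpec) -> tuple[AnnotatedVolume, GroundTruth]:
    """Generate a labeled bundle volume, bead observations and full ground truth.

    Deterministic given ``spec`` (including ``rng_seed``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    cilia = _layout_cilia(spec, rng)
    if not cilia:
        raise ValidationError("phantom contains no cilia")
    rates_by_row = spec.resolved_rates()

    # shift layout so every cilium (plus margin) has positive coordinates
    max_r = max(c.radius_nm for c in cilia)
    pad = max_r + spec.margin_nm
    ys = np.array([c.base_nm[1] for c in cilia])
    xs = np.array([c.base_nm[2] for c in cilia])
    shift = np.array([spec.margin_nm, pad - ys.min(), pad - xs.min()])
    for c in cilia:
        c.base_nm = c.base_nm + shift

    max_top = max(c.base_nm[0] + c.height_nm for c in cilia)
    extent = np.array(
        [
            max_top + spec.margin_nm,
            max(c.base_nm[1] for c in cilia) + pad,
            max(c.base_nm[2] for c in cilia) + pad,
        ]
    )
    spacing = np.asarray(spec.voxel_spacing_nm, dtype=float)
    shape = tuple(int(math.ceil(e / s)) + 1 for e, s in zip(extent, spacing))
    n_vox = shape[0] * shape[1] * shape[2]
    if n_vox > spec.max_voxels:
        raise SizingError(
            f"phantom volume {shape[0]}x{shape[1]}x{shape[2]} = {n_vox} voxels "
            f"exceeds max_voxels={spec.max_voxels}"
        )

    labels = np.zeros(shape, dtype=np.uint16)
    sz, sy, sx = spacing
    for c in cilia:
        bz, by, bx = c.base_nm
        k0 = max(0, int(math.floor(bz / sz)))
        k1 = min(shape[0] - 1, int(math.ceil((bz + c.height_nm) / sz)))
        j0 = max(0, int(math.floor((by - c.radius_nm) / sy)))
        j1 = min(shape[1] - 1, int(math.ceil((by + c.radius_nm) / sy)))
        i0 = max(0, int(math.floor((bx - c.radius_nm) / sx)))
        i1 = min(shape[2] - 1, int(math.ceil((bx + c.radius_nm) / sx)))
        t = np.arange(k0, k1 + 1) * sz - bz
        rbound = c.surface_radius(np.clip(t, 0.0, c.height_nm))
        rbound = np.where((t < 0) | (t > c.height_nm), -1.0, rbound)
        yy = np.arange(j0, j1 + 1) * sy - by
        xx = np.arange(i0, i1 + 1) * sx - bx
        rho2 = yy[:, None] ** 2 + xx[None, :] ** 2
        inside = rho2[None, :, :] <= (rbound**2)[:, None, None]
        inside &= (rbound > 0)[:, None, None]
        sub = labels[k0 : k1 + 1, j0 : j1 + 1, i0 : i1 + 1]
        sub[inside] = c.cilium_id

    # --- bead draw ---------------------------------------------------------
    axis = np.array([1.0, 0.0, 0.0])
    bead_rows: list[dict] = []
    for c in cilia:
        rates = rates_by_row.get(c.row)
        if rates is None:
            continue
        n_bins = rates.shape[0]
        expected = expected_counts_per_cilium(rates, 2 * c.radius_nm, c.height_nm)
        lvec = cross_zyx(axis, c.local_normal)
        cap_start = c.height_nm - c.radius_nm
        for b in range(n_bins):
            for si, sector in enumerate(SECTORS):
                n = int(rng.poisson(expected[b, si]))
                if n == 0:
                    continue
                hf = rng.uniform(b / n_bins, (b + 1) / n_bins, size=n)
                lo, hi = SECTOR_RANGES[sector]
                phi = rng.uniform(lo, hi, size=n)
                phi = (phi + 180.0) % 360.0 - 180.0
                offs = np.abs(rng.normal(spec.bead_offset_mean_nm, spec.bead_offset_sd_nm, size=n))
                t = hf * c.height_nm
                rho = c.surface_radius(t)
                rad = np.radians(phi)
                u = np.cos(rad)[:, None] * c.local_normal + np.sin(rad)[:, None] * lvec
                surf = c.base_nm + t[:, None] * axis + rho[:, None] * u
                # displacement direction: radial on the shaft, sphere-normal on the cap
                on_cap = t > cap_start
                ndir = u.copy()
                if on_cap.any():
                    cap_center = c.base_nm + cap_start * axis
                    v = surf[on_cap] - cap_center
                    v /= np.linalg.norm(v, axis=1, keepdims=True)
                    ndir[on_cap] = v
                pos = surf + offs[:, None] * ndir
                for i in range(n):
                    bead_rows.append(
                        {
                            "decoy": False,
                            "cilium_id": c.cilium_id,
                            "row": c.row,
                            "height_fraction": float(hf[i]),
                            "azimuth_deg": float(phi[i]),
                            "sector": sector_of(float(phi[i])),
                            "offset_nm": float(offs[i]),
                            "z_nm": float(pos[i, 0]),
                            "y_nm": float(pos[i, 1]),
                            "x_nm": float(pos[i, 2]),
                        }
                    )

    # --- decoys ------------------------------------------------------------
    clearance = DEFAULT_CUTOFF_NM + spec.decoy_margin_nm
    placed = 0
    attempts = 0
    max_attempts = 10000 * max(1, spec.n_decoy_beads)
    while placed < spec.n_decoy_beads:
        attempts += 1
        if attempts > max_attempts:
            raise SizingError(
                f"could not place {spec.n_decoy_beads} decoys with clearance {clearance} nm; "
                "volume too crowded"
            )
        p = rng.uniform(0.0, extent)
        if min(c.signed_distance(p) for c in cilia) > clearance:
            placed += 1
            bead_rows.append(
                {
                    "decoy": True,
                    "cilium_id": -1,
                    "row": "",
                    "height_fraction": np.nan,
                    "azimuth_deg": np.nan,
                    "sector": "",
                    "offset_nm": np.nan,
                    "z_nm": float(p[0]),
                    "y_nm": float(p[1]),
                    "x_nm": float(p[2]),
                }
            )

    beads = pd.DataFrame(
        bead_rows,
        columns=[
            "decoy",
            "cilium_id",
            "row",
            "height_fraction",
            "azimuth_deg",
            "sector",
            "offset_nm",
            "z_nm",
            "y_nm",
            "x_nm",
        ],
    )
    beads.insert(0, "bead_id", np.arange(len(beads)))

    bead_volume = np.zeros(shape, dtype=np.uint8)
    if len(beads):
        idx = np.rint(beads[["z_nm", "y_nm", "x_nm"]].to_numpy() / spacing).astype(int)
        idx = np.clip(idx, 0, np.array(shape) - 1)
        bead_volume[idx[:, 0], idx[:, 1], idx[:, 2]] = 1

    centroids = beads[["bead_id", "z_nm", "y_nm", "x_nm"]].copy()

    vol = AnnotatedVolume(
        cilium_labels=labels,
        spacing_nm=tuple(spacing),
        apical_direction=np.array([1.0, 0.0, 0.0]),
        mechano_direction=np.array([0.0, 0.0, 1.0]),
        label_table={c.cilium_id: LabelInfo(bundle=1, row=c.row) for c in cilia},
        bead_volume=bead_volume,
        bead_centroids=centroids,
    )

    cilia_df = pd.DataFrame(
        {
            "cilium_id": [c.cilium_id for c in cilia],
            "row": [c.row for c in cilia],
            "base_z_nm": [c.base_nm[0] for c in cilia],
            "base_y_nm": [c.base_nm[1] for c in cilia],
            "base_x_nm": [c.base_nm[2] for c in cilia],
            "axis_z": 1.0,
            "axis_y": 0.0,
            "axis_x": 0.0,
            "height_nm": [c.height_nm for c in cilia],
            "diameter_nm": [2 * c.radius_nm for c in cilia],
            "taper_fraction": [c.taper_fraction for c in cilia],
            "normal_z": [c.local_normal[0] for c in cilia],
            "normal_y": [c.local_normal[1] for c in cilia],
            "normal_x": [c.local_normal[2] for c in cilia],
        }
    )

    truth = GroundTruth(
        beads=beads,
        cilia=cilia_df,
        density=rates_by_row,
        n_bins={row: arr.shape[0] for row, arr in rates_by_row.items()},
    )
    return vol, truth


def write_bundle_phantom(vol: AnnotatedVolume, truth: GroundTruth, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_annotated_volume(
        vol,
        label_path=out / "labels.tif",
        metadata_path=out / "meta.json",
        bead_volume_path=out / "beads.tif",
        bead_table_path=out / "beads.csv",
    )
    truth.beads.to_csv(out / "truth_beads.csv", index=False)
    truth.cilia.to_csv(out / "truth_cilia.csv", index=False)
    recs = []
    for row, rates in truth.density.items():
        for b in range(rates.shape[0]):
            for si, sector in enumerate(SECTORS):
                recs.append(
                    {"row": row, "bin": b, "sector": sector, "rate_beads_per_um2": rates[b, si]}
                )
    pd.DataFrame(recs).to_csv(out / "truth_density.csv", index=False)


# ---------------------------------------------------------------------------
# coat phantoms
# ---------------------------------------------------------------------------


@dataclass
class CoatPhantomSpec:
    """Parameters of synthetic membrane-profile TEM images (two groups)."""

    pixel_size_nm: float = 1.92  # one of the acquisition pixel sizes by default
    background_gray: float = 200.0
    membrane_depth_gray: float = 60.0
    coat_amplitude_gray: float = 50.0
    actin_amplitude_gray: float = 50.0
    # outer leaflet at 80 nm + 20 nm membrane band puts the inner leaflet on
    # the 100-nm box midline and keeps the coat band a full pixel clear of
    # the default membrane summary window
    outer_leaflet_nm: float = 80.0
    membrane_thickness_nm: float = 20.0
    coat_extent_nm: float = 55.0
    profile_length_nm: float = 200.0
    box_width_nm: float = 200.0
    margin_nm: float = 30.0
    noise_sd_gray: float = 0.0
    n_sections_per_group: int = 14
    mutant_coat_scale: float = 0.3
    rng_seed: int = 0

    def validate(self) -> None:
        if self.pixel_size_nm <= 0:
            raise SizingError(f"pixel_size_nm must be positive, got {self.pixel_size_nm}")
        for name in ("profile_length_nm", "box_width_nm", "membrane_thickness_nm", "margin_nm"):
            if getattr(self, name) <= 0:
                raise SizingError(f"{name} must be positive, got {getattr(self, name)}")
        for name in (
            "membrane_depth_gray",
            "coat_amplitude_gray",
            "actin_amplitude_gray",
            "coat_extent_nm",
            "noise_sd_gray",
            "mutant_coat_scale",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_sections_per_group < 1:
            raise ValidationError("n_sections_per_group must be >= 1")


@dataclass
class CoatPhantomResult:
    images: dict[str, list[np.ndarray]]
    pixel_size_nm: float
    box: ProfileBox
    truth_positions: np.ndarray  # 1-nm grid over the profile length
    truth_profiles: dict[str, np.ndarray]  # noise-free normalized staining per group
    true_ratio: dict[str, float]  # true coat/actin amplitude ratio per group


def coat_staining(spec: CoatPhantomSpec, x_nm, coat_scale: float = 1.0) -> np.ndarray:
    """Noise-free staining (gray units removed from background) at profile positions."""
    x = np.asarray(x_nm, dtype=float)
    inner = spec.outer_leaflet_nm + spec.membrane_thickness_nm
    coat_start = spec.outer_leaflet_nm - spec.coat_extent_nm
    s = np.zeros_like(x)
    s = np.where((x >= coat_start) & (x < spec.outer_leaflet_nm), spec.coat_amplitude_gray * coat_scale, s)
    s = np.where((x >= spec.outer_leaflet_nm) & (x < inner), spec.membrane_depth_gray, s)
    s = np.where(x >= inner, spec.actin_amplitude_gray, s)
    return s


def generate_coat_phantom(spec: CoatPhantomSpec) -> CoatPhantomResult:
    """Per-group TEM membrane images plus the noise-free normalized ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    px = spec.pixel_size_nm
    width_nm = spec.profile_length_nm + 2 * spec.margin_nm
    height_nm = spec.box_width_nm + 2 * spec.margin_nm
    ncol = int(math.ceil(width_nm / px)) + 1
    nrow = int(math.ceil(height_nm / px)) + 1

    x_px = np.arange(ncol) * px - spec.margin_nm  # profile position of each column
    scales = {"control": 1.0, "mutant": spec.mutant_coat_scale}
    images: dict[str, list[np.ndarray]] = {}
    for group, scale in scales.items():
        base_row = spec.background_gray - coat_staining(spec, x_px, scale)
        base = np.tile(base_row, (nrow, 1))
        imgs = []
        for _ in range(spec.n_sections_per_group):
            img = base.copy()
            if spec.noise_sd_gray > 0:
                img = img + rng.normal(0.0, spec.noise_sd_gray, size=img.shape)
            imgs.append(img)
        images[group] = imgs

    yc = spec.margin_nm + spec.box_width_nm / 2.0
    box = ProfileBox(
        p0_nm=(spec.margin_nm, yc),
        p1_nm=(spec.margin_nm + spec.profile_length_nm, yc),
        width_nm=spec.box_width_nm,
    )

    grid = np.arange(0.0, math.floor(spec.profile_length_nm) + 1.0)
    truth_profiles = {}
    true_ratio = {}
    for group, scale in scales.items():
        s = coat_staining(spec, grid, scale)
        if spec.actin_amplitude_gray > 0:
            truth_profiles[group] = s / spec.actin_amplitude_gray
            true_ratio[group] = spec.coat_amplitude_gray * scale / spec.actin_amplitude_gray
        else:
            truth_profiles[group] = s
            true_ratio[group] = math.nan
    return CoatPhantomResult(
        images=images,
        pixel_size_nm=px,
        box=box,
        truth_positions=grid,
        truth_profiles=truth_profiles,
        true_ratio=true_ratio,
    )


def write_coat_phantom(result: CoatPhantomResult, out_dir) -> None:
    """Write phantom images (float32 TIFF) plus an ROI table and the truth traces."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    roi_rows = []
    for group, imgs in result.images.items():
        for i, img in enumerate(imgs):
            name = f"{group}_{i:03d}.tif"
            tifffile.imwrite(str(out / name), img.astype(np.float32))
            roi_rows.append(
                {
                    "image": name,
                    "section_id": f"{group}_{i:03d}",
                    "group": group,
                    "location": "tip_tall",
                    "x0_nm": result.box.p0_nm[0],
                    "y0_nm": result.box.p0_nm[1],
                    "x1_nm": result.box.p1_nm[0],
                    "y1_nm": result.box.p1_nm[1],
                    "width_nm": result.box.width_nm,
                }
            )
    pd.DataFrame(roi_rows).to_csv(out / "rois.csv", index=False)
    truth = pd.DataFrame({"position_nm": result.truth_positions})
    for group, trace in result.truth_profiles.items():
        truth[f"{group}_normalized"] = trace
    truth.to_csv(out / "truth_profiles.csv", index=False)
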