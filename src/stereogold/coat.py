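"""Membrane-perpendicular staining profiles and two-group coat comparison.

A ~200 x 200 nm box is placed across the stereociliary membrane with the
inner leaflet on its midline; the raw profile is the image intensity
sampled along the box axis (extracellular end first) averaged across the
box width. Staining is defined as background minus intensity (stain darkens
TEM images), regridded to 1-nm steps by linear interpolation and divided by
the mean staining over the actin window (140-200 nm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .exceptions import (
    ConsistencyError,
    NormalizationError,
    ParameterError,
    ProfileBoundsError,
)

DEFAULT_ACTIN_WINDOW = (140.0, 200.0)
DEFAULT_COAT_WINDOW = (30.0, 85.0)
DEFAULT_MEMBRANE_WINDOW = (85.0, 105.0)
DEFAULT_BACKGROUND_NM = 20.0


@dataclass
class ProfileBox:
    """Measurement box: axis from the extracellular end ``p0`` to the
    intracellular end ``p1`` (nm, image (x, y)), averaged over ``width_nm``."""

    p0_nm: tuple[float, float]
    p1_nm: tuple[float, float]
    width_nm: float = 200.0
    background_value: float | None = None  # precomputed cell-free ROI mean, if any

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ParameterError(f"box width must be positive, got {self.width_nm}")
        if np.allclose(self.p0_nm, self.p1_nm):
            raise ParameterError("box axis endpoints must be distinct")

    @property
    def length_nm(self) -> float:
        return math.hypot(self.p1_nm[0] - self.p0_nm[0], self.p1_nm[1] - self.p0_nm[1])


@dataclass
class IntensityProfile:
    """A 1-nm-gridded, background-subtracted, actin-normalized staining profile."""

    positions_nm: np.ndarray
    values: np.ndarray
    pixel_size_nm: float | None = None
    background_value: float | None = None
    actin_value: float | None = None
    section_id: str | None = None
    group: str | None = None


def extract_profile(
    image: np.ndarray, box: ProfileBox, pixel_size_nm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Raw intensity along the box axis, bilinearly averaged across the width.

    Samples at the native pixel pitch (the exact axis endpoint is always
    included); position 0 is the extracellular end. Raises
    :class:`ProfileBoundsError` if any sample falls outside the image.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ParameterError(f"image must be 2D grayscale, got ndim={img.ndim}")
    if pixel_size_nm <= 0:
        raise ParameterError("pixel_size_nm must be positive")
    p0 = np.asarray(box.p0_nm, dtype=float)
    p1 = np.asarray(box.p1_nm, dtype=float)
    length = box.length_nm
    u = (p1 - p0) / length
    n = np.array([-u[1], u[0]])  # +90 deg rotation of the axis

    positions = np.arange(0.0, length, pixel_size_nm)
    if positions[-1] < length:
        positions = np.append(positions, length)
    n_w = max(1, int(round(box.width_nm / pixel_size_nm))) + 1
    offsets = np.linspace(-box.width_nm / 2.0, box.width_nm / 2.0, n_w)

    # sample grid in nm: (n_pos, n_w, 2) as (x, y)
    pts = p0[None, None, :] + positions[:, None, None] * u[None, None, :] + offsets[None, :, None] * n[None, None, :]
    cols = pts[..., 0] / pixel_size_nm
    rows = pts[..., 1] / pixel_size_nm
    eps = 1e-9
    if (
        rows.min() < -eps
        or cols.min() < -eps
        or rows.max() > img.shape[0] - 1 + eps
        or cols.max() > img.shape[1] - 1 + eps
    ):
        raise ProfileBoundsError("measurement box extends outside the image")
    sampled = ndimage.map_coordinates(
        img, [rows.ravel(), cols.ravel()], order=1, mode="nearest"
    ).reshape(rows.shape)
    return positions, sampled.mean(axis=1)


def normalize_profile(
    positions_nm: np.ndarray,
    values: np.ndarray,
    pixel_size_nm: float | None = None,
    background_value: float | None = None,
    background_window_nm: float = DEFAULT_BACKGROUND_NM,
    actin_window: tuple[float, float] = DEFAULT_ACTIN_WINDOW,
    grid_step_nm: float = 1.0,
    section_id: str | None = None,
    group: str | None = None,
) -> IntensityProfile:
    """Background-subtract, regrid to 1-nm steps and actin-normalize a raw profile.

    Staining is ``B - I`` with ``B`` the supplied background gray (cell-free
    ROI mean) or the raw mean over the first ``background_window_nm``.
    """
    pos = np.asarray(positions_nm, dtype=float)
    raw = np.asarray(values, dtype=float)
    if pos.shape != raw.shape or pos.ndim != 1 or len(pos) < 2:
        raise ParameterError("positions and values must be matching 1D arrays of length >= 2")
    if pos[-1] < actin_window[1]:
        raise ParameterError(
            f"profile ends at {pos[-1]:.1f} nm and does not cover the actin window {actin_window}"
        )
    if background_value is None:
        head = raw[pos <= background_window_nm]
        if len(head) == 0:
            raise ParameterError("no samples within the background window")
        background_value = float(head.mean())
    staining = background_value - raw

    grid = np.arange(0.0, math.floor(pos[-1] / grid_step_nm) * grid_step_nm + grid_step_nm / 2, grid_step_nm)
    vals = np.interp(grid, pos, staining)
    in_actin = (grid >= actin_window[0]) & (grid <= actin_window[1])
    actin = float(vals[in_actin].mean())
    if actin <= 0:
        raise NormalizationError(f"actin-window mean staining is {actin:.4g} <= 0; cannot normalize")
    return IntensityProfile(
        positions_nm=grid,
        values=vals / actin,
        pixel_size_nm=pixel_size_nm,
        background_value=background_value,
        actin_value=actin,
        section_id=section_id,
        group=group,
    )


def average_profiles(profiles: list[IntensityProfile]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise mean and s.e.m. across sections; grids must match exactly."""
    if len(profiles) < 2:
        raise ParameterError("need at least 2 profiles to average")
    grid = profiles[0].positions_nm
    for p in profiles[1:]:
        if len(p.positions_nm) != len(grid) or not np.array_equal(p.positions_nm, grid):
            raise ConsistencyError("profiles are not on a common grid")
    stack = np.stack([p.values for p in profiles])
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / math.sqrt(len(profiles))
    return grid, mean, sem


def _window_mean(profile: IntensityProfile, window: tuple[float, float]) -> float:
    sel = (profile.positions_nm >= window[0]) & (profile.positions_nm <= window[1])
    if not sel.any():
        raise ParameterError(f"window {window} selects no grid points")
    return float(profile.values[sel].mean())


def _ttest(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float]:
    # guard the all-constant degenerate case (identical groups -> t=0, p=1)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.inf if a.mean() > b.mean() else -math.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


@dataclass
class WindowComparison:
    window_nm: tuple[float, float]
    control_values: np.ndarray  # per-section summary
    mutant_values: np.ndarray
    t: float
    p: float


@dataclass
class CoatComparison:
    """Group mean +/- s.e.m. traces, their difference, and per-window t tests."""

    positions_nm: np.ndarray
    control_mean: np.ndarray
    control_sem: np.ndarray
    mutant_mean: np.ndarray
    mutant_sem: np.ndarray
    difference: np.ndarray  # control - mutant, pointwise
    coat: WindowComparison
    membrane: WindowComparison
    n_control: int
    n_mutant: int


def compare_groups(
    control: list[IntensityProfile],
    mutant: list[IntensityProfile],
    coat_window: tuple[float, float] = DEFAULT_COAT_WINDOW,
    membrane_window: tuple[float, float] = DEFAULT_MEMBRANE_WINDOW,
    equal_var: bool = True,
) -> CoatComparison:
    """Two-group comparison of per-section coat and membrane window means.

    Uses a two-sample two-tailed Student's t test (equal variance by
    default; set ``equal_var=False`` for Welch).
    """
    grid, c_mean, c_sem = average_profiles(control)
    grid_m, m_mean, m_sem = average_profiles(mutant)
    if not np.array_equal(grid, grid_m):
        raise ConsistencyError("control and mutant profiles are not on a common grid")

    comparisons = {}
    for name, window in (("coat", coat_window), ("membrane", membrane_window)):
        c_vals = np.array([_window_mean(p, window) for p in control])
        m_vals = np.array([_window_mean(p, window) for p in mutant])
        t, p = _ttest(c_vals, m_vals, equal_var)
        comparisons[name] = WindowComparison(
            window_nm=tuple(window), control_values=c_vals, mutant_values=m_vals, t=t, p=p
        )

    return CoatComparison(
        positions_nm=grid,
        control_mean=c_mean,
        control_sem=c_sem,
        mutant_mean=m_mean,
        mutant_sem=m_sem,
        difference=c_mean - m_mean,
        coat=comparisons["coat"],
        membrane=comparisons["membrane"],
        n_control=len(control),
        n_mutant=len(mutant),
    )
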