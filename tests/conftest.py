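import numpy as np
import pytest

import stereogold as sg
from stereogold import synthetic


def cylinder_cloud(
    length_nm: float,
    radius_nm: float,
    n: int = 4000,
    rng=None,
    axis=None,
    origin=None,
) -> np.ndarray:
    """Ideal lateral-surface point cloud of a cylinder, (z, y, x) nm.

    Default axis is +z with the base at the origin; points are uniform in
    axial position and azimuth.
    """
    rng = np.random.default_rng(rng)
    t = rng.uniform(0.0, length_nm, n)
    phi = rng.uniform(0.0, 2 * np.pi, n)
    pts = np.stack([t, radius_nm * np.cos(phi), radius_nm * np.sin(phi)], axis=1)
    if axis is not None:
        pts = rotate_zyx_onto(pts, np.array([1.0, 0.0, 0.0]), np.asarray(axis, float))
    if origin is not None:
        pts = pts + np.asarray(origin, float)
    return pts


def rotation_matrix_zyx(axis_zyx, angle_rad: float) -> np.ndarray:
    """Proper rotation matrix acting on (z, y, x)-ordered vectors."""
    from scipy.spatial.transform import Rotation

    axis_xyz = np.asarray(axis_zyx, float)[::-1]
    axis_xyz = axis_xyz / np.linalg.norm(axis_xyz)
    R = Rotation.from_rotvec(angle_rad * axis_xyz).as_matrix()
    P = np.eye(3)[::-1]  # permutation xyz <-> zyx
    return P @ R @ P


def rotate_zyx(points: np.ndarray, R_zyx: np.ndarray) -> np.ndarray:
    return np.asarray(points, float) @ R_zyx.T


def rotate_zyx_onto(points: np.ndarray, src_zyx, dst_zyx) -> np.ndarray:
    """Rotate points by the minimal rotation carrying ``src`` onto ``dst``."""
    src = np.asarray(src_zyx, float)
    dst = np.asarray(dst_zyx, float)
    src = src / np.linalg.norm(src)
    dst = dst / np.linalg.norm(dst)
    v = np.cross(src[::-1], dst[::-1])[::-1]
    s = np.linalg.norm(v)
    c = float(np.dot(src, dst))
    if s < 1e-12:
        return points if c > 0 else -points
    ang = np.arctan2(s, c)
    return rotate_zyx(points, rotation_matrix_zyx(v / s, ang))


def make_geometry(
    cilium_id: int,
    points: np.ndarray,
    axis,
    taper,
    tip,
    row: str = "tall",
    diameter_nm: float = 150.0,
) -> sg.CiliumGeometry:
    axis = np.asarray(axis, float)
    taper = np.asarray(taper, float)
    tip = np.asarray(tip, float)
    return sg.CiliumGeometry(
        cilium_id=cilium_id,
        row=row,
        surface_points=np.asarray(points, float),
        axis=axis / np.linalg.norm(axis),
        tip_nm=tip,
        taper_nm=taper,
        height_nm=float(np.dot(tip - taper, axis)),
        diameter_nm=diameter_nm,
        base_centroid_nm=taper,
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A small (2 cilia/row) phantom with uniform bead density and 5 decoys."""
    spec = sg.BundlePhantomSpec(
        n_cilia_per_row={"tall": 2, "middle": 2, "short": 2},
        bead_density_field=synthetic.uniform_field(30.0),
        n_decoy_beads=5,
        rng_seed=1,
    )
    vol, truth = sg.generate_bundle_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def small_analysis(small_bundle):
    _, vol, _ = small_bundle
    return sg.map_bundle(vol, seed=0)
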