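"""Leaf inclination and azimuth from local plane fits.

For every point, the points inside an axis-aligned cube of side L (default
0.5 cm) centered on it are gathered and an orthogonal least-squares plane is
fitted: the plane normal is the least-variance direction of the centered
neighborhood (smallest eigenvector of its covariance).  The normal's zenith
angle — arccos of its (up-signed) z-component — is the leaf inclination
angle; its azimuth is the compass direction of the normal's horizontal
projection, measured counterclockwise from +x in [0°, 360°).

Normals are up-signed, so zenith lives in [0°, 90°]; a plane fit cannot tell
a leaf's top from its bottom, so leaves known to droop below the horizontal
get their sign restored afterwards from per-leaf orientation flags
(:func:`apply_leaf_sign`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cloud import CALIBRATED, ColoredPointCloud
from .errors import (
    DegenerateNeighborhoodError,
    FrameError,
    ValidationError,
)

#: below this zenith (degrees) the azimuth is numerically meaningless
DEFAULT_HORIZONTAL_THRESHOLD = 1.0


@dataclass
class NeighborhoodSpec:
    """Cubic-neighborhood parameters: cube side L (cm) and minimum points."""

    cube_side: float = 0.5
    min_points: int = 10

    def __post_init__(self) -> None:
        if self.cube_side <= 0:
            raise ValidationError("cube_side must be > 0")
        if self.min_points < 3:
            raise ValidationError("min_points must be >= 3 (a plane needs 3 points)")


@dataclass
class AngleField:
    """Per-point angle estimates with validity bookkeeping.

    ``zenith`` in [0, 90]°, ``azimuth`` in [0, 360)°; both are NaN where
    ``valid`` is False (too few neighbors or a degenerate neighborhood).
    ``azimuth_defined`` is additionally False where the surface is within the
    horizontal threshold of flat, so the azimuth direction is arbitrary.
    ``signed_zenith`` appears once per-leaf orientation flags are applied.
    """

    zenith: np.ndarray
    azimuth: np.ndarray
    valid: np.ndarray
    n_neighbors: np.ndarray
    azimuth_defined: np.ndarray
    signed_zenith: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.zenith)


def cube_neighborhood(
    cloud: ColoredPointCloud,
    index: int,
    spec: NeighborhoodSpec,
    tree: cKDTree | None = None,
) -> np.ndarray:
    """Indices of points inside the L-cube centered on point ``index``.

    The cube is axis-aligned in the calibrated frame with closed bounds:
    a point belongs iff |p_k − c_k| ≤ L/2 on every axis, so the target point
    itself is always included.
    """
    if cloud.frame != CALIBRATED:
        raise FrameError("cube_neighborhood needs a calibrated cloud (L is in cm)")
    if not 0 <= index < len(cloud):
        raise ValidationError(f"point index {index} out of range")
    if tree is None:
        tree = cKDTree(cloud.points)
    # Chebyshev ball of radius L/2 == closed axis-aligned cube of side L
    idx = tree.query_ball_point(cloud.points[index], r=spec.cube_side / 2.0, p=np.inf)
    return np.sort(np.asarray(idx, dtype=np.int64))


def fit_plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the orthogonal least-squares plane through ``points``.

    The normal is the eigenvector of the centered covariance with the
    smallest eigenvalue (direction of least variance).  Sign convention:
    z-component ≥ 0; when it is exactly 0, the first nonzero of (x, y) is
    made positive.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(points) < 3:
        raise DegenerateNeighborhoodError(
            f"plane fit needs >= 3 points, got {len(points)}"
        )
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    # collinear/coincident points: two vanishing variance directions
    if eigvals[1] <= 1e-12 * max(eigvals[-1], np.finfo(float).tiny):
        raise DegenerateNeighborhoodError(
            "neighborhood points are collinear or coincident; plane undefined"
        )
    normal = eigvecs[:, 0]
    normal = normal / np.linalg.norm(normal)
    if normal[2] < 0:
        normal = -normal
    elif normal[2] == 0:
        if normal[0] < 0 or (normal[0] == 0 and normal[1] < 0):
            normal = -normal
    return normal


def normal_to_angles(
    normal: np.ndarray,
    horizontal_threshold: float = DEFAULT_HORIZONTAL_THRESHOLD,
) -> tuple[float, float, bool]:
    """(zenith°, azimuth°, azimuth_defined) of an up-signed unit normal.

    zenith = arccos(n_z) ∈ [0, 90]; azimuth = atan2(n_y, n_x) mapped to
    [0, 360).  For zeniths below ``horizontal_threshold`` degrees the
    azimuth is still reported but flagged undefined.
    """
    normal = np.asarray(normal, dtype=np.float64).reshape(3)
    norm = np.linalg.norm(normal)
    if abs(norm - 1.0) > 1e-6:
        raise ValidationError(f"normal must be a unit vector, |n| = {norm:.8f}")
    if normal[2] < 0:
        raise ValidationError("normal must be up-signed (n_z >= 0)")
    zenith = float(np.degrees(np.arccos(np.clip(normal[2], -1.0, 1.0))))
    azimuth = float(np.degrees(np.arctan2(normal[1], normal[0])) % 360.0)
    return zenith, azimuth, zenith >= horizontal_threshold


def compute_angle_field(
    cloud: ColoredPointCloud,
    spec: NeighborhoodSpec | None = None,
    horizontal_threshold: float = DEFAULT_HORIZONTAL_THRESHOLD,
    stride: int = 1,
) -> AngleField:
    """Per-point zenith/azimuth over a whole calibrated cloud.

    Runs cube_neighborhood → fit_plane_normal → normal_to_angles at every
    point (or every ``stride``-th point); under-populated or degenerate
    neighborhoods are masked invalid, never extrapolated.  Results are also
    written back to the cloud as ``zenith``, ``azimuth`` and ``angle_valid``
    attributes.
    """
    if cloud.frame != CALIBRATED:
        raise FrameError("compute_angle_field needs a calibrated cloud")
    spec = spec or NeighborhoodSpec()
    n = len(cloud)
    zenith = np.full(n, np.nan)
    azimuth = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    azimuth_defined = np.zeros(n, dtype=bool)
    n_neighbors = np.zeros(n, dtype=np.int64)
    if n:
        tree = cKDTree(cloud.points)
        half = spec.cube_side / 2.0
        neighbor_lists = tree.query_ball_point(
            cloud.points[::stride], r=half, p=np.inf
        )
        for row, idx in zip(range(0, n, stride), neighbor_lists):
            nbrs = np.asarray(idx, dtype=np.int64)
            n_neighbors[row] = len(nbrs)
            if len(nbrs) < spec.min_points:
                continue
            try:
                normal = fit_plane_normal(cloud.points[nbrs])
            except DegenerateNeighborhoodError:
                continue
            z, a, a_def = normal_to_angles(normal, horizontal_threshold)
            zenith[row], azimuth[row] = z, a
            valid[row] = True
            azimuth_defined[row] = a_def
    if n and not valid.any():
        warnings.warn(
            "no point had a valid neighborhood; the whole angle field is masked",
            stacklevel=2,
        )
    cloud.attributes["zenith"] = zenith
    cloud.attributes["azimuth"] = azimuth
    cloud.attributes["angle_valid"] = valid.astype(np.float64)
    return AngleField(
        zenith=zenith,
        azimuth=azimuth,
        valid=valid,
        n_neighbors=n_neighbors,
        azimuth_defined=azimuth_defined,
    )


def apply_leaf_sign(
    field: AngleField,
    cloud: ColoredPointCloud,
    leaf_orientation: dict[int, str],
) -> AngleField:
    """Attach signed zeniths from per-leaf up/down orientation flags.

    Leaves flagged ``"down"`` (drooping below the horizontal) get negative
    signed zeniths; everything else keeps the positive value.  Flags for
    labels absent from the cloud are an error — they indicate a mismatched
    flags file.
    """
    if cloud.leaf_labels is None:
        raise ValidationError("apply_leaf_sign needs a cloud with leaf labels")
    present = set(int(v) for v in np.unique(cloud.leaf_labels))
    for label, flag in leaf_orientation.items():
        if flag not in ("up", "down"):
            raise ValidationError(f"orientation flag must be up|down, got {flag!r}")
        if int(label) not in present:
            raise ValidationError(
                f"orientation flag for leaf {label} but no such label in the cloud"
            )
    signed = field.zenith.copy()
    for label, flag in leaf_orientation.items():
        if flag == "down":
            mask = cloud.leaf_labels == int(label)
            signed[mask] = -signed[mask]
    return AngleField(
        zenith=field.zenith,
        azimuth=field.azimuth,
        valid=field.valid,
        n_neighbors=field.n_neighbors,
        azimuth_defined=field.azimuth_defined,
        signed_zenith=signed,
    )
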