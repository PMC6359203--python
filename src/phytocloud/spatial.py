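"""Spatial scale and orientation calibration from a reference cube.

Structure-from-motion reconstructions come out in arbitrary model units and an
arbitrary orientation.  Placing a box of known dimensions (here 13 cm × 12 cm
× 9 cm by default) in the scene lets us recover a similarity transform: a
metric scale (cm per model unit) from picked point pairs with known
separations, and a rotation bringing a known-vertical edge to +z.

The transform is ``p' = scale · R · p + t``; inverting and re-applying it must
restore coordinates to numerical precision.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cloud import CALIBRATED, RAW, ColoredPointCloud
from .errors import DegenerateMeasurementError, FrameError, ValidationError


@dataclass
class CubeMeasurement:
    """Picked point pairs on the reference cube.

    Each entry of ``point_pairs`` is ``(a, b, known_cm)``: two model-space
    points and the real-world distance between them in cm.  ``up_edge`` is an
    optional model-space pair known to be vertical (bottom point first).
    """

    point_pairs: list[tuple[np.ndarray, np.ndarray, float]]
    up_edge: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not self.point_pairs:
            raise ValidationError("CubeMeasurement needs at least one point pair")
        pairs = []
        for a, b, d in self.point_pairs:
            a = np.asarray(a, dtype=np.float64).reshape(3)
            b = np.asarray(b, dtype=np.float64).reshape(3)
            if d <= 0:
                raise ValidationError(f"known distance must be > 0, got {d}")
            pairs.append((a, b, float(d)))
        self.point_pairs = pairs
        if self.up_edge is not None:
            lo, hi = self.up_edge
            self.up_edge = (
                np.asarray(lo, dtype=np.float64).reshape(3),
                np.asarray(hi, dtype=np.float64).reshape(3),
            )


@dataclass
class ScaleCalibration:
    """Similarity transform mapping model space to the calibrated cm frame."""

    scale: float
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValidationError(f"scale must be > 0, got {self.scale}")
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValidationError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValidationError("rotation must be proper (det +1)")

    def transform(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return self.scale * points @ self.rotation.T + self.translation

    def inverse_transform(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return (points - self.translation) @ self.rotation / self.scale


def _rotation_to_z(direction: np.ndarray) -> np.ndarray:
    """Minimal rotation carrying ``direction`` onto +z (Rodrigues)."""
    d = direction / np.linalg.norm(direction)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(d, z))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # antiparallel: rotate by pi about x
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(d, z)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def estimate_scale_calibration(measurement: CubeMeasurement) -> ScaleCalibration:
    """Estimate scale (and optionally rotation) from reference-cube picks.

    The scale is the unweighted arithmetic mean over pairs of
    (known distance / model distance).  If ``up_edge`` is given, the rotation
    maps its direction onto +z; otherwise it is the identity.  Translation is
    zero (absolute position on the bench is arbitrary).
    """
    scales = []
    for a, b, known in measurement.point_pairs:
        model = float(np.linalg.norm(b - a))
        if model <= 0.0:
            raise DegenerateMeasurementError(
                "model-space pair separation is zero; picked points coincide"
            )
        scales.append(known / model)
    rotation = np.eye(3)
    if measurement.up_edge is not None:
        lo, hi = measurement.up_edge
        edge = hi - lo
        if np.linalg.norm(edge) <= 0.0:
            raise DegenerateMeasurementError("up-edge points coincide")
        rotation = _rotation_to_z(edge)
    return ScaleCalibration(
        scale=float(np.mean(scales)), rotation=rotation, translation=np.zeros(3)
    )


def apply_calibration(
    cloud: ColoredPointCloud, cal: ScaleCalibration
) -> ColoredPointCloud:
    """Map a raw cloud into the calibrated cm, z-up frame.

    Colors, attributes and labels are untouched.  Re-applying to an already
    calibrated cloud raises (double scaling would silently corrupt units).
    """
    if cloud.frame == CALIBRATED:
        raise FrameError("cloud is already calibrated; refusing to scale twice")
    out = cloud.copy()
    out.points = cal.transform(cloud.points)
    out.frame = CALIBRATED
    return out


def load_cube_measurement(path: str | Path) -> CubeMeasurement:
    """Load picked pairs from CSV (ax..bz,known_cm[,kind]) or JSON."""
    path = Path(path)
    pairs: list[tuple[np.ndarray, np.ndarray, float]] = []
    up_edge = None
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        for row in payload.get("pairs", []):
            pairs.append((np.asarray(row["a"]), np.asarray(row["b"]),
                          float(row["known_cm"])))
        if "up_edge" in payload:
            edge = payload["up_edge"]
            up_edge = (np.asarray(edge["a"]), np.asarray(edge["b"]))
    else:
        with open(path, newline="") as handle:
            for row in csv.DictReader(handle):
                a = np.array([float(row["ax"]), float(row["ay"]), float(row["az"])])
                b = np.array([float(row["bx"]), float(row["by"]), float(row["bz"])])
                if row.get("kind", "pair").strip() == "up_edge":
                    up_edge = (a, b)
                else:
                    pairs.append((a, b, float(row["known_cm"])))
    return CubeMeasurement(point_pairs=pairs, up_edge=up_edge)
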