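"""Synthetic plant clouds with known ground truth.

Real calibrated scans of stressed plants are not shippable, so this module
generates what the pipeline consumes — colored, labeled point clouds — from
fully known parameters: elliptical leaf patches at specified inclination and
azimuth (optionally bent by a parabolic fold), an affine within-leaf
chlorophyll field, Gaussian noise along the surface normal, a reference cube
of known edge lengths, and multi-day water-stress trajectories whose per-day
per-leaf target means are linearly interpolated between anchor days.

Colors are produced by inverting the chlorophyll calibration line: the red
channel is fixed so R/(R+G+B) hits the target normalized Red as exactly as
8-bit quantization allows (green is held at a leaf-like constant and blue
absorbs the remainder).  The resulting quantization step is the documented
noise floor of chlorophyll round-trip tests.

All randomness flows from a single integer seed through numpy Generators;
identical seeds give bit-identical clouds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cloud import CALIBRATED, RAW, ColoredPointCloud, concatenate
from .chlorophyll import CalibrationCurve, CalibrationSample
from .errors import ValidationError
from .spatial import CubeMeasurement
from .structure import normal_to_angles

# color realization: totals fixed at 400 with green pinned; realizable
# normalized Red is then [45/400, 255/400] = [0.1125, 0.6375]
_COLOR_TOTAL = 400
_GREEN = 100

# design calibration line used by generators: steep enough that the
# dimensionless day-mean presets land well inside the realizable r_n band
TRUE_SLOPE = -40.0
TRUE_INTERCEPT = 22.0


def design_curve() -> CalibrationCurve:
    """The generator's ground-truth calibration line (chl = −40·r_n + 22)."""
    return CalibrationCurve(
        slope=TRUE_SLOPE, intercept=TRUE_INTERCEPT, r_squared=1.0, n=0
    )


@dataclass
class LeafSpec:
    """Geometry, orientation and chlorophyll field of one synthetic leaf.

    ``chl_gradient`` is the affine field's slope in μg/mm² per cm along the
    leaf-local (long, short) axes; the field's value at the leaf center is
    ``chl_base``, which is also the leaf's expected mean (the patch is
    centered).  ``noise_sigma`` is Gaussian displacement along the local
    surface normal, emulating reconstruction roughness.
    """

    label: int
    center: tuple[float, float, float] = (0.0, 0.0, 30.0)
    long_axis_length: float = 4.0  # cm
    short_axis_length: float = 2.0  # cm
    zenith_true: float = 30.0  # degrees
    azimuth_true: float = 90.0  # degrees
    curvature: float = 0.0  # 1/cm, parabolic fold across the short axis
    orientation: str = "up"
    chl_base: float = 10.0
    chl_gradient: tuple[float, float] = (0.3, 0.0)
    point_density: float = 400.0  # points per cm^2
    noise_sigma: float = 0.02  # cm

    def __post_init__(self) -> None:
        if self.long_axis_length <= 0 or self.short_axis_length <= 0:
            raise ValidationError("leaf axis lengths must be > 0")
        if not 0.0 <= self.zenith_true <= 90.0:
            raise ValidationError("zenith_true must lie in [0, 90]")
        if self.point_density <= 0:
            raise ValidationError("point_density must be > 0")
        if self.orientation not in ("up", "down"):
            raise ValidationError("orientation must be 'up' or 'down'")


@dataclass
class LeafTruth:
    """Per-point ground truth carried alongside a generated leaf."""

    label: int
    chlorophyll: np.ndarray
    zenith: np.ndarray
    azimuth: np.ndarray
    normals: np.ndarray
    n_clipped: int
    orientation: str


@dataclass
class StressScenario:
    """Multi-day trajectories of per-leaf target means.

    ``trajectories[label][quantity]`` maps anchor day → target value;
    intermediate days are linearly interpolated.  Quantities are
    ``chlorophyll`` (leaf-mean), ``zenith`` and ``azimuth`` (degrees).
    """

    days: int
    trajectories: dict[int, dict[str, dict[int, float]]]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValidationError("scenario must span at least 1 day")

    def value(self, label: int, quantity: str, day: int, default: float) -> float:
        anchors = self.trajectories.get(label, {}).get(quantity)
        if not anchors:
            return default
        days = np.array(sorted(anchors))
        vals = np.array([anchors[d] for d in sorted(anchors)], dtype=np.float64)
        return float(np.interp(day, days, vals))


def _rotation(zenith_deg: float, azimuth_deg: float) -> np.ndarray:
    """Rz(azimuth) @ Ry(zenith): local +z maps to the leaf normal."""
    t = np.radians(zenith_deg)
    p = np.radians(azimuth_deg)
    ry = np.array([
        [np.cos(t), 0.0, np.sin(t)],
        [0.0, 1.0, 0.0],
        [-np.sin(t), 0.0, np.cos(t)],
    ])
    rz = np.array([
        [np.cos(p), -np.sin(p), 0.0],
        [np.sin(p), np.cos(p), 0.0],
        [0.0, 0.0, 1.0],
    ])
    return rz @ ry


def _realize_colors(r_n: np.ndarray) -> tuple[np.ndarray, int]:
    """8-bit RGB whose normalized Red approximates ``r_n`` as closely as
    the fixed-total scheme allows; returns (colors, number clipped)."""
    red_exact = r_n * _COLOR_TOTAL
    red = np.rint(red_exact).astype(np.int64)
    clipped = (red < 0) | (red > 255)
    red = np.clip(red, 0, 255)
    blue = _COLOR_TOTAL - _GREEN - red
    blue_bad = (blue < 0) | (blue > 255)
    clipped |= blue_bad
    blue = np.clip(blue, 0, 255)
    colors = np.column_stack([
        red,
        np.full_like(red, _GREEN),
        blue,
    ]).astype(np.uint8)
    return colors, int(np.count_nonzero(clipped))


def make_leaf(
    spec: LeafSpec,
    curve: CalibrationCurve | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[ColoredPointCloud, LeafTruth]:
    """Generate one leaf patch plus its ground truth.

    Points are sampled uniformly over the elliptical patch at the requested
    density, lifted by the parabolic fold, jittered along the local analytic
    normal, then rotated to (zenith_true, azimuth_true) and translated to the
    center.  Colors encode the chlorophyll field through the inverted
    calibration line.
    """
    curve = curve or design_curve()
    if curve.slope == 0:
        raise ValidationError("calibration line must have nonzero slope")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    a = spec.long_axis_length / 2.0
    b = spec.short_axis_length / 2.0
    n = max(3, int(round(spec.point_density * np.pi * a * b)))
    radius = np.sqrt(rng.uniform(0.0, 1.0, n))
    angle = rng.uniform(0.0, 2.0 * np.pi, n)
    u = radius * np.cos(angle) * a
    v = radius * np.sin(angle) * b
    w = 0.5 * spec.curvature * v**2

    # analytic surface normal of w(u, v): (−∂w/∂u, −∂w/∂v, 1) normalized
    local_normals = np.column_stack([
        np.zeros(n),
        -spec.curvature * v,
        np.ones(n),
    ])
    local_normals /= np.linalg.norm(local_normals, axis=1, keepdims=True)

    local = np.column_stack([u, v, w])
    if spec.noise_sigma > 0:
        local = local + local_normals * rng.normal(0.0, spec.noise_sigma, (n, 1))

    rot = _rotation(spec.zenith_true, spec.azimuth_true)
    points = local @ rot.T + np.asarray(spec.center, dtype=np.float64)
    world_normals = local_normals @ rot.T
    flip = world_normals[:, 2] < 0
    world_normals[flip] = -world_normals[flip]
    zen = np.empty(n)
    azi = np.empty(n)
    for i in range(n):
        zen[i], azi[i], _ = normal_to_angles(world_normals[i],
                                             horizontal_threshold=0.0)

    gu, gv = spec.chl_gradient
    chl = spec.chl_base + gu * u + gv * v
    r_n = np.asarray(curve.invert(chl))
    colors, n_clipped = _realize_colors(r_n)
    if n_clipped > n // 2:
        raise ValidationError(
            f"chlorophyll field maps {n_clipped}/{n} points outside the "
            f"realizable normalized-red band "
            f"[{45/_COLOR_TOTAL:.4f}, {255/_COLOR_TOTAL:.4f}]; "
            "adjust chl_base/chl_gradient or the calibration line"
        )
    cloud = ColoredPointCloud(
        points=points,
        colors=colors,
        leaf_labels=np.full(n, spec.label, dtype=np.int64),
        frame=CALIBRATED,
    )
    truth = LeafTruth(
        label=spec.label,
        chlorophyll=chl,
        zenith=zen,
        azimuth=azi,
        normals=world_normals,
        n_clipped=n_clipped,
        orientation=spec.orientation,
    )
    return cloud, truth


def make_reference_cube(
    edges: tuple[float, float, float] = (13.0, 12.0, 9.0),
    density: float = 10.0,
    seed: int | np.random.Generator = 0,
    model_scale: float = 1.0,
) -> tuple[ColoredPointCloud, CubeMeasurement]:
    """Surface samples of the scale-reference box plus picked corner pairs.

    ``model_scale`` expresses the cloud in model units = cm × model_scale
    (a reconstruction at true scale s corresponds to model_scale = 1/s).
    The returned measurement pairs are the three edges from the origin
    corner, with known distances equal to the edge lengths in cm, and the
    vertical edge as the up-edge.
    """
    ex, ey, ez = edges
    if min(edges) <= 0:
        raise ValidationError("cube edges must be > 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    faces = []
    for axis, extent in enumerate(edges):
        others = [e for i, e in enumerate(edges) if i != axis]
        area = others[0] * others[1]
        n_face = max(4, int(round(density * area)))
        for level in (0.0, extent):
            uv = rng.uniform(0.0, 1.0, (n_face, 2)) * np.array(others)
            pts = np.empty((n_face, 3))
            pts[:, axis] = level
            other_axes = [i for i in range(3) if i != axis]
            pts[:, other_axes[0]] = uv[:, 0]
            pts[:, other_axes[1]] = uv[:, 1]
            faces.append(pts)
    points = np.vstack(faces) * model_scale
    colors = np.full((len(points), 3), 128, dtype=np.uint8)
    cloud = ColoredPointCloud(points=points, colors=colors, frame=RAW)
    origin = np.zeros(3)
    s = model_scale
    measurement = CubeMeasurement(
        point_pairs=[
            (origin, np.array([ex * s, 0.0, 0.0]), ex),
            (origin, np.array([0.0, ey * s, 0.0]), ey),
            (origin, np.array([0.0, 0.0, ez * s]), ez),
        ],
        up_edge=(origin, np.array([0.0, 0.0, ez * s])),
    )
    return cloud, measurement


def make_calibration_samples(
    n: int = 30,
    r_squared: float = 0.81,
    curve: CalibrationCurve | None = None,
    r_n_range: tuple[float, float] = (0.2, 0.4),
    seed: int | np.random.Generator = 0,
) -> list[CalibrationSample]:
    """Paired (normalized Red, chlorophyll) samples around the design line.

    Gaussian response noise is sized so the *population* R² of the sampling
    scheme equals ``r_squared``; the fitted R² of one draw then scatters
    around that target as it would in a real calibration experiment.
    """
    curve = curve or design_curve()
    if not 0 < r_squared <= 1:
        raise ValidationError("r_squared target must lie in (0, 1]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    lo, hi = r_n_range
    r_n = rng.uniform(lo, hi, n)
    signal_var = curve.slope**2 * (hi - lo) ** 2 / 12.0
    noise_var = signal_var * (1.0 - r_squared) / r_squared
    chl = np.asarray(curve.predict(r_n)) + rng.normal(0.0, np.sqrt(noise_var), n)
    chl = np.maximum(chl, 0.0)
    return [CalibrationSample(normalized_red=float(r), chlorophyll=float(c))
            for r, c in zip(r_n, chl)]


def fig4_leaves() -> list[LeafSpec]:
    """Three-leaf plant mimicking the monitored sample: leaf 1 is the old,
    bottom, downward-inclined leaf whose trajectories follow the observed
    day-1/3/5 means; leaves 2 and 3 are younger with milder trends."""
    return [
        LeafSpec(label=1, center=(0.0, 5.0, 10.0), zenith_true=23.7,
                 azimuth_true=88.6, chl_base=12.9, orientation="down"),
        LeafSpec(label=2, center=(6.0, -3.0, 20.0), zenith_true=20.0,
                 azimuth_true=200.0, chl_base=14.0, orientation="up"),
        LeafSpec(label=3, center=(-5.0, -4.0, 30.0), zenith_true=15.0,
                 azimuth_true=300.0, chl_base=15.0, orientation="up"),
    ]


def fig4_scenario(days: int = 5, seed: int = 0) -> StressScenario:
    """Five-day water-stress preset.

    Leaf 1 anchors reproduce the observed day-1/3/5 means: chlorophyll
    12.9/11.7/7.0, zenith 23.7°/33.1°/33.9°, azimuth 88.6°/119.3°/156.9°.
    Leaves 2 and 3 decline more slowly and barely reorient.
    """
    return StressScenario(
        days=days,
        seed=seed,
        trajectories={
            1: {
                "chlorophyll": {1: 12.9, 3: 11.7, 5: 7.0},
                "zenith": {1: 23.7, 3: 33.1, 5: 33.9},
                "azimuth": {1: 88.6, 3: 119.3, 5: 156.9},
            },
            2: {
                "chlorophyll": {1: 14.0, 5: 12.5},
                "zenith": {1: 20.0, 5: 23.0},
                "azimuth": {1: 200.0, 5: 205.0},
            },
            3: {
                "chlorophyll": {1: 15.0, 5: 14.2},
                "zenith": {1: 15.0, 5: 17.0},
                "azimuth": {1: 300.0, 5: 302.0},
            },
        },
    )


def make_stress_timeseries(
    plant: list[LeafSpec],
    scenario: StressScenario,
    curve: CalibrationCurve | None = None,
    seed: int | None = None,
) -> dict[int, tuple[ColoredPointCloud, dict[int, LeafTruth]]]:
    """One labeled cloud per day, per-leaf parameters driven by the scenario.

    Each day's leaf specs take their chlorophyll mean, zenith and azimuth
    from the scenario trajectories (linear interpolation between anchors);
    zeniths pushed outside [0, 90] are clamped with a warning.  Returns
    ``{day: (cloud, {label: truth})}``.
    """
    import warnings

    curve = curve or design_curve()
    if seed is None:
        seed = scenario.seed
    root = np.random.SeedSequence(seed)
    day_seeds = root.spawn(scenario.days)
    out: dict[int, tuple[ColoredPointCloud, dict[int, LeafTruth]]] = {}
    for day in range(1, scenario.days + 1):
        leaf_rngs = [np.random.default_rng(s)
                     for s in day_seeds[day - 1].spawn(len(plant))]
        clouds = []
        truths: dict[int, LeafTruth] = {}
        for spec, rng in zip(plant, leaf_rngs):
            zen = scenario.value(spec.label, "zenith", day, spec.zenith_true)
            if not 0.0 <= zen <= 90.0:
                warnings.warn(
                    f"day {day} leaf {spec.label}: zenith {zen:.1f} clamped "
                    "to [0, 90]", stacklevel=2,
                )
                zen = float(np.clip(zen, 0.0, 90.0))
            day_spec = replace(
                spec,
                zenith_true=zen,
                azimuth_true=scenario.value(
                    spec.label, "azimuth", day, spec.azimuth_true
                ) % 360.0,
                chl_base=scenario.value(
                    spec.label, "chlorophyll", day, spec.chl_base
                ),
            )
            cloud, truth = make_leaf(day_spec, curve, rng)
            clouds.append(cloud)
            truths[spec.label] = truth
        out[day] = (concatenate(clouds), truths)
    return out


def leaf_orientations(plant: list[LeafSpec]) -> dict[int, str]:
    """Per-leaf up/down flags, the input format of apply_leaf_sign."""
    return {spec.label: spec.orientation for spec in plant}
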