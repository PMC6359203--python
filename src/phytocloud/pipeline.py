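"""Full-workflow driver: calibrate → map chlorophyll → angles → monitor.

Mirrors the experimental workflow: scale the reconstructions with the
reference-cube picks, fit the color→chlorophyll calibration, map it over
every day's cloud, estimate per-point angles, and aggregate per-leaf/region
day series.  Everything is deterministic given the config seed, and a run
manifest (config echo, package version, input checksums) is written so a run
can be reproduced from its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .chlorophyll import (
    fit_calibration,
    kfold_mae,
    load_calibration_samples,
    loocv_mae,
    map_chlorophyll,
)
from .cloud import RAW, ColoredPointCloud
from .errors import PhytocloudError, ValidationError
from .monitoring import build_series, leaf_histogram
from .ply import read_ply, write_ply
from .spatial import apply_calibration, estimate_scale_calibration, load_cube_measurement
from .structure import NeighborhoodSpec, apply_leaf_sign, compute_angle_field

logger = logging.getLogger("phytocloud")


@dataclass
class PipelineConfig:
    cube_side: float = 0.5  # cm
    min_points: int = 10
    region_radius: float = 0.25  # cm
    cv_mode: str = "loo"  # loo | kfold
    chl_bin_width: float = 1.0
    angle_bin_width: float = 5.0
    horizontal_threshold: float = 1.0  # degrees
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cube_side", "region_radius", "chl_bin_width",
                     "angle_bin_width"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.min_points < 3:
            raise ValidationError("min_points must be >= 3")
        if self.cv_mode not in ("loo", "kfold"):
            raise ValidationError("cv_mode must be 'loo' or 'kfold'")
        if self.horizontal_threshold < 0:
            raise ValidationError("horizontal_threshold must be >= 0")

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


class StageError(PhytocloudError):
    """Wraps a failure with the pipeline stage and offending input."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {detail}")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    cloud_paths: list[str | Path],
    samples_path: str | Path,
    out_dir: str | Path,
    labels_path: str | Path | None = None,
    cube_measurement_path: str | Path | None = None,
) -> Path:
    """Run the full workflow and write all outputs under ``out_dir``.

    ``cloud_paths`` are one PLY per observation day, in day order (day 1
    first).  On any stage failure the partial outputs are removed and a
    :class:`StageError` naming the stage is raised.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []

    def _target(name: str) -> Path:
        path = out_dir / name
        created.append(path)
        return path

    inputs = [Path(p) for p in cloud_paths] + [Path(samples_path)]
    if labels_path:
        inputs.append(Path(labels_path))
    if cube_measurement_path:
        inputs.append(Path(cube_measurement_path))

    try:
        for path in inputs:
            if not path.exists():
                stage = ("calibrate" if path == Path(samples_path)
                         else "load-inputs")
                raise StageError(stage, f"input file not found: {path}")

        # -- stage: load + spatial calibration ---------------------------
        clouds: dict[int, ColoredPointCloud] = {}
        t0 = time.perf_counter()
        scale_cal = None
        if cube_measurement_path:
            try:
                scale_cal = estimate_scale_calibration(
                    load_cube_measurement(cube_measurement_path)
                )
            except PhytocloudError as exc:
                raise StageError("scale-calibration", str(exc)) from exc
        for day, path in enumerate(cloud_paths, start=1):
            try:
                cloud = read_ply(path)
                if cloud.frame == RAW:
                    if scale_cal is None:
                        raise ValidationError(
                            f"{path} is in the raw frame and no cube "
                            "measurement was provided"
                        )
                    cloud = apply_calibration(cloud, scale_cal)
            except PhytocloudError as exc:
                raise StageError("load-clouds", f"{path}: {exc}") from exc
            clouds[day] = cloud
        logger.info("loaded %d day clouds (%d points total) in %.2fs",
                    len(clouds), sum(len(c) for c in clouds.values()),
                    time.perf_counter() - t0)

        # -- stage: chlorophyll calibration ------------------------------
        try:
            samples = load_calibration_samples(samples_path)
            curve = fit_calibration(samples)
            cv_error = (loocv_mae(samples) if config.cv_mode == "loo"
                        else kfold_mae(samples, seed=config.seed))
        except PhytocloudError as exc:
            raise StageError("calibrate", str(exc)) from exc
        curve.to_json(_target("curve.json"))
        logger.info("calibration: %s; %s MAE = %.4g",
                    curve.summary().splitlines()[1].strip(),
                    config.cv_mode, cv_error)

        # -- stage: map chlorophyll + angles -----------------------------
        orientations = None
        if labels_path:
            payload = json.loads(Path(labels_path).read_text())
            orientations = {int(k): v for k, v in payload.items()}
        spec = NeighborhoodSpec(cube_side=config.cube_side,
                                min_points=config.min_points)
        for day in sorted(clouds):
            try:
                cloud = map_chlorophyll(clouds[day], curve)
                field = compute_angle_field(
                    cloud, spec,
                    horizontal_threshold=config.horizontal_threshold,
                )
                if orientations and cloud.leaf_labels is not None:
                    present = set(int(v) for v in np.unique(cloud.leaf_labels))
                    flags = {k: v for k, v in orientations.items()
                             if k in present}
                    field = apply_leaf_sign(field, cloud, flags)
                    cloud.attributes["signed_zenith"] = field.signed_zenith
            except PhytocloudError as exc:
                raise StageError("annotate", f"day {day}: {exc}") from exc
            masked = int(np.count_nonzero(~field.valid))
            if masked:
                logger.warning("day %d: %d/%d points have no valid angle",
                               day, masked, len(cloud))
            clouds[day] = cloud
            write_ply(cloud, _target(f"day{day}_annotated.ply"),
                      format="binary_little_endian")

        # -- stage: monitor ----------------------------------------------
        try:
            series = build_series(clouds, region_radius=config.region_radius)
        except PhytocloudError as exc:
            raise StageError("monitor", str(exc)) from exc
        series.to_csv(_target("series.csv"), index=False)
        hist_rows = []
        for day in sorted(clouds):
            cloud = clouds[day]
            labels = [int(v) for v in np.unique(cloud.leaf_labels)
                      if v != 0] if cloud.leaf_labels is not None else []
            for label in labels:
                for quantity, width in (
                    ("chlorophyll", config.chl_bin_width),
                    ("zenith", config.angle_bin_width),
                    ("azimuth", config.angle_bin_width),
                ):
                    try:
                        hist = leaf_histogram(cloud, label, quantity, width)
                    except PhytocloudError:
                        continue
                    for lo, hi, count in zip(hist.bin_edges[:-1],
                                             hist.bin_edges[1:], hist.counts):
                        hist_rows.append({
                            "day": day, "leaf": label, "quantity": quantity,
                            "bin_lo": lo, "bin_hi": hi, "count": int(count),
                        })
        import pandas as pd

        pd.DataFrame(
            hist_rows,
            columns=["day", "leaf", "quantity", "bin_lo", "bin_hi", "count"],
        ).to_csv(_target("histograms.csv"), index=False)

        manifest = {
            "phytocloud_version": __version__,
            "config": dataclasses.asdict(config),
            "inputs": {str(p): _sha256(p) for p in inputs},
            "outputs": [p.name for p in created],
            "cv_error": cv_error,
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return out_dir
    except Exception:
        for path in created:
            path.unlink(missing_ok=True)
        raise
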