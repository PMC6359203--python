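"""Colored point-cloud container.

A :class:`ColoredPointCloud` is the in-memory unit every pipeline stage
consumes and produces: positions, 8-bit RGB colors, optional named per-point
scalar attributes (chlorophyll in μg/mm², zenith/azimuth in degrees, masks)
and optional integer leaf labels (0 = unassigned).  The ``frame`` tag records
whether positions are still in the reconstruction's arbitrary model units
(``"raw"``) or in centimetres with +z antiparallel to gravity
(``"calibrated"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

RAW = "raw"
CALIBRATED = "calibrated"


@dataclass
class ColoredPointCloud:
    points: np.ndarray  # (n, 3) float64
    colors: np.ndarray | None = None  # (n, 3) uint8
    attributes: dict[str, np.ndarray] = field(default_factory=dict)
    leaf_labels: np.ndarray | None = None  # (n,) int
    frame: str = RAW

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        n = len(self.points)
        if self.colors is not None:
            colors = np.asarray(self.colors)
            if colors.shape != (n, 3):
                raise ValidationError(
                    f"colors shape {colors.shape} does not match {n} points"
                )
            if colors.dtype != np.uint8:
                if np.any(colors < 0) or np.any(colors > 255):
                    raise ValidationError("colors must be integers in [0, 255]")
                colors = colors.astype(np.uint8)
            self.colors = colors
        if self.leaf_labels is not None:
            labels = np.asarray(self.leaf_labels, dtype=np.int64)
            if labels.shape != (n,):
                raise ValidationError("leaf_labels length does not match points")
            self.leaf_labels = labels
        for name, values in list(self.attributes.items()):
            values = np.asarray(values, dtype=np.float64)
            if values.shape != (n,):
                raise ValidationError(
                    f"attribute {name!r} length {values.shape} != {n} points"
                )
            self.attributes[name] = values
        if self.frame not in (RAW, CALIBRATED):
            raise ValidationError(f"unknown frame tag {self.frame!r}")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def has_colors(self) -> bool:
        return self.colors is not None

    def with_attribute(self, name: str, values: np.ndarray) -> "ColoredPointCloud":
        """Return a copy of the cloud with one attribute added/replaced."""
        attrs = dict(self.attributes)
        attrs[name] = np.asarray(values, dtype=np.float64)
        return ColoredPointCloud(
            points=self.points.copy(),
            colors=None if self.colors is None else self.colors.copy(),
            attributes={k: np.array(v) for k, v in attrs.items()},
            leaf_labels=None if self.leaf_labels is None else self.leaf_labels.copy(),
            frame=self.frame,
        )

    def copy(self) -> "ColoredPointCloud":
        return ColoredPointCloud(
            points=self.points.copy(),
            colors=None if self.colors is None else self.colors.copy(),
            attributes={k: v.copy() for k, v in self.attributes.items()},
            leaf_labels=None if self.leaf_labels is None else self.leaf_labels.copy(),
            frame=self.frame,
        )

    def label_mask(self, leaf_label: int) -> np.ndarray:
        if self.leaf_labels is None:
            raise ValidationError("cloud has no leaf labels")
        return self.leaf_labels == leaf_label


def concatenate(clouds: list[ColoredPointCloud]) -> ColoredPointCloud:
    """Stack clouds sharing frame, color presence and attribute names."""
    if not clouds:
        raise ValidationError("cannot concatenate an empty list of clouds")
    frame = clouds[0].frame
    if any(c.frame != frame for c in clouds):
        raise ValidationError("cannot concatenate clouds in different frames")
    has_colors = clouds[0].has_colors
    if any(c.has_colors != has_colors for c in clouds):
        raise ValidationError("cannot mix colored and colorless clouds")
    names = set(clouds[0].attributes)
    if any(set(c.attributes) != names for c in clouds):
        raise ValidationError("attribute sets differ between clouds")
    has_labels = clouds[0].leaf_labels is not None
    if any((c.leaf_labels is not None) != has_labels for c in clouds):
        raise ValidationError("cannot mix labeled and unlabeled clouds")
    return ColoredPointCloud(
        points=np.vstack([c.points for c in clouds]),
        colors=np.vstack([c.colors for c in clouds]) if has_colors else None,
        attributes={
            name: np.concatenate([c.attributes[name] for c in clouds])
            for name in names
        },
        leaf_labels=(
            np.concatenate([c.leaf_labels for c in clouds]) if has_labels else None
        ),
        frame=frame,
    )
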