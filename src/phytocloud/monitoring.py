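"""Per-leaf summaries and day-by-day stress monitoring.

Aggregates the per-point chlorophyll and angle attributes into per-leaf
histograms, per-region values (leaf centroid, left edge, right edge — the
small areas tracked through a stress time course), tidy day-indexed series,
and between-day significance tests.

Azimuth summaries are always circular (vector) means: arithmetic means of
angles straddling the 0°/360° wrap are meaningless.  The default between-day
test is Kruskal–Wallis because per-point angle and chlorophyll distributions
within a leaf are bounded and non-normal; note that per-point values are
spatially autocorrelated, so these p-values are descriptive rather than
strictly inferential.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .cloud import ColoredPointCloud
from .errors import DegenerateLeafError, ValidationError

QUANTITIES = ("chlorophyll", "zenith", "azimuth")
DEFAULT_REGION_RADIUS = 0.25  # cm
DEFAULT_BIN_WIDTHS = {"chlorophyll": 1.0, "zenith": 5.0, "azimuth": 5.0}


class Region(str, Enum):
    CENTROID = "centroid"
    LEFT_EDGE = "left_edge"
    RIGHT_EDGE = "right_edge"


@dataclass
class LeafRegion:
    leaf_label: int
    region: Region
    point_indices: np.ndarray
    anchor: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.point_indices = np.asarray(self.point_indices, dtype=np.int64)
        if len(self.point_indices) == 0:
            raise ValidationError("LeafRegion must have a non-empty index set")


@dataclass
class HistogramSummary:
    quantity: str
    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float
    n: int


@dataclass
class DayComparison:
    statistic: float
    df: int
    pvalue: float
    method: str


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Mean direction of angles in degrees, in [0, 360)."""
    return float(stats.circmean(np.asarray(angles_deg, dtype=np.float64),
                                high=360.0, low=0.0))


def _quantity_values(cloud: ColoredPointCloud, indices: np.ndarray, quantity: str):
    if quantity not in cloud.attributes:
        raise ValidationError(f"cloud has no {quantity!r} attribute")
    values = cloud.attributes[quantity][indices]
    if quantity in ("zenith", "azimuth") and "angle_valid" in cloud.attributes:
        values = values[cloud.attributes["angle_valid"][indices] > 0]
    return values[np.isfinite(values)]


def _summarize(values: np.ndarray, quantity: str) -> tuple[float, float, int]:
    if quantity == "azimuth":
        mean = circular_mean_deg(values)
        sd = float(stats.circstd(values, high=360.0, low=0.0))
    else:
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return mean, sd, len(values)


def locate_regions(
    cloud: ColoredPointCloud,
    leaf_label: int,
    radius: float = DEFAULT_REGION_RADIUS,
) -> dict[Region, LeafRegion]:
    """Find the centroid, left-edge and right-edge regions of one leaf.

    The centroid anchor is the labeled point nearest the labeled points'
    mean.  Edge anchors are the labeled points at the extremes of the leaf's
    second principal axis (the within-plane axis across the leaf's width);
    left = minimum projection, right = maximum.  Ties break to the lowest
    point index.  Each region pools the labeled points within ``radius`` cm
    of its anchor.
    """
    if cloud.leaf_labels is None:
        raise ValidationError("cloud has no leaf labels")
    if radius <= 0:
        raise ValidationError("radius must be > 0")
    idx = np.flatnonzero(cloud.leaf_labels == leaf_label)
    if len(idx) < 3:
        raise DegenerateLeafError(
            f"leaf {leaf_label} has {len(idx)} labeled points; need >= 3"
        )
    pts = cloud.points[idx]
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[-1] <= 0:
        raise DegenerateLeafError(f"leaf {leaf_label} points are all coincident")
    # eigh sorts ascending: [-1] long axis, [-2] width (second principal) axis
    width_axis = eigvecs[:, -2]
    projections = centered @ width_axis
    centroid_anchor = idx[int(np.argmin(np.linalg.norm(centered, axis=1)))]
    left_anchor = idx[int(np.argmin(projections))]
    right_anchor = idx[int(np.argmax(projections))]
    out: dict[Region, LeafRegion] = {}
    for region, anchor_idx in (
        (Region.CENTROID, centroid_anchor),
        (Region.LEFT_EDGE, left_anchor),
        (Region.RIGHT_EDGE, right_anchor),
    ):
        anchor = cloud.points[anchor_idx]
        members = idx[np.linalg.norm(pts - anchor, axis=1) <= radius]
        out[region] = LeafRegion(
            leaf_label=leaf_label,
            region=region,
            point_indices=members,
            anchor=anchor,
            radius=radius,
        )
    return out


def leaf_histogram(
    cloud: ColoredPointCloud,
    leaf_label: int,
    quantity: str,
    bin_width: float | None = None,
) -> HistogramSummary:
    """Fixed-width histogram of one quantity over a leaf's valid points."""
    if quantity not in QUANTITIES:
        raise ValidationError(f"unknown quantity {quantity!r}")
    bin_width = bin_width or DEFAULT_BIN_WIDTHS[quantity]
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    if cloud.leaf_labels is None:
        raise ValidationError("cloud has no leaf labels")
    idx = np.flatnonzero(cloud.leaf_labels == leaf_label)
    values = _quantity_values(cloud, idx, quantity)
    if len(values) == 0:
        raise ValidationError(
            f"leaf {leaf_label} has no valid {quantity!r} values"
        )
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    mean = circular_mean_deg(values) if quantity == "azimuth" else float(values.mean())
    return HistogramSummary(
        quantity=quantity,
        bin_edges=edges,
        counts=counts,
        mean=mean,
        n=len(values),
    )


def region_values(
    cloud: ColoredPointCloud, region: LeafRegion, quantity: str
) -> np.ndarray:
    """Valid per-point values of a quantity inside one region."""
    return _quantity_values(cloud, region.point_indices, quantity)


def build_series(
    clouds_by_day: dict[int, ColoredPointCloud],
    region_radius: float = DEFAULT_REGION_RADIUS,
    quantities: tuple[str, ...] = QUANTITIES,
) -> pd.DataFrame:
    """Tidy per-day/leaf/region/quantity summary table.

    One row per (day, leaf, region, quantity) with mean, sd and n.  Regions
    are located independently each day (reconstructions are independent, so
    point indices never correspond across days); leaves or regions with no
    valid values on a day are simply absent — gaps, never zeros.  Output is
    sorted by day, so input order is irrelevant.
    """
    if not clouds_by_day:
        raise ValidationError("build_series needs at least one day")
    rows = []
    for day in sorted(clouds_by_day):
        if day < 1:
            raise ValidationError(f"day index must be >= 1, got {day}")
        cloud = clouds_by_day[day]
        if cloud.leaf_labels is None:
            raise ValidationError(f"day {day} cloud has no leaf labels")
        labels = [int(v) for v in np.unique(cloud.leaf_labels) if v != 0]
        for label in labels:
            try:
                regions = locate_regions(cloud, label, radius=region_radius)
            except DegenerateLeafError:
                continue
            for region in regions.values():
                for quantity in quantities:
                    values = region_values(cloud, region, quantity)
                    if len(values) == 0:
                        continue
                    mean, sd, n = _summarize(values, quantity)
                    rows.append({
                        "day": day,
                        "leaf": label,
                        "region": region.region.value,
                        "quantity": quantity,
                        "mean": mean,
                        "sd": sd,
                        "n": n,
                    })
    return pd.DataFrame(
        rows, columns=["day", "leaf", "region", "quantity", "mean", "sd", "n"]
    )


def compare_days(
    values_by_day: dict[int, np.ndarray],
    method: str = "kruskal",
) -> DayComparison:
    """Omnibus between-day test on per-point values.

    ``kruskal`` (default) is the rank-based Kruskal–Wallis H test;
    ``welch`` is Welch's heteroscedastic one-way ANOVA.
    """
    if len(values_by_day) < 2:
        raise ValidationError("compare_days needs at least 2 days")
    groups = []
    for day in sorted(values_by_day):
        values = np.asarray(values_by_day[day], dtype=np.float64)
        values = values[np.isfinite(values)]
        if len(values) < 2:
            raise ValidationError(f"day {day} has fewer than 2 valid values")
        groups.append(values)
    if method == "kruskal":
        stat, p = stats.kruskal(*groups)
        return DayComparison(
            statistic=float(stat),
            df=len(groups) - 1,
            pvalue=float(p),
            method="kruskal",
        )
    if method == "welch":
        from statsmodels.stats.oneway import anova_oneway

        res = anova_oneway(groups, use_var="unequal", welch_correction=True)
        return DayComparison(
            statistic=float(res.statistic),
            df=int(round(res.df_num)),
            pvalue=float(res.pvalue),
            method="welch",
        )
    raise ValidationError(f"unknown method {method!r}; use kruskal or welch")
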