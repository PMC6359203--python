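"""Chlorophyll estimation from color.

Chlorophyll absorbs red light, so the red fraction of a leaf's reflected color
— the normalized Red value r = R/(R+G+B) — falls as areal chlorophyll content
rises.  A linear calibration ``chl = a·r + b`` is fitted by ordinary least
squares to paired (normalized Red, measured chlorophyll) samples, validated by
leave-one-out cross-validation, and then mapped over every point of a colored
cloud.

Ground-truth chlorophyll for the calibration comes from leaf punches extracted
in 80% acetone and read spectrophotometrically; the Porra (1989) equation
converts the two absorbance readings to a total chlorophyll a+b concentration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .cloud import ColoredPointCloud
from .errors import (
    ColorlessCloudError,
    RankDeficiencyError,
    UndefinedColorError,
    ValidationError,
)

# Porra, Thompson & Kriedemann (1989): total chl a+b in buffered 80% acetone,
# μg/mL from absorbances at 646.6 and 663.6 nm.
PORRA_COEF_A646 = 17.76
PORRA_COEF_A663 = 7.34

#: chlorophyll flag codes attached by :func:`map_chlorophyll`
FLAG_OK = 0.0
FLAG_UNDEFINED_COLOR = 1.0
FLAG_OUT_OF_RANGE = 2.0


@dataclass
class CalibrationSample:
    normalized_red: float
    chlorophyll: float  # μg/mm²
    source_point: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.normalized_red < 1.0:
            raise ValidationError(
                f"normalized_red must lie in (0, 1), got {self.normalized_red}"
            )
        if self.chlorophyll < 0:
            raise ValidationError("chlorophyll must be >= 0")


@dataclass
class AbsorbancePair:
    a646_6: float
    a663_6: float

    def __post_init__(self) -> None:
        if self.a646_6 < 0 or self.a663_6 < 0:
            raise ValidationError("absorbances must be >= 0")


@dataclass
class CalibrationCurve:
    """Fitted linear calibration ``chlorophyll = slope·r + intercept``.

    Carries the OLS estimates together with fit diagnostics: R² (squared
    Pearson correlation of the single-predictor fit), the sample count, and
    the per-sample residuals.
    """

    slope: float
    intercept: float
    r_squared: float
    n: int
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    def predict(self, normalized_red: np.ndarray | float) -> np.ndarray | float:
        return self.slope * np.asarray(normalized_red) + self.intercept

    def invert(self, chlorophyll: np.ndarray | float) -> np.ndarray | float:
        """Normalized Red that the line maps to the given chlorophyll."""
        if self.slope == 0:
            raise ValidationError("cannot invert a flat calibration line")
        return (np.asarray(chlorophyll) - self.intercept) / self.slope

    def summary(self) -> str:
        return (
            "Chlorophyll calibration (OLS)\n"
            f"  chl = {self.slope:+.4g} * r_n {self.intercept:+.4g}  [ug/mm^2]\n"
            f"  R^2 = {self.r_squared:.4f}   n = {self.n}\n"
            f"  residual SD = {float(np.std(self.residuals)):.4g}"
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n": self.n,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        payload = json.loads(Path(path).read_text())
        return cls(
            slope=payload["slope"],
            intercept=payload["intercept"],
            r_squared=payload["r_squared"],
            n=payload["n"],
        )


def normalized_red(r, g, b):
    """R/(R+G+B) for 8-bit channels; raises when the color is pure black."""
    r = np.asarray(r, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    total = r + g + b
    if np.any(total == 0):
        raise UndefinedColorError("normalized Red undefined for R+G+B = 0")
    out = r / total
    return float(out) if out.ndim == 0 else out


def porra_total_chlorophyll(absorbance: AbsorbancePair) -> float:
    """Total chlorophyll a+b (μg/mL) in 80% acetone from two absorbances."""
    return PORRA_COEF_A646 * absorbance.a646_6 + PORRA_COEF_A663 * absorbance.a663_6


def concentration_to_areal(
    concentration: float, extract_volume_ml: float, punch_area_mm2: float
) -> float:
    """Convert extract concentration (μg/mL) to areal content (μg/mm²)."""
    if extract_volume_ml <= 0 or punch_area_mm2 <= 0:
        raise ValidationError("extract volume and punch area must be > 0")
    return concentration * extract_volume_ml / punch_area_mm2


def _sample_arrays(samples):
    r = np.array([s.normalized_red for s in samples], dtype=np.float64)
    c = np.array([s.chlorophyll for s in samples], dtype=np.float64)
    return r, c


def fit_calibration(samples: list[CalibrationSample]) -> CalibrationCurve:
    """OLS fit of chlorophyll on normalized Red.

    Regression direction is predictive: chlorophyll is the response because
    the calibration is used to predict chlorophyll from color.
    """
    if len(samples) < 3:
        raise ValidationError(f"need at least 3 samples, got {len(samples)}")
    r, c = _sample_arrays(samples)
    if np.ptp(r) == 0.0:
        raise RankDeficiencyError(
            "all normalized_red values identical; slope is unidentifiable"
        )
    fit = stats.linregress(r, c)
    residuals = c - (fit.slope * r + fit.intercept)
    r2 = float(fit.rvalue**2) if np.ptp(c) > 0 else 0.0
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        n=len(samples),
        residuals=residuals,
    )


def loocv_mae(samples: list[CalibrationSample]) -> float:
    """Leave-one-out cross-validated mean absolute prediction error (μg/mm²).

    Each sample is predicted by the line fitted to the other n−1.  Computed
    with the OLS hat-matrix identity: the deleted residual is
    ``e_i / (1 − h_ii)`` where ``h_ii`` is the leverage, which equals an
    explicit n-refit loop exactly.
    """
    if len(samples) < 4:
        raise ValidationError(f"LOOCV needs at least 4 samples, got {len(samples)}")
    r, c = _sample_arrays(samples)
    n = len(r)
    # every fold must keep predictor spread: deleting one sample may not
    # leave the remaining normalized_red values all equal
    _, counts = np.unique(r, return_counts=True)
    if counts.max() >= n - 1:
        raise RankDeficiencyError(
            "a leave-one-out fold would have no spread in normalized_red"
        )
    curve = fit_calibration(samples)
    sxx = float(np.sum((r - r.mean()) ** 2))
    leverage = 1.0 / n + (r - r.mean()) ** 2 / sxx
    deleted = curve.residuals / (1.0 - leverage)
    return float(np.mean(np.abs(deleted)))


def kfold_mae(
    samples: list[CalibrationSample], k: int = 5, seed: int = 0
) -> float:
    """k-fold cross-validated MAE with a seeded shuffle (deterministic)."""
    if len(samples) < k:
        raise ValidationError(f"need at least k={k} samples")
    r, c = _sample_arrays(samples)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(r))
    folds = np.array_split(order, k)
    errors = []
    for fold in folds:
        train = np.setdiff1d(order, fold)
        if np.ptp(r[train]) == 0:
            raise RankDeficiencyError("a fold's training set has no r_n spread")
        fit = stats.linregress(r[train], c[train])
        errors.extend(np.abs(c[fold] - (fit.slope * r[fold] + fit.intercept)))
    return float(np.mean(errors))


def map_chlorophyll(
    cloud: ColoredPointCloud, curve: CalibrationCurve
) -> ColoredPointCloud:
    """Apply the calibration to every point of a colored cloud.

    Adds two attributes: ``chlorophyll`` (NaN where the color is pure black
    and normalized Red undefined) and ``chlorophyll_flag`` (0 ok, 1 undefined
    color, 2 prediction below zero — kept, not clipped, so histograms expose
    calibration extrapolation).
    """
    if not cloud.has_colors:
        raise ColorlessCloudError("map_chlorophyll requires a colored cloud")
    rgb = cloud.colors.astype(np.float64)
    total = rgb.sum(axis=1)
    defined = total > 0
    r_n = np.full(len(cloud), np.nan)
    r_n[defined] = rgb[defined, 0] / total[defined]
    chl = np.where(defined, curve.predict(np.where(defined, r_n, 0.0)), np.nan)
    flags = np.where(defined, FLAG_OK, FLAG_UNDEFINED_COLOR)
    flags[defined & (chl < 0)] = FLAG_OUT_OF_RANGE
    out = cloud.with_attribute("chlorophyll", chl)
    return out.with_attribute("chlorophyll_flag", flags)


def load_calibration_samples(path: str | Path) -> list[CalibrationSample]:
    """Read calibration samples from CSV.

    Direct mode: columns ``normalized_red, chlorophyll_ug_mm2``.  Raw mode:
    columns ``normalized_red, a646_6, a663_6, volume_ml, punch_area_mm2`` —
    absorbances are converted via the Porra equation and areal normalization.
    """
    import csv

    samples: list[CalibrationSample] = []
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle):
            r_n = float(row["normalized_red"])
            if "chlorophyll_ug_mm2" in row and row["chlorophyll_ug_mm2"]:
                chl = float(row["chlorophyll_ug_mm2"])
            else:
                conc = porra_total_chlorophyll(
                    AbsorbancePair(float(row["a646_6"]), float(row["a663_6"]))
                )
                chl = concentration_to_areal(
                    conc, float(row["volume_ml"]), float(row["punch_area_mm2"])
                )
            samples.append(CalibrationSample(normalized_red=r_n, chlorophyll=chl))
    if not samples:
        raise ValidationError(f"no calibration samples found in {path}")
    return samples
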