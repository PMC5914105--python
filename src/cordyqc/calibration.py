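"""Linear calibration curves, S/N-based LOD/LOQ, external-standard (ESM)
quantification and the validation statistics (RSD, recovery)."""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "ValidationStats",
    "fit_calibration",
    "lod_loq",
    "esm_quantify",
    "rsd",
    "recovery_percent",
]


@dataclass
class CalibrationCurve:
    """Per-analyte linear fit Y(area) = slope * X(ug/mL) + intercept.

    ``height_slope`` is an auxiliary peak-height-per-concentration slope used
    to convert the S/N criterion (a height ratio) into LOD/LOQ concentrations.
    """

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    linear_range: tuple[float, float] | None = None
    lod: float | None = None
    loq: float | None = None
    height_slope: float | None = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")
        self.r_squared = min(self.r_squared, 1.0)
        if self.linear_range is not None and not self.linear_range[0] < self.linear_range[1]:
            raise ValueError("linear range low must be below high")
        if self.lod is not None and self.loq is not None and not self.lod < self.loq:
            raise ValueError("LOD must be below LOQ")

    def predict(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept

    def invert(self, area: float) -> float:
        return (area - self.intercept) / self.slope


@dataclass
class ValidationStats:
    """Method-validation summary for one analyte (all values in percent)."""

    analyte: str
    intraday_rsd: float
    interday_rsd: float
    repeatability_rsd: float
    stability_rsd: float
    recovery: float

    def __post_init__(self) -> None:
        for name in ("intraday_rsd", "interday_rsd", "repeatability_rsd", "stability_rsd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.recovery <= 0:
            raise ValueError("recovery must be positive")


def fit_calibration(concentrations: Sequence[float], areas: Sequence[float],
                    analyte: str = "") -> CalibrationCurve:
    """Ordinary least squares fit of area on concentration.

    R-squared is the squared Pearson correlation of the points.  Requires at
    least three points with distinct concentrations.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(areas, dtype=float)
    if x.size != y.size:
        raise ValueError("concentrations and areas must have equal length")
    if x.size < 3:
        raise ValueError("need at least three calibration points")
    if np.ptp(x) == 0:
        raise ValueError("calibration concentrations are all equal (singular fit)")
    res = stats.linregress(x, y)
    return CalibrationCurve(
        analyte=analyte,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(float(res.rvalue) ** 2, 1.0),
        linear_range=(float(x.min()), float(x.max())),
    )


def lod_loq(noise: float, height_slope: float) -> tuple[float, float]:
    """LOD and LOQ (ug/mL) at signal-to-noise 3:1 and 10:1.

    ``height_slope`` converts concentration to peak height, so
    LOD = 3*noise/height_slope and LOQ = 10*noise/height_slope;
    their ratio is exactly 10/3.
    """
    if noise < 0:
        raise ValueError("noise must be non-negative")
    if height_slope <= 0:
        raise ValueError("height slope must be positive")
    return 3.0 * noise / height_slope, 10.0 * noise / height_slope


def esm_quantify(area: float, curve: CalibrationCurve,
                 extract_volume_ml: float = 50.0,
                 sample_mass_g: float = 1.0) -> float:
    """External-standard content (mg/g): invert the calibration line, scale by
    extract volume and sample mass.

    C = (area - intercept)/slope ug/mL; mass = C x V ug;
    content = mass / sample_mass / 1000 mg/g.  A computed concentration below
    zero (area under the intercept) is reported as 0 with a warning, as is an
    area outside the fitted linear range.
    """
    if sample_mass_g <= 0:
        raise ValueError("sample mass must be positive")
    if extract_volume_ml <= 0:
        raise ValueError("extract volume must be positive")
    conc = curve.invert(area)
    if conc < 0:
        warnings.warn(
            f"{curve.analyte or 'analyte'}: area {area:g} below the intercept; "
            "content reported as 0", stacklevel=2)
        return 0.0
    if curve.linear_range is not None:
        lo, hi = curve.linear_range
        if not (lo <= conc <= hi):
            warnings.warn(
                f"{curve.analyte or 'analyte'}: concentration {conc:g} ug/mL outside "
                f"the fitted range ({lo:g}, {hi:g})", stacklevel=2)
    mass_ug = conc * extract_volume_ml
    return mass_ug / sample_mass_g / 1000.0


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation in percent, with the sample (n-1) SD."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("RSD needs at least two replicates")
    mean = v.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / abs(mean))


def recovery_percent(measured: float, base: float, spiked: float) -> float:
    """Spike recovery: 100 x (measured - base) / spiked amount."""
    if spiked <= 0:
        raise ValueError("spiked amount must be positive")
    return 100.0 * (measured - base) / spiked
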