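"""Absorbance → loading capacity and cumulative-release quantitation.

A linear UV–vis calibration ``concentration = k·A + b`` converts absorbance
readings to concentration; multiplying by the solvent volume gives released
(or extracted) drug mass.  Loading capacity LA (g drug per g fabric) is

    LA = (k·A + b) · V / G

and the cumulative release percentage at time t, normalised by the loaded
amount, is

    Qt = [(k·At + b) · V1 / G1] / LA × 100.

Units only need to be internally consistent (concentration × volume = mass);
the package convention is g·L⁻¹ and litres, so the protocol's 250.0 mL and
150.0 mL are stored as 0.250 and 0.150.  No aliquot/dilution correction is
applied because each sampled aliquot is returned to the release bath; a
correction hook is available on :func:`build_release_curve` but off by
default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    InsufficientDataError,
    OrderingError,
    ValidationError,
)

__all__ = [
    "CalibrationLine",
    "LoadingMeasurement",
    "ReleaseMeasurement",
    "ReleaseCurve",
    "loading_capacity",
    "cumulative_release",
    "build_release_curve",
    "estimate_calibration",
    "read_curve_csv",
]

#: Qt above this is rejected outright; (100, QT_HARD_MAX] passes with a warning.
QT_HARD_MAX = 110.0
#: Small negative Qt (observation noise around zero) passes with a warning.
QT_HARD_MIN = -10.0


@dataclass(frozen=True)
class CalibrationLine:
    """Linear UV–vis calibration: concentration (g·L⁻¹) = slope_k·A + intercept_b."""

    slope_k: float
    intercept_b: float = 0.0
    wavelength_nm: float = 254.0

    def __post_init__(self):
        if self.slope_k <= 0:
            raise ValidationError("calibration slope_k must be positive")
        if not 190.0 <= self.wavelength_nm <= 400.0:
            raise ValidationError(
                "wavelength_nm must lie in the scan range [190, 400] nm"
            )

    def concentration(self, absorbance) -> float:
        return self.slope_k * np.asarray(absorbance, dtype=float) + self.intercept_b


@dataclass(frozen=True)
class LoadingMeasurement:
    """One extraction measurement: absorbance, extract volume (L), fabric mass (g)."""

    absorbance_A: float
    volume_V: float = 0.250
    fabric_mass_G: float = 1.0

    def __post_init__(self):
        if self.absorbance_A < 0:
            raise ValidationError("absorbance must be non-negative")
        if self.volume_V <= 0:
            raise ValidationError("volume_V must be positive")
        if self.fabric_mass_G <= 0:
            raise DomainError("fabric_mass_G must be positive")


@dataclass(frozen=True)
class ReleaseMeasurement:
    """One timed release reading: time (minutes) and absorbance."""

    time_t: float
    absorbance_At: float

    def __post_init__(self):
        if self.time_t < 0:
            raise DomainError("time must be non-negative")
        if self.absorbance_At < 0:
            raise ValidationError("absorbance must be non-negative")


@dataclass
class ReleaseCurve:
    """Ordered (time, cumulative-release %) series for one drug/fabric pair."""

    drug_id: str
    times: np.ndarray
    qt: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.qt = np.atleast_1d(np.asarray(self.qt, dtype=float))
        if self.times.size == 0:
            raise InsufficientDataError("a release curve needs at least one point")
        if self.times.shape != self.qt.shape:
            raise ValidationError("times and qt must have equal length")
        if np.any(self.times < 0):
            raise OrderingError("times must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise OrderingError("times must be strictly increasing")
        if np.any(~np.isfinite(self.qt)):
            raise ValidationError("Qt values must be finite")
        qmax, qmin = float(self.qt.max()), float(self.qt.min())
        if qmax > QT_HARD_MAX:
            raise ValidationError(
                f"Qt = {qmax:.4g} % exceeds the validity ceiling of {QT_HARD_MAX} %"
            )
        if qmax > 100.0:
            warnings.warn(
                f"{self.drug_id}: Qt above 100 % (max {qmax:.4g} %) — possible "
                "calibration drift",
                stacklevel=2,
            )
        if qmin < QT_HARD_MIN:
            raise ValidationError(
                f"Qt = {qmin:.4g} % is below the noise floor of {QT_HARD_MIN} %"
            )
        if qmin < 0.0:
            warnings.warn(
                f"{self.drug_id}: negative Qt (min {qmin:.4g} %) — observation "
                "noise around zero",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_points(self) -> int:
        return self.times.size

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times, "Q_percent": self.qt})

    def to_csv(self, path) -> None:
        self.as_dataframe().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, drug_id: str) -> "ReleaseCurve":
        if not {"time_min", "Q_percent"} <= set(df.columns):
            raise ValidationError(
                "expected columns 'time_min' and 'Q_percent', got "
                f"{list(df.columns)}"
            )
        return cls(drug_id, df["time_min"].to_numpy(), df["Q_percent"].to_numpy())


def loading_capacity(cal: CalibrationLine, m: LoadingMeasurement) -> float:
    """Drug loading capacity LA = (k·A + b)·V/G in g·g⁻¹.

    A negative computed concentration (absorbance below the calibration
    range) is returned as-is with a warning rather than raised, so the caller
    can inspect the evidence.
    """
    conc = cal.concentration(m.absorbance_A)
    if conc < 0:
        warnings.warn(
            f"computed concentration {conc:.4g} g/L is negative: absorbance "
            "below the calibration range",
            stacklevel=2,
        )
    return float(conc * m.volume_V / m.fabric_mass_G)


def cumulative_release(
    cal: CalibrationLine,
    rm: ReleaseMeasurement,
    volume_V1: float,
    fabric_mass_G1: float,
    LA: float,
) -> float:
    """Cumulative release Qt (%) of one timed reading against the loaded amount."""
    if LA <= 0:
        raise DomainError("LA must be positive: no loaded drug to release against")
    if fabric_mass_G1 <= 0:
        raise DomainError("fabric_mass_G1 must be positive")
    if volume_V1 <= 0:
        raise DomainError("volume_V1 must be positive")
    released_per_gram = cal.concentration(rm.absorbance_At) * volume_V1 / fabric_mass_G1
    return float(released_per_gram / LA * 100.0)


def build_release_curve(
    series: Sequence[ReleaseMeasurement],
    cal: CalibrationLine,
    volume_V1: float,
    fabric_mass_G1: float,
    LA: float,
    drug_id: str = "sample",
    volume_correction=None,
) -> ReleaseCurve:
    """Assemble a :class:`ReleaseCurve` from timed absorbance readings.

    ``volume_correction``, if given, maps the point index to the effective
    bath volume at that sampling time; by default the constant ``volume_V1``
    is used because sampled aliquots are returned to the bath.
    """
    if len(series) < 4:
        raise InsufficientDataError(
            f"need at least 4 measurements to build a curve, got {len(series)}"
        )
    times = np.array([rm.time_t for rm in series], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise OrderingError("measurement times must be strictly increasing")
    qt = np.array(
        [
            cumulative_release(
                cal,
                rm,
                volume_correction(i) if volume_correction is not None else volume_V1,
                fabric_mass_G1,
                LA,
            )
            for i, rm in enumerate(series)
        ]
    )
    return ReleaseCurve(drug_id, times, qt)


def estimate_calibration(
    concentrations: Iterable[float],
    absorbances: Iterable[float],
    wavelength_nm: float = 254.0,
) -> CalibrationLine:
    """Plain least-squares calibration line from standards (convenience only)."""
    conc = np.asarray(list(concentrations), dtype=float)
    absb = np.asarray(list(absorbances), dtype=float)
    if conc.size != absb.size or conc.size < 2:
        raise InsufficientDataError("need ≥ 2 matched standards")
    slope, intercept = np.polyfit(absb, conc, 1)
    return CalibrationLine(float(slope), float(intercept), wavelength_nm)


def read_curve_csv(
    path,
    drug_id: str | None = None,
    cal: CalibrationLine | None = None,
    volume_V1: float = 0.150,
    fabric_mass_G1: float = 1.0,
    LA: float | None = None,
) -> ReleaseCurve:
    """Read a delimited curve file.

    Two layouts are accepted: pre-computed mode with columns
    ``time_min, Q_percent``, or raw mode with ``time_min, absorbance`` plus a
    calibration line, bath volume, fabric mass and loading capacity.
    """
    path = Path(path)
    df = pd.read_csv(path)
    label = drug_id or path.stem
    cols = set(df.columns)
    if {"time_min", "Q_percent"} <= cols:
        return ReleaseCurve.from_dataframe(df, label)
    if {"time_min", "absorbance"} <= cols:
        if cal is None or LA is None:
            raise ValidationError(
                f"{path.name}: raw absorbance input needs a calibration line and LA"
            )
        series = [
            ReleaseMeasurement(t, a)
            for t, a in zip(df["time_min"], df["absorbance"])
        ]
        return build_release_curve(series, cal, volume_V1, fabric_mass_G1, LA, label)
    raise ValidationError(
        f"{path.name}: expected columns (time_min, Q_percent) or "
        f"(time_min, absorbance), got {sorted(cols)}"
    )
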