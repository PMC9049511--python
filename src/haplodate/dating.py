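"""Linear calibration between shared-haplotype length and divergence time.

Breed pairs that diverged recently share more long haplotypes than pairs
that diverged long ago. Over the roughly 35-160 years before sampling,
this relationship is modelled as a straight line

    y = m * x + b

where ``y`` is the total shared haplotype length in bp (the median over a
breed pair's individual-pair totals) and ``x`` is years since divergence.
The model can be fitted by ordinary least squares on pairs with known
event ages, or loaded with the published constants
(m = -8,736,150 bp/yr, b = 1,501,072,917 bp, r² = 1, sampling year 2019).
Inverting the line converts an observed sharing median into years before
sampling and hence a calendar year; estimates outside the calibration
regime are flagged rather than clipped.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Published calibration constants: slope in bp per year, intercept in bp.
PUBLISHED_SLOPE = -8_736_150.0
PUBLISHED_INTERCEPT = 1_501_072_917.0
PUBLISHED_SAMPLING_YEAR = 2019

#: Years-before-sampling span of the calibration events.
CALIBRATION_REGIME = (35.0, 160.0)


@dataclass
class CalibrationPoint:
    label: str
    years: float          # known event age, years before sampling
    shared_bp: float      # total shared haplotype length

    def __post_init__(self) -> None:
        if self.years <= 0:
            raise ValueError("event age must be > 0 years")
        if self.shared_bp < 0:
            raise ValueError("shared length must be >= 0")


@dataclass
class CalibrationModel:
    slope: float          # bp per year, expected negative
    intercept: float      # bp at x = 0
    r_squared: float
    sampling_year: int = PUBLISHED_SAMPLING_YEAR
    provenance: str = "fitted"

    def predict_length(self, years: float) -> float:
        """Expected total shared length (bp) at ``years`` since divergence."""
        return self.slope * years + self.intercept

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"slope": self.slope, "intercept": self.intercept,
                       "r_squared": self.r_squared,
                       "sampling_year": self.sampling_year,
                       "provenance": self.provenance}, fh, indent=1)


@dataclass
class DateEstimate:
    breed_a: str
    breed_b: str
    shared_bp: float
    years: float                  # estimated years before sampling
    calendar_year: float
    out_of_range: bool


@dataclass
class BreedDateRange:
    breed: str
    partners: list[str]
    min_year: float
    max_year: float


def fit_calibration(points: list[CalibrationPoint],
                    sampling_year: int = PUBLISHED_SAMPLING_YEAR) -> CalibrationModel:
    """Ordinary least squares of shared length on event age."""
    if len(points) < 2:
        raise ValueError("need at least two calibration points")
    x = np.array([p.years for p in points], dtype=float)
    y = np.array([p.shared_bp for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("calibration points need at least two distinct ages")
    res = stats.linregress(x, y)
    lo, hi = CALIBRATION_REGIME
    outside = [p.label for p in points if not lo <= p.years <= hi]
    if outside:
        warnings.warn(f"calibration point(s) outside the {lo:g}-{hi:g} year "
                      f"regime: {outside}", stacklevel=2)
    r2 = float(res.rvalue ** 2) if len(points) > 2 else 1.0
    return CalibrationModel(float(res.slope), float(res.intercept), r2,
                            sampling_year, "fitted")


def paper_default_calibration() -> CalibrationModel:
    """The published length-to-years line (2019 sampling anchor)."""
    return CalibrationModel(PUBLISHED_SLOPE, PUBLISHED_INTERCEPT, 1.0,
                            PUBLISHED_SAMPLING_YEAR, "paper-default")


def estimate_years(model: CalibrationModel, shared_bp: float,
                   breed_a: str = "A", breed_b: str = "B") -> DateEstimate:
    """Invert the calibration line: x̂ = (y - b) / m.

    Negative estimates (sharing above the intercept) and estimates
    outside the calibration regime are flagged, not clipped.
    """
    if model.slope == 0:
        raise ValueError("calibration slope is zero; line cannot be inverted")
    years = (shared_bp - model.intercept) / model.slope
    lo, hi = CALIBRATION_REGIME
    flag = years < lo or years > hi
    return DateEstimate(breed_a, breed_b, shared_bp, years,
                        model.sampling_year - years, flag)


def breed_ranges(estimates: list[DateEstimate], breed: str,
                 partner_set) -> BreedDateRange:
    """Min/max calendar year over a breed's pairings with the partner set."""
    partners = set(partner_set)
    years, used = [], []
    for e in estimates:
        if e.breed_a == breed and e.breed_b in partners:
            other = e.breed_b
        elif e.breed_b == breed and e.breed_a in partners:
            other = e.breed_a
        else:
            continue
        years.append(e.calendar_year)
        used.append(other)
    if not years:
        raise ValueError(f"no estimates pairing {breed!r} with the partner set")
    return BreedDateRange(breed, used, float(min(years)), float(max(years)))
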