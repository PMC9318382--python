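"""MRM calibration and gelatin-content computation.

Each quantified marker carries an ordinary least-squares calibration of
standard-material amount (mg) against MRM peak area, with LOD/LOQ read
off signal-to-noise series (S/N > 3 and > 10 respectively). Measured
areas invert through the curve to percent gelatin content (mg
marker-equivalent gelatin per mg of sample x 100).

The pharmacopoeia donkey marker (CP) also responds to horse gelatin, so
a donkey content based on it must subtract the horse contribution: the
response ratio r = CP/HM1 is estimated on pure horse-hide references and
the corrected content is max(0, cp - r*hm1). The ratio varies between
samples, so r is data, not a constant.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .constants import SAMPLE_MASS_MG


@dataclass(frozen=True)
class MrmTransition:
    """One precursor -> product transition monitored for a marker."""

    marker_id: str
    precursor_mz: float
    product_mz: float
    charge: int
    rt: float
    fragmentor: float
    collision_energy: float
    role: str  # quantifier | qualifier

    def __post_init__(self) -> None:
        if self.role not in ("quantifier", "qualifier"):
            raise ValueError(f"unknown transition role {self.role!r}")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear amount (mg) -> peak area model for one marker."""

    marker_id: str
    slope: float
    intercept: float
    r2: float
    lod: float | None = None
    loq: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError(f"r2 must lie in [0, 1], got {self.r2}")
        if self.lod is not None and self.loq is not None and self.loq < self.lod:
            raise ValueError("LOQ cannot be below LOD")

    def amount_to_area(self, amount_mg: float) -> float:
        return self.slope * amount_mg + self.intercept

    def area_to_amount(self, area: float) -> float:
        if self.slope == 0:
            raise ZeroDivisionError("calibration slope is zero")
        return (area - self.intercept) / self.slope


class ContentResult(NamedTuple):
    """Percent content with an absent flag for below-blank signals."""

    content: float
    absent: bool


def fit_calibration(
    amounts_mg: Sequence[float],
    areas: Sequence[float],
    marker_id: str = "",
) -> CalibrationCurve:
    """Fit the amount -> area line by ordinary least squares."""
    x = np.asarray(amounts_mg, dtype=float)
    y = np.asarray(areas, dtype=float)
    if x.size < 2 or y.size != x.size:
        raise ValueError("calibration needs >= 2 (amount, area) pairs")
    if np.ptp(x) == 0:
        raise ValueError("calibration amounts have zero variance")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue ** 2)
    if math.isnan(r2):  # zero variance in y: perfect horizontal fit
        r2 = 1.0
    return CalibrationCurve(
        marker_id=marker_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=min(r2, 1.0),
    )


class LodLoq(NamedTuple):
    lod: float | None
    loq: float | None
    above_range: bool  # no tested amount satisfied the criterion
    at_floor: bool  # every tested amount satisfied it (true limit below range)


def lod_loq(amounts_mg: Sequence[float], sn: Sequence[float]) -> LodLoq:
    """Read LOD and LOQ off a signal-to-noise series.

    LOD is the smallest tested amount with S/N > 3; LOQ the smallest with
    S/N > 10. If no amount qualifies the result is flagged above-range;
    if even the smallest amount qualifies for both, the true limits lie
    below the tested range and the result is flagged accordingly.
    """
    x = np.asarray(amounts_mg, dtype=float)
    s = np.asarray(sn, dtype=float)
    if x.size == 0 or s.size != x.size:
        raise ValueError("need matching, non-empty amount and S/N series")
    order = np.argsort(x)
    x, s = x[order], s[order]
    if np.any(np.diff(s) < 0):
        import logging

        logging.getLogger(__name__).warning(
            "S/N series is not monotone non-decreasing in amount"
        )
    lod_idx = np.flatnonzero(s > 3)
    loq_idx = np.flatnonzero(s > 10)
    lod = float(x[lod_idx[0]]) if lod_idx.size else None
    loq = float(x[loq_idx[0]]) if loq_idx.size else None
    above_range = lod is None
    at_floor = bool(lod_idx.size and loq_idx.size and lod_idx[0] == 0 and loq_idx[0] == 0)
    return LodLoq(lod, loq, above_range, at_floor)


def content_direct(
    area: float,
    curve: CalibrationCurve,
    sample_mass_mg: float = SAMPLE_MASS_MG,
) -> ContentResult:
    """Percent gelatin content from a measured marker peak area.

    content = 100 * ((area - intercept) / slope) / sample_mass. A
    negative estimate (signal below the blank response) clamps to 0 and
    is flagged absent.
    """
    if sample_mass_mg <= 0:
        raise ValueError("sample mass must be positive")
    amount = curve.area_to_amount(area)
    content = 100.0 * amount / sample_mass_mg
    if content < 0:
        return ContentResult(0.0, True)
    return ContentResult(content, False)


class HorseRatio(NamedTuple):
    ratio: float  # median CP/HM1 response ratio over pure-horse samples
    dispersion: float  # median absolute deviation of the per-sample ratios
    n: int


def estimate_horse_ratio(
    pure_horse_samples: Sequence[tuple[float, float]],
) -> HorseRatio:
    """Estimate the CP/HM1 response ratio from pure horse-hide samples.

    Each sample contributes cp_content / hm1_content; the ratio reported
    is the median, with the median absolute deviation as dispersion
    (the ratio genuinely varies between samples).
    """
    ratios = []
    for cp, hm1 in pure_horse_samples:
        if hm1 > 0:
            ratios.append(cp / hm1)
    if not ratios:
        raise ValueError("no pure-horse sample with positive HM1 content")
    arr = np.asarray(ratios)
    med = float(np.median(arr))
    return HorseRatio(med, float(np.median(np.abs(arr - med))), len(ratios))


def content_indirect_cp(cp_content: float, hm1_content: float, r: float) -> float:
    """Donkey content via the CP marker, corrected by horse subtraction.

    max(0, cp - r*hm1): the CP marker's horse-attributable share is
    removed using the response ratio r; never exceeds the uncorrected CP
    content and equals it when no horse marker was seen.
    """
    if r <= 0:
        raise ValueError("response ratio r must be positive")
    return max(0.0, cp_content - r * hm1_content)
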