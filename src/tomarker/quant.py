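"""Targeted carotenoid quantification: external calibration, LOQ, unit conversion.

Linear external calibration (unweighted OLS of detector response on
concentration), limit-of-quantification censoring, dry-weight to
fresh-weight conversion via the measured water fraction, and the
contribution of a tomato part (peel/pulp) to a serving.

Units: concentrations on a dry-weight basis are ug/g dw; on a fresh-weight
basis mg/kg fw (numerically ug/g == mg/kg, so the dw->fw conversion is
just multiplication by the dry-matter fraction 1 - water_fraction).
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np
from scipy import stats as sps


class QuantError(ValueError):
    pass


class BelowLOQ(enum.Enum):
    """Censoring sentinel: the value is below the limit of quantification."""

    token = "<LOQ"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "BELOW_LOQ"


BELOW_LOQ = BelowLOQ.token


@dataclasses.dataclass
class CalibrationCurve:
    """External linear calibration for one analyte.

    ``loq`` defaults to the lowest calibration concentration (the working
    range's lower bound), the convention for reporting a numeric value.
    """

    analyte: str
    points: list[tuple[float, float]]  # (concentration ug/g dw, response)
    slope: float
    intercept: float
    r_squared: float
    loq: float
    working_range: tuple[float, float]


def fit_calibration(
    analyte: str,
    points: list[tuple[float, float]],
    min_points: int = 2,
) -> CalibrationCurve:
    """Unweighted OLS of response on concentration.

    ``min_points=6`` enforces the 6-7 point design used for instrument
    calibration in practice; the default permits small test curves.
    """
    conc = np.asarray([p[0] for p in points], dtype=float)
    resp = np.asarray([p[1] for p in points], dtype=float)
    if len(points) < min_points:
        raise QuantError(f"calibration needs >= {min_points} points, got {len(points)}")
    if np.unique(conc).size < 2:
        raise QuantError("calibration needs at least 2 distinct concentrations")
    fit = sps.linregress(conc, resp)
    return CalibrationCurve(
        analyte=analyte,
        points=list(points),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        loq=float(conc.min()),
        working_range=(float(conc.min()), float(conc.max())),
    )


@dataclasses.dataclass
class QuantResult:
    analyte: str
    concentration_dw: float | BelowLOQ   # ug/g dw
    concentration_fw: float | BelowLOQ   # mg/kg fw
    dilution_factor: float
    water_fraction: float


def dw_to_fw(concentration_dw: float, water_fraction: float) -> float:
    """ug/g dry weight -> mg/kg fresh weight via the dry-matter fraction."""
    if not 0 <= water_fraction < 1:
        raise QuantError("water_fraction must be in [0, 1)")
    return concentration_dw * (1.0 - water_fraction)


def quantify(
    response: float,
    curve: CalibrationCurve,
    dilution_factor: float = 1.0,
    water_fraction: float = 0.92,
) -> QuantResult:
    """Concentration from a detector response; censored below the LOQ.

    dw concentration = (response - intercept) / slope * dilution_factor;
    values below ``curve.loq`` are reported as BELOW_LOQ in both units
    (censoring propagates through the unit conversion).
    """
    if curve.slope == 0:
        raise QuantError("calibration slope is zero; cannot invert")
    if dilution_factor < 1:
        raise QuantError("dilution_factor must be >= 1")
    dw = (response - curve.intercept) / curve.slope * dilution_factor
    if dw < curve.loq:
        return QuantResult(curve.analyte, BELOW_LOQ, BELOW_LOQ, dilution_factor, water_fraction)
    return QuantResult(
        analyte=curve.analyte,
        concentration_dw=dw,
        concentration_fw=dw_to_fw(dw, water_fraction),
        dilution_factor=dilution_factor,
        water_fraction=water_fraction,
    )


def part_contribution(
    conc_fw: float | BelowLOQ, part_mass_fraction: float, serving_g: float
) -> float | BelowLOQ:
    """mg of analyte contributed by one tomato part to a serving.

    mg = concentration (mg/kg fw) x serving mass (g) x part fraction / 1000.
    A BELOW_LOQ concentration propagates.
    """
    if isinstance(conc_fw, BelowLOQ):
        return BELOW_LOQ
    if conc_fw < 0 or not 0 <= part_mass_fraction <= 1 or serving_g < 0:
        raise QuantError("inputs must be non-negative (fraction in [0, 1])")
    return conc_fw * (serving_g * part_mass_fraction) / 1000.0
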