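"""Hemoglobin molar extinction coefficients over the visible band.

A coarse anchor table of oxy- and deoxyhemoglobin molar extinction
coefficients (cm^-1 / mol L^-1), compiled from the standard published
in-vitro compilations and rounded; values between anchors are obtained by
monotone piecewise-cubic interpolation.  The table reproduces the features
the pipeline relies on: the Soret band below 450 nm, the isosbestic point
near 500 nm, the oxyhemoglobin alpha/beta double peak at 542/577 nm versus
the single deoxy peak at 555 nm, and the roughly tenfold excess of deoxy
over oxy absorption in the red (~660 nm).  Treated as physical constants.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import ValidationError
from .spectra import SpectralGrid

#: Hemoglobin molar mass used to convert concentration, g/mol.
HEMOGLOBIN_MOLAR_MASS = 64500.0

#: Reference whole-blood hemoglobin concentration, mol/L (150 g/L).
WHOLE_BLOOD_HEME_MOLARITY = 150.0 / HEMOGLOBIN_MOLAR_MASS

# wavelength nm, eps_HbO2, eps_Hb  (cm^-1 / M); coarse anchors
_ANCHORS = np.array(
    [
        # lam    HbO2      Hb
        [410.0, 466000.0, 250000.0],
        [415.0, 480000.0, 290000.0],
        [420.0, 265000.0, 400000.0],
        [425.0, 160000.0, 475000.0],
        [430.0, 105000.0, 525000.0],
        [435.0, 68000.0, 490000.0],
        [440.0, 46000.0, 330000.0],
        [445.0, 50000.0, 200000.0],
        [450.0, 62816.0, 103292.0],
        [460.0, 44000.0, 72000.0],
        [470.0, 33000.0, 55000.0],
        [480.0, 26629.0, 45072.0],
        [490.0, 23000.0, 34000.0],
        [500.0, 20932.0, 20862.0],
        [510.0, 25000.0, 22000.0],
        [520.0, 31000.0, 27000.0],
        [530.0, 39000.0, 35000.0],
        [535.0, 46000.0, 40000.0],
        [540.0, 53236.0, 46000.0],
        [544.0, 56864.0, 49000.0],
        [548.0, 55540.0, 52276.0],
        [552.0, 48148.0, 53292.0],
        [556.0, 37020.0, 53412.0],
        [560.0, 32613.0, 52000.0],
        [565.0, 35000.0, 49000.0],
        [570.0, 45000.0, 45000.0],
        [576.0, 61015.0, 39500.0],
        [580.0, 53412.0, 37020.0],
        [585.0, 33000.0, 32000.0],
        [590.0, 14677.0, 26000.0],
        [600.0, 3200.0, 14677.0],
        [610.0, 1600.0, 9443.0],
        [620.0, 980.0, 6510.0],
        [630.0, 650.0, 5149.0],
        [640.0, 480.0, 4345.0],
        [650.0, 368.0, 3750.0],
        [660.0, 320.0, 3227.0],
        [670.0, 300.0, 2796.0],
        [680.0, 290.0, 2480.0],
        [690.0, 280.0, 2180.0],
        [700.0, 290.0, 1794.0],
        [710.0, 320.0, 1650.0],
        [720.0, 360.0, 1540.0],
        [730.0, 410.0, 1425.0],
        [740.0, 450.0, 1400.0],
        [750.0, 520.0, 1405.0],
        [760.0, 590.0, 1670.0],
    ]
)

_EPS_HBO2 = PchipInterpolator(_ANCHORS[:, 0], _ANCHORS[:, 1])
_EPS_HB = PchipInterpolator(_ANCHORS[:, 0], _ANCHORS[:, 2])


def extinction(grid: SpectralGrid | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(eps_HbO2, eps_Hb) in cm^-1/M on the given grid or wavelength array."""
    lam = grid.values if isinstance(grid, SpectralGrid) else np.asarray(grid, float)
    if lam.min() < _ANCHORS[0, 0] or lam.max() > _ANCHORS[-1, 0]:
        raise ValidationError(
            f"extinction table covers {_ANCHORS[0, 0]}-{_ANCHORS[-1, 0]} nm"
        )
    return _EPS_HBO2(lam), _EPS_HB(lam)


def blood_absorption_mm(
    so2: float | np.ndarray, grid: SpectralGrid | np.ndarray
) -> np.ndarray:
    """Absorption coefficient of whole blood, mm^-1.

    mu_a(lambda) = ln(10) * C_heme * (sO2 * eps_HbO2 + (1-sO2) * eps_Hb),
    with C_heme the reference whole-blood hemoglobin molarity.  Multiply by
    a blood-volume fraction to obtain the blood contribution in tissue.

    ``so2`` may be scalar or an array; an array broadcasts against the
    wavelength axis (last axis of the result).
    """
    so2 = np.asarray(so2, float)
    if np.any((so2 < 0) | (so2 > 1)):
        raise ValidationError("sO2 must lie in [0, 1]")
    eps_o, eps_d = extinction(grid)
    mua_cm = np.log(10.0) * WHOLE_BLOOD_HEME_MOLARITY * (
        so2[..., None] * eps_o + (1.0 - so2[..., None]) * eps_d
    )
    return mua_cm / 10.0
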