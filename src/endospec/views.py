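"""Functional visualisations derived from a reconstructed cube.

A single hyperspectral cube supports several co-registered clinical views:
a natural-colour image (white-light-endoscopy-like) synthesised through
colour-matching functions, a single-band narrow-band view (classically
415/540 nm, enhancing vessel contrast), and vessel contrast-versus-
wavelength curves that reveal vessel depth (contrast of deeper vessels
peaks at longer wavelengths because short wavelengths are absorbed and
scattered before reaching them).
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import ValidationError
from .spectra import HSICube, Spectrum

# CIE 1931 2-degree standard observer, 10 nm, 420-750 nm (truncated to the
# working band; values outside are negligible for natural scenes).
_CMF_LAMBDA = np.arange(420.0, 751.0, 10.0)
_CMF_XYZ = np.array([
    [0.1344, 0.0040, 0.6456], [0.2839, 0.0116, 1.3856],
    [0.3483, 0.0230, 1.7471], [0.3362, 0.0380, 1.7721],
    [0.2908, 0.0600, 1.6692], [0.1954, 0.0910, 1.2876],
    [0.0956, 0.1390, 0.8130], [0.0320, 0.2080, 0.4652],
    [0.0049, 0.3230, 0.2720], [0.0093, 0.5030, 0.1582],
    [0.0633, 0.7100, 0.0782], [0.1655, 0.8620, 0.0422],
    [0.2904, 0.9540, 0.0203], [0.4334, 0.9950, 0.0087],
    [0.5945, 0.9950, 0.0039], [0.7621, 0.9520, 0.0021],
    [0.9163, 0.8700, 0.0017], [1.0263, 0.7570, 0.0011],
    [1.0622, 0.6310, 0.0008], [1.0026, 0.5030, 0.0003],
    [0.8544, 0.3810, 0.0002], [0.6424, 0.2650, 0.0000],
    [0.4479, 0.1750, 0.0000], [0.2835, 0.1070, 0.0000],
    [0.1649, 0.0610, 0.0000], [0.0874, 0.0320, 0.0000],
    [0.0468, 0.0170, 0.0000], [0.0227, 0.0082, 0.0000],
    [0.0114, 0.0041, 0.0000], [0.0058, 0.0021, 0.0000],
    [0.0029, 0.0010, 0.0000], [0.0014, 0.0005, 0.0000],
    [0.0007, 0.0002, 0.0000], [0.0003, 0.0001, 0.0000],
])

_XYZ_TO_SRGB = np.array([
    [3.2406, -1.5372, -0.4986],
    [-0.9689, 1.8758, 0.0415],
    [0.0557, -0.2040, 1.0570],
])


def _rgb_weights(cube: HSICube) -> np.ndarray:
    """(C, 3) linear-RGB weights on the cube's grid, white-normalised so a
    spectrally flat cube maps to equal R = G = B."""
    lam = cube.grid.values
    if lam[0] > 430 or lam[-1] < 700:
        raise ValidationError("grid too narrow for colour synthesis")
    cmf = np.stack(
        [np.interp(lam, _CMF_LAMBDA, _CMF_XYZ[:, k], left=0, right=0)
         for k in range(3)], axis=1,
    )
    weights = cmf @ _XYZ_TO_SRGB.T  # (C, 3) linear RGB per unit radiance
    white = np.ones(len(lam)) @ weights
    return weights / white[None, :]


def synthesize_rgb(cube: HSICube, gamma: float = 2.2) -> np.ndarray:
    """Natural-colour (H, W, 3) image from the cube.

    Linear RGB is a fixed colour-matching weighting of the spectral
    channels with equal-energy white normalisation (flat spectrum -> gray);
    the result is clipped to [0, 1] and gamma-encoded.  Pass ``gamma=1``
    for the linear image (linear in the cube by construction).
    """
    weights = _rgb_weights(cube)
    rgb = cube.data @ weights
    rgb = np.clip(rgb, 0.0, 1.0)
    if gamma != 1:
        rgb = rgb ** (1.0 / gamma)
    return rgb


def nbe_view(
    cube: HSICube, wavelength_nm: float = 540.0, normalize: bool = True
) -> np.ndarray:
    """Single-band narrow-band-endoscopy-like view.

    Extracts the spectral channel nearest ``wavelength_nm`` (with a warning
    if the request is off-grid, e.g. 415 nm on the 420-750 nm grid) and,
    when ``normalize`` is set, contrast-stretches it between the 1st and
    99th intensity percentiles.  With ``normalize=False`` the raw slice is
    returned unchanged.
    """
    lam = cube.grid.values
    idx = cube.grid.index_of(wavelength_nm)
    if abs(lam[idx] - wavelength_nm) > 1e-9:
        warnings.warn(
            f"{wavelength_nm:g} nm is not a grid channel; using nearest "
            f"{lam[idx]:g} nm",
            stacklevel=2,
        )
    band = cube.data[:, :, idx]
    if not normalize:
        return band
    lo, hi = np.percentile(band, [1, 99])
    if hi <= lo:
        return np.zeros_like(band)
    return np.clip((band - lo) / (hi - lo), 0.0, 1.0)


def vessel_contrast_curve(
    cube: HSICube,
    vessel_region: np.ndarray,
    background_region: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Weber contrast of a vessel region against background, per band.

    C(lambda) = (mean_bg - mean_vessel) / mean_bg.  Returns the per-band
    contrast and the wavelength of peak contrast.  Regions are boolean
    masks, must be disjoint and contain at least 4 pixels each.
    """
    v = np.asarray(vessel_region, bool)
    b = np.asarray(background_region, bool)
    if v.shape != cube.data.shape[:2] or b.shape != cube.data.shape[:2]:
        raise ValidationError("region masks must match the cube's spatial shape")
    if np.any(v & b):
        raise ValidationError("vessel and background regions must be disjoint")
    if v.sum() < 4 or b.sum() < 4:
        raise ValidationError("each region needs at least 4 pixels")
    mean_v = cube.data[v].mean(axis=0)
    mean_b = cube.data[b].mean(axis=0)
    if np.any(mean_b <= 0):
        raise ValidationError("background mean must be positive in every band")
    contrast = (mean_b - mean_v) / mean_b
    peak = float(cube.grid.values[int(np.argmax(contrast))])
    return contrast, peak
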