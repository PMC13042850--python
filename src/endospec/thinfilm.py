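"""Transfer-matrix optics for multilayer dielectric filters.

The encoding illumination of the imaging system is produced by three
five-layer TiO2/SiO2 interference filters on a fused-silica substrate.  The
middle (third) layer acts as a weakly confined Fabry-Perot cavity whose
thickness (240, 320 or 560 nm) sets the fringe pattern; the resulting
transmission spectra are wide-band, smooth ("low-frequency") and mutually
nearly uncorrelated, which is what makes a three-shot encoding well
conditioned.

Transmittance is computed with the standard characteristic-matrix method
for coherent lossless layers between a semi-infinite incident medium and a
semi-infinite substrate.  Film indices default to bulk-crystal dispersion
formulas (rutile TiO2 ordinary ray after Devore; fused silica after
Malitson), i.e. a dense, rutile-like TiO2 film.  This choice reproduces the
near-zero pairwise correlation of the fabricated filter set, which lower
packing-density (n550 ~ 2.35) films do not; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ValidationError
from .spectra import SpectralGrid, Spectrum

#: Cavity-layer thicknesses (nm) of the three encoding filters.
FILTER_CAVITY_THICKNESSES_NM = (240.0, 320.0, 560.0)

#: Outer/spacer layer thicknesses (nm) common to all three filters:
#: TiO2 / SiO2 / cavity TiO2 / SiO2 / TiO2.
FILTER_OUTER_NM = 60.0
FILTER_SPACER_NM = 94.0


@dataclass(frozen=True)
class MaterialIndex:
    """Named refractive-index model n(lambda_nm), real part only."""

    name: str
    index: Callable[[np.ndarray], np.ndarray]

    def n(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        out = np.asarray(self.index(np.asarray(wavelengths_nm, float)), float)
        if np.any(out < 1.0):
            raise ValidationError(f"{self.name}: refractive index below 1")
        return out


def constant_index(name: str, n: float) -> MaterialIndex:
    if n < 1:
        raise ValidationError("refractive index must be >= 1")
    return MaterialIndex(name, lambda lam, n=n: np.full_like(lam, n, dtype=float))


def sio2_malitson() -> MaterialIndex:
    """Fused silica, Malitson three-term Sellmeier."""

    def n(lam_nm: np.ndarray) -> np.ndarray:
        l2 = (lam_nm * 1e-3) ** 2
        n2 = (
            1.0
            + 0.6961663 * l2 / (l2 - 0.0684043**2)
            + 0.4079426 * l2 / (l2 - 0.1162414**2)
            + 0.8974794 * l2 / (l2 - 9.896161**2)
        )
        return np.sqrt(n2)

    return MaterialIndex("SiO2", n)


def tio2_rutile() -> MaterialIndex:
    """Rutile TiO2, ordinary ray (Devore single-term Sellmeier)."""

    def n(lam_nm: np.ndarray) -> np.ndarray:
        l2 = (lam_nm * 1e-3) ** 2
        return np.sqrt(5.913 + 0.2441 / (l2 - 0.0803))

    return MaterialIndex("TiO2", n)


AIR = constant_index("air", 1.0)


@dataclass
class LayerStack:
    """Ordered coherent layers between semi-infinite media.

    ``layers`` runs from the incident side to the substrate side; each entry
    is (material, physical thickness in nm).
    """

    layers: Sequence[tuple[MaterialIndex, float]]
    incident: MaterialIndex = AIR
    substrate: MaterialIndex = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.substrate is None:
            self.substrate = sio2_malitson()
        for _, d in self.layers:
            if d <= 0:
                raise ValidationError("layer thickness must be positive")

    def reversed(self) -> "LayerStack":
        """Stack seen from the substrate side (media exchanged)."""
        return LayerStack(list(self.layers)[::-1], self.substrate, self.incident)


def _eta(n: np.ndarray, cos_t: np.ndarray, pol: str) -> np.ndarray:
    return n * cos_t if pol == "s" else n / cos_t


def _solve_stack(
    stack: LayerStack, grid: SpectralGrid, angle_deg: float
) -> tuple[np.ndarray, np.ndarray]:
    """(T, R) of the stack, unpolarised average at oblique incidence."""
    lam = grid.values
    n0 = stack.incident.n(lam)
    ns = stack.substrate.n(lam)
    sin0 = np.sin(np.deg2rad(angle_deg))
    T_pol, R_pol = [], []
    for pol in ("s", "p") if angle_deg != 0 else ("s",):
        M11 = np.ones(len(lam), complex)
        M12 = np.zeros(len(lam), complex)
        M21 = np.zeros(len(lam), complex)
        M22 = np.ones(len(lam), complex)
        for material, d in stack.layers:
            n = material.n(lam)
            cos_t = np.sqrt(1 - (n0 * sin0 / n) ** 2 + 0j)
            delta = 2 * np.pi * n * d * cos_t / lam
            eta = _eta(n, cos_t, pol)
            c, s = np.cos(delta), np.sin(delta)
            A11, A12, A21, A22 = c, 1j * s / eta, 1j * eta * s, c
            M11, M12, M21, M22 = (
                M11 * A11 + M12 * A21,
                M11 * A12 + M12 * A22,
                M21 * A11 + M22 * A21,
                M21 * A12 + M22 * A22,
            )
        cos0 = np.sqrt(1 - sin0**2 + 0j)
        coss = np.sqrt(1 - (n0 * sin0 / ns) ** 2 + 0j)
        eta0 = _eta(n0, cos0, pol)
        etas = _eta(ns, coss, pol)
        B = M11 + M12 * etas
        C = M21 + M22 * etas
        t = 2 * eta0 / (eta0 * B + C)
        r = (eta0 * B - C) / (eta0 * B + C)
        T_pol.append(np.real(etas) / np.real(eta0) * np.abs(t) ** 2)
        R_pol.append(np.abs(r) ** 2)
    return np.mean(T_pol, axis=0), np.mean(R_pol, axis=0)


def transmission_spectrum(
    stack: LayerStack, grid: SpectralGrid, angle_deg: float = 0.0
) -> Spectrum:
    """Transmittance T(lambda) of a coherent lossless stack.

    Characteristic-matrix method with semi-infinite incident medium and
    substrate; at normal incidence s- and p-polarisation coincide, at
    oblique incidence the unpolarised average is returned.  For real
    (lossless) indices T + R = 1.
    """
    T, _ = _solve_stack(stack, grid, angle_deg)
    return Spectrum(grid, np.clip(T, 0.0, 1.0))


def reflection_spectrum(
    stack: LayerStack, grid: SpectralGrid, angle_deg: float = 0.0
) -> Spectrum:
    """Reflectance R(lambda) companion of :func:`transmission_spectrum`."""
    _, R = _solve_stack(stack, grid, angle_deg)
    return Spectrum(grid, np.clip(R, 0.0, 1.0))


def encoding_filter_stack(
    cavity_nm: float,
    tio2: MaterialIndex | None = None,
    sio2: MaterialIndex | None = None,
) -> LayerStack:
    """Five-layer TiO2/SiO2/TiO2/SiO2/TiO2 stack with the given cavity."""
    tio2 = tio2 or tio2_rutile()
    sio2 = sio2 or sio2_malitson()
    return LayerStack(
        layers=[
            (tio2, FILTER_OUTER_NM),
            (sio2, FILTER_SPACER_NM),
            (tio2, cavity_nm),
            (sio2, FILTER_SPACER_NM),
            (tio2, FILTER_OUTER_NM),
        ],
        incident=AIR,
        substrate=sio2,
    )


def encoding_filter_set(
    grid: SpectralGrid | None = None,
    tio2: MaterialIndex | None = None,
    sio2: MaterialIndex | None = None,
) -> list[Spectrum]:
    """Transmission spectra f1, f2, f3 of the three encoding filters.

    The three stacks share outer 60 nm TiO2 and 94 nm SiO2 layers and
    differ only in the central cavity (240 / 320 / 560 nm).  Their spectra
    are smooth and wide-band with mean pairwise |correlation| of a few
    percent over the working band.
    """
    grid = grid or SpectralGrid()
    out = []
    for k, cav in enumerate(FILTER_CAVITY_THICKNESSES_NM):
        s = transmission_spectrum(encoding_filter_stack(cav, tio2, sio2), grid)
        s.name = f"f{k + 1}"
        out.append(s)
    return out
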