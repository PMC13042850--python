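"""Wavelength grids and spectrum containers.

Every spectral quantity in the package (filter transmissions, sensor
responses, tissue diffuse-reflectance spectra, hyperspectral cubes) lives on
a shared uniformly sampled wavelength axis.  The working band of the imaging
system is 420-750 nm sampled every 5 nm, i.e. 67 spectral channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridMismatchError, ValidationError

DEFAULT_LAMBDA_MIN = 420.0
DEFAULT_LAMBDA_MAX = 750.0
DEFAULT_STEP = 5.0


@dataclass(frozen=True)
class SpectralGrid:
    """Uniform wavelength axis in nanometres.

    Parameters
    ----------
    lambda_min, lambda_max : float
        Inclusive band edges in nm.
    step : float
        Sample spacing in nm; ``(lambda_max - lambda_min)`` must be an
        integer multiple of it.
    """

    lambda_min: float = DEFAULT_LAMBDA_MIN
    lambda_max: float = DEFAULT_LAMBDA_MAX
    step: float = DEFAULT_STEP

    def __post_init__(self) -> None:
        if self.lambda_max <= self.lambda_min:
            raise ValidationError("lambda_max must exceed lambda_min")
        if self.step <= 0:
            raise ValidationError("step must be positive")
        n_float = (self.lambda_max - self.lambda_min) / self.step
        if abs(n_float - round(n_float)) > 1e-9:
            raise ValidationError(
                "band width must be an integer number of steps, got "
                f"{self.lambda_min}..{self.lambda_max} @ {self.step}"
            )

    @property
    def values(self) -> np.ndarray:
        """Wavelength samples in nm, strictly increasing and uniform."""
        n = int(round((self.lambda_max - self.lambda_min) / self.step)) + 1
        return self.lambda_min + self.step * np.arange(n)

    @property
    def n(self) -> int:
        return int(round((self.lambda_max - self.lambda_min) / self.step)) + 1

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the grid sample nearest ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.values - wavelength_nm)))

    def require_same(self, other: "SpectralGrid") -> None:
        if self != other:
            raise GridMismatchError(f"grids differ: {self} vs {other}")


@dataclass
class Spectrum:
    """A single spectrum sampled on a :class:`SpectralGrid`.

    ``intensity`` is dimensionless (transmittance, reflectance or relative
    radiance).  Transmittance/reflectance values are expected in [0, 1] with
    a small headroom reserved for clipped specular highlights.
    """

    grid: SpectralGrid
    intensity: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1 or len(self.intensity) != self.grid.n:
            raise ValidationError(
                f"intensity length {self.intensity.shape} does not match "
                f"grid with {self.grid.n} samples"
            )

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.values

    def __mul__(self, other: "Spectrum | float") -> "Spectrum":
        """Pointwise product; grids must match."""
        if isinstance(other, Spectrum):
            self.grid.require_same(other.grid)
            return Spectrum(self.grid, self.intensity * other.intensity)
        return Spectrum(self.grid, self.intensity * float(other))

    __rmul__ = __mul__


@dataclass
class HSICube:
    """Hyperspectral cube t(x, y, lambda): one spectrum per pixel.

    ``data`` has shape (H, W, C) with C equal to the grid length.  ``mask``
    flags pixels that must be excluded from statistics (clipped specular
    highlights, overexposure); it is boolean with shape (H, W).
    """

    grid: SpectralGrid
    data: np.ndarray
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != self.grid.n:
            raise ValidationError(
                f"cube shape {self.data.shape} incompatible with "
                f"{self.grid.n}-channel grid"
            )
        if self.mask is None:
            self.mask = np.zeros(self.data.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:2]:
                raise ValidationError("mask shape must match spatial shape")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def pixel(self, x: int, y: int) -> Spectrum:
        """Spectrum at row ``y``, column ``x`` (0-based)."""
        return Spectrum(self.grid, self.data[y, x])
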