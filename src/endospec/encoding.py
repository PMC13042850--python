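"""Spectral encoding: illumination filters x Bayer mask x source, and the
forward measurement model.

One acquisition cycle illuminates the scene three times, each time through a
different low-frequency stochastic filter, and records one Bayer-mosaicked
frame per illumination.  The encoding spectrum seen by a pixel of colour
channel j under illumination i is the pointwise product

    e_ij(lambda) = f_i(lambda) * d_j(lambda) * s(lambda)   [* notch]

of the filter transmission f_i, the Bayer channel response d_j and the bare
source spectrum s.  A measured intensity is

    I_i(x, y) = V_i * sum_lambda e_ij(x,y)(lambda) t(x,y,lambda) dlambda + N

with V_i a per-frame illumination gain fluctuation and N additive detection
noise.  The nine (i, j) encoding spectra, discretised with the grid step as
quadrature weight, form the 9 x C encoding matrix used by reconstruction.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .errors import GridMismatchError, ValidationError
from .spectra import HSICube, SpectralGrid, Spectrum

_PATTERNS = {
    # (row % 2, col % 2) -> channel index 0=R, 1=G, 2=B
    "RGGB": {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2},
    "BGGR": {(0, 0): 2, (0, 1): 1, (1, 0): 1, (1, 1): 0},
    "GRBG": {(0, 0): 1, (0, 1): 0, (1, 0): 2, (1, 1): 1},
    "GBRG": {(0, 0): 1, (0, 1): 2, (1, 0): 0, (1, 1): 1},
}


@dataclass
class BayerResponse:
    """Spectral responses d_j(lambda) of the R, G, B mosaic channels."""

    grid: SpectralGrid
    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    pattern: str = "RGGB"

    def __post_init__(self) -> None:
        for name in ("red", "green", "blue"):
            v = np.asarray(getattr(self, name), float)
            if v.shape != (self.grid.n,):
                raise ValidationError(f"{name} response length mismatch")
            if np.any(v < 0) or v.sum() <= 0:
                raise ValidationError(f"{name} response must be >= 0 with mass")
            setattr(self, name, v)
        if self.pattern not in _PATTERNS:
            raise ValidationError(f"unknown mosaic pattern {self.pattern!r}")

    @property
    def channels(self) -> np.ndarray:
        """(3, C) array ordered R, G, B."""
        return np.vstack([self.red, self.green, self.blue])

    @classmethod
    def gaussian_model(
        cls, grid: SpectralGrid | None = None, pattern: str = "RGGB"
    ) -> "BayerResponse":
        """Parametric stand-in for an uncalibrated colour camera: Gaussian
        channel responses B ~ N(460, 30), G ~ N(540, 40), R ~ N(600, 40) nm
        with a weak red secondary lobe.  Synthetic; replace with a measured
        calibration for real sensors."""
        grid = grid or SpectralGrid()
        lam = grid.values

        def g(c, s):
            return np.exp(-0.5 * ((lam - c) / s) ** 2)

        red = 0.9 * g(600, 40) + 0.15 * g(680, 40)
        green = g(540, 40)
        blue = g(460, 30)
        return cls(grid, red, green, blue, pattern)


@dataclass
class SourceSpectrum:
    """Relative radiance s(lambda) of the bare (unfiltered) source."""

    grid: SpectralGrid
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, float)
        if self.intensity.shape != (self.grid.n,):
            raise ValidationError("source length mismatch")
        if np.any(self.intensity < 0):
            raise ValidationError("source radiance must be nonnegative")

    @classmethod
    def white_led(cls, grid: SpectralGrid | None = None) -> "SourceSpectrum":
        """Two-lobe phosphor-converted white LED model: a narrow 450 nm
        pump plus a broad 550 nm phosphor lobe.  Output is weak at the
        short-wavelength edge of the band (the reason the 415 nm channel of
        classical narrow-band viewing is unavailable)."""
        grid = grid or SpectralGrid()
        lam = grid.values
        s = 0.8 * np.exp(-0.5 * ((lam - 450) / 12) ** 2) + 1.0 * np.exp(
            -0.5 * ((lam - 560) / 75) ** 2
        )
        return cls(grid, s / s.max())


def notch_spectrum(
    grid: SpectralGrid, center_nm: float, width_nm: float
) -> Spectrum:
    """Smooth notch (raised-cosine dip) used to model a laser-blocking
    filter in the detection path.

    Transmission is exactly zero over center +/- width/4, rises with a
    raised-cosine flank to 1 at center +/- width/2, and is 1 elsewhere.
    """
    lam = grid.values
    half_zero = width_nm / 4.0
    half_full = width_nm / 2.0
    dist = np.abs(lam - center_nm)
    t = np.ones_like(lam)
    flank = (dist > half_zero) & (dist < half_full)
    t[dist <= half_zero] = 0.0
    t[flank] = 0.5 * (1 - np.cos(np.pi * (dist[flank] - half_zero) / (half_full - half_zero)))
    return Spectrum(grid, t, name=f"notch{center_nm:g}")


@dataclass
class EncodingSet:
    """The nine encoding spectra e_ij and the discrete encoding matrix.

    ``spectra`` has shape (3, 3, C) indexed (illumination i, channel j,
    wavelength); ``matrix`` is the 9 x C quadrature-weighted matrix with
    rows ordered (1,R),(1,G),(1,B),(2,R),...  A row of ``matrix`` applied
    to a discretised spectrum gives the noiseless measurement directly.
    """

    grid: SpectralGrid
    spectra: np.ndarray
    pattern: str = "RGGB"
    notch: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, float)
        if self.spectra.shape != (3, 3, self.grid.n):
            raise ValidationError("encoding spectra must have shape (3, 3, C)")
        if np.any(self.spectra < 0):
            raise ValidationError("encoding spectra must be nonnegative")

    @property
    def matrix(self) -> np.ndarray:
        """(9, C) encoding matrix including the dlambda quadrature weight."""
        return self.spectra.reshape(9, self.grid.n) * self.grid.step

    @property
    def encoding_id(self) -> str:
        h = hashlib.sha256(self.spectra.tobytes()).hexdigest()[:16]
        return f"{self.pattern}-{h}"

    def total_intensity(self) -> Spectrum:
        """Sum of all nine encoding spectra (the per-wavelength encoding
        strength; low values mark poorly encoded bands)."""
        return Spectrum(self.grid, self.spectra.sum(axis=(0, 1)))


def build_encoding_set(
    filters: list[Spectrum],
    bayer: BayerResponse,
    source: SourceSpectrum,
    notch: tuple[float, float] | None = None,
) -> EncodingSet:
    """Assemble the nine-spectrum encoding set e_ij = f_i * d_j * s.

    ``notch`` is an optional (center_nm, width_nm) pair multiplied into
    every row to model a laser-blocking filter in the imaging path.
    """
    if len(filters) != 3:
        raise ValidationError("exactly three illumination filters required")
    grid = bayer.grid
    for f in filters:
        if f.grid != grid:
            raise GridMismatchError("filter grid differs from Bayer grid")
    if source.grid != grid:
        raise GridMismatchError("source grid differs from Bayer grid")
    d = bayer.channels  # (3, C)
    s = source.intensity
    e = np.empty((3, 3, grid.n))
    for i, f in enumerate(filters):
        e[i] = f.intensity[None, :] * d * s[None, :]
    if notch is not None:
        e *= notch_spectrum(grid, *notch).intensity
    return EncodingSet(grid, e, pattern=bayer.pattern, notch=notch)


@dataclass
class NoiseModel:
    """Measurement perturbations of the forward model.

    ``noise_fraction`` sets additive Gaussian detection noise with standard
    deviation = fraction x mean noiseless frame intensity; the per-frame
    illumination gain V_i is drawn from Uniform(1-v, 1+v) with
    v = ``illumination_variation``.
    """

    noise_fraction: float = 0.05
    illumination_variation: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_fraction < 0 or self.illumination_variation < 0:
            raise ValidationError("noise fractions must be >= 0")
        if self.illumination_variation >= 1:
            raise ValidationError("illumination variation must keep V_i > 0")


NOISELESS = NoiseModel(0.0, 0.0)


@dataclass
class RawFrameSet:
    """The three mosaicked frames of one encoding cycle."""

    frames: np.ndarray  # (3, H, W)
    v_values: np.ndarray  # (3,) illumination gains actually drawn
    pattern: str = "RGGB"
    encoding_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, float)
        if self.frames.ndim != 3 or self.frames.shape[0] != 3:
            raise ValidationError("frames must have shape (3, H, W)")
        self.v_values = np.asarray(self.v_values, float)
        if self.v_values.shape != (3,):
            raise ValidationError("three V_i values expected")


def channel_map(pattern: str, shape: tuple[int, int]) -> np.ndarray:
    """(H, W) array of colour-channel indices (0=R,1=G,2=B) for a mosaic."""
    if pattern not in _PATTERNS:
        raise ValidationError(f"unknown mosaic pattern {pattern!r}")
    rows = np.arange(shape[0])[:, None] % 2
    cols = np.arange(shape[1])[None, :] % 2
    lut = _PATTERNS[pattern]
    out = np.empty(shape, dtype=np.int8)
    for (r, c), j in lut.items():
        out[(rows == r) & (cols == c)] = j
    return out


def encode(
    scene: HSICube, enc: EncodingSet, noise: NoiseModel = NOISELESS
) -> RawFrameSet:
    """Simulate one acquisition cycle of the encoded measurement.

    Per pixel, the frame intensity is the quadrature inner product of the
    pixel spectrum with the encoding spectrum of the pixel's native mosaic
    channel, scaled by the per-frame gain V_i, plus additive Gaussian
    detection noise.  Deterministic under a fixed ``noise.seed``.
    """
    scene.grid.require_same(enc.grid)
    if np.any(scene.data < 0):
        raise ValidationError("scene spectra must be nonnegative")
    h, w, c = scene.data.shape
    cmap = channel_map(enc.pattern, (h, w))
    rng = np.random.default_rng(noise.seed)
    v = rng.uniform(
        1 - noise.illumination_variation, 1 + noise.illumination_variation, 3
    )
    frames = np.empty((3, h, w))
    for i in range(3):
        # all three colour-channel responses of illumination i, then pick
        # the native channel per pixel following the mosaic
        per_channel = np.tensordot(scene.data, enc.spectra[i] * enc.grid.step, axes=([2], [1]))
        mosaicked = np.take_along_axis(per_channel, cmap[..., None].astype(int), axis=2)[..., 0]
        frames[i] = v[i] * mosaicked
        if noise.noise_fraction > 0:
            sigma = noise.noise_fraction * mosaicked.mean()
            frames[i] = frames[i] + rng.normal(0.0, sigma, (h, w))
    return RawFrameSet(
        frames,
        v,
        pattern=enc.pattern,
        encoding_id=enc.encoding_id,
        meta={"seed": noise.seed, "noise_fraction": noise.noise_fraction,
              "illumination_variation": noise.illumination_variation},
    )


def _lin_interp_axis(sites: np.ndarray, values: np.ndarray, n: int) -> np.ndarray:
    """Linear interpolation of ``values`` (sampled at ``sites`` along axis 0)
    onto 0..n-1, extrapolating linearly past the first/last site."""
    q = np.arange(n)
    k = np.clip(np.searchsorted(sites, q) - 1, 0, len(sites) - 2)
    t = (q - sites[k]) / (sites[k + 1] - sites[k])
    t = t[(slice(None),) + (None,) * (values.ndim - 1)]
    return (1 - t) * values[k] + t * values[k + 1]


def _interp_plane(
    frame: np.ndarray, rows: np.ndarray, cols: np.ndarray
) -> np.ndarray:
    """Separable bilinear interpolation of frame[rows][:, cols] onto the
    full raster, with linear extrapolation at the borders."""
    h, w = frame.shape
    sub = frame[np.ix_(rows, cols)]
    tmp = _lin_interp_axis(rows, sub, h)
    return _lin_interp_axis(cols, tmp.T, w).T


def demosaic(raw: RawFrameSet, enc: EncodingSet | None = None) -> np.ndarray:
    """Bilinear demosaicking of the three frames into a (H, W, 9) stack.

    Each colour plane of each frame is interpolated from its mosaic sample
    sites; values at a pixel's native sites are preserved exactly.  The
    green quincunx is handled as the average of its two rectangular
    sub-lattices.  Output channels are ordered to match the encoding-matrix
    rows: (i=1,R),(1,G),(1,B),(2,R),...

    Bilinear interpolation reproduces affine images exactly (borders
    included, via linear extrapolation).
    """
    pattern = raw.pattern
    if pattern not in _PATTERNS:
        raise ValidationError(f"unknown mosaic pattern {pattern!r}")
    if enc is not None and raw.encoding_id and enc.encoding_id != raw.encoding_id:
        raise ValidationError("encoding id of frames does not match encoding set")
    _, h, w = raw.frames.shape
    cmap = channel_map(pattern, (h, w))
    lut = _PATTERNS[pattern]
    sites = {j: [] for j in range(3)}
    for (r, c), j in lut.items():
        sites[j].append((np.arange(r, h, 2), np.arange(c, w, 2)))
    out = np.empty((h, w, 9))
    for i in range(3):
        frame = raw.frames[i]
        for j in range(3):
            planes = [_interp_plane(frame, rows, cols) for rows, cols in sites[j]]
            plane = np.mean(planes, axis=0)
            native = cmap == j
            plane[native] = frame[native]
            out[:, :, 3 * i + j] = plane
    return out
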