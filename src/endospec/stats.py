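"""Spectral statistics: correlation, Fourier analysis, RAE and SNR.

The Fourier convention used throughout: the sampled spectrum s[k] on a grid
with spacing ``step`` nm is transformed with the unnormalised real-input
DFT, and the frequency axis is expressed in cycles per micrometre of
wavelength (um^-1).  The zero-frequency ("dc") amplitude therefore equals
``|mean(s)| * N`` and all other amplitudes are compared against it, which is
the natural scaling when one asks what fraction of the signal sits above a
given wavelength-frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import DegenerateInputError, GridMismatchError, ValidationError
from .spectra import HSICube, SpectralGrid, Spectrum


@dataclass
class FourierAmplitude:
    """Amplitude of the real-input DFT of a spectrum.

    ``frequencies`` are uniformly spaced starting at 0, in cycles/um;
    ``amplitude`` is |DFT| (unnormalised); ``dc`` duplicates amplitude[0].
    ``convention`` documents the dc scaling.
    """

    frequencies: np.ndarray
    amplitude: np.ndarray
    dc: float
    convention: str = "unnormalised rDFT; dc = |mean| * N"


class CorrelationResult(NamedTuple):
    matrix: np.ndarray
    mean_offdiagonal: float
    mean_abs_offdiagonal: float


class SNRResult(NamedTuple):
    value: float
    zero_std: bool


def _common_grid(spectra: Sequence[Spectrum]) -> SpectralGrid:
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != grid:
            raise GridMismatchError("spectra are on different grids")
    return grid


def correlation_matrix(spectra: Sequence[Spectrum]) -> CorrelationResult:
    """Pearson correlation matrix of a set of spectra on a common grid.

    Returns the symmetric matrix with unit diagonal together with the mean
    off-diagonal value and the mean magnitude of the off-diagonal values.
    The magnitude summary is the relevant conditioning statistic for an
    encoding-filter set: anti-correlated filters are just as independent as
    uncorrelated ones.

    Raises
    ------
    GridMismatchError
        If the spectra are not on a common grid.
    DegenerateInputError
        If fewer than two spectra are given or any spectrum is constant.
    """
    if len(spectra) < 2:
        raise DegenerateInputError("need at least two spectra")
    _common_grid(spectra)
    X = np.vstack([s.intensity for s in spectra])
    if np.any(X.std(axis=1) == 0):
        raise DegenerateInputError("constant spectrum has no defined correlation")
    C = np.corrcoef(X)
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    off = C[~np.eye(len(spectra), dtype=bool)]
    return CorrelationResult(C, float(off.mean()), float(np.abs(off).mean()))


def fourier_amplitude(spectrum: Spectrum) -> FourierAmplitude:
    """Amplitude of the Fourier transform of a spectrum along wavelength.

    The grid must be uniform (guaranteed by :class:`SpectralGrid`).  The
    frequency axis is in cycles per micrometre of wavelength, so a cosine
    with a 50 nm period shows a single line at 20 um^-1.
    """
    step_um = spectrum.grid.step * 1e-3
    amp = np.abs(np.fft.rfft(spectrum.intensity))
    freqs = np.fft.rfftfreq(spectrum.grid.n, d=step_um)
    return FourierAmplitude(freqs, amp, float(amp[0]))


def spectral_inner_product(a: Spectrum, b: Spectrum) -> float:
    """Wavelength-domain inner product sum_k a[k] b[k] * dlambda.

    Equals the Fourier-domain sum over nu of conj(A(nu)) * B(nu) scaled by
    dlambda / N (Parseval), which is how an encoded measurement weights the
    Fourier components of the target spectrum.
    """
    a.grid.require_same(b.grid)
    return float(np.sum(a.intensity * b.intensity) * a.grid.step)


def fourier_inner_product(a: Spectrum, b: Spectrum) -> float:
    """Same quantity as :func:`spectral_inner_product`, evaluated in the
    Fourier domain via the full complex DFT (Parseval route)."""
    a.grid.require_same(b.grid)
    A = np.fft.fft(a.intensity)
    B = np.fft.fft(b.intensity)
    n = a.grid.n
    return float(np.real(np.sum(np.conj(A) * B)) / n * a.grid.step)


def dominant_range(
    spectra: Sequence[Spectrum] | Spectrum, threshold_fraction: float = 0.05
) -> float:
    """Frequency (um^-1) beyond which the set's Fourier amplitude stays
    below ``threshold_fraction`` of the zero-frequency component.

    Each spectrum's amplitude is normalised by its own dc before taking the
    pointwise maximum over the set; the result is the smallest grid
    frequency nu such that every strictly larger frequency is below the
    threshold.
    """
    if isinstance(spectra, Spectrum):
        spectra = [spectra]
    if not 0 < threshold_fraction < 1:
        raise ValidationError("threshold_fraction must lie in (0, 1)")
    rel = []
    freqs = None
    for s in spectra:
        fa = fourier_amplitude(s)
        if fa.dc == 0 and fa.amplitude.max() == 0:
            raise DegenerateInputError("all-zero spectrum")
        if fa.dc == 0:
            raise DegenerateInputError("zero-mean spectrum: dc reference undefined")
        rel.append(fa.amplitude / fa.dc)
        freqs = fa.frequencies
    envelope = np.max(np.vstack(rel), axis=0)
    above = np.nonzero(envelope >= threshold_fraction)[0]
    # index 0 (dc) is always >= threshold; the dominant range ends at the
    # last frequency still reaching the threshold.
    return float(freqs[above[-1]])


def _rae_arrays(
    recon: np.ndarray, truth: np.ndarray, mask: np.ndarray | None
) -> tuple:
    err = np.abs(recon - truth).mean(axis=-1)
    level = truth.mean(axis=-1)
    bad = level <= 0
    if mask is not None:
        bad = bad | mask
    with np.errstate(divide="ignore", invalid="ignore"):
        rmap = np.where(bad, np.nan, err / np.where(level == 0, np.nan, level)) * 100.0
    return rmap, bad


class RAEResult(NamedTuple):
    map: np.ndarray          # percent, NaN at masked/degenerate pixels
    mean: float              # percent, over valid pixels
    median: float            # percent, over valid pixels
    n_masked: int


def rae(recon, truth, mask: np.ndarray | None = None) -> RAEResult:
    """Relative absolute error of a reconstruction, in percent.

    Per pixel, RAE = mean_lambda |t_hat - t| / mean_lambda t * 100.  The
    normaliser is the spectrally averaged truth level, which keeps the
    statistic stable where individual bands approach zero.  Pixels with
    non-positive truth level, or flagged in ``mask``, are excluded from the
    summaries and counted in ``n_masked``.

    Accepts two :class:`Spectrum` or two :class:`HSICube` (or raw arrays of
    matching shape whose last axis is wavelength).
    """
    if isinstance(recon, Spectrum) and isinstance(truth, Spectrum):
        recon.grid.require_same(truth.grid)
        r, t = recon.intensity[None, :], truth.intensity[None, :]
    elif isinstance(recon, HSICube) and isinstance(truth, HSICube):
        recon.grid.require_same(truth.grid)
        if mask is None:
            mask = truth.mask | recon.mask
        r, t = recon.data, truth.data
    else:
        r, t = np.asarray(recon, float), np.asarray(truth, float)
    if r.shape != t.shape:
        raise ValidationError("reconstruction and truth shapes differ")
    rmap, bad = _rae_arrays(r, t, mask)
    valid = rmap[~np.isnan(rmap)]
    if valid.size == 0:
        return RAEResult(rmap, float("nan"), float("nan"), int(bad.sum()))
    return RAEResult(rmap, float(valid.mean()), float(np.median(valid)), int(bad.sum()))


def band_rae(
    recon: HSICube, truth: HSICube, mask: np.ndarray | None = None
) -> np.ndarray:
    """Per-band RAE in percent, averaged over valid pixels.

    For band k, RAE_k = mean_pixels |t_hat_k - t_k| / mean_lambda t * 100,
    using the same spectrally averaged per-pixel normaliser as :func:`rae`.
    """
    recon.grid.require_same(truth.grid)
    if mask is None:
        mask = truth.mask | recon.mask
    level = truth.data.mean(axis=-1)
    bad = (level <= 0) | mask
    err = np.abs(recon.data - truth.data)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = err / level[..., None] * 100.0
    rel[bad] = np.nan
    return np.nanmean(rel.reshape(-1, recon.grid.n), axis=0)


def snr(image_region: np.ndarray) -> SNRResult:
    """Signal-to-noise ratio of a uniform image region.

    Defined as mean / population standard deviation of the pixel values.
    A region with zero standard deviation is reported as infinite with the
    ``zero_std`` flag set.
    """
    region = np.asarray(image_region, dtype=float).ravel()
    if region.size < 2:
        raise ValidationError("region must contain at least 2 pixels")
    sd = region.std()  # population std (ddof=0)
    if sd == 0:
        warnings.warn("zero standard deviation in SNR region", stacklevel=2)
        return SNRResult(float("inf"), True)
    return SNRResult(float(region.mean() / sd), False)
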