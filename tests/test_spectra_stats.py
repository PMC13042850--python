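"""Spectral containers and statistics."""

import numpy as np
import pytest

from endospec.errors import (
    DegenerateInputError,
    GridMismatchError,
    ValidationError,
)
from endospec.spectra import SpectralGrid, Spectrum
from endospec.stats import (
    correlation_matrix,
    dominant_range,
    fourier_amplitude,
    fourier_inner_product,
    rae,
    snr,
    spectral_inner_product,
)


class TestSpectralGrid:
    def test_default_grid_has_67_channels_420_to_750(self):
        g = SpectralGrid()
        assert g.n == 67
        assert g.values[0] == 420.0
        assert g.values[-1] == 750.0
        assert np.allclose(np.diff(g.values), 5.0)

    def test_grid_values_strictly_increasing_and_uniform(self):
        g = SpectralGrid(400, 700, 2.5)
        d = np.diff(g.values)
        assert np.all(d > 0) and np.allclose(d, d[0])

    @pytest.mark.parametrize(
        "args", [(750, 420, 5), (420, 750, -5), (420, 750, 7)]
    )
    def test_invalid_grids_rejected(self, args):
        with pytest.raises(ValidationError):
            SpectralGrid(*args)

    def test_spectrum_length_must_match_grid(self):
        with pytest.raises(ValidationError):
            Spectrum(SpectralGrid(), np.ones(10))


class TestCorrelation:
    def test_identical_spectra_correlate_to_one(self, grid, rng):
        s = Spectrum(grid, rng.random(grid.n))
        res = correlation_matrix([s, Spectrum(grid, s.intensity.copy())])
        assert res.matrix[0, 1] == pytest.approx(1.0)

    def test_quadrature_sin_cos_uncorrelated(self):
        # 5 full periods of 100 nm sampled at 1 nm: discrete orthogonality
        g = SpectralGrid(400, 899, 1.0)
        lam = g.values
        a = Spectrum(g, np.sin(2 * np.pi * lam / 100.0))
        b = Spectrum(g, np.cos(2 * np.pi * lam / 100.0))
        res = correlation_matrix([a, b])
        assert res.matrix[0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_matrix_symmetric_unit_diagonal(self, grid, rng):
        spectra = [Spectrum(grid, rng.random(grid.n)) for _ in range(5)]
        res = correlation_matrix(spectra)
        assert np.allclose(res.matrix, res.matrix.T)
        assert np.allclose(np.diag(res.matrix), 1.0)

    def test_mismatched_grids_raise(self, grid, rng):
        other = SpectralGrid(400, 700, 5)
        with pytest.raises(GridMismatchError):
            correlation_matrix(
                [Spectrum(grid, rng.random(grid.n)),
                 Spectrum(other, rng.random(other.n))]
            )

    def test_constant_spectrum_degenerate(self, grid, rng):
        with pytest.raises(DegenerateInputError):
            correlation_matrix(
                [Spectrum(grid, np.ones(grid.n)),
                 Spectrum(grid, rng.random(grid.n))]
            )


class TestFourier:
    def test_constant_spectrum_is_dc_only(self, grid):
        fa = fourier_amplitude(Spectrum(grid, np.full(grid.n, 0.7)))
        assert fa.dc == pytest.approx(0.7 * grid.n)
        assert np.all(fa.amplitude[1:] < 1e-10)

    def test_cosine_50nm_period_peaks_at_20_per_um(self):
        # 400..749 nm at 1 nm: 350 samples, exactly 7 periods of 50 nm
        g = SpectralGrid(400, 749, 1.0)
        lam = g.values
        fa = fourier_amplitude(Spectrum(g, 1 + np.cos(2 * np.pi * lam / 50.0)))
        peak = fa.frequencies[1:][np.argmax(fa.amplitude[1:])]
        assert peak == pytest.approx(20.0, abs=0.1)

    def test_parseval_equivalence_random_pairs(self, grid, rng):
        # Fourier-domain inner product equals direct quadrature
        for _ in range(100):
            a = Spectrum(grid, rng.random(grid.n))
            b = Spectrum(grid, rng.random(grid.n))
            direct = spectral_inner_product(a, b)
            fourier = fourier_inner_product(a, b)
            assert abs(direct - fourier) <= 1e-9 * abs(direct)


class TestDominantRange:
    def test_dc_only_spectrum_gives_zero(self, grid):
        assert dominant_range(Spectrum(grid, np.ones(grid.n))) == 0.0

    def test_single_cosine_ends_at_its_frequency(self):
        g = SpectralGrid(400, 749, 1.0)
        lam = g.values
        s = Spectrum(g, 1 + 0.8 * np.cos(2 * np.pi * lam / 50.0))
        nu = dominant_range(s, 0.05)
        assert 19.5 <= nu <= 21.0

    def test_matches_brute_force_scan_on_tissue_spectra(self, grid):
        from endospec.tissue import synth_dr_spectrum

        spectra = [
            synth_dr_spectrum(s, b, grid=grid)
            for s, b in [(0.2, 0.01), (0.6, 0.03), (0.95, 0.08)]
        ]
        nu = dominant_range(spectra, 0.05)
        # exhaustive oracle over the amplitude sequences
        rel = []
        for s in spectra:
            fa = fourier_amplitude(s)
            rel.append(fa.amplitude / fa.dc)
            freqs = fa.frequencies
        env = np.max(rel, axis=0)
        expected = freqs[np.nonzero(env >= 0.05)[0][-1]]
        assert nu == pytest.approx(expected)

    def test_monotone_in_threshold(self, grid):
        from endospec.tissue import synth_dr_spectrum

        s = synth_dr_spectrum(0.5, 0.05, grid=grid)
        nus = [dominant_range(s, th) for th in (0.2, 0.1, 0.05, 0.02)]
        assert all(a <= b for a, b in zip(nus, nus[1:]))

    def test_all_zero_spectrum_degenerate(self, grid):
        with pytest.raises(DegenerateInputError):
            dominant_range(Spectrum(grid, np.zeros(grid.n)))


class TestRAE:
    def test_perfect_reconstruction_zero(self, grid, rng):
        t = rng.random(grid.n) + 0.1
        assert rae(t, t).mean == pytest.approx(0.0)

    def test_five_percent_scaling_is_five_percent(self, grid, rng):
        t = rng.random(grid.n) + 0.1
        assert rae(1.05 * t, t).mean == pytest.approx(5.0)

    @pytest.mark.parametrize("c", [0.5, 0.9, 1.3])
    def test_scale_covariance(self, grid, rng, c):
        t = rng.random(grid.n) + 0.1
        assert rae(c * t, t).mean == pytest.approx(abs(c - 1) * 100.0)

    def test_matches_direct_recomputation(self, grid, rng):
        recon = rng.random((4, 5, grid.n))
        truth = rng.random((4, 5, grid.n)) + 0.1
        res = rae(recon, truth)
        k = (2, 3)
        expected = (
            np.abs(recon[k] - truth[k]).mean() / truth[k].mean() * 100.0
        )
        assert res.map[k] == pytest.approx(expected)

    def test_masked_pixels_excluded_and_counted(self, grid, rng):
        recon = rng.random((3, 3, grid.n))
        truth = rng.random((3, 3, grid.n)) + 0.1
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = True
        res = rae(recon, truth, mask)
        assert np.isnan(res.map[0, 0])
        assert res.n_masked == 1

    def test_zero_mean_truth_pixel_masked(self, grid):
        truth = np.zeros((1, 1, grid.n))
        recon = np.ones((1, 1, grid.n))
        res = rae(recon, truth)
        assert res.n_masked == 1 and np.isnan(res.median)


class TestSNR:
    def test_hand_computable_region(self):
        res = snr(np.array([1.0, 2.0, 3.0]))
        assert res.value == pytest.approx(2.0 / np.sqrt(2.0 / 3.0), rel=1e-6)

    def test_constant_region_flagged_infinite(self):
        with pytest.warns(UserWarning):
            res = snr(np.full((8, 8), 3.0))
        assert np.isinf(res.value) and res.zero_std

    def test_gaussian_sampling_oracle(self, rng):
        region = rng.normal(100.0, 10.0, 10_000)
        assert snr(region).value == pytest.approx(10.0, rel=0.05)

    def test_too_small_region_rejected(self):
        with pytest.raises(ValidationError):
            snr(np.array([1.0]))
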