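"""Encoding set assembly, the forward measurement model and demosaicking."""

import numpy as np
import pytest

from endospec.encoding import (
    BayerResponse,
    EncodingSet,
    NoiseModel,
    RawFrameSet,
    SourceSpectrum,
    build_encoding_set,
    channel_map,
    demosaic,
    encode,
    notch_spectrum,
)
from endospec.errors import GridMismatchError, ValidationError
from endospec.spectra import HSICube, SpectralGrid, Spectrum
from endospec.stats import fourier_amplitude


@pytest.fixture()
def bayer(grid):
    return BayerResponse.gaussian_model(grid)


@pytest.fixture()
def source(grid):
    return SourceSpectrum.white_led(grid)


class TestBuildEncodingSet:
    def test_unit_filters_flat_source_reduce_to_bayer(self, grid, bayer):
        unit = [Spectrum(grid, np.ones(grid.n)) for _ in range(3)]
        flat = SourceSpectrum(grid, np.ones(grid.n))
        enc = build_encoding_set(unit, bayer, flat)
        for i in range(3):
            assert np.allclose(enc.spectra[i], bayer.channels)

    def test_nine_rows_in_declared_order(self, enc):
        assert enc.matrix.shape == (9, 67)
        # row (i, j) equals spectra[i, j] * step
        for i in range(3):
            for j in range(3):
                assert np.allclose(
                    enc.matrix[3 * i + j], enc.spectra[i, j] * enc.grid.step
                )

    def test_notch_zeroes_center_leaves_far_band(self, grid, filter_set, bayer, source):
        enc_plain = build_encoding_set(filter_set, bayer, source)
        enc_notch = build_encoding_set(
            filter_set, bayer, source, notch=(633.0, 20.0)
        )
        lam = grid.values
        inside = np.abs(lam - 633.0) <= 5.0
        far = np.abs(lam - 633.0) >= 30.0
        assert np.all(enc_notch.spectra[:, :, inside] == 0.0)
        assert np.allclose(
            enc_notch.spectra[:, :, far], enc_plain.spectra[:, :, far]
        )

    def test_grid_mismatch_rejected(self, filter_set, bayer):
        other = SourceSpectrum(SpectralGrid(400, 700, 5), np.ones(61))
        with pytest.raises(GridMismatchError):
            build_encoding_set(filter_set, bayer, other)

    def test_notch_profile_smooth_dip(self, grid):
        t = notch_spectrum(grid, 633.0, 20.0).intensity
        assert t.min() == 0.0 and t.max() == 1.0
        assert np.all((t >= 0) & (t <= 1))


class TestEncode:
    def test_zero_cube_zero_frames(self, grid, enc):
        cube = HSICube(grid, np.zeros((4, 4, grid.n)))
        raw = encode(cube, enc)
        assert np.all(raw.frames == 0)

    def test_delta_spectrum_reads_encoding_value(self, grid, enc):
        k0 = grid.index_of(550)
        data = np.zeros((2, 2, grid.n))
        data[..., k0] = 1.0
        raw = encode(HSICube(grid, data), enc)
        cmap = channel_map("RGGB", (2, 2))
        for y in range(2):
            for x in range(2):
                for i in range(3):
                    expected = enc.spectra[i, cmap[y, x], k0] * grid.step
                    assert raw.frames[i, y, x] == pytest.approx(expected)

    def test_matches_dense_matrix_oracle(self, grid, enc, rng):
        cube = HSICube(grid, rng.random((6, 7, grid.n)))
        raw = encode(cube, enc)
        A = enc.matrix
        cmap = channel_map("RGGB", (6, 7))
        for y in range(6):
            for x in range(7):
                for i in range(3):
                    expected = A[3 * i + cmap[y, x]] @ cube.data[y, x]
                    assert raw.frames[i, y, x] == pytest.approx(expected, rel=1e-12)

    def test_linearity_noise_off(self, grid, enc, rng):
        t1 = rng.random((4, 4, grid.n))
        t2 = rng.random((4, 4, grid.n))
        a, b = 0.7, 2.3
        f_sum = encode(HSICube(grid, a * t1 + b * t2), enc).frames
        f1 = encode(HSICube(grid, t1), enc).frames
        f2 = encode(HSICube(grid, t2), enc).frames
        assert np.allclose(f_sum, a * f1 + b * f2, atol=1e-10)

    def test_fourier_domain_measurement_consistency(self, grid, enc, rng):
        # Eq-1-style identity: the noiseless measurement equals the
        # Fourier-domain inner product of encoding row and pixel spectrum
        t = rng.random(grid.n)
        cube = HSICube(grid, t[None, None, :])
        raw = encode(cube, enc)
        row = enc.spectra[1, channel_map("RGGB", (1, 1))[0, 0]]
        E = np.fft.fft(row)
        T = np.fft.fft(t)
        fourier = np.real(np.sum(np.conj(E) * T)) / grid.n * grid.step
        assert raw.frames[1, 0, 0] == pytest.approx(fourier, rel=1e-10)

    def test_seed_determinism_bit_identical(self, grid, enc, rng):
        cube = HSICube(grid, rng.random((6, 6, grid.n)))
        nm = NoiseModel(0.05, 0.05, seed=42)
        raw1 = encode(cube, enc, nm)
        raw2 = encode(cube, enc, nm)
        assert np.array_equal(raw1.frames, raw2.frames)
        assert np.array_equal(raw1.v_values, raw2.v_values)

    def test_v_values_recorded_within_declared_range(self, grid, enc, rng):
        cube = HSICube(grid, rng.random((4, 4, grid.n)))
        raw = encode(cube, enc, NoiseModel(0.0, 0.05, seed=0))
        assert np.all((raw.v_values >= 0.95) & (raw.v_values <= 1.05))

    def test_negative_scene_rejected(self, grid, enc):
        data = np.full((2, 2, grid.n), -0.1)
        with pytest.raises(ValidationError):
            encode(HSICube(grid, data), enc)

    def test_low_frequency_encoding_beats_matched_random(self, grid, enc, rng):
        # encoding amplitude within the tissue-dominant Fourier range
        # exceeds that of an equal-energy pseudo-random encoding
        nu_max = 18.0
        rows = enc.spectra.reshape(9, grid.n)
        rand = rng.uniform(0, 1, rows.shape)
        rand *= np.linalg.norm(rows) / np.linalg.norm(rand)

        def low_freq_amp(X):
            tot = 0.0
            for r in X:
                fa = fourier_amplitude(Spectrum(grid, r))
                sel = (fa.frequencies > 0) & (fa.frequencies <= nu_max)
                tot += fa.amplitude[sel].sum()
            return tot

        assert low_freq_amp(rows) > low_freq_amp(rand)


class TestDemosaic:
    def test_constant_frames_constant_stack(self):
        raw = RawFrameSet(np.full((3, 6, 6), 2.5), np.ones(3))
        stack = demosaic(raw)
        assert np.allclose(stack, 2.5)

    def test_native_sites_preserved_exactly(self, rng):
        frames = rng.random((3, 8, 8))
        raw = RawFrameSet(frames, np.ones(3))
        stack = demosaic(raw)
        cmap = channel_map("RGGB", (8, 8))
        for i in range(3):
            for j in range(3):
                native = cmap == j
                assert np.array_equal(stack[:, :, 3 * i + j][native], frames[i][native])

    def test_affine_image_reproduced_exactly(self):
        ramp = 2.0 * np.arange(8)[:, None] + 3.0 * np.arange(10)[None, :] + 5.0
        raw = RawFrameSet(np.stack([ramp] * 3), np.ones(3))
        stack = demosaic(raw)
        assert np.allclose(stack, ramp[:, :, None], atol=1e-10)

    def test_unknown_pattern_rejected(self, rng):
        raw = RawFrameSet(rng.random((3, 4, 4)), np.ones(3), pattern="RGGB")
        raw.pattern = "XYZW"
        with pytest.raises(ValidationError):
            demosaic(raw)

    def test_encoding_id_mismatch_rejected(self, enc, rng):
        raw = RawFrameSet(
            rng.random((3, 4, 4)), np.ones(3), encoding_id="RGGB-deadbeef"
        )
        with pytest.raises(ValidationError):
            demosaic(raw, enc)
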