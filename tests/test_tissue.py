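"""Synthetic tissue scenes, probe spectra and dataset generation."""

import numpy as np
import pytest

from endospec import mc
from endospec.encoding import NoiseModel, channel_map
from endospec.errors import ValidationError
from endospec.hemoglobin import extinction
from endospec.spectra import SpectralGrid
from endospec.tissue import (
    SceneConfig,
    probe_spectrum,
    synth_dataset,
    synth_dr_spectrum,
    synth_probe_scene,
    synth_scene,
)
from endospec.views import vessel_contrast_curve


class TestDRSpectrum:
    def test_bloodless_tissue_is_spectrally_flat(self, grid):
        s = synth_dr_spectrum(0.5, 0.0, grid=grid)
        assert np.ptp(s.intensity) == pytest.approx(0.0, abs=1e-12)

    def test_oxygenated_blood_brighter_in_red(self, grid):
        # oxyhemoglobin absorbs far less at 660 nm than deoxyhemoglobin
        k = grid.index_of(660)
        hi = synth_dr_spectrum(1.0, 0.03, grid=grid).intensity[k]
        lo = synth_dr_spectrum(0.0, 0.03, grid=grid).intensity[k]
        assert hi > lo
        eps_o, eps_d = extinction(grid)
        assert eps_d[k] > eps_o[k]  # the sign the contract relies on

    def test_matches_lookup_table_interpolation(self, grid):
        table = mc.build_lookup(
            so2_grid=np.array([0.0, 0.5, 1.0]),
            bv_grid=np.array([0.01, 0.04]),
            cfg=mc.MCConfig(photons=2000, seed=5),
        )
        s = synth_dr_spectrum(0.3, 0.02, table=table)
        expected = table.interpolate(0.3, 0.02)
        assert np.allclose(s.intensity, expected)

    def test_parameter_continuity(self, grid):
        a = synth_dr_spectrum(0.5, 0.03, grid=grid).intensity
        b = synth_dr_spectrum(0.5 + 1e-6, 0.03, grid=grid).intensity
        assert np.abs(a - b).max() < 1e-4

    @pytest.mark.parametrize("so2,bv", [(-0.1, 0.01), (1.1, 0.01), (0.5, -1)])
    def test_out_of_range_rejected(self, grid, so2, bv):
        with pytest.raises(ValidationError):
            synth_dr_spectrum(so2, bv, grid=grid)


class TestScene:
    def test_uniform_scene_without_vessels(self):
        cfg = SceneConfig(
            height=16, width=16, n_vessels=0, specular_density=0.0,
            background_so2=(0.7, 0.7), background_bv=(0.02, 0.02),
            scatter_scale=(1.0, 1.0), seed=1,
        )
        scene = synth_scene(cfg)
        flat = scene.cube.data.reshape(-1, scene.cube.grid.n)
        assert np.allclose(flat, flat[0])

    def test_seed_determinism_bit_for_bit(self):
        cfg = SceneConfig(height=24, width=24, seed=7)
        a = synth_scene(cfg)
        b = synth_scene(cfg)
        assert np.array_equal(a.cube.data, b.cube.data)
        assert np.array_equal(a.specular_mask, b.specular_mask)

    def test_cube_bounded_and_specular_marked(self):
        cfg = SceneConfig(height=32, width=32, specular_density=0.05, seed=3)
        scene = synth_scene(cfg)
        assert scene.cube.data.min() >= 0
        assert scene.cube.data.max() <= 1.2 + 1e-12
        clipped = np.all(scene.cube.data >= 1.2 - 1e-12, axis=-1)
        assert np.array_equal(clipped, scene.specular_mask)

    def test_deep_vessel_contrast_peaks_at_longer_wavelength(self, grid):
        # build two controlled scenes differing only in vessel depth
        base = dict(so2=0.7, bv=0.02)
        bg = synth_dr_spectrum(**base, grid=grid).intensity
        shallow = synth_dr_spectrum(**base, grid=grid).intensity * 0 + \
            synth_dr_spectrum(0.6, 0.12, depth_um=20.0, grid=grid).intensity
        deep = synth_dr_spectrum(0.6, 0.12, depth_um=350.0, grid=grid).intensity
        cube_data = np.tile(bg, (4, 6, 1))
        cube_data[1:3, 1:3] = shallow
        cube_data[1:3, 4:6] = deep
        from endospec.spectra import HSICube

        cube = HSICube(grid, cube_data)
        vessel_s = np.zeros((4, 6), bool)
        vessel_s[1:3, 1:3] = True
        vessel_d = np.zeros((4, 6), bool)
        vessel_d[1:3, 4:6] = True
        background = ~(vessel_s | vessel_d)
        _, peak_shallow = vessel_contrast_curve(cube, vessel_s, background)
        _, peak_deep = vessel_contrast_curve(cube, vessel_d, background)
        assert peak_deep > peak_shallow


class TestProbeSpectrum:
    def test_single_peak_at_center(self, grid):
        s = probe_spectrum("single", 550.0, fwhm_nm=10.0, grid=grid)
        assert grid.values[np.argmax(s.intensity)] == 550.0

    def test_double_peaks_at_stated_separation(self, grid):
        s = probe_spectrum("double", 550.0, 20.0, 10.0, grid=grid)
        y = s.intensity
        maxima = [k for k in range(1, grid.n - 1)
                  if y[k] > y[k - 1] and y[k] >= y[k + 1]]
        assert len(maxima) == 2
        assert grid.values[maxima[1]] - grid.values[maxima[0]] == 20.0
        assert y[maxima[0]] == pytest.approx(y[maxima[1]], rel=1e-9)

    def test_sub_step_separation_rejected(self, grid):
        with pytest.raises(ValidationError):
            probe_spectrum("double", 550.0, 0.0, 10.0, grid=grid)

    def test_sub_step_fwhm_rejected(self, grid):
        with pytest.raises(ValidationError):
            probe_spectrum("single", 550.0, fwhm_nm=1.0, grid=grid)


class TestDataset:
    def test_pairs_have_distinct_logged_seeds(self, enc):
        ds = synth_dataset(
            4, SceneConfig(height=16, width=16), enc,
            NoiseModel(0.05, 0.05), seed=9,
        )
        seeds = [m["scene_seed"] for m in ds.manifest]
        assert len(set(seeds)) == 4
        assert len(ds.stacks) == len(ds.cubes) == 4

    def test_noiseless_pairs_match_dense_oracle(self, enc):
        ds = synth_dataset(
            2, SceneConfig(height=8, width=8, specular_density=0.0), enc,
            NoiseModel(0.0, 0.0), seed=2,
        )
        A = enc.matrix
        cmap = channel_map(enc.pattern, (8, 8))
        stack = ds.stacks[0]
        cube = ds.cubes[0].data
        for y in range(8):
            for x in range(8):
                for i in range(3):
                    j = cmap[y, x]
                    expected = A[3 * i + j] @ cube[y, x]
                    assert stack[y, x, 3 * i + j] == pytest.approx(expected)

    def test_default_noise_configuration_recorded(self, enc):
        ds = synth_dataset(
            2, SceneConfig(height=8, width=8), enc, NoiseModel(), seed=1
        )
        assert ds.manifest[0]["noise_fraction"] == 0.05
        assert ds.manifest[0]["illumination_variation"] == 0.05

    def test_single_scene_rejected(self, enc):
        with pytest.raises(ValidationError):
            synth_dataset(1, SceneConfig(), enc, NoiseModel(), seed=0)

    def test_probe_fraction_mixes_scene_kinds(self, enc):
        ds = synth_dataset(
            8, SceneConfig(height=16, width=16), enc, NoiseModel(),
            seed=3, probe_fraction=0.25,
        )
        kinds = [m["kind"] for m in ds.manifest]
        assert kinds.count("probe") == 2

    def test_probe_scene_deterministic(self):
        a = synth_probe_scene(11, 16, 16)
        b = synth_probe_scene(11, 16, 16)
        assert np.array_equal(a.cube.data, b.cube.data)
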