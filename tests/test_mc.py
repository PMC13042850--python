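"""Monte-Carlo transport, the lookup table and composition inversion."""

import numpy as np
import pytest

from endospec import mc
from endospec.errors import ValidationError
from endospec.hemoglobin import blood_absorption_mm
from endospec.spectra import HSICube


@pytest.fixture(scope="module")
def small_table():
    return mc.build_lookup(cfg=mc.MCConfig(photons=4000, seed=21))


class TestOpticalProperties:
    def test_bloodless_absorption_is_background_only(self, grid):
        props = mc.optical_properties(0.5, 0.0, grid=grid)
        assert np.allclose(props.mua_mm, mc.MUA_BACKGROUND_MM)

    def test_linear_in_so2(self, grid):
        p0 = mc.optical_properties(0.0, 0.02, grid=grid).mua_mm
        p1 = mc.optical_properties(1.0, 0.02, grid=grid).mua_mm
        ph = mc.optical_properties(0.5, 0.02, grid=grid).mua_mm
        assert np.allclose(ph, (p0 + p1) / 2.0)

    def test_recomputation_from_extinction_table(self, grid):
        so2, bv = 0.73, 0.035
        props = mc.optical_properties(so2, bv, grid=grid)
        expected = bv * blood_absorption_mm(so2, grid) + mc.MUA_BACKGROUND_MM
        assert np.allclose(props.mua_mm[0], expected)

    def test_scatter_power_law(self, grid):
        sp = mc.ScatterParams(a_mm=1.5, b=1.3)
        props = mc.optical_properties(0.5, 0.01, sp, grid)
        musp = props.mus_mm[0] * (1 - sp.g)
        assert musp[0] > musp[-1]  # scattering falls with wavelength
        assert musp[grid.index_of(500)] == pytest.approx(1.5, rel=1e-6)

    @pytest.mark.parametrize("so2,bv", [(-0.1, 0.01), (2.0, 0.01), (0.5, -0.1)])
    def test_invalid_params_rejected(self, grid, so2, bv):
        with pytest.raises(ValidationError):
            mc.optical_properties(so2, bv, grid=grid)


class TestTransport:
    def test_energy_conservation(self):
        props = mc.optical_properties(0.5, 0.02, grid=np.array([560.0]))
        res = mc.mc_diffuse_reflectance(props, mc.MCConfig(photons=5000, seed=1))
        assert res.total == pytest.approx(1.0, abs=3 * res.rd_stderr + 1e-3)

    def test_lossless_matched_medium_returns_everything(self):
        props = mc.OpticalProperties(
            np.array([500.0]), np.array([[0.0]]), np.array([[5.0]]),
            np.array([0.8]), np.array([1.0]), np.array([np.inf]),
        )
        res = mc.mc_diffuse_reflectance(props, mc.MCConfig(photons=1500, seed=3))
        assert res.rd > 0.97

    def test_diffusion_approximation_agreement(self):
        # musp/mua = 10, g = 0.9, matched boundary: compare with the
        # semi-infinite diffusion closed form (Groenhuis form, k = 1)
        props = mc.OpticalProperties(
            np.array([500.0]), np.array([[0.1]]), np.array([[10.0]]),
            np.array([0.9]), np.array([1.0]), np.array([np.inf]),
        )
        res = mc.mc_diffuse_reflectance(props, mc.MCConfig(photons=30000, seed=2))
        ap = 1.0 / 1.1  # musp' / (musp' + mua)
        diffusion = ap / (1 + 2 * (1 - ap) + (1 + 2 / 3) * np.sqrt(3 * (1 - ap)))
        assert res.rd == pytest.approx(diffusion, rel=0.10)

    def test_monotone_decreasing_in_absorption(self):
        rds = []
        for mua in (0.05, 0.2, 0.8):
            props = mc.OpticalProperties(
                np.array([500.0]), np.array([[mua]]), np.array([[10.0]]),
                np.array([0.9]), np.array([1.4]), np.array([np.inf]),
            )
            rds.append(mc.mc_diffuse_reflectance(
                props, mc.MCConfig(photons=5000, seed=4)).rd)
        assert rds[0] > rds[1] > rds[2]

    def test_seed_determinism(self):
        props = mc.optical_properties(0.5, 0.02, grid=np.array([560.0]))
        a = mc.mc_diffuse_reflectance(props, mc.MCConfig(photons=3000, seed=9))
        b = mc.mc_diffuse_reflectance(props, mc.MCConfig(photons=3000, seed=9))
        assert a.rd == b.rd

    def test_too_few_photons_rejected(self):
        with pytest.raises(ValidationError):
            mc.MCConfig(photons=10)


class TestSharedEnsemble:
    def test_agrees_with_direct_walk(self):
        ens = mc.ScatterCountEnsemble(photons=20000, seed=6)
        props = mc.optical_properties(0.5, 0.02, grid=np.array([560.0]))
        mua, mus = props.mua_mm[0, 0], props.mus_mm[0, 0]
        rd_shared, se_shared = ens.diffuse_reflectance(mus / (mua + mus))
        direct = mc.mc_diffuse_reflectance(props, mc.MCConfig(photons=20000, seed=7))
        tol = 3 * np.hypot(se_shared[0], direct.rd_stderr)
        assert rd_shared[0] == pytest.approx(direct.rd, abs=tol)

    def test_reflectance_monotone_in_albedo(self):
        ens = mc.ScatterCountEnsemble(photons=5000, seed=1)
        rd, _ = ens.diffuse_reflectance(np.array([0.5, 0.8, 0.95, 0.99]))
        assert np.all(np.diff(rd) > 0)


class TestLookup:
    def test_smoke_table_monotone_contracts(self):
        table = mc.build_lookup(
            so2_grid=np.array([0.0, 1.0]),
            bv_grid=np.array([0.01, 0.05]),
            cfg=mc.MCConfig(photons=2000, seed=13),
        )
        k660 = table.grid.index_of(660)
        k560 = table.grid.index_of(560)
        # more oxygen -> brighter red at fixed blood volume
        assert table.spectra[1, 0, k660] > table.spectra[0, 0, k660]
        # more blood -> darker green at fixed oxygenation
        assert table.spectra[0, 1, k560] < table.spectra[0, 0, k560]

    def test_half_saturation_row_between_extremes(self):
        table = mc.build_lookup(
            so2_grid=np.array([0.0, 0.5, 1.0]),
            bv_grid=np.array([0.02]),
            cfg=mc.MCConfig(photons=3000, seed=17),
        )
        k660 = table.grid.index_of(660)
        lo, mid, hi = table.spectra[:, 0, k660]
        assert lo <= mid <= hi

    def test_identical_seeds_identical_tables(self):
        kw = dict(
            so2_grid=np.array([0.0, 1.0]), bv_grid=np.array([0.02]),
            cfg=mc.MCConfig(photons=2000, seed=23),
        )
        a = mc.build_lookup(**kw)
        b = mc.build_lookup(**kw)
        assert np.array_equal(a.spectra, b.spectra)
        assert a.config_hash == b.config_hash

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValidationError):
            mc.build_lookup(
                so2_grid=np.array([1.0, 0.0]), bv_grid=np.array([0.02]),
                cfg=mc.MCConfig(photons=2000, seed=1),
            )


class TestInversion:
    def test_exact_table_entry_recovered(self, small_table):
        t = small_table
        data = np.tile(t.spectra[7, 2], (2, 2, 1))
        maps = mc.invert_composition(HSICube(t.grid, data), t)
        assert np.allclose(maps.so2, t.so2_grid[7])
        assert np.allclose(maps.blood_volume, t.bv_grid[2])
        assert np.allclose(maps.mse, 0.0)

    def test_matches_exhaustive_cell_scan(self, small_table, rng):
        t = small_table
        pix = rng.random((20, t.grid.n)) * 0.4 + 0.05
        cube = HSICube(t.grid, pix[None])
        maps = mc.invert_composition(cube, t, refine=False)
        flat = t.spectra.reshape(-1, t.grid.n)
        flat = flat / flat.max(axis=1, keepdims=True)
        for p in range(20):
            q = pix[p] / pix[p].max()
            d2 = ((flat - q) ** 2).mean(axis=1)
            ai, bi = np.unravel_index(np.argmin(d2), t.spectra.shape[:2])
            assert maps.so2[0, p] == t.so2_grid[ai]
            assert maps.blood_volume[0, p] == t.bv_grid[bi]

    def test_parameter_recovery_under_noise(self, small_table, rng):
        t = small_table
        so2_true = rng.uniform(0, 1, 100)
        bv_true = np.exp(rng.uniform(np.log(t.bv_grid[0]), np.log(t.bv_grid[-1]), 100))
        spec = t.interpolate(so2_true, bv_true)
        spec = spec / spec.max(axis=-1, keepdims=True)
        noisy = np.clip(spec + rng.normal(0, 0.01, spec.shape), 0, None)
        maps = mc.invert_composition(HSICube(t.grid, noisy[None]), t)
        assert np.median(np.abs(maps.so2[0] - so2_true)) < 0.05

    def test_pixel_permutation_invariance(self, small_table, rng):
        t = small_table
        pix = rng.random((12, t.grid.n)) * 0.4 + 0.05
        maps = mc.invert_composition(HSICube(t.grid, pix[None]), t)
        perm = rng.permutation(12)
        maps_p = mc.invert_composition(HSICube(t.grid, pix[perm][None]), t)
        assert np.allclose(maps_p.so2[0], maps.so2[0][perm])

    def test_masked_pixels_skipped(self, small_table):
        t = small_table
        data = np.tile(t.spectra[3, 1], (2, 2, 1))
        mask = np.array([[True, False], [False, False]])
        maps = mc.invert_composition(HSICube(t.grid, data, mask=mask), t)
        assert np.isnan(maps.so2[0, 0]) and not np.isnan(maps.so2[0, 1])

    def test_grid_mismatch_rejected(self, small_table):
        from endospec.spectra import SpectralGrid

        other = SpectralGrid(400, 730, 5)
        cube = HSICube(other, np.ones((1, 1, other.n)))
        with pytest.raises(Exception):
            mc.invert_composition(cube, small_table)
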