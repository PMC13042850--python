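"""Monte-Carlo lookup oximetry: recover sO2 and relative blood volume.

Builds the (sO2, blood-volume) -> diffuse-reflectance lookup table by
Monte-Carlo photon transport, generates a scene whose spectra are drawn
from the table, and inverts it by amplitude-normalised least squares.
"""

import numpy as np

from endospec import HSICube, MCConfig, build_lookup, invert_composition

table = build_lookup(cfg=MCConfig(photons=20_000, seed=11))
print(f"lookup table: {len(table.so2_grid)} sO2 x {len(table.bv_grid)} bv "
      f"cells, {table.grid.n} wavelengths (hash {table.config_hash})")

rng = np.random.default_rng(4)
so2_true = rng.uniform(0, 1, (32, 32))
bv_true = np.exp(rng.uniform(np.log(table.bv_grid[0]),
                             np.log(table.bv_grid[-1]), (32, 32)))
spectra = table.interpolate(so2_true, bv_true)
spectra /= spectra.max(axis=-1, keepdims=True)
noisy = np.clip(spectra + rng.normal(0, 0.01, spectra.shape), 0, None)

maps = invert_composition(HSICube(table.grid, noisy), table)
err = np.abs(maps.so2 - so2_true)
print(f"median |sO2 error| = {np.median(err):.3f} "
      f"(target scale: +/-0.05 under 1% noise)")
print(f"median per-pixel fit MSE = {np.median(maps.mse):.2e} "
      f"(well below the 1e-3 scale of a good fit)")
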