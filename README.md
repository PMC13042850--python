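# endospec

Simulation and analysis pipeline for **snapshot hyperspectral endoscopy
via low-frequency stochastic spectral encoding**: design of the encoding
filters, the spectral-encoding forward model, learned reconstruction of
67-channel reflectance cubes from three Bayer-mosaicked frames, and
Monte-Carlo tissue oximetry.

## The problem

Endoscopic tissue moves; scanning hyperspectral cameras blur. A snapshot
alternative encodes the spectrum into very few measurements: three
broadband illuminations, each filtered by a thin-film interference filter
with a smooth, weakly correlated transmission spectrum, imaged through an
ordinary Bayer colour sensor. Each pixel then carries nine weighted
integrals of its diffuse-reflectance (DR) spectrum t(λ),

    I_ij = V_i ∫ f_i(λ) d_j(λ) s(λ) t(λ) dλ + N,

with f_i the illumination filters, d_j the Bayer responses, s the source,
V_i a per-frame gain fluctuation and N detection noise. Because tissue DR
spectra are spectrally smooth (their Fourier content along λ sits at low
wavelength-frequency), smooth "low-frequency stochastic" encoding spectra
concentrate the encoding weight exactly where the signal lives, and a
learned reconstructor can recover a 67-channel cube (420–750 nm, 5 nm)
at full pixel resolution. From the cube follow white-light and
narrow-band views, vessel depth contrast, and — through a Monte-Carlo
lookup table — maps of hemoglobin oxygen saturation (sO₂) and relative
blood volume.

`endospec` implements this pipeline end to end on synthetic scenes:

- `endospec.thinfilm` — transfer-matrix optics; the three five-layer
  TiO₂/SiO₂ filter stacks (cavities 240/320/560 nm).
- `endospec.encoding` — encoding sets e_ij = f_i·d_j·s, the measurement
  model with mosaicking, 5% noise and ±5% illumination variation, and
  bilinear demosaicking.
- `endospec.tissue` — synthetic vascularised scenes (hemoglobin spectra,
  vessels at depth, specular highlights) and training datasets.
- `endospec.esanet` — the encoding-guided spectral-attention U-Net (pure
  NumPy, CPU-trainable, deployed as a two-member ensemble);
  `endospec.baseline` — the Tikhonov reference;
  `endospec.resolution` — the sparse-dictionary probe decoder and the
  double-peak resolution harness.
- `endospec.mc` — photon-transport Monte Carlo, the (sO₂, blood-volume)
  lookup table, least-squares composition inversion.
- `endospec.views` — RGB synthesis, narrow-band views, contrast curves.
- `endospec.io` / `endospec.cli` — ENVI-style cubes, TIFF frame sets,
  HDF5 lookups, and an `endospec` command with one subcommand per stage.

## Worked example

```python
from endospec.targets import default_encoding, train_reference_model, closed_loop_rae

enc = default_encoding()                      # filters x Bayer x LED
model, hist, _ = train_reference_model(enc, seed=0)  # ~10 min on 1 CPU
result = closed_loop_rae(model, enc, seed=1)
print(result["median_rae_percent"], result["max_band_rae_450_700"])
```

The reference run of this exact loop (the `--seed 1` acceptance run)
prints

```
median spectrally averaged RAE:  3.61 %
max per-band RAE in 450-700 nm:  4.61 %
```

meaning: across twenty fresh 64×64 tissue scenes encoded with 5%
detection noise and ±5% per-frame illumination variation, half of all
pixels are reconstructed with spectrally averaged error below ~4% of
their mean reflectance, and even band-by-band the central working range
stays within 5% (errors rise at the band edges, where the encoding
carries little light — the expected physical behaviour). The same run
resolves 20 nm double peaks after encode→reconstruct and fits the
Monte-Carlo lookup composition scene with median per-pixel MSE ≈ 2·10⁻⁴.

The examples directory holds one short narrative script per capability
(filter design, encoding + baseline, training, oximetry, views):

```bash
python examples/01_filter_design.py
```

prints the three filter spectra statistics and their correlation matrix
(mean |pairwise correlation| ≈ 0.037 — three nearly independent
measurements), and `examples/04_oximetry.py` builds the Monte-Carlo
lookup and recovers sO₂ to a median error of ~0.02 under 1% noise.

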