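# Methods

This note documents the models, numerical choices and limitations behind
`endospec`. The package simulates, end to end, a snapshot hyperspectral
endoscope that recovers a 67-channel diffuse-reflectance (DR) cube over
420-750 nm from three Bayer-mosaicked frames taken under three spectrally
distinct broadband illuminations.

## Spectral grid and statistics

All spectra live on a uniform wavelength axis, by default 420-750 nm at
5 nm: 67 channels. Fourier analysis of spectra uses the unnormalised
real-input DFT with frequencies in cycles per micrometre of wavelength
(um^-1); the dc amplitude equals `|mean| * N` and every other amplitude is
compared against it. The *dominant range* of a spectrum set is the largest
grid frequency at which any member's amplitude still reaches a stated
fraction (default 5%) of its own dc; tissue DR spectra concentrate their
content below roughly 18 um^-1, which is the physical rationale for
encoding with spectrally smooth ("low-frequency") illuminations.

Reconstruction error is reported as relative absolute error (RAE): per
pixel, `mean_lambda |t_hat - t| / mean_lambda t`, in percent. The
normaliser is the spectrally averaged truth level - stable where single
bands approach zero - and the same normaliser is used for the per-band RAE
curve. SNR of a uniform region is mean over population standard deviation.
Pixels flagged as clipped specular highlights are excluded from every
summary statistic.

## Thin-film filter model

The three encoding filters are five-layer TiO2/SiO2/TiO2/SiO2/TiO2 stacks
on fused silica with layer thicknesses 60/94/X/94/60 nm, X in {240, 320,
560}; the middle layer is a weakly confined Fabry-Perot cavity.
Transmission is computed with the characteristic-matrix (transfer-matrix)
method: coherent lossless layers, semi-infinite incident medium and
substrate, normal incidence by default (oblique incidence with s/p
averaging is supported). Energy conservation (T + R = 1) and reciprocity
hold to 1e-9 and are asserted in the tests, together with the Fresnel and
quarter-wave closed forms.

Film refractive indices are a genuinely open choice: no dispersion data
accompany the layer recipe, and the pairwise-correlation statistic of the
filter set is extremely sensitive to the TiO2 index (the signed mean
correlation moves from -0.25 to +0.09 as n_TiO2 goes from 2.3 to 2.75).
We model the films with bulk-crystal literature dispersion - rutile TiO2
(Devore, ordinary ray) and fused silica (Malitson) - i.e. dense,
rutile-like coatings. This zero-free-parameter choice gives pairwise
correlations of -0.029/-0.044/+0.037 (mean magnitude 0.037) over the
working band, reproducing the near-zero correlation of the fabricated
set, whereas lower-density amorphous indices (n550 ~ 2.35) do not. The
filter-set statistic we quote is the mean |off-diagonal| Pearson
correlation: for conditioning of the inverse problem the sign of a
correlation is irrelevant.

## Encoding forward model

The encoding spectrum of illumination i and colour channel j is the
pointwise product `e_ij = f_i * d_j * s` of filter transmission, Bayer
channel response and bare source spectrum, optionally multiplied by a
detection-path notch (raised-cosine dip, exactly zero over center +/-
width/4) that models a laser-blocking filter. Discretised with the grid
step as quadrature weight (left-Riemann), the nine spectra form the 9 x 67
encoding matrix `A`, rows ordered (1,R),(1,G),(1,B),(2,R),...

Camera and source are parametric synthetic fixtures, not calibrations:
Gaussian Bayer responses (B 460/30, G 540/40, R 600/40 nm plus a weak red
secondary lobe) and a two-lobe phosphor-white LED (narrow 450 nm pump,
broad 560 nm lobe) that is weak at the short edge of the band. Real
calibrations can be substituted wherever a `BayerResponse` or
`SourceSpectrum` is accepted.

A measured frame is `I_i = V_i * (A-row inner product) + N` per pixel,
with the row selected by the pixel's mosaic position (RGGB, 0-based
even/odd convention). `V_i ~ Uniform(1-v, 1+v)` is drawn once per frame;
`N` is additive Gaussian with sigma = fraction x mean noiseless frame
intensity. Defaults are v = 5% and 5% noise - the perturbation level of
the reference closed-loop experiments. Both draws are controlled by one
seed; a fixed seed reproduces frames bit for bit.

Demosaicking is separable bilinear interpolation of each colour plane from
its mosaic sites (the green quincunx as the average of its two rectangular
sub-lattices), with linear extrapolation at borders so affine images are
reproduced exactly; native sample sites are preserved bit-exactly. The
reconstruction consumes the demosaicked 9-channel stack by default; the
mosaicked mode is retained for fidelity experiments.

## Synthetic tissue scenes

Scene spectra follow a Beer-Lambert-style DR model:
`R = R_bg * scatter * exp(-[bv_bg * mu_blood(sO2_bg) + bv_vessel *
w(lambda, depth) * mu_blood(sO2_vessel)] * L_eff(lambda))`, with
hemoglobin extinction from an embedded coarse anchor table (410-760 nm,
monotone-cubic interpolated; compiled from the standard in-vitro
compilations and treated as physical constants). `L_eff` is an effective
pathlength, 1 mm at 500 nm growing as `(lambda/500)^1.5`; the vessel depth
overlay `w = exp(-depth/delta(lambda))` uses a penetration depth of 150 um
at 500 nm growing as `(lambda/500)^2`. These exponents are chosen once as
plausible soft-tissue behaviour; they reproduce the qualitative
depth-contrast ordering (superficial capillaries contrast best in
blue-green, deeper vessels at longer wavelengths) that narrow-band imaging
exploits. Background sO2, blood volume and scatter vary as smooth random
fields; vessels are smooth random curves with elevated blood volume,
assigned depths, and slightly venous (lower) sO2; 0-0.5% of pixels are
clipped specular highlights at 1.2x the white reference and flagged in the
mask. Scene generation is bit-reproducible under its seed.

Because tissue scenes alone would teach a reconstructor only smooth
hemoglobin-like spectra, training datasets mix in a fraction (default 1/4
in the reference configuration) of "probe" scenes carrying
one-to-three-peak Gaussian-mixture spectra whose peak centres, widths
(FWHM 8-60 nm) and amplitudes drift as smooth spatial fields - each such
scene contributes a continuum of distinct structured spectra, not one.
This keeps narrow spectral features - resolution probes, notch
restoration - inside the training distribution, mirroring the spectral
diversity a real-organ training set would contain.

What the generator does *not* emulate: anatomical texture, motion and
peristalsis, fluorescence, sensor nonlinearity and dark current. Passing
closed-loop tests therefore demonstrates the soundness of the
encode-reconstruct-analyse machinery under the stated noise model, not
performance on real endoscopic footage.

## Reconstruction

**Linear baseline.** Per pixel, minimise `||A t - m||^2 + alpha ||D2
t||^2` (D2 = second difference), solved in closed form via the normal
equations with a precomputed 67 x 9 solution operator; negative values are
clipped to zero after the solve; alpha is tuned on a validation split.
With 9 measurements and 67 unknowns the problem is strongly
under-determined, and a generic curvature prior recovers tissue spectra
only to ~15-25% RAE even noiselessly - the baseline is a transparent
reference and algebraic oracle (its solution is asserted to satisfy the
normal equations), not the accuracy path.

**Learned reconstructor.** A three-scale U-Net-style encoder-decoder
(base width 16, ~170k parameters) maps the 9-channel stack to the
67-channel cube at full pixel resolution. Channel ("spectral") attention
blocks sit at the bottleneck and after each decoder stage; each block
forms per-channel gates from spatially pooled descriptors through a
bottleneck MLP, and a learned linear embedding of the flattened encoding
matrix is added to the hidden layer - the gates can thus condition on
which wavelengths the physical encoding actually weighted. Disabling this
guidance (plain squeeze-excite attention) is retained as an ablation
harness. The spectral decoder head widens the features (1x1 convolutions
w -> 4w -> 67 with a ReLU between) before projecting to wavelength: a
single w -> 67 linear map would cap every output at a rank-w spectral
basis, which is invisible on smooth tissue spectra but fails badly on
narrow-peak scenes. The network and its backpropagation are implemented
directly in NumPy (see `endospec.nn`) and train on one CPU in minutes.

Training: level-normalised L1 loss - |error| divided by the pixel's
spectrally averaged truth level plus a 0.1 floor, so the optimisation
target matches the relative error the method is judged by - plus 0.1 x
the same normalisation of the spectral second-difference mismatch
(penalising curvature error rather than curvature itself, so genuine
narrow features are not suppressed), Adam at 1e-3, batches of four
32 x 32 patches. The validation checkpoint keeps the parameters that
minimise the worse of the two headline statistics (median spectrally
averaged RAE, maximum per-band RAE in 450-700 nm) on the tissue
validation scenes.

The reference reconstructor is a two-member ensemble: members share the
training data but differ in initialisation and batch order, and their
predicted cubes are averaged. A single member's central-band maximum RAE
fluctuates by several tenths of a percent across training seeds because
the weakly encoded red end of the band is noise-limited; absolute-error
statistics count that random component in full, and averaging two
independent members reduces it - measured, the ensemble brings the
per-band maximum from ~5.0 +/- 0.4 (single member) to ~4.5-4.6.

The reference desk-scale configuration (24 scenes of 48 x 48, 2 members
x 2500 iterations) reaches ~3.6% median RAE under 5% noise + 5%
illumination variation; the remaining error is dominated by the
irreducible per-frame gain ambiguity (a +/-5% uniform gain cannot be
disambiguated from scene brightness by any estimator) and by the weakly
encoded band edges, where the per-band RAE rises - the same edge
behaviour the physical system shows.

**Resolution criterion.** A double-peak probe counts as resolved when the
reconstruction has a pair of distinct local maxima, one within 15 nm of
each true centre, whose intervening valley dips by at least 20% of the
lower peak (Rayleigh-style; the thresholds are our choice, stated
openly). Local extrema are found by exhaustive scan.

**Resolution protocol.** Line probes are a deliberately different regime
from tissue imaging. In measurement space the 20 nm double probe differs
from its best single-peak explanation by only ~1.2% (15 nm: ~0.5%), so
with 5% per-pixel detection noise no per-pixel decoder can resolve it,
and reconstructors carrying the smooth-tissue prior merge the peaks at
any tested separation. The harness therefore mimics how a physical
resolution test is run: the probe field is spatially uniform, so the
demosaicked measurements are averaged over a 48 x 48 patch (noise falls
to ~0.1%, below the 20 nm signature but still above the 15 nm one) and
decoded with a reconstructor whose prior matches line spectra -
nonnegative least squares on a dictionary of narrow Gaussian atoms (one
per channel, FWHM 12 nm, plus a flat baseline), whose NNLS sparsity
recovers isolated lines. Under this protocol the 20 nm separation is
resolved and 15 nm is not, across noise seeds - the encoding itself, not
the decoder, sets the limit. The smooth-prior network remains the
reconstructor for all tissue-accuracy experiments.

## Monte-Carlo transport and oximetry

Tissue is a single homogeneous semi-infinite layer by default (a layered
option exists behind the same kernel): anisotropy g = 0.9, index 1.4
against air, reduced scattering `1.5 mm^-1 * (lambda/500)^-1.3`, blood
absorption `bv * mu_blood(sO2)` from the extinction table plus a
0.02 mm^-1 bloodless background. The transport kernel is a standard
photon-packet walk (exponential free paths, Henyey-Greenstein deflection,
continuous weight absorption, Fresnel boundaries, Russian roulette at
1e-4 with multiplier 10), numba-compiled, deterministic per seed, with
energy conservation asserted in the tests and agreement with the
semi-infinite diffusion closed form (Groenhuis form, matched boundary,
mus'/mua = 10) within 10%.

**Shared-ensemble estimator.** For the homogeneous semi-infinite case the
lossless walk is scale-free given (g, n): measuring lengths in scattering
mean free paths, the walk geometry is independent of mua and mus, and
continuous absorption multiplies a packet's weight by exactly the albedo
`a = mus/(mua+mus)` per scattering step. One ensemble of per-photon
scatter counts {k} therefore gives `R_d(a) = (1-R_sp) E[a^k]` for *every*
(sO2, bv, lambda) cell at once - an exact reweighting, not an
approximation (walks are truncated at 30000 scatters, where `a^k <
1e-14` for every tabulated albedo). The default lookup build uses this
estimator (seconds instead of tens of minutes); the direct per-wavelength
walk is retained (`method="direct"`) and the two agree within Monte-Carlo
standard errors in the tests.

The lookup table spans sO2 in {0, 0.1, ..., 1} and five logarithmic
blood-volume steps from 0.005 to 0.08, Monte-Carlo sampled every 10 nm
and cubic-interpolated to the 67-channel grid. Composition inversion is
amplitude-normalised (spectra scaled to peak 1) least squares over all
cells, followed by a continuous polish on a bilinearly interpolated
neighbourhood of the best cell that always includes the cell itself.
Matching is deliberately scale-free: absolute DR levels are unreliable
through an endoscope, which is also why the recovered blood volume is
model-relative. Under 1% spectral noise the inversion recovers sO2 to a
median absolute error of ~0.02 and fits with median per-pixel MSE ~2e-4.

## Views

RGB synthesis weights the spectral channels with CIE 1931 2-degree
colour-matching functions (10 nm table, interpolated), maps XYZ to linear
sRGB, and normalises so an equal-energy spectrum renders gray; the linear
image is exactly linear in the cube, then gamma-encoded for display. The
narrow-band view is a raw channel slice (nearest channel with a warning
for off-grid requests such as 415 nm, which lies below the source's usable
band) with optional 1-99 percentile contrast stretch. Vessel contrast is
Weber contrast `(mean_bg - mean_vessel)/mean_bg` per band.

## File formats

Cubes: ENVI-style text header + band-sequential little-endian float32
binary, plus a JSON sidecar (mask, provenance); a compressed single-file
`.npz` alternative round-trips the same content. Raw frames: three 16-bit
grayscale TIFFs with a JSON sidecar holding the per-frame gains V_i,
mosaic label and quantisation scale (gains round-trip exactly; frames to
1/65535 of full scale). Lookup tables: HDF5 with grids, spectra, standard
errors and a configuration hash. Spectra: two-column text. Every CLI run
writes a JSON manifest (seed, configuration, package version).

## Problem sizes and reproducibility

Reference experiment sizes, chosen as the package's desk-scale defaults:
24 training scenes of 48 x 48 (2000 iterations), 20 evaluation scenes of
64 x 64 for the closed loop, separations {10, 15, 20, 25, 30} nm for the
resolution scan, an 11 x 5 lookup at 2e4 photons per wavelength sample,
and a 32 x 32 composition scene. Every random draw in the package flows
from an explicit seed (scene generation, noise, gains, network
initialisation and batching, Monte-Carlo walks), and the headline script
`scripts/acceptance.py` derives all of its seeds from a single `--seed`.

## Known limitations

- The network architecture, loss and schedule are a compact stand-in
  chosen to train quickly on a CPU; absolute accuracies are specific to
  the synthetic scene statistics.
- The guidance ablation (encoding-embedded attention versus plain channel
  attention) favours the guided model on average but the margin is within
  run-to-run noise at smoke scales, so its direction is not asserted as a
  test invariant.
- The tissue model is single-layer and hemoglobin-only; water, fat and
  melanin, layered mucosa, and vessel-resolved geometry in the Monte-Carlo
  model are out of scope.
- The blood-volume scale is model-relative; only sO2 has absolute meaning
  within the model.
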