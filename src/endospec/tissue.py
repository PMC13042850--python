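"""Synthetic vascularised-tissue scenes and probe spectra.

The generator emulates the statistical structure of endoscopic
diffuse-reflectance scenes: hemoglobin-dominated, spectrally smooth pixel
spectra; curvilinear vessels with elevated blood volume at assigned depths
(deeper vessels lose short-wavelength contrast because short wavelengths do
not penetrate to them); sparse clipped specular highlights; and an optional
laser-notch in the detection path handled downstream by the encoding.

The per-pixel spectrum model is a Beer-Lambert-style diffuse reflectance

    R(lambda) = R_bg * exp(-[bv_bg * mu_mix(sO2_bg) +
                             bv_vessel * w(lambda, depth) * mu_mix(sO2_v)]
                            * L_eff(lambda))

with mu_mix the whole-blood absorption at the pixel's oxygen saturation,
L_eff an effective photon pathlength growing with wavelength, and
w(lambda, depth) = exp(-depth / delta(lambda)) the depth overlay built from
a penetration depth delta increasing with wavelength.  The Monte-Carlo
lookup table (``endospec.mc``) anchors absolute accuracy; this fast path is
what makes dataset generation tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .encoding import EncodingSet, NoiseModel, RawFrameSet, demosaic, encode
from .errors import ValidationError
from .hemoglobin import blood_absorption_mm
from .spectra import HSICube, SpectralGrid, Spectrum

#: Spectrally flat background reflectance at unit scatter scale.
BACKGROUND_REFLECTANCE = 0.75

#: Effective pathlength at 500 nm (mm) and its wavelength power law.
PATHLENGTH_500NM_MM = 1.0
PATHLENGTH_POWER = 1.5

#: Penetration depth at 500 nm (um) for the vessel-depth overlay.
PENETRATION_500NM_UM = 150.0
PENETRATION_POWER = 2.0

#: Specular highlights clip at this multiple of the white reference.
SPECULAR_CLIP = 1.2


def _pathlength_mm(lam_nm: np.ndarray) -> np.ndarray:
    return PATHLENGTH_500NM_MM * (lam_nm / 500.0) ** PATHLENGTH_POWER


def _penetration_um(lam_nm: np.ndarray) -> np.ndarray:
    return PENETRATION_500NM_UM * (lam_nm / 500.0) ** PENETRATION_POWER


def depth_overlay_weight(grid: SpectralGrid, depth_um: np.ndarray) -> np.ndarray:
    """w(lambda, depth) = exp(-depth/delta(lambda)): how much an absorber at
    ``depth_um`` still shapes the surface reflectance, per wavelength."""
    depth = np.asarray(depth_um, float)
    return np.exp(-depth[..., None] / _penetration_um(grid.values))


def synth_dr_spectrum(
    so2: float,
    bv: float,
    scatter_scale: float = 1.0,
    depth_um: float | None = None,
    grid: SpectralGrid | None = None,
    table=None,
) -> Spectrum:
    """Diffuse-reflectance spectrum of homogeneous tissue.

    ``so2`` in [0, 1]; ``bv`` is the blood-volume fraction (>= 0);
    ``scatter_scale`` scales the flat background reflectance; ``depth_um``
    optionally applies the depth overlay to the blood term.  When a
    Monte-Carlo lookup table is supplied the spectrum is interpolated from
    it instead of using the analytic fast path.
    """
    if not 0 <= so2 <= 1:
        raise ValidationError("sO2 must lie in [0, 1]")
    if bv < 0:
        raise ValidationError("blood volume fraction must be >= 0")
    if table is not None:
        return Spectrum(table.grid, table.interpolate(so2, bv))
    grid = grid or SpectralGrid()
    lam = grid.values
    mua = blood_absorption_mm(so2, grid)  # mm^-1 whole blood
    weight = 1.0 if depth_um is None else depth_overlay_weight(grid, depth_um)
    r = BACKGROUND_REFLECTANCE * scatter_scale * np.exp(
        -bv * weight * mua * _pathlength_mm(lam)
    )
    return Spectrum(grid, np.clip(np.atleast_1d(np.squeeze(r)), 0.0, 1.0))


@dataclass
class SceneConfig:
    """Parameters of a synthetic endoscopic scene."""

    height: int = 64
    width: int = 64
    n_vessels: int = 3
    vessel_width_px: tuple[float, float] = (1.5, 4.0)
    vessel_depth_um: tuple[float, float] = (0.0, 400.0)
    vessel_bv: tuple[float, float] = (0.05, 0.15)
    background_so2: tuple[float, float] = (0.5, 0.95)
    background_bv: tuple[float, float] = (0.005, 0.03)
    specular_density: float = 0.002
    scatter_scale: tuple[float, float] = (0.85, 1.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 4 or self.width < 4:
            raise ValidationError("scene must be at least 4x4 pixels")
        if self.vessel_width_px[0] < 0.5:
            raise ValidationError("vessel width must be >= 0.5 px")
        if not 0 <= self.specular_density <= 1:
            raise ValidationError("specular density is a probability")


@dataclass
class TissueScene:
    """A synthetic scene: cube plus the parameter maps that generated it."""

    cube: HSICube
    so2: np.ndarray
    bv: np.ndarray
    vessel_bv: np.ndarray
    vessel_depth_um: np.ndarray
    specular_mask: np.ndarray
    seed: int = 0


def _smooth_field(
    rng: np.random.Generator, shape: tuple, lo: float, hi: float, sigma: float = 8.0
) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    f = (f - f.min()) / max(f.max() - f.min(), 1e-12)
    return lo + (hi - lo) * f


def _draw_vessel(
    rng: np.random.Generator, shape: tuple, width_px: float
) -> np.ndarray:
    """Soft indicator (0..1) of one smooth curvilinear vessel."""
    h, w = shape
    n_pts = max(h, w) * 4
    t = np.linspace(0, 1, n_pts)
    # random smooth path: line across the image + low-order sinusoidal wiggle
    theta = rng.uniform(0, np.pi)
    cx, cy = rng.uniform(0.2, 0.8, 2)
    span = 1.5 * max(h, w)
    x = cx * w + np.cos(theta) * (t - 0.5) * span
    y = cy * h + np.sin(theta) * (t - 0.5) * span
    for _ in range(2):
        a = rng.uniform(2, 10)
        f = rng.uniform(1, 3)
        ph = rng.uniform(0, 2 * np.pi)
        x += a * np.sin(2 * np.pi * f * t + ph) * abs(np.sin(theta))
        y += a * np.sin(2 * np.pi * f * t + ph + 1.0) * abs(np.cos(theta))
    canvas = np.zeros(shape)
    xi = np.round(x).astype(int)
    yi = np.round(y).astype(int)
    ok = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
    canvas[yi[ok], xi[ok]] = 1.0
    # dilate the centreline into a soft tube of the requested width
    soft = gaussian_filter(canvas, width_px / 2.0, mode="constant")
    if soft.max() > 0:
        soft = np.clip(soft / soft.max(), 0, 1)
    return soft


def synth_scene(config: SceneConfig) -> TissueScene:
    """Generate a synthetic vascularised scene; deterministic under seed."""
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    grid = SpectralGrid()
    lam = grid.values

    so2_map = _smooth_field(rng, (h, w), *config.background_so2)
    bv_map = _smooth_field(rng, (h, w), *config.background_bv)
    scatter = _smooth_field(rng, (h, w), *config.scatter_scale, sigma=12.0)

    vessel_bv = np.zeros((h, w))
    depth_map = np.zeros((h, w))
    for _ in range(config.n_vessels):
        width_px = rng.uniform(*config.vessel_width_px)
        depth = rng.uniform(*config.vessel_depth_um)
        amp = rng.uniform(*config.vessel_bv)
        tube = _draw_vessel(rng, (h, w), width_px)
        sel = tube > vessel_bv / max(amp, 1e-12)
        vessel_bv = np.where(sel, amp * tube, vessel_bv)
        depth_map = np.where(sel & (tube > 0.05), depth, depth_map)

    # vessels are mostly venous; slightly lower sO2 than background
    vessel_so2 = np.clip(so2_map - 0.15, 0, 1)

    mua_bg = blood_absorption_mm(so2_map, grid)       # (h, w, C)
    mua_vessel = blood_absorption_mm(vessel_so2, grid)
    overlay = depth_overlay_weight(grid, depth_map)   # (h, w, C)
    leff = _pathlength_mm(lam)
    att = (bv_map[..., None] * mua_bg
           + vessel_bv[..., None] * overlay * mua_vessel) * leff
    cube_data = BACKGROUND_REFLECTANCE * scatter[..., None] * np.exp(-att)

    specular = rng.random((h, w)) < config.specular_density
    cube_data[specular] = SPECULAR_CLIP
    cube_data = np.clip(cube_data, 0.0, SPECULAR_CLIP)

    cube = HSICube(
        grid, cube_data, mask=specular.copy(),
        meta={"seed": config.seed, "source": "synth_scene"},
    )
    return TissueScene(
        cube, so2_map, bv_map, vessel_bv, depth_map, specular, config.seed
    )


def probe_spectrum(
    kind: str,
    center_nm: float = 550.0,
    separation_nm: float = 20.0,
    fwhm_nm: float = 10.0,
    grid: SpectralGrid | None = None,
    baseline: float = 0.02,
) -> Spectrum:
    """Gaussian probe spectra for spectral-resolution testing.

    ``kind`` is 'single' (one peak at ``center_nm``) or 'double' (two equal
    peaks straddling ``center_nm`` with the given peak-to-peak separation).
    Peaks have unit amplitude above a low flat baseline.
    """
    grid = grid or SpectralGrid()
    if kind not in ("single", "double"):
        raise ValidationError("kind must be 'single' or 'double'")
    if fwhm_nm < grid.step:
        raise ValidationError("fwhm must be at least one grid step")
    lam = grid.values
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if kind == "single":
        centers = [center_nm]
    else:
        if separation_nm < grid.step:
            raise ValidationError("separation must be at least one grid step")
        centers = [center_nm - separation_nm / 2, center_nm + separation_nm / 2]
    for c in centers:
        if not grid.lambda_min <= c <= grid.lambda_max:
            raise ValidationError("peak centre outside the grid")
    y = np.full_like(lam, baseline)
    for c in centers:
        y = np.maximum(y, baseline + np.exp(-0.5 * ((lam - c) / sigma) ** 2))
    return Spectrum(grid, y, name=f"probe-{kind}")


def synth_probe_scene(
    seed: int, height: int = 64, width: int = 64, grid: SpectralGrid | None = None
) -> TissueScene:
    """Scene of randomly structured (peaky) spectra for training.

    Each scene carries a random Gaussian-mixture spectrum (one to three
    peaks, FWHM 10-60 nm, random centres) on a low baseline, modulated by
    a smooth spatial amplitude field.  Tissue scenes alone teach a
    reconstructor only smooth hemoglobin-like spectra; mixing these scenes
    in keeps narrow spectral features (e.g. resolution probes, notch
    restoration) inside the training distribution.
    """
    grid = grid or SpectralGrid()
    rng = np.random.default_rng(seed)
    lam = grid.values
    shape = (height, width)
    n_peaks = int(rng.integers(1, 4))
    # smooth spatial drift of every peak parameter: each scene then carries
    # a continuum of distinct spectra, not a single one
    y = _smooth_field(rng, shape, 0.01, 0.1)[..., None] * np.ones(grid.n)
    for _ in range(n_peaks):
        c0 = rng.uniform(grid.lambda_min + 15, grid.lambda_max - 15)
        centers = np.clip(
            c0 + _smooth_field(rng, shape, -40.0, 40.0),
            grid.lambda_min + 5, grid.lambda_max - 5,
        )
        fwhm = _smooth_field(rng, shape, 8.0, 60.0)
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        amp = _smooth_field(rng, shape, 0.1, 0.9)
        y += amp[..., None] * np.exp(
            -0.5 * ((lam[None, None, :] - centers[..., None]) / sigma[..., None]) ** 2
        )
    cube = HSICube(
        grid, np.clip(y, 0.0, 1.0),
        meta={"seed": seed, "source": "synth_probe_scene"},
    )
    zeros = np.zeros((height, width))
    return TissueScene(cube, zeros, zeros, zeros, zeros, zeros.astype(bool), seed)


@dataclass
class SpectralDataset:
    """Paired (measurement, truth) samples for training/validating a
    reconstructor, with the randomness actually used recorded."""

    stacks: list          # (H, W, 9) demosaicked stacks (or RawFrameSet)
    cubes: list[HSICube]  # ground truth
    masks: list[np.ndarray]
    train_idx: np.ndarray
    val_idx: np.ndarray
    manifest: list[dict] = field(default_factory=list)
    encoding_id: str = ""


def synth_dataset(
    n_scenes: int,
    scene_config: SceneConfig,
    enc: EncodingSet,
    noise: NoiseModel,
    seed: int = 0,
    val_fraction: float = 0.25,
    demosaicked: bool = True,
    probe_fraction: float = 0.0,
) -> SpectralDataset:
    """Generate paired encoded measurements and ground-truth cubes.

    Each scene gets a fresh generation seed and fresh V_i / noise draws,
    all derived deterministically from ``seed``.  The train/validation
    split is recorded in the returned dataset.  ``probe_fraction`` of the
    scenes (rounded down, taken at regular intervals) are spectrally
    structured :func:`synth_probe_scene` scenes instead of tissue scenes.
    """
    if n_scenes < 2:
        raise ValidationError("need at least 2 scenes to split train/val")
    ss = np.random.SeedSequence(seed)
    scene_seeds, noise_seeds = ss.spawn(2)
    scene_s = scene_seeds.generate_state(n_scenes) % (2**31)
    noise_s = noise_seeds.generate_state(n_scenes) % (2**31)
    n_probe = int(probe_fraction * n_scenes)
    probe_ids = set(
        np.linspace(0, n_scenes - 1, n_probe).astype(int).tolist()
    ) if n_probe else set()
    stacks, cubes, masks, manifest = [], [], [], []
    for k in range(n_scenes):
        if k in probe_ids:
            scene = synth_probe_scene(
                int(scene_s[k]), scene_config.height, scene_config.width
            )
        else:
            cfg_k = SceneConfig(**{**scene_config.__dict__, "seed": int(scene_s[k])})
            scene = synth_scene(cfg_k)
        noise_k = NoiseModel(
            noise.noise_fraction, noise.illumination_variation, int(noise_s[k])
        )
        raw = encode(scene.cube, enc, noise_k)
        stacks.append(demosaic(raw, enc) if demosaicked else raw)
        cubes.append(scene.cube)
        masks.append(scene.specular_mask)
        manifest.append(
            {
                "scene_seed": int(scene_s[k]),
                "noise_seed": int(noise_s[k]),
                "kind": "probe" if k in probe_ids else "tissue",
                "v_values": raw.v_values.tolist(),
                "noise_fraction": noise.noise_fraction,
                "illumination_variation": noise.illumination_variation,
            }
        )
    n_val = max(1, int(round(val_fraction * n_scenes)))
    idx = np.arange(n_scenes)
    val_idx = idx[-n_val:]
    train_idx = idx[:-n_val]
    return SpectralDataset(
        stacks, cubes, masks, train_idx, val_idx, manifest, enc.encoding_id
    )
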