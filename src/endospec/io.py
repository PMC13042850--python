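"""File formats: hyperspectral cubes, raw frame sets, spectra, lookup
tables, stack definitions and run manifests.

Cubes are stored ENVI-style - a human-readable text header (``.hdr``) next
to a band-sequential little-endian float32 binary (``.raw``) - plus a JSON
sidecar carrying the overexposure mask and provenance.  A single-file
compressed ``.npz`` alternative round-trips the same content.  Raw frames
go to 16-bit grayscale TIFFs with a JSON sidecar holding the per-frame
gains V_i, seeds and quantisation scale.  Lookup tables use HDF5.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .encoding import RawFrameSet
from .errors import ValidationError
from .mc import MCLookupTable
from .spectra import HSICube, SpectralGrid, Spectrum
from . import thinfilm


class CubeFormatError(ValidationError):
    """Malformed cube container."""


# -- spectra as two-column text ---------------------------------------------

def save_spectrum_txt(spectrum: Spectrum, path: str | Path) -> None:
    """Two-column text: wavelength_nm, value."""
    np.savetxt(
        path,
        np.column_stack([spectrum.grid.values, spectrum.intensity]),
        header="wavelength_nm value",
    )


def load_spectrum_txt(path: str | Path) -> Spectrum:
    data = np.loadtxt(path)
    lam = data[:, 0]
    step = np.diff(lam)
    if not np.allclose(step, step[0]):
        raise CubeFormatError(f"{path}: non-uniform wavelength column")
    grid = SpectralGrid(float(lam[0]), float(lam[-1]), float(step[0]))
    return Spectrum(grid, data[:, 1])


# -- ENVI-style cube container ----------------------------------------------

def save_cube_envi(cube: HSICube, stem: str | Path) -> None:
    """Write ``stem.hdr`` + ``stem.raw`` (+ ``stem.json`` sidecar).

    Band-sequential (BSQ) little-endian float32, ENVI data type 4.
    """
    stem = Path(stem)
    h, w, c = cube.data.shape
    wavelengths = ", ".join(f"{v:g}" for v in cube.grid.values)
    header = (
        "ENVI\n"
        "description = {hyperspectral reflectance cube}\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {c}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wavelengths}}}\n"
    )
    stem.with_suffix(".hdr").write_text(header)
    # BSQ: band-major
    cube.data.transpose(2, 0, 1).astype("<f4").tofile(stem.with_suffix(".raw"))
    sidecar = {
        "mask": np.flatnonzero(cube.mask.ravel()).tolist(),
        "meta": cube.meta,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar))


def _parse_envi_header(path: Path) -> dict:
    text = path.read_text()
    if not text.lstrip().startswith("ENVI"):
        raise CubeFormatError(f"{path}: missing ENVI magic line")
    fields: dict = {}
    key, buf, in_braces = None, "", False
    for lineno, line in enumerate(text.splitlines()[1:], start=2):
        if in_braces:
            buf += " " + line
            if "}" in line:
                fields[key] = buf.split("{", 1)[1].rsplit("}", 1)[0].strip()
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{") and "}" not in val:
            buf = val
            in_braces = True
        elif val.startswith("{"):
            fields[key] = val[1:].rsplit("}", 1)[0].strip()
        else:
            fields[key] = val
    if in_braces:
        raise CubeFormatError(f"{path}: unterminated brace for '{key}'")
    return fields


def load_cube_envi(stem: str | Path) -> HSICube:
    stem = Path(stem)
    hdr = _parse_envi_header(stem.with_suffix(".hdr"))
    for required in ("samples", "lines", "bands", "interleave", "data type"):
        if required not in hdr:
            raise CubeFormatError(f"{stem}.hdr: missing field '{required}'")
    if "wavelength" not in hdr:
        raise CubeFormatError(
            f"{stem}.hdr: missing wavelength metadata; refusing to guess a grid"
        )
    if hdr["interleave"].lower() != "bsq":
        raise CubeFormatError(f"{stem}.hdr: only BSQ interleave supported")
    if hdr["data type"] != "4":
        raise CubeFormatError(f"{stem}.hdr: only float32 (data type 4) supported")
    w, h, c = int(hdr["samples"]), int(hdr["lines"]), int(hdr["bands"])
    lam = np.array([float(v) for v in hdr["wavelength"].split(",")])
    if len(lam) != c:
        raise CubeFormatError(f"{stem}.hdr: {len(lam)} wavelengths for {c} bands")
    step = np.diff(lam)
    if len(lam) < 2 or not np.allclose(step, step[0]):
        raise CubeFormatError(f"{stem}.hdr: non-uniform wavelength axis")
    grid = SpectralGrid(float(lam[0]), float(lam[-1]), float(step[0]))
    data = np.fromfile(stem.with_suffix(".raw"), dtype="<f4")
    if data.size != h * w * c:
        raise CubeFormatError(
            f"{stem}.raw: {data.size} values, expected {h * w * c}"
        )
    cube_data = data.reshape(c, h, w).transpose(1, 2, 0).astype(float)
    mask = np.zeros((h, w), bool)
    meta: dict = {}
    sidecar_path = stem.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        flat = np.zeros(h * w, bool)
        flat[np.asarray(sidecar.get("mask", []), int)] = True
        mask = flat.reshape(h, w)
        meta = sidecar.get("meta", {})
    return HSICube(grid, cube_data, mask=mask, meta=meta)


def save_cube_npz(cube: HSICube, path: str | Path) -> None:
    """Single-file compressed alternative container."""
    np.savez_compressed(
        path,
        data=cube.data,
        wavelengths=cube.grid.values,
        mask=cube.mask,
        meta=json.dumps(cube.meta),
    )


def load_cube_npz(path: str | Path) -> HSICube:
    with np.load(path, allow_pickle=False) as z:
        if "wavelengths" not in z:
            raise CubeFormatError(f"{path}: missing wavelength metadata")
        lam = z["wavelengths"]
        grid = SpectralGrid(float(lam[0]), float(lam[-1]), float(lam[1] - lam[0]))
        return HSICube(
            grid, z["data"], mask=z["mask"], meta=json.loads(str(z["meta"]))
        )


# -- raw frame sets ----------------------------------------------------------

def save_frames(raw: RawFrameSet, stem: str | Path) -> None:
    """Three 16-bit grayscale TIFFs plus a JSON sidecar.

    Frames are quantised to the uint16 range with a common scale recorded
    in the sidecar; V_i, the mosaic label and all metadata round-trip
    exactly.
    """
    stem = Path(stem)
    peak = float(raw.frames.max())
    scale = peak / 65535.0 if peak > 0 else 1.0
    for i in range(3):
        q = np.clip(np.round(raw.frames[i] / scale), 0, 65535).astype(np.uint16)
        tifffile.imwrite(f"{stem}_frame{i + 1}.tif", q)
    sidecar = {
        "v_values": raw.v_values.tolist(),
        "pattern": raw.pattern,
        "encoding_id": raw.encoding_id,
        "scale": scale,
        "meta": raw.meta,
    }
    Path(f"{stem}_frames.json").write_text(json.dumps(sidecar))


def load_frames(stem: str | Path) -> RawFrameSet:
    stem = Path(stem)
    sidecar = json.loads(Path(f"{stem}_frames.json").read_text())
    frames = np.stack(
        [
            tifffile.imread(f"{stem}_frame{i + 1}.tif").astype(float)
            * sidecar["scale"]
            for i in range(3)
        ]
    )
    return RawFrameSet(
        frames,
        np.asarray(sidecar["v_values"]),
        pattern=sidecar["pattern"],
        encoding_id=sidecar["encoding_id"],
        meta=sidecar.get("meta", {}),
    )


# -- Monte-Carlo lookup tables ----------------------------------------------

def save_lookup(table: MCLookupTable, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("so2_grid", data=table.so2_grid)
        f.create_dataset("bv_grid", data=table.bv_grid)
        f.create_dataset("wavelengths", data=table.grid.values)
        f.create_dataset("spectra", data=table.spectra)
        f.create_dataset("stderr", data=table.stderr)
        f.attrs["config_hash"] = table.config_hash
        f.attrs["meta"] = json.dumps(table.meta)


def load_lookup(path: str | Path) -> MCLookupTable:
    with h5py.File(path, "r") as f:
        lam = f["wavelengths"][:]
        grid = SpectralGrid(float(lam[0]), float(lam[-1]), float(lam[1] - lam[0]))
        return MCLookupTable(
            f["so2_grid"][:],
            f["bv_grid"][:],
            grid,
            f["spectra"][:],
            f["stderr"][:],
            config_hash=str(f.attrs["config_hash"]),
            meta=json.loads(str(f.attrs["meta"])),
        )


# -- layer stacks from YAML --------------------------------------------------

_MATERIALS = {
    "TiO2": thinfilm.tio2_rutile,
    "SiO2": thinfilm.sio2_malitson,
    "air": lambda: thinfilm.AIR,
}


def load_stack_yaml(path: str | Path) -> thinfilm.LayerStack:
    """Stack definition: materials by name or constant index.

    Example::

        incident: air
        substrate: SiO2
        layers:
          - {material: TiO2, thickness_nm: 60}
          - {material: {name: custom, n: 2.0}, thickness_nm: 100}
    """
    spec = yaml.safe_load(Path(path).read_text())

    def material(m):
        if isinstance(m, str):
            if m not in _MATERIALS:
                raise ValidationError(f"unknown material {m!r}")
            return _MATERIALS[m]()
        return thinfilm.constant_index(m["name"], float(m["n"]))

    layers = [
        (material(entry["material"]), float(entry["thickness_nm"]))
        for entry in spec.get("layers", [])
    ]
    return thinfilm.LayerStack(
        layers,
        incident=material(spec.get("incident", "air")),
        substrate=material(spec.get("substrate", "SiO2")),
    )


def write_manifest(path: str | Path, **entries) -> None:
    """JSON run manifest (seeds, config hashes, package version)."""
    from . import __version__

    payload = {"package_version": __version__, **entries}
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
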