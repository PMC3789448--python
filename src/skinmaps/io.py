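"""File formats: spectra CSV, ENVI cubes, TIFF stacks, maps and matrices.

Cubes go to ENVI (text header + band-sequential float32 raw, wavelengths in
the header) or to multi-page TIFF with a JSON wavelength sidecar. Raw and
corrected monoband stacks are multi-page TIFF with a JSON band-metadata
sidecar. Parameter maps export as one float TIFF per parameter plus a CSV
summary. The coefficient matrix is a CSV matrix with JSON metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .grids import SpectralGrid, Spectrum
from .reconstruction import CoefficientMatrix, ReflectanceCube

__all__ = [
    "write_spectrum_csv",
    "read_spectrum_csv",
    "envi_write",
    "envi_read",
    "write_cube_tiff",
    "read_cube_tiff",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_parameter_maps",
    "save_coefficient_matrix",
    "load_coefficient_matrix",
]


def write_spectrum_csv(spec: Spectrum, path) -> None:
    arr = np.column_stack([spec.grid.wavelengths, spec.values])
    np.savetxt(path, arr, delimiter=",", header="wavelength_nm,reflectance", comments="", fmt="%.8g")


def read_spectrum_csv(path) -> Spectrum:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    return Spectrum(grid=SpectralGrid(data[:, 0]), values=data[:, 1])


def envi_write(cube: ReflectanceCube, basepath) -> tuple[Path, Path]:
    """Write a cube as ENVI: <base>.hdr text header + <base>.img float32 BSQ."""
    base = Path(basepath)
    hdr, img = base.with_suffix(".hdr"), base.with_suffix(".img")
    h, w, nb = cube.data.shape
    wl = ", ".join(f"{v:g}" for v in cube.grid.wavelengths)
    header = (
        "ENVI\n"
        "description = {skin reflectance cube}\n"
        f"samples = {w}\nlines = {h}\nbands = {nb}\n"
        "header offset = 0\nfile type = ENVI Standard\n"
        "data type = 4\ninterleave = bsq\nbyte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr.write_text(header)
    np.transpose(cube.data, (2, 0, 1)).astype("<f4").tofile(img)
    return hdr, img


def _parse_envi_header(text: str) -> dict:
    fields: dict = {}
    # join brace-delimited multi-line values first
    text = text.replace("\r", "")
    merged, buf = [], ""
    for line in text.splitlines():
        buf = f"{buf} {line}".strip() if buf else line
        if buf.count("{") > buf.count("}"):
            continue
        merged.append(buf)
        buf = ""
    for line in merged:
        if "=" not in line:
            continue
        key, val = (part.strip() for part in line.split("=", 1))
        fields[key.lower()] = val
    return fields


def envi_read(basepath) -> ReflectanceCube:
    base = Path(basepath)
    hdr = base if base.suffix == ".hdr" else base.with_suffix(".hdr")
    fields = _parse_envi_header(hdr.read_text())
    if fields.get("interleave", "bsq").lower() != "bsq" or int(fields.get("data type", 4)) != 4:
        raise ValueError("only float32 BSQ ENVI files are supported")
    w, h, nb = (int(fields[k]) for k in ("samples", "lines", "bands"))
    wl = [float(v) for v in fields["wavelength"].strip("{} ").split(",")]
    data = np.fromfile(hdr.with_suffix(".img"), dtype="<f4").reshape(nb, h, w)
    return ReflectanceCube(data=np.transpose(data, (1, 2, 0)).astype(float), grid=SpectralGrid(np.array(wl)))


def write_cube_tiff(cube: ReflectanceCube, path) -> None:
    """Multi-page float32 TIFF (one page per band) + JSON wavelength sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.transpose(cube.data, (2, 0, 1)).astype(np.float32))
    sidecar = {"wavelengths_nm": list(map(float, cube.grid.wavelengths)), "meta": cube.meta}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_cube_tiff(path) -> ReflectanceCube:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    grid = SpectralGrid(np.array(sidecar["wavelengths_nm"]))
    return ReflectanceCube(data=np.transpose(data, (1, 2, 0)), grid=grid, meta=sidecar.get("meta", {}))


def write_stack_tiff(stack: np.ndarray, path, band_centres=None, **meta) -> None:
    """(h, w, bands) stack as multi-page TIFF, band metadata in a JSON sidecar."""
    path = Path(path)
    stack = np.asarray(stack)
    tifffile.imwrite(path, np.transpose(stack, (2, 0, 1)))
    sidecar = dict(meta)
    if band_centres is not None:
        sidecar["band_centres_nm"] = list(map(float, band_centres))
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_stack_tiff(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    stack = tifffile.imread(path)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return np.transpose(stack, (1, 2, 0)), meta


def write_parameter_maps(maps, outdir) -> Path:
    """One float32 TIFF per parameter (percent/mm units) plus a CSV summary."""
    from .maps import ParameterMaps  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assert isinstance(maps, ParameterMaps)
    for name in maps.data:
        tifffile.imwrite(outdir / f"{name}.tif", maps.as_percent(name).astype(np.float32))
    tifffile.imwrite(outdir / "fitness.tif", maps.fitness.astype(np.float32))
    tifffile.imwrite(outdir / "mask.tif", maps.mask.astype(np.uint8))
    summary = outdir / "summary.csv"
    maps.summary().to_csv(summary, index=False)
    return summary


def save_coefficient_matrix(W: CoefficientMatrix, path) -> None:
    path = Path(path)
    np.savetxt(path, W.weights, delimiter=",", fmt="%.12g")
    meta = {
        "wavelengths_nm": list(map(float, W.grid.wavelengths)),
        "training_rmse": W.training_rmse,
        "epochs": W.epochs,
        "ridge": W.ridge,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_coefficient_matrix(path) -> CoefficientMatrix:
    path = Path(path)
    weights = np.loadtxt(path, delimiter=",")
    meta = json.loads(path.with_suffix(".json").read_text())
    return CoefficientMatrix(
        weights=weights,
        grid=SpectralGrid(np.array(meta["wavelengths_nm"])),
        training_rmse=float(meta.get("training_rmse", float("nan"))),
        epochs=int(meta.get("epochs", 0)),
        ridge=float(meta.get("ridge", 0.0)),
    )
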