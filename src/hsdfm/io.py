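"""Raster I/O: ENVI (binary + text header) and multi-page TIFF with sidecar.

ENVI cubes are written band-sequential (BSQ) with the wavelength list and
"wavelength units = nm" recorded in the header; BSQ, BIL and BIP interleaves
are read.  Exposure times, when present, are stored under a custom
``exposure times`` header key so a HyperCube round-trips through the format.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from hsdfm.datacube import (
    ConfigurationError,
    HyperCube,
    ReflectanceCube,
    WavelengthGrid,
)

# ENVI numeric data-type codes
_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def _format_list(values) -> str:
    return "{ " + ", ".join(f"{v:g}" for v in values) + " }"


def write_envi(
    path: str | Path,
    values: np.ndarray,
    grid: WavelengthGrid,
    exposure: np.ndarray | None = None,
    description: str = "hsdfm data cube",
) -> Path:
    """Write a (rows, cols, bands) raster as ENVI BSQ; header goes to path + '.hdr'."""
    path = Path(path)
    values = np.ascontiguousarray(np.asarray(values, dtype=np.float64))
    if values.ndim != 3 or values.shape[2] != grid.n_bands:
        raise ConfigurationError("raster shape inconsistent with grid")
    rows, cols, bands = values.shape
    lines = [
        "ENVI",
        f"description = {{ {description} }}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_CODES[values.dtype]}",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = nm",
        f"fwhm = {_format_list([grid.bandwidth] * bands)}",
        f"wavelength = {_format_list(grid.wavelengths)}",
    ]
    if exposure is not None:
        lines.append(f"exposure times = {_format_list(exposure)}")
    Path(str(path) + ".hdr").write_text("\n".join(lines) + "\n")
    values.transpose(2, 0, 1).tofile(path)  # BSQ: band, line, sample
    return path


def _parse_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key, buf, in_braces = None, [], False
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.upper() == "ENVI":
            continue
        if not in_braces:
            if "=" not in line:
                continue
            key, _, rest = line.partition("=")
            key = key.strip().lower()
            rest = rest.strip()
            if rest.startswith("{") and "}" not in rest:
                in_braces, buf = True, [rest]
            else:
                fields[key] = rest
        else:
            buf.append(line)
            if "}" in line:
                in_braces = False
                fields[key] = " ".join(buf)
    return fields


def _parse_list(value: str) -> np.ndarray:
    inner = value.strip().lstrip("{").rstrip("}")
    return np.array([float(v) for v in inner.replace(",", " ").split()])


def read_envi(path: str | Path) -> tuple[np.ndarray, WavelengthGrid, np.ndarray | None]:
    """Read an ENVI raster; returns (values (rows, cols, bands), grid, exposure)."""
    path = Path(path)
    hdr_path = Path(str(path) + ".hdr")
    if not hdr_path.exists():
        hdr_path = path.with_suffix(".hdr")
    fields = _parse_header(hdr_path.read_text())
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    dtype = _DTYPES[int(fields["data type"])]
    interleave = fields.get("interleave", "bsq").lower()
    offset = int(fields.get("header offset", 0))
    raw = np.fromfile(path, dtype=dtype, offset=offset, count=rows * cols * bands)
    if interleave == "bsq":
        values = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        values = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bip":
        values = raw.reshape(rows, cols, bands)
    else:
        raise ConfigurationError(f"unsupported interleave {interleave!r}")
    wavelengths = _parse_list(fields["wavelength"])
    fwhm = _parse_list(fields["fwhm"]) if "fwhm" in fields else None
    bandwidth = float(fwhm[0]) if fwhm is not None and fwhm.size else 8.0
    grid = WavelengthGrid(wavelengths, bandwidth=bandwidth)
    exposure = _parse_list(fields["exposure times"]) if "exposure times" in fields else None
    return values.astype(np.float64), grid, exposure


def write_tiff_stack(
    path: str | Path,
    values: np.ndarray,
    grid: WavelengthGrid,
    exposure: np.ndarray | None = None,
    meta: dict | None = None,
) -> Path:
    """Multi-page TIFF (one page per band) with a JSON sidecar (path + '.json')."""
    path = Path(path)
    values = np.asarray(values, dtype=np.float32)
    tifffile.imwrite(path, values.transpose(2, 0, 1))
    sidecar = {
        "wavelengths_nm": list(map(float, grid.wavelengths)),
        "bandwidth_nm": float(grid.bandwidth),
        "exposure_ms": list(map(float, exposure)) if exposure is not None else None,
        "meta": meta or {},
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_tiff_stack(path: str | Path) -> tuple[np.ndarray, WavelengthGrid, np.ndarray | None, dict]:
    path = Path(path)
    stack = tifffile.imread(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    grid = WavelengthGrid(np.array(sidecar["wavelengths_nm"]), sidecar["bandwidth_nm"])
    exposure = (
        np.array(sidecar["exposure_ms"]) if sidecar.get("exposure_ms") is not None else None
    )
    return stack.transpose(1, 2, 0).astype(np.float64), grid, exposure, sidecar.get("meta", {})


def save_hypercube(path: str | Path, cube: HyperCube) -> Path:
    """Save a HyperCube; '.tif'/'.tiff' selects TIFF, anything else ENVI."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return write_tiff_stack(path, cube.intensity, cube.grid, cube.exposure, cube.meta)
    return write_envi(path, cube.intensity, cube.grid, cube.exposure)


def load_hypercube(path: str | Path) -> HyperCube:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        values, grid, exposure, meta = read_tiff_stack(path)
    else:
        values, grid, exposure = read_envi(path)
        meta = {}
    if exposure is None:
        raise ConfigurationError(f"{path} carries no exposure times; not a HyperCube")
    return HyperCube(values, exposure, grid, meta)


def save_reflectance(path: str | Path, cube: ReflectanceCube) -> Path:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        meta = dict(cube.meta)
        meta["flattened"] = cube.flattened
        return write_tiff_stack(path, cube.values, cube.grid, None, meta)
    return write_envi(path, cube.values, cube.grid, None,
                      description=f"hsdfm reflectance (flattened={cube.flattened})")


def load_reflectance(path: str | Path) -> ReflectanceCube:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        values, grid, _, meta = read_tiff_stack(path)
        return ReflectanceCube(values, grid, flattened=bool(meta.get("flattened", False)),
                               meta=meta)
    values, grid, _ = read_envi(path)
    return ReflectanceCube(values, grid)
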