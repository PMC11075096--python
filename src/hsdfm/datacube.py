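"""Data-cube model, reflectance normalization, spatial flattening, pseudo-color.

A hyperspectral dark-field acquisition is a stack of narrow-band images
``I(m, n, lambda)`` taken with per-band exposure times.  Together with a dark
cube and a white-standard reference cube it is converted to a reflectance
cube::

    X = (I / dt1 - I_dark / dt2) / (I_ref / dt3 - I_dark / dt4)

where each intensity is first normalized by its own exposure time and the
reference (and dark) spectra are averaged over the field of view.  Long-range
illumination non-uniformity is then removed per band by dividing by a
unit-mean Gaussian-blurred copy of the band ("spatial flattening").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)


class GridMismatchError(ValueError):
    """Cubes in one analysis do not share a wavelength grid."""


class DegenerateReferenceError(ValueError):
    """Exposure-normalized reference does not exceed dark in some band."""


class ConfigurationError(ValueError):
    """Invalid or inconsistent configuration of an operation."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing band centers in nm plus a common bandwidth."""

    wavelengths: np.ndarray
    bandwidth: float = 8.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ConfigurationError("wavelength grid must be a non-empty 1-D array")
        if not np.all(np.diff(wl) > 0):
            raise ConfigurationError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    @classmethod
    def default(cls) -> "WavelengthGrid":
        """480 to 650 nm inclusive in 5 nm steps (35 bands), 8 nm bandwidth."""
        return cls(np.arange(480.0, 650.0 + 2.5, 5.0), bandwidth=8.0)

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths.size)

    def band_index(self, wavelength: float, atol: float = 1e-6) -> int:
        """Index of the band centered at ``wavelength``; raises if absent."""
        hits = np.flatnonzero(np.isclose(self.wavelengths, wavelength, atol=atol))
        if hits.size == 0:
            raise ConfigurationError(
                f"no band at {wavelength} nm in grid "
                f"[{self.wavelengths[0]}..{self.wavelengths[-1]}]"
            )
        return int(hits[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return (
            self.wavelengths.shape == other.wavelengths.shape
            and np.allclose(self.wavelengths, other.wavelengths)
            and np.isclose(self.bandwidth, other.bandwidth)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.wavelengths.tobytes(), self.bandwidth))


@dataclass
class HyperCube:
    """Raw intensity stack with per-band exposure times.

    ``intensity`` has axis order (row, col, band), row-major, pixel (0, 0)
    at top-left.  Spatially uniform cubes (a dark or reference spectrum) are
    stored as 1x1 rasters and broadcast where needed.
    """

    intensity: np.ndarray
    exposure: np.ndarray
    grid: WavelengthGrid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.exposure = np.asarray(self.exposure, dtype=float)
        if self.intensity.ndim != 3:
            raise ConfigurationError("intensity must be (rows, cols, bands)")
        if self.intensity.shape[2] != self.grid.n_bands:
            raise GridMismatchError(
                f"cube has {self.intensity.shape[2]} bands, grid has {self.grid.n_bands}"
            )
        if self.exposure.shape != (self.grid.n_bands,):
            raise ConfigurationError("exposure must be one value per band")
        if np.any(self.exposure <= 0):
            raise ConfigurationError("exposure times must be strictly positive")

    @classmethod
    def uniform(
        cls,
        spectrum: Sequence[float],
        exposure: Sequence[float],
        grid: WavelengthGrid,
        meta: dict | None = None,
    ) -> "HyperCube":
        """A spatially uniform cube holding a single spectrum."""
        spec = np.asarray(spectrum, dtype=float).reshape(1, 1, -1)
        return cls(spec, np.asarray(exposure, dtype=float), grid, meta or {})

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    def mean_spectrum(self) -> np.ndarray:
        """Spectrum averaged over the field of view."""
        return self.intensity.mean(axis=(0, 1))


@dataclass
class ReflectanceCube:
    """Normalized reflectance raster X(m, n, lambda)."""

    values: np.ndarray
    grid: WavelengthGrid
    flattened: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ConfigurationError("values must be (rows, cols, bands)")
        if self.values.shape[2] != self.grid.n_bands:
            raise GridMismatchError(
                f"cube has {self.values.shape[2]} bands, grid has {self.grid.n_bands}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("reflectance values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def pixels(self) -> np.ndarray:
        """View of the cube as an (n_pixels, n_bands) matrix."""
        return self.values.reshape(-1, self.grid.n_bands)


def _require_same_grid(*cubes) -> WavelengthGrid:
    grid = cubes[0].grid
    for c in cubes[1:]:
        if c.grid != grid:
            raise GridMismatchError("all cubes in one analysis must share one grid")
    return grid


def normalize_cube(
    sample: HyperCube,
    dark: HyperCube,
    reference: HyperCube,
    dark_exposure_denominator: np.ndarray | None = None,
) -> ReflectanceCube:
    """Exposure-normalized reflectance of ``sample`` against dark and reference.

    The reference and dark cubes are spatially averaged over their field of
    view to spectra before use; each cube carries its own exposure vector.
    The one dark acquisition may enter the numerator and denominator with
    different exposures (``dark_exposure_denominator``, default: the dark
    cube's own exposure, i.e. dt2 == dt4).

    Raises
    ------
    GridMismatchError
        if the three cubes do not share a wavelength grid.
    DegenerateReferenceError
        if the exposure-normalized reference minus dark is not strictly
        positive in every band.
    """
    grid = _require_same_grid(sample, dark, reference)
    dt4 = (
        np.asarray(dark_exposure_denominator, dtype=float)
        if dark_exposure_denominator is not None
        else dark.exposure
    )
    if dt4.shape != (grid.n_bands,) or np.any(dt4 <= 0):
        raise ConfigurationError("denominator dark exposure must be positive per band")

    dark_spec = dark.mean_spectrum()
    ref_spec = reference.mean_spectrum()
    denom = ref_spec / reference.exposure - dark_spec / dt4
    bad = np.flatnonzero(denom <= 0)
    if bad.size:
        raise DegenerateReferenceError(
            f"reference does not exceed dark at band(s) "
            f"{grid.wavelengths[bad].tolist()} nm"
        )
    numer = sample.intensity / sample.exposure - dark_spec / dark.exposure
    values = numer / denom
    return ReflectanceCube(values, grid, flattened=False, meta={"source": "normalize_cube"})


def flatten_cube(
    cube: ReflectanceCube,
    smoothing_scale: float | tuple[float, float] = 50.0,
) -> ReflectanceCube:
    """Remove long-range illumination non-uniformity per band.

    Each band is divided by a unit-mean Gaussian-blurred copy of itself (the
    estimated illumination field) and rescaled to preserve the band mean
    exactly.  ``smoothing_scale`` is the Gaussian sigma in pixels; a
    (sigma_row, sigma_col) pair gives a directional (anisotropic) blur.
    """
    sigma = (
        tuple(float(s) for s in smoothing_scale)
        if isinstance(smoothing_scale, (tuple, list))
        else (float(smoothing_scale),) * 2
    )
    if any(s <= 0 for s in sigma):
        raise ConfigurationError("smoothing_scale must be positive")
    if not np.all(np.isfinite(cube.values)):
        raise ConfigurationError("cannot flatten a cube with non-finite values")

    out = np.empty_like(cube.values)
    for b in range(cube.grid.n_bands):
        band = cube.values[:, :, b]
        mean = band.mean()
        if abs(mean) < 1e-300:
            out[:, :, b] = band
            continue
        # Fixed-point estimate: divide by the unit-mean blurred field until
        # the blurred result is spatially uniform.  This makes the operator
        # idempotent (a flattened band is already at the fixed point) and
        # suppresses ramps whose scale approaches the image size.  'nearest'
        # keeps the field estimate monotone near borders.
        flat = band
        for _ in range(100):
            fld = ndimage.gaussian_filter(flat, sigma=sigma, mode="nearest")
            fld_mean = fld.mean()
            if abs(fld_mean) < 1e-300 or np.any(fld == 0):
                raise ConfigurationError(f"degenerate illumination field in band {b}")
            fld = fld / fld_mean
            flat = flat / fld
            if np.max(np.abs(fld - 1.0)) < 1e-6:
                break
        flat = flat * (mean / flat.mean())  # exact band-mean preservation
        out[:, :, b] = flat
    return ReflectanceCube(out, cube.grid, flattened=True, meta=dict(cube.meta))


def pseudo_color(
    cube: ReflectanceCube,
    bands_nm: tuple[float, float, float] = (480.0, 530.0, 630.0),
) -> np.ndarray:
    """Pseudo-color image from three bands (blue, green, red channels).

    Each channel is rescaled to [0, 1] by its 1st-99th percentile and
    clipped.  Returns an (rows, cols, 3) RGB array.
    """
    b_idx, g_idx, r_idx = (cube.grid.band_index(w) for w in bands_nm)
    rgb = np.empty(cube.shape[:2] + (3,), dtype=float)
    for ch, idx in enumerate((r_idx, g_idx, b_idx)):
        vals = cube.values[:, :, idx]
        lo, hi = np.percentile(vals, [1.0, 99.0])
        if hi - lo <= 0:
            # constant channel: nonzero maps to full intensity, zero stays dark
            rgb[:, :, ch] = (vals != 0).astype(float)
        else:
            rgb[:, :, ch] = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
    return rgb
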