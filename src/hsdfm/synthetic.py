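"""Synthetic HSDFM scenes with the statistical structure the analysis assumes.

Pixel spectra are linear mixtures of positive tissue templates whose shapes
follow the qualitative dark-field backscattering features of breast tissue:
blood with oxy-hemoglobin absorption dips near 540 and 575 nm on a declining
baseline; fat rising sigmoidally below 550 nm and nearly flat above;
interconnected (fibrous) tissue (ICT) variants with an overall negative
slope and a few-percent local ripple; epithelium ICT-like with reduced
ripple; and four mutually distinct carcinoma shapes (IDC, IMC, ILC,
phyllodes).  The generator emits the raw sample/dark/reference cube triplet
(counts with per-band exposures, multiplicative lamp x sensor response,
additive dark offset, optional smooth illumination field, multiplicative
Gaussian sensor noise) so that reflectance normalization recovers the
planted mixture, plus ground-truth label and abundance rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from hsdfm.datacube import ConfigurationError, HyperCube, WavelengthGrid


@dataclass(frozen=True)
class SpectralTemplate:
    """A labeled, strictly positive reflectance spectrum on a shared grid."""

    label: str
    spectrum: np.ndarray
    grid: WavelengthGrid
    provenance: str = "paper-shape"

    def __post_init__(self) -> None:
        spec = np.asarray(self.spectrum, dtype=float)
        if spec.shape != (self.grid.n_bands,):
            raise ConfigurationError(f"template {self.label!r}: spectrum/grid mismatch")
        if np.any(spec <= 0):
            raise ConfigurationError(f"template {self.label!r} must be strictly positive")
        object.__setattr__(self, "spectrum", spec)


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def make_tissue_templates(grid: WavelengthGrid | None = None) -> list[SpectralTemplate]:
    """Analytic stand-ins for the tissue endmember shapes seen in dark field.

    Returns ten templates: blood, fat, three ICT variants, epithelium and the
    four carcinoma subtypes.  The analytic forms (Gaussian absorption dips,
    sigmoidal rise, linear slope plus sinusoidal ripple, broad concave
    bumps) are chosen so all pairwise spectral angles are at least 0.1 rad,
    keeping the templates separable by angle-based classification.
    """
    grid = grid or WavelengthGrid.default()
    wl = grid.wavelengths
    u = (wl - 480.0) / 170.0  # 0..1 over the default span

    shapes: dict[str, np.ndarray] = {}
    # blood: declining baseline with oxy-Hb dips at 540 and 575 nm
    baseline = 1.0 - 0.25 * u
    shapes["blood"] = baseline * (
        1.0 - 0.40 * _gauss(wl, 540.0, 10.0) - 0.32 * _gauss(wl, 575.0, 9.0)
    )
    # fat: sigmoidal rise below 550 nm, nearly flat above
    shapes["fat"] = 0.15 + 0.90 / (1.0 + np.exp(-(wl - 512.0) / 14.0))
    # ICT variants: negative slope with a 3-4% ripple; slopes/periods differ
    shapes["ICT1"] = (1.15 - 0.75 * u) * (1.0 + 0.035 * np.sin(2 * np.pi * (wl - 480.0) / 45.0))
    shapes["ICTf"] = (1.10 - 0.42 * u) * (1.0 + 0.030 * np.sin(2 * np.pi * (wl - 492.0) / 60.0))
    shapes["ICTb"] = (1.22 - 1.05 * u) * (1.0 + 0.040 * np.sin(2 * np.pi * (wl - 470.0) / 36.0))
    # epithelium: ICT-like with reduced ripple, nearly flat
    shapes["epithelium"] = (1.00 - 0.03 * u) * (
        1.0 + 0.008 * np.sin(2 * np.pi * (wl - 480.0) / 50.0)
    )
    # carcinoma subtypes: distinct broad-band shapes
    # IDC: reduced intensity 510-610 nm on a declining baseline
    shapes["IDC"] = 0.98 - 0.30 * u - 0.26 * _gauss(wl, 580.0, 45.0)
    # phyllodes: similar family, deeper and more curved dip
    shapes["phyllodes"] = 0.92 - 0.10 * u - 0.34 * _gauss(wl, 552.0, 38.0)
    # IMC: concave-down with a local maximum near 590 nm
    shapes["IMC"] = 0.28 + 0.55 * _gauss(wl, 590.0, 70.0)
    # ILC: concave-down with a local maximum near 520 nm
    shapes["ILC"] = 0.22 + 0.60 * _gauss(wl, 520.0, 48.0)

    return [SpectralTemplate(name, spec, grid) for name, spec in shapes.items()]


@dataclass
class Region:
    """A rectangular scene region with linear mixing weights over templates.

    ``rows`` and ``cols`` are half-open (start, stop) pixel ranges; weights
    map template labels to nonnegative fractions summing to at most 1.
    """

    rows: tuple[int, int]
    cols: tuple[int, int]
    weights: dict[str, float]

    def validate(self) -> None:
        w = np.array(list(self.weights.values()), dtype=float)
        if np.any(w < 0) or w.sum() > 1.0 + 1e-12:
            raise ConfigurationError(
                f"region weights must be nonnegative and sum <= 1, got {self.weights}"
            )


@dataclass
class SceneSpec:
    """Recipe for one synthetic scene; a fixed seed gives byte-identical output."""

    shape: tuple[int, int]
    regions: list[Region]
    noise_sd: float = 0.0
    illumination_amplitude: float = 0.0  # peak-to-mean relative strength of smooth field
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "SceneSpec":
        doc = yaml.safe_load(open(path))
        regions = [
            Region(tuple(r["rows"]), tuple(r["cols"]), dict(r["weights"]))
            for r in doc["regions"]
        ]
        return cls(
            shape=tuple(doc["shape"]),
            regions=regions,
            noise_sd=float(doc.get("noise_sd", 0.0)),
            illumination_amplitude=float(doc.get("illumination_amplitude", 0.0)),
            seed=int(doc.get("seed", 0)),
        )


@dataclass
class SyntheticScene:
    """Generator output: raw cube triplet plus ground truth."""

    sample: HyperCube
    dark: HyperCube
    reference: HyperCube
    labels: np.ndarray          # (m, n) template index; -1 = mixed/background
    label_names: list[str]
    abundance: np.ndarray       # (m, n, n_templates) planted weights
    grid: WavelengthGrid = field(repr=False, default=None)


def _lamp_response(wl: np.ndarray) -> np.ndarray:
    """Synthetic lamp x AOTF x sensor spectral response, in counts/ms."""
    return 1000.0 * (0.55 + 0.45 * np.exp(-0.5 * ((wl - 560.0) / 90.0) ** 2))


def _exposures(wl: np.ndarray) -> np.ndarray:
    """Per-band exposures (ms) roughly equalizing counts, as an auto-scan would."""
    resp = _lamp_response(wl)
    return 20.0 * resp.max() / resp


def _illumination_field(shape: tuple[int, int], amplitude: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative long-range field with unit mean."""
    m, n = shape
    yy, xx = np.meshgrid(np.linspace(-1, 1, m), np.linspace(-1, 1, n), indexing="ij")
    phase = rng.uniform(0, 2 * np.pi, size=3)
    fld = (
        1.0
        + 0.6 * amplitude * np.sin(0.9 * xx + phase[0])
        + 0.6 * amplitude * np.sin(0.8 * yy + phase[1])
        + 0.4 * amplitude * xx * yy * np.cos(phase[2])
    )
    return fld / fld.mean()


def _assemble_triplet(
    reflectance: np.ndarray,
    grid: WavelengthGrid,
    noise_sd: float,
    illumination_amplitude: float,
    rng: np.random.Generator,
    meta: dict,
) -> tuple[HyperCube, HyperCube, HyperCube]:
    """Turn a true reflectance raster into a raw sample/dark/reference triplet."""
    wl = grid.wavelengths
    resp = _lamp_response(wl)
    dt_sample = _exposures(wl)
    dt_dark = np.full_like(dt_sample, 25.0)
    dt_ref = 0.5 * dt_sample
    dark_rate = 2.0  # counts/ms additive sensor offset

    m, n = reflectance.shape[:2]
    if illumination_amplitude > 0:
        vfield = _illumination_field((m, n), illumination_amplitude, rng)
    else:
        vfield = np.ones((m, n))

    sample_rate = reflectance * vfield[:, :, None] * resp + dark_rate
    sample_counts = sample_rate * dt_sample
    if noise_sd > 0:
        sample_counts = sample_counts * (
            1.0 + noise_sd * rng.standard_normal(sample_counts.shape)
        )
    dark_counts = np.broadcast_to(dark_rate * dt_dark, (1, 1, grid.n_bands)).copy()
    ref_counts = np.broadcast_to((resp + dark_rate) * dt_ref, (1, 1, grid.n_bands)).copy()

    sample = HyperCube(sample_counts, dt_sample, grid, dict(meta, role="sample"))
    dark = HyperCube(dark_counts, dt_dark, grid, dict(meta, role="dark"))
    reference = HyperCube(ref_counts, dt_ref, grid, dict(meta, role="reference"))
    return sample, dark, reference


def generate_cube(
    spec: SceneSpec, templates: Sequence[SpectralTemplate]
) -> SyntheticScene:
    """Generate a raw cube triplet plus ground truth from a scene recipe.

    Per pixel the true reflectance is the linear mixture of the region's
    templates; reflectance normalization of the triplet recovers it exactly
    when noise and illumination are off.
    """
    grid = templates[0].grid
    by_label = {t.label: t for t in templates}
    m, n = spec.shape
    k = len(templates)
    labels = np.full((m, n), -1, dtype=int)
    abundance = np.zeros((m, n, k))
    reflectance = np.zeros((m, n, grid.n_bands))

    for region in spec.regions:
        region.validate()
        r0, r1 = region.rows
        c0, c1 = region.cols
        mix = np.zeros(grid.n_bands)
        for lbl, w in region.weights.items():
            if lbl not in by_label:
                raise ConfigurationError(f"unknown template {lbl!r} in region")
            idx = list(by_label).index(lbl)
            abundance[r0:r1, c0:c1, idx] = w
            mix += w * by_label[lbl].spectrum
        reflectance[r0:r1, c0:c1, :] = mix
        pure = [lbl for lbl, w in region.weights.items() if w == 1.0]
        if len(pure) == 1 and len(region.weights) == 1:
            labels[r0:r1, c0:c1] = list(by_label).index(pure[0])

    rng = np.random.default_rng(spec.seed)
    meta = {"generator": "hsdfm.synthetic", "seed": spec.seed}
    sample, dark, reference = _assemble_triplet(
        reflectance, grid, spec.noise_sd, spec.illumination_amplitude, rng, meta
    )
    return SyntheticScene(
        sample=sample, dark=dark, reference=reference,
        labels=labels, label_names=[t.label for t in templates],
        abundance=abundance, grid=grid,
    )


def generate_reference_cube(
    template: SpectralTemplate,
    spec: SceneSpec,
    amplitude_range: tuple[float, float] = (0.7, 1.3),
) -> SyntheticScene:
    """A spatially textured single-endmember cube (e.g. fat-only reference).

    Per-pixel amplitude varies smoothly within ``amplitude_range`` while the
    spectral shape stays fixed up to noise, emulating a reference specimen
    containing one tissue type only.
    """
    rng = np.random.default_rng(spec.seed)
    m, n = spec.shape
    lo, hi = amplitude_range
    rough = rng.uniform(lo, hi, size=(max(m // 8, 1), max(n // 8, 1)))
    # smooth amplitude texture via bilinear upsampling of a coarse field
    ry = np.linspace(0, rough.shape[0] - 1, m)
    rx = np.linspace(0, rough.shape[1] - 1, n)
    iy, ix = np.floor(ry).astype(int), np.floor(rx).astype(int)
    iy1 = np.minimum(iy + 1, rough.shape[0] - 1)
    ix1 = np.minimum(ix + 1, rough.shape[1] - 1)
    fy, fx = (ry - iy)[:, None], (rx - ix)[None, :]
    amp = (
        rough[np.ix_(iy, ix)] * (1 - fy) * (1 - fx)
        + rough[np.ix_(iy1, ix)] * fy * (1 - fx)
        + rough[np.ix_(iy, ix1)] * (1 - fy) * fx
        + rough[np.ix_(iy1, ix1)] * fy * fx
    )
    reflectance = amp[:, :, None] * template.spectrum

    meta = {"generator": "hsdfm.synthetic", "seed": spec.seed, "reference_of": template.label}
    sample, dark, reference = _assemble_triplet(
        reflectance, template.grid, spec.noise_sd, spec.illumination_amplitude, rng, meta
    )
    labels = np.zeros((m, n), dtype=int)
    abundance = amp[:, :, None].copy()
    return SyntheticScene(
        sample=sample, dark=dark, reference=reference,
        labels=labels, label_names=[template.label],
        abundance=abundance, grid=template.grid,
    )
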