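"""Reflectance look-up table over volume fraction and wavelength, plus inversion.

For each (volume fraction, wavelength) node the Mie properties of the bead
suspension are computed and a Monte-Carlo dark-field reflectance simulated.
Volume-fraction inversion of a measured reflectance spectrum least-squares
fits the continuous piecewise-linear interpolation of the table between
volume-fraction rows; on each interval the objective is quadratic, so the
minimizer is closed-form and grid nodes invert exactly.  A companion
mu_s'(lambda) table (exactly linear in volume fraction) supports the
reduced-scattering readout at the fitted fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from hsdfm.datacube import ConfigurationError
from hsdfm.phantom.mie import BeadPhantom, bulk_optical_properties, mie_phase_function
from hsdfm.phantom.montecarlo import DarkFieldGeometry, PhaseTable, mc_darkfield_reflectance

DEFAULT_VOLUME_FRACTIONS = np.arange(0.0005, 0.00525, 0.0005)
DEFAULT_WAVELENGTHS = np.arange(400.0, 825.0, 25.0)


@dataclass
class ReflectanceLUT:
    volume_fractions: np.ndarray
    wavelengths_nm: np.ndarray
    reflectance: np.ndarray         # (n_vf, n_wl)
    stderr: np.ndarray              # (n_vf, n_wl)
    mu_s_prime: np.ndarray          # (n_vf, n_wl), 1/mm
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = (len(self.volume_fractions), len(self.wavelengths_nm))
        for name in ("reflectance", "stderr", "mu_s_prime"):
            if getattr(self, name).shape != shape:
                raise ConfigurationError(f"LUT field {name} has wrong shape")
        if np.any((self.reflectance < 0) | (self.reflectance > 1)):
            raise ConfigurationError("reflectance must lie in [0, 1]")

    def to_text(self) -> str:
        lines = ["# hsdfm reflectance LUT v1"]
        lines.append("# provenance: " + json.dumps(self.provenance, sort_keys=True))
        lines.append("# columns: volume_fraction wavelength_nm reflectance stderr mus_prime_per_mm")
        for i, vf in enumerate(self.volume_fractions):
            for j, wl in enumerate(self.wavelengths_nm):
                lines.append(
                    f"{float(vf)!r} {float(wl)!r} {float(self.reflectance[i, j])!r} "
                    f"{float(self.stderr[i, j])!r} {float(self.mu_s_prime[i, j])!r}"
                )
        return "\n".join(lines) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "ReflectanceLUT":
        provenance: dict = {}
        rows = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# provenance:"):
                    provenance = json.loads(line.split(":", 1)[1])
                continue
            rows.append([float(v) for v in line.split()])
        data = np.array(rows)
        vfs = np.unique(data[:, 0])
        wls = np.unique(data[:, 1])
        shape = (vfs.size, wls.size)
        refl = np.empty(shape)
        se = np.empty(shape)
        msp = np.empty(shape)
        vi = np.searchsorted(vfs, data[:, 0])
        wi = np.searchsorted(wls, data[:, 1])
        refl[vi, wi] = data[:, 2]
        se[vi, wi] = data[:, 3]
        msp[vi, wi] = data[:, 4]
        return cls(vfs, wls, refl, se, msp, provenance)

    @classmethod
    def load(cls, path: str | Path) -> "ReflectanceLUT":
        return cls.from_text(Path(path).read_text())


def build_lut(
    diameter_nm: float = 368.0,
    volume_fractions: np.ndarray | None = None,
    wavelengths_nm: np.ndarray | None = None,
    geom: DarkFieldGeometry | None = None,
    photons: int = 100_000,
    seed: int = 0,
    mu_a: float = 0.0,
    phase_angles: int = 1024,
) -> ReflectanceLUT:
    """Simulate the reflectance LUT for a family of bead phantoms.

    One Mie phase function is tabulated per wavelength (it does not depend
    on concentration in the independent-scattering regime); each (vf,
    wavelength) node runs its own seeded Monte-Carlo simulation.
    """
    geom = geom or DarkFieldGeometry()
    vfs = np.asarray(
        DEFAULT_VOLUME_FRACTIONS if volume_fractions is None else volume_fractions, dtype=float
    )
    wls = np.asarray(
        DEFAULT_WAVELENGTHS if wavelengths_nm is None else wavelengths_nm, dtype=float
    )
    shape = (vfs.size, wls.size)
    refl = np.zeros(shape)
    se = np.zeros(shape)
    msp = np.zeros(shape)

    phantoms = [BeadPhantom(diameter_nm, vf, mu_a=mu_a) for vf in vfs]
    tables = []
    for wl in wls:
        ph = phantoms[0]
        mu, p = mie_phase_function(
            diameter_nm, ph.n_sphere(wl), ph.n_medium(wl), wl, n_angles=phase_angles
        )
        tables.append(PhaseTable(mu, p))

    for i, ph in enumerate(phantoms):
        props = bulk_optical_properties(ph, wls)
        msp[i] = props.mu_s_prime
        for j, wl in enumerate(wls):
            if props.mu_s[j] + mu_a <= 0:
                continue  # vf = 0: nothing scatters back, row stays zero
            res = mc_darkfield_reflectance(
                props.mu_s[j], mu_a, tables[j], geom,
                photons=photons, seed=seed + 1000 * i + j,
            )
            refl[i, j] = res.reflectance
            se[i, j] = res.stderr
    provenance = {
        "diameter_nm": diameter_nm,
        "photons": photons,
        "seed": seed,
        "mu_a": mu_a,
        "geometry": {
            "incidence_deg": geom.incidence_deg,
            "source_diameter_mm": geom.source_diameter_mm,
            "na": geom.na,
            "medium_index": geom.medium_index,
            "fov_diameter_mm": geom.fov_diameter_mm,
        },
    }
    return ReflectanceLUT(vfs, wls, refl, se, msp, provenance)


@dataclass
class InversionResult:
    volume_fraction: float
    residuals: np.ndarray           # per-wavelength, fitted minus measured
    sse: float
    mu_s_prime: np.ndarray          # mu_s'(lambda) at the fitted fraction


def invert_volume_fraction(
    wavelengths_nm: np.ndarray,
    measured: np.ndarray,
    lut: ReflectanceLUT,
) -> InversionResult:
    """Least-squares volume fraction from a measured reflectance spectrum.

    The LUT is linearly interpolated between volume-fraction rows; within
    each interval the sum of squares is quadratic in the interpolation
    coordinate, so the per-interval minimizer is exact.  Measurement
    wavelengths must lie inside the LUT wavelength span.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    y = np.asarray(measured, dtype=float)
    if wl.shape != y.shape or wl.ndim != 1:
        raise ConfigurationError("wavelengths and measured spectrum must align")
    if wl.min() < lut.wavelengths_nm.min() - 1e-9 or wl.max() > lut.wavelengths_nm.max() + 1e-9:
        raise ConfigurationError(
            "measurement wavelengths extend beyond the LUT grid (extrapolation)"
        )
    # LUT rows resampled onto the measurement wavelengths
    rows = np.vstack(
        [np.interp(wl, lut.wavelengths_nm, lut.reflectance[i]) for i in range(len(lut.volume_fractions))]
    )
    best = None
    vfs = lut.volume_fractions
    for i in range(len(vfs) - 1):
        r0, r1 = rows[i], rows[i + 1]
        dr = r1 - r0
        denom = float(dr @ dr)
        t = float(dr @ (y - r0)) / denom if denom > 0 else 0.0
        t = min(1.0, max(0.0, t))
        fit = r0 + t * dr
        sse = float(((fit - y) ** 2).sum())
        vf = float(vfs[i] + t * (vfs[i + 1] - vfs[i]))
        if best is None or sse < best[0]:
            best = (sse, vf, fit)
    sse, vf, fit = best
    msp_rows = lut.mu_s_prime
    msp = np.empty(lut.wavelengths_nm.size)
    for j in range(lut.wavelengths_nm.size):
        msp[j] = np.interp(vf, vfs, msp_rows[:, j])
    return InversionResult(
        volume_fraction=vf, residuals=fit - y, sse=sse, mu_s_prime=msp
    )
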