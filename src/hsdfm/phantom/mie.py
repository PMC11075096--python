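"""Lorenz-Mie scattering of a homogeneous sphere and dilute-suspension optics.

The Mie coefficients are computed with the logarithmic-derivative downward
recurrence (numerically stable for the size parameters of sub-micron beads
in the visible), truncated after ``x + 4 x^(1/3) + 2`` terms.  Bulk
properties of a dilute monodisperse suspension follow from independent
scattering: ``mu_s = number_density * Q_sca * geometric cross-section`` and
``mu_s' = mu_s (1 - g)``.

Refractive-index dispersions are pinned Cauchy forms for polystyrene and
water (coefficients in the docs); both are smooth and accurate to a few
1e-3 over 400-800 nm, which is all the phantom model needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from hsdfm.datacube import ConfigurationError


def polystyrene_index(wavelength_nm: np.ndarray | float) -> np.ndarray | float:
    """Cauchy dispersion of polystyrene, wavelength in nm."""
    lam_um = np.asarray(wavelength_nm, dtype=float) / 1000.0
    n = 1.5725 + 0.0031080 / lam_um**2 + 0.00034779 / lam_um**4
    return float(n) if np.isscalar(wavelength_nm) else n


def water_index(wavelength_nm: np.ndarray | float) -> np.ndarray | float:
    """Cauchy dispersion of water at room temperature, wavelength in nm."""
    lam = np.asarray(wavelength_nm, dtype=float)
    n = 1.3199 + 6878.0 / lam**2 - 1.132e9 / lam**4 + 1.11e14 / lam**6
    return float(n) if np.isscalar(wavelength_nm) else n


@dataclass
class MieResult:
    x: float            # size parameter pi d n_medium / lambda
    m: float            # relative refractive index n_sphere / n_medium
    q_sca: float        # scattering efficiency
    q_ext: float        # extinction efficiency
    g: float            # asymmetry parameter <cos theta>
    n_terms: int


def _mie_coefficients(m: float, x: float) -> tuple[np.ndarray, np.ndarray]:
    """Mie a_n, b_n (n = 1..nmax) via logarithmic-derivative recurrence."""
    if not np.isfinite(x) or x <= 0:
        raise ConfigurationError(f"size parameter must be positive and finite, got {x}")
    nmax = int(round(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    mx = m * x
    # downward recurrence for D_n(mx), started well above nmax
    nstart = nmax + 16
    D = np.zeros(nstart + 1)
    for n in range(nstart, 0, -1):
        D[n - 1] = n / mx - 1.0 / (D[n] + n / mx)
    D = D[1:nmax + 1]

    n = np.arange(1, nmax + 1, dtype=float)
    # Riccati-Bessel psi_n(x), chi_n(x) by upward recurrence
    psi = np.zeros(nmax + 1)
    chi = np.zeros(nmax + 1)
    psi_m1, psi[0] = np.cos(x), np.sin(x)          # psi_{-1}, psi_0
    chi_m1, chi[0] = -np.sin(x), np.cos(x)         # chi_{-1}, chi_0
    for k in range(1, nmax + 1):
        psi[k] = (2 * k - 1) / x * psi[k - 1] - (psi[k - 2] if k >= 2 else psi_m1)
        chi[k] = (2 * k - 1) / x * chi[k - 1] - (chi[k - 2] if k >= 2 else chi_m1)
    xi = psi - 1j * chi  # Riccati-Hankel of the first kind
    if not np.all(np.isfinite(chi)):
        raise ConfigurationError("Mie series failed to converge (pathological inputs)")

    fa = D / m + n / x
    fb = D * m + n / x
    a = (fa * psi[1:] - psi[:-1]) / (fa * xi[1:] - xi[:-1])
    b = (fb * psi[1:] - psi[:-1]) / (fb * xi[1:] - xi[:-1])
    return a, b


def mie_single_sphere(
    diameter_nm: float,
    n_sphere: float,
    n_medium: float,
    wavelength_nm: float,
) -> MieResult:
    """Scattering efficiency and asymmetry of one sphere in a clear medium.

    ``wavelength_nm`` is the vacuum wavelength; the size parameter uses the
    wavelength in the medium.
    """
    if min(diameter_nm, n_sphere, n_medium, wavelength_nm) <= 0:
        raise ConfigurationError("all Mie inputs must be positive")
    x = np.pi * diameter_nm * n_medium / wavelength_nm
    m = n_sphere / n_medium
    a, b = _mie_coefficients(m, x)
    n = np.arange(1, a.size + 1, dtype=float)
    q_sca = (2.0 / x**2) * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
    q_ext = (2.0 / x**2) * np.sum((2 * n + 1) * (a.real + b.real))
    asym = np.sum(
        n[:-1] * (n[:-1] + 2) / (n[:-1] + 1)
        * (a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:])).real
    ) + np.sum((2 * n + 1) / (n * (n + 1)) * (a * np.conj(b)).real)
    g = (4.0 / x**2) * asym / q_sca if q_sca > 0 else 0.0
    return MieResult(x=float(x), m=float(m), q_sca=float(q_sca),
                     q_ext=float(q_ext), g=float(g), n_terms=a.size)


def mie_phase_function(
    diameter_nm: float,
    n_sphere: float,
    n_medium: float,
    wavelength_nm: float,
    n_angles: int = 1024,
) -> tuple[np.ndarray, np.ndarray]:
    """Unpolarized single-scattering phase function on a cosine grid.

    Returns (cos_theta ascending in [-1, 1], p) with p normalized so that
    the integral of p over cos_theta equals 1 (azimuthally integrated).
    """
    x = np.pi * diameter_nm * n_medium / wavelength_nm
    m = n_sphere / n_medium
    a, b = _mie_coefficients(m, x)
    nmax = a.size
    mu = np.linspace(-1.0, 1.0, n_angles)

    # angular functions pi_n, tau_n by upward recurrence, vectorized over mu
    s1 = np.zeros(mu.size, dtype=complex)
    s2 = np.zeros(mu.size, dtype=complex)
    pi_nm1 = np.zeros(mu.size)     # pi_0
    pi_n = np.ones(mu.size)        # pi_1
    for n in range(1, nmax + 1):
        tau_n = n * mu * pi_n - (n + 1) * pi_nm1
        fn = (2 * n + 1) / (n * (n + 1))
        s1 += fn * (a[n - 1] * pi_n + b[n - 1] * tau_n)
        s2 += fn * (a[n - 1] * tau_n + b[n - 1] * pi_n)
        pi_next = ((2 * n + 1) * mu * pi_n - (n + 1) * pi_nm1) / n
        pi_nm1, pi_n = pi_n, pi_next
    intensity = 0.5 * (np.abs(s1) ** 2 + np.abs(s2) ** 2)
    norm = np.trapezoid(intensity, mu)
    return mu, intensity / norm


@dataclass
class BeadPhantom:
    """A dilute aqueous suspension of monodisperse polystyrene spheres."""

    diameter_nm: float = 368.0
    volume_fraction: float = 0.003
    mu_a: float = 0.0                                  # absorption coefficient, 1/mm
    n_sphere: "Callable[[float], float] | None" = None  # wavelength_nm -> index
    n_medium: "Callable[[float], float] | None" = None

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0:
            raise ConfigurationError("bead diameter must be positive")
        if self.mu_a < 0:
            raise ConfigurationError("absorption coefficient must be nonnegative")
        if not (0.0 <= self.volume_fraction < 0.01):
            warnings.warn(
                f"volume fraction {self.volume_fraction} outside the dilute "
                "independent-scattering regime (< 0.01)",
                stacklevel=2,
            )
        if self.n_sphere is None:
            self.n_sphere = polystyrene_index
        if self.n_medium is None:
            self.n_medium = water_index


@dataclass
class OpticalProperties:
    """Per-wavelength scattering properties of a suspension."""

    wavelengths_nm: np.ndarray
    mu_s: np.ndarray                # 1/mm
    g: np.ndarray
    mu_a: float = 0.0               # 1/mm, wavelength-independent here

    def __post_init__(self) -> None:
        if np.any(self.mu_s < 0) or np.any(np.abs(self.g) >= 1.0):
            raise ConfigurationError("require mu_s >= 0 and -1 < g < 1")

    @property
    def mu_s_prime(self) -> np.ndarray:
        """Reduced scattering coefficient mu_s (1 - g), exact by construction."""
        return self.mu_s * (1.0 - self.g)


def bulk_optical_properties(
    phantom: BeadPhantom, wavelengths_nm: np.ndarray
) -> OpticalProperties:
    """Independent-scattering mu_s(lambda), g(lambda) of a dilute suspension.

    Number density is ``phi / sphere volume``; mu_s is exactly proportional
    to the volume fraction.
    """
    wl = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
    d_mm = phantom.diameter_nm * 1e-6
    density = phantom.volume_fraction / (np.pi / 6.0 * d_mm**3)   # spheres / mm^3
    cross_section = np.pi * (d_mm / 2.0) ** 2                      # mm^2
    mu_s = np.empty(wl.size)
    g = np.empty(wl.size)
    for i, lam in enumerate(wl):
        res = mie_single_sphere(
            phantom.diameter_nm, phantom.n_sphere(lam), phantom.n_medium(lam), lam
        )
        mu_s[i] = density * res.q_sca * cross_section
        g[i] = res.g
    return OpticalProperties(wavelengths_nm=wl, mu_s=mu_s, g=g, mu_a=phantom.mu_a)
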