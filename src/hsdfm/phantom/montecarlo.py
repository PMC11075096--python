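"""Monte-Carlo photon transport for the dark-field microscope geometry.

Photons enter a semi-infinite turbid medium at a 15 degree incidence angle,
launched uniformly over a 5 mm diameter source disc.  Free paths are
exponential with mu_t = mu_s + mu_a; scattering angles are sampled by
inverse CDF from the tabulated Mie phase function; absorption is handled by
survival weighting.  A photon is collected if it exits the top surface
inside the concentric 1.6 mm collection field of view with a polar exit
angle smaller than asin(NA / n) — smaller than the incidence angle, so
specular light is rejected (the dark-field condition).  The reflectance is
the collected weight over the injected photon count.

The boundary is refractive-index matched (no Fresnel reflection) by
default; photons reaching the depth cutoff or the step cap are tallied in a
separate bucket so total weight is conserved exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from hsdfm.datacube import ConfigurationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DarkFieldGeometry:
    """Illumination/collection geometry of the dark-field microscope."""

    incidence_deg: float = 15.0
    source_diameter_mm: float = 5.0
    na: float = 0.13
    medium_index: float = 1.33
    fov_diameter_mm: float = 1.6

    def __post_init__(self) -> None:
        if self.collection_half_angle_rad >= np.deg2rad(self.incidence_deg):
            raise ConfigurationError(
                "dark-field condition violated: collection half-angle must be "
                "smaller than the incidence angle"
            )

    @property
    def collection_half_angle_rad(self) -> float:
        return float(np.arcsin(self.na / self.medium_index))


@dataclass
class PhaseTable:
    """Tabulated phase function with an inverse-CDF sampler for cos(theta)."""

    cos_theta: np.ndarray
    p: np.ndarray
    cdf: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        mu = np.asarray(self.cos_theta, dtype=float)
        p = np.asarray(self.p, dtype=float)
        if mu.ndim != 1 or mu.size < 2 or np.any(np.diff(mu) <= 0):
            raise ConfigurationError("cos_theta grid must be increasing")
        if np.any(p < 0):
            raise ConfigurationError("phase function must be nonnegative")
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(mu))])
        if cdf[-1] <= 0:
            raise ConfigurationError("phase function integrates to zero")
        self.cos_theta = mu
        self.p = p / cdf[-1]
        self.cdf = cdf / cdf[-1]

    @classmethod
    def isotropic(cls, n: int = 512) -> "PhaseTable":
        mu = np.linspace(-1.0, 1.0, n)
        return cls(mu, np.full(n, 0.5))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.interp(rng.random(size), self.cdf, self.cos_theta)

    def mean_cosine(self) -> float:
        return float(np.trapezoid(self.cos_theta * self.p, self.cos_theta))


@dataclass
class MCResult:
    reflectance: float
    stderr: float
    photons: int
    collected_weight: float
    escaped_weight: float       # exited the top outside FOV or collection cone
    cutoff_weight: float        # depth cutoff or step cap
    absorbed_weight: float
    seed: int

    @property
    def total_weight(self) -> float:
        return (
            self.collected_weight + self.escaped_weight
            + self.cutoff_weight + self.absorbed_weight
        )


def _rotate(u: np.ndarray, cos_t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate direction vectors by polar angle theta and azimuth phi."""
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t**2))
    cos_p, sin_p = np.cos(phi), np.sin(phi)
    ux, uy, uz = u[:, 0], u[:, 1], u[:, 2]
    out = np.empty_like(u)
    near_pole = np.abs(uz) > 0.99999
    denom = np.sqrt(np.maximum(1e-24, 1.0 - uz**2))
    out[:, 0] = sin_t * (ux * uz * cos_p - uy * sin_p) / denom + ux * cos_t
    out[:, 1] = sin_t * (uy * uz * cos_p + ux * sin_p) / denom + uy * cos_t
    out[:, 2] = -sin_t * cos_p * denom + uz * cos_t
    if np.any(near_pole):
        sgn = np.sign(uz[near_pole])
        out[near_pole, 0] = sin_t[near_pole] * cos_p[near_pole]
        out[near_pole, 1] = sin_t[near_pole] * sin_p[near_pole]
        out[near_pole, 2] = sgn * cos_t[near_pole]
    # renormalize to curb drift over many scatterings
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out


def mc_darkfield_reflectance(
    mu_s: float,
    mu_a: float,
    phase: PhaseTable,
    geom: DarkFieldGeometry | None = None,
    photons: int = 1_000_000,
    seed: int = 0,
    depth_cutoff_mm: float = 10.0,
    max_steps: int = 20_000,
    roulette_threshold: float = 1e-4,
) -> MCResult:
    """Dark-field reflectance of a semi-infinite medium by photon random walk.

    Returns the collected-to-injected weight ratio and its Monte-Carlo
    standard error.  Deterministic for a fixed seed.  With ``mu_a == 0``
    (the phantom model) the four weight buckets sum to the injected count to
    machine precision.
    """
    geom = geom or DarkFieldGeometry()
    if photons < 1:
        raise ConfigurationError("need at least one photon")
    mu_t = mu_s + mu_a
    if mu_t <= 0:
        warnings.warn("ballistic medium (mu_t == 0): nothing scatters back", stacklevel=2)
        return MCResult(0.0, 0.0, photons, 0.0, float(photons), 0.0, 0.0, seed)
    albedo = mu_s / mu_t

    rng = np.random.default_rng(seed)
    n = photons
    # launch uniformly over the source disc, tilted incidence in the x-z plane
    r = 0.5 * geom.source_diameter_mm * np.sqrt(rng.random(n))
    phi0 = 2.0 * np.pi * rng.random(n)
    pos = np.column_stack([r * np.cos(phi0), r * np.sin(phi0), np.zeros(n)])
    theta_in = np.deg2rad(geom.incidence_deg)
    u0 = np.array([np.sin(theta_in), 0.0, np.cos(theta_in)])
    dirs = np.tile(u0, (n, 1))
    weight = np.ones(n)

    cos_cap = np.cos(geom.collection_half_angle_rad)
    fov_r = 0.5 * geom.fov_diameter_mm

    collected = 0.0
    collected_sq = 0.0
    escaped = 0.0
    cutoff = 0.0
    absorbed = 0.0

    for _ in range(max_steps):
        if pos.shape[0] == 0:
            break
        step = -np.log(rng.random(pos.shape[0])) / mu_t
        newpos = pos + dirs * step[:, None]
        exits = newpos[:, 2] < 0.0
        if np.any(exits):
            t = -pos[exits, 2] / dirs[exits, 2]
            lateral = pos[exits, :2] + dirs[exits, :2] * t[:, None]
            r_exit = np.hypot(lateral[:, 0], lateral[:, 1])
            ok = (r_exit <= fov_r) & (-dirs[exits, 2] > cos_cap)
            w_exit = weight[exits]
            collected += w_exit[ok].sum()
            collected_sq += (w_exit[ok] ** 2).sum()
            escaped += w_exit[~ok].sum()
        stay = ~exits
        pos, dirs, weight = newpos[stay], dirs[stay], weight[stay]

        deep = pos[:, 2] > depth_cutoff_mm
        if np.any(deep):
            cutoff += weight[deep].sum()
            keep = ~deep
            pos, dirs, weight = pos[keep], dirs[keep], weight[keep]
        if pos.shape[0] == 0:
            break

        # absorption by survival weighting, then scatter
        absorbed += ((1.0 - albedo) * weight).sum()
        weight = weight * albedo
        if albedo < 1.0:
            faint = weight < roulette_threshold
            if np.any(faint):
                survive = rng.random(faint.sum()) < 0.1
                killed = faint.copy()
                killed[np.flatnonzero(faint)[survive]] = False
                absorbed += weight[killed].sum()
                boosted = np.flatnonzero(faint)[survive]
                weight[boosted] /= 0.1
                keep = ~killed
                pos, dirs, weight = pos[keep], dirs[keep], weight[keep]
                if pos.shape[0] == 0:
                    break
        cos_t = phase.sample(rng, pos.shape[0])
        phi = 2.0 * np.pi * rng.random(pos.shape[0])
        dirs = _rotate(dirs, cos_t, phi)
    else:
        cutoff += weight.sum()
        pos = np.empty((0, 3))

    if pos.shape[0] > 0:
        cutoff += weight.sum()

    refl = collected / photons
    var = max(0.0, collected_sq / photons - refl**2)
    stderr = float(np.sqrt(var / photons))
    return MCResult(
        reflectance=float(refl), stderr=stderr, photons=photons,
        collected_weight=float(collected), escaped_weight=float(escaped),
        cutoff_weight=float(cutoff), absorbed_weight=float(absorbed), seed=seed,
    )
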