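"""Supervised spectral-angle-mapper classification with OSCA thresholds.

The spectral correlation angle (SCA) between a pixel spectrum x and an
endmember mu is ``arccos(x . mu / (|x| |mu|))`` — zero for identical shapes,
pi/2 for orthogonal ones, invariant to positive rescaling of either vector.
A tissue type's segmentation map marks pixels whose SCA falls strictly
below a threshold angle.

The threshold is anchored by the orthogonalized SCA (OSCA): the smallest
angle between the endmember and any pixel of a reference cube known to
contain none of that tissue ("fat-only" for non-fat endmembers,
"fibroadenoma-only" for fat).  Segmenting the reference cube at its own
OSCA therefore yields zero positive pixels by construction.  The integrated
map assigns each pixel the passing type with the smallest SCA.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from hsdfm.datacube import ConfigurationError, GridMismatchError, ReflectanceCube, WavelengthGrid

log = logging.getLogger(__name__)

RIGHT_ANGLE = float(np.pi / 2)


class DegeneratePixelError(ValueError):
    """A spectrum with zero norm has no direction, hence no angle."""


@dataclass
class Endmember:
    """Labeled mean spectrum of an annotated region of interest."""

    label: str
    mu: np.ndarray
    spread: np.ndarray
    n_pixels: int
    color: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.spread = np.asarray(self.spread, dtype=float)
        if np.linalg.norm(self.mu) == 0:
            raise DegeneratePixelError(f"endmember {self.label!r} has zero norm")
        if self.n_pixels < 1:
            raise ConfigurationError("endmember needs at least one source pixel")


@dataclass
class AngleMap:
    """Per-pixel SCA raster against one endmember, in radians ([0, pi/2])."""

    values: np.ndarray
    endmember_label: str
    source: str = ""
    n_degenerate: int = 0


@dataclass
class FillFactorCurve:
    """Fraction of reference pixels with angle <= threshold, per threshold."""

    thresholds: np.ndarray
    fractions: np.ndarray
    n_pixels: int

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(np.diff(self.fractions) < 0):
            raise ConfigurationError("fill-factor fractions must be nondecreasing")


@dataclass
class LibraryEntry:
    endmember: Endmember
    osca: float                      # orthogonalized SCA, rad
    threshold: float                 # active threshold (default: osca), rad
    reference_id: int                # 1 = fat-only ref, 2 = fibroadenoma-only ref
    fill_curve: FillFactorCurve | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= RIGHT_ANGLE + 1e-12):
            raise ConfigurationError("threshold must lie in (0, pi/2]")


@dataclass
class EndmemberLibrary:
    """Versioned collection of (endmember, OSCA, threshold) entries."""

    entries: list[LibraryEntry]
    version: int = 1

    def labels(self) -> list[str]:
        return [e.endmember.label for e in self.entries]

    def __getitem__(self, label: str) -> LibraryEntry:
        for e in self.entries:
            if e.endmember.label == label:
                return e
        raise KeyError(label)

    def to_json(self) -> str:
        doc = {
            "format": "hsdfm-endmember-library",
            "version": self.version,
            "entries": [
                {
                    "label": e.endmember.label,
                    "mu": e.endmember.mu.tolist(),
                    "spread": e.endmember.spread.tolist(),
                    "n_pixels": e.endmember.n_pixels,
                    "color": list(e.endmember.color),
                    "osca": e.osca,
                    "threshold": e.threshold,
                    "reference_id": e.reference_id,
                }
                for e in self.entries
            ],
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "EndmemberLibrary":
        doc = json.loads(text)
        entries = [
            LibraryEntry(
                endmember=Endmember(
                    label=d["label"],
                    mu=np.array(d["mu"]),
                    spread=np.array(d["spread"]),
                    n_pixels=int(d["n_pixels"]),
                    color=tuple(d["color"]),
                ),
                osca=float(d["osca"]),
                threshold=float(d["threshold"]),
                reference_id=int(d["reference_id"]),
            )
            for d in doc["entries"]
        ]
        return cls(entries=entries, version=int(doc["version"]))

    @classmethod
    def load(cls, path: str | Path) -> "EndmemberLibrary":
        return cls.from_json(Path(path).read_text())


@dataclass
class IntegratedSegmentation:
    """Per-pixel winning tissue label (-1 = background) with display colors."""

    labels: np.ndarray
    label_names: list[str]
    colors: list[tuple[float, float, float]]
    n_ties: int = 0

    def mask(self, label: str) -> np.ndarray:
        return self.labels == self.label_names.index(label)

    def to_rgb(self) -> np.ndarray:
        rgb = np.zeros(self.labels.shape + (3,))
        for i, color in enumerate(self.colors):
            rgb[self.labels == i] = color
        return rgb


def extract_endmember(
    cube: ReflectanceCube,
    roi: np.ndarray,
    label: str,
    color: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> Endmember:
    """Mean and per-band standard deviation over a region of interest."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != cube.shape[:2]:
        raise ConfigurationError("ROI shape does not match cube raster")
    n = int(roi.sum())
    if n == 0:
        raise ConfigurationError(f"empty ROI for endmember {label!r}")
    spectra = cube.values[roi]
    return Endmember(
        label=label,
        mu=spectra.mean(axis=0),
        spread=spectra.std(axis=0),
        n_pixels=n,
        color=color,
    )


def spectral_angle(x: np.ndarray, mu: np.ndarray) -> float:
    """SCA between two spectra, clamped to [0, pi/2]; scale-invariant."""
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if x.shape != mu.shape:
        raise GridMismatchError("spectra must share one grid")
    nx, nm = np.linalg.norm(x), np.linalg.norm(mu)
    if nx == 0 or nm == 0:
        raise DegeneratePixelError("zero-norm spectrum has no spectral angle")
    cos = float(np.dot(x, mu) / (nx * nm))
    return float(np.arccos(np.clip(cos, 0.0, 1.0)))


def angle_map(cube: ReflectanceCube, em: Endmember) -> AngleMap:
    """SCA of every pixel against one endmember; degenerate pixels get pi/2."""
    if em.mu.shape != (cube.grid.n_bands,):
        raise GridMismatchError("endmember/grid band count mismatch")
    pix = cube.pixels()
    norms = np.linalg.norm(pix, axis=1)
    mu_unit = em.mu / np.linalg.norm(em.mu)
    degenerate = norms == 0
    safe = np.where(degenerate, 1.0, norms)
    cos = np.clip((pix @ mu_unit) / safe, 0.0, 1.0)
    angles = np.arccos(cos)
    angles[degenerate] = RIGHT_ANGLE
    n_deg = int(degenerate.sum())
    if n_deg:
        log.info("angle_map(%s): %d degenerate pixel(s) set to pi/2", em.label, n_deg)
    return AngleMap(
        values=angles.reshape(cube.shape[:2]),
        endmember_label=em.label,
        n_degenerate=n_deg,
    )


def segment_type(am: AngleMap, threshold: float) -> np.ndarray:
    """Binary map: 1 where the angle is strictly below the threshold."""
    if not (0.0 < threshold <= RIGHT_ANGLE + 1e-12):
        raise ConfigurationError("threshold must lie in (0, pi/2]")
    return am.values < threshold


def fill_factor_curve(ref_angle_map: AngleMap, thresholds: np.ndarray) -> FillFactorCurve:
    """f(t) = fraction of reference pixels with angle <= t, per grid point."""
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0 or np.any(np.diff(thresholds) <= 0):
        raise ConfigurationError("threshold grid must be nonempty and increasing")
    beta = np.sort(ref_angle_map.values, axis=None)
    counts = np.searchsorted(beta, thresholds, side="right")
    return FillFactorCurve(thresholds, counts / beta.size, n_pixels=beta.size)


def determine_osca(curve: FillFactorCurve) -> float:
    """Smallest grid threshold with nonzero fill factor.

    On a uniform grid this is the minimum reference angle rounded up to the
    grid; as the grid refines it converges to the minimum angle itself.
    """
    nz = np.flatnonzero(curve.fractions > 0)
    if nz.size == 0:
        raise ConfigurationError("fill factor vanishes over the whole grid")
    return float(curve.thresholds[nz[0]])


def coverage_vs_threshold(am: AngleMap, thresholds: np.ndarray) -> FillFactorCurve:
    """Segmented-area fraction (strict <, matching the segmentation rule).

    Differs from the fill-factor curve only in counting ``angle < t`` rather
    than ``angle <= t``; at pi/2 it equals 1 minus the degenerate fraction.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0 or np.any(np.diff(thresholds) <= 0):
        raise ConfigurationError("threshold grid must be nonempty and increasing")
    alpha = np.sort(am.values, axis=None)
    counts = np.searchsorted(alpha, thresholds, side="left")
    return FillFactorCurve(thresholds, counts / alpha.size, n_pixels=alpha.size)


DEFAULT_THRESHOLD_GRID = np.append(np.arange(0.01, 1.57, 0.01), RIGHT_ANGLE)


def build_library(
    endmembers: Sequence[Endmember],
    ref_cubes: dict[int, ReflectanceCube],
    display_grid: np.ndarray | None = None,
    threshold_overrides: dict[str, float] | None = None,
    fat_labels: Sequence[str] | None = None,
) -> EndmemberLibrary:
    """Assemble the (endmember, OSCA) library against the two reference cubes.

    Non-fat endmembers are scored against reference cube 1 (fat only), fat
    endmembers against cube 2 (fibroadenoma only).  The stored OSCA is
    evaluated on the exact threshold grid formed by the reference angles
    themselves — the grid-step -> 0 limit of the uniform sweep — so
    segmenting the reference cube at its own OSCA yields exactly zero
    positive pixels.  A uniform-grid fill-factor curve is kept for display.
    """
    if 1 not in ref_cubes or 2 not in ref_cubes:
        raise ConfigurationError("reference cubes 1 (fat-only) and 2 (fibroadenoma-only) required")
    display_grid = (
        np.asarray(display_grid, dtype=float) if display_grid is not None
        else DEFAULT_THRESHOLD_GRID
    )
    overrides = threshold_overrides or {}
    fat_set = (
        {lbl.lower() for lbl in fat_labels}
        if fat_labels is not None
        else None
    )

    entries = []
    for em in endmembers:
        is_fat = (
            em.label.lower() in fat_set
            if fat_set is not None
            else em.label.lower().startswith("fat")
        )
        ref_id = 2 if is_fat else 1
        beta = angle_map(ref_cubes[ref_id], em)
        exact_grid = np.unique(np.append(beta.values.ravel(), RIGHT_ANGLE))
        exact_grid = exact_grid[exact_grid > 0]
        osca = determine_osca(fill_factor_curve(beta, exact_grid))
        curve = fill_factor_curve(beta, display_grid)
        threshold = float(overrides.get(em.label, osca))
        entries.append(
            LibraryEntry(
                endmember=em, osca=osca, threshold=threshold,
                reference_id=ref_id, fill_curve=curve,
            )
        )
    return EndmemberLibrary(entries=entries)


def integrate_segmentation(
    cube: ReflectanceCube, lib: EndmemberLibrary
) -> IntegratedSegmentation:
    """Per pixel, among types passing their threshold, assign the min-SCA type.

    Pixels passing no threshold are background (-1).  Exact ties are broken
    toward the earlier library entry and counted.
    """
    if not lib.entries:
        raise ConfigurationError("empty endmember library")
    shape = cube.shape[:2]
    angles = np.stack(
        [angle_map(cube, e.endmember).values for e in lib.entries], axis=0
    )
    thresholds = np.array([e.threshold for e in lib.entries])
    passing = angles < thresholds[:, None, None]
    masked = np.where(passing, angles, np.inf)
    best = masked.min(axis=0)
    winner = masked.argmin(axis=0)  # first minimum wins on ties
    labels = np.where(np.isfinite(best), winner, -1)
    n_ties = int(
        np.logical_and(
            np.isfinite(best), (masked == best).sum(axis=0) > 1
        ).sum()
    )
    if n_ties:
        log.info("integrate_segmentation: %d tied pixel(s) broken by library order", n_ties)
    return IntegratedSegmentation(
        labels=labels,
        label_names=lib.labels(),
        colors=[e.endmember.color for e in lib.entries],
        n_ties=n_ties,
    )
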