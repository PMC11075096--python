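"""Cross-validation between the supervised library and K-means endmembers.

Cluster centroids are matched to library endmembers greedily by ascending
spectral angle; each matched pair is scored by the bandwise residual ratio
``(mu_sup - mu_unsup) / mu_unsup`` (after bringing both spectra to equal
band-mean, since angle-based extraction is scale-free while centroids carry
amplitude) and by the Dice coefficient between the supervised segmentation
mask and the thresholded abundance map.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from hsdfm.datacube import ConfigurationError
from hsdfm.sam import EndmemberLibrary, spectral_angle
from hsdfm.unmix import ClusterResult

log = logging.getLogger(__name__)


@dataclass
class MatchedPair:
    library_label: str
    cluster: int
    angle: float
    max_residual_ratio: float | None = None
    residual_ratio: np.ndarray | None = None
    dice: float | None = None
    passed: bool | None = None


@dataclass
class MatchReport:
    pairs: list[MatchedPair]
    unmatched_clusters: list[int] = field(default_factory=list)
    residual_tolerance: float = 0.02
    dice_floor: float = 0.5

    def pair_for(self, label: str) -> MatchedPair:
        for p in self.pairs:
            if p.library_label == label:
                return p
        raise KeyError(label)

    def all_passed(self) -> bool:
        return all(p.passed for p in self.pairs if p.passed is not None)

    def to_json(self) -> str:
        doc = {
            "format": "hsdfm-crossval-report",
            "residual_tolerance": self.residual_tolerance,
            "dice_floor": self.dice_floor,
            "unmatched_clusters": self.unmatched_clusters,
            "pairs": [
                {
                    "library_label": p.library_label,
                    "cluster": p.cluster,
                    "angle": p.angle,
                    "max_residual_ratio": p.max_residual_ratio,
                    "residual_ratio": (
                        p.residual_ratio.tolist() if p.residual_ratio is not None else None
                    ),
                    "dice": p.dice,
                    "passed": p.passed,
                }
                for p in self.pairs
            ],
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "MatchReport":
        doc = json.loads(text)
        pairs = [
            MatchedPair(
                library_label=d["library_label"],
                cluster=int(d["cluster"]),
                angle=float(d["angle"]),
                max_residual_ratio=d["max_residual_ratio"],
                residual_ratio=(
                    np.array(d["residual_ratio"]) if d["residual_ratio"] is not None else None
                ),
                dice=d["dice"],
                passed=d["passed"],
            )
            for d in doc["pairs"]
        ]
        return cls(
            pairs=pairs,
            unmatched_clusters=list(doc["unmatched_clusters"]),
            residual_tolerance=float(doc["residual_tolerance"]),
            dice_floor=float(doc["dice_floor"]),
        )


def match_endmembers(
    lib: EndmemberLibrary, cr: ClusterResult, max_angle: float = 0.3
) -> MatchReport:
    """Greedy one-to-one pairing of clusters and library endmembers.

    Repeatedly pair the globally closest (library, centroid) couple by
    spectral angle until nothing remains below ``max_angle``.
    """
    if not lib.entries or cr.k == 0:
        raise ConfigurationError("library and cluster result must be nonempty")
    labels = lib.labels()
    angles = np.array(
        [
            [spectral_angle(e.endmember.mu, cr.centroids[c]) for c in range(cr.k)]
            for e in lib.entries
        ]
    )
    pairs: list[MatchedPair] = []
    free_lib = set(range(len(labels)))
    free_clu = set(range(cr.k))
    work = angles.copy()
    while free_lib and free_clu:
        i, c = np.unravel_index(np.argmin(work), work.shape)
        if work[i, c] > max_angle:
            break
        pairs.append(MatchedPair(library_label=labels[i], cluster=int(c), angle=float(work[i, c])))
        free_lib.discard(int(i))
        free_clu.discard(int(c))
        work[i, :] = np.inf
        work[:, c] = np.inf
    return MatchReport(pairs=pairs, unmatched_clusters=sorted(free_clu))


def residual_ratio(
    mu_sup: np.ndarray, mu_unsup: np.ndarray, align_scale: bool = True
) -> tuple[np.ndarray, float]:
    """Bandwise (mu_sup - mu_unsup) / mu_unsup and its maximum absolute value.

    With ``align_scale`` (default) both spectra are first normalized to unit
    band-mean, so the ratio measures shape disagreement only; disabling it
    compares the raw amplitudes exactly as given.
    """
    mu_sup = np.asarray(mu_sup, dtype=float)
    mu_unsup = np.asarray(mu_unsup, dtype=float)
    if mu_sup.shape != mu_unsup.shape:
        raise ConfigurationError("spectra must share one grid")
    if np.any(mu_unsup <= 0):
        raise ConfigurationError("unsupervised spectrum must be strictly positive")
    if align_scale:
        mu_sup = mu_sup / mu_sup.mean()
        mu_unsup = mu_unsup / mu_unsup.mean()
    ratio = (mu_sup - mu_unsup) / mu_unsup
    return ratio, float(np.max(np.abs(ratio)))


def colocalization_score(
    seg_mask: np.ndarray,
    abundance_raster: np.ndarray,
    abundance_threshold: float | None = None,
) -> float:
    """Dice coefficient between a segmentation mask and a thresholded abundance map.

    The abundance mask is ``raster >= threshold`` (default threshold: half
    the raster's maximum).  Two empty masks give 0, logged as undefined.
    """
    seg_mask = np.asarray(seg_mask, dtype=bool)
    abundance_raster = np.asarray(abundance_raster, dtype=float)
    if seg_mask.shape != abundance_raster.shape:
        raise ConfigurationError("mask and abundance raster shapes differ")
    if abundance_threshold is None:
        abundance_threshold = 0.5 * abundance_raster.max()
    ab_mask = abundance_raster >= abundance_threshold
    a, b = seg_mask.sum(), ab_mask.sum()
    if a + b == 0:
        log.warning("colocalization_score: both masks empty; Dice undefined, returning 0")
        return 0.0
    return float(2.0 * np.logical_and(seg_mask, ab_mask).sum() / (a + b))


def validate_library(
    lib: EndmemberLibrary,
    cr: ClusterResult,
    seg_masks: dict[str, np.ndarray],
    abundance_rasters: dict[int, np.ndarray],
    max_angle: float = 0.3,
    residual_tolerance: float = 0.02,
    dice_floor: float = 0.5,
    align_scale: bool = True,
) -> MatchReport:
    """Full cross-validation report: pairing, residual ratios, Dice, verdicts.

    ``seg_masks`` maps library labels to binary supervised segmentation
    rasters; ``abundance_rasters`` maps cluster indices to abundance maps on
    the same raster.
    """
    report = match_endmembers(lib, cr, max_angle=max_angle)
    report.residual_tolerance = residual_tolerance
    report.dice_floor = dice_floor
    for pair in report.pairs:
        mu_sup = lib[pair.library_label].endmember.mu
        mu_unsup = cr.centroids[pair.cluster]
        pair.residual_ratio, pair.max_residual_ratio = residual_ratio(
            mu_sup, mu_unsup, align_scale=align_scale
        )
        if pair.library_label in seg_masks and pair.cluster in abundance_rasters:
            pair.dice = colocalization_score(
                seg_masks[pair.library_label], abundance_rasters[pair.cluster]
            )
            pair.passed = (
                pair.max_residual_ratio < residual_tolerance and pair.dice >= dice_floor
            )
        else:
            pair.passed = pair.max_residual_ratio < residual_tolerance
    return report
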