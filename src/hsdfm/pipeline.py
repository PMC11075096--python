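"""End-to-end runs: simulate -> normalize -> library -> segment -> unmix -> crossval.

A ``RunConfig`` fully determines a run: the synthetic scene recipe, the
flattening and threshold options, the K-means settings and the seed.  Each
run produces a manifest with the config hash, seed and content hashes of
its outputs, so a rerun with the same config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from hsdfm import io as hsio
from hsdfm.crossval import MatchReport, validate_library
from hsdfm.datacube import ConfigurationError, ReflectanceCube, flatten_cube, normalize_cube
from hsdfm.sam import (
    Endmember,
    EndmemberLibrary,
    IntegratedSegmentation,
    build_library,
    extract_endmember,
    integrate_segmentation,
)
from hsdfm.synthetic import (
    Region,
    SceneSpec,
    SyntheticScene,
    generate_cube,
    generate_reference_cube,
    make_tissue_templates,
)
from hsdfm.unmix import (
    AbundanceMatrix,
    ClusterRanking,
    ClusterResult,
    PixelMatrix,
    abundance_to_maps,
    kmeans_endmembers,
    nnls_abundances,
    rank_clusters,
    stack_cubes,
)

log = logging.getLogger(__name__)

# display colors per tissue label (RGB in [0, 1])
PALETTE: dict[str, tuple[float, float, float]] = {
    "blood": (1.0, 0.0, 0.0),
    "fat": (1.0, 1.0, 0.0),
    "ICT1": (0.0, 0.0, 1.0),
    "ICTf": (0.3, 0.6, 1.0),
    "ICTb": (0.0, 0.3, 0.8),
    "epithelium": (0.0, 1.0, 1.0),
    "IDC": (0.5, 0.0, 0.5),
    "IMC": (1.0, 1.0, 1.0),
    "ILC": (0.0, 0.5, 0.0),
    "phyllodes": (1.0, 0.6, 0.8),
}

# the five tissue types used in the standard synthetic study scene
DEFAULT_SCENE_LABELS = ["blood", "fat", "ICT1", "IDC", "IMC"]
CARCINOMA_LABELS = ["IDC", "IMC", "ILC", "phyllodes"]


def pure_stripe_regions(shape: tuple[int, int]) -> list[dict]:
    """Five pure horizontal stripes (blood, fat, ICT, IDC, IMC) covering the frame.

    Every template holds ~20% of the pixels as pure pixels; no sub-pixel
    mixing anywhere (the exact-recovery reference scene).
    """
    m, n = shape
    bounds = np.linspace(0, m, len(DEFAULT_SCENE_LABELS) + 1).round().astype(int)
    return [
        {"rows": [int(bounds[i]), int(bounds[i + 1])], "cols": [0, n],
         "weights": {lbl: 1.0}}
        for i, lbl in enumerate(DEFAULT_SCENE_LABELS)
    ]


# geometry of the mixed boundary zones in the standard study scene
TRANSITION_ROWS_PER_SIDE = 2
TRANSITION_COLUMN_FRACTION = 1 / 3


def default_scene_regions(shape: tuple[int, int]) -> list[dict]:
    """The standard study scene: five tissue stripes with mixed boundaries.

    Stripe cores are pure (each tissue keeps well over 10% of the pixels as
    pure pixels).  At each internal boundary a four-row patch spanning a
    third of the columns carries a linear mixing gradient between the
    adjacent tissues, emulating the sub-pixel mixing found at real tissue
    interfaces; the mixed pixels also bridge the spectral clouds so that
    randomly initialized K-means reliably discovers all five tissues.
    """
    m, n = shape
    labels = DEFAULT_SCENE_LABELS
    bounds = np.linspace(0, m, len(labels) + 1).round().astype(int)
    rside = TRANSITION_ROWS_PER_SIDE
    cpix = int(round(n * TRANSITION_COLUMN_FRACTION))
    regions: list[dict] = []
    for i, lbl in enumerate(labels):
        r0 = int(bounds[i]) + (rside if i > 0 else 0)
        r1 = int(bounds[i + 1]) - (rside if i < len(labels) - 1 else 0)
        regions.append({"rows": [r0, r1], "cols": [0, n], "weights": {lbl: 1.0}})
    for i in range(len(labels) - 1):
        b = int(bounds[i + 1])
        upper, lower = labels[i], labels[i + 1]
        k = 2 * rside
        for j in range(k):
            w = 1.0 - (j + 0.5) / k
            row = b - rside + j
            regions.append({
                "rows": [row, row + 1], "cols": [0, cpix],
                "weights": {upper: round(w, 4), lower: round(1 - w, 4)},
            })
            # the rest of the boundary row stays pure (sharp interface)
            regions.append({
                "rows": [row, row + 1], "cols": [cpix, n],
                "weights": {(upper if j < rside else lower): 1.0},
            })
    return regions


@dataclass
class RunConfig:
    """Serializable description of one end-to-end run."""

    shape: tuple[int, int] = (128, 128)
    regions: list[dict] | None = None       # None -> default_scene_regions(shape)
    noise_sd: float = 0.02
    illumination_amplitude: float = 0.0
    seed: int = 0
    flatten: bool = False
    smoothing_scale: float = 50.0
    k: int = 5
    restarts: int = 10
    threshold_overrides: dict = field(default_factory=dict)
    roi_erosion: int = 3
    reference_labels: tuple[str, str] = ("fat", "ICTf")  # (fat-only, fibroadenoma-only)
    outdir: str | None = None

    def scene_spec(self) -> SceneSpec:
        regions = self.regions or default_scene_regions(tuple(self.shape))
        return SceneSpec(
            shape=tuple(self.shape),
            regions=[
                Region(tuple(r["rows"]), tuple(r["cols"]), dict(r["weights"]))
                for r in regions
            ],
            noise_sd=self.noise_sd,
            illumination_amplitude=self.illumination_amplitude,
            seed=self.seed,
        )

    def canonical_json(self) -> str:
        doc = asdict(self)
        doc.pop("outdir")
        return json.dumps(doc, sort_keys=True, default=list)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**doc)
        cfg.shape = tuple(cfg.shape)
        cfg.reference_labels = tuple(cfg.reference_labels)
        return cfg


def _content_hash(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        if isinstance(a, np.ndarray):
            h.update(np.ascontiguousarray(a).tobytes())
        else:
            h.update(str(a).encode())
    return h.hexdigest()


def _normalized_scene_cube(scene: SyntheticScene, config: RunConfig) -> ReflectanceCube:
    cube = normalize_cube(scene.sample, scene.dark, scene.reference)
    if config.flatten:
        cube = flatten_cube(cube, config.smoothing_scale)
    return cube


def _reference_cubes(config: RunConfig, templates) -> dict[int, ReflectanceCube]:
    by_label = {t.label: t for t in templates}
    refs: dict[int, ReflectanceCube] = {}
    for ref_id, label in zip((1, 2), config.reference_labels):
        if label not in by_label:
            raise ConfigurationError(
                f"run_supervised: reference tissue {label!r} is not a known template"
            )
        spec = SceneSpec(
            shape=(64, 64), regions=[], noise_sd=config.noise_sd,
            seed=config.seed + 9000 + ref_id,
        )
        ref_scene = generate_reference_cube(by_label[label], spec)
        refs[ref_id] = normalize_cube(ref_scene.sample, ref_scene.dark, ref_scene.reference)
    return refs


def derive_rois(labels: np.ndarray, erosion: int) -> dict[int, np.ndarray]:
    """Interior ROI per planted pure region (labels raster, -1 = none).

    Each region mask is binary-eroded so ROI pixels sit away from region
    borders, as a hand-drawn annotation would; if erosion empties a small
    region the full mask is kept.
    """
    rois = {}
    for idx in np.unique(labels):
        if idx < 0:
            continue
        mask = labels == idx
        if erosion > 0:
            eroded = ndimage.binary_erosion(mask, iterations=erosion)
            mask = eroded if eroded.any() else mask
        rois[int(idx)] = mask
    return rois


@dataclass
class SupervisedRun:
    config: RunConfig
    scene: SyntheticScene
    cube: ReflectanceCube
    endmembers: list[Endmember]
    library: EndmemberLibrary
    segmentation: IntegratedSegmentation
    manifest: dict


@dataclass
class UnsupervisedRun:
    config: RunConfig
    scene: SyntheticScene
    cube: ReflectanceCube
    pixels: PixelMatrix
    clusters: ClusterResult
    ranking: ClusterRanking
    abundance: AbundanceMatrix
    manifest: dict


@dataclass
class CrossvalRun:
    supervised: SupervisedRun
    unsupervised: UnsupervisedRun
    report: MatchReport


def run_supervised(config: RunConfig) -> SupervisedRun:
    """Extract endmembers, build the OSCA library, integrate the segmentation."""
    templates = make_tissue_templates()
    scene = generate_cube(config.scene_spec(), templates)
    cube = _normalized_scene_cube(scene, config)

    rois = derive_rois(scene.labels, config.roi_erosion)
    if not rois:
        raise ConfigurationError("run_supervised: scene contains no pure region to annotate")
    endmembers = [
        extract_endmember(
            cube, roi, scene.label_names[idx],
            color=PALETTE.get(scene.label_names[idx], (0.7, 0.7, 0.7)),
        )
        for idx, roi in sorted(rois.items())
    ]
    refs = _reference_cubes(config, templates)
    library = build_library(
        endmembers, refs, threshold_overrides=config.threshold_overrides
    )
    segmentation = integrate_segmentation(cube, library)

    manifest = {
        "stage": "supervised",
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "library_version": library.version,
        "content_hashes": {
            "cube": _content_hash(cube.values),
            "library": _content_hash(library.to_json()),
            "segmentation": _content_hash(segmentation.labels),
        },
    }
    run = SupervisedRun(config, scene, cube, endmembers, library, segmentation, manifest)
    if config.outdir:
        _write_supervised(run, Path(config.outdir))
    return run


def run_unsupervised(config: RunConfig, extra_cubes: list[ReflectanceCube] | None = None) -> UnsupervisedRun:
    """K-means endmember discovery plus NNLS abundance maps.

    ``extra_cubes`` are stacked with the scene cube before clustering, the
    way contiguous fields of view are combined.
    """
    templates = make_tissue_templates()
    scene = generate_cube(config.scene_spec(), templates)
    cube = _normalized_scene_cube(scene, config)
    pixels = stack_cubes([cube, *(extra_cubes or [])])
    clusters = kmeans_endmembers(
        pixels, k=config.k, restarts=config.restarts, seed=config.seed + 70001
    )
    ranking = rank_clusters(clusters, pixels)
    abundance = nnls_abundances(pixels, clusters.centroids.T)

    manifest = {
        "stage": "unsupervised",
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "content_hashes": {
            "cube": _content_hash(cube.values),
            "centroids": _content_hash(clusters.centroids),
            "abundance": _content_hash(abundance.M),
        },
    }
    run = UnsupervisedRun(config, scene, cube, pixels, clusters, ranking, abundance, manifest)
    if config.outdir:
        _write_unsupervised(run, Path(config.outdir))
    return run


def run_crossval(config: RunConfig, **validate_kwargs) -> CrossvalRun:
    """Match K-means centroids to the supervised library and score agreement."""
    sup = run_supervised(config)
    unsup = run_unsupervised(config)
    seg_masks = {
        label: sup.segmentation.mask(label) for label in sup.segmentation.label_names
    }
    abundance_rasters = {
        ci: unsup.pixels.unstack(unsup.abundance.M[:, ci])[0]
        for ci in range(unsup.clusters.k)
    }
    report = validate_library(
        sup.library, unsup.clusters, seg_masks, abundance_rasters, **validate_kwargs
    )
    run = CrossvalRun(sup, unsup, report)
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.save(outdir / "crossval_report.json")
    return run


def carcinoma_residual_study(
    base_seed: int = 0,
    n_seeds: int = 10,
    shape: tuple[int, int] = (128, 128),
    noise_sd: float = 0.02,
    k: int = 5,
    restarts: int = 10,
) -> dict:
    """Supervised-vs-unsupervised agreement on planted carcinoma endmembers.

    For each seed, a synthetic scene with two carcinoma (IDC, IMC) and three
    normal templates (each holding at least 10% of the pixels as pure
    pixels) is analyzed by both routes; the K-means centroids are matched to
    the supervised library by spectral angle and the bandwise residual
    ratio (supervised minus unsupervised over unsupervised, after equal
    band-mean normalization) is evaluated for the carcinoma pairs.  Returns
    per-seed and worst-case maxima of the absolute residual ratio.
    """
    per_seed: dict[int, float] = {}
    details = []
    for i in range(n_seeds):
        seed = base_seed + i
        cfg = RunConfig(shape=shape, noise_sd=noise_sd, seed=seed,
                        k=k, restarts=restarts)
        run = run_crossval(cfg)
        worst = 0.0
        for label in CARCINOMA_LABELS:
            try:
                pair = run.report.pair_for(label)
            except KeyError:
                continue
            worst = max(worst, pair.max_residual_ratio)
            details.append({"seed": seed, "label": label,
                            "cluster": pair.cluster,
                            "max_residual_ratio": pair.max_residual_ratio})
        per_seed[seed] = worst
    return {
        "per_seed_max": per_seed,
        "worst_case": max(per_seed.values()),
        "n_pixels_per_scene": int(shape[0] * shape[1]),
        "pairs": details,
    }


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _finish_manifest(manifest: dict, outdir: Path, files: list[Path]) -> None:
    manifest["files"] = {p.name: _sha256_file(p) for p in files}
    (outdir / f"manifest_{manifest['stage']}.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )


def _write_supervised(run: SupervisedRun, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    lib_path = outdir / "library.json"
    run.library.save(lib_path)
    files.append(lib_path)
    seg_path = outdir / "segmentation_labels.tif"
    hsio.tifffile.imwrite(seg_path, run.segmentation.labels.astype(np.int16))
    files.append(seg_path)
    cube_path = outdir / "reflectance.tif"
    hsio.save_reflectance(cube_path, run.cube)
    files.append(cube_path)
    _finish_manifest(run.manifest, outdir, files)


def _write_unsupervised(run: UnsupervisedRun, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    cent_path = outdir / "centroids.tsv"
    header = "# K-means centroid spectra; one column per cluster, rows are bands (nm)"
    lines = [header]
    for j, wl in enumerate(run.pixels.grid.wavelengths):
        row = "\t".join(f"{run.clusters.centroids[i, j]!r}" for i in range(run.clusters.k))
        lines.append(f"{wl:g}\t{row}")
    cent_path.write_text("\n".join(lines) + "\n")
    files.append(cent_path)
    rank_path = outdir / "cluster_ranking.json"
    rank_path.write_text(
        json.dumps(
            {
                "order": run.ranking.order.tolist(),
                "variance_shares": run.ranking.shares.tolist(),
                "objective": run.clusters.objective,
            },
            indent=1,
        )
    )
    files.append(rank_path)
    maps = abundance_to_maps(run.abundance, run.pixels)
    for ci, rasters in enumerate(maps):
        p = outdir / f"abundance_cluster{ci}.tif"
        hsio.tifffile.imwrite(p, rasters[0].astype(np.float32))
        files.append(p)
    _finish_manifest(run.manifest, outdir, files)
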