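"""End-to-end pipeline orchestration, file formats and provenance.

``run_pipeline`` chains the full analysis — simulate (or load) TCSPC stacks,
fit per-pixel lifetimes, segment granules on the intensity image, convert
granule lifetimes to viscosities through the calibration curve, and fit the
viscosity mixture — and returns a ``PopulationReport`` plus a ``RunManifest``
recording configuration hash, per-stage timings and warning counters.  Two
runs from the same config produce byte-identical reports.

File formats: TCSPC stacks are OME-TIFF (time bins on the T axis) with a JSON
sidecar carrying optics and seed; lifetime images are 3-plane float32 TIFFs
(lifetime_ns, intensity, chi2_red); granule tables are CSV; reports and
calibration curves are JSON.  Coordinates are (row, col), 0-based.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .decay_fit import LifetimeImage, fit_image
from .flim_synth import (
    GroundTruth,
    OpticalConfig,
    TCSPCImage,
    default_dataset,
)
from .granule_segmentation import (
    GranuleRecord,
    classify_clusters,
    compute_features,
    measure_granules,
    segment,
    train_classifier,
)
from .population_analysis import (
    MixtureFit,
    ViscosityDistribution,
    compare_groups,
    granule_viscosities,
    select_k,
)
from .rotor_calibration import CalibrationCurve, default_calibration

__all__ = [
    "PipelineConfig",
    "PopulationReport",
    "RunManifest",
    "FormatError",
    "StageError",
    "run_pipeline",
    "write_tcspc",
    "read_tcspc",
    "write_lifetime_image",
    "read_lifetime_image",
    "export_report",
    "granules_to_frame",
]

SCHEMA_VERSION = "1.0"


class FormatError(ValueError):
    """A file does not match the expected on-disk layout."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run; JSON round-trip stable."""

    group: str = "nonCF"
    n_images: int = 12
    seed: int = 1
    frame: Tuple[int, int] = (128, 128)
    n_granules_per_image: int = 50
    photons_per_granule_pixel: float = 500.0
    # optics
    n_time_bins: int = 256
    bin_width: float = 50.0 / 256.0
    rep_period: float = 50.0
    irf_fwhm: float = 0.2
    irf_center: float = 1.0
    # decay fitting
    max_components: int = 2
    min_counts: float = 100.0
    chi2_threshold: float = 0.2
    binning: int = 0
    # calibration (inline constants; a curve file may override via CLI)
    calibration: Dict = field(default_factory=lambda: default_calibration().to_dict())
    # segmentation
    min_area: float = 9.0
    circularity_min: float = 0.8
    n_label_pixels_per_class: int = 1500
    # population analysis
    k_max: int = 3
    summary_method: str = "viscosity_of_mean"

    def optics(self) -> OpticalConfig:
        return OpticalConfig(
            n_time_bins=self.n_time_bins,
            bin_width=self.bin_width,
            rep_period=self.rep_period,
            irf_fwhm=self.irf_fwhm,
            irf_center=self.irf_center,
        )

    def curve(self) -> CalibrationCurve:
        return CalibrationCurve.from_dict(self.calibration)

    def to_json(self, path=None) -> str:
        d = asdict(self)
        d["frame"] = list(d["frame"])
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            d = json.loads(Path(source).read_text())
        else:
            d = json.loads(source)
        d["frame"] = tuple(d.get("frame", (128, 128)))
        return cls(**d)

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class PopulationReport:
    """Selected mixture and provenance for one analysed group."""

    group: str
    selected: MixtureFit
    n_granules: int
    n_rejected: Dict[str, int]
    n_excluded: int
    cluster_comparison: Optional[dict]
    config_hash: str
    seed: int
    schema_version: str = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "group": self.group,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "n_granules": self.n_granules,
            "n_rejected": dict(sorted(self.n_rejected.items())),
            "n_excluded": self.n_excluded,
            "mixture": _mixture_to_dict(self.selected),
            "cluster_comparison": self.cluster_comparison,
        }


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    stages: List[dict] = field(default_factory=list)
    warnings: Dict[str, int] = field(default_factory=dict)
    outputs: Dict[str, str] = field(default_factory=dict)  # path -> sha256

    def add_stage(self, name: str, seconds: float, **info):
        self.stages.append({"name": name, "seconds": round(seconds, 3), **info})

    def to_dict(self) -> dict:
        return asdict(self)


def _mixture_to_dict(fit: MixtureFit) -> dict:
    return {
        "k": fit.k,
        "n": fit.n,
        "means_cP": [float(m) for m in fit.means],
        "sds_cP": [float(s) for s in fit.sds],
        "weights": [float(w) for w in fit.weights],
        "mean_standard_errors_cP": [float(s) for s in fit.mean_standard_errors],
        "log_likelihood": float(fit.log_likelihood),
        "bic": float(fit.bic),
        "converged": bool(fit.converged),
        "flagged": bool(fit.flagged),
        "se_method": fit.se_method,
    }


def _comparison_to_dict(cmp: dict) -> dict:
    return {
        "group_a": cmp["group_a"],
        "group_b": cmp["group_b"],
        "fit_a": _mixture_to_dict(cmp["fit_a"]),
        "fit_b": _mixture_to_dict(cmp["fit_b"]),
        "matched_components": cmp["matched_components"],
        "ks_distance": cmp["ks_distance"],
        "n_a": cmp["n_a"],
        "n_b": cmp["n_b"],
    }


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------
def _training_labels(truth: GroundTruth, n_per_class: int, seed: int) -> np.ndarray:
    """Sparse training labels sampled from ground truth (1 granule, 2 background).

    Stands in for the interactive scribbles a user would draw when training
    the pixel classifier on real data.
    """
    rng = np.random.default_rng(seed)
    lab = np.zeros(truth.granule_label_map.shape, dtype=np.uint8)
    fg = np.flatnonzero(truth.granule_label_map > 0)
    bg = np.flatnonzero(truth.granule_label_map == 0)
    fg_sel = rng.choice(fg, size=min(n_per_class, fg.size), replace=False)
    bg_sel = rng.choice(bg, size=min(n_per_class, bg.size), replace=False)
    lab.ravel()[fg_sel] = 1
    lab.ravel()[bg_sel] = 2
    return lab


def run_pipeline(
    config: PipelineConfig,
    dataset: Optional[List[Tuple[TCSPCImage, GroundTruth]]] = None,
) -> Tuple[PopulationReport, RunManifest]:
    """Execute simulate -> fit -> segment -> map -> analyze for one group.

    A pre-built ``dataset`` (e.g. loaded from disk) may be supplied to skip
    the simulation stage.  Raises ``StageError`` naming the failing stage.
    """
    manifest = RunManifest(config_hash=config.hash(), package_version=__version__)
    curve = config.curve()
    optics = config.optics()

    stage = "simulate"
    t0 = time.perf_counter()
    try:
        if dataset is None:
            dataset = default_dataset(
                config.group,
                n_images=config.n_images,
                seed=config.seed,
                frame=config.frame,
                n_granules_per_image=config.n_granules_per_image,
                photons_per_granule_pixel=config.photons_per_granule_pixel,
                optics=optics,
                calibration=curve,
            )
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError(stage, e) from e
    manifest.add_stage(stage, time.perf_counter() - t0, n_images=len(dataset))

    stage = "train_classifier"
    t0 = time.perf_counter()
    try:
        stack0 = compute_features(dataset[0][0].intensity)
        labels0 = _training_labels(
            dataset[0][1], config.n_label_pixels_per_class, seed=config.seed
        )
        classifier = train_classifier([stack0], [labels0], seed=config.seed)
    except Exception as e:
        raise StageError(stage, e) from e
    manifest.add_stage(
        stage,
        time.perf_counter() - t0,
        holdout_accuracy=classifier.holdout_accuracy,
        n_labeled=classifier.n_labeled,
    )

    stage = "fit_lifetimes"
    t0 = time.perf_counter()
    lifetime_images: List[LifetimeImage] = []
    try:
        for img, _ in dataset:
            lifetime_images.append(
                fit_image(
                    img,
                    min_counts=config.min_counts,
                    binning=config.binning,
                    max_M=config.max_components,
                    irf_handling="gaussian",
                    chi2_threshold=config.chi2_threshold,
                )
            )
    except Exception as e:
        raise StageError(stage, e) from e
    manifest.add_stage(
        stage,
        time.perf_counter() - t0,
        n_pixels_fitted=sum(li.n_fitted for li in lifetime_images),
        n_pixels_skipped=sum(li.n_skipped for li in lifetime_images),
    )

    stage = "segment"
    t0 = time.perf_counter()
    all_records: List[GranuleRecord] = []
    n_rejected: Dict[str, int] = {}
    per_image_records: List[List[GranuleRecord]] = []
    try:
        for idx, ((img, _), li) in enumerate(zip(dataset, lifetime_images)):
            mask = segment(
                classifier,
                li.intensity,
                min_area=config.min_area,
                circularity_min=config.circularity_min,
            )
            classify_clusters(mask)
            records = measure_granules(mask)
            for rec in records:
                rec.granule_id = idx * 100000 + rec.granule_id
                if rec.cluster_id is not None:
                    rec.cluster_id = idx * 100000 + rec.cluster_id
            for reason in mask.rejected.values():
                n_rejected[reason] = n_rejected.get(reason, 0) + 1
            per_image_records.append(records)
            all_records.extend(records)
    except Exception as e:
        raise StageError(stage, e) from e
    manifest.add_stage(
        stage,
        time.perf_counter() - t0,
        n_accepted=len(all_records),
        n_rejected=sum(n_rejected.values()),
    )

    stage = "map_viscosity"
    t0 = time.perf_counter()
    values: List[float] = []
    n_excluded = 0
    try:
        for records, li in zip(per_image_records, lifetime_images):
            if not records:
                continue
            try:
                dist_i = granule_viscosities(
                    records, li, curve, method=config.summary_method, group=config.group
                )
            except ValueError:
                n_excluded += len(records)
                continue
            values.extend(dist_i.values.tolist())
            n_excluded += dist_i.n_excluded
        if not values:
            raise ValueError("no granule viscosities survived the pipeline")
        dist = ViscosityDistribution(
            values=np.array(values), group=config.group, n_excluded=n_excluded
        )
    except StageError:
        raise
    except Exception as e:
        raise StageError(stage, e) from e
    manifest.add_stage(stage, time.perf_counter() - t0, n_granules=dist.n, n_excluded=n_excluded)

    stage = "analyze"
    t0 = time.perf_counter()
    try:
        selected = select_k(dist, k_max=config.k_max, seed=config.seed)
        clustered = [r.summary_viscosity for r in all_records if r.clustered and r.summary_viscosity is not None]
        individual = [r.summary_viscosity for r in all_records if not r.clustered and r.summary_viscosity is not None]
        cluster_cmp = None
        if len(clustered) >= 10 and len(individual) >= 10:
            cluster_cmp = _comparison_to_dict(
                compare_groups(
                    ViscosityDistribution(np.array(clustered), group="clustered"),
                    ViscosityDistribution(np.array(individual), group="individual"),
                    k_max=config.k_max,
                    seed=config.seed,
                )
            )
    except Exception as e:
        raise StageError(stage, e) from e
    manifest.add_stage(stage, time.perf_counter() - t0, selected_k=selected.k)

    manifest.warnings = {
        "pixels_below_min_counts": int(sum(li.n_skipped for li in lifetime_images)),
        "granules_rejected": int(sum(n_rejected.values())),
        "granules_excluded": int(n_excluded),
    }
    report = PopulationReport(
        group=config.group,
        selected=selected,
        n_granules=dist.n,
        n_rejected=n_rejected,
        n_excluded=n_excluded,
        cluster_comparison=cluster_cmp,
        config_hash=config.hash(),
        seed=config.seed,
    )
    # stash granule records for exporters / downstream analysis
    report.records = all_records  # type: ignore[attr-defined]
    return report, manifest


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------
def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_tcspc(img: TCSPCImage, path) -> Path:
    """OME-TIFF (axes TYX) plus JSON sidecar with optics and seed."""
    path = Path(path)
    tifffile.imwrite(path, img.counts, ome=True, metadata={"axes": "TYX"})
    sidecar = {
        "optics": asdict(img.optics),
        "seed": img.seed,
        "schema_version": SCHEMA_VERSION,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_tcspc(path) -> TCSPCImage:
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing sidecar {side.name} next to {path.name}")
    meta = json.loads(side.read_text())
    counts = tifffile.imread(path)
    counts = np.squeeze(counts)
    if counts.ndim != 3:
        raise FormatError(f"{path.name}: expected a TYX stack, got shape {counts.shape}")
    optics = OpticalConfig(**meta["optics"])
    if counts.shape[0] != optics.n_time_bins:
        raise FormatError(
            f"{path.name}: T axis ({counts.shape[0]}) does not match sidecar n_time_bins ({optics.n_time_bins})"
        )
    return TCSPCImage(counts=counts, optics=optics, seed=meta.get("seed"))


def write_lifetime_image(li: LifetimeImage, path) -> Path:
    """3-plane float32 TIFF (lifetime_ns, intensity, chi2_red) + JSON report."""
    path = Path(path)
    planes = np.stack(
        [li.mean_lifetime, li.intensity.astype(float), li.chi2_red]
    ).astype(np.float32)
    tifffile.imwrite(path, planes, photometric="minisblack")
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "planes": ["lifetime_ns", "intensity", "chi2_red"],
                "min_counts": li.min_counts,
                "n_fitted": li.n_fitted,
                "n_skipped": li.n_skipped,
                "schema_version": SCHEMA_VERSION,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return path


def read_lifetime_image(path) -> LifetimeImage:
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing sidecar {side.name} next to {path.name}")
    meta = json.loads(side.read_text())
    planes = tifffile.imread(path).astype(float)
    return LifetimeImage(
        mean_lifetime=planes[0],
        intensity=planes[1],
        chi2_red=planes[2],
        min_counts=meta["min_counts"],
        n_fitted=meta.get("n_fitted", 0),
        n_skipped=meta.get("n_skipped", 0),
    )


def granules_to_frame(records: List[GranuleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "granule_id": r.granule_id,
                "row": r.centroid[0],
                "col": r.centroid[1],
                "area_px2": r.area,
                "perimeter_px": r.perimeter,
                "circularity": r.circularity,
                "eq_diameter_px": r.equivalent_diameter,
                "clustered": r.clustered,
                "cluster_id": r.cluster_id,
                "n_defined_pixels": r.n_defined_pixels,
                "summary_lifetime_ns": r.summary_lifetime,
                "summary_viscosity_cP": r.summary_viscosity,
            }
            for r in records
        ]
    )


def export_report(report: PopulationReport, out_dir) -> Dict[str, Path]:
    """Write report JSON, granule CSV and a histogram-with-fit figure."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: Dict[str, Path] = {}

    report_path = out / f"report_{report.group}.json"
    report_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    files["report"] = report_path

    records = getattr(report, "records", [])
    csv_path = out / f"granules_{report.group}.csv"
    granules_to_frame(records).to_csv(csv_path, index=False)
    files["granules"] = csv_path

    values = np.array(
        [r.summary_viscosity for r in records if r.summary_viscosity is not None]
    )
    if values.size:
        files["plot"] = _plot_distribution(
            values, report.selected, out / f"viscosity_{report.group}.png", report.group
        )
    return files


def _plot_distribution(values, fit: MixtureFit, path: Path, group: str) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import norm

    fig, ax = plt.subplots(figsize=(6, 4))
    counts, edges = np.histogram(values, bins="fd")
    width = edges[1] - edges[0]
    ax.bar(edges[:-1], counts, width=width, align="edge", color="0.8", edgecolor="0.5")
    xs = np.linspace(values.min() - 50, values.max() + 50, 400)
    total = np.zeros_like(xs)
    comp_colors = ["green", "red", "purple"]
    for i in range(fit.k):
        dens = fit.weights[i] * norm.pdf(xs, fit.means[i], fit.sds[i])
        scaled = dens * fit.n * width
        total += scaled
        if fit.k > 1:
            ax.plot(xs, scaled, color=comp_colors[i % 3], lw=1.5,
                    label=f"population {i + 1}: {fit.means[i]:.0f} cP")
    ax.plot(xs, total, color="blue", lw=2, label="overall fit")
    ax.set_xlabel("viscosity (cP)")
    ax.set_ylabel("granule count")
    ax.set_title(f"Intragranular viscosity — {group} (N={fit.n})")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
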