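"""End-to-end orchestration: simulate -> preprocess -> filter -> segment ->
refine -> network labelling -> evaluate.

The pipeline is driven by a nested config (YAML-friendly dict) that is
validated up front — unknown keys are rejected by name. A single global
seed fans out to per-stage seeds via a fixed rule (``seed + stage index``)
so any stage can be reproduced in isolation. Every artifact written to the
output directory is listed in exactly one entry of the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np

from . import cube as hsi
from .phantom import PhantomSpec, generate_phantom, phantom_to_files
from .filters import FrostParams, filter_cube
from .firefly import FireflyParams, select_k
from .segment import KMeansParams, kmeans_segment, knn_refine, map_regions
from .mfnn import MFNNConfig, mfnn_train, label_map_from_segments, save_model
from .metrics import psnr, mae_labels, match_labels, classification_metrics

logger = logging.getLogger("hsimap.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "config_from_dict",
            "default_config"]

#: Stage order and seed offsets (global seed + offset).
STAGES = ("simulate", "preprocess", "filter", "segment", "refine", "label",
          "evaluate")


def _reject_unknown(section: str, given: dict, allowed: set) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(
            f"unknown config key(s) in section {section!r}: {sorted(unknown)}"
        )


@dataclass
class PhantomSection:
    height: int = 64
    width: int = 64
    n_bands: int = 16
    wavelength_range: tuple = (400.0, 1300.0)
    n_classes: int = 3
    region_geometry: str = "blobs"
    intra_class_sd: float = 0.02
    speckle_looks: float | None = 4.0


@dataclass
class FilterSection:
    enabled: bool = True
    mode: str = "frost"
    window_half: int = 2
    damping: float = 2.0
    border_mode: str = "reflect"
    noise_cv: float = 0.5


@dataclass
class FireflySection:
    auto_k: bool = True
    kmin: int = 2
    kmax: int = 5
    n_fireflies: int = 15
    max_generations: int = 20
    alpha: float = 0.2
    alpha_decay: float = 0.97
    beta0: float = 1.0
    gamma: float = 1.0


@dataclass
class KMeansSection:
    k: int = 3
    max_iter: int = 50
    min_error: float = 1e-3
    init: str = "kmeans++"
    n_restarts: int = 5
    min_cluster_frac: float = 0.005


@dataclass
class KNNSection:
    enabled: bool = True
    k_nn: int = 9
    mode: str = "spatial"


@dataclass
class MFNNSection:
    enabled: bool = True
    hidden_sizes: tuple = (16,)
    learning_rate: float = 0.5
    epochs: int = 150
    batch_size: int | None = None
    train_fraction: float = 0.80


@dataclass
class MetricsSection:
    psnr_max_value: float = 1.0
    positive_class: int | None = None


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "hsimap_run"
    phantom: PhantomSection = field(default_factory=PhantomSection)
    filter: FilterSection = field(default_factory=FilterSection)
    firefly: FireflySection = field(default_factory=FireflySection)
    kmeans: KMeansSection = field(default_factory=KMeansSection)
    knn: KNNSection = field(default_factory=KNNSection)
    mfnn: MFNNSection = field(default_factory=MFNNSection)
    metrics: MetricsSection = field(default_factory=MetricsSection)

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) + STAGES.index(stage)


_SECTION_TYPES = {
    "phantom": PhantomSection, "filter": FilterSection,
    "firefly": FireflySection, "kmeans": KMeansSection, "knn": KNNSection,
    "mfnn": MFNNSection, "metrics": MetricsSection,
}


def config_from_dict(raw: dict) -> PipelineConfig:
    """Build a validated config from a nested dict (e.g. parsed YAML)."""
    raw = dict(raw or {})
    top_allowed = {"seed", "output_dir", *_SECTION_TYPES}
    _reject_unknown("<top level>", raw, top_allowed)
    kwargs: dict = {}
    for key in ("seed", "output_dir"):
        if key in raw:
            kwargs[key] = raw[key]
    for name, cls in _SECTION_TYPES.items():
        section_raw = dict(raw.get(name) or {})
        allowed = {f.name for f in fields(cls)}
        _reject_unknown(name, section_raw, allowed)
        for k in ("wavelength_range", "hidden_sizes"):
            if k in section_raw and section_raw[k] is not None:
                section_raw[k] = tuple(section_raw[k])
        kwargs[name] = cls(**section_raw)
    return PipelineConfig(**kwargs)


def default_config(**overrides) -> PipelineConfig:
    cfg = config_from_dict(overrides)
    return cfg


def _config_hash(cfg: PipelineConfig) -> str:
    d = asdict(cfg)
    d.pop("output_dir", None)  # hash the scientific config, not the paths
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _save_png(path: Path, img01: np.ndarray) -> None:
    import imageio.v3 as iio
    arr = np.clip(np.asarray(img01) * 255.0, 0, 255).round().astype(np.uint8)
    iio.imwrite(path, arr)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest.

    Any stage failure raises ``RuntimeError`` naming the stage; outputs
    written before the failure are retained on disk.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": _config_hash(cfg), "seed": cfg.seed,
                      "stages": {}, "metrics": {}}
    artifacts: dict[str, list[str]] = {}

    def record(stage: str, *paths: Path) -> None:
        artifacts.setdefault(stage, []).extend(p.name for p in paths)
        manifest["stages"][stage] = {"status": "ok",
                                     "outputs": artifacts[stage]}

    def run_stage(stage, fn):
        logger.info("stage %-10s start (config %s)", stage,
                    manifest["config_hash"])
        try:
            return fn()
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- simulate -----------------------------------------------------------
    def _simulate():
        spec = PhantomSpec(seed=cfg.stage_seed("simulate"),
                           **asdict(cfg.phantom))
        phantom = generate_phantom(spec)
        phantom_to_files(phantom, out / "phantom")
        return phantom

    phantom = run_stage("simulate", _simulate)
    record("simulate", out / "phantom")
    H, W = phantom.spec.height, phantom.spec.width

    # --- preprocess: RGB render + grayscale ---------------------------------
    def _preprocess():
        rgb = hsi.cube_to_rgb(phantom.noisy())
        gray = hsi.rgb_to_gray(rgb)
        _save_png(out / "rgb.png", rgb.data)
        _save_png(out / "gray.png", gray.data)
        return rgb, gray

    rgb, gray = run_stage("preprocess", _preprocess)
    record("preprocess", out / "rgb.png", out / "gray.png")

    # --- filter -------------------------------------------------------------
    def _filter():
        if not cfg.filter.enabled:
            return phantom.noisy_cube
        if cfg.filter.mode == "frost":
            params = FrostParams(window_half=cfg.filter.window_half,
                                 damping=cfg.filter.damping,
                                 border_mode=cfg.filter.border_mode)
            return filter_cube(phantom.noisy_cube, params, mode="frost")
        return filter_cube(phantom.noisy_cube, mode="adaptive",
                           window_half=cfg.filter.window_half,
                           noise_cv=cfg.filter.noise_cv,
                           border_mode=cfg.filter.border_mode)

    filtered = run_stage("filter", _filter)
    filtered_cube = hsi.HyperspectralCube(np.clip(filtered, 0, None),
                                          phantom.wavelengths_nm)
    hsi.write_cube(filtered_cube, out / "filtered.npz")
    record("filter", out / "filtered.npz", out / "filtered.npz.hdr")

    # --- segment ------------------------------------------------------------
    features = filtered_cube.data.reshape(H * W, -1)

    def _segment():
        if cfg.firefly.auto_k:
            ffp = FireflyParams(
                n_fireflies=cfg.firefly.n_fireflies,
                max_generations=cfg.firefly.max_generations,
                alpha=cfg.firefly.alpha, alpha_decay=cfg.firefly.alpha_decay,
                beta0=cfg.firefly.beta0, gamma=cfg.firefly.gamma,
                seed=cfg.stage_seed("segment"),
            )
            k, trace, cache = select_k(features, cfg.firefly.kmin,
                                       cfg.firefly.kmax, ffp)
            rows = ["generation,best_k,best_fitness"]
            for g, (bp, bf) in enumerate(zip(trace.best_positions,
                                             trace.best_fitnesses)):
                rows.append(f"{g},{int(round(float(bp[0])))},{bf:.6f}")
            (out / "firefly_trace.csv").write_text("\n".join(rows) + "\n")
        else:
            k = cfg.kmeans.k
        kp = KMeansParams(k=k, max_iter=cfg.kmeans.max_iter,
                          min_error=cfg.kmeans.min_error, init=cfg.kmeans.init,
                          seed=cfg.stage_seed("segment"),
                          n_restarts=cfg.kmeans.n_restarts,
                          min_cluster_frac=cfg.kmeans.min_cluster_frac)
        return kmeans_segment(features, kp)

    seg = run_stage("segment", _segment)
    np.savez_compressed(out / "segmentation.npz",
                        labels=seg.as_map(H, W), centroids=seg.centroids)
    _save_png(out / "segments.png", map_regions(seg, (H, W)).data)
    seg_paths = [out / "segmentation.npz", out / "segments.png"]
    if cfg.firefly.auto_k:
        seg_paths.append(out / "firefly_trace.csv")
    record("segment", *seg_paths)

    # --- refine -------------------------------------------------------------
    def _refine():
        if not cfg.knn.enabled:
            return seg
        return knn_refine(seg, features, k_nn=cfg.knn.k_nn,
                          mode=cfg.knn.mode, shape=(H, W))

    refined = run_stage("refine", _refine)
    np.savez_compressed(out / "refined.npz", labels=refined.as_map(H, W))
    _save_png(out / "refined.png", map_regions(refined, (H, W)).data)
    record("refine", out / "refined.npz", out / "refined.png")

    # --- label (network) ----------------------------------------------------
    def _label():
        if not cfg.mfnn.enabled:
            mapping = match_labels(refined.as_map(H, W), phantom.truth_labels)
            return np.vectorize(mapping.get)(refined.as_map(H, W)), None
        mcfg = MFNNConfig(hidden_sizes=cfg.mfnn.hidden_sizes,
                          learning_rate=cfg.mfnn.learning_rate,
                          epochs=cfg.mfnn.epochs,
                          batch_size=cfg.mfnn.batch_size,
                          train_fraction=cfg.mfnn.train_fraction,
                          seed=cfg.stage_seed("label"))
        model = mfnn_train(features, phantom.truth_labels.ravel(), mcfg)
        save_model(model, out / "mfnn_model.npz")
        class_map = label_map_from_segments(refined, model, features, (H, W))
        return class_map, model

    class_map, model = run_stage("label", _label)
    np.savez_compressed(out / "class_map.npz", labels=class_map)
    _save_png(out / "class_map.png",
              map_regions(type(seg)(labels=class_map.ravel(),
                                    centroids=seg.centroids,
                                    inertia_trace=seg.inertia_trace,
                                    selected_k=seg.selected_k), (H, W)).data)
    label_paths = [out / "class_map.npz", out / "class_map.png"]
    if model is not None:
        label_paths += [out / "mfnn_model.npz", out / "mfnn_model.json"]
    record("label", *label_paths)

    # --- evaluate -----------------------------------------------------------
    def _evaluate():
        report = classification_metrics(
            class_map, phantom.truth_labels,
            positive_class=cfg.metrics.positive_class,
        )
        maxv = cfg.metrics.psnr_max_value
        results = {
            "selected_k": int(seg.selected_k),
            "pooled_accuracy_pct": report.pooled.accuracy(),
            **report.to_dict(),
            "mae_labels": mae_labels(class_map, phantom.truth_labels),
            "psnr_noisy_db": psnr(phantom.noisy_cube, phantom.clean_cube, maxv),
            "psnr_filtered_db": psnr(filtered_cube.data, phantom.clean_cube,
                                     maxv),
        }
        for k, v in results.items():
            if isinstance(v, float) and not np.isfinite(v):
                results[k] = "inf"
        (out / "metrics.json").write_text(json.dumps(results, indent=2))
        flat = {k: v for k, v in results.items() if not isinstance(v, dict)}
        (out / "metrics.csv").write_text(
            ",".join(flat) + "\n" + ",".join(str(v) for v in flat.values())
            + "\n")
        return results

    results = run_stage("evaluate", _evaluate)
    record("evaluate", out / "metrics.json", out / "metrics.csv")
    manifest["metrics"] = {k: v for k, v in results.items()
                           if not isinstance(v, dict)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
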