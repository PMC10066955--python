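"""End-to-end orchestration: simulate -> tile -> segment -> census -> yield -> evaluate.

A :class:`RunConfig` fully determines a run; every numeric output is a pure
function of the config (all randomness flows from its single seed), so
re-running the same config reproduces every output file bit-for-bit.  Each
output declares the hash of the resolved config that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .census import census as run_census
from .census import export_map, summarize, write_census_csv, write_geojson
from . import evaluation as eval_mod
from . import segmentation as seg_mod
from . import synthetic as syn_mod
from . import tiling as tiling_mod
from . import yield_model as yield_mod
from .utils import round_half_up

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("lrcensus")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Either ``scene`` (a synthetic scene spec) or ``input_raster`` (a TIFF +
    sidecar path, optionally with ``truth_labels``) provides the imagery.
    """

    outdir: str
    seed: int = 0
    scene: syn_mod.SceneSpec | None = None
    input_raster: str | None = None
    truth_labels: str | None = None
    tile_size: int = 512
    backend: str = "classical"
    classical_params: seg_mod.ClassicalParams = field(default_factory=seg_mod.ClassicalParams)
    score_threshold: float = 0.0
    min_pixels: int = 9
    merge: str = "connectivity"
    nms_iou: float = 0.5
    allometry_csv: str | None = None
    allometry_n: int = 86
    allometry_noise_sd: float = 0.3
    mean_dry_weight_g: float | None = None
    eval_iou: float = 0.5

    def validate(self) -> None:
        if self.tile_size < 64:
            raise ValueError("tile_size must be at least 64")
        if self.scene is None and self.input_raster is None:
            raise ValueError("config needs a scene spec or an input raster")
        for p in (self.input_raster, self.truth_labels, self.allometry_csv):
            if p is not None and not Path(p).exists():
                raise ValueError(f"referenced path does not exist: {p}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        # the output location does not influence any computed number
        d = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("scene") is not None:
            scene = d["scene"]
            if isinstance(scene, dict):
                if "size_range" in scene:
                    scene["size_range"] = tuple(scene["size_range"])
                d["scene"] = syn_mod.SceneSpec(**scene)
        if isinstance(d.get("classical_params"), dict):
            cp = d["classical_params"]
            if "hue_range" in cp:
                cp["hue_range"] = tuple(cp["hue_range"])
            d["classical_params"] = seg_mod.ClassicalParams(**cp)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


class StageError(RuntimeError):
    """A pipeline stage failed; earlier stage outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise StageError(name, exc) from exc
            logger.info("stage %-9s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages; returns the output directory.

    Writes: orthomosaic + sidecar, truth labels and COCO annotations (when
    synthetic), tile index, detections JSON, census CSV / GeoJSON / summary,
    yield report JSON, metrics JSON (when truth is available), the resolved
    config snapshot, and a stage-timing log.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, outdir, chash)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path, chash: str) -> Path:
    (outdir / "config.json").write_text(
        json.dumps({"config_hash": chash, "config": config.to_dict()}, indent=1, default=str)
    )

    ortho, truth = _stage("simulate")(_load_inputs)(config)
    if truth is not None:
        syn_mod.write_label_raster(truth, outdir / "labels.tif")
        syn_mod.export_coco(truth, outdir / "truth_coco.json", file_name="ortho.tif")
        syn_mod.write_allometry_csv(truth.allometry, outdir / "scene_allometry.csv")
    tiling_mod.write_orthomosaic(ortho, outdir / "ortho.tif")

    tiles, index = _stage("tile")(tiling_mod.tile_orthomosaic)(ortho, config.tile_size)
    index.to_json(outdir / "tile_index.json")

    dets_by_tile = _stage("segment")(_segment_all)(config, tiles, index, truth)
    _write_detections(dets_by_tile, outdir / "detections.json", chash)

    records, merged_labels = _stage("census")(run_census)(
        dets_by_tile,
        index,
        ortho.gsd,
        merge=config.merge,
        nms_iou=config.nms_iou,
        return_labels=True,
    )
    write_census_csv(records, outdir / "census.csv", header_comment=f"config_hash={chash}")
    layer = export_map(records, gsd=ortho.gsd)
    layer["properties"]["config_hash"] = chash
    write_geojson(layer, outdir / "census.geojson")
    summary = summarize(records) | {"config_hash": chash}
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    logger.info("census: %d plants, %.2f m2 leaf area", len(records), summary["total_leaf_area_m2"])

    report = _stage("yield")(_yield_stage)(config, records, truth)
    (outdir / "yield.json").write_text(
        json.dumps(report.rounded() | {"config_hash": chash}, indent=1)
    )

    if truth is not None:
        metrics = _stage("evaluate")(_evaluate)(config, records, merged_labels, truth, index)
        metrics["config_hash"] = chash
        (outdir / "metrics.json").write_text(json.dumps(metrics, indent=1))
    return outdir


def _load_inputs(config: RunConfig):
    if config.scene is not None:
        spec = dataclasses.replace(config.scene, rng_seed=config.seed)
        ortho, truth = syn_mod.generate_scene(spec)
        return ortho, truth
    ortho = tiling_mod.read_orthomosaic(config.input_raster)
    truth = None
    if config.truth_labels is not None:
        labels = syn_mod.read_label_raster(config.truth_labels)
        truth = _truth_from_labels(labels, ortho.gsd)
    return ortho, truth


def _truth_from_labels(labels: np.ndarray, gsd: float) -> syn_mod.GroundTruth:
    """Wrap an externally annotated label raster as ground truth (no allometry)."""
    import pandas as pd

    instances = []
    for k in np.unique(labels):
        if k == 0:
            continue
        rows, cols = np.nonzero(labels == k)
        instances.append(
            syn_mod.Instance(
                id=int(k),
                centroid=(float(rows.mean()), float(cols.mean())),
                pixel_count=int(rows.size),
                polygon=[],
                morphotype="unknown",
            )
        )
    empty = pd.DataFrame({"length_m": [], "width_m": [], "dry_weight_g": []})
    return syn_mod.GroundTruth(instance_label_raster=labels, instances=instances, allometry=empty)


def _segment_all(config: RunConfig, tiles, index, truth):
    if config.backend == "oracle":
        if truth is None:
            raise ValueError("oracle backend needs ground-truth labels")
        backend = seg_mod.OracleBackend(truth.instance_label_raster, index)
    elif config.backend == "classical":
        backend = seg_mod.ClassicalBackend(config.classical_params)
    else:
        backend = seg_mod.make_backend(config.backend)
    out = {}
    for tid, tile in enumerate(tiles):
        dets = backend.segment(tile, tid)
        out[tid] = seg_mod.filter_detections(dets, config.score_threshold, config.min_pixels)
    return out


def _write_detections(dets_by_tile, path: Path, chash: str) -> None:
    from .utils import mask_to_polygon

    rows = []
    for tid, dets in sorted(dets_by_tile.items()):
        for d in dets:
            rows.append(
                {
                    "tile_id": tid,
                    "bbox": list(d.bbox),
                    "score": d.score,
                    "pixel_count": d.pixel_count,
                    "category": d.class_label,
                    "segmentation": [mask_to_polygon(d.mask)],
                }
            )
    path.write_text(json.dumps({"config_hash": chash, "detections": rows}))


def _yield_stage(config: RunConfig, records, truth):
    if config.allometry_csv is not None:
        table = syn_mod.read_allometry_csv(config.allometry_csv)
    elif truth is not None and len(truth.allometry) >= 3:
        table = truth.allometry
    else:
        table = syn_mod.generate_allometry(
            config.allometry_n, noise_sd=config.allometry_noise_sd, seed=config.seed
        )
    model = yield_mod.fit_allometry(table)
    mean_weight = (
        config.mean_dry_weight_g
        if config.mean_dry_weight_g is not None
        else float(table["dry_weight_g"].mean())
    )
    return yield_mod.yield_report(records, model, mean_weight)


def _evaluate(config: RunConfig, records, merged_labels, truth, index):
    """Detection metrics in the mosaic frame + per-tile counting metrics."""
    truth_sets = eval_mod.instances_from_labels(truth.instance_label_raster)
    pred_sets = eval_mod.instances_from_labels(merged_labels)
    scores = [r.mean_score for r in records]
    match = eval_mod.match_instances(pred_sets, truth_sets, config.eval_iou, scores=scores)
    precision, recall, f1 = eval_mod.precision_recall_f1(match)
    out = {
        "tp": match.tp,
        "fp": match.fp,
        "fn": match.fn,
        "precision": round_half_up(100 * precision, 2),
        "recall": round_half_up(100 * recall, 2),
        "f1": round_half_up(100 * f1, 2),
    }
    if truth_sets:
        out["map50"] = round_half_up(
            eval_mod.average_precision_50(pred_sets, scores, truth_sets), 4
        )
        out["mar"] = round_half_up(
            eval_mod.mean_average_recall(pred_sets, scores, truth_sets), 4
        )
    # per-tile counting: truth count = instance centroids in tile
    t_counts = np.zeros(index.n_tiles)
    p_counts = np.zeros(index.n_tiles)
    for inst in truth.instances:
        tid, _ = tiling_mod.to_local(index, (int(inst.centroid[0]), int(inst.centroid[1])))
        t_counts[tid] += 1
    for rec in records:
        tid, _ = tiling_mod.to_local(index, (int(rec.centroid[0]), int(rec.centroid[1])))
        p_counts[tid] += 1
    ce = eval_mod.counting_metrics(t_counts, p_counts)
    out["counting"] = {
        "mae": round_half_up(ce.mae, 3),
        "acc": None if np.isnan(ce.acc) else round_half_up(ce.acc, 2),
        "r_squared": None if np.isnan(ce.r_squared) else round_half_up(ce.r_squared, 3),
        "rmse": round_half_up(ce.rmse, 3),
    }
    return out
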