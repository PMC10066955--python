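"""Mosaic-level plant census: merge tile detections into unique plant records.

Tiles are segmented independently, so one plant can surface as several
detections: duplicates inside a tile (resolved by mask-IoU non-maximum
suppression) and fragments split across a tile border (rejoined when their
global pixels are 8-connected across the border).  The result is one
:class:`PlantRecord` per surviving component with its centroid, pixel count
and physical leaf area (pixel_count x gsd^2), the input to counting and
yield estimation.

Border merging is the minimal policy that makes the count invariant to where
the tile grid happens to fall; ``merge="none"`` keeps the literal
split-tolerant behaviour (a border-straddling plant counts once per tile).
Genuinely connected clumped plants cannot be re-split here — separating
touching rosettes is the segmenter's job, not the census's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .segmentation import Detection
from .tiling import TileIndex
from .utils import UnionFind

__all__ = [
    "PlantRecord",
    "census",
    "count_plants",
    "summarize",
    "export_map",
    "records_to_dataframe",
    "write_census_csv",
    "read_census_csv",
    "write_geojson",
    "read_geojson",
]


@dataclass(frozen=True)
class PlantRecord:
    """One merged plant in orthomosaic coordinates."""

    plant_id: int
    centroid: tuple[float, float]  # (row, col), mosaic frame
    pixel_count: int
    leaf_area: float  # m^2, = pixel_count * gsd^2
    mean_score: float


def _mask_iou(a: Detection, b: Detection) -> float:
    inter = np.logical_and(a.mask, b.mask).sum()
    if inter == 0:
        return 0.0
    union = a.pixel_count + b.pixel_count - inter
    return inter / union


def _nms(dets: list[Detection], iou_threshold: float) -> list[Detection]:
    """Greedy mask NMS: highest score wins, ties broken by input order."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    kept: list[int] = []
    for i in order:
        if all(_mask_iou(dets[i], dets[j]) < iou_threshold for j in kept):
            kept.append(i)
    return [dets[i] for i in sorted(kept)]


def census(
    detections_by_tile: dict[int, list[Detection]],
    index: TileIndex,
    gsd: float,
    merge: str = "connectivity",
    nms_iou: float = 0.5,
    return_labels: bool = False,
):
    """Merge tile detections into mosaic-level plant records.

    Parameters
    ----------
    detections_by_tile:
        Mapping tile_id -> detections for that tile (tile-local masks).
    merge:
        ``"connectivity"`` rejoins masks from *different* tiles whose global
        pixels are 8-connected across a shared border; ``"none"`` keeps every
        post-NMS detection as its own record.
    return_labels:
        When true, also return the merged mosaic-frame label raster
        (record plant_id per pixel), which detection-level evaluation needs.
    """
    if merge not in ("connectivity", "none"):
        raise ValueError("merge must be 'connectivity' or 'none'")
    if not gsd > 0:
        raise ValueError("gsd must be positive")
    for tid in detections_by_tile:
        index.entry(tid)  # raises KeyError for unknown tiles

    # per-tile NMS, then lift surviving masks to global pixel coordinates
    kept: list[Detection] = []
    pixels: list[tuple[np.ndarray, np.ndarray]] = []
    for tid in sorted(detections_by_tile):
        e = index.entry(tid)
        for det in _nms(detections_by_tile[tid], nms_iou):
            rows, cols = np.nonzero(det.mask)
            valid = (rows < e.valid_rows) & (cols < e.valid_cols)
            rows, cols = rows[valid], cols[valid]
            if rows.size == 0:
                continue
            kept.append(det)
            pixels.append((rows + e.row_off, cols + e.col_off))

    H, W = index.rows, index.cols
    gid_raster = np.zeros((H, W), dtype=np.int32)
    for gid, (rows, cols) in enumerate(pixels, start=1):
        gid_raster[rows, cols] = gid  # later detections occlude earlier overlaps

    uf = UnionFind(len(kept) + 1)
    if merge == "connectivity" and kept:
        tile_of = np.zeros(len(kept) + 1, dtype=np.int64)
        for gid, det in enumerate(kept, start=1):
            tile_of[gid] = det.tile_id
        # 8-neighbourhood adjacency via four directed shifts
        for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
            a = gid_raster[max(0, -dr) : H - max(0, dr), max(0, -dc) : W - max(0, dc)]
            b = gid_raster[max(0, dr) : H + min(0, dr), max(0, dc) : W + min(0, dc)]
            touch = (a > 0) & (b > 0) & (a != b)
            if not touch.any():
                continue
            pairs = np.unique(np.stack([a[touch], b[touch]], axis=1), axis=0)
            for ga, gb in pairs:
                if tile_of[ga] != tile_of[gb]:  # only rejoin across tiles
                    uf.union(int(ga), int(gb))

    # group surviving pixels by union root; pixel counts come from the final
    # raster so no pixel is ever counted twice (conservation)
    rows_all, cols_all = np.nonzero(gid_raster)
    gids_all = gid_raster[rows_all, cols_all]
    root_of = np.array([uf.find(g) for g in range(len(kept) + 1)])
    roots_all = root_of[gids_all]

    records: list[PlantRecord] = []
    labels_out = np.zeros((H, W), dtype=np.int32) if return_labels else None
    order = [int(r) for r in pd.unique(roots_all)] if roots_all.size else []
    score_of = {gid: det.score for gid, det in enumerate(kept, start=1)}
    for plant_id, root in enumerate(sorted(order), start=1):
        sel = roots_all == root
        r, c = rows_all[sel], cols_all[sel]
        member_gids = np.unique(gids_all[sel])
        scores = [score_of[int(g)] for g in member_gids]
        records.append(
            PlantRecord(
                plant_id=plant_id,
                centroid=(float(r.mean()), float(c.mean())),
                pixel_count=int(sel.sum()),
                leaf_area=float(sel.sum()) * gsd**2,
                mean_score=float(np.mean(scores)),
            )
        )
        if labels_out is not None:
            labels_out[r, c] = plant_id

    if return_labels:
        return records, labels_out
    return records


def count_plants(records: list[PlantRecord]) -> int:
    """Number of unique plants in the census."""
    return len(records)


def summarize(records: list[PlantRecord]) -> dict:
    return {
        "count": count_plants(records),
        "total_pixels": int(sum(r.pixel_count for r in records)),
        "total_leaf_area_m2": float(sum(r.leaf_area for r in records)),
    }


def export_map(records: list[PlantRecord], gsd: float | None = None) -> dict:
    """GeoJSON point layer of plant locations (the distribution-map product).

    Coordinates are (col, row) in the raster frame, or metres when a GSD is
    given; one point feature per record with its census attributes.
    """
    features = []
    for rec in records:
        row, col = rec.centroid
        if gsd is not None:
            coords = [col * gsd, row * gsd]
        else:
            coords = [col, row]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": coords},
                "properties": {
                    "plant_id": rec.plant_id,
                    "pixel_count": rec.pixel_count,
                    "leaf_area": rec.leaf_area,
                    "score": rec.mean_score,
                },
            }
        )
    return {
        "type": "FeatureCollection",
        "features": features,
        "properties": {"coordinate_unit": "m" if gsd is not None else "pixel"},
    }


def records_to_dataframe(records: list[PlantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plant_id": [r.plant_id for r in records],
            "row": [r.centroid[0] for r in records],
            "col": [r.centroid[1] for r in records],
            "pixel_count": [r.pixel_count for r in records],
            "leaf_area_m2": [r.leaf_area for r in records],
            "score": [r.mean_score for r in records],
        }
    )


def write_census_csv(records: list[PlantRecord], path: str | Path, header_comment: str | None = None) -> None:
    path = Path(path)
    text = records_to_dataframe(records).to_csv(index=False)
    if header_comment:
        text = f"# {header_comment}\n" + text
    path.write_text(text)


def read_census_csv(path: str | Path) -> list[PlantRecord]:
    df = pd.read_csv(Path(path), comment="#")
    return [
        PlantRecord(
            plant_id=int(row.plant_id),
            centroid=(float(row.row), float(row.col)),
            pixel_count=int(row.pixel_count),
            leaf_area=float(row.leaf_area_m2),
            mean_score=float(row.score),
        )
        for row in df.itertuples()
    ]


def write_geojson(layer: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(layer))


def read_geojson(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
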