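"""Orthomosaic handling and non-overlapping fixed-size tiling.

An orthomosaic is a stitched, geometrically corrected aerial raster with a
uniform ground-sample distance (GSD, m/pixel).  Survey mosaics are far too
large for a segmentation model in one piece, so they are cut into
non-overlapping ``tile_size`` x ``tile_size`` tiles; non-overlap is what
guarantees a plant's pixels are never counted twice.  Edge tiles are
zero-padded to full size and the valid (un-padded) region is tracked so
tile-local detections can be mapped back to exact mosaic coordinates.

Conventions, used everywhere in this package: 0-based (row, col) indices,
half-open intervals, row-major tile ids.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "Orthomosaic",
    "TileEntry",
    "TileIndex",
    "plan_tiles",
    "tile_raster",
    "tile_orthomosaic",
    "reassemble",
    "to_global",
    "to_local",
    "split_dataset",
    "split_indices",
    "read_orthomosaic",
    "write_orthomosaic",
]


@dataclass
class Orthomosaic:
    """RGB raster plus its ground-sample distance.

    ``gsd`` converts pixels to metres; squared, it converts pixel counts to
    areas, which is the basis of every leaf-area and yield figure downstream.
    """

    pixels: np.ndarray  # (rows, cols, 3) uint8
    gsd: float  # m / pixel
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("orthomosaic pixels must be a (rows, cols, 3) RGB raster")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("orthomosaic must contain at least one pixel")
        if not self.gsd > 0:
            raise ValueError("ground-sample distance must be positive")

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def area_m2(self) -> float:
        return self.rows * self.cols * self.gsd**2


@dataclass(frozen=True)
class TileEntry:
    tile_id: int
    row_off: int
    col_off: int
    valid_rows: int
    valid_cols: int


@dataclass
class TileIndex:
    """Bookkeeping for a non-overlapping tiling of a rows x cols raster."""

    tile_size: int
    rows: int
    cols: int
    entries: list[TileEntry]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (
            math.ceil(self.rows / self.tile_size),
            math.ceil(self.cols / self.tile_size),
        )

    @property
    def n_tiles(self) -> int:
        return len(self.entries)

    def entry(self, tile_id: int) -> TileEntry:
        if not 0 <= tile_id < len(self.entries):
            raise KeyError(f"unknown tile id {tile_id}")
        return self.entries[tile_id]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tile_size": self.tile_size,
            "rows": self.rows,
            "cols": self.cols,
            "entries": [vars(e) for e in self.entries],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TileIndex":
        payload = json.loads(Path(path).read_text())
        entries = [TileEntry(**e) for e in payload["entries"]]
        return cls(payload["tile_size"], payload["rows"], payload["cols"], entries)


def plan_tiles(rows: int, cols: int, tile_size: int) -> TileIndex:
    """Pure-arithmetic tile plan: ceil(rows/ts) x ceil(cols/ts) row-major tiles."""
    if rows < 1 or cols < 1:
        raise ValueError("cannot tile an empty raster")
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    entries = []
    tile_id = 0
    for gr in range(math.ceil(rows / tile_size)):
        for gc in range(math.ceil(cols / tile_size)):
            r0, c0 = gr * tile_size, gc * tile_size
            entries.append(
                TileEntry(
                    tile_id=tile_id,
                    row_off=r0,
                    col_off=c0,
                    valid_rows=min(tile_size, rows - r0),
                    valid_cols=min(tile_size, cols - c0),
                )
            )
            tile_id += 1
    return TileIndex(tile_size, rows, cols, entries)


def tile_raster(raster: np.ndarray, tile_size: int) -> tuple[list[np.ndarray], TileIndex]:
    """Cut any 2-D (label) or 3-D (RGB) raster into zero-padded tiles."""
    raster = np.asarray(raster)
    index = plan_tiles(raster.shape[0], raster.shape[1], tile_size)
    tiles = []
    for e in index.entries:
        pad_shape = (tile_size, tile_size) + raster.shape[2:]
        tile = np.zeros(pad_shape, dtype=raster.dtype)
        tile[: e.valid_rows, : e.valid_cols] = raster[
            e.row_off : e.row_off + e.valid_rows, e.col_off : e.col_off + e.valid_cols
        ]
        tiles.append(tile)
    return tiles, index


def tile_orthomosaic(ortho: Orthomosaic, tile_size: int = 512) -> tuple[list[np.ndarray], TileIndex]:
    """Tile an orthomosaic into non-overlapping ``tile_size`` square tiles."""
    return tile_raster(ortho.pixels, tile_size)


def reassemble(tiles: list[np.ndarray], index: TileIndex) -> np.ndarray:
    """Stitch tile valid regions back into the source raster, bit-exactly."""
    if len(tiles) != index.n_tiles:
        raise ValueError("tile list does not match index")
    shape = (index.rows, index.cols) + tiles[0].shape[2:]
    out = np.zeros(shape, dtype=tiles[0].dtype)
    for tile, e in zip(tiles, index.entries):
        out[e.row_off : e.row_off + e.valid_rows, e.col_off : e.col_off + e.valid_cols] = tile[
            : e.valid_rows, : e.valid_cols
        ]
    return out


def to_global(index: TileIndex, tile_id: int, local: tuple[int, int]) -> tuple[int, int]:
    """Map a tile-local (row, col) inside the valid region to mosaic coordinates."""
    e = index.entry(tile_id)
    r, c = local
    if not (0 <= r < e.valid_rows and 0 <= c < e.valid_cols):
        raise ValueError(
            f"local ({r}, {c}) lies in the padded margin of tile {tile_id} "
            f"(valid {e.valid_rows}x{e.valid_cols})"
        )
    return e.row_off + r, e.col_off + c


def to_local(index: TileIndex, global_rc: tuple[int, int]) -> tuple[int, tuple[int, int]]:
    """Inverse of :func:`to_global`; every mosaic pixel belongs to exactly one tile."""
    R, C = global_rc
    if not (0 <= R < index.rows and 0 <= C < index.cols):
        raise ValueError(f"global ({R}, {C}) outside raster {index.rows}x{index.cols}")
    gr, gc = R // index.tile_size, C // index.tile_size
    tile_id = gr * index.grid_shape[1] + gc
    e = index.entry(tile_id)
    return tile_id, (R - e.row_off, C - e.col_off)


def split_dataset(n_tiles: int, train_fraction: float, seed: int | None = None) -> tuple[int, int]:
    """Train/test tile counts under a round-half-away-from-zero policy.

    5700 tiles at a 6:4 ratio give 3420 training and 2280 testing tiles.
    """
    if n_tiles == 0:
        raise ValueError("cannot split an empty dataset")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n_train = int(math.floor(n_tiles * train_fraction + 0.5))
    return n_train, n_tiles - n_train


def split_indices(
    n_tiles: int, train_fraction: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded, reproducible assignment of tile indices to train/test subsets."""
    n_train, _ = split_dataset(n_tiles, train_fraction)
    perm = np.random.default_rng(seed).permutation(n_tiles)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_orthomosaic(ortho: Orthomosaic, path: str | Path) -> None:
    """Write a TIFF raster with a JSON sidecar carrying the GSD and metadata."""
    path = Path(path)
    tifffile.imwrite(path, ortho.pixels)
    meta = {"gsd_m_per_px": ortho.gsd, **ortho.meta}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_orthomosaic(path: str | Path) -> Orthomosaic:
    path = Path(path)
    pixels = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    gsd = meta.pop("gsd_m_per_px")
    return Orthomosaic(pixels=pixels, gsd=gsd, meta=meta)
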