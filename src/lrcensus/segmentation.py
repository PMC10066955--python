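"""Instance-segmentation contract and backends.

Every detector backend — the classical reference segmenter here, a
ground-truth oracle, or an external Mask R-CNN adapter — returns the same
thing for a tile: a list of :class:`Detection` objects (tile-local binary
mask, tight box, confidence score, tile provenance).  Downstream census and
evaluation code is backend-agnostic.

The classical segmenter is a deterministic, seed-free pipeline:
colour-band threshold (dark-green hue/value band) -> morphological opening
-> hole filling -> marker-based watershed on the distance transform to split
touching rosettes -> connected components.  Its confidence score is an
explicit shape prior, roundness x relative greenness, both in [0, 1]: a
compact dark-green rosette scores high, an elongated grass tuft scores low.

The Mask R-CNN-side geometry that is independent of training — region
proposal anchor enumeration from aspect scales x base lengths — is
implemented and testable; training and GPU inference are out of scope and
live behind :class:`ExternalBackend`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import measure, morphology, segmentation as skseg
from skimage.feature import peak_local_max

from .tiling import TileIndex, tile_raster
from .utils import tight_bbox

__all__ = [
    "Detection",
    "AnchorSpec",
    "enumerate_anchors",
    "ClassicalParams",
    "classical_segment",
    "filter_detections",
    "ClassicalBackend",
    "OracleBackend",
    "ExternalBackend",
    "make_backend",
]


@dataclass
class Detection:
    """One predicted instance in tile-local coordinates."""

    mask: np.ndarray  # boolean, tile-shaped
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    score: float
    class_label: str = "LR"
    tile_id: int = 0

    def validate(self) -> None:
        if self.mask.dtype != bool:
            raise ValueError("mask must be boolean")
        if not self.mask.any():
            raise ValueError("detection mask must be non-empty")
        if tuple(self.bbox) != tight_bbox(self.mask):
            raise ValueError("bbox is not the tight box of the mask")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")

    @classmethod
    def from_mask(
        cls, mask: np.ndarray, score: float, class_label: str = "LR", tile_id: int = 0
    ) -> "Detection":
        det = cls(
            mask=mask.astype(bool),
            bbox=tight_bbox(mask),
            score=float(score),
            class_label=class_label,
            tile_id=tile_id,
        )
        det.validate()
        return det

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class AnchorSpec:
    """Region-proposal anchor configuration: aspect scales x base lengths."""

    aspect_scales: tuple[float, ...] = (0.5, 1.0, 2.0)
    base_lengths: tuple[float, ...] = (8.0, 16.0, 32.0, 64.0, 128.0)

    def validate(self) -> None:
        if not self.aspect_scales or not self.base_lengths:
            raise ValueError("anchor spec must list at least one scale and one length")
        if any(s <= 0 for s in self.aspect_scales) or any(l <= 0 for l in self.base_lengths):
            raise ValueError("anchor scales and lengths must be positive")


def enumerate_anchors(spec: AnchorSpec, position: tuple[float, float]) -> np.ndarray:
    """All anchor boxes centred at a feature-map position.

    For aspect scale s and base length l the box has width/height ratio s and
    area l^2 (height l/sqrt(s), width l*sqrt(s)).  The default 3 scales x 5
    lengths give 15 candidate regions per element point.  Boxes are
    (row0, col0, row1, col1) floats, half-open.
    """
    spec.validate()
    r, c = position
    boxes = []
    for s in spec.aspect_scales:
        for l in spec.base_lengths:
            h = l / np.sqrt(s)
            w = l * np.sqrt(s)
            boxes.append((r - h / 2, c - w / 2, r + h / 2, c + w / 2))
    return np.asarray(boxes, dtype=float)


@dataclass(frozen=True)
class ClassicalParams:
    """Tunables of the classical reference segmenter.

    The hue band and value ceiling select dark green foliage against the
    lighter grass background; ``min_distance`` sets the minimum separation
    (pixels) between watershed markers, i.e. the smallest centre-to-centre
    spacing at which two touching rosettes are still split.
    """

    hue_range: tuple[float, float] = (0.25, 0.45)
    min_saturation: float = 0.25
    max_value: float = 0.52
    opening_radius: int = 1
    watershed: bool = True
    min_distance: int = 7
    min_pixels: int = 9


def _foreground(tile: np.ndarray, params: ClassicalParams) -> np.ndarray:
    hsv = skcolor.rgb2hsv(tile)
    fg = (
        (hsv[..., 0] >= params.hue_range[0])
        & (hsv[..., 0] <= params.hue_range[1])
        & (hsv[..., 1] >= params.min_saturation)
        & (hsv[..., 2] <= params.max_value)
    )
    if params.opening_radius > 0:
        fg = morphology.opening(fg, morphology.disk(params.opening_radius))
    return ndi.binary_fill_holes(fg)


def _split_watershed(fg: np.ndarray, min_distance: int) -> np.ndarray:
    """Marker-based watershed on the distance transform of the foreground."""
    distance = ndi.distance_transform_edt(fg)
    blob_labels, _ = ndi.label(fg)
    coords = peak_local_max(
        distance, min_distance=min_distance, labels=blob_labels, exclude_border=False
    )
    if len(coords) == 0:
        return blob_labels
    markers = np.zeros(fg.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    return skseg.watershed(-distance, markers, mask=fg)


def classical_segment(tile: np.ndarray, params: ClassicalParams | None = None) -> list[Detection]:
    """Deterministic colour/shape segmentation of one RGB tile.

    Fully seed-free and idempotent: the same tile always yields the same
    detections in the same order (by label id).
    """
    tile = np.asarray(tile)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ValueError("classical_segment expects an RGB tile (rows, cols, 3)")
    params = params or ClassicalParams()
    fg = _foreground(tile, params)
    if not fg.any():
        return []
    if params.watershed:
        labels = _split_watershed(fg, params.min_distance)
    else:
        labels, _ = ndi.label(fg)

    rgbf = tile.astype(float)
    greenness_map = (rgbf[..., 1] - 0.5 * (rgbf[..., 0] + rgbf[..., 2])) / 128.0
    detections = []
    for region in measure.regionprops(labels):
        if region.area < params.min_pixels:
            continue
        mask = np.zeros(tile.shape[:2], dtype=bool)
        mask[labels == region.label] = True
        perimeter = region.perimeter
        roundness = 1.0 if perimeter == 0 else min(1.0, 4.0 * np.pi * region.area / perimeter**2)
        greenness = float(np.clip(greenness_map[mask].mean(), 0.0, 1.0))
        score = float(np.clip(roundness * greenness, 0.0, 1.0))
        detections.append(Detection.from_mask(mask, score))
    return detections


def filter_detections(
    detections: list[Detection], score_threshold: float = 0.0, min_pixels: int = 1
) -> list[Detection]:
    """Keep detections with score >= threshold and enough pixels; order preserved."""
    if score_threshold < 0 or min_pixels < 0:
        raise ValueError("thresholds must be non-negative")
    return [
        d for d in detections if d.score >= score_threshold and d.pixel_count >= min_pixels
    ]


class ClassicalBackend:
    """Backend wrapper around :func:`classical_segment`."""

    name = "classical"

    def __init__(self, params: ClassicalParams | None = None):
        self.params = params or ClassicalParams()

    def segment(self, tile: np.ndarray, tile_id: int = 0) -> list[Detection]:
        dets = classical_segment(tile, self.params)
        for d in dets:
            d.tile_id = tile_id
        return dets


class OracleBackend:
    """Replays ground-truth instance labels as perfect detections (score 1).

    Built from a scene's instance label raster and the tile index in use; a
    plant straddling a tile border yields one detection per tile, exactly as
    a real detector would, so census-level border merging is exercised.
    """

    name = "oracle"

    def __init__(self, label_raster: np.ndarray, index: TileIndex):
        self._tiles, tiled_index = tile_raster(label_raster, index.tile_size)
        if tiled_index.n_tiles != index.n_tiles:
            raise ValueError("label raster does not match the tile index")

    def segment(self, tile: np.ndarray, tile_id: int = 0) -> list[Detection]:
        label_tile = self._tiles[tile_id]
        dets = []
        for k in np.unique(label_tile):
            if k == 0:
                continue
            dets.append(Detection.from_mask(label_tile == k, score=1.0, tile_id=tile_id))
        return dets


class ExternalBackend:
    """Adapter slot for a trained instance-segmentation model.

    A plugged-in Mask R-CNN should consume 512 x 512 RGB tiles (resampled by
    bilinear interpolation if needed) and return detections honouring the
    :class:`Detection` contract — tile-local binary mask, tight box and a
    confidence in [0, 1] from its classifier head.  No trained weights ship
    with this package.
    """

    name = "external"

    def __init__(self, model=None):
        self.model = model

    def segment(self, tile: np.ndarray, tile_id: int = 0) -> list[Detection]:
        if self.model is None:
            raise NotImplementedError(
                "no external model attached; provide an object with "
                "segment(tile, tile_id) -> list[Detection]"
            )
        return self.model.segment(tile, tile_id)


def make_backend(name: str, **kwargs):
    """Backend factory for config files: classical | oracle | external."""
    if name == "classical":
        return ClassicalBackend(kwargs.get("params"))
    if name == "oracle":
        return OracleBackend(kwargs["label_raster"], kwargs["index"])
    if name == "external":
        return ExternalBackend(kwargs.get("model"))
    raise ValueError(f"unknown backend {name!r}")
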