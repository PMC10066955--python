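"""Small shared helpers: reporting-grade rounding, union-find, mask/polygon conversion."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from skimage import measure


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as survey tables are printed.

    Python's built-in ``round`` uses banker's rounding (92.615 -> 92.61 or
    92.62 depending on the float), which does not reproduce printed table
    averages such as 89.335 -> 89.34.  Going through ``Decimal(repr(x))``
    rounds the shortest decimal representation of the float, which is what a
    person computing the mean of printed values would round.
    """
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


class UnionFind:
    """Union-find over integer ids 0..n-1 with path compression."""

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)

    def groups(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for i in range(len(self.parent)):
            out.setdefault(self.find(i), []).append(i)
        return out


def tight_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Tight half-open bounding box (row0, col0, row1, col1) of a boolean mask."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask has no bounding box")
    return int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1


def mask_to_polygon(mask: np.ndarray, tolerance: float = 0.5) -> list[float]:
    """Outer boundary of a mask as a flat COCO-style [x0, y0, x1, y1, ...] list.

    The mask is padded by one pixel so boundary-touching instances still yield
    a closed contour; the longest contour is taken as the outer boundary and
    decimated with ``approximate_polygon``.
    """
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return []
    contour = max(contours, key=len) - 1.0  # undo padding
    contour = measure.approximate_polygon(contour, tolerance=tolerance)
    flat: list[float] = []
    for row, col in contour:
        flat.extend((float(col), float(row)))
    return flat
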