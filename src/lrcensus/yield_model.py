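"""Yield estimation from a plant census.

Two estimators, meant to cross-check each other:

* **Area-based**: an allometric ordinary-least-squares line maps leaf area
  (m^2) to dry weight (g); the line is fitted on field samples where the
  predictor is length x width of the harvested rosette, and applied at
  inference to mask leaf area (pixel_count x gsd^2).  Both are treated as
  proxies of the same "leaf area" quantity — rosettes grow flat, so the
  planar mask is the natural stand-in for the hand-measured extent.
* **Count-based**: plant count x mean per-plant dry weight.

Totals are reported in kg.  Physical quantities are carried at full
precision; reports round to 2 decimals, the precision of survey tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .census import PlantRecord
from .utils import round_half_up

__all__ = [
    "AllometryModel",
    "YieldReport",
    "leaf_area_from_pixels",
    "fit_allometry",
    "predict_dry_weight",
    "yield_by_area",
    "yield_by_count",
    "yield_report",
]


@dataclass(frozen=True)
class AllometryModel:
    """Fitted linear dry-weight ~ leaf-area relationship."""

    slope: float  # g per m^2
    intercept: float  # g
    r_squared: float
    n_samples: int
    slope_stderr: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("allometry model needs at least 3 samples")
        if self.r_squared > 1 + 1e-12:
            raise ValueError("coefficient of determination cannot exceed 1")


@dataclass(frozen=True)
class YieldReport:
    """Both yield estimators for one site plus their absolute difference."""

    count: int
    total_leaf_area_m2: float
    mean_dry_weight_g: float
    yield_by_area_kg: float
    yield_by_count_kg: float
    difference_kg: float

    def rounded(self, ndigits: int = 2) -> dict:
        out = asdict(self)
        for key, val in out.items():
            if key != "count":
                out[key] = round_half_up(val, ndigits)
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.rounded() | {"count": self.count}, indent=1))


def leaf_area_from_pixels(pixel_count: int, gsd: float) -> float:
    """Physical leaf area in m^2: pixel count x gsd^2."""
    if not gsd > 0:
        raise ValueError("gsd must be positive")
    if pixel_count < 0:
        raise ValueError("pixel_count must be non-negative")
    return pixel_count * gsd**2


def fit_allometry(samples: pd.DataFrame) -> AllometryModel:
    """OLS fit of dry weight on length x width over field samples.

    ``samples`` needs columns length_m, width_m, dry_weight_g.  The
    coefficient of determination is computed explicitly as
    1 - SS_res / SS_tot.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to fit the allometric line")
    x = np.asarray(samples["length_m"], dtype=float) * np.asarray(
        samples["width_m"], dtype=float
    )
    y = np.asarray(samples["dry_weight_g"], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("independent variable (length x width) has zero variance")
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
    return AllometryModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(r2),
        n_samples=len(samples),
        slope_stderr=float(fit.stderr),
    )


def predict_dry_weight(model: AllometryModel, leaf_area_m2: float) -> float:
    """Per-plant predicted dry weight (g), clamped at zero."""
    return max(model.slope * leaf_area_m2 + model.intercept, 0.0)


def yield_by_area(
    records: list[PlantRecord], model: AllometryModel, intercept_mode: str = "per_plant"
) -> float:
    """Area-based yield in kg: sum of per-plant predicted dry weights.

    ``intercept_mode="per_plant"`` applies the fitted line to every plant and
    clamps negative predictions at zero; ``"aggregate"`` applies the line
    once to the total leaf area (slope * total_area + intercept).  With a
    zero intercept and nothing clamped the two coincide exactly.
    """
    if intercept_mode not in ("per_plant", "aggregate"):
        raise ValueError("intercept_mode must be 'per_plant' or 'aggregate'")
    if intercept_mode == "aggregate":
        total_area = sum(r.leaf_area for r in records)
        return max(model.slope * total_area + model.intercept, 0.0) / 1000.0
    return sum(predict_dry_weight(model, r.leaf_area) for r in records) / 1000.0


def yield_by_count(count: int, mean_dry_weight_g: float) -> float:
    """Count-based yield in kg: count x mean per-plant dry weight."""
    if count < 0 or mean_dry_weight_g < 0:
        raise ValueError("count and mean dry weight must be non-negative")
    return count * mean_dry_weight_g / 1000.0


def yield_report(
    records: list[PlantRecord],
    model: AllometryModel,
    mean_dry_weight_g: float,
    intercept_mode: str = "per_plant",
) -> YieldReport:
    """Both estimators and their absolute difference for one census."""
    by_area = yield_by_area(records, model, intercept_mode)
    by_count = yield_by_count(len(records), mean_dry_weight_g)
    return YieldReport(
        count=len(records),
        total_leaf_area_m2=float(sum(r.leaf_area for r in records)),
        mean_dry_weight_g=float(mean_dry_weight_g),
        yield_by_area_kg=float(by_area),
        yield_by_count_kg=float(by_count),
        difference_kg=float(abs(by_area - by_count)),
    )
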