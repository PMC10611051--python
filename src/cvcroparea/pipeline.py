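"""The fixed-order crop-area pipeline.

Order is pinned: (optional) date screening/subsetting -> per-date
enhanced Lee despeckling -> temporal CV -> threshold -> (optional) sieve.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np

from .containers import BinaryCropMap, CVRaster, RadarStack
from .cv import build_annual_stack, classify_cv, temporal_cv
from .lee import enhanced_lee_filter
from .sieve import sieve as _sieve

__all__ = ["CropAreaResult", "run_pipeline", "despeckle_stack"]


@dataclass
class CropAreaResult:
    """Outputs of one crop-area run: CV raster, raw and sieved maps."""

    cv_raster: CVRaster
    crop_map: BinaryCropMap          # CA_ns: before sieving
    crop_map_sieved: BinaryCropMap   # CA: after sieving


def despeckle_stack(
    stack: RadarStack,
    window_size: int = 7,
    looks_L: float = 9.0,
    damping: float = 1.0,
) -> RadarStack:
    """Apply the enhanced Lee filter to every date of a stack."""
    filtered = np.stack(
        [
            enhanced_lee_filter(stack.values[t], window_size, looks_L, damping)
            for t in range(stack.n_dates)
        ]
    ).astype(np.float32)
    return RadarStack(stack.grid, list(stack.dates), filtered)


def run_pipeline(
    stack: RadarStack,
    cv_thr: float = 0.25,
    lee_window: int = 7,
    looks_L: float = 9.0,
    damping: float = 1.0,
    min_valid_dates: int = 2,
    start_date: _dt.date | None = None,
    end_date: _dt.date | None = None,
    exclude_dates: list[_dt.date] | None = None,
    sieve_min_size: int = 20,
    connectivity: int = 4,
    despeckle: bool = True,
) -> CropAreaResult:
    """Run the full crop-area pipeline in its fixed order."""
    if start_date or end_date or exclude_dates:
        stack = build_annual_stack(stack, start_date, end_date, exclude_dates)
    if despeckle:
        stack = despeckle_stack(stack, lee_window, looks_L, damping)
    cvr = temporal_cv(stack, min_valid_dates=min_valid_dates)
    crop_map = classify_cv(cvr, cv_thr)
    sieved = _sieve(crop_map, sieve_min_size, connectivity)
    return CropAreaResult(cvr, crop_map, sieved)
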