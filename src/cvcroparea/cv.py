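"""Temporal coefficient-of-variation crop mapping.

The classification premise: agricultural field management (tilling, crop
growth, harvest) changes the radar cross section of crop pixels over the
season far more than it changes forests or most built-up surfaces.  The
per-pixel temporal coefficient of variation

    CV = sigma / mu

(sigma the population temporal standard deviation, mu the temporal mean
of linear-power backscatter) is therefore high over crops and low over
stable covers, and a single threshold CV_thr turns the CV raster into a
binary crop / non-crop map:

    label = 1 (crop)      if CV >= CV_thr
    label = 0 (non-crop)  if CV <  CV_thr
"""
from __future__ import annotations

import datetime as _dt

import numpy as np

from .containers import MASK, BinaryCropMap, CVRaster, RadarStack

__all__ = [
    "temporal_cv",
    "classify_cv",
    "flag_anomalous_dates",
    "build_annual_stack",
]


def temporal_cv(stack: RadarStack, min_valid_dates: int = 2) -> CVRaster:
    """Per-pixel temporal CV (Eq. CV = sigma/mu) over valid dates.

    sigma is the *population* standard deviation (divide by the number of
    valid dates, not N-1).  A pixel is invalid (CV = NaN) when it has
    fewer than ``min_valid_dates`` finite observations or its temporal
    mean is nonpositive.
    """
    if stack.n_dates < 2:
        raise ValueError("temporal CV needs a stack with at least 2 dates")
    if min_valid_dates < 2:
        raise ValueError("min_valid_dates must be >= 2")

    vals = stack.values.astype(np.float64)
    valid = np.isfinite(vals)
    n_valid = valid.sum(axis=0)

    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # all-NaN pixels legitimately produce NaN statistics
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mu = np.nanmean(np.where(valid, vals, np.nan), axis=0)
        sigma = np.nanstd(np.where(valid, vals, np.nan), axis=0)  # population std
        cv = sigma / mu

    bad = (n_valid < min_valid_dates) | ~(mu > 0)
    cv = np.where(bad, np.nan, cv)
    sigma = np.where(n_valid == 0, np.nan, sigma)
    mu = np.where(n_valid == 0, np.nan, mu)
    return CVRaster(stack.grid, cv=cv, sigma=sigma, mu=mu, n_valid_dates=n_valid)


def classify_cv(cvr: CVRaster, cv_thr: float) -> BinaryCropMap:
    """Threshold a CV raster into a binary crop map.

    Pixels with CV >= ``cv_thr`` are crop (1), below are non-crop (0),
    invalid CV pixels become MASK.
    """
    if not cv_thr > 0:
        raise ValueError("cv_thr must be positive")
    labels = np.where(cvr.cv >= cv_thr, 1, 0).astype(np.uint8)
    labels[~np.isfinite(cvr.cv)] = MASK
    return BinaryCropMap(cvr.grid, labels)


def flag_anomalous_dates(
    stack: RadarStack,
    z_threshold: float = 3.5,
    min_relative_deviation: float = 0.2,
) -> np.ndarray:
    """Advisory screen for dates with scene-wide intensity artifacts.

    Radio-frequency interference and similar artifacts inflate intensities
    over a sizeable part of the scene on individual dates.  Each date is
    summarized by its scene-wide median intensity; a date is flagged when
    the robust z-score of its median — 0.6745 * (x - med) / MAD against
    the median and median absolute deviation of all dates' medians —
    exceeds ``z_threshold`` in absolute value.

    Because scene medians over many pixels are extremely tight, small
    seasonal drift (crop phenology shifting the median by a few percent)
    can reach large robust z-scores without being an artifact.  A date is
    therefore only flagged when its median additionally deviates from the
    across-date center by more than ``min_relative_deviation`` (default
    20% — gross artifacts such as interference stripes move the median
    by tens of percent).

    Returns a boolean array of length ``n_dates``.  Advisory only: callers
    decide whether to exclude flagged dates (see `build_annual_stack`).
    """
    if stack.n_dates < 4:
        raise ValueError("date screening needs at least 4 dates")
    medians = np.array(
        [np.nanmedian(stack.values[t]) for t in range(stack.n_dates)], dtype=float
    )
    center = np.median(medians)
    mad = np.median(np.abs(medians - center))
    if mad == 0 or center <= 0:
        return np.zeros(stack.n_dates, dtype=bool)
    z = 0.6745 * (medians - center) / mad
    relative = np.abs(medians - center) / center
    return (np.abs(z) > z_threshold) & (relative > min_relative_deviation)


def build_annual_stack(
    stack: RadarStack,
    start_date: _dt.date | None = None,
    end_date: _dt.date | None = None,
    exclude_dates: list[_dt.date] | None = None,
) -> RadarStack:
    """Subset a stack to a seasonal window, dropping excluded dates.

    The analysis window brackets the planting-to-harvest season (the
    study cadence is annual); dates flagged as corrupted can be removed
    via ``exclude_dates``.  Errors if fewer than 2 dates remain.
    """
    excluded = set(exclude_dates or [])
    keep = [
        i
        for i, d in enumerate(stack.dates)
        if (start_date is None or d >= start_date)
        and (end_date is None or d <= end_date)
        and d not in excluded
    ]
    if len(keep) < 2:
        raise ValueError("date selection leaves fewer than 2 dates")
    return RadarStack(
        stack.grid, [stack.dates[i] for i in keep], stack.values[keep].copy()
    )
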