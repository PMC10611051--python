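"""Synthetic radar scenes for end-to-end pipeline testing.

The generator emulates the statistical structure of a despeckle-ready
VH backscatter time series over an agricultural landscape: a mosaic of
rectangular crop fields whose temporal mean intensity step-changes at
management events (tilling, growth, harvest), forests and built-up areas
with a constant temporal mean, a minority of built-up pixels given
crop-like dynamics (double-bounce/parking-lot variability), and a water
body that is masked in the land cover.  Per-date pixel intensities are
L-look gamma speckle: intensity ~ Gamma(shape=L, mean=mu_t), so the
temporal CV of a constant-mean pixel concentrates at 1/sqrt(L).

This is a stylization of management-driven radar change, not a crop
growth or electromagnetic scattering model.
"""
from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import (
    MASK,
    BinaryCropMap,
    LandCoverRaster,
    RadarStack,
    TruthPolygon,
    rectangle_polygon,
)
from .cv import temporal_cv
from .grid import SceneGrid

__all__ = [
    "EventModel",
    "SceneConfig",
    "SyntheticBundle",
    "generate_scene",
    "inject_rfi",
    "write_fixture_bundle",
]

#: Synthetic land-cover legend (CDL-style codes).
SYNTHETIC_LEGEND = {
    1: "corn",
    5: "soybeans",
    111: "open water",
    121: "developed",
    141: "forest",
    176: "grass/pasture",
}
SYNTHETIC_CROP_CODES = frozenset({1, 5})
SYNTHETIC_MASKED_CODES = frozenset({111})


@dataclass(frozen=True)
class EventModel:
    """Management events as multiplicative step changes of the temporal mean.

    Each field receives between ``n_events_min`` and ``n_events_max``
    events at uniform-random dates; every event multiplies the current
    mean by a log-uniform factor in ``[gain_min, gain_max]``.  Factors
    with magnitude below ``min_magnitude`` (between 1/min and min) are
    resampled so that every event is a substantive change — management
    events alter VH backscatter by a couple of dB or more, and a x1.5
    floor (~1.8 dB) encodes that.  Set ``gain_min = gain_max = 1`` and
    ``min_magnitude = 1`` for the no-signal null configuration.
    """

    n_events_min: int = 1
    n_events_max: int = 4
    gain_min: float = 0.3
    gain_max: float = 3.0
    min_magnitude: float = 1.5

    def __post_init__(self) -> None:
        if not (0 < self.gain_min <= self.gain_max):
            raise ValueError("need 0 < gain_min <= gain_max")
        if self.n_events_min < 1 or self.n_events_max < self.n_events_min:
            raise ValueError("need 1 <= n_events_min <= n_events_max")

    def sample_factor(self, rng: np.random.Generator) -> float:
        if self.gain_min == self.gain_max:
            return self.gain_min
        lo, hi = np.log(self.gain_min), np.log(self.gain_max)
        for _ in range(1000):
            f = float(np.exp(rng.uniform(lo, hi)))
            if self.min_magnitude <= 1 or not (
                1 / self.min_magnitude < f < self.min_magnitude
            ):
                return f
        raise RuntimeError("event factor sampling failed; check gain range")


def null_event_model() -> EventModel:
    """No-signal configuration: all mean shifts are x1.0."""
    return EventModel(gain_min=1.0, gain_max=1.0, min_magnitude=1.0)


@dataclass(frozen=True)
class SceneConfig:
    """Full parameterization of a synthetic scene."""

    grid_width: int = 160
    grid_height: int = 160
    pixel_size: float = 30.0
    n_dates: int = 18
    looks_L: float = 9.0
    class_fractions: dict = field(
        default_factory=lambda: {
            "crop": 0.25,
            "forest": 0.35,
            "built-up": 0.20,
            "water": 0.03,
        }
    )
    n_crop_fields: int = 30
    n_builtup_polygons: int = 8
    n_forest_polygons: int = 5
    event_model: EventModel = field(default_factory=EventModel)
    builtup_dynamic_fraction: float = 0.05
    rfi_dates: tuple = ()
    rfi_gain: float = 10.0
    seed: int = 0
    # mean linear-power levels per cover (VH-like magnitudes)
    mean_levels: dict = field(
        default_factory=lambda: {
            "crop": 0.020,
            "forest": 0.030,
            "built-up": 0.050,
            "water": 0.003,
            "background": 0.015,
        }
    )

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if total > 1 + 1e-9:
            raise ValueError(f"class fractions sum to {total:.3f} > 1")
        if min(self.class_fractions.values(), default=0) < 0:
            raise ValueError("class fractions must be nonnegative")
        for name in ("grid_width", "grid_height", "n_dates", "n_crop_fields",
                     "n_builtup_polygons", "n_forest_polygons"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.looks_L < 1:
            raise ValueError("looks_L must be >= 1")
        if any(not 0 <= d < self.n_dates for d in self.rfi_dates):
            raise ValueError("rfi_dates out of range")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SyntheticBundle:
    """A generated scene plus its ground truth and provenance."""

    stack: RadarStack
    truth_polygons: list[TruthPolygon]
    landcover: LandCoverRaster
    truth_pixel_labels: BinaryCropMap
    generative_cv_crossover: float
    config: SceneConfig


class PlacementError(RuntimeError):
    """Raised when polygons cannot be placed; the grid is too small."""


def _place_rectangles(
    rng: np.random.Generator,
    occupied: np.ndarray,
    n_polygons: int,
    target_pixels: int,
    min_dim: int = 3,
    max_aspect: float = 4.0,
    max_tries: int = 200,
) -> list[tuple[int, int, int, int]]:
    """Place non-overlapping axis-aligned pixel rectangles (r0, c0, h, w).

    Rectangles keep a one-pixel gap from previously placed ones.  Failure
    after ``max_tries`` attempts per rectangle signals a too-small grid.
    """
    h_grid, w_grid = occupied.shape
    mean_area = max(target_pixels / n_polygons, min_dim * min_dim)
    rects = []
    for _ in range(n_polygons):
        for attempt in range(max_tries):
            # shrink the drawn area as attempts fail so packing still succeeds
            shrink = 0.97 ** attempt
            area = max(mean_area * shrink, min_dim * min_dim) * float(
                np.exp(rng.normal(0.0, 0.35))
            )
            aspect = float(rng.uniform(1.0, max_aspect))
            if rng.random() < 0.5:
                aspect = 1.0 / aspect
            rh = max(min_dim, int(round(np.sqrt(area * max(aspect, 1 / aspect)))))
            rw = max(min_dim, int(round(area / rh)))
            if rh > h_grid - 2 or rw > w_grid - 2:
                continue
            r0 = int(rng.integers(1, h_grid - rh))
            c0 = int(rng.integers(1, w_grid - rw))
            window = occupied[max(r0 - 1, 0): r0 + rh + 1, max(c0 - 1, 0): c0 + rw + 1]
            if not window.any():
                occupied[r0: r0 + rh, c0: c0 + rw] = True
                rects.append((r0, c0, rh, rw))
                break
        else:
            raise PlacementError(
                "could not place all polygons; increase the grid or lower fractions"
            )
    return rects


def _rect_geometry(grid: SceneGrid, r0: int, c0: int, rh: int, rw: int):
    x0 = grid.origin_x + c0 * grid.pixel_size_x
    x1 = grid.origin_x + (c0 + rw) * grid.pixel_size_x
    y0 = grid.origin_y + r0 * grid.pixel_size_y
    y1 = grid.origin_y + (r0 + rh) * grid.pixel_size_y
    return rectangle_polygon(x0, y0, x1, y1)


def _event_mean_profile(
    rng: np.random.Generator, base: float, n_dates: int, model: EventModel
) -> np.ndarray:
    """Piecewise-constant temporal mean with multiplicative step changes."""
    k = int(rng.integers(model.n_events_min, model.n_events_max + 1))
    times = rng.choice(np.arange(1, n_dates), size=min(k, n_dates - 1), replace=False)
    mu = np.full(n_dates, base, dtype=np.float64)
    level = base
    for t in sorted(int(t) for t in times):
        level = level * model.sample_factor(rng)
        mu[t:] = level
    return mu


def generate_scene(config: SceneConfig) -> SyntheticBundle:
    """Generate a complete synthetic scene; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    h, w = config.grid_height, config.grid_width
    n_px = h * w
    grid = SceneGrid(
        origin_x=300_000.0, origin_y=4_330_000.0,
        pixel_size_x=config.pixel_size, pixel_size_y=-config.pixel_size,
        width=w, height=h,
    )

    # place the large land-cover blocks first, then fit crop fields around them
    occupied = np.zeros((h, w), dtype=bool)
    fr = config.class_fractions
    forest_rects = _place_rectangles(
        rng, occupied, config.n_forest_polygons, int(fr.get("forest", 0) * n_px),
        min_dim=4,
    )
    builtup_rects = _place_rectangles(
        rng, occupied, config.n_builtup_polygons, int(fr.get("built-up", 0) * n_px),
        min_dim=4,
    )
    water_rects = (
        _place_rectangles(rng, occupied, 1, max(int(fr.get("water", 0) * n_px), 9))
        if fr.get("water", 0) > 0
        else []
    )
    crop_rects = _place_rectangles(
        rng, occupied, config.n_crop_fields, int(fr.get("crop", 0) * n_px)
    )

    levels = config.mean_levels
    codes = np.full((h, w), 176, dtype=np.int64)  # background grass/pasture
    truth = np.zeros((h, w), dtype=np.uint8)
    mu = np.empty((config.n_dates, h, w), dtype=np.float64)
    mu[:] = levels["background"] * float(np.exp(rng.normal(0.0, 0.1)))

    polygons: list[TruthPolygon] = []

    for i, (r0, c0, rh, rw) in enumerate(crop_rects):
        base = levels["crop"] * float(np.exp(rng.normal(0.0, 0.2)))
        profile = _event_mean_profile(rng, base, config.n_dates, config.event_model)
        mu[:, r0: r0 + rh, c0: c0 + rw] = profile[:, None, None]
        codes[r0: r0 + rh, c0: c0 + rw] = int(rng.choice([1, 5]))
        truth[r0: r0 + rh, c0: c0 + rw] = 1
        polygons.append(
            TruthPolygon(f"field-{i:03d}", "crop", _rect_geometry(grid, r0, c0, rh, rw))
        )

    for i, (r0, c0, rh, rw) in enumerate(forest_rects):
        base = levels["forest"] * float(np.exp(rng.normal(0.0, 0.1)))
        mu[:, r0: r0 + rh, c0: c0 + rw] = base
        codes[r0: r0 + rh, c0: c0 + rw] = 141
        polygons.append(
            TruthPolygon(f"forest-{i:03d}", "forest", _rect_geometry(grid, r0, c0, rh, rw))
        )

    for i, (r0, c0, rh, rw) in enumerate(builtup_rects):
        base = levels["built-up"] * float(np.exp(rng.normal(0.0, 0.15)))
        mu[:, r0: r0 + rh, c0: c0 + rw] = base
        codes[r0: r0 + rh, c0: c0 + rw] = 121
        # a minority of built-up pixels behaves like crop (double bounce,
        # parking-lot activity): give them their own event profiles
        block = rng.random((rh, rw)) < config.builtup_dynamic_fraction
        rows, cols = np.nonzero(block)
        for rr, cc in zip(rows, cols):
            mu[:, r0 + rr, c0 + cc] = _event_mean_profile(
                rng, base, config.n_dates, config.event_model
            )
        polygons.append(
            TruthPolygon(
                f"builtup-{i:03d}", "built-up", _rect_geometry(grid, r0, c0, rh, rw)
            )
        )

    for (r0, c0, rh, rw) in water_rects:
        mu[:, r0: r0 + rh, c0: c0 + rw] = levels["water"]
        codes[r0: r0 + rh, c0: c0 + rw] = 111
        truth[r0: r0 + rh, c0: c0 + rw] = MASK

    # L-look gamma speckle around the temporal mean
    values = rng.gamma(shape=config.looks_L, scale=mu / config.looks_L).astype(np.float32)

    # ~12-day revisit cadence across the season
    start = _dt.date(2021, 3, 20)
    span_days = 240
    step = max(span_days // max(config.n_dates - 1, 1), 1)
    dates = [start + _dt.timedelta(days=step * t) for t in range(config.n_dates)]
    stack = RadarStack(grid, dates, values)

    cvr = temporal_cv(stack)
    crop_med = float(np.nanmedian(cvr.cv[truth == 1]))
    noncrop_med = float(np.nanmedian(cvr.cv[truth == 0]))
    crossover = 0.5 * (crop_med + noncrop_med)

    if config.rfi_dates:
        stripe = (int(0.3 * h), int(0.7 * h))
        stack = inject_rfi(stack, list(config.rfi_dates), stripe, config.rfi_gain)

    landcover = LandCoverRaster(grid, codes, dict(SYNTHETIC_LEGEND))
    truth_map = BinaryCropMap(grid, truth)
    return SyntheticBundle(
        stack=stack,
        truth_polygons=polygons,
        landcover=landcover,
        truth_pixel_labels=truth_map,
        generative_cv_crossover=crossover,
        config=config,
    )


def inject_rfi(
    stack: RadarStack,
    date_indices: list[int],
    stripe_geometry: tuple[int, int],
    gain: float,
) -> RadarStack:
    """Corrupt a horizontal stripe on the listed dates by a gain factor.

    ``stripe_geometry`` is a half-open row interval ``(row_start, row_stop)``
    in pixels.  Returns a new stack; the input is untouched.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    for t in date_indices:
        if not 0 <= t < stack.n_dates:
            raise IndexError(f"date index {t} out of range for {stack.n_dates} dates")
    r0, r1 = stripe_geometry
    if not (0 <= r0 < r1 <= stack.grid.height):
        raise ValueError(f"invalid stripe rows {stripe_geometry}")
    out = stack.copy()
    for t in date_indices:
        out.values[t, r0:r1, :] *= gain
    return out


def write_fixture_bundle(bundle: SyntheticBundle, directory: str | Path) -> dict:
    """Write a bundle to disk in the package's standard formats.

    Returns (and writes) a manifest listing the files, the seed and a
    hash of the generating configuration.
    """
    from .io import write_landcover, write_polygons, write_raster, write_stack

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {
        "stack": "stack.tif",
        "dates": "dates.csv",
        "polygons": "truth_polygons.geojson",
        "landcover": "landcover.tif",
        "legend": "legend.json",
        "truth_labels": "truth_labels.tif",
    }
    write_stack(bundle.stack, directory / files["stack"], directory / files["dates"])
    write_polygons(
        bundle.truth_polygons, directory / files["polygons"],
        crs_id=bundle.stack.grid.crs_id,
    )
    write_landcover(
        bundle.landcover, directory / files["landcover"], directory / files["legend"]
    )
    write_raster(
        directory / files["truth_labels"],
        bundle.truth_pixel_labels.labels,
        bundle.truth_pixel_labels.grid,
        nodata=str(MASK),
    )
    manifest = {
        "files": files,
        "seed": bundle.config.seed,
        "config_hash": bundle.config.config_hash(),
        "generative_cv_crossover": bundle.generative_cv_crossover,
        "n_polygons": len(bundle.truth_polygons),
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
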