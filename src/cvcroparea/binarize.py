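"""Binarize a categorical land-cover raster into crop / non-crop / masked.

A CDL-style product carries dozens of crop and land-cover classes; for
comparison against a radar crop map it is collapsed to three values:
codes listed as crops become 1, codes listed as masked (open water,
aquaculture, clouds/no-data, tree crops — covers where the temporal CV
is either noisy or systematically uninformative) become MASK, and every
other code becomes non-crop (0).

The mapping is config-driven rather than hardcoded so synthetic legends
and future land-cover revisions work unchanged.  A reference CDL mapping
ships as package data (``data/cdl_classmap.json``) as a convenience
default; it encodes the usual convention, not a tested claim.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .containers import MASK, BinaryCropMap, LandCoverRaster

__all__ = [
    "ClassMapConfig",
    "load_class_map",
    "save_class_map",
    "default_class_map",
    "binarize_landcover",
    "harmonize_masks",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassMapConfig:
    """Which land-cover codes count as crop and which are masked."""

    crop_codes: frozenset[int]
    masked_codes: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "crop_codes", frozenset(int(c) for c in self.crop_codes))
        object.__setattr__(
            self, "masked_codes", frozenset(int(c) for c in self.masked_codes)
        )
        overlap = self.crop_codes & self.masked_codes
        if overlap:
            raise ValueError(f"codes in both crop and masked sets: {sorted(overlap)}")


def load_class_map(path: str | Path) -> ClassMapConfig:
    """Load a class map from a JSON file with ``crop_codes`` / ``masked_codes``."""
    with open(path) as fh:
        payload = json.load(fh)
    try:
        return ClassMapConfig(
            crop_codes=frozenset(payload["crop_codes"]),
            masked_codes=frozenset(payload.get("masked_codes", [])),
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed class map file {path}: {exc}") from exc


def save_class_map(cmap: ClassMapConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "crop_codes": sorted(cmap.crop_codes),
                "masked_codes": sorted(cmap.masked_codes),
            },
            fh,
            indent=2,
        )


def default_class_map() -> ClassMapConfig:
    """The shipped CDL-convention class map."""
    ref = resources.files("cvcroparea.data") / "cdl_classmap.json"
    with resources.as_file(ref) as path:
        return load_class_map(path)


def binarize_landcover(lc: LandCoverRaster, cmap: ClassMapConfig) -> BinaryCropMap:
    """Collapse a categorical raster to {0 non-crop, 1 crop, MASK}."""
    present = set(int(c) for c in np.unique(lc.codes))
    missing = present - set(int(k) for k in lc.legend)
    if missing:
        raise ValueError(f"raster codes missing from legend: {sorted(missing)}")
    labels = np.zeros(lc.codes.shape, dtype=np.uint8)
    labels[np.isin(lc.codes, list(cmap.crop_codes))] = 1
    labels[np.isin(lc.codes, list(cmap.masked_codes))] = MASK
    counts = {v: int((labels == v).sum()) for v in (0, 1, MASK)}
    logger.info(
        "binarized land cover: %d non-crop, %d crop, %d masked pixels",
        counts[0], counts[1], counts[MASK],
    )
    return BinaryCropMap(lc.grid, labels)


def harmonize_masks(a: BinaryCropMap, b: BinaryCropMap) -> tuple[BinaryCropMap, BinaryCropMap]:
    """Apply the union of both maps' masks to each map.

    Areas masked in either map are masked in both before any comparison,
    so pixel-wise agreement is computed over a common valid domain.
    """
    from .grid import validate_grid_alignment

    if not validate_grid_alignment([a.grid, b.grid]):
        raise ValueError("maps are not on the same grid")
    union = (a.labels == MASK) | (b.labels == MASK)
    out_a, out_b = a.copy(), b.copy()
    out_a.labels[union] = MASK
    out_b.labels[union] = MASK
    return out_a, out_b
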