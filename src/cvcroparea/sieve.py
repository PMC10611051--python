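"""Post-classification sieve: absorb small connected components.

Connected components of class 0 or 1 smaller than ``min_size`` pixels are
reassigned to the value of their largest adjacent component, mimicking the
standard raster sieve used to remove classification speckle.  MASK pixels
are never created, destroyed, or counted in components, and components
touching only MASK or the raster edge are retained (a mask must not bleed
into classes).

Cascading semantics are pinned deterministically: eligible components are
processed in ascending size — all components sharing the current smallest
size form one batch, absorptions within a batch are computed against the
pre-batch labeling, and components are relabeled after each batch.  Ties
for the largest neighbor are broken toward the lowest class value.

`sieve_reference` re-implements the identical contract with explicit
flood-fill labeling and no vectorization; it exists as an independent
oracle for tests.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .containers import MASK, BinaryCropMap

__all__ = ["sieve", "sieve_reference"]

logger = logging.getLogger(__name__)

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def _label_components(labels: np.ndarray, connectivity: int):
    """Label non-MASK components; returns (comp ids raster, value per id, size per id)."""
    structure = _STRUCTURES[connectivity]
    comp = np.zeros(labels.shape, dtype=np.int64)
    values: dict[int, int] = {}
    offset = 0
    for v in (0, 1):
        lab, n = ndimage.label(labels == v, structure=structure)
        comp[lab > 0] = lab[lab > 0] + offset
        for i in range(1, n + 1):
            values[offset + i] = v
        offset += n
    sizes = np.bincount(comp.ravel(), minlength=offset + 1)
    return comp, values, sizes


def _adjacency(comp: np.ndarray, connectivity: int) -> dict[int, set[int]]:
    """Adjacent component pairs from directional shifts."""
    shifts = [(0, 1), (1, 0)]
    if connectivity == 8:
        shifts += [(1, 1), (1, -1)]
    neighbors: dict[int, set[int]] = {}
    for dr, dc in shifts:
        a = comp[max(dr, 0) or None : comp.shape[0] - max(-dr, 0) or None,
                 max(dc, 0) or None : comp.shape[1] - max(-dc, 0) or None]
        b = comp[max(-dr, 0) or None : comp.shape[0] - max(dr, 0) or None,
                 max(-dc, 0) or None : comp.shape[1] - max(dc, 0) or None]
        touch = (a != b) & (a > 0) & (b > 0)
        for x, y in zip(a[touch].ravel(), b[touch].ravel()):
            neighbors.setdefault(int(x), set()).add(int(y))
            neighbors.setdefault(int(y), set()).add(int(x))
    return neighbors


def sieve(cmap: BinaryCropMap, min_size: int = 20, connectivity: int = 4) -> BinaryCropMap:
    """Remove connected components smaller than ``min_size`` pixels.

    "Smaller than" is strict: a component of exactly ``min_size`` pixels
    is retained.  ``min_size=0`` is the identity.
    """
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels = cmap.labels.copy()
    if min_size == 0:
        return BinaryCropMap(cmap.grid, labels)

    while True:
        comp, values, sizes = _label_components(labels, connectivity)
        neighbors = _adjacency(comp, connectivity)
        eligible = [
            c
            for c, v in values.items()
            if sizes[c] < min_size and neighbors.get(c)
        ]
        if not eligible:
            break
        batch_size = min(int(sizes[c]) for c in eligible)
        batch = [c for c in eligible if sizes[c] == batch_size]
        for c in batch:
            # largest adjacent component; ties -> lowest class value
            best = max(neighbors[c], key=lambda d: (sizes[d], -values[d]))
            tied = [d for d in neighbors[c] if sizes[d] == sizes[best]]
            if len(tied) > 1:
                logger.debug(
                    "sieve tie among neighbors of component %d (size %d)", c, batch_size
                )
            labels[comp == c] = values[best]

    isolated = [
        c for c, v in _zip_isolated(labels, connectivity, min_size)
    ]
    if isolated:
        logger.info(
            "sieve retained %d small component(s) with no non-mask neighbor", len(isolated)
        )
    return BinaryCropMap(cmap.grid, labels)


def _zip_isolated(labels, connectivity, min_size):
    comp, values, sizes = _label_components(labels, connectivity)
    neighbors = _adjacency(comp, connectivity)
    for c, v in values.items():
        if sizes[c] < min_size and not neighbors.get(c):
            yield c, v


def sieve_reference(
    cmap: BinaryCropMap, min_size: int = 20, connectivity: int = 4
) -> BinaryCropMap:
    """Brute-force sieve with explicit flood fill; test oracle for `sieve`."""
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    grid = [[int(v) for v in row] for row in cmap.labels]
    h, w = cmap.labels.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]

    def components():
        """List of (value, set of cells) for non-MASK components."""
        seen = [[False] * w for _ in range(h)]
        comps = []
        for r in range(h):
            for c in range(w):
                if seen[r][c] or grid[r][c] == MASK:
                    continue
                v = grid[r][c]
                stack, cells = [(r, c)], set()
                seen[r][c] = True
                while stack:
                    cr, cc = stack.pop()
                    cells.add((cr, cc))
                    for dr, dc in steps:
                        nr, nc = cr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and not seen[nr][nc]:
                            if grid[nr][nc] == v:
                                seen[nr][nc] = True
                                stack.append((nr, nc))
                comps.append((v, cells))
        return comps

    while True:
        comps = components()
        cell_to_comp = {}
        for i, (_, cells) in enumerate(comps):
            for cell in cells:
                cell_to_comp[cell] = i
        adj: list[set[int]] = [set() for _ in comps]
        for i, (_, cells) in enumerate(comps):
            for (r, c) in cells:
                for dr, dc in steps:
                    nr, nc = r + dr, c + dc
                    if 0 <= nr < h and 0 <= nc < w and grid[nr][nc] != MASK:
                        j = cell_to_comp[(nr, nc)]
                        if j != i:
                            adj[i].add(j)
        eligible = [
            i for i, (_, cells) in enumerate(comps) if len(cells) < min_size and adj[i]
        ]
        if not eligible:
            break
        batch_size = min(len(comps[i][1]) for i in eligible)
        batch = [i for i in eligible if len(comps[i][1]) == batch_size]
        for i in batch:
            best = max(adj[i], key=lambda j: (len(comps[j][1]), -comps[j][0]))
            new_value = comps[best][0]
            for (r, c) in comps[i][1]:
                grid[r][c] = new_value

    return BinaryCropMap(cmap.grid, np.array(grid, dtype=np.uint8))
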