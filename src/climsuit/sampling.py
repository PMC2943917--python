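"""Replicated pseudo-presence / pseudo-absence / background sampling.

Pseudo-presence points are drawn uniformly over the cells of a rasterized
range mask and placed at cell centres (predictors are cell-constant, so
sub-cell jitter would add no information while breaking exact
reproducibility).  Every sampler is a deterministic function of a derived
seed so that replicate sets form independent, order-insensitive streams.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np

from .grids import BioclimStack, Grid, PointSet, require_aligned

logger = logging.getLogger(__name__)


def derive_seed(master_seed: int, *parts: object) -> int:
    """Derive a child stream seed from a master seed and a label path.

    Hash-based so that streams for distinct (species, period, role, set)
    tuples are independent and do not depend on execution order.
    """
    key = "|".join([str(master_seed), *[str(p) for p in parts]])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RangeMask:
    """Boolean occupancy grid for one species and period.

    When both periods exist for a species the modern range must be nested
    inside the historical one (the historical range was larger and
    encompassed all of the modern range).
    """

    mask: Grid
    period: str = "modern"        # modern | historical
    species_label: str = "species"

    def __post_init__(self) -> None:
        vals = self.mask.values
        occ = (vals != 0) & self.mask.valid_mask()
        if not occ.any():
            raise ValueError("range mask has no occupied cells")

    def occupied(self) -> np.ndarray:
        return (self.mask.values != 0) & self.mask.valid_mask()

    def n_occupied(self) -> int:
        return int(self.occupied().sum())


def check_nested(modern: RangeMask, historical: RangeMask) -> None:
    """Assert modern ⊆ historical; raised at load time and by the generator."""
    require_aligned(modern.mask, historical.mask)
    stray = modern.occupied() & ~historical.occupied()
    if stray.any():
        raise ValueError(
            f"modern range is not nested in historical range: "
            f"{int(stray.sum())} modern cells fall outside the historical mask"
        )


@dataclass
class SampleDesign:
    """Replicated sampling layout: ``n_sets`` sets of ``n_points`` points.

    Defaults give the ten-sets-of-100-points layout used for model training.
    """

    n_points: int = 100
    n_sets: int = 10
    seed: int = 0
    with_replacement: bool = False

    def __post_init__(self) -> None:
        if self.n_points < 1 or self.n_sets < 1:
            raise ValueError("n_points and n_sets must be >= 1")


def _cells_to_points(grid: Grid, rows: np.ndarray, cols: np.ndarray,
                     prefix: str, role: str, period: str, seed: int) -> PointSet:
    xs = np.empty(rows.size)
    ys = np.empty(rows.size)
    for i, (r, c) in enumerate(zip(rows, cols)):
        xs[i], ys[i] = grid.cell_center(int(r), int(c))
    ids = [f"{prefix}_{i}" for i in range(rows.size)]
    return PointSet(ids=ids, x=xs, y=ys, role=role, period=period, seed=seed)


def sample_presence(mask: RangeMask, design: SampleDesign, set_index: int,
                    role: str = "train") -> PointSet:
    """Draw one replicate set of pseudo-presence points from a range mask.

    Cells are chosen uniformly among occupied cells; points are placed at
    cell centres.  Deterministic in (seed, species, period, role, set_index).
    """
    occ = mask.occupied()
    rows, cols = np.nonzero(occ)
    n_avail = rows.size
    if not design.with_replacement and n_avail < design.n_points:
        raise ValueError(
            f"cannot draw {design.n_points} points without replacement from a mask "
            f"with only {n_avail} occupied cells"
        )
    if design.with_replacement:
        logger.info("sampling %d presences with replacement from %d cells",
                    design.n_points, n_avail)
    seed = derive_seed(design.seed, mask.species_label, mask.period, role, set_index)
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_avail, size=design.n_points, replace=design.with_replacement)
    return _cells_to_points(mask.mask, rows[idx], cols[idx],
                            prefix=f"{mask.period[0]}{set_index}", role=role,
                            period=mask.period, seed=seed)


def sample_absence(mask: RangeMask, region: Grid, n_points: int, seed: int,
                   set_index: int = 0, role: str = "test") -> PointSet:
    """Draw pseudo-absence points uniformly from region cells outside the mask."""
    require_aligned(mask.mask, region)
    pool = (region.values != 0) & region.valid_mask() & ~mask.occupied()
    rows, cols = np.nonzero(pool)
    if rows.size < n_points:
        raise ValueError(
            f"cannot draw {n_points} absence points: region minus mask has only "
            f"{rows.size} cells"
        )
    child = derive_seed(seed, mask.species_label, mask.period, "absence", role, set_index)
    rng = np.random.default_rng(child)
    idx = rng.choice(rows.size, size=n_points, replace=False)
    return _cells_to_points(mask.mask, rows[idx], cols[idx],
                            prefix=f"a{set_index}", role=role,
                            period=mask.period, seed=child)


def sample_background(stack: BioclimStack, region: Grid, max_n: int,
                      seed: int) -> PointSet:
    """Background sample characterizing the available environment of a region.

    If the region holds at most ``max_n`` valid cells, all cell centres are
    returned in row-major order; otherwise a uniform random subset of size
    ``max_n`` is drawn (deterministic per seed).
    """
    require_aligned(stack.grid, region)
    pool = (region.values != 0) & region.valid_mask() & stack.valid_mask()
    rows, cols = np.nonzero(pool)
    if rows.size == 0:
        raise ValueError("background region is empty")
    if rows.size > max_n:
        rng = np.random.default_rng(derive_seed(seed, "background"))
        idx = np.sort(rng.choice(rows.size, size=max_n, replace=False))
        rows, cols = rows[idx], cols[idx]
    return _cells_to_points(stack.grid, rows, cols, prefix="bg", role="background",
                            period="", seed=seed)
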