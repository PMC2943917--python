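"""Non-analog-climate diagnostics for cross-continent projections.

When a model is projected onto a region whose climates fall outside the
training envelope, clamping silently pins the response at the boundary.
These diagnostics make that visible: a per-cell count of out-of-envelope
predictors (``novelty``), two-variable envelope-edge scatter data, and
suitable-area summaries for comparing projections trained on modern versus
historical ranges.

The envelope is rectangular — a per-variable (min, max) bounds check against
the training clamp bounds — matching the two-variable envelope-edge reasoning
it supports; multivariate similarity surfaces are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .grids import BioclimStack, Grid, PointSet, extract, require_aligned
from .maxent import MaxentModel


@dataclass
class EnvelopeSummary:
    """Training envelope bounds plus per-cell out-of-bounds accounting."""

    var_bounds: dict[str, tuple[float, float]]
    count_grid: Grid
    clamped_vars: dict[tuple[int, int], tuple[str, ...]]


def envelope_scatter(
    stack: BioclimStack,
    var_x: str,
    var_y: str,
    groups: dict[str, PointSet],
) -> pd.DataFrame:
    """Two-variable scatter table for envelope-edge inspection.

    ``groups`` maps a group label (e.g. native_range, native_continent,
    transfer_continent, focal) to the point set to sample; the result has
    columns ``group, x, y`` ready for plotting var_y against var_x.
    """
    for v in (var_x, var_y):
        if v not in stack.layers:
            raise ValueError(f"unknown variable {v!r}")
    frames = []
    for label, pts in groups.items():
        tab = extract(stack, pts)
        tab = tab[tab["valid"]]
        frames.append(pd.DataFrame({"group": label, "x": tab[var_x].to_numpy(),
                                    "y": tab[var_y].to_numpy()}))
    return pd.concat(frames, ignore_index=True)


def novelty(model: MaxentModel, stack: BioclimStack,
            region: Grid | None = None) -> EnvelopeSummary:
    """Count, per cell, the predictors outside the model's training bounds.

    A count of 0 at a cell is equivalent to clamped and unclamped projection
    agreeing there.  ``region`` restricts the diagnostic; elsewhere the count
    grid is nodata.
    """
    g = stack.grid
    valid = stack.valid_mask()
    if region is not None:
        require_aligned(g, region)
        valid = valid & (region.values != 0) & region.valid_mask()
    counts = np.zeros(g.shape)
    clamped: dict[tuple[int, int], tuple[str, ...]] = {}
    names: list[np.ndarray] = []
    oob_stack = []
    for v in model.spec.variables:
        lo, hi = model.spec.var_bounds[v]
        vals = stack.layers[v].values
        oob = valid & ((vals < lo) | (vals > hi))
        counts += oob
        oob_stack.append(oob)
    rows, cols = np.nonzero(counts > 0)
    for r, c in zip(rows, cols):
        clamped[(int(r), int(c))] = tuple(
            v for v, oob in zip(model.spec.variables, oob_stack) if oob[r, c])
    count_grid = g.with_values(np.where(valid, counts, g.nodata))
    return EnvelopeSummary(var_bounds=dict(model.spec.var_bounds),
                           count_grid=count_grid, clamped_vars=clamped)


def suitable_area(binary_map: Grid, region: Grid) -> tuple[int, float]:
    """Suitable cell count within a region and its fraction of the region."""
    require_aligned(binary_map, region)
    in_region = (region.values != 0) & region.valid_mask()
    n_region = int(in_region.sum())
    if n_region == 0:
        raise ValueError("region is empty")
    suitable = in_region & binary_map.valid_mask() & (binary_map.values != 0)
    count = int(suitable.sum())
    return count, count / n_region
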