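"""Synthetic landscapes with known climatic truth.

Real analyses of this kind run on interpolated global climate surfaces and
digitized range maps; neither is redistributable at desk scale, so every
pipeline stage here is exercised on generated landscapes whose truth is
known exactly.  A scenario consists of:

- a raster holding two disjoint rectangular regions, *native* (columns on
  the left) and *transfer* (columns on the right), with monthly climate
  built from a north-south temperature gradient, a seasonal sinusoid whose
  amplitude grows with latitude, a positive diurnal-range field, a moisture
  gradient with a seasonal phase, and smoothed Gaussian noise — the
  transfer region uses shifted gradient parameters (colder, more seasonal)
  so part of it is deliberately non-analog to the native region;
- a true niche: an exponential-family (Gibbs) suitability surface over the
  ten bioclim predictors with user-chosen linear weights, normalized over
  the native region;
- a *historical* range mask occupying the most-suitable native cells at a
  target occupancy fraction, and a *modern* mask produced by contraction —
  either random, or cold-biased (preferential loss of the coldest occupied
  cells), which recreates the equilibrium-assumption violation the modern
  ranges of large mammals exhibit after human-driven contraction;
- a handful of naturalized-introduction points: transfer-region cells whose
  true suitability clears the occupancy threshold, chosen just above it so
  they sit at the edge of the climatic envelope.

Everything is a deterministic function of the master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import (
    BIOCLIM_NAMES,
    BioclimStack,
    Grid,
    MonthlyClimate,
    PointSet,
    derive_bioclim,
    read_grid,
    read_points,
    write_grid,
    write_points,
)
from .sampling import RangeMask, check_nested, derive_seed

_REF_SMOOTHNESS = 3.0  # noise amplitude calibrated to ~unit SD at this kernel width


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  smoothness: float) -> np.ndarray:
    """Smoothed Gaussian noise; amplitude shrinks toward 0 as smoothness grows."""
    white = rng.standard_normal(shape)
    field = gaussian_filter(white, sigma=smoothness, mode="nearest")
    return field * (2.0 * _REF_SMOOTHNESS * np.sqrt(np.pi))


@dataclass
class RegionClimate:
    """Gradient parameters for one region's climate."""

    t_north: float      # annual mean temperature at the northern edge (degC)
    t_south: float      # ... at the southern edge
    amp_north: float    # seasonal amplitude at the northern edge (degC)
    amp_south: float
    prec_west: float    # monthly moisture at the western edge (mm)
    prec_east: float    # ... at the eastern edge (continentality gradient)
    prec_season: float  # fractional seasonal modulation of precipitation
    prec_phase: int     # month of peak precipitation


#: Native region: warm, weakly seasonal, wetter toward the west coast.
#: Temperature runs north-south and moisture west-east (continentality), so
#: the two main climatic axes of the landscape are not confounded.
NATIVE_CLIMATE = RegionClimate(t_north=12.0, t_south=28.0, amp_north=8.0,
                               amp_south=2.0, prec_west=160.0, prec_east=40.0,
                               prec_season=0.7, prec_phase=0)
#: Transfer region: colder and more seasonal overall, so its north is
#: non-analog, while its warm southern edge overlaps the native envelope.
TRANSFER_CLIMATE = RegionClimate(t_north=0.0, t_south=26.0, amp_north=14.0,
                                 amp_south=4.0, prec_west=110.0, prec_east=30.0,
                                 prec_season=0.9, prec_phase=6)


def gen_climate(rows: int, cols: int, seed: int, smoothness: float = 3.0,
                native: RegionClimate = NATIVE_CLIMATE,
                transfer: RegionClimate = TRANSFER_CLIMATE,
                cell_size: float = 0.5) -> MonthlyClimate:
    """Generate monthly climate on a raster holding two side-by-side regions.

    The output grid is ``rows x 2*cols``: native columns ``[0, cols)``,
    transfer columns ``[cols, 2*cols)``.  Deterministic per seed.
    """
    if rows < 4 or cols < 4:
        raise ValueError("rows and cols must both be >= 4")
    shape = (rows, 2 * cols)
    rng = np.random.default_rng(derive_seed(seed, "climate"))
    lat = np.linspace(0.0, 1.0, rows)[:, None] * np.ones((1, 2 * cols))  # 0=N, 1=S

    def blend(attr: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell north and south parameter values for each region."""
        n = np.empty(shape)
        s = np.empty(shape)
        n[:, :cols], s[:, :cols] = getattr(native, attr.replace("X", "north")), \
            getattr(native, attr.replace("X", "south"))
        n[:, cols:], s[:, cols:] = getattr(transfer, attr.replace("X", "north")), \
            getattr(transfer, attr.replace("X", "south"))
        return n, s

    def blend_we(attr: str) -> tuple[np.ndarray, np.ndarray]:
        w = np.empty(shape)
        e = np.empty(shape)
        w[:, :cols], e[:, :cols] = getattr(native, attr.replace("X", "west")), \
            getattr(native, attr.replace("X", "east"))
        w[:, cols:], e[:, cols:] = getattr(transfer, attr.replace("X", "west")), \
            getattr(transfer, attr.replace("X", "east"))
        return w, e

    tn, ts = blend("t_X")
    t_mean = tn + (ts - tn) * lat + 1.5 * _smooth_noise(rng, shape, smoothness)
    an, a_s = blend("amp_X")
    amp = an + (a_s - an) * lat
    diurnal = np.clip(8.0 + 3.0 * _smooth_noise(rng, shape, smoothness), 1.0, None)
    lon = np.empty(shape)                               # 0 = west edge, per region
    lon[:, :cols] = np.linspace(0.0, 1.0, cols)[None, :]
    lon[:, cols:] = np.linspace(0.0, 1.0, cols)[None, :]
    pw, pe = blend_we("prec_X")
    moisture = np.clip(pw + (pe - pw) * lon
                       + 25.0 * _smooth_noise(rng, shape, smoothness), 0.0, None)
    pseason = np.empty(shape)
    pseason[:, :cols] = native.prec_season
    pseason[:, cols:] = transfer.prec_season
    pphase = np.empty(shape)
    pphase[:, :cols] = native.prec_phase
    pphase[:, cols:] = transfer.prec_phase

    origin = (0.0, rows * cell_size)
    tmin, tmax, prec = [], [], []
    for month in range(12):
        season = np.cos(2.0 * np.pi * (month - 6) / 12.0)   # warm peak at month 6
        tm = t_mean + amp * season
        tmin.append(Grid(tm - diurnal / 2.0, origin, cell_size))
        tmax.append(Grid(tm + diurnal / 2.0, origin, cell_size))
        pm = np.clip(
            moisture * (1.0 + pseason * np.cos(2.0 * np.pi * (month - pphase) / 12.0)),
            0.0, None)
        prec.append(Grid(pm, origin, cell_size))
    return MonthlyClimate(tmin=tmin, tmax=tmax, prec=prec)


def region_masks(rows: int, cols: int, cell_size: float = 0.5) -> tuple[Grid, Grid]:
    """Boolean native / transfer region grids matching :func:`gen_climate`."""
    origin = (0.0, rows * cell_size)
    native = np.zeros((rows, 2 * cols))
    native[:, :cols] = 1.0
    transfer = np.zeros((rows, 2 * cols))
    transfer[:, cols:] = 1.0
    return (Grid(native, origin, cell_size, nodata=-1.0),
            Grid(transfer, origin, cell_size, nodata=-1.0))


def gen_truth(stack: BioclimStack, true_weights: dict[str, float], seed: int,
              native_region: Grid, occupancy: float = 0.2,
              species_label: str = "synthetic") -> tuple[Grid, float, RangeMask]:
    """True Gibbs suitability surface, occupancy threshold and historical mask.

    Variables are standardized to [0, 1] by their native-region min/max and
    combined linearly with ``true_weights`` (zeros allowed; all-zero gives a
    uniform truth, used for null tests).  Suitability is exp(score)
    normalized over the native region.  The historical mask occupies the
    top ``occupancy`` fraction of native cells, ties broken at random, so
    the occupied fraction is within one cell of the target.
    """
    unknown = set(true_weights) - set(BIOCLIM_NAMES)
    if unknown:
        raise ValueError(f"unknown variables in true_weights: {sorted(unknown)}")
    g = stack.grid
    valid = stack.valid_mask()
    native = (native_region.values != 0) & native_region.valid_mask() & valid
    score = np.zeros(g.shape)
    for v, w in true_weights.items():
        if w == 0.0:
            continue
        vals = stack.layers[v].values
        nat_vals = vals[native]
        lo, hi = float(nat_vals.min()), float(nat_vals.max())
        span = hi - lo if hi > lo else 1.0
        score += w * (vals - lo) / span
    expscore = np.where(valid, np.exp(score), 0.0)
    z = expscore[native].sum()
    suit = np.where(valid, expscore / z, g.nodata)
    suit_grid = g.with_values(suit)

    n_native = int(native.sum())
    k = int(round(occupancy * n_native))
    k = max(k, 1)
    rng = np.random.default_rng(derive_seed(seed, "occupancy"))
    nat_idx = np.nonzero(native)
    nat_suit = suit[nat_idx]
    order = np.lexsort((rng.random(n_native), -nat_suit))  # best first, random ties
    occupied = np.zeros(g.shape, dtype=bool)
    occupied[nat_idx[0][order[:k]], nat_idx[1][order[:k]]] = True
    threshold = float(nat_suit[order[k - 1]])
    mask_grid = Grid(np.where(valid, occupied.astype(float), -1.0),
                     g.origin, g.cell_size, nodata=-1.0)
    mask = RangeMask(mask=mask_grid, period="historical", species_label=species_label)
    return suit_grid, threshold, mask


def contract(historical: RangeMask, stack: BioclimStack, fraction: float,
             bias: str = "cold_edge", seed: int = 0) -> RangeMask:
    """Contract a historical range into a modern one.

    Removes ``ceil(fraction * n_occupied)`` cells.  ``bias="cold_edge"``
    removes the occupied cells with the lowest annual mean temperature
    (ties broken deterministically by cell order); ``bias="random"`` removes
    uniformly at random.  ``fraction=0`` returns an identical mask.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("contraction fraction must be in [0, 1)")
    if bias not in ("cold_edge", "random"):
        raise ValueError(f"unknown contraction bias {bias!r}")
    occ = historical.occupied()
    rows, cols = np.nonzero(occ)
    n = rows.size
    n_remove = int(np.ceil(fraction * n))
    if n_remove >= n:
        n_remove = n - 1
    keep = np.ones(n, dtype=bool)
    if n_remove > 0:
        if bias == "cold_edge":
            mtemp = stack.layers["MTEMP"].values[rows, cols]
            coldest = np.argsort(mtemp, kind="stable")[:n_remove]
            keep[coldest] = False
        else:
            rng = np.random.default_rng(derive_seed(seed, "contract", bias))
            keep[rng.choice(n, size=n_remove, replace=False)] = False
    g = historical.mask
    new = np.zeros(g.shape)
    new[rows[keep], cols[keep]] = 1.0
    new = np.where(g.valid_mask(), new, g.nodata)
    modern = RangeMask(mask=g.with_values(new), period="modern",
                       species_label=historical.species_label)
    check_nested(modern, historical)
    return modern


# ----------------------------------------------------------------------
# Scenario orchestration
# ----------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Defaults give the canonical scenario: 64 x 64 cells per region, a
    warm-and-dry-adapted true niche (positive annual-mean-temperature
    weight, negative wettest-quarter-precipitation weight, around 1.4
    landscape-SD of logit spread per variable), 20% native occupancy, 50%
    cold-biased contraction and four introduction points.
    """

    rows: int = 64
    cols: int = 64
    seed: int = 1
    smoothness: float = 3.0
    true_weights: dict[str, float] = field(
        default_factory=lambda: {"MTEMP": 8.0, "PWQ": -6.0})
    occupancy: float = 0.2
    contraction_fraction: float = 0.5
    contraction_bias: str = "cold_edge"
    n_intro: int = 4
    species_label: str = "synthetic"
    cell_size: float = 0.5


@dataclass
class SyntheticScenario:
    """A generated landscape bundle with its ground truth."""

    config: ScenarioConfig
    monthly: MonthlyClimate
    stack: BioclimStack
    native_region: Grid
    transfer_region: Grid
    true_suitability: Grid
    occupancy_threshold: float
    historical_mask: RangeMask
    modern_mask: RangeMask
    intro_points: PointSet


def gen_scenario(config: ScenarioConfig | None = None) -> SyntheticScenario:
    """Generate a complete scenario from a config (deterministic per seed)."""
    cfg = config or ScenarioConfig()
    monthly = gen_climate(cfg.rows, cfg.cols, cfg.seed, cfg.smoothness,
                          cell_size=cfg.cell_size)
    stack = derive_bioclim(monthly)
    native, transfer = region_masks(cfg.rows, cfg.cols, cfg.cell_size)
    suit, threshold, historical = gen_truth(
        stack, cfg.true_weights, cfg.seed, native, cfg.occupancy,
        species_label=cfg.species_label)
    modern = contract(historical, stack, cfg.contraction_fraction,
                      cfg.contraction_bias, cfg.seed)

    # introduction points: transfer cells whose true suitability clears the
    # occupancy threshold, taken just above it (edge of the envelope)
    valid = stack.valid_mask()
    trans = (transfer.values != 0) & valid
    tr_rows, tr_cols = np.nonzero(trans)
    tr_suit = suit.values[tr_rows, tr_cols]
    qual = tr_suit >= threshold
    if qual.sum() < cfg.n_intro:
        raise ValueError(
            f"transfer region has only {int(qual.sum())} cells above the occupancy "
            f"threshold; cannot place {cfg.n_intro} introduction points")
    q_idx = np.nonzero(qual)[0]
    order = np.argsort(tr_suit[q_idx], kind="stable")     # lowest qualifying first
    chosen = q_idx[order[: cfg.n_intro]]
    g = stack.grid
    xs, ys = [], []
    for i in chosen:
        x, y = g.cell_center(int(tr_rows[i]), int(tr_cols[i]))
        xs.append(x)
        ys.append(y)
    intro = PointSet(ids=[f"intro_{i}" for i in range(cfg.n_intro)],
                     x=np.array(xs), y=np.array(ys), role="test",
                     period="modern", seed=cfg.seed)
    return SyntheticScenario(
        config=cfg, monthly=monthly, stack=stack, native_region=native,
        transfer_region=transfer, true_suitability=suit,
        occupancy_threshold=threshold, historical_mask=historical,
        modern_mask=modern, intro_points=intro)


# ----------------------------------------------------------------------
# Scenario serialization (directory of plain-text artifacts)
# ----------------------------------------------------------------------

def write_scenario(scenario: SyntheticScenario, directory: str | Path) -> None:
    """Write a scenario as a directory of ESRI ASCII grids + JSON manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for m in range(12):
        write_grid(scenario.monthly.tmin[m], d / f"tmin_{m:02d}.asc")
        write_grid(scenario.monthly.tmax[m], d / f"tmax_{m:02d}.asc")
        write_grid(scenario.monthly.prec[m], d / f"prec_{m:02d}.asc")
    write_grid(scenario.native_region, d / "native_region.asc")
    write_grid(scenario.transfer_region, d / "transfer_region.asc")
    write_grid(scenario.true_suitability, d / "true_suitability.asc")
    write_grid(scenario.historical_mask.mask, d / "historical_mask.asc")
    write_grid(scenario.modern_mask.mask, d / "modern_mask.asc")
    write_points(scenario.intro_points, d / "intro_points.csv")
    manifest = {
        "format": "climsuit-scenario",
        "version": 1,
        "config": asdict(scenario.config),
        "occupancy_threshold": scenario.occupancy_threshold,
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_scenario(directory: str | Path) -> SyntheticScenario:
    """Reload a scenario written by :func:`write_scenario`."""
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    if manifest.get("format") != "climsuit-scenario":
        raise ValueError(f"{d}: not a scenario directory")
    cfg = ScenarioConfig(**manifest["config"])
    monthly = MonthlyClimate(
        tmin=[read_grid(d / f"tmin_{m:02d}.asc") for m in range(12)],
        tmax=[read_grid(d / f"tmax_{m:02d}.asc") for m in range(12)],
        prec=[read_grid(d / f"prec_{m:02d}.asc") for m in range(12)],
    )
    stack = derive_bioclim(monthly)
    native = read_grid(d / "native_region.asc")
    transfer = read_grid(d / "transfer_region.asc")
    suit = read_grid(d / "true_suitability.asc")
    historical = RangeMask(mask=read_grid(d / "historical_mask.asc"),
                           period="historical", species_label=cfg.species_label)
    modern = RangeMask(mask=read_grid(d / "modern_mask.asc"),
                       period="modern", species_label=cfg.species_label)
    check_nested(modern, historical)
    intro = read_points(d / "intro_points.csv", role="test")
    return SyntheticScenario(
        config=cfg, monthly=monthly, stack=stack, native_region=native,
        transfer_region=transfer, true_suitability=suit,
        occupancy_threshold=float(manifest["occupancy_threshold"]),
        historical_mask=historical, modern_mask=modern, intro_points=intro)
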