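"""End-to-end experiment orchestration.

For each period (modern, historical) the experiment runs ``n_sets`` seeded
replicate fits from independent pseudo-presence sets, projects each onto
the full landscape with clamping, combines them into a mean logistic map
and cumulative MTP/MTSS binary maps, and evaluates AUC (per run, against
the background sample) and Kappa (on the cumulative maps, against held-out
presence/absence test points), including the cross-period rows where
modern-trained models are tested against historical-range test data.

Every random draw is a pure function of the master seed, so a rerun of the
same config reproduces every number bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import novelty, suitable_area
from .grids import BIOCLIM_NAMES, BioclimStack, Grid, PointSet, extract, write_grid
from .maxent import (
    DEFAULT_CLASSES,
    MaxentModel,
    build_features,
    fit,
    jackknife_single,
    project,
    variable_contribution,
)
from .sampling import RangeMask, SampleDesign, derive_seed, sample_absence, \
    sample_background, sample_presence
from .synth import ScenarioConfig, SyntheticScenario, gen_scenario
from .thresholds import (
    EvaluationReport,
    ReplicateRun,
    cumulative_map,
    evaluate_transfer,
    make_run,
)

logger = logging.getLogger(__name__)

PERIODS = ("modern", "historical")


@dataclass
class ExperimentConfig:
    """Settings for a full replicated experiment.

    Defaults reproduce the standard layout: ten sets of 100 training
    pseudo-presences, 100 test pseudo-presences per run, regularization
    multiplier 1, all smooth feature classes, background capped at 10,000
    cells, MTP and MTSS thresholding.
    """

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    n_sets: int = 10
    n_points: int = 100
    n_test_points: int = 100
    beta: float = 1.0
    feature_classes: tuple[str, ...] = DEFAULT_CLASSES
    background_max: int = 10_000
    criteria: tuple[str, ...] = ("MTP", "MTSS")
    seed: int = 1
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if min(self.n_sets, self.n_points, self.n_test_points) < 1:
            raise ValueError("all counts must be positive")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass
class PeriodResult:
    """Everything computed for one training period."""

    period: str
    runs: list[ReplicateRun]
    models: list[MaxentModel]
    test_presence_scores: list[np.ndarray]
    test_presences: PointSet
    test_absences: PointSet
    report: EvaluationReport
    mean_logistic: Grid
    cumulative_maps: dict[str, Grid]
    contributions: pd.DataFrame
    jackknife: pd.DataFrame


def _clean_table(stack: BioclimStack, points: PointSet) -> pd.DataFrame:
    tab = extract(stack, points)
    return tab[tab["valid"]].reset_index(drop=True)


def run_period(
    scenario: SyntheticScenario,
    mask: RangeMask,
    config: ExperimentConfig,
    jackknife_tables: bool = True,
) -> PeriodResult:
    """Fit, project and evaluate all replicates for one training period."""
    stack = scenario.stack
    period = mask.period
    design = SampleDesign(n_points=config.n_points, n_sets=config.n_sets,
                          seed=config.seed)
    background = sample_background(stack, scenario.native_region,
                                   config.background_max,
                                   derive_seed(config.seed, period, "background"))
    bg_table = _clean_table(stack, background)

    runs: list[ReplicateRun] = []
    models: list[MaxentModel] = []
    test_scores: list[np.ndarray] = []
    contrib_rows = []
    first_presence_table = None
    first_test_table = None
    for i in range(config.n_sets):
        presences = sample_presence(mask, design, set_index=i, role="train")
        p_table = _clean_table(stack, presences)
        pooled = pd.concat([p_table, bg_table], ignore_index=True)
        spec, _ = build_features(pooled, classes=config.feature_classes)
        model = fit(spec.table_matrix(p_table), spec.table_matrix(bg_table),
                    beta=config.beta, spec=spec)
        smap = project(model, stack, clamp=True)
        smap.run_id = f"{period}_{i}"
        smap.period = period
        train_scores = model.predict_logistic(spec.table_matrix(p_table))
        ref_scores = model.predict_logistic(spec.table_matrix(bg_table))
        runs.append(make_run(smap, train_scores, ref_scores, run_id=f"{period}_{i}"))
        models.append(model)

        test_design = SampleDesign(n_points=config.n_test_points, n_sets=config.n_sets,
                                   seed=config.seed)
        test_pts = sample_presence(mask, test_design, set_index=i, role="test")
        t_table = _clean_table(stack, test_pts)
        test_scores.append(model.predict_logistic(spec.table_matrix(t_table, clamp=True)))
        contrib = variable_contribution(model)
        contrib["run"] = i
        contrib_rows.append(contrib)
        if i == 0:
            first_presence_table, first_test_table = p_table, t_table
        logger.info("fitted %s replicate %d/%d (converged=%s)",
                    period, i + 1, config.n_sets, model.converged)

    # held-out presence/absence test points for Kappa
    kappa_presences = sample_presence(
        mask, SampleDesign(n_points=config.n_test_points, n_sets=1,
                           seed=derive_seed(config.seed, period, "kappa")),
        set_index=0, role="test")
    kappa_absences = sample_absence(
        mask, scenario.native_region, config.n_test_points,
        seed=derive_seed(config.seed, period, "kappa_abs"))
    report = evaluate_transfer(runs, test_scores, kappa_presences, kappa_absences,
                               train_period=period, test_period=period,
                               criteria=config.criteria)

    mean_logistic = _mean_logistic([r.smap.logistic for r in runs])
    cmaps = {crit: cumulative_map(runs, crit) for crit in config.criteria}

    contrib_all = pd.concat(contrib_rows, ignore_index=True)
    contrib_summary = (contrib_all.groupby("variable")["contribution_pct"]
                       .agg(mean="mean", sd=lambda s: s.std(ddof=0))
                       .reset_index())
    jack = pd.DataFrame()
    if jackknife_tables:
        jack = jackknife_single(first_presence_table,
                                bg_table,
                                variables=[v for v in BIOCLIM_NAMES],
                                beta=config.beta, classes=config.feature_classes,
                                test_presence_table=first_test_table)
    return PeriodResult(
        period=period, runs=runs, models=models,
        test_presence_scores=test_scores, test_presences=kappa_presences,
        test_absences=kappa_absences, report=report,
        mean_logistic=mean_logistic, cumulative_maps=cmaps,
        contributions=contrib_summary, jackknife=jack)


def _mean_logistic(grids: Sequence[Grid]) -> Grid:
    ref = grids[0]
    valid = np.ones(ref.shape, dtype=bool)
    acc = np.zeros(ref.shape)
    for g in grids:
        valid &= g.valid_mask()
        acc += np.where(g.valid_mask(), g.values, 0.0)
    return ref.with_values(np.where(valid, acc / len(grids), ref.nodata))


def cross_period_report(
    modern_result: PeriodResult,
    scenario: SyntheticScenario,
    config: ExperimentConfig,
) -> EvaluationReport:
    """Evaluate modern-trained runs against historical-range test data."""
    stack = scenario.stack
    hist = scenario.historical_mask
    test_design = SampleDesign(n_points=config.n_test_points, n_sets=config.n_sets,
                               seed=config.seed)
    scores = []
    for i, model in enumerate(modern_result.models):
        pts = sample_presence(hist, test_design, set_index=i, role="test")
        tab = _clean_table(stack, pts)
        scores.append(model.predict_logistic(
            model.spec.table_matrix(tab, clamp=True)))
    kappa_presences = sample_presence(
        hist, SampleDesign(n_points=config.n_test_points, n_sets=1,
                           seed=derive_seed(config.seed, "xper", "kappa")),
        set_index=0, role="test")
    kappa_absences = sample_absence(
        hist, scenario.native_region, config.n_test_points,
        seed=derive_seed(config.seed, "xper", "kappa_abs"))
    return evaluate_transfer(modern_result.runs, scores, kappa_presences,
                             kappa_absences, train_period="modern",
                             test_period="historical", criteria=config.criteria)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    scenario: SyntheticScenario
    periods: dict[str, PeriodResult]
    cross_period: EvaluationReport
    transfer_fractions: dict[str, dict[str, float]]   # period -> criterion -> fraction


def run_experiment(config: ExperimentConfig | None = None,
                   scenario: SyntheticScenario | None = None,
                   jackknife_tables: bool = True) -> ExperimentResult:
    """Run the full experiment; write a result bundle when out_dir is set."""
    config = config or ExperimentConfig()
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    try:
        scenario = scenario or gen_scenario(config.scenario)
        periods: dict[str, PeriodResult] = {}
        for mask in (scenario.modern_mask, scenario.historical_mask):
            periods[mask.period] = run_period(scenario, mask, config,
                                              jackknife_tables=jackknife_tables)
        xper = cross_period_report(periods["modern"], scenario, config)
        transfer_fractions: dict[str, dict[str, float]] = {}
        for period, res in periods.items():
            transfer_fractions[period] = {}
            for crit, cmap in res.cumulative_maps.items():
                _, frac = suitable_area(cmap, scenario.transfer_region)
                transfer_fractions[period][crit] = frac
        result = ExperimentResult(config=config, scenario=scenario,
                                  periods=periods, cross_period=xper,
                                  transfer_fractions=transfer_fractions)
        if out is not None:
            _write_bundle(result, out)
        return result
    except Exception as exc:
        if out is not None:
            (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise


def _meta_header(config: ExperimentConfig) -> str:
    return (f"# climsuit {__version__} seed={config.seed} beta={config.beta} "
            f"features={','.join(config.feature_classes)} "
            f"criteria={','.join(config.criteria)} n_sets={config.n_sets} "
            f"n_points={config.n_points} n_test={config.n_test_points}\n")


def _write_csv(df: pd.DataFrame, path: Path, config: ExperimentConfig) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_header(config))
        df.to_csv(fh, index=False)


def _write_bundle(result: ExperimentResult, out: Path) -> None:
    cfg = result.config
    summary_rows = []
    for period, res in result.periods.items():
        pdir = out / period
        pdir.mkdir(exist_ok=True)
        write_grid(res.mean_logistic, pdir / "mean_logistic.asc")
        for crit, cmap in res.cumulative_maps.items():
            write_grid(cmap, pdir / f"cumulative_{crit.lower()}.asc")
        run_rows = [{
            "run": r.run_id, "auc": a, "mtp": r.thresholds.mtp,
            "mtss": r.thresholds.mtss,
        } for r, a in zip(res.runs, res.report.auc_per_run)]
        _write_csv(pd.DataFrame(run_rows), pdir / "runs.csv", cfg)
        _write_csv(res.contributions, pdir / "contributions.csv", cfg)
        if not res.jackknife.empty:
            _write_csv(res.jackknife, pdir / "jackknife.csv", cfg)
        for i, model in enumerate(res.models):
            model.to_json(pdir / f"model_{i}.json")
        row = {
            "train_period": period, "test_period": period,
            "auc_mean": res.report.auc_mean, "auc_sd": res.report.auc_sd,
            **res.report.kappa_by_criterion,
            **{f"transfer_fraction_{c.lower()}": f
               for c, f in result.transfer_fractions[period].items()},
        }
        summary_rows.append(row)
        # novelty of the transfer region under the first replicate's envelope
        env = novelty(res.models[0], result.scenario.stack,
                      result.scenario.transfer_region)
        write_grid(env.count_grid, pdir / "novelty_transfer.asc")
    xrow = {"train_period": "modern", "test_period": "historical",
            "auc_mean": result.cross_period.auc_mean,
            "auc_sd": result.cross_period.auc_sd,
            **result.cross_period.kappa_by_criterion}
    summary_rows.append(xrow)
    _write_csv(pd.DataFrame(summary_rows), out / "summary.csv", cfg)
    manifest = {
        "software": f"climsuit {__version__}",
        "config": {**dataclasses.asdict(cfg),
                   "scenario": dataclasses.asdict(cfg.scenario)},
        "periods": list(result.periods),
        "transfer_fractions": result.transfer_fractions,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ----------------------------------------------------------------------
# Sensitivity curves
# ----------------------------------------------------------------------

def sample_size_curve(config: ExperimentConfig,
                      point_counts: Sequence[int]) -> pd.DataFrame:
    """Mean test AUC as a function of the training pseudo-presence count.

    Reruns the replicate pipeline (AUC only) at each training-set size, for
    both periods; used to justify the 100-point training default.
    """
    if not point_counts:
        raise ValueError("point_counts must be non-empty")
    rows = []
    scenario = gen_scenario(config.scenario)
    for n in point_counts:
        cfg = dataclasses.replace(config, n_points=int(n), out_dir=None)
        for mask in (scenario.modern_mask, scenario.historical_mask):
            res = run_period(scenario, mask, cfg, jackknife_tables=False)
            rows.append({"n_points": int(n), "period": mask.period,
                         "auc_mean": res.report.auc_mean})
    return pd.DataFrame(rows)


def regularization_curve(config: ExperimentConfig,
                         betas: Sequence[float]) -> pd.DataFrame:
    """Mean test AUC as a function of the regularization multiplier."""
    if len(betas) == 0:
        raise ValueError("betas must be non-empty")
    rows = []
    scenario = gen_scenario(config.scenario)
    for b in betas:
        cfg = dataclasses.replace(config, beta=float(b), out_dir=None)
        for mask in (scenario.modern_mask, scenario.historical_mask):
            res = run_period(scenario, mask, cfg, jackknife_tables=False)
            rows.append({"beta": float(b), "period": mask.period,
                         "auc_mean": res.report.auc_mean})
    return pd.DataFrame(rows)
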