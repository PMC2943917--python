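"""Thresholding and evaluation: MTP, MTSS, cumulative maps, AUC, Kappa.

Two threshold criteria convert a continuous suitability surface into a
binary suitable/unsuitable map:

- **MTP** (minimum training presence): the lowest model score among the
  training presences — generous, zero training omission.
- **MTSS** (maximum training sensitivity plus specificity): the score that
  maximizes sensitivity + specificity over the training presences and a
  reference (background by default) sample — stringent, balances omission
  and commission.

Replicate runs are combined with the *cumulative* rule: a cell is suitable
if at least one run exceeds its own threshold there.  Classification is
always by the ``score >= t`` rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .grids import Grid, PointSet, require_aligned

logger = logging.getLogger(__name__)


@dataclass
class SuitabilityMap:
    """Continuous model output on a grid: logistic in [0, 1] plus raw density."""

    logistic: Grid
    raw: Grid
    run_id: str = ""
    species_label: str = ""
    period: str = ""

    def __post_init__(self) -> None:
        require_aligned(self.logistic, self.raw)
        vals = self.logistic.values[self.logistic.valid_mask()]
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise ValueError("logistic layer has values outside [0, 1]")


@dataclass
class ThresholdSet:
    """Per-run MTP and MTSS thresholds on the logistic scale."""

    mtp: float
    mtss: float
    run_id: str = ""

    def get(self, criterion: str) -> float:
        if criterion == "MTP":
            return self.mtp
        if criterion == "MTSS":
            return self.mtss
        raise KeyError(f"unknown threshold criterion {criterion!r}")


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must count at least one point")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")


# ----------------------------------------------------------------------
# Thresholds
# ----------------------------------------------------------------------

def mtp(train_scores: Sequence[float]) -> float:
    """Minimum training presence threshold: the lowest training score."""
    scores = np.asarray(train_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("mtp requires at least one training score")
    return float(scores.min())


def mtss(presence_scores: Sequence[float], absence_scores: Sequence[float]) -> float:
    """Threshold maximizing sensitivity + specificity (ties: smallest t).

    Candidates are the sorted unique observed scores; classification is
    ``score >= t``, so sensitivity is the presence fraction at or above t
    and specificity the reference fraction below t.
    """
    p = np.asarray(presence_scores, dtype=float)
    a = np.asarray(absence_scores, dtype=float)
    if p.size == 0 or a.size == 0:
        raise ValueError("mtss requires non-empty presence and absence scores")
    candidates = np.unique(np.concatenate([p, a]))
    best_t, best_val = candidates[0], -np.inf
    for t in candidates:
        sens = (p >= t).mean()
        spec = (a < t).mean()
        val = sens + spec
        if val > best_val + 1e-12:
            best_val, best_t = val, t
    return float(best_t)


def binarize(smap: SuitabilityMap | Grid, t: float) -> Grid:
    """Boolean grid: cell suitable iff logistic >= t; nodata propagates."""
    g = smap.logistic if isinstance(smap, SuitabilityMap) else smap
    valid = g.valid_mask()
    out = np.where(valid, (g.values >= t).astype(float), g.nodata)
    return g.with_values(out)


def cumulative(binary_maps: Sequence[Grid]) -> Grid:
    """Cell-wise union of aligned binary maps (suitable in any run => suitable)."""
    if not binary_maps:
        raise ValueError("cumulative requires at least one map")
    require_aligned(*binary_maps)
    ref = binary_maps[0]
    valid = np.ones(ref.shape, dtype=bool)
    acc = np.zeros(ref.shape, dtype=bool)
    for g in binary_maps:
        v = g.valid_mask()
        valid &= v
        acc |= v & (g.values != 0)
    out = np.where(valid, acc.astype(float), ref.nodata)
    return ref.with_values(out)


# ----------------------------------------------------------------------
# Evaluation statistics
# ----------------------------------------------------------------------

def auc(presence_scores: Sequence[float], reference_scores: Sequence[float]) -> float:
    """Rank AUC: P(random presence outscores random reference), ties count 1/2.

    Mann-Whitney U / (n1 * n2), computed via ranks so large samples stay fast.
    """
    p = np.asarray(presence_scores, dtype=float)
    r = np.asarray(reference_scores, dtype=float)
    if p.size == 0 or r.size == 0:
        raise ValueError("auc requires non-empty score sets")
    from scipy.stats import rankdata

    combined = np.concatenate([p, r])
    ranks = rankdata(combined)
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2
    return float(u / (p.size * r.size))


def confusion(binary_map: Grid, presence_points: PointSet,
              absence_points: PointSet) -> ConfusionMatrix:
    """Count the error matrix of a binary map against presence/absence points.

    Points on nodata cells are excluded with a logged count.
    """
    valid = binary_map.valid_mask()
    suitable = valid & (binary_map.values != 0)

    def classify(points: PointSet) -> tuple[int, int, int]:
        pos = neg = dropped = 0
        for pid, x, y in zip(points.ids, points.x, points.y):
            r, c = binary_map.cell_of(x, y)
            if not valid[r, c]:
                dropped += 1
            elif suitable[r, c]:
                pos += 1
            else:
                neg += 1
        return pos, neg, dropped

    tp, fn, d1 = classify(presence_points)
    fp, tn, d2 = classify(absence_points)
    if d1 or d2:
        logger.warning("confusion: %d presence and %d absence points on nodata "
                       "cells were excluded", d1, d2)
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's Kappa, the chance-corrected agreement of a confusion matrix."""
    n = cm.total
    p_o = (cm.tp + cm.tn) / n
    p_e = ((cm.tp + cm.fp) * (cm.tp + cm.fn)
           + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / n**2
    if p_e >= 1.0:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


# ----------------------------------------------------------------------
# Replicate-level evaluation
# ----------------------------------------------------------------------

@dataclass
class ReplicateRun:
    """One fitted replicate: its suitability map and per-run thresholds.

    ``train_scores`` are the logistic scores of the run's training presences;
    ``reference_scores`` those of its background sample (the MTSS reference).
    """

    smap: SuitabilityMap
    thresholds: ThresholdSet
    train_scores: np.ndarray
    reference_scores: np.ndarray
    run_id: str = ""


@dataclass
class EvaluationReport:
    """Summary of replicate performance mirroring the per-species report rows."""

    auc_mean: float
    auc_sd: float
    auc_per_run: tuple[float, ...]
    kappa_by_criterion: dict[str, float]
    n_runs: int
    train_period: str
    test_period: str

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.auc_mean <= 1 + 1e-9):
            raise ValueError("AUC out of [0, 1]")
        for k, v in self.kappa_by_criterion.items():
            if not (-1 - 1e-9 <= v <= 1 + 1e-9):
                raise ValueError(f"Kappa {k} out of [-1, 1]")


def make_run(smap: SuitabilityMap, train_scores: Sequence[float],
             reference_scores: Sequence[float], run_id: str = "") -> ReplicateRun:
    """Bundle a projected run with its MTP and MTSS thresholds."""
    ts = np.asarray(train_scores, dtype=float)
    rs = np.asarray(reference_scores, dtype=float)
    th = ThresholdSet(mtp=mtp(ts), mtss=mtss(ts, rs), run_id=run_id)
    return ReplicateRun(smap=smap, thresholds=th, train_scores=ts,
                        reference_scores=rs, run_id=run_id)


def cumulative_map(runs: Sequence[ReplicateRun], criterion: str) -> Grid:
    """Union of each run's own-threshold binary map for a criterion."""
    return cumulative([binarize(r.smap, r.thresholds.get(criterion)) for r in runs])


def evaluate_transfer(
    runs: Sequence[ReplicateRun],
    test_presence_scores: Sequence[Sequence[float]],
    test_presence_points: PointSet,
    test_absence_points: PointSet,
    train_period: str,
    test_period: str,
    criteria: Sequence[str] = ("MTP", "MTSS"),
) -> EvaluationReport:
    """Evaluate replicate runs against test data from a (possibly different) period.

    AUC is computed per run from that run's test presence scores against its
    background reference scores, then summarized as mean +/- SD.  Kappa is
    computed once per criterion on the cumulative binary map against the test
    presence/absence points.  Training on the modern range and testing
    against historical-range test sets quantifies cross-period transfer.
    """
    if not runs:
        raise ValueError("evaluate_transfer requires at least one run")
    if len(test_presence_scores) != len(runs):
        raise ValueError("need one test presence score vector per run")
    aucs = [auc(ps, r.reference_scores) for ps, r in zip(test_presence_scores, runs)]
    kappas = {}
    for crit in criteria:
        cmap = cumulative_map(runs, crit)
        kappas[f"Kappa_{crit}"] = kappa(
            confusion(cmap, test_presence_points, test_absence_points))
    return EvaluationReport(
        auc_mean=float(np.mean(aucs)),
        auc_sd=float(np.std(aucs)),
        auc_per_run=tuple(float(a) for a in aucs),
        kappa_by_criterion=kappas,
        n_runs=len(runs),
        train_period=train_period,
        test_period=test_period,
    )
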