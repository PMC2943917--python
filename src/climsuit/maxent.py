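"""Presence-only maximum-entropy (Gibbs) suitability model.

The model estimates a probability distribution ``q`` over the cells of a
background sample that is as close to uniform as possible (maximum entropy)
subject to the constraint that the expectation of each feature under ``q``
matches its empirical mean over the presence sample.  This is equivalent to
maximum-likelihood estimation of a Gibbs distribution

    q(x) = exp(lambda . f(x)) / Z,     Z = sum_background exp(lambda . f(x))

with an L1 penalty that relaxes exact constraint matching: the fitted weights
maximize

    sum_presences log q(x_i)  -  sum_j  beta * (s_j / sqrt(m_p)) * |lambda_j|

where ``m_p`` is the number of presences and ``s_j`` the presence-sample
standard deviation of feature j.  The penalized objective is concave; the
optimizer is deterministic coordinate-wise proximal Newton (soft-thresholding)
with a quasi-Newton polish on the active set.

Features are built from predictor variables standardized to [0, 1] by their
training min/max: ``linear`` (the standardized value), ``quadratic`` (its
square) and ``product`` (pairwise products).  The same training min/max serve
as clamp bounds when the model is projected onto new regions: projected
predictor values are clipped to the training range first, which prevents the
fitted response from being extrapolated beyond environments seen in training.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .grids import BIOCLIM_NAMES, BioclimStack, Grid

logger = logging.getLogger(__name__)

DEFAULT_CLASSES = ("linear", "quadratic", "product")
_CLASS_ORDER = {"linear": 0, "quadratic": 1, "product": 2}


# ----------------------------------------------------------------------
# Feature expansion
# ----------------------------------------------------------------------

@dataclass
class FeatureSpec:
    """Feature definitions, clamp bounds and standardization for a fit.

    ``var_bounds`` holds per-variable (min, max) learned from the training
    sample (presences plus background); they standardize variables to [0, 1]
    and double as clamp bounds at projection time.
    """

    variables: tuple[str, ...]
    classes: tuple[str, ...]
    var_bounds: dict[str, tuple[float, float]]
    feature_names: tuple[str, ...] = ()
    feature_vars: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.classes) - set(DEFAULT_CLASSES)
        if bad:
            raise ValueError(f"unknown feature classes {sorted(bad)}")
        self.classes = tuple(sorted(set(self.classes), key=_CLASS_ORDER.__getitem__))
        if not self.feature_names:
            names: list[str] = []
            fvars: list[tuple[str, ...]] = []
            if "linear" in self.classes:
                names += list(self.variables)
                fvars += [(v,) for v in self.variables]
            if "quadratic" in self.classes:
                names += [f"{v}^2" for v in self.variables]
                fvars += [(v,) for v in self.variables]
            if "product" in self.classes:
                for a, b in itertools.combinations(self.variables, 2):
                    names.append(f"{a}*{b}")
                    fvars.append((a, b))
            self.feature_names = tuple(names)
            self.feature_vars = tuple(fvars)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def standardize(self, X: np.ndarray, clamp: bool = False) -> np.ndarray:
        """Map raw variable columns (ordered as ``self.variables``) to [0,1]."""
        X = np.asarray(X, dtype=float)
        lo = np.array([self.var_bounds[v][0] for v in self.variables])
        hi = np.array([self.var_bounds[v][1] for v in self.variables])
        if clamp:
            X = np.clip(X, lo, hi)
        span = np.where(hi > lo, hi - lo, 1.0)
        return (X - lo) / span

    def transform(self, X: np.ndarray, clamp: bool = False) -> np.ndarray:
        """Design matrix for rows of raw variable values.

        ``X`` has one column per variable in ``self.variables`` order; the
        result has one column per feature in deterministic order (linear in
        canonical variable order, then squares, then lexicographic pairs).
        """
        Z = self.standardize(X, clamp=clamp)
        cols: list[np.ndarray] = []
        idx = {v: i for i, v in enumerate(self.variables)}
        for name, fv in zip(self.feature_names, self.feature_vars):
            if name.endswith("^2"):
                cols.append(Z[:, idx[fv[0]]] ** 2)
            elif len(fv) == 2:
                cols.append(Z[:, idx[fv[0]]] * Z[:, idx[fv[1]]])
            else:
                cols.append(Z[:, idx[fv[0]]])
        return np.column_stack(cols) if cols else np.empty((Z.shape[0], 0))

    def table_matrix(self, table: pd.DataFrame, clamp: bool = False) -> np.ndarray:
        """Design matrix from a value table with named variable columns."""
        X = table[list(self.variables)].to_numpy(dtype=float)
        return self.transform(X, clamp=clamp)


def build_features(
    table: pd.DataFrame,
    classes: Sequence[str] = DEFAULT_CLASSES,
    variables: Sequence[str] | None = None,
) -> tuple[FeatureSpec, np.ndarray]:
    """Learn a :class:`FeatureSpec` from a training value table.

    ``table`` holds the pooled training sample (presences plus background),
    one named column per predictor variable; clamp bounds and the [0, 1]
    standardization are taken from its column ranges.  Variables that are
    constant on the training data are dropped with a logged warning.

    Returns the feature spec and the design matrix of ``table`` itself.
    """
    if variables is None:
        variables = [v for v in BIOCLIM_NAMES if v in table.columns]
        if not variables:
            variables = [c for c in table.columns
                         if c not in ("id", "valid") and
                         pd.api.types.is_numeric_dtype(table[c])]
    if "valid" in table.columns and not table["valid"].all():
        raise ValueError("training table contains invalid rows; drop them first")
    if len(table) < 2:
        raise ValueError("need at least 2 training rows to build features")
    kept, bounds = [], {}
    for v in variables:
        col = table[v].to_numpy(dtype=float)
        lo, hi = float(np.min(col)), float(np.max(col))
        if hi <= lo:
            logger.warning("build_features: variable %s is constant on training data; dropped", v)
            continue
        kept.append(v)
        bounds[v] = (lo, hi)
    if not kept:
        raise ValueError("all candidate variables are constant on the training data")
    spec = FeatureSpec(variables=tuple(kept), classes=tuple(classes), var_bounds=bounds)
    return spec, spec.table_matrix(table)


# ----------------------------------------------------------------------
# Model fitting
# ----------------------------------------------------------------------

@dataclass
class MaxentModel:
    """A fitted maximum-entropy model: weights, normalizer, entropy, penalty.

    ``log_z`` is the log of the normalizer over the background sample;
    ``entropy`` the Shannon entropy (nats) of the fitted distribution over
    the background, which fixes the logistic output scaling so that a
    uniform model scores exactly 0.5 everywhere.
    """

    spec: FeatureSpec
    weights: np.ndarray
    log_z: float
    entropy: float
    beta: float
    n_presence: int
    n_background: int
    presence_mean: np.ndarray
    presence_sd: np.ndarray
    converged: bool = True
    objective: float = 0.0
    gain_trace: tuple[tuple[int, float], ...] = ()
    duplicate_groups: tuple[tuple[int, ...], ...] = ()

    # -- prediction ----------------------------------------------------

    def predict_raw(self, features: np.ndarray) -> np.ndarray:
        """Background-normalized Gibbs density exp(lambda.f)/Z per row."""
        features = np.atleast_2d(np.asarray(features, dtype=float))
        return np.exp(features @ self.weights - self.log_z)

    def predict_logistic(self, features: np.ndarray) -> np.ndarray:
        """Suitability index in [0, 1]: e^H q / (1 + e^H q), monotone in q."""
        features = np.atleast_2d(np.asarray(features, dtype=float))
        logit = self.entropy + (features @ self.weights - self.log_z)
        return expit(logit)

    def score_table(self, table: pd.DataFrame, clamp: bool = True,
                    output: str = "logistic") -> np.ndarray:
        F = self.spec.table_matrix(table, clamp=clamp)
        return self.predict_logistic(F) if output == "logistic" else self.predict_raw(F)

    # -- serialization -------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "format": "climsuit-maxent-model",
            "version": 1,
            "variables": list(self.spec.variables),
            "classes": list(self.spec.classes),
            "var_bounds": {v: list(b) for v, b in self.spec.var_bounds.items()},
            "feature_names": list(self.spec.feature_names),
            "weights": [float(w) for w in self.weights],
            "log_z": float(self.log_z),
            "entropy": float(self.entropy),
            "beta": float(self.beta),
            "n_presence": int(self.n_presence),
            "n_background": int(self.n_background),
            "presence_mean": [float(v) for v in self.presence_mean],
            "presence_sd": [float(v) for v in self.presence_sd],
            "converged": bool(self.converged),
            "objective": float(self.objective),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MaxentModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        if doc.get("format") != "climsuit-maxent-model":
            raise ValueError("not a serialized maxent model document")
        spec = FeatureSpec(
            variables=tuple(doc["variables"]),
            classes=tuple(doc["classes"]),
            var_bounds={v: tuple(b) for v, b in doc["var_bounds"].items()},
        )
        return cls(
            spec=spec,
            weights=np.array(doc["weights"], dtype=float),
            log_z=doc["log_z"],
            entropy=doc["entropy"],
            beta=doc["beta"],
            n_presence=doc["n_presence"],
            n_background=doc["n_background"],
            presence_mean=np.array(doc["presence_mean"], dtype=float),
            presence_sd=np.array(doc["presence_sd"], dtype=float),
            converged=doc["converged"],
            objective=doc["objective"],
        )


def _duplicate_groups(F: np.ndarray) -> tuple[tuple[int, ...], ...]:
    """Groups of feature columns that are exactly identical (symmetry ties)."""
    groups: dict[bytes, list[int]] = {}
    for j in range(F.shape[1]):
        groups.setdefault(F[:, j].tobytes(), []).append(j)
    return tuple(tuple(g) for g in groups.values() if len(g) > 1)


def penalized_objective(lam: np.ndarray, presence_mean: np.ndarray,
                        F_bg: np.ndarray, alpha: np.ndarray,
                        m_p: int) -> float:
    """Total penalized presence log-likelihood at ``lam`` (to be maximized)."""
    lam = np.asarray(lam, dtype=float)
    return float(m_p * (presence_mean @ lam - logsumexp(F_bg @ lam))
                 - np.abs(lam) @ alpha)


def fit(presence_features: np.ndarray, background_features: np.ndarray,
        beta: float = 1.0, spec: FeatureSpec | None = None,
        tol: float = 1e-8, max_iter: int = 500) -> MaxentModel:
    """Fit the L1-penalized maximum-entropy model.

    Parameters
    ----------
    presence_features, background_features : ndarray
        Design matrices (rows = samples, columns = features) produced by the
        same :class:`FeatureSpec`.
    beta : float
        Regularization multiplier; the per-feature penalty weight is
        ``beta * s_j / sqrt(m_p)``.  0 enforces exact constraint matching.
    spec : FeatureSpec, optional
        Attached to the returned model for projection; an anonymous spec is
        synthesized when omitted (prediction from raw design matrices only).

    Notes
    -----
    Optimization is coordinate-wise proximal Newton with monotone line
    search (each accepted update cannot decrease the penalized objective),
    run to a relative improvement below ``tol`` or ``max_iter`` sweeps,
    followed by an L-BFGS polish restricted to the active set with signs
    fixed (the penalty is then linear, hence smooth).  Non-convergence at
    the iteration cap returns the model flagged with ``converged=False``.
    """
    F_p = np.atleast_2d(np.asarray(presence_features, dtype=float))
    F_bg = np.atleast_2d(np.asarray(background_features, dtype=float))
    if beta < 0:
        raise ValueError("beta must be >= 0")
    m_p, n_feat = F_p.shape
    m_bg = F_bg.shape[0]
    if m_p < 1 or m_bg < 2:
        raise ValueError("need >= 1 presence and >= 2 background rows")
    if F_bg.shape[1] != n_feat:
        raise ValueError("presence and background feature matrices disagree on width")

    f_bar = F_p.mean(axis=0)
    s = F_p.std(axis=0)                      # presence-sample SD (population)
    alpha = beta * s / np.sqrt(m_p)          # per-feature L1 weight

    lam = np.zeros(n_feat)
    u = F_bg @ lam
    log_z = logsumexp(u)
    obj = penalized_objective(lam, f_bar, F_bg, alpha, m_p)
    gain_trace: list[tuple[int, float]] = []
    converged = False

    # phase 1: coordinate-wise proximal Newton sweeps.  These build the
    # per-feature gain trace (for variable contributions) and the initial
    # active set; the polish below carries convergence the rest of the way,
    # so sweeps beyond a modest cap buy nothing.  exp(u) is cached with a
    # running offset c so each coordinate update costs one exp pass.
    cd_sweeps = min(max_iter, 25)
    cols = [np.ascontiguousarray(F_bg[:, j]) for j in range(n_feat)]
    c_off = 0.0
    eu = np.exp(u - c_off)
    z_sum = eu.sum()
    log_z = c_off + np.log(z_sum)
    for sweep in range(cd_sweeps):
        obj_start = obj
        for j in range(n_feat):
            col = cols[j]
            w = eu / z_sum                   # current q over background
            e_j = w @ col
            v_j = w @ (col * col) - e_j * e_j
            if v_j < 1e-12:
                continue
            g = m_p * (f_bar[j] - e_j)
            h = m_p * v_j
            z = lam[j] + g / h
            target = np.sign(z) * max(abs(z) - alpha[j] / h, 0.0)
            d = target - lam[j]
            if d == 0.0:
                continue
            # backtracking: the proximal step direction is an ascent
            # direction for the penalized objective; halve until no decrease
            for _ in range(40):
                lam_j_new = lam[j] + d
                eu_new = eu * np.exp(d * col)
                z_new = eu_new.sum()
                log_z_new = c_off + np.log(z_new)
                obj_new = (m_p * (f_bar @ lam - f_bar[j] * lam[j]
                                  + f_bar[j] * lam_j_new - log_z_new)
                           - (np.abs(lam) @ alpha - abs(lam[j]) * alpha[j]
                              + abs(lam_j_new) * alpha[j]))
                if obj_new >= obj - 1e-15:
                    break
                d *= 0.5
            else:
                continue
            gain_trace.append((j, obj_new - obj))
            lam[j] = lam_j_new
            eu, z_sum, log_z, obj = eu_new, z_new, log_z_new, obj_new
            peak = eu.max()
            if peak > 1e100 or peak < 1e-100:  # keep exp cache in range
                c_off += np.log(peak)
                eu = eu / peak
                z_sum = eu.sum()
        rel = abs(obj - obj_start) / max(1.0, abs(obj))
        if rel < tol:
            converged = True
            break
    u = F_bg @ lam

    # phase 2: quasi-Newton polish on the active set with signs fixed (the
    # penalty is then linear, hence smooth), alternated with a KKT screen
    # that re-admits coordinates whose zero value violates optimality.
    active = np.nonzero(lam)[0] if beta > 0 else np.arange(n_feat)
    pending_signs = np.zeros(n_feat)
    for _round in range(10):
        obj_round_start = obj
        if active.size:
            signs = np.sign(lam[active])
            zero = signs == 0
            ps = pending_signs[active]
            signs[zero] = np.where(ps[zero] != 0, ps[zero], 1.0)

            F_act = np.ascontiguousarray(F_bg[:, active])

            def neg_obj(la: np.ndarray) -> tuple[float, np.ndarray]:
                full = lam.copy()
                full[active] = la
                uu = F_bg @ full
                mx = uu.max()
                eu = np.exp(uu - mx)
                z_shift = eu.sum()
                lz = mx + np.log(z_shift)
                ww = eu / z_shift
                val = m_p * (f_bar @ full - lz) - np.abs(full) @ alpha
                grad = (m_p * (f_bar[active] - ww @ F_act)
                        - alpha[active] * signs)
                return -val, -grad

            bounds = None if beta == 0 else [
                (0.0, None) if sg > 0 else (None, 0.0) for sg in signs]
            # gradient tolerance scaled to m_p: guarantees the beta=0
            # feature-matching gap |E_q[f] - mean| stays below 1e-7
            res = minimize(neg_obj, lam[active], jac=True, method="L-BFGS-B",
                           bounds=bounds,
                           options={"maxiter": 500, "ftol": 1e-15,
                                    "gtol": max(1e-9, 1e-7 * m_p)})
            cand = lam.copy()
            cand[active] = res.x
            cand_obj = penalized_objective(cand, f_bar, F_bg, alpha, m_p)
            if cand_obj >= obj - 1e-12:
                lam, obj = cand, cand_obj
                u = F_bg @ lam
                log_z = logsumexp(u)
        # KKT screen over all coordinates
        w = np.exp(u - log_z)
        smooth_grad = m_p * (f_bar - w @ F_bg)
        viol = (lam == 0) & (np.abs(smooth_grad) > alpha + 1e-9)
        no_improvement = abs(obj - obj_round_start) < tol * max(1.0, abs(obj))
        if beta > 0:
            at_optimum = not viol.any()
        else:
            at_optimum = bool(np.abs(smooth_grad).max() < 1e-6 * max(1.0, m_p))
        if at_optimum or no_improvement:
            # stop on first-order optimality or when the objective has
            # stalled at its numerical floor (the contract is a relative
            # objective improvement below tol)
            converged = converged or at_optimum or no_improvement
            break
        if viol.any():
            pending_signs[viol] = np.sign(smooth_grad[viol])
            active = np.unique(np.concatenate([active, np.nonzero(viol)[0]]))

    # first-order optimality: subgradient residual of the penalized objective
    w = np.exp(u - log_z)
    smooth_grad = m_p * (f_bar - w @ F_bg)
    resid = np.where(lam != 0,
                     np.abs(smooth_grad - alpha * np.sign(lam)),
                     np.maximum(0.0, np.abs(smooth_grad) - alpha))
    gnorm = float(np.max(resid)) if resid.size else 0.0
    if not converged:
        warnings.warn(f"maxent fit did not converge in {max_iter} sweeps "
                      f"(final gradient norm {gnorm:.3g})", RuntimeWarning)

    entropy = float(-(w @ np.log(np.clip(w, 1e-300, None))))
    if spec is None:
        spec = FeatureSpec(
            variables=tuple(f"x{i}" for i in range(n_feat)),
            classes=("linear",),
            var_bounds={f"x{i}": (0.0, 1.0) for i in range(n_feat)},
        )
    model = MaxentModel(
        spec=spec, weights=lam, log_z=float(log_z), entropy=entropy,
        beta=float(beta), n_presence=m_p, n_background=m_bg,
        presence_mean=f_bar, presence_sd=s, converged=converged,
        objective=float(obj), gain_trace=tuple(gain_trace),
        duplicate_groups=_duplicate_groups(np.vstack([F_p, F_bg])),
    )
    return model


# ----------------------------------------------------------------------
# Projection
# ----------------------------------------------------------------------

def project(model: MaxentModel, stack: BioclimStack, clamp: bool = True):
    """Project a fitted model onto a predictor stack.

    With ``clamp=True`` each predictor is clipped to its training range
    before featurization, so cells beyond the training envelope score as if
    they sat exactly on the boundary.  Cells with any nodata predictor are
    nodata in both output layers.

    Returns a :class:`climsuit.thresholds.SuitabilityMap`.
    """
    from .thresholds import SuitabilityMap

    missing = [v for v in model.spec.variables if v not in stack.layers]
    if missing:
        raise ValueError(f"predictor stack is missing layer(s) {missing}")
    g = stack.grid
    valid = stack.valid_mask()
    rows, cols = np.nonzero(valid)
    X = np.column_stack([stack.layers[v].values[rows, cols]
                         for v in model.spec.variables])
    F = model.spec.transform(X, clamp=clamp)
    raw = model.predict_raw(F)
    logistic = model.predict_logistic(F)
    raw_arr = np.full(g.shape, g.nodata)
    log_arr = np.full(g.shape, g.nodata)
    raw_arr[rows, cols] = raw
    log_arr[rows, cols] = logistic
    return SuitabilityMap(logistic=g.with_values(log_arr), raw=g.with_values(raw_arr))


# ----------------------------------------------------------------------
# Variable importance
# ----------------------------------------------------------------------

def variable_contribution(model: MaxentModel) -> pd.DataFrame:
    """Percent contribution of each source variable to the fitted model.

    Each optimizer iteration's increase in penalized log-likelihood is
    credited to the source variable(s) of the updated feature, split evenly
    for product features; credited gains are first averaged across groups of
    exactly identical feature columns (symmetric tie-break), then normalized
    to sum to 100 over variables.
    """
    gains = np.zeros(model.spec.n_features)
    for j, d in model.gain_trace:
        gains[j] += d
    for group in model.duplicate_groups:
        idx = list(group)
        gains[idx] = gains[idx].mean()
    per_var = {v: 0.0 for v in model.spec.variables}
    for j, fv in enumerate(model.spec.feature_vars):
        share = gains[j] / len(fv)
        for v in fv:
            per_var[v] += share
    total = sum(per_var.values())
    if total <= 0:
        warnings.warn("zero total objective gain; contributions set uniform",
                      RuntimeWarning)
        pct = {v: 100.0 / len(per_var) for v in per_var}
    else:
        pct = {v: 100.0 * gv / total for v, gv in per_var.items()}
    return pd.DataFrame({"variable": list(pct), "contribution_pct": list(pct.values())})


def jackknife_single(
    presence_table: pd.DataFrame,
    background_table: pd.DataFrame,
    variables: Sequence[str],
    beta: float = 1.0,
    classes: Sequence[str] = DEFAULT_CLASSES,
    test_presence_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Single-variable jackknife: refit with each variable alone, report AUC.

    AUC is test presences (training presences when no test table is given)
    scored against the background sample.  A row with variable ``"all"``
    reports the full model for reference.  Per-variable fit errors are
    logged and reported as NaN without aborting the remaining variables.
    """
    from .thresholds import auc

    if len(variables) < 1:
        raise ValueError("need at least one variable")
    test = test_presence_table if test_presence_table is not None else presence_table
    pooled = pd.concat([presence_table, background_table], ignore_index=True)
    records = []

    def _fit_auc(var_subset: Sequence[str]) -> float:
        spec, _ = build_features(pooled, classes=classes, variables=var_subset)
        model = fit(spec.table_matrix(presence_table),
                    spec.table_matrix(background_table), beta=beta, spec=spec)
        p = model.predict_logistic(spec.table_matrix(test, clamp=True))
        b = model.predict_logistic(spec.table_matrix(background_table))
        return auc(p, b)

    for v in variables:
        try:
            records.append({"variable": v, "auc": _fit_auc([v])})
        except Exception as exc:  # keep going: one bad variable must not kill the table
            logger.warning("jackknife fit failed for %s: %s", v, exc)
            records.append({"variable": v, "auc": float("nan")})
    records.append({"variable": "all", "auc": _fit_auc(list(variables))})
    return pd.DataFrame(records)
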