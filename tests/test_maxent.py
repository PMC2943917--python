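"""Maximum-entropy core: feature expansion, fitting, prediction, projection.

The fitting path is cross-checked against an independent derivative-free
maximization (Nelder-Mead) of the same penalized objective on small
instances, and against closed-form anchors solvable by hand or bisection.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import bisect, minimize

from climsuit.grids import BIOCLIM_NAMES
from climsuit.maxent import (
    FeatureSpec,
    MaxentModel,
    build_features,
    fit,
    jackknife_single,
    penalized_objective,
    project,
    variable_contribution,
)
from climsuit.thresholds import auc


def direct_maximize(f_bar, F_bg, alpha, m_p):
    """Derivative-free maximization of the penalized objective (oracle).

    Nelder-Mead from zero with restarts; independent of the fitting path.
    """
    x = np.zeros(F_bg.shape[1])
    for _ in range(4):
        res = minimize(lambda la: -penalized_objective(la, f_bar, F_bg, alpha, m_p),
                       x, method="Nelder-Mead",
                       options={"maxiter": 40_000, "maxfev": 40_000,
                                "xatol": 1e-11, "fatol": 1e-13})
        x = res.x
    return x, -res.fun


def random_instance(rng, n_feat=None, beta=None):
    n_feat = n_feat or rng.integers(1, 4)
    m_bg = rng.integers(10, 101)
    m_p = rng.integers(5, 31)
    F_bg = rng.random((m_bg, n_feat))
    # presences drawn from background rows: feasible, non-separable means
    F_p = F_bg[rng.integers(0, m_bg, size=m_p)] + 0.01 * rng.random((m_p, n_feat))
    beta = beta if beta is not None else float(rng.choice([0.0, 0.5, 1.0]))
    return F_p, F_bg, beta


class TestFeatures:
    def make_table(self, n=20, n_vars=10, seed=0):
        r = np.random.default_rng(seed)
        return pd.DataFrame({v: r.random(n) for v in BIOCLIM_NAMES[:n_vars]})

    def test_linear_only_counts(self):
        spec, X = build_features(self.make_table(n_vars=2), classes=["linear"])
        assert spec.n_features == 2 and X.shape[1] == 2

    def test_full_class_combinatorics(self):
        spec, X = build_features(self.make_table())
        assert spec.n_features == 10 + 10 + 45

    def test_constant_variable_dropped(self):
        tab = self.make_table(n_vars=3)
        tab["MTEMP"] = 5.0
        spec, _ = build_features(tab, classes=["linear"])
        assert "MTEMP" not in spec.variables and spec.n_features == 2

    def test_standardization_and_clamp(self):
        tab = pd.DataFrame({"MTEMP": [0.0, 10.0], "PREC": [100.0, 300.0]})
        spec, X = build_features(tab, classes=["linear"])
        np.testing.assert_allclose(X, [[0, 0], [1, 1]])
        clamped = spec.transform(np.array([[20.0, -50.0]]), clamp=True)
        np.testing.assert_allclose(clamped, [[1.0, 0.0]])


class TestFitAnchors:
    def test_no_signal_gives_uniform(self, rng):
        F_bg = rng.random((30, 2))
        F_p = np.tile(F_bg.mean(axis=0), (10, 1))
        m = fit(F_p, F_bg, beta=0.0)
        np.testing.assert_allclose(m.weights, 0.0, atol=1e-5)
        np.testing.assert_allclose(m.predict_raw(F_bg), 1 / 30, atol=1e-5)
        assert np.isclose(m.entropy, np.log(30), atol=1e-4)

    def test_two_cell_closed_form(self):
        # background {0, 1}, presence mean 0.7: e^l/(1+e^l) = 0.7
        lam_star = bisect(lambda l: np.exp(l) / (1 + np.exp(l)) - 0.7, -5, 5,
                          xtol=1e-12)
        m = fit(np.full((10, 1), 0.7), np.array([[0.0], [1.0]]), beta=0.0)
        assert np.isclose(m.weights[0], lam_star, atol=1e-6)
        assert np.isclose(m.weights[0], np.log(7 / 3), atol=1e-6)
        np.testing.assert_allclose(m.predict_raw(np.array([[0.0], [1.0]])).ravel(),
                                   [0.3, 0.7], atol=1e-6)

    def test_uniform_model_logistic_half(self, rng):
        F_bg = rng.random((25, 3))
        m = fit(np.tile(F_bg.mean(axis=0), (5, 1)), F_bg, beta=0.0)
        np.testing.assert_allclose(m.predict_logistic(F_bg), 0.5, atol=1e-4)

    def test_logistic_monotone_in_raw(self, rng):
        F_p, F_bg, _ = random_instance(rng, n_feat=2, beta=0.5)
        m = fit(F_p, F_bg, beta=0.5)
        raw = m.predict_raw(F_bg)
        logi = m.predict_logistic(F_bg)
        order = np.argsort(raw)
        assert (np.diff(logi[order]) >= -1e-12).all()

    def test_shrinkage_with_positive_beta(self, rng):
        F_p, F_bg, _ = random_instance(rng, n_feat=1)
        lam0 = fit(F_p, F_bg, beta=0.0).weights[0]
        for b in (0.5, 1.0, 2.0):
            lam_b = fit(F_p, F_bg, beta=b).weights[0]
            assert abs(lam_b) <= abs(lam0) + 1e-8


class TestFitInvariants:
    @pytest.mark.parametrize("beta", [0.0, 0.5, 1.0])
    def test_probability_and_constraint_invariants(self, beta, rng):
        for _ in range(5):
            F_p, F_bg, _ = random_instance(rng)
            m = fit(F_p, F_bg, beta=beta)
            q = m.predict_raw(F_bg)
            assert abs(q.sum() - 1.0) < 1e-9
            gap = np.abs(q @ F_bg - F_p.mean(axis=0))
            if beta == 0.0:
                assert (gap < 1e-6).all()
            else:
                bound = beta * F_p.std(axis=0) / np.sqrt(len(F_p)) + 1e-6
                assert (gap <= bound).all()

    def test_monotone_objective_trace(self, rng):
        F_p, F_bg, beta = random_instance(rng, n_feat=3, beta=1.0)
        m = fit(F_p, F_bg, beta=beta)
        gains = [d for _, d in m.gain_trace]
        assert all(g >= -1e-12 for g in gains)

    def test_oracle_equivalence_small_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(8):
            F_p, F_bg, beta = random_instance(rng)
            m_p = len(F_p)
            alpha = beta * F_p.std(axis=0) / np.sqrt(m_p)
            model = fit(F_p, F_bg, beta=beta)
            lam_o, obj_o = direct_maximize(F_p.mean(axis=0), F_bg, alpha, m_p)
            assert model.objective >= obj_o - 1e-8
            np.testing.assert_allclose(model.weights, lam_o, atol=1e-4)

    def test_parameter_recovery_from_known_gibbs(self):
        # presences simulated from a known 2-feature Gibbs model; the weight
        # magnitudes put the MLE comfortably inside the 10% band at n=1000
        # (Cramer-Rao sd is ~0.15, i.e. the band is ~2.5 sigma wide)
        for seed in (1, 2, 3):
            r = np.random.default_rng(seed)
            F_bg = r.random((10_000, 2))
            lam_star = np.array([5.0, -4.0])
            p = np.exp(F_bg @ lam_star)
            p /= p.sum()
            idx = r.choice(len(F_bg), size=1000, p=p)
            m = fit(F_bg[idx], F_bg, beta=0.0)
            rel = np.abs(m.weights - lam_star) / np.abs(lam_star)
            assert (rel < 0.10).all()


class TestProjection:
    def test_clamp_identity_in_training_region(self, small_scenario, small_config):
        from climsuit.pipeline import run_period

        res = run_period(small_scenario, small_scenario.modern_mask, small_config,
                         jackknife_tables=False)
        model = res.models[0]
        on = project(model, small_scenario.stack, clamp=True)
        off = project(model, small_scenario.stack, clamp=False)
        native = small_scenario.native_region.values != 0
        np.testing.assert_allclose(on.logistic.values[native],
                                   off.logistic.values[native], atol=1e-12)

    def test_clamped_cell_equals_boundary_cell(self):
        spec = FeatureSpec(variables=("MTEMP",), classes=("linear",),
                           var_bounds={"MTEMP": (0.0, 10.0)})
        F_p = spec.transform(np.array([[7.0], [9.0]]))
        F_bg = spec.transform(np.linspace(0, 10, 50)[:, None])
        m = fit(F_p, F_bg, beta=0.0, spec=spec)
        beyond = m.predict_logistic(spec.transform(np.array([[25.0]]), clamp=True))
        at_max = m.predict_logistic(spec.transform(np.array([[10.0]])))
        assert np.isclose(beyond[0], at_max[0])
        # unclamped continues the monotone response beyond the boundary
        un = m.predict_logistic(spec.transform(np.array([[25.0]]), clamp=False))
        assert un[0] > at_max[0]  # positive-weight linear feature

    def test_missing_layer_named(self, small_scenario):
        spec = FeatureSpec(variables=("NOPE",), classes=("linear",),
                           var_bounds={"NOPE": (0.0, 1.0)})
        m = fit(np.array([[0.4], [0.6]]), np.array([[0.1], [0.9]]), spec=spec)
        with pytest.raises(ValueError, match="NOPE"):
            project(m, small_scenario.stack)


class TestContributions:
    def test_single_variable_gets_all(self, rng):
        tab = pd.DataFrame({"MTEMP": rng.random(120)})
        spec, _ = build_features(tab, classes=["linear"])
        m = fit(spec.table_matrix(tab.iloc[:20]), spec.table_matrix(tab.iloc[20:]),
                beta=0.0, spec=spec)
        c = variable_contribution(m)
        assert np.isclose(c["contribution_pct"].sum(), 100.0)
        assert c.loc[c["variable"] == "MTEMP", "contribution_pct"].iloc[0] == 100.0

    def test_duplicate_columns_split_evenly(self, rng):
        x = rng.random(150)
        tab = pd.DataFrame({"MTEMP": x, "PREC": x})  # identical columns
        spec, _ = build_features(tab, classes=["linear"])
        m = fit(spec.table_matrix(tab.iloc[:30]), spec.table_matrix(tab.iloc[30:]),
                beta=1.0, spec=spec)
        c = variable_contribution(m).set_index("variable")["contribution_pct"]
        assert np.isclose(c["MTEMP"], c["PREC"])

    def test_rank_matches_drop_one_refit(self):
        # three variables with very different real effects
        r = np.random.default_rng(3)
        n_bg = 600
        tab_bg = pd.DataFrame({"MTEMP": r.random(n_bg), "PREC": r.random(n_bg),
                               "ISO": r.random(n_bg)})
        w_true = {"MTEMP": 3.0, "PREC": 1.0, "ISO": 0.0}
        score = sum(w * tab_bg[v] for v, w in w_true.items())
        p = np.exp(score)
        p /= p.sum()
        idx = r.choice(n_bg, size=300, p=p.to_numpy())
        tab_p = tab_bg.iloc[idx].reset_index(drop=True)
        pooled = pd.concat([tab_p, tab_bg], ignore_index=True)
        spec, _ = build_features(pooled, classes=["linear"])
        m = fit(spec.table_matrix(tab_p), spec.table_matrix(tab_bg),
                beta=0.0, spec=spec)
        contrib = variable_contribution(m).set_index("variable")["contribution_pct"]
        assert np.isclose(contrib.sum(), 100.0)

        def drop_one_loss(var):
            keep = [v for v in ("MTEMP", "PREC", "ISO") if v != var]
            s2, _ = build_features(pooled, classes=["linear"], variables=keep)
            m2 = fit(s2.table_matrix(tab_p), s2.table_matrix(tab_bg),
                     beta=0.0, spec=s2)
            return m.objective - m2.objective

        losses = {v: drop_one_loss(v) for v in ("MTEMP", "PREC", "ISO")}
        assert (contrib.sort_values(ascending=False).index.tolist()
                == sorted(losses, key=losses.get, reverse=True))


class TestJackknife:
    def test_noise_variable_near_half_and_driver_highest(self, small_scenario):
        r = np.random.default_rng(5)
        stack = small_scenario.stack
        native = small_scenario.native_region.values != 0
        valid = stack.valid_mask() & native
        mtemp = stack.layers["MTEMP"].values[valid]
        # presences driven purely by MTEMP rank; plus an independent noise var
        z = (mtemp - mtemp.min()) / (mtemp.max() - mtemp.min())
        p = np.exp(3.0 * z)
        p /= p.sum()
        idx = r.choice(valid.sum(), size=200, p=p)
        test_idx = r.choice(valid.sum(), size=200, p=p)   # held-out presences
        bg_tab = pd.DataFrame({"MTEMP": mtemp, "NOISE": r.random(valid.sum())})
        p_tab = bg_tab.iloc[idx].reset_index(drop=True)
        p_tab["NOISE"] = r.random(len(p_tab))  # independent of presence
        t_tab = bg_tab.iloc[test_idx].reset_index(drop=True)
        t_tab["NOISE"] = r.random(len(t_tab))
        table = jackknife_single(p_tab, bg_tab, ["MTEMP", "NOISE"], beta=1.0,
                                 classes=["linear", "quadratic"],
                                 test_presence_table=t_tab)
        by_var = table.set_index("variable")["auc"]
        assert abs(by_var["NOISE"] - 0.5) < 0.05
        assert by_var["MTEMP"] == by_var.drop("all").max()

    def test_single_variable_equals_full(self, rng):
        tab_bg = pd.DataFrame({"MTEMP": rng.random(200)})
        tab_p = tab_bg.iloc[rng.integers(0, 200, 50)].reset_index(drop=True)
        t = jackknife_single(tab_p, tab_bg, ["MTEMP"], beta=1.0,
                             classes=["linear"])
        by_var = t.set_index("variable")["auc"]
        assert np.isclose(by_var["MTEMP"], by_var["all"])


class TestSerialization:
    def test_round_trip_projection_identical(self, tmp_path, rng):
        F_p, F_bg, _ = random_instance(rng, n_feat=2, beta=1.0)
        spec = FeatureSpec(variables=("MTEMP", "PREC"), classes=("linear",),
                           var_bounds={"MTEMP": (0.0, 1.0), "PREC": (0.0, 1.0)})
        m = fit(F_p, F_bg, beta=1.0, spec=spec)
        path = tmp_path / "model.json"
        m.to_json(path)
        m2 = MaxentModel.from_json(path)
        np.testing.assert_array_equal(m.weights, m2.weights)
        X = rng.random((20, 2))
        np.testing.assert_array_equal(m.predict_logistic(spec.transform(X)),
                                      m2.predict_logistic(m2.spec.transform(X)))
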