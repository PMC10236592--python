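"""REML engine: oracle equivalences, invariances and derived parameters."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_pedigree
from nutrieff.animal_model import (
    DesignError,
    ModelFormula,
    RandomTerm,
    REMLFit,
    build_design,
    fit_mixed_model,
    genetic_parameters,
    reml_bivariate,
    reml_univariate,
    standard_errors,
)
from nutrieff.pedigree import additive_relationship


def _halfsib_data(seed, n_sires=50, n_prog=20, v_s=2.0, v_e=8.0):
    rng = np.random.default_rng(seed)
    sire = np.repeat(np.arange(n_sires), n_prog)
    y = 5.0 + rng.normal(0, np.sqrt(v_s), n_sires)[sire] + rng.normal(
        0, np.sqrt(v_e), n_sires * n_prog
    )
    return y, sire


class TestBuildDesign:
    def test_two_level_factor(self):
        df = pd.DataFrame({"y": [1.0, 2, 3, 4],
                           "sex": ["f", "m", "f", "m"]})
        d = build_design(df, ModelFormula(responses=["y"], fixed_terms=["sex"]))
        assert d.X.shape == (4, 2)  # intercept + one indicator
        assert d.xnames == ["(Intercept)", "sex[m]"]

    def test_missing_animal_named(self, trio):
        df = pd.DataFrame({"y": [1.0], "animal_id": ["ghost"]})
        with pytest.raises(DesignError, match="ghost"):
            build_design(
                df,
                ModelFormula(responses=["y"],
                             random_terms=[("animal_id", "pedigree")]),
                trio,
            )

    def test_litter_incidence(self):
        df = pd.DataFrame({"y": np.arange(12.0),
                           "lit": [f"L{i % 4}" for i in range(12)]})
        d = build_design(
            df, ModelFormula(responses=["y"], random_terms=[("lit", "identity")])
        )
        assert len(d.litter_levels) == 4
        # each record maps to exactly one litter level
        assert d.litter_index.shape == (12,)
        assert set(d.litter_index) == {0, 1, 2, 3}

    def test_aliased_column_dropped(self):
        df = pd.DataFrame({"y": np.arange(6.0), "a": [1.0] * 6,
                           "b": np.arange(6.0)})
        d = build_design(df, ModelFormula(responses=["y"], fixed_terms=["a", "b"]))
        assert "a" not in d.xnames  # constant column aliases the intercept

    def test_interaction_requires_mains(self):
        with pytest.raises(ValueError, match="main effect"):
            ModelFormula(responses=["y"], fixed_terms=["a:b"])


class TestUnivariateOracles:
    def test_balanced_halfsib_equals_anova(self):
        """Balanced one-way REML equals the closed-form ANOVA components."""
        y, sire = _halfsib_data(1)
        n_sires, n_prog = 50, 20
        fit = fit_mixed_model(y, np.ones((y.size, 1)), [RandomTerm("sire", sire)])
        ym = y.reshape(n_sires, n_prog)
        ms_s = n_prog * ((ym.mean(1) - y.mean()) ** 2).sum() / (n_sires - 1)
        ms_e = ((ym - ym.mean(1, keepdims=True)) ** 2).sum() / (n_sires * (n_prog - 1))
        assert fit.component("sire") == pytest.approx((ms_s - ms_e) / n_prog, rel=1e-4)
        assert fit.component("residual") == pytest.approx(ms_e, rel=1e-4)
        assert fit.converged

    def test_grid_search_oracle(self):
        """REML optimum matches brute-force likelihood maximisation on a toy."""
        rng = np.random.default_rng(9)
        ped = random_pedigree(4, 4, rng)
        A = additive_relationship(ped).values
        n = len(ped)
        L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
        y = 2.0 + L @ rng.normal(0, 1.0, n) + rng.normal(0, 1.0, n)
        X = np.ones((n, 1))

        def restricted_ll(va, ve):
            V = va * A + ve * np.eye(n)
            Vi = np.linalg.inv(V)
            XtVX = X.T @ Vi @ X
            beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
            r = y - X @ beta
            _, ldv = np.linalg.slogdet(V)
            _, ldx = np.linalg.slogdet(XtVX)
            return -0.5 * (ldv + ldx + r @ Vi @ r)

        # coarse scan then local 1e-3 refinement around the coarse optimum
        grid = np.arange(0.05, 4.0, 0.05)
        lls = np.array([[restricted_ll(a, e) for e in grid] for a in grid])
        ia, ie = np.unravel_index(lls.argmax(), lls.shape)
        fine_a = np.arange(max(grid[ia] - 0.06, 1e-3), grid[ia] + 0.06, 1e-3)
        fine_e = np.arange(max(grid[ie] - 0.06, 1e-3), grid[ie] + 0.06, 1e-3)
        lls2 = np.array([[restricted_ll(a, e) for e in fine_e] for a in fine_a])
        ja, je = np.unravel_index(lls2.argmax(), lls2.shape)
        fit = reml_univariate(y, X, Z_a=np.arange(n), A=A)
        assert fit.loglik >= lls2.max() - 1e-6
        assert fit.component("animal") == pytest.approx(fine_a[ja], abs=2e-3)
        assert fit.component("residual") == pytest.approx(fine_e[je], abs=2e-3)

    def test_null_genetic_variance_hits_boundary(self):
        """Pure-noise data: estimated genetic variance collapses to the floor."""
        h2_hat = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            sire = np.repeat(np.arange(25), 20)
            y = rng.normal(0, 1.0, 500)
            fit = fit_mixed_model(y, np.ones((500, 1)), [RandomTerm("s", sire)])
            h2_hat.append(fit.component("s") / (fit.component("s") + fit.component("residual")))
        mean = np.mean(h2_hat)
        se = np.std(h2_hat, ddof=1) / np.sqrt(len(h2_hat))
        assert mean == pytest.approx(0.0, abs=max(2 * se, 1e-3))


class TestInvariances:
    def test_scale_and_translation(self):
        y, sire = _halfsib_data(3, n_sires=30, n_prog=10)
        X = np.ones((y.size, 1))
        fit = fit_mixed_model(y, X, [RandomTerm("s", sire)])
        h2 = fit.component("s") / (fit.component("s") + fit.component("residual"))
        fit_scaled = fit_mixed_model(3.7 * y, X, [RandomTerm("s", sire)])
        h2_scaled = fit_scaled.component("s") / (
            fit_scaled.component("s") + fit_scaled.component("residual")
        )
        assert h2_scaled == pytest.approx(h2, rel=1e-4)
        fit_shift = fit_mixed_model(y + 42.0, X, [RandomTerm("s", sire)])
        assert fit_shift.component("s") == pytest.approx(fit.component("s"), rel=1e-5)
        assert fit_shift.component("residual") == pytest.approx(
            fit.component("residual"), rel=1e-5
        )

    def test_ai_matrix_symmetric(self):
        y, sire = _halfsib_data(4, n_sires=20, n_prog=8)
        fit = fit_mixed_model(y, np.ones((y.size, 1)), [RandomTerm("s", sire)])
        assert np.allclose(fit.ai_matrix, fit.ai_matrix.T)


class TestBivariate:
    def test_duplicate_trait_correlation_at_boundary(self):
        y, sire = _halfsib_data(5, n_sires=30, n_prog=10)
        fit = reml_bivariate(y, y.copy(), np.ones((y.size, 1)),
                             Z_a=sire, A=np.eye(30))
        gp = genetic_parameters(fit, litter=None)
        assert gp.rg == pytest.approx(1.0, abs=2e-3)
        assert any(p.startswith("C_") for p in fit.at_boundary)

    def test_null_genetic_correlation(self):
        """Independent breeding values: mean rg over replicates near zero."""
        est = []
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            n_s, n_p = 40, 20
            sire = np.repeat(np.arange(n_s), n_p)
            s1 = rng.normal(0, 1.0, n_s)
            s2 = rng.normal(0, 1.0, n_s)  # independent of s1
            y1 = s1[sire] + rng.normal(0, 2.0, n_s * n_p)
            y2 = s2[sire] + rng.normal(0, 2.0, n_s * n_p)
            fit = reml_bivariate(y1, y2, np.ones((n_s * n_p, 1)),
                                 Z_a=sire, A=np.eye(n_s))
            est.append(genetic_parameters(fit, litter=None).rg)
        mean = np.mean(est)
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(mean) < 2 * se + 0.02

    def test_univariate_equals_bivariate_margins(self):
        """With all covariances fixed at zero the bivariate fit factorises."""
        rng = np.random.default_rng(12)
        n_s, n_p = 30, 10
        sire = np.repeat(np.arange(n_s), n_p)
        y1 = rng.normal(0, 1, n_s)[sire] + rng.normal(0, 2, n_s * n_p)
        y2 = 0.5 * rng.normal(0, 1, n_s)[sire] + rng.normal(0, 1.5, n_s * n_p)
        X = np.ones((n_s * n_p, 1))
        u1 = fit_mixed_model(y1, X, [RandomTerm("animal", sire, np.eye(n_s))])
        u2 = fit_mixed_model(y2, X, [RandomTerm("animal", sire, np.eye(n_s))])
        biv = fit_mixed_model(
            np.column_stack([y1, y2]), X,
            [RandomTerm("animal", sire, np.eye(n_s))],
            trait_names=["a", "b"],
            fix={"C_animal(a,b)": 0.0, "C_residual(a,b)": 0.0},
        )
        assert biv.components["animal"][0, 0] == pytest.approx(
            u1.component("animal"), rel=1e-4)
        assert biv.components["animal"][1, 1] == pytest.approx(
            u2.component("animal"), rel=1e-4)
        assert biv.components["residual"][0, 0] == pytest.approx(
            u1.component("residual"), rel=1e-4)
        assert biv.loglik == pytest.approx(u1.loglik + u2.loglik, abs=1e-4)


from conftest import manual_fit as _manual_fit


class TestStandardErrors:
    def test_delta_h2_matches_hand_formula(self):
        """Diagonal information: SE(h2) from the symbolic delta expansion."""
        va, ve = 2.0, 6.0
        ia, ie = 0.25, 0.5   # Var(va)=4, Var(ve)=2
        fit = _manual_fit([va, ve], ["V_animal", "V_residual"],
                          np.diag([ia, ie]))
        gp = genetic_parameters(fit, litter=None)
        vp = va + ve
        # d h2/d va = ve/vp^2 ; d h2/d ve = -va/vp^2
        var = (ve / vp**2) ** 2 / ia + (va / vp**2) ** 2 / ie
        assert gp.h2["t"] == pytest.approx(va / vp)
        assert gp.h2_se["t"] == pytest.approx(np.sqrt(var), rel=1e-4)

    def test_component_ses_from_information(self):
        fit = _manual_fit([2.0, 6.0], ["V_animal", "V_residual"],
                          np.diag([0.25, 0.5]))
        se = standard_errors(fit)
        assert se["V_animal"] == pytest.approx(2.0)
        assert se["V_residual"] == pytest.approx(np.sqrt(2.0))

    def test_fixed_variance_has_zero_se(self):
        """A component treated as known contributes no sampling variance."""
        y, sire = _halfsib_data(6, n_sires=20, n_prog=10)
        fit = fit_mixed_model(y, np.ones((y.size, 1)),
                              [RandomTerm("s", sire)],
                              fix={"V_s": 2.0})
        assert fit.component("s") == 2.0
        assert standard_errors(fit)["V_s"] == pytest.approx(0.0, abs=1e-10)

    def test_boundary_correlation_flagged(self):
        fit = _manual_fit([1.0, 1.0], ["V_animal", "V_residual"], np.eye(2))
        assert fit.at_boundary == []
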