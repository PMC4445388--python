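"""RAM compilation, ML/FIML estimation, standardization, and inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.optimize import minimize

from edusem.sem_engine import (
    Covariance,
    ModelSpec,
    Path,
    compare,
    compile_ram,
    drop_test,
    fit_fiml,
    fit_indices,
    fit_ml,
    implied_moments,
    modification_indices,
    standardize,
)
from edusem.sem_engine.fit import FitResult, _MLObjective, _start_vector
from edusem.study_models import build
from edusem.summary_data import MomentInput, VariableSet
from edusem.synthetic_cohort import CohortMatrix, GeneratorConfig, cohort_moments, generate_cohort

from conftest import make_moments


def one_factor_spec(indicators, name="f1"):
    return ModelSpec(
        name=name,
        observed=tuple(indicators),
        latent=("f",),
        paths=tuple(Path("f", v) for v in indicators),
        covariances=(Covariance("f", "f", free=False, value=1.0),),
    )


class TestCompile:
    def test_one_factor_structural_counts(self):
        ram = compile_ram(one_factor_spec(("a", "b", "c")))
        a_cells = [c for cells in ram.cells.values() for c in cells if c[0] == "A"]
        s_cells = [c for cells in ram.cells.values() for c in cells if c[0] == "S"]
        assert len(a_cells) == 3           # three free loadings
        assert len(s_cells) == 3           # three free uniquenesses
        assert ram.S0[ram.index("f"), ram.index("f")] == 1.0  # fixed factor variance

    def test_model_a_education_cells(self):
        ram = compile_ram(build("model_a"))
        g_row = ram.index("g")
        edu_col = ram.index("education")
        edu_g = [c for cells in ram.cells.values() for c in cells
                 if c == ("A", g_row, edu_col)]
        assert len(edu_g) == 1
        # no education -> subtest directed cells
        for s in build("model_a").observed[2:]:
            assert ("A", ram.index(s), edu_col) not in {
                c for cells in ram.cells.values() for c in cells
            }

    def test_cyclic_regressions_rejected(self):
        spec = ModelSpec(name="cycle", observed=("x", "y"),
                         paths=(Path("x", "y"), Path("y", "x")))
        with pytest.raises(ValueError, match="cycle"):
            compile_ram(spec)

    def test_unknown_variable_rejected(self):
        spec = ModelSpec(name="bad", observed=("x",), paths=(Path("ghost", "x"),))
        with pytest.raises(ValueError, match="unknown variable"):
            compile_ram(spec)

    def test_conflicting_label_status_rejected(self):
        spec = ModelSpec(
            name="bad",
            observed=("x", "y", "z"),
            paths=(Path("x", "y", label="shared"),
                   Path("x", "z", free=False, value=0.3, label="shared")),
        )
        with pytest.raises(ValueError, match="conflicting"):
            compile_ram(spec)

    def test_shared_label_is_equality_constraint(self):
        spec = ModelSpec(
            name="eq",
            observed=("a", "b"),
            latent=("f",),
            paths=(Path("f", "a", label="lam"), Path("f", "b", label="lam")),
            covariances=(Covariance("f", "f", free=False, value=1.0),),
        )
        ram = compile_ram(spec)
        assert len(ram.cells["lam"]) == 2


class TestImpliedMoments:
    def test_no_paths_gives_selected_s(self):
        spec = ModelSpec(name="cov", observed=("x", "y"),
                         covariances=(Covariance("x", "x"), Covariance("y", "y"),
                                      Covariance("x", "y")))
        ram = compile_ram(spec)
        theta = np.array([ram.free_labels.index(lab) + 1.0 for lab in ram.free_labels])
        sigma, mu = implied_moments(ram, theta)
        A, S, _ = ram.materialize(theta)
        assert np.allclose(sigma, S[:2, :2])
        assert mu is None

    def test_one_factor_closed_form(self):
        ram = compile_ram(one_factor_spec(("a", "b", "c")))
        lam = {"a~f": 0.8, "b~f": 0.6, "c~f": 0.5}
        uniq = {"a~~a": 0.36, "b~~b": 0.64, "c~~c": 0.75}
        theta = np.array([{**lam, **uniq}[lab] for lab in ram.free_labels])
        sigma, _ = implied_moments(ram, theta)
        for i, vi in enumerate("abc"):
            for j, vj in enumerate("abc"):
                if i != j:
                    assert sigma[i, j] == pytest.approx(lam[f"{vi}~f"] * lam[f"{vj}~f"])

    def test_matches_nilpotent_path_series(self):
        # independent oracle: for a DAG, (I - A)^{-1} = sum_k A^k (finite)
        spec = ModelSpec(
            name="chain",
            observed=("w", "x", "y", "z"),
            paths=(Path("w", "x"), Path("x", "y"), Path("y", "z"), Path("w", "z")),
        )
        ram = compile_ram(spec)
        rng = np.random.default_rng(7)
        theta = rng.uniform(0.2, 0.8, ram.n_free)
        # give the variances sane values
        theta = np.array([
            rng.uniform(0.5, 1.5) if "~~" in lab else rng.uniform(0.2, 0.8)
            for lab in ram.free_labels
        ])
        sigma, _ = implied_moments(ram, theta)
        A, S, _ = ram.materialize(theta)
        total = np.eye(4)
        powered = np.eye(4)
        for _ in range(4):
            powered = powered @ A
            total += powered
        assert np.allclose(sigma, (total @ S @ total.T)[:4, :4], atol=1e-12)


class TestFitML:
    def test_saturated_model_fits_perfectly(self, toy3):
        spec = ModelSpec(
            name="sat", observed=("a", "b", "c"),
            covariances=tuple(Covariance(x, y) for i, x in enumerate("abc") for y in "abc"[i:]),
        )
        fit = fit_ml(toy3, spec)
        assert fit.discrepancy == 0.0
        assert fit.chi_square == 0.0
        assert fit.df == 0

    def test_tetrad_closed_form(self, toy3):
        # just-identified 1-factor model: lambda_a = sqrt(r_ab r_ac / r_bc)
        fit = fit_ml(toy3, one_factor_spec(("a", "b", "c")))
        assert fit.converged
        assert fit.estimates["a~f"] == pytest.approx(np.sqrt(0.5 * 0.3 / 0.4), abs=1e-8)
        assert fit.estimates["b~f"] == pytest.approx(np.sqrt(0.5 * 0.4 / 0.3), abs=1e-8)
        assert fit.chi_square == pytest.approx(0.0, abs=1e-8)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_analytic_gradient_matches_finite_differences(self, moments, seed):
        spec = build("model_a")
        ram = compile_ram(spec)
        idx = [moments.variables.names.index(v) for v in spec.observed]
        S = moments.cov[np.ix_(idx, idx)]
        obj = _MLObjective(ram, S, None, moments.n_eff)
        rng = np.random.default_rng(seed)
        theta = _start_vector(ram, S, None) * (1 + 0.1 * rng.standard_normal(ram.n_free))
        _, grad = obj.value_and_grad(theta)
        fd = np.zeros_like(grad)
        for j in range(len(theta)):
            h = 1e-6 * max(1.0, abs(theta[j]))
            up, dn = theta.copy(), theta.copy()
            up[j] += h
            dn[j] -= h
            fd[j] = (obj.value_and_grad(up)[0] - obj.value_and_grad(dn)[0]) / (2 * h)
        assert np.abs(grad - fd).max() < 1e-6

    def test_nested_monotonicity_and_aic_identity(self, moments):
        fa = fit_ml(moments, build("model_a"))
        fb = fit_ml(moments, build("model_b"))
        assert fb.chi_square <= fa.chi_square + 1e-8
        res = compare(fa, fb)
        assert res.delta_aic == pytest.approx(res.delta_chi_square - 2 * res.delta_df, abs=1e-8)

    def test_regression_se_closed_form(self):
        # ML SE of a bivariate slope: sqrt(sy^2 (1 - rho^2) / ((n-1) sx^2))
        rho, sx, sy, n = 0.6, 2.0, 3.0, 500
        mi = make_moments(("x", "y"), {"x": "early_iq", "y": "education"},
                          [[sx**2, rho * sx * sy], [rho * sx * sy, sy**2]], n_eff=n)
        fit = fit_ml(mi, ModelSpec(name="reg", observed=("x", "y"), paths=(Path("x", "y"),)))
        assert fit.estimates["y~x"] == pytest.approx(rho * sy / sx, abs=1e-10)
        assert fit.se["y~x"] == pytest.approx(np.sqrt(sy**2 * (1 - rho**2) / ((n - 1) * sx**2)),
                                              rel=1e-6)


class TestStandardize:
    def test_bivariate_standardized_path_is_the_correlation(self):
        mi = make_moments(("x", "y"), {"x": "early_iq", "y": "education"},
                          [[4.0, 0.6 * 2 * 3], [0.6 * 2 * 3, 9.0]])
        fit = fit_ml(mi, ModelSpec(name="reg", observed=("x", "y"), paths=(Path("x", "y"),)))
        assert fit.std("y~x") == pytest.approx(0.6, abs=1e-10)

    def test_invariant_under_rescaling(self, sm, moments):
        from edusem.summary_data import to_covariance

        scaled = to_covariance(sm)
        scale = np.ones(12)
        scale[3] = 10.0
        scaled = MomentInput(
            variables=scaled.variables,
            cov=scaled.cov * np.outer(scale, scale),
            mean=scaled.mean,
            n_eff=scaled.n_eff,
        )
        fit0 = fit_ml(moments, build("model_a"))
        fit1 = fit_ml(scaled, build("model_a"))
        for key, value in fit0.std_estimates.items():
            assert fit1.std_estimates[key] == pytest.approx(value, abs=1e-7)

    def test_unit_variance_model_already_standardized(self, toy3):
        fit = fit_ml(toy3, one_factor_spec(("a", "b", "c")))
        for v in "abc":
            assert fit.std(f"{v}~f") == pytest.approx(fit.estimates[f"{v}~f"], abs=1e-8)
        assert standardize(fit).std_estimates == fit.std_estimates  # idempotent


class TestFitIndices:
    @staticmethod
    def fake_fit(chi, df, n=1000, aic=0.0):
        return FitResult(model="m", method="ml", estimates={}, se={}, std_estimates={},
                         discrepancy=0.0, loglik=None, chi_square=chi, df=df, n_eff=n,
                         n_free=0, aic=aic, aic_scale="relative", converged=True)

    def test_perfect_fit_boundary(self):
        ix = fit_indices(self.fake_fit(30.0, 30), baseline=self.fake_fit(900.0, 45))
        assert ix.rmsea == 0.0
        assert ix.cfi == 1.0

    def test_tli_arithmetic(self):
        # chi_b/df_b = 10, chi/df = 2 -> TLI = 8/9
        ix = fit_indices(self.fake_fit(20.0, 10), baseline=self.fake_fit(100.0, 10))
        assert ix.tli == pytest.approx(8.0 / 9.0)

    def test_df_zero_undefined(self):
        ix = fit_indices(self.fake_fit(0.0, 0), baseline=self.fake_fit(100.0, 10))
        assert np.isnan(ix.rmsea) and np.isnan(ix.tli)

    def test_fixture_baseline_computed_automatically(self, moments):
        fit = fit_ml(moments, build("model_a"))
        ix = fit_indices(fit)
        assert 0.0 < ix.rmsea < 0.08
        assert 0.9 < ix.cfi <= 1.0
        assert ix.tli <= ix.cfi + 0.05


class TestCompare:
    def test_self_comparison_is_null(self, moments):
        fit = fit_ml(moments, build("model_a"))
        res = compare(fit, fit)
        assert res.delta_chi_square == 0.0
        assert res.p_value == 1.0

    def test_method_mismatch_rejected(self, sm, moments):
        coh = generate_cohort(sm, GeneratorConfig(n=100, seed=0))
        fm = fit_ml(moments, build("model_a"))
        ff = fit_fiml(coh, build("model_a"))
        with pytest.raises(ValueError, match="same method"):
            compare(fm, ff)

    def test_reversed_nesting_rejected(self, moments):
        fa = fit_ml(moments, build("model_a"))
        fb = fit_ml(moments, build("model_b"))
        with pytest.raises(ValueError, match="fewer free parameters"):
            compare(fb, fa)


@pytest.fixture(scope="module")
def toy5_moments():
    """5-variable one-factor population with one extra residual covariance."""
    lam = np.array([0.8, 0.7, 0.6, 0.5, 0.4])
    sigma = np.outer(lam, lam)
    np.fill_diagonal(sigma, 1.0)
    sigma[3, 4] = sigma[4, 3] = lam[3] * lam[4] + 0.15
    names = tuple("vwxyz")
    roles = {"v": "early_iq", "w": "education"} | {k: "subtest" for k in "xyz"}
    return make_moments(names, roles, sigma, n_eff=800)


class TestModificationIndices:
    def test_mi_close_to_refit_delta_chi_square(self, toy5_moments):
        spec = one_factor_spec(tuple("vwxyz"))
        fit = fit_ml(toy5_moments, spec)
        mis = modification_indices(fit, [Covariance("y", "z"), Covariance("v", "w")])
        refit = fit_ml(toy5_moments, spec.add(Covariance("y", "z")))
        delta = fit.chi_square - refit.chi_square
        assert mis["y~~z"] == pytest.approx(delta, rel=0.15)
        assert mis["y~~z"] > mis["v~~w"]

    def test_null_candidate_has_small_mi(self, toy5_moments):
        spec = one_factor_spec(tuple("vwxyz")).add(Covariance("y", "z"))
        fit = fit_ml(toy5_moments, spec)
        mis = modification_indices(fit, [Covariance("v", "x")])
        assert mis["v~~x"] < 4.0  # ~chi2(1) noise, not signal

    def test_already_free_candidate_rejected(self, toy5_moments):
        fit = fit_ml(toy5_moments, one_factor_spec(tuple("vwxyz")))
        with pytest.raises(ValueError, match="already free"):
            modification_indices(fit, [Covariance("v", "v")])


class TestDropTest:
    def test_null_drop_costs_nothing(self, toy5_moments):
        # population has no v~~w residual covariance: freeing it then dropping
        # it is free of charge
        spec = one_factor_spec(tuple("vwxyz")).add(Covariance("y", "z"), Covariance("v", "w"))
        fit = fit_ml(toy5_moments, spec)
        res = drop_test(fit, "v~~w")
        assert res.delta_chi_square == pytest.approx(0.0, abs=0.05)
        assert res.delta_df == 1

    def test_wald_lrt_consistency(self, toy5_moments):
        spec = one_factor_spec(tuple("vwxyz")).add(Covariance("y", "z"))
        fit = fit_ml(toy5_moments, spec)
        res = drop_test(fit, "y~~z")
        wald = (fit.estimates["y~~z"] / fit.se["y~~z"]) ** 2
        assert res.delta_chi_square == pytest.approx(wald, rel=0.2)

    def test_unknown_label_rejected(self, toy5_moments):
        fit = fit_ml(toy5_moments, one_factor_spec(tuple("vwxyz")))
        with pytest.raises(KeyError):
            drop_test(fit, "not~a~parameter")


class TestFIML:
    def test_complete_data_fiml_equals_summary_ml(self, sm):
        cohort = generate_cohort(sm, GeneratorConfig(n=1091, seed=5))
        ff = fit_fiml(cohort, build("model_a"))
        fm = fit_ml(cohort_moments(cohort, ddof=0), build("model_a"))
        for key in fm.estimates:
            assert ff.estimates[key] == pytest.approx(fm.estimates[key], abs=1e-6)

    def test_casewise_likelihood_matches_direct_evaluation(self):
        # oracle: sum of normal log-densities over each row's observed subset
        vs = VariableSet(names=("x", "y"), roles={"x": "early_iq", "y": "education"})
        df = pd.DataFrame(
            {"x": [1.0, 2.0, 3.0, np.nan, 0.5], "y": [0.8, 1.9, np.nan, 1.2, 0.4]}
        )
        cohort = CohortMatrix(data=df, variables=vs)
        spec = ModelSpec(
            name="sat2", observed=("x", "y"),
            covariances=(Covariance("x", "x"), Covariance("y", "y"), Covariance("x", "y")),
            mean_structure=True,
        )
        fit = fit_fiml(cohort, spec)
        sigma, mu = implied_moments(fit.ram, fit.theta)
        hand = 0.0
        for _, row in df.iterrows():
            obs = [i for i, v in enumerate(("x", "y")) if not np.isnan(row.iloc[i])]
            hand += stats.multivariate_normal.logpdf(
                row.iloc[obs], mean=mu[obs], cov=sigma[np.ix_(obs, obs)]
            )
        assert fit.discrepancy == pytest.approx(-2 * hand, rel=1e-10)

    def test_all_missing_rows_excluded_with_count(self, sm):
        cohort = generate_cohort(sm, GeneratorConfig(n=200, seed=1))
        df = cohort.data.copy()
        df.iloc[:3] = np.nan
        cohort = CohortMatrix(data=df, variables=cohort.variables)
        fit = fit_fiml(cohort, build("model_a"))
        assert fit.n_eff == 197
        assert any("excluded 3 rows" in w for w in fit.warnings)

    def test_fiml_with_missingness_close_to_summary_fit(self, sm, moments):
        # cross-method consistency: exact-moments cohort + printed MCAR
        # counts, Model C by FIML vs the summary ML fit
        from edusem.synthetic_cohort import impose_missingness, table1_missingness

        cohort = impose_missingness(
            generate_cohort(sm, GeneratorConfig(n=1091, seed=5)),
            table1_missingness(sm), seed=6,
        )
        ff = fit_fiml(cohort, build("model_c"))
        fm = fit_ml(moments, build("model_c"))
        assert abs(ff.std("logical_memory~education") - fm.std("logical_memory~education")) < 0.02

    def test_exact_moments_parameter_recovery(self, sm, moments):
        # population = model C implied covariance; an exact-moments cohort must
        # return the generating parameters to ~1e-6 with chi-square ~ 0
        gen = fit_ml(moments, build("model_c"))
        sigma, _ = implied_moments(gen.ram, gen.theta)
        pop = type(sm)(
            variables=sm.variables,
            corr=sigma / np.outer(np.sqrt(np.diag(sigma)), np.sqrt(np.diag(sigma))),
            sd=np.sqrt(np.diag(sigma)),
            mean=sm.mean,
            n_obs=sm.n_obs,
            n_total=sm.n_total,
        )
        cohort = generate_cohort(pop, GeneratorConfig(n=1091, seed=11))
        refit = fit_ml(cohort_moments(cohort, ddof=1), build("model_c"))
        assert refit.chi_square == pytest.approx(0.0, abs=1e-5)
        for key, value in gen.estimates.items():
            assert refit.estimates[key] == pytest.approx(value, abs=2e-6)


class TestCrossOracle:
    """Estimates agree with independent fitters sharing no engine code."""

    def test_mediation_model_matches_ols(self):
        # x -> m -> y: ML path estimates equal the OLS slopes from the
        # covariance algebra, residual variances equal the OLS residuals
        cov = np.array([[2.0, 0.8, 0.5], [0.8, 1.5, 0.9], [0.5, 0.9, 1.8]])
        mi = make_moments(("x", "m", "y"),
                          {"x": "early_iq", "m": "education", "y": "subtest"}, cov, n_eff=400)
        spec = ModelSpec(name="med", observed=("x", "m", "y"),
                         paths=(Path("x", "m"), Path("m", "y"), Path("x", "y")))
        fit = fit_ml(mi, spec)
        b_mx = cov[0, 1] / cov[0, 0]
        xm = cov[np.ix_([0, 1], [0, 1])]
        b_y = np.linalg.solve(xm, cov[[0, 1], 2])
        assert fit.estimates["m~x"] == pytest.approx(b_mx, abs=1e-8)
        assert fit.estimates["y~x"] == pytest.approx(b_y[0], abs=1e-8)
        assert fit.estimates["y~m"] == pytest.approx(b_y[1], abs=1e-8)
        resid_m = cov[1, 1] - cov[0, 1] ** 2 / cov[0, 0]
        assert fit.estimates["m~~m"] == pytest.approx(resid_m, abs=1e-8)

    def test_four_indicator_factor_matches_brute_force(self):
        # independent route: hand-written implied covariance + Nelder-Mead
        rng = np.random.default_rng(3)
        lam_true = np.array([0.9, 0.75, 0.6, 0.5])
        sigma = np.outer(lam_true, lam_true)
        np.fill_diagonal(sigma, 1.0)
        names = tuple("abcd")
        mi = make_moments(names, {"a": "early_iq", "b": "education",
                                  "c": "subtest", "d": "subtest"}, sigma, n_eff=300)
        fit = fit_ml(mi, one_factor_spec(names))

        def f_ml(theta):
            lam, psi = theta[:4], theta[4:]
            if np.any(psi <= 1e-6):
                return 1e6
            s_imp = np.outer(lam, lam) + np.diag(psi)
            sign, logdet = np.linalg.slogdet(s_imp)
            if sign <= 0:
                return 1e6
            return logdet + np.trace(np.linalg.solve(s_imp, sigma)) - np.linalg.slogdet(sigma)[1] - 4

        best = None
        for attempt in range(3):
            x0 = np.concatenate([np.full(4, 0.6), np.full(4, 0.5)]) * (
                1 + 0.1 * rng.standard_normal(8))
            res = minimize(f_ml, x0, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
            if best is None or res.fun < best.fun:
                best = res
        for i, v in enumerate(names):
            assert fit.estimates[f"{v}~f"] == pytest.approx(abs(best.x[i]), abs=1e-4)
            assert fit.estimates[f"{v}~~{v}"] == pytest.approx(best.x[4 + i], abs=1e-4)

    def test_three_indicator_closed_form_is_exact(self, toy3):
        # third oracle: the tetrad solution, checked against hand arithmetic
        fit = fit_ml(toy3, one_factor_spec(("a", "b", "c")))
        for a, b, c, key in (( .5, .3, .4, "a~f"), (.5, .4, .3, "b~f"), (.3, .4, .5, "c~f")):
            assert fit.estimates[key] == pytest.approx(np.sqrt(a * b / c), abs=1e-8)
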