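"""FOCE engine tests.

The central oracle: for models that are *linear* in eta the FOCE objective
is exact, so it must equal the closed-form marginal normal -2 log
likelihood computed independently from explicit covariance matrices.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from biosimpk import (
    CovariateDistribution,
    CovariateModelSpec,
    CovariateTerm,
    StructuralParams,
    TrialDesign,
    apply_exclusions,
    cv_percent,
    default_population,
    fit_model,
    foce_objective,
    simulate_trial,
)
from biosimpk.nlme_engine import (
    PopulationParameters,
    compute_shrinkage,
    foce_inner_ofv,
)

LOG_2PI = math.log(2.0 * math.pi)


def marginal_m2ll(y, mean, cov):
    """Closed-form -2 log N(y; mean, cov) (independent oracle)."""
    r = y - mean
    sign, logdet = np.linalg.slogdet(cov)
    assert sign > 0
    return len(y) * LOG_2PI + logdet + float(r @ np.linalg.solve(cov, r))


class TestLinearEtaOracle:
    def test_one_observation_per_subject(self, rng):
        # y_i = ln TVP + eta_i + W eps: exact marginal variance omega2 + W^2
        n, ln_tvp, omega2, w = 40, math.log(3.0), 0.09, 0.25
        y = ln_tvp + rng.normal(0, math.sqrt(omega2 + w * w), size=(n, 1))

        def log_pred(eta):
            return ln_tvp + eta

        ofv_i, eta, _, _ = foce_inner_ofv(
            log_pred, y, np.ones_like(y, dtype=bool), np.array([omega2]), w
        )
        expected = sum(
            marginal_m2ll(y[i], np.array([ln_tvp]), np.array([[omega2 + w * w]]))
            for i in range(n)
        )
        assert float(ofv_i.sum()) == pytest.approx(expected, abs=1e-6)
        # EB mode of the linear model: shrunken residual
        shrink = omega2 / (omega2 + w * w)
        np.testing.assert_allclose(eta[:, 0], shrink * (y[:, 0] - ln_tvp), atol=1e-7)

    def test_multiple_observations_compound_symmetry(self, rng):
        n, m, ln_tvp, omega2, w = 15, 6, math.log(0.01), 0.1, 0.3
        eta_true = rng.normal(0, math.sqrt(omega2), n)
        y = ln_tvp + eta_true[:, None] + rng.normal(0, w, size=(n, m))

        def log_pred(eta):
            return ln_tvp + np.repeat(eta, m, axis=1)

        ofv_i, _, _, _ = foce_inner_ofv(
            log_pred, y, np.ones_like(y, dtype=bool), np.array([omega2]), w
        )
        cov = w * w * np.eye(m) + omega2 * np.ones((m, m))
        expected = sum(
            marginal_m2ll(y[i], np.full(m, ln_tvp), cov) for i in range(n)
        )
        assert float(ofv_i.sum()) == pytest.approx(expected, abs=1e-6)

    def test_two_random_effects(self, rng):
        # y_ij = a + eta1 + x_j eta2 + W eps, design x known: still linear
        n, m, w = 12, 5, 0.2
        omega2 = np.array([0.05, 0.02])
        x = np.linspace(0.0, 2.0, m)
        eta_t = rng.normal(0, np.sqrt(omega2), size=(n, 2))
        y = 1.0 + eta_t[:, [0]] + eta_t[:, [1]] * x + rng.normal(0, w, (n, m))

        def log_pred(eta):
            return 1.0 + eta[:, [0]] + eta[:, [1]] * x

        ofv_i, _, _, _ = foce_inner_ofv(
            log_pred, y, np.ones_like(y, dtype=bool), omega2, w
        )
        G = np.stack([np.ones(m), x], axis=1)
        cov = w * w * np.eye(m) + G @ np.diag(omega2) @ G.T
        expected = sum(marginal_m2ll(y[i], np.full(m, 1.0), cov) for i in range(n))
        assert float(ofv_i.sum()) == pytest.approx(expected, abs=1e-6)

    def test_omega_zero_reduces_to_fixed_effects(self, rng):
        n, m, w = 10, 4, 0.3
        y = 2.0 + rng.normal(0, w, size=(n, m))

        def log_pred(eta):
            return np.full((n, m), 2.0)

        ofv_i, eta, _, _ = foce_inner_ofv(
            log_pred, y, np.ones_like(y, dtype=bool), np.array([]), w
        )
        r = y - 2.0
        expected = n * m * (LOG_2PI + math.log(w * w)) + float((r * r).sum()) / w**2
        assert float(ofv_i.sum()) == pytest.approx(expected, rel=1e-12)
        assert eta.shape == (n, 0)


class TestFOCEObjectivePK:
    def test_truth_beats_perturbed(self, pop):
        wins = 0
        for seed in range(20):
            design = TrialDesign(n_subjects=12, n_cycles=6, seed=seed)
            ds, _ = apply_exclusions(
                simulate_trial(design, CovariateDistribution(), pop), 0.25
            )
            ofv_true, _ = foce_objective(pop, ds)
            bad = pop.copy()
            bad.typicals = StructuralParams(
                pop.typicals.cl * 2, pop.typicals.v1 * 2,
                pop.typicals.q * 2, pop.typicals.v2 * 2,
            )
            ofv_bad, _ = foce_objective(bad, ds)
            wins += ofv_true < ofv_bad
        assert wins >= 15

    def test_invariant_to_subject_order(self, pop, small_trial):
        ofv_a, _ = foce_objective(pop, small_trial)
        df = small_trial.df
        ids = df["ID"].unique()[::-1]
        shuffled = pd.concat(
            [df[df["ID"] == i] for i in ids], ignore_index=True
        )
        from biosimpk import PKDataset
        ofv_b, _ = foce_objective(pop, PKDataset(shuffled))
        assert ofv_a == pytest.approx(ofv_b, abs=1e-8)

    def test_invariant_to_id_relabeling(self, pop, small_trial):
        ofv_a, _ = foce_objective(pop, small_trial)
        df = small_trial.df.copy()
        df["ID"] = df["ID"] + 1000
        from biosimpk import PKDataset
        ofv_b, _ = foce_objective(pop, PKDataset(df))
        assert ofv_a == pytest.approx(ofv_b, abs=1e-8)


class TestFitModel:
    def test_noise_free_recovery(self):
        # deterministic inversion: no IIV, vanishing residual noise
        spec = CovariateModelSpec([
            CovariateTerm("CL", "BWT", "power", 0.354, 71.0),
            CovariateTerm("V1", "BWT", "power", 0.468, 71.0),
        ])
        truth = PopulationParameters(
            typicals=StructuralParams(0.0113, 2.99, 0.269, 6.09),
            spec=spec, omega2={"CL": 0.0, "V1": 0.0}, w=1e-7,
        )
        design = TrialDesign(n_subjects=8, n_cycles=6, seed=13)
        ds, _ = apply_exclusions(
            simulate_trial(design, CovariateDistribution(), truth), 0.25
        )
        init = truth.copy()
        init.typicals = StructuralParams(0.008, 4.0, 0.4, 4.0)
        for term in init.spec.terms:
            term.theta = 0.2
        fit = fit_model(
            ds, init.spec, init,
            fixed=("W", "omega2_CL", "omega2_V1"), compute_se=False,
        )
        assert fit.converged
        est = fit.estimates()
        for key, expected in [
            ("CL", 0.0113), ("V1", 2.99), ("Q", 0.269), ("V2", 6.09),
            ("CL~BWT", 0.354), ("V1~BWT", 0.468),
        ]:
            assert est[key] == pytest.approx(expected, rel=1e-3), key

    def test_wilks_null_covariate_linear_toy(self, rng):
        # DOFV for a truly null effect ~ chi2(1) (exact for the linear model)
        n, omega2, w = 30, 0.09, 0.2
        var = omega2 + w * w
        dofvs = []
        for _ in range(200):
            x = rng.normal(size=n)
            y = 1.5 + rng.normal(0, math.sqrt(var), size=n)

            def m2ll(params, with_x):
                mu = params[0] + (params[1] * x if with_x else 0.0)
                r = y - mu
                return n * (LOG_2PI + math.log(var)) + float(r @ r) / var

            r0 = optimize.minimize(lambda p: m2ll(p, False), [1.0], method="BFGS")
            r1 = optimize.minimize(lambda p: m2ll(p, True), [1.0, 0.0], method="BFGS")
            dofvs.append(r0.fun - r1.fun)
        dofvs = np.array(dofvs)
        assert abs(dofvs.mean() - 1.0) < 0.35
        frac_below = float(np.mean(dofvs < 3.841))
        assert 0.90 <= frac_below <= 0.99


class TestShrinkage:
    def _fake_fit(self, eta_values, omega2, iwres):
        from biosimpk.nlme_engine import FitResult
        pop = default_population()
        pop = pop.copy()
        pop.omega2 = {"CL": omega2}
        return FitResult(
            params=pop, se=None, ofv=0.0,
            eta=pd.DataFrame({"ID": range(len(eta_values)),
                              "eta_CL": eta_values}),
            eta_shrinkage={}, eps_shrinkage=None, converged=True, message="",
            n_subjects=len(eta_values), n_obs=len(iwres), n_fev=0,
            condition_number=None, iiv_on=("CL",), structural="2cmt",
            fixed=(), runtime_s=0.0, iwres=np.asarray(iwres),
        )

    def test_all_zero_etas_is_full_shrinkage(self):
        fit = self._fake_fit([0.0] * 10, 0.09, [0.1, -0.1, 0.2])
        shr, _ = compute_shrinkage(fit)
        assert shr["CL"] == pytest.approx(100.0)

    def test_sd_equal_omega_is_zero_shrinkage(self):
        omega = 0.3
        a = omega / math.sqrt(2.0)  # sample SD (ddof=1) of [a, -a] is omega
        fit = self._fake_fit([a, -a], omega**2, [0.5, -0.5])
        shr, _ = compute_shrinkage(fit)
        assert shr["CL"] == pytest.approx(0.0, abs=1e-9)

    def test_omega_zero_undefined(self):
        fit = self._fake_fit([0.0, 0.1], 0.0, [0.1])
        fit.iiv_on = ("CL",)
        shr, _ = compute_shrinkage(fit)
        assert math.isnan(shr["CL"])

    def test_rich_sampling_shrinks_less(self, pop):
        # shrinkage of the EB modes at true parameters, rich vs sparse design
        sds = {}
        for n_cycles in (16, 2):
            design = TrialDesign(n_subjects=40, n_cycles=n_cycles, seed=21)
            ds, _ = apply_exclusions(
                simulate_trial(design, CovariateDistribution(), pop), 0.25
            )
            _, eta = foce_objective(pop, ds)
            sds[n_cycles] = float(np.std(eta["eta_CL"], ddof=1))
        omega = math.sqrt(pop.omega2["CL"])
        shr_rich = 100 * (1 - sds[16] / omega)
        shr_sparse = 100 * (1 - sds[2] / omega)
        assert shr_rich < shr_sparse


class TestCVPercent:
    def test_reference_values(self):
        assert cv_percent(0.0871) == pytest.approx(29.5, abs=0.05)
        assert cv_percent(0.117) == pytest.approx(34.2, abs=0.05)

    def test_zero(self):
        assert cv_percent(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cv_percent(-0.1)
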