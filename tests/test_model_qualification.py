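"""Residual, outlier/influence, bootstrap and VPC tests."""

import math

import numpy as np
import pandas as pd
import pytest

from biosimpk import (
    CovariateDistribution,
    PKDataset,
    TrialDesign,
    apply_exclusions,
    compute_residuals,
    fit_model,
    influence_check,
    simulate_trial,
    vpc,
)
from biosimpk.model_qualification import (
    bootstrap_ci,
    flag_outliers,
    resample_subjects,
)
from biosimpk.nlme_engine import default_initials


class TestComputeResiduals:
    def test_single_observation_reduction(self, pop):
        # with one observation per subject the whitened residual reduces to
        # (ln y - linearized population mean) / sqrt(total variance)
        design = TrialDesign(n_subjects=10, n_cycles=1, seed=3,
                             peak_sample_cycles=(1,))
        ds, _ = apply_exclusions(
            simulate_trial(design, CovariateDistribution(), pop), 0.25
        )
        # keep only the peak observation per subject
        df = ds.df[(ds.df["EVID"] == 1) | (ds.df["TAG"] == "C1_peak")]
        ds1 = PKDataset(df.reset_index(drop=True))
        tab = compute_residuals(ds1, pop)

        from biosimpk.nlme_engine import (
            _make_log_pred, encode_dataset, foce_inner_ofv,
        )
        enc = encode_dataset(ds1)
        omega2 = np.array([pop.omega2["CL"], pop.omega2["V1"]])
        lp = _make_log_pred(pop, enc, ["CL", "V1"])
        _, eta, f, G = foce_inner_ofv(lp, enc.lny, enc.mask, omega2, pop.w)
        for i in range(enc.n_subjects):
            g = G[i, 0, :]
            var = pop.w**2 + float(g @ (omega2 * g))
            r = enc.lny[i, 0] - f[i, 0] + float(g @ eta[i])
            assert tab["CWRES"].iloc[i] == pytest.approx(r / math.sqrt(var), rel=1e-9)

    def test_pooled_cwres_standard_normal_at_truth(self, pop):
        design = TrialDesign(n_subjects=170, n_cycles=16, seed=44)
        ds, _ = apply_exclusions(
            simulate_trial(design, CovariateDistribution(), pop), 0.25
        )
        tab = compute_residuals(ds, pop)
        assert len(tab) >= 3000
        cwres = tab["CWRES"].to_numpy()
        assert abs(cwres.mean()) < 0.1
        assert 0.9 < cwres.std() < 1.1

    def test_threshold_rule(self):
        tab = pd.DataFrame({
            "CWRES": [0.0, 0.0, 6.1, -6.1, 5.9],
            "IWRES": [6.1, 5.9, 0.0, 0.0, -5.9],
        })
        out = flag_outliers(tab)
        assert out["OUTLIER"].tolist() == [True, False, True, True, False]


class TestInfluence:
    def test_no_flags_noop(self, pop, small_trial):
        fit = fit_model(
            small_trial, pop.spec, pop, fixed=("Q", "V2"), compute_se=False
        )
        rep = influence_check(small_trial, fit, [])
        assert not rep.influential
        assert rep.refit is None
        assert rep.final_fit is fit

    def test_gross_errors_flagged_and_influential(self, pop):
        design = TrialDesign(n_subjects=50, n_cycles=6, seed=33)
        ds, _ = apply_exclusions(
            simulate_trial(design, CovariateDistribution(), pop), 0.25
        )
        df = ds.df.copy()
        # one discordant trough in each of five subjects
        targets = sorted(
            df[(df["TAG"] == "C3_trough") & (df["EVID"] == 0)].index[:5]
        )
        df.loc[targets, "DV"] *= 50.0
        contaminated = PKDataset(df)
        kw = dict(fixed=("Q", "V2"), maxiter=300)
        fit = fit_model(
            contaminated, pop.spec, default_initials(pop.spec),
            compute_se=False, **kw,
        )
        tab = compute_residuals(contaminated, fit.params)
        flagged = sorted(tab.loc[tab["OUTLIER"], "ROW"].tolist())
        assert flagged == targets
        rep = influence_check(contaminated, fit, flagged, **kw)
        assert rep.influential
        assert any(v > 0.2 for v in rep.relative_change.values())
        assert rep.final_fit is rep.refit
        # removal touches only the flagged set
        assert len(contaminated.df) - len(flagged) == len(
            rep.refit.eta
        ) * 0 + len(contaminated.df) - 5

    def test_median_point_removal_is_stable(self, pop):
        design = TrialDesign(n_subjects=30, n_cycles=16, seed=8)
        ds, _ = apply_exclusions(
            simulate_trial(design, CovariateDistribution(), pop), 0.25
        )
        kw = dict(fixed=("Q", "V2"), maxiter=300)
        fit = fit_model(ds, pop.spec, pop, compute_se=False, **kw)
        tab = compute_residuals(ds, fit.params)
        median_row = int(
            tab.iloc[(tab["CWRES"].abs()).argsort()].iloc[0]["ROW"]
        )
        rep = influence_check(ds, fit, [median_row], **kw)
        assert not rep.influential
        assert all(v < 0.01 for v in rep.relative_change.values())


class TestBootstrap:
    def test_single_rep_deterministic(self, small_trial):
        calls = []

        def fit_fn(ds):
            calls.append(tuple(ds.subject_covariates()["BWT"]))
            return {"mean_bwt": float(ds.subject_covariates()["BWT"].mean())}

        a = bootstrap_ci(small_trial, fit_fn, n_reps=1, seed=9)
        b = bootstrap_ci(small_trial, fit_fn, n_reps=1, seed=9)
        assert calls[0] == calls[1]
        assert a.table.equals(b.table)

    def test_resample_preserves_subject_count_and_blocks(self, small_trial, rng):
        res = resample_subjects(small_trial, rng)
        assert res.n_subjects == small_trial.n_subjects
        sizes = set(res.df.groupby("ID").size())
        assert sizes <= set(small_trial.df.groupby("ID").size())

    def test_toy_subject_mean_matches_analytic(self, rng):
        # estimator = mean over subjects of a per-subject value; the
        # bootstrap distribution of the mean is asymptotically
        # N(xbar, s^2 (n-1)/n^2): compare percentile CIs at 2000 reps
        n = 40
        values = rng.normal(10.0, 2.0, n)
        rows = []
        for i, v in enumerate(values, 1):
            rows.append({"ID": i, "TIME": 0.0, "NTIM": 0.0, "AMT": 100.0,
                         "RATE": 100.0, "DV": 0.0, "EVID": 1, "MDV": 1,
                         "BLQ": 0, "CYCLE": 1, "TAG": "", "VAL": v})
        ds = PKDataset(pd.DataFrame(rows))

        def fit_fn(rds):
            return {"mu": float(rds.subject_covariates()["VAL"].mean())}

        res = bootstrap_ci(ds, fit_fn, n_reps=2000, seed=5)
        lo, med, hi = res.ci("mu")
        xbar = values.mean()
        sd = values.std(ddof=1) * math.sqrt((n - 1) / n) / math.sqrt(n)
        assert med == pytest.approx(xbar, abs=3 * sd / math.sqrt(2000) * 40)
        assert lo == pytest.approx(xbar - 1.96 * sd, abs=0.15 * sd * 3)
        assert hi == pytest.approx(xbar + 1.96 * sd, abs=0.15 * sd * 3)
        assert lo <= med <= hi

    def test_median_approaches_estimate_with_reps(self, rng):
        n = 60
        values = rng.normal(5.0, 1.0, n)
        rows = []
        for i, v in enumerate(values, 1):
            rows.append({"ID": i, "TIME": 0.0, "NTIM": 0.0, "AMT": 100.0,
                         "RATE": 100.0, "DV": 0.0, "EVID": 1, "MDV": 1,
                         "BLQ": 0, "CYCLE": 1, "TAG": "", "VAL": v})
        ds = PKDataset(pd.DataFrame(rows))

        def fit_fn(rds):
            return {"mu": float(rds.subject_covariates()["VAL"].mean())}

        devs = []
        for n_reps in (30, 800):
            gaps = []
            for seed in range(10):
                res = bootstrap_ci(ds, fit_fn, n_reps=n_reps, seed=seed)
                gaps.append(abs(res.ci("mu")[1] - values.mean()))
            devs.append(np.mean(gaps))
        assert devs[1] < devs[0]

    def test_failed_replicates_counted(self, small_trial):
        def fit_fn(ds):
            return None

        res = bootstrap_ci(small_trial, fit_fn, n_reps=5, seed=1)
        assert res.n_converged == 0
        assert res.n_total == 5


class TestVPC:
    def test_self_consistency(self, pop):
        design = TrialDesign(n_subjects=60, n_cycles=8, seed=17)
        ds, _ = apply_exclusions(
            simulate_trial(design, CovariateDistribution(), pop), 0.25
        )
        res = vpc(ds, pop, n_trials=100, seed=23, lloq=0.25)
        t = res.table
        inside = 0
        total = 0
        for _, row in t.iterrows():
            for tag, obs in (("lo", "obs_lo"), ("med", "obs_med"), ("hi", "obs_hi")):
                total += 1
                if row[f"sim_{tag}_lower"] <= row[obs] <= row[f"sim_{tag}_upper"]:
                    inside += 1
        assert inside / total >= 0.9
        # percentile ordering within each bin
        assert (t["obs_lo"] <= t["obs_med"]).all()
        assert (t["obs_med"] <= t["obs_hi"]).all()
        assert (t["sim_lo"] <= t["sim_med"]).all()

    def test_single_trial_ci_collapses(self, pop, small_trial):
        res = vpc(small_trial, pop, n_trials=1, seed=3)
        t = res.table
        for tag in ("lo", "med", "hi"):
            np.testing.assert_allclose(t[f"sim_{tag}_lower"], t[f"sim_{tag}"])
            np.testing.assert_allclose(t[f"sim_{tag}_upper"], t[f"sim_{tag}"])

    def test_median_fraction_half(self, pop):
        design = TrialDesign(n_subjects=120, n_cycles=8, seed=29)
        ds, _ = apply_exclusions(
            simulate_trial(design, CovariateDistribution(), pop), 0.25
        )
        res = vpc(ds, pop, n_trials=200, seed=31)
        obs = ds.fit_observations()
        med_by_bin = res.table.set_index("bin")["sim_med"]
        below = total = 0
        for tag, grp in obs.groupby("TAG"):
            if tag in med_by_bin.index:
                below += int((grp["DV"] < med_by_bin[tag]).sum())
                total += len(grp)
        frac = below / total
        assert frac == pytest.approx(0.5, abs=0.03)

    def test_seed_reproducible_and_order_invariant(self, pop, small_trial):
        a = vpc(small_trial, pop, n_trials=10, seed=7)
        df = small_trial.df
        ids = df["ID"].unique()[::-1]
        shuffled = PKDataset(
            pd.concat([df[df["ID"] == i] for i in ids], ignore_index=True)
        )
        b = vpc(shuffled, pop, n_trials=10, seed=7)
        cols = [c for c in a.table.columns if c.startswith(("obs_", "sim_"))]
        merged = a.table.merge(b.table, on="bin", suffixes=("_a", "_b"))
        for c in cols:
            np.testing.assert_allclose(merged[f"{c}_a"], merged[f"{c}_b"],
                                       rtol=1e-9)
        c_again = vpc(small_trial, pop, n_trials=10, seed=7)
        pd.testing.assert_frame_equal(a.table, c_again.table)

    def test_time_binning_fallback(self, pop, small_trial):
        res = vpc(small_trial, pop, n_trials=5, seed=1, bin_by="time",
                  n_time_bins=5)
        assert len(res.table) >= 3
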