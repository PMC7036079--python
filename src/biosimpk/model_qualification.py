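"""Model qualification: conditional residuals, outlier/influence handling,
non-parametric bootstrap confidence intervals, and the visual predictive
check.

Residuals are computed on the log scale to match the additive-on-log error
model.  CWRES uses the standard FOCE construction: the subject's
log-observations are linearized around the empirical Bayes mode eta_hat,

    E[y_i] ~= f_i(eta_hat) - G_i eta_hat,
    Cov    ~= C_i = W^2 I + G_i Omega G_i',

and CWRES_i = L_i^{-1} (y_i - E[y_i]) with C_i = L_i L_i' (a whitened
residual, approximately standard normal when the model is right).  IWRES is
the individual weighted residual (y - f(eta_hat)) / W.  Observations with
|CWRES| > 6 or |IWRES| > 6 are flagged as potential outliers; flagged rows
are influential if their removal moves any key parameter by more than 20%,
in which case the refit without them becomes the final fit.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .dataset_io import PKDataset
from .nlme_engine import (
    FitResult,
    PopulationParameters,
    _make_log_pred,
    encode_dataset,
    fit_model,
    foce_inner_ofv,
)

__all__ = [
    "OUTLIER_THRESHOLD",
    "INFLUENCE_THRESHOLD",
    "compute_residuals",
    "flag_outliers",
    "influence_check",
    "InfluenceReport",
    "bootstrap_ci",
    "bootstrap_fit",
    "BootstrapResult",
    "vpc",
    "VPCResult",
]

log = logging.getLogger(__name__)

OUTLIER_THRESHOLD = 6.0
INFLUENCE_THRESHOLD = 0.20  # 20% relative change in a key parameter
_KEY_PARAMS = ("CL", "V1", "Q", "V2", "omega2_CL", "omega2_V1", "W")


def flag_outliers(table: pd.DataFrame, threshold: float = OUTLIER_THRESHOLD) -> pd.DataFrame:
    """Set the OUTLIER column: |CWRES| > threshold or |IWRES| > threshold."""
    table = table.copy()
    table["OUTLIER"] = (
        (table["CWRES"].abs() > threshold) | (table["IWRES"].abs() > threshold)
    ).fillna(False)
    return table


def compute_residuals(
    ds: PKDataset,
    pop: PopulationParameters,
    iiv_on: Sequence[str] = ("CL", "V1"),
    threshold: float = OUTLIER_THRESHOLD,
) -> pd.DataFrame:
    """Residual table for every usable observation at the given parameters.

    Columns: ROW (index into ``ds.df``), ID, TIME, TAG, DV, PRED and IPRED
    (population / individual predictions, mg/L), IWRES, CWRES, OUTLIER.
    Subjects whose linearized covariance is not positive definite get
    missing residuals and a warning.
    """
    enc = encode_dataset(ds)
    eta_params = [p for p in iiv_on if pop.omega2.get(p, 0.0) > 0]
    omega2 = np.array([pop.omega2[p] for p in eta_params])
    lp = _make_log_pred(pop, enc, eta_params)
    _, eta, f, G = foce_inner_ofv(lp, enc.lny, enc.mask, omega2, pop.w)
    f_pop = _make_log_pred(pop, enc, [])(np.zeros((enc.n_subjects, 0)))

    w2 = pop.w ** 2
    iwres = np.where(enc.mask, (enc.lny - f) / pop.w, np.nan)
    cwres = np.full_like(iwres, np.nan)
    k = len(eta_params)
    for i in range(enc.n_subjects):
        mi = enc.mask[i]
        m = int(mi.sum())
        if m == 0:
            continue
        Gi = G[i, mi, :] if k else np.zeros((m, 0))
        Ci = w2 * np.eye(m) + Gi @ np.diag(omega2) @ Gi.T if k else w2 * np.eye(m)
        r = (enc.lny[i, mi] - f[i, mi]) + (Gi @ eta[i] if k else 0.0)
        try:
            L = np.linalg.cholesky(Ci)
        except np.linalg.LinAlgError:
            log.warning("subject %s: singular linearized covariance; residuals missing",
                        enc.ids[i])
            continue
        cwres[i, mi] = solve_triangular(L, r, lower=True)

    # map back to dataset rows (fit_observations order matches encoding order)
    obs = ds.fit_observations()
    rows = []
    for i, sid in enumerate(enc.ids):
        g = obs[obs["ID"] == sid]
        mi = int(enc.mask[i].sum())
        for j in range(mi):
            rows.append(
                {
                    "ROW": int(g.index[j]),
                    "ID": sid,
                    "TIME": float(enc.obs_t[i, j]),
                    "TAG": str(g["TAG"].iloc[j]),
                    "DV": float(math.exp(enc.lny[i, j])),
                    "PRED": float(math.exp(f_pop[i, j])),
                    "IPRED": float(math.exp(f[i, j])),
                    "IWRES": float(iwres[i, j]),
                    "CWRES": float(cwres[i, j]),
                }
            )
    return flag_outliers(pd.DataFrame(rows), threshold)


@dataclass
class InfluenceReport:
    """Outcome of refitting without flagged outliers."""

    n_flagged: int
    flagged_rows: list[int]
    relative_change: dict[str, float]  # |new - old| / |old| per key parameter
    influential: bool
    refit: FitResult | None
    final_fit: FitResult  # refit if influential, original otherwise
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "n_flagged": self.n_flagged,
            "flagged_rows": self.flagged_rows,
            "relative_change": self.relative_change,
            "influential": self.influential,
            "refit_converged": self.refit.converged if self.refit else None,
            "message": self.message,
        }


def influence_check(
    ds: PKDataset,
    fit: FitResult,
    flagged_rows: Sequence[int],
    spec=None,
    **fit_kwargs,
) -> InfluenceReport:
    """Refit without the flagged rows and compare key parameter estimates.

    Influential iff any of CL, V1, Q, V2, omega2, W changes by more than
    20%; in that case the outlier-free fit becomes the final fit.  With no
    flagged rows this is a no-op report around the original fit.
    """
    flagged_rows = sorted(int(r) for r in flagged_rows)
    if not flagged_rows:
        return InfluenceReport(0, [], {}, False, None, fit, "no flagged observations")
    spec = spec if spec is not None else fit.params.spec
    reduced = PKDataset(ds.df.drop(index=flagged_rows).reset_index(drop=True))
    fit_kwargs.setdefault("iiv_on", fit.iiv_on)
    fit_kwargs.setdefault("structural", fit.structural)
    fit_kwargs.setdefault("fixed", fit.fixed)
    refit = fit_model(reduced, spec, fit.params, compute_se=False, **fit_kwargs)
    if not refit.converged:
        return InfluenceReport(
            len(flagged_rows), flagged_rows, {}, False, refit, fit,
            "refit without outliers did not converge; original fit retained",
        )
    old = fit.estimates()
    new = refit.estimates()
    changes = {
        p: abs(new[p] - old[p]) / abs(old[p])
        for p in _KEY_PARAMS
        if p in old and p in new and old[p] != 0
    }
    influential = any(c > INFLUENCE_THRESHOLD for c in changes.values())
    return InfluenceReport(
        len(flagged_rows),
        flagged_rows,
        changes,
        influential,
        refit,
        refit if influential else fit,
        "outliers influential; outlier-free fit adopted"
        if influential
        else "outliers not influential; original fit retained",
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Percentile confidence intervals over converged bootstrap replicates."""

    table: pd.DataFrame  # parameter, median, lower, upper
    replicates: pd.DataFrame  # one row per converged replicate
    n_converged: int
    n_total: int
    seed: int

    def ci(self, parameter: str) -> tuple[float, float, float]:
        row = self.table.set_index("parameter").loc[parameter]
        return float(row["lower"]), float(row["median"]), float(row["upper"])

    def to_dict(self) -> dict:
        return {
            "n_converged": self.n_converged,
            "n_total": self.n_total,
            "seed": self.seed,
            "table": self.table.to_dict(orient="records"),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def resample_subjects(
    ds: PKDataset, rng: np.random.Generator, stratify_by: str | None = None
) -> PKDataset:
    """Subject-level resample with replacement to the original subject count.

    Resampled subjects get fresh sequential IDs so repeated draws of the
    same subject stay distinct.  Optional stratification resamples within
    the levels of a subject-level column (e.g. ``"PROD"``).
    """
    ids = np.array(ds.subject_ids)
    if stratify_by is None:
        chosen = rng.choice(ids, size=len(ids), replace=True)
    else:
        covs = ds.subject_covariates().set_index("ID")
        chosen = np.concatenate(
            [
                rng.choice(grp.index.to_numpy(), size=len(grp), replace=True)
                for _, grp in covs.groupby(stratify_by, sort=True)
            ]
        )
    positions = ds.df.groupby("ID", sort=False).indices
    blocks = [positions[sid] for sid in chosen]
    out = ds.df.iloc[np.concatenate(blocks)].reset_index(drop=True)
    out["ID"] = np.repeat(
        np.arange(1, len(chosen) + 1), [len(b) for b in blocks]
    )
    return PKDataset.trusted(out)


def bootstrap_ci(
    ds: PKDataset,
    fit_fn: Callable[[PKDataset], dict[str, float] | None],
    n_reps: int,
    seed: int,
    stratify_by: str | None = None,
) -> BootstrapResult:
    """Generic non-parametric bootstrap: subject is the resampling unit.

    ``fit_fn`` maps a resampled dataset to a flat estimate dict, or None
    when its fit fails (such replicates are excluded and counted).  The CI
    is the 2.5-97.5 percentile range over converged replicates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    root = np.random.SeedSequence(seed)
    records = []
    n_failed = 0
    for child in root.spawn(n_reps):
        rng = np.random.default_rng(child)
        est = fit_fn(resample_subjects(ds, rng, stratify_by))
        if est is None:
            n_failed += 1
        else:
            records.append(est)
    reps = pd.DataFrame(records)
    rows = []
    for p in reps.columns:
        v = reps[p].to_numpy(dtype=float)
        lo, med, hi = np.percentile(v, [2.5, 50.0, 97.5])
        rows.append({"parameter": p, "lower": lo, "median": med, "upper": hi})
    return BootstrapResult(
        table=pd.DataFrame(rows),
        replicates=reps,
        n_converged=len(records),
        n_total=n_reps,
        seed=seed,
    )


def bootstrap_fit(
    ds: PKDataset,
    init: PopulationParameters,
    n_reps: int,
    seed: int,
    stratify_by: str | None = None,
    **fit_kwargs,
) -> BootstrapResult:
    """Bootstrap the population-model fit, warm-starting each replicate at
    the original estimates (``init`` should be the point estimate)."""
    fit_kwargs.setdefault("maxiter", 200)

    def fit_fn(rds: PKDataset) -> dict[str, float] | None:
        try:
            fit = fit_model(rds, init.spec, init, compute_se=False, **fit_kwargs)
        except (RuntimeError, ValueError, np.linalg.LinAlgError) as exc:
            log.warning("bootstrap replicate failed: %s", exc)
            return None
        return fit.estimates() if fit.converged else None

    return bootstrap_ci(ds, fit_fn, n_reps, seed, stratify_by)


# ---------------------------------------------------------------------------
# visual predictive check
# ---------------------------------------------------------------------------

@dataclass
class VPCResult:
    """Observed and simulated percentile bands per nominal-time bin."""

    table: pd.DataFrame
    n_trials: int
    seed: int
    lloq: float | None
    exclude_blq: bool
    percentiles: tuple[float, float, float] = (2.5, 50.0, 97.5)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_trials": self.n_trials,
            "seed": self.seed,
            "lloq": self.lloq,
            "exclude_blq": self.exclude_blq,
            "percentiles": list(self.percentiles),
            "table": self.table.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _band(values: np.ndarray, percentiles) -> np.ndarray:
    return np.percentile(values, percentiles)


def vpc(
    ds: PKDataset,
    pop: PopulationParameters,
    n_trials: int,
    seed: int,
    *,
    iiv_on: Sequence[str] = ("CL", "V1"),
    bin_by: str = "TAG",
    n_time_bins: int = 10,
    lloq: float | None = None,
    exclude_blq: bool = True,
    percentiles: tuple[float, float, float] = (2.5, 50.0, 97.5),
) -> VPCResult:
    """Visual predictive check against ``n_trials`` simulated replicates.

    Each replicate re-simulates the original design (doses, times and
    covariates of every subject) at the given population parameters, with
    fresh eta per subject and fresh residual noise per sample.  Per bin
    (nominal sampling tag by default, or ``bin_by="time"`` for quantile
    bins on nominal time) the observed 2.5/50/97.5 percentiles are reported
    next to the across-trial median and 95% CI of each simulated
    percentile.  Simulated values below ``lloq`` are excluded from the
    percentile computation when ``exclude_blq`` (their fraction is always
    reported); observed percentiles use the dataset's usable observations.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    enc = encode_dataset(ds)
    eta_params = [p for p in iiv_on if pop.omega2.get(p, 0.0) > 0]
    omega2 = np.array([pop.omega2[p] for p in eta_params])
    lp = _make_log_pred(pop, enc, eta_params)
    k = len(eta_params)
    n, m = enc.lny.shape

    # flat per-observation metadata aligned with the encoding order
    obs = ds.fit_observations()
    tags, ntims = [], []
    for sid in enc.ids:
        g = obs[obs["ID"] == sid]
        tags.extend(str(t) for t in g["TAG"])
        ntims.extend(float(t) for t in g["NTIM"])
    tags = np.array(tags)
    ntims = np.array(ntims)
    y_obs = np.exp(enc.lny[enc.mask])

    if bin_by == "TAG":
        order = {}
        for t, nt in zip(tags, ntims):
            order.setdefault(t, nt)
        bins = sorted(order, key=lambda t: (order[t], t))
        labels = tags
    elif bin_by == "time":
        edges = np.quantile(ntims, np.linspace(0, 1, n_time_bins + 1))
        edges = np.unique(edges)
        idx = np.clip(np.searchsorted(edges, ntims, side="right") - 1,
                      0, len(edges) - 2)
        labels = np.array([f"[{edges[i]:.0f},{edges[i + 1]:.0f}]" for i in idx])
        bins = sorted(set(labels), key=lambda s: float(s[1:].split(",")[0]))
    else:
        raise ValueError(f"unknown bin_by {bin_by!r}")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    # draw randomness in sorted-subject-ID order so the VPC is invariant to
    # the ordering of subjects in the dataset
    rank = np.empty(n, dtype=int)
    rank[np.argsort(np.asarray(enc.ids))] = np.arange(n)
    sim_bands = {b: [] for b in bins}
    sim_blq = {b: [] for b in bins}
    for _ in range(n_trials):
        eta = (
            rng.standard_normal((n, k))[rank] * np.sqrt(omega2)[None, :]
            if k
            else np.zeros((n, 0))
        )
        lnf = lp(eta)
        lny = lnf + pop.w * rng.standard_normal((n, m))[rank]
        y = np.exp(lny[enc.mask])
        for b in bins:
            sel = labels == b
            v = y[sel]
            if len(v) == 0:
                continue
            if lloq is not None:
                below = v < lloq
                sim_blq[b].append(float(below.mean()))
                if exclude_blq:
                    v = v[~below]
            if len(v):
                sim_bands[b].append(_band(v, percentiles))

    rows = []
    for b in bins:
        sel = labels == b
        if not sel.any():
            log.warning("VPC bin %s is empty; skipped", b)
            continue
        obs_band = _band(y_obs[sel], percentiles)
        sims = np.array(sim_bands[b])  # (n_trials, 3)
        row = {
            "bin": b,
            "nominal_time": float(np.median(ntims[sel])),
            "n_obs": int(sel.sum()),
            "obs_lo": obs_band[0],
            "obs_med": obs_band[1],
            "obs_hi": obs_band[2],
            "sim_blq_fraction": float(np.mean(sim_blq[b])) if sim_blq[b] else 0.0,
        }
        for j, tag in enumerate(("lo", "med", "hi")):
            ci = np.percentile(sims[:, j], [2.5, 50.0, 97.5])
            row[f"sim_{tag}_lower"] = ci[0]
            row[f"sim_{tag}"] = ci[1]
            row[f"sim_{tag}_upper"] = ci[2]
        rows.append(row)
    return VPCResult(
        table=pd.DataFrame(rows),
        n_trials=n_trials,
        seed=seed,
        lloq=lloq,
        exclude_blq=exclude_blq,
        percentiles=percentiles,
    )
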