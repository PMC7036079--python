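"""First-order conditional estimation (with eta-epsilon interaction) for the
log-transformed population PK model.

Model
-----
For subject i with usable log-observations y_i (length m_i):

    y_ij = f_ij(theta, eta_i) + W * eps_ij,     eps_ij ~ N(0, 1)
    eta_i ~ N(0, Omega),  Omega diagonal (random effects on CL and V1)

The objective function value (OFV) is the FOCE approximation to
-2 log marginal likelihood: each subject's contribution is evaluated by
linearizing f around the empirical Bayes mode eta_hat_i,

    OFV_i = m_i log(2 pi) + log|C_i| + r_i' C_i^{-1} r_i,
    C_i   = W^2 I + G_i Omega G_i',   G_i = df/deta at eta_hat_i,
    r_i   = y_i - f_i(eta_hat_i) + G_i eta_hat_i,

with the residual variance evaluated at the conditional mode (the
interaction term; under the constant-W log-additive error model the
residual variance does not itself depend on eta).  log|C_i| and the
quadratic form are computed in random-effect dimension via the matrix
determinant lemma / Woodbury identity, so the cost is O(m_i k^2) per
subject with k <= 2.

The inner problem (eta_hat maximizes the joint density of data and eta) is
solved by damped Gauss-Newton iterations, vectorized across subjects, with
warm starts between outer iterations.  The outer problem minimizes the OFV
by quasi-Newton iteration over transformed parameters (log scale for
positive quantities), with standard errors from the inverse Hessian of
OFV/2 and a delta-method back-transform.

The core (`foce_inner_ofv`) is deliberately model-agnostic: it accepts any
batched log-prediction function, which is what the test suite exploits to
check the FOCE objective against closed-form marginal likelihoods on
linear-in-eta fixtures.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .dataset_io import PKDataset
from .pk_model import CovariateModelSpec, StructuralParams

__all__ = [
    "PopulationParameters",
    "FitResult",
    "EncodedData",
    "encode_dataset",
    "foce_inner_ofv",
    "foce_objective",
    "fit_model",
    "compute_shrinkage",
    "cv_percent",
    "default_initials",
]

_LOG_2PI = math.log(2.0 * math.pi)
_ETA_FD_STEP = 1e-4
_OUTER_FD_STEP = 1e-4
_CONC_FLOOR = 1e-290


# ---------------------------------------------------------------------------
# population parameters
# ---------------------------------------------------------------------------

@dataclass
class PopulationParameters:
    """Fixed effects, random-effect variances and residual scale.

    Covariate coefficients live inside ``spec`` (one theta per term level);
    ``omega2`` maps structural-parameter names to IIV variances; ``w`` is
    the SD of the additive error on log concentrations (the epsilon variance
    is fixed to 1).
    """

    typicals: StructuralParams
    spec: CovariateModelSpec
    omega2: dict[str, float] = field(default_factory=dict)
    w: float = 0.3

    def __post_init__(self) -> None:
        if not self.w > 0:
            raise ValueError(f"residual scale w must be positive, got {self.w}")
        for name, v in self.omega2.items():
            if v < 0:
                raise ValueError(f"omega2[{name}] must be >= 0, got {v}")

    def copy(self) -> "PopulationParameters":
        return PopulationParameters(
            typicals=self.typicals,
            spec=self.spec.copy(),
            omega2=dict(self.omega2),
            w=self.w,
        )

    def to_dict(self) -> dict:
        return {
            "typicals": {
                "CL": self.typicals.cl,
                "V1": self.typicals.v1,
                "Q": self.typicals.q,
                "V2": self.typicals.v2,
            },
            "terms": [
                {
                    "parameter": t.parameter,
                    "covariate": t.covariate,
                    "form": t.form,
                    "theta": t.theta,
                    "reference": t.reference,
                }
                for t in self.spec.terms
            ],
            "omega2": dict(self.omega2),
            "w": self.w,
        }


# ---------------------------------------------------------------------------
# dataset encoding (padded rectangular arrays, one row per subject)
# ---------------------------------------------------------------------------

@dataclass
class EncodedData:
    """Padded per-subject arrays for batched likelihood evaluation."""

    ids: list[int]
    obs_t: np.ndarray  # (n, m)
    lny: np.ndarray  # (n, m) log observed concentrations
    mask: np.ndarray  # (n, m) bool, True where a real observation exists
    dose_t: np.ndarray  # (n, d)
    dose_amt: np.ndarray  # (n, d), 0 = padding
    dose_dur: np.ndarray  # (n, d)
    cov: dict[str, np.ndarray]  # subject-level covariate columns, (n,)

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())


def encode_dataset(ds: PKDataset) -> EncodedData:
    """Pack a PKDataset into padded arrays (subjects in order of appearance)."""
    obs = ds.fit_observations()
    doses = ds.doses()
    ids = ds.subject_ids
    obs_by = {k: g for k, g in obs.groupby("ID", sort=False)}
    dose_by = {k: g for k, g in doses.groupby("ID", sort=False)}
    n = len(ids)
    m = max((len(g) for g in obs_by.values()), default=0)
    d = max((len(g) for g in dose_by.values()), default=0)
    if m == 0:
        raise ValueError("dataset has no usable observations")
    if d == 0:
        raise ValueError("dataset has no dose events")

    obs_t = np.zeros((n, m))
    lny = np.zeros((n, m))
    mask = np.zeros((n, m), dtype=bool)
    dose_t = np.zeros((n, d))
    dose_amt = np.zeros((n, d))
    dose_dur = np.ones((n, d))
    for i, sid in enumerate(ids):
        g = obs_by.get(sid)
        if g is not None:
            mi = len(g)
            obs_t[i, :mi] = g["TIME"].to_numpy()
            dv = g["DV"].to_numpy(dtype=float)
            if np.any(dv <= 0):
                raise ValueError(
                    f"subject {sid}: non-positive DV among usable observations"
                )
            lny[i, :mi] = np.log(dv)
            mask[i, :mi] = True
        gd = dose_by.get(sid)
        if gd is None:
            raise ValueError(f"subject {sid} has observations but no dose events")
        di = len(gd)
        dose_t[i, :di] = gd["TIME"].to_numpy()
        amt = gd["AMT"].to_numpy(dtype=float)
        rate = gd["RATE"].to_numpy(dtype=float)
        if np.any(rate <= 0):
            raise ValueError(f"subject {sid}: dose row without a positive RATE")
        dose_amt[i, :di] = amt
        dose_dur[i, :di] = amt / rate

    cov_df = ds.subject_covariates().set_index("ID").loc[ids]
    cov = {c: cov_df[c].to_numpy(dtype=float) for c in cov_df.columns}
    return EncodedData(ids, obs_t, lny, mask, dose_t, dose_amt, dose_dur, cov)


# ---------------------------------------------------------------------------
# covariate factors and the batched log-prediction closure
# ---------------------------------------------------------------------------

def _typical_arrays(pop: PopulationParameters, enc: EncodedData) -> dict[str, np.ndarray]:
    n = enc.n_subjects
    tv = {
        "CL": np.full(n, pop.typicals.cl),
        "V1": np.full(n, pop.typicals.v1),
        "Q": np.full(n, pop.typicals.q),
        "V2": np.full(n, pop.typicals.v2),
    }
    for term in pop.spec.terms:
        try:
            col = enc.cov[term.covariate]
        except KeyError:
            raise KeyError(
                f"covariate column {term.covariate!r} required by term {term.key} "
                "is missing from the dataset"
            ) from None
        if term.form == "power":
            fac = np.exp(float(term.theta) * np.log(col / term.reference))
        elif term.form == "fractional":
            fac = np.ones(n)
            for level, theta in term.theta.items():
                fac = np.where(col == level, 1.0 + theta, fac)
            fac = np.where(col == term.reference, 1.0, fac)
        else:  # ratio
            ind = (col != (term.reference or 0.0)).astype(float)
            fac = float(term.theta) ** ind
        tv[term.parameter] = tv[term.parameter] * fac
    return tv


class _ConcKernel:
    """Dose/observation geometry cached once per dataset.

    The (subject, observation, dose) tensors of elapsed-infusion and
    post-infusion times do not depend on the parameters, so precomputing
    them removes most of the per-evaluation cost inside the FOCE loops.
    """

    def __init__(self, enc: EncodedData) -> None:
        tau = enc.obs_t[:, :, None] - enc.dose_t[:, None, :]
        self.active = tau > 0
        tau = np.where(self.active, tau, 0.0)
        dur = enc.dose_dur[:, None, :]
        self.te = np.minimum(tau, dur)
        self.post = np.maximum(tau - dur, 0.0)
        self.rate = np.where(
            enc.dose_amt > 0,
            enc.dose_amt / np.maximum(enc.dose_dur, 1e-300),
            0.0,
        )[:, None, :] * self.active

    def conc(
        self, cl: np.ndarray, v1: np.ndarray, q: np.ndarray, v2: np.ndarray
    ) -> np.ndarray:
        k10 = cl / v1
        k12 = q / v1
        k21 = q / v2
        s = k10 + k12 + k21
        p = k10 * k21
        disc = np.sqrt(np.maximum(s * s - 4.0 * p, 0.0))
        alpha = 0.5 * (s + disc)
        beta = np.where(alpha > 0, p / np.maximum(alpha, 1e-300), 0.0)
        near = disc < 1e-10 * alpha
        if np.any(near):
            bump = 1e-10 * alpha
            alpha = np.where(near, alpha + 0.5 * bump, alpha)
            beta = np.where(near, np.maximum(beta - 0.5 * bump, 0.0), beta)
        one_cmt = q == 0.0
        denom = np.maximum(alpha - beta, 1e-300)
        coef_a = (alpha - k21) / denom
        coef_b = (k21 - beta) / denom

        def term(lam, coef):
            lam_ = np.maximum(lam, 1e-300)[:, None, None]
            return (coef[:, None, None] / lam_) * (
                -np.expm1(-lam_ * self.te)
            ) * np.exp(-lam_ * self.post)

        if np.all(one_cmt):
            shape = term(k10, np.ones_like(k10))
        else:
            shape = term(alpha, coef_a) + term(beta, coef_b)
            if np.any(one_cmt):
                shape1 = term(k10, np.ones_like(k10))
                shape = np.where(one_cmt[:, None, None], shape1, shape)
        return (self.rate * shape).sum(axis=2) / v1[:, None]


_kernel_cache: dict[int, _ConcKernel] = {}


def _kernel_for(enc: EncodedData) -> _ConcKernel:
    kern = _kernel_cache.get(id(enc))
    if kern is None:
        _kernel_cache.clear()  # keep at most one dataset's geometry alive
        kern = _ConcKernel(enc)
        _kernel_cache[id(enc)] = kern
    return kern


def _make_log_pred(
    pop: PopulationParameters, enc: EncodedData, eta_params: Sequence[str]
) -> Callable[[np.ndarray], np.ndarray]:
    tv = _typical_arrays(pop, enc)
    idx = {p: j for j, p in enumerate(eta_params)}
    kern = _kernel_for(enc)

    def log_pred(eta: np.ndarray) -> np.ndarray:
        par = {}
        for p in ("CL", "V1", "Q", "V2"):
            if p in idx:
                par[p] = tv[p] * np.exp(eta[:, idx[p]])
            else:
                par[p] = tv[p]
        conc = kern.conc(par["CL"], par["V1"], par["Q"], par["V2"])
        return np.log(np.maximum(conc, _CONC_FLOOR))

    return log_pred


# ---------------------------------------------------------------------------
# FOCE core (model-agnostic)
# ---------------------------------------------------------------------------

def _fd_jacobian(
    log_pred: Callable[[np.ndarray], np.ndarray], eta: np.ndarray, step: float
) -> np.ndarray:
    """Central-difference d(log_pred)/d(eta), shape (n, m, k)."""
    n, k = eta.shape
    cols = []
    for j in range(k):
        e = np.zeros_like(eta)
        e[:, j] = step
        cols.append((log_pred(eta + e) - log_pred(eta - e)) / (2.0 * step))
    return np.stack(cols, axis=-1)


def foce_inner_ofv(
    log_pred: Callable[[np.ndarray], np.ndarray],
    y: np.ndarray,
    mask: np.ndarray,
    omega2: np.ndarray,
    w: float,
    eta0: np.ndarray | None = None,
    *,
    grad_tol: float = 1e-13,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Conditional modes and per-subject FOCE OFV contributions.

    Parameters: ``log_pred(eta) -> (n, m)`` batched log predictions;
    ``y``/``mask`` (n, m); ``omega2`` (k,) diagonal IIV variances (may be
    empty); ``w`` residual SD.  Returns ``(ofv_i, eta_hat, f_hat, G)``.

    ``grad_tol`` bounds the Newton decrement (the expected remaining
    objective decrease, in -2LL units) of the inner iteration.  Subjects
    far from that tolerance at exit get an infinite OFV contribution,
    which propagates a rejection to the outer optimizer.
    """
    n, m = y.shape
    k = len(omega2)
    w2 = max(w * w, 1e-300)
    mi = mask.sum(axis=1)

    if k == 0:
        f = log_pred(np.zeros((n, 0)))
        r = (y - f) * mask
        ofv_i = mi * (_LOG_2PI + math.log(w2)) + (r * r).sum(axis=1) / w2
        return ofv_i, np.zeros((n, 0)), f, np.zeros((n, m, 0))

    inv_o = 1.0 / np.maximum(omega2, 1e-300)
    eta = np.zeros((n, k)) if eta0 is None else np.array(eta0, dtype=float)

    def joint(e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        f = log_pred(e)
        r = (y - f) * mask
        return (r * r).sum(axis=1) / w2 + (e * e * inv_o).sum(axis=1), f

    val, f = joint(eta)
    # Newton decrement (expected objective decrease, in -2LL units): a
    # scale-invariant convergence measure that stays meaningful when
    # residuals are large (e.g. gross outliers)
    dec = np.full(n, np.inf)
    G = None
    stepped = True
    for _ in range(max_iter):
        G = _fd_jacobian(log_pred, eta, _ETA_FD_STEP) * mask[..., None]
        stepped = False
        r = (y - f) * mask
        grad = -2.0 * np.einsum("nmk,nm->nk", G, r) / w2 + 2.0 * eta * inv_o
        H = 2.0 * np.einsum("nmj,nmk->njk", G, G) / w2 + 2.0 * np.diag(inv_o)
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        dec = np.einsum("nk,nk->n", grad, step)
        if (dec < grad_tol).all():
            break
        remaining = dec >= grad_tol
        lam = np.ones(n)
        for _ in range(30):
            trial = np.where(remaining[:, None], eta - lam[:, None] * step, eta)
            tval, tf = joint(trial)
            improved = remaining & (tval <= val + 1e-13)
            if improved.any():
                eta[improved] = trial[improved]
                val[improved] = tval[improved]
                f[improved] = tf[improved]
                remaining = remaining & ~improved
                stepped = True
            if not remaining.any():
                break
            lam[remaining] *= 0.5
        else:
            break  # line search exhausted for some subject

    if stepped or G is None:
        G = _fd_jacobian(log_pred, eta, _ETA_FD_STEP) * mask[..., None]
    r_lin = (y - f) * mask + np.einsum("nmk,nk->nm", G, eta) * mask

    # log|C| and r'C^{-1}r via the determinant lemma / Woodbury in k dims
    GtG = np.einsum("nmj,nmk->njk", G, G)
    M = np.diag(inv_o)[None, :, :] + GtG / w2
    sign, logdet_m = np.linalg.slogdet(M)
    logdet = mi * math.log(w2) + float(np.log(omega2).sum()) + logdet_m
    Gtr = np.einsum("nmk,nm->nk", G, r_lin)
    Minv_Gtr = np.linalg.solve(M, Gtr[..., None])[..., 0]
    quad = (r_lin * r_lin).sum(axis=1) / w2 - np.einsum(
        "nk,nk->n", Gtr, Minv_Gtr
    ) / (w2 * w2)
    ofv_i = mi * _LOG_2PI + logdet + quad
    ofv_i = np.where((sign > 0) & (dec < max(grad_tol * 1e6, 1e-2)), ofv_i, np.inf)
    return ofv_i, eta, f, G


# ---------------------------------------------------------------------------
# parameter packing (transformed outer vector <-> PopulationParameters)
# ---------------------------------------------------------------------------

def _flat_values(pop: PopulationParameters, iiv_on: Sequence[str]) -> dict[str, float]:
    vals = {
        "CL": pop.typicals.cl,
        "V1": pop.typicals.v1,
        "Q": pop.typicals.q,
        "V2": pop.typicals.v2,
        "W": pop.w,
    }
    for term in pop.spec.terms:
        if term.form == "fractional":
            for level, theta in term.theta.items():
                vals[f"{term.key}@{level:g}"] = theta
        else:
            vals[term.key] = float(term.theta)
    for p in iiv_on:
        vals[f"omega2_{p}"] = pop.omega2.get(p, 0.0)
    return vals


def _apply_values(
    pop: PopulationParameters, vals: dict[str, float], iiv_on: Sequence[str]
) -> PopulationParameters:
    out = pop.copy()
    out.typicals = StructuralParams(vals["CL"], vals["V1"], vals["Q"], vals["V2"])
    out.w = vals["W"]
    for term in out.spec.terms:
        if term.form == "fractional":
            term.theta = {
                level: vals[f"{term.key}@{level:g}"] for level in term.theta
            }
        else:
            term.theta = vals[term.key]
    for p in iiv_on:
        out.omega2[p] = vals[f"omega2_{p}"]
    return out


class _Packing:
    """Transformed free-parameter vector <-> natural-scale value dict."""

    # inverse transforms clamp the argument: line searches may probe
    # extreme points where a bare math.exp would overflow
    _TRANSFORMS = {
        "log": (math.log, lambda x: math.exp(min(x, 700.0))),
        "raw": (lambda v: v, lambda x: x),
        "log1p": (math.log1p, lambda x: math.expm1(min(x, 700.0))),
    }

    def __init__(
        self,
        pop: PopulationParameters,
        iiv_on: Sequence[str],
        fixed: Sequence[str],
        structural: str,
    ) -> None:
        entries: list[tuple[str, str]] = [("CL", "log"), ("V1", "log")]
        if structural == "2cmt":
            entries += [("Q", "log"), ("V2", "log")]
        for term in pop.spec.terms:
            if term.form == "power":
                entries.append((term.key, "raw"))
            elif term.form == "ratio":
                entries.append((term.key, "log"))
            else:
                for level in sorted(term.theta):
                    entries.append((f"{term.key}@{level:g}", "log1p"))
        for p in iiv_on:
            entries.append((f"omega2_{p}", "log"))
        entries.append(("W", "log"))
        allowed_extra = {"Q", "V2"} | {f"omega2_{p}" for p in ("CL", "V1", "Q", "V2")}
        unknown = set(fixed) - {name for name, _ in entries} - allowed_extra
        if unknown:
            raise ValueError(f"fixed names not in the model: {sorted(unknown)}")
        self.entries = [(n, t) for n, t in entries if n not in set(fixed)]
        self.base = _flat_values(pop, iiv_on)
        self.iiv_on = tuple(iiv_on)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    def pack(self, pop: PopulationParameters) -> np.ndarray:
        vals = _flat_values(pop, self.iiv_on)
        return np.array(
            [self._TRANSFORMS[t][0](vals[n]) for n, t in self.entries]
        )

    def unpack(self, x: np.ndarray, template: PopulationParameters) -> PopulationParameters:
        vals = dict(self.base)
        for (name, t), xi in zip(self.entries, x):
            vals[name] = self._TRANSFORMS[t][1](float(xi))
        return _apply_values(template, vals, self.iiv_on)

    def natural_se(self, x: np.ndarray, se_x: np.ndarray) -> dict[str, float]:
        out: dict[str, float] = {}
        for (name, t), xi, si in zip(self.entries, x, se_x):
            if t == "log":
                out[name] = math.exp(float(xi)) * float(si)
            elif t == "log1p":
                out[name] = math.exp(float(xi)) * float(si)
            else:
                out[name] = float(si)
        return out


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimates, uncertainty and conditional-mode diagnostics from one fit."""

    params: PopulationParameters
    se: dict[str, float] | None
    ofv: float
    eta: pd.DataFrame  # one row per subject: ID + eta_<param> columns
    eta_shrinkage: dict[str, float]
    eps_shrinkage: float | None
    converged: bool
    message: str
    n_subjects: int
    n_obs: int
    n_fev: int
    condition_number: float | None
    iiv_on: tuple[str, ...]
    structural: str
    fixed: tuple[str, ...]
    runtime_s: float
    iwres: np.ndarray | None = None  # flat array over usable observations

    def estimates(self) -> dict[str, float]:
        """Flat natural-scale estimate dictionary (same keys as ``se``)."""
        return _flat_values(self.params, self.iiv_on)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "estimates": self.estimates(),
            "se": self.se,
            "ofv": self.ofv,
            "eta": {
                c: [round(v, 12) for v in self.eta[c].tolist()]
                for c in self.eta.columns
            },
            "eta_shrinkage": self.eta_shrinkage,
            "eps_shrinkage": self.eps_shrinkage,
            "converged": self.converged,
            "message": self.message,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
            "n_fev": self.n_fev,
            "condition_number": self.condition_number,
            "iiv_on": list(self.iiv_on),
            "structural": self.structural,
            "fixed": list(self.fixed),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def foce_objective(
    pop: PopulationParameters,
    ds: PKDataset | EncodedData,
    iiv_on: Sequence[str] = ("CL", "V1"),
) -> tuple[float, pd.DataFrame]:
    """OFV and empirical Bayes modes at fixed population parameters."""
    enc = ds if isinstance(ds, EncodedData) else encode_dataset(ds)
    eta_params = [p for p in iiv_on if pop.omega2.get(p, 0.0) > 0]
    omega2 = np.array([pop.omega2[p] for p in eta_params])
    lp = _make_log_pred(pop, enc, eta_params)
    ofv_i, eta, _, _ = foce_inner_ofv(lp, enc.lny, enc.mask, omega2, pop.w)
    eta_df = pd.DataFrame({"ID": enc.ids})
    for j, p in enumerate(eta_params):
        eta_df[f"eta_{p}"] = eta[:, j]
    return float(ofv_i.sum()), eta_df


def _fd_hessian(fun: Callable[[np.ndarray], float], x: np.ndarray, step: float) -> np.ndarray:
    p = len(x)
    h = np.full(p, step)
    f0 = fun(x)
    H = np.zeros((p, p))
    fp = np.zeros(p)
    fm = np.zeros(p)
    for i in range(p):
        e = np.zeros(p); e[i] = h[i]
        fp[i] = fun(x + e)
        fm[i] = fun(x - e)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] - fm[i] - fm[j] + fmm + 2.0 * f0
            ) / (2.0 * h[i] * h[j])
    return H


def fit_model(
    ds: PKDataset | EncodedData,
    spec: CovariateModelSpec,
    init: PopulationParameters,
    *,
    fixed: Sequence[str] = (),
    iiv_on: Sequence[str] = ("CL", "V1"),
    structural: str = "2cmt",
    compute_se: bool = True,
    maxiter: int = 400,
    ftol: float = 1e-10,
    gtol: float = 1e-6,
    inner_tol: float = 1e-13,
) -> FitResult:
    """Maximum-likelihood (FOCE) fit of the population model.

    ``fixed`` names parameters held at their ``init`` values (e.g. ``"Q"``,
    ``"V2"``, ``"omega2_V1"``, or a covariate-term key like ``"CL~BWT"``).
    ``structural`` is ``"2cmt"`` or ``"1cmt"`` (the latter drops Q/V2 from
    the estimation and forces Q = 0).
    """
    t0 = time.perf_counter()
    enc = ds if isinstance(ds, EncodedData) else encode_dataset(ds)
    # `spec` is authoritative for covariate structure and initial thetas;
    # `init` supplies typicals, omega2 and w
    init = init.copy()
    init.spec = spec.copy()
    if structural == "1cmt":
        init.typicals = StructuralParams(init.typicals.cl, init.typicals.v1, 0.0, 1.0)
    elif structural != "2cmt":
        raise ValueError(f"unknown structural model {structural!r}")

    eta_params = tuple(
        p for p in iiv_on
        if not (f"omega2_{p}" in fixed and init.omega2.get(p, 0.0) == 0.0)
    )
    packing = _Packing(init, eta_params, fixed, structural)
    k = len(eta_params)
    n = enc.n_subjects

    state = {"eta": np.zeros((n, k)), "nfev": 0}

    def ofv_at(x: np.ndarray, update: bool = True) -> float:
        pop = packing.unpack(x, init)
        omega2 = np.array([pop.omega2.get(p, 0.0) for p in eta_params])
        if np.any(omega2 <= 0):
            return np.inf
        lp = _make_log_pred(pop, enc, eta_params)
        try:
            # extreme probe points legitimately overflow and are rejected
            # via the non-finite OFV path below
            with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
                ofv_i, eta, _, _ = foce_inner_ofv(
                    lp, enc.lny, enc.mask, omega2, pop.w, eta0=state["eta"],
                    grad_tol=inner_tol,
                )
        except (np.linalg.LinAlgError, FloatingPointError):
            state["nfev"] += 1
            return 1e12
        if update and np.all(np.isfinite(ofv_i)):
            state["eta"] = eta
        state["nfev"] += 1
        total = float(ofv_i.sum())
        return total if np.isfinite(total) else 1e12

    def grad_at(x: np.ndarray) -> np.ndarray:
        # forward differences sharing the centre evaluation; the inner
        # problem is solved tightly enough that the O(h)
        # truncation error dominates and 1e-5 steps are accurate enough
        # for quasi-Newton progress
        f0 = ofv_at(x, update=True)
        h = 1e-5
        g = np.zeros_like(x)
        for i in range(len(x)):
            e = np.zeros_like(x)
            e[i] = h
            g[i] = (ofv_at(x + e, update=False) - f0) / h
        return g

    x0 = packing.pack(init)
    res = optimize.minimize(
        ofv_at,
        x0,
        jac=grad_at,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol},
    )
    xhat = res.x
    final = packing.unpack(xhat, init)
    omega2 = np.array([final.omega2.get(p, 0.0) for p in eta_params])
    lp = _make_log_pred(final, enc, eta_params)
    ofv_i, eta, f, _ = foce_inner_ofv(
        lp, enc.lny, enc.mask, omega2, final.w, eta0=state["eta"],
        grad_tol=inner_tol,
    )
    ofv = float(ofv_i.sum())
    converged = bool(res.success and np.isfinite(ofv))

    eta_df = pd.DataFrame({"ID": enc.ids})
    for j, p in enumerate(eta_params):
        eta_df[f"eta_{p}"] = eta[:, j]

    # shrinkage
    eta_shr: dict[str, float] = {}
    for j, p in enumerate(eta_params):
        om = math.sqrt(final.omega2[p])
        sd = float(np.std(eta[:, j], ddof=1)) if n > 1 else 0.0
        eta_shr[p] = 100.0 * (1.0 - sd / om) if om > 0 else float("nan")
    iwres = ((enc.lny - f) / final.w)[enc.mask]
    eps_shr = 100.0 * (1.0 - float(np.std(iwres, ddof=1))) if len(iwres) > 1 else None

    se = None
    cond = None
    message = str(res.message)
    if compute_se and converged:
        try:
            H = _fd_hessian(lambda x: ofv_at(x, update=False), xhat, 5e-4)
            ev, vec = np.linalg.eigh(H)
            if ev[0] <= 0:
                # near-flat directions (typically the peripheral parameters
                # under sparse sampling) can carry tiny negative curvature
                # from finite-difference noise; floor them so the flat
                # direction reports a huge, honest SE instead of failing
                floor = 1e-10 * ev[-1]
                ev = np.maximum(ev, floor)
                message += "; Hessian eigenvalues floored for SE computation"
            cov_x = 2.0 * (vec / ev) @ vec.T
            var_x = np.diag(cov_x)
            se = packing.natural_se(xhat, np.sqrt(var_x))
            d = 1.0 / np.sqrt(var_x)
            corr = cov_x * np.outer(d, d)
            evc = np.linalg.eigvalsh(corr)
            cond = float(evc.max() / evc.min()) if evc.min() > 0 else float("inf")
        except np.linalg.LinAlgError:
            message += "; Hessian inversion failed, SEs unavailable"

    return FitResult(
        params=final,
        se=se,
        ofv=ofv,
        eta=eta_df,
        eta_shrinkage=eta_shr,
        eps_shrinkage=eps_shr,
        converged=converged,
        message=message,
        n_subjects=n,
        n_obs=enc.n_obs,
        n_fev=state["nfev"],
        condition_number=cond,
        iiv_on=eta_params,
        structural=structural,
        fixed=tuple(fixed),
        runtime_s=time.perf_counter() - t0,
        iwres=iwres,
    )


def compute_shrinkage(fit: FitResult) -> tuple[dict[str, float], float | None]:
    """Eta-shrinkage per random effect and epsilon-shrinkage, in percent.

    eta-shrinkage = 100 (1 - SD(eta_hat) / omega); epsilon-shrinkage =
    100 (1 - SD(IWRES)).  Undefined (NaN) when omega = 0.
    """
    if not fit.converged:
        raise ValueError("shrinkage requires a converged fit")
    out: dict[str, float] = {}
    for p in fit.iiv_on:
        om2 = fit.params.omega2.get(p, 0.0)
        if om2 <= 0:
            out[p] = float("nan")
            continue
        sd = float(np.std(fit.eta[f"eta_{p}"].to_numpy(), ddof=1))
        out[p] = 100.0 * (1.0 - sd / math.sqrt(om2))
    eps = None
    if fit.iwres is not None and len(fit.iwres) > 1:
        eps = 100.0 * (1.0 - float(np.std(fit.iwres, ddof=1)))
    return out, eps


def cv_percent(omega2: float) -> float:
    """IIV variance to coefficient of variation: CV% = 100 sqrt(omega2)."""
    if omega2 < 0:
        raise ValueError(f"omega2 must be non-negative, got {omega2}")
    return 100.0 * math.sqrt(omega2)


def default_initials(spec: CovariateModelSpec) -> PopulationParameters:
    """Literature-scale starting values for a mAb-like two-compartment model."""
    init = PopulationParameters(
        typicals=StructuralParams(cl=0.01, v1=3.0, q=0.3, v2=6.0),
        spec=spec.copy(),
        omega2={"CL": 0.1, "V1": 0.1},
        w=0.3,
    )
    for term in init.spec.terms:
        if term.form == "power":
            term.theta = 0.3
        elif term.form == "ratio":
            term.theta = 1.0
        else:
            term.theta = {level: 0.0 for level in term.theta}
    return init
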