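"""Two-compartment IV-infusion kinetics and the multiplicative covariate model.

The structural model is a linear two-compartment system with zero-order
(constant-rate infusion) input into, and first-order elimination from, the
central compartment.  Concentrations are evaluated with the closed-form
bi-exponential solution and superposed over doses; this is the production
path used inside the estimation loop (an ODE integrator exists only as a
test oracle).

Units: time in hours, amounts in mg, volumes in L, concentrations in mg/L
(= ug/mL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StructuralParams",
    "MacroConstants",
    "DoseEvent",
    "CovariateVector",
    "CovariateTerm",
    "CovariateModelSpec",
    "IndividualParams",
    "MissingCovariateError",
    "micro_to_macro",
    "concentration",
    "typical_values",
    "individual_params",
    "SEX_CODES",
    "PRODUCT_CODES",
]

#: numeric codes used in rectangular datasets for the two built-in categoricals
SEX_CODES = {"F": 0, "M": 1}
PRODUCT_CODES = {"reference": 0, "test": 1}

# relative alpha/beta separation below which the guarded (repeated-root)
# limit expression is used
_DEGENERACY_EPS = 1e-10


class MissingCovariateError(KeyError):
    """A covariate referenced by the model spec is absent from the subject."""


@dataclass(frozen=True)
class StructuralParams:
    """Disposition parameters of the two-compartment model.

    ``q == 0`` collapses the model to one compartment (``v2`` is then inert).
    """

    cl: float  # systemic clearance, L/h
    v1: float  # central volume, L
    q: float  # intercompartmental clearance, L/h
    v2: float  # peripheral volume, L

    def __post_init__(self) -> None:
        if not (self.cl > 0 and self.v1 > 0 and self.v2 > 0):
            raise ValueError(f"cl, v1, v2 must be strictly positive, got {self}")
        if self.q < 0:
            raise ValueError(f"q must be non-negative, got {self.q}")


@dataclass(frozen=True)
class MacroConstants:
    """Micro rate constants and hybrid disposition roots (all 1/h)."""

    k10: float
    k12: float
    k21: float
    alpha: float  # fast hybrid root, alpha >= beta
    beta: float  # slow hybrid root (terminal)


@dataclass(frozen=True)
class DoseEvent:
    """A single constant-rate infusion (zero-order input only)."""

    start: float  # h
    amount: float  # mg
    duration: float  # h

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount}")
        if self.duration <= 0:
            raise ValueError(f"infusion duration must be > 0, got {self.duration}")

    @property
    def rate(self) -> float:
        return self.amount / self.duration


@dataclass(frozen=True)
class CovariateVector:
    """Baseline covariates for one subject.

    ``extras`` holds additional numeric covariates (e.g. baseline albumin,
    ALT, ALP, longest tumor diameter, ECOG, metastatic-site count) keyed by
    the dataset column name; categorical extras must already be coded
    numerically.
    """

    bwt: float  # baseline body weight, kg
    sex: str = "F"  # "F" (reference) | "M"
    product: str = "reference"  # "reference" | "test"
    extras: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.bwt > 0:
            raise ValueError(f"body weight must be > 0, got {self.bwt}")
        if self.sex not in SEX_CODES:
            raise ValueError(f"sex must be one of {sorted(SEX_CODES)}, got {self.sex!r}")
        if self.product not in PRODUCT_CODES:
            raise ValueError(
                f"product must be one of {sorted(PRODUCT_CODES)}, got {self.product!r}"
            )

    def value(self, name: str) -> float:
        """Numeric value of covariate ``name`` (categoricals as codes)."""
        if name == "BWT":
            return self.bwt
        if name == "SEX":
            return float(SEX_CODES[self.sex])
        if name == "PROD":
            return float(PRODUCT_CODES[self.product])
        try:
            return float(self.extras[name])
        except KeyError:
            raise MissingCovariateError(
                f"covariate {name!r} required by the model spec is missing"
            ) from None


@dataclass
class CovariateTerm:
    """One covariate effect on one structural parameter.

    Forms
    -----
    ``power``
        factor = (value / reference) ** theta, continuous covariates.
    ``fractional``
        categorical; ``theta`` maps non-reference level codes to fractional
        shifts, factor = 1 + theta[level] (reference level -> 1).
    ``ratio``
        binary categorical parameterized as theta ** indicator so the
        reference level contributes factor 1 and theta is the multiplicative
        ratio between levels; theta must be positive.
    """

    parameter: str  # "CL" | "V1" | "Q" | "V2"
    covariate: str  # dataset column / CovariateVector name
    form: str  # power | fractional | ratio
    theta: float | dict[float, float]
    reference: float | None = None  # median (power) or reference code (categoricals)

    def __post_init__(self) -> None:
        if self.form not in ("power", "fractional", "ratio"):
            raise ValueError(f"unknown covariate form {self.form!r}")
        if self.form == "power":
            if self.reference is None or not self.reference > 0:
                raise ValueError(
                    f"power term on {self.covariate} needs a positive reference value"
                )
        if self.form == "fractional" and not isinstance(self.theta, dict):
            raise ValueError("fractional term needs a {level: theta} mapping")
        if self.form == "ratio" and not float(self.theta) > 0:
            raise ValueError("ratio-form theta must be positive")

    @property
    def key(self) -> str:
        return f"{self.parameter}~{self.covariate}"

    def factor(self, value: float) -> float:
        if self.form == "power":
            return (value / self.reference) ** float(self.theta)
        if self.form == "fractional":
            if value == self.reference:
                return 1.0
            try:
                return 1.0 + self.theta[value]
            except KeyError:
                raise ValueError(
                    f"level {value!r} of {self.covariate} not declared in term {self.key}"
                ) from None
        # ratio: theta ** indicator, indicator 0 at reference
        ind = 0.0 if value == (self.reference or 0.0) else 1.0
        return float(self.theta) ** ind


@dataclass
class CovariateModelSpec:
    """Collection of covariate terms; at most one term per (parameter, covariate)."""

    terms: list[CovariateTerm] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [t.key for t in self.terms]
        if len(keys) != len(set(keys)):
            raise ValueError(f"duplicate covariate terms: {sorted(keys)}")

    def for_parameter(self, parameter: str) -> list[CovariateTerm]:
        return [t for t in self.terms if t.parameter == parameter]

    def copy(self) -> "CovariateModelSpec":
        return CovariateModelSpec(
            [replace(t, theta=dict(t.theta) if isinstance(t.theta, dict) else t.theta)
             for t in self.terms]
        )

    def covariate_names(self) -> list[str]:
        return sorted({t.covariate for t in self.terms})


@dataclass(frozen=True)
class IndividualParams:
    """Realized per-subject parameters after covariates and random effects."""

    cl: float
    v1: float
    q: float
    v2: float

    def __post_init__(self) -> None:
        if not (self.cl > 0 and self.v1 > 0 and self.v2 > 0) or self.q < 0:
            raise ValueError(f"individual parameters must be positive, got {self}")

    def structural(self) -> StructuralParams:
        return StructuralParams(self.cl, self.v1, self.q, self.v2)


def micro_to_macro(sp: StructuralParams) -> MacroConstants:
    """Micro rate constants and hybrid roots of the two-compartment system.

    ``alpha`` and ``beta`` (alpha >= beta) are the roots of
    ``x**2 - (k10 + k12 + k21) x + k10 k21 = 0``.  With ``q == 0`` the
    quadratic degenerates and the roots are ``{k10, 0}``.
    """
    k10 = sp.cl / sp.v1
    k12 = sp.q / sp.v1
    k21 = sp.q / sp.v2
    s = k10 + k12 + k21
    p = k10 * k21
    disc = math.sqrt(max(s * s - 4.0 * p, 0.0))
    alpha = 0.5 * (s + disc)
    # beta via the product for numerical accuracy (avoids cancellation)
    beta = p / alpha if alpha > 0 else 0.0
    return MacroConstants(k10=k10, k12=k12, k21=k21, alpha=alpha, beta=beta)


def _conc_batch(
    times: np.ndarray,
    dose_start: np.ndarray,
    dose_amount: np.ndarray,
    dose_duration: np.ndarray,
    cl: np.ndarray,
    v1: np.ndarray,
    q: np.ndarray,
    v2: np.ndarray,
) -> np.ndarray:
    """Vectorized central concentration for many subjects at once.

    Shapes: ``times`` (n, m); dose arrays (n, d) (``amount == 0`` rows are
    padding and contribute nothing); parameters (n,).  Returns (n, m).
    Used by the simulator and the estimation engine; `concentration` wraps
    the single-subject case.
    """
    times = np.asarray(times, dtype=float)
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    p = k10 * k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * p, 0.0))
    alpha = 0.5 * (s + disc)
    beta = np.where(alpha > 0, p / np.maximum(alpha, 1e-300), 0.0)

    # guard the repeated-root limit by nudging the separation
    near = disc < _DEGENERACY_EPS * alpha
    if np.any(near):
        bump = _DEGENERACY_EPS * alpha
        alpha = np.where(near, alpha + 0.5 * bump, alpha)
        beta = np.where(near, np.maximum(beta - 0.5 * bump, 0.0), beta)

    one_cmt = q == 0.0

    # bolus unit-impulse coefficients: C(t) = (D/V1)(A e^{-a t} + B e^{-b t})
    denom = np.maximum(alpha - beta, 1e-300)
    coef_a = (alpha - k21) / denom
    coef_b = (k21 - beta) / denom

    tau = times[:, :, None] - dose_start[:, None, :]  # (n, m, d)
    active = tau > 0
    tau = np.where(active, tau, 0.0)
    dur = dose_duration[:, None, :]
    rate = np.where(dose_amount > 0, dose_amount / np.maximum(dose_duration, 1e-300), 0.0)
    te = np.minimum(tau, dur)  # elapsed infusion time
    post = np.maximum(tau - dur, 0.0)  # time since end of infusion

    def term(lam: np.ndarray, coef: np.ndarray) -> np.ndarray:
        lam_ = np.maximum(lam, 1e-300)[:, None, None]
        return (coef[:, None, None] / lam_) * (-np.expm1(-lam_ * te)) * np.exp(-lam_ * post)

    if np.all(one_cmt):
        shape = term(k10, np.ones_like(k10))
    else:
        shape = term(alpha, coef_a) + term(beta, coef_b)
        if np.any(one_cmt):
            shape1 = term(k10, np.ones_like(k10))
            shape = np.where(one_cmt[:, None, None], shape1, shape)
    conc = (rate[:, None, :] * np.where(active, shape, 0.0)).sum(axis=2)
    return conc / v1[:, None]


def concentration(
    t: float | np.ndarray, doses: list[DoseEvent], sp: StructuralParams
) -> float | np.ndarray:
    """Central-compartment concentration (mg/L) at time(s) ``t``.

    Linear superposition over doses of the closed-form infusion solution;
    zero before the first dose; continuous in ``t``.  Negative times are a
    domain error.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("negative time is outside the model domain")
    if not doses:
        out = np.zeros_like(t_arr)
    else:
        out = _conc_batch(
            t_arr[None, :],
            np.array([[d.start for d in doses]]),
            np.array([[d.amount for d in doses]]),
            np.array([[d.duration for d in doses]]),
            np.array([sp.cl]),
            np.array([sp.v1]),
            np.array([sp.q]),
            np.array([sp.v2]),
        )[0]
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out[0])
    return out


def typical_values(
    typicals: StructuralParams, spec: CovariateModelSpec, cov: CovariateVector
) -> StructuralParams:
    """Typical (covariate-adjusted, eta = 0) parameters for one subject.

    Multiplicative composition of the spec's terms on top of the population
    typicals; order-independent.  A covariate referenced by the spec but
    absent from ``cov`` raises :class:`MissingCovariateError` naming it.
    """
    values = {"CL": typicals.cl, "V1": typicals.v1, "Q": typicals.q, "V2": typicals.v2}
    for term in spec.terms:
        values[term.parameter] *= term.factor(cov.value(term.covariate))
    return StructuralParams(values["CL"], values["V1"], values["Q"], values["V2"])


def individual_params(
    tvp: StructuralParams, eta: dict[str, float] | None = None
) -> IndividualParams:
    """Apply exponential random effects: P_j = TVP * exp(eta_j).

    ``eta`` maps parameter names ("CL", "V1", ...) to random-effect values;
    absent entries mean eta = 0 (the model carries inter-individual
    variability on CL and V1 only, but any parameter is accepted here).
    """
    eta = eta or {}
    return IndividualParams(
        cl=tvp.cl * math.exp(eta.get("CL", 0.0)),
        v1=tvp.v1 * math.exp(eta.get("V1", 0.0)),
        q=tvp.q * math.exp(eta.get("Q", 0.0)),
        v2=tvp.v2 * math.exp(eta.get("V2", 0.0)),
    )
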