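"""Stepwise covariate modeling: forward inclusion / backward elimination.

Candidate covariate-parameter relationships are tested one at a time with
the likelihood ratio test on the FOCE objective.  Forward steps use
alpha = 0.05; backward elimination uses alpha = 0.001; forced terms (e.g.
a drug-product effect kept for estimation purposes) are always present and
exempt from elimination.  The candidate final model is refit with standard
errors to screen for overparameterization (condition number > 1000).

Ties among equally significant candidates break on largest delta-OFV, then
lexicographic (parameter, covariate) order, so traces are deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_io import PKDataset
from .nlme_engine import EncodedData, FitResult, PopulationParameters, encode_dataset, fit_model
from .pk_model import CovariateModelSpec, CovariateTerm

__all__ = [
    "SCMCandidate",
    "SCMStep",
    "SCMTrace",
    "lrt_decision",
    "run_scm",
    "screen_covariates",
]

log = logging.getLogger(__name__)

FORWARD_ALPHA = 0.05
BACKWARD_ALPHA = 0.001
CONDITION_LIMIT = 1000.0


@dataclass(frozen=True)
class SCMCandidate:
    """One candidate covariate effect on one structural parameter."""

    parameter: str  # "CL" | "V1"
    covariate: str
    form: str  # power | fractional
    reference: float | None = None  # median (power) / reference code (fractional)
    levels: tuple[float, ...] = (1.0,)  # non-reference level codes (fractional)

    def __post_init__(self) -> None:
        if self.form not in ("power", "fractional"):
            raise ValueError(f"unsupported candidate form {self.form!r}")

    @property
    def df(self) -> int:
        return 1 if self.form == "power" else len(self.levels)

    @property
    def key(self) -> str:
        return f"{self.parameter}~{self.covariate}"

    def term(self, ds: PKDataset | EncodedData) -> CovariateTerm:
        """Neutral-theta term; power terms get the observed median as reference."""
        ref = self.reference
        if self.form == "power":
            if ref is None:
                if isinstance(ds, EncodedData):
                    ref = float(np.median(ds.cov[self.covariate]))
                else:
                    ref = float(
                        ds.subject_covariates()[self.covariate].median()
                    )
            return CovariateTerm(self.parameter, self.covariate, "power", 0.0, ref)
        return CovariateTerm(
            self.parameter, self.covariate, "fractional",
            {lv: 0.0 for lv in self.levels}, ref if ref is not None else 0.0,
        )


@dataclass
class SCMStep:
    direction: str  # "forward" | "backward"
    candidate: str  # term key
    delta_ofv: float
    df: int
    p_value: float
    accepted: bool  # forward: added; backward: removed


@dataclass
class SCMTrace:
    steps: list[SCMStep] = field(default_factory=list)
    final_spec: CovariateModelSpec | None = None
    final_fit: FitResult | None = None
    base_ofv: float = float("nan")
    overparameterized: bool | None = None

    def to_dict(self) -> dict:
        return {
            "base_ofv": self.base_ofv,
            "steps": [vars(s) for s in self.steps],
            "final_terms": [t.key for t in self.final_spec.terms]
            if self.final_spec
            else [],
            "final_ofv": self.final_fit.ofv if self.final_fit else None,
            "overparameterized": self.overparameterized,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def step_log(self) -> str:
        lines = [f"base OFV = {self.base_ofv:.4f}"]
        for s in self.steps:
            verdict = (
                ("added" if s.accepted else "not added")
                if s.direction == "forward"
                else ("removed" if s.accepted else "retained")
            )
            lines.append(
                f"{s.direction:8s} {s.candidate:16s} dOFV={s.delta_ofv:10.4f} "
                f"df={s.df} p={s.p_value:.3g} -> {verdict}"
            )
        if self.final_fit is not None:
            lines.append(f"final OFV = {self.final_fit.ofv:.4f}")
        return "\n".join(lines)


def lrt_decision(delta_ofv: float, df: int, alpha: float) -> tuple[bool, float]:
    """Likelihood-ratio decision for nested models.

    ``delta_ofv`` is the OFV improvement (>= 0 convention) of the larger
    model.  Accept iff delta_ofv exceeds the chi-square critical value at
    level ``alpha`` with ``df`` degrees of freedom; returns (accept, p).
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    p = float(stats.chi2.sf(max(delta_ofv, 0.0), df))
    threshold = float(stats.chi2.ppf(1.0 - alpha, df))
    return bool(delta_ofv > threshold), p


def _fit(enc, spec, init, fit_kwargs, compute_se=False):
    return fit_model(enc, spec, init, compute_se=compute_se, **fit_kwargs)


def run_scm(
    ds: PKDataset | EncodedData,
    base_spec: CovariateModelSpec,
    candidates: Sequence[SCMCandidate],
    init: PopulationParameters,
    forced: Sequence[SCMCandidate | CovariateTerm] = (),
    *,
    forward_alpha: float = FORWARD_ALPHA,
    backward_alpha: float = BACKWARD_ALPHA,
    **fit_kwargs,
) -> SCMTrace:
    """Forward-inclusion / backward-elimination covariate search.

    Forward: each round fits every remaining candidate on top of the
    working model and adds the one with the largest significant delta-OFV;
    stops when none is significant.  Backward: repeatedly tries to drop the
    least significant non-forced term added during the search unless its
    elimination test gives p < ``backward_alpha``.  Forced terms are added
    to the working model up front and never eliminated.  A final refit with
    standard errors flags overparameterization via the condition number.

    Extra keyword arguments (``fixed``, ``iiv_on``, ...) pass through to
    :func:`fit_model`.
    """
    enc = ds if isinstance(ds, EncodedData) else encode_dataset(ds)
    trace = SCMTrace()

    working = base_spec.copy()
    for f in forced:
        term = f.term(enc) if isinstance(f, SCMCandidate) else f
        working.terms.append(term)
    best_init = init.copy()

    base_fit = _fit(enc, working, best_init, fit_kwargs)
    if not base_fit.converged:
        raise RuntimeError(f"base model fit did not converge: {base_fit.message}")
    trace.base_ofv = base_fit.ofv
    working_fit = base_fit

    remaining = list(candidates)
    selected: list[SCMCandidate] = []

    while remaining:
        results = []
        for cand in remaining:
            spec_c = working_fit.params.spec.copy()
            spec_c.terms.append(cand.term(enc))
            try:
                fit_c = _fit(enc, spec_c, working_fit.params, fit_kwargs)
            except (RuntimeError, np.linalg.LinAlgError, ValueError) as exc:
                log.warning("candidate %s skipped this round: %s", cand.key, exc)
                continue
            if not fit_c.converged:
                log.warning("candidate %s did not converge; skipped", cand.key)
                continue
            dofv = working_fit.ofv - fit_c.ofv
            accept, p = lrt_decision(dofv, cand.df, forward_alpha)
            results.append((cand, fit_c, dofv, p, accept))
        if not results:
            break
        results.sort(key=lambda r: (-r[2], r[0].parameter, r[0].covariate))
        cand, fit_c, dofv, p, accept = results[0]
        for other, _, od, op, oa in results:
            if other is not cand:
                trace.steps.append(
                    SCMStep("forward", other.key, od, other.df, op, False)
                )
        trace.steps.append(SCMStep("forward", cand.key, dofv, cand.df, p, accept))
        if not accept:
            break
        working_fit = fit_c
        selected.append(cand)
        remaining = [c for c in remaining if c is not cand]

    # backward elimination over terms added in the forward pass
    eliminable = list(selected)
    while eliminable:
        results = []
        for cand in eliminable:
            spec_r = working_fit.params.spec.copy()
            spec_r.terms = [t for t in spec_r.terms if t.key != cand.key]
            try:
                fit_r = _fit(enc, spec_r, working_fit.params, fit_kwargs)
            except (RuntimeError, np.linalg.LinAlgError, ValueError) as exc:
                log.warning("elimination of %s skipped: %s", cand.key, exc)
                continue
            if not fit_r.converged:
                continue
            dofv = fit_r.ofv - working_fit.ofv  # loss when removing
            keep, p = lrt_decision(dofv, cand.df, backward_alpha)
            results.append((cand, fit_r, dofv, p, keep))
        if not results:
            break
        # least significant first: smallest loss in OFV
        results.sort(key=lambda r: (r[2], r[0].parameter, r[0].covariate))
        cand, fit_r, dofv, p, keep = results[0]
        trace.steps.append(
            SCMStep("backward", cand.key, dofv, cand.df, p, not keep)
        )
        if keep:  # p < backward_alpha for the weakest term: stop
            break
        working_fit = fit_r
        eliminable = [c for c in eliminable if c is not cand]

    final_fit = _fit(enc, working_fit.params.spec, working_fit.params, fit_kwargs,
                     compute_se=True)
    trace.final_spec = final_fit.params.spec
    trace.final_fit = final_fit
    cond = final_fit.condition_number
    trace.overparameterized = bool(cond > CONDITION_LIMIT) if cond is not None else None
    return trace


def screen_covariates(
    fit: FitResult, ds: PKDataset, covariates: Sequence[str]
) -> pd.DataFrame:
    """Empirical-Bayes screening report: eta vs covariate association.

    Continuous covariates get a Pearson correlation with each eta; binary /
    few-level covariates a one-way ANOVA F-test.  This automates the usual
    visual triage; the SCM candidate list remains user-supplied.
    """
    covs = ds.subject_covariates().set_index("ID").loc[fit.eta["ID"]]
    rows = []
    for p in fit.iiv_on:
        eta = fit.eta[f"eta_{p}"].to_numpy()
        for c in covariates:
            x = covs[c].to_numpy(dtype=float)
            levels = np.unique(x)
            if len(levels) <= min(6, max(2, len(x) // 10)):
                groups = [eta[x == lv] for lv in levels if (x == lv).sum() > 1]
                if len(groups) < 2:
                    continue
                f_stat, pval = stats.f_oneway(*groups)
                rows.append(
                    {"eta": p, "covariate": c, "test": "anova",
                     "statistic": float(f_stat), "p_value": float(pval)}
                )
            else:
                r, pval = stats.pearsonr(x, eta)
                rows.append(
                    {"eta": p, "covariate": c, "test": "pearson",
                     "statistic": float(r), "p_value": float(pval)}
                )
    return pd.DataFrame(rows)
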