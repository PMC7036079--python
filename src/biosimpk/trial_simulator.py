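"""Synthetic-trial generator for a weight-normalized IV-infusion mAb study.

Emulates a two-arm (reference vs test drug product, 1:1) design: 15 mg/kg
every 21 days for a configurable number of cycles, infusion shortened from
90 to 60 to 30 min over the first three cycles, pre-dose trough samples at
every cycle, post-infusion samples 1 h after the end of the infusion at
cycles 1 and 5, and an end-of-treatment sample.  Observations follow the
log-additive residual model ln Y = ln F + W * eps with per-subject
log-normal random effects on CL and V1.

A master seed spawns one independent substream per subject, so a subject's
record does not depend on how many other subjects are simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset_io import MANDATORY_COLUMNS, PKDataset
from .nlme_engine import PopulationParameters
from .pk_model import (
    SEX_CODES,
    PRODUCT_CODES,
    CovariateModelSpec,
    CovariateTerm,
    CovariateVector,
    DoseEvent,
    StructuralParams,
    concentration,
    individual_params,
    typical_values,
)

__all__ = [
    "TrialDesign",
    "CovariateDistribution",
    "SubjectRecord",
    "sample_population",
    "simulate_subject",
    "simulate_trial",
    "apply_lloq_censoring",
    "default_population",
    "default_covariate_spec",
]

HOURS_PER_CYCLE = 504.0  # 21 days


@dataclass(frozen=True)
class TrialDesign:
    """Dosing and sampling plan shared by all simulated subjects."""

    n_subjects: int = 100
    n_cycles: int = 16  # combination cycles followed by monotherapy, total cap
    cycle_hours: float = HOURS_PER_CYCLE
    dose_mg_per_kg: float = 15.0
    #: infusion duration by cycle; the last entry repeats for later cycles
    infusion_hours: tuple[float, ...] = (1.5, 1.0, 0.5)
    #: cycles with an extra sample ``peak_offset_h`` after the end of infusion
    peak_sample_cycles: tuple[int, ...] = (1, 5)
    peak_offset_h: float = 1.0
    #: half-width of the optional uniform jitter on post-infusion samples (h);
    #: 0 keeps deterministic nominal times
    peak_jitter_h: float = 0.0
    eot_offset_h: float = HOURS_PER_CYCLE  # EOT sample after the last dose
    lloq: float = 0.25  # mg/L (250 ng/mL)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if self.lloq <= 0:
            raise ValueError("LLOQ must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    def infusion_duration(self, cycle: int) -> float:
        """Infusion duration (h) for 1-based ``cycle``."""
        idx = min(cycle - 1, len(self.infusion_hours) - 1)
        return self.infusion_hours[idx]


@dataclass(frozen=True)
class CovariateDistribution:
    """Samplers for baseline covariates.

    Body weight is log-normal around ``weight_median`` (log-SD
    ``weight_log_sd``), truncated by resampling to ``weight_range``.
    ``extras`` maps covariate names to (median, low, high) tuples sampled
    the same way.  ``n_null`` appends permutation-style null covariates
    (standard normal, independent of PK) for covariate-screening tests.
    """

    weight_median: float = 71.0
    weight_log_sd: float = 0.2
    weight_range: tuple[float, float] = (28.0, 135.0)
    male_fraction: float = 0.648
    test_product_fraction: float = 0.5
    extras: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    n_null: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.male_fraction <= 1):
            raise ValueError("male_fraction must be in [0, 1]")
        if not (0 <= self.test_product_fraction <= 1):
            raise ValueError("test_product_fraction must be in [0, 1]")
        if self.weight_log_sd < 0 or self.weight_median <= 0:
            raise ValueError("invalid body-weight sampler parameters")
        lo, hi = self.weight_range
        if not (0 < lo <= self.weight_median <= hi):
            raise ValueError("weight_range must bracket the median")


def _truncated_lognormal(
    rng: np.random.Generator, median: float, log_sd: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        x = median * math.exp(rng.normal(0.0, log_sd))
        if lo <= x <= hi:
            return x
    return float(np.clip(x, lo, hi))


def sample_population(
    dist: CovariateDistribution, n: int, seed: int
) -> list[CovariateVector]:
    """Draw ``n`` baseline covariate vectors, reproducibly by ``seed``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    out: list[CovariateVector] = []
    for child in np.random.SeedSequence(seed).spawn(n):
        rng = np.random.default_rng(child)
        bwt = _truncated_lognormal(
            rng, dist.weight_median, dist.weight_log_sd, *dist.weight_range
        )
        sex = "M" if rng.random() < dist.male_fraction else "F"
        product = "test" if rng.random() < dist.test_product_fraction else "reference"
        extras: dict[str, float] = {}
        for name, (median, lo, hi) in dist.extras.items():
            log_sd = 0.25 if median <= 0 else min(
                0.5, abs(math.log(max(hi, median) / median)) / 3.0
            )
            extras[name] = _truncated_lognormal(rng, median, log_sd, lo, hi)
        for j in range(dist.n_null):
            extras[f"NULL{j + 1}"] = rng.normal()
        out.append(CovariateVector(bwt=bwt, sex=sex, product=product, extras=extras))
    return out


@dataclass
class SubjectRecord:
    """One subject's covariates, regimen and (possibly noisy) observations."""

    subject_id: int
    cov: CovariateVector
    doses: list[DoseEvent]
    obs_times: np.ndarray
    obs_nominal: np.ndarray
    obs_values: np.ndarray  # mg/L; 0 marks an unquantifiable pre-dose sample
    obs_cycles: np.ndarray
    obs_tags: list[str]
    blq: np.ndarray | None = None  # filled by apply_lloq_censoring

    def n_obs(self) -> int:
        return len(self.obs_times)


def _regimen(cov: CovariateVector, design: TrialDesign) -> list[DoseEvent]:
    amount = design.dose_mg_per_kg * cov.bwt  # baseline weight, fixed across cycles
    return [
        DoseEvent(
            start=(c - 1) * design.cycle_hours,
            amount=amount,
            duration=design.infusion_duration(c),
        )
        for c in range(1, design.n_cycles + 1)
    ]


def _sampling_plan(
    design: TrialDesign, rng: np.random.Generator | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    times, nominal, cycles, tags = [], [], [], []
    for c in range(1, design.n_cycles + 1):
        start = (c - 1) * design.cycle_hours
        times.append(start)
        nominal.append(start)
        cycles.append(c)
        tags.append(f"C{c}_trough")
        if c in design.peak_sample_cycles:
            t_nom = start + design.infusion_duration(c) + design.peak_offset_h
            t = t_nom
            if rng is not None and design.peak_jitter_h > 0:
                t = t_nom + rng.uniform(-design.peak_jitter_h, design.peak_jitter_h)
            times.append(t)
            nominal.append(t_nom)
            cycles.append(c)
            tags.append(f"C{c}_peak")
    t_eot = (design.n_cycles - 1) * design.cycle_hours + design.eot_offset_h
    times.append(t_eot)
    nominal.append(t_eot)
    cycles.append(design.n_cycles)
    tags.append("EOT")
    return (
        np.array(times), np.array(nominal), np.array(cycles, dtype=int), tags
    )


def simulate_subject(
    cov: CovariateVector,
    design: TrialDesign,
    pop: PopulationParameters,
    spec: CovariateModelSpec | None = None,
    seed: int | np.random.SeedSequence = 0,
    subject_id: int = 1,
) -> SubjectRecord:
    """Simulate one subject under the design and observation model.

    Draws eta once per subject from the diagonal Omega, builds the
    weight-normalized regimen, evaluates noise-free concentrations and
    applies ln Y = ln F + W * eps with independent eps per sample.
    """
    spec = spec if spec is not None else pop.spec
    rng = np.random.default_rng(seed)
    eta = {
        p: rng.normal(0.0, math.sqrt(om2)) if om2 > 0 else 0.0
        for p, om2 in pop.omega2.items()
    }
    tvp = typical_values(pop.typicals, spec, cov)
    ip = individual_params(tvp, eta)
    doses = _regimen(cov, design)
    times, nominal, cycles, tags = _sampling_plan(
        design, rng if design.peak_jitter_h > 0 else None
    )
    f = concentration(times, doses, ip.structural())
    values = np.zeros_like(f)
    pos = f > 0
    eps = rng.standard_normal(len(times))
    values[pos] = np.exp(np.log(f[pos]) + pop.w * eps[pos])
    return SubjectRecord(
        subject_id=subject_id,
        cov=cov,
        doses=doses,
        obs_times=times,
        obs_nominal=nominal,
        obs_values=values,
        obs_cycles=cycles,
        obs_tags=tags,
    )


def apply_lloq_censoring(rec: SubjectRecord, lloq: float) -> SubjectRecord:
    """Flag observations strictly below ``lloq``; values are kept for audit."""
    if lloq <= 0:
        raise ValueError("lloq must be positive")
    rec.blq = rec.obs_values < lloq
    return rec


def _record_rows(rec: SubjectRecord, design: TrialDesign) -> pd.DataFrame:
    if rec.blq is None:
        apply_lloq_censoring(rec, design.lloq)
    rows = []
    cov_cols = {
        "BWT": rec.cov.bwt,
        "SEX": SEX_CODES[rec.cov.sex],
        "PROD": PRODUCT_CODES[rec.cov.product],
        **rec.cov.extras,
    }
    events = [
        (d.start, 1, {"AMT": d.amount, "RATE": d.rate, "DV": 0.0, "MDV": 1,
                      "BLQ": 0, "NTIM": d.start, "CYCLE": c + 1, "TAG": f"C{c + 1}_dose"})
        for c, d in enumerate(rec.doses)
    ]
    for j in range(rec.n_obs()):
        blq = bool(rec.blq[j])
        events.append(
            (rec.obs_times[j], 0, {
                "AMT": 0.0, "RATE": 0.0,
                "DV": float(rec.obs_values[j]),
                # a zero value (pre-first-dose) carries no usable DV
                "MDV": 1 if rec.obs_values[j] <= 0 else 0,
                "BLQ": 1 if blq else 0,
                "NTIM": float(rec.obs_nominal[j]),
                "CYCLE": int(rec.obs_cycles[j]),
                "TAG": rec.obs_tags[j],
            })
        )
    # stable order: by time, observations before doses at the same time
    events.sort(key=lambda e: (e[0], e[1]))
    for t, evid, payload in events:
        rows.append({"ID": rec.subject_id, "TIME": t, "EVID": evid,
                     **payload, **cov_cols})
    return pd.DataFrame(rows)


def simulate_trial(
    design: TrialDesign,
    dist: CovariateDistribution,
    pop: PopulationParameters,
    spec: CovariateModelSpec | None = None,
    seed: int | None = None,
) -> PKDataset:
    """Simulate a full trial into a rectangular event dataset.

    The master seed (``seed`` or ``design.seed``) drives covariate sampling
    and spawns one substream per subject.
    """
    master = design.seed if seed is None else seed
    root = np.random.SeedSequence(master)
    cov_seed, subj_root = root.spawn(2)
    covs = sample_population(dist, design.n_subjects, seed=int(cov_seed.generate_state(1)[0]))
    frames = []
    for i, (cov, sub_seq) in enumerate(zip(covs, subj_root.spawn(design.n_subjects))):
        rec = simulate_subject(
            cov, design, pop, spec, seed=sub_seq, subject_id=i + 1
        )
        apply_lloq_censoring(rec, design.lloq)
        frames.append(_record_rows(rec, design))
    if not frames:
        df = pd.DataFrame(columns=MANDATORY_COLUMNS + ["BWT", "SEX", "PROD"])
        return PKDataset(df)
    df = pd.concat(frames, ignore_index=True)
    cols = MANDATORY_COLUMNS + [c for c in df.columns if c not in MANDATORY_COLUMNS]
    return PKDataset(df[cols])


# ---------------------------------------------------------------------------
# bundled reference parameterization (simulation truth for recovery tests)
# ---------------------------------------------------------------------------

def default_covariate_spec(
    weight_median: float = 71.0, include_product: bool = True
) -> CovariateModelSpec:
    """Covariate structure of the bundled reference model:
    body-weight power and sex shift on CL and V1, plus an optional
    drug-product ratio term on each."""
    terms = [
        CovariateTerm("CL", "BWT", "power", 0.354, weight_median),
        CovariateTerm("V1", "BWT", "power", 0.468, weight_median),
        CovariateTerm("CL", "SEX", "fractional", {1: 0.262}, 0),
        CovariateTerm("V1", "SEX", "fractional", {1: 0.247}, 0),
    ]
    if include_product:
        terms += [
            CovariateTerm("CL", "PROD", "ratio", 1.02, 0),
            CovariateTerm("V1", "PROD", "ratio", 1.07, 0),
        ]
    return CovariateModelSpec(terms)


def default_population(include_product: bool = True) -> PopulationParameters:
    """Bundled reference population estimates for an IgG-class mAb.

    Typical values refer to a 71-kg female on the reference product; used
    as the default simulation truth throughout the package.
    """
    return PopulationParameters(
        typicals=StructuralParams(cl=0.0113, v1=2.99, q=0.269, v2=6.09),
        spec=default_covariate_spec(include_product=include_product),
        omega2={"CL": 0.0871, "V1": 0.117},
        w=0.284,
    )
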