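"""Synthetic patient cohorts.

Two generators:

``fixture_cohort``
    A deterministic 249-record cohort whose covariate-pattern counts are
    consistent with the published reclassification table of the source
    study (30 events / 212 non-events among 242 complete records, plus
    1 record missing a clinical variable and 6 missing CRP, all
    non-events). Running the published equations and the default 2.5%/20%
    strata over it reproduces the published table cell-for-cell. Individual
    patient rows are synthetic reconstructions, not real patients.

``simulate_cohort``
    A seeded stochastic generator: independent Bernoulli symptom
    indicators, outcomes drawn from a configurable logistic equation, and
    log-normal biomarkers with outcome-conditional location shifts. The
    biomarker effect sizes are generator conventions chosen for testing
    (ordered CRP > PCT > MR-proADM), not estimates from any real cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
from scipy import stats
from scipy.special import logit

from .cohort import Cohort
from .logistic import LogisticEquation, published_crp_model

# Deterministic filler values for fields that do not enter the published
# equations; chosen as round typical primary-care values (cohort medians:
# age 56, CRB-65 0).
_FILLER = dict(
    age_years=56,
    current_smoker=0,
    confusion_new_onset=0,
    respiratory_rate_per_min=18.0,
    systolic_bp_mmHg=120.0,
    diastolic_bp_mmHg=80.0,
    oxygen_saturation_pct=97.0,
)

_CRP_LOW = 10.0   # a CRP clearly below the 30 mg/l model cutoff
_CRP_HIGH = 80.0  # clearly above it

#: (runny_nose_absent, feels_ill) patterns whose risk stratum is
#: intermediate under BOTH published equations regardless of direction of
#: the move -- i.e. "stayer" patterns, with their CRP>30 indicator.
_STAYER_PATTERNS = ((1, 0, 0), (1, 0, 1), (0, 1, 0))


def _rows(n: int, **fields) -> list[dict]:
    return [dict(_FILLER, **fields) for _ in range(n)]


def _fixture_rows() -> list[dict]:
    rows: list[dict] = []
    # clinical low stratum: runny nose present, does not feel ill
    rows += _rows(49, runny_nose_absent=0, feels_ill=0, crp_mg_per_l=_CRP_LOW,
                  consolidation=0)
    rows += _rows(2, runny_nose_absent=0, feels_ill=0, crp_mg_per_l=_CRP_HIGH,
                  consolidation=0)
    # clinical intermediate stratum
    rows += _rows(8, runny_nose_absent=1, feels_ill=0, crp_mg_per_l=_CRP_LOW,
                  consolidation=1)           # event stayers
    rows += _rows(8, runny_nose_absent=0, feels_ill=1, crp_mg_per_l=_CRP_HIGH,
                  consolidation=1)           # event up-movers
    rows += _rows(115, runny_nose_absent=1, feels_ill=0, crp_mg_per_l=_CRP_LOW,
                  consolidation=0)           # non-event stayers
    rows += _rows(15, runny_nose_absent=0, feels_ill=1, crp_mg_per_l=_CRP_HIGH,
                  consolidation=0)           # non-event up-movers
    # clinical high stratum: runny nose absent and feels ill
    rows += _rows(14, runny_nose_absent=1, feels_ill=1, crp_mg_per_l=_CRP_LOW,
                  consolidation=1)
    rows += _rows(31, runny_nose_absent=1, feels_ill=1, crp_mg_per_l=_CRP_LOW,
                  consolidation=0)
    # excluded records: 1 missing a clinical variable, 6 missing CRP
    rows += _rows(1, runny_nose_absent=1, crp_mg_per_l=_CRP_LOW,
                  consolidation=0)           # feels_ill missing
    rows += _rows(6, runny_nose_absent=1, feels_ill=0, consolidation=0)
    return rows


def fixture_cohort() -> Cohort:
    """The deterministic 249-record reconstruction cohort (30 events)."""
    rows = _fixture_rows()
    for i, r in enumerate(rows):
        r["patient_id"] = f"P{i + 1:03d}"
    return Cohort.from_records(rows, provenance="fixture")


def randomized_consistent_fixture(seed: int) -> Cohort:
    """A random cohort satisfying the same reclassification constraints.

    The published table under-determines patient-level data: "stayer"
    patients in the intermediate stratum may occupy any of three covariate
    patterns, high-stratum patients' CRP indicator is unconstrained, and
    the seven excluded records' observed fields are free. This generator
    resolves those degrees of freedom uniformly at random; every seed
    yields the identical reclassification table, strata prevalences and
    reclassification statistics.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    rows += _rows(49, runny_nose_absent=0, feels_ill=0, crp_mg_per_l=_CRP_LOW,
                  consolidation=0)
    rows += _rows(2, runny_nose_absent=0, feels_ill=0, crp_mg_per_l=_CRP_HIGH,
                  consolidation=0)
    for outcome, count in ((1, 8), (0, 115)):   # intermediate stayers
        for _ in range(count):
            r, i, c = _STAYER_PATTERNS[rng.integers(len(_STAYER_PATTERNS))]
            rows += _rows(1, runny_nose_absent=r, feels_ill=i,
                          crp_mg_per_l=_CRP_HIGH if c else _CRP_LOW,
                          consolidation=outcome)
    rows += _rows(8, runny_nose_absent=0, feels_ill=1, crp_mg_per_l=_CRP_HIGH,
                  consolidation=1)
    rows += _rows(15, runny_nose_absent=0, feels_ill=1, crp_mg_per_l=_CRP_HIGH,
                  consolidation=0)
    for outcome, count in ((1, 14), (0, 31)):   # high stratum, CRP free
        for _ in range(count):
            c = int(rng.integers(2))
            rows += _rows(1, runny_nose_absent=1, feels_ill=1,
                          crp_mg_per_l=_CRP_HIGH if c else _CRP_LOW,
                          consolidation=outcome)
    # excluded records: observed fields unconstrained
    rows += _rows(1, runny_nose_absent=int(rng.integers(2)),
                  crp_mg_per_l=_CRP_HIGH if rng.integers(2) else _CRP_LOW,
                  consolidation=0)
    for _ in range(6):
        rows += _rows(1, runny_nose_absent=int(rng.integers(2)),
                      feels_ill=int(rng.integers(2)), consolidation=0)
    for i, r in enumerate(rows):
        r["patient_id"] = f"P{i + 1:03d}"
    return Cohort.from_records(rows, provenance="synthetic")


@dataclass
class SyntheticCohortSpec:
    """Distributional parameters for the stochastic cohort generator.

    Symptom prevalences default to the fixture cohort's margins
    (runny nose absent 168/242 ~ 0.69; feels ill 68/242 ~ 0.28).
    ``p_crp_gt_30`` may be a scalar or a mapping from the
    (runny_nose_absent, feels_ill) pattern to a probability.
    Biomarker values are log-normal; ``*_log_mu`` gives the log-scale
    location for (non-event, event) and ``*_log_sigma`` the log-scale SD,
    so the standardized outcome effect is (mu1 - mu0)/sigma. Defaults
    order the effects CRP (1.2) > PCT (0.7) > MR-proADM (0.35); they are
    testing conventions, not estimates.
    """

    n: int = 1000
    seed: int = 0
    p_runny_absent: float = 0.69
    p_feels_ill: float = 0.28
    p_crp_gt_30: Union[float, Mapping[tuple[int, int], float]] = 0.25
    model: LogisticEquation = field(default_factory=published_crp_model)
    crp_log_mu: tuple[float, float] = (2.8, 4.0)
    crp_log_sigma: float = 1.0
    pct_log_mu: tuple[float, float] = (-1.6, -0.9)
    pct_log_sigma: float = 1.0
    mr_proadm_log_mu: tuple[float, float] = (-0.60, -0.25)
    mr_proadm_log_sigma: float = 1.0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be at least 1")
        probs = [self.p_runny_absent, self.p_feels_ill]
        if isinstance(self.p_crp_gt_30, Mapping):
            probs += list(self.p_crp_gt_30.values())
        else:
            probs.append(float(self.p_crp_gt_30))
        for p in probs:
            if not (0.0 <= float(p) <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        for s in (self.crp_log_sigma, self.pct_log_sigma,
                  self.mr_proadm_log_sigma):
            if not s > 0:
                raise ValueError("log-scale sigmas must be positive")


def _truncated_lognormal(
    rng: np.random.Generator,
    mu: np.ndarray,
    sigma: float,
    above: Optional[np.ndarray],
    threshold: float,
) -> np.ndarray:
    """Log-normal draws constrained to be >threshold (above=1) or <=threshold.

    Inverse-CDF sampling on the log scale keeps this exact and vectorised.
    """
    log_t = math.log(threshold)
    a = (log_t - mu) / sigma
    u = rng.uniform(size=len(mu))
    cdf_t = stats.norm.cdf(a)
    q = np.where(above == 1, cdf_t + u * (1.0 - cdf_t), u * cdf_t)
    q = np.clip(q, 1e-12, 1.0 - 1e-12)
    return np.exp(mu + sigma * stats.norm.ppf(q))


def simulate_cohort(spec: SyntheticCohortSpec) -> Cohort:
    """Draw a seeded stochastic cohort from ``spec``'s generative model."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    runny = (rng.uniform(size=n) < spec.p_runny_absent).astype(int)
    ill = (rng.uniform(size=n) < spec.p_feels_ill).astype(int)
    if isinstance(spec.p_crp_gt_30, Mapping):
        p_crp = np.array(
            [spec.p_crp_gt_30[(r, i)] for r, i in zip(runny, ill)], dtype=float
        )
    else:
        p_crp = np.full(n, float(spec.p_crp_gt_30))
    crp_ind = (rng.uniform(size=n) < p_crp).astype(int)

    lp = np.full(n, spec.model.intercept)
    cov = {"runny_nose_absent": runny, "feels_ill": ill, "crp_gt_30": crp_ind}
    for name, coef in spec.model.terms:
        if name not in cov:
            raise ValueError(
                f"generative model term {name!r} is not simulated"
            )
        lp += coef * cov[name]
    p_outcome = 1.0 / (1.0 + np.exp(-lp))
    outcome = (rng.uniform(size=n) < p_outcome).astype(int)

    crp_mu = np.where(outcome == 1, spec.crp_log_mu[1], spec.crp_log_mu[0])
    crp = _truncated_lognormal(rng, crp_mu, spec.crp_log_sigma, crp_ind, 30.0)
    crp = np.round(crp, 2)
    # rounding must not cross the 30 mg/l boundary the indicator encodes
    crp = np.where((crp_ind == 1) & (crp <= 30.0), 30.01, crp)
    pct_mu = np.where(outcome == 1, spec.pct_log_mu[1], spec.pct_log_mu[0])
    pct = np.exp(pct_mu + spec.pct_log_sigma * rng.standard_normal(n))
    mr_mu = np.where(
        outcome == 1, spec.mr_proadm_log_mu[1], spec.mr_proadm_log_mu[0]
    )
    mr = np.exp(mr_mu + spec.mr_proadm_log_sigma * rng.standard_normal(n))

    age = np.clip(np.round(rng.normal(56, 15, size=n)), 18, 95).astype(int)
    rr = np.clip(np.round(rng.normal(18, 3, size=n), 1), 8, 60)
    sbp = np.clip(np.round(rng.normal(125, 15, size=n), 0), 80, 220)
    dbp = np.clip(sbp - np.round(np.abs(rng.normal(45, 8, size=n))) - 1, 40, None)
    sat = np.clip(np.round(rng.normal(97, 1.5, size=n), 0), 50, 100)
    confusion = (rng.uniform(size=n) < 0.02).astype(int)
    smoker = (rng.uniform(size=n) < 0.30).astype(int)

    rows = [
        dict(
            patient_id=f"S{i + 1:06d}",
            age_years=int(age[i]),
            runny_nose_absent=int(runny[i]),
            feels_ill=int(ill[i]),
            current_smoker=int(smoker[i]),
            confusion_new_onset=int(confusion[i]),
            respiratory_rate_per_min=float(rr[i]),
            systolic_bp_mmHg=float(sbp[i]),
            diastolic_bp_mmHg=float(dbp[i]),
            oxygen_saturation_pct=float(sat[i]),
            crp_mg_per_l=float(crp[i]),
            pct=float(np.round(pct[i], 4)),
            mr_proadm_nmol_per_l=float(np.round(mr[i], 4)),
            consolidation=int(outcome[i]),
        )
        for i in range(n)
    ]
    return Cohort.from_records(rows, provenance="synthetic")


def intercept_for_rate(rate: float) -> float:
    """Intercept of a covariate-free generative model with a given event rate."""
    return float(logit(rate))
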