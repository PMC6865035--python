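"""Logistic prediction equations and maximum-likelihood logistic fitting.

Two published prediction equations for pneumonia (consolidation on chest
X ray) in primary-care patients with an acute respiratory tract infection
are shipped as constants:

* clinical-only:      logit p = -4.492 + 1.142*runny_nose_absent + 2.550*feels_ill
* clinical + CRP:     logit p = -4.797 + 1.230*runny_nose_absent + 2.378*feels_ill
                                + 1.572*(CRP > 30 mg/l)

``CohortLogit`` is the statsmodels-style estimator: build it from a cohort
(or DataFrame), call ``fit()`` and obtain a ``CohortLogitResults`` with
coefficients, Wald standard errors, odds ratios with 95% CIs and a
``summary()`` table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .cohort import Cohort, OUTCOME_FIELD, SCHEMA_COLUMNS, SchemaError
from .scores import biomarker_indicator

Z_95 = 1.96  # Wald normal quantile used for 95% CIs

#: Derived model covariates and the raw cohort field each one needs.
DERIVED_COVARIATES = {"crp_gt_30": "crp_mg_per_l"}


class MissingPredictorError(ValueError):
    """A model term has no (non-missing) covariate value."""


class SeparationError(RuntimeError):
    """The likelihood is monotone (perfect separation); no finite MLE."""


@dataclass(frozen=True)
class LogisticEquation:
    """An intercept plus named term coefficients under the logistic link."""

    label: str
    intercept: float
    terms: tuple[tuple[str, float], ...]

    def __post_init__(self):
        names = [t[0] for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("predictor names must be unique")

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return tuple(t[0] for t in self.terms)

    def coefficient(self, name: str) -> float:
        for n, c in self.terms:
            if n == name:
                return c
        raise KeyError(name)

    def linear_predictor(self, covariates: Mapping[str, float]) -> float:
        lp = self.intercept
        for name, coef in self.terms:
            value = covariates.get(name)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise MissingPredictorError(
                    f"model {self.label!r} requires covariate {name!r}"
                )
            lp += coef * float(value)
        return lp

    def predict(self, covariates: Mapping[str, float]) -> float:
        """Probability 1 / (1 + exp(-(intercept + sum coef*x)))."""
        return float(expit(self.linear_predictor(covariates)))

    def predict_frame(self, X: pd.DataFrame) -> np.ndarray:
        missing = [n for n in self.predictor_names if n not in X.columns]
        if missing:
            raise MissingPredictorError(
                f"model {self.label!r} requires covariates {missing}"
            )
        lp = np.full(len(X), self.intercept, dtype=float)
        for name, coef in self.terms:
            col = X[name].to_numpy(dtype=float)
            if np.isnan(col).any():
                raise MissingPredictorError(
                    f"covariate {name!r} has missing values; "
                    "take a complete-case subset first"
                )
            lp += coef * col
        return expit(lp)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "intercept": self.intercept,
            "terms": [[n, c] for n, c in self.terms],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "LogisticEquation":
        return cls(
            label=str(d["label"]),
            intercept=float(d["intercept"]),
            terms=tuple((str(n), float(c)) for n, c in d["terms"]),
        )

    @classmethod
    def from_json(cls, path) -> "LogisticEquation":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def published_clinical_model() -> LogisticEquation:
    """The published signs-and-symptoms-only pneumonia equation."""
    return LogisticEquation(
        label="clinical",
        intercept=-4.492,
        terms=(("runny_nose_absent", 1.142), ("feels_ill", 2.550)),
    )


def published_crp_model() -> LogisticEquation:
    """The published equation with CRP > 30 mg/l added to signs and symptoms."""
    return LogisticEquation(
        label="clinical_crp",
        intercept=-4.797,
        terms=(
            ("runny_nose_absent", 1.230),
            ("feels_ill", 2.378),
            ("crp_gt_30", 1.572),
        ),
    )


PUBLISHED_MODELS = {
    "clinical": published_clinical_model,
    "clinical_crp": published_crp_model,
}


def get_model(name_or_path: str) -> LogisticEquation:
    """Resolve a model by published name or a JSON file path."""
    if name_or_path in PUBLISHED_MODELS:
        return PUBLISHED_MODELS[name_or_path]()
    return LogisticEquation.from_json(name_or_path)


def predict_probability(
    model: LogisticEquation, covariates: Mapping[str, float]
) -> float:
    """Evaluate a model on one patient's covariates (all terms required)."""
    return model.predict(covariates)


def required_source_fields(predictors: Sequence[str]) -> list[str]:
    """Raw cohort fields needed to evaluate the given predictor names."""
    return [DERIVED_COVARIATES.get(p, p) for p in predictors]


def model_frame(cohort: Cohort, predictors: Sequence[str]) -> pd.DataFrame:
    """Per-patient covariate values for ``predictors`` (NaN where missing).

    Derived covariates (currently ``crp_gt_30``) are computed from their
    source fields; all other names must be cohort columns.
    """
    out = pd.DataFrame(index=cohort.data.index)
    for name in predictors:
        if name == "crp_gt_30":
            crp = cohort.data["crp_mg_per_l"]
            out[name] = pd.array(
                [biomarker_indicator(None if pd.isna(v) else float(v), 30.0)
                 for v in crp],
                dtype="Float64",
            ).astype(float)
        elif name in SCHEMA_COLUMNS:
            out[name] = cohort.data[name].astype("Float64").to_numpy(dtype=float)
        else:
            raise SchemaError(f"unknown predictor {name!r}")
    return out


@dataclass
class CohortLogitResults:
    """MLE results for a cohort logistic regression.

    Odds ratios are exp(coefficient); 95% CIs are Wald intervals
    exp(coef +/- 1.96 se).
    """

    equation: LogisticEquation
    params: pd.Series          # includes "intercept"
    std_errors: pd.Series
    p_values: pd.Series
    log_likelihood: float
    log_likelihood_null: float
    n_used: int
    converged: bool
    outcome: str

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params.drop("intercept"))

    @property
    def or_ci95(self) -> pd.DataFrame:
        coefs = self.params.drop("intercept")
        ses = self.std_errors.drop("intercept")
        return pd.DataFrame(
            {
                "lower": np.exp(coefs - Z_95 * ses),
                "upper": np.exp(coefs + Z_95 * ses),
            }
        )

    @property
    def nagelkerke_r2(self) -> float:
        from .evaluation import nagelkerke_r2

        return nagelkerke_r2(
            self.log_likelihood, self.log_likelihood_null, self.n_used
        )

    def summary(self) -> str:
        ci = self.or_ci95
        lines = [
            f"Logistic regression: {self.outcome} ~ "
            + " + ".join(self.equation.predictor_names),
            f"n = {self.n_used}, log-likelihood = {self.log_likelihood:.3f}, "
            f"Nagelkerke R2 = {self.nagelkerke_r2:.3f}, "
            f"converged = {self.converged}",
            "",
            f"{'term':<22}{'coef':>9}{'se':>8}{'OR':>8}"
            f"{'95% CI':>18}{'p':>8}",
        ]
        lines.append(
            f"{'intercept':<22}{self.params['intercept']:>9.3f}"
            f"{self.std_errors['intercept']:>8.3f}{'':>8}{'':>18}"
            f"{self.p_values['intercept']:>8.3f}"
        )
        for name in self.equation.predictor_names:
            lines.append(
                f"{name:<22}{self.params[name]:>9.3f}"
                f"{self.std_errors[name]:>8.3f}{self.odds_ratios[name]:>8.2f}"
                f"{'(%.2f-%.2f)' % (ci.loc[name, 'lower'], ci.loc[name, 'upper']):>18}"
                f"{self.p_values[name]:>8.3f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        ci = self.or_ci95
        return {
            "model": self.equation.to_dict(),
            "n_used": self.n_used,
            "converged": self.converged,
            "log_likelihood": self.log_likelihood,
            "nagelkerke_r2": self.nagelkerke_r2,
            "terms": {
                name: {
                    "coef": float(self.params[name]),
                    "se": float(self.std_errors[name]),
                    "odds_ratio": float(self.odds_ratios[name]),
                    "or_ci95": [
                        float(ci.loc[name, "lower"]),
                        float(ci.loc[name, "upper"]),
                    ],
                    "p": float(self.p_values[name]),
                }
                for name in self.equation.predictor_names
            },
            "intercept": {
                "coef": float(self.params["intercept"]),
                "se": float(self.std_errors["intercept"]),
                "p": float(self.p_values["intercept"]),
            },
        }


class CohortLogit:
    """Binary logistic regression model for a cohort outcome.

    Parameters
    ----------
    cohort : Cohort
        The patient cohort; rows with a missing outcome or missing
        predictor are dropped (complete-case analysis).
    outcome : str
        Binary outcome field, default ``consolidation``.
    predictors : sequence of str
        Cohort fields or derived covariates (``crp_gt_30``).
    """

    def __init__(
        self,
        cohort: Cohort,
        predictors: Sequence[str],
        outcome: str = OUTCOME_FIELD,
    ):
        if outcome not in SCHEMA_COLUMNS:
            raise SchemaError(f"unknown outcome field {outcome!r}")
        if not predictors:
            raise ValueError("at least one predictor is required")
        self.cohort = cohort
        self.outcome = outcome
        self.predictors = list(predictors)

        X = model_frame(cohort, self.predictors)
        y = cohort.data[outcome].astype("Float64").to_numpy(dtype=float)
        mask = ~np.isnan(y) & ~X.isna().to_numpy().any(axis=1) \
            & ~np.isnan(X.to_numpy(dtype=float)).any(axis=1)
        self.exog = X[mask].to_numpy(dtype=float)
        self.endog = y[mask]
        self.n_used = int(mask.sum())
        self._check_degenerate()

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, predictors: Sequence[str],
        outcome: str = OUTCOME_FIELD, provenance: str = "user",
    ) -> "CohortLogit":
        return cls(Cohort(data, provenance=provenance), predictors, outcome)

    def _check_degenerate(self) -> None:
        if self.n_used == 0:
            raise ValueError("no complete cases for the requested fit")
        n_events = int(self.endog.sum())
        if n_events == 0 or n_events == len(self.endog):
            raise ValueError(
                "outcome has a single class among complete cases "
                f"({n_events} events of {len(self.endog)})"
            )
        for j, name in enumerate(self.predictors):
            col = self.exog[:, j]
            if np.all(col == col[0]):
                raise ValueError(f"predictor {name!r} is constant")

    def fit(self, maxiter: int = 100) -> CohortLogitResults:
        """Maximum-likelihood fit (Newton/IRLS); raises on perfect separation."""
        X = sm.add_constant(self.exog, has_constant="add")
        model = sm.Logit(self.endog, X)
        import warnings as _warnings

        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("error", PerfectSeparationWarning)
                res = model.fit(disp=0, maxiter=maxiter)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(
                "perfect separation detected: a predictor (combination) "
                "splits events from non-events; coefficients diverge"
            ) from exc
        if np.max(np.abs(res.params)) > 15:
            raise SeparationError(
                "coefficient magnitude exceeds 15 on the logit scale; "
                "quasi-separation suspected"
            )
        names = ["intercept"] + self.predictors
        params = pd.Series(res.params, index=names)
        ses = pd.Series(res.bse, index=names)
        pvals = pd.Series(res.pvalues, index=names)
        equation = LogisticEquation(
            label="fitted",
            intercept=float(params["intercept"]),
            terms=tuple((n, float(params[n])) for n in self.predictors),
        )
        return CohortLogitResults(
            equation=equation,
            params=params,
            std_errors=ses,
            p_values=pvals,
            log_likelihood=float(res.llf),
            log_likelihood_null=float(res.llnull),
            n_used=self.n_used,
            converged=bool(res.mle_retvals.get("converged", True)),
            outcome=self.outcome,
        )


def fit_logistic(
    cohort: Cohort,
    outcome: str = OUTCOME_FIELD,
    predictors: Sequence[str] = (),
) -> CohortLogitResults:
    """Convenience wrapper: ``CohortLogit(cohort, predictors, outcome).fit()``."""
    return CohortLogit(cohort, predictors, outcome).fit()


def univariate_or(
    cohort: Cohort, outcome: str, predictor: str
) -> CohortLogitResults:
    """Single-predictor logistic fit; OR equals the 2x2 cross-product ratio."""
    return fit_logistic(cohort, outcome, [predictor])
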