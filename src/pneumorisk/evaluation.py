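"""Discrimination and calibration statistics.

* ROC AUC by threshold sweep with trapezoidal integration — numerically
  identical to the Mann-Whitney concordance probability with half credit
  for ties.
* Hosmer-Lemeshow goodness of fit on deciles of predicted risk.
* Nagelkerke's rescaled pseudo-R-squared.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .cohort import Cohort, OUTCOME_FIELD, complete_case_subset


@dataclass
class RocResult:
    """ROC curve and area for one score against a binary outcome."""

    auc: float
    n_events: int
    n_non_events: int
    roc_points: np.ndarray       # (k, 2) array of (fpr, tpr), (0,0) .. (1,1)
    thresholds: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "fpr": self.roc_points[:, 0],
                "tpr": self.roc_points[:, 1],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def roc_auc(scores: Sequence[float], outcomes: Sequence[int]) -> RocResult:
    """ROC curve and AUC; requires both outcome classes, no missing scores."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and outcomes must have equal length")
    if np.isnan(s).any():
        raise ValueError("scores contain missing values; subset first")
    n_events = int(y.sum())
    n_non = int(len(y) - n_events)
    if n_events == 0 or n_non == 0:
        raise ValueError("both outcome classes are required for a ROC curve")
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(
        auc=auc,
        n_events=n_events,
        n_non_events=n_non,
        roc_points=np.column_stack([fpr, tpr]),
        thresholds=thr,
    )


def plot_roc(result: RocResult, ax=None, label: Optional[str] = None):
    """Optional static ROC plot (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(result.roc_points[:, 0], result.roc_points[:, 1],
            label=label or f"AUC = {result.auc:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    return ax


@dataclass
class CalibrationResult:
    """Hosmer-Lemeshow test (and optionally Nagelkerke R2) for one model."""

    hl_statistic: float
    hl_df: int
    hl_p: float
    n_groups: int
    nagelkerke_r2: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "hl_statistic": self.hl_statistic,
            "hl_df": self.hl_df,
            "hl_p": self.hl_p,
            "n_groups": self.n_groups,
            "nagelkerke_r2": self.nagelkerke_r2,
        }


def hosmer_lemeshow(
    probs: Sequence[float],
    outcomes: Sequence[int],
    n_groups: int = 10,
) -> CalibrationResult:
    """Hosmer-Lemeshow chi-square on groups of predicted risk.

    Groups are equal-size deciles of the sorted predicted probabilities;
    tied probabilities stay in one group, so fewer than ``n_groups``
    groups can result. Degrees of freedom = (actual groups) - 2.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probs and outcomes must have equal length")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("predicted probabilities must lie strictly in (0, 1)")
    if len(p) < n_groups:
        raise ValueError(f"need at least {n_groups} observations")
    # qcut on the values keeps ties together; duplicate bin edges collapse
    bins = pd.qcut(p, q=n_groups, duplicates="drop")
    df = pd.DataFrame({"p": p, "y": y, "g": bins})
    grouped = df.groupby("g", observed=True)
    obs1 = grouped["y"].sum().to_numpy()
    exp1 = grouped["p"].sum().to_numpy()
    n = grouped.size().to_numpy()
    # merge groups whose expected count (either class) vanishes
    keep = (exp1 > 1e-12) & ((n - exp1) > 1e-12)
    if not keep.all():
        warnings.warn(
            "merging risk groups with zero expected count", stacklevel=2
        )
        # fold degenerate groups into the next non-degenerate neighbour
        merged_obs1, merged_exp1, merged_n = [], [], []
        acc = None
        for idx in range(len(n)):
            cur = np.array([obs1[idx], exp1[idx], n[idx]])
            if acc is None:
                acc = cur
            else:
                acc = acc + cur
            if exp1[idx] > 1e-12 and (n[idx] - exp1[idx]) > 1e-12:
                merged_obs1.append(acc[0])
                merged_exp1.append(acc[1])
                merged_n.append(acc[2])
                acc = None
        if acc is not None and merged_n:
            merged_obs1[-1] += acc[0]
            merged_exp1[-1] += acc[1]
            merged_n[-1] += acc[2]
        obs1 = np.asarray(merged_obs1)
        exp1 = np.asarray(merged_exp1)
        n = np.asarray(merged_n)
    obs0 = n - obs1
    exp0 = n - exp1
    statistic = float(
        np.sum((obs1 - exp1) ** 2 / exp1) + np.sum((obs0 - exp0) ** 2 / exp0)
    )
    g = len(n)
    dof = max(g - 2, 1)
    p_value = float(stats.chi2.sf(statistic, dof))
    return CalibrationResult(
        hl_statistic=statistic, hl_df=dof, hl_p=p_value, n_groups=g
    )


def nagelkerke_r2(
    loglik_model: float, loglik_null: float, n: int
) -> float:
    """Nagelkerke's rescaled R2 from model and null log-likelihoods."""
    if n <= 0:
        raise ValueError("n must be positive")
    if loglik_model < loglik_null - 1e-8:
        raise ValueError("model log-likelihood below the null's")
    cox_snell = 1.0 - math.exp(2.0 * (loglik_null - loglik_model) / n)
    max_r2 = 1.0 - math.exp(2.0 * loglik_null / n)
    if max_r2 <= 0:
        return 0.0
    return float(min(max(cox_snell / max_r2, 0.0), 1.0))


@dataclass
class BiomarkerAuc:
    """Discrimination of one biomarker on its complete-case subset."""

    name: str
    auc: float
    n: int
    roc: RocResult


def compare_biomarkers(
    cohort: Cohort,
    biomarkers: Sequence[str] = ("crp_mg_per_l", "pct", "mr_proadm_nmol_per_l"),
    outcome: str = OUTCOME_FIELD,
) -> list[BiomarkerAuc]:
    """Per-biomarker ROC AUC against the outcome, sorted by descending AUC.

    Each biomarker is evaluated on its own complete-case subset (its n is
    reported); biomarkers without usable data are skipped with a warning.
    """
    results: list[BiomarkerAuc] = []
    for name in biomarkers:
        subset = complete_case_subset(cohort, [name, outcome])
        if len(subset) == 0:
            warnings.warn(f"biomarker {name!r} has no complete cases; skipped",
                          stacklevel=2)
            continue
        scores = subset.data[name].to_numpy(dtype=float)
        y = subset.data[outcome].to_numpy(dtype=float).astype(int)
        if y.sum() == 0 or y.sum() == len(y):
            warnings.warn(
                f"biomarker {name!r}: single outcome class among complete "
                "cases; skipped", stacklevel=2)
            continue
        roc = roc_auc(scores, y)
        results.append(BiomarkerAuc(name=name, auc=roc.auc, n=len(subset), roc=roc))
    results.sort(key=lambda r: r.auc, reverse=True)
    return results
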