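"""Three-tier risk stratification and reclassification analysis.

Patients are stratified by predicted pneumonia probability into low
(< 2.5%), intermediate (2.5-20%, closed interval) and high (> 20%) risk
groups; the cut points map onto primary-care management (withhold
antibiotics / test further / treat).

Comparing an old and a new model yields a pair of 3x3 tables (events and
non-events separately). Two summary statistics are computed:

* overall reclassification improvement (ORI) =
  (correctly reclassified - incorrectly reclassified) / all analysed
  patients, where "correct" means any upward move for an event and any
  downward move for a non-event — every patient carries equal weight;
* net reclassification improvement (NRI) =
  (up - down)/n_events + (down - up)/n_non_events, the conventional
  two-group sum, which up-weights the smaller outcome group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, OUTCOME_FIELD, complete_case_subset
from .logistic import LogisticEquation, model_frame, required_source_fields
from ._round import round_half_up


class RiskGroup(IntEnum):
    """Ordered three-level risk stratum."""

    LOW = 0
    INTERMEDIATE = 1
    HIGH = 2

    @property
    def label(self) -> str:
        return self.name.lower()


GROUP_LABELS = tuple(g.label for g in RiskGroup)


@dataclass(frozen=True)
class RiskThresholds:
    """Probability cut points: low < ``low_upper`` <= intermediate <=
    ``high_lower`` < high (boundaries belong to the intermediate group)."""

    low_upper: float = 0.025
    high_lower: float = 0.20

    def __post_init__(self):
        if not (0.0 < self.low_upper < self.high_lower < 1.0):
            raise ValueError(
                "thresholds must satisfy 0 < low_upper < high_lower < 1"
            )


DEFAULT_THRESHOLDS = RiskThresholds()


def assign_risk_group(
    p: float, thresholds: RiskThresholds = DEFAULT_THRESHOLDS
) -> RiskGroup:
    """Map a probability to its risk stratum."""
    p = float(p)
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability must be in [0, 1], got {p}")
    if p < thresholds.low_upper:
        return RiskGroup.LOW
    if p > thresholds.high_lower:
        return RiskGroup.HIGH
    return RiskGroup.INTERMEDIATE


@dataclass
class Stratification:
    """Per-patient risk groups plus per-group outcome counts."""

    model_label: str
    assignments: pd.Series       # RiskGroup per analysed patient (cohort index)
    probabilities: pd.Series
    group_sizes: dict[RiskGroup, int]
    events_per_group: dict[RiskGroup, int]
    n_excluded: int

    @property
    def n_total(self) -> int:
        return int(sum(self.group_sizes.values()))

    @property
    def prevalence(self) -> dict[RiskGroup, Optional[float]]:
        """Observed outcome fraction per group (None for empty groups)."""
        out = {}
        for g in RiskGroup:
            n = self.group_sizes[g]
            out[g] = (self.events_per_group[g] / n) if n else None
        return out

    def to_dict(self) -> dict:
        prev = self.prevalence
        return {
            "model": self.model_label,
            "n_analysed": self.n_total,
            "n_excluded": self.n_excluded,
            "groups": {
                g.label: {
                    "n": self.group_sizes[g],
                    "events": self.events_per_group[g],
                    "prevalence": prev[g],
                    "prevalence_pct": (
                        None if prev[g] is None else round_half_up(100 * prev[g], 1)
                    ),
                }
                for g in RiskGroup
            },
        }


def stratify_cohort(
    cohort: Cohort,
    model: LogisticEquation,
    thresholds: RiskThresholds = DEFAULT_THRESHOLDS,
    extra_complete_fields: Sequence[str] = (),
) -> Stratification:
    """Assign each complete-case patient to a risk group under ``model``.

    Records missing any model covariate (or any ``extra_complete_fields``)
    are excluded and counted in ``n_excluded``.
    """
    required = required_source_fields(model.predictor_names)
    required += [f for f in extra_complete_fields if f not in required]
    required += [OUTCOME_FIELD] if OUTCOME_FIELD not in required else []
    subset = complete_case_subset(cohort, required)
    if len(subset) == 0:
        raise ValueError("no complete cases for the model covariates")
    X = model_frame(subset, model.predictor_names)
    probs = pd.Series(model.predict_frame(X), index=subset.data.index)
    groups = probs.map(lambda p: assign_risk_group(p, thresholds))
    outcomes = subset.data[OUTCOME_FIELD].to_numpy(dtype=float)
    sizes = {g: int((groups == g).sum()) for g in RiskGroup}
    events = {
        g: int(outcomes[(groups == g).to_numpy()].sum()) for g in RiskGroup
    }
    return Stratification(
        model_label=model.label,
        assignments=groups,
        probabilities=probs,
        group_sizes=sizes,
        events_per_group=events,
        n_excluded=len(cohort) - len(subset),
    )


def decisive_fraction(stratification: Stratification) -> float:
    """Fraction of analysed patients in the decision-ready strata (low or high)."""
    n = stratification.n_total
    if n == 0:
        raise ValueError("empty stratification")
    sizes = stratification.group_sizes
    return (sizes[RiskGroup.LOW] + sizes[RiskGroup.HIGH]) / n


@dataclass
class ReclassificationTable:
    """Paired 3x3 count matrices, rows = old-model group, cols = new-model.

    Events and non-events are tabulated separately, mirroring how
    reclassification tables are reported.
    """

    events: np.ndarray
    non_events: np.ndarray

    def __post_init__(self):
        self.events = np.asarray(self.events, dtype=int)
        self.non_events = np.asarray(self.non_events, dtype=int)
        for m in (self.events, self.non_events):
            if m.shape != (3, 3) or (m < 0).any():
                raise ValueError("matrices must be 3x3 with non-negative counts")

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def n_non_events(self) -> int:
        return int(self.non_events.sum())

    @property
    def n_total(self) -> int:
        return self.n_events + self.n_non_events

    def old_group_sizes(self) -> np.ndarray:
        """Marginal counts per old-model stratum (events + non-events)."""
        return self.events.sum(axis=1) + self.non_events.sum(axis=1)

    def new_group_sizes(self) -> np.ndarray:
        return self.events.sum(axis=0) + self.non_events.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, m in (("events", self.events), ("non_events", self.non_events)):
            for i, g in enumerate(GROUP_LABELS):
                rows.append(
                    {"outcome": label, "old_group": g}
                    | {f"new_{h}": int(m[i, j]) for j, h in enumerate(GROUP_LABELS)}
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_reclassification_table(
    old_assignments: Sequence[RiskGroup],
    new_assignments: Sequence[RiskGroup],
    outcomes: Sequence[int],
) -> ReclassificationTable:
    """Cross-tabulate old vs new strata, split by outcome status."""
    old = np.asarray([int(g) for g in old_assignments])
    new = np.asarray([int(g) for g in new_assignments])
    y = np.asarray([int(o) for o in outcomes])
    if not (len(old) == len(new) == len(y)):
        raise ValueError(
            f"length mismatch: old={len(old)}, new={len(new)}, outcomes={len(y)}"
        )
    events = np.zeros((3, 3), dtype=int)
    non_events = np.zeros((3, 3), dtype=int)
    for i, j, o in zip(old, new, y):
        (events if o == 1 else non_events)[i, j] += 1
    return ReclassificationTable(events, non_events)


def _moves(matrix: np.ndarray) -> tuple[int, int]:
    """(up, down) move counts in a 3x3 old-by-new table."""
    up = int(np.triu(matrix, k=1).sum())
    down = int(np.tril(matrix, k=-1).sum())
    return up, down


@dataclass
class ReclassSummary:
    """Signed reclassification statistics (fractions, not percent)."""

    event_improvement: float
    non_event_improvement: float
    overall_improvement: float
    nri: float
    n_up_events: int
    n_down_events: int
    n_up_non_events: int
    n_down_non_events: int
    n_events: int
    n_non_events: int

    def display(self) -> dict[str, str]:
        """Percent strings rounded half-up to one decimal (report style)."""
        return {
            "event_improvement": f"{round_half_up(100 * self.event_improvement, 1):.1f}%",
            "non_event_improvement": f"{round_half_up(100 * self.non_event_improvement, 1):.1f}%",
            "overall_improvement": f"{round_half_up(100 * self.overall_improvement, 1):.1f}%",
            "nri": f"{round_half_up(100 * self.nri, 1):.1f}%",
        }

    def to_dict(self) -> dict:
        return {
            "event_improvement": self.event_improvement,
            "non_event_improvement": self.non_event_improvement,
            "overall_improvement": self.overall_improvement,
            "nri": self.nri,
            "n_up_events": self.n_up_events,
            "n_down_events": self.n_down_events,
            "n_up_non_events": self.n_up_non_events,
            "n_down_non_events": self.n_down_non_events,
            "n_events": self.n_events,
            "n_non_events": self.n_non_events,
            "display": self.display(),
        }


def overall_reclassification_improvement(
    table: ReclassificationTable,
) -> ReclassSummary:
    """ORI and NRI from a reclassification table.

    Upward moves count as correct for events, downward moves as correct
    for non-events; every move (including single-step moves through the
    intermediate group) counts.
    """
    if table.n_events == 0:
        raise ZeroDivisionError("no events: event improvement undefined")
    if table.n_non_events == 0:
        raise ZeroDivisionError("no non-events: non-event improvement undefined")
    up_e, down_e = _moves(table.events)
    up_ne, down_ne = _moves(table.non_events)
    event_improvement = (up_e - down_e) / table.n_events
    non_event_improvement = (down_ne - up_ne) / table.n_non_events
    overall = (up_e - down_e + down_ne - up_ne) / table.n_total
    return ReclassSummary(
        event_improvement=event_improvement,
        non_event_improvement=non_event_improvement,
        overall_improvement=overall,
        nri=event_improvement + non_event_improvement,
        n_up_events=up_e,
        n_down_events=down_e,
        n_up_non_events=up_ne,
        n_down_non_events=down_ne,
        n_events=table.n_events,
        n_non_events=table.n_non_events,
    )


@dataclass
class IntermediateUpclassification:
    """Patients moving intermediate -> high when the new model is adopted."""

    n_moved: int
    n_events_moved: int
    event_fraction: Optional[float]   # None when nobody moved
    n_intermediate_old: int
    moved_share: Optional[float]      # of the old intermediate group
    n_moved_to_low: int

    def to_dict(self) -> dict:
        return {
            "n_moved_to_high": self.n_moved,
            "events_among_moved": self.n_events_moved,
            "event_fraction": self.event_fraction,
            "n_intermediate_old": self.n_intermediate_old,
            "moved_share": self.moved_share,
            "n_moved_to_low": self.n_moved_to_low,
        }


def upclassified_intermediate_summary(
    table: ReclassificationTable,
) -> IntermediateUpclassification:
    """Summarise intermediate-to-high moves (the clinically decisive shift)."""
    i, h, lo = RiskGroup.INTERMEDIATE, RiskGroup.HIGH, RiskGroup.LOW
    moved_events = int(table.events[i, h])
    moved_non = int(table.non_events[i, h])
    moved = moved_events + moved_non
    n_int = int(table.events[i, :].sum() + table.non_events[i, :].sum())
    return IntermediateUpclassification(
        n_moved=moved,
        n_events_moved=moved_events,
        event_fraction=(moved_events / moved) if moved else None,
        n_intermediate_old=n_int,
        moved_share=(moved / n_int) if n_int else None,
        n_moved_to_low=int(table.events[i, lo] + table.non_events[i, lo]),
    )


@dataclass
class ReclassificationResults:
    """Full results of comparing two prediction models on one cohort."""

    old_stratification: Stratification
    new_stratification: Stratification
    table: ReclassificationTable
    reclass: ReclassSummary
    upclassified: IntermediateUpclassification
    n_analysed: int
    n_excluded: int
    exclusions: dict

    @property
    def decisive_fraction_new(self) -> float:
        return decisive_fraction(self.new_stratification)

    @property
    def decisive_fraction_old(self) -> float:
        return decisive_fraction(self.old_stratification)

    def summary(self) -> str:
        d = self.reclass.display()
        old_l, new_l = (
            self.old_stratification.model_label,
            self.new_stratification.model_label,
        )
        lines = [
            f"Reclassification analysis: {old_l} -> {new_l}",
            f"analysed n = {self.n_analysed} "
            f"({self.reclass.n_events} events, {self.reclass.n_non_events} "
            f"non-events); excluded = {self.n_excluded}",
            "",
            "events (rows = old stratum, cols = new stratum):",
        ]
        for i, g in enumerate(GROUP_LABELS):
            lines.append(f"  {g:<13}" + "".join(
                f"{int(self.table.events[i, j]):>6}" for j in range(3)))
        lines.append("non-events:")
        for i, g in enumerate(GROUP_LABELS):
            lines.append(f"  {g:<13}" + "".join(
                f"{int(self.table.non_events[i, j]):>6}" for j in range(3)))
        lines += [
            "",
            f"event reclassification improvement     : {d['event_improvement']}",
            f"non-event reclassification improvement : {d['non_event_improvement']}",
            f"overall reclassification improvement   : {d['overall_improvement']}",
            f"net reclassification improvement (NRI) : {d['nri']}",
            f"intermediate -> high: {self.upclassified.n_moved} patients "
            f"({self.upclassified.n_events_moved} with the outcome)",
            f"decisive fraction (low or high, new model): "
            f"{round_half_up(100 * self.decisive_fraction_new):.0f}%",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "old_model": self.old_stratification.to_dict(),
            "new_model": self.new_stratification.to_dict(),
            "table": {
                "events": self.table.events.tolist(),
                "non_events": self.table.non_events.tolist(),
            },
            "reclassification": self.reclass.to_dict(),
            "intermediate_upclassification": self.upclassified.to_dict(),
            "decisive_fraction_new": self.decisive_fraction_new,
            "decisive_fraction_old": self.decisive_fraction_old,
            "n_analysed": self.n_analysed,
            "n_excluded": self.n_excluded,
            "exclusions": self.exclusions,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


class ReclassificationAnalysis:
    """Compare risk stratification under an old and a new prediction model.

    Both models are evaluated on the patients with complete data for the
    UNION of the two models' covariates, so old- and new-model strata
    describe the same analysed population.
    """

    def __init__(
        self,
        cohort: Cohort,
        old_model: LogisticEquation,
        new_model: LogisticEquation,
        thresholds: RiskThresholds = DEFAULT_THRESHOLDS,
    ):
        self.cohort = cohort
        self.old_model = old_model
        self.new_model = new_model
        self.thresholds = thresholds

    def fit(self) -> ReclassificationResults:
        required = required_source_fields(
            list(self.old_model.predictor_names)
        )
        for f in required_source_fields(list(self.new_model.predictor_names)):
            if f not in required:
                required.append(f)
        if OUTCOME_FIELD not in required:
            required.append(OUTCOME_FIELD)
        subset = complete_case_subset(self.cohort, required)
        if len(subset) == 0:
            raise ValueError("no complete cases for the two models' covariates")
        old = stratify_cohort(subset, self.old_model, self.thresholds)
        new = stratify_cohort(subset, self.new_model, self.thresholds)
        outcomes = subset.data[OUTCOME_FIELD].to_numpy(dtype=float).astype(int)
        table = build_reclassification_table(
            old.assignments.to_list(), new.assignments.to_list(), outcomes
        )
        return ReclassificationResults(
            old_stratification=old,
            new_stratification=new,
            table=table,
            reclass=overall_reclassification_improvement(table),
            upclassified=upclassified_intermediate_summary(table),
            n_analysed=len(subset),
            n_excluded=len(self.cohort) - len(subset),
            exclusions=subset.exclusions,
        )
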