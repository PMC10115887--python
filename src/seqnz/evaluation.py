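"""Strategy evaluation: fixed panels, multi-objective metrics, dominance.

Fixed-panel strategies acquire a predetermined set of measurements
(univariate vs multivariate x cross-sectional vs longitudinal) and conclude
with a forced choice; sequential strategies adapt.  All strategies are
summarized with the same objective metrics -- accuracy, sensitivity,
specificity, pre-conversion sensitivity, mean log-loss, resource usage and
cost decompositions -- and compared by Pareto dominance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .decision import (
    CostSpec,
    Decision,
    SequentialClassifier,
    SequentialTrace,
    forced_choice,
    immediate_decision_costs,
    run_two_stage,
)
from .model import ModelTheta, Observation, SubjectRecord, posterior_probability

__all__ = [
    "PanelSpec",
    "StrategySummary",
    "run_fixed_panel",
    "score_strategy",
    "pareto_dominance",
    "cost_grid_experiment",
    "standard_strategies",
    "PRESET_COST_TUPLES",
    "summaries_to_frame",
]

#: the ten prescription tuples (time; MRI; CSF; cognitive), misclassification
#: cost fixed at 100
PRESET_COST_TUPLES: tuple[tuple[float, float, float, float], ...] = (
    (2, 2, 4, 1),
    (1, 2, 4, 1),
    (4, 2, 4, 1),
    (8, 2, 4, 1),
    (2, 1, 2, 0.5),
    (2, 4, 8, 2),
    (2, 8, 16, 4),
    (1, 1, 2, 0.5),
    (4, 4, 8, 2),
    (8, 8, 16, 4),
)

LOGLOSS_CLIP = 1e-12


@dataclass(frozen=True)
class PanelSpec:
    """A fixed (non-adaptive) measurement panel.

    ``scope`` is 'univariate' (exactly one marker) or 'multivariate';
    ``timing`` is 'cross_sectional' (first slot per marker only) or
    'longitudinal' (all slots).
    """

    scope: str
    timing: str
    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.scope not in ("univariate", "multivariate"):
            raise ValueError("scope must be 'univariate' or 'multivariate'")
        if self.timing not in ("cross_sectional", "longitudinal"):
            raise ValueError("timing must be 'cross_sectional' or 'longitudinal'")
        if self.scope == "univariate" and len(self.markers) != 1:
            raise ValueError("a univariate panel must name exactly one marker")
        if not self.markers:
            raise ValueError("panel must name at least one marker")

    @property
    def name(self) -> str:
        core = "+".join(self.markers) if self.scope == "univariate" else "all"
        short = "cross" if self.timing == "cross_sectional" else "long"
        return f"fixed_{self.scope}_{short}_{core}"


def run_fixed_panel(
    record: SubjectRecord,
    theta: ModelTheta,
    panel: PanelSpec,
    costs: CostSpec,
) -> SequentialTrace:
    """Acquire exactly the panel's slots, then conclude with a forced choice.

    Cost accounting is identical to the sequential traces: measurement cost
    is the sum of acquisition costs, time cost is ``c_time`` times the
    latest acquired time.
    """
    per_marker: dict[str, list] = {m: [] for m in panel.markers}
    for o in record.observations:
        if o.slot.marker in per_marker:
            per_marker[o.slot.marker].append(o)
    acquired: list[Observation] = []
    for m in panel.markers:
        slots = sorted(per_marker[m], key=lambda o: o.slot.time)
        if not slots:
            raise ValueError(
                f"subject {record.subject_id} has no {m} measurement for panel"
            )
        acquired.extend(slots[:1] if panel.timing == "cross_sectional" else slots)
    pi_hat = posterior_probability(record.baseline_age, acquired, theta)
    c_neg, c_pos = immediate_decision_costs(pi_hat, costs)
    final = Decision(
        label=forced_choice(pi_hat, costs),
        posterior=pi_hat,
        cost_negative=c_neg,
        cost_positive=c_pos,
    )
    decision_time = max(o.slot.time for o in acquired)
    return SequentialTrace(
        subject_id=record.subject_id,
        strategy=panel.name,
        steps=[],
        final=final,
        acquired=acquired,
        decision_time=decision_time,
        measurement_cost=sum(costs.acquisition(o.slot.marker) for o in acquired),
        time_cost=costs.c_time * decision_time,
    )


@dataclass
class StrategySummary:
    """Per-strategy multi-objective metrics over an evaluation cohort."""

    name: str
    n_subjects: int
    accuracy: float
    sensitivity: float
    specificity: float
    pre_conversion_sensitivity: float
    mean_log_loss: float
    mean_n_obs: float
    mean_followup_time: float
    mean_measurement_cost: float
    mean_misclassification_cost: float
    mean_time_cost: float
    mean_total_cost: float
    se_total_cost: float = 0.0
    total_costs: Optional[np.ndarray] = None  # per-subject, for paired SEs

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "name", "n_subjects", "accuracy", "sensitivity", "specificity",
            "pre_conversion_sensitivity", "mean_log_loss", "mean_n_obs",
            "mean_followup_time", "mean_measurement_cost",
            "mean_misclassification_cost", "mean_time_cost",
            "mean_total_cost", "se_total_cost",
        )}
        return d


def score_strategy(
    traces: Sequence[SequentialTrace],
    records: Sequence[SubjectRecord],
    costs: CostSpec,
    name: Optional[str] = None,
) -> StrategySummary:
    """Confusion-matrix metrics, mean log-loss and cost decomposition.

    A converter counts toward pre-conversion sensitivity only when the final
    decision is positive *and* the decision time is strictly before the
    conversion time.
    """
    by_id = {r.subject_id: r for r in records}
    tp = tn = fp = fn = 0
    pre_conv = 0
    n_conv = 0
    log_losses = []
    mis_costs = []
    totals = []
    n_obs = []
    followup = []
    meas = []
    timec = []
    for tr in traces:
        rec = by_id[tr.subject_id]
        if rec.label is None:
            raise ValueError(f"subject {tr.subject_id} has no label")
        z = rec.label
        pred = tr.predicted_label
        if z == 1:
            n_conv += 1
            if rec.conversion_time is None:
                raise ValueError(
                    f"converter {tr.subject_id} is missing a conversion time"
                )
            if pred == 1:
                tp += 1
                if tr.decision_time < rec.conversion_time:
                    pre_conv += 1
            else:
                fn += 1
        else:
            if pred == 1:
                fp += 1
            else:
                tn += 1
        pi = float(np.clip(tr.final.posterior, LOGLOSS_CLIP, 1 - LOGLOSS_CLIP))
        log_losses.append(-(z * np.log(pi) + (1 - z) * np.log(1 - pi)))
        mis = costs.c_fp if (z == 0 and pred == 1) else (
            costs.c_fn if (z == 1 and pred == 0) else 0.0
        )
        mis_costs.append(mis)
        n_obs.append(tr.n_observations)
        followup.append(tr.decision_time)
        meas.append(tr.measurement_cost)
        timec.append(tr.time_cost)
        totals.append(mis + tr.measurement_cost + tr.time_cost)
    n = len(traces)
    totals = np.asarray(totals, dtype=float)
    return StrategySummary(
        name=name or (traces[0].strategy if traces else "strategy"),
        n_subjects=n,
        accuracy=(tp + tn) / n,
        sensitivity=tp / n_conv if n_conv else float("nan"),
        specificity=tn / (n - n_conv) if n > n_conv else float("nan"),
        pre_conversion_sensitivity=pre_conv / n_conv if n_conv else float("nan"),
        mean_log_loss=float(np.mean(log_losses)),
        mean_n_obs=float(np.mean(n_obs)),
        mean_followup_time=float(np.mean(followup)),
        mean_measurement_cost=float(np.mean(meas)),
        mean_misclassification_cost=float(np.mean(mis_costs)),
        mean_time_cost=float(np.mean(timec)),
        mean_total_cost=float(np.mean(totals)),
        se_total_cost=float(totals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        total_costs=totals,
    )


def pareto_dominance(
    summaries: Sequence[StrategySummary],
    objectives: Sequence[tuple[str, str]],
) -> np.ndarray:
    """Dominance matrix: entry (i, j) is True iff strategy i dominates j.

    i dominates j iff i is at least as good as j in every objective and
    strictly better in at least one; the diagonal is False.  ``objectives``
    is a list of (metric name, 'min' | 'max').
    """
    if len(summaries) < 2:
        raise ValueError("need at least two strategies")
    vals = np.empty((len(summaries), len(objectives)))
    for j, (metric, direction) in enumerate(objectives):
        if direction not in ("min", "max"):
            raise ValueError("objective direction must be 'min' or 'max'")
        for i, s in enumerate(summaries):
            if not hasattr(s, metric):
                raise ValueError(f"unknown metric {metric!r}")
            v = float(getattr(s, metric))
            vals[i, j] = v if direction == "min" else -v
    n = len(summaries)
    dom = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            dom[i, j] = np.all(vals[i] <= vals[j]) and np.any(vals[i] < vals[j])
    return dom


def standard_strategies(
    theta: ModelTheta,
    costs: CostSpec,
    seed: int = 0,
    mc_n: int = 10_000,
) -> dict[str, Callable[[SubjectRecord], SequentialTrace]]:
    """The standard strategy battery: greedy and exhaustive sequential plus
    the univariate/multivariate x cross-sectional/longitudinal panels."""
    strategies: dict[str, Callable] = {}
    for rule in ("greedy", "exhaustive"):
        clf = SequentialClassifier(theta, costs, rule=rule, mc_n=mc_n, seed=seed)
        strategies[f"sequential_{rule}"] = clf.run
    markers = tuple(theta.catalog)
    for timing in ("cross_sectional", "longitudinal"):
        for m in markers:
            panel = PanelSpec("univariate", timing, (m,))
            strategies[panel.name] = (
                lambda r, p=panel: run_fixed_panel(r, theta, p, costs)
            )
        panel = PanelSpec("multivariate", timing, markers)
        strategies[panel.name] = (
            lambda r, p=panel: run_fixed_panel(r, theta, p, costs)
        )
    return strategies


def cost_grid_experiment(
    records: Sequence[SubjectRecord],
    theta: ModelTheta,
    cost_tuples: Sequence[tuple[float, float, float, float]] = PRESET_COST_TUPLES,
    c_mis: float = 100.0,
    strategy_names: Optional[Sequence[str]] = None,
    seed: int = 0,
    mc_n: int = 10_000,
) -> pd.DataFrame:
    """Evaluate every strategy under every cost prescription tuple.

    Returns one row per (cost tuple, strategy) with the full metric set.
    """
    if not cost_tuples:
        raise ValueError("cost grid must be non-empty")
    rows = []
    for tup in cost_tuples:
        costs = CostSpec.from_tuple(*tup, c_mis=c_mis)
        strategies = standard_strategies(theta, costs, seed=seed, mc_n=mc_n)
        if strategy_names is not None:
            strategies = {k: v for k, v in strategies.items() if k in strategy_names}
        for sname, fn in strategies.items():
            traces = [fn(r) for r in records]
            summary = score_strategy(traces, records, costs, name=sname)
            row = summary.as_dict()
            row.update(
                c_time=tup[0], c_mri=tup[1], c_csf=tup[2], c_cognitive=tup[3],
                c_mis=c_mis,
            )
            rows.append(row)
    return pd.DataFrame(rows)


def summaries_to_frame(summaries: Sequence[StrategySummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_dict() for s in summaries])
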