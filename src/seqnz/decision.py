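"""Neutral-zone decision and selection rules for sequential diagnosis.

A forced-choice classifier picks the label with minimum expected
misclassification cost.  The sequential classifiers add a third, *neutral*
label: before concluding, each not-yet-acquired measurement slot is scored
by its expected cost reduction

    [min immediate decision cost now]
      - [expected misclassification cost after acquiring it]
      - [acquisition cost] - [cost-per-year * waiting time],

where the expected misclassification cost after acquisition is computed
from prospective false-positive / false-negative rates of the forced choice
under the class-conditional predictive distribution of the candidate value.
If some candidate has strictly positive expected cost reduction the
decision is postponed (neutral) and a selection rule picks the next
measurement: *greedy* takes the earliest such candidate, *exhaustive* the
one with the highest reduction.  Otherwise the process concludes with the
forced choice.

In the equal-covariance (linear discriminant) variant the forced-choice
region after acquiring a candidate is a half-space in the candidate values,
so the prospective rates have a normal-CDF closed form; with class-specific
covariances they are approximated by Monte Carlo simulation from the
predictive distributions.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import expit, logit, ndtr

from .model import (
    MeasurementSlot,
    ModelTheta,
    Observation,
    SubjectRecord,
    condition_on_observed,
    marginal_moments,
    posterior_log_odds,
)

__all__ = [
    "CostSpec",
    "Decision",
    "ProspectiveRates",
    "CandidateScore",
    "StepRecord",
    "SequentialTrace",
    "immediate_decision_costs",
    "forced_choice",
    "prospective_error_rates",
    "expected_cost_reduction",
    "score_candidates",
    "decide_or_continue",
    "run_two_stage",
    "run_sequential",
    "SequentialClassifier",
]

_TINY_VAR = 1e-14


@dataclass(frozen=True)
class CostSpec:
    """Prescribed costs of the decision process.

    ``c_fp`` / ``c_fn`` are the misclassification costs (default 100 each),
    ``c_acq`` maps marker name to acquisition cost, ``c_time`` is the cost
    per year of waiting.
    """

    c_fp: float = 100.0
    c_fn: float = 100.0
    c_acq: dict[str, float] = field(default_factory=dict)
    c_time: float = 0.0

    def __post_init__(self) -> None:
        if self.c_fp < 0 or self.c_fn < 0 or self.c_time < 0:
            raise ValueError("costs must be non-negative")
        if self.c_fp + self.c_fn <= 0:
            raise ValueError("c_fp + c_fn must be positive")
        if any(v < 0 for v in self.c_acq.values()):
            raise ValueError("acquisition costs must be non-negative")

    def acquisition(self, marker: str) -> float:
        return float(self.c_acq.get(marker, 0.0))

    @property
    def positive_threshold(self) -> float:
        """Posterior above which the forced choice is positive."""
        return self.c_fp / (self.c_fp + self.c_fn)

    @classmethod
    def from_tuple(
        cls,
        c_time: float,
        c_mri: float,
        c_csf: float,
        c_cognitive: float,
        c_mis: float = 100.0,
    ) -> "CostSpec":
        """Build from a (time; MRI; CSF; cognitive) prescription tuple with
        symmetric misclassification cost ``c_mis``."""
        return cls(
            c_fp=c_mis,
            c_fn=c_mis,
            c_acq={
                "mri_spare_ad": c_mri,
                "csf_abeta": c_csf,
                "mmse": c_cognitive,
                "ravlt": c_cognitive,
            },
            c_time=c_time,
        )


@dataclass
class ProspectiveRates:
    """Estimated misclassification rates of the forced choice after
    acquiring candidate measurement(s), before observing their values."""

    fp_hat: float
    fn_hat: float
    expected_error_after: float
    method: str
    mc_n: Optional[int] = None
    mc_se: Optional[float] = None
    fp_se: Optional[float] = None
    fn_se: Optional[float] = None


@dataclass
class CandidateScore:
    slot: MeasurementSlot
    reduction: float
    rates: Optional[ProspectiveRates] = None


@dataclass
class Decision:
    """Outcome of one decision point: a definitive label or neutral with the
    selected next measurement."""

    label: str  # "negative" | "positive" | "neutral"
    posterior: float
    cost_negative: float
    cost_positive: float
    selected_candidate: Optional[MeasurementSlot] = None
    scores: list[CandidateScore] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.label == "neutral") != (self.selected_candidate is not None):
            raise ValueError("selected_candidate present iff label is neutral")


@dataclass
class StepRecord:
    step: int
    current_time: float
    posterior: float
    decision: Decision
    acquired_value: Optional[float] = None


@dataclass
class SequentialTrace:
    """Audit record of one subject's decision process."""

    subject_id: str
    strategy: str
    steps: list[StepRecord]
    final: Decision
    acquired: list[Observation]
    decision_time: float
    measurement_cost: float
    time_cost: float

    @property
    def n_observations(self) -> int:
        return len(self.acquired)

    @property
    def predicted_label(self) -> int:
        return 1 if self.final.label == "positive" else 0

    def to_step_dicts(self) -> list[dict]:
        """JSON-serializable per-step audit rows (one per line in JSONL)."""
        rows = []
        for s in self.steps:
            rows.append(
                {
                    "subject_id": self.subject_id,
                    "strategy": self.strategy,
                    "step": s.step,
                    "current_time": s.current_time,
                    "posterior": s.posterior,
                    "decision": s.decision.label,
                    "selected_marker": (
                        s.decision.selected_candidate.marker
                        if s.decision.selected_candidate
                        else None
                    ),
                    "selected_time": (
                        s.decision.selected_candidate.time
                        if s.decision.selected_candidate
                        else None
                    ),
                    "acquired_value": s.acquired_value,
                    "scores": [
                        {
                            "marker": c.slot.marker,
                            "time": c.slot.time,
                            "reduction": c.reduction,
                        }
                        for c in s.decision.scores
                    ],
                }
            )
        return rows


# ---------------------------------------------------------------------------
# decision rules


def immediate_decision_costs(posterior: float, costs: CostSpec) -> tuple[float, float]:
    """Expected cost of deciding (negative, positive) right now.

    Deciding negative risks a false negative (cost ``c_fn * posterior``);
    deciding positive risks a false positive (``c_fp * (1 - posterior)``).
    """
    if not 0.0 <= posterior <= 1.0:
        raise ValueError(f"posterior must lie in [0, 1], got {posterior}")
    return costs.c_fn * posterior, costs.c_fp * (1.0 - posterior)


def forced_choice(posterior: float, costs: CostSpec) -> str:
    """Minimum-expected-cost binary decision; ties go to positive."""
    c_neg, c_pos = immediate_decision_costs(posterior, costs)
    return "positive" if c_pos <= c_neg else "negative"


def _predictives(age, observations, candidate_slots, theta):
    """Class-conditional predictive moments of the candidate slots given the
    observed values; returns (means, covs) as per-class pairs."""
    slots = [o.slot for o in observations] + list(candidate_slots)
    y = np.array([o.value for o in observations], dtype=float)
    n_obs = len(observations)
    out = []
    for z in (0, 1):
        mean, cov = marginal_moments(age, slots, theta, z)
        m, s = condition_on_observed(mean, cov, np.arange(n_obs), y)
        out.append((m, s))
    return out


def _mc_rates(pred, prior_lo, log_thresh, mc_n, rng):
    """Monte-Carlo prospective rates from class-conditional predictives.

    Antithetic draws; the posterior after acquisition only needs the
    predictive densities:  logit pi' = logit pi + log f1(y) - log f0(y).
    """
    (m0, s0), (m1, s1) = pred
    d = m0.shape[0]
    half = max(1, mc_n // 2)
    chol = [np.linalg.cholesky(s + _TINY_VAR * np.eye(d)) for s in (s0, s1)]
    logdet = [2.0 * float(np.sum(np.log(np.diag(c)))) for c in chol]

    def log_density(y, z):
        diff = y - (m0 if z == 0 else m1)[None, :]
        a = solve_triangular(chol[z], diff.T, lower=True)
        return -0.5 * (d * math.log(2 * math.pi) + logdet[z] + np.sum(a * a, axis=0))

    stats = {}
    for z, (m, c) in enumerate(((m0, chol[0]), (m1, chol[1]))):
        eps = rng.standard_normal((half, d))
        draws = np.concatenate([m + eps @ c.T, m - eps @ c.T], axis=0)
        lo = prior_lo + log_density(draws, 1) - log_density(draws, 0)
        pos = lo >= log_thresh
        err = pos if z == 0 else ~pos
        pair = 0.5 * (err[:half].astype(float) + err[half:].astype(float))
        rate = float(pair.mean())
        se = float(pair.std(ddof=1) / math.sqrt(half)) if half > 1 else 0.0
        stats[z] = (rate, se)
    return stats[0], stats[1]


def prospective_error_rates(
    baseline_age: float,
    observations: Sequence[Observation],
    candidate_slots: Sequence[MeasurementSlot],
    theta: ModelTheta,
    costs: CostSpec,
    method: str = "closed_form",
    mc_n: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> ProspectiveRates:
    """Prospective FP/FN rates of the forced choice after acquiring the
    candidate slot(s), given the current observations.

    ``fp_hat`` is the probability of a positive forced choice given z = 0
    (and the observed data); ``fn_hat`` the analogous rate under z = 1.
    ``expected_error_after`` weights them by the current posterior.
    """
    if not candidate_slots:
        raise ValueError("candidate_slots must be non-empty")
    observed = {o.slot for o in observations}
    if observed & set(candidate_slots):
        raise ValueError("candidate slots are already observed")
    prior_lo = posterior_log_odds(baseline_age, observations, theta)
    pi_hat = float(expit(prior_lo))
    log_thresh = float(logit(costs.positive_threshold))
    pred = _predictives(baseline_age, observations, candidate_slots, theta)

    if method == "closed_form":
        if not theta.equal_covariance:
            raise ValueError(
                "closed_form requires the equal-covariance variant; "
                "use method='monte_carlo' for class-specific covariances"
            )
        (m0, s), (m1, _) = pred
        w = np.linalg.solve(s + _TINY_VAR * np.eye(len(m0)), m1 - m0)
        var_g = float(w @ s @ w)
        # g(y) = logit pi'(y) - log_thresh is affine in the candidate values
        mean_g0 = prior_lo + float(w @ (m0 - 0.5 * (m0 + m1))) - log_thresh
        mean_g1 = prior_lo + float(w @ (m1 - 0.5 * (m0 + m1))) - log_thresh
        if var_g <= _TINY_VAR:
            fp = 1.0 if mean_g0 >= 0 else 0.0
            fn = 1.0 if mean_g1 < 0 else 0.0
        else:
            sd = math.sqrt(var_g)
            fp = float(ndtr(mean_g0 / sd))
            fn = float(ndtr(-mean_g1 / sd))
        rates = ProspectiveRates(
            fp_hat=fp,
            fn_hat=fn,
            expected_error_after=(1 - pi_hat) * fp + pi_hat * fn,
            method="closed_form",
        )
    elif method == "monte_carlo":
        rng = rng if rng is not None else np.random.default_rng(0)
        (fp, fp_se), (fn, fn_se) = _mc_rates(pred, prior_lo, log_thresh, mc_n, rng)
        rates = ProspectiveRates(
            fp_hat=fp,
            fn_hat=fn,
            expected_error_after=(1 - pi_hat) * fp + pi_hat * fn,
            method="monte_carlo",
            mc_n=mc_n,
            mc_se=math.hypot((1 - pi_hat) * fp_se, pi_hat * fn_se),
            fp_se=fp_se,
            fn_se=fn_se,
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return rates


def expected_cost_reduction(
    candidate: MeasurementSlot,
    baseline_age: float,
    observations: Sequence[Observation],
    theta: ModelTheta,
    costs: CostSpec,
    current_time: float = 0.0,
    method: str = "closed_form",
    mc_n: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Expected total-cost reduction from acquiring one candidate slot.

    With symmetric misclassification costs ``c`` and acquisition cost ``x``
    at no delay, the reduction is positive exactly when the expected
    accuracy increase exceeds ``x / c``.
    """
    if candidate.time < current_time:
        raise ValueError(
            f"candidate at t={candidate.time} lies before current time "
            f"{current_time}"
        )
    rates = prospective_error_rates(
        baseline_age, observations, [candidate], theta, costs,
        method=method, mc_n=mc_n, rng=rng,
    )
    pi_hat = float(expit(posterior_log_odds(baseline_age, observations, theta)))
    c_neg, c_pos = immediate_decision_costs(pi_hat, costs)
    after = costs.c_fp * (1 - pi_hat) * rates.fp_hat + costs.c_fn * pi_hat * rates.fn_hat
    waiting = costs.c_time * (candidate.time - current_time)
    return min(c_neg, c_pos) - after - costs.acquisition(candidate.marker) - waiting


def score_candidates(
    baseline_age: float,
    observations: Sequence[Observation],
    candidates: Sequence[MeasurementSlot],
    theta: ModelTheta,
    costs: CostSpec,
    current_time: float = 0.0,
    method: str = "closed_form",
    mc_n: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, list[CandidateScore]]:
    """Score every candidate slot singly; returns (current posterior, scores).

    The closed-form path evaluates all candidates in one batched linear
    solve against the observed-block Cholesky factor.
    """
    prior_lo = posterior_log_odds(baseline_age, observations, theta)
    pi_hat = float(expit(prior_lo))
    if not candidates:
        return pi_hat, []
    if method != "closed_form" or not theta.equal_covariance:
        c_neg0, c_pos0 = immediate_decision_costs(pi_hat, costs)
        scores = []
        for c in candidates:
            if c.time < current_time:
                raise ValueError(
                    f"candidate at t={c.time} lies before current time {current_time}"
                )
            rates = prospective_error_rates(
                baseline_age, observations, [c], theta, costs,
                method=method, mc_n=mc_n, rng=rng,
            )
            after = (
                costs.c_fp * (1 - pi_hat) * rates.fp_hat
                + costs.c_fn * pi_hat * rates.fn_hat
            )
            red = (
                min(c_neg0, c_pos0) - after
                - costs.acquisition(c.marker)
                - costs.c_time * (c.time - current_time)
            )
            scores.append(CandidateScore(slot=c, reduction=float(red), rates=rates))
        return pi_hat, scores

    cat = theta.catalog
    mk = theta.markers
    psi, rho = mk.psi, mk.rho
    idx_c = np.array([cat.index(c.marker) for c in candidates])
    t_c = np.array([c.time for c in candidates])
    n_c = len(candidates)
    zc = np.zeros((n_c, 2 * len(cat)))
    zc[np.arange(n_c), 2 * idx_c] = 1.0
    zc[np.arange(n_c), 2 * idx_c + 1] = t_c
    b = mk.beta[:, idx_c, :]  # (2, C, 3)
    mu_c = b[:, :, 0] + b[:, :, 1] * baseline_age + b[:, :, 2] * t_c  # (2, C)
    var_c = np.einsum("ij,jk,ik->i", zc, psi, zc) + rho[idx_c]

    if observations:
        slots_o = [o.slot for o in observations]
        y = np.array([o.value for o in observations])
        mu_o0, cov_o = marginal_moments(baseline_age, slots_o, theta, 0)
        mu_o1, _ = marginal_moments(baseline_age, slots_o, theta, 1)
        try:
            cf = cho_factor(cov_o, lower=True)
        except np.linalg.LinAlgError:
            cf = cho_factor(cov_o + 1e-8 * np.eye(len(y)), lower=True)
        idx_o = np.array([cat.index(s.marker) for s in slots_o])
        t_o = np.array([s.time for s in slots_o])
        zo = np.zeros((len(y), 2 * len(cat)))
        zo[np.arange(len(y)), 2 * idx_o] = 1.0
        zo[np.arange(len(y)), 2 * idx_o + 1] = t_o
        k = zo @ psi @ zc.T  # (m, C) cross-covariance
        sol_k = cho_solve(cf, k)
        m_cond0 = mu_c[0] + k.T @ cho_solve(cf, y - mu_o0)
        m_cond1 = mu_c[1] + k.T @ cho_solve(cf, y - mu_o1)
        s_cond = np.maximum(var_c - np.einsum("ij,ij->j", k, sol_k), 0.0)
    else:
        m_cond0, m_cond1 = mu_c[0], mu_c[1]
        s_cond = var_c

    log_thresh = float(logit(costs.positive_threshold))
    delta = m_cond1 - m_cond0
    # g(y) = logit pi'(y) - log_thresh is affine in y with slope delta / S,
    # so under either class predictive sd(g) = |delta| / sqrt(S)
    sd_g = np.abs(delta) / np.sqrt(np.maximum(s_cond, _TINY_VAR))
    mean_g0 = prior_lo - 0.5 * delta * delta / np.maximum(s_cond, _TINY_VAR) - log_thresh
    mean_g1 = prior_lo + 0.5 * delta * delta / np.maximum(s_cond, _TINY_VAR) - log_thresh
    degenerate = (sd_g <= math.sqrt(_TINY_VAR)) | (s_cond <= _TINY_VAR)
    with np.errstate(divide="ignore", invalid="ignore"):
        fp = np.where(degenerate, (mean_g0 >= 0).astype(float), ndtr(mean_g0 / sd_g))
        fn = np.where(degenerate, (mean_g1 < 0).astype(float), ndtr(-mean_g1 / sd_g))

    c_neg, c_pos = immediate_decision_costs(pi_hat, costs)
    after = costs.c_fp * (1 - pi_hat) * fp + costs.c_fn * pi_hat * fn
    acq = np.array([costs.acquisition(c.marker) for c in candidates])
    waiting = costs.c_time * (t_c - current_time)
    reductions = min(c_neg, c_pos) - after - acq - waiting
    err_after = (1 - pi_hat) * fp + pi_hat * fn
    scores = [
        CandidateScore(
            slot=candidates[j],
            reduction=float(reductions[j]),
            rates=ProspectiveRates(
                fp_hat=float(fp[j]),
                fn_hat=float(fn[j]),
                expected_error_after=float(err_after[j]),
                method="closed_form",
            ),
        )
        for j in range(n_c)
    ]
    return pi_hat, scores


def decide_or_continue(
    baseline_age: float,
    observations: Sequence[Observation],
    candidates: Sequence[MeasurementSlot],
    theta: ModelTheta,
    costs: CostSpec,
    rule: str = "greedy",
    current_time: float = 0.0,
    method: str = "closed_form",
    mc_n: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> Decision:
    """One decision point: definitive label, or neutral plus the selected
    next measurement.

    Greedy selection takes the earliest candidate with positive expected
    cost reduction (ties: catalog order, then highest reduction); exhaustive
    takes the highest reduction (ties: earliest time, then catalog order).
    """
    if rule not in ("greedy", "exhaustive"):
        raise ValueError("rule must be 'greedy' or 'exhaustive'")
    pi_hat, scores = score_candidates(
        baseline_age, observations, candidates, theta, costs,
        current_time=current_time, method=method, mc_n=mc_n, rng=rng,
    )
    c_neg, c_pos = immediate_decision_costs(pi_hat, costs)
    positive = [s for s in scores if s.reduction > 0.0]
    if not positive:
        return Decision(
            label=forced_choice(pi_hat, costs),
            posterior=pi_hat,
            cost_negative=c_neg,
            cost_positive=c_pos,
            scores=scores,
        )
    cat = theta.catalog
    if rule == "greedy":
        key = lambda s: (s.slot.time, cat.index(s.slot.marker), -s.reduction)
    else:
        key = lambda s: (-s.reduction, s.slot.time, cat.index(s.slot.marker))
    chosen = min(positive, key=key)
    return Decision(
        label="neutral",
        posterior=pi_hat,
        cost_negative=c_neg,
        cost_positive=c_pos,
        selected_candidate=chosen.slot,
        scores=scores,
    )


# ---------------------------------------------------------------------------
# classifiers


def _value_lookup(record: SubjectRecord) -> dict[MeasurementSlot, float]:
    return {o.slot: o.value for o in record.observations}


def _finalize(
    record, strategy, steps, final, acquired, costs
) -> SequentialTrace:
    decision_time = max((o.slot.time for o in acquired), default=0.0)
    measurement_cost = sum(costs.acquisition(o.slot.marker) for o in acquired)
    return SequentialTrace(
        subject_id=record.subject_id,
        strategy=strategy,
        steps=steps,
        final=final,
        acquired=list(acquired),
        decision_time=decision_time,
        measurement_cost=measurement_cost,
        time_cost=costs.c_time * decision_time,
    )


def run_two_stage(
    record: SubjectRecord,
    theta: ModelTheta,
    costs: CostSpec,
    stage1_marker: str = "mri_spare_ad",
    stage2_marker: str = "csf_abeta",
    method: str = "closed_form",
    mc_n: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> SequentialTrace:
    """Two-stage classifier: classify on the baseline MRI, or -- if the
    expected cost reduction of the baseline CSF is positive -- refer to CSF
    and conclude with a forced choice on both."""
    values = _value_lookup(record)
    stage1 = [s for s in values if s.marker == stage1_marker]
    stage2 = [s for s in values if s.marker == stage2_marker]
    if not stage1:
        raise ValueError(f"subject {record.subject_id} has no {stage1_marker} observation")
    if not stage2:
        raise ValueError(f"subject {record.subject_id} has no {stage2_marker} measurement")
    mri = min(stage1, key=lambda s: s.time)
    csf = min(stage2, key=lambda s: s.time)
    obs = [Observation(slot=mri, value=values[mri])]
    reduction = expected_cost_reduction(
        csf, record.baseline_age, obs, theta, costs,
        current_time=mri.time, method=method, mc_n=mc_n, rng=rng,
    )
    pi1 = float(expit(posterior_log_odds(record.baseline_age, obs, theta)))
    c_neg, c_pos = immediate_decision_costs(pi1, costs)
    steps = []
    if reduction > 0.0:
        d1 = Decision(
            label="neutral", posterior=pi1, cost_negative=c_neg,
            cost_positive=c_pos, selected_candidate=csf,
            scores=[CandidateScore(slot=csf, reduction=reduction)],
        )
        steps.append(
            StepRecord(step=0, current_time=mri.time, posterior=pi1,
                       decision=d1, acquired_value=values[csf])
        )
        obs = obs + [Observation(slot=csf, value=values[csf])]
        pi2 = float(expit(posterior_log_odds(record.baseline_age, obs, theta)))
        c_neg2, c_pos2 = immediate_decision_costs(pi2, costs)
        final = Decision(
            label=forced_choice(pi2, costs), posterior=pi2,
            cost_negative=c_neg2, cost_positive=c_pos2,
        )
    else:
        final = Decision(
            label=forced_choice(pi1, costs), posterior=pi1,
            cost_negative=c_neg, cost_positive=c_pos,
            scores=[CandidateScore(slot=csf, reduction=reduction)],
        )
    steps.append(
        StepRecord(step=len(steps), current_time=max(o.slot.time for o in obs),
                   posterior=final.posterior, decision=final)
    )
    return _finalize(record, "two_stage", steps, final, obs, costs)


def run_sequential(
    record: SubjectRecord,
    theta: ModelTheta,
    costs: CostSpec,
    rule: str = "greedy",
    max_steps: Optional[int] = None,
    initial_slots: Sequence[MeasurementSlot] = (),
    candidate_slots: Optional[Sequence[MeasurementSlot]] = None,
    method: Optional[str] = None,
    mc_n: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> SequentialTrace:
    """Sequential neutral-zone classification of one subject.

    Starting from the (possibly empty) ``initial_slots``, the loop computes
    the posterior from the acquired observations, scores every remaining
    candidate at a time at or after the current decision time, and either
    concludes (forced choice) or acquires the selected measurement.  Moving
    to a later time forfeits all candidates scheduled strictly earlier
    (prospective skipping); same-time candidates remain available.
    Candidate values are looked up from the subject's recorded observations.
    """
    if method is None:
        method = "closed_form" if theta.equal_covariance else "monte_carlo"
    values = _value_lookup(record)
    cat = theta.catalog
    pool = sorted(
        (candidate_slots if candidate_slots is not None
         else [s for s in values if s not in set(initial_slots)]),
        key=lambda s: (s.time, cat.index(s.marker)),
    )
    for s in list(initial_slots) + pool:
        if s not in values:
            raise ValueError(
                f"slot ({s.marker}, t={s.time}) has no recorded value for "
                f"subject {record.subject_id}"
            )
    obs = [Observation(slot=s, value=values[s]) for s in initial_slots]
    current_time = max((s.time for s in initial_slots), default=0.0)
    steps: list[StepRecord] = []
    k = 0
    while True:
        eligible = [s for s in pool if s.time >= current_time]
        budget_left = max_steps is None or k < max_steps
        decision = decide_or_continue(
            record.baseline_age, obs, eligible if budget_left else [],
            theta, costs, rule=rule, current_time=current_time,
            method=method, mc_n=mc_n, rng=rng,
        )
        if decision.label != "neutral":
            steps.append(
                StepRecord(step=k, current_time=current_time,
                           posterior=decision.posterior, decision=decision)
            )
            return _finalize(record, f"sequential_{rule}", steps, decision, obs, costs)
        slot = decision.selected_candidate
        steps.append(
            StepRecord(step=k, current_time=current_time,
                       posterior=decision.posterior, decision=decision,
                       acquired_value=values[slot])
        )
        obs.append(Observation(slot=slot, value=values[slot]))
        current_time = slot.time
        pool = [s for s in pool if s != slot and s.time >= current_time]
        k += 1


class SequentialClassifier:
    """Convenience wrapper binding a fitted model, costs and a selection rule.

    All Monte-Carlo randomness flows from the single ``seed``.
    """

    def __init__(
        self,
        theta: ModelTheta,
        costs: CostSpec,
        rule: str = "greedy",
        method: Optional[str] = None,
        mc_n: int = 10_000,
        max_steps: Optional[int] = None,
        seed: int = 0,
    ):
        self.theta = theta
        self.costs = costs
        self.rule = rule
        self.method = method
        self.mc_n = mc_n
        self.max_steps = max_steps
        self.seed = seed

    def run(self, record: SubjectRecord, **overrides) -> SequentialTrace:
        sid = zlib.crc32(record.subject_id.encode()) % 2**31
        rng = np.random.default_rng((self.seed, sid))
        kws = dict(
            rule=self.rule, max_steps=self.max_steps, method=self.method,
            mc_n=self.mc_n, rng=rng,
        )
        kws.update(overrides)
        return run_sequential(record, self.theta, self.costs, **kws)

    def run_cohort(self, records: Sequence[SubjectRecord], **overrides):
        return [self.run(r, **overrides) for r in records]
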