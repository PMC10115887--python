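"""Decision rules: Bayes risk, prospective rates, selection, sequences."""

import numpy as np
import pytest
from scipy import integrate
from scipy.special import expit

from conftest import make_theta, scalar_theta
from seqnz.decision import (
    CostSpec,
    Decision,
    SequentialClassifier,
    decide_or_continue,
    expected_cost_reduction,
    forced_choice,
    immediate_decision_costs,
    prospective_error_rates,
    run_sequential,
    run_two_stage,
    score_candidates,
)
from seqnz.model import (
    MeasurementSlot,
    Observation,
    posterior_probability,
)
from seqnz.simulate import default_preset, simulate_cohort


class TestImmediateCosts:
    @pytest.mark.parametrize(
        "pi, c_fn, c_fp, expected",
        [
            (0.5, 100, 100, (50.0, 50.0)),
            (0.0, 100, 100, (0.0, 100.0)),
            (0.3, 100, 50, (30.0, 35.0)),
        ],
    )
    def test_bayes_risk_pairs(self, pi, c_fn, c_fp, expected):
        costs = CostSpec(c_fp=c_fp, c_fn=c_fn)
        assert immediate_decision_costs(pi, costs) == pytest.approx(expected)

    def test_forced_choice_minimizes_and_breaks_ties_positive(self):
        assert forced_choice(0.3, CostSpec(c_fp=50, c_fn=100)) == "negative"
        # exact tie at pi = 0.5 under symmetric costs -> positive
        assert forced_choice(0.5, CostSpec(c_fp=100, c_fn=100)) == "positive"

    def test_invalid_posterior_rejected(self):
        with pytest.raises(ValueError):
            immediate_decision_costs(1.2, CostSpec())


def _two_marker_theta(uninformative_second=False):
    """Marker 'u' optionally carries no class information."""
    beta = np.array(
        [
            [[-1.0, 0.0, 0.0], [0.3, 0.0, 0.0]],
            [[1.0, 0.0, 0.0], [0.3 if uninformative_second else 1.1, 0.0, 0.0]],
        ]
    )
    return make_theta(["m", "u"], beta=beta, rho=[1.0, 0.8])


class TestProspectiveRates:
    def test_uninformative_candidate_keeps_current_error(self):
        theta = _two_marker_theta(uninformative_second=True)
        obs = [Observation(MeasurementSlot(0.0, "m"), 0.4)]
        costs = CostSpec()
        rates = prospective_error_rates(
            70.0, obs, [MeasurementSlot(0.0, "u")], theta, costs
        )
        pi = posterior_probability(70.0, obs, theta)
        current = min(pi, 1 - pi)
        assert rates.expected_error_after == pytest.approx(current, abs=1e-12)

    def test_point_mass_separation_gives_zero_rates(self):
        theta = make_theta(
            ["m"], beta=[[[-2.0, 0, 0]], [[2.0, 0, 0]]], rho=[1e-12]
        )
        rates = prospective_error_rates(
            70.0, [], [MeasurementSlot(0.0, "m")], theta, CostSpec()
        )
        assert rates.fp_hat == pytest.approx(0.0, abs=1e-9)
        assert rates.fn_hat == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_matches_monte_carlo_scalar(self):
        theta = scalar_theta(mu0=-0.6, mu1=0.7, var=1.3, prior_logit=0.2)
        cand = [MeasurementSlot(0.0, "m")]
        costs = CostSpec()
        cf = prospective_error_rates(70.0, [], cand, theta, costs, "closed_form")
        mc = prospective_error_rates(
            70.0, [], cand, theta, costs, "monte_carlo",
            mc_n=200_000, rng=np.random.default_rng(12),
        )
        assert abs(cf.fp_hat - mc.fp_hat) < 3 * mc.fp_se
        assert abs(cf.fn_hat - mc.fn_hat) < 3 * mc.fn_se
        assert mc.mc_se is not None and mc.mc_n == 200_000

    def test_closed_form_rejected_for_class_specific_covariance(self):
        psi0 = np.zeros((2, 2))
        theta = make_theta(
            ["m"], beta=[[[-1.0, 0, 0]], [[1.0, 0, 0]]], rho=[1.0],
            psi_by_class=np.stack([psi0, psi0]),
            rho_by_class=np.array([[1.0], [2.0]]),
        )
        with pytest.raises(ValueError, match="equal-covariance"):
            prospective_error_rates(
                70.0, [], [MeasurementSlot(0.0, "m")], theta, CostSpec(),
                method="closed_form",
            )

    def test_observed_candidate_rejected(self):
        theta = scalar_theta()
        slot = MeasurementSlot(0.0, "m")
        with pytest.raises(ValueError, match="already observed"):
            prospective_error_rates(
                70.0, [Observation(slot, 0.1)], [slot], theta, CostSpec()
            )


class TestExpectedCostReduction:
    def test_uninformative_candidate_costs_only(self):
        theta = _two_marker_theta(uninformative_second=True)
        obs = [Observation(MeasurementSlot(0.0, "m"), 0.4)]
        costs = CostSpec(c_acq={"u": 3.0}, c_time=2.0)
        red = expected_cost_reduction(
            MeasurementSlot(1.5, "u"), 70.0, obs, theta, costs, current_time=0.0
        )
        assert red == pytest.approx(-(3.0 + 2.0 * 1.5), abs=1e-10)

    def test_quadrature_oracle_scalar(self):
        """Closed-form reduction equals a numerical-integration oracle."""
        theta = scalar_theta(mu0=-0.8, mu1=0.9, var=1.4, prior_logit=-0.3)
        costs = CostSpec(c_acq={"m": 5.0})
        cand = MeasurementSlot(0.0, "m")
        red = expected_cost_reduction(cand, 70.0, [], theta, costs)

        pi = posterior_probability(70.0, [], theta)
        current = min(100 * pi, 100 * (1 - pi))

        def err_integrand(y):
            post = posterior_probability(70.0, [Observation(cand, y)], theta)
            dens0 = np.exp(-0.5 * (y + 0.8) ** 2 / 1.4) / np.sqrt(2 * np.pi * 1.4)
            dens1 = np.exp(-0.5 * (y - 0.9) ** 2 / 1.4) / np.sqrt(2 * np.pi * 1.4)
            fp_part = 100 * (1 - pi) * dens0 * (post >= 0.5)
            fn_part = 100 * pi * dens1 * (post < 0.5)
            return fp_part + fn_part

        # split the integral at the decision boundary (posterior = 0.5)
        from scipy.optimize import brentq

        boundary = brentq(
            lambda y: posterior_probability(70.0, [Observation(cand, y)], theta) - 0.5,
            -10, 10,
        )
        after, _ = integrate.quad(err_integrand, -15, boundary)
        after2, _ = integrate.quad(err_integrand, boundary, 15)
        oracle = current - (after + after2) - 5.0
        assert red == pytest.approx(oracle, abs=1e-6)

    def test_past_candidate_rejected(self):
        theta = scalar_theta()
        with pytest.raises(ValueError, match="before current time"):
            expected_cost_reduction(
                MeasurementSlot(0.5, "m"), 70.0, [], theta, CostSpec(),
                current_time=1.0,
            )

    def test_batch_scoring_agrees_with_single_candidate_path(self, theta_true):
        cohort = simulate_cohort(default_preset("adni_like", n_subjects=6, seed=21))
        costs = CostSpec.from_tuple(2, 2, 4, 1)
        for rec in cohort.records:
            obs = rec.observations[:3]
            observed = {o.slot for o in obs}
            cands = [o.slot for o in rec.observations if o.slot not in observed][:5]
            if not cands:
                continue
            _, scores = score_candidates(
                rec.baseline_age, obs, cands, theta_true, costs, current_time=0.0
            )
            for sc in scores:
                single = expected_cost_reduction(
                    sc.slot, rec.baseline_age, obs, theta_true, costs,
                    current_time=0.0,
                )
                assert sc.reduction == pytest.approx(single, abs=1e-9)


class TestDecideOrContinue:
    def test_empty_candidates_forces_choice_at_half(self):
        theta = scalar_theta(prior_logit=0.4)
        d = decide_or_continue(70.0, [], [], theta, CostSpec())
        assert d.label == "positive"  # prior = expit(0.4) > 0.5
        d = decide_or_continue(70.0, [], [], scalar_theta(prior_logit=-0.4), CostSpec())
        assert d.label == "negative"

    def test_greedy_takes_earliest_exhaustive_takes_best(self, theta_true):
        # an MRI now and a (more informative) CSF later, both worth acquiring
        costs = CostSpec(c_acq={}, c_time=0.0)
        cands = [
            MeasurementSlot(0.5, "mri_spare_ad"),
            MeasurementSlot(1.0, "csf_abeta"),
        ]
        _, scores = score_candidates(73.0, [], cands, theta_true, costs)
        by_slot = {s.slot: s.reduction for s in scores}
        assert all(r > 0 for r in by_slot.values())
        assert by_slot[cands[1]] > by_slot[cands[0]]  # CSF is worth more

        greedy = decide_or_continue(73.0, [], cands, theta_true, costs, rule="greedy")
        exhaustive = decide_or_continue(
            73.0, [], cands, theta_true, costs, rule="exhaustive"
        )
        assert greedy.label == exhaustive.label == "neutral"
        assert greedy.selected_candidate == cands[0]
        assert exhaustive.selected_candidate == cands[1]

    def test_decision_invariant(self):
        with pytest.raises(ValueError):
            Decision(label="neutral", posterior=0.5, cost_negative=1, cost_positive=1)
        with pytest.raises(ValueError):
            Decision(
                label="positive", posterior=0.5, cost_negative=1, cost_positive=1,
                selected_candidate=MeasurementSlot(0.0, "m"),
            )


class TestTwoStage:
    def test_zero_cost_informative_csf_always_referred(self, theta_true, small_cohort):
        costs = CostSpec(c_acq={"csf_abeta": 0.0}, c_time=0.0)
        for rec in small_cohort.records[:20]:
            trace = run_two_stage(rec, theta_true, costs)
            assert len(trace.acquired) == 2  # MRI + CSF for everyone

    def test_referral_fraction_non_increasing_in_csf_cost(self, theta_true, small_cohort):
        fractions = []
        for x in range(1, 21):
            costs = CostSpec(c_acq={"csf_abeta": float(x)})
            traces = [run_two_stage(r, theta_true, costs) for r in small_cohort.records]
            fractions.append(np.mean([len(t.acquired) == 2 for t in traces]))
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))

    def test_missing_stage1_marker_rejected(self, theta_true):
        from seqnz.model import SubjectRecord

        rec = SubjectRecord(
            "x", 70.0, label=0,
            observations=[Observation(MeasurementSlot(0.0, "mmse"), 0.5)],
        )
        with pytest.raises(ValueError, match="mri_spare_ad"):
            run_two_stage(rec, theta_true, CostSpec())


class TestSequential:
    def test_prohibitive_costs_mean_zero_acquisitions(self, theta_true, small_cohort):
        costs = CostSpec(
            c_acq={m: 100.0 for m in theta_true.catalog}, c_time=0.0
        )
        for rec in small_cohort.records[:15]:
            trace = run_sequential(rec, theta_true, costs, rule="greedy")
            assert trace.n_observations == 0
            assert trace.decision_time == 0.0
            # decision from the age prior alone
            assert trace.final.posterior == pytest.approx(
                posterior_probability(rec.baseline_age, [], theta_true)
            )

    def test_trace_accounting_identities(self, theta_true, small_cohort):
        costs = CostSpec.from_tuple(2, 2, 4, 1)
        clf = SequentialClassifier(theta_true, costs, rule="exhaustive", seed=1)
        for rec in small_cohort.records[:25]:
            tr = clf.run(rec)
            assert tr.measurement_cost == sum(
                costs.acquisition(o.slot.marker) for o in tr.acquired
            )
            assert tr.time_cost == costs.c_time * tr.decision_time
            assert tr.decision_time == max(
                (o.slot.time for o in tr.acquired), default=0.0
            )
            times = [s.decision.selected_candidate.time for s in tr.steps
                     if s.decision.label == "neutral"]
            assert times == sorted(times)  # step times non-decreasing

    def test_skipping_forfeits_earlier_candidates(self, theta_true, small_cohort):
        costs = CostSpec.from_tuple(2, 2, 4, 1)
        for rec in small_cohort.records[:15]:
            tr = run_sequential(rec, theta_true, costs, rule="exhaustive")
            acquired_times = [o.slot.time for o in tr.acquired]
            assert acquired_times == sorted(acquired_times)

    def test_max_steps_limits_acquisitions(self, theta_true, small_cohort):
        costs = CostSpec(c_acq={}, c_time=0.0)  # free: would acquire everything
        rec = small_cohort.records[0]
        tr = run_sequential(rec, theta_true, costs, rule="greedy", max_steps=2)
        assert tr.n_observations <= 2

    def test_restricted_sequential_reproduces_two_stage(self, theta_true, small_cohort):
        costs = CostSpec(c_acq={"csf_abeta": 4.0})
        for rec in small_cohort.records:
            ts = run_two_stage(rec, theta_true, costs)
            values = {o.slot: o.value for o in rec.observations}
            mri = min((s for s in values if s.marker == "mri_spare_ad"),
                      key=lambda s: s.time)
            csf = min((s for s in values if s.marker == "csf_abeta"),
                      key=lambda s: s.time)
            seq = run_sequential(
                rec, theta_true, costs, rule="greedy",
                initial_slots=[mri], candidate_slots=[csf],
            )
            assert seq.final.label == ts.final.label
            assert seq.n_observations == ts.n_observations
            assert seq.final.posterior == pytest.approx(ts.final.posterior, abs=1e-12)

    def test_raising_marker_cost_never_raises_its_use(self, theta_true, small_cohort):
        counts = []
        for c_csf in (2.0, 6.0, 12.0):
            costs = CostSpec(
                c_acq={"mri_spare_ad": 2, "csf_abeta": c_csf, "mmse": 1, "ravlt": 1},
                c_time=2.0,
            )
            n_csf = 0
            for rec in small_cohort.records:
                tr = run_sequential(rec, theta_true, costs, rule="greedy")
                n_csf += sum(o.slot.marker == "csf_abeta" for o in tr.acquired)
            counts.append(n_csf)
        assert counts[0] >= counts[1] >= counts[2]
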