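# Methods

## The model

`seqnz` classifies a subject into one of two diagnostic classes — here an
MCI patient who converts to manifest Alzheimer's disease within the study
window (z = 1) versus one who remains stable (z = 0) — from an arbitrary,
irregularly sampled subset of longitudinal marker measurements. Two
sub-models supply everything the decision machinery needs:

**Prevalence model.** A logistic regression of the class label on baseline
age a:

    P(z = 1 | a) = expit(lambda_0 + lambda_1 a).

A constant-prevalence mode (`prevalence="constant"`) replaces this with the
training relative frequency.

**Marker model.** A stacked linear mixed-effects model over the marker
catalog H (default: an MRI atrophy score `mri_spare_ad`, the CSF amyloid
assay `csf_abeta`, and two cognitive tests `mmse`, `ravlt`). A measurement
of marker h at time t (years since baseline) on subject i is

    y = beta_{h,1}^(z) + beta_{h,2}^(z) a_i + beta_{h,3}^(z) t
        + zeta_{h,i,1} + zeta_{h,i,2} t + sqrt(rho_h) eps,

with class-specific fixed effects, a per-subject random intercept and slope
per marker — the stacked vector zeta_i ~ N(0, Psi), Psi of dimension
2|H| x 2|H| — and marker-specific residual variance rho_h. Random-effect
and residual variances are shared across classes in the default
(equal-covariance / linear-discriminant) variant, so the class-conditional
law of any measurement subset is Gaussian with class-specific mean
X beta^(z) and common covariance Z Psi Z' + R. A quadratic variant
(`class_specific_covariance=True`) fits (Psi, rho) per class; posteriors
then follow the quadratic discriminant form.

Posterior class probabilities come from Bayes' rule on the two Gaussian
densities and the prevalence prior, computed in the log domain throughout.
Because the model is jointly Gaussian, the predictive distribution of any
not-yet-measured slot given the measured ones is available in closed form
by standard Gaussian conditioning; a jitter of 1e-8 on the diagonal is
applied if a covariance factorization fails.

## Estimation

Parameters are estimated by maximum likelihood. The fixed effects are
profiled out by generalized least squares given the variance parameters;
the variance parameters (a log-Cholesky factor of Psi and log rho) are
optimized by L-BFGS with an analytic gradient. Because the gradient of the
profiled log-likelihood with respect to the variance parameters equals the
partial gradient at the GLS solution (envelope theorem), no derivative of
the profiled fixed effects is needed. The Cholesky parameterization makes
the fitted Psi positive semi-definite by construction.

Numerical choices:

* markers are z-scored and baseline age is mean-centered internally; all
  returned estimates, Psi, rho and standard errors are transformed back to
  the original scale analytically. This stabilizes the 8 x 8 Psi
  optimization; it changes nothing about the model itself.
* multi-start: three starts (a diagonal moment-style start plus two
  jittered copies) are probed for 40 iterations; the best is continued to
  convergence (ftol 1e-10, gradient tolerance 1e-6, L-BFGS memory 50).
* standard errors of the fixed effects are the GLS covariance
  (sum X' V^-1 X)^-1 at the fitted variance parameters.
* REML is available behind `reml=True` but off by default: the discriminant
  construction uses plain ML.
* the prevalence logistic is fitted by Newton-Raphson; on separation or an
  unidentifiable slope the slope is refit with a ridge penalty of 1e-4 and
  a warning.

The `crossval_fit_predict` harness refits the model k times (default
k = 20) on subject-level folds stratified by label and predicts each
subject only from the model fitted without its fold.

## Decision and selection rules

Costs are prescribed a priori: misclassification costs c_FP and c_FN
(default 100 each), per-marker acquisition costs, and a cost per year of
waiting. A forced choice picks the label with minimal expected cost
(c_FN pi vs c_FP (1 - pi)); exact ties go to "positive" so the rule is
deterministic.

Before concluding, every remaining candidate slot (at or after the current
decision time) is scored **singly** — one-measurement lookahead — by its
expected cost reduction:

    [min immediate decision cost now]
      - [c_FP (1-pi) FP_hat + c_FN pi FN_hat]
      - c_acq(marker) - c_time (t_cand - t_now),

where FP_hat / FN_hat are the prospective misclassification rates of the
forced choice after acquiring the candidate, under its class-conditional
predictive distribution given everything observed so far. With symmetric
misclassification cost 100 and acquisition cost x at no delay, a candidate
is worth acquiring exactly when the expected accuracy gain exceeds x/100.

In the equal-covariance variant the post-acquisition log-odds is affine in
the candidate value, so the forced-choice region is a half-space and the
rates reduce to normal CDFs (closed form). With class-specific covariances
the rates are estimated by Monte Carlo from the two predictive
distributions (default 10,000 draws per class, antithetic; the posterior of
a draw needs only the two predictive densities, since the log-odds update
factorizes). All Monte-Carlo randomness flows from a single seed.

If some candidate has strictly positive expected cost reduction the
decision is postponed ("neutral") and a selection rule picks the next
measurement: **greedy** takes the earliest positive-reduction candidate
(ties: catalog order, then highest reduction); **exhaustive** takes the
highest reduction (ties: earliest time, then catalog order). Acquiring a
slot advances the decision time to that slot's time and forfeits all
candidates scheduled strictly earlier (prospective skipping); same-time
candidates remain available. The baseline prior alone may already trigger
a forced choice before any acquisition. The loop ends on a forced choice,
candidate exhaustion, or `max_steps`.

The two-stage classifier is the special case: classify on the baseline MRI
or — if the baseline CSF's expected cost reduction is positive — acquire
the CSF and conclude with a forced choice on both. `run_sequential`
restricted to that single candidate reproduces it exactly (tested).

One design point was left out deliberately: scoring "expected error after
acquisition" with a rule that retains a further neutral option would need a
continuation value for the post-acquisition neutral state (a recursion
depth or a neutral-state cost), and there is no principled default; the
implemented semantics conclude with a forced choice after the scored
acquisition, which is also what the two-stage flow specifies. Deeper
lookahead than one measurement is likewise out of scope; the greedy step
does not guarantee a globally optimal sequence.

## Evaluation

Fixed-panel baselines acquire a predetermined set of slots (univariate vs
multivariate x cross-sectional = first slot per marker vs longitudinal =
all slots) and conclude with a forced choice, with cost accounting
identical to the sequential traces (measurement cost = sum of acquisition
costs; time cost = c_time x latest acquired time).

Per-strategy metrics: accuracy, sensitivity, specificity, mean log-loss
(natural log, posteriors clipped to [1e-12, 1 - 1e-12]), mean number of
observations, mean follow-up time, and the cost decomposition
(misclassification + measurement + time = total, an exact identity).
**Pre-conversion sensitivity** counts a converter as correct only if the
final decision is positive *and* strictly earlier than the conversion time
(the boundary case "decided exactly at conversion" counts against, a
deliberate strict reading). Pareto dominance is the weak convention:
A dominates B iff A is at least as good in every objective and strictly
better in at least one.

The ten preset cost prescriptions (time; MRI; CSF; cognitive) with
misclassification cost 100 ship as `PRESET_COST_TUPLES`, headed by the
default (2; 2; 4; 1).

## The synthetic cohort generator

Real cohorts of this kind are access-restricted, so the generator draws
subjects exactly from the generative structure the classifier assumes:
truncated-normal baseline ages (mean 73, sd 7, bounds 55-90), Bernoulli
labels from the logistic prevalence, subject random effects from Psi,
jittered visits near {0, 0.25, 0.5, 1, 1.5, 2, 3} years (jitter sd 0.05,
baseline exact), per-visit retention 0.9, cognitive tests at every visit,
MRI near years {0, 1, 2}, CSF near {0, 1}. Converters receive a conversion
time uniform on (0.3, 3.25]; stable subjects always keep their final
scheduled visit so their follow-up respects the >= 2.75-year window that
defines the stable label. The `adni_like` preset uses n = 612 with a
converter fraction of 270/612 at the mean age; `zero_effect` equalizes the
class means for null testing.

The preset effect sizes are invented (chosen once, before any evaluation):
they make the markers behave like their clinical counterparts — baseline
MRI alone separates the classes at about d = 1.2 (accuracy ~0.73 at equal
prevalence), the CSF assay is markedly more sensitive (d = 1.8), the
cognitive tests are individually weak at baseline but their converter time
slopes are steep, so longitudinal follow-up is informative. Within-marker
intercept-slope correlation is 0.2, cross-marker intercept correlations
0.3, slope correlations 0.2 (the resulting Psi is PSD by construction of
its factor structure).

What the generator does **not** emulate: real covariate distributions,
informative missingness, label noise, model misspecification (nonlinear
trajectories, non-Gaussian residuals, site effects), or any dependence of
visit attendance on disease state beyond the stable-window rule. Passing
tests therefore demonstrate the *internal* correctness and coherence of
the machinery under its own assumptions, not clinical performance on real
data.

## Problem sizes used in the shipped checks

The property checks run at sizes chosen for a desk-scale machine: 1,000
random conditioning problems; 100 closed-form/Monte-Carlo comparisons at
200,000 draws; parameter recovery over 10 cohorts of n = 600; the x/100
acquisition rule on 200 subjects against a quadrature oracle; the
multi-objective comparison of all 12 strategies over the 10 preset cost
tuples on a test cohort of n = 400 with the model fitted on an independent
n = 612 training cohort. Strategy cost comparisons use 2 standard errors of
the paired per-subject total-cost difference.

## Known limitations

* One-step lookahead; no globally optimal acquisition sequence.
* Parameter uncertainty is ignored at decision time (the fitted theta is
  treated as known).
* The quadratic variant estimates class-specific (Psi, rho) by fitting the
  two classes separately; no pooling or shrinkage.
* High-dimensional catalogs enlarge Psi quadratically; no pairwise-model
  averaging is implemented.
* Visit-dependent or state-dependent cost schedules are expressible only
  through the per-marker cost map, not as logic.
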