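# Methods

`itesurv` estimates which of two treatments gives an individual patient more
months of life within a fixed window, and evaluates such recommendations on
observational survival data. This note documents the models, the synthetic
cohort the package is validated on, the numerical choices, and the limits of
what the tests demonstrate.

## Counterfactual survival model

The core estimator is a *balanced T-learner*. A shared encoder
Φ: ℝᵈ → ℝᵏ maps covariates to a representation; two Cox risk heads
h₀, h₁ map the representation to arm-specific log hazards
η_a(x) = h_a(Φ(x)). Training minimises

    L = L_Cox⁽⁰⁾ + L_Cox⁽¹⁾ + α · IPM(Φ(X|A=0), Φ(X|A=1)),

where each L_Cox is the negative log Cox partial likelihood (Breslow tie
handling, averaged over events) of that arm's head on that arm's patients,
and the IPM term is an integral probability metric between the two arms'
empirical representation distributions. The penalty discourages the encoder
from retaining covariate directions along which the arms differ, the
representation-balancing idea for reducing confounding in treatment-effect
estimation. Two IPMs are available:

- `wasserstein-sinkhorn` (default): the debiased entropic 2-Wasserstein
  (Sinkhorn) divergence with squared-Euclidean cost, regularisation 0.1,
  reported as a distance (square root). Gradients use the envelope theorem
  with transport plans held fixed.
- `mmd-rbf`: biased-estimator maximum mean discrepancy with an RBF kernel,
  bandwidth set by the median heuristic on pooled pairwise distances.

Both vanish on identical point sets and are symmetric; an all-one-arm
mini-batch gets penalty 0 with a warning. With α = 0 the loss is exactly the
sum of the two heads' Cox losses, and with no hidden layers
(`shared_layers=()`, `head_layers=()`) the model degenerates to two linear
Cox models — the correctly specified configuration for
proportional-hazards data, which the test suite verifies against
independent partial-likelihood fits.

The network is a plain NumPy multilayer perceptron (ReLU, inverted
dropout, L2 on weights) trained with Adam and hand-derived gradients; the
Cox-loss gradient is analytic
(∂L/∂η_j = −(δ_j − e^{η_j}·Â(t_j))/D with Â the Breslow cumulative hazard).
Training is fully seeded and bit-reproducible on one machine.

Absolute survival is reconstructed per arm with the Breslow baseline
estimated on that arm's own training data at the final parameters:
Ŝ_a(t|x) = exp(−Ĥ₀,a(t)·e^{η_a(x)}). Per-arm baselines matter because the
two treatment groups' baseline hazards carry prognostic information that
log hazard ratios alone do not.

**Early stopping and tuning.** The validation loss is the sum of the two
Cox terms only (no penalty), so it is comparable across balance weights;
training stops when it has not improved for `patience_steps` gradient steps
(default 300, configurable — "iteration" is interpreted as a gradient
step). Hyperparameters are tuned by exhaustive grid search with k-fold
cross-validation (default 5), the held-out fold serving as the validation
set; a grid point that fails to train scores +∞ rather than aborting the
search. Fold assignment is a deterministic function of the seed.

**Benchmarks.** Classical T-learners — per-arm Cox proportional hazards
(lifelines) and per-arm random survival forests (scikit-survival) — expose
the identical `predict_survival(features, arm, grid)` contract, so every
downstream computation is estimator-agnostic.

## From curves to recommendations

The per-patient potential outcome is the restricted survival time (RST):
the area under the predicted survival curve over [0, t], interpretable as
expected months alive within the window. The individual treatment effect is

    ITE(x; t) = ∫₀ᵗ Ŝ₁(u|x) du − ∫₀ᵗ Ŝ₀(u|x) du,

with t = 60 months by default. Step curves (Breslow/Kaplan–Meier type) are
integrated exactly as rectangles; smooth curves by the trapezoid rule with
the final partial interval interpolated linearly. The default integration
grid is a monthly grid united with both arms' baseline jump times, so step
curves integrate exactly. Arm 1 is recommended iff ITE > 0; a tie
recommends arm 0, the less intensive reference arm (ties have measure zero
on continuous predictors; the conservative default costs nothing). A
configurable minimum-benefit threshold exists and defaults to 0. The
cohort-level sum of per-patient ITEs is available separately; the
per-patient value is what drives recommendations.

## Evaluation on observational data

Patients whose received treatment matches the recommendation (Consis) are
compared with the rest (Inconsis) on overall survival. Because membership
is not randomised, contrasts are reweighted by stabilised IPTW weights
P(G=g)/P(G=g|x) from an unpenalised logistic propensity of *consistency*
(that is the exposure being evaluated) on the adjustment covariates plus,
by default, the actual treatment. Probabilities are clipped to
[0.01, 0.99] and weights truncated at the 1st/99th percentiles — the
standard variance-controlling choices. Reported metrics:

- multivariate and IPTW-weighted Cox HR with robust (sandwich) CIs;
- 5-year absolute risk reduction, 100·(S_C(60) − S_I(60)), from weighted
  Kaplan–Meier curves;
- difference in restricted mean survival time over 60 months (exact
  step-function integrals);
- weighted log-rank test (weights normalised to mean 1, so the statistic is
  invariant to rescaling all weights; unit weights give the classical test);
- the integrated Brier score per arm over [0, horizon] with
  inverse-probability-of-censoring weights from the Kaplan–Meier censoring
  estimator (integration truncates with a warning if that estimator hits 0).

CIs for ARR/DRMST are percentile bootstrap (200 resamples, propensity
refitted per resample); Cox CIs are analytic. Cause-specific HRs under
competing risks recode other-cause deaths as censoring at their own time
and apply the weighted Cox contrast (a marginal structural cause-specific
model); inputs are never mutated.

Two numerical safeguards in the propensity step: linearly dependent design
columns (complementary one-hot sets inside a subgroup) are pruned by
pivoted QR before fitting, and `subgroup_ate` retries with a light ridge
(l2 = 1) when sparse cells quasi-separate. The default fit stays
unpenalised so that a single binary covariate reproduces the 2×2-table log
odds ratio exactly, and true perfect separation raises an error.

## Interpretation layer

- **Probability difference (PD).** For a binary characteristic,
  100·[P(recommended | c=1) − P(recommended | c=0)], optionally
  IPTW-adjusted by a propensity of the characteristic on the remaining
  covariates. Multi-level characteristics are handled one-vs-rest per
  level; age uses bands [0,30), [30,60], (60,∞). Percentile-bootstrap CIs
  (500 resamples standalone, 200 inside the pipeline); no multiplicity
  correction is applied across characteristics, and the output says so by
  listing every characteristic tested.
- **Mediation.** The consistency effect on 5-year mortality is decomposed
  into a natural direct effect and an indirect effect through the actual
  treatment received, using linear probability models: NDE is the exposure
  slope with the mediator in the model, NIE the product of the
  exposure→mediator and mediator→outcome slopes. For OLS this is exactly
  additive (NDE + NIE equals the reduced-model slope, asserted to 1e-9). A
  counterfactual (Pearl-type) decomposition is out of scope. The outcome
  is death within the 60-month horizon.
- **Subgroup ATEs.** HRs of the actual treatment within
  recommendation-defined subgroups (and overall), unweighted and
  IPTW-weighted with a within-subgroup treatment propensity. A subgroup
  with events in only one arm is flagged non-estimable.

## The synthetic cohort

No registry extract ships with the package; a generator produces cohorts
with every structural feature the estimators rely on, with closed-form
ground truth:

- covariates modelled on a head-and-neck cancer registry: age (Normal 60 ±
  10 y), tumour size (35 ± 12 mm), sex (80% male), T stage (T1–T4), N
  stage, anatomical site (oral cavity / pharynx / larynx at 49/28/23%);
- confounded assignment by a logistic propensity: surgery-type treatment
  preferentially given to older patients with larger, T4, node-negative,
  laryngeal tumours;
- Weibull proportional-hazards survival (shape 1.1, scale 80 months —
  median OS near five years) with log hazard
  β·x + a·(γ + δ·x); the default γ = +0.35, δ(T4) = −0.90 makes the
  treatment harmful in T1–T3 and protective in T4: a qualitative
  interaction in roughly 30% of the cohort, the heterogeneity signature a
  recommender must exploit;
- independent exponential censoring (rate 1/120 per month) plus an
  administrative cutoff at 192 months, mimicking a mature registry
  follow-up (~30% censoring);
- causes of death drawn at event time with fixed probabilities (primary
  cancer 0.6, cardiovascular 0.2, adverse effect 0.1, other 0.1) —
  covariate-independent, enough to exercise the competing-risk machinery
  but not cause-specific confounding.

The true per-patient propensity, per-arm log hazards and RST treatment
effect (by adaptive quadrature of the two Weibull survival functions) are
returned alongside every cohort; a `round_months` switch coarsens times to
whole months for tie-handling tests. Identical config + seed reproduces
the cohort byte for byte. Time is months everywhere.

**What passing tests do not show.** The generator is exactly proportional
hazards with a logistic propensity, so the linear model is correctly
specified — recovery results certify the estimation machinery, not
robustness to misspecification, unmeasured confounding, non-proportional
hazards, informative censoring, or covariates the generator lacks (e.g.
HPV status). The confounded-null PD scenario keeps propensities inside the
clipping/truncation region; under more extreme confounding the deliberate
weight truncation leaves visible residual bias, which is a variance–bias
trade-off of the design, not an estimation error.

## Problem sizes and defaults

Validation runs use cohorts of 5,000 (20,000 for the per-arm
coefficient-recovery property, so each arm holds ~10,000), with the linear
configuration of the balanced T-learner (full-batch Adam, learning rate
0.05, ≤1,500 steps, patience 300). The end-to-end acceptance run uses
4,000 patients with a 70/30 split, 200 bootstrap resamples, horizon 60
months. These sizes give Monte-Carlo error comfortably inside the asserted
tolerances while keeping a full run in minutes on one core.

## Known limitations

- Mediation is a linear-probability approximation; effects are slopes, not
  counterfactual risk differences.
- The Sinkhorn gradient is the fixed-plan envelope approximation; extremely
  small regularisation will slow convergence of the plan itself.
- IPTW assumes no unmeasured confounding and positivity; truncation trades
  bias for variance as noted above.
- Fine–Gray subdistribution hazards, time-varying weights and individual
  ITE uncertainty intervals are not implemented.
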