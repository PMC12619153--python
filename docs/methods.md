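# Methods

## Setting

`gsmediate` studies what happens to mediation analysis when a two-arm trial
with a continuous endpoint is run under a two-stage group-sequential design
(GSD) with one interim look and early stopping for efficacy only. The data
mechanism is the standard single-mediator linear system

    M = i_m + a X + e_m,    e_m ~ N(0, sigma_m^2)
    Y = i_y + c' X + b M + e_y,  e_y ~ N(0, sigma_y^2)

with binary randomization X, independent errors and no treatment–mediator
interaction. The indirect effect is `a*b`, the direct effect `c'`, and the
total (intention-to-treat) effect `theta = a*b + c'`. Three null hypotheses
are tested: H01 `theta=0` (primary, on the sequential boundaries), H02
`c'=0` and H03 `ab=0` (secondary, each at the 5% level at whichever stage
the trial stops, without multiplicity adjustment).

## Design mathematics

The standardized statistics `(Z1, Z2)` are jointly normal with
`Z_k ~ N(theta*sqrt(I_k), 1)`, `I_k = n_k/(2 sigma^2)` for cumulative
per-arm size `n_k`, and `corr(Z1, Z2) = sqrt(I1/I2)`. The Pocock boundary
`b` solves `P0(|Z1|>=b) + P0(|Z1|<b, |Z2|>=b) = alpha`. The bivariate
rectangle probability is reduced to a 1-D integral of the conditional normal
and evaluated by adaptive quadrature (absolute tolerance 1e-10); the root is
bracketed on [1.5, 4] (widened adaptively) and solved to 1e-10. For a
two-sided 5% design with the interim at 50% information this gives
b1 = b2 = 2.1783.

Power and sample size use the same quadrature with shifted means.
"Standardized effect" always means mean difference over the *total* SD of
the outcome, which under the mechanism is `sqrt(b^2 sigma_m^2 + sigma_y^2)`
— hence the adjusted effect size

    delta_adj = (a*b + c') / sqrt(b^2 sigma_m^2 + sigma_y^2)

that a sample-size calculation must use when a mediator generates part of
the outcome variance. `required_sample_size` returns the smallest integer
per-arm n whose overall rejection probability reaches the target, with the
interim evaluated at the exact (possibly non-integer) fraction of n; at
delta = 0.3481 (alpha 5%, power 90%) this gives 191 per arm. One
convention note: the published nominal-power table for this design was
produced by a calculator that rounds the per-arm total down to an even
number (190/arm, interim 95) so the stage counts are integers; evaluating
`gsd_power` at n=190 reproduces all of its entries (e.g. 0.2998 -> 0.7917,
0.2607 -> 0.6698) to 1e-4, while n=191 gives values ~0.002 larger. Tests
that target those published values therefore evaluate at n=190. The
inflation factor (continuous GSD n over continuous fixed-design n) is
1.1001 and is effect-size invariant.

`mc_prediction_interval` is the plain binomial 95% band
`p ± 1.959964*sqrt(p(1-p)/R)` used to judge simulated rates.

## Trial protocol

Each simulated trial allocates exactly n subjects per arm (deterministic
balance, the analogue of block randomization of size two); the first
`ceil(n/2)` per arm form stage 1. The interim fits Y ~ 1 + X on stage-1
data and stops iff the t-statistic crosses 2.1783 (the normal-theory
boundary is applied to the t-statistic, as in practice; no t-quantile
correction). The analysis set is stage-1 data after stopping, all data
otherwise. All three regressions (total, mediator, outcome models) are
closed-form OLS with homoskedastic SEs and t-reference p-values — with all
three fit on the same records the product identity
`theta_hat = c'_hat + a_hat*b_hat` is exact.

H03 is tested four ways on every replication: first/second-order Sobel
(delta-method SEs `sqrt(b^2 se_a^2 + a^2 se_b^2 [+ se_a^2 se_b^2])`), joint
significance (both path p-values below alpha), and a Monte-Carlo CI test
drawing `a* ~ N(a_hat, se_a^2)`, `b* ~ N(b_hat, se_b^2)` and taking the
empirical (alpha/2, 1-alpha/2) percentiles of `a*b*` (linear interpolation).
The MC draw count defaults to 20,000 (configurable); at that size the
decision is stable across seeds except on razor-edge inputs.

## Estimators after stopping

Per trial the package reports, on the stopped branch, `mle_1` (stage-1 OLS)
and `pmle`; on the continued branch `mle_all` (pooled), `mle_2` (stage-2
only) and `cmle`. Information levels are plugged in from the analysis-stage
residual variance of the total-effect model.

*Conditional MLE (theta).* On the score scale `s_k = z_k*sqrt(I_k)` the
increments are independent, so the log-likelihood conditional on
continuation collapses to

    l(theta) = -I2*(theta - theta_hat_all)^2/2 - log[Phi(b - theta*sqrt(I1)) - Phi(-b - theta*sqrt(I1))]

maximized by bounded 1-D search over `theta_hat ± 10 SE` (xatol 1e-9).
Because continuation selects low stage-1 statistics, the correction moves
the pooled MLE upward (towards the truth, since `mle_all` is conditionally
negatively biased).

*Penalized MLE (theta).* After stopping, the stage-1 likelihood truncated
to the stopping event, `l_c(theta) = log phi(z1 - theta*sqrt(I1)) -
log P(|Z1|>=b; theta)`, is maximized with a Firth-type penalty
`+0.5*log I_c(theta)`, where the observed truncated information
`I_c = I1*(1 + d^2/dm^2 log P_stop(m))` is computed analytically. Regions
of nonpositive information are excluded; optimizer failure or an empty
admissible window is flagged as non-convergence, and such replications are
discarded from bias summaries and counted.

*Secondary parameters (a and c').* Stopping is driven solely by the theta
statistic, so the adjusted estimator for a secondary parameter conditions
on that event through the joint normal of the theta statistics and the
target estimate, with a plug-in correlation rho between same-data
estimators: for a, `rho = b*sigma_m/sqrt(b^2 sigma_m^2 + sigma_y^2)`
(estimated); for c', rho follows from the exact decomposition
`theta_hat = c'_hat + a_hat*b_hat` with `cov(a_hat, c'_hat) = 0`, using the
outcome-model coefficient covariance. rho is clamped to [-0.999, 0.999].
Profiling the target out of the joint conditional likelihood yields a
closed form: given the theta MLE, the stage-1 statistic carries no
additional information about the target, and

    beta~ = beta_hat - rho * (se_beta/se_theta) * (theta_hat - theta~)

where `theta~` is the branch-appropriate adjusted theta (conditional MLE
after continuation, penalized MLE after stopping). An alternative
construction that conditions only on the pair (z1, target estimate) was
evaluated and rejected: its profile routes the correction through a
stage-1-only conditional theta estimate, which is noisy enough to
*overcorrect* the direct effect (simulated conditional bias +0.07 where the
pooled MLE has -0.03 under scenario S3 at n=347), flipping rather than
shrinking the bias. The mediator–outcome path b is never adjusted: the
intervention does not modify the M–Y relation, and its MLE is unbiased
under stopping (verified in the bias studies).

## Simulation engine and scales

`run_study` loops single trials over substreams spawned from one master
seed (`numpy.random.SeedSequence`), so any replication can be regenerated
in isolation and results CSVs are byte-reproducible. Conditional biases are
reported per stopping stratum only when the stratum holds at least 1000
surviving replications; smaller strata are flagged, empty ones report an
absent (not zero) bias. Replication-level failures are caught, logged and
counted, never fatal.

Default scales follow the study design: 10,000 replications for
testing/operating-characteristic studies, 50,000 for bias studies (both
overridable). The packaged acceptance checks run the testing studies at
10,000 replications and the estimation study (scenario S3, n=347) at
10,000 with 3-MC-SE bands computed from the run itself; at that size both
stopping strata comfortably exceed the 1000-replication floor
(~3,500/~6,500). One scripted operating-characteristics run at n=191 takes
roughly 40 s on a single CPU; the bias study with the full estimator menu
roughly the same.

## Scenario registry

The registry carries the effect-size grid (a, b, c' in {0, 0.14, 0.39,
0.59}, c' also 0.59^2 = 0.3481, sigma_m in {1, 1.5}, intercepts -0.4) and
six named scenarios S1–S6 pairing the indirect effect 0.39×0.14 with
c' in {0, 0.14, 0.39}: S1/S3/S5 use (a, b) = (0.39, 0.14) and S2/S4/S6 the
transposed (0.14, 0.39). The S-scenarios are reconstructions (flagged
`reconstructed`, overridable via YAML): the assignment is pinned by three
independent anchors — the analytic stage-1 stopping probability of S5 at
n=191 (0.806 vs the reported 0.8016), S2's total effect ~0.055, and the ~5%
stage-1 (S1/S2) and stage-2 (S6) stopping rates at n=347.

## What the generator does and does not emulate

It reproduces the mechanism exactly as specified: linear structural
equations, normal homoskedastic errors, perfect balance, no missingness, no
covariates, no confounding of the M–Y relation. Real trials violate most of
these (non-normal outcomes, unequal arms after dropout, measured and
unmeasured confounders, interactions), so passing tests certify the
inferential machinery under the stated mechanism, not robustness to those
violations. In particular the unbiasedness of b's MLE under stopping leans
on the no-unmeasured-confounding assumption.

## Known limitations

* Efficacy stopping only; no futility, no K>2 stages, no error-spending
  families, no sample-size re-estimation.
* Adjusted estimators come without confidence intervals (naive bootstrap
  intervals after sequential stopping do not attain nominal coverage).
* The penalized MLE can fail to converge in small samples; such
  replications are reported as discarded counts.
* The secondary-parameter adjustment treats the plug-in rho as known; its
  sampling error is ignored.
* Binary mediators/outcomes are out of scope — with nonlinear links
  `theta != a*b + c'` and the machinery here does not transfer.
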