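# Methods

## Model

Each colostrum sample's outcome is its natural-log count after adding one,
`y = ln(count + 1)`, so that a zero count maps to exactly zero and the
transform inverts the generator's count construction up to integer rounding.
Samples are clustered on farms; the model is a Gaussian random-intercept
linear mixed model with farm-specific intercepts `U_j ~ N(0, theta_U)` and
residuals `eps_ij ~ N(0, theta_eps)`, giving a block compound-symmetric
marginal covariance per farm. Estimation is by full maximum likelihood, not
REML: the stepwise routine compares models with different fixed-effect
structures by AIC, which requires a common ML likelihood. AIC counts the
fixed coefficients plus both variance components,
`AIC = -2*loglik + 2*(n_fixed + 2)`.

### Fitting

The ML optimum is found by profiling the variance ratio
`lambda = theta_U / theta_eps`: for a fixed ratio the GLS coefficients and
the residual variance have closed forms expressible in per-farm sufficient
statistics (cross-products, per-farm column sums), so one model fit is a
bounded one-dimensional search. The search evaluates `lambda = 0` plus a
40-point log-spaced grid on [1e-6, 1e3] and refines the best bracket with a
bounded derivative-free minimiser (tolerance ~1e-8 on the log-likelihood).
`theta_U` is floored at zero; boundary fits (`lambda = 0`, the OLS limit)
are legal and flagged. The per-farm sufficient statistics are computed once
per (re)sample, so the thousands of submodel fits inside the bootstrap loop
reduce to matrix slicing plus the 1-D search; a fit on the full 13-term
study design takes a few milliseconds. The reported log-likelihood is
verified in the test suite against a dense-covariance multivariate-normal
density (to 1e-6) and against an independent mixed-model implementation.

### Design matrices and collinearity

Categorical terms are expanded to indicators against fixed reference levels
("Cows teat" for the collection source, "Water" for cleaning chemistries,
"Each use"/"Each calf" for frequencies, "No" for binary practices,
"Not applicable" for the milking system, whose N/A level is teat
collection). The continuous covariate (days between calving-pen clean-outs)
is centred and scaled by its sample standard deviation (n−1 denominator)
once, on the full analysis dataset, and those frozen parameters are reused
inside every bootstrap replicate and cross-validation fold — scaling happens
"prior to modelling", before any resampling.

The structural "Not applicable" coding makes several columns exact linear
combinations of others (e.g. every collection-equipment N/A indicator equals
the teat indicator; the parlor and robot indicators sum to the
machine-collection indicator). Rather than failing, the design builder drops
empty and linearly dependent columns deterministically — first column in
declared order wins, detected by incremental Cholesky on the Gram matrix
with relative tolerance 1e-8 — and records what was dropped. This mirrors
how the standard mixed-model software family treats rank-deficient fixed
effects, and it is re-evaluated per term subset, so a column that is
redundant in the full model can re-enter a submodel once its confounder has
been eliminated. A strict mode that raises and names the collinear columns
is available.

## Backward elimination

Greedy whole-term deletion: from the current model, each remaining candidate
term is removed in turn (its entire indicator block at once, never
level-by-level) and the deletion that most lowers AIC is committed; the loop
stops when no deletion strictly lowers AIC. No parsimony margin ("within 2
AIC") is applied. The farm random intercept is never a candidate. Ties
within 1e-9 AIC are broken toward the term later in the declared candidate
order, making the path deterministic. If a candidate refit fails to
converge, that deletion is unavailable at that step and is logged; the
profiled 1-D optimiser makes genuine non-convergence rare.

## Bootstrap stability

The resampling unit is the record (row): each replicate draws n records with
replacement, matching a same-size bootstrap of the sample table, even though
this perturbs farm cluster sizes; a farm-level cluster bootstrap is provided
as an optional mode but is not the default. Resamples with fewer than two
distinct farms are redrawn. Replicate seeds are independent substreams of
the master seed, so runs are exactly reproducible and summaries are
invariant to replicate order.

Stability is the percentage of all B replicates (non-converged ones included
in the denominator and reported alongside) in which a term survived
elimination; all levels of a categorical term share its stability. Mean
coefficients and percentile 95% intervals (linear-interpolation quantile
rule) are computed per level over only the replicates in which the term was
selected and the level present; a level emptied by resampling contributes no
coefficient (absent, not zero). The bootstrap p-value is one minus the
proportion of selected-replicate coefficients on the side of zero where
their mean lies; exact zeros count toward the minority side, making the
value conservative. The selection filter keeps terms with stability > 10%
and bootstrap p < 0.025, both strict, and keeps all levels of a kept term
together.

B defaults to 1,000; the test suite and acceptance script exercise the same
code path at B = 25–200 to keep runtimes in seconds-to-minutes on one CPU.
A full default analysis (B = 1,000, two outcomes, ~330 records) takes on
the order of ten minutes.

## Synthetic herd generator

The generator emulates the study population: 56 farms × 6 samples by
default. Management practices (cleaning chemistry and frequency, hot-water
use, milking system, freezing, pasteurisation, pen clean-out interval) are
drawn once per farm — questionnaire protocols are farm properties — while
the collection point is drawn per sample from the observed marginal shares
(17.8% teat, 36.3% bucket, 24.4% feeding teat, 21.6% tube). Practice levels
are drawn from the observed marginal frequencies renormalised over the
applicable levels, and structural applicability is then enforced per record
(teat collection forces all equipment variables to "Not applicable"; bucket
collection forces the feeding-equipment variables), which reproduces the
marginal "Not applicable" shares in expectation. A `covariate_sharing =
"sample"` option draws practices independently per sample instead; it
exists because farm-level draws necessarily induce chance herd-level
confounding between covariates and farm random effects in any single
realisation, which matters when a covariate is meant to act as a true null
in calibration experiments.

Counts are built from the latent log scale as `max(0, round(exp(y) - 1))`,
so the analysis transform recovers the latent value within the integer
rounding bound. Coliform counts are generated from their own intercept
(default 1.0 log cfu/ml vs 6.3 for TBC) and farm effects, then replaced by
structural zeros with probability 0.40, reproducing the observed excess of
zero coliform counts (roughly 40–75% zeros depending on collection point,
highest for teat-collected samples whose latent counts are smallest). The
pen clean-out interval is uniform on [3.5, 90] days, the observed range.
Default effect sizes are the management effects reported for TBC in the
56-farm study (robot +3.38, feeding equipment +2.36, hot water −2.54,
pasteurisation −3.79 log cfu/ml, ...), and the default variances
theta_U = 2.0, theta_eps = 4.0 were chosen once so the marginal log-TBC
standard deviation is ~3.3 log cfu/ml, the study's reported value.

What the generator does **not** emulate: laboratory measurement error,
cryopreservation and transport effects, correlations between practices
(practices are drawn independently), seasonal or within-farm temporal
structure, and any non-Gaussian residual behaviour beyond the CC zero
excess. Passing recovery and separation tests therefore demonstrate the
estimator and selection machinery are correct under the assumed model, not
that the model captures every feature of real colostrum data.

## Diagnostics

Cross-validation is record-level repeated k-fold (default 10×10): held-out
predictions use the fixed part plus the training-fold BLUP
`u_j = lambda*n_j/(1 + lambda*n_j) * rbar_j` for farms seen in training and
zero otherwise. R² is defined as 1 − SSE/SST over the held-out records (it
may be negative) and MAE is on the log scale; both are computed per repeat
over the pooled out-of-fold predictions and averaged. Exactly-zero residual
variance is a degenerate input for an ML fit (the profile likelihood is
unbounded), so "noise-free" test scenarios carry a 1e-5 jitter.

The correlation screen reports Pearson correlations over the numeric design
encoding and the maximum absolute correlation across distinct variables
(within-term dummy correlations are structural and excluded from the
maximum). The interaction screen compares, per pair of selected terms, the
ML fits with and without the product block by likelihood-ratio test against
a chi-square with df equal to the number of independent added columns;
structurally confounded pairs (no independent added column) are skipped.
Its type-I error is calibrated at the nominal 5% in simulation.

The power calculation is the conventional two-sided two-sample
normal-approximation with equal allocation:
`power = Phi(|delta| / (sd*sqrt(2/(n/2))) - z_{1-alpha/2})`. At the study's
size (sd 3.3 log cfu/ml, delta 1.0, n 328, alpha 0.05) it evaluates to
0.783 — a ~78% chance of detecting a 1-log change, commonly rounded to 80%.

## Numerical and reporting conventions

Percentages in descriptive tables are rounded half-up to one decimal;
display tables round coefficients and intervals to two decimals and
stability to one, with p-values below 0.01 shown as "<0.01". Failure
thresholds are strict inequalities (a count exactly at threshold passes).
Missing data are removed, never imputed, with per-rule exclusion tallies in
a `PreprocessReport`.

## Known limitations

- Record-level bootstrap understates clustering uncertainty relative to a
  farm-level bootstrap; the bootstrap p-value measures sign consistency of
  an association *within one realised dataset*, so covariates whose realised
  association is non-trivial — including chance herd-level confounding —
  can show low p and moderate stability despite a null generative effect.
- The AIC deletion rule is liberal (for one added parameter it corresponds
  to retaining at roughly p < 0.157), so low-stability terms are retained in
  an appreciable share of replicates by chance.
- Single random-effect level only: no crossed or nested random effects, no
  non-Gaussian (e.g. zero-inflated count) likelihoods — the CC zero excess
  is handled by the log transform and the bootstrap, not modelled.
- Percentile (not bias-corrected) bootstrap intervals.
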