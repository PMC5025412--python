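# Methods

This note documents the models, numerical choices and synthetic-data
design behind `dcequip`, and what the test suite does and does not
establish.

## Random-utility model and data layout

Choice data are a long-format panel: one row per (respondent, choice
set, alternative), exactly two alternatives per set (a candidate
program and a fixed comparator common to every set), exactly one chosen
row per set. Utility is `U_nit = β_n' x_nit + ε_nit` with i.i.d. type-I
extreme-value errors, giving multinomial-logit choice probabilities and
a product-form sequence probability per respondent. An
alternative-specific constant (ASC) is coded 1 on the candidate and 0
on the comparator; it absorbs any systematic tendency to accept or
reject change relative to the fixed comparator and is always treated as
a fixed (non-random) coefficient.

Categorical attributes are effects coded: an L-level attribute yields
L−1 columns, non-reference levels code +1 on their own column, the
reference level codes −1 on every column, so level effects sum to zero
and a balanced design's coded columns sum to zero over runs. The money
attribute (annual remuneration increase) enters as a single column in
raw euros; every downstream consumer of the money coefficient
(`β_w`, compensating variations) therefore works on the euro scale.
Bundled reference levels: payment method relative to *forfait*+FFS
(columns `forfait`, `p4p`), guidelines relative to none, and +1 =
{monthly payment, yes, solo practice} for the two-level attributes.
These conventions are configurable per `CodingSpec`.

## Design generation

The full factorial of the bundled eight-attribute table has
3·3·2·3·2·2·2·2 = 864 profiles; respondents can only be shown a small
fraction. `generate_fractional_design` draws an exactly level-balanced
starting design (each level of an L-level attribute appears n/L times
when L divides n; otherwise best-effort with a recorded warning) and
runs a seeded keep-best search over within-attribute pairwise swaps.
The objective is lexicographic: minimise the maximum absolute
correlation between effects-coded columns of different attributes, with
the sum of squared correlations as tie-break (the max alone is flat
over large plateaus and stalls the search). Sideways moves are
accepted; the best design seen is kept, so the reported objective is
monotone in iterations. Default 10,000 iterations (~1 s for 24 runs);
on a tiny instance the search provably reaches the exhaustive optimum
(tested). A residual warning threshold of 0.05 on the max correlation
flags, but does not reject, designs — with three 3-level attributes in
24 runs, perfect cross-attribute orthogonality is not attainable and
the search typically settles at 0.125.

Diagnostics report per-level counts, the max absolute cross-attribute
correlation, and D-efficiency `det(X'X/n)^(1/p)` computed on
max-abs-normalised coded columns (normalisation keeps the euro-scale
money column from dominating the determinant). Constant columns are
reported as undefined-correlation pairs rather than raising.

Choice sets pair every other scenario against one fixed comparator
(24 scenarios → 23 sets). The comparator is chosen as the scenario that
a-priori dominates the fewest others under the declared preference
signs; by default only the money attribute is signed ("more is
better") — preferences over the remaining attributes are exactly what
the experiment is meant to measure, so the dominance screen makes no
assumption about them. Blocking partitions the sets uniformly at
random into blocks whose sizes differ by at most one (23 sets, 4
blocks → 6/6/6/5), seeded and reproducible.

## Estimation

All likelihoods are computed in the log domain with max-shifted
softmaxes, so tiny sequence probabilities underflow gracefully and no
explicit probability floor is needed. All fits internally rescale each
covariate column by its max absolute value (an exact
reparameterisation, undone on output) so the euro-scale money column
does not wreck optimiser conditioning.

**Conditional logit.** Newton optimisation (`trust-ncg`) with analytic
gradient and Hessian, BFGS fallback; standard errors from the inverse
observed information. A singular information matrix (separation,
non-identification) is reported as non-convergence, never as silent
estimates. The test suite cross-checks coefficients, SEs aside, against
an independent route: a two-alternative conditional logit is a binary
logit on within-set covariate differences (statsmodels).

**Mixed logit.** Independent normal mixing on a configurable subset of
coefficients; the `mn1` menu randomises everything except the ASC and
the money coefficient (11 means + 9 SDs = 20 free parameters on the
bundled coding), `mn2` fixes only the ASC (21). Only the normal mixing
distribution is implemented. The simulated likelihood uses scrambled
Halton draws — one prime per random dimension, first 10 points dropped,
consecutive blocks of R draws per respondent, default R = 500,
bit-reproducible given the seed — generated once per fit and shared
across all evaluations. Optimisation is BFGS on the analytic simulated
score (means start at the conditional-logit fit, SDs at 0.1 in scaled
space; gradient tolerance 1e-6 in the scaled parameterisation). SDs are
estimated unconstrained and reported as absolute values (the likelihood
is symmetric in each SD's sign); sign-flipped SDs are listed on the
estimate. Standard errors are BHHH (outer product of per-respondent
scores), the standard choice for maximum simulated likelihood.

**Conditional (posterior) coefficients.** Per respondent,
`E[β|choices]` is the self-normalised importance average of the fit's
own Halton draws weighted by the respondent's sequence probability; a
Monte-Carlo error is reported from the weighted variance and effective
sample size. With all SDs zero every respondent's conditional mean is
the population mean (tested), and in one dimension the estimate agrees
with dense-grid posterior integration to 2 decimals (tested).
`share_sign` returns both estimands of "share of respondents valuing
attribute k positively": the population share Φ(mean/SD) under the
fitted normal, and the empirical share of positive conditional means.
The two differ by construction — the conditional means shrink towards
the population mean as T is small — so both are always reported.

**Latent-class logit.** EM with seeded restarts (default 50; sweeps in
the demo pipeline use fewer): the E-step computes posterior
memberships, the M-step re-fits each class by weighted conditional
logit (full inner maximisation, so the likelihood trace is monotone —
asserted on every run and recorded per restart), shares update to mean
posteriors. Stops at LL change < 1e-7 or 2000 iterations; a class
share falling below 1e-4 flags the restart. Classes are canonically
ordered by descending share. Class-share parameters are constant-only
(no membership covariates). Free parameters: C coefficient vectors of
length 11 plus C−1 shares, i.e. 12C−1 (47 for four classes). t
statistics come from the BHHH covariance of the full-mixture
per-respondent score (class coefficients plus C−1 share logits); they
are asymptotic and, as in any finite mixture, conditional on the
estimated labelling.

**Model selection.** AIC = 2k − 2LL, BIC = k ln N − 2LL,
CAIC = k(ln N + 1) − 2LL. The sample-size convention for BIC/CAIC is
the caller's choice; both alternative-row counts (N = 2·ΣT_n) and
respondent counts are in published use — the pipeline default is
respondents for the latent-class sweep and rows for the mixed logit,
matching the conventions the bundled goodness-of-fit identities verify.
Ties in the criterion go to the smaller class count.

## Welfare simulation

A policy profile declares a level for each attribute it includes;
omitted attributes (distinct from a "No" level of a yes/no attribute)
are masked and contribute zero utility. Continuous attributes accept
raw euro values off the design grid (the bundled baseline program pays
€4,200). Indirect utility applies a two-sided significance filter at
α = 0.05 (configurable; α = 1 disables filtering) to the subgroup's
coefficients before the dot product: a subgroup indifferent to an
attribute gains nothing from changing it. The ASC is excluded from
policy utilities.

Subgroups: the whole sample (mixed-logit means), sign-based subgroups
(mean of members' conditional coefficient vectors, with the
population-level t statistics as the filter source), and latent
classes (class coefficients and class t statistics). Each subgroup's
marginal utility of income `β_w` is the magnitude of its own money
coefficient; the magnitude rather than the signed value is used by
default so that rows with a negative money coefficient keep a
comparable CV orientation (switchable). CV against the baseline uses
the two-option formula; the logsum form is provided for multi-option
states and reduces to it exactly on singletons. Scale invariance
(jointly rescaling coefficients and β_w leaves CV unchanged),
antisymmetry and zero-at-baseline are property-tested.

The benchmark "maximum satisfaction" program is constructed
programmatically: each attribute set to the level maximising the
filtered utility, attributes whose every coefficient is filtered out
left absent, and the money attribute pinnable to a fixed budget.

## Synthetic populations

Two bundled fixtures drive tests and demos. The continuous fixture
(`mn1_like_population`) uses coefficient magnitudes typical of a GP
quality-program experiment: money ≈ 1.55e-4 per euro (≈ +0.65 utility
for a €4,200 raise), mild mean dislike of forfait and
pay-for-performance with strong heterogeneity concentrated on P4P and
NPP assistance (SDs ≈ 0.9–1.0), positive education/feedback effects,
and a homogeneous ASC. The discrete fixture (`four_class_population`)
preserves the sign pattern of four physician archetypes but divides the
two extreme classes' coefficients by 10 and clips non-money magnitudes
at 2.5: at the raw archetype magnitudes (up to ≈46) choices are
deterministic and estimator behaviour degenerates, so testability is
preferred over verisimilitude. A two-class 0.6/0.4 mixture with
well-separated vectors supports mixture-recovery checks.

Choice simulation adds inverse-CDF Gumbel noise from an RNG stream
separate from the preference-drawing stream and takes the arg-max, so
empirical choice frequencies converge to the closed-form logit
probabilities (tested at Monte-Carlo accuracy). Respondents are
assigned to blocks round-robin by default, giving 5 or 6 choice sets
each on the bundled design (mean T ≈ 5.75).

What the synthetic data do **not** emulate: non-response and selection,
lexicographic or inattentive response styles, violations of the i.i.d.
extreme-value error assumption, and correlation between random
coefficients. Passing recovery tests therefore shows the estimators
are correct under their own assumptions, not that those assumptions
hold in any particular survey.

## Problem sizes and tolerances

Recovery checks run at the study scale the package targets: 500
respondents / 200 Halton draws / 9 random coefficients for the mixed
logit (every mean and SD within 3 SEs of truth), 600 respondents for
the two-class mixture (shares within 0.05, coefficients within 3 SEs
after label matching). The null-data check uses the multiplicity-aware
0.1% two-sided critical value across its 11 simultaneous z statistics.
Oracle equivalences are exact identities (simulated likelihood with
zero SDs equals the conditional logit for any draw count) or tight
numerical ones (Gauss–Hermite quadrature to 1e-3 in one dimension;
one-class EM to 1e-4 in LL). The demo pipeline uses 150 respondents,
100 draws and 3 EM restarts per class count.

## Known limitations

* Mixing is independent-normal only; no log-normal, correlated, or
  willingness-to-pay-space specifications.
* The design search optimises linear-model orthogonality, not
  D-optimality under the logit criterion, and supports neither
  partial profiles nor opt-out alternatives (the fixed-comparator
  forced-choice format deliberately has none).
* BHHH covariances are first-order asymptotic; simulation noise in the
  mixed logit adds draw-count bias that the fixed-draw design controls
  but does not eliminate.
* Published welfare tables built from rounded coefficients cannot be
  reproduced cell-for-cell; the package instead verifies their internal
  consistency (a constant implied money coefficient across a row) and
  all structural properties of the CV calculus.
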