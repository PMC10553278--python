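# Methods

## The valuation problem

A discrete choice experiment (DCE) asks respondents to choose repeatedly
between hypothetical service profiles described by attributes with varying
levels. Under random utility theory each alternative `j` in choice set `s`
carries utility `U_sj = V_sj + ε_sj`, with deterministic part
`V_sj = β·x_sj` linear in the encoded attributes and `ε_sj` i.i.d. type-I
extreme value (standard Gumbel). The choice probability is then the
conditional logit `P(j|s) = exp(V_sj)/Σ_k exp(V_sk)`. With a monetary
attribute in the utility index, coefficient ratios convert preference
weights into money: here cost is framed as annual cost to the NHS, so the
ratios are willingness-to-accept (WTA) values — the public compensation at
which a respondent is indifferent to a service change.

The package instantiates the attribute space of a pharmacy–primary-care
collaborative management survey: four categorical attributes with three
levels each (level 1 = usual care, used as the dummy-coding reference) and
a four-level cost attribute treated as continuous (0, 30, 51, 76 €/yr) so
that the WTA ratio `β_x/β_cost` is defined with a single cost coefficient.

## Experimental design

The full factorial holds `3^4·4 = 324` profiles and `324·323/2 = 52,326`
unordered pairs, far beyond what respondents can answer, so a fraction is
selected by a Fedorov-style exchange: start from a random set of profile
rows, and repeatedly perform the single best swap of an in-design row for a
candidate profile while the determinant criterion improves (the classic
delta update `Δ = d(c) − d(x) − [d(c)d(x) − d(c,x)²]` avoids refactoring),
with configurable random restarts (default 10) and a 10,000-swap cap. By
default `2·n_sets` profiles are selected in one run and randomly paired
into two-alternative sets (identical-profile pairs rejected by
re-shuffling); a `paired_fractions` flag instead selects two independent
fractions of `n_sets` profiles and pairs them A-against-B. Sets are then
allocated at random into equal-sized blocks (questionnaire versions;
default 9 blocks of 4). Every stochastic step takes an explicit seed and
the seed is recorded in the `Design`.

Dominated pairs (one alternative at least as good on every attribute) are
*not* filtered: the orthogonal/efficient construction is kept as is, which
trades a risk of occasionally easy choices for lower statistical error.

### D-efficiency normalization

D-efficiency is `|X'X/N|^(1/p)` on a coded model matrix. The coding
matters. The package computes efficiency on the standard
*design-generation* coding — an intercept plus orthonormal main-effect
contrasts, treating every attribute (including cost) as qualitative — and
reports it relative to the level-balanced orthogonal ideal (uniform levels,
independent attributes), whose moment matrix is diagonal under this coding.
For main-effects models over a product space the uniform design is
D-optimal in this coding, so relative efficiency is guaranteed to lie in
(0, 1], and a design that is exactly balanced and orthogonal scores 1.0.

The *analysis* coding (dummies + continuous cost) is deliberately not used
for efficiency: under dummy coding the uniform/orthogonal ideal is not
D-optimal (already for two 2-level attributes, rows split between the
profiles (1,0) and (0,1) give `det(X'X/N) = 0.25` against the ideal's
0.1875), so a "relative efficiency" normalized that way can exceed 1 and
the scale loses its meaning. On the study's 3^4×4 space the exchange search
reaches relative efficiency ≈ 0.99–1.00, comfortably above the 93%
reported for the original catalogue-generated design.

### Sample-size rule

The Johnson–Orme rule of thumb is implemented as `N = ceil(500c/(t·a))`
with `c` the largest level count, `t` tasks per respondent and `a`
alternatives per task — at (4, 4, 2) this gives the study's minimum of 250
respondents. (The rule is a heuristic for main-effects stability, not a
power calculation.)

## Estimation

The conditional-logit log-likelihood
`LL(β) = Σ_s [V_chosen − ln Σ_j exp(V_sj)]` is globally concave; it is
maximized by damped Newton–Raphson with analytic gradient and Hessian
(start at β = 0, step-halving line search, tolerance 1e-8 on the gradient
max-norm, cap 200 iterations, BFGS fallback). Per-set log-sum-exp keeps the
likelihood finite for any finite inputs. The coefficient covariance is the
inverse observed information at the optimum, matching the model-based
standard errors of the stratified partial-likelihood route the original
analysis used; the test suite verifies agreement of coefficients,
likelihood and covariance with an independent implementation
(statsmodels' conditional logit) and with a hierarchical grid-search oracle
on tiny instances.

Identification is checked before optimization: covariates that never
differ within choice sets, rank deficiency of the within-set differenced
design, and (quasi-)separation are all surfaced as errors naming the
offending columns. Separation — a direction `w` with
`(x_chosen − x_other)·w ≥ 0` in every set and `> 0` in some — makes the MLE
diverge; it is detected exactly by a small linear program rather than by
waiting for non-convergence.

Model fit is the likelihood-ratio statistic `χ² = 2(LL_full − LL_0)`
against the null of indifferent choice (`LL_0 = −n_sets·ln 2` for forced
two-alternative sets) on `p = 9` degrees of freedom. Under a simulated null
the test's type-I error is verified ≈ 5%.

Coefficient CIs use a percentile cluster bootstrap resampling whole
respondents with replacement at the original cohort size (choices within a
respondent are dependent), 1,000 replications by default; failed refits
(separation in a resample) are skipped and counted, with an error above
20% failures. The three published analysis columns (All / Intervention /
Control) are reproduced as separate fits on the group-filtered data — group
is a filter, not an interaction — and demographic covariates are
deliberately absent from the model, as in the original analysis.

## Welfare and cost-benefit analysis

Marginal WTA for a level is `β_level/β_cost` in €/yr. The *plain* ratio is
the default sign convention because under the cost-to-the-NHS (WTA)
framing the cost coefficient is expected non-negative and the published
table uses the plain ratio throughout; the conventional `−β/β_cost` sits
behind a `negate` flag. WTA is computed even when `β_cost` is not
significant — as the original analysis did — but every estimate then
carries an explicit warning; an exactly zero `β_cost` raises instead of
returning infinity.

Krinsky–Robb CIs draw coefficient vectors from `N(β̂, V̂)` using an
eigen-factorization of the full covariance (valid for singular/zero
covariances, where the CI correctly collapses to the point estimate),
recompute the ratio per draw, and take percentiles; draws with
`|β_cost| < 1e-12` are rejected and redrawn. Non-PSD covariances raise,
with an opt-in projection onto the nearest PSD matrix.

Relative importance of an attribute is its utility range (max − min level
utility, reference = 0) over the summed ranges, restricted by default to
attributes with at least one level significant at p < 0.05. Note the
published importance percentages (57/25/18) are not reproducible from the
published coefficients via this range formula, which yields ≈ 43/33/23 for
the pooled column; the package follows the stated formula, reproduces the
*ordering* (waiting time > pharmacy model > integration), and treats the
printed percentages as unverifiable.

Scenario welfare uses log-sum compensating variation,
`CV = (1/β_cost)[ln Σ_j e^{V_j¹} − ln Σ_j e^{V_j⁰}]`; for single-alternative
states at equal cost this reduces exactly to the summed marginal WTAs
(tested as an identity on random coefficient vectors). With the
intervention-arm coefficients and the most/least preferred bundles the
total is €877.00/yr, and net benefit — total WTA minus the €88.80/yr
incremental programme cost supplied as a config constant from the
companion costing study — is €788.20/yr. Euro amounts are rounded
half-up to 2 decimals at presentation only.

## The simulator

`simulate_choices` draws from the model's exact data-generating process:
each respondent is randomly assigned one questionnaire block, answers all
its sets, and picks the alternative maximizing `β·x + Gumbel` with errors
generated by inverse CDF `−ln(−ln U)` from a seeded stream, one per
alternative per set, independent throughout. Defaults mirror the study
conditions: 78 intervention + 44 control respondents, 4 sets each from 9
blocks, forced choice, group-specific true coefficients (the published
columns) rather than covariate shifts. Dominant-responder contamination
overwrites a chosen fraction of respondents to always pick the best level
of one attribute whenever exactly one alternative carries it.

What the simulator does *not* emulate: scale heterogeneity or any
departure from i.i.d. Gumbel errors, preference heterogeneity within a
group, item non-response, and interviewer effects. Passing tests therefore
certify the estimator and welfare machinery under the model's own
assumptions, not robustness to their violation in real survey data.

The dominance screen counts a respondent as dominant when they chose the
best-level alternative in *every* informative set (exactly one alternative
carries the best level; other sets are skipped, and respondents with no
informative set are never flagged). With only 4 sets per respondent the
screen has a substantial chance-flagging rate — `(1/2)^k` for `k`
informative sets — so recovery tests compare flagged counts against the
injected fraction plus this analytically computed false-positive rate.

## Problem sizes used in the checks

Parameter-recovery checks use 500–2,000 simulated respondents (recovery
within 3 standard errors); the LR type-I error uses 500 null replicates at
the study's 122-respondent cohort; the bootstrap coverage study is scaled
to 25 replicates × 60 resamples at 120 respondents; Krinsky–Robb bounds
are validated against a 200,000-draw direct simulation of the normal-ratio
distribution. The exchange search uses 10 restarts at the study scale.

## Known limitations

- The raw individual-level choices were never deposited, so the published
  coefficient columns themselves cannot be re-derived; they enter as a
  fixture (with standard errors reconstructed from the printed p-values,
  diagonal covariance — a synthetic stand-in clearly separate from a
  fitted covariance) and as generating values for the simulator.
- The published log-likelihood-ratio figures (e.g. 3113.86 for the pooled
  fit) are inconsistent with the reported χ² values and forced-choice null
  likelihood and are not reproduced.
- Blocked designs are scored on their pooled alternative rows; block-level
  balance is not part of the efficiency criterion.
- No mixed logit / latent-class extensions: preference heterogeneity
  beyond the intervention/control split is out of scope.
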