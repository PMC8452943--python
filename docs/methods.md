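# Methods

This note documents the statistical procedures implemented in cdmkit, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter for
reproducibility.

## Latent structure and estimation

An examinee is a length-K binary mastery pattern α; with K attributes
there are 2^K latent classes, indexed canonically so that attribute 1 is
the fastest-varying bit (class c has α_k = bit k of c).  Responses are
locally independent given the class: P(X_i | c) = Π_j P_j(c)^{X_ij}
(1−P_j(c))^{1−X_ij}, where P_j(c) depends on c only through item j's
reduced pattern.  The structural model is a saturated multinomial over the
2^K classes (2^K − 1 free proportions): with large samples and K ≤ 7-8 this
avoids committing to a higher-order or independence structure and lets
pattern-prevalence tables be read straight off π.

Marginal maximum likelihood is computed by EM:

* **E-step** — class posteriors from the current item probabilities and π,
  computed in log space with a log-sum-exp normalization (posterior rows
  sum to 1 within 1e-10 by construction).
* **M-step, G-DINA** — each reduced class's success probability is the
  posterior-expected number correct over the posterior-expected membership
  in that class: the closed-form maximizer.  Delta coefficients are
  recovered on demand through the invertible identity-link design matrix.
* **M-step, DINA/DINO** — the same ratio after pooling the reduced classes
  into the two groups the model distinguishes.
* **M-step, RRUM** — L-BFGS-B maximization of the expected complete-data
  log-likelihood over logit(π*), logit(r*) starting from the current
  values, accepted only when it improves the objective (a generalized EM
  step).  This keeps the observed-data log-likelihood non-decreasing for
  every model, which the test suite asserts iteration by iteration.

Defaults: convergence when the largest absolute change in any item
probability or mixing proportion falls below 1e-4 (reporting precision in
diagnostic tables is 1e-2), at most 1,000 iterations; probabilities kept in
[1e-4, 1−1e-4] during estimation so likelihoods stay finite — invisible at
reporting precision but it means "boundary" estimates print as 0.00/1.00
while being 1e-4 off internally.  The default start is deterministic
(item probabilities spread 0.2 → 0.8 along mastered-attribute count, π
uniform), so default pipelines are bit-reproducible.  Monotonicity of the
item response function in the number of mastered attributes is *not*
imposed by default — saturated fits to real data are routinely
non-monotone — but a weighted pool-adjacent-violators projection is
available (`EMConfig(monotone=True)`).

Missing responses are rejected rather than imputed: the intended data are
complete multiple-choice records, and silent listwise or model-based
handling would change the estimand.  Standard errors are not computed.

Model comparison: AIC = −2LL + 2p and BIC = −2LL + p·ln N with p the item
parameter count (Σ_j 2^{K*_j} for G-DINA, 2J for DINA/DINO,
Σ_j (1 + K*_j) for RRUM) plus 2^K − 1 structural proportions.  The
likelihood-ratio test accepts only genuinely nested pairs
(DINA/DINO/RRUM inside G-DINA on the same data and Q-matrix) and uses a
chi-square reference on the parameter-count difference.

## Q-matrix validation

For each item, a saturated success-probability vector over all 2^K classes
is read off the fitted model's posterior (expected correct / expected
membership per class — the M-step estimate with the item treated as
requiring every attribute).  For a candidate q-vector the discrimination
index ς² is the π-weighted between-group variance of these probabilities
after collapsing classes into the candidate's reduced groups; PVAF is the
ratio to the full vector's ς².  The selected q-vector is the one with the
fewest attributes reaching the cutoff (0.95 by default), ties broken by
larger PVAF then lexicographic order.

**Finite-sample correction.**  The plug-in PVAF is biased when 2^K is
large relative to N: each class mean carries sampling variance
≈ P̄_c(1−P̄_c)/(N·w_c), and the full-attribute vector — which collapses
nothing — absorbs all of that noise into its ς².  At K = 7 and N = 2,000
(~16 expected examinees per class) this pushes the PVAF of the *true*
q-vector down to ~0.93-0.97, below any high cutoff.  The package therefore
subtracts the expected noise content, Σ_g P̄_g(1−P̄_g)/N, from every
between-group variance before forming the ratio (clipping the ratio to
[0, 1]).  With the correction the true q-vector's PVAF sits at ~1.0 and
validation behaves like its population version.  The raw ς² values are
still reported in the per-item tables.

**Limits of the rule.**  With the correction in place, remaining changes
to correctly specified items are dominated by items that are *genuinely*
near-degenerate: when a multi-attribute item's interior probabilities are
drawn at random (see the generator below), roughly one draw in nine
produces an item whose population PVAF for a proper sub-vector already
exceeds 0.95 — the rule then simplifies it, correctly by its own
criterion.  This is why the revised matrix is advisory output: the change
log and PVAF tables are returned for domain review, and the pipeline only
adopts the revision behind an explicit flag.

DFL discretization uses absolute loadings against the row mean of absolute
loadings, with ties passing: the sign of a loading is rotation-dependent,
and the row maximum must always survive so every item keeps at least one
attribute.

## Item fit, classification, reliability

Model-implied ("predicted") moments are computed analytically from the
fitted mixture — E[X_j] = Σ_c π_c P_j(c), E[X_j X_j'] = Σ_c π_c P_j(c)
P_j'(c) — rather than by simulating prediction data: the expectation is
identical and Monte-Carlo noise would only blur the residuals.  The three
statistics are l = |log OR_obs − log OR_pred| per item pair (zero observed
cells get +0.5 added to all four cells, flagged), r = |Z(corr_obs) −
Z(corr_pred)| with correlations clamped to |ρ| ≤ 1−1e-6 before the Fisher
transform, and p = |mean_obs − mean_pred| per item.  Note that for the
saturated model p is ~0 at any sample size (the M-step matches item means
by construction); l and r are the informative residuals.  Significance
flags use asymptotic z-tests — SE(log OR) from inverse observed cell
counts, SE of a Fisher z as 1/√(N−3), binomial SE for proportions — with
the Bonferroni family taken as all J(J−1)/2 pairs per pair statistic and J
items for p.  "SE at max" in the summary is the asymptotic SE at the pair
or item achieving the maximum, which is one reasonable reading of a
summary column whose definition is not standardized.

Classification: EAP is the posterior mean mastery probability per
attribute; MAP the posterior-modal pattern (ties to the lowest class
index, deterministic, with the tie count recorded); MLE the
likelihood-modal pattern.  Classification accuracy is posterior-based:
test level = average posterior mass at the MAP pattern; attribute level =
average posterior probability that each MAP attribute call is correct;
pattern level = the test-level average conditioned on the MAP assignment
(patterns with fewer than 30 examinees are flagged low-support).  Kappa is
reported in "truth" mode (MAP vs simulated truth) when a ground truth
exists and otherwise as the chance-corrected posterior self-consistency,
with the mode recorded — the two usages answer different questions and
must not be conflated silently.

Group mastery profiles average EAP probabilities (proportions of MAP
masters are emitted alongside); the high/low split is a median split on
raw total score by default, with the quantile configurable — a
convention, not an estimate, and flagged as such.

Tetrachoric correlations fix the normal thresholds at the margins and
solve Φ₂(τ_x, τ_y; ρ) = P(0,0) by Brent's method (the ML estimate under
margin-matched thresholds); a zero cell triggers a +0.5 continuity
correction with a warning, and a constant column yields NaN (undefined).

## Synthetic data generator

The generator emulates a 40-item, 7-attribute diagnostic test: one
single-attribute item, two four-attribute items, and the rest
two-attribute items cycling through all attribute pairs.  Attributes are
independent Bernoulli(0.5) by default; an equicorrelated latent-normal
option induces dependence with the marginal held fixed.  Item truth pins
P(no required attribute) = g and P(all required) = 1 − s, with interior
reduced classes drawn uniformly on (g, 1−s) and sorted non-decreasing in
mastered-attribute count.  The saturated default is deliberate: fixing
only the endpoints leaves real interaction structure in the truth, which
is what makes the constrained models distinguishable from the saturated
one — under pure conjunctive generation DINA would be correctly specified
and nothing could separate the models.  Pure DINA generation remains
available as an option.

What the generator does **not** emulate: realistic attribute prevalence
profiles (real cohorts concentrate on few patterns; the default is
uniform), item-quality heterogeneity beyond the uniform interiors,
response dependence beyond the latent classes (speededness, testlets), and
any content structure.  Passing simulation tests therefore demonstrates
estimator correctness under the model's own assumptions, not robustness to
their violation.

The reference comparison study uses N = 2,000 examinees, J = 40, K = 7,
guess = slip = 0.1, 10 replications, fitting all four models per
replication (about half a minute single-threaded; the E-step is a dense
N×2^K matrix product).  Recovery is summarized by RMSE (per-replication
root mean square over items, averaged over replications) and MAE —
RMSE ≥ MAE holds within every replication by Jensen's inequality and is
asserted — plus PCA (attribute-level agreement), PCV (whole-vector
agreement) and the partial-match curve P_m (share of examinees with at
least m attributes recovered), which is non-increasing in m by
construction.  One master seed spawns independent per-replication
substreams, all recorded in the report.

Under this design the saturated model attains the highest classification
accuracy (PCA ≈ 0.96, PCV ≈ 0.76) and the best AIC/BIC; RRUM follows
(PCA ≈ 0.94) and the two-parameter conjunctive/disjunctive models trail
(PCA ≈ 0.79-0.80) with essentially tied accuracy — their single split of
the reduced classes discards the interaction information the truth
contains.  Guess/slip recovery for the saturated model sits well inside
the conventional 0.05 RMSE cutoff.

## Known limitations

* Dichotomous responses only; no polytomous models, no ACDM/LLM/sequential
  family members, no attribute hierarchies.
* No standard errors or limited-information absolute fit statistics
  (M2-family RMSEA/SRMR).
* The saturated structural model needs N ≫ 2^K to estimate π well; a
  warning is emitted when N < 2^K.
* PVAF-based Q-validation inherits the cutoff's arbitrariness; 0.95 is
  the package default, and the advisory-output design expects a human in
  the loop.
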