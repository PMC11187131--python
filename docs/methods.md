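# Methods

## Model

The two-high-threshold (2-HT) eyewitness identification model is a
multinomial processing tree over the three observable lineup responses
(suspect identification, filler identification, rejection), with one
culprit-present and one culprit-absent tree per experimental group. Its
parameters are probabilities in [0, 1]:

| parameter | meaning | default treatment |
|---|---|---|
| dP | detection of the culprit's presence (culprit-present trees) | free per group |
| dA | detection of the culprit's absence (culprit-absent trees) | free; equated across groups in the base model |
| b  | biased selection of the suspect | free; equated across groups in the base model |
| g  | guessing-based selection of some lineup member | free per group |
| 1/n | probability that a guess samples the suspect in a lineup of size n | constant |

The model assumes the two detection states are high-threshold (detection
is never erroneous), that bias and guessing operate only when detection
fails, and that responses are independent multinomial draws per tree.
Each participant contributes two culprit-present and two culprit-absent
responses; treating those as independent trials is the convention of the
reference analyses and is shared by the z-tests below.

Sampling constants default to the 5-decimal truncations 0.33333 (n = 3)
and 0.16667 (n = 6) so that fits of the bundled data reproduce the
published statistics bit-for-bit; `GroupSpec(..., exact=True)` substitutes
the exact rational 1/n for new analyses.

The base model for the bundled 2×2 designs (lineup size three/six ×
low-culprit-probability/neutral instructions) has 10 free parameters
against 16 independent category proportions, giving 6 df. A numerical
Jacobian-rank check (`check_identifiability`) confirms local
identifiability.

## Estimation

The joint multinomial log-likelihood is maximized in three stages per
start: (1) EM — the E-step distributes each observed category count over
the branches ending in that category proportionally to the branch
probabilities; the M-step sets every free parameter to expected successes
over expected trials across all branches in which it appears in either
orientation; stops when the relative log-likelihood change is below 1e-10
or after 10 000 iterations; (2) L-BFGS refinement on the logit scale;
(3) a bounded L-BFGS-B polish on the natural scale with box
[1e-8, 1 - 1e-8], so that boundary optima land exactly on the clamp.
Optimizer tolerances are set tight (ftol 1e-14, gtol 1e-10): with scipy's
defaults the polish stops ~0.02 log-likelihood units early, which leaves
boundary solutions at interior values around 1e-4 and silently corrupts
their standard errors. Ten seeded random starts (first start at 0.5
throughout) are run by default; if their best log-likelihoods disagree by
more than 1e-6 a warning is attached. Ties break to the lowest start
index. Equality classes are fitted as a single underlying parameter;
fixed values are folded into branch constants before optimization.

Standard errors are square roots of the diagonal of the inverse observed
information (central finite-difference Hessian of the negative
log-likelihood, step 1e-5) on the natural probability scale. Estimates on
the [0, 1] clamp are flagged as boundary solutions and their SEs
suppressed, since the quadratic approximation is meaningless there. With
all bundled fits interior, observed and expected information agree to the
printed precision of the reference tables.

G² = 2·Σ obs·ln(obs/expected) over all categories; zero observed counts
contribute 0 (the x·ln x → 0 limit), and a zero expected probability with
a positive observed count yields +inf. Nested tests refit the restricted
model from a fresh multistart (never warm-started from the base solution,
to avoid optimizer-path artifacts) and refer ΔG² to a central chi-square
with df equal to the number of parameters removed (1 for all bundled
plans).

## Observable rates and sensitivity

Identification rates are simple proportions of lineup responses with Wald
95% intervals (Wilson available as an option); the two-proportion z-test
uses the pooled variance estimate, two-sided, without continuity
correction — the only convention that reproduces all four published z
values. Within-participant dependence between the two responses per tree
is ignored by construction; a clustered alternative is out of scope.

The sensitivity analysis solves for the noncentrality λ at which a
chi-square test with level α attains power 1-β (bracketed root-find on
the noncentral chi-square survival function, bracket [1e-6, 100] with
doubling expansion, tolerance 1e-10) and reports the minimum detectable
effect size w = sqrt(λ/N), N the total number of responses. λ does not
depend on N, so w scales exactly as N^(-1/2).

## Synthetic data and parameter recovery

`simulate_frequencies` draws one multinomial sample per tree from the
model's category probabilities — exactly the data-generating assumption
of the analysis. Defaults emulate the first bundled experiment: the four
size-by-instruction groups, 504 responses per tree (252 participants × 2
lineups of each type), and the experiment's base-model estimates as the
generating point. Per-tree random substreams are derived from the design
seed and a hash of the tree name, so group order cannot change the draws.

What the generator does **not** emulate: participant-level clustering
(two responses per participant per tree are simulated as independent),
last-selection-wins response recoding, attention-check exclusions, and
any stimulus-level heterogeneity. Passing recovery tests therefore show
that the estimator is consistent and well-calibrated under the model's
own assumptions, not that those assumptions hold in real lineup data.

`parameter_recovery` simulates, refits the base model per replication,
and reports bias, empirical SD, mean model-based SE, and 95% Wald-interval
coverage per parameter. Coverage is computed over replications with an
available SE: with a generating value of dA = 0.03 about a quarter of
replications put the dA estimate on the boundary, where no SE exists; for
the interior replications the Wald intervals are well calibrated. The
validation suite runs 200 replications at the default design — large
enough that a coverage estimate has a binomial SE of ~1.5 percentage
points while the whole battery stays desk-scale.

## Numerical and design choices

- Half-up rounding is used when comparing computed statistics to
  published values at printed precision; p-values are kept at full
  precision internally.
- `FrequencyTable` keys trees as `"<group>.<tree>"`; category order is
  (suspect/culprit identification, filler identification, rejection)
  throughout the packaged writers.
- The EQN emitter writes tree-qualified category names and inlines named
  constants at 5 decimals; the parser treats every symbolic name as a
  free parameter. Round-tripping a model preserves its category
  probabilities but not the distinction between named constants and
  literals.
- Showups (n = 1) are rejected by `GroupSpec`; unfair-lineup structure
  beyond the b parameter, confidence-rating/ROC analyses, and Bayesian or
  hierarchical MPT extensions are out of scope.

## Known limitations

- The observed-information SEs assume an interior MLE; parameters whose
  true values sit near 0 or 1 (dA here) will frequently hit the boundary
  at realistic sample sizes, and their interval coverage is then
  conditional on an interior estimate.
- The z-tests and the model likelihood both treat responses from the same
  participant as independent; standard errors are anti-conservative to
  the (unknown) extent of within-participant correlation.
- EQN parsing accepts only product terms of names, `(1-name)`
  complements, and numeric literals — no nested expressions.
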