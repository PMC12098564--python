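# Methods

`stagetrans` analyses two-wave panels of ordered behavior-change stages
from cluster-randomized trials. The motivating application is parental
HIV-disclosure readiness among parents living with HIV, staged under the
Health Action Process Approach (HAPA) as pre-intention < intention <
action, but nothing in the machinery is specific to that outcome beyond
the three-stage, absorbing-top structure.

## The model

Let `S2, S3 ∈ {1, 2, 3}` be the stage at the two follow-up waves and
`A ∈ {0, 1}` the trial arm. The model is a first-order *manifest* Markov
chain: the wave-3 stage depends only on the wave-2 stage (first order),
and stages are taken as measured without error (manifest — there is no
latent-class measurement layer). It is built from two multinomial
logistic regressions:

* **U1 (membership)** — `P(S2 = j | A, x)` with reference category
  *action*: for j ∈ {pre-intention, intention},
  `log P(S2=j)/P(S2=action) = α_j + c_j A + β_j' x`.
* **U2 (transition)** — `P(S3 = k | S2 = j, A, x)` per non-absorbing
  origin row j, with the *stay* cell (the diagonal) as reference:
  `log P(S3=k|j)/P(S3=j|j) = b_jk + g_jk A + γ_jk' x`.

*Action is absorbing*: its transition row is structurally fixed at
(0, 0, 1), contributes no parameters and no likelihood terms. This
encodes the substantive claim that disclosure cannot be undone.

Two model modes implement the restrained/unrestrained pair used for
testing intervention moderation:

* `mode="covariate"` (Model 1, restrained): arm enters U1 only; both arms
  share one transition matrix. 8 free parameters unadjusted.
* `mode="multigroup"` (Model 2, unrestrained): U2 logits carry the
  `g_jk A` terms, which is exactly a per-arm (group-specific) transition
  matrix. 12 free parameters unadjusted; the 4-parameter difference is
  the moderation being tested. With the stay reference, `exp(g_jk)` is
  the intervention-vs-control odds ratio of moving j→k rather than
  staying.

An alternative U2 coding with the *action* column as reference is
available via `reparameterize`; the map between codings is linear in the
logits, applies column-wise to every coefficient block, and leaves the
implied transition matrices identical (checked to 1e-10 in tests).
Adjusted models enter baseline covariates in **both** U1 and U2 linear
predictors; per-arm matrices are then reported at the reference covariate
profile (all covariates at zero — center covariates if that profile
should be the sample mean).

## Likelihood and missing data

Records missing one wave are retained by full-information maximum
likelihood. Per-record contributions:

* both waves observed: `log π_j + log P(k|j)`;
* wave 3 missing: `log π_j` (the transition marginalizes out by
  row-stochasticity);
* wave 2 missing: `log Σ_j π_j P(k|j)`.

Records missing both waves carry no information about the transition
structure and must be excluded up front (`validate_panel` flags them;
`exclude_both_missing` drops them). Records that leave the action stage
contradict the absorbing structure and are rejected at fit time (they are
flagged, not corrected, by validation).

## Estimation

The log-likelihood is maximized by L-BFGS with analytic gradients
(posterior-weighted multinomial scores), started from a moment-based
start (logits of complete-case empirical proportions, smoothed by +0.5
per cell) plus `n_starts − 1` random starts uniform on [−2, 2] per
coefficient. The best solution is then polished by Newton steps (numeric
Hessian of the analytic gradient, halving line search) until the gradient
max-norm falls below 1e−9; on complete data with no covariates this makes
the multigroup fit equal the saturated empirical conditional proportions
to machine precision. `n_starts_agreeing` reports how many starts ended
within 1e−4 of the best log-likelihood — a practical multimodality alarm.

Standard errors use the clinic-clustered sandwich `A⁻¹BA⁻¹` with
`A` the observed information and `B` the outer product of clinic-summed
scores. With one participant per clinic this reduces exactly to the
record-level robust sandwich (tested). Wald 95% intervals use
z = 1.959964. Boundary cells (zero observed transitions) are reported as
fitted probabilities 0/1 with the corresponding odds ratios flagged
non-estimable rather than smoothed.

Entropy summarizes posterior classification certainty:
`1 − Σ_i H_i / (n log 3)`, where `H_i` is the Shannon entropy of record
i's posterior over its missing stage (predicted transition row if wave 3
is missing; Bayes posterior over the origin if wave 2 is missing).
Complete records contribute zero, so a complete panel scores exactly 1.
Published entropy values computed by other software may use a different
posterior set; this definition is the package's own and is documented
precisely so it can be compared, not equated.

## Model comparison and efficacy summaries

All fit indices flow from the deviance `G² = −2ℓ`: `AIC = G² + 2p`,
`BIC = G² + p ln(n)` with n the analysis sample, and the nested
difference `ΔG² ~ χ²(Δdf)` with Δdf from free-parameter counts. The
"successful transition" contrast collapses each origin row to a binary
outcome whose failure cell is ending (or staying) in pre-intention;
the success odds ratio is computed closed-form from the two per-arm
matrices (`success / failure` cell sums within a row, so it is invariant
to row renormalization), with delta-method intervals when derived from a
fit. Closed-form matrix odds ratios and fit-based `exp(g_jk)` agree to
1e−6 on complete-data panels (the dual-route check in the tests).

## Descriptive statistics

* **Somers' D**, direction D(stage | group): concordant-minus-discordant
  cross-group pairs over pairs untied on the group, positive when the
  intervention row sits higher on the stage ordering. The asymptotic SE
  is the standard consistent estimator (the SAS PROC FREQ formula,
  spelled out in the docstring); p-values use the normal approximation.
* **MCAR test**: a categorical analogue of Little's test for the two
  stage variables — the sum of two Pearson homogeneity chi-squares
  (observed wave-2 stage split by wave-3 missingness, and vice versa),
  with summed df. Under MCAR the missingness indicator is independent of
  the observed stage, so each component is an ordinary homogeneity test.
  Simulated type-I error at the defaults is ~0.05; power against
  stage-dependent (MNAR) missingness with a logit shift of 1.5 at
  n = 2,000 exceeds 0.8.
* **VIF** per covariate from OLS auxiliary regressions with intercept;
  exact collinearity reports `inf`.

## The synthetic-trial generator

`TrialConfig` defaults encode the study conditions: 40 clinics of 20
participants, 1:1 cluster allocation, membership logits matched to the
published wave-2 stage distribution per arm, transition slopes `b`
inverted from the published control transition matrix and `g` from the
intervention-vs-control logit differences, per-wave MCAR missingness at
the observed rates (~1.2% wave 2, ~2.1% wave 3), and a clinic-level
random intercept with SD 0.605 — the value whose latent-logit ICC,
`σ²/(σ² + π²/3)`, equals the 0.10 used in the trial's power analysis.
The clinic effect is one shared draw per clinic added to every
non-reference logit (U1 and U2), the standard logistic-latent convention;
the trial never reported where its clustering actually lived, so this is
a modeling choice, not a reconstruction. Both-waves-missing draws are
retried, mirroring the analysis-set exclusion. MAR-on-arm and
MNAR-on-stage mechanisms shift the missingness logit by a configurable
amount (defaults 1.0).

What the generator does *not* emulate: measurement error in the stage
response, the raw six-category dynamics (it draws collapsed stages
directly, so it cannot produce the raw-scale regressions out of action
that real panels contain), covariate-dependent stage structure unless
explicitly configured, and any waves beyond the two modeled. Passing
recovery and calibration tests therefore demonstrates correctness of the
estimator under the stated model, not robustness to manifest-assumption
violations.

`fixture_from_counts` builds deterministic complete-data panels that
reproduce integer count tables exactly; transition counts for the
published-table fixture are apportioned from the printed 1-dp
probabilities by largest remainder so rows sum exactly to the wave-2
margins. The printed wave-3 margins themselves cannot be reproduced by
any absorbing-consistent panel (the published control action count falls
between waves), so the fixture's contract is the wave-2 margins and the
transition proportions, which is what the estimator checks need.

## Numerical and design choices

* Optimizer tolerances: L-BFGS `ftol` 1e−13 / `gtol` 1e−8, Newton polish
  to gradient max-norm 1e−9, max 50 polish steps.
* Ties and degenerate inputs: empty table rows, single-pattern MCAR
  input, non-nested comparisons and zero reference cells raise explicit
  typed errors rather than returning NaN.
* The LRT null simulations run at n = 4,000 (40 clinics × 100). At the
  trial's own n ≈ 800 the rarest transition cell
  (pre-intention → action, ~2.3%) has only ~4–5 expected events per arm
  and the deviance difference is mildly anticonservative (null rejection
  ~0.08–0.10 at α = 0.05; mean ΔG² 4.6 vs the χ²(4) mean of 4). At
  n = 4,000–8,000 the same pipeline is calibrated (mean ΔG² 3.94–3.95,
  rejection 0.05–0.06). Applied take-away: at this trial's scale a
  borderline moderation p-value from the G² difference test should be
  read cautiously.
* The G² difference test itself carries no cluster correction (the
  sandwich enters only the standard errors), so its null calibration is
  simulated with the clinic SD at zero; with real within-clinic
  correlation the LRT inherits the usual cluster-ignoring liberality.
* Parameter-recovery and CI-coverage simulations run at n = 10,000
  independent records (200 clinics × 50, clinic SD 0, no missingness),
  200 replications, coverage pooled over the four `g` slopes.

## Known limitations

* Three stages, two waves, one absorbing state — the likelihood is
  written for a single transition step; longer designs need a product of
  U2 terms that is not implemented.
* No latent (measurement-error) layer; misclassified stages bias
  transition estimates in the usual attenuating/absorbing ways.
* Per-arm matrices from adjusted fits are evaluated at the zero-covariate
  profile, not averaged over the covariate distribution.
* The sandwich assumes enough clinics for the cluster CLT (~40 is
  conventional; fewer clinics call for small-sample corrections that are
  not implemented).
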