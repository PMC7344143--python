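# Methods

## Measurement model

All computations assume a unidimensional latent trait θ on the z-metric
(mean 0, SD 1). Item j with K ordered response categories follows
Samejima's graded response model: the cumulative probability of scoring in
category t or above is a 2PL curve

    P*_jt(θ) = 1 / (1 + exp(−D a_j (θ − b_jt))),   t = 1..K−1,

with the scaling constant D = 1.702 so that slopes and thresholds live on
the normal-ogive metric, and category probabilities are adjacent
differences with the conventions P*(X ≥ 0) = 1 and P*(X ≥ K) = 0. A
dichotomous item is exactly the K = 2 case and shares the code path, so
the 2PL/GRM equivalence is an identity rather than an approximation. D is
configurable on the bank for interoperability with D = 1 conventions but
defaults to 1.702 everywhere, including information.

Fisher information of a GRM item uses the standard Samejima form
I_j(θ) = Σ_t (P*′_jt − P*′_j,t+1)² / P_jt with P*′ = D a P*(1 − P*); for
K = 2 this reduces to D²a²P(1−P). GPCM/PCM items (used only for model
comparison) follow the exponential-sum category form with the same D, PCM
constraining the slope to 1; their information is D²a²·Var(T | θ).

Reliability, standard error, and information are tied through
ρ = 1 − SE² = 1 − 1/I, valid on the standardized trait scale. The package
treats this identity as exact: `TraitEstimate.reliability` is computed
from the stored SE, and an information of 10 corresponds to ρ = 0.9.

## Calibration

Item parameters are estimated by Bock–Aitkin EM (marginal maximum
likelihood). The latent prior is fixed at N(0,1) — mean and variance are
never re-estimated — which identifies the scale; this matches the
assumption under which the ρ = 1 − SE² identity is used downstream.

Numerical choices:

- **Quadrature.** 401 equally spaced nodes on [−5, 5] with standard-normal
  weights whose two endpoint weights are halved (trapezoid correction) and
  which are renormalized to sum to one. The node count was chosen so that
  EAP posterior means and SDs agree with a 10⁵-node dense trapezoid
  integration of the same posterior to better than 10⁻⁶ across random
  response patterns on the packaged bank; a coarser 61-node grid leaves
  O(h²) discretization error near 10⁻⁵ and is still constructible via
  `QuadratureGrid.standard_normal(61)` when speed matters more than that
  last digit.
- **Threshold ordering.** The M-step optimizes b_1 and log-gaps
  (b_t = b_1 + Σ exp δ), so returned thresholds are ordered by
  construction for all three models. For the GPCM this is a mild
  restriction (unconstrained step difficulties may cross); it keeps every
  fitted item inside the same validity invariant and has no practical
  effect on the AIC ranking in the simulations tested.
- **Generalized EM.** Each item's expected complete-data log-likelihood is
  maximized by L-BFGS from the previous estimate, and a candidate is
  accepted only if it does not decrease the objective — the marginal
  deviance is therefore non-increasing across iterations (asserted in
  tests to 10⁻⁸ slack).
- **Convergence** is declared at a relative deviance change below 10⁻⁵
  (default), with an explicit warning and diagnostics on non-convergence.
- **Parameter counts** for AIC/BIC: GRM/GPCM count 1 + (K_j − 1) per item,
  PCM counts K_j − 1.
- Probabilities are clamped to [10⁻¹², 1 − 10⁻¹²] inside logarithms so
  extreme response patterns keep finite likelihoods.

Model comparison fits each candidate and ranks by AIC with BIC as the
tie-break; deviance is −2 times the marginal log-likelihood.

## Quality-control pipeline

Stages run in a fixed order — unidimensionality, model selection, local
independence, discrimination, item fit, DIF — with recalibration after
every stage that deletes items and an audit entry per stage. Design
choices where the procedure is conventionally underdetermined:

- **Unidimensionality.** Eigenvalues come from the pairwise-complete
  Pearson inter-item correlation matrix by default (deterministic and
  fast); a two-step polychoric estimate is available behind a flag.
  Iterative pruning uses a two-factor unrotated principal-axis solution:
  drop items with primary loading < 0.30 or with first- and second-factor
  loadings within 0.10 of each other, re-extract, repeat. The surviving
  set passes when eigenvalue ratio λ₁/λ₂ > 4 and the first factor explains
  ≥ 20% of total variance. Note that with Pearson correlations on
  dichotomous items loadings are attenuated relative to a polychoric
  solution, so weakly discriminating items are often caught here before
  the explicit discrimination filter sees them — the same items go, at an
  earlier gate.
- **Local independence.** Q3 is the Pearson correlation of IRT residuals
  x_ij − E[X_ij | θ̂_i] with θ̂ the EAP estimates from the unified
  calibration. Pairs with Q3 strictly above 0.36 are flagged; within a
  flagged pair the member with more flagged partners is deleted, ties
  broken by larger mean |Q3| over its flags, then by later bank position.
  Values in (0.26, 0.36] are reported but never acted on.
- **Discrimination.** Items with a < 0.5 are dropped; the boundary item
  (a = 0.5 exactly) is retained, because the rule is "less than".
- **Item fit.** Orlando–Thissen S-χ²: observed category frequencies within
  rest-score groups (the summed score over the other items, computed on
  fully observed rows) against model-implied frequencies from the
  Lord–Wingersky recursion over the quadrature prior. Adjacent groups are
  merged, smallest expected cell first, until every expected cell reaches
  1.0; df = (groups)·(K−1) − (number of item parameters), and an item with
  fewer than two usable groups or non-positive df is reported as
  not-computable rather than silently passed. The operative flag is
  p < 0.01.
- **DIF.** Per item, three nested binary (K = 2) or proportional-odds
  ordinal (K > 2) logistic regressions — matching θ̂ only; + group;
  + group + group×θ̂ — and the effect size is McFadden ΔR² between models
  3 and 1, flagged when strictly above 0.02. EAP θ̂ is the matching
  variable. MLE failures (separation) fall back to a ridge-stabilized
  refit with a warning.
- **No multiple-testing correction** is applied at any stage; all raw
  statistics are recorded in the audit so users can post-correct.

## Adaptive administration

The engine implements the five classical building blocks. Choices that
the generic recipe leaves open:

- **Starting item**: uniformly random per person (drawn from the person's
  own seeded generator, so the same person starts identically across
  stopping rules in a batch).
- **Selection**: maximum Fisher point information at the current θ̂; ties
  break by bank order for reproducibility.
- **Scoring**: EAP on the shared quadrature grid. Likelihood terms are
  accumulated in bank order regardless of administration order, so a full
  recorded administration reproduces the one-shot full-bank EAP estimate
  to machine equality. With zero responses the prior (0, 1) is returned.
- **Stopping**: checked after each response is scored (the first item is
  always answered); the test ends when 1 − SE² from the EAP posterior SD
  meets the target, at the 35-item cap, or when the bank is exhausted. An
  information-based variant (ρ = 1 − 1/I at θ̂) is available by flag; the
  posterior-SD form is the default because EAP is the scorer.
- **Batch simulation** follows the post-hoc design: a complete response
  matrix is drawn once from the true trait values, then replayed in
  recorded mode under every stopping rule, making rules comparable on
  identical responses. All randomness derives from one master seed.
- No exposure control; recorded rows with missing responses skip the
  selected item with a warning by default (an abort policy is available).

## Evaluation conventions

- **Marginal reliability** is 1 − mean(SE²), the average per-person
  reliability on the unit-variance scale; the variance-ratio form
  var(θ̂)/(var(θ̂) + mean SE²) is provided separately.
- **AUC** is the trapezoidal area under the empirical ROC curve, which
  equals the tie-adjusted Mann–Whitney concordance probability (asserted
  to 10⁻¹² against an independent rank-based route). The 95% CI is
  Hanley–McNeil's closed form; the reported cut-off maximizes the Youden
  index, with the lowest threshold winning ties.
- Predictive-utility analyses take explicit binary criterion labels. How a
  continuous external criterion should be dichotomized is a substantive
  decision the package deliberately does not make.

## Synthetic data

The generator draws GRM responses at each person's true θ ~ N(0,1), which
is what every downstream analysis assumes. Planted defects map one-to-one
onto the QC screens: `LowDiscrimination` replaces an item's slope
(default 0.3); `DifShift` adds a constant to all thresholds for the focal
group (default 0.6, uniform DIF); `LocalDependence` adds a shared
standard-normal residual (default weight 1.0) to the latent propensity of
both partner items. The binary criterion follows
P(label = 1 | θ) = expit(−1.0 + 1.5 θ), a moderately prevalent
(≈ 31%) screen correlating with the trait roughly as an external
diagnostic questionnaire would. Random banks for recovery studies draw
slopes uniformly on (0.7, 2.2) and sorted thresholds on (−2, 2) with a
minimum gap.

What the generator does **not** emulate: careless or inattentive
responding, person misfit, multidimensionality, non-normal trait
distributions, and item nonresponse mechanisms. Passing tests therefore
demonstrate internal consistency of the pipeline under its own model, not
robustness to the ways real survey data violate it.

The packaged 85-item narcissistic-personality bank (68 dichotomous items,
17 five-category items) ships as a versioned CSV with a recorded SHA-256
checksum; its classical-test-theory columns and item-fit p-values are
carried for provenance but never used in computation. The uniform DIF
power simulations use dichotomous target items: for five-category items a
0.6 threshold shift spreads over four thresholds and partially absorbs
into the matching score, leaving ΔR² near the 0.02 cut, which is a known
insensitivity of the ΔR² criterion rather than a defect of the screen.

## Problem sizes used in the test suite

Simulation-backed tests run at the sizes a desk check of each property
needs: parameter recovery at 20 items × n = 2000 over 5 seeds; null
calibration of the S-χ² and DIF screens at 10 items × n = 1000 over 20
seeds; the planted-defect pipeline at 30 items × n = 1000 over 3 seeds;
the stopping-rule ordering at 500 simulated respondents on the packaged
bank. Oracle equivalences (dense-quadrature EAP, Mann–Whitney AUC,
exhaustive-scan item selection) use 100–1000 random instances each.

## Known limitations

- The EM standard errors of item parameters are not computed (point
  estimation only).
- The polychoric correlation option is a two-step pairwise estimator and
  is O(p²) slow for large banks; the Pearson default is attenuated for
  dichotomous items, which shifts some deletions from the discrimination
  gate to the EFA gate as noted above.
- Proportional-odds DIF regressions inherit OrderedModel's occasional
  convergence fragility on sparse category tables; such items are
  reported as not-computable instead of flagged.
- No item-exposure control or content balancing; the engine targets
  single-administration simulation studies, not live high-stakes
  delivery.
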