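# Methods

## Data model

A coded PSE for one motive scale is a binary tensor x_{jpc} ∈ {0,1} for
subject j = 1..N, picture p = 1..P, category c = 1..C.  Three item matrices
are derived from it:

- **category mode** (n = C items): score(j,c) = Σ_p x_{jpc}, each entry ≤ P;
- **picture mode** (n = P items): score(j,p) = Σ_c x_{jpc}, each entry ≤ C;
- **dichotomous mode** (n = P·C items): the raw cells in picture-major order.

All three share the same subject totals, which is what makes the coefficient
comparison meaningful: only the partition of the total variance into item
variances and covariances changes.

The Heckhausen schemes are built in.  Hope of success (HS) has five main
categories (NS, IS, ES, P, A+) and the weighting category ST; fear of failure
(FF) has six (NF, IF, EF, A−, C, F) and FT.  ST is derived per story as:
(NS or ES coded) and no FF main category other than A− or EF present.  FT:
(NF and F coded) and no HS main category other than IS present.  Because each
rule inspects the opposite scale, derivation (`attach_weighting`) is a paired
operation on both tensors.  The FT requirement is implemented conjunctively
("NF and F", as the rule is stated); since the parallel ST rule is
disjunctive, a `ft_rule="disjunctive"` switch is provided in case the
conjunction is a transcription artefact of the coding manual.  With the
weighting categories included, the six-picture design yields 6 HS / 7 FF
category items and 36 / 42 dichotomous items.

Stories a subject skipped are representable only as all-zero rows; the tensor
constructor warns about all-zero subjects (strict mode rejects them), since
the coding data cannot distinguish "no imagery" from "no story".

## Coefficients

All coefficients are computed from first principles on the item matrix; no
statistics package's reliability routine is called anywhere.

Variances and covariances use the **population denominator N** by default
(`ddof=0`), consistent with the expectation-based definitions of the lower
bounds; `ddof=1` is available.  λ₁, λ₃ (= α), λ₄ and λ₆ are ratios of
variances and therefore identical under either convention; λ₂ and λ₅ take
square roots of summed squared covariances and are not, so their convention
is recorded in every report.

- λ₁ = 1 − ΣV_j/V_T
- λ₂ = λ₁ + √( n/(n−1) · Σ_{j≠k} γ_jk² ) / V_T
- λ₃ = α = n/(n−1)·(1 − ΣV_j/V_T).  On dichotomous items this is KR-20;
  `kr20()` implements the p·q form independently and agrees with α to
  machine precision under the population convention.
- λ₄ = 2·(1 − (V_a+V_b)/V_T) for a partition {a,b}.  Strategy `max`
  enumerates every balanced split exactly for n ≤ 20 (each split visited
  once; for even n item 1 is pinned to one side) and uses a greedy
  pairwise-swap ascent from the odd/even split above that; `first_last` and
  `odd_even` reproduce the fixed splits legacy packages use.  Reports carry
  both `max` and `first_last` values because published λ₄ figures rarely
  document their split.
- λ₅ = λ₁ + 2·√( max_j Σ_{k≠j} γ_jk² ) / V_T
- λ₆ = 1 − Σ_j V_j(1 − SMC_j) / V_T.  SMC_j is obtained by solving the
  normal equations of item j on the remaining items from the correlation
  matrix; a singular remaining-item block (perfectly collinear items) falls
  back to the minimum-norm solution with a warning, which still yields the
  projection R².  Zero-variance items contribute zero error variance and are
  excluded from the SMC computation (warning; strict mode raises).

### ω total

ω_t = 1 − Σu_j²/ΣR, with uniquenesses u_j² from a common-factor model of the
item **correlation** matrix and ΣR the sum of all its entries.  The factor
model is fitted by minimum residual (minres): the off-diagonal residual sum
of squares is minimised over the uniquenesses with L-BFGS-B (bounds
[0.001, 1], start 1 − SMC, up to 1000 iterations, gradient tolerance 1e−6);
given uniquenesses, loadings are the scaled leading eigenvectors of the
reduced correlation matrix.  Default is one factor.  Non-convergence is
flagged on the result, not fatal.  ω_t values are validated through two
limits rather than any published table figure: on a constructed one-factor
correlation matrix (loadings 0.8, n = 6) the fit recovers the closed form
1 − Σu²/ΣR to < 1e−4, and on simulated unidimensional data ω_t ≈ α —
published ω_t values depend on undocumented estimation settings and are
deliberately not treated as exact references.

Correlations are averaged on the Fisher z scale, tanh(mean(atanh r)); any
|r| = 1 is rejected (infinite z).

Report tables round to 2 decimals for display (half away from zero, matching
how such tables are conventionally printed); structured outputs always carry
full precision.

## Decomposition identities

Computed in sum-of-squares form (never divided by N) so no denominator
convention can blur them:

1. Per picture: SS_p = Σ_c SS_{pc} + 2·Σ_{c<c'} CP_{p,cc'}, where SS_{pc} is
   the SS of the 0/1 column of category c within picture p and CP the
   mean-deviation cross-product sum of a category pair.  Verified to a
   residual < 1e−10 on 500 random tensors.
2. Per mode: SS_T = Σ SS_i + 2·(pairwise cross-product sum), with the same
   SS_T in both modes.
3. Cross-level bookkeeping: every unordered pair of tensor cells lies in
   exactly one stratum — same picture, same category, or neither.  The
   picture-mode item SS absorbs the within-picture/between-category stratum
   that the category-mode covariance sum collects, and vice versa.  This is
   the exact sense in which high within-story category agreement
   simultaneously inflates picture-score variances and category-score
   covariances, producing the category-mode α advantage.  `alpha_gap_analysis`
   returns the gap together with these terms; the degenerate case of
   identical pictures (gap ≤ 0, picture intercorrelations 1) is flagged.

No closed-form expression for the gap itself is asserted; the monotone
relation between picture-cue variance and the gap is demonstrated by
simulation instead.

## Synthetic data generator

`simulate_pse` draws x_{jpc} ~ Bernoulli(σ(β_c + λ_c·θ_j + u_{jp} −
γ·s_{j,p−1})) with θ_j ~ N(0, θ_sd²) the latent motive, u_{jp} ~ N(0, σ_cue²)
the picture-cue interaction, and s_{j,p−1} the previous story's category
count (0 for the first picture) scaled by the saw-tooth strength γ.  Pictures
are generated in order so the saw-tooth term conditions on the realised
previous story; the memory is deliberately first-order.  Random streams are
split per subject from one root seed (numpy `SeedSequence.spawn`), so
enlarging N appends subjects without reshuffling earlier ones, and identical
configs are bit-reproducible.

Defaults describe a mid-sized validation study on the six-picture design:
N = 200, P = 6, C = 6, θ_sd = 1, unit loadings, base endorsement probability
0.2 per category (logit intercept −1.386, in the range of observed Heckhausen
category rates of roughly .03–.4 per picture), σ_cue = 1 and γ = 0.5 on the
logit scale.  An optional seventh "weighting-like" category fires with a
boosted probability when at least two main categories fired, mimicking the
derived nature of ST/FT without re-implementing the cross-scale rule.

`gap_experiment` replicates the tensor draw and reports means/SDs of the
category, picture and dichotomous α plus the gap and the fraction of
replicates with a positive gap.  With 100 replicates at the defaults the
category mode exceeds the picture mode in every replicate, and the mean gap
rises monotonically over σ_cue ∈ {0, .5, 1, 2}.

What the generator does **not** emulate: story length and verbal-fluency
confounds, coder disagreement, picture-specific category affinities (u_{jp}
is shared across categories), higher-order saw-tooth memory, and the exact
ST/FT logic.  Passing simulation tests therefore shows the coefficients and
the mode contrast behave as the variance bookkeeping predicts under
cue/saw-tooth structure — not that any particular real data set attains a
particular α.  The original coded data sets behind the published coefficient
tables are not distributed with the package, so those printed values are not
regression-tested; the identities, oracles and simulated properties stand in
for them.

## Numerical and design choices

- Exhaustive λ₄ split search caps at n = 20 (184 756 splits) to keep the
  36/42-item dichotomous reports fast; above that, greedy ascent (a lower
  bound on the true maximum, flagged by the strategy name).
- Zero-variance items: retained for variance-ratio coefficients, dropped with
  a warning for correlation-based ones (λ₆'s SMC, ω_t); strict mode raises.
- The worked-example fixture, simulation sizes in tests (N ≤ 1500 for the
  unidimensional ω/α check, 100-replicate experiments) and the 500-tensor
  identity sweep were chosen so the full suite runs in well under a minute
  on a single CPU while keeping Monte-Carlo error far below the asserted
  margins.
- Tables are displayed leading-zero-free at 2 decimals; JSON/CSV outputs are
  full precision.

## Known limitations

- The greedy λ₄ search can undershoot the true maximum split for n > 20.
- ω_t assumes the common-factor model is meaningful for counts; for the
  dichotomous mode a linear factor fit of φ-correlations is an
  approximation, and no tetrachoric/nonlinear option is provided.
- The `.DAT` reader requires the user to supply the column map; undocumented
  legacy layouts cannot be inferred.
- No confidence intervals or significance tests for coefficients, no
  hierarchical ω, and no item-response-theory modelling (deliberately out of
  scope).
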