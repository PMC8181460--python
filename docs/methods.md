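# Methods

## The model

All predictors in this package are conditional means under one multi-trait
Gaussian working model. For traits Y_1 (focal) through Y_{p+1} (secondary)
on n genotypes,

    Y = X beta + U + E,   U ~ N(0, Sigma_u ⊗ K),   E ~ N(0, Sigma_e ⊗ I_n),

where K is the genomic relationship matrix, Sigma_u the q×q genetic
covariance of the traits and Sigma_e their residual covariance. The target
of inference is U_f,t — the focal-trait breeding values of the n_t *test*
genotypes, which carry no focal phenotype. The two data-availability
scenarios differ in the conditioning set: scenario 1 observes secondary
traits on the training set only; scenario 2 also on the test set.

The three core predictors are exact conditional means:

* **Univariate GBLUP** conditions on Y_f,o alone:
  `U_hat_f,o = s2_u K_oo V^{-1}(y - X beta)` with `V = s2_u K_oo + s2_e I`,
  and `U_hat_f,t = K_to K_oo^{-1} U_hat_f,o`.
* **Multivariate scenario 1** conditions on all traits on the training set;
  the test-set prediction is again the kinship projection of the training
  BLUP.
* **Multivariate scenario 2** conditions jointly on (Y_f,o, Y_s on all n).
  The residual covariance between the focal training records and the
  secondary records of *test* genotypes is structurally zero (different
  plants), which the block system encodes explicitly.

Because n_o + (q-1)n can reach ~1900 at the default design, scenario-2
predictions are not computed by assembling that dense system. In the
eigenbasis of K the secondary-trait covariance is block-diagonal with
(q-1)×(q-1) blocks and every cross-covariance row is rank-one per
eigenvector, so the conditional mean reduces to one n_o×n_o solve plus
O(n q^3) small solves. The dense block system is retained in the test suite
as an independent oracle; both routes agree to 1e-8.

Predictions are breeding values only; X beta is never added back (all
accuracy measures are correlations, which are shift-invariant).

## REML estimation

* **Univariate** (`UnivariateGBLUP`): after one eigendecomposition of K_oo,
  the REML criterion is profiled over beta and the total variance, leaving
  a 1-D search over heritability h on (0, 1): a 21-point scan followed by
  bounded Brent. Degenerate traits (zero residual signal) return floored
  variances (1e-8) with the convergence flag set, never an exception.
* **Bivariate** (`BivariateGBLUP`): Sigma_u and Sigma_e are parameterised
  by log-Cholesky factors (every iterate PSD by construction) and optimised
  by Nelder–Mead. Balanced coverage uses the same eigenbasis trick — each
  likelihood evaluation is O(n) on 2×2 blocks. Unbalanced coverage (the
  secondary trait observed on genotypes without focal records) marginalises
  the missing cells in a dense likelihood over the observed ones.
  With `diagonal_residual=True` (traits measured on different plants) the
  residual off-diagonal is exactly zero. The residual diagonal is floored
  at 1e-8 *inside* the parameterisation: an overfitted derived trait (e.g.
  a LASSO prediction of the focal trait) can otherwise drive a residual
  variance to exactly zero and make downstream covariance solves singular.
* **Two-kernel** (`MultiKernelModel`): y ~ N(X beta, s2_K K + s2_M M + s2_E I),
  log-variance parameterisation, Nelder–Mead on the dense REML criterion
  (n_o ≤ ~500 here, a few ms per evaluation). The reported log-likelihood
  is re-evaluated at the floored components so results are self-consistent.

Starting values halve the phenotypic (co)variance between the genetic and
residual side. Fixed effects default to an intercept. Non-convergence is
flagged on the results object and warned, never raised.

The composed predictors fit their bivariate variance components on the
training genotypes (the balanced fast path) in both scenarios; scenario 2
then conditions on the secondary trait over all genotypes at prediction
time. Fitting the unbalanced model on all genotypes is available through
the dense path but is ~50× slower and changed nothing in our checks beyond
Monte-Carlo noise.

## Dimension reductions

* **LS-BLUP / RF-BLUP**: S = h_hat(Y_s) is a prediction of the focal trait
  from the secondary traits, fitted on the training set only — LASSO with
  internally cross-validated penalty (10 folds) or a random forest
  (500 trees, mtry = p/3; optional CV tuning of mtry and node size). The
  LASSO penalty uses the 1-SE rule by default: on pure-noise secondaries
  (n_o = 100, p = 300) the minimum-CV rule retains spurious variables in
  roughly half of datasets, while the 1-SE rule returns the empty model in
  ≳80% and matches the default of the R tooling this method descends from;
  `penalty_rule="min"` restores the alternative. An empty selected model
  flags the reduction degenerate and the composed predictor falls back to
  univariate GBLUP, so it cannot underperform GBLUP in that case.
  The whole training set is used for both the reduction and the REML step;
  sample splitting is deliberately not applied at these population sizes.
* **SI-BLUP**: the penalized selection index gamma(lambda) =
  (Sigma_s + lambda I)^{-1} Sigma_sf_u (ridge; LASSO via coordinate descent
  on the equivalent quadratic, tolerance 1e-9). Sigma_sf_u comes from
  one-way MANOVA on balanced plot-level replicates — genetic covariance =
  (between − within mean cross-products)/r — and Sigma_s is the sample
  covariance of the genotype-mean secondary traits; no multi-trait mixed
  model is fitted for the index. lambda is tuned by 5-fold CV over
  genotypes, maximising the held-out h(S)·rho_G(S, Y_f) estimated with the
  same MANOVA machinery (folds with non-positive variance components are
  skipped and logged). The default grid is 30 log-spaced values on
  [1e-4, 1e2]·mean diag(Sigma_s). Unbalanced replication is rejected.

## Multi-kernel predictors

M = Z_s Z_s^T / p with column-standardised secondary traits — the linear
kernel that makes the random-regression form Y_s b_s, b_s ~ N(0, s2_M/p I),
exactly equivalent to V_sec ~ N(0, s2_M M). Multi-BLUP (scenario 2 only)
sums the genomic and secondary-effect BLUPs, extending both to the test set
via K_t· and M_t·. GM-BLUP replaces the secondary-trait values by their
per-trait univariate genomic predictions (one shared eigendecomposition,
so p = 300 trait fits cost seconds) weighted by the Multi-BLUP
coefficients; it is the only multi-kernel method available in scenario 1.
M-BLUP drops the genomic kernel entirely. Variance components are always
REML, not cross-validation.

## The simulator

Traits are generated from the row-vector recursion y_i = y_i Λ + g_i + r_i
with Γ = (I − Λ)^{-1}, so Y = (G + R)Γ, U = GΓ, and the implied covariances
are Sigma_u = Γ^T Sigma_g Γ, Sigma_e = Γ^T Sigma_r Γ. The focal trait is
Y_1 = λ(Y_2 + Y_3 + Y_4) + G_1 + R_1: exactly three of the p = 300
secondary traits are causal, with a common effect size λ from
{−1, −0.5, 0, 0.5, 1}. Direct genetic variances are 0.2 (focal) and 0.7
(secondary); residual variances 0.8 and 0.3 — hence focal heritability
exactly 0.2 and secondary heritability 0.7 at λ = 0. rho_G, rho_E from
{−0.5, 0, 0.5} set the correlations of the direct genetic/residual effects
between the focal and each causal trait (covariances rho_G·sqrt(0.2·0.7)
and rho_E·sqrt(0.8·0.3)); all other off-diagonals are zero.

Genotypes are synthetic unlinked SNPs: per-SNP allele frequency uniform on
[0.3, 0.5], dosages Binomial(2, freq), defaults n = 500 (100 test),
m = 1500. K is the VanRaden GRM of those same SNPs, and direct genetic
effects are drawn from the kernel model N(0, Sigma_g ⊗ K), so the data
follow exactly the model the predictors assume and the true-parameter
benchmark is well defined. A marker-effect draw would be distributionally
identical for this K and is therefore not separately implemented. Only the
4-trait causal block needs a correlated draw; the remaining 297 secondary
traits are independent and drawn by a block-diagonal shortcut
(`full_draw=True` forces the full factorisation; the two routes are the
same law, checked by moment tests). Plot-level replicates reuse each
genotype's direct genetic effects with fresh residual draws propagated
through Γ.

Grid replication: each (cell, replicate) task draws from
`default_rng((master_seed, cell_index, replicate))`. This makes results
byte-identical under any execution order or parallelism, which a single
running seed sequence would not.

### What the generator does and does not emulate

The synthetic genotypes are *unlinked and unstructured*: no LD, no
population structure, no families. Real diversity panels (the setting the
study design comes from) have both, which concentrates the kinship
spectrum and makes test genotypes far more predictable from the training
set. This matters quantitatively: for i.i.d. markers the conditional
variance of a test genotype's genetic value given *all* training genetic
values is ≈ (m − n_o)/m = (1500−400)/1500 = 0.73 of its total (the Schur
complement of a Wishart-like K), capping the accuracy of *any* scenario-1
predictor near sqrt(0.27) ≈ 0.52 at this design — independent of
heritability. Scenario-2 predictors escape the cap because they condition
on secondary phenotypes observed on the test set directly. Consequently,
passing simulation tests demonstrate the estimators and predictors are
correct and well-calibrated under the stated generative model; absolute
accuracy levels on structured real panels will differ (upward in
scenario 1).

## Evaluation

Accuracy is the Pearson correlation on the test set against true simulated
genetic effects (simulation) or observed phenotypes (CV harness; a biased
but method-invariant estimate — validated on simulated data through the
attenuation identity r(U_hat, Y) ≈ h·r(U_hat, U)). A constant prediction
scores 0 with a warning. Failed fits inside the grid record NaN plus a
structured error entry and never abort the run.

Problem sizes used by the shipped checks: the acceptance grid runs all 45
(λ, rho_G, rho_E) cells at the full design size (n = 500, n_test = 100,
m = 1500) with 20 replicates per cell and the 4-trait block; estimator
recovery tests use n = 500 with 50–100 replicates; predictor-oracle tests
use ≤ 20-genotype toys at 1e-8 agreement; composed-predictor comparisons
use n ≈ 150–220, p = 40–300, 15–20 replicates.

## Known limitations

* REML for unstructured multivariate models is limited to q = 2 (the
  methods under study reduce the secondary dimension to one; the 4-trait
  benchmark needs no estimation).
* MANOVA-based selection indices require balanced replication.
* The CV harness evaluates against observed phenotypes without bias
  correction, as in the protocol it mirrors.
* The intermediate scenario (secondary traits on *some* test genotypes) is
  not operationalised.
* Genotype simulation has no LD/structure switch; see the caveat above.
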