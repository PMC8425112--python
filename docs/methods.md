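# Methods

## Model and pattern family

For a subject with genotype G ∈ {0,1,2} (minor-allele count), an
environmental factor E with k ordered or unordered levels, and outcome
Y (binary or continuous), every candidate model has the form

    g(E[Y]) = β₀ + [βₛ·S] + [Σₗ βₗ·I(E=l)] + Σₗ γₗ·S·I(E=l) + covariates

with g the logit (binary Y) or identity (continuous Y) link, S a
recoding of G, and the bracketed main-effect blocks present or absent
according to the model structure.  The four structures are Full (both
main effects), Mint_SNP (SNP main only), Mint_Env (environment main
only) and Int (interaction terms only); the three inheritance modes
recode G as additive (0,1,2), dominant (0,1,1) or recessive (0,0,1);
each factor may be coded in its original or reverse direction, where
reverse means the complement coding (2−S for additive, 1−S for the
binary modes; highest level as reference for an ordinal E).

Reversing a factor whose main effect is in the model is an affine
change of basis: e.g. with S present, S·I(E=1) = S − S·I(E=2) −
S·I(E=3), so the reversed design spans the same column space and has
identical likelihood.  Only direction choices that change the span are
kept, giving 3 (Full) + 6 (Mint_SNP) + 6 (Mint_Env) + 12 (Int) = 27
patterns for an ordinal E.  For a categorical E the reference level is
user-chosen, so environment reversal is dropped: 18 = 27 − 9 patterns.
This redundancy is verified numerically in the test suite (maximum
log-likelihood gap across redundant codings < 1e-6; observed ≈ 1e-13).

## Fitting and testing

Models are fitted by maximum likelihood (IRLS for logistic, least
squares for linear) through statsmodels.  The interaction is tested
jointly over the k−1 interaction columns by a likelihood-ratio test
against the reduced model that keeps the intercept, the structure's
main effects and all covariates.  The LRT statistic is clamped at zero
and referred to χ²(k−1); for the linear family the exact partial
F-test replaces it; a joint Wald χ² is available as an option.  The
LRT is the default because it is the standard likelihood-based choice
for a joint nested comparison; on well-behaved data the two agree.

Per-term Wald confidence intervals are computed on the coefficient
scale and exponentiated to odds ratios for the logistic family
(default level 0.95).

BIC = −2·logLik + p·ln(n), where p counts the design columns including
the intercept, plus the residual-variance parameter for the linear
family (so logistic and linear BICs are each internally consistent).
Selection rules: smallest BIC (default — a parsimonious pattern
generalizes better) or smallest interaction p-value.  BIC ties within
1e-9 break by smaller p-value, then enumeration order; p-value ties by
smaller BIC, then order.  Enumeration order is fixed (structures Full,
Mint_SNP, Mint_Env, Int; modes additive, dominant, recessive;
directions oo, or, ro, rr) so reruns are bit-identical.

## Degenerate inputs and numerical choices

* Complete cases are taken listwise over outcome, SNP, environment and
  covariates, per pair; n_used is reported.
* A coded SNP that is constant (monomorphic, or all-carriers under a
  binary mode) makes the pattern non-estimable; likewise a constant or
  collinear design column, or a single observed environment level.
  Non-estimable patterns are reported with missing p/BIC — never
  dropped silently, never an exception.  A pair with fewer than two
  estimable patterns becomes a failure record.
* Logistic convergence: iteration cap 100, tolerance 1e-8.  Separation
  is flagged when any |coefficient| > 15 or any standard error > 100;
  such fits count as non-estimable.
* Environments with any k ≥ 2 observed levels are supported with k−1
  indicator columns (k = 3 is the documented, tested case; other k are
  an extension).  Ordinal levels may be any order-comparable codes;
  "lowest"/"highest" follow sort order.
* Genotypes are always minor-allele counts.  Allele-pair strings are
  recoded through the allele summary (`maf_info` →
  `recode_minor_count`) so "original direction" has a consistent
  meaning; at MAF exactly 0.5 the alphabetically later allele is
  called minor.
* The batch report applies Bonferroni across pairs only
  (α/m, e.g. 0.05/5 = 0.01); the within-pair search over 27 patterns is
  deliberately left unadjusted, matching how the method is used, and
  documented as a caveat.  Under the null the searched minimum p-value
  is stochastically smaller than uniform, while any fixed pattern's
  p-value stays approximately uniform; both facts are tested.

## Synthetic-data generator

`simulate` draws independent SNPs under Hardy–Weinberg equilibrium
from their MAFs, a multinomial exposure (default: three levels,
uniform 1/3 each — an agnostic default for a low/medium/high
exposure), and outcomes from the linear predictor of any planted
pattern, so generating coefficients are log odds ratios.  A single
integer seed drives all draws through spawned substreams.

`make_simdata2_like` emulates the schema of a published example
dataset: n = 2000, five SNPs with MAFs 0.210, 0.071, 0.343, 0.342,
0.445, a 3-level ordinal exposure, binary outcome, baseline prevalence
0.2, and two planted interaction-only effects (snp2 under Int_AE_oo
with ORs 0.7/2.4; snp3 under Int_RE_or with ORs 2.0/1.8).  The
original dataset's generating model is not public, so this emulation
is qualitative: schema and allele frequencies match; per-pattern
p-values are not reproduction targets.

What the generator does **not** emulate: linkage disequilibrium
between SNPs, population stratification, genotyping error,
missing-data mechanisms, or covariate confounding.  Passing tests
therefore demonstrate correctness of the machinery and calibration
under clean sampling, not robustness to those real-data features.

## Operating characteristics (`benchmarks`)

* Type-I error: the fixed `Full_AE_oo` interaction LRT over 2000 null
  replicates of n = 500 (one SNP at MAF 0.3, prevalence 0.3 — chosen
  once as a typical candidate-SNP case-control setting) must reject in
  [0.04, 0.06] at α = 0.05.
* Recovery: interaction-only truths planted with ORs 1.5/2.2
  (additive, original codings) and 4.3/1.8 (recessive SNP, reversed
  environment) at n = 2000, MAF 0.35, prevalence 0.25, 200 replicates:
  best-BIC selection returns an Int structure in the clear majority of
  replicates and the exact planted pattern as the modal choice.

These problem sizes are the package's reference study conditions; the
examples use smaller Monte-Carlo sizes purely for illustration.

## Known limitations

The family searches 27 designed patterns, not all possible
genotype-by-exposure risk assignments; one environmental factor per
pair; no SNP–SNP interaction patterns; no penalized or Firth logistic
fallback for separated fits (they are reported non-estimable); no
FDR control beyond Bonferroni across pairs.
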