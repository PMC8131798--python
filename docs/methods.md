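# Methods

## Model

Each behavioural trait is analysed separately (no among-trait covariances)
with the Gaussian animal model

y_ij = mu_s + a_{i,s} + ce_{fam(i),s} + pe_i + c_{contest(ij)} + e_ij

on the analysis scale (natural log for activity and exploration; raw scale
otherwise). The breeding-value pairs a_i = (a_{i,female}, a_{i,male}) are
jointly multivariate normal with covariance **G** ⊗ **A**: **G** is the
unstructured 2×2 cross-sex additive covariance and **A** the numerator
relationship matrix built from the pedigree by the tabular method with
inbreeding (A_ii = 1 + F_i). Only the component matching the individual's
sex appears in its records; the other-sex component is latent but always
instantiated, which keeps the conditional for **G** a clean inverse-Wishart
over complete pairs. The common-environment/maternal term has one level
per (dam, offspring sex) — same-sex sibs of a clutch share it — and
parental founders, whose dams are unknown, carry none. The
permanent-environment term has one level per individual and is identified
by the parental generation's repeated measures. Contest effects (dyadic
aggression trials only) are shared by exactly the two same-sex contestants
of a trial and carry a single pooled variance V_C; CE/M, PE and residual
variances are sex-specific with cross-sex covariances fixed at zero.

Sex enters as a fixed effect through separate means mu_f and mu_m
(prior N(0, 1e8)); the per-sex means are what the reported mean contrasts
require.

## Sampler

A systematic-scan Gibbs sweep per iteration: fixed effects from their
Gaussian conditionals; breeding-value pairs individual-by-individual
through the sparse Henderson A⁻¹ (each 2-vector from a 2×2 Gaussian
conditional combining G⁻¹-weighted neighbours and the data term; the sweep
is numba-compiled and allocation-free); CE/M, PE and contest levels from
vectorized Gaussian conditionals (levels are conditionally independent
within each term); **G** from an inverse-Wishart driven by the
A⁻¹-weighted cross-products of the pairs; every diagonal variance from a
scaled inverse-chi-square. A⁻¹ is assembled directly by Henderson's rules
with Meuwissen–Luo inbreeding coefficients, so it is exact for inbred
pedigrees; tests verify A⁻¹·A = I to 1e−8 and agreement with dense
inversion to 1e−6 at 300 individuals.

Chains are deterministic given the seed. Profiles: `full` = 130,000
iterations, 30,000 burn-in, thin 100 (1,000 retained); `test` = 13,000 /
3,000 / 10 (also 1,000 retained). The test profile is the package's
desk-scale default and is what the analysis scripts, test suite and
acceptance script use; the full profile quadruples effective sample sizes
when final numbers are wanted.

## Priors

Variance components in this design are small and weakly identified (the
offspring are measured once; several posterior means sit near zero), so the
default priors are parameter-expanded (PX):

* **G block**: a = Λη with Λ = diag(λ_f, λ_m), η ~ N(0, G_w ⊗ A),
  G_w ~ IW(I, 2.002) on a working scale and λ_s ~ N(0, V_P). The implied
  prior on the reported G = Λ G_w Λ is heavy-tailed with positive density
  at zero additive variance.
* **CE/M, PE, contest**: working levels with a unit-scale scaled
  inverse-chi-square (1 df) times a N(0, V_P) expansion scalar, giving each
  reported variance a scaled-F marginal — the standard heavy-tailed choice
  for variance components that may vanish.
* **Residual**: scaled inverse-chi-square with scale V_P/2 and belief
  0.002 (near-flat on the variance).

V_P is the observed phenotypic variance of the trait on the analysis
scale, resolved at fit time. The non-expanded path
(`PriorSpec(px_g=False, px_var=False)`) keeps the plain
IW(diag(V_P/2), 2.002) / inv-chi-square(0.002, V_P/2) priors; it is used
by the conjugate-oracle and model-equivalence tests. The choice of PX as
the default is empirical in the honest sense: with the non-expanded IW
prior the posterior for a near-zero additive variance is bounded away from
zero and 95% intervals failed to cover small generating values in
simulation, while the PX priors give 90–100% coverage per component over
20 replicate studies at the design's size.

Every retained draw satisfies the container's invariants by construction:
variances are non-negative and COV_Amf² ≤ V_Af·V_Am (G is Λ G_w Λ with
G_w positive definite).

## Derived statistics

All ratios are computed per draw, never as ratios of posterior means:
h² = V_A/(V_A + V_CE/M + V_PE + V_R), with V_C added to the denominator
for dyadic traits; r_mf = COV_Amf/√(V_Af V_Am); CV_A = √V_A/mean,
I_A = V_A/mean² (so CV_A² = I_A holds per draw to floating precision),
CV_CE/M, CV_PE, CV_R. Phenotypic means for the mean-standardized
coefficients are sex-specific raw-scale means pooled across the parental
and offspring generations (a pooled-sex mean is available by argument).
Summaries are posterior means with 95% highest-posterior-density intervals
by default (quantile intervals by flag); HPD matches the reporting style
of the modelling tools this analysis descends from. Contrasts are
per-draw female − male, so the contrast's posterior mean equals the
difference of the by-sex means exactly; pMCMC = min(1, max(2·min(P(d ≥ 0),
P(d ≤ 0)), 1/n)).

**r_mf refusal rule.** A draw's r_mf is undefined when V_Af·V_Am falls
below an absolute floor (1e−12 on the trait scale); independently, the
pipeline withholds the r_mf point estimate whenever the lower 95% bound of
either sex's V_A is below 10⁻³·V_P — a posterior consistent with zero
additive variance makes the correlation a ratio of noise. In that case the
defined-draw fraction and the COV_Amf summary are still reported. At this
design size the rule fires for all four trait presets, which is the
substantive outcome of the original analysis.

## Synthetic data

The generator emulates the study design, not the assays: 30 founder dams
and 31 founder sires ("parental"), each scored twice per test; parents
rank-matched into pairs by their realized mean aggression score
(assortative mating — the pairing uses simulated phenotypes, so the
mate-pair phenotypic correlation is real and propagates into the offspring
genetics, because offspring breeding values are drawn conditionally on
their parents' realized values by the gene-flow recursion); 29 of the
pairs produce full-sib families aiming at 5 daughters + 5 sons, scored
once. Family sex ratios can be jittered binomially (off by default; the
realized field distribution is not knowable from the source text).
Aggression dyads are re-drawn at random within sex each measurement round;
with an odd count one individual sits the round out.

Trait presets use the study's fitted posterior means as generating
variance components. Two quantities the source tables do not print were
chosen once: the contest variance V_C = 5.0 for aggression (mid-range
relative to the female and male phenotypic variances) and the trait means,
which were set so that the simulated raw-scale sex differences and
mean-standardized coefficients are of the reported order (aggression
5.2/17.4; activity 3.4/3.7 and exploration 3.6/3.4 on the log scale;
boldness 120/114.25 s).

Censoring follows the measurement protocol: latencies are clipped at 300 s
on the observation scale and the clipped value is treated as an ordinary
observation downstream (no censored likelihood), matching how the original
analysis handled the 300 s maximum. Log-scale traits are simulated
latently on the log scale, exponentiated, clipped to [1, 300] s, and
re-logged at model build; the 1 s lower clip keeps the log transform
defined and is below the 2.5th percentile of simulated latencies at the
preset means.

What the generator does not emulate: non-Gaussian trait distributions,
assay mechanics, observer effects, viability selection within clutches.
Passing recovery tests therefore show that the estimator is correct and
calibrated *under the model's own assumptions* at the study's sample
sizes — not that real spider data satisfy those assumptions.

## Convergence diagnostics

Heidelberger–Welch as classically defined: the stationarity test computes
the Cramér–von Mises statistic of the Brownian-bridge functional of the
chain's cumulative sums, normalized by the spectral density at zero
estimated from the last half of the chain, dropping leading 10% increments
(up to 50%) until non-significant at alpha = 0.05; the halfwidth test then
requires z_{0.975}·√(S(0)/n) ≤ 0.1·|mean| on the retained segment. S(0)
is estimated from a Yule–Walker autoregressive fit with the order chosen
by AIC (up to 10·log10 n), which avoids window-choice ambiguity; the CvM
p-value uses the Bessel-K series of the asymptotic distribution. A
constant chain passes trivially and is flagged. The statistic is invariant
to affine rescaling of the chain.

Effective sample size uses the initial-monotone-sequence estimator
(paired autocorrelations summed while positive, forced non-increasing);
an AR(1) chain with coefficient 0.5 yields ESS ≈ n/3 as the closed form
requires, and a constant chain reports ESS 0 with a flag. Autocorrelations
use the biased (1/n) normalization, so lag 0 is exactly 1.

## Numerical choices and degenerate inputs

Pedigree parsing topologically sorts with id-lexicographic tie-breaking,
so the resulting order — and every matrix built from it — is invariant to
input row order. Unknown parents are "NA"/empty (configurable); sex is
mandatory; one-known-parent individuals are allowed (the unknown side
contributes zero). A constant response is flagged as near-degenerate
(prior-dominated posterior) rather than crashing, with sampled variances
floored at 1e−300 to keep the arithmetic finite; a non-finite conditional
raises an identifiability error rather than being silently repaired.
Assortative pairing breaks score ties by id order; unequal usable counts
pair the minimum and report the remainder.

## Problem sizes

The analysis scripts, tests and the acceptance script run the design at
its natural size (351 individuals, ~410 records per trait) with the test
chain profile; the recovery experiments use 10–20 replicate studies. These
sizes give stable qualitative results (coverage, orderings, refusal-rule
behaviour) at desk scale; the full chain profile is the one to use for
publication-grade posterior summaries.

## Known limitations

Single-site breeding-value updates mix more slowly than a joint
factorization; effective sample sizes for the additive components are in
the tens-to-hundreds per 1,000 retained draws at the test profile, and the
halfwidth diagnostic correctly flags the cross-sex covariance chains as
imprecise at this design size. The censored-as-observed convention biases
latency variances slightly downward relative to a censored likelihood (by
design, for fidelity to the source analysis). The r_mf refusal threshold
is a reporting policy, not an inference; it is configurable. Multi-trait
(among-behaviour) covariance models and genomic relationship matrices are
out of scope.
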