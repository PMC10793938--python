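# Methods

## Model and scope

`summr` works entirely on GWAS summary statistics under the standard
two-sample MR model.  Each instrument j carries an estimated exposure
effect b_Xj (SD units) with SE s_Xj and an estimated outcome effect b_Yj
(log-odds) with SE s_Yj, from non-overlapping samples, so the two noise
terms are independent.  Valid instruments satisfy the three IV
assumptions: association with the exposure, no association with
confounders, and no effect on the outcome except through the exposure.
The causal parameter θ is a log-odds per SD; odds ratios are exp(θ).
Estimation treats the summary statistics as normally distributed with
known SEs — the same approximation the field's standard tooling makes.

## Instrument pipeline

Selection is: p < 5e-8 (strict), greedy clumping (scan by ascending p,
ties broken lexicographically by variant id, accept a SNP iff r² with all
accepted SNPs inside the window is < 0.001), allele harmonization, per-SNP
F = (b_X/s_X)² > 10, outcome-association screen, and exclusion lists.
Every removal is appended to a provenance log, so the identity
`input = survivors + removals` holds at each stage and a run can be
audited or replayed.

Harmonization conventions:

- Swapped alleles (and strand-complement swaps) negate b_Y and complement
  the effect-allele frequency.
- A/T and C/G palindromes cannot be strand-resolved from alleles; they are
  aligned by allele frequency when both EAFs are outside the
  [0.42, 0.58] band and dropped otherwise (the band is the conventional
  "intermediate frequency" window and is a parameter).
- The outcome-association screen defaults to the same 5e-8 stringency as
  instrument selection; the source analyses do not pin this value, so it
  is configurable and logged.
- SNPs missing from the LD matrix are treated as independent with a
  warning; desk-scale runs use the synthetic block panels, and real LD
  reference panels are out of scope.

## Estimators

**IVW** is the origin-constrained weighted regression with w = 1/s_Y².
Fixed-effect SE is (Σ w b_X²)^{-1/2}; the random-effects mode multiplies
it by max(1, sqrt(Q/(k−1))) (multiplicative overdispersion, matching the
convention of the mainstream R toolchain); `auto` switches to random
effects when Cochran's Q has p < 0.05 and records the choice.  CIs are
beta ± 1.96·se throughout the normal-theory methods.

**MR-Egger** first orients instruments so b_X > 0 (jointly negating
outcome effects), then fits the weighted regression with intercept.  Both
SEs carry the max(1, sqrt(Q′/(k−2))) inflation.  The intercept, its SE
and p estimate directional pleiotropy.  I²GX quantifies how far the NOME
assumption holds; values above ~0.98 mean Egger attenuation is negligible.

**Weighted median** uses delta-method ratio variances for weights and
linear interpolation of the ordered ratios at cumulative weight 0.5.  Its
SE is the SD of the estimate over 1000 seeded parametric bootstrap
resamples of (b_X, b_Y).  Calibration note: under no heterogeneity the
observed ratio spread is purely sampling noise, and resampling centred at
the observed values adds that noise a second time, so the bootstrap SE is
conservative — measured coverage at the default study conditions is
97.6% ± 0.3% (2000 replicates) against the nominal 95%, with the
bootstrap SE about 1.16× the empirical SD.  This is a property of the
standard estimator, not a defect of the implementation; the acceptance
suite documents it as an out-of-band coverage reading.

**MR-PRESSO** computes, for each SNP, the weighted squared residual
against the IVW fit that excludes it; the global statistic is their sum.
Its null distribution is simulated (default 1000 draws) by resampling
both sides from the no-pleiotropy model; reported p-values use the
add-one estimator so they are never exactly zero, while the per-SNP
outlier decision uses the raw empirical exceedance count with Bonferroni
correction (with 1000 simulations and ~50 SNPs the add-one floor of
k/(n_sim+1) would otherwise make any outlier unflaggable).  The
distortion test compares the estimate shift after outlier removal with
the shifts from random removals of the same size.  The corrected estimate
is IVW on the outlier-free set.

**BWMR** models b_Yj ~ N(θγ_j + α_j, s_Yj²) with pleiotropy
α_j ~ N(0, τ²) and true exposure effects γ_j ~ N(b_Xj, s_Xj²).
Marginalising γ and α gives b_Yj ~ N(θ·b_Xj, τ² + s_Yj² + θ²s_Xj²),
which is sampled by adaptive random-walk Metropolis on (θ, log τ²), two
chains of 4000 iterations (half burn-in), priors θ ~ N(0, 10²) and
τ ~ half-N(0, 0.5²).  One down-weighting sweep follows: SNPs whose
posterior standardized residual |z| exceeds 3 get likelihood weight
(3/|z|)², and the chains re-run.  Split-chain R-hat above 1.1 is a hard
error carrying the diagnostic.  This MCMC formulation replaces the
original variational algorithm because it is simpler to verify; the
benchmark is agreement with IVW under no pleiotropy (posterior mean
within 0.05), not equality with the original software.

**Multivariable MR** solves the weighted normal equations of b_Y on the
k×m exposure-effect matrix (no intercept for the IVW extension, a common
intercept for the Egger extension with rows oriented on the first
exposure), with dispersion max(1, sqrt(Q_A/(k−m))).  The Q-minimization
estimator minimizes Q(θ) = Σ (b_Yj − b_Xj·θ)² / (s_Yj² + Σ_a θ_a²s_Xja²)
by multi-start Nelder-Mead seeded around the IVW solution ± 2 SE; its
per-coordinate 95% CIs come from the profile-Q rule ΔQ ≤ χ²₁(0.95),
which is deterministic given the data (a bootstrap is deliberately not
the default).  The returned minimum is asserted to be no worse than the
IVW point.  Conditional instrument strength for exposure a regresses its
SNP effects on the other exposures' effects, iteratively reweighting by
the propagated measurement variance s_Xa² + Σ δ²s_Xb², and reports
F_a = Q_xa/(k−m+1); duplicated (collinear) exposures drive F to 0, and
F < 10 flags weak conditional instruments.  Proxy substitution requires a
signed orientation per proxy; unsigned proxies are refused.

**Mediation** chains three IVW fits (exposure→outcome c,
exposure→mediator a, mediator→outcome b).  The indirect effect is a·b
with a Monte Carlo CI from 100,000 independent normal draws of a and b
(the count is a documented default; the upstream web tool's settings are
not published).  The proportion ab/c holds c at its point estimate (a
sensitivity option also draws c), truncates its CI below at 0, and
reports NA when ab and c disagree in sign — that rule is inferred from
the single NA row of the published mediation table and is flagged in the
output as such.

**Power** for a binary outcome uses the standard non-centrality
approximation NCP = n·R²·cf·(1−cf)·log(OR)², with
power = Φ(−z + √NCP) + Φ(−z − √NCP).  The published power entries are
checked qualitatively (≥ 0.99 at plausible inputs) because the analysis
inputs behind them are not printed.

Significance labelling follows the Bonferroni convention: p < α/n_tests
is significant, α/n_tests ≤ p < α suggestive, else null.  n_tests
defaults to the number of configured exposure-outcome pairs (the source
analysis had 4 × 6 = 24, giving the 0.0021 threshold).

## Synthetic data

The generator emulates exactly the structure the estimators assume:
MAFs uniform on (0.05, 0.5); per-SNP standardized effects scaled so
Σ 2p(1−p)γ² equals the target variance explained exactly; exposure SEs
1/sqrt(2p(1−p)n); outcome log-odds effects θγ_j + α_j with case-control
SEs 1/sqrt(2p(1−p)·n·cf·(1−cf)); independent noise streams on the two
sides.  Defaults mirror a biobank exposure GWAS against a registry
case-control outcome: k = 100, h² = 0.18, n_exposure = 440,000,
n_outcome = 307,452, case fraction 0.0136, θ = log(1.489).  Pleiotropy
modes: `balanced` (zero-mean α on a fraction of SNPs), `directional`
(nonzero-mean α applied along sign(γ), since directionality is defined in
the oriented frame), and `inside_violating` (α correlated with |γ|, which
defeats the InSIDE assumption and is what the Egger intercept test is
most sensitive to).  The MVMR generator draws per-SNP effect vectors
multivariate-normal with cross-exposure correlation ρ; the mediation
generator gives the mediator its own instruments (default 100 SNPs,
n = 100,000 — small enough that exposure instruments stay below
genome-wide significance on the mediator, as a real mediator GWAS's
instrument selection would enforce with its screens).

What the generator does not emulate: realistic LD (only block-diagonal r²
panels for exercising the clumper), sample overlap, population
stratification, winner's-curse selection of instruments, and
individual-level binary-trait likelihoods (outcome effects are generated
directly on the log-odds scale with normal noise).  Passing tests
therefore certify the estimators under their own statistical model, not
robustness to those real-data complications.

## Verification and problem sizes

The suite checks closed-form oracles exactly (IVW and MVMR-IVW against
explicit normal-equation solutions at 1e-10; weighted median against a
brute-force interpolation; Cochran's Q term by term; Q-minimization
against MVMR-IVW in the s_X → 0 limit at 1e-4) and statistical behaviour
by seeded simulation: 500-replicate bias/coverage at the default
conditions for the four main estimators, 300 replicates for MVMR direct
effects (0.4, 0) under a ρ = 0.5 covariate, 150 for mediation recovery of
a·b = 0.15, 400–500 replicates for error control (IVW type-I, MR-PRESSO
global-p uniformity, Egger intercept level under balanced pleiotropy,
outlier detection power at an 8·SE offset), and a five-point ρ sweep
(n_exposure = 33,000) for the conditional-F weak-instrument behaviour.
The acceptance script reruns the same experiments at 300/150/200
replicates, which keeps its end-to-end runtime around one to two minutes
while leaving simulation error well below the quantities' movement.

## Known limitations

- Normal-theory p-values and CIs everywhere (no t small-sample
  corrections); with k ≥ ~30 instruments the difference is negligible.
- BWMR's two-parameter marginalised MCMC does not expose per-SNP
  posterior pleiotropy effects, only the global τ² and the down-weights.
- The weighted-median bootstrap SE is conservative under homogeneity
  (see above).
- Proxy discovery is the caller's responsibility (a local signed table);
  there is no remote LD lookup by design.
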