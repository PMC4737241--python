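# Methods

## Rate estimation

All per-category rates are concatenated: d_N = Σ D_N / Σ N over the
contigs of a category, and likewise d_S, p_N, p_S and the diversity
measures. The ratio-of-sums form weights every site equally, avoids the
effectively infinite per-contig dN/dS values produced by contigs with
near-zero synonymous divergence, and makes every downstream statistic a
function of category column sums — which is what lets the resampling
kernels vectorize. The Faster-Z effect is the ratio of category ω
values, (d_NZ/d_SZ)/(d_NA/d_SA); the natural reference category is
autosomes 1–10, which match the Z in size and recombination
environment, while microchromosomes (here: autosomes numbered above 10)
are kept separate because their elevated recombination rate and GC
content alter the efficacy of selection.

Contigs with whole-tree synonymous divergence above `ds_max = 2.0` are
removed before estimation (strict inequality; a contig at exactly 2.0
is kept). Beyond that point synonymous sites saturate and dS is
underestimated, inflating ω.

## Resampling inference

The contig is the exchangeable unit. Bootstrap 95% CIs (default 1000
replicates) resample contigs with replacement within each category and
take the 2.5th/97.5th percentiles of the replicate statistics — the
percentile method, chosen for simplicity and exact reproducibility over
BCa. Permutation tests (default 1000 replicates) pool the two
categories, redraw labels with group sizes fixed, and report the
add-one-smoothed p = (1 + #{replicate ≥ observed})/(n_perm + 1), which
is valid (never below 1/(n_perm+1)) and slightly conservative.
Z-vs-autosome contrasts are one-tailed (the hypothesis is directional:
Z higher); between-expression-class contrasts are two-tailed (no
a-priori ordering). Replicates on which a statistic is undefined (zero
synonymous sums) are dropped; if more than half are undefined the
computation is refused rather than silently reported. All randomness
flows from a single seed through named, independent streams, so results
are bit-reproducible and the bootstrap and permutation draws do not
share state.

## McDonald–Kreitman analysis

Per contig, the 2×2 table [[D_N, D_S], [P_N, P_S]] enters the test only
when every marginal sum is ≥ 6; sparser tables are reported as excluded
rather than tested. The default test is the continuity-corrected
chi-squared, χ² = n(|ad−bc|−n/2)²/(r₁r₂c₁c₂) with the corrected
numerator floored at zero — this is the convention of the R
`chisq.test` default and reproduces the published per-species p-values
(e.g. p = 0.004 for counts 51/83/1174/3276). Uncorrected Pearson and a
fixed-margin Monte-Carlo p (hypergeometric table sampling, add-one
smoothed) are available as alternatives since which variant was used
per-contig historically is ambiguous. Direction: positive selection when
(D_N/D_S) > (P_N/P_S) with both defined; relaxed purifying selection for
the reverse, including P_S = 0 < P_N (an effectively infinite
polymorphism ratio) when D_N/D_S is finite; ties and undefined
comparisons (D_S = 0, or P_N = P_S = 0) are direction-free — no
infinite ratio is ever fabricated.

Multiple testing uses Storey q-values with the tuning parameter λ fixed
at 0: π₀ = #{p > λ}/((1−λ)m), clamped to (0, 1], followed by the
monotone step-up q(i) = min_{j≥i} π₀·m·p(j)/j. With λ = 0 and no
zero p-values π₀ = 1 and the q-values coincide exactly with
Benjamini–Hochberg adjusted p-values (property-tested against
statsmodels).

One caveat frozen into the tests: for the published turkey counts the
computed ratio is 1.7147 → 1.715 as printed, but for the pheasant
counts (89/157)/(1654/4950) = 1.697 while 1.700 was printed; the
implementation always reports the value computed from its inputs.

## Effective population size

Diversity is measured two ways: π as the polymorphic fraction of
fourfold-degenerate sites (Σ P_4D/Σ 4D, concatenated), and Watterson's
θ = S/(H(n−1)·sites) with H the harmonic number and n the sampled
allele copies — 20 autosomal and 15 Z-linked under a 5-male + 5-female
design (the printed θ formula in the source material is internally
inconsistent, omitting the segregating-site numerator; the standard
estimator is used). N_E = diversity/(4·U·g) with per-site per-year
mutation rates U_Z = 1.45×10⁻⁹ and U_A = 1.33×10⁻⁹ (Galliform
estimates; U = K/2T from divergence K and split time T), reflecting
male-biased mutation. Generation time g is a required input — it
cancels in the N_EZ/N_EA ratio but scales absolute N_E, and no default
is assumed.

For the Z/autosome ratio the package prefers the θ route: with unequal
sample sizes (15 vs 20 copies) the raw polymorphic-site fractions
differ by the factor H(14)/H(19) even at equal underlying diversity,
and Watterson's estimator removes exactly that factor. The ratio's
bootstrap CI resamples contigs within each category; a CI excluding ¾
rejects the equal-reproductive-variance expectation.

## SNP detection power

Detection power differs between Z and autosomes purely through sample
size. The simulation builds a population of 100 allele copies (50
diploids) holding round(maf·100) minor copies, draws n copies without
replacement per replicate (implemented as a hypergeometric draw, which
is the same distribution), and scores a false negative when a single
distinct allele is drawn — including the all-minor corner case. The
closed form [C(M−K, n) + C(K, n)]/C(M, n) serves as the oracle: 0.0262
for n = 20 and 0.0710 for n = 15 at MAF 0.15, dropping to 0.0015 and
0.0090 at MAF 0.25. The population size of 100 copies is a modelling
choice (it is the point where the analytic values sit within
Monte-Carlo sampling error of the published estimates of 0.023 and
0.068 at 1000 replicates, while an infinite-population binomial does
not); it is a parameter, not a constant.

## Expression classification

Genes pass the expression filter when more than half of the samples of
at least one sex-tissue group exceed 2 RPKM (strict). Fold change is
log₂(mean male RPKM) − log₂(mean female RPKM) on raw means; sex-limited
means one sex's mean is exactly 0 (the only reading under which the
fold-change thresholds are inapplicable). Significance comes from a
Welch two-sample t-test on log₂(RPKM+1) — unequal variances between
sexes are expected and the log stabilizes RPKM spread; whether the
historical analysis tested raw or logged values is not recoverable, and
the high concordance reported against count-based methods suggests the
choice is not critical — with Benjamini–Hochberg correction at FDR 5%
across the species-tissue gene set. Biased classes require significance
and |log₂ FC| ≥ 1 (the boundary value assigned outward, to the biased
class); everything else is unbiased.

The conserved cross-species map assigns a gene a class only when all
six species agree after pooling sex-limited with sex-biased per sex.
The relaxed map requires at least half of the species to be
limited/biased toward a sex and the fold change to have that sex's sign
in all species. Per-class Faster-Z reuses the divergence estimator
inside each class.

## Comparative regression

PGLS fits y = a + bx by generalized least squares with error covariance
C from Brownian motion on the species tree: C[i,j] is the root-to-MRCA
shared path length. The fit whitens with the Cholesky factor of C,
estimates residual variance as RSS_C/(n−2), and reports t = b/se(b)
against Student's t(n−2), one-tailed for the directional hypothesis
that Faster-Z increases with sperm-competition intensity. r² is
computed in the whitened space against the GLS intercept-only fit.
Pagel's λ is fixed at 1 (pure Brownian): with six species λ is too
weakly identified to estimate, and the GLS solution is deterministic,
so no run-averaging is needed. Residual testes mass is the deviation
from the avian allometry log₂ testes = −1.56 + 0.61·log₂ body (grams).
Robustness uses leave-one-species-out refits on the pruned tree (df
drops to n−3). The implementation is cross-checked against statsmodels
GLS in the test suite but does not depend on it for the fit.

## Synthetic data

The generators emulate the statistical structure the estimators assume,
not sequences: substitution counts are Poisson in sites × branch
divergence × ω (ω multiplied by the true Faster-Z effect on the Z);
polymorphic-site counts are Poisson with per-site rate θ·H(n−1)
(Watterson's expectation), the Z's θ scaled by the true N_EZ/N_EA and
the mutation-rate quotient U_Z/U_A, and nonsynonymous polymorphism
shrunk by a purifying-selection factor (default 0.3, matching observed
pN/pS); fourfold-degenerate counts are a binomial subset of synonymous
sites so P_4D ≤ 4D holds by construction. Contig lengths are log-normal
(median 900 sites, σ = 0.6) with a 3:1 nonsynonymous:synonymous site
ratio. Default dimensions are 160 Z / 1690 autosome-1–10 / 741
microchromosomal contigs; default rates are ω_A = 0.12, dS = 0.15 per
contig tree, θ_A = 0.005, true Faster-Z 1.2 and true N_EZ/N_EA 0.75 —
values a Galliform transcriptome study would consider realistic.
Expression is log-normal with configurable biased/limited fractions and
effect sizes; traits evolve by Brownian motion on the tree with a
linear signal plus Brownian noise.

What the generators do **not** emulate: linkage and shared genealogies
across contigs (counts are independent given their rates),
overdispersion from alignment or mapping error, expression count noise
(RPKM is treated as log-normal, not negative binomial), demography or
family structure in polymorphism data, and GC-driven rate covariates on
microchromosomes. Passing the recovery tests therefore shows the
estimators are correct and calibrated under their own model — not that
real transcriptome data meet that model.

## Problem sizes and numerical choices

The test suite runs recovery and calibration experiments at the scales
that make them statistically meaningful while staying fast: 100 seeded
runs at full table dimensions for Faster-Z and N_E-ratio coverage, 500
null runs (n_perm = 500) for permutation type-I error, 120 Brownian
replicates for PGLS slope unbiasedness, and 10 000 replicates for
Monte-Carlo/analytic agreement in the power simulation. Printed-table
comparisons round half away from zero to 3 decimals; rates are carried
at full precision internally. Degenerate inputs fail loudly: zero site
totals, zero synonymous rates, zero contingency margins, trees with
missing branch lengths and constant predictors all raise errors naming
the offending quantity rather than propagating NaN.

## Known limitations

- The MK framework here has no DFE-α/asymptotic-α extension; segregating
  slightly deleterious alleles bias individual MK tests toward relaxed
  selection.
- N_E estimation is moment-based; no coalescent or demographic model is
  fit, and the mutation-rate constants are external inputs.
- PGLS supports a single predictor with fixed λ = 1; with n = 6 species
  the power of the slope test is intrinsically low and leave-one-out
  refits are the only robustness check offered.
- The category scheme is tied to the chicken karyotype (autosomes 1–38,
  microchromosome = number > 10); linkage groups and unplaced scaffolds
  are excluded rather than assigned.
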