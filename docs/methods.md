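# Methods

## Model

The core model is the univariate animal model with a common full-sib
environmental term,

    y = X b + Z u + W c + e
    u ~ N(0, K σ²g),   c ~ N(0, I σ²c),   e ~ N(0, I σ²e)

where `y` are tagging-weight records, `X` carries generation and spawning
batch as factors plus tagging age (days) as a linear covariate, `Z` maps
records to animals, and `W` maps records to full-sib families. `K` is the
pedigree numerator relationship matrix `A` (PBLUP) or the single-step
matrix `H` (ssGBLUP). Heritability and the family-effect ratio are
h² = σ²g/(σ²g+σ²c+σ²e) and c² = σ²c/(σ²g+σ²c+σ²e). The reduced model used
to study omission bias simply drops `Wc`.

Assumptions worth stating: a single base population (no unknown-parent
groups or metafounders); families coincide with (sire, dam, batch)
triples; the c term is an environmental covariance shared exactly by full
sibs — maternal genetic effects and dominance, which a full-sib term
partially absorbs in real data, are not modelled separately.

## Relationship matrices

* `A` by the tabular recursion; a memory guard (default 20,000 animals)
  refuses accidental dense construction at population scale.
* `A⁻¹` by Henderson's rules with Mendelian-sampling variances
  dᵢ = 0.5 − 0.25(F_s + F_d); inbreeding F by the Meuwissen–Luo
  ancestor-tracing recursion (the F = −1 convention for unknown parents
  collapses the known/unknown-parent cases into one formula).
* `A22` (genotyped block) by Colleau's indirect method — two gene-flow
  sweeps per column — so the dense A is never formed for large pedigrees.
* `G` by VanRaden's first method, Z centred by 2pᵢ and scaled by
  Σ2pᵢ(1−pᵢ); missing gene content enters at its expectation 2pᵢ;
  monomorphic or all-missing SNPs are excluded. `G* = τG + ωA22` with
  τ = 0.95, ω = 0.05 by default — the de-facto standard blend; an explicit
  diagonal/mean tuning step is deliberately *not* applied so the
  single-step formula stays literal.
* `H⁻¹ = A⁻¹ + [0 0; 0 G*⁻¹ − A22⁻¹]` is held as sparse `A⁻¹` plus the
  dense genotyped-block correction; log|H| = log|A| + log|G*| − log|A22|
  is tracked for the REML likelihood.

## Variance-component estimation

**AI-REML.** The mixed-model equations are assembled in variance-scaled
form C = M′M/σ²e + diag(0, K⁻¹/σ²g, I/σ²c), so C⁻¹ is directly the
sampling covariance of the solutions. The restricted likelihood uses the
MME identity −2ℓ = n log σ²e + log|Kσ²g| + log|Iσ²c| + log|C| + y′Py +
(n−p) log 2π, gradients use the standard trace identities
(tr(K⁻¹C^{uu}), tr(C^{cc})), and the average-information matrix is built
from the working vectors fᵢ = VᵢPy. Updates are Newton steps on the AI
matrix with a backtracking line search on ℓ; a direction that cannot
improve ℓ falls back to an EM update, which is monotone, so ℓ never
decreases. Parameters are floored at 10⁻⁶ × var(y); a floored parameter
whose gradient points downhill leaves the active set and is flagged as a
boundary estimate. Convergence: relative parameter change < 1e-8 and
free-gradient norm < 1e-6 by default; the replicate experiments pass
1e-4/1e-2, at which point estimates are already stable to the third
decimal (checked against the tight setting on the same data).
Asymptotic SEs come from the inverse AI matrix, with delta-method SEs for
h² and c². Both likelihood and analytic gradients are verified in the
test suite against dense-V oracles.

The factorisation is dense Cholesky (LAPACK dpotrf/dpotri on a
Fortran-ordered buffer) up to 9,000 unknowns — the trace terms REML needs
have no shortcut without a supernodal selected inverse, and at the scales
this package targets (≲ 5,000 equations) dense is both simpler and fast —
with a sparse-LU path above that for plain solves.

**Gibbs sampling.** Location effects are drawn either jointly (blocked;
dense Cholesky per cycle, exact but cubic) or by single-site Gauss–Seidel
sweeps over the MME (the classic animal-breeding sampler; a numba kernel
over the union sparsity pattern makes full-scale chains practical).
Variances use scaled inverse-chi-square conditionals under flat priors
*bounded* at 5 × var(y), enforced by rejection; the bound matters — with
an unbounded flat prior, chains on designs with few family levels show
the well-known runaway behaviour. Post-burn-in traces are checked for
stability (Geweke-style z between the two halves); an unstable trace
gates the summary to the stabilised second half with a warning.

**Bivariate model.** Tag weight is co-analysed with challenge-test
survival time (treated as Gaussian) sharing the additive structure:
covariance G0 ⊗ K for the genetic term, C0 ⊗ I for families, and a 2×2
residual block for records carrying both traits (per-trait incidence for
missing survival records; phenotypes are never imputed). The restricted
likelihood decomposes over four fixed cross-product matrices because R⁻¹
takes only four distinct scalar weights, so each evaluation is scalar
algebra plus one Cholesky. It is maximised by L-BFGS-B on log-Cholesky
coordinates in two stages (cross-trait covariances first at fixed
univariate variances, then a joint polish) with loose box bounds that
keep the search out of degenerate corners. The Gibbs variant uses
inverse-Wishart conditionals with missing trait-2 residuals drawn from
their conditional each cycle. The likelihood is verified against a dense
stacked-V oracle.

**LRT for c².** χ² = 2(ℓ_full − ℓ_reduced) clipped at zero with a df = 1
chi-square p-value, matching common reporting practice; the 50:50
boundary mixture (which halves p) is available behind a flag. Note that a
df = 1 test needs χ² ≥ 3.84 for p < .05; published analyses sometimes
label smaller values significant, which this implementation does not
reproduce.

## Evaluation protocol

Five-fold cross-validation repeated five times (25 runs; fold sizes
differ by at most one). Variance components are estimated once per model
on the full data and held fixed across runs — a per-run re-estimation
flag exists but 25 REML fits buy little beyond cost. In each run the
validation phenotypes are excluded from the MME (relationship matrices
are untouched, so genotyped validation animals stay in H), and the
validation animals' EBVs — û only, never the family effect — are
correlated with their phenotypes, pre-adjusted for the fixed effects
estimated on the training records (raw-phenotype mode available).
Accuracy is r/√h². Which h² enters the denominator matters and is rarely
stated explicitly in applied reports. This package's pipeline divides
both model variants' correlations by the *same* trait heritability, the
one estimated by the full (with-c²) model; the per-variant ("own h²")
mode is available through the `h2` argument. The shared convention is the
one under which the omission-bias percentages
100 × (acc_without − acc_with)/acc_with behave as reported in the
literature: in this family-nested design the family-mean information
splits between û and ĉ in proportion to their prior variances, so even
the with-c² EBV co-varies with the family environment and its raw
validation correlation is far from small (at true components,
corr(û, true c) ≈ 0.4 was measured in simulation). Dividing each
variant's correlation by its own √h² then *deflates* the without-c²
accuracy by its inflated heritability and can push the with-c² accuracy
above 1 and the bias negative — an artefact of the normalisation, not of
the prediction. Under the shared denominator the bias is structurally
positive, because the without-c² EBV tracks family means strictly better.
Report tables compute the difference before rounding and display
accuracies to four decimals, differences to one.

## ssGWAS

SNP effects are back-solved from the genotyped animals' GEBVs,
a = Z′G*⁻¹û / Σ2pᵢ(1−pᵢ); with the unblended G this reproduces û exactly
(Z a = û), which the tests assert to 1e-8. Sampling variances propagate
var(û) = σ²g G* − PEV through the same linear map, where the PEV block is
obtained by solving the MME for the genotyped columns only; z-scores get
two-sided normal p-values, monomorphic SNPs carry effect 0 and p = 1. A
SNP enters the pre-selected panel when p < 1e-5 in *every* CV run
(intersection rule; a union rule is available — the choice is ambiguous
in common descriptions of the protocol). The evaluation is then re-run
with G rebuilt from the selected subset; an empty selection falls back to
the full panel with a warning. Iterative SNP re-weighting (WssGBLUP) is
deliberately out of scope — subset re-fitting is the protocol mirrored
here.

## Family imputation

Missing genotypes are filled by the first applicable deterministic rule:
(1) both parents observed → Mendelian expectation (g_s + g_d)/2;
(2) one parent observed → g_par/2 + p; (3) ≥ 3 genotyped full sibs →
sib mean; (4) population expectation 2p. Gene content stays real-valued
(G accepts it); integer rounding exists for PLINK export. This is a
deliberate simplification of phasing/peeling HMM imputation: the claim it
supports is "pedigree-aware filling beats the population-frequency
baseline", which the tests verify (strictly smaller MSE against truth),
not that it matches a full haplotype model. In the emulated design the
genotyped fish are offspring whose parents are ungenotyped, so rule 3
does most of the work.

## Synthetic-data generator

The generator emulates the study design the analysis assumes: three
cohorts (default 179/167/93 families; cohort 0 parents are founders,
later cohorts draw parents from cohort-0 offspring), semi-nested matings
(each sire serves one or two dams), truncated-negative-binomial family
sizes (min 10, max 87, mean 27.1; dispersion r = 3 reproduces the
observed spread with two parameters), spawning batches and tagging age
assigned per family (9/4/7 batches; ages uniform on the cohort ranges,
with a 0.05 g/day slope around the population mean age of 172.2 d), and a
genotyped subset of 560 fish from 40 cohort-1 families over 14,154 SNPs
with exactly 10% of cells masked. Founder genotypes are Hardy–Weinberg
draws at frequencies uniform on [0.05, 0.5]; offspring inherit one allele
per parent per locus independently (no linkage map — LD beyond
family/pedigree structure is not emulated, which mainly matters for
ssGWAS fine-mapping realism, not for the variance-component machinery).
True breeding values come from 500 QTL kept inside the panel (they can be
hidden by flag), with effects rescaled so the founder TBV variance equals
σ²g exactly; all animals carry simulated genotypes so σ²g is consistent
between A- and G-based analyses. Default variance components
σ²g = 22.5, σ²c = 106.5, σ²e = 21 g² reproduce the partition
h² = 0.15, c² = 0.71 at a phenotypic SD of ~12.2 g, and the cohort means
are calibrated so the expected population mean is 22.7 g. Batch effects
are N(0, 1.5²) g — their true magnitude is not identifiable from
published summaries, so this default is arbitrary and documented. The
second trait (survival time) is linear Gaussian with its own components
(20/15/65 g²-days scale) and a configurable genetic correlation
(default 0.3) realised through a shared pedigree-structured polygenic
deviate; no published estimate exists for this correlation, so it is a
free parameter, not a calibration.

Every stage draws from a fixed per-stage stream derived from the single
seed, so each operation is bit-reproducible in isolation and in the
pipeline.

## Problem sizes used in the shipped experiments

The replicate experiments run at a reduced scale that preserves the
design's structure: 150 families (61/57/32) of ~25 offspring (~3,750
records), 2,000 SNPs, 500 genotyped fish. At this scale the asymptotic SE
of a single ĥ² is ≈ 0.11 (computed from the AI matrix at the true
components) — the additive variance is separated from the family variance
only through cross-family genetic ties, so single replicates scatter
widely and recovery statements are made about means over 8–14
replicates. Estimates at this design occasionally hit the σ²g = 0
boundary; that is the true restricted-likelihood maximum for those draws,
not an optimiser failure (the tests check likelihood dominance
explicitly). The same identifiability ceiling applies, more mildly, at
the full scale of such studies, which is worth remembering when reading
any single-dataset h² for a trait with c² of this size.

## Known limitations

* Threshold (probit) models for survival are not implemented; the
  bivariate path treats survival time as Gaussian.
* The c² term cannot separate common environment from dominance or
  maternal genetic effects — as in the real design it emulates.
* No unknown-parent groups, metafounders, APY inverse, or SNP
  re-weighting.
* The single-site Gibbs sampler mixes slowly for σ²g under weak
  identification; chains at the shipped scale use 20k cycles with a
  REML-informed start, and the stability gate flags residual drift.
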