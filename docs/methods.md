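# Methods

## Statistical models

### Mixed-model association

Phenotypes are first residualized on sex and slaughter batch by ordinary
least squares on an intercept + indicator design (drop-first coding); a
rank-deficient design triggers a pseudoinverse fit with a warning.  The
per-SNP model is y = xβ + u + e with u ~ MVN(0, σ²ₐG), e ~ MVN(0, σ²ₑI),
genotypes coded as 0/1/2 copies of the minor allele (the effect allele is
always the minor allele; sites are flipped on import when the VCF ALT
allele is the major one).

The genomic relationship matrix is the centered-and-scaled form
G = (1/m) Σₖ (xₖ−2pₖ)(xₖ−2pₖ)ᵀ / (2pₖ(1−pₖ)), with per-SNP mean
imputation of missing dosages and monomorphic SNPs excluded.  REML
profiles δ = σ²ₑ/σ²ₐ using one spectral decomposition of G: with
ỹ = Uᵀy, X̃ = UᵀX and d = λ + δ, the profiled restricted log-likelihood
is

−2ℓ_R(δ) = (n−q)·log(2πσ̂²ₐ) + Σ log dᵢ + log|X̃ᵀD⁻¹X̃| − log|XᵀX| + (n−q),

σ̂²ₐ = GLS-RSS/(n−q).  δ is located on a 64-point log₁₀ grid over
[10⁻⁵, 10⁵] and refined by bounded scalar minimization in the bracketing
interval (xatol 10⁻¹⁰ in log₁₀δ); an optimum at the grid limits sets a
boundary flag.  Negative eigenvalues of G from numerical noise are
clipped at zero.

The scan defaults to reusing the null-model variance components for every
SNP (EMMAX approximation; `vc_mode="per_snp"` re-optimizes δ per SNP with
the SNP in the fixed effects).  Per SNP, β̂ and SE come from the 2×2
weighted normal equations in the eigenbasis — an O(n) operation per SNP
after the one-off transforms — and the p-value is a two-sided Wald χ²₁.
p-values are floored at the smallest positive double.

QC precedes everything: individuals with call rate ≤ the threshold are
removed first, SNP statistics are then recomputed, and SNPs are kept when
call rate and MAF strictly exceed their thresholds (0.9 and 0.05 by
default).  A threshold given as exactly 0 disables that filter, so QC at
all-zero thresholds is the identity.

**Leave-one-chromosome-out (LOCO).**  The pipeline scans each chromosome
against a GRM built from the *other* chromosomes, keeping the whole-genome
GRM only for the reported genomic heritability.  At desk scale this is
not optional: a 41-SNP causal window is a visible fraction of a GRM built
from a few hundred simulated SNPs, and including it absorbs the signal
into the polygenic term (proximal contamination).  `lmm_scan` itself is
agnostic — the caller chooses the GRM.

### Meta-analysis

The sample-size z-scheme: zᵢ = sign(β̂ᵢ)Φ⁻¹(1−pᵢ/2),
Z = Σ√Nᵢzᵢ/√ΣNᵢ.  Alleles are harmonized per variant to the first
population's effect/other pair (or a supplied reference): swapped pairs
negate z, incompatible pairs are excluded with an `allele_mismatch` flag,
strand-ambiguous pairs (A/T, C/G) are kept but flagged by default.
Variants absent from some populations are combined over those available
(configurable minimum); each record carries a per-population direction
string (`+`, `−`, `?`).  An inverse-variance alternative on β̂/SE exists
behind `scheme="invvar"`.  Input sample sizes are taken at face value; no
effective-N correction is applied to cross-bred populations.

### Haplotype effects and shared segments

Windows of 2k+1 SNPs (k = 20) are extracted around a lead from phased
haplotypes, truncating with a warning at chromosome ends.  Haplotypes
with frequency strictly above 0.05 get columns of the incidence matrix H
(copies 0/1/2, rows summing to 2); the rest pool into one rare column, so
no individuals are dropped and row sums stay 2.

The printed model y = Hβ + u + e is not identifiable together with an
intercept (rows of H sum to 2), so the most frequent haplotype is dropped
as reference and an intercept added; effects are per-copy deviations from
the reference.  Estimation whitens both sides with
W⁻¹ = U·diag((σ²ₐλ+σ²ₑ)^(−1/2))·Uᵀ and applies OLS, which reproduces
dense GLS to machine precision (tested at 10⁻⁸ relative).  Significance
is a two-sided t test with n − #columns degrees of freedom; collinear
columns are dropped with a warning.  Because the reference choice is
population-arbitrary, the result table also carries effects re-centered
to the frequency-weighted population mean, with standard errors derived
from the full coefficient covariance; these centered effects have
comparable polarity across populations and drive the cross-population
haplotype selection.

The shared segment of a set of selected haplotypes over common window
positions is the longest run of consecutive positions at which all
strings agree, reported as a 1-based inclusive bp interval (leftmost run
on ties, empty if none).  Pipeline selection rule: haplotypes significant
at α = 0.01 on the centered test, sign-matched to the strongest effect,
drawn only from populations that themselves have a lead SNP within the
sentinel window of the locus — the segment comparison is only meaningful
where the association exists.  Sharing classification per haplotype:
*specific* if frequency ≥ 0.05 in exactly one population and < 0.01
elsewhere, *shared* if ≥ 0.05 in at least two, otherwise *absent*.

Haplotype trees are Saitou–Nei neighbor joining on Hamming distances,
with Q-ties broken by the smallest node-creation-order pair and negative
branch lengths clamped to zero with a warning.  NJ is exact on additive
matrices (verified topology and lengths on random 6-taxon trees).

### Peak enrichment and candidate genes

BED intervals (0-based half-open) are converted to 1-based inclusive and
merged per mark when overlapping or abutting.  A variant on an interval
boundary counts as inside; a variant inside peaks of two marks counts
once.  Enrichment is the ratio of lead and background in-peak
proportions, overall and per mark, with an explicit undefined flag when
the background proportion is zero; no p-value is attached to the fold.
Candidate genes are gene features (GFF3) whose span lies within 500 kb of
a lead (inclusive bound, distance 0 inside the span), sorted by distance.

## The synthetic study design

The generator emulates a multi-population quantitative-trait study:

* **Ancestral panel** — per chromosome, a pool of haplotypes over L sites
  (default 150 per chromosome, 6 chromosomes).  A fraction 0.9 of sites
  segregate with Beta(0.5, 0.5) frequencies (U-shaped spectrum, excess of
  rare variants); four rounds of random mating at per-site crossover
  probability 0.02 mix the founders.  Site spacing averages 170 bp,
  matching whole-genome-sequence SNP density, so a 41-SNP window spans
  ≈7 kb.
* **Populations** — each population draws `drift_parameter` (default 20)
  founder haplotypes; every chromosome copy is a founder *mosaic*:
  crossovers at per-site probability 0.01, each segment from the copy's
  base lineage or (probability 0.3) a random founder.  Base-lineage
  assignments are Dirichlet-weighted (skewed haplotype spectra) and
  shared across chromosomes of the same individuals, so kinship is
  consistent genome-wide — the property that makes LOCO valid, as in real
  pedigrees.  Local haplotype sharing is thereby much finer-grained than
  genome-wide relatedness.  Default sizes are six populations of
  591/296/608/305/331/315 individuals.
* **Planted causal segments** — a window substring is written onto
  chromosome copies until the carrier frequency reaches its target
  (realized within ±1/(2n), and always within the ±0.05 contract).
  Copies are filled whole local-ancestry-group by group, in decreasing
  group size starting from the *second* largest: carriers form a few
  common, coherent window haplotypes (as carriers of a real old mutation
  do), while the major local haplotype stays wild-type and remains the
  natural reference.  The default study plants one ≈3.7-kb segment shared
  by three populations (effect −0.5 trait SD per copy, frequency 0.3,
  ≈10% of variance) and one private to a single population (+0.8 per
  copy, frequency 0.25, ≈24% — matching the 5–40% variance fractions
  typical of major fatty-acid-composition loci).
* **Phenotypes** — y = μ + sex + batch + Σ a·copies + u + e with
  u ~ MVN(0, σ²ₐG) from the population's realized GRM and e iid.  Sex
  offsets are {0, +1}·σₑ and batch offsets {0, +1, +2}·σₑ — large enough
  that skipping residualization is visible, small enough not to dominate.
  The polygenic heritability target (default 0.46) applies to the
  non-QTL variance; planting more QTL variance shrinks σ²ₐ+σ²ₑ
  accordingly so total phenotypic variance stays at σ²ₚ (default 1).

What the generator does **not** emulate: coalescent genealogies,
mutation-rate heterogeneity, genotyping/imputation error, X-chromosome
dosage, linkage maps with hotspots, phenotype measurement structure
beyond two crossed factors.  Passing tests therefore demonstrate correct
estimator behavior under a controlled, pedigree-like architecture — not
performance on real imputed sequence data.

## Validation experiments and problem sizes

The test suite checks every estimator against an independent oracle
(dense-inverse GLS, a dense 10⁴-point δ-grid REML evaluation, brute-force
interval/segment enumeration, dendropy path distances, scikit-bio's NJ)
and runs simulation studies at deliberately modest sizes chosen to keep
the default suite fast: heritability recovery at n = 500 × 50 phenotype
replicates; null calibration at n = 300 with ~2000 near-independent SNPs
× 20 replicates (the binomial envelope assumes weak dependence, hence the
high-recombination, no-bottleneck fixture); meta gain and haplotype-effect
recovery at 25 replicates each.  Two experiment-specific choices deserve
note as modelling decisions:

* The null-calibration fixture draws its polygenic term from the same
  realized GRM the analysis uses, so the model is exactly specified and
  p-values are exactly calibrated; this isolates the test statistic from
  generator realism.
* The haplotype-recovery experiment draws the polygenic background from
  the kinship of the non-causal chromosome.  With few simulated
  chromosomes, a background drawn from all chromosomes puts a large
  polygenic share on the causal one, confounded with carrier ancestry
  groups — a desk-scale artifact; in a real genome the causal
  chromosome's polygenic share is negligible.  The planted contrast is
  read symmetrically (carrier column against a wild-type reference, or
  the flipped wild-type column when the reference itself carries the
  segment), since either side estimates the same carrier-vs-wild-type
  effect.

`scripts/acceptance.py` runs the full default study (2446 individuals,
6 chromosomes × 150 SNPs) plus a 5-replicate null scan, in well under a
minute.

## Known limitations

* The EMMAX approximation slightly deflates test statistics at large
  per-SNP effects; `per_snp` mode is exact but linear-cost per SNP.
* With only six simulated chromosomes, LOCO leaves ≈1/6 of the polygenic
  variance unmodeled on the scanned chromosome; strong local ancestry
  blocks then inflate the extreme null tail, and an occasional spurious
  genome-wide lead appears in pipeline runs (visible as singleton
  sentinels far from planted windows).  Real genomes (18+ autosomes)
  shrink this share proportionally.
* Shared-segment boundaries can extend beyond a planted window when the
  selected haplotypes agree by chance in the immediate flanks; the
  detected interval is maximal by construction, not a credible interval.
* `nearest_genes` and the allele harmonization are quadratic/loop-based;
  they are meant for lead sets (hundreds), not genome-wide queries.
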