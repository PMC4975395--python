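# Methods

## Model and procedure

The pipeline predicts breeding values under a single-trait animal model and
converts them into per-SNP effects and window variance shares.

**Relationship matrices.** A is built by the tabular method with inbreeding
(a_ii = 1 + F_i, F_i = a(sire,dam)/2). A⁻¹ is assembled directly and
sparsely by Henderson's rules; the inbreeding coefficients it needs come
from the Meuwissen–Luo path recursion, so no dense inverse is formed. The
genomic matrix uses the VanRaden construction G = Z D Z′ λ with
Z = M − P, P_ij = 2 p_j and λ = 1/Σ 2p_i(1−p_i). The single-step inverse
H⁻¹ adds the dense correction G⁻¹ − A₂₂⁻¹ into the genotyped block of the
sparse A⁻¹; correctness is tested against an explicitly assembled joint H
(pedigree regression of non-genotyped on genotyped animals, block by
block).

**Centering convention.** P holds twice the allele frequency of the counted
allele. By default p is estimated from the genotyped animals themselves,
which makes every column of Z sum to zero — so the raw G is always singular
along the ones vector. G is therefore blended as (1−β)G + βA₂₂ with
β = 0.05 before inversion (β is configurable; β = 0 is honoured for
full-rank toys centered on external base-population frequencies, which
`center_and_lambda` accepts).

**Solvers.** Continuous trait: the mixed-model equations are solved by a
sparse factorization; the relative residual is checked to 1e-8, and a dense
GLS pedigree-BLUP oracle pins down correctness on toys. Variance components
are inputs, not estimated (the h² values of the emulated traits, 0.41
continuous and 0.30 liability, are treated as known). Binary trait: a
liability-threshold Gibbs sampler with data augmentation — truncated-normal
liability draws, one Gauss–Seidel sweep per cycle sampling each location
effect from its scalar conditional (a numba kernel over the CSR rows of
W′W and H⁻¹), and a scaled inverse chi-square draw for σ²_a. The threshold
is fixed at 0 with a free intercept, an equivalent parameterization of an
estimated threshold; σ²_e ≡ 1 because it is unidentifiable on the liability
scale. Priors are flat (fixed effects) and ν = −2 scaled inverse chi-square
(σ²_a). The default chain is 300,000 cycles, 30,000 burn-in, thinning 30
(9,000 retained); validation studies use a scaled-down 20,000/2,000/10
chain, which suffices at ~2,000 records.

**Weighted iteration.** D starts at I; â_g is computed once and never
updated; each iteration back-solves û = λ D Z′ G⁻¹ â_g with the current
D and G, reweights d_i = û_i² 2p_i(1−p_i), renormalizes to tr(D) = m and
rebuilds G. Three iterations are run; the second is the reporting default.
When G is blended (the usual case), the blended inverse is used in the
back-solve as well; the exact identity Z û = â_g is recovered whenever an
unblended full-rank G is supplied.

**Window report.** Windows are consecutive, non-overlapping blocks of
`window_size` adjacent SNPs within a chromosome (default 150; terminal
windows may be shorter and are flagged, not dropped). The variance of a
window is the empirical variance across genotyped animals of its genomic
score Σ_{i∈w} Z_i û_i (sample variance, n−1), expressed as a percentage of
σ²_a. This definition accounts for LD among the window's SNPs; the naive
sum of per-SNP variances 2p_i q_i û_i² is available as
`window_method="weight_share"` and ranked identically in every comparison
we ran. The denominator σ²_a is the input additive variance (continuous) or
the posterior mean (binary) and is recorded in the output metadata. Ties in
the top-k ranking break by (chromosome, first bp).

## Data preparation

**Phenotypes.** The binary success code is 1 iff the heifer calved strictly
before 31 months (the boundary counts as failure). Contemporary groups are
the exact tuple (year of birth, farm, management group at birth, weaning,
yearling). Screening order: variability rule (binary: monomorphic CGs
dropped whole) or ±3 SD rule (continuous: within-CG mean and sample SD,
outlier included in the moments — note this means the rule cannot fire in
CGs smaller than 11, since the largest attainable sample z is (n−1)/√n),
then the minimum-size rule (< 4 records), with one re-check. The filter is
idempotent and every removal is logged with its rule.

**Genotype QC.** SNP rules in fixed order (a SNP is logged under the first
failing rule): non-autosomal chromosome label (outside 1..29 by default),
duplicate map position (all members of the group removed — there is no
principled keep rule), exact conditional HWE test p < 1e-5, MAF < 0.02
(strict inequalities throughout), quality score < 0.15, call frequency
< 0.95. Sample rules: call rate < 0.90, then duplicate dosage vectors
(missing pattern included) keeping the lexicographically smallest id. SNP
then sample passes repeat until a pass removes nothing; the loop must
terminate because every productive pass strictly shrinks the matrix.
HWE and MAF use non-missing calls only; the HWE test is the exact
conditional test (sum of conditional probabilities of heterozygote counts
no more probable than observed), validated against an exact-fraction
enumeration oracle. Missing dosages that survive QC are mean-imputed (2p)
before centering, which keeps Z centered.

## Synthetic data generator

The generator emulates the study design the pipeline targets: a
multi-generation pedigree with discrete cohorts, random matings between the
sexes of the previous cohort (repeated parents create half-sib families),
founder haplotypes drawn per SNP from frequencies in a configurable MAF
range, and gene dropping with crossovers as a Poisson process (no
interference) along each chromosome. SNP maps have strictly increasing
1-based bp positions, ~1 Mb per cM. True breeding values are the sum of
planted QTL contributions (effect sizes set so QTL i explains fraction f_i
of σ²_a at its realized allele frequency, signs random) and an infinitesimal
pedigree-drawn remainder carrying the rest of σ²_a — the emulated traits
are polygenic, so most additive variance is deliberately not attached to
markers. Phenotypes add contemporary-group effects (random N(0, 0.3²) by
default, group sizes ≥ 4 enforced) and either a Gaussian residual scaled so
the phenotypic variance net of CG is 1 (continuous; an age covariate with
known slope 0.01/day is added) or a unit-variance liability residual with a
threshold placed at the realized-liability quantile of the target prevalence
(binary, default 18.6%). All randomness flows from one integer seed through
named substreams, so identical configs are bit-identical.

What the generator does **not** emulate: founder linkage disequilibrium
(founders are in linkage equilibrium; LD arises only from co-segregation in
the simulated generations), selection or assortative mating, sex
chromosomes, and genotyping error beyond missingness. Consequently, passing
tests demonstrate the correctness and behaviour of the machinery under a
clean additive architecture, not the detection power expected on real cattle
data, where ancestral LD substantially helps window-level signal.

## Validation studies and observed behaviour

Three replicated studies (in `wssgblup.validation`, shared verbatim by the
test suite, the acceptance script and `analysis/06`):

- **Liability-h² recovery** — ~2,000 binary records, purely polygenic
  liability h² = 0.30, pedigree-only relationships, 20,000-cycle chain.
  The posterior mean across 5 seeds lands within ±0.10 of the truth; a mild
  upward bias (~+0.05) is expected from the flat variance prior with one
  record per animal.
- **QTL window recovery** — 5 QTL × 4% of σ²_a among 5,000 SNPs,
  1,000 genotyped of 3,000 pedigreed (two cohorts over 600 founders; the
  genotyped subset is drawn from the last cohort), 100-SNP windows. The
  top-10 windows at iteration 2 capture ≥3 of the 5 QTL windows in roughly
  6–9 of 10 seeds depending on the seed batch (~0.65 long-run rate). The
  machinery itself is not the limit: with the entire additive variance
  placed on the QTL the recovery is 5/5, and breeding-value accuracy at
  these sizes is ~0.70. The limit is the architecture: each QTL is 1.6% of
  phenotypic variance, 80% of σ²_a is unmarked polygenic background, and
  founders carry no LD.
- **Weight amplification** — a single 30%-variance QTL's weight grows from
  iteration 1 to 2 in 10/10 seeds (typically 20–100-fold), the qualitative
  signature of the reweighting scheme.

## Numerical choices and degenerate inputs

SPD inversions go through Cholesky and raise with advice to blend when G is
singular. The MME solve raises if the relative residual exceeds 1e-8 or if
the fixed-effect design is rank deficient after absorbing the first CG
level into the intercept. Chains that would retain zero samples are
rejected at configuration time. All-zero weight vectors cannot be
renormalized and raise. QC that empties the matrix raises naming the last
rule fired. Truncated-normal sampling clips tail probabilities at 1e-12 to
avoid infinite quantiles. The σ²_a conditional needs more than two animals
(df = q − 2). Sorting is stable everywhere a tie-break is specified.

## Known limitations

Variance components for the continuous trait are never estimated (by
design); accuracy in the reported sense of the emulated study (a formula it
does not define) is not computed; metafounders, unknown-parent groups and
dominance are out of scope; the Gibbs sampler's σ²_a mixes slowly when
every animal has a single binary record, so posterior summaries there need
the longer default chain or replicate seeds.
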