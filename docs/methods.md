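# Methods

## The trisomic case / pseudo-control model

At a biallelic SNP with minor allele A, encode genotypes as minor-allele
dosages: parents in {0,1,2}, a trisomic child in {0,1,2,3}. The child of a
trisomic trio received a diploid gamete (two alleles) from the non-disjoining
parent (NDJP) and a single allele from the correctly disjoining parent
(CDJP). A homozygous NDJP has one gamete type, carrying both its alleles; a
heterozygous NDJP transmits one copy of each allele unless the meiotic error
*reduces the two chromosomes to homozygosity*, in which case it transmits AA
or aa with equal probability.

With X the NDJP dosage, Y the CDJP dosage and Z1 the case dosage, the
pseudo-control — the genotype assembled from the untransmitted diploid gamete
and the untransmitted CDJP allele — is

    Z2 = 2X + Y − Z1.

Writing X for the NDJP regardless of which parent it is unifies the maternal-
and paternal-nondisjunction forms of this identity into one formula. The
construction is an involution (applying it to Z2 returns Z1), Z2 is always
Mendelian-admissible when Z1 is, and Z1 + Z2 = 2X + Y is conserved. Under no
association, transmitted and untransmitted alleles are exchangeable, so
Z1 − Z2 is symmetric about zero; association shifts it.

## Association statistic

Per SNP the null Z1 − Z2 = 0 is tested with a two-sided Wilcoxon signed-rank
test: zero differences dropped, mid-ranks for tied absolute differences,
statistic V = sum of positive-difference ranks. With n nonzero differences
and tie group sizes t, the p-value uses the normal approximation with mean
n(n+1)/4, tie-corrected variance n(n+1)(2n+1)/24 − Σ(t³−t)/48 and a 0.5
continuity correction whenever ties or zeros are present, and the exact null
distribution otherwise (scipy's `wilcoxon` with `zero_method='wilcox'`,
`correction=True` implements exactly this recipe). Dosage differences are
small integers, so ties are the norm and the approximate path is the one
that matters in practice. All differences zero returns p = 1 by convention.

Transmission counts follow from two identities rather than per-gamete
bookkeeping: the number of informative transmissions is
S = #heterozygous CDJPs + 2·#heterozygous NDJPs (a heterozygous NDJP
transmits two alleles; disomic trios contribute one per heterozygous parent),
and T − U = Σ(Z1 − Z2). Hence T = (S + D)/2, U = (S − D)/2 with D the summed
difference; an odd S + D is impossible on Mendelian-consistent input and
raises. The odds ratio is the transmission-count estimator OR = T/U with
95% CI exp(ln(T/U) ± 1.96·√(1/T + 1/U)); a zero count yields a degenerate
estimate (0 or ∞) and a flagged, undefined interval. Minor-allele
frequencies are Σdosage/(ploidy·n). T and U are reported in the orientation
the data imply (T = minor alleles transmitted).

## Permutation correction

Family-wise error over a scan is controlled by min-p permutation: each
permutation flips an independent fair coin per *trio* and swaps case and
pseudo-control at every SNP of that trio simultaneously, so inter-SNP
correlation (LD) is preserved — the point of min-p over Bonferroni. With
minp_b the smallest nominal p of permutation b,

    p_adj(j) = (1 + #{b : minp_b ≤ p_nominal(j)}) / (B + 1),

computed streaming (no B × S matrix), then clipped from below at the nominal
p. The clip matters only in the single-SNP / weak-signal regime, where the
discreteness of the signed-rank distribution at small n makes the raw
permutation estimate exceed or (rarely, by Monte-Carlo noise) undershoot the
asymptotic nominal p; clipping guarantees adjusted ≥ nominal and preserves
monotonicity in the nominal p and the 1/(B+1) floor. Default B = 1000; the
seed is mandatory and recorded with the results.

## Genotype calling

Raw data are six probe intensities per individual per SNP (three replicate
probes per allele). The normalized allele ratio is

    ratio = mean(A-probes) / (mean(A-probes) + mean(B-probes)),

which is invariant under common rescaling of all probes and places noiseless
clusters exactly at the allele fractions dosage/ploidy — 0, 1/2, 1 for
disomic samples and 0, 1/3, 2/3, 1 for trisomic ones. (The alternative
mean-over-sum-of-six convention merely rescales every center by 1/3 and
breaks the fraction interpretation, so the symmetric form is used.) Zero
total intensity yields a missing ratio, logged.

**Pedigree-blind caller.** Each individual's ratios across SNPs are
clustered by 1-D K-means with k = ploidy + 1 (per-individual clustering,
because a 26-trio study has far too few observations per SNP to cluster
SNP-wise). Centers initialize at the canonical fractions; assignment ties
break toward the lower dosage; empty clusters keep their previous center
(monomorphic sets stay sane); convergence when assignments stop changing or
at 100 iterations. Individuals with fewer distinct ratios than clusters get
all-missing calls. Mendelian-impossible trio configurations are deliberately
*not* suppressed — they carry the parent-of-origin signal.

**Family-constrained caller.** Given the trio's parent of origin, the caller
iterates between (a) assigning each SNP the admissible (father, mother,
child) configuration — child dosage in {gamete + allele} for the roles —
minimizing the summed squared distance of the three ratios to the members'
current per-dosage centers, and (b) recomputing centers as means of assigned
ratios. The small Lloyd-style loop is written in-package because the
canonical-fraction initialization, lowest-dosage tie-break and
empty-cluster-keeps-center rules are part of the method's definition. At
convergence each SNP's assignment is the exhaustive per-SNP optimum given
the centers (SNPs are independent given centers), which the tests verify
directly against enumeration.

**QC.** Parental genotype counts are tested for Hardy–Weinberg equilibrium
with an exact test (full enumeration of heterozygote counts conditional on
the allele counts, two-sided by probability mass; chi-square available by
flag); SNPs with p < 10⁻⁴ are discarded, monomorphic SNPs kept with p = 1.
SNPs where the two callers disagree in more than 25% of children are
discarded (for 26 children: 7 or more discordant); missing calls count as
non-discrepant and are logged.

## Parent-of-origin inference

A called configuration with a heterozygous mother, a homozygous father, and
a child carrying two copies of the allele the father lacks — (f, m, z) in
{(2,1,1), (0,1,2)} — can arise genuinely only from a maternal diploid gamete
reduced to homozygosity; its mirror image only from a paternal one. For each
trio the maternal-diagnostic rate among het-mother/hom-father SNPs is
compared with the paternal-diagnostic rate among het-father/hom-mother SNPs
by a two-sided Fisher exact test (chi-square beyond 10⁴ informative SNPs);
the NDJP is called at α = 0.05, otherwise undetermined, and the single label
applies to all the trio's SNPs (nondisjunction is one meiotic event). The
denominators condition on the homozygous co-parent because the diagnostic
configurations require it. Opposite-homozygote matings are also
origin-asymmetric in principle, but they are excluded from the diagnostic
classes; with error-free calls they are never miscalled, so they add no
discriminating signal of this kind. Inference must run on pedigree-blind
calls: the family-constrained caller never emits the diagnostic
configurations. Under a true maternal origin and error-free calls the
paternal-diagnostic count is exactly zero.

## Synthetic-data generator

The generator emulates the study design stage by stage: parental dosages are
independent Binomial(2, MAF) draws per SNP (HWE, linkage equilibrium); one
parent per trio is the NDJP (maternal with probability `maternal_ndj_prob`);
a heterozygous NDJP's gamete is reduced to homozygosity as a per-trio-per-SNP
Bernoulli event with probability `reduction_prob`; the child is gamete +
CDJP allele; case ascertainment retains a trio with probability
RR^z / max_z RR^z (z the child dosage at the causal SNP) by rejection
sampling — the exact conditional retention under a multiplicative per-allele
risk, with a bounded-rounds guard; probe intensities place the allele ratio
at dosage/ploidy plus Gaussian noise (sd `intensity_sigma`) clipped to
[0, 1], with a random per-observation overall scale so callers must be
scale-invariant.

Defaults are the study conditions: 26 trios, `maternal_ndj_prob = 25/26`
(maternal origin dominates trisomy 21; roughly one paternal trio per 26),
`reduction_prob = 0.5` (no published stage-specific rate to calibrate to;
an uninformative split between reduced and unreduced heterozygous gametes),
`maf = 0.3` (a common variant, the regime the scan targets),
`intensity_sigma = 0.03` (clusters separated by ~1/3 are then called with
≥ 99% concordance, matching a well-behaved array), `relative_risk = 1`
(null). Sample sizes in tests are chosen so each check is informative at
desk scale: 500–1000 SNPs for calling/inference properties, 4×500 null SNPs
for the type-I-error check, 26 trios wherever the claim is about the target
design.

What the generator does *not* emulate: linkage disequilibrium between SNPs
(parents are drawn at linkage equilibrium; the permutation machinery
preserves whatever correlation the input has, but the synthetic null does
not create any), recombination, mosaicism, de novo mutation, population
stratification, genotyping batch effects, or the X chromosome. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to those real-data complications.

## Numerical and design choices

- Dosage encoding throughout; allele labels live in table metadata columns.
  Coordinates are 1-based physical positions; no strand handling.
- Mendelian-inconsistent records (possible after pedigree-blind calling) are
  excluded from pairing, not clamped; the association stage expects
  trio-consistent calls. The `pairs` CLI subcommand fails (exit 2) on them
  unless `--drop-inconsistent` is passed.
- The exact HWE enumeration works in log-space (gammaln) and normalizes the
  enumerated distribution, with a 1+10⁻¹² mass tolerance when collecting
  outcomes as extreme as observed.
- Wilcoxon path selection: exact only when there are no ties and no dropped
  zeros, mirroring the recipe above.
- All stochastic stages take explicit seeds; identical inputs, flags and
  seeds produce byte-identical output tables.

## Known limitations

- The per-trio NDJP test needs enough heterozygous-parent SNPs with reduced
  gametes; with `reduction_prob = 0`, diagnostic configurations never occur
  and every trio is undetermined — as in the real design, where inference
  relies on reduction events having happened.
- The permutation adjustment is Monte-Carlo; adjusted p-values have a
  1/(B+1) floor and sampling noise of order √(p(1−p)/B).
- Disomic trios are supported in the pseudo-control and association stages
  (the validation-cohort design) but the intensity simulator and callers
  treat each cohort's ploidy uniformly per individual.
- Trios with missing parents are not handled; records must be complete.
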