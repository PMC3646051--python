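# trisoscan

Association scanning in nuclear families whose child carries a trisomy.

## The problem

In a classical case/parent-trio design the child's untransmitted parental
alleles form a perfectly matched "pseudo-control", and over-transmission of an
allele to affected children is evidence of association. In a trisomic child
(for example trisomy 21 in Down syndrome) one parent — the **non-disjoining
parent (NDJP)** — contributed a *diploid* gamete, so the child carries three
alleles per locus and the standard transmission machinery no longer applies.
`trisoscan` implements the trisomic extension of the case/pseudo-control test,
together with everything a SNP-array trio study of this design needs:

- **Genotype calling for aneuploid samples**: probe intensities are
  normalized to an allele ratio and clustered per individual by 1-D K-means
  (clusters at the allele fractions 0, 1/3, 2/3, 1 for a trisomic child),
  plus a **family-constrained caller** that updates father, mother and child
  together, restricting each SNP to Mendelian-admissible configurations.
- **Parent-of-origin inference**: pedigree-blind calling occasionally emits
  trio configurations that are possible under only one parental origin of the
  extra chromosome (a heterozygous mother, a homozygous father, and a child
  duplicating the allele the father lacks, or the mirror image). Comparing
  the rates of the two diagnostic classes identifies each trio's NDJP.
- **Pseudo-control construction**: with X the NDJP dosage, Y the CDJP
  (correctly disjoining parent) dosage and Z1 the case's minor-allele dosage,
  the pseudo-control is **Z2 = 2X + Y − Z1** — the genotype assembled from
  the untransmitted diploid gamete and the untransmitted CDJP allele.
- **Association testing**: per SNP, a two-sided Wilcoxon signed-rank test on
  the paired differences Z1 − Z2 (zero differences dropped, mid-ranks,
  tie-corrected normal approximation with continuity correction);
  transmission counts T/U of minor alleles transmitted/untransmitted from
  heterozygous parents; odds ratio OR = T/U with
  CI = exp(ln(T/U) ± 1.96·√(1/T + 1/U)); family-wise error control by
  **min-p permutation** (a fair coin per trio swaps case and pseudo-control
  at all SNPs simultaneously, preserving linkage disequilibrium).
- **QC filters**: exact Hardy–Weinberg test on parental genotypes
  (discard p < 10⁻⁴) and a filter on SNPs where the two callers disagree in
  more than 25% of children.
- **A synthetic-trio generator** reproducing the design's statistical
  structure (HWE parents, per-trio nondisjunction with optional reduction to
  homozygosity, multiplicative disease-risk ascertainment, Gaussian
  probe-ratio noise), so every stage is testable without restricted data.

The estimators follow scikit-learn conventions (`fit`, `get_params`,
fitted attributes with trailing underscores) and compose with sklearn
pipelines; module-level functions are thin wrappers.

## Worked example

The package ships the genotypes of 26 trisomic case triads at rs2837770
(chromosome 21, *DSCAM* intron 3) as a fixture:

```python
import trisoscan as ts

triads = ts.load_rs2837770_triads()   # 26 trios x 1 SNP
results = ts.scan(triads)
print(results[["snp_id", "n_het_parents", "p_nominal", "T", "U",
               "or_hat", "maf_cases", "maf_pseudos"]])
```

or from the shell:

```console
$ trisoscan associate src/trisoscan/data/rs2837770_triads.tsv --out res.tsv
rs2837770	p=0.000150386	het_parents=24	T=26	U=7	OR=3.71
$ trisoscan report res.tsv
   snp_id  position minor_allele major_allele  maf_pseudos  maf_cases p_nominal  T  U  or_hat  ci_low  ci_high
rs2837770  40956222            A            G         0.31       0.55   0.00015 26  7    3.71    1.61     8.56
```

Reading the row: of the 52 parents, 24 are heterozygous and therefore
informative. The cases carry the minor allele at frequency 0.55 versus 0.31
in their pseudo-controls; 26 minor alleles were transmitted from heterozygous
parents against 7 untransmitted, an odds ratio of 3.71 (95% CI 1.61–8.56) in
favour of minor-allele over-transmission, and the Wilcoxon signed-rank test
on the 26 paired dosage differences gives p = 0.00015.

A full synthetic pipeline, end to end:

```console
$ trisoscan simulate --n-trios 26 --n-snps 500 --seed 7 --out sim.tsv
$ trisoscan permute sim.tsv --permutations 1000 --seed 8 --out scan.tsv
```

Under the null (no `--relative-risk`), no SNP should reach a small
permutation-adjusted p; plant a signal with
`--relative-risk 2.5 --causal-index 250` to see the scan recover it.

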