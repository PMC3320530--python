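# citrus-snp

Population-genetic analysis of SNP-array genotypes in a stratified,
clonally propagated gene pool, written for the *Citrus* situation:
a marker panel ascertained in one heterozygous genotype (Clementine-
style BAC-end mining), basic taxa with strong allele-frequency
divergence, interspecific hybrid cultivars with fixed heterozygosity,
frequent **null alleles** (alleles giving no array signal, whose
heterozygous carriers look like ordinary homozygotes), and an F1
progeny of a wide cross used as a segregation control.

The package provides, as an importable library plus numbered analysis
drivers:

* **Marker classification (C1–C8).** Each locus is assigned from call
  rate, the discovery genotype, chi-square segregation tests in the F1
  progeny (including null-allele cross models such as 0B×AB, 00×AB,
  00×0A) and germplasm polymorphism; valid sets WONA (= C2+C5, no null
  alleles) and WNA (= C3+C4+C6, with nulls) are selected under a 5%
  missing-data ceiling, and transferability is reported as
  WONA/(WONA+WNA).
* **Diversity.** Ho, Nei He = 1 − Σp², F = 1 − Ho/He, multilocus
  genotype counts, genotypic diversity GD = 1 − Σg² and null-homozygote
  frequencies for the null-allele sets, and Weir–Cockerham
  Fis/Fit/Fst from summed per-locus variance components with jackknife
  standard errors.
* **Structure.** Simple-matching dissimilarity
  d = 1 − (1/L)Σ mₗ/2, neighbor-joining with locus-bootstrap supports,
  and covariance PCA with active/supplementary individuals (hybrids
  projected onto axes defined by parental pools; per-locus cos² tracks
  pairwise Fst).
* **Linkage disequilibrium.** Composite r² on 0/1/2 dosages with
  seeded permutation p-values, contrasting the structured germplasm
  against the panmictic-equivalent F1 progeny.
* **Parentage.** Trio scoring by Mendelian incompatibility counting
  plus a null-robust "allele absent in both parents" counter, with
  hypothesis ranking.
* **Comparative mapping.** Species × species matrices of within- and
  shared-polymorphism locus counts.
* **Synthetic data.** A Balding–Nichols generator reproducing all of
  the above structure with ground-truth labels (`citrus_snp.synthetic_data`),
  so every estimator is tested against known truth.

## Worked example

```sh
python analysis/01_simulate.py
python analysis/02_classify_markers.py
python analysis/03_diversity.py
```

prints (seed 42, the default scenario):

```
simulated 95 accessions × 600 loci (seed 42)
true category spectrum: {'C1': 35, 'C2': 78, 'C3': 10, 'C4': 43, 'C5': 378, 'C6': 8, 'C7': 17, 'C8': 31}

selected 451 WONA + 50 WNA loci (99 excluded); transferability 90.0%
category recovery vs generator truth: 98.2%

WONA (451 loci), all-sample Ho 0.216, He 0.328
WNA (50 loci): null-homozygote frequency highest in medica_like (0.66), lowest in reticulata_like (0.10)
all WONA : Fst 0.488 ± 0.015, He(discovery taxon) 0.187  (n=432)
CHet     : Fst 0.386 ± 0.033, He(discovery taxon) 0.355  (n=72)
CHom     : Fst 0.518 ± 0.018, He(discovery taxon) 0.149  (n=338)
```

Reading this: the classifier recovers 98% of the generator's true
categories; null homozygotes concentrate outside the discovery taxon
(0.66 in the citron-like pool vs 0.10 in the mandarin-like pool, the
transferability pattern expected when primers come from one taxon);
and the ascertainment contrast is visible — loci chosen because the
discovery genotype is heterozygous (CHet) inflate diversity inside its
own taxon (He 0.355 vs 0.149) and deflate between-taxa differentiation
(Fst 0.386 vs 0.518) relative to loci homozygous in it (CHom).
Scripts 04–07 add the bootstrap NJ tree, the two-taxon PCA with
supplementary projection (cos²–Fst r² ≈ 0.91), the germplasm-vs-
progeny LD contrast (mean r² 0.093 vs 0.020), parentage ranking and
the mappability matrices, all under `results/`.

The same stages run as one reproducible pipeline with a manifest:

```sh
citrus-snp run --config run.yaml --out-dir results/run1
```

and each stage exists as a CLI subcommand (`simulate`, `classify`,
`diversity`, `tree`, `pca`, `ld`, `parentage`, `mapmatrix`,
`export-vcf`).

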