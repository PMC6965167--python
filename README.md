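# mhcdivkit

Population-genetic and functional-diversity analysis for a single, highly
multi-allelic MHC class II locus — the bovine *BoLA-DRB3* exon 2, whose β1
domain carries the peptide-binding region (PBR) that determines which
peptides an animal can present to CD4⁺ T cells. The package is aimed at
researchers characterizing MHC allele repertoires in livestock populations
from sequence-based typing data: it takes an allele catalog (FASTA), a
per-animal genotype table, and a PBR position mask, and asks two questions:

1. **How genetically diverse and differentiated are the populations?**
   Allele-frequency spectra with bootstrap CIs; observed and Nei's unbiased
   expected heterozygosity (h_o, h_e = n/(n−1)(1 − Σp²)); Weir–Cockerham
   F_IS and the conditional exact test of Hardy–Weinberg proportions;
   segregating sites S and nucleotide diversity π; net divergence
   Π_net = Π_AB − (Π_A + Π_B)/2; Weir–Cockerham θ (F_ST); Nei's
   D_A = 1 − Σ√(x_i y_i); neighbor-joining dendrograms with
   animal-resampling bootstrap support; metric MDS (with an RSQ fit
   statistic) and PCA of allele frequencies with allele loadings; and
   Nei–Gojobori dN/dS with Jukes–Cantor correction
   (d = −¾·ln(1 − 4p/3)) and a codon-bootstrap Z-test for positive
   selection, separately for the whole β1 fragment and for PBR codons.

2. **How functionally diverse are they?** Per-genotype PBR identity and
   similarity percentages (similar = identical residue or BLOSUM62 score
   > 0), randomized-subset one-way ANOVA with Bonferroni pairwise tests, a
   31 × 20 position-by-residue frequency profile per population (alleles
   above 5% frequency, renormalized) flattened to a 620-coordinate
   covariation vector, Pearson correlations between population vectors with
   metric MDS of the 1 − PCC distances, and distinct-PBR counting (alleles
   that differ only synonymously or outside the mask present the same
   repertoire).

A seeded synthetic-data module generates study-shaped datasets — diploid
populations with a tunable inbreeding coefficient f (per-animal forced
homozygosity, so E[h_o] = (1 − f)(1 − Σp²)) and allele pools with a
nonsynonymous mutation excess concentrated at PBR codons — so every stage is
testable without access to restricted genotype data.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
dataset shaped like the original one (four populations, N = 30/41/40/54,
f = 0.27, 40-allele pool, 5× nonsynonymous excess at the 31 PBR codons):

```
python analysis/01_simulate_study.py
python analysis/02_diversity.py
```

prints, among other things:

```
population  N  N_a    h_o    h_e   F_IS  HWE_p
    Cn_Nor 30   19 0.7000 0.9181 0.2406 0.0021
    Cc_Nor 41   20 0.6341 0.9094 0.3053 0.0006
    Cb_Nor 40   19 0.6750 0.9006 0.2529 0.0015
    Sp_Mor 54   26 0.7407 0.9278 0.2032 0.0016
```

Every population shows the injected heterozygote deficit: h_o well below
h_e, F_IS in the 0.20–0.31 range around the generator's f = 0.27, and small
Hardy–Weinberg exact-test p-values. `analysis/03_selection.py` then shows
dN > dS concentrated at PBR codons (e.g. dN_PBR ≈ 0.45 vs dS_PBR ≈ 0.11,
one-tailed p < 10⁻³) — the balancing-selection signature the generator
plants — while `analysis/04_structure.py` reports pairwise F_ST ≈ 0.05–0.08,
the D_A neighbor-joining tree with bootstrap supports, and an MDS RSQ of
0.98, and `analysis/05_pbr_covariation.py` summarizes per-genotype PBR
similarity and the global mean Pearson correlation (≈ 0.76) between the
populations' 620-coordinate PBR composition vectors.

`analysis/06_published_summaries.py` reproduces the desk-checkable
arithmetic of the published allele-frequency table: the eight pooled-
Normande high-frequency alleles account for 55.6% of gene copies, the four
Morucha ones for 51.9%, the two alleles shared by all three Colombian
regions for 16.1%, and the pooled *048:02 frequency reconstructed from
regional gene-copy counts is 0.099.

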