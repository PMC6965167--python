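# Methods

This note records the statistical conventions the package implements, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical corner cases.

## The setting

One autosomal locus (MHC class II DRB3 exon 2), treated as a gap-free
alignment of equal-length in-frame allele sequences, typed in diploid
animals grouped into labeled populations. Exon 2 encodes the β1 domain; a
user-supplied mask of 31 one-based amino-acid positions marks the
peptide-binding region (PBR). Allele names are opaque strings. Because only
one locus exists, every multi-locus convention (bootstrapping loci,
averaging over loci) has a documented single-locus substitute.

The reading frame of the exon fragment is not standardized across
laboratories, so a `frame_offset ∈ {0, 1, 2}` (bases trimmed from the 5'
end before translation) is part of the dataset definition, defaulting to 0.
Sequences that translate with an internal stop are excluded from the catalog
and reported, never silently dropped.

## Allele diversity

* **Frequencies** are direct counts over 2N gene copies. Confidence
  intervals are percentile bootstrap over animals (default 10,000
  resamples), clipped to [0, 1]; degenerate spectra (allele fixed or
  absent) return degenerate intervals. A finite-population small-sample CI
  algorithm exists in the literature for this kind of data but is not
  described reproducibly, so the bootstrap is used throughout and printed
  CI bounds from prior work are not comparison targets.
* **Heterozygosity**: h_o is the fraction of heterozygous animals; h_e is
  Nei's unbiased estimator n/(n−1)(1 − Σp²) with n = 2N. h_e of a
  monomorphic sample is 0; N = 1 is an error (the correction is undefined).
* **F_IS** is the Weir–Cockerham (1984) single-population f̂ =
  1 − Σc/Σ(b+c), per-allele variance components summed over alleles.
  Monomorphic samples raise an error rather than returning 0: "no
  variation" is not "no inbreeding".
* **Hardy–Weinberg exact test**: conditional on the observed allele counts.
  Two alleles: Levene's full enumeration over heterozygote counts. More
  alleles: Monte-Carlo — genotype tables are drawn by randomly re-pairing
  the observed 2N gene copies (an i.i.d. sample from the conditional null),
  and p is the share of tables whose conditional probability
  (∝ 2^h / Π n_ab!) is ≤ the observed table's, with the add-one correction
  (hits+1)/(steps+1). Default 100,000 tables. The i.i.d. permutation
  sampler replaces the usual Markov-chain walk; it targets the same null
  and needs no burn-in or mixing diagnostics.
* **High-frequency summaries** use a strict threshold (frequency > 0.05 by
  default) and report cumulative frequency as a percentage at one decimal.
  Pooling populations reconstructs integer gene-copy counts
  (round(f × 2N)) and re-divides, matching direct counting; pooled
  frequencies are never averages of regional frequencies. Published tables
  sometimes flag an allele as "high-frequency" whose pooled printed value
  rounds to just below the cut; summaries over such a flagged set are
  computed over the named alleles, while threshold summaries stay strict.
* **Randomized subsets** (default 5 sets of 30 animals, without
  replacement) exist to show that h_o does not depend on the original
  sample size.

## Sequence diversity and selection

* **S** counts alignment columns with ≥ 2 distinct bases among the distinct
  alleles present (presence-based; frequencies ignored).
* **π** = n/(n−1) Σᵢⱼ xᵢxⱼ dᵢⱼ per site (n = 2N gene copies, d = p-distance),
  equal to the mean difference over all C(n,2) gene-copy pairs.
* **Net divergence** Π_net = Π_AB − (Π_A + Π_B)/2. The within-population
  terms enter *uncorrected* (plain Σ xᵢxⱼ dᵢⱼ) so that Π_net(A, A) = 0
  exactly; with the n/(n−1) correction the identity would miss by π/n.
  Π_net can be legitimately negative when within-population diversity
  exceeds between-population divergence. Values are per site by default;
  a per-sequence variant (× alignment length) is also emitted, since
  pairwise-difference heat maps in the literature are often per sequence.
* **dN/dS** follows Nei–Gojobori (1986): synonymous site counts per codon
  are degeneracy fractions (at each codon position, the fraction of the
  three possible changes that are synonymous; changes to stop codons count
  as nonsynonymous capacity, so S + N = 3 × codons exactly); differences
  average equally over all minimal mutational pathways between two codons,
  excluding pathways through stop codons (waived if all pathways hit
  stops); p_S = S_d/S and p_N = N_d/N are Jukes–Cantor corrected,
  d = −¾ ln(1 − 4p/3), with p ≥ 0.75 a saturation error that excludes the
  pair (reported). Population-level d_N, d_S are unweighted means over all
  distinct-allele pairs — the population's allele *set*, not its genotype
  frequencies, carries the selection signal; a frequency-weighted variant
  is a one-line change on the pair list but is not the default.
* **Z-test**: Z = (d_N − d_S)/√(Var d_N + Var d_S), variances by bootstrap
  over codon columns (default 1000 replicates, seeded), one-tailed normal p
  for positive selection. Zero total variance (no polymorphism) returns
  p = 1 by convention.
* **Null behavior worth knowing**: for stop-free coding sequences the
  NG86 convention makes the neutral expectation of d_N slightly below d_S
  (stop-directed changes are counted as nonsynonymous site capacity but
  never occur — measured on single-step mutations, realized synonymous
  share 0.259 vs site share 0.245), so the one-tailed test is mildly
  conservative (empirical size ≈ 0.01–0.02 at α = 0.05 in the packaged
  simulations) and never anticonservative. Power against a 10×
  PBR-concentrated nonsynonymous excess exceeds 0.8 in the packaged
  simulation.

## Population structure

* **θ (F_ST)**: Weir–Cockerham variance components a (among populations),
  b (among individuals within), c (within individuals), summed over
  alleles; θ = Σa/Σ(a+b+c). Pairwise values are computed on each pair
  alone; jointly monomorphic input is an error. θ is invariant to allele
  relabeling and may be slightly negative in balanced null data.
* **D_A** = 1 − Σ√(xᵢyᵢ) (single-locus form); alleles absent from one
  spectrum contribute 0, so D_A ∈ [0, 1] with 0 iff identical spectra and
  1 iff disjoint allele sets.
* **Neighbor joining** (Saitou–Nei): ties in the Q criterion break on the
  lowest index pair (deterministic, no seed); a negative branch length is
  clamped to 0 with the deficit moved to the sister branch, preserving the
  joined pair's path length. On additive matrices the tree's path-length
  matrix reproduces the input to 1e−9 (tested against random additive trees
  and cross-checked against scikit-bio's NJ).
* **Bootstrap support** resamples animals with replacement within each
  population (the locus cannot be resampled — there is only one),
  recomputes spectra → D_A → NJ, and scores each original bipartition as a
  percentage of replicates (default 10,000).
* **Metric MDS** is classical scaling: double-center −½ D², eigendecompose,
  keep the top-k positive components; missing positive eigenvalues yield
  zero-padded columns and a `rank_deficient` flag. RSQ is defined as the
  squared Pearson correlation between input and embedded distances over all
  pairs (the fit measure the common ordination packages report in spirit;
  the exact formula is fixed here so it is reproducible); RSQ = 1 whenever
  the input is Euclidean-embeddable in k dimensions.
* **PCA** operates on the populations × alleles frequency matrix,
  column-centered, covariance form (frequencies share a scale, so no
  correlation rescaling); scores, non-increasing explained variances, and
  allele loadings per component are returned — the loadings are the
  "which alleles drive the grouping" report.

## PBR similarity and covariation

* Identity % = equal residues / mask length; similarity % additionally
  counts residue pairs with BLOSUM62 score > 0 (the matrix is Biopython's
  standard BLOSUM62; D↔E scores +2 and is similar, D↔K scores −1 and is
  not). Identity ≤ similarity always.
* Population similarity is the mean ± SD over *all* observed genotypes,
  homozygotes included at 100 (an exclude-homozygotes option exists for
  sensitivity analysis). SD is the population convention (÷ n) by default.
* The randomized-subset ANOVA draws one subset of 30 animals per population
  per set (5 sets), runs one-way ANOVA on per-genotype similarity and
  Bonferroni-adjusted pairwise t-tests. Type-I error on null (identical-
  distribution) populations is at the nominal 5% within Monte-Carlo bands.
* The **profile** restricts a population's spectrum to alleles above
  `min_freq` (default 0.05, strict), renormalizes their frequencies to sum
  to 1, and accumulates residue mass per mask position: a 31 × 20 matrix
  (columns in fixed alphabetical one-letter order ACDEFGHIKLMNPQRSTVWY)
  whose rows each sum to 1 and which flattens row-major to the
  620-coordinate covariation vector. Renormalization makes vectors
  comparable across populations with different cumulative high-frequency
  mass (it is what forces PCC = 1 for populations whose >5% sets coincide,
  regardless of rare tails); the un-renormalized variant is available since
  the original procedure leaves this unstated.
* **Covariation**: Pearson correlation between flattened vectors per
  population pair, distance 1 − PCC, metric MDS on that matrix, and the
  grand mean of off-diagonal PCCs as the global covariation figure.

## The synthetic-data generator

The generator produces the statistical structure the estimators are built
to detect, not cattle genetics:

* **Allele pool**: one random stop-free ancestral in-frame sequence;
  each allele applies `mutations_per_allele` point mutations. Proposals are
  uniform over (site, alternative base); a proposal that is nonsynonymous
  *and* in a mask codon is accepted with relative weight `pbr_nonsyn_bias`
  vs 1 (rejection sampling), and stop-creating proposals are always
  resampled. Bias > 1 concentrates amino-acid change in the PBR — the
  dN/dS signal; bias = 1 is the neutral control.
* **Populations**: per animal, with probability f one allele is drawn from
  the frequency vector and duplicated (forced homozygote), otherwise two
  independent draws. This gives E[h_o] = (1 − f)(1 − Σp²) exactly, so
  Weir–Cockerham F̂_IS recovers f (verified: |mean F̂_IS − f| < 0.02 at
  N = 500 for f ∈ {0, 0.27}); f = 0 is exact Hardy–Weinberg sampling.
* **Study-shaped default** (`paper_like_spec`): four populations with the
  sample sizes of the motivating study (N = 30, 41, 40, 54), f = 0.27 (the
  scale of the heterozygote deficiency reported there, F_IS ≈ 0.26–0.31),
  a 40-allele pool with Dirichlet(0.35) frequency vectors (a few common
  alleles over a long rare tail, the shape DRB spectra show), 89 codons
  with a 31-codon mask, 25 mutations per allele, bias 5.

Not emulated: coalescent genealogy shared between alleles, recombination,
selection acting over generations, genotyping error, and linkage to other
MHC loci. Tests passing on these data certify the estimators and the
pipeline plumbing — they do not validate biological conclusions about any
real population.

## Pipeline, seeds, problem sizes

`RunConfig` takes either the three input files or a simulation spec,
a stage subset (validate → diversity → selection → structure → pbr), the
thresholds, and one master seed; each stage's seed is CRC-32 of
"master:stage", so toggling stages never shifts another stage's stream, and
a fixed master seed gives byte-identical outputs. Outputs are TSV matrices
and tables (17 significant digits — lossless round trip), Newick trees, and
a JSON summary plus manifest with stage provenance; `render_report`
re-reads the files so the report always matches them.

Replicate counts mirror the motivating study where it states them (10,000
tree bootstraps; 5 subsets of 30; 100,000 HWE tables) and these remain the
library defaults. The packaged analysis scripts and the test suite use
smaller, stated sizes chosen to keep a full run on one CPU in minutes
(e.g. 2,000 tree bootstraps, 20,000 HWE tables, 500-replicate calibration
loops) with Monte-Carlo tolerance bands widened accordingly; all are
parameters, not constants.

## Known limitations

* The 31 PBR positions are an input; the package ships no canonical mask
  (the literature's set traces to structural work on human/mouse DR and is
  not printed in the motivating study).
* Bootstrap CIs for allele frequencies are not comparable to
  finite-population CI algorithms printed in older tables.
* The codon Z-test's mild conservatism under neutrality (above).
* Pairwise-difference and F_ST heat-map conventions differ across software
  (per-site vs per-sequence; corrected vs uncorrected within-diversity);
  both variants are emitted and labeled rather than guessing one.
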