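# Methods

This note documents the models behind `phylopan`, the defaults of the
synthetic study, the numerical choices, and what the passing tests do and
do not establish about real data.

## The scientific question

Marker-gene identity (typically 16S rRNA) is the standard currency for
grouping bacteria into operational taxonomic units. The package quantifies
three ways this currency can fail within a genus:

1. **Identity vs. relatedness** — pairwise marker identity against
   average nucleotide identity (ANI) and shared/unshared ortholog counts;
2. **Topology vs. topology** — Robinson–Foulds discordance between the
   marker tree, the core-genome tree, and a gene-content (Jaccard/UPGMA)
   dendrogram;
3. **Signal vs. topology** — Blomberg's K of each metabolite computed
   against each of the three trees, asking whether "this trait tracks
   phylogeny" depends on which phylogeny you ask.

## Synthetic study design

The generator produces data with the statistical structure the analysis
assumes; it is the package's test bed, not a genome simulator.

- **Species tree**: pure-birth (Yule) with `n_taxa = 16` tips,
  `birth_rate = 1`, rescaled to a root-to-tip depth of 0.1 expected
  substitutions/site. Yule is the minimal homogeneous branching model and
  leaves tree shape to chance; depth 0.1 puts the most divergent genome
  pairs near 82% ANI, the within-genus range the analysis targets.
- **Sequence evolution**: Jukes–Cantor, site-independent, uniform base
  frequencies. JC is deliberately the simplest model: it gives a
  closed-form expected identity, 1/4 + 3/4·e^(−4d/3), used as the
  generator's own oracle, and a closed-form distance for tree building.
- **Marker vs. core rates**: the marker alignment (1,500 bp) evolves at
  rate multiplier 0.05, the concatenated core alignment (10,000 sites) at
  1.0. The 20-fold ratio is the regime of interest — with a 0.1-deep tree
  the marker accumulates ≤1% divergence, so *every* strain pair sits
  inside the conventional 97% OTU cutoff while core genomes diverge
  measurably. 10,000 core sites keep neighbor joining in its consistent
  regime (topology recovery is itself a tested property).
- **Gene content**: core families (200) are universal and immune to loss.
  Accessory families follow an infinitely-many-families gain/loss process:
  along a branch of length L, Poisson(1500·L) new families arise and each
  present family survives with probability e^(−5L); the root carries 100
  accessory families. With total tree length ≈ 0.5 this yields several
  hundred families, most of them clade-restricted or strain-specific —
  qualitatively the long rare tail of real pangenome spectra, not its
  64,000-family scale.
- **Family sequences**: each family has a root sequence (length uniform
  300–1,500 bp) evolved down the whole tree at the core rate; a strain's
  representative is read only where the family is present (the latent
  sequence of an absent family is never used). Genome length is the summed
  length of present families; ANI's unaligned-length accounting therefore
  reflects content differences only, not intergenic DNA.
- **Features**: resistance (20), GCF (40), and CAZy (60) features inherit
  the presence patterns of randomly chosen accessory families — feature
  overlap then tracks gene content by construction. Hallmarks (12) are
  drawn independently at prevalence 0.8, mimicking coarse metabolic
  capabilities that most strains share. Resistance and GCF features carry
  strict/loose and full/fragment flags used as curve pre-filters.
- **Metabolites**: 20 Brownian-motion traits (covariance σ²V from the
  generating tree, σ² = 1) and 20 white-noise traits of matched scale.
  The LC-MS table expands each trait into 5 replicates × 2 ion modes with
  per-metabolite ion efficiencies U(0.3, 1), multiplicative log-normal
  noise (SD 0.1), media-control rows at `control_level = 100`, a 10×
  signal fold over controls, and 10% missing-completely-at-random dropout
  encoded as absent rows. The generator does not emulate retention-time
  drift, batch effects, or intensity-dependent missingness.

## Analysis constants

Defaults mirror the conventions of the field: OTU cutoff 97% (and a
near-identical readout at 99%), core/rare prevalence fractions 0.9/0.1,
clustering cutoffs >75% identity and >75% coverage on both genes (strict
inequalities), ANOVA FDR α = 0.05 (Benjamini–Hochberg), signal α = 0.01
with 1,000 randomizations, 100 bootstrap replicates, marker length filter
±20% of the reference length (closed interval).

## Numerical and design choices

- **Trees by distance methods.** Maximum-likelihood inference is out of
  scope; NJ on JC distances is consistent on additive inputs (tested) and
  deterministic. NJ ties in the Q criterion and UPGMA ties resolve to the
  lowest-index pair. Negative NJ branch estimates are clamped to 0 with
  the deficit moved to the sister edge, preserving the pair's summed
  length. JC distances saturate at d = 5.0 substitutions/site (with a
  warning) when the mismatch fraction reaches 3/4.
- **ANI over shared orthologs.** Fragment-mapping ANI tools need long
  genome sequences; here ANI is the length-weighted mean identity over
  shared-family alignments — the same "identity of pairwise aligned
  regions" quantity, computed on objects the simulation actually has, and
  exactly testable (a 90%/100 bp + 100%/300 bp pair must give 97.5).
- **Marker alignment backends.** Copies of equal length are treated as
  already jointly aligned (the simulator emits gapless MSAs); unaligned
  input goes through one joint mafft alignment of all retained copies, or
  through per-pair global alignment (match 1 / mismatch −1 / gap open −2 /
  extend −0.5). A column containing N counts as non-gap but non-matching.
  Reported identities are rounded to 2 decimals in output files only.
- **Clustering.** Single linkage over the identity/coverage graph; family
  id = lexicographically smallest member gene id. Coverage is the fraction
  of a gene's residues inside mutually non-gapped alignment columns,
  required of *both* genes. The amino-acid vs. nucleotide alphabet is a
  documented difference from annotation-pipeline practice; the cutoff
  semantics are preserved.
- **Blomberg's K.** Computed from the tip covariance V (shared root-to-MRCA
  branch lengths) via the observed/expected MSE ratio; the implementation
  matches R `phytools::phylosig` to 10 decimals on a fixed tree (frozen in
  the tests). The permutation p uses the add-one rule with a ≥ comparison
  and an absolute tie tolerance of 1e-9, so the exact star-tree identity
  (K ≡ 1, hence p = 1) survives floating point. Per-metabolite RNG streams
  are derived from (seed, tree index, metabolite index), making screen
  results independent of iteration order.
- **Singular covariances.** Trees with zero-length branches (e.g. a
  marker tree over near-identical sequences, or a UPGMA content dendrogram
  with duplicate rows) give singular V; a pseudo-inverse is used with a
  warning. Such a tree asserts that some strains are indistinguishable, so
  any trait difference between them is maximally surprising under Brownian
  motion and K collapses toward 0 for every trait. This is an honest
  statement — an unresolved tree cannot support Brownian signal — but it
  means K values on collapsed topologies discriminate poorly; the screen's
  p-values remain valid (they stay near 1). The composition tree's UPGMA
  heights are used as V as-is; they are cluster heights, not evolutionary
  time.
- **ANOVA groups.** The collapsed trait matrix has one value per strain,
  so the pipeline tests group differences on a replicate-level matrix
  (rows = strain × replicate, groups = strains), processed through the
  same imputation and glog/autoscaling stages. Detection "relative to
  media controls" means abundance > mean + 3 SD of that metabolite/mode's
  control rows. The imputation minimum is the matrix-wide minimum positive
  value, halved. glog uses λ = 1.
- **Determinism.** Every stochastic operation takes one integer seed; the
  pipeline derives per-stage sub-seeds from the master seed. Re-running a
  configuration reproduces every output byte-for-byte (tested).

## Problem sizes

The default study — 16 strains, 10 kb core, ~900 gene families, 40
metabolites — was chosen so a full pipeline run completes in seconds and
the entire test suite, including 2,000-replicate K calibration and
1,000-instance brute-force oracles, in well under a minute. Calibration
checks use a fixed 16-tip tree (2,000 Brownian and white-noise traits) and
1,000 null traits at 200 randomizations.

## What passing tests do and do not show

The suite establishes exact algebra (star-tree K, worked NJ/UPGMA/ANI/BH
examples), agreement with independent implementations (phytools, dendropy,
scikit-bio, brute-force oracles), calibration of the simulator against its
own closed forms, and the qualitative incongruence regime on synthetic
data. It does not establish that real 16S/genome/LC-MS data will show any
particular effect size: real rRNA operons have structure-correlated
substitution processes, real pangenomes have lateral transfer between
lineages (gains here are independent, not donor-tracked), and real LC-MS
missingness is intensity-dependent. Known limitations: no
maximum-likelihood trees, no within-strain paralog resolution, no genome
assembly realism (GC content, synteny, intergenic DNA), and
genome–metabolite association scores are consumed, never computed.
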