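# Methods

This package re-creates, as tested and reusable code, a comparative-genomics
workflow for the anthocyanin branch of the flavonoid biosynthesis pathway
(FBP): mining homologs of the seven core enzymes (CHS, CHI, F3H, F3′H, F3′5′H,
DFR, ANS) from two independent annotation sources per species, measuring how
well those sources agree, and summarising gene-family copy number and CDS
lengths. Because no real dual-source annotation bundle ships with the package,
a simulator generates gene families with known history and derives two
corrupted annotation sources from the same truth; every end-to-end claim the
test suite makes is a recovery statement against that ground truth.

## Workflow

1. **Normalisation** (`annotation_io`). Each source provides a nucleotide
   FASTA of annotated transcripts (optionally with a transcript→locus feature
   table, two-column TSV or GFF3). Transcripts that may carry UTRs are reduced
   to their longest forward-strand ORF (ATG to in-frame stop, standard code,
   all three frames); ORFs shorter than 300 nt are rejected. Transcript
   variants are collapsed to the longest sequence per locus (tie-break:
   lexicographically smallest transcript id), except for sources declared
   "primary transcripts only", which pass through. Records whose CDS is >10% N
   are dropped: ambiguity at that level degrades alignment columns downstream
   more than a missing record does.

   The longest-ORF rule replaces a dedicated ORF-inference tool on purpose: the
   workflow only needs UTRs stripped deterministically, and a defined rule is
   testable against an exhaustive (frame, start, stop) enumeration.

2. **Homolog mining** (`search`). A relaxed local similarity search assigns
   genes to enzymes. The reference backend is an in-package Smith–Waterman
   aligner (match +1, mismatch −1; a gap of length k costs 5 + 2k) with
   Karlin–Altschul E-values, E = K·m·n·e^(−λS). For ±1 scoring on uniform base
   composition λ = ln 3 exactly; K is fixed at 0.333, the conventional ungapped
   value, applied to gapped scores as a documented approximation. The cutoff
   E ≤ 1e−50 separates family members from unrelated CDS by tens of orders of
   magnitude, so nothing downstream depends on E-value precision. A gene hit
   by several enzymes' seeds is assigned to the enzyme giving its best score;
   the two CYP75 hydroxylases (F3′H, F3′5′H) are additionally pooled for joint
   tree analysis because they descend from one cytochrome-P450 subfamily.

3. **Pair classification** (`pairs`). Within each (species, enzyme), the two
   sources are matched by reciprocal best hits. A pair is *perfect* iff the
   two CDS are identical strings — the only symmetric reading of "100%
   identity over 100% of the length"; all other RBH pairs are *imperfect*,
   recording alignment identity and a length ratio (longer/shorter). Leftover
   genes are *unpaired*; an unpaired gene whose CDS duplicates another gene of
   the same source is excluded as redundant. Exact RBH ties (identical-sequence
   groups, e.g. recent duplicates) are resolved by a deterministic matching:
   queries in id order take the smallest unused tied partner. A pure
   "lexicographically smallest subject" rule would send every member of an
   identical group to the same partner and spuriously unpair the rest, which
   contradicts the clean-channel requirement that uncorrupted sources agree
   perfectly.

4. **Trees and rescue** (`phylo`). Per enzyme (CYP75 jointly), the union of
   both sources' non-excluded genes is aligned, trimmed and built into a tree:

   * *Alignment*: deterministic progressive alignment — neighbor joining on
     k-mer (k = 6) distances gives the guide tree; profiles are merged by
     global affine alignment with free end gaps (annotation discrepancies are
     concentrated at CDS boundaries). Profile columns score by expected
     match/mismatch; the MSA scheme is +2/−1 with gap open 10 / extend 2, which
     keeps homologous columns positive down to ~33% identity — necessary for
     the joint CYP75 alignment, where +1/−1 would leave deep subfamilies
     unaligned.
   * *Trimming*: codon-mode block filtering. A codon column is good iff its
     gap fraction is ≤ b5 (default 0.5) and its majority codon is shared by
     ≥ b2 (default 0.5) of non-gap rows; runs of good columns shorter than
     b4 = 5 codons are discarded. This is a simplified, testable analog of
     conserved-block trimming; at deep divergences it is aggressive, and when
     it removes everything the pipeline logs a warning and builds the tree
     from the untrimmed alignment rather than failing.
   * *Tree*: neighbor joining on pairwise GTR distances,
     d = −tr(Π log(Π⁻¹F)) with F the symmetrised divergence matrix of the pair
     and Π its average base composition; gamma rate heterogeneity is
     approximated by replacing −log x with α(x^(−1/α) − 1) on the eigenvalues
     (default α = 1; exact joint ML optimisation of GTR+Γ is out of scope).
     Saturated or degenerate pairs are capped at distance 10. Branch supports
     come from a nonparametric bootstrap over codon columns (resampling whole
     codons preserves within-codon correlation); supports are only computed
     when requested, since the rescue rule does not condition on support.
   * *Rescue*: unpaired genes from different sources that form a same-species
     two-leaf sister clade (cherry) are merged into one imperfect pair with
     `rescued_by_tree=True`. The cherry is the strictest reading of "a unique
     cluster" and minimises false rescues; a `clade` mode (any minimal clade
     with exactly one unpaired leaf per source and no paired leaves) and a
     minimum-support option (default 0) are available. Tree leaves are named
     `<gene_id>|<A/B>` because both sources may annotate a gene under the same
     id.

   For the CHS family, which is a large paralogous superfamily, trees can be
   rooted on a designated outgroup leaf set: the root goes on the edge whose
   bipartition best separates outgroup from ingroup (exact edge when the
   outgroup is monophyletic, best-agreement edge with a warning otherwise).

5. **Summaries** (`summary`). The concordance report counts perfect /
   imperfect / unpaired / excluded per source and enforces the accounting
   identity totalₐ = perfect + imperfect + unpairedₐ + excludedₐ (likewise for
   B). Copy-number matrices count per (enzyme, species, source) with
   discrepancy and zero flags; the final merged gene set keeps one member per
   pair, preferring source A (the NCBI-style annotation) for consistency.
   Length statistics are mean ± SD per (enzyme, source, category); the SD is
   the population (n-denominator) form, chosen because strata can be tiny and
   a convention had to be fixed.

## The simulator

`simulate` generates the study conditions:

* **Families.** A birth–death process (duplication λ, loss μ, events per unit
  branch length) runs along a species tree; every surviving tip lineage is a
  true gene. Defaults: λ = 7.0, μ = 0.6 on a 21-taxon ultrametric tree of
  depth 0.3 substitutions/site, giving ≈ e^((λ−μ)·0.3) ≈ 6.8 copies per
  species per family and on the order of a thousand true genes across seven
  families — enough duplication structure to exercise paralog confusion in
  RBH and tree rescue. The 21-taxon default tree is a synthetic stand-in
  assembled from the taxonomy of the sampled clades (8 Solanaceae, Ipomoea,
  3 Lamiales, Coffea, 4 campanulids, 4 rosid outgroups); its topology and
  depths are package choices, not published estimates.
* **Sequences.** Root CDS are random non-stop codon strings (default 900 nt,
  ATG…TAA). Substitutions follow JC or HKY (default κ = 2) with the rate
  matrix scaled to one expected substitution per site per unit length. First
  and last codons are held fixed and codons that would become internal stops
  are redrawn, so every true gene remains a valid ORF; the unprotected
  per-branch kernel is exposed separately and is what the closed-form
  calibration tests use. The two CYP75 family roots descend from a shared
  ancestor (0.1 substitutions/site each), so their joint alignment is
  meaningful.
* **Corruption.** Independently per source and gene: missed entirely
  (p = 0.1); UTR flanks added (p = 0.3), which with probability 0.5 include an
  in-frame upstream ATG that shifts the inferred CDS start (a visible
  boundary discrepancy) and otherwise leave the inferred CDS unchanged
  (pyrimidine-only flanks cannot create starts or stops, so the longest-ORF
  rule provably recovers the true CDS); in-frame truncation (p = 0.1, never
  below 300 nt); extra transcript variants (Poisson, mean 0.3) that
  normalisation must remove; identical within-source duplicates (p = 0.05).
  The truth table stores, per emitted record, the category this corruption
  implies under the classifier's own rules (string-identical → perfect, both
  present → imperfect, one side → unpaired, unpaired duplicating a same-source
  CDS → excluded), so "recovery" is exact bookkeeping, not heuristic.

### What the simulator does not model

Codon-usage bias, selection, indels within coding regions, introns/genome
coordinates, assembly errors, and cross-contamination between sources. Passing
tests therefore demonstrate that the *pipeline logic* is sound under the
stated discrepancy modes, not that it would reach the same accuracy on real
annotations, where mis-assembly and fragmented gene models add failure modes
the channel does not emulate.

## Numerical and problem-size choices

* Alignment kernels are exact dynamic programming (numba-compiled); the local
  aligner is verified against an independent optimal aligner in the tests.
* NJ can emit slightly negative branch lengths; they are clamped to zero.
* The analysis drivers and acceptance checks run at sizes chosen to keep a
  full run in minutes on one core: the clean-channel check uses 10 species
  with λ = 3.0, μ = 0.5; the conservation check uses 20 seeds on a 6-taxon
  tree with 600 nt roots; the recovery check runs the full default
  (~1000-gene) configuration once; bootstrap supports default to 0 in the
  shipped drivers and are switched on per tree when wanted.
* All randomness flows through numpy Generators seeded from a single
  configuration seed; identical seeds give byte-identical FASTA output.

## Known limitations

* The E-value model uses ungapped λ, K on gapped scores; fine for
  thresholding at 1e−50, not for reporting publishable E-values.
* The codon-majority trimming rule is stricter than classic conserved-block
  trimming at deep divergence; the untrimmed fallback keeps the workflow
  alive but such trees should be read with care.
* Distance NJ with an α = 1 gamma correction is a stand-in for full ML tree
  search; topologies within species complexes of near-identical paralogs are
  effectively arbitrary, which the rescue rule tolerates (it only needs
  near-identical cross-source copies to be sisters).
* RBH is computed within (species, enzyme); orthology across species is
  deliberately out of scope.
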