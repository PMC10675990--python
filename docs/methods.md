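# Methods

This note documents the models and procedures implemented in `evescout`,
the defaults they ship with, what the synthetic generator does and does not
emulate, and the design choices made where the problem left the design open.

## The inference problem

Given a fragmented assembly of a repeat-rich host genome, a table of viral
marker-gene hits, per-base sequencing depth from one or more read datasets,
transcript alignment loci, and biallelic SNP read counts, the package asks:
which regions are viral, how complete are they, are they resident in the
nuclear genome or independent episomes, and what is the host's ploidy?

The discriminating logic rests on four observations about a *bona fide*
endogenized element: (1) it is present at the same copy number as its host
chromosome, so its sequencing depth matches the assembly-wide level;
(2) it is embedded in host sequence, so its flanks show host-like (here,
higher) GC content and may carry host genes; (3) it is transcriptionally
silent unless undergoing domestication; and (4) its relative abundance is
stable over time. An active or episomal virus violates (1) — elevated,
fraction-correlated depth — and typically occupies (nearly) the entire
scaffold it assembles into, violating (2).

## Composition binning

Scaffolds are profiled by canonical k-mer frequencies (default k = 5;
a k-mer and its reverse complement share one of the 4^k/2 = 512 canonical
classes, making profiles strand-invariant; windows containing non-ACGT
bases are skipped, not imputed). Profiles are computed over the full
scaffold, matching per-scaffold plotting of composition maps.

Clustering is two-stage. Stage 1 uses only scaffolds at or above a length
threshold (default 33 kb) whose profiles are stable enough to define
clusters: profiles are projected onto the leading principal components
explaining ≥ 90 % of variance (minimum 2 kept) and clustered with
seed-fixed k-means, the cluster count chosen by silhouette over 2..10.
Stage 2 assigns each shorter scaffold to the nearest stage-1 centroid in
the projection space. The *core* is the cluster with the greatest summed
stage-1 scaffold length (ties: more members, then lexicographically
smallest member id); all other clusters are *satellites*. The reference
workflow this emulates identified satellite islands by visual inspection of
a nonlinear embedding; the silhouette-based count selection is this
package's deterministic, testable stand-in and is not claimed to reproduce
any particular embedding. Scaffold ids are sorted internally, so the
partition is invariant to input order.

## Fragment assembly from marker hits

Homology search is out of scope; hits arrive as a table (scaffold,
interval, strand, marker, clade, score). Hits are merged per clade into
fragments, bridging gaps ≤ `max_gap` (default 2,000 bp — wide enough to
span intergenic gaps at typical viral gene density, narrow enough not to
fuse neighboring elements). Merging per clade, rather than pooling all
clades, keeps a small element nested inside a larger element of another
clade (e.g., a complete PLV genome interrupting a giant-virus region) as
its own fragment; an alternative pooled mode assigns each merged fragment
the score-weighted plurality clade of its member hits (ties to the highest
single score). Merging is idempotent, and fragments of one clade on one
scaffold are disjoint.

Derived quantities:

- **Viral fraction** of a scaffold: union length of its fragments divided
  by scaffold length; a scaffold is "nearly entirely viral" when the
  fraction exceeds 0.9.
- **Nine-marker tally** (NCLDV fragments only): the count of distinct core
  giant-virus phylogenetic markers present; a fragment is eligible for
  multigene phylogenetic treatment when it carries at least three of the
  nine. The marker set ships as configuration (default RNAPL, RNAPS,
  TFIIS, VLTF3, MCP, pPolB, A32, D5, RNR) and is explicitly provisional —
  consumers with their own marker vocabulary override it.
- **Completeness**: fragment length over the clade's complete-genome
  reference length; "(near) complete" at ≥ 0.9 (inclusive), values > 1
  reported as-is. Defaults: PLVA/PLVB 24.5 kb (midpoint of the 19.5–29.5 kb
  complete-genome range), PLV2 15.1 kb (midpoint of 14.6–15.6 kb), NCLDV
  400 kb; CHeCME has no defined reference, so completeness is not
  applicable rather than guessed.
- **Census**: per clade, total bp covered, MCP-named hit count, and
  (near)-complete count. When a fragment of one clade lies strictly inside
  a fragment of another, the inner span is subtracted from the outer
  clade's coverage, so an interrupted element contributes only its net
  sequence (a 418 kb giant-virus region with a 23 kb PLV insert counts
  395 kb).

## Terminal inverted repeats

A TIR is a prefix of the element whose reverse complement appears at the
element's end. The detector considers the first and last `window` bp
(default 1,000), compares the prefix window against the reverse complement
of the suffix window along every alignment diagonal, and takes the
best-scoring ungapped segment (score = matches − mismatches; the
maximum-sum segment per diagonal, computed by a vectorized running-minimum
scan, ties resolved toward longer then 5'-most). A segment qualifies when
its length ≥ `min_len` (default 50) and its mismatch fraction ≤
`max_mismatch_frac` (default 0.1); absence of any qualifying pair is a
valid result. Indels are not modeled: the target repeats are short, and the
mismatch-only formulation keeps the detector checkable against an
exhaustive all-pairs scan, which the test suite does on short sequences.
When the unconstrained optimum on a diagonal violates the mismatch budget,
the detector falls back to the best valid fixed-length window greedily
extended — a borderline regime that planted-TIR and random-null inputs do
not enter.

## Endogenization diagnostics

- **Assembly median depth**: the median over per-scaffold median depths,
  weighting scaffolds equally; robust to a handful of high-copy scaffolds.
- **Relative depth** of a fragment: median depth inside the fragment over
  the assembly median. The median resists the uneven read recruitment that
  multi-locus repeat families produce; the windowed profile (default
  1,000 bp windows) uses means for smoothness. `r ≈ 1` means the region is
  in a 1:1 ratio with the host genome; the band [0.5, 2.0] ("within
  2-fold") is the host-like range, configurable.
- **GC differential**: GC%(usable flank) − GC%(fragment), flanks up to
  `flank_len` (default 5,000 bp) on each side, excluding bases inside any
  other viral fragment and beyond scaffold ends; reported as NA when the
  usable flank is shorter than `min_flank_used` (default 500 bp). The
  defaults are a compromise between composition stability (longer is
  steadier) and locality (shorter stays near the element); neither value
  is prescribed by the motivating study. Positive values mean GC-richer
  flanks, the expected direction for these AT-rich elements. The
  dispersion across a cohort is reported as SD.
- **Fraction–depth correlation**: Spearman rank correlation between
  per-scaffold viral fraction and relative depth (scaffold mean over
  assembly median, a continuous summary), with a seed-fixed permutation
  null (default 999 permutations). Endogenized cohorts show no
  correlation; episomal contamination shows depth rising with viral
  fraction. Fewer than 3 scaffolds or a constant column yields NA.
- **Transcript silence**: count of transcript loci overlapping any
  fragment by ≥ 1 bp, and distinct sequence-identity keys among them.
  Identity keys are an input column (clustering transcripts by sequence is
  out of scope); (0, 0) is "transcriptionally silent".
- **Temporal stability**: relative depth in dataset B over relative depth
  in dataset A, each normalized by its own assembly median; stable within
  the same [0.5, 2.0] band. NA when the fragment has zero depth in A.
- **Integration call**: `endogenized` when relative depth lies in the
  host-like band AND host context exists (computable flank GC or an
  annotated host gene in the flank); `episomal-like` when the scaffold is
  nearly entirely viral AND depth exceeds the band; otherwise `ambiguous`.
  A complete high-depth whole-scaffold virus with no flanks is thus
  deliberately ambiguous — depth alone cannot distinguish a recent
  endogenization from an episome, and that uncertainty is preserved rather
  than resolved by fiat.

## Ploidy inference

Input is a biallelic SNP table of ref/alt read counts (a VCF-with-AD path
is provided via the 12-column/BLAST-style readers for hits; SNP calling
itself is upstream). Filtering keeps sites with total depth ≥ `min_depth`
(default 20) and allele frequency within (0.02, 0.98).

For each candidate ploidy P ∈ {2..8}, alt counts are modeled as

    alt_i ~ Σ_{k=1}^{P-1} w_k · Binomial(n_i, p_k),
    p_k = (k/P)(1 − ε) + (1 − k/P) ε

with ε the per-read error rate (default 0.01). Peak locations are fixed by
P; only the weights are free, estimated by EM from a uniform start
(deterministic; tolerance 1e−8 on the log-likelihood, ≤ 500 iterations;
the log-likelihood is non-decreasing by construction and asserted so in
tests). Model selection minimizes BIC = −2 lnL + (P−2) ln n; P = 2 has a
single forced component and zero free parameters. Freeing peak locations
was rejected: it breaks identifiability between neighboring ploidies at
realistic depth. Candidates are capped at 8 because higher-ploidy peaks
(spacing < 1/8) are unresolvable at depth ~100. Note that composite
ploidies contain their divisors' peaks (P = 4 includes the 1/2 peak), so
the BIC penalty is what keeps a diploid from being over-fit as tetraploid;
the converse — recognizing a true tetraploid — rests on the 1/4 and 3/4
components carrying substantial weight.

## Synthetic data: what it emulates, and what it does not

The generator plants ground truth for every downstream contract:

- Host scaffolds with i.i.d. bases at P(G or C) = `base_gc` (study-scale
  default 0.514). Element sequence is i.i.d. at `base_gc + gc_offset`
  (default −10 percentage points, AT-richer than host, matching the
  observed direction of the flank differential; the true magnitude for any
  real element family is unknown, so it is a parameter, not an assertion).
- TIRs as exact reverse complements at element termini; nested insertions
  (with parent pointers, so net spans are computable); per-element copy
  numbers realized by the depth simulator as coverage multipliers —
  an element appears once in the assembly and its extra genomic copies
  manifest as depth, which is exactly how a collapsed repeat behaves.
- Per-base depth ~ Poisson(mean_depth · copy_number · dataset_factor),
  dataset_factor = 1 + drift per additional dataset (default drift 0,
  emulating two libraries years apart with no abundance change; default
  mean depth 50, in the range of short-read genome projects).
- Marker layouts tile elements with gene-sized intervals (900 bp at 500 bp
  spacing, first at the element start and last flush with its end),
  emulating the gene-dense organization of these viruses; hit tables drop
  markers at rate `fnr`, jitter endpoints uniformly in ±`jitter_bp`, and
  add Poisson-rate spurious hits.
- Tetraploid (by default) allele counts with uniform dosage k ∈ 1..P−1 and
  binomial sampling at depth 100 and ε = 0.01, n = 2,000 sites — sizes at
  which ploidy recovery is reliable but not trivial.

Deliberately not emulated: read-level artifacts (the depth model skips
mapping entirely), codon/gene structure inside elements (markers are truth
annotations, not realized ORFs — homology search is out of scope),
realistic retroelement sequence, GC-dependent coverage bias, and assembly
fragmentation/collapse. Consequently, passing tests demonstrate the
*inference logic* — recovery of planted signals through the package's own
readers, mergers, and estimators — not robustness to mapper bias, chimeric
scaffolds, or diverged element families, which only real data can probe.

All generator randomness flows from explicit integer seeds (the pipeline
derives per-stage streams from one master seed by fixed offsets); identical
seeds give byte-identical outputs.

## Coordinates and formats

0-based half-open everywhere in memory and in BED; depth TSVs
(samtools-style 3-column) and GFF3 are 1-based on disk and converted at
the IO boundary. FASTA via Biopython; every writer's output round-trips
through the package's reader.

## Problem sizes in the test suite

Tests run the study conditions at desk scale: the end-to-end recovery check
uses a 10 Mb, 100-scaffold genome with 20 planted elements; the GC
differential cohort 50 elements; depth discrimination 10 seeds of a 1.4 Mb
layout with a 10-copy episome; ploidy recovery 50 replicates per ploidy in
{2, 3, 4, 6}; clustering 10 seeds of 40 + 10 scaffold mixtures; the null
correlation 10–12 simulation seeds with 999-permutation tests. The original
study's headline counts (thousands of viral scaffolds, >1,500 MCP genes)
require the real ~1 Gb assembly and ~186 Gb of reads and are not
reproduced here; the package reproduces the *procedures* and verifies them
by parameter recovery on generated data.

## Known limitations

- The clade of a merged fragment comes from its hits; misassigned hits
  propagate (no composition-based re-checking of clade labels).
- The TIR detector is ungapped; indel-containing TIRs are found only if a
  mismatch-tolerated ungapped core survives.
- The silhouette-chosen cluster count always returns ≥ 2 clusters when two
  or more long scaffolds exist; a perfectly homogeneous assembly is split
  into arbitrary composition halves (the core/satellite labeling remains
  meaningful only when real structure exists).
- The ploidy model assumes a single genome-wide ploidy; mixed or segmental
  states (aneuploidy, subgenome divergence) are out of scope.
- The permutation p-value for the fraction–depth correlation is a
  significance summary, not a calibrated test under scaffold-length
  heterogeneity.
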