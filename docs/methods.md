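# Methods

## Model and pipeline

The pipeline treats a fusion gene as a DNA-level rearrangement that joins
the leading exons of a 5′ partner to the trailing exons of a 3′ partner,
transcribed from the 5′ partner's promoter and spliced so that the chimeric
mRNA contains one novel exon–exon junction.  Three layers of evidence are
modeled separately, because they fail independently in real data:

1. **Fragment-level** — paired-end fragments whose mates map uniquely into
   the two partners (discordant pairs).  This is the discovery signal; it
   is cheap but confounded by expression level, which is why candidate
   scores are expression-normalized (SPER/DASPER/RESPER, formulas in the
   README).  Mapping is exact (no mismatch/indel/splice within a read) and
   multi-mapping mates are discarded rather than rescued: on repetitive
   sequence the uniqueness requirement substitutes for mappability filters.
   No insert-size or orientation filter is applied, and junction reads
   whose overhang happens to be homologous to the other partner are *not*
   discarded — both filters are known to remove true positives of exactly
   the kind this analysis is after.
2. **Splice-junction level** — single-end split alignments of untrimmed
   reads crossing the chimeric exon–exon junction, requiring ≥ 8 exact nt
   on each side (`min_overhang`, configurable).  Annotated exon boundaries
   are preferred when decomposing a read; unannotated same-contig gaps must
   look intron-like (≥ 20 nt); cross-contig (chimeric) splits are accepted
   only at annotated boundaries.
3. **DNA level** — reads straddling the genomic fusion point, found by
   mapping each 76-nt read's two 17-nt ends as a synthetic pair onto the
   two-gene reference (genes ± 1 kb), keeping reads whose ends satisfy:
   different genes; either end inside the coverage-suspected break intron;
   neither end repeat-masked.  Each retained read is decomposed into its
   maximal exact prefix in the 5′ gene and maximal exact suffix in the 3′
   gene.  The overlap of the two maximal extensions equals the junction
   micro-homology *h*, and the break coordinate in each gene is knowable
   only up to a width-*h* interval — this is an identifiability limit of
   the data, not an algorithmic artifact.  Calls aggregate over reads by
   majority, ties going to the widest homology; a call needs
   `min_breakpoint_support = 2` reads (configurable; no published minimum
   exists).  Somatic status requires tumor support and zero matched-normal
   support.  When junction reads exist but no DNA-level read does, the
   event level is reported as "undetermined" rather than forced.

The reading-frame check is arithmetic: the fusion is in frame iff the 5′
partner's coding length up to the junction plus the GTF frame of the 3′
junction exon is `0 (mod 3)`.  Named 3′-partner domains wholly downstream
of the junction are reported as retained only in frame.

## Synthetic data: what it emulates, and what it does not

`simgen` generates a small genome (default 8 genes × 4 exons, exons
150–250 nt, introns 300–600 nt, both strands represented, ~22 kb total), a
planted fusion, and reads:

- **Tumor genome** is diploid-style: the wild-type contig is kept intact
  and a rearranged allele (`chr1_t`), equal to `wt[:b5] + wt[b3:]`, is
  added.  Break positions are searched inside the designated introns so
  that exactly *h* context bases match and the homology cannot be extended
  on either side; positions sit 40–120 nt into the intron so exome flank
  capture reaches the junction (the "fortuitously captured" intron effect).
- **RNA-seq**: fragments drawn per-gene ∝ expression weight, insert
  ~ Normal(250, 30) truncated to the read length, unstranded (fragments
  flipped with p = ½), qualities constant.  A configurable
  `premrna_fraction` (default 0.01) of fragments come from the unspliced
  pre-mRNA — the only RNA source of DNA-junction reads; the default is a
  calibration choice consistent with intronic reads being a ~1% minority,
  not a published value.  Base errors default to 0 because the mapper
  forbids mismatches; the error-rate knob exists to measure sensitivity
  loss.
- **Fusion study conditions** (`fusion_study_weights`): fused transcript
  weight 15, wild-type 3′ partner silent (weight 0), all other genes 1.
  This is the promoter-swap expression pattern — the kinase partner is
  expressed only through the fusion — and it is what produces the per-exon
  coverage discontinuity used to suspect break introns.  Under uniform
  weights there is no discontinuity and the validation stage correctly
  reports none.
- **Exome**: fragments uniform over merged exon ± flank (150 nt) windows,
  fully contained in a window.  Capture weights are separate from
  expression weights (a silent gene is still captured); setting one high
  emulates copy-number amplification for the ledger's amplicon rule.
  Normal-tissue exome always uses the wild-type genome when the fusion is
  somatic.
- **Cohort expression**: log2-scale Normal(6, sd) baseline; activated
  samples shifted ± log2(fold) on signature genes by direction; outlier
  samples shifted strongly on one target gene.

Coding sequences are built so the frame check and conceptual translation
agree *exactly*: codon streams avoid stop codons; a 9-nt cassette
(`GTAAGTAAG`) at a codon boundary in every exon guarantees a stop in both
shifted frames; and the first coding base of every exon is `C` so no
chimeric junction codon can form a stop.  Consequently "in frame ⇔ no
premature stop under direct translation" holds as an equivalence on random
fusions — a property real genomes only approximate.

Not emulated: sequencing error profiles and quality strings, PCR
duplicates, multi-isoform genes, overlapping genes, structural variants
other than the single fusion, GC/mappability bias, and stranded library
chemistry.  Passing tests therefore demonstrate the *logic* of each stage
under its stated assumptions, not robustness to real-data noise; the
mismatch-free mapper in particular would lose sensitivity roughly in
proportion to `1 − (1−e)^76` at per-base error rate `e`.

## Numerical and design choices

- Internal coordinates are 0-based half-open everywhere; GTF's 1-based
  inclusive convention is converted only at file boundaries.  `N` bases
  never match during exact mapping (strictest reading of "no mismatch").
- k-mer index defaults to k = 17 so the dual-17 ends are single-lookup
  queries; the split mapper seeds with k = 8 (the minimum overhang).
- Candidate 5′/3′ orientation: per discordant pair the 5′ gene is the one
  whose mate aligned on that gene's sense strand; majority vote across
  pairs, ties lexicographic.
- `p_G` floors at `1/M` so a silent gene (exactly the promoter-swap
  situation) cannot zero out the expectation term.
- With a single candidate, RESPER is identically 1 and DASPER identically 0
  (the expectation saturates), so the strict `> 1.0` filters would empty a
  one-candidate survey; the survey output therefore lists all scored
  candidates with a `pass_filter` column rather than dropping rows.
- Amplicon rule threshold 3.0×: published evidence excludes 6–12× cases and
  tolerates < 2×; 3.0 splits that evidence and is configurable.  Copy
  number is window mean depth over genome-wide median window depth, which
  presumes roughly uniform (WGS-like) background; capture data with large
  uncovered gaps inflates folds and should use a window near the capture
  target size.
- Coverage discontinuity: first inter-exon boundary where one side's mean
  depth ≥ 5 and the other side is more than 10× lower (both configurable).
- Junction-spanning reads (both the detector and the simulator's truth
  table) require ≥ 8 nt on each side: overhangs of 1–2 nt are not
  junction-specific, since micro-homology makes h-base overhangs ambiguous
  by construction.
- Signature derivation compares linear-scale ratios with an inclusive
  2-fold boundary, both directions, exclusions applied last.  Activity
  scoring is the cosine core of nearest-template prediction; per-gene
  z-scoring across the cohort makes it invariant to any per-gene affine
  transform.  Resampling-based significance is deliberately out of scope —
  the similarity itself is the reported activity.
- Degenerate inputs: zero-depth cohorts survive outlier detection through a
  MAD floor of `0.1·median + ε`; an empty candidate list yields an empty
  ledger; a read with no exact decomposition yields "no confident fusion
  point" rather than a forced call.

## Problem sizes

Tests and the acceptance script run entirely on generated data: ~22 kb
genomes, 2 000–5 000 read pairs per sample, 20 seeds per stochastic claim,
cohorts of 100–160 samples × 300 genes, 5 001-gene profiles for signature
derivation.  These sizes were chosen so each claim is measured with enough
replication to be stable while the whole suite stays interactive.

## Known limitations

- The exact FusionSeq score formulas are not public in the source analysis;
  the SPER/DASPER/RESPER definitions here implement the stated contract
  (per-million support, expression-based expectation, ratio to the sample
  average) and are pinned by this package's own tests, not by an external
  reference implementation.
- The misannotation rule requires an explicit joining-transcript table;
  live EST/cDNA lookup is out of scope.
- Split mapping considers at most two segments per read, which suffices for
  a single junction but not for reads crossing two junctions.
- The breakpoint resolver assumes both partners on the + strand of one
  contig (the generator constructs fusions that way); inversion-type
  fusions are not modeled.
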