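# Methods

## The problem

Multiple displacement amplification (MDA) lets a single microbial cell be
whole-genome amplified and sequenced, but the amplified product is a poor
substrate for assembly: locus-to-locus coverage is severely biased, whole
stretches of the genome drop out, and the polymerase produces chimeric
molecules that join noncontiguous — sometimes inverted — genomic segments.
A single-cell amplified genome (SAG) assembled naively is fragmented and
error-prone, and pooling several SAGs of the same strain accumulates each
cell's private artifacts while averaging away real within-strain variation.

This package implements a three-step workflow that turns several SAG read
sets from one strain into a *composite single-cell genome*:

1. **Grouping.** SAGs are grouped when their 16S rRNA V3–V4 fragments are
   ≥99% identical and the average nucleotide identity (ANI) between their
   raw contigs exceeds 95%, computed over local alignments of ≥500 bp.
   Contigs under 500 bp are excluded throughout.
2. **Cross-reference cleaning.** Each SAG's quality-controlled reads are
   mapped onto raw contigs assembled from the *other* SAGs of the group,
   so that an artifact private to one amplification cannot confirm
   itself. A read is *clean* when complete alignments are at least as
   frequent as partial (soft-clipped) ones, *potentially chimeric* when
   partial alignments dominate, and *unmapped* otherwise. Potential
   chimeras are cut at the boundaries of their best partial alignment;
   fragments of at least 20 bp re-enter the next cycle, shorter pieces
   are discarded. Cycles repeat until no potential chimeras remain.
3. **Co-assembly and bridging.** Clean reads from all SAGs are
   co-assembled into clean composite contigs, raw reads into raw
   composite contigs. A raw composite contig that aligns to clean contigs
   at ≥99% identity over ≥250 bp may bridge two clean contigs (or extend
   a contig end); the raw contig contributes only the gap between its two
   anchor alignments, clean sequence taking precedence everywhere else.

On top of the workflow sit a within-strain SNP caller (cleaned reads per
SAG mapped back onto the composite), QUAST-style evaluation metrics, and
a ground-truth simulator that makes all of it testable without external
data.

## Parameters that matter

| parameter | default | role |
| --- | --- | --- |
| QC low-quality rule | ≥50% of bases < Q25 | discard read |
| QC 3' trim | terminal bases < Q20 | stepwise single-base trim (no window) |
| QC length / N rules | <20 bp, ≥1% N | discard read; mate discarded with it |
| 16S identity | ≥99% (inclusive) | grouping edge, V3–V4 fragment |
| ANI | >95% (exclusive), alignments ≥500 bp | grouping edge; length-weighted mean identity |
| `max_clip_for_complete` | 9 bp | total clip still counted as a complete alignment |
| `min_fragment_len` | 20 bp | chimera-fragment floor (≥20 kept) |
| bridging anchors | ≥99% identity over ≥250 bp | raw contigs usable for joins/extensions |
| SNP site rule | depth ≥5, ≥99.9% mismatching, homogeneous alternate | per-SAG site classification |
| SNP call rule | ≥2 matched and ≥2 unmatched SAGs | both "multiple", per site |

Notes on the judgement calls:

* **Complete vs partial.** Any soft clipping marks an alignment partial
  in the strict reading, but real aligners clip a few terminal bases
  spuriously. A total clip of up to 9 bp (safely below the 20 bp fragment
  floor) counts as complete; `max_clip_for_complete=0` restores the
  strict rule. Frequencies are counts of all alignment records (primary,
  secondary, supplementary) against the cross-reference.
* **Grouping linkage.** Thresholded pairwise similarities define a graph;
  single-linkage components become groups — the most permissive reading
  of grouping by pairwise thresholds. A SAG with no recoverable 16S
  fragment (rRNA operons are often missing from partial SAGs) is grouped
  on ANI alone and flagged.
* **Split template.** The single best partial alignment (largest aligned
  length; ties broken by leftmost query start, then target id) defines
  the cut. Remapping in later cycles corrects suboptimal cuts, and the
  total tie-break order makes cleaning deterministic.
* **Bridging conflicts.** One accepted proposal per clean-contig end,
  greedy by descending anchored length; circular paths are rejected
  (union-find). This deliberately refuses multi-joins — the failure mode
  the cleaning step exists to remove. Gap sequence containing N is never
  inserted.
* **SNP thresholds.** "Multiple" is read as ≥2 for both the matched and
  the unmatched SAG sets (configurable). At depths below 1000 the
  inclusive ≥99.9% threshold means every read must mismatch, which is the
  operative regime at depth ≥5; homogeneity (all mismatching reads carry
  one identical base) gets no slack. Base qualities are not consulted.
  Sites where *no* SAG matches the reference are rejected as assembly
  errors rather than polymorphisms.

## Aligner and assembler backends

Mapping, ANI, bridging anchors and evaluation all go through one adapter
contract. Two backends exist:

* the **internal aligner**: exact 15-mer seeds every 4 bp (plus the final
  offset, so every ≥20 bp window contains a seed) with ungapped x-drop
  extension (match +1, mismatch −3, drop 12), reporting all distinct
  per-diagonal local matches on both strands. Seeds of 15 bp are the
  largest size guaranteed to land inside a 20 bp chimera arm, the
  smallest fragment the workflow keeps. The aligner models substitutions
  only — the chimera model it serves is a junction between ungapped
  segments, and the simulator produces no indels.
* a **bwa mem** subprocess adapter (`-a`, secondary alignments kept) for
  real data.

Assembly is strictly an adapter: the production backend is SPAdes with
single-cell flags (`--careful --disable-rr --sc`); the test backend
(`TruthAssembler`) maps reads onto the *known* simulated genome and emits
read-covered intervals (merged within 1 kb, the amplification-window
scale) as contigs. The stub is a deliberately perfect assembler: assembly
quality is not what the cleaning and bridging logic is being tested on,
and no assembly algorithm is part of this package's contract.

## What the simulator emulates — and what it does not

Per-SAG amplification is modelled as independent lognormal weights
(σ = 0.8 by default) on 1 kb windows, with a 20% dropout fraction zeroed
outright; read start positions follow the weights. Chimeras are two
independently placed arms (each ≥20 bp), the second reverse-complemented
with probability 0.5 (relocations and inversions equally likely).
Sequencing error is substitution-only; contaminant reads come from a
second random genome; strain SNPs are planted at chosen positions and
carried by a fixed ⌈fraction·n⌉ subset of SAGs. Every read carries a
truth label (arm intervals, strands, contaminant flag).

Default conditions — 500 kb genome, 6 SAGs, 2,000 reads of 300 bp per
SAG, 15% chimeric reads — put single-SAG raw coverage at ≈52–55%, inside
the 50–80% regime the generator is meant to reproduce; read length
matches the 2×300 bp regime such data sets are sequenced at. The model
makes no claim of mechanistic MDA fidelity: there is no branching
process, no inverted-repeat preference at junctions, no platform error
profile, no indels, and quality strings are constant (Q35, Q20 at error
positions) so the QC filters are exercised by explicit fixtures instead.
Consequently, passing tests show the *logic* of classification,
splitting, bridging and SNP calling is correct under its stated
assumptions — not that the thresholds are optimal for any particular
real instrument or polymerase.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; SAM's 1-based positions
  convert at the parser boundary, and positions are 1-based again in the
  TSV/VCF output.
* Quality encoding is fixed Phred+33; input that looks Phred+64 is
  rejected, never guessed.
* Ungapped extension trims alignments back to the score maximum in each
  direction, so an alignment ends at the last base that improves the
  score. When the genome coincidentally continues like the read past a
  chimera junction, the cut point is shifted by those bases — a local
  ambiguity no aligner can resolve; the affected fragments are still
  split and recovered, just not at the exact truth base.
* ANI is symmetrized as the mean of the two directed length-weighted
  means; alignments shorter than 500 bp never contribute.
* `nx_ngx` returns 0 when the half-target is unreachable (NG50 of an
  incomplete assembly).
* Empty inputs: an all-dropout amplification profile raises ("no
  amplifiable genome"); singleton groups cannot be cross-referenced and
  raise; a SAG whose clean read set is empty is skipped in co-assembly
  with a warning.
* Determinism: all randomness flows from a single seed through
  `numpy.random.default_rng`; pipeline manifests omit absolute paths so
  identical runs in different directories are byte-identical.

## Problem sizes used in the test suite

The acceptance properties run at desk scale: the cleaning/bridging
fixture is the default 6-SAG group above; the SNP experiment uses 8 SAGs
at uniform coverage (9,000 reads/SAG over 500 kb, ~5.4× per SAG) with 20
planted SNPs carried by 3 of 8 SAGs; whole-run determinism is exercised
on a 200 kb, 6-SAG, 1,000-reads/SAG group. Sensitivity of SNP recovery is
asserted on the planted sites that meet the depth-5 precondition in ≥2
carrier and ≥2 non-carrier SAGs, since at ~5× mean coverage a Poisson
minimum below 5 at some sites is expected and carries no information
about the calling rule.

## Known limitations

* The internal aligner is for tests and simulation; real data should go
  through bwa (mapping) and SPAdes (assembly) via the provided adapters.
* Indels are out of model end to end: no indel errors, no gapped
  alignment, no indel calls.
* Paired-end information is not used to rescue or constrain mapping;
  mates are cleaned independently and pairs broken by cleaning are
  emitted as singletons.
* Bridging inserts only gap sequence observed in an anchored raw contig;
  unanchored raw contigs are never used, and circularization of bacterial
  chromosomes is out of scope.
* CheckM-style completeness/contamination, 16S OTU clustering, gene
  annotation and visualization are out of scope; the report schema can
  carry externally computed values.
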